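"""Multivariate and univariate statistics for FA composition tables.

The workflow mirrors common metabolomics practice: a generalized-logarithm
(glog) variance-stabilising transform, PCA on the centered transformed
matrix, Ward/Euclidean hierarchical clustering, Kruskal–Wallis omnibus tests
with Dunn's tie-corrected post-hoc comparisons under Benjamini–Hochberg
control, and Pearson/Spearman correlation.

The glog used is ``glog(x) = log2((x + sqrt(x^2 + lambda^2)) / 2)`` with
``lambda`` defaulting to the smallest positive value of the matrix: it is
monotone, finite at zero, and approaches ``log2(x)`` for ``x >> lambda``.

Significance letters follow the convention where a letter SHARED by two
groups marks a SIGNIFICANT pairwise difference (q < alpha); each significant
pair receives its own letter.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TransformedMatrix",
    "PcaResult",
    "ClusterTree",
    "GroupComparison",
    "CorrelationResult",
    "GlogTransformer",
    "glog",
    "glog_transform",
    "run_pca",
    "hierarchical_clustering",
    "is_monophyletic",
    "to_newick",
    "kruskal_dunn",
    "assign_letters",
    "letters_to_pairs",
    "correlate",
]


# ---------------------------------------------------------------------------
# glog transform


def glog(x, lam: float):
    """Generalized logarithm, elementwise: log2((x + sqrt(x² + λ²)) / 2)."""
    if lam <= 0:
        raise ValueError(f"glog lambda must be positive, got {lam}")
    x = np.asarray(x, dtype=float)
    return np.log2((x + np.sqrt(x**2 + lam**2)) / 2.0)


@dataclass
class TransformedMatrix:
    """glog-transformed abundance matrix with its transform parameter."""

    values: pd.DataFrame  # rows = replicate profiles, columns = FA labels
    lam: float


class GlogTransformer(TransformerMixin, BaseEstimator):
    """scikit-learn transformer applying the glog.

    When ``lam`` is None the parameter is learned in ``fit`` as the smallest
    positive value of the training matrix (stored as ``lam_``).
    """

    def __init__(self, lam: float | None = None):
        self.lam = lam

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.lam is not None:
            if self.lam <= 0:
                raise ValueError("lam must be positive")
            self.lam_ = float(self.lam)
        else:
            positive = X[X > 0]
            if positive.size == 0:
                raise ValueError("matrix has no positive value to set lambda")
            self.lam_ = float(positive.min())
        self.n_features_in_ = X.shape[1] if X.ndim == 2 else 1
        return self

    def transform(self, X):
        check_is_fitted(self, "lam_")
        return glog(X, self.lam_)


def glog_transform(matrix: pd.DataFrame, lam: float | None = None) -> TransformedMatrix:
    """glog-transform an abundance table (rows = replicates, cols = FAs)."""
    tr = GlogTransformer(lam=lam).fit(matrix.to_numpy())
    values = pd.DataFrame(
        tr.transform(matrix.to_numpy()), index=matrix.index, columns=matrix.columns
    )
    return TransformedMatrix(values=values, lam=tr.lam_)


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PcaResult:
    scores: pd.DataFrame  # replicate x component
    loadings: pd.DataFrame  # FA x component
    variance_fraction: np.ndarray


def run_pca(matrix: TransformedMatrix | pd.DataFrame, *, center: bool = True) -> PcaResult:
    """PCA by singular value decomposition of the (column-centered) matrix.

    Deterministic up to component sign; the sign is fixed by making the
    largest-magnitude entry of each loading vector positive.  A degenerate
    matrix (single distinct row) yields zero components.
    """
    df = matrix.values if isinstance(matrix, TransformedMatrix) else matrix
    X = df.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs >= 2 rows and >= 2 columns")
    Xc = X - X.mean(axis=0) if center else X.copy()
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / (X.shape[0] - 1)
    keep = var > var.max() * 1e-12 if var.max() > 0 else np.zeros_like(var, bool)
    U, s, Vt, var = U[:, keep], s[keep], Vt[keep], var[keep]
    # sign convention: largest-|.| loading entry positive
    for k in range(Vt.shape[0]):
        if Vt[k, np.argmax(np.abs(Vt[k]))] < 0:
            Vt[k] = -Vt[k]
            U[:, k] = -U[:, k]
    comps = [f"PC{i + 1}" for i in range(len(var))]
    return PcaResult(
        scores=pd.DataFrame(U * s, index=df.index, columns=comps),
        loadings=pd.DataFrame(Vt.T, index=df.columns, columns=comps),
        variance_fraction=var / var.sum() if len(var) else var,
    )


# ---------------------------------------------------------------------------
# hierarchical clustering


@dataclass
class ClusterTree:
    """Agglomerative tree: scipy linkage matrix plus ordered leaf labels."""

    linkage: np.ndarray
    labels: list[str]

    def leaf_sets(self) -> list[set[str]]:
        """Leaf-label set of every internal node, in merge order."""
        n = len(self.labels)
        sets: dict[int, set[str]] = {i: {self.labels[i]} for i in range(n)}
        out = []
        for i, (a, b, _, _) in enumerate(self.linkage):
            merged = sets[int(a)] | sets[int(b)]
            sets[n + i] = merged
            out.append(merged)
        return out


def hierarchical_clustering(
    matrix: TransformedMatrix | pd.DataFrame,
    *,
    method: str = "ward",
    metric: str = "euclidean",
) -> ClusterTree:
    """Deterministic agglomerative clustering of the rows.

    Rows are sorted lexicographically by label before linkage so ties break
    on leaf order, making the tree reproducible.
    """
    df = matrix.values if isinstance(matrix, TransformedMatrix) else matrix
    if df.shape[0] < 2:
        raise ValueError("clustering needs >= 2 leaves")
    df = df.sort_index(kind="stable")
    Z = hierarchy.linkage(df.to_numpy(dtype=float), method=method, metric=metric)
    return ClusterTree(linkage=Z, labels=[str(i) for i in df.index])


def is_monophyletic(tree: ClusterTree, labels) -> bool:
    """Whether ``labels`` form a clade (some cluster equals exactly that set).

    Equivalently: the smallest cluster containing all of ``labels`` contains
    nothing else, i.e. the group merges completely before joining outsiders.
    """
    target = set(labels)
    if len(target) <= 1:
        return True
    return any(s == target for s in tree.leaf_sets())


def to_newick(tree: ClusterTree) -> str:
    """Serialise the tree with branch lengths derived from merge heights."""
    root = hierarchy.to_tree(tree.linkage)

    def walk(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{tree.labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    left = walk(root.left, root.dist)
    right = walk(root.right, root.dist)
    return f"({left},{right});"


# ---------------------------------------------------------------------------
# Kruskal–Wallis + Dunn post-hoc


@dataclass
class GroupComparison:
    variable: str
    h_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # group1, group2, z, p_raw, q
    letters: dict[str, str]
    alpha: float


def _dunn_pairwise(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's z statistics on the joint ranking with tie correction."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for g in names:
        n = len(groups[g])
        mean_ranks[g] = float(ranks[start : start + n].mean())
        sizes[g] = n
        start += n
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (n_total - 1)))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for g1, g2 in itertools.combinations(names, 2):
        se = math.sqrt(base_var * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se
        rows.append(
            {
                "group1": g1,
                "group2": g2,
                "z": z,
                "p_raw": 2.0 * stats.norm.sf(abs(z)),
            }
        )
    return pd.DataFrame(rows)


def kruskal_dunn(
    groups: dict[str, "np.ndarray | list[float]"],
    *,
    alpha: float = 0.05,
    adjust: str = "fdr_bh",
    variable: str = "",
) -> GroupComparison:
    """Kruskal–Wallis omnibus test with Dunn's post-hoc comparisons.

    Pairwise p-values are adjusted over all pairs of the variable with the
    Benjamini–Hochberg step-up procedure by default (``adjust="fdr_by"``
    selects Benjamini–Yekutieli).  Groups with fewer than two values are
    excluded from the post-hoc with a warning.  Letters encode significant
    pairs: two groups sharing a letter differ at q < alpha.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    clean = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    if any(len(v) == 0 for v in clean.values()):
        raise ValueError("groups must be non-empty")
    h, p = stats.kruskal(*clean.values())
    usable = {g: v for g, v in clean.items() if len(v) >= 2}
    dropped = sorted(set(clean) - set(usable))
    if dropped:
        warnings.warn(
            f"excluding group(s) with < 2 values from post-hoc: {dropped}",
            stacklevel=2,
        )
    pairwise = _dunn_pairwise(usable)
    if len(pairwise):
        _, q, _, _ = multipletests(pairwise["p_raw"].to_numpy(), method=adjust)
        pairwise["q"] = q
    else:
        pairwise["q"] = []
    sig = [
        (r.group1, r.group2) for r in pairwise.itertuples() if r.q < alpha
    ]
    letters = assign_letters(sig, list(clean))
    return GroupComparison(
        variable=variable,
        h_statistic=float(h),
        p_value=float(p),
        pairwise=pairwise,
        letters=letters,
        alpha=alpha,
    )


def assign_letters(
    significant_pairs: list[tuple[str, str]], group_names: list[str]
) -> dict[str, str]:
    """One letter per significant pair, attached to both of its groups.

    Follows the shared-letter-means-different convention; groups involved in
    no significant pair get an empty string.
    """
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, list[str]] = {g: [] for g in group_names}
    for i, (g1, g2) in enumerate(sorted(significant_pairs)):
        letter = (
            alphabet[i]
            if i < len(alphabet)
            else alphabet[i // len(alphabet) - 1] + alphabet[i % len(alphabet)]
        )
        letters[g1].append(letter)
        letters[g2].append(letter)
    return {g: ",".join(v) for g, v in letters.items()}


def letters_to_pairs(letters: dict[str, str]) -> set[tuple[str, str]]:
    """Reconstruct the significant-pair set encoded by a letter assignment."""
    by_letter: dict[str, list[str]] = {}
    for group, ls in letters.items():
        for letter in filter(None, ls.split(",")):
            by_letter.setdefault(letter, []).append(group)
    pairs = set()
    for members in by_letter.values():
        for g1, g2 in itertools.combinations(sorted(members), 2):
            pairs.add((g1, g2))
    return pairs


# ---------------------------------------------------------------------------
# correlation


@dataclass
class CorrelationResult:
    n: int
    pearson_r: float | None
    pearson_p: float | None
    spearman_rho: float | None
    spearman_p: float | None
    spearman_p_method: str


def correlate(x, y, *, exact_max_n: int = 8) -> CorrelationResult:
    """Pearson and Spearman correlation of two paired vectors.

    Both coefficients are reported because the appropriate method for a
    7-species summary is debatable.  The Spearman p-value is computed by
    exact permutation enumeration for n <= ``exact_max_n`` (feasible up to
    8! orderings) and by the usual t approximation above that.  Zero
    variance in either vector yields absent coefficients.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-d vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need >= 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(n, None, None, None, None, "undefined")
    pr, pp = stats.pearsonr(x, y)
    rho, sp_approx = stats.spearmanr(x, y)
    if n <= exact_max_n:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = abs(rho)
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r, _ = stats.pearsonr(rx, ry[list(perm)])
            if abs(r) >= obs - 1e-12:
                count += 1
            total += 1
        return CorrelationResult(
            n, float(pr), float(pp), float(rho), count / total, "exact-permutation"
        )
    return CorrelationResult(
        n, float(pr), float(pp), float(rho), float(sp_approx), "t-approximation"
    )
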