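"""Parsing and canonicalisation of fatty-acid shorthand.

Fatty acids (FAs) in GC-MS FAME reports are named with the ``C<carbons>:<double
bonds>`` shorthand, optionally decorated with carboxyl-numbered double-bond
start positions (the delta convention, e.g. ``Δ9,12``) and/or an omega class
giving the position of the terminal double bond counted from the methyl end
(e.g. ``(ω-3)``).  Published tables mix typographic variants of these
decorations (unicode deltas, superscript markers, minus-sign lookalikes); this
module strips the transport noise and returns structured, validated
descriptors.

Conventions
-----------
* Delta positions are carboxyl-based and 1-based; a position ``p`` marks the
  double bond between carbons ``p`` and ``p+1``.
* The omega class counts from the methyl end with the terminal methyl carbon
  as 1, so ``omega = carbons - max(delta_positions)``.
* Saturation class is derived: SFA (0 double bonds), MUFA (1), PUFA (>= 2).

cis/trans isomerism, branched chains and oxygenated FAs are out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "FattyAcidDescriptor",
    "FALabelError",
    "FAConsistencyError",
    "CannotInferOmegaError",
    "parse_fa_label",
    "infer_omega",
    "canonicalize_label",
]


class FALabelError(ValueError):
    """The FA shorthand could not be parsed."""


class FAConsistencyError(FALabelError):
    """The shorthand parsed but its annotations contradict each other."""


class CannotInferOmegaError(ValueError):
    """Omega class requested but no delta positions are available."""


@dataclass(frozen=True)
class FattyAcidDescriptor:
    """Structured identity of one fatty acid.

    Attributes
    ----------
    carbons : int
        Chain length (number of carbons), >= 4.
    double_bonds : int
        Number of C=C double bonds, ``0 <= double_bonds < carbons``.
    delta_positions : tuple of int or None
        Carboxyl-numbered double-bond start positions, strictly increasing,
        each in ``[2, carbons - 1]``; ``None`` when the source label carried
        no positional information.
    omega_class : int or None
        Methyl-end position of the terminal double bond; ``None`` when
        unknown.
    """

    carbons: int
    double_bonds: int
    delta_positions: tuple[int, ...] | None = None
    omega_class: int | None = None
    saturation_class: str = field(init=False)
    label: str = field(init=False)

    def __post_init__(self) -> None:
        if self.carbons < 4:
            raise FALabelError(f"chain length must be >= 4, got {self.carbons}")
        if not 0 <= self.double_bonds < self.carbons:
            raise FALabelError(
                f"double bond count {self.double_bonds} out of range for "
                f"C{self.carbons}"
            )
        if self.delta_positions is not None:
            pos = tuple(int(p) for p in self.delta_positions)
            object.__setattr__(self, "delta_positions", pos)
            if len(pos) != self.double_bonds:
                raise FAConsistencyError(
                    f"C{self.carbons}:{self.double_bonds} lists "
                    f"{len(pos)} delta position(s) for {self.double_bonds} "
                    "double bond(s)"
                )
            if any(b <= a for a, b in zip(pos, pos[1:])):
                raise FAConsistencyError(
                    f"delta positions must be strictly increasing, got {pos}"
                )
            if pos and not all(2 <= p <= self.carbons - 1 for p in pos):
                raise FAConsistencyError(
                    f"delta positions {pos} outside [2, {self.carbons - 1}]"
                )
        if self.omega_class is not None:
            if self.omega_class < 1:
                raise FAConsistencyError(
                    f"omega class must be >= 1, got {self.omega_class}"
                )
            if self.delta_positions:
                expected = self.carbons - max(self.delta_positions)
                if self.omega_class != expected:
                    raise FAConsistencyError(
                        f"omega tag ω-{self.omega_class} contradicts delta "
                        f"positions {self.delta_positions} "
                        f"(imply ω-{expected})"
                    )
        if self.double_bonds == 0:
            sat = "SFA"
        elif self.double_bonds == 1:
            sat = "MUFA"
        else:
            sat = "PUFA"
        object.__setattr__(self, "saturation_class", sat)
        object.__setattr__(self, "label", _canonical_string(self))


def _canonical_string(desc: FattyAcidDescriptor) -> str:
    parts = [f"C{desc.carbons}:{desc.double_bonds}"]
    if desc.delta_positions:
        parts.append("d" + ",".join(str(p) for p in desc.delta_positions))
    if desc.omega_class is not None:
        parts.append(f"n-{desc.omega_class}")
    return " ".join(parts)


# Transport-format noise stripped before parsing: markdown bold markers,
# superscript carets, unicode deltas/omegas and minus-sign lookalikes.
_DELTA_CHARS = "∆Δδ"  # ∆ (increment), Δ, δ
_OMEGA_CHARS = "ωΩ"  # ω, Ω
_DASH_CHARS = "−–—"  # −, –, —

_LABEL_RE = re.compile(
    r"""^C\s*(?P<carbons>\d+)\s*:\s*(?P<db>\d+)
        (?:\s*d\s*(?P<delta>\d+(?:\s*,\s*\d+)*))?
        (?:\s*\(?\s*n\s*-\s*(?P<omega>\d+)\s*\)?)?$""",
    re.VERBOSE,
)


def _normalize(text: str) -> str:
    s = text.strip().replace("**", "").replace("^", "").replace("*", "")
    for ch in _DELTA_CHARS:
        s = s.replace(ch, "d")
    for ch in _OMEGA_CHARS:
        s = s.replace(ch, "n")
    for ch in _DASH_CHARS:
        s = s.replace(ch, "-")
    s = s.replace("w-", "n-").replace("W-", "n-")
    s = re.sub(r"\s+", " ", s)
    return s


def parse_fa_label(text: str) -> FattyAcidDescriptor:
    """Parse FA shorthand such as ``"C20:5 ∆5,8,11,14,17 (ω-3)"``.

    Tolerates superscript markers, bold markers and whitespace/dash variants.
    When only a delta list is given the omega class is inferred from it; when
    both are given they must agree (a contradiction raises
    :class:`FAConsistencyError`, it is never silently corrected).

    Raises
    ------
    FALabelError
        If the text does not match the shorthand grammar.
    FAConsistencyError
        If the delta count differs from the double-bond count, or the omega
        tag contradicts the delta list.
    """
    if not text or not text.strip():
        raise FALabelError("empty FA label")
    m = _LABEL_RE.match(_normalize(text))
    if m is None:
        raise FALabelError(f"cannot parse FA label: {text!r}")
    carbons = int(m.group("carbons"))
    db = int(m.group("db"))
    delta = None
    if m.group("delta"):
        delta = tuple(int(p) for p in re.split(r"\s*,\s*", m.group("delta")))
    omega = int(m.group("omega")) if m.group("omega") else None
    if omega is None and delta:
        omega = carbons - max(delta)
    return FattyAcidDescriptor(
        carbons=carbons, double_bonds=db, delta_positions=delta, omega_class=omega
    )


def infer_omega(desc: FattyAcidDescriptor) -> FattyAcidDescriptor:
    """Return a descriptor with the omega class filled in from the delta list.

    Idempotent: a descriptor that already carries a (consistent) omega class
    is returned unchanged.
    """
    if desc.delta_positions is None:
        raise CannotInferOmegaError(
            f"{desc.label}: no delta positions, omega class cannot be inferred"
        )
    if desc.omega_class is not None:
        return desc
    return FattyAcidDescriptor(
        carbons=desc.carbons,
        double_bonds=desc.double_bonds,
        delta_positions=desc.delta_positions,
        omega_class=desc.carbons - max(desc.delta_positions),
    )


def canonicalize_label(desc: FattyAcidDescriptor) -> str:
    """Deterministic canonical string ``"C<c>:<d>[ d<p1,...>][ n-<ω>]"``."""
    return desc.label
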