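"""Tether-reach arithmetic.

A membrane protein's cytoplasmic tail tethers a binding determinant to the
membrane anchor point.  With hard geometric bounds (no polymer statistics),
the farthest a residue ``n`` inter-residue steps from the anchor can sit from
the membrane is ``n`` times a per-residue rise: ~3.5 Å/residue for a fully
extended chain, 1.5 Å/residue if the tether stays α-helical.  Comparing a
measured binding-site/membrane distance against both reaches decides which
conformational states of the tether are geometrically possible — the central
verdict for whether an amphipathic helix 8 must unfold (leave the membrane)
to reach its receptor site.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ReachModel",
    "ReachVerdict",
    "max_reach",
    "conformational_verdict",
    "tether_length_from_numbering",
]

EXTENDED = "extended"
HELICAL = "helical"


@dataclass(frozen=True)
class ReachModel:
    """Per-residue rise constants (Å/residue) for the two tether states."""

    extended_rise: float = 3.5
    helical_rise: float = 1.5

    def __post_init__(self) -> None:
        if not (self.extended_rise > self.helical_rise > 0):
            raise ValueError("require extended_rise > helical_rise > 0")


@dataclass(frozen=True)
class ReachVerdict:
    """Which tether states can span a measured site–membrane distance."""

    d_min: float
    n_residues: int
    extended_reach: float
    helical_reach: float
    compatible_states: frozenset[str]
    conclusion: str

    def as_dict(self) -> dict:
        return {
            "d_min_angstrom": self.d_min,
            "n_residues": self.n_residues,
            "extended_reach_angstrom": self.extended_reach,
            "helical_reach_angstrom": self.helical_reach,
            "compatible_states": sorted(self.compatible_states),
            "conclusion": self.conclusion,
        }


def max_reach(n_residues: int, state: str, model: ReachModel = ReachModel()) -> float:
    """Maximum membrane reach (Å) of a residue ``n_residues`` steps from the
    anchor, in the given tether state ("extended" or "helical")."""
    if n_residues < 0:
        raise ValueError("n_residues must be >= 0")
    if state == EXTENDED:
        return n_residues * model.extended_rise
    if state == HELICAL:
        return n_residues * model.helical_rise
    raise ValueError(f"unknown tether state {state!r}")


def conformational_verdict(d_min: float, n_residues: int, model: ReachModel = ReachModel()) -> ReachVerdict:
    """Decide which tether states are compatible with a site sitting ``d_min``
    Å from the membrane, ``n_residues`` steps from the anchor.

    A state is compatible iff ``d_min <= max_reach(n, state)``.  The verdict
    "must be unfolded" is issued exactly when the extended chain reaches but
    the helix does not — the geometric signature that the tether has to leave
    its folded, membrane-bound conformation to be bound.
    """
    if d_min < 0:
        raise ValueError("d_min must be >= 0")
    ext = max_reach(n_residues, EXTENDED, model)
    hel = max_reach(n_residues, HELICAL, model)
    compatible = frozenset(
        s for s, reach in ((HELICAL, hel), (EXTENDED, ext)) if d_min <= reach
    )
    if compatible == {EXTENDED}:
        conclusion = "must be unfolded"
    elif not compatible:
        conclusion = "unreachable"
    else:
        conclusion = "either state reaches"
    return ReachVerdict(d_min, n_residues, ext, hel, compatible, conclusion)


def tether_length_from_numbering(anchor_residue: int, contact_residue: int) -> int:
    """Inter-residue step count between an anchor residue and a contact
    residue (author numbering): ``contact - anchor``, not an inclusive count.
    """
    if contact_residue < anchor_residue:
        raise ValueError("contact residue must not precede the anchor residue")
    return contact_residue - anchor_residue
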