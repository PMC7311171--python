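"""Amphipathicity and basic sequence properties.

The hydrophobic moment μH of a sequence treated as an ideal α-helix
(100°/residue helical wheel) is the magnitude of the vector sum of
per-residue hydrophobicities:

    μH = | Σ_n H_n · exp(i·n·δ) | / N,   δ = helical twist in radians.

A high μH marks an amphipathic helix — hydrophobic face on one side, polar on
the other — the hallmark of a membrane-parallel helix 8 at a GPCR's
cytoplasmic membrane interface.  This module also annotates helix-8 windows
(from an annotated TM7 end, or by a helical-periodicity heuristic over the
start of the cytoplasmic tail) and computes length, charge composition and
the theoretical isoelectric point by bisection on the Henderson–Hasselbalch
net charge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import SequenceRecord

__all__ = [
    "HydrophobicityScale",
    "EISENBERG_CONSENSUS",
    "Helix8Annotation",
    "hydrophobic_moment",
    "helical_periodicity",
    "annotate_helix8",
    "sequence_properties",
    "net_charge",
    "isoelectric_point",
]

# Eisenberg normalised consensus hydrophobicity scale — the classical scale
# for hydrophobic-moment analysis of amphipathic helices.
_EISENBERG = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}


@dataclass(frozen=True)
class HydrophobicityScale:
    name: str
    values: dict

    def __post_init__(self) -> None:
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues {sorted(missing)}")

    def __getitem__(self, aa: str) -> float:
        return self.values.get(aa, 0.0)  # X and unknowns contribute 0


EISENBERG_CONSENSUS = HydrophobicityScale("eisenberg-consensus", _EISENBERG)


@dataclass(frozen=True)
class Helix8Annotation:
    """An inclusive helix-8 residue window in one sequence."""

    sequence_id: str
    start: int
    end: int
    source: str = "config"  # config | heuristic
    truncated: bool = False

    @property
    def empty(self) -> bool:
        return self.end < self.start


def hydrophobic_moment(
    seq: SequenceRecord | str,
    scale: HydrophobicityScale = EISENBERG_CONSENSUS,
    twist: float = 100.0,
) -> float:
    """Per-residue mean hydrophobic moment μH of a sequence on an ideal
    helical wheel with the given twist (degrees/residue)."""
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    if len(residues) == 0:
        raise ValueError("cannot compute a hydrophobic moment of an empty sequence")
    h = np.array([scale[aa] for aa in residues], dtype=float)
    n = np.arange(len(h))
    delta = np.radians(twist)
    return float(np.abs(np.sum(h * np.exp(1j * n * delta))) / len(h))


def helical_periodicity(
    seq: SequenceRecord | str,
    scale: HydrophobicityScale = EISENBERG_CONSENSUS,
    twist: float = 100.0,
) -> float:
    """R² of fitting the hydrophobicity profile with one helical-wheel
    harmonic, H_i ≈ a + b·cos(i·δ) + c·sin(i·δ).

    1 means the profile is perfectly periodic at the helical twist (a clean
    amphipathic helix); 0 means no periodic structure.  Returns 0 for
    constant profiles."""
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    if len(residues) < 4:
        raise ValueError("periodicity fit needs at least 4 residues")
    h = np.array([scale[aa] for aa in residues], dtype=float)
    ss_tot = float(np.sum((h - h.mean()) ** 2))
    if ss_tot == 0.0:
        return 0.0
    i = np.arange(len(h))
    delta = np.radians(twist)
    A = np.stack([np.ones(len(h)), np.cos(i * delta), np.sin(i * delta)], axis=1)
    coef, *_ = np.linalg.lstsq(A, h, rcond=None)
    ss_res = float(np.sum((h - A @ coef) ** 2))
    return 1.0 - ss_res / ss_tot


def annotate_helix8(
    seq: SequenceRecord,
    tm7_end: int | None = None,
    window_length: int = 17,
    scale: HydrophobicityScale = EISENBERG_CONSENSUS,
    search_span: int = 25,
) -> Helix8Annotation:
    """Annotate the helix-8 window of a cytoplasmic-tail sequence.

    With ``tm7_end`` (author number of the last TM7 residue) the window is the
    ``window_length`` residues immediately following it.  Without it, the
    heuristic scores every candidate window starting within the first
    ``search_span`` residues of the tail by its helical periodicity — the R²
    of fitting the hydrophobicity profile with a single helical-wheel
    harmonic (see :func:`helical_periodicity`) — and takes the best.  The fit
    R² localises an amphipathic stretch more sharply than the raw μH, which
    rewards windows that pick up incoherent flanking residues by chance.
    Windows running past the sequence end are truncated and flagged.
    """
    last = seq.author_number(len(seq) - 1)
    if tm7_end is not None:
        if not (seq.numbering_offset - 1 <= tm7_end <= last):
            raise ValueError(f"tm7_end {tm7_end} outside sequence numbering")
        start = tm7_end + 1
        end = tm7_end + window_length
        truncated = end > last
        return Helix8Annotation(seq.id, start, min(end, last), source="config", truncated=truncated)
    best_score, best_start = -1.0, seq.numbering_offset
    limit = min(search_span, len(seq) - window_length + 1)
    for i in range(max(limit, 1)):
        window = seq.residues[i : i + window_length]
        if len(window) < window_length:
            break
        score = helical_periodicity(window, scale, twist=100.0)
        if score > best_score:
            best_score, best_start = score, seq.author_number(i)
    end = best_start + window_length - 1
    return Helix8Annotation(seq.id, best_start, min(end, last), source="heuristic", truncated=end > last)


# -- charge and isoelectric point -----------------------------------------

# Bjellqvist-style pKa values (the set behind most "theoretical pI" tools),
# including the residue-specific N-terminal α-amino pKa corrections.
BJELLQVIST_PKA = {
    "positive": {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98},
    "negative": {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0},
    "nterm_by_residue": {
        "A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7,
    },
}


def net_charge(residues: str, pH: float, pka: dict = BJELLQVIST_PKA) -> float:
    """Henderson–Hasselbalch net charge of a peptide at a given pH."""
    pos, neg = pka["positive"], pka["negative"]
    nterm_pk = pka.get("nterm_by_residue", {}).get(residues[:1], pos["Nterm"])
    q = 1.0 / (1.0 + 10 ** (pH - nterm_pk))
    q -= 1.0 / (1.0 + 10 ** (neg["Cterm"] - pH))
    for aa in residues:
        if aa in pos:
            q += 1.0 / (1.0 + 10 ** (pH - pos[aa]))
        elif aa in neg:
            q -= 1.0 / (1.0 + 10 ** (neg[aa] - pH))
    return q


def isoelectric_point(residues: str, pka: dict = BJELLQVIST_PKA, tol: float = 1e-6) -> float:
    """pH of zero net charge, by bisection on the monotone charge curve."""
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(residues, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def sequence_properties(seq: SequenceRecord | str, pka: dict = BJELLQVIST_PKA) -> dict:
    """Length, acidic/basic residue counts and theoretical pI of a sequence."""
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    if len(residues) == 0:
        raise ValueError("empty sequence")
    return {
        "length": len(residues),
        "n_acidic": sum(residues.count(a) for a in "DE"),
        "n_basic": sum(residues.count(a) for a in "KR"),
        "theoretical_pI": isoelectric_point(residues, pka),
    }
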