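"""Short-linear-motif scanning with residue classes and bounded gaps.

Two motif families drive the analyses here:

* the BBSome-binding motif on GPCR helix 8 — an arginine (or lysine) preceded
  by an aromatic residue.  The strict form ``[WFY]R``, the relaxed form
  ``[WFY][KR]`` and a one-gap variant ``[WFY]x[KR]`` (capturing W·CR-type
  arrangements) are kept as distinct patterns and censused separately;
* the canonical PH-domain phosphoinositide-binding motif of the β1–β2 loop,
  ``K x_n [K/R] x R`` with a bounded spacer.

A match is a tuple of element positions satisfying class membership and gap
bounds; overlapping matches are all reported, positions are author-numbered.
``X`` never matches any class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .amphipathic import Helix8Annotation
from .structure import SequenceRecord

__all__ = [
    "MotifPattern",
    "MotifMatch",
    "BBSOME_STRICT",
    "BBSOME_RELAXED",
    "BBSOME_ONE_GAP",
    "pip_motif_pattern",
    "scan_motif",
    "cohort_motif_census",
    "scan_pip_motif",
]


@dataclass(frozen=True)
class MotifPattern:
    """Ordered residue classes with bounded gaps between consecutive classes.

    ``elements[k]`` is a string of admissible one-letter codes; ``gaps[k]``
    is the inclusive (min, max) number of unconstrained residues between
    element k and element k+1 (so ``len(gaps) == len(elements) - 1``).
    """

    id: str
    elements: tuple[str, ...]
    gaps: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if len(self.elements) < 1:
            raise ValueError("pattern needs at least one element")
        if len(self.gaps) != len(self.elements) - 1:
            raise ValueError("need exactly one gap bound between consecutive elements")
        for lo, hi in self.gaps:
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid gap bound ({lo}, {hi})")


@dataclass(frozen=True)
class MotifMatch:
    sequence_id: str
    pattern_id: str
    start: int  # author number of first matched element
    end: int  # author number of last matched element
    matched_text: str
    element_positions: tuple[int, ...] = ()  # author numbers of each element


BBSOME_STRICT = MotifPattern("bbsome[WFY]R", ("WFY", "R"), ((0, 0),))
BBSOME_RELAXED = MotifPattern("bbsome[WFY][KR]", ("WFY", "KR"), ((0, 0),))
BBSOME_ONE_GAP = MotifPattern("bbsome[WFY]x[KR]", ("WFY", "KR"), ((1, 1),))


def pip_motif_pattern(gap_range: tuple[int, int] = (3, 8)) -> MotifPattern:
    """Canonical PIP-binding motif K x_n [K/R] x R with n in ``gap_range``."""
    lo, hi = gap_range
    return MotifPattern(f"pip-Kx{{{lo},{hi}}}[KR]xR", ("K", "KR", "R"), ((lo, hi), (1, 1)))


def _extend(residues: str, pattern: MotifPattern, k: int, positions: list[int], out: list[tuple[int, ...]]) -> None:
    if k == len(pattern.elements):
        out.append(tuple(positions))
        return
    lo, hi = pattern.gaps[k - 1]
    prev = positions[-1]
    for gap in range(lo, hi + 1):
        i = prev + gap + 1
        if i >= len(residues):
            break
        if residues[i] in pattern.elements[k]:
            positions.append(i)
            _extend(residues, pattern, k + 1, positions, out)
            positions.pop()


def scan_motif(
    seq: SequenceRecord,
    pattern: MotifPattern,
    window: tuple[int, int] | Helix8Annotation | None = None,
) -> list[MotifMatch]:
    """All matches of ``pattern`` in ``seq`` whose full span lies inside the
    window (inclusive author-numbered interval; None scans the whole
    sequence).  Overlapping matches are all reported, left to right.
    """
    residues = seq.residues
    if isinstance(window, Helix8Annotation):
        window = (window.start, window.end)
    hits: list[tuple[int, ...]] = []
    for i, aa in enumerate(residues):
        if aa in pattern.elements[0]:
            _extend(residues, pattern, 1, [i], hits)
    matches = []
    for pos in sorted(hits):
        start_n = seq.author_number(pos[0])
        end_n = seq.author_number(pos[-1])
        if window is not None and not (window[0] <= start_n and end_n <= window[1]):
            continue
        matches.append(
            MotifMatch(
                sequence_id=seq.id,
                pattern_id=pattern.id,
                start=start_n,
                end=end_n,
                matched_text=residues[pos[0] : pos[-1] + 1],
                element_positions=tuple(seq.author_number(p) for p in pos),
            )
        )
    return matches


def cohort_motif_census(
    records: Sequence[SequenceRecord],
    pattern: MotifPattern,
    windows: dict[str, Helix8Annotation] | None = None,
) -> tuple[int, int, pd.DataFrame]:
    """Count sequences with ≥1 in-window match of ``pattern``.

    ``windows`` maps sequence id to its helix-8 annotation; missing/None means
    scan the whole sequence.  Returns (n_with_match, n_total, per-sequence
    table).
    """
    rows = []
    n_with = 0
    for rec in records:
        window = windows.get(rec.id) if windows else None
        hits = scan_motif(rec, pattern, window)
        n_with += bool(hits)
        rows.append(
            {
                "sequence_id": rec.id,
                "pattern_id": pattern.id,
                "window_start": window.start if window else None,
                "window_end": window.end if window else None,
                "n_matches": len(hits),
                "matches": ";".join(f"{m.start}-{m.end}:{m.matched_text}" for m in hits),
            }
        )
    return n_with, len(records), pd.DataFrame(rows)


def scan_pip_motif(seq: SequenceRecord, gap_range: tuple[int, int] = (3, 8)) -> list[MotifMatch]:
    """Scan for the canonical PH-domain PIP-binding motif K x_n [K/R] x R."""
    lo, hi = gap_range
    if lo < 0 or hi < lo:
        raise ValueError(f"invalid gap range ({lo}, {hi})")
    return scan_motif(seq, pip_motif_pattern(gap_range))
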