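"""Steric availability of PH-domain lipid-binding sites in a complex.

A PH domain that binds phosphoinositides does so at the canonical (C) site on
the β1–β2 loop, or — rarely — at an atypical (A) site.  Whether either site
is usable inside a larger assembly is decided geometrically: superpose a
lipid-bound template PH domain onto the query PH domain, carry the lipid
over, and count heavy-atom clashes between the placed lipid and the rest of
the complex.  A site with no clash can still be unusable if it sits too far
from the membrane plane for the headgroup to reach the bilayer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from statistics import median
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .geometry import GeometryError, PlaneModel, superpose
from .structure import DomainSelection, StructureModel, read_structure

__all__ = [
    "TemplateComplex",
    "SiteAssessment",
    "place_template_ligand",
    "count_clashes",
    "assess_site",
    "load_template_library",
]


@dataclass
class TemplateComplex:
    """A PH-domain/lipid co-structure used as a placement template: Cα trace
    of the PH domain plus the ligand's heavy atoms, labelled by site."""

    id: str
    site_label: str  # canonical | atypical
    ph_coords: np.ndarray  # (n, 3) Cα
    ligand_coords: np.ndarray  # (m, 3) heavy atoms

    def __post_init__(self) -> None:
        self.ph_coords = np.asarray(self.ph_coords, dtype=float).reshape(-1, 3)
        self.ligand_coords = np.asarray(self.ligand_coords, dtype=float).reshape(-1, 3)
        if self.site_label not in ("canonical", "atypical"):
            raise ValueError("site_label must be 'canonical' or 'atypical'")


@dataclass
class SiteAssessment:
    site_label: str
    clash_count: int
    nearest_blocker: str | None
    membrane_distance: float | None
    verdict: str  # open | blocked | distant
    per_template_clashes: tuple[int, ...] = ()
    superposition_rmsd: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "site_label": self.site_label,
            "clash_count": self.clash_count,
            "nearest_blocker": self.nearest_blocker,
            "membrane_distance_angstrom": self.membrane_distance,
            "verdict": self.verdict,
            "per_template_clashes": list(self.per_template_clashes),
            "superposition_rmsd": self.superposition_rmsd,
        }


def _query_ca(query_ph: StructureModel | np.ndarray) -> np.ndarray:
    if isinstance(query_ph, StructureModel):
        return query_ph.ca_coords()
    return np.asarray(query_ph, dtype=float).reshape(-1, 3)


def place_template_ligand(
    query_ph: StructureModel | np.ndarray,
    template: TemplateComplex,
    min_pairs: int = 20,
) -> tuple[np.ndarray, float]:
    """Superpose the template PH domain onto the query PH domain and carry
    the template ligand into the query frame.

    The Cα correspondence is positional (structure-alignment order); both
    traces must therefore cover the same core in the same order.  Returns
    (ligand coordinates in the query frame, superposition RMSD).
    """
    q = _query_ca(query_ph)
    t = template.ph_coords
    n = min(len(q), len(t))
    if n < min_pairs:
        raise GeometryError(
            f"only {n} alignable Cα pairs between query and template {template.id} "
            f"(need ≥{min_pairs})"
        )
    transform, rmsd = superpose(t[:n], q[:n])
    return transform.apply(template.ligand_coords), rmsd


def count_clashes(
    ligand: np.ndarray,
    environment: StructureModel,
    exclude: Sequence[DomainSelection] = (),
    cutoff: float = 3.0,
) -> tuple[int, str | None]:
    """Number of environment heavy atoms within ``cutoff`` of any ligand
    heavy atom, excluding listed selections (typically the PH domain itself).

    Returns (count, identifier of the domain/chain owning the closest
    clashing atom, or None)."""
    lig = np.asarray(ligand, dtype=float).reshape(-1, 3)
    if lig.size == 0:
        raise ValueError("empty ligand")

    def excluded(a) -> bool:
        return any(
            a.chain_id == s.subunit and s.start <= a.residue_number <= s.end for s in exclude
        )

    env_atoms = [a for a in environment.atoms if a.is_heavy and not excluded(a)]
    if not env_atoms:
        return 0, None
    env = np.asarray([a.position for a in env_atoms], dtype=float)
    tree = cKDTree(lig)
    dmin, _ = tree.query(env)
    clashing = dmin <= cutoff
    n = int(np.sum(clashing))
    if n == 0:
        return 0, None
    closest = env_atoms[int(np.argmin(np.where(clashing, dmin, np.inf)))]
    label = f"{closest.chain_id}:{closest.residue_number}"
    return n, label


def assess_site(
    query_ph: StructureModel | np.ndarray,
    site_label: str,
    templates: Sequence[TemplateComplex],
    environment: StructureModel,
    plane: PlaneModel | None = None,
    exclude: Sequence[DomainSelection] = (),
    clash_cutoff: float = 3.0,
    clash_threshold: int = 1,
    distance_threshold: float = 10.0,
) -> SiteAssessment:
    """Aggregate verdict for one lipid-binding site.

    Each template for the site places its ligand independently; the clash
    count is the median over templates.  The site is *blocked* when the
    median count reaches ``clash_threshold`` (default 1: any clash blocks),
    otherwise *distant* when the placed-ligand centroid sits farther than
    ``distance_threshold`` from the membrane plane (default 10 Å = 1 nm),
    otherwise *open*.
    """
    site_templates = [t for t in templates if t.site_label == site_label]
    if not site_templates:
        raise ValueError(f"no template with site_label {site_label!r}")
    counts, blockers, rmsds, centroids = [], [], [], []
    for tpl in site_templates:
        lig, rmsd = place_template_ligand(query_ph, tpl)
        n, blocker = count_clashes(lig, environment, exclude, clash_cutoff)
        counts.append(n)
        blockers.append(blocker)
        rmsds.append(rmsd)
        centroids.append(lig.mean(axis=0))
    med = int(median(counts))
    blocker = blockers[int(np.argmax(counts))] if med >= clash_threshold else None
    dist = None
    if plane is not None:
        centroid = np.mean(centroids, axis=0)
        dist = float(abs(np.dot(plane.normal, centroid) - plane.offset))
    if med >= clash_threshold:
        verdict = "blocked"
    elif dist is not None and dist > distance_threshold:
        verdict = "distant"
    else:
        verdict = "open"
    return SiteAssessment(
        site_label=site_label,
        clash_count=med,
        nearest_blocker=blocker,
        membrane_distance=dist,
        verdict=verdict,
        per_template_clashes=tuple(counts),
        superposition_rmsd=float(np.mean(rmsds)),
    )


def load_template_library(directory: str | Path) -> list[TemplateComplex]:
    """Load a template library: a directory of PDB files plus a
    ``manifest.json`` listing, per entry, the file, site label, PH-domain
    chain/range and ligand residue names."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    templates = []
    for entry in manifest["templates"]:
        model = read_structure(directory / entry["file"])
        ph = model.subset(
            lambda a, e=entry: a.chain_id == e["ph_chain"]
            and e["ph_start"] <= a.residue_number <= e["ph_end"]
            and a.name == "CA"
            and not a.is_het
        )
        lig = model.subset(
            lambda a, e=entry: a.residue_name in e["ligand_resnames"] and a.is_heavy
        )
        templates.append(
            TemplateComplex(
                id=entry.get("id", entry["file"]),
                site_label=entry["site"],
                ph_coords=ph.coords(heavy_only=False),
                ligand_coords=lig.coords(),
            )
        )
    return templates
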