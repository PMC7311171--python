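"""Quantifying domain rotations between two conformations of a complex.

Protocol: superpose the two models on a stable reference module (for a
BBSome-like complex, the base/corkscrew subunits that do not move on GTPase
binding), then superpose the mobile domain's common Cα atoms and report the
rotation angle of the residual transform.  This turns a qualitative
"the β-propeller swings out" into a single angle in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import GeometryError, RigidTransform, rotation_angle, superpose
from .structure import DomainSelection, StructureModel

__all__ = ["DomainRotationResult", "matched_ca", "domain_rotation"]


@dataclass
class DomainRotationResult:
    angle_deg: float
    base_rmsd: float
    domain_rmsd: float
    n_base_atoms: int
    n_domain_atoms: int
    residual: RigidTransform

    def as_dict(self) -> dict:
        return {
            "rotation_angle_deg": self.angle_deg,
            "base_rmsd_angstrom": self.base_rmsd,
            "domain_rmsd_angstrom": self.domain_rmsd,
            "n_base_atoms": self.n_base_atoms,
            "n_domain_atoms": self.n_domain_atoms,
        }


def matched_ca(
    model_a: StructureModel,
    model_b: StructureModel,
    selections: Sequence[DomainSelection],
) -> tuple[np.ndarray, np.ndarray]:
    """Cα coordinate pairs for residues present in both models within the
    given selections, matched on (chain, residue number, insertion code)."""

    def index(model: StructureModel) -> dict:
        out = {}
        for a in model.atoms:
            if a.name != "CA" or a.is_het:
                continue
            for s in selections:
                if a.chain_id == s.subunit and s.start <= a.residue_number <= s.end:
                    out[(a.chain_id, a.residue_number, a.insertion_code)] = a.position
                    break
        return out

    ia, ib = index(model_a), index(model_b)
    keys = sorted(set(ia) & set(ib))
    if len(keys) < 3:
        raise GeometryError(f"only {len(keys)} common Cα atoms in the selections (need ≥3)")
    return (
        np.asarray([ia[k] for k in keys], dtype=float),
        np.asarray([ib[k] for k in keys], dtype=float),
    )


def domain_rotation(
    model_ref: StructureModel,
    model_alt: StructureModel,
    base_selections: Sequence[DomainSelection],
    domain_selection: DomainSelection,
) -> DomainRotationResult:
    """Rotation of one domain between two conformations, measured relative
    to a shared reference frame.

    ``model_alt`` is first aligned to ``model_ref`` on ``base_selections``
    (the stationary module); the rotation of ``domain_selection`` is then the
    axis–angle magnitude of the transform superposing the aligned domain onto
    its reference-conformation position.
    """
    base_alt, base_ref = matched_ca(model_alt, model_ref, base_selections)
    t_base, base_rmsd = superpose(base_alt, base_ref)
    aligned = model_alt.transformed(t_base.rotation, t_base.translation)
    dom_alt, dom_ref = matched_ca(aligned, model_ref, [domain_selection])
    t_dom, dom_rmsd = superpose(dom_alt, dom_ref)
    return DomainRotationResult(
        angle_deg=rotation_angle(t_dom),
        base_rmsd=base_rmsd,
        domain_rmsd=dom_rmsd,
        n_base_atoms=len(base_alt),
        n_domain_atoms=len(dom_alt),
        residual=t_dom,
    )
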