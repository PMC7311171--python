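"""Membrane-plane placement, constrained orientation search, curvature and
charge analyses for a peripheral membrane complex.

The placement problem: an ARF-family GTPase anchors a complex to the inner
leaflet through its amphipathic N-terminal helix, which sits parallel to the
membrane inside the lipid-headgroup layer.  Given the anchor helix this
module constructs the compatible family of membrane (headgroup) planes:

* the helix axis must be parallel to the plane (within a tolerance),
* the helix Cα centroid sits at a headgroup depth below the plane,
* no heavy atom of the complex may cross the plane by more than a
  penetration tolerance (the protein body stays cytoplasmic).

One rotational degree of freedom remains (the roll of the plane normal about
the helix axis); it is resolved by the helix's own amphipathicity — the
membrane lies on the hydrophobic face, whose direction is fitted as a single
helical-wheel harmonic of the hydrophobicity profile, then nudged to the
nearest feasible roll if the body would otherwise pierce the plane.  The orientation search for the minimum distance between a cargo-site
patch and the membrane scans the full feasible family (roll × tilt) on a
deterministic grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .amphipathic import EISENBERG_CONSENSUS, HydrophobicityScale
from .geometry import CylinderModel, PlaneModel
from .structure import (
    THREE_TO_ONE,
    DomainSelection,
    SelectionError,
    StructureModel,
    select_domain,
)

__all__ = [
    "AnchorSpec",
    "OrientationSearchConfig",
    "InfeasibilityReport",
    "ChargeCensus",
    "place_membrane",
    "min_patch_distance",
    "curvature_compatibility",
    "membrane_facing_charge_census",
]


@dataclass(frozen=True)
class AnchorSpec:
    """The amphipathic membrane anchor: which chain/residues form the anchor
    helix (e.g. the GTPase N-terminus preceding the start of its core domain)
    and how deep it sits in the headgroup layer."""

    chain: str
    anchor_helix_start: int
    anchor_helix_end: int
    anchor_residue: int | None = None  # e.g. the first core-domain residue
    parallelism_tolerance: float = 10.0  # degrees
    headgroup_depth: float = 3.0  # Å below the headgroup plane
    penetration_tolerance: float = 2.0  # Å of allowed crossing

    def __post_init__(self) -> None:
        if self.anchor_helix_start > self.anchor_helix_end:
            raise ValueError("anchor helix range is empty")
        if self.anchor_residue is not None and not (
            self.anchor_helix_start - 1 <= self.anchor_residue <= self.anchor_helix_end + 1
        ):
            raise ValueError("anchor residue must lie within or adjacent to the anchor helix")


@dataclass(frozen=True)
class OrientationSearchConfig:
    """Deterministic grid over the feasible plane family: roll about the
    anchor-helix axis × tilt within the parallelism tolerance."""

    angular_grid_step: float = 2.0  # degrees
    refinement: str = "local"  # none | local
    penetration_tolerance: float = 2.0
    patch: DomainSelection | None = None
    patch_coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (0 < self.angular_grid_step <= 15.0):
            raise ValueError("angular grid step must be in (0, 15] degrees")
        if self.refinement not in ("none", "local"):
            raise ValueError("refinement must be 'none' or 'local'")


@dataclass
class InfeasibilityReport:
    """Returned when no plane satisfies the anchor + non-penetration
    constraints; lists the smallest achievable violation."""

    min_max_penetration: float
    penetration_tolerance: float
    message: str

    @property
    def feasible(self) -> bool:
        return False


@dataclass
class ChargeCensus:
    """Residue-level charge tally within a slab below the membrane plane."""

    slab_depth: float
    positive_count: int
    negative_count: int
    per_residue_table: pd.DataFrame

    @property
    def net(self) -> int:
        return self.positive_count - self.negative_count


# -- anchor-helix geometry -------------------------------------------------


def _anchor_ca(model: StructureModel, anchor: AnchorSpec) -> tuple[np.ndarray, list[str]]:
    try:
        helix = select_domain(
            model,
            DomainSelection(anchor.chain, anchor.anchor_helix_start, anchor.anchor_helix_end, "anchor"),
        )
    except SelectionError as exc:
        raise SelectionError(f"anchor helix unresolvable: {exc}") from exc
    coords, names = [], []
    for cid, num, icode, rname, atoms in helix.residues(anchor.chain):
        for a in atoms:
            if a.name == "CA":
                coords.append(a.position)
                names.append(rname)
                break
    xyz = np.asarray(coords, dtype=float)
    if len(xyz) < 4:
        raise SelectionError(
            f"anchor helix {anchor.chain}:{anchor.anchor_helix_start}-{anchor.anchor_helix_end} "
            f"has only {len(xyz)} Cα atoms (need ≥4)"
        )
    return xyz, names


def _helix_axis(ca: np.ndarray) -> np.ndarray:
    """Helix axis of a Cα trace, oriented N→C.

    For a regular helix the second differences of consecutive Cα positions
    point radially (perpendicular to the axis), so the axis is their smallest
    principal direction — unbiased even for traces covering a non-integer
    number of turns, where the principal axis of the raw coordinates tilts.
    Falls back to the coordinate principal axis for very short traces."""
    if len(ca) >= 6:
        d2 = ca[2:] - 2 * ca[1:-1] + ca[:-2]
        _, s, vt = np.linalg.svd(d2 - d2.mean(axis=0))
        axis = vt[-1]
        if s[1] > 1e-8:  # radial vectors span a plane: axis is well defined
            if np.dot(ca[-1] - ca[0], axis) < 0:
                axis = -axis
            return axis / np.linalg.norm(axis)
    centred = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(centred)
    axis = vt[0]
    if np.dot(ca[-1] - ca[0], axis) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def _hydrophobic_face_direction(
    ca: np.ndarray, resnames: list[str], axis: np.ndarray, scale: HydrophobicityScale
) -> np.ndarray | None:
    """In-plane (⊥ axis) direction of the anchor helix's hydrophobic face,
    hence where the membrane is.

    The per-residue hydrophobicity profile is fitted as a sinusoid of the
    angular position around the helix axis, H_i ≈ a + b·cos ψ_i + c·sin ψ_i,
    by least squares; the face direction is the fitted phase.  Unlike the raw
    hydrophobic-moment vector sum, the intercept and normal equations correct
    for uneven angular sampling of short helices."""
    centroid = ca.mean(axis=0)
    ref = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    h, cos_psi, sin_psi = [], [], []
    for xyz, rname in zip(ca, resnames):
        r = xyz - centroid
        r_perp = r - np.dot(r, axis) * axis
        nrm = np.linalg.norm(r_perp)
        if nrm < 1e-9:
            continue
        h.append(scale[THREE_TO_ONE.get(rname, "X")])
        cos_psi.append(np.dot(r_perp, u) / nrm)
        sin_psi.append(np.dot(r_perp, v) / nrm)
    if len(h) < 4:
        return None
    A = np.stack([np.ones(len(h)), np.asarray(cos_psi), np.asarray(sin_psi)], axis=1)
    coef, *_ = np.linalg.lstsq(A, np.asarray(h), rcond=None)
    b, c = coef[1], coef[2]
    amplitude = math.hypot(b, c)
    if amplitude < 0.3:  # apolar or symmetric helix: no usable face
        return None
    face = b * u + c * v
    return face / np.linalg.norm(face)


def _max_penetration(coords: np.ndarray, normal: np.ndarray, offset: float) -> float:
    return float(np.max(coords @ normal - offset))


def _normal_at(phi: float, tau: float, u: np.ndarray, v: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Unit normal with roll ``phi`` about the helix axis and tilt ``tau``
    toward the axis (both radians)."""
    n0 = math.cos(phi) * u + math.sin(phi) * v
    return math.cos(tau) * n0 + math.sin(tau) * axis


def place_membrane(
    model: StructureModel,
    anchor: AnchorSpec,
    scale: HydrophobicityScale = EISENBERG_CONSENSUS,
    grid_step: float = 2.0,
) -> PlaneModel | InfeasibilityReport:
    """Place the headgroup plane implied by an amphipathic anchor helix.

    The plane is parallel to the helix axis with the helix centroid at
    ``headgroup_depth`` below it; the roll of the normal about the axis comes
    from the helix's hydrophobic-moment direction (membrane on the
    hydrophobic face), moved to the nearest roll at which no heavy atom
    crosses the plane by more than the penetration tolerance.  If no roll is
    feasible an :class:`InfeasibilityReport` is returned.
    """
    ca, resnames = _anchor_ca(model, anchor)
    axis = _helix_axis(ca)
    centroid = ca.mean(axis=0)
    heavy = model.coords(heavy_only=True)

    # orthonormal frame perpendicular to the axis
    face = _hydrophobic_face_direction(ca, resnames, axis, scale)
    if face is not None:
        u = face
    else:
        ref = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        u = np.cross(axis, ref)
        u /= np.linalg.norm(u)
    v = np.cross(axis, u)

    def plane_for(phi: float) -> tuple[np.ndarray, float, float]:
        n = _normal_at(phi, 0.0, u, v, axis)
        offset = float(np.dot(n, centroid)) + anchor.headgroup_depth
        return n, offset, _max_penetration(heavy, n, offset)

    phis = np.radians(np.arange(0.0, 360.0, grid_step))
    pens = np.array([plane_for(p)[2] for p in phis])
    feasible = pens <= anchor.penetration_tolerance
    if not feasible.any():
        i = int(np.argmin(pens))
        return InfeasibilityReport(
            min_max_penetration=float(pens[i]),
            penetration_tolerance=anchor.penetration_tolerance,
            message=(
                "no roll of the membrane normal about the anchor-helix axis keeps all "
                f"heavy atoms within {anchor.penetration_tolerance} Å of the cytoplasmic side "
                f"(best achievable max penetration {pens[i]:.2f} Å)"
            ),
        )
    if face is not None:
        # prefer the hydrophobic-face direction: nearest feasible roll to phi=0
        order = np.argsort(np.minimum(phis, 2 * np.pi - phis))
    else:
        order = np.argsort(pens)
    best = next(i for i in order if feasible[i])
    n, offset, _ = plane_for(float(phis[best]))
    return PlaneModel(n, offset, headgroup_half_thickness=anchor.headgroup_depth)


def min_patch_distance(
    model: StructureModel,
    anchor: AnchorSpec,
    cfg: OrientationSearchConfig,
) -> tuple[float, PlaneModel] | InfeasibilityReport:
    """Minimum achievable distance between a cargo-site patch and the
    membrane plane over every anchored orientation.

    Scans roll (0–360°) × tilt (± parallelism tolerance) on the configured
    deterministic grid, keeps orientations in which no heavy atom crosses the
    plane by more than the penetration tolerance, and minimises the smallest
    patch-atom/plane distance.  Returns (min distance, achieving plane), or
    an infeasibility report if no orientation is feasible.
    """
    if cfg.patch is None and cfg.patch_coords is None:
        raise ValueError("orientation search needs a patch selection or explicit coordinates")
    if cfg.patch_coords is not None:
        patch = np.asarray(cfg.patch_coords, dtype=float).reshape(-1, 3)
    else:
        sub = select_domain(model, cfg.patch)
        patch = sub.coords(heavy_only=True)
    if patch.size == 0:
        raise ValueError("empty patch")

    ca, resnames = _anchor_ca(model, anchor)
    axis = _helix_axis(ca)
    centroid = ca.mean(axis=0)
    heavy = model.coords(heavy_only=True)
    ref = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)

    step = math.radians(cfg.angular_grid_step)
    tilt_max = math.radians(anchor.parallelism_tolerance)
    n_tilt = max(int(round(tilt_max / step)), 1)
    taus = np.linspace(-tilt_max, tilt_max, 2 * n_tilt + 1)
    phis = np.arange(0.0, 2 * math.pi, step)

    def evaluate(phi: float, tau: float) -> tuple[float, float, np.ndarray, float]:
        n = _normal_at(phi, tau, u, v, axis)
        offset = float(np.dot(n, centroid)) + anchor.headgroup_depth
        pen = _max_penetration(heavy, n, offset)
        d = float(np.min(offset - patch @ n))
        return d, pen, n, offset

    best: tuple[float, np.ndarray, float] | None = None
    best_pen = np.inf
    for phi in phis:
        for tau in taus:
            d, pen, n, offset = evaluate(float(phi), float(tau))
            best_pen = min(best_pen, pen)
            if pen <= cfg.penetration_tolerance and (best is None or d < best[0]):
                best = (d, n, offset)
    if best is None:
        return InfeasibilityReport(
            min_max_penetration=float(best_pen),
            penetration_tolerance=cfg.penetration_tolerance,
            message="no anchored orientation satisfies the non-penetration constraint",
        )
    if cfg.refinement == "local":
        from scipy.optimize import minimize

        d0, n0, off0 = best
        phi0 = math.atan2(float(np.dot(n0, v)), float(np.dot(n0, u)))
        tau0 = math.asin(float(np.clip(np.dot(n0, axis), -1, 1)))

        def objective(x):
            phi, tau = x
            tau = float(np.clip(tau, -tilt_max, tilt_max))
            d, pen, _, _ = evaluate(phi, tau)
            if pen > cfg.penetration_tolerance:
                return d0 + 100.0  # stay inside the feasible region
            return d

        res = minimize(objective, [phi0, tau0], method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400})
        phi_r, tau_r = float(res.x[0]), float(np.clip(res.x[1], -tilt_max, tilt_max))
        d, pen, n, offset = evaluate(phi_r, tau_r)
        if pen <= cfg.penetration_tolerance and d < best[0]:
            best = (d, n, offset)
    d, n, offset = best
    return d, PlaneModel(n, offset, headgroup_half_thickness=anchor.headgroup_depth)


# -- curvature -------------------------------------------------------------


def curvature_compatibility(
    model: StructureModel,
    plane: PlaneModel,
    cyl: CylinderModel,
    contact_shell: float = 8.0,
    penetration_tolerance: float = 0.0,
) -> tuple[int, float, CylinderModel]:
    """Check a placed complex against a curved (cylindrical) membrane.

    The cylinder (radius taken from ``cyl``) is repositioned tangent to the
    headgroup plane at the membrane-facing centroid of the complex, with its
    axis along the in-plane component of ``cyl.axis_direction`` (or, if that
    is degenerate, the in-plane principal axis of the membrane-facing atoms).
    Returns (number of heavy atoms penetrating the wall, fraction of
    membrane-facing residues within ``contact_shell`` of the wall, the
    repositioned cylinder).
    """
    heavy = model.coords(heavy_only=True)
    d = heavy @ plane.normal - plane.offset
    facing = heavy[d >= -contact_shell]
    if len(facing) == 0:
        facing = heavy[np.argsort(-d)[: max(len(heavy) // 10, 1)]]
    contact_point = facing.mean(axis=0)
    contact_point = contact_point + (plane.offset - contact_point @ plane.normal) * plane.normal

    axis_dir = cyl.axis_direction - np.dot(cyl.axis_direction, plane.normal) * plane.normal
    if np.linalg.norm(axis_dir) < 1e-6:
        centred = facing - facing.mean(axis=0)
        inplane = centred - np.outer(centred @ plane.normal, plane.normal)
        _, _, vt = np.linalg.svd(inplane)
        axis_dir = vt[0]
    axis_dir = axis_dir / np.linalg.norm(axis_dir)
    # the complex sits inside the tube: the axis is one radius away from the
    # membrane on the cytoplasmic side
    placed = CylinderModel(contact_point - plane.normal * cyl.radius, axis_dir, cyl.radius)

    rel = heavy - placed.axis_point
    radial = np.linalg.norm(rel - np.outer(rel @ axis_dir, axis_dir), axis=1)
    n_penetrating = int(np.sum(radial - placed.radius > penetration_tolerance))

    rel_f = facing - placed.axis_point
    radial_f = np.linalg.norm(rel_f - np.outer(rel_f @ axis_dir, axis_dir), axis=1)
    contact_fraction = float(np.mean(np.abs(placed.radius - radial_f) <= contact_shell)) if len(facing) else 0.0
    return n_penetrating, contact_fraction, placed


# -- charge census ---------------------------------------------------------

_CHARGE = {"LYS": 1, "ARG": 1, "ASP": -1, "GLU": -1}
_REP_ATOM = {"LYS": "NZ", "ARG": "CZ", "ASP": "CG", "GLU": "CD", "HIS": "NE2"}


def membrane_facing_charge_census(
    model: StructureModel,
    plane: PlaneModel,
    slab_depth: float = 10.0,
    histidine_charge: int = 0,
) -> ChargeCensus:
    """Tally charged residues whose side chains face the membrane.

    A residue is in the slab when its side-chain representative atom (the
    terminal charged-group atom when present, else Cβ, else Cα) lies within
    ``slab_depth`` below the headgroup plane.  Lys/Arg count +1, Asp/Glu −1,
    His per ``histidine_charge``.
    """
    if slab_depth < 0:
        raise ValueError("slab depth must be >= 0")
    rows = []
    pos = neg = 0
    for cid, num, icode, rname, atoms in model.residues():
        charge = _CHARGE.get(rname, histidine_charge if rname == "HIS" else 0)
        if charge == 0:
            continue
        wanted = _REP_ATOM.get(rname)
        rep = None
        for name in (wanted, "CB", "CA"):
            rep = next((a for a in atoms if a.name == name), None)
            if rep is not None:
                break
        if rep is None:
            rep = atoms[0]
        dist = float(np.dot(plane.normal, rep.position) - plane.offset)
        in_slab = dist >= -slab_depth
        if in_slab:
            pos += charge > 0
            neg += charge < 0
        rows.append(
            {
                "chain": cid,
                "residue_number": num,
                "residue_name": rname,
                "charge": charge,
                "plane_distance": dist,
                "in_slab": in_slab,
            }
        )
    return ChargeCensus(
        slab_depth=slab_depth,
        positive_count=int(pos),
        negative_count=int(neg),
        per_residue_table=pd.DataFrame(rows),
    )
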