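"""Synthetic structures and sequence cohorts with planted ground truth.

Every downstream stage — membrane placement, orientation search, motif
census, clash counting — is exercised on generators from this module, so the
whole pipeline is testable at desk scale with no downloads.  All generators
are deterministic given a seed, and each returns its planted ground truth in
machine-readable form alongside the data.

What the fixtures emulate (and what they do not): Cα-level traces stand in
for full-atom structures; an amphipathic anchor helix with its hydrophobic
face planted toward the membrane emulates an ARF-family N-terminal anchor;
a Gaussian atom cloud emulates the bulk of a peripheral complex on the
cytoplasmic side; cohort sequences emulate GPCR cytoplasmic tails with a
helix-8 window of controlled amphipathicity and motif content.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import PlaneModel, RigidTransform
from .motifs import BBSOME_RELAXED, MotifPattern, scan_motif
from .structure import AtomRecord, ONE_TO_THREE, SequenceRecord, StructureModel

__all__ = [
    "HelixSpec",
    "CohortSpec",
    "Cohort",
    "make_ideal_helix",
    "make_extended_chain",
    "make_membrane_complex_fixture",
    "make_gpcr_cohort",
    "make_census_cohort",
    "make_ph_site_fixture",
]

HYDROPHOBIC_FACE = "LIVF"  # used when painting amphipathic faces
POLAR_FACE = "STNQ"  # polar but uncharged and never motif-forming

# uncharged palette for anchor-helix painting, keyed by Eisenberg consensus
# hydrophobicity (no K/R/D/E so charge censuses stay controlled)
_ANCHOR_PALETTE = {
    "I": 1.38, "F": 1.19, "L": 1.06, "V": 1.08, "W": 0.81, "M": 0.64,
    "A": 0.62, "G": 0.48, "C": 0.29, "Y": 0.26, "P": 0.12, "T": -0.05,
    "S": -0.18, "H": -0.40, "N": -0.78, "Q": -0.85,
}


@dataclass(frozen=True)
class HelixSpec:
    """Ideal α-helix geometry: 1.5 Å rise and 100° twist per residue on a
    2.3 Å Cα radius."""

    n_residues: int
    rise_per_residue: float = 1.5
    twist_per_residue: float = 100.0
    helix_radius: float = 2.3

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("need at least one residue")
        if self.rise_per_residue <= 0:
            raise ValueError("rise must be positive")
        if not (0 < self.twist_per_residue <= 180):
            raise ValueError("twist must be in (0, 180] degrees")


def _ca(xyz: np.ndarray, resnum: int, resname: str = "ALA", chain: str = "A") -> AtomRecord:
    return AtomRecord(
        element="C",
        name="CA",
        position=(float(xyz[0]), float(xyz[1]), float(xyz[2])),
        residue_number=resnum,
        residue_name=resname,
        chain_id=chain,
    )


def make_ideal_helix(
    spec: HelixSpec,
    chain: str = "A",
    residue_names: str | None = None,
    start_number: int = 1,
) -> StructureModel:
    """Cα trace of an ideal α-helix along +z; axial extent (n−1)·rise.

    ``residue_names`` optionally paints a one-letter sequence onto the trace.
    """
    n = spec.n_residues
    theta = np.radians(spec.twist_per_residue) * np.arange(n)
    xyz = np.stack(
        [
            spec.helix_radius * np.cos(theta),
            spec.helix_radius * np.sin(theta),
            spec.rise_per_residue * np.arange(n),
        ],
        axis=1,
    )
    names = (
        [ONE_TO_THREE[c] for c in residue_names]
        if residue_names is not None
        else ["ALA"] * n
    )
    if residue_names is not None and len(residue_names) != n:
        raise ValueError("residue_names length must equal n_residues")
    return StructureModel(
        [_ca(xyz[i], start_number + i, names[i], chain) for i in range(n)],
        id="ideal-helix",
    )


def make_extended_chain(n: int, rise: float = 3.5, chain: str = "A") -> StructureModel:
    """Straight Cα trace along +z with ``rise`` Å between consecutive
    residues; end-to-end distance (n−1)·rise."""
    if n < 1:
        raise ValueError("need at least one residue")
    return StructureModel(
        [_ca(np.array([0.0, 0.0, rise * i]), i + 1, "ALA", chain) for i in range(n)],
        id="extended-chain",
    )


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two orthonormal in-plane directions for a unit normal."""
    n = np.asarray(normal, dtype=float)
    ref = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(n, ref)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def make_membrane_complex_fixture(
    plane: PlaneModel,
    seed: int,
    n_anchor_residues: int = 14,
    body_size: float = 30.0,
    n_body_atoms: int = 120,
    n_positive_in_slab: int = 0,
    n_negative_in_slab: int = 0,
    charge_slab_depth: float = 6.0,
) -> tuple[StructureModel, dict]:
    """Toy peripheral complex with a planted membrane plane.

    Chain A is an amphipathic anchor helix whose axis is parallel to the
    planted plane, Cα centroid at the headgroup half-thickness below it, and
    whose graded hydrophobic face points at the membrane while the polar
    face points into the cytoplasm.  Chain B is a globular atom cloud
    entirely on the cytoplasmic side.  Chains P/N optionally plant an
    exact number of charged residues inside a slab below the plane for
    charge-census tests.  Returns (model, ground_truth).
    """
    rng = np.random.default_rng(seed)
    n_vec = plane.normal
    u, v = _plane_basis(n_vec)
    phi = rng.uniform(0, 2 * np.pi)
    axis = math.cos(phi) * u + math.sin(phi) * v  # in-plane helix axis
    side = np.cross(n_vec, axis)

    depth = plane.headgroup_half_thickness
    spec = HelixSpec(n_anchor_residues)
    # build helix in its own frame, then paint faces by radial direction
    theta = np.radians(spec.twist_per_residue) * np.arange(n_anchor_residues)
    radial = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    local = np.stack(
        [
            spec.helix_radius * radial[:, 0],
            spec.helix_radius * radial[:, 1],
            spec.rise_per_residue * np.arange(n_anchor_residues),
        ],
        axis=1,
    )
    local -= local.mean(axis=0)
    # map local x -> membrane normal, local y -> side, local z -> axis
    frame = np.stack([n_vec, side, axis], axis=1)  # columns
    anchor_xyz = local @ frame.T
    # place centroid at `depth` below the plane
    point_on_plane = plane.offset * n_vec
    anchor_xyz += point_on_plane - depth * n_vec
    # graded amphipathic painting: hydrophobicity tracks the cosine of the
    # angle between each residue's radial direction and the membrane normal,
    # as in a real amphipathic anchor (hydrophobic face in the bilayer)
    atoms: list[AtomRecord] = []
    helix_centroid = anchor_xyz.mean(axis=0)
    for i in range(n_anchor_residues):
        r = anchor_xyz[i] - helix_centroid
        r_perp = r - np.dot(r, axis) * axis
        cos_psi = float(np.dot(r_perp, n_vec) / np.linalg.norm(r_perp))
        target = 1.0 * cos_psi + rng.normal(scale=0.03)
        letter = min(_ANCHOR_PALETTE, key=lambda aa: abs(_ANCHOR_PALETTE[aa] - target))
        atoms.append(_ca(anchor_xyz[i], i + 1, ONE_TO_THREE[letter], "A"))

    # body: random cloud fully below the plane, adjacent to the helix
    body_center = point_on_plane - (depth + body_size / 2 + 6.0) * n_vec
    body = rng.normal(scale=body_size / 4, size=(n_body_atoms, 3)) + body_center
    # clip any strays back under the plane
    d = body @ n_vec - plane.offset
    too_high = d > -depth
    body[too_high] -= np.outer(d[too_high] + depth + 1.0, n_vec)
    for j in range(n_body_atoms):
        atoms.append(_ca(body[j], j + 1, "ALA", "B"))

    # planted in-slab charges (single-atom residues; census falls back to Cα)
    for k in range(n_positive_in_slab):
        pos = point_on_plane - rng.uniform(0.5, charge_slab_depth - 0.5) * n_vec
        pos += rng.uniform(-10, 10) * u + rng.uniform(-10, 10) * v
        atoms.append(_ca(pos, k + 1, "LYS", "P"))
    for k in range(n_negative_in_slab):
        pos = point_on_plane - rng.uniform(0.5, charge_slab_depth - 0.5) * n_vec
        pos += rng.uniform(-10, 10) * u + rng.uniform(-10, 10) * v
        atoms.append(_ca(pos, k + 1, "GLU", "N"))

    model = StructureModel(atoms, id=f"membrane-fixture-{seed}")
    truth = {
        "plane_normal": [float(x) for x in n_vec],
        "plane_offset": float(plane.offset),
        "headgroup_depth": float(depth),
        "anchor_axis": [float(x) for x in axis],
        "anchor_chain": "A",
        "anchor_range": [1, n_anchor_residues],
        "n_positive_in_slab": n_positive_in_slab,
        "n_negative_in_slab": n_negative_in_slab,
        "charge_slab_depth": charge_slab_depth,
        "seed": seed,
    }
    return model, truth


# -- sequence cohorts ------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """GPCR-like cytoplasmic-tail cohort with motifs planted at a stated
    frequency inside the helix-8 window."""

    n_sequences: int
    h8_window_length: int = 17
    motif_fraction: float = 0.0
    alphabet_background: dict | None = None
    seed: int = 0
    amphipathic_windows: bool = True
    window_start_index: int = 5
    tail_length: int = 20
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.motif_fraction <= 1.0):
            raise ValueError("motif_fraction must be a probability")
        if self.h8_window_length < 5:
            raise ValueError("helix-8 window must be at least 5 residues")
        if self.alphabet_background is not None:
            total = sum(self.alphabet_background.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("background frequencies must sum to 1")


@dataclass
class Cohort:
    records: list
    windows: dict  # sequence id -> (start, end) author-numbered window
    labels: dict  # sequence id -> {"has_motif": bool, "planted": str | None}

    def truth_sidecar(self) -> dict:
        return {
            "windows": {k: list(v) for k, v in self.windows.items()},
            "labels": self.labels,
        }


def _sample_background(rng: np.random.Generator, n: int, freqs: dict | None) -> str:
    alphabet = sorted(freqs) if freqs else list("ACDEFGHIKLMNPQRSTVWY")
    p = np.array([freqs[a] for a in alphabet]) if freqs else None
    return "".join(rng.choice(alphabet, n, p=p))


def _amphipathic_window(rng: np.random.Generator, length: int, twist: float = 100.0) -> str:
    """Graded periodic hydrophobicity on the helical wheel: residue i tracks
    cos(i·twist), drawn from an uncharged palette (no K/R/D/E, so motif
    content stays fully controlled by explicit planting)."""
    out = []
    for i in range(length):
        target = 1.2 * math.cos(math.radians(i * twist)) + rng.normal(scale=0.05)
        out.append(min(_ANCHOR_PALETTE, key=lambda aa: abs(_ANCHOR_PALETTE[aa] - target)))
    return "".join(out)


def _on_face(i: int, twist: float = 100.0) -> bool:
    angle = (i * twist) % 360.0
    return angle <= 90.0 or angle >= 270.0


def _face_positions(length: int, twist: float = 100.0) -> list[int]:
    return [i for i in range(length) if _on_face(i, twist)]


def _window_without_matches(
    rng: np.random.Generator, length: int, freqs: dict | None, pattern: MotifPattern
) -> str:
    for _ in range(1000):
        w = _sample_background(rng, length, freqs)
        rec = SequenceRecord(id="w", residues=w)
        if not scan_motif(rec, pattern):
            return w
    raise RuntimeError("could not sample a motif-free window")


def _plant(window: str, pos: int, aromatic: str, basic: str) -> str:
    return window[:pos] + aromatic + basic + window[pos + 2 :]


def _build_cohort(
    spec: CohortSpec,
    planted_kinds: list,  # per-sequence: None | ("W", "R")-style letter pair
) -> Cohort:
    rng = np.random.default_rng(spec.seed)
    records, windows, labels = [], {}, {}
    L = spec.h8_window_length
    wstart = spec.window_start_index
    for i, kind in enumerate(planted_kinds):
        if spec.amphipathic_windows:
            window = _amphipathic_window(rng, L)
        else:
            window = _window_without_matches(rng, L, spec.alphabet_background, BBSOME_RELAXED)
        if kind is not None:
            # aromatic on a membrane-facing position whose successor is on
            # the polar side, as in a genuine helix-8 motif (W in the
            # bilayer, basic residue at the interface)
            face = [p for p in _face_positions(L) if p < L - 1 and not _on_face(p + 1)]
            pos = int(rng.choice(face)) if face else 0
            window = _plant(window, pos, kind[0], kind[1])
        prefix = _window_without_matches(rng, wstart, spec.alphabet_background, BBSOME_RELAXED)
        tail = _sample_background(rng, spec.tail_length, spec.alphabet_background)
        seq = prefix + window + tail
        sid = f"synthetic-gpcr-{i:03d}"
        rec = SequenceRecord(id=sid, residues=seq, numbering_offset=spec.numbering_offset)
        start = spec.numbering_offset + wstart
        records.append(rec)
        windows[sid] = (start, start + L - 1)
        labels[sid] = {"has_motif": kind is not None, "planted": None if kind is None else "".join(kind)}
    return Cohort(records, windows, labels)


def make_gpcr_cohort(spec: CohortSpec) -> Cohort:
    """Cohort in which exactly ``round(motif_fraction · n)`` sequences carry a
    [W/F/Y][K/R] match inside the helix-8 window and the rest carry none."""
    rng = np.random.default_rng(spec.seed + 1)
    n_with = round(spec.motif_fraction * spec.n_sequences)
    kinds: list = [
        (rng.choice(list("WF")), rng.choice(list("KR"))) for _ in range(n_with)
    ] + [None] * (spec.n_sequences - n_with)
    rng.shuffle(kinds)  # type: ignore[arg-type]
    return _build_cohort(spec, kinds)


def make_census_cohort(
    n_total: int = 26,
    n_strict: int = 20,
    n_relaxed_only: int = 3,
    seed: int = 0,
    **kwargs,
) -> Cohort:
    """Cohort emulating a ciliary-GPCR helix-8 census: ``n_strict`` sequences
    carry an aromatic–arginine ([W/F/Y]R) motif in-window, ``n_relaxed_only``
    carry an aromatic–lysine motif (matching [W/F/Y][K/R] but not the strict
    form), and the remainder carry none."""
    if n_strict + n_relaxed_only > n_total:
        raise ValueError("planted counts exceed cohort size")
    rng = np.random.default_rng(seed + 2)
    kinds: list = (
        [(rng.choice(list("WF")), "R") for _ in range(n_strict)]
        + [(rng.choice(list("WF")), "K") for _ in range(n_relaxed_only)]
        + [None] * (n_total - n_strict - n_relaxed_only)
    )
    rng.shuffle(kinds)  # type: ignore[arg-type]
    spec = CohortSpec(n_sequences=n_total, seed=seed, **kwargs)
    return _build_cohort(spec, kinds)


# -- two-conformation rotation fixture -------------------------------------


def make_rotation_fixture(
    angle_deg: float,
    seed: int,
    n_base_atoms: int = 60,
    n_domain_residues: int = 30,
) -> tuple[StructureModel, StructureModel, dict]:
    """Two conformations of a toy two-module complex with a planted domain
    rotation.

    The reference model has a stationary base (chain B, a random rigid atom
    cloud) and a mobile domain (chain D, a Cα helix).  The alternate model
    rotates the domain by ``angle_deg`` about a random axis through its
    centroid, then moves the whole model by a random global rigid transform —
    so recovering the planted angle requires aligning on the base first.
    Returns (reference, alternate, truth).
    """
    rng = np.random.default_rng(seed)
    base_xyz = rng.normal(scale=12.0, size=(n_base_atoms, 3))
    base = [
        _ca(base_xyz[i], i + 1, "ALA", "B") for i in range(n_base_atoms)
    ]
    helix = make_ideal_helix(HelixSpec(n_domain_residues), chain="D")
    dom_xyz = helix.ca_coords() + np.array([30.0, 0.0, 0.0])
    domain = [_ca(dom_xyz[i], i + 1, "ALA", "D") for i in range(n_domain_residues)]
    ref = StructureModel(base + domain, id="rotation-ref")

    axis = rng.normal(size=3)
    centroid = dom_xyz.mean(axis=0)
    spin = RigidTransform.about_axis(axis, angle_deg)
    dom_alt = (dom_xyz - centroid) @ spin.rotation.T + centroid
    alt_atoms = base + [_ca(dom_alt[i], i + 1, "ALA", "D") for i in range(n_domain_residues)]
    alt = StructureModel(alt_atoms, id="rotation-alt")
    global_move = RigidTransform.about_axis(rng.normal(size=3), rng.uniform(5, 175),
                                            translation=rng.uniform(-25, 25, 3))
    alt = alt.transformed(global_move.rotation, global_move.translation)
    truth = {"angle_deg": float(angle_deg), "seed": seed}
    return ref, alt, truth


# -- PH-site occlusion fixture ---------------------------------------------


def make_ph_site_fixture(
    n_clashes: int,
    seed: int,
    cutoff: float = 3.0,
    n_far_atoms: int = 30,
):
    """Query PH domain + template complex + environment with a known clash
    count.

    The template is a 25-residue Cα trace with an 8-atom ligand beside it;
    the query is the same trace under a random rigid motion.  The environment
    holds exactly ``n_clashes`` atoms within ``cutoff`` of the ligand once the
    ligand is carried over by template superposition (planted at distances
    1.8–2.9 Å from their nearest ligand atom), plus decoy atoms all farther
    than ``cutoff`` + 5 Å.  Returns (query_ph, template, environment, truth).
    """
    from .occlusion import TemplateComplex  # local import avoids a cycle

    rng = np.random.default_rng(seed)
    ph = make_ideal_helix(HelixSpec(25), chain="Q")
    ph_xyz = ph.ca_coords()
    lig_local = np.array(
        [
            [6.0, 0.0, 10.0], [7.2, 0.8, 10.5], [6.5, -0.9, 11.4], [7.8, 0.1, 12.2],
            [6.2, 1.1, 12.9], [7.0, -0.5, 13.8], [8.1, 0.9, 14.2], [6.6, 0.2, 15.0],
        ]
    )
    template = TemplateComplex(
        id=f"synthetic-template-{seed}",
        site_label="canonical",
        ph_coords=ph_xyz.copy(),
        ligand_coords=lig_local.copy(),
    )
    # random proper rigid motion for the query frame
    axis = rng.normal(size=3)
    angle = rng.uniform(10, 170)
    t = RigidTransform.about_axis(axis, angle, translation=rng.uniform(-20, 20, 3))
    query = ph.transformed(t.rotation, t.translation)
    lig_true = t.apply(lig_local)

    env_atoms = []
    for k in range(n_clashes):
        anchor = lig_true[k % len(lig_true)]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pos = anchor + direction * rng.uniform(1.8, cutoff - 0.1)
        # keep it a single counted atom: nearest-ligand distance is < cutoff
        env_atoms.append(pos)
    placed = 0
    while placed < n_far_atoms:
        pos = lig_true.mean(axis=0) + rng.uniform(-60, 60, 3)
        if np.min(np.linalg.norm(lig_true - pos, axis=1)) > cutoff + 5.0:
            env_atoms.append(pos)
            placed += 1
    environment = StructureModel(
        [_ca(p, j + 1, "ALA", "E") for j, p in enumerate(env_atoms)],
        id=f"ph-env-{seed}",
    )
    truth = {
        "n_clashes": n_clashes,
        "cutoff": cutoff,
        "ligand_true": lig_true.tolist(),
        "transform_angle_deg": float(angle),
        "seed": seed,
    }
    return query, template, environment, truth
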