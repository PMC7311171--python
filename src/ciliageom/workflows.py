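"""End-to-end reproduction workflow on synthetic fixtures.

Chains every stage of the pipeline — reach arithmetic, motif census,
membrane placement and recovery, constrained orientation search, domain
rotation, clash counting, charge census, curvature — on generators with
planted ground truth, and collects the headline numbers into one report.
Deposited coordinate files, when available locally, can be analysed with the
same operations through the CLI; this module needs no downloads.
"""

from __future__ import annotations

import numpy as np

from .amphipathic import hydrophobic_moment
from .geometry import CylinderModel, PlaneModel
from .membrane import (
    AnchorSpec,
    InfeasibilityReport,
    OrientationSearchConfig,
    curvature_compatibility,
    membrane_facing_charge_census,
    min_patch_distance,
    place_membrane,
)
from .motifs import BBSOME_RELAXED, BBSOME_STRICT, cohort_motif_census, scan_pip_motif
from .occlusion import assess_site, count_clashes, place_template_ligand
from .structure import SequenceRecord
from .synthetic import (
    make_census_cohort,
    make_membrane_complex_fixture,
    make_ph_site_fixture,
    make_rotation_fixture,
)
from .tether import conformational_verdict, max_reach, tether_length_from_numbering

__all__ = [
    "synthetic_ph1_loop_sequence",
    "reproduce_synthetic",
]

# Study conditions used throughout the synthetic reproduction.
TETHER_ANCHOR = 543  # first cytoplasmic-tail residue after TM7 (SMO numbering)
TETHER_CONTACT = 549  # the critical tryptophan of the helix-8 motif
SITE_DISTANCE = 15.0  # Å, minimum cargo-site/membrane distance of the complex
IFT38_TAIL = (329, 413)  # acidic IFT-B tail interval (author numbering)
COHORT = dict(n_total=26, n_strict=20, n_relaxed_only=3)  # ciliary-GPCR helix-8 census
CILIA_RADIUS = 1250.0  # Å (250 nm diameter ciliary membrane cylinder)
PLANTED_ROTATION = 20.0  # degrees, GTPase-induced β-propeller swing
PLANTED_CLASHES = 12
PLANTED_CHARGES = (7, 2)  # positive, negative in the membrane-facing slab


def synthetic_ph1_loop_sequence() -> SequenceRecord:
    """Synthetic stand-in for a PH-domain β1–β2 loop region numbered so that
    the PIP-binding motif falls at K41...R47xR49 (the real loop sequence is
    not redistributable here; only the motif positions matter)."""
    offset = 30
    letters = ["A"] * 30
    for num, aa in ((41, "K"), (47, "R"), (49, "R")):
        letters[num - offset] = aa
    return SequenceRecord(id="synthetic-ph1-loop", residues="".join(letters), numbering_offset=offset)


def reproduce_synthetic(seed: int, fine_oracle: bool = True) -> dict:
    """Run every pipeline stage on seeded synthetic inputs and return the
    headline quantities, each as {"value": float, "n": problem size}."""
    seed = int(seed) % (2**31 - 1)
    out: dict[str, dict] = {}

    # 1. tether-reach arithmetic and the conformational verdict
    n_steps = tether_length_from_numbering(TETHER_ANCHOR, TETHER_CONTACT)
    out["tether_steps_tm7_to_trp"] = {"value": n_steps, "n": 1}
    out["extended_reach_angstrom"] = {"value": max_reach(n_steps, "extended"), "n": n_steps}
    out["helical_reach_angstrom"] = {"value": max_reach(n_steps, "helical"), "n": n_steps}
    verdict = conformational_verdict(SITE_DISTANCE, n_steps)
    out["helix8_must_unfold"] = {"value": int(verdict.conclusion == "must be unfolded"), "n": n_steps}

    # 2. sequence-interval arithmetic (acidic IFT-B tail length)
    out["ift38_tail_length_aa"] = {"value": IFT38_TAIL[1] - IFT38_TAIL[0] + 1, "n": 1}

    # 3. helix-8 motif census on the planted 26-sequence cohort
    cohort = make_census_cohort(seed=seed, **COHORT)
    windows = {
        sid: _annotation(sid, w) for sid, w in cohort.windows.items()
    }
    strict, n_total, _ = cohort_motif_census(cohort.records, BBSOME_STRICT, windows)
    relaxed, _, _ = cohort_motif_census(cohort.records, BBSOME_RELAXED, windows)
    out["strict_motif_census_hits"] = {"value": strict, "n": n_total}
    out["relaxed_motif_census_hits"] = {"value": relaxed, "n": n_total}

    # 4. PIP-binding motif on the synthetic β1–β2 loop
    pip = scan_pip_motif(synthetic_ph1_loop_sequence())
    out["pip_motif_span_aa"] = {
        "value": (pip[0].end - pip[0].start + 1) if pip else 0,
        "n": len(pip),
    }

    # 5. membrane placement: recover a planted plane
    rng = np.random.default_rng(seed + 10)
    normal = rng.normal(size=3)
    normal /= np.linalg.norm(normal)
    plane_true = PlaneModel(normal, float(rng.uniform(-20, 20)), 3.0)
    model, truth = make_membrane_complex_fixture(
        plane_true, seed=seed + 11,
        n_positive_in_slab=PLANTED_CHARGES[0], n_negative_in_slab=PLANTED_CHARGES[1],
    )
    anchor = AnchorSpec(chain="A", anchor_helix_start=1, anchor_helix_end=truth["anchor_range"][1])
    placed = place_membrane(model, anchor)
    if isinstance(placed, InfeasibilityReport):
        raise RuntimeError(placed.message)
    cosang = float(np.clip(np.dot(placed.normal, plane_true.normal), -1, 1))
    out["plane_normal_recovery_error_deg"] = {"value": float(np.degrees(np.arccos(cosang))), "n": len(model)}
    out["plane_offset_recovery_error_angstrom"] = {
        "value": abs(placed.offset - plane_true.offset), "n": len(model),
    }

    # 6. constrained orientation search vs a dense-grid oracle
    patch = model.subset(lambda a: a.chain_id == "B").coords()[:25]
    cfg = OrientationSearchConfig(angular_grid_step=2.0, patch_coords=patch)
    search = min_patch_distance(model, anchor, cfg)
    if isinstance(search, InfeasibilityReport):
        raise RuntimeError(search.message)
    d_coarse, _ = search
    out["min_patch_distance_angstrom"] = {"value": d_coarse, "n": len(patch)}
    if fine_oracle:
        fine = OrientationSearchConfig(angular_grid_step=0.5, refinement="none", patch_coords=patch)
        fine_result = min_patch_distance(model, anchor, fine)
        assert not isinstance(fine_result, InfeasibilityReport)
        d_fine, _ = fine_result
        out["orientation_grid_vs_dense_gap_angstrom"] = {
            "value": abs(d_coarse - d_fine), "n": len(patch),
        }

    # 7. membrane-facing charge census on the planted charges
    census = membrane_facing_charge_census(model, placed, slab_depth=truth["charge_slab_depth"])
    out["charge_census_positive"] = {"value": census.positive_count, "n": PLANTED_CHARGES[0]}
    out["charge_census_negative"] = {"value": census.negative_count, "n": PLANTED_CHARGES[1]}

    # 8. curvature: the placed complex against the ciliary cylinder
    n_pen, contact_frac, _ = curvature_compatibility(
        model, placed, CylinderModel(np.zeros(3), np.array([1.0, 0, 0]), CILIA_RADIUS)
    )
    out["cylinder_wall_penetrations"] = {"value": n_pen, "n": len(model)}

    # 9. domain rotation between two conformations (planted swing)
    from .conformation import domain_rotation
    from .structure import DomainSelection

    ref, alt, rot_truth = make_rotation_fixture(PLANTED_ROTATION, seed + 12)
    rot = domain_rotation(
        ref, alt,
        base_selections=[DomainSelection("B", 1, 10**6)],
        domain_selection=DomainSelection("D", 1, 10**6),
    )
    out["domain_rotation_deg"] = {"value": rot.angle_deg, "n": rot.n_domain_atoms}

    # 10. lipid-site occlusion: planted clash count and site verdicts
    query, template, env, ph_truth = make_ph_site_fixture(PLANTED_CLASHES, seed + 13)
    lig, _ = place_template_ligand(query, template)
    n_clash, _ = count_clashes(lig, env, cutoff=ph_truth["cutoff"])
    out["planted_clash_count"] = {"value": n_clash, "n": PLANTED_CLASHES}
    query0, template0, env0, _ = make_ph_site_fixture(0, seed + 14)
    far_plane = PlaneModel(np.array([0.0, 0.0, 1.0]), float(np.max(env0.coords()[:, 2]) + 200.0), 3.0)
    open_far = assess_site(query0, "canonical", [template0], env0, plane=far_plane)
    out["open_site_distant_verdict"] = {"value": int(open_far.verdict == "distant"), "n": 1}

    # 11. amphipathicity of a planted helix-8 window vs its scrambled form
    sid = cohort.records[0]
    w = cohort.windows[sid.id]
    window_seq = sid.window(*w)
    mu = hydrophobic_moment(window_seq)
    out["planted_window_hydrophobic_moment"] = {"value": mu, "n": len(window_seq)}

    out["seed"] = {"value": seed, "n": 1}
    return out


def _annotation(sid: str, window: tuple[int, int]):
    from .amphipathic import Helix8Annotation

    return Helix8Annotation(sid, window[0], window[1], source="config")
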