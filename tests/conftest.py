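import numpy as np
import pytest

from ciliageom import AnchorSpec, PlaneModel
from ciliageom.synthetic import make_membrane_complex_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def planted_plane():
    n = np.array([0.36, -0.48, 0.8])
    n = n / np.linalg.norm(n)
    return PlaneModel(n, offset=7.5, headgroup_half_thickness=3.0)


@pytest.fixture
def membrane_fixture(planted_plane):
    """Planted-plane complex with 7 positive / 2 negative in-slab charges."""
    model, truth = make_membrane_complex_fixture(
        planted_plane, seed=7, n_positive_in_slab=7, n_negative_in_slab=2
    )
    anchor = AnchorSpec(
        chain="A", anchor_helix_start=1, anchor_helix_end=truth["anchor_range"][1]
    )
    return model, truth, anchor


def quaternion_superpose(moving: np.ndarray, fixed: np.ndarray):
    """Independent superposition oracle: Horn's closed-form quaternion method.

    Builds the 4x4 key matrix from the cross-covariance of the centred sets;
    the optimal rotation is the eigenvector of the largest eigenvalue, and
    the minimised squared deviation is Σ|P|²+Σ|Q|² − 2λ_max.
    """
    P = moving - moving.mean(axis=0)
    Q = fixed - fixed.mean(axis=0)
    S = P.T @ Q
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    w, v = np.linalg.eigh(K)
    lam = w[-1]
    q = v[:, -1]
    q0, q1, q2, q3 = q
    R = np.array(
        [
            [q0**2 + q1**2 - q2**2 - q3**2, 2 * (q1 * q2 - q0 * q3), 2 * (q1 * q3 + q0 * q2)],
            [2 * (q1 * q2 + q0 * q3), q0**2 - q1**2 + q2**2 - q3**2, 2 * (q2 * q3 - q0 * q1)],
            [2 * (q1 * q3 - q0 * q2), 2 * (q2 * q3 + q0 * q1), q0**2 - q1**2 - q2**2 + q3**2],
        ]
    ).T  # maps moving-frame vectors onto fixed-frame vectors
    ss = (P**2).sum() + (Q**2).sum() - 2.0 * lam
    rmsd = float(np.sqrt(max(ss, 0.0) / len(P)))
    return R, rmsd


def brute_force_matches(residues: str, pattern):
    """Enumerate every index tuple satisfying a gapped-class motif pattern —
    the oracle the scanning implementation is checked against."""
    from itertools import combinations

    k = len(pattern.elements)
    out = []
    for tup in combinations(range(len(residues)), k):
        if not all(residues[tup[j]] in pattern.elements[j] for j in range(k)):
            continue
        if all(
            pattern.gaps[j][0] <= tup[j + 1] - tup[j] - 1 <= pattern.gaps[j][1]
            for j in range(k - 1)
        ):
            out.append(tup)
    return sorted(out)
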