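import logging

import numpy as np
import pytest

from amideir.fixtures import (
    FixtureSpec,
    build_ideal_backbone,
    solvate_shell,
    synthetic_nnc_map,
)
from amideir.hamiltonian import NNCMap, SiteEnergyParams
from amideir.structures_io import assign_charges, identify_peptide_units

# keep charge-mismatch warnings from flooding test output
logging.getLogger("amideir.structures_io").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def helix_snapshot():
    return build_ideal_backbone(FixtureSpec(kind="helix", n_residues=12))


@pytest.fixture(scope="session")
def helix_units(helix_snapshot):
    return identify_peptide_units(helix_snapshot)


@pytest.fixture(scope="session")
def helix_env(helix_snapshot, helix_units):
    return assign_charges(helix_snapshot, units=helix_units)


@pytest.fixture(scope="session")
def solvated_helix():
    snap = build_ideal_backbone(FixtureSpec(kind="helix", n_residues=12))
    return solvate_shell(snap, 80, seed=1)


@pytest.fixture(scope="session")
def nnc_map():
    return NNCMap(synthetic_nnc_map(3))


@pytest.fixture(scope="session")
def params():
    return SiteEnergyParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_one_exciton(rng, n, coupling_scale=8.0, energy_spread=15.0):
    """Random symmetric one-quantum Hamiltonian around 1680 cm⁻¹."""
    H = rng.normal(0.0, coupling_scale, (n, n))
    H = 0.5 * (H + H.T)
    np.fill_diagonal(H, 1680.0 + rng.normal(0.0, energy_spread, n))
    return H


def boson_ladder_two_quantum(h1, anharmonicity):
    """Independent oracle: explicit two-boson product basis.

    H = Σ_ij H1[i,j] a†_i a_j − (Δ/2) Σ_i n_i (n_i − 1) restricted to the
    two-quantum subspace spanned by |mn⟩ = a†_m a†_n |0⟩ / norm, m ≤ n.
    """
    h1 = np.asarray(h1, float)
    n = h1.shape[0]
    pairs = [(m, k) for m in range(n) for k in range(m, n)]

    def occ(pair):
        v = np.zeros(n, int)
        v[pair[0]] += 1
        v[pair[1]] += 1
        return tuple(v)

    index = {occ(p): a for a, p in enumerate(pairs)}
    dim = len(pairs)
    H2 = np.zeros((dim, dim))
    for a, p in enumerate(pairs):
        state = np.array(occ(p))
        # anharmonic diagonal
        H2[a, a] += -0.5 * anharmonicity * np.sum(state * (state - 1))
        # hopping / site-energy terms a†_i a_j
        for j in range(n):
            if state[j] == 0:
                continue
            for i in range(n):
                new = state.copy()
                amp = np.sqrt(new[j])
                new[j] -= 1
                amp *= np.sqrt(new[i] + 1)
                new[i] += 1
                b = index[tuple(new)]
                H2[b, a] += h1[i, j] * amp
    return pairs, H2
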