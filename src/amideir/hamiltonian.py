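"""One- and two-quantum vibrational exciton Hamiltonians for the Amide I band.

The one-quantum Hamiltonian has three kinds of element: diagonal site
frequencies from an electrostatic map (central frequency plus linear
response of the local mode to the potential at the four amide atoms),
nearest-neighbor couplings looked up on a (φ, ψ) dihedral grid, and all
remaining couplings from the transition-dipole coupling (TDC) model.  The
two-quantum Hamiltonian is the symmetric two-boson lift of the one-quantum
matrix with a diagonal overtone anharmonicity Δ.

Units: energies in cm⁻¹, distances in Å, charges in e, dipole magnitudes in
D Å⁻¹ amu⁻¹ᐟ².  The TDC prefactor is 0.1/ε on these inputs ("internal
units"); a configurable ``tdc_scale`` multiplier calibrates to a physical
coupling scale and is recorded in output metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .structures_io import ChargeEnvironment, PeptideUnit

logger = logging.getLogger("amideir.hamiltonian")

__all__ = [
    "SiteEnergyParams",
    "TransitionDipole",
    "OneExcitonHamiltonian",
    "TwoExcitonSystem",
    "NNCMap",
    "place_transition_dipole",
    "tdc_coupling",
    "nnc_coupling",
    "site_potentials",
    "site_frequency",
    "build_one_exciton",
    "build_two_exciton",
    "two_quantum_dipoles",
    "diagonalize",
    "write_hamiltonian",
    "read_hamiltonian",
    "POTENTIAL_UNIT_SCALE",
]

BOHR_RADIUS_ANGSTROM = 0.529177210903
HARTREE_IN_CM = 219474.6313632

#: Default conversion for the electrostatic potential: charges in e and
#: distances in Å give the potential in atomic units, and the resulting
#: e·φ energy is expressed in cm⁻¹ (Hartree → cm⁻¹).  With the map's linear
#: expansion coefficients (fractions of e) this yields solvent-induced site
#: shifts of order tens of cm⁻¹.
POTENTIAL_UNIT_SCALE = BOHR_RADIUS_ANGSTROM * HARTREE_IN_CM

EVAL_ATOMS = ("C", "O", "N", "H")


@dataclass
class SiteEnergyParams:
    """Parameters of the electrostatic site-frequency map.

    ``omega0`` is the unperturbed central frequency; proline units (no amide
    hydrogen) take a fixed frequency; isotope labeling (¹³C¹⁸O) red-shifts a
    site's diagonal by ``isotope_shift``.  ``l_coefficients`` are the linear
    expansion coefficients (e) multiplying the potential at C, O, N, H.
    """

    omega0: float = 1680.0
    proline_frequency: float = 1653.0
    isotope_shift: float = 65.0
    l_coefficients: dict[str, float] = field(default_factory=lambda: {
        "C": 0.00160, "O": -0.00554, "N": 0.00479, "H": -0.00086,
    })
    potential_unit_scale: float = POTENTIAL_UNIT_SCALE

    def __post_init__(self) -> None:
        if self.omega0 <= 0:
            raise ValueError("omega0 must be positive")
        if self.isotope_shift <= 0:
            raise ValueError("isotope_shift must be positive")
        missing = set(EVAL_ATOMS) - self.l_coefficients.keys()
        if missing:
            raise ValueError(f"l_coefficients missing atoms: {sorted(missing)}")


@dataclass
class TransitionDipole:
    """An Amide I transition dipole: origin (Å), unit direction, magnitude."""

    origin: np.ndarray
    direction: np.ndarray
    magnitude: float = 3.7

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, float)
        self.direction = np.asarray(self.direction, float)
        norm = np.linalg.norm(self.direction)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"direction must be a unit vector (|d| = {norm})")

    @property
    def vector(self) -> np.ndarray:
        return self.magnitude * self.direction


@dataclass
class OneExcitonHamiltonian:
    """N×N one-quantum Hamiltonian (cm⁻¹) with per-site transition dipoles."""

    matrix: np.ndarray
    dipoles: list[TransitionDipole]
    site_metadata: list[PeptideUnit] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ValueError("Hamiltonian must be square")
        if n != len(self.dipoles):
            raise ValueError("dipole count does not match matrix dimension")
        if np.max(np.abs(self.matrix - self.matrix.T)) > 1e-9:
            raise ValueError("Hamiltonian must be symmetric")

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[0]

    @property
    def dipole_vectors(self) -> np.ndarray:
        """(N, 3) site transition-dipole vectors (magnitude × direction)."""
        return np.array([d.vector for d in self.dipoles])


@dataclass
class TwoExcitonSystem:
    """The symmetric two-quantum space: N(N+1)/2 pair states (m ≤ n)."""

    pair_index: list[tuple[int, int]]
    matrix: np.ndarray
    dipole_table: np.ndarray  # (N, P, 3) site-basis one→two quantum dipoles
    anharmonicity: float = 16.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        p = len(self.pair_index)
        if self.matrix.shape != (p, p):
            raise ValueError("two-quantum matrix dimension mismatch")
        if np.max(np.abs(self.matrix - self.matrix.T)) > 1e-9:
            raise ValueError("two-quantum Hamiltonian must be symmetric")

    @property
    def n_pair_states(self) -> int:
        return len(self.pair_index)


# ---------------------------------------------------------------------------
# Transition dipole placement and couplings
# ---------------------------------------------------------------------------

DIPOLE_OFFSET_ANGSTROM = 0.868
DIPOLE_TILT_DEG = 20.0


def place_transition_dipole(unit: PeptideUnit,
                            magnitude: float = 3.7) -> TransitionDipole:
    """Place the Amide I transition dipole on a peptide unit.

    The origin lies on the C=O axis, 0.868 Å from the carbonyl carbon toward
    the oxygen; the direction is the C→O direction rotated 20° toward the
    amide nitrogen within the O-C-N plane.
    """
    u = unit.o - unit.c
    u = u / np.linalg.norm(u)
    v = unit.n - unit.c
    w = v - np.dot(v, u) * u  # in-plane component toward N
    wn = np.linalg.norm(w)
    if wn < 1e-9:
        raise ValueError(
            f"unit {unit.site_index}: O, C, N are collinear; dipole plane undefined"
        )
    w /= wn
    theta = np.radians(DIPOLE_TILT_DEG)
    direction = np.cos(theta) * u + np.sin(theta) * w
    direction /= np.linalg.norm(direction)
    return TransitionDipole(
        origin=unit.c + DIPOLE_OFFSET_ANGSTROM * u,
        direction=direction,
        magnitude=magnitude,
    )


def tdc_coupling(d_i: TransitionDipole, d_j: TransitionDipole,
                 dielectric: float = 1.0, tdc_scale: float = 1.0) -> float:
    """Transition-dipole coupling between two sites (cm⁻¹ internal units).

    f_ij = tdc_scale · (0.1/ε) · [μ̂_i·μ̂_j − 3 (μ̂_i·η̂)(μ̂_j·η̂)] · m_i m_j / r³
    with r the origin separation in Å.  Symmetric in (i, j); decays as r⁻³.
    """
    sep = d_j.origin - d_i.origin
    r = float(np.linalg.norm(sep))
    if r <= 0.1:
        raise ValueError(f"dipole separation {r:.3f} Å too small for TDC")
    eta = sep / r
    kappa = float(np.dot(d_i.direction, d_j.direction)
                  - 3.0 * np.dot(d_i.direction, eta) * np.dot(d_j.direction, eta))
    return tdc_scale * (0.1 / dielectric) * kappa * d_i.magnitude * d_j.magnitude / r ** 3


class NNCMap:
    """Nearest-neighbor coupling map: a periodic 13×13 grid over (φ, ψ).

    Nodes at −180°, −150°, …, +180° on each axis; values in cm⁻¹.  Lookup is
    bilinear interpolation on the torus (wrap-around at ±180°), exact at
    grid nodes.
    """

    NODES = np.arange(-180, 181, 30)

    def __init__(self, grid: np.ndarray):
        grid = np.asarray(grid, float)
        if grid.shape != (13, 13):
            raise ValueError(f"NNC map must be 13×13, got {grid.shape}")
        if not np.all(np.isfinite(grid)):
            raise ValueError("NNC map contains non-finite values")
        edge_err = max(np.max(np.abs(grid[0] - grid[-1])),
                       np.max(np.abs(grid[:, 0] - grid[:, -1])))
        if edge_err > 1e-6:
            logger.warning("NNC map periodic edges differ by up to %.3g cm⁻¹; "
                           "wrap-around uses the -180° nodes", edge_err)
        self.grid = grid

    @classmethod
    def from_file(cls, path: str | Path) -> "NNCMap":
        values: dict[tuple[int, int], float] = {}
        lines = Path(path).read_text().splitlines()
        for line in lines:
            line = line.strip()
            if not line or line.lower().startswith("phi"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"malformed NNC map line: {line!r}")
            values[(int(round(float(parts[0]))), int(round(float(parts[1]))))] = \
                float(parts[2])
        grid = np.empty((13, 13))
        missing = []
        for i, p in enumerate(cls.NODES):
            for j, q in enumerate(cls.NODES):
                if (p, q) in values:
                    grid[i, j] = values[(p, q)]
                else:
                    missing.append((int(p), int(q)))
        if missing:
            raise ValueError(f"NNC map missing {len(missing)} nodes, e.g. {missing[:3]}")
        return cls(grid)

    @classmethod
    def constant(cls, value: float) -> "NNCMap":
        return cls(np.full((13, 13), float(value)))

    def __call__(self, phi: float, psi: float) -> float:
        return self.interpolate(phi, psi)

    def interpolate(self, phi: float, psi: float) -> float:
        # use the 12 independent nodes; node 12 (+180°) duplicates node 0
        fp = (float(phi) + 180.0) / 30.0 % 12.0
        fq = (float(psi) + 180.0) / 30.0 % 12.0
        i0, j0 = int(np.floor(fp)), int(np.floor(fq))
        tp, tq = fp - i0, fq - j0
        i1, j1 = (i0 + 1) % 12, (j0 + 1) % 12
        g = self.grid
        return float(
            g[i0, j0] * (1 - tp) * (1 - tq)
            + g[i1, j0] * tp * (1 - tq)
            + g[i0, j1] * (1 - tp) * tq
            + g[i1, j1] * tp * tq
        )


def nnc_coupling(phi: float, psi: float, nnc_map: NNCMap) -> float:
    """Nearest-neighbor coupling (cm⁻¹) at the shared residue's (φ, ψ)."""
    return nnc_map.interpolate(phi, psi)


# ---------------------------------------------------------------------------
# Electrostatic site frequencies
# ---------------------------------------------------------------------------

def site_potentials(unit: PeptideUnit, env: ChargeEnvironment,
                    potential_unit_scale: float = POTENTIAL_UNIT_SCALE) -> np.ndarray:
    """Electrostatic potential at the unit's C, O, N, H atoms.

    φ_atom = scale · Σ_j c_j / r_j over all environment charges not owned by
    this unit (the unit's own amide charges are excluded).  For proline (no
    amide H) the H entry is zero.  A charge within 0.2 Å of an evaluation
    atom is an unphysical clash and raises.
    """
    mask = env.owner_site != unit.site_index
    pos = env.positions[mask]
    q = env.charges[mask]
    out = np.zeros(4)
    if len(q) == 0:
        return out
    for a, name in enumerate(EVAL_ATOMS):
        p = unit.evaluation_positions[name]
        if p is None:
            continue
        r = np.linalg.norm(pos - p, axis=1)
        if np.any(r < 0.2):
            raise ValueError(
                f"charge within 0.2 Å of unit {unit.site_index} atom {name}"
            )
        out[a] = potential_unit_scale * float(np.sum(q / r))
    return out


def site_frequency(unit: PeptideUnit, potentials: np.ndarray,
                   params: SiteEnergyParams) -> float:
    """Site frequency (cm⁻¹): ω = ω₀ + Σ_atom l_atom φ_atom.

    Proline units take the fixed proline frequency regardless of the
    potentials; isotope-labeled units are further red-shifted by the isotope
    shift.
    """
    if unit.is_proline:
        omega = params.proline_frequency
    else:
        l = np.array([params.l_coefficients[a] for a in EVAL_ATOMS])
        omega = params.omega0 + float(np.dot(l, np.asarray(potentials, float)))
    if unit.isotope_labeled:
        omega -= params.isotope_shift
    return float(omega)


# ---------------------------------------------------------------------------
# Hamiltonian assembly
# ---------------------------------------------------------------------------

def _are_sequence_adjacent(a: PeptideUnit, b: PeptideUnit) -> bool:
    return (a.following_residue.chain_id == b.preceding_residue.chain_id
            and a.following_residue.index == b.preceding_residue.index)


def build_one_exciton(units: Sequence[PeptideUnit], env: ChargeEnvironment,
                      params: SiteEnergyParams | None = None,
                      nnc_map: NNCMap | None = None,
                      dielectric: float = 1.0,
                      tdc_scale: float = 1.0,
                      dipole_magnitude: float = 3.7) -> OneExcitonHamiltonian:
    """Assemble the one-quantum exciton Hamiltonian.

    Diagonal: electrostatic site frequencies.  Off-diagonal: sequence-
    adjacent units within a chain use the nearest-neighbor coupling map
    evaluated at the shared residue's (φ, ψ); every other pair — including
    across chain breaks and between chains — uses transition-dipole
    coupling.
    """
    if not units:
        raise ValueError("at least one peptide unit is required")
    params = params or SiteEnergyParams()
    n = len(units)
    dipoles = [place_transition_dipole(u, magnitude=dipole_magnitude) for u in units]
    H = np.zeros((n, n))
    for i, u in enumerate(units):
        pots = site_potentials(u, env, params.potential_unit_scale)
        H[i, i] = site_frequency(u, pots, params)
    for i in range(n):
        for j in range(i + 1, n):
            if _are_sequence_adjacent(units[i], units[j]):
                if nnc_map is None:
                    raise ValueError(
                        "nearest-neighbor pair present but no NNC map supplied"
                    )
                # (φ, ψ) of the shared residue
                coupling = nnc_coupling(units[i].phi, units[j].psi, nnc_map)
            else:
                coupling = tdc_coupling(dipoles[i], dipoles[j],
                                        dielectric=dielectric, tdc_scale=tdc_scale)
            H[i, j] = H[j, i] = coupling
    return OneExcitonHamiltonian(matrix=H, dipoles=dipoles,
                                 site_metadata=list(units))


def pair_states(n: int) -> list[tuple[int, int]]:
    """Ordered two-quantum pair index: all (m, n) with m ≤ n."""
    return [(m, k) for m in range(n) for k in range(m, n)]


def build_two_exciton(h1: OneExcitonHamiltonian | np.ndarray,
                      anharmonicity: float = 16.0) -> TwoExcitonSystem:
    """Lift the one-quantum Hamiltonian to the symmetric two-quantum space.

    Diagonal: overtones (m,m) at 2H_mm − Δ, combinations (m,n) at
    H_mm + H_nn.  Off-diagonal: overtone↔combination sharing one index is
    √2·H (bosonic enhancement); combinations sharing exactly one index
    couple by the corresponding one-quantum element; disjoint pairs do not
    couple.
    """
    if isinstance(h1, OneExcitonHamiltonian):
        H = h1.matrix
        dip = h1.dipole_vectors
    else:
        H = np.asarray(h1, float)
        dip = None
    if np.max(np.abs(H - H.T)) > 1e-9:
        raise ValueError("one-quantum Hamiltonian must be symmetric")
    n = H.shape[0]
    pairs = pair_states(n)
    p = len(pairs)
    H2 = np.zeros((p, p))
    for a, (m, k) in enumerate(pairs):
        H2[a, a] = (2.0 * H[m, m] - anharmonicity) if m == k else H[m, m] + H[k, k]
        for b in range(a + 1, p):
            q, r = pairs[b]
            shared = {m, k} & {q, r}
            # elements between states sharing exactly one site index
            if m == k and len(shared) == 1:       # overtone (m,m) ↔ (q,r)
                other = r if q == m else (q if r == m else None)
                if other is not None:
                    H2[a, b] = np.sqrt(2.0) * H[m, other]
            elif q == r and len(shared) == 1:     # (m,k) ↔ overtone (q,q)
                other = k if m == q else (m if k == q else None)
                if other is not None:
                    H2[a, b] = np.sqrt(2.0) * H[q, other]
            elif len(shared) == 1 and m != k and q != r:
                s = shared.pop()
                i1 = k if m == s else m
                i2 = r if q == s else q
                H2[a, b] = H[i1, i2]
            H2[b, a] = H2[a, b]
    table = two_quantum_dipoles(dip, pairs) if dip is not None else \
        np.zeros((n, p, 3))
    return TwoExcitonSystem(pair_index=pairs, matrix=H2, dipole_table=table,
                            anharmonicity=anharmonicity)


def two_quantum_dipoles(dipole_vectors: np.ndarray,
                        pair_index: Sequence[tuple[int, int]]) -> np.ndarray:
    """Site-basis one-quantum → two-quantum transition dipoles.

    T[n, p] for pair state p = (m, k): √2·μ_n if m = k = n (overtone),
    μ_k if n = m ≠ k, μ_m if n = k ≠ m, zero otherwise.  Transformed to the
    eigenbasis downstream by the one- and two-exciton eigenvector matrices.
    """
    mu = np.asarray(dipole_vectors, float)
    n = mu.shape[0]
    table = np.zeros((n, len(pair_index), 3))
    for p, (m, k) in enumerate(pair_index):
        if m == k:
            table[m, p] = np.sqrt(2.0) * mu[m]
        else:
            table[m, p] = mu[k]
            table[k, p] = mu[m]
    return table


def write_hamiltonian(h1: OneExcitonHamiltonian, path: str | Path,
                      **parameters) -> None:
    """Export the one-quantum matrix as plain text with a header recording
    the model parameters (one ``# key = value`` line each)."""
    lines = [f"# n_sites = {h1.n_sites}"]
    lines += [f"# {k} = {v}" for k, v in parameters.items()]
    for row in h1.matrix:
        lines.append("\t".join(f"{x:.6f}" for x in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_hamiltonian(path: str | Path) -> np.ndarray:
    """Read a plain-text symmetric matrix written by :func:`write_hamiltonian`."""
    rows = [[float(x) for x in line.split()]
            for line in Path(path).read_text().splitlines()
            if line.strip() and not line.startswith("#")]
    H = np.array(rows, float)
    if H.ndim != 2 or H.shape[0] != H.shape[1]:
        raise ValueError("matrix file is not square")
    return H


def diagonalize(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (ascending) and orthonormal eigenvectors of a symmetric
    matrix, with the phase of each eigenvector fixed so its largest-
    magnitude component is positive (reproducible reports under
    degeneracy)."""
    H = np.asarray(matrix, float)
    if H.ndim != 2 or H.shape[0] != H.shape[1]:
        raise ValueError("matrix must be square")
    scale = np.max(np.abs(H)) or 1.0
    if np.max(np.abs(H - H.T)) > 1e-8 * scale:
        raise ValueError("matrix must be symmetric")
    evals, evecs = np.linalg.eigh(H)
    for a in range(evecs.shape[1]):
        i = int(np.argmax(np.abs(evecs[:, a])))
        if evecs[i, a] < 0:
            evecs[:, a] = -evecs[:, a]
    return evals, evecs
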