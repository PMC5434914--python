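"""1D absorption and absorptive 2D IR spectra from exciton eigensystems.

The 2D signal is the static (snapshot-frozen, t₂ = 0) frequency-domain sum
over states: rephasing plus nonrephasing third-order pathways evaluated per
snapshot, with positive ground-state-bleach/stimulated-emission sticks and
negative excited-state-absorption sticks.  Orientational averaging follows
the ⟨ZZZZ⟩ and ⟨ZXXZ⟩ polarization conditions; the cross-peak-enhanced
signal is ⟨ZZZZ⟩ − 3⟨ZXXZ⟩.

Line shapes: 1D sticks are convolved with a unit-area Gaussian (default
FWHM 4 cm⁻¹); 2D sticks with a separable 2D Lorentzian (default FWHM
10 cm⁻¹ in each axis).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .hamiltonian import (
    NNCMap,
    OneExcitonHamiltonian,
    SiteEnergyParams,
    TwoExcitonSystem,
    build_one_exciton,
    build_two_exciton,
    diagonalize,
)
from .structures_io import (
    ChargeEnvironment,
    Snapshot,
    SnapshotEnsemble,
    assign_charges,
    filter_environment,
    identify_peptide_units,
)

logger = logging.getLogger("amideir.spectra")

__all__ = [
    "Spectrum1D",
    "Spectrum2D",
    "Stick1DList",
    "Stick2DList",
    "SCHEMES",
    "stick_spectrum_1d",
    "convolve_gaussian",
    "spectrum_2d_sticks",
    "orientational_factor",
    "enhanced_signal",
    "convolve_lorentzian_2d",
    "ensemble_average",
    "find_peaks",
    "default_grid_1d",
    "default_grid_2d",
    "snapshot_spectrum_1d",
    "snapshot_sticks_2d",
    "ensemble_spectrum_1d",
    "ensemble_spectrum_2d",
]

SCHEMES = ("zzzz", "zxxz", "enhanced")

GAUSSIAN_FWHM_DEFAULT = 4.0     # cm⁻¹, 1D homogeneous broadening
LORENTZIAN_FWHM_DEFAULT = 10.0  # cm⁻¹, 2D homogeneous broadening


def default_grid_1d(step: float = 0.5) -> np.ndarray:
    """Default 1D wavenumber axis: 1500–1800 cm⁻¹ (covers isotope shifts)."""
    return np.arange(1500.0, 1800.0 + 0.5 * step, step)


def default_grid_2d(step: float = 1.0) -> np.ndarray:
    """Default 2D axis (used for both ω₁ and ω₃): 1520–1780 cm⁻¹."""
    return np.arange(1520.0, 1780.0 + 0.5 * step, step)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class Spectrum1D:
    grid: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, float)
        self.intensity = np.asarray(self.intensity, float)
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if self.grid.shape != self.intensity.shape:
            raise ValueError("grid/intensity shape mismatch")
        if np.any(self.intensity < -1e-12 * max(1.0, np.max(np.abs(self.intensity)))):
            raise ValueError("1D intensity must be non-negative")

    def write_tsv(self, path: str | Path) -> None:
        lines = [f"# {k} = {v}" for k, v in self.metadata.items()]
        lines.append("# wavenumber_cm-1\tintensity")
        lines += [f"{w:.4f}\t{i:.8e}" for w, i in zip(self.grid, self.intensity)]
        Path(path).write_text("\n".join(lines) + "\n")

    def write_hdf5(self, path: str | Path) -> None:
        import h5py

        with h5py.File(str(path), "w") as f:
            f.create_dataset("grid_cm-1", data=self.grid)
            f.create_dataset("intensity", data=self.intensity)
            for k, v in self.metadata.items():
                f.attrs[k] = v


@dataclass
class Spectrum2D:
    omega1_grid: np.ndarray
    omega3_grid: np.ndarray
    amplitude: np.ndarray  # indexed [i_omega1, i_omega3], signed
    scheme: str = "zzzz"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.omega1_grid = np.asarray(self.omega1_grid, float)
        self.omega3_grid = np.asarray(self.omega3_grid, float)
        self.amplitude = np.asarray(self.amplitude, float)
        for g in (self.omega1_grid, self.omega3_grid):
            if np.any(np.diff(g) <= 0):
                raise ValueError("grids must be strictly increasing")
        if self.amplitude.shape != (len(self.omega1_grid), len(self.omega3_grid)):
            raise ValueError("amplitude shape mismatch")
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")

    def write_tsv(self, path: str | Path) -> None:
        lines = [f"# {k} = {v}" for k, v in self.metadata.items()]
        lines.append(f"# scheme = {self.scheme}")
        lines.append("# omega1_cm-1\tomega3_cm-1\tamplitude")
        for i, w1 in enumerate(self.omega1_grid):
            for j, w3 in enumerate(self.omega3_grid):
                lines.append(f"{w1:.4f}\t{w3:.4f}\t{self.amplitude[i, j]:.8e}")
        Path(path).write_text("\n".join(lines) + "\n")

    def write_hdf5(self, path: str | Path) -> None:
        import h5py

        with h5py.File(str(path), "w") as f:
            f.create_dataset("omega1_cm-1", data=self.omega1_grid)
            f.create_dataset("omega3_cm-1", data=self.omega3_grid)
            f.create_dataset("amplitude", data=self.amplitude)
            f.attrs["scheme"] = self.scheme
            for k, v in self.metadata.items():
                f.attrs[k] = v


@dataclass
class Stick1DList:
    """1D stick spectrum: one stick per one-exciton eigenstate."""

    positions: np.ndarray   # cm⁻¹
    weights: np.ndarray     # |eigenstate dipole|²
    states: np.ndarray      # eigenstate indices

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())


@dataclass
class Stick2DList:
    """2D stick spectrum with pathway bookkeeping.

    ``weight`` includes the orientational factor and pathway multiplicity;
    ``dipole_mag`` is the product of the four interaction dipole magnitudes
    (squared pairs), kept for dipole-strength analyses.  ``state_a`` /
    ``state_b`` are one-exciton eigenstates; ``state_c`` the two-exciton
    eigenstate for ESA sticks (−1 otherwise).
    """

    omega1: np.ndarray
    omega3: np.ndarray
    weight: np.ndarray
    pathway: np.ndarray  # 'GB' | 'SE' | 'ESA'
    state_a: np.ndarray
    state_b: np.ndarray
    state_c: np.ndarray
    dipole_mag: np.ndarray
    scheme: str = "zzzz"

    def __len__(self) -> int:
        return len(self.weight)

    @classmethod
    def concatenate(cls, parts: Sequence["Stick2DList"]) -> "Stick2DList":
        return cls(
            omega1=np.concatenate([p.omega1 for p in parts]),
            omega3=np.concatenate([p.omega3 for p in parts]),
            weight=np.concatenate([p.weight for p in parts]),
            pathway=np.concatenate([p.pathway for p in parts]),
            state_a=np.concatenate([p.state_a for p in parts]),
            state_b=np.concatenate([p.state_b for p in parts]),
            state_c=np.concatenate([p.state_c for p in parts]),
            dipole_mag=np.concatenate([p.dipole_mag for p in parts]),
            scheme=parts[0].scheme,
        )


# ---------------------------------------------------------------------------
# 1D spectra
# ---------------------------------------------------------------------------

def stick_spectrum_1d(eigenvalues: np.ndarray, eigenvectors: np.ndarray,
                      dipole_vectors: np.ndarray) -> Stick1DList:
    """One stick per eigenstate: position λ_a, weight |Σ_i V_ia μ_i|²."""
    V = np.asarray(eigenvectors, float)
    mu = np.asarray(dipole_vectors, float)
    M = V.T @ mu  # (N_states, 3) eigenstate dipoles
    weights = np.einsum("ax,ax->a", M, M)
    return Stick1DList(positions=np.asarray(eigenvalues, float).copy(),
                       weights=weights, states=np.arange(len(weights)))


def convolve_gaussian(sticks: Stick1DList, fwhm: float = GAUSSIAN_FWHM_DEFAULT,
                      grid: np.ndarray | None = None,
                      metadata: dict | None = None) -> Spectrum1D:
    """Replace each stick by a unit-area Gaussian of the given FWHM."""
    if grid is None:
        grid = default_grid_1d()
    grid = np.asarray(grid, float)
    if len(sticks.positions):
        lo, hi = sticks.positions.min(), sticks.positions.max()
        if grid[0] > lo - 5 * fwhm or grid[-1] < hi + 5 * fwhm:
            raise ValueError(
                f"grid [{grid[0]}, {grid[-1]}] does not cover sticks "
                f"[{lo:.1f}, {hi:.1f}] ± 5·FWHM"
            )
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    norm = 1.0 / (sigma * np.sqrt(2.0 * np.pi))
    diff = grid[:, None] - sticks.positions[None, :]
    intensity = norm * np.exp(-0.5 * (diff / sigma) ** 2) @ sticks.weights
    meta = {"fwhm_1d_cm-1": fwhm, **(metadata or {})}
    return Spectrum1D(grid=grid, intensity=intensity, metadata=meta)


# ---------------------------------------------------------------------------
# Orientational averaging
# ---------------------------------------------------------------------------

def _orient_terms(v1, v2, v3, v4) -> tuple[float, float, float]:
    return (float(np.dot(v1, v2) * np.dot(v3, v4)),
            float(np.dot(v1, v3) * np.dot(v2, v4)),
            float(np.dot(v1, v4) * np.dot(v2, v3)))


def _combine(t_abgd: np.ndarray, t_agbd: np.ndarray, t_adbg: np.ndarray,
             scheme: str) -> np.ndarray:
    """Combine the three isotropic invariants per polarization scheme.

    ⟨ZZZZ⟩ = (1/15)(A + B + C); ⟨ZXXZ⟩ = −(1/30)(A − 4B + C) with
    A = cosθ_αβ cosθ_γδ, B = cosθ_αγ cosθ_βδ, C = cosθ_αδ cosθ_βγ.
    """
    if scheme == "zzzz":
        return (t_abgd + t_agbd + t_adbg) / 15.0
    if scheme == "zxxz":
        return -(t_abgd - 4.0 * t_agbd + t_adbg) / 30.0
    if scheme == "enhanced":
        return (_combine(t_abgd, t_agbd, t_adbg, "zzzz")
                - 3.0 * _combine(t_abgd, t_agbd, t_adbg, "zxxz"))
    raise ValueError(f"unknown scheme {scheme!r}")


def orientational_factor(d_alpha, d_beta, d_gamma, d_delta,
                         scheme: str = "zzzz") -> float:
    """Isotropic orientational factor for four unit interaction dipoles."""
    dirs = []
    for v in (d_alpha, d_beta, d_gamma, d_delta):
        v = np.asarray(v, float)
        n = np.linalg.norm(v)
        if abs(n - 1.0) > 1e-9:
            warnings.warn("orientational_factor: normalizing non-unit vector")
            v = v / n
        dirs.append(v)
    a, b, c = _orient_terms(*dirs)
    return float(_combine(np.array(a), np.array(b), np.array(c), scheme))


# ---------------------------------------------------------------------------
# 2D stick spectra (static sum over states, t2 = 0)
# ---------------------------------------------------------------------------

def spectrum_2d_sticks(one_evals: np.ndarray, one_evecs: np.ndarray,
                       two_evals: np.ndarray, two_evecs: np.ndarray,
                       dipole_vectors: np.ndarray, dipole_table: np.ndarray,
                       scheme: str = "zzzz") -> Stick2DList:
    """Stick 2D spectrum from the one- and two-exciton eigensystems.

    Six double-sided pathways at t₂ = 0 (amplitudes carry the orientational
    factor with the four interaction dipole vectors unnormalised, so dipole
    magnitudes are folded in):

    * GB  (rephasing + nonrephasing, weight 2): +O(μa, μa, μb, μb) at (Ea, Eb)
    * SE  rephasing:                            +O(μa, μb, μa, μb) at (Ea, Eb)
    * SE  nonrephasing:                         +O(μa, μb, μb, μa) at (Ea, Ea)
    * ESA rephasing:    −O(μa, μb, μ_{b→c}, μ_{a→c}) at (Ea, Fc − Ea)
    * ESA nonrephasing: −O(μa, μb, μ_{a→c}, μ_{b→c}) at (Ea, Fc − Eb)

    where μa are one-exciton eigenstate dipoles and μ_{a→c} the eigenbasis
    two-quantum dipoles.  With Δ = 0 the positive and negative sticks cancel
    identically (harmonic limit).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    E = np.asarray(one_evals, float)
    V1 = np.asarray(one_evecs, float)
    F = np.asarray(two_evals, float)
    V2 = np.asarray(two_evecs, float)
    mu = np.asarray(dipole_vectors, float)
    T = np.asarray(dipole_table, float)
    n = len(E)

    M = V1.T @ mu                                  # (n, 3) eigenstate dipoles
    U = np.einsum("nb,pc,npx->bcx", V1, V2, T)     # (n, P, 3) eigenbasis 1→2 dipoles
    Mmag = np.sqrt(np.einsum("ax,ax->a", M, M))
    Umag = np.sqrt(np.einsum("bcx,bcx->bc", U, U))

    D = M @ M.T                                    # Ma·Mb
    X = np.einsum("ax,bcx->abc", M, U)             # Ma·U[b,c]
    Y = np.einsum("bcx,acx->bac", U, U)            # U[b,c]·U[a,c]

    a_idx, b_idx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    a_flat, b_flat = a_idx.ravel(), b_idx.ravel()

    parts: list[Stick2DList] = []

    def _mk(o1, o3, w, pathway, sa, sb, sc, dm):
        parts.append(Stick2DList(
            omega1=np.asarray(o1, float).ravel(),
            omega3=np.asarray(o3, float).ravel(),
            weight=np.asarray(w, float).ravel(),
            pathway=np.full(np.size(w), pathway, dtype="U3"),
            state_a=np.asarray(sa, int).ravel(),
            state_b=np.asarray(sb, int).ravel(),
            state_c=np.asarray(sc, int).ravel(),
            dipole_mag=np.asarray(dm, float).ravel(),
            scheme=scheme,
        ))

    # GB: α=a, β=a, γ=b, δ=b (two diagrams)
    w_gb = 2.0 * _combine(D[a_idx, a_idx] * D[b_idx, b_idx],
                          D[a_idx, b_idx] * D[a_idx, b_idx],
                          D[a_idx, b_idx] * D[a_idx, b_idx], scheme)
    _mk(E[a_idx], E[b_idx], w_gb, "GB", a_flat, b_flat,
        np.full(n * n, -1), (Mmag[a_idx] ** 2 * Mmag[b_idx] ** 2))

    # SE rephasing: α=a, β=b, γ=a, δ=b at (Ea, Eb)
    w_ser = _combine(D[a_idx, b_idx] * D[a_idx, b_idx],
                     D[a_idx, a_idx] * D[b_idx, b_idx],
                     D[a_idx, b_idx] * D[a_idx, b_idx], scheme)
    _mk(E[a_idx], E[b_idx], w_ser, "SE", a_flat, b_flat,
        np.full(n * n, -1), (Mmag[a_idx] ** 2 * Mmag[b_idx] ** 2))

    # SE nonrephasing: α=a, β=b, γ=b, δ=a at (Ea, Ea)
    w_sen = _combine(D[a_idx, b_idx] * D[a_idx, b_idx],
                     D[a_idx, b_idx] * D[a_idx, b_idx],
                     D[a_idx, a_idx] * D[b_idx, b_idx], scheme)
    _mk(E[a_idx], E[a_idx], w_sen, "SE", a_flat, b_flat,
        np.full(n * n, -1), (Mmag[a_idx] ** 2 * Mmag[b_idx] ** 2))

    # ESA: dot products between M and eigenbasis two-quantum dipoles
    P = len(F)
    A3, B3, C3 = np.meshgrid(np.arange(n), np.arange(n), np.arange(P),
                             indexing="ij")
    Dab = D[A3, B3]
    # rephasing: α=a, β=b, γ=U[b,c], δ=U[a,c] at (Ea, Fc − Ea)
    w_esar = -_combine(Dab * Y[B3, A3, C3],
                       X[A3, B3, C3] * X[B3, A3, C3],
                       X[A3, A3, C3] * X[B3, B3, C3], scheme)
    _mk(E[A3], F[C3] - E[A3], w_esar, "ESA", A3, B3, C3,
        Mmag[A3] * Mmag[B3] * Umag[B3, C3] * Umag[A3, C3])
    # nonrephasing: α=a, β=b, γ=U[a,c], δ=U[b,c] at (Ea, Fc − Eb)
    w_esan = -_combine(Dab * Y[A3, B3, C3],
                       X[A3, A3, C3] * X[B3, B3, C3],
                       X[A3, B3, C3] * X[B3, A3, C3], scheme)
    _mk(E[A3], F[C3] - E[B3], w_esan, "ESA", A3, B3, C3,
        Mmag[A3] * Mmag[B3] * Umag[A3, C3] * Umag[B3, C3])

    return Stick2DList.concatenate(parts)


def enhanced_signal(s_zzzz: Spectrum2D, s_zxxz: Spectrum2D) -> Spectrum2D:
    """Cross-peak-enhanced spectrum: pointwise ⟨ZZZZ⟩ − 3⟨ZXXZ⟩."""
    if (not np.array_equal(s_zzzz.omega1_grid, s_zxxz.omega1_grid)
            or not np.array_equal(s_zzzz.omega3_grid, s_zxxz.omega3_grid)):
        raise ValueError("grids of the two spectra do not match")
    return Spectrum2D(
        omega1_grid=s_zzzz.omega1_grid, omega3_grid=s_zzzz.omega3_grid,
        amplitude=s_zzzz.amplitude - 3.0 * s_zxxz.amplitude,
        scheme="enhanced",
        metadata={**s_zzzz.metadata, "combination": "zzzz - 3*zxxz"},
    )


def convolve_lorentzian_2d(sticks: Stick2DList,
                           width: float = LORENTZIAN_FWHM_DEFAULT,
                           omega1_grid: np.ndarray | None = None,
                           omega3_grid: np.ndarray | None = None,
                           metadata: dict | None = None) -> Spectrum2D:
    """Broaden each 2D stick with a separable unit-area Lorentzian kernel
    of the given FWHM in both axes; signed amplitudes are preserved."""
    if omega1_grid is None:
        omega1_grid = default_grid_2d()
    if omega3_grid is None:
        omega3_grid = default_grid_2d()
    omega1_grid = np.asarray(omega1_grid, float)
    omega3_grid = np.asarray(omega3_grid, float)
    gamma = width / 2.0

    keep = np.abs(sticks.weight) > 0.0
    s1, s3, w = sticks.omega1[keep], sticks.omega3[keep], sticks.weight[keep]
    amp = np.zeros((len(omega1_grid), len(omega3_grid)))
    chunk = 20000
    for start in range(0, len(w), chunk):
        sl = slice(start, start + chunk)
        l1 = (gamma / np.pi) / ((omega1_grid[:, None] - s1[None, sl]) ** 2 + gamma ** 2)
        l3 = (gamma / np.pi) / ((omega3_grid[:, None] - s3[None, sl]) ** 2 + gamma ** 2)
        amp += (l1 * w[None, sl]) @ l3.T
    meta = {"lorentzian_fwhm_cm-1": width, **(metadata or {})}
    return Spectrum2D(omega1_grid=omega1_grid, omega3_grid=omega3_grid,
                      amplitude=amp, scheme=sticks.scheme, metadata=meta)


# ---------------------------------------------------------------------------
# Ensemble averaging and peak finding
# ---------------------------------------------------------------------------

def ensemble_average(spectra: Sequence[Spectrum1D | Spectrum2D]
                     ) -> tuple[Spectrum1D | Spectrum2D, np.ndarray, int, int]:
    """Pointwise mean and standard deviation over snapshot spectra.

    Returns (mean spectrum, std array, index of the snapshot most similar
    to the mean, index least similar).  Similarity is the Euclidean distance
    between a snapshot spectrum and the mean on the common grid; ties take
    the lowest index.
    """
    if not spectra:
        raise ValueError("empty spectra list")
    first = spectra[0]
    if isinstance(first, Spectrum1D):
        grids = [s.grid for s in spectra]
        values = np.stack([s.intensity for s in spectra])
    else:
        grids = [s.omega1_grid for s in spectra]
        values = np.stack([s.amplitude for s in spectra])
    for g in grids[1:]:
        if not np.array_equal(g, grids[0]):
            raise ValueError("spectra are not on a common grid")
    mean = values.mean(axis=0)
    std = values.std(axis=0)
    dist = np.sqrt(((values - mean) ** 2).reshape(len(spectra), -1).sum(axis=1))
    most = int(np.argmin(dist))
    least = int(np.argmax(dist))
    meta = {"n_snapshots": len(spectra), **first.metadata}
    if isinstance(first, Spectrum1D):
        mean_spec: Spectrum1D | Spectrum2D = Spectrum1D(
            grid=first.grid, intensity=mean, metadata=meta)
    else:
        mean_spec = Spectrum2D(omega1_grid=first.omega1_grid,
                               omega3_grid=first.omega3_grid,
                               amplitude=mean, scheme=first.scheme, metadata=meta)
    return mean_spec, std, most, least


@dataclass(frozen=True)
class Peak:
    position: tuple[float, ...]
    amplitude: float
    is_diagonal: bool | None = None


def find_peaks(spectrum: Spectrum1D | Spectrum2D,
               threshold_fraction: float = 0.10) -> list[Peak]:
    """Local maxima (1D) or signed local extrema (2D) above a fraction of
    the global maximum magnitude.  2D peaks with |ω₁ − ω₃| within two grid
    steps are labeled diagonal."""
    if isinstance(spectrum, Spectrum1D):
        y = spectrum.intensity
        if np.max(np.abs(y)) == 0:
            return []
        thr = threshold_fraction * np.max(np.abs(y))
        peaks = []
        for i in range(1, len(y) - 1):
            if y[i] >= y[i - 1] and y[i] >= y[i + 1] and y[i] >= thr \
                    and (y[i] > y[i - 1] or y[i] > y[i + 1]):
                peaks.append(Peak(position=(float(spectrum.grid[i]),),
                                  amplitude=float(y[i])))
        return peaks

    amp = spectrum.amplitude
    if np.max(np.abs(amp)) == 0:
        return []
    thr = threshold_fraction * np.max(np.abs(amp))
    step = float(np.mean(np.diff(spectrum.omega1_grid)))
    peaks = []
    for i in range(1, amp.shape[0] - 1):
        for j in range(1, amp.shape[1] - 1):
            v = amp[i, j]
            if abs(v) < thr:
                continue
            patch = amp[i - 1:i + 2, j - 1:j + 2]
            if (v > 0 and v >= patch.max() and v > patch.min()) or \
               (v < 0 and v <= patch.min() and v < patch.max()):
                w1 = float(spectrum.omega1_grid[i])
                w3 = float(spectrum.omega3_grid[j])
                peaks.append(Peak(position=(w1, w3), amplitude=float(v),
                                  is_diagonal=abs(w1 - w3) <= 2.0 * step + 1e-9))
    return peaks


# ---------------------------------------------------------------------------
# Snapshot and ensemble pipelines
# ---------------------------------------------------------------------------

def _snapshot_eigensystem(snapshot: Snapshot, params: SiteEnergyParams,
                          nnc_map: NNCMap, include_solvent: bool,
                          charge_table=None, dielectric: float = 1.0,
                          tdc_scale: float = 1.0,
                          labeled_sites: Iterable[int] = ()):
    units = identify_peptide_units(snapshot)
    for s in labeled_sites:
        units[s].isotope_labeled = True
    env = assign_charges(snapshot, charge_table, units=units)
    if not include_solvent:
        env = filter_environment(env, {"backbone", "sidechain", "ion"})
    h1 = build_one_exciton(units, env, params, nnc_map,
                           dielectric=dielectric, tdc_scale=tdc_scale)
    return h1


def snapshot_spectrum_1d(snapshot: Snapshot, params: SiteEnergyParams,
                         nnc_map: NNCMap, include_solvent: bool = True,
                         charge_table=None, fwhm: float = GAUSSIAN_FWHM_DEFAULT,
                         grid: np.ndarray | None = None,
                         labeled_sites: Iterable[int] = (),
                         tdc_scale: float = 1.0) -> Spectrum1D:
    """Full 1D pipeline for one snapshot: chromophores → Hamiltonian →
    eigensystem → Gaussian-broadened absorption spectrum."""
    h1 = _snapshot_eigensystem(snapshot, params, nnc_map, include_solvent,
                               charge_table, tdc_scale=tdc_scale,
                               labeled_sites=labeled_sites)
    evals, evecs = diagonalize(h1.matrix)
    sticks = stick_spectrum_1d(evals, evecs, h1.dipole_vectors)
    return convolve_gaussian(sticks, fwhm=fwhm, grid=grid,
                             metadata={"omega0_cm-1": params.omega0,
                                       "n_sites": h1.n_sites,
                                       "solvent": include_solvent})


def snapshot_sticks_2d(snapshot: Snapshot, params: SiteEnergyParams,
                       nnc_map: NNCMap, scheme: str = "zzzz",
                       include_solvent: bool = True, charge_table=None,
                       anharmonicity: float = 16.0,
                       labeled_sites: Iterable[int] = (),
                       tdc_scale: float = 1.0) -> Stick2DList:
    """Full 2D stick pipeline for one snapshot."""
    h1 = _snapshot_eigensystem(snapshot, params, nnc_map, include_solvent,
                               charge_table, tdc_scale=tdc_scale,
                               labeled_sites=labeled_sites)
    h2 = build_two_exciton(h1, anharmonicity=anharmonicity)
    e1, v1 = diagonalize(h1.matrix)
    e2, v2 = diagonalize(h2.matrix)
    return spectrum_2d_sticks(e1, v1, e2, v2, h1.dipole_vectors,
                              h2.dipole_table, scheme=scheme)


def select_snapshots(ensemble: SnapshotEnsemble,
                     n_snapshots: int | None) -> tuple[list[Snapshot], list[int]]:
    """Uniformly strided snapshot selection over the ensemble."""
    total = ensemble.n_snapshots
    if n_snapshots is None or n_snapshots >= total:
        return list(ensemble.snapshots), list(range(total))
    if n_snapshots < 1:
        raise ValueError("n_snapshots must be >= 1")
    idx = np.unique(np.round(np.linspace(0, total - 1, n_snapshots)).astype(int))
    logger.info("using %d of %d snapshots: %s", len(idx), total, idx.tolist())
    return [ensemble.snapshots[i] for i in idx], idx.tolist()


def ensemble_spectrum_1d(ensemble: SnapshotEnsemble, params: SiteEnergyParams,
                         nnc_map: NNCMap, include_solvent: bool = True,
                         charge_table=None, fwhm: float = GAUSSIAN_FWHM_DEFAULT,
                         grid: np.ndarray | None = None,
                         n_snapshots: int | None = None,
                         labeled_sites: Iterable[int] = (),
                         tdc_scale: float = 1.0
                         ) -> tuple[Spectrum1D, list[Spectrum1D]]:
    """Mean 1D spectrum over uniformly weighted snapshots, plus the
    individual snapshot spectra."""
    snaps, _ = select_snapshots(ensemble, n_snapshots)
    spectra = [snapshot_spectrum_1d(s, params, nnc_map, include_solvent,
                                    charge_table, fwhm, grid, labeled_sites,
                                    tdc_scale)
               for s in snaps]
    mean, _, _, _ = ensemble_average(spectra)
    return mean, spectra


def ensemble_spectrum_2d(ensemble: SnapshotEnsemble, params: SiteEnergyParams,
                         nnc_map: NNCMap, scheme: str = "zzzz",
                         include_solvent: bool = True, charge_table=None,
                         anharmonicity: float = 16.0,
                         lorentzian_fwhm: float = LORENTZIAN_FWHM_DEFAULT,
                         omega1_grid: np.ndarray | None = None,
                         omega3_grid: np.ndarray | None = None,
                         n_snapshots: int | None = None,
                         labeled_sites: Iterable[int] = (),
                         tdc_scale: float = 1.0) -> Spectrum2D:
    """Mean absorptive 2D spectrum over uniformly weighted snapshots.

    For the enhanced scheme the ⟨ZZZZ⟩ and ⟨ZXXZ⟩ spectra are computed from
    the same sticks and combined as ⟨ZZZZ⟩ − 3⟨ZXXZ⟩ (the orientational
    factors are linear, so combining at the stick level is equivalent)."""
    snaps, _ = select_snapshots(ensemble, n_snapshots)
    spectra = []
    for s in snaps:
        sticks = snapshot_sticks_2d(s, params, nnc_map, scheme, include_solvent,
                                    charge_table, anharmonicity, labeled_sites,
                                    tdc_scale)
        spectra.append(convolve_lorentzian_2d(sticks, lorentzian_fwhm,
                                              omega1_grid, omega3_grid))
    mean, _, _, _ = ensemble_average(spectra)
    mean.metadata["n_snapshots"] = len(snaps)
    mean.metadata["anharmonicity_cm-1"] = anharmonicity
    return mean
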