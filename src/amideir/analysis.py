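"""Post-hoc analyses: exciton delocalization, hydrogen-bond / frequency-shift
statistics, isotope-label selection and per-residue transition-dipole
strengths.

All operations are pure: they never mutate the ensembles or eigensystems
they are given (``select_labels`` returns labeled copies).
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .hamiltonian import SiteEnergyParams, site_frequency, site_potentials
from .spectra import Stick2DList
from .structures_io import (
    AtomRecord,
    PeptideUnit,
    Snapshot,
    SnapshotEnsemble,
    StructureError,
    assign_charges,
    filter_environment,
    identify_peptide_units,
)

logger = logging.getLogger("amideir.analysis")

__all__ = [
    "DelocalizationReport",
    "HBondHistogram",
    "delocalization",
    "count_hbonds",
    "solvent_shift_histogram",
    "select_labels",
    "load_ss_labels",
    "dipole_strength_per_residue",
    "SS_LABELS",
]

#: Secondary-structure vocabulary: H (α-helix), G (3₁₀ helix), E (strand),
#: T (turn), C (coil).  Helix labeling targets H ∪ G by default.
SS_LABELS = frozenset({"H", "G", "E", "T", "C"})


@dataclass
class DelocalizationReport:
    """Per-eigenstate local-mode composition.

    The squared eigenvector coefficients give the contribution of each local
    mode to a transition; sites whose squared coefficient exceeds the
    threshold are flagged dominant.
    """

    eigenvalues: np.ndarray
    squared_coefficients: np.ndarray  # (n_states, n_sites)
    dominant_sites: list[list[int]]
    threshold: float

    def participation_ratio(self) -> np.ndarray:
        """Inverse participation ratio per eigenstate: 1/Σ_i c_i⁴."""
        return 1.0 / np.sum(self.squared_coefficients ** 2, axis=1)


def delocalization(eigenvalues: np.ndarray, eigenvectors: np.ndarray,
                   threshold: float = 0.25) -> DelocalizationReport:
    """Squared eigenvector coefficients per site, per eigenstate."""
    V = np.asarray(eigenvectors, float)
    sq = (V ** 2).T  # row a = squared coefficients of eigenstate a
    norms = sq.sum(axis=1)
    if np.max(np.abs(norms - 1.0)) > 1e-9:
        raise ValueError("eigenvectors are not orthonormal")
    dominant = [list(np.flatnonzero(row > threshold)) for row in sq]
    return DelocalizationReport(
        eigenvalues=np.asarray(eigenvalues, float).copy(),
        squared_coefficients=sq, dominant_sites=dominant, threshold=threshold,
    )


# ---------------------------------------------------------------------------
# Hydrogen bonding to solvent
# ---------------------------------------------------------------------------

def count_hbonds(unit: PeptideUnit, solvent_atoms: Sequence[AtomRecord],
                 d_max: float = 2.6, angle_min: float = 130.0) -> int:
    """Water hydrogens donating to the unit's carbonyl oxygen.

    Criterion: H···O(carbonyl) ≤ ``d_max`` Å and O_w–H···O angle ≥
    ``angle_min`` degrees.  Water hydrogens are paired with the oxygen of
    the same water residue.
    """
    o_by_res: dict[tuple[str, int], np.ndarray] = {}
    hydrogens: list[tuple[tuple[str, int], np.ndarray]] = []
    for atom in solvent_atoms:
        key = (atom.chain_id, atom.residue_index)
        if atom.element.upper() == "O":
            o_by_res[key] = atom.position
        elif atom.element.upper() == "H":
            hydrogens.append((key, atom.position))

    count = 0
    oc = unit.o
    for key, h_pos in hydrogens:
        d = float(np.linalg.norm(h_pos - oc))
        if d > d_max:
            continue
        ow = o_by_res.get(key)
        if ow is None:
            continue
        v1 = ow - h_pos
        v2 = oc - h_pos
        cosang = float(np.dot(v1, v2) /
                       (np.linalg.norm(v1) * np.linalg.norm(v2)))
        angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        if angle >= angle_min:
            count += 1
    return count


@dataclass
class HBondHistogram:
    """Distribution of solvent-induced frequency shifts grouped by the
    number of hydrogen bonds to solvent (0, 1, 2+)."""

    shifts_by_count: dict[int, list[float]] = field(default_factory=dict)

    @property
    def n_observations(self) -> int:
        return sum(len(v) for v in self.shifts_by_count.values())

    def mean_shift(self, n_bonds: int) -> float:
        vals = self.shifts_by_count.get(n_bonds, [])
        if not vals:
            return float("nan")
        return float(np.mean(vals))


def solvent_shift_histogram(ensemble: SnapshotEnsemble,
                            params: SiteEnergyParams | None = None,
                            charge_table: Mapping[str, float] | None = None,
                            d_max: float = 2.6,
                            angle_min: float = 130.0) -> HBondHistogram:
    """Solvent-only frequency shift vs hydrogen-bond count.

    For every (chromophore, snapshot): evaluate the site frequency with the
    environment restricted to solvent charges, subtract the central
    frequency, and bin the shift by the number of water hydrogen bonds to
    the carbonyl oxygen (counts of 2 or more share a bin).  Proline units
    (fixed frequency, no map evaluation) are excluded.
    """
    params = params or SiteEnergyParams()
    hist = HBondHistogram(shifts_by_count={0: [], 1: [], 2: []})
    any_solvent = False
    for snap in ensemble.snapshots:
        if not np.any(snap.is_solvent):
            continue
        any_solvent = True
        units = identify_peptide_units(snap)
        env = assign_charges(snap, charge_table, units=units)
        solvent_env = filter_environment(env, {"solvent"})
        solvent_atoms = snap.solvent_atoms()
        for u in units:
            if u.is_proline:
                continue
            pots = site_potentials(u, solvent_env, params.potential_unit_scale)
            shift = site_frequency(u, pots, params) - params.omega0
            n_hb = min(count_hbonds(u, solvent_atoms, d_max, angle_min), 2)
            hist.shifts_by_count[n_hb].append(shift)
    if not any_solvent:
        raise StructureError("ensemble contains no solvent")
    return hist


# ---------------------------------------------------------------------------
# Isotope-label selection
# ---------------------------------------------------------------------------

def load_ss_labels(path: str | Path) -> dict[tuple[str, int], str]:
    """Read whitespace-delimited secondary-structure labels:
    ``chain residue_index label`` per line."""
    labels: dict[tuple[str, int], str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"malformed label line: {line!r}")
        labels[(parts[0], int(parts[1]))] = parts[2].upper()
    return labels


def select_labels(units: Sequence[PeptideUnit],
                  ss_labels: Mapping[tuple[str, int], str],
                  target: str = "helix",
                  include_310: bool = True) -> list[PeptideUnit]:
    """Return copies of ``units`` with ``isotope_labeled`` set on those whose
    carbonyl residue carries the targeted secondary-structure label.

    ``helix`` targets H (α-helix) and, by default, G (3₁₀); ``sheet``
    targets E.  The carbonyl (preceding) residue decides, since ¹³C¹⁸O
    substitution sits on that residue's C=O group.
    """
    if target not in {"helix", "sheet"}:
        raise ValueError(f"target must be 'helix' or 'sheet', got {target!r}")
    wanted = ({"H", "G"} if include_310 else {"H"}) if target == "helix" else {"E"}

    bad = set(ss_labels.values()) - SS_LABELS
    if bad:
        raise ValueError(f"unknown secondary-structure labels: {sorted(bad)}")

    out = []
    for u in units:
        key = (u.preceding_residue.chain_id, u.preceding_residue.index)
        if key not in ss_labels:
            raise ValueError(f"no secondary-structure label for residue {key}")
        v = copy.copy(u)
        v.isotope_labeled = ss_labels[key] in wanted
        out.append(v)
    n = sum(u.isotope_labeled for u in out)
    logger.info("isotope labeling target=%s: %d of %d units labeled",
                target, n, len(out))
    return out


# ---------------------------------------------------------------------------
# Per-residue two-quantum transition-dipole strength
# ---------------------------------------------------------------------------

def dipole_strength_per_residue(sticks: Stick2DList,
                                n_residues: int) -> tuple[float, float]:
    """(|μ|⁴ per residue, |μ|² per residue) from the 2D diagonal signal.

    |μ|⁴_total is the sum of the positive diagonal bleach contributions
    before orientational averaging (the isotropic factor divided out):
    the ground-state-bleach sticks with identical pump and probe
    eigenstates, whose dipole magnitude product is |μ_a|⁴.  The per-residue
    |μ|² value is the square root of the per-residue |μ|⁴ value.
    """
    if n_residues <= 0:
        raise ValueError("n_residues must be positive")
    mask = (sticks.pathway == "GB") & (sticks.state_a == sticks.state_b)
    mu4_total = float(sticks.dipole_mag[mask].sum())
    mu4_per_res = mu4_total / n_residues
    return mu4_per_res, float(np.sqrt(mu4_per_res))
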