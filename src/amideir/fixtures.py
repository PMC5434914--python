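"""Synthetic structure fixtures: ideal backbones, solvation shells,
perturbed ensembles and a smooth nearest-neighbor coupling map.

These generators stand in for molecular-dynamics ensembles: they produce
multi-model PDB files with controlled geometry (exact φ/ψ, rigid TIP3P
waters, Gaussian positional disorder) so every downstream stage can be
exercised deterministically from a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structures_io import (
    Snapshot,
    SnapshotEnsemble,
    StructureError,
    identify_peptide_units,
)

logger = logging.getLogger("amideir.fixtures")

__all__ = [
    "FixtureSpec",
    "IDEAL_GEOMETRY",
    "build_ideal_backbone",
    "solvate_shell",
    "perturb_ensemble",
    "synthetic_nnc_map",
    "HELIX_PHI_PSI",
    "SHEET_PHI_PSI",
]

#: Ideal backbone geometry: bond lengths (Å) and angles (degrees).
#: Single source of truth for all fixture construction and geometry tests.
IDEAL_GEOMETRY = {
    "N-CA": 1.458,
    "CA-C": 1.525,
    "C-N": 1.329,
    "C=O": 1.231,
    "N-H": 1.02,
    "N-CA-C": 111.2,
    "CA-C-N": 116.2,
    "C-N-CA": 121.7,
    "CA-C=O": 120.8,
    "C-N-H": 119.0,
    "omega": 180.0,
    # rigid TIP3P water
    "O-Hw": 0.9572,
    "H-O-H": 104.52,
}

HELIX_PHI_PSI = (-57.0, -47.0)
SHEET_PHI_PSI = (-139.0, 135.0)
SHEET_STRAND_SPACING = 4.8  # Å, inter-strand offset for antiparallel sheets


@dataclass
class FixtureSpec:
    """Declarative description of a synthetic structure."""

    kind: str = "helix"  # helix | antiparallel_sheet | dipeptide | solvated
    n_residues: int = 12
    n_strands: int = 2
    phi: float | None = None
    psi: float | None = None
    n_waters: int = 0
    jitter_amplitude: float = 0.0
    n_models: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 2:
            raise StructureError("n_residues must be >= 2")
        if self.jitter_amplitude < 0:
            raise StructureError("jitter_amplitude must be >= 0")


# ---------------------------------------------------------------------------
# Internal-coordinate (NeRF) placement
# ---------------------------------------------------------------------------

def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Position atom d with |cd| = bond, angle(b,c,d) and dihedral(a,b,c,d)."""
    ang = np.radians(angle_deg)
    tor = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([
        -np.cos(ang),
        np.sin(ang) * np.cos(tor),
        -np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_chain(n_residues: int, phi: float, psi: float,
                 chain_id: str, res_offset: int = 1) -> list[dict]:
    """Poly-alanine backbone (N, H, CA, C, O per residue) at exact (φ, ψ)."""
    g = IDEAL_GEOMETRY
    residues: list[dict] = []
    # residue 1 seed frame
    n1 = np.zeros(3)
    ca1 = np.array([g["N-CA"], 0.0, 0.0])
    ang = np.radians(g["N-CA-C"])
    c1 = ca1 + g["CA-C"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    residues.append({"N": n1, "CA": ca1, "C": c1})
    for i in range(1, n_residues):
        prev = residues[-1]
        n_next = _place_atom(prev["N"], prev["CA"], prev["C"],
                             g["C-N"], g["CA-C-N"], psi)
        ca_next = _place_atom(prev["CA"], prev["C"], n_next,
                              g["N-CA"], g["C-N-CA"], g["omega"])
        c_next = _place_atom(prev["C"], n_next, ca_next,
                             g["CA-C"], g["N-CA-C"], phi)
        # carbonyl O of the previous residue: anti to the next N across C
        prev["O"] = _place_atom(prev["N"], prev["CA"], prev["C"],
                                g["C=O"], g["CA-C=O"], psi + 180.0)
        # amide H of the next residue: in the peptide plane, anti to CA(i)
        h_next = _place_atom(prev["CA"], prev["C"], n_next,
                             g["N-H"], g["C-N-H"], g["omega"] + 180.0)
        residues.append({"N": n_next, "H": h_next, "CA": ca_next, "C": c_next})
    # terminal carboxyl oxygen of the last residue
    last = residues[-1]
    last["O"] = _place_atom(last["N"], last["CA"], last["C"],
                            g["C=O"], g["CA-C=O"], psi + 180.0)

    out = []
    for i, res in enumerate(residues):
        out.append({
            "chain": chain_id, "index": res_offset + i, "name": "ALA",
            "atoms": {k: res[k] for k in ("N", "H", "CA", "C", "O") if k in res},
        })
    return out


def _residues_to_snapshot(residue_groups: list[dict]) -> Snapshot:
    names, elements, coords, ridx, rname, chain = [], [], [], [], [], []
    for res in residue_groups:
        for aname, pos in res["atoms"].items():
            names.append(aname)
            elements.append(aname[0])
            coords.append(pos)
            ridx.append(res["index"])
            rname.append(res["name"])
            chain.append(res["chain"])
    n = len(names)
    rname_arr = np.array(rname, dtype="U4")
    from .structures_io import WATER_RESNAMES
    is_solvent = np.isin(np.char.upper(rname_arr), list(WATER_RESNAMES))
    return Snapshot(
        names=np.array(names, "U6"), elements=np.array(elements, "U2"),
        coords=np.array(coords, float), residue_index=np.array(ridx, int),
        residue_name=rname_arr, chain_id=np.array(chain, "U4"),
        is_solvent=is_solvent, is_ion=np.zeros(n, bool),
    )


def build_ideal_backbone(spec: FixtureSpec) -> Snapshot:
    """Construct an ideal poly-alanine backbone snapshot.

    ``helix`` defaults to (φ, ψ) = (-57, -47); ``antiparallel_sheet`` to
    (-139, +135) with ~4.8 Å inter-strand spacing and alternating strand
    direction; ``dipeptide`` is a two-residue chain with a single
    chromophore.
    """
    kind = spec.kind
    if kind not in {"helix", "antiparallel_sheet", "dipeptide"}:
        raise StructureError(f"unknown fixture kind: {kind!r}")
    if kind == "dipeptide" and spec.n_residues != 2:
        spec = FixtureSpec(**{**spec.__dict__, "n_residues": 2})
    default = SHEET_PHI_PSI if kind == "antiparallel_sheet" else HELIX_PHI_PSI
    phi = default[0] if spec.phi is None else spec.phi
    psi = default[1] if spec.psi is None else spec.psi

    if kind != "antiparallel_sheet":
        groups = _build_chain(spec.n_residues, phi, psi, "A")
        return _residues_to_snapshot(groups)

    # Antiparallel sheet: one template strand, alternate strands rotated
    # 180° about an axis perpendicular to the strand direction and offset
    # laterally by the inter-strand spacing.
    template = _build_chain(spec.n_residues, phi, psi, "A")
    ca = np.array([r["atoms"]["CA"] for r in template])
    v = ca[-1] - ca[0]
    v /= np.linalg.norm(v)
    # lateral axis perpendicular to the strand direction
    trial = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(trial, v)) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    e2 = trial - np.dot(trial, v) * v
    e2 /= np.linalg.norm(e2)
    centroid = ca.mean(axis=0)

    groups: list[dict] = []
    chain_labels = "ABCDEFGHIJKLMNOP"
    offset_res = 0
    for s in range(spec.n_strands):
        strand = _build_chain(spec.n_residues, phi, psi,
                              chain_labels[s], res_offset=1 + offset_res)
        for res in strand:
            for aname, pos in res["atoms"].items():
                p = pos - centroid
                if s % 2 == 1:
                    p = 2.0 * np.dot(p, e2) * e2 - p  # 180° about e2
                res["atoms"][aname] = p + centroid + s * SHEET_STRAND_SPACING * e2
        groups.extend(strand)
        offset_res += spec.n_residues
    return _residues_to_snapshot(groups)


# ---------------------------------------------------------------------------
# Solvation and ensemble perturbation
# ---------------------------------------------------------------------------

def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def _tip3p_template() -> np.ndarray:
    g = IDEAL_GEOMETRY
    r = g["O-Hw"]
    half = np.radians(g["H-O-H"] / 2.0)
    return np.array([
        [0.0, 0.0, 0.0],
        [r * np.sin(half), r * np.cos(half), 0.0],
        [-r * np.sin(half), r * np.cos(half), 0.0],
    ])


def _oriented_water(o_pos: np.ndarray, acceptor: np.ndarray | None,
                    rng: np.random.Generator) -> np.ndarray:
    """Rigid TIP3P water at ``o_pos``; if an acceptor is given, one O-H bond
    donates toward it (random azimuth for the second hydrogen), otherwise
    the orientation is uniformly random."""
    g = IDEAL_GEOMETRY
    if acceptor is None:
        return o_pos + (_tip3p_template() @ _random_rotation(rng).T)
    u = acceptor - o_pos
    u /= np.linalg.norm(u)
    e = rng.normal(size=3)
    v = e - np.dot(e, u) * u
    v /= np.linalg.norm(v)
    ang = np.radians(g["H-O-H"])
    d2 = np.cos(ang) * u + np.sin(ang) * v
    return np.stack([o_pos, o_pos + g["O-Hw"] * u, o_pos + g["O-Hw"] * d2])


def solvate_shell(snapshot: Snapshot, n_waters: int, seed: int,
                  shell: tuple[float, float] = (3.0, 6.0),
                  min_dist: float = 2.2, max_tries_per_water: int = 400,
                  hbond_cutoff: float = 5.0) -> Snapshot:
    """Add ``n_waters`` rigid TIP3P waters in a shell around the protein.

    Oxygen positions are rejection-sampled uniformly within ``shell`` Å of a
    randomly chosen protein atom; any water atom closer than ``min_dist`` Å
    to an existing atom rejects the placement.  A water whose oxygen lies
    within ``hbond_cutoff`` Å of a protein oxygen acceptor is oriented to
    donate one O-H toward the nearest such acceptor — the dominant
    orientational motif of first-shell water around carbonyls, and the
    origin of the solvent-induced red shift; waters without a nearby
    acceptor are oriented uniformly at random.  Deterministic under
    ``seed``.
    """
    if n_waters < 0:
        raise StructureError("n_waters must be >= 0")
    if n_waters == 0:
        return snapshot
    rng = np.random.default_rng(seed)
    pmask = snapshot.protein_mask()
    protein_coords = snapshot.coords[pmask]
    elem_up = np.char.upper(snapshot.elements.astype("U2"))
    acceptor_coords = snapshot.coords[pmask & (elem_up == "O")]
    existing = [snapshot.coords]
    placed: list[np.ndarray] = []
    next_res = int(snapshot.residue_index.max()) + 1

    for w in range(n_waters):
        ok = False
        for _ in range(max_tries_per_water):
            anchor = protein_coords[rng.integers(len(protein_coords))]
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            radius = rng.uniform(*shell)
            o_pos = anchor + radius * direction
            acceptor = None
            if len(acceptor_coords):
                d_acc = np.linalg.norm(acceptor_coords - o_pos, axis=1)
                i_acc = int(np.argmin(d_acc))
                if d_acc[i_acc] <= hbond_cutoff:
                    acceptor = acceptor_coords[i_acc]
            water = _oriented_water(o_pos, acceptor, rng)
            all_coords = np.concatenate(existing)
            dmin = np.min(np.linalg.norm(
                all_coords[:, None, :] - water[None, :, :], axis=2))
            if dmin >= min_dist:
                ok = True
                break
        if not ok:
            raise StructureError(
                f"water placement failed after {max_tries_per_water} tries; "
                f"placed {w} of {n_waters}"
            )
        placed.append(water)
        existing.append(water)

    n_new = 3 * n_waters
    names = np.concatenate([snapshot.names,
                            np.tile(np.array(["O", "H1", "H2"], "U6"), n_waters)])
    elements = np.concatenate([snapshot.elements,
                               np.tile(np.array(["O", "H", "H"], "U2"), n_waters)])
    coords = np.concatenate([snapshot.coords, np.concatenate(placed)])
    ridx = np.concatenate([snapshot.residue_index,
                           np.repeat(np.arange(next_res, next_res + n_waters), 3)])
    rname = np.concatenate([snapshot.residue_name,
                            np.full(n_new, "HOH", dtype="U4")])
    chain = np.concatenate([snapshot.chain_id, np.full(n_new, "W", dtype="U4")])
    is_solvent = np.concatenate([snapshot.is_solvent, np.ones(n_new, bool)])
    is_ion = np.concatenate([snapshot.is_ion, np.zeros(n_new, bool)])
    return Snapshot(names=names, elements=elements, coords=coords,
                    residue_index=ridx, residue_name=rname, chain_id=chain,
                    is_solvent=is_solvent, is_ion=is_ion)


def perturb_ensemble(snapshot: Snapshot, amplitude: float,
                     n_models: int, seed: int) -> SnapshotEnsemble:
    """Gaussian positional disorder: ``n_models`` copies with independent
    per-coordinate displacements of standard deviation ``amplitude`` (Å).
    Model 0 is the unperturbed snapshot."""
    if amplitude < 0:
        raise StructureError("amplitude must be >= 0")
    if n_models < 1:
        raise StructureError("n_models must be >= 1")
    rng = np.random.default_rng(seed)
    snaps = [snapshot]
    for _ in range(1, n_models):
        disp = rng.normal(0.0, amplitude, size=snapshot.coords.shape) \
            if amplitude > 0 else 0.0
        snaps.append(snapshot.with_coords(snapshot.coords + disp))
    n_res = len(snapshot.residue_ids())
    return SnapshotEnsemble(snapshots=snaps, n_residues=n_res)


def solvated_ensemble(snapshot: Snapshot, n_waters: int, n_models: int,
                      seed: int,
                      shell: tuple[float, float] = (3.0, 7.0)) -> SnapshotEnsemble:
    """Ensemble whose snapshots share the solute but carry independently
    resampled solvation shells — the dominant snapshot-to-snapshot disorder
    of a solvated simulation, where the water rearranges much faster than
    the backbone."""
    if n_models < 1:
        raise StructureError("n_models must be >= 1")
    snaps = [solvate_shell(snapshot, n_waters, seed=seed + k, shell=shell)
             for k in range(n_models)]
    return SnapshotEnsemble(snapshots=snaps,
                            n_residues=len(snapshot.residue_ids()))


# ---------------------------------------------------------------------------
# Synthetic nearest-neighbor coupling map
# ---------------------------------------------------------------------------

NNC_GRID = np.arange(-180, 181, 30)  # 13 nodes per axis


def synthetic_nnc_map(seed: int, path: str | Path | None = None) -> np.ndarray:
    """Generate a smooth periodic 13×13 (φ, ψ) coupling grid in ±10 cm⁻¹.

    A low-order random Fourier series on the torus guarantees smoothness and
    exactly equal values on the periodic edges (φ or ψ = ±180°).  Returns the
    grid (rows = φ nodes, columns = ψ nodes) and optionally writes the map
    file (``phi psi coupling_cm-1`` rows).
    """
    rng = np.random.default_rng(seed)
    phi = np.radians(NNC_GRID)[:, None]
    psi = np.radians(NNC_GRID)[None, :]
    grid = np.zeros((13, 13))
    for kp in range(3):
        for kq in range(3):
            if kp == 0 and kq == 0:
                continue
            a, b, c, d = rng.normal(size=4) / (1.0 + kp + kq)
            grid += (a * np.cos(kp * phi) * np.cos(kq * psi)
                     + b * np.cos(kp * phi) * np.sin(kq * psi)
                     + c * np.sin(kp * phi) * np.cos(kq * psi)
                     + d * np.sin(kp * phi) * np.sin(kq * psi))
    grid *= 9.0 / np.max(np.abs(grid))
    if path is not None:
        lines = ["phi psi coupling_cm-1"]
        for i, p in enumerate(NNC_GRID):
            for j, q in enumerate(NNC_GRID):
                lines.append(f"{p:d} {q:d} {grid[i, j]:.6f}")
        Path(path).write_text("\n".join(lines) + "\n")
    return grid


# ---------------------------------------------------------------------------
# Convenience: spec -> ensemble
# ---------------------------------------------------------------------------

def build_fixture_ensemble(spec: FixtureSpec) -> SnapshotEnsemble:
    """Full pipeline: ideal backbone -> optional solvation -> perturbation."""
    base_kind = "helix" if spec.kind == "solvated" else spec.kind
    snap = build_ideal_backbone(FixtureSpec(**{**spec.__dict__, "kind": base_kind,
                                               "n_waters": 0, "n_models": 1}))
    if spec.n_waters > 0:
        snap = solvate_shell(snap, spec.n_waters, spec.seed)
    ens = perturb_ensemble(snap, spec.jitter_amplitude, spec.n_models,
                           spec.seed + 1)
    # construction sanity: every model yields the same chromophores
    n_units = len(identify_peptide_units(ens.snapshots[0]))
    logger.info("fixture %s: %d residues, %d units, %d model(s), %d waters",
                spec.kind, spec.n_residues, n_units, spec.n_models, spec.n_waters)
    return ens
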