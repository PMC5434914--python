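"""Structure input/output and chromophore identification.

Reads multi-model PDB ensembles, locates the backbone amide (Amide I)
chromophores, and assembles the atom-centered point-charge environment that
drives the electrostatic frequency map.

Conventions: coordinates in Å, charges in elementary charge units (e),
dihedrals in degrees in (-180, 180], chromophore sites 0-indexed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger("amideir.structures_io")

__all__ = [
    "AtomRecord",
    "PeptideUnit",
    "ChargeEnvironment",
    "Snapshot",
    "SnapshotEnsemble",
    "StructureError",
    "MissingAtomError",
    "ChargeTableError",
    "read_ensemble",
    "write_ensemble",
    "identify_peptide_units",
    "assign_charges",
    "filter_environment",
    "load_charge_table",
    "write_charge_table",
    "DEFAULT_CHARGE_TABLE",
    "dihedral_deg",
]


class StructureError(ValueError):
    """Raised for malformed or inconsistent structural input."""


class MissingAtomError(StructureError):
    """A residue lacks backbone atoms required to define a chromophore."""


class ChargeTableError(StructureError):
    """An atom could not be resolved in the partial-charge table."""


WATER_RESNAMES = frozenset({"HOH", "TIP3", "TIP3P", "WAT", "SPC", "SOL", "H2O"})
ION_RESNAMES = frozenset(
    {"NA", "SOD", "K", "POT", "CL", "CLA", "MG", "ZN", "CAL", "LI", "CS", "BR", "IOD", "F"}
)
ION_ELEMENTS = frozenset({"NA", "K", "CL", "MG", "ZN", "LI", "CS", "BR", "I", "F"})

#: Built-in monovalent/divalent ion charges (e), keyed by residue or element name.
ION_CHARGES = {
    "NA": 1.0, "SOD": 1.0, "K": 1.0, "POT": 1.0, "LI": 1.0, "CS": 1.0,
    "CL": -1.0, "CLA": -1.0, "BR": -1.0, "IOD": -1.0, "I": -1.0, "F": -1.0,
    "MG": 2.0, "ZN": 2.0, "CAL": 2.0,
}

#: TIP3P water partial charges (e); fixed regardless of the user charge table.
TIP3P_CHARGES = {"O": -0.834, "H": 0.417}

#: Default partial-charge table.  Backbone amide atoms carry the CHARMM values
#: used by the frequency map (C +0.51, O -0.51, N -0.47, H +0.31); the Cα entry
#: is an effective united-atom charge (+0.16 e) absorbing Hα and the alanine
#: side chain so that a backbone-only fixture residue is electrically neutral.
DEFAULT_CHARGE_TABLE: dict[str, float] = {
    "C": 0.51,
    "O": -0.51,
    "N": -0.47,
    "H": 0.31,
    "HN": 0.31,
    "CA": 0.16,
}

# Amide geometry sanity windows (Å).
_CO_BOND_RANGE = (1.0, 1.5)
_CN_BOND_RANGE = (1.2, 1.5)
_CHAIN_BREAK_CN = 2.0


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomRecord:
    """A single atom: label, element, position (Å) and residue bookkeeping."""

    name: str
    element: str
    position: np.ndarray
    residue_index: int
    residue_name: str
    chain_id: str
    is_solvent: bool = False
    is_ion: bool = False

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise StructureError(f"atom {self.name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if self.residue_index < 0:
            raise StructureError(f"atom {self.name}: negative residue index")


@dataclass
class Snapshot:
    """One structural model, stored column-wise for vectorised access."""

    names: np.ndarray
    elements: np.ndarray
    coords: np.ndarray
    residue_index: np.ndarray
    residue_name: np.ndarray
    chain_id: np.ndarray
    is_solvent: np.ndarray
    is_ion: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise StructureError("coords must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates in snapshot")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def atom(self, i: int) -> AtomRecord:
        return AtomRecord(
            name=str(self.names[i]),
            element=str(self.elements[i]),
            position=self.coords[i],
            residue_index=int(self.residue_index[i]),
            residue_name=str(self.residue_name[i]),
            chain_id=str(self.chain_id[i]),
            is_solvent=bool(self.is_solvent[i]),
            is_ion=bool(self.is_ion[i]),
        )

    def __iter__(self):
        return (self.atom(i) for i in range(self.n_atoms))

    def protein_mask(self) -> np.ndarray:
        return ~(self.is_solvent | self.is_ion)

    def solvent_atoms(self) -> list[AtomRecord]:
        return [self.atom(i) for i in np.flatnonzero(self.is_solvent)]

    def with_coords(self, coords: np.ndarray) -> "Snapshot":
        return Snapshot(
            names=self.names, elements=self.elements, coords=np.array(coords, float),
            residue_index=self.residue_index, residue_name=self.residue_name,
            chain_id=self.chain_id, is_solvent=self.is_solvent, is_ion=self.is_ion,
        )

    def residue_ids(self, protein_only: bool = True) -> list[tuple[str, int]]:
        """Ordered unique (chain, residue_index), by first appearance."""
        mask = self.protein_mask() if protein_only else np.ones(self.n_atoms, bool)
        seen: dict[tuple[str, int], None] = {}
        for i in np.flatnonzero(mask):
            seen.setdefault((str(self.chain_id[i]), int(self.residue_index[i])))
        return list(seen)


@dataclass(frozen=True)
class ResidueId:
    """Identity of one residue: chain, sequence index and 3-letter name."""

    chain_id: str
    index: int
    name: str


@dataclass
class PeptideUnit:
    """One backbone amide chromophore (the C=O...N-H linkage between two
    sequential residues).

    ``phi`` is the main-chain φ of the following residue (the one donating
    N-H) and ``psi`` the ψ of the preceding residue (the one donating C=O);
    these are the two dihedrals that always exist for an interior linkage.
    The (φ, ψ) pair of the residue *shared* by two sequence-adjacent units —
    the pair entering the nearest-neighbor coupling map — is therefore
    (unit_k.phi, unit_{k+1}.psi).
    """

    site_index: int
    c: np.ndarray
    o: np.ndarray
    n: np.ndarray
    h: np.ndarray | None
    preceding_residue: ResidueId
    following_residue: ResidueId
    phi: float
    psi: float
    is_proline: bool = False
    isotope_labeled: bool = False
    h_constructed: bool = False
    atom_indices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        for attr in ("c", "o", "n"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=float))
        if self.h is not None:
            self.h = np.asarray(self.h, dtype=float)
        d_co = float(np.linalg.norm(self.o - self.c))
        d_cn = float(np.linalg.norm(self.n - self.c))
        if not (_CO_BOND_RANGE[0] <= d_co <= _CO_BOND_RANGE[1]):
            raise StructureError(
                f"unit {self.site_index}: C-O distance {d_co:.3f} Å outside "
                f"{_CO_BOND_RANGE}"
            )
        if not (_CN_BOND_RANGE[0] <= d_cn <= _CN_BOND_RANGE[1]):
            raise StructureError(
                f"unit {self.site_index}: C-N distance {d_cn:.3f} Å outside "
                f"{_CN_BOND_RANGE}"
            )
        for ang in (self.phi, self.psi):
            if not (-180.0 < ang <= 180.0):
                raise StructureError(
                    f"unit {self.site_index}: dihedral {ang} outside (-180, 180]"
                )

    @property
    def evaluation_positions(self) -> dict[str, np.ndarray | None]:
        return {"C": self.c, "O": self.o, "N": self.n, "H": self.h}


CATEGORIES = ("backbone", "sidechain", "solvent", "ion")


@dataclass
class ChargeEnvironment:
    """Point charges defining the electrostatic surroundings.

    ``owner_site`` is the chromophore index owning a backbone amide charge,
    or -1; charges owned by a unit are excluded when evaluating the
    potential at that unit's own atoms.
    """

    positions: np.ndarray
    charges: np.ndarray
    owner_site: np.ndarray
    category: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float).reshape(-1, 3)
        self.charges = np.asarray(self.charges, float).reshape(-1)
        self.owner_site = np.asarray(self.owner_site, int).reshape(-1)
        self.category = np.asarray(self.category, dtype="U9").reshape(-1)
        n = len(self.charges)
        if not (len(self.positions) == len(self.owner_site) == len(self.category) == n):
            raise StructureError("charge environment arrays have mismatched lengths")
        bad = set(np.unique(self.category)) - set(CATEGORIES) if n else set()
        if bad:
            raise StructureError(f"unknown charge categories: {sorted(bad)}")
        if np.any((self.category == "backbone") & (self.owner_site < 0)):
            raise StructureError("backbone charge without an owner site")

    @property
    def n_charges(self) -> int:
        return len(self.charges)

    def total_charge(self, categories: Iterable[str] | None = None) -> float:
        if categories is None:
            return float(self.charges.sum())
        mask = np.isin(self.category, list(categories))
        return float(self.charges[mask].sum())

    def subset(self, mask: np.ndarray) -> "ChargeEnvironment":
        return ChargeEnvironment(
            self.positions[mask], self.charges[mask],
            self.owner_site[mask], self.category[mask],
        )


@dataclass
class SnapshotEnsemble:
    """An ordered set of structural snapshots of the same system."""

    snapshots: list[Snapshot]
    n_residues: int

    @property
    def n_snapshots(self) -> int:
        return len(self.snapshots)

    def validate(self) -> None:
        if not self.snapshots:
            raise StructureError("empty ensemble")
        n0 = self.snapshots[0].n_atoms
        units0 = [u.site_index for u in identify_peptide_units(self.snapshots[0])]
        for k, snap in enumerate(self.snapshots[1:], start=1):
            if snap.n_atoms != n0:
                raise StructureError(f"snapshot {k}: atom count differs from model 0")
            units = [u.site_index for u in identify_peptide_units(snap)]
            if units != units0:
                raise StructureError(f"snapshot {k}: unit ordering differs from model 0")


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def dihedral_deg(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral p0-p1-p2-p3 in degrees, mapped into (-180, 180]."""
    b0 = np.asarray(p1, float) - np.asarray(p0, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def _construct_amide_h(n_pos: np.ndarray, c_pos: np.ndarray, o_pos: np.ndarray) -> np.ndarray:
    # N-H antiparallel to C=O, length 1.02 Å: lies exactly in the O=C-N plane.
    u = o_pos - c_pos
    u = u / np.linalg.norm(u)
    return n_pos - 1.02 * u


# ---------------------------------------------------------------------------
# Reading / writing ensembles
# ---------------------------------------------------------------------------

def _classify(res_name: np.ndarray, element: np.ndarray,
              chain_id: np.ndarray, res_index: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    res_up = np.char.upper(res_name.astype("U4"))
    is_solvent = np.isin(res_up, list(WATER_RESNAMES))
    # Ions: named ion residues, or single-atom residues of an ionic element.
    counts: dict[tuple[str, int], int] = {}
    for c, r in zip(chain_id, res_index):
        counts[(str(c), int(r))] = counts.get((str(c), int(r)), 0) + 1
    single = np.array(
        [counts[(str(c), int(r))] == 1 for c, r in zip(chain_id, res_index)], bool
    )
    elem_up = np.char.upper(element.astype("U2"))
    is_ion = (~is_solvent) & (
        np.isin(res_up, list(ION_RESNAMES)) & single
        | (single & np.isin(elem_up, list(ION_ELEMENTS)))
    )
    return is_solvent, is_ion


def _snapshot_from_atom_array(arr) -> Snapshot:
    names = arr.atom_name.astype("U6")
    elements = arr.element.astype("U2")
    res_index = arr.res_id.astype(int)
    res_name = arr.res_name.astype("U4")
    chain = arr.chain_id.astype("U4")
    is_solvent, is_ion = _classify(res_name, elements, chain, res_index)
    return Snapshot(
        names=names, elements=elements, coords=np.array(arr.coord, float),
        residue_index=res_index, residue_name=res_name, chain_id=chain,
        is_solvent=is_solvent, is_ion=is_ion,
    )


def _validate_backbone_complete(snapshot: Snapshot) -> None:
    mask = snapshot.protein_mask()
    per_res: dict[tuple[str, int], set[str]] = {}
    for i in np.flatnonzero(mask):
        key = (str(snapshot.chain_id[i]), int(snapshot.residue_index[i]))
        per_res.setdefault(key, set()).add(str(snapshot.names[i]))
    for (chain, idx), names in per_res.items():
        missing = {"N", "CA", "C", "O"} - names
        if missing:
            raise MissingAtomError(
                f"residue {chain}:{idx} is missing backbone atoms {sorted(missing)}"
            )


def read_ensemble(path: str | Path, format: str = "pdb") -> SnapshotEnsemble:
    """Read a (multi-model) PDB file into a :class:`SnapshotEnsemble`.

    One snapshot per MODEL record; a single-structure file yields one
    snapshot.  Water (HOH/TIP3/WAT/SPC...) and monoatomic ions are flagged.
    Alternate locations resolve to the first altloc; discarded records are
    logged.
    """
    if format.lower() != "pdb":
        raise StructureError(f"unsupported format: {format!r}")
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    try:
        stack = pdb.get_structure(model=None, altloc="first")
    except Exception as exc:  # biotite raises on inconsistent models
        raise StructureError(f"{path}: inconsistent or unparsable models: {exc}") from exc
    if stack.stack_depth() == 0:
        raise StructureError(f"{path}: no models found")

    snapshots = []
    for m in range(stack.stack_depth()):
        snap = _snapshot_from_atom_array(stack[m])
        _validate_backbone_complete(snap)
        snapshots.append(snap)
    n_atoms = {s.n_atoms for s in snapshots}
    if len(n_atoms) != 1:
        raise StructureError(f"{path}: inconsistent atom counts across models: {n_atoms}")
    n_res = len(snapshots[0].residue_ids())
    ens = SnapshotEnsemble(snapshots=snapshots, n_residues=n_res)
    logger.info("read %d model(s), %d atoms, %d protein residues from %s",
                ens.n_snapshots, snapshots[0].n_atoms, n_res, path)
    return ens


def write_ensemble(ensemble: SnapshotEnsemble | Sequence[Snapshot],
                   path: str | Path) -> None:
    """Write snapshots as a multi-model PDB (MODEL/ENDMDL records)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    snaps = ensemble.snapshots if isinstance(ensemble, SnapshotEnsemble) else list(ensemble)
    if not snaps:
        raise StructureError("nothing to write")
    ref = snaps[0]
    arr = struc.AtomArray(ref.n_atoms)
    arr.atom_name = ref.names.astype("U6")
    arr.element = ref.elements.astype("U2")
    arr.res_id = ref.residue_index.astype(int)
    arr.res_name = ref.residue_name.astype("U5")
    arr.chain_id = ref.chain_id.astype("U4")
    arr.hetero = ref.is_solvent | ref.is_ion
    coords = np.stack([s.coords for s in snaps]).astype(np.float32)
    stack = struc.from_template(arr, coords)
    out = PDBFile()
    out.set_structure(stack)
    out.write(str(Path(path)))


# ---------------------------------------------------------------------------
# Chromophore identification
# ---------------------------------------------------------------------------

_AMIDE_H_NAMES = ("H", "HN")


def identify_peptide_units(snapshot: Snapshot) -> list[PeptideUnit]:
    """Locate one chromophore per backbone amide linkage.

    Terminal ammonium/carboxylate groups and Gln/Asn side-chain amides are
    not chromophores.  Units whose nitrogen belongs to proline are flagged
    ``is_proline`` and carry no amide hydrogen.  A C(i)-N(i+1) separation
    above 2.0 Å is treated as a chain break (no unit, warning logged).
    """
    mask = snapshot.protein_mask()
    atoms_by_res: dict[tuple[str, int], dict[str, int]] = {}
    order: list[tuple[str, int]] = []
    for i in np.flatnonzero(mask):
        key = (str(snapshot.chain_id[i]), int(snapshot.residue_index[i]))
        if key not in atoms_by_res:
            atoms_by_res[key] = {}
            order.append(key)
        atoms_by_res[key].setdefault(str(snapshot.names[i]), int(i))

    units: list[PeptideUnit] = []
    site = 0
    for k in range(len(order) - 1):
        (chain_a, idx_a), (chain_b, idx_b) = order[k], order[k + 1]
        if chain_a != chain_b:
            continue
        res_a, res_b = atoms_by_res[order[k]], atoms_by_res[order[k + 1]]
        required_a, required_b = {"N", "CA", "C", "O"}, {"N", "CA", "C"}
        if not required_a <= res_a.keys():
            raise MissingAtomError(
                f"residue {chain_a}:{idx_a} missing "
                f"{sorted(required_a - res_a.keys())}"
            )
        if not required_b <= res_b.keys():
            raise MissingAtomError(
                f"residue {chain_b}:{idx_b} missing "
                f"{sorted(required_b - res_b.keys())}"
            )
        c_i, o_i, n_j = res_a["C"], res_a["O"], res_b["N"]
        c_pos, o_pos, n_pos = (snapshot.coords[i] for i in (c_i, o_i, n_j))
        if np.linalg.norm(n_pos - c_pos) > _CHAIN_BREAK_CN:
            logger.warning("chain break between %s:%d and %s:%d (C-N > %.1f Å)",
                           chain_a, idx_a, chain_b, idx_b, _CHAIN_BREAK_CN)
            continue

        name_b = str(snapshot.residue_name[res_b["N"]])
        is_pro = name_b.upper() == "PRO"
        h_pos = None
        h_idx = None
        constructed = False
        if not is_pro:
            for hname in _AMIDE_H_NAMES:
                if hname in res_b:
                    h_idx = res_b[hname]
                    h_pos = snapshot.coords[h_idx]
                    break
            if h_pos is None:
                h_pos = _construct_amide_h(n_pos, c_pos, o_pos)
                constructed = True
                logger.info("constructed amide H for residue %s:%d", chain_b, idx_b)

        phi = dihedral_deg(c_pos, n_pos, snapshot.coords[res_b["CA"]],
                           snapshot.coords[res_b["C"]])
        psi = dihedral_deg(snapshot.coords[res_a["N"]], snapshot.coords[res_a["CA"]],
                           c_pos, n_pos)
        indices = (c_i, o_i, n_j) + ((h_idx,) if h_idx is not None else ())
        units.append(PeptideUnit(
            site_index=site, c=c_pos, o=o_pos, n=n_pos, h=h_pos,
            preceding_residue=ResidueId(chain_a, idx_a, str(snapshot.residue_name[c_i])),
            following_residue=ResidueId(chain_b, idx_b, name_b),
            phi=phi, psi=psi, is_proline=is_pro,
            h_constructed=constructed, atom_indices=indices,
        ))
        site += 1
    return units


# ---------------------------------------------------------------------------
# Charge assignment
# ---------------------------------------------------------------------------

def load_charge_table(path: str | Path) -> dict[str, float]:
    """Read a two-column charge table: ``key  charge_e`` per line.

    Keys are atom names (``CA``) or residue-qualified names (``GLY:CA``,
    which take precedence).  Lines starting with ``#`` are ignored.
    """
    table: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ChargeTableError(f"malformed charge-table line: {line!r}")
        table[parts[0].upper()] = float(parts[1])
    if not table:
        raise ChargeTableError(f"empty charge table: {path}")
    return table


def write_charge_table(table: Mapping[str, float], path: str | Path) -> None:
    lines = ["# atom_key  charge_e"]
    lines += [f"{k}  {v:+.4f}" for k, v in table.items()]
    Path(path).write_text("\n".join(lines) + "\n")


_WARNED_NET_CHARGES: set[tuple[float, float]] = set()


def assign_charges(snapshot: Snapshot,
                   charge_table: Mapping[str, float] | None = None,
                   units: Sequence[PeptideUnit] | None = None,
                   formal_charge: float = 0.0) -> ChargeEnvironment:
    """Assign a partial charge to every atom and categorise it.

    Backbone amide atoms (C, O, N, H of a chromophore) are category
    ``backbone`` with ``owner_site`` set; every other protein atom is
    ``sidechain``; waters carry fixed TIP3P charges; monoatomic ions carry
    their formal charge.
    """
    table = {k.upper(): v for k, v in (charge_table or DEFAULT_CHARGE_TABLE).items()}
    if units is None:
        units = identify_peptide_units(snapshot)

    owner = np.full(snapshot.n_atoms, -1, dtype=int)
    for u in units:
        for i in u.atom_indices:
            owner[i] = u.site_index

    charges = np.zeros(snapshot.n_atoms)
    category = np.empty(snapshot.n_atoms, dtype="U9")
    unknown: list[str] = []
    for i in range(snapshot.n_atoms):
        name = str(snapshot.names[i]).upper()
        res = str(snapshot.residue_name[i]).upper()
        elem = str(snapshot.elements[i]).upper()
        if snapshot.is_solvent[i]:
            category[i] = "solvent"
            if elem not in TIP3P_CHARGES:
                unknown.append(f"{res}:{name}")
            else:
                charges[i] = TIP3P_CHARGES[elem]
        elif snapshot.is_ion[i]:
            category[i] = "ion"
            q = ION_CHARGES.get(res, ION_CHARGES.get(elem, table.get(name)))
            if q is None:
                unknown.append(f"{res}:{name}")
            else:
                charges[i] = q
        else:
            category[i] = "backbone" if owner[i] >= 0 else "sidechain"
            key_full = f"{res}:{name}"
            if key_full in table:
                charges[i] = table[key_full]
            elif name in table:
                charges[i] = table[name]
            else:
                unknown.append(key_full)
    if unknown:
        raise ChargeTableError(
            "atoms not resolvable in the charge table: " + ", ".join(sorted(set(unknown)))
        )

    env = ChargeEnvironment(
        positions=snapshot.coords.copy(), charges=charges,
        owner_site=owner, category=category,
    )
    net = env.total_charge(["backbone", "sidechain", "ion"])
    if abs(net - formal_charge) > 1e-6:
        key = (round(net, 4), round(formal_charge, 4))
        if key not in _WARNED_NET_CHARGES:  # warn once per distinct mismatch
            _WARNED_NET_CHARGES.add(key)
            logger.warning("net protein+ion charge %.4f e differs from declared "
                           "formal charge %.4f e", net, formal_charge)
    return env


def filter_environment(env: ChargeEnvironment,
                       include: Iterable[str]) -> ChargeEnvironment:
    """Restrict the environment to the requested charge categories."""
    include = set(include)
    if not include:
        raise StructureError("empty category set")
    bad = include - set(CATEGORIES)
    if bad:
        raise StructureError(f"unknown categories: {sorted(bad)}")
    return env.subset(np.isin(env.category, list(include)))
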