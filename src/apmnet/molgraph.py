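"""Molecular graphs for protein-pocket / ligand affinity scoring.

Molecules are abstracted to ordered atom records and undirected bond
records, then featurized: each atom becomes a 75-dimensional vector
(element one-hot over 43 named elements plus "unknown", degree,
explicit valence, raw formal charge, raw radical-electron count,
hybridization, aromaticity flag, total hydrogen count) and each bond a
6-dimensional indicator vector (single / double / triple / aromatic /
conjugated / in-ring). A protein-ligand complex is the disjoint union
of the pocket graph and the ligand graph — no cross edges; the model
never sees the non-covalent interface, only the two covalent topologies.
"""

from __future__ import annotations

import logging
import math
import os
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

# Element vocabulary, fixed order; index 43 is the "unknown" catch-all.
ELEMENTS = (
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca", "Fe",
    "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag", "Pd", "Co",
    "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn",
    "Zr", "Cr", "Pt", "Hg", "Pb",
)
_ELEMENT_INDEX = {e: i for i, e in enumerate(ELEMENTS)}

HYBRIDIZATIONS = ("SP", "SP2", "SP3", "SP3D", "SP3D2")

N_ATOM_FEATURES = 75       # 44 + 11 + 7 + 1 + 1 + 5 + 1 + 5
N_BOND_FEATURES = 6

_DEGREE_BINS = 11          # 0..10
_VALENCE_BINS = 7          # 0..6
_HYDROGEN_BINS = 5         # 0..4

BOND_ORDERS = ("single", "double", "triple", "aromatic")

# Unit factors to molar for affinity labels.
_UNIT_TO_MOLAR = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9, "pM": 1e-12}


class StructureParseError(ValueError):
    """Raised when a structure file cannot be turned into a Molecule.

    Carries the complex/molecule id so dataset assembly can discard the
    offending entry (e.g. unreasonable explicit valences) and keep going.
    """

    def __init__(self, message: str, mol_id: str = ""):
        super().__init__(message)
        self.mol_id = mol_id


@dataclass
class AtomRecord:
    element: str
    degree: int
    explicit_valence: int
    formal_charge: int = 0
    num_radical_electrons: int = 0
    hybridization: str = "SP3"
    is_aromatic: bool = False
    total_hydrogens: int = 0

    def __post_init__(self):
        if not self.element:
            raise ValueError("element symbol must be non-empty")
        if self.degree < 0 or self.total_hydrogens < 0:
            raise ValueError("degree and hydrogen count must be >= 0")


@dataclass
class BondRecord:
    i: int
    j: int
    order: str = "single"
    is_conjugated: bool = False
    is_in_ring: bool = False

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError("self-bonds are not allowed")
        if self.order not in BOND_ORDERS:
            raise ValueError(f"unknown bond order {self.order!r}")


@dataclass
class Molecule:
    atoms: list[AtomRecord]
    bonds: list[BondRecord]
    id: str = ""

    def __post_init__(self):
        n = len(self.atoms)
        seen = set()
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ValueError(f"bond ({b.i},{b.j}) out of range for {n} atoms")
            key = (min(b.i, b.j), max(b.i, b.j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


@dataclass
class MolGraph:
    """Featurized molecule: node matrix X (n x 75), directed edge list
    (2, 2*#bonds) and edge feature matrix E (2*#bonds x 6)."""

    X: np.ndarray
    edge_index: np.ndarray
    E: np.ndarray

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_index.shape[1]


@dataclass
class ComplexGraph:
    """Pocket and ligand graphs concatenated; pocket nodes come first."""

    graph: MolGraph
    n_pocket: int
    n_ligand: int
    label: Optional[float] = None
    id: str = ""


def _one_hot(index: int, size: int) -> np.ndarray:
    v = np.zeros(size)
    v[index] = 1.0
    return v


def _clamped(value: int, n_bins: int, what: str) -> int:
    if value >= n_bins:
        logger.warning("%s=%d exceeds top bin %d; clamping", what, value,
                       n_bins - 1)
        return n_bins - 1
    return value


def featurize_atom(atom: AtomRecord) -> np.ndarray:
    """75-dim atom feature vector in fixed group order.

    Layout: element one-hot (44, unknown last), degree one-hot (11),
    explicit-valence one-hot (7), formal charge raw (1), radical
    electrons raw (1), hybridization one-hot (5), aromatic flag (1),
    total-H one-hot (5). Out-of-range counts clamp to the top bin with a
    warning; unlisted elements map to "unknown"; unlisted hybridizations
    clamp to SP3.
    """
    elem_idx = _ELEMENT_INDEX.get(atom.element, len(ELEMENTS))
    hyb = atom.hybridization if atom.hybridization in HYBRIDIZATIONS else None
    if hyb is None:
        logger.warning("hybridization %r not in %s; clamping to SP3",
                       atom.hybridization, HYBRIDIZATIONS)
        hyb = "SP3"
    parts = [
        _one_hot(elem_idx, len(ELEMENTS) + 1),
        _one_hot(_clamped(atom.degree, _DEGREE_BINS, "degree"), _DEGREE_BINS),
        _one_hot(_clamped(atom.explicit_valence, _VALENCE_BINS, "valence"),
                 _VALENCE_BINS),
        np.array([float(atom.formal_charge)]),
        np.array([float(atom.num_radical_electrons)]),
        _one_hot(HYBRIDIZATIONS.index(hyb), len(HYBRIDIZATIONS)),
        np.array([1.0 if atom.is_aromatic else 0.0]),
        _one_hot(_clamped(atom.total_hydrogens, _HYDROGEN_BINS, "hydrogens"),
                 _HYDROGEN_BINS),
    ]
    return np.concatenate(parts)


def featurize_bond(bond: BondRecord) -> np.ndarray:
    """6-dim bond indicator: [single, double, triple, aromatic,
    conjugated, in-ring]. The four order flags are mutually exclusive."""
    v = np.zeros(N_BOND_FEATURES)
    v[BOND_ORDERS.index(bond.order)] = 1.0
    if bond.is_conjugated:
        v[4] = 1.0
    if bond.is_in_ring:
        v[5] = 1.0
    return v


def mol_to_graph(mol: Molecule) -> MolGraph:
    """Featurize a molecule. Each undirected bond becomes two directed
    edges carrying the same feature row, so neighbor aggregation is a
    single pass over incoming edges."""
    if mol.n_atoms == 0:
        raise StructureParseError("molecule has no atoms", mol.id)
    X = np.stack([featurize_atom(a) for a in mol.atoms])
    src, dst, rows = [], [], []
    for b in mol.bonds:
        f = featurize_bond(b)
        src += [b.i, b.j]
        dst += [b.j, b.i]
        rows += [f, f]
    edge_index = (np.array([src, dst], dtype=np.int64)
                  if src else np.zeros((2, 0), dtype=np.int64))
    E = np.stack(rows) if rows else np.zeros((0, N_BOND_FEATURES))
    return MolGraph(X=X, edge_index=edge_index, E=E)


def build_complex(pocket: MolGraph, ligand: MolGraph,
                  label: Optional[float] = None,
                  complex_id: str = "") -> ComplexGraph:
    """Disjoint union of pocket and ligand graphs; ligand node indices
    are offset by the pocket size and no cross edges are introduced."""
    if pocket.n == 0 or ligand.n == 0:
        raise ValueError("pocket and ligand must be non-empty")
    X = np.vstack([pocket.X, ligand.X])
    edge_index = np.hstack([pocket.edge_index, ligand.edge_index + pocket.n])
    E = np.vstack([pocket.E, ligand.E])
    return ComplexGraph(graph=MolGraph(X=X, edge_index=edge_index, E=E),
                        n_pocket=pocket.n, n_ligand=ligand.n,
                        label=label, id=complex_id)


def affinity_to_pka(value: float, unit: str = "M") -> float:
    """pKa = -log10 of a dissociation/inhibition constant in molar."""
    if unit not in _UNIT_TO_MOLAR:
        raise ValueError(f"unknown unit {unit!r}; expected one of "
                         f"{sorted(_UNIT_TO_MOLAR)}")
    if not value > 0:
        raise ValueError("affinity must be positive")
    return -math.log10(value * _UNIT_TO_MOLAR[unit])


# ---------------------------------------------------------------------------
# Structure file reading (rdkit; openbabel CLI for mol2 -> pdb conversion)
# ---------------------------------------------------------------------------

def _from_rdkit(rdmol, mol_id: str) -> Molecule:
    from rdkit import Chem

    hyb_map = {
        Chem.HybridizationType.SP: "SP",
        Chem.HybridizationType.SP2: "SP2",
        Chem.HybridizationType.SP3: "SP3",
        Chem.HybridizationType.SP3D: "SP3D",
        Chem.HybridizationType.SP3D2: "SP3D2",
    }
    order_map = {
        Chem.BondType.SINGLE: "single",
        Chem.BondType.DOUBLE: "double",
        Chem.BondType.TRIPLE: "triple",
        Chem.BondType.AROMATIC: "aromatic",
    }
    atoms = []
    for a in rdmol.GetAtoms():
        atoms.append(AtomRecord(
            element=a.GetSymbol(),
            degree=a.GetDegree(),
            explicit_valence=a.GetExplicitValence(),
            formal_charge=a.GetFormalCharge(),
            num_radical_electrons=a.GetNumRadicalElectrons(),
            hybridization=hyb_map.get(a.GetHybridization(), "other"),
            is_aromatic=a.GetIsAromatic(),
            total_hydrogens=a.GetTotalNumHs(),
        ))
    bonds = []
    for b in rdmol.GetBonds():
        order = order_map.get(b.GetBondType())
        if order is None:
            raise StructureParseError(
                f"unsupported bond type {b.GetBondType()}", mol_id)
        bonds.append(BondRecord(
            i=b.GetBeginAtomIdx(), j=b.GetEndAtomIdx(), order=order,
            is_conjugated=b.GetIsConjugated(), is_in_ring=b.IsInRing()))
    return Molecule(atoms=atoms, bonds=bonds, id=mol_id)


def _mol2_to_pdb(path: str) -> str:
    """Convert a mol2 file to a temporary PDB file via the openbabel CLI."""
    if shutil.which("obabel") is None:
        return ""
    fd, out = tempfile.mkstemp(suffix=".pdb")
    os.close(fd)
    proc = subprocess.run(["obabel", path, "-O", out],
                          capture_output=True, text=True)
    if proc.returncode != 0 or not os.path.getsize(out):
        os.unlink(out)
        return ""
    return out


def read_structure(path: str, fmt: Optional[str] = None,
                   mol_id: str = "") -> Molecule:
    """Read a PDB / mol2 / SDF structure file into a Molecule.

    Hydrogens stay as present in the file; no protonation editing.
    mol2 input is first converted to PDB with openbabel and then parsed
    with rdkit (falling back to rdkit's native mol2 reader when the
    obabel executable is unavailable). Unparseable structures raise
    :class:`StructureParseError` carrying ``mol_id`` so callers can
    discard the complex.
    """
    from rdkit import Chem

    if not os.path.exists(path):
        raise StructureParseError(f"file not found: {path}", mol_id)
    if fmt is None:
        fmt = os.path.splitext(path)[1].lstrip(".").lower()
    mol_id = mol_id or os.path.splitext(os.path.basename(path))[0]

    rdmol = None
    try:
        if fmt == "pdb":
            rdmol = Chem.MolFromPDBFile(path, removeHs=False,
                                        proximityBonding=False)
        elif fmt == "sdf":
            supplier = Chem.SDMolSupplier(path, removeHs=False)
            rdmol = next(iter(supplier), None)
        elif fmt == "mol2":
            pdb_path = _mol2_to_pdb(path)
            if pdb_path:
                try:
                    rdmol = Chem.MolFromPDBFile(pdb_path, removeHs=False,
                                                proximityBonding=False)
                finally:
                    os.unlink(pdb_path)
            if rdmol is None:
                rdmol = Chem.MolFromMol2File(path, removeHs=False)
        else:
            raise StructureParseError(f"unsupported format {fmt!r}", mol_id)
    except StructureParseError:
        raise
    except Exception as exc:  # rdkit sanitization errors etc.
        raise StructureParseError(f"cannot parse {path}: {exc}", mol_id)
    if rdmol is None or rdmol.GetNumAtoms() == 0:
        raise StructureParseError(f"cannot parse {path}", mol_id)
    return _from_rdkit(rdmol, mol_id)


# ---------------------------------------------------------------------------
# PDBbind-style index file and graph caching
# ---------------------------------------------------------------------------

def parse_affinity_string(s: str) -> float:
    """Parse an index affinity string like ``Kd=50uM`` into a pKa."""
    for sep in ("=", "~", "<", ">"):
        if sep in s:
            _, rhs = s.split(sep, 1)
            break
    else:
        raise ValueError(f"cannot parse affinity string {s!r}")
    rhs = rhs.strip()
    for unit in ("mM", "uM", "nM", "pM", "fM", "M"):
        if rhs.endswith(unit):
            number = float(rhs[: -len(unit)])
            if unit == "fM":
                return affinity_to_pka(number * 1e-3, "pM")
            return affinity_to_pka(number, unit)
    raise ValueError(f"no recognised unit in affinity string {s!r}")


def read_index(path: str) -> dict[str, float]:
    """Read a PDBbind-style index file into {complex id: pKa}.

    Lines are whitespace-delimited: pdb_id, resolution, year,
    -logKd/Ki, affinity string, ... ; ``#`` lines are comments. The
    printed -logKd/Ki column is used as the label; the affinity string
    is parsed as a cross-check fallback when that column is missing.
    """
    labels: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 4:
                continue
            pdb_id = parts[0]
            try:
                labels[pdb_id] = float(parts[3])
            except ValueError:
                labels[pdb_id] = parse_affinity_string(parts[4])
    return labels


def save_complex(cg: ComplexGraph, path: str) -> None:
    """Cache a ComplexGraph as a compressed npz container."""
    np.savez_compressed(
        path, X=cg.graph.X, edge_index=cg.graph.edge_index, E=cg.graph.E,
        n_pocket=cg.n_pocket, n_ligand=cg.n_ligand,
        label=np.nan if cg.label is None else cg.label,
        id=np.array(cg.id))


def load_complex(path: str) -> ComplexGraph:
    with np.load(path) as z:
        label = float(z["label"])
        return ComplexGraph(
            graph=MolGraph(X=z["X"], edge_index=z["edge_index"], E=z["E"]),
            n_pocket=int(z["n_pocket"]), n_ligand=int(z["n_ligand"]),
            label=None if math.isnan(label) else label,
            id=str(z["id"]))
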