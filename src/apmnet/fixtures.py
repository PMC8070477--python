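"""Synthetic molecules, pocket-ligand complexes and a miniature
PDBbind-layout directory.

The generator builds connected random molecules (random spanning tree
plus a few ring-closing edges, degree-capped by element valence) whose
attributes are chemically self-consistent: hydrogen counts fill the
default valence, hybridization follows bond orders, and all values fall
inside the featurization bins so no clamping ever fires.

Each complex carries a planted affinity label that is linear in the
element composition of pocket plus ligand (optionally plus a ring-count
term that only the topology-aware stages can exploit), with fixed
published-in-code weights. A correctly wired network can learn this
function from the pooled graph representation, which makes end-to-end
learnability a test of plumbing rather than of model power. Labels are
clipped to the physically sensible pKa range [0, 14].
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .molgraph import (AtomRecord, BondRecord, ComplexGraph, Molecule,
                       build_complex, mol_to_graph)

# Default valences used both for hydrogen filling and as degree caps.
VALENCE_CAP = {"C": 4, "N": 3, "O": 2, "S": 2, "P": 3}

# Planted affinity: pKa = BIAS + sum_e W[e] * count(e) (+ ring term).
PLANTED_WEIGHTS = {"C": 0.12, "N": 0.25, "O": 0.20, "S": 0.35, "P": 0.30}
PLANTED_BIAS = 1.0
PLANTED_RING_WEIGHT = 0.40


@dataclass
class SyntheticSpec:
    n_complexes: int = 250
    pocket_size_range: tuple[int, int] = (16, 32)
    ligand_size_range: tuple[int, int] = (6, 16)
    element_alphabet: tuple[str, ...] = ("C", "N", "O", "S")
    noise_sd: float = 0.1
    seed: int = 0
    topology_term: bool = False

    def __post_init__(self):
        if min(self.pocket_size_range) < 2 or min(self.ligand_size_range) < 2:
            raise ValueError("molecule sizes must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        unknown = set(self.element_alphabet) - set(VALENCE_CAP)
        if unknown:
            raise ValueError(f"unsupported elements {sorted(unknown)}")


def make_random_molecule(n_atoms: int, alphabet: Sequence[str] = ("C", "N", "O"),
                         seed=0, allow_double: bool = True,
                         extra_edge_prob: float = 0.25,
                         mol_id: str = "") -> Molecule:
    """Connected random molecule with degree-consistent attributes.

    A random spanning tree guarantees connectivity; extra edges close
    rings where both endpoints still have spare valence (simple degree
    capped at 4). Some eligible bonds become double bonds when
    ``allow_double``. ``seed`` may be an int or a numpy Generator.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    elements = [str(rng.choice(list(alphabet))) for _ in range(n_atoms)]
    caps = [VALENCE_CAP[e] for e in elements]
    used = [0] * n_atoms          # valence consumed (sum of bond orders)
    neighbors: list[set[int]] = [set() for _ in range(n_atoms)]
    bonds: list[list] = []        # [i, j, order]

    def open_nodes(upto: int) -> list[int]:
        return [i for i in range(upto)
                if used[i] < caps[i] and len(neighbors[i]) < 4]

    for i in range(1, n_atoms):
        parent = int(rng.choice(open_nodes(i)))
        bonds.append([parent, i, 1])
        used[parent] += 1
        used[i] += 1
        neighbors[parent].add(i)
        neighbors[i].add(parent)

    # ring-closing extra edges
    n_extra = rng.binomial(max(n_atoms - 2, 0), extra_edge_prob)
    for _ in range(n_extra):
        candidates = open_nodes(n_atoms)
        pairs = [(i, j) for ai, i in enumerate(candidates)
                 for j in candidates[ai + 1:] if j not in neighbors[i]]
        if not pairs:
            break
        i, j = pairs[int(rng.integers(len(pairs)))]
        bonds.append([i, j, 1])
        used[i] += 1
        used[j] += 1
        neighbors[i].add(j)
        neighbors[j].add(i)

    if allow_double:
        for b in bonds:
            i, j, _ = b
            if used[i] < caps[i] and used[j] < caps[j] and rng.random() < 0.25:
                b[2] = 2
                used[i] += 1
                used[j] += 1

    ring_flags = _ring_bonds(n_atoms, bonds)
    double_atoms = {a for b in bonds if b[2] == 2 for a in b[:2]}
    atoms = [AtomRecord(
        element=elements[i],
        degree=len(neighbors[i]),
        explicit_valence=used[i],
        formal_charge=0,
        num_radical_electrons=0,
        hybridization="SP2" if i in double_atoms else "SP3",
        is_aromatic=False,
        total_hydrogens=caps[i] - used[i],
    ) for i in range(n_atoms)]
    bond_records = [BondRecord(i=i, j=j,
                               order="double" if o == 2 else "single",
                               is_conjugated=False, is_in_ring=ring)
                    for (i, j, o), ring in zip(bonds, ring_flags)]
    return Molecule(atoms=atoms, bonds=bond_records, id=mol_id)


def _ring_bonds(n: int, bonds: list[list]) -> list[bool]:
    """A bond is in a ring iff its endpoints stay connected without it."""
    adj: list[set[int]] = [set() for _ in range(n)]
    for i, j, _ in bonds:
        adj[i].add(j)
        adj[j].add(i)
    flags = []
    for i, j, _ in bonds:
        adj[i].discard(j)
        adj[j].discard(i)
        seen = {i}
        stack = [i]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        flags.append(j in seen)
        adj[i].add(j)
        adj[j].add(i)
    return flags


def ring_count(mol: Molecule) -> int:
    """Number of independent cycles (cyclomatic number; graph is connected
    by construction, but compute components to be safe)."""
    n = len(mol.atoms)
    adj: list[set[int]] = [set() for _ in range(n)]
    for b in mol.bonds:
        adj[b.i].add(b.j)
        adj[b.j].add(b.i)
    seen: set[int] = set()
    components = 0
    for s in range(n):
        if s in seen:
            continue
        components += 1
        stack = [s]
        seen.add(s)
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
    return len(mol.bonds) - n + components


def planted_affinity(pocket: Molecule, ligand: Molecule,
                     topology_term: bool = False) -> float:
    """Noiseless planted label: linear in element composition, optionally
    plus a ring-count term; clipped to [0, 14] pKa."""
    value = PLANTED_BIAS
    for mol in (pocket, ligand):
        for atom in mol.atoms:
            value += PLANTED_WEIGHTS[atom.element]
    if topology_term:
        value += PLANTED_RING_WEIGHT * (ring_count(pocket) + ring_count(ligand))
    return float(np.clip(value, 0.0, 14.0))


def make_synthetic_molecules(spec: SyntheticSpec, index: int
                             ) -> tuple[Molecule, Molecule]:
    """The (pocket, ligand) molecule pair of complex ``index``."""
    rng = np.random.default_rng([spec.seed, index])
    n_pocket = int(rng.integers(*spec.pocket_size_range, endpoint=True))
    n_ligand = int(rng.integers(*spec.ligand_size_range, endpoint=True))
    cid = f"syn{index:04d}"
    pocket = make_random_molecule(n_pocket, spec.element_alphabet, rng,
                                  allow_double=False, mol_id=cid + "_pocket")
    ligand = make_random_molecule(n_ligand, spec.element_alphabet, rng,
                                  allow_double=True, mol_id=cid + "_ligand")
    return pocket, ligand


def make_synthetic_complex(spec: SyntheticSpec, index: int) -> ComplexGraph:
    """Featurized complex ``index`` with its (possibly noisy) planted label."""
    pocket, ligand = make_synthetic_molecules(spec, index)
    label = planted_affinity(pocket, ligand, spec.topology_term)
    if spec.noise_sd > 0:
        noise_rng = np.random.default_rng([spec.seed, index, 1])
        label = float(np.clip(label + noise_rng.normal(0, spec.noise_sd),
                              0.0, 14.0))
    return build_complex(mol_to_graph(pocket), mol_to_graph(ligand),
                         label=label, complex_id=f"syn{index:04d}")


def make_synthetic_dataset(spec: SyntheticSpec) -> list[ComplexGraph]:
    return [make_synthetic_complex(spec, i) for i in range(spec.n_complexes)]


# ---------------------------------------------------------------------------
# Miniature PDBbind-layout directory
# ---------------------------------------------------------------------------

def _to_rdkit(mol: Molecule):
    """Build a sanitized rdkit molecule with spread-out grid coordinates
    (topology is what matters; coordinates only need to be valid)."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    order_map = {"single": Chem.BondType.SINGLE,
                 "double": Chem.BondType.DOUBLE,
                 "triple": Chem.BondType.TRIPLE,
                 "aromatic": Chem.BondType.AROMATIC}
    rw = Chem.RWMol()
    for atom in mol.atoms:
        a = Chem.Atom(atom.element)
        a.SetFormalCharge(atom.formal_charge)
        rw.AddAtom(a)
    for b in mol.bonds:
        rw.AddBond(b.i, b.j, order_map[b.order])
    m = rw.GetMol()
    Chem.SanitizeMol(m)
    conf = Chem.Conformer(m.GetNumAtoms())
    for i in range(m.GetNumAtoms()):
        conf.SetAtomPosition(i, Point3D(2.0 * (i % 8), 2.0 * ((i // 8) % 8),
                                        2.0 * (i // 64)))
    m.AddConformer(conf)
    return m


def _affinity_string(pka: float) -> str:
    """Render a pKa as a PDBbind-style ``Kd=<value><unit>`` string."""
    kd_molar = 10.0 ** (-pka)
    for unit, factor in (("M", 1.0), ("mM", 1e-3), ("uM", 1e-6),
                         ("nM", 1e-9), ("pM", 1e-12)):
        value = kd_molar / factor
        if value >= 1.0 or unit == "pM":
            return f"Kd={value:.6g}{unit}"
    raise AssertionError("unreachable")


def write_mini_pdbbind(directory: str, spec: SyntheticSpec,
                       corrupt_ids: Sequence[str] = ()) -> list[str]:
    """Write a PDBbind-layout fixture tree and return the complex ids.

    Layout: ``<dir>/<id>/<id>_pocket.pdb`` + ``<id>_ligand.sdf`` plus a
    whitespace-delimited ``index.dat`` (id, resolution, year, pKa,
    affinity string). Ids listed in ``corrupt_ids`` get an unparseable
    ligand file, emulating structures with unreasonable valences that
    dataset assembly must discard.
    """
    from rdkit import Chem

    os.makedirs(directory, exist_ok=True)
    ids = []
    index_lines = ["# id  resolution  year  -logKd/Ki  affinity"]
    for i in range(spec.n_complexes):
        cid = f"syn{i:04d}"
        pocket, ligand = make_synthetic_molecules(spec, i)
        label = planted_affinity(pocket, ligand, spec.topology_term)
        sub = os.path.join(directory, cid)
        os.makedirs(sub, exist_ok=True)
        Chem.MolToPDBFile(_to_rdkit(pocket),
                          os.path.join(sub, f"{cid}_pocket.pdb"))
        lig_path = os.path.join(sub, f"{cid}_ligand.sdf")
        if cid in corrupt_ids:
            with open(lig_path, "w") as fh:
                fh.write("this is not a structure file\n$$$$\n")
        else:
            writer = Chem.SDWriter(lig_path)
            writer.write(_to_rdkit(ligand))
            writer.close()
        index_lines.append(f"{cid}  2.00  2020  {label:.4f}  "
                           f"{_affinity_string(label)}")
        ids.append(cid)
    with open(os.path.join(directory, "index.dat"), "w") as fh:
        fh.write("\n".join(index_lines) + "\n")
    return ids
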