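"""Numeric descriptors for scoring functions.

Three families: element-pair close-contact counts in the style of the
RF-Score scoring function (36 ligand-element × protein-element pair counts
within a cutoff, default 12 Å), a circular (Morgan-style) fingerprint built
by iterative neighborhood hashing, and a linear-path fingerprint. Hashing
uses a fixed 64-bit mixing function so bit assignments are stable across
platforms and runs. Bit-for-bit compatibility with FP2/MACCS/RDKit
fingerprints is explicitly not a goal — the descriptor structure, not the
exact bitset, is what downstream models consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import GeometryError
from .molio import Molecule, ProteinStructure

__all__ = [
    "DescriptorVector",
    "LIGAND_ELEMENTS",
    "PROTEIN_ELEMENTS",
    "rfscore_descriptor",
    "rfscore_names",
    "circular_fingerprint",
    "path_fingerprint",
    "tanimoto",
]

LIGAND_ELEMENTS = ("C", "N", "O", "F", "P", "S", "Cl", "Br", "I")
PROTEIN_ELEMENTS = ("C", "N", "O", "S")


@dataclass
class DescriptorVector:
    values: np.ndarray
    names: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.names):
            raise ValueError("values and names length mismatch")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))

    @property
    def generator_id(self) -> str:
        return self.meta.get("generator", "unknown")


def rfscore_names() -> list[str]:
    """Fixed row-major order: ligand element varies slowest."""
    return [f"{le}.{pe}" for le in LIGAND_ELEMENTS for pe in PROTEIN_ELEMENTS]


def rfscore_descriptor(protein: ProteinStructure, ligand: Molecule,
                       cutoff: float = 12.0) -> DescriptorVector:
    """Close-contact counts: one per (ligand element, protein element) pair.

    Counts heavy-atom pairs within ``cutoff`` Å; hydrogens and elements
    outside the two tables are ignored. The default 12 Å cutoff and the
    9 × 4 element pairing follow the original close-contact formulation.
    """
    if not protein.has_coords() or not ligand.has_coords():
        raise GeometryError("contact descriptors require coordinates on both sides")
    lig_idx = [i for i, a in enumerate(ligand.atoms) if a.element in LIGAND_ELEMENTS]
    pro_idx = [i for i, a in enumerate(protein.atoms) if a.element in PROTEIN_ELEMENTS]
    counts = np.zeros((len(LIGAND_ELEMENTS), len(PROTEIN_ELEMENTS)), dtype=int)
    if lig_idx and pro_idx:
        lc = np.array([ligand.atoms[i].coords for i in lig_idx])
        pc = np.array([protein.atoms[i].coords for i in pro_idx])
        within = cdist(lc, pc) <= cutoff
        lrow = np.array([LIGAND_ELEMENTS.index(ligand.atoms[i].element) for i in lig_idx])
        pcol = np.array([PROTEIN_ELEMENTS.index(protein.atoms[i].element) for i in pro_idx])
        for a, b in zip(*np.nonzero(within)):
            counts[lrow[a], pcol[b]] += 1
    return DescriptorVector(values=counts.reshape(-1).astype(float),
                            names=rfscore_names(),
                            meta={"generator": "rfscore", "cutoff": cutoff})


# ---------------------------------------------------------------------------
# Hashing — fixed 64-bit mix (splitmix64 finalizer), platform-independent
# ---------------------------------------------------------------------------

_MASK = (1 << 64) - 1


def _mix64(x: int) -> int:
    x &= _MASK
    x = (x ^ (x >> 30)) * 0xBF58476D1CE4E5B9 & _MASK
    x = (x ^ (x >> 27)) * 0x94D049BB133111EB & _MASK
    return x ^ (x >> 31)


def _hash_tuple(items) -> int:
    h = 0x9E3779B97F4A7C15
    for it in items:
        h = _mix64(h ^ _mix64(int(it)))
    return h


_ELEMENT_CODES = {el: k + 1 for k, el in enumerate(
    ("H", "B", "C", "N", "O", "F", "Na", "Mg", "P", "S", "Cl", "K", "Ca",
     "Mn", "Fe", "Co", "Ni", "Cu", "Zn", "Se", "Br", "I", "X"))}


def circular_fingerprint(mol: Molecule, radius: int = 2,
                         nbits: int = 1024) -> DescriptorVector:
    """Morgan-style circular fingerprint by iterative neighborhood hashing.

    The initial atom invariant combines element, heavy degree, formal charge,
    aromaticity and total hydrogen count; each round rehashes the atom code
    with the sorted (bond order, neighbor code) list. Every environment code
    from radius 0..r sets bit ``code % nbits``. Canonical by construction:
    independent of input atom order.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if nbits < 64:
        raise ValueError("nbits must be >= 64")
    heavy = mol.heavy_indices()
    codes: dict[int, int] = {}
    for i in heavy:
        a = mol.atoms[i]
        heavy_deg = sum(1 for n in mol.neighbors(i) if mol.atoms[n].element != "H")
        codes[i] = _hash_tuple((
            _ELEMENT_CODES.get(a.element, 0), heavy_deg, a.charge + 8,
            int(a.aromatic), mol.total_h(i)))
    adj: dict[int, list[tuple[int, int]]] = {i: [] for i in heavy}
    for b in mol.bonds:
        if b.i in adj and b.j in adj:
            order_code = 4 if b.aromatic else b.order
            adj[b.i].append((b.j, order_code))
            adj[b.j].append((b.i, order_code))
    bits = np.zeros(nbits, dtype=float)
    for code in codes.values():
        bits[code % nbits] = 1.0
    for _ in range(radius):
        new_codes = {}
        for i in heavy:
            env = sorted((oc, codes[j]) for j, oc in adj[i])
            flat = [codes[i]]
            for oc, nc in env:
                flat.extend((oc, nc))
            new_codes[i] = _hash_tuple(flat)
        codes = new_codes
        for code in codes.values():
            bits[code % nbits] = 1.0
    names = [f"fp_{k}" for k in range(nbits)]
    return DescriptorVector(values=bits, names=names,
                            meta={"generator": "circular", "radius": radius,
                                  "nbits": nbits})


def path_fingerprint(mol: Molecule, maxlen: int = 7,
                     nbits: int = 1024) -> DescriptorVector:
    """Linear-path fingerprint: every simple path of 1..maxlen heavy atoms.

    A path label is the sequence of (element, aromatic) atom codes joined by
    bond-order codes, canonicalized as the lexicographic minimum of the two
    read directions, then hashed to a bit.
    """
    if maxlen < 1:
        raise ValueError("maxlen must be >= 1")
    if nbits < 64:
        raise ValueError("nbits must be >= 64")
    heavy = set(mol.heavy_indices())
    adj: dict[int, list[tuple[int, int]]] = {i: [] for i in heavy}
    for b in mol.bonds:
        if b.i in heavy and b.j in heavy:
            order_code = 4 if b.aromatic else b.order
            adj[b.i].append((b.j, order_code))
            adj[b.j].append((b.i, order_code))

    def atom_code(i: int) -> tuple[int, int]:
        a = mol.atoms[i]
        return (_ELEMENT_CODES.get(a.element, 0), int(a.aromatic))

    labels: set[tuple] = set()

    def extend(path: list[int], label: list[int]):
        labels.add(min(tuple(label), tuple(reversed(label))))
        if len(path) >= maxlen:
            return
        last = path[-1]
        for j, oc in sorted(adj[last]):
            if j not in path:
                extend(path + [j], label + [100 + oc, *atom_code(j)])

    for i in sorted(heavy):
        extend([i], list(atom_code(i)))

    bits = np.zeros(nbits, dtype=float)
    for lab in labels:
        bits[_hash_tuple(lab) % nbits] = 1.0
    names = [f"fp_{k}" for k in range(nbits)]
    return DescriptorVector(values=bits, names=names,
                            meta={"generator": "path", "maxlen": maxlen,
                                  "nbits": nbits})


def tanimoto(a: DescriptorVector | np.ndarray, b: DescriptorVector | np.ndarray) -> float:
    """Tanimoto similarity |a∧b| / |a∨b| of two bit vectors.

    Two all-zero fingerprints compare as identical (1.0) by convention.
    """
    va = a.values if isinstance(a, DescriptorVector) else np.asarray(a, dtype=float)
    vb = b.values if isinstance(b, DescriptorVector) else np.asarray(b, dtype=float)
    ba = va > 0.5
    bb = vb > 0.5
    union = np.logical_or(ba, bb).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(ba, bb).sum() / union)
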