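"""Molecular data model and file IO.

One :class:`Molecule` type carries both ligands and proteins: an atom table
(element, coordinates, formal charge, implicit hydrogens, aromaticity) plus an
undirected bond table. Readers/writers cover SDF V2000, PDB (read),
AutoDock/Vina PDBQT and an organic-subset SMILES grammar. PDB files carry no
bonds, so connectivity is inferred from covalent radii; ring perception and a
Hückel-style aromaticity model complete the perception pipeline.

Conventions: coordinates in Å throughout; atom indices are 0-based in memory
and 1-based only inside file formats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .errors import CapacityError, GeometryError, ParseError

__all__ = [
    "Atom",
    "Bond",
    "Molecule",
    "AtomSite",
    "ProteinStructure",
    "Pose",
    "PoseSet",
    "parse_sdf",
    "write_sdf",
    "parse_pdb",
    "infer_bonds",
    "parse_smiles",
    "parse_pdbqt",
    "write_pdbqt",
    "perceive_rings",
    "perceive_aromaticity",
    "assign_implicit_h",
    "COVALENT_RADII",
    "METALS",
    "ATOMIC_WEIGHTS",
]

# Cordero-style single-bond covalent radii (Å); 0.4 Å slack added when
# inferring bonds — the common PDB-processing convention.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "Na": 1.66, "Mg": 1.41, "P": 1.07, "S": 1.05, "Cl": 1.02, "K": 2.03,
    "Ca": 1.76, "Mn": 1.39, "Fe": 1.32, "Co": 1.26, "Ni": 1.24, "Cu": 1.32,
    "Zn": 1.22, "Se": 1.20, "Br": 1.20, "I": 1.39,
}

BOND_SLACK = 0.4  # Å added to the radius sum

METALS = {"Zn", "Mg", "Ca", "Fe", "Mn", "Cu", "Ni", "Co", "Na", "K"}

ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008, "B": 10.811, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "Na": 22.990, "Mg": 24.305, "P": 30.974, "S": 32.06,
    "Cl": 35.453, "K": 39.098, "Ca": 40.078, "Mn": 54.938, "Fe": 55.845,
    "Co": 58.933, "Ni": 58.693, "Cu": 63.546, "Zn": 65.38, "Se": 78.971,
    "Br": 79.904, "I": 126.904,
}

_WATER_RESIDUES = {"HOH", "WAT", "H2O", "DOD"}


@dataclass
class Atom:
    element: str
    coords: np.ndarray | None = None  # shape (3,), Å; None for topology-only
    charge: int = 0                   # formal charge, e
    implicit_h: int = 0
    aromatic: bool = False

    def __post_init__(self):
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
        if not -4 <= self.charge <= 4:
            raise ValueError(f"formal charge {self.charge} outside [-4, +4]")


@dataclass
class Bond:
    i: int
    j: int
    order: int = 1        # 1, 2, 3; aromatic bonds carry order 1 + flag
    aromatic: bool = False

    def key(self) -> tuple[int, int]:
        return (self.i, self.j) if self.i < self.j else (self.j, self.i)


@dataclass
class Molecule:
    atoms: list[Atom] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)
    name: str = ""
    properties: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    # -- structural helpers -------------------------------------------------
    def validate(self) -> None:
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n) or b.i == b.j:
                raise ValueError(f"bond ({b.i},{b.j}) has invalid endpoints for {n} atoms")
            if b.key() in seen:
                raise ValueError(f"duplicate bond {b.key()}")
            seen.add(b.key())
            if b.aromatic and not (self.atoms[b.i].aromatic and self.atoms[b.j].aromatic):
                raise ValueError(f"aromatic bond {b.key()} joins non-aromatic atoms")

    def n_atoms(self) -> int:
        return len(self.atoms)

    def has_coords(self) -> bool:
        return all(a.coords is not None for a in self.atoms) and bool(self.atoms)

    def coords_array(self) -> np.ndarray:
        if not self.has_coords():
            raise GeometryError(f"molecule {self.name!r} lacks coordinates")
        return np.array([a.coords for a in self.atoms], dtype=float)

    def neighbors(self, idx: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.i == idx:
                out.append(b.j)
            elif b.j == idx:
                out.append(b.i)
        return sorted(out)

    def adjacency(self) -> dict[int, list[tuple[int, Bond]]]:
        adj: dict[int, list[tuple[int, Bond]]] = {i: [] for i in range(len(self.atoms))}
        for b in self.bonds:
            adj[b.i].append((b.j, b))
            adj[b.j].append((b.i, b))
        return adj

    def degree(self, idx: int) -> int:
        return len(self.neighbors(idx))

    def heavy_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.element != "H"]

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.atoms)))
        g.add_edges_from((b.i, b.j) for b in self.bonds)
        return g

    def bond_between(self, i: int, j: int) -> Bond | None:
        key = (i, j) if i < j else (j, i)
        for b in self.bonds:
            if b.key() == key:
                return b
        return None

    def total_h(self, idx: int) -> int:
        """Explicit H neighbors plus implicit count."""
        expl = sum(1 for n in self.neighbors(idx) if self.atoms[n].element == "H")
        return expl + self.atoms[idx].implicit_h

    def translated(self, shift) -> "Molecule":
        m = self.copy()
        for a in m.atoms:
            if a.coords is not None:
                a.coords = a.coords + np.asarray(shift, float)
        return m

    def transformed(self, rotation, translation) -> "Molecule":
        """Rigid motion x -> R x + t applied to every atom."""
        m = self.copy()
        rot = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        for a in m.atoms:
            if a.coords is not None:
                a.coords = rot @ a.coords + t
        return m

    def copy(self) -> "Molecule":
        return Molecule(
            atoms=[Atom(a.element, None if a.coords is None else a.coords.copy(),
                        a.charge, a.implicit_h, a.aromatic) for a in self.atoms],
            bonds=[Bond(b.i, b.j, b.order, b.aromatic) for b in self.bonds],
            name=self.name,
            properties=dict(self.properties),
        )


@dataclass
class AtomSite:
    """Per-atom annotation from a PDB/PDBQT record."""
    atom_name: str = ""
    residue_name: str = ""
    residue_seq: int = 0
    chain: str = ""
    record: str = "ATOM"  # ATOM or HETATM


class ProteinStructure(Molecule):
    """A Molecule plus residue annotations and flagged metal centres."""

    def __init__(self, atoms=None, bonds=None, name="", properties=None,
                 sites=None, metals=None, warnings=None):
        self.sites: list[AtomSite] = list(sites or [])
        self.metals: list[int] = list(metals or [])
        self.warnings: list[str] = list(warnings or [])
        super().__init__(atoms=list(atoms or []), bonds=list(bonds or []),
                         name=name, properties=dict(properties or {}))
        for idx in self.metals:
            if self.atoms[idx].element not in METALS:
                raise ValueError(f"metal index {idx} is element {self.atoms[idx].element}")

    def copy(self) -> "ProteinStructure":
        base = Molecule.copy(self)
        return ProteinStructure(atoms=base.atoms, bonds=base.bonds, name=base.name,
                                properties=base.properties,
                                sites=[AtomSite(s.atom_name, s.residue_name, s.residue_seq,
                                                s.chain, s.record) for s in self.sites],
                                metals=list(self.metals), warnings=list(self.warnings))

    def transformed(self, rotation, translation) -> "ProteinStructure":
        m = self.copy()
        rot = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        for a in m.atoms:
            if a.coords is not None:
                a.coords = rot @ a.coords + t
        return m


@dataclass
class Pose:
    molecule: Molecule
    score: float | None
    rank: int


@dataclass
class PoseSet:
    poses: list[Pose] = field(default_factory=list)
    source_engine: str = ""

    def __post_init__(self):
        for k, p in enumerate(self.poses, start=1):
            if p.rank != k:
                raise ValueError("pose ranks must be contiguous 1..n")
        if self.poses:
            ref = [a.element for a in self.poses[0].molecule.atoms]
            for p in self.poses[1:]:
                if [a.element for a in p.molecule.atoms] != ref:
                    raise ValueError("poses differ in atom count or element sequence")


# ---------------------------------------------------------------------------
# SDF V2000
# ---------------------------------------------------------------------------

_SDF_CHARGE_CODES = {0: 0, 1: 3, 2: 2, 3: 1, 5: -1, 6: -2, 7: -3}
_SDF_CHARGE_CODES_INV = {v: k for k, v in _SDF_CHARGE_CODES.items()}


def parse_sdf(text: str) -> list[Molecule]:
    """Parse an SDF V2000 document into a list of molecules.

    Records are delimited by ``$$$$``; an empty document yields an empty list.
    Bond type 4 marks both endpoints (and the bond) aromatic. ``M  CHG`` lines
    override atom-block charge codes. Data fields (``> <tag>`` blocks) are
    captured into :attr:`Molecule.properties`.
    """
    mols: list[Molecule] = []
    lines = text.splitlines()
    pos = 0
    record_idx = 0
    while pos < len(lines):
        # skip blank padding between records
        while pos < len(lines) and lines[pos].strip() == "":
            pos += 1
        if pos >= len(lines):
            break
        record_idx += 1
        start = pos
        mols.append(_parse_sdf_record(lines, start, record_idx))
        # advance to past $$$$
        while pos < len(lines) and lines[pos].strip() != "$$$$":
            pos += 1
        pos += 1
    return mols


def _parse_sdf_record(lines: list[str], start: int, record: int) -> Molecule:
    if start + 3 >= len(lines):
        raise ParseError("truncated header block", line=start + 1, record=record)
    name = lines[start].strip()
    counts_line_no = start + 3
    counts = lines[counts_line_no]
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except (ValueError, IndexError):
        raise ParseError(f"malformed counts line {counts!r}",
                         line=counts_line_no + 1, record=record) from None
    atoms: list[Atom] = []
    base = counts_line_no + 1
    for k in range(n_atoms):
        ln = base + k
        if ln >= len(lines):
            raise ParseError("truncated atom block", line=ln + 1, record=record)
        row = lines[ln]
        try:
            x, y, z = float(row[0:10]), float(row[10:20]), float(row[20:30])
            element = row[31:34].strip()
            code = int(row[36:39]) if row[36:39].strip() else 0
        except (ValueError, IndexError):
            raise ParseError(f"malformed atom line {row!r}", line=ln + 1, record=record) from None
        atoms.append(Atom(element, np.array([x, y, z]),
                          charge=_SDF_CHARGE_CODES.get(code, 0)))
    bonds: list[Bond] = []
    base += n_atoms
    for k in range(n_bonds):
        ln = base + k
        if ln >= len(lines):
            raise ParseError("truncated bond block", line=ln + 1, record=record)
        row = lines[ln]
        try:
            i, j, btype = int(row[0:3]) - 1, int(row[3:6]) - 1, int(row[6:9])
        except (ValueError, IndexError):
            raise ParseError(f"malformed bond line {row!r}", line=ln + 1, record=record) from None
        if btype == 4:
            atoms[i].aromatic = True
            atoms[j].aromatic = True
            bonds.append(Bond(i, j, order=1, aromatic=True))
        else:
            bonds.append(Bond(i, j, order=btype))
    # properties block: M lines then "> <tag>" data items until $$$$
    pos = base + n_bonds
    props: dict[str, str] = {}
    charges_reset = False
    while pos < len(lines) and lines[pos].strip() != "$$$$":
        row = lines[pos]
        if row.startswith("M  CHG"):
            if not charges_reset:
                for a in atoms:
                    a.charge = 0
                charges_reset = True
            fields = row.split()
            cnt = int(fields[2])
            for t in range(cnt):
                idx = int(fields[3 + 2 * t]) - 1
                atoms[idx].charge = int(fields[4 + 2 * t])
        elif row.startswith("> "):
            tag = row[row.find("<") + 1:row.rfind(">")]
            pos += 1
            vals = []
            while pos < len(lines) and lines[pos].strip() not in ("", "$$$$"):
                vals.append(lines[pos])
                pos += 1
            props[tag] = "\n".join(vals)
        pos += 1
    return Molecule(atoms=atoms, bonds=bonds, name=name, properties=props)


def write_sdf(mols: list[Molecule] | Molecule) -> str:
    """Serialize molecules to SDF V2000 text (``%10.4f`` coordinates)."""
    if isinstance(mols, Molecule):
        mols = [mols]
    out: list[str] = []
    for m in mols:
        if m.n_atoms() > 999:
            raise CapacityError(f"{m.n_atoms()} atoms exceed the V2000 limit of 999")
        out.append(m.name)
        out.append("  oddkit")
        out.append("")
        out.append(f"{m.n_atoms():3d}{len(m.bonds):3d}  0  0  0  0  0  0  0  0999 V2000")
        for a in m.atoms:
            xyz = a.coords if a.coords is not None else np.zeros(3)
            out.append(f"{xyz[0]:10.4f}{xyz[1]:10.4f}{xyz[2]:10.4f} {a.element:<3s} 0  0  0  0  0  0  0  0  0  0  0  0")
        for b in m.bonds:
            btype = 4 if b.aromatic else b.order
            out.append(f"{b.i + 1:3d}{b.j + 1:3d}{btype:3d}  0")
        charged = [(i, a.charge) for i, a in enumerate(m.atoms) if a.charge != 0]
        for k in range(0, len(charged), 8):
            chunk = charged[k:k + 8]
            row = f"M  CHG{len(chunk):3d}"
            for i, c in chunk:
                row += f"{i + 1:4d}{c:4d}"
            out.append(row)
        out.append("M  END")
        for tag, val in m.properties.items():
            out.append(f"> <{tag}>")
            out.append(val)
            out.append("")
        out.append("$$$$")
    return "\n".join(out) + ("\n" if out else "")


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

_KNOWN_ELEMENTS = set(COVALENT_RADII) | {"X"}


def _element_from_pdb(line: str, atom_name: str) -> str:
    el = line[76:78].strip() if len(line) >= 78 else ""
    if not el:
        # fall back to the atom-name field: strip digits, try 2- then 1-char
        stripped = "".join(c for c in atom_name if c.isalpha())
        cand2 = stripped[:2].capitalize()
        cand1 = stripped[:1].upper()
        el = cand2 if cand2 in COVALENT_RADII and cand2 not in ("Ca", "Cd") else cand1
        # heuristics: atom names like "CA" in proteins are carbons
        if atom_name.strip() in ("CA", "CB", "CD", "CG", "CE", "CZ", "CH"):
            el = "C"
    else:
        el = el.capitalize()
    return el


def parse_pdb(text: str, het_as_ligand: bool = False):
    """Parse fixed-column ATOM/HETATM records into a :class:`ProteinStructure`.

    Bonds are inferred from covalent radii (PDB carries none); metal atoms are
    flagged and excluded from covalent bonding. With ``het_as_ligand`` the
    non-water, non-metal HETATM residues are split out and returned as a list
    of ligand molecules: ``(protein, ligands)``.
    """
    atoms: list[Atom] = []
    sites: list[AtomSite] = []
    warnings: list[str] = []
    for ln, line in enumerate(text.splitlines(), start=1):
        rec = line[0:6].strip()
        if rec not in ("ATOM", "HETATM"):
            continue
        if len(line) < 54:
            raise ParseError("record shorter than coordinate columns", line=ln)
        try:
            x, y, z = float(line[30:38]), float(line[38:46]), float(line[46:54])
        except ValueError:
            raise ParseError(f"unparseable coordinates in {line!r}", line=ln) from None
        atom_name = line[12:16]
        element = _element_from_pdb(line, atom_name)
        if element not in _KNOWN_ELEMENTS and element != "H":
            warnings.append(f"line {ln}: unknown element {element!r} recorded as 'X'")
            element = "X"
        atoms.append(Atom(element, np.array([x, y, z])))
        sites.append(AtomSite(
            atom_name=atom_name.strip(),
            residue_name=line[17:20].strip(),
            residue_seq=int(line[22:26]) if line[22:26].strip() else 0,
            chain=line[21].strip(),
            record=rec,
        ))
    metals = [i for i, a in enumerate(atoms) if a.element in METALS]
    ligands: list[Molecule] = []
    if het_as_ligand:
        het_groups: dict[tuple, list[int]] = {}
        for i, s in enumerate(sites):
            if (s.record == "HETATM" and s.residue_name not in _WATER_RESIDUES
                    and i not in metals):
                het_groups.setdefault((s.chain, s.residue_seq, s.residue_name), []).append(i)
        lig_atom_set = {i for grp in het_groups.values() for i in grp}
        keep = [i for i in range(len(atoms)) if i not in lig_atom_set]
        remap = {old: new for new, old in enumerate(keep)}
        prot_atoms = [atoms[i] for i in keep]
        prot_sites = [sites[i] for i in keep]
        prot_metals = [remap[i] for i in metals]
        prot_bonds = infer_bonds(prot_atoms)
        protein = ProteinStructure(atoms=prot_atoms, bonds=prot_bonds, sites=prot_sites,
                                   metals=prot_metals, warnings=warnings)
        for key in sorted(het_groups):
            grp = het_groups[key]
            lig_atoms = [Atom(atoms[i].element, atoms[i].coords.copy()) for i in grp]
            lig = Molecule(atoms=lig_atoms, bonds=infer_bonds(lig_atoms),
                           name=f"{key[2]}_{key[0]}{key[1]}")
            ligands.append(lig)
        return protein, ligands
    bonds = infer_bonds(atoms)
    return ProteinStructure(atoms=atoms, bonds=bonds, sites=sites,
                            metals=metals, warnings=warnings)


def infer_bonds(atoms: list[Atom]) -> list[Bond]:
    """Distance-based bond inference: i,j bonded iff both non-metal and
    ``d(i,j) <= r_cov(i) + r_cov(j) + 0.4 Å``. Deterministic and symmetric."""
    idx = [k for k, a in enumerate(atoms)
           if a.coords is not None and a.element not in METALS]
    if len(idx) < 2:
        return []
    coords = np.array([atoms[k].coords for k in idx])
    radii = np.array([COVALENT_RADII.get(atoms[k].element, 0.0) for k in idx])
    rmax = radii.max()
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=2 * rmax + BOND_SLACK, output_type="ndarray")
    bonds: list[Bond] = []
    for a, b in pairs:
        cut = radii[a] + radii[b] + BOND_SLACK
        if radii[a] > 0 and radii[b] > 0 and np.linalg.norm(coords[a] - coords[b]) <= cut:
            i, j = idx[a], idx[b]
            bonds.append(Bond(min(i, j), max(i, j)))
    bonds.sort(key=lambda bo: bo.key())
    return bonds


# ---------------------------------------------------------------------------
# SMILES subset
# ---------------------------------------------------------------------------

_ORGANIC_TWO = ("Cl", "Br")
_ORGANIC_ONE = set("BCNOPSFI")
_AROMATIC_ORGANIC = set("bcnops")
_DEFAULT_VALENCES: dict[str, tuple[int, ...]] = {
    "B": (3,), "C": (4,), "N": (3,), "O": (2,), "P": (3, 5), "S": (2, 4, 6),
    "F": (1,), "Cl": (1,), "Br": (1,), "I": (1,),
}


def parse_smiles(s: str) -> Molecule:
    """Parse an organic-subset SMILES string into a topology-only molecule.

    Supported: organic-subset atoms (B C N O P S F Cl Br I), lowercase
    aromatic forms, bonds ``- = # :``, branches, ring closures (digits and
    ``%nn``), and bracket atoms with charge and explicit H count. Stereo
    markers and isotopes are rejected. Implicit hydrogens are filled from
    standard valences (aromatic bonds counting 3/2).
    """
    atoms: list[Atom] = []
    bonds: list[Bond] = []
    explicit_h: dict[int, int] = {}   # bracket atoms: fixed H count
    stack: list[int] = []
    prev: int | None = None
    pending_bond: str | None = None
    ring_open: dict[int, tuple[int, str | None]] = {}
    i = 0
    n = len(s)

    def add_bond(a: int, b: int, sym: str | None):
        if sym == "=":
            bonds.append(Bond(a, b, 2))
        elif sym == "#":
            bonds.append(Bond(a, b, 3))
        elif sym == ":":
            bonds.append(Bond(a, b, 1, aromatic=True))
        else:  # default: aromatic if both ends aromatic
            if atoms[a].aromatic and atoms[b].aromatic:
                bonds.append(Bond(a, b, 1, aromatic=True))
            else:
                bonds.append(Bond(a, b, 1))

    def new_atom(element: str, aromatic: bool, charge: int = 0,
                 hcount: int | None = None) -> int:
        atoms.append(Atom(element, None, charge=charge, aromatic=aromatic))
        idx = len(atoms) - 1
        if hcount is not None:
            explicit_h[idx] = hcount
        return idx

    while i < n:
        c = s[i]
        if c in "/\\@":
            raise ParseError(f"stereochemistry marker {c!r} not supported", line=None,
                             record=None) from None
        if c == "(":
            if prev is None:
                raise ParseError(f"branch open at offset {i} with no preceding atom")
            stack.append(prev)
            i += 1
        elif c == ")":
            if not stack:
                raise ParseError(f"unmatched ')' at offset {i}")
            prev = stack.pop()
            i += 1
        elif c in "-=#:":
            pending_bond = c
            i += 1
        elif c.isdigit() or c == "%":
            if c == "%":
                if i + 2 >= n or not s[i + 1:i + 3].isdigit():
                    raise ParseError(f"malformed %nn ring closure at offset {i}")
                num = int(s[i + 1:i + 3])
                i += 3
            else:
                num = int(c)
                i += 1
            if prev is None:
                raise ParseError(f"ring closure digit before any atom at offset {i}")
            if num in ring_open:
                other, sym = ring_open.pop(num)
                add_bond(min(other, prev), max(other, prev), sym or pending_bond)
            else:
                ring_open[num] = (prev, pending_bond)
            pending_bond = None
        elif c == "[":
            close = s.find("]", i)
            if close < 0:
                raise ParseError(f"unmatched '[' at offset {i}")
            idx = _parse_bracket_atom(s[i + 1:close], i, new_atom)
            if prev is not None:
                add_bond(min(prev, idx), max(prev, idx), pending_bond)
            pending_bond = None
            prev = idx
            i = close + 1
        else:
            matched = None
            if s[i:i + 2] in _ORGANIC_TWO:
                matched = (s[i:i + 2], False)
                i += 2
            elif c in _ORGANIC_ONE:
                matched = (c, False)
                i += 1
            elif c in _AROMATIC_ORGANIC:
                matched = (c.upper(), True)
                i += 1
            else:
                raise ParseError(f"unknown token {c!r} at offset {i}")
            idx = new_atom(matched[0], matched[1])
            if prev is not None:
                add_bond(min(prev, idx), max(prev, idx), pending_bond)
            pending_bond = None
            prev = idx
    if ring_open:
        raise ParseError(f"unmatched ring closure digit(s) {sorted(ring_open)}")
    if stack:
        raise ParseError("unmatched '(' at end of input")

    mol = Molecule(atoms=atoms, bonds=bonds, name=s)
    _fill_implicit_h(mol, explicit_h)
    return mol


def _parse_bracket_atom(body: str, offset: int, new_atom) -> int:
    """Parse the inside of ``[...]``: element, optional aromatic-lowercase,
    optional H count, optional charge. Isotopes/stereo rejected."""
    if not body:
        raise ParseError(f"empty bracket atom at offset {offset}")
    if body[0].isdigit():
        raise ParseError(f"isotope specification not supported at offset {offset}")
    k = 0
    aromatic = False
    if body[:2].capitalize() in COVALENT_RADII and body[:2] not in ("Cl", "Br") and body[:2].istitle():
        element = body[:2]
        k = 2
    elif body[:2] in ("Cl", "Br"):
        element = body[:2]
        k = 2
    elif body[0].isupper():
        element = body[0]
        k = 1
    elif body[0] in _AROMATIC_ORGANIC:
        element = body[0].upper()
        aromatic = True
        k = 1
    else:
        raise ParseError(f"unknown bracket element in [{body}] at offset {offset}")
    hcount = 0
    charge = 0
    while k < len(body):
        c = body[k]
        if c == "H":
            k += 1
            num = ""
            while k < len(body) and body[k].isdigit():
                num += body[k]
                k += 1
            hcount = int(num) if num else 1
        elif c in "+-":
            sign = 1 if c == "+" else -1
            k += 1
            num = ""
            while k < len(body) and body[k].isdigit():
                num += body[k]
                k += 1
            if num:
                charge = sign * int(num)
            else:
                charge = sign
                while k < len(body) and body[k] == c:
                    charge += sign
                    k += 1
        elif c == "@":
            raise ParseError(f"stereochemistry not supported in [{body}] at offset {offset}")
        else:
            raise ParseError(f"unknown token {c!r} in bracket atom at offset {offset}")
    return new_atom(element, aromatic, charge=charge, hcount=hcount)


def _fill_implicit_h(mol: Molecule, explicit_h: dict[int, int]) -> None:
    assign_implicit_h(mol)
    for idx, count in explicit_h.items():  # bracket atoms carry exact H counts
        mol.atoms[idx].implicit_h = count


def assign_implicit_h(mol: Molecule) -> Molecule:
    """Fill implicit hydrogen counts from standard valences in place.

    Used after reading formats that carry no hydrogens (SDF written without
    them, PDB heavy-atom records). Atoms with explicit H neighbors have those
    subtracted; elements outside the valence table get zero.
    """
    order_sum = [0.0] * mol.n_atoms()
    for b in mol.bonds:
        val = 1.5 if b.aromatic else float(b.order)
        order_sum[b.i] += val
        order_sum[b.j] += val
    for idx, a in enumerate(mol.atoms):
        if a.element == "H":
            a.implicit_h = 0
            continue
        valences = _DEFAULT_VALENCES.get(a.element)
        if valences is None:
            a.implicit_h = 0
            continue
        adjusted = [v + a.charge for v in valences]
        need = order_sum[idx]
        fill = 0
        for v in sorted(adjusted):
            if v >= need - 1e-9:
                fill = int(math.floor(v - need + 1e-9))
                break
        a.implicit_h = max(0, fill)
    return mol


# ---------------------------------------------------------------------------
# PDBQT (AutoDock/Vina dialect)
# ---------------------------------------------------------------------------

_PDBQT_TYPE_TO_ELEMENT = {
    "A": "C", "C": "C", "HD": "H", "H": "H", "HS": "H", "N": "N", "NA": "N",
    "NS": "N", "O": "O", "OA": "O", "OS": "O", "S": "S", "SA": "S", "P": "P",
    "F": "F", "CL": "Cl", "BR": "Br", "I": "I", "ZN": "Zn", "MG": "Mg",
    "CA": "Ca", "FE": "Fe", "MN": "Mn",
}


def parse_pdbqt(text: str) -> PoseSet:
    """Parse (possibly multi-MODEL) Vina-style PDBQT output into a PoseSet.

    Pose scores come from the first numeric field of ``REMARK VINA RESULT:``
    lines; a model lacking one gets score ``None``. Models must agree in atom
    count; a MODEL without ENDMDL is a parse error.
    """
    models: list[tuple[list[Atom], float | None]] = []
    cur_atoms: list[Atom] | None = None
    cur_score: float | None = None
    in_model = False
    saw_model_kw = False
    for ln, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if line.startswith("MODEL"):
            if in_model:
                raise ParseError("MODEL without matching ENDMDL", line=ln)
            in_model = True
            saw_model_kw = True
            cur_atoms = []
            cur_score = None
        elif line.startswith("ENDMDL"):
            if not in_model:
                raise ParseError("ENDMDL without MODEL", line=ln)
            models.append((cur_atoms, cur_score))
            in_model = False
            cur_atoms = None
        elif line.startswith("REMARK VINA RESULT:"):
            fields = line.split(":", 1)[1].split()
            score = float(fields[0])
            if in_model:
                cur_score = score
            else:
                cur_score = score  # single-model document: remember for flush
        elif rec in ("ATOM", "HETATM"):
            if len(line) < 54:
                raise ParseError("record shorter than coordinate columns", line=ln)
            x, y, z = float(line[30:38]), float(line[38:46]), float(line[46:54])
            ad_type = line[77:79].strip() if len(line) >= 78 else ""
            element = _PDBQT_TYPE_TO_ELEMENT.get(ad_type.upper())
            if element is None:
                element = _element_from_pdb(line, line[12:16])
            aromatic = ad_type.upper() == "A"
            if cur_atoms is None:
                cur_atoms = []
            cur_atoms.append(Atom(element, np.array([x, y, z]), aromatic=aromatic))
    if in_model:
        raise ParseError("MODEL without matching ENDMDL at end of input")
    if not saw_model_kw and cur_atoms:
        models.append((cur_atoms, cur_score))
    if models:
        n0 = len(models[0][0])
        for k, (al, _) in enumerate(models, start=1):
            if len(al) != n0:
                raise ParseError(f"model {k} has {len(al)} atoms, expected {n0}")
    poses = []
    for k, (al, score) in enumerate(models, start=1):
        mol = Molecule(atoms=al, bonds=infer_bonds(al), name=f"pose_{k}")
        poses.append(Pose(molecule=mol, score=score, rank=k))
    return PoseSet(poses=poses, source_engine="vina")


def _pdbqt_atom_type(mol: Molecule, idx: int) -> str:
    a = mol.atoms[idx]
    if a.element == "C" and a.aromatic:
        return "A"
    if a.element == "H":
        # polar H: bonded to N/O/S
        if any(mol.atoms[n].element in ("N", "O", "S") for n in mol.neighbors(idx)):
            return "HD"
        return "H"
    return a.element


def write_pdbqt(mol: Molecule) -> str:
    """Write a rigid-ligand PDBQT block (single ROOT, TORSDOF 0).

    AutoDock types derive from element + aromaticity: aromatic C → ``A``,
    polar H → ``HD``, all else the element symbol. Charges are written as 0 —
    partial-charge assignment is out of scope and documented as such.
    """
    if not mol.has_coords():
        raise GeometryError("PDBQT writing requires coordinates")
    out = [f"REMARK  Name = {mol.name}", "ROOT"]
    for k, a in enumerate(mol.atoms, start=1):
        t = _pdbqt_atom_type(mol, k - 1)
        name = (a.element + str(k))[:4]
        out.append(
            f"ATOM  {k:5d} {name:<4s} LIG A   1    "
            f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
            f"  1.00  0.00    {0.0:6.3f} {t:<2s}"
        )
    out.append("ENDROOT")
    out.append("TORSDOF 0")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Ring perception & aromaticity
# ---------------------------------------------------------------------------

def _order_cycle(nodes: list[int], graph: nx.Graph) -> list[int]:
    """Order a cycle-basis node set into an atom cycle, deterministically:
    start at the smallest index, step to its smaller eligible neighbor."""
    nodeset = set(nodes)
    sub = {v: sorted(u for u in graph.neighbors(v) if u in nodeset) for v in nodeset}
    start = min(nodeset)

    def walk(path: list[int], visited: set[int]) -> list[int] | None:
        cur = path[-1]
        if len(path) == len(nodeset):
            return path if start in sub[cur] else None
        for nxt in sub[cur]:
            if nxt not in visited:
                res = walk(path + [nxt], visited | {nxt})
                if res:
                    return res
        return None

    ordered = walk([start], {start})
    if ordered is None:  # not a simple cycle (should not happen for SSSR sets)
        return sorted(nodeset)
    # canonical direction: second element is the smaller of the two neighbors
    if ordered[1] > ordered[-1]:
        ordered = [ordered[0]] + ordered[:0:-1]
    return ordered


def perceive_rings(mol: Molecule) -> list[list[int]]:
    """Return an SSSR-equivalent set of rings as ordered atom cycles.

    Uses a minimum cycle basis of the molecular graph; output is sorted by
    (ring size, atom indices) so results are deterministic for a given input
    atom order.
    """
    g = mol.graph()
    basis = nx.minimum_cycle_basis(g)
    rings = [_order_cycle(cyc, g) for cyc in basis]
    rings.sort(key=lambda r: (len(r), sorted(r)))
    return rings


def perceive_aromaticity(mol: Molecule) -> Molecule:
    """Set aromatic flags on rings that pass a Hückel 4n+2 heuristic.

    Flags already present (SDF type-4 bonds, lowercase SMILES) are trusted and
    kept. Otherwise a ring is aromatic iff every member is C/N/O/S with at
    most 3 heavy neighbors, every member is conjugated (has a double bond or
    is a lone-pair donor heteroatom), and the π-electron count is 4n+2 —
    contributions: atom in a ring double bond → 1, pyrrole-type N/O/S → 2.
    This is a documented stand-in for a full aromaticity model.
    """
    rings = perceive_rings(mol)
    double_partners: dict[int, set[int]] = {}
    for b in mol.bonds:
        if b.order == 2:
            double_partners.setdefault(b.i, set()).add(b.j)
            double_partners.setdefault(b.j, set()).add(b.i)
    for ring in rings:
        if any(mol.atoms[i].aromatic for i in ring):
            continue  # trusted input flags handled below
        ok = True
        pi = 0
        ringset = set(ring)
        for i in ring:
            el = mol.atoms[i].element
            heavy_nb = [n for n in mol.neighbors(i) if mol.atoms[n].element != "H"]
            if el not in ("C", "N", "O", "S") or len(heavy_nb) > 3:
                ok = False
                break
            partners = double_partners.get(i, set())
            if partners:
                pi += 1  # one electron from a double bond (in or out of ring)
            elif el in ("N", "O", "S") and mol.atoms[i].charge <= 0:
                pi += 2  # pyrrole-type lone pair
            else:
                ok = False  # sp3 carbon breaks conjugation
                break
        if ok and pi % 4 == 2:
            for i in ring:
                mol.atoms[i].aromatic = True
            for a, b in zip(ring, ring[1:] + ring[:1]):
                bond = mol.bond_between(a, b)
                if bond is not None:
                    bond.aromatic = True
    # ensure consistency: aromatic bonds between flagged atoms in trusted rings
    for ring in rings:
        if all(mol.atoms[i].aromatic for i in ring):
            for a, b in zip(ring, ring[1:] + ring[:1]):
                bond = mol.bond_between(a, b)
                if bond is not None and not bond.aromatic:
                    bond.aromatic = True
    return mol
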