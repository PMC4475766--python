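"""Pharmacophoric feature perception.

Reduces a molecule (or annotated protein structure) to a uniform
:class:`FeatureSet`: hydrogen-bond donors/acceptors, formal/functional-group
ions, hydrophobes, halogen-bond donors, aromatic rings with fitted planes,
and metal centres. Interaction detectors consume only this structure, so
custom binding queries can be written against it directly.

Charge perception is rule-based — formal charges plus the common ionizable
groups at physiological pH (carboxylate, phosphate, sulfonate oxygens;
guanidinium/amidinium carbons; protein Asp/Glu/Lys/Arg side chains). The
toolkit does not predict pKa; the rule table is the documented model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError
from .molio import METALS, Molecule, ProteinStructure

__all__ = ["FeatureSet", "RingFeature", "perceive_features", "ring_geometry",
           "count_donors", "count_acceptors"]

_PROTEIN_CATION_ATOMS = {("ARG", "CZ"), ("LYS", "NZ")}
_PROTEIN_ANION_ATOMS = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
_HIS_AMBIG = {("HIS", "ND1"), ("HIS", "NE2")}
_STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


@dataclass
class RingFeature:
    atoms: list[int]
    centroid: np.ndarray
    normal: np.ndarray


@dataclass
class FeatureSet:
    donors: list[tuple[int, list[int]]] = field(default_factory=list)
    acceptors: list[int] = field(default_factory=list)
    cations: list[int] = field(default_factory=list)
    anions: list[int] = field(default_factory=list)
    hydrophobes: list[int] = field(default_factory=list)
    halogens: list[tuple[int, int]] = field(default_factory=list)  # (X, bonded C)
    rings: list[RingFeature] = field(default_factory=list)
    metals: list[int] = field(default_factory=list)
    molecule: Molecule | None = None

    def validate(self) -> None:
        n = self.molecule.n_atoms() if self.molecule is not None else None
        donor_atoms = {d for d, _ in self.donors}
        assert not donor_atoms & set(self.metals), "donors and metals overlap"
        assert not set(self.cations) & set(self.anions), "cations and anions overlap"
        for ring in self.rings:
            assert abs(np.linalg.norm(ring.normal) - 1.0) < 1e-9
        if n is not None:
            everything = (donor_atoms | set(self.acceptors) | set(self.cations)
                          | set(self.anions) | set(self.hydrophobes)
                          | {x for x, _ in self.halogens} | set(self.metals))
            assert all(0 <= i < n for i in everything), "feature index out of range"


def ring_geometry(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit normal of a ring given its atom coordinates.

    The normal is the eigenvector of the coordinate covariance with the
    smallest eigenvalue (best-fit plane). Sign convention: positive z
    component; if z is ~0, positive x; if both ~0, positive y.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 3:
        raise GeometryError("ring needs at least 3 atoms")
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    cov = centered.T @ centered
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] < 1e-12:  # two near-zero eigenvalues: collinear atoms
        raise GeometryError("collinear ring atoms: no unique plane")
    normal = evecs[:, 0]
    normal = normal / np.linalg.norm(normal)
    for comp in (2, 0, 1):
        if abs(normal[comp]) > 1e-9:
            if normal[comp] < 0:
                normal = -normal
            break
    return centroid, normal


# -- topology-only counting rules (shared with the property filters) --------

def _is_donor(mol: Molecule, i: int) -> bool:
    a = mol.atoms[i]
    return a.element in ("N", "O", "S") and mol.total_h(i) >= 1


def _is_acceptor(mol: Molecule, i: int) -> bool:
    a = mol.atoms[i]
    if a.element not in ("N", "O"):
        return False
    if a.element == "N":
        order_sum = sum((1.5 if b.aromatic else b.order)
                        for b in mol.bonds if i in (b.i, b.j))
        order_sum += mol.total_h(i)
        if a.charge > 0 or order_sum >= 4:      # quaternary/charged N
            return False
        if a.aromatic and not any(b.order == 2 for b in mol.bonds if i in (b.i, b.j)):
            # pyrrole-type aromatic N: lone pair in the π system
            if mol.total_h(i) >= 1 or order_sum >= 3.5:
                return False
    return True


def count_donors(mol: Molecule) -> int:
    return sum(1 for i in mol.heavy_indices() if _is_donor(mol, i))


def count_acceptors(mol: Molecule) -> int:
    return sum(1 for i in mol.heavy_indices() if _is_acceptor(mol, i))


def _group_anion_oxygens(mol: Molecule) -> set[int]:
    """Oxygens of carboxylate/phosphate/sulfonate groups; symmetric O atoms of
    a group are labelled identically regardless of which one carries the
    formal charge."""
    out: set[int] = set()
    for c, a in enumerate(mol.atoms):
        if a.element not in ("C", "P", "S"):
            continue
        oxy = [n for n in mol.neighbors(c) if mol.atoms[n].element == "O"]
        terminal_o = [o for o in oxy if len([x for x in mol.neighbors(o)
                                             if mol.atoms[x].element != "H"]) == 1]
        if len(terminal_o) < 2:
            continue
        has_double = any(
            (b.order == 2 and {b.i, b.j} <= {c, *terminal_o})
            for b in mol.bonds)
        has_charge = any(mol.atoms[o].charge < 0 for o in terminal_o)
        if has_double and has_charge:
            out.update(o for o in terminal_o if mol.total_h(o) == 0)
    return out


def _guanidinium_carbons(mol: Molecule) -> set[int]:
    """Carbons of guanidinium/amidinium groups (C bonded to ≥2 N, one by a
    double bond, with a positive formal charge somewhere in the group)."""
    out: set[int] = set()
    for c, a in enumerate(mol.atoms):
        if a.element != "C":
            continue
        nbr_n = [n for n in mol.neighbors(c) if mol.atoms[n].element == "N"]
        if len(nbr_n) < 2:
            continue
        dbl = any(b.order == 2 and {b.i, b.j} <= {c, *nbr_n} for b in mol.bonds)
        charged = a.charge > 0 or any(mol.atoms[n].charge > 0 for n in nbr_n)
        if dbl and charged:
            out.add(c)
    return out


def perceive_features(mol: Molecule, as_protein: bool = False) -> FeatureSet:
    """Build the uniform feature structure from a molecule with coordinates.

    Element rules: donor = N/O/S with ≥1 H; acceptor = N/O with an available
    lone pair; hydrophobe = uncharged C or S with no N/O/charged neighbor;
    halogen feature = F/Cl/Br/I bonded to carbon; ring features for aromatic
    rings only. In protein mode, standard residues additionally type their
    ionizable side chains by atom name (Arg CZ/Lys NZ cation, Asp/Glu
    carboxylate O anion, His ND1/NE2 both donor and acceptor); unknown
    residues fall back to the element rules.
    """
    if not mol.has_coords():
        raise GeometryError("feature perception requires coordinates")
    from .molio import perceive_rings  # local import to avoid cycle at module load

    fs = FeatureSet(molecule=mol)
    sites = mol.sites if isinstance(mol, ProteinStructure) else None
    metal_set = set(mol.metals) if isinstance(mol, ProteinStructure) else {
        i for i, a in enumerate(mol.atoms) if a.element in METALS}
    fs.metals = sorted(metal_set)

    anion_oxy = _group_anion_oxygens(mol)
    guanidinium = _guanidinium_carbons(mol)

    cations: set[int] = set()
    anions: set[int] = set()

    for i, a in enumerate(mol.atoms):
        if a.element == "H" or i in metal_set:
            continue
        site = sites[i] if sites is not None else None
        res_known = (site is not None and site.residue_name in _STANDARD_RESIDUES)
        if as_protein and res_known:
            key = (site.residue_name, site.atom_name)
            if key in _PROTEIN_CATION_ATOMS:
                cations.add(i)
            if key in _PROTEIN_ANION_ATOMS:
                anions.add(i)
            if key in _HIS_AMBIG:
                h_neighbors = [n for n in mol.neighbors(i) if mol.atoms[n].element == "H"]
                fs.donors.append((i, h_neighbors))
                fs.acceptors.append(i)
                continue
        if _is_donor(mol, i):
            h_neighbors = [n for n in mol.neighbors(i) if mol.atoms[n].element == "H"]
            fs.donors.append((i, h_neighbors))
        if _is_acceptor(mol, i):
            fs.acceptors.append(i)
        if a.charge > 0 or i in guanidinium:
            cations.add(i)
        if a.charge < 0 or i in anion_oxy:
            anions.add(i)
        if a.element in ("C", "S") and a.charge == 0:
            nbrs = mol.neighbors(i)
            if not any(mol.atoms[n].element in ("N", "O") or mol.atoms[n].charge != 0
                       for n in nbrs):
                fs.hydrophobes.append(i)
        if a.element in ("F", "Cl", "Br", "I"):
            carbons = [n for n in mol.neighbors(i) if mol.atoms[n].element == "C"]
            if carbons:
                fs.halogens.append((i, carbons[0]))

    fs.cations = sorted(cations - anions)
    fs.anions = sorted(anions - cations)

    for ring in perceive_rings(mol):
        if all(mol.atoms[i].aromatic for i in ring):
            coords = np.array([mol.atoms[i].coords for i in ring])
            centroid, normal = ring_geometry(coords)
            fs.rings.append(RingFeature(atoms=list(ring), centroid=centroid, normal=normal))

    fs.validate()
    return fs
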