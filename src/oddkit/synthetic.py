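"""Synthetic fixtures with known ground truth.

Every generator is a pure function of its arguments (seed included) and
returns a manifest that fully determines the expected output of the module
under test: planted protein–ligand complexes at controlled geometry for the
interaction detectors, affinity datasets with known linear weights for the
regressors, active/decoy score sets with a closed-form AUC, and small
molecule libraries with planted rule-of-five violation counts.

Plantings use idealized fragments (fixed bond lengths, exact angles);
chemical realism is deliberately not attempted — geometric detectors care
about geometry only. Fragments are separated by ≥15 Å so plantings never
interfere, and each template is engineered so it triggers exactly its
planted interaction and no other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .molio import Atom, AtomSite, Bond, Molecule, ProteinStructure, write_sdf

__all__ = [
    "PlantManifest",
    "make_hbond_complex",
    "make_planted_complex",
    "random_interaction_spec",
    "default_contact_weights",
    "make_affinity_dataset",
    "make_screening_set",
    "make_library",
    "make_quinone",
    "make_catechol",
    "random_rotation",
    "PLANT_PRESETS",
]

_SITE_SPACING = 20.0  # Å between planted fragments (spec floor: 15)
_OH_LEN = 0.96
_C_CL_LEN = 1.77
_RING_R = 1.39


@dataclass
class PlantManifest:
    """Bookkeeping for a planted complex: what was placed, what must be found."""
    interactions: list[tuple[str, bool]] = field(default_factory=list)  # (kind, strict)
    expected_class: str | None = None   # single-interaction complexes: strict|crude|none
    details: dict = field(default_factory=dict)

    def expected_counts(self) -> dict[str, tuple[int, int]]:
        """kind → (crude count, strict count)."""
        out: dict[str, list[int]] = {}
        for kind, strict in self.interactions:
            c = out.setdefault(kind, [0, 0])
            c[0] += 1
            if strict:
                c[1] += 1
        return {k: (v[0], v[1]) for k, v in out.items()}


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, sign-fixed)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


# ---------------------------------------------------------------------------
# Fragment builders. Each returns (protein_atoms, protein_sites,
# protein_bonds, ligand_atoms, ligand_bonds). Coordinates are
# relative to the fragment origin.
# ---------------------------------------------------------------------------

def _site(name: str, res: str = "UNK", seq: int = 1, record: str = "ATOM") -> AtomSite:
    return AtomSite(atom_name=name, residue_name=res, residue_seq=seq, record=record,
                    chain="A")


def _solve_h_position(d: float, angle_deg: float) -> np.ndarray:
    """Place H bonded to donor D=(d,0,0) so the D–H…A angle at H (A at the
    origin) equals ``angle_deg``."""
    target = np.radians(angle_deg)

    def theta(alpha: float) -> float:
        h = np.array([d, 0.0, 0.0]) + _OH_LEN * np.array([np.cos(alpha), np.sin(alpha), 0.0])
        v1 = np.array([d, 0.0, 0.0]) - h
        v2 = -h
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        return float(np.arccos(np.clip(cosang, -1, 1)))

    if angle_deg >= 179.999:
        alpha = np.pi
    elif angle_deg <= 0.001:
        alpha = 0.0
    else:
        alpha = brentq(lambda a: theta(a) - target, 1e-9, np.pi - 1e-9)
    return np.array([d, 0.0, 0.0]) + _OH_LEN * np.array([np.cos(alpha), np.sin(alpha), 0.0])


def _frag_hbond(distance: float, angle: float):
    """Protein acceptor O at origin; ligand donor O–H at the requested
    distance, with the D–H…A angle set exactly."""
    p_atoms = [Atom("O", np.zeros(3))]
    p_sites = [_site("O1")]
    h = _solve_h_position(distance, angle)
    l_atoms = [Atom("O", np.array([distance, 0.0, 0.0])), Atom("H", h)]
    l_bonds = [Bond(0, 1)]
    return p_atoms, p_sites, [], l_atoms, l_bonds


def _frag_salt_bridge(distance: float):
    p_atoms = [Atom("N", np.zeros(3), charge=1)]
    p_sites = [_site("N1")]
    l_atoms = [Atom("O", np.array([distance, 0.0, 0.0]), charge=-1)]
    return p_atoms, p_sites, [], l_atoms, []


def _frag_hydrophobic(distance: float):
    p_atoms = [Atom("C", np.zeros(3))]
    p_sites = [_site("C1")]
    l_atoms = [Atom("C", np.array([distance, 0.0, 0.0]))]
    return p_atoms, p_sites, [], l_atoms, []


def _frag_halogen(distance: float, angle: float):
    """Protein acceptor O at origin, ligand Cl at the distance, carbon placed
    so the C–X…A angle equals ``angle``."""
    alpha = np.radians(180.0 - angle)
    x = np.array([distance, 0.0, 0.0])
    c = x + _C_CL_LEN * np.array([np.cos(alpha), np.sin(alpha), 0.0])
    p_atoms = [Atom("O", np.zeros(3))]
    p_sites = [_site("O1")]
    l_atoms = [Atom("Cl", x), Atom("C", c)]
    return p_atoms, p_sites, [], l_atoms, [Bond(0, 1)]


def _benzene_atoms(center: np.ndarray, rot: np.ndarray | None = None) -> list[Atom]:
    atoms = []
    for k in range(6):
        ang = np.pi / 3 * k
        pos = np.array([_RING_R * np.cos(ang), _RING_R * np.sin(ang), 0.0])
        if rot is not None:
            pos = rot @ pos
        atoms.append(Atom("C", center + pos, aromatic=True))
    return atoms


def _ring_bonds(offset: int) -> list[Bond]:
    return [Bond(offset + k, offset + (k + 1) % 6, aromatic=True) for k in range(6)]


def _tilt_x(angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    return np.array([[1, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]])


def _frag_pi_stack(distance: float, angle: float):
    """Protein ring in z=0; ligand ring centered ``distance`` above, tilted
    about x by ``angle``. Distances are chosen by the presets so that no
    atom pair falls within the hydrophobic cutoff."""
    p_atoms = _benzene_atoms(np.zeros(3))
    p_sites = [_site(f"C{k+1}") for k in range(6)]
    l_atoms = _benzene_atoms(np.array([0.0, 0.0, distance]), rot=_tilt_x(angle))
    return p_atoms, p_sites, _ring_bonds(0), l_atoms, _ring_bonds(0)


def _frag_pi_cation(distance: float, angle: float):
    """Protein ring; ligand cation at ``distance`` from the centroid, at
    ``angle`` off the ring normal."""
    a = np.radians(angle)
    pos = distance * np.array([np.sin(a), 0.0, np.cos(a)])
    p_atoms = _benzene_atoms(np.zeros(3))
    p_sites = [_site(f"C{k+1}") for k in range(6)]
    l_atoms = [Atom("N", pos, charge=1)]
    return p_atoms, p_sites, _ring_bonds(0), l_atoms, []


def _frag_pi_metal(distance: float, angle: float):
    """Ligand ring; protein Zn at ``distance`` from the centroid."""
    a = np.radians(angle)
    pos = distance * np.array([np.sin(a), 0.0, np.cos(a)])
    p_atoms = [Atom("Zn", pos)]
    p_sites = [_site("ZN", res="ZN", record="HETATM")]
    l_atoms = _benzene_atoms(np.zeros(3))
    return p_atoms, p_sites, [], l_atoms, _ring_bonds(0)


def _frag_metal_coordination(distance: float):
    p_atoms = [Atom("Zn", np.zeros(3))]
    p_sites = [_site("ZN", res="ZN", record="HETATM")]
    l_atoms = [Atom("O", np.array([distance, 0.0, 0.0]))]
    return p_atoms, p_sites, [], l_atoms, []


# Safe preset geometries per kind: (params tuple, strict flag). "Safe" means
# the fragment triggers only its own interaction at these values.
PLANT_PRESETS: dict[str, list[tuple[tuple, bool]]] = {
    "hbond": [((2.9, 180.0), True), ((2.5, 150.0), True), ((3.3, 100.0), False)],
    "salt_bridge": [((3.5,), True), ((3.9,), True)],
    "hydrophobic": [((3.8,), True), ((3.2,), True)],
    "halogen_bond": [((3.3, 180.0), True), ((3.5, 120.0), False)],
    "pi_stack_f2f": [((4.5, 0.0), True), ((4.6, 20.0), True), ((5.4, 40.0), False)],
    "pi_stack_e2f": [((5.2, 90.0), True), ((5.2, 70.0), True), ((5.4, 50.0), False)],
    "pi_cation": [((4.0, 0.0), True), ((4.2, 20.0), True), ((4.5, 90.0), False)],
    "pi_metal": [((3.5, 0.0), True), ((4.5, 80.0), False)],
    "metal_coordination": [((2.1,), True), ((2.8,), True)],
}

_FRAGMENT_BUILDERS = {
    "hbond": _frag_hbond,
    "salt_bridge": _frag_salt_bridge,
    "hydrophobic": _frag_hydrophobic,
    "halogen_bond": _frag_halogen,
    "pi_stack_f2f": _frag_pi_stack,
    "pi_stack_e2f": _frag_pi_stack,
    "pi_cation": _frag_pi_cation,
    "pi_metal": _frag_pi_metal,
    "metal_coordination": _frag_metal_coordination,
}


def make_hbond_complex(distance: float, angle: float):
    """Minimal donor/acceptor pair at exactly the requested geometry.

    Returns (protein, ligand, manifest); the manifest's ``expected_class``
    states whether the default criteria call this strict, crude or nothing
    (donor–acceptor distance cutoff 3.5 Å, D–H…A angle cutoff 120°).
    """
    p_atoms, p_sites, _, l_atoms, l_bonds = _frag_hbond(distance, angle)
    protein = ProteinStructure(atoms=p_atoms, sites=p_sites, name="hbond_acceptor")
    ligand = Molecule(atoms=l_atoms, bonds=l_bonds, name="hbond_donor")
    if distance <= 3.5:
        cls = "strict" if angle >= 120.0 else "crude"
    else:
        cls = "none"
    manifest = PlantManifest(
        interactions=[("hbond", cls == "strict")] if cls != "none" else [],
        expected_class=cls,
        details={"distance": distance, "angle": angle})
    return protein, ligand, manifest


def make_planted_complex(spec: list[tuple[str, tuple]], seed: int = 0,
                         n_decoys: int = 6):
    """Compose interaction fragments at requested geometries.

    ``spec`` is a list of (kind, geometry-params) pairs; geometry params are
    the per-kind preset tuples (distance[, angle]). Fragments sit ≥15 Å apart
    on a line; seeded decoy carbon atoms are scattered ≥8 Å from everything
    so they stay outside every cutoff. Returns (protein, ligand, manifest).
    """
    rng = np.random.default_rng(seed)
    p_atoms: list[Atom] = []
    p_sites: list[AtomSite] = []
    p_bonds: list[Bond] = []
    l_atoms: list[Atom] = []
    l_bonds: list[Bond] = []
    interactions: list[tuple[str, bool]] = []
    for k, (kind, params) in enumerate(spec):
        if kind not in _FRAGMENT_BUILDERS:
            raise ValueError(f"unknown interaction kind {kind!r}")
        builder = _FRAGMENT_BUILDERS[kind]
        fa, fs, pb, la, lb = builder(*params)
        offset = np.array([_SITE_SPACING * k, 0.0, 0.0])
        atom_off = len(l_atoms)
        p_atom_off = len(p_atoms)
        for a in fa:
            a.coords = a.coords + offset
        for a in la:
            a.coords = a.coords + offset
        p_atoms.extend(fa)
        p_sites.extend(fs)
        p_bonds.extend(Bond(b.i + p_atom_off, b.j + p_atom_off, b.order, b.aromatic)
                       for b in pb)
        l_atoms.extend(la)
        l_bonds.extend(Bond(b.i + atom_off, b.j + atom_off, b.order, b.aromatic)
                       for b in lb)
        strict = _preset_strict(kind, params)
        interactions.append((kind, strict))

    all_coords = [a.coords for a in p_atoms + l_atoms]
    for side in ("protein", "ligand"):
        placed = 0
        attempts = 0
        while placed < n_decoys and attempts < 1000:
            attempts += 1
            pos = rng.uniform([-15, 12, -15], [_SITE_SPACING * max(1, len(spec)), 40, 15])
            if all(np.linalg.norm(pos - c) >= 8.0 for c in all_coords):
                if side == "protein":
                    p_atoms.append(Atom("C", pos))
                    p_sites.append(_site(f"CD{placed}"))
                else:
                    l_atoms.append(Atom("C", pos))
                all_coords.append(pos)
                placed += 1

    metals = [i for i, a in enumerate(p_atoms) if a.element in ("Zn",)]
    protein = ProteinStructure(atoms=p_atoms, bonds=p_bonds, sites=p_sites,
                               metals=metals, name="planted_protein")
    ligand = Molecule(atoms=l_atoms, bonds=l_bonds, name="planted_ligand")
    manifest = PlantManifest(interactions=interactions,
                             details={"seed": seed, "spec": spec})
    return protein, ligand, manifest


def _preset_strict(kind: str, params: tuple) -> bool:
    for preset, strict in PLANT_PRESETS[kind]:
        if preset == tuple(params):
            return strict
    # not a preset: derive from the default criteria for the simple kinds
    if kind == "hbond":
        return params[1] >= 120.0
    if kind == "halogen_bond":
        return params[1] >= 150.0
    if kind in ("pi_cation", "pi_metal"):
        return params[1] <= 30.0
    if kind == "pi_stack_f2f":
        return params[1] <= 30.0
    if kind == "pi_stack_e2f":
        return 60.0 <= params[1] <= 90.0
    return True


def random_interaction_spec(rng: np.random.Generator, n: int,
                            kinds: tuple[str, ...] = tuple(PLANT_PRESETS)) -> list:
    """Sample n plantings from the safe preset table."""
    out = []
    for _ in range(n):
        kind = kinds[rng.integers(len(kinds))]
        presets = PLANT_PRESETS[kind]
        params, _ = presets[rng.integers(len(presets))]
        out.append((kind, params))
    return out


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------

def default_contact_weights(seed: int, n_features: int = 36,
                            n_dominant: int = 4) -> np.ndarray:
    """A realistic ground-truth weight vector for contact-count affinities.

    A handful of contact types dominate binding affinity (as element-pair
    importance analyses of contact-count scoring functions consistently
    find), so the vector has ``n_dominant`` weights of magnitude 0.4–1.0 on
    randomly chosen pairs and a small ±0.05 background on the rest.
    """
    rng = np.random.default_rng(seed)
    w = rng.uniform(-0.05, 0.05, n_features)
    big = rng.choice(n_features, n_dominant, replace=False)
    w[big] = rng.uniform(0.4, 1.0, n_dominant) * rng.choice([-1, 1], n_dominant)
    return w


def make_affinity_dataset(n: int, w: np.ndarray, sigma: float, seed: int):
    """Contact-count design matrix with known linear weights.

    X is Poisson(20) counts (the scale of real close-contact descriptors),
    y = X·w + N(0, σ). Returns (X, y, manifest).
    """
    w = np.asarray(w, dtype=float)
    rng = np.random.default_rng(seed)
    X = rng.poisson(20.0, size=(n, len(w))).astype(float)
    noise = rng.normal(0.0, sigma, size=n) if sigma > 0 else np.zeros(n)
    y = X @ w + noise
    manifest = {"w": w.copy(), "sigma": sigma, "seed": seed, "n": n}
    return X, y, manifest


def make_screening_set(n_act: int, n_dec: int, delta: float, seed: int):
    """Active scores ~ N(delta, 1), decoys ~ N(0, 1).

    The population ROC AUC is Φ(delta/√2) in closed form, which acceptance
    tests recover from the sample.
    """
    rng = np.random.default_rng(seed)
    scores = np.concatenate([rng.normal(delta, 1.0, n_act),
                             rng.normal(0.0, 1.0, n_dec)])
    labels = np.concatenate([np.ones(n_act, dtype=int), np.zeros(n_dec, dtype=int)])
    return scores, labels


# ---------------------------------------------------------------------------
# Libraries with planted rule violations
# ---------------------------------------------------------------------------

def _alkane(n_c: int, name: str) -> Molecule:
    atoms = [Atom("C", np.zeros(3), implicit_h=(3 if k in (0, n_c - 1) else 2))
             for k in range(n_c)]
    if n_c == 1:
        atoms[0].implicit_h = 4
    bonds = [Bond(k, k + 1) for k in range(n_c - 1)]
    return Molecule(atoms=atoms, bonds=bonds, name=name)


def _polyol(n_c: int, n_oh: int, name: str) -> Molecule:
    """Linear carbon chain with one OH on each of the first n_oh carbons."""
    assert n_oh <= n_c
    atoms = []
    bonds = []
    for k in range(n_c):
        has_oh = k < n_oh
        base_h = 3 if k in (0, n_c - 1) else 2
        atoms.append(Atom("C", np.zeros(3), implicit_h=base_h - (1 if has_oh else 0)))
        if k > 0:
            bonds.append(Bond(k - 1, k))
    for k in range(n_oh):
        atoms.append(Atom("O", np.zeros(3), implicit_h=1))
        bonds.append(Bond(k, n_c + len([a for a in atoms if a.element == "O"]) - 1))
    return Molecule(atoms=atoms, bonds=bonds, name=name)


def make_library(n: int, violation_plan: dict[int, int] | list[int], seed: int):
    """A small-molecule library with planted RO5 violation counts.

    ``violation_plan`` maps violation count (0, 1, 2) to a number of
    molecules, or lists a count per molecule. 0 → short alkane (compliant);
    1 → hexaol (6 H-bond donors); 2 → undecaol (11 donors and 11 acceptors).
    Returns (sdf_text, manifest); the manifest records each molecule's
    planted violation count and expected RO5 verdict (pass while violations
    ≤ 1, Lipinski's allowance).
    """
    if isinstance(violation_plan, dict):
        plan = []
        for v in sorted(violation_plan):
            plan.extend([v] * violation_plan[v])
    else:
        plan = list(violation_plan)
    if len(plan) != n:
        raise ValueError(f"violation plan covers {len(plan)} molecules, expected {n}")
    rng = np.random.default_rng(seed)
    mols = []
    manifest = []
    for k, v in enumerate(plan):
        if v == 0:
            mol = _alkane(int(rng.integers(3, 9)), f"mol_{k}_v0")
        elif v == 1:
            mol = _polyol(6, 6, f"mol_{k}_v1")
        elif v == 2:
            mol = _polyol(11, 11, f"mol_{k}_v2")
        else:
            raise ValueError("violation counts above 2 are not templated")
        mol.properties["planted_violations"] = str(v)
        mols.append(mol)
        manifest.append({"name": mol.name, "violations": v, "ro5_pass": v <= 1})
    return write_sdf(mols), manifest


def make_quinone() -> Molecule:
    """Para-quinone (cyclohexadiene-1,4-dione): the planted PAINS positive."""
    atoms = [Atom("C", np.zeros(3)) for _ in range(6)] + [
        Atom("O", np.zeros(3)), Atom("O", np.zeros(3))]
    for k in (1, 2, 4, 5):
        atoms[k].implicit_h = 1
    bonds = [Bond(0, 1, 1), Bond(1, 2, 2), Bond(2, 3, 1), Bond(3, 4, 1),
             Bond(4, 5, 2), Bond(5, 0, 1), Bond(0, 6, 2), Bond(3, 7, 2)]
    return Molecule(atoms=atoms, bonds=bonds, name="para_quinone")


def make_catechol() -> Molecule:
    """Benzene-1,2-diol: the planted catechol PAINS positive."""
    atoms = [Atom("C", np.zeros(3), aromatic=True) for _ in range(6)] + [
        Atom("O", np.zeros(3), implicit_h=1), Atom("O", np.zeros(3), implicit_h=1)]
    for k in (2, 3, 4, 5):
        atoms[k].implicit_h = 1
    bonds = [Bond(k, (k + 1) % 6, 1, aromatic=True) for k in range(6)]
    bonds += [Bond(0, 6, 1), Bond(1, 7, 1)]
    return Molecule(atoms=atoms, bonds=bonds, name="catechol")
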