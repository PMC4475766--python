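"""Molecular properties and rule-based library filtering.

Six properties are computed (MW, a reduced atomic-contribution logP, H-bond
donors/acceptors, rotatable bonds, heavy atoms) and fed to rule sets such as
Lipinski's Rule of Five (one violation allowed, his original formulation) or
the Rule of Three (none allowed). A small graph-pattern engine provides
substructure matching for a representative subset of the PAINS
(pan-assay interference) catalogue.

The logP model is a deliberately reduced, fully documented contribution
table; it is the definitional property used by the filters, not a calibrated
literature logP estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
from networkx.algorithms import isomorphism

from .errors import ConfigError
from .molio import ATOMIC_WEIGHTS, Molecule
from .perception import count_acceptors, count_donors

__all__ = [
    "PropertyRecord",
    "RuleSet",
    "GraphPattern",
    "PatternAtom",
    "PatternBond",
    "compute_properties",
    "apply_rule_filter",
    "match_substructure",
    "pains_filter",
    "RO5",
    "RO3",
    "PAINS_PATTERNS",
]

# Reduced Crippen-style atomic logP contributions (documented model).
LOGP_CONTRIB = {
    "C_aromatic": 0.29, "C": 0.14, "N": -0.60, "O": -0.40, "S": 0.26,
    "F": 0.22, "Cl": 0.65, "Br": 0.86, "I": 1.12,
    "H_polar": 0.0, "H_on_C": 0.12,
}


@dataclass
class PropertyRecord:
    mw: float
    logp: float
    hbd: int
    hba: int
    rotatable: int
    heavy_atoms: int

    def get(self, name: str) -> float:
        if not hasattr(self, name):
            raise ConfigError(f"unknown property {name!r}")
        return getattr(self, name)


@dataclass
class RuleSet:
    name: str
    rules: list[tuple[str, str, float]]  # (property, "<=" or ">=", threshold)
    max_violations: int = 0

    def __post_init__(self):
        for prop, cmp_, thr in self.rules:
            if cmp_ not in ("<=", ">="):
                raise ConfigError(f"comparator {cmp_!r} must be '<=' or '>='")
            if not (thr == thr and abs(thr) != float("inf")):
                raise ConfigError("rule thresholds must be finite")
            if prop not in PropertyRecord.__dataclass_fields__:
                raise ConfigError(f"unknown property {prop!r} in rule set {self.name!r}")


RO5 = RuleSet("RO5", [("mw", "<=", 500), ("logp", "<=", 5),
                      ("hbd", "<=", 5), ("hba", "<=", 10)], max_violations=1)
RO3 = RuleSet("RO3", [("mw", "<=", 300), ("logp", "<=", 3), ("hbd", "<=", 3),
                      ("hba", "<=", 3), ("rotatable", "<=", 3)], max_violations=0)


def _is_amide_cn(mol: Molecule, i: int, j: int) -> bool:
    for c, n in ((i, j), (j, i)):
        if mol.atoms[c].element == "C" and mol.atoms[n].element == "N":
            for b in mol.bonds:
                if b.order == 2 and c in (b.i, b.j):
                    other = b.j if b.i == c else b.i
                    if mol.atoms[other].element == "O":
                        return True
    return False


def compute_properties(mol: Molecule) -> PropertyRecord:
    """Property record for a molecule with implicit H counts assigned."""
    mw = 0.0
    logp = 0.0
    for i, a in enumerate(mol.atoms):
        if a.element not in ATOMIC_WEIGHTS:
            raise ConfigError(f"no atomic weight for element {a.element!r}")
        mw += ATOMIC_WEIGHTS[a.element]
        if a.element == "H":
            nb = mol.neighbors(i)
            logp += LOGP_CONTRIB["H_on_C"] if any(
                mol.atoms[n].element == "C" for n in nb) else LOGP_CONTRIB["H_polar"]
            continue
        mw += a.implicit_h * ATOMIC_WEIGHTS["H"]
        if a.element == "C":
            logp += LOGP_CONTRIB["C_aromatic"] if a.aromatic else LOGP_CONTRIB["C"]
            logp += a.implicit_h * LOGP_CONTRIB["H_on_C"]
        else:
            logp += LOGP_CONTRIB.get(a.element, 0.0)
            logp += a.implicit_h * LOGP_CONTRIB["H_polar"]

    ring_bonds = set()
    g = mol.graph()
    for cyc in nx.cycle_basis(g):
        for a_, b_ in zip(cyc, cyc[1:] + cyc[:1]):
            ring_bonds.add((min(a_, b_), max(a_, b_)))
    rotatable = 0
    for b in mol.bonds:
        if b.order != 1 or b.aromatic or b.key() in ring_bonds:
            continue
        ai, aj = mol.atoms[b.i], mol.atoms[b.j]
        if ai.element == "H" or aj.element == "H":
            continue
        deg_i = sum(1 for n in mol.neighbors(b.i) if mol.atoms[n].element != "H")
        deg_j = sum(1 for n in mol.neighbors(b.j) if mol.atoms[n].element != "H")
        if deg_i >= 2 and deg_j >= 2 and not _is_amide_cn(mol, b.i, b.j):
            rotatable += 1

    return PropertyRecord(
        mw=mw, logp=round(logp, 6),
        hbd=count_donors(mol), hba=count_acceptors(mol),
        rotatable=rotatable, heavy_atoms=len(mol.heavy_indices()))


def apply_rule_filter(mol: Molecule, rules: RuleSet) -> tuple[bool, list[str]]:
    """Evaluate a rule set; pass iff violations ≤ the set's allowance."""
    props = compute_properties(mol)
    violations = []
    for prop, cmp_, thr in rules.rules:
        val = props.get(prop)
        ok = val <= thr if cmp_ == "<=" else val >= thr
        if not ok:
            violations.append(f"{prop} {val:g} violates {prop} {cmp_} {thr:g}")
    return len(violations) <= rules.max_violations, violations


# ---------------------------------------------------------------------------
# Graph-pattern substructure matching
# ---------------------------------------------------------------------------

@dataclass
class PatternAtom:
    element: str | None = None      # None = wildcard
    aromatic: bool | None = None    # None = either
    min_degree: int = 0


@dataclass
class PatternBond:
    i: int
    j: int
    order: int | None = None        # None = any; 4 = aromatic


@dataclass
class GraphPattern:
    name: str
    atoms: list[PatternAtom]
    bonds: list[PatternBond]

    def __post_init__(self):
        g = nx.Graph()
        g.add_nodes_from(range(len(self.atoms)))
        g.add_edges_from((b.i, b.j) for b in self.bonds)
        if len(self.atoms) and not nx.is_connected(g):
            raise ConfigError(f"pattern {self.name!r} is not connected")


def match_substructure(mol: Molecule, pattern: GraphPattern) -> list[dict[int, int]]:
    """All embeddings of the pattern into the molecule graph.

    Returns pattern-atom → molecule-atom mappings for every subgraph
    monomorphism satisfying the element/aromatic/degree/bond constraints.
    Symmetry-equivalent embeddings are retained; order is deterministic
    (sorted by the mapped atom tuple).
    """
    gm = nx.Graph()
    for i, a in enumerate(mol.atoms):
        gm.add_node(i, element=a.element, aromatic=a.aromatic, degree=mol.degree(i))
    for b in mol.bonds:
        gm.add_edge(b.i, b.j, order=4 if b.aromatic else b.order)
    gp = nx.Graph()
    for i, pa in enumerate(pattern.atoms):
        gp.add_node(i, element=pa.element, aromatic=pa.aromatic, min_degree=pa.min_degree)
    for pb in pattern.bonds:
        gp.add_edge(pb.i, pb.j, order=pb.order)

    def node_match(mol_attrs, pat_attrs):
        if pat_attrs["element"] is not None and mol_attrs["element"] != pat_attrs["element"]:
            return False
        if pat_attrs["aromatic"] is not None and mol_attrs["aromatic"] != pat_attrs["aromatic"]:
            return False
        return mol_attrs["degree"] >= pat_attrs["min_degree"]

    def edge_match(mol_attrs, pat_attrs):
        return pat_attrs["order"] is None or mol_attrs["order"] == pat_attrs["order"]

    matcher = isomorphism.GraphMatcher(gm, gp, node_match=node_match,
                                       edge_match=edge_match)
    mappings = []
    for m in matcher.subgraph_monomorphisms_iter():
        mappings.append({p: g for g, p in m.items()})
    mappings.sort(key=lambda mp: tuple(mp[k] for k in sorted(mp)))
    return mappings


def _build_pains_patterns() -> list[GraphPattern]:
    pats = []

    # para-quinone: cyclohexadiene-1,4-dione
    atoms = [PatternAtom("C", False) for _ in range(6)] + [PatternAtom("O", False),
                                                           PatternAtom("O", False)]
    bonds = [PatternBond(0, 1, 1), PatternBond(1, 2, 2), PatternBond(2, 3, 1),
             PatternBond(3, 4, 1), PatternBond(4, 5, 2), PatternBond(5, 0, 1),
             PatternBond(0, 6, 2), PatternBond(3, 7, 2)]
    pats.append(GraphPattern("quinone_A", atoms, bonds))

    # ortho-quinone
    atoms = [PatternAtom("C", False) for _ in range(6)] + [PatternAtom("O", False),
                                                           PatternAtom("O", False)]
    bonds = [PatternBond(0, 1, 1), PatternBond(1, 2, 1), PatternBond(2, 3, 2),
             PatternBond(3, 4, 1), PatternBond(4, 5, 2), PatternBond(5, 0, 1),
             PatternBond(0, 6, 2), PatternBond(1, 7, 2)]
    pats.append(GraphPattern("quinone_B", atoms, bonds))

    # catechol: aromatic ring with two adjacent OH oxygens
    atoms = [PatternAtom("C", True) for _ in range(6)] + [PatternAtom("O", False),
                                                          PatternAtom("O", False)]
    bonds = [PatternBond(k, (k + 1) % 6, 4) for k in range(6)]
    bonds += [PatternBond(0, 6, 1), PatternBond(1, 7, 1)]
    pats.append(GraphPattern("catechol_A", atoms, bonds))

    # rhodanine core: S-C(=S)-N in a 5-ring with a carbonyl
    atoms = [PatternAtom("S", None), PatternAtom("C", None), PatternAtom("N", None),
             PatternAtom("C", None), PatternAtom("C", None), PatternAtom("S", False),
             PatternAtom("O", False)]
    bonds = [PatternBond(0, 1, None), PatternBond(1, 2, None), PatternBond(2, 3, None),
             PatternBond(3, 4, None), PatternBond(4, 0, None), PatternBond(1, 5, 2),
             PatternBond(3, 6, 2)]
    pats.append(GraphPattern("rhodanine_A", atoms, bonds))

    # enone: C=C-C=O conjugated acceptor
    atoms = [PatternAtom("C", False, 1), PatternAtom("C", False),
             PatternAtom("C", False), PatternAtom("O", False)]
    bonds = [PatternBond(0, 1, 2), PatternBond(1, 2, 1), PatternBond(2, 3, 2)]
    pats.append(GraphPattern("ene_one_A", atoms, bonds))

    # azo: C-N=N-C
    atoms = [PatternAtom("C", None), PatternAtom("N", False),
             PatternAtom("N", False), PatternAtom("C", None)]
    bonds = [PatternBond(0, 1, 1), PatternBond(1, 2, 2), PatternBond(2, 3, 1)]
    pats.append(GraphPattern("azo_A", atoms, bonds))

    # hydroxyphenyl hydrazone: aromatic C-C=N-N
    atoms = [PatternAtom("C", True), PatternAtom("C", False),
             PatternAtom("N", False), PatternAtom("N", False)]
    bonds = [PatternBond(0, 1, 1), PatternBond(1, 2, 2), PatternBond(2, 3, 1)]
    pats.append(GraphPattern("hzone_phenol_A", atoms, bonds))

    # thiocarbonyl flanked by two N (thiourea-like)
    atoms = [PatternAtom("N", None), PatternAtom("C", False),
             PatternAtom("N", None), PatternAtom("S", False)]
    bonds = [PatternBond(0, 1, 1), PatternBond(1, 2, 1), PatternBond(1, 3, 2)]
    pats.append(GraphPattern("thiourea_A", atoms, bonds))

    # nitro on aromatic carbon (frequent assay interferer in this reduced set)
    atoms = [PatternAtom("C", True), PatternAtom("N", False),
             PatternAtom("O", False), PatternAtom("O", False)]
    bonds = [PatternBond(0, 1, 1), PatternBond(1, 2, 2), PatternBond(1, 3, 1)]
    pats.append(GraphPattern("aryl_nitro_A", atoms, bonds))

    # Michael-acceptor acrylamide-like: C=C-C(=O)-N
    atoms = [PatternAtom("C", False, 1), PatternAtom("C", False),
             PatternAtom("C", False), PatternAtom("O", False), PatternAtom("N", False)]
    bonds = [PatternBond(0, 1, 2), PatternBond(1, 2, 1), PatternBond(2, 3, 2),
             PatternBond(2, 4, 1)]
    pats.append(GraphPattern("acrylamide_A", atoms, bonds))

    # imine of an aldehyde: C=N-N=C (bis-hydrazone)
    atoms = [PatternAtom("C", False), PatternAtom("N", False),
             PatternAtom("N", False), PatternAtom("C", False)]
    bonds = [PatternBond(0, 1, 2), PatternBond(1, 2, 1), PatternBond(2, 3, 2)]
    pats.append(GraphPattern("bis_hzone_A", atoms, bonds))

    return pats


PAINS_PATTERNS: list[GraphPattern] = _build_pains_patterns()


def pains_filter(mol: Molecule) -> tuple[bool, list[str]]:
    """Screen against the shipped PAINS subset; clean iff no pattern matches."""
    hits = [p.name for p in PAINS_PATTERNS if match_substructure(mol, p)]
    return len(hits) == 0, hits
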