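"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain loops over all pairs, with its own angle
and geometry arithmetic (math module, no numpy vector tricks), so that
agreement with the package is a genuine two-route check. Oracles share only
*definitional* constants with the implementation (the covalent-radii table,
the cutoff values inside GeometricCriteria) — the algorithms are separate.
"""

from __future__ import annotations

import math
from itertools import combinations

from oddkit.interactions import GeometricCriteria
from oddkit.molio import BOND_SLACK, COVALENT_RADII, METALS


def _dist(a, b) -> float:
    return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))


def _angle_deg(a, vertex, c) -> float:
    v1 = [x - y for x, y in zip(a, vertex)]
    v2 = [x - y for x, y in zip(c, vertex)]
    n1 = math.sqrt(sum(x * x for x in v1))
    n2 = math.sqrt(sum(x * x for x in v2))
    if n1 == 0 or n2 == 0:
        return 0.0
    cosv = sum(x * y for x, y in zip(v1, v2)) / (n1 * n2)
    return math.degrees(math.acos(max(-1.0, min(1.0, cosv))))


def _axis_angle_deg(normal, vec) -> float:
    nv = math.sqrt(sum(x * x for x in vec))
    if nv == 0:
        return 0.0
    cosv = abs(sum(a * b for a, b in zip(normal, vec))) / nv
    return math.degrees(math.acos(max(0.0, min(1.0, cosv))))


def brute_infer_bonds(atoms) -> set[tuple[int, int]]:
    """O(n^2) pair check against the covalent-radius rule."""
    out = set()
    for i, j in combinations(range(len(atoms)), 2):
        ai, aj = atoms[i], atoms[j]
        if ai.coords is None or aj.coords is None:
            continue
        if ai.element in METALS or aj.element in METALS:
            continue
        ri = COVALENT_RADII.get(ai.element, 0.0)
        rj = COVALENT_RADII.get(aj.element, 0.0)
        if ri == 0.0 or rj == 0.0:
            continue
        if _dist(ai.coords, aj.coords) <= ri + rj + BOND_SLACK:
            out.add((i, j))
    return out


# ---------------------------------------------------------------------------
# Interaction-detector oracles: each returns a set of hashable record tuples
# (kind, protein participant, ligand participant, strict) for exact
# comparison with the package's detectors.
# ---------------------------------------------------------------------------

def _rec(kind, p, l, strict):
    return (kind, p, l, bool(strict))


def oracle_hbonds(pf, lf, crit: GeometricCriteria) -> set:
    out = set()
    for donor_fs, acceptor_fs, donor_is_protein in ((pf, lf, True), (lf, pf, False)):
        dmol = donor_fs.molecule
        for d_idx, h_list in donor_fs.donors:
            d = dmol.atoms[d_idx].coords
            for a_idx in acceptor_fs.acceptors:
                a = acceptor_fs.molecule.atoms[a_idx].coords
                dist = _dist(d, a)
                if not 0 < dist <= crit.hbond_dist:
                    continue
                if h_list:
                    strict = any(
                        _angle_deg(d, dmol.atoms[h].coords, a) >= crit.hbond_dha_min
                        for h in h_list)
                else:
                    heavies = [x for x in dmol.neighbors(d_idx)
                               if dmol.atoms[x].element != "H"]
                    strict = all(
                        _angle_deg(dmol.atoms[x].coords, d, a) >= crit.hbond_xda_min
                        for x in heavies)
                p, l = (d_idx, a_idx) if donor_is_protein else (a_idx, d_idx)
                out.add(_rec("hbond", p, l, strict))
    return out


def oracle_salt_bridges(pf, lf, crit) -> set:
    out = set()
    for p_items, l_items in ((pf.cations, lf.anions), (pf.anions, lf.cations)):
        for p in p_items:
            for l in l_items:
                d = _dist(pf.molecule.atoms[p].coords, lf.molecule.atoms[l].coords)
                if 0 < d <= crit.salt_bridge_dist:
                    out.add(_rec("salt_bridge", p, l, True))
    return out


def oracle_hydrophobic(pf, lf, crit) -> set:
    out = set()
    for p in pf.hydrophobes:
        for l in lf.hydrophobes:
            d = _dist(pf.molecule.atoms[p].coords, lf.molecule.atoms[l].coords)
            if 0 < d <= crit.hydrophobic_dist:
                out.add(_rec("hydrophobic", p, l, True))
    return out


def oracle_halogen_bonds(pf, lf, crit) -> set:
    out = set()
    for x_idx, c_idx in lf.halogens:
        x = lf.molecule.atoms[x_idx].coords
        c = lf.molecule.atoms[c_idx].coords
        for a_idx in pf.acceptors:
            a = pf.molecule.atoms[a_idx].coords
            d = _dist(x, a)
            if 0 < d <= crit.halogen_dist:
                strict = _angle_deg(c, x, a) >= crit.halogen_cxa_min
                out.add(_rec("halogen_bond", a_idx, x_idx, strict))
    return out


def oracle_pi_stacking(pf, lf, crit) -> set:
    out = set()
    for p_id, pr in enumerate(pf.rings):
        for l_id, lr in enumerate(lf.rings):
            d = _dist(pr.centroid, lr.centroid)
            if not 0 < d <= crit.pi_stack_dist:
                continue
            ang = _axis_angle_deg(pr.normal, lr.normal)
            if ang <= crit.pi_f2f_max:
                out.add(_rec("pi_stack_f2f", p_id, l_id, True))
            elif crit.pi_e2f_min <= ang <= crit.pi_e2f_max:
                out.add(_rec("pi_stack_e2f", p_id, l_id, True))
            else:
                mid = (crit.pi_f2f_max + crit.pi_e2f_min) / 2
                kind = "pi_stack_f2f" if ang < mid else "pi_stack_e2f"
                out.add(_rec(kind, p_id, l_id, False))
    return out


def oracle_pi_cation(pf, lf, crit) -> set:
    out = set()
    for ring_fs, cat_fs, ring_is_protein in ((pf, lf, True), (lf, pf, False)):
        for r_id, ring in enumerate(ring_fs.rings):
            for c_idx in cat_fs.cations:
                c = cat_fs.molecule.atoms[c_idx].coords
                vec = [a - b for a, b in zip(c, ring.centroid)]
                d = math.sqrt(sum(x * x for x in vec))
                if not 0 < d <= crit.pi_cation_dist:
                    continue
                strict = _axis_angle_deg(ring.normal, vec) <= crit.pi_cation_angle_max
                p, l = (r_id, c_idx) if ring_is_protein else (c_idx, r_id)
                out.add(_rec("pi_cation", p, l, strict))
    return out


def oracle_metal(pf, lf, crit) -> set:
    out = set()
    for metal_fs, other_fs, metal_is_protein in ((pf, lf, True), (lf, pf, False)):
        omol = other_fs.molecule
        coord_atoms = sorted(set(other_fs.acceptors)
                             | {i for i, a in enumerate(omol.atoms) if a.element == "S"})
        for m_idx in metal_fs.metals:
            m = metal_fs.molecule.atoms[m_idx].coords
            for a_idx in coord_atoms:
                d = _dist(m, omol.atoms[a_idx].coords)
                if 0 < d <= crit.metal_coord_dist:
                    p, l = (m_idx, a_idx) if metal_is_protein else (a_idx, m_idx)
                    out.add(_rec("metal_coordination", p, l, True))
            for r_id, ring in enumerate(other_fs.rings):
                vec = [a - b for a, b in zip(m, ring.centroid)]
                d = math.sqrt(sum(x * x for x in vec))
                if not 0 < d <= crit.pi_metal_dist:
                    continue
                strict = _axis_angle_deg(ring.normal, vec) <= crit.pi_metal_angle_max
                p, l = (m_idx, r_id) if metal_is_protein else (r_id, m_idx)
                out.add(_rec("pi_metal", p, l, strict))
    return out


def oracle_all(pf, lf, crit: GeometricCriteria | None = None) -> set:
    crit = crit or GeometricCriteria()
    out = set()
    for fn in (oracle_hbonds, oracle_salt_bridges, oracle_hydrophobic,
               oracle_halogen_bonds, oracle_pi_stacking, oracle_pi_cation,
               oracle_metal):
        out |= fn(pf, lf, crit)
    return out


def records_as_set(records) -> set:
    return {_rec(r.kind, r.protein, r.ligand, r.strict) for r in records}


# ---------------------------------------------------------------------------
# Other oracles
# ---------------------------------------------------------------------------

def brute_roc_auc(scores, labels) -> float:
    """Pairwise P(s+ > s-) + 0.5 P(tie), by explicit double loop."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_rfscore_counts(protein, ligand, cutoff, lig_elements, pro_elements):
    """Explicit double loop over typed atom pairs."""
    counts = {(le, pe): 0 for le in lig_elements for pe in pro_elements}
    for la in ligand.atoms:
        if la.element not in lig_elements:
            continue
        for pa in protein.atoms:
            if pa.element not in pro_elements:
                continue
            if _dist(la.coords, pa.coords) <= cutoff:
                counts[(la.element, pa.element)] += 1
    return [counts[(le, pe)] for le in lig_elements for pe in pro_elements]


def brute_match_substructure(mol, pattern) -> set[tuple[int, ...]]:
    """Recursive embedding enumeration with backtracking."""
    n_pat = len(pattern.atoms)
    pat_adj: dict[int, dict[int, int | None]] = {i: {} for i in range(n_pat)}
    for b in pattern.bonds:
        pat_adj[b.i][b.j] = b.order
        pat_adj[b.j][b.i] = b.order
    mol_adj: dict[int, dict[int, int]] = {i: {} for i in range(mol.n_atoms())}
    for b in mol.bonds:
        order = 4 if b.aromatic else b.order
        mol_adj[b.i][b.j] = order
        mol_adj[b.j][b.i] = order

    def atom_ok(p, g):
        pa = pattern.atoms[p]
        ga = mol.atoms[g]
        if pa.element is not None and ga.element != pa.element:
            return False
        if pa.aromatic is not None and ga.aromatic != pa.aromatic:
            return False
        return len(mol_adj[g]) >= pa.min_degree

    results: set[tuple[int, ...]] = set()

    def extend(mapping: dict[int, int]):
        if len(mapping) == n_pat:
            results.add(tuple(mapping[i] for i in range(n_pat)))
            return
        # next pattern atom adjacent to the mapped region (pattern connected)
        nxt = next(i for i in range(n_pat)
                   if i not in mapping and any(j in mapping for j in pat_adj[i]))
        for g in range(mol.n_atoms()):
            if g in mapping.values() or not atom_ok(nxt, g):
                continue
            ok = True
            for pj, order in pat_adj[nxt].items():
                if pj in mapping:
                    gj = mapping[pj]
                    if gj not in mol_adj[g]:
                        ok = False
                        break
                    if order is not None and mol_adj[g][gj] != order:
                        ok = False
                        break
            if ok:
                mapping[nxt] = g
                extend(mapping)
                del mapping[nxt]

    for g0 in range(mol.n_atoms()):
        if atom_ok(0, g0):
            extend({0: g0})
    return results


def brute_simple_paths(mol, maxlen: int) -> set[tuple]:
    """All canonical path labels via exhaustive DFS (mirror of the contract,
    written against raw bond lists)."""
    heavy = [i for i, a in enumerate(mol.atoms) if a.element != "H"]
    adj = {i: {} for i in heavy}
    for b in mol.bonds:
        if b.i in adj and b.j in adj:
            order = 4 if b.aromatic else b.order
            adj[b.i][b.j] = order
            adj[b.j][b.i] = order
    from oddkit.descriptors import _ELEMENT_CODES

    def code(i):
        a = mol.atoms[i]
        return (_ELEMENT_CODES.get(a.element, 0), int(a.aromatic))

    labels = set()

    def walk(path):
        lab = []
        for k, i in enumerate(path):
            if k:
                lab.append(100 + adj[path[k - 1]][i])
            lab.extend(code(i))
        labels.add(min(tuple(lab), tuple(reversed(lab))))
        if len(path) < maxlen:
            for j in adj[path[-1]]:
                if j not in path:
                    walk(path + [j])

    for i in heavy:
        walk([i])
    return labels


def enumerate_all_cycles(mol) -> list[int]:
    """Sizes of every simple cycle in the molecular graph (exhaustive DFS)."""
    adj = {i: set() for i in range(mol.n_atoms())}
    for b in mol.bonds:
        adj[b.i].add(b.j)
        adj[b.j].add(b.i)
    cycles = set()

    def walk(start, path):
        cur = path[-1]
        for nxt in adj[cur]:
            if nxt == start and len(path) >= 3:
                cycles.add(frozenset(path))
            elif nxt not in path and nxt > start:
                walk(start, path + [nxt])

    for s in range(mol.n_atoms()):
        walk(s, [s])
    return sorted(len(c) for c in cycles)
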