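"""Protein–ligand interaction detection.

Eight interaction types are detected between two :class:`FeatureSet` objects:
hydrogen bonds, salt bridges, hydrophobic contacts, halogen bonds,
pi-stacking (face-to-face and edge-to-face), pi-cation, pi-metal and metal
coordination. Directional interactions carry a *strict* flag — the angle
criteria pass — next to the *crude* distance-only criterion; a strict record
always also satisfies the crude test.

All numeric cutoffs live in :class:`GeometricCriteria`; they are literature-
consistent defaults, user-overridable per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .descriptors import DescriptorVector
from .perception import FeatureSet

__all__ = [
    "GeometricCriteria",
    "InteractionRecord",
    "KINDS",
    "detect_hbonds",
    "detect_salt_bridges",
    "detect_hydrophobic",
    "detect_halogen_bonds",
    "detect_pi_stacking",
    "detect_pi_cation",
    "detect_metal_interactions",
    "detect_all",
    "interaction_profile",
    "PROFILE_NAMES",
]

KINDS = (
    "hbond", "salt_bridge", "hydrophobic", "halogen_bond",
    "pi_stack_f2f", "pi_stack_e2f", "pi_cation", "pi_metal",
    "metal_coordination",
)

PROFILE_NAMES = tuple(f"{k}_{term}" for k in KINDS for term in ("crude", "strict"))


@dataclass(frozen=True)
class GeometricCriteria:
    hbond_dist: float = 3.5            # donor–acceptor heavy-atom distance, Å
    hbond_dha_min: float = 120.0       # D–H…A angle with explicit H, degrees
    hbond_xda_min: float = 90.0        # X–D…A angle fallback (implicit H)
    salt_bridge_dist: float = 4.0
    hydrophobic_dist: float = 4.0
    halogen_dist: float = 4.0
    halogen_cxa_min: float = 150.0     # C–X…A angle
    pi_stack_dist: float = 5.5         # centroid–centroid
    pi_f2f_max: float = 30.0           # inter-normal angle, face-to-face
    pi_e2f_min: float = 60.0           # inter-normal window, edge-to-face
    pi_e2f_max: float = 90.0
    pi_cation_dist: float = 5.5
    pi_cation_angle_max: float = 30.0  # normal vs centroid→cation
    metal_coord_dist: float = 3.0
    pi_metal_dist: float = 5.0
    pi_metal_angle_max: float = 30.0

    def __post_init__(self):
        for name in ("hbond_dist", "salt_bridge_dist", "hydrophobic_dist",
                     "halogen_dist", "pi_stack_dist", "pi_cation_dist",
                     "metal_coord_dist", "pi_metal_dist"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("hbond_dha_min", "hbond_xda_min", "halogen_cxa_min",
                     "pi_f2f_max", "pi_e2f_min", "pi_e2f_max",
                     "pi_cation_angle_max", "pi_metal_angle_max"):
            if not 0.0 <= getattr(self, name) <= 180.0:
                raise ValueError(f"{name} outside [0, 180] degrees")

    def override(self, **kwargs) -> "GeometricCriteria":
        return replace(self, **kwargs)


@dataclass
class InteractionRecord:
    kind: str
    protein: int          # atom index, or ring id for ring participants
    ligand: int
    distance: float
    angles: dict[str, float] = field(default_factory=dict)
    strict: bool = False

    def sort_key(self):
        return (self.kind, self.protein, self.ligand)


def _angle(a: np.ndarray, vertex: np.ndarray, c: np.ndarray) -> float:
    """Angle a–vertex–c in degrees; dot products clamped to avoid NaN."""
    v1 = a - vertex
    v2 = c - vertex
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return 0.0
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _axis_angle(normal: np.ndarray, vec: np.ndarray) -> float:
    """Angle between a ring normal and a direction, folded to [0, 90]°."""
    nv = np.linalg.norm(vec)
    if nv == 0:
        return 0.0
    cosang = np.clip(abs(np.dot(normal, vec) / nv), 0.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _coords(fs: FeatureSet, idx: int) -> np.ndarray:
    return fs.molecule.atoms[idx].coords


def detect_hbonds(protein: FeatureSet, ligand: FeatureSet,
                  crit: GeometricCriteria = GeometricCriteria()) -> list[InteractionRecord]:
    """Hydrogen bonds, donor↔acceptor tested in both directions.

    Crude: donor heavy atom to acceptor distance within cutoff. Strict: with
    an explicit hydrogen, some D–H…A angle is at least ``hbond_dha_min``;
    with only implicit hydrogens, every heavy-neighbor angle X–D…A must reach
    ``hbond_xda_min`` (heavy-atom fallback geometry).
    """
    records = []
    for donor_fs, acceptor_fs, donor_is_protein in (
            (protein, ligand, True), (ligand, protein, False)):
        dmol = donor_fs.molecule
        for d_idx, h_list in donor_fs.donors:
            d = _coords(donor_fs, d_idx)
            for a_idx in acceptor_fs.acceptors:
                a = _coords(acceptor_fs, a_idx)
                dist = float(np.linalg.norm(d - a))
                if dist > crit.hbond_dist or dist <= 0:
                    continue
                angles: dict[str, float] = {}
                if h_list:
                    best = max(_angle(d, dmol.atoms[h].coords, a) for h in h_list)
                    angles["DHA"] = best
                    strict = best >= crit.hbond_dha_min
                else:
                    heavies = [x for x in dmol.neighbors(d_idx)
                               if dmol.atoms[x].element != "H"]
                    strict = True
                    worst = 180.0
                    for x in heavies:
                        ang = _angle(dmol.atoms[x].coords, d, a)
                        worst = min(worst, ang)
                        if ang < crit.hbond_xda_min:
                            strict = False
                    angles["XDA_min"] = worst
                p_idx, l_idx = (d_idx, a_idx) if donor_is_protein else (a_idx, d_idx)
                records.append(InteractionRecord("hbond", p_idx, l_idx, dist,
                                                 angles, strict))
    records.sort(key=InteractionRecord.sort_key)
    return records


def _pair_detector(kind, p_items, l_items, p_fs, l_fs, cutoff):
    records = []
    for p_idx in p_items:
        p = _coords(p_fs, p_idx)
        for l_idx in l_items:
            dist = float(np.linalg.norm(p - _coords(l_fs, l_idx)))
            if 0 < dist <= cutoff:
                records.append(InteractionRecord(kind, p_idx, l_idx, dist,
                                                 strict=True))
    records.sort(key=InteractionRecord.sort_key)
    return records


def detect_salt_bridges(protein: FeatureSet, ligand: FeatureSet,
                        crit: GeometricCriteria = GeometricCriteria()) -> list[InteractionRecord]:
    """Cation–anion heavy-atom contacts; no angle term, so strict = crude."""
    recs = _pair_detector("salt_bridge", protein.cations, ligand.anions,
                          protein, ligand, crit.salt_bridge_dist)
    recs += _pair_detector("salt_bridge", protein.anions, ligand.cations,
                           protein, ligand, crit.salt_bridge_dist)
    recs.sort(key=InteractionRecord.sort_key)
    return recs


def detect_hydrophobic(protein: FeatureSet, ligand: FeatureSet,
                       crit: GeometricCriteria = GeometricCriteria()) -> list[InteractionRecord]:
    """Hydrophobe–hydrophobe contacts; strict = crude."""
    return _pair_detector("hydrophobic", protein.hydrophobes, ligand.hydrophobes,
                          protein, ligand, crit.hydrophobic_dist)


def detect_halogen_bonds(protein: FeatureSet, ligand: FeatureSet,
                         crit: GeometricCriteria = GeometricCriteria()) -> list[InteractionRecord]:
    """Ligand C–X σ-hole bonds to protein acceptors.

    Crude: halogen–acceptor distance; strict: C–X…A angle ≥ cutoff (the
    σ-hole points away from the carbon).
    """
    records = []
    for x_idx, c_idx in ligand.halogens:
        x = _coords(ligand, x_idx)
        c = _coords(ligand, c_idx)
        for a_idx in protein.acceptors:
            a = _coords(protein, a_idx)
            dist = float(np.linalg.norm(x - a))
            if not 0 < dist <= crit.halogen_dist:
                continue
            ang = _angle(c, x, a)
            records.append(InteractionRecord(
                "halogen_bond", a_idx, x_idx, dist, {"CXA": ang},
                strict=ang >= crit.halogen_cxa_min))
    records.sort(key=InteractionRecord.sort_key)
    return records


def detect_pi_stacking(protein: FeatureSet, ligand: FeatureSet,
                       crit: GeometricCriteria = GeometricCriteria()) -> list[InteractionRecord]:
    """Aromatic ring stacking, reported once with the protein ring first.

    The inter-normal angle (folded to [0, 90]°) classifies the geometry:
    face-to-face strict when ≤ ``pi_f2f_max``, edge-to-face strict inside
    [``pi_e2f_min``, ``pi_e2f_max``]. Outside both windows the record is
    crude, with the kind assigned by the nearest angle class.
    """
    records = []
    for p_id, p_ring in enumerate(protein.rings):
        for l_id, l_ring in enumerate(ligand.rings):
            dist = float(np.linalg.norm(p_ring.centroid - l_ring.centroid))
            if not 0 < dist <= crit.pi_stack_dist:
                continue
            ang = _axis_angle(p_ring.normal, l_ring.normal)
            if ang <= crit.pi_f2f_max:
                kind, strict = "pi_stack_f2f", True
            elif crit.pi_e2f_min <= ang <= crit.pi_e2f_max:
                kind, strict = "pi_stack_e2f", True
            else:
                mid = (crit.pi_f2f_max + crit.pi_e2f_min) / 2
                kind, strict = ("pi_stack_f2f" if ang < mid else "pi_stack_e2f"), False
            records.append(InteractionRecord(kind, p_id, l_id, dist,
                                             {"normal": ang}, strict))
    records.sort(key=InteractionRecord.sort_key)
    return records


def detect_pi_cation(protein: FeatureSet, ligand: FeatureSet,
                     crit: GeometricCriteria = GeometricCriteria()) -> list[InteractionRecord]:
    """Cation over an aromatic ring face, tested in both directions.

    Strict when the centroid→cation direction lies within
    ``pi_cation_angle_max`` of the ring normal.
    """
    records = []
    for ring_fs, cat_fs, ring_is_protein in ((protein, ligand, True),
                                             (ligand, protein, False)):
        for r_id, ring in enumerate(ring_fs.rings):
            for c_idx in cat_fs.cations:
                c = _coords(cat_fs, c_idx)
                vec = c - ring.centroid
                dist = float(np.linalg.norm(vec))
                if not 0 < dist <= crit.pi_cation_dist:
                    continue
                ang = _axis_angle(ring.normal, vec)
                p, l = (r_id, c_idx) if ring_is_protein else (c_idx, r_id)
                records.append(InteractionRecord(
                    "pi_cation", p, l, dist, {"axial": ang},
                    strict=ang <= crit.pi_cation_angle_max))
    records.sort(key=InteractionRecord.sort_key)
    return records


def _coordinating_atoms(fs: FeatureSet) -> list[int]:
    """N/O acceptors plus sulfur atoms — lone-pair donors toward metals."""
    mol = fs.molecule
    sulfurs = [i for i, a in enumerate(mol.atoms) if a.element == "S"]
    return sorted(set(fs.acceptors) | set(sulfurs))


def detect_metal_interactions(protein: FeatureSet, ligand: FeatureSet,
                              crit: GeometricCriteria = GeometricCriteria()) -> list[InteractionRecord]:
    """Metal coordination (metal to N/O/S lone pair, strict = crude) and
    pi-metal (metal over an aromatic face, strict on the axial angle).
    Metals on either side are tested against partners on the other."""
    records = []
    for metal_fs, other_fs, metal_is_protein in ((protein, ligand, True),
                                                 (ligand, protein, False)):
        coords_list = _coordinating_atoms(other_fs)
        for m_idx in metal_fs.metals:
            m = _coords(metal_fs, m_idx)
            for a_idx in coords_list:
                dist = float(np.linalg.norm(m - _coords(other_fs, a_idx)))
                if 0 < dist <= crit.metal_coord_dist:
                    p, l = (m_idx, a_idx) if metal_is_protein else (a_idx, m_idx)
                    records.append(InteractionRecord("metal_coordination", p, l,
                                                     dist, strict=True))
            for r_id, ring in enumerate(other_fs.rings):
                vec = m - ring.centroid
                dist = float(np.linalg.norm(vec))
                if not 0 < dist <= crit.pi_metal_dist:
                    continue
                ang = _axis_angle(ring.normal, vec)
                p, l = (m_idx, r_id) if metal_is_protein else (r_id, m_idx)
                records.append(InteractionRecord(
                    "pi_metal", p, l, dist, {"axial": ang},
                    strict=ang <= crit.pi_metal_angle_max))
    records.sort(key=InteractionRecord.sort_key)
    return records


_DETECTORS = (
    detect_hbonds, detect_salt_bridges, detect_hydrophobic,
    detect_halogen_bonds, detect_pi_stacking, detect_pi_cation,
    detect_metal_interactions,
)


def detect_all(protein: FeatureSet, ligand: FeatureSet,
               crit: GeometricCriteria = GeometricCriteria()) -> list[InteractionRecord]:
    records: list[InteractionRecord] = []
    for det in _DETECTORS:
        records.extend(det(protein, ligand, crit))
    records.sort(key=InteractionRecord.sort_key)
    return records


def interaction_profile(records: list[InteractionRecord]) -> DescriptorVector:
    """Summarize records as an 18-component count vector.

    For each of the nine kinds, in the fixed :data:`KINDS` order, the crude
    count (all records of that kind — strict contacts satisfy the crude
    criterion too) and the strict count. Usable directly as rescoring terms.
    """
    crude = dict.fromkeys(KINDS, 0)
    strict = dict.fromkeys(KINDS, 0)
    for r in records:
        crude[r.kind] += 1
        if r.strict:
            strict[r.kind] += 1
    values = []
    for k in KINDS:
        values.extend([crude[k], strict[k]])
    return DescriptorVector(values=np.array(values, dtype=float),
                            names=list(PROFILE_NAMES),
                            meta={"generator": "interaction_profile"})
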