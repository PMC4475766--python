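"""Common docking API: engine contract, Vina adapter, deterministic mock
engine, and order-invariant parallel virtual screening.

Engines that cannot take multiple ligands (AutoDock/Vina) are driven one
ligand at a time behind a uniform interface; per-ligand failures are recorded
and never abort the screen. The central contract is worker-count invariance:
the ligand→poses map is identical whatever the parallelism degree or
completion order.
"""

from __future__ import annotations

import os
import shutil
import subprocess
import tempfile
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, GeometryError
from .molio import Molecule, Pose, PoseSet, ProteinStructure, parse_pdbqt, write_pdbqt

__all__ = [
    "DockingBox",
    "EngineConfig",
    "ScreenResult",
    "LigandResult",
    "box_from_ligand",
    "dock",
    "mock_engine",
    "vina_engine",
    "vina_command",
    "parse_vina_output",
    "virtual_screen",
    "ENGINE_REGISTRY",
]


@dataclass(frozen=True)
class DockingBox:
    center: tuple[float, float, float]
    size: tuple[float, float, float]

    def __post_init__(self):
        if any(s <= 0 for s in self.size):
            raise ConfigError("docking box sizes must be positive")


@dataclass
class EngineConfig:
    engine: str
    executable: str | None = None
    parameters: dict = field(default_factory=dict)
    seed: int | None = None
    exhaustiveness: int | None = None

    def __post_init__(self):
        if self.engine not in ENGINE_REGISTRY:
            raise ConfigError(f"engine {self.engine!r} is not registered "
                              f"(known: {sorted(ENGINE_REGISTRY)})")


@dataclass
class LigandResult:
    ligand_id: str
    poses: PoseSet
    best_score: float | None


@dataclass
class ScreenResult:
    results: dict[str, LigandResult] = field(default_factory=dict)
    failures: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)


def box_from_ligand(crystal_ligand: Molecule, padding: float = 8.0) -> DockingBox:
    """Box centered on the crystal ligand's heavy-atom centroid; each axis
    spans the coordinate extent plus ``2 * padding``."""
    if not crystal_ligand.has_coords():
        raise GeometryError("crystal ligand lacks coordinates")
    heavy = crystal_ligand.heavy_indices() or list(range(crystal_ligand.n_atoms()))
    coords = np.array([crystal_ligand.atoms[i].coords for i in heavy])
    center = coords.mean(axis=0)
    extent = coords.max(axis=0) - coords.min(axis=0)
    size = extent + 2 * padding
    return DockingBox(center=tuple(float(c) for c in center),
                      size=tuple(float(s) for s in size))


# ---------------------------------------------------------------------------
# Engines
# ---------------------------------------------------------------------------

def mock_engine() -> EngineConfig:
    """A deterministic stand-in engine for tests and dry runs.

    Each ligand docks to itself as a single pose scored
    ``-(heavy atom count) / 10``; a ligand named ``FAIL`` (or containing it)
    simulates an engine failure for that ligand only.
    """
    return EngineConfig(engine="mock")


def vina_engine(executable: str = "vina", seed: int | None = None,
                exhaustiveness: int | None = None, **parameters) -> EngineConfig:
    return EngineConfig(engine="vina", executable=executable, seed=seed,
                        exhaustiveness=exhaustiveness, parameters=parameters)


def vina_command(config: EngineConfig, receptor_path: str, ligand_path: str,
                 out_path: str, box: DockingBox) -> list[str]:
    """Explicit Vina argument list (no shell) for one ligand."""
    cmd = [config.executable or "vina",
           "--receptor", receptor_path, "--ligand", ligand_path,
           "--out", out_path,
           "--center_x", f"{box.center[0]:g}", "--center_y", f"{box.center[1]:g}",
           "--center_z", f"{box.center[2]:g}",
           "--size_x", f"{box.size[0]:g}", "--size_y", f"{box.size[1]:g}",
           "--size_z", f"{box.size[2]:g}"]
    if config.seed is not None:
        cmd += ["--seed", str(config.seed)]
    if config.exhaustiveness is not None:
        cmd += ["--exhaustiveness", str(config.exhaustiveness)]
    for key, val in sorted(config.parameters.items()):
        cmd += [f"--{key}", str(val)]
    return cmd


def parse_vina_output(text: str) -> PoseSet:
    """Vina multi-model PDBQT → PoseSet; scores from REMARK VINA RESULT.

    A model without a result remark keeps its pose with score ``None`` so
    the missing score is visible downstream, never silently dropped.
    """
    return parse_pdbqt(text)


def _dock_one_mock(ligand: Molecule, ligand_id: str) -> LigandResult:
    if "FAIL" in ligand_id or "FAIL" in ligand.name:
        raise RuntimeError("mock engine simulated failure")
    score = -len(ligand.heavy_indices()) / 10.0
    pose = Pose(molecule=ligand.copy(), score=score, rank=1)
    return LigandResult(ligand_id=ligand_id,
                        poses=PoseSet(poses=[pose], source_engine="mock"),
                        best_score=score)


def _dock_one_vina(config: EngineConfig, receptor_pdbqt: str, ligand: Molecule,
                   ligand_id: str, box: DockingBox, scratch: str,
                   timeout: float) -> LigandResult:
    lig_path = os.path.join(scratch, f"{ligand_id}.pdbqt")
    out_path = os.path.join(scratch, f"{ligand_id}_out.pdbqt")
    with open(lig_path, "w") as fh:
        fh.write(write_pdbqt(ligand))
    cmd = vina_command(config, receptor_pdbqt, lig_path, out_path, box)
    subprocess.run(cmd, check=True, capture_output=True, timeout=timeout)
    with open(out_path) as fh:
        poses = parse_vina_output(fh.read())
    # Vina convention: more negative = better; keep poses sorted by score
    scored = sorted(poses.poses, key=lambda p: (p.score is None, p.score))
    poses = PoseSet(poses=[Pose(p.molecule, p.score, k + 1)
                           for k, p in enumerate(scored)], source_engine="vina")
    best = poses.poses[0].score if poses.poses else None
    return LigandResult(ligand_id=ligand_id, poses=poses, best_score=best)


ENGINE_REGISTRY = {"mock", "vina"}


def _ligand_ids(ligands: list[Molecule]) -> list[str]:
    ids = []
    for k, lig in enumerate(ligands):
        ids.append(lig.name if lig.name else f"ligand_{k}")
    # de-duplicate while keeping order
    seen: dict[str, int] = {}
    out = []
    for i in ids:
        if i in seen:
            seen[i] += 1
            out.append(f"{i}_{seen[i]}")
        else:
            seen[i] = 0
            out.append(i)
    return out


def dock(engine: EngineConfig, receptor: ProteinStructure | None,
         ligands: list[Molecule], box: DockingBox,
         timeout: float = 600.0) -> ScreenResult:
    """Dock ligands one by one; failures are recorded, the run continues.

    For external engines the receptor is written to PDBQT in a per-run
    scratch directory, removed on success and retained on failure for
    debugging. A missing engine executable is a configuration error raised
    before any ligand is attempted.
    """
    return virtual_screen(engine, receptor, ligands, box, n_workers=1,
                          timeout=timeout)


def virtual_screen(engine: EngineConfig, receptor: ProteinStructure | None,
                   ligands: list[Molecule], box: DockingBox,
                   n_workers: int = 1, timeout: float = 600.0) -> ScreenResult:
    """Parallel screen; results are identical for every worker count.

    ``n_workers = 0`` uses all available CPUs. Results are keyed by ligand id
    and assembled in input order, so the output never depends on completion
    order; one ligand's failure never affects another's result.
    """
    if n_workers < 0:
        raise ConfigError("n_workers must be >= 0")
    workers = n_workers if n_workers > 0 else (os.cpu_count() or 1)
    ids = _ligand_ids(ligands)
    result = ScreenResult()

    if engine.engine == "mock":
        def work(pair):
            lig, lid = pair
            return _dock_one_mock(lig, lid)
        scratch = None
        receptor_pdbqt = None
    elif engine.engine == "vina":
        exe = shutil.which(engine.executable or "vina")
        if exe is None:
            raise ConfigError(f"vina executable {engine.executable!r} not found")
        scratch = tempfile.mkdtemp(prefix="oddkit_screen_")
        receptor_pdbqt = os.path.join(scratch, "receptor.pdbqt")
        with open(receptor_pdbqt, "w") as fh:
            fh.write(write_pdbqt(receptor))

        def work(pair):
            lig, lid = pair
            return _dock_one_vina(engine, receptor_pdbqt, lig, lid, box,
                                  scratch, timeout)
    else:  # pragma: no cover - registry guards this
        raise ConfigError(f"engine {engine.engine!r} not supported")

    outcomes: list[tuple[str, LigandResult | None, str | None]] = [None] * len(ligands)

    def run_one(k: int):
        lid = ids[k]
        try:
            outcomes[k] = (lid, work((ligands[k], lid)), None)
        except Exception as e:
            outcomes[k] = (lid, None, str(e))

    if workers == 1 or len(ligands) <= 1:
        for k in range(len(ligands)):
            run_one(k)
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            list(pool.map(run_one, range(len(ligands))))

    failed = False
    for lid, res, err in outcomes:
        if err is not None:
            result.failures.append((lid, err))
            failed = True
        else:
            result.results[lid] = res
    if scratch is not None and not failed:
        shutil.rmtree(scratch, ignore_errors=True)
    return result
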