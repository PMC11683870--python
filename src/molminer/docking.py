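"""Docking backends: abstract contract, external engine adapter, mock scorer.

A backend maps a molecule to a binding-affinity estimate in kcal/mol
(lower = stronger) plus a best pose in the receptor frame.  Scores keep
the engine's sign convention end to end; negation happens only inside
reward composition.  Because engines are stochastic even under a fixed
seed budget, docking-derived reward terms of duplicate molecules inside
one batch are averaged before training.

The :class:`MockDockingBackend` is a deterministic smooth stand-in used
by the test-suite and the RL smoke runs: a negative Gaussian well in
(molecular weight, logP) with a documented unique optimum.
"""

from __future__ import annotations

import logging
import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors

from .rewards import embed_3d
from .strings import canonical_identity

log = logging.getLogger(__name__)


@dataclass
class DockingTask:
    receptor: str                              # path to PDBQT/PDB
    center: tuple[float, float, float]         # box center, Angstrom
    size: tuple[float, float, float]           # box size, Angstrom
    exhaustiveness: int = 8
    seed: int = 0
    num_modes: int = 9

    def __post_init__(self):
        if any(s <= 0 for s in self.size):
            raise ValueError("docking box sizes must be positive")


@dataclass
class DockingResult:
    score: float | None                        # kcal/mol, lower is better
    pose: np.ndarray | None = None             # (n_atoms, 3), receptor frame
    status: str = "ok"                         # ok | failed
    detail: str = ""

    def __post_init__(self):
        if (self.status == "ok") != (self.pose is not None):
            raise ValueError("pose must be present exactly when status is ok")


class DockingBackend(Protocol):
    def score(self, mol: Chem.Mol, task: DockingTask) -> DockingResult: ...


# ---------------------------------------------------------------------------
# mock backend


@dataclass
class MockDockingBackend:
    """Deterministic smooth score with one optimum; no external engine.

    score(X) = -depth * exp(-((MW-mw_opt)^2 / (2 sw^2) + (logP-logp_opt)^2 /
    (2 sl^2))): minimized exactly at (mw_opt, logp_opt), worsening
    monotonically along each descriptor away from it.
    """

    mw_optimum: float = 320.0
    logp_optimum: float = 2.5
    mw_width: float = 120.0
    logp_width: float = 1.8
    depth_kcal: float = 12.0
    embed_poses: bool = False

    def closed_form(self, mw: float, logp: float) -> float:
        return -self.depth_kcal * math.exp(
            -((mw - self.mw_optimum) ** 2 / (2 * self.mw_width ** 2)
              + (logp - self.logp_optimum) ** 2 / (2 * self.logp_width ** 2)))

    def score(self, mol: Chem.Mol, task: DockingTask | None = None) -> DockingResult:
        value = self.closed_form(Descriptors.MolWt(mol), Crippen.MolLogP(mol))
        if self.embed_poses:
            mol3d = embed_3d(mol)
            if mol3d is None:
                return DockingResult(score=None, status="failed",
                                     detail="3D embedding failed")
            pose = mol3d.GetConformer().GetPositions()
        else:
            pose = np.zeros((mol.GetNumAtoms(), 3))
        return DockingResult(score=value, pose=pose)


# ---------------------------------------------------------------------------
# external engine adapter (AutoDock Vina command-line contract)


@dataclass
class VinaBackend:
    """Subprocess adapter for an AutoDock-Vina-compatible executable.

    Ligand preparation: single embedded conformer with force-field
    cleanup (rdkit), conversion to PDBQT via openbabel with rotatable
    bonds flexible and protonation for pH 7.4.  The engine is invoked with
    --receptor/--center_*/--size_*/--seed/--exhaustiveness and the best
    pose parsed back from the output PDBQT.
    """

    executable: str = "vina"
    obabel: str = "obabel"
    timeout_s: float = 300.0

    def available(self) -> bool:
        return shutil.which(self.executable) is not None

    def score(self, mol: Chem.Mol, task: DockingTask) -> DockingResult:
        mol3d = embed_3d(mol)
        if mol3d is None:
            return DockingResult(score=None, status="failed",
                                 detail="3D embedding failed")
        with tempfile.TemporaryDirectory() as tmp:
            tmp = Path(tmp)
            sdf = tmp / "ligand.sdf"
            pdbqt = tmp / "ligand.pdbqt"
            out = tmp / "out.pdbqt"
            writer = Chem.SDWriter(str(sdf))
            writer.write(mol3d)
            writer.close()
            try:
                subprocess.run(
                    [self.obabel, str(sdf), "-O", str(pdbqt), "-p", "7.4"],
                    check=True, capture_output=True, timeout=self.timeout_s)
                proc = subprocess.run(
                    [self.executable,
                     "--receptor", str(task.receptor),
                     "--ligand", str(pdbqt),
                     "--center_x", str(task.center[0]),
                     "--center_y", str(task.center[1]),
                     "--center_z", str(task.center[2]),
                     "--size_x", str(task.size[0]),
                     "--size_y", str(task.size[1]),
                     "--size_z", str(task.size[2]),
                     "--seed", str(task.seed),
                     "--exhaustiveness", str(task.exhaustiveness),
                     "--num_modes", str(task.num_modes),
                     "--out", str(out)],
                    check=True, capture_output=True, timeout=self.timeout_s)
            except (subprocess.CalledProcessError, subprocess.TimeoutExpired) as exc:
                detail = getattr(exc, "stderr", b"") or b""
                return DockingResult(score=None, status="failed",
                                     detail=detail.decode(errors="replace"))
            score, pose = _parse_vina_output(out, proc.stdout.decode(errors="replace"))
            if score is None:
                return DockingResult(score=None, status="failed",
                                     detail="no pose in engine output")
            return DockingResult(score=score, pose=pose)


def prepare_receptor(pdb_path, pdbqt_path, obabel: str = "obabel",
                     timeout_s: float = 300.0) -> None:
    """Convert a receptor PDB to rigid PDBQT via openbabel (-xr)."""
    subprocess.run([obabel, str(pdb_path), "-O", str(pdbqt_path), "-xr"],
                   check=True, capture_output=True, timeout=timeout_s)


def _parse_vina_output(out_path: Path, stdout: str
                       ) -> tuple[float | None, np.ndarray | None]:
    score = None
    coords: list[list[float]] = []
    if out_path.exists():
        in_first = False
        for line in out_path.read_text().splitlines():
            if line.startswith("MODEL"):
                if in_first:
                    break
                in_first = True
            elif line.startswith("REMARK VINA RESULT:") and score is None:
                score = float(line.split()[3])
            elif line.startswith(("ATOM", "HETATM")) and in_first:
                coords.append([float(line[30:38]), float(line[38:46]),
                               float(line[46:54])])
            elif line.startswith("ENDMDL") and in_first:
                break
    if score is None:
        for line in stdout.splitlines():
            parts = line.split()
            if len(parts) >= 2 and parts[0] == "1":
                try:
                    score = float(parts[1])
                    break
                except ValueError:
                    continue
    return score, (np.asarray(coords) if coords else None)


# ---------------------------------------------------------------------------
# batched evaluation


def score_molecule(smiles: str, task: DockingTask | None,
                   backend: DockingBackend) -> DockingResult:
    """Score one SMILES; failures are reported, never raised."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return DockingResult(score=None, status="failed",
                             detail=f"unparseable SMILES {smiles!r}")
    try:
        return backend.score(mol, task)
    except Exception as exc:  # backend bugs must not abort a batch
        log.warning("backend error for %s: %s", smiles, exc)
        return DockingResult(score=None, status="failed", detail=str(exc))


def score_batch(molecules: Sequence[str], task: DockingTask | None,
                backend: DockingBackend, workers: int = 1
                ) -> list[DockingResult]:
    """Score molecules preserving input order; failures stay per-molecule."""
    if workers > 1:
        from concurrent.futures import ThreadPoolExecutor
        with ThreadPoolExecutor(max_workers=workers) as pool:
            return list(pool.map(lambda s: score_molecule(s, task, backend),
                                 molecules))
    return [score_molecule(s, task, backend) for s in molecules]


def average_duplicates(smiles: Sequence[str], results: Sequence[DockingResult]
                       ) -> list[float | None]:
    """Mean docking score per canonical identity, assigned to every copy.

    Failed scores are excluded from the mean (and logged); a molecule whose
    every copy failed gets ``None``.
    """
    if len(smiles) != len(results):
        raise ValueError("inputs and results differ in length")
    keys = []
    for s in smiles:
        try:
            keys.append(canonical_identity(s))
        except ValueError:
            keys.append(s)
    sums: dict[str, list[float]] = {}
    for key, res in zip(keys, results):
        if res.status == "ok" and res.score is not None:
            sums.setdefault(key, []).append(res.score)
        else:
            log.debug("failed duplicate for %s excluded from average", key)
    return [float(np.mean(sums[k])) if k in sums else None for k in keys]
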