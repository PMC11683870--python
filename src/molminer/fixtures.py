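"""Deterministic toy inputs: corpora, a receptor stub, synthetic trajectories.

Real runs pretrain on a large public corpus and dock against a prepared
receptor; desk-scale testing instead uses molecules enumerated from a few
drug-like ring scaffolds with small substituent sets, a minimal tripeptide
receptor, and trajectories with closed-form expected RMSD.  Everything is
a pure function of an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import random

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors

from .rewards import Contact, InteractionProfile

_CORES = [
    "c1ccccc1", "c1ccncc1", "c1cncnc1", "c1ccoc1", "c1ccsc1", "c1cc[nH]c1",
    "C1CCCCC1", "C1CCNCC1", "C1CCOCC1", "C1CCCC1", "C1CNCCO1", "c1ccc2ccccc2c1",
]

# substituents written with the attachment atom first
_SUBSTITUENTS = [
    "C", "CC", "CCC", "C(C)C", "O", "OC", "N", "NC", "F", "Cl", "Br",
    "C(=O)O", "C(=O)N", "C(=O)OC", "C#N", "C(F)(F)F", "CO", "CN", "OCC",
    "NC(C)=O", "C=C", "CCO",
]


@dataclass
class FixtureSpec:
    """Parameters of the toy corpus generator."""

    seed: int = 7
    size: int = 5000
    max_substituents: int = 3
    mw_range: tuple[float, float] | None = None
    cores: list[str] = field(default_factory=lambda: list(_CORES))
    substituents: list[str] = field(default_factory=lambda: list(_SUBSTITUENTS))


def _attach(core: Chem.Mol, sub: Chem.Mol, core_idx: int) -> Chem.Mol | None:
    combo = Chem.RWMol(Chem.CombineMols(core, sub))
    combo.AddBond(core_idx, core.GetNumAtoms(), Chem.BondType.SINGLE)
    try:
        mol = combo.GetMol()
        Chem.SanitizeMol(mol)
        return mol
    except Exception:
        return None


def toy_corpus(spec: FixtureSpec | None = None, **kwargs) -> list[str]:
    """Enumerate ``spec.size`` unique valid canonical SMILES, seeded.

    Molecules are ring cores decorated with 0..max_substituents groups at
    random positions; with an ``mw_range`` request, candidates outside the
    window are rejected so the whole corpus lies inside it.
    """
    spec = spec or FixtureSpec(**kwargs)
    if spec.size == 0:
        return []
    rng = random.Random(spec.seed)
    cores = [Chem.MolFromSmiles(s) for s in spec.cores]
    subs = [Chem.MolFromSmiles(s) for s in spec.substituents]
    seen: set[str] = set()
    out: list[str] = []
    attempts = 0
    max_attempts = 400 * max(spec.size, 1)
    while len(out) < spec.size and attempts < max_attempts:
        attempts += 1
        core = rng.choice(cores)
        mol = core
        n_sub = rng.randint(0, spec.max_substituents)
        failed = False
        for _ in range(n_sub):
            # attach only to ring atoms with a free implicit H
            sites = [a.GetIdx() for a in mol.GetAtoms()
                     if a.GetIsAromatic() or a.IsInRing()]
            sites = [i for i in sites if mol.GetAtomWithIdx(i).GetTotalNumHs() > 0]
            if not sites:
                failed = True
                break
            grown = _attach(mol, rng.choice(subs), rng.choice(sites))
            if grown is None:
                failed = True
                break
            mol = grown
        if failed:
            continue
        smiles = Chem.MolToSmiles(mol)
        if smiles in seen:
            continue
        if spec.mw_range is not None:
            mw = Descriptors.MolWt(mol)
            if not (spec.mw_range[0] <= mw <= spec.mw_range[1]):
                continue
        seen.add(smiles)
        out.append(smiles)
    if len(out) < spec.size:
        raise RuntimeError(
            f"could only enumerate {len(out)}/{spec.size} unique molecules"
        )
    return out


# ---------------------------------------------------------------------------
# receptor stub

# A minimal rigid three-residue "receptor" (Gly-His-Glu) with hand-placed
# coordinates: enough structure for the interaction profiler, trajectory
# topology and docking-box plumbing.  Synthetic — not derived from any
# deposited structure.
_RECEPTOR_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.450   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.000   1.420   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.250   2.400   0.000  1.00  0.00           O
ATOM      5  N   HIS A   2       3.330   1.540   0.000  1.00  0.00           N
ATOM      6  CA  HIS A   2       3.960   2.860   0.000  1.00  0.00           C
ATOM      7  C   HIS A   2       5.480   2.720   0.000  1.00  0.00           C
ATOM      8  O   HIS A   2       6.030   1.620   0.000  1.00  0.00           O
ATOM      9  CB  HIS A   2       3.530   3.680   1.220  1.00  0.00           C
ATOM     10  CG  HIS A   2       4.050   5.080   1.250  1.00  0.00           C
ATOM     11  ND1 HIS A   2       3.310   6.130   0.760  1.00  0.00           N
ATOM     12  CD2 HIS A   2       5.240   5.570   1.700  1.00  0.00           C
ATOM     13  CE1 HIS A   2       4.020   7.240   0.930  1.00  0.00           C
ATOM     14  NE2 HIS A   2       5.200   6.950   1.510  1.00  0.00           N
ATOM     15  N   GLU A   3       6.170   3.860   0.000  1.00  0.00           N
ATOM     16  CA  GLU A   3       7.630   3.900   0.000  1.00  0.00           C
ATOM     17  C   GLU A   3       8.180   5.320   0.000  1.00  0.00           C
ATOM     18  O   GLU A   3       7.430   6.300   0.000  1.00  0.00           O
ATOM     19  CB  GLU A   3       8.200   3.110   1.190  1.00  0.00           C
ATOM     20  CG  GLU A   3       9.720   3.000   1.180  1.00  0.00           C
ATOM     21  CD  GLU A   3      10.260   2.200   2.350  1.00  0.00           C
ATOM     22  OE1 GLU A   3       9.490   1.870   3.280  1.00  0.00           O
ATOM     23  OE2 GLU A   3      11.470   1.910   2.380  1.00  0.00           O
TER
END
"""


def receptor_stub(path) -> dict:
    """Write the stub receptor PDB; return the docking task description."""
    with open(path, "w") as fh:
        fh.write(_RECEPTOR_PDB)
    return {
        "receptor": str(path),
        "center": (5.0, 4.0, 1.0),
        "size": (18.0, 18.0, 18.0),
    }


def receptor_stub_coordinates() -> np.ndarray:
    coords = []
    for line in _RECEPTOR_PDB.splitlines():
        if line.startswith("ATOM"):
            coords.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
    return np.asarray(coords)


# ---------------------------------------------------------------------------
# synthetic trajectories


def synthetic_trajectory(start_pose: np.ndarray, n_frames: int,
                         drift_A: float = 0.0, noise_A: float = 0.0,
                         seed: int = 0) -> np.ndarray:
    """Ligand frames with linearly growing displacement plus isotropic noise.

    Frame ``k`` (1-based) is the start pose translated along +x by
    ``k * drift_A / n_frames`` with i.i.d. Gaussian coordinate noise of
    standard deviation ``noise_A``, so per-frame RMSD has a closed form.
    """
    start = np.asarray(start_pose, dtype=float)
    rng = np.random.default_rng(seed)
    frames = np.empty((n_frames,) + start.shape)
    for k in range(1, n_frames + 1):
        shift = np.array([k * drift_A / n_frames, 0.0, 0.0])
        frames[k - 1] = start + shift + rng.normal(0.0, noise_A, size=start.shape)
    return frames


def write_trajectory_pdb(path, ligand_frames: np.ndarray,
                         receptor_coords: np.ndarray | None = None) -> None:
    """Multi-frame PDB: fixed receptor (CA-style) plus moving ligand atoms."""
    with open(path, "w") as fh:
        for f, lig in enumerate(ligand_frames, start=1):
            fh.write(f"MODEL     {f:4d}\n")
            serial = 1
            if receptor_coords is not None:
                for x, y, z in receptor_coords:
                    fh.write(
                        f"ATOM  {serial:5d}  CA  REC A{serial:4d}    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n")
                    serial += 1
            for i, (x, y, z) in enumerate(lig, start=1):
                fh.write(
                    f"HETATM{serial:5d}  C{i:<2d} LIG B   1    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n")
                serial += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")


def synthetic_interaction_profiles(pattern: dict[tuple[str, str], float],
                                   n_frames: int) -> list[InteractionProfile]:
    """Per-frame profiles hitting each (residue, type) at an exact frequency.

    A pattern entry ``(("His163", "hydrogen_bond"), 0.4)`` with 10 frames
    places the contact in exactly 4 evenly spaced frames (deterministic).
    """
    profiles = []
    for f in range(n_frames):
        contacts = []
        for (residue, ctype), freq in pattern.items():
            count = round(freq * n_frames)
            # evenly spaced deterministic placement
            hit = f * count // n_frames < (f + 1) * count // n_frames
            if hit:
                contacts.append(Contact(type=ctype, residue=residue,
                                        distance=2.9, angle=160.0,
                                        strength="strong"))
        profiles.append(InteractionProfile(contacts=contacts))
    return profiles
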