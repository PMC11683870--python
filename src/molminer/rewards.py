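"""Reward terms for docking-guided generation and their composition.

The total reward for a generated molecule X is a weighted sum of clipped
terms,

    R(X) = sum_i lambda_i * clip_i(S_i(X))  >= 0,

where the de novo case uses the docking score S_vina (negative is
favourable; positive scores clip to zero contribution) and the
drug-likeliness score S_DL (negative scores clip to zero).  Optional terms
add topological fragment similarity (BRICS fragments x Morgan/Dice),
2D-pharmacophore similarity, a pose-alignment penalty on the docking score,
and a residue-interaction score with weak hydrogen bonds down-weighted by
0.5 (weak: donor angle < 135 deg or H-donor distance > 2.8 A).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, BRICS, DataStructs
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.Pharm2D import Generate, Gobbi_Pharm2D

log = logging.getLogger(__name__)

WEAK_HBOND_ANGLE_DEG = 135.0
WEAK_HBOND_DISTANCE_A = 2.8
WEAK_SCALE = 0.5


# ---------------------------------------------------------------------------
# interaction profiles


@dataclass(frozen=True)
class Contact:
    """One typed protein-ligand contact with its geometry."""

    type: str                       # hydrogen_bond | hydrophobic | pi_stacking | salt_bridge | halogen
    residue: str                    # e.g. "A:HIS:163" or any user label
    distance: float                 # Angstrom
    angle: float | None = None      # degrees, where applicable
    strength: str = "strong"        # strong | weak

    def __post_init__(self):
        if self.distance <= 0:
            raise ValueError("contact distance must be positive")
        if self.angle is not None and not (0.0 <= self.angle <= 180.0):
            raise ValueError("contact angle must lie in [0, 180] degrees")


@dataclass
class InteractionProfile:
    contacts: list[Contact] = field(default_factory=list)


def classify_hbond(donor_angle_deg: float, donor_distance_A: float) -> str:
    """Classify a hydrogen bond as ``strong`` or ``weak``.

    Weak whenever the donor angle is below 135 degrees *or* the
    hydrogen-donor distance exceeds 2.8 A; either defect alone marks a
    geometrically poor bond.
    """
    if donor_angle_deg < WEAK_HBOND_ANGLE_DEG or donor_distance_A > WEAK_HBOND_DISTANCE_A:
        return "weak"
    return "strong"


def interaction_score(profile: InteractionProfile,
                      residue_weights: Mapping[str, float],
                      type_weights: Mapping[str, float] | None = None) -> float:
    """Weighted contact total; weak contacts contribute at half strength.

    Contacts to residues absent from ``residue_weights`` are ignored (and
    logged) so users only reward the residues they care about.
    """
    type_weights = dict(type_weights or {})
    if any(w < 0 for w in residue_weights.values()) or any(
            w < 0 for w in type_weights.values()):
        raise ValueError("interaction weights must be non-negative")
    total = 0.0
    for c in profile.contacts:
        rw = residue_weights.get(c.residue)
        if rw is None:
            log.debug("contact to unweighted residue %s ignored", c.residue)
            continue
        tw = type_weights.get(c.type, 1.0)
        strength = WEAK_SCALE if c.strength == "weak" else 1.0
        total += rw * tw * strength
    return total


# ---------------------------------------------------------------------------
# similarity terms

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def _strip_dummies(mol: Chem.Mol) -> Chem.Mol:
    rw = Chem.RWMol(mol)
    for idx in sorted((a.GetIdx() for a in rw.GetAtoms() if a.GetAtomicNum() == 0),
                      reverse=True):
        rw.RemoveAtom(idx)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out


def brics_fragments(mol: Chem.Mol) -> list[Chem.Mol]:
    """BRICS fragments with attachment dummies removed; the whole molecule
    when no BRICS bond exists."""
    frags = []
    for smi in BRICS.BRICSDecompose(mol):
        frag = Chem.MolFromSmiles(smi)
        if frag is None:
            continue
        try:
            frags.append(_strip_dummies(frag))
        except Exception:
            continue
    return frags or [mol]


def fragment_similarity(mol: Chem.Mol | str, reference: Chem.Mol | str) -> float:
    """Maximum Dice similarity between Morgan fingerprints of the query's
    BRICS fragments and the reference molecule/fragment."""
    mol = Chem.MolFromSmiles(mol) if isinstance(mol, str) else mol
    ref = Chem.MolFromSmiles(reference) if isinstance(reference, str) else reference
    if mol is None or ref is None:
        raise ValueError("unparseable molecule in fragment_similarity")
    ref_fp = _MORGAN.GetFingerprint(ref)
    best = 0.0
    for frag in brics_fragments(mol):
        best = max(best, DataStructs.DiceSimilarity(_MORGAN.GetFingerprint(frag), ref_fp))
    return best


_PHARM_FACTORY = Gobbi_Pharm2D.factory


def pharmacophore_similarity(mol: Chem.Mol | str, reference: Chem.Mol | str) -> float:
    """Dice similarity of 2D pharmacophore fingerprints (Gobbi features)."""
    mol = Chem.MolFromSmiles(mol) if isinstance(mol, str) else mol
    ref = Chem.MolFromSmiles(reference) if isinstance(reference, str) else reference
    if mol is None or ref is None:
        raise ValueError("unparseable molecule in pharmacophore_similarity")
    fp_a = Generate.Gen2DFingerprint(mol, _PHARM_FACTORY)
    fp_b = Generate.Gen2DFingerprint(ref, _PHARM_FACTORY)
    if fp_a.GetNumOnBits() == 0 or fp_b.GetNumOnBits() == 0:
        warnings.warn("molecule with no pharmacophore features; similarity 0")
        return 0.0
    return DataStructs.DiceSimilarity(fp_a, fp_b)


# ---------------------------------------------------------------------------
# pose-alignment penalty


@dataclass
class PosePenaltyConfig:
    rmsd_threshold_A: float = 2.0

    def __post_init__(self):
        if self.rmsd_threshold_A <= 0:
            raise ValueError("pose RMSD threshold must be positive")


def pose_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Coordinate RMSD over matched atoms, no re-fitting (common frame)."""
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    if a.shape != b.shape:
        raise ValueError("matched coordinate sets differ in shape")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def pose_adjusted_docking_score(docking_score: float,
                                docked_pose: "np.ndarray | Chem.Mol",
                                fragment_pose: "np.ndarray | Chem.Mol",
                                cfg: PosePenaltyConfig | None = None) -> float:
    """Clip the docking score to 0 when the docked copy of the reference
    fragment strays from the reference pose.

    Poses may be coordinate arrays over matched atoms, or rdkit molecules
    with conformers, in which case the fragment is substructure-matched
    inside the docked molecule first; a missing match clips to 0.
    """
    cfg = cfg or PosePenaltyConfig()
    if isinstance(docked_pose, Chem.Mol) and isinstance(fragment_pose, Chem.Mol):
        match = docked_pose.GetSubstructMatch(fragment_pose)
        if not match:
            log.info("pose penalty: no substructure match; score clipped to 0")
            return 0.0
        mol_xyz = docked_pose.GetConformer().GetPositions()[list(match)]
        frag_xyz = fragment_pose.GetConformer().GetPositions()
    else:
        mol_xyz = np.asarray(docked_pose, float)
        frag_xyz = np.asarray(fragment_pose, float)
    if pose_rmsd(mol_xyz, frag_xyz) > cfg.rmsd_threshold_A:
        return 0.0
    return docking_score


# ---------------------------------------------------------------------------
# composition


def _clip_docking(s: float) -> float:
    return max(-s, 0.0)          # favourable (negative) scores only


def _clip_nonnegative(s: float) -> float:
    return max(s, 0.0)


_CLIPS: dict[str, Callable[[float], float]] = {
    "docking": _clip_docking,
    "drug_likeliness": _clip_nonnegative,
    "fragment_similarity": _clip_nonnegative,
    "pharmacophore_similarity": _clip_nonnegative,
    "interaction": _clip_nonnegative,
}


@dataclass
class RewardSpec:
    """Term weights (lambda) and the active-term set."""

    weights: dict[str, float] = field(
        default_factory=lambda: {"drug_likeliness": 1.0, "docking": 1.0})

    def __post_init__(self):
        if not self.weights:
            raise ValueError("at least one reward term must be active")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("lambda weights must be non-negative")
        unknown = set(self.weights) - set(_CLIPS)
        if unknown:
            raise ValueError(f"unknown reward terms: {sorted(unknown)}")

    @property
    def active_terms(self) -> set[str]:
        return set(self.weights)


@dataclass
class RewardResult:
    raw: dict[str, float]
    clipped: dict[str, float]
    total: float


def compose_reward(terms: Mapping[str, float], spec: RewardSpec) -> RewardResult:
    """R = sum_i lambda_i * clip_i(term_i); always non-negative."""
    missing = spec.active_terms - set(terms)
    if missing:
        raise ValueError(f"missing active reward terms: {sorted(missing)}")
    raw = {k: float(terms[k]) for k in spec.active_terms}
    clipped = {k: _CLIPS[k](v) for k, v in raw.items()}
    total = sum(spec.weights[k] * clipped[k] for k in clipped)
    return RewardResult(raw=raw, clipped=clipped, total=total)


# ---------------------------------------------------------------------------
# geometric interaction profiler (built-in; external profilers plug in by
# returning InteractionProfile objects)


@dataclass
class ReceptorSite:
    """A labelled receptor atom the profiler can contact."""

    residue: str
    xyz: np.ndarray
    is_donor: bool = False
    is_acceptor: bool = False
    is_hydrophobic: bool = False
    is_aromatic_center: bool = False


class GeometricInteractionProfiler:
    """Distance/angle-rule contact detection against labelled site atoms.

    Deliberately minimal: hydrogen bonds (donor/acceptor pairs within
    ``hbond_max_A``, classified strong/weak from the supplied geometry),
    hydrophobic contacts (apolar carbons within ``hydrophobic_max_A``) and
    pi-stacking (aromatic ring centroids within ``stacking_max_A``).
    External profilers conforming to InteractionProfile replace it for
    production use.
    """

    def __init__(self, sites: Sequence[ReceptorSite],
                 hbond_max_A: float = 3.5, hydrophobic_max_A: float = 4.0,
                 stacking_max_A: float = 5.5):
        self.sites = list(sites)
        self.hbond_max_A = hbond_max_A
        self.hydrophobic_max_A = hydrophobic_max_A
        self.stacking_max_A = stacking_max_A

    def profile(self, mol: Chem.Mol) -> InteractionProfile:
        if mol.GetNumConformers() == 0:
            raise ValueError("profiler needs a 3D conformer")
        xyz = mol.GetConformer().GetPositions()
        contacts: list[Contact] = []
        ring_info = mol.GetRingInfo()
        aromatic_centroids = []
        for ring in ring_info.AtomRings():
            if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
                aromatic_centroids.append(xyz[list(ring)].mean(axis=0))
        for atom in mol.GetAtoms():
            p = xyz[atom.GetIdx()]
            is_polar = atom.GetSymbol() in ("N", "O")
            has_h = atom.GetTotalNumHs() > 0
            for site in self.sites:
                d = float(np.linalg.norm(p - site.xyz))
                if is_polar and (site.is_acceptor and has_h or site.is_donor):
                    if d <= self.hbond_max_A:
                        # idealized donor angle from heavy-atom geometry
                        angle = 180.0
                        contacts.append(Contact(
                            type="hydrogen_bond", residue=site.residue,
                            distance=d, angle=angle,
                            strength=classify_hbond(angle, d)))
                if (not is_polar and atom.GetSymbol() == "C"
                        and site.is_hydrophobic and d <= self.hydrophobic_max_A):
                    contacts.append(Contact(
                        type="hydrophobic", residue=site.residue, distance=d))
        for centroid in aromatic_centroids:
            for site in self.sites:
                if site.is_aromatic_center:
                    d = float(np.linalg.norm(centroid - site.xyz))
                    if d <= self.stacking_max_A:
                        contacts.append(Contact(
                            type="pi_stacking", residue=site.residue, distance=d))
        return InteractionProfile(contacts=contacts)


def embed_3d(mol: Chem.Mol, seed: int = 0) -> Chem.Mol | None:
    """Single lowest-effort 3D conformer with force-field cleanup."""
    mol3d = Chem.AddHs(mol)
    if AllChem.EmbedMolecule(mol3d, randomSeed=seed) != 0:
        return None
    try:
        AllChem.MMFFOptimizeMolecule(mol3d)
    except Exception:
        pass
    return Chem.RemoveHs(mol3d)
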