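"""Post-generation pipeline: filters, consensus rescoring, benchmarks,
and binding-stability analysis of MD trajectories.

Generated molecules pass a conjunctive filter bank — no PAINS substructure
hits, zero Lipinski rule-of-five violations, synthetic-accessibility score
within threshold, drug-likeliness score strictly above its cutoff (default
2.8), optionally confirmed residue interactions.  Survivors can be
rescored by multiple pluggable scoring functions, keeping molecules inside
every scorer's top fraction (consensus).  Distribution benchmarks
(validity / uniqueness / novelty / KL-divergence score) characterize a
generated set against its training corpus.  Finally, ligand trajectories
from MD are judged stable when the mean ligand RMSD after receptor
superposition stays below 4 A and more than one protein-ligand hydrogen
bond persists on average.
"""

from __future__ import annotations

import os
import sys
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, RDConfig
from rdkit.Chem import FilterCatalog

from .properties import (PROPERTY_NAMES, ReferenceDistributions,
                         UndesirablePatternSet, compute_properties,
                         drug_likeliness_score, shannon_entropy)
from .rewards import InteractionProfile
from .strings import canonical_identity

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (Ertl fragment-contribution SA score)


# ---------------------------------------------------------------------------
# filters


@dataclass
class FilterThresholds:
    sa_max: float = 4.5                 # Ertl SA scale 1 (easy) .. 10 (hard)
    dl_min: float = 2.8                 # strict >, shifted drug-likeliness scale
    max_lipinski_violations: int = 0
    require_interaction: bool = False


@dataclass
class FilterRecord:
    smiles: str
    pains_hit: bool = False
    lipinski_violations: int = 0
    sa_score: float = float("nan")
    drug_likeliness: float = float("nan")
    interaction_confirmed: bool | None = None
    passed: bool = False
    fail_reasons: list[str] = field(default_factory=list)


_PAINS: FilterCatalog.FilterCatalog | None = None


def _pains_catalog() -> FilterCatalog.FilterCatalog:
    global _PAINS
    if _PAINS is None:
        params = FilterCatalog.FilterCatalogParams()
        params.AddCatalog(FilterCatalog.FilterCatalogParams.FilterCatalogs.PAINS)
        _PAINS = FilterCatalog.FilterCatalog(params)
    return _PAINS


def lipinski_violations(mol: Chem.Mol) -> int:
    """Rule-of-five violation count: MW>500, logP>5, donors>5, acceptors>10."""
    return sum([
        Descriptors.MolWt(mol) > 500.0,
        Crippen.MolLogP(mol) > 5.0,
        Lipinski.NumHDonors(mol) > 5,
        Lipinski.NumHAcceptors(mol) > 10,
    ])


def apply_filters(molecules: Sequence[str],
                  ref: ReferenceDistributions | None = None,
                  patterns: UndesirablePatternSet | None = None,
                  thresholds: FilterThresholds | None = None,
                  dl_scores: Sequence[float] | None = None,
                  interaction_confirmed: Sequence[bool] | None = None,
                  ) -> list[FilterRecord]:
    """Conjunctive, order-independent postfilters.

    Drug-likeliness values come from ``dl_scores`` when given (e.g. cached
    from the reward pipeline) and are otherwise computed from ``ref``.
    """
    thresholds = thresholds or FilterThresholds()
    out: list[FilterRecord] = []
    for i, smiles in enumerate(molecules):
        rec = FilterRecord(smiles=smiles)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            rec.fail_reasons.append("unparseable")
            out.append(rec)
            continue
        rec.pains_hit = _pains_catalog().HasMatch(mol)
        if rec.pains_hit:
            rec.fail_reasons.append("pains")
        rec.lipinski_violations = lipinski_violations(mol)
        if rec.lipinski_violations > thresholds.max_lipinski_violations:
            rec.fail_reasons.append("lipinski")
        rec.sa_score = float(sascorer.calculateScore(mol))
        if rec.sa_score > thresholds.sa_max:
            rec.fail_reasons.append("synthetic_accessibility")
        if dl_scores is not None:
            rec.drug_likeliness = float(dl_scores[i])
        elif ref is not None:
            rec.drug_likeliness = drug_likeliness_score(mol, ref, patterns)
        if not np.isnan(rec.drug_likeliness) and \
                not rec.drug_likeliness > thresholds.dl_min:
            rec.fail_reasons.append("drug_likeliness")
        if thresholds.require_interaction:
            confirmed = bool(interaction_confirmed[i]) \
                if interaction_confirmed is not None else False
            rec.interaction_confirmed = confirmed
            if not confirmed:
                rec.fail_reasons.append("interaction")
        rec.passed = not rec.fail_reasons
        out.append(rec)
    return out


def filter_report(records: Sequence[FilterRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "smiles": r.smiles, "pains_hit": r.pains_hit,
        "lipinski_violations": r.lipinski_violations, "sa_score": r.sa_score,
        "drug_likeliness": r.drug_likeliness,
        "interaction_confirmed": r.interaction_confirmed,
        "passed": r.passed, "fail_reasons": ";".join(r.fail_reasons)}
        for r in records])


# ---------------------------------------------------------------------------
# consensus rescoring


def consensus_rescore(items: Sequence,
                      scorers: Mapping[str, Callable | Sequence[float]],
                      top_fraction: float = 0.1) -> list[int]:
    """Indices of items inside every scorer's top fraction (lower = better).

    Scorers are either callables on the items (e.g. retrained scoring
    functions applied to poses) or pre-computed score sequences.  At least
    two scorers are required for a consensus.  Ties at the cutoff resolve
    by input order (deterministic).
    """
    if len(scorers) < 2:
        raise ValueError("consensus needs at least two scoring functions")
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    n = len(items)
    keep = max(int(np.ceil(top_fraction * n)), 1)
    selected: set[int] | None = None
    for name, scorer in scorers.items():
        scores = np.asarray([scorer(x) for x in items] if callable(scorer)
                            else list(scorer), dtype=float)
        if len(scores) != n:
            raise ValueError(f"scorer {name!r} returned {len(scores)} scores")
        top = set(np.argsort(scores, kind="stable")[:keep].tolist())
        selected = top if selected is None else (selected & top)
    return sorted(selected)


# ---------------------------------------------------------------------------
# distribution benchmarks


@dataclass
class BenchmarkReport:
    validity: float
    uniqueness: float
    novelty: float
    kl_divergence_score: float
    n_valid: int = 0
    n_unique: int = 0
    n_novel: int = 0

    def __post_init__(self):
        for name in ("validity", "uniqueness", "novelty", "kl_divergence_score"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0,1]")


def _kl_divergence_score(generated: Sequence[str], corpus: Sequence[str],
                         n_bins: int = 32) -> float:
    """Descriptor-distribution similarity: mean over descriptors of
    exp(-KL(corpus || generated)) on shared-support histograms."""
    gen = np.stack([compute_properties(s).as_array() for s in generated])
    ref = np.stack([compute_properties(s).as_array() for s in corpus])
    floor = 1e-10
    scores = []
    for j in range(len(PROPERTY_NAMES)):
        lo = min(gen[:, j].min(), ref[:, j].min())
        hi = max(gen[:, j].max(), ref[:, j].max())
        if hi <= lo:
            scores.append(1.0)
            continue
        edges = np.linspace(lo, hi, n_bins + 1)
        p, _ = np.histogram(ref[:, j], bins=edges)
        q, _ = np.histogram(gen[:, j], bins=edges)
        p = np.maximum(p / p.sum(), floor)
        q = np.maximum(q / q.sum(), floor)
        p /= p.sum()
        q /= q.sum()
        kl = float((p * np.log(p / q)).sum())
        scores.append(np.exp(-kl))
    return float(np.mean(scores))


def benchmark(generated: Sequence[str | None], corpus: Sequence[str],
              kl_sample: int = 500) -> BenchmarkReport:
    """Distribution-learning metrics of a generated set vs its corpus.

    Conventions (chained bases): validity = valid / generated;
    uniqueness = distinct canonical identities / valid; novelty =
    identities absent from the corpus / distinct.  The KL-divergence score
    compares descriptor histograms of (up to ``kl_sample``) valid
    generated molecules with the corpus, 1 = identical distributions.
    """
    n = len(generated)
    if n == 0:
        raise ValueError("empty generated set")
    valid: list[str] = []
    for s in generated:
        if s is None:
            continue
        mol = Chem.MolFromSmiles(s)
        if mol is not None:
            valid.append(Chem.MolToSmiles(mol))
    unique = list(dict.fromkeys(valid))
    corpus_ids = {canonical_identity(s) for s in corpus}
    novel = [s for s in unique if s not in corpus_ids]
    kl = 1.0
    if valid and corpus:
        kl = _kl_divergence_score(valid[:kl_sample], list(corpus)[:kl_sample])
    return BenchmarkReport(
        validity=len(valid) / n,
        uniqueness=len(unique) / len(valid) if valid else 0.0,
        novelty=len(novel) / len(unique) if unique else 0.0,
        kl_divergence_score=kl,
        n_valid=len(valid), n_unique=len(unique), n_novel=len(novel))


# ---------------------------------------------------------------------------
# trajectory stability


@dataclass
class StabilityCriteria:
    rmsd_threshold_A: float = 4.0
    min_mean_hbonds: float = 1.0        # stable requires mean count > this


@dataclass
class TrajectorySummary:
    rmsd_A: np.ndarray                  # per frame
    hbond_counts: np.ndarray            # per frame
    interaction_frequency: pd.DataFrame  # residue x type -> frequency
    stable: bool

    @property
    def mean_rmsd(self) -> float:
        return float(self.rmsd_A.mean())

    @property
    def mean_hbonds(self) -> float:
        return float(self.hbond_counts.mean())


def kabsch(mobile: np.ndarray, target: np.ndarray
           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Best-fit rotation R and translations aligning mobile onto target:
    x -> (x - mobile_centroid) @ R + target_centroid."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    H = (mobile - mc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    return R, mc, tc


def ligand_rmsd(frames: np.ndarray, start_pose: np.ndarray,
                receptor_frames: np.ndarray | None = None,
                receptor_ref: np.ndarray | None = None) -> np.ndarray:
    """Per-frame ligand RMSD vs the starting pose, after superposing each
    frame's receptor onto the reference receptor (when provided)."""
    frames = np.asarray(frames, float)
    start = np.asarray(start_pose, float)
    if frames.ndim != 3 or frames.shape[1:] != start.shape:
        raise ValueError("frame/pose atom mismatch")
    out = np.empty(len(frames))
    for k, lig in enumerate(frames):
        if receptor_frames is not None:
            R, mc, tc = kabsch(receptor_frames[k], receptor_ref)
            lig = (lig - mc) @ R + tc
        out[k] = np.sqrt(np.mean(np.sum((lig - start) ** 2, axis=1)))
    return out


def interaction_frequency(profiles: Sequence[InteractionProfile]) -> pd.DataFrame:
    """Fraction of frames in which each (residue, type) contact occurs."""
    n = len(profiles)
    counts: dict[tuple[str, str], int] = {}
    for prof in profiles:
        present = {(c.residue, c.type) for c in prof.contacts}
        for key in present:
            counts[key] = counts.get(key, 0) + 1
    rows = [{"residue": r, "type": t, "frequency": c / n}
            for (r, t), c in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["residue", "type", "frequency"])


def analyze_trajectory(frames: np.ndarray, start_pose: np.ndarray,
                       profiles: Sequence[InteractionProfile] | None = None,
                       hbond_counts: Sequence[float] | None = None,
                       receptor_frames: np.ndarray | None = None,
                       receptor_ref: np.ndarray | None = None,
                       criteria: StabilityCriteria | None = None
                       ) -> TrajectorySummary:
    """Binding-stability analysis of a ligand trajectory.

    Hydrogen-bond counts come from per-frame interaction profiles (or an
    explicit count sequence).  The complex is stable iff mean ligand RMSD
    stays below the threshold *and* the mean hydrogen-bond count exceeds
    ``min_mean_hbonds``.
    """
    criteria = criteria or StabilityCriteria()
    rmsd = ligand_rmsd(frames, start_pose, receptor_frames, receptor_ref)
    if hbond_counts is not None:
        hb = np.asarray(hbond_counts, float)
    elif profiles is not None:
        hb = np.array([sum(1 for c in p.contacts if c.type == "hydrogen_bond")
                       for p in profiles], dtype=float)
    else:
        hb = np.zeros(len(rmsd))
    if len(hb) != len(rmsd):
        raise ValueError("hydrogen-bond series misaligned with frames")
    freq = (interaction_frequency(profiles) if profiles is not None
            else pd.DataFrame(columns=["residue", "type", "frequency"]))
    stable = (rmsd.mean() < criteria.rmsd_threshold_A
              and hb.mean() > criteria.min_mean_hbonds)
    return TrajectorySummary(rmsd_A=rmsd, hbond_counts=hb,
                             interaction_frequency=freq, stable=stable)


def load_trajectory_pdb(path, ligand_selection: str = "resname LIG",
                        receptor_selection: str = "protein or resname REC"
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Read a multi-frame PDB into (receptor_frames, ligand_frames)."""
    import MDAnalysis as mda
    u = mda.Universe(str(path))
    lig = u.select_atoms(ligand_selection)
    rec = u.select_atoms(receptor_selection)
    lig_frames, rec_frames = [], []
    for _ in u.trajectory:
        lig_frames.append(lig.positions.copy())
        rec_frames.append(rec.positions.copy())
    return np.asarray(rec_frames), np.asarray(lig_frames)
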