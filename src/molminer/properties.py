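"""Drug-likeness descriptors and the entropy-weighted drug-likeliness score.

Thirteen 2D descriptors characterize how drug-like a molecule is.  A
reference corpus defines, for each descriptor i, a discrete probability
distribution p_i (fixed-width histogram) with Shannon entropy

    S_i = - sum_b p_i(b) ln p_i(b),

and a weight sigma_i proportional to 1/S_i, so narrow (low-entropy)
reference distributions dominate the score.  The drug-likeliness score of
molecule X is the sigma-weighted average of per-descriptor log-likelihoods

    S_DL(X) = sum_i sigma_i log p_i(prop_i(X)) / sum_i sigma_i ,

optionally shifted by -log(p_floor) so the score is non-negative and a
fixed positive postfilter cutoff is usable.  A molecule matching any
user-defined undesirable SMARTS pattern scores exactly 0.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, fields
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

PROBABILITY_FLOOR = 1e-6
ENTROPY_FLOOR = 1e-3
DEFAULT_CONTINUOUS_BINS = 64
DEFAULT_PERCENTILE_SPAN = (1.0, 99.0)

#: descriptors measured on a [0,1] or real scale (histogrammed in 64 bins);
#: the remaining descriptors are integer counts (unit bins).
CONTINUOUS_PROPERTIES = frozenset({
    "sp3_carbon_fraction", "heteroatom_fraction", "molecular_weight",
    "alogp", "polar_surface_area",
})


@dataclass(frozen=True)
class PropertyVector:
    """The 13 drug-likeness descriptors of one molecule."""

    sp3_carbon_fraction: float
    heavy_atom_count: int
    heteroatom_fraction: float
    hbond_donors: int
    hbond_acceptors: int
    rotatable_bonds: int
    aliphatic_rings: int
    aromatic_rings: int
    molecular_weight: float
    alogp: float
    polar_surface_area: float
    structural_alerts: int
    largest_ring_size: int

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PROPERTY_NAMES], dtype=float)


PROPERTY_NAMES: tuple[str, ...] = tuple(f.name for f in fields(PropertyVector))


# ---------------------------------------------------------------------------
# SMARTS catalogues


class UndesirablePatternSet:
    """Labelled SMARTS patterns; every pattern is compiled at load time."""

    def __init__(self, patterns: Iterable[tuple[str, str]] = ()):
        self.entries: list[tuple[str, str, Chem.Mol]] = []
        for smarts, label in patterns:
            query = Chem.MolFromSmarts(smarts)
            if query is None:
                raise ValueError(f"SMARTS does not compile: {smarts!r} ({label})")
            self.entries.append((smarts, label, query))

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_file(cls, path) -> "UndesirablePatternSet":
        pairs = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                pairs.append((parts[0], parts[1] if len(parts) > 1 else parts[0]))
        return cls(pairs)

    @classmethod
    def bundled(cls, name: str = "undesirable") -> "UndesirablePatternSet":
        ref = resources.files("molminer.data") / f"{name}.smarts"
        with resources.as_file(ref) as path:
            return cls.from_file(path)


def matches_undesirable(mol: Chem.Mol | str,
                        patterns: UndesirablePatternSet) -> tuple[bool, list[str]]:
    mol = Chem.MolFromSmiles(mol) if isinstance(mol, str) else mol
    labels = [label for _, label, query in patterns.entries
              if mol.HasSubstructMatch(query)]
    return bool(labels), labels


_ALERTS: UndesirablePatternSet | None = None


def _alert_catalogue() -> UndesirablePatternSet:
    global _ALERTS
    if _ALERTS is None:
        _ALERTS = UndesirablePatternSet.bundled("structural_alerts")
    return _ALERTS


# ---------------------------------------------------------------------------
# descriptors


def compute_properties(mol: Chem.Mol | str) -> PropertyVector:
    """All 13 descriptors from 2D topology; deterministic."""
    if isinstance(mol, str):
        parsed = Chem.MolFromSmiles(mol)
        if parsed is None:
            raise ValueError(f"unparseable molecule: {mol!r}")
        mol = parsed
    heavy = mol.GetNumHeavyAtoms()
    if heavy == 0:
        raise ValueError("empty molecule")
    hetero = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() not in (1, 6))
    rings = mol.GetRingInfo().AtomRings()
    _, alert_labels = matches_undesirable(mol, _alert_catalogue())
    return PropertyVector(
        sp3_carbon_fraction=float(Descriptors.FractionCSP3(mol)),
        heavy_atom_count=heavy,
        heteroatom_fraction=hetero / heavy,
        hbond_donors=int(Lipinski.NumHDonors(mol)),
        hbond_acceptors=int(Lipinski.NumHAcceptors(mol)),
        rotatable_bonds=int(Lipinski.NumRotatableBonds(mol)),
        aliphatic_rings=int(rdMolDescriptors.CalcNumAliphaticRings(mol)),
        aromatic_rings=int(rdMolDescriptors.CalcNumAromaticRings(mol)),
        molecular_weight=float(Descriptors.MolWt(mol)),
        alogp=float(Crippen.MolLogP(mol)),
        polar_surface_area=float(Descriptors.TPSA(mol)),
        structural_alerts=len(alert_labels),
        largest_ring_size=max((len(r) for r in rings), default=0),
    )


# ---------------------------------------------------------------------------
# reference distributions


@dataclass
class _PropertyHistogram:
    edges: np.ndarray          # bin edges, len = n_bins + 1
    probs: np.ndarray          # bin probabilities, sum to 1
    entropy: float             # nats, floored
    weight: float = 0.0        # sigma_i, set by the parent

    def probability(self, value: float) -> float:
        idx = int(np.searchsorted(self.edges, value, side="right") - 1)
        if idx == len(self.probs):        # right edge inclusive
            idx -= 1
        if idx < 0 or idx >= len(self.probs):
            return PROBABILITY_FLOOR
        return max(float(self.probs[idx]), PROBABILITY_FLOOR)


@dataclass
class ReferenceDistributions:
    """Per-descriptor histograms, entropies and inverse-entropy weights."""

    histograms: dict[str, _PropertyHistogram]
    p_floor: float = PROBABILITY_FLOOR

    @property
    def entropies(self) -> dict[str, float]:
        return {k: h.entropy for k, h in self.histograms.items()}

    @property
    def weights(self) -> dict[str, float]:
        return {k: h.weight for k, h in self.histograms.items()}

    def to_json(self) -> str:
        return json.dumps({
            name: {"edges": h.edges.tolist(), "probs": h.probs.tolist(),
                   "entropy": h.entropy, "weight": h.weight}
            for name, h in self.histograms.items()})

    @classmethod
    def from_json(cls, text: str) -> "ReferenceDistributions":
        payload = json.loads(text)
        hists = {
            name: _PropertyHistogram(
                edges=np.asarray(d["edges"]), probs=np.asarray(d["probs"]),
                entropy=d["entropy"], weight=d["weight"])
            for name, d in payload.items()}
        return cls(histograms=hists)


def shannon_entropy(probs: np.ndarray) -> float:
    p = np.asarray(probs, float)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def fit_reference(corpus: Sequence[PropertyVector | str | Chem.Mol],
                  n_bins: int = DEFAULT_CONTINUOUS_BINS,
                  percentile_span: tuple[float, float] = DEFAULT_PERCENTILE_SPAN,
                  ) -> ReferenceDistributions:
    """Fit per-descriptor histograms on a reference corpus.

    Continuous descriptors use ``n_bins`` fixed-width bins spanning the
    corpus 1st-99th percentile; integer descriptors use unit bins.
    Weights are sigma_i = c / max(S_i, floor), normalized to sum to 1.
    """
    vectors = [v if isinstance(v, PropertyVector) else compute_properties(v)
               for v in corpus]
    if not vectors:
        raise ValueError("empty reference corpus")
    if len(vectors) < 100:
        warnings.warn(f"reference fitted on only {len(vectors)} molecules; "
                      "distributions may be noisy")
    table = np.stack([v.as_array() for v in vectors])
    hists: dict[str, _PropertyHistogram] = {}
    for j, name in enumerate(PROPERTY_NAMES):
        values = table[:, j]
        if name in CONTINUOUS_PROPERTIES:
            lo, hi = np.percentile(values, percentile_span)
            if hi <= lo:
                hi = lo + 1.0
            edges = np.linspace(lo, hi, n_bins + 1)
        else:
            lo, hi = int(values.min()), int(values.max())
            edges = np.arange(lo - 0.5, hi + 1.5)
        counts, edges = np.histogram(np.clip(values, edges[0], edges[-1]), bins=edges)
        probs = counts / counts.sum()
        entropy = shannon_entropy(probs)
        if entropy < ENTROPY_FLOOR:
            warnings.warn(f"degenerate reference distribution for {name!r}; "
                          "entropy floored")
            entropy = ENTROPY_FLOOR
        hists[name] = _PropertyHistogram(edges=edges, probs=probs, entropy=entropy)
    inv = {name: 1.0 / h.entropy for name, h in hists.items()}
    norm = sum(inv.values())
    for name, h in hists.items():
        h.weight = inv[name] / norm
    return ReferenceDistributions(histograms=hists)


# ---------------------------------------------------------------------------
# the score


def drug_likeliness_score(mol: Chem.Mol | str,
                          ref: ReferenceDistributions,
                          patterns: UndesirablePatternSet | None = None,
                          scale: str = "shifted",
                          props: PropertyVector | None = None) -> float:
    """Entropy-weighted average log-likelihood of the descriptors.

    ``scale='shifted'`` (default) adds -log(p_floor) per term so scores are
    non-negative with maximum -log(p_floor) ~ 13.8 and a positive filter
    cutoff is meaningful; ``scale='raw'`` returns the plain weighted mean
    of log p_i, which is always <= 0.  Matching any undesirable pattern
    forces the score to exactly 0 on either scale.
    """
    if scale not in ("shifted", "raw"):
        raise ValueError("scale must be 'shifted' or 'raw'")
    if isinstance(mol, str):
        mol = Chem.MolFromSmiles(mol)
        if mol is None:
            raise ValueError("unparseable molecule")
    if patterns is not None:
        hit, _ = matches_undesirable(mol, patterns)
        if hit:
            return 0.0
    vec = (props or compute_properties(mol)).as_dict()
    num = 0.0
    den = 0.0
    offset = -math.log(ref.p_floor) if scale == "shifted" else 0.0
    for name, hist in ref.histograms.items():
        logp = math.log(hist.probability(vec[name]))
        num += hist.weight * (logp + offset)
        den += hist.weight
    return num / den
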