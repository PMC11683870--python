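"""Policy-gradient training of the generator against composite rewards.

The generator defines p_Theta(s_T) over complete token sequences; training
maximizes the expected terminal reward J(Theta) = E[R(s_T)].  The plain
REINFORCE estimator follows gradients of mean(R * log p_Theta); the PPO
variant used here replaces it with the clipped surrogate

    J_ppo = mean_b min(r_b R_b, clip(r_b, 1-eps, 1+eps) R_b)
            + alpha * mean token entropy,

with r_b = p_Theta(s_b) / p_Theta_old(s_b) the sequence-level probability
ratio against the policy snapshot taken when the batch was collected.
Each iteration samples a fresh batch, evaluates rewards (docking-derived
terms averaged over duplicate molecules), then reuses the batch for up to
``max_epochs`` gradient steps, stopping early once the mean token KL
divergence from the snapshot exceeds ``kl_threshold``.  Training stops
when the mean token entropy collapses (drops below a configured fraction
of its trailing-window maximum) — the signal that the policy has stopped
exploring — or at the iteration cap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from rdkit import Chem

from . import docking as dk
from .generator import Adam, LSTMPolicy, log_softmax, softmax
from .properties import (ReferenceDistributions, UndesirablePatternSet,
                         drug_likeliness_score)
from .rewards import (RewardResult, RewardSpec, compose_reward,
                      fragment_similarity, pharmacophore_similarity)
from .strings import TokenSequence, decode_sequence

log = logging.getLogger(__name__)


@dataclass
class PPOConfig:
    clip_epsilon: float = 0.2
    entropy_coef: float = 0.01
    use_baseline: bool = False          # subtract the batch-mean reward
    kl_threshold: float = 0.03
    max_epochs: int = 10
    molecules_per_iteration: int = 2000
    max_iterations: int = 50
    learning_rate: float = 1e-4
    entropy_collapse_fraction: float = 0.5
    entropy_collapse_window: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.clip_epsilon <= 0:
            raise ValueError("clip epsilon must be positive")
        if self.entropy_coef < 0:
            raise ValueError("entropy coefficient must be non-negative")
        if self.kl_threshold <= 0 or self.max_epochs < 1:
            raise ValueError("invalid reuse-control settings")


@dataclass
class RolloutBatch:
    sequences: list[TokenSequence]
    rewards: np.ndarray                   # R(s_T) >= 0 per sequence
    logp_old: list[np.ndarray]            # per-token log-probs under Theta_old
    identities: list[str | None]          # canonical SMILES or None (empty)

    def __post_init__(self):
        if np.any(self.rewards < 0):
            raise ValueError("rewards must be non-negative")
        for seq, lp in zip(self.sequences, self.logp_old):
            if len(seq.indices) != len(lp):
                raise ValueError("log-prob array misaligned with tokens")


@dataclass
class TraceRow:
    iteration: int
    mean_reward: float
    mean_entropy: float
    kl: float
    validity: float
    epochs_used: int


# ---------------------------------------------------------------------------
# batched forward helpers


def _pad_batch(policy: LSTMPolicy, sequences: Sequence[TokenSequence]
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    brk = policy.vocab.break_index
    T = max(len(s.indices) for s in sequences)
    B = len(sequences)
    inputs = np.full((B, T), brk)
    targets = np.zeros((B, T), dtype=int)
    mask = np.zeros((B, T))
    for b, s in enumerate(sequences):
        n = len(s.indices)
        inputs[b, 1:n] = s.indices[:-1]
        targets[b, :n] = s.indices
        mask[b, :n] = 1.0
    return inputs, targets, mask


def _token_logp(logits: np.ndarray, targets: np.ndarray) -> np.ndarray:
    logp = log_softmax(logits)
    return np.take_along_axis(logp, targets[..., None], axis=2)[..., 0]


def probability_ratio(policy: LSTMPolicy, seq: TokenSequence) -> float:
    """r = p_Theta(seq) / p_Theta_old(seq); 1 when the snapshot is current."""
    if policy.old_params is None:
        raise ValueError("no old-policy snapshot available")
    new, _ = policy.sequence_log_prob(seq)
    old, _ = policy.sequence_log_prob(seq, params=policy.old_params)
    return float(np.exp(new - old))


def mean_token_entropy(policy: LSTMPolicy,
                       sequences: Sequence[TokenSequence]) -> float:
    """Average entropy of the next-token distributions visited by the
    sequences; lies in [0, ln V]."""
    inputs, _, mask = _pad_batch(policy, sequences)
    logits, _ = policy.forward(inputs)
    logp = log_softmax(logits)
    ent = -(np.exp(logp) * logp).sum(axis=2)
    return float((ent * mask).sum() / mask.sum())


def policy_kl(policy: LSTMPolicy, sequences: Sequence[TokenSequence],
              old_params: dict | None = None) -> float:
    """Mean per-token KL(new || old) over visited positions."""
    old_params = old_params or policy.old_params
    if old_params is None:
        raise ValueError("no old-policy snapshot available")
    inputs, _, mask = _pad_batch(policy, sequences)
    logits_new, _ = policy.forward(inputs)
    saved = policy.params
    policy.params = old_params
    try:
        logits_old, _ = policy.forward(inputs)
    finally:
        policy.params = saved
    lp_new = log_softmax(logits_new)
    lp_old = log_softmax(logits_old)
    kl = (np.exp(lp_new) * (lp_new - lp_old)).sum(axis=2)
    return float((kl * mask).sum() / mask.sum())


# ---------------------------------------------------------------------------
# objectives and gradients


def reinforce_gradient(policy: LSTMPolicy, batch: RolloutBatch
                       ) -> dict[str, np.ndarray]:
    """Ascent gradient of mean_b R_b * log p_Theta(s_b)."""
    inputs, targets, mask = _pad_batch(policy, batch.sequences)
    logits, cache = policy.forward(inputs)
    probs = softmax(logits)
    B, T, V = logits.shape
    onehot = np.zeros_like(probs)
    np.put_along_axis(onehot, targets[..., None], 1.0, axis=2)
    coef = batch.rewards[:, None] / B
    dlogits = coef[..., None] * (onehot - probs) * mask[..., None]
    return policy.backward(cache, dlogits)


def ppo_objective(policy: LSTMPolicy, batch: RolloutBatch,
                  cfg: PPOConfig) -> float:
    value, _ = ppo_objective_and_grad(policy, batch, cfg, want_grad=False)
    return value


def ppo_objective_and_grad(policy: LSTMPolicy, batch: RolloutBatch,
                           cfg: PPOConfig, want_grad: bool = True
                           ) -> tuple[float, dict[str, np.ndarray] | None]:
    """Clipped-surrogate objective (plus entropy bonus) and its ascent
    gradient under the sequence-level probability ratio."""
    inputs, targets, mask = _pad_batch(policy, batch.sequences)
    logits, cache = policy.forward(inputs)
    token_lp = _token_logp(logits, targets) * mask
    logp_new = token_lp.sum(axis=1)
    logp_old = np.array([lp.sum() for lp in batch.logp_old])
    r = np.exp(logp_new - logp_old)
    R = batch.rewards
    A = R - R.mean() if cfg.use_baseline else R
    eps = cfg.clip_epsilon
    clipped = np.clip(r, 1 - eps, 1 + eps)
    unclipped_term = r * A
    term = np.minimum(unclipped_term, clipped * A)
    B = len(R)
    logp_all = log_softmax(logits)
    probs = softmax(logits)
    ent = -(probs * logp_all).sum(axis=2)
    n_tokens = mask.sum()
    mean_entropy = float((ent * mask).sum() / n_tokens)
    objective = float(term.mean() + cfg.entropy_coef * mean_entropy)
    if not want_grad:
        return objective, None
    # d(term)/d(logp_new): A*r while the unclipped branch attains the min
    active = unclipped_term <= clipped * A
    coef = np.where(active, A * r, 0.0) / B
    onehot = np.zeros_like(probs)
    np.put_along_axis(onehot, targets[..., None], 1.0, axis=2)
    dlogits = coef[:, None, None] * (onehot - probs) * mask[..., None]
    # entropy bonus: dH/dz_j = -p_j (log p_j + H)
    dent = -probs * (logp_all + ent[..., None])
    dlogits += cfg.entropy_coef * dent * mask[..., None] / n_tokens
    return objective, policy.backward(cache, dlogits)


# ---------------------------------------------------------------------------
# reward evaluation


class RewardEvaluator:
    """Maps decoded molecules to total rewards per the active term set.

    Wires together the docking backend (scores averaged over duplicate
    canonical identities within a batch), the drug-likeliness score with
    undesirable-pattern zeroing, optional similarity terms against a
    reference molecule, and an optional user interaction-score hook
    ``interaction_fn(smiles, pose) -> float``.
    """

    def __init__(self, spec: RewardSpec,
                 backend: dk.DockingBackend | None = None,
                 task: dk.DockingTask | None = None,
                 reference_distributions: ReferenceDistributions | None = None,
                 patterns: UndesirablePatternSet | None = None,
                 reference_smiles: str | None = None,
                 interaction_fn: Callable[[str, np.ndarray | None], float] | None = None,
                 dl_scale: str = "shifted"):
        self.spec = spec
        self.backend = backend
        self.task = task
        self.ref = reference_distributions
        self.patterns = patterns
        self.reference_smiles = reference_smiles
        self.interaction_fn = interaction_fn
        self.dl_scale = dl_scale
        need = spec.active_terms
        if "docking" in need and backend is None:
            raise ValueError("docking term active but no backend given")
        if "drug_likeliness" in need and reference_distributions is None:
            raise ValueError("drug-likeliness term active but no reference")
        if {"fragment_similarity", "pharmacophore_similarity"} & need \
                and reference_smiles is None:
            raise ValueError("similarity term active but no reference molecule")
        if "interaction" in need and interaction_fn is None:
            raise ValueError("interaction term active but no interaction_fn")

    def evaluate(self, smiles_list: Sequence[str | None]
                 ) -> tuple[np.ndarray, list[RewardResult | None]]:
        """Total reward per molecule; empty/invalid molecules get 0."""
        n = len(smiles_list)
        valid_idx = [i for i, s in enumerate(smiles_list) if s is not None]
        valid = [smiles_list[i] for i in valid_idx]
        docking_terms: list[float | None] = [None] * len(valid)
        if "docking" in self.spec.active_terms and valid:
            results = dk.score_batch(valid, self.task, self.backend)
            docking_terms = dk.average_duplicates(valid, results)
        rewards = np.zeros(n)
        details: list[RewardResult | None] = [None] * n
        for j, i in enumerate(valid_idx):
            smiles = smiles_list[i]
            terms: dict[str, float] = {}
            if "docking" in self.spec.active_terms:
                score = docking_terms[j]
                terms["docking"] = score if score is not None else 0.0
            if "drug_likeliness" in self.spec.active_terms:
                terms["drug_likeliness"] = drug_likeliness_score(
                    smiles, self.ref, self.patterns, scale=self.dl_scale)
            if "fragment_similarity" in self.spec.active_terms:
                terms["fragment_similarity"] = fragment_similarity(
                    smiles, self.reference_smiles)
            if "pharmacophore_similarity" in self.spec.active_terms:
                terms["pharmacophore_similarity"] = pharmacophore_similarity(
                    smiles, self.reference_smiles)
            if "interaction" in self.spec.active_terms:
                terms["interaction"] = self.interaction_fn(smiles, None)
            res = compose_reward(terms, self.spec)
            rewards[i] = res.total
            details[i] = res
        return rewards, details


# ---------------------------------------------------------------------------
# the training loop


def collect_rollouts(policy: LSTMPolicy, evaluator: RewardEvaluator,
                     n: int, rng: np.random.Generator) -> RolloutBatch:
    """Sample molecules, decode, evaluate rewards (duplicates averaged)."""
    seqs, logps = policy.sample(n, rng)
    records = policy.decode_samples(seqs)
    identities = [r.smiles_canonical if r is not None else None for r in records]
    rewards, _ = evaluator.evaluate(identities)
    return RolloutBatch(sequences=seqs, rewards=rewards, logp_old=logps,
                        identities=identities)


def train_iteration(policy: LSTMPolicy, evaluator: RewardEvaluator,
                    cfg: PPOConfig, opt: Adam, rng: np.random.Generator,
                    iteration: int = 0) -> TraceRow | None:
    """One collect-and-update cycle; returns the trace row (None if the
    whole batch decoded empty)."""
    policy.snapshot_old()
    batch = collect_rollouts(policy, evaluator, cfg.molecules_per_iteration, rng)
    n_valid = sum(1 for s in batch.identities if s is not None)
    if n_valid == 0:
        warnings.warn(f"iteration {iteration}: every sample decoded empty; skipped")
        return None
    kl = 0.0
    epochs = 0
    for _ in range(cfg.max_epochs):
        _, grads = ppo_objective_and_grad(policy, batch, cfg)
        neg = {k: -v for k, v in grads.items()}     # optimizer minimizes
        opt.step(policy.params, neg, lr=cfg.learning_rate)
        policy.step_count += 1
        epochs += 1
        kl = policy_kl(policy, batch.sequences)
        if not reuse_allowed(kl, cfg):
            break
    return TraceRow(
        iteration=iteration,
        mean_reward=float(batch.rewards.mean()),
        mean_entropy=mean_token_entropy(policy, batch.sequences),
        kl=kl,
        validity=n_valid / len(batch.sequences),
        epochs_used=epochs)


def reuse_allowed(kl: float, cfg: PPOConfig) -> bool:
    """Batch-reuse control: keep taking epochs on the collected batch only
    while the policy has not drifted past the KL threshold."""
    return kl <= cfg.kl_threshold


def entropy_collapsed(entropies: Sequence[float], fraction: float,
                      window: int) -> bool:
    """True when the latest mean token entropy has fallen below
    ``fraction`` of its trailing-window maximum."""
    if len(entropies) < 2:
        return False
    recent = entropies[-window - 1:]
    return recent[-1] < fraction * max(recent)


def train(policy: LSTMPolicy, evaluator: RewardEvaluator, cfg: PPOConfig,
          checkpoint_dir: str | None = None,
          callback: Callable[[TraceRow], None] | None = None
          ) -> list[TraceRow]:
    """Run PPO until entropy collapse or the iteration cap; returns the
    training trace (one row per iteration)."""
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(policy.params, lr=cfg.learning_rate)
    trace: list[TraceRow] = []
    for it in range(cfg.max_iterations):
        row = train_iteration(policy, evaluator, cfg, opt, rng, iteration=it)
        if row is None:
            continue
        trace.append(row)
        if callback is not None:
            callback(row)
        if checkpoint_dir is not None:
            policy.save(Path(checkpoint_dir) / f"iteration_{it:04d}")
        ents = [r.mean_entropy for r in trace]
        if entropy_collapsed(ents, cfg.entropy_collapse_fraction,
                             cfg.entropy_collapse_window):
            log.info("entropy collapse at iteration %d; stopping", it)
            break
    return trace


def trace_to_csv(trace: Sequence[TraceRow], path) -> None:
    import pandas as pd
    pd.DataFrame([asdict(r) for r in trace]).to_csv(path, index=False)
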