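"""Autoregressive token policy: weight-dropped stacked LSTM in numpy.

The generator is a language model over the valence-safe token alphabet.
Each step embeds the previous token, passes it through a stack of LSTM
cells

    i_t = sigmoid(W^i x_t + U^i h_{t-1} + b^i)
    f_t = sigmoid(W^f x_t + U^f h_{t-1} + b^f)
    o_t = sigmoid(W^o x_t + U^o h_{t-1} + b^o)
    c~_t = tanh(W^c x_t + U^c h_{t-1} + b^c)
    c_t = f_t * c_{t-1} + i_t * c~_t
    h_t = o_t * tanh(c_t)

and decodes the last hidden state to a softmax over tokens.  DropConnect
regularization zeroes a random subset of the recurrent (U) weights, with
one mask per forward/backward pass shared across all time steps.

Gradients are hand-derived (backpropagation through time); the package
deliberately has no deep-learning framework dependency, so the same code
path serves supervised pretraining and policy-gradient training.
Sequence probabilities factorize as a Markov decision process:
p(s_T) = prod_t p(token_t | token_<t), with s_0 the break token.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .strings import (BREAK_TOKEN, TokenSequence, TokenVocabulary,
                      decode_sequence, encode_sequence, StringEncodingError,
                      DEFAULT_MAX_TOKENS)


@dataclass
class GeneratorConfig:
    """Architecture and regularization constants.

    Defaults follow the published architecture (400-dim embeddings, three
    stacked cells of 1152/1152/400 units, the four dropout rates);
    tests and desk-scale runs shrink them.  ``dropout_multiplier`` scales
    all four rates at once.
    """

    vocab_size: int
    embedding_dim: int = 400
    cell_units: tuple[int, ...] = (1152, 1152, 400)
    max_sequence_length: int = DEFAULT_MAX_TOKENS
    dropout_embedding: float = 0.002
    dropout_weight: float = 0.02
    dropout_hidden: float = 0.015
    dropout_output: float = 0.01
    dropout_multiplier: float = 1.0

    def __post_init__(self):
        for name in ("dropout_embedding", "dropout_weight", "dropout_hidden",
                     "dropout_output"):
            rate = getattr(self, name) * self.dropout_multiplier
            if not (0.0 <= rate < 1.0):
                raise ValueError(f"{name} out of [0,1)")

    def rate(self, name: str) -> float:
        return getattr(self, f"dropout_{name}") * self.dropout_multiplier


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=axis, keepdims=True))


def cell_step(x: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray,
              W: np.ndarray, U: np.ndarray, b: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM cell update; gate order [i, f, o, c~] along the 4H axis."""
    H = h_prev.shape[-1]
    if W.shape != (4 * H, x.shape[-1]) or U.shape != (4 * H, H):
        raise ValueError("cell parameter shapes inconsistent with inputs")
    z = x @ W.T + h_prev @ U.T + b
    i = _sigmoid(z[..., :H])
    f = _sigmoid(z[..., H:2 * H])
    o = _sigmoid(z[..., 2 * H:3 * H])
    g = np.tanh(z[..., 3 * H:])
    c = f * c_prev + i * g
    h = o * np.tanh(c)
    return h, c


def apply_weight_drop(params: dict[str, np.ndarray], rate: float,
                      mask_seed: int) -> dict[str, np.ndarray]:
    """Return a copy of ``params`` with DropConnect applied to U matrices.

    The mask is a pure function of ``mask_seed`` so one mask can be shared
    across every time step of a forward/backward pass.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError("drop rate must lie in [0,1]")
    if rate == 0.0:
        return dict(params)
    rng = np.random.default_rng(mask_seed)
    out = dict(params)
    for name in sorted(params):
        if name.startswith("U_"):
            mask = rng.random(params[name].shape) >= rate
            scale = 0.0 if rate == 1.0 else 1.0 / (1.0 - rate)
            out[name] = params[name] * mask * scale
    return out


def _init_params(cfg: GeneratorConfig, seed: int) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)
    p: dict[str, np.ndarray] = {}
    p["embedding"] = rng.normal(0, 0.1, (cfg.vocab_size, cfg.embedding_dim))
    in_dim = cfg.embedding_dim
    for l, H in enumerate(cfg.cell_units):
        bound = 1.0 / math.sqrt(H)
        p[f"W_{l}"] = rng.uniform(-bound, bound, (4 * H, in_dim))
        p[f"U_{l}"] = rng.uniform(-bound, bound, (4 * H, H))
        b = np.zeros(4 * H)
        b[H:2 * H] = 1.0          # forget-gate bias: remember by default
        p[f"b_{l}"] = b
        in_dim = H
    p["decoder_W"] = rng.normal(0, 0.05, (cfg.vocab_size, cfg.cell_units[-1]))
    p["decoder_b"] = np.zeros(cfg.vocab_size)
    return p


class LSTMPolicy:
    """Stacked weight-dropped LSTM over a token vocabulary.

    Holds the trainable parameters Theta, an optional frozen snapshot
    Theta_old (for probability ratios during policy optimization), and a
    step counter.
    """

    def __init__(self, vocab: TokenVocabulary, config: GeneratorConfig | None = None,
                 seed: int = 0, **config_kwargs):
        if config is None:
            config = GeneratorConfig(vocab_size=len(vocab), **config_kwargs)
        if config.vocab_size != len(vocab):
            raise ValueError("decoder size must equal vocabulary size")
        self.vocab = vocab
        self.config = config
        self.seed = seed
        self.params = _init_params(config, seed)
        self.old_params: dict[str, np.ndarray] | None = None
        self.step_count = 0

    # -- snapshots ---------------------------------------------------------

    def snapshot_old(self) -> None:
        """Freeze the current parameters as the 'old policy'."""
        self.old_params = {k: v.copy() for k, v in self.params.items()}

    def clone(self) -> "LSTMPolicy":
        other = LSTMPolicy(self.vocab, self.config, seed=self.seed)
        other.params = {k: v.copy() for k, v in self.params.items()}
        other.step_count = self.step_count
        return other

    # -- forward / backward ------------------------------------------------

    def _train_masks(self, batch: int, seed: int) -> dict:
        cfg = self.config
        rng = np.random.default_rng(seed)
        masks: dict = {"params": apply_weight_drop(
            self.params, cfg.rate("weight"), mask_seed=int(rng.integers(2 ** 31)))}
        r_e = cfg.rate("embedding")
        masks["emb"] = (
            (rng.random((cfg.vocab_size, 1)) >= r_e) / (1 - r_e) if r_e else None)
        r_h = cfg.rate("hidden")
        masks["hidden"] = [
            (rng.random((batch, H)) >= r_h) / (1 - r_h) if r_h else None
            for H in cfg.cell_units[:-1]]
        r_o = cfg.rate("output")
        masks["out"] = (
            (rng.random((batch, cfg.cell_units[-1])) >= r_o) / (1 - r_o)
            if r_o else None)
        return masks

    def forward(self, inputs: np.ndarray, train: bool = False,
                dropout_seed: int = 0) -> tuple[np.ndarray, dict]:
        """Teacher-forced pass.  ``inputs``: (B, T) int token indices.

        Returns logits (B, T, V) and a cache for :meth:`backward`.
        """
        inputs = np.asarray(inputs)
        B, T = inputs.shape
        cfg = self.config
        masks = self._train_masks(B, dropout_seed) if train else {
            "params": self.params, "emb": None,
            "hidden": [None] * (len(cfg.cell_units) - 1), "out": None}
        p = masks["params"]
        emb_table = self.params["embedding"]
        if masks["emb"] is not None:
            emb_table = emb_table * masks["emb"]
        x = emb_table[inputs]                                   # (B,T,E)
        cache: dict = {"inputs": inputs, "masks": masks, "layers": [], "x0": x}
        layer_in = x
        for l, H in enumerate(cfg.cell_units):
            W, U, b = p[f"W_{l}"], p[f"U_{l}"], p[f"b_{l}"]
            h = np.zeros((B, H))
            c = np.zeros((B, H))
            steps = []
            hs = np.empty((B, T, H))
            for t in range(T):
                xt = layer_in[:, t]
                z = xt @ W.T + h @ U.T + b
                i = _sigmoid(z[:, :H])
                f = _sigmoid(z[:, H:2 * H])
                o = _sigmoid(z[:, 2 * H:3 * H])
                g = np.tanh(z[:, 3 * H:])
                c_new = f * c + i * g
                tanh_c = np.tanh(c_new)
                h = o * tanh_c
                steps.append({"x": xt, "h_prev": None, "c_prev": c,
                              "i": i, "f": f, "o": o, "g": g, "tanh_c": tanh_c})
                steps[-1]["h_prev"] = hs[:, t - 1] if t else np.zeros((B, H))
                hs[:, t] = h
                c = c_new
            cache["layers"].append({"steps": steps, "hs": hs, "input": layer_in})
            layer_in = hs
            if l < len(cfg.cell_units) - 1 and masks["hidden"][l] is not None:
                layer_in = layer_in * masks["hidden"][l][:, None, :]
                cache["layers"][-1]["out_masked"] = layer_in
        top = layer_in
        if masks["out"] is not None:
            top = top * masks["out"][:, None, :]
        cache["top"] = top
        logits = top @ p["decoder_W"].T + p["decoder_b"]
        return logits, cache

    def backward(self, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        """BPTT given d(objective)/d(logits); returns gradients for Theta."""
        cfg = self.config
        masks = cache["masks"]
        p = masks["params"]
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        top = cache["top"]
        B, T, _ = dlogits.shape
        grads["decoder_W"] = np.einsum("btv,bth->vh", dlogits, top)
        grads["decoder_b"] = dlogits.sum(axis=(0, 1))
        dtop = dlogits @ p["decoder_W"]
        if masks["out"] is not None:
            dtop = dtop * masks["out"][:, None, :]
        d_layer_out = dtop
        for l in range(len(cfg.cell_units) - 1, -1, -1):
            layer = cache["layers"][l]
            if l < len(cfg.cell_units) - 1 and masks["hidden"][l] is not None:
                d_layer_out = d_layer_out * masks["hidden"][l][:, None, :]
            H = cfg.cell_units[l]
            W, U = p[f"W_{l}"], p[f"U_{l}"]
            dW = np.zeros_like(W)
            dU = np.zeros_like(U)
            db = np.zeros(4 * H)
            d_input = np.zeros_like(layer["input"])
            dh_next = np.zeros((B, H))
            dc_next = np.zeros((B, H))
            for t in range(T - 1, -1, -1):
                s = layer["steps"][t]
                dh = d_layer_out[:, t] + dh_next
                do = dh * s["tanh_c"]
                dc = dh * s["o"] * (1 - s["tanh_c"] ** 2) + dc_next
                df = dc * s["c_prev"]
                di = dc * s["g"]
                dg = dc * s["i"]
                dc_next = dc * s["f"]
                dz = np.concatenate([
                    di * s["i"] * (1 - s["i"]),
                    df * s["f"] * (1 - s["f"]),
                    do * s["o"] * (1 - s["o"]),
                    dg * (1 - s["g"] ** 2)], axis=1)
                dW += dz.T @ s["x"]
                dU += dz.T @ s["h_prev"]
                db += dz.sum(axis=0)
                d_input[:, t] = dz @ W
                dh_next = dz @ U
            grads[f"W_{l}"] = dW
            grads[f"b_{l}"] = db
            if cfg.rate("weight") > 0 and masks["params"] is not self.params:
                # U was masked+scaled; chain rule through the elementwise mask
                scale_mask = np.where(self.params[f"U_{l}"] != 0,
                                      p[f"U_{l}"] / self.params[f"U_{l}"], 0.0)
                grads[f"U_{l}"] = dU * scale_mask
            else:
                grads[f"U_{l}"] = dU
            d_layer_out = d_input
        demb = np.zeros_like(self.params["embedding"])
        np.add.at(demb, cache["inputs"].reshape(-1),
                  d_layer_out.reshape(-1, cfg.embedding_dim))
        if masks["emb"] is not None:
            demb = demb * masks["emb"]
        grads["embedding"] = demb
        return grads

    # -- inference ---------------------------------------------------------

    def next_token_distribution(self, prefix: Sequence[int]) -> np.ndarray:
        """p(token | prefix); the prefix excludes the leading break token."""
        inputs = np.array([[self.vocab.break_index] + list(prefix)])
        logits, _ = self.forward(inputs)
        return softmax(logits[0, -1])

    def sample(self, n: int, rng: np.random.Generator,
               max_length: int | None = None
               ) -> tuple[list[TokenSequence], list[np.ndarray]]:
        """Draw ``n`` sequences autoregressively (temperature 1).

        Returns sequences and their per-token log-probabilities.  A
        sequence ends at the break token or at the length cap, in which
        case it is flagged ``terminated_by_cap``.
        """
        cfg = self.config
        max_length = max_length or cfg.max_sequence_length
        B = n
        p = self.params
        h = [np.zeros((B, H)) for H in cfg.cell_units]
        c = [np.zeros((B, H)) for H in cfg.cell_units]
        tokens = np.full((B,), self.vocab.break_index)
        active = np.ones(B, bool)
        out_tokens: list[list[int]] = [[] for _ in range(B)]
        out_logps: list[list[float]] = [[] for _ in range(B)]
        capped = np.zeros(B, bool)
        for _ in range(max_length):
            x = p["embedding"][tokens]
            for l, H in enumerate(cfg.cell_units):
                h[l], c[l] = cell_step(x, h[l], c[l],
                                       p[f"W_{l}"], p[f"U_{l}"], p[f"b_{l}"])
                x = h[l]
            logits = x @ p["decoder_W"].T + p["decoder_b"]
            logp = log_softmax(logits)
            probs = np.exp(logp)
            # vectorized categorical draw
            u = rng.random(B)
            next_tok = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
            next_tok = np.minimum(next_tok, cfg.vocab_size - 1)
            for b in range(B):
                if not active[b]:
                    continue
                out_tokens[b].append(int(next_tok[b]))
                out_logps[b].append(float(logp[b, next_tok[b]]))
                if next_tok[b] == self.vocab.break_index:
                    active[b] = False
            tokens = next_tok
            if not active.any():
                break
        capped[active] = True
        seqs = [TokenSequence(indices=toks,
                              terminated=True,
                              terminated_by_cap=bool(capped[b]))
                for b, toks in enumerate(out_tokens)]
        return seqs, [np.array(lp) for lp in out_logps]

    def sequence_log_prob(self, seq: TokenSequence | Sequence[int],
                          params: dict[str, np.ndarray] | None = None
                          ) -> tuple[float, np.ndarray]:
        """Total and per-token log p(seq) under Theta (or given parameters)."""
        indices = seq.indices if isinstance(seq, TokenSequence) else list(seq)
        saved = self.params
        if params is not None:
            self.params = params
        try:
            inputs = np.array([[self.vocab.break_index] + indices[:-1]])
            logits, _ = self.forward(inputs)
        finally:
            self.params = saved
        logp = log_softmax(logits[0])
        per_token = logp[np.arange(len(indices)), indices]
        return float(per_token.sum()), per_token

    def decode_samples(self, seqs: Iterable[TokenSequence]):
        return [decode_sequence(s, self.vocab) for s in seqs]

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "params.npz", **self.params)
        meta = {"config": asdict(self.config), "vocab": list(self.vocab.tokens),
                "step_count": self.step_count, "seed": self.seed}
        (path / "meta.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path) -> "LSTMPolicy":
        path = Path(path)
        meta = json.loads((path / "meta.json").read_text())
        cfg_d = meta["config"]
        cfg_d["cell_units"] = tuple(cfg_d["cell_units"])
        cfg = GeneratorConfig(**cfg_d)
        vocab = TokenVocabulary(tuple(meta["vocab"]))
        policy = cls(vocab, cfg, seed=meta["seed"])
        with np.load(path / "params.npz") as data:
            policy.params = {k: data[k] for k in data.files}
        policy.step_count = meta["step_count"]
        return policy


# ---------------------------------------------------------------------------
# losses and optimization


def cross_entropy(logits: np.ndarray, targets: np.ndarray, mask: np.ndarray
                  ) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy over unmasked positions + d/dlogits."""
    logp = log_softmax(logits)
    B, T, V = logits.shape
    picked = np.take_along_axis(logp, targets[..., None], axis=2)[..., 0]
    n = mask.sum()
    loss = -(picked * mask).sum() / n
    dlogits = np.exp(logp)
    flat = dlogits.reshape(-1, V)
    flat[np.arange(B * T), targets.reshape(-1)] -= 1.0
    dlogits = dlogits * mask[..., None] / n
    return float(loss), dlogits


class Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float = 5e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
             lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1, b2 = self.betas
        for k, g in grads.items():
            if self.weight_decay and k != "decoder_b" and not k.startswith("b_"):
                g = g + self.weight_decay * params[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)


def one_cycle_lr(step: int, total_steps: int, max_lr: float,
                 warmup_frac: float = 0.3, start_div: float = 25.0,
                 final_div: float = 1e4) -> float:
    """One-cycle schedule: cosine ramp to ``max_lr`` then cosine anneal."""
    warm = max(int(total_steps * warmup_frac), 1)
    if step < warm:
        frac = step / warm
        lo = max_lr / start_div
        return lo + (max_lr - lo) * (1 - math.cos(math.pi * frac)) / 2
    frac = (step - warm) / max(total_steps - warm, 1)
    lo = max_lr / final_div
    return lo + (max_lr - lo) * (1 + math.cos(math.pi * frac)) / 2


# ---------------------------------------------------------------------------
# training


@dataclass
class PretrainSchedule:
    epochs: int = 10
    batch_size: int = 64
    max_lr: float = 5e-4
    weight_decay: float = 0.01
    validation_fraction: float = 0.05
    shuffle_seed: int = 0
    train_dropout: bool = True


def _batches(seqs: list[list[int]], batch_size: int, rng: np.random.Generator,
             pad: int) -> Iterable[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    order = rng.permutation(len(seqs))
    # length-sorted buckets cut padding cost; buckets themselves shuffled
    order = sorted(order, key=lambda i: len(seqs[i]) + rng.random())
    chunks = [order[i:i + batch_size] for i in range(0, len(order), batch_size)]
    rng.shuffle(chunks)
    for chunk in chunks:
        T = max(len(seqs[i]) for i in chunk)
        inputs = np.full((len(chunk), T), pad)
        targets = np.zeros((len(chunk), T), dtype=int)
        mask = np.zeros((len(chunk), T))
        for row, i in enumerate(chunk):
            s = seqs[i]
            inputs[row, 0] = pad
            inputs[row, 1:len(s)] = s[:-1]
            targets[row, :len(s)] = s
            mask[row, :len(s)] = 1.0
        yield inputs, targets, mask


def _evaluate_ce(policy: LSTMPolicy, seqs: list[list[int]],
                 batch_size: int) -> float:
    rng = np.random.default_rng(0)
    total, count = 0.0, 0
    for inputs, targets, mask in _batches(seqs, batch_size, rng,
                                          policy.vocab.break_index):
        logits, _ = policy.forward(inputs)
        loss, _ = cross_entropy(logits, targets, mask)
        n = mask.sum()
        total += loss * n
        count += n
    return total / count


def corpus_to_sequences(corpus: Sequence[str], vocab: TokenVocabulary,
                        max_tokens: int) -> list[list[int]]:
    seqs = []
    for lineno, smiles in enumerate(corpus, start=1):
        try:
            seqs.append(encode_sequence(smiles, vocab, max_tokens).indices)
        except KeyError as exc:
            raise ValueError(
                f"line {lineno}: token {exc} missing from vocabulary") from exc
        except StringEncodingError:
            continue
    if not seqs:
        raise ValueError("no corpus molecule could be encoded")
    return seqs


def pretrain(corpus: Sequence[str], vocab: TokenVocabulary | None = None,
             config: GeneratorConfig | None = None,
             schedule: PretrainSchedule | None = None,
             seed: int = 0, verbose: bool = False
             ) -> tuple[LSTMPolicy, dict[str, list[float]]]:
    """Supervised pretraining by teacher-forced cross-entropy (break token
    appended to every sequence), Adam + one-cycle learning rate.

    Returns the trained policy and per-epoch train/validation loss curves.
    """
    from .strings import build_vocabulary
    schedule = schedule or PretrainSchedule()
    if vocab is None:
        vocab = build_vocabulary(corpus)
    policy = LSTMPolicy(vocab, config, seed=seed)
    seqs = corpus_to_sequences(corpus, vocab, policy.config.max_sequence_length)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(seqs))
    n_val = max(int(len(seqs) * schedule.validation_fraction), 1) \
        if len(seqs) > 1 else 0
    val_seqs = [seqs[i] for i in perm[:n_val]]
    train_seqs = [seqs[i] for i in perm[n_val:]] or val_seqs
    opt = Adam(policy.params, lr=schedule.max_lr,
               weight_decay=schedule.weight_decay)
    steps_per_epoch = math.ceil(len(train_seqs) / schedule.batch_size)
    total_steps = steps_per_epoch * schedule.epochs
    history: dict[str, list[float]] = {"train": [], "validation": []}
    step = 0
    for epoch in range(schedule.epochs):
        epoch_loss, epoch_n = 0.0, 0
        for inputs, targets, mask in _batches(train_seqs, schedule.batch_size,
                                              rng, vocab.break_index):
            train = schedule.train_dropout
            logits, cache = policy.forward(
                inputs, train=train, dropout_seed=int(rng.integers(2 ** 31)))
            loss, dlogits = cross_entropy(logits, targets, mask)
            grads = policy.backward(cache, dlogits)
            opt.step(policy.params, grads,
                     lr=one_cycle_lr(step, total_steps, schedule.max_lr))
            step += 1
            policy.step_count += 1
            epoch_loss += loss * mask.sum()
            epoch_n += mask.sum()
        history["train"].append(epoch_loss / epoch_n)
        history["validation"].append(
            _evaluate_ce(policy, val_seqs or train_seqs, schedule.batch_size))
        if verbose:
            print(f"epoch {epoch + 1}: train CE {history['train'][-1]:.4f} "
                  f"val CE {history['validation'][-1]:.4f}")
    return policy, history


def finetune(policy: LSTMPolicy, substructure_corpus: Sequence[str],
             epochs: int = 5, max_lr: float = 1e-4, batch_size: int = 32,
             seed: int = 0) -> LSTMPolicy:
    """Continue cross-entropy training on a scaffold-bearing corpus.

    Shifts sampling toward the scaffold; the caller keeps the original
    policy (a copy is trained and returned).
    """
    if len(substructure_corpus) == 0:
        raise ValueError("empty fine-tuning corpus")
    tuned = policy.clone()
    seqs = corpus_to_sequences(substructure_corpus, tuned.vocab,
                               tuned.config.max_sequence_length)
    rng = np.random.default_rng(seed)
    opt = Adam(tuned.params, lr=max_lr)
    total_steps = math.ceil(len(seqs) / batch_size) * epochs
    step = 0
    for _ in range(epochs):
        for inputs, targets, mask in _batches(seqs, batch_size, rng,
                                              tuned.vocab.break_index):
            logits, cache = tuned.forward(inputs)
            _, dlogits = cross_entropy(logits, targets, mask)
            grads = tuned.backward(cache, dlogits)
            opt.step(tuned.params, grads,
                     lr=one_cycle_lr(step, total_steps, max_lr))
            step += 1
            tuned.step_count += 1
    return tuned
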