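"""Character-level recurrent language model over DNA reads.

A plain tanh RNN: per layer the hidden state is

    s_t = tanh(U x_t + W s_{t-1} + b)

with a softmax projection of the top state onto the four-letter vocabulary
(A, C, G, T).  Model quality is reported as perplexity, the exponential of
the mean next-character cross-entropy; an all-zero (or untrained) model is
uniform and scores perplexity 4.

Training is truncated backpropagation through time with Adam and global
gradient-norm clipping.  The hidden state is reset at read boundaries (reads
are independent molecules) and reads containing N are excluded from
training.  All randomness (initialization, shuffling, train/validation
split) derives from ``RNNConfig.seed``, so training is bit-reproducible.

The production default mirrors a 2x300 architecture with mini-batch 200 and
learning rate 2e-3; tests use much smaller desk-scale models.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .readset_io import ReadSet

__all__ = [
    "RNNError",
    "RNNConfig",
    "RNNModel",
    "rnn_step",
    "train_rnn",
    "rnn_perplexity",
    "save_rnn",
    "load_rnn",
]

VOCAB = "ACGT"
_CHAR_TO_INDEX = {c: i for i, c in enumerate(VOCAB)}


class RNNError(RuntimeError):
    """Invalid configuration, undersized corpus, or non-finite training loss."""


@dataclass
class RNNConfig:
    """Hyper-parameters of the character RNN.

    ``bptt_length`` is the truncation window in characters; ``train_fraction``
    is the share of reads used for training (the rest validate the
    best-so-far checkpoint).
    """

    num_layers: int = 2
    hidden_size: int = 300
    batch_size: int = 200
    learning_rate: float = 2e-3
    bptt_length: int = 50
    epochs: int = 5
    seed: int = 0
    train_fraction: float = 0.9
    grad_clip: float = 5.0
    init_scale: float = 0.08

    def __post_init__(self) -> None:
        for name in ("num_layers", "hidden_size", "batch_size", "bptt_length", "epochs"):
            if getattr(self, name) < 1:
                raise RNNError(f"{name} must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise RNNError("train_fraction must lie strictly between 0 and 1")
        if self.learning_rate <= 0:
            raise RNNError("learning_rate must be > 0")


class RNNModel:
    """Weights and step function of the tanh RNN.

    Parameters per layer l: input matrix ``U[l]``, recurrent matrix ``W[l]``
    and bias ``b[l]``; the output projection ``V``/``c`` maps the top hidden
    state to 4 logits.
    """

    def __init__(self, config: RNNConfig, params: dict[str, np.ndarray] | None = None):
        self.config = config
        H = config.hidden_size
        if params is not None:
            self.params = params
        else:
            rng = np.random.default_rng(config.seed)
            scale = config.init_scale
            self.params = {}
            for l in range(config.num_layers):
                in_dim = 4 if l == 0 else H
                self.params[f"U{l}"] = rng.uniform(-scale, scale, (in_dim, H))
                self.params[f"W{l}"] = rng.uniform(-scale, scale, (H, H))
                self.params[f"b{l}"] = np.zeros(H)
            self.params["V"] = rng.uniform(-scale, scale, (H, 4))
            self.params["c"] = np.zeros(4)

    def zero_state(self, batch: int = 1) -> list[np.ndarray]:
        H = self.config.hidden_size
        return [np.zeros((batch, H)) for _ in range(self.config.num_layers)]

    def forward_batch(
        self, x_indices: np.ndarray, states: list[np.ndarray]
    ) -> tuple[list[np.ndarray], np.ndarray]:
        """One time step for a batch of character indices (shape (B,)).

        Returns the new per-layer states and the (B, 4) probability rows.
        Out-of-vocabulary indices (< 0) propagate a zero input vector; their
        outputs must be masked by the caller.
        """
        B = x_indices.shape[0]
        x = np.zeros((B, 4))
        valid = x_indices >= 0
        x[valid, x_indices[valid]] = 1.0
        new_states = []
        inp = x
        for l in range(self.config.num_layers):
            a = inp @ self.params[f"U{l}"] + states[l] @ self.params[f"W{l}"] + self.params[f"b{l}"]
            s = np.tanh(a)
            new_states.append(s)
            inp = s
        logits = inp @ self.params["V"] + self.params["c"]
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        return new_states, probs


def rnn_step(
    model: RNNModel, prev_states: list[np.ndarray] | None, input_char: str
) -> tuple[list[np.ndarray], np.ndarray]:
    """Advance the RNN by one character; return (next states, P(next char)).

    The returned distribution is over (A, C, G, T) and sums to 1.
    """
    if input_char not in _CHAR_TO_INDEX:
        raise RNNError(f"character {input_char!r} outside vocabulary {VOCAB}")
    if prev_states is None:
        prev_states = model.zero_state(1)
    states_2d = [np.atleast_2d(s) for s in prev_states]
    new_states, probs = model.forward_batch(
        np.array([_CHAR_TO_INDEX[input_char]]), states_2d
    )
    return [s[0] for s in new_states], probs[0]


def _encode_reads(rs: ReadSet, skip_n: bool) -> list[np.ndarray]:
    seqs = []
    for read in rs:
        seq = read.sequence
        if "N" in seq:
            if skip_n:
                continue
            seq = seq.split("N", 1)[0]  # score only positions before the first N
            if len(seq) < 2:
                continue
        seqs.append(np.fromiter((_CHAR_TO_INDEX[c] for c in seq), dtype=np.int64))
    return seqs


def _pad_batch(seqs: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Stack variable-length index arrays into (B, T) inputs plus a validity mask."""
    T = max(len(s) for s in seqs)
    batch = np.full((len(seqs), T), -1, dtype=np.int64)
    for i, s in enumerate(seqs):
        batch[i, : len(s)] = s
    mask = batch >= 0
    return batch, mask


def _cross_entropy(model: RNNModel, seqs: list[np.ndarray], batch_size: int = 512) -> tuple[float, int]:
    """Summed next-character negative log-likelihood and transition count."""
    total, count = 0.0, 0
    for lo in range(0, len(seqs), batch_size):
        chunk = seqs[lo : lo + batch_size]
        batch, mask = _pad_batch(chunk)
        B, T = batch.shape
        states = model.zero_state(B)
        for t in range(T - 1):
            states, probs = model.forward_batch(batch[:, t], states)
            valid = mask[:, t] & mask[:, t + 1]
            if valid.any():
                targets = batch[valid, t + 1]
                total -= np.log(probs[valid, targets]).sum()
                count += int(valid.sum())
    return total, count


def rnn_perplexity(model: RNNModel, rs: ReadSet) -> float:
    """exp(mean cross-entropy) of `rs` under `model`.

    The state is reset per read; positions at or after the first N in a read
    are skipped.  Raises :class:`RNNError` if no transition is scorable.
    """
    seqs = [s for s in _encode_reads(rs, skip_n=False) if len(s) >= 2]
    if not seqs:
        raise RNNError("no scorable character transitions")
    total, count = _cross_entropy(model, seqs)
    if count == 0:
        raise RNNError("no scorable character transitions")
    return math.exp(total / count)


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        corr1 = 1 - b1**self.t
        corr2 = 1 - b2**self.t
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            params[k] -= self.lr * (self.m[k] / corr1) / (np.sqrt(self.v[k] / corr2) + eps)


def _clip_global_norm(grads: dict[str, np.ndarray], max_norm: float) -> None:
    norm = math.sqrt(sum(float((g * g).sum()) for g in grads.values()))
    if norm > max_norm > 0:
        scale = max_norm / norm
        for g in grads.values():
            g *= scale


def _bptt_chunk(
    model: RNNModel,
    inputs: np.ndarray,
    targets: np.ndarray,
    mask: np.ndarray,
    states: list[np.ndarray],
) -> tuple[float, int, dict[str, np.ndarray], list[np.ndarray]]:
    """Forward + backward over one truncated window.

    `inputs`, `targets`, `mask` have shape (B, T); returns summed loss,
    number of predicted characters, parameter gradients of the mean loss and
    the detached final states.
    """
    p = model.params
    L = model.config.num_layers
    B, T = inputs.shape
    states_hist: list[list[np.ndarray]] = [states]
    probs_hist: list[np.ndarray] = []
    xs: list[np.ndarray] = []
    for t in range(T):
        new_states, probs = model.forward_batch(inputs[:, t], states_hist[-1])
        states_hist.append(new_states)
        probs_hist.append(probs)
        x = np.zeros((B, 4))
        valid_in = inputs[:, t] >= 0
        x[valid_in, inputs[:, t][valid_in]] = 1.0
        xs.append(x)
    n_pred = int(mask.sum())
    if n_pred == 0:
        return 0.0, 0, {k: np.zeros_like(v) for k, v in p.items()}, states_hist[-1]
    loss = 0.0
    grads = {k: np.zeros_like(v) for k, v in p.items()}
    dstate_carry = [np.zeros_like(s) for s in states]
    for t in range(T - 1, -1, -1):
        probs = probs_hist[t]
        dlogits = np.zeros_like(probs)
        m_t = mask[:, t]
        if m_t.any():
            rows = np.flatnonzero(m_t)
            tgt = targets[rows, t]
            loss -= float(np.log(probs[rows, tgt]).sum())
            dlogits[rows] = probs[rows] / n_pred
            dlogits[rows, tgt] -= 1.0 / n_pred
        s_top = states_hist[t + 1][L - 1]
        grads["V"] += s_top.T @ dlogits
        grads["c"] += dlogits.sum(axis=0)
        d_above = dlogits @ p["V"].T
        for l in range(L - 1, -1, -1):
            s = states_hist[t + 1][l]
            ds = d_above + dstate_carry[l]
            da = ds * (1.0 - s * s)
            x_in = xs[t] if l == 0 else states_hist[t + 1][l - 1]
            grads[f"U{l}"] += x_in.T @ da
            grads[f"W{l}"] += states_hist[t][l].T @ da
            grads[f"b{l}"] += da.sum(axis=0)
            dstate_carry[l] = da @ p[f"W{l}"].T
            d_above = da @ p[f"U{l}"].T if l > 0 else None
    return loss, n_pred, grads, states_hist[-1]


def train_rnn(rs: ReadSet, config: RNNConfig) -> RNNModel:
    """Train a character RNN on `rs` per `config`.

    Reads containing N are skipped.  Validation cross-entropy is evaluated
    each epoch on the held-out split and the best-so-far weights are kept, so
    the reported model never regresses across epochs.  Raises
    :class:`RNNError` for an undersized corpus or a non-finite loss.
    """
    seqs = _encode_reads(rs, skip_n=True)
    seqs = [s for s in seqs if len(s) >= 2]
    total_chars = sum(len(s) for s in seqs)
    if total_chars < config.bptt_length:
        raise RNNError(
            f"corpus too small: {total_chars} usable characters "
            f"< bptt_length {config.bptt_length}"
        )
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(seqs))
    if len(seqs) >= 2:
        n_train = min(len(seqs) - 1, max(1, int(round(config.train_fraction * len(seqs)))))
        train_seqs = [seqs[i] for i in order[:n_train]]
        val_seqs = [seqs[i] for i in order[n_train:]]
    else:
        train_seqs = val_seqs = seqs
    model = RNNModel(config)
    opt = _Adam(model.params, config.learning_rate)
    best_ce = math.inf
    best_params = {k: v.copy() for k, v in model.params.items()}
    for epoch in range(config.epochs):
        perm = rng.permutation(len(train_seqs))
        for lo in range(0, len(perm), config.batch_size):
            chunk = [train_seqs[i] for i in perm[lo : lo + config.batch_size]]
            batch, mask = _pad_batch(chunk)
            B, T = batch.shape
            states = model.zero_state(B)
            for c0 in range(0, T - 1, config.bptt_length):
                c1 = min(c0 + config.bptt_length, T - 1)
                inputs = batch[:, c0:c1]
                targets = batch[:, c0 + 1 : c1 + 1]
                step_mask = mask[:, c0:c1] & mask[:, c0 + 1 : c1 + 1]
                loss, n_pred, grads, states = _bptt_chunk(
                    model, inputs, targets, step_mask, states
                )
                if n_pred == 0:
                    continue
                if not math.isfinite(loss):
                    raise RNNError(f"non-finite training loss at epoch {epoch}")
                _clip_global_norm(grads, config.grad_clip)
                opt.step(model.params, grads)
        val_total, val_count = _cross_entropy(model, val_seqs)
        val_ce = val_total / max(val_count, 1)
        if not math.isfinite(val_ce):
            raise RNNError(f"non-finite validation loss at epoch {epoch}")
        if val_ce < best_ce:
            best_ce = val_ce
            best_params = {k: v.copy() for k, v in model.params.items()}
    model.params = best_params
    return model


def save_rnn(model: RNNModel, path: str | Path) -> Path:
    """Persist weights as an ``.npz`` archive with a JSON config sidecar."""
    path = Path(path)
    np.savez(path, **model.params)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    sidecar = Path(str(path) + ".json")
    sidecar.write_text(json.dumps(asdict(model.config), indent=2))
    return path


def load_rnn(path: str | Path) -> RNNModel:
    path = Path(path)
    sidecar = Path(str(path) + ".json")
    if not path.exists() or not sidecar.exists():
        raise RNNError(f"missing model archive or sidecar for {path}")
    config = RNNConfig(**json.loads(sidecar.read_text()))
    with np.load(path) as archive:
        params = {k: archive[k] for k in archive.files}
    return RNNModel(config, params=params)
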