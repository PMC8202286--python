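"""Probabilistic endpoint classifiers over template sentences.

Two interchangeable kinds sit behind one contract (train on a labeled split,
emit a per-report positive-endpoint probability):

* ``token-logistic`` — logistic regression on binary token-presence features,
  fitted by deterministic full-batch gradient descent.  Fast and bitwise
  reproducible; the workhorse for simulation studies.
* ``transformer`` — a small bidirectional self-attention encoder trained from
  scratch (learned token + position embeddings, multi-head attention,
  post-layer-norm residual blocks, and a two-way softmax head on the CLS
  token).  Written in numpy with manual backpropagation.

Training records a trace of (step, dev loss, dev accuracy) at every
checkpoint and restores the parameters of the checkpoint with maximum dev
accuracy (ties broken toward the earliest step).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .data_model import ProbabilityTable, SentenceRecord

__all__ = [
    "ClassifierConfig",
    "TrainingTrace",
    "TokenLogisticModel",
    "TransformerModel",
    "train_classifier",
    "predict_proba",
    "cross_entropy",
    "evaluate_accuracy",
    "CrossEntropy",
    "save_model",
    "load_model",
]

PAD, OOV, CLS = 0, 1, 2


@dataclass(frozen=True)
class ClassifierConfig:
    kind: str = "token-logistic"  # or "transformer"
    max_seq_len: int = 64
    batch_size: int = 32
    total_steps: int = 300
    warmup_steps: int = 30
    checkpoint_every: int = 50
    learning_rate: float = 0.5  # GD step for token-logistic; Adam lr ~1e-3 for transformer
    hidden_size: int = 32
    n_layers: int = 2
    n_heads: int = 4
    ffn_size: int = 64
    weight_decay: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("token-logistic", "transformer"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.checkpoint_every > self.total_steps:
            raise ValueError("checkpoint_every must be <= total_steps")
        if self.hidden_size % self.n_heads:
            raise ValueError("hidden_size must be divisible by n_heads")


class TraceEntry(NamedTuple):
    step: int
    dev_loss: float
    dev_accuracy: float


@dataclass
class TrainingTrace:
    entries: list[TraceEntry] = field(default_factory=list)

    def append(self, step: int, dev_loss: float, dev_accuracy: float) -> None:
        if self.entries and step <= self.entries[-1].step:
            raise ValueError("trace steps must be strictly increasing")
        if not 0.0 <= dev_accuracy <= 1.0:
            raise ValueError("accuracy must lie in [0, 1]")
        self.entries.append(TraceEntry(step, dev_loss, dev_accuracy))

    @property
    def best(self) -> TraceEntry:
        """Checkpoint with maximum dev accuracy, earliest step on ties."""
        return max(self.entries, key=lambda e: (e.dev_accuracy, -e.step))

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("step\tdev_loss\tdev_accuracy\n")
            for e in self.entries:
                fh.write(f"{e.step}\t{e.dev_loss!r}\t{e.dev_accuracy!r}\n")


def _tokenize(text: str) -> list[str]:
    return text.lower().split()


def _build_vocab(records: Sequence[SentenceRecord]) -> dict[str, int]:
    vocab: dict[str, int] = {}
    for r in records:
        for tok in _tokenize(r.text):
            if tok not in vocab:
                vocab[tok] = len(vocab) + 3  # reserve PAD/OOV/CLS
    return vocab


# ---------------------------------------------------------------------------
# Token-logistic baseline
# ---------------------------------------------------------------------------


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


class TokenLogisticModel:
    """Logistic regression on binary token-presence features."""

    def __init__(self, vocab: dict[str, int]):
        self.vocab = vocab
        self.w = np.zeros(len(vocab))
        self.b = 0.0
        self._index = {tok: i for i, tok in enumerate(vocab)}

    def _features(self, records: Sequence[SentenceRecord]) -> np.ndarray:
        X = np.zeros((len(records), len(self.vocab)))
        for i, r in enumerate(records):
            for tok in _tokenize(r.text):
                j = self._index.get(tok)
                if j is not None:  # unseen tokens fall into an implicit OOV bucket
                    X[i, j] = 1.0
        return X

    def predict_proba_array(self, records: Sequence[SentenceRecord]) -> np.ndarray:
        return _sigmoid(self._features(records) @ self.w + self.b)

    def fit(
        self, train: Sequence[SentenceRecord], dev: Sequence[SentenceRecord],
        config: ClassifierConfig,
    ) -> TrainingTrace:
        X = self._features(train)
        y = np.array([r.label for r in train], dtype=float)
        Xd = self._features(dev)
        yd = np.array([r.label for r in dev], dtype=float)
        trace = TrainingTrace()
        checkpoints: dict[int, tuple[np.ndarray, float]] = {}
        n = len(train)
        step = 0
        while step < config.total_steps:
            step += 1
            p = _sigmoid(X @ self.w + self.b)
            gw = X.T @ (p - y) / n + config.weight_decay * self.w
            gb = float(np.mean(p - y))
            self.w -= config.learning_rate * gw
            self.b -= config.learning_rate * gb
            if step % config.checkpoint_every == 0 or step == config.total_steps:
                pd = _sigmoid(Xd @ self.w + self.b)
                loss = cross_entropy(pd, yd).mean
                acc = float(np.mean((pd >= 0.5) == yd))
                trace.append(step, loss, acc)
                checkpoints[step] = (self.w.copy(), self.b)
        best = trace.best
        self.w, self.b = checkpoints[best.step]
        return trace


# ---------------------------------------------------------------------------
# From-scratch transformer encoder (numpy, manual backprop)
# ---------------------------------------------------------------------------


def _layer_norm(x: np.ndarray, g: np.ndarray, b: np.ndarray, eps: float = 1e-5):
    mu = x.mean(-1, keepdims=True)
    var = x.var(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv
    return g * xhat + b, (xhat, inv)


def _layer_norm_backward(dy: np.ndarray, g: np.ndarray, cache):
    xhat, inv = cache
    dxhat = dy * g
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    m = xhat.shape[-1]
    dx = inv * (
        dxhat
        - dxhat.mean(-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(-1, keepdims=True)
    )
    return dx, dg, db


class TransformerModel:
    """Small bidirectional self-attention encoder with a CLS softmax head."""

    def __init__(self, vocab: dict[str, int], config: ClassifierConfig):
        self.vocab = vocab
        self.config = config
        rng = np.random.default_rng(config.seed)
        d, f, L = config.hidden_size, config.ffn_size, config.n_layers
        V = len(vocab) + 3
        s = 0.02
        self.params: dict[str, np.ndarray] = {
            "E": rng.normal(0, s, (V, d)),
            "P": rng.normal(0, s, (config.max_seq_len + 1, d)),
            "Wc": rng.normal(0, s, (d, 2)),
            "bc": np.zeros(2),
        }
        for layer in range(L):
            p = self.params
            for name in ("Wq", "Wk", "Wv", "Wo"):
                p[f"{name}{layer}"] = rng.normal(0, s, (d, d))
                p[f"{name.replace('W', 'b')}{layer}"] = np.zeros(d)
            p[f"g1_{layer}"] = np.ones(d)
            p[f"be1_{layer}"] = np.zeros(d)
            p[f"W1_{layer}"] = rng.normal(0, s, (d, f))
            p[f"b1_{layer}"] = np.zeros(f)
            p[f"W2_{layer}"] = rng.normal(0, s, (f, d))
            p[f"b2_{layer}"] = np.zeros(d)
            p[f"g2_{layer}"] = np.ones(d)
            p[f"be2_{layer}"] = np.zeros(d)

    # -- encoding ----------------------------------------------------------

    def encode(self, records: Sequence[SentenceRecord]):
        T = self.config.max_seq_len + 1  # room for CLS
        ids = np.full((len(records), T), PAD, dtype=np.int64)
        for i, r in enumerate(records):
            toks = [CLS] + [
                self.vocab.get(t, OOV) for t in _tokenize(r.text)
            ][: self.config.max_seq_len]
            ids[i, : len(toks)] = toks
        mask = (ids != PAD).astype(float)
        return ids, mask

    # -- forward / backward ------------------------------------------------

    def _forward(self, ids: np.ndarray, mask: np.ndarray):
        p = self.params
        cfg = self.config
        B, T = ids.shape
        H = cfg.n_heads
        d = cfg.hidden_size
        dh = d // H
        x = p["E"][ids] + p["P"][:T]
        caches = []
        neg = (1.0 - mask)[:, None, None, :] * -1e9  # mask pad keys
        for l in range(cfg.n_layers):
            q = x @ p[f"Wq{l}"] + p[f"bq{l}"]
            k = x @ p[f"Wk{l}"] + p[f"bk{l}"]
            v = x @ p[f"Wv{l}"] + p[f"bv{l}"]
            qh = q.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            kh = k.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            vh = v.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            scores = qh @ kh.transpose(0, 1, 3, 2) / math.sqrt(dh) + neg
            scores -= scores.max(-1, keepdims=True)
            e = np.exp(scores)
            attn = e / e.sum(-1, keepdims=True)
            ctx = (attn @ vh).transpose(0, 2, 1, 3).reshape(B, T, d)
            attn_out = ctx @ p[f"Wo{l}"] + p[f"bo{l}"]
            res1 = x + attn_out
            h1, ln1 = _layer_norm(res1, p[f"g1_{l}"], p[f"be1_{l}"])
            pre = h1 @ p[f"W1_{l}"] + p[f"b1_{l}"]
            act = np.maximum(pre, 0.0)
            ffn = act @ p[f"W2_{l}"] + p[f"b2_{l}"]
            res2 = h1 + ffn
            h2, ln2 = _layer_norm(res2, p[f"g2_{l}"], p[f"be2_{l}"])
            caches.append((x, qh, kh, vh, attn, ctx, ln1, h1, pre, act, ln2))
            x = h2
        cls = x[:, 0, :]
        logits = cls @ p["Wc"] + p["bc"]
        return logits, (ids, mask, caches, cls)

    @staticmethod
    def _softmax(logits: np.ndarray) -> np.ndarray:
        z = logits - logits.max(-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(-1, keepdims=True)

    def loss_and_grads(self, ids: np.ndarray, mask: np.ndarray, labels: np.ndarray):
        """Mean cross-entropy and analytic gradients for one batch."""
        p = self.params
        cfg = self.config
        B, T = ids.shape
        H, d = cfg.n_heads, cfg.hidden_size
        dh = d // H
        logits, (ids, mask, caches, cls) = self._forward(ids, mask)
        probs = self._softmax(logits)
        loss = float(
            -np.mean(np.log(np.clip(probs[np.arange(B), labels], 1e-12, None)))
        )
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dlogits = probs.copy()
        dlogits[np.arange(B), labels] -= 1.0
        dlogits /= B
        grads["Wc"] = cls.T @ dlogits
        grads["bc"] = dlogits.sum(0)
        dx = np.zeros((B, T, d))
        dx[:, 0, :] = dlogits @ p["Wc"].T
        for l in reversed(range(cfg.n_layers)):
            x, qh, kh, vh, attn, ctx, ln1, h1, pre, act, ln2 = caches[l]
            dres2, dg2, dbe2 = _layer_norm_backward(dx, p[f"g2_{l}"], ln2)
            grads[f"g2_{l}"] += dg2
            grads[f"be2_{l}"] += dbe2
            dffn = dres2
            dh1 = dres2.copy()
            dact = dffn @ p[f"W2_{l}"].T
            grads[f"W2_{l}"] += act.reshape(-1, act.shape[-1]).T @ dffn.reshape(-1, d)
            grads[f"b2_{l}"] += dffn.sum((0, 1))
            dpre = dact * (pre > 0)
            grads[f"W1_{l}"] += h1.reshape(-1, d).T @ dpre.reshape(-1, dpre.shape[-1])
            grads[f"b1_{l}"] += dpre.sum((0, 1))
            dh1 += dpre @ p[f"W1_{l}"].T
            dres1, dg1, dbe1 = _layer_norm_backward(dh1, p[f"g1_{l}"], ln1)
            grads[f"g1_{l}"] += dg1
            grads[f"be1_{l}"] += dbe1
            dattn_out = dres1
            dx_l = dres1.copy()
            grads[f"Wo{l}"] += ctx.reshape(-1, d).T @ dattn_out.reshape(-1, d)
            grads[f"bo{l}"] += dattn_out.sum((0, 1))
            dctx = dattn_out @ p[f"Wo{l}"].T
            dctx_h = dctx.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            dattn = dctx_h @ vh.transpose(0, 1, 3, 2)
            dvh = attn.transpose(0, 1, 3, 2) @ dctx_h
            dscores = attn * (dattn - (dattn * attn).sum(-1, keepdims=True))
            dscores /= math.sqrt(dh)
            dqh = dscores @ kh
            dkh = dscores.transpose(0, 1, 3, 2) @ qh
            dq = dqh.transpose(0, 2, 1, 3).reshape(B, T, d)
            dk = dkh.transpose(0, 2, 1, 3).reshape(B, T, d)
            dv = dvh.transpose(0, 2, 1, 3).reshape(B, T, d)
            for name, dmat in (("Wq", dq), ("Wk", dk), ("Wv", dv)):
                grads[f"{name}{l}"] += x.reshape(-1, d).T @ dmat.reshape(-1, d)
                grads[f"{name.replace('W', 'b')}{l}"] += dmat.sum((0, 1))
                dx_l += dmat @ p[f"{name}{l}"].T
            dx = dx_l
        dE = grads["E"]
        np.add.at(dE, ids.reshape(-1), dx.reshape(-1, d))
        grads["P"] += dx.sum(0)
        return loss, grads

    # -- training ----------------------------------------------------------

    def fit(
        self, train: Sequence[SentenceRecord], dev: Sequence[SentenceRecord],
        config: ClassifierConfig,
    ) -> TrainingTrace:
        rng = np.random.default_rng(config.seed + 1)
        ids_tr, mask_tr = self.encode(train)
        y_tr = np.array([r.label for r in train])
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(vv) for k, vv in self.params.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        lr0 = config.learning_rate
        trace = TrainingTrace()
        checkpoints: dict[int, dict[str, np.ndarray]] = {}
        n = len(train)
        for step in range(1, config.total_steps + 1):
            batch = rng.integers(0, n, size=min(config.batch_size, n))
            _, grads = self.loss_and_grads(ids_tr[batch], mask_tr[batch], y_tr[batch])
            warm = min(1.0, step / max(1, config.warmup_steps))
            lr = lr0 * warm
            for k in self.params:
                g = grads[k] + config.weight_decay * self.params[k]
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                mh = m[k] / (1 - b1**step)
                vh = v[k] / (1 - b2**step)
                self.params[k] -= lr * mh / (np.sqrt(vh) + eps)
            if step % config.checkpoint_every == 0 or step == config.total_steps:
                pd = self.predict_proba_array(dev)
                yd = np.array([r.label for r in dev], dtype=float)
                loss = cross_entropy(pd, yd).mean
                acc = float(np.mean((pd >= 0.5) == yd))
                trace.append(step, loss, acc)
                checkpoints[step] = {k: vv.copy() for k, vv in self.params.items()}
        self.params = checkpoints[trace.best.step]
        return trace

    def predict_proba_array(self, records: Sequence[SentenceRecord]) -> np.ndarray:
        ids, mask = self.encode(records)
        out = np.empty(len(records))
        for start in range(0, len(records), 256):
            sl = slice(start, start + 256)
            logits, _ = self._forward(ids[sl], mask[sl])
            out[sl] = self._softmax(logits)[:, 1]
        return out


# ---------------------------------------------------------------------------
# Contract-level entry points
# ---------------------------------------------------------------------------


def train_classifier(
    train: Sequence[SentenceRecord],
    dev: Sequence[SentenceRecord],
    config: ClassifierConfig,
):
    """Fit a classifier of the configured kind; returns (model, trace).

    The returned model's parameters are those of the dev-accuracy-maximizing
    checkpoint (earliest step on ties).
    """
    if not train or not dev:
        raise ValueError("train and dev splits must be nonempty")
    labels = {r.label for r in train}
    if len(labels) < 2:
        raise ValueError("training set contains a single class")
    vocab = _build_vocab(train)
    if config.kind == "token-logistic":
        model: TokenLogisticModel | TransformerModel = TokenLogisticModel(vocab)
    else:
        model = TransformerModel(vocab, config)
    trace = model.fit(train, dev, config)
    return model, trace


def predict_proba(model, records: Sequence[SentenceRecord]) -> ProbabilityTable:
    """Per-report positive-endpoint probability (the classifier's output set)."""
    probs = model.predict_proba_array(records)
    return ProbabilityTable(
        {r.report_id: float(p) for r, p in zip(records, probs)}
    )


class CrossEntropy(NamedTuple):
    total: float
    mean: float


def cross_entropy(probs: Sequence[float], labels: Sequence[int]) -> CrossEntropy:
    """Natural-log cross-entropy of positive-class probabilities vs labels.

    ``probs`` holds the predicted probability of the *positive* class; the
    probability assigned to the true class is clamped at 1e-12 before the log.
    Returns both the summed and the per-instance mean loss.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {y.shape}")
    p_true = np.where(y == 1, p, 1.0 - p)
    logs = np.log(np.clip(p_true, 1e-12, None))
    return CrossEntropy(total=float(-logs.sum()), mean=float(-logs.mean()))


def save_model(model, dirpath) -> None:
    """Persist a fitted model to a directory (vocab + parameters + config)."""
    import json
    from pathlib import Path

    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    if isinstance(model, TokenLogisticModel):
        meta = {"kind": "token-logistic", "vocab": model.vocab}
        np.savez(d / "params.npz", w=model.w, b=np.array([model.b]))
    elif isinstance(model, TransformerModel):
        meta = {
            "kind": "transformer",
            "vocab": model.vocab,
            "config": model.config.__dict__,
        }
        np.savez(d / "params.npz", **model.params)
    else:
        raise TypeError(f"cannot save model of type {type(model).__name__}")
    with open(d / "model.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh)


def load_model(dirpath):
    """Inverse of :func:`save_model`; predictions round-trip exactly."""
    import json
    from pathlib import Path

    d = Path(dirpath)
    with open(d / "model.json", encoding="utf-8") as fh:
        meta = json.load(fh)
    arrays = np.load(d / "params.npz")
    if meta["kind"] == "token-logistic":
        model = TokenLogisticModel(meta["vocab"])
        model.w = arrays["w"]
        model.b = float(arrays["b"][0])
        return model
    model = TransformerModel(meta["vocab"], ClassifierConfig(**meta["config"]))
    model.params = {k: arrays[k] for k in arrays.files}
    return model


def evaluate_accuracy(model, records: Sequence[SentenceRecord], threshold: float = 0.5) -> float:
    """Fraction of records whose thresholded probability matches the label."""
    if not records:
        raise ValueError("empty record set")
    probs = model.predict_proba_array(records)
    labels = np.array([r.label for r in records])
    return float(np.mean((probs >= threshold) == labels))
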