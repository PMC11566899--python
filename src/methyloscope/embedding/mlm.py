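"""Masked-language-model transformer encoder in pure numpy.

A bidirectional pre-LayerNorm transformer (token + learned absolute position
embeddings, multi-head dot-product self-attention, ReLU feed-forward blocks)
trained with cross-entropy on randomly masked token positions.  No
next-sentence objective and no [CLS]/[SEP] tokens: pooling is mean-based, so
the only special tokens are [PAD] and [MASK].

Forward and backward passes are hand-written; the optimizer is Adam.  The
implementation targets desk-scale models (2 layers, 64 dims, vocab ~512) and
is deterministic given the config seed in a fixed thread configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from methyloscope.embedding.bpe import TokenizedCgi, TokenizerModel
from methyloscope.errors import ConfigError, ValidationError

SCHEMA_VERSION = 1


@dataclass
class MlmConfig:
    embed_dim: int = 64
    n_layers: int = 2
    n_heads: int = 4
    ffn_dim: int | None = None  # default 4 x embed_dim
    mask_rate: float = 0.15
    max_tokens: int = 512
    epochs: int = 20
    batch_size: int = 16
    learning_rate: float = 1e-3
    seed: int = 0
    mask_scheme: str = "mask_only"  # or 'bert_80_10_10'
    dtype: str = "float32"  # float32 halves desk-scale training time

    def __post_init__(self):
        if self.embed_dim % self.n_heads != 0:
            raise ConfigError("embed_dim must be divisible by n_heads")
        if not (0.0 < self.mask_rate < 1.0):
            raise ConfigError("mask_rate must be in (0, 1)")
        if self.mask_scheme not in ("mask_only", "bert_80_10_10"):
            raise ConfigError(f"unknown mask_scheme {self.mask_scheme!r}")
        if self.ffn_dim is None:
            self.ffn_dim = 4 * self.embed_dim


def _layer_norm(x, g, b, eps=1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    xhat = (x - mu) / np.sqrt(var + eps)
    return xhat * g + b, (xhat, np.sqrt(var + eps))


def _layer_norm_bwd(dy, g, cache):
    xhat, std = cache
    dxhat = dy * g
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    m = dxhat.mean(axis=-1, keepdims=True)
    mx = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = (dxhat - m - xhat * mx) / std
    return dx, dg, db


def _softmax(x, axis=-1):
    x = x - x.max(axis=axis, keepdims=True)
    e = np.exp(x)
    return e / e.sum(axis=axis, keepdims=True)


class MlmEncoder:
    """Trainable encoder; parameters live in ``self.params`` (name -> array)."""

    PAD = -1  # resolved to concrete ids at construction
    _special = 2  # [PAD], [MASK]

    def __init__(self, tokenizer_vocab_size: int, config: MlmConfig):
        self.config = config
        self.base_vocab = tokenizer_vocab_size
        self.pad_id = tokenizer_vocab_size
        self.mask_id = tokenizer_vocab_size + 1
        self.vocab = tokenizer_vocab_size + self._special
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 9000)))
        D, F, V, L = config.embed_dim, config.ffn_dim, self.vocab, config.max_tokens
        scale = 0.02
        p: dict[str, np.ndarray] = {
            "tok_emb": rng.normal(0, scale, (V, D)),
            "pos_emb": rng.normal(0, scale, (L, D)),
            "lnf_g": np.ones(D), "lnf_b": np.zeros(D),
            "w_out": rng.normal(0, scale, (D, V)), "b_out": np.zeros(V),
        }
        for l in range(config.n_layers):
            p.update({
                f"l{l}_ln1_g": np.ones(D), f"l{l}_ln1_b": np.zeros(D),
                f"l{l}_wq": rng.normal(0, scale, (D, D)), f"l{l}_bq": np.zeros(D),
                f"l{l}_wk": rng.normal(0, scale, (D, D)), f"l{l}_bk": np.zeros(D),
                f"l{l}_wv": rng.normal(0, scale, (D, D)), f"l{l}_bv": np.zeros(D),
                f"l{l}_wo": rng.normal(0, scale, (D, D)), f"l{l}_bo": np.zeros(D),
                f"l{l}_ln2_g": np.ones(D), f"l{l}_ln2_b": np.zeros(D),
                f"l{l}_w1": rng.normal(0, scale, (D, F)), f"l{l}_b1": np.zeros(F),
                f"l{l}_w2": rng.normal(0, scale, (F, D)), f"l{l}_b2": np.zeros(D),
            })
        dtype = np.dtype(config.dtype)
        self.params = {k: v.astype(dtype) for k, v in p.items()}
        self._adam_m = {k: np.zeros_like(v) for k, v in p.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in p.items()}
        self._adam_t = 0
        self.loss_history: list[float] = []

    # ------------------------------------------------------------- forward
    def _forward(self, ids: np.ndarray, pad_mask: np.ndarray):
        """ids, pad_mask: (B, T).  Returns final hidden states and caches."""
        cfg, p = self.config, self.params
        B, T = ids.shape
        H, D = cfg.n_heads, cfg.embed_dim
        dh = D // H
        x = p["tok_emb"][ids] + p["pos_emb"][None, :T, :]
        caches = []
        neg = np.where(pad_mask[:, None, None, :], 0.0, -1e9).astype(x.dtype)
        for l in range(cfg.n_layers):
            a, ln1c = _layer_norm(x, p[f"l{l}_ln1_g"], p[f"l{l}_ln1_b"])
            q = a @ p[f"l{l}_wq"] + p[f"l{l}_bq"]
            k = a @ p[f"l{l}_wk"] + p[f"l{l}_bk"]
            v = a @ p[f"l{l}_wv"] + p[f"l{l}_bv"]
            qh = q.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            kh = k.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            vh = v.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            scores = qh @ kh.transpose(0, 1, 3, 2) / np.sqrt(dh) + neg
            attn = _softmax(scores)
            ctx = (attn @ vh).transpose(0, 2, 1, 3).reshape(B, T, D)
            o = ctx @ p[f"l{l}_wo"] + p[f"l{l}_bo"]
            x1 = x + o
            f, ln2c = _layer_norm(x1, p[f"l{l}_ln2_g"], p[f"l{l}_ln2_b"])
            pre = f @ p[f"l{l}_w1"] + p[f"l{l}_b1"]
            relu = np.maximum(pre, 0.0)
            ff = relu @ p[f"l{l}_w2"] + p[f"l{l}_b2"]
            x2 = x1 + ff
            caches.append((a, ln1c, qh, kh, vh, attn, ctx, x, x1, f, ln2c, pre, relu))
            x = x2
        h, lnfc = _layer_norm(x, p["lnf_g"], p["lnf_b"])
        return h, (caches, lnfc, ids, pad_mask)

    def _backward(self, dh: np.ndarray, cache) -> dict[str, np.ndarray]:
        cfg, p = self.config, self.params
        caches, lnfc, ids, pad_mask = cache
        B, T = ids.shape
        H, D = cfg.n_heads, cfg.embed_dim
        dh_ = D // H
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dx, grads["lnf_g"], grads["lnf_b"] = _layer_norm_bwd(
            dh, p["lnf_g"], lnfc
        )
        for l in reversed(range(cfg.n_layers)):
            a, ln1c, qh, kh, vh, attn, ctx, x0, x1, f, ln2c, pre, relu = caches[l]
            # FFN block
            dff = dx
            grads[f"l{l}_w2"] += relu.reshape(-1, relu.shape[-1]).T @ dff.reshape(-1, D)
            grads[f"l{l}_b2"] += dff.sum(axis=(0, 1))
            drelu = dff @ p[f"l{l}_w2"].T
            dpre = drelu * (pre > 0)
            grads[f"l{l}_w1"] += f.reshape(-1, D).T @ dpre.reshape(-1, dpre.shape[-1])
            grads[f"l{l}_b1"] += dpre.sum(axis=(0, 1))
            df = dpre @ p[f"l{l}_w1"].T
            dx1_ln, dg2, db2 = _layer_norm_bwd(df, p[f"l{l}_ln2_g"], ln2c)
            grads[f"l{l}_ln2_g"] += dg2
            grads[f"l{l}_ln2_b"] += db2
            dx1 = dx + dx1_ln
            # attention block
            do = dx1
            grads[f"l{l}_wo"] += ctx.reshape(-1, D).T @ do.reshape(-1, D)
            grads[f"l{l}_bo"] += do.sum(axis=(0, 1))
            dctx = (do @ p[f"l{l}_wo"].T).reshape(B, T, H, dh_).transpose(0, 2, 1, 3)
            dattn = dctx @ vh.transpose(0, 1, 3, 2)
            dvh = attn.transpose(0, 1, 3, 2) @ dctx
            dscores = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
            dscores /= np.sqrt(dh_)
            dqh = dscores @ kh
            dkh = dscores.transpose(0, 1, 3, 2) @ qh
            dq = dqh.transpose(0, 2, 1, 3).reshape(B, T, D)
            dk = dkh.transpose(0, 2, 1, 3).reshape(B, T, D)
            dv = dvh.transpose(0, 2, 1, 3).reshape(B, T, D)
            a2 = a.reshape(-1, D)
            grads[f"l{l}_wq"] += a2.T @ dq.reshape(-1, D)
            grads[f"l{l}_bq"] += dq.sum(axis=(0, 1))
            grads[f"l{l}_wk"] += a2.T @ dk.reshape(-1, D)
            grads[f"l{l}_bk"] += dk.sum(axis=(0, 1))
            grads[f"l{l}_wv"] += a2.T @ dv.reshape(-1, D)
            grads[f"l{l}_bv"] += dv.sum(axis=(0, 1))
            da = dq @ p[f"l{l}_wq"].T + dk @ p[f"l{l}_wk"].T + dv @ p[f"l{l}_wv"].T
            dx0_ln, dg1, db1 = _layer_norm_bwd(da, p[f"l{l}_ln1_g"], ln1c)
            grads[f"l{l}_ln1_g"] += dg1
            grads[f"l{l}_ln1_b"] += db1
            dx = dx1 + dx0_ln
        # embeddings
        np.add.at(grads["tok_emb"], ids, dx)
        grads["pos_emb"][:T] += dx.sum(axis=0)
        return grads

    # ------------------------------------------------------------ training
    def _loss_and_grads(self, ids, pad_mask, targets, target_mask):
        p = self.params
        h, cache = self._forward(ids, pad_mask)
        n_masked = int(target_mask.sum())
        if n_masked == 0:
            return 0.0, None, 0
        # logits only at masked positions: the loss is zero elsewhere
        rows = np.where(target_mask)
        h_sel = h[rows]
        logits = h_sel @ p["w_out"] + p["b_out"]
        probs = _softmax(logits)
        tgt = targets[rows]
        loss = -np.mean(np.log(probs[np.arange(n_masked), tgt] + 1e-12))
        dsel = probs.copy()
        dsel[np.arange(n_masked), tgt] -= 1.0
        dsel /= n_masked
        dh = np.zeros_like(h)
        dh[rows] = dsel @ p["w_out"].T
        grads = self._backward(dh, cache)
        grads["w_out"] += h_sel.T @ dsel
        grads["b_out"] += dsel.sum(axis=0)
        return float(loss), grads, n_masked

    def _adam_step(self, grads, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            m = self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * g
            v = self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * g * g
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    def _make_batch(self, seqs: list[list[int]]):
        T = max(len(s) for s in seqs)
        B = len(seqs)
        ids = np.full((B, T), self.pad_id, dtype=np.int64)
        pad_mask = np.zeros((B, T), dtype=bool)
        for i, s in enumerate(seqs):
            ids[i, : len(s)] = s
            pad_mask[i, : len(s)] = True
        return ids, pad_mask

    def _apply_masking(self, ids, pad_mask, rng):
        cfg = self.config
        masked_ids = ids.copy()
        targets = ids.copy()
        target_mask = np.zeros_like(pad_mask)
        for i in range(ids.shape[0]):
            real = np.flatnonzero(pad_mask[i])
            n_mask = int(round(cfg.mask_rate * real.size))
            if n_mask == 0:
                continue
            picks = rng.choice(real, size=n_mask, replace=False)
            target_mask[i, picks] = True
            if cfg.mask_scheme == "mask_only":
                masked_ids[i, picks] = self.mask_id
            else:  # 80% [MASK], 10% random token, 10% unchanged
                u = rng.random(n_mask)
                masked_ids[i, picks[u < 0.8]] = self.mask_id
                rand = picks[(u >= 0.8) & (u < 0.9)]
                masked_ids[i, rand] = rng.integers(0, self.base_vocab, rand.size)
        return masked_ids, targets, target_mask

    def fit(self, corpus: Sequence[TokenizedCgi]) -> "MlmEncoder":
        cfg = self.config
        if not corpus:
            raise ConfigError("empty corpus")
        for c in corpus:
            if c.n_tokens > cfg.max_tokens:
                raise ValidationError(
                    f"sequence {c.cgi_id} has {c.n_tokens} tokens > max_tokens "
                    f"{cfg.max_tokens}; run the length filter first"
                )
            if any(t < 0 or t >= self.base_vocab for t in c.tokens):
                raise ValidationError(f"sequence {c.cgi_id}: token id out of range")
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 9001)))
        seqs = [list(c.tokens) for c in corpus if c.n_tokens > 0]
        # bucket by length to limit padding waste; batch order is shuffled
        by_len = sorted(range(len(seqs)), key=lambda i: len(seqs[i]))
        batches = [
            by_len[b0 : b0 + cfg.batch_size]
            for b0 in range(0, len(by_len), cfg.batch_size)
        ]
        for epoch in range(cfg.epochs):
            order = rng.permutation(len(batches))
            losses, weights = [], []
            for bi in order:
                batch = [seqs[i] for i in batches[bi]]
                ids, pad_mask = self._make_batch(batch)
                masked_ids, targets, target_mask = self._apply_masking(
                    ids, pad_mask, rng
                )
                loss, grads, n_masked = self._loss_and_grads(
                    masked_ids, pad_mask, targets, target_mask
                )
                if grads is None:
                    continue
                self._adam_step(grads, cfg.learning_rate)
                losses.append(loss)
                weights.append(n_masked)
            epoch_loss = (
                float(np.average(losses, weights=weights)) if losses else 0.0
            )
            self.loss_history.append(epoch_loss)
        return self

    # ----------------------------------------------------------- inference
    def encode(self, tokens: Sequence[int]) -> np.ndarray:
        """Final-layer hidden states for one unmasked sequence: (T, D)."""
        tokens = list(tokens)
        if any(t < 0 or t >= self.base_vocab for t in tokens):
            raise ValidationError("unknown token id")
        ids, pad_mask = self._make_batch([tokens])
        h, _ = self._forward(ids, pad_mask)
        return h[0, : len(tokens)]

    def masked_accuracy(
        self, corpus: Sequence[TokenizedCgi], rng: np.random.Generator
    ) -> float:
        """Fraction of masked tokens predicted correctly (evaluation helper)."""
        correct = total = 0
        for c in corpus:
            if c.n_tokens == 0:
                continue
            ids, pad_mask = self._make_batch([list(c.tokens)])
            masked_ids, targets, target_mask = self._apply_masking(ids, pad_mask, rng)
            if not target_mask.any():
                continue
            h, _ = self._forward(masked_ids, pad_mask)
            logits = h @ self.params["w_out"] + self.params["b_out"]
            pred = logits.argmax(axis=-1)
            correct += int((pred[target_mask] == targets[target_mask]).sum())
            total += int(target_mask.sum())
        return correct / total if total else float("nan")

    # --------------------------------------------------------- persistence
    def save(self, path: str | Path) -> None:
        path = Path(path)
        meta = {
            "schema_version": SCHEMA_VERSION,
            "base_vocab": self.base_vocab,
            "config": {
                k: getattr(self.config, k)
                for k in (
                    "embed_dim", "n_layers", "n_heads", "ffn_dim", "mask_rate",
                    "max_tokens", "epochs", "batch_size", "learning_rate",
                    "seed", "mask_scheme", "dtype",
                )
            },
            "loss_history": self.loss_history,
        }
        np.savez(path, __meta__=json.dumps(meta), **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "MlmEncoder":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["__meta__"]))
        if meta["schema_version"] != SCHEMA_VERSION:
            raise ValidationError(
                f"checkpoint schema {meta['schema_version']} unsupported"
            )
        enc = cls(meta["base_vocab"], MlmConfig(**meta["config"]))
        for k in enc.params:
            enc.params[k] = data[k]
        enc.loss_history = list(meta["loss_history"])
        return enc


@dataclass
class EmbeddingMatrix:
    cgi_ids: list[str]
    vectors: np.ndarray  # (n, embed_dim)
    pooled_by: str = "mean"


def train_mlm(corpus: Sequence[TokenizedCgi], tokenizer: TokenizerModel,
              config: MlmConfig) -> MlmEncoder:
    """Train an encoder on the tokenized corpus (masked-token objective)."""
    return MlmEncoder(tokenizer.vocab_size, config).fit(corpus)


def embed_cgis(
    corpus: Sequence[TokenizedCgi], encoder: MlmEncoder
) -> EmbeddingMatrix:
    """Mean-pool final-layer token vectors (no masking, pads excluded)."""
    ids: list[str] = []
    rows: list[np.ndarray] = []
    for c in corpus:
        if c.n_tokens == 0:
            continue
        h = encoder.encode(c.tokens)
        ids.append(c.cgi_id)
        rows.append(h.mean(axis=0))
    vectors = np.vstack(rows) if rows else np.empty((0, encoder.config.embed_dim))
    if not np.all(np.isfinite(vectors)):
        raise ValidationError("non-finite embedding values")
    return EmbeddingMatrix(cgi_ids=ids, vectors=vectors)
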