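"""A small bidirectional transformer encoder in pure NumPy.

This is a BERT-style stack — learned token + absolute position embeddings
summed and layer-normalized, multi-head self-attention with padding masks,
GELU feed-forward blocks with post-residual LayerNorm — with hand-written
backpropagation and an AdamW optimizer. The default configuration is
deliberately tiny (2 layers, width 64) so masked-language-model pre-training
runs on one CPU core; the architecture scales to BERT-base sizes purely
through the config.

Forward caches needed for the backward pass are kept explicitly, and the
gradient of every parameter is checked against finite differences in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

_LN_EPS = 1e-5
_NEG_INF = -1e9
_SQRT_2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class EncoderConfig:
    vocab_size: int
    max_len: int = 512
    layers: int = 2
    hidden_size: int = 64
    attention_heads: int = 2
    ffn_mult: int = 4

    def __post_init__(self) -> None:
        if self.hidden_size % self.attention_heads != 0:
            raise ValueError("hidden_size must be divisible by attention_heads")


def _gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + erf(x / _SQRT_2))


def _gelu_grad(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + erf(x / _SQRT_2)) + x * _INV_SQRT_2PI * np.exp(-0.5 * x * x)


def _layernorm_forward(x, gamma, beta):
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = xc * inv
    return gamma * xhat + beta, (xhat, inv, gamma)


def _layernorm_backward(dy, cache):
    xhat, inv, gamma = cache
    reduce_axes = tuple(range(dy.ndim - 1))
    dgamma = (dy * xhat).sum(axis=reduce_axes)
    dbeta = dy.sum(axis=reduce_axes)
    dxhat = dy * gamma
    dx = inv * (
        dxhat
        - dxhat.mean(axis=-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
    )
    return dx, dgamma, dbeta


class TransformerEncoder:
    """Token-level encoder with a masked-LM output head.

    Parameters live in ``self.params`` (name -> float32 array); gradients
    come back from :meth:`loss_and_grads` as a matching dict.
    """

    def __init__(self, config: EncoderConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        d, V, L = config.hidden_size, config.vocab_size, config.max_len
        f = config.ffn_mult * d

        def init(*shape, scale=0.02):
            return rng.normal(0.0, scale, size=shape).astype(np.float32)

        p: dict[str, np.ndarray] = {
            "tok_emb": init(V, d),
            "pos_emb": init(L, d),
            "ln_emb_g": np.ones(d, dtype=np.float32),
            "ln_emb_b": np.zeros(d, dtype=np.float32),
            "lm_W": init(d, V),
            "lm_b": np.zeros(V, dtype=np.float32),
        }
        for l in range(config.layers):
            p[f"{l}.Wq"], p[f"{l}.bq"] = init(d, d), np.zeros(d, dtype=np.float32)
            p[f"{l}.Wk"], p[f"{l}.bk"] = init(d, d), np.zeros(d, dtype=np.float32)
            p[f"{l}.Wv"], p[f"{l}.bv"] = init(d, d), np.zeros(d, dtype=np.float32)
            p[f"{l}.Wo"], p[f"{l}.bo"] = init(d, d), np.zeros(d, dtype=np.float32)
            p[f"{l}.W1"], p[f"{l}.b1"] = init(d, f), np.zeros(f, dtype=np.float32)
            p[f"{l}.W2"], p[f"{l}.b2"] = init(f, d), np.zeros(d, dtype=np.float32)
            p[f"{l}.ln1_g"], p[f"{l}.ln1_b"] = np.ones(d, dtype=np.float32), np.zeros(d, dtype=np.float32)
            p[f"{l}.ln2_g"], p[f"{l}.ln2_b"] = np.ones(d, dtype=np.float32), np.zeros(d, dtype=np.float32)
        self.params = p

    # ----------------------------------------------------------- head helpers

    def _split_heads(self, x: np.ndarray) -> np.ndarray:
        B, L, d = x.shape
        H = self.config.attention_heads
        return x.reshape(B, L, H, d // H).transpose(0, 2, 1, 3)

    def _merge_heads(self, x: np.ndarray) -> np.ndarray:
        B, H, L, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, L, H * dh)

    # ---------------------------------------------------------------- forward

    def forward(self, ids: np.ndarray, mask: np.ndarray, need_cache: bool = False):
        """Run the stack. ids: (B, L) int; mask: (B, L), 1 = real token.

        Returns ``hidden`` (B, L, d) or ``(hidden, cache)`` if ``need_cache``.
        """
        p = self.params
        cfg = self.config
        B, L = ids.shape
        dh = cfg.hidden_size // cfg.attention_heads
        scale = 1.0 / np.sqrt(dh)

        x0 = p["tok_emb"][ids] + p["pos_emb"][:L]
        h, ln_emb_cache = _layernorm_forward(x0, p["ln_emb_g"], p["ln_emb_b"])
        # pad positions are excluded as attention keys
        key_bias = np.where(mask[:, None, None, :] > 0, 0.0, _NEG_INF).astype(np.float32)

        layer_caches = []
        for l in range(cfg.layers):
            h_in = h
            q = self._split_heads(h_in @ p[f"{l}.Wq"] + p[f"{l}.bq"])
            k = self._split_heads(h_in @ p[f"{l}.Wk"] + p[f"{l}.bk"])
            v = self._split_heads(h_in @ p[f"{l}.Wv"] + p[f"{l}.bv"])
            scores = (q @ k.transpose(0, 1, 3, 2)) * scale + key_bias
            scores -= scores.max(axis=-1, keepdims=True)
            attn = np.exp(scores)
            attn /= attn.sum(axis=-1, keepdims=True)
            ctx = self._merge_heads(attn @ v)
            attn_out = ctx @ p[f"{l}.Wo"] + p[f"{l}.bo"]
            h1, ln1_cache = _layernorm_forward(h_in + attn_out, p[f"{l}.ln1_g"], p[f"{l}.ln1_b"])
            u = h1 @ p[f"{l}.W1"] + p[f"{l}.b1"]
            g = _gelu(u)
            ffn_out = g @ p[f"{l}.W2"] + p[f"{l}.b2"]
            h, ln2_cache = _layernorm_forward(h1 + ffn_out, p[f"{l}.ln2_g"], p[f"{l}.ln2_b"])
            if need_cache:
                layer_caches.append((h_in, q, k, v, attn, ctx, ln1_cache, h1, u, g, ln2_cache))
            else:
                layer_caches.append(None)

        if need_cache:
            return h, (ids, ln_emb_cache, layer_caches)
        return h

    # --------------------------------------------------------------- training

    def loss_and_grads(
        self,
        ids: np.ndarray,
        mask: np.ndarray,
        target_positions: tuple[np.ndarray, np.ndarray],
        target_ids: np.ndarray,
    ):
        """Masked-LM cross-entropy and gradients for every parameter.

        ``target_positions`` is a pair of index arrays (batch_idx, pos_idx)
        selecting the in-span positions; ``target_ids`` holds the original
        token ids there. Loss is the mean cross-entropy over those positions
        only.
        """
        p = self.params
        cfg = self.config
        if target_ids.size == 0:
            raise ValueError("no target positions to train on")
        hidden, cache = self.forward(ids, mask, need_cache=True)
        rows = hidden[target_positions]  # (T, d)
        logits = rows @ p["lm_W"] + p["lm_b"]  # (T, V)
        logits -= logits.max(axis=-1, keepdims=True)
        exp = np.exp(logits)
        probs = exp / exp.sum(axis=-1, keepdims=True)
        T = target_ids.size
        nll = -np.log(probs[np.arange(T), target_ids] + 1e-12)
        loss = float(nll.mean())

        grads: dict[str, np.ndarray] = {}
        dlogits = probs
        dlogits[np.arange(T), target_ids] -= 1.0
        dlogits /= T
        grads["lm_W"] = rows.T @ dlogits
        grads["lm_b"] = dlogits.sum(axis=0)
        drows = dlogits @ p["lm_W"].T

        dhidden = np.zeros_like(hidden)
        dhidden[target_positions] = drows
        self._backward(dhidden, mask, cache, grads)
        return loss, grads

    def _backward(self, dh, mask, cache, grads):
        p = self.params
        cfg = self.config
        ids, ln_emb_cache, layer_caches = cache
        dh_scale = 1.0 / np.sqrt(cfg.hidden_size // cfg.attention_heads)

        for l in reversed(range(cfg.layers)):
            h_in, q, k, v, attn, ctx, ln1_cache, h1, u, g, ln2_cache = layer_caches[l]
            d_res2, dg2, db2 = _layernorm_backward(dh, ln2_cache)
            grads[f"{l}.ln2_g"], grads[f"{l}.ln2_b"] = dg2, db2
            # ffn branch
            dffn = d_res2
            grads[f"{l}.W2"] = g.reshape(-1, g.shape[-1]).T @ dffn.reshape(-1, dffn.shape[-1])
            grads[f"{l}.b2"] = dffn.sum(axis=(0, 1))
            dg_act = dffn @ p[f"{l}.W2"].T
            du = dg_act * _gelu_grad(u)
            grads[f"{l}.W1"] = h1.reshape(-1, h1.shape[-1]).T @ du.reshape(-1, du.shape[-1])
            grads[f"{l}.b1"] = du.sum(axis=(0, 1))
            dh1 = d_res2 + du @ p[f"{l}.W1"].T

            d_res1, dg1, db1 = _layernorm_backward(dh1, ln1_cache)
            grads[f"{l}.ln1_g"], grads[f"{l}.ln1_b"] = dg1, db1
            # attention output projection
            dctx = d_res1 @ p[f"{l}.Wo"].T
            grads[f"{l}.Wo"] = ctx.reshape(-1, ctx.shape[-1]).T @ d_res1.reshape(-1, d_res1.shape[-1])
            grads[f"{l}.bo"] = d_res1.sum(axis=(0, 1))
            dctx_h = self._split_heads(dctx)
            dattn = dctx_h @ v.transpose(0, 1, 3, 2)
            dv = attn.transpose(0, 1, 3, 2) @ dctx_h
            dscores = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
            dq = (dscores @ k) * dh_scale
            dk = (dscores.transpose(0, 1, 3, 2) @ q) * dh_scale

            dh_in = d_res1.copy()
            for name, dmat in (("Wq", dq), ("Wk", dk), ("Wv", dv)):
                dflat = self._merge_heads(dmat)
                grads[f"{l}.{name}"] = (
                    h_in.reshape(-1, h_in.shape[-1]).T @ dflat.reshape(-1, dflat.shape[-1])
                )
                grads[f"{l}.b{name[1]}"] = dflat.sum(axis=(0, 1))
                dh_in += dflat @ p[f"{l}.{name}"].T
            dh = dh_in

        dx0, dg_emb, db_emb = _layernorm_backward(dh, ln_emb_cache)
        grads["ln_emb_g"], grads["ln_emb_b"] = dg_emb, db_emb
        d_tok = np.zeros_like(p["tok_emb"])
        np.add.at(d_tok, ids.reshape(-1), dx0.reshape(-1, dx0.shape[-1]))
        grads["tok_emb"] = d_tok
        d_pos = np.zeros_like(p["pos_emb"])
        d_pos[: dx0.shape[1]] = dx0.sum(axis=0)
        grads["pos_emb"] = d_pos

    # -------------------------------------------------------------- inference

    def cls_vectors(self, ids: np.ndarray, mask: np.ndarray) -> np.ndarray:
        """Final-hidden-layer vectors at the [CLS] (first) position, (B, d)."""
        return self.forward(ids, mask)[:, 0, :]


class AdamW:
    """Decoupled weight-decay Adam, applied to a parameter dict in place."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 2e-5,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.01):
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for k, g in grads.items():
            g = g.astype(np.float32)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * (g * g)
            update = (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
            # no weight decay on norms/biases, matching common BERT practice
            if k.endswith(("_g", "_b")) or k.endswith(("bq", "bk", "bv", "bo", "b1", "b2", "lm_b")):
                params[k] -= self.lr * update
            else:
                params[k] -= self.lr * (update + self.weight_decay * params[k])
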