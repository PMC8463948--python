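"""Lead-masked multi-head self-attention over per-lead embeddings.

The fusion stage of the classifier.  Queries, keys and values are single
dense maps of the 12 per-lead embeddings; scaled dot-product scores are
softmaxed into an N x N attention matrix per head (N = number of lead
channels).  Masking happens *on the attention matrices*: unavailable leads
are removed as keys (score -inf before the softmax, so their attention
weight is exactly zero) and their fused output rows are zeroed, so nothing
a masked lead's encoder produced can reach the classifier.  This exact
zeroing — not approximate down-weighting — is what makes one trained model
usable for any lead subset.
"""

from __future__ import annotations

import numpy as np

from .layers import DTYPE, Layer


class AllLeadsMaskedError(ValueError):
    """At least one lead must be available."""


class MaskedSelfAttention(Layer):
    """Multi-head self-attention with exact key/output masking.

    Input (N, L, E) with L lead channels; ``mask`` is boolean (L,) or
    (N, L).  Output has the same shape; masked rows are zero.
    """

    def __init__(
        self,
        embed_dim: int,
        n_heads: int,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        if embed_dim % n_heads:
            raise ValueError(
                f"embed_dim {embed_dim} not divisible by n_heads {n_heads}"
            )
        rng = rng or np.random.default_rng()
        self.embed_dim = embed_dim
        self.n_heads = n_heads
        self.head_dim = embed_dim // n_heads
        scale = 1.0 / np.sqrt(embed_dim)
        for name in ("wq", "wk", "wv", "wo"):
            self.params[name] = rng.normal(
                0, scale, (embed_dim, embed_dim)
            ).astype(DTYPE)
            self.params[name[0] + "b" + name[1]] = np.zeros(embed_dim, dtype=DTYPE)
        for key, val in list(self.params.items()):
            self.grads[key] = np.zeros_like(val)

    @staticmethod
    def _check_mask(mask: np.ndarray, n: int, n_leads: int) -> np.ndarray:
        mask = np.asarray(mask, dtype=bool)
        if mask.ndim == 1:
            mask = np.broadcast_to(mask, (n, n_leads))
        if not mask.any(axis=1).all():
            raise AllLeadsMaskedError("every record needs >= 1 available lead")
        return mask

    def _split(self, x: np.ndarray) -> np.ndarray:
        # (N, L, E) -> (N, H, L, hd)
        n, length, _ = x.shape
        return x.reshape(n, length, self.n_heads, self.head_dim).transpose(
            0, 2, 1, 3
        )

    def _merge(self, x: np.ndarray) -> np.ndarray:
        n, _, length, _ = x.shape
        return x.transpose(0, 2, 1, 3).reshape(n, length, self.embed_dim)

    def forward_masked(
        self, x: np.ndarray, mask: np.ndarray, train: bool = False
    ) -> np.ndarray:
        n, n_leads, _ = x.shape
        mask = self._check_mask(mask, n, n_leads)
        p = self.params
        q = self._split(x @ p["wq"] + p["wbq"])
        k = self._split(x @ p["wk"] + p["wbk"])
        v = self._split(x @ p["wv"] + p["wbv"])
        scores = (q @ k.transpose(0, 1, 3, 2)) / np.sqrt(self.head_dim)
        # mask on the attention matrices: unavailable keys get -inf
        keymask = mask[:, None, None, :]
        scores = np.where(keymask, scores, -np.inf)
        scores = scores - scores.max(axis=3, keepdims=True)
        expo = np.exp(scores, where=np.isfinite(scores), out=np.zeros_like(scores))
        attn = expo / expo.sum(axis=3, keepdims=True)
        fused = self._merge(attn @ v) @ p["wo"] + p["wbo"]
        fused = fused * mask[:, :, None]  # masked leads' rows are exactly zero
        if train:
            self._cache = (x, q, k, v, attn, mask)
        self._last_attention = attn
        return fused.astype(DTYPE)

    # Layer interface used inside the full model; mask is set beforehand.
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward_masked(x, self._mask_in, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, q, k, v, attn, mask = self._cache
        p = self.params
        dy = dy * mask[:, :, None]
        ctx = self._merge(attn @ v)  # pre-projection concat, recomputed cheaply
        n, n_leads, _ = x.shape
        dy2 = dy.reshape(-1, self.embed_dim)
        self.grads["wo"] += ctx.reshape(-1, self.embed_dim).T @ dy2
        self.grads["wbo"] += dy2.sum(axis=0)
        dctx = self._split((dy @ p["wo"].T).astype(DTYPE))
        dattn = dctx @ v.transpose(0, 1, 3, 2)
        dv = attn.transpose(0, 1, 3, 2) @ dctx
        # softmax backward; masked keys have attn == 0 hence dscore == 0
        dscore = attn * (dattn - (dattn * attn).sum(axis=3, keepdims=True))
        dscore = dscore / np.sqrt(self.head_dim)
        dq = dscore @ k
        dk = dscore.transpose(0, 1, 3, 2) @ q
        dx = np.zeros_like(x)
        for dproj, wname in ((dq, "wq"), (dk, "wk"), (dv, "wv")):
            dflat = self._merge(dproj).reshape(-1, self.embed_dim)
            xflat = x.reshape(-1, self.embed_dim)
            self.grads[wname] += xflat.T @ dflat
            self.grads["wb" + wname[1]] += dflat.sum(axis=0)
            dx += (dflat @ p[wname].T).reshape(x.shape)
        return dx.astype(DTYPE)

    @property
    def last_attention(self) -> np.ndarray:
        """Attention matrices (N, heads, L, L) from the latest forward."""
        return self._last_attention
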