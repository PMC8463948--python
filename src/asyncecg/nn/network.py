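"""The asynchronous-lead ECG classifier.

Architecture: each available lead's 2.5 s segment (625 samples at 250 Hz)
runs through one weight-shared residual 1-D CNN encoder (conv -> batch norm
-> ReLU throughout, kernel 7, "same" padding, feature depth doubling every
``depth_doubling_period`` blocks, stride-2 convs downsampling on a per-block
schedule); global average pooling yields one embedding per lead.  The 12
embeddings are fused by lead-masked multi-head self-attention, flattened to
``n_leads * embed_dim`` (6144 for the default model) and passed through a
two-layer dense classifier ending in a sigmoid that calibrates the
probability of acute myocardial infarction.

Masked leads are fed zeros through the encoder (keeping a fixed 12-channel
graph) and are excluded exactly at the attention stage, so in inference
mode the predicted probability is bit-for-bit independent of whatever
signal the masked leads carry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ..leads import LEAD_NAMES
from .attention import MaskedSelfAttention
from .layers import (
    DTYPE,
    AvgPool1d,
    BatchNorm1d,
    Conv1d,
    Dense,
    GlobalAvgPool,
    Layer,
    ReLU,
    sigmoid,
)


def _default_strides(n_blocks: int) -> list[list[int]]:
    """Default stride schedule.

    Block 1: three convs with strides (1, 2, 1) — its shortcut taps the
    first ReLU output and average-pools it by the same factor 2.  Odd blocks
    3, 5, ... are 3-conv blocks with strides (2, 1, 1); even blocks are
    2-conv (1, 1) blocks.  For 16 blocks this downsamples 2^8: 625 -> 3.
    """
    sched: list[list[int]] = []
    for i in range(n_blocks):
        if i == 0:
            sched.append([1, 2, 1])
        elif i % 2 == 0:
            sched.append([2, 1, 1])
        else:
            sched.append([1, 1])
    return sched


@dataclass
class ModelConfig:
    """All architecture hyperparameters.

    ``stride_schedule`` lists per-block per-conv strides (its length fixes
    the conv count of each block).  Depth doubles every
    ``depth_doubling_period`` blocks starting from ``initial_depth``; the
    final stage depth must equal ``embed_dim`` because the encoder output
    feeds the attention module directly.
    """

    n_leads: int = 12
    input_samples: int = 625  # 2.5 s at 250 Hz
    n_blocks: int = 16
    kernel_size: int = 7
    initial_depth: int = 64
    depth_doubling_period: int = 4
    stride_schedule: list[list[int]] = field(default_factory=list)
    embed_dim: int = 512
    n_heads: int = 8
    classifier_hidden: int = 512

    def __post_init__(self) -> None:
        if not self.stride_schedule:
            self.stride_schedule = _default_strides(self.n_blocks)
        if len(self.stride_schedule) != self.n_blocks:
            raise ValueError("stride_schedule length must equal n_blocks")
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.final_depth != self.embed_dim:
            raise ValueError(
                f"final encoder depth {self.final_depth} != embed_dim "
                f"{self.embed_dim}; adjust initial_depth or n_blocks"
            )

    def block_depth(self, block: int) -> int:
        return self.initial_depth * 2 ** (block // self.depth_doubling_period)

    @property
    def final_depth(self) -> int:
        return self.block_depth(self.n_blocks - 1)

    @property
    def classifier_input(self) -> int:
        return self.n_leads * self.embed_dim

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.n_heads


def reduced_config() -> ModelConfig:
    """The scaled-down model used in this package's desk-scale experiments.

    8 blocks, initial depth 16 (stages 16/32, embed 32), downsampling in
    every block (block 1 strides (2, 2, 1), then (2, 1)): 625 -> 2 before
    pooling.  Small enough to train on one CPU in minutes.
    """
    sched = [[2, 2, 1]] + [[2, 1]] * 7
    return ModelConfig(
        n_blocks=8,
        initial_depth=16,
        stride_schedule=sched,
        embed_dim=32,
        n_heads=8,
        classifier_hidden=64,
    )


def tiny_config(input_samples: int = 625) -> ModelConfig:
    """A 2-block micro model for fast tests and property checks."""
    return ModelConfig(
        n_blocks=2,
        input_samples=input_samples,
        initial_depth=8,
        stride_schedule=[[2, 2, 1], [2, 1]],
        embed_dim=8,
        n_heads=2,
        classifier_hidden=8,
    )


class ResidualBlock:
    """conv -> BN -> ReLU stack plus a shortcut.

    Block 1 connects its *first ReLU output* to the block output through an
    average-pooling layer matching the remaining downsampling.  Later blocks
    connect input to output; when the block changes length or depth the
    shortcut average-pools by the block's total stride and zero-pads the new
    channels (a parameter-free projection).
    """

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        strides: list[int],
        first_block: bool,
        rng: np.random.Generator,
    ) -> None:
        self.first_block = first_block
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.units: list[tuple[Conv1d, BatchNorm1d, ReLU]] = []
        ch = in_ch
        for s in strides:
            self.units.append(
                (Conv1d(ch, out_ch, kernel, s, rng), BatchNorm1d(out_ch), ReLU())
            )
            ch = out_ch
        if first_block:
            # shortcut from after the first ReLU; pool by remaining strides
            pool = int(np.prod(strides[1:]))
        else:
            pool = int(np.prod(strides))
        self.shortcut_pool = AvgPool1d(pool) if pool > 1 else None

    @property
    def layers(self) -> list[Layer]:
        out: list[Layer] = []
        for conv, bn, _ in self.units:
            out.extend([conv, bn])
        return out

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        h = x
        tap = None
        for i, (conv, bn, relu) in enumerate(self.units):
            h = relu.forward(bn.forward(conv.forward(h, train), train), train)
            if i == 0 and self.first_block:
                tap = h
        short = tap if self.first_block else x
        if self.shortcut_pool is not None:
            short = self.shortcut_pool.forward(short, train)
        if short.shape[1] != h.shape[1]:
            pad = h.shape[1] - short.shape[1]
            self._chan_pad = pad
            short = np.pad(short, ((0, 0), (0, pad), (0, 0)))
        else:
            self._chan_pad = 0
        return h + short

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dshort = dy
        if self._chan_pad:
            dshort = dshort[:, : dshort.shape[1] - self._chan_pad]
        if self.shortcut_pool is not None:
            dshort = self.shortcut_pool.backward(dshort)
        dh = dy
        dx_short_at = 0 if self.first_block else None
        dx = None
        for i in reversed(range(len(self.units))):
            conv, bn, relu = self.units[i]
            if self.first_block and i == 0:
                dh = dh + dshort  # tap gradient joins after first ReLU
            dh = conv.backward(bn.backward(relu.backward(dh)))
        dx = dh
        if not self.first_block:
            dx = dx + dshort
        return dx


class AsyncEcgClassifier:
    """Weight-shared encoder + lead-masked attention + dense classifier."""

    def __init__(self, config: ModelConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        self.blocks: list[ResidualBlock] = []
        ch = 1
        for b in range(config.n_blocks):
            out_ch = config.block_depth(b)
            self.blocks.append(
                ResidualBlock(
                    ch,
                    out_ch,
                    config.kernel_size,
                    config.stride_schedule[b],
                    first_block=(b == 0),
                    rng=rng,
                )
            )
            ch = out_ch
        self.pool = GlobalAvgPool()
        self.attention = MaskedSelfAttention(config.embed_dim, config.n_heads, rng)
        self.fc1 = Dense(config.classifier_input, config.classifier_hidden, rng)
        self.fc_relu = ReLU()
        self.fc2 = Dense(config.classifier_hidden, 1, rng)

    # ------------------------------------------------------------------
    # parameter plumbing

    @property
    def layers(self) -> list[Layer]:
        out: list[Layer] = []
        for block in self.blocks:
            out.extend(block.layers)
        out.extend([self.attention, self.fc1, self.fc2])
        return out

    def parameter_count(self) -> int:
        return sum(p.size for layer in self.layers for p in layer.params.values())

    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self.layers):
            for key, val in layer.params.items():
                state[f"layer{i}.{key}"] = val
            if isinstance(layer, BatchNorm1d):
                state[f"layer{i}.running_mean"] = layer.running_mean
                state[f"layer{i}.running_var"] = layer.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for key in layer.params:
                layer.params[key][...] = state[f"layer{i}.{key}"]
            if isinstance(layer, BatchNorm1d):
                layer.running_mean[...] = state[f"layer{i}.running_mean"]
                layer.running_var[...] = state[f"layer{i}.running_var"]

    def save(self, path: str | Path) -> None:
        """Checkpoint: parameters (.npz) + config and lead order (.json)."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.state_arrays())
        meta = {"config": asdict(self.config), "lead_order": list(LEAD_NAMES)}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path, seed: int = 0) -> "AsyncEcgClassifier":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(ModelConfig(**meta["config"]), seed=seed)
        with np.load(path.with_suffix(".npz")) as npz:
            model.load_state_arrays(dict(npz))
        return model

    # ------------------------------------------------------------------
    # forward / backward

    def encode(self, segments: np.ndarray, train: bool = False) -> np.ndarray:
        """(N, n_leads, L) -> per-lead embeddings (N, n_leads, embed_dim).

        All leads of all records pass through the one shared encoder as a
        single batch of single-channel segments.
        """
        n, n_leads, length = segments.shape
        if length != self.config.input_samples:
            raise ValueError(
                f"segment length {length} != input_samples "
                f"{self.config.input_samples}"
            )
        h = segments.reshape(n * n_leads, 1, length).astype(DTYPE)
        for block in self.blocks:
            h = block.forward(h, train)
        emb = self.pool.forward(h, train)
        return emb.reshape(n, n_leads, self.config.embed_dim)

    def encode_lead(self, segment: np.ndarray) -> np.ndarray:
        """One lead segment (length input_samples) -> (embed_dim,) embedding."""
        seg = np.asarray(segment, dtype=DTYPE)
        if seg.ndim != 1:
            raise ValueError("encode_lead expects a 1-D segment")
        return self.encode(seg[None, None, :])[0, 0]

    def masked_attention(
        self, embeddings: np.ndarray, mask: np.ndarray
    ) -> np.ndarray:
        """Fuse (n_leads, embed_dim) embeddings under an availability mask."""
        emb = np.asarray(embeddings, dtype=DTYPE)
        if emb.ndim == 2:
            return self.attention.forward_masked(emb[None], mask)[0]
        return self.attention.forward_masked(emb, mask)

    def forward_logits(
        self, segments: np.ndarray, mask: np.ndarray, train: bool = False
    ) -> np.ndarray:
        emb = self.encode(segments, train)
        fused = self.attention.forward_masked(emb, mask, train)
        flat = fused.reshape(fused.shape[0], -1)
        h = self.fc_relu.forward(self.fc1.forward(flat, train), train)
        z = self.fc2.forward(h, train)
        return z[:, 0]

    def predict_proba(self, segments: np.ndarray, mask: np.ndarray) -> np.ndarray:
        """Probability of acute myocardial infarction per record."""
        return sigmoid(self.forward_logits(segments, mask, train=False))

    def backward_from_logits(self, dlogits: np.ndarray) -> None:
        """Backpropagate d(loss)/d(logit); accumulates parameter grads."""
        dz = dlogits[:, None].astype(DTYPE)
        dh = self.fc2.backward(dz)
        dflat = self.fc1.backward(self.fc_relu.backward(dh))
        n = dflat.shape[0]
        dfused = dflat.reshape(n, self.config.n_leads, self.config.embed_dim)
        demb = self.attention.backward(dfused)
        dpooled = demb.reshape(n * self.config.n_leads, self.config.embed_dim)
        dh = self.pool.backward(dpooled)
        for block in reversed(self.blocks):
            dh = block.backward(dh)

    def zero_grads(self) -> None:
        for layer in self.layers:
            for g in layer.grads.values():
                g[...] = 0
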