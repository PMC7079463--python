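"""Composite network blocks: encoder/decoder blocks, residual modules,
hourglasses, and the full patch-level / refinement networks.

The two networks share one chassis (:class:`PatchNet`): three encoder blocks
(each two 3x3 conv -> ReLU -> batch-norm stages, then 2x2 max-pool), a
bottleneck of three hourglasses with one scale-up and one scale-down between
them (present in the local-patch network, absent in the mask-refinement
network), and three decoder blocks fed by stride-2 transpose convolutions
with skip concatenations from the encoder.  A 3x3 single-channel sigmoid
head yields per-pixel spike probabilities.
"""

from __future__ import annotations

import numpy as np

from .layers import (
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    Layer,
    MaxPool2d,
    ReLU,
    Sequential,
    Sigmoid,
    UpsampleNearest2,
)


def conv_block(in_channels: int, out_channels: int, *, rng) -> Sequential:
    """Two 3x3 convolutions, each followed by ReLU then batch-norm."""
    return Sequential(
        Conv2d(in_channels, out_channels, 3, pad=1, rng=rng),
        ReLU(),
        BatchNorm2d(out_channels),
        Conv2d(out_channels, out_channels, 3, pad=1, rng=rng),
        ReLU(),
        BatchNorm2d(out_channels),
    )


class ResidualModule(Layer):
    """1x1 reduce -> 3x3 body -> 1x1 expand with an (identity or projected)
    skip connection and a ReLU after the element-wise addition."""

    def __init__(self, in_channels: int, mid: int, out_channels: int, *, rng):
        self.reduce = Conv2d(in_channels, mid, 1, rng=rng)
        self.relu1 = ReLU()
        self.body = Conv2d(mid, mid, 3, pad=1, rng=rng)
        self.relu2 = ReLU()
        self.expand = Conv2d(mid, out_channels, 1, rng=rng)
        self.proj = None if in_channels == out_channels else Conv2d(
            in_channels, out_channels, 1, rng=rng)
        self.relu3 = ReLU()

    def params(self):
        out = self.reduce.params() + self.body.params() + self.expand.params()
        if self.proj is not None:
            out += self.proj.params()
        return out

    def forward(self, x, train=True):
        h = self.relu1(self.reduce(x, train), train)
        h = self.relu2(self.body(h, train), train)
        h = self.expand(h, train)
        s = x if self.proj is None else self.proj(x, train)
        return self.relu3(h + s, train)

    def backward(self, dy):
        d = self.relu3.backward(dy)
        dskip = d if self.proj is None else self.proj.backward(d)
        d = self.expand.backward(d)
        d = self.body.backward(self.relu2.backward(d))
        d = self.reduce.backward(self.relu1.backward(d))
        return d + dskip


class Hourglass(Layer):
    """Symmetric down/up tower of residual modules.

    Four residual modules down (max-pooling between the first three), four
    up (nearest-neighbour upsampling mirroring the pools), and three long
    skip branches, each passing through its own residual module before the
    element-wise addition.  Spatial dims and channel count are preserved;
    internally channels expand to twice the I/O width and a final 1x1
    projection restores them.
    """

    def __init__(self, channels: int, *, rng):
        c, e = channels, 2 * channels
        self.res_down = [ResidualModule(c, c, e, rng=rng)] + [
            ResidualModule(e, c, e, rng=rng) for _ in range(3)
        ]
        self.res_skip = [ResidualModule(e, c, e, rng=rng) for _ in range(3)]
        self.res_up = [ResidualModule(e, c, e, rng=rng) for _ in range(4)]
        self.proj = Conv2d(e, c, 1, rng=rng)
        self.pools = [MaxPool2d() for _ in range(3)]
        self.ups = [UpsampleNearest2() for _ in range(3)]

    def params(self):
        out = []
        for m in self.res_down + self.res_skip + self.res_up + [self.proj]:
            out.extend(m.params())
        return out

    def forward(self, x, train=True):
        acts, pooled = [], []
        cur = x
        for i in range(3):
            cur = self.res_down[i](cur, train)
            acts.append(cur)
            can_pool = cur.shape[2] >= 2 and cur.shape[2] % 2 == 0 and \
                cur.shape[3] >= 2 and cur.shape[3] % 2 == 0
            pooled.append(can_pool)
            if can_pool:
                cur = self.pools[i](cur, train)
        cur = self.res_down[3](cur, train)
        cur = self.res_up[3](cur, train)
        for i in reversed(range(3)):
            if pooled[i]:
                cur = self.ups[i](cur, train)
            cur = cur + self.res_skip[i](acts[i], train)
            cur = self.res_up[i](cur, train)
        self._pooled = pooled
        return self.proj(cur, train)

    def backward(self, dy):
        d = self.proj.backward(dy)
        dacts = [None] * 3
        for i in range(3):
            d = self.res_up[i].backward(d)
            dacts[i] = self.res_skip[i].backward(d)
            if self._pooled[i]:
                d = self.ups[i].backward(d)
        d = self.res_up[3].backward(d)
        d = self.res_down[3].backward(d)
        for i in reversed(range(3)):
            if self._pooled[i]:
                d = self.pools[i].backward(d)
            d = d + dacts[i]
            d = self.res_down[i].backward(d)
        return d


class PatchNet(Layer):
    """Encoder / (optional hourglass bottleneck) / decoder network with a
    single-channel sigmoid head.

    ``with_bottleneck=True`` gives the local-patch network; ``False`` gives
    the mask-refinement network (identical encoder/decoder, empty
    bottleneck).
    """

    def __init__(self, in_channels: int, widths=(16, 64, 128),
                 with_bottleneck: bool = True, *, rng):
        if len(widths) != 3:
            raise ValueError("widths must be a channel triple")
        w0, w1, w2 = widths
        self.in_channels, self.widths = in_channels, tuple(widths)
        self.with_bottleneck = with_bottleneck
        self.enc = [
            conv_block(in_channels, w0, rng=rng),
            conv_block(w0, w1, rng=rng),
            conv_block(w1, w2, rng=rng),
        ]
        self.enc_pools = [MaxPool2d() for _ in range(3)]
        if with_bottleneck:
            self.hourglasses = [Hourglass(w2, rng=rng) for _ in range(3)]
            self.scale_up = UpsampleNearest2()
            self.scale_down = MaxPool2d()
        else:
            self.hourglasses = []
        # transpose-conv channel plan mirrors the printed decoder tables:
        # w2->w2 (concat w2 -> 2*w2), w2->w1 (concat w1 -> 2*w1),
        # w1->w1 (concat w0 -> w1+w0)
        self.tconvs = [
            ConvTranspose2d(w2, w2, rng=rng),
            ConvTranspose2d(w2, w1, rng=rng),
            ConvTranspose2d(w1, w1, rng=rng),
        ]
        self.dec = [
            conv_block(2 * w2, w2, rng=rng),
            conv_block(2 * w1, w1, rng=rng),
            conv_block(w1 + w0, w0, rng=rng),
        ]
        self.head = Conv2d(w0, 1, 3, pad=1, rng=rng)
        self.out_act = Sigmoid()

    def params(self):
        out = []
        for m in self.enc + self.hourglasses + self.tconvs + self.dec + [self.head]:
            out.extend(m.params())
        return out

    def forward(self, x, train=True):
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected (N, {self.in_channels}, H, W) input, got {x.shape}")
        shapes = {"input": x.shape[1:]}
        skips = []
        cur = x
        for i in range(3):
            e = self.enc[i](cur, train)
            skips.append(e)
            shapes[f"encoder{i + 1}"] = e.shape[1:]
            cur = self.enc_pools[i](e, train)
            shapes[f"pool{i + 1}"] = cur.shape[1:]
        if self.with_bottleneck:
            cur = self.hourglasses[0](cur, train)
            shapes["hourglass1"] = cur.shape[1:]
            cur = self.scale_up(cur, train)
            shapes["scale_up"] = cur.shape[1:]
            cur = self.hourglasses[1](cur, train)
            shapes["hourglass2"] = cur.shape[1:]
            cur = self.scale_down(cur, train)
            shapes["scale_down"] = cur.shape[1:]
            cur = self.hourglasses[2](cur, train)
            shapes["hourglass3"] = cur.shape[1:]
        for i in range(3):
            cur = self.tconvs[i](cur, train)
            shapes[f"tconv{i + 1}"] = cur.shape[1:]
            cur = np.concatenate([cur, skips[2 - i]], axis=1)
            shapes[f"concat{i + 1}"] = cur.shape[1:]
            cur = self.dec[i](cur, train)
            shapes[f"decoder{i + 1}"] = cur.shape[1:]
        cur = self.out_act(self.head(cur, train), train)
        shapes["head"] = cur.shape[1:]
        self.stage_shapes_ = shapes
        return cur

    def backward(self, dy):
        w0, w1, w2 = self.widths
        splits = [w2, w1, w1]  # decoder-path channels entering each concat
        d = self.head.backward(self.out_act.backward(dy))
        dskips = [None, None, None]
        for i in reversed(range(3)):
            d = self.dec[i].backward(d)
            dskips[2 - i] = d[:, splits[i]:]
            d = self.tconvs[i].backward(np.ascontiguousarray(d[:, :splits[i]]))
        if self.with_bottleneck:
            d = self.hourglasses[2].backward(d)
            d = self.scale_down.backward(d)
            d = self.hourglasses[1].backward(d)
            d = self.scale_up.backward(d)
            d = self.hourglasses[0].backward(d)
        for i in reversed(range(3)):
            d = self.enc_pools[i].backward(d)
            d = self.enc[i].backward(d + dskips[i])
        return d

    def batch_norms(self) -> list:
        """Batch-norm layers in deterministic order (for checkpointing)."""
        bns = []
        for blk in self.enc + self.dec:
            bns.extend(l for l in blk.layers if isinstance(l, BatchNorm2d))
        return bns

    def predict(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Inference-mode forward over a (possibly large) batch."""
        outs = [self.forward(x[i:i + batch_size], train=False)
                for i in range(0, len(x), batch_size)]
        return np.concatenate(outs, axis=0)
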