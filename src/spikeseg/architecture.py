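"""Declarative network specifications, shape tracing, and model construction.

The two networks are described by small dataclasses rather than framework
objects, so their layer plan can be inspected, serialized, and shape-checked
by pure arithmetic (:func:`shape_trace`) without building any weights.  At
the default scale (256-px patches, widths 16/64/128) the traced shapes are
the published layer tables of the method; everything is configurable so a
CPU-scale variant (64-px patches, widths 4/8/16) exists for tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .nn.blocks import PatchNet

DEFAULT_WIDTHS = (16, 64, 128)
SMALL_WIDTHS = (4, 8, 16)


class SpecError(ValueError):
    """A network spec is internally inconsistent or incompatible with its input."""


@dataclass(frozen=True)
class TensorShape:
    height: int
    width: int
    channels: int

    def __post_init__(self):
        if min(self.height, self.width, self.channels) < 1:
            raise SpecError(f"tensor dims must be >= 1, got {self}")

    def as_tuple(self) -> Tuple[int, int, int]:
        return (self.height, self.width, self.channels)


@dataclass
class EncoderBlockSpec:
    in_channels: int
    width: int
    n_convs: int = 2
    pool: int = 2  # 2x2 window, stride 2


@dataclass
class HourglassSpec:
    channels: int
    n_levels: int = 4
    n_skips: int = 3
    rescale: Optional[str] = None  # "up" | "down" | None, applied after the hourglass


@dataclass
class DecoderBlockSpec:
    tconv_in: int
    tconv_out: int
    skip_channels: int
    width: int
    n_convs: int = 2


@dataclass
class NetworkSpec:
    name: str
    input_shape: TensorShape
    encoder: List[EncoderBlockSpec]
    bottleneck: List[HourglassSpec]
    decoder: List[DecoderBlockSpec]
    head_kernel: int = 3
    head_channels: int = 1

    @property
    def base_widths(self) -> Tuple[int, ...]:
        return tuple(b.width for b in self.encoder)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        return cls(
            name=d["name"],
            input_shape=TensorShape(**d["input_shape"]),
            encoder=[EncoderBlockSpec(**b) for b in d["encoder"]],
            bottleneck=[HourglassSpec(**b) for b in d["bottleneck"]],
            decoder=[DecoderBlockSpec(**b) for b in d["decoder"]],
            head_kernel=d.get("head_kernel", 3),
            head_channels=d.get("head_channels", 1),
        )


def _check_patch_size(patch_size: int) -> None:
    if patch_size % 8 != 0 or patch_size < 8:
        raise SpecError(
            f"patch size must be a positive multiple of 8 (three 2x2 pools), "
            f"got {patch_size}")


def lpnet_spec(base_widths=DEFAULT_WIDTHS, patch_size: int = 256,
               in_channels: int = 3) -> NetworkSpec:
    """Local-patch segmentation network: encoder, 3-hourglass bottleneck
    (one scale-up, one scale-down between them), mirrored decoder."""
    _check_patch_size(patch_size)
    w0, w1, w2 = base_widths
    return NetworkSpec(
        name="LPNet",
        input_shape=TensorShape(patch_size, patch_size, in_channels),
        encoder=[
            EncoderBlockSpec(in_channels, w0),
            EncoderBlockSpec(w0, w1),
            EncoderBlockSpec(w1, w2),
        ],
        bottleneck=[
            HourglassSpec(w2, rescale="up"),
            HourglassSpec(w2, rescale="down"),
            HourglassSpec(w2, rescale=None),
        ],
        decoder=[
            DecoderBlockSpec(w2, w2, w2, w2),
            DecoderBlockSpec(w2, w1, w1, w1),
            DecoderBlockSpec(w1, w1, w0, w0),
        ],
    )


def gmrnet_spec(base_widths=DEFAULT_WIDTHS, patch_size: int = 256,
                in_channels: int = 1) -> NetworkSpec:
    """Mask-refinement network: identical encoder/decoder, empty bottleneck."""
    spec = lpnet_spec(base_widths, patch_size, in_channels)
    spec.name = "GMRNet"
    spec.bottleneck = []
    return spec


def shape_trace(spec: NetworkSpec,
                input_shape: Optional[TensorShape] = None
                ) -> List[Tuple[str, TensorShape]]:
    """Pure-arithmetic walk of the spec: ordered (layer label, shape) pairs.

    3x3 pad-1 stride-1 convolutions preserve H and W; pools halve; the
    stride-2 transpose convolutions double; hourglasses preserve; concat
    sums channels.  Raises :class:`SpecError` naming the first failing
    layer on any incompatibility.
    """
    shape = input_shape or spec.input_shape
    if shape.channels != spec.encoder[0].in_channels:
        raise SpecError(
            f"encoder1: expects {spec.encoder[0].in_channels} input channels, "
            f"got {shape.channels}")
    trace = [("input", shape)]
    skip_widths = []
    h, w = shape.height, shape.width
    for i, blk in enumerate(spec.encoder, start=1):
        expected_in = spec.encoder[i - 2].width if i > 1 else spec.encoder[0].in_channels
        if blk.in_channels != expected_in:
            raise SpecError(f"encoder{i}: in_channels {blk.in_channels} != {expected_in}")
        trace.append((f"encoder{i}", TensorShape(h, w, blk.width)))
        if h % blk.pool or w % blk.pool:
            raise SpecError(f"pool{i}: cannot halve odd dims {h}x{w}")
        h, w = h // blk.pool, w // blk.pool
        trace.append((f"pool{i}", TensorShape(h, w, blk.width)))
        skip_widths.append(blk.width)
    c = spec.encoder[-1].width
    for i, hg in enumerate(spec.bottleneck, start=1):
        if hg.channels != c:
            raise SpecError(f"hourglass{i}: channels {hg.channels} != {c}")
        trace.append((f"hourglass{i}", TensorShape(h, w, c)))
        if hg.rescale == "up":
            h, w = h * 2, w * 2
            trace.append(("scale_up", TensorShape(h, w, c)))
        elif hg.rescale == "down":
            if h % 2 or w % 2:
                raise SpecError(f"scale_down after hourglass{i}: odd dims {h}x{w}")
            h, w = h // 2, w // 2
            trace.append(("scale_down", TensorShape(h, w, c)))
    cur_c = c
    for i, blk in enumerate(spec.decoder, start=1):
        if blk.tconv_in != cur_c:
            raise SpecError(f"tconv{i}: in_channels {blk.tconv_in} != {cur_c}")
        h, w = h * 2, w * 2
        trace.append((f"tconv{i}", TensorShape(h, w, blk.tconv_out)))
        if blk.skip_channels != skip_widths[-i]:
            raise SpecError(
                f"concat{i}: skip channels {blk.skip_channels} != encoder "
                f"width {skip_widths[-i]}")
        trace.append((f"concat{i}", TensorShape(h, w, blk.tconv_out + blk.skip_channels)))
        trace.append((f"decoder{i}", TensorShape(h, w, blk.width)))
        cur_c = blk.width
    if (h, w) != (shape.height, shape.width):
        raise SpecError(f"head: decoder output {h}x{w} != input {shape.height}x{shape.width}")
    trace.append(("head", TensorShape(h, w, spec.head_channels)))
    return trace


def build_network(spec: NetworkSpec, seed: int) -> PatchNet:
    """Instantiate the network with reproducible He-initialized weights.

    The spec is shape-traced first, so an inconsistent spec raises
    :class:`SpecError` before any weights are allocated.
    """
    shape_trace(spec)
    expected = lpnet_spec(spec.base_widths, spec.input_shape.height,
                          spec.encoder[0].in_channels)
    if [dataclasses.asdict(b) for b in spec.decoder] != \
            [dataclasses.asdict(b) for b in expected.decoder]:
        raise SpecError("decoder plan does not match the supported chassis")
    rng = np.random.default_rng(seed)
    model = PatchNet(
        in_channels=spec.encoder[0].in_channels,
        widths=spec.base_widths,
        with_bottleneck=len(spec.bottleneck) > 0,
        rng=rng,
    )
    model.spec = spec
    return model


def count_parameters(spec: NetworkSpec) -> int:
    """Closed-form trainable parameter count (weights + biases + batch-norm
    scale/shift) from the layer table; equals the built model's count."""

    def conv(k, cin, cout):
        return k * k * cin * cout + cout

    def block(cin, c):  # two 3x3 convs, each with a batch-norm
        return conv(3, cin, c) + 2 * c + conv(3, c, c) + 2 * c

    def residual(cin, mid, cout):
        n = conv(1, cin, mid) + conv(3, mid, mid) + conv(1, mid, cout)
        if cin != cout:
            n += conv(1, cin, cout)
        return n

    def hourglass(c):
        e = 2 * c
        n = residual(c, c, e) + 3 * residual(e, c, e)  # down tower
        n += 3 * residual(e, c, e)                     # skip branches
        n += 4 * residual(e, c, e)                     # up tower
        n += conv(1, e, c)                             # output projection
        return n

    total = 0
    for blk in spec.encoder:
        total += block(blk.in_channels, blk.width)
    for hg in spec.bottleneck:
        total += hourglass(hg.channels)
    for blk in spec.decoder:
        total += conv(3, blk.tconv_in, blk.tconv_out)  # transpose conv
        total += block(blk.tconv_out + blk.skip_channels, blk.width)
    total += conv(spec.head_kernel, spec.decoder[-1].width, spec.head_channels)
    return total


def realized_parameter_count(model: PatchNet) -> int:
    return sum(p.value.size for p in model.params())


def save_spec(spec: NetworkSpec, path) -> None:
    with open(path, "w") as fh:
        json.dump(spec.to_dict(), fh, indent=2)


def load_spec(path) -> NetworkSpec:
    with open(path) as fh:
        return NetworkSpec.from_dict(json.load(fh))


def save_checkpoint(model: PatchNet, path) -> None:
    """Weights + batch-norm running stats + embedded spec, as an .npz."""
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params())}
    for i, bn in enumerate(model.batch_norms()):
        arrays[f"bn{i}_mean"] = bn.running_mean
        arrays[f"bn{i}_var"] = bn.running_var
    arrays["spec_json"] = np.frombuffer(
        json.dumps(model.spec.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> PatchNet:
    data = np.load(path)
    spec = NetworkSpec.from_dict(json.loads(bytes(data["spec_json"]).decode()))
    model = build_network(spec, seed=0)
    for i, p in enumerate(model.params()):
        arr = data[f"p{i}"]
        if arr.shape != p.value.shape:
            raise SpecError(f"checkpoint mismatch at parameter {i}")
        p.value = arr.astype(float)
    for i, bn in enumerate(model.batch_norms()):
        bn.running_mean = data[f"bn{i}_mean"].astype(float)
        bn.running_var = data[f"bn{i}_var"].astype(float)
    return model
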