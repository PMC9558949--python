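"""The three classifier architectures, as declarative specs plus a runnable
network built on the numpy engine in :mod:`perinet.nn`.

All three are plain reduction networks: spatial size is reduced purely by
strided convolutions (no pooling, no normalization layers), followed by two
fully connected layers and a softmax over the two lymph-node classes.

* ``SFB-NET`` — 3D, three blocks of 5x5x5 kernels at stride 4 (padding 2),
  for the fixed 160x160x80 box.
* ``VB-NET`` — 3D, five blocks of 4x4x4 kernels at stride 2, padding 1 on
  blocks 1-4 and 0 on the last, for 64^3 cubes; collapses 64 -> 1 spatially.
* ``2DS-NET`` — the same scheme with 2D 4x4 kernels, for 64x64 slices.

Channel widths double per block (16, 32, ... ), a documented convention:
the architecture family fixes kernels/strides/padding but not widths.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import nn

__all__ = [
    "ArchitectureSpec",
    "ConvBlock",
    "build",
    "output_spatial_shape",
    "Network",
    "NET_NAMES",
    "NET_FOR_OPTION",
]

NET_NAMES = ("SFB-NET", "VB-NET", "2DS-NET")

#: which network consumes which bounding option's samples
NET_FOR_OPTION = {
    "sfb": "SFB-NET",
    "svb": "VB-NET",
    "sib": "VB-NET",
    "slvb": "VB-NET",
    "slib": "VB-NET",
    "2ds": "2DS-NET",
}


@dataclass(frozen=True)
class ConvBlock:
    kernel: int
    stride: int
    padding: int
    out_channels: int


@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative description of one reduction network."""

    name: str
    dimensionality: str  # "3D" or "2D"
    input_shape: tuple[int, ...]  # channels-first, e.g. (4, 64, 64, 64)
    blocks: tuple[ConvBlock, ...]
    head: tuple[int, ...]  # fully connected widths, ending in 2

    @property
    def ndim(self) -> int:
        return 3 if self.dimensionality == "3D" else 2

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "name": self.name,
            "dimensionality": self.dimensionality,
            "input_shape": list(self.input_shape),
            "blocks": [
                {
                    "kernel": b.kernel,
                    "stride": b.stride,
                    "padding": b.padding,
                    "out_channels": b.out_channels,
                }
                for b in self.blocks
            ],
            "head": list(self.head),
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @staticmethod
    def from_yaml(path: str | Path) -> "ArchitectureSpec":
        doc = yaml.safe_load(Path(path).read_text())
        return ArchitectureSpec(
            name=doc["name"],
            dimensionality=doc["dimensionality"],
            input_shape=tuple(doc["input_shape"]),
            blocks=tuple(ConvBlock(**b) for b in doc["blocks"]),
            head=tuple(doc["head"]),
        )


def _scaled(channels: list[int], width_scale: float) -> list[int]:
    return [max(2, int(round(c * width_scale))) for c in channels]


def build(name: str, width_scale: float = 1.0) -> ArchitectureSpec:
    """Return the canonical spec for one of the three networks.

    ``width_scale`` scales the channel progression (kernels, strides,
    padding and depth are untouched); it exists so small-scale experiments
    can train a lighter network of the same family.
    """
    if name == "SFB-NET":
        widths = _scaled([16, 32, 64], width_scale)
        blocks = tuple(ConvBlock(5, 4, 2, c) for c in widths)
        return ArchitectureSpec(
            name=name,
            dimensionality="3D",
            input_shape=(4, 160, 160, 80),
            blocks=blocks,
            head=(128, 2),
        )
    if name in ("VB-NET", "2DS-NET"):
        widths = _scaled([16, 32, 64, 128, 256], width_scale)
        blocks = tuple(
            ConvBlock(4, 2, 1 if i < 4 else 0, c) for i, c in enumerate(widths)
        )
        if name == "VB-NET":
            return ArchitectureSpec(
                name=name,
                dimensionality="3D",
                input_shape=(4, 64, 64, 64),
                blocks=blocks,
                head=(128, 2),
            )
        return ArchitectureSpec(
            name=name,
            dimensionality="2D",
            input_shape=(4, 64, 64),
            blocks=blocks,
            head=(128, 2),
        )
    raise ValueError(f"unknown network name {name!r}; valid: {NET_NAMES}")


def output_spatial_shape(spec: ArchitectureSpec, input_shape=None) -> tuple[int, ...]:
    """Spatial shape after all reduction blocks, by convolution arithmetic.

    Applies ``floor((D + 2p - k) / s) + 1`` per block per axis; raises if
    any intermediate dimension collapses below 1.
    """
    input_shape = tuple(input_shape or spec.input_shape)
    if input_shape != tuple(spec.input_shape):
        raise ValueError(
            f"{spec.name} expects input shape {spec.input_shape}, got {input_shape}"
        )
    shape = list(input_shape[1:])
    for bi, b in enumerate(spec.blocks):
        for ax, d in enumerate(shape):
            o = (d + 2 * b.padding - b.kernel) // b.stride + 1
            if o < 1:
                raise ValueError(
                    f"{spec.name}: axis {ax} collapses below 1 at block {bi + 1}"
                )
            shape[ax] = o
    return tuple(shape)


class Network:
    """A trainable classifier instantiated from an :class:`ArchitectureSpec`.

    Accepts exactly the spec's canonical input shape (channels first) and
    produces two-class probabilities via softmax.  Weight initialization is
    fully determined by ``seed``.
    """

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        layers = []
        in_c = spec.input_shape[0]
        for bi, b in enumerate(spec.blocks):
            layers.append(
                nn.ConvNd(
                    in_c, b.out_channels, b.kernel, b.stride, b.padding,
                    ndim=spec.ndim, rng=rng,
                    needs_input_grad=bi > 0,  # no gradient w.r.t. the image itself
                )
            )
            layers.append(nn.ReLU())
            in_c = b.out_channels
        layers.append(nn.Flatten())
        flat = in_c * int(np.prod(output_spatial_shape(spec)))
        widths = list(spec.head)
        prev = flat
        for i, w in enumerate(widths):
            layers.append(nn.Dense(prev, w, rng))
            if i < len(widths) - 1:
                layers.append(nn.ReLU())
            prev = w
        self.model = nn.Sequential(layers)

    # -- inference ---------------------------------------------------------
    def _check_batch(self, batch: np.ndarray) -> np.ndarray:
        batch = np.asarray(batch, dtype=np.float32)
        if batch.ndim != len(self.spec.input_shape) + 1 or tuple(
            batch.shape[1:]
        ) != tuple(self.spec.input_shape):
            raise ValueError(
                f"{self.spec.name} expects batches of shape "
                f"(B, {', '.join(map(str, self.spec.input_shape))}), "
                f"got {batch.shape}"
            )
        return batch

    def logits(self, batch: np.ndarray, train: bool = False) -> np.ndarray:
        return self.model.forward(self._check_batch(batch), train=train)

    def forward(self, batch: np.ndarray) -> np.ndarray:
        """Class probabilities, shape (B, 2); rows sum to 1."""
        return nn.softmax(self.logits(batch))

    predict_proba = forward

    def num_parameters(self) -> int:
        return int(sum(p.size for p in self.model.parameters()))

    # -- checkpointing -----------------------------------------------------
    def save(self, path: str | Path) -> None:
        state = {f"p{i}": p for i, p in enumerate(self.model.parameters())}
        np.savez(path, **state)

    def load(self, path: str | Path) -> None:
        with np.load(path) as data:
            self.model.set_state([data[f"p{i}"] for i in range(len(data.files))])


def forward(network: Network, batch: np.ndarray) -> np.ndarray:
    """Module-level convenience: class probabilities for a batch."""
    return network.forward(batch)
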