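"""Configurable encoder-decoder segmentation family on the numpy engine.

Five architectures share one parameterization (depth and base filter
count) and one contract: input (B, 3, H, W), output a single-logit plane
(B, 1, H, W) at input resolution.

* ``unet`` — plain double-conv blocks with skip concatenation.
* ``res_unet`` — residual double-conv blocks (1x1 projection on the skip
  when channel counts differ).
* ``attention_unet`` — additive attention gates on the skip connections:
  the skip is scaled by ``sigmoid(psi(relu(Wg g + Wx x)))`` where ``g`` is
  the upsampled decoder feature.
* ``nested_unet`` — a dense grid of nodes X[i][j] where each node sees all
  previous same-level outputs plus the upsampled deeper node.
* ``attention_dense_unet`` — attention gates combined with two-step dense
  blocks (the second convolution sees the block input concatenated with
  the first convolution's output).

The ``FusionModel`` wrapper prepends the learnable 1x1 channel mixer
(5 -> 3 planes, initialized to pass the grayscale plane through) so that
training starts exactly from the grayscale baseline.
"""

from __future__ import annotations

from typing import Dict, List

import numpy as np

from . import engine as E
from .engine import Tensor

__all__ = ["SegmentationNet", "FusionModel", "MODEL_FAMILIES"]

MODEL_FAMILIES = ("unet", "attention_unet", "nested_unet", "res_unet",
                  "attention_dense_unet")


def _he(rng: np.random.Generator, shape) -> np.ndarray:
    fan_in = int(np.prod(shape[1:]))
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class _ParamStore:
    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.params: Dict[str, Tensor] = {}

    def conv(self, name: str, cin: int, cout: int, k: int = 3):
        if name + ".w" not in self.params:
            self.params[name + ".w"] = Tensor(
                _he(self.rng, (cout, cin, k, k)), requires_grad=True)
            self.params[name + ".b"] = Tensor(
                np.zeros(cout, np.float32), requires_grad=True)
        return self.params[name + ".w"], self.params[name + ".b"]


class SegmentationNet:
    """One member of the encoder-decoder family."""

    def __init__(self, family: str = "unet", depth: int = 3,
                 base_filters: int = 8, in_channels: int = 3,
                 seed: int = 0):
        if family not in MODEL_FAMILIES:
            raise ValueError(f"unknown family {family!r}; "
                             f"choose from {MODEL_FAMILIES}")
        if depth < 2:
            raise ValueError("depth must be >= 2")
        self.family = family
        self.depth = depth
        self.base_filters = base_filters
        self.in_channels = in_channels
        self.store = _ParamStore(np.random.default_rng(seed))
        self._build()

    # -- construction ------------------------------------------------------
    def _filters(self, level: int) -> int:
        return self.base_filters * (2 ** level)

    def _build(self) -> None:
        s, d = self.store, self.depth
        cin = self.in_channels
        if self.family == "nested_unet":
            # encoder column
            for i in range(d + 1):
                self._build_block(f"x{i}0", cin if i == 0 else self._filters(i - 1),
                                  self._filters(i))
            # nested nodes
            for j in range(1, d + 1):
                for i in range(0, d + 1 - j):
                    cat_ch = self._filters(i) * j + self._filters(i + 1)
                    self._build_block(f"x{i}{j}", cat_ch, self._filters(i))
            s.conv("head", self._filters(0), 1, k=1)
            return
        for i in range(d):
            self._build_block(f"enc{i}", cin if i == 0 else self._filters(i - 1),
                              self._filters(i))
        self._build_block("bottleneck", self._filters(d - 1), self._filters(d))
        for i in reversed(range(d)):
            up_ch = self._filters(i + 1)
            if self.family in ("attention_unet", "attention_dense_unet"):
                inter = max(1, self._filters(i) // 2)
                s.conv(f"att{i}.g", up_ch, inter, k=1)
                s.conv(f"att{i}.x", self._filters(i), inter, k=1)
                s.conv(f"att{i}.psi", inter, 1, k=1)
            self._build_block(f"dec{i}", up_ch + self._filters(i),
                              self._filters(i))
        s.conv("head", self._filters(0), 1, k=1)

    def _build_block(self, name: str, cin: int, cout: int) -> None:
        s = self.store
        if self.family == "attention_dense_unet":
            s.conv(name + ".c1", cin, cout)
            s.conv(name + ".c2", cin + cout, cout)
        else:
            s.conv(name + ".c1", cin, cout)
            s.conv(name + ".c2", cout, cout)
            if self.family == "res_unet" and cin != cout:
                s.conv(name + ".proj", cin, cout, k=1)

    # -- forward -----------------------------------------------------------
    def _block(self, name: str, x: Tensor) -> Tensor:
        s = self.store
        if self.family == "attention_dense_unet":
            h1 = E.relu(E.conv2d(x, *s.conv(name + ".c1", 0, 0)))
            h2 = E.relu(E.conv2d(E.concat([x, h1]), *s.conv(name + ".c2", 0, 0)))
            return h2
        h = E.relu(E.conv2d(x, *s.conv(name + ".c1", 0, 0)))
        h = E.conv2d(h, *s.conv(name + ".c2", 0, 0))
        if self.family == "res_unet":
            shortcut = x
            if (name + ".proj.w") in s.params:
                shortcut = E.conv2d(x, *s.conv(name + ".proj", 0, 0))
            h = E.add(h, shortcut)
        return E.relu(h)

    def _attend(self, level: int, g: Tensor, x: Tensor) -> Tensor:
        s = self.store
        a = E.relu(E.add(E.conv2d(g, *s.conv(f"att{level}.g", 0, 0)),
                         E.conv2d(x, *s.conv(f"att{level}.x", 0, 0))))
        psi = E.sigmoid(E.conv2d(a, *s.conv(f"att{level}.psi", 0, 0)))
        return E.mul(x, psi)

    def forward(self, x: Tensor) -> Tensor:
        d = self.depth
        if self.family == "nested_unet":
            grid: Dict[tuple, Tensor] = {}
            h = x
            for i in range(d + 1):
                h = self._block(f"x{i}0", h if i == 0 else E.maxpool2(grid[(i - 1, 0)]))
                grid[(i, 0)] = h
            for j in range(1, d + 1):
                for i in range(0, d + 1 - j):
                    prev = [grid[(i, t)] for t in range(j)]
                    up = E.upsample2(grid[(i + 1, j - 1)])
                    grid[(i, j)] = self._block(f"x{i}{j}", E.concat(prev + [up]))
            return E.conv2d(grid[(0, d)], *self.store.conv("head", 0, 0))
        skips: List[Tensor] = []
        h = x
        for i in range(d):
            h = self._block(f"enc{i}", h)
            skips.append(h)
            h = E.maxpool2(h)
        h = self._block("bottleneck", h)
        for i in reversed(range(d)):
            up = E.upsample2(h)
            skip = skips[i]
            if self.family in ("attention_unet", "attention_dense_unet"):
                skip = self._attend(i, up, skip)
            h = self._block(f"dec{i}", E.concat([up, skip]))
        return E.conv2d(h, *self.store.conv("head", 0, 0))

    def parameters(self) -> List[Tensor]:
        return list(self.store.params.values())


class FusionModel:
    """Learnable 1x1 channel mixer (5 -> 3) followed by a segmentation net.

    Mixer weights start as the identity on the grayscale plane (1.0 in
    every output row) with zeros elsewhere, so the step-0 network input
    equals the plain radiograph regardless of the selected channels.
    """

    def __init__(self, family: str = "unet", depth: int = 3,
                 base_filters: int = 8, seed: int = 0):
        w0 = np.zeros((3, 5, 1, 1), np.float32)
        w0[:, 0, 0, 0] = 1.0
        self.mixer_w = Tensor(w0, requires_grad=True)
        self.mixer_b = Tensor(np.zeros(3, np.float32), requires_grad=True)
        self.net = SegmentationNet(family, depth, base_filters,
                                   in_channels=3, seed=seed)

    def forward(self, x5: Tensor) -> Tensor:
        fused = E.conv2d(x5, self.mixer_w, self.mixer_b)
        return self.net.forward(fused)

    def predict_proba(self, x5: np.ndarray) -> np.ndarray:
        """Sigmoid probabilities for a (B, 5, H, W) stack (no gradients)."""
        logits = self.forward(Tensor(np.asarray(x5, np.float32))).data
        return 1.0 / (1.0 + np.exp(-np.clip(logits[:, 0], -60, 60)))

    def parameters(self) -> List[Tensor]:
        return [self.mixer_w, self.mixer_b] + self.net.parameters()
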