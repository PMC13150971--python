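"""Early fusion of the heuristic channels with the grayscale radiograph.

The channel set is five aligned planes at a fixed working resolution: the
grayscale image ``Io`` plus four heuristic priors — two Canny variants
(``cn1``, ``cn2``), the pruned LoG lung representation (``log``) and the
heuristic's predicted lung mask (``pm``).  A channel *combination* is
``Io`` together with any subset of the four priors, giving 2^4 = 16
distinct configurations.  Selection zeroes out inactive planes; a
learnable 1x1 mixer then projects the five planes to three.  With its
default initialization (weight 1 on ``Io`` in each output row, all other
weights and biases 0) the mixer reproduces the grayscale image exactly, so
training starts from the plain-radiograph baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations as itercombos
from typing import List, Sequence, Tuple

import numpy as np
from skimage.transform import resize

__all__ = ["CHANNEL_NAMES", "ChannelSet", "Combination", "MixerParams",
           "build_channel_set", "enumerate_combinations", "selector_vector",
           "apply_selection", "channel_mixer"]

CHANNEL_NAMES: Tuple[str, ...] = ("cn1", "cn2", "log", "pm")


@dataclass
class ChannelSet:
    """Five aligned float planes in [0, 1] at the working resolution."""

    image: np.ndarray
    cn1: np.ndarray
    cn2: np.ndarray
    log: np.ndarray
    pm: np.ndarray

    def stack(self) -> np.ndarray:
        """(5, H, W) float array in plane order (Io, cn1, cn2, log, pm)."""
        return np.stack([self.image, self.cn1, self.cn2, self.log, self.pm])


@dataclass(frozen=True)
class Combination:
    """One channel combination: Io plus a subset of the heuristic priors."""

    index: int                       # 1-based
    selector: Tuple[bool, bool, bool, bool]  # over (cn1, cn2, log, pm)

    @property
    def label(self) -> str:
        parts = ["Io"] + [n for n, s in zip(CHANNEL_NAMES, self.selector) if s]
        return "_".join(parts)


def _resize_gray(img: np.ndarray, size: int) -> np.ndarray:
    out = resize(np.asarray(img, np.float64), (size, size), order=1,
                 anti_aliasing=False, preserve_range=True, mode="edge")
    return np.clip(out, 0.0, 1.0)


def _resize_binary(mask: np.ndarray, size: int) -> np.ndarray:
    out = resize(np.asarray(mask, np.float64), (size, size), order=0,
                 anti_aliasing=False, preserve_range=True, mode="edge")
    return (out > 0.5).astype(np.float64)


def build_channel_set(image: np.ndarray, canny1: np.ndarray,
                      canny2: np.ndarray, log_edges: np.ndarray,
                      predicted_mask: np.ndarray, size: int = 256) -> ChannelSet:
    """Resize the Stage-1 planes to ``size`` x ``size`` and cast to [0, 1].

    The grayscale plane is resized bilinearly; binary planes use
    nearest-neighbor so they stay exactly {0, 1}.
    """
    for name, plane in (("canny1", canny1), ("canny2", canny2),
                        ("log", log_edges), ("pm", predicted_mask)):
        if plane is None:
            raise ValueError(f"missing Stage-1 artifact: {name}")
    return ChannelSet(
        image=_resize_gray(image, size),
        cn1=_resize_binary(canny1, size),
        cn2=_resize_binary(canny2, size),
        log=_resize_binary(log_edges, size),
        pm=_resize_binary(predicted_mask, size),
    )


def enumerate_combinations() -> List[Combination]:
    """All 16 combinations, ordered by subset size then channel order."""
    combos: List[Combination] = []
    idx = 1
    for r in range(len(CHANNEL_NAMES) + 1):
        for subset in itercombos(range(len(CHANNEL_NAMES)), r):
            sel = tuple(i in subset for i in range(len(CHANNEL_NAMES)))
            combos.append(Combination(index=idx, selector=sel))
            idx += 1
    return combos


def selector_vector(combo: Combination) -> np.ndarray:
    """Length-5 selection vector with the always-on Io plane prepended."""
    return np.array([1.0] + [1.0 if s else 0.0 for s in combo.selector])


def apply_selection(stack: np.ndarray, combo: Combination) -> np.ndarray:
    """Zero out deselected planes of a (..., 5, H, W) stack."""
    arr = np.asarray(stack, dtype=np.float64)
    if arr.shape[-3] != 5:
        raise ValueError(f"expected 5 channel planes, got {arr.shape[-3]}")
    m = selector_vector(combo)
    return arr * m[(...,) + (None,) * 2]


@dataclass
class MixerParams:
    """Weights of the learnable 1x1 channel mixer (3 outputs x 5 inputs)."""

    weights: np.ndarray = field(
        default_factory=lambda: MixerParams.default_weights())
    bias: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @staticmethod
    def default_weights() -> np.ndarray:
        w = np.zeros((3, 5))
        w[:, 0] = 1.0  # pass the grayscale plane through unchanged
        return w


def channel_mixer(stack: np.ndarray, params: MixerParams | None = None
                  ) -> np.ndarray:
    """Per-pixel linear projection of 5 planes to 3: ``W @ x + b``."""
    p = params or MixerParams()
    w = np.asarray(p.weights, dtype=np.float64)
    b = np.asarray(p.bias, dtype=np.float64)
    if w.shape != (3, 5):
        raise ValueError(f"mixer weights must be 3x5, got {w.shape}")
    arr = np.asarray(stack, dtype=np.float64)
    if arr.shape[0] != 5:
        raise ValueError(f"expected a (5, H, W) stack, got {arr.shape}")
    return np.einsum("ci,ihw->chw", w, arr) + b[:, None, None]
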