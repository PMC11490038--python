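"""Per-pixel viability classification of two-channel fluorescence slices.

LIVE/DEAD BacLight semantics: SYTO 9 (green) stains all bacteria, propidium
iodide (red) only membrane-compromised ones.  On the 0-255 intensity scale a
pixel is

* VIABLE      — green > 100 and red < 100 (green-dominant),
* NONVIABLE   — red > 100, whatever the green level: this covers both the
  red-only case and the visually orange double-high case, because PI
  positivity indicates a compromised membrane regardless of SYTO 9 signal,
* BACKGROUND  — everything else, including pixels sitting exactly on a
  threshold (the classification rules use strict inequalities, so the
  boundary value 100 satisfies neither the "high" nor the "low" test).

Both thresholds default to 100 and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "BACKGROUND",
    "VIABLE",
    "NONVIABLE",
    "Thresholds",
    "ClassMap",
    "classify_slice",
    "classify_stack",
    "class_counts",
]

BACKGROUND: int = 0
VIABLE: int = 1
NONVIABLE: int = 2

_LABEL_NAMES = {BACKGROUND: "BACKGROUND", VIABLE: "VIABLE", NONVIABLE: "NONVIABLE"}


@dataclass(frozen=True)
class Thresholds:
    """Channel intensity thresholds on the 0-255 scale (defaults 100/100)."""

    green_thr: float = 100.0
    red_thr: float = 100.0

    def __post_init__(self) -> None:
        for name, v in (("green_thr", self.green_thr), ("red_thr", self.red_thr)):
            if not (0 < v < 255):
                raise ValueError(f"{name} must lie in (0, 255), got {v}")


@dataclass
class ClassMap:
    """Per-slice per-pixel labels, same shape as the source stack.

    ``labels`` is ``(n_slices, H, W)`` of ``uint8`` codes BACKGROUND=0,
    VIABLE=1, NONVIABLE=2; slice order follows the stack (surface first).
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim == 2:
            self.labels = self.labels[None, ...]
        if self.labels.ndim != 3:
            raise ValueError("labels must be (n_slices, H, W)")
        if not np.isin(self.labels, (BACKGROUND, VIABLE, NONVIABLE)).all():
            raise ValueError("labels contain unknown codes")

    @property
    def n_slices(self) -> int:
        return self.labels.shape[0]

    def copy(self) -> "ClassMap":
        return ClassMap(self.labels.copy())

    def viable_mask(self, index: int) -> np.ndarray:
        return self.labels[index] == VIABLE

    def nonviable_mask(self, index: int) -> np.ndarray:
        return self.labels[index] == NONVIABLE

    def bacterial_mask(self, index: int) -> np.ndarray:
        """Union of viable and non-viable pixels: the bacterial aggregates."""
        return self.labels[index] != BACKGROUND

    def to_tiff(self, path: str | Path) -> Path:
        """Export label codes as a multi-page TIFF for visual QC."""
        path = Path(path)
        tifffile.imwrite(path, self.labels)
        return path


def classify_slice(
    green: np.ndarray, red: np.ndarray, thr: Thresholds = Thresholds()
) -> np.ndarray:
    """Classify one optical section; returns a label raster (``uint8``)."""
    green = np.asarray(green)
    red = np.asarray(red)
    if green.shape != red.shape:
        raise ValueError(f"channel shapes differ: {green.shape} vs {red.shape}")
    labels = np.zeros(green.shape, dtype=np.uint8)
    labels[(green > thr.green_thr) & (red < thr.red_thr)] = VIABLE
    labels[red > thr.red_thr] = NONVIABLE  # red-dominant rule takes precedence
    return labels


def classify_stack(stack, thr: Thresholds = Thresholds()) -> ClassMap:
    """Classify every slice of a :class:`~bvquant.stacks.ZStack`."""
    labels = np.stack(
        [classify_slice(g, r, thr) for g, r in zip(stack.green, stack.red)]
    )
    return ClassMap(labels)


def class_counts(labels: np.ndarray) -> tuple[int, int, int]:
    """Pixel tally ``(viable, nonviable, background)`` of one label slice.

    The three counts always partition the slice: they sum to its pixel count.
    """
    labels = np.asarray(labels)
    viable = int((labels == VIABLE).sum())
    nonviable = int((labels == NONVIABLE).sum())
    background = int(labels.size - viable - nonviable)
    return viable, nonviable, background
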