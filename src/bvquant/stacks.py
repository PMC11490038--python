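"""Two-channel confocal z-stack container, TIFF I/O, manifests and projection.

A :class:`ZStack` holds registered green (SYTO 9) and red (propidium iodide)
intensity rasters for every optical section of a field, ordered from the
biofilm surface (index 0) down to the substrate (last index).  Intensities are
kept on the 0-255 scale the downstream classification thresholds are quoted
on; deeper bit depths are linearly rescaled on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ZStack",
    "SampleManifest",
    "StackFormatError",
    "DEFAULT_Z_STEP_UM",
    "DEFAULT_PIXEL_SIZE_UM",
    "read_stack",
    "write_stack",
    "project_stack",
    "read_manifest",
]

#: Optical sectioning interval of the acquisition protocol, in micrometres.
DEFAULT_Z_STEP_UM = 0.71

#: Lateral pixel edge length in micrometres.  Back-derived so that the
#: 250 um^2 minimum-aggregate gate corresponds to exactly 4750 pixels
#: (sqrt(250 / 4750) ~= 0.2294 um), matching the acquisition geometry the
#: gate was stated for.  Always overridable per stack or via config.
DEFAULT_PIXEL_SIZE_UM = (250.0 / 4750.0) ** 0.5

GELS = ("TEST", "CONTROL")
EXPERIMENTS = ("SALIVA", "BIOFILM")
TIMEPOINTS = ("BASAL", "5MIN", "1H", "3H", "5H", "7H")


class StackFormatError(ValueError):
    """Raised when an image file cannot be interpreted as a two-channel stack."""


@dataclass
class ZStack:
    """Ordered z-series of registered green/red intensity slices.

    Parameters
    ----------
    green, red
        Arrays of shape ``(n_slices, height, width)`` on the 0-255 scale.
        ``float64`` or ``uint8``; both channels must share a shape.
    z_step_um
        Axial distance between consecutive slices, in micrometres.
    pixel_size_um
        Lateral pixel edge length in micrometres.
    field_id
        Opaque identifier of the microscope field.
    surface_first
        ``True`` when slice 0 is the biofilm surface and the last slice the
        substrate (the canonical orientation).  Constructors normalise
        base-first data before setting this flag.
    """

    green: np.ndarray
    red: np.ndarray
    z_step_um: float = DEFAULT_Z_STEP_UM
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    field_id: str = ""
    surface_first: bool = True

    def __post_init__(self) -> None:
        self.green = _as_stack(self.green)
        self.red = _as_stack(self.red)
        if self.green.shape != self.red.shape:
            raise StackFormatError(
                f"green shape {self.green.shape} != red shape {self.red.shape}"
            )
        if self.green.ndim != 3:
            raise StackFormatError("channels must be (n_slices, height, width)")
        for name, chan in (("green", self.green), ("red", self.red)):
            lo, hi = float(chan.min(initial=0)), float(chan.max(initial=0))
            if lo < 0 or hi > 255:
                raise StackFormatError(
                    f"{name} intensities outside [0, 255]: [{lo}, {hi}]"
                )
        if self.z_step_um <= 0:
            raise ValueError("z_step_um must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_slices(self) -> int:
        return self.green.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.green.shape

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um**2

    def slice_channels(self, index: int) -> tuple[np.ndarray, np.ndarray]:
        """Return the ``(green, red)`` rasters of one optical section."""
        return self.green[index], self.red[index]


def _as_stack(arr: np.ndarray | Sequence[np.ndarray]) -> np.ndarray:
    a = np.asarray(arr)
    if a.ndim == 2:
        a = a[None, ...]
    return a


def read_stack(
    path: str | Path,
    channel_map: Mapping[int, str] | None = None,
    bit_depth: int = 8,
    z_step_um: float = DEFAULT_Z_STEP_UM,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    surface_first: bool = True,
    field_id: str | None = None,
) -> ZStack:
    """Read a two-channel TIFF / OME-TIFF z-stack.

    Accepted on-disk layouts are ``(n_slices, 2, H, W)`` and ``(2, H, W)``
    (single slice).  ``channel_map`` assigns channel indices to ``"green"``
    and ``"red"`` (default ``{0: "green", 1: "red"}``).  Data deeper than
    8 bits are linearly rescaled so that the full scale ``2**bit_depth - 1``
    maps to 255; 8-bit data pass through unchanged.  ``surface_first=False``
    declares a base-first file, which is reversed into the canonical
    surface-to-base order.
    """
    path = Path(path)
    try:
        raw = tifffile.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # tifffile raises several format exceptions
        raise StackFormatError(f"cannot read TIFF stack {path}: {exc}") from exc

    raw = np.asarray(raw)
    if raw.ndim == 3:
        raw = raw[None, ...]  # single slice with channel axis
    if raw.ndim != 4:
        raise StackFormatError(
            f"{path}: expected (slices, channels, H, W) data, got shape {raw.shape}"
        )
    if raw.shape[1] != 2:
        raise StackFormatError(
            f"{path}: expected exactly 2 channels, found {raw.shape[1]}"
        )

    channel_map = dict(channel_map or {0: "green", 1: "red"})
    roles = sorted(channel_map.values())
    if roles != ["green", "red"]:
        raise StackFormatError(f"channel_map must assign green and red once: {channel_map}")
    idx_of = {role: idx for idx, role in channel_map.items()}

    data = raw.astype(np.float64)
    if bit_depth > 8:
        data *= 255.0 / (2**bit_depth - 1)
    if not surface_first:
        data = data[::-1]

    return ZStack(
        green=data[:, idx_of["green"]],
        red=data[:, idx_of["red"]],
        z_step_um=z_step_um,
        pixel_size_um=pixel_size_um,
        field_id=field_id if field_id is not None else path.stem,
        surface_first=True,
    )


def write_stack(stack: ZStack, path: str | Path) -> Path:
    """Write a stack as an 8-bit multi-page TIFF laid out ``(Z, C, H, W)``.

    Channel 0 is green, channel 1 red; intensities are rounded to ``uint8``,
    so 8-bit stacks round-trip exactly through :func:`read_stack`.
    """
    path = Path(path)
    arr = np.stack([stack.green, stack.red], axis=1)
    arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    tifffile.imwrite(path, arr)
    return path


def project_stack(stack: ZStack, method: str = "max") -> ZStack:
    """Collapse a z-stack to a single-slice overall projection image.

    Maximum-intensity projection per channel: each output pixel is the
    per-pixel maximum over all slices, taken independently in the green and
    red channels.  Used for the planktonic (saliva) experiment, where
    viability is scored on the overall projection rather than per section.
    """
    if method != "max":
        raise ValueError(f"unknown projection method: {method!r}")
    if stack.n_slices == 0:
        raise ValueError("cannot project an empty stack")
    return replace(
        stack,
        green=stack.green.max(axis=0, keepdims=True),
        red=stack.red.max(axis=0, keepdims=True),
    )


@dataclass
class SampleManifest:
    """Mapping of study samples to image files.

    One row per field: ``(subject_id, gel, experiment, timepoint, field_id,
    path)``.  ``gel`` is TEST (CHX + cymenol) or CONTROL (CHX), ``experiment``
    SALIVA or BIOFILM, ``timepoint`` one of the six sampling times.
    """

    rows: pd.DataFrame = field(repr=False)

    REQUIRED = ("subject_id", "gel", "experiment", "timepoint", "field_id", "path")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.rows.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        df = self.rows
        bad_gel = set(df["gel"]) - set(GELS)
        if bad_gel:
            raise ValueError(f"unknown gel labels: {sorted(bad_gel)}")
        bad_exp = set(df["experiment"]) - set(EXPERIMENTS)
        if bad_exp:
            raise ValueError(f"unknown experiment labels: {sorted(bad_exp)}")
        bad_tp = set(df["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise ValueError(f"unknown timepoints: {sorted(bad_tp)}")
        key = ["subject_id", "gel", "experiment", "timepoint", "field_id"]
        if df.duplicated(subset=key).any():
            dupes = df[df.duplicated(subset=key, keep=False)]
            raise ValueError(f"duplicate manifest keys:\n{dupes[key]}")

    def __len__(self) -> int:
        return len(self.rows)

    def sample_groups(self):
        """Iterate ``((subject, gel, experiment, timepoint), sub-frame)``."""
        return self.rows.groupby(
            ["subject_id", "gel", "experiment", "timepoint"], sort=True
        )


def read_manifest(path: str | Path) -> SampleManifest:
    """Read a sample manifest CSV (columns per :class:`SampleManifest`)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return SampleManifest(rows=df)
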