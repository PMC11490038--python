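"""Detection and exclusion of epithelial cell nuclei from the non-viable count.

Shed epithelial cells in saliva and plaque carry large, compact, brightly
PI-stained nuclei.  Their pixels are red-dominant and would otherwise inflate
the non-viable bacterial population, so connected red-dominant regions are
screened against three joint criteria — area above 200 pixels, solidity above
0.70, mean red intensity of at least 180 — and regions meeting all three are
relabelled as background before viability is computed.  Viability before and
after the exclusion is recorded for every slice.

Solidity here is ``area / convex_area`` where ``convex_area`` counts the
lattice pixels whose unit square overlaps (with positive area) the convex
hull of the region's pixel squares.  A single pixel and any solid rectangle
have solidity exactly 1; a 2x3 block missing one corner has solidity 5/6.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint
from skimage import measure

from .classify import BACKGROUND, NONVIABLE, ClassMap, class_counts

__all__ = [
    "Component",
    "EpithelialCriteria",
    "ExclusionReport",
    "pixel_convex_area",
    "find_red_components",
    "find_red_components_stack",
    "flag_epithelial",
    "exclude_epithelial",
]


@dataclass
class Component:
    """A connected region of red-dominant (non-viable labelled) pixels.

    ``solidity`` (area over filled-convex-hull pixel count) is computed
    lazily on first access: the epithelial filter only needs it for the few
    regions that already pass the cheaper area and brightness tests.
    """

    slice_index: int
    coords: np.ndarray  # (n, 2) array of (row, col) pixel coordinates
    area_px: int
    mean_red: float
    _solidity: float | None = None

    def __post_init__(self) -> None:
        if self.area_px < 1:
            raise ValueError("component must contain at least one pixel")
        if self._solidity is not None and not (0 < self._solidity <= 1 + 1e-9):
            raise ValueError(f"solidity out of range: {self._solidity}")
        if not (0 <= self.mean_red <= 255):
            raise ValueError(f"mean_red out of range: {self.mean_red}")

    @property
    def solidity(self) -> float:
        if self._solidity is None:
            self._solidity = self.area_px / pixel_convex_area(self.coords)
        return self._solidity


@dataclass(frozen=True)
class EpithelialCriteria:
    """Joint criteria identifying an epithelial nucleus.

    Defaults: area strictly greater than 200 px, solidity strictly greater
    than 0.70, mean red intensity of at least 180 (0-255 scale).
    """

    min_area_px: int = 200
    min_solidity: float = 0.70
    min_mean_intensity: float = 180.0

    def __post_init__(self) -> None:
        if self.min_area_px < 1:
            raise ValueError("min_area_px must be >= 1")
        if not (0 < self.min_solidity <= 1):
            raise ValueError("min_solidity must lie in (0, 1]")
        if not (0 < self.min_mean_intensity < 255):
            raise ValueError("min_mean_intensity must lie in (0, 255)")


def pixel_convex_area(coords: np.ndarray) -> int:
    """Pixel count of the filled convex hull of a set of pixels.

    The hull is taken over the four corners of every pixel's unit square;
    a lattice pixel is counted when its square overlaps the hull with
    positive area.  Collinear sets (rows, columns, single pixels) reduce to
    their own pixel count.
    """
    coords = np.asarray(coords)
    n = len(coords)
    if n == 1:
        return 1
    r, c = coords[:, 0], coords[:, 1]
    corners = np.concatenate(
        [
            np.stack([r, c], axis=1),
            np.stack([r + 1, c], axis=1),
            np.stack([r, c + 1], axis=1),
            np.stack([r + 1, c + 1], axis=1),
        ]
    )
    hull = MultiPoint(corners).convex_hull
    r0, r1 = int(r.min()), int(r.max())
    c0, c1 = int(c.min()), int(c.max())
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    boxes = shapely.box(rr.ravel(), cc.ravel(), rr.ravel() + 1, cc.ravel() + 1)
    overlap = shapely.area(shapely.intersection(boxes, hull))
    return int((overlap > 1e-9).sum())


def find_red_components(
    label_slice: np.ndarray,
    red: np.ndarray,
    connectivity: int = 8,
    slice_index: int = 0,
) -> list[Component]:
    """Extract connected components of NONVIABLE pixels from one slice.

    ``connectivity`` is 4 or 8 (neighbour count).  Components are disjoint
    and together cover every non-viable pixel of the slice.
    """
    label_slice = np.asarray(label_slice)
    red = np.asarray(red)
    if label_slice.shape != red.shape:
        raise ValueError(
            f"shape mismatch: labels {label_slice.shape} vs red {red.shape}"
        )
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = label_slice == NONVIABLE
    lab = measure.label(mask, connectivity=1 if connectivity == 4 else 2)
    out: list[Component] = []
    for region in measure.regionprops(lab, intensity_image=red):
        out.append(
            Component(
                slice_index=slice_index,
                coords=region.coords,
                area_px=int(region.area),
                mean_red=float(region.intensity_mean),
            )
        )
    return out


def find_red_components_stack(
    classmap: ClassMap, red_stack: np.ndarray, connectivity: int = 8
) -> list[Component]:
    """Per-slice component extraction over a whole classified stack."""
    comps: list[Component] = []
    for idx in range(classmap.n_slices):
        comps.extend(
            find_red_components(
                classmap.labels[idx], red_stack[idx], connectivity, slice_index=idx
            )
        )
    return comps


def flag_epithelial(
    components: list[Component], criteria: EpithelialCriteria = EpithelialCriteria()
) -> list[tuple[Component, bool]]:
    """Flag components meeting all three epithelial criteria jointly.

    Cheap tests (area, mean intensity) run first so the convex hull behind
    the solidity test is only evaluated for plausible nuclei.
    """
    return [
        (
            comp,
            comp.area_px > criteria.min_area_px
            and comp.mean_red >= criteria.min_mean_intensity
            and comp.solidity > criteria.min_solidity,
        )
        for comp in components
    ]


@dataclass
class ExclusionReport:
    """Per-slice bookkeeping of the epithelial exclusion step.

    ``bv_before`` / ``bv_after`` are the slice viability percentages before
    and after removing flagged nuclei (NaN where no bacterial pixels remain);
    ``excluded_px`` counts relabelled pixels, ``n_flagged`` flagged regions.
    """

    per_slice: pd.DataFrame = field(repr=False)

    @property
    def total_excluded_px(self) -> int:
        return int(self.per_slice["excluded_px"].sum())

    @property
    def n_flagged(self) -> int:
        return int(self.per_slice["n_flagged"].sum())


def _bv_pct(viable: int, nonviable: int) -> float:
    denom = viable + nonviable
    return 100.0 * viable / denom if denom > 0 else float("nan")


def exclude_epithelial(
    classmap: ClassMap, flagged: list[tuple[Component, bool]]
) -> tuple[ClassMap, ExclusionReport]:
    """Relabel flagged nuclei as background; report per-slice before/after BV.

    Only NONVIABLE pixels move (to BACKGROUND); viable counts are untouched,
    so per-slice viability can only stay equal or rise.
    """
    out = classmap.copy()
    n_slices, h, w = out.labels.shape
    flagged_by_slice: dict[int, list[Component]] = {}
    for comp, is_flagged in flagged:
        if not is_flagged:
            continue
        r, c = comp.coords[:, 0], comp.coords[:, 1]
        if comp.slice_index >= n_slices or r.max() >= h or c.max() >= w:
            raise ValueError("flagged component references out-of-range pixels")
        if not (out.labels[comp.slice_index][r, c] == NONVIABLE).all():
            raise ValueError("flagged component pixels are not NONVIABLE in this map")
        flagged_by_slice.setdefault(comp.slice_index, []).append(comp)

    rows = []
    for idx in range(n_slices):
        v_before, nv_before, _ = class_counts(classmap.labels[idx])
        excluded = 0
        n_flagged = 0
        for comp in flagged_by_slice.get(idx, []):
            r, c = comp.coords[:, 0], comp.coords[:, 1]
            out.labels[idx][r, c] = BACKGROUND
            excluded += comp.area_px
            n_flagged += 1
        v_after, nv_after, _ = class_counts(out.labels[idx])
        rows.append(
            {
                "slice_index": idx,
                "bv_before": _bv_pct(v_before, nv_before),
                "bv_after": _bv_pct(v_after, nv_after),
                "excluded_px": excluded,
                "n_flagged": n_flagged,
            }
        )
    return out, ExclusionReport(per_slice=pd.DataFrame(rows))
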