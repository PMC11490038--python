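"""Slice, field and sample-level viability metrics.

Per optical section, bacterial viability (BV) is

    BV% = 100 * viable_px / (viable_px + nonviable_px)

and a section enters the field mean only when its bacterial aggregate area
(viable + non-viable pixels, converted through the pixel size) reaches the
250 um^2 minimum.  Field-level metrics add the maximum field thickness (MFT,
from the topmost slice holding a sufficiently large bacterial cluster down to
the base, times the 0.71 um section step) and viability resolved into the
upper (surface-side) and lower (substrate-side) halves of the MFT span.
Sample summaries average fields without weighting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .classify import ClassMap, class_counts
from .epithelial import ExclusionReport

__all__ = [
    "MIN_AREA_UM2",
    "SliceViability",
    "FieldSummary",
    "SampleSummary",
    "slice_viability",
    "compute_mft",
    "split_layers",
    "layer_split_means",
    "field_summary",
    "sample_summary",
    "harmonised_layer_thickness",
]

#: Minimum bacterial-aggregate area for a section to be scored, in um^2
#: (approximately 4750 pixels at the default 0.2294 um pixel size).
MIN_AREA_UM2 = 250.0


@dataclass
class SliceViability:
    """Viability bookkeeping for one optical section."""

    slice_index: int
    viable_px: int
    nonviable_px: int
    aggregate_area_um2: float
    bv_pct: float  # NaN when no bacterial pixels
    included: bool


@dataclass
class FieldSummary:
    """Per-field results: mean BV, thickness, layer-resolved viability."""

    field_id: str
    slices: list[SliceViability] = field(repr=False)
    mean_bv_pct: float
    mean_bv_before_excl_pct: float
    mft_um: float
    upper_bv_pct: float
    lower_bv_pct: float
    excluded: bool  # True when no slice passed the area gate
    n_included: int


@dataclass
class SampleSummary:
    """Per-sample (subject x gel x experiment x timepoint) aggregation."""

    subject_id: str
    gel: str
    experiment: str
    timepoint: str
    n_fields: int
    mean_bv_pct: float
    mean_bv_before_excl_pct: float
    mean_thickness_um: float
    upper_bv_pct: float
    lower_bv_pct: float
    missing: bool  # True when every field was excluded


def slice_viability(
    counts: tuple[int, int, int],
    pixel_size_um: float,
    min_area_um2: float = MIN_AREA_UM2,
    slice_index: int = 0,
) -> SliceViability:
    """Score one section from its ``(viable, nonviable, background)`` counts."""
    viable, nonviable, _ = counts
    if viable < 0 or nonviable < 0:
        raise ValueError("pixel counts must be non-negative")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    area = (viable + nonviable) * pixel_size_um**2
    denom = viable + nonviable
    bv = 100.0 * viable / denom if denom > 0 else float("nan")
    return SliceViability(
        slice_index=slice_index,
        viable_px=viable,
        nonviable_px=nonviable,
        aggregate_area_um2=area,
        bv_pct=bv,
        included=area >= min_area_um2 - 1e-9,
    )


def _topmost_cluster_slice(classmap: ClassMap, min_aggregate_px: int) -> int | None:
    """Smallest slice index whose largest bacterial component reaches the gate."""
    for idx in range(classmap.n_slices):
        mask = classmap.bacterial_mask(idx)
        if not mask.any():
            continue
        lab = measure.label(mask, connectivity=2)
        largest = np.bincount(lab.ravel())[1:].max()
        if largest >= min_aggregate_px:
            return idx
    return None


def compute_mft(
    classmap: ClassMap, z_step_um: float, min_aggregate_px: int
) -> float:
    """Maximum field thickness in micrometres.

    Distance from the substrate (base slice) up to the peaks of the highest
    bacterial cell clusters: ``(n_slices - topmost) * z_step_um`` where
    ``topmost`` is the shallowest slice whose largest connected bacterial
    component (viable or non-viable, 8-connected) has at least
    ``min_aggregate_px`` pixels.  Returns 0 when no slice qualifies.
    """
    if min_aggregate_px < 1:
        raise ValueError("min_aggregate_px must be >= 1")
    top = _topmost_cluster_slice(classmap, min_aggregate_px)
    if top is None:
        return 0.0
    return (classmap.n_slices - top) * z_step_um


def split_layers(
    slices: list[SliceViability], mft_um: float, z_step_um: float
) -> tuple[list[SliceViability], list[SliceViability]]:
    """Split the MFT span into the upper (surface) and lower (base) halves.

    ``slices`` are the sections inside the MFT span, ordered surface to base.
    The split sits at MFT/2; with an odd slice count the middle section goes
    to the upper layer.  The two halves partition the input.  A zero MFT is
    degenerate: both layers come back empty.
    """
    if mft_um <= 0:
        return [], []
    n = len(slices)
    n_upper = math.ceil(n / 2)
    return list(slices[:n_upper]), list(slices[n_upper:])


def _mean_bv(slices: list[SliceViability], mode: str = "slice_mean") -> float:
    """Layer/field BV from included slices: mean of per-slice BVs, or the
    BV of the pooled pixel counts (``mode="pixel_pooled"``)."""
    ok = [s for s in slices if s.included and not math.isnan(s.bv_pct)]
    if not ok:
        return float("nan")
    if mode == "pixel_pooled":
        v = sum(s.viable_px for s in ok)
        nv = sum(s.nonviable_px for s in ok)
        return 100.0 * v / (v + nv)
    if mode != "slice_mean":
        raise ValueError(f"unknown layer BV mode: {mode!r}")
    return float(np.mean([s.bv_pct for s in ok]))


def layer_split_means(
    slices: list[SliceViability],
    mft_um: float,
    n_slices: int,
    z_step_um: float,
    span_um: float | None = None,
    mode: str = "slice_mean",
) -> tuple[float, float]:
    """Upper/lower layer BVs for one field.

    The MFT span runs from the topmost cluster-bearing slice to the base;
    ``span_um`` (harmonised layer mode) caps the span length measured from
    its top.  Returns ``(upper_bv, lower_bv)``, NaN where undefined.
    """
    if mft_um <= 0:
        return float("nan"), float("nan")
    span_len = mft_um if span_um is None else min(span_um, mft_um)
    top = n_slices - round(mft_um / z_step_um)
    n_span = max(1, round(span_len / z_step_um))
    span = [s for s in slices if top <= s.slice_index < top + n_span]
    upper, lower = split_layers(span, span_len, z_step_um)
    return _mean_bv(upper, mode), _mean_bv(lower, mode)


def field_summary(
    slices: list[SliceViability],
    classmap: ClassMap,
    exclusion: ExclusionReport,
    z_step_um: float,
    min_aggregate_px: int,
    field_id: str = "",
    layer_thickness_um: float | None = None,
    layer_bv_mode: str = "slice_mean",
) -> FieldSummary:
    """Aggregate per-slice results into a field summary.

    ``slices`` must be the post-exclusion viabilities, index-aligned with
    ``classmap`` (also post-exclusion); ``exclusion`` supplies the
    before-exclusion BVs.  ``layer_thickness_um``, when given, replaces the
    per-field MFT as the span length for the upper/lower split (harmonised
    layer mode); the split point is still half the span, from the top of the
    field's own MFT span.
    """
    if not slices:
        raise ValueError("field requires at least one slice")
    mft = compute_mft(classmap, z_step_um, min_aggregate_px)
    mean_bv = _mean_bv(slices)
    before = exclusion.per_slice.set_index("slice_index")["bv_before"]
    incl_idx = [s.slice_index for s in slices if s.included]
    mean_before = float(before.loc[incl_idx].mean()) if incl_idx else float("nan")

    upper_bv, lower_bv = layer_split_means(
        slices,
        mft_um=mft,
        n_slices=classmap.n_slices,
        z_step_um=z_step_um,
        span_um=layer_thickness_um,
        mode=layer_bv_mode,
    )
    n_included = sum(s.included for s in slices)
    return FieldSummary(
        field_id=field_id,
        slices=slices,
        mean_bv_pct=mean_bv,
        mean_bv_before_excl_pct=mean_before,
        mft_um=mft,
        upper_bv_pct=upper_bv,
        lower_bv_pct=lower_bv,
        excluded=n_included == 0,
        n_included=n_included,
    )


def sample_summary(
    fields: list[FieldSummary],
    subject_id: str,
    gel: str,
    experiment: str,
    timepoint: str,
) -> SampleSummary:
    """Unweighted mean across non-excluded fields of a sample.

    Mean thickness is the mean of the per-field MFTs.  A sample whose fields
    were all excluded by the area gate is flagged ``missing``.
    """
    ok = [f for f in fields if not f.excluded]

    def _mean(vals: list[float]) -> float:
        vals = [v for v in vals if not math.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    return SampleSummary(
        subject_id=subject_id,
        gel=gel,
        experiment=experiment,
        timepoint=timepoint,
        n_fields=len(fields),
        mean_bv_pct=_mean([f.mean_bv_pct for f in ok]),
        mean_bv_before_excl_pct=_mean([f.mean_bv_before_excl_pct for f in ok]),
        mean_thickness_um=_mean([f.mft_um for f in ok]),
        upper_bv_pct=_mean([f.upper_bv_pct for f in ok]),
        lower_bv_pct=_mean([f.lower_bv_pct for f in ok]),
        missing=not ok,
    )


def harmonised_layer_thickness(mfts_by_group: dict[tuple, list[float]]) -> float:
    """Common layer-span length for the harmonised split mode.

    Takes per-(gel, timepoint) collections of field MFTs, computes each
    group's median, and returns the minimum of those medians — a single span
    length applied to every field so that layer comparisons cover the same
    depth range in all samples.
    """
    medians = [float(np.median(v)) for v in mfts_by_group.values() if len(v)]
    if not medians:
        return 0.0
    return min(medians)
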