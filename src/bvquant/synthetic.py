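"""Ground-truthed synthetic inputs: image stacks and simulated trials.

Two generators stand in for the study's unavailable clinical data:

* :func:`generate_stack` paints two-channel z-stacks of clustered bacterial
  aggregates with a controlled per-slice viable fraction, optional planted
  epithelial nuclei (compact bright-red ellipses that satisfy the exclusion
  criteria by construction), and a biofilm thickness drawn from the observed
  11-19 um median range.  The returned ground truth records the realised
  per-slice pixel counts, every nucleus mask, and the true thickness, so the
  whole quantification pipeline can be checked against known answers.

* :func:`generate_trial` draws subject-level BV trajectories for a
  two-gel crossover (29 subjects by default) from truncated normals whose
  means/SDs default to the published per-timepoint summary statistics, with
  within-subject correlation induced by a shared subject effect.

Everything is deterministic under a fixed seed.

The default stack geometry is a deliberately scaled-down field (160 x 160
pixels at 1 um/pixel) rather than the full 2048 x 2048 acquisition format:
it preserves the structures that matter to the pipeline (aggregate clusters
large enough to pass the 250 um^2 gates, nuclei larger than 200 px) at a
fraction of the pixel budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .classify import BACKGROUND, NONVIABLE, VIABLE, ClassMap
from .stacks import DEFAULT_Z_STEP_UM, ZStack

__all__ = [
    "StackSpec",
    "TrialSpec",
    "StackGroundTruth",
    "TrialGroundTruth",
    "SALIVA_BV_SUMMARY",
    "BIOFILM_FULL_BV_SUMMARY",
    "BIOFILM_UPPER_BV_SUMMARY",
    "BIOFILM_LOWER_BV_SUMMARY",
    "generate_stack",
    "generate_trial",
    "fixture_small",
]

# ---------------------------------------------------------------------------
# Published per-(gel, timepoint) BV summary statistics (mean, SD in %),
# used as the default generating parameters for simulated trials.
# ---------------------------------------------------------------------------

TIMEPOINTS = ("BASAL", "5MIN", "1H", "3H", "5H", "7H")

SALIVA_BV_SUMMARY: dict[tuple[str, str], tuple[float, float]] = {
    ("TEST", "BASAL"): (87.00, 6.90),
    ("TEST", "5MIN"): (26.50, 8.20),
    ("TEST", "1H"): (28.90, 6.50),
    ("TEST", "3H"): (34.20, 16.00),
    ("TEST", "5H"): (36.90, 16.90),
    ("TEST", "7H"): (40.40, 18.60),
    ("CONTROL", "BASAL"): (88.90, 8.90),
    ("CONTROL", "5MIN"): (31.60, 24.70),
    ("CONTROL", "1H"): (36.00, 22.10),
    ("CONTROL", "3H"): (33.40, 14.50),
    ("CONTROL", "5H"): (40.10, 18.40),
    ("CONTROL", "7H"): (37.50, 18.10),
}

BIOFILM_FULL_BV_SUMMARY: dict[tuple[str, str], tuple[float, float]] = {
    ("TEST", "BASAL"): (91.00, 7.60),
    ("TEST", "5MIN"): (5.80, 14.70),
    ("TEST", "1H"): (3.70, 9.70),
    ("TEST", "3H"): (7.10, 9.30),
    ("TEST", "5H"): (12.50, 16.50),
    ("TEST", "7H"): (21.30, 22.10),
    ("CONTROL", "BASAL"): (88.40, 10.30),
    ("CONTROL", "5MIN"): (7.40, 15.20),
    ("CONTROL", "1H"): (5.30, 10.60),
    ("CONTROL", "3H"): (11.80, 21.10),
    ("CONTROL", "5H"): (12.60, 17.70),
    ("CONTROL", "7H"): (14.30, 18.70),
}

BIOFILM_UPPER_BV_SUMMARY: dict[tuple[str, str], tuple[float, float]] = {
    ("TEST", "BASAL"): (91.29, 7.79),
    ("TEST", "5MIN"): (3.94, 10.73),
    ("TEST", "1H"): (5.42, 12.38),
    ("TEST", "3H"): (8.02, 10.14),
    ("TEST", "5H"): (10.87, 16.16),
    ("TEST", "7H"): (24.13, 25.65),
    ("CONTROL", "BASAL"): (89.26, 10.21),
    ("CONTROL", "5MIN"): (9.16, 19.77),
    ("CONTROL", "1H"): (7.44, 14.24),
    ("CONTROL", "3H"): (14.37, 24.60),
    ("CONTROL", "5H"): (12.65, 18.17),
    ("CONTROL", "7H"): (15.96, 22.69),
}

BIOFILM_LOWER_BV_SUMMARY: dict[tuple[str, str], tuple[float, float]] = {
    ("TEST", "BASAL"): (86.29, 12.87),
    ("TEST", "5MIN"): (3.83, 11.28),
    ("TEST", "1H"): (9.04, 23.06),
    ("TEST", "3H"): (8.20, 10.71),
    ("TEST", "5H"): (13.08, 17.83),
    ("TEST", "7H"): (22.06, 27.65),
    ("CONTROL", "BASAL"): (83.81, 18.31),
    ("CONTROL", "5MIN"): (7.82, 19.24),
    ("CONTROL", "1H"): (8.71, 18.24),
    ("CONTROL", "3H"): (10.17, 18.51),
    ("CONTROL", "5H"): (10.58, 18.59),
    ("CONTROL", "7H"): (10.45, 18.62),
}


# ---------------------------------------------------------------------------
# Synthetic z-stacks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StackSpec:
    """Recipe for one synthetic two-channel field.

    Bacterial aggregates are Gaussian-profiled disks (radius 1-4 px, so a
    single blob never approaches the 200 px epithelial area criterion)
    grouped into a few tight clusters per slice; clustering makes the merged
    aggregates large enough for the thickness gate while individual blobs
    stay bacteria-sized.  Non-viable bacteria are painted with red peaks
    below 180 so that even merged red components can never satisfy the
    nucleus intensity criterion; planted nuclei are painted at 200-240 and
    are kept clear of bacterial pixels.
    """

    width: int = 160
    height: int = 160
    n_slices: int | None = None  # None: derive from thickness_um
    thickness_um: float | None = None  # None: draw uniformly from 11-19 um
    z_step_um: float = DEFAULT_Z_STEP_UM
    pixel_size_um: float = 1.0
    viable_fraction: float | Sequence[float] = 0.5
    n_clusters: int = 4
    blobs_per_cluster: int = 22
    cluster_sigma_px: float = 4.5
    n_scatter_blobs: int = 8
    blob_radius_px: tuple[float, float] = (1.0, 4.0)
    n_epithelial: int = 0
    epithelial_radius_px: tuple[float, float] = (9.0, 14.0)
    epithelial_intensity: tuple[float, float] = (200.0, 240.0)
    viable_peak: tuple[float, float] = (150.0, 220.0)
    nonviable_peak: tuple[float, float] = (130.0, 170.0)
    background_level: float = 20.0
    noise_sd: float = 4.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("frame dimensions must be positive")
        fracs = np.atleast_1d(np.asarray(self.viable_fraction, dtype=float))
        if ((fracs < 0) | (fracs > 1)).any():
            raise ValueError("viable_fraction must lie in [0, 1]")
        if self.nonviable_peak[1] >= 180:
            raise ValueError(
                "non-viable peak intensity must stay below the 180 nucleus criterion"
            )
        if self.epithelial_intensity[0] < 180:
            raise ValueError("epithelial intensity must be >= 180 by construction")


@dataclass
class StackGroundTruth:
    """Realised truth for one generated stack."""

    viable_px: list[int]  # per slice, painted bacterial pixels above threshold
    nonviable_px: list[int]
    viable_fraction: list[float]  # realised per-slice pixel fraction
    target_fraction: list[float]  # the spec's requested fraction per slice
    nucleus_masks: list[tuple[int, np.ndarray]] = field(repr=False)  # (slice, coords)
    thickness_um: float = 0.0


def _disk_offsets(radius: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integer offsets within ``radius`` and the Gaussian radial profile."""
    r = int(np.ceil(radius))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = dy**2 + dx**2
    inside = d2 <= radius**2
    # gentle Gaussian shoulder: ~0.84 of the peak at the rim, so every
    # painted pixel of a blob stays above the 100 classification threshold
    profile = np.exp(-0.5 * d2 / (1.69 * radius) ** 2)
    return dy[inside], dx[inside], profile[inside]


def _paint_blob(chan: np.ndarray, y: int, x: int, radius: float, peak: float) -> None:
    dy, dx, prof = _disk_offsets(radius)
    yy, xx = y + dy, x + dx
    ok = (yy >= 0) & (yy < chan.shape[0]) & (xx >= 0) & (xx < chan.shape[1])
    yy, xx, prof = yy[ok], xx[ok], prof[ok]
    np.maximum.at(chan, (yy, xx), peak * prof)


def _blob_mask_coords(
    shape: tuple[int, int], y: int, x: int, radius: float, peak: float, thr: float
) -> np.ndarray:
    """Coordinates of the blob pixels whose noiseless intensity exceeds thr."""
    dy, dx, prof = _disk_offsets(radius)
    yy, xx = y + dy, x + dx
    ok = (
        (yy >= 0)
        & (yy < shape[0])
        & (xx >= 0)
        & (xx < shape[1])
        & (peak * prof > thr)
    )
    return np.stack([yy[ok], xx[ok]], axis=1)


def _ellipse_coords(
    shape: tuple[int, int], cy: float, cx: float, a: float, b: float, theta: float
) -> np.ndarray:
    r = int(np.ceil(max(a, b)))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    ct, st = np.cos(theta), np.sin(theta)
    u = dy * ct + dx * st
    v = -dy * st + dx * ct
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    yy = (int(round(cy)) + dy[inside]).ravel()
    xx = (int(round(cx)) + dx[inside]).ravel()
    ok = (yy >= 0) & (yy < shape[0]) & (xx >= 0) & (xx < shape[1])
    return np.stack([yy[ok], xx[ok]], axis=1)


def generate_stack(
    spec: StackSpec, seed: int | np.random.Generator = 0
) -> tuple[ZStack, StackGroundTruth]:
    """Generate one synthetic two-channel z-stack with its ground truth.

    Blob classes are assigned blob-by-blob against a pixel-area quota so the
    realised per-slice viable fraction tracks the requested one closely;
    viable and non-viable blobs never overlap (cross-class overlaps would
    read as orange and bias viability downward), while same-class blobs
    merge freely into larger aggregates.
    """
    rng = np.random.default_rng(seed)
    if spec.thickness_um is not None:
        thickness = spec.thickness_um
        n_slices = max(1, round(thickness / spec.z_step_um))
    elif spec.n_slices is not None:
        n_slices = spec.n_slices
        thickness = n_slices * spec.z_step_um
    else:
        thickness = rng.uniform(11.0, 19.0)
        n_slices = max(1, round(thickness / spec.z_step_um))
    thickness = n_slices * spec.z_step_um

    fracs = np.atleast_1d(np.asarray(spec.viable_fraction, dtype=float))
    if fracs.size == 1:
        fracs = np.full(n_slices, fracs[0])
    elif fracs.size != n_slices:
        raise ValueError("per-slice viable_fraction length must match n_slices")

    h, w = spec.height, spec.width
    max_r = spec.blob_radius_px[1]
    margin = int(np.ceil(max_r)) + 1
    if w <= 2 * margin or h <= 2 * margin:
        raise ValueError("frame too small for the requested blob radii")

    green = np.zeros((n_slices, h, w))
    red = np.zeros((n_slices, h, w))
    gt = StackGroundTruth(
        viable_px=[],
        nonviable_px=[],
        viable_fraction=[],
        target_fraction=list(fracs),
        nucleus_masks=[],
        thickness_um=thickness,
    )

    # Nuclei: choose slices and positions first so bacteria can avoid them.
    nucleus_keepout = [np.zeros((h, w), dtype=bool) for _ in range(n_slices)]
    for _ in range(spec.n_epithelial):
        s = int(rng.integers(0, n_slices))
        a = rng.uniform(*spec.epithelial_radius_px)
        b = rng.uniform(*spec.epithelial_radius_px)
        theta = rng.uniform(0, np.pi)
        r_out = max(a, b) + 2
        cy = rng.uniform(r_out, h - r_out)
        cx = rng.uniform(r_out, w - r_out)
        coords = _ellipse_coords((h, w), cy, cx, a, b, theta)
        level = rng.uniform(*spec.epithelial_intensity)
        red[s][coords[:, 0], coords[:, 1]] = level
        gt.nucleus_masks.append((s, coords))
        halo = _ellipse_coords((h, w), cy, cx, a + 3, b + 3, theta)
        nucleus_keepout[s][halo[:, 0], halo[:, 1]] = True

    for s in range(n_slices):
        # Place blobs without pixel overlap (retrying jittered positions)
        # so that every blob's class can be chosen freely by the quota:
        # touching blobs of either class merge into larger aggregates by
        # 8-adjacency, but no pixel ever carries both stains, which would
        # read as orange and bias viability downward.
        occupied = nucleus_keepout[s].copy()
        placed: list[tuple[int, int, float, np.ndarray]] = []

        def try_place(y: float, x: float, radius: float) -> bool:
            yi = int(np.clip(round(y), margin, h - margin - 1))
            xi = int(np.clip(round(x), margin, w - margin - 1))
            coords = _blob_mask_coords((h, w), yi, xi, radius, 255.0, 0.0)
            if coords.size == 0 or occupied[coords[:, 0], coords[:, 1]].any():
                return False
            occupied[coords[:, 0], coords[:, 1]] = True
            placed.append((yi, xi, radius, coords))
            return True

        # Clusters grow by tangential accretion: after a seed blob, every
        # blob attaches flush against an already-placed cluster member, so
        # a cluster forms one 8-connected aggregate (like a microcolony).
        lim = 3 * spec.cluster_sigma_px
        for _ in range(spec.n_clusters):
            ay, ax = rng.uniform(lim, h - lim), rng.uniform(lim, w - lim)
            members: list[int] = []
            for k in range(spec.blobs_per_cluster):
                radius = rng.uniform(*spec.blob_radius_px)
                for _try in range(20):
                    if not members:
                        y = ay + rng.normal(0, spec.cluster_sigma_px / 2)
                        x = ax + rng.normal(0, spec.cluster_sigma_px / 2)
                    else:
                        py, px, pr, _ = placed[members[int(rng.integers(len(members)))]]
                        theta = rng.uniform(0, 2 * np.pi)
                        gap = rng.uniform(0.0, 0.5)
                        y = py + (pr + radius + gap) * np.sin(theta)
                        x = px + (pr + radius + gap) * np.cos(theta)
                    if try_place(y, x, radius):
                        members.append(len(placed) - 1)
                        break
        for _ in range(spec.n_scatter_blobs):
            radius = rng.uniform(*spec.blob_radius_px)
            for _try in range(12):
                if try_place(
                    rng.uniform(margin, h - margin), rng.uniform(margin, w - margin), radius
                ):
                    break

        # pixel-area quota: walk blobs in random order and give each the
        # class that keeps the running viable fraction closest to target
        viable_area = 0
        nonviable_area = 0
        target = fracs[s]
        for bi in rng.permutation(len(placed)):
            y, x, radius, coords = placed[bi]
            area = len(coords)
            total = viable_area + nonviable_area + area
            err_v = abs((viable_area + area) / total - target)
            err_n = abs(viable_area / total - target)
            if err_v <= err_n:
                _paint_blob(green[s], y, x, radius, rng.uniform(*spec.viable_peak))
                viable_area += area
            else:
                _paint_blob(red[s], y, x, radius, rng.uniform(*spec.nonviable_peak))
                nonviable_area += area

        # realised truth: suprathreshold (classification-intent) pixel counts
        nucleus_mask = np.zeros((h, w), dtype=bool)
        for ns, coords in gt.nucleus_masks:
            if ns == s:
                nucleus_mask[coords[:, 0], coords[:, 1]] = True
        v_px = int(((green[s] > 100) & (red[s] < 100)).sum())
        nv_px = int(((red[s] > 100) & ~nucleus_mask).sum())
        gt.viable_px.append(v_px)
        gt.nonviable_px.append(nv_px)
        gt.viable_fraction.append(v_px / (v_px + nv_px) if v_px + nv_px else float("nan"))

    # background floor and detector noise
    green += spec.background_level * 0.5 + rng.normal(0, spec.noise_sd, green.shape)
    red += spec.background_level * 0.5 + rng.normal(0, spec.noise_sd, red.shape)
    np.clip(green, 0, 255, out=green)
    np.clip(red, 0, 255, out=red)

    stack = ZStack(
        green=green,
        red=red,
        z_step_um=spec.z_step_um,
        pixel_size_um=spec.pixel_size_um,
        field_id="synthetic",
    )
    return stack, gt


# ---------------------------------------------------------------------------
# Simulated crossover trials
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrialSpec:
    """Recipe for one simulated crossover trial (both gels per subject)."""

    n_subjects: int = 29
    summary: tuple = tuple(sorted(BIOFILM_FULL_BV_SUMMARY.items()))
    rho: float = 0.5  # within-subject correlation across timepoints
    experiment: str = "BIOFILM"
    layer: str = "FULL"

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least two subjects")
        if not (0 <= self.rho < 1):
            raise ValueError("rho must lie in [0, 1)")
        for (gel, tp), (mean, sd) in self.summary:
            if not (0 <= mean <= 100):
                raise ValueError(f"mean out of [0,100] for {(gel, tp)}: {mean}")
            if sd <= 0:
                raise ValueError(f"SD must be positive for {(gel, tp)}: {sd}")

    @classmethod
    def from_summary(
        cls,
        summary: dict[tuple[str, str], tuple[float, float]],
        n_subjects: int = 29,
        rho: float = 0.5,
        experiment: str = "BIOFILM",
        layer: str = "FULL",
    ) -> "TrialSpec":
        return cls(
            n_subjects=n_subjects,
            summary=tuple(sorted(summary.items())),
            rho=rho,
            experiment=experiment,
            layer=layer,
        )


@dataclass
class TrialGroundTruth:
    means: dict[tuple[str, str], float]
    sds: dict[tuple[str, str], float]
    rho: float


def generate_trial(
    spec: TrialSpec, seed: int | np.random.Generator = 0
):
    """Simulate a crossover trial table with its generating parameters.

    Per subject and gel cell, BV is ``mu + sd * (sqrt(rho) * z_subject +
    sqrt(1 - rho) * noise)`` clamped to [0, 100]: the shared subject effect
    induces correlation ``rho`` between any two cells of the same subject.
    Returns a long-format :class:`pandas.DataFrame` with columns
    (subject_id, gel, experiment, timepoint, layer, bv_pct) and the ground
    truth used to generate it.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    summary = dict(spec.summary)
    rows = []
    z_subj = rng.normal(size=spec.n_subjects)
    for i in range(spec.n_subjects):
        sid = f"S{i + 1:02d}"
        for (gel, tp), (mu, sd) in summary.items():
            value = mu + sd * (
                np.sqrt(spec.rho) * z_subj[i] + np.sqrt(1 - spec.rho) * rng.normal()
            )
            rows.append(
                {
                    "subject_id": sid,
                    "gel": gel,
                    "experiment": spec.experiment,
                    "timepoint": tp,
                    "layer": spec.layer,
                    "bv_pct": float(np.clip(value, 0.0, 100.0)),
                }
            )
    table = pd.DataFrame(rows)
    gt = TrialGroundTruth(
        means={k: v[0] for k, v in summary.items()},
        sds={k: v[1] for k, v in summary.items()},
        rho=spec.rho,
    )
    return table, gt


# ---------------------------------------------------------------------------
# Deterministic hand-built fixture
# ---------------------------------------------------------------------------


def fixture_small() -> tuple[ZStack, ClassMap]:
    """A deterministic 64x64x6 stack covering every classification branch.

    Pixel size 1 um so the 250 um^2 gate equals 250 pixels.  Content, by
    slice (surface to base):

    0. a 20x20 viable block (green 150 / red 50) — included;
    1. a 15x20 red-only non-viable block plus a 10x10 orange block — included;
    2. boundary pixels at exactly 100 (background by strict inequality) next
       to a 18x18 viable block — included;
    3. a 10x10 viable block only (100 px < 250) — excluded by the area gate;
    4. an 18x18 bright-red epithelial nucleus (324 px, intensity 220),
       a 15x15 viable block and a 5x10 non-viable block — the nucleus is
       flagged, so BV rises after exclusion;
    5. empty background.

    The returned :class:`ClassMap` is the expected classification of the
    stack (before epithelial exclusion), built by construction.
    """
    h = w = 64
    n = 6
    green = np.full((n, h, w), 20.0)
    red = np.full((n, h, w), 20.0)
    labels = np.zeros((n, h, w), dtype=np.uint8)

    def block(s, y, x, dy, dx, g, r, lab):
        green[s, y : y + dy, x : x + dx] = g
        red[s, y : y + dy, x : x + dx] = r
        labels[s, y : y + dy, x : x + dx] = lab

    block(0, 10, 10, 20, 20, 150, 50, VIABLE)
    block(1, 5, 5, 15, 20, 50, 150, NONVIABLE)  # red-only
    block(1, 30, 30, 10, 10, 150, 150, NONVIABLE)  # orange double-high
    block(2, 4, 4, 18, 18, 150, 50, VIABLE)
    block(2, 40, 40, 3, 3, 100, 100, BACKGROUND)  # both exactly at threshold
    block(2, 50, 50, 3, 3, 150, 100, BACKGROUND)  # green high, red exactly 100
    block(3, 20, 20, 10, 10, 150, 50, VIABLE)  # sub-area slice
    block(4, 8, 8, 18, 18, 50, 220, NONVIABLE)  # epithelial nucleus
    block(4, 40, 8, 15, 15, 150, 50, VIABLE)
    block(4, 40, 40, 5, 10, 50, 150, NONVIABLE)  # genuine non-viable bacteria

    stack = ZStack(
        green=green, red=red, z_step_um=DEFAULT_Z_STEP_UM, pixel_size_um=1.0,
        field_id="fixture_small",
    )
    return stack, ClassMap(labels)
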