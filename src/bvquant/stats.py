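"""Crossover-trial substantivity statistics.

Descriptives (mean +/- SD, median and IQR), Shapiro-Wilk normality
screening, exact paired (signed-rank) and unpaired (rank-sum) Wilcoxon
tests, and Bonferroni-adjusted comparison families:

* intra-gel — within one product, paired across timepoints: baseline versus
  every post-application time, and the five-minute trough versus every later
  time (nine pairs per gel); familywise alpha 0.05 over the five
  baseline-versus-post tests gives the working threshold p < 0.01;
* inter-gel — between products at each timepoint, independent-samples tests;
  0.05 over six timepoints, displayed to three decimals, gives p < 0.008.

Exact null distributions are used whenever the data allow (no ties, n small
enough); otherwise the normal approximation with continuity correction.  The
pipeline always proceeds nonparametrically: Shapiro-Wilk results are
reported, not used for gating.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GELS",
    "TIMEPOINTS",
    "LAYERS",
    "INTRA_GEL_FAMILY_SIZE",
    "INTER_GEL_FAMILY_SIZE",
    "Descriptives",
    "ComparisonResult",
    "ComparisonConfig",
    "descriptives",
    "shapiro_wilk",
    "wilcoxon_test",
    "bonferroni_alpha",
    "run_comparisons",
    "render_table",
    "read_trial_table",
    "write_trial_table",
]

logger = logging.getLogger(__name__)

GELS = ("TEST", "CONTROL")
TIMEPOINTS = ("BASAL", "5MIN", "1H", "3H", "5H", "7H")
LAYERS = ("FULL", "UPPER", "LOWER", "NA")

#: Bonferroni family sizes reproducing the published thresholds:
#: 0.05 / 5 = 0.01 (intra-gel) and 0.05 / 6 = 0.008 (inter-gel, 3 decimals).
INTRA_GEL_FAMILY_SIZE = 5
INTER_GEL_FAMILY_SIZE = 6

#: Largest sample size for which the exact Wilcoxon null is enumerated.
EXACT_N_MAX = 29

#: Intra-gel paired comparisons as laid out in the report tables.
INTRA_GEL_PAIRS = (
    ("BASAL", "5MIN"),
    ("BASAL", "1H"),
    ("5MIN", "1H"),
    ("BASAL", "3H"),
    ("5MIN", "3H"),
    ("BASAL", "5H"),
    ("5MIN", "5H"),
    ("BASAL", "7H"),
    ("5MIN", "7H"),
)


@dataclass(frozen=True)
class Descriptives:
    n: int
    mean: float
    sd: float
    median: float
    iqr: float


def descriptives(values) -> Descriptives:
    """Mean, sample SD (n-1), median, IQR (linear-interpolation quartiles)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("descriptives of an empty sample")
    q1, q3 = np.percentile(v, [25, 75])  # linear interpolation convention
    return Descriptives(
        n=int(v.size),
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)) if v.size > 1 else 0.0,
        median=float(np.median(v)),
        iqr=float(q3 - q1),
    )


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk normality test; requires 3 <= n <= 5000 and variance > 0."""
    v = np.asarray(values, dtype=float)
    if not (3 <= v.size <= 5000):
        raise ValueError(f"Shapiro-Wilk needs 3 <= n <= 5000, got n={v.size}")
    if np.ptp(v) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    res = sps.shapiro(v)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str  # "exact" | "normal" | "degenerate"
    n: int


def _has_ties(v: np.ndarray) -> bool:
    return len(np.unique(v)) < len(v)


def wilcoxon_test(x, y, mode: str = "paired", exact: bool | None = None) -> TestResult:
    """Two-sided Wilcoxon test.

    ``mode="paired"`` runs the signed-rank test on the differences (zero
    differences dropped, ties mid-ranked); ``mode="unpaired"`` the rank-sum
    (Mann-Whitney) test.  ``exact=None`` enumerates the exact null when
    there are no ties (and, paired, no zero differences) and n <= 29,
    otherwise falls back to the normal approximation with continuity
    correction; pass True/False to force a method.  A paired sample whose
    differences are all zero is degenerate and reported with p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if mode == "paired":
        if x.shape != y.shape:
            raise ValueError("paired mode requires equal-length samples")
        d = x - y
        d = d[d != 0]
        n = d.size
        if n == 0:
            return TestResult(statistic=0.0, p_value=1.0, method="degenerate", n=0)
        if exact is None:
            exact = n <= EXACT_N_MAX and not _has_ties(np.abs(d))
        res = sps.wilcoxon(
            d,
            zero_method="wilcox",
            correction=not exact,
            alternative="two-sided",
            method="exact" if exact else "approx",
        )
        return TestResult(
            statistic=float(res.statistic),
            p_value=float(min(res.pvalue, 1.0)),
            method="exact" if exact else "normal",
            n=n,
        )
    if mode == "unpaired":
        n = max(x.size, y.size)
        if x.size == 0 or y.size == 0:
            raise ValueError("unpaired mode requires two non-empty samples")
        if exact is None:
            exact = n <= EXACT_N_MAX and not _has_ties(np.concatenate([x, y]))
        res = sps.mannwhitneyu(
            x,
            y,
            alternative="two-sided",
            method="exact" if exact else "asymptotic",
            use_continuity=True,
        )
        return TestResult(
            statistic=float(res.statistic),
            p_value=float(min(res.pvalue, 1.0)),
            method="exact" if exact else "normal",
            n=n,
        )
    raise ValueError(f"unknown mode: {mode!r}")


def bonferroni_alpha(alpha: float, k: int, decimals: int | None = None) -> float:
    """Per-comparison threshold alpha/k, optionally truncated for display."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if k < 1:
        raise ValueError("family size k must be >= 1")
    thr = alpha / k
    if decimals is not None:
        thr = math.floor(thr * 10**decimals) / 10**decimals
    return thr


@dataclass(frozen=True)
class ComparisonResult:
    family: str  # INTRA_GEL | INTER_GEL
    gel: str  # gel under test (intra) or "TEST vs CONTROL" (inter)
    pair: str  # e.g. "BASAL vs 5MIN"
    test: str  # paired | unpaired
    statistic: float
    p_value: float
    method: str
    adjusted_alpha: float
    significant: bool
    n: int


@dataclass(frozen=True)
class ComparisonConfig:
    familywise_alpha: float = 0.05
    intra_family_size: int = INTRA_GEL_FAMILY_SIZE
    inter_family_size: int = INTER_GEL_FAMILY_SIZE
    inter_display_decimals: int = 3
    paired_inter_gel: bool = False  # crossover pairing of inter-gel tests

    @property
    def intra_alpha(self) -> float:
        return bonferroni_alpha(self.familywise_alpha, self.intra_family_size)

    @property
    def inter_alpha(self) -> float:
        return bonferroni_alpha(
            self.familywise_alpha, self.inter_family_size, self.inter_display_decimals
        )


def _pivot(table: pd.DataFrame, gel: str) -> pd.DataFrame:
    sub = table[table["gel"] == gel]
    return sub.pivot(index="subject_id", columns="timepoint", values="bv_pct")


def run_comparisons(
    table: pd.DataFrame, config: ComparisonConfig = ComparisonConfig()
) -> list[ComparisonResult]:
    """Run the intra- and inter-gel comparison families on one trial table.

    ``table`` is long-format with columns (subject_id, gel, experiment,
    timepoint, layer, bv_pct), already restricted to one experiment/layer.
    Intra-gel tests pair subjects across timepoints; inter-gel tests compare
    the gels at each timepoint with independent samples (a paired inter-gel
    mode exists for the crossover design, off by default).  Comparisons with
    missing cells are skipped with a warning.
    """
    results: list[ComparisonResult] = []
    gels = [g for g in GELS if g in set(table["gel"])]

    for gel in gels:
        wide = _pivot(table, gel)
        for a, b in INTRA_GEL_PAIRS:
            if a not in wide.columns or b not in wide.columns:
                logger.warning("skipping intra-gel %s vs %s for %s: missing cells", a, b, gel)
                continue
            sub = wide[[a, b]].dropna()
            if sub.empty:
                logger.warning("skipping intra-gel %s vs %s for %s: no subjects", a, b, gel)
                continue
            res = wilcoxon_test(sub[a].to_numpy(), sub[b].to_numpy(), mode="paired")
            alpha = config.intra_alpha
            results.append(
                ComparisonResult(
                    family="INTRA_GEL",
                    gel=gel,
                    pair=f"{a} vs {b}",
                    test="paired",
                    statistic=res.statistic,
                    p_value=res.p_value,
                    method=res.method,
                    adjusted_alpha=alpha,
                    significant=res.p_value < alpha,
                    n=res.n,
                )
            )

    if len(gels) == 2:
        mode = "paired" if config.paired_inter_gel else "unpaired"
        for tp in TIMEPOINTS:
            sub = table[table["timepoint"] == tp]
            if config.paired_inter_gel:
                wide = sub.pivot(index="subject_id", columns="gel", values="bv_pct").dropna()
                if wide.empty:
                    logger.warning("skipping inter-gel at %s: no paired subjects", tp)
                    continue
                x, y = wide["TEST"].to_numpy(), wide["CONTROL"].to_numpy()
            else:
                x = sub.loc[sub["gel"] == "TEST", "bv_pct"].to_numpy()
                y = sub.loc[sub["gel"] == "CONTROL", "bv_pct"].to_numpy()
                if x.size == 0 or y.size == 0:
                    logger.warning("skipping inter-gel at %s: missing cells", tp)
                    continue
            res = wilcoxon_test(x, y, mode=mode)
            alpha = config.inter_alpha
            results.append(
                ComparisonResult(
                    family="INTER_GEL",
                    gel="TEST vs CONTROL",
                    pair=tp,
                    test=mode,
                    statistic=res.statistic,
                    p_value=res.p_value,
                    method=res.method,
                    adjusted_alpha=alpha,
                    significant=res.p_value < alpha,
                    n=res.n,
                )
            )
    else:
        logger.warning("inter-gel family skipped: only gels %s present", gels)

    return results


def _fmt_p(p: float) -> str:
    if p < 1e-4:
        return f"{p:.4e}"
    return f"{p:.4g}"


def render_table(
    table: pd.DataFrame,
    results: list[ComparisonResult],
    title: str = "BACTERIAL VIABILITY",
) -> str:
    """Render descriptives and comparison outcomes as a text report table.

    Layout mirrors the published tables: one descriptives row per gel
    (mean +/- SD and median (IQR) at each timepoint), one intra-gel
    significance row per gel, and one inter-gel row; non-significant tests
    print as NS.
    """
    lines = [title, "=" * len(title), ""]
    header = "timepoint".ljust(10) + "".join(t.rjust(22) for t in TIMEPOINTS)
    for gel in GELS:
        sub = table[table["gel"] == gel]
        if sub.empty:
            continue
        lines.append(f"[{gel}]")
        lines.append(header)
        cells_ms, cells_mi = [], []
        for tp in TIMEPOINTS:
            vals = sub.loc[sub["timepoint"] == tp, "bv_pct"]
            if vals.empty:
                cells_ms.append("-".rjust(22))
                cells_mi.append("-".rjust(22))
            else:
                d = descriptives(vals)
                cells_ms.append(f"{d.mean:.2f} +/- {d.sd:.2f}".rjust(22))
                cells_mi.append(f"{d.median:.2f} ({d.iqr:.2f})".rjust(22))
        lines.append("mean+/-SD ".ljust(10) + "".join(cells_ms))
        lines.append("med (IQR) ".ljust(10) + "".join(cells_mi))
        lines.append("")

    intra = [r for r in results if r.family == "INTRA_GEL"]
    if intra:
        lines.append(f"INTRA-GEL ANALYSIS (paired Wilcoxon, significance p < {intra[0].adjusted_alpha:g})")
        for gel in GELS:
            rows = [r for r in intra if r.gel == gel]
            if not rows:
                continue
            cells = [
                f"{r.pair}: " + (_fmt_p(r.p_value) if r.significant else "NS")
                for r in rows
            ]
            lines.append(f"  {gel}: " + "; ".join(cells))
        lines.append("")
    inter = [r for r in results if r.family == "INTER_GEL"]
    if inter:
        lines.append(
            f"INTER-GEL ANALYSIS ({inter[0].test} Wilcoxon, significance p < {inter[0].adjusted_alpha:g})"
        )
        cells = [
            f"{r.pair}: " + (_fmt_p(r.p_value) if r.significant else "NS") for r in inter
        ]
        lines.append("  TEST vs CONTROL: " + "; ".join(cells))
        lines.append("")
    return "\n".join(lines)


TRIAL_COLUMNS = ["subject_id", "gel", "experiment", "timepoint", "layer", "bv_pct"]


def read_trial_table(path) -> pd.DataFrame:
    """Read a long-format trial table CSV (layer "NA" kept as a string)."""
    df = pd.read_csv(path, dtype={c: str for c in TRIAL_COLUMNS[:-1]}, keep_default_na=False)
    df["bv_pct"] = df["bv_pct"].astype(float)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    return df


def write_trial_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=TRIAL_COLUMNS, float_format="%.6f")
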