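"""End-to-end orchestration: quantify stacks, aggregate, analyze, report.

``run_pipeline`` walks a sample manifest, quantifies every field
(classification, epithelial exclusion, per-slice viability, thickness and
layers), aggregates to samples and a long-format trial table, runs the
comparison families, and writes all artifacts as CSV/text plus a JSON run
log.  Unreadable stacks are contained: the sample is recorded as failed and
the run continues.  Output is deterministic for fixed inputs.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import class_counts, classify_stack
from .config import PipelineConfig
from .epithelial import (
    exclude_epithelial,
    find_red_components_stack,
    flag_epithelial,
)
from .stacks import SampleManifest, ZStack, project_stack, read_manifest, read_stack
from .stats import TRIAL_COLUMNS, render_table, run_comparisons
from .viability import (
    FieldSummary,
    field_summary,
    harmonised_layer_thickness,
    layer_split_means,
    sample_summary,
    slice_viability,
)

logger = logging.getLogger(__name__)

__all__ = ["FieldResult", "QuantifyResult", "quantify_field", "quantify", "analyze", "run_pipeline"]

#: Advisory field counts per sample (warn-only validation).
EXPECTED_FIELDS = {"SALIVA": (10, 15), "BIOFILM": (1, 6)}


@dataclass
class FieldResult:
    """One quantified field plus what harmonised-layer recomputation needs."""

    summary: FieldSummary
    slice_rows: pd.DataFrame = field(repr=False)
    n_slices: int = 0


def quantify_field(
    stack: ZStack, config: PipelineConfig, experiment: str
) -> FieldResult:
    """Quantify one field: classify, exclude nuclei, score slices and layers.

    Saliva fields are collapsed to their overall maximum-intensity
    projection first and scored as a single section (no thickness/layers).
    """
    if experiment == "SALIVA":
        stack = project_stack(stack)
    classmap = classify_stack(stack, config.thresholds())
    comps = find_red_components_stack(
        classmap, stack.red, connectivity=config.epithelial.connectivity
    )
    flagged = flag_epithelial(comps, config.criteria())
    classmap_after, report = exclude_epithelial(classmap, flagged)

    slices = [
        slice_viability(
            class_counts(classmap_after.labels[i]),
            pixel_size_um=stack.pixel_size_um,
            min_area_um2=config.min_area_um2,
            slice_index=i,
        )
        for i in range(classmap_after.n_slices)
    ]
    summary = field_summary(
        slices,
        classmap_after,
        report,
        z_step_um=stack.z_step_um,
        min_aggregate_px=config.mft_min_cluster_px(),
        field_id=stack.field_id,
        layer_bv_mode=config.layer_bv_mode,
    )
    rows = report.per_slice.copy()
    rows.insert(0, "field_id", stack.field_id)
    rows["viable_px"] = [s.viable_px for s in slices]
    rows["nonviable_px"] = [s.nonviable_px for s in slices]
    rows["area_um2"] = [s.aggregate_area_um2 for s in slices]
    rows["included"] = [s.included for s in slices]
    return FieldResult(summary=summary, slice_rows=rows, n_slices=classmap_after.n_slices)


@dataclass
class QuantifyResult:
    slices: pd.DataFrame
    fields: pd.DataFrame
    samples: pd.DataFrame
    trial_table: pd.DataFrame
    failures: list[dict]
    harmonised_span_um: float | None = None


def _trial_rows(samples: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for _, s in samples.iterrows():
        base = {
            "subject_id": s["subject_id"],
            "gel": s["gel"],
            "experiment": s["experiment"],
            "timepoint": s["timepoint"],
        }
        if s["experiment"] == "SALIVA":
            layers = [("NA", s["mean_bv_pct"])]
        else:
            layers = [
                ("FULL", s["mean_bv_pct"]),
                ("UPPER", s["upper_bv_pct"]),
                ("LOWER", s["lower_bv_pct"]),
            ]
        for layer, bv in layers:
            if bv is None or (isinstance(bv, float) and math.isnan(bv)):
                continue
            rows.append({**base, "layer": layer, "bv_pct": float(bv)})
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def quantify(manifest: SampleManifest, config: PipelineConfig, base_dir: Path | None = None) -> QuantifyResult:
    """Quantify every field in the manifest and aggregate to samples.

    ``base_dir`` resolves relative stack paths (defaults to the CWD).  In
    harmonised layer mode the common span is the minimum over
    (gel, timepoint) groups of the median per-field MFT of the biofilm
    fields, recomputed before layer viabilities are aggregated.
    """
    base = Path(base_dir) if base_dir is not None else Path(".")
    slice_frames: list[pd.DataFrame] = []
    failures: list[dict] = []
    per_sample: dict[tuple, list] = {}

    for key, group in manifest.sample_groups():
        subject, gel, experiment, timepoint = key
        lo, hi = EXPECTED_FIELDS.get(experiment, (1, 10**9))
        if not (lo <= len(group) <= hi):
            logger.warning(
                "sample %s has %d fields (expected %d-%d for %s)",
                key, len(group), lo, hi, experiment,
            )
        results = []
        for _, row in group.iterrows():
            path = Path(row["path"])
            if not path.is_absolute():
                path = base / path
            try:
                stack = read_stack(
                    path,
                    channel_map=config.channel_map,
                    bit_depth=config.bit_depth,
                    z_step_um=config.z_step_um,
                    pixel_size_um=config.pixel_size_um,
                    surface_first=config.slice_order == "surface_first",
                    field_id=str(row["field_id"]),
                )
                res = quantify_field(stack, config, experiment)
            except Exception as exc:
                logger.error("field %s of sample %s failed: %s", row["field_id"], key, exc)
                failures.append(
                    {"subject_id": subject, "gel": gel, "experiment": experiment,
                     "timepoint": timepoint, "field_id": str(row["field_id"]),
                     "error": str(exc)}
                )
                continue
            sr = res.slice_rows.copy()
            for col, val in zip(("subject_id", "gel", "experiment", "timepoint"), key):
                sr.insert(0, col, val)
            slice_frames.append(sr)
            results.append(res)
        per_sample[key] = results

    harmonised_span = None
    if config.layer_mode == "harmonised":
        mfts: dict[tuple, list[float]] = {}
        for (subject, gel, experiment, timepoint), results in per_sample.items():
            if experiment != "BIOFILM":
                continue
            mfts.setdefault((gel, timepoint), []).extend(
                r.summary.mft_um for r in results if not r.summary.excluded
            )
        if mfts:
            harmonised_span = harmonised_layer_thickness(mfts)
            for (subject, gel, experiment, timepoint), results in per_sample.items():
                if experiment != "BIOFILM":
                    continue
                for r in results:
                    upper, lower = layer_split_means(
                        r.summary.slices,
                        mft_um=r.summary.mft_um,
                        n_slices=r.n_slices,
                        z_step_um=config.z_step_um,
                        span_um=harmonised_span,
                        mode=config.layer_bv_mode,
                    )
                    r.summary.upper_bv_pct = upper
                    r.summary.lower_bv_pct = lower

    field_rows = []
    sample_rows = []
    for key, results in per_sample.items():
        subject, gel, experiment, timepoint = key
        for r in results:
            s = r.summary
            field_rows.append(
                {"subject_id": subject, "gel": gel, "experiment": experiment,
                 "timepoint": timepoint, "field_id": s.field_id,
                 "mean_bv_pct": s.mean_bv_pct,
                 "mean_bv_before_excl_pct": s.mean_bv_before_excl_pct,
                 "mft_um": s.mft_um, "upper_bv_pct": s.upper_bv_pct,
                 "lower_bv_pct": s.lower_bv_pct, "n_included": s.n_included,
                 "excluded": s.excluded}
            )
        if results:
            summ = sample_summary(
                [r.summary for r in results], subject, gel, experiment, timepoint
            )
            sample_rows.append(
                {"subject_id": subject, "gel": gel, "experiment": experiment,
                 "timepoint": timepoint, "n_fields": summ.n_fields,
                 "mean_bv_pct": summ.mean_bv_pct,
                 "mean_bv_before_excl_pct": summ.mean_bv_before_excl_pct,
                 "mean_thickness_um": summ.mean_thickness_um,
                 "upper_bv_pct": summ.upper_bv_pct,
                 "lower_bv_pct": summ.lower_bv_pct, "missing": summ.missing}
            )

    slices_df = (
        pd.concat(slice_frames, ignore_index=True) if slice_frames else pd.DataFrame()
    )
    samples_df = pd.DataFrame(sample_rows)
    trial_df = _trial_rows(samples_df) if not samples_df.empty else pd.DataFrame(columns=TRIAL_COLUMNS)
    return QuantifyResult(
        slices=slices_df,
        fields=pd.DataFrame(field_rows),
        samples=samples_df,
        trial_table=trial_df,
        failures=failures,
        harmonised_span_um=harmonised_span,
    )


def analyze(trial_table: pd.DataFrame, config: PipelineConfig):
    """Run the comparison families for every (experiment, layer) present.

    Returns ``(comparisons_df, reports)`` where ``reports`` maps
    ``(experiment, layer)`` to a rendered text table.
    """
    comp_rows = []
    reports: dict[tuple[str, str], str] = {}
    cc = config.comparison_config()
    for (experiment, layer), sub in trial_table.groupby(["experiment", "layer"], sort=True):
        results = run_comparisons(sub, cc)
        for r in results:
            comp_rows.append(
                {"experiment": experiment, "layer": layer, "family": r.family,
                 "gel": r.gel, "pair": r.pair, "test": r.test, "n": r.n,
                 "statistic": r.statistic, "p_value": r.p_value,
                 "method": r.method, "adjusted_alpha": r.adjusted_alpha,
                 "significant": r.significant}
            )
        title = f"BACTERIAL VIABILITY — {experiment} ({layer})"
        reports[(experiment, layer)] = render_table(sub, results, title=title)
    return pd.DataFrame(comp_rows), reports


def run_pipeline(
    manifest_path: str | Path,
    config: PipelineConfig,
    out_dir: str | Path,
) -> QuantifyResult:
    """Full pipeline: quantify -> aggregate -> analyze -> write artifacts.

    Artifacts under ``out_dir``: ``slices.csv``, ``fields.csv``,
    ``samples.csv``, ``trial_table.csv``, ``comparisons.csv``,
    ``report.txt`` and ``run_log.json`` (software version, config hash and
    dump, failure list).  Per-sample read failures do not abort the run.
    """
    manifest_path = Path(manifest_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = read_manifest(manifest_path)
    result = quantify(manifest, config, base_dir=manifest_path.parent)

    fmt = "%.6f"
    result.slices.to_csv(out / "slices.csv", index=False, float_format=fmt)
    result.fields.to_csv(out / "fields.csv", index=False, float_format=fmt)
    result.samples.to_csv(out / "samples.csv", index=False, float_format=fmt)
    result.trial_table.to_csv(out / "trial_table.csv", index=False, float_format=fmt)

    comparisons, reports = analyze(result.trial_table, config)
    comparisons.to_csv(out / "comparisons.csv", index=False, float_format="%.6g")
    report_text = "\n\n".join(reports[k] for k in sorted(reports))
    (out / "report.txt").write_text(report_text)

    log = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "config": config.model_dump(mode="json"),
        "n_fields": int(len(result.fields)),
        "n_samples": int(len(result.samples)),
        "n_failures": len(result.failures),
        "failures": result.failures,
        "harmonised_span_um": result.harmonised_span_um,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return result
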