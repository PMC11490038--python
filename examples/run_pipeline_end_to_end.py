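"""End-to-end pipeline run on a miniature synthetic study.

Writes a small manifest (2 subjects x 2 gels x 2 timepoints of biofilm
stacks with a strong antiseptic effect), runs the full pipeline
(quantify -> aggregate -> analyze) and lists the artifacts it produces.
"""

import tempfile
from pathlib import Path

import pandas as pd

from bvquant import PipelineConfig, StackSpec, generate_stack, run_pipeline, write_stack

workdir = Path(tempfile.mkdtemp(prefix="bvquant_demo_"))
rows = []
seed = 0
for subject in ("S1", "S2"):
    for gel in ("TEST", "CONTROL"):
        for timepoint, p in (("BASAL", 0.9), ("5MIN", 0.1)):
            spec = StackSpec(width=128, height=128, thickness_um=7.0, viable_fraction=p)
            stack, _ = generate_stack(spec, seed=seed)
            seed += 1
            name = f"{subject}_{gel}_{timepoint}.tif"
            write_stack(stack, workdir / name)
            rows.append(
                {"subject_id": subject, "gel": gel, "experiment": "BIOFILM",
                 "timepoint": timepoint, "field_id": "f1", "path": name}
            )
pd.DataFrame(rows).to_csv(workdir / "manifest.csv", index=False)

config = PipelineConfig(pixel_size_um=1.0)  # synthetic stacks use 1 um pixels
result = run_pipeline(workdir / "manifest.csv", config, workdir / "out")

print(f"quantified {len(result.fields)} fields, {len(result.samples)} samples")
print("\nsample-level viability:")
cols = ["subject_id", "gel", "timepoint", "mean_bv_pct", "mft_um"]
print(result.samples.rename(columns={"mean_thickness_um": "mft_um"})[cols]
      .to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print("\nartifacts written to", workdir / "out")
for f in sorted((workdir / "out").iterdir()):
    print("  ", f.name)
print(
    "\nBaseline samples sit near 90% viability and five-minute samples near"
    " 10%, matching the viable fractions the stacks were generated with."
)
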