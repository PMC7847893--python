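"""Simulate a two-group plate and run the full comparison pipeline.

One group carries a doubled spontaneous bout rate.  Every metric in
every section is compared across groups with Kruskal-Wallis and scored
with SSMD; the run-level summary gives the p < 0.05 count and the KDE
peak of the SSMD distribution.
"""

import json
import tempfile
from pathlib import Path

import pandas as pd

from zfplate import RunConfig, run_pipeline
from zfplate.synth import SyntheticSpec, simulate_experiment

root = Path(tempfile.mkdtemp())
spec = SyntheticSpec(seed=3, n_wells=24)
exp = simulate_experiment(spec, root / "exp", duration_s=600.0,
                          bout_rate_scales={"group2": 2.0})

cfg = RunConfig(
    rois=str(exp.rois_path), events=str(exp.events_path),
    sections=str(exp.sections_path), platemap=str(exp.platemap_path),
    slow_dir=str(exp.root / "slow"), hs_dir=str(exp.root / "hs"),
    out_dir=str(root / "out"), seed=3,
)
out = run_pipeline(cfg)

summary = json.loads((out / "summary.json").read_text())
print(f"{summary['n_metrics']} metrics compared; "
      f"{summary['n_p_below_05']} with p < 0.05; "
      f"SSMD KDE peak {summary['kde_peak']:+.2f}")

table = pd.read_csv(out / "comparison.csv", index_col=0)
top = table.reindex(table["p"].sort_values().index).head(5)
print("\nstrongest group differences:")
print(top[["p", "ssmd"]].to_string(float_format=lambda v: f"{v:.3g}"))
# Activity metrics (bout frequency, active fraction) surface first:
# those carry the implanted 2x bout-rate difference. Response metrics
# stay near the null because stimulus responsiveness was not altered.
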