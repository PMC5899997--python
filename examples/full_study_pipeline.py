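"""Run the whole pipeline (simulate -> analyze -> stats -> burden) end to end.

Uses the shipped 15-cohort study configuration scaled to ~20% of the
published sample sizes so it finishes in about a minute, and prints where
each artefact landed plus the classification table.

Equivalent shell command:  navclamp run --seed 0 --out scratch/study_run
"""

from pathlib import Path

import pandas as pd

from navclamp.pipeline_io import default_config, run_pipeline

out = Path("scratch/example_run")
cfg = default_config(seed=0, scale=0.2)
paths = run_pipeline(cfg, out)

for name, path in paths.items():
    print(f"{name:15s} {path}")

cls = pd.read_csv(paths["classification"], sep="\t")
print("\n" + cls.to_string(index=False))
print("\nAt this reduced scale few if any changes clear the stringent "
      "0.05/98 Bonferroni threshold, so most variants read as "
      "wild-type-like; detecting the published pattern needs the complete "
      "sample sizes (scale=1.0, ~376 cells, a few minutes).")
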