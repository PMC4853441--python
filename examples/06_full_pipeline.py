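"""Run the complete study replica into a directory.

Scoring -> z-adjustment -> VLSM per outcome -> overlap -> subtraction ->
region report / selection -> ROI regressions, with every map written as
NIfTI, every table as CSV, and a JSON manifest of all parameters.
"""

import json
from pathlib import Path

from fluencymap import RunConfig, make_cohort, run_full_analysis
from fluencymap.synthetic import default_norms

out = Path("scratch/example_run")
cohort = make_cohort(seed=1)
result = run_full_analysis(cohort, RunConfig(seed=1), norms=default_norms(), out_dir=out)

print("run directory contents:")
for p in sorted(out.iterdir()):
    print(" ", p.name)

manifest = json.loads((out / "manifest.json").read_text())
print("\nkey parameters:", {k: manifest["config"][k]
      for k in ("min_count", "q", "min_sig", "statistic_kind", "tails")})
print("FDR summary:", manifest["fdr"])
# The manifest is sufficient to re-run the analysis identically: same
# cohort seed + same config -> bit-identical CSV outputs.
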