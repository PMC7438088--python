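"""Full simulate → fit → report run on a small two-group configuration.

Writes synthetic datasets (traces, image fields, force curves, shape
masks, channel pairs) with ground truth and a manifest, fits every assay,
and assembles the group-level report.  Equivalent to the CLI:

    cytomech simulate --config cfg.yaml --out data
    cytomech fit      --config cfg.yaml --in data --out results
    cytomech report   --config cfg.yaml --in results --out report
"""

import tempfile
from pathlib import Path

from cytomech.pipeline import RunConfig, run_fit, run_report, run_simulate

config = RunConfig(
    seed=7,
    groups=["untreated", "TNFa"],
    n_osmotic=4,     # cells per group for the osmotic assay
    n_radius=20,     # disks per rendered field
    n_modulus=10,    # force curves per group
    n_shapes=10,     # shape masks per group
)

root = Path(tempfile.mkdtemp(prefix="cytomech_"))
run_simulate(config, root / "data")
run_fit(config, root / "data", root / "results")
report = run_report(config, root / "results", root / "report")

print(f"report written to {report}")
print("--- group summaries (excerpt) ---")
for line in (root / "report" / "group_summaries.csv").read_text().splitlines()[:8]:
    print(line)
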