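#!/usr/bin/env python
"""SNP-metabolome association scan with covariate adjustment, per-cohort PC
residualization, and the permutation metabolome-wide significance level."""
import json
from pathlib import Path

from common import RUN_DIR, run_stage

run_stage("mwas")
out = RUN_DIR
summary = json.loads((out / "mwas_summary.json").read_text())
print(f"significant associations: {summary['n_significant']}")
print(f"MWSL per SNP: {summary['mwsl']}")
if summary["proportions_defined"]:
    print(f"class proportions (%): {summary['class_proportions_percent']}")
print(f"effective tests ~ fwer/MWSL = "
      f"{ {s: round(0.05 / t, 1) for s, t in summary['mwsl'].items()} }")
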