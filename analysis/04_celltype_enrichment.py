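#!/usr/bin/env python
"""Bootstrap expression-weighted cell-type enrichment of the planted gene
set against the simulated single-cell reference (10000 bootstraps)."""
import json
from pathlib import Path

import pandas as pd

from common import RUN_DIR, run_stage

run_stage("ewce")
out = RUN_DIR
res = pd.read_csv(out / "ewce.tsv", sep="\t")
truth = json.loads((out / "truth.json").read_text())
print(res[["celltype", "score", "sdfm", "p", "q"]].to_string(index=False))
best = res.loc[res["p"].idxmin(), "celltype"]
print(f"smallest p in {best} (planted target: {truth['celltype_target']})")
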