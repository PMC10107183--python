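#!/usr/bin/env python
"""Preprocess the lipidomics feature matrix: QC-pool presence (>=50%) and
CV (<=20%) filtering, KNN imputation (k=5), PQN against the pool median."""
from pathlib import Path

import pandas as pd

from common import RUN_DIR, run_stage

run_stage("qc")
out = RUN_DIR
qc_matrix = pd.read_csv(out / "lipidomics_qc.tsv", sep="\t", index_col=0)
try:
    report = pd.read_csv(out / "qc_report.tsv", sep="\t")
except pd.errors.EmptyDataError:
    report = pd.DataFrame(columns=["feature", "reason"])
print(f"retained {qc_matrix.shape[1]} features over {qc_matrix.shape[0]} samples")
if len(report):
    print("dropped:", report.groupby("reason").size().to_dict())
else:
    print("dropped: none")
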