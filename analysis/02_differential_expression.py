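#!/usr/bin/env python
"""Differential expression on the simulated omics layers.

Transcriptomics goes through the SAM-style permutation test (FDR targets
3% global / 5% at the 90th percentile of permutation false positives);
proteomics through decoy/missingness filtering, down-shifted-normal
imputation, the 200-permutation t-test and the 1.17-0.83 iTRAQ band.
"""
import json
from pathlib import Path

import pandas as pd

from common import RUN_DIR, run_stage

run_stage("de")
out = RUN_DIR
sam = pd.read_csv(out / "de_transcripts.tsv", sep="\t")
prot = pd.read_csv(out / "de_proteins.tsv", sep="\t")
truth = json.loads((out / "truth.json").read_text())
called = set(sam.loc[sam["called"], "id"])
print(f"SAM called {len(called)}/{len(sam)} transcripts "
      f"({len(called & set(truth['de_transcripts']))} planted)")
print(f"proteomics called {int(prot['called'].sum())}/{len(prot)} after the iTRAQ band")
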