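#!/usr/bin/env python
"""Map called DE transcripts onto the metabolic network and test pathway
over-representation (right-tailed hypergeometric, BH, dual raw-p/q rule)."""
import json
from pathlib import Path

import pandas as pd

from common import RUN_DIR, run_stage

run_stage("enrich")
out = RUN_DIR
table = pd.read_csv(out / "enrichment.tsv", sep="\t")
mapped = json.loads((out / "mapped.json").read_text())
print(f"mapped {mapped['n_mapped']}/{mapped['n_input']} DE ids onto the network")
sig = table[table["significant"]]
print(f"significant pathways: {sig['term'].tolist()}")
print(sig[["term", "k", "K", "p", "q", "coverage"]].to_string(index=False))
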