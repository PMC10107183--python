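#!/usr/bin/env python
"""Generate every synthetic input for the demo analysis.

Emulates the study's data layers: a metabolic network with two lipid
pathways, two-group microarray expression with DE planted inside those
pathways, MNAR proteomics, a 7+7 crossed genotype x sex cortical lipidome
with 3 QC pools, a cell-type expression reference, and (later, stage 08) a
single-SNP metabolome cohort.  Artifacts and the ground truth go to
results/demo/.
"""
import json
from pathlib import Path

from common import RUN_DIR, run_stage

manifest = run_stage("simulate")
out = RUN_DIR
truth = json.loads((out / "truth.json").read_text())
print(f"wrote {len(manifest['stages']['simulate']['outputs'])} artifacts to {out}")
print(f"planted DE transcripts: {len(truth['de_transcripts'])} "
      f"(all inside lipid pathways {truth['enriched_pathways']})")
print(f"planted signature species: {len(truth['signature_species'])}")
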