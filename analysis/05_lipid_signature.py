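#!/usr/bin/env python
"""Extract the lipid subnetwork from the enriched pathways and build the
predicted lipid signature by first/second-order identifier matching, then
validate it against the per-mode annotations of the simulated lipidome."""
import json
from pathlib import Path

from common import RUN_DIR, run_stage

run_stage("signature")
out = RUN_DIR
counts = json.loads((out / "signature_counts.json").read_text())
sub = counts["subnetwork"]
pred = counts["predicted"]
val = counts["validated"]
print(f"selected lipid pathways: {counts['selected_pathways']}")
print(f"subnetwork: {sub['genes']} genes, {sub['reactions']} reactions, "
      f"{sub['metabolites']} metabolites ({sub['class_level']} lipid terms)")
print(f"predicted signature: {pred['unique_species']} unique species "
      f"({pred['first_order_species']} first-order + "
      f"{pred['second_order_species']} second-order from "
      f"{pred['terms_expanded']} terms)")
print(f"validated: {val['species_negative']} negative-mode, "
      f"{val['species_positive']} positive-mode species")
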