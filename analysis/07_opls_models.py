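#!/usr/bin/env python
"""OPLS-DA models of genotype (and genotype x sex) on the full lipidome and
on the validated-signature subset, with VIP scores, 100-permutation
validation, and the univariate screen on VIP>1 features."""
import json
from pathlib import Path

import pandas as pd

from common import RUN_DIR, run_stage

run_stage("opls")
out = RUN_DIR
models = json.loads((out / "opls_models.json").read_text())
for name, m in models.items():
    two = m["two_class"]
    perm = m["two_class_permutation"]
    four = m["four_class"]
    print(f"{name}: 2-class R2X={two['R2X_cum']} R2Y={two['R2Y_cum']} "
          f"Q2={two['Q2_cum']} | perm intercepts R2Y={perm['r2y_intercept']} "
          f"Q2={perm['q2_intercept']} | 4-class Q2={four['Q2_cum']}")
try:
    uni = pd.read_csv(out / "univariate.tsv", sep="\t")
    print(f"univariate on VIP>1 features: "
          f"{int(uni['significant'].sum())}/{len(uni)} significant "
          f"(both tests p<0.05 and |rFC|>0.5)")
except (pd.errors.EmptyDataError, KeyError):
    print("univariate: no VIP>1 features")
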