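#!/usr/bin/env python
"""Render the run report (Markdown + the JSON it is built from)."""
from pathlib import Path

from common import RUN_DIR
from lipidsig import pipeline

data = pipeline.report(RUN_DIR)
print((RUN_DIR / "report.md").read_text())
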