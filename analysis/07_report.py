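#!/usr/bin/env python
"""Step 7: run every stage end to end and write the full summary report.

The report's percentages are recomputable from its counts (self-checked
on every run) and the config hash ties the artifact to its thresholds.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import run_stages

if __name__ == "__main__":
    run_stages(
        "07_report",
        {s: True for s in ("catalog", "linking", "expression",
                           "crossspecies", "enrichment")},
        __doc__)
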