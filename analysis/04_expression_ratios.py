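#!/usr/bin/env python
"""Step 4: expression analysis of linked genes.

HC/AllG mean-expression ratios for the focal (pancreas) and control
(muscle) sample groups with one-sided rank-sum p-values, plus the
per-enhancer-class ratio time course over developmental stages.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import run_stages

if __name__ == "__main__":
    data, result, outdir = run_stages(
        "04_expression",
        {"catalog": True, "linking": True, "expression": True}, __doc__)
    tc = result.report.sections["expression"]
    (outdir / "timecourse.json").write_text(
        json.dumps({"stages": tc["timecourse_stages"],
                    "ratios": tc["timecourse"]}, indent=2) + "\n")
    print(f"time course: {outdir / 'timecourse.json'}")
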