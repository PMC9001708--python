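#!/usr/bin/env python
"""Step 5: cross-species mapping and mark-sharing enrichment.

Maps the catalog to the target genome through alignment blocks
(min_match = 0.95), counts elements sharing target marks, and compares
against a length-preserving uniform shuffle null (fold change and
add-one empirical p). Also summarizes conservation by sharing group.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import run_stages

if __name__ == "__main__":
    data, result, outdir = run_stages(
        "05_crossspecies", {"catalog": True, "crossspecies": True}, __doc__)
    result.enrichment_outcomes["catalog"].to_json(outdir / "enrichment.json")
    print(f"shuffle-null outcome: {outdir / 'enrichment.json'}")
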