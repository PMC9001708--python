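#!/usr/bin/env python
"""Step 6: disease-gene and motif-overlap enrichment.

Filters the gene-disease table (score > 0.1, >= 15 translated genes),
tests linked genes per disease with the exact hypergeometric upper tail,
applies Benjamini-Hochberg with the joint rule (q <= 0.05 and ratio
>= 1.5), and computes the top-140 motif overlap structure.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import run_stages

from crelink.enrichment import results_to_frame

if __name__ == "__main__":
    data, result, outdir = run_stages(
        "06_enrichment",
        {"catalog": True, "linking": True, "enrichment": True}, __doc__)
    frame = results_to_frame(result.disease_results)
    frame.to_csv(outdir / "disease_enrichment.tsv", sep="\t", index=False)
    print(f"disease table: {outdir / 'disease_enrichment.tsv'}")
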