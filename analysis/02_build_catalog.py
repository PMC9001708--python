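#!/usr/bin/env python
"""Step 2: build the enhancer catalog.

Replicate-reproducible peaks, TSS exclusion, recurrent-artifact
blacklist, tissue-specificity split, temporal k-means clusters, and
genomic-location annotation. Writes the catalog table and stage report.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import run_stages

if __name__ == "__main__":
    data, result, outdir = run_stages(
        "02_catalog", {"catalog": True}, __doc__)
    with open(outdir / "catalog.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tspecificity\tcluster\tlocation\t"
                 "blacklisted\n")
        for r in result.records:
            fh.write(f"{r.interval.chrom}\t{r.interval.start}\t"
                     f"{r.interval.end}\t{r.specificity}\t{r.cluster}\t"
                     f"{r.location}\t{int(r.blacklisted)}\n")
    print(f"catalog table: {outdir / 'catalog.tsv'}")
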