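#!/usr/bin/env python
"""Step 3: link enhancers to genes through filtered chromatin contacts.

Calls active promoters from the promoter-mark replicates, filters
contacts (count >= 2, distance <= 100 kb), and joins enhancer chunks to
TSS chunks. Writes the link table and stage report.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import run_stages

from crelink.linking import write_links_tsv

if __name__ == "__main__":
    data, result, outdir = run_stages(
        "03_linking", {"catalog": True, "linking": True}, __doc__)
    write_links_tsv(result.links, outdir / "links.tsv")
    print(f"link table: {outdir / 'links.tsv'}")
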