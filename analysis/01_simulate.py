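#!/usr/bin/env python
"""Step 1: generate the synthetic input bundle with planted ground truth.

Writes BED/bedGraph/TSV inputs plus the ground-truth sidecar under
results/data/. All later steps read from that directory.
"""

import argparse
from pathlib import Path

from crelink.synth import SimulationConfig, simulate_all, write_dataset

if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/data"))
    args = ap.parse_args()

    cfg = SimulationConfig(seed=args.seed)
    cfg.validate()
    ds = simulate_all(cfg)
    write_dataset(ds, args.outdir)
    print(f"seed {args.seed}: wrote {len(ds.h3k27ac_rep1)} rep1 peaks, "
          f"{len(ds.contacts)} contacts, {ds.expression_values.shape} "
          f"expression matrix to {args.outdir}")
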