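"""Shared plumbing for the numbered analysis steps: load the data
directory, run the requested pipeline stages, write stage reports."""

import argparse
from pathlib import Path

from crelink.dataio import load_dataset
from crelink.pipeline import PipelineConfig, run_pipeline, write_report

ALL_STAGES = ("catalog", "linking", "expression", "crossspecies",
              "enrichment")


def run_stages(step_name: str, enabled: dict[str, bool], description: str):
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=None)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    outdir = args.outdir or Path("results") / step_name
    outdir.mkdir(parents=True, exist_ok=True)

    cfg = PipelineConfig(seed=args.seed)
    for stage in ALL_STAGES:
        setattr(cfg, f"run_{stage}", enabled.get(stage, False))
    data = load_dataset(args.datadir)
    result = run_pipeline(data, cfg)
    write_report(result.report, outdir / "report.json", fmt="json")
    write_report(result.report, outdir / "report.txt", fmt="text")
    cfg.to_json(outdir / "pipeline_config.json")
    print((outdir / "report.txt").read_text())
    return data, result, outdir
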