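#!/usr/bin/env python
"""Run the filter cascade: catalog/control removal -> truncating classes ->
linkage-region intersection; writes filter_report.json and shortlist.tsv."""
import argparse
import dataclasses
from pathlib import Path

from linkmend.pipeline import PipelineConfig, run_stage

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--outdir", type=Path, default=Path("results/run"))
args = ap.parse_args()

cfg = dataclasses.replace(PipelineConfig(), seed=args.seed)
report = run_stage("prioritize", cfg, args.outdir)
for s in report.stages:
    print(f"  {s.name:8s} {s.variants_in:5d} -> {s.variants_out:5d}")
print(f"shortlist ({len(report.shortlist)} variant(s)):")
for e in report.shortlist:
    d = e.to_dict()
    print(f"  {d['chrom']}:{d['pos']} {d['class']} {d['hgvs_c']} in {d['gene']} "
          f"(region peak LOD {d['region_peak_lod']:.2f})")
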