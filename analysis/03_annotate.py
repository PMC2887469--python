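#!/usr/bin/env python
"""Predict coding consequences for every proband variant.

Projects each variant onto the transcript models (strand-aware), classifies
it (stop_gained / frameshift / splice_site / missense / inframe_indel /
synonymous / noncoding), runs the downstream premature-stop scan for
frameshifts, and writes annotated.vcf with CLASS/HGVSC/NOVEL_CODONS/
TRUNCATING INFO keys.
"""
import argparse
import dataclasses
from pathlib import Path

from linkmend.pipeline import A, PipelineConfig, run_stage
from linkmend import io as lio

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--outdir", type=Path, default=Path("results/run"))
args = ap.parse_args()

cfg = dataclasses.replace(PipelineConfig(), seed=args.seed)
run_stage("annotate", cfg, args.outdir)
table = lio.read_vcf(args.outdir / A["annotated"])
counts = {}
for inf in table.info:
    counts[inf.get("CLASS", "?")] = counts.get(inf.get("CLASS", "?"), 0) + 1
print("consequence classes in the proband genome:")
for klass, n in sorted(counts.items(), key=lambda kv: -kv[1]):
    print(f"  {klass:14s} {n}")
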