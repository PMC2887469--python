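"""The rare-truncating-variant filter cascade.

Three intersection filters applied to the proband's variant list:

1. remove variants present in a known-variant catalog or in any control
   genome (presence/absence on normalized allele identity);
2. keep only variants whose most severe consequence is protein-truncating
   (stop_gained or frameshift by default);
3. keep only variants inside the candidate linkage regions.

Because each filter is a set intersection, the final shortlist is invariant
under filter order; the per-stage accounting makes the narrowing auditable
(at study scale: ~10^2 genome-wide private truncating variants collapse to a
single candidate once restricted to the linked megabases).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .annotate import Consequence, ConsequenceClass, SEVERITY
from .intervals import GenomicInterval, point_in_any
from .linkage import CandidateRegion
from .variants import ReferenceLookup, Variant, left_align


class FilterError(ValueError):
    pass


DEFAULT_KEEP_CLASSES = frozenset(
    {ConsequenceClass.STOP_GAINED, ConsequenceClass.FRAMESHIFT}
)

DEFAULT_ORDER = ("known", "class", "regions")


@dataclass
class FilterStage:
    name: str
    variants_in: int
    variants_out: int
    removed_ids: list[str]


@dataclass
class ShortlistEntry:
    variant: Variant
    consequence: Consequence
    region: GenomicInterval
    region_peak_lod: float

    def to_dict(self) -> dict:
        return {
            "chrom": self.variant.chrom,
            "pos": self.variant.pos,
            "ref": self.variant.ref,
            "alt": self.variant.alt,
            "class": self.consequence.klass.value,
            "hgvs_c": self.consequence.hgvs_text,
            "gene": self.consequence.gene_id,
            "region": f"{self.region.chrom}:{self.region.start}-{self.region.end}",
            "region_peak_lod": self.region_peak_lod,
        }


@dataclass
class FilterReport:
    stages: list[FilterStage]
    shortlist: list[ShortlistEntry]

    def __post_init__(self) -> None:
        for a, b in zip(self.stages, self.stages[1:]):
            if b.variants_in != a.variants_out:
                raise FilterError(
                    f"stage chaining broken: {a.name} out {a.variants_out} != "
                    f"{b.name} in {b.variants_in}"
                )
        for s in self.stages:
            if s.variants_out > s.variants_in:
                raise FilterError(f"stage {s.name} gained variants")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "stages": [
                {
                    "name": s.name,
                    "variants_in": s.variants_in,
                    "variants_out": s.variants_out,
                    "removed_ids": s.removed_ids,
                }
                for s in self.stages
            ],
            "shortlist": [e.to_dict() for e in self.shortlist],
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def _vid(v: Variant) -> str:
    return v.id or f"{v.chrom}:{v.pos}:{v.ref}:{v.alt}"


# ---------------------------------------------------------------------------
# Individual filters
# ---------------------------------------------------------------------------

def filter_known(
    proband: Sequence[Variant],
    catalog: Sequence[Variant],
    control_sets: Sequence[Sequence[Variant]],
    reference: ReferenceLookup,
) -> list[Variant]:
    """Drop proband variants present in the catalog or any control genome.

    Matching is by exact normalized (chrom, pos, ref, alt) identity - a
    control that carries at least one alternate allele counts as having the
    variant; a different allele at the same site does not.
    """
    known: set = set()
    for vs in [catalog, *control_sets]:
        known.update(left_align(v, reference).key for v in vs)
    return [v for v in proband if left_align(v, reference).key not in known]


def filter_by_class(
    variants: Sequence[Variant],
    consequences: dict[tuple, Sequence[Consequence]],
    keep_classes: frozenset = DEFAULT_KEEP_CLASSES,
) -> list[Variant]:
    """Keep variants whose most severe consequence class is in keep_classes."""
    out = []
    for v in variants:
        cons = consequences.get(v.key)
        if not cons:
            raise FilterError(f"variant {_vid(v)} has no annotation")
        best = min(cons, key=lambda c: SEVERITY[c.klass])
        if best.klass in keep_classes:
            out.append(v)
    return out


def filter_by_regions(
    variants: Sequence[Variant], regions: Sequence[GenomicInterval]
) -> list[Variant]:
    """Keep variants whose position lies inside any candidate region
    (1-based inclusive containment; empty region list is an error so that
    "no linkage signal" is distinct from "no variants")."""
    if not regions:
        raise FilterError("no candidate regions: refusing to filter by position")
    return [v for v in variants if point_in_any(regions, v.chrom, v.pos)]


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------

def run_cascade(
    proband: Sequence[Variant],
    catalog: Sequence[Variant],
    control_sets: Sequence[Sequence[Variant]],
    regions: Sequence[CandidateRegion],
    consequences: dict[tuple, Sequence[Consequence]],
    reference: ReferenceLookup,
    keep_classes: frozenset = DEFAULT_KEEP_CLASSES,
    order: Sequence[str] = DEFAULT_ORDER,
) -> FilterReport:
    """Apply the three filters in ``order`` and account for every removal.

    The shortlist is ranked by consequence severity, then by the peak LOD of
    the containing region, then position.
    """
    if sorted(order) != sorted(DEFAULT_ORDER):
        raise FilterError(f"order must be a permutation of {DEFAULT_ORDER}")
    intervals = [r.interval for r in regions]
    current = list(proband)
    stages: list[FilterStage] = []
    for name in order:
        n_in = len(current)
        if name == "known":
            nxt = filter_known(current, catalog, control_sets, reference)
        elif name == "class":
            nxt = filter_by_class(current, consequences, keep_classes)
        else:
            nxt = filter_by_regions(current, intervals)
        kept = {v.key for v in nxt}
        removed = [_vid(v) for v in current if v.key not in kept]
        stages.append(FilterStage(name, n_in, len(nxt), removed))
        current = nxt

    entries = []
    for v in current:
        best = min(consequences[v.key], key=lambda c: SEVERITY[c.klass])
        containing = [
            r for r in regions if r.interval.contains(v.chrom, v.pos)
        ]
        peak = max((r.peak_lod for r in containing), default=float("nan"))
        region = containing[0].interval if containing else None
        entries.append(ShortlistEntry(v, best, region, peak))
    entries.sort(
        key=lambda e: (
            SEVERITY[e.consequence.klass],
            -(e.region_peak_lod if e.region_peak_lod == e.region_peak_lod else -1e9),
            e.variant.chrom,
            e.variant.pos,
        )
    )
    return FilterReport(stages, entries)
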