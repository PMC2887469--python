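"""End-to-end orchestration: simulate -> linkage -> annotate -> prioritize -> validate.

Each stage reads and writes files under a run directory so stages can be run
in isolation and re-runs are byte-identical for a fixed config + seed.  The
in-memory :func:`end_to_end` shortcut executes the same computations without
touching disk (used by tests and calibration loops).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import io as lio
from .annotate import Annotator, Consequence, ConsequenceClass, info_fields
from .disease import DiseaseModel
from .hgvs import parse_hgvs_c
from .intervals import GenomicInterval
from .linkage import (
    CandidateRegion,
    LodCurve,
    SnpSelectionRule,
    affected_sharing_scan,
    call_candidate_regions,
    compute_multipoint_lod,
    select_linkage_snps,
)
from .markers import read_genotypes_ped, read_map, write_genotypes_ped, write_map
from .pedigree import Affection, Pedigree, Sex, read_pedigree, write_pedigree
from .prioritize import DEFAULT_ORDER, FilterReport, run_cascade
from .simulate import (
    CohortConfig,
    SyntheticCohort,
    TruthRecord,
    VariantCounts,
    build_cohort,
)
from .transcripts import read_gff_transcripts, write_gff3
from .validate import (
    CARRIER,
    NON_CARRIER,
    CoverageRule,
    control_cohort_screen,
    cosegregation_test,
    coverage_assess,
    read_carrier_table,
    restriction_site_diff,
    write_carrier_table,
)
from .variants import Variant

logger = logging.getLogger(__name__)

STAGES = ("simulate", "linkage", "annotate", "prioritize", "validate")


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the pipeline with their documented defaults
    (penetrance 0.8, het-in-4 selection at 2%, LOD threshold 1.0,
    covered base = 5 reads with positive score)."""

    seed: int = 0
    cohort: CohortConfig = CohortConfig()
    snp_selection: SnpSelectionRule = SnpSelectionRule()
    lod_threshold: float = 1.0
    merge_gap_markers: int = 0
    max_sharing_exceptions: int = 1
    filter_order: tuple[str, ...] = DEFAULT_ORDER
    coverage_rule: CoverageRule = CoverageRule()

    # -- YAML round trip ----------------------------------------------
    def to_dict(self) -> dict:
        c = self.cohort
        return {
            "seed": self.seed,
            "cohort": {
                "template": c.template,
                "markers_per_cm": c.markers_per_cm,
                "n_genes": c.n_genes,
                "region_mb": c.region_mb,
                "min_affected": c.min_affected,
                "mean_depth": c.mean_depth,
                "depth_bases": c.depth_bases,
                "counts": dataclasses.asdict(c.counts),
            },
            "disease_model": dataclasses.asdict(c.model),
            "snp_selection": dataclasses.asdict(self.snp_selection),
            "lod_threshold": self.lod_threshold,
            "merge_gap_markers": self.merge_gap_markers,
            "max_sharing_exceptions": self.max_sharing_exceptions,
            "filter_order": list(self.filter_order),
            "coverage_rule": dataclasses.asdict(self.coverage_rule),
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        try:
            cd = dict(d.get("cohort", {}))
            counts = VariantCounts(**cd.pop("counts", {}))
            model = DiseaseModel(**d.get("disease_model", {}))
            cohort = CohortConfig(model=model, counts=counts, **cd)
            return cls(
                seed=int(d.get("seed", 0)),
                cohort=cohort,
                snp_selection=SnpSelectionRule(**d.get("snp_selection", {})),
                lod_threshold=float(d.get("lod_threshold", 1.0)),
                merge_gap_markers=int(d.get("merge_gap_markers", 0)),
                max_sharing_exceptions=int(d.get("max_sharing_exceptions", 1)),
                filter_order=tuple(d.get("filter_order", DEFAULT_ORDER)),
                coverage_rule=CoverageRule(**d.get("coverage_rule", {})),
            )
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            payload = yaml.safe_load(Path(path).read_text())
        except OSError as exc:
            raise ConfigError(f"cannot read config: {exc}") from exc
        if not isinstance(payload, dict):
            raise ConfigError("config file must hold a mapping")
        return cls.from_dict(payload)


# ---------------------------------------------------------------------------
# Artifact names
# ---------------------------------------------------------------------------

A = {
    "pedigree": "pedigree.ped",
    "genotypes": "genotypes.ped",
    "map": "markers.map",
    "proband": "proband.vcf",
    "catalog": "catalog.vcf",
    "gff": "transcripts.gff3",
    "fasta": "reference.fa",
    "depth": "depth.tsv",
    "truth": "truth.json",
    "carriers": "carriers.tsv",
    "lod": "lod.tsv",
    "regions_bed": "regions.bed",
    "regions_json": "regions.json",
    "sharing_json": "sharing_regions.json",
    "dropped": "dropped_markers.log",
    "annotated": "annotated.vcf",
    "report": "filter_report.json",
    "shortlist": "shortlist.tsv",
    "segregation": "segregation.json",
    "rflp": "rflp.json",
    "coverage": "coverage.json",
    "control_screen": "control_screen.json",
    "manifest": "run_manifest.json",
}


def control_path(outdir: Path, j: int) -> Path:
    return outdir / f"control_{j + 1}.vcf"


def _require(outdir: Path, names: Sequence[str], stage: str, producer: str) -> None:
    for n in names:
        if not (outdir / A[n]).exists():
            raise StageError(
                stage, f"missing input {A[n]} (run the {producer!r} stage first)"
            )


def _contigs(cfg: PipelineConfig) -> dict[str, int]:
    return {c: l for c, l in cfg.cohort.genome.chrom_lengths}


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

_SEX_OUT = {Sex.MALE: "1", Sex.FEMALE: "2"}
_AFF_OUT = {Affection.UNAFFECTED: "1", Affection.AFFECTED: "2", Affection.UNKNOWN: "0"}


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> SyntheticCohort:
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = build_cohort(cfg.cohort, cfg.seed)
    write_pedigree(cohort.pedigree, outdir / A["pedigree"])
    write_map(cohort.gmap, outdir / A["map"])
    rows = [
        (
            i.id,
            i.father_id or "0",
            i.mother_id or "0",
            _SEX_OUT[i.sex],
            _AFF_OUT[i.affection],
        )
        for i in cohort.pedigree.individuals
    ]
    order = [r[0] for r in rows]
    geno = cohort.genotypes
    perm = [geno.sample_ids.index(i) for i in order]
    from .markers import GenotypeMatrix

    write_genotypes_ped(
        outdir / A["genotypes"],
        cohort.pedigree.family_id,
        rows,
        GenotypeMatrix(order, geno.alleles[:, perm, :]),
    )
    contigs = _contigs(cfg)
    vs = cohort.variant_sets
    n = len(vs.proband)
    lio.write_vcf(
        outdir / A["proband"],
        vs.proband,
        contigs,
        samples=["PROBAND"],
        genotypes=np.ones((n, 1), dtype=np.int8),
    )
    lio.write_vcf(outdir / A["catalog"], vs.catalog, contigs)
    for j, cset in enumerate(vs.controls):
        lio.write_vcf(
            control_path(outdir, j),
            cset,
            contigs,
            samples=[f"CTRL{j + 1}"],
            genotypes=np.ones((len(cset), 1), dtype=np.int8),
        )
    write_gff3(cohort.transcripts, outdir / A["gff"])
    lio.write_fasta(cohort.reference, outdir / A["fasta"])
    lio.write_depth_tsv(cohort.depth, outdir / A["depth"])
    cohort.truth.to_json(outdir / A["truth"])
    calls = {
        i.id: (CARRIER if i.id in cohort.truth.carrier_ids else NON_CARRIER)
        for i in cohort.pedigree.individuals
        if i.genotyped
    }
    write_carrier_table(calls, outdir / A["carriers"])
    return cohort


def stage_linkage(cfg: PipelineConfig, outdir: Path) -> list[CandidateRegion]:
    _require(
        outdir, ["pedigree", "genotypes", "map"], "linkage", "simulate"
    )
    pedigree = read_pedigree(outdir / A["pedigree"])
    gmap = read_map(outdir / A["map"])
    _, genotypes = read_genotypes_ped(outdir / A["genotypes"], len(gmap))
    keep = select_linkage_snps(genotypes, gmap, cfg.snp_selection, cfg.seed)
    sub_map = gmap.subset(keep)
    sub_geno = genotypes.subset_markers(keep)
    curve = compute_multipoint_lod(pedigree, sub_geno, sub_map, cfg.cohort.model)
    curve.to_frame().to_csv(outdir / A["lod"], sep="\t", index=False)
    (outdir / A["dropped"]).write_text(
        "".join(f"{m}\n" for m in curve.dropped_markers)
    )
    regions = call_candidate_regions(curve, cfg.lod_threshold, cfg.merge_gap_markers)
    lio.write_bed([r.interval for r in regions], outdir / A["regions_bed"])
    (outdir / A["regions_json"]).write_text(
        json.dumps([r.to_dict() for r in regions], indent=1) + "\n"
    )
    sharing = affected_sharing_scan(
        pedigree, sub_geno, sub_map, cfg.max_sharing_exceptions
    )
    (outdir / A["sharing_json"]).write_text(
        json.dumps(
            [
                {k: v for k, v in r.to_dict().items() if k != "peak_lod"}
                for r in sharing
            ],
            indent=1,
        )
        + "\n"
    )
    return regions


def stage_annotate(cfg: PipelineConfig, outdir: Path) -> None:
    _require(outdir, ["proband", "gff", "fasta"], "annotate", "simulate")
    table = lio.read_vcf(outdir / A["proband"])
    transcripts = read_gff_transcripts(outdir / A["gff"])
    reference = lio.read_fasta(outdir / A["fasta"])
    ann = Annotator(transcripts, reference)
    info = [info_fields(ann.annotate(v)) for v in table.variants]
    lio.write_vcf(
        outdir / A["annotated"],
        table.variants,
        _contigs(cfg),
        info=info,
        samples=table.samples,
        genotypes=table.genotypes,
    )


def _consequences_from_info(table: lio.VcfTable) -> dict[tuple, list[Consequence]]:
    out: dict[tuple, list[Consequence]] = {}
    for v, inf in zip(table.variants, table.info):
        klass = ConsequenceClass(inf.get("CLASS", "noncoding"))
        hgvs = parse_hgvs_c(inf["HGVSC"]) if inf.get("HGVSC") else None
        out[v.key] = [
            Consequence(
                v,
                klass,
                gene_id=inf.get("GENE"),
                hgvs_c=hgvs,
                novel_codons_before_stop=inf.get("NOVEL_CODONS"),
            )
        ]
    return out


def stage_prioritize(cfg: PipelineConfig, outdir: Path) -> FilterReport:
    _require(
        outdir,
        ["annotated", "catalog", "regions_json", "fasta"],
        "prioritize",
        "annotate (and linkage)",
    )
    table = lio.read_vcf(outdir / A["annotated"])
    catalog = lio.read_vcf(outdir / A["catalog"]).variants
    controls = []
    j = 0
    while control_path(outdir, j).exists():
        controls.append(lio.read_vcf(control_path(outdir, j)).variants)
        j += 1
    regions_payload = json.loads((outdir / A["regions_json"]).read_text())
    regions = [
        CandidateRegion(
            GenomicInterval(r["chrom"], r["start"], r["end"]),
            r["peak_lod"],
            r["n_markers"],
            r["n_tolerated_nonpenetrant"],
        )
        for r in regions_payload
    ]
    reference = lio.read_fasta(outdir / A["fasta"])
    report = run_cascade(
        table.variants,
        catalog,
        controls,
        regions,
        _consequences_from_info(table),
        reference,
        order=cfg.filter_order,
    )
    report.to_json(outdir / A["report"])
    lines = ["chrom\tpos\tref\talt\tclass\thgvs_c\tgene\tregion\tregion_peak_lod"]
    for e in report.shortlist:
        d = e.to_dict()
        lines.append(
            "\t".join(
                str(d[k])
                for k in (
                    "chrom", "pos", "ref", "alt", "class", "hgvs_c", "gene",
                    "region", "region_peak_lod",
                )
            )
        )
    (outdir / A["shortlist"]).write_text("\n".join(lines) + "\n")
    return report


def stage_validate(cfg: PipelineConfig, outdir: Path) -> None:
    _require(
        outdir,
        ["pedigree", "carriers", "shortlist", "fasta", "gff", "depth", "regions_bed"],
        "validate",
        "prioritize",
    )
    pedigree = read_pedigree(outdir / A["pedigree"])
    calls = read_carrier_table(outdir / A["carriers"])
    verdict = cosegregation_test(pedigree, calls)
    verdict.to_json(outdir / A["segregation"])

    reference = lio.read_fasta(outdir / A["fasta"])
    transcripts = read_gff_transcripts(outdir / A["gff"])
    ann = Annotator(transcripts, reference)

    shortlist_lines = (outdir / A["shortlist"]).read_text().splitlines()[1:]
    rflp_payload = []
    screen_payload: dict[str, object] = {"regions": []}
    if shortlist_lines:
        f = shortlist_lines[0].split("\t")
        top = Variant(f[0], int(f[1]), f[2], f[3])
        window = reference.window_containing(top.chrom, top.pos)
        seq = reference.fetch(top.chrom, window.start, window.end)
        from .validate import ENZYME_LIBRARY

        diffs = restriction_site_diff(
            seq, window.start, top, list(ENZYME_LIBRARY.values())
        )
        rflp_payload = [
            {"enzyme": d.enzyme, "lost": d.lost, "gained": d.gained}
            for d in diffs
            if d.lost or d.gained
        ]
        # control screen over the top variant's gene footprint
        gene_region = next(
            (
                t.span
                for t in transcripts
                if t.span.contains(top.chrom, top.pos)
            ),
            None,
        )
        if gene_region is not None:
            controls = []
            j = 0
            while control_path(outdir, j).exists():
                table = lio.read_vcf(control_path(outdir, j))
                controls.append(
                    [
                        (v, int(table.genotypes[i, 0]))
                        for i, v in enumerate(table.variants)
                    ]
                )
                j += 1
            count = control_cohort_screen(controls, gene_region, ann)
            screen_payload = {
                "region": f"{gene_region.chrom}:{gene_region.start}-{gene_region.end}",
                "truncating_alleles": count,
                "n_controls": j,
            }
    (outdir / A["rflp"]).write_text(json.dumps(rflp_payload, indent=1) + "\n")
    (outdir / A["control_screen"]).write_text(
        json.dumps(screen_payload, indent=1) + "\n"
    )

    depth = lio.read_depth_tsv(outdir / A["depth"])
    regions = lio.read_bed(outdir / A["regions_bed"])
    report = coverage_assess(depth, cfg.coverage_rule, regions)
    report.to_json(outdir / A["coverage"])


# ---------------------------------------------------------------------------
# Full runs
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(cfg: PipelineConfig, outdir: Path) -> None:
    from . import __version__

    artifacts = {}
    for p in sorted(outdir.iterdir()):
        if p.name == A["manifest"] or p.is_dir():
            continue
        artifacts[p.name] = _sha256(p)
    payload = {
        "package": "linkmend",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "artifacts": artifacts,
    }
    (outdir / A["manifest"]).write_text(
        json.dumps(payload, indent=1, sort_keys=True) + "\n"
    )


def run_stage(name: str, cfg: PipelineConfig, outdir: Path):
    fn = {
        "simulate": stage_simulate,
        "linkage": stage_linkage,
        "annotate": stage_annotate,
        "prioritize": stage_prioritize,
        "validate": stage_validate,
    }[name]
    try:
        return fn(cfg, outdir)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(name, str(exc)) from exc


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> FilterReport:
    """Execute all stages in order and write a checksummed run manifest."""
    outdir = Path(outdir)
    report: Optional[FilterReport] = None
    for name in STAGES:
        logger.info("running stage %s", name)
        result = run_stage(name, cfg, outdir)
        if name == "prioritize":
            report = result
    write_manifest(cfg, outdir)
    assert report is not None
    return report


# ---------------------------------------------------------------------------
# In-memory end-to-end (no files) - used by tests and recovery studies
# ---------------------------------------------------------------------------

@dataclass
class EndToEndResult:
    cohort: SyntheticCohort
    curve: LodCurve
    regions: list[CandidateRegion]
    report: Optional[FilterReport]  # None when linkage called no region at all
    region_recovered: bool
    causal_in_shortlist: bool


def end_to_end(cfg: PipelineConfig, seed: Optional[int] = None) -> EndToEndResult:
    """Simulate a cohort and run linkage + cascade in memory."""
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    cohort = build_cohort(cfg.cohort, cfg.seed)
    keep = select_linkage_snps(
        cohort.genotypes, cohort.gmap, cfg.snp_selection, cfg.seed
    )
    curve = compute_multipoint_lod(
        cohort.pedigree,
        cohort.genotypes.subset_markers(keep),
        cohort.gmap.subset(keep),
        cfg.cohort.model,
    )
    regions = call_candidate_regions(curve, cfg.lod_threshold, cfg.merge_gap_markers)
    causal = cohort.truth.causal_variant
    if not regions:
        return EndToEndResult(cohort, curve, regions, None, False, False)
    ann = Annotator(cohort.transcripts, cohort.reference)
    consequences = {
        v.key: ann.annotate(v) for v in cohort.variant_sets.proband
    }
    report = run_cascade(
        cohort.variant_sets.proband,
        cohort.variant_sets.catalog,
        cohort.variant_sets.controls,
        regions,
        consequences,
        cohort.reference,
        order=cfg.filter_order,
    )
    recovered = any(
        r.interval.contains(causal.chrom, causal.pos) for r in regions
    )
    in_shortlist = any(
        e.variant.key == causal.key for e in report.shortlist
    )
    return EndToEndResult(cohort, curve, regions, report, recovered, in_shortlist)
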