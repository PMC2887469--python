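# Methods

`linkmend` implements the strategy of mapping a dominant Mendelian disease
gene by combining weak linkage evidence from one small family with
whole-genome variant prioritization in a single sequenced proband.  The
pipeline has five stages: simulate (or load) a cohort, compute parametric
multipoint linkage, annotate coding consequences, filter the proband's
variants down to a shortlist, and confirm the surviving candidate.

## Disease model

A diallelic single-locus model: disease allele frequency `q` and penetrance
vector `(f0, f1, f2)` for 0/1/2 copies.  Defaults: `q = 1e-4`, `f0 = 0`
(no phenocopies), `f1 = f2 = 0.8` — a rare dominant allele with reduced
penetrance.  The penetrance of 0.8 is the value used in the motivating
analysis; `q` and `f0` are conventional rare-dominant defaults and are
configurable (`disease_model:` in the YAML config).  Unaffected carriers
(non-penetrance) are therefore expected and tolerated throughout: the
linkage likelihood weighs them by `1 - f1` rather than excluding linkage,
the sharing scan allows a configurable number of exceptions, and the
co-segregation test reports them instead of calling incompatibility.

## Multipoint linkage engine

The hidden state at each marker is the inheritance vector: one bit per
parent-to-child meiosis recording which grandparental allele was
transmitted (2 non-founder members × 2 bits; the engine refuses pedigrees
beyond 2^24 states, and the shipped fixtures need 2^12).  The chain over
markers has independent per-bit flip probability θ given by the Haldane map
function θ(d) = (1 − e^(−2d/100))/2 on the cM map — no interference, the
standard multipoint assumption.

Marker data enter through the founder-allele graph: for a fixed inheritance
vector, every individual's two alleles are copies of founder "slots";
observed homozygotes pin slot values, heterozygotes force their two slots
to differ, and each connected component contributes the summed probability
of its consistent assignments (a parity-carrying union–find, implemented as
a numba kernel over all vectors).  Phenotypes enter through an exhaustive
sum over founder disease-allele configurations weighted by `q` and the
penetrance vector.  The reported score at marker x is

    LOD(x) = log10 [ P(M, Φ | disease locus at x) / (P(M) · P(Φ)) ],

computed from the forward–backward posterior of the vector at x; the LOD is
evaluated at marker positions only (no between-marker interpolation) and is
0 wherever the data are entirely uninformative.  Markers whose genotypes
are Mendelian-impossible for the pedigree (total emission zero) are dropped
and logged.  Founder marker-allele frequencies are estimated from the
genotyped members with a symmetric pseudocount of 1 unless supplied.

Correctness is guarded by an independent oracle in the test suite: complete
enumeration of joint descent patterns across loci together with brute-force
founder-configuration sums.  On all test pedigrees the engine agrees with
the enumeration to better than 1e-6; a phase-known, fully penetrant family
with m informative meioses gives exactly m·log10 2 at the co-segregating
marker (evaluated at q = 1e-8; the identity holds in the q → 0 limit).

### SNP selection

Markers heterozygous in at least 4 genotyped members are eligible;
`round(0.02 × eligible)` are retained, thinned evenly in genetic position
per chromosome (allocation proportional to eligible counts).  Both numbers
mirror the motivating study's chip filtering and are configurable.

### Region calling

Maximal runs of markers with LOD ≥ threshold (default 1.0, the smallest
value treated as suggestive in the motivating analysis; ties included) are
reported, optionally merging runs separated by ≤ `merge_gap_markers`
sub-threshold markers.  By default each region is extended to the flanking
sub-threshold markers (support-interval convention): with the desk-scale
map's ~1.6 cM selected-marker spacing, the locus is not excluded anywhere
short of the flanking marker, and spanning only the qualifying markers
systematically clipped true loci off region edges.
`extend_to_flanking=False` restores the qualifying-markers-only rule.

### Affected-sharing scan

A deliberately simplified IBS (identity-by-state) scan: at each marker it
asks whether a single allele could be carried by every genotyped affected,
tolerating up to `max_sharing_exceptions` affecteds (default 1); maximal
compatible runs become regions, and unaffected members carrying the shared
allele at every typed marker of a run are reported as candidate
non-penetrants.  IBD-based sharing is out of scope.

## Consequence annotation

Variants (VCF left-anchored; all set comparisons run on left-aligned,
minimal representations so repeat-tract indels match regardless of how they
were written) are projected into spliced CDS coordinates, strand-aware.
Classes: stop_gained, frameshift, splice_site (±2 intronic bp of an exon
edge, and any indel crossing an exon boundary), missense, inframe_indel,
synonymous, noncoding; severity follows that order and the most severe
consequence represents the variant.  An indel wholly inside the CDS is a
frameshift iff its net length change is not divisible by 3.  For
frameshifts, the mutated CDS is translated from the last unaffected codon
boundary and the novel codons before the first stop are counted; a shifted
frame that never reaches a stop is still classified truncating and flagged
(`terminates = false`).  "Protein-truncating" means stop_gained or
frameshift, by class alone.

## Filter cascade

Three intersection filters with per-stage accounting: (1) remove variants
whose normalized identity appears in the known-variant catalog or in any of
the control genomes (presence/absence, not frequency; a different allele at
a known site is kept); (2) keep protein-truncating classes; (3) keep
variants positioned inside the candidate regions (1-based inclusive; an
empty region list is an error so "no linkage signal" cannot masquerade as
"no variants").  The filters commute — the shortlist is order-invariant,
which a property test demonstrates — and the shortlist is ranked by
severity, then regional peak LOD.

## Synthetic cohorts

The generator provides truth-labelled inputs for every stage.

* **Pedigree fixtures.**  `pedigree1_like`: four generations, 12 genotyped,
  7 affected / 5 unaffected (six founders, six non-founders; maximum
  attainable LOD 5·log10 2 ≈ 1.51 at perfect co-segregation).
  `pedigree2_like`: three generations, 10 genotyped, 3 affected, with two
  obligate-carrier branches through unaffected parents.  Both match
  published member/affected counts; the exact drawn topologies of the real
  families are not public, so these are canonical stand-ins.
* **Genome and chip.**  22 autosomes at human-like lengths (2,872 Mb
  total), uniform 1.2 cM/Mb.  Chip markers are evenly spaced at 40/cM
  (~138,000 markers) with allele frequencies uniform in [0.2, 0.8]
  (common-SNP ascertainment).  The real chip is ~4× denser; 40/cM is the
  densest map that keeps a full pipeline run near 3 s on one CPU, and the
  2% selection then yields ~2,200 linkage markers (~1.6 cM spacing, ~5×
  the study's selected spacing).
* **Planting and ascertainment.**  One founder introduces a single copy of
  the disease allele; descent bits at the causal locus are drawn per
  meiosis and phenotypes per the penetrance model.  Descent and phenotypes
  are rejection-sampled until ≥ `min_affected` members are affected
  (default 7, the study family's affected count) — the ascertainment that
  makes a clinically collected, multiply affected family; penetrance
  calibration uses `min_affected=None` for unbiased sampling.  Marker
  genotypes are then gene-dropped *conditionally* on the causal descent
  (Markov walk outward from the causal position), so nearby markers
  co-segregate with carrier status at the Haldane rate.
* **Variant sets.**  The proband list is the causal 11 bp frameshifting CDS
  deletion plus four decoy strata: 1,000 catalog-known SNVs, 500
  control-shared SNVs (each carried by ≥ 1 of 8 control genomes), 300
  private benign SNVs, and 108 private truncating decoys (19 stop gains
  engineered by single-base codon→stop changes and 89 frameshifting
  indels), for 109 private truncating variants in total.  Truncating decoys
  are placed in genes outside the planted region, so that region contains
  exactly one private truncating variant; decoys can and do fall inside
  false-positive linkage regions, which is why the final shortlist has a
  handful of entries rather than exactly one.  Reference sequence exists
  only in windows around the 280 simulated genes (sparse FASTA with
  `chrom:start-end` headers); every simulated variant lies inside a window.
* **Depth profiles.**  Per-base Poisson reads at 31.8× with 2.2% of bases
  unmappable (zero reads, emulating gaps and unalignable sequence, which is
  what keeps genome-wide covered fraction near 98% rather than ~100%);
  consensus scores are positive wherever reads landed (an optional
  `score_zero_fraction` marks covered bases low-confidence to exercise the
  score clause).  The covered-base rule is ≥ 5 reads and score > 0, and the
  per-region report uses a strict > 10× cutoff.

What the generator does **not** emulate: genotyping and sequencing error,
linkage disequilibrium between founder haplotypes, interference, sex-
specific maps, structural variants, X-linkage, and population structure in
the catalog/controls.  Green tests therefore demonstrate the machinery and
its statistical calibration on idealized data, not robustness to the noise
of real call sets.

Two engineered single-gene fixtures (clearly synthetic; the real
transcripts are not bundled) reproduce the geometry of the study's two
mutations: `make_truncation_demo` builds a 200-codon CDS in which deleting
coding bases 514–524 shifts the frame into 12 novel codons followed by a
premature stop, and `make_nonsense_demo` fixes codons 137–138 to GTA·CGA so
the C>T at coding position 412 creates a stop codon and destroys the RsaI
site GTAC spanning the codon boundary.

## Confirmation stage

Co-segregation: compatible iff every genotyped affected is a carrier and
every carrier's status is transmissible (a non-founder carrier needs a
carrier or untyped parent; untyped members are permissive, allowing
obligate-carrier paths).  Unaffected carriers are reported as non-penetrant.
RFLP design scans both strands with IUPAC-degenerate recognition patterns
(library: RsaI, AluI, HaeIII, TaqI, HinfI, EcoRI, BamHI, HindIII) and
reports sites lost/gained by a variant; the scan is cross-checked against
Biopython's enzyme catalog in tests.  The control screen counts truncating
alleles among control variant sets restricted to a region (zero across a
sizeable cohort supports pathogenicity).

## Determinism and numerics

All randomness flows from one master seed through named streams
(`SeedSequence`-style: seed + CRC of the stage label), so any stage is
reproducible in isolation; identical config + seed gives byte-identical
artifacts (checksummed in `run_manifest.json`, which contains no
timestamps).  Forward–backward vectors are renormalized per marker; the
reported LOD is clamped at −20 to keep curves finite when full-penetrance
models meet incompatible vectors; ties at the region threshold are included
(`≥`).  Degenerate inputs fail loudly: empty maps, regionless cascades,
unsorted depth profiles, Mendelian-impossible carrier tables.

## Problem sizes

Defaults were chosen so that a full synthetic study (simulate → linkage →
cascade) runs in ~3 s on one CPU: ~138k chip markers, ~2,200 linkage
markers, 2^12 inheritance vectors, 280 genes, ~1,900 proband variants.  The
50-seed recovery study runs in under 4 minutes.  At these sizes the
measured behaviour (seeded, recomputed by `scripts/acceptance.py`) is:
region recovery ≈ 98% at threshold 1.0 with the causal variant present in
the shortlist in every recovered run, and a mean shortlist of ~6 variants
(the causal one plus truncating decoys caught by false-positive regions).

## Known limitations

The engine targets fixture-scale pedigrees (≲ 2^16 inheritance vectors);
founder-couple symmetry reduction is not implemented.  HGVS support covers
the coding-DNA subset actually emitted (substitution, deletion, insertion,
delins; no intronic offsets or protein notation).  The sharing scan is IBS
only.  Multi-family pooled LOD, error-model genotyping and non-parametric
statistics are out of scope.
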