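# Methods

## Setting and model

`cleftshare` targets study designs in which several distantly related
affected individuals (second/third-degree relatives) per family are
sequenced, many families are consanguineous, and no parents or unaffected
relatives are available. Under a recessive model, a rare risk allele
descending from a shared ancestor through a marriage loop appears as
*shared homozygosity* among affected relatives; under a compound-het
model it appears as two or more rare heterozygous sites in one gene in
every affected individual. The pipeline contains no statistical test:
each step is a deterministic counting criterion, and no multiple-testing
correction is applied. Its output is a candidate list, not an inference.

Genotypes are modelled per alternate allele. Multiallelic sites are split
at ingest into biallelic records; a genotype carrying two different
alternates is heterozygous on each split record. Missing calls (`./.`)
are a first-class state and are never imputed: a missing call can never
satisfy a carrier or homozygote requirement, but by default it remains in
the "all cases" denominator of the population filter (toggle:
`population_exclude_missing_from_denominator`).

## Filter parameters

All thresholds live in `FilterConfig`:

| parameter | default | meaning |
|---|---|---|
| `min_mapping_quality` | 30 | drop below |
| `min_depth` / `max_depth` | 8 / 20 000 | total site depth across samples |
| `min_call_rate` | 0.98 | fraction of samples called; rule skipped on chr Y |
| `max_replicate_discordant_pairs` | 1 | duplicate pairs with a genotype mismatch; drop on strictly more |
| `low_quality_prob_threshold` | 0.70 | classifier probability; drops only together with a VQSR failure, and only when *strictly* exceeded |
| `max_maf` | 0.05 | reference-panel frequency ceiling (strictly greater drops) |
| `population_min_carrier_fraction` | 0.20 | carriers / all cases |
| `population_min_hom` | 1 | homozygotes required per population |
| `family_min_hom` | 2 | homozygous affected members per family |
| `wgs_min_carriers` / `wgs_reference_family_size` | 7 / 8 | carrier quota, scaled as `ceil(7m/8)` for other family sizes |
| `hla_chrom/start/end` | 6: 28 477 797–33 448 354 | extended MHC interval used for the HLA exclusion |
| `enhancer_min_score` | 5 | GeneHancer-style score cut used when *building* region BEDs |
| `promoter_max_tss_distance` | 200 000 bp | promoter screening distance, likewise applied at BED construction |

Interpretation choices behind the defaults:

* **Depth is site-level**, summed over samples: an 8–20 000 range is only
  meaningful site-wise for a cohort of ~110 samples.
* **HLA exclusion is a per-analysis toggle**, on for population scans and
  off for the family scan. The source analyses report an HLA-region
  family hit while excluding HLA at the population level, so a global
  exclusion would be wrong; the toggle makes the ordering explicit.
* **The genome-discovery carrier quota includes the homozygote** by
  default. The alternative reading — seven of the eight *other* members,
  i.e. the quota excludes one obligate homozygote — is available as
  `wgs_homozygote_counts_as_carrier=False`.
* **Absent frequency means rare.** Novel alleles are precisely the most
  interesting candidates, so a variant missing from every frequency
  database passes the rarity filter.
* **dbSNP-common status and the low-quality probability are consumed as
  input columns**, not recomputed or fetched: this pins database versions
  and keeps the pipeline runnable offline. QC metrics without a standard
  VCF tag are accepted as `MQ`/`DP`/`LOWQ_PROB`/`REP_DISC` INFO keys or
  as a per-variant sidecar TSV.
* **Predictor labels** are mapped to damaging/not-damaging per source
  (e.g. MutationTaster `A`/`D`, MutationAssessor `H`/`M`); only the
  aggregate count of the nine sources is used downstream.

Because the QC, exclusion and rarity rules are pure per-variant
predicates, the kept set is their conjunction and is independent of
evaluation order; the suite asserts this, along with idempotence and
monotonicity in the thresholds.

## Compound-heterozygote scan

"More than one variant" is counted over distinct sites with genotype
exactly `AR`; homozygous-alternate sites do not count toward the pair
(they belong to the sharing filters). No phasing is attempted — the two
alternate alleles may sit on one parental haplotype — so all calls are
*potential* compound heterozygotes, and validation in an independent
sample set uses the same per-individual two-het-sites rule. Input
variants pass the same QC + rarity chain as the single-variant analysis.

## Simulator

The generator (`cleftshare.simulate`) emulates the statistical structure
the filters assume, not sequence-level realism:

* **Consanguinity is structural.** Marriage loops (first-cousin matings)
  are built into the pedigree, so excess homozygosity emerges from
  transmission rather than from an inbreeding-coefficient adjustment.
  The `first_cousin_pedigree` helper yields an offspring with F = 1/16,
  and the gene-dropped homozygosity rate is checked against the closed
  form F·q + (1−F)·q².
* **Gene-dropping.** Founder alleles are Bernoulli draws from the site
  frequency; each non-founder inherits one uniformly chosen allele per
  parent. An exhaustive Mendelian audit runs on every generated bundle.
* **Founder frequency spectrum.** Three classes per site: novel point
  mass (default 10% of sites at q = 0.002, absent from the annotation's
  frequency columns), a rare range U(0.001, 0.05) and a common range
  U(0.051, 0.5) (15% of sites, mostly flagged dbSNP-common) so the rarity
  filter has something to remove.
* **Planted risk variants** are written over zeroed columns and
  propagated up through ancestors to keep every transmission
  Mendelian-consistent; a designated non-carrier who turns out to be an
  obligate transmitter raises unless forced. Planted alleles are private
  to the designated family: their population frequency is zero, so
  controls and other families never carry them — matching the novel-
  allele semantics of the planted scenario. A heterogeneity slot leaves
  a designated member homozygous-reference, mirroring within-family
  heterogeneity.
* **Observation model.** Symmetric per-allele flip error (default 0.001)
  and completely-at-random missingness (default 0.005); duplicates are
  copied verbatim so replicate concordance holds by construction.
* **Presets** reproduce the study shapes: `wes` (52 families, 4 with
  three affected members, 108 affected, 4 duplicate subjects, 2 unrelated
  controls), `wgs` (32 families, 113 individuals, 107 affected, six
  individuals from two families tagged as present in both datasets) and
  `family1` (one looped family with eight affected members of
  first-cousin matings, with one planted recessive-shared variant and one
  planted compound-het pair). The per-population family-size compositions
  were solved to satisfy the published per-population totals and the
  global family-size list simultaneously.

What the simulator does **not** model: linkage disequilibrium and
haplotype structure, exome capture or coverage bias, population
stratification, de novo mutation, and non-random missingness. Passing
tests therefore demonstrate correctness of the counting logic and of the
pedigree transmission model under idealised noise — not robustness to
real-data artefacts such as batch effects or systematically miscalled
regions.

## Numerical and design choices

* All threshold comparisons are inclusive (`≥`) at the stated values —
  "at least" semantics — except the rarity ceiling and the low-quality
  probability, which are strict (`>`), and duplicate discordance (`> 1`).
* The carrier quota for family sizes other than eight uses exact integer
  ceiling arithmetic, never floating-point division.
* Region membership follows BED convention: 0-based half-open intervals,
  a 1-based position p inside [start, end) iff start < p ≤ end.
  Chromosome labels are normalised by stripping the `chr` prefix.
* Tie handling in the regulatory scan: all samples achieving the maximum
  heterozygous count are reported as a set.
* Degenerate inputs raise early: a population with zero cases, a family
  reduced to one sequenced affected member, a cyclic pedigree, an
  asymmetric duplicate pairing, an interval with end ≤ start.
* Reports are written in sorted order and fixtures flow from a single
  seeded generator, so identical inputs give byte-identical outputs.
* Problem sizes: bundled worked-example tables are desk-scale (≤ 19
  variants, ≤ 30 samples); simulated bundles default to 100–150 variants
  and ≤ 120 samples; the homozygosity calibration uses 10⁵ gene-dropping
  replicates and recovery checks 100 seeded replicates. The full suite
  runs in a few seconds on one CPU.

## Known limitations

* The pipeline consumes annotation as given; disagreements between
  annotation sources, transcript-dependent consequences and liftover
  between genome builds are out of scope (coordinates are treated as
  opaque).
* Sharing criteria are counting rules; they quantify neither
  identity-by-descent probability nor statistical significance of the
  observed sharing.
* The unphased compound-het caller cannot distinguish true compound
  heterozygotes from rare haplotypes carrying both alleles in cis.
* The simulator's genotyping error is symmetric and site-independent;
  real callers err asymmetrically (ref-biased) and locally.
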