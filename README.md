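# cleftshare

Family-based rare-variant sharing analysis for consanguineous multiplex
pedigrees.

`cleftshare` implements the filtering-and-counting strategy used to hunt
for rare, potentially damaging risk variants in families with several
affected relatives — the setting of nonsyndromic oral clefts (cleft lip
and/or palate) in highly consanguineous families, where recessive risk
alleles surface as runs of shared homozygosity among distantly related
affected individuals. It is aimed at statistical geneticists analysing
multi-sample WES/WGS call sets of multiplex families, and at anyone who
needs a tested, scriptable version of this class of sharing filters.

## The method

All filters act on biallelic variant records with per-sample genotypes
collapsed to `AA` (homozygous alternate), `AR` (heterozygous), `RR`
(homozygous reference) or missing. Writing $n_{AA}$, $n_{AR}$ for the
tallies over a set of affected individuals ("cases") of size $n$:

1. **Variant QC.** Drop a variant if mapping quality $< 30$, site depth
   $\notin [8,\,20{,}000]$, non-Y call rate $< 0.98$, genotype
   discordance in $> 1$ declared duplicate pair, a monomorphic genotype
   vector, or failure of **both** the VQSR filter and a low-quality
   classifier ($P(\text{low quality}) > 0.70$). Variants in
   frequent-hitter genes (and, per analysis, the extended MHC/HLA region)
   are excluded.
2. **Rarity.** Drop if reference-panel frequency $> 5\%$, if flagged as a
   dbSNP common variant, or if either unrelated control carries the
   alternate allele. An allele absent from every database is rare.
3. **Population sharing.** Keep a variant for a population iff
   $n_{AA} \ge 1$ and $(n_{AA} + n_{AR})/n \ge 0.20$.
4. **Family sharing.** Keep for a family iff $n_{AA} \ge 2$ among its
   sequenced affected members.
5. **Within-family genome discovery.** For a genome-sequenced family of
   $m$ affected members, keep iff $n_{AA} \ge 1$ and
   $n_{AA} + n_{AR} \ge \lceil 7m/8 \rceil$ (7-of-8 at the reference
   size), restricted to exonic, nonsynonymous variants.
6. **Compound heterozygotes (unphased).** A gene qualifies iff every
   index individual is heterozygous at $\ge 2$ of its rare, exonic,
   nonsynonymous sites; genes are validated in an independent genotype
   set by the same per-individual rule.

Pathogenicity is summarised as the number of predictor sources (of nine:
SIFT, PolyPhen-2 HDIV/HVAR, LRT, MutationTaster, MutationAssessor,
FATHMM, RadialSVM, LR) calling the variant damaging. A regulatory scan
tallies rare het/hom-alt calls inside enhancer/promoter BED intervals.

A gene-dropping simulator (`cleftshare.simulate`) generates complete
study bundles — consanguineous pedigrees with marriage loops, rare
founder alleles, planted recessive-shared or compound-het risk variants,
controls, duplicates, genotyping error and missingness — so every stage
is testable without external data.

## Worked example

The package bundles the published candidate-variant tables of a
multiplex oral-cleft study as worked-example data
(`cleftshare.examples`). Running the family analysis on the
reconstructed exome bundle:

```python
from cleftshare import examples as ex
from cleftshare.pipeline import run_family_analysis

variants, roster, annotations = ex.family_scan_bundle()
report = run_family_analysis(variants, roster, annotations)
print(len(report.rows), "passing variant-family rows")
print(report.rows[["scope", "gene", "AA", "AR", "RR",
                   "location", "freq_1000g", "n_damaging"]].head(6).to_string(index=False))
```

prints

```
19 passing variant-family rows
      scope     gene  AA  AR  RR   location  freq_1000g  n_damaging
Filipino-10 HLA-DPA2   2   0   0 intergenic      0.0130           0
 Filipino-8     TNK2   2   0   0     exonic      0.0004           4
  German-10     PALM   2   0   0     exonic      0.0018           0
  German-12    CHAC1   2   0   0     exonic      0.0008           1
  German-20    HMHA1   2   0   0     exonic         NaN           7
   German-7    MYO16   2   0   0     exonic      0.0058           0
```

i.e. 19 variants where at least two affected relatives of one family are
homozygous for a rare alternate allele (11 Syrian, 5 German, 1 Indian,
2 Filipino families). `AA/AR/RR` are genotype tallies over that family's
affected members; `n_damaging` counts the predictor sources calling the
variant damaging (`HMHA1`: 7 of 9); `NaN` frequency means the allele is
absent from the reference panel (novel).

The same bundles drive the genome-side analyses: the *CASP9* candidate is
carried by 7 of the 8 genome-sequenced members of the largest
consanguineous family (4 homozygous), discovery adds three *FAT4*
variants, and the unphased compound-het scan contributes *COL7A1*,
*CELSR3*, *TKT* and *NLRP14* — a combined family result set of 8 exonic,
nonsynonymous variants.

From a shell, the same pipeline runs over files:

```bash
cleftshare simulate --preset family1 --seed 3 --out-dir sim/
cleftshare family-scan --vcf sim/study.vcf --metadata sim/samples.tsv \
    --annotation sim/annotation.tsv --out-dir results/
```

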