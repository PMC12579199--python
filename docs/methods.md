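# Methods

This note documents the models, rules, parameters and design choices behind
`ptriage`, and what the synthetic cohort does and does not emulate.

## Conventions

All genomic positions are VCF-style 1-based; BED-like interval inputs are
converted on read. Variant identity is the canonical `contig-pos-ref-alt`
string after normalization: shared-suffix/prefix trimming plus
left-alignment against the reference (classic extend-left/truncate-right
algorithm), so that co-occurrence joins by identifier are well defined
regardless of how an indel was written. Multi-allelic records are
decomposed to one record per alternate allele on read. All printed
percentages and burdens round half away from zero to one decimal; this
single convention (in `variants.pct` / `round_half_away`) is used by every
summary operation.

Combined allele frequency pools exome and genome call sets,
AF = (AC_ex + AC_ge)/(AN_ex + AN_ge), falling back to the single available
call set; presence in the cohort requires a QC pass flag in either call set
and total AC ≥ 1. The pathogenic-allele burden divides the summed allele
counts of present P/LP variants by the number of individuals, so a
homozygote contributes two alleles.

## The rule engine

Only LOFTEE high-confidence pLoF variants (nonsense, frameshift, essential
splice) are curated; HC status is an input annotation, not recomputed.
Curation runs on the MANE Select transcript when the variant has a
consequence there, otherwise on the longest coding transcript among those
with consequences; the chosen transcript is recorded.

Rules, defaults, and what fires them (all thresholds in
`ptriage.config.Thresholds`, overridable from YAML):

| rule | fires when | strength |
|---|---|---|
| `nmd_escape` | stop/frameshift in the last coding exon or ≤ 50 coding bp from the penultimate exon's 3' junction, and < 25% of the CDS removed | strong rescue |
| `low_pext` | relative pext (exon mean / gene max) ≤ 0.2; (0.2, 0.5] → uncertain | weak rescue / uncertain |
| `mnv_rescue` | stop-gain SNV where *every* carrier carries a same-codon SNV whose joint codon is not a stop (strand-aware standard codon table) | strong rescue |
| `frame_restoring_indel` | frameshift where every carrier carries a second indel within 105 bp in the same exon, signed lengths summing to 0 mod 3, and no stop codon in the shifted frame between them | strong rescue |
| `splice_rescue` | first match of: (a) predicted loss (delta ≥ 0.2) abolishing an adjacent in-frame exon covering < 25% of the CDS; (b) gained site (delta ≥ 0.2) at an in-frame offset moving < 25% of the CDS; (c) both loss deltas < 0.2 | strong / strong / weak |
| `isoform_rescue` | variant exon present only in likely-non-coding isoforms; or an annotated in-frame downstream start in the first coding exon with < 25% removed; or an exon unique to a non-MANE overhang isoform | weak rescue |
| `somatic_ab` | median heterozygous-carrier allele balance < 0.25 (strict) | weak rescue |
| `homopolymer_artifact` | indel whose single-base unit matches an adjacent reference run of ≥ 6 identical bases | artifact/uncertain |

The 25%-protein-removed cut-off, the 0.2/0.5 pext fractions (an ~80% and
~50% expression reduction relative to the gene maximum), the 0.25 AB bound
and the 50 bp NMD window are the community's established values; the splice
delta threshold 0.2, homopolymer run 6 and the 105 bp pairing window are
conventional defaults surfaced in config. The penultimate-exon window and
the pext fractions are boundary-inclusive (with a 1e-9 float guard on the
pext division).

Aggregation: any strong rescue → **Not LoF**; else any weak rescue →
**Likely not LoF**; else any uncertain/artifact evidence → **Uncertain
LoF**; else **LoF**. *Likely LoF* is reserved for rule catalogs that map
specific rules to weaker strengths via the `DEFAULT_RULE_STRENGTHS`
configuration table; the default catalog never emits it. Outcomes:
Not/Likely-not LoF → *explained*; Uncertain → *uncertain*; LoF/Likely LoF →
*unexplained*. The explanation category is the firing rescue's label, or
`combination_of_explanations` when two or more distinct rescue categories
fired. When the MNV or frame-restore partner is present in only a subset of
carriers, the rule fires at *uncertain* strength rather than as a rescue —
mixed per-carrier evidence demotes the verdict to Uncertain LoF instead of
explaining the variant.

## Cis-rescue scan

Candidate P/LP variants: P/LP aggregate class, total AC ≤ 50, gene pLI
< 0.9 (LoF-tolerant, consistent with a gain-of-function disease mechanism)
and at least one reported autosomal-dominant condition. Carriers are
genotype-QC filtered (fail on depth < 10, GQ < 20, or het AB < 0.2;
boundaries pass — the sources state the thresholds as failure conditions,
so ≥ is our boundary decision). Modifiers are same-gene pLoF variants at
combined AF ≤ 1%. A candidate pair is *interesting* when (1) the
co-carrier fraction strictly exceeds 0.5, (2) the modifier is itself
curated as a genuine LoF (outcome *unexplained* — not rescued, somatic or
artifactual), and (3) the P/LP variant's reported mechanism is dominant
gain-of-function/dominant-negative (an input column; *unknown* fails the
criterion). Phase is `cis_confirmed` only when a phase-partner genotype
annotation links the pair in at least one carrier.

## Triage cascade

Input: curation-unexplained variants with their carriers. Stage 1 removes
carriers from the configured excluded project (cell-line-derived samples);
a variant is dropped only when no carriers remain — this carrier-level
semantics is required for variant and carrier counts to decrement
independently. Stage 2 drops variants with median carrier AB < 0.35
and/or in clonal-hematopoiesis genes, as a single OR stage (the two flags
are reported separately). The 0.35 bound is strict; ABs below 0.25 were
already consumed by the curation rule and below 0.20 by genotype QC.
Stage 3 drops variants with no consequence on a MANE Select transcript.
Samples without an age are excluded from the age tests but not from the
filters.

### Wilcoxon rank-sum test

The statistic is the rank sum of the first group with midranks for ties.
When the smaller group has ≤ 8 observations and there are no ties the
two-sided p-value is exact, by enumeration of all C(n, n_small) rank
assignments (two-sided extremeness = distance of the rank sum from its
null mean). Otherwise a normal approximation is used with tie-corrected
variance n₁n₂/12 · (N + 1 − Σ(t³ − t)/(N(N − 1))) and a 0.5 continuity
correction. Exhaustive comparison over the n=8 vs 8 tie-free support shows
the approximation within 10% relative error wherever exact p ≥ 0.04 and
conservative (approx ≥ exact) in the extreme tail — an intrinsic property
of normal approximations at the support edge, documented rather than
hidden. Type-I error at α = 0.05 is calibrated by simulation in the test
suite (2,000 null replicates, rejection rate required within [0.03, 0.07]).

## sQTL association

Per (exon, variant) pair within a 1 Mb cis window and with ≥ 10 informative
samples, association between PSI and dosage is Spearman rank correlation —
PSI is bounded and ranks make the test invariant to monotone
transformation; a linear-on-ranks alternative would be equivalent up to the
test statistic. Constant PSI or dosage vectors are skipped. p-values are
Benjamini–Hochberg adjusted **pooled across all tested pairs in the run**
(the pooling unit was an open choice; per-gene pooling would be more
conservative at scale but is indistinguishable at desk scale), with hits at
q < 0.05. Flagging reports, per pLoF variant inside a hit exon, the sQTL
variant, its q-value, each carrier's genotype at the sQTL variant, and
whether the exon's relative pext is ≤ 0.5 (pext-concordant alternative
splicing).

## Synthetic cohort

The generator emulates the study conditions at desk scale: 500
genome-sequenced samples (configurable), five genetic ancestry groups
(55/15/12/10/8% nfe/afr/eas/amr/sas), 5% of samples in a cell-line-derived
project, ages Normal(55, 12) truncated to [18, 95]. A virtual exome
stratum (AN = 200,000, AC 0 for planted variants) mirrors a cohort whose
exome arm dwarfs its genome arm, keeping combined allele frequencies in
the rare range — in particular it lets the 35-carrier cis haplotype stay
under the 1% modifier-AF cap, as it does at real cohort scale.

Each planted scenario gets its own gene on its own ~12 kb contig; a
five-exon template (CDS segment lengths 120/300/201/300/279) is filled
with random non-stop codons (ATG…TAA), homopolymer runs capped at 4 except
where planted. Planted conditions include: stop-gains in the last exon and
the penultimate-exon tail (one on the minus strand); low-pext exons at
relative 0.15 (rescue) and 0.40 (uncertain — the deliberately
boundary-adjacent plant); a CGA-codon MNV pair; a −1/+1 indel pair 30 bp
apart with a regenerated stop-free shifted frame; three splice scenarios
(in-frame 201 bp exon skip, in-frame alternative site where the adjacent
exon is exactly 25% of the CDS so only the gained site rescues, and a
no-loss annotation); a 7-base A-run frameshift artifact; an exon unique to
a likely-non-coding isoform; genuine unexplained LoF plants; a
project-restricted cluster; two clonal-hematopoiesis genes whose 5+5
carriers have AB drawn in (0.25, 0.35) and ages shifted +15 years; the
35-carrier (34:1 ancestry split) missense+nonsense cis haplotype with one
phase-annotated carrier; and one sQTL gene where exon-3 PSI responds to a
non-coding variant (AF 0.3, effect −0.25 PSI per allele, noise SD 0.04)
with the planted pLoF carried by sQTL heterozygotes. Germline carrier
genotypes draw DP ~ Poisson(30) floored at 10 with het AB confined to
[0.4, 0.6]; planted pLoF allele counts stay ≤ 5 except the cis haplotype.
Every planted variant has a truth-table row (variant, scenario, expected
verdict/category/outcome); non-pLoF plants carry `NA` expectations.

Identical (config, seed) pairs produce byte-identical files; the recovery
test requires 100% agreement between pipeline outcomes and the truth table,
verified across 25 seeds during development.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: read-level error models (no BAMs; depth and AB
are the only genotype-quality signals), joint-calling and sample-QC
artifacts, realistic linkage disequilibrium and site-frequency spectra,
overlapping genes and complex transcript structures, population
stratification beyond discrete ancestry labels, and the long tail of rare
annotation errors that motivates manual curation. Recovery on this cohort
demonstrates that the rules implement their definitions, not that the
definitions capture every real-world evasion.

## Numerical and scale choices

Problem sizes were chosen so the full suite runs in minutes on one CPU:
the default cohort is 500 samples / ~21 genes with ~46 variants; the
Wilcoxon calibration uses 2,000 replicates of n = 200 vs 200; the sQTL
null calibration 500 replicates of ~100 pairs at n = 30; the age-dominance
property is tested directly against the age-sampling routine over 200
seeds (the property concerns the age model, and regenerating full cohorts
adds nothing but runtime). Ties in rank tests use midranks; degenerate
inputs (empty groups, zero AN, constant vectors, missing annotations) are
either errors or explicit "no data" rule results, never silent defaults.

## Known limitations

The engine is deterministic and rule-driven; free-text curator reasoning,
conservation scoring of alternate open reading frames (consumed as an
input flag), VEP/LOFTEE/SpliceAI internals, pext derivation and read-backed
phasing are out of scope by design. The AC-bin histogram treats allele
count as a proxy for individual counts, valid for rare, mostly-heterozygous
variants. The frame-restore pairing logic assumes indel CDS offsets are
anchored in transcript orientation; exotic multi-indel haplotypes (three or
more interacting indels) are not searched.
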