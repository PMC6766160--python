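# Methods

## Scope and model

The package implements a two-stage design for recessive,
incompletely penetrant disease variants. Stage one screens a small
sequenced discovery panel (default 4 affected cases, 2 unaffected
controls) for variants whose genotype pattern is compatible with
recessive inheritance, at three levels of stringency; stage two tests
the prioritized variants in a large genotyped case/control cohort with
an uncorrected Pearson chi-squared on the recessive 2×2 contingency
table. The design assumes a biallelic, autosomal locus inside a known
associated region, diploid genotypes, and a single causal variant per
locus; it makes no attempt to model X-linkage, de novo variation, or
polygenic architecture.

## Genotype and coordinate conventions

Genotypes are classified as homozygous-reference, heterozygous,
homozygous-alternate, or missing; any no-call allele makes the whole
genotype missing. Phase is ignored. Coordinates are 1-based with
closed intervals, matching VCF `POS`. Multiallelic VCF records are
split into biallelic records (each sample classified against one
alternate allele at a time, other alternates counting as reference);
the pre-split allele count is retained so the artifact screen can
still reject sites where more than two alleles segregate. Alleles are
normalized by trimming shared flanking bases (trailing first, then
leading, advancing the position); full left-alignment is not performed
because the indels in scope are simple insertions.

## Concordance filters

For each variant the panel is tallied into six counts (cases/controls
× hom-alt / other-called / missing). The three presets are:

* **filter1** — every case homozygous-alternate (at least one), no
  control homozygous-alternate;
* **filter2** — every case homozygous-alternate, at most one control
  homozygous-alternate (tolerating one non-penetrant control);
* **filter3** — at least one case homozygous-alternate and at least
  one control carrying a reference allele (heterozygous controls
  qualify, by the literal "carries a reference allele" reading).

Two genuinely open points were resolved as follows. Missing panel
genotypes: under the default `strict` policy a missing genotype in any
constrained class disqualifies the variant (perfect concordance cannot
be asserted from an uncalled sample); a `permissive` policy that
evaluates conditions over called samples only is available. The
filter1 control condition requires controls to be non-homozygous-
alternate rather than strictly homozygous-reference, consistent with a
recessive model in which carriers are unaffected; the stricter
alternative is expressible through a custom `FilterSpec`.

## Prioritization cascade

Filter-1 hits are always prioritized. From filter 2, non-synonymous
HIGH/MODERATE/LOW variants are kept regardless of caller provenance
(a real single-caller missense can still be a valid candidate), while
MODIFIER-class variants must be dual-caller and inside the strict core
region. From filter 3, only dual-caller MODERATE/LOW non-synonymous
variants are added. A variant reachable by several routes keeps the
highest-priority tag (filter1 > filter2 > filter3), so downstream
counts per filter are disjoint. Synonymous variants are excluded
wherever a functional impact is required.

## Artifact screen

Manual alignment inspection is replaced by three parameterized rules:
more than `max_alleles` (default 2) observed alleles at the locus;
site depth above `depth_ratio_max` (default 3.0) times the local
median depth (repetitive-region signature); mapping-quality-zero read
fraction above `mq0_max` (default 0.2, multi-mapping signature). The
defaults are deliberate order-of-magnitude choices — the screen's
purpose is reproducibility and auditability, and all three thresholds
are exposed in the run configuration. The local median depth is
computed over the in-region merged callset.

## Callset merging

Records are matched across callers on the normalized
(chrom, pos, ref, alt) key. Matched records carry both caller labels
and keep the first callset's genotypes; a genotype disagreement in
more than half the shared samples is logged but not reconciled,
because discovery genotypes only feed the concordance filters and the
cohort stage runs on independently assayed genotypes.

## Association statistics

* **Chi-squared:** Pearson, 1 df, **no continuity correction**, upper
  tail. The uncorrected statistic is the convention of standard SNP
  association suites for recessive-coded 2×2 tables; degenerate tables
  (a zero margin) are an error at the statistics layer and are skipped
  with an audit entry by the pipeline.
* **Fisher's exact:** two-sided by the probability-mass method (sum of
  all tables with the observed margins no more probable than the
  observed one, with ~1e-7 relative tie tolerance), delegated to
  scipy; the test suite checks it against full margin enumeration.
* ***t*-test:** pooled-variance Student form with df = n1+n2−2, the
  classical unpaired t-test; Welch is available directly via scipy for
  users who prefer it.
* **QC:** call rate = called/total; MAF over called genotypes only;
  failures are strict inequalities (a variant at exactly the threshold
  passes). "Insufficient cardinality" means fewer than two distinct
  called genotype classes — logged separately from low MAF because the
  two failure modes have different remedies.
* **Risk-allele orientation:** default is the allele whose homozygote
  class shows the larger case-vs-control excess; overridable per
  variant.
* Ranking is by ascending p with (chrom, pos) tie-breaks. No
  multiple-testing correction is applied; raw p-values are reported.

## Synthetic data generator

The simulator generates the statistical structure the pipeline
assumes, not sequence reads. Per variant, genotypes are Binomial(2, p)
draws (exact Hardy-Weinberg proportions); variants within
`ld_block_length` (default 100 kb) of the planted risk variant copy
its genotype with probability exp(−4d / ld_block_length), an
exponential-decay stand-in for haplotype structure that creates
realistic tagging variants without coalescent machinery. Phenotype
follows the recessive penetrance model (defaults: penetrance 0.85 for
homozygous-risk, phenocopy rate 0.10), and individuals are drawn until
the case pool (56) and control pool (62) fill, mimicking case/control
ascertainment; the default genotyped panel is 57 variants over a
~2.5 Mb region with a 483 kb strict core. Ages are normal draws per
genotype class (homozygous-risk cases 10.13 ± 5.37 years, other cases
13.14 ± 6.39), truncated at zero, with controls floored at 13 years to
honor the minimum-age inclusion criterion for controls; castration
status among males is gelding-enriched in cases (0.96 vs 0.71).

Because the discovery-panel scenario deliberately includes discordant
individuals (it mirrors a study design that selected its most
informative animals, including a known unaffected homozygous-risk
individual), the sampler by default keeps drawing (within a bounded
budget) until all four panel genotype classes exist in the cohort,
swapping surplus members out. This is a property of the emulated study
population, not of random sampling; it can be disabled with
`ensure_panel_classes=False`.

Caller emission: caller A reports every true variant, caller B each
with probability 0.8; both gain unique false positives at rate 0.05.
The planted variant is written as a clean dual-caller moderate
missense call — it represents a well-supported coding variant both
callers agree on. Artifact sites (default 3, one of them triallelic)
get 5× depth and 0.5 MQ0 fraction with perfectly concordant
genotypes, so they reach the candidate list and must be caught by the
screen. Panel VCF genotypes are the latent truth without missingness
(sequencing-grade calls on six animals), while cohort genotypes carry
2% random missingness (array-style assay noise).

**What the simulator does not model:** read-level error, linkage
beyond the single exponential-decay block, population structure and
relatedness, genotyping error correlated with probe chemistry, and
caller-specific error profiles. Passing end-to-end tests therefore
demonstrates the pipeline's logic and statistical behavior under its
stated assumptions, not robustness to the full error structure of real
sequencing data.

## Numerical and testing choices

Every stochastic path flows from one integer seed through
`numpy.random.default_rng`; identical seeds reproduce cohorts, panels
and emitted VCFs byte for byte. The test suite validates the filters
against exhaustive truth tables over all 3⁶ complete genotype patterns
of the 4+2 panel, Fisher's test against full margin enumeration, and
the chi-squared p-value against a 10⁶-draw Monte-Carlo permutation
null. For the latter, the asymptotic p is required to lie between
P(T > t) and P(T ≥ t) of the discrete null distribution, give or take
four binomial standard errors — a point comparison to pure Monte-Carlo
error would be ill-posed because the observed statistic carries an
atom of null probability mass. Replicated power checks use 100
simulations at the default cohort size (56/62); the suite runs in
well under a minute on one CPU.

## Known limitations

Assembly liftover, annotation generation, and read processing are out
of scope; the pipeline consumes annotated VCFs. The cascade's per-tag
counts reflect whatever input callsets are given — reproducing a
specific study's variant counts requires that study's sequencing data.
The recessive table collapses carriers with homozygous-reference
individuals; additive or dominant codings are not fitted.
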