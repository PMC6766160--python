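# varprio

Case/control genotype-concordance variant prioritization and
recessive-model association testing, built for small-panel resequencing
studies of recessive, incompletely penetrant diseases — the motivating
application is ocular squamous cell carcinoma (SCC) in Haflinger
horses, where a missense variant in *DDB2* on chromosome 12 acts as a
recessive risk factor with incomplete penetrance.

## Who this is for

Groups that sequence a handful of affected and unaffected individuals
from a mapped disease locus, call variants with two independent
callers, and need to narrow thousands of candidate variants to a short
list worth genotyping in a large cohort — then test that cohort under a
recessive model. The package also ships a deterministic simulator that
generates the whole study (cohort, discovery panel, caller VCFs) with
known ground truth, so every stage can be validated end to end.

## The method

**Concordance filters.** For a panel of `n` affected cases and `m`
unaffected controls, each biallelic variant's genotype pattern is
tallied and tested against three nested criteria:

| filter | cases | controls |
|---|---|---|
| `filter1` | all homozygous-alternate | none homozygous-alternate |
| `filter2` | all homozygous-alternate | ≤ 1 homozygous-alternate |
| `filter3` | ≥ 1 homozygous-alternate | ≥ 1 carrying a reference allele |

`filter1` demands perfect concordance under a recessive model;
`filter2` tolerates one non-penetrant control; `filter3` additionally
tolerates phenocopy cases. With complete genotypes,
filter1 ⊆ filter2 ⊆ filter3.

**Prioritization cascade.** Filter-1 hits are always kept. From filter
2, functional variants (HIGH/MODERATE/LOW impact, non-synonymous) are
kept regardless of caller provenance, and MODIFIER variants only when
called by both callers inside the strictly associated core region.
From filter 3, only dual-caller MODERATE/LOW non-synonymous variants
are added. An automated artifact screen then drops sites with more
than two observed alleles, depth above 3× the local median, or a
mapping-quality-zero read fraction above 0.2.

**Association.** In the genotyped cohort, variants failing QC (call
rate < 90%, minor allele frequency < 0.05, fewer than two genotype
classes) are excluded; the rest are tested with an uncorrected Pearson
chi-squared on the recessive 2×2 table

|  | carrier or ref | homozygous risk |
|---|---|---|
| affected | a | b |
| unaffected | c | d |

and ranked by p. Supporting statistics: two-sided Fisher's exact tests
(probability-mass convention), a pooled two-sample *t*-test, and the
standard error of the mean.

## Worked example

```sh
varprio simulate  --seed 3 --out-dir demo
varprio prioritize --callset-a demo/caller_a.vcf --callset-b demo/caller_b.vcf \
                   --panel demo/panel.tsv --out-dir demo
varprio associate --cohort demo/cohort.tsv --out-dir demo
varprio report    --out-dir demo
```

prints (abridged):

```
wrote cohort (118 samples, 57 variants), panel (6 samples), callsets caller_a.vcf / caller_b.vcf to demo
filter1 kept 3 of 66 variants
filter3 kept 18 of 66 variants
2 candidate variants (64 exclusions logged) -> demo/candidates.tsv
52 variants tested; top hit 12:11500000:C>T p=2.65e-19 (-log10 p = 18.58) -> demo/association.tsv
report with 2 prioritized variants (2 association-tested) -> demo/report.tsv
```

What happened: the simulator planted a recessive risk variant at
12:11500000 with penetrance 0.85 and a 0.10 phenocopy rate, and chose a
deliberately discordant discovery panel (two homozygous-risk cases, two
phenocopy cases, one homozygous-reference control, one unaffected
homozygous-risk control). The three variants passing `filter1` are
planted alignment artifacts with perfectly concordant genotypes — the
artifact screen removes them. The risk variant itself fails the strict
filters (by design of the panel), survives `filter3` as a dual-caller
missense candidate, and in the 118-animal cohort it is the
top-ranked association (p = 2.6 × 10⁻¹⁹; its table is 46/9 homozygous
risk among cases vs 1/60 among controls). The run also reproduces the
expected discordance: one control carries the risk genotype.

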