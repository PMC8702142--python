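# Methods

`forcekin` implements the computational workflow around a forensic
all-in-one SNP capture panel: designing a linkage-aware kinship marker set,
simulating pedigree genotypes and sequencing observations, calling
genotypes from coverage and allele counts, computing likelihood-ratio (LR)
kinship statistics on linked markers, and making ancestry, Y-haplogroup and
phenotype-encoding predictions. This note records the models, the defaults
and why they were chosen, and what the synthetic data do and do not show.

## Pedigree likelihood on linked markers

The central quantity is the likelihood of observed biallelic genotypes for
the typed members of a pedigree, with genetic linkage between markers fully
modeled. We use the inheritance-vector formulation: each of the `m`
modeled meioses contributes one bit recording whether the grandpaternal or
grandmaternal allele was transmitted, and the vector of all bits evolves
along a chromosome as a hidden Markov chain. Between adjacent markers each
bit flips independently with the recombination fraction

    theta = (1 - exp(-2 d / 100)) / 2       (d in cM)

— Haldane's map function, i.e. crossovers occur as a Poisson process with
no interference. This matches the assumption of standard multipoint
linkage engines; nothing in the pipeline depends on interference.

At a marker, the emission probability of the observed genotypes given the
inheritance vector is obtained by summing over founder-allele assignments.
Two structural facts make this fast:

* free founder alleles (never inherited by a typed individual under the
  current vector) marginalize to 1 and can be ignored;
* because markers are biallelic and founder alleles are exchangeable draws
  from a single population frequency, the emission depends on the vector
  only through the *partition* of the typed individuals' founder-allele
  slots into identity classes, and the weight of an allele assignment
  depends only on how many classes carry the alternate allele.

The 2^m states are therefore grouped once per analysis into a handful of
partition classes, and emissions are evaluated per class and per marker in
vectorized form. The forward pass costs O(m 2^m) per marker interval
(per-bit conditional updates); chromosomes combine additively in log space
and running rescaling prevents underflow. Likelihoods for a *batch* of
genotype observation sets sharing a pedigree and marker map are computed in
one pass with a leading batch axis; batched passes switch to single
precision (the per-marker rescaling keeps values near 1, and the resulting
log10-LR error is ~1e-5, far below any decision threshold), while single
evaluations stay in double precision.

Pedigrees requiring more than 18 meioses are rejected with an explanatory
error. The cap of 18 (2^18 = 262,144 states, still a few seconds per
likelihood) was chosen so that the largest reference constellation in the
bundled casework fixtures — a missing person typed against a first cousin
twice removed, a nephew and a daughter — runs in pedigree mode.

Mendelian conflicts are strict by default: a marker whose observed
genotypes are impossible under every inheritance vector zeroes the
likelihood (LR = 0). An optional per-genotype error rate `e` mixes each
individual's emission with a uniform genotype error, `(1-e)·match + e/3`
(diploid; `e/2` hemizygous), which absorbs isolated conflicts instead of
modeling them. The study that motivated this package excluded
conflict-ridden degraded samples rather than modeling genotyping error, so
`e = 0` is the default.

Allele frequencies are clamped to [1e-4, 1-1e-4] before likelihoods so a
private allele never makes a founder assignment impossible. Co-located
markers (identical cM position) are perturbed by 1e-6 cM with a warning so
inter-marker gaps are strictly positive.

### X-chromosomal mode

Males are hemizygous: a male founder carries one X slot, a male non-founder
inherits his single X from his mother's pair (one meiosis bit), and a
father transmits his single X to daughters deterministically (no bit). The
same partition/class machinery applies with per-individual ploidies; sons
receive no paternal X. Hypothesis H2 for hemizygous individuals is the
allele frequency itself rather than a diploid HWE probability.

### Relationship hypotheses

Pairwise tests cover parent/offspring, full siblings, half siblings, first
cousins, first cousins once removed, second cousins and second cousins once
removed (degrees 1-6), each expressed as a template pedigree linking the
two typed individuals through untyped intermediates. The second-degree
template is half siblings (sharing an untyped mother). The standard
unlinked IBD coefficients (kappa0, kappa1, kappa2) for these relationships
are carried alongside: they power a fast unlinked mode and serve as an
independent closed-form cross-check of the multipoint engine in the test
suite — with every marker on its own chromosome the two routes must agree
to 1e-9.

LRs always compare H1 (the related hypothesis, or "the unknown is the
missing person of this pedigree") against H2 (unrelated; for the
missing-person form, `L(pedigree with slot untyped) * L(unknown alone under
HWE)`). Posteriors assume a flat prior over the tested hypothesis set; the
default pairwise report is the two-hypothesis pair, `LR / (1 + LR)`. A
result has *strong statistical support* when log10 LR >= 4 and the
posterior >= 99.99%. Blind search evaluates all hypotheses up to a chosen
degree for every pair and applies the same joint criterion, with the
posterior normalized over the tested set plus unrelated — which is why
false positives are rare even at sixth degree: an unrelated pair may reach
a moderately positive LR under one distant hypothesis, but rarely both a
four-orders-of-magnitude LR and near-total posterior mass.

## Panel design cascade

Kinship-SNP selection applies, in the printed order: intersection across
chip manifests; an allele-frequency window of [0.2, 0.8] in each of the
five continental populations (AFR, AMR, EAS, EUR, SAS); greedy
left-to-right thinning to >= 0.5 cM spacing; LD pruning; a strict < 0.35
cap on the maximum between-population frequency difference; and a
clinical-region exclusion list. Choices made where the source material was
ambiguous:

* "MAF 0.2-0.8" is read as the designated (alt) allele frequency lying in
  the closed interval [0.2, 0.8] — a folded MAF cannot exceed 0.5, and the
  chip-annotation convention reports the designated allele. A `freq_mode`
  switch selects the folded reading instead.
* Thinning keeps a boundary gap of exactly 0.5 cM ("at least"); co-located
  candidates are ranked so the one with mean folded MAF closest to 0.5
  wins. Genetic positions absent from the manifest are linearly
  interpolated from the map; SNPs outside the anchor range are excluded.
* LD r^2 is the squared Pearson correlation of genotype dosages (composite
  LD, no phasing needed) within a 10 cM window; when a pair reaches
  r^2 >= 0.1 the later SNP is removed. The reference panel and window of
  the original design are not stated; these defaults are recorded in
  `DesignParams` and auditable.
* The clinical exclusion takes a user-supplied BED blocklist; no gene list
  is bundled.

Every filter is idempotent, and attrition counts are non-increasing by
construction; both properties are asserted in tests.

## Genotype calling

A site needs >= 10 reads. With minor-read fraction `m` over the top two
observed alleles: `m <= 0.10` calls a homozygote, `m >= 0.30` calls a
heterozygote (diploid sites), and `0.10 < m < 0.30` is "imbalanced" —
excluded from every downstream analysis. Boundary ties resolve toward the
call ("90% or greater", "at least 30%"). Hemizygous sites (Y; male X) are
called under the homozygote rule only; a hemizygous site with `m >= 0.10`
is imbalanced, since heterozygosity is impossible. Reads beyond the top
two alleles count toward coverage but never the genotype (the panel
excludes triallelic sites). An imbalanced site whose minor allele carries
the low-quality flag is *noted* as a homozygote for concordance accounting
only; its status never changes.

Read-level base quality and strand balance are abstracted into a boolean
low-quality-minor flag on the observation record, because the pipeline
starts from per-site allele counts, not reads.

Profile completeness uses a sex-adjusted denominator: males can call every
panel site; females cannot call Y-SNPs. Sex may be declared (casework
metadata) or inferred — male iff >= 50 Y-SNP sites reach 10x coverage.
Inference is reliable for reference-quality data but not for degraded
samples, which is why the fixtures record the known sex of the casework
remains.

## Synthetic data

The generators replace non-distributable casework inputs.

* **Population frequencies.** Balding-Nichols: per SNP an ancestral
  frequency `p ~ Uniform(0.05, 0.95)`, then each population draws from
  `Beta(p(1-F)/F, (1-p)(1-F)/F)`. Default `F = 0.1` for most categories;
  ancestry-informative SNPs use `F = 0.35` so the five continental groups
  separate clearly, as the curated aiSNP sets do.
* **Pedigree genotypes.** Gene dropping: founder haplotypes are iid
  Bernoulli(freq) draws — Hardy-Weinberg and linkage equilibrium, the
  right regime for an LD-pruned panel — and each meiosis transmits a
  recombinant haplotype with Haldane switch probabilities. Y sites copy
  down patrilines without mutation; X follows the hemizygous rules above.
* **Sequencing observations.** Coverage is negative binomial
  (mean, dispersion) with per-site dropout; each read reports an allele
  drawn uniformly from the genotype and flips to the other panel allele
  with probability epsilon. Presets: reference quality (mean 225x,
  dispersion 5, epsilon 0.005, dropout 0.005) matching the ~225x average
  and ~99% completeness of reference samples, and degraded bone (mean 8x,
  dispersion 1, epsilon 0.01, dropout 0.3) matching the ~44% average
  completeness of bone extracts. The fixture gives the first extract of
  each case a 4x better preset, mirroring the wide between-extract quality
  range seen in practice. The low-quality-minor flag is set (with
  probability 0.9) when a truly homozygous site shows error-derived minor
  reads — a stand-in for the base-quality/strand review the pipeline
  cannot perform without reads.

What the synthetic data do *not* emulate: reference-bias or deamination
error profiles of ancient DNA, contamination and mixtures, linkage
disequilibrium between panel SNPs, mutation (including Y), and real
continental allele-frequency spectra. Tests passing on these data show the
*inference machinery* is correct under its own model; they do not validate
the laboratory performance claims of the assay.

## Simulation studies

`run_scenario` simulates, per replicate, the scenario's template pedigree
(related arm) or two independent individuals (unrelated arm), then the
pairwise LR for the scenario's hypothesis versus unrelated. Partial-panel
fractions (1.0 / 0.75 / 0.25) are realized by masking an independent
random marker subset per replicate — equivalent to subsampling, because a
missing marker emits no information while linkage correctly spans the gap.
Replicates are batched through the engine. The default replicate count is
500 at desk scale; the original study's 10,000 is a parameter, not a
different code path. The acceptance-grade reruns in this repository use
200 replicates per arm on the full-scale synthetic kinship set (3,931
markers), which reproduces the qualitative results: complete separation of
half-sibling and first-cousin scenarios at log10 LR >= 4, and overlapping
arms for second cousins.

## Predictions

* **Ancestry (naive Bayes).** Per population, the log-likelihood sums log
  HWE genotype probabilities over called aiSNPs (frequencies clamped at
  1e-4); posteriors are flat-prior normalized. No admixture model — the
  per-population likelihood is exactly what it claims to be.
* **Ancestry (PCA).** Axes are trained on a labelled reference genotype
  matrix only (columns centred/scaled by reference statistics, missing
  values mean-imputed); queries are projected, never refit, and must share
  at least half of the matrix markers.
* **Y haplogroup.** Derived calls mark haplogroups on a single-rooted
  tree; the reported haplogroup maximizes on-path derived support minus
  off-path derived calls, ties toward the shallower node. This scoring
  automates what is otherwise a manual review; off-path derived calls are
  reported as conflicts and on-path ancestral calls as possible
  back-mutations so a reviewer can still inspect them.
* **Phenotype.** Only strand-normalized effect-allele dosage encoding
  (0/1/2/NA) and batch-file export are implemented; the prediction model
  itself is an external webtool and out of scope.

## Problem sizes and tolerances in the test suite

Oracle equivalences run on <= 3 markers across all seven relationship
templates at 1e-9 relative tolerance against an independent brute-force
enumerator (explicit state enumeration, popcount closed-form transitions,
direct founder-allele sums). Distributional checks use fixed seeds:
2,000 meioses for the Poisson recombination test, 2,000 unrelated pairs at
50 markers for E[LR] = 1, 200 replicates per arm for the LR-distribution
study, 200 unrelated pairs for the blind-search false-positive screen, and
200 replicates at 246 X-SNPs for sibling X-LR positivity. The end-to-end
fixture runs at roughly 10% of assay scale so the whole suite completes in
minutes; full-scale runs use the same code paths.

## Known limitations

* No mutation model (a true parent-offspring pair with a genotyping error
  at one marker gives LR = 0 under strict mode; use the error rate option).
* No inbred or looped pedigrees; no founder-couple symmetry reduction, so
  the meiosis cap binds earlier than in heavily optimized linkage engines.
* The unlinked kappa mode is exact only for unlinked markers; it is
  provided for cross-checks and quick screens, not casework.
* Sex inference from Y coverage fails for degraded male samples; declare
  sex when it is known.
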