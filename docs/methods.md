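# Methods

## The screen model

The package models a sensitized dominant suppressor screen. A G1 mouse of
the lethal genotype survives ("rescue") iff it carries a potentially
deleterious variant in a suppressor gene *and* that gene's penetrance
Bernoulli succeeds, *or* a background phenocopy Bernoulli succeeds.
Penetrance defaults to 0.33 per suppressor gene (the level observed for
known coagulation-balance suppressors) and the phenocopy rate to 0.02 (the
background survival rate of the lethal genotype). Both are per-cohort
configuration, not estimates made by the package.

Two cohort generators are provided: `simulate_screen` labels an unselected
set of G1 genomes (useful for null calibration), and
`simulate_rescue_cohort` keeps drawing G1 mice until the requested number of
rescues is collected — the ascertainment of a sequenced screen cohort, under
which suppressor genes are enriched in proportion to penetrance and diluted
by phenocopies.

## Synthetic cohort generator

Per G1 genome the ENU variant count is Poisson(λ), λ = 65 exonic variants
by default. Each variant lands in a gene with probability proportional to
its coding length, receives a consequence class and (for SNVs) a
strand-collapsed substitution class from the spectrum configuration, a
genomic position uniform in the gene interval (globally unique, so
single-carrier variants never collide into spurious shared calls), and a
carrier read depth. Males draw their ENU variants from the autosomal
universe only: the mutagenized parent is the sire and males inherit their
single X from the dam, which is what produces the large female excess of
X-linked mutations.

Spectrum defaults: the three published substitution fractions are fixed
(T/A→C/G 0.47, T/A→A/T 0.24, C/G→G/C 0.008); the remaining 0.282 is split
T/A→G/C 0.10, C/G→T/A 0.13, C/G→A/T 0.052. These three are free choices
(the source material reports the remainder only graphically) and are
configurable. Consequence classes default to nonsynonymous 0.47, UTR 0.31,
synonymous 0.15, splice 0.02, stopgain 0.015, stoploss 0.005, INDEL 0.03,
which puts the deleterious fraction at 0.535, near the observed ~51% of
candidates called potentially harmful.

Depth model: a carrier's DP is Poisson(77) with probability 0.96 and
Uniform{0..5} with probability 0.04, mirroring "96% of the capture covered
at ≥ 6 reads" while guaranteeing the 6X filter is exercised. A direct
consequence: the expected post-filter candidate rate is 0.96 · λ ≈ 62.4 per
mouse, a few percent below λ.

Other cohort features: de novo mutations arise at 5.4×10⁻⁹ per bp per
transmitted genome over the annotated intervals, with substitution class
uniform (the spontaneous spectrum is not ENU-skewed) and, on the Tfpi
chromosome, a recorded phase relative to the Tfpi-null allele, enabling the
maternally inherited suppressor scenario. Artifact calls (strain variants,
systematic miscalls) are injected at a Poisson cohort rate (default 175)
with 2 + Poisson(1) carriers each, some intergenic. Sibships can be
generated from a shared spermatogonial stem-cell mutation pool (expected
pool size 2λ, each sib inheriting each pool variant with probability 1/2,
hence ~50% pairwise sharing) or as independent genomes.

Gene annotation is synthetic: CDS lengths log-normal (μ = 7.1, σ = 0.8 on
the log scale; median ≈ 1.2 kb, ≈ 35 Mb total over 20,586 genes, the scale
of the mouse coding exome), one optional Ttn-like giant gene at 10⁵ bp to
represent extreme multi-hit targets, genes laid out non-overlapping on 19
autosomes plus X (X holding ~4% of genes).

Randomness: one master seed feeds a `SeedSequence`; the cohort and artifact
stages receive independent spawned streams and every mouse its own child
substream, so enlarging a cohort leaves earlier mice bit-identical and
fixed seeds give byte-identical output files.

### What the generator does not emulate

Read-level errors, alignment and calling artifacts correlated with sequence
context, capture-efficiency variation between genes, the chromatin/sequence
preferences of ENU lesions, linkage between ENU variants on one chromosome
(variants are placed independently), and litter/survival structure. Passing
tests therefore certify the statistical machinery under the stated
generative model, not the behaviour of any particular caller on real reads.

## Candidate filter

The filter retains calls that are (a) non-reference in exactly one mouse
(missing genotypes do not count as presence), (b) heterozygous in that
mouse, and (c) covered by ≥ 6 reads in the carrier (the carrier's DP, not
site depth — per-sample filter semantics). Removal reasons partition the
removed set (`shared`, `not_het`, `low_depth`), with the shared rule applied
first; the retained set is order-independent. The filter is deliberately
blind to variant origin: a de novo variant transmitted to several siblings
is removed as "shared", reproducing the known false-negative mode of
uniqueness filtering.

Deleterious classes are missense/nonsynonymous, nonsense/stopgain,
splice-altering, and out-of-frame INDELs. Stoploss is excluded by default —
the operative deleterious list in the source methods omits it even though
the narrative mentions stoploss variants — and a flag flips it.

The stem-cell origin test uses sharing fraction = shared variants divided by
the smaller sibling's candidate count (the denominator is not defined in the
source; the smaller count is the conservative choice), with "plausible"
requiring strictly more than 10% sharing.

## Burden test

p_g = L_g / ΣL over the *full* annotated universe. Each permutation is one
M-trial multinomial draw (distributionally identical to placing variants
one at a time, far faster). Since genes with k = 0 have p = 1 by
construction, the draw is taken over the observed genes plus one lumped
"rest of the universe" cell — marginally identical for every reported gene
and conserving M exactly, which an assertion checks on every chunk.
P-values use the add-one Monte-Carlo estimator p = (b+1)/(N+1), so p > 0
always; the analytic marginal P(Bin(M, p_g) ≥ k_g) is computed alongside as
an internal oracle. The default permutation count is 10⁶, configurable to
10⁷ (the source states both).

BH q-values are computed twice from the same ranked p-values: with the
multiplier equal to the number of genes carrying mutations
(observed-universe) and with the multiplier equal to the full gene count
(the stringent normalization). Tied p-values receive the standard step-up
treatment via the running minimum from the largest rank. Genes with k = 0
are excluded from the ranked list but counted in the full-universe
multiplier.

## Pedigree statistics

A meiosis is informative when the transmitting parent is doubly
heterozygous (trait allele and marker) with recorded phase; offspring are
non-recombinant when they receive the parental haplotype intact. LOD is
maximized on the θ grid {10⁻⁶} ∪ {0.001, …, 0.5} (step 0.001: θ̂
reproducible to three decimals without evaluating log 0); with zero
recombinants the θ → 0 limit NR·log₁₀2 is reported at θ̂ = 0. Significance
uses the genome-wide two-point threshold 3.3.

Co-segregation reports two constructions side by side — Fisher's exact test
on [rescues, littermates] × [R, NR] and the exact binomial
P(≤ R_rescue | θ_expected) — because the construction behind a single
printed co-segregation p-value is not uniquely recoverable; with zero
recombinants the binomial term is (1−θ)^NR exactly (0.859⁴⁰ ≈ 0.0023 for 40
meioses at the 14.1% predicted recombination rate).

Linkage power is Monte-Carlo: the pedigree is summarized by its informative
meiosis count, the suppressor transmits with probability 1/2 per meiosis,
the phenotype follows the penetrance/phenocopy model, and each marker is
genotyped with recombination fraction obtained by placing the trait locus
at θ_true from the nearest marker and combining map distances under no
interference (θ = θ₁ + θ₂ − 2θ₁θ₂, Haldane positions). Power is the
fraction of replicates whose best two-point LOD reaches the threshold, with
a Clopper–Pearson interval. Pedigrees are reduced to i.i.d. meiosis
transmissions — adequate for two-point power, not for multipoint layouts.

## Cross statistics

Expected offspring fractions multiply independent Mendelian transmissions
(loci on different chromosomes). The Fisher construction assumes Mendelian
segregation of the engineered allele among non-rescue littermates: they are
split as evenly as possible, odd animal to the carrier column (the choice
shifts p by < 0.005 on all bundled rows, which a test verifies). Two-sided
p-values sum the probabilities of tables/outcomes no more likely than the
observed one (minimum-likelihood convention, matching `scipy.stats`).
Penetrance divides observed rescues-with-allele by the Mendelian expected
carrier count (n/8 for the het × het-modifier design), with a
Clopper–Pearson interval on the rounded denominator; the estimate makes no
adjustment for pre-weaning loss, so it is an upper-bound-flavoured naive
estimate (≈ 0.47 for the bundled frameshift-validation cross).

## Numerical and scale choices

Test and acceptance runs use reduced problem sizes chosen so every check
retains ≥ 3-standard-error resolution: 200–2,000-gene universes and
2·10⁴–10⁵ permutations for null-model properties, ~2,000 simulated genomes
(> 10⁵ variants) for spectrum frequencies, 20 replicates for
planted-suppressor recovery, and a full 20,586-gene, 107-mouse cohort for
the end-to-end recovery checks. The permutation/oracle agreement tolerance
is 3·√(p(1−p)/N) plus the 2/(N+1) add-one offset. Degenerate inputs are
defined errors: empty annotations, empty tallies, all-zero contingency
tables, θ outside [0, 0.5], sib groups that overlap, and zero-candidate
siblings in the sharing fraction all raise; a zero rescue margin in the
cross Fisher returns p = 1 flagged degenerate rather than raising, since
such rows occur in real cross tables.

## Known limitations

- The burden p-values for observed genes are conditioned on k ≥ 1; the
  observed-universe BH therefore operates on a selected set, exactly as in
  the original analysis — the full-universe normalization is provided as
  the honest stringent alternative.
- Two-point linkage only; multipoint likelihoods are out of scope, and with
  20–26 markers per pedigree two-point is the informative regime anyway.
- The simulator's annotation is synthetic; analyses that depend on the real
  gene length distribution tail (beyond the one giant-gene outlier) or on
  real inter-gene linkage will differ quantitatively.
- Real-data absolute counts (total variant yields, per-gene hit lists)
  depend on caller and annotation versions and are not reproduction
  targets; the package reproduces rates, spectra, and test statistics.
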