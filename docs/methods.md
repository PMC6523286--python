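# Methods

## The shadow-Y model

A retrocopy on the Y chromosome that diverged from its autosomal or
X-linked parent creates, at each diverged nucleotide, an apparent SNP at
the parent locus: males (two parent alleles + one hemizygous Y allele)
read as heterozygous, females (parent alleles only) as homozygous for the
reference base. The package's inference chain rests on three
consequences of this model:

1. **Perfect sex separation at the array level.** Under the dominant
   coding (carrier = at least one minor allele), every male is a carrier
   and no female is. In a balanced cohort of *n* males and *n* females
   the two-sided exact P is 2/C(2n, n) at every such marker — identical
   across markers, and 1.58 × 10⁻¹⁴ at n = 25.
2. **An exon-restricted male-only duplication footprint in WGS.** The Y
   copy's reads pile onto the parent exons in males only, raising depth,
   apparent heterozygosity, discordant-mate and low-mapQ fractions.
   Because retrocopies derive from spliced mRNA, introns show no signal;
   intronic signal instead indicates a tandem duplication.
3. **Shared derived substitutions mark a single ancestral insertion.**
   Two species' retrocopies sharing more than 2 substitutions (same
   parent position, same substituted base) are taken to descend from one
   gain; the event is then placed on the species tree by Dollo parsimony
   (one gain, losses free).

## Exact test

`fisher_exact_two_sided` enumerates all 2×2 tables with the observed
margins and sums hypergeometric point probabilities ≤ the observed one
(ties included; no continuity or mid-P correction) — the conventional
"two-sided Fisher" definition, which also reproduces the
perfect-separation value above. Numerical choices:

* Point probabilities are computed via `lgamma` in log space (overflow-free
  at cohort sizes of 50+); ties are admitted with a relative tolerance of
  10⁻⁷ in log space, the tolerance R's `fisher.test` uses.
* Rows are put in a canonical order before enumeration so the sex-swap
  symmetry P(a,b,c,d) = P(c,d,a,b) holds exactly in floating point.
* If every admissible table falls at or below the observed probability
  the function returns exactly 1.0 (the mathematical value), avoiding
  0.99999… artifacts; a zero-margin table has a single configuration and
  likewise returns exactly 1.
* Minor-allele orientation is computed from the pooled QC-retained
  cohort; an exact 0.5 frequency tie resolves to the alphabetically
  first allele letter. Significance uses the inclusive comparison
  `p ≤ α/m`. Missing genotypes are dropped per marker (complete case).

QC follows array convention: markers need call rate ≥ 0.95 **and**
MAF ≥ 0.05 (boundary values retained; an all-missing marker is removed
with reason "no data"), samples need call rate strictly > 0.97.

## Pattern classification and regions

A marker is `SHADOW_Y` when the fraction of non-missing males that are
not heterozygous is ≤ `male_tolerance` (default 0 — strict, since the
motivating cohorts show literal perfect separation; raise it for noisy
data) and all non-missing females share one *homozygous* genotype
(a heterozygous female disqualifies, per the hemizygous-paralog model).
Females monoallelic but males mixing heterozygous and homozygous calls
gives `EXCLUDED_HOM` — the signature of a genuinely segregating X or
pseudoautosomal locus.

Regions are built by single-linkage merging along each chromosome with
`max_gap` = 1 Mb by default; the rule is order-invariant and idempotent,
and the default reproduces one region per cluster in the bundled marker
catalog (13 regions for its 47 retained markers). Coordinates are
1-based inclusive throughout; BED inputs are converted on ingest.
Telomere/centromere windows default to 500 kb and are explicit inputs —
telomeric/centromeric counts are therefore annotation-dependent and not
treated as fixed truths.

## Duplication-signature calling

All thresholds are invented operationalizations of what a human would
judge in a genome browser, and every one is a config knob
(`SignatureThresholds`): depth ratio ≥ 1.3, plus at least 2 of
{het-density excess ≥ 1 site/kb, discordant-mate excess ≥ 0.05, low-mapQ
excess ≥ 0.05}, computed on sex-mean features per window. The depth
ratio is plain male/female mean — exactly scale-invariant — with a 0.5
pseudocount denominator only when the female mean is zero. With one
sample per sex the contrast degrades gracefully to a single-sample
comparison. A gene becomes a retrocopy candidate when ≥ 50% of its exon
windows are called and no intron-only window is.

## Sequence comparison

Global affine-gap alignment (match +1, mismatch −1, gap open −5, gap
extend −1, a length-L gap scoring open + extend·(L−1)) is delegated to
Biopython's `PairwiseAligner`; the first co-optimal alignment in its
deterministic traversal is used, and the score is verified in tests
against an exhaustive enumeration oracle on short pairs. Percent
identity excludes gap columns by default ("identity"); an include-gaps
mode exists because published "similarity" figures vary in convention.
The ancestry rule counts substitutions only — indel sharing is reported
separately and never contributes, a deliberately conservative reading of
"shared polymorphisms".

ORF prediction aligns the copy to a clean parent CDS (ATG…stop, length
divisible by 3), then translates the raw copy sequence from the base
aligned to the parent start, so indels of length ≢ 0 (mod 3) shift the
frame exactly as in vivo. The predicted protein length is the number of
complete codons before the first stop — an intact copy reproduces the
parent protein length exactly and has truncation 0.

## Dollo placement

`dollo_place` evaluates every branch (clade-identified; the branch above
the root is valid and means presence in the common ancestor) as the
single gain, counting one loss per maximal subtree with no present tip
and ≥ 1 known-absent tip. Ties break toward the root, then
lexicographically, so output is deterministic. `unknown` tips impose no
constraint; `present_independent` tips model a non-homologous copy with
a mandatory gain on their own terminal branch, excluded from the shared
copy's objective. Optimality is verified against a brute-force
enumeration over gain × loss-subset assignments, exhaustively for all
labeled rooted binary topologies at 3 and 4 tips × all 3-state profiles,
one 5-tip topology × all 243 profiles, and a 6-tip caterpillar × all
presence/absence profiles — sizes chosen to keep the exponential oracle
comfortably fast while covering every structural case (nested absence,
multiple losses, unknown-only clades).

## Synthetic data: what it does and does not emulate

`simulate_genotypes` defaults to the study conditions the pipeline
targets: 25 males + 25 females, thousands of Hardy–Weinberg null markers
(MAF uniform in [0.05, 0.5]), planted shadow-Y markers, X-linked markers
(hemizygous males emitted as homozygous calls, as arrays report them)
and excluded-type markers (males 50:50 heterozygous : opposite-homozygous
by default, with both guaranteed present so the class is identifiable).
Null markers are sex-independent and mutually independent — no linkage
disequilibrium, population structure or relatedness — so Bonferroni
behavior on simulations is if anything conservative relative to real
arrays, and passing recovery tests does not demonstrate robustness to
stratification.

`simulate_feature_tracks` draws window mean depth as Poisson(λ·L)/L
(λ = 30×, L = 1 kb windows), so the mean has the small variance an
averaged per-base coverage would; fraction features are binomial over
~depth·L/150 reads (150 bp nominal read length). Signal windows use
1.5× depth, 4 het sites/kb vs 1/kb background, and 0.15 vs 0.02
discordant/low-mapQ fractions — plausible magnitudes chosen once, since
the motivating observations were visual; no read-level artifacts (GC
bias, mapping edge effects) are modeled.

`simulate_retrocopy_sequences` uses uniform base composition and
uniform substitution over the 3 alternatives (divergence percentages,
not substitution spectra, are what the downstream methods consume);
the gain-branch rate defaults to 0.02 (the ~98%-identity regime of a
recent retrocopy) with 0.005 per descendant branch and no indels unless
requested.

Every generator draws from a single `numpy.random.Generator` seeded per
call; identical configs reproduce outputs exactly.

## Problem sizes

The test suite exercises the GWAS recovery property at 5,010 markers ×
50 samples across 20 seeds, signature recovery at 210 windows × 4
samples across 3 seeds, and identity recovery on 4 kb parents — sizes at
which the binomial/Poisson standard errors make the assertions sharp
while the whole suite runs in well under a minute. The acceptance script
recomputes the perfect-separation exact P from the 25 + 25 cohort design.

## Known limitations

* The exact test is two-sided by the point-probability rule; software
  using a different two-sided convention can differ on asymmetric
  margins (never on the perfect-separation table).
* Region annotation depends entirely on the supplied interval sets;
  no genome build is bundled.
* The signature caller consumes window summaries; computing them from
  BAMs is left to standard tooling upstream (the TSV contract is the
  interface), so read-level evidence like split reads is out of scope.
* Dollo placement assumes the input topology is correct and offers no
  uncertainty quantification; with extensive loss the single-gain
  hypothesis can tie with multiple-gain scenarios it will not report.
* The ORF predictor assumes the parent frame is the only reading frame
  of interest and does not model splice variation.
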