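# Methods

## Rate calculus

An MA point rate is m/(G·L): m observed mutations over G cumulative
generations across L target sites (bp). Multiplying by genome size gives
the per-genome per-generation rate; multiplying that by elapsed generations
and by the coding and synonymous fractions gives expected class counts. The
defaults coding_fraction = 0.86 and synonymous_fraction = 0.25 are the
conventional *E. coli* constants (≈86% of the genome is protein-coding; a
quarter of random coding substitutions are synonymous at near-equal base
composition); both are overridable. Rates are carried at full float
precision; the 2-significant-figure presentation customary in print is
applied only by the report-time helpers (`format_rate`, `round_sig`).

## Spectrum classes and codon usage vectors

Substitutions are classified at the base-pair level: the six
strand-collapsed classes merge each forward-strand change with its
complement (C→T with G→A as G·C→A·T, and so on), so the classification is
invariant under complementing both bases — a property tested exhaustively
over the 12 ordered base pairs. Transitions are exactly G·C→A·T and
A·T→G·C.

Codon changes are translated with the bacterial genetic code (NCBI
table 11); a change is synonymous when the amino acid is conserved,
nonsense when it creates a stop. Minus-strand genes are handled by mapping
the forward-strand coordinate into the coding frame and
reverse-complementing, so codons are always read in coding orientation.

A synonymous change's *usage vector* compares within-family usage
fractions u(·) from a user-supplied codon usage table: **down** when
u(before) > ρ·u(after), **up** when u(after) > ρ·u(before), otherwise
**similar**. There is no canonical definition of "similarly used"; the
ratio band with ρ = 1.5 (default, configurable) was chosen because it is
symmetric (antisymmetry between a change and its reverse holds by
construction), scale-free, and has a single interpretable parameter. Tallies
report ρ alongside the counts. Usage tables accept any consistent scale
(per-thousand, percent, relative) since only within-family ratios enter.

Regional G+C composition is compared with the genomic proportion by an
exact binomial test. The default two-tailed convention doubles the smaller
tail and caps at 1 (so an observation exactly at the integer expectation
gives P = 1); the minimum-likelihood summation convention is available as
an option. For a lacI-like region (609.7 expected G/C in 1083 bp at the
genomic 50.8%, 610 observed implied by 56.3%) the exact two-tail is ≈3×10⁻⁴.

## Flanking-context replicated G-test

For each validated mutation the ±5 bp window is read from the genome
(offset 0 uses the pre-mutation reference base) and per-offset G/C counts
are accumulated. Under the null, each offset's count is Binomial(n, p)
with p the *regional* expected G/C proportion — always user-suppliable,
because a locus-restricted mutation set (e.g. one gene at 56.3% G+C) must
not be tested against the genome-wide 50.8%.

Each flanking offset is one replicate of the two-class G-test
G = 2[O·ln(O/np) + (n−O)·ln((n−O)/n(1−p))], with 0·ln 0 = 0. The total
G_T = ΣG_i (k df) decomposes into the pooled G_P = G(ΣO, k·n, p) (1 df)
and the heterogeneity G_H = G_T − G_P (k−1 df); the identity
G_T = G_P + G_H holds to machine precision by construction and the suite
re-derives the total with a second naive accumulation. Tail probabilities
come from the chi-square survival function (scipy's regularized incomplete
gamma).

Conventions and their rationale:

* **Center exclusion.** The profile reports all 11 offsets, but the test
  runs on the 10 flanking offsets by default (9 heterogeneity df): the
  mutated site's own composition is constrained by which substitution
  classes occurred, not by neighborhood mutability, and including it
  conflates the two. A flag includes it.
* **Boundary handling.** On a linear genome, mutations whose window
  crosses an end are skipped entirely rather than truncated — the
  decomposition assumes the same n in every replicate. Circular genomes
  wrap. Skipped records are listed in the profile.
* **No small-sample correction by default.** The plain statistic is the
  reference behavior; the Williams correction q = 1 + (a²−1)/(6nν) and an
  exact-binomial per-offset alternative are opt-in flags. At n = 23 the
  pooled G test is mildly anticonservative, which the null-calibration
  test bounds (type-I error 0.05 ± 0.015 at α = 0.05 over 2000 binomial
  replicates).
* **Rounding.** Statistics are reported at 3 significant figures and P
  values at 4 decimals at the presentation layer only.

## Serial-bottleneck selection model

The regime is daily serial dilution: 100-fold growth to saturation
(g = log₂100 ≈ 6.64 generations per cycle) followed by transfer of
N_b = 5×10⁶ cells. Modeling choices, all of which were genuinely open:

* **Deterministic growth, drift only at transfer.** During growth the
  census size is ≥5×10⁶, so within-day drift is negligible relative to
  the bottleneck sampling; selection enters through the relative-fitness
  frequency update f′ = f(1+s)^g / (f(1+s)^g + 1 − f), and the bottleneck
  draws Binomial(N_b, f′). The selection coefficient s is per generation,
  constant in time, with no epistasis or clonal interference.
* **Mutant entry.** A new mutation is introduced as a single cell at a
  bottleneck (f₀ = 1/N_b). Arising mid-growth would roughly halve the
  initial odds; since the entry model affects both the neutral and the
  selected lineage alike, the retention *ratio* is insensitive to it.
* **Retention** means ≥1 copy in the bottleneck sample. A neutral single
  founder behaves as a critical Poisson(1) branching process, so neutral
  retention decays like 2/cycles; deleterious lineages decay
  geometrically faster, and the ratio retention(0)/retention(s) is the
  factor by which selection depresses the apparent accumulation rate.
* **Common random numbers.** The ratio is computed with both legs run
  from the same seed, so the neutral ratio is exactly 1 and the ratio
  curve is a fixed monotone function of s — which makes the inversion
  well posed: `infer_selection_coefficient` bisects s over [s_min, 0]
  until the bracket is below 10⁻⁴, with a fixed replicate budget per
  evaluation, and propagates the Monte Carlo error of the ratio through
  the locally estimated slope.
* **Horizon.** The default horizon is 400 generations (≈60 daily cycles,
  about two months of transfers) with 10⁴–4×10⁴ replicate lineages: long
  enough for selection at |s| ~ 0.01 to separate clearly from neutrality,
  short enough that retention probabilities stay resolvable by Monte
  Carlo. The horizon is a parameter, not a constant, because the
  residence time relevant to an observed rate depression depends on when
  mutations arose — estimates of s should be read as
  horizon-conditional.
* Reconstruction controls: under the growth model, logit f is linear in
  cumulative generations with slope ln(1+s), so mixtures are fitted by
  least squares on the logit scale and points at exactly 0 or 1 (no
  information about s) are dropped.

All stochastic operations take explicit seeds (numpy `default_rng`; no
global state) and are bit-reproducible given (seed, replicates,
parameters).

## Synthetic data

The generators emulate the study conditions: genomes are i.i.d. with
P(G)=P(C)=p/2 at the *E. coli*-like default p = 0.508; genes sample codons
within each synonymous family proportional to a usage table (amino acids
uniform across families), flanked by ATG/TAA and alternating strands;
MA line counts are Poisson with mean rate × generations (0.0025 × 40,000 =
100 at the defaults).

Planted mutations draw their six-class spectrum first
(Multinomial(n, spectrum_probs) — so the spectrum is recovered exactly in
expectation), then assign each class a site compatible with its starting
base pair, sampled without replacement with weight exp(β·c), where c is
the G/C count in the ±flank window, center excluded to match the test's
convention. β = 0 reduces exactly to the uniform null the G-test assumes;
β > 0 produces the G/C-rich-neighborhood hypermutability alternative with
one interpretable knob. The default spectrum (0.45, 0.15, 0.05, 0.15,
0.05, 0.15 over G·C→A·T, G·C→T·A, G·C→C·G, A·T→G·C, A·T→C·G, A·T→T·A)
reflects the G/C→A/T-dominated bias seen in enteric bacteria.

What the generators do *not* emulate: real gene content and operon
structure, replication-origin distance effects, strand-specific context
asymmetry, mutator heterogeneity among lines, and selection during the MA
propagation itself. Passing tests therefore demonstrate that the
statistics recover known planted structure under their own model
assumptions — not that real genomes satisfy those assumptions.

## Numerical notes and limitations

* G statistics handle O ∈ {0, n} via the 0·ln 0 = 0 convention and are
  non-negative by construction; the frequency update groups (1 − f) so
  that f = 0 and f = 1 are exactly absorbing in floating point.
* The pooled/total pair printed for the 23-mutation genome-wide set in
  the source compilation (4.88 / 19.5) is not what the plain statistic
  gives from the printed counts (5.15 / 19.8, while the heterogeneity
  14.7 matches exactly); the variant behind those two numbers is unknown
  and deliberately not imitated — the package reports the plain
  statistic and documents the difference. Likewise the per-offset tail
  probabilities of the lacI set at offsets −1/+4/+5 and the "P ≈ 0.01"
  composition claim match no convention implemented here; the exact
  binomial gives ≈3×10⁻⁴ for the composition comparison.
* Codon-usage-vector tallies depend on the usage table and on ρ; with no
  reference table specified by the source material, reproducing any
  particular published tally requires both the original mutation list
  and that unstated choice.
* The selection-coefficient estimate from an observed rate depression is
  conditional on the regime, the entry model, and the horizon; it is an
  order-of-magnitude tool, not a likelihood-based estimator with
  frequentist coverage guarantees.
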