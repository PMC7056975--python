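# Methods

## The divergence scan

The scan operates on a table of per-variant reference-allele frequencies
for n selected (O) and n control (B) replicate lines (default 5 + 5),
sorted by chromosome arm and position.  Divergence at a variant is
|Δp| = |mean(freq_O) − mean(freq_B)|, the absolute difference of the two
group means.  (An alternative — the mean of pairwise line differences —
is not implemented; the mean-of-means form is an explicit assumption.)
Allele polarity does not matter because only |Δp| is used.

Interval construction has three parameters, all strict inequalities:

* `high_threshold` (default 0.8): a variant qualifies when |Δp| exceeds it;
* maximal runs of *consecutively indexed* qualifying variants seed
  intervals — adjacency is counted in the variant table, not in bp,
  because the interruption rule below is stated in variant counts and
  would be meaningless under a bp definition;
* two neighbouring seed intervals merge, together with the run between
  them, when that run has at most `max_interruption` variants (default 2,
  i.e. fewer than three) and every one has |Δp| above
  `interruption_threshold` (default 0.5).

Merging is iterated to a fixpoint with a left-to-right sweep.  The
fixpoint is order-independent: whether an interruption qualifies depends
only on its own length and values, never on the extent of its flanking
intervals, so no merge can enable or disable another.  The test suite
asserts this by comparing against a brute-force merger that applies
merges one at a time in random order.  Interruption runs at arm ends have
only one flanking interval and are never merged.  Single qualifying
variants are emitted as one-variant, zero-span intervals (suppressible in
the CLI with `--min-variants`).

Interval span is the distance between the first and last member variant —
an underestimate of the true swept region when variants are sparse.
Internally all coordinates are 1-based inclusive (FlyBase convention);
the BED exporter converts to 0-based half-open (`chromStart = start − 1`,
`chromEnd = end`).

Gene assignment lists a gene on an interval when the gene span, extended
by `flank_bp` (default 0), overlaps the interval by at least 1 bp.  No
canonical flank distance exists for this assignment, so it is exposed as
a parameter rather than guessed.

## Candidate selection

A gene is admitted genomically by either of two routes: membership in a
divergence interval together with a per-SNP divergence P-value below
`p_cutoff` (default 10⁻⁵), or a nominally significant SNP
(`nominal_p_cutoff`, default 10⁻³) for genes whose divergence never
reaches the interval threshold.  The exact Boolean published gene lists
were built with is not recoverable, so the rule mode (`either`,
`interval`, `nominal`) is a parameter and every rejection carries an
audit code (`genomic`, `expression`, `unknown-expression`, `rnai`) that
makes any alternative combination reconstructible from the output.
Expression and RNAi-stock availability are input flags, not live database
lookups, keeping the pipeline download-free.  The divergence P-values
themselves are consumed as an input column; computing them from raw
sequencing data is out of scope.

## The ANOVA engine

All phenotype models are classical fixed or mixed factorial ANOVAs on
balanced or nearly balanced designs:

| response | model |
|---|---|
| lifespan (full) | Y = µ + S + G + S×G + Rep(G) + S×Rep(G) + ε |
| lifespan (per sex) | Y = µ + G + Rep(G) + ε |
| lifetime productivity | Y = µ + G + ε |
| weekly productivity | Y = µ + W + G + W×G + ε, per-week Y = µ + G + ε |
| O/B productivity | Y = µ + Gm + Gf + W + Gm×W + Gf×W + Gm×Gf + Gm×Gf×W + ε |
| qPCR (combined) | Y = µ + L + G + L×G + Rep(L×G) + ε |
| qPCR (per gene) | Y = µ + L + Rep(L) + ε |

S = sex, G = genotype, W = week, Gm/Gf = maternal/paternal regime,
L = RNAi vs control line, Rep = the random replicate unit (vial, or
biological replicate for qPCR), nested within the parenthesized factors.

Sums of squares are partial (Type III-style, full-versus-reduced) under
sum-to-zero effect coding; nested replicate terms are effect-coded within
each nesting cell.  On balanced data this reduces exactly to the
sequential decomposition (asserted to 1e-8 relative in the tests, along
with orthogonality of the decomposition and equality with an independent
statsmodels Type III computation on unbalanced fixed designs).

F denominators follow expected-mean-squares rules: a fixed term is tested
against the smallest random term whose factor set contains it (G against
Rep(G); S and S×G against S×Rep(G); L, G and L×G against Rep(L×G)), a
random term against the smallest random term strictly containing it, and
otherwise against the residual.  This is the classical construction, not
REML.  Commercial packages fit the random terms by REML and can differ
slightly on unbalanced data (e.g. after dead-fly attrition), so
regenerated gene counts from real screen tables may shift by a gene or
two; the choice is recorded here rather than asserted as universal.
Under a simulated null at the screen's design size the per-sex lifespan
call rejects at 0.051 over 3000 simulations (0.05 nominal), so the EMS
test is correctly calibrated for these designs.

Tukey–Kramer pairwise comparisons use the studentized range distribution
against the term's EMS denominator, with a compact letter display built
by the insert-and-absorb algorithm (levels sharing a letter are not
significantly different).

Significance is per test at α = 0.05 (configurable) with no
multiple-testing correction — the screen is deliberately operated at
nominal α, and the classifier consumes the resulting directions.

## Screen effect calling

Each RNAi genotype is compared with its background-matched control within
its experimental block.  The sex-specific lifespan calls come from the
per-sex reduced models (the full model's S×G P-value is attached for
sensitivity analyses); "affected lifespan" means a significant G effect
in at least one per-sex model.  Lifetime productivity per vial is the sum
of its observed weekly offspring-per-female values — weeks after a vial's
extinction genuinely contribute zero to lifetime reproduction — whereas
the weekly models treat extinct cells as missing and skip weeks a
genotype never reached.  qPCR is analyzed as log2 normalized expression,
−(Ct_target − Ct_reference); the per-gene estimate is the RNAi-minus-
control difference of line means, i.e. the log2 knockdown.  With two
biological replicates the denominator has 2 degrees of freedom, which is
why moderate between-replicate variance produces low point estimates with
non-significant calls — the engine reproduces this under-powering
qualitatively when the biological variance is raised.

Two properties hold by construction and are asserted exactly: swapping
the RNAi and control roles negates every estimate and preserves every
P-value, and a genotype that is a relabelled copy of its control yields
estimate 0 and P = 1.

## Pleiotropy classification

Directions (increase / decrease / ns) per trait feed a deterministic rule
cascade with three antagonism axes: **sex** (lifespan directions oppose
between females and males), **early vs late reproduction** (significant
weekly calls oppose between the early-week set, default {1, 2}, and the
late-week set, default weeks ≥ 4), and **lifespan vs reproduction** (any
significant lifespan call opposes any significant productivity call in
fitness sign; decreases of either trait are costs).  The early/late
boundary is a parameter because the terms have no canonical cutoff; the
golden-fixture tests verify that the defaults reproduce every category in
the fixture set, and the classifier is exercised over every direction
combination to confirm it is total.  A gene with at least one axis is
`antagonistic_pleiotropy`; otherwise it is `no_effect`,
`lifespan_only_benefit`/`_cost`, `productivity_only`, or
`concordant_beneficial`/`_deleterious`.  When weekly directions are mixed
without an early/late opposition, the productivity pattern falls back to
`some_week_down` over `some_week_up` (a cost-conservative tie-break).

## The synthetic-data generator

The generator emulates the *structure* of the study, not its biology.

**Genome.**  Each variant gets an ancestral frequency p₀ ~ U(0.05, 0.95);
B-line frequencies are Beta(p₀·c, (1−p₀)·c) with drift concentration
c = 50 by default, O lines likewise outside sweeps.  Inside a planted
sweep with target divergence d, p₀ is drawn from U(0, 1−d) and the O-line
mean is p₀ + d, so the expected |Δp| equals d exactly (verified to ±0.01
over 20 seeds) and the noise-free limit (c → ∞, depth → ∞, d = 1) gives
|Δp| = 1 exactly.  Observed frequencies add binomial sequencing noise at
mean depth 50.  Under these null conditions the fraction of variants with
|Δp| > 0.8 is below 0.1% and no 3-variant interval arises in 10,000
variants.  A per-variant divergence P-value is provided as a 5-vs-5
t-test on arcsine-square-root transformed frequencies — a stand-in that
is monotone in divergence so the candidate filter has a realistic input;
the real pipeline consumes externally computed P-values.  Linkage
structure within sweeps and forward Wright–Fisher dynamics are not
modelled.

**Screen.**  Lifespan = sex baseline (F 60 d, M 55 d) + planted genotype
shift + vial effect N(0, 3²) shared by all six flies of a vial +
N(0, 10²) residual, truncated at zero.  Noise is Gaussian rather than
Gompertz because the downstream models are ANOVAs on means; only the
variance components matter, and this is a documented simplification.
Weekly productivity is simulated directly on the analyzed
offspring-per-female scale (not raw egg counts) with declining weekly
baselines (25, 20, 12, 6, 3), N(0, 5²) noise, truncation at zero, and
vials dropping out once all three simulated females are dead.  qPCR Ct
values use a constant-expression reference gene, biological-replicate
noise of 0.3 Ct on the target and 0.15 Ct technical noise, so a planted
knockdown k shifts ΔCt by −log2(k).  Effect magnitudes for planted genes
(≈ ±8–10 days of lifespan, ±5–8 offspring/female/week, 4-fold knockdown)
are free parameters chosen to sit at the scale the assays can resolve at
the design sizes; no effect-size distribution for real causal loci is
implied.  Design constants default to the screen layout: 48 lifespan
vials × 3 flies/sex, 13 productivity vials, 15 O/B vials per cross,
2 biological × 3 technical qPCR replicates.  The O/B generator works at
the regime level (maternal/paternal ∈ {B, O}) rather than simulating the
five individual line pairs, since the analysis models only use regime
factors.

All randomness flows from one seed through named substreams (genome,
lifespan, productivity, qPCR, O/B, annotation), so identical seeds give
byte-identical tables and adding screen genes never perturbs the genome
simulation.

Because the generator matches the models' assumptions (Gaussian noise,
shared vial effects, no linkage), passing tests demonstrate correctness
of the algorithms and calibration of the tests under those assumptions —
not robustness to the skewness, censoring, or block-to-block
heterogeneity of real screen data.

## Problem sizes

The acceptance harness uses 10,000 variants across the five major
chromosome arms with 20 planted 150-kb sweeps (≈ 11 variants each),
1000 null simulations for the type-I error of the lifespan call, 50
replicates for its power, and 5 replicate screens for category recovery;
these sizes give Monte-Carlo error comfortably inside the asserted
margins while keeping a full run under a minute.

## Known limitations

* The EMS construction assumes (near-)balance; heavy attrition would
  favour REML (not implemented by design).
* Interval span underestimates sweep extent at low variant density.
* The classifier trusts per-test directions at nominal α; no
  multiplicity control is applied anywhere.
* The generator's divergence P-values are synthetic stand-ins, and its
  annotation table places screen genes inside sweeps by construction.
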