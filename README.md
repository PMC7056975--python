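# senescan

Reverse engineering laboratory evolution of postponed senescence in
*Drosophila melanogaster*.

Replicate populations selected for late-age reproduction (O lines) evolve
roughly doubled lifespan relative to unselected baseline (B) lines, and
resequencing the two sets of lines reveals genomic regions driven to near
fixation by that selection.  `senescan` implements the computational chain
that turns such an evolve-and-resequence experiment plus an RNAi
phenotyping screen into a classified gene list:

1. **Divergence scan** — given per-variant allele frequencies for 5 O and
   5 B lines, find variants whose absolute mean frequency difference
   |Δp| = |p̄_O − p̄_B| exceeds 0.8, merge consecutive qualifying variants
   into intervals, and bridge interruptions of fewer than three variants
   when every interrupting variant has |Δp| > 0.5.  These intervals are
   putative selective-sweep footprints.
2. **Candidate filter** — keep genes that (1) carry a SNP with divergence
   *P* < 10⁻⁵ inside an interval, or are nominally significant
   (*P* < 10⁻³) without reaching the 0.8 divergence criterion; (2) are
   expressed in ovaries and accessory glands; (3) have viable RNAi stocks.
3. **Screen analysis** — classical EMS (expected-mean-squares) mixed
   ANOVA of the RNAi screen.  Lifespan:
   *Y* = *µ* + *S* + *G* + *S*×*G* + *Rep*(*G*) + *S*×*Rep*(*G*) + *ε*
   with per-sex reduced models *Y* = *µ* + *G* + *Rep*(*G*) + *ε*;
   lifetime productivity *Y* = *µ* + *G* + *ε*; weekly productivity
   *Y* = *µ* + *W* + *G* + *W*×*G* + *ε* with per-week reduced models;
   reciprocal-cross productivity
   *Y* = *µ* + *Gm* + *Gf* + *W* + interactions + *ε* with Tukey–Kramer
   letters; qPCR knockdown on the ΔΔCt (log2) scale with biological
   replicate as the random stratum.
4. **Pleiotropy classifier** — map each gene's effect calls onto the
   antagonism axes predicted by the antagonistic-pleiotropy theory of
   senescence: sexually antagonistic lifespan effects, early-vs-late
   reproduction trade-offs, and lifespan-vs-reproduction trade-offs.

A synthetic-data module generates allele-frequency tables with planted
sweeps and screen phenotype tables with planted effects at the study's
design sizes (48 lifespan vials × 3 flies/sex, 13 productivity vials,
15 O/B vials, 2 × 3 qPCR replicates), so the whole chain is testable
without any downloads.  It is aimed at researchers analyzing
evolve-and-resequence or RNAi life-history screen data who want a
transparent, scriptable version of the JMP-style ANOVA workflow.

## Worked example

The bundled demonstration configuration plants two sweeps (target
divergence 0.95 and 0.92) and four screen genes: a sexually antagonistic
gene with an early/late reproduction trade-off (`ap-1`), a concordant
benefit (`ben-1`), a concordant cost (`del-1`) and a null (`null-1`).

```sh
senescan all -o demo --seed 7
```

prints

```
senescan 0.1.0 report (seed=7)

Intervals per arm:
  X: 1 interval(s), 50 variants, 365690 bp covered
  3R: 1 interval(s), 23 variants, 290763 bp covered

Candidate genes selected: 4
Screened genes: 4
  affecting lifespan:          3
  increased in at least 1 sex: 2
  decreased in at least 1 sex: 2
  sexually antagonistic:       1

Pleiotropy categories:
  no_effect: 1
  lifespan_only_benefit: 0
  lifespan_only_cost: 0
  productivity_only: 0
  concordant_beneficial: 1
  concordant_deleterious: 1
  antagonistic_pleiotropy: 1
```

Both planted sweeps are recovered as single intervals (the bp span is the
distance between the first and last member variant, hence slightly short
of the planted 400 kb and 300 kb); the four planted effect classes come
back as one gene each in the matching category, and `ap-1` is the one
sexually antagonistic gene.  Alongside the report the output directory
holds every intermediate table (variants, intervals + BED, candidates
with per-criterion audit flags, effect calls, profiles).

The same stages are available programmatically, built around
statsmodels-style model objects:

```python
from senescan import AnovaModel

model = AnovaModel.from_formula(
    "lifespan ~ S + G + S*G + Rep(G) + S*Rep(G)", data, rep_col="vial"
)
res = model.fit()
print(res.summary())            # ANOVA table with EMS denominators
res.contrast("G", "rnai", "control")
res.tukey("G", alpha=0.05)      # Tukey-Kramer + compact letter display
```

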