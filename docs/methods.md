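# Methods

## The two-locus model

Scale-pattern inheritance in common carp (*Cyprinus carpio*) is modeled by
two unlinked autosomal loci. Writing genotypes in the field's notation
(S-locus first, e.g. `SsNn`):

| genotype | phenotype |
|---|---|
| `SSnn`, `Ssnn` | scaled (wild type) |
| `SSNn`, `SsNn` | linear |
| `ssnn` | scattered (mirror + irregular) |
| `ssNn` | nude ("leather") |
| any `NN` | lethal before hatching |

Assumptions: independent assortment (the loci lie on different chromosomes;
no linkage parameter is modeled), Mendelian segregation, complete dominance
of `S` over `s`, and no differential survival after hatching. Under these
assumptions a dihybrid `SsNn x SsNn` cross yields scaled 3/16, linear 6/16,
scattered 1/16, nude 2/16 and lethal 4/16; a nude x nude cross yields
25% scattered : 50% nude : 25% lethal at the zygote level, hence 1/3 : 2/3
among survivors.

All transmission probabilities are computed with `fractions.Fraction`, so
distributions sum to exactly 1 and the expectation tables are reproduced as
exact rationals; floats appear only when reporting percentages or feeding
statistics. Expected distributions are reported at the zygote level (lethal
class included), matching the classical presentation; survivor-level views
are obtained by `condition_on_survival`, which removes the lethal mass and
renormalizes (idempotent; rejects an all-lethal input).

The model predicts only the aggregate scattered class. The irregular/mirror
split is an observation-layer parameter (`AlleleModel.scattered_split`,
default 0.5, meaning no prior preference), because the two-locus system
makes no genotypic prediction for it.

## Variant allele hypotheses

Two departures from the standard model are parameterized as first-class
`AlleleModel` objects:

* **weak-N** — `NN` is viable and presents as nude; nothing else changes.
  No cross then has a lethal class, and `ssNn x ssNn` yields nude 3/4,
  scattered 1/4. This is the hypothesis motivated by Hungarian nude x nude
  broods showing neither the 25% early loss nor the expected survivor split.
* **strong-s** — a third S-locus allele `s*` with complete loss of function.
  `s*s*` homozygotes are nude-like without any N mutation; `ss*` fish remain
  in the scattered class (one ordinary `s` still supports the mirror
  pattern). A nude-looking `s*s*nn` parent crossed to an ordinary mirror
  (`ssnn`) therefore produces 100% scattered offspring and 0% nudes — the
  configuration that explains all-mirror broods from nude x mirror crosses.
  Making `ss*` nude-like instead would predict 100% nudes from that cross
  and could not explain the observation, so dosage of `s*` matters: two
  copies are required for the nude-like presentation.

Phenotype-level cross enumeration (`expected_for_cross_type`) lists every
viable genotype pair compatible with two parental phenotypes under a model
and groups pairs with identical offspring distributions into equivalence
classes; classes are reported, never silently collapsed, because e.g. the
two admissible linear genotypes (`SSNn`, `SsNn`) predict different broods.

## Inference

* `reconstruct_counts` converts printed per-category percentages back into
  integers: nearest integer per category (half away from zero), any rounding
  residual absorbed by the largest category so the total is exact. On the 19
  packaged crosses the residual is always zero.
* `multinomial_loglik` includes the multinomial coefficient (rankings are
  unaffected; absolute values are comparable across reports) and returns
  `-inf` when a non-zero count sits on a zero-probability category. With
  `merge_scattered` (the default when fitting models that predict only the
  aggregate) irregular and mirror counts are pooled against the scattered
  probability.
* `goodness_of_fit` computes Pearson X² with df = retained categories − 1;
  categories with zero expected probability and zero count are dropped.
  A df of 0 is reported as a degenerate fit (statistic 0, p 1), not an
  error. An exact multinomial tail (total probability of outcomes no more
  likely than the observed one) is offered for n ≤ 500 and at most four
  categories, where full enumeration is feasible; the chi-square tail is the
  default. A warning is raised when any expected count falls below 1.
* `rank_parent_hypotheses` evaluates every (model, genotype-pair class)
  hypothesis on survivor-conditioned expectations and sorts by
  log-likelihood with a stable sort, so exact ties resolve to hypothesis
  registration order (documented in the output).
* `compare_survival` uses the pooled-variance Student's t-test (Welch behind
  a flag), reporting group means and SDs alongside. Two constant, equal
  groups are defined to give t = 0, p = 1.

## Fin and teeth scoring

Fin defects are scored per fish over seven fins (dorsal, caudal, anal,
paired pectorals, paired pelvics — the inventory used in per-fin defect
breakdowns for these phenotypes) on the cumulative scale absent 1, stunted 0.75, reduced
0.5, slightly reduced 0.25, normal 0; the score is a multiple of 0.25 in
[0, 7] and monotone in any single fin's severity. Teeth are counted out of
a fixed maximum of 10 (the scaled wild-type complement). Group summaries
report mean/SD/n per category and all pairwise Student's t-tests without
multiple-testing correction, matching the field's presentation; a
Holm-adjusted column is emitted alongside. Categories with fewer than two
fish are excluded from tests with a warning.

## The rheostat simulator

The generator realizes the dose/threshold ("rheostat") picture: a baseline
signal profile over a 100 x 30 grid (dorso-ventral positions x head-to-tail
columns) with flank level 1.0 and preferential bands — dorsal line 3.0,
lateral line 1.5, ventral/belly line 2.6, each a few rows thick. A scale
forms at a position iff

```
attenuation(genotype) * fish_level * (baseline + noise) >= threshold
```

with threshold 0.7, per-position Gaussian noise (sd 0.08) and a per-fish
lognormal level (sd 0.08) representing modifier-gene variation; the
per-fish term exists because purely positional noise cannot move a whole
fish across a classification boundary. Genotype attenuations default to
scaled 1.0, linear 0.55, scattered 0.35, nude 0.12 — chosen so the default
classifier recovers each intended class from its own maps in ≥ 90% of
replicates at default noise (in practice ≥ 98%). The equivalent
falling-signal and rising-threshold parameterizations produce the same
outcome; only the falling-signal form is implemented.

Map classification is rule-based: coverage ≥ 95% → scaled; ≤ 5% → nude
(sub-typed `nude1` when residual scales remain); complete dorsal line with a
populated lateral line over sparse flanks → linear; dorsal plus ventral
lines only at ≤ 25% coverage → mirror; everything else — substantial cover
without tight row structure — → irregular.

Whole-cross simulation draws n zygotes by exact gamete sampling, removes and
counts lethal zygotes (pre-hatching loss, reported separately), and realizes
each survivor: category, per-fin states (severity level ~ Binomial(4, q)
with q = expit(1.702 − 9.395·attenuation), so the expected per-fin weight
equals q) and teeth ~ Binomial(10, p) with p = expit(−3.128 +
5.715·attenuation). The teeth constants are calibrated to the two anchor
means of the koi-involving crosses (scaled ≈ 9.3 of 10, nude < 1) and live
in `RheostatParams`, not in code paths. Nude sub-types 1–3 are assigned
phenomenologically from residual scales and fin-loss severity; their genetic
basis is unknown and nothing downstream depends on the assignment.

Irregular vs mirror within the `ssnn` class can be realized two mutually
exclusive ways per run: the default `"split"` path applies
`scattered_split` as an observation-layer Bernoulli, while the
`"rheostat"` path classifies each simulated map. At the calibrated default
noise the map path realizes the scattered class almost entirely as mirrors
(the attenuation gap to the linear class leaves little room for
noise-driven flank coverage), so the split path is the default for
generating cohorts with realistic irregular fractions.

A counts-only fast path (`simulate_cross_counts`) samples categories
directly from the exact cross distribution for studies that need many
replicates.

## What the generator does and does not emulate

It emulates Mendelian transmission with the lethal class, survivor
conditioning, and monotone dose-coupling of scale cover, fins and teeth —
so passing tests demonstrate correctness of the transmission arithmetic,
the inference machinery's ability to recover generating hypotheses, and the
direction of the phenotype gradients. It does not emulate: differential
post-hatching loss of severely affected nude fry (cannibalism in communal
rearing; reports carry this as a caveat only), subspecies origin effects,
between-family heterogeneity in the irregular/mirror split (observed range
roughly 15–86%), teeth means of the intermediate classes (only the scaled
and nude anchors are calibrated), or any spatial development of scale
placodes. Agreement of simulated cohorts with the package's own
expectations therefore says nothing about which allele hypothesis is true
of any real stock.

## Validation problem sizes

The shipped studies use sizes chosen to keep Monte-Carlo error well below
the assertion margins: 4,000 zygotes for the lethality/survivor-ratio
check (3 SE bounds), 5,000 for convergence of simulated frequencies to the
exact distribution (max gap < 0.05), 100 replicates x 5 cross types at 300
zygotes for genotype-class recovery (≥ 95% hit rate), 2,000 replicates at
n = 200 for chi-square type-I calibration (acceptance band 0.03–0.07), and
50 fish per group for the scoring contrasts.

## Known limitations

* Genotype inference is maximum-likelihood ranking only; no posterior over
  genotypes and no estimation of linkage (assumed free recombination).
* Standard-vs-weak-N discrimination from a single nude x nude brood of ~300
  zygotes has limited power (~91%): the competing survivor splits (1/3 vs
  1/4 scattered) are close. Pooling broods or using survival data resolves
  this.
* The classifier's thresholds are tuned to the default profile geometry;
  custom profiles may need re-tuned thresholds.
* Triploid genotypes and saddleback/egg-fish phenotypes are out of scope.
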