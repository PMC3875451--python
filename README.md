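# carpscales

Two-locus genetics of scale-pattern formation in common carp
(*Cyprinus carpio*): exact cross expectations with a lethal genotype class,
likelihood-based inference of parental genotypes and variant allele
hypotheses from offspring counts, fin/teeth phenotype scoring, and a
rheostat (signal x threshold) simulator that generates fully synthetic
crosses for end-to-end testing.

The package is aimed at fish geneticists and teachers of classical
genetics working with carp scalation data: brood phenotype count tables,
per-fish fin/teeth records, or simulated cohorts.

## The model

Scale cover is controlled by two unlinked loci with two alleles each. With
genotypes written S-locus first (`SsNn`):

* `S_nn` — scaled (wild type); `S_Nn` — linear;
* `ssnn` — scattered (the classical mirror plus the irregular sub-type);
* `ssNn` — nude ("leather"), with reduced pharyngeal teeth and fin defects;
* `NN` — lethal before hatching, in any combination.

A dihybrid `SsNn x SsNn` cross therefore segregates scaled 3/16 : linear
6/16 : scattered 1/16 : nude 2/16 : lethal 4/16, and a nude x nude cross
gives 25% : 50% : 25% (scattered : nude : lethal) at the zygote level —
1/3 : 2/3 among survivors. All transmission arithmetic is exact (stdlib
`Fraction`); floats appear only at reporting boundaries.

Observed broods often deviate from these ratios. Two variant hypotheses are
built in and can be ranked against the standard model by multinomial
log-likelihood: a **weak-N** allele (viable `NN`, nude, no lethal class) and
a **strong-s** allele `s*` (complete loss of function; `s*s*` nude-like
without any N mutation, `ss*` still scattered). See `docs/methods.md` for
the full account.

## Worked example

Expected survivor distribution of a nude x nude cross:

```
$ carpscales expect --parents ssNn,ssNn --survivors
ssNnxssNn  [standard]
  nude        66.67%
  scattered   33.33%
```

Confront the packaged Hungarian nude x nude brood (208 offspring: 13%
mirror, 87% nude as printed) with that expectation:

```
$ carpscales gof --fixture table2 --cross 26nu.nu --model standard
26nu.nu: ssNnxssNn  expected[nude 66.7%, scattered 33.3%]  X2=38.77 df=1 p=4.76e-10  REJECT
```

The brood deviates decisively from the standard 1/3 : 2/3 split. Ranking
allele hypotheses on the same counts:

```
$ carpscales infer --fixture table2 --cross 26nu.nu
26nu.nu (n=208):
  #1 [strong-s] ss*Nnxs*s*Nn | s*s*Nnxss*Nn  lnL=-3.59
  #2 [weak-N] ssNnxssNn  lnL=-11.71
  #3 [strong-s] ss*Nnxss*Nn  lnL=-11.71
  #4 [strong-s] ss*Nnxs*s*nn | s*s*nnxss*Nn  lnL=-11.71
  #5 [standard] ssNnxssNn  lnL=-25.26
```

Every variant hypothesis predicting an excess of nudes outranks the
standard genotype assignment — the 87% nude brood is far more likely under
a weak-N or strong-s parent than under ordinary `ssNn x ssNn`
(log-likelihood difference > 13).

Simulated crosses are fully reproducible from a seed:

```
$ carpscales simulate --parents ssNn,ssNn --n 4000 --seed 1 --out sim/
3014 survivors, 986 lethal zygotes
```

(the lethal fraction 24.7% reflects the expected 25% loss of `NN`
zygotes), and `carpscales score --input sim/fish.csv --out scores/`
summarizes fin-defect scores and teeth counts per category with pairwise
t-tests.

The same functionality is available as a library: `cross_distribution`,
`expected_for_cross_type`, `goodness_of_fit`, `rank_parent_hypotheses`,
`simulate_cross`, `group_score_summary`, `teeth_summary`, and
`table2_fixture` for the packaged 19-cross table.

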