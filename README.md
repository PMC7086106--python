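# matesys

Mating-system genetics for small, closed, individually known populations —
the setting of managed megafauna reserves, fenced game farms and captive
breeding programmes, where a handful of territorial males and a few dozen
females are all sampled and the questions are: *who fathered whom, how skewed
is reproduction, does extra mating pay, and do mates avoid their relatives?*

`matesys` provides the full analysis chain for codominant microsatellite
data, plus a pedigree simulator so every stage can be exercised, power-tested
and unit-tested without any field data:

1. **Marker QC** — observed/expected heterozygosity (unbiased
   H<sub>e</sub>), polymorphic information content
   (PIC = 1 − Σp<sub>i</sub>² − Σ<sub>i&lt;j</sub>2p<sub>i</sub>²p<sub>j</sub>²),
   an exact conditional Hardy–Weinberg test with a locus-exclusion rule
   (default p &lt; 0.001), and replicate-PCR genotyping error rates.
2. **Parentage** — trio/pair likelihoods summed over all true-genotype
   states under an error model (allelic dropout d, default 0.01, plus an
   optional random-genotype misprint), a flat prior over the closed,
   temporally feasible candidate pool, and assignment at posterior ≥ 0.80.
   Candidate feasibility uses presence windows offset by the 16-month
   gestation. Replicate power simulations score how often the true father is
   recovered under three information regimes (no pedigree information /
   known mothers / known mothers with cohort-split pools).
3. **Relatedness** — the maximum-likelihood dyadic estimator over
   identity-by-descent modes (EM on the k-coefficient simplex, with the full
   nine-state Jacquard space behind a flag), r = k₂ + k₁/2; plus
   Queller–Goodnight, Lynch–Ritland and Wang-style moment estimators and a
   benchmarking harness over simulated kinship-category dyads.
4. **Skew & selection** — Nonacs' binomial skew index
   B = Σ(p<sub>i</sub> − n<sub>i</sub>/N<sub>t</sub>)² − (1 − 1/Ń)/K with a
   residence-weighted multinomial Monte-Carlo null (one-tailed p), and the
   Bateman gradient β<sub>SS</sub>, the OLS slope of relative reproductive on
   relative mating success.
5. **Correlate screen** — Spearman rank correlations of nine male traits
   (horn-PCA composite, faecal testosterone, territory size, four habitat
   openness fractions, selected-food volume, mean relatedness to females)
   against both fitness components, reported with uncapped Bonferroni
   E-values (E = 9p); Fisher exact 2×2 contrasts and paired Wilcoxon
   signed-rank tests.

## Worked example

Everything is driven by the `matesys` CLI (each subcommand is a thin wrapper
over a library function). A zero-argument demonstration simulates the
default two-cohort dataset — 10 weakly polymorphic loci (each PIC &lt; 0.5),
14 candidate fathers in two cohorts, 51 mothers, 68 offspring, dropout
0.01 — and runs the whole chain:

```text
$ matesys demo --seed 11 --out demo_out
demo complete: 60/68 offspring assigned (88.2%); outputs in demo_out/
```

`demo_out/summary.json` then holds, among the per-stage sections (numbers
from this exact run):

* assignment: 60 of 68 offspring assigned at ≥ 80% posterior, 86.8% of all
  offspring to their true father;
* male skew: B_mat = 0.0147 (p = 0.043, N = 14, K = 49 matings) and
  B_rep = 0.0236 (p = 0.0035, K = 60 offspring) — reproduction is
  significantly more skewed than residence-weighted chance;
* Bateman gradients β_SS ≈ 1.00 (cohort 1) and 1.06 (cohort 2): each extra
  genetic partner brings a proportional gain in offspring;
* sire relatedness: mean r to actual mates 0.087 vs 0.127 to all available
  females (W = 11, p = 0.054 in this draw — no planted kin preference).

Per-stage CSVs (`qc_loci.csv`, `assignments.csv`, `success.csv`,
`screen.csv`, `relatedness_males.csv`) sit next to the JSON. The power of
the assignment design itself:

```text
$ matesys power --scenario 3 --replicates 10 --seed 1
scenario 3: 85.0% +/- 7.5 (10 replicates)
$ matesys power --scenario 2 --replicates 10 --seed 1
scenario 2: 75.0% +/- 9.1 (10 replicates)
```

i.e. with cohort-split candidate pools and known mothers (scenario 3) the
true father is the most likely candidate at ≥ 80% confidence for about 85%
of offspring; dropping the cohort split (scenario 2) costs about ten points,
and hiding the mothers entirely (scenario 1) costs ten more.

Other entry points: `matesys simulate` (export a synthetic dataset),
`qc`, `assign`, `relatedness`, `skew`, `bateman`, `screen`, and `run`
(config-driven pipeline; see `matesys run --help`).

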