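# Methods

This note documents the models implemented in `matesys`, the calibration of
the synthetic-data generator, and the numerical choices a maintainer or
reviewer would want spelled out. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Study system and data model

The package targets closed populations in which every adult is individually
known and tissue-sampled: a small pool of territorial males (two sequential
cohorts in the motivating system), a few dozen females, and offspring with
field-known mothers, genotyped at ~10 codominant microsatellite loci with
two to four alleles each. Genotypes live in a `GenotypeTable`
(individuals × loci × 2 allele indices, with a missing mask); each `Locus`
carries allele labels and population frequencies. Because the species'
genetic diversity is low, every marker is weakly informative
(PIC &lt; 0.5), which is the central difficulty the whole pipeline is built
around.

## Marker QC

* H<sub>e</sub> uses the small-sample unbiased correction
  (2n/(2n−1))(1 − Σp²), the convention of the standard parentage QC tools,
  so PIC ≤ H<sub>e</sub> always holds.
* The Hardy–Weinberg test is the exact conditional test: given the observed
  allele counts, every genotype array is enumerated (DFS over genotype
  categories with margin pruning) and the p-value sums the probabilities of
  arrays no more probable than the observed one. When the enumeration
  budget (2×10⁶ nodes) is exceeded — only relevant far beyond the 4-allele,
  ~120-individual regime used here — a seeded Monte-Carlo permutation of
  the allele vector with the same ordering statistic takes over. Loci with
  p below 0.001 (configurable) are flagged for exclusion, mirroring how a
  marker with null alleles would be discarded.
* Replicate-based error rates: the modal genotype across replicate PCRs is
  the consensus (ties broken by first occurrence, deterministic), and the
  per-locus error rate is the fraction of replicate genotypes differing
  from it. Note the identifiability caveat: a misprint that lands on the
  true genotype is invisible, so the estimator converges to
  m(1 − Σ<sub>g</sub>P(g)²) rather than the raw misprint rate m; tests
  assert consistency against that identifiable target.

## Error model

One model serves both the simulator and the likelihood: a true heterozygote
drops to either homozygote with probability d/2 each (allelic dropout,
default d = 0.01 — a conservative rate for tissue-derived microsatellite
genotypes); independently, with probability m (default 0) the recorded
genotype is replaced by a random Hardy–Weinberg draw. Homozygotes cannot
drop. The same P(observed | true) matrix enters the assignment likelihood,
so simulated data and engine assumptions match exactly.

## Parentage assignment

For offspring o, mother m and candidate father f the per-locus likelihood
is

P(obs<sub>o</sub> | obs<sub>m</sub>, obs<sub>f</sub>) =
Σ P(g<sub>m</sub>|obs<sub>m</sub>) P(g<sub>f</sub>|obs<sub>f</sub>)
T(g<sub>o</sub>|g<sub>m</sub>,g<sub>f</sub>) P(obs<sub>o</sub>|g<sub>o</sub>),

summing over all true genotypes, with parents' true genotypes integrated
over their posterior given their own observed genotype (HWE prior ×
observation model) and T the Mendelian transmission probability.
Conditioning the parents on their own data — rather than multiplying in
their marginal genotype probabilities — keeps candidate comparison free of
a spurious "common genotype" bonus. With error rates at zero a single
opposing-homozygote mismatch drives the log-likelihood to −∞ (hard
exclusion); with dropout at 0.01 it costs a finite ~d/2 factor.

Assignment uses a flat prior over the feasible candidates of a closed pool
(every adult is sampled, so the probability that the true parents are in
the pool is taken as 1): posterior<sub>i</sub> = L<sub>i</sub>/ΣL<sub>j</sub>,
assigned iff the posterior reaches 0.80. Exact likelihood ties are left
unassigned (conservative). When mothers are unknown the engine takes a
flat joint prior over all feasible (mother, father) pairs and assigns on
the father's marginal posterior. Temporal feasibility: a candidate must be
present at conception, birth minus 16 months (rhinoceros gestation), with
half-open presence windows [start, end); candidates with missing dates are
retained with a warning.

This is deliberately *not* joint sibship reconstruction: each offspring is
scored independently. With small, fully sampled pools and mostly known
mothers the pairwise likelihood carries almost all the information, and the
engine stays transparent and desk-scale. The difference shows exactly where
expected — see "Power scenarios" below.

## Synthetic data

The generator's defaults are the study conditions, not tuning knobs.

* **Marker panel.** Microsatellite panels are assembled by screening many
  candidate markers and keeping the best, and in a depauperate species even
  the best stay weak. The generator reproduces that protocol: 60 candidate
  loci (configurable) with 2–4 alleles and symmetric-Dirichlet(α = 1)
  frequencies, candidates at PIC ≥ 0.5 rejected, and the 10 most
  polymorphic admissible candidates kept (panel mean PIC ≈ 0.47, every
  locus &lt; 0.5). Setting `candidate_pool = n_loci` disables selection and
  yields a plain low-polymorphism draw (mean PIC ≈ 0.35); assignment power
  is strongly sensitive to this difference, which is why the selection step
  matters for emulating a real screened panel.
* **Pedigree.** Founders are drawn from HWE at the panel frequencies.
  Offspring counts per father follow a Dirichlet-multinomial
  (concentration 1.0), reproducing strong paternal skew around the target
  mean sibship of 5.6 (13 fathers × 5.6 ≈ 73 offspring in the default
  design); mothers are allocated near-evenly (concentration 10) under a
  litter cap of 5, giving the small maternal sibships of a long-gestation
  grazer. Offspring inherit one allele per parent per locus uniformly;
  errors are applied afterwards to the whole observed table. Birth dates
  are drawn uniformly inside the window where both parents' presence
  covers the conception date; each cohort can include a truncated-residence
  male (present ~2 years), emulating males that died mid-study and giving
  the temporal filter something to do.
* **Kinship dyads.** Parent–offspring, full-sib, half-sib, first-cousin,
  second-cousin and unrelated dyads are built from explicit mini-pedigrees
  (shared parents / grandparents / great-grandparents), so each category is
  exactly realised rather than approximated through target identity
  coefficients. Founders are non-inbred; inbred dyads arise only through
  pedigrees.
* **What is not emulated.** Null alleles, stutter, population structure,
  linkage between loci, age-dependent fertility, and non-random mate
  encounter. Passing tests therefore certify the statistical machinery
  under the stated model, not robustness to those field realities.
* **Covariates.** Per-male horn measurements (four correlated lengths and
  circumferences in cm), faecal testosterone (gamma-distributed around
  ~54 ng/g), territory sizes (12–75 km²), habitat-openness fractions
  (Dirichlet) and transect points are simulated at field-plausible scales
  purely so the screen stage has inputs; no biological claim rides on them.

## Power scenarios

Three information regimes, matrix sizes fixed at the study's: scenario 1 —
13 fathers × 33 mothers, 68 offspring, mothers hidden (joint pair
assignment); scenario 2 — same data with known mothers; scenario 3 — two
cohort-split runs (7 fathers with 28 mothers / 36 offspring and 7 with
23 / 32) with known mothers and one temporally restricted male per cohort.
Scenarios 1 and 2 share identical datasets under the same seed. Power is
the percentage of offspring whose true father is the most likely candidate
at posterior ≥ 0.80, averaged over 10 seeded replicates (the acceptance
script reports mean, SD and total offspring scored).

Information ordering (s3 ≥ s2 ≥ s1) holds at every seed tried. Absolute
levels under the default calibration run ≈ 85% / 75% for scenarios 3 and 2.
Scenario 1 lands in the ~58–73% range depending on seed — somewhat higher
than a sibship-reconstruction analysis reports for the same design, which
is expected: with a closed, fully sampled pool the exact father-marginal
over all 429 parent pairs is a strong extractor even without sibship
clustering, and confidence measures differ between engines.

## Dyadic relatedness

Per locus, the probability of an unordered genotype pair is linear in the
IBD-mode weights: the three k-coefficients (k₀, k₁, k₂) for non-inbred
dyads, or the nine condensed Jacquard states Δ₁..Δ₉ behind
`allow_inbreeding=True`. The 3-mode table uses the classical closed forms;
the 9-state table is built by exhaustive enumeration of allele assignments
to the identity classes of each state (and its (Δ₉, Δ₈, Δ₇) slice equals
the closed forms, which is tested). The multi-locus log-likelihood —
Σ<sub>l</sub> log(P<sub>l</sub>·w) — is therefore concave on the weight
simplex, so EM from the simplex centre attains the global maximum; random
restarts exist (`n_restarts`) but are redundant and default to 1.
Convergence: absolute log-likelihood increase &lt; 1e-8, cap 2000
iterations. Relatedness is r = k₂ + k₁/2, or
r = 2Δ₁ + Δ₃ + Δ₅ + Δ₇ + Δ₈/2 in the Jacquard space; ML estimates are
bounded in [0, 1] by construction. The non-inbred space is the default:
founders are non-inbred, and with 10 weak loci the nine-state space is
poorly identified (it can place weight on inbred states for dyads sharing
homozygotes, shifting r upward — the nesting is tested, the equality is
deliberately not).

Genotyping error is ignored inside the relatedness likelihood by default
(matching the error-free formulations moment estimators use, so the
benchmark compares like with like); an error-aware variant convolves the
pair tables with the observation matrix (`error_model=`).

Moment estimators: Queller–Goodnight (multi-locus ratio form, symmetrised
over reference orderings), Lynch–Ritland (locus-weighted regression form,
symmetrised), and a Wang-style similarity-class estimator that solves the
exact class-probability moment equations for (k₁, k₂) by weighted least
squares (weights 1/[c(1−c)] from the unrelated-dyad class probabilities);
its weighting may differ in detail from Wang's published solution, but it
is exact for pure-class patterns and unbiased by linearity. Moment
estimates are unbounded (r &lt; 0 or &gt; 1 happens routinely at 10 weak
loci) — that is a property of the estimators, not a bug. Monomorphic loci
are skipped; for Queller–Goodnight a heterozygous reference at a biallelic
locus contributes zero denominator and drops out naturally.

Benchmarking simulates dyads per kinship category and reports per-category
medians/quartiles and RMSE against pedigree relatedness, ranking
estimators by overall RMSE. With a PIC-&lt;-0.5 panel the category
distributions overlap heavily; the ML estimator tracks the median truth for
PO/FS/HS/U within ±0.08 but overestimates second cousins (their true
r = 0.03125 sits below the resolution of 10 weak markers, and the ML
boundary at 0 folds the error upward).

## Skew and Bateman statistics

Mating success (`mat`) counts distinct genetic partners; reproductive
success (`rep`) counts assigned offspring; unassigned offspring contribute
to nobody, so both are floors under incomplete assignment. Nonacs' B is
implemented exactly as printed in the field:

B = Σ<sub>i</sub>(p<sub>i</sub> − n<sub>i</sub>/N<sub>t</sub>)² − (1 − 1/Ń)/K,
  Ń = N<sub>t</sub>/n<sub>max</sub>.

The Monte-Carlo null reallocates the K observed benefits multinomially
with probabilities n<sub>i</sub>/N<sub>t</sub> (default 100,000 draws,
seeded) and p = (1 + #{B<sub>null</sub> ≥ B<sub>obs</sub>})/(n<sub>sim</sub>+1),
one-tailed toward excess skew (the directional question; a two-tailed flag
doubles the smaller tail). The +1 smoothing keeps p away from zero.
A subtlety worth recording: the correction term (1 − 1/Ń)/K equals the
exact multinomial variance (1 − Σπ<sub>i</sub>²)/K only when every
n<sub>i</sub> = n<sub>max</sub>; under heterogeneous residence the null
mean of B sits slightly above zero. The Monte-Carlo test is unaffected
(its null is the same multinomial the data are compared to — type-I error
is calibrated, which is tested at the study-like N = 12, K = 70 with
heterogeneous residence), but "B &gt; 0" alone should not be read as skew
when residence varies. When cohorts with different n_max are pooled, each
individual's n<sub>i</sub> is its own calendar presence and Ń uses the
pooled N<sub>t</sub> with the global n_max — a documented interpretation,
since the pooled computation has no single canonical form.

The Bateman gradient is the OLS slope of rep/mean(rep) on mat/mean(mat);
it requires ≥ 3 individuals, positive mean success and variance in mating
success, and errors out explicitly otherwise.

## Correlate screen

The horn composite is the first principal component of the four horn
measurements, centred but not scaled (all share cm units), sign-fixed so
anterior horn length loads positively. Spearman correlations use midrank
ties and the t-approximation p-value (the non-exact mode of the standard
test — appropriate and reproducible at n = 5–6); each cohort × fitness
component screen is exactly nine tests (horn, testosterone, territory
size, four openness fractions, food volume, mean relatedness), and the
Bonferroni correction is reported as uncapped E-values E = 9p. Fisher's
exact test sums hypergeometric probabilities ≤ the observed one and
reports the conditional-ML odds ratio; the paired Wilcoxon reports W = sum
of positive ranks with an exact p for n ≤ 25 without ties (normal
approximation with tie correction otherwise). These elementary tests stand
on scipy; the suite checks them against independent enumeration oracles.

## Pipeline and reproducibility

`run_pipeline` chains QC → assignment → success tabulation → skew/Bateman →
relatedness → screen on a simulated scenario, writing per-stage CSVs and
one JSON summary; every random stream descends from the configured seed
through `SeedSequence.spawn`, so re-runs are byte-identical. A stage
failure aborts with the stage named and partial outputs marked
(`FAILED_STAGE.txt`). The demo pipeline uses 10,000 skew-null draws to
stay interactive; the standalone `matesys skew` command defaults to the
full 100,000.

## Problem sizes

Defaults were chosen as the smallest sizes at which the statistical checks
are stable: 10 replicate power simulations per scenario (50 for the
information-ordering check), 100 dyads per kinship category, 100,000
skew-null draws (2,000 × 499 for the type-I calibration), 500 dyads for
moment-estimator unbiasedness, and 200 randomized cases per
oracle-equivalence suite.

## Known limitations

* No joint sibship reconstruction; scenario-1-style inference is stronger
  here than a reconstruction engine's confidence measure on the same data,
  and assignment rates on *real* data depend on the true (unknown)
  frequency spectrum.
* The Wang-style estimator's least-squares weighting is a reconstruction
  (see above), adequate for benchmarking but not a drop-in for published
  Wang values.
* The exact HWE enumeration is exponential in principle; it silently falls
  back to permutation beyond its node budget.
* Success statistics inherit assignment error: at 80% confidence a few
  percent of offspring are mis-assigned, which slightly inflates skew
  nulls' K and blurs mate counts.
* Relatedness estimators assume known allele frequencies; feeding
  sample-estimated frequencies (the practical case) adds a small bias at
  n ≈ 100 genomes that is not corrected for.
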