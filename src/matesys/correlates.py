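"""Covariate construction and the trait/fitness statistical screen.

Small-n field studies of territorial males cannot support multivariate
models, so the screen is deliberately simple: Spearman rank correlations
of each trait against mating and reproductive success, with a Bonferroni
correction expressed as E-values (p multiplied by the number of tests,
nine per cohort and fitness component, left uncapped), a Fisher exact
test for comparing assignment rates between cohorts, a paired Wilcoxon
signed-rank test for the mate-relatedness contrast, and a centred
(unscaled -- all horn measurements share centimetre units) PCA that
collapses the four horn measurements into one composite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio

BONFERRONI_TESTS = 9

#: the nine screened traits, in report order
SCREEN_TRAITS = (
    "horn_pc1",
    "testosterone",
    "territory_km2",
    "grassland",
    "open_woodland",
    "close_woodland",
    "thickets",
    "food_volume",
    "mean_relatedness",
)

HABITAT_CATEGORIES = ("grassland", "open_woodland", "close_woodland", "thickets")


@dataclass(frozen=True)
class CorrelationResult:
    trait: str
    fitness: str  # "mat" | "rep"
    rho: float
    p: float
    E: float
    n: int


@dataclass
class HornPCA:
    scores: pd.Series
    variance_share: float
    loadings: pd.Series


# ---------------------------------------------------------------------------
# horn composite
# ---------------------------------------------------------------------------


def horn_pc1(horn: pd.DataFrame, anterior_column: str = "anterior_length") -> HornPCA:
    """First principal component of the four horn measurements.

    Centred, unscaled PCA (the measurements share units); the sign is fixed
    so the anterior horn length loads positively, making larger scores mean
    longer front horns.
    """
    if horn.shape[0] < 3:
        raise ValueError("need at least three males")
    if horn.shape[1] != 4:
        raise ValueError("expected exactly four horn measurements")
    for col in horn.columns:
        if np.isclose(horn[col].std(ddof=0), 0.0):
            raise ValueError(f"measurement {col!r} is constant; PCA undefined")
    X = horn.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    load = Vt[0]
    if load[list(horn.columns).index(anterior_column)] < 0:
        load = -load
    scores = Xc @ load
    var = s**2
    return HornPCA(
        scores=pd.Series(scores, index=horn.index, name="horn_pc1"),
        variance_share=float(var[0] / var.sum()),
        loadings=pd.Series(load, index=horn.columns, name="pc1_loading"),
    )


# ---------------------------------------------------------------------------
# elementary tests (library-backed, with the conventions the screen needs)
# ---------------------------------------------------------------------------


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho with midrank ties and the t-approximation p-value
    (the non-exact mode of the usual correlation test)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise ValueError("need n >= 4 per correlation test")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table.

    p sums the hypergeometric probabilities of all tables (with the
    observed margins) no more probable than the observed one; the odds
    ratio is the conditional maximum-likelihood estimate from the
    noncentral hypergeometric likelihood.  A zero margin returns p = 1
    with an undefined (nan) odds ratio.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a non-negative 2x2 integer table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return float("nan"), 1.0
    res_p = stats.fisher_exact(t, alternative="two-sided")
    orr = _odds_ratio(t, kind="conditional")
    return float(orr.statistic), float(res_p.pvalue)


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float] | None = None
) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test.

    Returns W = the sum of the ranks of the positive differences (the
    convention of the standard paired test) and the two-sided p-value:
    exact by sign-pattern enumeration when there are no ties among the
    absolute differences and n <= 25, the tie-corrected normal
    approximation otherwise.  Zero differences are discarded; if all
    differences are zero, p = 1.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    d = d[d != 0]
    if d.size == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    ties = len(np.unique(np.abs(d))) < len(d)
    method = "exact" if (not ties and len(d) <= 25) else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method, correction=False)
    return w_pos, float(res.pvalue)


# ---------------------------------------------------------------------------
# covariate table construction
# ---------------------------------------------------------------------------


def habitat_fractions(transects: pd.DataFrame) -> pd.DataFrame:
    """Per-territory fraction of transect points in each openness category."""
    counts = (
        transects.groupby(["territory", "openness"]).size().unstack(fill_value=0)
    )
    for cat in HABITAT_CATEGORIES:
        if cat not in counts.columns:
            counts[cat] = 0
    counts = counts[list(HABITAT_CATEGORIES)]
    return counts.div(counts.sum(axis=1), axis=0)


def food_volume(transects: pd.DataFrame) -> pd.Series:
    """Mean grass volume (cover x height) over each territory's points."""
    vol = transects["grass_cover"] * transects["grass_height"]
    return vol.groupby(transects["territory"]).mean().rename("food_volume")


def build_covariate_table(
    males: Sequence[str],
    horn: pd.DataFrame,
    hormone_samples: pd.DataFrame,
    territory_sizes: Mapping[str, float],
    transects: pd.DataFrame,
    relatedness_to_females: Mapping[str, float],
) -> pd.DataFrame:
    """Assemble the male covariate table used by the screen.

    hormone_samples: long table with columns ``id`` and ``testosterone``
    (one row per faecal sample); transects: columns ``territory``,
    ``openness``, ``grass_cover``, ``grass_height``.  Males whose
    territory has no transect points get missing habitat covariates and
    are dropped from habitat tests with a warning column.
    """
    pc = horn_pc1(horn.loc[list(males)])
    hormones = hormone_samples.groupby("id")["testosterone"].mean()
    fracs = habitat_fractions(transects)
    vol = food_volume(transects)
    rows = []
    for m in males:
        row: dict = {"id": m, "horn_pc1": float(pc.scores[m])}
        row["testosterone"] = float(hormones[m]) if m in hormones.index else np.nan
        row["territory_km2"] = float(territory_sizes[m])
        if m in fracs.index:
            for cat in HABITAT_CATEGORIES:
                row[cat] = float(fracs.loc[m, cat])
            row["food_volume"] = float(vol[m]) if m in vol.index else np.nan
        else:
            for cat in HABITAT_CATEGORIES:
                row[cat] = np.nan
            row["food_volume"] = np.nan
        row["mean_relatedness"] = float(relatedness_to_females[m])
        rows.append(row)
    df = pd.DataFrame(rows).set_index("id")
    bad = df[HABITAT_CATEGORIES[0]].isna()
    if bad.any():
        import warnings

        warnings.warn(
            f"territories without transect points: {', '.join(df.index[bad])}; "
            "habitat covariates missing"
        )
    return df


# ---------------------------------------------------------------------------
# the screen
# ---------------------------------------------------------------------------


def spearman_screen(
    covariates: pd.DataFrame,
    success: pd.DataFrame,
    traits: Sequence[str] = SCREEN_TRAITS,
    n_tests: int = BONFERRONI_TESTS,
) -> list[CorrelationResult]:
    """Spearman correlations of each trait against mating and reproductive
    success, Bonferroni-corrected into E-values (E = p x n_tests, uncapped).

    ``success`` must carry columns ``mat`` and ``rep`` indexed like
    ``covariates``.  All-tied traits yield an undefined (nan) rho and are
    reported as such rather than dropped.
    """
    results = []
    joined = covariates.join(success[["mat", "rep"]], how="inner")
    for fitness in ("mat", "rep"):
        for trait in traits:
            sub = joined[[trait, fitness]].dropna()
            rho, p = spearman(sub[trait], sub[fitness])
            results.append(
                CorrelationResult(
                    trait=trait,
                    fitness=fitness,
                    rho=rho,
                    p=p,
                    E=p * n_tests,
                    n=len(sub),
                )
            )
    return results


def screen_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"trait": r.trait, "fitness": r.fitness, "n": r.n, "rho": r.rho, "p": r.p, "E": r.E}
            for r in results
        ]
    )
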