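"""Pairwise (dyadic) relatedness estimation from codominant markers.

The workhorse is the maximum-likelihood dyadic estimator: the genotype
pair at each locus has a probability that is *linear* in the weights of
the identity-by-descent modes -- the three k-coefficients (k0, k1, k2)
when neither individual is inbred, or the nine condensed Jacquard states
when inbreeding is allowed -- so the multi-locus log-likelihood is
concave on the weight simplex and EM converges to the global maximum.
Relatedness follows from the weights:

    r = k2 + k1/2                      (no inbreeding)
    r = 2*D1 + D3 + D5 + D7 + D8/2     (Jacquard states D1..D9)

Three classical moment estimators (Queller-Goodnight, Lynch-Ritland and
a Wang-style similarity-class estimator) are provided for benchmarking;
unlike the ML estimator they are unbounded and may fall outside [0, 1].
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_core import GenotypeTable, Locus, ErrorModel

#: condensed Jacquard identity states as partitions of the four gene slots
#: (0, 1 = first individual; 2, 3 = second individual), in D1..D9 order
_JACQUARD_STATES: list[list[list[int]]] = [
    [[0, 1, 2, 3]],
    [[0, 1], [2, 3]],
    [[0, 1, 2], [3]],
    [[0, 1], [2], [3]],
    [[0, 2, 3], [1]],
    [[2, 3], [0], [1]],
    [[0, 2], [1, 3]],
    [[0, 2], [1], [3]],
    [[0], [1], [2], [3]],
]

#: r = c . weights for the two mode spaces
_R_COEF_3 = np.array([0.0, 0.5, 1.0])  # (k0, k1, k2)
_R_COEF_9 = np.array([2.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.5, 0.0])  # D1..D9


@dataclass
class RelatednessEstimate:
    dyad: tuple[str, str]
    estimator: str
    r: float
    k_coefficients: tuple[float, ...] | None = None
    loglik: float | None = None
    converged: bool = True
    n_loci_used: int = 0


@dataclass
class EstimatorBenchmark:
    summary: pd.DataFrame  # estimator x category medians/quartiles/RMSE
    ranking: list[str]  # estimators ordered by overall RMSE (best first)
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# mode-conditional genotype-pair probabilities
# ---------------------------------------------------------------------------


def _genotype_list(k: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(k) for j in range(i, k)]


def pair_probs_k(locus: Locus) -> np.ndarray:
    """(G, G, 3) array of P(G1, G2 | mode) for modes (k0, k1, k2), from the
    classical closed-form table for non-inbred dyads."""
    p = locus.frequencies
    genos = _genotype_list(locus.k)
    G = len(genos)
    out = np.zeros((G, G, 3))
    for x, (a, b) in enumerate(genos):
        for y, (c, d) in enumerate(genos):
            pg1 = p[a] ** 2 if a == b else 2 * p[a] * p[b]
            pg2 = p[c] ** 2 if c == d else 2 * p[c] * p[d]
            out[x, y, 0] = pg1 * pg2
            # k2: both gene pairs identical by descent
            out[x, y, 2] = pg1 if (a, b) == (c, d) else 0.0
            # k1: exactly one pair IBD
            s1, s2 = {a, b}, {c, d}
            if a == b and c == d:
                out[x, y, 1] = p[a] ** 3 if a == c else 0.0
            elif a == b and c != d:
                out[x, y, 1] = p[a] ** 2 * p[({c, d} - {a}).pop()] if a in s2 else 0.0
            elif a != b and c == d:
                out[x, y, 1] = p[c] ** 2 * p[({a, b} - {c}).pop()] if c in s1 else 0.0
            else:
                if s1 == s2:
                    out[x, y, 1] = p[a] * p[b] * (p[a] + p[b])
                else:
                    shared = s1 & s2
                    if len(shared) == 1:
                        x_ = shared.pop()
                        y1 = (s1 - {x_}).pop()
                        y2 = (s2 - {x_}).pop()
                        out[x, y, 1] = p[x_] * p[y1] * p[y2]
    return out


def pair_probs_jacquard(locus: Locus) -> np.ndarray:
    """(G, G, 9) array of P(G1, G2 | Jacquard state D1..D9), by exhaustive
    enumeration of allele assignments to the identity classes of each state.
    The non-inbred modes satisfy (k0, k1, k2) = (D9, D8, D7)."""
    p = locus.frequencies
    genos = _genotype_list(locus.k)
    gidx = {g: t for t, g in enumerate(genos)}
    G = len(genos)
    out = np.zeros((G, G, 9))
    for s, classes in enumerate(_JACQUARD_STATES):
        for assign in itertools.product(range(locus.k), repeat=len(classes)):
            slot = [0, 0, 0, 0]
            prob = 1.0
            for cls, al in zip(classes, assign):
                prob *= p[al]
                for t in cls:
                    slot[t] = al
            g1 = tuple(sorted(slot[:2]))
            g2 = tuple(sorted(slot[2:]))
            out[gidx[g1], gidx[g2], s] += prob
    return out


class ModeTables:
    """Per-locus genotype-pair probability tables for one mode space,
    optionally convolved with the genotyping-error observation model."""

    def __init__(
        self,
        loci: Sequence[Locus],
        allow_inbreeding: bool = False,
        error_model: ErrorModel | None = None,
    ):
        self.loci = list(loci)
        self.allow_inbreeding = allow_inbreeding
        self.n_modes = 9 if allow_inbreeding else 3
        self.r_coef = _R_COEF_9 if allow_inbreeding else _R_COEF_3
        self.tables: list[np.ndarray] = []
        self._geno_index: list[dict[tuple[int, int], int]] = []
        for locus in self.loci:
            tab = pair_probs_jacquard(locus) if allow_inbreeding else pair_probs_k(locus)
            if error_model is not None:
                from .parentage import observation_matrix, hwe_genotype_prior

                genos = _genotype_list(locus.k)
                prior = hwe_genotype_prior(locus.frequencies, genos)
                E = observation_matrix(genos, prior, error_model)
                # P(obs1, obs2 | mode) = E' P(true1, true2 | mode) E
                tab = np.einsum("to,tum,uv->ovm", E, tab, E)
            self.tables.append(tab)
            self._geno_index.append({g: t for t, g in enumerate(_genotype_list(locus.k))})

    def dyad_matrix(self, g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
        """(L_used, n_modes) mode-conditional probabilities for one dyad;
        loci missing in either individual are dropped."""
        rows = []
        for li, tab in enumerate(self.tables):
            a, b = g1[li]
            c, d = g2[li]
            if a < 0 or c < 0:
                continue
            gi = self._geno_index[li][(int(a), int(b))]
            gj = self._geno_index[li][(int(c), int(d))]
            rows.append(tab[gi, gj])
        if not rows:
            return np.empty((0, self.n_modes))
        return np.asarray(rows)


def dyad_loglik(
    g1: np.ndarray,
    g2: np.ndarray,
    loci: Sequence[Locus],
    weights: Sequence[float],
    error_model: ErrorModel | None = None,
    tables: ModeTables | None = None,
) -> float:
    """Multi-locus log-likelihood of a dyad under fixed mode weights."""
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < -1e-12) or abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("mode weights must be a probability vector")
    if tables is None:
        tables = ModeTables(loci, allow_inbreeding=(len(weights) == 9), error_model=error_model)
    P = tables.dyad_matrix(g1, g2)
    vals = P @ weights
    if np.any(vals <= 0.0):
        return -np.inf
    return float(np.log(vals).sum())


# ---------------------------------------------------------------------------
# maximum-likelihood (DyadML-style) estimation
# ---------------------------------------------------------------------------


def _em(P: np.ndarray, w0: np.ndarray, tol: float, max_iter: int) -> tuple[np.ndarray, float, bool]:
    w = w0.copy()
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        num = P * w[np.newaxis, :]
        denom = num.sum(axis=1, keepdims=True)
        if np.any(denom <= 0.0):
            return w, -np.inf, False
        resp = num / denom
        w = resp.mean(axis=0)
        ll = float(np.log(denom).sum())
        if ll - prev < tol and np.isfinite(prev):
            converged = True
            prev = ll
            break
        prev = ll
    return w, prev, converged


def estimate_dyadml(
    g1: np.ndarray,
    g2: np.ndarray,
    loci: Sequence[Locus] | None = None,
    allow_inbreeding: bool = False,
    error_model: ErrorModel | None = None,
    tables: ModeTables | None = None,
    n_restarts: int = 1,
    tol: float = 1e-8,
    max_iter: int = 2000,
    rng: np.random.Generator | None = None,
    dyad: tuple[str, str] = ("1", "2"),
) -> RelatednessEstimate:
    """Maximum-likelihood dyadic relatedness via EM over IBD-mode weights.

    The likelihood is concave in the weights, so the default single start
    from the simplex centre reaches the global maximum; extra random
    restarts are available for belt-and-braces use.
    """
    if tables is None:
        if loci is None:
            raise ValueError("either loci or tables must be given")
        tables = ModeTables(loci, allow_inbreeding=allow_inbreeding, error_model=error_model)
    P = tables.dyad_matrix(g1, g2)
    if P.shape[0] == 0:
        raise ValueError("no informative loci for this dyad")
    M = tables.n_modes
    starts = [np.full(M, 1.0 / M)]
    if n_restarts > 1:
        rng = np.random.default_rng(0) if rng is None else rng
        starts += [rng.dirichlet(np.ones(M)) for _ in range(n_restarts - 1)]
    best_w, best_ll, best_conv = None, -np.inf, False
    for w0 in starts:
        w, ll, conv = _em(P, w0, tol, max_iter)
        if ll > best_ll:
            best_w, best_ll, best_conv = w, ll, conv
    if best_w is None or not np.isfinite(best_ll):
        raise ValueError("zero-probability genotype configuration under all modes")
    r = float(tables.r_coef @ best_w)
    return RelatednessEstimate(
        dyad=dyad,
        estimator="dyadml" + ("_jacquard" if allow_inbreeding else ""),
        r=r,
        k_coefficients=tuple(float(x) for x in best_w),
        loglik=best_ll,
        converged=best_conv,
        n_loci_used=P.shape[0],
    )


# ---------------------------------------------------------------------------
# moment estimators
# ---------------------------------------------------------------------------


def _qg_terms(ref: tuple[int, int], oth: tuple[int, int], p: np.ndarray) -> tuple[float, float]:
    a, b = ref
    c, d = oth
    sim = 0.5 * ((a == c) + (a == d) + (b == c) + (b == d))
    num = sim - p[a] - p[b]
    den = 1.0 + (a == b) - p[a] - p[b]
    return num, den


def _lr_terms(ref: tuple[int, int], oth: tuple[int, int], p: np.ndarray) -> tuple[float, float]:
    # Lynch & Ritland (1999) single-locus regression estimator; returns the
    # numerator and denominator of the weighted multi-locus ratio.
    a, b = ref
    c, d = oth
    pa, pb = p[a], p[b]
    num = pa * ((b == c) + (b == d)) + pb * ((a == c) + (a == d)) - 4.0 * pa * pb
    den = (1.0 + (a == b)) * (pa + pb) - 4.0 * pa * pb
    w = 2.0 * pa * pb
    return num / w, den / w


def _wang_class(g1: tuple[int, int], g2: tuple[int, int]) -> int:
    """Similarity class: 0 identical genotypes, 1 homozygote vs sharing
    heterozygote, 2 heterozygotes sharing exactly one allele, 3 no shared
    alleles / remaining patterns."""
    a, b = g1
    c, d = g2
    if (a, b) == (c, d):
        return 0
    s1, s2 = {a, b}, {c, d}
    shared = s1 & s2
    if not shared:
        return 3
    if a == b or c == d:
        return 1 if len(shared) == 1 else 3
    return 2 if len(shared) == 1 else 3


def _wang_class_probs(locus: Locus) -> np.ndarray:
    """(3 modes, 4 classes) exact class probabilities per IBD mode."""
    tab = pair_probs_k(locus)
    genos = _genotype_list(locus.k)
    out = np.zeros((3, 4))
    for x, gx in enumerate(genos):
        for y, gy in enumerate(genos):
            cls = _wang_class(gx, gy)
            out[:, cls] += tab[x, y, :]
    return out


def estimate_moment(
    g1: np.ndarray,
    g2: np.ndarray,
    loci: Sequence[Locus],
    estimator: str = "queller_goodnight",
    dyad: tuple[str, str] = ("1", "2"),
) -> RelatednessEstimate:
    """Moment estimators of relatedness.

    queller_goodnight: multi-locus ratio estimator, symmetrised over the
    two reference orderings.  lynch_ritland: locus-weighted regression
    estimator, also symmetrised.  wang: similarity-class estimator solving
    the exact class-probability moment equations for (k1, k2) by weighted
    least squares and returning r = k2 + k1/2.  Monomorphic (or otherwise
    uninformative) loci are skipped; estimates are unbounded.
    """
    used = 0
    if estimator in ("queller_goodnight", "lynch_ritland"):
        terms = _qg_terms if estimator == "queller_goodnight" else _lr_terms
        num = den = 0.0
        for li, locus in enumerate(loci):
            a, b = int(g1[li, 0]), int(g1[li, 1])
            c, d = int(g2[li, 0]), int(g2[li, 1])
            if a < 0 or c < 0 or locus.k < 2:
                continue
            p = locus.frequencies
            if np.max(p) >= 1.0 - 1e-12:
                continue
            n1, d1 = terms((a, b), (c, d), p)
            n2, d2 = terms((c, d), (a, b), p)
            num += n1 + n2
            den += d1 + d2
            used += 1
        if used == 0 or den == 0.0:
            raise ValueError("no informative loci for this dyad")
        r = num / den
        k = None
    elif estimator == "wang":
        rows_A, rows_y, weights = [], [], []
        for li, locus in enumerate(loci):
            a, c = int(g1[li, 0]), int(g2[li, 0])
            if a < 0 or c < 0 or locus.k < 2:
                continue
            p = locus.frequencies
            if np.max(p) >= 1.0 - 1e-12:
                continue
            cp = _wang_class_probs(locus)  # (mode, class)
            obs = np.zeros(4)
            obs[_wang_class((int(g1[li, 0]), int(g1[li, 1])), (int(g2[li, 0]), int(g2[li, 1])))] = 1.0
            for cls in range(3):  # class 4 is redundant (probabilities sum to 1)
                var0 = cp[0, cls] * (1.0 - cp[0, cls])
                if var0 <= 1e-12:
                    continue
                rows_A.append([cp[1, cls] - cp[0, cls], cp[2, cls] - cp[0, cls]])
                rows_y.append(obs[cls] - cp[0, cls])
                weights.append(1.0 / var0)
            used += 1
        if used == 0:
            raise ValueError("no informative loci for this dyad")
        A = np.asarray(rows_A)
        y = np.asarray(rows_y)
        w = np.sqrt(np.asarray(weights))
        sol, *_ = np.linalg.lstsq(A * w[:, None], y * w, rcond=None)
        k1, k2 = float(sol[0]), float(sol[1])
        r = k2 + 0.5 * k1
        k = (1.0 - k1 - k2, k1, k2)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return RelatednessEstimate(dyad=dyad, estimator=estimator, r=float(r), k_coefficients=k, n_loci_used=used)


# ---------------------------------------------------------------------------
# benchmarking on simulated dyads
# ---------------------------------------------------------------------------

_DEFAULT_ESTIMATORS = ("dyadml", "queller_goodnight", "lynch_ritland", "wang")


def estimate_any(
    g1: np.ndarray,
    g2: np.ndarray,
    loci: Sequence[Locus],
    estimator: str,
    tables: ModeTables | None = None,
    **kwargs,
) -> RelatednessEstimate:
    if estimator.startswith("dyadml"):
        return estimate_dyadml(
            g1, g2, loci,
            allow_inbreeding=estimator.endswith("jacquard"),
            tables=tables, **kwargs,
        )
    return estimate_moment(g1, g2, loci, estimator)


def benchmark_estimators(
    dyads_by_category: Mapping[str, tuple[np.ndarray, np.ndarray]],
    loci: Sequence[Locus],
    r_true: Mapping[str, float],
    estimators: Sequence[str] = _DEFAULT_ESTIMATORS,
) -> EstimatorBenchmark:
    """Score estimators on simulated kinship-category dyads.

    Reports per-category medians and quartiles plus RMSE against the
    pedigree relatedness, and ranks estimators by overall RMSE.  With the
    weakly polymorphic panels used here the category distributions overlap
    substantially; the ranking orders estimators, it does not certify
    separation.
    """
    if len(estimators) < 2 or len(dyads_by_category) < 2:
        raise ValueError("need at least two estimators and two dyad categories")
    def _name(est) -> str:
        return est if isinstance(est, str) else est[0]

    warnings_ = []
    tables = ModeTables(loci, allow_inbreeding=False)
    tables9 = None
    rows = []
    sq_err: dict[str, list[float]] = {_name(e): [] for e in estimators}
    for cat, (g1s, g2s) in dyads_by_category.items():
        if len(g1s) == 0:
            warnings_.append(f"category {cat} empty; excluded")
            continue
        rt = r_true[cat]
        for est_spec in estimators:
            est = _name(est_spec)
            tab = tables
            if est == "dyadml_jacquard":
                if tables9 is None:
                    tables9 = ModeTables(loci, allow_inbreeding=True)
                tab = tables9
            if isinstance(est_spec, str):
                vals = [
                    estimate_any(g1, g2, loci, est, tables=tab).r
                    for g1, g2 in zip(g1s, g2s)
                ]
            else:  # (name, callable) pair, e.g. a reference estimator
                fn = est_spec[1]
                vals = [float(fn(g1, g2, loci)) for g1, g2 in zip(g1s, g2s)]
            vals = np.asarray(vals)
            sq_err[est].extend(((vals - rt) ** 2).tolist())
            rows.append(
                {
                    "estimator": est,
                    "category": cat,
                    "r_true": rt,
                    "n": len(vals),
                    "median": float(np.median(vals)),
                    "q1": float(np.percentile(vals, 25)),
                    "q3": float(np.percentile(vals, 75)),
                    "rmse": float(np.sqrt(np.mean((vals - rt) ** 2))),
                }
            )
    summary = pd.DataFrame(rows)
    overall = {e: float(np.sqrt(np.mean(v))) for e, v in sq_err.items() if v}
    ranking = sorted(overall, key=overall.get)
    return EstimatorBenchmark(summary=summary, ranking=ranking, warnings=warnings_)


# ---------------------------------------------------------------------------
# sires' relatedness to mates vs available females
# ---------------------------------------------------------------------------


@dataclass
class MateRelatednessComparison:
    per_male: pd.DataFrame  # male, n_mates, mean_r_mates, mean_r_available
    mean_mates: float
    mean_available: float
    w_statistic: float
    p_value: float


def compare_mate_relatedness(
    mates: Mapping[str, Sequence[str]],
    table: GenotypeTable,
    females_available: Sequence[str],
    estimator: str = "dyadml",
    allow_inbreeding: bool = False,
) -> MateRelatednessComparison:
    """Do sires mate with females more or less related than the available
    pool?  Per male with >= 1 mate: mean relatedness to actual mates and to
    all available females; the male-level pairs go into a two-sided paired
    Wilcoxon signed-rank test."""
    from .correlates import wilcoxon_signed_rank

    males = [m for m, ms in mates.items() if len(ms) > 0]
    if len(males) < 2:
        raise ValueError("need at least two males with mates")
    tables = ModeTables(table.loci, allow_inbreeding=allow_inbreeding) if estimator.startswith("dyadml") else None

    def r_of(a: str, b: str) -> float:
        g1, g2 = table.row(a), table.row(b)
        return estimate_any(g1, g2, table.loci, estimator, tables=tables, dyad=(a, b)).r

    rows = []
    for m in males:
        r_mates = [r_of(m, f) for f in mates[m]]
        r_avail = [r_of(m, f) for f in females_available]
        rows.append(
            {
                "male": m,
                "n_mates": len(r_mates),
                "mean_r_mates": float(np.mean(r_mates)),
                "mean_r_available": float(np.mean(r_avail)),
            }
        )
    df = pd.DataFrame(rows)
    w, p = wilcoxon_signed_rank(df["mean_r_mates"].to_numpy(), df["mean_r_available"].to_numpy())
    return MateRelatednessComparison(
        per_male=df,
        mean_mates=float(df["mean_r_mates"].mean()),
        mean_available=float(df["mean_r_available"].mean()),
        w_statistic=w,
        p_value=p,
    )
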