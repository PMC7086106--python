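"""Likelihood-based parentage assignment with a genotyping-error model.

Fathers (or joint mother-father pairs when maternity is unknown) are
assigned by comparing trio likelihoods across a closed candidate pool.
Per locus the likelihood sums over all true-genotype states of the trio,
weighting observed genotypes by an error model (allelic dropout plus a
random-genotype misprint), so a single Mendelian mismatch is penalised
rather than hard-excluding a candidate.  With a flat prior over the
feasible candidates the normalised likelihoods are posterior
probabilities, and a candidate is *assigned* when its posterior reaches a
confidence threshold (default 0.80).  Temporal feasibility restricts the
pool: a candidate can only be a parent if the offspring's conception date
(birth minus the 16-month gestation) falls inside the candidate's
presence window (half-open ``[start, end)``).

The engine deliberately scores each offspring independently (no joint
sibship reconstruction): the candidate pools here are small, fully
sampled, and mothers are mostly field-known, which is when independent
trio likelihoods carry almost all of the information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .genotype_core import ErrorModel, GenotypeTable, Locus, MISSING

GESTATION_MONTHS = 16  # average gestation of the white rhinoceros

DEFAULT_CONFIDENCE = 0.80


# ---------------------------------------------------------------------------
# roster and result types
# ---------------------------------------------------------------------------


def add_months(d: date, months: int) -> date:
    """Calendar-month offset (day clamped to the target month's length)."""
    y, m = divmod(d.month - 1 + months, 12)
    year = d.year + y
    month = m + 1
    day = d.day
    while day > 28:
        try:
            return date(year, month, day)
        except ValueError:
            day -= 1
    return date(year, month, day)


@dataclass(frozen=True)
class RosterEntry:
    """One candidate parent: presence window is half-open [start, end)."""

    id: str
    sex: str  # "M" or "F"
    cohort: str = ""
    start: date | None = None
    end: date | None = None
    sampled: bool = True

    def __post_init__(self):
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.start is not None and self.end is not None and not self.start < self.end:
            raise ValueError(f"{self.id}: presence window must satisfy start < end")


class CandidateRoster:
    """Candidate mothers and fathers with presence windows and cohorts.

    The pool is treated as closed: the probability that both true parents
    are among the candidates is taken to be 1 (every adult was individually
    known and sampled).
    """

    def __init__(self, entries: Iterable[RosterEntry]):
        self.entries = list(entries)
        ids = [e.id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate ids in roster")
        self._by_id = {e.id: e for e in self.entries}

    def __getitem__(self, id_: str) -> RosterEntry:
        return self._by_id[id_]

    def __contains__(self, id_: str) -> bool:
        return id_ in self._by_id

    def __iter__(self):
        return iter(self.entries)

    def males(self) -> list[RosterEntry]:
        return [e for e in self.entries if e.sex == "M"]

    def females(self) -> list[RosterEntry]:
        return [e for e in self.entries if e.sex == "F"]

    def residence_years(self, id_: str) -> float:
        e = self._by_id[id_]
        if e.start is None or e.end is None:
            raise ValueError(f"{id_}: no presence window")
        return (e.end - e.start).days / 365.25


@dataclass
class AssignmentResult:
    offspring: str
    best_father: str | None
    posterior: float
    likelihoods: dict[str, float]  # candidate -> log-likelihood
    posteriors: dict[str, float]
    assigned: bool
    threshold: float = DEFAULT_CONFIDENCE
    status: str = "ok"  # ok | all_excluded | tie | no_candidates


@dataclass
class PowerSummary:
    scenario: int
    replicates: int
    mean_percent: float
    sd_percent: float
    percent_per_replicate: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# per-locus likelihood machinery
# ---------------------------------------------------------------------------


@dataclass
class LocusContext:
    """Precomputed arrays for one locus.

    genotypes: list of unordered allele-index pairs (i <= j)
    prior:     HWE genotype prior from the locus allele frequencies
    trans:     trans[gm, gf, go] Mendelian transmission probability
    obs_lik:   obs_lik[g_true, g_obs] observation model under the error model
    """

    locus: Locus
    genotypes: list[tuple[int, int]]
    geno_index: dict[tuple[int, int], int]
    prior: np.ndarray
    trans: np.ndarray
    obs_lik: np.ndarray


def _genotype_list(k: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(k) for j in range(i, k)]


def hwe_genotype_prior(p: np.ndarray, genotypes: Sequence[tuple[int, int]]) -> np.ndarray:
    out = np.empty(len(genotypes))
    for g, (i, j) in enumerate(genotypes):
        out[g] = p[i] ** 2 if i == j else 2 * p[i] * p[j]
    return out


def _transmission_tensor(genotypes: Sequence[tuple[int, int]], k: int) -> np.ndarray:
    G = len(genotypes)
    # per-parent allele transmission: P(transmit allele a | genotype)
    tp = np.zeros((G, k))
    for g, (i, j) in enumerate(genotypes):
        tp[g, i] += 0.5
        tp[g, j] += 0.5
    trans = np.zeros((G, G, G))
    gidx = {g: t for t, g in enumerate(genotypes)}
    for gm in range(G):
        for gf in range(G):
            for a in range(k):
                pa = tp[gm, a]
                if pa == 0:
                    continue
                for b in range(k):
                    pb = tp[gf, b]
                    if pb == 0:
                        continue
                    go = gidx[(a, b) if a <= b else (b, a)]
                    trans[gm, gf, go] += pa * pb
    return trans


def observation_matrix(
    genotypes: Sequence[tuple[int, int]], prior: np.ndarray, error_model: ErrorModel
) -> np.ndarray:
    """P(observed genotype | true genotype) under dropout + misprint.

    A true heterozygote drops to either homozygote with probability d/2
    each; independently, with probability m the record is replaced by a
    random Hardy-Weinberg draw.
    """
    G = len(genotypes)
    d, m = error_model.dropout_rate, error_model.misprint_rate
    drop = np.zeros((G, G))
    gidx = {g: t for t, g in enumerate(genotypes)}
    for g, (i, j) in enumerate(genotypes):
        if i == j:
            drop[g, g] = 1.0
        else:
            drop[g, g] = 1.0 - d
            drop[g, gidx[(i, i)]] = d / 2.0
            drop[g, gidx[(j, j)]] = d / 2.0
    return (1.0 - m) * drop + m * prior[np.newaxis, :]


def build_locus_contexts(loci: Sequence[Locus], error_model: ErrorModel) -> list[LocusContext]:
    contexts = []
    for locus in loci:
        genotypes = _genotype_list(locus.k)
        prior = hwe_genotype_prior(locus.frequencies, genotypes)
        trans = _transmission_tensor(genotypes, locus.k)
        obs = observation_matrix(genotypes, prior, error_model)
        contexts.append(
            LocusContext(
                locus=locus,
                genotypes=genotypes,
                geno_index={g: t for t, g in enumerate(genotypes)},
                prior=prior,
                trans=trans,
                obs_lik=obs,
            )
        )
    return contexts


class LikelihoodEngine:
    """Vectorised trio/pair likelihoods for one genotype table."""

    def __init__(self, table: GenotypeTable, error_model: ErrorModel = ErrorModel()):
        self.table = table
        self.error_model = error_model
        self.contexts = build_locus_contexts(table.loci, error_model)
        self._geno_codes = self._encode_calls()
        # genotype posterior P(g_true | obs) per individual and locus, and
        # offspring observation vectors P(obs | g_true)
        self._post = []
        self._obsvec = []
        for li, ctx in enumerate(self.contexts):
            G = len(ctx.genotypes)
            codes = self._geno_codes[:, li]
            post = np.tile(ctx.prior, (self.table.n, 1))
            obsv = np.ones((self.table.n, G))
            typed = codes >= 0
            if typed.any():
                lik = ctx.obs_lik[:, codes[typed]].T  # (n_typed, G_true)
                w = ctx.prior[np.newaxis, :] * lik
                post[typed] = w / w.sum(axis=1, keepdims=True)
                obsv[typed] = lik
            self._post.append(post)
            self._obsvec.append(obsv)

    def _encode_calls(self) -> np.ndarray:
        n, L = self.table.n, self.table.n_loci
        codes = np.full((n, L), -1, dtype=np.int32)
        for li, ctx in enumerate(self.contexts):
            col = self.table.calls[:, li]
            for r in range(n):
                a, b = col[r]
                if a >= 0:
                    codes[r, li] = ctx.geno_index[(int(a), int(b))]
        return codes

    def idx(self, individual: str) -> int:
        return self.table._index[individual]

    # -- likelihood kernels -------------------------------------------------

    def trio_loglik(self, offspring: str, mother: str | None, father: str) -> float:
        """Log-likelihood of the offspring's observed genotypes given the
        (candidate) parents' observed genotypes; parents' true genotypes are
        integrated over their genotype posteriors, the offspring over the
        observation model.  Missing offspring loci are skipped."""
        oi = self.idx(offspring)
        fi = self.idx(father)
        mi = self.idx(mother) if mother is not None else None
        total = 0.0
        for li, ctx in enumerate(self.contexts):
            if self._geno_codes[oi, li] < 0:
                continue
            ov = self._obsvec[li][oi]
            W = ctx.trans @ ov  # (Gm, Gf)
            pm = self._post[li][mi] if mi is not None else ctx.prior
            pf = self._post[li][fi]
            val = float(pm @ W @ pf)
            if val <= 0.0:
                return -np.inf
            total += np.log(val)
        return total

    def father_logliks(self, offspring: str, mother: str | None, fathers: Sequence[str]) -> np.ndarray:
        oi = self.idx(offspring)
        fids = np.array([self.idx(f) for f in fathers])
        mi = self.idx(mother) if mother is not None else None
        out = np.zeros(len(fathers))
        for li, ctx in enumerate(self.contexts):
            if self._geno_codes[oi, li] < 0:
                continue
            W = ctx.trans @ self._obsvec[li][oi]
            pm = self._post[li][mi] if mi is not None else ctx.prior
            row = pm @ W  # (Gf,)
            vals = self._post[li][fids] @ row
            with np.errstate(divide="ignore"):
                out += np.log(vals)
        return out

    def pair_logliks(
        self, offspring: str, mothers: Sequence[str], fathers: Sequence[str]
    ) -> np.ndarray:
        """(n_mothers, n_fathers) joint log-likelihood matrix."""
        oi = self.idx(offspring)
        mids = np.array([self.idx(m) for m in mothers])
        fids = np.array([self.idx(f) for f in fathers])
        out = np.zeros((len(mothers), len(fathers)))
        for li, ctx in enumerate(self.contexts):
            if self._geno_codes[oi, li] < 0:
                continue
            W = ctx.trans @ self._obsvec[li][oi]
            vals = self._post[li][mids] @ W @ self._post[li][fids].T
            with np.errstate(divide="ignore"):
                out += np.log(vals)
        return out


def trio_loglik(
    offspring: str,
    mother: str | None,
    father: str,
    table: GenotypeTable,
    error_model: ErrorModel = ErrorModel(),
) -> float:
    """Convenience wrapper building a one-shot :class:`LikelihoodEngine`."""
    return LikelihoodEngine(table, error_model).trio_loglik(offspring, mother, father)


# ---------------------------------------------------------------------------
# temporal feasibility
# ---------------------------------------------------------------------------


def filter_candidates_by_window(
    birth_date: date | None,
    candidates: Sequence[RosterEntry],
    gestation_months: int = GESTATION_MONTHS,
) -> list[RosterEntry]:
    """Candidates whose presence window contains the conception date.

    Conception is the birth date minus the gestation; windows are half-open
    ``[start, end)``.  Candidates (or offspring) without dates are retained
    with a warning -- a permissive default so incomplete field records do
    not silently drop true parents.
    """
    if birth_date is None:
        warnings.warn("offspring has no birth date; temporal filter skipped")
        return list(candidates)
    conception = add_months(birth_date, -gestation_months)
    feasible = []
    for c in candidates:
        if c.start is None or c.end is None:
            warnings.warn(f"candidate {c.id} has no presence window; retained")
            feasible.append(c)
        elif c.start <= conception < c.end:
            feasible.append(c)
    return feasible


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------


def _posterior_from_logliks(logliks: np.ndarray) -> np.ndarray | None:
    finite = np.isfinite(logliks)
    if not finite.any():
        return None
    post = np.zeros_like(logliks)
    z = logsumexp(logliks[finite])
    post[finite] = np.exp(logliks[finite] - z)
    return post


def _resolve(
    offspring: str,
    names: list[str],
    logliks: np.ndarray,
    posteriors: np.ndarray | None,
    threshold: float,
) -> AssignmentResult:
    liks = dict(zip(names, map(float, logliks)))
    if posteriors is None:
        return AssignmentResult(
            offspring, None, 0.0, liks, {n: 0.0 for n in names}, False, threshold, "all_excluded"
        )
    posts = dict(zip(names, map(float, posteriors)))
    order = np.argsort(posteriors)[::-1]
    best = int(order[0])
    top = posteriors[best]
    tie = len(order) > 1 and np.isclose(posteriors[int(order[1])], top, rtol=1e-9, atol=1e-12)
    if tie:
        return AssignmentResult(offspring, None, float(top), liks, posts, False, threshold, "tie")
    assigned = bool(top >= threshold)
    return AssignmentResult(offspring, names[best], float(top), liks, posts, assigned, threshold)


def assign_father(
    offspring: str,
    known_mother: str | None,
    engine: LikelihoodEngine,
    candidates: Sequence[RosterEntry],
    birth_date: date | None = None,
    threshold: float = DEFAULT_CONFIDENCE,
    gestation_months: int = GESTATION_MONTHS,
) -> AssignmentResult:
    """Assign a father by flat-prior posterior over feasible candidates."""
    feasible = filter_candidates_by_window(birth_date, candidates, gestation_months) if any(
        c.start is not None for c in candidates
    ) else list(candidates)
    if not feasible:
        return AssignmentResult(offspring, None, 0.0, {}, {}, False, threshold, "no_candidates")
    names = [c.id for c in feasible]
    logliks = engine.father_logliks(offspring, known_mother, names)
    return _resolve(offspring, names, logliks, _posterior_from_logliks(logliks), threshold)


def assign_parent_pair(
    offspring: str,
    engine: LikelihoodEngine,
    mother_candidates: Sequence[RosterEntry],
    father_candidates: Sequence[RosterEntry],
    birth_date: date | None = None,
    threshold: float = DEFAULT_CONFIDENCE,
    gestation_months: int = GESTATION_MONTHS,
) -> AssignmentResult:
    """Joint flat prior over feasible (mother, father) pairs; the father's
    marginal posterior drives the assignment."""
    dated = any(c.start is not None for c in list(mother_candidates) + list(father_candidates))
    moms = (
        filter_candidates_by_window(birth_date, mother_candidates, gestation_months)
        if dated
        else list(mother_candidates)
    )
    dads = (
        filter_candidates_by_window(birth_date, father_candidates, gestation_months)
        if dated
        else list(father_candidates)
    )
    if not moms or not dads:
        return AssignmentResult(offspring, None, 0.0, {}, {}, False, threshold, "no_candidates")
    mnames = [c.id for c in moms]
    fnames = [c.id for c in dads]
    joint = engine.pair_logliks(offspring, mnames, fnames)
    finite = np.isfinite(joint)
    if not finite.any():
        return AssignmentResult(
            offspring, None, 0.0, {f: -np.inf for f in fnames},
            {f: 0.0 for f in fnames}, False, threshold, "all_excluded",
        )
    z = logsumexp(joint[finite])
    with np.errstate(divide="ignore"):
        marg = np.array([logsumexp(joint[:, j][np.isfinite(joint[:, j])]) if np.isfinite(joint[:, j]).any() else -np.inf for j in range(len(fnames))])
    posteriors = np.exp(np.where(np.isfinite(marg), marg - z, -np.inf))
    return _resolve(offspring, fnames, marg, posteriors, threshold)


def assign_all(
    engine: LikelihoodEngine,
    roster: CandidateRoster,
    offspring_ids: Sequence[str],
    known_mothers: Mapping[str, str] | None = None,
    birth_dates: Mapping[str, date] | None = None,
    threshold: float = DEFAULT_CONFIDENCE,
) -> list[AssignmentResult]:
    """Assign every offspring; uses known maternity when available, joint
    parent-pair marginalisation otherwise."""
    results = []
    males = roster.males()
    females = roster.females()
    for off in offspring_ids:
        bd = birth_dates.get(off) if birth_dates else None
        mother = known_mothers.get(off) if known_mothers else None
        if mother is not None:
            res = assign_father(off, mother, engine, males, bd, threshold)
        else:
            res = assign_parent_pair(off, engine, females, males, bd, threshold)
        results.append(res)
    return results


# ---------------------------------------------------------------------------
# scenario power simulations
# ---------------------------------------------------------------------------


def run_scenario_power(
    scenario_id: int,
    design=None,
    replicates: int = 10,
    seed: int = 0,
    threshold: float = DEFAULT_CONFIDENCE,
    error_model: ErrorModel | None = None,
) -> PowerSummary:
    """Percentage of offspring whose true father is recovered as the most
    likely candidate at the confidence threshold, per replicate simulation.

    Scenarios differ only in the information handed to the engine:
    1. one pooled candidate set, maternity unknown (joint pair assignment);
    2. same data with known mother-offspring links;
    3. cohort-split candidate pools with known mothers and temporal
       restrictions.
    """
    from . import synthetic_data as sd  # deferred: synthetic_data builds on roster types

    percents = []
    children = np.random.SeedSequence(seed).spawn(replicates)
    for child in children:
        rng = np.random.default_rng(child)
        bundle = sd.build_scenario(scenario_id, design=design, rng=rng)
        n_total = 0
        n_correct = 0
        for run in bundle.runs:
            em = error_model if error_model is not None else run.design.error_model
            engine = LikelihoodEngine(run.table, em)
            results = assign_all(
                engine,
                run.roster,
                list(run.truth.parents),
                known_mothers=run.known_mothers,
                birth_dates=run.truth.birth_dates,
                threshold=threshold,
            )
            for res in results:
                n_total += 1
                true_father = run.truth.parents[res.offspring][1]
                if res.assigned and res.best_father == true_father:
                    n_correct += 1
        percents.append(100.0 * n_correct / n_total)
    arr = np.asarray(percents)
    return PowerSummary(
        scenario=scenario_id,
        replicates=replicates,
        mean_percent=float(arr.mean()),
        sd_percent=float(arr.std(ddof=1)) if replicates > 1 else 0.0,
        percent_per_replicate=[float(x) for x in arr],
    )
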