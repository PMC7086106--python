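"""Reproductive skew and sexual-selection statistics.

Mating success (``mat``) counts an individual's distinct genetic
partners; reproductive success (``rep``) counts its assigned offspring.
Skew in either quantity is tested with Nonacs' binomial skew index

    B = sum_i (p_i - n_i / N_t)^2  -  (1 - 1/N') / K

where p_i is individual i's share of the K benefits, n_i its residence
time, N_t = sum n_i, and N' = N_t / n_max the residence-weighted group
size (n_max being the longest residence any member could have had).  B
compares the observed variance in benefit shares with the binomial
variance expected from demographic stochasticity alone, corrected for
unequal residence.  Significance comes from a Monte-Carlo null that
reallocates the K benefits multinomially with probabilities n_i / N_t.
Note the correction term equals the exact multinomial variance only when
every n_i = n_max; under heterogeneous residence the null mean of B sits
slightly above zero, which the Monte-Carlo test absorbs by construction.

The Bateman gradient beta_SS is the OLS slope of relative reproductive
success on relative mating success (both scaled by their group means): a
slope near 1 means each extra genetic partner brings a proportional
increase in offspring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .parentage import AssignmentResult, CandidateRoster


@dataclass(frozen=True)
class SuccessRecord:
    id: str
    sex: str
    cohort: str
    mat: int  # distinct genetic partners
    rep: int  # assigned offspring
    n_i: float  # residence time, years

    def __post_init__(self):
        if self.mat < 0 or self.rep < 0 or self.mat > self.rep:
            raise ValueError(f"{self.id}: need 0 <= mat <= rep")
        if self.n_i <= 0:
            raise ValueError(f"{self.id}: residence time must be positive")


@dataclass
class SkewResult:
    B: float
    K: int
    N: int
    N_t: float
    N_bar: float
    n_max: float
    p: float
    null_sample: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))
    alternative: str = "greater"


@dataclass
class BatemanResult:
    beta_ss: float
    n: int
    relative_mat: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))
    relative_rep: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))


# ---------------------------------------------------------------------------
# success tabulation
# ---------------------------------------------------------------------------


def tabulate_success(
    assignments: Sequence[AssignmentResult],
    known_mothers: Mapping[str, str],
    roster: CandidateRoster,
    residence: Mapping[str, float] | None = None,
) -> list[SuccessRecord]:
    """Per-individual mating and reproductive success from assignments.

    Only offspring with an assigned father contribute; each contributes one
    unit of reproductive success to its father and its mother, and partners
    are counted once however many offspring they share.  Residence defaults
    to the roster presence window length in years.
    """
    partners: dict[str, set[str]] = {e.id: set() for e in roster}
    n_off: dict[str, int] = {e.id: 0 for e in roster}
    for res in assignments:
        if not res.assigned or res.best_father is None:
            continue
        father = res.best_father
        mother = known_mothers.get(res.offspring)
        if father not in partners:
            raise ValueError(f"father {father} absent from roster")
        n_off[father] += 1
        if mother is not None:
            if mother not in partners:
                raise ValueError(f"mother {mother} absent from roster")
            partners[father].add(mother)
            partners[mother].add(father)
            n_off[mother] += 1
    records = []
    for entry in roster:
        n_i = (
            residence[entry.id]
            if residence is not None
            else roster.residence_years(entry.id)
        )
        records.append(
            SuccessRecord(
                id=entry.id,
                sex=entry.sex,
                cohort=entry.cohort,
                mat=len(partners[entry.id]),
                rep=n_off[entry.id],
                n_i=n_i,
            )
        )
    return records


def success_frame(records: Sequence[SuccessRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"id": r.id, "sex": r.sex, "cohort": r.cohort, "mat": r.mat, "rep": r.rep, "n_i": r.n_i}
            for r in records
        ]
    )


# ---------------------------------------------------------------------------
# Nonacs' binomial skew index
# ---------------------------------------------------------------------------


def _benefits_residence(
    records: Sequence[SuccessRecord], benefit: str
) -> tuple[np.ndarray, np.ndarray]:
    if benefit not in ("mat", "rep"):
        raise ValueError("benefit must be 'mat' or 'rep'")
    x = np.array([getattr(r, benefit) for r in records], dtype=float)
    n = np.array([r.n_i for r in records], dtype=float)
    return x, n


def nonacs_b_values(benefits: np.ndarray, residence: np.ndarray, n_max: float) -> np.ndarray:
    """Vectorised B for a (n_samples, N) matrix of benefit vectors."""
    benefits = np.atleast_2d(np.asarray(benefits, dtype=float))
    residence = np.asarray(residence, dtype=float)
    K = benefits.sum(axis=1)
    if np.any(K <= 0):
        raise ValueError("total benefits K must be positive")
    N_t = residence.sum()
    N_bar = N_t / n_max
    shares = benefits / K[:, None]
    expected = residence / N_t
    obs_var = ((shares - expected[None, :]) ** 2).sum(axis=1)
    return obs_var - (1.0 - 1.0 / N_bar) / K


def nonacs_b(
    records: Sequence[SuccessRecord], n_max: float, benefit: str = "rep"
) -> float:
    """Observed Nonacs' B for a group of individuals."""
    x, n = _benefits_residence(records, benefit)
    return float(nonacs_b_values(x, n, n_max)[0])


def nonacs_b_test(
    records: Sequence[SuccessRecord],
    n_max: float,
    benefit: str = "rep",
    n_sim: int = 100_000,
    seed: int | np.random.Generator = 0,
    alternative: str = "greater",
) -> SkewResult:
    """Monte-Carlo test of B against the demographic-stochasticity null.

    Each null replicate reallocates the K observed benefits multinomially
    with probabilities proportional to residence times and recomputes B;
    the one-tailed p-value is (1 + #{B_null >= B_obs}) / (n_sim + 1)
    (the +1 keeps p away from zero).  ``alternative="two-sided"`` doubles
    the smaller tail.
    """
    x, n = _benefits_residence(records, benefit)
    K = int(round(x.sum()))
    if K <= 0:
        raise ValueError("total benefits K must be positive; skew is undefined")
    b_obs = float(nonacs_b_values(x, n, n_max)[0])
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    null = rng.multinomial(K, n / n.sum(), size=n_sim)
    b_null = nonacs_b_values(null, n, n_max)
    upper = (1 + int(np.sum(b_null >= b_obs))) / (n_sim + 1)
    if alternative == "greater":
        p = upper
    elif alternative == "two-sided":
        lower = (1 + int(np.sum(b_null <= b_obs))) / (n_sim + 1)
        p = min(1.0, 2.0 * min(upper, lower))
    else:
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    N_t = float(n.sum())
    return SkewResult(
        B=b_obs,
        K=K,
        N=len(records),
        N_t=N_t,
        N_bar=N_t / n_max,
        n_max=n_max,
        p=float(p),
        null_sample=b_null,
        alternative=alternative,
    )


# ---------------------------------------------------------------------------
# Bateman gradient
# ---------------------------------------------------------------------------


def bateman_gradient(records: Sequence[SuccessRecord]) -> BatemanResult:
    """OLS slope of relative reproductive on relative mating success."""
    if len(records) < 3:
        raise ValueError("need at least three individuals")
    mat = np.array([r.mat for r in records], dtype=float)
    rep = np.array([r.rep for r in records], dtype=float)
    if mat.mean() == 0 or rep.mean() == 0:
        raise ValueError("Bateman gradient undefined: a group mean success is zero")
    if np.var(mat) == 0:
        raise ValueError("Bateman gradient undefined: no variance in mating success")
    rel_mat = mat / mat.mean()
    rel_rep = rep / rep.mean()
    slope = float(np.cov(rel_mat, rel_rep, ddof=0)[0, 1] / np.var(rel_mat))
    return BatemanResult(beta_ss=slope, n=len(records), relative_mat=rel_mat, relative_rep=rel_rep)
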