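"""Synthetic microsatellite pedigrees emulating a small managed rhinoceros
population.

Everything downstream (QC, parentage power, relatedness benchmarking,
skew and correlate screens) is exercisable on data from this module, so
its defaults *are* the study conditions: 10 loci with two to four alleles
of low polymorphism (every locus PIC < 0.5), allelic dropout 0.01, a
closed roster of 13 candidate fathers and ~33 mothers, skewed paternal
sibships (target mean 5.6) against small maternal sibships, presence
windows with a 16-month gestation offset, and the three assignment
scenarios (pooled/unknown mothers, pooled/known mothers, cohort-split
with temporal restrictions).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_core import ErrorModel, GenotypeTable, Locus, MISSING, pic_from_frequencies
from .parentage import CandidateRoster, RosterEntry, add_months, GESTATION_MONTHS

# study-calendar anchors for the two male cohorts
C1_WINDOW = (date(1995, 6, 1), date(2001, 7, 1))
C2_WINDOW = (date(2001, 7, 1), date(2008, 12, 31))
FULL_WINDOW = (C1_WINDOW[0], C2_WINDOW[1])


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationDesign:
    """Knobs of the pedigree simulator; defaults mirror the study system."""

    n_loci: int = 10
    alleles_min: int = 2
    alleles_max: int = 4
    dirichlet_alpha: float = 1.0
    max_locus_pic: float = 0.5
    candidate_pool: int = 60  # markers screened; the n_loci most polymorphic are kept
    n_fathers: int = 13
    n_mothers: int = 33
    n_offspring: int | None = None  # default: n_fathers * paternal_sibship_mean
    paternal_sibship_mean: float = 5.6
    maternal_sibship_mean: float = 1.6
    sibship_concentration: float = 1.0  # Dirichlet-multinomial over fathers
    maternal_concentration: float = 10.0  # near-even allocation over mothers
    max_maternal_sibship: int = 5
    error_model: ErrorModel = field(default_factory=ErrorModel)
    window: tuple[date, date] = FULL_WINDOW
    n_truncated_fathers: int = 0  # fathers present only ~2 years (e.g. died)
    cohort: str = "C1"
    seed: int | None = None
    scenario: int | None = None

    def __post_init__(self):
        if min(self.n_loci, self.n_fathers, self.n_mothers) <= 0:
            raise ValueError("counts must be positive")
        if self.paternal_sibship_mean <= 0 or self.maternal_sibship_mean <= 0:
            raise ValueError("sibship means must be positive")
        if not 2 <= self.alleles_min <= self.alleles_max:
            raise ValueError("allele range must satisfy 2 <= min <= max")

    @property
    def offspring_count(self) -> int:
        if self.n_offspring is not None:
            return self.n_offspring
        return int(round(self.n_fathers * self.paternal_sibship_mean))


@dataclass
class PedigreeTruth:
    """True parentage of simulated offspring."""

    parents: dict[str, tuple[str, str]]  # offspring -> (mother, father)
    birth_dates: dict[str, date] = field(default_factory=dict)

    def validate(self, roster: CandidateRoster, gestation_months: int = GESTATION_MONTHS) -> None:
        for off, (mo, fa) in self.parents.items():
            for parent in (mo, fa):
                if parent not in roster:
                    raise ValueError(f"{off}: parent {parent} not in roster")
            bd = self.birth_dates.get(off)
            if bd is None:
                continue
            conception = add_months(bd, -gestation_months)
            for parent in (mo, fa):
                e = roster[parent]
                if e.start is not None and not (e.start <= conception < e.end):
                    raise ValueError(
                        f"{off}: conception {conception} outside window of {parent}"
                    )

    def fathers(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for off, (_, fa) in self.parents.items():
            out.setdefault(fa, []).append(off)
        return out


@dataclass(frozen=True)
class KinshipCategory:
    """A canonical dyad class with its pedigree relatedness."""

    name: str
    r_true: float


KINSHIP_CATEGORIES: dict[str, KinshipCategory] = {
    "PO": KinshipCategory("PO", 0.5),
    "FS": KinshipCategory("FS", 0.5),
    "HS": KinshipCategory("HS", 0.25),
    "FC": KinshipCategory("FC", 0.125),
    "SC": KinshipCategory("SC", 0.03125),
    "U": KinshipCategory("U", 0.0),
}


@dataclass
class ScenarioRun:
    design: SimulationDesign
    roster: CandidateRoster
    table: GenotypeTable
    truth: PedigreeTruth
    known_mothers: dict[str, str] | None


@dataclass
class ScenarioBundle:
    scenario: int
    loci: list[Locus]
    runs: list[ScenarioRun]


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------


def generate_frequencies(
    design: SimulationDesign = SimulationDesign(), rng: np.random.Generator | None = None
) -> list[Locus]:
    """Draw a marker panel the way a microsatellite study assembles one.

    Candidate loci (``candidate_pool``, default 60 -- the number screened
    for this study system) get 2-4 alleles and symmetric-Dirichlet
    frequencies; any candidate at or above the low-polymorphism ceiling
    (PIC 0.5) is rejected and redrawn, and the ``n_loci`` *most*
    polymorphic admissible candidates form the panel.  This mimics
    selecting the best markers available in a genetically depauperate
    species where even the best stay below PIC 0.5; setting
    ``candidate_pool = n_loci`` disables the selection step and yields a
    plain low-polymorphism draw.
    """
    rng = np.random.default_rng(design.seed) if rng is None else rng
    pool = max(design.candidate_pool, design.n_loci)
    candidates: list[tuple[float, np.ndarray]] = []
    attempts = 0
    while len(candidates) < pool:
        attempts += 1
        if attempts > 10_000 * pool:  # pragma: no cover - extreme ceilings only
            raise RuntimeError("could not draw frequencies under the PIC ceiling")
        k = int(rng.integers(design.alleles_min, design.alleles_max + 1))
        freqs = rng.dirichlet(np.full(k, design.dirichlet_alpha))
        pic = pic_from_frequencies(freqs)
        if pic < design.max_locus_pic:
            candidates.append((pic, freqs))
    candidates.sort(key=lambda t: -t[0])
    loci = []
    for li, (_, freqs) in enumerate(candidates[: design.n_loci]):
        alleles = tuple(str(a + 1) for a in range(len(freqs)))
        loci.append(Locus(f"L{li + 1:02d}", alleles, freqs))
    return loci


# ---------------------------------------------------------------------------
# genotype machinery
# ---------------------------------------------------------------------------


def _founder_calls(n: int, loci: Sequence[Locus], rng: np.random.Generator) -> np.ndarray:
    calls = np.empty((n, len(loci), 2), dtype=np.int32)
    for li, locus in enumerate(loci):
        calls[:, li, :] = rng.choice(locus.k, size=(n, 2), p=locus.frequencies)
    return np.sort(calls, axis=2)


def _mendelian_child(
    mother: np.ndarray, father: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    L = mother.shape[0]
    pick_m = rng.integers(0, 2, size=L)
    pick_f = rng.integers(0, 2, size=L)
    child = np.stack([mother[np.arange(L), pick_m], father[np.arange(L), pick_f]], axis=1)
    return np.sort(child, axis=1)


def apply_errors(
    calls: np.ndarray,
    loci: Sequence[Locus],
    error_model: ErrorModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Corrupt true calls: per-genotype allelic dropout (heterozygotes only)
    then whole-genotype misprint replacement by a Hardy-Weinberg draw."""
    out = calls.copy()
    n = out.shape[0]
    d, m = error_model.dropout_rate, error_model.misprint_rate
    for li, locus in enumerate(loci):
        col = out[:, li, :]
        typed = col[:, 0] >= 0
        het = typed & (col[:, 0] != col[:, 1])
        if d > 0 and het.any():
            drop = het & (rng.random(n) < d)
            if drop.any():
                side = rng.integers(0, 2, size=int(drop.sum()))
                kept = col[drop, :][np.arange(int(drop.sum())), side]
                col[drop, 0] = kept
                col[drop, 1] = kept
        if m > 0 and typed.any():
            mis = typed & (rng.random(n) < m)
            if mis.any():
                draw = rng.choice(locus.k, size=(int(mis.sum()), 2), p=locus.frequencies)
                col[mis, :] = np.sort(draw, axis=1)
    return out


# ---------------------------------------------------------------------------
# pedigree simulation
# ---------------------------------------------------------------------------


def _default_roster(design: SimulationDesign, prefix: str = "") -> CandidateRoster:
    start, end = design.window
    entries = []
    for i in range(design.n_fathers):
        truncated = i >= design.n_fathers - design.n_truncated_fathers
        f_end = min(end, add_months(start, 24)) if truncated else end
        entries.append(
            RosterEntry(f"{prefix}F{i + 1:02d}", "M", design.cohort, start, f_end)
        )
    for i in range(design.n_mothers):
        entries.append(RosterEntry(f"{prefix}M{i + 1:02d}", "F", design.cohort, start, end))
    return CandidateRoster(entries)


def _allocate_fathers(
    design: SimulationDesign, roster: CandidateRoster, rng: np.random.Generator
) -> list[str]:
    fathers = [e.id for e in roster.males()]
    w = rng.dirichlet(np.full(len(fathers), design.sibship_concentration))
    counts = rng.multinomial(design.offspring_count, w)
    out = []
    for f, c in zip(fathers, counts):
        out.extend([f] * int(c))
    return out


def _allocate_mothers(
    design: SimulationDesign, roster: CandidateRoster, n: int, rng: np.random.Generator
) -> list[str]:
    mothers = [e.id for e in roster.females()]
    cap = design.max_maternal_sibship
    if n > len(mothers) * cap:
        raise ValueError(
            f"infeasible design: {n} offspring exceed {len(mothers)} mothers x {cap} litters"
        )
    w = rng.dirichlet(np.full(len(mothers), design.maternal_concentration))
    counts = np.zeros(len(mothers), dtype=int)
    out = []
    for _ in range(n):
        probs = np.where(counts < cap, w, 0.0)
        probs = probs / probs.sum()
        j = int(rng.choice(len(mothers), p=probs))
        counts[j] += 1
        out.append(mothers[j])
    return out


def _draw_birth_date(
    mother: RosterEntry, father: RosterEntry, rng: np.random.Generator
) -> date:
    lo = add_months(max(mother.start, father.start), GESTATION_MONTHS)
    hi = add_months(min(mother.end, father.end) - timedelta(days=1), GESTATION_MONTHS)
    span = (hi - lo).days
    if span < 0:
        raise ValueError("parents' windows leave no feasible conception date")
    return lo + timedelta(days=int(rng.integers(0, span + 1)))


def simulate_pedigree(
    design: SimulationDesign = SimulationDesign(),
    loci: Sequence[Locus] | None = None,
    rng: np.random.Generator | None = None,
    roster: CandidateRoster | None = None,
    prefix: str = "",
) -> tuple[PedigreeTruth, GenotypeTable, CandidateRoster]:
    """Simulate founders, a skewed mating matrix, Mendelian offspring and
    observation errors.  Fathers receive offspring by a
    Dirichlet-multinomial allocator (skew with the target mean sibship);
    mothers near-evenly up to a litter cap."""
    rng = np.random.default_rng(design.seed) if rng is None else rng
    if loci is None:
        loci = generate_frequencies(design, rng)
    if roster is None:
        roster = _default_roster(design, prefix=prefix)
    father_of = _allocate_fathers(design, roster, rng)
    mother_of = _allocate_mothers(design, roster, len(father_of), rng)

    father_ids = [e.id for e in roster.males()]
    mother_ids = [e.id for e in roster.females()]
    founders = father_ids + mother_ids
    founder_calls = _founder_calls(len(founders), loci, rng)
    geno = {ind: founder_calls[i] for i, ind in enumerate(founders)}

    parents: dict[str, tuple[str, str]] = {}
    birth_dates: dict[str, date] = {}
    off_rows = []
    for i, (mo, fa) in enumerate(zip(mother_of, father_of)):
        off = f"{prefix}O{i + 1:03d}"
        parents[off] = (mo, fa)
        birth_dates[off] = _draw_birth_date(roster[mo], roster[fa], rng)
        child = _mendelian_child(geno[mo], geno[fa], rng)
        geno[off] = child
        off_rows.append(off)

    individuals = founders + off_rows
    true_calls = np.stack([geno[ind] for ind in individuals])
    observed = apply_errors(true_calls, loci, design.error_model, rng)
    table = GenotypeTable(individuals, list(loci), observed)
    truth = PedigreeTruth(parents, birth_dates)
    truth.validate(roster)
    return truth, table, roster


# ---------------------------------------------------------------------------
# kinship-category dyads
# ---------------------------------------------------------------------------


def _child_of(a, b, rng):
    return _mendelian_child(a, b, rng)


def _founder(loci, rng):
    return _founder_calls(1, loci, rng)[0]


def simulate_dyads(
    category: str | KinshipCategory,
    n: int,
    loci: Sequence[Locus],
    rng: np.random.Generator,
    error_model: ErrorModel | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate ``n`` genotype pairs of a kinship category via explicit
    mini-pedigrees (shared parents / grandparents / great-grandparents),
    so every category is exactly realised rather than approximated by
    target identity coefficients.  Returns two ``(n, L, 2)`` call arrays.
    """
    name = category.name if isinstance(category, KinshipCategory) else str(category)
    if name not in KINSHIP_CATEGORIES:
        raise ValueError(f"unknown kinship category {name!r}")
    g1 = np.empty((n, len(loci), 2), dtype=np.int32)
    g2 = np.empty((n, len(loci), 2), dtype=np.int32)
    for t in range(n):
        if name == "U":
            a, b = _founder(loci, rng), _founder(loci, rng)
        elif name == "PO":
            a = _founder(loci, rng)
            b = _child_of(a, _founder(loci, rng), rng)
        elif name == "FS":
            p, q = _founder(loci, rng), _founder(loci, rng)
            a, b = _child_of(p, q, rng), _child_of(p, q, rng)
        elif name == "HS":
            p = _founder(loci, rng)
            a = _child_of(p, _founder(loci, rng), rng)
            b = _child_of(p, _founder(loci, rng), rng)
        elif name == "FC":
            gp, gq = _founder(loci, rng), _founder(loci, rng)
            s1, s2 = _child_of(gp, gq, rng), _child_of(gp, gq, rng)
            a = _child_of(s1, _founder(loci, rng), rng)
            b = _child_of(s2, _founder(loci, rng), rng)
        else:  # SC
            gp, gq = _founder(loci, rng), _founder(loci, rng)
            s1, s2 = _child_of(gp, gq, rng), _child_of(gp, gq, rng)
            c1 = _child_of(s1, _founder(loci, rng), rng)
            c2 = _child_of(s2, _founder(loci, rng), rng)
            a = _child_of(c1, _founder(loci, rng), rng)
            b = _child_of(c2, _founder(loci, rng), rng)
        g1[t], g2[t] = a, b
    if error_model is not None:
        g1 = apply_errors(g1, loci, error_model, rng)
        g2 = apply_errors(g2, loci, error_model, rng)
    return g1, g2


# ---------------------------------------------------------------------------
# assignment scenarios
# ---------------------------------------------------------------------------


def scenario_design(scenario_id: int) -> list[SimulationDesign]:
    """The per-run simulation designs of the three power scenarios."""
    if scenario_id in (1, 2):
        return [
            SimulationDesign(
                n_fathers=13, n_mothers=33, n_offspring=68, window=FULL_WINDOW, cohort="C1+C2"
            )
        ]
    if scenario_id == 3:
        return [
            SimulationDesign(
                n_fathers=7, n_mothers=28, n_offspring=36, window=C1_WINDOW,
                cohort="C1", n_truncated_fathers=1,
            ),
            SimulationDesign(
                n_fathers=7, n_mothers=23, n_offspring=32, window=C2_WINDOW,
                cohort="C2", n_truncated_fathers=1,
            ),
        ]
    raise ValueError(f"unknown scenario id {scenario_id!r}")


def build_scenario(
    scenario_id: int,
    design: SimulationDesign | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> ScenarioBundle:
    """Simulate the dataset(s) of one power scenario.

    Scenarios 1 and 2 share the identical generation path (and therefore
    identical data under the same seed); they differ only in whether the
    mother-offspring links are exposed to the assignment engine.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    designs = scenario_design(scenario_id)
    if design is not None:
        # caller-supplied marker panel / error settings propagate to all runs
        designs = [
            replace(
                d,
                n_loci=design.n_loci,
                alleles_min=design.alleles_min,
                alleles_max=design.alleles_max,
                dirichlet_alpha=design.dirichlet_alpha,
                max_locus_pic=design.max_locus_pic,
                candidate_pool=design.candidate_pool,
                error_model=design.error_model,
                sibship_concentration=design.sibship_concentration,
            )
            for d in designs
        ]
    loci = generate_frequencies(designs[0], rng)
    runs = []
    for r, d in enumerate(designs):
        prefix = f"{d.cohort}_" if len(designs) > 1 else ""
        truth, table, roster = simulate_pedigree(d, loci=loci, rng=rng, prefix=prefix)
        known = {off: mo for off, (mo, _) in truth.parents.items()} if scenario_id >= 2 else None
        runs.append(ScenarioRun(d, roster, table, truth, known))
    return ScenarioBundle(scenario_id, list(loci), runs)


# ---------------------------------------------------------------------------
# replicate tables (error-rate estimation) and covariates
# ---------------------------------------------------------------------------


def simulate_replicate_tables(
    table: GenotypeTable,
    n_replicates: int,
    error_model: ErrorModel,
    rng: np.random.Generator,
    individuals: Sequence[str] | None = None,
) -> list[GenotypeTable]:
    """Re-genotype (a subset of) individuals ``n_replicates`` times under the
    error model, treating the table's calls as the true genotypes."""
    sub = table.subset(individuals) if individuals is not None else table
    out = []
    for _ in range(n_replicates):
        calls = apply_errors(sub.calls, sub.loci, error_model, rng)
        out.append(GenotypeTable(sub.individuals, sub.loci, calls))
    return out


def simulate_male_covariates(
    males: Sequence[str], rng: np.random.Generator, cohorts: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-male covariates shaped like the field data: four horn
    measurements (cm, correlated), faecal testosterone (ng/g), territory
    size (km^2), habitat-openness fractions and selected-food volume."""
    n = len(males)
    size_factor = rng.normal(0, 1, n)  # shared scale behind the horn traits
    horn = {
        "anterior_length": 55 + 8 * size_factor + rng.normal(0, 4, n),
        "anterior_circumference": 60 + 5 * size_factor + rng.normal(0, 4, n),
        "posterior_length": 15 + 3 * size_factor + rng.normal(0, 2, n),
        "posterior_circumference": 40 + 4 * size_factor + rng.normal(0, 3, n),
    }
    habitat = rng.dirichlet([2.0, 3.0, 4.0, 2.0], size=n)
    df = pd.DataFrame(
        {
            "id": list(males),
            "cohort": list(cohorts) if cohorts is not None else ["C1"] * n,
            **horn,
            "testosterone": rng.gamma(12.0, 4.5, n),  # ~ mean 54 ng/g
            "territory_km2": rng.uniform(12.0, 75.0, n),
            "grassland": habitat[:, 0],
            "open_woodland": habitat[:, 1],
            "close_woodland": habitat[:, 2],
            "thickets": habitat[:, 3],
            "food_volume": rng.gamma(6.0, 25.0, n),
        }
    )
    return df.set_index("id")


def simulate_transect_points(
    males: Sequence[str], rng: np.random.Generator, mean_points: float = 13.0
) -> pd.DataFrame:
    """Habitat-survey transect points tagged with territory membership."""
    rows = []
    cats = ["grassland", "open_woodland", "close_woodland", "thickets"]
    for m in males:
        n_pts = max(1, int(rng.poisson(mean_points)))
        probs = rng.dirichlet([2.0, 3.0, 4.0, 2.0])
        for _ in range(n_pts):
            cover = float(rng.uniform(0.05, 0.9))
            height = float(rng.uniform(5.0, 80.0))
            rows.append(
                {
                    "territory": m,
                    "openness": cats[int(rng.choice(4, p=probs))],
                    "grass_cover": cover,
                    "grass_height": height,
                }
            )
    return pd.DataFrame(rows)
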