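"""Diploid codominant genotype data model and marker quality control.

Holds the substrate every other stage builds on: loci with allele
frequencies, a rectangular individuals x loci genotype table with a
missing-data mask, marker summary statistics (observed/expected
heterozygosity, polymorphic information content), an exact
Hardy-Weinberg test with locus exclusion, a replicate-based genotyping
error-rate estimator, and CSV / Genepop readers and writers.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1

#: Default p-value below which a locus is flagged for exclusion from
#: downstream analyses (markers this far out of HWE usually indicate null
#: alleles or systematic scoring problems).
DEFAULT_HWE_ALPHA = 1e-3


class ParseError(ValueError):
    """Raised when a genotype file cannot be interpreted."""


class NoDataError(ValueError):
    """Raised when an operation is asked to summarise an all-missing locus."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Locus:
    """A codominant marker: allele labels plus population frequencies."""

    name: str
    alleles: tuple[str, ...]
    frequencies: np.ndarray

    def __post_init__(self):
        freqs = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "alleles", tuple(str(a) for a in self.alleles))
        object.__setattr__(self, "frequencies", freqs)
        if len(self.alleles) < 1:
            raise ValueError(f"locus {self.name}: needs at least one allele")
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError(f"locus {self.name}: duplicate allele labels")
        if freqs.shape != (len(self.alleles),):
            raise ValueError(f"locus {self.name}: frequency/allele length mismatch")
        if np.any(freqs < 0) or abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError(f"locus {self.name}: frequencies must be >=0 and sum to 1")

    @property
    def k(self) -> int:
        return len(self.alleles)

    def allele_index(self, label: str) -> int:
        return self.alleles.index(str(label))


@dataclass(frozen=True)
class ErrorModel:
    """Genotyping-error model used both to corrupt simulated data and inside
    the assignment likelihood.

    dropout_rate
        Probability that a true heterozygote is observed as a homozygote
        (either allele lost with equal probability).  Default 0.01, a
        conservative rate for microsatellites typed from tissue samples.
    misprint_rate
        Probability that the observed single-locus genotype is replaced by
        an independent Hardy-Weinberg draw (scoring/recording error).
    """

    dropout_rate: float = 0.01
    misprint_rate: float = 0.0

    def __post_init__(self):
        for name in ("dropout_rate", "misprint_rate"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1), got {v}")


@dataclass(frozen=True)
class LocusSummary:
    name: str
    n_typed: int
    k_alleles: int
    Ho: float
    He: float
    PIC: float
    hwe_p: float
    error_rate: float = float("nan")
    hwe_testable: bool = True


class GenotypeTable:
    """Individuals x loci diploid allele calls.

    Calls are stored as an ``(n_individuals, n_loci, 2)`` integer array of
    allele indices into each :class:`Locus`; a genotype is missing when
    either slot is :data:`MISSING`.
    """

    def __init__(self, individuals: Sequence[str], loci: Sequence[Locus], calls: np.ndarray):
        self.individuals = [str(i) for i in individuals]
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("individual identifiers must be unique")
        self.loci = list(loci)
        calls = np.asarray(calls, dtype=np.int32)
        if calls.shape != (len(self.individuals), len(self.loci), 2):
            raise ValueError(
                f"calls shape {calls.shape} != ({len(self.individuals)}, {len(self.loci)}, 2)"
            )
        for li, locus in enumerate(self.loci):
            col = calls[:, li, :]
            valid = col[col >= 0]
            if valid.size and valid.max() >= locus.k:
                raise ValueError(f"locus {locus.name}: allele index out of range")
        # normalise: a half-missing genotype is treated as fully missing,
        # and allele order within a genotype is canonical (sorted)
        half = (calls < 0).any(axis=2)
        calls[half] = MISSING
        calls = np.sort(calls, axis=2)
        self.calls = calls
        self._index = {ind: i for i, ind in enumerate(self.individuals)}
        self._locus_index = {loc.name: i for i, loc in enumerate(self.loci)}

    # -- basic accessors ----------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def row(self, individual: str) -> np.ndarray:
        return self.calls[self._index[individual]]

    def locus_position(self, locus: str | Locus) -> int:
        name = locus.name if isinstance(locus, Locus) else str(locus)
        return self._locus_index[name]

    def genotype(self, individual: str, locus: str | Locus) -> tuple[str, str] | None:
        li = self.locus_position(locus)
        a, b = self.calls[self._index[individual], li]
        if a < 0:
            return None
        loc = self.loci[li]
        return (loc.alleles[a], loc.alleles[b])

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, n_loci) array, True where the genotype is missing."""
        return self.calls[:, :, 0] < 0

    def subset(self, individuals: Iterable[str]) -> "GenotypeTable":
        ids = [str(i) for i in individuals]
        rows = [self._index[i] for i in ids]
        return GenotypeTable(ids, self.loci, self.calls[rows].copy())

    def select_loci(self, names: Iterable[str]) -> "GenotypeTable":
        pos = [self._locus_index[str(n)] for n in names]
        return GenotypeTable(self.individuals, [self.loci[p] for p in pos], self.calls[:, pos].copy())

    def with_loci(self, loci: Sequence[Locus]) -> "GenotypeTable":
        """Return a table with the same calls but a-priori allele frequencies."""
        if [l.name for l in loci] != [l.name for l in self.loci]:
            raise ValueError("locus names must match")
        for new, old in zip(loci, self.loci):
            if new.alleles != old.alleles:
                raise ValueError(f"locus {new.name}: allele sets must match")
        return GenotypeTable(self.individuals, loci, self.calls.copy())

    # -- frequency helpers --------------------------------------------------

    def allele_counts(self, locus: str | Locus) -> np.ndarray:
        li = self.locus_position(locus)
        col = self.calls[:, li, :].ravel()
        col = col[col >= 0]
        return np.bincount(col, minlength=self.loci[li].k)

    def sample_frequencies(self, locus: str | Locus) -> np.ndarray:
        counts = self.allele_counts(locus)
        total = counts.sum()
        if total == 0:
            raise NoDataError(f"locus {self.loci[self.locus_position(locus)].name}: no data")
        return counts / total

    def estimated_loci(self) -> list[Locus]:
        """Loci with frequencies re-estimated from this table's calls."""
        out = []
        for locus in self.loci:
            out.append(Locus(locus.name, locus.alleles, self.sample_frequencies(locus)))
        return out


def table_from_records(
    records: dict[str, dict[str, tuple[str, str] | None]], loci: Sequence[Locus]
) -> GenotypeTable:
    """Build a table from ``{individual: {locus_name: (a1, a2) | None}}``."""
    individuals = list(records)
    calls = np.full((len(individuals), len(loci), 2), MISSING, dtype=np.int32)
    for i, ind in enumerate(individuals):
        for li, locus in enumerate(loci):
            g = records[ind].get(locus.name)
            if g is None:
                continue
            calls[i, li] = [locus.allele_index(g[0]), locus.allele_index(g[1])]
    return GenotypeTable(individuals, loci, calls)


# ---------------------------------------------------------------------------
# marker summaries
# ---------------------------------------------------------------------------


def pic_from_frequencies(p: np.ndarray) -> float:
    """Polymorphic information content, 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2."""
    p = np.asarray(p, dtype=float)
    a2 = float(np.sum(p**2))
    a4 = float(np.sum(p**4))
    return 1.0 - a2 - (a2 * a2 - a4)


def expected_heterozygosity(p: np.ndarray, n_typed: int) -> float:
    """Unbiased expected heterozygosity, (2n/(2n-1)) (1 - sum p_i^2)."""
    p = np.asarray(p, dtype=float)
    if n_typed < 1:
        raise NoDataError("no typed individuals")
    raw = 1.0 - float(np.sum(p**2))
    if n_typed == 0:
        return raw
    return min(1.0, (2 * n_typed) / (2 * n_typed - 1) * raw)


def summarize_locus(
    table: GenotypeTable, locus: str | Locus, hwe: bool = True, hwe_seed: int = 0
) -> LocusSummary:
    """Per-locus summary: typed count, observed alleles, Ho, He, PIC, HWE p.

    Allele frequencies are taken from the table itself (the convention of
    the standard parentage QC tools); He carries the small-sample unbiased
    correction, so PIC <= He always holds.
    """
    li = table.locus_position(locus)
    loc = table.loci[li]
    col = table.calls[:, li, :]
    typed = col[col[:, 0] >= 0]
    n_typed = typed.shape[0]
    if n_typed == 0:
        raise NoDataError(f"locus {loc.name}: no data")
    p = table.sample_frequencies(loc)
    k_obs = int(np.count_nonzero(table.allele_counts(loc)))
    ho = float(np.mean(typed[:, 0] != typed[:, 1]))
    he = expected_heterozygosity(p, n_typed) if k_obs > 1 else 0.0
    pic = pic_from_frequencies(p) if k_obs > 1 else 0.0
    if hwe:
        hwe_p, testable = hwe_exact_test(table, loc, seed=hwe_seed, return_testable=True)
    else:
        hwe_p, testable = float("nan"), False
    return LocusSummary(
        name=loc.name,
        n_typed=n_typed,
        k_alleles=k_obs,
        Ho=ho,
        He=he,
        PIC=pic,
        hwe_p=hwe_p,
        hwe_testable=testable,
    )


def summarize_table(table: GenotypeTable, hwe_seed: int = 0) -> pd.DataFrame:
    rows = []
    for locus in table.loci:
        s = summarize_locus(table, locus, hwe_seed=hwe_seed)
        rows.append(
            {
                "locus": s.name,
                "n_typed": s.n_typed,
                "k_alleles": s.k_alleles,
                "Ho": s.Ho,
                "He": s.He,
                "PIC": s.PIC,
                "hwe_p": s.hwe_p,
                "hwe_testable": s.hwe_testable,
                "error_rate": s.error_rate,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def _genotype_counts(table: GenotypeTable, li: int) -> dict[tuple[int, int], int]:
    col = table.calls[:, li, :]
    typed = col[col[:, 0] >= 0]
    counts: dict[tuple[int, int], int] = {}
    for a, b in typed:
        key = (int(a), int(b))
        counts[key] = counts.get(key, 0) + 1
    return counts


def _log_table_prob(counts: dict[tuple[int, int], int], allele_counts: np.ndarray) -> float:
    # conditional probability of a genotype array given allele counts
    # (Levene / Louis & Dempster):  n! prod(a_i!) 2^H / ((2n)! prod(g_ij!))
    n = sum(counts.values())
    het = sum(v for (a, b), v in counts.items() if a != b)
    logp = math.lgamma(n + 1) - math.lgamma(2 * n + 1) + het * math.log(2.0)
    for a in allele_counts:
        logp += math.lgamma(a + 1)
    for v in counts.values():
        logp -= math.lgamma(v + 1)
    return logp


class _EnumerationBudgetExceeded(Exception):
    pass


def _enumerate_hwe_tables(allele_counts: np.ndarray, budget: int = 2_000_000):
    """Yield (log probability, heterozygote pattern) for every genotype array
    with the given allele-count margins.  DFS over genotype categories with
    margin pruning; raises when the node budget is exhausted."""
    k = len(allele_counts)
    cats = [(i, j) for i in range(k) for j in range(i, k)]
    remaining = list(int(a) for a in allele_counts)
    counts: dict[tuple[int, int], int] = {}
    nodes = 0
    results: list[float] = []

    def last_cat_for(i: int) -> int:
        # index of the final category that can consume allele i
        return max(t for t, (a, b) in enumerate(cats) if a == i or b == i)

    last = {i: last_cat_for(i) for i in range(k)}

    def rec(t: int):
        nonlocal nodes
        nodes += 1
        if nodes > budget:
            raise _EnumerationBudgetExceeded
        if t == len(cats):
            if all(r == 0 for r in remaining):
                results.append(_log_table_prob(counts, allele_counts))
            return
        i, j = cats[t]
        cap = remaining[i] // 2 if i == j else min(remaining[i], remaining[j])
        for c in range(cap, -1, -1):
            take_i = 2 * c if i == j else c
            remaining[i] -= take_i
            if i != j:
                remaining[j] -= c
            if c:
                counts[(i, j)] = c
            # prune: any allele whose last category has passed must be spent
            ok = all(remaining[a] == 0 for a in range(k) if last[a] <= t)
            if ok:
                rec(t + 1)
            remaining[i] += take_i
            if i != j:
                remaining[j] += c
            counts.pop((i, j), None)

    rec(0)
    return results


def hwe_exact_test(
    table: GenotypeTable,
    locus: str | Locus,
    n_mc: int = 10_000,
    seed: int = 0,
    enum_budget: int = 2_000_000,
    return_testable: bool = False,
):
    """Exact conditional Hardy-Weinberg test.

    The p-value sums the conditional probabilities (given allele counts) of
    every genotype array no more probable than the observed one.  Complete
    enumeration is used whenever the margin-constrained table space fits a
    node budget (always the case for <= 4 alleles at the sample sizes used
    here); otherwise a seeded Monte-Carlo permutation of the allele vector
    is used with the same ordering statistic.

    A monomorphic locus is untestable and returns p = 1 by convention.
    """
    li = table.locus_position(locus)
    counts = _genotype_counts(table, li)
    n_typed = sum(counts.values())
    if n_typed == 0:
        raise NoDataError(f"locus {table.loci[li].name}: no data")
    allele_counts = table.allele_counts(locus)
    observed_alleles = np.nonzero(allele_counts)[0]
    if len(observed_alleles) < 2:
        return (1.0, False) if return_testable else 1.0
    # re-index to observed alleles only
    remap = {int(a): t for t, a in enumerate(observed_alleles)}
    counts = {(remap[a], remap[b]): v for (a, b), v in counts.items()}
    acounts = allele_counts[observed_alleles]
    log_obs = _log_table_prob(counts, acounts)
    tol = 1e-9 * max(1.0, abs(log_obs))
    try:
        logps = _enumerate_hwe_tables(acounts, budget=enum_budget)
        logps = np.asarray(logps)
        p = float(np.exp(logps[logps <= log_obs + tol]).sum() / np.exp(logps).sum())
    except _EnumerationBudgetExceeded:
        rng = np.random.default_rng(seed)
        pool = np.repeat(np.arange(len(acounts)), acounts)
        hits = 0
        for _ in range(n_mc):
            rng.shuffle(pool)
            pairs = pool.reshape(-1, 2)
            c: dict[tuple[int, int], int] = {}
            for a, b in np.sort(pairs, axis=1):
                key = (int(a), int(b))
                c[key] = c.get(key, 0) + 1
            if _log_table_prob(c, acounts) <= log_obs + tol:
                hits += 1
        p = (1 + hits) / (n_mc + 1)
    p = min(1.0, p)
    return (p, True) if return_testable else p


def flag_hwe_outliers(
    table: GenotypeTable, alpha: float = DEFAULT_HWE_ALPHA, seed: int = 0
) -> list[str]:
    """Names of loci whose HWE exact p falls below ``alpha`` (exclusion rule)."""
    flagged = []
    for locus in table.loci:
        p, testable = hwe_exact_test(table, locus, seed=seed, return_testable=True)
        if testable and p < alpha:
            flagged.append(locus.name)
    return flagged


# ---------------------------------------------------------------------------
# replicate-based error rates
# ---------------------------------------------------------------------------


def estimate_error_rates(replicate_tables: Sequence[GenotypeTable]) -> pd.Series:
    """Per-locus genotyping error rate from replicate PCR genotypes.

    For each individual and locus the modal genotype across replicates is
    the consensus (ties broken by first occurrence); the error rate at a
    locus is the fraction of non-missing replicate genotypes that differ
    from the consensus.  Mirrors the replicate design of re-running a
    subset of individuals several times.
    """
    if len(replicate_tables) < 2:
        raise ValueError("need at least two replicate tables")
    first = replicate_tables[0]
    for t in replicate_tables[1:]:
        if t.individuals != first.individuals or [l.name for l in t.loci] != [
            l.name for l in first.loci
        ]:
            raise ValueError("replicate tables must share individuals and loci")
    n_loci = first.n_loci
    errors = np.zeros(n_loci)
    totals = np.zeros(n_loci)
    stack = np.stack([t.calls for t in replicate_tables])  # (R, n, L, 2)
    for i in range(first.n):
        for li in range(n_loci):
            reps = [tuple(g) for g in stack[:, i, li] if g[0] >= 0]
            if not reps:
                continue
            best, best_count = None, 0
            seen: dict[tuple, int] = {}
            for g in reps:
                seen[g] = seen.get(g, 0) + 1
                if seen[g] > best_count:
                    best, best_count = g, seen[g]
            errors[li] += sum(1 for g in reps if g != best)
            totals[li] += len(reps)
    with np.errstate(invalid="ignore"):
        rates = np.where(totals > 0, errors / np.maximum(totals, 1), np.nan)
    return pd.Series(rates, index=[l.name for l in first.loci], name="error_rate")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_CSV_MISSING = {"", "0", "NA", "na", "0/0"}


def _sorted_alleles(labels: set[str]) -> list[str]:
    try:
        return sorted(labels, key=lambda s: (0, int(s)))
    except ValueError:
        return sorted(labels)


def read_genotypes(path: str | Path, dialect: str = "csv", loci: Sequence[Locus] | None = None) -> GenotypeTable:
    """Read a genotype table.

    dialect "csv": one row per individual, columns ``id, <locus>_1,
    <locus>_2, ...``; empty cells or "0" are missing.  dialect "genepop":
    3-digit allele coding, "000" missing.

    When ``loci`` is given the file's allele labels are validated against
    it and its a-priori frequencies are attached; otherwise frequencies
    are estimated from the file.
    """
    path = Path(path)
    if dialect == "csv":
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
        if raw.columns[0].lower() != "id":
            raise ParseError(f"{path}: first column must be 'id', got {raw.columns[0]!r}")
        cols = list(raw.columns[1:])
        if len(cols) % 2 != 0:
            raise ParseError(f"{path}: odd number of allele columns")
        locus_names = []
        for a, b in zip(cols[::2], cols[1::2]):
            ma, mb = re.fullmatch(r"(.+)_1", a), re.fullmatch(r"(.+)_2", b)
            if not (ma and mb and ma.group(1) == mb.group(1)):
                raise ParseError(f"{path}: columns {a!r}/{b!r} are not a <locus>_1/<locus>_2 pair")
            locus_names.append(ma.group(1))
        genos: list[list[tuple[str, str] | None]] = []
        for r, row in raw.iterrows():
            entry: list[tuple[str, str] | None] = []
            for ln, (ca, cb) in zip(locus_names, zip(cols[::2], cols[1::2])):
                a, b = row[ca].strip(), row[cb].strip()
                if a in _CSV_MISSING or b in _CSV_MISSING:
                    entry.append(None)
                else:
                    entry.append((a, b))
            genos.append(entry)
        individuals = list(raw["id"] if "id" in raw.columns else raw[raw.columns[0]])
    elif dialect == "genepop":
        lines = path.read_text().splitlines()
        if len(lines) < 3:
            raise ParseError(f"{path}: truncated Genepop file")
        body = lines[1:]
        locus_names = []
        i = 0
        while i < len(body) and body[i].strip().lower() != "pop":
            locus_names.extend([s.strip() for s in body[i].split(",") if s.strip()])
            i += 1
        if i == len(body):
            raise ParseError(f"{path}: no 'Pop' line")
        individuals, genos = [], []
        for line in body[i + 1 :]:
            if not line.strip():
                continue
            if line.strip().lower() == "pop":
                continue  # populations are pooled on read
            if "," not in line:
                raise ParseError(f"{path}: sample line without comma: {line!r}")
            ind, rest = line.split(",", 1)
            fields = rest.split()
            if len(fields) != len(locus_names):
                raise ParseError(
                    f"{path}: individual {ind.strip()!r} has {len(fields)} genotypes, "
                    f"expected {len(locus_names)}"
                )
            entry = []
            for f in fields:
                if len(f) not in (4, 6) or not f.isdigit():
                    raise ParseError(f"{path}: bad genotype field {f!r}")
                half = len(f) // 2
                a, b = f[:half], f[half:]
                if int(a) == 0 or int(b) == 0:
                    entry.append(None)
                else:
                    entry.append((str(int(a)), str(int(b))))
            individuals.append(ind.strip())
            genos.append(entry)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if loci is not None:
        if [l.name for l in loci] != locus_names:
            raise ParseError(f"{path}: locus names do not match the provided loci")
        use_loci = list(loci)
    else:
        labels: list[set[str]] = [set() for _ in locus_names]
        for entry in genos:
            for li, g in enumerate(entry):
                if g is not None:
                    labels[li].update(g)
        use_loci = []
        for ln, lab in zip(locus_names, labels):
            alleles = _sorted_alleles(lab) or ["1"]
            counts = np.zeros(len(alleles))
            idx = {a: t for t, a in enumerate(alleles)}
            for entry in genos:
                g = entry[locus_names.index(ln)]
                if g is not None:
                    counts[idx[g[0]]] += 1
                    counts[idx[g[1]]] += 1
            freqs = counts / counts.sum() if counts.sum() else np.ones(len(alleles)) / len(alleles)
            use_loci.append(Locus(ln, tuple(alleles), freqs))

    calls = np.full((len(individuals), len(use_loci), 2), MISSING, dtype=np.int32)
    for r, entry in enumerate(genos):
        for li, g in enumerate(entry):
            if g is None:
                continue
            loc = use_loci[li]
            try:
                calls[r, li] = [loc.allele_index(g[0]), loc.allele_index(g[1])]
            except ValueError:
                raise ParseError(
                    f"{path}: row {r + 1}, locus {loc.name}: unknown allele in {g}"
                ) from None
    return GenotypeTable(individuals, use_loci, calls)


def write_genotypes(table: GenotypeTable, path: str | Path, dialect: str = "csv") -> None:
    path = Path(path)
    if dialect == "csv":
        data: dict[str, list] = {"id": table.individuals}
        for li, locus in enumerate(table.loci):
            col = table.calls[:, li, :]
            a1 = [locus.alleles[a] if a >= 0 else "" for a in col[:, 0]]
            a2 = [locus.alleles[b] if b >= 0 else "" for b in col[:, 1]]
            data[f"{locus.name}_1"] = a1
            data[f"{locus.name}_2"] = a2
        pd.DataFrame(data).to_csv(path, index=False)
    elif dialect == "genepop":
        lines = ["matesys genotype export"]
        lines.extend(l.name for l in table.loci)
        lines.append("Pop")
        for i, ind in enumerate(table.individuals):
            fields = []
            for li, locus in enumerate(table.loci):
                a, b = table.calls[i, li]
                if a < 0:
                    fields.append("000000")
                else:
                    # numeric labels are preserved, others coded by position
                    def code(x: int) -> str:
                        lab = locus.alleles[x]
                        return f"{int(lab):03d}" if lab.isdigit() else f"{x + 1:03d}"

                    fields.append(code(a) + code(b))
            lines.append(f"{ind} ,  " + " ".join(fields))
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
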