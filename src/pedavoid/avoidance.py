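"""Permutation test for inbreeding avoidance under a structured mating null.

The question: do breeding pairs in a group-living population have lower
pedigree relatedness than expected if females mated at random given the
population's mating structure?  The null model re-assigns a sire to every
offspring while respecting three empirical features of male reproduction:

* a fixed fraction of offspring are sired by **extra-group** males
  (default 0.24),
* a fraction by **natal** males that have not yet dispersed from their
  birth group (default 0.16),
* the remainder by non-natal males of the mother's group, of which only a
  **skew fraction** (default 0.20) per group and birth cohort is allowed
  to reproduce, mimicking male reproductive skew.

Each simulated dataset yields a mean parental relatedness; the observed
dataset is counted as one of the ``n_sim`` datasets and the one-sided
P-value is the proportion of datasets whose mean is at least as small as
the observed mean.  Significance indicates inbreeding avoidance.

Usage follows the model/results idiom::

    model = MateChoiceNullModel(pedigree, demography, pairs, scheme)
    res = model.fit(seed=1)
    print(res.summary())
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pedigree import FEMALE, MALE, Pedigree

logger = logging.getLogger(__name__)

#: Relatedness values realizable in shallow pedigrees; the observed
#: histogram is reported over these classes plus an overflow class.
R_CLASSES = (0.0, 0.0625, 0.125, 0.25, 0.5)

DAYS_PER_YEAR = 365.25


class AvoidanceError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationScheme:
    """Parameters of the sire-assignment null model.

    ``p_extra``/``p_natal`` are the extra-group and natal paternity
    fractions; the within-group remainder is thinned to ``skew_fraction``
    of each group's males per birth cohort (optionally restricted to
    ``skew_age_window`` in years).  ``maturity_age`` (years) gates which
    males are candidate sires; ``conception_offset`` (days) backdates
    conception from birth (rhesus gestation ~166 days).
    ``completeness_filter_depth`` requires both members of a pair (and all
    candidate sires) to have that many fully known ancestor generations;
    0 disables the filter.  ``relatedness_depth`` truncates the kinship
    computation (None = use all recorded ancestors).  ``partition`` is
    "exact" (category counts fixed at round(p * n)) or "bernoulli"
    (independent per-offspring category draws).
    """

    p_extra: float = 0.24
    p_natal: float = 0.16
    skew_fraction: float = 0.20
    skew_age_window: tuple[float, float] | None = None
    maturity_age: float = 4.0
    conception_offset: int = 166
    n_sim: int = 1000
    include_natal: bool = True
    completeness_filter_depth: int = 2
    relatedness_depth: int | None = None
    partition: str = "exact"
    empty_pool_policy: str = "within"  # or "drop"

    @property
    def p_within(self) -> float:
        return 1.0 - self.p_extra - self.p_natal

    def __post_init__(self):
        if not (0 <= self.p_extra <= 1 and 0 <= self.p_natal <= 1):
            raise AvoidanceError("paternity proportions must lie in [0, 1]")
        if self.p_extra + self.p_natal > 1:
            raise AvoidanceError("p_extra + p_natal must not exceed 1")
        if not 0 < self.skew_fraction <= 1:
            raise AvoidanceError("skew_fraction must lie in (0, 1]")
        if self.n_sim < 2:
            raise AvoidanceError("n_sim must be >= 2")
        if self.partition not in ("exact", "bernoulli"):
            raise AvoidanceError("partition must be 'exact' or 'bernoulli'")


@dataclass(frozen=True)
class BreedingRecord:
    """A realized or simulated offspring-mother-sire triple."""

    offspring: object
    mother: object
    sire: object
    birth_date: dt.date
    conception_date: dt.date
    mother_group: object


@dataclass
class SirePools:
    """Candidate sires for one offspring, split by the null's categories."""

    natal: list
    within: list
    extra: list

    def all_empty(self) -> bool:
        return not (self.natal or self.within or self.extra)


class Demography:
    """Group-membership intervals: who was in which group when.

    Intervals are half-open ``[start, end)``; a missing end is open-ended.
    Overlapping intervals for one individual are rejected.
    """

    def __init__(self, intervals: pd.DataFrame):
        required = {"id", "group", "start_date", "end_date"}
        missing = required - set(intervals.columns)
        if missing:
            raise AvoidanceError(f"demography table missing columns {sorted(missing)}")
        self._by_id: dict = {}
        for row in intervals.itertuples(index=False):
            start = row.start_date
            end = row.end_date if not pd.isna(row.end_date) else None
            if end is not None and end < start:
                raise AvoidanceError(
                    f"interval with end before start for id {row.id!r}")
            self._by_id.setdefault(row.id, []).append((start, end, row.group))
        for iid, ivs in self._by_id.items():
            ivs.sort(key=lambda t: t[0])
            for (s1, e1, _), (s2, _, _) in zip(ivs, ivs[1:]):
                if e1 is None or s2 < e1:
                    raise AvoidanceError(
                        f"overlapping group intervals for id {iid!r}")

    def group_of(self, id, date: dt.date):
        """Group of ``id`` at ``date``, or None if not covered."""
        for start, end, group in self._by_id.get(id, ()):
            if start <= date and (end is None or date < end):
                return group
        return None

    def ids(self):
        return list(self._by_id)

    def to_frame(self) -> pd.DataFrame:
        rows = [(iid, g, s, e) for iid, ivs in self._by_id.items()
                for s, e, g in ivs]
        return pd.DataFrame(rows, columns=["id", "group", "start_date",
                                           "end_date"])


@dataclass
class ObservedStats:
    """Summary of parental relatedness across breeding pairs."""

    n: int
    mean: float
    sd: float
    histogram: dict
    proportion_unrelated: float
    r_values: np.ndarray = field(repr=False, default=None)


def relatedness_summary(r_values) -> ObservedStats:
    """Mean, sample SD, class histogram and proportion unrelated of a set
    of pairwise relatedness values."""
    r = np.asarray(list(r_values), dtype=float)
    if r.size == 0:
        raise AvoidanceError("no breeding pairs supplied")
    hist = {c: int(np.sum(np.isclose(r, c))) for c in R_CLASSES}
    hist["other"] = int(r.size - sum(hist.values()))
    return ObservedStats(
        n=int(r.size),
        mean=float(r.mean()),
        sd=float(r.std(ddof=1)) if r.size > 1 else 0.0,
        histogram=hist,
        proportion_unrelated=float(np.mean(r == 0.0)),
        r_values=r,
    )


def observed_statistic(pairs, pedigree: Pedigree,
                       depth: int | None = None) -> ObservedStats:
    """Relatedness summary of realized breeding pairs (mother, sire) taken
    from ``pairs`` (an iterable of :class:`BreedingRecord`)."""
    r = [pedigree.relatedness(p.mother, p.sire, depth).r for p in pairs]
    return relatedness_summary(r)


def permutation_p(observed_mean: float, simulated_means) -> float:
    """One-sided P: the share of the ``n_sim`` datasets (the observed one
    included) whose mean relatedness is at least as small as observed."""
    sims = np.asarray(list(simulated_means), dtype=float)
    if sims.size < 1:
        raise AvoidanceError("need at least one simulated mean")
    n_total = sims.size + 1
    return float((1 + np.sum(sims <= observed_mean)) / n_total)


def assign_categories(n: int, p_extra: float, p_natal: float,
                      partition: str, rng) -> np.ndarray:
    """Assign each of ``n`` offspring a paternity category: 0 = extra-group,
    1 = natal, 2 = within-group.  ``partition`` "exact" fixes the category
    counts at ``round(p * n)``; "bernoulli" draws categories independently.
    """
    if partition == "bernoulli":
        u = rng.random(n)
        return np.where(u < p_extra, 0,
                        np.where(u < p_extra + p_natal, 1, 2))
    n_extra = min(int(math.floor(p_extra * n + 0.5)), n)
    n_natal = min(int(math.floor(p_natal * n + 0.5)), n - n_extra)
    cats = np.full(n, 2, dtype=int)
    order = rng.permutation(n)
    cats[order[:n_extra]] = 0
    cats[order[n_extra:n_extra + n_natal]] = 1
    return cats


def skew_subsample(pool, skew_fraction: float, rng,
                   age_window=None, age_of=None):
    """Thin a within-group male pool to the fraction allowed to reproduce.

    Size is ``max(1, round(fraction * |pool|))``, drawn uniformly without
    replacement.  With ``age_window`` (years) set, sampling is restricted to
    males inside the window, falling back to the whole pool if none are.
    """
    pool = list(pool)
    if not pool:
        raise AvoidanceError("cannot subsample an empty pool")
    candidates = pool
    if age_window is not None and age_of is not None:
        lo, hi = age_window
        windowed = [m for m in pool if lo <= age_of(m) <= hi]
        if windowed:
            candidates = windowed
    k = max(1, int(math.floor(skew_fraction * len(candidates) + 0.5)))
    k = min(k, len(candidates))
    idx = rng.choice(len(candidates), size=k, replace=False)
    return [candidates[i] for i in sorted(idx)]


@dataclass
class AvoidanceResults:
    """Results of the avoidance permutation test.

    ``null_means`` holds the ``n_sim`` dataset means with the observed mean
    as its first element; ``pvalue`` is one-sided (small means = avoidance).
    """

    observed: ObservedStats
    null_means: np.ndarray
    prop_related: np.ndarray
    pvalue: float
    scheme: SimulationScheme
    n_pairs: int
    n_excluded: int
    fallback_counts: dict

    @property
    def observed_mean_r(self) -> float:
        return self.observed.mean

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_means[1:]))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_means[1:], ddof=1))

    def summary(self) -> str:
        o = self.observed
        sims = self.null_means[1:]
        lines = [
            "Inbreeding avoidance permutation test",
            "=" * 46,
            f"breeding pairs:              {self.n_pairs}"
            + (f"  ({self.n_excluded} excluded, empty pools)"
               if self.n_excluded else ""),
            f"observed mean relatedness:   {o.mean:.4f} (SD {o.sd:.4f})",
            f"observed proportion r = 0:   {100 * o.proportion_unrelated:.1f}%",
            f"simulated datasets:          {len(sims)} (+ observed)",
            f"null mean of dataset means:  {self.null_mean:.4f} "
            f"(SD {self.null_sd:.4f})",
            f"null range of dataset means: [{sims.min():.4f}, {sims.max():.4f}]",
            f"mean proportion r > 0:       {float(np.mean(self.prop_related[1:])):.4f}",
            f"natal breeding allowed:      {self.scheme.include_natal}",
            f"one-sided P (avoidance):     {self.pvalue:.4f}",
        ]
        return "\n".join(lines)

    def plot_null(self, ax=None, bins=20):
        """Histogram of the null dataset means with the observed mean marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.null_means[1:], bins=bins, color="0.6",
                edgecolor="white", label="simulated means")
        ax.axvline(self.observed.mean, color="black", linestyle="--",
                   label=f"observed ({self.observed.mean:.4f})")
        ax.set_xlabel("mean parental relatedness")
        ax.set_ylabel("simulations")
        ax.legend()
        return ax


class MateChoiceNullModel:
    """Null model of sire assignment for the avoidance permutation test.

    Parameters
    ----------
    pedigree : Pedigree
        Provides parent links, sexes, birth/death dates and relatedness.
    demography : Demography
        Group-membership intervals used to split candidate sires into
        natal / within-group / extra-group pools at each conception.
    pairs : iterable of BreedingRecord
        The realized offspring-mother-sire triples under test.
    scheme : SimulationScheme, optional
        Null-model parameters (defaults above).

    Candidate-sire pools are computed once per offspring at construction;
    :meth:`fit` then draws the simulated datasets.
    """

    def __init__(self, pedigree: Pedigree, demography: Demography,
                 pairs, scheme: SimulationScheme | None = None):
        self.pedigree = pedigree
        self.demography = demography
        self.scheme = scheme or SimulationScheme()
        self._r_cache: dict = {}

        all_pairs = list(pairs)
        if not all_pairs:
            raise AvoidanceError("no breeding pairs supplied")
        d = self.scheme.completeness_filter_depth
        self.pairs = [
            p for p in all_pairs
            if self._complete(p.mother, d) and self._complete(p.sire, d)
        ]
        self.n_filtered_pairs = len(all_pairs) - len(self.pairs)
        if not self.pairs:
            raise AvoidanceError(
                "no breeding pair passes the pedigree-completeness filter")

        self._males = self._index_males()
        self.pools: list[SirePools] = []
        kept = []
        n_empty = 0
        for rec in self.pairs:
            pools = self.eligible_sires(rec)
            if pools.all_empty():
                n_empty += 1
                logger.warning("offspring %r: no eligible sire in any pool; "
                               "excluded", rec.offspring)
                continue
            kept.append(rec)
            self.pools.append(pools)
        self.pairs = kept
        self.n_excluded = n_empty
        if not self.pairs:
            raise AvoidanceError("every offspring lost all candidate pools")

    # -- helpers ------------------------------------------------------- #

    def _complete(self, id, depth: int) -> bool:
        if depth <= 0:
            return True
        return self.pedigree.ancestor_complete_depth(id) >= depth

    def _index_males(self):
        d = self.scheme.completeness_filter_depth
        males = []
        for rec in self.pedigree.records.values():
            if rec.sex != MALE or rec.is_stub or rec.birth_date is None:
                continue
            if not self._complete(rec.id, d):
                continue
            males.append(rec)
        return males

    def _age(self, rec, date: dt.date) -> float:
        return (date - rec.birth_date).days / DAYS_PER_YEAR

    def eligible_sires(self, record: BreedingRecord) -> SirePools:
        """Split all alive, mature, completeness-passing males into natal /
        within-group / extra-group pools at the record's conception date."""
        conc = record.conception_date
        mother_group = record.mother_group
        natal, within, extra = [], [], []
        for m in self._males:
            if m.birth_date > conc:
                continue
            if self._age(m, conc) < self.scheme.maturity_age:
                continue
            if m.death_date is not None and m.death_date <= conc:
                continue
            group = self.demography.group_of(m.id, conc)
            if group is None:
                continue
            if group == mother_group:
                if m.birth_group == group:
                    natal.append(m.id)
                else:
                    within.append(m.id)
            else:
                extra.append(m.id)
        return SirePools(natal=natal, within=within, extra=extra)

    def _pair_r(self, i, j) -> float:
        key = (i, j) if repr(i) <= repr(j) else (j, i)
        r = self._r_cache.get(key)
        if r is None:
            r = self.pedigree.relatedness(i, j, self.scheme.relatedness_depth).r
            self._r_cache[key] = r
        return r

    # -- simulation ---------------------------------------------------- #

    def _assign_categories(self, n: int, include_natal: bool, rng):
        scheme = self.scheme
        p_natal = scheme.p_natal if include_natal else 0.0
        return assign_categories(n, scheme.p_extra, p_natal,
                                 scheme.partition, rng)

    def simulate_dataset(self, rng, include_natal: bool | None = None):
        """One null dataset: a simulated sire per offspring.

        Returns ``(sires, fallbacks)``: the list of assigned sire ids
        (aligned with ``self.pairs``) and a dict counting empty-pool
        fallbacks by category.
        """
        scheme = self.scheme
        if include_natal is None:
            include_natal = scheme.include_natal
        n = len(self.pairs)
        cats = self._assign_categories(n, include_natal, rng)

        # one skew subsample per (mother group, birth cohort) per simulation
        cohort_pool: dict = {}
        for rec, pools in zip(self.pairs, self.pools):
            key = (rec.mother_group, rec.birth_date.year)
            cohort_pool.setdefault(key, set()).update(pools.within)
        cohort_sub: dict = {}
        for key in sorted(cohort_pool, key=repr):
            pool = sorted(cohort_pool[key], key=repr)
            if not pool:
                cohort_sub[key] = []
                continue
            conc_ref = dt.date(key[1], 1, 1)
            age_of = (lambda m, c=conc_ref:
                      self._age(self.pedigree[m], c))
            cohort_sub[key] = skew_subsample(
                pool, scheme.skew_fraction, rng,
                age_window=scheme.skew_age_window, age_of=age_of)

        sires = []
        fallbacks = {"natal": 0, "extra": 0, "within": 0}
        for idx, (rec, pools) in enumerate(zip(self.pairs, self.pools)):
            cat = cats[idx]
            key = (rec.mother_group, rec.birth_date.year)
            sub = [m for m in cohort_sub[key] if m in pools.within] \
                or pools.within
            if cat == 0:
                pool = pools.extra
                if not pool:
                    fallbacks["extra"] += 1
                    pool = sub
            elif cat == 1:
                pool = pools.natal
                if not pool:
                    fallbacks["natal"] += 1
                    pool = sub
            else:
                pool = sub
                if not pool:
                    fallbacks["within"] += 1
            if not pool:
                pool = pools.natal or pools.extra
            sires.append(pool[int(rng.integers(len(pool)))])
        return sires, fallbacks

    def fit(self, n_sim: int | None = None, seed=None,
            include_natal: bool | None = None) -> AvoidanceResults:
        """Run the permutation test.

        Draws ``n_sim - 1`` simulated datasets (the observed dataset counts
        as one of the ``n_sim``), computes each dataset's mean parental
        relatedness and the one-sided P-value.
        """
        scheme = self.scheme
        if n_sim is None:
            n_sim = scheme.n_sim
        if include_natal is None:
            include_natal = scheme.include_natal
        if n_sim < 2:
            raise AvoidanceError("n_sim must be >= 2")
        rng = np.random.default_rng(seed)

        obs_r = np.array([self._pair_r(p.mother, p.sire) for p in self.pairs])
        observed = relatedness_summary(obs_r)

        means = np.empty(n_sim)
        props = np.empty(n_sim)
        means[0] = observed.mean
        props[0] = float(np.mean(obs_r > 0))
        fallback_counts = {"natal": 0, "extra": 0, "within": 0}
        for s in range(1, n_sim):
            sires, fb = self.simulate_dataset(rng, include_natal)
            for k in fallback_counts:
                fallback_counts[k] += fb[k]
            r = np.fromiter(
                (self._pair_r(p.mother, sire)
                 for p, sire in zip(self.pairs, sires)),
                dtype=float, count=len(sires))
            means[s] = r.mean()
            props[s] = float(np.mean(r > 0))

        pvalue = permutation_p(observed.mean, means[1:])
        return AvoidanceResults(
            observed=observed,
            null_means=means,
            prop_related=props,
            pvalue=pvalue,
            scheme=replace(scheme, include_natal=include_natal, n_sim=n_sim),
            n_pairs=len(self.pairs),
            n_excluded=self.n_excluded,
            fallback_counts=fallback_counts,
        )


def breeding_records(pedigree: Pedigree, demography: Demography,
                     offspring_ids=None,
                     conception_offset: int = 166):
    """Build :class:`BreedingRecord` triples for offspring with both parents
    known, a birth date, and a mother group resolvable at conception."""
    records = []
    ids = offspring_ids if offspring_ids is not None else pedigree.ids
    for oid in ids:
        rec = pedigree[oid]
        if rec.sire is None or rec.dam is None or rec.birth_date is None:
            continue
        conc = rec.birth_date - dt.timedelta(days=conception_offset)
        group = demography.group_of(rec.dam, conc)
        if group is None:
            continue
        records.append(BreedingRecord(
            offspring=oid, mother=rec.dam, sire=rec.sire,
            birth_date=rec.birth_date, conception_date=conc,
            mother_group=group))
    return records


def run_avoidance(pedigree: Pedigree, demography: Demography, pairs,
                  scheme: SimulationScheme | None = None, seed=None,
                  both_natal_modes: bool = False):
    """Convenience wrapper: fit the null model once (or once per natal
    mode) and return :class:`AvoidanceResults` (or a dict of them)."""
    model = MateChoiceNullModel(pedigree, demography, pairs, scheme)
    if not both_natal_modes:
        return model.fit(seed=seed)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=2)
    return {
        "include_natal": model.fit(seed=int(seeds[0]), include_natal=True),
        "exclude_natal": model.fit(seed=int(seeds[1]), include_natal=False),
    }
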