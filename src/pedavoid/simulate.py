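"""Synthetic group-living primate population generator.

Emulates the demographic and genetic structure the pipeline assumes: a
founder cohort released at a point in time, several social groups, female
philopatry with male natal dispersal, one offspring per female per birth
season, paternal reproductive skew, fixed shares of extra-group and natal
paternity, and highly polymorphic codominant markers transmitted by
Mendelian gene dropping.  Defaults mirror the Cayo Santiago founding
colony: 409 founders of which 183 adult females and 40 adult males, ~7
social groups, male dispersal at a median age of 4.5 years, 14.4% infant
mortality, ~30 markers.

Mate choice is tunable through :class:`MateChoiceModel`: with avoidance
strength ``theta = 0`` sires are assigned exactly by the null scheme of
:mod:`pedavoid.avoidance` (extra-group / natal / skewed within-group), so
the avoidance test is calibrated by construction; with ``theta = 1`` any
candidate related to the mother at or above ``r_threshold`` is rejected
whenever an unrelated alternative exists.

Everything is driven by one seeded generator; identical seeds give
identical populations, genotype tables and files.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import avoidance as av
from .estimators import GenotypeTable
from .pedigree import FEMALE, MALE, Pedigree, PedigreeRecord

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class FounderConfig:
    """Founder cohort: counts, group layout and marker panel."""

    n_founders: int = 409
    n_adult_females: int = 183
    n_adult_males: int = 40
    n_groups: int = 7
    n_loci: int = 30
    alleles_per_locus: int = 8
    dirichlet_alpha: float = 1.0   # founder allele-frequency prior per locus
    start_year: int = 2000
    adult_age_range: tuple[float, float] = (6.0, 14.0)
    immature_age_range: tuple[float, float] = (0.5, 4.0)

    def __post_init__(self):
        if self.n_adult_females + self.n_adult_males > self.n_founders:
            raise SimulationError("adult founders exceed n_founders")
        if self.n_groups < 1:
            raise SimulationError("need at least one group")


@dataclass(frozen=True)
class DemographyConfig:
    """Vital rates and the generative mating scheme.

    ``birth_probability`` is per adult female per year; infant mortality is
    applied in the first year of life, ``adult_annual_mortality``
    afterwards.  Males draw a dispersal age of ``dispersal_min_age`` plus an
    exponential with median ``dispersal_median_age`` overall, then move to a
    uniformly chosen other group.  ``p_extra`` / ``p_natal`` /
    ``skew_fraction`` are used generatively with the same meaning as in the
    avoidance null.  ``culling_target`` (optional) removes random juveniles
    whenever the living population exceeds it.
    """

    n_years: int = 20
    birth_probability: float = 0.5
    infant_mortality: float = 0.144
    adult_annual_mortality: float = 0.04
    max_age: float = 28.0
    maturity_age: float = 4.0
    dispersal_min_age: float = 3.0
    dispersal_median_age: float = 4.5
    p_extra: float = 0.24
    p_natal: float = 0.16
    skew_fraction: float = 0.20
    partition: str = "exact"
    conception_offset: int = 166
    culling_target: int | None = None
    culling_age_range: tuple[float, float] = (1.0, 3.0)


@dataclass(frozen=True)
class MateChoiceModel:
    """Kin-avoidant mate choice: a drawn candidate with relatedness to the
    mother at or above ``r_threshold`` is rejected with probability
    ``theta`` and redrawn (up to ``max_redraws``; then the least related
    candidate of the pool is taken).  ``theta = 0`` reproduces the null
    scheme exactly."""

    theta: float = 0.0
    r_threshold: float = 0.0625
    max_redraws: int = 100


@dataclass
class SimOutput:
    """A simulated population: pedigree, genotypes, group membership,
    per-individual true inbreeding coefficients, and provenance."""

    pedigree: Pedigree
    genotypes: GenotypeTable | None
    demography: av.Demography
    true_F: pd.Series
    founder_config: FounderConfig
    demography_config: DemographyConfig
    mate_choice: MateChoiceModel
    seed: object = None
    warnings: list = field(default_factory=list)


class _State:
    """Mutable simulation state with incremental kinship memoization."""

    def __init__(self):
        self.records: dict = {}        # id -> PedigreeRecord fields (mutable dict)
        self.intervals: dict = {}      # id -> [(start, end, group), ...]
        self.gen: dict = {}            # id -> generation rank
        self._kin_cache: dict = {}
        self.founder_genotypes: dict = {}
        self.n_created = 0

    def new_id(self, prefix: str) -> str:
        self.n_created += 1
        return f"{prefix}{self.n_created:05d}"

    def add(self, id, sire, dam, sex, birth_date, birth_group):
        self.records[id] = {
            "id": id, "sire": sire, "dam": dam, "sex": sex,
            "birth_date": birth_date, "death_date": None, "removed": False,
            "birth_group": birth_group,
        }
        self.gen[id] = 0 if sire is None else 1 + max(self.gen[sire],
                                                      self.gen[dam])

    def group_at(self, id, date):
        for start, end, group in self.intervals.get(id, ()):
            if start <= date and (end is None or date < end):
                return group
        return None

    def kinship(self, i, j) -> float:
        if i is None or j is None:
            return 0.0
        if i == j:
            key = (i,)
        else:
            key = (i, j) if i <= j else (j, i)
        hit = self._kin_cache.get(key)
        if hit is not None:
            return hit
        if i == j:
            rec = self.records[i]
            val = 0.5 * (1.0 + self.kinship(rec["sire"], rec["dam"]))
        else:
            if self.gen[i] < self.gen[j]:
                i, j = j, i
            rec = self.records[i]
            val = 0.5 * (self.kinship(rec["sire"], j)
                         + self.kinship(rec["dam"], j))
        self._kin_cache[key] = val
        return val

    def relatedness(self, i, j) -> float:
        return 2.0 * self.kinship(i, j)

    def alive(self, id, date) -> bool:
        rec = self.records[id]
        if rec["birth_date"] > date:
            return False
        return rec["death_date"] is None or rec["death_date"] > date

    def age(self, id, date) -> float:
        return (date - self.records[id]["birth_date"]).days / DAYS_PER_YEAR

    def living_ids(self, date):
        return [i for i in self.records if self.alive(i, date)]


def _random_date(year: int, rng, start_doy=120, span=61) -> dt.date:
    """A birth-season date: a day drawn inside a ~2-month season."""
    return (dt.date(year, 1, 1)
            + dt.timedelta(days=int(start_doy + rng.integers(span))))


def generate_founders(cfg: FounderConfig, rng) -> _State:
    """Create the founder cohort: sexed, aged, grouped and genotyped.

    Adults get ages from ``adult_age_range``, the remainder are immatures
    with random sex.  Founder genotypes are Hardy-Weinberg draws from
    per-locus allele frequencies sampled from a symmetric Dirichlet.
    Founder males carry no birth group (they were introduced, not born, to
    their group), so none counts as natal.
    """
    state = _State()
    start = dt.date(cfg.start_year, 1, 1)
    n_immature = cfg.n_founders - cfg.n_adult_females - cfg.n_adult_males

    sexes = ([FEMALE] * cfg.n_adult_females + [MALE] * cfg.n_adult_males
             + [FEMALE if rng.random() < 0.5 else MALE
                for _ in range(n_immature)])
    lo_a, hi_a = cfg.adult_age_range
    lo_i, hi_i = cfg.immature_age_range
    ages = np.concatenate([
        rng.uniform(lo_a, hi_a, cfg.n_adult_females + cfg.n_adult_males),
        rng.uniform(lo_i, hi_i, n_immature),
    ])
    groups = rng.integers(cfg.n_groups, size=cfg.n_founders)

    freqs = None
    if cfg.n_loci > 0:
        freqs = rng.dirichlet(
            np.full(cfg.alleles_per_locus, cfg.dirichlet_alpha),
            size=cfg.n_loci)

    for sex, age, grp in zip(sexes, ages, groups):
        iid = state.new_id("F")
        birth = start - dt.timedelta(days=int(age * DAYS_PER_YEAR))
        group = f"G{int(grp) + 1}"
        # founder females are treated as philopatric in their release group
        state.add(iid, None, None, sex, birth,
                  group if sex == FEMALE else None)
        state.intervals[iid] = [(birth, None, group)]
        if freqs is not None:
            geno = np.empty((cfg.n_loci, 2), dtype=np.int64)
            for locus in range(cfg.n_loci):
                geno[locus] = rng.choice(cfg.alleles_per_locus, size=2,
                                         p=freqs[locus])
            state.founder_genotypes[iid] = geno
    state.founder_freqs = freqs
    return state


def _eligible_pools(state: _State, mother_group, conception,
                    maturity_age: float) -> av.SirePools:
    natal, within, extra = [], [], []
    for iid, rec in state.records.items():
        if rec["sex"] != MALE:
            continue
        if not state.alive(iid, conception):
            continue
        if state.age(iid, conception) < maturity_age:
            continue
        group = state.group_at(iid, conception)
        if group is None:
            continue
        if group == mother_group:
            if rec["birth_group"] == group:
                natal.append(iid)
            else:
                within.append(iid)
        else:
            extra.append(iid)
    return av.SirePools(natal=natal, within=within, extra=extra)


def _choose_sire(state: _State, mother, pool, mate: MateChoiceModel, rng):
    """Uniform draw with kin-avoidant rejection."""
    sire = pool[int(rng.integers(len(pool)))]
    if mate.theta <= 0.0:
        return sire
    tries = 0
    while (state.relatedness(mother, sire) >= mate.r_threshold
           and rng.random() < mate.theta):
        tries += 1
        if tries > mate.max_redraws:
            return min(pool, key=lambda m: (state.relatedness(mother, m), m))
        sire = pool[int(rng.integers(len(pool)))]
    return sire


def simulate_years(state: _State, cfg: DemographyConfig,
                   mate: MateChoiceModel | None = None,
                   rng=None, start_year: int | None = None) -> _State:
    """Advance the population ``cfg.n_years`` one birth season at a time.

    Each year: adult females give birth with ``birth_probability``; each
    cohort's sires are assigned by the extra-group / natal / within-group
    scheme with the within-group pool thinned to ``skew_fraction`` per
    group, then filtered through the mate-choice model; newborn males draw
    a dispersal age and a destination group; mortality and optional culling
    close the year.
    """
    mate = mate or MateChoiceModel()
    rng = rng if rng is not None else np.random.default_rng()
    if start_year is None:
        start_year = max(r["birth_date"].year
                         for r in state.records.values()) + 1
    group_names = sorted({g for ivs in state.intervals.values()
                          for _, _, g in ivs})
    warnings_log: list[str] = []
    state.sim_warnings = warnings_log

    for year in range(start_year, start_year + cfg.n_years):
        season_ref = dt.date(year, 1, 1)
        mothers = [
            i for i, r in state.records.items()
            if r["sex"] == FEMALE and state.alive(i, season_ref)
            and state.age(i, season_ref) >= cfg.maturity_age
        ]
        mothers.sort()
        births = [m for m in mothers if rng.random() < cfg.birth_probability]
        if not births:
            continue
        cohort = []
        for m in births:
            bdate = _random_date(year, rng)
            conc = bdate - dt.timedelta(days=cfg.conception_offset)
            if not state.alive(m, conc):
                continue
            grp = state.group_at(m, conc)
            cohort.append((m, bdate, conc, grp))

        cats = av.assign_categories(len(cohort), cfg.p_extra, cfg.p_natal,
                                    cfg.partition, rng)
        pools = [_eligible_pools(state, grp, conc, cfg.maturity_age)
                 for (_, _, conc, grp) in cohort]

        # one skew subsample per group per cohort
        cohort_pool: dict = {}
        for (m, bdate, conc, grp), pl in zip(cohort, pools):
            cohort_pool.setdefault(grp, set()).update(pl.within)
        cohort_sub: dict = {}
        for grp in sorted(cohort_pool, key=repr):
            pool = sorted(cohort_pool[grp])
            if pool:
                cohort_sub[grp] = av.skew_subsample(
                    pool, cfg.skew_fraction, rng)
            else:
                cohort_sub[grp] = []

        extinct = True
        for (m, bdate, conc, grp), pl, cat in zip(cohort, pools, cats):
            sub = [x for x in cohort_sub[grp] if x in pl.within] or pl.within
            if cat == 0:
                pool = pl.extra or sub
            elif cat == 1:
                pool = pl.natal or sub
            else:
                pool = sub
            if not pool:
                pool = pl.natal or pl.extra
            if not pool:
                warnings_log.append(
                    f"{year}: no eligible sire for a birth in group {grp}")
                continue
            extinct = False
            sire = _choose_sire(state, m, pool, mate, rng)
            child = state.new_id("I")
            sex = FEMALE if rng.random() < 0.5 else MALE
            state.add(child, sire, m, sex, bdate, grp)
            if sex == MALE:
                disp_age = (cfg.dispersal_min_age
                            + rng.exponential(
                                (cfg.dispersal_median_age
                                 - cfg.dispersal_min_age) / math.log(2)))
                disp_date = bdate + dt.timedelta(
                    days=int(disp_age * DAYS_PER_YEAR))
                others = [g for g in group_names if g != grp]
                if others:
                    dest = others[int(rng.integers(len(others)))]
                    state.intervals[child] = [(bdate, disp_date, grp),
                                              (disp_date, None, dest)]
                else:
                    state.intervals[child] = [(bdate, None, grp)]
            else:
                state.intervals[child] = [(bdate, None, grp)]

        if extinct and cohort:
            warnings_log.append(f"{year}: no sire available for any birth")

        # mortality at year end
        year_end = dt.date(year, 12, 31)
        for iid in state.living_ids(year_end):
            rec = state.records[iid]
            age = state.age(iid, year_end)
            if age < 1.0:
                p_die = cfg.infant_mortality
            elif age > cfg.max_age:
                p_die = 1.0
            else:
                p_die = cfg.adult_annual_mortality
            if rng.random() < p_die:
                lived = (year_end - rec["birth_date"]).days
                offset = int(rng.integers(min(365, max(lived, 1))))
                rec["death_date"] = year_end - dt.timedelta(days=offset)
                if rec["death_date"] <= rec["birth_date"]:
                    rec["death_date"] = rec["birth_date"] + dt.timedelta(days=1)

        if cfg.culling_target is not None:
            alive = state.living_ids(year_end)
            excess = len(alive) - cfg.culling_target
            if excess > 0:
                lo, hi = cfg.culling_age_range
                juveniles = sorted(
                    i for i in alive if lo <= state.age(i, year_end) <= hi)
                take = min(excess, len(juveniles))
                for k in rng.choice(len(juveniles), size=take, replace=False):
                    rec = state.records[juveniles[k]]
                    rec["death_date"] = year_end
                    rec["removed"] = True

        if not any(state.records[i]["sex"] == FEMALE
                   for i in state.living_ids(year_end)):
            warnings_log.append(f"{year}: population extinct")
            logger.warning("population extinct in %d; partial output", year)
            break
    return state


def drop_genotypes(pedigree: Pedigree, founder_genotypes: dict,
                   missing_rate: float = 0.0, rng=None,
                   n_loci: int | None = None) -> GenotypeTable:
    """Mendelian gene dropping: every non-founder inherits one uniformly
    chosen allele per locus from each parent; whole genotypes are then
    masked at ``missing_rate``."""
    rng = rng if rng is not None else np.random.default_rng()
    if n_loci is None:
        any_geno = next(iter(founder_genotypes.values()))
        n_loci = any_geno.shape[0]
    genos: dict = {}
    for iid in pedigree.topological_order():
        sire, dam = pedigree.parents(iid)
        if sire is None and dam is None:
            if iid not in founder_genotypes:
                raise SimulationError(f"founder {iid!r} has no genotypes")
            genos[iid] = founder_genotypes[iid]
            continue
        if sire is None or dam is None or sire not in genos or dam not in genos:
            raise SimulationError(
                f"individual {iid!r} has an ungenotyped or missing parent")
        child = np.empty((n_loci, 2), dtype=np.int64)
        for parent_idx, parent in enumerate((sire, dam)):
            picks = rng.integers(0, 2, size=n_loci)
            child[:, parent_idx] = genos[parent][np.arange(n_loci), picks]
        genos[iid] = child

    ids = sorted(genos)
    arr = np.stack([genos[i] for i in ids]).astype(float)  # (n, loci, 2)
    if missing_rate > 0:
        mask = rng.random((len(ids), n_loci)) < missing_rate
        arr[mask] = np.nan
    cols = {}
    for locus in range(n_loci):
        cols[f"L{locus + 1:02d}.1"] = arr[:, locus, 0]
        cols[f"L{locus + 1:02d}.2"] = arr[:, locus, 1]
    wide = pd.DataFrame(cols, index=pd.Index(ids, name="id"))
    return GenotypeTable.from_wide(wide)


def _finalize(state: _State, founder_cfg, demog_cfg, mate, seed,
              missing_rate: float, rng) -> SimOutput:
    records = [PedigreeRecord(**rec) for _, rec in
               sorted(state.records.items())]
    pedigree = Pedigree.from_records(records)
    demog_rows = [(iid, g, s, e) for iid, ivs in sorted(state.intervals.items())
                  for s, e, g in ivs]
    demography = av.Demography(pd.DataFrame(
        demog_rows, columns=["id", "group", "start_date", "end_date"]))
    true_f = pd.Series(
        {iid: (state.kinship(rec["sire"], rec["dam"])
               if rec["sire"] is not None else 0.0)
         for iid, rec in state.records.items()},
        name="F").sort_index()
    genotypes = None
    if founder_cfg.n_loci > 0:
        genotypes = drop_genotypes(pedigree, state.founder_genotypes,
                                   missing_rate=missing_rate, rng=rng)
    return SimOutput(
        pedigree=pedigree, genotypes=genotypes, demography=demography,
        true_F=true_f, founder_config=founder_cfg,
        demography_config=demog_cfg, mate_choice=mate, seed=seed,
        warnings=list(getattr(state, "sim_warnings", [])),
    )


def simulate_population(founder_cfg: FounderConfig | None = None,
                        demog_cfg: DemographyConfig | None = None,
                        mate: MateChoiceModel | None = None,
                        seed=None, missing_rate: float = 0.0) -> SimOutput:
    """End-to-end simulation: founders, years of reproduction, gene-dropped
    genotypes, all from one seeded generator."""
    founder_cfg = founder_cfg or FounderConfig()
    demog_cfg = demog_cfg or DemographyConfig()
    mate = mate or MateChoiceModel()
    rng = np.random.default_rng(seed)
    state = generate_founders(founder_cfg, rng)
    simulate_years(state, demog_cfg, mate, rng,
                   start_year=founder_cfg.start_year)
    return _finalize(state, founder_cfg, demog_cfg, mate, seed,
                     missing_rate, rng)


def replicate_avoidance_pvalues(theta: float = 0.0, n_runs: int = 50,
                                n_sim: int = 100, seed=None,
                                founder_cfg: FounderConfig | None = None,
                                demog_cfg: DemographyConfig | None = None
                                ) -> np.ndarray:
    """P-values of the avoidance test over independently simulated
    populations whose mate choice has avoidance strength ``theta``.

    With ``theta = 0`` sires are generated by exactly the scheme the test
    simulates, so the returned P-values probe the test's type-I error;
    with ``theta = 1`` they probe its power.  The test is run without the
    pedigree-completeness filter and with the same category-partition mode
    as the generator, so that under ``theta = 0`` the observed dataset is
    exchangeable with the simulated ones.
    """
    founder_cfg = founder_cfg or FounderConfig(
        n_founders=80, n_adult_females=30, n_adult_males=12,
        n_groups=3, n_loci=0)
    demog_cfg = demog_cfg or DemographyConfig(
        n_years=12, birth_probability=0.5, partition="bernoulli")
    rng = np.random.default_rng(seed)
    pvals = np.empty(n_runs)
    for k in range(n_runs):
        s_pop, s_fit = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
        sim = simulate_population(founder_cfg, demog_cfg,
                                  MateChoiceModel(theta=theta), seed=s_pop)
        pairs = av.breeding_records(
            sim.pedigree, sim.demography,
            conception_offset=demog_cfg.conception_offset)
        scheme = av.SimulationScheme(
            p_extra=demog_cfg.p_extra, p_natal=demog_cfg.p_natal,
            skew_fraction=demog_cfg.skew_fraction,
            maturity_age=demog_cfg.maturity_age,
            conception_offset=demog_cfg.conception_offset,
            completeness_filter_depth=0, partition=demog_cfg.partition,
            n_sim=n_sim)
        model = av.MateChoiceNullModel(sim.pedigree, sim.demography,
                                       pairs, scheme)
        pvals[k] = model.fit(seed=s_fit).pvalue
    return pvals


def recovery_harness(sim: SimOutput, seed=None, n_sim: int = 200) -> dict:
    """Self-check on a simulated population: (a) pedigree F recomputed from
    a file round trip matches the generator's true F exactly; (b) marker
    estimators correlate with true F in the expected directions; (c) the
    avoidance test runs end to end on the emitted tables."""
    import io as _io

    from scipy import stats as _stats

    from .io import read_pedigree, write_pedigree

    buf = _io.StringIO()
    write_pedigree(sim.pedigree, buf)
    buf.seek(0)
    ped2 = read_pedigree(buf)
    max_abs_err = 0.0
    for iid in sim.true_F.index:
        case = ped2.inbreeding_coefficient(iid)
        f = case.F if case.F is not None else 0.0
        max_abs_err = max(max_abs_err, abs(f - sim.true_F[iid]))

    report: dict = {"F_roundtrip_max_abs_error": max_abs_err}

    if sim.genotypes is not None:
        from .estimators import estimate_all
        est = estimate_all(sim.genotypes, min_loci=1)
        joined = est.table.join(sim.true_F)
        joined = joined.dropna()
        for col in ("SH", "IR", "HL"):
            if joined[col].nunique() > 1 and joined["F"].nunique() > 1:
                rho = _stats.spearmanr(joined[col], joined["F"]).statistic
            else:
                rho = float("nan")
            report[f"spearman_F_{col}"] = float(rho)

    scheme = av.SimulationScheme(
        p_extra=sim.demography_config.p_extra,
        p_natal=sim.demography_config.p_natal,
        skew_fraction=sim.demography_config.skew_fraction,
        maturity_age=sim.demography_config.maturity_age,
        conception_offset=sim.demography_config.conception_offset,
        completeness_filter_depth=0,
        partition=sim.demography_config.partition,
        n_sim=n_sim,
    )
    pairs = av.breeding_records(
        sim.pedigree, sim.demography,
        conception_offset=sim.demography_config.conception_offset)
    if pairs:
        model = av.MateChoiceNullModel(sim.pedigree, sim.demography,
                                       pairs, scheme)
        res = model.fit(seed=seed)
        report["avoidance_p"] = res.pvalue
        report["observed_mean_r"] = res.observed.mean
        report["null_mean_r"] = res.null_mean
    return report
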