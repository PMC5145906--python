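"""Marker-based inbreeding estimators for diploid codominant genotypes.

Three individual-level estimators widely used in heterozygosity–fitness
studies with microsatellite (STR) panels:

* **SH** (standardized heterozygosity): the individual's proportion of
  heterozygous typed loci divided by the mean population heterozygosity of
  the loci it was typed at.  0 means fully homozygous; values above 1 mean
  more heterozygous than the panel average.
* **IR** (internal relatedness): ``(2H - sum f_i) / (2N - sum f_i)`` where
  ``H`` is the number of homozygous typed loci, ``N`` the number of typed
  loci and ``sum f_i`` the summed sample frequencies of the individual's
  ``2N`` allele copies.  Rare shared alleles weigh more; range [-1, 1],
  positive values indicating more inbred parentage.
* **HL** (homozygosity by loci): ``sum E_h / (sum E_h + sum E_j)`` where
  ``E`` is a locus's expected heterozygosity ``1 - sum p_k^2``, summed over
  the individual's homozygous (``E_h``) and heterozygous (``E_j``) typed
  loci.  Range [0, 1]; 1 means all loci homozygous, 0 all heterozygous.

Allele frequencies are by default computed on the full genotyped sample,
focal individual included; ``exclude_focal`` recomputes them per individual
with that individual's two copies removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy import stats


class GenotypeError(ValueError):
    pass


@dataclass
class GenotypeTable:
    """Diploid genotypes: ``data[locus]`` is a DataFrame indexed by
    individual with columns ``a1``/``a2`` (NaN pair = missing genotype).

    Build from a wide DataFrame with :meth:`from_wide` (columns
    ``<locus>.1``, ``<locus>.2``).
    """

    individuals: list
    loci: list
    data: dict = field(repr=False, default_factory=dict)

    @classmethod
    def from_wide(cls, df: pd.DataFrame) -> "GenotypeTable":
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise GenotypeError(f"duplicate individual ids: {dupes}")
        loci: list = []
        data: dict = {}
        cols = list(df.columns)
        if len(cols) % 2 != 0:
            raise GenotypeError(
                f"odd number of allele columns ({len(cols)}); expected "
                "two columns per locus named <locus>.1 and <locus>.2")
        for c1, c2 in zip(cols[::2], cols[1::2]):
            base1, _, suf1 = str(c1).rpartition(".")
            base2, _, suf2 = str(c2).rpartition(".")
            if base1 != base2 or {suf1, suf2} != {"1", "2"}:
                raise GenotypeError(
                    f"columns {c1!r}/{c2!r} do not form a <locus>.1/<locus>.2 pair")
            sub = df[[c1, c2]].copy()
            sub.columns = ["a1", "a2"]
            half = sub["a1"].isna() != sub["a2"].isna()
            if half.any():
                raise GenotypeError(
                    f"half-called genotypes at locus {base1!r} for "
                    f"{df.index[half].tolist()}")
            loci.append(base1)
            data[base1] = sub
        return cls(individuals=list(df.index), loci=loci, data=data)

    def to_wide(self) -> pd.DataFrame:
        out = {}
        for locus in self.loci:
            out[f"{locus}.1"] = self.data[locus]["a1"]
            out[f"{locus}.2"] = self.data[locus]["a2"]
        return pd.DataFrame(out, index=pd.Index(self.individuals, name="id"))

    def genotype(self, individual, locus):
        """Unordered allele pair, or None if untyped."""
        row = self.data[locus].loc[individual]
        if pd.isna(row["a1"]):
            return None
        return (row["a1"], row["a2"])

    def n_typed(self, individual) -> int:
        return sum(self.genotype(individual, loc) is not None
                   for loc in self.loci)


@dataclass
class LocusFrequencies:
    frequencies: pd.Series  # allele -> sample frequency
    h_obs: float            # fraction of typed individuals heterozygous
    h_exp: float            # 1 - sum p^2
    n_typed: int


@dataclass
class AlleleFrequencies:
    """Per-locus sample allele frequencies plus observed/expected
    heterozygosity; loci with no typed individuals are dropped."""

    loci: dict  # locus -> LocusFrequencies

    def __getitem__(self, locus) -> LocusFrequencies:
        return self.loci[locus]

    def __contains__(self, locus) -> bool:
        return locus in self.loci


def allele_frequencies(g: GenotypeTable,
                       exclude: object | None = None) -> AlleleFrequencies:
    """Sample allele frequencies, H_obs and H_exp per locus, counting both
    alleles of every typed individual.  ``exclude`` removes one individual's
    copies from the counts (for focal-excluded weighting)."""
    if not g.loci or not g.individuals:
        raise GenotypeError("empty genotype table")
    out: dict = {}
    for locus in g.loci:
        sub = g.data[locus]
        if exclude is not None:
            sub = sub.drop(index=exclude, errors="ignore")
        typed = sub.dropna()
        if typed.empty:
            warnings.warn(f"locus {locus!r} has no typed individuals; dropped",
                          stacklevel=2)
            continue
        counts = pd.concat([typed["a1"], typed["a2"]]).value_counts()
        freqs = counts / counts.sum()
        h_obs = float((typed["a1"] != typed["a2"]).mean())
        h_exp = float(1.0 - np.sum(freqs.to_numpy() ** 2))
        out[locus] = LocusFrequencies(frequencies=freqs, h_obs=h_obs,
                                      h_exp=h_exp, n_typed=len(typed))
    if not out:
        raise GenotypeError("no locus with typed individuals")
    return AlleleFrequencies(loci=out)


def _typed_loci(ind, g: GenotypeTable, freqs: AlleleFrequencies):
    for locus in g.loci:
        if locus not in freqs:
            continue
        geno = g.genotype(ind, locus)
        if geno is not None:
            yield locus, geno


def standardized_heterozygosity(ind, g: GenotypeTable, freqs: AlleleFrequencies,
                                use_expected: bool = False) -> float:
    """SH: proportion of heterozygous typed loci over the mean population
    heterozygosity of the individual's typed loci (observed heterozygosity
    by default, expected with ``use_expected``).  NaN when the denominator
    is zero (all typed loci monomorphic) or the individual is untyped."""
    het = 0
    mean_h = []
    for locus, (a1, a2) in _typed_loci(ind, g, freqs):
        het += a1 != a2
        lf = freqs[locus]
        mean_h.append(lf.h_exp if use_expected else lf.h_obs)
    if not mean_h:
        return float("nan")
    denom = float(np.mean(mean_h))
    if denom == 0.0:
        return float("nan")
    return (het / len(mean_h)) / denom


def internal_relatedness(ind, g: GenotypeTable, freqs: AlleleFrequencies) -> float:
    """IR = (2H - sum f_i) / (2N - sum f_i); NaN when degenerate."""
    hom = 0
    n = 0
    sum_f = 0.0
    for locus, (a1, a2) in _typed_loci(ind, g, freqs):
        n += 1
        hom += a1 == a2
        f = freqs[locus].frequencies
        sum_f += float(f[a1]) + float(f[a2])
    denom = 2.0 * n - sum_f
    if n == 0 or denom <= 0:
        return float("nan")
    return (2.0 * hom - sum_f) / denom


def homozygosity_by_loci(ind, g: GenotypeTable, freqs: AlleleFrequencies) -> float:
    """HL = sum E_h / (sum E_h + sum E_j); NaN when every typed locus is
    monomorphic (all expected heterozygosities zero)."""
    e_hom = 0.0
    e_het = 0.0
    n = 0
    for locus, (a1, a2) in _typed_loci(ind, g, freqs):
        n += 1
        e = freqs[locus].h_exp
        if a1 == a2:
            e_hom += e
        else:
            e_het += e
    total = e_hom + e_het
    if n == 0 or total == 0.0:
        return float("nan")
    return e_hom / total


@dataclass
class MarkerEstimates:
    """Per-individual SH/IR/HL plus Spearman rank correlations among them.

    ``table`` has columns ``n_loci, SH, IR, HL`` indexed by individual;
    individuals failing the minimum-loci filter keep their row with NaN
    estimates.  ``correlations`` maps pairs like ``("HL", "SH")`` to rho
    (NaN when undefined, e.g. zero variance or fewer than two individuals).
    """

    table: pd.DataFrame
    correlations: dict

    def summary(self) -> str:
        lines = ["Marker-based inbreeding estimators",
                 "=" * 42,
                 f"individuals: {len(self.table)}  "
                 f"(estimated: {int(self.table['SH'].notna().sum())})",
                 "",
                 self.table.describe().loc[["mean", "std", "min", "max"]]
                     .to_string(float_format=lambda v: f"{v:.4f}"),
                 "",
                 "Spearman rank correlations:"]
        for (a, b), rho in self.correlations.items():
            lines.append(f"  {a} ~ {b}: {rho: .4f}")
        return "\n".join(lines)


def estimate_all(g: GenotypeTable, min_loci: int = 10,
                 exclude_focal: bool = False,
                 sh_expected_het: bool = False) -> MarkerEstimates:
    """SH, IR and HL for every individual typed at >= ``min_loci`` loci,
    with the three pairwise Spearman correlations among the estimators.

    Individuals below the filter are reported with NaN estimates, never
    dropped.  ``exclude_focal`` recomputes allele frequencies without the
    focal individual for its own estimates.
    """
    base_freqs = allele_frequencies(g)
    rows = []
    for ind in g.individuals:
        n = g.n_typed(ind)
        if n < min_loci:
            rows.append((ind, n, np.nan, np.nan, np.nan))
            continue
        freqs = allele_frequencies(g, exclude=ind) if exclude_focal else base_freqs
        rows.append((
            ind, n,
            standardized_heterozygosity(ind, g, freqs,
                                        use_expected=sh_expected_het),
            internal_relatedness(ind, g, freqs),
            homozygosity_by_loci(ind, g, freqs),
        ))
    table = pd.DataFrame(rows, columns=["id", "n_loci", "SH", "IR", "HL"])
    table = table.set_index("id")

    correlations: dict = {}
    for a, b in (("HL", "SH"), ("IR", "SH"), ("HL", "IR")):
        sub = table[[a, b]].dropna()
        if len(sub) < 2 or sub[a].nunique() < 2 or sub[b].nunique() < 2:
            correlations[(a, b)] = float("nan")
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rho = stats.spearmanr(sub[a], sub[b]).statistic
            correlations[(a, b)] = float(rho)
    return MarkerEstimates(table=table, correlations=correlations)
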