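"""Pedigree construction, kinship and depth-truncated inbreeding coefficients.

The central quantity is the kinship coefficient ``f(i, j)``: the probability
that an allele drawn at random from individual *i* and one drawn from *j* are
identical by descent within the recorded pedigree.  Additive relatedness is
``r = 2 f`` and the inbreeding coefficient of an individual is the kinship of
its parents, ``F = f(sire, dam)``.

Pedigree depth is counted in ancestor generations above a focal individual
(parents are generation 1, grandparents generation 2).  A "complete
three-generation pedigree" in the field's usage therefore corresponds to
``ancestor_complete_depth >= 2`` and a four-generation pedigree to ``>= 3``.
Depth-truncated coefficients treat every ancestor beyond the stated depth as
a fresh, unrelated and non-inbred founder, which is how shallow pedigrees
hide inbreeding events whose common ancestor sits deeper in the genealogy.

Founders (individuals with no recorded parents) are assumed unrelated and
non-inbred throughout.
"""

from __future__ import annotations

import datetime as dt
from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

Identifier = Hashable

MALE = "M"
FEMALE = "F"
UNKNOWN = "U"

#: Relationship taxonomy used when classifying how the parents of an inbred
#: individual are related.  Anything outside it collapses to "other".
RELATIONSHIP_LABELS = (
    "parent-offspring",
    "full-sibs",
    "maternal half-sibs",
    "paternal half-sibs",
    "uncle-niece",
    "aunt-nephew",
    "first cousins",
    "other",
)

KIN_LINES = ("maternal", "paternal", "maternal-and-paternal")


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, sex conflicts)."""


@dataclass(frozen=True)
class PedigreeRecord:
    """One individual: identity, parent links, sex, dates, natal group."""

    id: Identifier
    sire: Identifier | None = None
    dam: Identifier | None = None
    sex: str = UNKNOWN
    birth_date: dt.date | None = None
    death_date: dt.date | None = None
    removed: bool = False
    birth_group: Identifier | None = None
    is_stub: bool = False


@dataclass
class ValidationReport:
    """Outcome of pedigree validation: stub founders created, date issues."""

    n_records: int = 0
    n_stubs: int = 0
    stub_ids: list[Identifier] = field(default_factory=list)
    date_violations: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class KinshipValue:
    pair: tuple[Identifier, Identifier]
    f: float
    depth_limit: int | None = None


@dataclass(frozen=True)
class RelatednessValue:
    pair: tuple[Identifier, Identifier]
    r: float
    depth_limit: int | None = None


@dataclass(frozen=True)
class KinPath:
    """A group of inbreeding loops sharing a relationship interpretation.

    ``ancestors`` holds the nearest common ancestors involved,
    ``relationship`` one of :data:`RELATIONSHIP_LABELS`, ``kin_line`` whether
    the two breeders reach those ancestors through their sires, their dams or
    a mix, ``contribution`` the summed term
    ``(1/2)^(n_up + n_down + 1) * (1 + F_ancestor)`` of the loops, and
    ``detail`` a raw description of the path lengths for "other" paths.
    """

    ancestors: frozenset
    relationship: str
    kin_line: str
    contribution: float
    detail: str = ""


@dataclass(frozen=True)
class InbreedingCase:
    """Inbreeding coefficient of one individual at a stated pedigree depth."""

    individual: Identifier
    F: float | None
    depth_limit: int | None
    kin_paths: tuple[KinPath, ...] | None = None

    @property
    def defined(self) -> bool:
        return self.F is not None


@dataclass(frozen=True)
class GeneDropResult:
    individual: Identifier
    F_hat: float
    se: float
    n_replicates: int


@dataclass
class PrevalenceSummary:
    """Counts and proportions of inbred individuals, per cohort and overall."""

    per_cohort: pd.DataFrame
    overall: pd.Series

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [self.per_cohort.to_string(), "", "overall:"]
        lines.append(self.overall.to_string())
        return "\n".join(lines)


def _as_parent(value) -> Identifier | None:
    if value is None:
        return None
    if isinstance(value, float) and np.isnan(value):
        return None
    if isinstance(value, str) and value.strip() in ("", "NA", "0"):
        return None
    if isinstance(value, (int, np.integer)) and value == 0:
        return None
    return value


class Pedigree:
    """A validated pedigree with parent indexes and memoized kinship.

    Build with :meth:`from_records` (an iterable of mappings or
    :class:`PedigreeRecord`) or :func:`build_pedigree`.  Parent links must
    form a directed acyclic graph; parents referenced but absent from the
    input are created as flagged founder stubs.
    """

    def __init__(self, records: Mapping[Identifier, PedigreeRecord],
                 report: ValidationReport | None = None):
        self.records: dict[Identifier, PedigreeRecord] = dict(records)
        self.report = report or ValidationReport(n_records=len(self.records))
        self._offspring: dict[Identifier, list[Identifier]] = {}
        for rec in self.records.values():
            for parent in (rec.sire, rec.dam):
                if parent is not None:
                    self._offspring.setdefault(parent, []).append(rec.id)
        self._rank = self._compute_ranks()
        self._kin_cache: dict[tuple, float] = {}

    # ------------------------------------------------------------------ #
    # construction and validation

    @classmethod
    def from_records(cls, rows: Iterable, strict_dates: bool = False) -> "Pedigree":
        records: dict[Identifier, PedigreeRecord] = {}
        for row in rows:
            if not isinstance(row, PedigreeRecord):
                row = PedigreeRecord(
                    id=row["id"],
                    sire=_as_parent(row.get("sire")),
                    dam=_as_parent(row.get("dam")),
                    sex=row.get("sex", UNKNOWN) or UNKNOWN,
                    birth_date=row.get("birth_date"),
                    death_date=row.get("death_date"),
                    removed=bool(row.get("removed", False)),
                    birth_group=row.get("birth_group"),
                )
            if row.id in records:
                raise PedigreeError(f"duplicate id {row.id!r}")
            if row.sire == row.id or row.dam == row.id:
                raise PedigreeError(f"individual {row.id!r} is its own parent")
            records[row.id] = row

        report = ValidationReport(n_records=len(records))
        for rec in list(records.values()):
            for parent in (rec.sire, rec.dam):
                if parent is not None and parent not in records:
                    records[parent] = PedigreeRecord(id=parent, is_stub=True)
                    report.stub_ids.append(parent)
        report.n_stubs = len(report.stub_ids)
        report.n_records = len(records)

        offenders = []
        for rec in records.values():
            if rec.sire is not None and records[rec.sire].sex == FEMALE:
                offenders.append((rec.id, rec.sire, "female sire"))
            if rec.dam is not None and records[rec.dam].sex == MALE:
                offenders.append((rec.id, rec.dam, "male dam"))
        if offenders:
            msg = "; ".join(f"{c!r}: {p!r} is a {what}" for c, p, what in offenders)
            raise PedigreeError(f"parent sex inconsistency: {msg}")

        for rec in records.values():
            if rec.birth_date is None:
                continue
            for parent in (rec.sire, rec.dam):
                if parent is None:
                    continue
                pb = records[parent].birth_date
                if pb is not None and pb >= rec.birth_date:
                    report.date_violations.append(
                        f"parent {parent!r} born {pb} not before offspring "
                        f"{rec.id!r} born {rec.birth_date}"
                    )
        if strict_dates and report.date_violations:
            raise PedigreeError(
                "date-order violations: " + "; ".join(report.date_violations)
            )
        return cls(records, report)

    def _compute_ranks(self) -> dict[Identifier, int]:
        # Kahn topological pass; rank = longest founder-to-node path length.
        # Doubles as the cycle check.
        indeg = {i: 0 for i in self.records}
        for rec in self.records.values():
            indeg[rec.id] = sum(p is not None for p in (rec.sire, rec.dam))
        queue = deque(i for i, d in indeg.items() if d == 0)
        rank: dict[Identifier, int] = {i: 0 for i in queue}
        seen = 0
        while queue:
            node = queue.popleft()
            seen += 1
            for child in self._offspring.get(node, ()):
                rank[child] = max(rank.get(child, 0), rank[node] + 1)
                indeg[child] -= 1
                if indeg[child] == 0:
                    queue.append(child)
        if seen != len(self.records):
            cyclic = sorted((i for i, d in indeg.items() if d > 0), key=repr)
            raise PedigreeError(
                f"parent links contain a cycle involving {cyclic[0]!r}"
            )
        return rank

    # ------------------------------------------------------------------ #
    # basic queries

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, id: Identifier) -> bool:
        return id in self.records

    def __getitem__(self, id: Identifier) -> PedigreeRecord:
        return self.records[id]

    @property
    def ids(self) -> list[Identifier]:
        return list(self.records)

    def parents(self, id: Identifier) -> tuple[Identifier | None, Identifier | None]:
        rec = self.records[id]
        return rec.sire, rec.dam

    def founders(self) -> list[Identifier]:
        return [i for i, r in self.records.items()
                if r.sire is None and r.dam is None]

    def topological_order(self) -> list[Identifier]:
        """Ids sorted parents-before-offspring (deterministic)."""
        return sorted(self.records, key=lambda i: (self._rank[i], repr(i)))

    def ancestor_complete_depth(self, id: Identifier) -> int:
        """Number of fully known ancestor generations above ``id``.

        Returns the largest ``d`` such that for every generation
        ``1 <= g <= d`` all ``2**g`` ancestors exist as real (non-stub)
        records.  A founder returns 0.
        """
        if id not in self.records:
            raise KeyError(f"unknown id {id!r}")
        frontier = [id]
        depth = 0
        while True:
            parents: list[Identifier] = []
            for node in frontier:
                rec = self.records[node]
                if rec.sire is None or rec.dam is None:
                    return depth
                for p in (rec.sire, rec.dam):
                    if self.records[p].is_stub:
                        return depth
                    parents.append(p)
            depth += 1
            frontier = parents

    # ------------------------------------------------------------------ #
    # kinship machinery

    def _visible_parents(self, roots: Sequence[Identifier], depth: int
                         ) -> Callable[[Identifier], tuple]:
        """Parent accessor for the pedigree truncated ``depth`` generations
        above ``roots``: a node keeps its parents only while its minimum
        generation distance from a root is below ``depth``."""
        dist: dict[Identifier, int] = {}
        queue = deque()
        for r in roots:
            dist[r] = 0
            queue.append(r)
        while queue:
            node = queue.popleft()
            if dist[node] >= depth:
                continue
            for p in self.parents(node):
                if p is not None and (p not in dist or dist[p] > dist[node] + 1):
                    dist[p] = dist[node] + 1
                    queue.append(p)

        def parent_of(i: Identifier) -> tuple:
            if dist.get(i, depth) >= depth:
                return (None, None)
            return self.parents(i)

        return parent_of

    def _kin(self, i, j, parent_of, cache) -> float:
        rank = self._rank
        if i is None or j is None:
            return 0.0
        if i == j:
            key = (i,)
            hit = cache.get(key)
            if hit is not None:
                return hit
            s, d = parent_of(i)
            val = 0.5 * (1.0 + self._kin(s, d, parent_of, cache))
            cache[key] = val
            return val
        key = (i, j) if repr(i) <= repr(j) else (j, i)
        hit = cache.get(key)
        if hit is not None:
            return hit
        # Expand the individual furthest from the founders; its ancestors all
        # have strictly smaller rank, so we never expand an ancestor of the
        # other member, which the recursion requires.
        if rank[i] < rank[j]:
            i, j = j, i
        s, d = parent_of(i)
        val = 0.5 * (self._kin(s, j, parent_of, cache)
                     + self._kin(d, j, parent_of, cache))
        cache[key] = val
        return val

    def kinship(self, i: Identifier, j: Identifier,
                depth_limit: int | None = None) -> KinshipValue:
        """Kinship coefficient ``f(i, j)``.

        With ``depth_limit`` set, ancestors more than that many generations
        above either focal individual are treated as unrelated founders.
        ``f(i, i) = (1 + F_i) / 2``.
        """
        for x in (i, j):
            if x not in self.records:
                raise KeyError(f"unknown id {x!r}")
        if depth_limit is None:
            f = self._kin(i, j, self.parents, self._kin_cache)
        else:
            parent_of = self._visible_parents((i, j), depth_limit)
            f = self._kin(i, j, parent_of, {})
        return KinshipValue(pair=(i, j), f=f, depth_limit=depth_limit)

    def relatedness(self, i: Identifier, j: Identifier,
                    depth_limit: int | None = None) -> RelatednessValue:
        """Additive relatedness ``r = 2 f``."""
        k = self.kinship(i, j, depth_limit)
        return RelatednessValue(pair=k.pair, r=2.0 * k.f, depth_limit=depth_limit)

    def inbreeding_coefficient(self, id: Identifier,
                               depth_limit: int | None = None) -> InbreedingCase:
        """``F`` of ``id``: the kinship of its parents, with the ancestry of
        ``id`` truncated ``depth_limit`` generations up (parents are
        generation 1).  Undefined (``F is None``) when a parent is missing."""
        if id not in self.records:
            raise KeyError(f"unknown id {id!r}")
        sire, dam = self.parents(id)
        if sire is None or dam is None:
            return InbreedingCase(individual=id, F=None, depth_limit=depth_limit)
        if depth_limit is None:
            f = self._kin(sire, dam, self.parents, self._kin_cache)
        else:
            parent_of = self._visible_parents((id,), depth_limit)
            f = self._kin(sire, dam, parent_of, {})
        return InbreedingCase(individual=id, F=f, depth_limit=depth_limit)

    # ------------------------------------------------------------------ #
    # kin-path classification

    def _ascending_paths(self, start: Identifier, parent_of, max_len: int):
        """All simple ascending paths from ``start``; each path is a tuple of
        (node, step) pairs where step is 'sire' or 'dam' for the link taken."""
        paths = [()]
        out = [()]
        frontier = [((), start)]
        while frontier:
            nxt = []
            for path, node in frontier:
                if len(path) >= max_len:
                    continue
                s, d = parent_of(node)
                for p, step in ((s, "sire"), (d, "dam")):
                    if p is None:
                        continue
                    new = path + ((p, step),)
                    out.append(new)
                    nxt.append((new, p))
            frontier = nxt
        return out

    def classify_inbreeding(self, id: Identifier,
                            depth_limit: int | None = None) -> InbreedingCase:
        """``F`` of ``id`` together with the kin-path classification of its
        parents: which nearest common ancestors connect them, the standard
        relationship label and whether the connection runs through the
        maternal line, the paternal line or both.

        The summed contribution of the enumerated loops,
        ``sum (1/2)^(n_up + n_down + 1) (1 + F_A)``, reproduces ``F``.
        """
        case = self.inbreeding_coefficient(id, depth_limit)
        if case.F is None:
            return case
        if case.F == 0.0:
            return InbreedingCase(individual=id, F=0.0,
                                  depth_limit=depth_limit, kin_paths=())
        sire, dam = self.parents(id)
        if depth_limit is None:
            parent_of = self.parents
            max_len = max(self._rank.values()) + 1
        else:
            parent_of = self._visible_parents((id,), depth_limit)
            max_len = depth_limit  # paths start at the parents (generation 1)

        sire_paths = self._ascending_paths(sire, parent_of, max_len)
        dam_paths = self._ascending_paths(dam, parent_of, max_len)

        # Wright's loops: one ascending path from each breeder, meeting at a
        # common ancestor and sharing no other node (the breeders themselves
        # may coincide with the ancestor for ancestor-descendant matings).
        loops = []  # (ancestor, n_s, n_d, step_s, step_d, contribution)
        for ps in sire_paths:
            end_s = ps[-1][0] if ps else sire
            nodes_s = {n for n, _ in ps} | {sire}
            for pd_ in dam_paths:
                end_d = pd_[-1][0] if pd_ else dam
                if end_s != end_d:
                    continue
                ancestor = end_s
                nodes_d = {n for n, _ in pd_} | {dam}
                if (nodes_s & nodes_d) != {ancestor}:
                    continue
                fa = self._kin(*parent_of(ancestor), parent_of, {})
                contrib = 0.5 ** (len(ps) + len(pd_) + 1) * (1.0 + fa)
                step_s = ps[0][1] if ps else None
                step_d = pd_[0][1] if pd_ else None
                loops.append((ancestor, len(ps), len(pd_), step_s, step_d, contrib))

        kin_paths = self._label_loops(loops, sire, dam)
        return InbreedingCase(individual=id, F=case.F,
                              depth_limit=depth_limit, kin_paths=tuple(kin_paths))

    def _label_loops(self, loops, sire, dam):
        def line_of(step_s, step_d):
            steps = {s for s in (step_s, step_d) if s is not None}
            if steps == {"sire"}:
                return "paternal"
            if steps == {"dam"}:
                return "maternal"
            return "maternal-and-paternal"

        labelled = []  # (label, line, ancestor, contribution, detail)
        shared_parents = [lp for lp in loops if lp[1] == 1 and lp[2] == 1]
        for anc, ns, nd, step_s, step_d, contrib in loops:
            detail = f"up {ns} from sire, up {nd} from dam via {anc!r}"
            if ns == 0 or nd == 0:
                # one breeder is an ancestor of the other; the descendant's
                # steps define the kin line
                step = step_d if ns == 0 else step_s
                dist = max(ns, nd)
                label = "parent-offspring" if dist == 1 else "other"
                line = "paternal" if step == "sire" else "maternal"
            elif ns == 1 and nd == 1:
                if len(shared_parents) == 2:
                    label, line = "full-sibs", "maternal-and-paternal"
                elif step_s == step_d == "sire":
                    label, line = "paternal half-sibs", "paternal"
                elif step_s == step_d == "dam":
                    label, line = "maternal half-sibs", "maternal"
                else:
                    label, line = "other", line_of(step_s, step_d)
            elif {ns, nd} == {1, 2}:
                closer = sire if ns == 1 else dam
                sex = self.records[closer].sex
                label = {MALE: "uncle-niece", FEMALE: "aunt-nephew"}.get(sex, "other")
                line = line_of(step_s, step_d)
            elif ns == 2 and nd == 2:
                label, line = "first cousins", line_of(step_s, step_d)
            else:
                label, line = "other", line_of(step_s, step_d)
            labelled.append((label, line, anc, contrib, detail))

        grouped: dict[tuple[str, str], list] = {}
        for label, line, anc, contrib, detail in labelled:
            grouped.setdefault((label, line), []).append((anc, contrib, detail))
        out = []
        for (label, line), items in sorted(grouped.items()):
            out.append(KinPath(
                ancestors=frozenset(a for a, _, _ in items),
                relationship=label,
                kin_line=line,
                contribution=sum(c for _, c, _ in items),
                detail="; ".join(d for _, _, d in items),
            ))
        return out

    # ------------------------------------------------------------------ #
    # gene-dropping Monte-Carlo oracle

    def gene_drop_F(self, id: Identifier, n_replicates: int,
                    seed=None) -> GeneDropResult:
        """Monte-Carlo estimate of ``F`` by dropping labelled founder alleles
        down the full pedigree: each founder carries two globally distinct
        alleles; every non-founder inherits one uniformly chosen allele from
        each parent; ``F_hat`` is the fraction of replicates in which ``id``
        receives two copies of the same founder allele.
        """
        if id not in self.records:
            raise KeyError(f"unknown id {id!r}")
        if n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        rng = np.random.default_rng(seed)
        alleles: dict[Identifier, tuple[np.ndarray, np.ndarray]] = {}
        label = 0
        for node in self.topological_order():
            s, d = self.parents(node)
            pair = []
            for parent in (s, d):
                if parent is None:
                    pair.append(np.full(n_replicates, label, dtype=np.int64))
                    label += 1
                else:
                    pa, pb = alleles[parent]
                    pick = rng.integers(0, 2, size=n_replicates, dtype=np.int8)
                    pair.append(np.where(pick == 0, pa, pb))
            alleles[node] = (pair[0], pair[1])
        a, b = alleles[id]
        f_hat = float(np.mean(a == b))
        se = float(np.sqrt(f_hat * (1.0 - f_hat) / n_replicates))
        return GeneDropResult(individual=id, F_hat=f_hat, se=se,
                              n_replicates=n_replicates)


def build_pedigree(records: Iterable, strict_dates: bool = False) -> Pedigree:
    """Validate raw rows (mappings or :class:`PedigreeRecord`) into a
    :class:`Pedigree`; see :meth:`Pedigree.from_records`."""
    return Pedigree.from_records(records, strict_dates=strict_dates)


def prevalence_summary(cases: Iterable[InbreedingCase],
                       cohorts: Mapping[Identifier, Hashable] | None = None
                       ) -> PrevalenceSummary:
    """Per-cohort and overall prevalence of inbreeding (``F > 0``).

    ``cohorts`` maps individual id to a cohort label (e.g. birth year);
    omitted, all individuals form one cohort.  Cases with undefined ``F``
    are counted separately and excluded from proportions.
    """
    rows = []
    for case in cases:
        cohort = cohorts.get(case.individual) if cohorts else "all"
        rows.append((cohort, case.individual, case.F))
    df = pd.DataFrame(rows, columns=["cohort", "id", "F"])

    def summarize(group: pd.DataFrame) -> pd.Series:
        defined = group["F"].dropna()
        inbred = defined[defined > 0]
        n = len(defined)
        return pd.Series({
            "n_individuals": n,
            "n_undefined": len(group) - n,
            "n_inbred": len(inbred),
            "proportion_inbred": (len(inbred) / n) if n else 0.0,
            "percent_inbred": round(100.0 * len(inbred) / n, 2) if n else 0.0,
            "mean_F_among_inbred": inbred.mean() if len(inbred) else np.nan,
        })

    if df.empty:
        per_cohort = pd.DataFrame(columns=[
            "n_individuals", "n_undefined", "n_inbred", "proportion_inbred",
            "percent_inbred", "mean_F_among_inbred"])
        overall = summarize(df)
    else:
        per_cohort = (df.groupby("cohort", sort=True)
                        .apply(summarize, include_groups=False))
        overall = summarize(df)
    for col in ("n_individuals", "n_undefined", "n_inbred"):
        if col in per_cohort:
            per_cohort[col] = per_cohort[col].astype(int)
    return PrevalenceSummary(per_cohort=per_cohort, overall=overall)
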