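"""Minimal pedigrees realizing the canonical close-kin matings.

Each builder returns a :class:`MatingExample`: the raw records of a
smallest pedigree in which a sire and dam related in the stated way
produce one offspring, all other ancestors being unrelated founders.
Useful as fixtures and for reproducing textbook inbreeding coefficients
with the kinship recursion (e.g. parent-offspring F = 0.25, half-sib
F = 0.125, half-avuncular F = 0.0625, half-first-cousin F = 0.03125).

The ``line`` arguments control whether the breeders reach their common
ancestor through their sires ("paternal"), their dams ("maternal") or one
of each.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import count

from .pedigree import FEMALE, MALE, Pedigree, build_pedigree

_counter = count(1)


@dataclass
class MatingExample:
    """Records of a minimal close-kin mating; ``offspring`` is the inbred
    individual's id."""

    records: list
    offspring: str

    @property
    def pedigree(self) -> Pedigree:
        return build_pedigree(self.records)


def _new_prefix() -> str:
    return f"m{next(_counter)}_"


def _founder(records, pid, sex):
    records.append(dict(id=pid, sire=None, dam=None, sex=sex))
    return pid


def _child(records, pid, sire, dam, sex):
    records.append(dict(id=pid, sire=sire, dam=dam, sex=sex))
    return pid


def _chain(records, p, breeder_id, breeder_sex, steps, ancestor):
    """Build a lineage from ``ancestor`` down to a new breeder through the
    given parent-role ``steps`` (ordered breeder -> ancestor)."""
    node = ancestor
    for i in range(len(steps) - 1, 0, -1):
        up_role = steps[i]  # role of `node` relative to the new child
        child_sex = MALE if steps[i - 1] == "sire" else FEMALE
        spouse = _founder(records, f"{p}sp{breeder_id}{i}",
                          FEMALE if up_role == "sire" else MALE)
        child = f"{p}x{breeder_id}{i}"
        if up_role == "sire":
            _child(records, child, node, spouse, child_sex)
        else:
            _child(records, child, spouse, node, child_sex)
        node = child
    up_role = steps[0]
    spouse = _founder(records, f"{p}sp{breeder_id}0",
                      FEMALE if up_role == "sire" else MALE)
    if up_role == "sire":
        _child(records, breeder_id, node, spouse, breeder_sex)
    else:
        _child(records, breeder_id, spouse, node, breeder_sex)
    return breeder_id


def related_pair(sire_steps, dam_steps, prefix: str | None = None
                 ) -> MatingExample:
    """Offspring of a sire and dam connected through one common ancestor.

    ``sire_steps``/``dam_steps`` list the parent roles ("sire"/"dam")
    climbed from each breeder to the shared ancestor; an empty tuple means
    that breeder *is* the ancestor.  The two chains must approach the
    ancestor through the same role (its sex must be consistent).
    """
    sire_steps, dam_steps = tuple(sire_steps), tuple(dam_steps)
    p = prefix if prefix is not None else _new_prefix()
    records: list = []

    tops = {steps[-1] for steps in (sire_steps, dam_steps) if steps}
    if len(tops) > 1:
        raise ValueError("chains reach the ancestor through conflicting roles")

    if not sire_steps:
        anc, anc_sex = f"{p}S", MALE
        _founder(records, anc, anc_sex)
        sire = anc
        dam = _chain(records, p, f"{p}D", FEMALE, dam_steps, anc)
    elif not dam_steps:
        anc, anc_sex = f"{p}D", FEMALE
        _founder(records, anc, anc_sex)
        dam = anc
        sire = _chain(records, p, f"{p}S", MALE, sire_steps, anc)
    else:
        anc_sex = MALE if tops == {"sire"} else FEMALE
        anc = _founder(records, f"{p}A", anc_sex)
        sire = _chain(records, p, f"{p}S", MALE, sire_steps, anc)
        dam = _chain(records, p, f"{p}D", FEMALE, dam_steps, anc)
    off = _child(records, f"{p}O", sire, dam, FEMALE)
    return MatingExample(records=records, offspring=off)


def parent_offspring(line: str = "paternal") -> MatingExample:
    """Daughter x sire (``paternal``: the sire is the dam's father) or
    mother x son (``maternal``).  F = 0.25."""
    if line == "paternal":
        return related_pair((), ("sire",))
    return related_pair(("dam",), ())


def half_sibs(line: str = "paternal") -> MatingExample:
    """Half-siblings sharing a sire (``paternal``) or a dam
    (``maternal``).  F = 0.125."""
    step = "sire" if line == "paternal" else "dam"
    return related_pair((step,), (step,))


def full_sibs(prefix: str | None = None) -> MatingExample:
    """Full siblings: both parents shared.  F = 0.25."""
    p = prefix if prefix is not None else _new_prefix()
    records: list = []
    f = _founder(records, f"{p}GS", MALE)
    m = _founder(records, f"{p}GD", FEMALE)
    s = _child(records, f"{p}S", f, m, MALE)
    d = _child(records, f"{p}D", f, m, FEMALE)
    off = _child(records, f"{p}O", s, d, FEMALE)
    return MatingExample(records=records, offspring=off)


def half_avuncular(closer: str = "sire", sire_step: str = "sire",
                   dam_step: str = "sire") -> MatingExample:
    """Uncle x niece (``closer='sire'``) or aunt x nephew
    (``closer='dam'``), the linking siblings being half-sibs.  F = 0.0625.

    ``sire_step``/``dam_step`` give each breeder's first parent role toward
    the common ancestor, fixing the kin line.
    """
    if closer == "sire":
        return related_pair((sire_step,), (dam_step, sire_step))
    return related_pair((sire_step, dam_step), (dam_step,))


def half_cousins(sire_step: str = "sire", dam_step: str = "dam",
                 top_step: str = "sire") -> MatingExample:
    """First cousins through a single shared grandparent (the linking
    parents are half-sibs).  F = 0.03125."""
    return related_pair((sire_step, top_step), (dam_step, top_step))


def full_cousins(prefix: str | None = None) -> MatingExample:
    """First cousins whose linking parents are full siblings (the dam's
    dam and the sire's sire): two shared ancestors, F = 0.0625, connected
    through both the maternal and the paternal line."""
    p = prefix if prefix is not None else _new_prefix()
    records: list = []
    a = _founder(records, f"{p}A", MALE)
    b = _founder(records, f"{p}B", FEMALE)
    x = _child(records, f"{p}X", a, b, MALE)     # sire's sire
    y = _child(records, f"{p}Y", a, b, FEMALE)   # dam's dam
    xs = _founder(records, f"{p}XS", FEMALE)
    ys = _founder(records, f"{p}YS", MALE)
    s = _child(records, f"{p}S", x, xs, MALE)
    d = _child(records, f"{p}D", ys, y, FEMALE)
    off = _child(records, f"{p}O", s, d, FEMALE)
    return MatingExample(records=records, offspring=off)


def table_configurations(table: str) -> list[tuple[MatingExample, int, int]]:
    """The close-kin mating configurations detectable at a given pedigree
    depth, as (example, depth, count) triples.

    ``table='three-generation'``: matings whose common ancestor is at most
    a grandparent of the offspring (2 father-daughter, 18 paternal and 1
    maternal half-sib matings).  ``table='four-generation'``: matings
    visible only with great-grandparents included as well (4 paternal
    half-sib, 34 half-first-cousin and 7 half-avuncular matings).
    """
    if table == "three-generation":
        return [
            (parent_offspring("paternal"), 2, 2),
            (half_sibs("paternal"), 2, 18),
            (half_sibs("maternal"), 2, 1),
        ]
    if table == "four-generation":
        return [
            (half_sibs("paternal"), 3, 4),
            (half_cousins("dam", "dam"), 3, 1),                    # maternal
            (half_cousins("sire", "sire"), 3, 4),                  # paternal
            (half_cousins("sire", "dam"), 3, 29),                  # both lines
            (half_avuncular("sire", "sire", "dam"), 3, 1),         # uncle-niece, both
            (half_avuncular("dam", "sire", "dam"), 3, 3),          # aunt-nephew, both
            (half_avuncular("sire", "sire", "sire"), 3, 2),        # uncle-niece, paternal
            (half_avuncular("dam", "sire", "sire"), 3, 1),         # aunt-nephew, paternal
        ]
    raise ValueError(f"unknown table {table!r}")
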