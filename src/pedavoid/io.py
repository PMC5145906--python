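"""Readers and writers for the three tabular formats.

* Pedigree: TSV with header
  ``id  sire  dam  sex  birth_date  death_date  removed  birth_group``;
  missing values are ``NA`` (a parent of ``0`` also reads as missing);
  dates are ISO-8601; sex is M/F/U; removed is 0/1.
* Genotypes: CSV with header ``id,<locus>.1,<locus>.2,...``; a missing
  genotype is the pair ``NA,NA``.
* Demography: TSV ``id  group  start_date  end_date`` of half-open
  ``[start, end)`` group-membership intervals; a missing end is open-ended.

Writers emit the identical dialect, so write-read round trips are stable.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .avoidance import Demography
from .estimators import GenotypeTable
from .pedigree import Pedigree, PedigreeRecord

PEDIGREE_COLUMNS = ["id", "sire", "dam", "sex", "birth_date", "death_date",
                    "removed", "birth_group"]
DEMOGRAPHY_COLUMNS = ["id", "group", "start_date", "end_date"]

NA = "NA"


class FormatError(ValueError):
    pass


def _parse_date(value: str, line: int, column: str) -> dt.date | None:
    if value in (NA, ""):
        return None
    try:
        return dt.date.fromisoformat(value)
    except ValueError:
        raise FormatError(
            f"line {line}: bad {column} {value!r} (expected YYYY-MM-DD)"
        ) from None


def _fmt(value) -> str:
    if value is None:
        return NA
    if isinstance(value, dt.date):
        return value.isoformat()
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return NA if np.isnan(value) else f"{value:g}"
    return str(value)


def read_pedigree(source, strict_dates: bool = False) -> Pedigree:
    """Read a pedigree TSV into a validated :class:`Pedigree`.

    ``source`` is a path or an open text handle.  Errors cite 1-based line
    numbers.
    """
    close = False
    if isinstance(source, (str, Path)):
        handle = open(source)
        close = True
    else:
        handle = source
    try:
        header = handle.readline().rstrip("\n").split("\t")
        if header != PEDIGREE_COLUMNS:
            raise FormatError(
                f"line 1: bad pedigree header {header!r}; expected "
                f"{PEDIGREE_COLUMNS!r}")
        records = []
        seen: set = set()
        for lineno, raw in enumerate(handle, start=2):
            raw = raw.rstrip("\n")
            if not raw:
                continue
            parts = raw.split("\t")
            if len(parts) != len(PEDIGREE_COLUMNS):
                raise FormatError(
                    f"line {lineno}: expected {len(PEDIGREE_COLUMNS)} "
                    f"fields, got {len(parts)}")
            row = dict(zip(PEDIGREE_COLUMNS, parts))
            if row["id"] in seen:
                raise FormatError(f"line {lineno}: duplicate id {row['id']!r}")
            seen.add(row["id"])
            if row["sex"] not in ("M", "F", "U"):
                raise FormatError(
                    f"line {lineno}: bad sex {row['sex']!r} (expected M/F/U)")
            records.append(PedigreeRecord(
                id=row["id"],
                sire=None if row["sire"] in (NA, "0", "") else row["sire"],
                dam=None if row["dam"] in (NA, "0", "") else row["dam"],
                sex=row["sex"],
                birth_date=_parse_date(row["birth_date"], lineno, "birth_date"),
                death_date=_parse_date(row["death_date"], lineno, "death_date"),
                removed=row["removed"] not in ("0", NA, ""),
                birth_group=None if row["birth_group"] in (NA, "")
                else row["birth_group"],
            ))
    finally:
        if close:
            handle.close()
    return Pedigree.from_records(records, strict_dates=strict_dates)


def write_pedigree(pedigree: Pedigree, target) -> None:
    """Write a pedigree TSV (stubs excluded; they are re-created on read)."""
    close = False
    if isinstance(target, (str, Path)):
        handle = open(target, "w")
        close = True
    else:
        handle = target
    try:
        handle.write("\t".join(PEDIGREE_COLUMNS) + "\n")
        for iid in sorted(pedigree.records, key=str):
            rec = pedigree[iid]
            if rec.is_stub:
                continue
            handle.write("\t".join(_fmt(v) for v in (
                rec.id, rec.sire, rec.dam, rec.sex, rec.birth_date,
                rec.death_date, rec.removed, rec.birth_group)) + "\n")
    finally:
        if close:
            handle.close()


def read_genotypes(source) -> GenotypeTable:
    """Read a genotype CSV (``id,<locus>.1,<locus>.2,...``; NA = missing).

    Allele columns are parsed numerically where possible, otherwise kept as
    strings; only equality between allele labels is ever used.
    """
    df = pd.read_csv(source, dtype=str, na_values=[NA], keep_default_na=True)
    if df.columns[0] != "id":
        raise FormatError(
            f"first genotype column must be 'id', got {df.columns[0]!r}")
    df = df.set_index("id")
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            pass
    return GenotypeTable.from_wide(df)


def write_genotypes(table: GenotypeTable, target) -> None:
    wide = table.to_wide()

    def fmt(v):
        if pd.isna(v):
            return NA
        if isinstance(v, float) and v == int(v):
            return str(int(v))
        return str(v)

    out = wide.map(fmt)
    out.to_csv(target)


def read_demography(source) -> Demography:
    """Read the group-membership interval TSV."""
    df = pd.read_csv(source, sep="\t", dtype=str, na_values=[NA],
                     keep_default_na=True)
    missing = set(DEMOGRAPHY_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"demography header missing {sorted(missing)}")
    for col in ("start_date", "end_date"):
        df[col] = pd.to_datetime(df[col], format="%Y-%m-%d",
                                 errors="raise").dt.date
    return Demography(df)


def write_demography(demography: Demography, target) -> None:
    df = demography.to_frame().sort_values(["id", "start_date"],
                                           key=lambda s: s.astype(str))
    df = df.copy()
    for col in ("start_date", "end_date"):
        df[col] = df[col].map(_fmt)
    df.to_csv(target, sep="\t", index=False)


def write_sim_output(sim, out_dir) -> dict:
    """Write a simulated population as the three standard tables plus the
    true inbreeding coefficients and a JSON provenance file; returns the
    paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"pedigree": out / "pedigree.tsv",
             "demography": out / "demography.tsv",
             "true_F": out / "true_F.tsv",
             "provenance": out / "provenance.json"}
    write_pedigree(sim.pedigree, paths["pedigree"])
    write_demography(sim.demography, paths["demography"])
    sim.true_F.rename("F").to_csv(paths["true_F"], sep="\t",
                                  index_label="id", float_format="%.10g")
    if sim.genotypes is not None:
        paths["genotypes"] = out / "genotypes.csv"
        write_genotypes(sim.genotypes, paths["genotypes"])

    def plain(cfg):
        d = asdict(cfg) if is_dataclass(cfg) else dict(cfg)
        return {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in d.items()}

    provenance = {
        "seed": sim.seed,
        "founder_config": plain(sim.founder_config),
        "demography_config": plain(sim.demography_config),
        "mate_choice": plain(sim.mate_choice),
        "n_individuals": len(sim.pedigree),
        "warnings": sim.warnings,
    }
    paths["provenance"].write_text(json.dumps(provenance, indent=2,
                                              default=str) + "\n")
    return {k: str(v) for k, v in paths.items()}
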