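"""Embedded single-file relational store for normalized variant data.

Tables
------
``fields``      the queryable-field catalogue (name, category, type, column)
``samples``     VCF samples merged with optional pedigree attributes
``variants``    one row per decomposed (chrom, pos, ref, alt), with INFO
                values and materialized genotype-count aggregates as columns
``annotations`` one row per transcript annotation, columns per ANN/CSQ field
``genotypes``   one row per (variant, sample) with the encoded gt code
``selections``  named variant subsets ("sources") + membership table
``wordsets``    named string sets for membership filters

Aggregate counts (``count_hom`` … ``control_count_ref``) are computed once
at import so queries filter on them as ordinary fields.
"""

from __future__ import annotations

import re
import sqlite3
from bisect import bisect_right
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "CountSet",
    "Selection",
    "Wordset",
    "VariantStore",
    "StoreError",
    "BedError",
    "compute_counts",
    "read_bed",
]

#: Aggregate columns materialized on every variant row.
COUNT_FIELDS = (
    "count_hom",
    "count_het",
    "count_ref",
    "count_var",
    "case_count_hom",
    "case_count_het",
    "case_count_ref",
    "control_count_hom",
    "control_count_het",
    "control_count_ref",
)

#: Always-present selection holding every imported variant.
ALL_VARIANTS = "variants"

_SQL_TYPE = {"int": "INTEGER", "float": "REAL", "string": "TEXT", "bool": "INTEGER"}


class StoreError(RuntimeError):
    pass


class BedError(ValueError):
    pass


@dataclass(frozen=True)
class CountSet:
    """Per-variant genotype tallies, globally and split by PED phenotype."""

    count_hom: int = 0
    count_het: int = 0
    count_ref: int = 0
    count_var: int = 0
    case_count_hom: int = 0
    case_count_het: int = 0
    case_count_ref: int = 0
    control_count_hom: int = 0
    control_count_het: int = 0
    control_count_ref: int = 0

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in COUNT_FIELDS}


@dataclass(frozen=True)
class Selection:
    name: str
    keys: frozenset
    provenance: str = ""


@dataclass(frozen=True)
class Wordset:
    name: str
    words: frozenset


def compute_counts(gt_by_sample: dict, phenotype_by_sample: dict) -> CountSet:
    """Tally genotype codes; unknown (-1) genotypes count nowhere and samples
    with unknown phenotype contribute only to the global counts."""
    hom = het = ref = 0
    c_hom = c_het = c_ref = 0
    k_hom = k_het = k_ref = 0
    for sample, gt in gt_by_sample.items():
        if gt == 2:
            hom += 1
        elif gt == 1:
            het += 1
        elif gt == 0:
            ref += 1
        else:
            continue
        pheno = phenotype_by_sample.get(sample, 0)
        if pheno == 2:
            c_hom += gt == 2
            c_het += gt == 1
            c_ref += gt == 0
        elif pheno == 1:
            k_hom += gt == 2
            k_het += gt == 1
            k_ref += gt == 0
    return CountSet(
        hom, het, ref, hom + het,
        c_hom, c_het, c_ref,
        k_hom, k_het, k_ref,
    )


def _regexp(pattern, value) -> int:
    if value is None or pattern is None:
        return 0
    return 1 if re.search(pattern, str(value)) else 0


def _quote_ident(name: str) -> str:
    return '"' + name.replace('"', '""') + '"'


class VariantStore:
    """SQLite-backed variant store; a single file openable repeatedly."""

    def __init__(self, path=":memory:", chr_prefix_policy: str = "strip"):
        if chr_prefix_policy not in ("strip", "exact"):
            raise ValueError("chr_prefix_policy must be 'strip' or 'exact'")
        self.path = str(path)
        self.chr_prefix_policy = chr_prefix_policy
        self.conn = sqlite3.connect(self.path)
        self.conn.row_factory = sqlite3.Row
        self.conn.create_function("vql_regexp", 2, _regexp, deterministic=True)
        self.conn.execute("PRAGMA foreign_keys = ON")
        self._catalogue_cache = None

    # -- lifecycle ---------------------------------------------------------

    def close(self) -> None:
        self.conn.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    @property
    def is_initialized(self) -> bool:
        row = self.conn.execute(
            "SELECT name FROM sqlite_master WHERE type='table' AND name='variants'"
        ).fetchone()
        return row is not None

    # -- import ------------------------------------------------------------

    def begin_import(self, schema, pedigree: Sequence = ()) -> None:
        """Create all tables for the given VCF schema inside one transaction
        (committed by :meth:`finish_import`, discarded by :meth:`abort_import`)."""
        if self.is_initialized:
            raise StoreError("store already contains an import")
        self._catalogue_cache = None
        cur = self.conn.cursor()
        cur.execute("BEGIN")
        cur.execute(
            "CREATE TABLE fields ("
            " name TEXT NOT NULL, category TEXT NOT NULL,"
            " value_type TEXT NOT NULL, multiplicity TEXT NOT NULL,"
            " description TEXT NOT NULL DEFAULT '', column_name TEXT NOT NULL,"
            " PRIMARY KEY (category, name))"
        )
        cur.execute(
            "CREATE TABLE samples ("
            " id INTEGER PRIMARY KEY, name TEXT UNIQUE NOT NULL,"
            " family TEXT, father TEXT, mother TEXT,"
            " sex INTEGER NOT NULL DEFAULT 0,"
            " phenotype INTEGER NOT NULL DEFAULT 0)"
        )
        cur.execute(
            "CREATE TABLE selections ("
            " id INTEGER PRIMARY KEY, name TEXT UNIQUE NOT NULL,"
            " provenance TEXT NOT NULL DEFAULT '')"
        )
        cur.execute(
            "CREATE TABLE selection_variants ("
            " selection_id INTEGER NOT NULL REFERENCES selections(id)"
            "   ON DELETE CASCADE,"
            " variant_id INTEGER NOT NULL,"
            " PRIMARY KEY (selection_id, variant_id))"
        )
        cur.execute(
            "CREATE TABLE wordsets (name TEXT NOT NULL, word TEXT NOT NULL,"
            " PRIMARY KEY (name, word))"
        )

        info = [d for d in schema.descriptors if d.category == "info"]
        ann = [d for d in schema.descriptors if d.category == "annotation"]
        fmt = [d for d in schema.descriptors
               if d.category == "sample" and d.name != "gt"]

        variant_cols = [
            "id INTEGER PRIMARY KEY",
            "chrom TEXT NOT NULL",
            "pos INTEGER NOT NULL",
            "ref TEXT NOT NULL",
            "alt TEXT NOT NULL",
            "qual REAL",
            "filter TEXT",
        ]
        variant_cols += [f"{name} INTEGER NOT NULL DEFAULT 0" for name in COUNT_FIELDS]
        for d in info:
            variant_cols.append(f"{_quote_ident('info_' + d.name)} {_SQL_TYPE[d.value_type]}")
        variant_cols.append("UNIQUE (chrom, pos, ref, alt)")
        cur.execute(f"CREATE TABLE variants ({', '.join(variant_cols)})")

        ann_cols = [
            "id INTEGER PRIMARY KEY",
            "variant_id INTEGER NOT NULL REFERENCES variants(id)",
            "allele TEXT",
        ]
        for d in ann:
            ann_cols.append(f"{_quote_ident('ann_' + d.name)} TEXT")
        cur.execute(f"CREATE TABLE annotations ({', '.join(ann_cols)})")
        cur.execute("CREATE INDEX idx_ann_variant ON annotations(variant_id)")

        gt_cols = [
            "variant_id INTEGER NOT NULL REFERENCES variants(id)",
            "sample_id INTEGER NOT NULL REFERENCES samples(id)",
            "gt INTEGER NOT NULL DEFAULT -1",
        ]
        for d in fmt:
            gt_cols.append(f"{_quote_ident('fmt_' + d.name)} {_SQL_TYPE[d.value_type]}")
        gt_cols.append("PRIMARY KEY (variant_id, sample_id)")
        cur.execute(f"CREATE TABLE genotypes ({', '.join(gt_cols)})")

        # field catalogue, including alias names the query language exposes
        rows = []
        for d in schema.descriptors:
            if d.category == "core":
                column = d.name
            elif d.category == "info":
                column = "info_" + d.name
            elif d.category == "annotation":
                column = "ann_" + d.name
            else:
                column = "gt" if d.name == "gt" else "fmt_" + d.name
            rows.append(
                (d.name, d.category, d.value_type, d.multiplicity,
                 d.description, column)
            )
        for name in COUNT_FIELDS:
            rows.append((name, "core", "int", "1", "materialized genotype count", name))
        rows.append(("chr", "core", "string", "1", "alias of chrom", "chrom"))
        if any(d.category == "info" and d.name == "dp" for d in schema.descriptors):
            rows.append(("depth", "core", "int", "1", "alias of INFO DP", "info_dp"))
        cur.executemany("INSERT INTO fields VALUES (?,?,?,?,?,?)", rows)

        ped_by_name = {p.individual: p for p in pedigree}
        for i, name in enumerate(schema.samples, start=1):
            p = ped_by_name.get(name)
            cur.execute(
                "INSERT INTO samples VALUES (?,?,?,?,?,?,?)",
                (i, name,
                 p.family if p else None,
                 p.father if p else None,
                 p.mother if p else None,
                 p.sex if p else 0,
                 p.phenotype if p else 0),
            )

        self._sample_ids = {name: i for i, name in enumerate(schema.samples, start=1)}
        self._phenotypes = {
            name: (ped_by_name[name].phenotype if name in ped_by_name else 0)
            for name in schema.samples
        }
        self._info_cols = ["info_" + d.name for d in info]
        self._info_names = [d.name for d in info]
        self._ann_cols = ["ann_" + d.name for d in ann]
        self._ann_names = [d.name for d in ann]
        self._fmt_cols = ["fmt_" + d.name for d in fmt]
        self._fmt_names = [d.name for d in fmt]

    def add_variant(self, variant, genotypes: Sequence, annotations: Sequence) -> int:
        """Insert one decomposed variant with its genotypes and annotations;
        aggregates are computed here from the genotype codes."""
        gt_by_sample = {g.sample: g.gt for g in genotypes}
        counts = compute_counts(gt_by_sample, self._phenotypes)
        cols = ["chrom", "pos", "ref", "alt", "qual", "filter", *COUNT_FIELDS,
                *self._info_cols]
        values = [
            variant.chrom, variant.pos, variant.ref, variant.alt,
            variant.qual, variant.filter,
            *(getattr(counts, name) for name in COUNT_FIELDS),
            *(_sql_value(variant.info.get(name)) for name in self._info_names),
        ]
        placeholders = ",".join("?" * len(values))
        collist = ",".join(_quote_ident(c) for c in cols)
        cur = self.conn.execute(
            f"INSERT INTO variants ({collist}) VALUES ({placeholders})", values
        )
        vid = cur.lastrowid
        for g in genotypes:
            gvals = [vid, self._sample_ids[g.sample], g.gt,
                     *(_sql_value(g.fields.get(n)) for n in self._fmt_names)]
            self.conn.execute(
                "INSERT INTO genotypes VALUES ("
                + ",".join("?" * len(gvals)) + ")",
                gvals,
            )
        for a in annotations:
            avals = [vid, a.allele,
                     *(a.fields.get(n) for n in self._ann_names)]
            acols = ",".join(
                ["variant_id", "allele"]
                + [_quote_ident(c) for c in self._ann_cols]
            )
            self.conn.execute(
                f"INSERT INTO annotations ({acols}) VALUES ("
                + ",".join("?" * len(avals)) + ")",
                avals,
            )
        return vid

    def finish_import(self) -> None:
        self.conn.commit()

    def abort_import(self) -> None:
        self.conn.rollback()
        # roll back cannot undo DDL executed outside the transaction on some
        # sqlite versions; drop leftovers so no partial store remains
        for table in ("genotypes", "annotations", "selection_variants",
                      "selections", "wordsets", "variants", "samples", "fields"):
            self.conn.execute(f"DROP TABLE IF EXISTS {table}")
        self.conn.commit()

    # -- catalogue ---------------------------------------------------------

    def field_catalogue(self) -> list:
        """All queryable fields as dict rows (name, category, value_type,
        multiplicity, description, column)."""
        if self._catalogue_cache is None:
            rows = self.conn.execute(
                "SELECT name, category, value_type, multiplicity, description,"
                " column_name FROM fields ORDER BY rowid"
            ).fetchall()
            self._catalogue_cache = [
                {
                    "name": r["name"],
                    "category": r["category"],
                    "value_type": r["value_type"],
                    "multiplicity": r["multiplicity"],
                    "description": r["description"],
                    "column": r["column_name"],
                }
                for r in rows
            ]
        return self._catalogue_cache

    def sample_names(self) -> list:
        return [r["name"] for r in
                self.conn.execute("SELECT name FROM samples ORDER BY id")]

    def sample_ids(self) -> dict:
        return {r["name"]: r["id"] for r in
                self.conn.execute("SELECT id, name FROM samples")}

    def phenotypes(self) -> dict:
        return {r["name"]: r["phenotype"] for r in
                self.conn.execute("SELECT name, phenotype FROM samples")}

    def pedigree_rows(self) -> list:
        return [dict(r) for r in self.conn.execute(
            "SELECT name, family, father, mother, sex, phenotype"
            " FROM samples ORDER BY id")]

    # -- variant access ----------------------------------------------------

    def n_variants(self) -> int:
        return self.conn.execute("SELECT COUNT(*) FROM variants").fetchone()[0]

    def variant_id(self, key) -> int | None:
        row = self.conn.execute(
            "SELECT id FROM variants WHERE chrom=? AND pos=? AND ref=? AND alt=?",
            tuple(key),
        ).fetchone()
        return row["id"] if row else None

    def variant_key(self, vid: int):
        row = self.conn.execute(
            "SELECT chrom, pos, ref, alt FROM variants WHERE id=?", (vid,)
        ).fetchone()
        return (row["chrom"], row["pos"], row["ref"], row["alt"]) if row else None

    def all_variant_ids(self) -> list:
        return [r["id"] for r in
                self.conn.execute("SELECT id FROM variants ORDER BY id")]

    def variant_rows(self, selection: str = ALL_VARIANTS) -> list:
        """Variant rows of a selection as dicts keyed by column name
        (core names verbatim, INFO fields as ``info_<name>``), in stable
        store order, plus ``id`` and the identity ``key`` tuple."""
        sql = "SELECT * FROM variants"
        params: tuple = ()
        if selection != ALL_VARIANTS:
            sql += (" WHERE id IN (SELECT variant_id FROM selection_variants"
                    " WHERE selection_id = ?)")
            params = (self._selection_id(selection),)
        sql += " ORDER BY id"
        out = []
        for r in self.conn.execute(sql, params):
            d = dict(r)
            d["key"] = (r["chrom"], r["pos"], r["ref"], r["alt"])
            out.append(d)
        return out

    def annotations_for(self, vid: int) -> list:
        """Annotation rows for a variant as dicts keyed by annotation field
        name, in stable store order."""
        names = [f["name"] for f in self.field_catalogue()
                 if f["category"] == "annotation"]
        out = []
        for r in self.conn.execute(
            "SELECT * FROM annotations WHERE variant_id=? ORDER BY id", (vid,)
        ):
            d = {"allele": r["allele"]}
            for name in names:
                d[name] = r["ann_" + name]
            out.append(d)
        return out

    def genotype_map(self, vid: int) -> dict:
        """sample name -> {gt, <format fields>} for one variant."""
        fmt = [f["name"] for f in self.field_catalogue()
               if f["category"] == "sample" and f["name"] != "gt"]
        out = {}
        for r in self.conn.execute(
            "SELECT s.name AS sample, g.* FROM genotypes g"
            " JOIN samples s ON s.id = g.sample_id WHERE g.variant_id=?",
            (vid,),
        ):
            d = {"gt": r["gt"]}
            for name in fmt:
                d[name] = r["fmt_" + name]
            out[r["sample"]] = d
        return out

    # -- selections --------------------------------------------------------

    def selection_names(self) -> list:
        names = [ALL_VARIANTS]
        names += [r["name"] for r in self.conn.execute(
            "SELECT name FROM selections ORDER BY name")]
        return names

    def _selection_id(self, name: str) -> int:
        row = self.conn.execute(
            "SELECT id FROM selections WHERE name=?", (name,)
        ).fetchone()
        if row is None:
            raise StoreError(f"no selection named {name!r}")
        return row["id"]

    def selection_variant_ids(self, name: str) -> set:
        if name == ALL_VARIANTS:
            return set(self.all_variant_ids())
        sid = self._selection_id(name)
        return {r["variant_id"] for r in self.conn.execute(
            "SELECT variant_id FROM selection_variants WHERE selection_id=?",
            (sid,))}

    def selection_keys(self, name: str) -> frozenset:
        return frozenset(
            self.variant_key(v) for v in self.selection_variant_ids(name)
        )

    def get_selection(self, name: str) -> Selection:
        if name == ALL_VARIANTS:
            return Selection(name, self.selection_keys(name), "all imported variants")
        row = self.conn.execute(
            "SELECT provenance FROM selections WHERE name=?", (name,)
        ).fetchone()
        if row is None:
            raise StoreError(f"no selection named {name!r}")
        return Selection(name, self.selection_keys(name), row["provenance"])

    def create_selection(
        self, name: str, variant_ids: Iterable[int], provenance: str = "",
        overwrite: bool = False,
    ) -> Selection:
        if name == ALL_VARIANTS:
            raise StoreError(f"{ALL_VARIANTS!r} is a reserved selection name")
        known = set(self.all_variant_ids())
        ids = set(variant_ids)
        unknown = ids - known
        if unknown:
            raise StoreError(f"selection references unknown variant ids: {sorted(unknown)[:5]}")
        existing = self.conn.execute(
            "SELECT id FROM selections WHERE name=?", (name,)
        ).fetchone()
        if existing is not None:
            if not overwrite:
                raise StoreError(f"selection {name!r} already exists")
            self.conn.execute("DELETE FROM selections WHERE id=?", (existing["id"],))
        cur = self.conn.execute(
            "INSERT INTO selections (name, provenance) VALUES (?,?)",
            (name, provenance),
        )
        sid = cur.lastrowid
        self.conn.executemany(
            "INSERT INTO selection_variants VALUES (?,?)",
            [(sid, vid) for vid in sorted(ids)],
        )
        self.conn.commit()
        return self.get_selection(name)

    def create_selection_from_keys(
        self, name: str, keys: Iterable, provenance: str = "",
        overwrite: bool = False,
    ) -> Selection:
        ids = []
        for key in keys:
            vid = self.variant_id(key)
            if vid is None:
                raise StoreError(f"unknown variant key {key!r}")
            ids.append(vid)
        return self.create_selection(name, ids, provenance, overwrite)

    def drop_selection(self, name: str) -> None:
        if name == ALL_VARIANTS:
            raise StoreError(f"cannot drop reserved selection {ALL_VARIANTS!r}")
        sid = self._selection_id(name)
        self.conn.execute("DELETE FROM selections WHERE id=?", (sid,))
        self.conn.commit()

    def selection_set_op(
        self, a: str, b: str, op: str, name: str, overwrite: bool = False,
    ) -> Selection:
        """Create a named selection from a set operation over two existing
        ones: 'intersection' (&), 'union' (|) or 'difference' (-)."""
        ids_a = self.selection_variant_ids(a)
        ids_b = self.selection_variant_ids(b)
        if op in ("intersection", "&"):
            ids, sym = ids_a & ids_b, "&"
        elif op in ("union", "|"):
            ids, sym = ids_a | ids_b, "|"
        elif op in ("difference", "-"):
            ids, sym = ids_a - ids_b, "-"
        else:
            raise ValueError(f"unknown set operation {op!r}")
        return self.create_selection(
            name, ids, provenance=f"{a} {sym} {b}", overwrite=overwrite
        )

    # -- wordsets ----------------------------------------------------------

    def wordset_names(self) -> list:
        return [r["name"] for r in self.conn.execute(
            "SELECT DISTINCT name FROM wordsets ORDER BY name")]

    def create_wordset(
        self, name: str, lines: Iterable[str], overwrite: bool = False,
    ) -> Wordset:
        """Build a wordset from one-term-per-line text; blanks stripped,
        duplicates collapsed, case preserved.  Empty result is an error."""
        words = {line.strip() for line in lines}
        words.discard("")
        if not words:
            raise StoreError(f"wordset {name!r} would be empty")
        exists = self.conn.execute(
            "SELECT 1 FROM wordsets WHERE name=? LIMIT 1", (name,)
        ).fetchone()
        if exists:
            if not overwrite:
                raise StoreError(f"wordset {name!r} already exists")
            self.conn.execute("DELETE FROM wordsets WHERE name=?", (name,))
        self.conn.executemany(
            "INSERT INTO wordsets VALUES (?,?)",
            [(name, w) for w in sorted(words)],
        )
        self.conn.commit()
        return Wordset(name, frozenset(words))

    def wordset(self, name: str) -> frozenset:
        rows = self.conn.execute(
            "SELECT word FROM wordsets WHERE name=?", (name,)
        ).fetchall()
        if not rows:
            raise StoreError(f"no wordset named {name!r}")
        return frozenset(r["word"] for r in rows)

    def drop_wordset(self, name: str) -> None:
        self.wordset(name)  # existence check
        self.conn.execute("DELETE FROM wordsets WHERE name=?", (name,))
        self.conn.commit()

    # -- BED intersection --------------------------------------------------

    def _norm_chrom(self, chrom: str) -> str:
        if self.chr_prefix_policy == "strip" and chrom.lower().startswith("chr"):
            return chrom[3:]
        return chrom

    def _merged_intervals(self, bed_intervals: Sequence) -> dict:
        by_chrom: dict[str, list] = {}
        for chrom, start, end in bed_intervals:
            by_chrom.setdefault(self._norm_chrom(chrom), []).append((start, end))
        merged: dict[str, tuple] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            starts: list[int] = []
            ends: list[int] = []
            for s, e in ivs:
                if ends and s <= ends[-1]:
                    ends[-1] = max(ends[-1], e)
                else:
                    starts.append(s)
                    ends.append(e)
            merged[chrom] = (starts, ends)
        return merged

    def filter_ids_by_bed(
        self, variant_ids: Iterable[int], bed_intervals: Sequence
    ) -> list:
        """Keep variant ids whose 0-based start position falls inside some
        interval on the same (prefix-harmonized) chromosome."""
        merged = self._merged_intervals(bed_intervals)
        wanted = set(variant_ids)
        kept = []
        for r in self.conn.execute(
            "SELECT id, chrom, pos FROM variants ORDER BY id"
        ):
            if r["id"] not in wanted:
                continue
            entry = merged.get(self._norm_chrom(r["chrom"]))
            if entry is None:
                continue
            starts, ends = entry
            p = r["pos"] - 1
            i = bisect_right(starts, p) - 1
            if i >= 0 and p < ends[i]:
                kept.append(r["id"])
        return kept

    def intersect_bed(
        self, source: str, bed_intervals: Sequence, name: str,
        overwrite: bool = False,
    ) -> Selection:
        """Selection of source variants whose (pos - 1) falls inside a BED
        interval on the same chromosome.  Intervals are 0-based half-open;
        only the variant start position is considered, not its REF span."""
        ids = self.filter_ids_by_bed(
            self.selection_variant_ids(source), bed_intervals
        )
        return self.create_selection(
            name, ids, provenance=f"{source} INTERSECT bed", overwrite=overwrite
        )


def _sql_value(value):
    if value is True:
        return 1
    if value is False:
        return 0
    return value


def read_bed(lines: Iterable[str]) -> list:
    """Parse BED 3+ text into (chrom, start, end) tuples; malformed lines
    raise :class:`BedError` naming the line number."""
    intervals = []
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n\r")
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        cols = re.split(r"\s+", line.strip())
        if len(cols) < 3:
            raise BedError(f"BED line {lineno}: expected >= 3 columns")
        try:
            start, end = int(cols[1]), int(cols[2])
        except ValueError:
            raise BedError(f"BED line {lineno}: non-integer interval bounds")
        if start < 0 or end < start:
            raise BedError(f"BED line {lineno}: invalid interval [{start}, {end})")
        intervals.append((cols[0], start, end))
    return intervals
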