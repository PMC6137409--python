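"""SQLite schema and whole-database read/write with referential validation.

The on-disk layout is one table per record kind, joined through integer
"link" fields (``locus_link``, ``pedigree_link``, ``person_link``)
rather than pointers, so related tables merge cheaply in pandas.  Phenotype
values are stored as one raw blob per person, 8 bytes per trait;
biallelic genotypes as one packed 2-bit blob per person per chromosome
(see :mod:`genodb.codec`).  A ``metadata`` table records the schema
version and compression mode.

Loop-breaking is out of scope here: the ``*_brkloop`` tables are carried
as verbatim copies of the pedigree/person tables so that downstream
consumers expecting the full table set still find them.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvariantError, ReferentialError, SchemaError

SCHEMA_VERSION = "1.0"
COMPRESSION = "2 bits"

# locus type codes (LINKAGE-flavoured, matching stored Type integers)
LOCUS_QUANTITATIVE = 1
LOCUS_AFFECTION = 2
LOCUS_POLY_MARKER = 3
LOCUS_BIALLELIC_MARKER = 4

PHENOTYPE_TYPES = (LOCUS_AFFECTION, LOCUS_QUANTITATIVE)
MARKER_TYPES = (LOCUS_BIALLELIC_MARKER, LOCUS_POLY_MARKER)

#: table name -> (column name -> SQLite type). Order is the storage order.
TABLE_COLUMNS: dict[str, dict[str, str]] = {
    "locus_table": {
        "pId": "INTEGER",
        "LocusName": "TEXT",
        "Type": "INTEGER",
        "AlleleCnt": "INTEGER",
        "locus_link": "INTEGER",
    },
    "allele_table": {
        "pId": "INTEGER",
        "locus_link": "INTEGER",
        "indexX": "INTEGER",
        "AlleleName": "TEXT",
        "Frequency": "REAL",
    },
    "marker_table": {
        "pId": "INTEGER",
        "locus_link": "INTEGER",
        "locus_link_fill": "INTEGER",
        "MarkerName": "TEXT",
        "chromosome": "INTEGER",
        "position": "INTEGER",
        "raw_offset": "INTEGER",
        "unified_offset": "INTEGER",
    },
    "map_table": {
        "pId": "INTEGER",
        "locus_link": "INTEGER",
        "MarkerName": "TEXT",
        "chromosome": "INTEGER",
        "map_index": "INTEGER",
        "position": "REAL",
    },
    "mapnames_table": {
        "pId": "INTEGER",
        "map_name": "TEXT",
        "map_number": "INTEGER",
        "map_type": "TEXT",
        "units": "TEXT",
        "comment": "TEXT",
    },
    "pedigree_table": {
        "pId": "INTEGER",
        "PedName": "TEXT",
        "NumPersons": "INTEGER",
        "NumFounders": "INTEGER",
        "NumMales": "INTEGER",
        "NumFemales": "INTEGER",
        "NumUnknown": "INTEGER",
        "pedigree_link": "INTEGER",
    },
    "person_table": {
        "pId": "INTEGER",
        "PerName": "TEXT",
        "Father": "TEXT",
        "Mother": "TEXT",
        "Sex": "INTEGER",
        "proband": "INTEGER",
        "father_link": "INTEGER",
        "mother_link": "INTEGER",
        "next_sib": "INTEGER",
        "pedigree_link": "INTEGER",
        "person_link": "INTEGER",
    },
    "phenotype_table": {
        "pId": "INTEGER",
        "pedigree_link": "INTEGER",
        "person_link": "INTEGER",
        "pheno_vec": "BLOB",
    },
    "genotype_table": {
        "pId": "INTEGER",
        "pedigree_link": "INTEGER",
        "person_link": "INTEGER",
        "chromosome": "INTEGER",
        "genotype_vec": "BLOB",
    },
}

#: loop-broken copies; identical columns to their sources
_BRKLOOP = {
    "pedigree_brkloop_table": "pedigree_table",
    "person_brkloop_table": "person_table",
}

ALL_TABLES = (
    list(TABLE_COLUMNS)[:7]
    + list(_BRKLOOP)
    + ["phenotype_table", "genotype_table", "metadata"]
)

_ATTR_FOR_TABLE = {
    "locus_table": "locus",
    "allele_table": "allele",
    "marker_table": "marker",
    "map_table": "map",
    "mapnames_table": "mapnames",
    "pedigree_table": "pedigree",
    "person_table": "person",
    "pedigree_brkloop_table": "pedigree_brkloop",
    "person_brkloop_table": "person_brkloop",
    "phenotype_table": "phenotype",
    "genotype_table": "genotype",
}


def _empty(table: str) -> pd.DataFrame:
    cols = TABLE_COLUMNS.get(table) or TABLE_COLUMNS[_BRKLOOP[table]]
    return pd.DataFrame({c: pd.Series(dtype=_dtype(t)) for c, t in cols.items()})


def _dtype(sql_type: str):
    return {"INTEGER": "int64", "REAL": "float64"}.get(sql_type, "object")


@dataclass
class TableSet:
    """In-memory record collection mirroring the database tables."""

    locus: pd.DataFrame = field(default_factory=lambda: _empty("locus_table"))
    allele: pd.DataFrame = field(default_factory=lambda: _empty("allele_table"))
    marker: pd.DataFrame = field(default_factory=lambda: _empty("marker_table"))
    map: pd.DataFrame = field(default_factory=lambda: _empty("map_table"))
    mapnames: pd.DataFrame = field(default_factory=lambda: _empty("mapnames_table"))
    pedigree: pd.DataFrame = field(default_factory=lambda: _empty("pedigree_table"))
    person: pd.DataFrame = field(default_factory=lambda: _empty("person_table"))
    pedigree_brkloop: pd.DataFrame | None = None
    person_brkloop: pd.DataFrame | None = None
    phenotype: pd.DataFrame = field(default_factory=lambda: _empty("phenotype_table"))
    genotype: pd.DataFrame = field(default_factory=lambda: _empty("genotype_table"))
    metadata: dict[str, str] = field(default_factory=dict)

    def frame(self, table: str) -> pd.DataFrame:
        df = getattr(self, _ATTR_FOR_TABLE[table])
        if df is None:  # brkloop defaults to a copy of its source
            df = getattr(self, _ATTR_FOR_TABLE[_BRKLOOP[table]])
        return df

    def copy(self) -> "TableSet":
        return replace(
            self,
            **{
                a: (getattr(self, a).copy() if getattr(self, a) is not None else None)
                for a in _ATTR_FOR_TABLE.values()
            },
            metadata=dict(self.metadata),
        )

    def markers_per_chromosome(self) -> list[tuple[int, int]]:
        """(chromosome, marker count) in raw_offset storage order."""
        if not len(self.marker):
            return []
        m = self.marker.sort_values("raw_offset")
        counts = m.groupby("chromosome", sort=False).size()
        return [(int(c), int(n)) for c, n in counts.items()]


def create_database(
    path: str | Path, schema_version: str = SCHEMA_VERSION, overwrite: bool = False
) -> sqlite3.Connection:
    """Create an empty database with the full table set.

    Refuses to clobber an existing file unless ``overwrite`` is set.
    """
    path = Path(path)
    if path.exists():
        if not overwrite:
            raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
        path.unlink()
    conn = sqlite3.connect(path)
    for table in ALL_TABLES:
        if table == "metadata":
            conn.execute("CREATE TABLE metadata (key TEXT PRIMARY KEY, value TEXT)")
            continue
        cols = TABLE_COLUMNS.get(table) or TABLE_COLUMNS[_BRKLOOP[table]]
        decl = ", ".join(f'"{c}" {t}' for c, t in cols.items())
        conn.execute(f"CREATE TABLE {table} ({decl})")
    conn.executemany(
        "INSERT INTO metadata (key, value) VALUES (?, ?)",
        [("schema_version", schema_version), ("compression", COMPRESSION)],
    )
    conn.commit()
    return conn


def list_tables(conn: sqlite3.Connection) -> list[str]:
    rows = conn.execute(
        "SELECT name FROM sqlite_master WHERE type='table' ORDER BY name"
    ).fetchall()
    return [r[0] for r in rows]


def validate_links(tables: TableSet) -> list[tuple[str, str, object]]:
    """Report every dangling link as a (table, field, value) triple."""
    report: list[tuple[str, str, object]] = []
    locus_keys = set(tables.locus["locus_link"].tolist())
    ped_keys = set(tables.pedigree["pedigree_link"].tolist())
    person_keys = set(tables.person["person_link"].tolist())

    def check(df: pd.DataFrame, table: str, fld: str, keys: set) -> None:
        if fld not in df.columns:
            return
        for v in df[fld][~df[fld].isin(keys)].tolist():
            report.append((table, fld, v))

    check(tables.allele, "allele_table", "locus_link", locus_keys)
    check(tables.marker, "marker_table", "locus_link", locus_keys)
    check(tables.map, "map_table", "locus_link", locus_keys)
    check(tables.person, "person_table", "pedigree_link", ped_keys)
    check(tables.phenotype, "phenotype_table", "person_link", person_keys)
    check(tables.phenotype, "phenotype_table", "pedigree_link", ped_keys)
    check(tables.genotype, "genotype_table", "person_link", person_keys)
    check(tables.genotype, "genotype_table", "pedigree_link", ped_keys)
    map_numbers = set(tables.mapnames["map_number"].tolist())
    check(tables.map, "map_table", "map_index", map_numbers)
    return report


def write_tables(conn: sqlite3.Connection, tables: TableSet) -> dict[str, int]:
    """Persist a record collection; returns per-table row counts written."""
    dangling = validate_links(tables)
    if dangling:
        t, f, v = dangling[0]
        raise ReferentialError(t, f, v)
    counts: dict[str, int] = {}
    for table in ALL_TABLES:
        if table == "metadata":
            conn.executemany(
                "INSERT OR REPLACE INTO metadata (key, value) VALUES (?, ?)",
                list(tables.metadata.items()),
            )
            counts[table] = len(tables.metadata)
            continue
        df = tables.frame(table)
        cols = TABLE_COLUMNS.get(table) or TABLE_COLUMNS[_BRKLOOP[table]]
        conn.execute(f"DELETE FROM {table}")
        names = list(cols)
        ph = ", ".join("?" for _ in names)
        rows = [
            tuple(_to_sql(row[c]) for c in names)
            for row in df[names].to_dict("records")
        ]
        conn.executemany(
            f'INSERT INTO {table} ({", ".join(chr(34) + n + chr(34) for n in names)})'
            f" VALUES ({ph})",
            rows,
        )
        counts[table] = len(rows)
    conn.commit()
    return counts


def _to_sql(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v


def read_tables(conn: sqlite3.Connection | str | Path) -> TableSet:
    """Load a whole database back into a :class:`TableSet`.

    Verifies the schema (table set and version) and the blob-length
    invariants of the phenotype and genotype payloads.
    """
    own = False
    if not isinstance(conn, sqlite3.Connection):
        path = Path(conn)
        if not path.exists():
            raise SchemaError(f"no database at {path}")
        conn = sqlite3.connect(path)
        own = True
    try:
        present = set(list_tables(conn))
        missing = [t for t in ALL_TABLES if t not in present]
        if missing:
            raise SchemaError(f"missing tables: {', '.join(missing)}")
        meta = dict(conn.execute("SELECT key, value FROM metadata").fetchall())
        version = meta.get("schema_version")
        if version != SCHEMA_VERSION:
            raise SchemaError(
                f"database schema version {version!r} is not the supported "
                f"{SCHEMA_VERSION!r}"
            )
        out = TableSet(metadata=meta)
        for table, attr in _ATTR_FOR_TABLE.items():
            cols = TABLE_COLUMNS.get(table) or TABLE_COLUMNS[_BRKLOOP[table]]
            names = list(cols)
            rows = conn.execute(
                f'SELECT {", ".join(chr(34) + n + chr(34) for n in names)} FROM {table}'
            ).fetchall()
            df = pd.DataFrame(rows, columns=names)
            if not len(df):
                df = _empty(table if table in TABLE_COLUMNS else _BRKLOOP[table])
            else:
                for c, t in cols.items():
                    if t != "BLOB":
                        df[c] = df[c].astype(_dtype(t))
                    else:
                        df[c] = df[c].map(bytes)
            setattr(out, attr, df)
        _check_payload_lengths(out)
        return out
    finally:
        if own:
            conn.close()


def _check_payload_lengths(tables: TableSet) -> None:
    n_pheno = int((tables.locus["Type"].isin(PHENOTYPE_TYPES)).sum())
    for row in tables.phenotype.itertuples():
        if len(row.pheno_vec) != 8 * n_pheno:
            raise InvariantError(
                f"person {row.person_link}: phenotype payload "
                f"{len(row.pheno_vec)} bytes, expected {8 * n_pheno}"
            )
    per_chrom = dict(tables.markers_per_chromosome())
    for row in tables.genotype.itertuples():
        want = (per_chrom.get(int(row.chromosome), 0) + 3) // 4
        if len(row.genotype_vec) != want:
            raise InvariantError(
                f"person {row.person_link}, chromosome {row.chromosome}: "
                f"genotype payload {len(row.genotype_vec)} bytes, expected {want}"
            )
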