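"""In-memory session over a database: derived tables, fam pruning, summary.

A :class:`Session` loads every table once and derives what per-sample
work needs: the ``markers`` frame (name, chromosome, position, and the
two offsets the decoders use), the unified genotype table (all
per-chromosome packed vectors concatenated per person, gaps included),
an allele-label lookup per locus, and the ``fam`` sample sheet merged
from the pedigree, person and phenotype tables.

Pruning the fam (``setfam``) filters the phenotype rows and the unified
genotype rows to the same person set in the same order, so every
downstream decode stays aligned with the sample sheet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import codec, datastore
from .datastore import (
    LOCUS_AFFECTION,
    LOCUS_QUANTITATIVE,
    PHENOTYPE_TYPES,
    TableSet,
)
from .errors import GenodbError, InvariantError

_TYPE_NAMES = {
    LOCUS_AFFECTION: "affection",
    LOCUS_QUANTITATIVE: "quantitative",
    datastore.LOCUS_BIALLELIC_MARKER: "marker",
    datastore.LOCUS_POLY_MARKER: "marker",
}

FAM_COLUMNS = [
    "PedName", "PerName", "Father", "Mother", "Sex", "trait",
    "pedigree_link", "person_link",
]


@dataclass
class Session:
    """Loaded database plus derived tables; the context every operation takes."""

    tables: TableSet
    db_path: Path
    verbose: bool = False
    trait_name: str = ""
    markers: pd.DataFrame = field(default_factory=pd.DataFrame)
    fam: pd.DataFrame = field(default_factory=pd.DataFrame)
    unified: codec.UnifiedGenotypeTable | None = None
    allele_labels: dict[int, tuple[str, str]] = field(default_factory=dict)
    # per-marker arrays aligned to raw_offset order
    marker_label1: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))
    marker_label2: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))
    freq1: np.ndarray = field(default_factory=lambda: np.empty(0))
    ranges: pd.DataFrame | None = None
    annotations: pd.DataFrame | None = None

    # -- construction -----------------------------------------------------

    @classmethod
    def open(cls, db_path: str | Path, verbose: bool = False, trait: str | None = None) -> "Session":
        """Load a database; equivalent free function: :func:`open_session`."""
        tables = datastore.read_tables(db_path)
        if not len(tables.person):
            raise GenodbError("no samples: the person table is empty")
        if not len(tables.marker):
            raise GenodbError("no markers: the marker table is empty")
        ses = cls(tables=tables, db_path=Path(db_path), verbose=verbose)
        ses._derive_markers()
        ses._derive_alleles()
        ses._derive_unified()
        if trait is None:
            trait = tables.metadata.get("trait_name") or ses.phenotype_names()[0]
        ses.fam = mkfam(ses, trait)
        ses.trait_name = trait
        if verbose:
            print(ses.summary())
        return ses

    def _derive_markers(self) -> None:
        m = self.tables.marker.sort_values("raw_offset")
        self.markers = pd.DataFrame(
            {
                "MarkerName": m["MarkerName"].to_numpy(),
                "chromosome": m["chromosome"].to_numpy(),
                "position": m["position"].to_numpy(),
                "raw_offset": m["raw_offset"].to_numpy(),
                "unified_offset": m["unified_offset"].to_numpy(),
            }
        )
        self._marker_links = m["locus_link"].to_numpy(dtype=np.int64)

    def _derive_alleles(self) -> None:
        al = self.tables.allele
        self.allele_labels = {}
        freq1 = {}
        for link, grp in al.groupby("locus_link", sort=False):
            grp = grp.sort_values("indexX")
            labels = grp["AlleleName"].tolist()
            if len(labels) >= 2:
                self.allele_labels[int(link)] = (str(labels[0]), str(labels[1]))
            elif labels:
                self.allele_labels[int(link)] = (str(labels[0]), str(labels[0]))
            freq1[int(link)] = float(grp["Frequency"].iloc[0]) if len(grp) else np.nan
        n = len(self.markers)
        self.marker_label1 = np.empty(n, dtype=object)
        self.marker_label2 = np.empty(n, dtype=object)
        self.freq1 = np.empty(n)
        for i, link in enumerate(self._marker_links):
            self.marker_label1[i], self.marker_label2[i] = self.allele_labels[int(link)]
            self.freq1[i] = freq1[int(link)]

    def _derive_unified(self) -> None:
        chrom_counts = self.tables.markers_per_chromosome()
        ledger = codec.build_gap_ledger(chrom_counts)
        geno = self.tables.genotype
        person_links = self.tables.person["person_link"].to_numpy(dtype=np.int64)
        by_key = {
            (int(r.person_link), int(r.chromosome)): r.genotype_vec
            for r in geno.itertuples()
        }
        rows = []
        for link in person_links:
            parts = []
            for chrom, count in chrom_counts:
                vec = by_key.get((int(link), chrom))
                if vec is None:
                    raise InvariantError(
                        f"person {link} has no genotype block for chromosome {chrom}"
                    )
                parts.append(vec)
            rows.append(np.frombuffer(b"".join(parts), dtype=np.uint8))
        data = np.vstack(rows) if rows else np.zeros((0, 0), dtype=np.uint8)
        self.unified = codec.UnifiedGenotypeTable(person_links, data, ledger)

    # -- phenotype access --------------------------------------------------

    def phenotype_loci(self) -> pd.DataFrame:
        loc = self.tables.locus
        return loc[loc["Type"].isin(PHENOTYPE_TYPES)].reset_index(drop=True)

    def phenotype_names(self) -> list[str]:
        return self.phenotype_loci()["LocusName"].tolist()

    def decode_phenotype_column(self, trait_name: str) -> np.ndarray:
        """Per-person value of one named trait, fam/person-table order.

        Affection traits yield the 0/1/2 status; quantitative traits the
        float value with NaN for the missing sentinel.
        """
        loci = self.phenotype_loci()
        names = loci["LocusName"].tolist()
        if trait_name not in names:
            raise GenodbError(
                f"unknown trait {trait_name!r}; available: {', '.join(names)}"
            )
        idx = names.index(trait_name)
        types = loci["Type"].tolist()
        ph = self.tables.phenotype.set_index("person_link")["pheno_vec"]
        out = []
        for link in self.tables.person["person_link"]:
            values = codec.decode_phenotypes(ph.loc[int(link)], types)
            v = values[idx]
            out.append(v[0] if isinstance(v, tuple) else v)
        return np.asarray(out)

    # -- summary -----------------------------------------------------------

    def counts(self) -> dict[str, int | float | str]:
        """Structured summary quantities."""
        loc = self.tables.locus
        slots = self.unified.total_slots if self.unified else 0
        bits = (
            8.0 * self.unified.bytes_per_person / slots
            if self.unified and slots
            else float("nan")
        )
        return {
            "locus_count": int(len(loc)),
            "phenotype_count": int(loc["Type"].isin(PHENOTYPE_TYPES).sum()),
            "marker_count": int(len(self.tables.marker)),
            "sample_count": int(len(self.tables.person)),
            "compression": self.tables.metadata.get("compression", ""),
            "bits_per_genotype": bits,
        }

    def summary(self) -> "SessionSummary":
        return SessionSummary(self)


def open_session(db_path: str | Path, verbose: bool = False, trait: str | None = None) -> Session:
    """Open a database into a new, independent session context."""
    return Session.open(db_path, verbose=verbose, trait=trait)


def mkfam(session: Session, trait_name: str) -> pd.DataFrame:
    """Merge pedigree, person and phenotype tables into the 8-column fam.

    Columns: pedigree name, person id, father id, mother id, sex, the
    decoded value of the named trait, and the two link fields.
    """
    trait = session.decode_phenotype_column(trait_name)
    person = session.tables.person
    ped = session.tables.pedigree.set_index("pedigree_link")["PedName"]
    fam = pd.DataFrame(
        {
            "PedName": person["pedigree_link"].map(ped).to_numpy(),
            "PerName": person["PerName"].to_numpy(),
            "Father": person["Father"].to_numpy(),
            "Mother": person["Mother"].to_numpy(),
            "Sex": person["Sex"].to_numpy(),
            "trait": trait,
            "pedigree_link": person["pedigree_link"].to_numpy(),
            "person_link": person["person_link"].to_numpy(),
        }
    )
    return fam


def setfam(session: Session, pruned: pd.DataFrame) -> Session:
    """Install a pruned fam, filtering phenotype and genotype rows to match.

    The pruned rows must be a subset of the current fam; phenotype table
    and unified genotype table are restricted to the same persons in the
    same order.  The marker table is untouched.
    """
    current = set(session.fam["person_link"].tolist())
    links = pruned["person_link"].to_numpy(dtype=np.int64)
    stray = [int(x) for x in links if int(x) not in current]
    if stray:
        raise GenodbError(f"person_link {stray[0]} is not in the current fam")
    session.fam = pruned.reset_index(drop=True)
    pos = {int(l): i for i, l in enumerate(session.unified.person_links)}
    rows = np.array([pos[int(l)] for l in links], dtype=np.int64)
    session.unified = session.unified.subset(rows)
    ph = session.tables.phenotype.set_index("person_link", drop=False)
    session.tables.phenotype = ph.loc[links].reset_index(drop=True)
    return session


class SessionSummary:
    """Printable overview of a session (counts, maps, traits, table shapes)."""

    def __init__(self, session: Session) -> None:
        self.session = session
        self.values = session.counts()
        loci = session.phenotype_loci()
        self.phenotypes = pd.DataFrame(
            {
                "Index": np.arange(1, len(loci) + 1),
                "Name": loci["LocusName"],
                "Type": [_TYPE_NAMES[t] for t in loci["Type"]],
            }
        )
        self.maps = session.tables.mapnames[["map_name", "map_number"]].rename(
            columns={"map_name": "map name", "map_number": "map number"}
        )
        tables = session.tables
        self.basic_tables = {
            t: tuple(tables.frame(t).shape) for t in datastore.ALL_TABLES if t != "metadata"
        }
        self.derived_tables = {
            "fam": tuple(session.fam.shape),
            "markers": tuple(session.markers.shape),
            "unified_genotype_table": (session.unified.n_persons, 2),
        }

    def __getitem__(self, key: str):
        return self.values[key]

    def __str__(self) -> str:
        v = self.values
        lines = [
            f"locus count:   {v['locus_count']}; phenotype count:  "
            f"{v['phenotype_count']}; compression: {v['compression']}",
            f"marker count:  {v['marker_count']}; sample count:  {v['sample_count']}",
            "",
            "genetic and physical maps:",
            self.maps.to_string(),
            "",
            "Phenotypes:",
            self.phenotypes.to_string(index=False),
            "",
            "basic tables:",
            "%-24s %5s %4s" % ("", "rows", "cols"),
        ]
        for t, (r, c) in sorted(self.basic_tables.items()):
            lines.append("%-24s %5d %4d" % (t, r, c))
        lines += ["", "derived tables:", "%-24s %5s %4s" % ("", "rows", "cols")]
        for t, (r, c) in self.derived_tables.items():
            lines.append("%-24s %5d %4d" % (t, r, c))
        return "\n".join(lines)
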