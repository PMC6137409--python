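"""PLINK-style .ped/.map import: parse, validate, compress, populate.

The importer reads whitespace-separated pedigree files (6 leading
columns plus two allele tokens per marker) and 3- or 4-column map files,
computes per-locus allele frequencies, assigns allele index 1 to the
major allele, runs a nuclear-family trio Mendelian check (inconsistent
offspring genotypes are zeroed and counted), packs the genotypes into
the 2-bit format, and writes a complete database.

Heterozygote allele order in the input is not preserved: the packed
representation is unphased, so decoders always emit the lower allele
index first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import codec, datastore
from .datastore import (
    LOCUS_AFFECTION,
    LOCUS_BIALLELIC_MARKER,
    TableSet,
)
from .errors import GenodbError, ParseError, PolymorphicMarkerError

MISSING_ALLELE = "0"


@dataclass
class PedData:
    """Parsed .ped content: sample sheet plus raw allele calls."""

    samples: pd.DataFrame       # PedName, PerName, Father, Mother, Sex, trait
    allele1: np.ndarray         # (persons, markers) object array of labels
    allele2: np.ndarray


@dataclass
class MapData:
    """Parsed .map content, sorted by (chromosome, physical position)."""

    markers: pd.DataFrame       # MarkerName, chromosome, position, cm (may be NaN)
    order: np.ndarray           # permutation from file row order to sorted order
    has_genetic: bool


@dataclass
class LocusFreqs:
    """Per-marker allele labels and frequencies after major-allele assignment."""

    label1: np.ndarray          # major allele label (index 1)
    label2: np.ndarray          # minor/placeholder allele label (index 2)
    freq1: np.ndarray
    freq2: np.ndarray
    all_missing: np.ndarray     # markers where every call was missing
    monomorphic: np.ndarray


@dataclass
class ImportReport:
    n_pedigrees: int = 0
    n_samples: int = 0
    n_markers: int = 0
    n_loci: int = 0
    mendel_inconsistencies: int = 0
    all_missing_markers: int = 0
    monomorphic_markers: int = 0
    notes: list[str] = field(default_factory=list)


def parse_ped(path: str | Path, missing_pheno_code: str = "-9") -> PedData:
    """Parse a .ped file.

    Trait tokens equal to ``missing_pheno_code`` map to the unknown
    affection code 0.  Raw allele labels are preserved as given; a
    marker with more than two distinct non-missing labels is refused
    (2-bit compression cannot hold it).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    except pd.errors.ParserError as exc:
        line = _parser_error_line(exc)
        raise ParseError(f"ragged .ped row in {path.name}", line) from exc
    if df.empty:
        raise ParseError(f"{path.name} is empty")
    ragged = df.isna().any(axis=1)
    if ragged.any():
        raise ParseError(
            f"ragged .ped row in {path.name}", int(ragged.idxmax()) + 1
        )
    n_tokens = df.shape[1]
    if n_tokens < 6 or (n_tokens - 6) % 2:
        raise ParseError(
            f"{path.name}: {n_tokens} tokens per row; expected 6 + 2×markers"
        )
    samples = df.iloc[:, :6].copy()
    samples.columns = ["PedName", "PerName", "Father", "Mother", "Sex", "trait"]
    sex = pd.to_numeric(samples["Sex"], errors="coerce")
    samples["Sex"] = sex.where(sex.isin([1, 2]), 0).astype(int)
    trait = samples["trait"].where(samples["trait"] != missing_pheno_code, "0")
    trait_num = pd.to_numeric(trait, errors="coerce")
    bad = ~trait_num.isin([0, 1, 2])
    if bad.any():
        raise ParseError(
            f"trait value {samples['trait'][bad].iloc[0]!r} is not an "
            "affection code (0/1/2) or the missing code",
            int(bad.idxmax()) + 1,
        )
    samples["trait"] = trait_num.astype(int)
    geno = df.iloc[:, 6:].to_numpy(dtype=object)
    allele1, allele2 = geno[:, 0::2], geno[:, 1::2]
    _check_biallelic(allele1, allele2)
    _check_parents(samples)
    return PedData(samples, allele1, allele2)


def _parser_error_line(exc: Exception) -> int | None:
    import re

    m = re.search(r"line (\d+)", str(exc))
    return int(m.group(1)) if m else None


def _check_biallelic(allele1: np.ndarray, allele2: np.ndarray) -> None:
    for j in range(allele1.shape[1]):
        labels = set(allele1[:, j]) | set(allele2[:, j])
        labels.discard(MISSING_ALLELE)
        if len(labels) > 2:
            raise PolymorphicMarkerError(
                f"marker column {j + 1} has {len(labels)} alleles "
                f"({sorted(labels)}); 2-bit compression refused"
            )


def _check_parents(samples: pd.DataFrame) -> None:
    for ped, group in samples.groupby("PedName", sort=False):
        ids = set(group["PerName"])
        for col in ("Father", "Mother"):
            named = group[col][group[col] != "0"]
            missing = named[~named.isin(ids)]
            if len(missing):
                raise ParseError(
                    f"pedigree {ped}: {col.lower()} {missing.iloc[0]!r} "
                    "is not a member of the pedigree"
                )


def parse_map(path: str | Path, cm: bool = True) -> MapData:
    """Parse a 3- or 4-column .map file.

    Four columns are chromosome, name, genetic position (cM), physical
    position (bp); three columns omit the genetic map.  An all-zero
    genetic column (the PLINK "unknown" convention) is treated as
    absent.  Markers are sorted by (chromosome, physical position).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        return MapData(
            pd.DataFrame(columns=["MarkerName", "chromosome", "position", "cm"]),
            np.empty(0, dtype=np.int64),
            False,
        )
    except pd.errors.ParserError as exc:
        raise ParseError(f"ragged .map row in {path.name}", _parser_error_line(exc)) from exc
    if df.shape[1] not in (3, 4):
        raise ParseError(f"{path.name}: expected 3 or 4 columns, found {df.shape[1]}")
    four = df.shape[1] == 4
    out = pd.DataFrame(
        {
            "MarkerName": df.iloc[:, 1].astype(str),
            "chromosome": pd.to_numeric(df.iloc[:, 0], errors="coerce"),
            "position": pd.to_numeric(df.iloc[:, 3 if four else 2], errors="coerce"),
            "cm": pd.to_numeric(df.iloc[:, 2], errors="coerce") if four else np.nan,
        }
    )
    for col in ("chromosome", "position") + (("cm",) if four else ()):
        bad = out[col].isna()
        if bad.any():
            raise ParseError(
                f"non-numeric {col} value in {path.name}", int(bad.idxmax()) + 1
            )
    dup = out["MarkerName"].duplicated()
    if dup.any():
        raise ParseError(
            f"duplicate marker name {out['MarkerName'][dup].iloc[0]!r} in {path.name}"
        )
    has_genetic = bool(four and cm and (out["cm"] != 0).any())
    order = np.lexsort((out["position"].to_numpy(), out["chromosome"].to_numpy()))
    sorted_df = out.iloc[order].reset_index(drop=True)
    sorted_df["chromosome"] = sorted_df["chromosome"].astype(int)
    sorted_df["position"] = sorted_df["position"].astype(np.int64)
    return MapData(sorted_df, np.asarray(order, dtype=np.int64), has_genetic)


def compute_allele_freqs(allele1: np.ndarray, allele2: np.ndarray) -> LocusFreqs:
    """Allele labels, indices and frequencies from raw calls.

    Frequency = count / (2 × non-missing persons).  Index 1 goes to the
    more frequent label, ties broken lexicographically.  A monomorphic
    marker gets a placeholder second allele at frequency 0; a marker
    with no calls at all gets placeholder labels at (1.0, 0.0) and is
    flagged.
    """
    m = allele1.shape[1]
    label1 = np.empty(m, dtype=object)
    label2 = np.empty(m, dtype=object)
    freq1 = np.empty(m)
    freq2 = np.empty(m)
    all_missing = np.zeros(m, dtype=bool)
    mono = np.zeros(m, dtype=bool)
    for j in range(m):
        counts: dict[str, int] = {}
        for arr in (allele1[:, j], allele2[:, j]):
            for lab in arr:
                if lab != MISSING_ALLELE:
                    counts[lab] = counts.get(lab, 0) + 1
        if not counts:
            label1[j], label2[j] = "1", "2"
            freq1[j], freq2[j] = 1.0, 0.0
            all_missing[j] = True
            mono[j] = True
            continue
        # sort by descending count, then lexicographic label for ties
        ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        total = sum(counts.values())
        label1[j] = ordered[0][0]
        freq1[j] = ordered[0][1] / total
        if len(ordered) > 1:
            label2[j] = ordered[1][0]
            freq2[j] = ordered[1][1] / total
        else:
            label2[j] = _placeholder(label1[j])
            freq2[j] = 0.0
            mono[j] = True
    return LocusFreqs(label1, label2, freq1, freq2, all_missing, mono)


def _placeholder(taken: str) -> str:
    for cand in ("2", "1", "A", "C", "G", "T"):
        if cand != taken:
            return cand
    return taken + "'"


def calls_to_codes(
    allele1: np.ndarray, allele2: np.ndarray, freqs: LocusFreqs
) -> np.ndarray:
    """Map raw label calls to 2-bit codes under the index assignment."""
    p, m = allele1.shape
    codes = np.full((p, m), codec.MISSING, dtype=np.uint8)
    for j in range(m):
        a1, a2 = allele1[:, j], allele2[:, j]
        is1a = a1 == freqs.label1[j]
        is1b = a2 == freqs.label1[j]
        missing = (a1 == MISSING_ALLELE) | (a2 == MISSING_ALLELE)
        n_major = is1a.astype(int) + is1b.astype(int)
        col = np.where(n_major == 2, codec.HOM1, np.where(n_major == 1, codec.HET, codec.HOM2))
        codes[:, j] = np.where(missing, codec.MISSING, col).astype(np.uint8)
    return codes


def mendel_check(
    codes: np.ndarray, father_row: np.ndarray, mother_row: np.ndarray
) -> int:
    """Trio Mendelian check; zeroes inconsistent offspring genotypes in place.

    ``father_row``/``mother_row`` give, per person, the row index of the
    named parent or −1 for founders.  A child genotype is inconsistent
    when it cannot receive one allele from each non-missing parent
    genotype.  Returns the number of genotypes zeroed (set to missing).
    """
    dose = codec._DOSAGE_BY_CODE[codes].astype(np.int8)  # -1 missing, else allele-2 count
    kids = np.flatnonzero((father_row >= 0) & (mother_row >= 0))
    if not kids.size:
        return 0
    kd = dose[kids]
    fd = dose[father_row[kids]]
    md = dose[mother_row[kids]]
    bad = np.zeros(kd.shape, dtype=bool)
    # a hom child needs that allele from both parents
    bad |= (kd == 0) & ((fd == 2) | (md == 2))
    bad |= (kd == 2) & ((fd == 0) | (md == 0))
    # a het child needs one of each; impossible if both parents are the same hom
    bad |= (kd == 1) & (((fd == 0) & (md == 0)) | ((fd == 2) & (md == 2)))
    bad &= kd >= 0
    rows, cols = np.nonzero(bad)
    codes[kids[rows], cols] = codec.MISSING
    return int(bad.sum())


def build_database(
    ped_path: str | Path,
    map_path: str | Path,
    out_path: str | Path,
    *,
    trait_name: str = "default",
    missing_pheno_code: str = "-9",
    cm: bool = True,
    overwrite: bool = False,
    timestamp: str = "",
) -> tuple[Path, ImportReport]:
    """Import a .ped/.map pair into a new database.

    The resulting database holds one affection locus (``trait_name``)
    followed by one biallelic locus per marker; genotypes are packed per
    chromosome; trio-inconsistent offspring genotypes are zeroed and
    counted in the report.  ``timestamp`` is recorded verbatim in the
    metadata so imports can be made byte-reproducible.
    """
    ped = parse_ped(ped_path, missing_pheno_code)
    mp = parse_map(map_path, cm=cm)
    n_markers = len(mp.markers)
    if n_markers == 0:
        raise GenodbError("no markers: the map file is empty")
    if ped.allele1.shape[1] != n_markers:
        raise ParseError(
            f".ped carries {ped.allele1.shape[1]} markers but .map has {n_markers}"
        )
    # .ped columns follow .map file order; re-order to sorted marker order
    allele1 = ped.allele1[:, mp.order]
    allele2 = ped.allele2[:, mp.order]
    freqs = compute_allele_freqs(allele1, allele2)
    codes = calls_to_codes(allele1, allele2, freqs)

    samples = ped.samples
    father_row, mother_row = _parent_rows(samples)
    n_mendel = mendel_check(codes, father_row, mother_row)

    tables = _assemble_tables(samples, mp, freqs, codes, trait_name, timestamp)
    conn = datastore.create_database(out_path, overwrite=overwrite)
    try:
        datastore.write_tables(conn, tables)
    finally:
        conn.close()
    report = ImportReport(
        n_pedigrees=samples["PedName"].nunique(),
        n_samples=len(samples),
        n_markers=n_markers,
        n_loci=n_markers + 1,
        mendel_inconsistencies=n_mendel,
        all_missing_markers=int(freqs.all_missing.sum()),
        monomorphic_markers=int(freqs.monomorphic.sum()),
    )
    if n_mendel:
        report.notes.append(
            f"{n_mendel} Mendelian-inconsistent offspring genotypes set to missing"
        )
    return Path(out_path), report


def _parent_rows(samples: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    key = {
        (ped, per): i
        for i, (ped, per) in enumerate(zip(samples["PedName"], samples["PerName"]))
    }
    father = np.full(len(samples), -1, dtype=np.int64)
    mother = np.full(len(samples), -1, dtype=np.int64)
    for i, (ped, fa, mo) in enumerate(
        zip(samples["PedName"], samples["Father"], samples["Mother"])
    ):
        if fa != "0":
            father[i] = key[(ped, fa)]
        if mo != "0":
            mother[i] = key[(ped, mo)]
    return father, mother


def _assemble_tables(
    samples: pd.DataFrame,
    mp: MapData,
    freqs: LocusFreqs,
    codes: np.ndarray,
    trait_name: str,
    timestamp: str,
) -> TableSet:
    n_markers = len(mp.markers)
    n_persons = len(samples)

    locus = pd.DataFrame(
        {
            "pId": np.arange(1, n_markers + 2),
            "LocusName": [trait_name] + mp.markers["MarkerName"].tolist(),
            "Type": [LOCUS_AFFECTION] + [LOCUS_BIALLELIC_MARKER] * n_markers,
            "AlleleCnt": 2,
            "locus_link": np.arange(n_markers + 1),
        }
    )
    allele_rows = [(0, 1, "1", 0.5), (0, 2, "2", 0.5)]  # trait liability alleles
    for j in range(n_markers):
        link = j + 1
        allele_rows.append((link, 1, freqs.label1[j], freqs.freq1[j]))
        allele_rows.append((link, 2, freqs.label2[j], freqs.freq2[j]))
    allele = pd.DataFrame(allele_rows, columns=["locus_link", "indexX", "AlleleName", "Frequency"])
    allele.insert(0, "pId", np.arange(1, len(allele) + 1))

    chrom_counts: list[tuple[int, int]] = []
    for c, n in mp.markers.groupby("chromosome", sort=False).size().items():
        chrom_counts.append((int(c), int(n)))
    ledger = codec.build_gap_ledger(chrom_counts)
    raw_offsets = np.arange(n_markers, dtype=np.int64)
    uni_offsets = codec.unified_offsets(ledger, raw_offsets)

    marker = pd.DataFrame(
        {
            "pId": np.arange(1, n_markers + 1),
            "locus_link": np.arange(1, n_markers + 1),
            "locus_link_fill": np.arange(1, n_markers + 1),
            "MarkerName": mp.markers["MarkerName"],
            "chromosome": mp.markers["chromosome"],
            "position": mp.markers["position"],
            "raw_offset": raw_offsets,
            "unified_offset": uni_offsets,
        }
    )

    maps: list[tuple[str, int, str, str, str]] = []
    map_rows = []
    if mp.has_genetic:
        maps.append(("Map", 0, "genetic", "cM", "from .map column 3"))
        for j in range(n_markers):
            map_rows.append(
                (j + 1, mp.markers["MarkerName"].iat[j], int(mp.markers["chromosome"].iat[j]),
                 0, float(mp.markers["cm"].iat[j]))
            )
    bp_number = 1 if mp.has_genetic else 0
    maps.append(("BP", bp_number, "physical", "bp", "from .map last column"))
    for j in range(n_markers):
        map_rows.append(
            (j + 1, mp.markers["MarkerName"].iat[j], int(mp.markers["chromosome"].iat[j]),
             bp_number, float(mp.markers["position"].iat[j]))
        )
    map_df = pd.DataFrame(
        map_rows, columns=["locus_link", "MarkerName", "chromosome", "map_index", "position"]
    )
    map_df.insert(0, "pId", np.arange(1, len(map_df) + 1))
    mapnames = pd.DataFrame(maps, columns=["map_name", "map_number", "map_type", "units", "comment"])
    mapnames.insert(0, "pId", np.arange(1, len(mapnames) + 1))

    ped_names = samples["PedName"].drop_duplicates().tolist()
    ped_link = {name: i for i, name in enumerate(ped_names)}
    founders = (samples["Father"] == "0") & (samples["Mother"] == "0")
    pedigree = pd.DataFrame(
        {
            "pId": np.arange(1, len(ped_names) + 1),
            "PedName": ped_names,
            "NumPersons": [int((samples["PedName"] == p).sum()) for p in ped_names],
            "NumFounders": [int(founders[samples["PedName"] == p].sum()) for p in ped_names],
            "NumMales": [int((samples["Sex"][samples["PedName"] == p] == 1).sum()) for p in ped_names],
            "NumFemales": [int((samples["Sex"][samples["PedName"] == p] == 2).sum()) for p in ped_names],
            "NumUnknown": [int((samples["Sex"][samples["PedName"] == p] == 0).sum()) for p in ped_names],
            "pedigree_link": np.arange(len(ped_names)),
        }
    )

    father_row, mother_row = _parent_rows(samples)
    person = pd.DataFrame(
        {
            "pId": np.arange(1, n_persons + 1),
            "PerName": samples["PerName"],
            "Father": samples["Father"],
            "Mother": samples["Mother"],
            "Sex": samples["Sex"],
            "proband": 0,
            "father_link": father_row,
            "mother_link": mother_row,
            "next_sib": -1,
            "pedigree_link": samples["PedName"].map(ped_link).astype(np.int64),
            "person_link": np.arange(n_persons),
        }
    )

    phenotype = pd.DataFrame(
        {
            "pId": np.arange(1, n_persons + 1),
            "pedigree_link": person["pedigree_link"],
            "person_link": person["person_link"],
            "pheno_vec": [
                codec.encode_phenotypes([int(t)], [LOCUS_AFFECTION])
                for t in samples["trait"]
            ],
        }
    )

    geno_rows = []
    col0 = 0
    for chrom, count in chrom_counts:
        packed = codec.pack_matrix(codes[:, col0 : col0 + count])
        for i in range(n_persons):
            geno_rows.append(
                (int(person["pedigree_link"].iat[i]), i, chrom, packed[i].tobytes())
            )
        col0 += count
    genotype = pd.DataFrame(
        geno_rows, columns=["pedigree_link", "person_link", "chromosome", "genotype_vec"]
    )
    genotype.insert(0, "pId", np.arange(1, len(genotype) + 1))

    meta = {
        "schema_version": datastore.SCHEMA_VERSION,
        "compression": datastore.COMPRESSION,
        "created": timestamp,
        "trait_name": trait_name,
    }
    return TableSet(
        locus=locus,
        allele=allele,
        marker=marker,
        map=map_df,
        mapnames=mapnames,
        pedigree=pedigree,
        person=person,
        phenotype=phenotype,
        genotype=genotype,
        metadata=meta,
    )
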