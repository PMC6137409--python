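"""Exporters: VCF with sidecar files, and PLINK transposed (.tped/.tfam).

The VCF writer emits a v4.2 text file with REF = allele index 1 (the
major allele at import time) and unphased genotypes; the body is
produced a fixed-size chunk of markers at a time so the peak memory is
bounded by the chunk, and the output bytes are identical for any chunk
size.  The sidecars carry the sample sheet (.fam), allele frequencies
(.freq), all stored maps (.map), decoded phenotypes (.phe) and a
penetrance stub (.pen).

The transposed-PLINK writer emits real allele labels, two tokens per
sample per row, missing as ``0 0``.
"""

from __future__ import annotations

import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from . import codec, datastore
from .errors import GenodbError
from .session import Session

#: value written to .phe for a missing quantitative phenotype
PHE_MISSING = "-9"


def _sample_names(session: Session) -> list[str]:
    return [
        f"{p}_{i}" for p, i in zip(session.fam["PedName"], session.fam["PerName"])
    ]


def write_vcf(
    session: Session,
    out_prefix: str | Path,
    chunk_size: int = 1000,
    filedate: str | None = None,
) -> Path:
    """Write ``<prefix>.vcf`` chunk-by-chunk; returns the path.

    ``filedate`` fixes the ``##filedate`` header line for reproducible
    output; by default the current date is stamped.
    """
    if not len(session.fam):
        raise GenodbError("refusing to write a VCF with zero samples")
    if chunk_size < 1:
        raise GenodbError("chunk_size must be at least 1")
    out = Path(str(out_prefix) + ".vcf")
    markers = session.markers
    names = _sample_names(session)
    if filedate is None:
        filedate = datetime.date.today().strftime("%Y%m%d")
    gt_by_code = np.array(["0/0", "./.", "0/1", "1/1"], dtype=object)
    with open(out, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##filedate={filedate}\n")
        fh.write("##source=genodb\n")
        for chrom in pd.unique(markers["chromosome"]):
            sub = markers[markers["chromosome"] == chrom]
            fh.write(
                f"##contig=<ID={int(chrom)},length={int(sub['position'].max()) + 1}>\n"
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(names)
            + "\n"
        )
        for lo in range(0, len(markers), chunk_size):
            chunk = markers.iloc[lo : lo + chunk_size]
            codes = codec.extract_codes(
                session.unified, chunk["unified_offset"].to_numpy(np.int64)
            )
            raws = chunk["raw_offset"].to_numpy(np.int64)
            for j in range(len(chunk)):
                row = chunk.iloc[j]
                ref = session.marker_label1[raws[j]]
                alt = session.marker_label2[raws[j]]
                gts = gt_by_code[codes[:, j]]
                fh.write(
                    f"{int(row['chromosome'])}\t{int(row['position'])}\t"
                    f"{row['MarkerName']}\t{ref}\t{alt}\t.\t.\t.\tGT\t"
                    + "\t".join(gts)
                    + "\n"
                )
    return out


def write_sidecars(session: Session, out_prefix: str | Path) -> dict[str, Path]:
    """Write the .fam, .freq, .map, .phe and .pen sidecar files."""
    prefix = str(out_prefix)
    paths = {ext: Path(prefix + "." + ext) for ext in ("fam", "freq", "map", "phe", "pen")}

    fam6 = session.fam[["PedName", "PerName", "Father", "Mother", "Sex", "trait"]]
    fam6.to_csv(paths["fam"], sep="\t", header=False, index=False)

    al = session.tables.allele
    mk = session.tables.marker[["locus_link", "MarkerName"]]
    freq = al.merge(mk, on="locus_link")[["MarkerName", "AlleleName", "Frequency"]]
    freq.to_csv(paths["freq"], sep="\t", header=False, index=False, float_format="%.6f")

    mapnames = session.tables.mapnames.set_index("map_number")["map_name"]
    mp = session.tables.map.copy()
    mp["map_name"] = mp["map_index"].map(mapnames)
    mp[["chromosome", "MarkerName", "map_name", "position"]].to_csv(
        paths["map"], sep="\t", header=False, index=False
    )

    loci = session.phenotype_loci()
    types = loci["Type"].tolist()
    ph = session.tables.phenotype.set_index("person_link")["pheno_vec"]
    with open(paths["phe"], "w") as fh:
        fh.write("PedName\tPerName\t" + "\t".join(loci["LocusName"]) + "\n")
        for _, row in session.fam.iterrows():
            values = codec.decode_phenotypes(ph.loc[int(row["person_link"])], types)
            cells = []
            for v, t in zip(values, types):
                if t == datastore.LOCUS_AFFECTION:
                    cells.append(str(int(v[0])))
                else:
                    cells.append(PHE_MISSING if np.isnan(v) else repr(float(v)))
            fh.write(f"{row['PedName']}\t{row['PerName']}\t" + "\t".join(cells) + "\n")

    with open(paths["pen"], "w") as fh:
        # penetrance stub: no penetrance metadata is carried by PLINK-style
        # input, so every affection trait gets a single fully-penetrant class
        for _, locus in loci[loci["Type"] == datastore.LOCUS_AFFECTION].iterrows():
            fh.write(f"{locus['LocusName']}\t1\t1.0\t1.0\t1.0\n")
    return paths


def write_tped(session: Session, out_prefix: str | Path) -> tuple[Path, Path]:
    """Write PLINK transposed files ``<prefix>.tped`` and ``<prefix>.tfam``.

    Each .tped row is chromosome, marker, genetic position (cM; 0 when no
    genetic map is stored), physical position, then two allele-label
    tokens per sample in index order (lower first); missing is ``0 0``.
    """
    if not len(session.fam):
        raise GenodbError("refusing to write .tped with zero samples")
    tped = Path(str(out_prefix) + ".tped")
    tfam = Path(str(out_prefix) + ".tfam")
    markers = session.markers
    mp = session.tables.map
    mapnames = session.tables.mapnames
    genetic_numbers = mapnames[mapnames["map_type"] == "genetic"]["map_number"]
    cm_by_marker: dict[str, float] = {}
    if len(genetic_numbers):
        sub = mp[mp["map_index"] == int(genetic_numbers.iloc[0])]
        cm_by_marker = dict(zip(sub["MarkerName"], sub["position"]))
    with open(tped, "w") as fh:
        codes = codec.extract_codes(
            session.unified, markers["unified_offset"].to_numpy(np.int64)
        )
        raws = markers["raw_offset"].to_numpy(np.int64)
        for j in range(len(markers)):
            row = markers.iloc[j]
            l1 = session.marker_label1[raws[j]]
            l2 = session.marker_label2[raws[j]]
            pair_by_code = np.array(
                [f"{l1} {l1}", "0 0", f"{l1} {l2}", f"{l2} {l2}"], dtype=object
            )
            cm = cm_by_marker.get(row["MarkerName"], 0.0)
            fh.write(
                f"{int(row['chromosome'])} {row['MarkerName']} {cm:g} "
                f"{int(row['position'])} "
                + " ".join(pair_by_code[codes[:, j]])
                + "\n"
            )
    fam6 = session.fam[["PedName", "PerName", "Father", "Mother", "Sex", "trait"]]
    fam6.to_csv(tfam, sep=" ", header=False, index=False)
    return tped, tfam
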