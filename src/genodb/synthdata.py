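"""Seeded generator of Mendelian-consistent pedigree datasets.

Emulates the shape of the tutorial-scale dataset the rest of the package
is sized against: nuclear families (two founders plus a sibship) typed
at biallelic SNPs on one or more chromosomes, with an affection-status
trait, configurable minor-allele frequencies and uniform genotype
missingness.  Defaults reproduce that scale exactly: 20 pedigrees of 69
(2 founders + 67 offspring) = 1,380 persons and 1,000 markers on a
sub-range of chromosome 1, written as a PLINK-style .ped plus a 4-column
.map carrying both genetic (cM) and physical (bp) positions.

Founder genotypes are drawn from Hardy–Weinberg proportions at the true
minor-allele frequency; offspring receive one allele from each parent
(a heterozygous parent transmits either allele with probability 1/2),
so generated trios are Mendelian-consistent unless an error rate is
injected.  Affection status is an independent Bernoulli draw at the
configured prevalence — there is no disease model — with an optional
single-causal-marker odds-ratio knob for power smoke tests.

The same machinery generates transcript-annotation and range tables,
including empty ranges (no markers) and duplicate transcripts, so the
region-iteration edge cases are exercisable without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

NUCLEOTIDES = ("A", "C", "G", "T")


@dataclass
class SimulationSpec:
    """Parameters of one synthetic dataset."""

    seed: int = 0
    n_pedigrees: int = 20
    offspring_per_pedigree: int = 67
    n_markers: int = 1000
    chromosomes: tuple[int, ...] = (1,)
    bp_span: tuple[int, int] = (2_000_000, 13_000_000)
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.01
    prevalence: float = 0.5
    trait_name: str = "default"
    allele_scheme: str = "12"        # "12" for 1/2 labels, "ACGT" for nucleotides
    causal_marker: int | None = None  # column index of the causal marker
    causal_or: float = 1.0            # per-allele odds ratio at the causal marker
    mendel_error_rate: float = 0.0    # per-genotype rate of injected transmission errors

    def __post_init__(self) -> None:
        for name in ("missing_rate", "prevalence", "mendel_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_markers < 1:
            raise ValueError("n_markers must be at least 1")
        if self.offspring_per_pedigree < 1 or self.n_pedigrees < 1:
            raise ValueError("a pedigree needs two founders and at least one offspring")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")

    @property
    def n_persons(self) -> int:
        return self.n_pedigrees * (2 + self.offspring_per_pedigree)


@dataclass
class SimulatedDataset:
    """Generated files plus ground truth."""

    ped_path: Path
    map_path: Path
    samples: pd.DataFrame            # PedName, PerName, Father, Mother, Sex, trait
    markers: pd.DataFrame            # MarkerName, chromosome, position, cm
    true_maf: np.ndarray             # minor (allele "2") frequency per marker
    dosage: np.ndarray               # (persons, markers) allele-2 count; -1 missing
    labels: pd.DataFrame             # major/minor allele labels per marker


def simulate_dataset(spec: SimulationSpec, out_prefix: str | Path) -> SimulatedDataset:
    """Write ``<prefix>.ped``/``<prefix>.map`` and return them with the truth.

    A fixed seed yields byte-identical files.
    """
    rng = np.random.default_rng(spec.seed)
    markers = _marker_table(spec, rng)
    m = spec.n_markers
    maf = rng.uniform(*spec.maf_range, size=m)

    n_off = spec.offspring_per_pedigree
    fam_size = 2 + n_off
    p = spec.n_persons
    dosage = np.empty((p, m), dtype=np.int8)
    for k in range(spec.n_pedigrees):
        base = k * fam_size
        founders = rng.binomial(2, maf, size=(2, m)).astype(np.int8)
        dosage[base : base + 2] = founders
        for parent_row in (0, 1):
            d = founders[parent_row]
            transmit = np.where(
                d == 1, rng.integers(0, 2, size=(n_off, m)), (d == 2).astype(np.int8)
            ).astype(np.int8)
            if parent_row == 0:
                kids = transmit
            else:
                kids = kids + transmit
        dosage[base + 2 : base + fam_size] = kids
    if spec.mendel_error_rate > 0:
        err = rng.random((p, m)) < spec.mendel_error_rate
        off_rows = np.ones(p, dtype=bool)
        off_rows[:: fam_size] = False
        off_rows[1 :: fam_size] = False
        err &= off_rows[:, None]
        dosage[err] = rng.integers(0, 3, size=int(err.sum()), dtype=np.int8)

    miss = rng.random((p, m)) < spec.missing_rate
    dosage[miss] = -1

    trait = _draw_trait(spec, rng, dosage)
    samples = _sample_sheet(spec, rng, trait)
    labels = _allele_labels(spec, rng)

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    ped_path = out_prefix.with_suffix(".ped")
    map_path = out_prefix.with_suffix(".map")
    _write_ped(ped_path, samples, dosage, labels)
    _write_map(map_path, markers)
    return SimulatedDataset(
        ped_path, map_path, samples, markers, maf, dosage, labels
    )


def _marker_table(spec: SimulationSpec, rng: np.random.Generator) -> pd.DataFrame:
    lo, hi = spec.bp_span
    n_chrom = len(spec.chromosomes)
    per = np.full(n_chrom, spec.n_markers // n_chrom, dtype=int)
    per[: spec.n_markers % n_chrom] += 1
    rows = []
    name_no = 1
    for chrom, count in zip(spec.chromosomes, per):
        if hi - lo < count:
            raise ValueError("bp span too small for the requested marker count")
        draw = np.unique(rng.integers(lo, hi, size=4 * count, dtype=np.int64))
        while len(draw) < count:  # vanishingly rare unless the span is tight
            draw = np.unique(
                np.concatenate([draw, rng.integers(lo, hi, size=4 * count, dtype=np.int64)])
            )
        positions = np.sort(rng.choice(draw, size=count, replace=False))
        for pos in positions:
            rows.append((f"snp{name_no}", int(chrom), int(pos), pos / 1e6))
            name_no += 1
    return pd.DataFrame(rows, columns=["MarkerName", "chromosome", "position", "cm"])


def _draw_trait(spec: SimulationSpec, rng: np.random.Generator, dosage: np.ndarray) -> np.ndarray:
    p = dosage.shape[0]
    if spec.causal_marker is None or spec.causal_or == 1.0:
        affected = rng.random(p) < spec.prevalence
    else:
        d = np.clip(dosage[:, spec.causal_marker], 0, 2)
        logit = np.log(spec.prevalence / (1 - spec.prevalence)) + np.log(spec.causal_or) * d
        affected = rng.random(p) < 1 / (1 + np.exp(-logit))
    return np.where(affected, 2, 1)


def _sample_sheet(spec: SimulationSpec, rng: np.random.Generator, trait: np.ndarray) -> pd.DataFrame:
    rows = []
    i = 0
    for k in range(spec.n_pedigrees):
        ped = f"ped{k + 1}"
        rows.append((ped, "p1", "0", "0", 1, int(trait[i]))); i += 1
        rows.append((ped, "p2", "0", "0", 2, int(trait[i]))); i += 1
        for j in range(spec.offspring_per_pedigree):
            sex = int(rng.integers(1, 3))
            rows.append((ped, f"o{j + 1}", "p1", "p2", sex, int(trait[i])))
            i += 1
    return pd.DataFrame(
        rows, columns=["PedName", "PerName", "Father", "Mother", "Sex", "trait"]
    )


def _allele_labels(spec: SimulationSpec, rng: np.random.Generator) -> pd.DataFrame:
    m = spec.n_markers
    if spec.allele_scheme == "12":
        major = np.full(m, "1", dtype=object)
        minor = np.full(m, "2", dtype=object)
    elif spec.allele_scheme == "ACGT":
        pick = rng.integers(0, 4, size=m)
        shift = rng.integers(1, 4, size=m)
        major = np.array([NUCLEOTIDES[i] for i in pick], dtype=object)
        minor = np.array([NUCLEOTIDES[(i + s) % 4] for i, s in zip(pick, shift)], dtype=object)
    else:
        raise ValueError(f"unknown allele scheme {spec.allele_scheme!r}")
    return pd.DataFrame({"major": major, "minor": minor})


def _write_ped(path: Path, samples: pd.DataFrame, dosage: np.ndarray, labels: pd.DataFrame) -> None:
    major = labels["major"].to_numpy()
    minor = labels["minor"].to_numpy()
    with open(path, "w") as fh:
        for i, row in enumerate(samples.itertuples(index=False)):
            d = dosage[i]
            a1 = np.where(d >= 1, minor, major)
            a2 = np.where(d == 2, minor, major)
            a1 = np.where(d < 0, "0", a1)
            a2 = np.where(d < 0, "0", a2)
            tokens = np.empty(2 * len(d), dtype=object)
            tokens[0::2] = a1
            tokens[1::2] = a2
            fh.write(
                f"{row.PedName} {row.PerName} {row.Father} {row.Mother} "
                f"{row.Sex} {row.trait} " + " ".join(tokens) + "\n"
            )


def _write_map(path: Path, markers: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        for r in markers.itertuples(index=False):
            fh.write(f"{r.chromosome} {r.MarkerName} {r.cm:.6f} {r.position}\n")


def simulate_annotations(
    spec: SimulationSpec,
    markers: pd.DataFrame,
    n_genes: int = 10,
    transcripts_per_gene: int = 2,
    n_empty: int = 3,
    n_duplicates: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate transcript-annotation and range tables over simulated markers.

    Produces ``n_genes`` genes whose transcripts overlap marker positions,
    ``n_empty`` extra transcripts guaranteed to contain no markers (placed
    in inter-marker gaps), and ``n_duplicates`` verbatim duplicate rows to
    exercise deduplication on load.  Returns (annotations, ranges); the
    range table is the chr/start/end/name projection of the annotations.
    """
    rng = np.random.default_rng(spec.seed + 1)
    rows = []
    pos = markers.sort_values(["chromosome", "position"])
    for g in range(n_genes):
        chrom = int(pos["chromosome"].sample(1, random_state=int(rng.integers(2**31))).iloc[0])
        chrom_pos = pos[pos["chromosome"] == chrom]["position"].to_numpy()
        for t in range(transcripts_per_gene):
            anchor = int(rng.choice(chrom_pos))
            start = max(1, anchor - int(rng.integers(1_000, 20_000)))
            end = anchor + int(rng.integers(1_000, 20_000))
            rows.append(
                (f"GENE{g + 1}", f"G{g + 1}", f"tx{g + 1}.{t + 1}", chrom,
                 "+" if rng.random() < 0.5 else "-", start, end)
            )
    # transcripts in marker-free gaps
    gaps = []
    for chrom, grp in pos.groupby("chromosome"):
        pp = grp["position"].to_numpy()
        widths = np.diff(pp)
        for i in np.argsort(widths)[::-1][: n_empty * 2]:
            if widths[i] > 4:
                gaps.append((int(chrom), int(pp[i]) + 1, int(pp[i + 1]) - 1))
    for e, (chrom, lo, hi) in enumerate(gaps[:n_empty]):
        mid = (lo + hi) // 2
        rows.append(
            (f"EMPTY{e + 1}", f"E{e + 1}", f"txe{e + 1}", chrom, "+", lo, min(mid + 1, hi))
        )
    ann = pd.DataFrame(
        rows,
        columns=["SYMBOL", "ALIAS", "TXNAME", "TXCHROM", "TXSTRAND", "TXSTART", "TXEND"],
    )
    if n_duplicates and len(ann):
        dup_idx = rng.integers(0, len(ann), size=n_duplicates)
        ann = pd.concat([ann, ann.iloc[dup_idx]], ignore_index=True)
    ranges = ann.rename(
        columns={"TXCHROM": "chr", "TXSTART": "start", "TXEND": "end", "SYMBOL": "name"}
    )[["chr", "start", "end", "name"]]
    return ann, ranges


def write_annotation_files(
    ann: pd.DataFrame, ranges: pd.DataFrame, out_prefix: str | Path
) -> tuple[Path, Path]:
    """Write the annotation and range tables as tab-separated files."""
    out_prefix = Path(out_prefix)
    ann_path = out_prefix.with_suffix(".annot.tsv")
    rng_path = out_prefix.with_suffix(".ranges.tsv")
    ann.to_csv(ann_path, sep="\t", index=False)
    ranges.to_csv(rng_path, sep="\t", index=False)
    return ann_path, rng_path
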