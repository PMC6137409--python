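"""2-bit genotype codec: packing, unified-vector assembly, and decoders.

Biallelic genotypes are stored 4 to a byte, two bits each, using the
PLINK .bed bit-pair convention with the first genotype in the least
significant pair:

    ``00`` homozygous for allele index 1
    ``01`` missing
    ``10`` heterozygous
    ``11`` homozygous for allele index 2

Per-chromosome packed vectors are padded to a byte boundary, so the last
byte of each chromosome may contain up to three unused bit pairs
("virtual markers").  The unified genotype vector concatenates every
chromosome's padded vector per person; a gap ledger records, per
chromosome, where its slots start so that genome-wide marker offsets can
be translated into slot positions without rebuilding the vector.

Three decoders read the packed data lazily (only the requested markers'
slots are touched): allele-label pairs (``"12"``), 16-bit-shifted raw
integer codes (``0x10001`` ...), and 0/1/2 dosages of the non-major
allele.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import InvariantError

# 2-bit genotype codes (on-disk contract, PLINK .bed convention)
HOM1 = 0b00
MISSING = 0b01
HET = 0b10
HOM2 = 0b11

#: raw integer code per 2-bit code: (index1 << 16) | index2, missing = 0
_RAW_BY_CODE = np.array(
    [(1 << 16) | 1, 0, (1 << 16) | 2, (2 << 16) | 2], dtype=np.int64
)

#: dosage of allele index 2 per 2-bit code; -1 marks missing
_DOSAGE_BY_CODE = np.array([0, -1, 1, 2], dtype=np.int8)

#: sentinel stored for a missing quantitative phenotype value
MISSING_QUANTITATIVE = -99.99


def slots_for(marker_count: int) -> int:
    """Padded 2-bit slot count for one chromosome (multiple of 4)."""
    return 4 * ((marker_count + 3) // 4)


@dataclass(frozen=True)
class PackedGenotypeVector:
    """One person's packed genotypes for one chromosome."""

    chromosome: int
    marker_count: int
    data: bytes

    def __post_init__(self) -> None:
        need = (self.marker_count + 3) // 4
        if len(self.data) != need:
            raise InvariantError(
                f"chromosome {self.chromosome}: payload is {len(self.data)} "
                f"bytes, expected {need} for {self.marker_count} markers"
            )


def pack(codes: Sequence[int] | np.ndarray, chromosome: int = 0) -> PackedGenotypeVector:
    """Pack a sequence of 2-bit genotype codes into a byte vector.

    Four genotypes per byte, first genotype in the least significant bit
    pair.  Trailing slots of the final byte are zero-filled virtual
    markers that every decoder ignores.
    """
    arr = np.asarray(codes, dtype=np.uint8)
    if arr.ndim != 1:
        raise ValueError("pack expects a 1-D code sequence")
    if arr.size and arr.max() > 3:
        raise ValueError("2-bit codes must be in 0..3")
    payload = pack_matrix(arr[None, :])[0].tobytes()
    return PackedGenotypeVector(chromosome, int(arr.size), payload)


def pack_matrix(codes: np.ndarray) -> np.ndarray:
    """Pack a (persons, markers) uint8 code matrix into (persons, bytes)."""
    codes = np.ascontiguousarray(codes, dtype=np.uint8)
    p, m = codes.shape
    padded = np.zeros((p, slots_for(m)), dtype=np.uint8)
    padded[:, :m] = codes
    quads = padded.reshape(p, -1, 4)
    out = (
        quads[:, :, 0]
        | (quads[:, :, 1] << 2)
        | (quads[:, :, 2] << 4)
        | (quads[:, :, 3] << 6)
    )
    return out.astype(np.uint8)


def unpack(vec: PackedGenotypeVector | bytes, marker_count: int | None = None) -> np.ndarray:
    """Inverse of :func:`pack`: recover the 2-bit codes, virtual slots dropped."""
    if isinstance(vec, PackedGenotypeVector):
        data, marker_count = vec.data, vec.marker_count
    else:
        data = vec
        if marker_count is None:
            raise ValueError("marker_count required when unpacking raw bytes")
    return unpack_matrix(np.frombuffer(data, dtype=np.uint8)[None, :], marker_count)[0]


def unpack_matrix(payload: np.ndarray, marker_count: int) -> np.ndarray:
    """Unpack (persons, bytes) into (persons, marker_count) 2-bit codes."""
    payload = np.asarray(payload, dtype=np.uint8)
    p = payload.shape[0]
    codes = np.empty((p, payload.shape[1] * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (payload >> (2 * k)) & 0b11
    return codes[:, :marker_count]


@dataclass(frozen=True)
class GapLedgerEntry:
    """Offset bookkeeping for one chromosome inside the unified vector."""

    chromosome: int
    first_raw_offset: int   # genome-wide ordinal of the chromosome's first marker
    marker_count: int
    first_slot: int         # unified 2-bit slot where this chromosome starts

    @property
    def padded_slots(self) -> int:
        return slots_for(self.marker_count)


def build_gap_ledger(chrom_counts: Sequence[tuple[int, int]]) -> list[GapLedgerEntry]:
    """Ledger from ``[(chromosome, marker_count), ...]`` in storage order."""
    ledger: list[GapLedgerEntry] = []
    raw = slot = 0
    for chrom, count in chrom_counts:
        ledger.append(GapLedgerEntry(chrom, raw, count, slot))
        raw += count
        slot += slots_for(count)
    return ledger


def unified_offsets(ledger: Sequence[GapLedgerEntry], raw_offsets: np.ndarray) -> np.ndarray:
    """Translate genome-wide raw marker ordinals into unified slot positions."""
    raw_offsets = np.asarray(raw_offsets, dtype=np.int64)
    out = np.empty_like(raw_offsets)
    done = np.zeros(raw_offsets.shape, dtype=bool)
    for entry in ledger:
        here = (
            (raw_offsets >= entry.first_raw_offset)
            & (raw_offsets < entry.first_raw_offset + entry.marker_count)
            & ~done
        )
        out[here] = entry.first_slot + (raw_offsets[here] - entry.first_raw_offset)
        done |= here
    if not done.all():
        bad = raw_offsets[~done][0]
        raise InvariantError(f"raw offset {bad} not covered by the gap ledger")
    return out


@dataclass
class UnifiedGenotypeTable:
    """All persons' concatenated packed vectors plus the gap ledger."""

    person_links: np.ndarray            # (persons,) int64
    data: np.ndarray                    # (persons, total bytes) uint8
    ledger: list[GapLedgerEntry] = field(default_factory=list)

    @property
    def n_persons(self) -> int:
        return int(self.person_links.size)

    @property
    def bytes_per_person(self) -> int:
        return int(self.data.shape[1])

    @property
    def total_slots(self) -> int:
        return sum(e.padded_slots for e in self.ledger)

    def subset(self, row_indices: np.ndarray) -> "UnifiedGenotypeTable":
        return UnifiedGenotypeTable(
            self.person_links[row_indices].copy(),
            self.data[row_indices].copy(),
            list(self.ledger),
        )


def unify(blocks: Sequence[PackedGenotypeVector]) -> tuple[bytes, list[GapLedgerEntry]]:
    """Concatenate one person's per-chromosome vectors in the given order.

    Returns the unified byte vector and the gap ledger describing it.
    """
    ledger = build_gap_ledger([(b.chromosome, b.marker_count) for b in blocks])
    return b"".join(b.data for b in blocks), ledger


def build_unified_table(
    person_links: Sequence[int],
    blocks_by_person: Sequence[Sequence[PackedGenotypeVector]],
) -> UnifiedGenotypeTable:
    """Assemble the unified table for many persons.

    Every person must supply one block per chromosome with consistent
    marker counts; a missing or mismatched block is an invariant error.
    """
    links = np.asarray(person_links, dtype=np.int64)
    if len(blocks_by_person) != links.size:
        raise InvariantError("one block list required per person")
    if not len(blocks_by_person):
        return UnifiedGenotypeTable(links, np.zeros((0, 0), dtype=np.uint8), [])
    shape0 = [(b.chromosome, b.marker_count) for b in blocks_by_person[0]]
    rows = []
    ledger = build_gap_ledger(shape0)
    for link, blocks in zip(links, blocks_by_person):
        shape = [(b.chromosome, b.marker_count) for b in blocks]
        if shape != shape0:
            raise InvariantError(
                f"person {link}: chromosome blocks {shape} do not match {shape0}"
            )
        vec, _ = unify(blocks)
        rows.append(np.frombuffer(vec, dtype=np.uint8))
    return UnifiedGenotypeTable(links, np.vstack(rows), ledger)


def extract_codes(table: UnifiedGenotypeTable, slot_offsets: np.ndarray) -> np.ndarray:
    """Decode selected unified slots into a (persons, markers) code matrix.

    Only the bytes holding the requested slots are touched, so the cost
    is proportional to the selection, not to the genome.
    """
    offs = np.asarray(slot_offsets, dtype=np.int64)
    if offs.size and offs.max() >= table.data.shape[1] * 4:
        raise InvariantError("slot offset beyond unified vector")
    byte_idx = offs // 4
    shift = (2 * (offs % 4)).astype(np.uint8)
    return (table.data[:, byte_idx] >> shift[None, :]) & 0b11


# ---------------------------------------------------------------------------
# decoders


def _marker_slots(markers, session) -> np.ndarray:
    import pandas as pd  # local: avoid hard dependency ordering

    if isinstance(markers, pd.DataFrame):
        return markers["unified_offset"].to_numpy(dtype=np.int64)
    return np.asarray(markers, dtype=np.int64)


def getgenotypes(markers, session) -> np.ndarray:
    """Matrix of allele-label pairs, one row per sample, one column per marker.

    Missing genotypes decode to ``"00"``.
    """
    slots = _marker_slots(markers, session)
    if slots.size == 0:
        return np.empty((session.unified.n_persons, 0), dtype=object)
    codes = extract_codes(session.unified, slots)
    raws = markers["raw_offset"].to_numpy(dtype=np.int64)
    out = np.empty(codes.shape, dtype=object)
    for j, raw in enumerate(raws):
        l1 = session.marker_label1[raw]
        l2 = session.marker_label2[raw]
        lut = np.array([l1 + l1, "00", l1 + l2, l2 + l2], dtype=object)
        out[:, j] = lut[codes[:, j]]
    return out


def getgenotypesraw(markers, session) -> np.ndarray:
    """Matrix of raw integer genotype codes ``(index1 << 16) | index2``.

    Homozygous 1/1 is ``0x10001`` (65537), heterozygous 1/2 is ``0x10002``
    (65538), homozygous 2/2 is ``0x20002`` (131074); missing is 0.  The
    code ``0x20001`` (131073) is never produced because the packed format
    is unphased, but :func:`recode_dosage` accepts it.
    """
    slots = _marker_slots(markers, session)
    if slots.size == 0:
        return np.empty((session.unified.n_persons, 0), dtype=np.int64)
    codes = extract_codes(session.unified, slots)
    return _RAW_BY_CODE[codes]


RAW_HOM1 = 0x10001
RAW_HET = 0x10002
RAW_HET_FLIPPED = 0x20001
RAW_HOM2 = 0x20002


def recode_dosage(raw: np.ndarray, freq1) -> np.ndarray:
    """Recode raw genotype integers to non-major-allele dosages 0/1/2.

    ``freq1`` is the per-marker frequency of allele index 1.  Where it is
    below 0.5 the column is flipped (dosage ← 2 − dosage) so that the
    count is always of the *minor* allele, as burden-style tests expect.
    Missing (raw 0) becomes NaN.
    """
    raw = np.asarray(raw)
    freq1 = np.atleast_1d(np.asarray(freq1, dtype=float))
    dose = np.full(raw.shape, np.nan)
    dose[raw == RAW_HOM1] = 0.0
    dose[(raw == RAW_HET) | (raw == RAW_HET_FLIPPED)] = 1.0
    dose[raw == RAW_HOM2] = 2.0
    flip = freq1 < 0.5
    if raw.ndim == 2:
        dose[:, flip] = 2.0 - dose[:, flip]
    elif flip.any():
        dose = 2.0 - dose
    return dose


def recode_affection(status: np.ndarray) -> np.ndarray:
    """Translate 0/1/2 affection codes to NaN/0/1 (unknown/control/case)."""
    status = np.asarray(status)
    if status.size and not np.isin(status, (0, 1, 2)).all():
        bad = status[~np.isin(status, (0, 1, 2))][0]
        raise ValueError(f"affection status must be 0, 1 or 2; got {bad}")
    out = np.full(status.shape, np.nan)
    out[status == 1] = 0.0
    out[status == 2] = 1.0
    return out


# ---------------------------------------------------------------------------
# phenotype payloads: 8 bytes per trait per person, little-endian.
# Affection slot = (status int32, class int32); quantitative slot = float64.


def encode_phenotypes(values: Sequence, types: Sequence[int]) -> bytes:
    """Encode one person's trait values into the 8-byte-per-trait payload.

    ``types`` uses the locus type codes (see :mod:`genodb.datastore`);
    an affection value may be an int status or a (status, class) pair,
    a quantitative value is a float (NaN stored as the −99.99 sentinel).
    """
    from .datastore import LOCUS_AFFECTION, LOCUS_QUANTITATIVE

    out = bytearray()
    for value, typ in zip(values, types, strict=True):
        if typ == LOCUS_AFFECTION:
            if isinstance(value, tuple):
                status, klass = value
            else:
                status, klass = value, 1
            out += struct.pack("<ii", int(status), int(klass))
        elif typ == LOCUS_QUANTITATIVE:
            v = float(value)
            if np.isnan(v):
                v = MISSING_QUANTITATIVE
            out += struct.pack("<d", v)
        else:
            raise ValueError(f"locus type {typ} is not a phenotype type")
    return bytes(out)


def decode_phenotypes(payload: bytes, types: Sequence[int]) -> list:
    """Decode an 8-byte-per-trait payload back into per-trait values.

    Affection traits decode to (status, class) int pairs; quantitative
    traits to floats with the −99.99 sentinel mapped to NaN.
    """
    from .datastore import LOCUS_AFFECTION, LOCUS_QUANTITATIVE

    if len(payload) != 8 * len(types):
        raise InvariantError(
            f"phenotype payload is {len(payload)} bytes, expected {8 * len(types)}"
        )
    values: list = []
    for i, typ in enumerate(types):
        chunk = payload[8 * i : 8 * i + 8]
        if typ == LOCUS_AFFECTION:
            values.append(struct.unpack("<ii", chunk))
        elif typ == LOCUS_QUANTITATIVE:
            (v,) = struct.unpack("<d", chunk)
            values.append(np.nan if v == MISSING_QUANTITATIVE else v)
        else:
            raise ValueError(f"locus type {typ} is not a phenotype type")
    return values
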