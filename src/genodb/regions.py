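"""Range and gene iteration: set ranges/annotations, apply callbacks, scan.

The iteration framework walks a table of genomic ranges (chromosome,
start, end, name), selects the markers whose physical position falls
inside each range (1-based, both ends inclusive), and invokes a
three-argument callback ``(markers, range_row, session)`` for every
range that contains at least one marker.  Gene selection resolves gene
symbols (then aliases) against a transcript-annotation table, producing
one callback invocation per transcript.  A marker-list entry point
invokes the callback once with a ``None`` range.

``fisher_scan`` is the bundled per-variant analysis: for each marker it
tabulates the fam trait against the genotype categories (hom/het/hom,
missing excluded) and computes a two-sided Fisher exact p-value by full
hypergeometric enumeration over tables with the observed margins.
"""

from __future__ import annotations

import itertools
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from . import codec
from .errors import GenodbError, RegionCallbackError
from .session import Session

RANGE_COLUMNS = ["chr", "start", "end", "name"]
ANNOTATION_COLUMNS = [
    "SYMBOL", "ALIAS", "TXNAME", "TXCHROM", "TXSTRAND", "TXSTART", "TXEND",
]


def _coerce_ranges(table, indices) -> pd.DataFrame:
    """Normalize a user range table + 1-based column indices to chr/start/end/name."""
    df = pd.DataFrame(table)
    if indices is None:
        indices = list(range(1, min(df.shape[1], 4) + 1))
    if len(indices) not in (3, 4):
        raise GenodbError("indices must name 3 or 4 columns (chr, start, end[, name])")
    for ix in indices:
        if not 1 <= ix <= df.shape[1]:
            raise GenodbError(f"column index {ix} outside table with {df.shape[1]} columns")
    cols = [df.columns[i - 1] for i in indices]
    out = pd.DataFrame(
        {
            "chr": pd.to_numeric(df[cols[0]]).astype(np.int64),
            "start": pd.to_numeric(df[cols[1]]).astype(np.int64),
            "end": pd.to_numeric(df[cols[2]]).astype(np.int64),
        }
    )
    if len(indices) == 4:
        out["name"] = df[cols[3]].astype(str).to_numpy()
    else:
        out["name"] = [
            f"chr{c}:{s}-{e}" for c, s, e in zip(out["chr"], out["start"], out["end"])
        ]
    bad = out.index[out["start"] > out["end"]]
    if len(bad):
        raise GenodbError(f"range row {int(bad[0])}: start exceeds end")
    return out.reset_index(drop=True)


def set_ranges(session: Session, table, indices=None) -> Session:
    """Install a range table on the session.

    ``indices`` is a 1-based vector of 3 or 4 column positions for
    (chromosome, start, end[, name]); with 3 positions a name column is
    generated as ``chr{c}:{start}-{end}``.
    """
    session.ranges = _coerce_ranges(table, indices)
    return session


def set_annotations(session: Session, source) -> Session:
    """Install a transcript-annotation table from a file path or DataFrame.

    Requires the columns SYMBOL, ALIAS, TXNAME, TXCHROM, TXSTRAND,
    TXSTART, TXEND.  Duplicate records of a gene with the exact same
    transcript start and end are dropped.
    """
    if isinstance(source, (str, Path)):
        df = pd.read_csv(source, sep="\t", dtype={"TXCHROM": str})
    else:
        df = pd.DataFrame(source)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise GenodbError(f"annotation table lacks columns: {', '.join(missing)}")
    df = df.drop_duplicates(subset=["SYMBOL", "TXCHROM", "TXSTART", "TXEND"])
    df = df.reset_index(drop=True)
    df["TXSTART"] = df["TXSTART"].astype(np.int64)
    df["TXEND"] = df["TXEND"].astype(np.int64)
    session.annotations = df
    return session


def _chrom_int(value) -> int:
    s = str(value)
    return int(s[3:]) if s.startswith("chr") else int(s)


def markers_in_range(session: Session, chromosome, start, end) -> pd.DataFrame:
    """All markers with the given chromosome and start ≤ position ≤ end."""
    m = session.markers
    mask = (
        (m["chromosome"] == _chrom_int(chromosome))
        & (m["position"] >= int(start))
        & (m["position"] <= int(end))
    )
    return m[mask]


def apply_to_ranges(session: Session, callback, ranges=None, indices=None) -> int:
    """Invoke ``callback(markers, range_row, session)`` per non-empty range.

    Uses the session's installed range table unless an override table
    (with its column indices) is supplied.  Ranges containing no markers
    are skipped; when the session is verbose a diagnostic is printed.
    Returns the number of invocations.
    """
    if ranges is not None:
        table = _coerce_ranges(ranges, indices)
    elif session.ranges is not None:
        table = session.ranges
    else:
        raise GenodbError("no ranges set; call set_ranges or pass an override")
    invoked = 0
    for _, row in table.iterrows():
        hits = markers_in_range(session, row["chr"], row["start"], row["end"])
        if not len(hits):
            if session.verbose:
                print(
                    f"No markers in range: {row['name']}, {row['chr']}, "
                    f"{row['start']}, {row['end']}"
                )
            continue
        try:
            callback(hits.reset_index(drop=True), row, session)
        except Exception as exc:
            raise RegionCallbackError(
                f"callback failed in range {row['name']} "
                f"(chr{row['chr']}:{row['start']}-{row['end']}): {exc}"
            ) from exc
        invoked += 1
    return invoked


def apply_to_genes(
    session: Session,
    callback,
    genes=None,
    ranges=None,
    indices=None,
    chromosomes=None,
    markers=None,
) -> int:
    """Gene/chromosome/range/marker selectors on top of the range iteration.

    Exactly one selector family may be given.  Gene names resolve by
    exact symbol match, then by alias; ``"*"`` selects every transcript.
    Each matching transcript yields its own range (no union/merge).
    Chromosome selectors become whole-chromosome ranges; a marker list
    delegates to :func:`apply_to_markers`.
    """
    chosen = [x is not None for x in (genes, ranges, chromosomes, markers)]
    if sum(chosen) != 1:
        raise GenodbError(
            "exactly one of genes, ranges, chromosomes or markers must be given"
        )
    if markers is not None:
        return apply_to_markers(session, callback, markers)
    if ranges is not None:
        return apply_to_ranges(session, callback, ranges, indices)
    if chromosomes is not None:
        table = pd.DataFrame(
            {
                "chr": [int(c) for c in np.atleast_1d(chromosomes)],
                "start": 0,
                "end": np.iinfo(np.int64).max,
            }
        )
        table["name"] = [f"chr{c}" for c in table["chr"]]
        return apply_to_ranges(session, callback, table, [1, 2, 3, 4])
    ann = session.annotations
    if ann is None:
        raise GenodbError("no annotation table set; call set_annotations first")
    if isinstance(genes, str):
        genes = [genes]
    if list(genes) == ["*"]:
        hits = ann
    else:
        parts = []
        for g in genes:
            sub = ann[ann["SYMBOL"] == g]
            if not len(sub):
                sub = ann[ann["ALIAS"] == g]
            if not len(sub):
                warnings.warn(f"gene {g!r} not found in the annotation table")
                continue
            parts.append(sub)
        hits = pd.concat(parts) if parts else ann.iloc[0:0]
    if not len(hits):
        return 0
    table = pd.DataFrame(
        {
            "chr": [_chrom_int(c) for c in hits["TXCHROM"]],
            "start": hits["TXSTART"].to_numpy(),
            "end": hits["TXEND"].to_numpy(),
            "name": hits["SYMBOL"].astype(str).to_numpy(),
        }
    )
    return apply_to_ranges(session, callback, table, [1, 2, 3, 4])


def apply_to_markers(session: Session, callback, markers) -> int:
    """Invoke the callback once on an explicit marker selection, range=None."""
    if isinstance(markers, (str, list, tuple, np.ndarray)) and not isinstance(
        markers, pd.DataFrame
    ):
        names = [markers] if isinstance(markers, str) else list(markers)
        table = session.markers
        unknown = [n for n in names if n not in set(table["MarkerName"])]
        if unknown:
            raise GenodbError(f"unknown marker {unknown[0]!r}")
        markers = table[table["MarkerName"].isin(names)]
    if not len(markers):
        return 0
    callback(markers.reset_index(drop=True), None, session)
    return 1


def genotype_counts(markers: pd.DataFrame, session: Session, gene: str = "") -> pd.DataFrame:
    """Per-marker genotype counts (n11, n12, n22, n_missing), index 1 = major.

    When the session is verbose, prints one ``gene marker n11 n12 n22``
    line per marker.
    """
    raw = codec.getgenotypesraw(markers, session)
    freq1 = session.freq1[markers["raw_offset"].to_numpy(dtype=np.int64)]
    dose = codec.recode_dosage(raw, freq1)
    out = pd.DataFrame(
        {
            "MarkerName": markers["MarkerName"].to_numpy(),
            "n11": (dose == 0).sum(axis=0),
            "n12": (dose == 1).sum(axis=0),
            "n22": (dose == 2).sum(axis=0),
            "n_missing": np.isnan(dose).sum(axis=0),
        }
    )
    if session.verbose:
        for r in out.itertuples():
            print(f"{gene} {r.MarkerName} {r.n11} {r.n12} {r.n22}")
    return out


# ---------------------------------------------------------------------------
# Fisher exact test by hypergeometric enumeration


def fisher_exact(table: np.ndarray, tol: float = 1e-7) -> float:
    """Two-sided Fisher exact p-value for an r×c contingency table.

    Enumerates every table with the observed margins; the p-value is the
    total conditional (multivariate hypergeometric) probability of the
    tables no more probable than the observed one (within a relative
    tolerance on the probability, as exact-test implementations
    conventionally apply).  Degenerate tables (a single row or column
    after dropping empty margins) return NaN.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2:
        raise ValueError("contingency table must be 2-D")
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        return float("nan")
    if t.shape[0] != 2 and t.shape[1] == 2:
        t = t.T  # p is transpose-invariant; the 2-row path is vectorized
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n = int(t.sum())
    base = gammaln(rows + 1).sum() + gammaln(cols + 1).sum() - gammaln(n + 1)
    logp_obs = base - gammaln(t + 1).sum()
    cutoff = logp_obs + np.log1p(tol)
    if t.shape[0] == 2:
        logps = _enumerate_two_rows(rows, cols, base)
    else:
        logps = np.array(list(_enumerate_general(rows, cols, base)))
    return float(np.exp(logps[logps <= cutoff]).sum())


def _enumerate_two_rows(rows: np.ndarray, cols: np.ndarray, base: float) -> np.ndarray:
    """Vectorized enumeration for 2×c margins: grid over the first row."""
    r1 = int(rows[0])
    axes = [np.arange(min(r1, int(c)) + 1) for c in cols[:-1]]
    lg = [gammaln(np.arange(int(c) + 1) + 1) for c in cols]
    grids = np.meshgrid(*axes, indexing="ij", sparse=True)
    s = sum(grids)
    last = r1 - s
    ok = (last >= 0) & (last <= int(cols[-1]))
    # log prob of first row; second row forced by the column margins
    logq = np.zeros(np.broadcast_shapes(*(g.shape for g in grids)))
    for j, g in enumerate(grids):
        cj = int(cols[j])
        logq = logq + lg[j][g] + lg[j][cj - g]
    lastc = int(cols[-1])
    safe_last = np.clip(last, 0, lastc)
    logq = logq + lg[-1][safe_last] + lg[-1][lastc - safe_last]
    return (base - logq)[ok].ravel()


def _enumerate_general(rows, cols, base):
    """Cell-by-cell recursive enumeration for tables with 3+ rows."""
    r, c = len(rows), len(cols)

    def rec(i, col_rem, acc):
        if i == r - 1:  # last row forced
            yield acc - gammaln(np.asarray(col_rem) + 1).sum()
            return
        ri = int(rows[i])
        rest_rows = int(sum(rows[i + 1 :]))
        for combo in _row_fills(ri, col_rem, rest_rows):
            yield from rec(
                i + 1,
                [cr - x for cr, x in zip(col_rem, combo)],
                acc - gammaln(np.asarray(combo) + 1).sum(),
            )

    yield from rec(0, [int(x) for x in cols], base)


def _row_fills(total, col_rem, rest_rows):
    """All ways to place ``total`` items into cells bounded by col_rem,
    leaving each later column satisfiable."""
    c = len(col_rem)

    def rec(j, remaining):
        if j == c - 1:
            if 0 <= remaining <= col_rem[j]:
                yield (remaining,)
            return
        tail_cap = sum(col_rem[j + 1 :])
        lo = max(0, remaining - tail_cap)
        hi = min(col_rem[j], remaining)
        for x in range(lo, hi + 1):
            for rest in rec(j + 1, remaining - x):
                yield (x, *rest)

    yield from rec(0, total)


def fisher_scan(markers: pd.DataFrame, range_row, session: Session) -> pd.Series:
    """Per-marker Fisher exact p-value of trait × genotype category.

    Genotype categories are the decoded label pairs (hom1/het/hom2);
    missing genotypes are excluded.  Markers whose table degenerates to
    a single row or column yield NaN.
    """
    geno = codec.getgenotypes(markers, session)
    trait = session.fam["trait"].to_numpy()
    pvals = []
    for j in range(geno.shape[1]):
        col = geno[:, j]
        keep = col != "00"
        if not keep.any():
            pvals.append(float("nan"))
            continue
        ct = pd.crosstab(pd.Series(trait[keep]), pd.Series(col[keep]))
        pvals.append(fisher_exact(ct.to_numpy()))
    return pd.Series(pvals, index=markers["MarkerName"].to_numpy(), name="p_fisher")
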