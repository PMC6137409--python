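"""Region iteration tests: ranges, annotations, callbacks, Fisher scan."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from genodb import (
    apply_to_genes,
    apply_to_markers,
    apply_to_ranges,
    codec,
    genotype_counts,
    markers_in_range,
    set_annotations,
    set_ranges,
)
from genodb.errors import GenodbError, RegionCallbackError
from genodb.regions import fisher_exact, fisher_scan
from genodb.synthdata import simulate_annotations


class TestSetRanges:
    EXAMPLE = np.array(
        [[1, 2240000, 2245000], [1, 2245000, 2250000], [1, 3760000, 3761000]]
    )

    def test_three_index_form_generates_names(self, toy_session):
        ses = set_ranges(toy_session, self.EXAMPLE, [1, 2, 3])
        assert ses.ranges.shape == (3, 4)
        assert ses.ranges["name"].iloc[0] == "chr1:2240000-2245000"

    def test_four_index_form_preserves_names(self, toy_session):
        table = pd.DataFrame(self.EXAMPLE, columns=["chr", "start", "end"])
        table = pd.concat([table, table.iloc[[0]]], ignore_index=True)
        table["name"] = list("ABCD")
        ses = set_ranges(toy_session, table, [1, 2, 3, 4])
        assert ses.ranges["name"].tolist() == list("ABCD")

    def test_empty_table_iterates_as_noop(self, toy_session):
        ses = set_ranges(toy_session, pd.DataFrame(columns=["c", "s", "e"]), [1, 2, 3])
        assert apply_to_ranges(ses, lambda *a: pytest.fail("must not run")) == 0

    def test_start_after_end_names_the_row(self, toy_session):
        with pytest.raises(GenodbError, match="row 1"):
            set_ranges(toy_session, np.array([[1, 5, 9], [1, 9, 5]]), [1, 2, 3])

    def test_bad_column_index_is_error(self, toy_session):
        with pytest.raises(GenodbError, match="index 7"):
            set_ranges(toy_session, self.EXAMPLE, [1, 2, 7])


class TestMarkersInRange:
    def test_inclusive_at_both_endpoints(self, toy_session):
        m = toy_session.markers.iloc[3]
        hit = markers_in_range(
            toy_session, m["chromosome"], m["position"], m["position"]
        )
        assert m["MarkerName"] in set(hit["MarkerName"])

    def test_agreement_with_linear_scan_on_1000_random_ranges(self, toy_session):
        ses = toy_session
        rng = np.random.default_rng(17)
        table = ses.markers
        for _ in range(1000):
            chrom = int(rng.choice([1, 2, 3]))
            a, b = sorted(rng.integers(0, 2_100_000, size=2))
            got = set(markers_in_range(ses, chrom, a, b)["MarkerName"])
            want = {
                r.MarkerName
                for r in table.itertuples()
                if r.chromosome == chrom and a <= r.position <= b
            }
            assert got == want


class TestApplyToRanges:
    def test_invocation_count_equals_nonempty_ranges(self, toy_session):
        ses = toy_session
        rng = np.random.default_rng(3)
        rows = []
        for _ in range(6):
            chrom = int(rng.choice([1, 2]))
            a, b = sorted(rng.integers(0, 2_100_000, size=2))
            rows.append((chrom, a, b))
        table = pd.DataFrame(rows, columns=["chr", "start", "end"])
        nonempty = sum(
            bool(len(markers_in_range(ses, c, a, b))) for c, a, b in rows
        )
        seen = []
        n = apply_to_ranges(ses, lambda m, r, e: seen.append(len(m)), table, [1, 2, 3])
        assert n == len(seen) == nonempty

    def test_every_delivered_marker_satisfies_the_range_predicate(self, toy_session):
        ses = toy_session
        rng = np.random.default_rng(8)
        rows = [
            (int(rng.choice([1, 2])), *sorted(rng.integers(0, 2_100_000, size=2)))
            for _ in range(40)
        ]
        table = pd.DataFrame(rows, columns=["chr", "start", "end"])

        def check(m, r, e):
            assert (m["chromosome"] == r["chr"]).all()
            assert ((m["position"] >= r["start"]) & (m["position"] <= r["end"])).all()

        apply_to_ranges(ses, check, table, [1, 2, 3])

    def test_empty_ranges_emit_verbose_diagnostic(self, toy_session, capsys):
        ses = toy_session
        ses.verbose = True
        table = pd.DataFrame({"chr": [9], "start": [1], "end": [2]})
        n = apply_to_ranges(ses, lambda *a: None, table, [1, 2, 3])
        assert n == 0
        assert "No markers in range" in capsys.readouterr().out

    def test_whole_chromosome_range_delivers_all_its_markers(self, toy_session):
        ses = toy_session
        got = {}
        apply_to_ranges(
            ses,
            lambda m, r, e: got.setdefault("n", len(m)),
            pd.DataFrame({"c": [1], "s": [0], "e": [10**9]}),
            [1, 2, 3],
        )
        assert got["n"] == int((ses.markers["chromosome"] == 1).sum())

    def test_callback_exception_names_the_range(self, toy_session):
        ses = toy_session
        table = pd.DataFrame({"c": [1], "s": [0], "e": [10**9]})

        def boom(m, r, e):
            raise RuntimeError("inner")

        with pytest.raises(RegionCallbackError, match="chr1:0-1000000000"):
            apply_to_ranges(ses, boom, table, [1, 2, 3])


class TestAnnotations:
    def test_duplicate_transcripts_deduplicated_on_load(self, toy_session):
        ann = pd.DataFrame(
            {
                "SYMBOL": ["G1", "G1"],
                "ALIAS": ["g1", "g1"],
                "TXNAME": ["tx1", "tx1b"],
                "TXCHROM": [1, 1],
                "TXSTRAND": ["+", "-"],
                "TXSTART": [100, 100],
                "TXEND": [200, 200],
            }
        )
        ses = set_annotations(toy_session, ann)
        assert len(ses.annotations) == 1

    def test_missing_columns_named(self, toy_session):
        with pytest.raises(GenodbError, match="TXSTART.*TXEND|TXEND.*TXSTART"):
            set_annotations(toy_session, pd.DataFrame({"SYMBOL": [], "ALIAS": [],
                                                       "TXNAME": [], "TXCHROM": [],
                                                       "TXSTRAND": []}))

    def test_swap_and_swap_back_restores_lookups(self, toy, toy_session):
        spec, ds, _, _ = toy
        ann, _ = simulate_annotations(spec, ds.markers, n_genes=4)
        other = ann.copy()
        other["SYMBOL"] = other["SYMBOL"] + "X"
        set_annotations(toy_session, ann)
        first = toy_session.annotations.copy()
        set_annotations(toy_session, other)
        set_annotations(toy_session, ann)
        pd.testing.assert_frame_equal(toy_session.annotations, first)

    def test_transcript_marker_counts_match_scan_oracle(self, toy, toy_session):
        spec, ds, _, _ = toy
        ann, _ = simulate_annotations(spec, ds.markers, n_genes=6, n_empty=2)
        ses = set_annotations(toy_session, ann)
        seen = []
        apply_to_genes(ses, lambda m, r, e: seen.append((r["name"], len(m))), genes="*")
        dedup = ann.drop_duplicates(subset=["SYMBOL", "TXCHROM", "TXSTART", "TXEND"])
        oracle = []
        for t in dedup.itertuples():
            k = len(markers_in_range(ses, t.TXCHROM, t.TXSTART, t.TXEND))
            if k:
                oracle.append((t.SYMBOL, k))
        assert seen == oracle


class TestApplyToGenes:
    def test_single_gene_single_transcript(self, toy, toy_session):
        spec, ds, _, _ = toy
        ann, _ = simulate_annotations(spec, ds.markers, n_genes=5, transcripts_per_gene=1,
                                      n_empty=0, n_duplicates=0)
        ses = set_annotations(toy_session, ann)
        target = ann.iloc[0]
        calls = []
        apply_to_genes(ses, lambda m, r, e: calls.append(r), genes=[target["SYMBOL"]])
        for r in calls:
            assert r["start"] == target["TXSTART"] and r["end"] == target["TXEND"]

    def test_alias_resolution_after_symbol(self, toy, toy_session):
        spec, ds, _, _ = toy
        ann, _ = simulate_annotations(spec, ds.markers, n_genes=3, n_empty=0)
        ses = set_annotations(toy_session, ann)
        by_symbol, by_alias = [], []
        apply_to_genes(ses, lambda m, r, e: by_symbol.append(len(m)), genes=["GENE1"])
        apply_to_genes(ses, lambda m, r, e: by_alias.append(len(m)), genes=["G1"])
        assert by_symbol == by_alias

    def test_unknown_gene_warns_and_skips(self, toy, toy_session):
        spec, ds, _, _ = toy
        ann, _ = simulate_annotations(spec, ds.markers, n_genes=2)
        ses = set_annotations(toy_session, ann)
        with pytest.warns(UserWarning, match="NOPE"):
            n = apply_to_genes(ses, lambda *a: None, genes=["NOPE"])
        assert n == 0

    def test_absent_chromosomes_yield_zero_invocations(self, toy_session):
        n = apply_to_genes(toy_session, lambda *a: pytest.fail("ran"), chromosomes=[24, 26])
        assert n == 0

    def test_no_selector_is_error(self, toy_session):
        with pytest.raises(GenodbError, match="exactly one"):
            apply_to_genes(toy_session, lambda *a: None)

    def test_two_selectors_is_error(self, toy_session):
        with pytest.raises(GenodbError, match="exactly one"):
            apply_to_genes(toy_session, lambda *a: None, genes=["X"], chromosomes=[1])


class TestApplyToMarkers:
    def test_named_marker_reaches_callback_with_null_range(self, toy_session):
        name = toy_session.markers["MarkerName"].iloc[0]
        got = {}

        def cb(m, r, e):
            assert r is None
            got["geno"] = codec.getgenotypes(m, e)

        assert apply_to_markers(toy_session, cb, name) == 1
        assert got["geno"].shape == (toy_session.unified.n_persons, 1)

    def test_empty_selection_never_invokes(self, toy_session):
        assert apply_to_markers(toy_session, lambda *a: pytest.fail("ran"), []) == 0

    def test_unknown_marker_is_error(self, toy_session):
        with pytest.raises(GenodbError, match="snpX"):
            apply_to_markers(toy_session, lambda *a: None, ["snpX"])

    def test_equivalent_to_degenerate_ranges(self, toy_session):
        ses = toy_session
        names = ses.markers["MarkerName"].iloc[:5].tolist()
        via_markers = []
        apply_to_markers(ses, lambda m, r, e: via_markers.extend(m["MarkerName"]), names)
        sub = ses.markers[ses.markers["MarkerName"].isin(names)]
        table = pd.DataFrame(
            {"chr": sub["chromosome"], "s": sub["position"], "e": sub["position"]}
        )
        via_ranges = []
        apply_to_ranges(ses, lambda m, r, e: via_ranges.extend(m["MarkerName"]),
                        table, [1, 2, 3])
        assert sorted(via_markers) == sorted(via_ranges)


class TestGenotypeCounts:
    def test_counts_sum_to_sample_count(self, toy_session):
        out = genotype_counts(toy_session.markers, toy_session)
        total = out[["n11", "n12", "n22", "n_missing"]].sum(axis=1)
        assert (total == toy_session.unified.n_persons).all()

    def test_counts_match_dosage_histogram(self, toy_session):
        ses = toy_session
        out = genotype_counts(ses.markers, ses)
        raw = codec.getgenotypesraw(ses.markers, ses)
        dose = codec.recode_dosage(raw, ses.freq1)
        for k, colname in [(0, "n11"), (1, "n12"), (2, "n22")]:
            assert (out[colname].to_numpy() == (dose == k).sum(axis=0)).all()

    def test_verbose_line_format(self, toy_session, capsys):
        ses = toy_session
        ses.verbose = True
        out = genotype_counts(ses.markers.iloc[:1], ses, gene="GENE1")
        r = out.iloc[0]
        line = capsys.readouterr().out.strip()
        assert line == f"GENE1 {r['MarkerName']} {r['n11']} {r['n12']} {r['n22']}"

    def test_all_hom_major(self, toy_session):
        ses = toy_session
        ses.unified.data[:] = 0  # every slot HOM1
        out = genotype_counts(ses.markers.iloc[:3], ses)
        assert (out["n11"] == ses.unified.n_persons).all()
        assert (out[["n12", "n22", "n_missing"]].to_numpy() == 0).all()


def r_fisher_pvalues(tables, tmp_path):
    """Batch-evaluate fisher.test p-values in one Rscript invocation."""
    import subprocess

    lines = []
    for t in tables:
        t = np.asarray(t)
        lines.append(" ".join([str(t.shape[0])] + [str(x) for x in t.ravel()]))
    (tmp_path / "tables.txt").write_text("\n".join(lines) + "\n")
    script = tmp_path / "fisher.R"
    script.write_text(
        'con <- file(commandArgs(TRUE)[1], "r")\n'
        "while (length(line <- readLines(con, n = 1)) == 1) {\n"
        "  v <- as.integer(strsplit(line, ' ')[[1]])\n"
        "  m <- matrix(v[-1], nrow = v[1], byrow = TRUE)\n"
        "  cat(sprintf('%.17g\\n', fisher.test(m, workspace = 2e6)$p.value))\n"
        "}\n"
    )
    out = subprocess.run(
        ["Rscript", str(script), str(tmp_path / "tables.txt")],
        capture_output=True, text=True, check=True,
    )
    return [float(x) for x in out.stdout.split()]


class TestFisher:
    def test_perfectly_separated_2x2(self):
        p = fisher_exact([[10, 0], [0, 10]])
        assert p == pytest.approx(
            scipy.stats.fisher_exact([[10, 0], [0, 10]])[1], abs=1e-12
        )

    def test_agrees_with_scipy_on_random_2x2_tables(self):
        """250 random 2×2 tables; SciPy's 2×2 path is a fully independent
        exact implementation, so agreement is demanded to 1e-10."""
        rng = np.random.default_rng(123)
        for _ in range(250):
            t = rng.integers(0, 12, size=(2, 2))
            t[0, 0] += 1  # avoid fully empty tables
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            ours = fisher_exact(t)
            ref = scipy.stats.fisher_exact(t).pvalue
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_agrees_with_r_on_random_2x3_and_3x3_tables(self, tmp_path):
        """250 random 2×3 tables plus 20 3×3 tables against R's fisher.test
        (an independent exact enumeration), to 1e-10."""
        rng = np.random.default_rng(321)
        tables = []
        for _ in range(250):
            t = rng.integers(0, 12, size=(2, 3))
            t[0, 0] += 1
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            tables.append(t)
        for _ in range(20):
            tables.append(rng.integers(1, 6, size=(3, 3)))
        refs = r_fisher_pvalues(tables, tmp_path)
        for t, ref in zip(tables, refs):
            assert fisher_exact(t) == pytest.approx(ref, abs=1e-10)

    def test_degenerate_tables_are_nan(self):
        assert np.isnan(fisher_exact([[5, 5]]))
        assert np.isnan(fisher_exact([[5], [5]]))
        assert np.isnan(fisher_exact([[3, 0], [2, 0]]))

    def test_scan_monomorphic_marker_is_nan(self, toy_session):
        ses = toy_session
        ses.unified.data[:] = 0  # all hom-major everywhere
        pv = fisher_scan(ses.markers.iloc[:2], None, ses)
        assert pv.isna().all()

    def test_scan_excludes_missing_genotypes(self, toy_session):
        ses = toy_session
        pv = fisher_scan(ses.markers, None, ses)
        geno = codec.getgenotypes(ses.markers, ses)
        trait = ses.fam["trait"].to_numpy()
        j = 0  # spot-check the first marker against a hand-built table
        keep = geno[:, j] != "00"
        ct = pd.crosstab(pd.Series(trait[keep]), pd.Series(geno[keep, j]))
        assert pv.iloc[j] == pytest.approx(fisher_exact(ct.to_numpy()), abs=1e-12)
        assert len(pv) == len(ses.markers)
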