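import numpy as np
import pandas as pd
import pytest

from l1quant import l1loci
from l1quant.synthdata import CountDesign, L1FixtureSpec, generate_count_matrix, generate_l1_fixture


def intervals(rows, cols=("chrom", "start", "end")):
    return pd.DataFrame(rows, columns=cols)


class TestContext:
    def test_uid_inside_gene(self):
        uids = intervals([("chr1", 100, 200)])
        genes = pd.DataFrame(
            [("chr1", 50, 500, "+", "G")],
            columns=["chrom", "start", "end", "strand", "gene_id"],
        )
        out = l1loci.classify_uid_context(uids, genes)
        assert out.context[0] == "intronic" and out.host_gene[0] == "G"

    def test_chromosome_without_genes(self):
        uids = intervals([("chr9", 100, 200)])
        genes = pd.DataFrame(
            [("chr1", 50, 500, "+", "G")],
            columns=["chrom", "start", "end", "strand", "gene_id"],
        )
        out = l1loci.classify_uid_context(uids, genes)
        assert out.context[0] == "intergenic" and out.host_gene[0] is None

    def test_longest_overlap_wins(self):
        uids = intervals([("chr1", 1000, 2000)])
        genes = pd.DataFrame(
            [("chr1", 800, 1200, "+", "A"),     # 200 bp overlap
             ("chr1", 1100, 2500, "-", "B")],   # 900 bp overlap
            columns=["chrom", "start", "end", "strand", "gene_id"],
        )
        out = l1loci.classify_uid_context(uids, genes)
        assert out.host_gene[0] == "B"

    def test_negative_interval_rejected(self):
        with pytest.raises(ValueError):
            l1loci.classify_uid_context(
                intervals([("chr1", 200, 100)]),
                pd.DataFrame(columns=["chrom", "start", "end", "strand", "gene_id"]),
            )


class TestMappability:
    def test_worked_example(self):
        uids = intervals([("chr1", 100, 300)])
        mers = intervals([("chr1", 100, 160), ("chr1", 150, 210), ("chr1", 290, 360)])
        # overlaps 60, 60, 10 -> only the first two reach 45 bp
        assert l1loci.mappability_score(uids, mers)[0] == 2

    def test_no_regions_on_chromosome(self):
        uids = intervals([("chr2", 100, 300)])
        mers = intervals([("chr1", 100, 160)])
        assert l1loci.mappability_score(uids, mers)[0] == 0

    def test_boundary_overlap_inclusive(self):
        uids = intervals([("chr1", 100, 300)])
        mers = intervals([("chr1", 100, 145)])  # exactly 45 bp inside
        assert l1loci.mappability_score(uids, mers)[0] == 1
        assert l1loci.mappability_score(uids, mers, min_overlap=46)[0] == 0

    @pytest.mark.parametrize("seed", range(25))
    def test_brute_force_oracle(self, seed):
        r = np.random.default_rng(seed)
        uids = intervals(
            [("chr1", int(s), int(s) + int(r.integers(500, 2000)))
             for s in r.integers(0, 50_000, size=8)]
        )
        starts = r.integers(0, 52_000, size=200)
        mers = intervals(
            [("chr1", int(s), int(s) + int(l))
             for s, l in zip(starts, r.integers(30, 200, size=200))]
        )
        got = l1loci.mappability_score(uids, mers)
        for i, u in uids.iterrows():
            brute = sum(
                1 for _, m in mers.iterrows()
                if min(u.end, m.end) - max(u.start, m.start) >= 45
            )
            assert got[i] == brute


class TestComposition:
    def test_family_percentages(self):
        rec = pd.DataFrame({"family": ["L1HS"] * 111 + ["L1PA2"] * 35})
        rep = l1loci.summarize_uid_annotation(rec).set_index("category")
        assert rep.loc["L1HS", "percent"] == 76.03
        assert rep.loc["L1PA2", "percent"] == 23.97

    def test_context_percentages(self):
        rec = pd.DataFrame({"context": ["intergenic"] * 78 + ["intronic"] * 68})
        rep = l1loci.summarize_uid_annotation(rec).set_index("category")
        assert rep.loc["intronic", "percent"] == 46.58

    def test_single_family(self):
        rec = pd.DataFrame({"family": ["L1HS"] * 7})
        rep = l1loci.summarize_uid_annotation(rec)
        assert rep.percent.iloc[0] == 100.00

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            l1loci.summarize_uid_annotation(pd.DataFrame(columns=["family"]))


class TestFilter:
    def test_uid_keep_rule_worked_example(self):
        counts = pd.DataFrame(
            [[4, 4, 4, 4, 4, 4, 0, 0],
             [4, 4, 4, 4, 4, 0, 0, 0],
             [0] * 8],
            index=["keep", "drop", "zero"],
        )
        kept, dropped = l1loci.filter_low_counts(counts, min_reads=3,
                                                 min_individuals=6, strict=True)
        assert list(kept.index) == ["keep"]
        assert sorted(dropped) == ["drop", "zero"]

    def test_zero_min_individuals_is_identity(self):
        counts = pd.DataFrame([[0, 0], [1, 2]])
        kept, dropped = l1loci.filter_low_counts(counts, 3, 0)
        assert len(kept) == 2 and dropped == []

    def test_gene_rule_inclusive_threshold(self):
        counts = pd.DataFrame([[10, 10], [9, 9]], index=["a", "b"])
        kept, _ = l1loci.filter_low_counts(counts, min_reads=10,
                                           min_individuals=2, strict=False)
        assert list(kept.index) == ["a"]

    @pytest.mark.parametrize("seed", range(25))
    def test_brute_force_oracle(self, seed):
        r = np.random.default_rng(seed)
        counts = pd.DataFrame(r.poisson(4, size=(12, 9)))
        thr, k = int(r.integers(1, 8)), int(r.integers(0, 10))
        strict = bool(r.integers(2))
        kept, dropped = l1loci.filter_low_counts(counts, thr, k, strict)
        for idx in counts.index:
            row = counts.loc[idx]
            n_hit = sum((v > thr if strict else v >= thr) for v in row)
            assert (idx in kept.index) == (n_hit >= k)


class TestNormalization:
    def test_identical_columns_equal_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        f = l1loci.size_factors(counts)
        assert f["a"] == pytest.approx(f["b"])

    def test_doubled_column_closed_form(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        f = l1loci.size_factors(counts)
        assert f["a"] == pytest.approx(1 / np.sqrt(2))
        assert f["b"] == pytest.approx(np.sqrt(2))
        assert f["b"] / f["a"] == pytest.approx(2.0)

    def test_library_scaling_property(self, rng):
        """Tripling one library triples its size factor relative to the
        others (the geometric-mean reference renormalizes all factors by a
        common 3^(1/n) scalar, so only factor ratios are identifiable)."""
        base = pd.DataFrame(rng.poisson(50, size=(30, 4)) + 1,
                            columns=list("abcd"))
        f0 = l1loci.size_factors(base)
        scaled = base.copy()
        scaled["c"] = base["c"] * 3
        f1 = l1loci.size_factors(scaled)
        assert f1["c"] / f1["a"] == pytest.approx(3.0 * f0["c"] / f0["a"])
        assert f1["b"] / f1["a"] == pytest.approx(f0["b"] / f0["a"])
        assert f1["d"] / f1["a"] == pytest.approx(f0["d"] / f0["a"])

    def test_no_zero_free_rows_rejected(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="zero-free"):
            l1loci.size_factors(counts)

    def test_factors_from_full_matrix_applied_to_submatrix(self, rng):
        full = pd.DataFrame(rng.poisson(100, size=(50, 4)) + 1, columns=list("abcd"))
        sub = full.iloc[:5]
        f, norm = l1loci.size_factors_and_normalize(sub, full_matrix=full)
        pd.testing.assert_series_equal(f, l1loci.size_factors(full), check_names=False)
        pd.testing.assert_frame_equal(norm, sub / f)

    def test_normalization_removes_programmed_size_effects(self):
        design = CountDesign(
            n_young=4, n_aged=4, baseline_mean=500.0, dispersion=0.05,
            library_size_factors=np.array([0.5, 1, 2, 1, 0.5, 1, 2, 1]),
            seed=9,
        )
        counts, meta = generate_count_matrix([f"U{i}" for i in range(60)], design)
        f, norm = l1loci.size_factors_and_normalize(counts)
        # factors recover the programmed ratios (up to a common scale)
        prog = np.array([0.5, 1, 2, 1, 0.5, 1, 2, 1])
        ratio = f.to_numpy() / prog
        assert ratio.std() / ratio.mean() < 0.05
        # normalized per-row means agree across samples within NB noise
        cv = (norm.std(axis=1) / norm.mean(axis=1)).median()
        assert cv < 0.4


class TestDifferential:
    def test_fold_change_recovered(self):
        """A programmed 2-fold UID in an 8-locus panel is detected in most
        seeds and its log2 fold change is unbiased on average.  Size factors
        come from a 200-row background matrix, as locus panels are too small
        to anchor median-of-ratios themselves."""
        fold = np.ones(208)
        fold[0] = 2.0
        detections, fcs = [], []
        for seed in range(20):
            design = CountDesign(baseline_mean=100.0, dispersion=0.1,
                                 fold_change=fold, seed=3000 + seed)
            counts, meta = generate_count_matrix(
                [f"U{i}" for i in range(8)] + [f"G{i}" for i in range(200)],
                design,
            )
            panel = counts.iloc[:8]
            background = counts.iloc[8:]
            _, norm = l1loci.size_factors_and_normalize(
                panel, full_matrix=background
            )
            table = l1loci.differential_uid_expression(norm, meta["group"])
            detections.append(table.loc["U0", "padj"] < 0.05)
            fcs.append(table.loc["U0", "log2fc"])
        assert np.mean(detections) >= 0.7
        assert np.mean(fcs) == pytest.approx(1.0, abs=0.1)

    def test_constant_row_p_one(self):
        norm = pd.DataFrame(np.vstack([np.full(8, 5.0),
                                       np.arange(8, dtype=float)]),
                            index=["const", "var"],
                            columns=[f"s{i}" for i in range(8)])
        groups = pd.Series(["young"] * 4 + ["aged"] * 4,
                           index=norm.columns)
        with pytest.warns(UserWarning, match="constant"):
            table = l1loci.differential_uid_expression(norm, groups)
        assert table.loc["const", "p"] == 1.0

    def test_single_sample_group_rejected(self):
        norm = pd.DataFrame(np.ones((3, 3)), columns=list("abc"))
        groups = pd.Series(["young", "aged", "aged"], index=list("abc"))
        with pytest.raises(ValueError):
            l1loci.differential_uid_expression(norm, groups)


class TestGlobalTrend:
    def _norm(self, shift=0.0, n_uids=20, seed=0):
        rng = np.random.default_rng(seed)
        young = rng.poisson(100, size=(n_uids, 6)).astype(float)
        aged = young[:, :5].repeat(7, axis=1) + shift
        norm = pd.DataFrame(np.hstack([young, aged]))
        norm.columns = [f"s{i}" for i in range(norm.shape[1])]
        groups = pd.Series(["young"] * 6 + ["aged"] * 35, index=norm.columns)
        return norm, groups

    def test_uniform_positive_shift_minimal_p(self):
        norm, groups = self._norm(shift=5.0, n_uids=10)
        res = l1loci.global_uid_trend(norm, groups)
        # every per-UID mean difference positive -> two-sided exact minimum
        assert res["paired_means"].exact
        assert res["paired_means"].p == pytest.approx(2 * 0.5 ** 10, rel=1e-9)

    def test_too_few_uids_rejected(self):
        norm, groups = self._norm()
        with pytest.raises(ValueError):
            l1loci.global_uid_trend(norm.iloc[:4], groups)

    def test_sums_invariant_to_uid_permutation(self, rng):
        norm, groups = self._norm(shift=1.0)
        shuffled = norm.sample(frac=1.0, random_state=1)
        a = l1loci.global_uid_trend(norm, groups)["per_sample_sums"]
        b = l1loci.global_uid_trend(shuffled, groups)["per_sample_sums"]
        assert a.p == pytest.approx(b.p)


class TestRegulatorCorrelation:
    def _expr(self):
        x = np.arange(10, dtype=float) + 4.1
        data = {"L1HS": x, "REG_UP": x * 2 + 1, "REG_DOWN": x[::-1].copy(),
                "LOW": np.full(10, 0.5)}
        return pd.DataFrame(data).T.set_axis([f"s{i}" for i in range(10)], axis=1)

    def test_monotone_pairs(self):
        rho, p, excluded = l1loci.regulator_correlation(
            self._expr(), ["L1HS"], ["REG_UP", "REG_DOWN"]
        )
        assert rho.loc["L1HS", "REG_UP"] == pytest.approx(1.0)
        assert rho.loc["L1HS", "REG_DOWN"] == pytest.approx(-1.0)

    def test_hand_computed_rho(self):
        # rank differences (-1, 1, -1, 1, 0): rho = 1 - 6*4/(5*24) = 0.8
        expr = pd.DataFrame(
            {"te": [1, 2, 3, 4, 5], "reg": [2, 1, 4, 3, 5]}
        ).T.set_axis([f"s{i}" for i in range(5)], axis=1) + 10
        rho, _, _ = l1loci.regulator_correlation(expr, ["te"], ["reg"],
                                                 min_individuals=4)
        assert rho.loc["te", "reg"] == pytest.approx(0.8)

    def test_threshold_exclusion_reported(self):
        rho, p, excluded = l1loci.regulator_correlation(
            self._expr(), ["L1HS"], ["REG_UP", "LOW"]
        )
        assert excluded == ["LOW"]
        assert "LOW" not in rho.columns


class TestGrouping:
    def test_age_65_is_young(self):
        g = l1loci.group_from_age([38, 65, 66, 97])
        assert list(g) == ["young", "young", "aged", "aged"]
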