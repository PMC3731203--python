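import numpy as np
import pandas as pd
import pytest

import ribocodon as rc
from ribocodon.expression import ExpressionConfig

from conftest import make_orf
from oracles import hypergeom_upper_tail_enum


def unsplit_track(rows, orfs):
    return rc.pool_and_frameshift(pd.DataFrame(rows), orfs, rc.fixed_calibration())


@pytest.fixture
def gene101():
    # 101 codons: stop codon first nt at L = 300
    return {"g": make_orf("g", "ATG" + "GCT" * 99 + "TAA")}


class TestOrfWindowCount:
    def test_default_window_arithmetic(self, gene101):
        track = unsplit_track([{"orf_id": "g", "fiveprime": 0, "length": 28, "count": 1}], gene101)
        reads, length = rc.orf_window_count(track, gene101["g"])
        assert length == 274  # [12, 286)

    def test_head_codon_read_excluded(self, gene101):
        track = unsplit_track([{"orf_id": "g", "fiveprime": 5, "length": 28, "count": 7}], gene101)
        reads, _ = rc.orf_window_count(track, gene101["g"])
        assert reads == 0

    def test_boundary_positions(self, gene101):
        rows = [
            {"orf_id": "g", "fiveprime": 12, "length": 28, "count": 1},   # first included
            {"orf_id": "g", "fiveprime": 11, "length": 28, "count": 1},   # just outside
            {"orf_id": "g", "fiveprime": 285, "length": 28, "count": 1},  # last included
            {"orf_id": "g", "fiveprime": 286, "length": 28, "count": 1},  # just outside
        ]
        reads, _ = rc.orf_window_count(unsplit_track(rows, gene101), gene101["g"])
        assert reads == 2

    def test_uniform_coverage_counts_equal_length(self, gene101):
        rows = [
            {"orf_id": "g", "fiveprime": p, "length": 28, "count": 1} for p in range(-20, 300)
        ]
        reads, length = rc.orf_window_count(unsplit_track(rows, gene101), gene101["g"])
        assert reads == length

    def test_ambiguous_reads_count_in_unsplit_pool(self, gene101):
        rows = [{"orf_id": "g", "fiveprime": 100, "length": rc.AMBIGUOUS, "count": 5}]
        reads, _ = rc.orf_window_count(unsplit_track(rows, gene101), gene101["g"])
        assert reads == 5

    def test_tiny_orf_flagged(self):
        tiny = {"t": make_orf("t", "ATG" + "GCT" * 7 + "TAA")}  # window empty
        track = unsplit_track([{"orf_id": "t", "fiveprime": 0, "length": 28, "count": 1}], tiny)
        reads, length = rc.orf_window_count(track, tiny["t"])
        assert reads is None and length == 0


class TestRpkm:
    def test_definitional_example(self, gene101):
        # ~1000 reads over the window; library total is what lands in windows
        rows = [{"orf_id": "g", "fiveprime": 100, "length": 28, "count": 1000}]
        table = rc.rpkm_table(unsplit_track(rows, gene101), gene101)
        r = table.iloc[0]
        # rpkm = 1000 / 0.274 kb / (1000/1e6 M reads)
        assert r["rpkm"] == pytest.approx(1000 / 0.274 / (1000 / 1e6))

    def test_scale_invariance(self, gene101):
        rows1 = [{"orf_id": "g", "fiveprime": 100, "length": 28, "count": 50}]
        rows2 = [{"orf_id": "g", "fiveprime": 100, "length": 28, "count": 100}]
        t1 = rc.rpkm_table(unsplit_track(rows1, gene101), gene101)
        t2 = rc.rpkm_table(unsplit_track(rows2, gene101), gene101)
        assert t1["rpkm"].iloc[0] == pytest.approx(t2["rpkm"].iloc[0])

    def test_three_gene_toy(self):
        orfs = {
            "a": make_orf("a", "ATG" + "GCT" * 340 + "TAA"),
            "b": make_orf("b", "ATG" + "GCT" * 340 + "TAA"),
            "c": make_orf("c", "ATG" + "GCT" * 681 + "TAA"),
        }
        # window lengths: a,b = 1026-26=1000... use explicit computation below
        rows = [
            {"orf_id": "a", "fiveprime": 100, "length": 28, "count": 100},
            {"orf_id": "b", "fiveprime": 100, "length": 28, "count": 300},
            {"orf_id": "c", "fiveprime": 100, "length": 28, "count": 600},
        ]
        table = rc.rpkm_table(unsplit_track(rows, orfs), orfs).set_index("orf_id")
        la = table.loc["a", "window_length_nt"]
        lc = table.loc["c", "window_length_nt"]
        total = 1000
        assert table.loc["a", "rpkm"] == pytest.approx(100 / (la / 1000) / (total / 1e6))
        assert table.loc["b", "rpkm"] == pytest.approx(3 * table.loc["a", "rpkm"])
        assert table.loc["c", "rpkm"] == pytest.approx(600 / (lc / 1000) / (total / 1e6))

    def test_zero_library_total_rejected(self, gene101):
        empty = unsplit_track([{"orf_id": "g", "fiveprime": 0, "length": 28, "count": 1}], gene101)
        empty.unsplit["g"][:] = 0
        with pytest.raises(ValueError):
            rc.rpkm_table(empty, gene101)


class TestFoldChangeTable:
    def _records(self, counts, gene_names=None):
        genes = gene_names or [f"g{i}" for i in range(len(counts))]
        return pd.DataFrame(
            {
                "orf_id": genes,
                "window_reads": counts,
                "window_length_nt": [300] * len(counts),
                "flagged": [False] * len(counts),
                "rpkm": [c / 0.3 for c in counts],
            }
        )

    def test_identical_samples_give_zero(self):
        r = self._records([100, 200, 300])
        out = rc.fold_change_table([r], [r])
        np.testing.assert_allclose(out["log2_fc"], 0.0)

    def test_swap_antisymmetry(self):
        a = self._records([100, 200, 300])
        b = self._records([150, 120, 300])
        fwd = rc.fold_change_table([a], [b]).set_index("orf_id")["log2_fc"]
        rev = rc.fold_change_table([b], [a]).set_index("orf_id")["log2_fc"]
        np.testing.assert_allclose(fwd, -rev)

    def test_replicate_mean(self):
        a1, a2 = self._records([200, 200]), self._records([400, 100])
        b = self._records([100, 200])
        out = rc.fold_change_table([a1, a2], [b, b]).set_index("orf_id")
        assert out.loc["g0", "log2_fc"] == pytest.approx((1 + 2) / 2)

    def test_low_expression_genes_dropped(self):
        a = self._records([100, 3])
        b = self._records([100, 100])
        out = rc.fold_change_table([a], [b], min_window_reads=10)
        assert list(out["orf_id"]) == ["g0"]
        assert out.attrs["n_dropped"] == 1

    def test_simulated_doubling_recovered(self):
        orfs = rc.build_synthetic_reference(6, (100, 100), seed=31)
        boosted = list(orfs)[0]
        ab_wt = {k: 1.0 for k in orfs}
        ab_mut = dict(ab_wt, **{boosted: 2.0})
        tables = {}
        for name, ab, seed in (("wt", ab_wt, 1), ("mut", ab_mut, 2)):
            reads = rc.simulate_rnaseq(orfs, ab, 120_000, seed=seed)
            track = unsplit_track(rc.reads_to_sized_counts(reads), orfs)
            tables[name] = rc.rpkm_table(track, orfs, sample_id=name)
        fc = rc.fold_change_table([tables["mut"]], [tables["wt"]]).set_index("orf_id")
        # fixed sequencing depth makes fold changes compositional: the boosted
        # gene's read share goes from 1/6 to 2/7 of the library
        expect_boost = np.log2((2 / 7) / (1 / 6))
        expect_other = np.log2((1 / 7) / (1 / 6))
        assert fc.loc[boosted, "log2_fc"] == pytest.approx(expect_boost, abs=0.1)
        others = fc.drop(index=boosted)["log2_fc"]
        np.testing.assert_allclose(others, expect_other, atol=0.1)


class TestEnrichment:
    def test_exact_full_overlap_probability(self):
        bg = set(range(10))
        res = rc.hypergeometric_overlap(set(range(5)), set(range(5)), bg)
        assert res.hypergeometric_p == pytest.approx(1 / 252)
        assert res.overlap_count == 5

    def test_zero_overlap_tail_is_one(self):
        bg = set(range(10))
        res = rc.hypergeometric_overlap({0, 1}, {5, 6}, bg)
        assert res.hypergeometric_p == pytest.approx(1.0)

    @pytest.mark.parametrize("n_bg,size_a,size_b", [(8, 3, 4), (10, 5, 3), (12, 6, 4)])
    def test_matches_enumeration_oracle(self, n_bg, size_a, size_b):
        rng = np.random.default_rng(n_bg)
        bg = set(range(n_bg))
        a = set(rng.choice(n_bg, size_a, replace=False).tolist())
        b = set(rng.choice(n_bg, size_b, replace=False).tolist())
        res = rc.hypergeometric_overlap(a, b, bg)
        expected = hypergeom_upper_tail_enum(bg, a, size_b, len(a & b))
        assert res.hypergeometric_p == pytest.approx(expected, abs=1e-12)

    def test_sets_outside_background_rejected(self):
        with pytest.raises(ValueError, match="zzz"):
            rc.hypergeometric_overlap({"zzz"}, {"a"}, {"a", "b"})


class TestTargetSetKS:
    def _fc(self, values):
        return pd.DataFrame({"orf_id": [f"g{i}" for i in range(len(values))],
                             "log2_fc": values})

    def test_target_set_covering_everything_rejected(self):
        fc = self._fc([0.1, 0.2])
        with pytest.raises(ValueError):
            rc.target_set_ks(fc, {"g0", "g1"})

    def test_shifted_targets_detected(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 0.3, 1000)
        vals[:100] += 0.5
        fc = self._fc(vals.tolist())
        res = rc.target_set_ks(fc, {f"g{i}" for i in range(100)})
        assert res["p_value"] < 1e-3
        assert res["median_fold_targets"] > res["median_fold_rest"]

    def test_null_targets_not_detected(self):
        rng = np.random.default_rng(4)
        fc = self._fc(rng.normal(0, 0.3, 1000).tolist())
        res = rc.target_set_ks(fc, {f"g{i}" for i in range(100)})
        assert res["p_value"] > 0.01


class TestRiboRnaCorrelation:
    def _fc(self, values):
        return pd.DataFrame({"orf_id": [f"g{i}" for i in range(len(values))],
                             "log2_fc": values})

    def test_identical_vectors_r_one(self):
        fc = self._fc([0.1, -0.5, 1.2, 0.3])
        assert rc.riboseq_rnaseq_correlation(fc, fc)["r"] == pytest.approx(1.0)

    def test_anticorrelated_r_minus_one(self):
        a = self._fc([0.1, -0.5, 1.2, 0.3])
        b = a.copy()
        b["log2_fc"] = -b["log2_fc"]
        assert rc.riboseq_rnaseq_correlation(a, b)["r"] == pytest.approx(-1.0)

    def test_constructed_correlation_recovered(self):
        # shared transcriptional component + independent noise, target r
        rng = np.random.default_rng(9)
        n = 2000
        shared = rng.normal(0, 1.0, n)
        ribo = shared + rng.normal(0, 0.75, n)
        rna = shared + rng.normal(0, 0.75, n)
        target_r = 1.0 / (1.0 + 0.75 ** 2)  # var(shared)/var(each)
        res = rc.riboseq_rnaseq_correlation(self._fc(ribo.tolist()), self._fc(rna.tolist()))
        assert res["r"] == pytest.approx(target_r, abs=0.05)
        assert res["n"] == n

    def test_too_few_genes_rejected(self):
        fc = self._fc([0.1, 0.2])
        with pytest.raises(ValueError):
            rc.riboseq_rnaseq_correlation(fc, fc)
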