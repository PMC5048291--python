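import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mutiface import (
    ProteinRecord,
    bh_fdr,
    binomial_pvalue,
    call_significant,
    compute_enrichment,
    estimate_background_rate,
    shuffle_bm1,
    shuffle_bm2,
)
from _oracles import bh_oracle, binomial_tail_oracle
from conftest import variants_frame


class TestShuffleBM1:
    def test_single_legal_target(self):
        prot = [ProteinRecord("P1", "AGCDEFGHIK")]
        v = variants_frame([("s1", "P1", 1, "A", "V")])
        out = shuffle_bm1(v, prot, seed=0)
        assert out.loc[0, "position"] == 1

    def test_position_stays_in_legal_set(self):
        prot = [ProteinRecord("P1", "AAGDEFGHIK")]
        v = variants_frame([("s1", "P1", 1, "A", "V")] * 50)
        out = shuffle_bm1(v, prot, seed=1)
        assert set(out["position"]) <= {1, 2}
        assert (out["ref_aa"] == "A").all() and (out["alt_aa"] == "V").all()

    def test_uniform_over_legal_positions(self):
        prot = [ProteinRecord("P1", "AAGDEFGHIK")]
        v = variants_frame([("s1", "P1", 1, "A", "V")] * 10_000)
        out = shuffle_bm1(v, prot, seed=2)
        freq1 = (out["position"] == 1).mean()
        assert abs(freq1 - 0.5) < 0.02

    def test_conserves_pair_multiset_and_sample_counts(self, cohort_factory, small_proteome):
        variants, _ = cohort_factory(n_samples=100, background_rate=3.0, seed=4)
        out = shuffle_bm1(variants, small_proteome, seed=5)
        key = ["protein_id", "ref_aa", "alt_aa"]
        before = variants[key].value_counts()
        after = out[key].value_counts()
        pd.testing.assert_series_equal(before, after)
        pd.testing.assert_series_equal(
            variants["sample_id"].value_counts(), out["sample_id"].value_counts()
        )

    def test_unplaceable_variant_dropped_with_warning(self, caplog):
        prot = [ProteinRecord("P1", "GGGDEFGHIK")]
        v = variants_frame([("s1", "P1", 1, "A", "V")])
        import logging

        with caplog.at_level(logging.WARNING):
            out = shuffle_bm1(v, prot, seed=0)
        assert len(out) == 0
        assert any("dropped" in r.message for r in caplog.records)


class TestShuffleBM2:
    def test_single_position_protein(self):
        prot = [ProteinRecord("P1", "M")]
        v = variants_frame([("s1", "P1", 1, "M", "V")] * 20)
        out = shuffle_bm2(v, prot, seed=0)
        assert (out["position"] == 1).all()
        assert (out["ref_aa"] == "M").all()

    def test_alt_never_equals_ref(self, cohort_factory, small_proteome):
        variants, _ = cohort_factory(n_samples=100, background_rate=3.0, seed=6)
        out = shuffle_bm2(variants, small_proteome, seed=7)
        assert (out["ref_aa"] != out["alt_aa"]).all()
        seqs = {p.protein_id: p.sequence for p in small_proteome}
        for row in out.itertuples():
            assert seqs[row.protein_id][row.position - 1] == row.ref_aa

    def test_alternate_uniform_over_19(self):
        prot = [ProteinRecord("P1", "M")]
        v = variants_frame([("s1", "P1", 1, "M", "V")] * 19_000)
        out = shuffle_bm2(v, prot, seed=0)
        counts = out["alt_aa"].value_counts()
        assert len(counts) == 19
        chi2 = (((counts - 1000) ** 2) / 1000).sum()
        assert stats.chi2.sf(chi2, df=18) > 0.01

    def test_conserves_per_protein_and_per_sample_counts(self, cohort_factory, small_proteome):
        variants, _ = cohort_factory(n_samples=100, background_rate=3.0, seed=9)
        out = shuffle_bm2(variants, small_proteome, seed=10)
        pd.testing.assert_series_equal(
            variants["protein_id"].value_counts(), out["protein_id"].value_counts()
        )
        pd.testing.assert_series_equal(
            variants["sample_id"].value_counts(), out["sample_id"].value_counts()
        )


class TestBackgroundRate:
    def test_stated_estimator(self):
        events = pd.DataFrame(
            {"interface_id": ["IF1"] * 3, "sample_id": ["s1", "s2", "s3"]}
        )
        pr = estimate_background_rate([events], 100, ["IF1"])
        assert pr["IF1"] == pytest.approx(4 / 101)

    def test_pseudocount_floor(self):
        empty = pd.DataFrame(columns=["interface_id", "sample_id"])
        pr = estimate_background_rate([empty], 100, ["IF1"])
        assert pr["IF1"] == pytest.approx(1 / 101)

    def test_clamped_to_one(self):
        events = pd.DataFrame(
            {"interface_id": ["IF1"] * 100, "sample_id": [f"s{i}" for i in range(100)]}
        )
        pr = estimate_background_rate([events], 100, ["IF1"])
        assert pr["IF1"] == 1.0

    def test_replicates_averaged(self):
        hit = pd.DataFrame({"interface_id": ["IF1"], "sample_id": ["s1"]})
        empty = pd.DataFrame(columns=["interface_id", "sample_id"])
        pr = estimate_background_rate([hit, empty], 10, ["IF1"])
        assert pr["IF1"] == pytest.approx((0.5 + 1) / 11)

    def test_zero_cohort_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            estimate_background_rate([pd.DataFrame()], 0, ["IF1"])


class TestBinomialPvalue:
    def test_zero_count_is_certain(self):
        assert binomial_pvalue(10, 0, 0.1) == 1.0

    def test_all_successes(self):
        assert binomial_pvalue(5, 5, 0.5) == pytest.approx(0.03125, abs=1e-12)

    def test_spot_value(self):
        assert binomial_pvalue(10, 2, 0.1) == pytest.approx(0.26390107, abs=1e-8)

    @pytest.mark.parametrize("n,c,pr", [(20, 7, 0.01), (35, 12, 0.1), (50, 25, 0.5)])
    def test_matches_summation_oracle(self, n, c, pr):
        assert binomial_pvalue(n, c, pr) == pytest.approx(
            binomial_tail_oracle(n, c, pr), abs=1e-10
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            binomial_pvalue(10, 11, 0.1)
        with pytest.raises(ValueError):
            binomial_pvalue(10, 2, 0.0)


class TestBHFDR:
    def test_single_p(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_worked_case(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_boundary_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0]), [1.0, 1.0])

    def test_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(bh_fdr(p), bh_oracle(list(p)), atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.random(200)
        np.testing.assert_allclose(
            bh_fdr(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )

    def test_permutation_equivariant(self):
        rng = np.random.default_rng(2)
        p = rng.random(30)
        perm = rng.permutation(30)
        np.testing.assert_allclose(bh_fdr(p)[perm], bh_fdr(p[perm]), atol=1e-15)

    def test_q_at_least_p_never_below(self):
        rng = np.random.default_rng(3)
        p = rng.random(100)
        assert (bh_fdr(p) >= p - 1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestCallSignificant:
    @pytest.fixture
    def results(self):
        return pd.DataFrame(
            {
                "interface_id": ["A", "B", "C"],
                "N": 100, "c": [25, 25, 15],
                "q_bm1": [0.005, 0.005, 0.005],
                "q_bm2": [0.005, 0.02, 0.005],
            }
        )

    def test_passes_all_thresholds(self, results):
        kept = call_significant(results)
        assert list(kept["interface_id"]) == ["A"]

    def test_fails_one_model_dropped(self, results):
        assert "B" not in set(call_significant(results)["interface_id"])

    def test_min_samples_relaxation(self, results):
        assert "C" not in set(call_significant(results, min_samples=20)["interface_id"])
        assert "C" in set(call_significant(results, min_samples=10)["interface_id"])

    def test_ranked_by_sample_count(self):
        res = pd.DataFrame(
            {
                "interface_id": ["A", "B"], "N": 100, "c": [25, 40],
                "q_bm1": [1e-4, 1e-4], "q_bm2": [1e-4, 1e-4],
            }
        )
        assert list(call_significant(res)["interface_id"]) == ["B", "A"]


def test_compute_enrichment_recovers_planted_driver(cohort_factory, small_proteome, small_catalog):
    iface = small_catalog[0].interface_id
    variants, samples = cohort_factory(
        n_samples=200, background_rate=1.0,
        planted=[(iface, 0.15, "disabling")], seed=12,
    )
    res = compute_enrichment(
        variants, small_proteome, small_catalog, n_samples=len(samples),
        seed=13, replicates=3,
    )
    row = res.set_index("interface_id").loc[iface]
    assert row["c"] >= 30
    assert bool(row["significant"])
    assert (res["q_bm1"] >= res["p_bm1"] - 1e-12).all()
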