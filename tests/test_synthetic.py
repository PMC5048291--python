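import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mutiface import (
    AMINO_ACIDS,
    ClinicalSpec,
    CohortSpec,
    generate_clinical,
    generate_cohort,
    generate_interface_catalog,
    generate_proteome,
    site_score,
)


class TestGenerateProteome:
    def test_parameters_echoed(self):
        prots = generate_proteome(5, 100, seed=1)
        assert len(prots) == 5
        assert all(p.length == 100 for p in prots)
        assert all(set(p.sequence) <= set(AMINO_ACIDS) for p in prots)

    def test_fixed_seed_determinism(self):
        a = generate_proteome(1, 10, seed=7)
        b = generate_proteome(1, 10, seed=7)
        assert a[0].sequence == b[0].sequence

    def test_letter_frequencies_match_composition(self):
        prots = generate_proteome(200, 300, seed=3)
        letters = "".join(p.sequence for p in prots)
        n = len(letters)
        p0 = 1 / 20
        sigma = np.sqrt(p0 * (1 - p0) / n)
        for aa in AMINO_ACIDS:
            freq = letters.count(aa) / n
            assert abs(freq - p0) < 3 * sigma + 1e-9, aa

    def test_length_range_sampled(self):
        prots = generate_proteome(50, (10, 20), seed=2)
        assert all(10 <= p.length <= 20 for p in prots)

    @pytest.mark.parametrize("n,length", [(0, 50), (3, 5)])
    def test_bad_sizes_rejected(self, n, length):
        with pytest.raises(ValueError):
            generate_proteome(n, length, seed=0)


class TestGenerateInterfaceCatalog:
    def test_degenerate_mix_all_protein(self, small_proteome):
        cat = generate_interface_catalog(
            small_proteome, 20, 4, partner_class_mix={"protein": 1.0}, seed=1
        )
        assert all(i.partner_class == "protein" for i in cat)

    def test_class_counts_within_multinomial_noise(self, small_proteome):
        mix = {"protein": 0.4, "chemical": 0.5, "dna_rna": 0.1}
        n = 500
        cat = generate_interface_catalog(small_proteome, n, 4, partner_class_mix=mix, seed=3)
        counts = pd.Series([i.partner_class for i in cat]).value_counts()
        for cls, frac in mix.items():
            sigma = np.sqrt(n * frac * (1 - frac))
            assert abs(counts.get(cls, 0) - n * frac) < 3.5 * sigma

    def test_positions_distinct_and_counted(self, small_proteome):
        cat = generate_interface_catalog(small_proteome, 10, 6, seed=4)
        for iface in cat:
            assert len(iface.positions) == 6
            assert len(set(iface.positions)) == 6

    def test_identity_range_and_confidence(self, small_proteome):
        cat = generate_interface_catalog(small_proteome, 30, 4, seed=5)
        assert all(70.0 <= i.template_identity <= 100.0 for i in cat)
        assert all(i.confidence == "high" for i in cat)

    def test_empty_proteome_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            generate_interface_catalog([], 5, 4, seed=0)

    def test_oversized_interface_rejected(self, small_proteome):
        with pytest.raises(ValueError, match="shortest"):
            generate_interface_catalog(small_proteome, 5, 1000, seed=0)


class TestGenerateCohort:
    def test_planted_fraction_exact(self, cohort_factory, small_catalog):
        iface = small_catalog[0]
        variants, samples = cohort_factory(
            n_samples=100, background_rate=0.0,
            planted=[(iface.interface_id, 0.3, "disabling")],
        )
        hit = variants[
            (variants["protein_id"] == iface.protein_id)
            & (variants["position"].isin(iface.positions))
        ]
        assert hit["sample_id"].nunique() == 30
        assert samples[f"planted_{iface.interface_id}"].sum() == 30

    def test_exclusivity_pair_disjoint(self, cohort_factory, small_catalog):
        a, b = small_catalog[0].interface_id, small_catalog[1].interface_id
        _, samples = cohort_factory(
            n_samples=100, background_rate=0.0,
            planted=[(a, 0.4, "disabling"), (b, 0.4, "enabling")],
            exclusive=[(a, b)],
        )
        both = samples[f"planted_{a}"] & samples[f"planted_{b}"]
        assert both.sum() == 0
        assert samples[f"planted_{a}"].sum() == 40
        assert samples[f"planted_{b}"].sum() == 40

    def test_planted_direction_forced(self, cohort_factory, small_catalog, random_table, small_proteome):
        iface = small_catalog[2]
        variants, _ = cohort_factory(
            n_samples=50, background_rate=0.0,
            planted=[(iface.interface_id, 0.5, "enabling")],
        )
        for row in variants.itertuples():
            types = iface.contacts[row.position]
            assert site_score(row.ref_aa, row.alt_aa, types, random_table) > 0

    def test_passenger_total_poisson(self, cohort_factory):
        variants, _ = cohort_factory(n_samples=1000, background_rate=2.0)
        expected, sigma = 2000, np.sqrt(2000)
        assert abs(len(variants) - expected) < 3 * sigma

    def test_passenger_ref_matches_sequence_and_alt_differs(self, cohort_factory, small_proteome):
        variants, _ = cohort_factory(n_samples=50, background_rate=2.0)
        seqs = {p.protein_id: p.sequence for p in small_proteome}
        for row in variants.itertuples():
            assert seqs[row.protein_id][row.position - 1] == row.ref_aa
            assert row.ref_aa != row.alt_aa

    def test_fixed_seed_byte_identical(self, cohort_factory):
        v1, s1 = cohort_factory(n_samples=30, background_rate=1.0, seed=9)
        v2, s2 = cohort_factory(n_samples=30, background_rate=1.0, seed=9)
        assert v1.to_csv() == v2.to_csv()
        assert s1.to_csv() == s2.to_csv()

    def test_infeasible_fraction_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            CohortSpec(
                n_samples=10, cancer_types=[("a", "b")], background_rate=1.0,
                planted_drivers=[("IF0001", 1.5, "disabling")],
            )

    def test_unknown_planted_interface_rejected(self, small_proteome, small_catalog, random_table):
        spec = CohortSpec(
            n_samples=10, cancer_types=[("a", "b")], background_rate=0.0,
            planted_drivers=[("NOPE", 0.5, "disabling")],
        )
        with pytest.raises(ValueError, match="not in catalog"):
            generate_cohort(small_proteome, small_catalog, spec, table=random_table)

    def test_overfull_exclusive_pair_rejected(self, cohort_factory, small_catalog):
        a, b = small_catalog[0].interface_id, small_catalog[1].interface_id
        with pytest.raises(ValueError, match="exclusive"):
            cohort_factory(
                n_samples=100, background_rate=0.0,
                planted=[(a, 0.7, "disabling"), (b, 0.7, "disabling")],
                exclusive=[(a, b)],
            )


class TestGenerateClinical:
    @pytest.fixture
    def samples(self):
        return pd.DataFrame(
            {
                "sample_id": [f"S{i:04d}" for i in range(400)],
                "primary_tissue": "lung",
                "histology": "adenocarcinoma",
            }
        )

    def test_no_censoring_all_events(self, samples):
        spec = ClinicalSpec(group_hazards={"g": 1.0}, censoring_fraction=0.0)
        groups = pd.Series("g", index=samples["sample_id"])
        clin = generate_clinical(samples, groups, spec, seed=1)
        assert clin["event_observed"].all()
        assert (clin["vital_status"] == "deceased").all()

    def test_censored_implies_alive(self, samples):
        spec = ClinicalSpec(group_hazards={"g": 1.0}, censoring_fraction=0.3)
        groups = pd.Series("g", index=samples["sample_id"])
        clin = generate_clinical(samples, groups, spec, seed=2)
        assert (clin["vital_status"] == "alive").sum() == round(0.3 * len(samples))
        assert (clin.loc[~clin["event_observed"], "vital_status"] == "alive").all()

    def test_unit_hazards_pool_to_one_exponential(self, samples):
        spec = ClinicalSpec(
            group_hazards={"a": 1.0, "b": 1.0}, baseline_hazard=0.02,
            censoring_fraction=0.0,
        )
        groups = pd.Series(
            np.where(np.arange(len(samples)) % 2 == 0, "a", "b"),
            index=samples["sample_id"],
        )
        clin = generate_clinical(samples, groups, spec, seed=3)
        ks = stats.kstest(clin["survival_time"], "expon", args=(0, 1 / 0.02))
        assert ks.pvalue > 0.01

    def test_unknown_group_rejected(self, samples):
        spec = ClinicalSpec(group_hazards={"g": 1.0})
        groups = pd.Series("other", index=samples["sample_id"])
        with pytest.raises(ValueError, match="unknown group"):
            generate_clinical(samples, groups, spec, seed=0)

    def test_missing_group_label_rejected(self, samples):
        spec = ClinicalSpec(group_hazards={"g": 1.0})
        groups = pd.Series("g", index=samples["sample_id"][:10])
        with pytest.raises(ValueError, match="without a group"):
            generate_clinical(samples, groups, spec, seed=0)

    @pytest.mark.parametrize("kwargs", [
        {"baseline_hazard": 0.0}, {"censoring_fraction": 1.5},
    ])
    def test_bad_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ClinicalSpec(group_hazards={"g": 1.0}, **kwargs)

    def test_negative_multiplier_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            ClinicalSpec(group_hazards={"g": -1.0})
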