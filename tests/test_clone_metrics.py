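import math

import numpy as np
import pandas as pd
import pytest

from clonetrace import clone_metrics as cm
from clonetrace.qc_normalize import ClonalProfile

from conftest import make_profile, random_profile


class TestEngraftment:
    def test_ten_percent(self):
        p = make_profile({f"B{i}": 1.0 for i in range(250)})
        out = cm.engraftment_summary(p, n_injected=2500)
        assert out == {"n_clones": 250, "efficiency": 0.1}

    def test_empty_profile(self):
        p = ClonalProfile(sample_id="S", frequencies=pd.Series(dtype=float))
        out = cm.engraftment_summary(p, n_injected=2500)
        assert out == {"n_clones": 0, "efficiency": 0.0}

    def test_full_engraftment(self):
        p = make_profile({f"B{i}": 1.0 for i in range(2500)})
        assert cm.engraftment_summary(p, 2500)["efficiency"] == 1.0

    def test_invalid_n_injected(self):
        p = make_profile({"B1": 1.0})
        with pytest.raises(ValueError):
            cm.engraftment_summary(p, 0)


class TestCumulativeDistribution:
    def test_two_equal_clones(self):
        curve = cm.cumulative_clone_distribution([make_profile({"A": 0.5, "B": 0.5})])
        assert curve["cumulative_fraction"].iloc[-1] == 1.0
        assert curve["frequency"].iloc[-1] == 0.5

    def test_two_point_case(self):
        curve = cm.cumulative_clone_distribution([make_profile({"A": 0.9, "B": 0.1})])
        assert curve["frequency"].tolist() == [0.1, 0.9]
        assert curve["cumulative_fraction"].tolist() == [0.5, 1.0]

    def test_pooling_identical_mice(self):
        p = make_profile({"A": 0.7, "B": 0.3})
        one = cm.cumulative_clone_distribution([p])
        two = cm.cumulative_clone_distribution([p, p])
        # same set of (frequency, cumulative) support points
        assert np.allclose(
            one["frequency"].unique(), two["frequency"].unique()
        )
        for f in one["frequency"]:
            c1 = one.loc[one["frequency"] <= f, "cumulative_fraction"].max()
            c2 = two.loc[two["frequency"] <= f, "cumulative_fraction"].max()
            assert c1 == pytest.approx(c2)

    def test_monotone(self, rng):
        curve = cm.cumulative_clone_distribution(
            [random_profile(rng, 50), random_profile(rng, 30)]
        )
        assert (np.diff(curve["cumulative_fraction"]) >= 0).all()
        assert curve["cumulative_fraction"].iloc[-1] == pytest.approx(1.0)

    def test_all_empty_rejected(self):
        empty = ClonalProfile(sample_id="S", frequencies=pd.Series(dtype=float))
        with pytest.raises(ValueError):
            cm.cumulative_clone_distribution([empty])


class TestDispersion:
    def make_pieces(self, presence: dict):
        """presence: barcode -> list of piece indices (of 8)."""
        pieces = []
        for k in range(8):
            freqs = {bc: 1.0 for bc, idxs in presence.items() if k in idxs}
            freqs.setdefault("_fill", 1.0)
            pieces.append(make_profile(freqs, sample_id=f"p{k}"))
        return pieces

    def test_half_of_pieces(self):
        pieces = self.make_pieces({"B1": [0, 1, 2, 3]})
        assert cm.dispersion(pieces)["B1"] == 0.5

    def test_all_pieces(self):
        pieces = self.make_pieces({"B1": list(range(8))})
        assert cm.dispersion(pieces)["B1"] == 1.0

    def test_absent_barcode_not_reported(self):
        pieces = self.make_pieces({"B1": [0]})
        assert "B2" not in cm.dispersion(pieces)

    def test_values_in_unit_interval(self, rng):
        pieces = [random_profile(rng, 12, sample_id=f"p{k}") for k in range(5)]
        d = cm.dispersion(pieces)
        assert ((d > 0) & (d <= 1)).all()

    def test_single_piece_rejected(self):
        with pytest.raises(ValueError):
            cm.dispersion([make_profile({"B1": 1.0})])


class TestBiomassRepresentation:
    def test_partial_overlap(self):
        tumor = make_profile({"B1": 0.5, "B2": 0.3, "B3": 0.2})
        distal = make_profile({"B1": 0.6, "B3": 0.4})
        assert cm.biomass_representation(tumor, distal) == pytest.approx(0.7)

    def test_complete_overlap_is_one(self, rng):
        tumor = random_profile(rng, 40)
        assert cm.biomass_representation(tumor, tumor) == pytest.approx(1.0)

    def test_disjoint_is_zero(self):
        tumor = make_profile({"B1": 1.0})
        distal = make_profile({"B2": 1.0})
        assert cm.biomass_representation(tumor, distal) == 0.0


class TestFoldChange:
    def test_threshold_rules(self):
        tumor = make_profile({"O": 0.001, "P": 0.1, "U": 0.2, "_f": 0.699})
        distal = make_profile({"O": 0.02, "P": 0.1, "U": 0.01, "_f": 0.87})
        classes, props = cm.fold_change_classify(tumor, distal)
        by_id = {c.barcode_id: c for c in classes}
        assert by_id["O"].label == "over" and by_id["O"].ratio == pytest.approx(20)
        assert by_id["U"].label == "under" and by_id["U"].ratio == pytest.approx(0.05)
        assert by_id["P"].label == "proportional"
        assert sum(props.values()) == pytest.approx(1.0)

    def test_identical_profiles_all_proportional(self, rng):
        p = random_profile(rng, 30)
        classes, props = cm.fold_change_classify(p, p)
        assert all(c.label == "proportional" for c in classes)
        assert props["proportional"] == 1.0

    def test_partition_invariant_to_order(self, rng):
        tumor = random_profile(rng, 50)
        distal = random_profile(rng, 50)
        _, props1 = cm.fold_change_classify(tumor, distal)
        shuffled = ClonalProfile(
            sample_id="x", frequencies=tumor.frequencies.sample(frac=1, random_state=1)
        )
        _, props2 = cm.fold_change_classify(shuffled, distal)
        assert props1 == props2

    def test_no_overlap_flagged(self):
        classes, props = cm.fold_change_classify(
            make_profile({"A": 1.0}), make_profile({"B": 1.0})
        )
        assert classes == []
        assert all(math.isnan(v) for v in props.values())

    def test_threshold_must_exceed_one(self):
        p = make_profile({"A": 1.0})
        with pytest.raises(ValueError):
            cm.fold_change_classify(p, p, threshold=1.0)


class TestDiversity:
    @pytest.mark.parametrize("k", [4, 10, 100, 10_000])
    def test_uniform_closed_forms(self, k):
        p = make_profile({f"B{i}": 1.0 for i in range(k)})
        out = cm.diversity_indices(p)
        assert out["shannon"] == pytest.approx(math.log(k), rel=1e-9)
        assert out["simpson"] == pytest.approx(1.0 / k, rel=1e-9)

    def test_single_clone(self):
        out = cm.diversity_indices(make_profile({"B1": 1.0}))
        assert out["shannon"] == 0.0
        assert out["simpson"] == 1.0

    def test_bounds(self, rng):
        for _ in range(20):
            p = random_profile(rng, int(rng.integers(2, 50)))
            out = cm.diversity_indices(p)
            k = p.n_barcodes_detected
            assert 0 <= out["shannon"] <= math.log(k) + 1e-12
            assert 1.0 / k - 1e-12 <= out["simpson"] <= 1.0

    def test_simpson_complement_toggle(self, rng):
        p = random_profile(rng, 10)
        plain = cm.diversity_indices(p)["simpson"]
        comp = cm.diversity_indices(p, simpson_complement=True)["simpson"]
        assert plain + comp == pytest.approx(1.0)


class TestSharedRegression:
    def test_identity(self, rng):
        p = random_profile(rng, 20)
        comp = cm.shared_barcode_regression(p, p)
        assert comp.slope == pytest.approx(1.0)
        assert comp.adj_r_squared == pytest.approx(1.0)

    def test_scaling_gives_slope_one(self, rng):
        a = random_profile(rng, 20)
        scaled = a.frequencies * 3.7
        b = ClonalProfile(sample_id="b", frequencies=scaled / scaled.sum())
        comp = cm.shared_barcode_regression(a, b)
        assert comp.slope == pytest.approx(1.0, abs=1e-9)

    def test_known_slope_recovery(self):
        # oracle: log10 b = 0.8 * log10 a + N(0, 0.1); OLS must recover
        # the slope within 3 standard errors
        rng = np.random.default_rng(2024)
        log_a = rng.uniform(-6, -1, 100)
        a_w = 10.0**log_a
        b_w = 10.0 ** (0.8 * log_a + rng.normal(0, 0.1, 100))
        a = ClonalProfile(
            sample_id="a", frequencies=pd.Series(a_w / a_w.sum(), index=[f"B{i}" for i in range(100)])
        )
        b = ClonalProfile(
            sample_id="b", frequencies=pd.Series(b_w / b_w.sum(), index=[f"B{i}" for i in range(100)])
        )
        comp = cm.shared_barcode_regression(a, b)
        resid_sd = 0.1
        se = resid_sd / (np.std(log_a) * np.sqrt(100))
        assert abs(comp.slope - 0.8) < 3 * se
        assert comp.f_pvalue < 1e-10

    def test_too_few_shared(self):
        a = make_profile({"A": 0.5, "B": 0.3, "X": 0.2})
        b = make_profile({"A": 0.5, "B": 0.3, "Y": 0.2})
        comp = cm.shared_barcode_regression(a, b)
        assert not comp.has_regression
        assert comp.shared_barcodes == {"A", "B"}
        assert comp.a_only == {"X"} and comp.b_only == {"Y"}


class TestOrganOverlap:
    def make_mouse(self):
        return {
            "tumor": make_profile({"B1": 0.4, "B2": 0.3, "B3": 0.3}),
            "lung": make_profile({"B2": 0.5, "B4": 0.5}),
            "blood": make_profile({"B2": 0.6, "B3": 0.4}),
        }

    def test_counts_and_histogram(self):
        counts, hist, non_resident = cm.organ_overlap_counts(self.make_mouse(), "tumor")
        assert counts["B1"] == 0
        assert counts["B2"] == 2
        assert counts["B3"] == 1
        assert hist == {0: 1, 1: 1, 2: 1}
        assert non_resident == {"B4"}

    def test_missing_tumor_rejected(self):
        with pytest.raises(ValueError):
            cm.organ_overlap_counts({"lung": make_profile({"A": 1.0})}, "tumor")


class TestGroupComparisons:
    def test_welch_identical_groups(self):
        g = [1.0, 2.0, 3.0, 4.0]
        out = cm.group_comparison_tests(g, g, mode="welch_log")
        assert out["statistic"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(1.0)

    def test_welch_rejects_nonpositive(self):
        with pytest.raises(ValueError, match="positive"):
            cm.group_comparison_tests([1.0, -1.0], [1.0, 2.0], mode="welch_log")

    def test_welch_separated_groups(self):
        rng = np.random.default_rng(5)
        a = np.exp(rng.normal(0, 1, 20))
        b = np.exp(rng.normal(5, 1, 20))
        out = cm.group_comparison_tests(a, b, mode="welch_log")
        assert out["p"] < 1e-3

    def test_ks_identical_distributions(self):
        v = list(np.linspace(0.1, 1, 50))
        out = cm.group_comparison_tests([v, v], [v, v], mode="ks_pairwise_mean")
        assert all(p == pytest.approx(1.0) for p in out["pairwise_p"])

    def test_wilcoxon(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 20)
        b = rng.normal(3, 1, 20)
        out = cm.group_comparison_tests(a, b, mode="wilcoxon")
        assert out["p"] < 1e-3

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            cm.group_comparison_tests([1, 2], [3, 4], mode="bogus")


class TestTumorCellEstimate:
    def test_volume_formula(self):
        out = cm.estimate_tumor_cells(5, 12)
        assert out["volume_mm3"] == pytest.approx(150.0)

    def test_cells_from_mass(self):
        out = cm.estimate_tumor_cells(5, 12, mass_mg=600)
        assert out["cell_estimate"] == pytest.approx(6e8)

    def test_symmetric_diameters(self):
        out = cm.estimate_tumor_cells(4, 4)
        assert out["volume_mm3"] == pytest.approx(4**3 / 2)

    def test_max_less_than_min_rejected(self):
        with pytest.raises(ValueError):
            cm.estimate_tumor_cells(10, 5)


class TestSingleIntegration:
    def test_band_at_stated_transduction(self):
        # 10-20% transduction should give 90-95% single-integration cells
        lo = cm.single_integration_fraction(0.20)
        hi = cm.single_integration_fraction(0.10)
        assert 0.89 < lo < hi < 0.95

    def test_closed_form(self):
        f = 0.15
        lam = -math.log(1 - f)
        expected = lam * math.exp(-lam) / (1 - math.exp(-lam))
        assert cm.single_integration_fraction(f) == pytest.approx(expected, rel=1e-12)

    def test_domain(self):
        for bad in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                cm.single_integration_fraction(bad)
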