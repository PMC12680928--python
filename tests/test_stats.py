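"""Group-statistics tests: Mann-Whitney, Grubbs, percent change, Hill fit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from astromorph import grubbs_exclude, hill, hill_fit, mann_whitney_u, percent_change
from astromorph.datasets import MICRODIALYSIS_MEANS_MM
from astromorph.errors import AstromorphError, ConfigurationError
from astromorph.stats import aggregate_per_animal, holm_adjust, swelling_report

from helpers import mann_whitney_enumeration


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 extreme labelings out of C(6,3) = 20

    def test_identical_samples_near_one(self):
        x = np.arange(10.0)
        _, p = mann_whitney_u(x, x)  # ties force the approximation path
        assert p >= 0.99

    def test_exact_path_equals_enumeration(self, rng):
        for _ in range(25):
            n1, n2 = rng.integers(2, 7, 2)
            while True:
                x = rng.normal(size=n1)
                y = rng.normal(size=n2)
                if np.unique(np.concatenate([x, y])).size == n1 + n2:
                    break
            u_impl, p_impl = mann_whitney_u(x, y)
            u_ref, p_ref = mann_whitney_enumeration(x, y)
            assert u_impl == pytest.approx(u_ref)
            assert p_impl == pytest.approx(p_ref, abs=1e-12)

    def test_approximation_close_to_exact_at_n10(self, rng):
        from scipy import stats as sps

        for _ in range(10):
            x = rng.normal(size=10)
            y = rng.normal(0.5, 1.0, size=10)
            pe = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            pa = sps.mannwhitneyu(x, y, alternative="two-sided",
                                  method="asymptotic", use_continuity=True).pvalue
            assert abs(pe - pa) <= 0.01

    def test_empty_sample_rejected(self):
        with pytest.raises(ConfigurationError):
            mann_whitney_u([], [1, 2])


class TestGrubbs:
    def test_gross_outlier_removed(self):
        retained, excluded = grubbs_exclude([1.0, 1.1, 0.9, 50.0])
        assert excluded == [50.0]
        assert sorted(retained) == [0.9, 1.0, 1.1]

    def test_clean_sample_untouched(self):
        retained, excluded = grubbs_exclude([1.0, 2.0, 3.0])
        assert excluded == []
        assert len(retained) == 3

    def test_constant_sample_noop_with_warning(self):
        with pytest.warns(UserWarning):
            retained, excluded = grubbs_exclude([2.0, 2.0, 2.0, 2.0])
        assert excluded == []

    def test_too_small_sample_noop_with_warning(self):
        with pytest.warns(UserWarning):
            retained, excluded = grubbs_exclude([1.0, 9.0])
        assert list(retained) == [1.0, 9.0]

    def test_permutation_invariant_and_idempotent(self, rng):
        data = [1.0, 1.2, 0.8, 1.1, 30.0, 0.9]
        r1, e1 = grubbs_exclude(data)
        perm = list(rng.permutation(data))
        r2, e2 = grubbs_exclude(perm)
        assert sorted(r1) == sorted(r2) and sorted(e1) == sorted(e2)
        r3, e3 = grubbs_exclude(r1)
        assert e3 == [] and sorted(r3) == sorted(r1)


class TestPercentChange:
    @pytest.mark.parametrize(
        "key,expected_rounded",
        [("glutamine", 73), ("glutamine_post_k", 79), ("alanine_post_k", 42)],
    )
    def test_published_group_means(self, key, expected_rounded):
        means = MICRODIALYSIS_MEANS_MM[key]
        assert round(percent_change(means["ctr"], means["cko"])) == expected_rounded

    def test_identity(self):
        assert percent_change(3.7, 3.7) == 0.0

    @settings(deadline=None, derandomize=True)
    @given(m=st.floats(0.1, 1e3), p=st.floats(-90, 500))
    def test_round_trip_recovers_percent(self, m, p):
        assert percent_change(m, m * (1 + p / 100)) == pytest.approx(p, abs=1e-8)

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ConfigurationError):
            percent_change(0.0, 1.0)


class TestAggregation:
    def test_animal_mean(self):
        df = pd.DataFrame({"group": ["CTR"] * 2, "animal_id": ["a1"] * 2,
                           "volume_um3": [2.0, 4.0]})
        out = aggregate_per_animal(df)
        assert out.volume_um3.tolist() == [3.0]

    def test_row_count_per_animal(self):
        rows = []
        for g in ("CTR", "cKO"):
            for a in range(4):
                for c in range(3):
                    rows.append({"group": g, "animal_id": f"{g}{a}",
                                 "volume_um3": float(c)})
        out = aggregate_per_animal(pd.DataFrame(rows))
        assert len(out) == 8


class TestHillFit:
    def test_noiseless_parameter_recovery(self):
        steps = np.arange(-200, 1001, 20, dtype=float)
        resp = np.where(steps > 0, hill(np.maximum(steps, 1e-9), 20.0, 2.0, 300.0), 0.0)
        fit = hill_fit(steps, resp)
        assert fit.a == pytest.approx(20.0, rel=0.01)
        assert fit.b == pytest.approx(2.0, rel=0.01)
        assert fit.c == pytest.approx(300.0, rel=0.01)

    def test_half_max_identity(self):
        for b in (0.5, 1.0, 3.7):
            assert hill(300.0, 20.0, b, 300.0) == pytest.approx(10.0)

    def test_current_at_max_takes_first_argmax(self):
        steps = np.array([100, 200, 300, 400, 500, 600, 700], dtype=float)
        resp = np.array([0, 0, 1, 3, 5, 5, 5], dtype=float)
        fit = hill_fit(steps, resp)
        assert fit.current_at_max_pa == 500.0

    def test_all_zero_responses_rejected(self):
        steps = np.arange(20, 201, 20, dtype=float)
        with pytest.raises(AstromorphError, match="no spiking"):
            hill_fit(steps, np.zeros_like(steps))

    def test_noisy_steepness_recovery_median_within_10pct(self, rng):
        """Parameter recovery across 100 noisy curves (noise sd = 0.05 a)."""
        steps = np.arange(20, 1001, 20, dtype=float)
        errors = []
        for _ in range(100):
            a, b, c = 20.0, rng.uniform(1.5, 3.0), rng.uniform(200, 500)
            resp = np.maximum(hill(steps, a, b, c) + rng.normal(0, 0.05 * a, steps.size), 0)
            fit = hill_fit(steps, resp)
            errors.append(abs(fit.b - b) / b)
        assert np.median(errors) <= 0.10


class TestSwellingReport:
    def make_tables(self, rng, shift=0.0):
        ctr = pd.DataFrame({
            "group": "CTR",
            "animal_id": [f"c{i % 5}" for i in range(15)],
            "volume_um3": rng.normal(1000, 80, 15),
            "area_um2": rng.normal(2000, 150, 15),
            "soma_um3": rng.normal(500, 40, 15),
        })
        cko = pd.DataFrame({
            "group": "cKO",
            "animal_id": [f"k{i % 5}" for i in range(15)],
            "volume_um3": rng.normal(1000 * (1 + shift), 80, 15),
            "area_um2": rng.normal(2000 * (1 + shift), 150, 15),
            "soma_um3": rng.normal(500, 40, 15),
        })
        return ctr, cko

    def test_percent_change_round_trips_through_report(self, rng):
        ctr, cko = self.make_tables(rng, shift=0.3)
        report = swelling_report(ctr, cko)
        entry = report["metrics"]["volume_um3"]
        assert entry["percent_change"] == pytest.approx(
            percent_change(ctr.volume_um3.mean(), cko.volume_um3.mean()))
        assert entry["percent_change_rounded"] == round(entry["percent_change"])
        assert "p_animal" in entry

    def test_missing_group_rejected(self, rng):
        ctr, _ = self.make_tables(rng)
        with pytest.raises(ConfigurationError):
            swelling_report(ctr, pd.DataFrame())

    def test_identical_groups_rarely_flag_significance(self):
        """Type-I control: with identically distributed groups, no metric is
        flagged significant in >= 95% of seeded replicates."""
        from astromorph.synthgen import SimulationConfig, sample_morphometry_table

        cfg = SimulationConfig()
        rng = np.random.default_rng(7)
        clean = 0
        n_rep = 100
        for _ in range(n_rep):
            a = sample_morphometry_table(cfg, 15, 5, "CTR", rng)
            b = sample_morphometry_table(cfg, 15, 5, "cKO", rng)
            report = swelling_report(a, b)
            if not any(m["significant"] for m in report["metrics"].values()):
                clean += 1
        assert clean / n_rep >= 0.95

    def test_holm_adjustment_caps_and_orders(self):
        adj = holm_adjust([0.01, 0.04, 0.03])
        assert adj[0] == pytest.approx(0.03)
        assert np.all(adj <= 1.0)
        assert np.all(adj >= [0.01, 0.04, 0.03])
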