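"""DMS structure scoring: normalization, subtraction, Gini and background."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foldscreen.dms_structure import (
    DmsProfile,
    StructureScore,
    background_comparison,
    gini,
    normalize_profile,
    score_profile,
    subtract_denatured,
    vivo_vitro_agreement,
)
from foldscreen.synthetic_data import simulate_dms


def gini_bruteforce(x):
    """Independent double-loop oracle: G = sum_ij |xi-xj| / (2 n^2 mean)."""
    x = np.asarray(x, float)
    n = len(x)
    total = sum(abs(a - b) for a in x for b in x)
    return total / (2 * n * n * x.mean())


class TestNormalize:
    def test_scales_to_unit_maximum(self):
        assert np.allclose(normalize_profile(np.array([2.0, 4.0])), [0.5, 1.0])

    def test_already_normalized_unchanged(self):
        vec = np.array([0.5, 1.0, 0.25])
        assert np.allclose(normalize_profile(vec), vec)

    def test_all_zero_flagged_and_unchanged(self):
        with pytest.warns(UserWarning, match="unreactive"):
            out = normalize_profile(np.zeros(4))
        assert np.array_equal(out, np.zeros(4))

    @given(st.lists(st.floats(0, 100), min_size=1, max_size=50))
    @settings(max_examples=100)
    def test_idempotent(self, vals):
        vec = np.asarray(vals)
        if vec.max() == 0:
            return
        once = normalize_profile(vec)
        assert np.allclose(normalize_profile(once), once)


class TestSubtractDenatured:
    def test_clips_negative_residuals_at_zero(self):
        out = subtract_denatured(np.array([0.5, 1.0]), np.array([0.6, 0.2]))
        assert np.allclose(out, [0.0, 0.8])

    def test_zero_vector_is_identity(self):
        x = np.array([0.3, 0.7, 1.0])
        assert np.allclose(subtract_denatured(x, np.zeros(3)), x)

    def test_self_subtraction_is_zero(self):
        x = np.array([0.3, 0.7, 1.0])
        assert np.allclose(subtract_denatured(x, x), 0.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            subtract_denatured(np.ones(3), np.ones(4))

    def test_output_in_unit_interval_for_normalized_inputs(self):
        rng = np.random.default_rng(0)
        a = normalize_profile(rng.uniform(0, 5, 100))
        b = normalize_profile(rng.uniform(0, 5, 100))
        out = subtract_denatured(a, b)
        assert out.min() >= 0 and out.max() <= 1


class TestAgreement:
    def test_monotone_pair_is_one(self):
        assert vivo_vitro_agreement(np.arange(5.0), np.arange(5.0) ** 2) == pytest.approx(1.0)

    def test_reversed_order_is_minus_one(self):
        assert vivo_vitro_agreement(np.arange(5.0), -np.arange(5.0)) == pytest.approx(-1.0)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(7)
        rho = vivo_vitro_agreement(rng.normal(size=1000), rng.normal(size=1000))
        assert abs(rho) < 0.1

    def test_constant_vector_reported_missing(self):
        assert np.isnan(vivo_vitro_agreement(np.ones(5), np.arange(5.0)))


class TestGini:
    @pytest.mark.parametrize(
        "vec,expected",
        [([1, 1, 1, 1], 0.0), ([0, 0, 0, 1], 0.75), ([1, 2, 3], 2 / 9)],
    )
    def test_oracle_computed_values(self, vec, expected):
        assert gini(vec) == pytest.approx(expected, abs=1e-12)

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            x = rng.uniform(0, 10, rng.integers(2, 200))
            assert gini(x) == pytest.approx(gini_bruteforce(x), abs=1e-12)

    @given(
        st.lists(st.floats(0.01, 50), min_size=2, max_size=40),
        st.floats(0.1, 100),
    )
    @settings(max_examples=100)
    def test_scale_invariant(self, vals, c):
        x = np.asarray(vals)
        assert gini(c * x) == pytest.approx(gini(x), abs=1e-9)

    def test_bounds(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            x = rng.uniform(0, 1, 20)
            g = gini(x)
            assert 0 <= g <= 19 / 20

    def test_zero_mean_reported_missing(self):
        assert np.isnan(gini(np.zeros(5)))


class TestPipeline:
    def test_structured_gini_exceeds_unstructured_every_seed(self):
        for seed in range(100):
            s = score_profile(simulate_dms(80, structured=True, seed=seed), subtract=False)
            u = score_profile(simulate_dms(80, structured=False, seed=seed), subtract=False)
            assert s.gini_vivo > u.gini_vivo

    def test_vivo_vitro_agreement_high_for_shared_structure(self):
        rhos = [
            score_profile(simulate_dms(100, structured=True, seed=s), subtract=False).rho_vivo_vitro
            for s in range(20)
        ]
        assert np.median(rhos) > 0.7


class TestBackgroundComparison:
    def _setup(self):
        rng = np.random.default_rng(5)
        track = rng.uniform(0.4, 0.6, 5000)  # even background signal
        intervals = {
            "intergenic": [("chr", 0, 1200)],
            "5UTR": [("chr", 1200, 2400)],
            "3UTR": [("chr", 2400, 3600)],
            "CDS": [("chr", 3600, 5000)],
        }
        return {"chr": track}, intervals

    def test_one_hot_folds_beat_uniform_background(self):
        signal, intervals = self._setup()
        # one-hot profiles: maximally unequal, Gini (n-1)/n
        folds = [
            StructureScore(f"f{i}", 1.0, gini([0] * 49 + [1]), 0.9) for i in range(10)
        ]
        table = background_comparison(folds, [50] * 10, signal, intervals, n_random=40, seed=1)
        fold_med = table.loc[table.group == "fold", "gini"].median()
        bg_med = table.loc[table.group == "background", "gini"].median()
        assert fold_med > bg_med
        assert table.attrs["rank_sum_p"] < 0.01

    def test_identical_generators_give_uniformish_p(self):
        signal, intervals = self._setup()
        rng = np.random.default_rng(2)
        ps = []
        for seed in range(40):
            # folds sampled from the same even track
            ginis = []
            for _ in range(10):
                start = rng.integers(0, 4950)
                ginis.append(gini(signal["chr"][start : start + 50]))
            folds = [StructureScore(f"f{i}", 1.0, g, g) for i, g in enumerate(ginis)]
            table = background_comparison(
                folds, [50] * 10, signal, intervals, n_random=20, seed=seed
            )
            ps.append(table.attrs["rank_sum_p"])
        # under the null p-values should not pile up near zero
        assert np.mean(np.array(ps) < 0.05) < 0.3

    def test_zero_random_regions_rejected(self):
        signal, intervals = self._setup()
        folds = [StructureScore("f", 1.0, 0.5, 0.5)]
        with pytest.raises(ValueError):
            background_comparison(folds, [50], signal, intervals, n_random=0)

    def test_category_without_long_interval_errors(self):
        signal, intervals = self._setup()
        intervals["CDS"] = [("chr", 0, 10)]
        folds = [StructureScore("f", 1.0, 0.5, 0.5)]
        with pytest.raises(ValueError, match="CDS"):
            background_comparison(folds, [50], signal, intervals, n_random=8)


def test_profile_validation():
    with pytest.raises(ValueError, match="length"):
        DmsProfile("r", np.ones(5), np.ones(5), np.ones(4))
    with pytest.raises(ValueError):
        DmsProfile("r", -np.ones(5), np.ones(5), np.ones(5))
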