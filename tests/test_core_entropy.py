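"""Unit and property tests for the entropy estimator's six steps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mmdisten import (
    DegenerateSignalError,
    EntropyConfig,
    MultichannelSignal,
    assemble_multivariate,
    coarse_grain,
    distance_matrix,
    embed,
    empirical_pdf,
    entropy_profile,
    fuzzy_transform,
    mm_mdisten,
    read_channel_csv,
    read_config,
    remove_baseline,
    write_channel_csv,
    write_profile_csv,
)
from mmdisten.core_entropy import CoarseGrainedSeries

from .bruteforce import bruteforce_entropy
from .conftest import random_signal


class TestAssemble:
    def test_stacks_rows_in_order(self):
        sig = assemble_multivariate([[1, 2, 3], [4, 5, 6]])
        np.testing.assert_array_equal(sig.data, [[1, 2, 3], [4, 5, 6]])
        assert sig.n_channels == 2 and sig.n_samples == 3

    def test_univariate_degenerate_case(self):
        sig = assemble_multivariate([[1.0, 2.0, 3.0, 4.0]])
        assert sig.data.shape == (1, 4)

    @pytest.mark.parametrize(
        "rows", [[[1, 2, 3], [4, 5, 6, 7]], [], [[1, np.nan, 3]], [[1, np.inf, 3]]]
    )
    def test_invalid_inputs_rejected(self, rows):
        with pytest.raises(ValueError):
            assemble_multivariate(rows)


class TestCoarseGrain:
    def test_scale_one_is_identity(self):
        sig = MultichannelSignal(data=np.random.default_rng(0).standard_normal((3, 50)))
        out = coarse_grain(sig, 1)
        np.testing.assert_array_equal(out.data, sig.data)

    @pytest.mark.parametrize(
        "series,s,expected",
        [
            ([1, 2, 3, 4, 5, 6], 2, [1.5, 3.5, 5.5]),
            ([1, 2, 3, 4, 5, 6, 7], 3, [2.0, 5.0]),  # trailing sample discarded
        ],
    )
    def test_window_means(self, series, s, expected):
        out = coarse_grain(assemble_multivariate([series]), s)
        np.testing.assert_allclose(out.data[0], expected)

    def test_too_large_scale_rejected(self):
        sig = assemble_multivariate([[1, 2, 3, 4]])
        with pytest.raises(ValueError):
            coarse_grain(sig, 3)  # floor(4/3) = 1 < 2
        with pytest.raises(ValueError):
            coarse_grain(sig, 0)


class TestEmbed:
    def test_univariate_windows(self):
        ps = embed(np.array([1.0, 2.0, 3.0, 4.0]), m=2, tau=1)
        np.testing.assert_array_equal(ps.vectors, [[1, 2], [2, 3], [3, 4]])

    def test_bivariate_composite_vectors(self):
        cg = CoarseGrainedSeries(data=np.array([[1.0, 2, 3], [10.0, 20, 30]]), scale=1)
        ps = embed(cg, m=2, tau=1)
        np.testing.assert_array_equal(ps.vectors, [[1, 2, 10, 20], [2, 3, 20, 30]])

    def test_delay_skips_samples(self):
        ps = embed(np.array([1.0, 2, 3, 4, 5, 6, 7]), m=3, tau=2)
        np.testing.assert_array_equal(ps.vectors[0], [1, 3, 5])

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            embed(np.array([1.0, 2, 3, 4, 5]), m=3, tau=2)  # V = 1


class TestDistances:
    def test_pair_count_and_values(self):
        from mmdisten.core_entropy import PhaseSpaceMatrix

        ps = PhaseSpaceMatrix(vectors=np.array([[0.0, 0.0], [3.0, 4.0], [0.0, 0.0]]))
        d = distance_matrix(ps)
        assert d.shape == (3,)  # V(V-1)/2
        assert d[0] == 4.0  # chebyshev of (0,0)-(3,4)
        assert d[1] == 0.0  # identical vectors

    def test_baseline_removal_per_channel_block(self):
        from mmdisten.core_entropy import PhaseSpaceMatrix

        # 1 vector, 2 channels, m=2: each block loses its own mean
        ps = PhaseSpaceMatrix(vectors=np.array([[1.0, 3.0, 10.0, 20.0], [0.0, 0.0, 0.0, 0.0]]))
        out = remove_baseline(ps, n_channels=2, m=2)
        np.testing.assert_allclose(out.vectors[0], [-1, 1, -5, 5])


class TestFuzzyTransform:
    def test_closed_form_values(self):
        assert fuzzy_transform(np.array([0.0]), r=0.5, n=2)[0] == 1.0
        np.testing.assert_allclose(fuzzy_transform(np.array([0.5]), r=0.5, n=2)[0], np.exp(-1))

    def test_monotone_decreasing(self):
        d = np.linspace(0, 5, 100)
        mu = fuzzy_transform(d, r=0.3, n=2)
        assert np.all(np.diff(mu) < 0)
        assert np.all((mu > 0) & (mu <= 1))

    @pytest.mark.parametrize("r,n", [(0, 2), (-1, 2), (1, 0), (1, -3)])
    def test_invalid_parameters_rejected(self, r, n):
        with pytest.raises(ValueError):
            fuzzy_transform(np.array([1.0]), r=r, n=n)


class TestEmpiricalPdf:
    def test_direct_binning(self):
        np.testing.assert_allclose(empirical_pdf(np.array([0.1, 0.9]), 2), [0.5, 0.5])

    def test_identical_values_one_bin(self):
        p = empirical_pdf(np.full(10, 0.37), 64)
        assert p.max() == 1.0 and p.sum() == 1.0

    def test_interior_edge_assigned_upward_and_one_in_last_bin(self):
        p = empirical_pdf(np.array([0.5, 1.0]), 2)
        np.testing.assert_allclose(p, [0.0, 1.0])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=200))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_normalization_property(self, vals):
        p = empirical_pdf(np.array(vals), 16)
        assert p.shape == (16,)
        np.testing.assert_allclose(p.sum(), 1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            empirical_pdf(np.array([]), 8)


class TestMMmDistEn:
    def test_zero_variance_raises_named_error(self, default_cfg):
        sig = MultichannelSignal(data=np.ones((2, 40)))
        with pytest.raises(DegenerateSignalError):
            mm_mdisten(sig, default_cfg, 1)

    def test_bounded_in_unit_interval(self, default_cfg):
        rng = np.random.default_rng(42)
        for _ in range(10):
            sig = random_signal(rng, int(rng.integers(1, 4)), int(rng.integers(40, 120)))
            e = mm_mdisten(sig, default_cfg, 1)
            assert 0.0 <= e <= 1.0

    def test_deterministic(self, default_cfg):
        sig = random_signal(np.random.default_rng(7), 2, 80)
        assert mm_mdisten(sig, default_cfg, 2) == mm_mdisten(sig, default_cfg, 2)

    def test_matches_bruteforce_oracle(self, default_cfg):
        rng = np.random.default_rng(123)
        for _ in range(8):
            c = int(rng.integers(1, 4))
            n = int(rng.integers(30, 100))
            sig = random_signal(rng, c, n)
            for s in (1, 2, 3):
                expected = bruteforce_entropy(
                    sig.data.tolist(), m=3, tau=1, r_coeff=0.2, n=2, B=64, s=s
                )
                assert mm_mdisten(sig, default_cfg, s) == pytest.approx(expected, abs=1e-10)

    def test_matches_bruteforce_euclidean_and_no_baseline(self):
        cfg = EntropyConfig(metric="euclidean", baseline="none")
        rng = np.random.default_rng(5)
        sig = random_signal(rng, 2, 60)
        expected = bruteforce_entropy(
            sig.data.tolist(), m=3, tau=1, r_coeff=0.2, n=2, B=64, s=1,
            baseline=False, metric="euclidean",
        )
        assert mm_mdisten(sig, cfg, 1) == pytest.approx(expected, abs=1e-10)

    def test_channel_permutation_invariance(self, default_cfg):
        rng = np.random.default_rng(11)
        sig = random_signal(rng, 3, 90)
        permuted = MultichannelSignal(data=sig.data[[2, 0, 1]])
        for s in (1, 2):
            assert mm_mdisten(sig, default_cfg, s) == pytest.approx(
                mm_mdisten(permuted, default_cfg, s), abs=1e-12
            )

    def test_amplitude_scale_invariance(self, default_cfg):
        rng = np.random.default_rng(13)
        sig = random_signal(rng, 2, 90)
        scaled = MultichannelSignal(data=sig.data * 7.3)
        assert mm_mdisten(sig, default_cfg, 1) == pytest.approx(
            mm_mdisten(scaled, default_cfg, 1), abs=1e-12
        )


class TestEntropyProfile:
    def test_profile_composes_single_scales(self, default_cfg):
        sig = random_signal(np.random.default_rng(3), 2, 400)
        prof = entropy_profile(sig, default_cfg)
        assert set(prof.entropy_by_scale) == set(range(1, 16))
        assert prof.entropy_by_scale[1] == mm_mdisten(sig, default_cfg, 1)
        vec = prof.as_vector()
        assert vec.shape == (15,)
        assert np.all((vec >= 0) & (vec <= 1))

    def test_offending_scale_named_in_error(self):
        cfg = EntropyConfig(scales=(1, 30))
        sig = random_signal(np.random.default_rng(3), 1, 80)
        with pytest.raises(ValueError, match="scale 30"):
            entropy_profile(sig, cfg)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"m": 0}, {"tau": 0}, {"r_coeff": -0.1}, {"n": 0}, {"B": 1},
            {"scales": ()}, {"scales": (0, 1)}, {"metric": "cosine"},
            {"sd_mode": "other"}, {"baseline": "both"},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            EntropyConfig(**kwargs)

    def test_defaults(self, default_cfg):
        assert (default_cfg.m, default_cfg.tau) == (3, 1)
        assert (default_cfg.r_coeff, default_cfg.n, default_cfg.B) == (0.2, 2.0, 64)
        assert default_cfg.scales == tuple(range(1, 16))


class TestFileInterfaces:
    def test_channel_csv_roundtrip(self, tmp_path):
        sig = assemble_multivariate(
            [[1.25, 2.5, 3.75], [4.0, 5.0, 6.0]], channel_names=["AF3", "AF4"]
        )
        p = tmp_path / "sig.csv"
        write_channel_csv(sig, p)
        back = read_channel_csv(p)
        np.testing.assert_array_equal(back.data, sig.data)
        assert back.channel_names == ("AF3", "AF4")

    def test_headerless_csv(self, tmp_path):
        p = tmp_path / "sig.csv"
        p.write_text("1,2,3\n4,5,6\n")
        sig = read_channel_csv(p)
        assert sig.channel_names is None
        assert sig.data.shape == (2, 3)

    def test_config_toml_with_range_string(self, tmp_path):
        p = tmp_path / "cfg.toml"
        p.write_text('m = 2\ntau = 1\nscales = "1-4"\n')
        cfg = read_config(p)
        assert cfg.m == 2 and cfg.scales == (1, 2, 3, 4)
        p.write_text("bogus = 1\n")
        with pytest.raises(ValueError, match="unknown config keys"):
            read_config(p)

    def test_profile_csv(self, tmp_path, default_cfg):
        sig = random_signal(np.random.default_rng(1), 1, 200)
        prof = entropy_profile(sig, EntropyConfig(scales=(1, 2)))
        p = tmp_path / "prof.csv"
        write_profile_csv(prof, p)
        lines = p.read_text().splitlines()
        assert lines[0] == "scale,entropy"
        assert len(lines) == 3
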