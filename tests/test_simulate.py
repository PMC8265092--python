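"""Generator: distributional structure, counting identities, acceptance."""

import numpy as np
import pytest

from clustersim import grids
from clustersim.simulate import (
    AcceptanceError,
    ClusteredSample,
    SimulationSpec,
    draw_sd_shift,
    generate_accepted_sample,
    generate_binary_x,
    generate_continuous_x,
    generate_outcome,
    generate_sample,
    read_sample,
    realized_sample_icc,
    write_sample,
    x_dispersion,
)


def _spec(**kw):
    base = dict(sd_u=0.3, icc_target_range=None)
    base.update(kw)
    return SimulationSpec(**base)


class TestDrawSdShift:
    def test_bounds_and_moments(self, rng):
        draws = np.array([draw_sd_shift("continuous", rng) for _ in range(10_000)])
        assert draws.min() >= 0 and draws.max() <= 20
        # U[0,20]: mean 10, SD 20/sqrt(12) ~ 5.77
        assert draws.mean() == pytest.approx(10.0, abs=0.2)
        assert draws.std() == pytest.approx(20 / np.sqrt(12), abs=0.15)

    def test_binary_scale(self, rng):
        draws = np.array([draw_sd_shift("binary", rng) for _ in range(2_000)])
        assert draws.max() <= 0.05
        assert draws.mean() == pytest.approx(0.025, abs=0.002)

    def test_unknown_type_rejected(self, rng):
        with pytest.raises(ValueError):
            draw_sd_shift("ordinal", rng)


class TestContinuousX:
    def test_no_shift_is_iid_standard_normal(self, rng):
        spec = _spec(sd_shift=0.0)
        x, shift = generate_continuous_x(spec, rng)
        assert np.all(shift == 0)
        # SD of cluster means of 100 iid N(0,1) obs is ~ 1/sqrt(100) = 0.1
        means = x.reshape(100, 100).mean(axis=1)
        assert means.std(ddof=1) == pytest.approx(0.1, rel=0.25)

    def test_cluster_mean_dispersion_tracks_sd_shift(self, rng):
        # var(cluster mean) = sd_shift^2 + 1/m; at sd_shift=20 the shift
        # dominates, with ~7% sampling error over 100 clusters
        spec = _spec(sd_shift=20.0)
        x, _ = generate_continuous_x(spec, rng)
        means = x.reshape(100, 100).mean(axis=1)
        assert means.std(ddof=1) == pytest.approx(20.0, rel=0.25)

    def test_within_cluster_variance_is_one(self, rng):
        spec = _spec(sd_shift=20.0)
        x, _ = generate_continuous_x(spec, rng)
        within = x.reshape(100, 100)
        within = within - within.mean(axis=1, keepdims=True)
        assert within.var(ddof=1) * 10_000 / 9_900 == pytest.approx(1.0, rel=0.05)

    def test_single_cluster(self, rng):
        spec = _spec(sd_shift=3.0, n_clusters=1, cluster_size=500)
        x, shift = generate_continuous_x(spec, rng)
        assert len(shift) == 1
        assert x.mean() == pytest.approx(shift[0], abs=0.2)


class TestBinaryX:
    def test_count_identity(self, rng):
        # per-cluster number of ones == round(cluster_size * prevalence)
        spec = _spec(x_type="binary", target_prevalence=0.2, sd_shift=0.04)
        x, prevalence, _ = generate_binary_x(spec, rng)
        counts = x.reshape(100, 100).sum(axis=1)
        assert np.array_equal(counts, np.floor(100 * prevalence + 0.5))

    def test_worked_count_example(self):
        # assigned prevalence 0.223 over 100 observations -> 22 ones
        assert int(np.floor(100 * 0.223 + 0.5)) == 22

    def test_half_rounds_away_from_zero(self, rng):
        spec = _spec(x_type="binary", target_prevalence=0.225, sd_shift=0.0)
        x, prevalence, _ = generate_binary_x(spec, rng)
        assert np.all(x.reshape(100, 100).sum(axis=1) == 23)

    def test_negative_prevalence_clipped_to_all_zero_cluster(self, rng):
        # large shifts at low target prevalence force negative assignments
        spec = _spec(x_type="binary", target_prevalence=0.01, sd_shift=0.05)
        x, prevalence, shift = generate_binary_x(spec, rng)
        assert (spec.target_prevalence + shift < 0).any()
        assert prevalence.min() == 0.0
        zero_clusters = np.flatnonzero(prevalence == 0.0)
        counts = x.reshape(100, 100).sum(axis=1)
        assert np.all(counts[zero_clusters] == 0)

    def test_no_shift_exact_counts_zero_dispersion(self, rng):
        spec = _spec(x_type="binary", target_prevalence=0.4, sd_shift=0.0)
        sample = generate_sample(spec, rng)
        counts = sample.x.reshape(100, 100).sum(axis=1)
        assert np.all(counts == 40)
        assert x_dispersion(sample) == pytest.approx(0.0, abs=1e-12)


class TestOutcome:
    def test_noiseless_identity(self, rng):
        spec = _spec(sd_u=0.0, sd_e=1e-12, beta0=0.0, beta1=1.0)
        x, _ = generate_continuous_x(spec, rng)
        cid = np.repeat(np.arange(100), 100)
        y, u, e = generate_outcome(x, cid, spec, rng)
        assert np.allclose(y, x, atol=1e-9)

    def test_variance_decomposition(self, rng):
        # var(y - x) = sd_u^2 + sd_e^2 = 0.6547^2 + 1 = 1.4286
        spec = _spec(sd_u=0.6547, n_clusters=1000, cluster_size=100)
        x = np.zeros(spec.n_obs)
        cid = np.repeat(np.arange(1000), 100)
        y, u, e = generate_outcome(x, cid, spec, rng)
        assert y.var() == pytest.approx(1.4286, rel=0.03)

    def test_null_outcome_independent_of_x(self, rng):
        spec = _spec(beta1=0.0, sd_u=0.3, sd_shift=10.0)
        sample = generate_sample(spec, rng)
        assert abs(np.corrcoef(sample.x, sample.y)[0, 1]) < 0.05


class TestRealizedIcc:
    def test_zero_when_no_cluster_variance(self, rng):
        assert realized_sample_icc(np.zeros(50), rng.normal(size=100)) == 0.0

    def test_half_at_equal_variances(self):
        v = np.array([1.0, -1.0, 2.0, -2.0])
        assert realized_sample_icc(v, v) == pytest.approx(0.5)

    def test_large_sample_matches_analytic(self, rng):
        u = rng.normal(0, 0.6547, 20_000)
        e = rng.normal(0, 1.0, 20_000)
        assert realized_sample_icc(u, e) == pytest.approx(0.3, abs=0.01)

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            realized_sample_icc(np.zeros(5), np.zeros(5))
        with pytest.raises(ValueError):
            realized_sample_icc(np.array([1.0]), np.array([1.0, 2.0]))


class TestAcceptance:
    @pytest.mark.parametrize("level", grids.ICC_LEVELS, ids=lambda l: str(l.label))
    def test_accepted_icc_in_range(self, level, rng):
        spec = _spec(sd_u=level.sd_u, icc_target_range=level.icc_range,
                     sd_shift=5.0)
        for _ in range(5):
            s = generate_accepted_sample(spec, rng)
            assert level.icc_range[0] <= s.sample_icc <= level.icc_range[1]

    def test_infeasible_range_raises(self):
        spec = _spec(sd_u=0.0, icc_target_range=(0.25, 0.349), max_attempts=10)
        with pytest.raises(AcceptanceError, match="infeasible"):
            generate_accepted_sample(spec)

    def test_fitted_estimator_switch(self, rng):
        lev = grids.level_for_label(0.3)
        spec = _spec(sd_u=lev.sd_u, icc_target_range=lev.icc_range,
                     sd_shift=2.0, icc_estimator="fitted")
        s = generate_accepted_sample(spec, rng)
        assert lev.icc_range[0] <= s.sample_icc <= lev.icc_range[1]

    def test_reproducible_from_seed(self):
        lev = grids.level_for_label(0.1)
        spec = _spec(sd_u=lev.sd_u, icc_target_range=lev.icc_range,
                     sd_shift=3.0, seed=42)
        a = generate_accepted_sample(spec)
        b = generate_accepted_sample(spec)
        assert np.array_equal(a.x, b.x)
        assert np.array_equal(a.y, b.y)
        assert a.sample_icc == b.sample_icc
        assert a.attempts == b.attempts


class TestSampleStructure:
    def test_balanced_design(self, rng):
        s = generate_sample(_spec(sd_shift=1.0), rng)
        assert s.n_obs == 10_000
        assert np.all(s.cluster_sizes() == 100)

    def test_dispersion_two_point(self):
        # cluster means {0, 2}: sample SD (n-1 denominator) = sqrt(2)
        s = ClusteredSample(
            cluster_id=np.array([0, 0, 1, 1]),
            x=np.array([0.0, 0.0, 2.0, 2.0]),
            y=np.zeros(4),
        )
        assert x_dispersion(s) == pytest.approx(np.sqrt(2.0))

    def test_dispersion_single_cluster_errors(self):
        s = ClusteredSample(
            cluster_id=np.zeros(4, dtype=int),
            x=np.arange(4.0), y=np.zeros(4),
        )
        with pytest.raises(ValueError):
            x_dispersion(s)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            SimulationSpec(sd_u=-0.1)
        with pytest.raises(ValueError):
            SimulationSpec(sd_u=0.1, x_type="binary")  # missing prevalence
        with pytest.raises(ValueError):
            SimulationSpec(sd_u=0.1, icc_target_range=(0.3, 0.2))
        with pytest.raises(ValueError):
            SimulationSpec(sd_u=0.1, sd_e=0.0)


class TestIO:
    def test_csv_roundtrip(self, rng, tmp_path):
        lev = grids.level_for_label(0.3)
        spec = _spec(sd_u=lev.sd_u, icc_target_range=lev.icc_range, sd_shift=2.0)
        s = generate_accepted_sample(spec, rng)
        path = tmp_path / "sample.csv"
        write_sample(s, path, spec)
        loaded = read_sample(path)
        assert np.allclose(loaded.x, s.x)
        assert np.allclose(loaded.y, s.y)
        assert np.array_equal(loaded.cluster_id, s.cluster_id)
        assert loaded.sample_icc == pytest.approx(s.sample_icc)
        assert (path.with_suffix(".json")).exists()

    def test_header_contract(self, rng, tmp_path):
        s = generate_sample(_spec(sd_shift=1.0, n_clusters=3, cluster_size=4), rng)
        path = tmp_path / "s.csv"
        write_sample(s, path)
        assert path.read_text().splitlines()[0] == "cluster,x,y"
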