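import numpy as np
import pytest

from uromics import PLGEM, IntensityMatrix, differential_by_sex
from uromics.errors import ParameterError, ValidationError

from conftest import make_annotation, make_matrix


def powerlaw_fixture(slope=0.8, coef=0.5, n_feat=60, seed=0, n_per_cell=3):
    """Replicated matrix whose per-feature SD follows coef * mean^slope exactly.

    Each cell's replicates are mean + d * z for a fixed zero-mean, unit-SD
    pattern z, so the sample mean is the mean and the sample SD is exactly
    d = coef * mean^slope — the power law without noise.
    """
    ann = make_annotation(groups=("DOM",), n_per_cell=n_per_cell, n_blanks=0)
    rng = np.random.default_rng(seed)
    means = rng.uniform(10, 1e4, n_feat)
    d = coef * means ** slope
    z = np.arange(n_per_cell) - (n_per_cell - 1) / 2.0
    z = z / z.std(ddof=1)
    block = means[:, None] + d[:, None] * z[None, :]
    vals = np.concatenate([block, block], axis=1)   # M cell then F cell
    return make_matrix(vals, ann, kind="protein"), ann


class TestFit:
    def test_exact_powerlaw_recovery(self):
        m, ann = powerlaw_fixture(slope=0.8, coef=0.5)
        res = PLGEM(m, ann).fit(("DOM", "M"))
        assert res.slope == pytest.approx(0.8, abs=1e-6)
        assert res.intercept == pytest.approx(np.log(0.5), abs=1e-6)
        assert res.r2 == pytest.approx(1.0, abs=1e-9)

    def test_constant_features_error(self):
        ann = make_annotation(groups=("DOM",), n_per_cell=3, n_blanks=0)
        m = make_matrix(np.ones((5, 6)), ann, kind="protein")
        with pytest.raises(ValidationError, match="SD"):
            PLGEM(m, ann).fit(("DOM", "M"))

    def test_too_few_replicates_error(self):
        ann = make_annotation(groups=("DOM",), n_per_cell=2, n_blanks=0)
        m = make_matrix(np.random.default_rng(0).lognormal(5, 1, (10, 4)),
                        ann, kind="protein")
        with pytest.raises(ValidationError, match="DOM"):
            PLGEM(m, ann).fit(("DOM", "M"))

    def test_slope_recovery_on_simulated_proteome(self, sim_default):
        protein, _, ann, _ = sim_default
        res = PLGEM(protein, ann).fit()
        assert res.slope == pytest.approx(0.75, abs=0.05)

    def test_default_condition_is_most_replicated(self, sim_default):
        protein, _, ann, _ = sim_default
        model = PLGEM(protein, ann)
        # all cells equally replicated -> lexicographic first
        assert model.default_condition() == ("DOM", "F")


class TestStn:
    def test_zero_for_equal_means_and_antisymmetry(self):
        m, ann = powerlaw_fixture()
        model = PLGEM(m, ann)
        res = model.fit(("DOM", "M"))
        stn_ab = res.stn((("DOM", "M"), ("DOM", "F")))
        np.testing.assert_allclose(stn_ab, 0.0, atol=1e-12)
        # plant a difference, check antisymmetry
        vals = m.values.copy()
        vals[:, 3:] *= 3.0
        m2 = m.copy_with(vals)
        model2 = PLGEM(m2, ann)
        res2 = model2.fit(("DOM", "M"))
        ab = res2.stn((("DOM", "M"), ("DOM", "F")))
        ba = res2.stn((("DOM", "F"), ("DOM", "M")))
        np.testing.assert_allclose(ab, -ba)

    def test_matches_handcoded_formula(self):
        rng = np.random.default_rng(7)
        ann = make_annotation(groups=("DOM",), n_per_cell=3, n_blanks=0)
        vals = rng.lognormal(6, 1, (10, 6))
        m = make_matrix(vals, ann, kind="protein")
        model = PLGEM(m, ann)
        res = model.fit(("DOM", "M"))
        got = res.stn((("DOM", "M"), ("DOM", "F"))).to_numpy()
        ids = ann.sample_ids
        males = [i for i, s in enumerate(ids) if "_M" in s]
        females = [i for i, s in enumerate(ids) if "_F" in s]
        for i in range(10):
            ma = vals[i, males].mean()
            mb = vals[i, females].mean()
            sd = lambda mu: np.exp(res.intercept) * mu ** res.slope
            assert got[i] == pytest.approx((mb - ma) / (sd(ma) + sd(mb)))


class TestNull:
    def test_deterministic_given_seed(self, sim_default):
        protein, _, ann, _ = sim_default
        model = PLGEM(protein, ann)
        res = model.fit()
        a = res.resample_null(n_iter=50, seed=3)
        b = model.fit().resample_null(n_iter=50, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_null_centered(self, sim_default):
        protein, _, ann, _ = sim_default
        res = PLGEM(protein, ann).fit()
        null = res.resample_null(n_iter=200, seed=1)
        assert abs(np.mean(null)) < 0.05

    def test_null_pvalues_uniform_for_no_effect_features(self, sim_default):
        protein, _, ann, truth = sim_default
        diff = differential_by_sex(protein, ann, "DOM", n_iter=500, seed=5)
        planted = set(truth.sexbiased) | {p for p, _, _ in truth.pairs}
        null_p = diff.loc[~diff["feature_id"].isin(planted), "p"].dropna()
        from scipy.stats import kstest
        assert kstest(null_p, "uniform").statistic < 0.08

    def test_too_few_replicates_for_split(self):
        m, ann = powerlaw_fixture()       # 3 replicates per cell
        res = PLGEM(m, ann).fit(("DOM", "M"))
        with pytest.raises(ValidationError, match="4"):
            res.resample_null(n_iter=100, seed=0)


class TestDifferential:
    def test_planted_effects_called_with_direction(self, sim_default):
        protein, _, ann, truth = sim_default
        diff = differential_by_sex(protein, ann, "DOM", n_iter=500, seed=5)
        table = diff.set_index("feature_id")
        planted = truth.sexbiased_in_group("DOM", "protein")
        called = 0
        for fid, (_, fav, _, _) in planted.items():
            row = table.loc[fid]
            if row["significant"]:
                called += 1
                expect = "male_biased" if fav == "M" else "female_biased"
                assert row["direction"] == expect
        assert called / len(planted) >= 0.9

    def test_high_p_low_fd_combinations(self):
        # significance needs BOTH p < alpha and |FD| > threshold
        m, ann = powerlaw_fixture(n_feat=40, n_per_cell=4)
        vals = m.values.copy()
        vals[:, 4:] *= 1.5            # FD = 1.5 everywhere
        m2 = m.copy_with(vals)
        model = PLGEM(m2, ann)
        res = model.fit(("DOM", "M"))
        res.resample_null(n_iter=100, seed=0)
        diff = res.differential((("DOM", "M"), ("DOM", "F")))
        assert not diff["significant"].any()
        assert (diff["direction"] == "unbiased").all()

    def test_fd_sign_convention(self, sim_default):
        protein, _, ann, truth = sim_default
        diff = differential_by_sex(protein, ann, "MUS", n_iter=200, seed=5)
        fd = diff.set_index("feature_id")["fd"]
        assert (fd.dropna().abs() >= 1).all()
        for fid, (kind, fav, _, groups) in truth.sexbiased.items():
            if kind == "protein" and "MUS" in groups:
                assert (fd[fid] > 0) == (fav == "F")

    def test_p_in_unit_interval_never_zero(self, sim_default):
        protein, _, ann, _ = sim_default
        diff = differential_by_sex(protein, ann, "DOM", n_iter=100, seed=5)
        p = diff["p"].dropna()
        assert (p > 0).all() and (p <= 1).all()
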