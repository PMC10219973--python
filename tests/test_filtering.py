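import numpy as np
import pytest

from uromics import (filter_pipeline, fit_blank_mixture, identity_index,
                     mixture_filter, prevalence_filter, remove_blank_only)
from uromics.errors import ParameterError, ValidationError
from uromics.filtering import BlankMixtureModel, blank_fold_difference

from conftest import make_annotation, make_matrix


@pytest.fixture
def ann6():
    # 2 groups x 2 sexes x 3 specimens + 2 blanks = 14 columns
    return make_annotation(n_per_cell=3, n_blanks=2)


class TestPrevalence:
    def test_kept_when_one_cell_reaches_three(self, ann6):
        vals = np.zeros((1, 14))
        dom_m = [i for i, s in enumerate(ann6.sample_ids) if s.startswith("DOM_M")]
        vals[0, dom_m] = 5.0          # 3 DOM males
        m = make_matrix(vals, ann6)
        kept, rep = prevalence_filter(m, ann6, min_count=3)
        assert kept.n_features == 1
        assert rep.n_after_prevalence == 1

    def test_dropped_when_spread_across_cells(self, ann6):
        vals = np.zeros((1, 14))
        ids = ann6.sample_ids
        hit = [i for i, s in enumerate(ids) if s in
               ("DOM_M0", "DOM_M1", "MUS_F0", "MUS_F1")]
        vals[0, hit] = 5.0            # 2 + 2, no cell reaches 3
        m = make_matrix(vals, ann6)
        kept, rep = prevalence_filter(m, ann6, min_count=3)
        assert kept.n_features == 0
        assert (rep.records["drop_reason"] == "singleton").all()

    def test_blanks_never_count(self, ann6):
        vals = np.zeros((1, 14))
        blank_cols = [i for i, s in enumerate(ann6.sample_ids) if s.startswith("B")]
        some_spec = [0, 1]
        vals[0, blank_cols] = 9.0
        vals[0, some_spec] = 9.0      # only 2 specimens
        m = make_matrix(vals, ann6)
        kept, _ = prevalence_filter(m, ann6, min_count=3)
        assert kept.n_features == 0

    def test_matches_bruteforce_recount(self, sim_small):
        _, volatile, ann, _ = sim_small
        kept, rep = prevalence_filter(volatile, ann, min_count=3)
        cells = ann.cell_members()
        frame = volatile.to_frame()
        expected = 0
        for fid in volatile.feature_ids:
            row = frame.loc[fid]
            if any((row[m] > 0).sum() >= 3 for m in cells.values()):
                expected += 1
        assert rep.n_after_prevalence == expected

    def test_min_count_validation(self, ann6):
        m = make_matrix(np.ones((1, 14)), ann6)
        with pytest.raises(ParameterError):
            prevalence_filter(m, ann6, min_count=0)


class TestBlankOnly:
    def test_blank_only_feature_dropped(self, ann6):
        vals = np.zeros((2, 14))
        blank_cols = [i for i, s in enumerate(ann6.sample_ids) if s.startswith("B")]
        vals[0, blank_cols] = 4.0     # only in blanks
        vals[1, :] = 1.0              # everywhere
        m = make_matrix(vals, ann6)
        kept, rep = remove_blank_only(m, ann6)
        assert kept.feature_ids == ["F1"]
        assert rep.records.loc[rep.records.feature_id == "F0",
                               "drop_reason"].item() == "blank_only"

    def test_one_specimen_is_enough_to_survive(self, ann6):
        vals = np.zeros((1, 14))
        ids = ann6.sample_ids
        vals[0, [i for i, s in enumerate(ids) if s.startswith("B")]] = 4.0
        vals[0, 0] = 2.0              # one specimen detection
        m = make_matrix(vals, ann6)
        kept, _ = remove_blank_only(m, ann6)
        assert kept.n_features == 1

    def test_volatile_without_blanks_errors(self):
        ann = make_annotation(n_blanks=0)
        m = make_matrix(np.ones((1, 12)), ann)
        with pytest.raises(ValidationError, match="blank"):
            remove_blank_only(m, ann)


class TestIdentityIndex:
    def test_symmetry_zero(self):
        assert identity_index(5, 5) == 0.0

    def test_arithmetic(self):
        assert identity_index(19, 1) == pytest.approx(0.9)

    def test_specimen_exclusive_is_one(self):
        for x in (0.1, 7.0, 1e9):
            assert identity_index(x, 0) == 1.0

    def test_antisymmetric(self):
        assert identity_index(3, 11) == -identity_index(11, 3)

    def test_undefined_case_outside_legal_range(self):
        li = identity_index(0, 0)
        assert not (-1 <= li <= 1)   # NaN compares false


class TestMixtureEM:
    def test_recovers_planted_components(self):
        rng = np.random.default_rng(42)
        x = np.concatenate([rng.normal(0, 1, 400), rng.normal(6, 1, 600)])
        fit = BlankMixtureModel(x).fit()
        assert fit.converged
        assert -0.3 <= fit.mu1 <= 0.3
        assert 5.7 <= fit.mu2 <= 6.3
        assert fit.lam == pytest.approx(0.4, abs=0.05)

    def test_loglik_monotone_and_above_init(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0, 1, 200), rng.normal(4, 1, 300)])
        fit = BlankMixtureModel(x).fit()
        diffs = np.diff(fit.loglik_path)
        assert (diffs >= -1e-9).all()
        assert fit.loglik >= fit.loglik_path[0]

    def test_all_identical_values_degenerate_but_no_crash(self):
        fit = BlankMixtureModel(np.full(50, 3.0)).fit()
        assert not fit.converged

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0, 1, 100), rng.normal(5, 1, 100)])
        fit = BlankMixtureModel(x).fit()
        post_bio = fit.posterior_bio(x)
        assert np.all((post_bio >= 0) & (post_bio <= 1))


class TestMixtureFilter:
    def test_extreme_features_kept_and_dropped(self, sim_small):
        _, volatile, ann, _ = sim_small
        m1, rep = prevalence_filter(volatile, ann)
        m2, rep = remove_blank_only(m1, ann, rep)
        fit = fit_blank_mixture(m2, ann)
        x, _ = blank_fold_difference(m2, ann)
        post = fit.posterior_bio(x)
        far_above = x > fit.mu2
        assert post[far_above].min() > 0.99
        at_mu1 = np.argmin(np.abs(x - fit.mu1))
        assert post[at_mu1] < 0.95

    def test_posterior_filter_monotone_in_x(self, sim_small):
        _, volatile, ann, _ = sim_small
        m1, rep = prevalence_filter(volatile, ann)
        m2, rep = remove_blank_only(m1, ann, rep)
        fit = fit_blank_mixture(m2, ann)
        kept, rep = mixture_filter(m2, ann, fit, report=rep)
        x, _ = blank_fold_difference(m2, ann)
        kept_set = set(kept.feature_ids)
        x_kept = [xi for f, xi in zip(m2.feature_ids, x) if f in kept_set]
        x_drop = [xi for f, xi in zip(m2.feature_ids, x) if f not in kept_set]
        if x_kept and x_drop:
            assert min(x_kept) > max(x_drop)

    def test_threshold_validation(self, sim_small):
        _, volatile, ann, _ = sim_small
        fit = fit_blank_mixture(volatile, ann)
        with pytest.raises(ParameterError):
            mixture_filter(volatile, ann, fit, posterior_threshold=1.5)


class TestFunnel:
    def test_stage_counts_monotone(self, sim_default):
        _, volatile, ann, _ = sim_default
        _, rep, _ = filter_pipeline(volatile, ann)
        c = rep.stage_counts()
        assert (c["n_input"] >= c["n_after_prevalence"]
                >= c["n_after_blank_only"] >= c["n_after_mixture"])

    def test_recovers_planted_truth(self, sim_default):
        _, volatile, ann, truth = sim_default
        kept, rep, fit = filter_pipeline(volatile, ann)
        kept_set = set(kept.feature_ids)
        bio_rate = len(kept_set & truth.bio_ids) / len(truth.bio_ids)
        blank_rate = len(kept_set & truth.blank_origin_ids) / len(truth.blank_origin_ids)
        assert bio_rate >= 0.95
        assert blank_rate <= 0.05
        assert fit.converged

    def test_protein_passes_prevalence_only(self, sim_default):
        protein, _, ann, _ = sim_default
        kept, rep, fit = filter_pipeline(protein, ann)
        assert fit is None
        assert rep.n_after_mixture == rep.n_after_prevalence

    def test_deterministic_rerun(self, sim_small):
        _, volatile, ann, _ = sim_small
        a, _, _ = filter_pipeline(volatile, ann)
        b, _, _ = filter_pipeline(volatile, ann)
        assert a == b

    def test_li_and_fd_cutoffs_reported(self, sim_default):
        _, volatile, ann, _ = sim_default
        _, rep, _ = filter_pipeline(volatile, ann)
        assert rep.implied_fd_cutoff > 1
        assert -1 <= rep.implied_li_cutoff <= 1
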