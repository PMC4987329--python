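"""Classifier-agreement statistic, subband contrasts, exemplar selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from matdecode.classification import CVResult
from matdecode.consistency import (AgreementResult, actual_agreement,
                                   agreement_test, exemplar_images,
                                   expected_agreement, subband_ttests)
from matdecode.features import FeatureSet
from matdecode.grouping import PropertyGroups
from matdecode.pyramid import PyramidSpec
from scipy import stats as sps


def enumerate_expected(a, b, n):
    """Exhaustive oracle: mean agreement over all label assignments with
    fixed marginals a and b, classifiers independent and exchangeable."""
    items = list(range(n))
    total, count = 0.0, 0
    for set_a in itertools.combinations(items, a):
        for set_b in itertools.combinations(items, b):
            sa, sb = set(set_a), set(set_b)
            agree = sum(1 for i in items if (i in sa) == (i in sb))
            total += agree / n
            count += 1
    return total / count


class TestExpectedAgreement:
    def test_paper_worked_example_rounds_to_059(self):
        assert round(expected_agreement(14, 16.2, 21), 2) == 0.59

    def test_both_classifiers_saturated_agree_always(self):
        assert expected_agreement(21, 21, 21) == 1.0

    def test_small_case_matches_exhaustive_enumeration(self):
        assert expected_agreement(1, 1, 2) == pytest.approx(
            enumerate_expected(1, 1, 2))  # = 0.5
        for a, b, n in [(2, 1, 3), (2, 2, 4), (3, 1, 4)]:
            assert expected_agreement(a, b, n) == pytest.approx(
                enumerate_expected(a, b, n))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(1, 30), st.integers(0, 30), st.integers(0, 30))
    def test_symmetry_and_linearity_in_each_count(self, n, a, b):
        a, b = min(a, n), min(b, n)
        assert expected_agreement(a, b, n) == pytest.approx(
            expected_agreement(b, a, n))
        # E is linear in b, so its minimum over b sits at an endpoint:
        # b = n when a < n/2, b = 0 when a > n/2
        lo = min(expected_agreement(a, 0, n), expected_agreement(a, n, n))
        assert expected_agreement(a, b, n) >= lo - 1e-12
        mid = 0.5 * (expected_agreement(a, 0, n) + expected_agreement(a, n, n))
        assert expected_agreement(a, n / 2.0, n) == pytest.approx(mid)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            expected_agreement(1, 1, 0)
        with pytest.raises(ValueError):
            expected_agreement(5, 1, 4)


class TestActualAgreement:
    def test_identical_labels_agree_fully(self):
        assert actual_agreement([1, 0, 1], [1, 0, 1]) == 1.0

    def test_complementary_labels_never_agree(self):
        assert actual_agreement([1, 0, 1], [0, 1, 0]) == 0.0

    def test_id_alignment_and_mismatch(self):
        assert actual_agreement([1, 0], [0, 1], ids_a=["x", "y"],
                                ids_b=["y", "x"]) == 1.0
        with pytest.raises(ValueError, match="mismatch"):
            actual_agreement([1, 0], [1, 0], ids_a=["x", "y"],
                             ids_b=["x", "z"])

    def test_reordering_images_leaves_agreement_unchanged(self):
        rng = np.random.default_rng(0)
        la, lb = rng.integers(0, 2, 30), rng.integers(0, 2, 30)
        perm = rng.permutation(30)
        assert actual_agreement(la, lb) == actual_agreement(la[perm], lb[perm])

    def test_independent_labelers_match_expected_within_3se(self):
        rng = np.random.default_rng(42)
        n, draws = 21, 10_000
        pa, pb = 14 / 21, 0.6
        agree = np.empty(draws)
        for d in range(draws):
            la = rng.random(n) < pa
            lb = rng.random(n) < pb
            agree[d] = np.mean(la == lb)
        expected = expected_agreement(pa * n, pb * n, n)
        se = agree.std(ddof=1) / np.sqrt(draws)
        assert abs(agree.mean() - expected) < 3 * se


def make_results(diffs_by_participant, pole="high", prop="roughness"):
    out = []
    for p, d in enumerate(diffs_by_participant):
        out.append(AgreementResult(property=prop, pole=pole,
                                   participant_id=f"sub{p:02d}", n=21,
                                   a=14, b=15, expected=0.6,
                                   actual=0.6 + d))
    return out


class TestAgreementTest:
    def test_actual_equal_expected_gives_t0_p_half(self):
        res = make_results([0.0, 0.0, 0.0], "high") + \
              make_results([0.0, 0.0, 0.0], "low")
        out = agreement_test(res)
        assert out["high"]["t"] == 0.0 and out["high"]["p"] == 0.5
        assert out["pooled"]["t"] == 0.0

    def test_consistent_positive_differences_reject(self):
        res = make_results([0.08, 0.1, 0.06, 0.09], "high") + \
              make_results([0.07, 0.11, 0.05, 0.1], "low")
        out = agreement_test(res)
        assert out["high"]["p"] < 0.05
        assert out["pooled"]["p"] < 0.05

    def test_independent_labelers_hold_nominal_type_one_error(self):
        # reduced-size null simulation: per seed, 8 participants with
        # independent image-stat and MVPA labels; rejection rate ~ alpha
        rejections = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            results = []
            for p in range(8):
                for pole in ("high", "low"):
                    n = 21
                    la = rng.random(n) < 0.7
                    lb = rng.random(n) < 0.65
                    a, b = la.sum(), lb.sum()
                    results.append(AgreementResult(
                        property="r", pole=pole, participant_id=f"s{p}",
                        n=n, a=a, b=b,
                        expected=expected_agreement(a, b, n),
                        actual=float(np.mean(la == lb))))
            if agreement_test(results)["pooled"]["p"] < 0.05:
                rejections += 1
        lo, hi = sps.binom.ppf([0.025, 0.975], n_seeds, 0.05)
        assert lo <= rejections <= hi

    def test_single_participant_rejected(self):
        with pytest.raises(ValueError):
            agreement_test(make_results([0.1]))


class TestSubbandTtests:
    def make_spectra(self, low, high, spec=PyramidSpec(2, 3)):
        cols = [f"energy_s{s}_o{o}" for s in range(1, spec.n_scales + 1)
                for o in range(1, spec.n_orientations + 1)]
        cols += ["energy_highpass", "energy_lowpass"]
        rows = {}
        for i, v in enumerate(low):
            rows[f"lo{i}"] = v
        for i, v in enumerate(high):
            rows[f"hi{i}"] = v
        mat = pd.DataFrame(
            {c: {k: rows[k][j] for k in rows}
             for j, c in enumerate(cols[: spec.n_scales * spec.n_orientations])})
        mat["energy_highpass"] = 0.1
        mat["energy_lowpass"] = 0.1
        groups = PropertyGroups("p", [k for k in rows if k.startswith("lo")],
                                [k for k in rows if k.startswith("hi")],
                                0, 1)
        return FeatureSet("spectral", mat), groups, spec

    def test_identical_groups_give_zero_t(self):
        vals = [np.arange(6) + 1.0, np.arange(6) + 2.0, np.arange(6) + 3.0]
        fs, g, spec = self.make_spectra(vals, vals)
        t = subband_ttests(fs, g, spec).t_values.to_numpy(dtype=float)
        assert np.allclose(t, 0.0)

    def test_scaled_high_group_gives_all_positive_t(self):
        low = [np.arange(6) + 1.0, np.arange(6) + 1.5, np.arange(6) + 2.0]
        high = [2.0 * v for v in low]
        fs, g, spec = self.make_spectra(low, high)
        t = subband_ttests(fs, g, spec).t_values.to_numpy(dtype=float)
        assert (t > 0).all()

    def test_three_vs_three_matches_textbook_formula(self):
        low = [np.full(6, 1.0), np.full(6, 2.0), np.full(6, 3.0)]
        high = [np.full(6, 2.0), np.full(6, 4.0), np.full(6, 6.0)]
        fs, g, spec = self.make_spectra(low, high)
        t = subband_ttests(fs, g, spec).t_values.iloc[0, 0]
        x, y = np.array([2.0, 4.0, 6.0]), np.array([1.0, 2.0, 3.0])
        sp = np.sqrt(((x - x.mean()) ** 2).sum() / 2 / 2
                     + ((y - y.mean()) ** 2).sum() / 2 / 2)
        # pooled two-sample t with equal n
        sp2 = np.sqrt((np.var(x, ddof=1) + np.var(y, ddof=1)) / 2)
        expect = (x.mean() - y.mean()) / (sp2 * np.sqrt(2 / 3))
        assert t == pytest.approx(expect)

    def test_singleton_group_rejected(self):
        low = [np.arange(6) + 1.0]
        high = [np.arange(6) + 2.0, np.arange(6) + 3.0]
        fs, g, spec = self.make_spectra(low, high)
        with pytest.raises(ValueError, match="at least 2"):
            subband_ttests(fs, g, spec)


class TestExemplarImages:
    def groups(self):
        return PropertyGroups("p", ["a", "b"], ["c", "d"], 0, 1)

    def test_single_correct_image_is_chosen(self):
        cv = CVResult(predicted=np.array(["low", "high", "high", "low"]),
                      posterior=np.array([0.9, 0.8, 0.7, 0.6]),
                      accuracy=0.5, n_folds=4)
        out = exemplar_images(cv, ["a", "b", "c", "d"], self.groups())
        assert out["low"] == "a"
        assert out["high"] == "c"

    def test_posterior_tie_resolves_to_lowest_id(self):
        cv = CVResult(predicted=np.array(["low", "low", "high", "high"]),
                      posterior=np.array([0.8, 0.8, 0.9, 0.9]),
                      accuracy=1.0, n_folds=4)
        out = exemplar_images(cv, ["a", "b", "c", "d"], self.groups())
        assert out["low"] == "a" and out["high"] == "c"

    def test_no_correct_classification_yields_none_with_warning(self, caplog):
        cv = CVResult(predicted=np.array(["high", "high", "high", "high"]),
                      posterior=np.full(4, 0.9), accuracy=0.5, n_folds=4)
        out = exemplar_images(cv, ["a", "b", "c", "d"], self.groups())
        assert out["low"] is None
        assert out["high"] is not None

    def test_separable_data_exemplar_has_extreme_posterior(self, small_groups,
                                                           small_stats):
        from matdecode.classification import loo_cv
        g = small_groups
        X = small_stats.loc[g.all_ids, ["hf_energy"]].to_numpy()
        X = np.hstack([X, X ** 2])
        y = np.array([0] * g.n + [1] * g.n)
        X[y == 1] += 100.0  # force separability
        cv = CVResult(*loo_cv(X, y).__dict__.values())
        labels = np.where(cv.predicted == 1, "high", "low")
        cv2 = CVResult(predicted=labels, posterior=cv.posterior,
                       accuracy=cv.accuracy, n_folds=cv.n_folds)
        out = exemplar_images(cv2, g.all_ids, g)
        idx = {i: k for k, i in enumerate(g.all_ids)}
        assert cv.posterior[idx[out["high"]]] > 0.99
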