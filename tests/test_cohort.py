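import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clincirc import (
    circular_mean_iqr,
    correlate_counts,
    entrainment_regression,
    prevalence_test,
    summarize_subjects,
    watson_u2,
)
from clincirc.fixtures import CLOCK_GENES


def _calls(counts: dict, genes=CLOCK_GENES, group=None):
    rows = []
    for subject, k in counts.items():
        for i, g in enumerate(genes):
            rows.append(
                {"subject": subject, "analyte": g, "circadian": i < k, "group": group}
            )
    return pd.DataFrame(rows)


class TestSummarize:
    def test_threshold_rule(self):
        summaries = summarize_subjects(_calls({"P1": 3, "P2": 0, "P3": 9}), K=3)
        by = {s.subject_id: s for s in summaries}
        assert by["P1"].n_rhythmic == 3 and by["P1"].classification == "standard"
        assert by["P2"].classification == "reduced"
        assert by["P3"].classification == "standard"

    @pytest.mark.parametrize("K,expected", [(2, "standard"), (3, "standard"), (4, "reduced")])
    def test_threshold_sensitivity(self, K, expected):
        (s,) = summarize_subjects(_calls({"P1": 3}), K=K)
        assert s.classification == expected

    def test_order_invariance(self):
        df = _calls({"P1": 4, "P2": 7})
        shuffled = df.sample(frac=1.0, random_state=0)
        a = {s.subject_id: s.n_rhythmic for s in summarize_subjects(df)}
        b = {s.subject_id: s.n_rhythmic for s in summarize_subjects(shuffled)}
        assert a == b

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_subjects(pd.DataFrame(columns=["subject", "analyte", "circadian"]))


class TestPrevalence:
    @staticmethod
    def _group(n_yes, n_total):
        return pd.DataFrame(
            {
                "subject": [f"s{i}" for i in range(n_total)],
                "analyte": "PER2",
                "circadian": [i < n_yes for i in range(n_total)],
            }
        )

    def test_identical_prevalence(self):
        r = prevalence_test(self._group(10, 20), self._group(10, 20), "PER2")
        assert r.chi2 == pytest.approx(0.0) and r.pvalue == pytest.approx(1.0)

    def test_extreme_difference(self):
        """Hand-computed 2x2 chi-square for 19/20 vs 1/20 is 32.4."""
        r = prevalence_test(self._group(19, 20), self._group(1, 20), "PER2")
        assert r.chi2 == pytest.approx(32.4, abs=1e-6)
        assert r.pvalue < 0.001

    def test_symmetry(self):
        a, b = self._group(15, 20), self._group(5, 20)
        assert prevalence_test(a, b, "PER2").pvalue == pytest.approx(
            prevalence_test(b, a, "PER2").pvalue
        )

    def test_degenerate_table(self):
        r = prevalence_test(self._group(0, 20), self._group(0, 20), "PER2")
        assert r.degenerate and r.pvalue == 1.0


class TestCorrelateCounts:
    def _summaries(self, counts):
        return summarize_subjects(_calls(dict(counts)))

    def test_perfect_positive_and_negative(self):
        summaries = self._summaries({"a": 1, "b": 2, "c": 3, "d": 4})
        cov = {"a": 2.0, "b": 4.0, "c": 6.0, "d": 8.0}
        r, r2, _ = correlate_counts(summaries, cov)
        assert r == pytest.approx(1.0) and r2 == pytest.approx(1.0)
        r, _, _ = correlate_counts(summaries, {k: -v for k, v in cov.items()})
        assert r == pytest.approx(-1.0)

    def test_permutation_null_centers_at_zero(self):
        summaries = self._summaries({f"s{i}": i % 9 for i in range(12)})
        cov_vals = np.arange(12.0)
        rng = np.random.default_rng(0)
        rs = []
        for _ in range(300):
            cov = dict(zip([f"s{i}" for i in range(12)], rng.permutation(cov_vals)))
            rs.append(correlate_counts(summaries, cov)[0])
        assert abs(np.mean(rs)) < 0.05

    def test_constant_covariate_errors(self):
        with pytest.raises(ValueError, match="constant"):
            correlate_counts(self._summaries({"a": 1, "b": 2, "c": 3}), {"a": 1, "b": 1, "c": 1})


class TestCircularMean:
    def test_wraparound(self):
        r = circular_mean_iqr([23.0, 1.0])
        assert r.mean_h == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_point_mass(self):
        r = circular_mean_iqr([6.0, 6.0, 6.0])
        assert r.mean_h == pytest.approx(6.0)
        assert r.iqr_low_h == pytest.approx(r.iqr_high_h)

    def test_uniform_undefined(self):
        assert not circular_mean_iqr([0.0, 6.0, 12.0, 18.0]).defined

    @pytest.mark.parametrize("delta", [1.0, 7.5, 13.0, 23.0])
    def test_rotation_equivariance(self, delta):
        base = [2.0, 3.0, 4.5, 22.0]
        r0 = circular_mean_iqr(base)
        r1 = circular_mean_iqr([(x + delta) % 24 for x in base])
        assert r1.mean_h == pytest.approx((r0.mean_h + delta) % 24, abs=1e-9)


class TestWatsonU2:
    def test_identical_samples(self):
        a = [1.0, 5.0, 9.0, 13.0, 17.0]
        u2, p = watson_u2(a, a)
        assert u2 < 0.05 and p > 0.5

    def test_separated_clusters(self):
        rng = np.random.default_rng(1)
        a = rng.normal(2, 0.5, 10) % 24
        b = rng.normal(14, 0.5, 10) % 24
        u2, p = watson_u2(a, b, method="permutation", n_perm=999, seed=0)
        assert p < 0.01

    def test_null_calibration(self):
        """Both samples from one wrapped distribution: rejection ~ alpha."""
        rng = np.random.default_rng(3)
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            a = rng.normal(6, 3, 12) % 24
            b = rng.normal(6, 3, 12) % 24
            _, p = watson_u2(a, b)
            hits += p < 0.05
        rate = hits / n_rep
        assert rate < 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep) + 0.01

    def test_ties_force_permutation(self):
        a = [1.0, 1.0, 5.0, 9.0]
        b = [1.0, 3.0, 7.0, 11.0]
        u2, p = watson_u2(a, b, n_perm=499, seed=1)
        assert 0.0 < p <= 1.0

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            watson_u2([1, 2, 3], [4, 5, 6, 7])


class TestEntrainment:
    def test_perfect_entrainment_with_wraparound(self):
        rng = np.random.default_rng(2)
        ev = {f"s{i}": float(e) for i, e in enumerate(rng.uniform(0, 24, 8))}
        for offset in (5.0, 12.0, 20.0):
            ac = {k: (v + offset) % 24 for k, v in ev.items()}
            fit = entrainment_regression(ac, ev)
            assert fit.slope == pytest.approx(1.0, abs=1e-9)
            assert fit.r2 == pytest.approx(1.0, abs=1e-9)
            assert fit.intercept == pytest.approx(offset, abs=1e-6)

    def test_constant_acrophase(self):
        ev = {f"s{i}": 3.0 * i for i in range(6)}
        ac = {k: 8.0 for k in ev}
        fit = entrainment_regression(ac, ev)
        assert fit.slope == pytest.approx(0.0, abs=1e-9)
        assert fit.r2 == pytest.approx(0.0, abs=1e-9)

    def test_noisy_slope_recovery(self):
        """Slope 1 with wrapped noise SD 1 h recovered within +/-0.15."""
        rng = np.random.default_rng(4)
        ev = {f"s{i}": float(e) for i, e in enumerate(rng.uniform(0, 24, 20))}
        ac = {k: (v + 5 + rng.standard_normal()) % 24 for k, v in ev.items()}
        fit = entrainment_regression(ac, ev)
        assert fit.slope == pytest.approx(1.0, abs=0.15)

    def test_narrow_event_span_warns(self):
        ev = {"a": 10.0, "b": 11.0, "c": 12.0}
        ac = {"a": 1.0, "b": 2.0, "c": 3.0}
        with pytest.warns(UserWarning, match="span"):
            fit = entrainment_regression(ac, ev)
        assert not fit.identifiable
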