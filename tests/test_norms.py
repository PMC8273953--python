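"""Normative regression fitting, built-in constants and model files."""

import io
import json
import math

import numpy as np
import pytest

from phescore import (
    Direction,
    FitError,
    Group,
    RawBattery,
    Subject,
    Test,
    ValidationError,
    builtin_cameroon_norms,
    correlate,
    fit_norms,
    fit_test_model,
    load_norms,
    save_norms,
    score_battery,
)

CAMEROON_TABLE = {
    Test.NCT_A: (125.62, 0.3, -4.47, 11.69),
    Test.NCT_B: (159.82, 1.39, -7.96, 24.65),
    Test.SDT: (78.89, 0.35, -1.6, 9.39),
    Test.LTT: (150.02, 0.11, -3.82, 15.10),
    Test.DST: (23.40, -0.20, 1.63, 3.24),
}


def _linear_sample(intercept, age_coef, edu_coef, n=40, seed=0, noise_sd=0.0,
                   target="nct_a"):
    """Volunteers whose `target` result follows a known linear model exactly."""
    rng = np.random.default_rng(seed)
    ages = rng.uniform(20, 70, n)
    edus = rng.uniform(4, 20, n)
    out = []
    for i in range(n):
        y = intercept + age_coef * ages[i] + edu_coef * edus[i]
        y += rng.normal(0, noise_sd) if noise_sd else 0.0
        fields = dict(nct_a=200.0, nct_b=200.0, sdt=200.0, ltt_time=200.0,
                      ltt_errors=0.0, dst=30.0)
        fields[target] = y
        out.append((Subject(id=f"v{i}", age=float(ages[i]), education=float(edus[i]),
                            group=Group.VOLUNTEER), RawBattery(**fields)))
    return out


class TestBuiltinNorms:
    @pytest.mark.parametrize("test", list(Test))
    def test_published_constants(self, cameroon, test):
        b0, ba, be, sd = CAMEROON_TABLE[test]
        norm = cameroon.norms[test]
        assert (norm.intercept, norm.age_coef, norm.edu_coef) == (b0, ba, be)
        assert norm.residual_sd == sd

    def test_directions_and_population_stats(self, cameroon):
        assert cameroon.norms[Test.DST].direction is Direction.HIGHER_IS_BETTER
        for t in (Test.NCT_A, Test.NCT_B, Test.SDT, Test.LTT):
            assert cameroon.norms[t].direction is Direction.HIGHER_IS_WORSE
        assert cameroon.phes_mean == -0.08
        assert cameroon.phes_sd == 1.28
        assert cameroon.cutoff == -3


class TestFitTestModel:
    def test_zero_noise_recovers_generating_coefficients(self):
        sample = _linear_sample(125.62, 0.3, -4.47)
        norm = fit_test_model(sample, Test.NCT_A)
        assert norm.intercept == pytest.approx(125.62, rel=1e-8)
        assert norm.age_coef == pytest.approx(0.3, rel=1e-8)
        assert norm.edu_coef == pytest.approx(-4.47, rel=1e-8)
        assert norm.residual_sd == pytest.approx(0.0, abs=1e-8)

    def test_parameter_recovery_nct_b(self):
        """n = 2000 noisy draws recover the generating model within 3 SE."""
        from phescore import gen_volunteers

        model = builtin_cameroon_norms()
        sample = gen_volunteers(2000, model, seed=1234)
        norm = fit_test_model(sample, Test.NCT_B)
        ages = np.array([s.age for s, _ in sample])
        edus = np.array([s.education for s, _ in sample])
        X = np.column_stack([np.ones_like(ages), ages, edus])
        se = 24.65 * np.sqrt(np.diag(np.linalg.inv(X.T @ X)))
        for got, true, se_j in zip(
            (norm.intercept, norm.age_coef, norm.edu_coef), (159.82, 1.39, -7.96), se
        ):
            assert abs(got - true) <= 3 * se_j
        assert norm.residual_sd == pytest.approx(24.65, rel=0.10)

    def test_ltt_fitted_on_error_adjusted_composite(self):
        """Splitting a fixed composite into (time, errors) leaves the fit unchanged."""
        sample = _linear_sample(150.02, 0.11, -3.82, target="ltt_time")
        recombined = []
        for k, (s, b) in enumerate(sample):
            errors = float(k % 30)
            recombined.append(
                (s, RawBattery(nct_a=b.nct_a, nct_b=b.nct_b, sdt=b.sdt,
                               ltt_time=b.ltt_time / (1 + errors / 100),
                               ltt_errors=errors, dst=b.dst))
            )
        norm = fit_test_model(recombined, Test.LTT)
        assert norm.intercept == pytest.approx(150.02, rel=1e-8)
        assert norm.edu_coef == pytest.approx(-3.82, rel=1e-8)

    def test_constant_education_is_rank_deficient(self):
        sample = _linear_sample(100.0, 0.5, 0.0)
        sample = [
            (Subject(id=s.id, age=s.age, education=12.0, group=s.group), b)
            for s, b in sample
        ]
        with pytest.raises(FitError, match="education"):
            fit_test_model(sample, Test.NCT_A)

    def test_small_sample_rejected(self):
        sample = _linear_sample(100.0, 0.5, -1.0, n=9)
        with pytest.raises(FitError, match="10"):
            fit_test_model(sample, Test.NCT_A)

    def test_per_test_complete_case(self):
        """A subject missing one result drops out of that fit only."""
        sample = _linear_sample(125.62, 0.3, -4.47, n=30)
        sample[0][1].nct_b = None
        norm_b = fit_test_model(sample, Test.NCT_B)  # fits on the remaining 29
        norm_a = fit_test_model(sample, Test.NCT_A)
        assert norm_a.intercept == pytest.approx(125.62, rel=1e-8)
        assert norm_b.residual_sd >= 0

    def test_residual_sd_shift_equivariance(self):
        """Adding a constant to every observation leaves the residual SD unchanged."""
        sample = _linear_sample(100.0, 0.5, -2.0, noise_sd=8.0, seed=5)
        shifted = [
            (s, RawBattery(**{**b.__dict__, "nct_a": b.nct_a + 500.0}))
            for s, b in sample
        ]
        sd0 = fit_test_model(sample, Test.NCT_A).residual_sd
        sd1 = fit_test_model(shifted, Test.NCT_A).residual_sd
        assert sd1 == pytest.approx(sd0, rel=1e-9)

    def test_volunteers_only_enter_the_fit(self):
        sample = _linear_sample(125.62, 0.3, -4.47, n=30)
        # Contaminate with off-model cirrhotic rows; the fit must ignore them.
        for i in range(30):
            sample.append(
                (Subject(id=f"c{i}", age=50.0 + i / 10, education=5.0 + (i % 7),
                         group=Group.CIRRHOTIC),
                 RawBattery(nct_a=1000.0, nct_b=200.0, sdt=200.0,
                            ltt_time=200.0, ltt_errors=0.0, dst=30.0))
            )
        norm = fit_test_model(sample, Test.NCT_A)
        assert norm.intercept == pytest.approx(125.62, rel=1e-8)


class TestFitNorms:
    def test_self_normalisation(self, volunteer_sample):
        """Norms fitted on a sample score that sample near PHES 0."""
        model = fit_norms(volunteer_sample, name="self")
        phes = [score_battery(s, b, model).phes for s, b in volunteer_sample]
        assert -0.6 <= float(np.mean(phes)) <= 0.4
        assert model.cutoff <= 0


class TestCorrelate:
    def _scored(self, sample, model):
        return [(s, b, score_battery(s, b, model)) for s, b in sample]

    def test_perfect_linear_dependence(self, cameroon):
        sample = []
        rng = np.random.default_rng(7)
        for i in range(20):
            age = float(rng.uniform(20, 60))
            sample.append(
                (Subject(id=f"v{i}", age=age, education=10.0 + i % 5, group=Group.VOLUNTEER),
                 RawBattery(nct_a=2 * age, nct_b=100.0, sdt=60.0, ltt_time=100.0,
                            ltt_errors=0.0, dst=30.0))
            )
        table = correlate(self._scored(sample, cameroon))
        row = table[(table.measure == "NCT_A") & (table.predictor == "age")].iloc[0]
        assert row.pearson_r == pytest.approx(1.0)

    def test_education_correlation_signs(self, cameroon, volunteer_sample):
        """Higher education predicts faster times and more DST points."""
        table = correlate(self._scored(volunteer_sample, cameroon))
        by = {(r.measure, r.predictor): r for r in table.itertuples()}
        assert by[("DST", "education")].pearson_r > 0
        assert by[("NCT_A", "education")].pearson_r < 0
        # PHES itself carries no education signal here: scored against the
        # generating norms, the age/education effect is removed exactly.
        assert by[("PHES", "education")].defined

    def test_small_sample_rejected(self, cameroon, volunteer_sample):
        with pytest.raises(ValueError):
            correlate(self._scored(volunteer_sample[:2], cameroon))

    def test_zero_variance_flags_not_crashes(self, cameroon):
        sample = [
            (Subject(id=f"v{i}", age=30.0, education=float(5 + i), group=Group.VOLUNTEER),
             RawBattery(nct_a=80.0 + i, nct_b=100.0, sdt=60.0, ltt_time=100.0,
                        ltt_errors=0.0, dst=30.0))
            for i in range(10)
        ]
        table = correlate(self._scored(sample, cameroon))
        age_rows = table[table.predictor == "age"]
        assert (~age_rows.defined).all()
        assert age_rows.pearson_r.isna().all()


class TestNormFiles:
    def test_round_trip_identity(self, cameroon, tmp_path):
        path = tmp_path / "norms.json"
        save_norms(cameroon, path)
        loaded = load_norms(path)
        assert loaded == cameroon

    def test_stream_round_trip(self, cameroon):
        buf = io.StringIO()
        save_norms(cameroon, buf)
        buf.seek(0)
        assert load_norms(buf) == cameroon

    def _payload(self, cameroon):
        buf = io.StringIO()
        save_norms(cameroon, buf)
        return json.loads(buf.getvalue())

    def test_missing_test_entry_named(self, cameroon):
        payload = self._payload(cameroon)
        del payload["norms"]["LTT"]
        with pytest.raises(ValidationError, match="LTT"):
            load_norms(io.StringIO(json.dumps(payload)))

    def test_nonpositive_sd_rejected(self, cameroon):
        payload = self._payload(cameroon)
        payload["norms"]["SDT"]["residual_sd"] = 0.0
        with pytest.raises(ValidationError, match="residual_sd"):
            load_norms(io.StringIO(json.dumps(payload)))

    def test_unknown_test_name_rejected(self, cameroon):
        payload = self._payload(cameroon)
        payload["norms"]["TMT"] = payload["norms"]["NCT_A"]
        with pytest.raises(ValidationError, match="TMT"):
            load_norms(io.StringIO(json.dumps(payload)))
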