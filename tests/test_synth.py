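"""Synthetic study generator: determinism, censoring, round-trips, recovery."""

import math

import numpy as np
import pytest

from tracerisk import core, quantify, risk, synth


@pytest.fixture(scope="module")
def config():
    return synth.SyntheticConfig(seed=11)


@pytest.fixture(scope="module")
def noise_free():
    return synth.SyntheticConfig(seed=11, reading_noise_cv=0.0, blank_level=0.0)


class TestGenerateConcentrations:
    def test_default_design_sizes(self, config):
        records = synth.generate_concentrations(config)
        # 6 markets x 3 chickens x 6 parts x 6 elements
        assert len(records) == 6 * 3 * 6 * 6
        per_element = sum(1 for r in records if r.element == "Pb")
        assert per_element == 108  # part-samples per element

    def test_deterministic_under_seed(self, config):
        a = synth.generate_concentrations(config, seed=5)
        b = synth.generate_concentrations(config, seed=5)
        c = synth.generate_concentrations(config, seed=6)
        assert [r.mean_conc for r in a] == [r.mean_conc for r in b]
        assert [r.mean_conc for r in a] != [r.mean_conc for r in c]

    def test_gsd_one_degenerates_to_median(self):
        params = {(p, e): (1.7, 1.0) for p in core.BODY_PARTS for e in core.ELEMENTS}
        cfg = synth.SyntheticConfig(conc_params=params, seed=1)
        records = synth.generate_concentrations(cfg)
        assert all(r.mean_conc == pytest.approx(1.7, rel=1e-12) for r in records)

    def test_invalid_params_rejected(self):
        bad = {(p, e): (0.0, 2.0) for p in core.BODY_PARTS for e in core.ELEMENTS}
        with pytest.raises(core.ValidationError):
            synth.SyntheticConfig(conc_params=bad)

    def test_parameter_recovery_at_n200(self):
        """Sample geometric mean of each cell is within 3 geometric SEs of
        the configured median at 200 chickens per market."""
        cfg = synth.SyntheticConfig(n_markets=1, n_chickens_per_market=200, seed=3)
        records = synth.generate_concentrations(cfg)
        by_cell: dict[tuple[str, str], list[float]] = {}
        for r in records:
            by_cell.setdefault((r.body_part, r.element), []).append(r.mean_conc)
        for key, vals in by_cell.items():
            median, gsd = cfg.conc_params[key]
            logs = np.log(vals)
            se = math.log(gsd) / math.sqrt(len(vals))
            assert abs(logs.mean() - math.log(median)) < 3 * se, key


class TestMomentMatching:
    def test_matches_market_mean_and_sd(self, survey):
        """The fitted lognormal reproduces the first two moments of each
        cell's detected market means."""
        params = synth.fit_lognormal_params(survey)
        detected: dict[tuple[str, str], list[float]] = {}
        for r in survey:
            if not r.bdl:
                detected.setdefault((r.body_part, r.element), []).append(r.mean_conc)
        for key, vals in detected.items():
            if len(vals) < 2 or np.std(vals, ddof=1) == 0:
                continue
            median, gsd = params[key]
            sigma2 = math.log(gsd) ** 2
            mean_ln = median * math.exp(sigma2 / 2)
            var_ln = median**2 * math.exp(sigma2) * (math.exp(sigma2) - 1)
            assert mean_ln == pytest.approx(np.mean(vals), rel=1e-9)
            assert math.sqrt(var_ln) == pytest.approx(np.std(vals, ddof=1), rel=1e-9)


class TestCensoring:
    def test_zero_limits_no_censoring(self, config):
        records = synth.generate_concentrations(config)
        censored, frac = synth.censor_bdl(records, {e: 0.0 for e in core.ELEMENTS})
        assert frac == 0.0
        assert not any(r.bdl for r in censored)

    def test_huge_limits_censor_everything(self, config):
        records = synth.generate_concentrations(config)
        censored, frac = synth.censor_bdl(records, {e: 1e9 for e in core.ELEMENTS})
        assert frac == 1.0
        assert all(r.bdl for r in censored)

    def test_limit_at_median_censors_half(self):
        params = {(p, e): (0.02, 2.0) for p in core.BODY_PARTS for e in core.ELEMENTS}
        cfg = synth.SyntheticConfig(
            n_markets=1, n_chickens_per_market=1000,
            body_parts=("muscle",), elements=("Cd",),
            conc_params=params, seed=9,
        )
        records = synth.generate_concentrations(cfg)
        _, frac = synth.censor_bdl(records, {"Cd": 0.02})
        # binomial(1000, 0.5): 4 sigma is about 0.063
        assert frac == pytest.approx(0.5, abs=0.065)

    def test_cd_and_cr_censored_most(self, config):
        """Default detection limits reproduce the qualitative censoring
        pattern: Cd and Cr are the most-censored elements."""
        study = synth.simulate_study(config)
        frac = {}
        for el in core.ELEMENTS:
            rows = [r for r in study["records"] if r.element == el]
            frac[el] = sum(r.bdl for r in rows) / len(rows)
        worst_two = sorted(frac, key=frac.get, reverse=True)[:2]
        assert set(worst_two) == {"Cd", "Cr"}


class TestReadingsRoundTrip:
    def test_noise_free_exact_inverse(self, noise_free):
        records = synth.generate_concentrations(noise_free)[:50]
        readings = synth.emit_readings(records, noise_free)
        assert len(readings) == 50 * noise_free.replicates
        by_sample: dict[str, list[float]] = {}
        for rd in readings:
            conc, clamped = quantify.concentration_from_reading(rd)
            assert not clamped
            by_sample.setdefault(rd.sample_id, []).append(conc)
        for i, rec in enumerate(records):
            got = np.mean(by_sample[f"S{i:04d}"])
            assert got == pytest.approx(rec.mean_conc, rel=1e-12)

    def test_expected_reading_for_known_concentration(self, noise_free):
        rec = core.ConcentrationRecord("m", "muscle", "Pb", mean_conc=10.0)
        readings = synth.emit_readings([rec], noise_free)
        assert all(r.reading == pytest.approx(0.2, rel=1e-12) for r in readings)

    def test_noisy_mean_recovers_concentration(self):
        cfg = synth.SyntheticConfig(seed=21, reading_noise_cv=0.02)
        rec = core.ConcentrationRecord("m", "muscle", "Fe", mean_conc=5.0)
        readings = synth.emit_readings([rec] * 1000, cfg)
        concs = [quantify.concentration_from_reading(r)[0] for r in readings]
        assert np.mean(concs) == pytest.approx(5.0, rel=5e-3)


class TestRecoverySet:
    def test_noise_free_recovers_configured_truth(self, noise_free):
        results = synth.generate_recovery_set(noise_free)
        for r in results:
            expected = 100.0 * noise_free.recovery_true[r.element]
            assert r.recovery_pct == pytest.approx(expected, rel=1e-12)

    def test_unit_recovery_is_100(self):
        cfg = synth.SyntheticConfig(
            seed=1, reading_noise_cv=0.0,
            recovery_true={e: 1.0 for e in core.ELEMENTS},
        )
        results = synth.generate_recovery_set(cfg)
        assert all(r.recovery_pct == pytest.approx(100.0) for r in results)

    def test_noisy_mean_recovery_within_one_point(self):
        cfg = synth.SyntheticConfig(seed=2, reading_noise_cv=0.02)
        results = synth.generate_recovery_set(cfg, spike_levels=(1.0,) * 40)
        for el in core.ELEMENTS:
            vals = [r.recovery_pct for r in results if r.element == el]
            assert np.mean(vals) == pytest.approx(100.0 * cfg.recovery_true[el], abs=1.0)


class TestEndToEnd:
    def test_generate_quantify_summarize_assess_recovers_truth(self, specs, adult):
        """Simulated readings, re-quantified, summarised and fed through
        the intake computation, land near the indices implied by the
        generating lognormal means."""
        cfg = synth.SyntheticConfig(seed=17, n_chickens_per_market=30)
        study = synth.simulate_study(cfg)
        # re-quantify each sample from its replicate readings
        by_sample: dict[str, list[float]] = {}
        meta: dict[str, tuple[str, str, str]] = {}
        for rd in study["readings"]:
            by_sample.setdefault(rd.sample_id, []).append(
                quantify.concentration_from_reading(rd)[0]
            )
            meta[rd.sample_id] = (rd.market, rd.body_part, rd.element)
        requant = [
            core.ConcentrationRecord(
                market=meta[s][0], body_part=meta[s][1], element=meta[s][2],
                mean_conc=float(np.mean(v)),
            )
            for s, v in by_sample.items()
        ]
        sums = {
            (s.body_part, s.element): s for s in quantify.summarize(requant, "zero")
        }
        for el in ("Pb", "Fe", "Zn"):  # elements with negligible censoring
            median, gsd = cfg.conc_params[("muscle", el)]
            true_mean = median * np.exp(np.log(gsd) ** 2 / 2)
            expected = risk.edi(true_mean, adult)
            got = risk.edi(sums[("muscle", el)].overall_mean, adult)
            assert got == pytest.approx(expected, rel=0.15), el

    def test_chicken_level_records_rejected_by_assess(self, specs, scenarios):
        cfg = synth.SyntheticConfig(seed=17)
        records = synth.generate_concentrations(cfg)
        with pytest.raises(core.ValidationError, match="duplicate cell"):
            risk.assess(records, specs, scenarios, body_part="muscle")
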