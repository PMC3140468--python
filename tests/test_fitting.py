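"""Marginalized posterior ratio, greedy matching pursuit, two-pass sorting."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import multivariate_normal

from spikesort.data import Clip
from spikesort.fitting import (
    FitConfig,
    _embed,
    assignments_frame,
    best_single_fit,
    detect_incomplete,
    greedy_fit,
    log_posterior_ratio,
    subtract_fit,
    update_priors,
)
from spikesort.noise_model import NoiseModel
from spikesort.synthetic import SimConfig, _add_spike, make_templates
from spikesort.templates import Template, make_phases

UP = 5


def _simple_template(rng, depth=-60.0, mu=1.0, sd=0.1, rate=5.0, unit_id=0, leader=0,
                     n_rows=2, Wu=40):
    """Small template living on explicit channels for oracle-sized problems."""
    wave = np.zeros((9, Wu))
    t = np.arange(Wu)
    wave[4] = depth * np.exp(-0.5 * ((t - Wu // 2) / 4.0) ** 2)
    if n_rows > 1:
        wave[1] = 0.5 * wave[4]
    chidx = np.full(9, -1)
    chidx[4] = 0
    if n_rows > 1:
        chidx[1] = 1
    valid = chidx >= 0
    return Template(wave, leader, chidx, valid, make_phases(wave), amp_mean=mu,
                    amp_sd=sd, rate_hz=rate, unit_id=unit_id)


def _quadrature_oracle(V, tpl, phase, t, nm):
    """Direct 1-D integration of the marginalized posterior ratio."""
    n_ch, n = V.shape
    T = _embed(tpl, phase, t, n_ch, n)
    C = nm.dense_covariance(n)
    mu, sd, r = tpl.amp_mean, tpl.amp_sd, tpl.rate_hz

    def loglik(x):
        return sum(multivariate_normal.logpdf(x[i], cov=C) for i in range(n_ch))

    base = loglik(V)

    def integrand(lam):
        return (
            np.exp(loglik(V - lam * T) - base)
            * np.exp(-((lam - mu) ** 2) / (2 * sd**2))
            / np.sqrt(2 * np.pi * sd**2)
        )

    A_d = sum(T[i] @ np.linalg.solve(C, T[i]) for i in range(n_ch)) + 1 / sd**2
    b_d = sum(T[i] @ np.linalg.solve(C, V[i]) for i in range(n_ch)) + mu / sd**2
    lam_c, w = b_d / A_d, 1 / np.sqrt(A_d)
    lo = min(mu - 10 * sd, lam_c - 12 * w)
    hi = max(mu + 10 * sd, lam_c + 12 * w)
    val, _ = quad(integrand, lo, hi, limit=400,
                  points=[lam_c, mu], epsabs=1e-300, epsrel=1e-12)
    return np.log(r * nm.dt) + np.log(val)


class TestLogPosteriorRatio:
    def test_matches_quadrature_on_random_instances(self, rng):
        """Closed-form Gaussian marginalization == numerical quadrature."""
        worst = 0.0
        for _ in range(30):
            nm = NoiseModel(
                sigma=float(rng.uniform(0.5, 2.0)),
                tau=float(rng.uniform(0.5, 5.0)) * 1e-4,
                dt=1e-4,
            )
            tpl = _simple_template(
                rng,
                depth=float(rng.uniform(-8, -2)),
                mu=float(rng.uniform(0.5, 1.5)),
                sd=float(rng.uniform(0.05, 0.3)),
                rate=float(rng.uniform(0.5, 20)),
                Wu=30,
            )
            V = nm.sigma * rng.standard_normal((2, 8))
            phase = int(rng.integers(0, 5))
            t = int(rng.integers(1, 7))
            ours = log_posterior_ratio(V, tpl, phase, t, nm)
            oracle = _quadrature_oracle(V, tpl, phase, t, nm)
            worst = max(worst, abs(ours - oracle) / max(abs(oracle), 1.0))
        assert worst < 1e-6

    def test_exact_signal_explains_full_energy(self):
        """V = mu T with a tight prior: log ratio -> log(r dt) + mu^2 |T|^2 / 2."""
        nm = NoiseModel(sigma=1.0, tau=1e-9, dt=1e-4)  # white, unit sd
        rng = np.random.default_rng(0)
        tpl = _simple_template(rng, depth=-6.0, mu=1.2, sd=1e-4, rate=5.0, Wu=40)
        n = 40
        V = np.zeros((2, n))
        T = _embed(tpl, 0, n // 2, 2, n)
        V += tpl.amp_mean * T
        got = log_posterior_ratio(V, tpl, 0, n // 2, nm)
        expected = np.log(tpl.rate_hz * nm.dt) + tpl.amp_mean**2 * np.sum(T**2) / 2
        assert got == pytest.approx(expected, rel=1e-3)

    def test_silence_rejects_large_spike(self, rng):
        nm = NoiseModel(sigma=1.0, tau=1e-9, dt=1e-4)
        tpl = _simple_template(rng, depth=-8.0, mu=1.0, sd=0.1, rate=5.0)
        V = np.zeros((2, 40))
        assert log_posterior_ratio(V, tpl, 0, 20, nm) < 0

    def test_zero_prior_sd_plugin_limit(self, rng):
        nm = NoiseModel(sigma=1.0, tau=1e-9, dt=1e-4)
        tpl = _simple_template(rng, sd=0.0)
        V = rng.standard_normal((2, 40))
        with pytest.warns(UserWarning, match="plug-in"):
            val = log_posterior_ratio(V, tpl, 0, 20, nm)
        assert np.isfinite(val)

    def test_scale_consistency(self, rng):
        """Scaling noise sd, templates, and data together changes nothing."""
        nm1 = NoiseModel(sigma=1.0, tau=2e-4, dt=1e-4)
        nm2 = NoiseModel(sigma=3.0, tau=2e-4, dt=1e-4)
        tpl1 = _simple_template(rng, depth=-6.0)
        tpl2 = _simple_template(rng, depth=-18.0)
        V = rng.standard_normal((2, 40))
        r1 = log_posterior_ratio(V, tpl1, 2, 20, nm1)
        r2 = log_posterior_ratio(3 * V, tpl2, 2, 20, nm2)
        assert r1 == pytest.approx(r2, rel=1e-9)


class TestBestSingleFit:
    def test_recovers_planted_unit_and_time(self, sim_config, small_bank, noise_model, rng):
        geom = sim_config.geometry
        config = FitConfig()
        hits = 0
        n_trials = 60
        for _ in range(n_trials):
            u = int(rng.integers(len(small_bank)))
            v = noise_model.sigma * rng.standard_normal((geom.n_electrodes, 64))
            # mild temporal correlation mismatch is fine for recovery
            _add_spike(v, small_bank[u], 32, 0, 1.0)
            c, phase, t, sums = best_single_fit(v, small_bank, noise_model, config, geom)
            if c == small_bank[u].unit_id and abs(t - 32) <= 1:
                hits += 1
        assert hits >= 0.95 * n_trials

    def test_pure_noise_rarely_accepted(self, sim_config, small_bank, noise_model, rng):
        geom = sim_config.geometry
        config = FitConfig()
        accepts = 0
        n_trials = 100
        for _ in range(n_trials):
            v = noise_model.sigma * rng.standard_normal((geom.n_electrodes, 64))
            try:
                _, _, _, sums = best_single_fit(v, small_bank, noise_model, config, geom)
            except ValueError:
                continue
            if sums and max(sums.values()) > 0:
                accepts += 1
        assert accepts <= 0.02 * n_trials

    def test_amplitude_prior_discriminates_same_shape_units(self, rng, geometry):
        """Two identical shapes differing 3x in scale: big spikes go to the big unit."""
        nm = NoiseModel(sigma=1.0, tau=1e-9, dt=1e-4)
        small = _simple_template(rng, depth=-6.0, mu=1.0, sd=0.1, rate=5.0, unit_id=0)
        big = _simple_template(rng, depth=-18.0, mu=1.0, sd=0.1, rate=5.0, unit_id=1)
        config = FitConfig()
        wins = 0
        for _ in range(40):
            v = rng.standard_normal((30, 64))
            lam = float(rng.normal(1.0, 0.1))
            _add_spike(v, big, 32, 0, lam)
            c, _, _, _ = best_single_fit(v, [small, big], nm, config, geometry)
            wins += c == 1
        assert wins >= 38  # >= 95%

    def test_empty_bank_rejected(self, noise_model, geometry):
        with pytest.raises(ValueError, match="empty"):
            best_single_fit(np.zeros((30, 64)) - 1, [], noise_model, FitConfig(), geometry)


class TestSubtract:
    def test_noiseless_scaled_template(self, rng, geometry):
        tpl = _simple_template(rng)
        v = np.zeros((30, 64))
        _add_spike(v, tpl, 30, 0, 1.1)
        res, lam, t_sub, phase = subtract_fit(v, tpl, 30)
        assert lam == pytest.approx(1.1, rel=1e-9)
        assert np.linalg.norm(res) < 1e-6 * np.linalg.norm(v)

    def test_subsample_shift_selects_matching_phase(self, rng, geometry):
        tpl = _simple_template(rng)
        v = np.zeros((30, 64))
        _add_spike(v, tpl, 30, 3, 1.0)
        res, lam, t_sub, phase = subtract_fit(v, tpl, 30)
        assert phase == 3
        assert np.linalg.norm(res) < 1e-6

    def test_matches_amplitude_prior_formula(self, rng):
        from spikesort.templates import amplitude_prior

        tpl = _simple_template(rng)
        v = np.zeros((30, 64))
        _add_spike(v, tpl, 32, 0, 0.93)
        res, lam, _, _ = subtract_fit(v, tpl, 32)
        # same closed form as the prior's per-event lambda-hat
        W = tpl.phases[0].shape[1]
        ev = np.zeros((1, 9, W))
        for slot, ch in enumerate(tpl.channel_indices):
            if ch >= 0:
                ev[0, slot] = v[ch, 32 - W // 2 : 32 + W - W // 2]
        mu, _ = amplitude_prior(ev, tpl.phases[0])
        assert lam == pytest.approx(mu, rel=1e-9)

    def test_wrong_polarity_rejected(self, rng):
        tpl = _simple_template(rng)
        v = np.zeros((30, 64))
        _add_spike(v, tpl, 30, 0, 1.0)
        assert subtract_fit(-v, tpl, 30) is None


class TestGreedy:
    def test_silent_event_empty(self, small_bank, noise_model, geometry):
        fits, res = greedy_fit(np.zeros((30, 64)), small_bank, noise_model, FitConfig(), geometry)
        assert fits == []

    def test_three_overlapping_spikes_recovered(self, sim_config, small_bank, noise_model, rng):
        geom = sim_config.geometry
        config = FitConfig()
        n_trials = 40
        n_found = 0
        n_extra = 0
        n_planted = 0
        for _ in range(n_trials):
            v = noise_model.sigma * rng.standard_normal((geom.n_electrodes, 96))
            units = rng.choice(len(small_bank), 3, replace=False)
            planted = []
            for u in units:
                t = int(rng.integers(35, 65))
                _add_spike(v, small_bank[u], t, 0, max(rng.normal(1.0, 0.1), 0.1))
                planted.append((small_bank[u].unit_id, t))
            fits, _ = greedy_fit(v, small_bank, noise_model, config, geom)
            n_planted += 3
            got = [(f.unit_id, round(f.time_s / noise_model.dt)) for f in fits]
            for u, t in planted:
                if any(gu == u and abs(gt - t) <= 5 for gu, gt in got):
                    n_found += 1
            n_extra += max(0, len(got) - 3)
        assert n_found / n_planted >= 0.95
        assert n_extra / n_planted <= 0.05

    def test_burst_of_varying_amplitudes(self, sim_config, small_bank, noise_model, rng):
        """Five spikes of one unit at 0.7-1.3x the mean amplitude all recovered."""
        geom = sim_config.geometry
        tpl = small_bank[0]
        v = noise_model.sigma * rng.standard_normal((geom.n_electrodes, 400))
        lams = [0.7, 0.85, 1.0, 1.15, 1.3]
        times = [60, 120, 190, 260, 330]
        for t, lam in zip(times, lams):
            _add_spike(v, tpl, t, 0, lam)
        fits, _ = greedy_fit(v, small_bank, noise_model, FitConfig(), geom)
        mine = sorted((f for f in fits if f.unit_id == tpl.unit_id), key=lambda f: f.time_s)
        assert len(mine) == 5
        for f, t, lam in zip(mine, times, lams):
            assert abs(f.time_s / noise_model.dt - t) <= 1
            assert abs(f.lam - lam) <= 0.1

    def test_energy_decreases_at_each_accepted_step(self, sim_config, small_bank, noise_model, rng):
        geom = sim_config.geometry
        v = noise_model.sigma * rng.standard_normal((geom.n_electrodes, 96))
        for u in (0, 1):
            _add_spike(v, small_bank[u], 40 + 20 * u, 0, 1.0)
        # re-run the loop manually to observe energies
        from spikesort.fitting import _scan_candidates

        config = FitConfig()
        event = v.copy()
        energies = [noise_model.quadratic_form(event, event)]
        for _ in range(10):
            table = _scan_candidates(event, small_bank, noise_model, config, geom)
            if table.best is None or max(table.per_unit_sum.values()) <= 0:
                break
            by_id = {t.unit_id: t for t in small_bank}
            sub = subtract_fit(event, by_id[table.best[0]], table.best[2], config)
            if sub is None:
                break
            event = sub[0]
            energies.append(noise_model.quadratic_form(event, event))
        assert len(energies) >= 3
        assert all(b < a for a, b in zip(energies, energies[1:]))

    def test_acceptance_threshold_consistency(self, sim_config, small_bank, noise_model, rng):
        geom = sim_config.geometry
        for _ in range(10):
            v = noise_model.sigma * rng.standard_normal((geom.n_electrodes, 64))
            if rng.random() < 0.7:
                u = int(rng.integers(len(small_bank)))
                _add_spike(v, small_bank[u], 32, 0, 1.0)
            fits, _ = greedy_fit(v, small_bank, noise_model, FitConfig(), geom)
            for f in fits:
                assert f.log_ratio > 0  # summed ratio exceeded 1 at acceptance


class TestIncompleteAndPriors:
    def test_clean_fit_not_incomplete(self, rng):
        assert not detect_incomplete(rng.standard_normal((30, 64)), -40.0)

    def test_unknown_template_flags_incomplete(self, sim_config, small_bank, noise_model, rng):
        geom = sim_config.geometry
        held_out = small_bank[-1]
        bank = small_bank[:-1]
        v = noise_model.sigma * rng.standard_normal((geom.n_electrodes, 64))
        _add_spike(v, held_out, 32, 0, 1.0)
        fits, res = greedy_fit(v, bank, noise_model, FitConfig(), geom)
        assert detect_incomplete(res, -4 * noise_model.sigma)

    def test_pure_noise_rarely_incomplete(self, noise_model, rng):
        flags = sum(
            detect_incomplete(noise_model.sigma * rng.standard_normal((30, 32)), -4 * noise_model.sigma)
            for _ in range(200)
        )
        # a 4-sigma excursion somewhere in 960 white samples is uncommon but
        # not negligible; well-modeled noise stays mostly below threshold
        assert flags <= 10

    def test_update_priors_rates_and_amplitudes(self, small_bank):
        import pandas as pd

        rows = []
        rng = np.random.default_rng(0)
        for k in range(200):
            rows.append({"unit_id": 0, "time_s": 0.01 * k, "lam": float(rng.normal(1.1, 0.05)),
                         "log_ratio": 1.0, "fit_pass": 1, "clip_index": k})
        df = pd.DataFrame(rows)
        updated = update_priors(df, 100.0, small_bank)
        assert updated[0].rate_hz == pytest.approx(2.0)
        assert updated[0].amp_mean == pytest.approx(1.1, abs=0.02)
        # unfit units keep their priors
        assert updated[1].amp_mean == small_bank[1].amp_mean

    def test_zero_duration_rejected(self, small_bank):
        import pandas as pd

        with pytest.raises(ValueError, match="duration"):
            update_priors(pd.DataFrame({"unit_id": [], "lam": []}), 0.0, small_bank)
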