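"""FBCSP components: filter bank, CSP eigenproblem, features, MIBIF, metrics."""

import numpy as np
import pytest
from scipy import linalg

from lmbci.errors import ConfigError, DegenerateInputError
from lmbci.fbcsp import (
    FILTER_BANK,
    FBCSPClassifier,
    compute_metrics,
    csp_fit,
    extract_features,
    filter_bank,
    mibif_select,
)

FS = 160.0


def trials_with_covariance(cov, n_trials, n_samples, rng):
    """Trials whose per-trial sample covariance is exactly ``cov``.

    Empirically whiten white noise, then color by the Cholesky factor,
    so the CSP inputs equal the analytic covariances with no sampling
    error.
    """
    n_ch = cov.shape[0]
    left = linalg.cholesky(cov, lower=True)
    out = np.empty((n_trials, n_ch, n_samples))
    for t in range(n_trials):
        x = rng.standard_normal((n_ch, n_samples))
        x -= x.mean(axis=1, keepdims=True)
        emp = x @ x.T / n_samples
        white = linalg.inv(linalg.cholesky(emp, lower=True)) @ x
        out[t] = left @ white
    return out


def random_spd(n, rng):
    a = rng.standard_normal((n, n))
    return a @ a.T + n * np.eye(n)


class TestFilterBank:
    def test_tone_lands_in_its_band(self):
        t = np.arange(480) / FS
        for freq, band_idx in ((10.0, 0), (30.0, 5)):
            x = np.sin(2 * np.pi * freq * t)[None, None, :]
            banded = filter_bank(x, FS)
            energies = [b[0, 0, 100:380].var() for b in banded]
            assert int(np.argmax(energies)) == band_idx
            assert energies[band_idx] > 10 * sorted(energies)[-2]

    def test_white_noise_spreads_over_equal_width_bands(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((1, 1, 160000))
        banded = filter_bank(x, FS)
        # bands 2-6 all span 4 Hz; their variances agree within 20 %
        variances = [b[0, 0].var() for b in banded[1:]]
        assert max(variances) / min(variances) < 1.2

    def test_nyquist_guard(self):
        with pytest.raises(ConfigError):
            filter_bank(np.zeros((1, 1, 100)), 60.0)


class TestCSP:
    def test_known_variance_ratio_recovers_eigenvalue(self):
        rng = np.random.default_rng(1)
        ca = np.diag([4.0, 1.0, 1.0, 1.0])
        cb = np.eye(4)
        xa = trials_with_covariance(ca, 6, 400, rng)
        xb = trials_with_covariance(cb, 6, 400, rng)
        csp = csp_fit(xa, xb, n_pairs=1)
        # trace normalization rescales: top eigenvalue solves the
        # normalized pencil; compute the oracle from normalized covs
        can, cbn = ca / np.trace(ca), cb / np.trace(cb)
        expected = linalg.eigh(can, can + cbn, eigvals_only=True)[-1]
        assert csp.eigenvalues[0] == pytest.approx(expected, abs=1e-9)
        # top filter aligned with channel 0
        w = csp.filters[0] / np.abs(csp.filters[0]).max()
        assert np.abs(w[0]) == pytest.approx(1.0)
        assert np.all(np.abs(w[1:]) < 0.05)

    def test_identical_covariances_give_half_eigenvalues(self):
        rng = np.random.default_rng(2)
        c = random_spd(5, rng)
        x = trials_with_covariance(c, 5, 300, rng)
        csp = csp_fit(x, x.copy(), n_pairs=2)
        np.testing.assert_allclose(csp.eigenvalues, 0.5, atol=1e-9)

    def test_label_swap_reverses_spectrum(self):
        rng = np.random.default_rng(3)
        xa = trials_with_covariance(random_spd(5, rng), 5, 300, rng)
        xb = trials_with_covariance(random_spd(5, rng), 5, 300, rng)
        ab = csp_fit(xa, xb)
        ba = csp_fit(xb, xa)
        np.testing.assert_allclose(ab.eigenvalues, 1 - ba.eigenvalues[::-1], atol=1e-9)

    def test_matches_whitening_oracle_on_random_pairs(self):
        # independent route: whiten the composite covariance, then
        # eigendecompose the whitened class-a covariance
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = rng.integers(3, 9)
            ca = random_spd(n, rng)
            cb = random_spd(n, rng)
            xa = trials_with_covariance(ca, 4, 40 * n, rng)
            xb = trials_with_covariance(cb, 4, 40 * n, rng)
            csp = csp_fit(xa, xb, n_pairs=1)
            can, cbn = ca / np.trace(ca), cb / np.trace(cb)
            comp = can + cbn
            evals, evecs = linalg.eigh(comp)
            whit = evecs @ np.diag(evals**-0.5) @ evecs.T
            lam = np.sort(linalg.eigh(whit @ can @ whit, eigvals_only=True))[::-1]
            np.testing.assert_allclose(csp.eigenvalues, lam, atol=1e-8)

    def test_too_few_trials_rejected(self):
        with pytest.raises(DegenerateInputError):
            csp_fit(np.zeros((1, 4, 100)), np.zeros((5, 4, 100)))


class TestFeatures:
    def test_equal_variance_components_give_log_half(self):
        rng = np.random.default_rng(5)
        x = trials_with_covariance(np.eye(2), 3, 500, rng)
        csp = csp_fit(x, x.copy(), n_pairs=1)
        feats = extract_features(csp, x)
        np.testing.assert_allclose(feats, np.log(0.5), atol=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(6)
        xa = trials_with_covariance(random_spd(4, rng), 4, 300, rng)
        xb = trials_with_covariance(random_spd(4, rng), 4, 300, rng)
        csp = csp_fit(xa, xb)
        np.testing.assert_allclose(
            extract_features(csp, xa), extract_features(csp, 7.3 * xa), atol=1e-12)


class TestMIBIF:
    def test_informative_feature_wins(self):
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(100):
            y = rng.integers(0, 2, 80)
            feats = rng.standard_normal((80, 10))
            feats[:, 4] = y + 0.1 * rng.standard_normal(80)
            hits += mibif_select(feats, y, k=1)[0] == 4
        assert hits >= 95

    def test_k_equal_total_is_identity(self):
        rng = np.random.default_rng(8)
        feats = rng.standard_normal((40, 6))
        y = rng.integers(0, 2, 40)
        assert sorted(mibif_select(feats, y, k=6).tolist()) == list(range(6))

    def test_constant_feature_never_beats_informative(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 100)
        feats = np.zeros((100, 3))
        feats[:, 0] = 5.0  # constant
        feats[:, 1] = y + 0.2 * rng.standard_normal(100)
        feats[:, 2] = rng.standard_normal(100)
        assert mibif_select(feats, y, k=1)[0] == 1

    def test_k_too_large_rejected(self):
        with pytest.raises(ConfigError):
            mibif_select(np.zeros((10, 3)), np.zeros(10, dtype=int), k=4)


class TestMetrics:
    @pytest.mark.parametrize("tp,fp,fn,tn,acc,f1", [
        (40, 0, 0, 40, 100.0, 100.0),
        (30, 10, 10, 30, 75.0, 75.0),
        (0, 0, 40, 40, 50.0, 0.0),  # recall 0 -> F1 0
    ])
    def test_closed_form_cases(self, tp, fp, fn, tn, acc, f1):
        a, f = compute_metrics(tp, fp, fn, tn)
        assert a == pytest.approx(acc)
        assert f == pytest.approx(f1)

    def test_undefined_f1_sentinel(self):
        acc, f1 = compute_metrics(0, 0, 0, 40)
        assert acc == 100.0
        assert np.isnan(f1)

    def test_negative_counts_rejected(self):
        with pytest.raises(ConfigError):
            compute_metrics(-1, 0, 0, 10)


class TestNoLeakage:
    def test_fit_ignores_held_out_labels(self):
        # the trained model depends only on training data: permuting the
        # held-out labels afterwards cannot change its parameters
        rng = np.random.default_rng(10)
        x = rng.standard_normal((24, 8, 480))
        y = np.repeat([0, 1], 12)
        clf = FBCSPClassifier(fs=FS, C_grid=(1.0,), gamma_grid=(0.125,),
                              random_state=0)
        clf.fit(x[:16], y[:16])
        sel = clf.selected_.copy()
        filters = [c.filters.copy() for c in clf.csp_]
        pred_before = clf.predict(x[16:])
        _ = rng.permutation(y[16:])  # an adversary shuffles test labels
        pred_after = clf.predict(x[16:])
        np.testing.assert_array_equal(pred_before, pred_after)
        np.testing.assert_array_equal(sel, clf.selected_)
        for a, b in zip(filters, clf.csp_):
            np.testing.assert_array_equal(a, b.filters)
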