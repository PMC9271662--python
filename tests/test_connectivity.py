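"""MVAR fitting, order selection, DTF / pCoh / dDTF spectral quantities."""

import numpy as np
import pytest

from bcinet import (
    CouplingSpec,
    make_var_model,
    simulate_eeg,
)
from bcinet.connectivity import (
    VARFit,
    band_average_adjacency,
    ddtf,
    default_freq_grid,
    dtf,
    fit_var,
    partial_coherence,
    select_model_order,
    transfer_matrix,
)

from conftest import random_stable_varfit

FS = 512.0
BAND = (8.0, 13.0)


def _band_mask(freqs, band=BAND):
    return (freqs >= band[0]) & (freqs <= band[1])


class TestFitVar:
    def test_recovers_known_var2(self, chain3_model):
        rec = simulate_eeg(chain3_model, 100_000, seed=1)
        fit = fit_var(rec.data, 2)
        np.testing.assert_allclose(fit.coeffs, chain3_model.coeffs, atol=0.03)
        np.testing.assert_allclose(
            fit.noise_cov, chain3_model.noise_cov, atol=0.05
        )

    def test_matches_statsmodels_var(self, chain3_model):
        """Cross-check the OLS solution against an independent implementation."""
        from statsmodels.tsa.api import VAR

        rec = simulate_eeg(chain3_model, 20_000, seed=4)
        fit = fit_var(rec.data, 2)
        sm_res = VAR(rec.data.T).fit(maxlags=2, trend="n")
        np.testing.assert_allclose(
            fit.coeffs, sm_res.coefs, atol=1e-6
        )

    def test_iid_noise_gives_near_zero_coefficients(self, rng):
        data = rng.normal(size=(3, 50_000))
        fit = fit_var(data, 2)
        assert np.abs(fit.coeffs).max() < 0.05

    def test_constant_channel_rejected(self, rng):
        data = rng.normal(size=(3, 1000))
        data[1] = 4.2
        with pytest.raises(ValueError, match="constant"):
            fit_var(data, 2)

    def test_too_short_window_rejected(self, rng):
        with pytest.raises(ValueError, match="short"):
            fit_var(rng.normal(size=(5, 20)), 3)


class TestSelectModelOrder:
    def test_recovers_var3_order(self, rng):
        fit = random_stable_varfit(rng, n=3, p=3, radius=0.8)
        from bcinet.cohort import VARModel

        model = VARModel(
            coeffs=fit.coeffs, noise_cov=np.eye(3), labels=("a", "b", "c"),
            fs=FS,
        )
        rec = simulate_eeg(model, 20_000, seed=9)
        sel = select_model_order([rec.data], p_max=6)
        assert abs(sel.chosen_order - 3) <= 1

    def test_white_noise_chooses_minimal_order(self, rng):
        data = rng.normal(size=(3, 20_000))
        sel = select_model_order([data], p_max=5)
        assert sel.chosen_order == 1

    def test_sbc_never_exceeds_aic_order(self, chain3_model):
        rec = simulate_eeg(chain3_model, 20_000, seed=2)
        sel = select_model_order([rec.data], p_max=8)
        aic_order = sel.candidates[int(np.argmin(sel.aic))]
        assert sel.chosen_order <= aic_order
        for name in ("aic", "sbc", "fpe", "hq"):
            assert np.all(np.isfinite(sel.curve(name)))

    def test_excessive_pmax_rejected(self, rng):
        with pytest.raises(ValueError):
            select_model_order([rng.normal(size=(4, 100))], p_max=20)


class TestTransferMatrix:
    def test_zero_coefficients_give_identity_transfer(self):
        V = np.diag([1.0, 2.0, 3.0])
        fit = VARFit(coeffs=np.zeros((2, 3, 3)), noise_cov=V, nobs=1000)
        tr = transfer_matrix(fit, default_freq_grid(FS), FS)
        for f in range(len(tr.freqs)):
            np.testing.assert_allclose(tr.H[f], np.eye(3), atol=1e-12)
            np.testing.assert_allclose(tr.S[f], V, atol=1e-12)

    def test_scalar_var1_closed_form(self):
        a = 0.6
        fit = VARFit(
            coeffs=np.array([[[a]]]), noise_cov=np.eye(1), nobs=1000
        )
        freqs = default_freq_grid(FS)
        tr = transfer_matrix(fit, freqs, FS)
        expected = 1.0 / np.abs(1 - a * np.exp(-2j * np.pi * freqs / FS)) ** 2
        np.testing.assert_allclose(np.abs(tr.H[:, 0, 0]) ** 2, expected, rtol=1e-10)

    def test_spectral_matrix_hermitian_psd_and_inverse_consistent(self, rng):
        fit = random_stable_varfit(rng, n=4, p=2, radius=0.8)
        tr = transfer_matrix(fit, default_freq_grid(FS), FS)
        np.testing.assert_allclose(
            tr.S, np.conj(np.swapaxes(tr.S, 1, 2)), atol=1e-10
        )
        assert np.real(np.einsum("fii->fi", tr.S)).min() > 0
        resid = np.abs(tr.A @ tr.H - np.eye(4)[None]).max()
        assert resid < 1e-8


class TestDtf:
    def test_identity_transfer_gives_identity_dtf(self):
        fit = VARFit(coeffs=np.zeros((1, 3, 3)), noise_cov=np.eye(3), nobs=100)
        g2 = dtf(transfer_matrix(fit, default_freq_grid(FS), FS))
        np.testing.assert_allclose(g2, np.eye(3)[None].repeat(g2.shape[0], 0))

    def test_rows_sum_to_one_machine_precision(self, rng):
        for _ in range(5):
            fit = random_stable_varfit(rng, n=5, p=3, radius=0.9)
            g2 = dtf(transfer_matrix(fit, default_freq_grid(FS), FS))
            np.testing.assert_allclose(g2.sum(axis=2), 1.0, atol=1e-12)
            assert g2.min() >= 0 and g2.max() <= 1 + 1e-10

    def test_unidirectional_two_channel_model(self):
        spec = CouplingSpec(
            n_channels=2, edges=(("x1", "x2", 0.5),), oscillator_damping=0.95
        )
        model = make_var_model(spec, fs=FS)
        fit = VARFit(coeffs=model.coeffs, noise_cov=model.noise_cov, nobs=1000)
        freqs = default_freq_grid(FS)
        g2 = dtf(transfer_matrix(fit, freqs, FS))
        in_band = g2[_band_mask(freqs)].mean(axis=0)
        assert in_band[1, 0] > 0.2      # flow x1 -> x2
        assert in_band[0, 1] < 0.01     # no flow x2 -> x1


class TestPartialCoherence:
    def test_diagonal_spectral_matrix_gives_zero_off_diagonal(self):
        fit = VARFit(
            coeffs=np.zeros((1, 3, 3)), noise_cov=np.diag([1.0, 2.0, 3.0]),
            nobs=100,
        )
        P2 = partial_coherence(transfer_matrix(fit, default_freq_grid(FS), FS))
        off = P2 - np.einsum("fij,ij->fij", P2, np.eye(3))
        assert np.abs(off).max() < 1e-12

    def test_matches_explicit_minor_computation(self, rng):
        """Cofactor-identity route equals the defining minor ratios."""
        fit = random_stable_varfit(rng, n=4, p=2, radius=0.8)
        freqs = np.array([5.0, 10.0, 20.0])
        tr = transfer_matrix(fit, freqs, FS)
        P2 = partial_coherence(tr)
        for fi in range(len(freqs)):
            S = tr.S[fi]
            for i in range(4):
                for j in range(4):
                    minor_ij = np.linalg.det(
                        np.delete(np.delete(S, i, axis=0), j, axis=1)
                    )
                    minor_ii = np.linalg.det(
                        np.delete(np.delete(S, i, axis=0), i, axis=1)
                    )
                    minor_jj = np.linalg.det(
                        np.delete(np.delete(S, j, axis=0), j, axis=1)
                    )
                    expected = np.abs(minor_ij) ** 2 / np.real(
                        minor_ii * minor_jj
                    )
                    assert P2[fi, i, j] == pytest.approx(expected, rel=1e-5)

    def test_symmetric_in_its_arguments(self, rng):
        fit = random_stable_varfit(rng, n=5, p=2, radius=0.85)
        P2 = partial_coherence(transfer_matrix(fit, default_freq_grid(FS), FS))
        np.testing.assert_allclose(P2, np.swapaxes(P2, 1, 2), rtol=1e-8, atol=1e-12)

    def test_chain_conditional_independence(self, chain3_model):
        """x1 and x3 are coherent but conditionally independent given x2."""
        fit = VARFit(
            coeffs=chain3_model.coeffs, noise_cov=chain3_model.noise_cov,
            nobs=1000,
        )
        freqs = default_freq_grid(FS)
        tr = transfer_matrix(fit, freqs, FS)
        band = _band_mask(freqs)
        P2 = partial_coherence(tr)[band].mean(axis=0)
        S = tr.S[band]
        coh_13 = np.mean(
            np.abs(S[:, 0, 2]) ** 2
            / (np.real(S[:, 0, 0]) * np.real(S[:, 2, 2]))
        )
        assert coh_13 > 0.2            # ordinary coherence sees the cascade
        assert P2[0, 2] < 0.05 * coh_13  # partial coherence removes it


class TestDdtf:
    def test_diagonal_model_no_cross_flow(self):
        fit = VARFit(
            coeffs=np.zeros((1, 3, 3)), noise_cov=np.diag([1.0, 2.0, 0.5]),
            nobs=100,
        )
        d2, _ = ddtf(fit, default_freq_grid(FS), FS)
        off = d2 - np.einsum("fij,ij->fij", d2, np.eye(3))
        assert np.abs(off).max() < 1e-12

    def test_chain_indirect_suppression(self, chain3_model):
        """The defining dDTF property: cascade flow 1->3 is suppressed."""
        fit = VARFit(
            coeffs=chain3_model.coeffs, noise_cov=chain3_model.noise_cov,
            nobs=1000,
        )
        freqs = default_freq_grid(FS)
        d2, tr = ddtf(fit, freqs, FS)
        band = _band_mask(freqs)
        d2b = d2[band].mean(axis=0)
        g2b = dtf(tr)[band].mean(axis=0)
        assert g2b[2, 0] > 0.01                     # DTF sees 1->3
        assert d2b[2, 0] < 0.05 * d2b[1, 0]         # dDTF: 1->3 << 1->2
        assert d2b[2, 0] / g2b[2, 0] < 0.25         # suppression vs DTF

    def test_edge_reversal_transposes_dominant_entries(self):
        fwd = CouplingSpec(n_channels=3, edges=(("x1", "x2", 0.5),))
        rev = CouplingSpec(n_channels=3, edges=(("x2", "x1", 0.5),))
        freqs = default_freq_grid(FS)
        band = _band_mask(freqs)
        mats = []
        for spec, seed in ((fwd, 11), (rev, 12)):
            model = make_var_model(spec, fs=FS)
            rec = simulate_eeg(model, 50_000, seed=seed)
            fit = fit_var(rec.data, 2)
            d2, _ = ddtf(fit, freqs, FS)
            mats.append(d2[band].mean(axis=0))
        assert mats[0][1, 0] > 10 * mats[0][0, 1]
        assert mats[1][0, 1] > 10 * mats[1][1, 0]

    def test_band_restricted_eta_mode(self, chain3_model):
        """Restricting the eta frequency sum rescales but keeps structure."""
        fit = VARFit(
            coeffs=chain3_model.coeffs, noise_cov=chain3_model.noise_cov,
            nobs=1000,
        )
        freqs = default_freq_grid(FS)
        band = _band_mask(freqs)
        full, _ = ddtf(fit, freqs, FS)
        restricted, _ = ddtf(fit, freqs, FS, eta_band=BAND)
        assert restricted[band].mean(axis=0)[1, 0] > full[band].mean(axis=0)[1, 0]
        # ordering of entries preserved within each row
        fm, rm = full[band].mean(axis=0), restricted[band].mean(axis=0)
        assert np.argmax(fm[1]) == np.argmax(rm[1])


class TestBandAverageAdjacency:
    def test_single_window_single_bin_identity(self, rng):
        d2 = rng.random((1, 3, 3))
        adj = band_average_adjacency([d2], np.array([10.0]), band=(8, 13))
        np.testing.assert_allclose(adj.weights, d2[0])

    def test_mean_over_windows(self, rng):
        d2 = rng.random((2, 3, 3))
        adj = band_average_adjacency(
            [d2, 3 * d2], np.array([9.0, 12.0]), band=(8, 13)
        )
        np.testing.assert_allclose(adj.weights, 2 * d2.mean(axis=0))

    def test_empty_band_rejected(self, rng):
        with pytest.raises(ValueError, match="band"):
            band_average_adjacency(
                [rng.random((1, 3, 3))], np.array([50.0]), band=(8, 13)
            )

    def test_ground_truth_recovery_topk(self):
        """Top-k dDTF edges on a long raw recording match the true graph."""
        from bcinet import DEFAULT_COUPLING, truth_matrix

        model = make_var_model(DEFAULT_COUPLING, fs=FS)
        rec = simulate_eeg(model, 100_000, seed=21)
        fit = fit_var(rec.data, 2)
        freqs = default_freq_grid(FS)
        d2, _ = ddtf(fit, freqs, FS)
        adj = band_average_adjacency([d2], freqs, labels=model.labels)
        W = adj.weights.copy()
        np.fill_diagonal(W, 0.0)
        truth = truth_matrix(DEFAULT_COUPLING) > 0
        k = truth.sum()
        order = np.argsort(W, axis=None)[::-1][:k]
        hits = sum(truth[np.unravel_index(i, W.shape)] for i in order)
        assert hits / k >= 0.8


def test_analytic_oracle_equivalence(chain3_model):
    """Fitted-model spectral quantities match true-coefficient values in band."""
    rec = simulate_eeg(chain3_model, 100_000, seed=31)
    fitted = fit_var(rec.data, 2)
    true = VARFit(
        coeffs=chain3_model.coeffs, noise_cov=chain3_model.noise_cov, nobs=1,
    )
    freqs = default_freq_grid(FS)
    band = _band_mask(freqs)

    def quantities(fit):
        d2, tr = ddtf(fit, freqs, FS)
        return {
            "H": tr.H[band], "S": tr.S[band],
            "dtf": dtf(tr)[band], "pcoh": partial_coherence(tr)[band],
            "ddtf": d2[band],
        }

    qf, qt = quantities(fitted), quantities(true)
    for name in qf:
        rel = np.linalg.norm(qf[name] - qt[name]) / np.linalg.norm(qt[name])
        assert rel < 0.10, f"{name}: relative error {rel:.3f}"
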