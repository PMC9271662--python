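"""MVAR spectral estimation and the direct directed transfer function.

Per analysis window, a p-order multivariate autoregressive (MVAR) model

    X(t) = sum_{k=1..p} A(k) X(t-k) + E(t),   E ~ white, Cov(E) = V

is fitted by ordinary least squares. From the fitted coefficients the
frequency-domain quantities follow:

    A(f)  = I - sum_k A(k) exp(-i 2 pi f k / fs)
    H(f)  = A(f)^-1                      (transfer matrix)
    S(f)  = H(f) V H(f)*                 (spectral matrix)

    DTF   gamma^2_ij(f) = |H_ij(f)|^2 / sum_n |H_in(f)|^2
    pCoh  P^2_ij(f)     = |N_ij(f)|^2 / (N_ii(f) N_jj(f))
    dDTF  delta^2_ij(f) = eta^2_ij(f) * P^2_ij(f)

where eta^2 is the DTF renormalised over the full frequency grid
(denominator sums |H_in|^2 over every computed bin as well as over n) and
N_ij is the minor of S(f) with row i and column j removed. The dDTF
multiplies the directed-flow term by partial coherence, which suppresses
indirect (cascade) connections that plain DTF cannot distinguish from
direct ones.

Direction convention throughout: entry (i, j) of every matrix quantifies
flow FROM channel j INTO channel i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .preprocess import WindowSet

__all__ = [
    "VARFit",
    "OrderSelection",
    "SpectralTransfer",
    "ConnectivityMatrix",
    "fit_var",
    "select_model_order",
    "transfer_matrix",
    "dtf",
    "partial_coherence",
    "ddtf",
    "band_average_adjacency",
    "window_adjacency",
    "connectivity_from_windows",
]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VARFit:
    """Estimated MVAR model: coefficient stack and innovation covariance.

    coeffs : (p, n, n) array; coeffs[k-1] is A(k)
    noise_cov : (n, n) innovation covariance V
    nobs : number of regression equations (samples minus p)
    """

    coeffs: np.ndarray
    noise_cov: np.ndarray
    nobs: int
    labels: tuple[str, ...] | None = None

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    def companion(self) -> np.ndarray:
        """Companion-form transition matrix (np x np)."""
        p, n, _ = self.coeffs.shape
        comp = np.zeros((n * p, n * p))
        comp[:n] = np.concatenate(self.coeffs, axis=1)
        if p > 1:
            comp[n:, :-n] = np.eye(n * (p - 1))
        return comp

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.companion()))))

    def is_stable(self, tol: float = 1.0) -> bool:
        return self.spectral_radius() < tol


@dataclass(frozen=True)
class OrderSelection:
    """Information-criterion curves over candidate MVAR orders.

    Each criterion maps candidate order -> window-averaged value; the
    chosen order is the argmin of the chooser criterion (default SBC).
    """

    candidates: tuple[int, ...]
    aic: np.ndarray
    sbc: np.ndarray
    fpe: np.ndarray
    hq: np.ndarray
    chosen_order: int
    chooser: str = "sbc"

    def curve(self, name: str) -> np.ndarray:
        return getattr(self, name)


@dataclass(frozen=True)
class SpectralTransfer:
    """Frequency-resolved MVAR transfer and spectral matrices.

    freqs : (n_f,) Hz grid
    A : (n_f, n, n) complex, A(f) = I - sum_k A(k) e^{-i 2 pi f k / fs}
    H : (n_f, n, n) complex, H(f) = A(f)^-1
    S : (n_f, n, n) complex Hermitian, S(f) = H V H*
    """

    freqs: np.ndarray
    A: np.ndarray
    H: np.ndarray
    S: np.ndarray
    fs: float


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Band- and window-averaged dDTF adjacency.

    weights[i, j] = mean in-band dDTF flow from channel j into channel i.
    The diagonal is meaningless downstream (zeroed at thresholding).
    """

    weights: np.ndarray
    labels: tuple[str, ...]
    band: tuple[float, float]
    n_windows: int

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if not np.all(np.isfinite(w)) or np.any(w < 0):
            raise ValueError("connectivity weights must be finite and >= 0")


# ---------------------------------------------------------------------------
# MVAR fitting and order selection
# ---------------------------------------------------------------------------

def fit_var(window: np.ndarray, p: int, labels: tuple[str, ...] | None = None) -> VARFit:
    """Fit a p-order MVAR model to one (n_channels, n_samples) segment by OLS.

    All channels share the regressor matrix of p stacked lags, so the
    multivariate OLS reduces to one least-squares solve. The innovation
    covariance uses the residual outer product with denominator T - p
    (the equation count), matching the classical information-criterion
    forms used in :func:`select_model_order`.

    Average-referenced (and narrowband-filtered) EEG yields an exactly
    rank-deficient regressor matrix; the minimum-norm least-squares
    solution is used in that case, as in standard EEG MVAR practice. A
    constant (zero-variance) channel, however, is a hard error: no
    autoregressive description of it exists.
    """
    X = np.asarray(window, dtype=float)
    if X.ndim != 2:
        raise ValueError("window must be 2-D (channels x samples)")
    n, T = X.shape
    if p < 1:
        raise ValueError("order must be >= 1")
    nobs = T - p
    if nobs <= n * p + n:
        raise ValueError(
            f"window too short to identify VAR({p}) on {n} channels"
        )
    scale = np.abs(X).max()
    variances = X.var(axis=1)
    if scale > 0 and np.any(variances < 1e-24 * scale * scale):
        dead = int(np.argmin(variances))
        raise ValueError(
            f"channel {dead} is constant: regressor matrix is rank deficient"
        )
    # regressors: Z[t] = [X(t-1); ...; X(t-p)], response Y[t] = X(t)
    Y = X[:, p:].T                                   # (nobs, n)
    Z = np.concatenate(
        [X[:, p - k: T - k].T for k in range(1, p + 1)], axis=1
    )                                                # (nobs, n*p)
    return _fit_from_moments(Z.T @ Z, Z.T @ Y, Y.T @ Y, nobs, n, p, labels)


def _fit_from_moments(
    G: np.ndarray, C: np.ndarray, YY: np.ndarray,
    nobs: int, n: int, p: int, labels=None,
) -> VARFit:
    """Minimum-norm OLS from the moment matrices G=Z'Z, C=Z'Y, YY=Y'Y.

    pinv(Z) Y equals pinv(Z'Z) Z'Y, so the pseudo-inverse of the small
    Gram matrix reproduces the minimum-norm least-squares coefficients at
    a fraction of the cost of an SVD of Z itself.
    """
    from scipy.linalg import pinvh

    B = pinvh(G, rtol=1e-12) @ C                     # (n*p, n)
    resid_cov = YY - C.T @ B - B.T @ C + B.T @ G @ B
    V = (resid_cov + resid_cov.T) / (2 * nobs)
    coeffs = np.stack(
        [B[k * n: (k + 1) * n].T for k in range(p)], axis=0
    )                                                # (p, n, n)
    return VARFit(coeffs=coeffs, noise_cov=V, nobs=nobs, labels=labels)


def ljung_box_whiteness(fit: VARFit, window: np.ndarray, lags: int = 10) -> np.ndarray:
    """Per-channel Ljung-Box p-values on the fit residuals (diagnostic).

    High p-values are consistent with white residuals, i.e. an adequate
    model order.
    """
    X = np.asarray(window, dtype=float)
    p = fit.order
    Y = X[:, p:].T
    Z = np.concatenate(
        [X[:, p - k: X.shape[1] - k].T for k in range(1, p + 1)], axis=1
    )
    B = np.concatenate(fit.coeffs, axis=1).T
    resid = Y - Z @ B
    nobs = resid.shape[0]
    pvals = []
    for e in resid.T:
        e = e - e.mean()
        denom = float(e @ e)
        acf = np.array([
            (e[h:] @ e[:-h]) / denom for h in range(1, lags + 1)
        ])
        q = nobs * (nobs + 2) * np.sum(acf**2 / (nobs - np.arange(1, lags + 1)))
        pvals.append(sstats.chi2.sf(q, df=max(lags - p, 1)))
    return np.asarray(pvals)


def _criteria(fit: VARFit) -> dict[str, float]:
    """AIC / SBC / FPE / HQ for one fitted model (log-det-V forms)."""
    T = fit.nobs
    n = fit.n_channels
    m = fit.order * n * n          # free coefficient count
    # average-referenced data gives V one (numerically) zero eigenvalue;
    # floor the spectrum so log det stays finite and comparable across p
    V = (fit.noise_cov + fit.noise_cov.T) / 2
    eigs = np.linalg.eigvalsh(V)
    floor = max(eigs.max(), np.finfo(float).tiny) * 1e-12
    logdet = float(np.log(np.clip(eigs, floor, None)).sum())
    aic = logdet + 2.0 * m / T
    sbc = logdet + np.log(T) * m / T
    hq = logdet + 2.0 * np.log(np.log(T)) * m / T
    q = fit.order * n              # regressors per equation
    if T > q:
        log_fpe = logdet + n * (np.log(T + q) - np.log(T - q))
    else:
        log_fpe = np.inf
    return {"aic": aic, "sbc": sbc, "hq": hq, "fpe": log_fpe}


def select_model_order(
    windows: WindowSet | list[np.ndarray],
    p_max: int,
    chooser: str = "sbc",
) -> OrderSelection:
    """Window-averaged information-criterion order selection.

    Computes AIC, SBC (BIC), FPE (on log scale, order-equivalent) and HQ
    for each candidate order 1..p_max on every window, averages the
    curves over windows, and picks the argmin of the chooser criterion
    (default SBC, the most parsimonious of the four).
    """
    if p_max < 2:
        raise ValueError("p_max must be >= 2")
    if chooser not in ("aic", "sbc", "fpe", "hq"):
        raise ValueError(f"unknown chooser criterion {chooser!r}")
    segments = list(windows)
    if not segments:
        raise ValueError("no windows to select an order on")
    n, T = np.asarray(segments[0]).shape
    if T - p_max <= n * p_max + n:
        raise ValueError(
            f"p_max={p_max} too large for windows of {T} samples on {n} channels"
        )
    candidates = tuple(range(1, p_max + 1))
    curves = {name: np.zeros(p_max) for name in ("aic", "sbc", "fpe", "hq")}
    for seg in segments:
        # all candidate orders are scored on the same nobs = T - p_max
        # equations (conditioning on the first p_max lags), so their
        # criteria are directly comparable; the Gram matrix of the
        # deepest lag stack is built once and sliced per order
        X = np.asarray(seg, dtype=float)
        nseg, Tseg = X.shape
        nobs = Tseg - p_max
        Y = X[:, p_max:].T
        Z = np.concatenate(
            [X[:, p_max - k: Tseg - k].T for k in range(1, p_max + 1)], axis=1
        )
        G_full, C_full, YY = Z.T @ Z, Z.T @ Y, Y.T @ Y
        for p in candidates:
            m = nseg * p
            fit = _fit_from_moments(
                G_full[:m, :m], C_full[:m], YY, nobs, nseg, p
            )
            crit = _criteria(fit)
            for name in curves:
                curves[name][p - 1] += crit[name]
    for name in curves:
        curves[name] /= len(segments)
        if not np.all(np.isfinite(curves[name])):
            raise ValueError(f"non-finite {name.upper()} curve")
    chosen = candidates[int(np.argmin(curves[chooser]))]
    return OrderSelection(
        candidates=candidates,
        aic=curves["aic"],
        sbc=curves["sbc"],
        fpe=curves["fpe"],
        hq=curves["hq"],
        chosen_order=chosen,
        chooser=chooser,
    )


# ---------------------------------------------------------------------------
# Spectral quantities
# ---------------------------------------------------------------------------

def default_freq_grid(fs: float, resolution: float = 0.5) -> np.ndarray:
    """Linear frequency grid 0..fs/2 inclusive at the given resolution."""
    n_bins = int(np.floor(fs / 2 / resolution)) + 1
    return np.arange(n_bins) * resolution


def transfer_matrix(fit: VARFit, freqs: np.ndarray, fs: float) -> SpectralTransfer:
    """Evaluate A(f), H(f) = A(f)^-1 and S(f) = H V H* on a frequency grid."""
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    p, n, _ = fit.coeffs.shape
    # phase[k, f] = exp(-i 2 pi f (k+1) / fs)
    phase = np.exp(-2j * np.pi * np.outer(np.arange(1, p + 1), freqs) / fs)
    A = np.eye(n)[None] - np.einsum("kf,kij->fij", phase, fit.coeffs)
    # narrowband-fitted models legitimately put poles almost on the unit
    # circle, so only truly singular bins (cond at machine-precision
    # limit) are rejected
    conds = np.linalg.cond(A)
    bad = np.where(~np.isfinite(conds) | (conds > 1e15))[0]
    if bad.size:
        raise np.linalg.LinAlgError(
            f"A(f) numerically singular at {freqs[bad[0]]:.3f} Hz"
        )
    H = np.linalg.inv(A)
    S = H @ fit.noise_cov @ np.conj(np.swapaxes(H, 1, 2))
    return SpectralTransfer(freqs=freqs, A=A, H=H, S=S, fs=fs)


def dtf(transfer: SpectralTransfer) -> np.ndarray:
    """Row-normalised DTF gamma^2: (n_f, n, n), rows sum to 1 per bin."""
    H2 = np.abs(transfer.H) ** 2
    denom = H2.sum(axis=2, keepdims=True)
    if np.any(denom == 0):
        raise ValueError("zero inflow row in transfer matrix")
    return H2 / denom


def partial_coherence(transfer: SpectralTransfer) -> np.ndarray:
    """Partial coherence P^2 from minors of the spectral matrix.

    P^2_ij(f) = |N_ij|^2 / (N_ii N_jj) with N_ij the determinant of S(f)
    with row i and column j removed. Computed through the cofactor
    identity N_ij = (-1)^{i+j} det(S) [S^-1]_{ji}, which gives
    P^2_ij = |G_ji|^2 / (G_ii G_jj) for G = S^-1 — identical values at
    O(n^3) per bin instead of O(n^5). Tiny negative numerical residue is
    clipped to 0.

    Average-referenced EEG makes the innovation covariance (hence S)
    exactly singular; any bin whose eigenvalue spread exceeds 1e12 is
    diagonally loaded up to that conditioning floor before inversion.
    Well-conditioned bins are inverted untouched, so structural zeros of
    the partial coherence (e.g. the two ends of a causal chain) stay at
    machine level.
    """
    S = transfer.S
    n = S.shape[1]
    if n < 3:
        raise ValueError("partial coherence needs >= 3 channels")
    Sh = (S + np.conj(np.swapaxes(S, 1, 2))) / 2
    eigs = np.linalg.eigvalsh(Sh)                # (n_f, n), ascending
    lam_max = eigs[:, -1]
    if np.any(lam_max <= 0):
        raise ValueError("spectral matrix has no power; pCoh undefined")
    floor = 1e-12 * lam_max
    deficit = np.clip(floor - eigs[:, 0], 0.0, None)   # per-bin load
    loaded = Sh + deficit[:, None, None] * np.eye(n)[None]
    try:
        G = np.linalg.inv(loaded)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular spectral matrix; partial coherence undefined"
        ) from err
    diag = np.real(np.einsum("fii->fi", G))
    if np.any(diag <= 0):
        raise ValueError("non-positive principal minor of S(f)")
    num = np.abs(np.swapaxes(G, 1, 2)) ** 2      # |G_ji|^2 at (i, j)
    P2 = num / (diag[:, :, None] * diag[:, None, :])
    return np.clip(P2, 0.0, None)


def ddtf(
    fit: VARFit,
    freqs: np.ndarray,
    fs: float,
    *,
    eta_band: tuple[float, float] | None = None,
) -> tuple[np.ndarray, SpectralTransfer]:
    """dDTF delta^2 on the given grid; returns (delta2, transfer).

    delta^2_ij(f) = eta^2_ij(f) P^2_ij(f), with the eta denominator
    summing |H_in|^2 over the whole computed grid by default. If
    ``eta_band`` is given, the frequency sum is restricted to bins inside
    that band instead.
    """
    transfer = transfer_matrix(fit, freqs, fs)
    H2 = np.abs(transfer.H) ** 2                  # (n_f, n, n)
    if eta_band is None:
        in_sum = np.ones(len(transfer.freqs), dtype=bool)
    else:
        lo, hi = eta_band
        in_sum = (transfer.freqs >= lo) & (transfer.freqs <= hi)
        if not in_sum.any():
            raise ValueError(f"no frequency bins inside eta band {eta_band}")
    denom = H2[in_sum].sum(axis=(0, 2))           # per row i
    if np.any(denom == 0):
        raise ValueError("zero inflow row in transfer matrix")
    eta2 = H2 / denom[None, :, None]
    P2 = partial_coherence(transfer)
    return eta2 * P2, transfer


def band_average_adjacency(
    per_window_delta2: list[np.ndarray],
    freqs: np.ndarray,
    band: tuple[float, float] = (8.0, 13.0),
    labels: tuple[str, ...] | None = None,
) -> ConnectivityMatrix:
    """Average per-window delta^2 stacks over in-band bins, then windows."""
    if not per_window_delta2:
        raise ValueError("need at least one window")
    freqs = np.asarray(freqs, dtype=float)
    lo, hi = band
    in_band = (freqs >= lo) & (freqs <= hi)
    if not in_band.any():
        raise ValueError(f"no frequency bins inside band {band}")
    means = [d2[in_band].mean(axis=0) for d2 in per_window_delta2]
    weights = np.mean(means, axis=0)
    n = weights.shape[0]
    if labels is None:
        labels = tuple(f"ch{i}" for i in range(n))
    return ConnectivityMatrix(
        weights=weights, labels=tuple(labels), band=band,
        n_windows=len(per_window_delta2),
    )


# ---------------------------------------------------------------------------
# Windowed front-end
# ---------------------------------------------------------------------------

def window_adjacency(
    windows: WindowSet,
    order: int,
    band: tuple[float, float] = (8.0, 13.0),
    freq_resolution: float = 0.5,
    eta_band: tuple[float, float] | None = None,
) -> ConnectivityMatrix:
    """Per-window MVAR fit at a fixed order -> band-averaged dDTF adjacency."""
    freqs = default_freq_grid(windows.fs, freq_resolution)
    stacks = []
    for seg in windows:
        fit = fit_var(seg, order, labels=windows.labels)
        delta2, _ = ddtf(fit, freqs, windows.fs, eta_band=eta_band)
        stacks.append(delta2)
    return band_average_adjacency(stacks, freqs, band, labels=windows.labels)


def connectivity_from_windows(
    windows: WindowSet,
    p_max: int = 10,
    chooser: str = "sbc",
    band: tuple[float, float] = (8.0, 13.0),
    freq_resolution: float = 0.5,
    eta_band: tuple[float, float] | None = None,
) -> tuple[ConnectivityMatrix, OrderSelection]:
    """Order selection + per-window refit + band averaging in one call.

    One model order is used for the whole recording (argmin of the
    window-averaged chooser criterion); every window is then refitted at
    that order.
    """
    selection = select_model_order(windows, p_max, chooser)
    adj = window_adjacency(
        windows, selection.chosen_order, band, freq_resolution, eta_band
    )
    return adj, selection
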