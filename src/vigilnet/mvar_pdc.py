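"""MVAR model fitting and partial directed coherence.

A multivariate autoregressive (MVAR) model of order ``p`` over ``m``
channels,

    x(t) = sum_{r=1..p} A(r) x(t-r) + e(t),

is fitted per epoch by least squares; its frequency-domain counterpart

    Abar(f) = I - sum_{r=1..p} A(r) exp(-i 2 pi f r / fs)

yields the partial directed coherence (PDC) from channel j to channel i,

    PDC_{ij}(f) = |Abar_{ij}(f)| / sqrt( abar_j(f)^H abar_j(f) ),

where abar_j is the j-th column of Abar.  PDC is column-normalized:
sum_i PDC_{ij}(f)^2 = 1 at every frequency, and each entry lies in
[0, 1].  Band-averaged PDC matrices (entry (i, j) = flow j -> i) are the
directed connectivity networks fed to the graph-theory stage.

Orientation convention, package-wide: row = receiver, column = sender.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "VARModel",
    "PDCSpectrum",
    "ConnectivityMatrix",
    "companion_matrix",
    "spectral_radius",
    "fit_mvar",
    "select_order_aic",
    "pdc_spectrum",
    "band_average",
    "block_connectivity",
    "default_freq_grid",
]

DEFAULT_ORDER = 7           # model order used in the reference analysis
DEFAULT_BAND = (0.5, 30.0)  # Hz, full-spectrum connectivity band
DEFAULT_FREQ_STEP = 0.5     # Hz


class StabilityError(ValueError):
    """Raised when an operation requires a stable MVAR model."""


class ConditioningError(np.linalg.LinAlgError):
    """Raised when the regression problem is rank-deficient or a residual
    covariance is not positive definite."""


@dataclass
class VARModel:
    """MVAR coefficients ``coeffs[r-1] = A(r)`` (row = receiving channel)
    plus innovation covariance."""

    coeffs: np.ndarray      # (p, m, m)
    noise_cov: np.ndarray   # (m, m), symmetric positive definite
    order: int

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        if self.coeffs.ndim != 3 or self.coeffs.shape[1] != self.coeffs.shape[2]:
            raise ValueError("coeffs must have shape (p, m, m)")
        if self.coeffs.shape[0] != self.order:
            raise ValueError("coeffs first dimension must equal order")
        m = self.coeffs.shape[1]
        if self.noise_cov.shape != (m, m):
            raise ValueError("noise_cov must be m x m")
        if not np.allclose(self.noise_cov, self.noise_cov.T, atol=1e-12):
            raise ValueError("noise_cov must be symmetric within 1e-12")
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("coefficients must be finite")

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    def spectral_radius(self) -> float:
        return spectral_radius(self.coeffs)

    def is_stable(self, tol: float = 1.0) -> bool:
        return self.spectral_radius() < tol


@dataclass
class PDCSpectrum:
    """|PDC| on a frequency grid; ``values[k, i, j]`` = flow j -> i at
    ``freqs[k]``."""

    values: np.ndarray  # (n_freqs, m, m), entries in [0, 1]
    freqs: np.ndarray   # Hz

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.values.shape[0] != self.freqs.shape[0]:
            raise ValueError("values and freqs disagree on frequency count")


@dataclass
class ConnectivityMatrix:
    """Band-averaged directed connectivity.

    ``W[i, j]`` is the mean |PDC| of the flow j -> i over ``band``;
    entries lie in [0, 1].  ``threshold_applied`` records provenance once
    a thresholding scheme has been applied downstream.
    """

    W: np.ndarray
    band: tuple[float, float]
    n_epochs_averaged: int = 1
    threshold_applied: float | str | None = None
    channel_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2 or self.W.shape[0] != self.W.shape[1]:
            raise ValueError("W must be square")

    @property
    def n_channels(self) -> int:
        return self.W.shape[0]


def companion_matrix(coeffs: np.ndarray) -> np.ndarray:
    """Companion form of the lag polynomial: (m*p) x (m*p)."""
    coeffs = np.asarray(coeffs, dtype=float)
    p, m, _ = coeffs.shape
    top = np.concatenate([coeffs[r] for r in range(p)], axis=1)
    if p == 1:
        return top
    lower = np.eye(m * (p - 1), m * p)
    return np.vstack([top, lower])


def spectral_radius(coeffs: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(companion_matrix(coeffs)))))


def _lag_design(x: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Response Y (n-p, m) and stacked lag regressors Z (n-p, m*p)."""
    m, n = x.shape
    Y = x[:, p:].T
    Z = np.concatenate([x[:, p - r : n - r].T for r in range(1, p + 1)], axis=1)
    return Y, Z


def fit_mvar(epoch: np.ndarray, p: int = DEFAULT_ORDER, ridge: float = 0.0) -> VARModel:
    """Least-squares MVAR fit of one epoch (channels x samples).

    Parameters
    ----------
    epoch : ndarray, shape (m, n)
    p : int
        Model order (number of lags); default 7.
    ridge : float
        Nonnegative Tikhonov penalty, expressed relative to the mean
        regressor power (scale-invariant, so channel rescaling does not
        change the effective regularization).  Leave at 0 unless the
        regressor matrix is rank-deficient — common-average-referenced
        data always is, because the channels sum to zero — in which case
        a :class:`ConditioningError` advises a positive value.

    Returns
    -------
    VARModel with ``coeffs[r-1] = A(r)`` and residual covariance
    estimated on the fitted window (normalized by the residual count).
    """
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 2:
        raise ValueError("epoch must be 2-D (channels x samples)")
    m, n = epoch.shape
    if p < 1:
        raise ValueError("order must be >= 1")
    if n <= m * p:
        raise ValueError(f"need more than m*p={m * p} samples, got {n}")
    Y, Z = _lag_design(epoch, p)
    if ridge > 0:
        gram = Z.T @ Z
        lam = ridge * np.trace(gram) / gram.shape[0]
        B = np.linalg.solve(gram + lam * np.eye(gram.shape[0]), Z.T @ Y)
    else:
        B, _, rank, _ = np.linalg.lstsq(Z, Y, rcond=None)  # (m*p, m)
        if rank < Z.shape[1]:
            raise ConditioningError(
                f"rank-deficient MVAR regression (rank {rank} < {Z.shape[1]}; "
                "common-average-referenced channels are exactly collinear); "
                "pass ridge > 0 or use a longer window / fewer channels"
            )
    resid = Y - Z @ B
    n_eff = Y.shape[0]
    sigma = resid.T @ resid / n_eff
    coeffs = np.stack([B[(r - 1) * m : r * m, :].T for r in range(1, p + 1)])
    return VARModel(coeffs=coeffs, noise_cov=0.5 * (sigma + sigma.T), order=p)


def select_order_aic(
    epoch: np.ndarray, p_max: int, ridge: float = 0.0
) -> tuple[int, np.ndarray]:
    """Select the MVAR order by the Akaike information criterion.

    AIC(p) = ln det(Sigma_hat_p) + 2 p m^2 / N_eff, with N_eff the
    residual sample count of the order-p fit.  Returns the argmin over
    1..p_max together with the full AIC curve for audit.
    """
    epoch = np.asarray(epoch, dtype=float)
    m, n = epoch.shape
    if p_max * m >= n / 2:
        raise ValueError("p_max too large for the window length")
    curve = np.empty(p_max)
    for p in range(1, p_max + 1):
        model = fit_mvar(epoch, p=p, ridge=ridge)
        sign, logdet = np.linalg.slogdet(model.noise_cov)
        if sign <= 0:
            raise ConditioningError(
                f"residual covariance not positive definite at order {p}"
            )
        n_eff = n - p
        curve[p - 1] = logdet + 2.0 * p * m * m / n_eff
    return int(np.argmin(curve)) + 1, curve


def default_freq_grid(
    band: tuple[float, float] = DEFAULT_BAND, step: float = DEFAULT_FREQ_STEP
) -> np.ndarray:
    """Frequency grid lo, lo+step, ..., hi (inclusive)."""
    lo, hi = band
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


def pdc_spectrum(model: VARModel, freqs: np.ndarray, fs: float) -> PDCSpectrum:
    """|PDC| of a fitted MVAR model on a frequency grid.

    ``Abar(f) = I - sum_r A(r) exp(-i 2 pi f r / fs)``; entry (i, j) is
    ``|Abar_ij(f)|`` normalized by the Euclidean norm of column j, so the
    squared entries of every column sum to one at each frequency.
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if np.any(freqs < 0) or np.any(freqs >= fs / 2):
        raise ValueError("frequencies must lie in [0, fs/2)")
    p, m = model.order, model.n_channels
    # Abar for all freqs at once: (n_freqs, m, m)
    r = np.arange(1, p + 1)
    phase = np.exp(-2j * np.pi * np.outer(freqs, r) / fs)  # (n_freqs, p)
    abar = np.eye(m)[None, :, :] - np.einsum("fr,rij->fij", phase, model.coeffs.astype(complex))
    col_norm = np.sqrt(np.sum(np.abs(abar) ** 2, axis=1))  # (n_freqs, m)
    if np.any(col_norm == 0):
        raise np.linalg.LinAlgError("degenerate PDC: zero column norm in Abar(f)")
    values = np.abs(abar) / col_norm[:, None, :]
    return PDCSpectrum(values=values, freqs=freqs)


def band_average(
    spec: PDCSpectrum, lo: float = DEFAULT_BAND[0], hi: float = DEFAULT_BAND[1]
) -> ConnectivityMatrix:
    """Arithmetic mean of |PDC| over frequency bins in [lo, hi]."""
    mask = (spec.freqs >= lo) & (spec.freqs <= hi)
    if not np.any(mask):
        raise ValueError(f"band ({lo}, {hi}) Hz contains no frequency bins")
    W = spec.values[mask].mean(axis=0)
    return ConnectivityMatrix(W=W, band=(lo, hi), n_epochs_averaged=1)


def epoch_connectivity(
    epoch: np.ndarray,
    fs: float,
    p: int = DEFAULT_ORDER,
    ridge: float = 0.0,
    band: tuple[float, float] = DEFAULT_BAND,
    freq_step: float = DEFAULT_FREQ_STEP,
) -> ConnectivityMatrix:
    """Fit one epoch and return its band-averaged PDC matrix."""
    model = fit_mvar(epoch, p=p, ridge=ridge)
    freqs = default_freq_grid(band, freq_step)
    return band_average(pdc_spectrum(model, freqs, fs), *band)


def block_connectivity(
    epochs,
    block: int,
    p: int = DEFAULT_ORDER,
    ridge: float = 0.0,
    band: tuple[float, float] = DEFAULT_BAND,
    freq_step: float = DEFAULT_FREQ_STEP,
    concatenate: bool = False,
) -> ConnectivityMatrix:
    """Directed connectivity of one time-on-task block.

    Each kept epoch of the block is fitted separately (one PDC network
    per window); the band-averaged matrices are then averaged entrywise
    and the diagonal zeroed for graph use.  ``concatenate=True`` instead
    fits a single model on the horizontally concatenated epochs.

    Parameters
    ----------
    epochs : EpochSet
    block : int
        Time-on-task level (1-based).
    """
    data = epochs.kept(block)
    if data.shape[0] == 0:
        raise ValueError(f"no kept epochs in block {block}")
    freqs = default_freq_grid(band, freq_step)
    if concatenate:
        model = fit_mvar(np.concatenate(list(data), axis=1), p=p, ridge=ridge)
        W = band_average(pdc_spectrum(model, freqs, epochs.fs), *band).W
        n_avg = data.shape[0]
    else:
        mats = []
        for ep in data:
            model = fit_mvar(ep, p=p, ridge=ridge)
            mats.append(band_average(pdc_spectrum(model, freqs, epochs.fs), *band).W)
        W = np.mean(mats, axis=0)
        n_avg = len(mats)
    np.fill_diagonal(W, 0.0)
    return ConnectivityMatrix(
        W=W,
        band=band,
        n_epochs_averaged=n_avg,
        channel_labels=list(epochs.channel_labels),
    )
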