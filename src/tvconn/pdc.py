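"""Time-varying partial directed coherence (PDC).

PDC is a frequency-domain measure of directed influence between the channels
of a multivariate autoregressive (MVAR) process.  For a time-varying MVAR
model with coefficient matrices ``A_k(n)`` the frequency-domain coefficient
matrix is

    Abar(f, n) = I - sum_k A_k(n) * exp(-i 2 pi (f / fs) k)

and the squared PDC from sender ``j`` to receiver ``i`` is

    |pi_ij(f, n)|^2 = |Abar_ij(f, n)|^2 / sum_r |Abar_rj(f, n)|^2

which is column-normalized: the squared values over receivers sum to one for
every sender, frequency and time bin.  Squared PDC is used throughout because
it offers better sensitivity than the plain modulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PDCTensor",
    "spectral_transform",
    "squared_pdc",
    "strategy_pdc",
    "default_frequency_grid",
]


def default_frequency_grid() -> np.ndarray:
    """Default analysis band: 1-40 Hz in 1 Hz steps."""
    return np.arange(1.0, 41.0)


@dataclass
class PDCTensor:
    """Squared PDC values over (receiver, sender, frequency, time).

    Attributes
    ----------
    values : ndarray, shape (m, m, F, N)
        ``values[i, j, f, n]`` is the squared PDC from sender ``j`` to
        receiver ``i`` at frequency bin ``f`` and time bin ``n``.
    freqs_hz : ndarray, shape (F,)
    fs : float
        Sampling frequency in Hz.
    """

    values: np.ndarray
    freqs_hz: np.ndarray
    fs: float
    strategy: str | None = field(default=None)

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


def spectral_transform(
    coefficients: np.ndarray, freqs_hz: np.ndarray, fs: float
) -> np.ndarray:
    """Frequency-domain MVAR coefficient matrix Abar(f, n).

    Parameters
    ----------
    coefficients : ndarray, shape (N, p, m, m)
        Time-varying MVAR coefficients ``A_k(n)`` indexed (time bin, lag-1,
        receiver, sender).
    freqs_hz : array-like
        Frequencies in Hz, inside (0, fs/2].
    fs : float

    Returns
    -------
    ndarray, complex, shape (F, N, m, m)
    """
    coefficients = np.asarray(coefficients, dtype=float)
    if coefficients.ndim != 4:
        raise ValueError("coefficients must have shape (N, p, m, m)")
    freqs_hz = np.atleast_1d(np.asarray(freqs_hz, dtype=float))
    if np.any(freqs_hz <= 0) or np.any(freqs_hz > fs / 2):
        raise ValueError("frequencies must lie in (0, fs/2]")
    n_time, order, m, _ = coefficients.shape
    k = np.arange(1, order + 1)
    # phase[f, k] = exp(-i 2 pi (f/fs) k)
    phase = np.exp(-2j * np.pi * np.outer(freqs_hz / fs, k))
    abar = -np.einsum("fk,nkij->fnij", phase, coefficients)
    abar += np.eye(m)
    return abar


def squared_pdc(abar: np.ndarray, freqs_hz=None, fs: float = 1.0) -> PDCTensor:
    """Squared PDC from the frequency-domain coefficient matrix.

    Raises
    ------
    ValueError
        If some column of ``Abar`` vanishes entirely (the normalization is
        then undefined); the offending (sender, frequency, time) index is
        reported.
    """
    abar = np.asarray(abar)
    power = np.abs(abar) ** 2  # (F, N, i, j)
    denom = power.sum(axis=2)  # sum over receivers -> (F, N, j)
    bad = denom <= 0
    if np.any(bad):
        f, n, j = [idx[0] for idx in np.nonzero(bad)]
        raise ValueError(
            f"all-zero Abar column: sender j={j}, frequency bin {f}, time bin {n}"
        )
    vals = power / denom[:, :, None, :]
    # (F, N, i, j) -> (i, j, F, N)
    vals = np.transpose(vals, (2, 3, 0, 1))
    if freqs_hz is None:
        freqs_hz = np.arange(vals.shape[2], dtype=float)
    return PDCTensor(values=vals, freqs_hz=np.asarray(freqs_hz, float), fs=fs)


def pdc_from_coefficients(
    coefficients: np.ndarray, freqs_hz, fs: float
) -> PDCTensor:
    """Squared PDC directly from a time-varying coefficient tensor."""
    abar = spectral_transform(coefficients, freqs_hz, fs)
    return squared_pdc(abar, freqs_hz=freqs_hz, fs=fs)


def strategy_pdc(trials, strategy: str, config=None, freqs_hz=None) -> PDCTensor:
    """Squared PDC of multi-trial data under one of three estimation strategies.

    ``CKF-1``: PDC of the trial-averaged classical-Kalman MVAR estimates.
    ``CKF-2``: trial average of per-trial squared PDC values.
    ``GLKF`` : PDC of the multi-trial general-linear-Kalman estimate.

    Parameters
    ----------
    trials : ndarray (r, m, N) or TrialTensor
        Multi-trial channel time series.
    strategy : {"CKF-1", "CKF-2", "GLKF"}
    config : KalmanConfig, optional
    freqs_hz : array-like, optional
        Defaults to 1-40 Hz in 1 Hz steps.

    Notes
    -----
    CKF-2 averages column-normalized tensors, so its column sums are no
    longer guaranteed to equal one (they stay in (0, 1] per receiver count
    bounds); values remain within [0, 1].
    """
    from .kalman import KalmanConfig, aggregate_ckf, ckf_fit, glkf_fit

    data = getattr(trials, "data", trials)
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError("trials must have shape (r, m, N)")
    fs = getattr(trials, "fs", None) or 256.0
    if config is None:
        config = KalmanConfig()
    if freqs_hz is None:
        freqs_hz = default_frequency_grid()
    freqs_hz = np.asarray(freqs_hz, dtype=float)

    if strategy == "GLKF":
        traj = glkf_fit(data, config)
        out = pdc_from_coefficients(traj.coefficients, freqs_hz, fs)
    elif strategy == "CKF-1":
        trajs = [ckf_fit(trial, config) for trial in data]
        traj = aggregate_ckf(trajs)
        out = pdc_from_coefficients(traj.coefficients, freqs_hz, fs)
    elif strategy == "CKF-2":
        acc = None
        for trial in data:
            traj = ckf_fit(trial, config)
            t = pdc_from_coefficients(traj.coefficients, freqs_hz, fs)
            acc = t.values if acc is None else acc + t.values
        out = PDCTensor(values=acc / data.shape[0], freqs_hz=freqs_hz, fs=fs)
    else:
        raise ValueError(f"unknown strategy {strategy!r}; use CKF-1, CKF-2 or GLKF")
    out.strategy = strategy
    return out
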