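"""Time-varying MVAR estimation by Kalman filtering.

Two adaptive estimators are provided, both tracking the time-varying MVAR
coefficients through a random-walk state model

    state:       Atilde(n+1) = Atilde(n) + v(n),   v ~ N(0, V(n))
    measurement: y(n) = H(n) Atilde(n) + e(n)

where H(n) holds the p past data points.

* The classical Kalman filter (CKF) operates on a single trial.  Following
  the canonical adaptive formulation, the state is kept as the (m*p, m)
  coefficient matrix with a shared (m*p, m*p) state covariance, the state
  noise is isotropic with magnitude UC * trace(P)/dim, and the residual
  covariance is tracked by exponential smoothing with the same update
  constant UC.

* The general linear Kalman filter (GLKF) stacks all trials into one
  measurement block per time bin that shares a single coefficient state, so
  every trial updates the same trajectory.  It is not a trivial extension of
  the CKF and does not reduce to it for one trial (the innovation-covariance
  handling differs).

Both filters are deterministic given (data, config).  The statsmodels-style
entry points are :class:`ClassicalKalmanVAR` and
:class:`GeneralLinearKalmanVAR`, whose ``fit()`` returns a
:class:`TVVARResults`.

State vector layout (documented for oracles): the state matrix ``X`` has
shape (m*p, m); column ``i`` holds receiver ``i``'s coefficients and row
``(k-1)*m + j`` corresponds to lag ``k``, sender ``j``, i.e.
``A_k(n)[i, j] = X[(k-1)*m + j, i]``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KalmanConfig",
    "MVARTrajectory",
    "TVVARResults",
    "ClassicalKalmanVAR",
    "GeneralLinearKalmanVAR",
    "ckf_fit",
    "glkf_fit",
    "aggregate_ckf",
]


@dataclass(frozen=True)
class KalmanConfig:
    """Filter settings.

    Attributes
    ----------
    order : int
        MVAR model order p (8 by default, the value used throughout the
        factorial study).
    uc : float
        Update constant in (0, 1) controlling both the state-noise magnitude
        and the residual-covariance smoothing; 0.02 by default.
    initial_state_cov : float
        Scale of the initial (isotropic) state covariance.
    """

    order: int = 8
    uc: float = 0.02
    initial_state_cov: float = 1.0

    def __post_init__(self):
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if not 0.0 < self.uc < 1.0:
            raise ValueError("uc must lie in (0, 1)")


@dataclass
class MVARTrajectory:
    """Estimated time-varying MVAR coefficients.

    ``coefficients[n, k, i, j]`` is the lag-(k+1) coefficient from sender j
    to receiver i at time bin n; bins before the first valid estimate
    (n < p) are back-filled with that estimate so the grid spans the full
    record.  ``resid_cov`` is the smoothed innovation covariance trajectory.
    """

    coefficients: np.ndarray
    resid_cov: np.ndarray
    config: KalmanConfig

    @property
    def order(self) -> int:
        return self.coefficients.shape[1]

    @property
    def n_channels(self) -> int:
        return self.coefficients.shape[2]


def _state_to_coeffs(x: np.ndarray, p: int, m: int) -> np.ndarray:
    """(m*p, m) state matrix -> (p, m, m) coefficient tensor A[k, i, j]."""
    return x.reshape(p, m, m).transpose(0, 2, 1)


def _regressor(y: np.ndarray, n: int, p: int) -> np.ndarray:
    """Stacked past samples [y(n-1); ...; y(n-p)] for channel-major y (m, N)."""
    return y[:, n - p:n][:, ::-1].T.ravel()


def _channel_scales(y: np.ndarray, axis) -> np.ndarray:
    """Per-channel standard deviations used to standardize before filtering.

    The filters share one innovation variance across channels, which is only
    appropriate on comparable scales; fitting on standardized channels and
    mapping the estimates back (A_k = D A'_k D^-1 under y' = D^-1 y) keeps
    the estimator exactly scale-equivariant.  Constant channels get scale 1
    so that all-zero input passes through untouched.
    """
    s = np.asarray(y).std(axis=axis)
    return np.where(s > 0, s, 1.0)


def _unscale(coeffs: np.ndarray, resid: np.ndarray, s: np.ndarray):
    """Map standardized-channel estimates back to the original scale."""
    ratio = s[:, None] / s[None, :]  # (i, j)
    coeffs *= ratio[None, None, :, :]
    resid *= np.outer(s, s)[None, :, :]
    return coeffs, resid


def ckf_fit(series: np.ndarray, config: KalmanConfig | None = None) -> MVARTrajectory:
    """Classical (single-trial) Kalman-filter MVAR estimation.

    Parameters
    ----------
    series : ndarray (m, N)
    config : KalmanConfig

    Notes
    -----
    Innovation variance in the gain uses the channel-averaged smoothed
    residual covariance; a tiny jitter guards against a numerically singular
    innovation variance.
    """
    if config is None:
        config = KalmanConfig()
    y = np.asarray(series, dtype=float)
    if y.ndim != 2:
        raise ValueError("series must have shape (m, N)")
    m, n_samp = y.shape
    p, uc = config.order, config.uc
    if n_samp <= p:
        raise ValueError("series shorter than model order")
    scales = _channel_scales(y, axis=1)
    y = y / scales[:, None]
    dim = m * p
    x = np.zeros((dim, m))
    cov = config.initial_state_cov * np.eye(dim)
    resid = np.eye(m)
    coeffs = np.empty((n_samp, p, m, m))
    resid_traj = np.empty((n_samp, m, m))
    for n in range(p, n_samp):
        # predict: random walk with isotropic UC-scaled state noise
        cov = cov + (uc * np.trace(cov) / dim) * np.eye(dim)
        h = _regressor(y, n, p)
        err = y[:, n] - x.T @ h
        resid = (1.0 - uc) * resid + uc * np.outer(err, err)
        sigma2 = max(np.trace(resid) / m, 1e-12)
        ph = cov @ h
        s = float(h @ ph) + sigma2
        gain = ph / s
        x = x + np.outer(gain, err)
        cov = cov - np.outer(gain, ph)
        coeffs[n] = _state_to_coeffs(x, p, m)
        resid_traj[n] = resid
    coeffs[:p] = coeffs[p]
    resid_traj[:p] = resid_traj[p]
    coeffs, resid_traj = _unscale(coeffs, resid_traj, scales)
    return MVARTrajectory(coefficients=coeffs, resid_cov=resid_traj, config=config)


def glkf_fit(trials: np.ndarray, config: KalmanConfig | None = None) -> MVARTrajectory:
    """General linear (multi-trial) Kalman-filter MVAR estimation.

    All ``r`` trials are stacked into a single (r, m*p) measurement matrix at
    each time bin, updating one shared coefficient state; the innovation
    covariance is a full (r, r) matrix solved exactly, with per-channel
    residual variances from the smoothed residual covariance (the CKF, by
    contrast, pools one scalar variance across channels — so the two filters
    do not coincide even for a single trial).

    Parameters
    ----------
    trials : ndarray (r, m, N)
    """
    if config is None:
        config = KalmanConfig()
    data = np.asarray(trials, dtype=float)
    if data.ndim != 3:
        raise ValueError("trials must have shape (r, m, N)")
    r, m, n_samp = data.shape
    p, uc = config.order, config.uc
    if n_samp <= p:
        raise ValueError("series shorter than model order")
    scales = _channel_scales(data, axis=(0, 2))
    data = data / scales[None, :, None]
    dim = m * p
    x = np.zeros((dim, m))
    cov = config.initial_state_cov * np.eye(dim)
    resid = np.eye(m)
    coeffs = np.empty((n_samp, p, m, m))
    resid_traj = np.empty((n_samp, m, m))
    eye_r = np.eye(r)
    for n in range(p, n_samp):
        cov = cov + (uc * np.trace(cov) / dim) * np.eye(dim)
        # H: one regressor row per trial
        h = data[:, :, n - p:n][:, :, ::-1].transpose(0, 2, 1).reshape(r, dim)
        yn = data[:, :, n]  # (r, m)
        err = yn - h @ x
        resid = (1.0 - uc) * resid + uc * (err.T @ err) / r
        sigma2 = np.maximum(np.diag(resid), 1e-12)  # per-channel variances
        ph = cov @ h.T  # (dim, r)
        hph = h @ ph
        # state update: channel-specific innovation covariances
        s_stack = hph[None, :, :] + sigma2[:, None, None] * eye_r[None]
        try:
            gains = np.linalg.solve(s_stack, np.broadcast_to(ph.T, (m, r, dim)))
        except np.linalg.LinAlgError:
            gains = np.stack([np.linalg.pinv(s) @ ph.T for s in s_stack])
        x = x + np.einsum("ird,ri->di", gains, err)
        # covariance update: pooled-variance gain (shared state covariance)
        s_bar = hph + (sigma2.mean()) * eye_r
        try:
            gain_bar = np.linalg.solve(s_bar, ph.T).T
        except np.linalg.LinAlgError:
            gain_bar = ph @ np.linalg.pinv(s_bar)
        cov = cov - gain_bar @ ph.T
        coeffs[n] = _state_to_coeffs(x, p, m)
        resid_traj[n] = resid
    coeffs[:p] = coeffs[p]
    resid_traj[:p] = resid_traj[p]
    coeffs, resid_traj = _unscale(coeffs, resid_traj, scales)
    return MVARTrajectory(coefficients=coeffs, resid_cov=resid_traj, config=config)


def aggregate_ckf(trajectories: list[MVARTrajectory]) -> MVARTrajectory:
    """Element-wise mean of per-trial CKF trajectories (the CKF-1 strategy)."""
    if not trajectories:
        raise ValueError("no trajectories to aggregate")
    shape = trajectories[0].coefficients.shape
    for t in trajectories[1:]:
        if t.coefficients.shape != shape:
            raise ValueError("trajectory shapes differ")
    coeffs = np.mean([t.coefficients for t in trajectories], axis=0)
    resid = np.mean([t.resid_cov for t in trajectories], axis=0)
    return MVARTrajectory(
        coefficients=coeffs, resid_cov=resid, config=trajectories[0].config
    )


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------

class TVVARResults:
    """Results of a time-varying VAR fit.

    Carries the coefficient trajectory, the residual-covariance trajectory
    and the configuration; ``pdc()`` transforms to squared partial directed
    coherence and ``summary()`` renders a compact text report.
    """

    def __init__(self, model, trajectory: MVARTrajectory, fs: float):
        self.model = model
        self.trajectory = trajectory
        self.fs = fs

    @property
    def coefficients(self) -> np.ndarray:
        return self.trajectory.coefficients

    @property
    def resid_cov(self) -> np.ndarray:
        return self.trajectory.resid_cov

    def pdc(self, freqs_hz=None):
        from . import pdc as _pdc

        if freqs_hz is None:
            freqs_hz = _pdc.default_frequency_grid()
        return _pdc.pdc_from_coefficients(
            self.trajectory.coefficients, freqs_hz, self.fs
        )

    def time_averaged_coefficients(self) -> np.ndarray:
        """Mean A_k over time, summed over lags -> (m, m) net coupling."""
        return self.trajectory.coefficients.mean(axis=0).sum(axis=0)

    def summary(self) -> str:
        traj = self.trajectory
        m = traj.n_channels
        buf = io.StringIO()
        print(type(self.model).__name__, "fit", file=buf)
        print(
            f"  channels: {m}  order: {traj.order}  UC: {traj.config.uc}"
            f"  samples: {traj.coefficients.shape[0]}  fs: {self.fs} Hz",
            file=buf,
        )
        net = self.time_averaged_coefficients()
        print("  time-averaged net coupling (receiver x sender):", file=buf)
        for i in range(m):
            print("   ", " ".join(f"{net[i, j]:+7.3f}" for j in range(m)), file=buf)
        sigma = traj.resid_cov[-1]
        print(
            f"  final residual variances: "
            + " ".join(f"{sigma[i, i]:.3g}" for i in range(m)),
            file=buf,
        )
        return buf.getvalue()


class _KalmanVARBase:
    def __init__(self, order: int = 8, uc: float = 0.02,
                 initial_state_cov: float = 1.0, fs: float = 256.0):
        self.config = KalmanConfig(
            order=order, uc=uc, initial_state_cov=initial_state_cov
        )
        self.fs = fs


class ClassicalKalmanVAR(_KalmanVARBase):
    """Single-trial time-varying VAR model estimated with the classical
    Kalman filter.

    Parameters
    ----------
    endog : ndarray (m, N)
        Channel-major single-trial time series.
    order, uc, initial_state_cov, fs :
        See :class:`KalmanConfig`.

    Examples
    --------
    >>> res = ClassicalKalmanVAR(series, order=8, uc=0.02).fit()
    >>> res.coefficients.shape   # (N, 8, m, m)
    """

    def __init__(self, endog, **kwargs):
        super().__init__(**kwargs)
        self.endog = np.asarray(endog, dtype=float)

    @classmethod
    def from_dataframe(cls, frame, **kwargs):
        """Build from a (samples x channels) pandas DataFrame."""
        return cls(np.asarray(frame, dtype=float).T, **kwargs)

    def fit(self) -> TVVARResults:
        traj = ckf_fit(self.endog, self.config)
        return TVVARResults(self, traj, self.fs)


class GeneralLinearKalmanVAR(_KalmanVARBase):
    """Multi-trial time-varying VAR model estimated with the general linear
    Kalman filter (all trials share one coefficient trajectory)."""

    def __init__(self, trials, **kwargs):
        super().__init__(**kwargs)
        data = getattr(trials, "data", trials)
        self.trials = np.asarray(data, dtype=float)

    def fit(self) -> TVVARResults:
        traj = glkf_fit(self.trials, self.config)
        return TVVARResults(self, traj, self.fs)
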