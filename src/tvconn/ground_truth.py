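"""Ground-truth time-varying MVAR network of the visual spatial attention system.

This module defines the simulated "truth" of the benchmark: a 10-region
directed network (V1 input, bilateral visual areas, IPS, FEF, plus right TPJ,
VFC/AI and MFG) whose couplings follow a time-varying multivariate
autoregressive (MVAR) process

    y(n) = sum_{k=1..p} A_k(n) y(n-k) + e(n)

at 256 Hz.  Interhemispheric couplings are stationary with strength 0.5;
all other connections carry a stationary baseline of 0.2 plus a raised-cosine
time-varying bump.  V1 is driven by a fixed AR(10) process with a 1/f-like
spectrum and an alpha-band resonance, mimicking cortical visual input.

The module also provides stationary-model order selection by Schwarz's
Bayesian Criterion (SBC) and the theoretical squared-PDC reference computed
from the exact coefficient schedule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.signal import lfilter

from . import pdc as _pdc

__all__ = [
    "RegionSpec",
    "ConnectionSpec",
    "GroundTruthModel",
    "TVMVARParams",
    "TrialTensor",
    "build_attention_model",
    "generate_input_signal",
    "load_input_ar_coefficients",
    "sbc_order_select",
    "simulate_trials",
    "theoretical_pdc",
    "coefficient_trajectory",
    "stability_radius",
    "connection_matrix",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionSpec:
    """A cortical region: label, MNI coordinate (mm) and hemisphere."""

    label: str
    name: str
    mni_xyz: tuple[float, float, float]
    hemisphere: str


@dataclass(frozen=True)
class TVWaveform:
    """Raised-cosine coupling bump added on top of a stationary baseline.

    ``onset_ms`` is relative to stimulus onset (end of the baseline period).
    """

    onset_ms: float
    duration_ms: float
    peak_amplitude: float


@dataclass(frozen=True)
class ConnectionSpec:
    """A directed coupling sender -> receiver at a fixed lag."""

    sender: str
    receiver: str
    lag_ms: float
    baseline_strength: float
    category: str
    tv_waveform: TVWaveform | None = None


@dataclass
class GroundTruthModel:
    """The complete ground-truth generator definition."""

    regions: list[RegionSpec]
    connections: list[ConnectionSpec]
    fs: float = 256.0
    duration_ms: float = 1200.0
    baseline_ms: float = 200.0
    source_snr: float = 20.0

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.regions]

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_ms * self.fs / 1000.0))

    @property
    def n_baseline(self) -> int:
        return int(round(self.baseline_ms * self.fs / 1000.0))

    @property
    def p_true(self) -> int:
        """Maximum coupling lag in samples."""
        return max((self._lag_samples(c) for c in self.connections), default=1)

    def _lag_samples(self, conn: ConnectionSpec) -> int:
        lag = int(round(conn.lag_ms * self.fs / 1000.0))
        if lag < 1:
            raise ValueError(
                f"connection {conn.sender}->{conn.receiver}: lag {conn.lag_ms} ms "
                f"maps to {lag} samples at fs={self.fs}; must be >= 1"
            )
        return lag

    def index(self, label: str) -> int:
        return self.labels.index(label)


@dataclass
class TVMVARParams:
    """Time-varying MVAR coefficients A_k(n), indexed (n, lag-1, receiver, sender)."""

    coefficients: np.ndarray
    fs: float

    @property
    def order(self) -> int:
        return self.coefficients.shape[1]

    @property
    def n_channels(self) -> int:
        return self.coefficients.shape[2]

    def embed(self, order: int) -> "TVMVARParams":
        """Zero-pad the lag axis to a larger model order (for comparisons)."""
        n, p, m, _ = self.coefficients.shape
        if order < p:
            raise ValueError("cannot embed into a smaller order")
        out = np.zeros((n, order, m, m))
        out[:, :p] = self.coefficients
        return TVMVARParams(coefficients=out, fs=self.fs)


@dataclass
class TrialTensor:
    """Multi-trial time series: data[trial, channel, sample].

    ``t0_ms`` is the time of sample 0 relative to stimulus onset (negative
    during the pre-stimulus baseline).
    """

    data: np.ndarray
    fs: float
    t0_ms: float
    labels: list[str] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.n_samples) * 1000.0 / self.fs


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

def _load_json(name: str) -> dict:
    with resources.files("tvconn.datasets").joinpath(name).open() as fh:
        return json.load(fh)


def load_input_ar_coefficients() -> np.ndarray:
    """The fixed AR(10) coefficients of the visual-input process."""
    return np.asarray(_load_json("ar_input.json")["coefficients"], dtype=float)


def build_attention_model(config: dict | None = None) -> GroundTruthModel:
    """Build the default 10-region attention-network ground-truth model.

    Parameters
    ----------
    config : dict, optional
        Overrides for scalar fields (``fs``, ``duration_ms``, ``baseline_ms``,
        ``source_snr``) or a replacement ``connections`` list (each entry a
        dict in the same schema as the packaged fixture).

    Raises
    ------
    ValueError
        If an override references an unknown region or yields an unstable
        coefficient schedule.
    """
    raw = _load_json("attention_model.json")
    config = dict(config or {})
    regions = [
        RegionSpec(
            label=r["label"],
            name=r["name"],
            mni_xyz=tuple(r["mni_xyz"]),
            hemisphere=r["hemisphere"],
        )
        for r in raw["regions"]
    ]
    conn_raw = config.pop("connections", raw["connections"])
    connections = []
    for c in conn_raw:
        wf = c.get("tv_waveform")
        connections.append(
            ConnectionSpec(
                sender=c["sender"],
                receiver=c["receiver"],
                lag_ms=float(c["lag_ms"]),
                baseline_strength=float(c["baseline_strength"]),
                category=c["category"],
                tv_waveform=None if wf is None else TVWaveform(
                    onset_ms=float(wf["onset_ms"]),
                    duration_ms=float(wf["duration_ms"]),
                    peak_amplitude=float(wf["peak_amplitude"]),
                ),
            )
        )
    model = GroundTruthModel(
        regions=regions,
        connections=connections,
        fs=float(config.pop("fs", raw["fs_hz"])),
        duration_ms=float(config.pop("duration_ms", raw["duration_ms"])),
        baseline_ms=float(config.pop("baseline_ms", raw["baseline_ms"])),
        source_snr=float(config.pop("source_snr", raw["source_snr"])),
    )
    if config:
        raise ValueError(f"unknown override keys: {sorted(config)}")
    labels = set(model.labels)
    for c in model.connections:
        if c.sender not in labels or c.receiver not in labels:
            raise ValueError(
                f"connection references unknown region: {c.sender}->{c.receiver}"
            )
        if c.sender == c.receiver:
            raise ValueError(f"self-connection not allowed: {c.sender}")
    params = coefficient_trajectory(model)
    rho = stability_radius(params)
    if rho.max() >= 1.0:
        n_bad = int(np.argmax(rho >= 1.0))
        raise ValueError(
            f"unstable coefficient schedule: companion spectral radius "
            f"{rho.max():.3f} >= 1 first at time bin {n_bad}"
        )
    return model


def connection_matrix(model: GroundTruthModel) -> np.ndarray:
    """Boolean (receiver, sender) matrix of realized directed connections."""
    m = model.n_regions
    mask = np.zeros((m, m), dtype=bool)
    for c in model.connections:
        mask[model.index(c.receiver), model.index(c.sender)] = True
    return mask


# ---------------------------------------------------------------------------
# Coefficient schedule and stability
# ---------------------------------------------------------------------------

def _raised_cosine(times_ms: np.ndarray, wf: TVWaveform) -> np.ndarray:
    """Raised-cosine bump over [onset, onset + duration], peak at midpoint."""
    u = (times_ms - wf.onset_ms) / wf.duration_ms
    bump = np.where(
        (u >= 0) & (u <= 1),
        0.5 * wf.peak_amplitude * (1.0 - np.cos(2.0 * np.pi * u)),
        0.0,
    )
    return bump


def coefficient_trajectory(model: GroundTruthModel) -> TVMVARParams:
    """Assemble the exact A_k(n) tensor from the connection schedule."""
    m = model.n_regions
    n_samp = model.n_samples
    p = model.p_true
    times = -model.baseline_ms + np.arange(n_samp) * 1000.0 / model.fs
    coeffs = np.zeros((n_samp, p, m, m))
    for c in model.connections:
        k = model._lag_samples(c) - 1
        i = model.index(c.receiver)
        j = model.index(c.sender)
        strength = np.full(n_samp, c.baseline_strength)
        if c.tv_waveform is not None:
            strength = strength + _raised_cosine(times, c.tv_waveform)
        coeffs[:, k, i, j] += strength
    return TVMVARParams(coefficients=coeffs, fs=model.fs)


def stability_radius(params: TVMVARParams) -> np.ndarray:
    """Spectral radius of the MVAR companion matrix at every time bin."""
    n_samp, p, m, _ = params.coefficients.shape
    radius = np.empty(n_samp)
    comp = np.zeros((m * p, m * p))
    if p > 1:
        comp[m:, :-m] = np.eye(m * (p - 1))
    # coefficient schedules are piecewise-smooth; evaluating every bin is cheap
    for n in range(n_samp):
        comp[:m] = params.coefficients[n].transpose(1, 0, 2).reshape(m, m * p)
        radius[n] = np.max(np.abs(np.linalg.eigvals(comp)))
    return radius


# ---------------------------------------------------------------------------
# Input signal and order selection
# ---------------------------------------------------------------------------

def generate_input_signal(
    n_samples: int,
    seed=None,
    innovations: np.ndarray | None = None,
    burn_in: int = 2000,
) -> np.ndarray:
    """Realize the fixed AR(10) visual-input process.

    Parameters
    ----------
    n_samples : int
    seed : int or numpy Generator, optional
        Ignored when explicit ``innovations`` are given.
    innovations : ndarray, optional
        Driving noise of length ``n_samples + burn_in`` (or ``n_samples``,
        in which case no burn-in is used); zero innovations with the implied
        zero initial state yield an identically zero output.
    burn_in : int
        Samples discarded to remove the transient of the zero initial state.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    a = load_input_ar_coefficients()
    if innovations is None:
        rng = np.random.default_rng(seed)
        e = rng.standard_normal(n_samples + burn_in)
    else:
        e = np.asarray(innovations, dtype=float)
        if e.size == n_samples:
            burn_in = 0
        elif e.size != n_samples + burn_in:
            raise ValueError("innovations must have n_samples(+burn_in) entries")
    x = lfilter([1.0], np.r_[1.0, -a], e)
    return x[burn_in:burn_in + n_samples]


def input_spectrum(freqs_hz: np.ndarray, fs: float = 256.0) -> np.ndarray:
    """Theoretical power spectrum |1/A(e^{i 2 pi f})|^2 of the input process."""
    a = load_input_ar_coefficients()
    k = np.arange(1, a.size + 1)
    A = 1.0 - np.sum(
        a[None, :] * np.exp(-2j * np.pi * np.outer(freqs_hz / fs, k)), axis=1
    )
    return 1.0 / np.abs(A) ** 2


def sbc_order_select(series: np.ndarray, max_order: int) -> int:
    """Select a stationary (M)AR model order by Schwarz's Bayesian Criterion.

    Models of orders 1..max_order are fitted by least squares on a common
    effective sample (the first ``max_order`` samples are used as presample
    only), and SBC(p) = N log det(Sigma_p) + p m^2 log N is minimized, with
    Sigma_p the residual covariance and N the effective sample count.

    Parameters
    ----------
    series : ndarray (N,) or (m, N)
    max_order : int

    Raises
    ------
    ValueError
        For degenerate input (a constant channel makes the regression
        rank-deficient); the offending channel is named.
    """
    y = np.atleast_2d(np.asarray(series, dtype=float))
    m, n = y.shape
    if n <= max_order * m + max_order:
        raise ValueError("series too short for requested max_order")
    stds = y.std(axis=1)
    if np.any(stds == 0):
        ch = int(np.argmin(stds))
        raise ValueError(f"channel {ch} is constant; order selection undefined")
    n_eff = n - max_order
    target = y[:, max_order:].T  # (n_eff, m)
    lagged = np.concatenate(
        [y[:, max_order - k: n - k].T for k in range(1, max_order + 1)], axis=1
    )  # (n_eff, m*max_order)
    best_order, best_sbc = None, np.inf
    for p in range(1, max_order + 1):
        X = lagged[:, : m * p]
        coef, *_ = np.linalg.lstsq(X, target, rcond=None)
        resid = target - X @ coef
        sigma = (resid.T @ resid) / n_eff
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            ch = int(np.argmin(np.diag(sigma)))
            raise ValueError(
                f"rank-deficient residual covariance at order {p} "
                f"(smallest variance on channel {ch})"
            )
        sbc = n_eff * logdet + p * m * m * np.log(n_eff)
        if sbc < best_sbc:
            best_sbc, best_order = sbc, p
    return best_order


# ---------------------------------------------------------------------------
# Trial simulation
# ---------------------------------------------------------------------------

def simulate_trials(
    model: GroundTruthModel,
    n_trials: int,
    seed=None,
    return_components: bool = False,
    input_signals: np.ndarray | None = None,
    innovation_noise: np.ndarray | None = None,
):
    """Simulate multi-trial source time series from the ground-truth model.

    Each trial is generated iteratively: the V1 channel carries an
    independent realization of the AR(10) input process; every other channel
    follows the time-varying MVAR recursion driven by the lagged signals plus
    white innovation noise.  The innovation standard deviation is rescaled at
    every time point so that the signal-to-innovation power ratio (pooled
    over the MVAR-driven channels of a trial) equals ``model.source_snr``.

    Parameters
    ----------
    model : GroundTruthModel
    n_trials : int
    seed : int or numpy Generator, optional
    return_components : bool
        Additionally return the noise-free signal part and the innovation
        part (``data = signal + innovation``).
    input_signals, innovation_noise : ndarray, optional
        Override the random draws (used for deterministic contracts):
        shapes (n_trials, N) and (n_trials, m, N); innovation noise is the
        unscaled standard-normal draw.

    Returns
    -------
    trials : TrialTensor, shape (n_trials, m, N)
    params : TVMVARParams
        The exact A_k(n) used.
    components : (signal, innovation), only when ``return_components``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    m = model.n_regions
    n_samp = model.n_samples
    params = coefficient_trajectory(model)
    p = params.order
    a = params.coefficients  # (N, p, m, m)
    v1 = model.index("V1") if "V1" in model.labels else 0
    driven = np.array([c for c in range(m) if c != v1])

    if input_signals is None:
        input_signals = np.empty((n_trials, n_samp))
        for r in range(n_trials):
            input_signals[r] = generate_input_signal(n_samp, rng)
    else:
        input_signals = np.asarray(input_signals, dtype=float)
    if innovation_noise is None:
        innovation_noise = rng.standard_normal((n_trials, m, n_samp))
    else:
        innovation_noise = np.asarray(innovation_noise, dtype=float)

    y = np.zeros((n_trials, m, n_samp))
    signal = np.zeros_like(y)
    innovation = np.zeros_like(y)
    snr = model.source_snr
    for n in range(n_samp):
        s = np.zeros((n_trials, m))
        for k in range(min(n, p)):
            s += y[:, :, n - k - 1] @ a[n, k].T
        s[:, v1] = input_signals[:, n]
        # per-trial innovation scale from the instantaneous driven-channel power
        power = np.mean(s[:, driven] ** 2, axis=1)
        sd = np.sqrt(power / snr)
        eps = sd[:, None] * innovation_noise[:, :, n]
        eps[:, v1] = 0.0
        y[:, :, n] = s + eps
        signal[:, :, n] = s
        innovation[:, :, n] = eps
        amax = np.abs(y[:, :, n]).max()
        if not np.isfinite(amax) or amax > 1e8:
            raise RuntimeError(f"simulation diverged at time bin {n}")
    trials = TrialTensor(
        data=y, fs=model.fs, t0_ms=-model.baseline_ms, labels=model.labels
    )
    if return_components:
        return trials, params, (signal, innovation)
    return trials, params


def theoretical_pdc(params: TVMVARParams, freqs_hz) -> _pdc.PDCTensor:
    """Squared PDC of the exact ground-truth coefficients (same code path as
    the estimation-side PDC)."""
    return _pdc.pdc_from_coefficients(params.coefficients, freqs_hz, params.fs)
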