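"""sLORETA inverse modeling of the simulated scalp EEG.

A minimum-norm kernel ``K_mne = G' (G G' + lambda C)^+`` is standardized per
vertex by the square root of the corresponding diagonal element of the
model resolution ``K_mne G`` (fixed-orientation sLORETA).  The
regularization follows the rule lambda = 1/SNR^2, with the noise covariance
C restricted to its diagonal (uncorrelated measurement noise), diagonally
loaded, and scaled to unit mean diagonal before entering the kernel.  One
shared kernel serves every trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import LeadField
from .ground_truth import TrialTensor

__all__ = [
    "NoiseCov",
    "InversionKernel",
    "ResolutionMatrix",
    "estimate_noise_covariance",
    "compute_sloreta_kernel",
    "apply_kernel",
    "resolution_matrix",
]


@dataclass
class NoiseCov:
    """Diagonal sensor-noise covariance with the applied loading factor."""

    variances: np.ndarray  # (E,)
    reg_factor: float

    @property
    def matrix(self) -> np.ndarray:
        return np.diag(self.variances)


@dataclass
class InversionKernel:
    """Standardized sLORETA kernel K (V x E) with its regularization."""

    K: np.ndarray
    lam: float
    standardization: np.ndarray  # per-vertex scale factors sqrt(diag(K_mne G))


@dataclass
class ResolutionMatrix:
    """R = K G; diagonal = resolution indices, rows/columns = cross-talk."""

    R: np.ndarray


def estimate_noise_covariance(
    scalp_trials: TrialTensor,
    baseline_window: tuple[int, int] | None = None,
    reg_factor: float = 0.1,
) -> NoiseCov:
    """Per-sensor baseline variance with diagonal loading.

    The variance of each sensor is computed over all baseline samples of all
    trials; each variance is then increased by ``reg_factor`` times the mean
    diagonal.  Off-diagonal covariance is discarded by construction.

    Parameters
    ----------
    baseline_window : (start, stop) sample indices
        Defaults to the samples preceding stimulus onset (t < 0).
    """
    data = scalp_trials.data
    if baseline_window is None:
        # baseline = the first round(baseline_ms * fs) samples
        n_base = int(round(-scalp_trials.t0_ms * scalp_trials.fs / 1000.0))
        baseline_window = (0, n_base)
    start, stop = baseline_window
    if not 0 <= start < stop <= data.shape[2]:
        raise ValueError(f"empty or out-of-range baseline window {baseline_window}")
    seg = data[:, :, start:stop]  # (r, E, nb)
    var = seg.transpose(1, 0, 2).reshape(seg.shape[1], -1).var(axis=1)
    var = var + reg_factor * var.mean()
    if np.any(var <= 0):
        raise ValueError("non-positive baseline variance; cannot regularize")
    return NoiseCov(variances=var, reg_factor=reg_factor)


def compute_sloreta_kernel(
    leadfield: LeadField,
    noisecov: NoiseCov | None,
    scalp_snr: float,
) -> InversionKernel:
    """Shared sLORETA inversion kernel with lambda = 1/SNR^2.

    The noise covariance is scaled to unit mean diagonal before the
    lambda-weighted loading; with no covariance given the identity is used.
    The Gram matrix is inverted by pseudoinverse, which also handles the
    average-reference rank deficiency of G.
    """
    if scalp_snr <= 0:
        raise ValueError("scalp_snr must be positive")
    lam = 1.0 / scalp_snr ** 2
    g = leadfield.G
    n_sensors = g.shape[0]
    if noisecov is None:
        c = np.eye(n_sensors)
    else:
        v = noisecov.variances / noisecov.variances.mean()
        c = np.diag(v)
    gram = g @ g.T + lam * c
    k_mne = g.T @ np.linalg.pinv(gram, hermitian=True)
    res_diag = np.einsum("ve,ev->v", k_mne, g)
    std = np.sqrt(np.maximum(res_diag, 1e-30))
    k = k_mne / std[:, None]
    return InversionKernel(K=k, lam=lam, standardization=std)


def apply_kernel(
    kernel: InversionKernel, scalp_trials: TrialTensor, vertices=None
) -> TrialTensor:
    """Apply the shared kernel to every trial (optionally a vertex subset)."""
    k = kernel.K if vertices is None else kernel.K[vertices]
    data = scalp_trials.data
    if k.shape[1] != data.shape[1]:
        raise ValueError(
            f"kernel expects {k.shape[1]} sensors, data has {data.shape[1]}"
        )
    est = np.einsum("ve,ren->rvn", k, data)
    return TrialTensor(
        data=est, fs=scalp_trials.fs, t0_ms=scalp_trials.t0_ms, labels=[]
    )


def resolution_matrix(kernel, leadfield: LeadField) -> ResolutionMatrix:
    """R = K G for the kernel (an InversionKernel or a bare V x E matrix)."""
    k = kernel.K if hasattr(kernel, "K") else np.asarray(kernel)
    if k.shape[1] != leadfield.G.shape[0]:
        raise ValueError("kernel/lead-field dimension mismatch")
    return ResolutionMatrix(R=k @ leadfield.G)
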