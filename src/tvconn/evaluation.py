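"""Figures of merit and the SNR x trial-count factorial benchmark.

Two errors score an estimate against the ground truth, each computed
separately for existing and non-existing connections:

* ``MSE_MVAR``: mean squared difference between estimated and theoretical
  time-varying MVAR coefficients, averaged over time bins, lags and the
  masked (receiver, sender) pairs.
* ``MSE_PDC``: mean squared difference between estimated and theoretical
  squared PDC values over frequency, time and masked off-diagonal pairs;
  the diagonal is always excluded because of the column normalization.

``run_factorial_study`` repeats the full pipeline (simulate -> project ->
invert -> select -> Kalman fit -> PDC -> score) over a grid of scalp SNRs
and trial counts with fresh scalp-noise realizations, the source trials and
head model being shared across realizations (each repetition restarts from
the simulated scalp recordings).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import forward, inverse, selection as sel_mod
from .ground_truth import (
    GroundTruthModel,
    TVMVARParams,
    build_attention_model,
    coefficient_trajectory,
    connection_matrix,
    simulate_trials,
    theoretical_pdc,
)
from .kalman import KalmanConfig, MVARTrajectory, aggregate_ckf, ckf_fit, glkf_fit
from .pdc import PDCTensor, pdc_from_coefficients

__all__ = [
    "ConnectionMask",
    "StudyResult",
    "make_connection_masks",
    "mse_mvar",
    "mse_pdc",
    "run_factorial_study",
    "plot_study_medians",
]

KALMAN_STRATEGIES = ("CKF-1", "CKF-2", "GLKF")


@dataclass(frozen=True)
class ConnectionMask:
    """Boolean matrix over ordered (receiver, sender) pairs."""

    mask: np.ndarray
    cls: str  # "existing" or "nonexisting"

    @property
    def n_pairs(self) -> int:
        return int(self.mask.sum())


def make_connection_masks(model: GroundTruthModel) -> dict[str, ConnectionMask]:
    """Existing / non-existing off-diagonal pair masks of a model."""
    existing = connection_matrix(model)
    m = existing.shape[0]
    off = ~np.eye(m, dtype=bool)
    return {
        "existing": ConnectionMask(mask=existing & off, cls="existing"),
        "nonexisting": ConnectionMask(mask=~existing & off, cls="nonexisting"),
    }


def _coeffs_of(est) -> np.ndarray:
    if isinstance(est, MVARTrajectory):
        return est.coefficients
    return np.asarray(est)


def mse_mvar(estimated, theoretical: TVMVARParams, mask: ConnectionMask) -> float:
    """Mean squared coefficient error over time, lags and masked pairs."""
    est = _coeffs_of(estimated)
    theo = theoretical.coefficients
    if theo.shape[1] < est.shape[1]:
        theo = theoretical.embed(est.shape[1]).coefficients
    if est.shape != theo.shape:
        raise ValueError(f"coefficient grids differ: {est.shape} vs {theo.shape}")
    if mask.n_pairs == 0:
        raise ValueError("empty connection mask")
    diff2 = (est - theo) ** 2
    return float(diff2[:, :, mask.mask].mean())


def mse_pdc(estimated: PDCTensor, theoretical: PDCTensor, mask: ConnectionMask) -> float:
    """Mean squared PDC error over frequency, time and masked off-diagonal pairs."""
    if estimated.values.shape != theoretical.values.shape:
        raise ValueError("PDC grids differ")
    m = estimated.values.shape[0]
    eff = mask.mask & ~np.eye(m, dtype=bool)
    if not eff.any():
        raise ValueError("mask covers only the diagonal; no pairs to score")
    diff2 = (estimated.values - theoretical.values) ** 2
    return float(diff2[eff].mean())


@dataclass
class StudyResult:
    """Long-format factorial result table plus the configuration used."""

    table: pd.DataFrame
    config: dict = field(default_factory=dict)

    def medians(self, by=("kalman", "conn_class")) -> pd.DataFrame:
        ok = self.table[self.table["error"].isna()] if "error" in self.table else self.table
        return ok.groupby(list(by))[["mse_mvar", "mse_pdc"]].median()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _selected_tensor(strategy, rois, signs, est_by_roi, gt_avg, resolution):
    """Stack per-region selected series into a (trials, regions, samples) array."""
    picks, series = [], []
    for r, roi in enumerate(rois):
        res = sel_mod.select_dipole(
            strategy,
            roi,
            est_by_roi[r],
            signs=signs[r],
            ground_truth_series=gt_avg[r],
            resolution=resolution,
        )
        picks.append(res.vertex)
        series.append(res.series)
    return np.stack(series, axis=1), picks


def run_factorial_study(
    snr_levels=(1, 3, 5, 10),
    trial_counts=(3, 5, 10, 20, 40, 60, 80, 100),
    n_realizations: int = 100,
    selection_strategies=("GT2", "DD1", "DD2", "DD3"),
    kalman_strategies=KALMAN_STRATEGIES,
    seed: int = 0,
    model: GroundTruthModel | None = None,
    kalman_config: KalmanConfig | None = None,
    freqs_hz=None,
    n_vertices: int = 1000,
    n_electrodes: int = 32,
    fold_amplitude: float = 6.0,
    roi_size: int = 45,
) -> StudyResult:
    """Run the factorial benchmark over scalp SNR and trial count.

    For each (SNR, realization) the scalp noise is redrawn, the shared
    sLORETA kernel recomputed, dipoles selected per strategy on the full
    trial set, and for every trial count the three Kalman strategies are
    fitted on the leading trials and scored against the theoretical
    references.  Per-trial classical-Kalman fits are computed once per
    selection and reused across trial counts; failures are recorded per cell
    in an ``error`` column and the study continues.

    Deterministic given ``seed`` (one master seed fanned out per stage via a
    spawned SeedSequence counter scheme).
    """
    if model is None:
        model = build_attention_model()
    if kalman_config is None:
        kalman_config = KalmanConfig()
    if freqs_hz is None:
        freqs_hz = np.arange(2.0, 41.0, 4.0)
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    snr_levels = list(snr_levels)
    trial_counts = sorted(trial_counts)
    max_trials = max(trial_counts)

    ss = np.random.SeedSequence(seed)
    sim_seed, *noise_seeds = ss.spawn(1 + len(snr_levels) * n_realizations)

    params = coefficient_trajectory(model)
    theo_params = params.embed(kalman_config.order)
    theo_pdc = theoretical_pdc(params, freqs_hz)
    masks = make_connection_masks(model)

    source_trials, _ = simulate_trials(model, max_trials, seed=np.random.default_rng(sim_seed))
    gt_avg = source_trials.data.mean(axis=0)  # (regions, samples)

    head, sources, sensors = forward.build_head_model(
        n_vertices=n_vertices,
        n_electrodes=n_electrodes,
        fold_amplitude=fold_amplitude,
    )
    lf = forward.compute_leadfield(head, sources, sensors)
    seeds_idx = forward.map_ground_truth_dipoles(sources, model)
    rois = sel_mod.define_rois(sources, seeds_idx, target_size=roi_size)
    signs = [sel_mod.dominant_sign_flip(sources, roi) for roi in rois]
    member_union = np.unique(np.concatenate([roi.members for roi in rois]))
    member_pos = {v: i for i, v in enumerate(member_union)}

    rows = []
    counter = 0
    for snr in snr_levels:
        for real in range(n_realizations):
            noise_rng = np.random.default_rng(noise_seeds[counter])
            counter += 1
            scalp = forward.project_and_add_noise(
                lf, source_trials, scalp_snr=snr, vertex_indices=seeds_idx,
                seed=noise_rng,
            )
            cov = inverse.estimate_noise_covariance(scalp)
            kernel = inverse.compute_sloreta_kernel(lf, cov, scalp_snr=snr)
            est = inverse.apply_kernel(kernel, scalp, vertices=member_union)
            resolution = inverse.resolution_matrix(kernel, lf)
            est_by_roi = [
                est.data[:, [member_pos[v] for v in roi.members], :] for roi in rois
            ]
            for sel_name in selection_strategies:
                try:
                    selected, _ = _selected_tensor(
                        sel_name, rois, signs, est_by_roi, gt_avg, resolution
                    )
                except Exception as exc:  # record and continue
                    rows.extend(
                        _error_rows(kalman_strategies, trial_counts, sel_name,
                                    snr, real, masks, str(exc))
                    )
                    continue
                rows.extend(
                    _score_cell(
                        selected, sel_name, snr, real, trial_counts,
                        kalman_strategies, kalman_config, freqs_hz,
                        model.fs, theo_params, theo_pdc, masks,
                    )
                )
    table = pd.DataFrame(rows)
    config = dict(
        snr_levels=snr_levels, trial_counts=trial_counts,
        n_realizations=n_realizations,
        selection_strategies=list(selection_strategies),
        kalman_strategies=list(kalman_strategies), seed=seed,
        freqs_hz=freqs_hz.tolist(), n_vertices=n_vertices,
        n_electrodes=n_electrodes, fold_amplitude=fold_amplitude,
        roi_size=roi_size, order=kalman_config.order, uc=kalman_config.uc,
    )
    return StudyResult(table=table, config=config)


def _error_rows(kalman_strategies, trial_counts, sel_name, snr, real, masks, msg):
    out = []
    for kal in kalman_strategies:
        for nt in trial_counts:
            for cls in masks:
                out.append(dict(
                    kalman=kal, selection=sel_name, snr=snr, n_trials=nt,
                    realization=real, conn_class=cls,
                    mse_mvar=np.nan, mse_pdc=np.nan, error=msg,
                ))
    return out


def _score_cell(selected, sel_name, snr, real, trial_counts, kalman_strategies,
                config, freqs_hz, fs, theo_params, theo_pdc, masks):
    """Score all (kalman, n_trials, class) cells for one selected tensor."""
    max_trials = selected.shape[0]
    need_ckf = any(k in kalman_strategies for k in ("CKF-1", "CKF-2"))
    if need_ckf:
        ckf_trajs = [ckf_fit(selected[t], config) for t in range(max_trials)]
        ckf_pdcs = [
            pdc_from_coefficients(tr.coefficients, freqs_hz, fs) for tr in ckf_trajs
        ]
        ckf_mse = {
            cls: [mse_mvar(tr, theo_params, masks[cls]) for tr in ckf_trajs]
            for cls in masks
        }
    rows = []
    for nt in trial_counts:
        for kal in kalman_strategies:
            try:
                if kal == "CKF-1":
                    traj = aggregate_ckf(ckf_trajs[:nt])
                    tensor = pdc_from_coefficients(traj.coefficients, freqs_hz, fs)
                    mv = {cls: mse_mvar(traj, theo_params, masks[cls]) for cls in masks}
                elif kal == "CKF-2":
                    vals = np.mean([p.values for p in ckf_pdcs[:nt]], axis=0)
                    tensor = PDCTensor(values=vals, freqs_hz=freqs_hz, fs=fs)
                    mv = {cls: float(np.mean(ckf_mse[cls][:nt])) for cls in masks}
                elif kal == "GLKF":
                    traj = glkf_fit(selected[:nt], config)
                    tensor = pdc_from_coefficients(traj.coefficients, freqs_hz, fs)
                    mv = {cls: mse_mvar(traj, theo_params, masks[cls]) for cls in masks}
                else:
                    raise ValueError(f"unknown Kalman strategy {kal!r}")
                for cls, cmask in masks.items():
                    rows.append(dict(
                        kalman=kal, selection=sel_name, snr=snr, n_trials=nt,
                        realization=real, conn_class=cls,
                        mse_mvar=mv[cls],
                        mse_pdc=mse_pdc(tensor, theo_pdc, cmask),
                        error=np.nan,
                    ))
            except Exception as exc:
                for cls in masks:
                    rows.append(dict(
                        kalman=kal, selection=sel_name, snr=snr, n_trials=nt,
                        realization=real, conn_class=cls,
                        mse_mvar=np.nan, mse_pdc=np.nan, error=str(exc),
                    ))
    return rows


def plot_study_medians(result: StudyResult, metric: str = "mse_pdc", ax=None):
    """Minimal visual summary: median metric vs trial count per Kalman
    strategy, one line style per connection class."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    med = (
        result.table.groupby(["kalman", "conn_class", "n_trials"])[metric]
        .median()
        .reset_index()
    )
    for (kal, cls), grp in med.groupby(["kalman", "conn_class"]):
        ls = "-" if cls == "existing" else "--"
        ax.plot(grp["n_trials"], grp[metric], ls, label=f"{kal} ({cls})")
    ax.set_xlabel("trials")
    ax.set_ylabel(f"median {metric}")
    ax.legend(fontsize=7)
    return ax
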