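"""Run-level design matrices and ordinary-least-squares β estimation.

Each run's design matrix has 24 stimulus regressors of interest (4-s
events convolved with the canonical SPM double-gamma HRF), one
no-interest regressor collecting catch trials, head-motion nuisance
columns (accepted as given, zeros by default), and a constant — 32
columns for the default six motion parameters. β-images per stimulus and
run are estimated by OLS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from nilearn.glm.first_level import compute_regressor
from sklearn.base import BaseEstimator

from .stimuli import N_STIMULI
from .synth import TrialSchedule

DEFAULT_TR = 2.0
EVENT_DURATION_S = 4.0  # two 2-s presentations per trial
DEFAULT_HRF = "spm"


@dataclass
class DesignMatrix:
    matrix: np.ndarray  # (n_frames, n_regressors)
    names: list[str]
    tr: float
    run_id: int = 0

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.tr

    def stimulus_columns(self) -> np.ndarray:
        return np.array([i for i, n in enumerate(self.names) if n.startswith("stim_")])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.names)


def make_design_matrix(
    schedule: TrialSchedule,
    tr: float = DEFAULT_TR,
    hrf: str = DEFAULT_HRF,
    n_motion: int = 6,
    motion: np.ndarray | None = None,
    run_id: int = 0,
) -> DesignMatrix:
    """Build the run design matrix from a trial schedule.

    Stimulus regressors are driven only by non-catch trials of that
    stimulus; catch trials load a single no-interest column. Frames are
    sampled every ``tr`` seconds over the run; a trailing partial frame
    is dropped with a warning when ``tr`` does not divide the run
    duration.
    """
    if tr <= 0:
        raise ValueError("TR must be positive")
    if n_motion < 0:
        raise ValueError("n_motion must be >= 0")
    dur = schedule.run_duration
    n_frames = int(dur / tr)
    if abs(n_frames * tr - dur) > 1e-9:
        warnings.warn(
            f"run duration {dur} s is not a multiple of TR={tr} s; "
            "dropping the trailing partial frame",
            RuntimeWarning,
            stacklevel=2,
        )
    frame_times = np.arange(n_frames) * tr
    trials = schedule.trials

    cols, names = [], []
    for sid in range(1, N_STIMULI + 1):
        onsets = trials.loc[
            (trials["stimulus_id"] == sid) & (~trials["is_catch"]), "onset"
        ].to_numpy(dtype=float)
        cols.append(_event_regressor(onsets, frame_times, hrf))
        names.append(f"stim_{sid:02d}")

    catch_onsets = trials.loc[trials["is_catch"], "onset"].to_numpy(dtype=float)
    cols.append(_event_regressor(catch_onsets, frame_times, hrf))
    names.append("catch")

    if n_motion:
        if motion is None:
            motion = np.zeros((n_frames, n_motion))
        motion = np.asarray(motion, dtype=float)
        if motion.shape != (n_frames, n_motion):
            raise ValueError(
                f"motion must be ({n_frames}, {n_motion}), got {motion.shape}"
            )
        for m in range(n_motion):
            cols.append(motion[:, m])
            names.append(f"motion_{m + 1}")

    cols.append(np.ones(n_frames))
    names.append("constant")
    return DesignMatrix(np.column_stack(cols), names, tr, run_id)


def _event_regressor(onsets: np.ndarray, frame_times: np.ndarray, hrf: str) -> np.ndarray:
    if len(onsets) == 0:
        return np.zeros(len(frame_times))
    cond = np.vstack(
        [onsets, np.full_like(onsets, EVENT_DURATION_S), np.ones_like(onsets)]
    )
    sig, _ = compute_regressor(cond, hrf, frame_times, con_id="c")
    return sig[:, 0]


class RunGLM(BaseEstimator):
    """OLS general linear model for one run's voxel time series.

    sklearn-style estimator: ``fit(X_design, Y_timeseries)`` stores the
    full coefficient matrix in ``coef_`` (regressors × voxels) and the
    24 stimulus β-vectors in ``stimulus_betas_``.
    """

    def __init__(self, check_rank: bool = True):
        self.check_rank = check_rank

    def fit(self, design: DesignMatrix, Y: np.ndarray) -> "RunGLM":
        X = design.matrix
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if Y.shape[0] != X.shape[0]:
            raise ValueError(
                f"timeseries has {Y.shape[0]} frames but design has {X.shape[0]}"
            )
        # all-zero nuisance columns (e.g. placeholder motion regressors) are
        # inert: lstsq's minimum-norm solution assigns them β = 0 and leaves
        # the stimulus β unique, so only active columns enter the rank check
        active = np.flatnonzero(np.any(X != 0, axis=0))
        if self.check_rank and np.linalg.matrix_rank(X[:, active]) < len(active):
            names_active = [design.names[i] for i in active]
            raise ValueError(
                "design matrix is rank deficient; collinear columns: "
                + ", ".join(_collinear_columns(X[:, active], names_active))
            )
        coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
        self.coef_ = coef
        self.names_ = list(design.names)
        self.residuals_ = Y - X @ coef
        stim_idx = design.stimulus_columns()
        self.stimulus_betas_ = coef[stim_idx]  # (24, n_voxels)
        return self

    def get_betas(self, names: list[str] | None = None) -> np.ndarray:
        if names is None:
            return self.stimulus_betas_
        idx = [self.names_.index(n) for n in names]
        return self.coef_[idx]


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Name columns involved in rank deficiency via small QR pivots."""
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    return [names[i] for i in np.flatnonzero(diag <= tol)] or ["<unidentified>"]


def fit_glm(timeseries: np.ndarray, design: DesignMatrix) -> np.ndarray:
    """OLS fit returning only the 24 stimulus β-vectors (24 × voxels)."""
    return RunGLM().fit(design, timeseries).stimulus_betas_


def simulate_timeseries(
    design: DesignMatrix,
    stimulus_betas: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator,
    nuisance_betas: np.ndarray | None = None,
) -> np.ndarray:
    """Forward model: Y = X β + white noise, for pipeline round-trips."""
    B = np.asarray(stimulus_betas, dtype=float)
    n_vox = B.shape[1]
    full = np.zeros((design.matrix.shape[1], n_vox))
    full[design.stimulus_columns()] = B
    if nuisance_betas is not None:
        nb = np.asarray(nuisance_betas, dtype=float)
        other = [i for i in range(len(design.names)) if i not in design.stimulus_columns()]
        full[other] = nb
    Y = design.matrix @ full
    if noise_sd > 0:
        Y = Y + rng.normal(0.0, noise_sd, size=Y.shape)
    return Y


__all__ = [
    "DesignMatrix",
    "RunGLM",
    "make_design_matrix",
    "fit_glm",
    "simulate_timeseries",
    "DEFAULT_TR",
    "EVENT_DURATION_S",
]
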