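"""Synthetic cohorts, trial schedules, behavioral ratings and β-patterns.

This module generates data with the statistical structure the downstream
analyses assume, so the whole chain (design/GLM → ROI definition → decoding
→ RSA → nonparametric group inference) can be exercised and validated
without any scanner data.

The β-pattern generator plants a chosen representational geometry: the
target model dissimilarity matrix (1 − Pearson r space) is factorised into
8 category prototype vectors whose pairwise correlation distances
reproduce the target, the prototypes are lifted into voxel space by a
random orthonormal map orthogonal to the constant vector (so Pearson
correlations are preserved exactly), and each run's observation is
``signal_scale × prototype + iid Gaussian noise``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stimuli import (
    CATEGORIES,
    SUPERORDINATE_ORDER,
    N_STIMULI,
    make_stimulus_table,
    superordinate_labels,
)

TRIAL_DURATION_S = 6.0  # 4 s stimulus pair + 2 s inter-trial interval
REST_DURATION_S = 20.0
DEFAULT_N_REPS = 3
DEFAULT_N_CATCH = 8
DEFAULT_N_RUNS = 5


class ScheduleInfeasibleError(RuntimeError):
    """Raised when no trial order satisfying the adjacency rule is found."""


@dataclass
class TrialSchedule:
    """An ordered run schedule.

    trials: DataFrame with columns onset (s), stimulus_id,
        second_stimulus_id, is_catch. Non-catch trials repeat the same
        stimulus twice; catch trials present two different stimuli.
    rest_periods: list of (onset, duration) in seconds.
    run_duration: total run length in seconds.
    """

    trials: pd.DataFrame
    rest_periods: list[tuple[float, float]]
    run_duration: float


@dataclass
class Cohort:
    """Subjects with group membership and age."""

    subjects: pd.DataFrame  # columns: subject_id, group, age

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.subjects["group"]))

    def ids(self, group: str | None = None) -> list[str]:
        df = self.subjects
        if group is not None:
            df = df[df["group"] == group]
        return list(df["subject_id"])

    def __len__(self) -> int:
        return len(self.subjects)


@dataclass
class BetaArray:
    """Per-subject stimulus response estimates for one ROI.

    values: array (n_subjects, n_runs, 24, n_voxels).
    """

    values: np.ndarray
    subject_ids: list[str]
    roi: str
    condition_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4:
            raise ValueError("values must be (subject, run, condition, voxel)")
        if self.values.shape[2] != N_STIMULI:
            raise ValueError(f"condition axis must have length {N_STIMULI}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("β values must be finite")
        if len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("subject_ids length mismatch")

    @property
    def n_runs(self) -> int:
        return self.values.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[3]

    def subject(self, subject_id: str) -> np.ndarray:
        """(n_runs, 24, n_voxels) for one subject."""
        return self.values[self.subject_ids.index(subject_id)]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    signal_scale is either a scalar applied everywhere or a mapping
    ``(group, roi) -> scale`` for group-by-region differences in signal
    strength. ``target_model`` names the model DSM governing the planted
    condition geometry (see :mod:`soundcat.rsa`).
    """

    n_voxels: int = 100
    signal_scale: float | dict = 1.0
    noise_sd: float = 1.0
    target_model: str = "human"
    n_runs: int = DEFAULT_N_RUNS
    rois: tuple[str, ...] = ("occipital", "temporal")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_voxels < 9:
            raise ValueError("n_voxels must be at least 9 (8 prototypes + mean)")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not (np.isfinite(self.noise_sd) and self.noise_sd > 0):
            raise ValueError("noise_sd must be positive and finite")
        for s in self._all_scales():
            if not (np.isfinite(s) and s >= 0):
                raise ValueError("signal scales must be finite and >= 0")

    def _all_scales(self):
        if isinstance(self.signal_scale, dict):
            return list(self.signal_scale.values())
        return [float(self.signal_scale)]

    def scale_for(self, group: str, roi: str) -> float:
        if isinstance(self.signal_scale, dict):
            if (group, roi) in self.signal_scale:
                return float(self.signal_scale[(group, roi)])
            return 0.0
        return float(self.signal_scale)


# ---------------------------------------------------------------------------
# Trial schedules
# ---------------------------------------------------------------------------

def build_run_schedule(
    stimuli: pd.DataFrame,
    n_reps: int = DEFAULT_N_REPS,
    n_catch: int = DEFAULT_N_CATCH,
    seed: int = 0,
    with_rests: bool = True,
    max_restarts: int = 1000,
) -> TrialSchedule:
    """Build one pseudo-randomised run schedule.

    Each trial lasts 6 s (two 2-s presentations + 2-s gap). The run holds
    ``n_reps`` repetitions of each of the 24 stimuli plus ``n_catch``
    catch trials (second stimulus differs from the first), with one 20-s
    rest mid-run and one at the end when ``with_rests``. Consecutive
    trials never share a superordinate class; a bounded number of
    restarts guards against pathological draws.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if n_catch < 0:
        raise ValueError("n_catch must be >= 0")
    rng = np.random.default_rng(seed)
    sups = superordinate_labels(stimuli)
    sids = stimuli.sort_values("stimulus_id")["stimulus_id"].to_numpy()

    # Trial pool: (stimulus_id, second_stimulus_id, is_catch, superordinate)
    pool: list[tuple[int, int, bool, str]] = []
    for sid, sup in zip(sids, sups):
        pool.extend([(int(sid), int(sid), False, sup)] * n_reps)
    for _ in range(n_catch):
        i = int(rng.integers(N_STIMULI))
        j = int((i + 1 + rng.integers(N_STIMULI - 1)) % N_STIMULI)
        pool.append((int(sids[i]), int(sids[j]), True, sups[i]))

    order = _order_without_adjacent_class(pool, rng, max_restarts)

    n_trials = len(order)
    onsets, rests = [], []
    t = 0.0
    mid = n_trials // 2
    for k in range(n_trials):
        if with_rests and k == mid:
            rests.append((t, REST_DURATION_S))
            t += REST_DURATION_S
        onsets.append(t)
        t += TRIAL_DURATION_S
    if with_rests:
        rests.append((t, REST_DURATION_S))
        t += REST_DURATION_S

    trials = pd.DataFrame(
        {
            "onset": onsets,
            "stimulus_id": [tr[0] for tr in order],
            "second_stimulus_id": [tr[1] for tr in order],
            "is_catch": [tr[2] for tr in order],
        }
    )
    return TrialSchedule(trials=trials, rest_periods=rests, run_duration=t)


def _order_without_adjacent_class(pool, rng, max_restarts):
    """Sequence trials so consecutive superordinate classes differ.

    Greedy random construction: when one class holds at least half of the
    remaining trials it must be drawn (else it is forced into adjacency
    later); otherwise a uniform draw among allowed trials. Restart on a
    dead end.
    """
    for _ in range(max_restarts):
        remaining = list(pool)
        rng.shuffle(remaining)
        out = []
        prev = None
        ok = True
        while remaining:
            counts: dict[str, int] = {}
            for tr in remaining:
                counts[tr[3]] = counts.get(tr[3], 0) + 1
            majority = max(counts, key=counts.get)
            if counts[majority] * 2 > len(remaining) + 1 and majority != prev:
                cands = [i for i, tr in enumerate(remaining) if tr[3] == majority]
            else:
                cands = [i for i, tr in enumerate(remaining) if tr[3] != prev]
            if not cands:
                ok = False
                break
            i = cands[int(rng.integers(len(cands)))]
            out.append(remaining.pop(i))
            prev = out[-1][3]
        if ok:
            return out
    raise ScheduleInfeasibleError(
        f"no order satisfying the superordinate adjacency rule after "
        f"{max_restarts} restarts; the design is likely infeasible"
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

DEFAULT_AGE_RANGES = {"EB": (22.0, 62.0), "LB": (25.0, 68.0), "SC": (23.0, 63.0)}


def generate_cohort(
    n_per_group: dict[str, int],
    age_ranges: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> Cohort:
    """Generate a reproducible cohort with uniform ages per group."""
    rng = np.random.default_rng(seed)
    age_ranges = age_ranges or {}
    rows = []
    for group, n in n_per_group.items():
        if n < 2:
            raise ValueError(f"group {group!r} needs >= 2 subjects, got {n}")
        lo, hi = age_ranges.get(group, DEFAULT_AGE_RANGES.get(group, (20.0, 65.0)))
        if lo <= 0 or hi < lo:
            raise ValueError(f"invalid age range for group {group!r}")
        ages = rng.uniform(lo, hi, size=n)
        for k in range(n):
            rows.append(
                {
                    "subject_id": f"{group}{k + 1:02d}",
                    "group": group,
                    "age": float(ages[k]),
                }
            )
    return Cohort(subjects=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# β-pattern generation
# ---------------------------------------------------------------------------

def embed_dsm_prototypes(
    target_dsm: np.ndarray, n_voxels: int, rng: np.random.Generator
) -> np.ndarray:
    """Embed an 8×8 correlation-distance DSM as 8 voxel patterns.

    Factorises the similarity Gram matrix G = 1 − DSM (clipping negative
    eigenvalues when G is not positive semidefinite, with a warning) and
    lifts the factor rows into voxel space through a random orthonormal
    basis orthogonal to the constant vector. The returned (8, n_voxels)
    patterns are zero-mean with unit norm, so their pairwise Pearson
    correlation matrix equals the (unit-diagonal-normalised) clipped G.
    """
    D = np.asarray(target_dsm, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T):
        raise ValueError("target DSM must be square and symmetric")
    G = 1.0 - D
    np.fill_diagonal(G, 1.0)
    evals, evecs = np.linalg.eigh(G)
    if evals.min() < -1e-10:
        warnings.warn(
            "target DSM is not embeddable in correlation-distance space; "
            "negative Gram eigenvalues clipped to zero",
            RuntimeWarning,
            stacklevel=2,
        )
    evals = np.clip(evals, 0.0, None)
    V = evecs * np.sqrt(evals)  # (n, n) factor, rows ~ prototypes
    norms = np.linalg.norm(V, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("degenerate prototype from target DSM")
    V = V / norms[:, None]

    d = V.shape[1]
    if n_voxels < d + 1:
        raise ValueError(f"need at least {d + 1} voxels to embed {n} prototypes")
    # Orthonormal lift whose basis vectors are all zero-mean across voxels:
    # centering rows removes the component along the constant vector before QR.
    M = rng.normal(size=(d, n_voxels))
    M -= M.mean(axis=1, keepdims=True)
    Q, _ = np.linalg.qr(M.T)  # (n_voxels, d), orthonormal columns ⟂ 1
    return V @ Q.T  # (n, n_voxels)


def generate_beta_patterns(
    cohort: Cohort,
    stimuli: pd.DataFrame,
    config: SimulationConfig,
    target_dsm: np.ndarray | None = None,
) -> dict[str, BetaArray]:
    """Simulate β-pattern arrays for every subject and ROI.

    All three exemplars of a category share that category's prototype
    pattern, so the noise-free condition-level (8×8) Pearson-distance DSM
    matches the target geometry. Observations per run are
    ``scale × prototype + N(0, noise_sd)`` i.i.d. over voxels and runs.
    """
    if target_dsm is None:
        from .rsa import build_categorical_model_dsms

        target_dsm = build_categorical_model_dsms()[config.target_model].values
    ss = np.random.SeedSequence(config.seed)
    embed_rng = np.random.default_rng(ss.spawn(1)[0])
    prototypes8 = embed_dsm_prototypes(target_dsm, config.n_voxels, embed_rng)
    # Expand to the 24-stimulus level: exemplars inherit the category prototype.
    cat_index = (
        stimuli.sort_values("stimulus_id")["category"]
        .map({c: i for i, c in enumerate(CATEGORIES)})
        .to_numpy()
    )
    prototypes24 = prototypes8[cat_index]  # (24, n_voxels)

    labels = list(stimuli.sort_values("stimulus_id")["label"])
    out: dict[str, BetaArray] = {}
    noise_ss = ss.spawn(len(config.rois))
    for roi, roi_seed in zip(config.rois, noise_ss):
        rng = np.random.default_rng(roi_seed)
        vals = np.empty((len(cohort), config.n_runs, N_STIMULI, config.n_voxels))
        for s, (sid, group) in enumerate(
            zip(cohort.subjects["subject_id"], cohort.subjects["group"])
        ):
            scale = config.scale_for(group, roi)
            noise = rng.normal(
                0.0, config.noise_sd, size=(config.n_runs, N_STIMULI, config.n_voxels)
            )
            vals[s] = scale * prototypes24[None] + noise
        out[roi] = BetaArray(
            values=vals,
            subject_ids=list(cohort.subjects["subject_id"]),
            roi=roi,
            condition_labels=labels,
        )
    return out


# ---------------------------------------------------------------------------
# Acoustic features and behavioral ratings
# ---------------------------------------------------------------------------

def generate_acoustic_and_behavioral(
    stimuli: pd.DataFrame | None = None,
    cohort: Cohort | None = None,
    seed: int = 0,
    behavioral_noise_sd: float = 0.1,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Fill acoustic columns and simulate per-subject 8×8 rating DSMs.

    Behavioral dissimilarity ratings follow the superordinate category
    structure (0 within category, 0.4 within superordinate class, 1
    otherwise) plus symmetric Gaussian subject noise, clipped at 0, with
    a zero diagonal.
    """
    ss = np.random.SeedSequence(seed)
    s_stim, s_beh = ss.spawn(2)
    if stimuli is None:
        stimuli = make_stimulus_table(seed=int(s_stim.generate_state(1)[0] % 2**31))
    base = _behavioral_base_dsm()
    ratings: dict[str, np.ndarray] = {}
    rng = np.random.default_rng(s_beh)
    subject_ids = cohort.ids() if cohort is not None else []
    for sid in subject_ids:
        noise = rng.normal(0.0, behavioral_noise_sd, size=base.shape)
        noise = (noise + noise.T) / 2.0
        dsm = np.clip(base + noise, 0.0, None)
        np.fill_diagonal(dsm, 0.0)
        ratings[sid] = dsm
    return stimuli, ratings


def _behavioral_base_dsm() -> np.ndarray:
    from .stimuli import CATEGORY_TO_SUPERORDINATE

    sup_of = [CATEGORY_TO_SUPERORDINATE[cat] for cat in CATEGORIES]
    base = np.ones((len(CATEGORIES), len(CATEGORIES)))
    for i in range(len(CATEGORIES)):
        for j in range(len(CATEGORIES)):
            if i == j:
                base[i, j] = 0.0
            elif sup_of[i] == sup_of[j]:
                base[i, j] = 0.4
    return base


__all__ = [
    "TrialSchedule",
    "Cohort",
    "BetaArray",
    "SimulationConfig",
    "ScheduleInfeasibleError",
    "build_run_schedule",
    "generate_cohort",
    "generate_beta_patterns",
    "generate_acoustic_and_behavioral",
    "embed_dsm_prototypes",
    "SUPERORDINATE_ORDER",
]
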