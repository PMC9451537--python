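"""Representational similarity analysis.

Brain dissimilarity matrices (1 − Pearson r between condition patterns),
the seven candidate representational models (behavioral ratings, four
categorical composites, HNR and pitch), model–brain Spearman comparison
with a leave-one-subject-out noise ceiling, cross-ROI DSM correlation
with condition-permutation inference, rank-based partial correlation,
and split-half pattern stability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stimuli import CATEGORIES, CATEGORY_TO_SUPERORDINATE, SUPERORDINATES
from .synth import BetaArray

MODEL_NAMES = ("behavioral", "human", "animal", "manipulable", "big_place", "hnr", "pitch")


@dataclass
class DSM:
    """A symmetric, zero-diagonal dissimilarity matrix.

    Analyses only ever consume the upper triangle (``.vec``), which for
    the 8-condition case is a 28-vector.
    """

    values: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("DSM must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("DSM entries must be finite")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("DSM must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-10):
            raise ValueError("DSM diagonal must be zero")
        self.values = v
        if not self.labels:
            self.labels = [str(i) for i in range(v.shape[0])]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def vec(self) -> np.ndarray:
        """Upper-triangle entries (row-major, diagonal excluded)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def permuted(self, perm: np.ndarray) -> "DSM":
        """Jointly permute rows and columns (condition relabelling)."""
        p = np.asarray(perm)
        return DSM(self.values[np.ix_(p, p)], [self.labels[i] for i in p])


@dataclass
class ModelDSM(DSM):
    name: str = ""
    provenance: str = ""  # ratings | categorical rule | acoustic feature


# ---------------------------------------------------------------------------
# Brain DSMs
# ---------------------------------------------------------------------------

def compute_brain_dsm(condition_maps: np.ndarray, labels: list[str] | None = None) -> DSM:
    """Pearson-distance DSM of condition patterns.

    ``condition_maps`` is (n_conditions, n_voxels); entry (i, j) of the
    result is ``1 − Pearson r(pattern_i, pattern_j)``.
    """
    P = np.asarray(condition_maps, dtype=float)
    if P.ndim != 2 or P.shape[1] < 3:
        raise ValueError("need (n_conditions, n_voxels>=3) condition patterns")
    sd = P.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        name = labels[bad] if labels else str(bad)
        raise ValueError(f"zero-variance pattern for condition {name!r}")
    d = 1.0 - np.corrcoef(P)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DSM(d, labels or [])


def condition_patterns(
    subject_betas: np.ndarray, mode: str = "t", level: str = "category"
) -> np.ndarray:
    """Condition-level patterns from one subject's (runs, 24, voxels) β.

    mode 't' (default): per-voxel t statistic of β across runs
    (mean / SE), emulating contrast T-maps; mode 'beta': plain run mean.
    level 'category' averages the 3 exemplars of each of the 8
    categories; level 'stimulus' keeps all 24.
    """
    B = np.asarray(subject_betas, dtype=float)
    if B.ndim != 3:
        raise ValueError("subject betas must be (runs, conditions, voxels)")
    n_runs = B.shape[0]
    if mode == "t":
        if n_runs < 2:
            raise ValueError("t mode needs >= 2 runs")
        se = B.std(axis=0, ddof=1) / np.sqrt(n_runs)
        se = np.where(se == 0, np.finfo(float).eps, se)
        maps = B.mean(axis=0) / se
    elif mode == "beta":
        maps = B.mean(axis=0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if level == "stimulus":
        return maps
    if level != "category":
        raise ValueError(f"unknown level {level!r}")
    n_cat = len(CATEGORIES)
    per = maps.shape[0] // n_cat
    return maps.reshape(n_cat, per, -1).mean(axis=1)


def subject_dsm(subject_betas: np.ndarray, mode: str = "t") -> DSM:
    """8×8 Pearson-distance DSM for one subject."""
    return compute_brain_dsm(condition_patterns(subject_betas, mode=mode), list(CATEGORIES))


# ---------------------------------------------------------------------------
# Model DSMs
# ---------------------------------------------------------------------------

def _composite_categorical_dsm(target_categories: list[str]) -> np.ndarray:
    """Average of the two binary cluster hypotheses for a target class.

    Hypothesis A: the target categories form one cluster and everything
    else a second cluster (0 within each, 1 between). Hypothesis B: the
    target categories cluster and all other categories are mutually
    different (1 among themselves and to the target). The composite mean
    gives 0 within the target, 1 target↔other, 0.5 other↔other.
    """
    n = len(CATEGORIES)
    in_t = np.array([c in target_categories for c in CATEGORIES])
    A = np.where(in_t[:, None] == in_t[None, :], 0.0, 1.0)
    B = np.where(in_t[:, None] & in_t[None, :], 0.0, 1.0)
    M = (A + B) / 2.0
    np.fill_diagonal(M, 0.0)
    return M


def build_categorical_model_dsms() -> dict[str, ModelDSM]:
    """The four categorical composite models (human, animal, manipulable, big_place)."""
    out = {}
    for sup, cats in SUPERORDINATES.items():
        out[sup] = ModelDSM(
            _composite_categorical_dsm(cats),
            list(CATEGORIES),
            name=sup,
            provenance="categorical rule",
        )
    return out


def acoustic_model_dsm(stimuli: pd.DataFrame, feature: str, name: str) -> ModelDSM:
    """|Δfeature| between condition-mean acoustic values (8×8)."""
    if feature not in stimuli.columns:
        raise ValueError(f"stimulus table lacks feature {feature!r}")
    means = stimuli.groupby("category", sort=False)[feature].mean()
    v = means.reindex(CATEGORIES).to_numpy()
    if np.any(~np.isfinite(v)):
        raise ValueError(f"missing {feature} values for some category")
    M = np.abs(v[:, None] - v[None, :])
    return ModelDSM(M, list(CATEGORIES), name=name, provenance="acoustic feature")


def build_model_dsms(
    stimuli: pd.DataFrame, ratings: dict[str, np.ndarray] | None = None
) -> dict[str, ModelDSM]:
    """The full set of seven representational models.

    ``ratings`` maps subject_id → 8×8 behavioral dissimilarity DSM; the
    behavioral model is their elementwise mean (typically taken within a
    group, one behavioral model per group).
    """
    models = build_categorical_model_dsms()
    models["hnr"] = acoustic_model_dsm(stimuli, "hnr", "hnr")
    models["pitch"] = acoustic_model_dsm(stimuli, "pitch", "pitch")
    if ratings:
        mean_dsm = np.mean([np.asarray(r, dtype=float) for r in ratings.values()], axis=0)
        models["behavioral"] = ModelDSM(
            mean_dsm, list(CATEGORIES), name="behavioral", provenance="ratings"
        )
    return {k: models[k] for k in MODEL_NAMES if k in models}


# ---------------------------------------------------------------------------
# Comparisons
# ---------------------------------------------------------------------------

def correlate_model(brain: DSM, model: DSM) -> float:
    """Spearman rank correlation of the two upper-triangle vectors."""
    x, y = brain.vec, model.vec
    if len(x) != len(y):
        raise ValueError("DSM sizes differ")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rho, _ = sps.spearmanr(x, y)
    return float(rho)


def partial_correlate_model(brain: DSM, model: DSM, covariates: list[DSM]) -> float:
    """Rank-based partial correlation of brain and model given covariates.

    All upper-triangle vectors are rank-transformed (average ranks);
    brain and model ranks are residualised on the covariate ranks (plus
    an intercept) by least squares, and the residuals correlated.
    """
    if not covariates:
        raise ValueError("need at least one covariate model")
    for cov in covariates:
        if cov is model or np.array_equal(cov.values, model.values):
            raise ValueError("a covariate duplicates the model of interest")
    rx = sps.rankdata(brain.vec)
    ry = sps.rankdata(model.vec)
    Z = np.column_stack([sps.rankdata(c.vec) for c in covariates])
    Z = np.column_stack([np.ones(len(rx)), Z])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("collinear covariates")
    coef_x, _, _, _ = np.linalg.lstsq(Z, rx, rcond=None)
    coef_y, _, _, _ = np.linalg.lstsq(Z, ry, rcond=None)
    ex, ey = rx - Z @ coef_x, ry - Z @ coef_y
    if np.allclose(ex, 0) or np.allclose(ey, 0):
        return float("nan")
    return float(np.corrcoef(ex, ey)[0, 1])


def cross_roi_correlation(
    dsm_a: DSM,
    dsm_b: DSM,
    n_perm: int = 10000,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman correlation of two DSMs with a condition-permutation p.

    The null jointly permutes rows and columns of one matrix (condition
    relabelling); p is the proportion of null correlations ≥ observed,
    floored at 1/n_perm.
    """
    if dsm_a.n != dsm_b.n:
        raise ValueError("DSM shapes differ")
    obs = correlate_model(dsm_a, dsm_b)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(dsm_a.n)
        if correlate_model(dsm_a.permuted(perm), dsm_b) >= obs:
            count += 1
    p = max(count, 1) / n_perm
    return obs, float(p)


def noise_ceiling_lower(subject_dsms: list[DSM]) -> float:
    """Lower bound of the noise ceiling for a group of subject DSMs.

    Mean over subjects of the Spearman correlation between each
    subject's DSM and the mean DSM of the remaining subjects: the
    reliability-limited correlation any model could attain.
    """
    if len(subject_dsms) < 3:
        raise ValueError("noise ceiling needs >= 3 subjects")
    mats = np.stack([d.values for d in subject_dsms])
    total = mats.sum(axis=0)
    vals = []
    for i, d in enumerate(subject_dsms):
        loo = DSM((total - mats[i]) / (len(subject_dsms) - 1), d.labels)
        vals.append(correlate_model(d, loo))
    return float(np.mean(vals))


@dataclass
class ModelComparison:
    """Per-model group comparison against subject DSMs."""

    per_subject_rho: pd.DataFrame  # subjects × models
    mean_rho: pd.Series
    noise_ceiling: float
    p_values: pd.Series | None = None  # FDR-corrected, filled by callers


def compare_models(
    subject_dsms: dict[str, DSM], models: dict[str, ModelDSM]
) -> ModelComparison:
    """Spearman correlation of every subject DSM with every model."""
    rows = {
        sid: {name: correlate_model(d, m) for name, m in models.items()}
        for sid, d in subject_dsms.items()
    }
    table = pd.DataFrame.from_dict(rows, orient="index")
    ceiling = noise_ceiling_lower(list(subject_dsms.values())) if len(subject_dsms) >= 3 else float("nan")
    return ModelComparison(
        per_subject_rho=table, mean_rho=table.mean(axis=0), noise_ceiling=ceiling
    )


# ---------------------------------------------------------------------------
# Split-half stability
# ---------------------------------------------------------------------------

def split_half_matrix(
    subject_betas: np.ndarray, half_a: list[int] | None = None
) -> np.ndarray:
    """24×24 cross-half correlation matrix of stimulus patterns.

    Runs are split into two halves (odd-index runs {0, 2, 4} vs even
    {1, 3} by default for five runs), patterns averaged within each
    half, and every half-1 stimulus pattern correlated with every
    half-2 stimulus pattern.
    """
    B = np.asarray(subject_betas, dtype=float)
    n_runs = B.shape[0]
    if n_runs < 2:
        raise ValueError("split-half needs >= 2 runs")
    if half_a is None:
        half_a = list(range(0, n_runs, 2))
    half_b = [r for r in range(n_runs) if r not in half_a]
    if not half_a or not half_b:
        raise ValueError("both halves must contain at least one run")
    A = B[half_a].mean(axis=0)  # (24, voxels)
    Bm = B[half_b].mean(axis=0)
    n = A.shape[0]
    C = np.corrcoef(A, Bm)[:n, n:]
    return C


def split_half_stability(
    subject_betas: np.ndarray, half_a: list[int] | None = None
) -> float:
    """Mean on-diagonal minus mean off-diagonal cross-half correlation."""
    C = split_half_matrix(subject_betas, half_a=half_a)
    n = C.shape[0]
    diag = np.trace(C) / n
    off = (C.sum() - np.trace(C)) / (n * n - n)
    return float(diag - off)


def split_half_from_beta_array(betas: BetaArray, subject_id: str) -> float:
    return split_half_stability(betas.subject(subject_id))


__all__ = [
    "DSM",
    "ModelDSM",
    "ModelComparison",
    "MODEL_NAMES",
    "compute_brain_dsm",
    "condition_patterns",
    "subject_dsm",
    "build_model_dsms",
    "build_categorical_model_dsms",
    "acoustic_model_dsm",
    "correlate_model",
    "partial_correlate_model",
    "cross_roi_correlation",
    "noise_ceiling_lower",
    "compare_models",
    "split_half_matrix",
    "split_half_stability",
]
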