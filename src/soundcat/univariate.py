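"""Univariate analyses: contrasts, leave-one-subject-out ROIs, mixed ANOVA.

ROIs are defined without circularity: for each subject the group
contrast (sounds vs. baseline, compared between groups by a voxelwise
Welch t) is computed on all subjects *except* the one under analysis,
and that subject inherits the resulting top-k voxel mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stimuli import CATEGORIES, CATEGORY_TO_SUPERORDINATE, SUPERORDINATE_ORDER
from .synth import BetaArray, Cohort


@dataclass
class ROIMask:
    """A voxel index set within a named grid/ROI voxel space."""

    voxel_indices: np.ndarray
    name: str
    defining_contrast: str = ""
    excluded_subject_id: str | None = None
    n_voxels_total: int | None = None

    def __post_init__(self) -> None:
        idx = np.asarray(self.voxel_indices, dtype=int)
        if idx.size == 0:
            raise ValueError("ROI mask must be non-empty")
        if len(np.unique(idx)) != len(idx):
            raise ValueError("ROI voxel indices must be unique")
        if self.n_voxels_total is not None and (
            idx.min() < 0 or idx.max() >= self.n_voxels_total
        ):
            raise ValueError("ROI voxel indices outside the grid")
        self.voxel_indices = np.sort(idx)

    def __len__(self) -> int:
        return len(self.voxel_indices)


def sound_vs_baseline_contrast(betas: BetaArray) -> np.ndarray:
    """Per-subject all-sounds-vs-baseline contrast map.

    Mean β over every condition and run: (n_subjects, n_voxels).
    """
    vals = betas.values
    if np.isnan(vals).any():
        warnings.warn("missing runs; averaging over available values", RuntimeWarning)
        return np.nanmean(vals, axis=(1, 2))
    return vals.mean(axis=(1, 2))


def define_roi_loso(
    contrast_maps: np.ndarray,
    cohort: Cohort,
    target_subject: str,
    group_a: str,
    group_b: str,
    k_voxels: int = 50,
    threshold: float | None = None,
    name: str = "roi",
) -> ROIMask:
    """LOSO ROI: voxels where group_a > group_b, excluding the target.

    ``contrast_maps`` is (n_subjects, n_voxels) in cohort order. A
    voxelwise Welch t statistic (group_a minus group_b) is computed on
    every subject except ``target_subject``; the ROI is the top-k voxels
    by t, or the supra-threshold set when ``threshold`` is given.
    """
    groups = np.asarray(cohort.subjects["group"])
    sids = np.asarray(cohort.subjects["subject_id"])
    keep = sids != target_subject
    a = contrast_maps[keep & (groups == group_a)]
    b = contrast_maps[keep & (groups == group_b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 subjects per group after LOSO exclusion")
    t, _ = sps.ttest_ind(a, b, axis=0, equal_var=False)
    t = np.nan_to_num(t, nan=-np.inf)
    if threshold is not None:
        idx = np.flatnonzero(t > threshold)
        if idx.size == 0:
            raise ValueError(
                f"no voxel exceeds threshold {threshold}; use k_voxels selection"
            )
    else:
        if k_voxels < 1:
            raise ValueError("k_voxels must be >= 1")
        k = min(k_voxels, t.size)
        # stable top-k: sort by (-t, index) so ties break on lowest index
        order = np.lexsort((np.arange(t.size), -t))
        idx = order[:k]
    return ROIMask(
        voxel_indices=idx,
        name=name,
        defining_contrast=f"{group_a}>{group_b}",
        excluded_subject_id=target_subject,
        n_voxels_total=contrast_maps.shape[1],
    )


def extract_category_betas(
    betas: BetaArray, roi: ROIMask, stimuli: pd.DataFrame
) -> pd.DataFrame:
    """Mean β per superordinate class: subjects × 4 table.

    Averages over the ROI voxels, all runs, and the six stimuli of each
    superordinate class.
    """
    if roi.n_voxels_total is not None and roi.n_voxels_total != betas.n_voxels:
        raise ValueError("ROI grid does not match the β array voxel space")
    if roi.voxel_indices.max() >= betas.n_voxels:
        raise ValueError("ROI indices exceed the β array voxel space")
    sup = (
        stimuli.sort_values("stimulus_id")["category"]
        .map(CATEGORY_TO_SUPERORDINATE)
        .to_numpy()
    )
    vals = betas.values[:, :, :, roi.voxel_indices]  # subj × run × cond × roi-vox
    out = {}
    for s in SUPERORDINATE_ORDER:
        out[s] = vals[:, :, sup == s, :].mean(axis=(1, 2, 3))
    return pd.DataFrame(out, index=betas.subject_ids)


@dataclass
class AnovaResult:
    """Mixed (split-plot) ANOVA table for Group × Category."""

    table: pd.DataFrame  # rows Group/Category/Interaction: SS, df1, df2, F, p
    cell_means: pd.DataFrame
    ss_partition: dict = field(default_factory=dict)
    gg_epsilon: float | None = None

    def F(self, effect: str) -> float:
        return float(self.table.loc[effect, "F"])

    def p(self, effect: str) -> float:
        return float(self.table.loc[effect, "p"])


def _gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the within-measure covariance."""
    k = data.shape[1]
    S = np.cov(data, rowvar=False)
    C = np.eye(k) - np.ones((k, k)) / k
    V = C @ S @ C
    lam = np.linalg.eigvalsh(V)
    lam = np.clip(lam, 0.0, None)
    denom = (k - 1) * (lam**2).sum()
    if denom <= 0:
        return 1.0
    return float(min(1.0, lam.sum() ** 2 / denom))


def mixed_anova(
    data: np.ndarray | pd.DataFrame,
    group_labels: np.ndarray,
    covariates: np.ndarray | None = None,
    gg_correction: bool = True,
    effect_names: tuple[str, str, str] = ("Group", "Category", "Interaction"),
) -> AnovaResult:
    """Mixed ANOVA: one between-subject factor, one within-subject factor.

    ``data`` is subjects × within-levels (each row one subject, balanced
    within factor); ``group_labels`` assigns each subject to a group.
    With ``covariates`` (e.g. age), every within-level column is
    residualised on the centred covariates before the ANOVA. The
    Greenhouse-Geisser correction is applied to within-factor p-values
    when the factor has more than two levels.

    The sums of squares partition additively:
    SS_total = SS_group + SS_subj(group) + SS_within + SS_interaction + SS_error.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be subjects × within-levels")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite inputs")
    groups = np.asarray(group_labels)
    if groups.shape[0] != X.shape[0]:
        raise ValueError("group_labels length mismatch")
    glev = list(dict.fromkeys(groups))
    if len(glev) < 2:
        raise ValueError("need >= 2 groups")
    for g in glev:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")

    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        Z = np.column_stack([np.ones(len(X)), C - C.mean(axis=0)])
        coef, _, _, _ = np.linalg.lstsq(Z, X, rcond=None)
        # residualise on the centred covariates, keeping the intercept part
        X = X - Z[:, 1:] @ coef[1:]

    n_subj, k = X.shape
    N = n_subj * k
    grand = X.mean()
    subj_means = X.mean(axis=1)
    cond_means = X.mean(axis=0)
    g_sizes = np.array([(groups == g).sum() for g in glev])
    g_means = np.array([X[groups == g].mean() for g in glev])
    cell_means = np.vstack([X[groups == g].mean(axis=0) for g in glev])

    ss_total = ((X - grand) ** 2).sum()
    ss_between_subj = k * ((subj_means - grand) ** 2).sum()
    ss_group = k * (g_sizes * (g_means - grand) ** 2).sum()
    ss_subj_within_g = ss_between_subj - ss_group
    ss_cond = n_subj * ((cond_means - grand) ** 2).sum()
    ss_cells = (g_sizes[:, None] * (cell_means - grand) ** 2).sum()
    ss_inter = ss_cells - ss_group - ss_cond
    ss_within_total = ss_total - ss_between_subj
    ss_err_within = ss_within_total - ss_cond - ss_inter

    G = len(glev)
    df_group, df_eb = G - 1, n_subj - G
    df_cond, df_inter = k - 1, (G - 1) * (k - 1)
    df_ew = (n_subj - G) * (k - 1)

    ms_eb = ss_subj_within_g / df_eb
    ms_ew = ss_err_within / df_ew

    def f_and_p(ss, df1, ms_err, df2, eps=1.0):
        if ms_err <= 0:
            return (0.0, 1.0) if ss <= 1e-300 else (np.inf, 0.0)
        F = (ss / df1) / ms_err
        p = float(sps.f.sf(F, df1 * eps, df2 * eps))
        return float(F), p

    eps = _gg_epsilon(X) if (gg_correction and k > 2) else 1.0

    Fg, pg = f_and_p(ss_group, df_group, ms_eb, df_eb)
    Fc, pc = f_and_p(ss_cond, df_cond, ms_ew, df_ew, eps)
    Fi, pi = f_and_p(ss_inter, df_inter, ms_ew, df_ew, eps)

    table = pd.DataFrame(
        {
            "SS": [ss_group, ss_cond, ss_inter],
            "df1": [df_group, df_cond, df_inter],
            "df2": [df_eb, df_ew, df_ew],
            "F": [Fg, Fc, Fi],
            "p": [pg, pc, pi],
        },
        index=list(effect_names),
    )
    partition = {
        "total": float(ss_total),
        "group": float(ss_group),
        "subjects_within_groups": float(ss_subj_within_g),
        "within": float(ss_cond),
        "interaction": float(ss_inter),
        "error_within": float(ss_err_within),
    }
    return AnovaResult(
        table=table,
        cell_means=pd.DataFrame(cell_means, index=glev),
        ss_partition=partition,
        gg_epsilon=eps if k > 2 else None,
    )


def mixed_anova_2x4(
    category_means: pd.DataFrame,
    cohort: Cohort,
    use_age_covariate: bool = False,
    gg_correction: bool = True,
) -> AnovaResult:
    """2(Groups) × 4(Categories) mixed ANOVA on extracted category β-means."""
    df = category_means.loc[cohort.ids()]
    if list(df.columns) != SUPERORDINATE_ORDER:
        df = df[SUPERORDINATE_ORDER]
    cov = np.asarray(cohort.subjects["age"], dtype=float) if use_age_covariate else None
    res = mixed_anova(
        df.to_numpy(),
        np.asarray(cohort.subjects["group"]),
        covariates=cov,
        gg_correction=gg_correction,
    )
    res.cell_means.columns = SUPERORDINATE_ORDER
    return res


__all__ = [
    "ROIMask",
    "AnovaResult",
    "sound_vs_baseline_contrast",
    "define_roi_loso",
    "extract_category_betas",
    "mixed_anova",
    "mixed_anova_2x4",
]
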