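"""Nonparametric group inference for decoding and RSA statistics.

Within-subject label-permutation nulls, the bootstrap aggregation that
turns them into a group-level null distribution (default 100,000
draws), size-preserving group-label permutation for between-group
differences (default 10,000), Benjamini-Hochberg FDR, Cohen's d, and
the adjusted rank transform (ART) test for a 2 × 2 group-by-region
interaction.

Every p-value is floored at 1/n so a permutation p of exactly zero can
never occur.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .univariate import mixed_anova

DEFAULT_N_PERM_SUBJECT = 100
DEFAULT_N_BOOT = 100_000
DEFAULT_N_PERM_GROUP = 10_000


@dataclass
class GroupInference:
    observed: float
    null_values: np.ndarray
    p: float
    effect_size: float | None = None
    n_perm_subject: int | None = None
    n_boot: int | None = None
    n_perm_group: int | None = None
    seed: int | None = None

    def to_record(self) -> dict:
        return {
            "observed": self.observed,
            "p": self.p,
            "effect_size": self.effect_size,
            "null_mean": float(np.mean(self.null_values)),
            "null_sd": float(np.std(self.null_values)),
            "n_null": int(len(self.null_values)),
            "n_perm_subject": self.n_perm_subject,
            "n_boot": self.n_boot,
            "n_perm_group": self.n_perm_group,
            "seed": self.seed,
        }


@dataclass
class ARTResult:
    interaction_F: float
    interaction_p: float
    design: tuple[int, int] = (2, 2)
    ranks: np.ndarray | None = None


def _floored_p(count_ge: int, n: int) -> float:
    return max(count_ge, 1) / n


def permute_labels_within_runs(
    labels_24: np.ndarray, n_runs: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """One independent shuffle of the condition labels per run."""
    return [rng.permutation(np.asarray(labels_24)) for _ in range(n_runs)]


def subject_permutation_null(
    analysis_fn,
    subject_betas: np.ndarray,
    labels_24: np.ndarray,
    n_perm: int = DEFAULT_N_PERM_SUBJECT,
    seed: int = 0,
) -> np.ndarray:
    """Null statistic values for one subject under label shuffling.

    ``analysis_fn(betas, run_labels)`` must return a scalar given the
    (runs, conditions, voxels) β array and a per-run list of condition
    labels. Condition labels are shuffled independently within each run,
    which preserves the run structure the cross-validation relies on.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    B = np.asarray(subject_betas, dtype=float)
    rng = np.random.default_rng(seed)
    out = np.empty(n_perm)
    for i in range(n_perm):
        perm_labels = permute_labels_within_runs(labels_24, B.shape[0], rng)
        try:
            out[i] = float(analysis_fn(B, perm_labels))
        except Exception as e:
            raise RuntimeError(f"analysis_fn failed on permutation {i}") from e
    return out


def decoding_permutation_null(
    subject_betas: np.ndarray,
    labels_24: np.ndarray,
    n_perm: int = DEFAULT_N_PERM_SUBJECT,
    k: int = 40,
    seed: int = 0,
) -> np.ndarray:
    """Label-permutation null of the LORO decoding accuracy for one subject."""
    from .mvpa import EightWayDecoder

    def fn(B, run_labels):
        n_runs, n_cond, n_vox = B.shape
        X = B.reshape(n_runs * n_cond, n_vox)
        y = np.concatenate(run_labels)
        runs = np.repeat(np.arange(n_runs), n_cond)
        accs = []
        for r in range(n_runs):
            tr, te = runs != r, runs == r
            clf = EightWayDecoder(k=k).fit(X[tr], y[tr])
            accs.append(clf.score(X[te], y[te]))
        return float(np.mean(accs))

    return subject_permutation_null(fn, subject_betas, labels_24, n_perm, seed)


def bootstrap_group_null(
    per_subject_nulls: list[np.ndarray] | np.ndarray,
    observed: float | None = None,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> tuple[np.ndarray, float | None]:
    """Group-level null: draw one value per subject (with replacement), average.

    Returns the ``n_boot`` averaged null values and, when ``observed``
    is given, p = proportion of null ≥ observed, floored at 1/n_boot.
    """
    nulls = [np.asarray(v, dtype=float) for v in per_subject_nulls]
    if not nulls or any(len(v) == 0 for v in nulls):
        raise ValueError("every subject needs at least one null value")
    rng = np.random.default_rng(seed)
    draws = np.empty((n_boot, len(nulls)))
    for s, v in enumerate(nulls):
        draws[:, s] = v[rng.integers(0, len(v), size=n_boot)]
    group_null = draws.mean(axis=1)
    p = None
    if observed is not None:
        p = _floored_p(int(np.sum(group_null >= observed)), n_boot)
    return group_null, p


def group_level_inference(
    observed_values: np.ndarray,
    per_subject_nulls: list[np.ndarray],
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> GroupInference:
    """Permutation+bootstrap test of a group-mean statistic against chance."""
    obs = float(np.mean(observed_values))
    null, p = bootstrap_group_null(per_subject_nulls, obs, n_boot=n_boot, seed=seed)
    return GroupInference(
        observed=obs,
        null_values=null,
        p=float(p),
        n_perm_subject=len(per_subject_nulls[0]),
        n_boot=n_boot,
        seed=seed,
    )


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Difference of group means over the pooled standard deviation."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def group_difference_permutation(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_perm: int = DEFAULT_N_PERM_GROUP,
    seed: int = 0,
    alternative: str = "greater",
) -> GroupInference:
    """Size-preserving group-label permutation test on the mean difference.

    One-sided by default ('greater': mean(a) − mean(b) above the null);
    'two-sided' compares absolute differences.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    obs = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    na = len(a)
    for i in range(n_perm):
        perm = rng.permutation(len(pooled))
        null[i] = pooled[perm[:na]].mean() - pooled[perm[na:]].mean()
    if alternative == "two-sided":
        count = int(np.sum(np.abs(null) >= abs(obs)))
    else:
        count = int(np.sum(null >= obs))
    return GroupInference(
        observed=float(obs),
        null_values=null,
        p=_floored_p(count, n_perm),
        effect_size=cohens_d(a, b),
        n_perm_group=n_perm,
        seed=seed,
    )


def fdr_correct(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, adjusted p-values)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def art_interaction(
    region_a: dict[str, np.ndarray], region_b: dict[str, np.ndarray]
) -> ARTResult:
    """Adjusted rank transform test of a 2 group × 2 region interaction.

    ``region_a`` / ``region_b`` map the two group names to per-subject
    values in one region each (region is within-subject: subject order
    must match across regions within a group). Cell-mean estimates of
    both main effects are subtracted, the adjusted scores are ranked
    across the whole dataset (average ranks for ties), and a 2 × 2 mixed
    ANOVA on the ranks provides the interaction F and p; main effects of
    the rank ANOVA are not interpretable and not reported.
    """
    groups = list(region_a)
    if set(groups) != set(region_b) or len(groups) != 2:
        raise ValueError("need the same 2 groups in both regions")
    for g in groups:
        if len(region_a[g]) != len(region_b[g]):
            raise ValueError(f"group {g!r}: every subject needs both region values")
        if len(region_a[g]) < 2:
            raise ValueError("need >= 2 subjects per group")

    # data matrix: subjects × 2 regions, plus group labels
    X = np.vstack(
        [
            np.column_stack([region_a[g], region_b[g]])
            for g in groups
        ]
    ).astype(float)
    labels = np.concatenate([[g] * len(region_a[g]) for g in groups])

    grand = X.mean()
    row_eff = {g: X[labels == g].mean() - grand for g in groups}  # group main effect
    col_eff = X.mean(axis=0) - grand  # region main effect
    adj = X.copy()
    for g in groups:
        adj[labels == g] -= row_eff[g]
    adj -= col_eff[None, :]

    ranks = sps.rankdata(adj.reshape(-1)).reshape(adj.shape)
    res = mixed_anova(
        ranks, labels, gg_correction=False, effect_names=("Group", "Region", "Interaction")
    )
    return ARTResult(
        interaction_F=res.F("Interaction"),
        interaction_p=res.p("Interaction"),
        ranks=ranks,
    )


__all__ = [
    "GroupInference",
    "ARTResult",
    "DEFAULT_N_PERM_SUBJECT",
    "DEFAULT_N_BOOT",
    "DEFAULT_N_PERM_GROUP",
    "subject_permutation_null",
    "decoding_permutation_null",
    "permute_labels_within_runs",
    "bootstrap_group_null",
    "group_level_inference",
    "group_difference_permutation",
    "cohens_d",
    "fdr_correct",
    "art_interaction",
]
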