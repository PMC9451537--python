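"""Reference study conditions used by validation suites and scripts.

Bundles the canonical synthetic-study setups (noise-only chance cohort,
human-geometry two-group cohort) so tests and reproduction scripts run
the exact same conditions.
"""

from __future__ import annotations

import numpy as np

from . import synth
from .stimuli import make_stimulus_table


def noise_only_cohort(
    n_subjects: int = 8, n_voxels: int = 100, n_runs: int = 5, seed: int = 0
):
    """Noise-only β patterns (no category signal): chance-level decoding."""
    stimuli = make_stimulus_table()
    half = n_subjects // 2
    cohort = synth.generate_cohort(
        {"blind": half, "sighted": n_subjects - half}, seed=seed
    )
    cfg = synth.SimulationConfig(
        n_voxels=n_voxels,
        signal_scale=0.0,
        noise_sd=1.0,
        n_runs=n_runs,
        rois=("occipital",),
        seed=seed + 1,
    )
    betas = synth.generate_beta_patterns(cohort, stimuli, cfg)
    return stimuli, cohort, betas["occipital"]


def blind_occipital_cohort(
    n_per_group: int = 16,
    n_voxels: int = 80,
    signal: float = 1.2,
    noise_sd: float = 1.0,
    seed: int = 0,
):
    """Two-group cohort with human-geometry signal everywhere except the
    sighted-like occipital ROI (the study's qualitative group contrast)."""
    stimuli = make_stimulus_table()
    cohort = synth.generate_cohort(
        {"blind": n_per_group, "sighted": n_per_group}, seed=seed
    )
    cfg = synth.SimulationConfig(
        n_voxels=n_voxels,
        signal_scale={
            ("blind", "occipital"): signal,
            ("blind", "temporal"): signal,
            ("sighted", "occipital"): 0.0,
            ("sighted", "temporal"): signal,
        },
        noise_sd=noise_sd,
        target_model="human",
        seed=seed + 1,
    )
    betas = synth.generate_beta_patterns(cohort, stimuli, cfg)
    return stimuli, cohort, betas


__all__ = ["noise_only_cohort", "blind_occipital_cohort"]
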