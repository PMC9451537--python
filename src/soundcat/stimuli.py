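"""Stimulus space: 24 sounds, 8 categories, 4 superordinate classes.

The experimental design uses 24 environmental/vocal sounds organised as 8
categories of 3 exemplars each; pairs of categories roll up into 4
superordinate classes (human, animal, manipulable, big objects/places).
Each sound additionally carries two low-level acoustic descriptors: pitch
(Hz, autocorrelation method) and harmonicity-to-noise ratio (HNR, dB).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Canonical 8-category order used everywhere (condition axis order).
CATEGORIES = [
    "human_vocalization",
    "human_nonvocalization",
    "birds",
    "mammals",
    "tools",
    "graspable_objects",
    "environmental_scenes",
    "big_mechanical",
]

#: Superordinate classes, two categories each, in canonical order.
SUPERORDINATES = {
    "human": ["human_vocalization", "human_nonvocalization"],
    "animal": ["birds", "mammals"],
    "manipulable": ["tools", "graspable_objects"],
    "big_place": ["environmental_scenes", "big_mechanical"],
}

SUPERORDINATE_ORDER = ["human", "animal", "manipulable", "big_place"]

CATEGORY_TO_SUPERORDINATE = {
    cat: sup for sup, cats in SUPERORDINATES.items() for cat in cats
}

N_STIMULI = 24
N_CATEGORIES = 8
N_PER_CATEGORY = 3

# Per-category acoustic profiles (mean pitch Hz, sd; mean HNR dB, sd) used
# by the synthetic generator. Values are plausible for the sound classes
# (birdsong is high-pitched and periodic, machinery low-pitched and noisy).
ACOUSTIC_PROFILES = {
    "human_vocalization": {"pitch": (210.0, 40.0), "hnr": (15.0, 3.0)},
    "human_nonvocalization": {"pitch": (260.0, 60.0), "hnr": (6.0, 2.0)},
    "birds": {"pitch": (2400.0, 500.0), "hnr": (12.0, 3.0)},
    "mammals": {"pitch": (420.0, 120.0), "hnr": (8.0, 2.5)},
    "tools": {"pitch": (820.0, 200.0), "hnr": (3.0, 1.5)},
    "graspable_objects": {"pitch": (600.0, 150.0), "hnr": (4.0, 1.5)},
    "environmental_scenes": {"pitch": (320.0, 90.0), "hnr": (1.5, 1.0)},
    "big_mechanical": {"pitch": (120.0, 30.0), "hnr": (2.0, 1.0)},
}


def make_stimulus_table(seed: int | None = None) -> pd.DataFrame:
    """Build the 24-sound stimulus table.

    Returns a DataFrame with columns ``stimulus_id`` (1-24), ``label``,
    ``category``, ``superordinate``, ``pitch`` (Hz) and ``hnr`` (dB).
    Pitch and HNR are drawn from per-category Gaussian profiles (pitch
    floored at 30 Hz); with ``seed=None`` the profile means are used,
    giving a deterministic table.
    """
    rows = []
    rng = np.random.default_rng(seed) if seed is not None else None
    sid = 1
    for cat in CATEGORIES:
        prof = ACOUSTIC_PROFILES[cat]
        for k in range(N_PER_CATEGORY):
            if rng is None:
                pitch, hnr = prof["pitch"][0], prof["hnr"][0]
            else:
                pitch = max(30.0, rng.normal(*prof["pitch"]))
                hnr = rng.normal(*prof["hnr"])
            rows.append(
                {
                    "stimulus_id": sid,
                    "label": f"{cat}_{k + 1}",
                    "category": cat,
                    "superordinate": CATEGORY_TO_SUPERORDINATE[cat],
                    "pitch": pitch,
                    "hnr": hnr,
                }
            )
            sid += 1
    return pd.DataFrame(rows)


def validate_stimulus_table(stimuli: pd.DataFrame) -> None:
    """Check the structural invariants of a stimulus table."""
    if len(stimuli) != N_STIMULI:
        raise ValueError(f"expected {N_STIMULI} stimuli, got {len(stimuli)}")
    counts = stimuli["category"].value_counts()
    if sorted(counts.index) != sorted(CATEGORIES) or (counts != N_PER_CATEGORY).any():
        raise ValueError("each of the 8 categories must have exactly 3 stimuli")
    for sup, cats in SUPERORDINATES.items():
        got = set(stimuli.loc[stimuli["superordinate"] == sup, "category"])
        if got != set(cats):
            raise ValueError(f"superordinate {sup!r} must map categories {cats}")
    for col in ("pitch", "hnr"):
        vals = np.asarray(stimuli[col], dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite {col} values")
    if (np.asarray(stimuli["pitch"], dtype=float) <= 0).any():
        raise ValueError("pitch must be positive")


def category_labels(stimuli: pd.DataFrame) -> np.ndarray:
    """8-way category label per stimulus, in stimulus_id order."""
    s = stimuli.sort_values("stimulus_id")
    return s["category"].to_numpy()


def superordinate_labels(stimuli: pd.DataFrame) -> np.ndarray:
    """4-way superordinate label per stimulus, in stimulus_id order."""
    s = stimuli.sort_values("stimulus_id")
    return s["superordinate"].to_numpy()
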