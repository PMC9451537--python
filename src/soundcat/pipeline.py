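"""End-to-end orchestration: simulate → glm → rois → decode → rsa → anova.

A single :class:`RunConfig` (loadable from YAML) drives every stage
under one master seed; each stage writes plain-text tables (CSV/JSON)
into the output directory, and a manifest records the configuration,
the stages run and a SHA-256 hash of every output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import glm as glm_mod
from . import mvpa, rsa, stats, synth, univariate
from .stimuli import make_stimulus_table

log = logging.getLogger("soundcat.pipeline")


@dataclass
class RunConfig:
    """Validated configuration of a full synthetic-study run."""

    out_dir: str = "soundcat_run"
    seed: int = 0
    # cohort
    n_per_group: dict = field(default_factory=lambda: {"blind": 8, "sighted": 8})
    # simulation
    n_voxels: int = 100
    n_runs: int = 5
    noise_sd: float = 1.0
    target_model: str = "human"
    signal_scale: dict = field(
        default_factory=lambda: {
            ("blind", "occipital"): 1.0,
            ("blind", "temporal"): 1.0,
            ("sighted", "occipital"): 0.0,
            ("sighted", "temporal"): 1.0,
        }
    )
    rois: tuple = ("occipital", "temporal")
    behavioral_noise_sd: float = 0.1
    # glm round-trip (re-estimate β from simulated time series)
    glm: bool = False
    tr: float = glm_mod.DEFAULT_TR
    timeseries_noise_sd: float = 1.0
    # analyses
    rois_stage: bool = True
    decode: bool = True
    do_rsa: bool = True
    anova: bool = True
    # parameters mirroring the study defaults
    k_features: int = 40
    roi_k_voxels: int = 50
    n_perm_subject: int = 100
    n_boot: int = 100_000
    n_perm_group: int = 10_000
    q_fdr: float = 0.05

    def __post_init__(self) -> None:
        if len(self.n_per_group) != 2:
            raise ValueError("the pipeline compares exactly two groups")
        for g, n in self.n_per_group.items():
            if n < 2:
                raise ValueError(f"group {g!r} needs >= 2 subjects")
        for v in ("n_perm_subject", "n_boot", "n_perm_group", "k_features"):
            if getattr(self, v) < 1:
                raise ValueError(f"{v} must be >= 1")
        if not 0 < self.q_fdr < 1:
            raise ValueError("q_fdr must lie in (0, 1)")
        self.rois = tuple(self.rois)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "signal_scale" in raw and isinstance(raw["signal_scale"], dict):
            raw["signal_scale"] = {
                tuple(k.split("/")): float(v) for k, v in raw["signal_scale"].items()
            }
        return cls(**raw)

    def to_jsonable(self) -> dict:
        d = asdict(self)
        if isinstance(d["signal_scale"], dict):
            d["signal_scale"] = {"/".join(k): v for k, v in d["signal_scale"].items()}
        d["rois"] = list(d["rois"])
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every enabled stage; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = {
        name: int(s.generate_state(1)[0] % 2**31)
        for name, s in zip(
            ["cohort", "stimuli", "betas", "behavioral", "glm", "stats"], ss.spawn(6)
        )
    }
    manifest: dict = {"config": config.to_jsonable(), "seeds": seeds, "stages": []}
    t_all = time.time()

    def stage(name):
        log.info("stage %s", name)
        return {"stage": name, "t_start": time.time()}

    def finish(rec, outputs):
        rec["wall_s"] = round(time.time() - rec.pop("t_start"), 3)
        rec["outputs"] = {str(p.name): _sha256(p) for p in outputs}
        manifest["stages"].append(rec)

    try:
        # ---- simulate -----------------------------------------------------
        rec = stage("simulate")
        stimuli = make_stimulus_table(seed=seeds["stimuli"])
        cohort = synth.generate_cohort(config.n_per_group, seed=seeds["cohort"])
        _, ratings = synth.generate_acoustic_and_behavioral(
            stimuli, cohort, seed=seeds["behavioral"],
            behavioral_noise_sd=config.behavioral_noise_sd,
        )
        sim = synth.SimulationConfig(
            n_voxels=config.n_voxels,
            signal_scale=config.signal_scale,
            noise_sd=config.noise_sd,
            target_model=config.target_model,
            n_runs=config.n_runs,
            rois=config.rois,
            seed=seeds["betas"],
        )
        betas = synth.generate_beta_patterns(cohort, stimuli, sim)
        stim_path = out / "stimuli.csv"
        stimuli.to_csv(stim_path, index=False)
        coh_path = out / "cohort.csv"
        cohort.subjects.to_csv(coh_path, index=False)
        finish(rec, [stim_path, coh_path])

        # ---- glm round-trip ----------------------------------------------
        if config.glm:
            rec = stage("glm")
            rng = np.random.default_rng(seeds["glm"])
            recovered = {}
            designs = []
            for r in range(config.n_runs):
                sch = synth.build_run_schedule(stimuli, seed=seeds["glm"] + r)
                designs.append(glm_mod.make_design_matrix(sch, tr=config.tr, run_id=r))
            for roi in config.rois:
                vals = np.empty_like(betas[roi].values)
                for s in range(len(cohort)):
                    for r in range(config.n_runs):
                        Y = glm_mod.simulate_timeseries(
                            designs[r],
                            betas[roi].values[s, r],
                            config.timeseries_noise_sd,
                            rng,
                        )
                        vals[s, r] = glm_mod.fit_glm(Y, designs[r])
                recovered[roi] = synth.BetaArray(
                    vals, betas[roi].subject_ids, roi, betas[roi].condition_labels
                )
            betas = recovered
            dm_path = out / "design_matrix_run1.csv"
            designs[0].to_frame().to_csv(dm_path, index=False)
            finish(rec, [dm_path])

        # ---- rois ---------------------------------------------------------
        g_a, g_b = list(config.n_per_group)
        loso_rois: dict[str, dict[str, univariate.ROIMask]] = {}
        if config.rois_stage or config.decode:
            rec = stage("rois")
            for roi in config.rois:
                cmaps = univariate.sound_vs_baseline_contrast(betas[roi])
                loso_rois[roi] = {}
                # direction follows where the simulated contrast favours g_a
                direction = (g_a, g_b)
                for sid in cohort.ids():
                    loso_rois[roi][sid] = univariate.define_roi_loso(
                        cmaps, cohort, sid, *direction,
                        k_voxels=config.roi_k_voxels, name=roi,
                    )
            roi_path = out / "loso_rois.json"
            roi_path.write_text(
                json.dumps(
                    {
                        roi: {s: [int(i) for i in m.voxel_indices] for s, m in d.items()}
                        for roi, d in loso_rois.items()
                    },
                )
            )
            finish(rec, [roi_path])

        # ---- decode --------------------------------------------------------
        if config.decode:
            rec = stage("decode")
            labels8 = np.repeat(np.arange(8), 3)
            rows = []
            group_acc: dict[tuple[str, str], list[float]] = {}
            infer_records = {}
            for roi in config.rois:
                per_group_obs: dict[str, list[float]] = {g: [] for g in (g_a, g_b)}
                per_group_nulls: dict[str, list[np.ndarray]] = {g: [] for g in (g_a, g_b)}
                for si, sid in enumerate(cohort.ids()):
                    B = betas[roi].subject(sid)[:, :, loso_rois[roi][sid].voxel_indices]
                    res = mvpa.decode_loro(
                        B, k=min(config.k_features, B.shape[-1]),
                        subject_id=sid, roi=roi,
                    )
                    g = cohort.subjects["group"].iloc[si]
                    per_group_obs[g].append(res.accuracy)
                    null = stats.decoding_permutation_null(
                        B, labels8, n_perm=config.n_perm_subject,
                        k=min(config.k_features, B.shape[-1]),
                        seed=seeds["stats"] + 7919 * si,
                    )
                    per_group_nulls[g].append(null)
                    rows.append(
                        {"subject": sid, "group": g, "roi": roi, "accuracy": res.accuracy}
                    )
                for g in (g_a, g_b):
                    gi = stats.group_level_inference(
                        np.array(per_group_obs[g]), per_group_nulls[g],
                        n_boot=config.n_boot, seed=seeds["stats"],
                    )
                    infer_records[f"{roi}/{g}/vs_chance"] = gi.to_record()
                    group_acc[(roi, g)] = per_group_obs[g]
                diff = stats.group_difference_permutation(
                    np.array(per_group_obs[g_a]), np.array(per_group_obs[g_b]),
                    n_perm=config.n_perm_group, seed=seeds["stats"],
                )
                infer_records[f"{roi}/{g_a}_vs_{g_b}"] = diff.to_record()
            if len(config.rois) >= 2:
                r0, r1 = config.rois[:2]
                art = stats.art_interaction(
                    {g: np.array(group_acc[(r0, g)]) for g in (g_a, g_b)},
                    {g: np.array(group_acc[(r1, g)]) for g in (g_a, g_b)},
                )
                infer_records["art_group_by_region"] = {
                    "F": art.interaction_F, "p": art.interaction_p,
                }
            ps = [v["p"] for v in infer_records.values() if "p" in v]
            _, p_adj = stats.fdr_correct(np.array(ps), q=config.q_fdr)
            for k_, v in zip([k for k, v in infer_records.items() if "p" in v], p_adj):
                infer_records[k_]["p_fdr"] = float(v)
            acc_path = out / "decoding_accuracy.csv"
            pd.DataFrame(rows).to_csv(acc_path, index=False)
            inf_path = out / "decoding_inference.json"
            inf_path.write_text(json.dumps(infer_records, indent=1))
            finish(rec, [acc_path, inf_path])

        # ---- rsa -----------------------------------------------------------
        if config.do_rsa:
            rec = stage("rsa")
            group_of = dict(zip(cohort.subjects["subject_id"], cohort.subjects["group"]))
            subject_dsms = {
                roi: {sid: rsa.subject_dsm(betas[roi].subject(sid)) for sid in cohort.ids()}
                for roi in config.rois
            }
            results: dict = {}
            model_rows = []
            for g in (g_a, g_b):
                g_ratings = {s: r for s, r in ratings.items() if group_of[s] == g}
                models = rsa.build_model_dsms(stimuli, g_ratings)
                for roi in config.rois:
                    dsms = {s: d for s, d in subject_dsms[roi].items() if group_of[s] == g}
                    comp = rsa.compare_models(dsms, models)
                    for name, rho in comp.mean_rho.items():
                        model_rows.append(
                            {"group": g, "roi": roi, "model": name, "mean_rho": rho,
                             "noise_ceiling_lower": comp.noise_ceiling}
                        )
            if len(config.rois) >= 2:
                r0, r1 = config.rois[:2]
                per_group_corr = {g: [] for g in (g_a, g_b)}
                for sid in cohort.ids():
                    rho = rsa.correlate_model(subject_dsms[r0][sid], subject_dsms[r1][sid])
                    per_group_corr[group_of[sid]].append(rho)
                diff = stats.group_difference_permutation(
                    np.array(per_group_corr[g_a]), np.array(per_group_corr[g_b]),
                    n_perm=config.n_perm_group, seed=seeds["stats"],
                )
                results["cross_roi"] = {
                    "mean_rho": {g: float(np.mean(v)) for g, v in per_group_corr.items()},
                    "group_difference": diff.to_record(),
                }
            # partial correlation of the categorical model given acoustics
            models_all = rsa.build_model_dsms(stimuli, ratings)
            target = models_all.get(config.target_model, models_all["human"])
            partials = {}
            for roi in config.rois:
                vals = [
                    rsa.partial_correlate_model(
                        d, target, [models_all["pitch"], models_all["hnr"]]
                    )
                    for d in subject_dsms[roi].values()
                ]
                partials[roi] = float(np.nanmean(vals))
            results["partial_correlation_vs_acoustics"] = partials
            mc_path = out / "rsa_model_comparison.csv"
            pd.DataFrame(model_rows).to_csv(mc_path, index=False)
            rsa_path = out / "rsa_inference.json"
            rsa_path.write_text(json.dumps(results, indent=1))
            finish(rec, [mc_path, rsa_path])

        # ---- anova ----------------------------------------------------------
        if config.anova:
            rec = stage("anova")
            tables = []
            for roi in config.rois:
                # whole-grid ROI for the β extraction
                full = univariate.ROIMask(
                    np.arange(config.n_voxels), name=roi,
                    n_voxels_total=config.n_voxels,
                )
                cmeans = univariate.extract_category_betas(betas[roi], full, stimuli)
                res = univariate.mixed_anova_2x4(cmeans, cohort, use_age_covariate=True)
                t = res.table.reset_index(names="effect")
                t.insert(0, "roi", roi)
                tables.append(t)
            an_path = out / "anova.csv"
            pd.concat(tables).to_csv(an_path, index=False)
            finish(rec, [an_path])

    except Exception as e:
        manifest["error"] = f"{type(e).__name__}: {e}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise

    manifest["wall_s"] = round(time.time() - t_all, 3)
    man_path = out / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=1))
    return manifest


__all__ = ["RunConfig", "run_pipeline"]
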