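"""Shared fixtures.

`small_sim` is a lightweight dataset for structural tests.  `standard_runs`
is the expensive session fixture behind the end-to-end recovery tests: for
each of three seeds it simulates the standard desk-scale trial (300 plots,
h2 = 0.5, mid-season-informative multispectral imagery, noise-dominated
thermal/DEM channels), trains the multi-modal model and the genotype-only
network on the same grouped-stratified split, fine-tunes genotype-only, and
collects test metrics plus attention summaries.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from phegemil.datagen import SimConfig, simulate_dataset, simulate_new_environment
from phegemil.interpret import attention_by_channel, attention_by_date
from phegemil.mil_model import ModelConfig
from phegemil.training_eval import (
    TrainConfig,
    finetune_genotype_only,
    make_splits,
    pearson,
    predictions_for,
    train_model,
)

#: desk-scale study conditions shared by the recovery tests
STANDARD_SIM = dict(
    n_lines=150,
    n_reps=2,
    n_trials=5,
    n_markers=150,
    n_causal=8,
    h2_target=0.5,
    images_per_plot_per_date_mean=1.5,
    thermal_noise_sd=0.6,  # only multispectral carries usable signal
    dem_noise_sd=0.6,
)
STANDARD_SEEDS = (11, 12, 13)


def standard_model_config(cfg: SimConfig) -> ModelConfig:
    return ModelConfig(
        n_markers=cfg.n_markers,
        n_heads=4,
        bag_size=8,
        temporal_encoding=True,
        channel_encoding=True,
        date_vocabulary=cfg.flight_dates,
    )


MULTIMODAL_TRAIN = dict(epochs=12, patience=4, batch_size=8, lr=1e-3)
GENO_ONLY_TRAIN = dict(epochs=40, patience=10, batch_size=8, lr=1e-3, genotype_only=True)


@pytest.fixture(scope="session")
def small_sim():
    """60-plot dataset with small images: cheap structural checks."""
    cfg = SimConfig(
        n_lines=30,
        n_markers=40,
        n_causal=6,
        n_trials=3,
        seed=5,
        image_size=(32, 32),
        images_per_plot_per_date_mean=1.0,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_model(small_sim):
    """Untrained model matching `small_sim` (forward-pass contracts)."""
    mc = ModelConfig(
        n_markers=small_sim.config.n_markers,
        n_heads=2,
        input_downsample=4,
        date_vocabulary=small_sim.config.flight_dates,
        temporal_encoding=True,
        channel_encoding=True,
    )
    from phegemil.mil_model import PheGeMIL

    return PheGeMIL(mc, np.random.default_rng(7))


def _run_one_seed(seed: int) -> dict:
    cfg = SimConfig(seed=seed, **STANDARD_SIM)
    res = simulate_dataset(cfg)
    plan = make_splits(res.samples, repeats=1, seed=seed)
    tr = plan.partition(res.samples, 0, "train")
    va = plan.partition(res.samples, 0, "val")
    te = plan.partition(res.samples, 0, "test")
    obs = np.array([s.yield_t_ha for s in te])
    mc = standard_model_config(cfg)

    mm, mm_hist = train_model(tr, va, mc, TrainConfig(seed=seed, **MULTIMODAL_TRAIN))
    r_mm = pearson(predictions_for(mm, te), obs)

    go, _ = train_model(tr, va, mc, TrainConfig(seed=seed, **GENO_ONLY_TRAIN))
    r_go = pearson(predictions_for(go, te, genotype_only=True), obs)
    r_mm_geno = pearson(predictions_for(mm, te, genotype_only=True), obs)

    by_channel = attention_by_channel(mm, te)
    by_date = attention_by_date(mm, te, channel="multispectral")

    ft, _ = finetune_genotype_only(mm, tr, va, epochs=5, seed=seed)
    r_ft = pearson(predictions_for(ft, te, genotype_only=True), obs)

    out = {
        "seed": seed,
        "config": cfg,
        "split_assignments": plan.assignments,
        "r_multimodal": r_mm,
        "r_genotype_only": r_go,
        "r_mm_genotype_pre_ft": r_mm_geno,
        "r_mm_genotype_ft": r_ft,
        "attention_by_channel": by_channel,
        "attention_by_date": by_date,
        "mm_history": mm_hist,
    }
    if seed == STANDARD_SEEDS[0]:
        # keep artefacts for permutation-invariance / determinism / cross-env
        out["model"] = mm
        out["finetuned"] = ft
        out["test_samples"] = te
        out["train_samples"] = tr
        out["val_samples"] = va
        out["sim_result"] = dataclasses.replace(res, samples=[])  # drop images
        envb = simulate_new_environment(
            res, dataclasses.replace(cfg, n_lines=100, channel_set=())
        )
        pb = predictions_for(ft, envb.samples, genotype_only=True)
        ob = np.array([s.yield_t_ha for s in envb.samples])
        out["crossenv_pred"] = pb
        out["crossenv_obs"] = ob
    return out


@pytest.fixture(scope="session")
def standard_runs():
    return {seed: _run_one_seed(seed) for seed in STANDARD_SEEDS}


@pytest.fixture(scope="session")
def determinism_rerun(standard_runs):
    """Re-train the genotype-only network of the first seed from scratch."""
    seed = STANDARD_SEEDS[0]
    run = standard_runs[seed]
    cfg = run["config"]
    mc = standard_model_config(cfg)
    go, _ = train_model(
        run["train_samples"],
        run["val_samples"],
        mc,
        TrainConfig(seed=seed, **GENO_ONLY_TRAIN),
    )
    obs = np.array([s.yield_t_ha for s in run["test_samples"]])
    return pearson(
        predictions_for(go, run["test_samples"], genotype_only=True), obs
    )
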