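"""Reproducible synthetic recovery benchmarks.

Self-contained experiments on :mod:`mhcbind.simulate` worlds that
exercise the full pipeline at single-CPU scale and return the
quantities a user would quote:

* :func:`run_recovery_benchmark` — 2-allele world, 20,000
  binding-affinity pairs + 5,000 eluted-ligand samples; semi-supervised
  curation, 5-fold classifier training, held-out evaluation against
  noise-free ground truth, and a permuted-label control;
* :func:`run_deconvolution_benchmark` — 3-allele world with
  well-separated motifs; regression pre-training, multi-allele
  deconvolution scored against the hidden true alleles, and the decoy
  contamination rate before/after negative filtering;
* :func:`run_ablation_benchmark` — the three single-module ablations
  (no CBAM, no 1D-CNN-BiLSTM, no BLOSUM encoding) trained and evaluated
  on the recovery benchmark's data.

Model sizes here are deliberately tiny (a few filters, 8 LSTM units)
so every experiment runs in minutes on one CPU; the published training
recipe's learning-rate schedule and fold-ensembling are retained.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .affinity import ic50_to_score
from .curation import CurationConfig, filter_negatives, run_curation
from .network import ModelConfig, PanMHCNet, fusion_dim
from .simulate import make_world, sample_ba, sample_el, sample_eval_pairs
from .train_eval import FoldEnsemble, pr_auc, roc_auc, top_k_ppv


def tiny_model_config(task: str = "classification", seed: int = 0,
                      epochs: int = 4, learning_rate: float = 1e-3,
                      batch_size: int = 256, **overrides) -> ModelConfig:
    """Desk-scale model: 4 2D / 8 1D conv filters, 8 LSTM units."""
    base = dict(
        task=task, n_filters_1d=8, n_filters_2d=4, lstm_hidden=8,
        blosum_dense=24, mlp_hidden=(32,), cbam_reduction=2,
        epochs=epochs, t_max=epochs, batch_size=batch_size,
        learning_rate=learning_rate, seed=seed,
    )
    base.update(overrides)
    return ModelConfig(**base)


def run_recovery_benchmark(seed: int = 0, n_ba: int = 20000,
                           n_el_pos: int = 2500, n_el_neg: int = 2500,
                           n_folds: int = 5, pretrain_epochs: int = 4,
                           classifier_epochs: int = 3,
                           n_eval_pos: int = 1000,
                           n_eval_neg: int = 3000) -> dict:
    """Full pipeline on a 2-allele world; returns data, models, metrics.

    The held-out evaluation pairs carry noise-free ground-truth labels;
    the permuted-label control re-trains a single classifier on shuffled
    labels and must stay at chance.
    """
    world = make_world(n_alleles=2, seed=seed)
    ba = sample_ba(world, n_ba, seed=seed + 1)
    el, truth = sample_el(world, n_el_pos, n_el_neg, multi_allele=False,
                          seed=seed + 2)

    reg_cfg = tiny_model_config("regression", seed=seed,
                                epochs=pretrain_epochs)
    ccfg = CurationConfig(model_config=reg_cfg,
                          pseudo_sequences=world.alleles,
                          rounds=1, n_folds=n_folds, seed=seed)
    table, report, regressor = run_curation(ba, el, el.iloc[0:0], ccfg)

    clf_cfg = tiny_model_config("classification", seed=seed,
                                epochs=classifier_epochs)
    ensemble = FoldEnsemble(config=clf_cfg, pseudo_sequences=world.alleles,
                            n_folds=n_folds, seed=seed)
    ensemble.fit(table[["peptide", "allele"]],
                 table["label"].to_numpy(dtype=float))

    eval_df = sample_eval_pairs(world, n_eval_pos, n_eval_neg, seed=seed + 9)
    scores = ensemble.predict(eval_df[["peptide", "allele"]])
    labels = eval_df["label"].to_numpy()

    rng = np.random.default_rng(seed + 17)
    control_cfg = replace(clf_cfg, epochs=2, t_max=2)
    control = PanMHCNet(control_cfg, world.alleles)
    control.fit(table[["peptide", "allele"]],
                rng.permutation(table["label"].to_numpy(dtype=float)))
    control_scores = control.predict(eval_df[["peptide", "allele"]])

    return {
        "world": world,
        "ba": ba,
        "el": el,
        "truth": truth,
        "table": table,
        "report": report,
        "regressor": regressor,
        "ensemble": ensemble,
        "eval_df": eval_df,
        "scores": scores,
        "labels": labels,
        "roc_auc": roc_auc(labels, scores),
        "pr_auc": pr_auc(labels, scores),
        "top20_ppv": top_k_ppv(labels, scores, k=0.20),
        "control_roc_auc": roc_auc(labels, control_scores),
    }


def run_deconvolution_benchmark(seed: int = 0, n_alleles: int = 3,
                                n_ba: int = 18000, n_ma_pos: int = 1500,
                                n_neg: int = 1500, n_folds: int = 2,
                                epochs: int = 8,
                                learning_rate: float = 1.5e-3) -> dict:
    """Deconvolution and decoy-filtering recovery on a 3-allele world.

    Returns the fraction of multi-allele positives assigned their hidden
    true allele and the contamination rate (true binders among decoy
    negatives) before and after filtering.
    """
    world = make_world(n_alleles=n_alleles, seed=seed + 100,
                       disjoint_motifs=True)
    ba = sample_ba(world, n_ba, seed=seed + 101)
    el_ma, truth = sample_el(world, n_ma_pos, 0, multi_allele=True,
                             seed=seed + 102)
    # negatives come from a single-allele draw so the filter scores each
    # decoy against the same allele its hidden binder status refers to
    el_neg, neg_truth = sample_el(world, 0, n_neg, multi_allele=False,
                                  seed=seed + 103)

    reg_cfg = tiny_model_config("regression", seed=seed, epochs=epochs,
                                learning_rate=learning_rate)
    regressor = FoldEnsemble(config=reg_cfg, pseudo_sequences=world.alleles,
                             n_folds=n_folds, seed=seed)
    regressor.fit(ba[["peptide", "allele"]],
                  ic50_to_score(ba["ic50_nM"].to_numpy()))

    from .curation import deconvolve_multi_allele

    deconv = deconvolve_multi_allele(el_ma, regressor, world.alleles)
    recovery = float(np.mean(
        deconv["assigned_allele"].to_numpy()
        == truth["true_allele"].to_numpy()))

    neg_binder = neg_truth["true_binder"].to_numpy()
    from .affinity import BINDER_SCORE

    # filter_negatives resets the index, so positions align with neg_binder
    kept, removed, _ = filter_negatives(el_neg, regressor,
                                        float(BINDER_SCORE))
    before = float(neg_binder.mean())
    after = float(neg_binder[kept.index.to_numpy()].mean()) if len(kept) else 0.0

    return {
        "world": world,
        "regressor": regressor,
        "deconvolved": deconv,
        "recovery": recovery,
        "contamination_before": before,
        "contamination_after": after,
        "n_negatives_removed": int(len(removed)),
    }


ABLATION_VARIANTS = {
    "no_cbam": {"use_cbam": False},
    "no_1dcnn_bilstm": {"use_1dcnn_bilstm": False},
    "no_blosum": {"use_blosum": False},
}


def run_ablation_benchmark(table: pd.DataFrame, pseudo_sequences: dict,
                           eval_df: pd.DataFrame, seed: int = 0,
                           n_rows: int = 6000, epochs: int = 2) -> dict:
    """Train and evaluate the three module ablations on a subsample of
    the curated table; reports ROC-AUC and fusion dimensionality."""
    rng = np.random.default_rng(seed + 23)
    idx = rng.choice(len(table), size=min(n_rows, len(table)), replace=False)
    sub = table.iloc[idx]
    labels = eval_df["label"].to_numpy()
    pseudo_len = len(next(iter(pseudo_sequences.values())))
    out = {}
    for name, toggles in ABLATION_VARIANTS.items():
        cfg = tiny_model_config("classification", seed=seed, epochs=epochs,
                                **toggles)
        model = PanMHCNet(cfg, pseudo_sequences)
        model.fit(sub[["peptide", "allele"]],
                  sub["label"].to_numpy(dtype=float))
        scores = model.predict(eval_df[["peptide", "allele"]])
        out[name] = {
            "fusion_dim": fusion_dim(cfg, pseudo_len),
            "roc_auc": roc_auc(labels, scores),
            "pr_auc": pr_auc(labels, scores),
        }
    out["full"] = {"fusion_dim": fusion_dim(
        tiny_model_config("classification"), pseudo_len)}
    return out
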