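"""Reference synthetic experiments: planted-signal recovery and imbalance.

These functions wire the generator, sampler, featurizers and classifiers
into the two benchmark designs used throughout the test battery:

* ``planted_signal_experiment`` — marks planted at the observed DSB/non-DSB
  colocalization probabilities (DNase-like 0.91/0.11, H3K4me2-like
  0.74/0.11, CTCF-like 0.25/0.02) on a 2-Mb toy genome with 1 000 DSB and
  1 000 matched control sites; a random forest is trained on occupancy
  features and evaluated on the held-out split.
* ``imbalance_experiment`` — the same generative process at a fixed model,
  evaluated once on a balanced test set and once at a 1:60 class ratio, to
  expose the ROC/PR divergence under class imbalance.
"""

from __future__ import annotations

import numpy as np

from .features import occupancy_features
from .models import (
    LabeledDataset,
    assemble_dataset,
    evaluate_scores,
    train_forest,
)
from .simulate import SimulationConfig, fig2b_marks, simulate_dataset

__all__ = ["planted_signal_experiment", "imbalance_experiment"]


def planted_signal_experiment(
    seed: int,
    n_dsb: int = 1000,
    n_chroms: int = 2,
    chrom_length: int = 1_000_000,
    n_trees: int = 500,
    n_boot: int = 0,
) -> dict:
    """Simulate, featurize, train a forest, evaluate; return the key numbers.

    Returns a dict with ``auroc``, ``aupr``, the CI when ``n_boot`` > 0, the
    variable-importance series, the top-ranked feature name, and the fitted
    results/dataset for further inspection.
    """
    cfg = SimulationConfig(
        seed=seed,
        n_dsb=n_dsb,
        n_chroms=n_chroms,
        chrom_length=chrom_length,
        marks=fig2b_marks(),
    )
    genome, truth = simulate_dataset(cfg)
    pos = occupancy_features(truth.dsb_sites, truth.mark_peaks)
    neg = occupancy_features(truth.control_sites, truth.mark_peaks)
    data = assemble_dataset(pos, neg, test_fraction=0.3, seed=seed)
    results = train_forest(data, seed=seed, n_trees=n_trees)
    ev = results.evaluate(data, n_boot=n_boot, seed=seed)
    return {
        "auroc": ev.auroc,
        "aupr": ev.aupr,
        "auroc_ci": ev.auroc_ci,
        "importance": results.importance,
        "top_feature": str(results.importance.idxmax()),
        "results": results,
        "data": data,
        "truth": truth,
        "genome": genome,
    }


def imbalance_experiment(
    seed: int,
    n_pos: int = 1000,
    imbalance: int = 60,
    n_train_per_class: int = 500,
    n_pos_test: int = 400,
    chrom_length: int = 30_000_000,
    n_trees: int = 500,
    n_boot: int = 0,
) -> dict:
    """One model, two test class ratios: 1:1 versus 1:``imbalance``.

    A forest is trained on a balanced subset; the same positive test sites
    are then evaluated against a same-size control sample (1:1) and against
    ``imbalance`` times as many controls (all drawn from the same matched
    null), so the score quality is fixed and only the class ratio moves.
    """
    n_neg_needed = n_train_per_class + n_pos_test + imbalance * n_pos_test
    ratio = n_neg_needed / n_pos
    cfg = SimulationConfig(
        seed=seed,
        n_dsb=n_pos,
        n_chroms=1,
        chrom_length=chrom_length,
        control_ratio=ratio,
        marks=fig2b_marks(),
    )
    genome, truth = simulate_dataset(cfg)
    pos = occupancy_features(truth.dsb_sites, truth.mark_peaks)
    neg = occupancy_features(truth.control_sites, truth.mark_peaks)

    rng = np.random.default_rng(seed)
    pos_idx = rng.permutation(len(pos))
    neg_idx = rng.permutation(len(neg))
    pos_train = pos.iloc[pos_idx[:n_train_per_class]]
    pos_test = pos.iloc[pos_idx[n_train_per_class : n_train_per_class + n_pos_test]]
    neg_train = neg.iloc[neg_idx[:n_train_per_class]]
    rest = neg_idx[n_train_per_class:]
    neg_test_1 = neg.iloc[rest[:n_pos_test]]
    neg_test_k = neg.iloc[rest[n_pos_test : n_pos_test + imbalance * n_pos_test]]

    import pandas as pd

    features = pd.concat([pos_train, neg_train], ignore_index=True)
    labels = np.r_[np.ones(len(pos_train), int), np.zeros(len(neg_train), int)]
    # train on everything assembled here; the token test pair satisfies the
    # split contract, but evaluation happens on the external test sets below
    train_idx = np.arange(len(labels))
    data = LabeledDataset(features, labels, train_idx, np.array([0, len(labels) - 1]), seed)
    results = train_forest(data, seed=seed, n_trees=n_trees)

    out = {}
    for tag, neg_test in (("balanced", neg_test_1), ("imbalanced", neg_test_k)):
        scores = np.r_[
            results.predict_proba(pos_test), results.predict_proba(neg_test)
        ]
        y = np.r_[np.ones(len(pos_test), int), np.zeros(len(neg_test), int)]
        ev = evaluate_scores(y, scores, n_boot=n_boot, seed=seed)
        out[f"auroc_{tag}"] = ev.auroc
        out[f"aupr_{tag}"] = ev.aupr
    out["class_ratio"] = imbalance
    return out
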