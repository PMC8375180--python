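"""Reusable end-to-end experiment drivers on synthetic data.

These run the whole pipeline — simulate a CNV population, unify it into an
allele-frequency database, build the 30-column feature matrix, fit the
booster on a stratified training split, and score the held-out split —
and return the quantities the package's validation studies report.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.model_selection import train_test_split

from .core import PathogenicityLabel
from .evaluate import roc_auc
from .features import FeatureMatrix, build_feature_matrix
from .model import CVConfig, PathogenicityModel, derive_cutoffs, tune
from .simulate import SimConfig, simulate_dataset


def _subset(fm: FeatureMatrix, idx) -> FeatureMatrix:
    return FeatureMatrix(
        data=fm.data.iloc[idx].reset_index(drop=True),
        mask=fm.mask.iloc[idx].reset_index(drop=True),
    )


def holdout_experiment(
    seed: int,
    n_cnvs: int = 2000,
    effect_size: float = 1.0,
    test_fraction: float = 0.3,
    config: Optional[SimConfig] = None,
) -> dict:
    """Simulate, train on a stratified split, and evaluate the held-out part.

    Returns held-out pathogenic-vs-benign AUC, the five-tier MVP cutoffs
    derived from scores over the full labeled set, whether those cutoffs
    needed monotonicity correction, and the unified/true CNV counts.
    """
    cfg = config or SimConfig(seed=seed, n_true_cnvs=n_cnvs, effect_size=effect_size)
    ds = simulate_dataset(cfg)
    fm = build_feature_matrix(ds.records, ds.bundle, ds.afdb)

    y_binary = np.array([
        1 if lab is PathogenicityLabel.PATHOGENIC
        else 0 if lab is PathogenicityLabel.BENIGN
        else -1
        for lab in ds.labels
    ])
    binary_idx = np.flatnonzero(y_binary >= 0)
    tr, te = train_test_split(
        binary_idx,
        test_size=test_fraction,
        stratify=y_binary[binary_idx],
        random_state=seed % (2**31 - 1),
    )
    model = PathogenicityModel(_subset(fm, tr), y_binary[tr], seed=seed)
    res = model.fit()
    auc = roc_auc(res.predict(_subset(fm, te)), y_binary[te])

    all_scores = res.predict(fm)
    cutoffs = derive_cutoffs(all_scores, ds.labels)
    return {
        "auc": float(auc),
        "cutoffs": cutoffs,
        "cutoffs_corrected": cutoffs.corrected,
        "n_true_cnvs": len(ds.true_cnvs),
        "n_unified": len(ds.afdb.entries),
        "n_train": len(tr),
        "n_test": len(te),
        "results": res,
        "dataset": ds,
        "features": fm,
    }


def tuning_experiment(
    seed: int,
    n_cnvs: int = 2000,
    effect_size: float = 1.0,
    repeats: int = 5,
    folds: int = 5,
):
    """Run the reduced cross-validation hyperparameter search on one dataset."""
    cfg = SimConfig(seed=seed, n_true_cnvs=n_cnvs, effect_size=effect_size)
    ds = simulate_dataset(cfg)
    fm = build_feature_matrix(ds.records, ds.bundle, ds.afdb)
    keep = [
        i for i, lab in enumerate(ds.labels)
        if lab in (PathogenicityLabel.PATHOGENIC, PathogenicityLabel.BENIGN)
    ]
    labels = [ds.labels[i] for i in keep]
    return tune(_subset(fm, keep), labels, CVConfig(repeats=repeats, folds=folds, seed=seed))
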