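"""Gradient-boosted CNV pathogenicity model and MVP scores.

The model is a statsmodels-style pair: :class:`PathogenicityModel` holds the
(imputed) feature matrix and binary pathogenic/benign labels and knows how to
select its booster and learning objective by repeated stratified k-fold
cross-validation (100 repeats of 10 folds at full scale); ``fit()`` returns a
:class:`PathogenicityResults` carrying the trained booster, the training
column minima used for imputation, feature importances and, once derived,
the four MVP category cutoffs.

The MVP (meta-voting prediction) score is the booster's probabilistic output
in [0, 1], higher meaning more pathogenic.  Five-tier category cutoffs are
placed, one per adjacent class boundary, at the score threshold minimizing
|sensitivity - specificity| for the classes-above-vs-below dichotomy.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.model_selection import StratifiedKFold

from .core import LABEL_ORDER, PathogenicityLabel
from .evaluate import roc_auc
from .features import (
    FEATURE_SCHEMA,
    FeatureMatrix,
    column_minima,
    impute_with_minima,
)

LENGTH_GATE_BP = 10_000_000

#: declared search order; ties in median AUC resolve to the earliest entry
BOOSTERS = ("gbtree", "dart", "gblinear")
OBJECTIVES = (
    "binary:logistic",
    "reg:logistic",
    "reg:squarederror",
    "reg:squaredlogerror",
)


def length_gate(cnvs: Sequence, max_bp: int = LENGTH_GATE_BP):
    """Split CNVs into modelable (length <= 10 Mb) and excluded.

    CNVs longer than the gate are overwhelmingly pathogenic and are not
    scored; they are returned with an explanatory flag instead.
    """
    modelable, excluded = [], []
    for r in cnvs:
        if r.length > max_bp:
            excluded.append((r, f"length>{max_bp // 1_000_000}Mb: assumed likely pathogenic, not scored"))
        else:
            modelable.append(r)
    return modelable, excluded


def binary_labels(labels) -> np.ndarray:
    """Coerce labels to a 0/1 array (benign=0, pathogenic=1).

    Accepts ints/bools or five-tier labels; intermediate classes are not
    valid binary training labels and raise.
    """
    out = []
    for v in labels:
        if isinstance(v, (bool, int, np.integer)) and v in (0, 1):
            out.append(int(v))
            continue
        lab = PathogenicityLabel.coerce(v)
        if lab is PathogenicityLabel.PATHOGENIC:
            out.append(1)
        elif lab is PathogenicityLabel.BENIGN:
            out.append(0)
        else:
            raise ValueError(
                f"label {lab.value!r} is not a binary training class "
                "(use pathogenic/benign rows only)"
            )
    return np.asarray(out, dtype=int)


@dataclass
class CVConfig:
    """Cross-validation search space and bookkeeping."""

    boosters: tuple = BOOSTERS
    objectives: tuple = OBJECTIVES
    repeats: int = 100
    folds: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not self.boosters or not self.objectives:
            raise ValueError("boosters and objectives must be nonempty")
        unknown = set(self.boosters) - set(BOOSTERS)
        unknown |= set(self.objectives) - set(OBJECTIVES)
        if unknown:
            raise ValueError(f"unknown booster/objective: {sorted(unknown)}")


@dataclass
class TuningResult:
    """Per-combination CV summary and the selected hyperparameters."""

    table: pd.DataFrame           # booster, objective, median_auc, mean_auc, ...
    booster: str
    objective: str
    repeat_aucs: dict             # (booster, objective) -> list of per-repeat mean AUCs
    fold_aucs: dict               # (booster, objective) -> list of per-fold AUCs

    def summary(self) -> str:
        lines = ["CV hyperparameter search (median AUC per combination)", ""]
        lines.append(self.table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
        lines.append("")
        lines.append(f"selected: booster={self.booster}, objective={self.objective}")
        return "\n".join(lines)


def _xgb_params(booster: str, objective: str, seed: int) -> dict:
    params = {
        "booster": booster,
        "objective": objective,
        "seed": int(seed) % (2**31 - 1),
        "nthread": 1,
        "verbosity": 0,
    }
    if booster in ("gbtree", "dart"):
        params.update({"max_depth": 6, "eta": 0.3})
    return params


def _train_booster(X, y, booster, objective, seed, num_boost_round):
    dtrain = xgb.DMatrix(np.asarray(X, dtype=float), label=np.asarray(y, dtype=float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return xgb.train(
            _xgb_params(booster, objective, seed), dtrain,
            num_boost_round=num_boost_round,
        )


def _predict_raw(bst, X) -> np.ndarray:
    return bst.predict(xgb.DMatrix(np.asarray(X, dtype=float)))


def tune(features, labels, config: CVConfig, num_boost_round: int = 50) -> TuningResult:
    """Select booster and objective by repeated stratified k-fold CV.

    For every booster x objective combination, each repeat runs a freshly
    shuffled stratified k-fold split, AUC is computed per held-out fold and
    averaged into a per-repeat value; the combination with the highest
    median per-repeat AUC wins, ties resolving to the declared search order.
    Combinations whose training fails numerically record NaN and never win.
    """
    X = features.data.to_numpy() if isinstance(features, FeatureMatrix) else np.asarray(features, dtype=float)
    y = binary_labels(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("tuning requires both pathogenic and benign labels")

    rng = np.random.default_rng(config.seed)
    repeat_seeds = rng.integers(0, 2**31 - 1, size=config.repeats)
    combos = [(b, o) for b in config.boosters for o in config.objectives]
    repeat_aucs = {c: [] for c in combos}
    fold_aucs = {c: [] for c in combos}

    for rep_seed in repeat_seeds:
        skf = StratifiedKFold(
            n_splits=config.folds, shuffle=True, random_state=int(rep_seed) % (2**31 - 1)
        )
        splits = list(skf.split(X, y))
        for combo in combos:
            booster, objective = combo
            per_fold = []
            for tr, te in splits:
                try:
                    bst = _train_booster(
                        X[tr], y[tr], booster, objective, rep_seed, num_boost_round
                    )
                    pred = _predict_raw(bst, X[te])
                    if not np.all(np.isfinite(pred)):
                        raise FloatingPointError("non-finite predictions")
                    per_fold.append(roc_auc(pred, y[te]))
                except Exception:
                    per_fold.append(float("nan"))
            fold_aucs[combo].extend(per_fold)
            repeat_aucs[combo].append(float(np.mean(per_fold)))

    rows = []
    for combo in combos:
        vals = np.asarray(repeat_aucs[combo])
        ok = np.isfinite(vals)
        rows.append({
            "booster": combo[0],
            "objective": combo[1],
            "median_auc": float(np.median(vals)) if ok.all() else float("nan"),
            "mean_auc": float(np.mean(vals)) if ok.all() else float("nan"),
            "sd_auc": float(np.std(vals, ddof=1)) if ok.all() and len(vals) > 1 else float("nan"),
            "failed": int((~ok).sum()),
        })
    table = pd.DataFrame(rows)
    medians = table["median_auc"].to_numpy()
    if np.all(np.isnan(medians)):
        raise RuntimeError("every booster/objective combination failed during CV")
    best_idx = int(np.nanargmax(medians))  # argmax keeps first (declared-order) tie
    return TuningResult(
        table=table,
        booster=table.loc[best_idx, "booster"],
        objective=table.loc[best_idx, "objective"],
        repeat_aucs=repeat_aucs,
        fold_aucs=fold_aucs,
    )


# ---------------------------------------------------------------- cutoffs

@dataclass
class MVPCutoffs:
    """Four ordered thresholds splitting [0,1] into the five categories."""

    c_benign: float
    c_likely_benign: float
    c_uncertain: float
    c_pathogenic: float
    corrected: bool = False  # True when isotonic correction reordered raw cutoffs

    def as_tuple(self):
        return (self.c_benign, self.c_likely_benign, self.c_uncertain, self.c_pathogenic)

    def __post_init__(self):
        a, b, c, d = self.as_tuple()
        if not (0.0 <= a <= b <= c <= d <= 1.0):
            raise ValueError(f"cutoffs must be monotone within [0,1]: {self.as_tuple()}")


#: published cutoffs: benign < 0.14, likely benign 0.14-0.16, uncertain
#: 0.16-0.46, likely pathogenic 0.46-0.76, pathogenic > 0.76
PUBLISHED_CUTOFFS = MVPCutoffs(0.14, 0.16, 0.46, 0.76)


def _best_threshold(scores: np.ndarray, positive: np.ndarray) -> float:
    """Threshold (predict positive when score >= t) minimizing |sens - spec|.

    Candidates are the observed score values; ties take the smaller
    threshold (more sensitive boundary calls).
    """
    thresholds = np.unique(scores)
    n_pos = positive.sum()
    n_neg = len(positive) - n_pos
    best_t, best_gap = None, None
    for t in thresholds:
        pred = scores >= t
        sens = (pred & positive).sum() / n_pos
        spec = (~pred & ~positive).sum() / n_neg
        gap = abs(sens - spec)
        if best_gap is None or gap < best_gap:
            best_t, best_gap = float(t), gap
    return best_t


def derive_cutoffs(scores, labels5) -> MVPCutoffs:
    """Derive the four five-tier category cutoffs from scored CNVs.

    For each adjacent class boundary, classes above the boundary are the
    positives and the cutoff is the score threshold minimizing
    |sensitivity - specificity|.  The four cutoffs are derived
    independently; if they come out non-monotone they are corrected by a
    running maximum and a warning is emitted.
    """
    scores = np.asarray(scores, dtype=float)
    labels = [PathogenicityLabel.coerce(v) for v in labels5]
    present = set(labels)
    missing = [lab.value for lab in LABEL_ORDER if lab not in present]
    if missing:
        raise ValueError(f"cannot derive cutoffs; missing class(es): {', '.join(missing)}")
    order_index = {lab: i for i, lab in enumerate(LABEL_ORDER)}
    ranks = np.asarray([order_index[lab] for lab in labels])

    raw = []
    for boundary in range(4):  # positives are classes with rank > boundary
        raw.append(_best_threshold(scores, ranks > boundary))
    raw = np.asarray(raw)
    monotone = np.maximum.accumulate(raw)
    corrected = not np.array_equal(raw, monotone)
    if corrected:
        warnings.warn(
            "independently derived MVP cutoffs were non-monotone; "
            f"applied running-maximum correction ({raw.tolist()} -> {monotone.tolist()})",
            RuntimeWarning,
        )
    return MVPCutoffs(*map(float, monotone), corrected=corrected)


def categorize(score: float, cutoffs: MVPCutoffs = PUBLISHED_CUTOFFS) -> PathogenicityLabel:
    """Map an MVP score in [0,1] to the five-tier category.

    benign: s < c_benign; likely benign: c_benign <= s < c_likely_benign;
    uncertain: c_likely_benign <= s < c_uncertain; likely pathogenic:
    c_uncertain <= s <= c_pathogenic; pathogenic: s > c_pathogenic.
    """
    s = float(score)
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"MVP score outside [0,1]: {s}")
    a, b, c, d = cutoffs.as_tuple()
    if s < a:
        return PathogenicityLabel.BENIGN
    if s < b:
        return PathogenicityLabel.LIKELY_BENIGN
    if s < c:
        return PathogenicityLabel.UNCERTAIN
    if s <= d:
        return PathogenicityLabel.LIKELY_PATHOGENIC
    return PathogenicityLabel.PATHOGENIC


def categorize_scores(scores, cutoffs: MVPCutoffs = PUBLISHED_CUTOFFS) -> list:
    return [categorize(s, cutoffs) for s in np.asarray(scores, dtype=float)]


# ---------------------------------------------------------------- model/results

class PathogenicityModel:
    """Gradient-boosted pathogenic-vs-benign CNV classifier.

    Parameters
    ----------
    features : FeatureMatrix or DataFrame
        Training features (the 30-column schema).  A FeatureMatrix with
        missing cells is imputed with its own column minima; the minima are
        stored for prediction-time imputation.
    labels : sequence
        Binary 0/1 or pathogenic/benign labels, one per row.
    booster, objective : str
        Hyperparameters; either set directly or via ``select_hyperparameters``.
    num_boost_round : int
        Boosting rounds for the final fit (early stopping is not used).
    seed : int
        Seed for the booster; full refits with the same seed and data are
        reproducible.
    """

    def __init__(
        self,
        features,
        labels,
        booster: str = "gbtree",
        objective: str = "binary:logistic",
        num_boost_round: int = 50,
        seed: int = 0,
    ):
        if isinstance(features, FeatureMatrix):
            self.schema = list(features.data.columns)
            self.training_minima = column_minima(features)
            fm = features if features.imputed else impute_with_minima(features, self.training_minima)
            self.X = fm.data.to_numpy(dtype=float)
        elif isinstance(features, pd.DataFrame):
            if list(features.columns) != FEATURE_SCHEMA:
                raise ValueError(
                    f"expected the {len(FEATURE_SCHEMA)}-column feature schema, "
                    f"got {len(features.columns)} columns"
                )
            self.schema = list(features.columns)
            self.training_minima = features.min(axis=0, skipna=True)
            self.X = features.fillna(self.training_minima).to_numpy(dtype=float)
        else:
            raise TypeError("features must be a FeatureMatrix or DataFrame")
        if not np.isfinite(self.X).all():
            raise ValueError("features contain non-finite values after imputation")
        self.y = binary_labels(labels)
        if len(self.y) != len(self.X):
            raise ValueError("features and labels length mismatch")
        self.booster = booster
        self.objective = objective
        self.num_boost_round = num_boost_round
        self.seed = seed
        self.tuning_: Optional[TuningResult] = None

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label", **kwargs):
        """Build from a single DataFrame holding features plus a label column."""
        labels = df[label_col]
        feats = df[[c for c in FEATURE_SCHEMA]]
        return cls(feats, labels, **kwargs)

    def select_hyperparameters(self, config: Optional[CVConfig] = None) -> TuningResult:
        """Run the CV search and adopt the winning booster/objective."""
        cfg = config or CVConfig(seed=self.seed)
        result = tune(
            pd.DataFrame(self.X, columns=self.schema), self.y, cfg,
            num_boost_round=self.num_boost_round,
        )
        self.booster = result.booster
        self.objective = result.objective
        self.tuning_ = result
        return result

    def fit(self) -> "PathogenicityResults":
        """Train on the full training set with the current hyperparameters."""
        bst = _train_booster(
            self.X, self.y, self.booster, self.objective, self.seed,
            self.num_boost_round,
        )
        return PathogenicityResults(self, bst)


class PathogenicityResults:
    """Fitted model: MVP scoring, cutoff derivation, categorization, summary."""

    def __init__(self, model: PathogenicityModel, booster_obj: xgb.Booster):
        self.model = model
        self.booster_ = booster_obj
        self.cutoffs: Optional[MVPCutoffs] = None

    # -- feature importances ------------------------------------------------
    @property
    def feature_importances(self) -> pd.Series:
        """Gain-based importances normalized to sum to 1 (weight-based for
        the linear booster, which has no per-split gain)."""
        try:
            raw = self.booster_.get_score(importance_type="gain")
        except Exception:
            raw = {}
        if not raw:
            try:
                raw = self.booster_.get_score(importance_type="weight")
            except Exception:
                raw = {}
        imp = pd.Series(0.0, index=self.model.schema)
        for key, val in raw.items():
            # xgboost names features f0, f1, ... when trained from arrays
            idx = int(key[1:]) if key.startswith("f") and key[1:].isdigit() else None
            name = self.model.schema[idx] if idx is not None else key
            imp[name] = abs(float(val))
        total = imp.sum()
        return imp / total if total > 0 else imp

    # -- prediction ---------------------------------------------------------
    def _prepare(self, features) -> np.ndarray:
        if isinstance(features, FeatureMatrix):
            fm = features if features.imputed else impute_with_minima(
                features, self.model.training_minima
            )
            if list(fm.data.columns) != self.model.schema:
                raise ValueError("feature schema mismatch")
            return fm.data.to_numpy(dtype=float)
        if isinstance(features, pd.DataFrame):
            if list(features.columns) != self.model.schema:
                raise ValueError("feature schema mismatch")
            return features.fillna(self.model.training_minima).to_numpy(dtype=float)
        arr = np.asarray(features, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != len(self.model.schema):
            raise ValueError("feature schema mismatch")
        return arr

    def predict(self, features) -> np.ndarray:
        """MVP scores in [0,1], one per row.

        Regression objectives can produce raw values outside [0,1]; those
        are clamped with a warning (the selected model normally uses a
        logistic objective, whose outputs are already probabilities).
        """
        raw = _predict_raw(self.booster_, self._prepare(features))
        if raw.size and (raw.min() < 0.0 or raw.max() > 1.0):
            warnings.warn(
                f"objective {self.model.objective!r} produced scores outside "
                "[0,1]; clamping for MVP",
                RuntimeWarning,
            )
            raw = np.clip(raw, 0.0, 1.0)
        return raw.astype(float)

    def derive_cutoffs(self, scores, labels5) -> MVPCutoffs:
        """Derive and store five-tier cutoffs from externally scored CNVs."""
        self.cutoffs = derive_cutoffs(scores, labels5)
        return self.cutoffs

    def categorize(self, scores) -> list:
        cutoffs = self.cutoffs or PUBLISHED_CUTOFFS
        return categorize_scores(np.atleast_1d(scores), cutoffs)

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "CNV pathogenicity model (gradient boosting)",
            "=" * 46,
            f"booster:    {self.model.booster}",
            f"objective:  {self.model.objective}",
            f"rounds:     {self.model.num_boost_round}",
            f"n_train:    {len(self.model.y)} "
            f"({int(self.model.y.sum())} pathogenic / {int((1 - self.model.y).sum())} benign)",
            f"n_features: {len(self.model.schema)}",
        ]
        if self.model.tuning_ is not None:
            t = self.model.tuning_.table
            sel = t[(t.booster == self.model.booster) & (t.objective == self.model.objective)]
            med = float(sel["median_auc"].iloc[0])
            sd = float(sel["sd_auc"].iloc[0])
            lines.append(f"CV AUC:     {med:.4f} +/- {sd:.4f} (median +/- sd across repeats)")
        if self.cutoffs is not None:
            a, b, c, d = self.cutoffs.as_tuple()
            lines.append(f"MVP cutoffs: {a:.4f} / {b:.4f} / {c:.4f} / {d:.4f}")
        top = self.feature_importances.sort_values(ascending=False).head(10)
        lines.append("")
        lines.append("top features (normalized gain importance):")
        for name, val in top.items():
            lines.append(f"  {name:<16s} {val:.4f}")
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        """Save a model bundle (directory with booster JSON + metadata)."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.booster_.save_model(str(path / "booster.json"))
        meta = {
            "version": 1,
            "booster": self.model.booster,
            "objective": self.model.objective,
            "num_boost_round": self.model.num_boost_round,
            "seed": self.model.seed,
            "schema": self.model.schema,
            "training_minima": {k: float(v) for k, v in self.model.training_minima.items()},
            "cutoffs": list(self.cutoffs.as_tuple()) if self.cutoffs else None,
        }
        (path / "meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "PathogenicityResults":
        path = Path(path)
        meta = json.loads((path / "meta.json").read_text())
        bst = xgb.Booster()
        bst.load_model(str(path / "booster.json"))
        model = PathogenicityModel.__new__(PathogenicityModel)
        model.schema = meta["schema"]
        model.training_minima = pd.Series(meta["training_minima"])
        model.booster = meta["booster"]
        model.objective = meta["objective"]
        model.num_boost_round = meta["num_boost_round"]
        model.seed = meta["seed"]
        model.X = np.empty((0, len(model.schema)))
        model.y = np.empty(0, dtype=int)
        model.tuning_ = None
        res = cls(model, bst)
        if meta.get("cutoffs"):
            res.cutoffs = MVPCutoffs(*meta["cutoffs"])
        return res
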