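"""Labeling, subject-wise scaling, feature selection, hyperparameter search,
leave-one-subject-out evaluation and additive feature attribution.

Four binary targets are supported. Pain state is read from the stimulation
window of each trial, labeled either by that trial's pain VAS (``pain_vas``)
or by the objective stimulation level (``stim_level``). Anticipation anxiety
is read from the pre-stimulus window, labeled by the *previous* trial's pain
VAS (``prev_pain_vas``) or stimulation level (``prev_stim_level``) within
the same test block — the most recent painful stimulus shapes anticipation
of the next one, making prior pain a usable anxiety proxy when self-report
is unreliable.

Class imbalance is handled through the optimization metric only: balanced
accuracy, BAC = (sensitivity + specificity) / 2, drives both the greedy
backward feature elimination and the successive-halving hyperparameter
search, each evaluated with subject-grouped inner folds so no subject leaks
across an inner split.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import GroupKFold, LeaveOneGroupOut
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from nocisense.features import METADATA_COLUMNS, feature_columns

logger = logging.getLogger(__name__)

__all__ = [
    "LabelSpec",
    "CVResult",
    "TrainedModel",
    "MODEL_FAMILIES",
    "DEFAULT_GRIDS",
    "make_labels",
    "subject_scale",
    "rfe_select",
    "halving_search",
    "loso_cv",
    "compute_metrics",
    "train_final",
    "attribute_features",
]

MODEL_FAMILIES = ("xgb", "svm", "rfc", "lr", "knn")

TARGETS = ("pain_vas", "stim_level", "prev_pain_vas", "prev_stim_level")


@dataclass(frozen=True)
class LabelSpec:
    """Binary labeling rule for one classification target.

    ``positive_threshold`` marks the "medium or higher" boundary (score or
    level at/above it is positive); ``negative_threshold`` the "none"
    boundary (score or level at/below it is negative); rows in between
    follow ``middle_policy`` (``"exclude"`` or ``"negative"``).

    Defaults operationalize "medium or higher" as VAS >= 5 and "no pain or
    anxiety" as VAS = 0; for stimulation levels, sham (level 0) is negative
    and levels >= 2 positive with level 1 excluded.
    """

    target: str
    positive_threshold: float = 5.0
    negative_threshold: float = 0.0
    middle_policy: str = "exclude"

    def __post_init__(self) -> None:
        if self.target not in TARGETS:
            raise ValueError(f"unknown target {self.target!r}; expected {TARGETS}")
        if self.positive_threshold <= self.negative_threshold:
            raise ValueError("positive and negative rules must be disjoint")
        if self.middle_policy not in ("exclude", "negative"):
            raise ValueError("middle_policy must be 'exclude' or 'negative'")

    @classmethod
    def for_target(cls, target: str, **kw) -> "LabelSpec":
        if target in ("stim_level", "prev_stim_level"):
            kw.setdefault("positive_threshold", 2.0)
            kw.setdefault("negative_threshold", 0.0)
        return cls(target=target, **kw)


@dataclass
class FoldResult:
    subject: str
    y_true: np.ndarray
    y_score: np.ndarray
    y_pred: np.ndarray
    selected_features: list[str]
    hyperparameters: dict[str, Any]
    skipped: bool = False
    skip_reason: str = ""


@dataclass
class CVResult:
    folds: list[FoldResult]
    sensitivity: float
    specificity: float
    bac: float
    auc: float
    roc: tuple[np.ndarray, np.ndarray]  # (fpr, tpr)

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "bac": self.bac,
            "auc": self.auc,
            "folds": [
                {
                    "subject": f.subject,
                    "y_true": f.y_true.tolist(),
                    "y_score": [round(s, 12) for s in f.y_score],
                    "y_pred": f.y_pred.tolist(),
                    "selected_features": f.selected_features,
                    "hyperparameters": {k: (v if not isinstance(v, np.generic) else v.item())
                                        for k, v in f.hyperparameters.items()},
                    "skipped": f.skipped,
                }
                for f in self.folds
            ],
        }


@dataclass
class TrainedModel:
    family: str
    estimator: Any
    calibrator: LogisticRegression
    selected_features: list[str]
    imputation_medians: pd.Series
    scaling_mode: str
    hyperparameters: dict[str, Any]

    def _matrix(self, table: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.selected_features if f not in table.columns]
        if missing:
            raise ValueError(f"features absent from table: {missing}")
        X = table[self.selected_features].copy()
        return X.fillna(self.imputation_medians[self.selected_features]).to_numpy(float)

    def decision_scores(self, table: pd.DataFrame) -> np.ndarray:
        return _raw_scores(self.estimator, self._matrix(table))

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        raw = self.decision_scores(table)
        return self.calibrator.predict_proba(raw.reshape(-1, 1))[:, 1]


# ---------------------------------------------------------------------------
# labeling

def _apply_rule(values: pd.Series, spec: LabelSpec) -> pd.Series:
    label = pd.Series(np.nan, index=values.index)
    label[values >= spec.positive_threshold] = 1.0
    label[values <= spec.negative_threshold] = 0.0
    if spec.middle_policy == "negative":
        label = label.fillna(0.0)
    return label


def make_labels(table: pd.DataFrame, spec: LabelSpec) -> pd.DataFrame:
    """Attach a binary ``label`` column and drop unlabeled rows.

    Pain targets keep stimulation-phase rows labeled by that trial's own
    pain VAS or level. Anxiety targets keep anticipation-phase rows labeled
    by the previous trial (same subject and modality block, by trial
    order); the first trial of each block has no previous and is dropped.
    """
    for col in METADATA_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"metadata column {col!r} missing")
    df = table.copy()
    if spec.target == "pain_vas":
        df = df[df["phase"] == "stimulation"].copy()
        df["label"] = _apply_rule(df["pain_vas"].astype(float), spec)
    elif spec.target == "stim_level":
        df = df[df["phase"] == "stimulation"].copy()
        df["label"] = _apply_rule(df["level"].astype(float), spec)
    elif spec.target in ("prev_pain_vas", "prev_stim_level"):
        df = df[df["phase"] == "anticipation"].copy()
        source = "pain_vas" if spec.target == "prev_pain_vas" else "level"
        prev = (df.sort_values("trial_index")
                  .groupby(["subject_id", "modality"])[source].shift(1))
        df["prev_value"] = prev
        df = df[df["prev_value"].notna()].copy()
        df["label"] = _apply_rule(df["prev_value"].astype(float), spec)
        df = df.drop(columns=["prev_value"])
    else:  # pragma: no cover - guarded by LabelSpec
        raise ValueError(f"unknown target {spec.target!r}")
    df = df[df["label"].notna()].copy()
    df["label"] = df["label"].astype(int)
    return df.reset_index(drop=True)


def subject_scale(table: pd.DataFrame, mode: str = "per_subject") -> pd.DataFrame:
    """Subject-wise standard scaling of every feature column.

    Per subject and feature: ``(x - subject mean) / subject s.d.``; a
    feature constant within a subject scales to 0. Subjects contributing a
    single row cannot be scaled and raise.
    """
    if mode != "per_subject":
        raise ValueError("only per_subject scaling is defined here")
    counts = table["subject_id"].value_counts()
    singles = counts[counts < 2]
    if len(singles):
        raise ValueError(f"cannot scale subjects with one row: {list(singles.index)}")
    feats = feature_columns(table.drop(columns=["label"], errors="ignore"))
    df = table.copy()

    def _scale(group: pd.DataFrame) -> pd.DataFrame:
        mu = group.mean()
        sd = group.std(ddof=0)
        out = (group - mu) / sd.replace(0.0, np.nan)
        constant = sd.index[sd == 0.0]
        out[constant] = 0.0  # subject-constant feature carries no signal
        return out

    df[feats] = (df.groupby("subject_id", group_keys=False)[feats]
                   .apply(_scale))
    return df


# ---------------------------------------------------------------------------
# models

def make_estimator(family: str, seed: int = 0, **params) -> Any:
    if family == "lr":
        return LogisticRegression(max_iter=2000, random_state=seed, **params)
    if family == "svm":
        params.setdefault("kernel", "linear")
        return SVC(random_state=seed, **params)
    if family == "rfc":
        params.setdefault("n_estimators", 100)
        return RandomForestClassifier(random_state=seed, **params)
    if family == "knn":
        params.setdefault("n_neighbors", 5)
        return KNeighborsClassifier(**params)
    if family == "xgb":
        from xgboost import XGBClassifier
        params.setdefault("n_estimators", 50)
        params.setdefault("max_depth", 3)
        return XGBClassifier(random_state=seed, eval_metric="logloss",
                             verbosity=0, **params)
    raise ValueError(f"unknown model family {family!r}; expected {MODEL_FAMILIES}")


DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "lr": {"C": [0.01, 0.1, 1.0, 10.0]},
    "svm": {"C": [0.01, 0.1, 1.0, 10.0]},
    "rfc": {"n_estimators": [50, 100], "max_depth": [3, 5, None],
            "min_samples_leaf": [1, 3]},
    "knn": {"n_neighbors": [3, 5, 7, 11], "weights": ["uniform", "distance"]},
    "xgb": {"n_estimators": [50, 100], "max_depth": [2, 3, 4],
            "learning_rate": [0.1, 0.3]},
}


def _raw_scores(estimator: Any, X: np.ndarray) -> np.ndarray:
    if hasattr(estimator, "predict_proba"):
        return estimator.predict_proba(X)[:, 1]
    return estimator.decision_function(X)


def _feature_importance(estimator: Any, X: np.ndarray, y: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    if hasattr(estimator, "coef_"):
        return np.abs(np.ravel(estimator.coef_))
    if hasattr(estimator, "feature_importances_"):
        return np.asarray(estimator.feature_importances_)
    # model families without intrinsic importances (KNN): permutation loss
    base = np.mean(estimator.predict(X) == y)
    imp = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        Xp = X.copy()
        Xp[:, j] = rng.permutation(Xp[:, j])
        imp[j] = base - np.mean(estimator.predict(Xp) == y)
    return imp


def _inner_bac(family: str, X: np.ndarray, y: np.ndarray, groups: np.ndarray,
               seed: int, params: dict | None = None, n_splits: int = 3) -> float:
    """Grouped inner-CV balanced accuracy (pooled over inner folds)."""
    uniq = np.unique(groups)
    k = min(n_splits, len(uniq))
    if k < 2:
        raise ValueError("need at least 2 subject groups for inner CV")
    y_true_all, y_pred_all = [], []
    for tr, te in GroupKFold(n_splits=k).split(X, y, groups):
        if len(np.unique(y[tr])) < 2:
            continue
        est = make_estimator(family, seed=seed, **(params or {}))
        est.fit(X[tr], y[tr])
        y_true_all.append(y[te])
        y_pred_all.append(est.predict(X[te]))
    if not y_true_all:
        raise ValueError("degenerate single-class training data in every inner fold")
    yt = np.concatenate(y_true_all)
    yp = np.concatenate(y_pred_all)
    pos, neg = yt == 1, yt == 0
    sens = np.mean(yp[pos] == 1) if pos.any() else np.nan
    spec = np.mean(yp[neg] == 0) if neg.any() else np.nan
    return float(np.nanmean([sens, spec]))


def rfe_select(family: str, X: np.ndarray, y: np.ndarray, groups: np.ndarray,
               feature_names: Sequence[str], seed: int = 0,
               params: dict | None = None) -> list[str]:
    """Greedy backward feature elimination scored by inner grouped-CV BAC.

    At each step the lowest-importance feature (from a fit on the full
    training data) is dropped; the drop is kept only if the inner BAC does
    not decrease. The returned subset is the one with maximal inner BAC
    seen, with ties broken toward fewer features.
    """
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate single-class training data")
    rng = np.random.default_rng(seed)
    current = list(range(X.shape[1]))
    best_subset = list(current)
    best_bac = _inner_bac(family, X[:, current], y, groups, seed, params)
    current_bac = best_bac
    while len(current) > 1:
        est = make_estimator(family, seed=seed, **(params or {}))
        est.fit(X[:, current], y)
        imp = _feature_importance(est, X[:, current], y, rng)
        drop = current[int(np.argmin(imp))]
        candidate = [c for c in current if c != drop]
        cand_bac = _inner_bac(family, X[:, candidate], y, groups, seed, params)
        if cand_bac < current_bac:
            break
        current, current_bac = candidate, cand_bac
        if cand_bac > best_bac or (cand_bac == best_bac and len(candidate) < len(best_subset)):
            best_bac, best_subset = cand_bac, list(candidate)
    return [feature_names[i] for i in best_subset]


def _sample_grid(grid: dict[str, list], n_candidates: int,
                 rng: np.random.Generator) -> list[dict]:
    keys = sorted(grid)
    all_combos: list[dict] = [{}]
    for k in keys:
        all_combos = [dict(c, **{k: v}) for c in all_combos for v in grid[k]]
    if len(all_combos) <= n_candidates:
        return all_combos
    idx = rng.choice(len(all_combos), size=n_candidates, replace=False)
    return [all_combos[i] for i in sorted(idx)]


def halving_search(family: str, X: np.ndarray, y: np.ndarray,
                   groups: np.ndarray, seed: int = 0,
                   grid: dict[str, list] | None = None,
                   n_candidates: int = 8, factor: int = 3) -> dict:
    """Randomized grid search with successive halving over sample budgets.

    Candidates are sampled uniformly from the family's grid; each rung
    evaluates the survivors by inner grouped-CV BAC on a subject-subsampled
    training budget, keeps the top ``1/factor``, and triples the budget;
    the final rung always uses the full training set. Deterministic given
    the seed.
    """
    grid = grid if grid is not None else DEFAULT_GRIDS[family]
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("empty hyperparameter grid")
    rng = np.random.default_rng(seed)
    candidates = _sample_grid(grid, n_candidates, rng)
    if len(candidates) == 1:
        return candidates[0]

    subjects = np.unique(groups)
    n_rungs = int(np.ceil(np.log(len(candidates)) / np.log(factor))) + 1
    # strictly increasing subject budgets ending at the full set
    budgets = [max(3, int(round(len(subjects) / factor ** (n_rungs - 1 - r))))
               for r in range(n_rungs)]
    budgets[-1] = len(subjects)

    for rung, budget in enumerate(budgets):
        if budget >= len(subjects):
            chosen = subjects
        else:
            chosen = rng.choice(subjects, size=budget, replace=False)
        mask = np.isin(groups, chosen)
        if len(np.unique(y[mask])) < 2:
            mask = np.ones(len(y), dtype=bool)
        scores = []
        for params in candidates:
            try:
                scores.append(_inner_bac(family, X[mask], y[mask],
                                         groups[mask], seed, params))
            except ValueError:
                scores.append(-np.inf)
        if rung == len(budgets) - 1 or len(candidates) == 1:
            return candidates[int(np.argmax(scores))]
        keep = max(1, len(candidates) // factor)
        order = np.argsort(scores)[::-1][:keep]
        candidates = [candidates[i] for i in sorted(order)]
    return candidates[0]  # pragma: no cover


# ---------------------------------------------------------------------------
# metrics

def compute_metrics(y_true: np.ndarray, y_score: np.ndarray,
                    threshold: float = 0.5):
    """Sensitivity, specificity, BAC and trapezoidal AUC over the ROC.

    BAC = (sensitivity + specificity) / 2 at the given score threshold;
    the ROC is the full monotone step curve from (0,0) to (1,1).
    """
    y_true = np.asarray(y_true, dtype=int)
    y_score = np.asarray(y_score, dtype=float)
    if len(np.unique(y_true)) < 2:
        raise ValueError("both classes must be present")
    y_pred = (y_score >= threshold).astype(int)
    pos, neg = y_true == 1, y_true == 0
    sensitivity = float(np.mean(y_pred[pos] == 1))
    specificity = float(np.mean(y_pred[neg] == 0))
    bac = (sensitivity + specificity) / 2.0
    fpr, tpr, _ = roc_curve(y_true, y_score)
    auc = float(np.trapezoid(tpr, fpr))
    return sensitivity, specificity, bac, auc, (fpr, tpr)


def _platt(scores: np.ndarray, y: np.ndarray, seed: int) -> LogisticRegression:
    cal = LogisticRegression(max_iter=2000, random_state=seed)
    cal.fit(scores.reshape(-1, 1), y)
    return cal


def _impute(train: pd.DataFrame, others: list[pd.DataFrame],
            feats: list[str]) -> tuple[pd.DataFrame, list[pd.DataFrame], pd.Series]:
    medians = train[feats].median()
    medians = medians.fillna(0.0)  # feature missing in the whole training fold
    out_train = train.copy()
    out_train[feats] = out_train[feats].fillna(medians)
    out_others = []
    for df in others:
        d = df.copy()
        d[feats] = d[feats].fillna(medians)
        out_others.append(d)
    return out_train, out_others, medians


def loso_cv(table: pd.DataFrame, spec: LabelSpec, family: str,
            seed: int = 0, do_rfe: bool = True,
            do_search: bool = True) -> CVResult:
    """Leave-one-subject-out evaluation of the full pipeline.

    Per fold: median imputation, greedy feature elimination and the halving
    hyperparameter search are fit on all-but-one subject; the left-out
    subject's rows are scored by the fold's Platt-calibrated model. Scores
    are pooled across folds for a single ROC; single-class training folds
    are skipped with a warning and recorded.
    """
    labeled = make_labels(table, spec)
    if labeled["subject_id"].nunique() < 3:
        raise ValueError("need at least 3 subjects")
    if labeled["label"].nunique() < 2:
        raise ValueError("both classes must be present overall")
    scaled = subject_scale(labeled)
    feats = feature_columns(scaled.drop(columns=["label"]))
    groups_all = scaled["subject_id"].to_numpy()

    folds: list[FoldResult] = []
    logo = LeaveOneGroupOut()
    X_all = scaled[feats]
    y_all = scaled["label"].to_numpy(int)
    for tr_idx, te_idx in logo.split(X_all, y_all, groups_all):
        subject = str(groups_all[te_idx[0]])
        train_df = scaled.iloc[tr_idx]
        test_df = scaled.iloc[te_idx]
        y_tr = y_all[tr_idx]
        if len(np.unique(y_tr)) < 2:
            warnings.warn(f"fold {subject}: single-class training set; skipped")
            folds.append(FoldResult(subject, y_all[te_idx], np.array([]),
                                    np.array([]), [], {}, skipped=True,
                                    skip_reason="single-class training set"))
            continue
        fold_seed = seed + zlib.crc32(subject.encode()) % 10007
        train_imp, (test_imp,), _ = _impute(train_df, [test_df], feats)
        Xtr = train_imp[feats].to_numpy(float)
        gtr = train_imp["subject_id"].to_numpy()
        selected = (rfe_select(family, Xtr, y_tr, gtr, feats, seed=fold_seed)
                    if do_rfe else list(feats))
        Xsel = train_imp[selected].to_numpy(float)
        params = (halving_search(family, Xsel, y_tr, gtr, seed=fold_seed)
                  if do_search else {})
        est = make_estimator(family, seed=fold_seed, **params)
        est.fit(Xsel, y_tr)
        cal = _platt(_raw_scores(est, Xsel), y_tr, seed=fold_seed)
        raw_te = _raw_scores(est, test_imp[selected].to_numpy(float))
        proba = cal.predict_proba(raw_te.reshape(-1, 1))[:, 1]
        folds.append(FoldResult(
            subject=subject, y_true=y_all[te_idx], y_score=proba,
            y_pred=(proba >= 0.5).astype(int),
            selected_features=selected, hyperparameters=params))

    scored = [f for f in folds if not f.skipped]
    y_true = np.concatenate([f.y_true for f in scored])
    y_score = np.concatenate([f.y_score for f in scored])
    sens, spec_, bac, auc, roc = compute_metrics(y_true, y_score)
    return CVResult(folds=folds, sensitivity=sens, specificity=spec_,
                    bac=bac, auc=auc, roc=roc)


def train_final(table: pd.DataFrame, spec: LabelSpec, family: str,
                seed: int = 0, cv: CVResult | None = None,
                do_rfe: bool = True, do_search: bool = True) -> TrainedModel:
    """Aggregate per-fold selections into one model fit on all data.

    Features kept in at least half of the (non-skipped) LOSO folds form the
    final subset (falling back to the full set with a warning if the
    aggregate is empty); hyperparameters take the per-parameter mode
    (median for numeric values with no mode tie-break need).
    """
    if cv is None:
        cv = loso_cv(table, spec, family, seed=seed,
                     do_rfe=do_rfe, do_search=do_search)
    labeled = make_labels(table, spec)
    scaled = subject_scale(labeled)
    feats = feature_columns(scaled.drop(columns=["label"]))
    scored = [f for f in cv.folds if not f.skipped]

    counts: dict[str, int] = {}
    for f in scored:
        for name in f.selected_features:
            counts[name] = counts.get(name, 0) + 1
    selected = [n for n in feats if counts.get(n, 0) >= len(scored) / 2.0]
    if not selected:
        warnings.warn("empty aggregate feature set; falling back to full set")
        selected = list(feats)

    agg_params: dict[str, Any] = {}
    keys = {k for f in scored for k in f.hyperparameters}
    for k in keys:
        vals = [f.hyperparameters[k] for f in scored if k in f.hyperparameters]
        if all(isinstance(v, (int, float)) and not isinstance(v, bool)
               for v in vals if v is not None) and None not in vals:
            agg_params[k] = type(vals[0])(np.median(vals))
        else:
            uniq, cnt = np.unique([repr(v) for v in vals], return_counts=True)
            winner = uniq[int(np.argmax(cnt))]
            agg_params[k] = next(v for v in vals if repr(v) == winner)

    full_imp, _, medians = _impute(scaled, [], feats)
    X = full_imp[selected].to_numpy(float)
    y = full_imp["label"].to_numpy(int)
    est = make_estimator(family, seed=seed, **agg_params)
    est.fit(X, y)
    cal = _platt(_raw_scores(est, X), y, seed=seed)
    return TrainedModel(family=family, estimator=est, calibrator=cal,
                        selected_features=selected,
                        imputation_medians=medians, scaling_mode="per_subject",
                        hyperparameters=agg_params)


# ---------------------------------------------------------------------------
# additive feature attribution

def attribute_features(model: TrainedModel, table: pd.DataFrame,
                       n_permutations: int = 30, seed: int = 0
                       ) -> pd.DataFrame:
    """Per-sample additive attributions and their mean-|value| ranking.

    Linear families get the closed form ``w_j (x_j - mean(x_j))`` on the
    model's decision scale, which is exact. Other families use a
    permutation-sampling Shapley approximation against the feature-mean
    reference point; because every sampled permutation's marginal
    contributions telescope, attributions always sum to
    ``f(x) - f(reference)`` (the efficiency property).

    Returns a DataFrame indexed by feature with columns ``mean_abs`` and
    ``rank`` (1 = most influential), carrying the per-sample attribution
    matrix in ``.attrs["attributions"]``.
    """
    feats = model.selected_features
    X = model._matrix(table)
    est = model.estimator
    n, p = X.shape

    if hasattr(est, "coef_"):
        w = np.ravel(est.coef_)
        phi = (X - X.mean(axis=0)) * w
    else:
        rng = np.random.default_rng(seed)
        ref = X.mean(axis=0)
        phi = np.zeros((n, p))
        for _ in range(n_permutations):
            order = rng.permutation(p)
            current = np.tile(ref, (n, 1))
            prev_scores = _raw_scores(est, current)
            for j in order:
                current[:, j] = X[:, j]
                new_scores = _raw_scores(est, current)
                phi[:, j] += new_scores - prev_scores
                prev_scores = new_scores
        phi /= n_permutations

    mean_abs = np.abs(phi).mean(axis=0)
    out = pd.DataFrame({"mean_abs": mean_abs}, index=pd.Index(feats, name="feature"))
    out["rank"] = out["mean_abs"].rank(ascending=False, method="min").astype(int)
    out = out.sort_values("mean_abs", ascending=False)
    out.attrs["attributions"] = phi
    out.attrs["feature_order"] = list(feats)
    return out
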