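"""Surr-INVIGOR: a KNN surrogate for the growth-rate label.

Most patients have a single (diagnostic) mammogram, so the serial-imaging
growth-rate label cannot be computed for them. The surrogate classifier
predicts the fast/slow label from routine clinicopathological features:

1. *Screening*: per candidate feature, a Welch two-tailed t-test between
   fast- and slow-growing tumours; features with p below an admission
   threshold (default 0.2) enter, ranked by ascending p.
2. *Selection*: forward sequential selection in screening-rank order —
   feature sets are rank prefixes, grown one feature at a time. For each
   set size and each algorithm in the zoo, a seeded budgeted
   hyperparameter search is scored by repeated stratified k-fold
   cross-validation (standardisation learned on each training fold only).
   The configuration with maximal mean CV accuracy wins; ties break to
   fewer features, then zoo order, then the smaller hyperparameter.
3. *Freezing*: the winning KNN (z-scored features, Euclidean distance,
   odd k, majority vote, distance ties to training order) is stored with
   its standardisation parameters and training points in a versioned JSON
   artifact that reloads bit-identically.

KNN is implemented natively; the other zoo members (svm, decision_tree,
naive_bayes, discriminant, random_forest) are optional comparators that
delegate to scikit-learn when it is installed and never gate the
pipeline: the frozen artifact is always the best KNN configuration, with
any higher-scoring comparator noted in the trace.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import survival
from .errors import DataError
from .sm_invigor import DEFAULT_ADJUSTERS, encode_covariates

ARTIFACT_VERSION = "1"

#: default candidate surrogate features. ``mammographic_size_mm`` (the mean
#: diagnostic-mammogram diameter) is derived on the fly and stands in for the
#: second size variable alongside the histological size.
DEFAULT_FEATURES = (
    "ki67_percent",
    "mitotic_score",
    "histological_size_mm",
    "npi",
    "grade",
    "nodal_stage",
    "mammographic_size_mm",
)

CLASSES = ("slow", "fast")


@dataclass
class ScreeningResult:
    """Welch t-test screen of candidate features."""

    table: pd.DataFrame  # feature, t_statistic, p_value, rank, admitted
    threshold_p: float
    excluded: list[str] = field(default_factory=list)

    @property
    def admitted_features(self) -> list[str]:
        adm = self.table[self.table["admitted"]]
        return adm.sort_values("rank")["feature"].tolist()


@dataclass
class SurrogateModelArtifact:
    """Frozen surrogate classifier.

    Standardisation parameters are learned once on the full training data
    and stored; they are never recomputed at prediction time. Training
    points are stored already standardised.
    """

    algorithm: str
    selected_features: list[str]
    k: int
    feature_means: np.ndarray
    feature_scales: np.ndarray
    training_values: np.ndarray  # standardised, patients x features
    training_labels: np.ndarray  # 0 = slow, 1 = fast
    cv_accuracy: float
    resubstitution_accuracy: float
    seed_ledger: dict
    version: str = ARTIFACT_VERSION
    notes: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "version": self.version,
            "algorithm": self.algorithm,
            "selected_features": list(self.selected_features),
            "k": int(self.k),
            "feature_means": self.feature_means.tolist(),
            "feature_scales": self.feature_scales.tolist(),
            "training_values": self.training_values.tolist(),
            "training_labels": self.training_labels.tolist(),
            "cv_accuracy": self.cv_accuracy,
            "resubstitution_accuracy": self.resubstitution_accuracy,
            "seed_ledger": self.seed_ledger,
            "notes": list(self.notes),
        }
        return json.dumps(payload, sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SurrogateModelArtifact":
        d = json.loads(text)
        return cls(
            algorithm=d["algorithm"],
            selected_features=list(d["selected_features"]),
            k=int(d["k"]),
            feature_means=np.asarray(d["feature_means"], dtype=float),
            feature_scales=np.asarray(d["feature_scales"], dtype=float),
            training_values=np.asarray(d["training_values"], dtype=float),
            training_labels=np.asarray(d["training_labels"], dtype=int),
            cv_accuracy=float(d["cv_accuracy"]),
            resubstitution_accuracy=float(d["resubstitution_accuracy"]),
            seed_ledger=d["seed_ledger"],
            version=d["version"],
            notes=list(d.get("notes", [])),
        )

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(self.to_json() + "\n")
        return path

    @classmethod
    def load(cls, path) -> "SurrogateModelArtifact":
        return cls.from_json(Path(path).read_text())

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


def build_feature_matrix(cohort, features=DEFAULT_FEATURES, labels=None):
    """Numeric feature matrix (complete-case) from a cohort.

    Derived feature ``mammographic_size_mm`` = mean of the two diagnostic
    diameters. Returns ``(X, y, index)`` where ``y`` is None without
    labels; rows with any missing selected feature (or missing label) are
    dropped, complete-case per fitted feature set.
    """
    df = cohort.df if hasattr(cohort, "df") else cohort
    cols = {}
    for f in features:
        if f == "mammographic_size_mm":
            cols[f] = (
                pd.to_numeric(df["diag_dim_major"], errors="coerce")
                + pd.to_numeric(df["diag_dim_minor"], errors="coerce")
            ) / 2.0
        elif f in df.columns:
            cols[f] = encode_covariates(df, [f])[f]
        else:
            raise KeyError(f"feature column '{f}' not found in cohort")
    X = pd.DataFrame(cols, index=df.index)
    if labels is not None:
        y = pd.Series(np.asarray(labels, dtype=object), index=df.index)
        keep = X.notna().all(axis=1) & y.isin(CLASSES)
        return X[keep], y[keep], keep
    keep = X.notna().all(axis=1)
    return X[keep], None, keep


def screen_features(X: pd.DataFrame, y, threshold_p: float = 0.2) -> ScreeningResult:
    """Welch two-sample two-tailed t-test per feature; rank by ascending p.

    Features with zero variance in both groups are excluded with a
    diagnostic rather than tested. ``threshold_p = 1.0`` admits every
    testable feature.
    """
    y = np.asarray(y, dtype=object)
    fast = y == "fast"
    slow = y == "slow"
    if fast.sum() < 2 or slow.sum() < 2:
        raise DataError("both classes need at least two members for screening")
    rows = []
    excluded = []
    for feat in X.columns:
        a = X.loc[fast, feat].to_numpy(dtype=float)
        b = X.loc[slow, feat].to_numpy(dtype=float)
        if np.var(a) == 0 and np.var(b) == 0:
            excluded.append(feat)
            continue
        if np.array_equal(np.sort(a), np.sort(b)):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append({"feature": feat, "t_statistic": float(t), "p_value": float(p)})
    if not rows:
        raise DataError("no testable features")
    table = pd.DataFrame(rows).sort_values("p_value", kind="mergesort").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    table["admitted"] = table["p_value"] < threshold_p
    return ScreeningResult(table=table, threshold_p=threshold_p, excluded=excluded)


# ---------------------------------------------------------------------------
# native KNN


def _standardise_fit(X: np.ndarray):
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale = np.where(scale == 0, 1.0, scale)
    return mean, scale


def _knn_votes(train: np.ndarray, labels01: np.ndarray, queries: np.ndarray, k: int):
    """Majority vote of the k nearest training points (Euclidean).

    Distance ties break to the earlier training point (stable argsort),
    so predictions are exactly reproducible.
    """
    if train.shape[0] < k:
        raise DataError(f"fewer training points ({train.shape[0]}) than k ({k})")
    d2 = ((queries[:, None, :] - train[None, :, :]) ** 2).sum(axis=2)
    order = np.argsort(d2, axis=1, kind="stable")
    neighbours = labels01[order[:, :k]]
    votes = neighbours.sum(axis=1)
    return (votes > k / 2).astype(int), votes


def knn_predict(model: SurrogateModelArtifact, query):
    """Predict fast/slow for query feature vectors (raw, unstandardised).

    Returns ``(labels, fast_votes)``; ``query`` may be a single vector or a
    matrix with one row per patient, columns in ``model.selected_features``
    order.
    """
    q = np.atleast_2d(np.asarray(query, dtype=float))
    if q.shape[1] != len(model.selected_features):
        raise DataError(
            f"query has {q.shape[1]} features; model expects {len(model.selected_features)}"
        )
    qs = (q - model.feature_means) / model.feature_scales
    pred, votes = _knn_votes(model.training_values, model.training_labels, qs, model.k)
    labels = np.asarray(CLASSES, dtype=object)[pred]
    return labels, votes


# ---------------------------------------------------------------------------
# cross-validation


def _stratified_folds(y01: np.ndarray, folds: int, rng: np.random.Generator):
    """Shuffled stratified fold assignment; returns an int array per subject."""
    assignment = np.empty(y01.size, dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y01 == cls)
        rng.shuffle(idx)
        assignment[idx] = np.arange(idx.size) % folds
    return assignment


def cross_validate(
    X,
    y,
    k: int | None = None,
    algorithm: str = "knn",
    hyperparams: dict | None = None,
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
):
    """Repeated stratified k-fold CV accuracy of one configuration.

    Accuracy is the fraction of held-out patients whose prediction matches
    their label, pooled over the folds of a repeat; the mean over repeats
    is returned together with the per-repeat accuracies. Standardisation
    is fit on each training fold only. Fully reproducible from the seed.
    """
    hyperparams = dict(hyperparams or {})
    if k is not None:
        hyperparams["k"] = k
    per_repeat = cross_validate_grid(
        X, y, [(algorithm, hyperparams)], folds=folds, repeats=repeats, seed=seed
    )[0]
    return float(np.mean(per_repeat)), np.asarray(per_repeat)


def _encode_labels(y) -> np.ndarray:
    y = np.asarray(y, dtype=object)
    bad = ~np.isin(y, CLASSES)
    if bad.any():
        raise DataError(f"labels must be in {CLASSES}")
    return (y == "fast").astype(int)


def cross_validate_grid(X, y, configs, folds=5, repeats=10, seed=0):
    """Per-repeat CV accuracies for many configurations on shared folds.

    ``configs`` is a list of ``(algorithm, hyperparams)``. All KNN
    configurations share each fold's distance ordering, so an exhaustive
    odd-k grid costs barely more than a single k. Returns a list of
    per-repeat accuracy arrays aligned with ``configs``.
    """
    Xv = np.asarray(X, dtype=float)
    y01 = _encode_labels(y)
    n = y01.size
    if min((y01 == 0).sum(), (y01 == 1).sum()) < folds:
        raise DataError(f"each class needs at least {folds} members for {folds}-fold CV")
    rng = np.random.default_rng(seed)
    knn_ks = [int(hp.get("k", 5)) for alg, hp in configs if alg == "knn"]
    kmax = max(knn_ks) if knn_ks else 0
    accs = [np.zeros(repeats) for _ in configs]
    for rep in range(repeats):
        assignment = _stratified_folds(y01, folds, rng)
        correct = [0 for _ in configs]
        for f in range(folds):
            test = assignment == f
            train = ~test
            mean, scale = _standardise_fit(Xv[train])
            Xtr = (Xv[train] - mean) / scale
            Xte = (Xv[test] - mean) / scale
            ytr, yte = y01[train], y01[test]
            knn_cum = None
            if kmax:
                d2 = ((Xte[:, None, :] - Xtr[None, :, :]) ** 2).sum(axis=2)
                order = np.argsort(d2, axis=1, kind="stable")
                knn_cum = np.cumsum(ytr[order], axis=1)
            for ci, (alg, hp) in enumerate(configs):
                if alg == "knn":
                    k = int(hp.get("k", 5))
                    if k > Xtr.shape[0]:
                        raise DataError(f"fewer training points ({Xtr.shape[0]}) than k ({k})")
                    pred = (knn_cum[:, k - 1] > k / 2).astype(int)
                else:
                    pred = _sklearn_fit_predict(alg, hp, Xtr, ytr, Xte)
                correct[ci] += int((pred == yte).sum())
        for ci in range(len(configs)):
            accs[ci][rep] = correct[ci] / n
    return accs


def _sklearn_fit_predict(alg, hyperparams, Xtr, ytr, Xte):
    """Comparator zoo members, delegated to scikit-learn (lazy import)."""
    try:
        from sklearn import discriminant_analysis, ensemble, naive_bayes, svm, tree
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise DataError(
            f"zoo algorithm '{alg}' needs scikit-learn, which is not installed"
        ) from exc
    seed = int(hyperparams.get("random_state", 0))
    if alg == "svm":
        est = svm.SVC(
            C=float(hyperparams.get("C", 1.0)), gamma=hyperparams.get("gamma", "scale")
        )
    elif alg == "decision_tree":
        est = tree.DecisionTreeClassifier(
            max_depth=hyperparams.get("max_depth"), random_state=seed
        )
    elif alg == "naive_bayes":
        est = naive_bayes.GaussianNB()
    elif alg == "discriminant":
        est = discriminant_analysis.LinearDiscriminantAnalysis()
    elif alg == "random_forest":
        est = ensemble.RandomForestClassifier(
            n_estimators=int(hyperparams.get("n_estimators", 100)), random_state=seed
        )
    else:
        raise DataError(f"unknown zoo algorithm '{alg}'")
    est.fit(Xtr, ytr)
    return est.predict(Xte)


# ---------------------------------------------------------------------------
# sequential selection


def default_k_grid(n: int) -> list[int]:
    """Odd neighbour counts 1, 3, ..., min(31, n // 3)."""
    upper = min(31, max(1, n // 3))
    return list(range(1, upper + 1, 2))


def _hyperparam_candidates(alg, n, rng, per_algorithm=8):
    if alg == "knn":
        return [{"k": k} for k in default_k_grid(n)]
    if alg == "svm":
        return [
            {"C": float(10 ** rng.uniform(-2, 2)), "gamma": "scale"}
            for _ in range(per_algorithm)
        ]
    if alg == "decision_tree":
        return [{"max_depth": int(rng.integers(1, 8))} for _ in range(per_algorithm)]
    if alg in ("naive_bayes", "discriminant"):
        return [{}]
    if alg == "random_forest":
        return [
            {"n_estimators": int(rng.integers(20, 200))} for _ in range(per_algorithm)
        ]
    raise DataError(f"unknown zoo algorithm '{alg}'")


def sequential_select(
    X: pd.DataFrame,
    y,
    threshold_p: float = 0.2,
    zoo=("knn",),
    budget: int = 180,
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
) -> tuple[SurrogateModelArtifact, pd.DataFrame]:
    """Screen, forward-select and freeze the surrogate classifier.

    Feature sets are prefixes of the screening ranking. At each set size
    every zoo algorithm gets a budgeted hyperparameter search (exhaustive
    odd-k grid for KNN, seeded random draws for comparators), each
    candidate scored by :func:`cross_validate_grid`. ``budget`` caps the
    total number of scored configurations; the search stops when it is
    exhausted (noted in the trace). Returns the frozen artifact and a
    trace with one row per evaluated configuration.
    """
    zoo = list(zoo)
    if budget < len(zoo):
        raise DataError(f"budget ({budget}) smaller than the zoo ({len(zoo)} algorithms)")
    screening = screen_features(X, y, threshold_p)
    admitted = screening.admitted_features
    if not admitted:
        raise DataError("no features admitted by the screening threshold")
    rng = np.random.default_rng(seed)
    y01 = _encode_labels(y)
    n = y01.size

    trace_rows = []
    evaluations = 0
    truncated = False
    for size in range(1, len(admitted) + 1):
        feats = admitted[:size]
        Xsub = X[feats].to_numpy(dtype=float)
        for alg in zoo:
            candidates = _hyperparam_candidates(alg, n, rng)
            room = budget - evaluations
            if room <= 0:
                truncated = True
                break
            if len(candidates) > room:
                candidates = candidates[:room]
                truncated = True
            configs = [(alg, hp) for hp in candidates]
            accs = cross_validate_grid(Xsub, y, configs, folds=folds, repeats=repeats, seed=seed)
            evaluations += len(configs)
            for (a, hp), acc in zip(configs, accs):
                trace_rows.append(
                    {
                        "n_features": size,
                        "features": ",".join(feats),
                        "algorithm": a,
                        "hyperparams": json.dumps(hp, sort_keys=True),
                        "cv_accuracy": float(np.mean(acc)),
                        "cv_sd": float(np.std(acc)),
                    }
                )
        if truncated and evaluations >= budget:
            break
    trace = pd.DataFrame(trace_rows)
    if truncated:
        warnings.warn("evaluation budget exhausted before the full grid was scored")

    # winner: max accuracy; ties -> fewer features -> zoo order -> smaller k
    def _sort_key(row):
        zoo_pos = zoo.index(row["algorithm"])
        hp = json.loads(row["hyperparams"])
        return (-row["cv_accuracy"], row["n_features"], zoo_pos, hp.get("k", 0))

    best_overall = min(trace.to_dict("records"), key=_sort_key)
    knn_rows = [r for r in trace.to_dict("records") if r["algorithm"] == "knn"]
    if not knn_rows:
        raise DataError("the zoo must include 'knn' (the artifact's prediction path)")
    best_knn = min(knn_rows, key=_sort_key)
    notes = []
    if truncated:
        notes.append("budget exhausted before full grid")
    if best_overall["algorithm"] != "knn":
        notes.append(
            f"comparator {best_overall['algorithm']} scored "
            f"{best_overall['cv_accuracy']:.3f} vs knn {best_knn['cv_accuracy']:.3f}; "
            "artifact frozen from the best knn"
        )

    feats = best_knn["features"].split(",")
    k = int(json.loads(best_knn["hyperparams"])["k"])
    Xw = X[feats].to_numpy(dtype=float)
    mean, scale = _standardise_fit(Xw)
    Xs = (Xw - mean) / scale
    resub_pred, _ = _knn_votes(Xs, y01, Xs, k)
    artifact = SurrogateModelArtifact(
        algorithm="knn",
        selected_features=feats,
        k=k,
        feature_means=mean,
        feature_scales=scale,
        training_values=Xs,
        training_labels=y01,
        cv_accuracy=float(best_knn["cv_accuracy"]),
        resubstitution_accuracy=float((resub_pred == y01).mean()),
        seed_ledger={"seed": int(seed), "folds": int(folds), "repeats": int(repeats)},
        notes=notes,
    )
    return artifact, trace


def apply_surrogate(
    model: SurrogateModelArtifact,
    cohort,
    adjusters=DEFAULT_ADJUSTERS,
    horizon_months: float | None = None,
) -> dict:
    """Predict fast/slow for a cohort and, if survival is present, report it.

    Raises ``KeyError`` naming any feature column the cohort lacks. Rows
    missing a model feature are left unlabelled. The survival report
    contains per-group KM summaries, the log-rank test and a Cox fit of
    the predicted label adjusted for the configured confounders.
    """
    X, _, keep = build_feature_matrix(cohort, model.selected_features)
    df = cohort.df if hasattr(cohort, "df") else cohort
    labels = pd.Series([None] * len(df), index=df.index, dtype=object)
    if keep.any():
        pred, _ = knn_predict(model, X.to_numpy(dtype=float))
        labels.loc[keep] = pred
    out: dict = {"labels": labels, "n_labelled": int(keep.sum()), "report": None}
    if "bcss_months" not in df.columns or df["bcss_months"].isna().all():
        return out
    have = keep & df["bcss_months"].notna() & df["event"].notna()
    lab = labels[have].to_numpy(dtype=object)
    if have.sum() == 0 or len(set(lab)) < 2:
        return out
    time = df.loc[have, "bcss_months"].to_numpy(dtype=float)
    event = df.loc[have, "event"].to_numpy(dtype=float)
    if horizon_months is not None:
        time, event = survival.administrative_censor(time, event, horizon_months)
    report: dict = {}
    for grp in CLASSES:
        mask = lab == grp
        curve = survival.km_estimate(time[mask], event[mask])
        report[f"km_{grp}"] = {
            "n": int(mask.sum()),
            "events": int(event[mask].sum()),
            "survival_at_120m": curve.survival_at(120.0),
        }
    if event.sum() > 0:
        lr = survival.logrank_test(time, event, lab == "fast")
        report["logrank"] = {"chi_square": lr.chi_square, "p_value": lr.p_value}
        design = pd.DataFrame({"fast": (lab == "fast").astype(float)})
        usable_adjusters = []
        if adjusters:
            enc = encode_covariates(df.loc[have], adjusters).reset_index(drop=True)
            for c in enc.columns:
                if enc[c].nunique() > 1:
                    design[c] = enc[c]
                    usable_adjusters.append(c)
        design["time"] = time
        design["event"] = event
        try:
            fit = survival.fit_cox(
                design, [c for c in design.columns if c not in ("time", "event")]
            )
            report["cox_adjusted"] = {
                "hazard_ratio_fast": float(fit.hazard_ratios["fast"]),
                "p_value_fast": float(fit.p_values["fast"]),
                "adjusters": usable_adjusters,
                "aic": fit.aic,
            }
        except DataError as exc:
            report["cox_adjusted"] = {"error": str(exc)}
    out["report"] = report
    return out
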