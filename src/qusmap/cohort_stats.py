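"""Patient-level statistics and cross-validated lesion classification.

Per-plane biomarkers (six parametric maps x {mean, contrast, correlation,
energy, homogeneity}) are volume-averaged per patient, compared between
groups with a two-sided Mann-Whitney U test, combined into a hybrid
biomarker by stepwise (Wilks'-lambda) linear discriminant feature selection,
and evaluated with a k-nearest-neighbour classifier under
leave-one-patient-out cross-validation (sensitivity, specificity, accuracy,
AUC; malignant is the positive class).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .maps import PARAMETER_IDS

__all__ = [
    "FEATURE_NAMES",
    "aggregate_patient",
    "build_feature_table",
    "mwu_test",
    "significance_tier",
    "feature_stats",
    "StepwiseModel",
    "stepwise_lda",
    "ClassificationResult",
    "knn_lopo",
    "roc_auc",
]

TEXTURE_KINDS = ("mean", "contrast", "correlation", "energy", "homogeneity")

#: The 30 candidate biomarkers: 6 parameters x 5 features.
FEATURE_NAMES = tuple(f"{p}_{k}" for p in PARAMETER_IDS for k in TEXTURE_KINDS)


# --------------------------------------------------------------------------
# aggregation
# --------------------------------------------------------------------------

def aggregate_patient(plane_table: pd.DataFrame) -> pd.Series:
    """Volume-average one patient's per-plane features.

    ``plane_table`` holds one row per (plane, parameter) with columns
    mean/contrast/correlation/energy/homogeneity (long form, as written by
    the pipeline).  Missing per-plane values are skipped; a feature missing
    in every plane stays NaN and flags the patient incomplete downstream.
    """
    out = {}
    for p in plane_table["parameter"].unique():
        sub = plane_table[plane_table["parameter"] == p]
        for k in TEXTURE_KINDS:
            if k in sub.columns:
                out[f"{p}_{k}"] = sub[k].mean(skipna=True)
    for extra in ("ace",):
        if extra in plane_table.columns:
            out[f"{extra}_mean"] = plane_table.drop_duplicates("plane")[extra].mean(skipna=True)
    return pd.Series(out)


def build_feature_table(features_long: pd.DataFrame) -> pd.DataFrame:
    """Patient x biomarker table from the long per-plane feature table.

    Expects columns patient_id, label, plane, parameter and the texture
    feature columns; returns one row per patient with the 30 biomarkers
    (plus ace_mean when present) and the label.
    """
    rows = []
    for pid, sub in features_long.groupby("patient_id", sort=True):
        row = aggregate_patient(sub)
        row["patient_id"] = pid
        row["label"] = sub["label"].iloc[0]
        rows.append(row)
    table = pd.DataFrame(rows).set_index("patient_id")
    return table


# --------------------------------------------------------------------------
# group comparison
# --------------------------------------------------------------------------

def mwu_test(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (exact for small tie-free samples)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if np.all(x == x[0]) and np.all(y == x[0]):
        return float(len(x) * len(y) / 2.0), 1.0
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def significance_tier(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def feature_stats(table: pd.DataFrame, candidates: tuple[str, ...] | None = None,
                  holm: bool = False) -> pd.DataFrame:
    """Per-biomarker Mann-Whitney comparison of benign vs malignant patients.

    p-values are reported uncorrected by default (one test per biomarker);
    ``holm=True`` adds a Holm step-down adjusted column.
    """
    candidates = candidates or [c for c in FEATURE_NAMES if c in table.columns]
    benign = table[table["label"] == "benign"]
    malignant = table[table["label"] == "malignant"]
    rows = []
    for c in candidates:
        x = benign[c].dropna()
        y = malignant[c].dropna()
        u, p = mwu_test(x, y)
        rows.append({"feature": c, "U": u, "p": p, "tier": significance_tier(p),
                     "benign_mean": x.mean(), "malignant_mean": y.mean()})
    out = pd.DataFrame(rows).set_index("feature")
    if holm:
        from statsmodels.stats.multitest import multipletests

        out["p_holm"] = multipletests(out["p"], method="holm")[1]
    return out


# --------------------------------------------------------------------------
# stepwise LDA feature selection
# --------------------------------------------------------------------------

@dataclass
class StepwiseModel:
    selected: list[str]  # in entry order
    coefficients: pd.Series  # standardized, sorted by |coefficient|
    steps: list[dict] = field(default_factory=list)
    empty: bool = False


def _wilks_lambda(X: np.ndarray, y01: np.ndarray) -> float | None:
    """det(W)/det(T) for the column subset X (two groups).

    Returns None when the total scatter is (numerically) singular — the
    subset is collinear and the lambda ratio is undefined; 0.0 when the
    within-group scatter vanishes (perfect separation).
    """
    if X.shape[1] == 0:
        return 1.0
    T = np.atleast_2d(np.cov(X, rowvar=False, bias=True) * len(X))
    W = np.zeros_like(T)
    for g in (0, 1):
        Xg = X[y01 == g]
        W += np.atleast_2d(np.cov(Xg, rowvar=False, bias=True) * len(Xg))
    eig_t = np.linalg.eigvalsh(T)
    if eig_t[0] <= 1e-9 * max(eig_t[-1], 1e-30):
        return None
    sign_w, logdet_w = np.linalg.slogdet(W)
    _, logdet_t = np.linalg.slogdet(T)
    if sign_w <= 0:
        return 0.0
    return float(np.exp(logdet_w - logdet_t))


def stepwise_lda(table: pd.DataFrame, labels: pd.Series | None = None,
                 candidates: tuple[str, ...] | None = None,
                 f_enter: float = 3.84, f_remove: float = 2.71,
                 max_steps: int = 50) -> StepwiseModel:
    """Wilks'-lambda stepwise selection followed by a two-class LDA refit.

    At each step the candidate with the largest partial F enters if
    F >= f_enter; any included feature whose partial F falls to <= f_remove
    is then removed.  Defaults match the classic SPSS stepwise thresholds.
    Coefficients are standardized (computed on z-scored features) and
    reported sorted from highest to lowest absolute contribution.
    """
    if labels is None:
        labels = table["label"]
    candidates = list(candidates or [c for c in FEATURE_NAMES if c in table.columns])
    y01 = (np.asarray(labels) == "malignant").astype(int)
    if min((y01 == 0).sum(), (y01 == 1).sum()) < 2:
        raise ValueError("need >= 2 patients per class")
    Xall = table[candidates].to_numpy(dtype=float)
    mu, sd = np.nanmean(Xall, axis=0), np.nanstd(Xall, axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (Xall - mu) / sd
    Z = np.nan_to_num(Z)
    n = len(Z)

    selected: list[int] = []
    steps: list[dict] = []

    def partial_f(current: list[int], j: int) -> float:
        lam0 = _wilks_lambda(Z[:, current], y01)
        lam1 = _wilks_lambda(Z[:, current + [j]], y01)
        if lam0 is None or lam1 is None:
            return 0.0  # collinear addition brings no discrimination
        if lam1 <= 0:
            return np.inf
        p = len(current)
        return (n - 2 - p) * (lam0 / lam1 - 1.0)

    for _ in range(max_steps):
        changed = False
        remaining = [j for j in range(len(candidates)) if j not in selected]
        if remaining and n - 2 - len(selected) > 0:
            fs = np.array([partial_f(selected, j) for j in remaining])
            best = int(np.argmax(fs))
            if fs[best] >= f_enter:
                selected.append(remaining[best])
                steps.append({"action": "enter",
                              "feature": candidates[remaining[best]],
                              "F": float(fs[best])})
                changed = True
        if len(selected) > 1:
            f_out = np.array([
                partial_f([s for s in selected if s != j], j) for j in selected
            ])
            worst = int(np.argmin(f_out))
            if f_out[worst] <= f_remove:
                steps.append({"action": "remove",
                              "feature": candidates[selected[worst]],
                              "F": float(f_out[worst])})
                del selected[worst]
                changed = True
        if not changed:
            break

    if not selected:
        return StepwiseModel([], pd.Series(dtype=float), steps, empty=True)

    Zs = Z[:, selected]
    m0 = Zs[y01 == 0].mean(axis=0)
    m1 = Zs[y01 == 1].mean(axis=0)
    Sw = np.zeros((len(selected), len(selected)))
    for g in (0, 1):
        Xg = Zs[y01 == g]
        Sw += np.cov(Xg, rowvar=False, bias=True) * len(Xg)
    Sw /= max(1, n - 2)
    w = np.linalg.pinv(Sw) @ (m1 - m0)
    coeffs = pd.Series(w, index=[candidates[j] for j in selected])
    coeffs = coeffs.reindex(coeffs.abs().sort_values(ascending=False).index)
    return StepwiseModel([candidates[j] for j in selected], coeffs, steps)


# --------------------------------------------------------------------------
# k-NN LOPO classification
# --------------------------------------------------------------------------

@dataclass
class ClassificationResult:
    predictions: pd.DataFrame  # per patient: label, predicted, score
    sensitivity: float  # %
    specificity: float  # %
    accuracy: float  # %
    auc: float
    roc: pd.DataFrame  # fpr, tpr, threshold
    selected_features: list[str] = field(default_factory=list)


def _knn_scores(train_X: np.ndarray, train_y: np.ndarray, test_X: np.ndarray,
                k: int) -> np.ndarray:
    """Fraction of malignant neighbours among the k nearest (Euclidean).

    Distance ties resolve by training-row order via a stable argsort, which
    the caller keeps aligned with patient-id order.
    """
    d = np.linalg.norm(train_X[None, :, :] - test_X[:, None, :], axis=2)
    order = np.argsort(d, axis=1, kind="stable")
    neigh = train_y[order[:, :k]]
    return neigh.mean(axis=1)


def knn_lopo(table: pd.DataFrame, k: int = 5,
             candidates: tuple[str, ...] | None = None,
             select: str | None = None, select_per_fold: bool = True,
             f_enter: float = 3.84, f_remove: float = 2.71) -> ClassificationResult:
    """Leave-one-patient-out k-NN classification.

    Features are z-scored with the training fold's statistics; when
    ``select='stepwise'`` the stepwise LDA selection is, by default, refit
    inside every fold so the held-out patient never influences it
    (``select_per_fold=False`` reproduces a single global selection).
    k must be odd so majority votes cannot tie.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd to avoid vote ties")
    if k >= len(table):
        raise ValueError("k must be smaller than the number of patients")
    candidates = list(candidates or [c for c in FEATURE_NAMES if c in table.columns])
    table = table.sort_index()
    y = (table["label"] == "malignant").to_numpy(dtype=int)
    X = table[candidates].to_numpy(dtype=float)
    X = np.nan_to_num(X, nan=np.nanmean(X, axis=0) if np.isnan(X).any() else 0.0)

    global_selected: list[str] = []
    if select == "stepwise" and not select_per_fold:
        model = stepwise_lda(table, candidates=tuple(candidates),
                             f_enter=f_enter, f_remove=f_remove)
        global_selected = model.selected or list(candidates)

    scores = np.empty(len(table))
    for i in range(len(table)):
        train = np.ones(len(table), dtype=bool)
        train[i] = False
        if y[train].min() == y[train].max():
            raise ValueError("a class is absent from a training fold")
        if select == "stepwise" and select_per_fold:
            model = stepwise_lda(table.iloc[train], candidates=tuple(candidates),
                                 f_enter=f_enter, f_remove=f_remove)
            cols = [candidates.index(s) for s in model.selected] or list(range(len(candidates)))
        elif select == "stepwise":
            cols = [candidates.index(s) for s in global_selected]
        else:
            cols = list(range(len(candidates)))
        Xt = X[train][:, cols]
        mu, sd = Xt.mean(axis=0), Xt.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        scores[i] = _knn_scores((Xt - mu) / sd, y[train],
                                (X[i:i + 1, cols] - mu) / sd, k)[0]

    pred = (scores > 0.5).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    sens = 100.0 * tp / max(1, tp + fn)
    spec = 100.0 * tn / max(1, tn + fp)
    acc = 100.0 * (tp + tn) / len(y)
    auc, roc = roc_auc(scores, y)

    predictions = pd.DataFrame({
        "label": table["label"],
        "predicted": np.where(pred == 1, "malignant", "benign"),
        "score": scores,
    }, index=table.index)
    if select == "stepwise" and not select_per_fold:
        selected = global_selected
    else:
        selected = []
    return ClassificationResult(predictions, sens, spec, acc, auc, roc, selected)


def roc_auc(scores, labels) -> tuple[float, pd.DataFrame]:
    """Rank-based AUC (ties count 1/2) and the threshold-swept ROC curve.

    The AUC equals the Mann-Whitney U statistic of the malignant scores
    divided by n+ * n-, which is also the trapezoidal area under the swept
    ROC — asserted by the test suite, not assumed here.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if y.dtype.kind in "UOS":
        y = (y == "malignant").astype(int)
    pos = scores[y == 1]
    neg = scores[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    auc = float(wins) / (len(pos) * len(neg))

    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    tpr = [(pos >= t).mean() for t in thresholds]
    fpr = [(neg >= t).mean() for t in thresholds]
    roc = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    return auc, roc
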