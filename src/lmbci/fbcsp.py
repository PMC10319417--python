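"""Filter-bank common spatial patterns (FBCSP) with an RBF-SVM decoder.

Two-class motor-imagery decoding in three stages: (1) band-pass the
task epochs into six sub-bands spanning 7-32 Hz; (2) per band, fit
common spatial patterns — the generalized eigenproblem of the two class
covariances — and take the log of the normalized variance of the top
and bottom spatial components as features; (3) rank the pooled features
by mutual information with the class label, keep the best eight, and
classify with a Gaussian-kernel SVM whose C and gamma are grid-searched
by inner cross-validation.  Evaluation is stratified outer 5-fold
cross-validation with all fitting confined to the training folds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from lmbci.errors import ConfigError, DegenerateInputError
from lmbci.filters import bandpass_filter
from lmbci.preprocessing import EpochSet

log = logging.getLogger(__name__)

#: Six sub-bands covering 7-32 Hz.
FILTER_BANK: tuple[tuple[float, float], ...] = (
    (7.0, 12.0), (12.0, 16.0), (16.0, 20.0), (20.0, 24.0), (24.0, 28.0), (28.0, 32.0),
)

#: The four two-class pairings; the second condition is the positive class.
DATASET_PAIRS: dict[str, tuple[str, str]] = {
    "D1": ("rest", "V-rest"),
    "D2": ("rest", "no-LMI"),
    "D3": ("rest", "KI-LMI"),
    "D4": ("V-rest", "KI-LMI"),
}

DEFAULT_C_GRID = tuple(2.0**k for k in range(-3, 8))
DEFAULT_GAMMA_GRID = tuple(2.0**k for k in range(-7, 4))


@dataclass
class DatasetPair:
    """Task epochs of two conditions with binary labels (1 = second condition)."""

    name: str
    conditions: tuple[str, str]
    trials: np.ndarray  # (n_trials, n_channels, n_samples)
    labels: np.ndarray  # 0/1
    fs: float
    montage: tuple[str, ...]


def make_dataset_pair(epochs: EpochSet, name: str,
                      conditions: tuple[str, str] | None = None) -> DatasetPair:
    """Build one of the four pairings (D1..D4) from clean trials."""
    if conditions is None:
        if name not in DATASET_PAIRS:
            raise ConfigError(f"unknown dataset {name!r}; expected one of {list(DATASET_PAIRS)}")
        conditions = DATASET_PAIRS[name]
    ia = epochs.condition_indices(conditions[0])
    ib = epochs.condition_indices(conditions[1])
    if len(ia) == 0 or len(ib) == 0:
        raise DegenerateInputError(f"empty class in pairing {conditions}")
    idx = np.concatenate([ia, ib])
    labels = np.concatenate([np.zeros(len(ia), int), np.ones(len(ib), int)])
    return DatasetPair(
        name=name, conditions=tuple(conditions),
        trials=epochs.task[idx], labels=labels,
        fs=epochs.fs, montage=epochs.montage,
    )


def filter_bank(
    data: np.ndarray, fs: float, bands: tuple[tuple[float, float], ...] = FILTER_BANK
) -> list[np.ndarray]:
    """Zero-phase band-pass copies of the epochs, one per sub-band."""
    if fs / 2 <= max(b[1] for b in bands):
        raise ConfigError(f"fs={fs} too low for the {max(b[1] for b in bands)} Hz band edge")
    return [bandpass_filter(data, b, fs) for b in bands]


def _class_covariance(trials: np.ndarray, shrinkage_tol: float = 1e10) -> np.ndarray:
    """Average of trace-normalized per-trial covariances, shrunk if ill-conditioned."""
    covs = np.einsum("tis,tjs->tij", trials, trials)
    traces = np.trace(covs, axis1=1, axis2=2)
    cov = (covs / traces[:, None, None]).mean(axis=0)
    if np.linalg.cond(cov) > shrinkage_tol:
        gamma = 1e-6
        cov = (1 - gamma) * cov + gamma * np.trace(cov) / cov.shape[0] * np.eye(cov.shape[0])
        log.warning("rank-deficient class covariance: shrinkage %.0e applied", gamma)
    return cov


@dataclass
class CSPFilters:
    """Spatial filters from the two-class covariance eigenproblem.

    ``eigenvalues`` solve C_a w = lambda (C_a + C_b) w and are sorted in
    descending order, so each lambda is class a's share of the variance
    along its filter and the class-b eigenvalue is 1 - lambda.
    ``filters`` keeps the first and last ``n_pairs`` rows (most
    discriminative for each class).
    """

    filters: np.ndarray  # (2 * n_pairs, n_channels)
    eigenvalues: np.ndarray  # (n_channels,), descending
    all_filters: np.ndarray  # (n_channels, n_channels), rows in eigenvalue order
    n_pairs: int


def csp_fit(class_a: np.ndarray, class_b: np.ndarray, n_pairs: int = 2) -> CSPFilters:
    """Fit CSP filters for two classes of (n_trials, n_ch, n_samples) epochs."""
    if class_a.shape[0] < 2 or class_b.shape[0] < 2:
        raise DegenerateInputError("CSP needs >= 2 trials per class")
    n_ch = class_a.shape[1]
    if 2 * n_pairs > n_ch:
        raise ConfigError(f"n_pairs={n_pairs} too large for {n_ch} channels")
    ca = _class_covariance(class_a)
    cb = _class_covariance(class_b)
    eigvals, eigvecs = linalg.eigh(ca, ca + cb)
    order = np.argsort(eigvals)[::-1]  # descending; ties keep channel order stable
    eigvals = eigvals[order]
    w = eigvecs[:, order].T  # rows are filters
    selected = np.vstack([w[:n_pairs], w[-n_pairs:]])
    return CSPFilters(filters=selected, eigenvalues=eigvals, all_filters=w, n_pairs=n_pairs)


def extract_features(filters: CSPFilters, data: np.ndarray) -> np.ndarray:
    """Log normalized-variance features of the spatially filtered epochs.

    Scale-invariant: multiplying an epoch by a constant leaves the
    features unchanged because variances are normalized to their sum
    over components before taking the log.
    """
    z = np.einsum("fc,tcs->tfs", filters.filters, data)
    var = z.var(axis=2)
    return np.log(var / var.sum(axis=1, keepdims=True))


def _freedman_diaconis_bins(x: np.ndarray) -> int:
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    if iqr <= 0 or np.ptp(x) == 0:
        return 1
    width = 2 * iqr / len(x) ** (1 / 3)
    return int(np.clip(np.ceil(np.ptp(x) / width), 2, 64))


def _mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Histogram MI between a continuous feature and a binary label.

    Bin count from the Freedman-Diaconis rule, bin edges at quantiles
    (equal-frequency), counts smoothed by nothing — empty cells simply
    contribute zero.
    """
    n_bins = _freedman_diaconis_bins(x)
    if n_bins < 2:
        return 0.0
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) < 3:
        return 0.0
    xb = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, len(edges) - 2)
    classes = np.unique(y)
    n = len(x)
    mi = 0.0
    for b in range(len(edges) - 1):
        px = np.mean(xb == b)
        if px == 0:
            continue
        for c in classes:
            pxy = np.mean((xb == b) & (y == c))
            if pxy == 0:
                continue
            py = np.mean(y == c)
            mi += pxy * np.log(pxy / (px * py))
    return float(max(mi, 0.0))


def mibif_select(features: np.ndarray, labels: np.ndarray, k: int = 8) -> np.ndarray:
    """Top-k feature indices by mutual information with the label.

    Ties break toward the lower index; exactly k indices are returned,
    in descending-MI order.
    """
    n_feat = features.shape[1]
    if k > n_feat:
        raise ConfigError(f"k={k} exceeds {n_feat} candidate features")
    mi = np.array([_mutual_information(features[:, j], labels) for j in range(n_feat)])
    order = np.lexsort((np.arange(n_feat), -mi))
    return order[:k]


class FBCSPClassifier(BaseEstimator, ClassifierMixin):
    """sklearn-style FBCSP + RBF-SVM estimator for (trials, channels, samples) X.

    Parameters
    ----------
    fs : sampling rate of the epochs, Hz.
    bands : filter-bank sub-bands.
    n_pairs : CSP filter pairs per band (2 pairs -> 4 components -> 24
        pooled candidate features over 6 bands).
    k : number of features kept by mutual-information selection.
    C_grid, gamma_grid : SVM hyperparameter search ranges.
    inner_folds : folds of the hyperparameter grid search.
    """

    def __init__(self, fs: float, bands=FILTER_BANK, n_pairs: int = 2, k: int = 8,
                 C_grid=DEFAULT_C_GRID, gamma_grid=DEFAULT_GAMMA_GRID,
                 inner_folds: int = 3, random_state: int | None = None):
        self.fs = fs
        self.bands = bands
        self.n_pairs = n_pairs
        self.k = k
        self.C_grid = C_grid
        self.gamma_grid = gamma_grid
        self.inner_folds = inner_folds
        self.random_state = random_state

    def _pooled_features(self, X: np.ndarray, fitted: bool) -> np.ndarray:
        banded = filter_bank(X, self.fs, self.bands)
        if not fitted:
            self.csp_: list[CSPFilters] = []
            for xb in banded:
                self.csp_.append(
                    csp_fit(xb[self._y01 == 0], xb[self._y01 == 1], self.n_pairs)
                )
        feats = [extract_features(c, xb) for c, xb in zip(self.csp_, banded)]
        return np.hstack(feats)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FBCSPClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ConfigError("FBCSP is a two-class method")
        self._y01 = (y == self.classes_[1]).astype(int)
        pooled = self._pooled_features(X, fitted=False)
        self.selected_ = mibif_select(pooled, self._y01, self.k)
        fsel = pooled[:, self.selected_]
        # order grids center-out so GridSearchCV's first-best tie-breaking
        # prefers the least extreme hyperparameters (C near 1, gamma near 1/k)
        def center_out(vals, center):
            return sorted(vals, key=lambda v: (abs(np.log2(v / center)), v))

        grid = {
            "svc__C": center_out(list(self.C_grid), 1.0),
            "svc__gamma": center_out(list(self.gamma_grid), 1.0 / max(self.k, 1)),
        }
        inner = StratifiedKFold(self.inner_folds, shuffle=True,
                                random_state=self.random_state)
        pipe = Pipeline([("scale", StandardScaler()), ("svc", SVC(kernel="rbf"))])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            search = GridSearchCV(pipe, grid, cv=inner, n_jobs=None)
            search.fit(fsel, self._y01)
        self.svm_ = search.best_estimator_
        self.best_params_ = {
            "C": search.best_params_["svc__C"],
            "gamma": search.best_params_["svc__gamma"],
        }
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        pooled = self._pooled_features(np.asarray(X, dtype=float), fitted=True)
        pred01 = self.svm_.predict(pooled[:, self.selected_])
        return self.classes_[pred01.astype(int)]


def compute_metrics(tp: int, fp: int, fn: int, tn: int) -> tuple[float, float]:
    """Accuracy and F1 score in %, from confusion counts.

    Acc = (TP + TN) / (TP + TN + FP + FN); F1 is the harmonic mean of
    precision and recall.  F1 is NaN (sentinel) when both precision and
    recall are undefined (TP + FP = 0 and TP + FN = 0).
    """
    counts = (tp, fp, fn, tn)
    if any(c < 0 for c in counts):
        raise ConfigError("negative confusion counts")
    total = sum(counts)
    if total == 0:
        raise ConfigError("empty confusion matrix")
    acc = (tp + tn) / total * 100.0
    if tp + fp == 0 and tp + fn == 0:
        return acc, float("nan")
    if tp == 0:
        return acc, 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return acc, 2 * precision * recall / (precision + recall) * 100.0


@dataclass
class EvalReport:
    """Cross-validated evaluation of one dataset pairing."""

    dataset: str
    confusion: dict[str, int]  # pooled over folds: tp, fp, fn, tn
    accuracy: float  # % from pooled confusion
    f1: float  # % from pooled confusion
    per_fold: list[dict] = field(default_factory=list)
    mean_fold_accuracy: float = float("nan")
    sd_fold_accuracy: float = float("nan")
    mean_fold_f1: float = float("nan")
    chosen_params: list[dict] = field(default_factory=list)
    selected_features: list[list[int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "dataset": self.dataset,
            "confusion": self.confusion,
            "accuracy_percent": self.accuracy,
            "f1_percent": self.f1,
            "per_fold": self.per_fold,
            "mean_fold_accuracy": self.mean_fold_accuracy,
            "sd_fold_accuracy": self.sd_fold_accuracy,
            "mean_fold_f1": self.mean_fold_f1,
            "chosen_params": self.chosen_params,
            "selected_features": self.selected_features,
        }


def train_eval_cv(
    pair: DatasetPair,
    folds: int = 5,
    rng_seed: int = 0,
    n_pairs: int = 2,
    k: int = 8,
    C_grid=DEFAULT_C_GRID,
    gamma_grid=DEFAULT_GAMMA_GRID,
    inner_folds: int = 3,
) -> EvalReport:
    """Stratified outer k-fold evaluation with nested hyperparameter search.

    All fitting — CSP filters, mutual-information selection and the SVM
    grid search — happens inside each training fold; the test fold only
    ever reaches ``predict``.  Headline accuracy and F1 come from the
    confusion counts pooled across folds; per-fold metrics (and their
    mean +/- SD) are reported alongside.
    """
    y = pair.labels
    n_min = min((y == c).sum() for c in np.unique(y))
    if folds > n_min:
        raise ConfigError(f"{folds} folds exceed the {n_min} trials of the smaller class")
    outer = StratifiedKFold(folds, shuffle=True, random_state=rng_seed % 2**31)
    tp = fp = fn = tn = 0
    per_fold, chosen, selected = [], [], []
    for fold_i, (tr, te) in enumerate(outer.split(pair.trials, y)):
        clf = FBCSPClassifier(
            fs=pair.fs, n_pairs=n_pairs, k=k, C_grid=C_grid,
            gamma_grid=gamma_grid, inner_folds=inner_folds,
            random_state=(rng_seed + fold_i) % 2**31,
        )
        clf.fit(pair.trials[tr], y[tr])
        pred = clf.predict(pair.trials[te])
        truth = y[te]
        ftp = int(((pred == 1) & (truth == 1)).sum())
        ffp = int(((pred == 1) & (truth == 0)).sum())
        ffn = int(((pred == 0) & (truth == 1)).sum())
        ftn = int(((pred == 0) & (truth == 0)).sum())
        tp, fp, fn, tn = tp + ftp, fp + ffp, fn + ffn, tn + ftn
        facc, ff1 = compute_metrics(ftp, ffp, ffn, ftn)
        per_fold.append({
            "fold": fold_i, "tp": ftp, "fp": ffp, "fn": ffn, "tn": ftn,
            "accuracy": facc, "f1": ff1,
        })
        chosen.append(clf.best_params_)
        selected.append([int(j) for j in clf.selected_])
    acc, f1 = compute_metrics(tp, fp, fn, tn)
    fold_accs = [f["accuracy"] for f in per_fold]
    fold_f1s = [f["f1"] for f in per_fold]
    return EvalReport(
        dataset=pair.name,
        confusion={"tp": tp, "fp": fp, "fn": fn, "tn": tn},
        accuracy=acc, f1=f1, per_fold=per_fold,
        mean_fold_accuracy=float(np.mean(fold_accs)),
        sd_fold_accuracy=float(np.std(fold_accs, ddof=1)),
        mean_fold_f1=float(np.nanmean(fold_f1s)),
        chosen_params=chosen, selected_features=selected,
    )
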