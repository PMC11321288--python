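"""Prognostic benchmark: clusters vs demographic, grading and supervised systems.

For each eligible visit the benchmark predicts time (in years) until the
eye's conversion to MNV, to cRORA, and to late AMD (the earlier of the
two), plus the current visual acuity in letters.  Four systems compete:
a demographic baseline (age + sex, ordinary least squares), the clinical
grading system (stage one-hot, Lasso), the cluster-similarity vectors
(Lasso with inner 5-fold CV penalty selection), and a fully supervised
linear support-vector regression directly on the feature space.
Evaluation uses patient-wise random 80/20 splits repeated 10 times;
the whole experiment, from clustering to regression, is repeated over
seeds and MAEs reported as mean +/- SD over folds x seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LassoCV, LinearRegression
from sklearn.svm import LinearSVR

from .annotation import GRADING_LABELS
from .clustering import kmeans_fit, order_clusters_by_va, similarity_matrix

SYSTEMS = ("demographic", "grading", "clusters", "fully_supervised")
TASKS = ("time_to_mnv", "time_to_crora", "time_to_late", "current_va")

__all__ = ["SYSTEMS", "TASKS", "build_outcomes", "make_folds", "fit_predict",
           "run_benchmark", "BenchmarkResult", "va_stratification",
           "lasso_support_recovery"]


def build_outcomes(visits: pd.DataFrame, conversions: pd.DataFrame) -> pd.DataFrame:
    """Per-visit outcome table with time-to-event targets in years.

    A visit enters a conversion task only if the eye's event of that
    type occurs strictly after the visit; eyes whose event precedes
    their first visit are dropped from that task with a warning.
    time_to_late is the minimum of the two event times where defined.
    """
    conv = conversions.set_index("eye_id")
    out = visits.copy()
    for task, col in [("time_to_mnv", "time_to_mnv"), ("time_to_crora", "time_to_crora")]:
        event = out["eye_id"].map(conv[col])
        t = event - out["visit_time"]
        first_visit = out.groupby("eye_id")["visit_time"].transform("min")
        bad_eye = (event - first_visit) <= 0
        if bad_eye.any():
            n = out.loc[bad_eye, "eye_id"].nunique()
            warnings.warn(f"{task}: {n} eye(s) converted before first visit; excluded")
        t = t.where((t > 0) & ~bad_eye)
        out[task] = t
    both = out[["time_to_mnv", "time_to_crora"]]
    out["time_to_late"] = both.min(axis=1)
    out["current_va"] = out["letters"]
    return out


def make_folds(patient_ids, n_folds: int = 10, seed: int = 0,
               test_frac: float = 0.2) -> list[tuple[set, set]]:
    """Independent patient-wise random 80/20 splits (one per fold)."""
    pids = np.unique(np.asarray(patient_ids))
    if pids.size < n_folds:
        raise ValueError("fewer patients than folds")
    rng = np.random.default_rng(seed)
    n_test = max(1, int(round(test_frac * pids.size)))
    folds = []
    for _ in range(n_folds):
        perm = rng.permutation(pids)
        folds.append((set(perm[n_test:]), set(perm[:n_test])))
    return folds


def _design(system: str, rows: pd.DataFrame, sim: np.ndarray | None,
            feats: np.ndarray | None) -> np.ndarray:
    if system == "demographic":
        sex01 = (rows["sex"].astype(str) == "F").astype(float)
        return np.column_stack([rows["age"].to_numpy(float), sex01])
    if system == "grading":
        onehot = np.zeros((len(rows), len(GRADING_LABELS)))
        for j, lab in enumerate(GRADING_LABELS):
            onehot[:, j] = (rows["grading_label"] == lab).to_numpy()
        return onehot
    idx = rows["image_index"].to_numpy()
    if system == "clusters":
        return sim[idx]
    if system == "fully_supervised":
        return feats[idx]
    raise ValueError(f"unknown system {system!r}")


def fit_predict(system: str, X_train: np.ndarray, y_train: np.ndarray,
                X_test: np.ndarray, seed: int = 0) -> np.ndarray:
    """Train the system's regressor and predict the test targets."""
    if np.ptp(y_train) == 0:
        warnings.warn("constant training target; predicting the train mean")
        return np.full(X_test.shape[0], float(y_train[0]) if len(y_train) else 0.0)
    if system == "demographic":
        model = LinearRegression()
    elif system in ("grading", "clusters"):
        model = LassoCV(cv=5, alphas=30, max_iter=5000, random_state=seed)
    elif system == "fully_supervised":
        model = LinearSVR(C=1.0, max_iter=5000, random_state=seed)
    else:
        raise ValueError(f"unknown system {system!r}")
    model.fit(X_train, y_train)
    pred = model.predict(X_test)
    if not np.all(np.isfinite(pred)):
        raise FloatingPointError("non-finite predictions")
    return pred


def mae(pred: np.ndarray, truth: np.ndarray) -> float:
    return float(np.mean(np.abs(np.asarray(pred) - np.asarray(truth))))


@dataclass
class BenchmarkResult:
    grid: pd.DataFrame        # seed, fold, task, system, mae, n_test
    summary: pd.DataFrame     # task x system MAE mean and SD over folds x seeds

    def pivot(self, stat: str = "mean") -> pd.DataFrame:
        return self.summary.pivot(index="system", columns="task", values=stat)


def run_benchmark(features: np.ndarray, outcomes: pd.DataFrame, *, k: int,
                  n_seeds: int = 7, n_folds: int = 10, seed0: int = 0,
                  systems=SYSTEMS, tasks=TASKS, min_rows: int = 30) -> BenchmarkResult:
    """Full protocol: per seed re-cluster, rebuild similarities, run all folds.

    ``features`` rows align with ``outcomes['image_index']``.  Patient
    disjointness between train and test is asserted in every fold.
    Tasks with fewer than ``min_rows`` eligible visits are skipped.
    """
    records = []
    for s in range(n_seeds):
        seed = seed0 + s
        model = kmeans_fit(features, k=k, seed=seed)
        letters = np.full(features.shape[0], np.nan)
        letters[outcomes["image_index"].to_numpy()] = outcomes["letters"].to_numpy()
        order_clusters_by_va(model, letters)
        sim = similarity_matrix(features, model)
        folds = make_folds(outcomes["patient_id"], n_folds=n_folds, seed=seed)
        for fi, (train_p, test_p) in enumerate(folds):
            assert not (train_p & test_p), "patient leakage between train and test"
            tr = outcomes[outcomes["patient_id"].isin(train_p)]
            te = outcomes[outcomes["patient_id"].isin(test_p)]
            for task in tasks:
                tr_t = tr.dropna(subset=[task])
                te_t = te.dropna(subset=[task])
                if len(tr_t) < min_rows or len(te_t) == 0:
                    warnings.warn(f"task {task}: too few eligible rows; skipped")
                    continue
                for system in systems:
                    Xtr = _design(system, tr_t, sim, features)
                    Xte = _design(system, te_t, sim, features)
                    pred = fit_predict(system, Xtr, tr_t[task].to_numpy(float),
                                       Xte, seed=seed)
                    records.append({"seed": seed, "fold": fi, "task": task,
                                    "system": system,
                                    "mae": mae(pred, te_t[task].to_numpy(float)),
                                    "n_test": len(te_t)})
    grid = pd.DataFrame(records)
    summary = (grid.groupby(["task", "system"])["mae"]
               .agg(mean="mean", sd="std").reset_index())
    return BenchmarkResult(grid=grid, summary=summary)


def va_stratification(assignments: np.ndarray, letters: np.ndarray) -> pd.DataFrame:
    """Per ordered cluster: mean letters with a normal-approximation 95% CI.

    Single-image clusters are flagged (CI undefined).
    """
    assignments = np.asarray(assignments)
    letters = np.asarray(letters, dtype=float)
    rows = []
    for c in np.unique(assignments):
        vals = letters[assignments == c]
        vals = vals[np.isfinite(vals)]
        n = vals.size
        m = float(vals.mean()) if n else np.nan
        if n >= 2:
            se = vals.std(ddof=1) / np.sqrt(n)
            lo, hi = m - 1.96 * se, m + 1.96 * se
            flag = False
        else:
            lo = hi = np.nan
            flag = True
        rows.append({"cluster": int(c), "n": n, "mean": m,
                     "ci_lo": lo, "ci_hi": hi, "flagged": flag})
    return pd.DataFrame(rows)


def lasso_support_recovery(n: int = 1000, k: int = 30, support=(2, 7, 11),
                           snr: float = 5.0, n_reps: int = 20,
                           seed: int = 0) -> float:
    """Fraction of replicates in which inner-CV Lasso recovers the true support.

    Targets are linear in a sparse subset of similarity-style simplex
    features (Dirichlet rows) with Gaussian noise at the given SNR
    (variance ratio); success means the selected support is a superset
    of the true one.
    """
    rng = np.random.default_rng(seed)
    support = tuple(support)
    hits = 0
    for rep in range(n_reps):
        X = rng.dirichlet(np.full(k, 0.5), size=n)
        beta = np.zeros(k)
        beta[list(support)] = rng.uniform(3.0, 6.0, size=len(support)) * \
            rng.choice([-1.0, 1.0], size=len(support))
        y0 = X @ beta
        noise_sd = y0.std() / np.sqrt(snr)
        y = y0 + rng.normal(0, noise_sd, size=n)
        model = LassoCV(cv=5, alphas=30, max_iter=5000,
                        random_state=int(rng.integers(2**31)))
        model.fit(X, y)
        selected = set(np.flatnonzero(np.abs(model.coef_) > 1e-8))
        if set(support) <= selected:
            hits += 1
    return hits / n_reps
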