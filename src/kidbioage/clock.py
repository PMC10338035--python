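"""Sparse elastic-net age clocks: hyperparameter line search, Δ age, validation.

Training follows the glmnet-style recipe: the mixing parameter α is line-
searched over {0.0, 0.1, …, 1.0}; for each α a descending λ path is scored
by K-fold cross-validated mean squared error; the (α, λ) pair with the
minimum CV MSE (ties broken toward larger λ, then larger α — the sparser
model) is refit on all data. The objective matches the glmnet/scikit-learn
convention::

    (1/2n)·||y − Xβ − β₀||² + λ·(α·||β||₁ + (1−α)/2·||β||²)

with the intercept unpenalized and no internal re-standardization (features
are expected to be pre-scaled once, by the preprocessing stage).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet

ALPHA_GRID = tuple(round(0.1 * k, 1) for k in range(11))


class ClockError(ValueError):
    pass


@dataclass
class ClockModel:
    """A fitted sparse linear age predictor."""

    weights: pd.Series  # full coefficient vector over training features
    intercept: float
    alpha: float  # L1/L2 mixing parameter
    lam: float  # penalty strength
    feature_names: list[str]
    block_composition: dict[str, int] = field(default_factory=dict)
    cv_mse_path: pd.DataFrame | None = None  # columns alpha, lam, cv_mse
    fold_assignments: np.ndarray | None = None

    @property
    def nonzero_features(self) -> list[str]:
        return list(self.weights.index[self.weights != 0.0])

    def to_json(self, path: str | Path) -> None:
        nz = self.weights[self.weights != 0.0]
        payload = {
            "weights": {str(k): float(v) for k, v in nz.items()},
            "intercept": self.intercept,
            "alpha": self.alpha,
            "lambda": self.lam,
            "feature_names": self.feature_names,
            "block_composition": self.block_composition,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClockModel":
        d = json.loads(Path(path).read_text())
        weights = pd.Series(0.0, index=pd.Index(d["feature_names"]))
        for k, v in d["weights"].items():
            weights[k] = v
        return cls(
            weights=weights,
            intercept=d["intercept"],
            alpha=d["alpha"],
            lam=d["lambda"],
            feature_names=d["feature_names"],
            block_composition=d.get("block_composition", {}),
        )


@dataclass
class ClockValidation:
    pearson_r: float
    r_p_value: float
    mae: float
    n: int
    per_group: dict[str, tuple[float, float]] = field(default_factory=dict)
    constant_predictions: bool = False


@dataclass
class ProgressionStats:
    mean_increase: float
    sd: float
    t: float
    one_sided_p: float
    n_pairs: int


def age_stratified_folds(ages: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Fold assignment stratified by age decile, to stabilize CV MSE."""
    rng = np.random.default_rng(seed)
    n = len(ages)
    order = np.argsort(ages, kind="stable")
    assignment = np.empty(n, dtype=int)
    # walk the age ordering in blocks of `folds`, permuting fold labels per block
    for start in range(0, n, folds):
        block = order[start : start + folds]
        labels = rng.permutation(folds)[: len(block)]
        assignment[block] = labels
    return assignment


def lambda_path(X: np.ndarray, y: np.ndarray, alpha: float, n_lambdas: int = 30, min_ratio: float = 1e-3) -> np.ndarray:
    """Descending log-spaced λ grid starting at the smallest λ that zeroes
    every coefficient (glmnet's λ_max), with α floored for the ridge end."""
    n = len(y)
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    lam_max = np.max(np.abs(Xc.T @ yc)) / (n * max(alpha, 1e-3))
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambdas)


def _fit_path(Xtr, ytr, Xval, yval, alpha: float, lams: np.ndarray) -> np.ndarray:
    """Validation MSE along a descending λ path for one α and one fold."""
    mses = np.empty(len(lams))
    if alpha == 0.0:
        # closed-form ridge along the whole path via one SVD
        xm, ym = Xtr.mean(axis=0), ytr.mean()
        U, s, Vt = np.linalg.svd(Xtr - xm, full_matrices=False)
        uty = U.T @ (ytr - ym)
        n = len(ytr)
        for i, lam in enumerate(lams):
            d = s / (s**2 + n * lam)
            beta = Vt.T @ (d * uty)
            pred = (Xval - xm) @ beta + ym
            mses[i] = np.mean((yval - pred) ** 2)
        return mses
    model = ElasticNet(l1_ratio=alpha, fit_intercept=True, warm_start=True, max_iter=5000)
    for i, lam in enumerate(lams):
        model.set_params(alpha=lam)
        model.fit(Xtr, ytr)
        pred = model.predict(Xval)
        mses[i] = np.mean((yval - pred) ** 2)
    return mses


def _fit_final(X, y, alpha: float, lam: float) -> tuple[np.ndarray, float]:
    if alpha == 0.0:
        xm, ym = X.mean(axis=0), y.mean()
        U, s, Vt = np.linalg.svd(X - xm, full_matrices=False)
        n = len(y)
        beta = Vt.T @ ((s / (s**2 + n * lam)) * (U.T @ (y - ym)))
        return beta, float(ym - xm @ beta)
    model = ElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=True, max_iter=50000)
    model.fit(X, y)
    return model.coef_.copy(), float(model.intercept_)


def tune_and_fit(
    blocks: list,
    ages,
    folds: int = 10,
    seed: int = 0,
    alphas: tuple = ALPHA_GRID,
    n_lambdas: int = 30,
) -> ClockModel:
    """Line-search (α, λ) by K-fold CV MSE and refit at the optimum.

    ``blocks`` is a list of scaled :class:`~kidbioage.preprocess.OmicsBlock`
    (or bare DataFrames) sharing sample order; they are concatenated
    column-wise. Ties on CV MSE break toward larger λ, then larger α.
    """
    frames, block_of = [], {}
    for b in blocks:
        df = b.values if hasattr(b, "values") and isinstance(getattr(b, "values"), pd.DataFrame) else b
        label = df.columns[0].rsplit("_f", 1)[0] if len(df.columns) else "block"
        if hasattr(b, "feature_meta") and "block" in b.feature_meta.columns:
            labels = b.feature_meta.loc[df.columns, "block"]
        else:
            labels = pd.Series(label, index=df.columns)
        for f in df.columns:
            block_of[f] = str(labels[f])
        frames.append(df)
    Xdf = pd.concat(frames, axis=1)
    if Xdf.columns.has_duplicates:
        raise ClockError("duplicate feature names across blocks")
    X = Xdf.to_numpy(dtype=float)
    y = np.asarray(ages, dtype=float)
    if len(y) != X.shape[0]:
        raise ClockError("ages length does not match sample count")
    if not np.isfinite(X).all():
        bad = Xdf.columns[~np.isfinite(X).all(axis=0)].tolist()
        raise ClockError(f"non-finite values in features: {bad[:5]}")
    if not np.isfinite(y).all():
        raise ClockError("non-finite ages")
    n = len(y)
    if n < folds:
        raise ClockError(f"n={n} is smaller than the number of folds ({folds})")

    fold_id = age_stratified_folds(y, folds, seed)
    records = []
    for alpha in alphas:
        lams = lambda_path(X, y, alpha, n_lambdas=n_lambdas)
        fold_mses = np.zeros((folds, len(lams)))
        for k in range(folds):
            tr, va = fold_id != k, fold_id == k
            fold_mses[k] = _fit_path(X[tr], y[tr], X[va], y[va], alpha, lams)
        weights = np.array([(fold_id == k).sum() for k in range(folds)], dtype=float) / n
        cv_mse = weights @ fold_mses
        for lam, mse in zip(lams, cv_mse):
            records.append((alpha, float(lam), float(mse)))
    path = pd.DataFrame(records, columns=["alpha", "lam", "cv_mse"])
    alpha_best, lam_best = select_optimum(path)

    beta, intercept = _fit_final(X, y, alpha_best, lam_best)
    weights = pd.Series(beta, index=Xdf.columns)
    comp: dict[str, int] = {}
    for f in weights.index[weights != 0.0]:
        comp[block_of[f]] = comp.get(block_of[f], 0) + 1
    return ClockModel(
        weights=weights,
        intercept=intercept,
        alpha=float(alpha_best),
        lam=float(lam_best),
        feature_names=list(Xdf.columns),
        block_composition=comp,
        cv_mse_path=path,
        fold_assignments=fold_id,
    )


def select_optimum(path: pd.DataFrame) -> tuple[float, float]:
    """Arg-min of CV MSE; ties break toward larger λ then larger α."""
    best = path.sort_values(["cv_mse", "lam", "alpha"], ascending=[True, False, False]).iloc[0]
    return float(best["alpha"]), float(best["lam"])


def predict_ages(model: ClockModel, block_values: pd.DataFrame, chronological_ages) -> pd.DataFrame:
    """Predicted age and Δ age (predicted − chronological) per sample.

    ``block_values`` must already carry the *training* scaling. Features the
    model was trained on must all be present — missing features raise.
    """
    missing = [f for f in model.feature_names if f not in block_values.columns]
    if missing:
        raise ClockError(f"input lacks model features: {missing[:10]}")
    X = block_values[model.feature_names].to_numpy(dtype=float)
    predicted = model.intercept + X @ model.weights.to_numpy()
    ages = np.asarray(chronological_ages, dtype=float)
    return pd.DataFrame(
        {
            "predicted_age": predicted,
            "chronological_age": ages,
            "delta_age": predicted - ages,
        },
        index=block_values.index,
    )


def validate(
    model: ClockModel,
    test_blocks: list,
    test_ages,
    groups: pd.Series | None = None,
) -> ClockValidation:
    """Test-set Pearson r and MAE, plus per-group correlations.

    Test samples must be disjoint from training (caller-asserted).
    """
    frames = [b.values if hasattr(b, "feature_meta") else b for b in test_blocks]
    Xdf = pd.concat(frames, axis=1)
    ages = np.asarray(test_ages, dtype=float)
    if len(ages) < 3:
        raise ClockError("need at least 3 test samples")
    preds = predict_ages(model, Xdf, ages)
    p = preds["predicted_age"].to_numpy()
    if np.ptp(p) == 0.0:
        return ClockValidation(
            pearson_r=float("nan"), r_p_value=float("nan"), mae=float(np.mean(np.abs(p - ages))),
            n=len(ages), constant_predictions=True,
        )
    r, pv = stats.pearsonr(p, ages)
    per_group: dict[str, tuple[float, float]] = {}
    if groups is not None:
        groups = pd.Series(np.asarray(groups), index=Xdf.index)
        for g, idx in groups.groupby(groups).groups.items():
            sub = preds.loc[idx]
            if len(sub) >= 3 and np.ptp(sub["predicted_age"].to_numpy()) > 0:
                gr, gp = stats.pearsonr(sub["predicted_age"], sub["chronological_age"])
                per_group[str(g)] = (float(gr), float(gp))
    return ClockValidation(
        pearson_r=float(r),
        r_p_value=float(pv),
        mae=float(np.mean(np.abs(p - ages))),
        n=len(ages),
        per_group=per_group,
    )


def progression_test(first_visit: pd.DataFrame, second_visit: pd.DataFrame) -> ProgressionStats:
    """Paired one-tailed t-test that predicted age increased between visits.

    Inputs are prediction frames from :func:`predict_ages`, paired on index.
    Alternative hypothesis: mean(second − first) > 0.
    """
    common = first_visit.index.intersection(second_visit.index)
    if len(common) < 2:
        raise ClockError("need at least 2 paired samples for the progression test")
    diffs = (second_visit.loc[common, "predicted_age"] - first_visit.loc[common, "predicted_age"]).to_numpy()
    sd = float(np.std(diffs, ddof=1))
    if sd == 0.0:
        raise ClockError("zero-variance paired differences: progression test degenerate")
    res = stats.ttest_1samp(diffs, 0.0, alternative="greater")
    return ProgressionStats(
        mean_increase=float(np.mean(diffs)),
        sd=sd,
        t=float(res.statistic),
        one_sided_p=float(res.pvalue),
        n_pairs=len(diffs),
    )
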