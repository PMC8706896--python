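"""Ripening trend analysis: PCA, PLS vs soluble solids, resampling checks.

The lipid concentration matrix (samples x compounds, post-imputation) is
log-transformed, then either unit-variance or Pareto scaled.  A PLS
regression predicts the per-sample sugar content (degrees Brix, the
ripeness proxy); its component count comes from 10-fold cross-validation
with a one-standard-error tie-break toward parsimony.  Predictive power
is summarized by the median Q2 (1 - PRESS/TSS on a held-out third) over
repeated random 2/3-1/3 splits, against a label-permutation null.  At
the class level, compounds whose coefficients fall below the first or
above the fourth quartile of the coefficient distribution mark classes
that globally decrease or increase with ripening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

__all__ = [
    "pareto_pca",
    "PCAResult",
    "PLSResult",
    "select_components",
    "fit_pls",
    "q2_resampling",
    "permutation_null",
    "quartile_class_summary",
    "analyze_ripening",
]


def log_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Natural log of a strictly positive concentration matrix."""
    if (matrix <= 0).any().any() or matrix.isna().any().any():
        raise ValueError(
            "log transform needs strictly positive, complete values "
            "(impute missing values first)"
        )
    return np.log(matrix)


def _drop_zero_variance(matrix: pd.DataFrame) -> pd.DataFrame:
    sd = matrix.std(ddof=1)
    dead = sd[sd == 0].index
    if len(dead):
        warnings.warn(
            f"dropping {len(dead)} zero-variance compound(s): "
            f"{list(dead[:5])}{'...' if len(dead) > 5 else ''}"
        )
        matrix = matrix.drop(columns=dead)
    return matrix


@dataclass(frozen=True)
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray


def pareto_pca(matrix: pd.DataFrame, *, log: bool = True) -> PCAResult:
    """PCA on (log-transformed,) Pareto-scaled data via SVD.

    Pareto scaling centers each compound and divides by the square root
    of its standard deviation, damping the dominance of high-abundance
    compounds without flattening the variance structure entirely.
    """
    if matrix.shape[0] < 3:
        raise ValueError("PCA needs at least 3 samples")
    X = log_transform(matrix) if log else matrix.copy()
    X = _drop_zero_variance(X)
    centered = X - X.mean(axis=0)
    scaled = centered / np.sqrt(X.std(ddof=1, axis=0))
    u, s, vt = np.linalg.svd(scaled.to_numpy(), full_matrices=False)
    var = s**2
    ratio = var / var.sum()
    n = len(s)
    pcs = [f"PC{i + 1}" for i in range(n)]
    scores = pd.DataFrame(u * s, index=X.index, columns=pcs)
    loadings = pd.DataFrame(vt.T, index=X.columns, columns=pcs)
    return PCAResult(scores, loadings, ratio)


class _ParetoPLS:
    """PLS on Pareto-scaled predictors (scale factor fit on training data)."""

    def __init__(self, n_components: int):
        self.n_components = n_components

    def fit(self, X, y):
        sd = np.asarray(X).std(axis=0, ddof=1)
        self._scale = np.sqrt(np.where(sd > 0, sd, 1.0))
        self._pls = PLSRegression(n_components=self.n_components, scale=False)
        self._pls.fit(np.asarray(X) / self._scale, y)
        return self

    def predict(self, X):
        return self._pls.predict(np.asarray(X) / self._scale)

    @property
    def coef_(self):
        return self._pls.coef_ / self._scale


def _make_model(n_components: int, scaling: str):
    if scaling == "uv":
        return PLSRegression(n_components=n_components, scale=True)
    if scaling == "pareto":
        return _ParetoPLS(n_components)
    raise ValueError(f"unknown scaling {scaling!r} (use 'uv' or 'pareto')")


def select_components(
    X: np.ndarray,
    y: np.ndarray,
    *,
    max_components: int = 10,
    folds: int = 10,
    seed: int = 0,
    scaling: str = "uv",
) -> tuple[int, np.ndarray, np.ndarray]:
    """Cross-validated component count with a one-SE parsimony tie-break.

    Returns (n_components, mean RMSEP per count, its standard error).
    """
    n_samples, n_features = X.shape
    cap = min(max_components, n_samples - 2, n_features)
    if cap < 1:
        raise ValueError("not enough samples/features for even one component")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    rmsep = np.zeros((cap, folds))
    for k, (train, test) in enumerate(splits):
        for a in range(1, cap + 1):
            model = _make_model(a, scaling).fit(X[train], y[train])
            pred = np.ravel(model.predict(X[test]))
            rmsep[a - 1, k] = np.sqrt(np.mean((y[test] - pred) ** 2))
    mean = rmsep.mean(axis=1)
    se = rmsep.std(axis=1, ddof=1) / np.sqrt(folds)
    best = int(np.argmin(mean))
    threshold = mean[best] + se[best]
    chosen = int(np.nonzero(mean <= threshold)[0][0]) + 1
    return chosen, mean, se


@dataclass
class PLSResult:
    n_components: int
    coefficients: pd.Series  # per compound, on standardized predictors
    r2: float
    scaling: str
    rmsep: np.ndarray = field(default=None, repr=False)
    q2_distribution: np.ndarray | None = field(default=None, repr=False)
    q2_median: float | None = None
    permutation_q2: np.ndarray | None = field(default=None, repr=False)
    permutation_q2_median: float | None = None
    quartile_thresholds: tuple[float, float] | None = None
    class_summary: pd.DataFrame | None = None


def _prepare(matrix: pd.DataFrame, log: bool) -> pd.DataFrame:
    X = log_transform(matrix) if log else matrix.copy()
    return _drop_zero_variance(X)


def fit_pls(
    matrix: pd.DataFrame,
    brix: pd.Series,
    *,
    folds: int = 10,
    max_components: int = 10,
    seed: int = 0,
    scaling: str = "uv",
    log: bool = True,
    n_components: int | None = None,
) -> PLSResult:
    """Fit the Brix PLS model with CV-selected component count.

    Coefficients are reported on the standardized predictor scale so
    they are comparable across compounds (the scale the class-quartile
    summary operates on).
    """
    X = _prepare(matrix, log)
    y = brix.loc[X.index].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("Brix values must be finite")
    Xv = X.to_numpy()
    if n_components is None:
        n_components, rmsep, _ = select_components(
            Xv, y, max_components=max_components, folds=min(folds, len(y)),
            seed=seed, scaling=scaling,
        )
    else:
        cap = min(len(y) - 2, Xv.shape[1])
        if n_components > cap:
            raise ValueError(
                f"{n_components} components exceed what the data rank permits ({cap})"
            )
        rmsep = None
    model = _make_model(n_components, scaling).fit(Xv, y)
    pred = np.ravel(model.predict(Xv))
    r2 = 1.0 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2)
    # put coefficients on the standardized-predictor scale
    raw = np.ravel(model.coef_)
    sd = Xv.std(axis=0, ddof=1)
    scale = sd if scaling == "uv" else np.sqrt(sd)
    coefs = pd.Series(raw * scale, index=X.columns, name="coefficient")
    return PLSResult(
        n_components=n_components, coefficients=coefs, r2=float(r2),
        scaling=scaling, rmsep=rmsep,
    )


def _q2(y_test: np.ndarray, pred: np.ndarray, y_train_mean: float) -> float:
    press = np.sum((y_test - pred) ** 2)
    tss = np.sum((y_test - y_train_mean) ** 2)
    return 1.0 - press / tss


def q2_resampling(
    matrix: pd.DataFrame,
    brix: pd.Series,
    n_components: int,
    *,
    n: int = 1000,
    train_frac: float = 2 / 3,
    seed: int = 0,
    scaling: str = "uv",
    log: bool = True,
    permute: bool = False,
) -> tuple[np.ndarray, float]:
    """Q2 over repeated random train/test splits (2/3 vs 1/3 by default).

    Returns the Q2 distribution (NaN for skipped degenerate splits where
    the training response is constant) and the median over valid splits.
    With ``permute=True`` the response is independently permuted each
    iteration, giving the label-permutation null.
    """
    if n < 1:
        raise ValueError("need at least one split")
    X = _prepare(matrix, log)
    y = brix.loc[X.index].to_numpy(dtype=float)
    Xv = X.to_numpy()
    rng = np.random.default_rng(seed)
    n_samples = len(y)
    if n_samples < 6:
        raise ValueError("resampling validation needs at least 6 samples")
    n_train = int(round(train_frac * n_samples))
    q2s = np.full(n, np.nan)
    for i in range(n):
        yy = rng.permutation(y) if permute else y
        order = rng.permutation(n_samples)
        train, test = order[:n_train], order[n_train:]
        if np.ptp(yy[train]) == 0:
            continue  # degenerate split: skipped, stays NaN
        model = _make_model(n_components, scaling).fit(Xv[train], yy[train])
        pred = np.ravel(model.predict(Xv[test]))
        q2s[i] = _q2(yy[test], pred, yy[train].mean())
    return q2s, float(np.nanmedian(q2s))


def permutation_null(
    matrix: pd.DataFrame,
    brix: pd.Series,
    n_components: int | None = None,
    *,
    n: int = 1000,
    seed: int = 0,
    scaling: str = "uv",
    log: bool = True,
    reselect_components: bool = False,
    folds: int = 10,
) -> tuple[np.ndarray, float]:
    """Label-permutation Q2 null distribution and its median.

    By default the component count of the observed-data model is reused
    for every permuted fit; ``reselect_components=True`` repeats the
    cross-validated selection inside each permutation instead.
    """
    if n < 1:
        raise ValueError("need at least one permutation")
    if not reselect_components:
        if n_components is None:
            raise ValueError("n_components required unless reselect_components")
        return q2_resampling(
            matrix, brix, n_components, n=n, seed=seed, scaling=scaling,
            log=log, permute=True,
        )
    X = _prepare(matrix, log)
    y = brix.loc[X.index].to_numpy(dtype=float)
    Xv = X.to_numpy()
    rng = np.random.default_rng(seed)
    n_samples = len(y)
    n_train = int(round(2 / 3 * n_samples))
    q2s = np.full(n, np.nan)
    for i in range(n):
        yy = rng.permutation(y)
        order = rng.permutation(n_samples)
        train, test = order[:n_train], order[n_train:]
        if np.ptp(yy[train]) == 0:
            continue
        a, _, _ = select_components(
            Xv[train], yy[train], folds=min(folds, n_train),
            seed=int(rng.integers(2**31 - 1)), scaling=scaling,
        )
        model = _make_model(a, scaling).fit(Xv[train], yy[train])
        pred = np.ravel(model.predict(Xv[test]))
        q2s[i] = _q2(yy[test], pred, yy[train].mean())
    return q2s, float(np.nanmedian(q2s))


def quartile_class_summary(
    coefficients: pd.Series, classes: pd.Series | dict
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Per-class fractions of compounds in the coefficient Q1/Q4 tails.

    Thresholds are the 25th/75th percentiles (linear interpolation) of
    all coefficients; membership is strict (< Q1 threshold, > Q4
    threshold), so a degenerate all-equal distribution yields zero
    fractions everywhere.
    """
    classes = pd.Series(classes)
    labels = classes.reindex(coefficients.index)
    if labels.isna().any():
        missing = coefficients.index[labels.isna()].tolist()[:5]
        raise KeyError(f"no class label for compounds {missing}")
    q1, q4 = np.percentile(coefficients.to_numpy(), [25, 75])
    df = pd.DataFrame({"coefficient": coefficients, "lipid_class": labels})
    rows = []
    for cls, sub in df.groupby("lipid_class"):
        n = len(sub)
        n_q1 = int((sub["coefficient"] < q1).sum())
        n_q4 = int((sub["coefficient"] > q4).sum())
        rows.append(
            {
                "lipid_class": cls,
                "n": n,
                "n_q1": n_q1,
                "frac_q1": n_q1 / n,
                "n_q4": n_q4,
                "frac_q4": n_q4 / n,
                "median_coefficient": float(sub["coefficient"].median()),
            }
        )
    summary = pd.DataFrame(rows).set_index("lipid_class").sort_index()
    return summary, (float(q1), float(q4))


def analyze_ripening(
    matrix: pd.DataFrame,
    brix: pd.Series,
    classes: pd.Series | dict,
    *,
    seed: int = 0,
    n_splits: int = 1000,
    n_permutations: int = 1000,
    folds: int = 10,
    scaling: str = "uv",
    log: bool = True,
) -> PLSResult:
    """Full pipeline: fit, repeated-split Q2, permutation null, quartiles."""
    result = fit_pls(
        matrix, brix, folds=folds, seed=seed, scaling=scaling, log=log
    )
    dist, med = q2_resampling(
        matrix, brix, result.n_components, n=n_splits, seed=seed,
        scaling=scaling, log=log,
    )
    result.q2_distribution, result.q2_median = dist, med
    pdist, pmed = permutation_null(
        matrix, brix, result.n_components, n=n_permutations, seed=seed + 1,
        scaling=scaling, log=log,
    )
    result.permutation_q2, result.permutation_q2_median = pdist, pmed
    summary, thresholds = quartile_class_summary(result.coefficients, classes)
    result.class_summary, result.quartile_thresholds = summary, thresholds
    return result
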