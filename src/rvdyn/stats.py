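"""Diagnostic statistics: group tests, mixed logistic models, ROC, CART.

The diagnostic layer mirrors how dynamic conduction/repolarization
features are turned into group-level evidence:

* pairwise Welch t-tests with Holm correction for single-value-per-patient
  metrics;
* a mixed-effects logistic regression (single Gaussian random intercept,
  Laplace-approximated maximum likelihood) for electrode-level predictors,
  with a shipped reference coefficient fixture so the previously reported
  diagnostic model can be applied without refitting;
* ROC curves / AUC for model scores;
* CART recursive partitioning (greedy Gini splits on threshold midpoints)
  to derive interpretable diagnostic cut-offs from paced-ECG hysteresis
  features.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sstats
from sklearn.metrics import auc as _sk_auc, roc_curve as _sk_roc_curve
from statsmodels.stats.multitest import multipletests


@dataclass
class LogisticModel:
    """Logit-link model: fixed coefficients plus a random-intercept SD.

    ``coefficients`` maps covariate names to estimates and must contain an
    ``intercept`` entry.  Prediction uses the fixed effects only unless a
    group-level intercept is supplied.
    """

    coefficients: dict[str, float]
    random_intercept_sd: float = 0.0
    std_errors: dict[str, float] = field(default_factory=dict)
    converged: bool = True

    def covariates(self) -> list[str]:
        return [k for k in self.coefficients if k != "intercept"]


#: Reference mixed-effects logistic coefficients for discriminating early
#: (definite) ARVC from benign RVOT ectopy on endocardial features, as
#: reported by the clinical high-density-mapping study this package's
#: methods follow.  Shipped verbatim as a fixture (the original electrogram
#: data are not public, so the model is applied, never refit, here).  The
#: reported random-intercept (location) SD was 0.26+-0.51.
REFERENCE_DIAGNOSTIC_MODEL = LogisticModel(
    coefficients={
        "intercept": 3.57,
        "delta_at_preverp_ms": -0.03,
        "frac_sinus": 0.37,
        "frac_preverp": 0.40,
        "sinus_rt_ms": -0.01,
        "steady_at_ms": -0.05,
    },
    random_intercept_sd=0.26,
    std_errors={"intercept": 0.78, "delta_at_preverp_ms": 0.01,
                "frac_sinus": 0.06, "frac_preverp": 0.08,
                "sinus_rt_ms": 0.00, "steady_at_ms": 0.00},
)


def predict_logistic(model: LogisticModel, x: Mapping[str, float],
                     group_intercept: float = 0.0) -> float:
    """p = logistic(intercept + sum_i beta_i x_i [+ group intercept]).

    Raises ``KeyError`` naming the first covariate missing from ``x``.
    """
    lp = model.coefficients.get("intercept", 0.0) + group_intercept
    for name in model.covariates():
        if name not in x:
            raise KeyError(f"missing covariate {name!r}")
        lp += model.coefficients[name] * float(x[name])
    return float(1.0 / (1.0 + np.exp(-lp)))


# ---------------------------------------------------------------------------
# Mixed-effects logistic regression (Laplace approximation)


def _laplace_nll(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
                 gidx: np.ndarray, n_groups: int, fit_random: bool,
                 ridge: float) -> float:
    """Negative Laplace-approximated marginal log-likelihood."""
    beta = theta[:-1] if fit_random else theta
    sigma2 = float(np.exp(2 * theta[-1])) if fit_random else 0.0
    eta0 = X @ beta
    if sigma2 < 1e-10:
        p = 1.0 / (1.0 + np.exp(-eta0))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        ll = float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))
        return -ll + ridge * float(beta @ beta)
    u = np.zeros(n_groups)
    for _ in range(25):
        p = 1.0 / (1.0 + np.exp(-(eta0 + u[gidx])))
        grad = np.bincount(gidx, weights=y - p,
                           minlength=n_groups) - u / sigma2
        hess = np.bincount(gidx, weights=p * (1 - p),
                           minlength=n_groups) + 1.0 / sigma2
        step = grad / hess
        u = u + step
        if np.max(np.abs(step)) < 1e-10:
            break
    p = 1.0 / (1.0 + np.exp(-(eta0 + u[gidx])))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    ll_data = float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))
    hess = np.bincount(gidx, weights=p * (1 - p),
                       minlength=n_groups) + 1.0 / sigma2
    ll = (ll_data - float(np.sum(u ** 2)) / (2 * sigma2)
          - 0.5 * n_groups * np.log(sigma2)
          - 0.5 * float(np.sum(np.log(hess))))
    return -ll + ridge * float(beta @ beta)


def _numeric_hessian(f, x0: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = x0.size
    h = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            fpp = f(x0 + ei + ej)
            fpm = f(x0 + ei - ej)
            fmp = f(x0 - ei + ej)
            fmm = f(x0 - ei - ej)
            h[i, j] = h[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps * eps)
    return h


def fit_mixed_logistic(features: pd.DataFrame, outcome, random_grouping,
                       covariates: Sequence[str] | None = None,
                       fit_random: bool = True,
                       stepwise: bool = False,
                       ridge: float = 1e-6) -> LogisticModel:
    """Fit a random-intercept logistic model by Laplace-approximated ML.

    ``features`` holds the covariate columns; ``outcome`` is a binary
    vector (or column name); ``random_grouping`` assigns each row to a
    grouping unit (or column name).  With ``fit_random=False`` the
    random-intercept variance is fixed at 0 and the fit reduces to
    ordinary logistic regression.  ``stepwise=True`` applies backward
    elimination by AIC starting from all covariates.  Quasi-separated fits
    are reported with a warning and refit under a stronger ridge penalty.
    """
    if isinstance(outcome, str):
        outcome = features[outcome]
    if isinstance(random_grouping, str):
        random_grouping = features[random_grouping]
    y = np.asarray(outcome, dtype=float)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("outcome must contain at least two classes")
    if covariates is None:
        covariates = [c for c in features.columns
                      if features[c].dtype.kind in "if"]
    groups, gidx = np.unique(np.asarray(random_grouping),
                             return_inverse=True)

    def fit(cols: list[str], ridge_: float):
        X = np.column_stack([np.ones(len(features))]
                            + [np.asarray(features[c], dtype=float)
                               for c in cols])
        scale = np.maximum(np.abs(X).max(axis=0), 1e-12)
        Xs = X / scale
        k = X.shape[1]
        x0 = np.zeros(k + 1) if fit_random else np.zeros(k)
        if fit_random:
            x0[-1] = np.log(0.5)
        obj = lambda th: _laplace_nll(th, Xs, y, gidx, groups.size,
                                      fit_random, ridge_)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(obj, x0, method="BFGS",
                                    options={"maxiter": 500, "gtol": 1e-7})
        beta = (res.x[:-1] if fit_random else res.x) / scale
        sigma = float(np.exp(res.x[-1])) if fit_random else 0.0
        nll = float(res.fun)
        n_par = k + (1 if fit_random else 0)
        se = np.full(k, np.nan)
        try:
            H = _numeric_hessian(obj, res.x)
            cov = np.linalg.inv(H)
            se_s = np.sqrt(np.clip(np.diag(cov)[:k], 0, None))
            se = se_s / scale
        except np.linalg.LinAlgError:
            pass
        return beta, sigma, se, nll, 2 * nll + 2 * n_par, res.success

    cols = list(covariates)
    beta, sigma, se, nll, aic, ok = fit(cols, ridge)
    if stepwise:
        improved = True
        while improved and cols:
            improved = False
            best = (aic, None)
            for c in cols:
                sub = [x for x in cols if x != c]
                *_, aic_c, _ = fit(sub, ridge)
                if aic_c < best[0] - 1e-9:
                    best = (aic_c, c)
            if best[1] is not None:
                cols = [x for x in cols if x != best[1]]
                beta, sigma, se, nll, aic, ok = fit(cols, ridge)
                improved = True
    if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 25:
        warnings.warn("possible separation: coefficients from a penalized "
                      "fallback fit", RuntimeWarning, stacklevel=2)
        beta, sigma, se, nll, aic, ok = fit(cols, max(ridge, 1e-2))
    names = ["intercept"] + cols
    return LogisticModel(
        coefficients=dict(zip(names, (float(b) for b in beta))),
        random_intercept_sd=sigma,
        std_errors=dict(zip(names, (float(s) for s in se))),
        converged=bool(ok))


def fit_random_intercept_linear(df: pd.DataFrame, response: str,
                                covariates: Sequence[str], group: str):
    """Random-intercept linear model via REML (supporting machinery).

    Thin wrapper over statsmodels' mixed linear model, used for
    electrode-level group contrasts of continuous measurements.
    """
    import statsmodels.formula.api as smf
    formula = f"{response} ~ " + " + ".join(covariates)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return smf.mixedlm(formula, df, groups=df[group]).fit(reml=True)


# ---------------------------------------------------------------------------
# ROC


def roc_auc(scores, labels) -> tuple[pd.DataFrame, float]:
    """ROC curve (all thresholds) and trapezoidal AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return curve, float(_sk_auc(fpr, tpr))


# ---------------------------------------------------------------------------
# CART


@dataclass
class CartNode:
    n: int
    counts: dict
    prediction: object
    feature: str | None = None
    threshold: float | None = None
    left: "CartNode | None" = None     # feature <= threshold
    right: "CartNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def to_dict(self) -> dict:
        d = {"n": self.n, "counts": {str(k): int(v)
                                     for k, v in self.counts.items()},
             "prediction": str(self.prediction)}
        if not self.is_leaf:
            d.update(feature=self.feature, threshold=self.threshold,
                     left=self.left.to_dict(), right=self.right.to_dict())
        return d


@dataclass
class CartTree:
    root: CartNode
    features: list[str]
    min_leaf: int
    max_depth: int

    def predict_one(self, x: Mapping[str, float]):
        node = self.root
        while not node.is_leaf:
            node = node.left if float(x[node.feature]) <= node.threshold \
                else node.right
        return node.prediction

    def predict(self, X: pd.DataFrame) -> list:
        return [self.predict_one(row) for _, row in X.iterrows()]

    def to_dict(self) -> dict:
        return self.root.to_dict()


def _gini(y: np.ndarray) -> float:
    _, counts = np.unique(y, return_counts=True)
    p = counts / y.size
    return 1.0 - float(np.sum(p * p))


def best_split(X: np.ndarray, y: np.ndarray, feature_names: list[str],
               min_leaf: int) -> tuple[int, float, float] | None:
    """Exhaustive best first split (feature index, threshold, gain).

    Candidate thresholds are midpoints of sorted unique values; the gain
    is the Gini impurity decrease weighted by child sizes.  Ties break
    toward the lower feature index, then the lower threshold.
    """
    n = y.size
    parent = _gini(y)
    best: tuple[int, float, float] | None = None
    for fi in range(X.shape[1]):
        vals = np.unique(X[:, fi])
        if vals.size < 2:
            continue
        for thr in (vals[:-1] + vals[1:]) / 2.0:
            mask = X[:, fi] <= thr
            nl = int(mask.sum())
            if nl < min_leaf or n - nl < min_leaf:
                continue
            gain = parent - (nl * _gini(y[mask])
                             + (n - nl) * _gini(y[~mask])) / n
            if gain > 1e-12 and (best is None or gain > best[2] + 1e-12):
                best = (fi, float(thr), float(gain))
    return best


def cart_fit(features: pd.DataFrame, labels, min_leaf: int = 5,
             max_depth: int = 3) -> CartTree:
    """Greedy binary CART on numeric features (Gini impurity)."""
    cols = [c for c in features.columns
            if features[c].dtype.kind in "if"]
    X = features[cols].to_numpy(dtype=float)
    y = np.asarray(labels)
    if y.size < 2 * min_leaf:
        raise ValueError(f"need at least {2 * min_leaf} rows")

    def leaf(yv: np.ndarray) -> CartNode:
        vals, counts = np.unique(yv, return_counts=True)
        order = np.argsort(-counts, kind="stable")
        return CartNode(n=int(yv.size),
                        counts=dict(zip(vals[order], counts[order])),
                        prediction=vals[order][0])

    def grow(Xv: np.ndarray, yv: np.ndarray, depth: int) -> CartNode:
        node = leaf(yv)
        if depth >= max_depth or _gini(yv) == 0.0:
            return node
        split = best_split(Xv, yv, cols, min_leaf)
        if split is None:
            return node
        fi, thr, _ = split
        mask = Xv[:, fi] <= thr
        node.feature = cols[fi]
        node.threshold = thr
        node.left = grow(Xv[mask], yv[mask], depth + 1)
        node.right = grow(Xv[~mask], yv[~mask], depth + 1)
        return node

    return CartTree(root=grow(X, y, 0), features=cols,
                    min_leaf=min_leaf, max_depth=max_depth)


# ---------------------------------------------------------------------------
# Group comparisons


def group_tests(values, groups, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise Welch t-tests with Holm correction across group pairs.

    Returns one row per pair with group means, SDs, sizes, the Welch t
    statistic, raw and Holm-adjusted p-values and a significance flag.
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "group": np.asarray(groups)}).dropna()
    names = list(pd.unique(df.group))
    if len(names) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for g1, g2 in itertools.combinations(names, 2):
        v1 = df.value[df.group == g1]
        v2 = df.value[df.group == g2]
        t, p = sstats.ttest_ind(v1, v2, equal_var=False)
        rows.append({"group1": g1, "group2": g2,
                     "mean1": v1.mean(), "sd1": v1.std(ddof=1),
                     "n1": len(v1),
                     "mean2": v2.mean(), "sd2": v2.std(ddof=1),
                     "n2": len(v2), "t": float(t), "p": float(p)})
    out = pd.DataFrame(rows)
    reject, p_adj, *_ = multipletests(out.p, alpha=alpha, method="holm")
    out["p_adj"] = p_adj
    out["significant"] = reject
    return out
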