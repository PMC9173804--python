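"""Presence/background environmental niche model and its validation.

The model relates camp presence cells to environmental predictors.  Two modes
are provided:

* ``maxent_like`` — an L1-penalised logistic model over an expanded feature
  basis (linear, quadratic, product, hinge, threshold and categorical
  indicator features), fitted on presence cells against a background sample
  of land cells.  The penalty plays the role of the per-term regularization
  that protects against overfitting when projecting into novel climates.
* ``favorability_glm`` — a binomial GLM on presence/absence over all land
  cells, whose predicted probability is passed through the favorability
  transform so the output is corrected for prevalence.

Both produce suitability scores in [0, 1]; predictor training extremes are
recorded as clamp ranges so projections never extrapolate beyond them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import cohen_kappa_score

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# feature basis


@dataclass
class FeatureBasis:
    """Expanded feature set with recorded clamp ranges.

    Continuous predictors are min-max scaled to [0,1] on the training data;
    hinge and threshold knots sit at interior deciles of the scaled training
    distribution.  Categorical predictors become one indicator per trained
    level; unseen levels at projection time map to the nearest trained level.
    """

    predictor_names: list[str]
    categorical: set[str] = field(default_factory=set)
    n_knots: int = 5
    feature_classes: tuple[str, ...] = (
        "linear", "quadratic", "product", "hinge", "threshold", "categorical")
    clamp_range: dict[str, tuple[float, float]] = field(default_factory=dict)
    knots: dict[str, np.ndarray] = field(default_factory=dict)
    levels: dict[str, np.ndarray] = field(default_factory=dict)
    feature_names_: list[str] = field(default_factory=list)

    def fit(self, X: pd.DataFrame) -> "FeatureBasis":
        for name in self.predictor_names:
            col = X[name].to_numpy()
            if name in self.categorical:
                self.levels[name] = np.unique(col)
            else:
                lo, hi = float(np.min(col)), float(np.max(col))
                self.clamp_range[name] = (lo, hi)
                qs = np.linspace(0, 1, self.n_knots + 2)[1:-1]
                z = self._scale(name, np.clip(col, lo, hi))
                self.knots[name] = np.quantile(z, qs)
        self.feature_names_ = self._names()
        return self

    def _scale(self, name, v):
        lo, hi = self.clamp_range[name]
        if hi == lo:
            return np.zeros_like(np.asarray(v, dtype=float))
        return (np.asarray(v, dtype=float) - lo) / (hi - lo)

    def _names(self) -> list[str]:
        cont = [n for n in self.predictor_names if n not in self.categorical]
        names = []
        if "linear" in self.feature_classes:
            names += [f"lin({n})" for n in cont]
        if "quadratic" in self.feature_classes:
            names += [f"quad({n})" for n in cont]
        if "product" in self.feature_classes:
            names += [f"prod({a},{b})" for k, a in enumerate(cont) for b in cont[k + 1:]]
        if "hinge" in self.feature_classes:
            for n in cont:
                names += [f"hingeF({n},{k:.3f})" for k in self.knots[n]]
                names += [f"hingeR({n},{k:.3f})" for k in self.knots[n]]
        if "threshold" in self.feature_classes:
            for n in cont:
                names += [f"thr({n},{k:.3f})" for k in self.knots[n]]
        if "categorical" in self.feature_classes:
            for n in self.predictor_names:
                if n in self.categorical:
                    names += [f"cat({n}={lv})" for lv in self.levels[n]]
        return names

    def transform(self, X: pd.DataFrame, clamp: bool = True) -> np.ndarray:
        cont = [n for n in self.predictor_names if n not in self.categorical]
        z = {}
        for n in cont:
            v = X[n].to_numpy(dtype=float)
            if clamp:
                lo, hi = self.clamp_range[n]
                v = np.clip(v, lo, hi)
            z[n] = self._scale(n, v)
        cols = []
        if "linear" in self.feature_classes:
            cols += [z[n] for n in cont]
        if "quadratic" in self.feature_classes:
            cols += [z[n] ** 2 for n in cont]
        if "product" in self.feature_classes:
            cols += [z[a] * z[b] for k, a in enumerate(cont) for b in cont[k + 1:]]
        if "hinge" in self.feature_classes:
            for n in cont:
                for k in self.knots[n]:
                    cols.append(np.maximum(0.0, (z[n] - k) / max(1.0 - k, 1e-12)))
                for k in self.knots[n]:
                    cols.append(np.maximum(0.0, (k - z[n]) / max(k, 1e-12)))
        if "threshold" in self.feature_classes:
            for n in cont:
                for k in self.knots[n]:
                    cols.append((z[n] >= k).astype(float))
        if "categorical" in self.feature_classes:
            for n in self.predictor_names:
                if n in self.categorical:
                    v = X[n].to_numpy()
                    lv = self.levels[n]
                    # unseen level -> nearest trained level (clamp analogue)
                    if np.issubdtype(np.asarray(lv).dtype, np.number):
                        vv = np.asarray(v, dtype=float)
                        snapped = lv[np.argmin(
                            np.abs(vv[:, None] - np.asarray(lv, float)[None, :]), axis=1)]
                        unseen = ~np.isin(vv, np.asarray(lv, float))
                        if unseen.any():
                            log.info("categorical %s: %d unseen values snapped to "
                                     "nearest trained level", n, int(unseen.sum()))
                        v = snapped
                    for level in lv:
                        cols.append((v == level).astype(float))
        return np.column_stack(cols) if cols else np.empty((len(X), 0))


# ---------------------------------------------------------------------------
# model container


@dataclass
class NicheModel:
    """Fitted niche model: feature weights, clamp ranges, prevalence, threshold."""

    basis: FeatureBasis
    weights: np.ndarray
    intercept: float
    regularization: float
    n1: int  # presences
    n0: int  # background / absences
    mode: str = "maxent_like"
    threshold: float = 0.5  # tau, set by compute_threshold after fitting

    def __post_init__(self):
        if self.n1 < 1 or self.n0 < 1:
            raise ValueError("need at least one presence and one background case")
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError("threshold outside [0,1]")

    def predict(self, X: pd.DataFrame, clamp: bool = True) -> np.ndarray:
        """Suitability in [0,1]; predictors clipped into clamp ranges first."""
        F = self.basis.transform(X, clamp=clamp)
        eta = F @ self.weights + self.intercept
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        if self.mode == "favorability_glm":
            return favorability(p, self.n1, self.n0)
        return p

    @property
    def predictor_names(self) -> list[str]:
        return self.basis.predictor_names

    @property
    def clamp_range(self) -> dict[str, tuple[float, float]]:
        return self.basis.clamp_range


@dataclass
class EvalMetrics:
    """Cross-validated discrimination metrics (means over repeats)."""

    auc: float
    kappa: float
    sensitivity: float
    specificity: float
    reps: int

    @property
    def tss(self) -> float:
        """True skill statistic: sensitivity + specificity - 1."""
        return self.sensitivity + self.specificity - 1.0


# ---------------------------------------------------------------------------
# operations


def _univariate_d2(x: np.ndarray, y: np.ndarray) -> float:
    """Explained deviance of a single-predictor binomial GLM."""
    import statsmodels.api as sm

    X = sm.add_constant(np.asarray(x, dtype=float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        except Exception:
            return 0.0
    if res.null_deviance <= 0:
        return 0.0
    return float(1.0 - res.deviance / res.null_deviance)


def select07(predictor_table: pd.DataFrame, response: np.ndarray,
             r_cut: float = 0.7) -> list[str]:
    """Collinearity screen: among each pair with |Pearson r| >= r_cut drop the
    predictor with lower univariate explained deviance, iterating on the
    strongest remaining pair until no offending pair is left.

    Constant predictors (undefined r) are dropped with a warning.  Returns the
    retained predictor names in their original column order.
    """
    y = np.asarray(response)
    if len(predictor_table) < 2:
        raise ValueError("need at least two cases")
    names = [c for c in predictor_table.columns]
    kept = []
    for n in names:
        if np.std(predictor_table[n].to_numpy(dtype=float)) == 0:
            warnings.warn(f"select07: predictor {n!r} is constant; dropped")
        else:
            kept.append(n)
    d2 = {n: _univariate_d2(predictor_table[n].to_numpy(), y) for n in kept}
    while True:
        if len(kept) < 2:
            break
        corr = predictor_table[kept].corr().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        if abs(corr[i, j]) < r_cut:
            break
        a, b = kept[i], kept[j]
        loser = a if d2[a] < d2[b] else b
        kept.remove(loser)
    return kept


def favorability(P, n1: int, n0: int):
    """Prevalence-corrected suitability.

    F = (P/(1-P)) / (n1/n0 + P/(1-P)); equals 0.5 exactly when P equals the
    training prevalence n1/(n1+n0), 0 as P -> 0 and 1 as P -> 1.
    """
    if n1 <= 0 or n0 <= 0:
        raise ValueError("n1 and n0 must be positive")
    P = np.asarray(P, dtype=float)
    scalar = P.ndim == 0
    P = np.atleast_1d(P)
    if np.any((P < 0) | (P > 1)):
        raise ValueError("P outside [0,1]")
    F = np.empty_like(P)
    lo = P <= 0.0
    hi = P >= 1.0
    mid = ~(lo | hi)
    odds = P[mid] / (1.0 - P[mid])
    F[mid] = odds / (n1 / n0 + odds)
    F[lo] = 0.0
    F[hi] = 1.0
    return float(F[0]) if scalar else F


def compute_threshold(scores_pres: np.ndarray, scores_abs: np.ndarray) -> float:
    """Threshold maximising sensitivity + specificity (rule: score >= tau).

    Candidates are the observed scores plus 0 and 1; ties broken by the
    smallest candidate.
    """
    sp = np.asarray(scores_pres, dtype=float)
    sa = np.asarray(scores_abs, dtype=float)
    if sp.size == 0 or sa.size == 0:
        raise ValueError("both score sets must be non-empty")
    cands = np.unique(np.concatenate([sp, sa, [0.0, 1.0]]))
    best_tau, best = 0.0, -np.inf
    for tau in cands:  # ascending, so first max wins the tie-break
        sens = float(np.mean(sp >= tau))
        spec = float(np.mean(sa < tau))
        if sens + spec > best + 1e-12:
            best, best_tau = sens + spec, float(tau)
    return best_tau


def auc_mann_whitney(scores_pres: np.ndarray, scores_abs: np.ndarray) -> float:
    """Rank-based AUC (probability a presence outscores an absence)."""
    sp, sa = np.asarray(scores_pres, float), np.asarray(scores_abs, float)
    n1, n0 = sp.size, sa.size
    ranks = rankdata(np.concatenate([sp, sa]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _sample_background(rng: np.random.Generator, candidates: np.ndarray,
                       n: int) -> np.ndarray:
    if n >= candidates.shape[0]:
        if n > candidates.shape[0]:
            warnings.warn("background_n exceeds available absence cells; using all")
        return candidates
    idx = rng.choice(candidates.shape[0], size=n, replace=False)
    return candidates[idx]


def fit_enm(presences, env_slice: dict[str, np.ndarray], mode: str = "maxent_like",
            background_n: int = 10_000, regularization: float = 1.0,
            seed: int = 0, categorical: set[str] | None = None,
            n_knots: int = 5, set_threshold: bool = True) -> NicheModel:
    """Fit the niche model on a presence grid against one environmental slice.

    ``maxent_like`` contrasts presence cells with a seeded uniform background
    sample of non-presence land cells; ``favorability_glm`` fits an
    (unpenalised) binomial GLM on presence/absence over all land cells and
    wraps its probability in the favorability transform.
    """
    if mode not in ("maxent_like", "favorability_glm"):
        raise ValueError(f"unknown mode {mode!r}")
    categorical = set(categorical or ())
    grid = presences.grid
    land = grid.land_mask
    pres = presences.presence
    if pres.sum() < 1:
        raise ValueError("need at least one presence cell")
    names = sorted(env_slice)

    def table(mask):
        return pd.DataFrame({n: np.asarray(env_slice[n])[mask] for n in names})

    rng = np.random.default_rng(seed)
    Xp = table(pres)
    if mode == "maxent_like":
        absence_idx = np.argwhere(land & ~pres)
        bg = _sample_background(rng, absence_idx, background_n)
        mask0 = np.zeros(grid.shape, dtype=bool)
        mask0[bg[:, 0], bg[:, 1]] = True
        X0 = table(mask0)
        classes = ("linear", "quadratic", "product", "hinge", "threshold", "categorical")
    else:
        X0 = table(land & ~pres)
        classes = ("linear", "quadratic", "categorical")

    Xall = pd.concat([Xp, X0], ignore_index=True)
    y = np.concatenate([np.ones(len(Xp)), np.zeros(len(X0))])
    basis = FeatureBasis(predictor_names=names, categorical=categorical,
                         n_knots=n_knots, feature_classes=classes).fit(Xall)
    F = basis.transform(Xall)

    if mode == "maxent_like":
        C = 1.0 / max(regularization, 1e-12)
        clf = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear",
                                 max_iter=2000, tol=1e-7)
        clf.fit(F, y)
        w, b = clf.coef_.ravel(), float(clf.intercept_[0])
    else:
        import statsmodels.api as sm

        Xd = sm.add_constant(F, has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, Xd, family=sm.families.Binomial()).fit(maxiter=200)
        if not res.converged:
            log.warning("favorability GLM did not converge (possible separation)")
        w, b = np.asarray(res.params[1:]), float(res.params[0])

    model = NicheModel(basis=basis, weights=w, intercept=b,
                       regularization=regularization, n1=int(len(Xp)),
                       n0=int(len(X0)), mode=mode)
    if set_threshold:
        s = model.predict(Xall)
        model.threshold = compute_threshold(s[y == 1], s[y == 0])
    log.info("fit_enm mode=%s n1=%d n0=%d regularization=%g background_n=%d",
             mode, model.n1, model.n0, regularization, background_n)
    return model


def evaluate_cv(X: pd.DataFrame, y: np.ndarray, mode: str = "maxent_like",
                train_frac: float = 0.8, reps: int = 500, seed: int = 0,
                regularization: float = 1.0, categorical: set[str] | None = None,
                n_knots: int = 5) -> EvalMetrics:
    """Repeated random-split cross-validation at the cell level.

    Per repeat: refit on the training fraction, set tau on the training
    scores, then score the held-out cells.  A repeat whose validation fold
    lacks one class is redrawn.  Reports mean rank-based AUC, Cohen's Kappa,
    sensitivity and specificity (TSS follows from the identity).
    """
    y = np.asarray(y).astype(int)
    n = len(y)
    if n < 5 or y.sum() == 0 or y.sum() == n:
        raise ValueError("need both classes and enough cases to split")
    rng = np.random.default_rng(seed)
    categorical = set(categorical or ())
    classes = (("linear", "quadratic", "product", "hinge", "threshold", "categorical")
               if mode == "maxent_like" else ("linear", "quadratic", "categorical"))
    aucs, kappas, senss, specs = [], [], [], []
    done = 0
    while done < reps:
        idx = rng.permutation(n)
        k = int(round(train_frac * n))
        tr, va = idx[:k], idx[k:]
        if len(np.unique(y[va])) < 2 or len(np.unique(y[tr])) < 2:
            log.info("validation fold lacked a class; repeat redrawn")
            continue
        basis = FeatureBasis(predictor_names=list(X.columns), categorical=categorical,
                             n_knots=n_knots, feature_classes=classes).fit(X.iloc[tr])
        Ftr = basis.transform(X.iloc[tr])
        if mode == "maxent_like":
            clf = LogisticRegression(l1_ratio=1.0, C=1.0 / max(regularization, 1e-12),
                                     solver="liblinear", max_iter=1000, tol=1e-6)
            clf.fit(Ftr, y[tr])
            w, b = clf.coef_.ravel(), float(clf.intercept_[0])
        else:
            import statsmodels.api as sm
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(y[tr], sm.add_constant(Ftr, has_constant="add"),
                             family=sm.families.Binomial()).fit(maxiter=100)
            w, b = np.asarray(res.params[1:]), float(res.params[0])
        model = NicheModel(basis=basis, weights=w, intercept=b,
                           regularization=regularization,
                           n1=int(y[tr].sum()), n0=int((1 - y[tr]).sum()), mode=mode)
        str_ = model.predict(X.iloc[tr])
        tau = compute_threshold(str_[y[tr] == 1], str_[y[tr] == 0])
        sva = model.predict(X.iloc[va])
        pred = (sva >= tau).astype(int)
        aucs.append(auc_mann_whitney(sva[y[va] == 1], sva[y[va] == 0]))
        kappas.append(cohen_kappa_score(y[va], pred))
        senss.append(float(np.mean(pred[y[va] == 1] == 1)))
        specs.append(float(np.mean(pred[y[va] == 0] == 0)))
        done += 1
    return EvalMetrics(auc=float(np.mean(aucs)), kappa=float(np.mean(kappas)),
                       sensitivity=float(np.mean(senss)),
                       specificity=float(np.mean(specs)), reps=reps)
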