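"""Two-step elastic-net prediction of drug response.

A baseline elastic net is trained on somatic markers; its in-sample training
predictions are subtracted from the (tissue-residualized) phenotype and a
second elastic net is trained on germline dosages against those residuals.
Joint test-set predictions are the sum of the two stages.  Performance is
scored as the Pearson correlation between out-of-sample predictions and the
observed phenotype, averaged over repeated fivefold cross-validation with
different random splits; a drug is called as having a significant germline
component when the mean improvement of the joint model over the somatic
baseline exceeds two standard deviations of that improvement across repeats
(a one-sided rule at the Phi(2) = 97.72% confidence level).

All scalers and hyperparameters are learned strictly inside training folds;
hyperparameters are chosen by nested (inner-fold) cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler

__all__ = [
    "PredictionResult",
    "TwoStepModel",
    "residualize_covariates",
    "fit_elastic_net",
    "fit_two_step",
    "evaluate_repeated_cv",
    "call_germline_component",
    "TWO_SD_CONFIDENCE",
]

#: Implied one-sided confidence level of the 2-SD rule, Phi(2).
TWO_SD_CONFIDENCE: float = float(stats.norm.cdf(2.0))

DEFAULT_L1_RATIOS: tuple[float, ...] = (0.1, 0.5, 0.9)


def residualize_covariates(y, W) -> np.ndarray:
    """Residuals of y after least-squares removal of covariates + intercept.

    Rank-deficient covariate matrices have their redundant columns dropped
    (with a warning) via pivoted QR before fitting.  The returned residuals
    are orthogonal to every covariate column and mean-centred.
    """
    y = np.asarray(y, dtype=float)
    W = np.asarray(W, dtype=float) if W is not None else np.empty((y.size, 0))
    if W.ndim == 1:
        W = W[:, None]
    if W.shape[0] != y.size:
        raise ValueError("covariate rows must match phenotype length")
    M = np.hstack([np.ones((y.size, 1)), W])
    _, R, piv = linalg.qr(M, mode="economic", pivoting=True)
    tol = np.abs(R[0, 0]) * max(M.shape) * np.finfo(float).eps
    rank = int(np.sum(np.abs(np.diag(R)) > tol))
    if rank < M.shape[1]:
        warnings.warn(f"covariate matrix rank deficient: dropping "
                      f"{M.shape[1] - rank} redundant column(s)")
        M = M[:, np.sort(piv[:rank])]
    coef, *_ = np.linalg.lstsq(M, y, rcond=None)
    return y - M @ coef


@dataclass
class ElasticNetStage:
    """A fitted, scaled elastic-net stage (feature scaler learned on the
    training data only; zero-variance features excluded)."""

    scaler: StandardScaler
    model: ElasticNetCV
    kept: np.ndarray  # indices of non-constant features
    n_features_in: int

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)[:, self.kept]
        return self.model.predict(self.scaler.transform(X))

    @property
    def coef_full(self) -> np.ndarray:
        out = np.zeros(self.n_features_in)
        out[self.kept] = self.model.coef_
        return out

    @property
    def n_selected(self) -> int:
        return int(np.count_nonzero(self.model.coef_))


def fit_elastic_net(
    X,
    y,
    l1_ratios=DEFAULT_L1_RATIOS,
    n_alphas: int = 30,
    inner_folds: int = 3,
    seed: int = 0,
) -> ElasticNetStage:
    """Elastic net with nested hyperparameter selection.

    The mixing parameter grid crossed with a logarithmic penalty path is
    searched by ``inner_folds``-fold CV on the supplied (training) data only.
    ``n_alphas`` is either the length of the automatic penalty path or an
    explicit sequence of penalty values.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    kept = np.flatnonzero(X.std(axis=0) > 0)
    if kept.size < X.shape[1]:
        warnings.warn(f"excluding {X.shape[1] - kept.size} zero-variance feature(s)")
    if kept.size == 0:
        raise ValueError("no non-constant features to fit")
    scaler = StandardScaler().fit(X[:, kept])
    Xs = scaler.transform(X[:, kept])
    cv = KFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    alphas = n_alphas if np.isscalar(n_alphas) else list(n_alphas)
    model = ElasticNetCV(l1_ratio=list(l1_ratios), alphas=alphas, cv=cv,
                         max_iter=5000, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Xs, y)
    return ElasticNetStage(scaler=scaler, model=model, kept=kept,
                           n_features_in=X.shape[1])


@dataclass
class TwoStepModel:
    """Somatic baseline + germline residual model; joint prediction is the
    sum of the two stages' predictions."""

    somatic_model: ElasticNetStage
    germline_model: ElasticNetStage

    def predict_somatic(self, X_somatic) -> np.ndarray:
        return self.somatic_model.predict(X_somatic)

    def predict_germline(self, X_germline) -> np.ndarray:
        return self.germline_model.predict(X_germline)

    def predict(self, X_somatic, X_germline) -> np.ndarray:
        return self.predict_somatic(X_somatic) + self.predict_germline(X_germline)


def fit_two_step(
    X_somatic,
    X_germline,
    y,
    inner_folds: int = 3,
    l1_ratios=DEFAULT_L1_RATIOS,
    n_alphas: int = 30,
    seed: int = 0,
) -> TwoStepModel:
    """Fit the two-step model on training data (y already tissue-residualized).

    Stage 1 is fitted on somatic features; its in-sample training predictions
    are subtracted from y; stage 2 is fitted on germline features against the
    residuals.  Stage 2 never sees somatic features and vice versa.
    """
    y = np.asarray(y, dtype=float)
    stage1 = fit_elastic_net(X_somatic, y, l1_ratios, n_alphas, inner_folds, seed)
    resid = y - stage1.predict(X_somatic)
    stage2 = fit_elastic_net(X_germline, resid, l1_ratios, n_alphas, inner_folds,
                             seed + 1)
    return TwoStepModel(somatic_model=stage1, germline_model=stage2)


@dataclass
class PredictionResult:
    """Cross-validated performance of the somatic-only vs joint model."""

    drug: str
    r_somatic: float
    r_joint: float
    r_germline_component: float
    sd_diff: float
    sd_component: float
    n_selected_germline: float
    n_repeats: int
    significant: bool = False
    per_repeat: dict = field(default_factory=dict, repr=False)


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0  # constant predictions score at chance level
    return float(np.corrcoef(a, b)[0, 1])


def evaluate_repeated_cv(
    X_somatic,
    X_germline,
    y,
    k: int = 5,
    n_repeats: int = 10,
    seed: int = 0,
    drug: str = "drug",
    inner_folds: int = 3,
    l1_ratios=DEFAULT_L1_RATIOS,
    n_alphas: int = 30,
) -> PredictionResult:
    """Repeated k-fold CV of the somatic-only and joint models.

    Folds are identical for both models within a repeat.  Pearson r is
    computed on the concatenated out-of-sample predictions of each repeat;
    the across-repeat SD of (r_joint - r_somatic) feeds the 2-SD call.
    """
    X_somatic = np.asarray(X_somatic, dtype=float)
    X_germline = np.asarray(X_germline, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 2 * k:
        raise ValueError("need at least 2k samples for k-fold CV")
    r_som, r_joint, r_germ, n_sel = [], [], [], []
    for rep in range(n_repeats):
        rep_seed = (seed * 1000 + rep) % (2 ** 31)
        kf = KFold(n_splits=k, shuffle=True, random_state=rep_seed)
        pred_s = np.empty(n)
        pred_j = np.empty(n)
        pred_g = np.empty(n)
        for train, test in kf.split(y):
            model = fit_two_step(X_somatic[train], X_germline[train], y[train],
                                 inner_folds=inner_folds, l1_ratios=l1_ratios,
                                 n_alphas=n_alphas, seed=rep_seed)
            pred_s[test] = model.predict_somatic(X_somatic[test])
            pred_g[test] = model.predict_germline(X_germline[test])
            pred_j[test] = pred_s[test] + pred_g[test]
            n_sel.append(model.germline_model.n_selected)
        r_som.append(_safe_pearson(pred_s, y))
        r_joint.append(_safe_pearson(pred_j, y))
        r_germ.append(_safe_pearson(pred_g, y))
    r_som = np.array(r_som)
    r_joint = np.array(r_joint)
    r_germ = np.array(r_germ)
    diffs = r_joint - r_som
    result = PredictionResult(
        drug=drug,
        r_somatic=float(r_som.mean()),
        r_joint=float(r_joint.mean()),
        r_germline_component=float(r_germ.mean()),
        sd_diff=float(diffs.std(ddof=1)) if n_repeats > 1 else 0.0,
        sd_component=float(r_germ.std(ddof=1)) if n_repeats > 1 else 0.0,
        n_selected_germline=float(np.median(n_sel)),
        n_repeats=n_repeats,
        per_repeat={"r_somatic": r_som, "r_joint": r_joint,
                    "r_germline_component": r_germ},
    )
    result.significant = call_germline_component(result)
    return result


def call_germline_component(result: PredictionResult, rule: str = "difference"
                            ) -> bool:
    """One-sided 2-SD rule for a significant germline component.

    ``difference`` (default): mean(r_joint - r_somatic) > 2 * SD across
    repeats of that difference.  ``component``: r_germline_component > 2 * its
    across-repeat SD.  A zero SD with zero improvement is not significant.
    """
    if result.n_repeats < 2:
        raise ValueError("need >= 2 repeats to estimate the repeat SD")
    if rule == "difference":
        improvement = result.r_joint - result.r_somatic
        sd = result.sd_diff
    elif rule == "component":
        improvement = result.r_germline_component
        sd = result.sd_component
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return bool(improvement > 2.0 * sd)
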