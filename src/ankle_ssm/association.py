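"""Logistic regression with cluster-robust (intra-person) covariance.

Two ankles of one participant are not independent, so Wald inference uses
the sandwich estimator with cluster score sums (clusters = participants)
and the small-sample factor G/(G-1).  The fit itself is maximum likelihood
by iteratively reweighted least squares (IRLS).

Surface:

* ``ClusterLogit(y, X, groups).fit()`` -> :class:`ClusterLogitResults`
  with ``summary()`` and ``odds_ratio_table()``;
* the underlying functions :func:`fit_logistic_irls`,
  :func:`cluster_robust_covariance`, :func:`odds_ratio_table`;
* study-level drivers :func:`run_injury_models` (minimally and fully
  adjusted odds-ratio tables) and :func:`run_race_model` (race as the
  dependent variable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .shape_model import ModeScores

__all__ = [
    "LogisticFit",
    "SeparationError",
    "ClusterLogit",
    "ClusterLogitResults",
    "fit_logistic_irls",
    "cluster_robust_covariance",
    "odds_ratio_table",
    "run_injury_models",
    "run_race_model",
]

ADJUSTMENT_COVARIATES = ("age", "bmi", "race", "sex", "klg", "symptoms")


class SeparationError(RuntimeError):
    """The outcome is (quasi-)completely separated; the MLE does not exist."""


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit."""

    coef: np.ndarray
    cov_naive: np.ndarray  # inverse observed information
    fitted: np.ndarray
    converged: bool
    n_obs: int
    names: list[str]
    X: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)
    n_iter: int = 0


def _check_design(X: np.ndarray, names: list[str]) -> None:
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n={n} rows cannot identify {p} coefficients")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the collinear columns via pivoted QR
        from scipy.linalg import qr

        _, r, piv = qr(X, mode="economic", pivoting=True)
        bad = sorted(piv[rank:])
        raise ValueError(
            "rank-deficient design; collinear columns: "
            + ", ".join(names[j] for j in bad)
        )


def fit_logistic_irls(
    X: np.ndarray,
    y: np.ndarray,
    names: list[str] | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> LogisticFit:
    """Logistic MLE by IRLS with step-halving on the deviance.

    ``X`` must include the intercept column.  Separation is flagged when
    coefficients diverge (|beta| > 30) while the gradient direction does
    not vanish.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    # X carries the intercept in its first column by contract
    names = list(names) if names is not None else (
        ["const"] + [f"x{j}" for j in range(1, p)]
    )
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise SeparationError("degenerate outcome: y is constant")
    _check_design(X, names)

    def nll(beta: np.ndarray) -> float:
        eta = X @ beta
        # log(1+e^eta) - y*eta, computed stably
        return float(np.sum(np.logaddexp(0.0, eta) - y * eta))

    beta = np.zeros(p)
    current = nll(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - mu)
        w = mu * (1.0 - mu)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "singular information matrix (separation or degenerate fit)"
            ) from exc
        # step-halving to guarantee deviance decrease
        t = 1.0
        while True:
            candidate = beta + t * step
            new = nll(candidate)
            if new <= current + 1e-12 or t < 1e-8:
                break
            t /= 2.0
        beta, current = candidate, new
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        if np.max(np.abs(beta)) > 30.0 and np.max(np.abs(grad)) > 1e-6:
            raise SeparationError(
                "coefficients diverging (|beta| > 30): complete or "
                "quasi-complete separation"
            )

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    info = (X * w[:, None]).T @ X
    cov = np.linalg.inv(info)
    if not converged and np.max(np.abs(X.T @ (y - mu))) > 1e-6:
        if np.max(np.abs(beta)) > 30.0:
            raise SeparationError("coefficients diverging: separation")
    return LogisticFit(
        coef=beta, cov_naive=cov, fitted=mu, converged=converged,
        n_obs=n, names=names, X=X, y=y, n_iter=it,
    )


def cluster_robust_covariance(fit: LogisticFit, clusters) -> np.ndarray:
    """Cluster sandwich B M B with the small-sample factor G/(G-1).

    B is the inverse observed information; M sums outer products of the
    per-cluster score sums s_g = sum_i x_i (y_i - mu_i).  With every row
    its own cluster this reduces to the HC0 sandwich times n/(n-1).
    """
    clusters = np.asarray(clusters)
    if clusters.shape[0] != fit.n_obs:
        raise ValueError("one cluster id per observation required")
    labels = pd.unique(clusters)
    G = len(labels)
    if G < 2:
        raise ValueError("cluster-robust covariance needs at least 2 clusters")
    resid = fit.y - fit.fitted
    scores = fit.X * resid[:, None]  # (n, p) per-row score contributions
    p = fit.X.shape[1]
    meat = np.zeros((p, p))
    frame = pd.DataFrame(scores)
    for _, block in frame.groupby(pd.Series(clusters), sort=False):
        s = block.to_numpy().sum(axis=0)
        meat += np.outer(s, s)
    meat *= G / (G - 1)
    cov = fit.cov_naive @ meat @ fit.cov_naive
    return (cov + cov.T) / 2.0


def odds_ratio_table(
    fit: LogisticFit,
    cov: np.ndarray | None = None,
    label: str = "",
    z: float = 1.96,
) -> pd.DataFrame:
    """Per-predictor OR, Wald 95% CI and p; the intercept is excluded.

    CI = exp(beta +/- 1.96 SE) with SE from the supplied covariance
    (naive if none given); ``significant`` flags CIs excluding 1.
    """
    cov = fit.cov_naive if cov is None else np.asarray(cov, dtype=float)
    if cov.shape != (len(fit.coef), len(fit.coef)):
        raise ValueError("covariance not conformable with coefficients")
    var = np.diag(cov)
    if np.any(var <= 0):
        raise ValueError("non-positive variance on the covariance diagonal")
    se = np.sqrt(var)
    rows = []
    for j, name in enumerate(fit.names):
        if name in ("const", "intercept"):
            continue
        beta, s = fit.coef[j], se[j]
        lo, hi = np.exp(beta - z * s), np.exp(beta + z * s)
        pval = 2.0 * stats.norm.sf(abs(beta) / s)
        rows.append(
            dict(predictor=name, log_or=beta, se=s, odds_ratio=np.exp(beta),
                 ci_lower=lo, ci_upper=hi, p_value=pval,
                 significant=bool(lo > 1.0 or hi < 1.0), model=label)
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model / results interface
# ---------------------------------------------------------------------------

class ClusterLogit:
    """Logistic model with clustered observations.

    Parameters
    ----------
    y : (n,) binary outcome.
    X : (n, p) design (no intercept; one is prepended unless
        ``add_constant=False``).
    groups : (n,) cluster ids (participants); ``None`` treats rows as
        independent (each its own cluster).
    names : predictor names matching X's columns.
    """

    def __init__(self, y, X, groups=None, names=None, add_constant=True):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if names is None:
            names = [f"x{j + 1}" for j in range(X.shape[1])]
        if add_constant:
            X = np.column_stack([np.ones(len(X)), X])
            names = ["const"] + list(names)
        self.y = np.asarray(y, dtype=float).ravel()
        self.X = X
        self.names = list(names)
        self.groups = np.arange(len(self.y)) if groups is None else np.asarray(groups)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outcome: str, predictors: list[str],
                       groups: str | None = None) -> "ClusterLogit":
        g = df[groups].to_numpy() if groups else None
        return cls(df[outcome].to_numpy(), df[predictors].to_numpy(),
                   groups=g, names=list(predictors))

    def fit(self, **kwargs) -> "ClusterLogitResults":
        fit = fit_logistic_irls(self.X, self.y, names=self.names, **kwargs)
        cov_cluster = cluster_robust_covariance(fit, self.groups)
        return ClusterLogitResults(fit=fit, cov_cluster=cov_cluster, model=self)


@dataclass
class ClusterLogitResults:
    """Fitted cluster-robust logistic model."""

    fit: LogisticFit
    cov_cluster: np.ndarray
    model: ClusterLogit

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.fit.coef, index=self.fit.names)

    @property
    def bse(self) -> pd.Series:
        """Cluster-robust standard errors."""
        return pd.Series(np.sqrt(np.diag(self.cov_cluster)), index=self.fit.names)

    @property
    def bse_naive(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.fit.cov_naive)), index=self.fit.names)

    def conf_int(self, robust: bool = True, z: float = 1.96) -> pd.DataFrame:
        se = self.bse if robust else self.bse_naive
        return pd.DataFrame(
            {"lower": self.params - z * se, "upper": self.params + z * se}
        )

    def odds_ratio_table(self, label: str = "", robust: bool = True) -> pd.DataFrame:
        cov = self.cov_cluster if robust else self.fit.cov_naive
        return odds_ratio_table(self.fit, cov, label=label)

    def summary(self) -> pd.DataFrame:
        tab = self.odds_ratio_table()
        tab.insert(3, "se_naive", [
            self.bse_naive[p] for p in tab["predictor"]
        ])
        return tab


# ---------------------------------------------------------------------------
# Study-level drivers
# ---------------------------------------------------------------------------

def _scores_frame(scores: ModeScores | pd.DataFrame) -> pd.DataFrame:
    return scores.frame().reset_index(drop=True) if isinstance(scores, ModeScores) else scores.reset_index(drop=True)


def _prepare(scores, metadata: pd.DataFrame):
    sf = _scores_frame(scores)
    md = metadata.reset_index(drop=True)
    if len(sf) != len(md):
        raise ValueError("scores and metadata must align row-wise")
    return pd.concat([sf, md], axis=1), list(sf.columns)


def run_injury_models(scores, metadata: pd.DataFrame):
    """Injury (prior injury vs non-injured) on all retained mode scores.

    Returns two odds-ratio tables: model 1 contains the mode scores only,
    adjusted solely for intra-person correlation (clusters = participant);
    model 2 additionally adjusts for age, BMI, race, sex, KLG and symptoms.
    """
    df, mode_cols = _prepare(scores, metadata)
    res1 = ClusterLogit.from_dataframe(
        df, "injury", mode_cols, groups="participant_id"
    ).fit()
    res2 = ClusterLogit.from_dataframe(
        df, "injury", list(ADJUSTMENT_COVARIATES) + mode_cols,
        groups="participant_id",
    ).fit()
    return (
        res1.odds_ratio_table(label="OR1 (intra-person correlation only)"),
        res2.odds_ratio_table(label="OR2 (fully adjusted)"),
    )


def run_race_model(scores, metadata: pd.DataFrame) -> pd.DataFrame:
    """Race (white vs African American) on all retained mode scores."""
    df, mode_cols = _prepare(scores, metadata)
    res = ClusterLogit.from_dataframe(
        df, "race", mode_cols, groups="participant_id"
    ).fit()
    return res.odds_ratio_table(label="race model")
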