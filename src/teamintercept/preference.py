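"""Bradley-Terry preference model over pairwise agent comparisons.

The log-odds of choosing the first-presented agent X over the second Y is
modeled as an order bias plus a weighted sum of feature differences,

    logit P(choice = X) = b0 + sum_i b_i (X_i - Y_i),

so the b form a utility function over agent features and b0 captures any
baseline first-position preference.  Inference is Bayesian with
independent Normal(0, prior_scale^2) priors on the standardized
coefficients; the posterior is summarized by its mode and a Laplace
(Gaussian) approximation, and per-feature inclusion Bayes factors compare
the Laplace marginal likelihood of the full model against the model with
that feature removed.  This is a deliberately reproducible stand-in for
point-and-click Bayesian GLM stacks built on bespoke g-priors; the prior
actually used is recorded in every summary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import betaln, expit

from .metrics import OBJECTIVE_FEATURES, SUBJECTIVE_FEATURES

DEFAULT_PRIOR_SCALE = 2.5
FAMILIES = {"objective": OBJECTIVE_FEATURES, "subjective": SUBJECTIVE_FEATURES}


class SeparationWarning(UserWarning):
    pass


class UnstableApproximationError(Exception):
    pass


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Standardizer:
    mean: np.ndarray
    scale: np.ndarray  # zero-variance columns get scale 1

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.scale


def raw_differences(table: pd.DataFrame, family: str) -> tuple[np.ndarray, np.ndarray, list]:
    """(first - second) feature differences and 0/1 labels (1 = first chosen)."""
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {sorted(FAMILIES)}")
    names = FAMILIES[family]
    cols = [f"first_{f}" for f in names] + [f"second_{f}" for f in names]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"incomplete choice rows: missing columns {missing}")
    if table[cols].isna().any().any():
        raise ValueError("incomplete choice rows: NaN feature values")
    first = table[[f"first_{f}" for f in names]].to_numpy(dtype=float)
    second = table[[f"second_{f}" for f in names]].to_numpy(dtype=float)
    labels = (table["choice"].astype(str) == "first").to_numpy(dtype=int)
    return first - second, labels, list(names)


def standardize(X: np.ndarray) -> tuple[np.ndarray, Standardizer]:
    """Z-score columns, keeping the scale parameters for reuse on held-out
    data; constant columns are centered only."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    scale = np.where(sd > 0, sd, 1.0)
    sc = Standardizer(mean=mean, scale=scale)
    return sc.transform(X), sc


def design_matrix(table: pd.DataFrame, family: str):
    """Standardized difference matrix, labels, feature names, scaler."""
    diffs, labels, names = raw_differences(table, family)
    Z, sc = standardize(diffs)
    return Z, labels, names, sc


# ---------------------------------------------------------------------------
# MAP fit + Laplace approximation
# ---------------------------------------------------------------------------

def _neg_log_posterior(theta, A, y, prior_scale):
    eta = A @ theta
    # log1p(exp(-|eta|)) formulation for stability
    ll = np.sum(y * eta - np.logaddexp(0.0, eta))
    d = len(theta)
    lp = -0.5 * np.sum(theta**2) / prior_scale**2 - d * math.log(
        prior_scale * math.sqrt(2.0 * math.pi)
    )
    return -(ll + lp)


def _map_fit(A: np.ndarray, y: np.ndarray, prior_scale: float, max_iter: int = 100):
    """Newton (ridge-IRLS) ascent to the posterior mode; returns
    (theta_hat, Hessian of the negative log posterior at the mode)."""
    n, d = A.shape
    theta = np.zeros(d)
    prec = np.eye(d) / prior_scale**2
    for _ in range(max_iter):
        eta = A @ theta
        p = expit(eta)
        grad = A.T @ (p - y) + theta / prior_scale**2
        W = p * (1.0 - p)
        H = A.T @ (A * W[:, None]) + prec
        try:
            delta = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise UnstableApproximationError("singular Hessian during fit") from exc
        theta = theta - delta
        if np.max(np.abs(delta)) < 1e-10:
            break
    eta = A @ theta
    p = expit(eta)
    W = p * (1.0 - p)
    H = A.T @ (A * W[:, None]) + prec
    return theta, H


def _log_marginal_laplace(A, y, prior_scale):
    theta, H = _map_fit(A, y, prior_scale)
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0:
        raise UnstableApproximationError("Hessian not positive definite")
    d = len(theta)
    return (
        -_neg_log_posterior(theta, A, y, prior_scale)
        + 0.5 * d * math.log(2.0 * math.pi)
        - 0.5 * logdet
    )


@dataclass(frozen=True)
class PosteriorSummary:
    """Fitted Bradley-Terry coefficients with uncertainty and evidence.

    ``betas`` maps feature name -> (posterior mean, 2.5%, 97.5%, sd) on
    the standardized-difference scale; ``beta0`` is the order bias.
    ``inclusion_bf`` holds BF10 for keeping each feature (full model vs
    the model without it).
    """

    beta0: tuple
    betas: dict
    inclusion_bf: dict
    n_features: int
    n_obs: int
    prior_scale: float
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "feature": "(order bias)",
                "estimate": self.beta0[0],
                "ci_low": self.beta0[1],
                "ci_high": self.beta0[2],
                "sd": self.beta0[3],
                "inclusion_bf": np.nan,
            }
        ]
        for name, (est, lo, hi, sd) in self.betas.items():
            rows.append(
                {
                    "feature": name,
                    "estimate": est,
                    "ci_low": lo,
                    "ci_high": hi,
                    "sd": sd,
                    "inclusion_bf": self.inclusion_bf.get(name, np.nan),
                }
            )
        return pd.DataFrame(rows)


def fit_bradley_terry(
    matrix: np.ndarray,
    labels: np.ndarray,
    names: Optional[Sequence[str]] = None,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
    compute_bf: bool = True,
) -> PosteriorSummary:
    """MAP + Laplace posterior for the order-bias logistic model.

    ``matrix`` holds standardized feature differences (no intercept
    column; it is added internally).  95% credible intervals come from
    the Gaussian Laplace approximation.  Perfectly separable data leave
    the posterior proper under the Gaussian prior but trigger a
    SeparationWarning when coefficients run implausibly large.
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels, dtype=float)
    if X.ndim != 2 or len(X) != len(y) or len(y) == 0:
        raise ValueError("matrix and labels must be non-empty and aligned")
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    A = np.hstack([np.ones((len(X), 1)), X])
    theta, H = _map_fit(A, y, prior_scale)
    if np.max(np.abs(theta)) > 10.0:  # implausible on the standardized scale
        warnings.warn(
            "coefficients far in the prior tails; data may be (quasi-)separable",
            SeparationWarning,
        )
    cov = np.linalg.inv(H)
    sd = np.sqrt(np.diag(cov))
    z = 1.959963984540054
    lo, hi = theta - z * sd, theta + z * sd
    betas = {
        name: (theta[i + 1], lo[i + 1], hi[i + 1], sd[i + 1])
        for i, name in enumerate(names)
    }
    bfs = {}
    if compute_bf:
        lml_full = _log_marginal_laplace(A, y, prior_scale)
        for i, name in enumerate(names):
            A_red = np.delete(A, i + 1, axis=1)
            lml_red = _log_marginal_laplace(A_red, y, prior_scale)
            bfs[name] = math.exp(min(700.0, lml_full - lml_red))
    return PosteriorSummary(
        beta0=(theta[0], lo[0], hi[0], sd[0]),
        betas=betas,
        inclusion_bf=bfs,
        n_features=len(names),
        n_obs=len(y),
        prior_scale=prior_scale,
        metadata={
            "prior": f"independent Normal(0, {prior_scale}^2) on standardized coefficients",
            "inference": "posterior mode + Laplace approximation",
            "inclusion_bf": "Laplace marginal likelihood, full vs drop-one model",
        },
    )


def inclusion_bf(
    matrix: np.ndarray,
    labels: np.ndarray,
    feature_index: int,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
) -> float:
    """BF10 for retaining one feature: full model vs the model without it."""
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels, dtype=float)
    A = np.hstack([np.ones((len(X), 1)), X])
    lml_full = _log_marginal_laplace(A, y, prior_scale)
    lml_red = _log_marginal_laplace(np.delete(A, feature_index + 1, axis=1), y, prior_scale)
    return math.exp(min(700.0, lml_full - lml_red))


def predict_proba(
    summary: PosteriorSummary, matrix: np.ndarray, names: Sequence[str]
) -> np.ndarray:
    """P(choice = first) at the posterior mode; with all-zero differences
    and no order bias this is exactly 0.5."""
    beta = np.array([summary.betas[n][0] for n in names])
    return expit(summary.beta0[0] + np.asarray(matrix, dtype=float) @ beta)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVReport:
    k: int
    accuracy: float
    fold_accuracies: tuple
    seed: int


def crossvalidate(
    raw_diffs: np.ndarray,
    labels: np.ndarray,
    k: int = 10,
    seed: int = 0,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
) -> CVReport:
    """Seeded k-fold choice-prediction accuracy.

    Standardization and the fit are redone per training split; held-out
    choices are predicted as "first" iff p > 0.5, with exact ties counted
    incorrect for conservatism.
    """
    X = np.asarray(raw_diffs, dtype=float)
    y = np.asarray(labels, dtype=int)
    n = len(y)
    if n < k:
        raise ValueError("need at least k observations")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    accs = []
    for i in range(k):
        test = folds[i]
        train = np.concatenate([folds[j] for j in range(k) if j != i])
        Ztr, sc = standardize(X[train])
        summ = fit_bradley_terry(
            Ztr, y[train], prior_scale=prior_scale, compute_bf=False
        )
        names = list(summ.betas)
        p = predict_proba(summ, sc.transform(X[test]), names)
        pred = p > 0.5
        correct = (pred == y[test].astype(bool)) & (p != 0.5)
        accs.append(float(np.mean(correct)))
    return CVReport(k=k, accuracy=float(np.mean(accs)), fold_accuracies=tuple(accs), seed=seed)


# ---------------------------------------------------------------------------
# Choice matrices
# ---------------------------------------------------------------------------

def _binomial_bf10(k: int, n: int) -> float:
    """Evidence against p = 0.5 from a beta-binomial with a uniform prior:
    BF10 = B(k+1, n-k+1) / 0.5^n."""
    return math.exp(betaln(k + 1, n - k + 1) + n * math.log(2.0))


def choice_matrix(choices: pd.DataFrame) -> pd.DataFrame:
    """Pairwise preference percentages with Bayes-factor flags.

    One output row per ordered agent pair and density: the percentage of
    comparisons (pooled over presentation orders) in which the row agent
    was preferred over the column agent, the count, BF10 against 50%, and
    a flag for BF10 > 10.  Rows with agent_b = "(all)" give each agent's
    marginal preference across all its pairings.
    """
    if choices.empty:
        raise ValueError("empty choice table")
    recs = []
    for density, sub in choices.groupby("density"):
        agents = sorted(set(sub["agent_first"]) | set(sub["agent_second"]))
        for a in agents:
            marg_w = marg_n = 0
            for b in agents:
                if a == b:
                    continue
                mask = ((sub["agent_first"] == a) & (sub["agent_second"] == b)) | (
                    (sub["agent_first"] == b) & (sub["agent_second"] == a)
                )
                cell = sub[mask]
                if cell.empty:
                    continue
                wins = int(
                    (
                        ((cell["agent_first"] == a) & (cell["choice"] == "first"))
                        | ((cell["agent_second"] == a) & (cell["choice"] == "second"))
                    ).sum()
                )
                n = len(cell)
                bf = _binomial_bf10(wins, n)
                recs.append(
                    {
                        "density": density,
                        "agent_a": a,
                        "agent_b": b,
                        "pct_a_preferred": 100.0 * wins / n,
                        "n": n,
                        "bf10_vs_50pct": bf,
                        "significant": bf > 10.0,
                    }
                )
                marg_w += wins
                marg_n += n
            if marg_n:
                bf = _binomial_bf10(marg_w, marg_n)
                recs.append(
                    {
                        "density": density,
                        "agent_a": a,
                        "agent_b": "(all)",
                        "pct_a_preferred": 100.0 * marg_w / marg_n,
                        "n": marg_n,
                        "bf10_vs_50pct": bf,
                        "significant": bf > 10.0,
                    }
                )
    return pd.DataFrame(recs)
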