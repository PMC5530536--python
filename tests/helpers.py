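"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the logistic oracle
goes through scipy's trust-region Newton minimizer on the exact negative
log-likelihood, and the mode-score helper wraps ground-truth generator
scores so association tests do not depend on the shape-model fit.
"""

import numpy as np

from ankle_ssm.shape_model import ModeScores


def logistic_mle_oracle(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Logistic MLE by full Newton with Armijo backtracking on the exact NLL."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)

    def nll(b):
        eta = X @ b
        return float(np.sum(np.logaddexp(0.0, eta) - y * eta))

    def grad(b):
        mu = 1.0 / (1.0 + np.exp(-(X @ b)))
        return X.T @ (mu - y)

    def hess(b):
        mu = 1.0 / (1.0 + np.exp(-(X @ b)))
        w = mu * (1.0 - mu)
        return (X * w[:, None]).T @ X

    beta = np.zeros(X.shape[1])
    value = nll(beta)
    for _ in range(200):
        g = grad(beta)
        if np.abs(g).max() < 1e-12:
            break
        step = np.linalg.solve(hess(beta), -g)
        t = 1.0
        while t > 1e-12:
            candidate = beta + t * step
            new = nll(candidate)
            if new <= value + 1e-4 * t * float(g @ step):
                break
            t /= 2.0
        beta, value = candidate, new
    return beta


def truth_mode_scores(truth) -> ModeScores:
    """Wrap a cohort's true standardized scores as ModeScores."""
    K = truth.scores.shape[1]
    return ModeScores(
        scores=truth.scores, modes=list(range(K)), standardized=True,
        ankle_ids=truth.ankle_ids,
    )
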