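"""Storey q-values for positive false discovery rate control.

The null proportion pi0 is estimated from the flat right tail of the p-value
histogram: pi0(lambda) = #{p > lambda} / (m*(1 - lambda)) over a lambda grid,
smoothed with a cubic polynomial evaluated at the largest lambda (a bootstrap
MSE-minimizing variant is available). q-values then follow the step-up rule
q(p_(i)) = min_{j >= i} pi0 * m * p_(j) / j, so forcing pi0 = 1 reproduces
the Benjamini-Hochberg adjusted p-values exactly; tied p-values share a q.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["QvalueResult", "estimate_pi0", "storey_qvalues"]

DEFAULT_LAMBDAS = np.round(np.arange(0.0, 0.9001, 0.05), 2)


@dataclass
class QvalueResult:
    pvalues: np.ndarray
    pi0: float
    lambda_grid: np.ndarray
    pi0_lambda: np.ndarray
    qvalues: np.ndarray
    pi0_method: str


def _validate_p(pvalues) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("need a non-empty 1-D vector of p-values")
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1] with no NaN")
    return p


def estimate_pi0(
    pvalues,
    lambdas=DEFAULT_LAMBDAS,
    method: str = "smoother",
    n_boot: int = 100,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Estimate the null proportion pi0; returns (pi0, pi0_lambda grid)."""
    p = _validate_p(pvalues)
    lambdas = np.asarray(lambdas, dtype=float)
    m = p.size
    pi0_lambda = np.array(
        [np.mean(p > lam) / (1.0 - lam) for lam in lambdas]
    )
    if method == "smoother":
        if m < 2 or np.allclose(pi0_lambda, pi0_lambda[0]):
            pi0 = float(pi0_lambda[-1])
        else:
            coeffs = np.polynomial.polynomial.polyfit(lambdas, pi0_lambda, deg=3)
            pi0 = float(np.polynomial.polynomial.polyval(lambdas.max(), coeffs))
    elif method == "bootstrap":
        # Storey & Tibshirani bootstrap: pick the lambda minimizing estimated
        # MSE against the minimum pi0(lambda) over the grid
        rng = np.random.default_rng(seed)
        min_pi0 = pi0_lambda.min()
        mse = np.zeros_like(lambdas)
        for _ in range(n_boot):
            pb = rng.choice(p, size=m, replace=True)
            pi0_b = np.array(
                [np.mean(pb > lam) / (1.0 - lam) for lam in lambdas]
            )
            mse += (pi0_b - min_pi0) ** 2
        pi0 = float(pi0_lambda[np.argmin(mse)])
    else:
        raise ValueError("method must be 'smoother' or 'bootstrap'")
    pi0 = float(np.clip(pi0, 1.0 / m if m else 1e-8, 1.0))
    return pi0, pi0_lambda


def storey_qvalues(
    pvalues,
    lambdas=DEFAULT_LAMBDAS,
    pi0: float | None = None,
    pi0_method: str = "smoother",
) -> QvalueResult:
    """Compute Storey q-values for a family of p-values.

    ``pi0`` may be supplied to bypass estimation (pi0=1 gives BH step-up).
    """
    p = _validate_p(pvalues)
    m = p.size
    lambdas = np.asarray(lambdas, dtype=float)
    if pi0 is None:
        pi0_hat, pi0_lambda = estimate_pi0(p, lambdas, method=pi0_method)
    else:
        if not 0.0 < pi0 <= 1.0:
            raise ValueError("pi0 must lie in (0, 1]")
        pi0_hat = float(pi0)
        pi0_lambda = np.array(
            [np.mean(p > lam) / (1.0 - lam) for lam in lambdas]
        )

    order = np.argsort(p, kind="mergesort")
    p_sorted = p[order]
    ranks = np.arange(1, m + 1, dtype=float)
    raw = pi0_hat * m * p_sorted / ranks
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    # tied p-values share the smallest q in their tie group
    first_of_tie = np.searchsorted(p_sorted, p_sorted, side="left")
    q_sorted = q_sorted[first_of_tie]
    q = np.empty(m)
    q[order] = q_sorted
    return QvalueResult(
        pvalues=p,
        pi0=pi0_hat,
        lambda_grid=lambdas,
        pi0_lambda=pi0_lambda,
        qvalues=q,
        pi0_method="fixed" if pi0 is not None else pi0_method,
    )
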