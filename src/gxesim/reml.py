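"""Reaction-norm mixed model fitted by restricted maximum likelihood.

The model for phenotype y_j with environmental covariate c_j is

    y = mu*1 + a0 + c o a1 + e,    [a0; a1] ~ N(0, VC (x) K),   e ~ N(0, I*ve)

where K is a relationship matrix (pedigree A or genomic G), VC the 2x2
covariance of the random intercept and slope, and "o" the elementwise product.
The phenotypic covariance is therefore

    V = va0*K + cov*(KD + DK) + va1*DKD + ve*I,   D = diag(c),

and REML maximizes the restricted log-likelihood

    lR = -1/2 [ log|V| + log|X'V^-1 X| + y'Py + (n-p) log 2pi ]

over a log-Cholesky parameterization of VC plus log(ve), which keeps VC
positive semi-definite throughout.  Optimization uses L-BFGS-B with numerical
gradients; a finite-difference Hessian at the optimum provides approximate
standard errors and flags non-identifiable fits (e.g. K = I with c = 0, where
va0 and ve are jointly unidentifiable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .config import ValidationError

_BIG = 1e12
_LOG_BOUND = 12.0


class ReactionNormModel:
    """Random-regression (reaction-norm) mixed model for one trait.

    Parameters
    ----------
    y : array
        Phenotypes, length n.
    c : array
        Environmental covariate, length n, entered exactly as recorded.
    K : array
        n x n symmetric PSD relationship matrix aligned with y.
    X : array, optional
        Fixed-effect design matrix; defaults to an intercept column.
    """

    def __init__(self, y, c, K, X=None):
        self.y = np.asarray(y, dtype=float).ravel()
        self.c = np.asarray(c, dtype=float).ravel()
        self.K = np.asarray(K, dtype=float)
        n = self.y.size
        if self.c.size != n or self.K.shape != (n, n):
            raise ValidationError("y, c and K dimensions must agree")
        if not np.allclose(self.K, self.K.T, atol=1e-8):
            raise ValidationError("K must be symmetric")
        self.X = np.ones((n, 1)) if X is None else np.asarray(X, dtype=float)
        self.nobs = n
        # precomputed covariance building blocks
        self._KD = self.K * self.c[None, :]
        self._cross = self._KD + self._KD.T  # KD + DK
        self._DKD = self.K * np.outer(self.c, self.c)

    # -- likelihood ---------------------------------------------------------

    def _build_V(self, va0, cov, va1, ve):
        V = va0 * self.K + cov * self._cross + va1 * self._DKD
        V[np.diag_indices_from(V)] += ve
        return V

    def neg2_restricted_loglike(self, va0, cov, va1, ve):
        """-2 lR at the given variance components (including constants)."""
        n, p = self.nobs, self.X.shape[1]
        V = self._build_V(va0, cov, va1, ve)
        try:
            L = linalg.cholesky(V, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return _BIG
        logdetV = 2.0 * np.sum(np.log(np.diag(L)))
        ViX = linalg.cho_solve((L, True), self.X, check_finite=False)
        Viy = linalg.cho_solve((L, True), self.y, check_finite=False)
        XtViX = self.X.T @ ViX
        sign, logdetX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return _BIG
        beta = np.linalg.solve(XtViX, self.X.T @ Viy)
        Py = Viy - ViX @ beta
        quad = float(self.y @ Py)
        return logdetV + logdetX + quad + (n - p) * np.log(2.0 * np.pi)

    def restricted_loglike(self, va0, cov, va1, ve):
        return -0.5 * self.neg2_restricted_loglike(va0, cov, va1, ve)

    # -- parameterization ---------------------------------------------------

    @staticmethod
    def _theta_to_vc(theta):
        s0 = np.exp(theta[0])
        t = theta[1]
        s1 = np.exp(theta[2])
        ve = np.exp(theta[3])
        return s0 * s0, s0 * t, t * t + s1 * s1, ve

    def _objective(self, theta):
        va0, cov, va1, ve = self._theta_to_vc(theta)
        return self.neg2_restricted_loglike(va0, cov, va1, ve)

    def _start(self):
        vy = float(np.var(self.y))
        vc2 = max(float(np.mean(self.c**2)), 1e-8)
        va0 = max(vy / 3.0, 1e-6)
        va1 = max(vy / (3.0 * vc2), 1e-6)
        ve = max(vy / 3.0, 1e-6)
        return np.array([0.5 * np.log(va0), 0.0, 0.5 * np.log(va1), np.log(ve)])

    # -- fitting ------------------------------------------------------------

    def fit(self, start=None, maxiter=500, tol=1e-8, compute_se=True):
        """Maximize the restricted likelihood; returns ReactionNormResults."""
        theta0 = self._start() if start is None else np.asarray(start, dtype=float)
        bounds = [
            (-_LOG_BOUND, _LOG_BOUND),
            (-1e3, 1e3),
            (-_LOG_BOUND, _LOG_BOUND),
            (-_LOG_BOUND, _LOG_BOUND),
        ]
        res = optimize.minimize(
            self._objective,
            theta0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-7},
        )
        va0, cov, va1, ve = self._theta_to_vc(res.x)
        llf = -0.5 * res.fun
        hess_cond = np.inf
        bse = None
        if compute_se:
            H = _fd_hessian(self._objective, res.x)
            hess_cond = float(np.linalg.cond(H))
            bse = self._delta_se(res.x, H)
        return ReactionNormResults(
            model=self,
            va0=va0,
            cov_a0_a1=cov,
            va1=va1,
            ve0=ve,
            llf=llf,
            converged=bool(res.success),
            n_iter=int(res.nit),
            message=str(res.message),
            theta=res.x,
            hessian_condition=hess_cond,
            bse=bse,
        )

    def _delta_se(self, theta, H):
        """Approximate SEs of (va0, cov, va1, ve0) by the delta method."""
        try:
            cov_theta = 2.0 * np.linalg.pinv(H)  # lR = -n2ll/2
        except np.linalg.LinAlgError:
            return None
        eps = 1e-5
        J = np.zeros((4, 4))
        base = np.array(self._theta_to_vc(theta))
        for k in range(4):
            th = theta.copy()
            th[k] += eps
            J[:, k] = (np.array(self._theta_to_vc(th)) - base) / eps
        cov_nat = J @ cov_theta @ J.T
        var = np.clip(np.diag(cov_nat), 0.0, None)
        return np.sqrt(var)


def _fd_hessian(fun, x, eps=1e-4):
    n = x.size
    H = np.zeros((n, n))
    f0 = fun(x)
    fp = np.zeros(n)
    for i in range(n):
        xi = x.copy()
        xi[i] += eps
        fp[i] = fun(xi)
    for i in range(n):
        for j in range(i, n):
            xij = x.copy()
            xij[i] += eps
            xij[j] += eps
            fij = fun(xij)
            H[i, j] = H[j, i] = (fij - fp[i] - fp[j] + f0) / eps**2
    return H


@dataclass
class ReactionNormResults:
    """REML estimates of the reaction-norm variance components."""

    model: ReactionNormModel
    va0: float
    cov_a0_a1: float
    va1: float
    ve0: float
    llf: float
    converged: bool
    n_iter: int
    message: str
    theta: np.ndarray
    hessian_condition: float = np.inf
    bse: np.ndarray | None = field(default=None)

    PARAM_NAMES = ("Var(a0)", "Cov(a0,a1)", "Var(a1)", "Var(e0)")

    @property
    def params(self) -> pd.Series:
        return pd.Series(
            [self.va0, self.cov_a0_a1, self.va1, self.ve0], index=self.PARAM_NAMES
        )

    @property
    def genetic_vcov(self) -> np.ndarray:
        return np.array([[self.va0, self.cov_a0_a1], [self.cov_a0_a1, self.va1]])

    @property
    def near_singular(self) -> bool:
        """True when the curvature of -2lR is numerically rank-deficient,
        i.e. some variance-component direction is unidentifiable."""
        return not np.isfinite(self.hessian_condition) or self.hessian_condition > 1e8

    def summary(self) -> str:
        lines = [
            "Reaction-norm REML results",
            "=" * 46,
            f"No. observations:      {self.model.nobs}",
            f"Restricted loglike:    {self.llf:.4f}",
            f"Converged:             {self.converged} ({self.n_iter} iterations)",
            f"Identifiable:          {not self.near_singular} "
            f"(Hessian condition {self.hessian_condition:.3g})",
            "-" * 46,
            f"{'parameter':<14}{'estimate':>12}{'std err':>12}",
        ]
        se = self.bse if self.bse is not None else [np.nan] * 4
        for name, val, s in zip(self.PARAM_NAMES, self.params, se):
            lines.append(f"{name:<14}{val:>12.4f}{s:>12.4f}")
        lines.append("=" * 46)
        return "\n".join(lines)


def summarize_replicates(
    estimates: list,
    assigned: dict | None = None,
) -> pd.DataFrame:
    """Across-replicate mean and SD of the four variance components.

    Rows follow the conventional report order Var(a0), Cov(a0,a1), Var(a1),
    Var(e0); the ``report`` column formats each as ``mean(SD)``.
    """
    if len(estimates) < 2:
        raise ValidationError("need at least 2 replicates to summarize")
    mat = np.array([res.params.to_numpy() for res in estimates])
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    out = pd.DataFrame(
        {
            "parameter": list(ReactionNormResults.PARAM_NAMES),
            "mean": mean,
            "sd": sd,
            "report": [f"{m:.3f}({s:.3f})" for m, s in zip(mean, sd)],
            "n_replicates": len(estimates),
        }
    )
    if assigned is not None:
        out.insert(1, "assigned", [assigned.get(p, np.nan) for p in out["parameter"]])
    return out
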