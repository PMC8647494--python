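"""Environmental values and reaction-norm phenotypes.

The environmental value of individual j decomposes as c_j = beta_j + eps_j,
where beta_j is its breeding value for the genetic environmental component and
eps_j a residual.  The phenotype follows the reaction norm

    full:    y = a0 + a1*c + e0 + e1*c      (heterogeneous residual variance)
    reduced: y = a0 + a1*c + e0             (homogeneous residual)

with (e0, e1, eps) drawn per individual from a zero-mean multivariate normal.
Setting the beta variance and the (e0,eps)/(e1,eps) covariances to zero
decouples c from y genetically: the environment carries no genetic signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ValidationError, check_psd

RESIDUAL_COMPONENTS = ("e0", "e1", "eps")
MODEL_FORMS = ("full", "reduced")


@dataclass
class PhenotypeTable:
    """Per-individual phenotype records; y is reconstructable from components."""

    data: pd.DataFrame  # id, y, c, tbv_a0, tbv_beta, tbv_a1, e0, e1, eps, ...
    model: str

    def reconstruct_y(self) -> np.ndarray:
        d = self.data
        y = d["tbv_a0"] + d["tbv_a1"] * d["c"] + d["e0"]
        if self.model == "full":
            y = y + d["e1"] * d["c"]
        return y.to_numpy()


def sample_residual_triplets(
    rvcov: np.ndarray,
    n: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """n i.i.d. (e0, e1, eps) draws from N(0, rvcov); shape (n, 3)."""
    rvcov = check_psd(rvcov, "residual variance-covariance")
    if rvcov.shape[0] != 3:
        raise ValidationError("residual variance-covariance must be 3x3 (e0, e1, eps)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multivariate_normal(np.zeros(3), rvcov, size=n, method="svd")


def compose_environment(tbv_beta: np.ndarray, epsilon: np.ndarray) -> np.ndarray:
    """Environmental value c = beta + eps."""
    tbv_beta = np.asarray(tbv_beta, dtype=float)
    epsilon = np.asarray(epsilon, dtype=float)
    if tbv_beta.shape != epsilon.shape:
        raise ValidationError("beta and eps columns must have equal length")
    return tbv_beta + epsilon


def compose_phenotype(
    tbv: np.ndarray,
    c: np.ndarray,
    residuals: np.ndarray,
    model: str = "reduced",
    ids: np.ndarray | None = None,
) -> PhenotypeTable:
    """Assemble the phenotype table from TBV components, c and residuals.

    *tbv* holds the (a0, beta, a1) columns, *residuals* the (e0, e1, eps)
    columns; rows are aligned with the population's individuals.
    """
    if model not in MODEL_FORMS:
        raise ValidationError(f"unknown model form {model!r}")
    tbv = np.atleast_2d(np.asarray(tbv, dtype=float))
    residuals = np.atleast_2d(np.asarray(residuals, dtype=float))
    if tbv.shape[1] != 3 or residuals.shape[1] != 3:
        raise ValidationError("expected 3 TBV components and 3 residual components")
    n = tbv.shape[0]
    c = np.asarray(c, dtype=float)
    if residuals.shape[0] != n or c.shape[0] != n:
        raise ValidationError("tbv, c and residual rows must align")
    e0, e1 = residuals[:, 0], residuals[:, 1]
    y = tbv[:, 0] + tbv[:, 2] * c + e0
    if model == "full":
        y = y + e1 * c
    if ids is None:
        ids = np.arange(1, n + 1, dtype=np.int64)
    data = pd.DataFrame(
        {
            "id": ids,
            "y": y,
            "c": c,
            "tbv_a0": tbv[:, 0],
            "tbv_beta": tbv[:, 1],
            "tbv_a1": tbv[:, 2],
            "e0": e0,
            "e1": e1,
            "eps": residuals[:, 2],
        }
    )
    return PhenotypeTable(data, model)


def variance_profile(
    gvcov: np.ndarray,
    rvcov: np.ndarray,
    c_grid: np.ndarray,
    model: str = "reduced",
) -> pd.DataFrame:
    """Genetic, residual and total variance and heritability along c.

    With the (a0, beta, a1) genetic matrix G and (e0, e1, eps) residual matrix
    R, the genetic variance at environment c is
    G[a0,a0] + 2c*G[a0,a1] + c^2*G[a1,a1]; the residual variance is
    R[e0,e0] (+ 2c*R[e0,e1] + c^2*R[e1,e1] under the full model).
    """
    if model not in MODEL_FORMS:
        raise ValidationError(f"unknown model form {model!r}")
    gvcov = check_psd(gvcov, "genetic variance-covariance")
    rvcov = check_psd(rvcov, "residual variance-covariance")
    c = np.atleast_1d(np.asarray(c_grid, dtype=float))
    if not np.all(np.isfinite(c)):
        raise ValidationError("environment grid must be finite")
    g = gvcov[0, 0] + 2.0 * c * gvcov[0, 2] + c**2 * gvcov[2, 2]
    if model == "full":
        r = rvcov[0, 0] + 2.0 * c * rvcov[0, 1] + c**2 * rvcov[1, 1]
    else:
        r = np.full_like(c, rvcov[0, 0])
    total = g + r
    return pd.DataFrame(
        {
            "c": c,
            "genetic_variance": g,
            "residual_variance": r,
            "total_variance": total,
            "heritability": g / total,
        }
    )
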