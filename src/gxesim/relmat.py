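"""Pedigree (A) and genomic (G) additive relationship matrices.

A follows Henderson's tabular method on a topologically ordered pedigree.
G is the first-method genomic relationship: centered allele dosages
Z = M - 2p cross-multiplied and scaled by 2*sum p(1-p), with a small ridge on
the diagonal so the matrix stays invertible for mixed-model use.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ValidationError


def build_A(pedigree: pd.DataFrame) -> np.ndarray:
    """Numerator relationship matrix in pedigree order (tabular method).

    *pedigree* needs ``id``, ``sire`` and ``dam`` columns with 0 for unknown
    parents; every known parent must appear before its offspring.
    """
    ids = pedigree["id"].to_numpy()
    pos = {int(i): k for k, i in enumerate(ids)}
    n = ids.size
    sire = np.full(n, -1, dtype=np.intp)
    dam = np.full(n, -1, dtype=np.intp)
    for k, (s, d) in enumerate(zip(pedigree["sire"].to_numpy(), pedigree["dam"].to_numpy())):
        for arr, parent in ((sire, int(s)), (dam, int(d))):
            if parent == 0:
                continue
            if parent not in pos or pos[parent] >= k:
                raise ValidationError(
                    f"pedigree is not topologically ordered: parent {parent} does not "
                    f"precede individual {int(ids[k])}"
                )
            arr[k] = pos[parent]
    A = np.zeros((n, n))
    for j in range(n):
        s, d = sire[j], dam[j]
        row = np.zeros(j)
        if s >= 0:
            row += 0.5 * A[s, :j]
        if d >= 0:
            row += 0.5 * A[d, :j]
        A[j, :j] = row
        A[:j, j] = row
        A[j, j] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return A


def build_G(
    dosages: np.ndarray,
    freqs: np.ndarray,
    ridge: float = 1e-6,
) -> np.ndarray:
    """Genomic relationship matrix from 0/1/2 dosages and allele frequencies."""
    M = np.asarray(dosages, dtype=float)
    p = np.asarray(freqs, dtype=float)
    if M.ndim != 2 or M.shape[1] != p.size:
        raise ValidationError("dosage columns must match the frequency vector")
    if p.size < 2:
        raise ValidationError("need at least 2 markers to build G")
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValidationError(
            "monomorphic marker in input (frequency outside (0,1)); filter upstream"
        )
    Z = M - 2.0 * p[None, :]
    denom = 2.0 * np.sum(p * (1.0 - p))
    G = (Z @ Z.T) / denom
    G[np.diag_indices_from(G)] += ridge
    return G


def write_lower_triangle(mat: np.ndarray, path) -> None:
    """Export a relationship matrix as whitespace 'row col value' lower triangle."""
    with open(path, "w") as fh:
        fh.write("# gxesim v1 relationship matrix (1-based row col value)\n")
        for i in range(mat.shape[0]):
            for j in range(i + 1):
                fh.write(f"{i + 1} {j + 1} {mat[i, j]:.10g}\n")
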