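"""Independent brute-force oracles used by the test suite only."""

import numpy as np


def gene_drop_relationship(pedigree, n_drops: int = 100_000, seed: int = 0) -> np.ndarray:
    """Monte-Carlo additive relationship (2 x kinship) by gene dropping.

    Founders receive unique allele labels; alleles are dropped through the
    pedigree with fair Mendelian sampling.  The kinship of i and j is the
    probability that one allele drawn at random from each is identical by
    descent, estimated over *n_drops* independent drops.
    """
    rng = np.random.default_rng(seed)
    ids = pedigree["id"].to_numpy()
    pos = {int(i): k for k, i in enumerate(ids)}
    n = ids.size
    alleles = np.zeros((n, 2, n_drops), dtype=np.int32)
    label = 1
    for k in range(n):
        s, d = int(pedigree["sire"].iloc[k]), int(pedigree["dam"].iloc[k])
        for slot, parent in ((0, s), (1, d)):
            if parent == 0:
                alleles[k, slot, :] = label
                label += 1
            else:
                p = pos[parent]
                pick = rng.integers(0, 2, size=n_drops)
                alleles[k, slot, :] = alleles[p, pick, np.arange(n_drops)]
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            match = 0.0
            for a in range(2):
                for b in range(2):
                    match += np.mean(alleles[i, a] == alleles[j, b])
            A[i, j] = A[j, i] = match / 2.0  # 2 * kinship
    return A


def naive_tbv(dosages: np.ndarray, effects: np.ndarray) -> np.ndarray:
    """Per-individual loop computation of centered breeding values."""
    n, t = dosages.shape[0], effects.shape[1]
    tbv = np.zeros((n, t))
    for j in range(n):
        for comp in range(t):
            acc = 0.0
            for i in range(dosages.shape[1]):
                acc += dosages[j, i] * effects[i, comp]
            tbv[j, comp] = acc
    return tbv - tbv.mean(axis=0, keepdims=True)
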