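"""Independent brute-force oracles used by the tests.

These deliberately re-derive every quantity from first principles (explicit
loops, np.delete, textbook formulas) and share no code path with the
package implementation they check.
"""

import numpy as np


def brute_force_loo_z(pooled: np.ndarray) -> np.ndarray:
    """Leave-one-as-singleton z for every row, one relabeling at a time."""
    m, n_patches = pooled.shape
    out = np.full((m, n_patches), np.nan)
    for i in range(m):
        others = np.delete(pooled, i, axis=0)
        for k in range(n_patches):
            col = others[:, k]
            mu = col.mean()
            sd = col.std(ddof=1)
            if sd > 0 and np.isfinite(pooled[i, k]):
                out[i, k] = (pooled[i, k] - mu) / sd
    return out


def brute_force_pvalues(pooled: np.ndarray) -> np.ndarray:
    """Permutation p for row 0 (the patient): tie-inclusive count of
    relabelings with z <= the observed z, over all m relabelings."""
    z = brute_force_loo_z(pooled)
    m, n_patches = z.shape
    p = np.full(n_patches, np.nan)
    for k in range(n_patches):
        obs = z[0, k]
        if not np.isfinite(obs):
            continue
        count = 0
        for r in range(m):
            if np.isfinite(z[r, k]) and z[r, k] <= obs:
                count += 1
        p[k] = count / m
    return p


def crawford_howell_t(patient_value: float, control_values: np.ndarray):
    """Single-case t-test against a control sample (closed form)."""
    x = np.asarray(control_values, dtype=float)
    n = x.size
    t = (patient_value - x.mean()) / (x.std(ddof=1) * np.sqrt(1.0 + 1.0 / n))
    return t, n - 1


def bh_stepup(p: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini-Hochberg by the literal step-up definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * alpha / m:
            k_star = rank
    reject = np.zeros(m, dtype=bool)
    if k_star:
        thresh = p[order[k_star - 1]]
        reject = p <= thresh
    return reject
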