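"""Independent oracles used by the test suite.

These deliberately re-derive quantities along a different computational path
than the package: Henderson's mixed-model equations assembled explicitly as
dense matrices, and brute-force record-level recomputations.
"""

import numpy as np


def henderson_genotype_blups(values: np.ndarray, vg: float, vge: float,
                             vr: float) -> np.ndarray:
    """Solve the mixed-model equations for the genotype effects.

    ``values`` has shape (n_genotypes, n_treatments, n_reps).  Treatment is
    fixed (cell-mean coding), genotype and genotype x treatment random with
    the given variance components.  Returns the predicted genotype effects
    g_hat (length n), i.e. deviations from the fixed part.
    """
    n, t, r = values.shape
    N = n * t * r
    y = values.reshape(N)
    # design: observation order (genotype, treatment, replicate)
    X = np.zeros((N, t))
    Zg = np.zeros((N, n))
    Zu = np.zeros((N, n * t))
    row = 0
    for i in range(n):
        for j in range(t):
            for _ in range(r):
                X[row, j] = 1.0
                Zg[row, i] = 1.0
                Zu[row, i * t + j] = 1.0
                row += 1
    lam_g = vr / vg
    lam_u = vr / vge
    W = np.hstack([X, Zg, Zu])
    C = W.T @ W
    C[t:t + n, t:t + n] += lam_g * np.eye(n)
    C[t + n:, t + n:] += lam_u * np.eye(n * t)
    rhs = W.T @ y
    sol = np.linalg.lstsq(C, rhs, rcond=None)[0]
    return sol[t:t + n]


def brute_force_cell_means(df, trait):
    """Group-by mean over records, computed without pandas pivoting."""
    sums, counts = {}, {}
    for _, rec in df.iterrows():
        if rec["trait"] != trait or rec["value"] != rec["value"]:
            continue
        key = (rec["genotype"], rec["treatment"])
        sums[key] = sums.get(key, 0.0) + rec["value"]
        counts[key] = counts.get(key, 0) + 1
    return {k: sums[k] / counts[k] for k in sums}


def brute_force_consensus(results):
    """Rank-averaging recomputed with plain sorting."""
    genos = list(results.index)

    def ranks(vals, ascending):
        order = sorted(vals.values())
        if not ascending:
            order = order[::-1]
        # average rank for ties
        out = {}
        for g, v in vals.items():
            positions = [i + 1 for i, x in enumerate(order) if x == v]
            out[g] = sum(positions) / len(positions)
        return out

    r1 = ranks(dict(results["DSI"]), True)
    r2 = ranks(dict(results["TOL"]), True)
    r3 = ranks(dict(results["STI"]), False)
    r4 = ranks(dict(results["YSI"]), False)
    avg = {g: (r1[g] + r2[g] + r3[g] + r4[g]) / 4 for g in genos}
    order = sorted(genos, key=lambda g: (avg[g], g))
    return {g: i + 1 for i, g in enumerate(order)}
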