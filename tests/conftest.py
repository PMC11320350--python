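import numpy as np
import pandas as pd
import pytest

from protclock import ProteinMatrix, SimulationParams, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """400 participants x 30 proteins, 3 causal — shared read-only fixture."""
    params = SimulationParams(n_participants=400, n_proteins=30,
                              n_causal_proteins=3, seed=42)
    return generate_cohort(params)


@pytest.fixture()
def toy_matrix():
    rng = np.random.default_rng(7)
    vals = pd.DataFrame(rng.normal(size=(8, 5)),
                        index=[f"ID{i}" for i in range(8)],
                        columns=[f"P{j}" for j in range(5)])
    return ProteinMatrix(vals)


def newton_cox_breslow(X, time, event, tol=1e-12, max_iter=200):
    """Independent unpenalized Cox oracle: Newton-Raphson on the Breslow
    partial likelihood, written directly from the definition (O(n^2) risk
    sets, no shared code with the package implementation)."""
    X = np.asarray(X, dtype=float)
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        r = np.exp(eta)
        U = np.zeros(p)
        H = np.zeros((p, p))
        for i in range(n):
            if d[i] != 1:
                continue
            risk = t >= t[i]
            s0 = r[risk].sum()
            s1 = (r[risk, None] * X[risk]).sum(axis=0)
            s2 = (r[risk, None, None] * X[risk, :, None] * X[risk, None, :]).sum(axis=0)
            U += X[i] - s1 / s0
            H += s2 / s0 - np.outer(s1, s1) / s0**2
        step = np.linalg.solve(H, U)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def brute_force_concordance(time, event, risk):
    """Harrell's C by pair enumeration: comparable pairs are those whose
    shorter time is an event; risk ties count 1/2."""
    t = np.asarray(time, float)
    d = np.asarray(event, int)
    r = np.asarray(risk, float)
    conc = comp = 0.0
    n = len(t)
    for i in range(n):
        for j in range(i + 1, n):
            if t[i] == t[j]:
                continue  # Harrell: equal times not comparable unless... skip
            a, b = (i, j) if t[i] < t[j] else (j, i)
            if d[a] != 1:
                continue
            comp += 1
            if r[a] > r[b]:
                conc += 1
            elif r[a] == r[b]:
                conc += 0.5
    if comp == 0:
        raise ValueError("no comparable pairs")
    return conc / comp, int(comp)


def brute_force_bh(p):
    """Step-up BH from the definition: q_i = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out
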