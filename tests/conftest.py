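import numpy as np
import pytest
from scipy.optimize import minimize

import acpsmo as a


def qp_dual_oracle(X, y, C, kernel):
    """Independent reference for the SVM dual: SLSQP on the QP.

    Returns (objective, lambdas) maximizing sum(l) - 0.5 l'Ql under the box
    and equality constraints, from two starts to dodge poor local behavior.
    """
    K = a.kernel_matrix(X, X, kernel)
    Q = K * np.outer(y, y)
    m = len(y)
    cons = [{"type": "eq", "fun": lambda l: l @ y, "jac": lambda l: y}]
    best_obj, best_lam = -np.inf, None
    for x0 in (np.zeros(m), np.full(m, C / 2)):
        r = minimize(
            lambda l: -(l.sum() - 0.5 * l @ Q @ l),
            x0,
            jac=lambda l: -(np.ones(m) - Q @ l),
            bounds=[(0, C)] * m,
            constraints=cons,
            method="SLSQP",
            options={"maxiter": 500, "ftol": 1e-12},
        )
        if -r.fun > best_obj:
            best_obj, best_lam = -r.fun, r.x
    return best_obj, best_lam


def oracle_bias(X, y, lam, C, kernel, edge=1e-6):
    """The KKT-consistent bias for a multiplier vector: mean over free
    support vectors, else the midpoint of the feasible interval."""
    s = a.kernel_matrix(X, X, kernel) @ (lam * y)
    free = (lam > edge) & (lam < C - edge)
    if free.any():
        return float(np.mean(y[free] - s[free]))
    lo, hi = -np.inf, np.inf
    for i in range(len(y)):
        bound = y[i] - s[i]
        at_zero = lam[i] <= edge
        if (at_zero and y[i] > 0) or (not at_zero and y[i] < 0):
            lo = max(lo, bound)
        if (at_zero and y[i] < 0) or (not at_zero and y[i] > 0):
            hi = min(hi, bound)
    if np.isfinite(lo) and np.isfinite(hi):
        return 0.5 * (lo + hi)
    return lo if np.isfinite(lo) else hi


def random_tiny_problem(rng, trial):
    """One random SVM problem with at most 8 points, both classes present."""
    m = int(rng.integers(3, 9))
    d = int(rng.integers(1, 4))
    X = rng.normal(size=(m, d))
    y = np.r_[1.0, -1.0, rng.choice([1.0, -1.0], m - 2)]
    if trial % 2 == 0:
        kernel = a.KernelSpec("linear")
    else:
        kernel = a.KernelSpec("rbf", gamma=float(rng.uniform(0.2, 2.0)))
    C = float(rng.choice([0.5, 1.0, 10.0]))
    return X, y, C, kernel


@pytest.fixture(scope="session")
def strong_benchmark():
    """200 peptides per class with a strong compositional class contrast."""
    return a.make_benchmark("strong", 200, seed=11)


@pytest.fixture(scope="session")
def strong_benchmark_aac(strong_benchmark):
    pos, neg = strong_benchmark
    spec = a.FeatureSpec(("AAC",))
    X = np.vstack([a.encode_set(pos, spec)[0], a.encode_set(neg, spec)[0]])
    y = np.r_[np.ones(len(pos)), -np.ones(len(neg))]
    return X, y


@pytest.fixture(scope="session")
def null_benchmark_aac():
    pos, neg = a.make_benchmark("null", 200, seed=13)
    spec = a.FeatureSpec(("AAC",))
    X = np.vstack([a.encode_set(pos, spec)[0], a.encode_set(neg, spec)[0]])
    y = np.r_[np.ones(len(pos)), -np.ones(len(neg))]
    return X, y


def random_peptides(rng, n, min_len=2, max_len=50, prefix="r"):
    residues = np.array(list(a.ALPHABET))
    peps = []
    for i in range(n):
        L = int(rng.integers(min_len, max_len + 1))
        peps.append(a.Peptide(f"{prefix}{i}", "".join(rng.choice(residues, L))))
    return a.PeptideSet(peps, name=prefix)
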