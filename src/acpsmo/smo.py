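"""Soft-margin SVM trained by sequential minimal optimization (SMO).

The classifier solves the dual of the soft-margin SVM,

    max_λ  Σ_j λ_j − ½ Σ_j Σ_k λ_j λ_k y_j y_k K(x_j, x_k)
    s.t.   0 ≤ λ_j ≤ C,   Σ_j y_j λ_j = 0,

by repeatedly picking two multipliers and solving their two-variable
subproblem analytically along the equality-constraint line
λ₁y₁ + λ₂y₂ = const, clipped to the [0, C] box.  Working-set selection
follows Platt's two-loop heuristic: an outer loop alternating full passes
with passes over non-bound points, and a second-choice heuristic that
maximizes |E₁ − E₂| with randomized fallback scans.  For linear kernels the
explicit weight vector is maintained incrementally,

    w_new = w + y₁(λ₁ⁿᵉʷ − λ₁)x₁ + y₂(λ₂ⁿᵉʷ'ᶜˡᶦᵖᵖᵉᵈ − λ₂)x₂.

Decision values f(x) = Σ λ_j y_j K(x_j, x) + b are mapped to class
probabilities P⁺ = 1/(1 + exp(A·f + B)) by Platt's sigmoid fit with
target smoothing (`fit_platt`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import FeatureMismatchError, NotCalibratedError


# ---------------------------------------------------------------------------
# kernels

@dataclass(frozen=True)
class KernelSpec:
    """Kernel choice: ``linear`` (dot product) or ``rbf`` (gamma > 0)."""

    kind: str = "linear"
    gamma: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "rbf"):
            raise ValueError(f"unknown kernel {self.kind!r}")
        if self.kind == "rbf" and (self.gamma is None or self.gamma <= 0):
            raise ValueError("rbf kernel requires gamma > 0")


def kernel_eval(a: np.ndarray, b: np.ndarray, spec: KernelSpec) -> float:
    """K(a, b) for a single pair of vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise FeatureMismatchError(f"dimension mismatch: {a.shape} vs {b.shape}")
    if spec.kind == "linear":
        return float(a @ b)
    d = a - b
    return float(np.exp(-spec.gamma * (d @ d)))


def kernel_matrix(X: np.ndarray, Z: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Gram matrix K[i, j] = K(X[i], Z[j])."""
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if X.shape[1] != Z.shape[1]:
        raise FeatureMismatchError(f"dimension mismatch: {X.shape[1]} vs {Z.shape[1]}")
    if spec.kind == "linear":
        return X @ Z.T
    sq = (X**2).sum(1)[:, None] + (Z**2).sum(1)[None, :] - 2.0 * (X @ Z.T)
    return np.exp(-spec.gamma * np.maximum(sq, 0.0))


# ---------------------------------------------------------------------------
# problem and model containers

@dataclass(frozen=True)
class TrainingProblem:
    """A binary training set with labels in {+1, −1} and a box constraint C."""

    x: np.ndarray
    y: np.ndarray
    C: float = 1.0
    kernel: KernelSpec = KernelSpec()
    tolerance: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.ndim != 2 or len(y) != len(x):
            raise ValueError("x must be (m, d) with one label per row")
        if len(x) < 2:
            raise ValueError("need at least two training points")
        if not np.isfinite(x).all():
            raise ValueError("non-finite feature values")
        if not set(np.unique(y)) == {-1.0, 1.0}:
            raise ValueError("labels must contain both +1 and -1")
        if self.C <= 0:
            raise ValueError("C must be positive")


@dataclass
class SvmModel:
    """A trained (optionally calibrated) SVM.

    Stores the full multiplier vector λ alongside the training data so the
    kernel expansion f(x) = Σ λ_j y_j K(x_j, x) + b can be evaluated;
    `support_index` lists the points with λ > 0.  For linear kernels `w`
    holds the explicit weight vector.  `platt_a` / `platt_b` are the
    sigmoid calibration parameters (None until `fit_platt` has run).
    """

    x: np.ndarray
    y: np.ndarray
    lambdas: np.ndarray
    bias: float
    kernel: KernelSpec
    C: float
    w: Optional[np.ndarray] = None
    platt_a: Optional[float] = None
    platt_b: Optional[float] = None
    dual_objective: float = 0.0
    feature_fingerprint: str = ""

    @property
    def support_index(self) -> np.ndarray:
        return np.flatnonzero(self.lambdas > 0)

    @property
    def is_calibrated(self) -> bool:
        return self.platt_a is not None and self.platt_b is not None


def dual_objective(problem: TrainingProblem, lambdas: np.ndarray) -> float:
    """The dual value W(λ) = Σλ − ½ Σ λλ' y y' K — the quantity SMO maximizes."""
    lam = np.asarray(lambdas, dtype=float)
    if lam.shape != (len(problem.x),):
        raise ValueError("one multiplier per training point required")
    K = kernel_matrix(problem.x, problem.x, problem.kernel)
    u = lam * problem.y
    return float(lam.sum() - 0.5 * (u @ K @ u))


# ---------------------------------------------------------------------------
# the SMO trainer

class SmoTrainer:
    """Mutable optimizer state for one training problem.

    Exposes `take_step` (the analytic two-multiplier update) and `solve`
    (Platt's outer loop).  `eps` is the minimum multiplier change accepted
    as progress; `debug=True` additionally asserts after every accepted
    step that the dual objective did not decrease and that dual
    feasibility (0 ≤ λ ≤ C, Σyλ = 0) still holds.
    """

    def __init__(self, problem: TrainingProblem, eps: float = 1e-12, debug: bool = False):
        self.problem = problem
        self.X = problem.x
        self.y = problem.y
        self.C = problem.C
        self.tol = problem.tolerance
        self.eps = eps
        self.debug = debug
        self.m = len(self.X)
        self.K = kernel_matrix(self.X, self.X, problem.kernel)
        self.alphas = np.zeros(self.m)
        self.b = 0.0
        # cached kernel expansion without bias: s_i = sum_j a_j y_j K_ij
        self.s = np.zeros(self.m)
        self.w = np.zeros(self.X.shape[1]) if problem.kernel.kind == "linear" else None
        self.rng = np.random.default_rng(problem.seed)
        self._last_objective = 0.0
        self.objective_trace: list[float] = [0.0]

    # -- errors -------------------------------------------------------------
    def error(self, i: int) -> float:
        """E_i = f(x_i) − y_i with the current multipliers and bias."""
        return self.s[i] + self.b - self.y[i]

    # -- the two-variable analytic step ------------------------------------
    def take_step(self, i1: int, i2: int) -> bool:
        """Jointly optimize multipliers i1 and i2; True if either moved.

        Solves the one-dimensional quadratic along the constraint line
        λ₁y₁ + λ₂y₂ = const and clips to the [0, C] box, whose endpoints
        L/H differ between the y₁ = y₂ and y₁ ≠ y₂ geometries.  Degenerate
        curvature (η ≤ 0) is resolved by evaluating the objective at both
        endpoints and keeping the larger; ties leave λ₂ unchanged.
        """
        if i1 == i2:
            return False
        a1_old, a2_old = self.alphas[i1], self.alphas[i2]
        y1, y2 = self.y[i1], self.y[i2]
        E1, E2 = self.error(i1), self.error(i2)
        s = y1 * y2
        if s < 0:
            L = max(0.0, a2_old - a1_old)
            H = min(self.C, self.C + a2_old - a1_old)
        else:
            L = max(0.0, a1_old + a2_old - self.C)
            H = min(self.C, a1_old + a2_old)
        if L >= H:
            return False
        k11 = self.K[i1, i1]
        k12 = self.K[i1, i2]
        k22 = self.K[i2, i2]
        eta = k11 + k22 - 2.0 * k12
        if eta > 0:
            a2 = a2_old + y2 * (E1 - E2) / eta
            a2 = min(max(a2, L), H)
        else:
            # flat or concave direction: compare the dual at both endpoints
            f1 = y1 * self.s[i1] - a1_old * k11 - s * a2_old * k12
            f2 = y2 * self.s[i2] - s * a1_old * k12 - a2_old * k22
            L1 = a1_old + s * (a2_old - L)
            H1 = a1_old + s * (a2_old - H)
            psi_L = L1 * f1 + L * f2 + 0.5 * L1 * L1 * k11 + 0.5 * L * L * k22 + s * L * L1 * k12
            psi_H = H1 * f1 + H * f2 + 0.5 * H1 * H1 * k11 + 0.5 * H * H * k22 + s * H * H1 * k12
            if psi_L < psi_H - self.eps:
                a2 = L
            elif psi_L > psi_H + self.eps:
                a2 = H
            else:
                a2 = a2_old
        if abs(a2 - a2_old) < self.eps * (a2 + a2_old + self.eps):
            return False
        a1 = a1_old + s * (a2_old - a2)
        # guard fp drift at the box edges
        a1 = min(max(a1, 0.0), self.C)

        d1 = y1 * (a1 - a1_old)
        d2 = y2 * (a2 - a2_old)
        b1 = self.b - E1 - d1 * k11 - d2 * k12
        b2 = self.b - E2 - d1 * k12 - d2 * k22
        if 0.0 < a1 < self.C:
            b_new = b1
        elif 0.0 < a2 < self.C:
            b_new = b2
        else:
            b_new = 0.5 * (b1 + b2)

        self.alphas[i1] = a1
        self.alphas[i2] = a2
        self.b = b_new
        self.s += d1 * self.K[:, i1] + d2 * self.K[:, i2]
        if self.w is not None:
            self.w += d1 * self.X[i1] + d2 * self.X[i2]

        if self.debug:
            obj = self.current_objective()
            assert obj >= self._last_objective - 1e-9, (
                f"dual objective decreased: {self._last_objective} -> {obj}"
            )
            assert abs(float(self.alphas @ self.y)) <= 1e-9
            assert (self.alphas >= -1e-12).all() and (self.alphas <= self.C + 1e-12).all()
            self._last_objective = obj
            self.objective_trace.append(obj)
        return True

    def current_objective(self) -> float:
        u = self.alphas * self.y
        return float(self.alphas.sum() - 0.5 * (u @ (self.K @ u)))

    # -- working-set selection ----------------------------------------------
    def _examine(self, i2: int) -> int:
        y2 = self.y[i2]
        a2 = self.alphas[i2]
        E2 = self.error(i2)
        r2 = E2 * y2
        if not ((r2 < -self.tol and a2 < self.C) or (r2 > self.tol and a2 > 0)):
            return 0
        non_bound = np.flatnonzero((self.alphas > 0) & (self.alphas < self.C))
        if len(non_bound) > 1:
            errors = self.s[non_bound] + self.b - self.y[non_bound]
            i1 = int(non_bound[np.argmax(np.abs(errors - E2))])
            if self.take_step(i1, i2):
                return 1
        if len(non_bound):
            start = self.rng.integers(len(non_bound))
            for i1 in np.roll(non_bound, -start):
                if self.take_step(int(i1), i2):
                    return 1
        start = self.rng.integers(self.m)
        for i1 in np.roll(np.arange(self.m), -start):
            if self.take_step(int(i1), i2):
                return 1
        return 0

    def solve(self, max_passes: int = 10_000) -> None:
        """Platt's outer loop: alternate full and non-bound passes to KKT."""
        num_changed = 0
        examine_all = True
        passes = 0
        while (num_changed > 0 or examine_all) and passes < max_passes:
            num_changed = 0
            if examine_all:
                for i2 in range(self.m):
                    num_changed += self._examine(i2)
            else:
                for i2 in np.flatnonzero((self.alphas > 0) & (self.alphas < self.C)):
                    num_changed += self._examine(int(i2))
            if examine_all:
                examine_all = False
            elif num_changed == 0:
                examine_all = True
            passes += 1
        self.finalize_bias()

    def finalize_bias(self) -> None:
        """Recompute b from the converged multipliers.

        The pairwise b updates track the optimization but can leave a
        stale threshold when every multiplier ends at a bound.  Given
        optimal λ, b must satisfy y_i(s_i + b) ≥ 1 where λ_i can grow and
        ≤ 1 where it can shrink; this sets b to the mean over free support
        vectors when any exist, else to the midpoint of the feasible
        interval.
        """
        edge = 1e-8 * self.C
        free = (self.alphas > edge) & (self.alphas < self.C - edge)
        if free.any():
            self.b = float(np.mean(self.y[free] - self.s[free]))
            return
        lo, hi = -np.inf, np.inf
        for i in range(self.m):
            bound = self.y[i] - self.s[i]
            at_zero = self.alphas[i] <= edge
            if (at_zero and self.y[i] > 0) or (not at_zero and self.y[i] < 0):
                lo = max(lo, bound)
            if (at_zero and self.y[i] < 0) or (not at_zero and self.y[i] > 0):
                hi = min(hi, bound)
        if np.isfinite(lo) and np.isfinite(hi):
            self.b = 0.5 * (lo + hi)
        elif np.isfinite(lo):
            self.b = lo
        elif np.isfinite(hi):
            self.b = hi

    def kkt_violation(self) -> float:
        """Largest KKT violation over all points (0 at exact optimality)."""
        edge = 1e-8 * self.C
        worst = 0.0
        for i in range(self.m):
            r = self.error(i) * self.y[i]
            if self.alphas[i] < self.C - edge and r < 0:
                worst = max(worst, -r)
            if self.alphas[i] > edge and r > 0:
                worst = max(worst, r)
        return worst


def train_smo(problem: TrainingProblem, eps: float = 1e-12, debug: bool = False) -> SvmModel:
    """Train the SVM by SMO; the returned model satisfies KKT within tolerance."""
    trainer = SmoTrainer(problem, eps=eps, debug=debug)
    trainer.solve()
    return SvmModel(
        x=problem.x,
        y=problem.y,
        lambdas=trainer.alphas.copy(),
        bias=trainer.b,
        kernel=problem.kernel,
        C=problem.C,
        w=None if trainer.w is None else trainer.w.copy(),
        dual_objective=trainer.current_objective(),
    )


# ---------------------------------------------------------------------------
# prediction

def decision_value(model: SvmModel, x: np.ndarray) -> float:
    """f(x) = Σ λ_j y_j K(x_j, x) + b for one query vector."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.x.shape[1],):
        raise FeatureMismatchError(
            f"query has {x.shape} features, model expects ({model.x.shape[1]},)"
        )
    return float(decision_values(model, x[None, :])[0])


def decision_values(model: SvmModel, X: np.ndarray) -> np.ndarray:
    """Vectorized decision function over the rows of X."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.x.shape[1]:
        raise FeatureMismatchError(
            f"queries have {X.shape[1]} features, model expects {model.x.shape[1]}"
        )
    sv = model.support_index
    if len(sv) == 0:
        return np.full(len(X), model.bias)
    Kq = kernel_matrix(X, model.x[sv], model.kernel)
    return Kq @ (model.lambdas[sv] * model.y[sv]) + model.bias


# ---------------------------------------------------------------------------
# Platt probability calibration

def fit_platt(decision_vals: np.ndarray, labels: np.ndarray, max_iter: int = 100) -> tuple[float, float]:
    """Fit P⁺(f) = 1/(1 + exp(A·f + B)) by regularized maximum likelihood.

    Uses Platt's target smoothing — positives aim at (N⁺+1)/(N⁺+2) rather
    than 1, negatives at 1/(N⁻+2) — and Newton iterations with backtracking
    line search.  Requires both classes to be present.
    """
    f = np.asarray(decision_vals, dtype=float)
    y = np.asarray(labels, dtype=float)
    n_pos = int((y > 0).sum())
    n_neg = int((y < 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("Platt calibration needs both classes")
    hi = (n_pos + 1.0) / (n_pos + 2.0)
    lo = 1.0 / (n_neg + 2.0)
    t = np.where(y > 0, hi, lo)

    A = 0.0
    B = math.log((n_neg + 1.0) / (n_pos + 1.0))
    sigma = 1e-12

    def nll(a: float, b: float) -> float:
        z = a * f + b
        # stable log(1+exp(z)) bookkeeping
        pos = z >= 0
        val = np.where(pos, t * z + np.log1p(np.exp(-np.abs(z))),
                       (t - 1.0) * z + np.log1p(np.exp(-np.abs(z))))
        return float(val.sum())

    best = nll(A, B)
    for _ in range(max_iter):
        z = A * f + B
        p = np.where(z >= 0, np.exp(-z) / (1.0 + np.exp(-z)), 1.0 / (1.0 + np.exp(z)))
        d1 = t - p
        d2 = p * (1.0 - p)
        g1 = float((f * d1).sum())
        g2 = float(d1.sum())
        if abs(g1) < 1e-10 and abs(g2) < 1e-10:
            break
        h11 = float((f * f * d2).sum()) + sigma
        h22 = float(d2.sum()) + sigma
        h21 = float((f * d2).sum())
        det = h11 * h22 - h21 * h21
        dA = -(h22 * g1 - h21 * g2) / det
        dB = -(-h21 * g1 + h11 * g2) / det
        g_d = g1 * dA + g2 * dB
        step = 1.0
        while step >= 1e-10:
            a_new, b_new = A + step * dA, B + step * dB
            val = nll(a_new, b_new)
            if val < best + 1e-4 * step * g_d:
                A, B, best = a_new, b_new, val
                break
            step /= 2.0
        else:
            break
    return A, B


def calibrate(model: SvmModel, X: Optional[np.ndarray] = None, y: Optional[np.ndarray] = None) -> SvmModel:
    """Return a copy of `model` with Platt parameters fitted.

    By default calibration uses the model's own training decision values;
    pass X, y to calibrate on held-out data instead.
    """
    if X is None:
        X, y = model.x, model.y
    f = decision_values(model, X)
    a, b = fit_platt(f, y)
    return replace_platt(model, a, b)


def replace_platt(model: SvmModel, a: float, b: float) -> SvmModel:
    import copy

    out = copy.copy(model)
    out.platt_a = a
    out.platt_b = b
    return out


def predict_proba(model: SvmModel, X: np.ndarray) -> np.ndarray:
    """(P⁺, P⁻) per row of X; requires a calibrated model.  P⁺ + P⁻ = 1."""
    if not model.is_calibrated:
        raise NotCalibratedError("model has no Platt parameters; run calibrate() first")
    f = decision_values(model, np.atleast_2d(np.asarray(X, dtype=float)))
    z = model.platt_a * f + model.platt_b
    p_plus = np.where(z >= 0, np.exp(-z) / (1.0 + np.exp(-z)), 1.0 / (1.0 + np.exp(z)))
    return np.column_stack([p_plus, 1.0 - p_plus])
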