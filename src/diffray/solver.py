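"""Gradient-based minimization with closure semantics, plus gradient oracles.

Each iteration follows the canonical loop: clear old gradients, simulate the
forward model (the closure rebuilds the computation graph at the current
parameter values), differentiate by unrolling the graph, and apply the
update step of the chosen algorithm.

Two methods are provided:

* ``"quasi-newton"`` — limited-memory BFGS with strong-Wolfe line search
  (scipy's L-BFGS-B driven by gradients from the AD engine), the default
  for real-valued, moderately sized problems;
* ``"adam"`` — a first-order adaptive method for large, non-convex problems
  such as ptychography, where complex parameters are exposed to the
  optimizer as paired real coordinates.

The finite-difference oracle (:func:`fd_gradient`) is the independent
reference every backend gradient is validated against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize as sopt

from .autodiff import Tensor

__all__ = ["LinearOperator", "OptimResult", "GradientReport", "minimize",
           "analytic_grad_x", "analytic_grad_A", "fd_gradient",
           "verify_gradients"]

_QN_ALIASES = {"quasi-newton", "quasi-newton-limited-memory", "lbfgs",
               "l-bfgs"}
_ADAM_ALIASES = {"adam", "first-order-adaptive"}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

class LinearOperator:
    """A linear map with an explicit adjoint."""

    def __init__(self, forward, adjoint, domain_shape, range_shape):
        self.forward = forward
        self.adjoint = adjoint
        self.domain_shape = tuple(domain_shape)
        self.range_shape = tuple(range_shape)

    @classmethod
    def from_dense(cls, a: np.ndarray) -> "LinearOperator":
        a = np.asarray(a, dtype=np.float64)
        return cls(lambda v: a @ v, lambda u: a.T @ u,
                   (a.shape[1],), (a.shape[0],))

    def dot_test(self, seed: int = 0) -> float:
        """Relative discrepancy of <Mv, u> vs <v, M^T u> on random vectors."""
        rng = np.random.default_rng(seed)
        v = rng.standard_normal(self.domain_shape)
        u = rng.standard_normal(self.range_shape)
        lhs = float(np.vdot(self.forward(v), u))
        rhs = float(np.vdot(v, self.adjoint(u)))
        return abs(lhs - rhs) / max(abs(lhs), abs(rhs), 1e-300)


@dataclass
class OptimResult:
    """Outcome of a :func:`minimize` run."""

    params: dict
    loss_trace: np.ndarray
    n_iter: int
    converged: bool
    stop_reason: str

    @property
    def final_loss(self) -> float:
        return float(self.loss_trace[-1]) if self.loss_trace.size else np.nan

    def __post_init__(self):
        self.loss_trace = np.asarray(self.loss_trace, dtype=np.float64)
        if self.loss_trace.size and not np.all(np.isfinite(self.loss_trace)):
            raise ValueError("loss trace contains non-finite values")


@dataclass
class GradientReport:
    """Backend-vs-finite-difference gradient comparison per parameter."""

    max_abs: dict
    max_rel: dict

    @property
    def worst_rel(self) -> float:
        return max(self.max_rel.values()) if self.max_rel else 0.0


# ---------------------------------------------------------------------------
# parameter flattening
# ---------------------------------------------------------------------------

def _layout(params: dict):
    names = list(params.keys())
    shapes = [np.asarray(params[n], dtype=np.float64).shape for n in names]
    sizes = [int(np.prod(s)) if s else 1 for s in shapes]
    offsets = np.concatenate([[0], np.cumsum(sizes)]).astype(int)
    return names, shapes, sizes, offsets


def _pack(params: dict, names, sizes) -> np.ndarray:
    return np.concatenate([np.asarray(params[n], dtype=np.float64).reshape(-1)
                           for n in names]) if names else np.zeros(0)


def _unpack(vec: np.ndarray, names, shapes, offsets) -> dict:
    out = {}
    for i, n in enumerate(names):
        chunk = vec[offsets[i]:offsets[i + 1]]
        out[n] = chunk.reshape(shapes[i]) if shapes[i] else chunk.reshape(())
    return out


def _make_objective(loss_closure, names, shapes, offsets):
    """Return f(vec) -> (loss, grad) evaluating the closure through the AD
    engine: fresh leaves (cleared gradients), forward pass, backward pass."""

    def objective(vec):
        tensors = {}
        for i, n in enumerate(names):
            chunk = vec[offsets[i]:offsets[i + 1]]
            val = chunk.reshape(shapes[i]) if shapes[i] else chunk.reshape(())
            tensors[n] = Tensor(val.copy(), requires_grad=True)
        loss = loss_closure(tensors)
        f = float(loss.value)
        loss.backward()
        grads = []
        for n in names:
            t = tensors[n]
            g = t.grad if t.grad is not None else np.zeros_like(t.value)
            grads.append(np.asarray(g, dtype=np.float64).reshape(-1))
        grad = np.concatenate(grads) if grads else np.zeros(0)
        return f, grad

    return objective


# ---------------------------------------------------------------------------
# minimize
# ---------------------------------------------------------------------------

class _EarlyStop(Exception):
    pass


class _NonFinite(Exception):
    pass


def _converged(trace, tol, window: int = 5) -> bool:
    """Relative loss change below ``tol`` sustained over ``window`` iters."""
    if len(trace) < window + 1:
        return False
    ref = abs(trace[-window - 1]) + 1e-300
    recent = trace[-window - 1:]
    changes = np.abs(np.diff(recent)) / ref
    return bool(np.all(changes < tol))


def minimize(loss_closure, params: dict, method: str = "quasi-newton",
             max_iter: int = 500, tol: float = 1e-8, seed: int = 0,
             lr: float = 0.05, callback=None) -> OptimResult:
    """Minimize a scalar closure over named parameter arrays.

    Parameters
    ----------
    loss_closure : callable mapping ``{name: Tensor}`` to a scalar Tensor;
        it must rebuild the computation graph at every call.
    params : ``{name: ndarray}`` of initial values.
    method : ``"quasi-newton"`` (limited-memory BFGS, strong-Wolfe line
        search) or ``"adam"`` (first-order adaptive).
    max_iter, tol : iteration budget and convergence tolerance (relative
        loss change below ``tol`` sustained for 5 iterations).
    seed : recorded for provenance; both methods are deterministic.
    lr : Adam step size (ignored by quasi-Newton).

    Raises ``FloatingPointError`` ... no: a non-finite loss aborts the run
    and returns the best state reached, with ``stop_reason`` set.
    """
    names, shapes, sizes, offsets = _layout(params)
    x0 = _pack(params, names, sizes)
    objective = _make_objective(loss_closure, names, shapes, offsets)

    f0, _ = objective(x0)
    if not np.isfinite(f0):
        raise ValueError("loss is non-finite at the initial point")

    if max_iter == 0:
        return OptimResult(_unpack(x0, names, shapes, offsets),
                           np.zeros(0), 0, False, "max_iter reached")

    if method.lower() in _QN_ALIASES:
        return _minimize_lbfgs(objective, x0, names, shapes, offsets,
                               max_iter, tol, callback)
    if method.lower() in _ADAM_ALIASES:
        return _minimize_adam(objective, x0, names, shapes, offsets,
                              max_iter, tol, lr, callback)
    raise ValueError(f"unknown method {method!r}")


def _minimize_lbfgs(objective, x0, names, shapes, offsets, max_iter, tol,
                    callback):
    trace: list[float] = []
    state = {"x": x0.copy(), "last_f": None, "bad": False}

    def fun(v):
        f, g = objective(v)
        if not np.isfinite(f) or not np.all(np.isfinite(g)):
            state["bad"] = True
            raise _NonFinite
        state["last_f"] = f
        return f, g

    def cb(xk):
        state["x"] = np.array(xk, copy=True)
        trace.append(state["last_f"])
        if callback is not None:
            callback(len(trace), state["last_f"], xk)
        if _converged(trace, tol):
            raise _EarlyStop

    converged = False
    reason = "max_iter reached"
    try:
        res = sopt.minimize(fun, x0, jac=True, method="L-BFGS-B", callback=cb,
                            options={"maxiter": max_iter, "ftol": 0.0,
                                     "gtol": 1e-16, "maxcor": 20,
                                     "maxls": 40})
        state["x"] = res.x
        if res.status == 0:
            converged, reason = True, "scipy converged"
        elif "ABNORMAL" in str(res.message).upper() \
                or "ROUNDING" in str(res.message).upper():
            # line search exhausted by rounding: treat as converged-in-place
            converged, reason = True, "line search at numerical precision"
    except _EarlyStop:
        converged, reason = True, "loss change below tol for 5 iterations"
    except _NonFinite:
        reason = "aborted: non-finite loss"

    x = state["x"]
    if not trace:  # ensure invariant: trace length == iterations run
        f, _ = objective(x)
        if np.isfinite(f):
            trace.append(f)
    return OptimResult(_unpack(x, names, shapes, offsets),
                       np.asarray(trace), len(trace), converged, reason)


def _minimize_adam(objective, x0, names, shapes, offsets, max_iter, tol, lr,
                   callback, beta1=0.9, beta2=0.999, eps=1e-8):
    x = x0.copy()
    m = np.zeros_like(x)
    v = np.zeros_like(x)
    trace: list[float] = []
    best_x, best_f = x.copy(), np.inf
    converged = False
    reason = "max_iter reached"
    for it in range(1, max_iter + 1):
        f, g = objective(x)
        if not np.isfinite(f) or not np.all(np.isfinite(g)):
            reason = "aborted: non-finite loss"
            x = best_x
            break
        trace.append(f)
        if f < best_f:
            best_f, best_x = f, x.copy()
        if callback is not None:
            callback(it, f, x)
        if _converged(trace, tol):
            converged = True
            reason = "loss change below tol for 5 iterations"
            break
        m = beta1 * m + (1 - beta1) * g
        v = beta2 * v + (1 - beta2) * g * g
        mhat = m / (1 - beta1 ** it)
        vhat = v / (1 - beta2 ** it)
        x = x - lr * mhat / (np.sqrt(vhat) + eps)
    return OptimResult(_unpack(x, names, shapes, offsets),
                       np.asarray(trace), len(trace), converged, reason)


# ---------------------------------------------------------------------------
# analytic and finite-difference gradient oracles
# ---------------------------------------------------------------------------

def analytic_grad_x(A, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Hand-derived gradient of ||Ax-y||^2 + ||x||_1 with respect to x:
    2 A^T (Ax - y) + sign(x), with sign(0) = 0."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if isinstance(A, LinearOperator):
        r = A.forward(x) - y
        back = A.adjoint(r)
    else:
        a = np.asarray(A, dtype=np.float64)
        if a.shape[1] != x.size:
            raise ValueError("A and x shapes are inconsistent")
        r = a @ x - y
        back = a.T @ r
    return 2.0 * back + np.sign(x)


def analytic_grad_A(A: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Hand-derived gradient of ||Ax-y||^2 with respect to a dense A:
    the outer product 2 (Ax - y) x^T."""
    a = np.asarray(A, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if a.shape[1] != x.size or a.shape[0] != y.size:
        raise ValueError("shape mismatch")
    return 2.0 * np.outer(a @ x - y, x)


def fd_gradient(f, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central finite differences of a scalar function, one evaluation pair
    per coordinate; steps are scale-normalized per coordinate."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    x = np.asarray(x, dtype=np.float64)
    flat = x.reshape(-1)
    grad = np.zeros_like(flat)
    for i in range(flat.size):
        h = eps * max(1.0, abs(flat[i]))
        xp = flat.copy()
        xm = flat.copy()
        xp[i] += h
        xm[i] -= h
        fp = float(f(xp.reshape(x.shape)))
        fm = float(f(xm.reshape(x.shape)))
        if not (np.isfinite(fp) and np.isfinite(fm)):
            raise FloatingPointError("non-finite evaluation in fd_gradient")
        grad[i] = (fp - fm) / (2.0 * h)
    return grad.reshape(x.shape)


def verify_gradients(loss_closure, params: dict, eps: float = 1e-5
                     ) -> GradientReport:
    """Compare backend gradients of a closure against central finite
    differences, parameter by parameter."""
    names, shapes, sizes, offsets = _layout(params)
    if sum(sizes) > 10_000:
        raise ValueError("total parameter dimension exceeds the oracle budget")
    x0 = _pack(params, names, sizes)
    objective = _make_objective(loss_closure, names, shapes, offsets)
    _, g_ad = objective(x0)

    def f_only(v):
        fv, _ = objective(v)
        return fv

    g_fd = fd_gradient(f_only, x0, eps=eps)
    max_abs, max_rel = {}, {}
    for i, n in enumerate(names):
        sl = slice(offsets[i], offsets[i + 1])
        diff = np.abs(g_ad[sl] - g_fd[sl])
        max_abs[n] = float(diff.max()) if diff.size else 0.0
        denom = max(float(np.abs(g_fd[sl]).max()) if diff.size else 0.0, 1e-12)
        max_rel[n] = max_abs[n] / denom
    return GradientReport(max_abs=max_abs, max_rel=max_rel)
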