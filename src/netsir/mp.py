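"""Message-passing (MP) models for SIR epidemics on networks.

The average message H1(t) is the probability that a random neighbour of a
cavity-state test node has not attempted to transmit to it by time t.  On the
configuration-model ensemble it satisfies the Volterra integral equation

    H1(t) = 1 - int_0^t f(a) [1 - z G1(H1(t-a))] da,      H1(0) = 1,

with f(a) = tau(a) xi_q(a), and the population fractions follow as

    S(t) = z G0(H1(t)),
    R(t) = int_0^t q(a) [1 - S(t-a)] da,
    I(t) = 1 - S(t) - R(t).

On a finite tree the *per-edge* messages solve the same equation with the
product over the neighbour's other edges kept explicit, and reproduce the
stochastic epidemic exactly.

Numerics: product-trapezoidal discretisation — per-cell masses of the kernel
are computed exactly (atom-aware), the unknown is treated as piecewise linear,
and the implicit endpoint is resolved by damped fixed-point iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .degree import GeneratingFunctionSet, StaticNetwork
from .disease import DiseaseModel, product_cell_integrals
from .trajectory import MeanFieldTrajectory

__all__ = [
    "solve_mp",
    "solve_mp_markovian_ode",
    "solve_mp_per_edge",
    "final_size",
    "epidemic_threshold",
    "PerEdgeMPResult",
]

_FP_TOL = 1e-10
_FP_MAXITER = 50


class ConvergenceError(ArithmeticError):
    """Inner iteration of an implicit step failed to converge."""


def _grid(T: float, h: float) -> np.ndarray:
    if h <= 0 or T < h:
        raise ValueError("need h > 0 and T >= h")
    n = int(round(T / h))
    return np.arange(n + 1) * h


def _check_z(z: float) -> None:
    if not 0.0 < z <= 1.0:
        raise ValueError("initial susceptible fraction z must satisfy 0 < z <= 1")


def _lag_eval(series: np.ndarray, m: int, candidate: float, lag_steps: float) -> float:
    """series evaluated at index m - lag_steps, linear between grid points;
    index m is the (not yet stored) candidate value."""
    pos = m - lag_steps
    if pos <= 0:
        return float(series[0])
    j = int(np.floor(pos))
    frac = pos - j
    right = candidate if j + 1 == m else series[j + 1]
    if frac == 0.0:
        return float(series[j])
    return float((1.0 - frac) * series[j] + frac * right)


def _convolve_R(Wq, q_atoms, u, t, h):
    """R(t_m) = sum_cells Wq_j * avg(u at cell ends) + atom terms, all m."""
    n = len(t) - 1
    R = np.zeros(n + 1)
    for m in range(1, n + 1):
        acc = float(np.dot(Wq[:m], 0.5 * (u[m:0:-1] + u[m - 1 :: -1])))
        for loc, w in q_atoms:
            if t[m] >= loc - 1e-12:
                acc += w * _lag_eval(u, m, u[m], loc / h)
        R[m] = acc
    return R


def solve_mp(gfs: GeneratingFunctionSet, model: DiseaseModel, z: float,
             T: float, h: float) -> MeanFieldTrajectory:
    """Solve the average-message model on the grid 0, h, ..., T."""
    _check_z(z)
    t = _grid(T, h)
    n = len(t) - 1
    Wf = product_cell_integrals(model.transmission, model.recovery, h, n)
    f_atoms = [(loc, w) for loc, w in model.f_atoms if w > 0]

    H1 = np.ones(n + 1)
    psi = np.zeros(n + 1)  # psi = 1 - z G1(H1)
    psi[0] = 1.0 - z * gfs.G1(1.0)

    for m in range(1, n + 1):
        # known part: cells j = 1 .. m-1 fully lagged, plus the lagged half of cell 0
        known = 1.0
        if m > 1:
            known -= float(np.dot(Wf[1:m], 0.5 * (psi[m - 1 : 0 : -1] + psi[m - 2 :: -1])))
        known -= 0.5 * Wf[0] * psi[m - 1]

        x = H1[m - 1]
        for it in range(_FP_MAXITER):
            psi_m = 1.0 - z * gfs.G1(min(max(x, 0.0), 1.0))
            val = known - 0.5 * Wf[0] * psi_m
            for loc, w in f_atoms:
                if t[m] >= loc - 1e-12:
                    val -= w * _lag_eval(psi, m, psi_m, loc / h)
            if abs(val - x) < _FP_TOL:
                x = val
                break
            x = 0.5 * (x + val)  # damped
        else:
            raise ConvergenceError(
                f"message fixed point did not converge at t={t[m]:.6g}, "
                f"residual {abs(val - x):.3g}")
        H1[m] = min(max(x, 0.0), 1.0)
        psi[m] = 1.0 - z * gfs.G1(H1[m])

    S = z * np.asarray(gfs.G0(H1))
    Wq = product_cell_integrals(model.recovery, _UNIT_SURVIVAL, h, n)
    R = _convolve_R(Wq, model.recovery.atoms, 1.0 - S, t, h)
    I = 1.0 - S - R
    return MeanFieldTrajectory(t, H1, S, I, R, z,
                               meta={"solver": "mp", "h": h, "T": T})


class _UnitSurvival:
    """Survival identically 1 (used to integrate a bare density)."""

    @staticmethod
    def sf(a):
        return np.ones_like(np.asarray(a, dtype=float))

    sf_left = sf


_UNIT_SURVIVAL = _UnitSurvival()


def solve_mp_markovian_ode(gfs: GeneratingFunctionSet, beta: float, gamma: float,
                           z: float, T: float, h: float) -> MeanFieldTrajectory:
    """Markovian special case: dH1/dt = gamma - (beta+gamma) H1 + beta z G1(H1).

    Classic fixed-step 4th-order Runge-Kutta on (H1, R) with R' = gamma I.
    """
    if beta <= 0 or gamma <= 0:
        raise ValueError("beta and gamma must be > 0")
    _check_z(z)
    t = _grid(T, h)
    n = len(t) - 1
    H1 = np.ones(n + 1)
    R = np.zeros(n + 1)

    def rhs(y):
        h1, r = y
        h1c = min(max(h1, 0.0), 1.0)
        dh1 = gamma - (beta + gamma) * h1 + beta * z * gfs.G1(h1c)
        s = z * gfs.G0(h1c)
        dr = gamma * (1.0 - s - r)
        return np.array([dh1, dr])

    y = np.array([1.0, 0.0])
    for m in range(1, n + 1):
        k1 = rhs(y)
        k2 = rhs(y + 0.5 * h * k1)
        k3 = rhs(y + 0.5 * h * k2)
        k4 = rhs(y + h * k3)
        y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not -1e-9 <= y[0] <= 1 + 1e-9:
            raise ConvergenceError(
                f"H1 left [0,1] at t={t[m]:.6g}; reduce the step size h")
        H1[m], R[m] = min(max(y[0], 0.0), 1.0), y[1]

    S = z * np.asarray(gfs.G0(H1))
    I = 1.0 - S - R
    return MeanFieldTrajectory(t, H1, S, I, R, z,
                               meta={"solver": "mp_markovian_ode", "h": h, "T": T,
                                     "beta": beta, "gamma": gamma})


@dataclass(frozen=True)
class PerEdgeMPResult:
    """Exact tree solution: per-directed-edge messages and node susceptibilities."""

    t: np.ndarray
    node_susceptibility: np.ndarray  # (N, len(t))
    messages: dict = field(repr=False, default_factory=dict)  # (u, v) -> series H^{u<-v}


def solve_mp_per_edge(network: StaticNetwork, model: DiseaseModel, z: float,
                      T: float, h: float, allow_cycles: bool = False) -> PerEdgeMPResult:
    """Per-edge message passing; exact on forests.

    z is the independent per-node probability of being initially susceptible.
    On a cyclic network the equations are only an approximation; pass
    ``allow_cycles=True`` to run them anyway.
    """
    _check_z(z)
    if not allow_cycles and not network.is_forest():
        raise ValueError("network contains a cycle; per-edge MP is exact only on "
                         "forests (pass allow_cycles=True for the approximation)")
    t = _grid(T, h)
    n = len(t) - 1
    Wf = product_cell_integrals(model.transmission, model.recovery, h, n)
    f_atoms = [(loc, w) for loc, w in model.f_atoms if w > 0]

    adj = network.adjacency()
    directed = [(u, v) for u, v in network.edges] + [(v, u) for u, v in network.edges]
    # edge (u, v) carries the message H^{u<-v}
    index = {e: i for i, e in enumerate(directed)}
    # for message u<-v the product runs over v's neighbours w != u: messages v<-w
    feeders = [[index[(v, w)] for w in adj[v] if w != u] for u, v in directed]

    m_edges = len(directed)
    H = np.ones((m_edges, n + 1))
    psi = np.zeros((m_edges, n + 1))

    def _psi_col(Hcol):
        out = np.empty(m_edges)
        for i in range(m_edges):
            prod = 1.0
            for j in feeders[i]:
                prod *= Hcol[j]
            out[i] = 1.0 - z * prod
        return out

    psi[:, 0] = _psi_col(H[:, 0])

    for m in range(1, n + 1):
        known = np.ones(m_edges)
        if m > 1:
            known -= 0.5 * (psi[:, m - 1 : 0 : -1] + psi[:, m - 2 :: -1]) @ Wf[1:m]
        known -= 0.5 * Wf[0] * psi[:, m - 1]
        x = H[:, m - 1].copy()
        for it in range(_FP_MAXITER):
            psi_m = _psi_col(np.clip(x, 0.0, 1.0))
            val = known - 0.5 * Wf[0] * psi_m
            for loc, w in f_atoms:
                if t[m] >= loc - 1e-12:
                    pos = m - loc / h
                    if pos <= 0:
                        lagged = psi[:, 0]
                    else:
                        j = int(np.floor(pos))
                        frac = pos - j
                        right = psi_m if j + 1 == m else psi[:, j + 1]
                        lagged = (1 - frac) * psi[:, j] + frac * right
                    val = val - w * lagged
            if np.max(np.abs(val - x)) < _FP_TOL:
                x = val
                break
            x = 0.5 * (x + val)
        else:
            raise ConvergenceError(f"per-edge fixed point did not converge at t={t[m]:.6g}")
        H[:, m] = np.clip(x, 0.0, 1.0)
        psi[:, m] = _psi_col(H[:, m])

    sus = np.full((network.n_nodes, n + 1), z)
    for u in range(network.n_nodes):
        for w in adj[u]:
            sus[u] *= H[index[(u, w)]]
    messages = {e: H[i].copy() for e, i in index.items()}
    return PerEdgeMPResult(t, sus, messages)


def final_size(gfs: GeneratingFunctionSet, model: DiseaseModel,
               tol: float = 1e-12, maxiter: int = 100000) -> tuple[float, float]:
    """Final epidemic size for a vanishing initial infected fraction.

    Returns (Theta_inf, r_inf) where Theta_inf is the smallest fixed point of
    Theta = 1 - T + T G1(Theta) on [0, 1] (reached monotonically from 0) and
    r_inf = 1 - G0(Theta_inf).
    """
    T_tilde = model.transmissibility()
    theta = 0.0
    for _ in range(maxiter):
        nxt = 1.0 - T_tilde + T_tilde * gfs.G1(theta)
        if abs(nxt - theta) < tol:
            theta = nxt
            break
        theta = nxt
    return float(theta), float(1.0 - gfs.G0(min(theta, 1.0)))


def epidemic_threshold(gfs: GeneratingFunctionSet, model: DiseaseModel) -> float:
    """Reproduction-like ratio T * (mean excess degree); > 1 means a giant
    outbreak (r_inf > 0) is possible."""
    return model.transmissibility() * gfs.mean_excess_degree
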