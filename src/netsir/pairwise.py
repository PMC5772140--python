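"""Pairwise-like models: re-parametrisations of the message-passing model
for Markovian (Poisson, rate beta) transmission.

With exponential transmission the average-message model can be recast in
terms of population-level counts: [S], [I], [R] nodes and [SI] edges (plus
[SS] on regular networks).  The general configuration-model system is

    dH1/dt  = -beta [SI] / (z <k> N G1(H1))
    d[SI]/dt = -beta [SI]^2 G2(H1)/(z <k> N G1(H1)^2) - beta [SI]
               + z beta [SI] G2(H1)
               - q(t) e^{-beta t} (1-z) z G1(H1) <k> N
               - z beta int_0^t q(a) e^{-beta a} [SI](t-a) G2(H1(t-a))
                                        G1(H1(t)) / G1(H1(t-a)) da
    [I](t)  = beta int_0^t [SI](t-a) xi_q(a) da + N (1-z) xi_q(t)
    [S](t)  = z N G0(H1(t)),     [R] = N - [S] - [I]

and it closes without any moment-closure approximation because the message
H1 is retained.  Specialisations implemented here: regular networks (the
message eliminated in favour of [SS]), exponentially distributed infectious
periods (a plain ODE system), and fixed-length infectious periods (a delay
differential equation with impulsive recovery of the initial cohort).

[I] is computed from the integral (convolution) form rather than its
differential form: it needs no point evaluation of q and is cheaper when the
infectious period carries atoms.

All solvers use Heun's method (explicit trapezoidal) on a fixed grid; history
integrals are product-trapezoidal on the same grid, and recovery-time atoms
enter as exact lagged terms and impulsive jumps, never as smeared densities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .degree import GeneratingFunctionSet, make_degree_distribution
from .disease import (DelayDistribution, UnsupportedModelError,
                      make_delay_distribution, product_cell_integrals)
from .trajectory import MeanFieldTrajectory

__all__ = [
    "PairwiseState",
    "solve_pairwise_cm",
    "solve_pairwise_regular",
    "solve_pairwise_markovian",
    "solve_pairwise_fixed_delay",
]


@dataclass(frozen=True)
class PairwiseState:
    """Population-level counts on a uniform grid ([SS] only for regular)."""

    N: float
    t: np.ndarray
    H1: np.ndarray
    S: np.ndarray
    I: np.ndarray
    R: np.ndarray
    SI: np.ndarray
    SS: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def per_capita(self) -> MeanFieldTrajectory:
        """Fractions, for comparison against the mean-field trajectories."""
        z = self.meta.get("z", float(self.S[0] / self.N))
        return MeanFieldTrajectory(self.t, self.H1, self.S / self.N,
                                   self.I / self.N, self.R / self.N, z,
                                   meta=dict(self.meta))

    def to_frame(self) -> pd.DataFrame:
        data = {"t": self.t, "S": self.S, "I": self.I, "R": self.R,
                "message": self.H1, "SI": self.SI}
        if self.SS is not None:
            data["SS"] = self.SS
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def _grid(T, h):
    if h <= 0 or T < h:
        raise ValueError("need h > 0 and T >= h")
    n = int(round(T / h))
    return np.arange(n + 1) * h, n


def _check_atoms_on_grid(recovery: DelayDistribution, h: float):
    atoms = []
    for loc, w in recovery.atoms:
        steps = loc / h
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError(
                f"recovery atom at {loc} is not a multiple of the step h={h}; "
                "lagged terms are evaluated on the grid without interpolation")
        atoms.append((int(round(steps)), loc, w))
    return atoms


def _survival_cells(recovery: DelayDistribution, h: float, n: int) -> np.ndarray:
    """Per-cell integrals of xi_q(a) (Simpson, atom-aware at cell ends)."""
    subdiv = 8
    offsets = h * np.arange(subdiv + 1) / subdiv
    a = np.arange(n)[:, None] * h + offsets[None, :]
    surv = np.asarray(recovery.sf(a.ravel()), dtype=float).reshape(a.shape)
    surv[:, -1] = np.asarray(recovery.sf_left(a[:, -1]), dtype=float)
    w = np.ones(subdiv + 1)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    w *= (h / subdiv) / 3.0
    return surv @ w


def _infected_by_convolution(SI: np.ndarray, recovery: DelayDistribution,
                             beta: float, N: float, z: float,
                             h: float) -> np.ndarray:
    """[I](t) = beta int_0^t [SI](t-a) xi_q(a) da + N(1-z) xi_q(t)."""
    n = len(SI) - 1
    Wxi = _survival_cells(recovery, h, n)
    t = np.arange(n + 1) * h
    I = np.empty(n + 1)
    I[0] = N * (1.0 - z)
    sf_t = np.asarray(recovery.sf(t), dtype=float)
    for m in range(1, n + 1):
        conv = float(np.dot(Wxi[:m], 0.5 * (SI[m:0:-1] + SI[m - 1 :: -1])))
        I[m] = beta * conv + N * (1.0 - z) * sf_t[m]
    return I


def solve_pairwise_cm(gfs: GeneratingFunctionSet, beta: float,
                      recovery: DelayDistribution, z: float, N: float,
                      T: float, h: float,
                      transmission: DelayDistribution | None = None) -> PairwiseState:
    """General configuration-model pairwise system (Poisson transmission).

    ``transmission`` may be passed for interface symmetry but must be
    exponential with rate ``beta``; anything else raises
    :class:`UnsupportedModelError` — the re-parametrisation assumes a
    memoryless transmission process.
    """
    if transmission is not None:
        if transmission.kind != "exponential" or \
                abs(transmission.params.get("rate", -1.0) - beta) > 1e-12:
            raise UnsupportedModelError(
                "the pairwise hierarchy requires exponential (Poisson) "
                "transmission with rate beta")
    if beta <= 0:
        raise ValueError("beta must be > 0")
    if not 0.0 < z <= 1.0:
        raise ValueError("z must satisfy 0 < z <= 1")
    t, n = _grid(T, h)
    atoms = _check_atoms_on_grid(recovery, h)
    kbar = gfs.mean_degree
    exp_beta = make_delay_distribution("exponential", rate=beta)
    # kernel cells: int q(a) e^{-beta a} over each grid cell
    Wqb = product_cell_integrals(recovery, exp_beta, h, n)

    H1 = np.ones(n + 1)
    SI = np.zeros(n + 1)
    psi = np.zeros(n + 1)  # psi(s) = [SI](s) G2(H1(s)) / G1(H1(s))
    SI[0] = kbar * N * z * (1.0 - z)
    psi[0] = SI[0] * gfs.G2(1.0) / gfs.G1(1.0)

    q_cont = np.asarray(recovery.density(t), dtype=float)

    def conv(mi: int, psi_mi: float) -> float:
        """History integral sum at grid index mi (candidate endpoint value)."""
        if mi == 0:
            return 0.0
        hist = psi[: mi + 1].copy()
        hist[mi] = psi_mi
        acc = float(np.dot(Wqb[:mi], 0.5 * (hist[mi:0:-1] + hist[mi - 1 :: -1])))
        for steps, loc, w in atoms:
            if mi >= steps:
                acc += w * np.exp(-beta * loc) * hist[mi - steps]
        return acc

    def rhs(mi: int, h1: float, si: float) -> tuple[float, float]:
        g1 = gfs.G1(min(max(h1, 0.0), 1.0))
        g2 = gfs.G2(min(max(h1, 0.0), 1.0))
        dh1 = -beta * si / (z * kbar * N * g1)
        psi_mi = si * g2 / g1
        dsi = (-beta * si * si * g2 / (z * kbar * N * g1 * g1)
               - beta * si + z * beta * si * g2
               - q_cont[mi] * np.exp(-beta * t[mi]) * (1.0 - z) * z * g1 * kbar * N
               - z * beta * g1 * conv(mi, psi_mi))
        return dh1, dsi

    for m in range(n):
        dh1, dsi = rhs(m, H1[m], SI[m])
        h1p, sip = H1[m] + h * dh1, SI[m] + h * dsi
        dh1b, dsib = rhs(m + 1, h1p, sip)
        H1[m + 1] = min(max(H1[m] + 0.5 * h * (dh1 + dh1b), 0.0), 1.0)
        SI[m + 1] = max(SI[m] + 0.5 * h * (dsi + dsib), 0.0)
        for steps, loc, w in atoms:  # impulsive recovery of the initial cohort
            if steps == m + 1:
                SI[m + 1] = max(
                    SI[m + 1] - w * np.exp(-beta * loc) * (1.0 - z) * z
                    * gfs.G1(H1[m + 1]) * kbar * N, 0.0)
        psi[m + 1] = SI[m + 1] * gfs.G2(H1[m + 1]) / gfs.G1(H1[m + 1])

    S = z * N * np.asarray(gfs.G0(H1))
    I = _infected_by_convolution(SI, recovery, beta, N, z, h)
    R = N - S - I
    return PairwiseState(N, t, H1, S, I, R, SI,
                         meta={"solver": "pairwise_cm", "z": z, "beta": beta,
                               "h": h, "T": T})


def solve_pairwise_regular(k: int, beta: float, recovery: DelayDistribution,
                           z: float, N: float, T: float, h: float) -> PairwiseState:
    """Closed [S], [I], [SS], [SI] system on a k-regular network.

    The message is eliminated: H1^{k-1}(t) = exp(-beta int_0^t ((k-1)/k)
    [SI]/[S] da), and that exponential memory factor is maintained
    incrementally from the running integral.
    """
    if int(k) != k or k < 2:
        raise ValueError("regular degree k must be an integer >= 2")
    if not 0.0 < z <= 1.0:
        raise ValueError("z must satisfy 0 < z <= 1")
    k = int(k)
    t, n = _grid(T, h)
    atoms = _check_atoms_on_grid(recovery, h)
    exp_beta = make_delay_distribution("exponential", rate=beta)
    Wqb = product_cell_integrals(recovery, exp_beta, h, n)
    q_cont = np.asarray(recovery.density(t), dtype=float)
    fk = (k - 1.0) / k

    S = np.empty(n + 1)
    SS = np.empty(n + 1)
    SI = np.zeros(n + 1)
    c = np.zeros(n + 1)  # c(t) = beta int_0^t fk [SI]/[S]; H1^{k-1} = e^{-c}
    psi_r = np.zeros(n + 1)  # fk [SS][SI]/[S] * e^{c}, history for the kernel
    S[0] = z * N
    SS[0] = k * N * z * z
    SI[0] = k * N * z * (1.0 - z)
    psi_r[0] = fk * SS[0] * SI[0] / S[0]
    truncated_at = None

    def conv(mi, psi_mi, c_mi):
        if mi == 0:
            return 0.0
        hist = psi_r[: mi + 1].copy()
        hist[mi] = psi_mi
        acc = float(np.dot(Wqb[:mi], 0.5 * (hist[mi:0:-1] + hist[mi - 1 :: -1])))
        for steps, loc, w in atoms:
            if mi >= steps:
                acc += w * np.exp(-beta * loc) * hist[mi - steps]
        return acc * np.exp(-c_mi)

    def rhs(mi, s, ss, si, cval):
        if s <= 0:
            return 0.0, 0.0, 0.0, 0.0
        ratio = si / s
        ds = -beta * si
        dss = -2.0 * beta * fk * ss * si / s
        psi_mi = fk * ss * si / s * np.exp(cval)
        dsi = (-beta * fk * si * ratio - beta * si + beta * fk * ss * ratio
               - k * N * q_cont[mi] * np.exp(-beta * t[mi]) * (1.0 - z) * z
               * np.exp(-cval)
               - beta * conv(mi, psi_mi, cval))
        dc = beta * fk * ratio
        return ds, dss, dsi, dc

    for m in range(n):
        if S[m] <= 0:
            truncated_at = t[m]
            S[m:], SS[m:], SI[m:], c[m:] = S[m], SS[m], 0.0, c[m]
            break
        d1 = rhs(m, S[m], SS[m], SI[m], c[m])
        pred = (S[m] + h * d1[0], SS[m] + h * d1[1], SI[m] + h * d1[2], c[m] + h * d1[3])
        d2 = rhs(m + 1, *pred)
        S[m + 1] = S[m] + 0.5 * h * (d1[0] + d2[0])
        SS[m + 1] = max(SS[m] + 0.5 * h * (d1[1] + d2[1]), 0.0)
        SI[m + 1] = max(SI[m] + 0.5 * h * (d1[2] + d2[2]), 0.0)
        c[m + 1] = c[m] + 0.5 * h * (d1[3] + d2[3])
        for steps, loc, w in atoms:
            if steps == m + 1:
                SI[m + 1] = max(
                    SI[m + 1] - k * N * w * np.exp(-beta * loc) * (1.0 - z) * z
                    * np.exp(-c[m + 1]), 0.0)
        psi_r[m + 1] = (fk * SS[m + 1] * SI[m + 1] / S[m + 1] * np.exp(c[m + 1])
                        if S[m + 1] > 0 else 0.0)

    H1 = np.exp(-c / (k - 1.0))
    I = _infected_by_convolution(SI, recovery, beta, N, z, h)
    R = N - S - I
    meta = {"solver": "pairwise_regular", "z": z, "beta": beta, "k": k,
            "h": h, "T": T}
    if truncated_at is not None:
        meta["truncated_at"] = float(truncated_at)
    return PairwiseState(N, t, H1, S, I, R, SI, SS=SS, meta=meta)


def solve_pairwise_markovian(gfs: GeneratingFunctionSet, beta: float,
                             gamma: float, z: float, N: float,
                             T: float, h: float) -> PairwiseState:
    """Fully Markovian system: exponential recovery closes the history terms,
    leaving a plain ODE system in (H1, [SI], [I])."""
    if beta <= 0 or gamma <= 0:
        raise ValueError("beta and gamma must be > 0")
    if not 0.0 < z <= 1.0:
        raise ValueError("z must satisfy 0 < z <= 1")
    t, n = _grid(T, h)
    kbar = gfs.mean_degree

    def rhs(y):
        h1, si, i = y
        h1c = min(max(h1, 0.0), 1.0)
        g1, g2 = gfs.G1(h1c), gfs.G2(h1c)
        dh1 = -beta * si / (z * kbar * N * g1)
        dsi = (-beta * si * si * g2 / (z * kbar * N * g1 * g1)
               - (beta + gamma) * si + z * beta * si * g2)
        di = beta * si - gamma * i
        return np.array([dh1, dsi, di])

    H1 = np.ones(n + 1)
    SI = np.zeros(n + 1)
    I = np.empty(n + 1)
    SI[0] = kbar * N * z * (1.0 - z)
    I[0] = N * (1.0 - z)
    y = np.array([1.0, SI[0], I[0]])
    for m in range(n):
        k1 = rhs(y)
        k2 = rhs(y + 0.5 * h * k1)
        k3 = rhs(y + 0.5 * h * k2)
        k4 = rhs(y + h * k3)
        y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        H1[m + 1] = min(max(y[0], 0.0), 1.0)
        SI[m + 1] = max(y[1], 0.0)
        I[m + 1] = y[2]

    S = z * N * np.asarray(gfs.G0(H1))
    R = N - S - I
    return PairwiseState(N, t, H1, S, I, R, SI,
                         meta={"solver": "pairwise_markovian", "z": z,
                               "beta": beta, "gamma": gamma, "h": h, "T": T})


def solve_pairwise_fixed_delay(gfs: GeneratingFunctionSet, beta: float,
                               sigma: float, z: float, N: float,
                               T: float, h: float) -> PairwiseState:
    """Fixed infectious period sigma: the history integrals collapse to a
    delay differential equation with lag sigma; the initially infected
    cohort recovers impulsively at t = sigma."""
    if beta <= 0 or sigma <= 0:
        raise ValueError("beta and sigma must be > 0")
    if not 0.0 < z <= 1.0:
        raise ValueError("z must satisfy 0 < z <= 1")
    steps = sigma / h
    if abs(steps - round(steps)) > 1e-9:
        raise ValueError(f"sigma={sigma} must be a multiple of the step h={h}")
    L = int(round(steps))
    t, n = _grid(T, h)
    kbar = gfs.mean_degree
    ebs = np.exp(-beta * sigma)

    H1 = np.ones(n + 1)
    SI = np.zeros(n + 1)
    I = np.empty(n + 1)
    SI[0] = kbar * N * z * (1.0 - z)
    I[0] = N * (1.0 - z)

    def lag(arr, mi):
        j = mi - L
        return arr[j] if j >= 0 else 0.0

    def lagH(mi):
        j = mi - L
        return H1[j] if j >= 0 else 1.0

    def rhs(mi, h1, si, i):
        h1c = min(max(h1, 0.0), 1.0)
        g1, g2 = gfs.G1(h1c), gfs.G2(h1c)
        si_lag = lag(SI, mi)
        h1_lag = lagH(mi)
        dh1 = -beta * si / (z * kbar * N * g1)
        di = beta * si - beta * si_lag
        dsi = (-beta * si * si * g2 / (z * kbar * N * g1 * g1)
               - beta * si + z * beta * si * g2
               - z * beta * ebs * si_lag * gfs.G2(h1_lag) * g1 / gfs.G1(h1_lag))
        return dh1, dsi, di

    for m in range(n):
        d1 = rhs(m, H1[m], SI[m], I[m])
        pred = (H1[m] + h * d1[0], SI[m] + h * d1[1], I[m] + h * d1[2])
        d2 = rhs(m + 1, pred[0], pred[1], pred[2])
        H1[m + 1] = min(max(H1[m] + 0.5 * h * (d1[0] + d2[0]), 0.0), 1.0)
        SI[m + 1] = max(SI[m] + 0.5 * h * (d1[1] + d2[1]), 0.0)
        I[m + 1] = I[m] + 0.5 * h * (d1[2] + d2[2])
        if m + 1 == L:  # the initial cohort recovers exactly now
            I[m + 1] -= N * (1.0 - z)
            SI[m + 1] = max(
                SI[m + 1] - ebs * (1.0 - z) * z * gfs.G1(H1[m + 1]) * kbar * N, 0.0)

    S = z * N * np.asarray(gfs.G0(H1))
    R = N - S - I
    return PairwiseState(N, t, H1, S, I, R, SI,
                         meta={"solver": "pairwise_fixed_delay", "z": z,
                               "beta": beta, "sigma": sigma, "h": h, "T": T})
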