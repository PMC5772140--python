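"""Stochastically exact SIR simulation on explicit networks.

Two samplers are provided.  ``simulate_rejection`` implements the classic
scheme for Poisson (rate beta per S-I edge) transmission with an arbitrary
infectious-period law: recovery times are drawn at the moment of infection,
the next putative transmission time is exponential with rate beta times the
current S-I edge count, and whenever a scheduled recovery precedes it the
transmission is rejected and the clock jumps to that recovery.

``simulate_event_driven`` generalises to arbitrary transmission-delay laws:
when a node is infected its recovery delay r ~ q is drawn, and for each
neighbour a transmission delay d ~ tau; an attempt is scheduled iff d < r,
so the per-edge first-attempt density is exactly f(a) = tau(a) xi_q(a), the
kernel of the mean-field models.  Attempts on non-susceptible targets are
no-ops.

Ensembles use one master seed with per-run generators derived as
``default_rng([master_seed, run_index])`` — runs are independent and
individually reproducible.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .degree import StaticNetwork
from .disease import DelayDistribution

__all__ = [
    "EpidemicEventLog",
    "EnsembleSummary",
    "simulate_rejection",
    "simulate_event_driven",
    "ensemble_average",
    "align_at_threshold",
    "run_rng",
]


def run_rng(master_seed: int, run_index: int) -> np.random.Generator:
    """Per-run generator derived from (master seed, run index)."""
    return np.random.default_rng([int(master_seed), int(run_index)])


@dataclass(frozen=True)
class EpidemicEventLog:
    """Ordered record of one sample path.

    Events are (time, node, kind, source) with kind "infection" or
    "recovery"; seed infections appear at t = 0 with source None.
    """

    n_nodes: int
    seed: object
    init: tuple
    events: tuple
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, columns=["time", "node", "event", "source"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def final_size(self) -> int:
        """Number of nodes ever infected."""
        return sum(1 for _, _, kind, _ in self.events if kind == "infection")

    def state_fractions(self, grid: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """S, I, R fractions at the grid times (state after the last event
        at or before each time; the path is right-continuous)."""
        grid = np.asarray(grid, dtype=float)
        if not self.events:  # no seeds drawn: the all-susceptible path
            ones = np.ones_like(grid)
            return ones, np.zeros_like(grid), np.zeros_like(grid)
        times = np.array([e[0] for e in self.events])
        dS = np.array([-1 if e[2] == "infection" else 0 for e in self.events])
        dI = np.array([+1 if e[2] == "infection" else -1 for e in self.events])
        # events are time-ordered; cumulated counts after each event
        S_after = self.n_nodes + np.cumsum(dS)
        I_after = np.cumsum(dI)
        idx = np.searchsorted(times, grid, side="right") - 1
        S = np.where(idx >= 0, S_after[np.maximum(idx, 0)], self.n_nodes)
        I = np.where(idx >= 0, I_after[np.maximum(idx, 0)], 0)
        N = float(self.n_nodes)
        return S / N, I / N, (self.n_nodes - S - I) / N


def _resolve_init(network: StaticNetwork, init, rng: np.random.Generator) -> list[int]:
    """Initial infected set.

    - iterable of node ids: used as given (must be non-empty);
    - int k: k nodes sampled uniformly without replacement;
    - float p in (0, 1): each node independently infected with probability p
      (the mean-field convention with z = 1 - p).
    """
    if isinstance(init, (set, frozenset, list, tuple, np.ndarray)):
        nodes = sorted(int(u) for u in init)
        if not nodes:
            raise ValueError("initial infected set is empty")
        return nodes
    if isinstance(init, (int, np.integer)):
        if not 1 <= init <= network.n_nodes:
            raise ValueError("initial infected count out of range")
        return sorted(rng.choice(network.n_nodes, size=int(init), replace=False).tolist())
    if isinstance(init, float):
        if not 0.0 < init < 1.0:
            raise ValueError("initial infected fraction must be in (0, 1)")
        return np.flatnonzero(rng.random(network.n_nodes) < init).tolist()
    raise ValueError(f"cannot interpret initial condition {init!r}")


def simulate_rejection(network: StaticNetwork, beta: float,
                       recovery: DelayDistribution, init, seed) -> EpidemicEventLog:
    """Rejection-method sample path: Poisson transmission, general recovery."""
    if beta <= 0:
        raise ValueError("beta must be > 0")
    rng = np.random.default_rng(seed)
    adj = network.adjacency()
    n = network.n_nodes
    status = np.zeros(n, dtype=np.int8)  # 0 S, 1 I, 2 R
    ns = np.zeros(n, dtype=np.int64)  # susceptible-neighbour count of infecteds
    kmax = max((len(a) for a in adj), default=0)

    seeds = _resolve_init(network, init, rng)
    events: list[tuple] = []
    recovery_heap: list[tuple] = []
    infected: list[int] = []
    edge_count = 0
    t = 0.0

    def infect(v: int, tt: float, source):
        nonlocal edge_count
        status[v] = 1
        events.append((tt, v, "infection", source))
        r = float(recovery.sample(1, rng)[0])
        heapq.heappush(recovery_heap, (tt + r, v))
        infected.append(v)
        for w in adj[v]:
            if status[w] == 0:
                ns[v] += 1
                edge_count += 1
            elif status[w] == 1:
                ns[w] -= 1
                edge_count -= 1

    for v in seeds:
        infect(v, 0.0, None)

    while recovery_heap:
        if edge_count > 0:
            t_trans = t + rng.exponential(1.0 / (beta * edge_count))
        else:
            t_trans = np.inf
        t_rec, v_rec = recovery_heap[0]
        if t_rec <= t_trans:
            heapq.heappop(recovery_heap)
            status[v_rec] = 2
            edge_count -= ns[v_rec]
            ns[v_rec] = 0
            infected.remove(v_rec)
            events.append((t_rec, v_rec, "recovery", None))
            t = t_rec
        else:
            # uniform S-I edge: rejection-sample the infected endpoint
            # proportionally to its susceptible-neighbour count
            while True:
                v = infected[rng.integers(len(infected))]
                if rng.random() * kmax < ns[v]:
                    break
            sus = [w for w in adj[v] if status[w] == 0]
            target = sus[rng.integers(len(sus))]
            infect(target, t_trans, v)
            t = t_trans

    return EpidemicEventLog(n, seed, tuple(seeds), tuple(events),
                            meta={"method": "rejection", "beta": beta})


def simulate_event_driven(network: StaticNetwork, transmission: DelayDistribution,
                          recovery: DelayDistribution, init, seed) -> EpidemicEventLog:
    """Event-driven sample path for general independent tau and q."""
    rng = np.random.default_rng(seed)
    adj = network.adjacency()
    n = network.n_nodes
    status = np.zeros(n, dtype=np.int8)
    recovery_time = np.full(n, np.inf)

    seeds = _resolve_init(network, init, rng)
    events: list[tuple] = []
    # heap entries (time, node, kind_rank, source); recovery ranks before
    # attempt so simultaneous events resolve deterministically
    heap: list[tuple] = []

    def infect(v: int, tt: float, source):
        status[v] = 1
        events.append((tt, v, "infection", source))
        r = float(recovery.sample(1, rng)[0])
        recovery_time[v] = tt + r
        heapq.heappush(heap, (tt + r, v, 0, None))
        nbrs = adj[v]
        if nbrs:
            delays = np.atleast_1d(transmission.sample(len(nbrs), rng))
            for w, d in zip(nbrs, delays):
                if d < r:
                    heapq.heappush(heap, (tt + float(d), w, 1, v))

    for v in seeds:
        infect(v, 0.0, None)

    while heap:
        tt, v, kind_rank, source = heapq.heappop(heap)
        if kind_rank == 0:
            status[v] = 2
            events.append((tt, v, "recovery", None))
        else:
            if status[v] == 0:
                infect(v, tt, source)

    events.sort(key=lambda e: (e[0], e[1], e[2]))
    return EpidemicEventLog(n, seed, tuple(seeds), tuple(events),
                            meta={"method": "event_driven"})


@dataclass(frozen=True)
class EnsembleSummary:
    """Binned ensemble means and standard errors of the S/I/R fractions."""

    t: np.ndarray
    S_mean: np.ndarray
    S_se: np.ndarray
    I_mean: np.ndarray
    I_se: np.ndarray
    R_mean: np.ndarray
    R_se: np.ndarray
    n_retained: int
    n_discarded: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t, "S_mean": self.S_mean, "S_se": self.S_se,
            "I_mean": self.I_mean, "I_se": self.I_se,
            "R_mean": self.R_mean, "R_se": self.R_se,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def ensemble_average(logs, grid, discard_policy=None) -> EnsembleSummary:
    """Average sample paths on a common grid.

    ``discard_policy`` is an optional predicate; runs for which it returns
    False are excluded (e.g. runs that died out before a threshold).
    """
    grid = np.asarray(grid, dtype=float)
    kept, dropped = [], 0
    sizes = set()
    for log in logs:
        if log is None or (discard_policy is not None and not discard_policy(log)):
            dropped += 1
            continue
        sizes.add(log.n_nodes)
        kept.append(log)
    if not kept:
        raise ValueError("no runs retained for averaging")
    if len(sizes) != 1:
        raise ValueError("runs have different network sizes")

    S = np.empty((len(kept), len(grid)))
    I = np.empty_like(S)
    R = np.empty_like(S)
    for i, log in enumerate(kept):
        S[i], I[i], R[i] = log.state_fractions(grid)
    m = len(kept)
    ddof = 1 if m > 1 else 0

    def se(arr):
        return arr.std(axis=0, ddof=ddof) / np.sqrt(m)

    return EnsembleSummary(grid, S.mean(axis=0), se(S), I.mean(axis=0), se(I),
                           R.mean(axis=0), se(R), m, dropped)


def align_at_threshold(log: EpidemicEventLog, threshold_fraction: float):
    """Reset the clock to the first time the infected fraction reaches the
    threshold (the burn-in protocol for comparing against mean-field curves).

    Returns the shifted log, or None if the run never reaches the threshold.
    The shifted log's meta records the shift and the susceptible fraction at
    reset (the z to hand to a mean-field model).
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must be in (0, 1)")
    n = log.n_nodes
    target = threshold_fraction * n
    s_count, i_count = n, 0
    t_star = None
    for tt, node, kind, source in log.events:
        if kind == "infection":
            s_count -= 1
            i_count += 1
        else:
            i_count -= 1
        if i_count >= target:
            t_star = tt
            break
    if t_star is None:
        return None
    shifted = tuple((tt - t_star, node, kind, source) for tt, node, kind, source in log.events)
    meta = dict(log.meta)
    meta.update({"shift": float(t_star), "z_at_reset": s_count / n,
                 "threshold_fraction": threshold_fraction})
    return EpidemicEventLog(log.n_nodes, log.seed, log.init, shifted, meta)
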