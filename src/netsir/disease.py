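"""Transmission and recovery processes for the SIR epidemic.

The stochastic model attaches to every infected node an *age of infection* a
(time since infection).  Two independent delay distributions drive the
dynamics: tau(a), the density of the time from infection to a transmission
attempt along a given edge, and q(a), the density of the infectious period.
Their survival functions xi_tau, xi_q and hazard functions zeta = tau/xi_tau,
rho = q/xi_q are the representations the mean-field models need.

Two derived kernels appear throughout:

    f(a) = tau(a) * xi_q(a)   -- transmit at age a, not yet recovered
    g(a) = q(a) * xi_tau(a)   -- recover at age a, never having transmitted

Under independence f and g exhaust the first event on an edge, so
int (f + g) da = 1, and T = int f(a) da is the *transmissibility*: the
probability that an infected node attempts transmission across a given edge
before recovering.

Fixed-length periods are represented as point masses (atoms), never as
narrow densities; every solver in the package evaluates atoms directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate
from scipy import stats

__all__ = [
    "DelayDistribution",
    "DiseaseModel",
    "make_delay_distribution",
    "parse_delay_spec",
    "f_and_g",
    "transmissibility",
    "sample_delay",
    "product_cell_integrals",
]

_TINY = 1e-300


class DelayParameterError(ValueError):
    """Raised when delay-distribution parameters are invalid."""


class UnsupportedModelError(ValueError):
    """Raised when a solver cannot handle the supplied disease model."""


@dataclass(frozen=True)
class DelayDistribution:
    """A non-negative delay: absolutely continuous part plus point masses.

    ``frozen`` is a scipy frozen distribution carrying the continuous part
    (or ``None`` for purely atomic laws); ``cont_weight`` is its total mass.
    ``atoms`` is a list of (location, weight) pairs.  The survival function
    here is right-continuous, ``sf(a) = P(X > a)``; ``sf_left(a) = P(X >= a)``
    differs only at atom locations and is what quadrature needs when a cell
    ends exactly on an atom.
    """

    kind: str
    params: dict = field(default_factory=dict)
    frozen: object | None = None
    cont_weight: float = 1.0
    atoms: tuple = ()

    # -- continuous density -------------------------------------------------
    def density(self, a):
        """Density of the absolutely continuous part (atoms excluded)."""
        a = np.asarray(a, dtype=float)
        if self.frozen is None:
            out = np.zeros_like(a)
        else:
            out = self.cont_weight * self.frozen.pdf(a)
            out = np.where(a < 0, 0.0, out)
        return out if out.ndim else float(out)

    # -- survival -----------------------------------------------------------
    def sf(self, a):
        """P(X > a), right-continuous."""
        a = np.asarray(a, dtype=float)
        out = np.zeros_like(a, dtype=float)
        if self.frozen is not None:
            out = out + self.cont_weight * self.frozen.sf(a)
        for loc, w in self.atoms:
            out = out + w * (a < loc)
        out = np.where(a < 0, 1.0, out)
        return out if out.ndim else float(out)

    def sf_left(self, a):
        """P(X >= a): left limit of the survival function."""
        a = np.asarray(a, dtype=float)
        out = np.zeros_like(a, dtype=float)
        if self.frozen is not None:
            out = out + self.cont_weight * self.frozen.sf(a)
        for loc, w in self.atoms:
            out = out + w * (a <= loc)
        out = np.where(a <= 0, 1.0, out)
        return out if out.ndim else float(out)

    def hazard(self, a):
        """density / survival on the continuous part; defined where sf > 0."""
        a = np.asarray(a, dtype=float)
        s = np.asarray(self.sf(a), dtype=float)
        d = np.asarray(self.density(a), dtype=float)
        out = np.where(s > _TINY, d / np.where(s > _TINY, s, 1.0), 0.0)
        return out if out.ndim else float(out)

    @property
    def has_atoms(self) -> bool:
        return len(self.atoms) > 0

    @property
    def atom_locations(self) -> tuple:
        return tuple(loc for loc, _ in self.atoms)

    def mean(self) -> float:
        m = sum(w * loc for loc, w in self.atoms)
        if self.frozen is not None:
            m += self.cont_weight * float(self.frozen.mean())
        return float(m)

    def support_cap(self, tail: float = 1e-12) -> float:
        """An age A with P(X > A) < tail (caps improper integrals)."""
        caps = [loc for loc, _ in self.atoms]
        if self.frozen is not None:
            caps.append(float(self.frozen.isf(min(tail / max(self.cont_weight, tail), 1.0))))
        return max(caps) if caps else 0.0

    def _sample_continuous(self, n: int, rng: np.random.Generator) -> np.ndarray:
        p = self.params
        if self.kind == "exponential":
            return rng.exponential(1.0 / p["rate"], n)
        if self.kind == "gamma":
            return rng.gamma(p["shape"], p["scale"], n)
        if self.kind == "weibull":
            return p["scale"] * rng.weibull(p["shape"], n)
        if self.kind == "truncated_normal":
            # truncation at 0 by redrawing the (small) negative tail
            out = rng.normal(p["mean"], p["sd"], n)
            bad = out < 0
            while bad.any():
                out[bad] = rng.normal(p["mean"], p["sd"], int(bad.sum()))
                bad = out < 0
            return out
        return np.asarray(self.frozen.rvs(size=n, random_state=rng), dtype=float)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """n i.i.d. draws, reproducible under the supplied generator."""
        atom_w = sum(w for _, w in self.atoms)
        if self.frozen is None or atom_w >= 1.0 - 1e-15:
            locs = np.array([loc for loc, _ in self.atoms])
            ws = np.array([w for _, w in self.atoms], dtype=float)
            return rng.choice(locs, size=n, p=ws / ws.sum())
        if atom_w <= 1e-15:
            return self._sample_continuous(n, rng)
        out = np.empty(n)
        from_atom = rng.random(n) < atom_w
        k = int(from_atom.sum())
        if k:
            locs = np.array([loc for loc, _ in self.atoms])
            ws = np.array([w for _, w in self.atoms], dtype=float)
            out[from_atom] = rng.choice(locs, size=k, p=ws / ws.sum())
        out[~from_atom] = self._sample_continuous(n - k, rng)
        return out


def make_delay_distribution(kind: str, **params) -> DelayDistribution:
    """Build a delay distribution of a named family.

    Kinds: ``exponential`` (rate), ``fixed`` (duration), ``truncated_normal``
    (mean, sd; truncated to a >= 0 and renormalised), ``gamma`` (shape,
    scale), ``weibull`` (shape, scale), ``empirical`` (table: delay -> mass).
    """
    if kind == "exponential":
        rate = params.get("rate")
        if rate is None or rate <= 0:
            raise DelayParameterError(f"exponential rate must be > 0, got {rate!r}")
        return DelayDistribution("exponential", {"rate": rate},
                                 frozen=stats.expon(scale=1.0 / rate))
    if kind == "fixed":
        duration = params.get("duration")
        if duration is None or duration <= 0:
            raise DelayParameterError(f"fixed duration must be > 0, got {duration!r}")
        return DelayDistribution("fixed", {"duration": duration},
                                 frozen=None, cont_weight=0.0,
                                 atoms=((float(duration), 1.0),))
    if kind == "truncated_normal":
        mean, sd = params.get("mean"), params.get("sd")
        if mean is None or sd is None or sd <= 0:
            raise DelayParameterError(f"truncated_normal needs mean and sd > 0, got {params!r}")
        a = (0.0 - mean) / sd  # truncate the negative tail, renormalise
        return DelayDistribution("truncated_normal", {"mean": mean, "sd": sd},
                                 frozen=stats.truncnorm(a, np.inf, loc=mean, scale=sd))
    if kind == "gamma":
        shape, scale = params.get("shape"), params.get("scale")
        if shape is None or scale is None or shape <= 0 or scale <= 0:
            raise DelayParameterError(f"gamma needs shape, scale > 0, got {params!r}")
        return DelayDistribution("gamma", {"shape": shape, "scale": scale},
                                 frozen=stats.gamma(shape, scale=scale))
    if kind == "weibull":
        shape, scale = params.get("shape"), params.get("scale")
        if shape is None or scale is None or shape <= 0 or scale <= 0:
            raise DelayParameterError(f"weibull needs shape, scale > 0, got {params!r}")
        return DelayDistribution("weibull", {"shape": shape, "scale": scale},
                                 frozen=stats.weibull_min(shape, scale=scale))
    if kind == "empirical":
        table = params.get("table")
        if not table:
            raise DelayParameterError("empirical delay table is missing or empty")
        locs = sorted(float(k) for k in table)
        if any(loc < 0 for loc in locs):
            raise DelayParameterError("empirical delays must be non-negative")
        ws = np.array([float(table[k]) for k in locs])
        if np.any(ws < 0) or ws.sum() <= 0:
            raise DelayParameterError("empirical masses must be non-negative, sum > 0")
        ws = ws / ws.sum()
        return DelayDistribution("empirical", {"table": dict(table)},
                                 frozen=None, cont_weight=0.0,
                                 atoms=tuple(zip(locs, ws)))
    raise DelayParameterError(f"unknown delay-distribution kind {kind!r}")


def parse_delay_spec(spec: str) -> DelayDistribution:
    """Parse a textual spec: "exp:0.5", "fixed:2", "normal:2,0.75",
    "gamma:shape,scale", "weibull:shape,scale", "empirical:path.tsv"."""
    try:
        name, arg = spec.split(":", 1)
    except ValueError as exc:
        raise DelayParameterError(f"malformed delay spec {spec!r}") from exc
    name = name.strip().lower()
    if name in ("exp", "exponential"):
        return make_delay_distribution("exponential", rate=float(arg))
    if name == "fixed":
        return make_delay_distribution("fixed", duration=float(arg))
    if name in ("normal", "truncated_normal"):
        mean, sd = (float(x) for x in arg.split(","))
        return make_delay_distribution("truncated_normal", mean=mean, sd=sd)
    if name == "gamma":
        shape, scale = (float(x) for x in arg.split(","))
        return make_delay_distribution("gamma", shape=shape, scale=scale)
    if name == "weibull":
        shape, scale = (float(x) for x in arg.split(","))
        return make_delay_distribution("weibull", shape=shape, scale=scale)
    if name == "empirical":
        table = {}
        with open(arg) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                d, p = line.split("\t")
                table[float(d)] = float(p)
        return make_delay_distribution("empirical", table=table)
    raise DelayParameterError(f"unknown delay spec {spec!r}")


@dataclass(frozen=True)
class DiseaseModel:
    """Independent transmission (tau) and recovery (q) processes."""

    transmission: DelayDistribution
    recovery: DelayDistribution

    def f_density(self, a):
        """Continuous part of f(a) = tau(a) xi_q(a)."""
        return self.transmission.density(a) * self.recovery.sf(a)

    def g_density(self, a):
        """Continuous part of g(a) = q(a) xi_tau(a)."""
        return self.recovery.density(a) * self.transmission.sf(a)

    @property
    def f_atoms(self) -> tuple:
        """Point masses of f: transmission atoms thinned by recovery survival.

        A transmission atom at d fires iff the recovery time strictly exceeds
        d (ties go to recovery, matching the event-driven simulator)."""
        return tuple((loc, w * float(self.recovery.sf(loc)))
                     for loc, w in self.transmission.atoms)

    @property
    def g_atoms(self) -> tuple:
        """Point masses of g: recovery atoms thinned by transmission survival."""
        return tuple((loc, w * float(self.transmission.sf_left(loc)))
                     for loc, w in self.recovery.atoms)

    def support_cap(self, tail: float = 1e-12) -> float:
        """Age beyond which xi_tau * xi_q < tail (either factor suffices)."""
        return float(min(self.transmission.support_cap(tail),
                         self.recovery.support_cap(tail)))

    def transmissibility(self) -> float:
        """T = int f(a) da, the per-edge transmission probability."""
        cap = self.support_cap()
        total = sum(w for _, w in self.f_atoms)
        if self.transmission.frozen is not None and cap > 0:
            breaks = sorted({0.0, cap, *[loc for loc in self.recovery.atom_locations
                                         if 0.0 < loc < cap]})
            for lo, hi in zip(breaks[:-1], breaks[1:]):
                val, err = integrate.quad(self.f_density, lo, hi, limit=200,
                                          epsabs=1e-10, epsrel=1e-10)
                if not np.isfinite(val):
                    raise ArithmeticError(
                        f"transmissibility quadrature failed on [{lo}, {hi}]: {val}")
                total += val
        if not -1e-8 <= total <= 1 + 1e-8:
            raise ArithmeticError(f"transmissibility {total} outside [0, 1]")
        return float(min(max(total, 0.0), 1.0))

    def fg_total_mass(self) -> float:
        """int (f + g) da including atoms; equals 1 for proper distributions."""
        cap = self.support_cap()
        total = sum(w for _, w in self.f_atoms) + sum(w for _, w in self.g_atoms)
        breaks = sorted({0.0, cap,
                         *[loc for loc in self.recovery.atom_locations if 0 < loc < cap],
                         *[loc for loc in self.transmission.atom_locations if 0 < loc < cap]})
        for lo, hi in zip(breaks[:-1], breaks[1:]):
            if self.transmission.frozen is not None:
                total += integrate.quad(self.f_density, lo, hi, limit=200,
                                        epsabs=1e-10)[0]
            if self.recovery.frozen is not None:
                total += integrate.quad(self.g_density, lo, hi, limit=200,
                                        epsabs=1e-10)[0]
        return float(total)


def f_and_g(model: DiseaseModel, a):
    """Continuous parts (f(a), g(a)); atoms via model.f_atoms / model.g_atoms."""
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise ValueError("age of infection must be >= 0")
    return model.f_density(a), model.g_density(a)


def transmissibility(model: DiseaseModel) -> float:
    """Probability that infection is transmitted along an edge before recovery."""
    return model.transmissibility()


def sample_delay(dist: DelayDistribution, rng: np.random.Generator, n: int = 1):
    """Draw delays; returns a scalar for n=1, else an array."""
    out = dist.sample(n, rng)
    return float(out[0]) if n == 1 else out


def product_cell_integrals(density_dist: DelayDistribution,
                           survival_dist: DelayDistribution,
                           h: float, n_cells: int,
                           subdiv: int = 8) -> np.ndarray:
    """W_j = int over [j h, (j+1) h] of density_dist(a) * survival_dist.sf(a) da.

    Composite Simpson on ``subdiv`` subintervals per cell; the right endpoint
    of each cell is evaluated with the left limit of the survival function so
    that survival jumps sitting on cell boundaries (fixed infectious period on
    a matching grid) are integrated exactly from within each cell.

    These per-cell kernel masses are what the Volterra solvers convolve with
    piecewise-linear reconstructions of the unknown (product integration).
    """
    if subdiv % 2:
        raise ValueError("subdiv must be even for Simpson weights")
    if density_dist.frozen is None:
        return np.zeros(n_cells)
    offsets = h * np.arange(subdiv + 1) / subdiv
    a = np.arange(n_cells)[:, None] * h + offsets[None, :]
    dens = density_dist.density(a.ravel()).reshape(a.shape)
    surv = np.asarray(survival_dist.sf(a.ravel()), dtype=float).reshape(a.shape)
    # right endpoint from the left: P(X >= a)
    surv[:, -1] = np.asarray(survival_dist.sf_left(a[:, -1]), dtype=float)
    w = np.ones(subdiv + 1)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    w *= (h / subdiv) / 3.0
    return (dens * surv) @ w
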