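"""Degree distributions, generating functions, and configuration-model networks.

A configuration-model (CM) network is a random graph with a prescribed degree
distribution ``p_k``, built by uniform stub matching.  As the network grows it
becomes locally tree-like, which is what makes the mean-field models in this
package exact on the infinite-size CM ensemble.

The probability generating functions of the degree distribution,

    G0(x) = sum_k p_k x^k
    G1(x) = sum_k p_k k x^(k-1) / <k>        (excess-degree distribution)
    G2(x) = G1'(x) = sum_k p_k k(k-1) x^(k-2) / <k>

are the only way the network topology enters the mean-field equations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DegreeDistribution",
    "GeneratingFunctionSet",
    "StaticNetwork",
    "make_degree_distribution",
    "evaluate_gfs",
    "mean_excess_degree",
    "sample_configuration_network",
    "read_edge_list",
    "write_edge_list",
]

_NORM_TOL = 1e-12


class DegreeParameterError(ValueError):
    """Raised when degree-distribution parameters are invalid."""


@dataclass(frozen=True)
class DegreeDistribution:
    """Probability mass function p_k over non-negative integer degrees."""

    support: np.ndarray
    pmf: np.ndarray
    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        support = np.asarray(self.support, dtype=int)
        pmf = np.asarray(self.pmf, dtype=float)
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "pmf", pmf)
        if support.ndim != 1 or pmf.shape != support.shape:
            raise DegreeParameterError("support and pmf must be 1-d arrays of equal length")
        if np.any(support < 0):
            raise DegreeParameterError("support contains negative degrees")
        if np.any(pmf < 0):
            raise DegreeParameterError("pmf contains negative masses")
        total = pmf.sum()
        if abs(total - 1.0) > 1e-9:
            raise DegreeParameterError(f"pmf sums to {total!r}, not 1")
        # renormalise away the residual so downstream identities hold to 1e-12
        object.__setattr__(self, "pmf", pmf / total)

    @property
    def mean_degree(self) -> float:
        """<k> = sum_k k p_k."""
        return float(np.dot(self.support, self.pmf))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n i.i.d. degrees."""
        return rng.choice(self.support, size=n, p=self.pmf)


def make_degree_distribution(kind: str, **params) -> DegreeDistribution:
    """Build a degree distribution of a named family.

    Supported kinds:

    - ``regular``: every node has degree ``k``.
    - ``poisson``: Poisson(``lam``) truncated at ``kmax`` (default: smallest k
      whose tail mass is below 1e-10) and renormalised.
    - ``powerlaw_truncated``: p_k proportional to k^-``exponent`` on
      [``kmin``, ``kmax``].
    - ``empirical``: explicit ``pmf`` mapping degree -> mass (renormalised).
    """
    if kind == "regular":
        k = params.get("k")
        if k is None or int(k) != k or k < 1:
            raise DegreeParameterError(f"regular degree k must be an integer >= 1, got {k!r}")
        return DegreeDistribution(np.array([int(k)]), np.array([1.0]), "regular", {"k": int(k)})

    if kind == "poisson":
        lam = params.get("lam")
        if lam is None or lam <= 0:
            raise DegreeParameterError(f"poisson rate lam must be > 0, got {lam!r}")
        kmax = params.get("kmax")
        if kmax is None:
            from scipy.stats import poisson as _poisson

            kmax = int(_poisson.isf(1e-10, lam)) + 1
        support = np.arange(0, int(kmax) + 1)
        from scipy.stats import poisson as _poisson

        pmf = _poisson.pmf(support, lam)
        pmf = pmf / pmf.sum()
        return DegreeDistribution(support, pmf, "poisson", {"lam": lam, "kmax": int(kmax)})

    if kind == "powerlaw_truncated":
        exponent = params.get("exponent")
        kmin = params.get("kmin")
        kmax = params.get("kmax")
        if exponent is None or exponent <= 1:
            raise DegreeParameterError(f"powerlaw exponent must be > 1, got {exponent!r}")
        if kmin is None or kmax is None or not (1 <= kmin <= kmax):
            raise DegreeParameterError(
                f"powerlaw bounds must satisfy 1 <= kmin <= kmax, got kmin={kmin!r} kmax={kmax!r}"
            )
        support = np.arange(int(kmin), int(kmax) + 1)
        pmf = support.astype(float) ** (-float(exponent))
        pmf = pmf / pmf.sum()
        return DegreeDistribution(
            support, pmf, "powerlaw_truncated",
            {"exponent": float(exponent), "kmin": int(kmin), "kmax": int(kmax)},
        )

    if kind == "empirical":
        table = params.get("pmf")
        if not table:
            raise DegreeParameterError("empirical pmf table is missing or empty")
        support = np.array(sorted(int(k) for k in table))
        masses = np.array([float(table[k]) for k in support])
        if np.any(masses < 0):
            raise DegreeParameterError("empirical pmf has negative masses")
        total = masses.sum()
        if total <= 0:
            raise DegreeParameterError("empirical pmf sums to 0")
        return DegreeDistribution(support, masses / total, "empirical", {"pmf": dict(table)})

    raise DegreeParameterError(f"unknown degree-distribution kind {kind!r}")


class GeneratingFunctionSet:
    """G0, G1, G2 evaluators backed by a :class:`DegreeDistribution`."""

    def __init__(self, dd: DegreeDistribution):
        if dd.mean_degree <= 0:
            raise DegreeParameterError("generating functions require mean degree > 0")
        self.dd = dd
        k = dd.support.astype(float)
        p = dd.pmf
        kbar = dd.mean_degree
        self._k = k
        self._p = p
        self._kbar = kbar
        # coefficient arrays for G1 and G2 (excess-degree gf and its derivative)
        self._c1 = p * k / kbar
        self._c2 = p * k * (k - 1.0) / kbar

    @staticmethod
    def _check_domain(x):
        x = np.asarray(x, dtype=float)
        if np.any(x < 0.0) or np.any(x > 1.0):
            raise ValueError("generating functions are defined on x in [0, 1]")
        return x

    def _powsum(self, coeff: np.ndarray, exponents: np.ndarray, x) -> np.ndarray | float:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        # 0^0 := 1 so a degree-0 (or degree-1 in G1) term contributes its mass at x=0
        with np.errstate(divide="ignore"):
            vals = np.where(
                exponents[None, :] == 0, 1.0, x[:, None] ** np.maximum(exponents, 0)[None, :]
            )
        out = vals @ coeff
        return out

    def G0(self, x):
        x = self._check_domain(x)
        out = self._powsum(self._p, self._k.astype(int), x)
        return float(out[0]) if np.isscalar(x) or x.ndim == 0 else out

    def G1(self, x):
        x = self._check_domain(x)
        out = self._powsum(self._c1, self._k.astype(int) - 1, x)
        return float(out[0]) if np.isscalar(x) or x.ndim == 0 else out

    def G2(self, x):
        x = self._check_domain(x)
        out = self._powsum(self._c2, self._k.astype(int) - 2, x)
        return float(out[0]) if np.isscalar(x) or x.ndim == 0 else out

    @property
    def mean_degree(self) -> float:
        return self._kbar

    @property
    def mean_excess_degree(self) -> float:
        """G1'(1) = sum_k p_k k(k-1) / <k>."""
        return float(self._c2.sum())


def evaluate_gfs(gfs: GeneratingFunctionSet, x):
    """Evaluate (G0(x), G1(x), G2(x)); x must lie in [0, 1]."""
    return gfs.G0(x), gfs.G1(x), gfs.G2(x)


def mean_excess_degree(gfs: GeneratingFunctionSet) -> float:
    """Mean number of onward contacts of a node reached along a random edge."""
    return gfs.mean_excess_degree


@dataclass(frozen=True)
class StaticNetwork:
    """Simple undirected graph: node ids 0..N-1, sorted unique edge list."""

    n_nodes: int
    edges: np.ndarray  # (m, 2) int array, each row sorted, rows lexsorted

    def __post_init__(self):
        edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        edges = np.sort(edges, axis=1)
        if edges.size and np.any(edges[:, 0] == edges[:, 1]):
            raise ValueError("self-loops are not allowed")
        if edges.size:
            uniq = np.unique(edges, axis=0)
            if uniq.shape != edges.shape:
                raise ValueError("duplicate edges are not allowed")
            edges = uniq[np.lexsort((uniq[:, 1], uniq[:, 0]))]
            if edges.max() >= self.n_nodes or edges.min() < 0:
                raise ValueError("edge endpoint outside node range")
        object.__setattr__(self, "edges", edges)

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    @property
    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        if self.edges.size:
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for u, v in self.edges:
            adj[u].append(int(v))
            adj[v].append(int(u))
        return adj

    def is_forest(self) -> bool:
        """True iff the graph contains no cycle (union-find)."""
        parent = list(range(self.n_nodes))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for u, v in self.edges:
            ru, rv = find(int(u)), find(int(v))
            if ru == rv:
                return False
            parent[ru] = rv
        return True


def sample_configuration_network(
    dd: DegreeDistribution, n_nodes: int, seed: int, max_retries: int = 100
) -> StaticNetwork:
    """Draw a simple CM network: i.i.d. degrees, uniform stub matching.

    Self-loops and duplicate edges produced by the matching are erased (the
    standard "erased configuration model"); for the network sizes and degree
    distributions used here this removes well under 2% of edges.  If the drawn
    degree sequence has odd total, the last node's degree is redrawn until the
    parity is even.
    """
    if n_nodes < 2:
        raise DegreeParameterError("configuration model needs N >= 2")
    if dd.support.max() > n_nodes - 1:
        warnings.warn(
            "degree support exceeds N-1; truncating the distribution", stacklevel=2
        )
        keep = dd.support <= n_nodes - 1
        dd = DegreeDistribution(
            dd.support[keep], dd.pmf[keep] / dd.pmf[keep].sum(), dd.kind, dd.params
        )
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        degrees = dd.sample(n_nodes, rng)
        tries = 0
        while degrees.sum() % 2 == 1:
            degrees[-1] = dd.sample(1, rng)[0]
            tries += 1
            if tries > 1000:  # all-odd support with odd N: flip one stub instead
                degrees[-1] += 1
                break
        stubs = np.repeat(np.arange(n_nodes), degrees)
        rng.shuffle(stubs)
        pairs = stubs.reshape(-1, 2)
        pairs = np.sort(pairs, axis=1)
        keep = pairs[:, 0] != pairs[:, 1]
        pairs = np.unique(pairs[keep], axis=0)
        if pairs.size:
            return StaticNetwork(n_nodes, pairs)
    raise RuntimeError("failed to build a non-empty simple graph after retries")


def write_edge_list(net: StaticNetwork, path) -> None:
    """Write a two-column tab-separated edge list (0-based ids, sorted, no header)."""
    with open(path, "w") as fh:
        for u, v in net.edges:
            fh.write(f"{u}\t{v}\n")


def read_edge_list(path, n_nodes: int | None = None) -> StaticNetwork:
    """Read a two-column tab-separated edge list; rejects self-loops/duplicates."""
    edges = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{line_no}: expected two tab-separated columns")
            u, v = int(parts[0]), int(parts[1])
            if u == v:
                raise ValueError(f"{path}:{line_no}: self-loop {u}")
            edges.append((u, v))
    arr = np.array(edges, dtype=int).reshape(-1, 2)
    if n_nodes is None:
        n_nodes = int(arr.max()) + 1 if arr.size else 0
    return StaticNetwork(n_nodes, arr)
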