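"""Experiment configuration, fixtures, and the end-to-end runner.

An experiment bundles one degree distribution, one disease model, a grid and
an ensemble size, runs every requested solver on the same grid, simulates a
stochastic ensemble, and writes trajectory/ensemble CSVs plus a JSON summary
with final-size analytics and pairwise equivalence gaps.  The whole bundle
is a pure function of the configuration (including the master seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .degree import (DegreeDistribution, GeneratingFunctionSet, StaticNetwork,
                     make_degree_distribution, sample_configuration_network,
                     write_edge_list)
from .disease import (DiseaseModel, UnsupportedModelError, parse_delay_spec)
from .ebcm import equivalence_report, solve_ebcm
from .mp import epidemic_threshold, final_size, solve_mp, solve_mp_markovian_ode
from .pairwise import (solve_pairwise_cm, solve_pairwise_fixed_delay,
                       solve_pairwise_markovian, solve_pairwise_regular)
from .simulate import ensemble_average, simulate_event_driven, simulate_rejection

__all__ = ["ExperimentConfig", "run_experiment", "make_fixture",
           "parse_degree_spec", "VALIDATION_RECOVERY_SPECS"]

# the validation design used throughout: truncated scale-free network,
# Poisson transmission at rate 0.3, three infectious-period laws with mean 2
VALIDATION_DEGREE = {"kind": "powerlaw_truncated", "exponent": 2.5, "kmin": 3, "kmax": 60}
VALIDATION_BETA = 0.3
VALIDATION_RECOVERY_SPECS = {"exponential": "exp:0.5", "normal": "normal:2,0.75",
                             "fixed": "fixed:2"}


def parse_degree_spec(spec: str) -> DegreeDistribution:
    """Parse "regular:5", "poisson:6[,kmax]", "powerlaw:2.5,3,60" or
    "empirical:{json degree->mass}"."""
    name, _, arg = spec.partition(":")
    name = name.strip().lower()
    if name == "regular":
        return make_degree_distribution("regular", k=int(arg))
    if name == "poisson":
        parts = arg.split(",")
        kw = {"lam": float(parts[0])}
        if len(parts) > 1:
            kw["kmax"] = int(parts[1])
        return make_degree_distribution("poisson", **kw)
    if name in ("powerlaw", "powerlaw_truncated"):
        expo, kmin, kmax = arg.split(",")
        return make_degree_distribution("powerlaw_truncated", exponent=float(expo),
                                        kmin=int(kmin), kmax=int(kmax))
    if name == "empirical":
        table = {int(k): float(v) for k, v in json.loads(arg).items()}
        return make_degree_distribution("empirical", pmf=table)
    raise ValueError(f"unknown degree spec {spec!r}")


@dataclass
class ExperimentConfig:
    """Flat, JSON-serialisable experiment description."""

    degree: str = "powerlaw:2.5,3,60"
    transmission: str = "exp:0.3"
    recovery: str = "exp:0.5"
    z: float = 0.99
    N: int = 1000
    T: float = 15.0
    h: float = 0.01
    runs: int = 200
    seed: int = 1
    solvers: list = field(default_factory=lambda: ["mp", "ebcm"])
    sim_method: str = "event"  # "event" | "rejection" | "none"
    label: str = "experiment"

    def validate(self) -> "ExperimentConfig":
        parse_degree_spec(self.degree)
        parse_delay_spec(self.transmission)
        parse_delay_spec(self.recovery)
        if self.h <= 0 or self.T < self.h:
            raise ValueError("need h > 0 and T >= h")
        if not 0 < self.z <= 1:
            raise ValueError("z must be in (0, 1]")
        if self.sim_method != "none" and self.runs < 1:
            raise ValueError("run count must be >= 1")
        return self

    @classmethod
    def from_json(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls(**json.load(fh)).validate()

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _solve_one(name: str, gfs, model, cfg: ExperimentConfig):
    tau, q = model.transmission, model.recovery
    if name == "mp":
        return solve_mp(gfs, model, cfg.z, cfg.T, cfg.h)
    if name == "ebcm":
        return solve_ebcm(gfs, model, cfg.z, cfg.T, cfg.h, keep_densities=False)[0]
    if name == "ode":
        if tau.kind != "exponential" or q.kind != "exponential":
            raise UnsupportedModelError("ode solver needs exponential tau and q")
        return solve_mp_markovian_ode(gfs, tau.params["rate"], q.params["rate"],
                                      cfg.z, cfg.T, cfg.h)
    if name.startswith("pairwise"):
        if tau.kind != "exponential":
            raise UnsupportedModelError("pairwise hierarchy needs exponential tau")
        beta = tau.params["rate"]
        if name == "pairwise_cm":
            return solve_pairwise_cm(gfs, beta, q, cfg.z, cfg.N, cfg.T, cfg.h).per_capita()
        if name == "pairwise_regular":
            if gfs.dd.kind != "regular":
                raise UnsupportedModelError("pairwise_regular needs a regular degree")
            return solve_pairwise_regular(gfs.dd.params["k"], beta, q, cfg.z,
                                          cfg.N, cfg.T, cfg.h).per_capita()
        if name == "pairwise_markovian":
            if q.kind != "exponential":
                raise UnsupportedModelError("pairwise_markovian needs exponential q")
            return solve_pairwise_markovian(gfs, beta, q.params["rate"], cfg.z,
                                            cfg.N, cfg.T, cfg.h).per_capita()
        if name == "pairwise_fixed":
            if q.kind != "fixed":
                raise UnsupportedModelError("pairwise_fixed needs a fixed period")
            return solve_pairwise_fixed_delay(gfs, beta, q.params["duration"],
                                              cfg.z, cfg.N, cfg.T, cfg.h).per_capita()
    raise ValueError(f"unknown solver {name!r}")


def run_experiment(config: ExperimentConfig, out_dir,
                   network: StaticNetwork | None = None) -> dict:
    """Run every requested solver plus a simulation ensemble; write CSVs and
    a JSON summary; return the summary dict."""
    cfg = config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dd = parse_degree_spec(cfg.degree)
    gfs = GeneratingFunctionSet(dd)
    model = DiseaseModel(parse_delay_spec(cfg.transmission), parse_delay_spec(cfg.recovery))

    summary: dict = {
        "config": asdict(cfg),
        "transmissibility": model.transmissibility(),
        "epidemic_threshold": epidemic_threshold(gfs, model),
        "solvers": {},
        "errors": {},
    }
    theta_inf, r_inf = final_size(gfs, model)
    summary["final_size"] = {"theta_inf": theta_inf, "r_inf": r_inf}

    trajectories = {}
    for name in cfg.solvers:
        try:
            traj = _solve_one(name, gfs, model, cfg)
        except (UnsupportedModelError, ValueError) as exc:
            summary["errors"][name] = str(exc)
            continue
        trajectories[name] = traj
        traj.to_csv(out / f"trajectory_{name}.csv")
        summary["solvers"][name] = {"peak_time": traj.peak()[0],
                                    "peak_prevalence": traj.peak()[1],
                                    "final_R": float(traj.R[-1])}

    names = sorted(trajectories)
    summary["equivalence"] = {
        f"{a}_vs_{b}": equivalence_report(trajectories[a], trajectories[b])
        for i, a in enumerate(names) for b in names[i + 1:]
    }

    if cfg.sim_method != "none":
        if network is None:
            network = sample_configuration_network(dd, cfg.N, seed=cfg.seed)
        grid = np.arange(int(round(cfg.T / cfg.h)) + 1) * cfg.h
        logs = []
        for r in range(cfg.runs):
            rng_seed = [cfg.seed, r]
            if cfg.sim_method == "rejection":
                if model.transmission.kind != "exponential":
                    raise UnsupportedModelError("rejection method needs exponential tau")
                log = simulate_rejection(network, model.transmission.params["rate"],
                                         model.recovery, 1.0 - cfg.z, rng_seed)
            else:
                log = simulate_event_driven(network, model.transmission,
                                            model.recovery, 1.0 - cfg.z, rng_seed)
            logs.append(log)
        ens = ensemble_average(logs, grid)
        ens.to_csv(out / "ensemble.csv")
        summary["ensemble"] = {"n_retained": ens.n_retained,
                               "n_discarded": ens.n_discarded,
                               "peak_prevalence": float(ens.I_mean.max())}
        # fraction of grid points where each mean-field curve sits inside
        # the 95% confidence band of the ensemble mean
        band = {}
        lo = ens.I_mean - 1.96 * ens.I_se
        hi = ens.I_mean + 1.96 * ens.I_se
        for name, traj in trajectories.items():
            inside = (traj.I >= lo) & (traj.I <= hi)
            band[name] = float(inside.mean())
        summary["ci_band_coverage"] = band

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    return summary


def validation_ensemble(recovery_spec: str, runs: int = 200, seed: int = 1,
                        N: int = 1000, z: float = 0.99, T: float = 15.0,
                        grid_step: float = 0.1, h: float = 0.01,
                        beta: float = VALIDATION_BETA) -> dict:
    """The package's reference validation experiment: mean-field curve versus
    a stochastic ensemble on truncated scale-free networks.

    Each run draws a fresh configuration-model network (the mean-field models
    are exact on the CM *ensemble*) and an event-driven sample path with
    fresh-cohort seeding (each node initially infected with probability
    1 - z, infection age 0).  Returns the grid, the ensemble mean/spread of
    the prevalence, the mean-field prevalence, coverage fractions for the
    realisation band (mean +/- 1.96 sd, ~95% of runs) and for the far
    narrower confidence band of the ensemble mean (mean +/- 1.96 se), and
    peak statistics.
    """
    dd = make_degree_distribution(**VALIDATION_DEGREE)
    gfs = GeneratingFunctionSet(dd)
    tau = parse_delay_spec(f"exp:{beta}")
    q = parse_delay_spec(recovery_spec)
    model = DiseaseModel(tau, q)
    grid = np.arange(int(round(T / grid_step)) + 1) * grid_step
    I_runs = np.empty((runs, len(grid)))
    for r in range(runs):
        net = sample_configuration_network(dd, N, seed=[seed, r, 0])
        log = simulate_event_driven(net, tau, q, 1.0 - z, [seed, r, 1])
        I_runs[r] = log.state_fractions(grid)[1]
    mean = I_runs.mean(axis=0)
    sd = I_runs.std(axis=0, ddof=1)
    se = sd / np.sqrt(runs)
    mf = solve_mp(gfs, model, z, T, h)
    I_mf = np.interp(grid, mf.t, mf.I)
    # simulated prevalence lives on a lattice of spacing 1/N: differences
    # below half a node are not resolvable, so the bands carry that floor
    # (otherwise the band degenerates to a point once every run has I = 0)
    resolution = 0.5 / N
    in_run_band = np.abs(I_mf - mean) <= 1.96 * sd + resolution
    in_mean_band = np.abs(I_mf - mean) <= 1.96 * se + resolution
    j = int(np.argmax(mean))
    return {
        "grid": grid, "I_mean": mean, "I_sd": sd, "I_se": se, "I_mf": I_mf,
        "coverage_run_band": float(in_run_band.mean()),
        "coverage_mean_band": float(in_mean_band.mean()),
        "peak_prevalence": float(mean[j]),
        "peak_se": float(se[j]),
        "peak_time": float(grid[j]),
        "mf_peak_prevalence": float(I_mf.max()),
        "runs": runs,
    }


def _fixture_networks() -> dict[str, StaticNetwork]:
    path3 = StaticNetwork(3, [(0, 1), (1, 2)])
    star5 = StaticNetwork(5, [(0, 1), (0, 2), (0, 3), (0, 4)])
    btree3 = StaticNetwork(15, [(i, 2 * i + 1) for i in range(7)]
                           + [(i, 2 * i + 2) for i in range(7)])
    cycle10 = StaticNetwork(10, [(i, (i + 1) % 10) for i in range(10)])
    return {"path3": path3, "star5": star5, "btree3": btree3, "cycle10": cycle10}


def make_fixture(kind: str, out_dir) -> Path:
    """Write a named deterministic fixture (network TSV or experiment JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    networks = _fixture_networks()
    if kind in networks:
        path = out / f"{kind}.tsv"
        write_edge_list(networks[kind], path)
        return path
    configs = {
        f"validation_{label}": ExperimentConfig(
            degree="powerlaw:2.5,3,60", transmission=f"exp:{VALIDATION_BETA}",
            recovery=spec, z=0.99, N=1000, T=15.0, h=0.01, runs=200,
            solvers=["mp", "ebcm"], sim_method="event", label=f"validation_{label}")
        for label, spec in VALIDATION_RECOVERY_SPECS.items()
    }
    configs["markovian_regular"] = ExperimentConfig(
        degree="regular:5", transmission="exp:0.3", recovery="exp:0.5",
        z=0.99, N=1000, T=15.0, h=0.01, runs=200,
        solvers=["mp", "ebcm", "ode", "pairwise_cm", "pairwise_regular",
                 "pairwise_markovian"],
        sim_method="rejection", label="markovian_regular")
    if kind in configs:
        path = out / f"{kind}.json"
        configs[kind].to_json(path)
        return path
    raise ValueError(f"unknown fixture {kind!r}; available: "
                     f"{sorted(networks) + sorted(configs)}")
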