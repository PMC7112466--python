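"""Reproducible experiment orchestration.

An :class:`ExperimentConfig` is a flat, YAML-serializable description of one
threshold-identification run: the network (generated or loaded from an edge
list), the epidemic model and its lambda grid, and the realization counts
with a master seed.  ``run_experiment`` executes it end to end — generate or
load the network, scan the grid, locate the variability and susceptibility
peaks, evaluate every closed-form prediction — and writes a scan TSV, a peak
JSON and a per-network report row whose columns mirror the standard
real-network comparison table (N, k_max, r, HMF and QMF predictions, and the
numerical thresholds).

A config plus the package version determines every output bit-for-bit:
realization substreams are keyed by grid position, not execution order.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .epidemic import DEFAULT_T_MAX, DEFAULT_T_WINDOW, run_ensemble
from .estimators import (
    PeakEstimate,
    ThresholdScan,
    anchored_lambda_grid,
    build_scan,
    find_peak,
)
from .exceptions import EpithreshError, InvalidParameterError
from .netgen import (
    Network,
    SFNConfig,
    degree_stats,
    generate_rrn,
    generate_sfn,
    read_edge_list,
)
from .theory import TheoreticalThresholds, compute_thresholds

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "NetworkReport",
    "validate_config",
    "run_experiment",
    "report_row",
    "REPORT_COLUMNS",
]

REPORT_COLUMNS = ["name", "N", "k_max", "r", "lambda_hmf", "lambda_qmf",
                  "lambda_pDelta", "lambda_pchi", "model", "mu"]


@dataclass
class ExperimentConfig:
    """Flat key-value description of one experiment (YAML round-trippable)."""

    # network: either a generator model or an edge-list path
    network_model: str = "rrn"          # rrn | sfn | edgelist
    n_nodes: int = 1000
    degree: int = 10                    # rrn only
    gamma: float = 2.5                  # sfn only
    k_min: int = 3                      # sfn only
    cutoff_mode: str = "structural"     # sfn only
    edge_list_path: str | None = None   # edgelist only
    # epidemic
    model: str = "SIR"                  # SIR | SIS
    mu: float = 1.0
    lambda_min: float | None = None     # None -> anchored grid
    lambda_max: float | None = None
    lambda_steps: int = 31
    t_max: int = DEFAULT_T_MAX
    t_window: int = DEFAULT_T_WINDOW
    # ensemble
    n_networks: int = 1
    n_runs: int = 1000
    master_seed: int = 1
    # outputs
    out_dir: str = "."
    name: str = "experiment"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class NetworkReport:
    """One comparison-table row for a single network."""

    name: str
    n_nodes: int
    k_max: int
    assortativity_r: float
    lambda_hmf: float
    lambda_qmf: float
    lambda_p_delta: float
    lambda_p_chi: float
    model: str
    mu: float

    def as_row(self) -> dict:
        return {
            "name": self.name, "N": self.n_nodes, "k_max": self.k_max,
            "r": self.assortativity_r, "lambda_hmf": self.lambda_hmf,
            "lambda_qmf": self.lambda_qmf, "lambda_pDelta": self.lambda_p_delta,
            "lambda_pchi": self.lambda_p_chi, "model": self.model, "mu": self.mu,
        }


@dataclass
class ExperimentResult:
    scan: ThresholdScan
    peak_delta: PeakEstimate
    peak_chi: PeakEstimate
    thresholds: TheoreticalThresholds
    report: NetworkReport
    paths: dict = field(default_factory=dict)


def validate_config(config: ExperimentConfig) -> list[str]:
    """Return a list of problems; empty iff the config is runnable."""
    problems: list[str] = []
    if config.network_model not in ("rrn", "sfn", "edgelist"):
        problems.append(f"unknown network model {config.network_model!r}")
    if config.model not in ("SIR", "SIS"):
        problems.append(f"unknown epidemic model {config.model!r}")
    if not 0.0 < config.mu <= 1.0:
        problems.append(f"mu = {config.mu} outside (0, 1]")
    if config.network_model == "rrn":
        if (config.n_nodes * config.degree) % 2:
            problems.append("n_nodes * degree is odd: no regular graph exists")
        if config.degree >= config.n_nodes:
            problems.append("degree must be below n_nodes")
    if config.network_model == "sfn":
        try:
            SFNConfig(n_nodes=config.n_nodes, gamma=config.gamma,
                      k_min=config.k_min, cutoff_mode=config.cutoff_mode)
        except EpithreshError as exc:
            problems.append(str(exc))
    if config.network_model == "edgelist":
        if not config.edge_list_path:
            problems.append("edge_list_path is required for network_model=edgelist")
        elif not Path(config.edge_list_path).is_file():
            problems.append(f"edge list not found: {config.edge_list_path}")
    if config.lambda_max is not None and config.lambda_max * config.mu > 1.0:
        problems.append(
            f"beta = lambda_max * mu = {config.lambda_max * config.mu:.4g} exceeds 1")
    if (config.lambda_min is None) != (config.lambda_max is None):
        problems.append("lambda_min and lambda_max must be given together")
    if config.lambda_min is not None and config.lambda_max is not None \
            and not 0 <= config.lambda_min < config.lambda_max:
        problems.append("need 0 <= lambda_min < lambda_max")
    if config.lambda_steps < 3:
        problems.append("lambda_steps must be at least 3")
    for count_name in ("n_networks", "n_runs"):
        if getattr(config, count_name) < 1:
            problems.append(f"{count_name} must be positive")
    if config.model == "SIS" and not config.t_window < config.t_max:
        problems.append("t_window must be smaller than t_max")
    return problems


def _network_source(config: ExperimentConfig):
    """Return (fixed Network or seed->Network callable, effective n_networks)."""
    if config.network_model == "edgelist":
        net = read_edge_list(config.edge_list_path)
        frac = _giant_fraction(net)
        if frac < 1.0:
            logger.warning("edge list %s: giant component holds %.1f%% of nodes "
                           "(used as-is, no extraction)",
                           config.edge_list_path, 100 * frac)
        return net, 1
    if config.network_model == "rrn":
        return (lambda seed: generate_rrn(config.n_nodes, config.degree, seed),
                config.n_networks)
    sfn = SFNConfig(n_nodes=config.n_nodes, gamma=config.gamma,
                    k_min=config.k_min, cutoff_mode=config.cutoff_mode)
    return (lambda seed: generate_sfn(sfn, seed)), config.n_networks


def _giant_fraction(network: Network) -> float:
    import networkx as nx
    g = network.to_networkx()
    return max(len(c) for c in nx.connected_components(g)) / network.n_nodes


def _lambda_grid(config: ExperimentConfig, anchor_net: Network) -> np.ndarray:
    if config.lambda_min is not None and config.lambda_max is not None:
        return np.linspace(config.lambda_min, config.lambda_max, config.lambda_steps)
    thr = compute_thresholds(anchor_net, mu=config.mu)
    anchor = thr.hmf_sir if config.model == "SIR" else thr.hmf_sis
    if not np.isfinite(anchor):
        raise InvalidParameterError(
            "no finite mean-field anchor for this network; "
            "set lambda_min/lambda_max explicitly")
    grid = anchored_lambda_grid(anchor, config.lambda_steps)
    return np.clip(grid, 0.0, 1.0 / config.mu)


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Execute a full threshold-identification experiment and write outputs.

    Writes ``<name>.scan.tsv``, ``<name>.peaks.json``, ``<name>.report.tsv``
    and ``<name>.log.json`` under ``config.out_dir``.
    """
    problems = validate_config(config)
    if problems:
        raise InvalidParameterError("invalid config: " + "; ".join(problems))
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    source, n_networks = _network_source(config)
    # representative instance for theory and the anchored grid
    if isinstance(source, Network):
        anchor_net = source
    else:
        anchor_seed = int(np.random.SeedSequence(
            entropy=config.master_seed, spawn_key=(0, 0)).generate_state(1)[0] % 2 ** 31)
        anchor_net = source(anchor_seed)
    grid = _lambda_grid(config, anchor_net)
    logger.info("experiment %s: model=%s mu=%g N=%d grid=[%.4g, %.4g] x %d, "
                "%d networks x %d runs, master_seed=%d",
                config.name, config.model, config.mu, anchor_net.n_nodes,
                grid[0], grid[-1], grid.size, n_networks, config.n_runs,
                config.master_seed)

    ensembles = run_ensemble(
        source if isinstance(source, Network) else source,
        grid, config.mu, model=config.model, n_networks=n_networks,
        n_runs=config.n_runs, master_seed=config.master_seed,
        t_max=config.t_max, t_window=config.t_window)
    scan = build_scan(ensembles)
    peak_delta = find_peak(scan, "variability")
    peak_chi = find_peak(scan, "susceptibility")

    stats = degree_stats(anchor_net)
    thr = compute_thresholds(anchor_net, mu=config.mu, stats=stats)
    lam_hmf = thr.hmf_sir if config.model == "SIR" else thr.hmf_sis
    report = NetworkReport(
        name=config.name, n_nodes=stats.n_nodes, k_max=stats.k_max,
        assortativity_r=stats.assortativity_r, lambda_hmf=lam_hmf,
        lambda_qmf=thr.qmf, lambda_p_delta=peak_delta.lambda_peak,
        lambda_p_chi=peak_chi.lambda_peak, model=config.model, mu=config.mu)

    paths = {
        "scan": out_dir / f"{config.name}.scan.tsv",
        "peaks": out_dir / f"{config.name}.peaks.json",
        "report": out_dir / f"{config.name}.report.tsv",
        "log": out_dir / f"{config.name}.log.json",
    }
    scan.to_tsv(paths["scan"])
    with open(paths["peaks"], "w") as fh:
        json.dump({
            "variability": dataclasses.asdict(peak_delta),
            "susceptibility": dataclasses.asdict(peak_chi),
            "theory": dataclasses.asdict(thr),
        }, fh, indent=2)
    _write_report_rows([report], paths["report"])
    with open(paths["log"], "w") as fh:
        json.dump({
            "config": dataclasses.asdict(config),
            "epithresh_version": __version__,
            "elapsed_seconds": round(time.time() - t0, 3),
            "n_realizations_per_lambda": n_networks * config.n_runs,
        }, fh, indent=2)
    logger.info("experiment %s finished in %.1f s: lambda_pDelta=%.4g "
                "lambda_pchi=%.4g", config.name, time.time() - t0,
                peak_delta.lambda_peak, peak_chi.lambda_peak)
    return ExperimentResult(scan=scan, peak_delta=peak_delta, peak_chi=peak_chi,
                            thresholds=thr, report=report,
                            paths={k: str(v) for k, v in paths.items()})


def _write_report_rows(reports: list[NetworkReport], path) -> None:
    import pandas as pd
    pd.DataFrame([r.as_row() for r in reports], columns=REPORT_COLUMNS) \
        .to_csv(path, sep="\t", index=False)


def report_row(reports: list[NetworkReport], path) -> None:
    """Aggregate report rows from several experiments into one table."""
    _write_report_rows(reports, path)
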