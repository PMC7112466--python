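"""Fluctuation-based numerical threshold estimators.

The estimators operate on the ensemble of final outbreak fractions
``{rho_i}`` collected at one transmission rate lambda:

* variability  Delta = sqrt(<rho^2> - <rho>^2) / <rho>   — the relative
  standard deviation of the outbreak size; its peak over lambda locates the
  epidemic threshold for both SIR and SIS;
* susceptibility  chi = N (<rho^2> - <rho>^2) / <rho>    — the classical
  finite-size fluctuation measure; reliable for SIS but biased upward for
  SIR, where the supercritical large-outbreak "lump" inflates the variance
  well above threshold.

The two satisfy chi = N * Delta^2 * <rho> identically.  Moments are plug-in
(population, 1/n) moments: Delta and chi are defined through ensemble
moments, and at the realization counts used here the n vs n-1 distinction is
negligible while the identity above then holds to machine precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .epidemic import OutbreakEnsemble
from .exceptions import InvalidParameterError

__all__ = [
    "ThresholdScan",
    "PeakEstimate",
    "variability",
    "susceptibility",
    "build_scan",
    "find_peak",
    "normalize_variability",
    "anchored_lambda_grid",
    "ensemble_moments",
]

SCAN_COLUMNS = ["lambda", "mean_rho", "mean_rho2", "Delta", "chi", "n_samples"]


def ensemble_moments(values: np.ndarray) -> tuple[float, float]:
    """Plug-in first and second moments <rho>, <rho^2>."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise InvalidParameterError("empty ensemble")
    return float(values.mean()), float((values ** 2).mean())


def _delta_chi(values: np.ndarray, n_nodes: int) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        warnings.warn("empty ensemble (all realizations absorbed?); "
                      "variability and susceptibility are undefined",
                      RuntimeWarning, stacklevel=3)
        return float("nan"), float("nan")
    m1, m2 = ensemble_moments(values)
    if m1 == 0.0:
        warnings.warn("ensemble mean is zero (all realizations absorbed?); "
                      "variability and susceptibility are undefined",
                      RuntimeWarning, stacklevel=3)
        return float("nan"), float("nan")
    var = max(m2 - m1 * m1, 0.0)
    return float(np.sqrt(var) / m1), float(n_nodes * var / m1)


def variability(ensemble: OutbreakEnsemble) -> float:
    """Delta = sqrt(<rho^2> - <rho>^2) / <rho> for one ensemble."""
    return _delta_chi(ensemble.values, ensemble.n_nodes)[0]


def susceptibility(ensemble: OutbreakEnsemble) -> float:
    """chi = N (<rho^2> - <rho>^2) / <rho> for one ensemble."""
    return _delta_chi(ensemble.values, ensemble.n_nodes)[1]


@dataclass
class ThresholdScan:
    """Per-lambda moments and fluctuation measures over an ascending grid."""

    lambdas: np.ndarray
    mean_rho: np.ndarray
    mean_rho2: np.ndarray
    delta: np.ndarray
    chi: np.ndarray
    n_samples: np.ndarray
    n_nodes: int

    def __len__(self) -> int:
        return self.lambdas.size

    def measure(self, name: str) -> np.ndarray:
        if name in ("variability", "delta"):
            return self.delta
        if name in ("susceptibility", "chi"):
            return self.chi
        raise InvalidParameterError(
            f"measure must be 'variability' or 'susceptibility', got {name!r}")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "lambda": self.lambdas,
            "mean_rho": self.mean_rho,
            "mean_rho2": self.mean_rho2,
            "Delta": self.delta,
            "chi": self.chi,
            "n_samples": self.n_samples,
        })

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, n_nodes: int | None = None) -> "ThresholdScan":
        df = pd.read_csv(Path(path), sep="\t")
        missing = set(SCAN_COLUMNS) - set(df.columns)
        if missing:
            raise InvalidParameterError(f"scan file missing columns {sorted(missing)}")
        if n_nodes is None:
            # recover N from the identity chi = N Delta^2 <rho> at the most
            # fluctuation-rich grid point
            with np.errstate(invalid="ignore", divide="ignore"):
                ratio = df["chi"] / (df["Delta"] ** 2 * df["mean_rho"])
            finite = ratio[np.isfinite(ratio)]
            n_nodes = int(round(float(finite.iloc[0]))) if len(finite) else 0
        return cls(
            lambdas=df["lambda"].to_numpy(float),
            mean_rho=df["mean_rho"].to_numpy(float),
            mean_rho2=df["mean_rho2"].to_numpy(float),
            delta=df["Delta"].to_numpy(float),
            chi=df["chi"].to_numpy(float),
            n_samples=df["n_samples"].to_numpy(int),
            n_nodes=n_nodes,
        )


@dataclass(frozen=True)
class PeakEstimate:
    """Grid-point location and height of a fluctuation measure's maximum."""

    lambda_peak: float
    peak_value: float
    measure: str
    index: int


def build_scan(ensembles: list[OutbreakEnsemble]) -> ThresholdScan:
    """Assemble per-lambda moments, Delta and chi into a sorted scan."""
    if not ensembles:
        raise InvalidParameterError("no ensembles given")
    n_nodes = ensembles[0].n_nodes
    if any(e.n_nodes != n_nodes for e in ensembles):
        raise InvalidParameterError("ensembles mix different network sizes N")
    lams = np.array([e.lambda_ for e in ensembles], dtype=float)
    if np.unique(lams).size != lams.size:
        raise InvalidParameterError("duplicate lambda values in scan")
    order = np.argsort(lams)
    rows = []
    for idx in order:
        e = ensembles[idx]
        if e.values.size:
            m1, m2 = ensemble_moments(e.values)
        else:  # e.g. an all-absorbed SIS grid point
            m1 = m2 = float("nan")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            d, c = _delta_chi(e.values, n_nodes)
        rows.append((e.lambda_, m1, m2, d, c, e.n_samples))
    arr = np.array(rows, dtype=float)
    return ThresholdScan(
        lambdas=arr[:, 0], mean_rho=arr[:, 1], mean_rho2=arr[:, 2],
        delta=arr[:, 3], chi=arr[:, 4], n_samples=arr[:, 5].astype(int),
        n_nodes=n_nodes)


def find_peak(scan: ThresholdScan, measure: str = "variability",
              quadratic_refine: bool = False) -> PeakEstimate:
    """Locate the grid argmax of a fluctuation measure.

    Ties are broken toward the smallest lambda; an argmax at either grid
    endpoint triggers a warning (the scan range is probably too narrow).
    With ``quadratic_refine`` a 3-point parabola through the peak and its
    neighbors refines the location off-grid (off by default: the discrete
    argmax carries no smoothing bias).
    """
    if len(scan) < 3:
        raise InvalidParameterError("scan needs at least 3 grid points")
    y = scan.measure(measure)
    if np.all(np.isnan(y)):
        raise InvalidParameterError(f"all-{measure} values are NaN")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        idx = int(np.nanargmax(y))  # np.nanargmax returns the FIRST maximum
    if idx in (0, len(scan) - 1):
        warnings.warn(
            f"{measure} argmax at grid endpoint lambda={scan.lambdas[idx]:.4g}; "
            "the scan range may be too narrow", RuntimeWarning, stacklevel=2)
    lam_peak = float(scan.lambdas[idx])
    if quadratic_refine and 0 < idx < len(scan) - 1:
        x0, x1, x2 = scan.lambdas[idx - 1:idx + 2]
        y0, y1, y2 = y[idx - 1:idx + 2]
        denom = (y0 - 2 * y1 + y2)
        if np.isfinite(denom) and denom < 0:
            lam_peak = float(x1 - 0.5 * (x2 - x0) / 2 * (y2 - y0) / denom)
    return PeakEstimate(lambda_peak=lam_peak, peak_value=float(y[idx]),
                        measure=measure, index=idx)


def normalize_variability(scan: ThresholdScan) -> np.ndarray:
    """Delta / Delta_max per grid point; the maximum is exactly 1."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        dmax = np.nanmax(scan.delta)
    if not np.isfinite(dmax) or dmax <= 0:
        raise InvalidParameterError("Delta_max is zero or undefined; cannot normalize")
    return scan.delta / dmax


def anchored_lambda_grid(anchor: float, n_points: int = 31,
                         lo: float = 0.5, hi: float = 2.0) -> np.ndarray:
    """Uniform lambda grid spanning [lo, hi] x a theoretical anchor value
    (typically the degree-based mean-field prediction)."""
    if anchor <= 0:
        raise InvalidParameterError("anchor threshold must be positive")
    return np.linspace(lo * anchor, hi * anchor, n_points)
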