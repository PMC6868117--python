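"""Batch-fermentation accounting for aerobic acetaldehyde production.

Covers the quantities derived from a batch culture time course:

* molar product yields, as the ordinary-least-squares slope of product
  concentration against consumed glucose (both in mM, so the slope is
  mol/mol),
* OD600 to dry-cell-weight conversion (default 0.24 g cdw/l per OD unit),
* off-gas accounting for a volatile product: back-calculation of the
  gas-phase concentration from a derivatization trap, and reconstruction
  of the total (liquid + stripped) acetaldehyde referred to culture volume,
* carbon-atom distribution of consumed glucose over products and biomass,
* exponential growth rate and specific glucose uptake,
* adenylate energy charge EC = (ATP + ADP/2) / (ATP + ADP + AMP).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .fba import FluxDistribution
from .model import MetabolicModel

__all__ = [
    "BatchTimeSeries",
    "OffgasSample",
    "YieldEstimate",
    "CarbonDistribution",
    "AdenylatePools",
    "fit_yield",
    "od_to_cdw",
    "offgas_concentration",
    "total_acetaldehyde",
    "carbon_distribution",
    "carbon_distribution_from_fluxes",
    "growth_rate",
    "specific_glucose_uptake",
    "energy_charge",
    "read_batch_series",
    "write_batch_series",
]

#: g dry cell weight per liter per OD600 unit
OD_TO_CDW = 0.24
#: g carbon per g dry cell weight (generic bacterial composition)
BIOMASS_CARBON_CONTENT = 0.48
#: g/mol of carbon
CARBON_MOLAR_MASS = 12.011
#: carbon atoms per product molecule
PRODUCT_CARBONS = {
    "ethanol": 2,
    "acetaldehyde": 2,
    "acetaldehyde_liquid": 2,
    "acetate": 2,
    "acetoin": 4,
    "co2": 1,
    "e4p": 4,
}
#: regression window: points with glucose above this fraction of the start
GLUCOSE_FLOOR_FRACTION = 0.05

SPECIES = ("glucose", "ethanol", "acetaldehyde_liquid", "acetate", "acetoin")


@dataclass(frozen=True)
class OffgasSample:
    """One derivatization-trap measurement of the bioreactor off-gas."""

    time_h: float
    trapped_umol: float
    gas_flow_l_h: float
    duration_s: float


@dataclass
class BatchTimeSeries:
    """Timed OD600, glucose and product concentrations plus off-gas records.

    Concentrations are mM; times are hours and must be strictly increasing.
    """

    times: np.ndarray
    od600: np.ndarray
    concentrations: dict[str, np.ndarray]
    offgas: list[OffgasSample] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.od600.shape != self.times.shape:
            raise ValueError("od600 and times must have equal length")
        self.concentrations = {
            k: np.asarray(v, dtype=float) for k, v in self.concentrations.items()
        }
        for name, values in self.concentrations.items():
            if values.shape != self.times.shape:
                raise ValueError(f"{name}: length mismatch with times")
            if np.any(values < 0):
                raise ValueError(f"{name}: concentrations must be >= 0")


@dataclass
class YieldEstimate:
    """Molar yield from the product-vs-consumed-glucose regression."""

    yield_mol_mol: float
    intercept_mm: float
    r_squared: float
    std_error: float
    n_points: int


@dataclass
class CarbonDistribution:
    """Fractions of consumed glucose carbon in each product and in biomass.

    ``closure`` is the plain sum of fractions — reported, never forced to 1.
    """

    fractions: dict[str, float]
    closure: float


@dataclass
class AdenylatePools:
    """ATP/ADP/AMP concentrations (any common unit)."""

    atp: float
    adp: float
    amp: float

    def __post_init__(self) -> None:
        if min(self.atp, self.adp, self.amp) < 0:
            raise ValueError("adenylate pools must be >= 0")


# ---------------------------------------------------------------------------
# Yields
# ---------------------------------------------------------------------------


def fit_yield(
    series: BatchTimeSeries,
    product: str,
    glucose_floor_fraction: float = GLUCOSE_FLOOR_FRACTION,
) -> YieldEstimate:
    """Molar yield of a product: OLS slope of product (mM) vs consumed
    glucose S0 - S(t) (mM) over the glucose-consumption phase.

    Points after glucose falls below ``glucose_floor_fraction`` of its
    initial value are excluded: the late phase (ethanol re-uptake, delayed
    acetate formation) violates the constant-yield assumption the
    regression relies on.
    """
    if product not in series.concentrations:
        raise KeyError(f"product {product!r} not measured in this series")
    glucose = series.concentrations["glucose"]
    s0 = glucose[0]
    mask = glucose > glucose_floor_fraction * s0
    consumed = s0 - glucose[mask]
    prod = series.concentrations[product][mask]
    if consumed.size < 3:
        raise ValueError(
            f"need >= 3 points in the consumption phase, have {consumed.size}"
        )
    if np.ptp(consumed) == 0:
        raise ValueError("no variance in consumed glucose; cannot regress")
    if np.ptp(prod) == 0:
        # flat product (e.g. identically zero): slope 0, perfect fit
        return YieldEstimate(0.0, float(prod[0]), 1.0, 0.0, int(consumed.size))
    fit = stats.linregress(consumed, prod)
    return YieldEstimate(
        yield_mol_mol=float(fit.slope),
        intercept_mm=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        std_error=float(fit.stderr),
        n_points=int(consumed.size),
    )


def od_to_cdw(od600: float | np.ndarray, factor: float = OD_TO_CDW):
    """Dry cell weight (g/l) from OD600 via a linear calibration factor."""
    od600 = np.asarray(od600, dtype=float)
    if np.any(od600 < 0):
        raise ValueError("od600 must be >= 0")
    out = od600 * factor
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Off-gas accounting
# ---------------------------------------------------------------------------


def offgas_concentration(
    trapped_umol: float, gas_flow_l_h: float, duration_s: float
) -> float:
    """Gas-phase concentration (µmol/l) from a trap sample, assuming the
    derivatization mix captures the volatile product completely."""
    if gas_flow_l_h <= 0 or duration_s <= 0:
        raise ValueError("gas flow and sampling duration must be > 0")
    sampled_volume_l = gas_flow_l_h * duration_s / 3600.0
    return trapped_umol / sampled_volume_l


def total_acetaldehyde(
    series: BatchTimeSeries, liquid_volume_l: float
) -> np.ndarray:
    """Total acetaldehyde (mM, referred to culture volume) at each series
    time point: liquid concentration plus the cumulative amount stripped
    to the off-gas.

    The stripped term is the trapezoidal integral of gas_flow x gas-phase
    concentration over the off-gas samples, divided by the liquid volume.
    The stripping rate is extrapolated as constant before the first sample
    and the cumulative amount is held constant after the last one.
    """
    if liquid_volume_l is None or liquid_volume_l <= 0:
        raise ValueError("liquid_volume_l must be > 0")
    liquid = series.concentrations["acetaldehyde_liquid"]
    if not series.offgas:
        return liquid.copy()
    samples = sorted(series.offgas, key=lambda s: s.time_h)
    t_gas = np.array([s.time_h for s in samples])
    # µmol/h leaving the culture at each sample time
    rate = np.array(
        [
            s.gas_flow_l_h
            * offgas_concentration(s.trapped_umol, s.gas_flow_l_h, s.duration_s)
            for s in samples
        ]
    )
    if t_gas[0] > 0:
        t_gas = np.insert(t_gas, 0, 0.0)
        rate = np.insert(rate, 0, rate[0])
    cumulative_umol = np.concatenate(
        [[0.0], np.cumsum(np.diff(t_gas) * (rate[:-1] + rate[1:]) / 2.0)]
    )
    stripped_umol_at_t = np.interp(series.times, t_gas, cumulative_umol)
    stripped_mm = stripped_umol_at_t / 1000.0 / liquid_volume_l
    return liquid + stripped_mm


def with_total_acetaldehyde(
    series: BatchTimeSeries, liquid_volume_l: float
) -> BatchTimeSeries:
    """A copy of the series with a derived ``acetaldehyde_total`` column
    (liquid + stripped), the quantity whose regression against consumed
    glucose gives the true molar acetaldehyde yield when part of the
    product leaves with the off-gas."""
    total = total_acetaldehyde(series, liquid_volume_l)
    concentrations = {k: v.copy() for k, v in series.concentrations.items()}
    concentrations["acetaldehyde_total"] = total
    return BatchTimeSeries(
        times=series.times.copy(),
        od600=series.od600.copy(),
        concentrations=concentrations,
        offgas=list(series.offgas),
    )


# ---------------------------------------------------------------------------
# Carbon distribution
# ---------------------------------------------------------------------------


def carbon_distribution(
    yields: dict[str, float],
    biomass_yield_g_per_mol: float = 0.0,
    carbon_content: float = BIOMASS_CARBON_CONTENT,
) -> CarbonDistribution:
    """Distribute consumed glucose carbon (6 atoms) over products and biomass.

    Product fractions are yield x carbon atoms / 6; the biomass fraction
    converts a gravimetric yield (g cdw per mol glucose) through the
    biomass carbon content (default 0.48 g C per g cdw).
    """
    fractions: dict[str, float] = {}
    for product, y in yields.items():
        if y < 0:
            raise ValueError(f"yield for {product!r} must be >= 0")
        key = product.removesuffix("_liquid").removesuffix("_total")
        fractions[key] = y * PRODUCT_CARBONS[key] / 6.0
    if biomass_yield_g_per_mol:
        fractions["biomass"] = (
            biomass_yield_g_per_mol * carbon_content / (6.0 * CARBON_MOLAR_MASS)
        )
    return CarbonDistribution(fractions=fractions, closure=sum(fractions.values()))


_EXCHANGE_PRODUCT_NAMES = {
    "EX_ethanol": "ethanol",
    "EX_acetaldehyde": "acetaldehyde",
    "EX_acetate": "acetate",
    "EX_acetoin": "acetoin",
    "EX_co2": "co2",
    "EX_e4p": "e4p",
    "EX_biomass": "biomass",
}


def carbon_distribution_from_fluxes(
    model: MetabolicModel, solution: FluxDistribution
) -> CarbonDistribution:
    """Carbon distribution implied by a model flux distribution.

    Fractions are export flux x metabolite carbon count / (6 x glucose
    uptake); the biomass pseudo-metabolite contributes its full 35 carbons.
    Closure is exactly 1 for any steady-state solution (carbon conservation).
    """
    glc_uptake = -solution["EX_glc"]
    if glc_uptake <= 0:
        raise ValueError("solution has no glucose uptake")
    fractions: dict[str, float] = {}
    for rid, name in _EXCHANGE_PRODUCT_NAMES.items():
        rxn = model.reaction(rid)
        (mid,) = rxn.stoichiometry
        carbons = model.metabolite(mid).carbon_count
        fractions[name] = solution[rid] * carbons / (6.0 * glc_uptake)
    return CarbonDistribution(fractions=fractions, closure=sum(fractions.values()))


# ---------------------------------------------------------------------------
# Growth kinetics
# ---------------------------------------------------------------------------


def _ln_od_slope(times: np.ndarray, od: np.ndarray) -> tuple[float, float]:
    """(slope, r^2) of ln(OD) vs time; zero-variance OD gives (0, 1)."""
    y = np.log(od)
    if np.ptp(y) == 0:
        return 0.0, 1.0
    fit = stats.linregress(times, y)
    return float(fit.slope), float(fit.rvalue**2)


def _exponential_window(
    series: BatchTimeSeries, min_points: int = 3, r2_threshold: float = 0.99
) -> np.ndarray:
    """Indices of the auto-selected exponential window: the longest
    contiguous run of points whose ln(OD)-vs-time fit has r^2 above the
    threshold (ties broken toward the earliest run); falls back to the
    best-r^2 run of minimal length if none qualifies."""
    n = series.times.size
    if n < min_points:
        raise ValueError(f"need >= {min_points} points, have {n}")
    best: tuple[int, float, int, int] | None = None  # (length, r2, start, stop)
    for start in range(n - min_points + 1):
        for stop in range(start + min_points, n + 1):
            od = series.od600[start:stop]
            if np.any(od <= 0):
                continue
            _, r2 = _ln_od_slope(series.times[start:stop], od)
            if r2 < r2_threshold:
                continue
            key = (stop - start, r2, -start, -stop)
            if best is None or key > (best[0], best[1], -best[2], -best[3]):
                best = (stop - start, r2, start, stop)
    if best is None:
        raise ValueError(
            "no exponential window found (ln OD never linear at r^2 >= "
            f"{r2_threshold} over >= {min_points} points)"
        )
    return np.arange(best[2], best[3])


def growth_rate(
    series: BatchTimeSeries, window: tuple[float, float] | None = None
) -> float:
    """Specific growth rate µ (1/h): slope of ln(OD600) vs time over the
    exponential window (auto-selected unless a (t_start, t_end) window in
    hours is given)."""
    if window is not None:
        idx = np.where(
            (series.times >= window[0]) & (series.times <= window[1])
        )[0]
        if idx.size < 3:
            raise ValueError("window contains fewer than 3 points")
        if np.any(series.od600[idx] <= 0):
            raise ValueError("window contains non-positive OD600")
    else:
        idx = _exponential_window(series)
    slope, _ = _ln_od_slope(series.times[idx], series.od600[idx])
    return slope


def specific_glucose_uptake(
    series: BatchTimeSeries,
    window: tuple[float, float] | None = None,
    od_factor: float = OD_TO_CDW,
) -> float:
    """Specific glucose uptake rate q (mmol per g cdw per h) over the
    exponential window: q = µ x ΔS / ΔX, the balanced-growth solution of
    dS/dt = -qX with X growing exponentially at µ."""
    if window is not None:
        idx = np.where(
            (series.times >= window[0]) & (series.times <= window[1])
        )[0]
        if idx.size < 3:
            raise ValueError("window contains fewer than 3 points")
    else:
        idx = _exponential_window(series)
    mu = growth_rate(series, window)
    glucose = series.concentrations["glucose"][idx]
    biomass = od_to_cdw(series.od600[idx], factor=od_factor)
    delta_s = glucose[0] - glucose[-1]
    delta_x = biomass[-1] - biomass[0]
    if delta_x <= 0:
        raise ValueError("no biomass increase over the window")
    return mu * delta_s / delta_x


# ---------------------------------------------------------------------------
# Energy charge
# ---------------------------------------------------------------------------


def energy_charge(pools: AdenylatePools) -> float:
    """Adenylate energy charge EC = (ATP + ADP/2) / (ATP + ADP + AMP)."""
    total = pools.atp + pools.adp + pools.amp
    if total <= 0:
        raise ValueError("adenylate pools sum to zero")
    return (pools.atp + 0.5 * pools.adp) / total


# ---------------------------------------------------------------------------
# Long-format series I/O
# ---------------------------------------------------------------------------


def write_batch_series(
    series: BatchTimeSeries, path: str | Path, offgas_path: str | Path | None = None
) -> None:
    """Write a series as long-format TSV (time_h, variable, value); off-gas
    records go to a separate TSV if a path is given."""
    rows = [
        {"time_h": t, "variable": "od600", "value": v}
        for t, v in zip(series.times, series.od600)
    ]
    for name, values in series.concentrations.items():
        rows.extend(
            {"time_h": t, "variable": name, "value": v}
            for t, v in zip(series.times, values)
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    if offgas_path is not None:
        pd.DataFrame(
            [
                {
                    "time_h": s.time_h,
                    "trapped_umol": s.trapped_umol,
                    "gas_flow_l_h": s.gas_flow_l_h,
                    "duration_s": s.duration_s,
                }
                for s in series.offgas
            ]
        ).to_csv(offgas_path, sep="\t", index=False)


def read_batch_series(
    path: str | Path, offgas_path: str | Path | None = None
) -> BatchTimeSeries:
    """Read a long-format series TSV (and optionally an off-gas TSV)."""
    long = pd.read_csv(path, sep="\t")
    wide = long.pivot(index="time_h", columns="variable", values="value").sort_index()
    if "od600" not in wide.columns:
        raise ValueError(f"{path}: no od600 variable found")
    offgas: list[OffgasSample] = []
    if offgas_path is not None:
        og = pd.read_csv(offgas_path, sep="\t")
        offgas = [
            OffgasSample(
                time_h=row["time_h"],
                trapped_umol=row["trapped_umol"],
                gas_flow_l_h=row["gas_flow_l_h"],
                duration_s=row["duration_s"],
            )
            for _, row in og.iterrows()
        ]
    return BatchTimeSeries(
        times=wide.index.to_numpy(),
        od600=wide["od600"].to_numpy(),
        concentrations={
            c: wide[c].to_numpy() for c in wide.columns if c != "od600"
        },
        offgas=offgas,
    )
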