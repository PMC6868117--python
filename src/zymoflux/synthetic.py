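"""Synthetic aerobic batch fermentations with known ground truth.

The generator produces exactly the statistical structure the batch analysis
assumes: exponential growth X(t) = x0 e^(µt) until glucose runs out,
glucose consumption dS/dt = -q X, products coupled to consumed glucose by
constant molar yields, first-order stripping of liquid acetaldehyde into
the off-gas at a rate k (1/h), and additive Gaussian measurement noise
truncated at zero.  All curves have closed forms, so ground truth is exact:

    S(t) = S0 - (q x0/µ)(e^(µt) - 1)                     (floored at 0)
    L(t) = Y_acald q x0 (e^(µt) - e^(-kt)) / (µ + k)     (liquid acetaldehyde)

with growth, consumption and production frozen once glucose is exhausted
and L decaying as e^(-kt) afterwards.  Off-gas trap records are emitted at
every sampling time, consistent with the trap model used by the analysis
(complete capture over a short sampling window at known gas flow).

Defaults emulate the study conditions for the wild type: µ = 0.38 1/h,
q = 40 mmol/(g cdw h), 50 g/l glucose (277.5 mM), 0.4 l culture sparged at
1 vvm (24 l/h), ethanol/acetaldehyde yields 0.77/0.68 mol/mol, noise 1 mM
on glucose, 0.5 mM on products, 2% on OD600.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .batch import AdenylatePools, BatchTimeSeries, OffgasSample, energy_charge

__all__ = [
    "SyntheticBatchConfig",
    "BatchGroundTruth",
    "simulate_batch",
    "simulate_adenylates",
]

DEFAULT_YIELDS = {
    "ethanol": 0.77,
    "acetaldehyde": 0.68,
    "acetate": 0.07,
    "acetoin": 0.06,
}
DEFAULT_NOISE = {
    "glucose": 1.0,        # mM, absolute
    "ethanol": 0.5,        # mM
    "acetaldehyde": 0.5,   # mM (liquid)
    "acetate": 0.5,        # mM
    "acetoin": 0.5,        # mM
    "od600": 0.02,         # relative (fraction of the true value)
}
PRODUCT_CARBONS = {"ethanol": 2, "acetaldehyde": 2, "acetate": 2, "acetoin": 4}


@dataclass
class SyntheticBatchConfig:
    """Parameters of one synthetic batch; the seed is mandatory."""

    seed: int
    mu: float = 0.38                  # 1/h
    x0: float = 0.06                  # g cdw/l (inoculum ~OD 0.25)
    s0: float = 277.5                 # mM glucose (50 g/l)
    q_glc: float = 40.0               # mmol/(g cdw h)
    yields: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_YIELDS))
    strip_rate: float = 0.2           # 1/h, first-order acetaldehyde stripping
    gas_flow: float = 24.0            # l/h (1 vvm on 0.4 l)
    liquid_volume: float = 0.4        # l
    trap_duration_s: float = 6.0      # off-gas sampling window
    noise_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE))
    n_points: int = 12
    t_end: float = 10.0               # h
    od_factor: float = 0.24           # g cdw/l per OD600 unit

    def validate(self) -> None:
        if min(self.mu, self.x0, self.s0, self.q_glc) <= 0:
            raise ValueError("mu, x0, s0 and q_glc must all be > 0")
        if any(y < 0 for y in self.yields.values()):
            raise ValueError("yields must be >= 0")
        carbon = sum(
            y * PRODUCT_CARBONS[p] for p, y in self.yields.items()
        )
        if carbon > 6 + 1e-9:
            raise ValueError(
                f"carbon-infeasible yields: {carbon:.2f} C per glucose (> 6)"
            )
        if self.strip_rate < 0:
            raise ValueError("strip_rate must be >= 0")
        if self.n_points < 2:
            raise ValueError("need at least 2 time points")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class BatchGroundTruth:
    """Noise-free curves and the parameters that generated a series."""

    config: SyntheticBatchConfig
    times: np.ndarray
    biomass: np.ndarray                 # g cdw/l
    od600: np.ndarray
    glucose: np.ndarray                 # mM
    produced: dict[str, np.ndarray]     # mM produced (cumulative), per product
    acetaldehyde_liquid: np.ndarray     # mM in the liquid
    stripped: np.ndarray                # mM equivalents removed to the gas
    t_exhaustion: float                 # h at which glucose hits zero


def _exhaustion_time(cfg: SyntheticBatchConfig) -> float:
    # S0 = (q x0/µ)(e^(µt) - 1)  =>  t* = ln(1 + µ S0/(q x0)) / µ
    return float(np.log1p(cfg.mu * cfg.s0 / (cfg.q_glc * cfg.x0)) / cfg.mu)


def _true_curves(cfg: SyntheticBatchConfig) -> BatchGroundTruth:
    t = np.linspace(0.0, cfg.t_end, cfg.n_points)
    t_star = _exhaustion_time(cfg)
    tg = np.minimum(t, t_star)  # growth clock stops at exhaustion
    biomass = cfg.x0 * np.exp(cfg.mu * tg)
    glucose = cfg.s0 - (cfg.q_glc * cfg.x0 / cfg.mu) * np.expm1(cfg.mu * tg)
    glucose = np.maximum(glucose, 0.0)
    consumed = cfg.s0 - glucose
    produced = {p: y * consumed for p, y in cfg.yields.items()}
    y_ac = cfg.yields.get("acetaldehyde", 0.0)
    k = cfg.strip_rate
    if k == 0:
        liquid = y_ac * consumed
    else:
        a = cfg.q_glc * cfg.x0 * y_ac / (cfg.mu + k)
        liquid = a * (np.exp(cfg.mu * tg) - np.exp(-k * tg))
        late = t > t_star
        if np.any(late):
            l_star = a * (np.exp(cfg.mu * t_star) - np.exp(-k * t_star))
            liquid[late] = l_star * np.exp(-k * (t[late] - t_star))
    stripped = produced.get("acetaldehyde", np.zeros_like(t)) - liquid
    return BatchGroundTruth(
        config=cfg,
        times=t,
        biomass=biomass,
        od600=biomass / cfg.od_factor,
        glucose=glucose,
        produced=produced,
        acetaldehyde_liquid=liquid,
        stripped=stripped,
        t_exhaustion=t_star,
    )


def simulate_batch(
    cfg: SyntheticBatchConfig,
) -> tuple[BatchTimeSeries, BatchGroundTruth]:
    """Generate one noisy batch series plus its exact ground truth.

    The same config (including seed) always returns an identical series.
    Off-gas trap records are noise-free: their gas-phase concentration is
    the instantaneous stripping rate k·L(t)·V divided by the gas flow.
    """
    cfg.validate()
    truth = _true_curves(cfg)
    rng = np.random.default_rng(cfg.seed)
    sd = {**DEFAULT_NOISE, **cfg.noise_sd}

    od_obs = truth.od600 * (1.0 + sd["od600"] * rng.standard_normal(cfg.n_points))
    od_obs = np.maximum(od_obs, 1e-6)
    concentrations: dict[str, np.ndarray] = {}
    glc = truth.glucose + sd["glucose"] * rng.standard_normal(cfg.n_points)
    concentrations["glucose"] = np.maximum(glc, 0.0)
    for product in ("ethanol", "acetate", "acetoin"):
        if product in truth.produced:
            noisy = truth.produced[product] + sd[product] * rng.standard_normal(
                cfg.n_points
            )
            concentrations[product] = np.maximum(noisy, 0.0)
    liq = truth.acetaldehyde_liquid + sd["acetaldehyde"] * rng.standard_normal(
        cfg.n_points
    )
    concentrations["acetaldehyde_liquid"] = np.maximum(liq, 0.0)

    offgas: list[OffgasSample] = []
    if cfg.strip_rate > 0:
        for t, liquid_mm in zip(truth.times, truth.acetaldehyde_liquid):
            rate_mmol_h = cfg.strip_rate * liquid_mm * cfg.liquid_volume
            conc_umol_l = 1000.0 * rate_mmol_h / cfg.gas_flow
            trapped = conc_umol_l * cfg.gas_flow * cfg.trap_duration_s / 3600.0
            offgas.append(
                OffgasSample(
                    time_h=float(t),
                    trapped_umol=float(trapped),
                    gas_flow_l_h=cfg.gas_flow,
                    duration_s=cfg.trap_duration_s,
                )
            )
    series = BatchTimeSeries(
        times=truth.times.copy(),
        od600=od_obs,
        concentrations=concentrations,
        offgas=offgas,
    )
    return series, truth


def simulate_adenylates(
    target_ec: float, total_pool: float = 1.0, seed: int | None = None
) -> AdenylatePools:
    """Adenylate pools with a prescribed energy charge and total.

    EC fixes one degree of freedom; the ADP share is drawn uniformly from
    its admissible interval (both endpoints keep all pools non-negative),
    so different seeds give different pools with identical EC.
    """
    if not 0.0 <= target_ec <= 1.0:
        raise ValueError("target_ec must be in [0, 1]")
    if total_pool <= 0:
        raise ValueError("total_pool must be > 0")
    rng = np.random.default_rng(seed)
    adp_max = 2.0 * total_pool * min(target_ec, 1.0 - target_ec)
    adp = float(rng.uniform(0.0, adp_max)) if adp_max > 0 else 0.0
    atp = target_ec * total_pool - 0.5 * adp
    amp = total_pool - atp - adp
    pools = AdenylatePools(atp=max(atp, 0.0), adp=adp, amp=max(amp, 0.0))
    assert abs(energy_charge(pools) - target_ec) < 1e-9
    return pools
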