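"""Fed-batch penicillin fermentation simulator.

Generates multi-batch process datasets with the 15 measured variables a
plant historian would log (actuator flows, concentrations, pH,
temperature, heat) plus the product concentration target, sampled hourly
by default.  The kinetics are a Monod-type fed-batch model in the
Birol/Pensim family: substrate- and oxygen-limited growth,
non-growth-associated product formation with substrate inhibition,
dilution by feeding, and simple proportional pH/temperature control
loops that generate the acid/base and hot/cooling-water flow columns.

States integrated with a fixed-step classical Runge-Kutta scheme:
biomass, substrate, product, dissolved oxygen, volume, cumulative heat,
pH and temperature.  CO2 off-gas is an algebraic output.
"""

from __future__ import annotations

import argparse
import dataclasses
import json
import logging
import math
import sys
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .dataset import ProcessDataset
from .errors import DataError, SimulationError

__all__ = [
    "KineticParams",
    "BatchSimConfig",
    "VARIABLE_NAMES",
    "simulate_batch",
    "simulate_campaign",
    "add_measurement_noise",
    "make_preset",
    "DATASET_PRESETS",
    "DEFAULT_CAMPAIGN_VARIATION",
]

log = logging.getLogger(__name__)

#: The measured process variables, in column order.
VARIABLE_NAMES = [
    "air_flow",
    "agitator_power",
    "feed_rate",
    "acid_flow",
    "base_flow",
    "cooling_water_flow",
    "hot_water_flow",
    "substrate_conc",
    "dissolved_oxygen",
    "biomass_conc",
    "culture_volume",
    "co2_conc",
    "ph",
    "temperature",
    "heat_generated",
]

_STATE_NAMES = (
    "biomass",
    "substrate",
    "product",
    "dissolved_oxygen",
    "volume",
    "heat",
    "ph",
    "temperature",
)


@dataclass(frozen=True)
class KineticParams:
    """Biological rate constants and yields.

    Units: rates 1/h, saturation constants g/L (dissolved oxygen mg/L),
    yields g/g, heat yields kcal/g.
    """

    mu_max: float = 0.092            # max specific growth rate
    K_s: float = 0.15                # substrate saturation for growth
    K_o: float = 0.05                # oxygen saturation for growth
    k_prod: float = 0.005            # product formation rate constant
    K_p: float = 0.0002              # product-path substrate saturation
    K_inhib: float = 0.10            # product-path substrate inhibition
    K_op: float = 0.05               # product-path oxygen saturation
    yield_xs: float = 0.45           # biomass per substrate
    yield_ps: float = 0.90           # product per substrate
    maintenance: float = 0.014       # substrate maintenance demand
    yield_xo: float = 0.04           # biomass per oxygen
    yield_po: float = 0.20           # product per oxygen
    maintenance_o: float = 0.467     # oxygen maintenance demand
    product_decay: float = 0.02      # product hydrolysis
    co2_per_growth: float = 4.0      # CO2 evolution per unit growth rate
    co2_per_biomass: float = 0.01    # CO2 evolution per unit biomass
    heat_per_growth: float = 0.06    # heat yield of growth (kcal/g)
    heat_per_biomass: float = 2e-3   # maintenance heat (kcal/(g h))
    acid_per_growth: float = 0.2     # pH drop per unit of volumetric growth

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not (v > 0) or not math.isfinite(v):
                raise DataError(f"kinetic parameter {f.name} must be finite and > 0")
        if self.yield_xs > 10 or self.yield_ps > 10:
            raise DataError("yield coefficients above 10 g/g fail the sanity bound")


@dataclass(frozen=True)
class BatchSimConfig:
    """One batch run: initial state, feeding, control loops, sampling."""

    substrate_init: float = 15.0     # g/L
    biomass_init: float = 0.1        # g/L
    product_init: float = 0.0        # g/L
    volume_init: float = 100.0       # L
    ph_init: float = 5.05
    temp_init: float = 298.0         # K
    duration: float = 400.0          # h
    dt: float = 0.05                 # integration step, h
    sample_period: float = 1.0       # h
    # feeding
    feed_rate: float = 0.03          # L/h once the feed is on
    feed_substrate: float = 600.0    # g/L in the feed
    feed_start: Optional[float] = None  # h; None -> substrate-triggered
    substrate_trigger: float = 0.5   # g/L threshold that latches the feed on
    # setpoints / actuators
    air_flow: float = 8.6            # L/h (normalized)
    agitator_power: float = 30.0     # W
    ph_setpoint: float = 5.0
    temp_setpoint: float = 298.0     # K
    ph_control_gain: float = 0.1     # L/h per pH unit of error
    temp_control_gain: float = 1.0   # L/h per K of error
    base_ph_effect: float = 10.0     # pH/h per L/h of base
    acid_ph_effect: float = 10.0
    cool_heat_coeff: float = 10.0    # kcal removed per L of cooling water
    hot_heat_coeff: float = 10.0
    ambient_loss_coeff: float = 0.5  # kcal/(K h)
    ambient_temp: float = 293.0      # K
    heat_capacity: float = 1.0       # kcal/(L K)
    oxygen_sat_conc: float = 1.16    # mg/L
    kla_coeff: float = 8.0           # oxygen transfer scale
    evaporation_rate: float = 2.5e-4  # fraction of volume per h
    seed: int = 0

    def validate(self) -> None:
        if self.duration <= 0:
            raise DataError("duration must be > 0")
        if self.dt <= 0 or self.dt > self.sample_period:
            raise DataError("integration step must satisfy 0 < dt <= sample_period")
        if self.volume_init <= 0:
            raise DataError("initial volume must be > 0")
        if self.feed_rate < 0:
            raise DataError("negative feed rate")
        for name in ("substrate_init", "biomass_init", "product_init"):
            if getattr(self, name) < 0:
                raise DataError(f"{name} must be >= 0")

    @property
    def kla(self) -> float:
        return self.kla_coeff * math.sqrt(self.air_flow) * self.agitator_power ** 0.2

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "BatchSimConfig":
        return cls(**json.loads(text))


def _derivs(state, p: KineticParams, c: BatchSimConfig, feed_on: bool):
    """Time derivatives of the 8 states; returns (derivs, actuator flows)."""
    X, S, P, CL, V, _Q, pH, T = state
    Se = S if S > 0.0 else 0.0
    CLe = CL if CL > 0.0 else 0.0

    mu = p.mu_max * Se / (p.K_s + Se) * CLe / (p.K_o + CLe)
    mu_pp = (
        p.k_prod
        * Se
        / (p.K_p + Se + Se * Se / p.K_inhib)
        * CLe
        / (p.K_op + CLe)
    )
    growth = mu * X

    feed = c.feed_rate if feed_on else 0.0
    f_base = c.ph_control_gain * max(c.ph_setpoint - pH, 0.0)
    f_acid = c.ph_control_gain * max(pH - c.ph_setpoint, 0.0)
    f_hot = c.temp_control_gain * max(c.temp_setpoint - T, 0.0)
    f_cool = c.temp_control_gain * max(T - c.temp_setpoint, 0.0)
    evap = c.evaporation_rate * V

    dV = feed + f_acid + f_base - evap
    dil = dV / V
    maint_s = p.maintenance * X * Se / (Se + 0.01)
    dX = growth - X * dil
    dS = (
        -growth / p.yield_xs
        - mu_pp * X / p.yield_ps
        - maint_s
        + feed * c.feed_substrate / V
        - S * dil
    )
    dP = mu_pp * X - p.product_decay * P - P * dil
    o2_uptake = (
        growth / p.yield_xo
        + mu_pp * X / p.yield_po
        + p.maintenance_o * X * CLe / (CLe + 0.01)
    )
    dCL = c.kla * (c.oxygen_sat_conc - CL) - o2_uptake - CL * dil
    dQ = (p.heat_per_growth * growth + p.heat_per_biomass * X) * V
    dpH = (
        -p.acid_per_growth * growth
        + c.base_ph_effect * f_base
        - c.acid_ph_effect * f_acid
    )
    dT = (
        dQ
        - c.cool_heat_coeff * f_cool
        + c.hot_heat_coeff * f_hot
        - c.ambient_loss_coeff * (T - c.ambient_temp)
    ) / (V * c.heat_capacity)

    return (
        (dX, dS, dP, dCL, dV, dQ, dpH, dT),
        (feed, f_acid, f_base, f_cool, f_hot),
    )


def _co2(state, p: KineticParams, c: BatchSimConfig) -> float:
    X, S, _P, CL, *_ = state
    Se = max(S, 0.0)
    CLe = max(CL, 0.0)
    mu = p.mu_max * Se / (p.K_s + Se) * CLe / (p.K_o + CLe)
    return 0.03 + p.co2_per_growth * mu * X + p.co2_per_biomass * X


def _rk4_step(state, dt, p, c, feed_on):
    k1, _ = _derivs(state, p, c, feed_on)
    s2 = tuple(s + 0.5 * dt * d for s, d in zip(state, k1))
    k2, _ = _derivs(s2, p, c, feed_on)
    s3 = tuple(s + 0.5 * dt * d for s, d in zip(state, k2))
    k3, _ = _derivs(s3, p, c, feed_on)
    s4 = tuple(s + dt * d for s, d in zip(state, k3))
    k4, _ = _derivs(s4, p, c, feed_on)
    return tuple(
        s + dt / 6.0 * (a + 2 * b + 2 * cc + d)
        for s, a, b, cc, d in zip(state, k1, k2, k3, k4)
    )


def simulate_batch(
    config: BatchSimConfig, params: Optional[KineticParams] = None, batch_id: int = 0
) -> ProcessDataset:
    """Simulate one fed-batch run and sample it at ``config.sample_period``.

    The trajectory is integrated at ``config.dt`` with a classical
    fixed-step RK4 scheme and sub-sampled to the (hourly by default)
    sampling grid.  Deterministic: noise is added separately by
    :func:`add_measurement_noise`.
    """
    params = params or KineticParams()
    config.validate()
    params.validate()

    n_sub = max(1, round(config.sample_period / config.dt))
    dt = config.sample_period / n_sub
    n_samples = round(config.duration / config.sample_period)
    if n_samples < 1:
        raise DataError("duration shorter than one sampling period")

    state = (
        config.biomass_init,
        config.substrate_init,
        config.product_init,
        config.oxygen_sat_conc,
        config.volume_init,
        0.0,
        config.ph_init,
        config.temp_init,
    )
    feed_on = config.feed_start is not None and config.feed_start <= 0.0

    rows = np.empty((n_samples, len(VARIABLE_NAMES)))
    target = np.empty(n_samples)
    t = 0.0
    for k in range(n_samples):
        for _ in range(n_sub):
            if config.feed_start is None:
                feed_on = feed_on or state[1] < config.substrate_trigger
            else:
                feed_on = t >= config.feed_start
            state = _rk4_step(state, dt, params, config, feed_on)
            t += dt
            cleaned = []
            for name, value in zip(_STATE_NAMES, state):
                if not math.isfinite(value):
                    raise SimulationError(
                        f"state {name!r} became non-finite at t={t:.3f} h"
                    )
                if name in ("biomass", "substrate", "product", "dissolved_oxygen") and value < 0:
                    if value < -1e-4:
                        raise SimulationError(
                            f"state {name!r} went negative ({value:.3e}) at t={t:.3f} h"
                        )
                    value = 0.0
                cleaned.append(value)
            state = tuple(cleaned)

        _, flows = _derivs(state, params, config, feed_on)
        feed, f_acid, f_base, f_cool, f_hot = flows
        X, S, P, CL, V, Q, pH, T = state
        rows[k] = (
            config.air_flow,
            config.agitator_power,
            feed,
            f_acid,
            f_base,
            f_cool,
            f_hot,
            S,
            CL,
            X,
            V,
            _co2(state, params, config),
            pH,
            T,
            Q,
        )
        target[k] = P

    return ProcessDataset(
        X=rows,
        y=target,
        variable_names=list(VARIABLE_NAMES),
        batch_ids=np.full(n_samples, batch_id, dtype=int),
        sample_period=config.sample_period,
    )


#: Relative ranges applied batch-to-batch by :func:`simulate_campaign`.
DEFAULT_CAMPAIGN_VARIATION: Mapping[str, float] = {
    "substrate_init": 0.10,
    "biomass_init": 0.10,
    "volume_init": 0.05,
}


def simulate_campaign(
    n_batches: int,
    base: Optional[BatchSimConfig] = None,
    variation: Optional[Mapping[str, float]] = None,
    seed: int = 0,
    params: Optional[KineticParams] = None,
    first_batch_id: int = 0,
) -> ProcessDataset:
    """Concatenate ``n_batches`` runs with initial conditions drawn
    uniformly within +/- the given relative range of the base config."""
    if n_batches < 1:
        raise DataError("n_batches must be >= 1")
    base = base or BatchSimConfig()
    if variation is None:
        variation = DEFAULT_CAMPAIGN_VARIATION
    for name, r in variation.items():
        if not hasattr(base, name):
            raise DataError(f"unknown config field in variation spec: {name!r}")
        if not 0 <= r < 1:
            raise DataError(f"variation range for {name!r} must lie in [0, 1)")
    if not variation and n_batches > 1:
        warnings.warn(
            "empty variation spec: all batches share identical initial conditions",
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    parts = []
    for b in range(n_batches):
        overrides = {
            name: getattr(base, name) * (1.0 + r * rng.uniform(-1.0, 1.0))
            for name, r in variation.items()
        }
        cfg = replace(base, **overrides)
        parts.append(simulate_batch(cfg, params, batch_id=first_batch_id + b))
    return ProcessDataset.concat(parts)


def add_measurement_noise(
    data: ProcessDataset,
    noise: Union[Mapping[str, float], float, None],
    seed: int = 0,
    include_target: bool = False,
    target_sd: float = 0.0,
) -> ProcessDataset:
    """Return a copy of ``data`` with Gaussian measurement noise on the
    input columns.

    ``noise`` is either a per-variable-SD mapping or a single number
    interpreted as a signal-to-noise ratio in dB applied to every input
    column (SD = RMS(column) / 10^(SNR/20)).  Values are clipped at zero
    (all process variables are non-negative); the target stays clean
    unless ``include_target``.
    """
    out = data.copy()
    if noise is None:
        return out
    if isinstance(noise, Mapping):
        sds = np.zeros(data.n_variables)
        for name, sd in noise.items():
            if name not in data.variable_names:
                raise DataError(f"unknown variable name in noise spec: {name!r}")
            if sd < 0:
                raise DataError(f"noise SD for {name!r} must be >= 0")
            sds[data.variable_names.index(name)] = sd
    else:
        snr_db = float(noise)
        rms = np.sqrt(np.mean(data.X**2, axis=0))
        sds = rms / 10.0 ** (snr_db / 20.0)

    rng = np.random.default_rng(seed)
    out.X = data.X + rng.standard_normal(data.X.shape) * sds
    np.clip(out.X, 0.0, None, out=out.X)
    if include_target:
        if target_sd < 0:
            raise DataError("target_sd must be >= 0")
        out.y = np.clip(data.y + rng.standard_normal(len(data)) * target_sd, 0.0, None)
    return out


# --------------------------------------------------------------------------
# Experiment presets: (n_batches, hours per batch, train SNR dB or None)
DATASET_PRESETS = {
    "table3_1": (2, 400, None),      # 800 samples
    "table3_2": (4, 400, None),      # 1600 samples
    "table3_3": (13, 400, None),     # 5200 samples
    "table3_4": (25, 400, None),     # 10000 samples
    "campaign20": (20, 400, 40.0),   # 20-batch training campaign, 40 dB noise
}


def make_preset(
    name: str,
    seed: int = 0,
    noise_snr: Optional[float] = "default",  # type: ignore[assignment]
    batch_hours: Optional[int] = None,
) -> ProcessDataset:
    """Build one of the named multi-batch datasets.

    ``noise_snr`` defaults to the preset's own noise treatment; pass
    ``None`` to force clean data or a number to override the SNR in dB.
    """
    if name not in DATASET_PRESETS:
        raise DataError(
            f"unknown preset {name!r}; choose from {sorted(DATASET_PRESETS)}"
        )
    n_batches, hours, preset_snr = DATASET_PRESETS[name]
    if noise_snr == "default":
        noise_snr = preset_snr
    base = BatchSimConfig(duration=float(batch_hours or hours), seed=seed)
    data = simulate_campaign(n_batches, base, seed=seed)
    if noise_snr is not None:
        data = add_measurement_noise(data, float(noise_snr), seed=seed + 1)
    return data


# --------------------------------------------------------------------------
def main(argv: Optional[Sequence[str]] = None) -> int:
    parser = argparse.ArgumentParser(
        prog="fermsim",
        description="Simulate fed-batch penicillin fermentation datasets.",
    )
    sub = parser.add_subparsers(dest="command", required=True)
    sim = sub.add_parser("simulate", help="generate a multi-batch CSV dataset")
    sim.add_argument("--batches", type=int, default=1)
    sim.add_argument("--hours", type=float, default=400.0)
    sim.add_argument("--seed", type=int, default=0)
    sim.add_argument("--noise-snr", type=float, default=None, metavar="DB")
    sim.add_argument("--preset", choices=sorted(DATASET_PRESETS), default=None)
    sim.add_argument("--config", default=None, help="JSON file of config overrides")
    sim.add_argument("--out", required=True)
    args = parser.parse_args(argv)

    logging.basicConfig(level=logging.INFO, stream=sys.stderr)
    try:
        if args.preset:
            snr = args.noise_snr if args.noise_snr is not None else "default"
            data = make_preset(args.preset, seed=args.seed, noise_snr=snr)
        else:
            base = BatchSimConfig(duration=args.hours, seed=args.seed)
            if args.config:
                with open(args.config) as fh:
                    base = replace(base, **json.load(fh))
            data = simulate_campaign(args.batches, base, seed=args.seed)
            if args.noise_snr is not None:
                data = add_measurement_noise(data, args.noise_snr, seed=args.seed + 1)
        data.to_csv(args.out)
    except DataError as exc:
        log.error("%s", exc)
        return 3
    except SimulationError as exc:
        log.error("%s", exc)
        return 4
    log.info("wrote %d rows to %s", len(data), args.out)
    return 0


if __name__ == "__main__":  # pragma: no cover
    raise SystemExit(main())
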