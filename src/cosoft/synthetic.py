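"""Synthetic fed-batch fermentation campaigns with 2D (batch x time) dynamics.

Real quality-prediction studies in batch bioprocessing draw on campaigns of
repeated fed-batch runs whose operating setpoints drift slowly from batch to
batch (aging seed cultures, recalibrated probes, seasonal utilities).  This
module generates such campaigns from a minimal three-state kinetic core --
substrate-limited biomass growth, substrate depletion with a feed that
switches on partway through the run, and Luedeking-Piret product formation
-- so the whole pipeline is testable end to end without any proprietary data
or an external simulator.

The defaults emulate a classic campaign design: pH drifting 4.95 -> 5.2 and
temperature 297.5 -> 298.5 K across the campaign, per-batch setpoint
fluctuation of about 1%, and additive Gaussian measurement noise on the
process variables.  The quality variable (product concentration) is a
deterministic, nonlinear function of the latent kinetic states; setpoint
drift feeds into the growth kinetics, so quality trajectories are correlated
along both the time and the batch direction by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .batch_data import BatchTensor

__all__ = [
    "KineticParams",
    "CampaignConfig",
    "SimulationError",
    "simulate_batch",
    "simulate_campaign",
    "train_test_split",
]


class SimulationError(RuntimeError):
    """Raised when the kinetic integration produces non-finite state."""


@dataclass
class KineticParams:
    """Parameters of the three-state (biomass, substrate, product) core.

    Units: concentrations g/L, volume L, time h.  ``alpha`` is the
    growth-associated and ``beta`` the non-growth-associated product yield
    (Luedeking-Piret); ``yxs`` the biomass-per-substrate yield.
    """

    mu_max: float = 0.11       # 1/h, maximum specific growth rate
    ks: float = 0.5            # g/L, Monod half-saturation
    yxs: float = 0.45          # g biomass / g substrate
    alpha: float = 0.6         # g product / g biomass formed
    beta: float = 0.002        # g product / (g biomass * h)
    biomass_init: float = 0.1  # g/L inoculum
    biomass_max: float = 15.0  # g/L logistic carrying capacity
    feed_rate: float = 0.04    # L/h, substrate feed after the switch
    feed_substrate: float = 400.0  # g/L substrate in the feed
    ph_optimum: float = 5.0
    ph_width: float = 0.35
    temp_optimum: float = 298.0
    temp_width: float = 1.2

    def __post_init__(self) -> None:
        for name in ("mu_max", "ks", "yxs", "alpha", "beta", "biomass_init",
                     "biomass_max", "feed_rate", "feed_substrate",
                     "ph_width", "temp_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"kinetic parameter {name} must be positive")


#: constant setpoints of the campaign design (variable name -> value)
_BASE_SETPOINTS = {
    "temperature": 298.0,        # K (overridden by drift by default)
    "ph": 5.0,                   # -  (overridden by drift by default)
    "aeration_rate": 8.6,        # L/h
    "agitator_power": 30.0,      # W
    "substrate_conc": 15.0,      # g/L initial substrate
    "culture_volume": 100.0,     # L initial volume
    "substrate_feed_temp": 296.0,  # K (11-variable layout only)
    "co2_conc": 0.5,             # g/L baseline (11-variable layout only)
}

#: per-variable measurement-noise sd at noise_sd=1 (instrument precision;
#: temperature/pH anchored to typical probe margins ~0.2 K / ~0.02 pH)
_NOISE_SCALES = {
    "temperature": 0.1,
    "ph": 0.02,
    "aeration_rate": 0.09,
    "agitator_power": 0.3,
    "substrate_feed_rate": 0.001,
    "substrate_feed_temp": 0.1,
    "substrate_conc": 0.15,
    "culture_volume": 0.5,
    "co2_conc": 0.01,
    "generated_heat": 20.0,
    "cold_water_flow": 0.5,
}

#: batch-to-batch setpoint jitter is multiplicative (+-fraction of setpoint)
#: except temperature, where a fraction of the absolute Kelvin value would be
#: physically absurd (1% of 298 K = 3 K against a controller holding ~0.2 K);
#: its jitter scale is 20 K, i.e. +-0.2 K at the default 1% fluctuation.
_TEMP_FLUCT_SCALE = 20.0

#: observed-variable layouts; order fixes the J axis
_VARIABLES_7 = [
    "temperature", "ph", "aeration_rate", "agitator_power",
    "substrate_feed_rate", "substrate_conc", "culture_volume",
]
_VARIABLES_11 = [
    "aeration_rate", "agitator_power", "substrate_feed_rate",
    "substrate_feed_temp", "substrate_conc", "culture_volume",
    "co2_conc", "ph", "temperature", "generated_heat", "cold_water_flow",
]


@dataclass
class CampaignConfig:
    """Design of a simulated campaign.

    ``drift_specs`` maps variable names to (start, end) setpoints reached at
    the first and last batch of the campaign (linear interpolation between).
    ``fluctuation_fraction`` perturbs each batch's setpoints (uniform in
    +-fraction of the setpoint, once per batch; temperature uses a 20 K
    reference scale so 1% means +-0.2 K).  ``noise_sd`` multiplies the
    per-variable instrument-noise scales (additive Gaussian per time point);
    1.0 is typical probe precision, 0 disables measurement noise.
    """

    n_batches: int = 20
    n_timepoints: int = 100
    n_variables: int = 7
    duration: float = 400.0  # h, total fermentation time
    drift_specs: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"ph": (4.95, 5.2), "temperature": (297.5, 298.5)}
    )
    fluctuation_fraction: float = 0.01
    noise_sd: float = 1.0
    feed_switch_fraction: float = 0.25
    kinetic_params: KineticParams = field(default_factory=KineticParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_batches < 1 or self.n_timepoints < 1:
            raise ValueError("n_batches and n_timepoints must be >= 1")
        if self.n_variables not in (7, 11):
            raise ValueError("n_variables must be 7 or 11")
        if self.fluctuation_fraction < 0:
            raise ValueError("fluctuation_fraction must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name, (a, b) in self.drift_specs.items():
            if not (np.isfinite(a) and np.isfinite(b)):
                raise ValueError(f"drift setpoints for {name} must be finite")
            if name not in _BASE_SETPOINTS:
                raise ValueError(f"unknown drifting variable {name!r}")

    @property
    def variable_names(self) -> list[str]:
        return list(_VARIABLES_7 if self.n_variables == 7 else _VARIABLES_11)

    @property
    def time_step(self) -> float:
        return self.duration / self.n_timepoints


def _batch_setpoints(config: CampaignConfig, batch_index: int,
                     rng: np.random.Generator) -> dict[str, float]:
    """Setpoints for one batch: drift interpolation then +-fluctuation."""
    sp = dict(_BASE_SETPOINTS)
    frac = batch_index / (config.n_batches - 1) if config.n_batches > 1 else 0.0
    for name, (start, end) in config.drift_specs.items():
        sp[name] = start + frac * (end - start)
    if config.fluctuation_fraction > 0:
        for name in sp:
            u = rng.uniform(-config.fluctuation_fraction,
                            config.fluctuation_fraction)
            scale = _TEMP_FLUCT_SCALE if name == "temperature" else sp[name]
            sp[name] += u * scale
    return sp


def simulate_batch(
    config: CampaignConfig, batch_index: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one batch; returns (J x K process matrix, length-K quality).

    Forward-Euler integration of the kinetic core at the configured time
    step.  The growth rate is modulated by Gaussian response curves in the
    batch's pH and temperature setpoints, which is how batch-direction drift
    reaches the quality trajectory.
    """
    if not 0 <= batch_index < config.n_batches:
        raise ValueError("batch_index out of range")
    kp = config.kinetic_params
    sp = _batch_setpoints(config, batch_index, rng)
    n_k = config.n_timepoints
    dt = config.time_step
    t_switch = config.feed_switch_fraction * config.duration

    env = np.exp(-((sp["ph"] - kp.ph_optimum) / kp.ph_width) ** 2) * np.exp(
        -((sp["temperature"] - kp.temp_optimum) / kp.temp_width) ** 2
    )

    biomass = kp.biomass_init
    substrate = sp["substrate_conc"]
    product = 0.0
    volume = sp["culture_volume"]

    b_traj = np.empty(n_k)
    s_traj = np.empty(n_k)
    p_traj = np.empty(n_k)
    v_traj = np.empty(n_k)
    f_traj = np.empty(n_k)
    mu_traj = np.empty(n_k)
    for k in range(n_k):
        t = k * dt
        feeding = t >= t_switch
        feed = kp.feed_rate if feeding else 0.0
        mu = kp.mu_max * env * substrate / (kp.ks + substrate)
        growth = mu * biomass * (1.0 - biomass / kp.biomass_max)
        b_traj[k], s_traj[k], p_traj[k] = biomass, substrate, product
        v_traj[k], f_traj[k], mu_traj[k] = volume, feed, mu
        biomass += growth * dt
        substrate += (-growth / kp.yxs + feed * kp.feed_substrate / volume) * dt
        substrate = max(substrate, 0.0)
        product += (kp.alpha * growth + kp.beta * biomass) * dt
        volume += feed * dt
        if not (np.isfinite(biomass) and np.isfinite(substrate)
                and np.isfinite(product) and np.isfinite(volume)):
            raise SimulationError(
                f"non-finite kinetic state at step {k}; check mu_max/feed_rate"
            )

    traj = {
        "temperature": np.full(n_k, sp["temperature"]),
        "ph": np.full(n_k, sp["ph"]),
        "aeration_rate": np.full(n_k, sp["aeration_rate"]),
        "agitator_power": np.full(n_k, sp["agitator_power"]),
        "substrate_feed_rate": f_traj,
        "substrate_feed_temp": np.full(n_k, sp["substrate_feed_temp"]),
        "substrate_conc": s_traj,
        "culture_volume": v_traj,
        "co2_conc": sp["co2_conc"] * (1.0 + 0.08 * b_traj),
        "generated_heat": 500.0 * np.cumsum(mu_traj * b_traj) * dt,
        "cold_water_flow": 60.0 * mu_traj * b_traj,
    }
    names = config.variable_names
    x = np.stack([traj[name] for name in names])
    if config.noise_sd > 0:
        scale = np.array([_NOISE_SCALES[name] for name in names])
        x = x + rng.normal(0.0, config.noise_sd, size=x.shape) * scale[:, None]
    return x, p_traj


def simulate_campaign(config: CampaignConfig) -> BatchTensor:
    """Simulate the full campaign; the returned mask is all-true."""
    rng = np.random.default_rng(config.seed)
    xs, ys = [], []
    for b in range(config.n_batches):
        x, y = simulate_batch(config, b, rng)
        xs.append(x)
        ys.append(y)
    x = np.stack(xs)
    y = np.stack(ys)
    mask = np.ones_like(y, dtype=bool)
    return BatchTensor(
        x=x, y=y, mask=mask,
        variable_names=config.variable_names,
        time_step=config.time_step,
    )


def train_test_split(data: BatchTensor, n_train: int) -> tuple[BatchTensor, BatchTensor]:
    """First ``n_train`` batches for training, the rest for testing.

    No shuffling: the batch-direction drift is preserved so test batches
    genuinely extrapolate the campaign, as they would online.
    """
    if not 0 < n_train < data.n_batches:
        raise ValueError("n_train must satisfy 0 < n_train < I")
    def slice_tensor(sl: slice) -> BatchTensor:
        return BatchTensor(
            x=data.x[sl].copy(),
            y=data.y[sl].copy(),
            mask=data.mask[sl].copy(),
            variable_names=list(data.variable_names),
            time_step=data.time_step,
        )
    return slice_tensor(slice(0, n_train)), slice_tensor(slice(n_train, None))
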