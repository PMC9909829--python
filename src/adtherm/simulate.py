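"""Synthetic cohorts of active-dynamic-thermography recordings.

The scanner protocol emulated here heats a clipped skin region for 10 s
(calibrated to a 7 °C surface rise), then records free thermal relaxation,
for a total of 60 s, over a 5x5 pixel grid covering 1.5x1.5 mm^2.  Two such
grids exist per mass: "site" (over the mass) and "control" (adjacent normal
tissue).

Tissue heat transport is the Pennes bioheat balance: conduction, blood
perfusion exchanging heat with arterial blood, and metabolic generation.
At the scale of one pixel's surface-temperature curve, the model is reduced
to a single-compartment linear ODE

    dT/dt = -lambda_p * (T - T_eq) + g * u(t)

with u(t) = 1 during the heating window and 0 afterwards.  The effective
relaxation rate is

    lambda_p = (omega_b * rho_b * c_b) / (rho * c) + kappa_geom

i.e. the perfusion time constant of the Pennes equation plus a lumped
conduction-loss term, and g is calibrated so the noiseless heating rise
hits the protocol target exactly.  Malignant tissue is modelled with an
elevated resting baseline (~+1 °C) and an altered relaxation rate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TissueParams",
    "LumpedModel",
    "Protocol",
    "ThermalSignal",
    "MassRecord",
    "CohortConfig",
    "reduce_to_lumped",
    "simulate_signal",
    "simulate_signal_ode",
    "simulate_mass",
    "simulate_cohort",
    "reference_cohort_config",
    "benign_tissue_template",
    "malignant_tissue_template",
]

# substream tags for counter-based RNG splitting (see CohortConfig.rng_seed)
_STREAM_COHORT = 11
_STREAM_DOG = 13
_STREAM_MASS = 17
_STREAM_PIXEL_SITE = 19
_STREAM_PIXEL_CONTROL = 23


@dataclass(frozen=True)
class TissueParams:
    """Physical and physiological parameters of a simulated tissue region.

    Units follow the bioheat literature: SI throughout, temperatures in
    degrees Celsius.  ``delta_base`` is the elevation of the resting surface
    temperature over adjacent control tissue (malignant masses run warm).
    """

    conductivity: float = 0.5           # k, W m^-1 K^-1
    density: float = 1050.0             # rho, kg m^-3
    heat_capacity: float = 3600.0       # c, J kg^-1 K^-1
    perfusion_rate: float = 5.0e-4      # omega_b, s^-1 (volumetric blood flow per tissue volume)
    blood_density: float = 1060.0       # rho_b, kg m^-3
    blood_heat_capacity: float = 3800.0  # c_b, J kg^-1 K^-1
    arterial_temp: float = 38.5         # T_a, °C (canine core)
    metabolic_heat: float = 700.0       # Q_m, W m^-3
    delta_base: float = 0.0             # °C above control baseline

    def __post_init__(self) -> None:
        positive = {
            "conductivity": self.conductivity,
            "density": self.density,
            "heat_capacity": self.heat_capacity,
            "blood_density": self.blood_density,
            "blood_heat_capacity": self.blood_heat_capacity,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if self.perfusion_rate < 0:
            raise ValueError(f"perfusion_rate must be >= 0, got {self.perfusion_rate}")
        if self.metabolic_heat < 0:
            raise ValueError(f"metabolic_heat must be >= 0, got {self.metabolic_heat}")
        if self.delta_base < 0:
            raise ValueError(f"delta_base must be >= 0, got {self.delta_base}")
        if not 30.0 <= self.arterial_temp <= 45.0:
            raise ValueError(
                f"arterial_temp must lie in [30, 45] °C, got {self.arterial_temp}"
            )


@dataclass(frozen=True)
class LumpedModel:
    """Single-compartment reduction of the bioheat model for one pixel."""

    equilibrium_temp: float  # T_eq, °C
    decay_rate: float        # lambda_p, s^-1
    forcing_gain: float      # g, °C s^-1 while the heater is on

    def __post_init__(self) -> None:
        if not self.decay_rate > 0:
            raise ValueError(
                f"decay_rate must be strictly positive, got {self.decay_rate}"
            )


@dataclass(frozen=True)
class Protocol:
    """Scan protocol: heating window, recording length, grid geometry."""

    total_duration: float = 60.0   # s
    heat_duration: float = 10.0    # s
    target_heat_rise: float = 7.0  # °C
    sampling_rate: float = 10.0    # Hz (camera frame rate; configurable)
    grid_side: int = 5             # pixels per region edge
    region_size: float = 1.5       # mm

    def __post_init__(self) -> None:
        if not self.heat_duration < self.total_duration:
            raise ValueError("heat_duration must be shorter than total_duration")
        if not self.target_heat_rise > 0:
            raise ValueError("target_heat_rise must be positive")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if self.grid_side < 1:
            raise ValueError("grid_side must be >= 1")

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration * self.sampling_rate))

    @property
    def n_pixels(self) -> int:
        return self.grid_side**2

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    @property
    def heat_end_index(self) -> int:
        """Index of the first sample at or after the end of heating."""
        return int(np.ceil(self.heat_duration * self.sampling_rate - 1e-12))


@dataclass(frozen=True)
class ThermalSignal:
    """One pixel's temperature time series with protocol annotations."""

    times: np.ndarray         # s, uniform, starting at 0
    temperatures: np.ndarray  # °C
    heat_end_index: int       # first post-heating sample

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        temps = np.asarray(self.temperatures, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "temperatures", temps)
        if times.shape != temps.shape or times.ndim != 1:
            raise ValueError("times and temperatures must be 1-D and equal length")
        if len(times) >= 2 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if not 0 <= self.heat_end_index <= len(times):
            raise ValueError("heat_end_index out of range")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def sampling_interval(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class MassRecord:
    """One mass: site and control pixel grids plus identity and pathology."""

    dog_id: str
    mass_id: str
    site_grid: tuple          # row-major tuple of ThermalSignal, grid_side^2 long
    control_grid: tuple
    label: str                # "benign" | "malignant"
    tumor_type_name: str = ""

    def __post_init__(self) -> None:
        if len(self.site_grid) != len(self.control_grid):
            raise ValueError("site and control grids must have identical shape")
        if self.label not in ("benign", "malignant"):
            raise ValueError(f"label must be 'benign' or 'malignant', got {self.label!r}")

    @property
    def grid_side(self) -> int:
        return int(round(len(self.site_grid) ** 0.5))


@dataclass(frozen=True)
class CohortConfig:
    """Statistical design of a synthetic cohort.

    Defaults mirror the study cohort: 45 dogs with a 24/18/3 split of
    one/two/three masses (69 total) and 27/69 malignant.  Effect sizes:
    malignant baseline elevation ~N(1.0, 0.3) °C and decay-rate ratio 1.3
    (log-sd 0.1).  Noise: 0.05 °C per-pixel measurement noise, dog-level
    random effects on decay rate (log-sd 0.10) and baseline (sd 0.3 °C),
    and mass-level effects (log-sd 0.05 on decay rate, 0.05 °C baseline)
    shared by all pixels of the site grid.
    """

    n_dogs: int = 45
    masses_per_dog_probs: tuple = (24 / 45, 18 / 45, 3 / 45)  # P(1), P(2), P(3)
    malignancy_prevalence: float = 27 / 69
    delta_base_mean: float = 1.0       # °C, malignant resting elevation
    delta_base_sd: float = 0.3
    lambda_ratio: float = 1.3          # malignant:benign decay-rate ratio
    lambda_ratio_log_sd: float = 0.1
    pixel_noise_sd: float = 0.05       # °C, i.i.d. per sample
    dog_lambda_log_sd: float = 0.10
    dog_baseline_sd: float = 0.3       # °C
    mass_lambda_log_sd: float = 0.05
    mass_baseline_sd: float = 0.05     # °C
    control_baseline_c: float = 34.0   # °C, clipped-skin surface temperature
    kappa_geom: float = 0.02           # s^-1, conduction loss into lambda_p
    exact_counts: bool = False         # quota-assign masses-per-dog instead of sampling
    exact_prevalence: bool = False     # quota-assign labels instead of Bernoulli
    protocol: Protocol = field(default_factory=Protocol)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.masses_per_dog_probs) - 1.0) > 1e-9:
            raise ValueError("masses_per_dog_probs must sum to 1")
        if any(p < 0 for p in self.masses_per_dog_probs):
            raise ValueError("masses_per_dog_probs must be non-negative")
        if not 0.0 <= self.malignancy_prevalence <= 1.0:
            raise ValueError("malignancy_prevalence must lie in [0, 1]")
        for name in (
            "delta_base_sd", "lambda_ratio_log_sd", "pixel_noise_sd",
            "dog_lambda_log_sd", "dog_baseline_sd", "mass_lambda_log_sd",
            "mass_baseline_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_dogs < 1:
            raise ValueError("n_dogs must be >= 1")


def benign_tissue_template() -> TissueParams:
    """Default parameters for normal subcutaneous tissue."""
    return TissueParams()


def malignant_tissue_template(config: CohortConfig) -> TissueParams:
    """Mean malignant tissue: elevated baseline; rate shifts are drawn per mass."""
    return dataclasses.replace(
        benign_tissue_template(), delta_base=config.delta_base_mean
    )


def reduce_to_lumped(
    params: TissueParams,
    protocol: Protocol,
    control_baseline_c: float = 34.0,
    kappa_geom: float = 0.02,
) -> LumpedModel:
    """Collapse full tissue parameters to the one-compartment relaxation model.

    ``lambda_p`` is the Pennes perfusion rate constant
    (omega_b*rho_b*c_b)/(rho*c) plus ``kappa_geom``, a lumped conduction loss
    to surrounding tissue that keeps relaxation finite at low perfusion.
    ``T_eq`` is the control surface baseline plus the region's resting
    elevation.  The forcing gain is solved so that the noiseless heating
    rise at t = heat_duration equals the protocol target exactly.
    """
    if kappa_geom < 0:
        raise ValueError("kappa_geom must be >= 0")
    lambda_p = (
        params.perfusion_rate * params.blood_density * params.blood_heat_capacity
    ) / (params.density * params.heat_capacity) + kappa_geom
    if not lambda_p > 0:
        raise ValueError(
            "decay_rate must be > 0; zero perfusion with zero conduction loss "
            "gives a non-relaxing model"
        )
    t_eq = control_baseline_c + params.delta_base
    g = _calibrate_gain(lambda_p, protocol)
    return LumpedModel(equilibrium_temp=t_eq, decay_rate=lambda_p, forcing_gain=g)


def _calibrate_gain(lambda_p: float, protocol: Protocol) -> float:
    """Forcing gain giving exactly target_heat_rise at t = heat_duration."""
    rise_factor = -np.expm1(-lambda_p * protocol.heat_duration)  # 1 - e^{-l*hd}
    return protocol.target_heat_rise * lambda_p / rise_factor


def _lumped_trajectory(model: LumpedModel, times: np.ndarray, heat_duration: float) -> np.ndarray:
    """Closed-form piecewise-exponential solution with T(0) = T_eq."""
    lam, g, teq = model.decay_rate, model.forcing_gain, model.equilibrium_temp
    t = np.asarray(times, dtype=float)
    temps = np.empty_like(t)
    heating = t < heat_duration
    # heating: T = T_eq + (g/lam) (1 - e^{-lam t})
    temps[heating] = teq + (g / lam) * -np.expm1(-lam * t[heating])
    # relaxation: exponential return from the heat-end excursion
    rise_end = (g / lam) * -np.expm1(-lam * heat_duration)
    temps[~heating] = teq + rise_end * np.exp(-lam * (t[~heating] - heat_duration))
    return temps


def simulate_signal(
    model: LumpedModel,
    protocol: Protocol,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> ThermalSignal:
    """Simulate one pixel's temperature curve under the scan protocol.

    The noiseless trajectory is the closed-form solution of
    dT/dt = -lambda_p (T - T_eq) + g u(t) with T(0) = T_eq; Gaussian
    measurement noise of standard deviation ``noise_sd`` is added per
    sample.  Deterministic given ``rng``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    times = protocol.times()
    temps = _lumped_trajectory(model, times, protocol.heat_duration)
    if noise_sd > 0:
        if rng is None:
            raise ValueError("rng is required when noise_sd > 0")
        temps = temps + rng.normal(0.0, noise_sd, size=temps.shape)
    return ThermalSignal(
        times=times, temperatures=temps, heat_end_index=protocol.heat_end_index
    )


def simulate_signal_ode(
    model: LumpedModel, protocol: Protocol, substeps: int = 200
) -> ThermalSignal:
    """Fixed-step RK4 integration of the same ODE; numerical cross-check only.

    Provided as an independent route to the closed-form trajectory; not a
    pipeline stage.  ``substeps`` RK4 steps are taken per sampling interval;
    any sub-step straddling the heating switch-off is split there, so the
    discontinuous drive never degrades the integration order.
    """
    times = protocol.times()
    lam, g, teq = model.decay_rate, model.forcing_gain, model.equilibrium_temp
    hd = protocol.heat_duration

    def rk4(temp: float, h: float, drive: float) -> float:
        # drive is constant within a (sub-)step, so the RHS is autonomous
        def f(x: float) -> float:
            return -lam * (x - teq) + drive

        k1 = f(temp)
        k2 = f(temp + h * k1 / 2)
        k3 = f(temp + h * k2 / 2)
        k4 = f(temp + h * k3)
        return temp + (h / 6) * (k1 + 2 * k2 + 2 * k3 + k4)

    temps = np.empty_like(times)
    temps[0] = teq
    temp = teq
    for i in range(1, len(times)):
        t0, t1 = times[i - 1], times[i]
        h = (t1 - t0) / substeps
        t = t0
        for _ in range(substeps):
            a, b = t, t + h
            if b <= hd:
                temp = rk4(temp, h, g)
            elif a >= hd:
                temp = rk4(temp, h, 0.0)
            else:
                temp = rk4(temp, hd - a, g)
                temp = rk4(temp, b - hd, 0.0)
            t = b
        temps[i] = temp
    return ThermalSignal(
        times=times, temperatures=temps, heat_end_index=protocol.heat_end_index
    )


def _rng_for(config: CohortConfig, *key: int) -> np.random.Generator:
    """Counter-based substream: content independent of generation order."""
    return np.random.default_rng(np.random.SeedSequence((config.rng_seed, *key)))


@dataclass(frozen=True)
class _DogEffects:
    """Dog-level random effects shared by every mass of one dog."""

    baseline_shift: float     # °C added to both grids' equilibria
    lambda_log_shift: float   # multiplicative (log scale) on both grids' decay rates


def _draw_dog_effects(config: CohortConfig, dog_index: int) -> _DogEffects:
    rng = _rng_for(config, _STREAM_DOG, dog_index)
    return _DogEffects(
        baseline_shift=rng.normal(0.0, config.dog_baseline_sd) if config.dog_baseline_sd > 0 else 0.0,
        lambda_log_shift=rng.normal(0.0, config.dog_lambda_log_sd) if config.dog_lambda_log_sd > 0 else 0.0,
    )


def simulate_mass(
    config: CohortConfig,
    label: str,
    dog_effects: _DogEffects,
    dog_index: int,
    mass_index: int,
    tumor_type_name: str = "",
) -> MassRecord:
    """Simulate one mass's site and control grids.

    The control grid follows the benign tissue template plus the dog-level
    effects.  The site grid additionally carries mass-level effects, and for
    malignant masses a baseline elevation drawn around +1 °C and a decay
    rate scaled by the configured malignant:benign ratio.  All pixels of a
    grid share the mass-level draw; only per-pixel measurement noise is
    independent.
    """
    protocol = config.protocol
    base = reduce_to_lumped(
        benign_tissue_template(),
        protocol,
        control_baseline_c=config.control_baseline_c,
        kappa_geom=config.kappa_geom,
    )

    ctrl_lambda = base.decay_rate * np.exp(dog_effects.lambda_log_shift)
    ctrl_teq = base.equilibrium_temp + dog_effects.baseline_shift
    control_model = LumpedModel(
        equilibrium_temp=ctrl_teq,
        decay_rate=ctrl_lambda,
        forcing_gain=_calibrate_gain(ctrl_lambda, protocol),
    )

    mass_rng = _rng_for(config, _STREAM_MASS, dog_index, mass_index)
    mass_lambda_shift = (
        mass_rng.normal(0.0, config.mass_lambda_log_sd)
        if config.mass_lambda_log_sd > 0 else 0.0
    )
    mass_baseline_shift = (
        mass_rng.normal(0.0, config.mass_baseline_sd)
        if config.mass_baseline_sd > 0 else 0.0
    )
    if label == "malignant":
        delta_base = config.delta_base_mean
        if config.delta_base_sd > 0:
            delta_base = max(0.0, mass_rng.normal(config.delta_base_mean, config.delta_base_sd))
        log_ratio = np.log(config.lambda_ratio)
        if config.lambda_ratio_log_sd > 0:
            log_ratio = mass_rng.normal(log_ratio, config.lambda_ratio_log_sd)
    else:
        delta_base = 0.0
        log_ratio = 0.0

    site_lambda = ctrl_lambda * np.exp(log_ratio + mass_lambda_shift)
    site_teq = ctrl_teq + delta_base + mass_baseline_shift
    site_model = LumpedModel(
        equilibrium_temp=site_teq,
        decay_rate=site_lambda,
        forcing_gain=_calibrate_gain(site_lambda, protocol),
    )

    grids = {}
    for region, model, stream in (
        ("site", site_model, _STREAM_PIXEL_SITE),
        ("control", control_model, _STREAM_PIXEL_CONTROL),
    ):
        pixel_rng = _rng_for(config, stream, dog_index, mass_index)
        grids[region] = tuple(
            simulate_signal(model, protocol, config.pixel_noise_sd, pixel_rng)
            for _ in range(protocol.n_pixels)
        )

    return MassRecord(
        dog_id=f"dog{dog_index:03d}",
        mass_id=f"dog{dog_index:03d}_m{mass_index}",
        site_grid=grids["site"],
        control_grid=grids["control"],
        label=label,
        tumor_type_name=tumor_type_name,
    )


def _quota_counts(probs: tuple, n: int) -> list[int]:
    """Largest-remainder apportionment of n items over categories."""
    raw = [p * n for p in probs]
    counts = [int(np.floor(r)) for r in raw]
    short = n - sum(counts)
    remainders = sorted(range(len(probs)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in remainders[:short]:
        counts[i] += 1
    return counts


def simulate_cohort(config: CohortConfig) -> list[MassRecord]:
    """Simulate a full cohort of mass recordings.

    The number of masses per dog follows the configured distribution
    (categorical draw, or a deterministic quota when ``exact_counts``);
    labels are Bernoulli(prevalence) per mass, or quota-assigned and
    shuffled when ``exact_prevalence``.  Fully reproducible from
    ``rng_seed``; dog/mass/pixel substreams are split by counters so the
    content of each mass does not depend on generation order.
    """
    cohort_rng = _rng_for(config, _STREAM_COHORT)
    n_options = np.arange(1, len(config.masses_per_dog_probs) + 1)
    if config.exact_counts:
        quota = _quota_counts(config.masses_per_dog_probs, config.n_dogs)
        per_dog = np.repeat(n_options, quota)
        cohort_rng.shuffle(per_dog)
    else:
        per_dog = cohort_rng.choice(
            n_options, size=config.n_dogs, p=config.masses_per_dog_probs
        )

    n_masses = int(per_dog.sum())
    if config.exact_prevalence:
        n_mal = int(round(config.malignancy_prevalence * n_masses))
        labels = np.array(["malignant"] * n_mal + ["benign"] * (n_masses - n_mal))
        cohort_rng.shuffle(labels)
        label_iter = iter(labels)
    else:
        label_iter = None

    records = []
    for dog_index, count in enumerate(per_dog):
        effects = _draw_dog_effects(config, dog_index)
        for mass_index in range(int(count)):
            if label_iter is not None:
                label = str(next(label_iter))
            else:
                mass_rng = _rng_for(config, _STREAM_MASS, dog_index, mass_index, 0)
                label = (
                    "malignant"
                    if mass_rng.random() < config.malignancy_prevalence
                    else "benign"
                )
            records.append(
                simulate_mass(config, label, effects, dog_index, mass_index)
            )
    return records


def reference_cohort_config(seed: int = 0, **overrides) -> CohortConfig:
    """Study-shaped cohort: 45 dogs, 24/18/3 mass split (69 masses), 27 malignant.

    Uses deterministic quota assignment for both the masses-per-dog counts
    and the malignancy labels so every replicate has exactly the study's
    cohort composition; all other settings are the defaults.
    """
    return CohortConfig(
        exact_counts=True, exact_prevalence=True, rng_seed=seed, **overrides
    )
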