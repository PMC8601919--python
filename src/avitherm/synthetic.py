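"""Synthetic populations, thermal profiles, and raw respirometry traces.

Every downstream stage of the pipeline is exercised on generated data
whose statistical structure mirrors a winter respirometry study of a
Mediterranean Great tit population (~16 g birds, n = 24, balanced
sexes):

* **Population**: sex-specific normal morphometrics with males larger in
  wing length, body mass and bill dimensions but identical tarsi;
  per-individual latent thermal parameters (Tlc, Tuc, BMR, EWL
  inflection) drawn around the population means.
* **Thermal profiles**: the U-shaped VO2(Ta) curve

      VO2 = BMR + cold_slope * min(Ta - Tlc, 0) + hot_slope * (Ta - Tuc)_+

  (cold_slope < 0, hot_slope > 0, flat plateau across the TNZ) and the
  flat-then-rising EWL(Ta) curve with a single inflection, both under
  multiplicative lognormal noise of configurable CV.  For males only,
  EWL at 40 degC is additionally scaled by ``exp(effect * tarsi_index)``,
  creating a positive male-specific dependence of cooling efficiency on
  relative leg area.
* **Raw traces**: a forward model of the analyzer chain — baseline and
  animal segments on the multiplexer schedule, excurrent O2/H2O obtained
  by inverting the reduction module's gas equations, single-compartment
  exponential chamber washout, linear analyzer drift and white noise.

Defaults encode the study conditions (population means, protocol
temperatures, flow rates, chamber geometry); seeds are handled through
one master seed with fixed per-individual substreams so that adding
individuals never perturbs earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .morphometrics import IndividualRecord, add_size_indices, add_surface_areas
from .respirometry import (DEFAULT_RQ, WATER_VAPOR_DENSITY_STP,
                           RespirometryTrace, ThermalProfile)

__all__ = [
    "SexMorphometrics",
    "GeneratorConfig",
    "TraceConfig",
    "DEFAULT_TEST_TEMPS",
    "generate_population",
    "generate_thermal_profile",
    "generate_profiles",
    "generate_trace",
]

#: Stepped protocol temperatures: 10-30 degC at 1000 ml/min for the cold
#: side, 35/37/40 degC at 3000 ml/min for the hot side.
DEFAULT_TEST_TEMPS = (10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 37.0, 40.0)


@dataclass(frozen=True)
class SexMorphometrics:
    """Normal means/SDs for one sex: mass (g), wing and caliper mm."""

    mb_mean: float
    mb_sd: float
    wing_mean: float
    wing_sd: float
    bl_mean: float
    bl_sd: float
    bw_mean: float
    bw_sd: float
    bd_mean: float
    bd_sd: float
    tl_mean: float
    tl_sd: float
    tw_mean: float
    tw_sd: float
    td_mean: float
    td_sd: float

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if name.endswith("_sd") and value < 0:
                raise ValueError(f"{name} must be non-negative")
            if name.endswith("_mean") and value <= 0:
                raise ValueError(f"{name} must be positive")


# Literature-plausible Great tit morphometrics.  Males are larger in
# wing, mass and bill; tarsi are identical between the sexes by
# construction — only this relative structure matters downstream.
MALE_MORPHOMETRICS = SexMorphometrics(
    mb_mean=17.0, mb_sd=0.8, wing_mean=78.0, wing_sd=1.5,
    bl_mean=13.2, bl_sd=0.4, bw_mean=4.1, bw_sd=0.15, bd_mean=4.7, bd_sd=0.15,
    tl_mean=19.5, tl_sd=0.6, tw_mean=2.2, tw_sd=0.08, td_mean=1.8, td_sd=0.08,
)
FEMALE_MORPHOMETRICS = SexMorphometrics(
    mb_mean=16.2, mb_sd=0.8, wing_mean=74.0, wing_sd=1.5,
    bl_mean=12.8, bl_sd=0.4, bw_mean=3.9, bw_sd=0.15, bd_mean=4.5, bd_sd=0.15,
    tl_mean=19.5, tl_sd=0.6, tw_mean=2.2, tw_sd=0.08, td_mean=1.8, td_sd=0.08,
)


@dataclass
class GeneratorConfig:
    """Population-level truths and noise levels for the generator.

    The thermal defaults are the study's reported population values:
    Tlc 17.7 degC, Tuc 34.5 degC, EWL inflection 31.85 degC, BMR
    0.96 ml O2 min^-1; the printed dispersions serve as
    between-individual SDs.  The cold- and hot-side slopes and the EWL
    parameters are set so that a bird at 10 degC runs ~1.4x BMR, a bird
    at 40 degC ~1.3x BMR, and the population mean cooling efficiency at
    40 degC is ~0.83.  ``tarsi_effect_male`` is the male-only log-scale
    coefficient of EWL at 40 degC on the tarsi index, sized to give the
    cooling-efficiency/tarsi-index regression an R^2 near 0.5.
    """

    n_individuals: int = 24
    sex_ratio: float = 0.5  # fraction male
    true_tlc: float = 17.7
    true_tlc_sd: float = 1.6
    true_tuc: float = 34.5
    true_tuc_sd: float = 0.7
    true_ewl_inflection: float = 31.85
    true_ewl_inflection_sd: float = 0.27
    true_bmr_mean: float = 0.96  # ml O2 min^-1
    true_bmr_sd: float = 0.12
    cold_slope: float = -0.05  # ml O2 min^-1 degC^-1, < 0
    hot_slope: float = 0.05  # ml O2 min^-1 degC^-1, > 0
    ewl_baseline: float = 120.0  # mg h^-1
    ewl_baseline_sd: float = 10.0
    ewl_hot_slope: float = 48.0  # mg h^-1 degC^-1
    vo2_noise_cv: float = 0.05
    ewl_noise_cv: float = 0.05
    tarsi_effect_male: float = 4.2  # log-scale, per unit tarsi index
    min_tnz_breadth: float = 5.0  # truncation: Tlc < Tuc - this
    test_temps: tuple[float, ...] = DEFAULT_TEST_TEMPS
    male: SexMorphometrics = field(default_factory=lambda: MALE_MORPHOMETRICS)
    female: SexMorphometrics = field(default_factory=lambda: FEMALE_MORPHOMETRICS)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must lie in [0, 1]")
        if not self.true_tlc < self.true_tuc:
            raise ValueError("true_Tlc must be below true_Tuc")
        if self.cold_slope >= 0:
            raise ValueError("cold_slope must be negative (VO2 falls as Ta "
                             "rises toward the TNZ)")
        if self.hot_slope <= 0:
            raise ValueError("hot_slope must be positive")
        for name in ("true_tlc_sd", "true_tuc_sd", "true_ewl_inflection_sd",
                     "true_bmr_sd", "ewl_baseline_sd", "vo2_noise_cv",
                     "ewl_noise_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        temps = np.asarray(self.test_temps, dtype=float)
        if temps.size == 0 or np.any(np.diff(temps) <= 0):
            raise ValueError("test_temps must be strictly increasing")


@dataclass
class TraceConfig:
    """Forward-model parameters for raw trace synthesis."""

    flow_rate: float = 1000.0  # ml min^-1 STP (1000 cold side, 3000 hot)
    sample_interval: float = 1.0  # s
    channel_dwell: float = 360.0  # s per animal segment
    baseline_duration: float = 300.0  # s
    baseline_every_k_chambers: int = 2
    n_animal_segments: int = 4
    chamber_volume_l: float = 3.9
    fio2: float = 0.2095
    incurrent_wvp: float = 0.5  # kPa, dry incurrent air (< 1 kPa)
    barometric_pressure: float = 101.0  # kPa
    drift_rate_o2: float = 0.0  # O2 fraction per hour
    drift_rate_wvp: float = 0.0  # kPa per hour
    analyzer_noise_sd_o2: float = 0.0  # O2 fraction
    analyzer_noise_sd_wvp: float = 0.0  # kPa

    def __post_init__(self) -> None:
        if self.flow_rate <= 0:
            raise ValueError("flow_rate must be positive")
        if self.incurrent_wvp >= 1.0:
            raise ValueError("incurrent air must be dry (< 1 kPa WVP)")
        if self.channel_dwell < 120.0:
            raise ValueError("channel_dwell must allow a 2-min window")
        if self.n_animal_segments < 1 or self.baseline_every_k_chambers < 1:
            raise ValueError("segment counts must be positive")

    @property
    def washout_tau(self) -> float:
        return self.chamber_volume_l * 1000.0 / self.flow_rate * 60.0


def _individual_rng(seed: int, index: int, stream: int = 0) -> np.random.Generator:
    """Fixed per-individual substream of the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(index, stream)))


def _positive_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    for _ in range(100):
        v = rng.normal(mean, sd)
        if v > 0:
            return float(v)
    raise ValueError(f"could not draw a positive value around {mean} +/- {sd}")


def generate_population(config: GeneratorConfig) -> list[IndividualRecord]:
    """Draw a population of individuals with latent thermal truths.

    Sexes are interleaved deterministically (individual ``i`` is male
    when ``floor((i+1)*ratio) > floor(i*ratio)``), which yields
    ``round(n * sex_ratio)`` males and keeps each individual's sex — and
    its dedicated random substream — independent of ``n_individuals``,
    so enlarging a population never perturbs existing records.  Surface
    areas and sex-stratified size indices are computed before returning.
    """
    n = config.n_individuals
    population: list[IndividualRecord] = []
    for i in range(n):
        rng = _individual_rng(config.seed, i)
        sex = "M" if int((i + 1) * config.sex_ratio) > \
            int(i * config.sex_ratio) else "F"
        morph = config.male if sex == "M" else config.female
        record = IndividualRecord(
            id=f"GT{i + 1:03d}",
            sex=sex,
            mb=_positive_normal(rng, morph.mb_mean, morph.mb_sd),
            bl=_positive_normal(rng, morph.bl_mean, morph.bl_sd),
            bw=_positive_normal(rng, morph.bw_mean, morph.bw_sd),
            bd=_positive_normal(rng, morph.bd_mean, morph.bd_sd),
            tl=_positive_normal(rng, morph.tl_mean, morph.tl_sd),
            tw=_positive_normal(rng, morph.tw_mean, morph.tw_sd),
            td=_positive_normal(rng, morph.td_mean, morph.td_sd),
            wing=_positive_normal(rng, morph.wing_mean, morph.wing_sd),
        )
        for _ in range(100):
            tlc = rng.normal(config.true_tlc, config.true_tlc_sd)
            tuc = rng.normal(config.true_tuc, config.true_tuc_sd)
            if tlc < tuc - config.min_tnz_breadth:
                break
        else:
            raise ValueError("could not draw Tlc < Tuc - min_tnz_breadth; "
                             "check breakpoint means/SDs")
        record.true_tlc = float(tlc)
        record.true_tuc = float(tuc)
        record.true_bmr = _positive_normal(rng, config.true_bmr_mean,
                                           config.true_bmr_sd)
        record.true_ewl_inflection = float(
            rng.normal(config.true_ewl_inflection,
                       config.true_ewl_inflection_sd))
        record.true_ewl_baseline = _positive_normal(rng, config.ewl_baseline,
                                                    config.ewl_baseline_sd)
        population.append(record)
    add_surface_areas(population)
    add_size_indices(population)
    return population


def _lognormal_factors(rng: np.random.Generator, cv: float,
                       size: int) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with coefficient of
    variation ``cv`` (rates are positive and right-skewed)."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def expected_vo2(record: IndividualRecord, temps: np.ndarray,
                 config: GeneratorConfig) -> np.ndarray:
    """Noise-free U-shaped VO2(Ta) for one individual."""
    temps = np.asarray(temps, dtype=float)
    return (record.true_bmr
            + config.cold_slope * np.minimum(temps - record.true_tlc, 0.0)
            + config.hot_slope * np.maximum(temps - record.true_tuc, 0.0))


def expected_ewl(record: IndividualRecord, temps: np.ndarray,
                 config: GeneratorConfig) -> np.ndarray:
    """Noise-free flat-then-rising EWL(Ta), including the male-only
    tarsi effect at 40 degC."""
    temps = np.asarray(temps, dtype=float)
    ewl = (record.true_ewl_baseline
           + config.ewl_hot_slope
           * np.maximum(temps - record.true_ewl_inflection, 0.0))
    if (record.sex == "M" and config.tarsi_effect_male != 0.0
            and record.tarsi_index is not None):
        at40 = np.isclose(temps, 40.0)
        ewl = np.where(
            at40,
            ewl * np.exp(config.tarsi_effect_male * record.tarsi_index),
            ewl)
    return ewl


def generate_thermal_profile(record: IndividualRecord,
                             temps: Sequence[float],
                             config: GeneratorConfig,
                             rng: np.random.Generator | None = None,
                             ) -> ThermalProfile:
    """Steady-state VO2/EWL profile for one individual.

    Deterministic means from :func:`expected_vo2` / :func:`expected_ewl`
    multiplied by mean-one lognormal noise of the configured CVs.  Pass
    the per-individual substream ``rng`` for reproducible populations
    (see :func:`generate_profiles`).
    """
    temps = np.asarray(temps, dtype=float)
    if temps.size == 0:
        raise ValueError("temps must be non-empty")
    if np.any(temps < 5.0) or np.any(temps > 45.0):
        raise ValueError("test temperatures must lie within [5, 45] degC")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    vo2 = expected_vo2(record, temps, config)
    ewl = expected_ewl(record, temps, config)
    vo2 = vo2 * _lognormal_factors(rng, config.vo2_noise_cv, temps.size)
    ewl = ewl * _lognormal_factors(rng, config.ewl_noise_cv, temps.size)
    return ThermalProfile(record.id, temps, vo2, ewl)


def generate_profiles(population: Sequence[IndividualRecord],
                      config: GeneratorConfig,
                      temps: Sequence[float] | None = None,
                      ) -> list[ThermalProfile]:
    """Profiles for a whole population, one noise substream each."""
    if temps is None:
        temps = config.test_temps
    return [
        generate_thermal_profile(rec, temps, config,
                                 rng=_individual_rng(config.seed, i, stream=1))
        for i, rec in enumerate(population)
    ]


def _steady_fractions(steady_vo2: float, steady_ewl: float,
                      tconfig: TraceConfig) -> tuple[float, float]:
    """Excurrent O2 fraction and WVP implied by the steady rates.

    Inverts the reduction module's gas equations, so a noise-free trace
    round-trips exactly once the chamber has washed out.
    """
    feo2 = tconfig.fio2 - steady_vo2 * (
        1.0 - tconfig.fio2 * (1.0 - DEFAULT_RQ)) / tconfig.flow_rate
    flux = steady_ewl / (WATER_VAPOR_DENSITY_STP * 60.0)  # ml min^-1
    fi = tconfig.incurrent_wvp / tconfig.barometric_pressure
    fe = (flux + tconfig.flow_rate * fi) / (tconfig.flow_rate + flux)
    return feo2, fe * tconfig.barometric_pressure


def generate_trace(record: IndividualRecord, ta: float, steady_vo2: float,
                   steady_ewl: float, tconfig: TraceConfig,
                   rng: np.random.Generator | None = None,
                   ) -> RespirometryTrace:
    """Forward-model a raw analyzer trace for one individual at one Ta.

    The schedule opens with a baseline segment and inserts another after
    every ``baseline_every_k_chambers`` animal segments, closing with a
    final baseline so drift anchors bracket all animal data.  The
    chamber washes toward its steady excurrent composition with the
    single-compartment time constant volume/flow, on a clock that runs
    from the start of the trace (the chamber is flushed continuously;
    the multiplexer only selects which stream is analyzed).  Linear
    drift and white analyzer noise are added on top.

    A trace whose post-washout animal samples cannot fill a 2-min window
    is flagged ``insufficient_equilibrated_time``.
    """
    if steady_vo2 <= 0:
        raise ValueError("steady_vo2 must be positive")
    if steady_ewl < 0:
        raise ValueError("steady_ewl must be non-negative")
    if rng is None:
        rng = np.random.default_rng(0)
    feo2_ss, wvp_ss = _steady_fractions(steady_vo2, steady_ewl, tconfig)

    segments: list[tuple[bool, float]] = [(True, tconfig.baseline_duration)]
    for i in range(tconfig.n_animal_segments):
        segments.append((False, tconfig.channel_dwell))
        last = i == tconfig.n_animal_segments - 1
        if (i + 1) % tconfig.baseline_every_k_chambers == 0 or last:
            segments.append((True, tconfig.baseline_duration))

    dt = tconfig.sample_interval
    times, o2, wvp, seg_ids, is_base = [], [], [], [], []
    t_cursor = 0.0
    tau = tconfig.washout_tau
    for seg_id, (baseline, duration) in enumerate(segments):
        t = t_cursor + np.arange(0.0, duration, dt)
        if baseline:
            o2_seg = np.full(t.size, tconfig.fio2)
            wvp_seg = np.full(t.size, tconfig.incurrent_wvp)
        else:
            washout = 1.0 - np.exp(-t / tau)
            o2_seg = tconfig.fio2 + (feo2_ss - tconfig.fio2) * washout
            wvp_seg = tconfig.incurrent_wvp + \
                (wvp_ss - tconfig.incurrent_wvp) * washout
        times.append(t)
        o2.append(o2_seg)
        wvp.append(wvp_seg)
        seg_ids.append(np.full(t.size, seg_id, dtype=int))
        is_base.append(np.full(t.size, baseline))
        t_cursor = t_cursor + duration

    time = np.concatenate(times)
    o2 = np.concatenate(o2)
    wvp = np.concatenate(wvp)
    hours = time / 3600.0
    o2 = o2 + tconfig.drift_rate_o2 * hours
    wvp = wvp + tconfig.drift_rate_wvp * hours
    if tconfig.analyzer_noise_sd_o2 > 0:
        o2 = o2 + rng.normal(0.0, tconfig.analyzer_noise_sd_o2, time.size)
    if tconfig.analyzer_noise_sd_wvp > 0:
        wvp = wvp + rng.normal(0.0, tconfig.analyzer_noise_sd_wvp, time.size)

    flags = []
    is_base = np.concatenate(is_base)
    usable = (~is_base) & (time >= 5.0 * tau)
    if usable.sum() * dt < 120.0:
        flags.append("insufficient_equilibrated_time")

    return RespirometryTrace(
        time=time,
        o2=o2,
        wvp=np.maximum(wvp, 0.0),
        segment_id=np.concatenate(seg_ids),
        is_baseline=is_base,
        flow_rate=tconfig.flow_rate,
        barometric_pressure=tconfig.barometric_pressure,
        ta=float(ta),
        fio2=tconfig.fio2,
        incurrent_wvp=tconfig.incurrent_wvp,
        chamber_volume_l=tconfig.chamber_volume_l,
        individual_id=record.id,
        flags=flags,
    )


def trace_config_for_temperature(ta: float, base: TraceConfig | None = None,
                                 ) -> TraceConfig:
    """Protocol flow-rate switch: 1000 ml/min up to 30 degC, 3000 above."""
    base = base or TraceConfig()
    flow = 3000.0 if ta > 30.0 else 1000.0
    return replace(base, flow_rate=flow)
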