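"""Synthetic NIR glucose-sensor data with a Beer–Lambert forward model.

The real study population (101 volunteers, reference glucose 80–488 mg/dL,
three skin tones, two sensor sites) is not publicly deposited, so this module
generates cohorts and per-acquisition voltage frame logs with the statistical
structure the downstream analysis assumes:

* reflected intensity follows the Beer–Lambert law
  ``R = R0 * exp(-mu_eff * l)`` with effective attenuation
  ``mu_eff = sqrt(3 * gamma_a * (gamma_a + gamma_s'))``, absorption
  ``gamma_a = 2.303 * epsilon * C`` and reduced scattering
  ``gamma_s' = gamma_s * (1 - a)``;
* voltage is strictly decreasing in glucose (high concentration absorbs more,
  so the reflected signal is low);
* skin tone enters as a small multiplicative transmission factor on the
  incident intensity (melanin attenuation at 940 nm is weak);
* each acquisition is a frame log (100 frames by default) with additive
  dark-current, optional ambient-light and pressure offsets, and i.i.d.
  Gaussian frame noise.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "SKIN_TONES",
    "SITES",
    "MEAL_STATES",
    "GLUCOSE_MOLAR_MASS",
    "BeerLambertParams",
    "SynthConfig",
    "glucose_to_molar",
    "effective_attenuation",
    "forward_voltage",
    "generate_cohort",
    "generate_frame_log",
    "generate_dataset",
]

SKIN_TONES = ("dark", "wheatish", "fair")
SITES = ("finger", "wrist")
MEAL_STATES = ("fasting", "postprandial", "random")

#: molar mass of glucose (C6H12O6), g/mol
GLUCOSE_MOLAR_MASS = 180.156

#: age-group composition of the volunteer cohort (years, inclusive bounds)
#: and head counts at n=101
AGE_GROUPS = ((20, 35, 4), (35, 50, 22), (50, 65, 61), (65, 90, 14))
MALE_COUNT_AT_101 = 57
DIABETIC_COUNT_AT_101 = 97

#: canonical sample-table column order (the CSV dialect every reader assumes)
SAMPLE_COLUMNS = [
    "volunteer_id", "site", "visit", "reference_mgdl", "skin_tone",
    "age", "sex", "bmi", "diabetic", "meal_state", "sleep", "stress",
    "spo2", "wrist_hair", "hv_volts", "dc_volts", "lv_volts",
]


def glucose_to_molar(glucose_mgdl: float) -> float:
    """Convert a blood-glucose level in mg/dL to a molar chromophore
    concentration in mol/L (mg/dL -> g/L divides by 100, then by the molar
    mass)."""
    if glucose_mgdl < 0:
        raise ConfigurationError(f"glucose must be >= 0, got {glucose_mgdl}")
    return glucose_mgdl / (GLUCOSE_MOLAR_MASS * 100.0)


@dataclass(frozen=True)
class BeerLambertParams:
    """Optical parameters of the diffuse-reflectance forward model.

    Defaults put noise-free voltages in the 0.13–0.19 V band reported for the
    wrist sensor, with a mild (~25% in log) attenuation span over the
    80–488 mg/dL range.
    """

    incident_intensity: float = 1.0     # R0, volts-equivalent
    path_length: float = 0.09           # l, cm
    molar_extinction: float = 30.0      # epsilon, L mol^-1 cm^-1
    scatter_coefficient: float = 10.0   # gamma_s, cm^-1
    anisotropy: float = 0.99            # a, mean cosine of scattering angle

    def __post_init__(self):
        if self.incident_intensity <= 0:
            raise ConfigurationError("incident_intensity must be > 0")
        if self.path_length <= 0:
            raise ConfigurationError("path_length must be > 0")
        if self.molar_extinction <= 0:
            raise ConfigurationError("molar_extinction must be > 0")
        if self.scatter_coefficient < 0:
            raise ConfigurationError("scatter_coefficient must be >= 0")
        if not 0 <= self.anisotropy < 1:
            raise ConfigurationError("anisotropy must satisfy 0 <= a < 1")

    @property
    def reduced_scattering(self) -> float:
        """gamma_s' = gamma_s * (1 - a), cm^-1."""
        return self.scatter_coefficient * (1.0 - self.anisotropy)


def effective_attenuation(concentration: float, params: BeerLambertParams) -> float:
    """mu_eff = sqrt(3 * gamma_a * (gamma_a + gamma_s')), cm^-1, with
    gamma_a = 2.303 * epsilon * C."""
    if concentration < 0:
        raise ConfigurationError("concentration must be >= 0")
    gamma_a = 2.303 * params.molar_extinction * concentration
    return math.sqrt(3.0 * gamma_a * (gamma_a + params.reduced_scattering))


@dataclass
class SynthConfig:
    """Study conditions of the synthetic cohort and acquisition protocol."""

    n_volunteers: int = 101
    glucose_range: tuple[int, int] = (80, 488)          # mg/dL
    skin_tone_multipliers: dict = field(
        default_factory=lambda: {"dark": 0.98, "wheatish": 0.99, "fair": 1.00}
    )
    site_gains: dict = field(
        default_factory=lambda: {"finger": 0.21, "wrist": 0.19}
    )  # V per unit reflectance
    dark_current: float = 0.002          # V
    bare_led_voltage: float | None = None  # V; None -> site_gain * R0 + dark
    ambient_offset: float = 0.005        # V, added only when ambient_enabled
    ambient_enabled: bool = False
    pressure_effect: float = 0.0         # V
    frame_noise_sd: float = 1e-4         # V, i.i.d. Gaussian per frame
    frames_per_sample: int = 100
    seed: int = 0
    #: "interval": one volunteer per skin tone per 5 mg/dL interval with a
    #: matched reference value (the calibration sweep the adjustment
    #: algorithm assumes); "random": per-volunteer visits with a meal-state
    #: glucose mixture.
    design: str = "interval"
    visits_per_volunteer: int = 3        # used by the "random" design
    interval_width: int = 5              # mg/dL, the grouping the analysis uses

    def __post_init__(self):
        if self.n_volunteers < 1:
            raise ConfigurationError("n_volunteers must be >= 1")
        lo, hi = self.glucose_range
        if not 0 < lo < hi:
            raise ConfigurationError("glucose_range must satisfy 0 < low < high")
        if self.frame_noise_sd < 0:
            raise ConfigurationError("frame_noise_sd must be >= 0")
        if self.frames_per_sample < 1:
            raise ConfigurationError("frames_per_sample must be >= 1")
        if self.ambient_offset < 0 or self.dark_current < 0:
            raise ConfigurationError("offsets must be >= 0")
        if self.design not in ("interval", "random"):
            raise ConfigurationError(f"unknown design {self.design!r}")
        if self.visits_per_volunteer < 1:
            raise ConfigurationError("visits_per_volunteer must be >= 1")
        for tone, mult in self.skin_tone_multipliers.items():
            if mult <= 0:
                raise ConfigurationError(f"multiplier for tone {tone!r} must be > 0")

    def tone_multiplier(self, tone: str) -> float:
        try:
            return self.skin_tone_multipliers[tone]
        except KeyError:
            raise ConfigurationError(
                f"unknown skin tone {tone!r}; configured: "
                f"{sorted(self.skin_tone_multipliers)}"
            ) from None

    def site_gain(self, site: str) -> float:
        try:
            return self.site_gains[site]
        except KeyError:
            raise ConfigurationError(
                f"unknown site {site!r}; configured: {sorted(self.site_gains)}"
            ) from None

    def led_voltage(self, site: str, params: BeerLambertParams) -> float:
        """Bare-LED calibration reading: full reflectance plus dark current."""
        if self.bare_led_voltage is not None:
            return self.bare_led_voltage
        return self.site_gain(site) * params.incident_intensity + self.dark_current


def forward_voltage(
    glucose: float,
    tone: str,
    site: str,
    params: BeerLambertParams | None = None,
    cfg: SynthConfig | None = None,
) -> float:
    """Noise-free detector voltage for one acquisition.

    ``V = site_gain * tone_multiplier * R0 * exp(-mu_eff(glucose) * l)
    + dark_current``; strictly decreasing in glucose for fixed tone and site.
    """
    params = params or BeerLambertParams()
    cfg = cfg or SynthConfig()
    conc = glucose_to_molar(glucose)
    mu_eff = effective_attenuation(conc, params)
    reflect = params.incident_intensity * math.exp(-mu_eff * params.path_length)
    return cfg.site_gain(site) * cfg.tone_multiplier(tone) * reflect + cfg.dark_current


def _allocate(n: int, weights: list[float]) -> list[int]:
    """Integer allocation of n slots proportional to weights (largest
    remainder), so marginals match the documented head counts exactly."""
    total = sum(weights)
    raw = [n * w / total for w in weights]
    counts = [int(math.floor(r)) for r in raw]
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[: n - sum(counts)]:
        counts[i] += 1
    return counts


def generate_cohort(cfg: SynthConfig | None = None) -> pd.DataFrame:
    """Draw a volunteer cohort with the documented age/sex structure.

    At n=101 the age-group and sex marginals match the study head counts
    exactly (57 M / 44 F; age groups 4/22/61/14); other sizes scale
    proportionally. Skin tones are assigned round-robin.
    """
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_volunteers

    group_counts = _allocate(n, [g[2] for g in AGE_GROUPS])
    ages = []
    for (lo, hi, _), k in zip(AGE_GROUPS, group_counts):
        ages.extend(rng.integers(lo, hi, size=k).tolist())
    ages = np.array(ages[:n])

    n_male = _allocate(n, [MALE_COUNT_AT_101, 101 - MALE_COUNT_AT_101])[0]
    sexes = np.array(["M"] * n_male + ["F"] * (n - n_male))
    rng.shuffle(sexes)

    n_diab = _allocate(n, [DIABETIC_COUNT_AT_101, 101 - DIABETIC_COUNT_AT_101])[0]
    diabetic = np.array([1] * n_diab + [0] * (n - n_diab))
    rng.shuffle(diabetic)

    cohort = pd.DataFrame(
        {
            "volunteer_id": [f"V{i + 1:03d}" for i in range(n)],
            "age": ages,
            "sex": sexes,
            "bmi": np.round(np.clip(rng.normal(26.0, 4.0, size=n), 16, 45), 1),
            "diabetic": diabetic,
            "skin_tone": [SKIN_TONES[i % 3] for i in range(n)],
            "sleep": rng.integers(0, 2, size=n),        # 1 = adequate sleep
            "stress": rng.integers(0, 2, size=n),       # 1 = self-reported stress
            "spo2": np.round(np.clip(rng.normal(97.0, 1.2, size=n), 90, 100), 1),
            "wrist_hair": rng.integers(0, 2, size=n),   # 1 = hair on the wrist
        }
    )
    return cohort


def _tone_of(volunteer) -> str:
    if isinstance(volunteer, str):
        return volunteer
    try:
        return volunteer["skin_tone"]
    except (KeyError, TypeError, IndexError):
        raise ConfigurationError(
            "volunteer must be a skin-tone string or a mapping with a "
            "'skin_tone' entry"
        ) from None


def generate_frame_log(
    volunteer,
    glucose: float,
    site: str,
    cfg: SynthConfig | None = None,
    params: BeerLambertParams | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One acquisition: ``frames_per_sample`` voltage frames.

    Each frame is the noise-free forward voltage plus the ambient offset (if
    enabled), the pressure offset, and an independent Gaussian perturbation
    of SD ``frame_noise_sd``.
    """
    cfg = cfg or SynthConfig()
    params = params or BeerLambertParams()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    base = forward_voltage(glucose, _tone_of(volunteer), site, params, cfg)
    if cfg.ambient_enabled:
        base += cfg.ambient_offset
    base += cfg.pressure_effect
    noise = rng.normal(0.0, cfg.frame_noise_sd, size=cfg.frames_per_sample)
    return base + noise


def _interval_visits(cfg: SynthConfig, cohort: pd.DataFrame, rng) -> list[dict]:
    """Calibration sweep: for every interval in the glucose range, one
    volunteer of each skin tone measured at a matched reference value."""
    lo, hi = cfg.glucose_range
    w = cfg.interval_width
    first = 81 + w * math.floor((lo - 81) / w)
    lowers = range(first, hi + 1, w)
    by_tone = {
        tone: cohort[cohort["skin_tone"] == tone].to_dict("records")
        for tone in SKIN_TONES
    }
    for tone, members in by_tone.items():
        if not members:
            raise ConfigurationError(
                f"cohort has no volunteer with skin tone {tone!r}; "
                "increase n_volunteers"
            )
    visits = []
    for b, lower in enumerate(lowers):
        g = int(rng.integers(max(lower, lo), min(lower + w - 1, hi) + 1))
        meal = MEAL_STATES[b % len(MEAL_STATES)]
        for tone in SKIN_TONES:
            members = by_tone[tone]
            vol = members[b % len(members)]
            visits.append({"volunteer": vol, "glucose": g, "meal_state": meal})
    return visits


def _random_visits(cfg: SynthConfig, cohort: pd.DataFrame, rng) -> list[dict]:
    """Survey design: each volunteer contributes ``visits_per_volunteer``
    readings drawn from a meal-state glucose mixture."""
    lo, hi = cfg.glucose_range
    means = {  # (diabetic, meal_state) -> (mean, sd), mg/dL
        (1, "fasting"): (145, 40), (1, "postprandial"): (220, 70),
        (1, "random"): (185, 60), (0, "fasting"): (95, 10),
        (0, "postprandial"): (125, 15), (0, "random"): (105, 15),
    }
    visits = []
    for _, vol in cohort.iterrows():
        for v in range(cfg.visits_per_volunteer):
            meal = MEAL_STATES[v % len(MEAL_STATES)]
            mu, sd = means[(int(vol["diabetic"]), meal)]
            g = int(np.clip(round(rng.normal(mu, sd)), lo, hi))
            visits.append(
                {"volunteer": vol.to_dict(), "glucose": g, "meal_state": meal}
            )
    return visits


def generate_dataset(
    cfg: SynthConfig | None = None,
    params: BeerLambertParams | None = None,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the full acquisition campaign.

    Returns ``(samples, ground_truth)``: one finger and one wrist record per
    volunteer-visit, with the aggregated (frame-mean) voltage ``hv_volts``,
    the dark-current ``dc_volts`` and bare-LED ``lv_volts`` calibration
    values, and all volunteer covariates. ``ground_truth`` keeps the
    noise-free voltage and generating parameters for recovery tests.

    When ``out_dir`` is given, writes ``samples.csv``, ``ground_truth.csv``
    and ``cohort.csv`` there.
    """
    cfg = cfg or SynthConfig()
    params = params or BeerLambertParams()
    rng = np.random.default_rng(cfg.seed)
    cohort = generate_cohort(cfg)

    if cfg.design == "interval":
        visits = _interval_visits(cfg, cohort, rng)
    else:
        visits = _random_visits(cfg, cohort, rng)

    rows, truth_rows = [], []
    visit_counter: dict[str, int] = {}
    for visit in visits:
        vol, g, meal = visit["volunteer"], visit["glucose"], visit["meal_state"]
        vid = vol["volunteer_id"]
        visit_counter[vid] = visit_counter.get(vid, 0) + 1
        for site in SITES:
            frames = generate_frame_log(vol, g, site, cfg, params, rng)
            clean = forward_voltage(g, vol["skin_tone"], site, params, cfg)
            rows.append(
                {
                    "volunteer_id": vid,
                    "site": site,
                    "visit": visit_counter[vid],
                    "reference_mgdl": g,
                    "skin_tone": vol["skin_tone"],
                    "age": vol["age"],
                    "sex": vol["sex"],
                    "bmi": vol["bmi"],
                    "diabetic": vol["diabetic"],
                    "meal_state": meal,
                    "sleep": vol["sleep"],
                    "stress": vol["stress"],
                    "spo2": vol["spo2"],
                    "wrist_hair": vol["wrist_hair"],
                    "hv_volts": float(np.mean(frames)),
                    "dc_volts": cfg.dark_current,
                    "lv_volts": cfg.led_voltage(site, params),
                }
            )
            truth_rows.append(
                {
                    "volunteer_id": vid,
                    "site": site,
                    "visit": visit_counter[vid],
                    "reference_mgdl": g,
                    "skin_tone": vol["skin_tone"],
                    "noise_free_volts": clean,
                    "tone_multiplier": cfg.tone_multiplier(vol["skin_tone"]),
                    "site_gain": cfg.site_gain(site),
                }
            )

    samples = pd.DataFrame(rows, columns=SAMPLE_COLUMNS)
    truth = pd.DataFrame(truth_rows)

    if out_dir is not None:
        out = Path(out_dir)
        try:
            out.mkdir(parents=True, exist_ok=True)
            samples.to_csv(out / "samples.csv", index=False)
            truth.to_csv(out / "ground_truth.csv", index=False)
            cohort.to_csv(out / "cohort.csv", index=False)
        except OSError as exc:
            raise NirGlucoseIOError(out, exc) from exc
    return samples, truth


class NirGlucoseIOError(ConfigurationError):
    def __init__(self, path, exc):
        super().__init__(f"could not write dataset under {path}: {exc}")


def with_overrides(cfg: SynthConfig, **kwargs) -> SynthConfig:
    """Return a copy of ``cfg`` with the given fields replaced (re-validated)."""
    return replace(cfg, **kwargs)
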