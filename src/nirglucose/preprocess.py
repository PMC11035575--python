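"""The three preprocessing branches of the analysis.

* ``raw``: the aggregated sensor voltage as measured.
* ``normalized``: dark-current normalization
  ``N = 100 * (HV - DC) / (LV - DC)`` against the bare-LED calibration value.
* ``framework``: the interval-based data analytic framework — a per-interval
  skin-tone adjustment factor applied to the voltages (the square root of the
  pooled within-interval voltage variance across tones), followed by target
  integration (each reference value replaced by the mean reference of its
  5 mg/dL interval, in mmol/L).

The branches are alternatives: the framework branch does not additionally
apply the normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import MGDL_PER_MMOL, mgdl_to_mmol
from .errors import (
    ConfigurationError,
    CoverageError,
    DegenerateIntervalError,
    SchemaError,
)

__all__ = [
    "BRANCHES",
    "BIN_WIDTH",
    "BIN_ORIGIN",
    "AdjustmentBin",
    "AdjustmentModel",
    "IntegratedDataset",
    "normalize_voltage",
    "bin_lower",
    "assign_bins",
    "interval_variance",
    "correction_factor",
    "adjustment_factor",
    "fit_adjustment_model",
    "apply_adjustment",
    "integrate_targets",
    "encode_features",
    "build_branch",
]

BRANCHES = ("raw", "normalized", "framework")

#: interval width and first interior lower bound, mg/dL ([81,85], [86,90], ...)
BIN_WIDTH = 5
BIN_ORIGIN = 81

#: the ten model inputs: the sensor voltage plus nine covariates
COVARIATES = [
    "age", "sex", "bmi", "diabetic", "meal_state",
    "sleep", "stress", "spo2", "wrist_hair",
]


def normalize_voltage(hv, dc, lv):
    """Dark-current normalization, percent scale:
    ``N = 100 * (hv - dc) / (lv - dc)``. Requires ``lv > dc``."""
    hv = np.asarray(hv, float)
    dc = np.asarray(dc, float)
    lv = np.asarray(lv, float)
    if np.any(lv <= dc):
        raise ConfigurationError(
            "normalization undefined: bare-LED voltage must exceed dark current"
        )
    out = 100.0 * (hv - dc) / (lv - dc)
    return float(out) if out.ndim == 0 else out


def bin_lower(reference, width: int = BIN_WIDTH, origin: int = BIN_ORIGIN):
    """Lower bound of the inclusive integer interval containing ``reference``.

    Interior bins are [81,85], [86,90], ...; the grid extends below 81 and
    above 500 by the same width, so every observed value maps to exactly one
    bin (80 falls in [76,80]). Non-integer references are assigned by floor.
    """
    if width <= 0:
        raise ConfigurationError("interval width must be positive")
    ref = np.asarray(reference, float)
    lower = origin + width * np.floor((ref - origin) / width)
    out = lower.astype(int)
    return int(out) if out.ndim == 0 else out


@dataclass
class AdjustmentBin:
    """Per-interval statistics: member voltages, their variance, and the
    correction/adjustment factors derived from it."""

    lower: int
    upper: int
    member_values: np.ndarray
    mean: float
    n: int
    x_var: float | None
    f_correct: float | None
    a_factor: float

    @property
    def degenerate(self) -> bool:
        return self.f_correct is None


@dataclass
class AdjustmentModel:
    """Ordered, non-overlapping interval bins covering the observed range."""

    bins: list[AdjustmentBin]
    width: int = BIN_WIDTH
    origin: int = BIN_ORIGIN
    value_column: str = "hv_volts"
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._index = {b.lower: b for b in self.bins}

    def lookup(self, reference: float) -> AdjustmentBin:
        lo = bin_lower(reference, self.width, self.origin)
        try:
            return self._index[lo]
        except KeyError:
            raise CoverageError(
                f"no adjustment bin covers reference value {reference} "
                f"(interval [{lo}, {lo + self.width - 1}])"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lower": [b.lower for b in self.bins],
                "bin_upper": [b.upper for b in self.bins],
                "n": [b.n for b in self.bins],
                "x_var": [b.x_var for b in self.bins],
                "f_correct": [b.f_correct for b in self.bins],
                "a_factor": [b.a_factor for b in self.bins],
            }
        )


def assign_bins(records: pd.DataFrame, width: int = BIN_WIDTH,
                origin: int = BIN_ORIGIN) -> pd.DataFrame:
    """Return a copy of ``records`` with a ``bin_lower`` column assigning
    every row to exactly one inclusive interval."""
    if width <= 0:
        raise ConfigurationError("interval width must be positive")
    out = records.copy()
    out["bin_lower"] = bin_lower(out["reference_mgdl"].to_numpy(), width, origin)
    return out


def interval_variance(values) -> float:
    """Sample variance of the member values, divisor n-1.

    Fewer than two members leaves the statistic undefined and raises
    :class:`DegenerateIntervalError`; callers fall back to the identity
    adjustment factor.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise DegenerateIntervalError(
            f"interval variance needs at least two members, got {arr.size}"
        )
    return float(np.var(arr, ddof=1))


def correction_factor(x_var: float) -> float:
    """``F_correct = 1 / sqrt(X_var)``; requires a positive variance."""
    if x_var <= 0:
        raise DegenerateIntervalError(
            f"correction factor undefined for variance {x_var}"
        )
    return 1.0 / math.sqrt(x_var)


def adjustment_factor(x_var: float, f_correct: float | None = None) -> float:
    """``A_factor = X_var * F_correct`` (algebraically ``sqrt(X_var)``)."""
    if f_correct is None:
        f_correct = correction_factor(x_var)
    return x_var * f_correct


def fit_adjustment_model(
    records: pd.DataFrame,
    value_column: str = "hv_volts",
    width: int = BIN_WIDTH,
    origin: int = BIN_ORIGIN,
) -> AdjustmentModel:
    """Build the per-interval adjustment model.

    Member voltages are pooled across skin tones within each interval; the
    interval variance, correction factor and adjustment factor follow.
    Degenerate intervals (one member, or zero variance) carry the identity
    factor ``A = 1``. The model's bin grid is contiguous over the observed
    reference range, so every record of the fitted data maps to a bin.
    """
    if len(records) == 0:
        raise SchemaError("cannot fit an adjustment model on an empty table")
    if value_column not in records.columns:
        raise SchemaError(f"missing value column {value_column!r}")
    binned = assign_bins(records, width, origin)
    first = bin_lower(binned["reference_mgdl"].min(), width, origin)
    last = bin_lower(binned["reference_mgdl"].max(), width, origin)
    bins = []
    for lo in range(first, last + 1, width):
        members = binned.loc[binned["bin_lower"] == lo, value_column].to_numpy(float)
        try:
            x_var = interval_variance(members)
            f_corr = correction_factor(x_var)
            a_fact = adjustment_factor(x_var, f_corr)
        except DegenerateIntervalError:
            x_var = float(np.var(members, ddof=1)) if members.size >= 2 else None
            f_corr = None
            a_fact = 1.0
        bins.append(
            AdjustmentBin(
                lower=lo,
                upper=lo + width - 1,
                member_values=members,
                mean=float(members.mean()) if members.size else float("nan"),
                n=int(members.size),
                x_var=x_var,
                f_correct=f_corr,
                a_factor=a_fact,
            )
        )
    return AdjustmentModel(bins=bins, width=width, origin=origin,
                           value_column=value_column)


def apply_adjustment(records: pd.DataFrame, model: AdjustmentModel) -> pd.DataFrame:
    """Multiply each record's voltage by its interval's adjustment factor.

    Adds an ``adjusted_volts`` column; every other field is unchanged and the
    row count is conserved. A record whose interval the model does not cover
    raises :class:`CoverageError` naming the reference value.
    """
    factors = np.array(
        [model.lookup(ref).a_factor for ref in records["reference_mgdl"]]
    )
    out = records.copy()
    out["adjusted_volts"] = factors * out[model.value_column].to_numpy(float)
    return out


@dataclass
class IntegratedDataset:
    """Feature matrix with interval-averaged targets (mmol/L)."""

    features: pd.DataFrame
    target_mmol: pd.Series
    bin_lower: pd.Series
    branch: str


def integrate_targets(records: pd.DataFrame, width: int = BIN_WIDTH,
                      origin: int = BIN_ORIGIN,
                      factor: float = MGDL_PER_MMOL) -> pd.DataFrame:
    """Replace each reference value by its interval mean, in mmol/L.

    Every member row of an interval receives that interval's average
    reference value as its ``target_mmol``; row count is conserved, and the
    target always lies between the interval's min and max reference.
    """
    if len(records) == 0:
        raise SchemaError("cannot integrate targets of an empty table")
    binned = assign_bins(records, width, origin)
    ref_mmol = mgdl_to_mmol(binned["reference_mgdl"].to_numpy(), factor=factor)
    binned["reference_mmol"] = ref_mmol
    binned["target_mmol"] = binned.groupby("bin_lower")["reference_mmol"].transform("mean")
    return binned


def encode_features(records: pd.DataFrame, branch: str = "raw") -> pd.DataFrame:
    """Numeric feature matrix of the ten model inputs.

    Column order is deterministic: the branch's voltage column first
    (``voltage``), then ``age, sex_male, bmi, diabetic, meal_fasting,
    meal_postprandial, meal_random, sleep, stress, spo2, wrist_hair``.
    Binary fields are single 0/1 columns; the three-level meal state is
    one-hot encoded.
    """
    if branch not in BRANCHES:
        raise ConfigurationError(f"unknown branch {branch!r}; expected one of {BRANCHES}")
    needed = list(COVARIATES)
    if branch == "raw":
        needed += ["hv_volts"]
    elif branch == "normalized":
        needed += ["hv_volts", "dc_volts", "lv_volts"]
    else:
        needed += ["adjusted_volts"]
    for col in needed:
        if col not in records.columns:
            raise SchemaError(f"missing field {col!r} required by branch {branch!r}")
        na = records[col].isna()
        if na.any():
            raise SchemaError(
                f"missing covariate {col!r} at rows {records.index[na].tolist()[:5]}"
            )

    if branch == "raw":
        voltage = records["hv_volts"].to_numpy(float)
    elif branch == "normalized":
        voltage = normalize_voltage(
            records["hv_volts"], records["dc_volts"], records["lv_volts"]
        )
    else:
        voltage = records["adjusted_volts"].to_numpy(float)

    unknown_meal = set(records["meal_state"]) - {"fasting", "postprandial", "random"}
    if unknown_meal:
        raise SchemaError(f"unknown meal_state values: {sorted(unknown_meal)}")
    features = pd.DataFrame(
        {
            "voltage": voltage,
            "age": records["age"].to_numpy(float),
            "sex_male": (records["sex"].astype(str) == "M").astype(float).to_numpy(),
            "bmi": records["bmi"].to_numpy(float),
            "diabetic": records["diabetic"].astype(float).to_numpy(),
            "meal_fasting": (records["meal_state"] == "fasting").astype(float).to_numpy(),
            "meal_postprandial": (records["meal_state"] == "postprandial").astype(float).to_numpy(),
            "meal_random": (records["meal_state"] == "random").astype(float).to_numpy(),
            "sleep": records["sleep"].astype(float).to_numpy(),
            "stress": records["stress"].astype(float).to_numpy(),
            "spo2": records["spo2"].to_numpy(float),
            "wrist_hair": records["wrist_hair"].astype(float).to_numpy(),
        },
        index=records.index,
    )
    return features


def build_branch(records: pd.DataFrame, branch: str,
                 adjustment: AdjustmentModel | None = None) -> IntegratedDataset:
    """Assemble one branch's (features, target) pair.

    ``raw`` and ``normalized`` regress against the individual reference
    values (mmol/L); ``framework`` first fits (or reuses) the adjustment
    model on the given records, applies it, and integrates the targets by
    interval averaging.
    """
    if branch not in BRANCHES:
        raise ConfigurationError(f"unknown branch {branch!r}; expected one of {BRANCHES}")
    if branch == "framework":
        model = adjustment or fit_adjustment_model(records)
        adjusted = apply_adjustment(records, model)
        integrated = integrate_targets(adjusted)
        features = encode_features(integrated, branch)
        return IntegratedDataset(
            features=features,
            target_mmol=integrated["target_mmol"],
            bin_lower=integrated["bin_lower"],
            branch=branch,
        )
    binned = assign_bins(records)
    features = encode_features(binned, branch)
    target = pd.Series(
        mgdl_to_mmol(binned["reference_mgdl"].to_numpy()),
        index=binned.index, name="target_mmol",
    )
    return IntegratedDataset(
        features=features, target_mmol=target,
        bin_lower=binned["bin_lower"], branch=branch,
    )
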