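"""Clinical-validation computations for glucose method comparison.

Implements the accuracy metrics (MAE, MSE, r2 about the reference mean),
the mg/dL error table, Bland–Altman limits of agreement, Clarke Error Grid
zone classification (canonical 1987 piecewise boundaries), and the paired
t-test between reference and predicted values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import MGDL_PER_MMOL, mmol_to_mgdl
from .errors import ConfigurationError

__all__ = [
    "MetricsReport",
    "compute_metrics",
    "error_table",
    "BlandAltmanSummary",
    "bland_altman",
    "ceg_zone",
    "ceg_zones",
    "CEGSummary",
    "ceg_summary",
    "TTestSummary",
    "paired_t_test",
    "plot_bland_altman",
    "plot_ceg",
]

CEG_ZONES = ("A", "B", "C", "D", "E")


def _paired(ref, pred, min_n=1):
    ref = np.asarray(ref, dtype=float).ravel()
    pred = np.asarray(pred, dtype=float).ravel()
    if ref.shape != pred.shape:
        raise ConfigurationError(
            f"length mismatch: {ref.size} reference vs {pred.size} predicted"
        )
    if ref.size < min_n:
        raise ConfigurationError(f"need at least {min_n} paired values, got {ref.size}")
    return ref, pred


@dataclass
class MetricsReport:
    """MAE, MSE and r2 with the sum-of-squares intermediates."""

    mae: float
    mse: float
    r2: float
    ss_res: float
    ss_tot: float
    n: int


def compute_metrics(ref, pred) -> MetricsReport:
    """MAE, MSE, and r2 = 1 - SS_res/SS_tot with SS_tot taken about the
    mean of the *reference* values (the standard convention)."""
    ref, pred = _paired(ref, pred, min_n=2)
    err = pred - ref
    mae = float(np.mean(np.abs(err)))
    mse = float(np.mean(err**2))
    ss_res = float(np.sum((ref - pred) ** 2))
    ss_tot = float(np.sum((ref - np.mean(ref)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    return MetricsReport(mae=mae, mse=mse, r2=r2, ss_res=ss_res,
                         ss_tot=ss_tot, n=ref.size)


def error_table(ref_mmol, pred_mmol, factor: float = MGDL_PER_MMOL) -> pd.DataFrame:
    """Per-sample signed error in mg/dL from mmol/L series.

    Columns: reference and prediction in both unit systems plus
    ``error_mgdl = pred - ref``; the summary MAE (mmol scale, matching the
    calibration metric) is stored in ``DataFrame.attrs['mae_mmol']``.
    """
    ref, pred = _paired(ref_mmol, pred_mmol)
    if np.any(ref <= 0) or np.any(pred <= 0):
        raise ConfigurationError("glucose values must be positive")
    ref_mgdl = mmol_to_mgdl(ref, factor=factor)
    pred_mgdl = mmol_to_mgdl(pred, factor=factor)
    table = pd.DataFrame(
        {
            "reference_mmol": ref,
            "predicted_mmol": pred,
            "reference_mgdl": ref_mgdl,
            "predicted_mgdl": pred_mgdl,
            "error_mgdl": pred_mgdl - ref_mgdl,
        }
    )
    table.attrs["mae_mmol"] = float(np.mean(np.abs(pred - ref)))
    table.attrs["mae_mgdl"] = float(np.mean(np.abs(pred_mgdl - ref_mgdl)))
    return table


@dataclass
class BlandAltmanSummary:
    """Bias and 1.96-SD limits of agreement of paired differences."""

    bias: float
    sd: float
    loa_lower: float
    loa_upper: float
    pct_within_loa: float
    n: int
    units: str = "mg/dL"


def bland_altman(ref, pred, units: str = "mg/dL") -> BlandAltmanSummary:
    """Differences d = pred - ref; bias = mean(d); SD with n-1 divisor;
    LOA = bias +/- 1.96 SD; percentage of differences inside the LOA."""
    ref, pred = _paired(ref, pred, min_n=2)
    d = pred - ref
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    lower, upper = bias - 1.96 * sd, bias + 1.96 * sd
    within = float(np.mean((d >= lower) & (d <= upper)) * 100.0)
    return BlandAltmanSummary(bias=bias, sd=sd, loa_lower=lower,
                              loa_upper=upper, pct_within_loa=within, n=d.size,
                              units=units)


def ceg_zone(ref: float, pred: float) -> str:
    """Clarke Error Grid zone of one (reference, predicted) pair in mg/dL.

    Canonical 1987 piecewise boundaries; the rule order (A, E, C, D, else B)
    resolves boundary ties. Zone A is clinically accurate, B benign,
    C overcorrection, D dangerous failure to detect, E erroneous treatment.
    """
    if ref <= 0 or pred <= 0:
        raise ConfigurationError("glucose values must be positive")
    if (ref <= 70 and pred <= 70) or abs(pred - ref) <= 0.2 * ref:
        return "A"
    if (ref >= 180 and pred <= 70) or (ref <= 70 and pred >= 180):
        return "E"
    if (70 <= ref <= 290 and pred >= ref + 110) or (
        130 <= ref <= 180 and pred <= (7.0 / 5.0) * ref - 182
    ):
        return "C"
    if (
        (ref >= 240 and 70 <= pred <= 180)
        or (ref <= 175.0 / 3.0 and 70 <= pred <= 180)
        or (175.0 / 3.0 <= ref <= 70 and pred >= (6.0 / 5.0) * ref)
    ):
        return "D"
    return "B"


def ceg_zones(ref, pred) -> np.ndarray:
    """Vectorized :func:`ceg_zone`."""
    ref, pred = _paired(ref, pred)
    return np.array([ceg_zone(r, p) for r, p in zip(ref, pred)])


@dataclass
class CEGSummary:
    """Zone label per point and the zone percentage breakdown."""

    zones: np.ndarray
    counts: dict
    percentages: dict
    n: int

    @property
    def clinically_acceptable_pct(self) -> float:
        """Share of points in zones A or B."""
        return self.percentages["A"] + self.percentages["B"]


def ceg_summary(ref, pred) -> CEGSummary:
    zones = ceg_zones(ref, pred)
    n = zones.size
    counts = {z: int(np.sum(zones == z)) for z in CEG_ZONES}
    pct = {z: 100.0 * counts[z] / n for z in CEG_ZONES}
    return CEGSummary(zones=zones, counts=counts, percentages=pct, n=n)


@dataclass
class TTestSummary:
    """Paired t-test of H0: mean difference = 0."""

    t_calculated: float
    df: int
    p_value: float
    t_critical: float
    alpha: float
    tails: str
    decision: str            # "accept H0" iff |t| < t_critical
    zero_variance: bool = False


def paired_t_test(ref, pred, alpha: float = 0.05, tails: str = "two") -> TTestSummary:
    """t = mean(d) / (sd(d)/sqrt(n)) with d = pred - ref and df = n-1.

    ``tails`` is "two" (default) or "one"; the critical value is taken from
    the t distribution at the configured alpha. Zero-variance differences
    with nonzero mean give an infinite t, reported as a rejection with the
    ``zero_variance`` flag set.
    """
    ref, pred = _paired(ref, pred, min_n=2)
    if tails not in ("one", "two"):
        raise ConfigurationError("tails must be 'one' or 'two'")
    d = pred - ref
    n = d.size
    df = n - 1
    mean_d = float(np.mean(d))
    sd_d = float(np.std(d, ddof=1))
    quantile = 1 - alpha / (2 if tails == "two" else 1)
    t_crit = float(stats.t.ppf(quantile, df))
    if sd_d == 0:
        if mean_d == 0:
            return TTestSummary(0.0, df, 1.0, t_crit, alpha, tails,
                                "accept H0", zero_variance=True)
        t = float(np.inf) if mean_d > 0 else float(-np.inf)
        return TTestSummary(t, df, 0.0, t_crit, alpha, tails,
                            "reject H0", zero_variance=True)
    t = mean_d / (sd_d / np.sqrt(n))
    if tails == "two":
        p = 2 * float(stats.t.sf(abs(t), df))
    else:
        p = float(stats.t.sf(abs(t), df))
    decision = "accept H0" if abs(t) < t_crit else "reject H0"
    return TTestSummary(float(t), df, p, t_crit, alpha, tails, decision)


# ---------------------------------------------------------------------------
# plots


def plot_bland_altman(summary: BlandAltmanSummary, ref, pred, path) -> None:
    """Mean-vs-difference plot with bias and LOA lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ref, pred = _paired(ref, pred)
    mean = (ref + pred) / 2.0
    diff = pred - ref
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(mean, diff, s=12, alpha=0.6)
    ax.axhline(summary.bias, color="k", label=f"bias {summary.bias:.3f}")
    for loa, lab in ((summary.loa_upper, "+1.96 SD"), (summary.loa_lower, "-1.96 SD")):
        ax.axhline(loa, color="r", linestyle="--", label=f"{lab} {loa:.3f}")
    ax.set_xlabel(f"mean of reference and predicted ({summary.units})")
    ax.set_ylabel(f"predicted - reference ({summary.units})")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_ceg(ref, pred, path, limit: float = 550.0) -> None:
    """Scatter on the Clarke grid with the zone boundary segments."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ref, pred = _paired(ref, pred)
    fig, ax = plt.subplots(figsize=(5.5, 5.5))
    ax.scatter(ref, pred, s=12, alpha=0.6, zorder=3)
    L = limit
    segs = [  # canonical zone boundary segments
        ((0, L), (0, L)),
        ((0, 175 / 3.0), (70, 70)),
        ((175 / 3.0, 400 / 1.2), (70, 400)),
        ((70, 70), (84, 0)),
        ((70, 290), (180, 400)),
        ((70, 70), (0, 56)),
        ((70, L), (56, 320)),
        ((130, 180), (0, 70)),
        ((180, 180), (70, 0)),
        ((180, L), (70, 70)),
        ((240, 240), (70, 180)),
        ((240, L), (180, 180)),
        ((0, 70), (180, 180)),
        ((0, 58.3), (70, 70)),
    ]
    for (x0, x1), (y0, y1) in segs:
        ax.plot([x0, x1], [y0, y1], "k-", linewidth=0.7, zorder=2)
    for x, y, z in [(30, 20, "A"), (360, 320, "A"), (280, 420, "B"), (420, 250, "B"),
                    (160, 420, "C"), (160, 15, "C"), (30, 130, "D"), (420, 130, "D"),
                    (30, 420, "E"), (420, 30, "E")]:
        ax.text(x, y, z, fontsize=11, ha="center")
    ax.set_xlim(0, L)
    ax.set_ylim(0, L)
    ax.set_xlabel("reference glucose (mg/dL)")
    ax.set_ylabel("predicted glucose (mg/dL)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
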