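"""End-to-end orchestration: simulate -> preprocess -> train -> evaluate.

A single YAML config drives every stage; all randomness is seeded, so a rerun
with the same config reproduces every artifact. Each report bundle carries
the config hash and seeds for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dataio, evaluate, preprocess
from .errors import ConfigurationError
from .models import RidgeSpec, SplitConfig, run_comparison
from .simulate import SITES, BeerLambertParams, SynthConfig, generate_dataset

__all__ = ["EvalConfig", "PipelineConfig", "load_config", "run_pipeline"]


def _from_mapping(cls, data: dict, context: str):
    """Build a dataclass from a mapping, rejecting unknown keys."""
    if data is None:
        return cls()
    if not isinstance(data, dict):
        raise ConfigurationError(f"{context} must be a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigurationError(f"unknown keys in {context}: {sorted(unknown)}")
    coerced = dict(data)
    if "glucose_range" in coerced and coerced["glucose_range"] is not None:
        coerced["glucose_range"] = tuple(coerced["glucose_range"])
    return cls(**coerced)


@dataclass(frozen=True)
class EvalConfig:
    alpha: float = 0.05
    tails: str = "two"
    units: str = "mg/dL"     # units of the error table / Bland-Altman

    def __post_init__(self):
        if self.tails not in ("one", "two"):
            raise ConfigurationError("evaluation tails must be 'one' or 'two'")
        if self.units not in ("mg/dL", "mmol/L"):
            raise ConfigurationError("evaluation units must be 'mg/dL' or 'mmol/L'")


@dataclass
class PipelineConfig:
    synth: SynthConfig = field(default_factory=SynthConfig)
    optics: BeerLambertParams = field(default_factory=BeerLambertParams)
    ridge: RidgeSpec = field(default_factory=RidgeSpec)
    split: SplitConfig = field(default_factory=SplitConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)
    sites: tuple = tuple(SITES)
    branches: tuple = tuple(preprocess.BRANCHES)
    models: list | None = None           # None -> the full twelve-model roster

    def __post_init__(self):
        for site in self.sites:
            if site not in SITES:
                raise ConfigurationError(f"unknown site {site!r}")
        for branch in self.branches:
            if branch not in preprocess.BRANCHES:
                raise ConfigurationError(f"unknown branch {branch!r}")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = data or {}
        if not isinstance(data, dict):
            raise ConfigurationError("pipeline config must be a mapping")
        known = {"synth", "optics", "ridge", "split", "evaluation",
                 "sites", "branches", "models"}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown top-level config keys: {sorted(unknown)}")
        return cls(
            synth=_from_mapping(SynthConfig, data.get("synth"), "synth"),
            optics=_from_mapping(BeerLambertParams, data.get("optics"), "optics"),
            ridge=_from_mapping(RidgeSpec, data.get("ridge"), "ridge"),
            split=_from_mapping(SplitConfig, data.get("split"), "split"),
            evaluation=_from_mapping(EvalConfig, data.get("evaluation"), "evaluation"),
            sites=tuple(data.get("sites", SITES)),
            branches=tuple(data.get("branches", preprocess.BRANCHES)),
            models=data.get("models"),
        )

    def to_dict(self) -> dict:
        return {
            "synth": dataclasses.asdict(self.synth),
            "optics": dataclasses.asdict(self.optics),
            "ridge": dataclasses.asdict(self.ridge),
            "split": dataclasses.asdict(self.split),
            "evaluation": dataclasses.asdict(self.evaluation),
            "sites": list(self.sites),
            "branches": list(self.branches),
            "models": self.models,
        }

    def hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load and validate a YAML pipeline config; None gives the defaults."""
    if path is None:
        return PipelineConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return PipelineConfig.from_dict(data)


def _branch_xy(records: pd.DataFrame, branch: str):
    ds = preprocess.build_branch(records, branch)
    return ds.features.to_numpy(float), ds.target_mmol.to_numpy(float)


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute all stages and write the report bundle under ``out_dir``.

    Returns a summary dict (per-site best models, framework ridge metrics,
    clinical validation summaries). Stage failures abort with the stage name
    and cause.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_hash": cfg.hash(), "seed": cfg.synth.seed, "sites": {}}

    stage = "simulate"
    try:
        samples, truth = generate_dataset(cfg.synth, cfg.optics, out_dir=out)

        comparison_tables = []
        for site in cfg.sites:
            stage = f"preprocess[{site}]"
            records = samples[samples["site"] == site].reset_index(drop=True)
            adj_model = preprocess.fit_adjustment_model(records)
            adj_model.to_frame().to_csv(out / f"adjustment_model_{site}.csv",
                                        index=False)
            branches = {b: _branch_xy(records, b) for b in cfg.branches}

            stage = f"train[{site}]"
            report = run_comparison(
                branches, models=cfg.models, split=cfg.split,
                ridge_spec=cfg.ridge,
            )
            table = report.table.copy()
            table.insert(0, "site", site)
            comparison_tables.append(table)

            stage = f"evaluate[{site}]"
            site_summary = {"best": {}}
            for branch in cfg.branches:
                best = report.best(branch)
                site_summary["best"][branch] = {
                    "model": best["model"], "r2_score": float(best["r2_score"]),
                    "MAE": float(best["MAE"]), "MSE": float(best["MSE"]),
                }
            site_summary.update(
                _clinical_bundle(report, site, cfg, out)
            )
            summary["sites"][site] = site_summary

        pd.concat(comparison_tables, ignore_index=True).to_csv(
            out / "comparison.csv", index=False
        )
        stage = "report"
        _write_report(summary, cfg, out)
    except Exception as exc:
        exc.add_note(f"pipeline stage {stage!r} failed")
        raise
    return summary


def _clinical_bundle(report, site: str, cfg: PipelineConfig, out: Path) -> dict:
    """Error analysis, Bland-Altman, CEG and paired t-test on the framework
    branch's ridge predictions (the calibrated device configuration)."""
    branch = "framework" if "framework" in cfg.branches else cfg.branches[0]
    key = (branch, "RR") if (branch, "RR") in report.fits else next(
        k for k in report.fits if k[0] == branch
    )
    fit = report.fits[key]
    ref_mmol, pred_mmol = fit.y_test, fit.predictions
    pred_mmol = np.clip(pred_mmol, 1e-6, None)  # guard for unit conversion

    metrics = evaluate.compute_metrics(ref_mmol, pred_mmol)
    table = evaluate.error_table(ref_mmol, pred_mmol)
    table.round(6).to_csv(out / f"error_table_{site}.csv", index=False)

    if cfg.evaluation.units == "mg/dL":
        ref_u = dataio.mmol_to_mgdl(ref_mmol)
        pred_u = dataio.mmol_to_mgdl(pred_mmol)
    else:
        ref_u, pred_u = ref_mmol, pred_mmol
    ba = evaluate.bland_altman(ref_u, pred_u, units=cfg.evaluation.units)
    evaluate.plot_bland_altman(ba, ref_u, pred_u, out / f"bland_altman_{site}.png")

    ref_mgdl = dataio.mmol_to_mgdl(ref_mmol)
    pred_mgdl = dataio.mmol_to_mgdl(pred_mmol)
    ceg = evaluate.ceg_summary(ref_mgdl, pred_mgdl)
    evaluate.plot_ceg(ref_mgdl, pred_mgdl, out / f"ceg_{site}.png")

    tt = evaluate.paired_t_test(ref_u, pred_u, alpha=cfg.evaluation.alpha,
                                tails=cfg.evaluation.tails)
    tt_dict = dataclasses.asdict(tt)
    with open(out / f"ttest_{site}.json", "w", encoding="utf-8") as fh:
        json.dump(tt_dict, fh, indent=2)

    return {
        "validated_branch": branch,
        "validated_model": key[1],
        "metrics": {"MAE": metrics.mae, "MSE": metrics.mse, "r2_score": metrics.r2},
        "bland_altman": dataclasses.asdict(ba),
        "ceg_percentages": ceg.percentages,
        "t_test": tt_dict,
    }


def _write_report(summary: dict, cfg: PipelineConfig, out: Path) -> None:
    lines = [
        "# NIR glucose pipeline report",
        "",
        f"- config hash: `{summary['config_hash']}`",
        f"- simulation seed: {summary['seed']}",
        f"- split seed: {cfg.split.seed}",
        "",
    ]
    for site, s in summary["sites"].items():
        lines += [f"## {site.capitalize()} sensor", ""]
        lines += ["| branch | best model | MAE | MSE | r2_score |",
                  "|---|---|---|---|---|"]
        for branch, b in s["best"].items():
            lines.append(
                f"| {branch} | {b['model']} | {b['MAE']:.4f} | "
                f"{b['MSE']:.4f} | {b['r2_score']:.4f} |"
            )
        m = s["metrics"]
        ba = s["bland_altman"]
        tt = s["t_test"]
        lines += [
            "",
            f"Clinical validation of the {s['validated_branch']} branch "
            f"({s['validated_model']}), held-out split:",
            "",
            f"- MAE {m['MAE']:.4f} mmol/L, MSE {m['MSE']:.4f}, "
            f"r2 {m['r2_score']:.4f}",
            f"- Bland-Altman bias {ba['bias']:.3f} {ba['units']}, "
            f"LOA [{ba['loa_lower']:.3f}, {ba['loa_upper']:.3f}], "
            f"{ba['pct_within_loa']:.1f}% within LOA",
            f"- CEG zone A {s['ceg_percentages']['A']:.1f}%, "
            f"zone B {s['ceg_percentages']['B']:.1f}%",
            f"- paired t-test: t={tt['t_calculated']:.3f}, df={tt['df']}, "
            f"p={tt['p_value']:.3g}, t_critical={tt['t_critical']:.3f} "
            f"({tt['tails']}-tailed) -> {tt['decision']}",
            "",
            f"![Bland-Altman {site}](bland_altman_{site}.png)",
            f"![CEG {site}](ceg_{site}.png)",
            "",
        ]
    (out / "report.md").write_text("\n".join(lines), encoding="utf-8")
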