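"""End-to-end orchestration: simulate -> code exposures -> exclude -> fit ->
DFY -> pool -> sensitivity, with manifests for reproducibility.

A single structured config drives every stage; sensitivity analyses (21-unit
threshold, 8 g units, non-smoker restriction, SES strata, composite endpoint)
are config deltas, not separate code paths.  Every run directory carries a
manifest (seed, config hash, stage timings, row counts) so each numeric
output is traceable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .competing import aalen_johansen, composite_dfy
from .dfy import (DEFAULT_REFERENCE, DFYConfig, estimate_dfy, estimates_frame,
                  run_exclusions)
from .exposure import MISSING, CodingConfig, add_categories
from .meta import compare_stages, one_stage, two_stage
from .model import ModelConfig
from .simulate import default_consortium_specs, generate_consortium

log = logging.getLogger(__name__)

GROUPING_COLUMN = {3: "cat3", 5: "cat5", 6: "cat6", 8: "cat8"}


@dataclass
class RunConfig:
    """One pipeline run; sensitivity analyses are deltas of this object."""

    input_path: str | None = None  # None -> simulate the default consortium
    out_dir: str = "runs/default"
    grouping: int = 6
    sex_handling: str = "stratified"  # "stratified" | "combined"
    coding: CodingConfig = field(default_factory=CodingConfig)
    knot_candidates: tuple[int, ...] = (0, 1, 2)
    n_boot: int = 1000
    grid_step: float = 0.05
    death_handling: str = "censor"
    pooling: bool = True
    sensitivity: bool = True
    nonsmokers_only: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.grouping not in GROUPING_COLUMN:
            raise ValueError("grouping must be one of 3, 5, 6, 8")
        if self.grouping == 8:
            # small 8-level cells: men and women analysed together, sex adjusted
            self.sex_handling = "combined"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "coding" in raw:
            raw["coding"] = CodingConfig(**raw["coding"])
        if "knot_candidates" in raw:
            raw["knot_candidates"] = tuple(raw["knot_candidates"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _model_config(cfg: RunConfig, covariates: tuple[str, ...] = ()) -> ModelConfig:
    return ModelConfig(
        category_column=GROUPING_COLUMN[cfg.grouping],
        knot_candidates=cfg.knot_candidates,
        covariate_columns=covariates,
    )


def _dfy_config(cfg: RunConfig) -> DFYConfig:
    return DFYConfig(
        grid_step=cfg.grid_step,
        n_boot=cfg.n_boot,
        seed=cfg.seed,
        death_handling=cfg.death_handling,
    )


def load_or_simulate(cfg: RunConfig, out: Path) -> pd.DataFrame:
    if cfg.input_path:
        return pd.read_csv(cfg.input_path)
    specs = default_consortium_specs()
    data, world = generate_consortium(specs, cfg.seed)
    (out / "trueworld.json").write_text(world.to_json())
    return data


def prepare(data: pd.DataFrame, cfg: RunConfig, out: Path) -> pd.DataFrame:
    """Exposure coding, exclusion cascade and configured filters."""
    coded = add_categories(data, cfg.coding)
    analytic, report = run_exclusions(coded)
    col = GROUPING_COLUMN[cfg.grouping]
    n0 = len(analytic)
    analytic = analytic[analytic[col].astype(str) != MISSING].reset_index(drop=True)
    report["n_unclassified"] = n0 - len(analytic)
    if cfg.nonsmokers_only:
        analytic = analytic[analytic["smoker"] == 0].reset_index(drop=True)
    report["n_final"] = len(analytic)
    (out / "exclusions.json").write_text(json.dumps(report, indent=2))
    analytic.to_csv(out / "analytic.csv", index=False)
    return analytic


def _fit_summary(fit_) -> dict:
    return {
        "categories": list(fit_.categories),
        "knots": {
            k: {"boundary": list(v.boundary), "internal": list(v.internal)}
            for k, v in fit_.knots.items()
        },
        "gamma": {k: [float(v) for v in fit_.raw_gamma(k)] for k in fit_.gamma},
        "beta": {n: float(b) for n, b in zip(fit_.covariate_names, fit_.beta)},
        "loglik": fit_.loglik,
        "aic": fit_.aic,
        "n_params": fit_.n_params,
        "n_subjects": fit_.n_subjects,
        "converged": fit_.converged,
        "message": fit_.message,
    }


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all enabled stages into ``cfg.out_dir``; idempotent given seed."""
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "stages": {},
    }

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception:
            manifest["stages"][name] = {"status": "failed"}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
            log.exception("stage %s failed; partial outputs retained in %s", name, out)
            raise
        manifest["stages"][name] = {
            "status": "ok",
            "seconds": round(time.perf_counter() - t0, 3),
        }
        return result

    data = stage("simulate_or_load", lambda: load_or_simulate(cfg, out))
    manifest["stages"]["simulate_or_load"]["n"] = len(data)
    analytic = stage("prepare", lambda: prepare(data, cfg, out))
    manifest["stages"]["prepare"]["n"] = len(analytic)

    col = GROUPING_COLUMN[cfg.grouping]
    reference = DEFAULT_REFERENCE[col]
    dfy_cfg = _dfy_config(cfg)

    def dfy_stage():
        frames = []
        fits = {}
        if cfg.sex_handling == "stratified":
            groups = [(sx, analytic[analytic["sex"] == sx]) for sx in ("male", "female")]
        else:
            aug = analytic.copy()
            aug["sex_male"] = (aug["sex"] == "male").astype(float)
            groups = [("combined", aug)]
        for label, chunk in groups:
            covs = ("sex_male",) if label == "combined" else ()
            fit_, ests = estimate_dfy(
                chunk.reset_index(drop=True), _model_config(cfg, covs), dfy_cfg, reference
            )
            fits[label] = _fit_summary(fit_)
            frames.append(estimates_frame(ests, sex=label, grouping=cfg.grouping))
        (out / "fits.json").write_text(json.dumps(fits, indent=2))
        table = pd.concat(frames, ignore_index=True)
        table.to_csv(out / "dfy.csv", index=False)
        return table

    stage("dfy", dfy_stage)

    if cfg.pooling:
        def pooling_stage():
            mc = _model_config(cfg)
            ref3 = DEFAULT_REFERENCE["cat3"]
            # per-cohort first-stage fits cap the spline at 1 internal knot:
            # cohort-level curves only feed pooled differences, and richer
            # splines make per-cohort bootstrap SEs fragile
            mc3 = replace(mc, category_column="cat3",
                          knot_candidates=tuple(k for k in cfg.knot_candidates if k <= 1) or (0, 1))
            meta = two_stage(analytic, mc3, replace(dfy_cfg, n_boot=0), ref3,
                             n_boot=min(cfg.n_boot, 50))
            rows = [
                {"category": c, "pooled": m.pooled, "ci_low": m.ci_low,
                 "ci_high": m.ci_high, "tau2": m.tau2, "Q": m.Q, "i2": m.i2,
                 "p_q": m.p_q, "k": m.k}
                for c, m in meta.items()
            ]
            pd.DataFrame(rows).to_csv(out / "meta.csv", index=False)
            ests, table = one_stage(analytic, mc3, replace(dfy_cfg, n_boot=min(cfg.n_boot, 200)), ref3)
            table.to_csv(out / "one_stage.csv", index=False)
            if meta:
                compare_stages(meta, ests).to_csv(out / "stage_comparison.csv", index=False)
        stage("pooling", pooling_stage)

    if cfg.sensitivity:
        def sensitivity_stage():
            _, ests = composite_dfy(
                analytic, _model_config(cfg), replace(dfy_cfg, n_boot=0), reference
            )
            estimates_frame(ests, mode="composite").to_csv(
                out / "sensitivity_composite.csv", index=False
            )
            curves = []
            for cat in sorted(analytic[col].astype(str).unique()):
                cif = aalen_johansen(analytic, cat, col)
                curves.append(pd.DataFrame({
                    "category": cat, "age": cif.ages,
                    "cif_disease": cif.cif_disease, "cif_death": cif.cif_death,
                    "at_risk": cif.at_risk,
                }))
            pd.concat(curves, ignore_index=True).to_csv(out / "sensitivity_cif.csv", index=False)
        stage("sensitivity", sensitivity_stage)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def stratified_runs(cfg: RunConfig, stratum_column: str = "ses") -> dict[str, Path]:
    """Independent pipeline runs per stratum level, plus a combined summary."""
    base = Path(cfg.out_dir)
    base.mkdir(parents=True, exist_ok=True)
    data_cfg = replace(cfg, pooling=False, sensitivity=False)
    probe = load_or_simulate(cfg, base)
    levels = sorted(probe[stratum_column].astype(str).unique())
    out: dict[str, Path] = {}
    frames = []
    for lv in levels:
        sub = replace(data_cfg, out_dir=str(base / f"{stratum_column}={lv}"))
        path = Path(sub.out_dir)
        path.mkdir(parents=True, exist_ok=True)
        chunk = probe[probe[stratum_column].astype(str) == lv]
        if len(chunk) == 0:
            log.warning("empty stratum %s=%s skipped", stratum_column, lv)
            continue
        coded = prepare(chunk.reset_index(drop=True), sub, path)
        col = GROUPING_COLUMN[sub.grouping]
        fit_, ests = estimate_dfy(
            coded, _model_config(sub), _dfy_config(sub), DEFAULT_REFERENCE[col]
        )
        tab = estimates_frame(ests, stratum=lv)
        tab.to_csv(path / "dfy.csv", index=False)
        frames.append(tab)
        out[lv] = path
    if frames:
        pd.concat(frames, ignore_index=True).to_csv(base / "strata_summary.csv", index=False)
    return out


def report_tables(run_dir: str | Path) -> str:
    """Plain-text category x sex table of disease-free years from a run."""
    run_dir = Path(run_dir)
    path = run_dir / "dfy.csv"
    if not path.exists():
        raise FileNotFoundError(f"missing dfy stage output in {run_dir}")
    table = pd.read_csv(path)
    lines = ["Disease-free years between ages 40 and 75 (95% CI)", "=" * 58]
    for sex, chunk in table.groupby("sex"):
        lines.append(f"\n{sex}")
        for _, r in chunk.iterrows():
            ci = (f" ({r.ci_low:.1f}-{r.ci_high:.1f})"
                  if np.isfinite(r.ci_low) else "")
            diff = (f"  diff {r['diff']:+.2f}" if np.isfinite(r["diff"]) else "")
            lines.append(f"  {r.category:<22}{r.years:6.1f}{ci}{diff}")
    meta_path = run_dir / "meta.csv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path)
        lines.append("\nHeterogeneity (two-stage pooling, 3-level grouping)")
        for _, r in meta.iterrows():
            lines.append(
                f"  {r.category:<22}pooled {r.pooled:+.2f} "
                f"({r.ci_low:+.2f} to {r.ci_high:+.2f})  I2={r.i2:.1f}%  k={int(r.k)}"
            )
    text = "\n".join(lines)
    (run_dir / "report.txt").write_text(text)
    table.to_csv(run_dir / "report.csv", index=False)
    return text
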