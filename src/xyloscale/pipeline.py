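"""End-to-end orchestration: data -> metrics -> balanced fits -> collapse.

Produces, in order, the organ summary table, bin-balanced SMA/OLS scaling
fits (with curvature and AIC model comparison) for each configured
relationship, the thickness-to-span decay fit, and the collapse-limit
profile with per-conduit safety assessment. A machine-readable manifest
records the seed, a config hash, package and library versions, and per-stage
status, so a run is reproducible from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, anatomy, collapse, resample, scaling, synthetic

__all__ = ["PipelineConfig", "ValidationReport", "run_pipeline", "validate_input"]

log = logging.getLogger("xyloscale")

#: the relationships the analysis estimates by default
DEFAULT_FIT_SPECS = {
    # conduit diameter vs path length, shoot organs, binned on L
    "d_vs_L_shoots": {"organs": synthetic.SHOOT_ORGANS, "bin_var": "L",
                      "x": "L_m", "y": "d_um"},
    # conduit diameter vs external stem diameter, binned on D
    "d_vs_D_stems": {"organs": synthetic.STEM_ORGANS, "bin_var": "D",
                     "x": "D_mm", "y": "d_um"},
    # conduit diameter vs external root diameter, binned on D
    "d_vs_D_roots": {"organs": synthetic.ROOT_ORGANS, "bin_var": "D",
                     "x": "D_mm", "y": "d_um"},
}


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of a full analysis run."""

    input_path: str | None = None          # CSV; None -> generate
    generator: synthetic.GeneratorConfig = field(
        default_factory=synthetic.GeneratorConfig)
    fit_names: tuple[str, ...] = tuple(DEFAULT_FIT_SPECS)
    mode: str = "bootstrap"
    n_iterations: int | None = None        # default: 1000 bootstrap / 10000 subsample
    min_count: int = 100
    max_bins: int = 30
    stability_tol: float = 1e-3
    collapse: collapse.CollapseConfig = field(
        default_factory=collapse.CollapseConfig)
    outdir: str = "xyloscale_out"
    seed: int = 0
    log_level: str = "INFO"

    @property
    def iterations(self) -> int:
        if self.n_iterations is not None:
            return self.n_iterations
        return 1000 if self.mode == "bootstrap" else 10000

    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(asdict(self)), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass(frozen=True)
class ValidationReport:
    path: str
    n_rows: int
    findings: list

    @property
    def ok(self) -> bool:
        return not self.findings


def validate_input(path) -> ValidationReport:
    """Row-level validation of a conduit CSV without loading it for analysis."""
    df = pd.read_csv(path)
    canon = {c.lower(): c for c in synthetic.COLUMNS}
    df = df.rename(columns={c: canon[c.lower()] for c in df.columns
                            if c.lower() in canon})
    findings = synthetic.validate_table(df)
    return ValidationReport(str(path), len(df), findings)


def _fit_stage(df, name, spec, cfg, seed):
    sub = df[df["organ"].isin(spec["organs"])]
    sub = sub.dropna(subset=[spec["x"]])
    fs = resample.FitSpec(x=spec["x"], y=spec["y"])
    outcome = resample.iterate_fit(
        sub.reset_index(drop=True), spec["bin_var"], cfg.mode, fs,
        cfg.iterations, seed, stability_tol=cfg.stability_tol,
        min_count=cfg.min_count, max_bins=cfg.max_bins)
    # curvature + model comparison on one balanced replicate
    balanced = (resample.bootstrap_balance if cfg.mode == "bootstrap"
                else resample.subsample_balance)(
        sub.reset_index(drop=True), outcome.plan, seed)
    x = balanced[spec["x"]].to_numpy(float)
    y = balanced[spec["y"]].to_numpy(float)
    quad = scaling.quadratic_curvature(np.log10(x), np.log10(y))
    mc = scaling.model_compare(x, y)
    ols = scaling.ols_fit(x, y, x_var=spec["x"], y_var=spec["y"])
    return {
        "name": name,
        "resample": outcome.to_dict(),
        "ols_balanced": ols.to_dict(),
        "quadratic_coefficient": {"coef": quad.coef, "ci": list(quad.ci),
                                  "p": quad.p},
        "model_comparison": {"winner": mc.winner, "aic_winner": mc.aic_winner,
                             "table": _jsonable(mc.table)},
    }, outcome


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; halt on failure with stage name, keep partial output."""
    cfg = config
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg.log_level)
    manifest = {
        "package": "xyloscale", "version": __version__,
        "seed": cfg.seed, "config_hash": cfg.config_hash(),
        "config": _jsonable(asdict(cfg)),
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "stages": {},
    }
    t_all = time.time()

    def stage(name, fn):
        t0 = time.time()
        log.info("stage %s ...", name)
        try:
            result = fn()
        except Exception as exc:
            manifest["stages"][name] = {"status": "FAILED", "error": str(exc)}
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
            (outdir / "FAILED").write_text(f"{name}: {exc}\n")
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {"status": "ok",
                                    "seconds": round(time.time() - t0, 3)}
        return result

    def load():
        if cfg.input_path is not None:
            rep = validate_input(cfg.input_path)
            if not rep.ok:
                raise synthetic.TableValidationError(rep.findings)
            return synthetic.read_table(cfg.input_path)
        gen = replace(cfg.generator, seed=cfg.seed)
        df = synthetic.generate_dataset(gen)
        synthetic.write_table(df, outdir / "data.csv")
        return df

    df = stage("load_data", load)
    manifest["n_records"] = int(len(df))

    df = stage("metrics", lambda: anatomy.conduit_metrics(df))
    stage("organ_summary", lambda: anatomy.organ_summary(df).to_csv(
        outdir / "organ_summary.csv", index=False))

    fits = {}
    alpha = cfg.collapse.alpha
    ss = np.random.SeedSequence(cfg.seed).spawn(len(cfg.fit_names) + 1)
    for i, name in enumerate(cfg.fit_names):
        spec = DEFAULT_FIT_SPECS[name]
        result, outcome = stage(f"fit_{name}",
                                lambda s=spec, n=name, sd=ss[i]: _fit_stage(
                                    df, n, s, cfg, sd))
        fits[name] = result
        if name == "d_vs_L_shoots":
            alpha = outcome.aggregate_slope
    (outdir / "fits.json").write_text(json.dumps(_jsonable(fits), indent=2))

    def tb2_stage():
        shoots = df[df["organ"].isin(synthetic.SHOOT_ORGANS)]
        fit = scaling.tb2_decay_fit(shoots["tb2"], shoots["L_rel"])
        out = fit.to_dict()
        out["decay_rate"] = -fit.slope * np.log(10.0)
        (outdir / "tb2_decay.json").write_text(json.dumps(out, indent=2))
        return out

    tb2 = stage("tb2_decay", tb2_stage)

    def collapse_stage():
        ccfg = replace(cfg.collapse, alpha=float(alpha))
        prof = collapse.simulate_profile(ccfg)
        prof.to_frame().iloc[::max(1, prof.n_segments // 2000)].to_csv(
            outdir / "collapse_profile.csv", index=False)
        assessment = collapse.assess_by_tree(df, ccfg)
        (outdir / "safety_summary.json").write_text(
            json.dumps(_jsonable(assessment.to_dict()), indent=2))
        return assessment.to_dict()

    safety = stage("collapse", collapse_stage)

    manifest["results"] = {
        "fits": {k: v["resample"]["aggregate_slope"] for k, v in fits.items()},
        "tb2_decay_rate": tb2["decay_rate"],
        "fraction_safe": safety["fraction_safe"],
        "median_safety_factor": safety["median_safety_factor"],
    }
    manifest["seconds_total"] = round(time.time() - t_all, 3)
    (outdir / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=2))
    return manifest
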