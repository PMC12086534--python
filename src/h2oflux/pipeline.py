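"""End-to-end orchestration: tables in, tidy per-sample results out.

The analysis chain per sample x analyte: water-enrichment calibration gives
p; raw m0-mK areas are natural-abundance corrected (empirical baseline matrix
when unlabeled samples exist, else theoretical from the ion formula); the
corrected MID yields the analyte enrichment; Eq.-1 fractional synthesis
f = enrichment / (p * n) * 100 follows, by default divided by the binomial
truncation-bias factor so the mK cutoff does not bias f low (the uncorrected
value is kept alongside).  When internal-standard curves are provided,
concentrations and absolute newly synthesized amounts are added.

Everything is deterministic given its inputs, and every row carries
provenance: correction mode, p source, solve residual, flags.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import fit_calibration, quantify
from .correction import NaturalAbundanceCorrector
from .isotopes import DEFAULT_K
from .labeling import (
    analyte_enrichment,
    estimate_n,
    fractional_synthesis,
    new_pool_amount,
    truncation_bias_factor,
)
from .isotopes import MID
from .panel import default_panel, load_panel

_RESULT_COLUMNS = ("sample_id", "analyte_id", "enrichment", "p", "p_source",
                   "n", "f_percent", "f_uncorrected_percent", "residual", "flags")


@dataclass
class RunConfig:
    """File-based run description (the YAML the CLI consumes)."""

    areas: str
    water: str
    baseline: str | None = None
    metadata: str | None = None
    curve_standards: str | None = None
    panel: str | None = None
    correction: str = "auto"  # auto | empirical | theoretical
    K: int = DEFAULT_K
    p_source: str = "per-animal"  # per-animal | cohort-mean
    solver: str = "nnls"
    tol: float = 1e-8
    truncation_correction: bool = True
    outdir: str | None = None

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.p_source not in ("per-animal", "cohort-mean"):
            raise ValueError(f"unknown p_source {self.p_source!r}")
        if self.correction not in ("auto", "empirical", "theoretical"):
            raise ValueError(f"unknown correction mode {self.correction!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


@dataclass
class AnalysisResult:
    """Tidy per-sample results plus the QC/audit report."""

    results: pd.DataFrame
    qc: dict
    paths: dict = field(default_factory=dict)


def _water_enrichment_table(water_df: pd.DataFrame) -> tuple[dict, float, dict]:
    """Per-sample p from the standards' line; returns (p by sample, cohort mean, curve qc)."""
    std = water_df[water_df["kind"] == "standard"]
    if len(std) < 2:
        raise ValueError("need >= 2 water-enrichment standards")
    curve = fit_calibration(x=std["known_fraction"].to_numpy(),
                            y=std["ratio"].to_numpy())
    samples = water_df[water_df["kind"] == "sample"]
    p_by_sample = {
        str(row.sample_id): float((row.ratio - curve.intercept) / curve.slope)
        for row in samples.itertuples()
    }
    if not p_by_sample:
        raise ValueError("no water-enrichment sample measurements")
    cohort_mean = float(np.mean(list(p_by_sample.values())))
    qc = {"slope": curve.slope, "intercept": curve.intercept, "r": curve.r,
          "cohort_mean_p": cohort_mean, "n_standards": int(len(std))}
    return p_by_sample, cohort_mean, qc


def analyze_tables(
    areas: pd.DataFrame,
    water: pd.DataFrame,
    baseline: pd.DataFrame | None = None,
    metadata: pd.DataFrame | None = None,
    curve_standards: pd.DataFrame | None = None,
    panel: dict | None = None,
    correction: str = "auto",
    K: int = DEFAULT_K,
    p_source: str = "per-animal",
    solver: str = "nnls",
    tol: float = 1e-8,
    truncation_correction: bool = True,
) -> AnalysisResult:
    """Run the full tracer analysis on in-memory tables.

    ``areas`` needs columns sample_id, analyte_id, area_m0..area_mK (area_is
    optional, required for concentrations); extra columns pass through to the
    results.
    """
    if panel is None:
        panel = default_panel()
    area_cols = [f"area_m{i}" for i in range(K + 1)]
    missing_cols = [c for c in ("sample_id", "analyte_id", *area_cols)
                    if c not in areas.columns]
    if missing_cols:
        raise ValueError(f"areas table missing columns: {missing_cols}")
    analytes = list(dict.fromkeys(areas["analyte_id"]))
    undefined = [a for a in analytes if a not in panel]
    if undefined:
        raise ValueError(f"no analyte definition for: {undefined}")

    p_by_sample, cohort_p, water_qc = _water_enrichment_table(water)

    # one corrector per analyte
    correctors: dict = {}
    corr_qc: dict = {}
    for analyte in analytes:
        base_rows = None
        if baseline is not None and len(baseline):
            sub = baseline[baseline["analyte_id"] == analyte]
            if len(sub):
                base_rows = sub[area_cols].to_numpy(dtype=float)
        corrector = NaturalAbundanceCorrector(
            formula=panel[analyte].formula, K=K, mode=correction,
            solver=solver, tol=tol,
        ).fit(base_rows)
        correctors[analyte] = corrector
        corr_qc[analyte] = {
            "mode": corrector.correction_matrix_.provenance,
            "natural_mid": [round(v, 8) for v in corrector.natural_mid_.values],
            "n_baseline_samples": 0 if base_rows is None else int(len(base_rows)),
        }

    curves: dict = {}
    if curve_standards is not None and len(curve_standards):
        for analyte, sub in curve_standards.groupby("analyte_id"):
            curves[analyte] = fit_calibration(
                x=sub["known_conc"].to_numpy(), y=sub["response"].to_numpy())

    extra_cols = [c for c in areas.columns
                  if c not in ("sample_id", "analyte_id", "area_is", *area_cols)]
    rows = []
    for rec in areas.to_dict("records"):
        sid = str(rec["sample_id"])
        analyte = str(rec["analyte_id"])
        adef = panel[analyte]
        flags = []
        if p_source == "per-animal" and sid in p_by_sample:
            p, p_src = p_by_sample[sid], "per-animal"
        else:
            if p_source == "per-animal":
                flags.append("p_cohort_fallback")
            p, p_src = cohort_p, "cohort-mean"
        if p <= 0:
            raise ValueError(f"water enrichment unavailable for sample {sid}")
        raw = np.array([rec[c] for c in area_cols], dtype=float)
        corrected, residual = correctors[analyte].correct(raw[None, :])
        mid = MID(values=corrected[0], truncated_mass=0.0)
        enr = analyte_enrichment(mid)
        n = adef.n_exchangeable
        f_raw = fractional_synthesis(enr, p, n)
        factor = truncation_bias_factor(n, p, K) if truncation_correction else 1.0
        f = f_raw / factor
        if float(residual[0]) > tol:
            flags.append("high_residual")
        if f > 100.0:
            flags.append("f_gt_100")
        row = {"sample_id": sid, "analyte_id": analyte}
        row.update({f"m{i}": mid.values[i] for i in range(K + 1)})
        row.update({
            "enrichment": enr, "p": p, "p_source": p_src, "n": n,
            "f_percent": f, "f_uncorrected_percent": f_raw,
            "residual": float(residual[0]),
        })
        if analyte in curves and "area_is" in areas.columns:
            conc = quantify(float(raw.sum()), float(rec["area_is"]), curves[analyte])
            row["concentration_ug_g"] = conc
            row["new_pool_ug_g"] = new_pool_amount(min(f, 100.0), conc)
        row["flags"] = ";".join(flags)
        for c in extra_cols:
            row[c] = rec[c]
        rows.append(row)

    results = pd.DataFrame(rows)
    _validate_results(results, K)
    qc = {
        "K": K, "solver": solver, "tol": tol, "p_source": p_source,
        "truncation_correction": truncation_correction,
        "n_samples": int(results["sample_id"].nunique()),
        "n_analytes": len(analytes),
        "water_calibration": water_qc,
        "correction": corr_qc,
        "concentration_curves": {
            a: {"slope": c.slope, "intercept": c.intercept, "r": c.r}
            for a, c in curves.items()
        },
    }
    return AnalysisResult(results=results, qc=qc)


def _validate_results(results: pd.DataFrame, K: int) -> None:
    missing = [c for c in _RESULT_COLUMNS if c not in results.columns]
    if missing:
        raise RuntimeError(f"results schema invalid, missing {missing}")
    num = results[["enrichment", "p", "f_percent", "residual"]].to_numpy(dtype=float)
    if not np.isfinite(num).all():
        raise RuntimeError("results contain non-finite values")
    if (results["enrichment"] < -1e-12).any() or (results["enrichment"] > K).any():
        raise RuntimeError("enrichment outside [0, K]")


def run_analysis(config: RunConfig) -> AnalysisResult:
    """File-level entry point: read tables per config, analyze, write outputs."""
    read = pd.read_csv
    for name in ("areas", "water"):
        path = getattr(config, name)
        if not Path(path).exists():
            raise FileNotFoundError(f"{name} table not found: {path}")
    areas = read(config.areas)
    water = read(config.water)
    baseline = read(config.baseline) if config.baseline else None
    metadata = read(config.metadata) if config.metadata else None
    curve_standards = (read(config.curve_standards)
                       if config.curve_standards else None)
    panel = load_panel(config.panel) if config.panel else default_panel()
    result = analyze_tables(
        areas, water, baseline=baseline, metadata=metadata,
        curve_standards=curve_standards, panel=panel,
        correction=config.correction, K=config.K, p_source=config.p_source,
        solver=config.solver, tol=config.tol,
        truncation_correction=config.truncation_correction,
    )
    if metadata is not None:
        result.results = result.results.merge(metadata, on="sample_id", how="left")
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        results_path = outdir / "results.csv"
        qc_path = outdir / "qc.json"
        result.results.to_csv(results_path, index=False)
        qc_path.write_text(json.dumps(result.qc, indent=2, sort_keys=True))
        result.paths = {"results": results_path, "qc": qc_path}
    return result


def run_estimate_n(config: RunConfig, analyte: str, candidates=range(1, 41)) -> dict:
    """Pooled exchangeable-hydrogen estimation for one analyte.

    Corrects every labeled sample's MID, pools them, and reports the best-fit
    binomial size with its residual profile and the m2/m1 closed-form check.
    """
    areas = pd.read_csv(config.areas)
    water = pd.read_csv(config.water)
    baseline = pd.read_csv(config.baseline) if config.baseline else None
    panel = load_panel(config.panel) if config.panel else default_panel()
    if analyte not in panel:
        raise ValueError(f"no analyte definition for: {analyte}")
    sub = areas[areas["analyte_id"] == analyte]
    if not len(sub):
        raise ValueError(f"no labeled samples for analyte {analyte!r}")
    K = config.K
    area_cols = [f"area_m{i}" for i in range(K + 1)]
    base_rows = None
    if baseline is not None and len(baseline):
        bsub = baseline[baseline["analyte_id"] == analyte]
        if len(bsub):
            base_rows = bsub[area_cols].to_numpy(dtype=float)
    corrector = NaturalAbundanceCorrector(
        formula=panel[analyte].formula, K=K, mode=config.correction,
        solver=config.solver, tol=config.tol,
    ).fit(base_rows)
    corrected, _ = corrector.correct(sub[area_cols].to_numpy(dtype=float))
    _, cohort_p, _ = _water_enrichment_table(water)
    est = estimate_n(corrected, cohort_p, candidates)
    report = {
        "analyte": analyte,
        "p": cohort_p,
        "n_hat": est.n,
        "n_assigned": panel[analyte].n_exchangeable,
        "ratio_diagnostic": est.ratio_estimate,
        "tie": est.tie,
        "residual_profile": {int(c): float(r)
                             for c, r in zip(est.candidates, est.residuals)},
    }
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / f"n_report_{analyte}.json").write_text(
            json.dumps(report, indent=2))
    return report
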