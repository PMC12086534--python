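"""Synthetic tracer studies with known ground truth.

``simulate_study`` is the generative twin of the measurement model: each
animal gets a body-water enrichment p drawn around the dosing target (~4%),
each analyte a true fractional synthesis drawn around its group mean
(logit-normal, so biological variability keeps f in (0, 1)), and the
observed m0-m3 peak areas are the forward-model MID scaled by an
internal-standard-tied abundance with multiplicative lognormal instrument
noise — the error structure of MS peak areas.  Unlabeled baseline animals,
gravimetric water-enrichment standards, and internal-standard concentration
curves are emitted alongside, plus a truth table the analysis never reads.

Presets mirror the group structures of typical aerobic-capacity / exercise /
knockout designs (two-group wheel-running, 8-cell strain x diet x feeding,
and a 4-group knockout study with shrunken bile-acid pools).  Their effect
sizes are synthetic defaults chosen to be physiologically plausible, not
measured values.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .labeling import LabelingParameters, forward_observed_mid
from .panel import AnalyteDefinition, default_panel

DEFAULT_SEED = 20250407

# nominal acetone-exchange reduction: m1/m0 signal ratio of the acetone ion,
# linear in the water 2H mol fraction (intercept = natural background)
ACETONE_INTERCEPT = 0.0334
ACETONE_SLOPE = 6.0


@dataclass
class CohortConfig:
    """Description of a synthetic tracer study.

    Parameters
    ----------
    groups : tuple of (label, size)
    f_true : dict
        group -> analyte -> true fractional synthesis in percent.
    pool_mean : dict
        analyte -> mean pool concentration (µg/g tissue).
    pool_cv, noise_cv : float
        Lognormal CVs for biological pool-size variability and per-
        isotopologue instrument noise on areas.
    p_mean, p_sd : float
        Body-water ²H mol-fraction excess across animals (dosing targets
        ~4%; per-animal spread from dosing/water turnover).
    f_logit_sd : float
        Biological variability of f on the logit scale.
    sexes : tuple
        Each group is replicated per sex ("M",) by default.
    pool_scale : dict
        Optional group -> multiplier on pool concentrations (e.g. a knockout
        with a shrunken bile-acid pool).
    """

    groups: tuple
    f_true: dict
    pool_mean: dict
    pool_cv: float = 0.25
    p_mean: float = 0.04
    p_sd: float = 0.003
    panel: dict = field(default_factory=default_panel)
    noise_cv: float = 0.05
    f_logit_sd: float = 0.10
    sexes: tuple = ("M",)
    pool_scale: dict = field(default_factory=dict)
    n_baseline: int = 4
    K: int = 3
    seed: int = DEFAULT_SEED
    is_area: float = 1.0e6
    response_factor: float = 0.01  # area ratio per µg/g
    water_standards: tuple = (0.0, 0.01, 0.02, 0.04, 0.06)
    water_noise_rel: float = 0.005
    body_mass_mean: float = 30.0
    body_mass_sd: float = 2.0

    def __post_init__(self):
        problems = []
        if not self.groups:
            problems.append("groups: empty")
        for label, size in self.groups:
            if size < 1:
                problems.append(f"groups[{label}]: size must be >= 1")
            if label not in self.f_true:
                problems.append(f"f_true: missing group {label!r}")
        analytes = self.analytes
        for g, per in self.f_true.items():
            for a, f in per.items():
                if not 0.0 <= f <= 100.0:
                    problems.append(f"f_true[{g}][{a}]: {f} outside [0, 100]")
                if a not in self.panel:
                    problems.append(f"panel: missing analyte {a!r}")
        for a in analytes:
            if a not in self.pool_mean:
                problems.append(f"pool_mean: missing analyte {a!r}")
            elif self.pool_mean[a] < 0:
                problems.append(f"pool_mean[{a}]: must be >= 0")
            if a in self.panel and self.panel[a].n_exchangeable < 1:
                problems.append(f"panel[{a}]: n must be >= 1")
        for name in ("pool_cv", "noise_cv", "f_logit_sd", "p_sd", "water_noise_rel"):
            if getattr(self, name) < 0:
                problems.append(f"{name}: must be >= 0")
        if not 0.0 < self.p_mean < 1.0:
            problems.append("p_mean: must lie in (0, 1)")
        if problems:
            raise ValueError("invalid cohort config: " + "; ".join(problems))

    @property
    def analytes(self) -> list:
        seen = []
        for per in self.f_true.values():
            for a in per:
                if a not in seen:
                    seen.append(a)
        return seen


@dataclass
class SyntheticStudy:
    """All tables of a simulated study, plus the ground truth."""

    areas: pd.DataFrame
    baseline: pd.DataFrame
    water: pd.DataFrame
    metadata: pd.DataFrame
    truth: pd.DataFrame
    curve_standards: pd.DataFrame
    config: CohortConfig

    def write(self, outdir) -> dict:
        """Write every table as CSV under ``outdir``; returns name -> path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("areas", "baseline", "water", "metadata", "truth",
                     "curve_standards"):
            path = outdir / f"{name}.csv"
            getattr(self, name).to_csv(path, index=False)
            paths[name] = path
        return paths


def _lognormal_noise(rng, cv, size=None):
    """Multiplicative mean-1 lognormal noise; exactly 1 when cv = 0."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    s = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-0.5 * s**2, s, size=size))


def _lognormal_around(rng, mean, cv):
    if cv == 0 or mean == 0:
        return mean
    s = np.sqrt(np.log1p(cv**2))
    return float(np.exp(rng.normal(np.log(mean) - 0.5 * s**2, s)))


def _draw_f(rng, f_percent, logit_sd):
    frac = f_percent / 100.0
    if logit_sd == 0 or frac <= 0.0 or frac >= 1.0:
        return frac
    z = np.log(frac / (1.0 - frac)) + rng.normal(0.0, logit_sd)
    return float(1.0 / (1.0 + np.exp(-z)))


def simulate_study(config: CohortConfig) -> SyntheticStudy:
    """Generate a complete synthetic study (deterministic given config+seed)."""
    rng = np.random.default_rng(config.seed)
    K = config.K
    area_cols = [f"area_m{i}" for i in range(K + 1)]
    analytes = config.analytes

    # gravimetric water standards, shared by the whole study
    water_rows = []
    for i, frac in enumerate(config.water_standards):
        ratio = ACETONE_INTERCEPT + ACETONE_SLOPE * frac
        ratio *= 1.0 + rng.normal(0.0, config.water_noise_rel) if config.water_noise_rel else 1.0
        water_rows.append({"kind": "standard", "sample_id": f"std_{i}",
                           "known_fraction": frac, "ratio": ratio})

    area_rows, meta_rows, truth_rows = [], [], []
    for label, size in config.groups:
        for sex in config.sexes:
            for i in range(size):
                sid = f"{label}_{sex}{i + 1:02d}" if len(config.sexes) > 1 else \
                      f"{label}_{i + 1:02d}"
                p = -1.0
                while not 0.0 < p < 1.0:
                    p = rng.normal(config.p_mean, config.p_sd) if config.p_sd else config.p_mean
                ratio = ACETONE_INTERCEPT + ACETONE_SLOPE * p
                ratio *= 1.0 + rng.normal(0.0, config.water_noise_rel) if config.water_noise_rel else 1.0
                water_rows.append({"kind": "sample", "sample_id": sid,
                                   "known_fraction": np.nan, "ratio": ratio})
                body_mass = rng.normal(config.body_mass_mean, config.body_mass_sd)
                meta_rows.append({"sample_id": sid, "group": label, "sex": sex,
                                  "body_mass_g": round(float(body_mass), 2)})
                scale = config.pool_scale.get(label, 1.0)
                for analyte in analytes:
                    adef = config.panel[analyte]
                    f = _draw_f(rng, config.f_true[label].get(analyte, 0.0),
                                config.f_logit_sd)
                    conc = _lognormal_around(rng, config.pool_mean[analyte] * scale,
                                             config.pool_cv)
                    params = LabelingParameters(p=p, n=adef.n_exchangeable, f=f)
                    mid = forward_observed_mid(params, adef.formula, K,
                                               truncation_bound=1.0)
                    total = config.is_area * config.response_factor * conc
                    areas = total * mid.values * _lognormal_noise(rng, config.noise_cv,
                                                                  K + 1)
                    is_area = config.is_area * _lognormal_noise(rng, config.noise_cv)
                    row = {"sample_id": sid, "analyte_id": analyte}
                    row.update({c: a for c, a in zip(area_cols, areas)})
                    row["area_is"] = float(is_area)
                    area_rows.append(row)
                    truth_rows.append({"sample_id": sid, "analyte_id": analyte,
                                       "f_true_percent": f * 100.0, "p_true": p,
                                       "pool_ug_g": conc})

    # unlabeled baseline animals: natural abundance only
    baseline_rows = []
    for i in range(config.n_baseline):
        sid = f"baseline_{i + 1:02d}"
        for analyte in analytes:
            adef = config.panel[analyte]
            conc = _lognormal_around(rng, config.pool_mean[analyte], config.pool_cv)
            params = LabelingParameters(p=0.0, n=adef.n_exchangeable, f=0.0)
            mid = forward_observed_mid(params, adef.formula, K, truncation_bound=1.0)
            total = config.is_area * config.response_factor * conc
            areas = total * mid.values * _lognormal_noise(rng, config.noise_cv, K + 1)
            is_area = config.is_area * _lognormal_noise(rng, config.noise_cv)
            row = {"sample_id": sid, "analyte_id": analyte}
            row.update({c: a for c, a in zip(area_cols, areas)})
            row["area_is"] = float(is_area)
            baseline_rows.append(row)

    # internal-standard concentration curves (noiseless lines)
    curve_rows = []
    for analyte in analytes:
        for mult in (0.2, 0.5, 1.0, 2.0, 4.0):
            known = config.pool_mean[analyte] * mult
            curve_rows.append({"analyte_id": analyte, "known_conc": known,
                               "response": config.response_factor * known})

    return SyntheticStudy(
        areas=pd.DataFrame(area_rows),
        baseline=pd.DataFrame(baseline_rows),
        water=pd.DataFrame(water_rows),
        metadata=pd.DataFrame(meta_rows),
        truth=pd.DataFrame(truth_rows),
        curve_standards=pd.DataFrame(curve_rows),
        config=config,
    )


_BA = ("T-CA", "T-aMCA", "T-bMCA", "T-CDCA", "T-DCA")
_BA_POOLS = {"T-CA": 60.0, "T-aMCA": 40.0, "T-bMCA": 80.0,
             "T-CDCA": 10.0, "T-DCA": 15.0}


def preset_study(name: str) -> CohortConfig:
    """Named study designs with plausible synthetic effect sizes.

    ``"vwr_mice"``: two groups of 8 (sedentary vs voluntary wheel running);
    exercise raises bile-acid synthesis.  ``"lcyp7a1ko"``: 4 groups of 7 in
    both sexes (control/knockout x sedentary/exercise); the knockout shrinks
    bile-acid pool concentrations.  ``"hcr_lcr_1wk"``: 8 groups of 8
    (strain x diet x feeding status) over the full 7-analyte panel.

    All f values and pool sizes are synthetic defaults, not measured values.
    """
    if name == "vwr_mice":
        sed = {"T-CA": 20.0, "T-aMCA": 15.0, "T-bMCA": 12.0,
               "T-CDCA": 10.0, "T-DCA": 8.0}
        vwr = {a: round(f * 1.6, 1) for a, f in sed.items()}
        return CohortConfig(
            groups=(("SED", 8), ("VWR", 8)),
            f_true={"SED": sed, "VWR": vwr},
            pool_mean=dict(_BA_POOLS),
        )
    if name == "lcyp7a1ko":
        ctrl = {"T-CA": 22.0, "T-aMCA": 16.0, "T-bMCA": 13.0,
                "T-CDCA": 10.0, "T-DCA": 8.0}
        vwr = {a: round(f * 1.4, 1) for a, f in ctrl.items()}
        return CohortConfig(
            groups=(("Ctrl-SED", 7), ("Ctrl-VWR", 7),
                    ("KO-SED", 7), ("KO-VWR", 7)),
            # fractions similar across genotype; the knockout's deficit shows
            # in absolute new amounts via its shrunken pools
            f_true={"Ctrl-SED": ctrl, "Ctrl-VWR": vwr,
                    "KO-SED": ctrl, "KO-VWR": vwr},
            pool_mean=dict(_BA_POOLS),
            pool_scale={"KO-SED": 0.3, "KO-VWR": 0.3},
            sexes=("M", "F"),
        )
    if name == "hcr_lcr_1wk":
        groups = []
        f_true = {}
        base = {"T-CA": 18.0, "T-aMCA": 14.0, "T-bMCA": 11.0, "T-CDCA": 9.0,
                "T-DCA": 7.0, "palmitate": 12.0, "cholesterol-fragment": 6.0}
        for strain, smul in (("HCR", 1.5), ("LCR", 1.0)):
            for diet, dmul in (("LFD", 1.0), ("HFD", 1.2)):
                for fed, fmul in (("FED", 1.0), ("FASTED", 0.6)):
                    label = f"{strain}-{diet}-{fed}"
                    groups.append((label, 8))
                    f_true[label] = {
                        a: round(min(f * (smul if a != "palmitate" else 1.0 / smul)
                                     * dmul * (fmul if a in ("palmitate",
                                                             "cholesterol-fragment")
                                               else 1.0), 95.0), 2)
                        for a, f in base.items()
                    }
        pools = dict(_BA_POOLS)
        pools.update({"palmitate": 2000.0, "cholesterol-fragment": 1500.0})
        return CohortConfig(
            groups=tuple(groups),
            f_true=f_true,
            pool_mean=pools,
            body_mass_mean=350.0,
            body_mass_sd=25.0,
        )
    raise ValueError(f"unknown preset {name!r}")
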