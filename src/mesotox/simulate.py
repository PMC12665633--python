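"""Synthetic mesocosm experiment generator.

Generates complete experiments with the statistical structure the analyses
assume, so every pipeline stage is testable without the original raw data and
parameter-recovery studies are possible.  The default configuration encodes
the study conditions of a 6-treatment x 5-replicate outdoor mesocosm design
(30 tanks) with a single herbicide application:

* chemistry: 1-h measured concentrations average 84% of nominal with
  lognormal tank-to-tank noise; first-order dissipation (DT50 ~ 2 d for the
  three lowest treatments, ~3.5 d for the two highest); censoring at the
  5 µg/L reporting limit;
* caged amphipods: binomial survival (2 cages x 20 animals per tank, weeks
  2/4/6) on a quadratic-logit hormetic curve whose coefficients are solved
  from interpretable anchors (control survival per week, peak concentration
  10 µg/L, week-6 LC50 155 µg/L) plus Normal(0, sigma_tank) tank intercepts;
  weekly counts are binomially thinned so week-w survival is marginally
  Binomial(20, p_w);
* tadpoles: 15 per tank, survival rising log-linearly with concentration
  from 77.5% (control) to 90% (top treatment), development-rate step increase
  (0.092 control vs 0.333 stages/day treated), mass +2.29% per concentration
  doubling with a rise-and-fall Gosner-stage trend, sex recorded only at
  Gosner stage >= 36;
* phytoplankton: Dirichlet-multinomial counts (>= 300 cells) whose
  composition shifts toward two tolerant taxa with increasing dose after
  day 0;
* oxidative-stress markers: treatment-independent lognormal (a true null).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .datamodel import DETECTION_LIMIT_UG_L, Dataset
from .hormesis import transform_concentration

__all__ = [
    "SimConfig",
    "solve_beta_from_metrics",
    "simulate_experiment",
    "simulate_null_experiment",
]

TOLERANT_TAXA = ["Chlorella spp.", "Scenedesmus quadricauda"]

_TAXA = TOLERANT_TAXA + [
    "Cryptomonas sp.", "Cyclotella sp.", "Monoraphidium sp.",
    "Dolichospermum sp.", "Chlamydomonas sp.", "Navicula sp.",
    "Oocystis sp.", "Peridinium sp.",
]
# relative cell biomass (mg per 10^6 cells), arbitrary but fixed per taxon
_CELL_MASS = np.array([0.6, 1.1, 2.5, 1.8, 0.7, 1.4, 0.9, 2.0, 1.2, 3.0])

_BASE_TAXON_WEIGHTS = np.array(
    [0.14, 0.11, 0.12, 0.11, 0.10, 0.09, 0.10, 0.08, 0.08, 0.07])


@dataclass
class SimConfig:
    """Full parameterization of the synthetic experiment."""
    # design
    nominal_levels: tuple = (0.0, 74.0, 147.0, 291.0, 579.0, 1153.0)
    replicates: int = 5
    cages_per_tank: int = 2
    amphipods_per_cage: int = 20
    tadpoles_per_tank: int = 15
    # chemistry
    fraction_of_nominal_1h: float = 0.84
    fraction_cv: float = 0.10
    dt50_low_days: float = 2.0       # three lowest treatments
    dt50_high_days: float = 3.5      # two highest treatments
    detection_limit: float = DETECTION_LIMIT_UG_L
    sample_days: tuple = (0.0, 1.0, 2.0, 4.0, 7.0, 21.0, 41.0)  # day 0 = 1 h
    # amphipod survival (weekly control survival; hormesis anchors)
    control_survival_by_week: tuple = ((2, 0.82), (4, 0.67), (6, 0.60))
    peak_conc: float = 10.0          # µg/L, vertex of the hormetic curve
    lc50_week6: float = 155.0        # µg/L, week-6 median lethal concentration
    sigma_tank: float = 0.3
    # amphipod secondary endpoints
    growth_base_mg: float = 0.35
    growth_log2_boost: tuple = (0.0, 0.5, 0.9, 0.9, 0.7, 0.7)  # per treatment
    growth_log2_sd: float = 0.15
    juvenile_log_rate: float = 1.1
    juvenile_conc_slope: float = 0.07
    juvenile_log_sd: float = 0.4
    # tadpoles
    tadpole_control_survival: float = 0.775
    tadpole_top_survival: float = 0.90
    tadpole_sigma_tank: float = 0.3
    dev_rate_control: float = 0.092   # Gosner stages / day
    dev_rate_treated: float = 0.333
    dev_rate_conc_log2_slope: float = 0.01  # small log-linear term on treated
    dev_rate_log2_sd: float = 0.25
    duration_days: float = 53.0
    mass_base_g: float = 1.2
    mass_pct_per_doubling: float = 2.29
    mass_log2_sd: float = 0.30
    hsi_base: float = 3.0
    hsi_stage_log2_slope: float = 0.03
    hsi_log2_sd: float = 0.35
    # algae
    cells_min: int = 300
    cells_mean_extra: float = 150.0
    algae_days: tuple = (0.0, 7.0, 41.0)
    tolerant_shift_day7: float = 0.37    # per unit log2 concentration
    tolerant_shift_day41: float = 0.25
    control_day41_evenness_loss: float = 1.5
    dirichlet_precision: float = 60.0
    # stress markers (null effect)
    hne_mean: float = 323.8
    hne_log_sd: float = 0.30
    pc_mean: float = 1.19
    pc_log_sd: float = 0.13
    seed: int = 0

    def validate(self) -> None:
        for p in (self.tadpole_control_survival, self.tadpole_top_survival,
                  self.fraction_of_nominal_1h):
            if not (0 < p < 1):
                raise ValueError("probabilities/fractions must be in (0, 1)")
        for w, p in self.control_survival_by_week:
            if not (0 < p < 1):
                raise ValueError("control survival must be in (0, 1)")
        if min(self.replicates, self.cages_per_tank, self.amphipods_per_cage,
               self.tadpoles_per_tank) <= 0:
            raise ValueError("design counts must be positive")
        if self.dt50_low_days <= 0 or self.dt50_high_days <= 0:
            raise ValueError("dissipation half-lives must be positive")

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2, sort_keys=True, default=list)
        if path is not None:
            from pathlib import Path
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, src) -> "SimConfig":
        from pathlib import Path
        if isinstance(src, (str, Path)) and Path(src).exists():
            src = Path(src).read_text()
        d = json.loads(src)
        for key in ("nominal_levels", "sample_days", "algae_days",
                    "growth_log2_boost"):
            if key in d:
                d[key] = tuple(d[key])
        if "control_survival_by_week" in d:
            d["control_survival_by_week"] = tuple(
                (int(w), float(p)) for w, p in d["control_survival_by_week"])
        return cls(**d)


def solve_beta_from_metrics(p0: float, c_peak: float, lc50: float
                            ) -> tuple[float, float, float]:
    """Invert the quadratic-logit hormesis curve from interpretable anchors.

    Given control survival p0, the peak (vertex) concentration c_peak and the
    LC50 (concentration where survival falls to p0 / 2 on the descending
    limb), returns (beta0, beta1, beta2) on the logit/log2 scale:
    beta0 = logit(p0); the vertex condition x_peak = -beta1 / (2 beta2) and
    the LC50 condition beta0 + beta1 x50 + beta2 x50^2 = logit(p0 / 2) form a
    linear system in (beta1, beta2).
    """
    if not (0 < p0 < 1):
        raise ValueError("p0 must be in (0, 1)")
    if not (0 <= c_peak < lc50):
        raise ValueError("need 0 <= c_peak < lc50")
    beta0 = float(logit(p0))
    xp = transform_concentration(c_peak)
    x50 = transform_concentration(lc50)
    denom = x50 ** 2 - 2.0 * xp * x50
    if denom <= 0:
        raise ValueError("inconsistent anchors: no beta2 < 0 solution "
                         "(need lc50 well beyond twice the peak on log2 scale)")
    beta2 = float((logit(0.5 * p0) - beta0) / denom)
    beta1 = float(-2.0 * beta2 * xp)
    if beta2 >= 0:
        raise ValueError("inconsistent anchors: no beta2 < 0 solution")
    return beta0, beta1, beta2


def _tank_table(cfg: SimConfig, rng: np.random.Generator
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tank assignments plus 1-h measured concentrations (chemistry day 0)."""
    rows, chem = [], []
    tank_no = 0
    measured = {}
    for rep in range(1, cfg.replicates + 1):
        for nominal in cfg.nominal_levels:
            tank_no += 1
            tid = f"T{tank_no:02d}"
            if nominal > 0:
                m1h = nominal * cfg.fraction_of_nominal_1h * rng.lognormal(
                    -0.5 * np.log(1 + cfg.fraction_cv ** 2),
                    np.sqrt(np.log(1 + cfg.fraction_cv ** 2)))
            else:
                m1h = 0.0
            measured[tid] = m1h
            rows.append({"tank_id": tid, "block": rep, "nominal_conc": nominal})
    tanks = pd.DataFrame(rows)
    tanks["measured_1h"] = tanks["tank_id"].map(measured)
    grp = tanks.groupby("nominal_conc")["measured_1h"].transform("mean")
    tanks["initial_measured_conc"] = grp.round(6)
    return tanks[["tank_id", "block", "nominal_conc", "initial_measured_conc"]], \
        tanks[["tank_id", "nominal_conc", "measured_1h"]]


def _chemistry(cfg: SimConfig, meas: pd.DataFrame, rng: np.random.Generator
               ) -> pd.DataFrame:
    rows = []
    low_set = set(sorted([l for l in cfg.nominal_levels if l > 0])[:3])
    for r in meas.itertuples():
        dt50 = cfg.dt50_low_days if r.nominal_conc in low_set else cfg.dt50_high_days
        k = np.log(2.0) / dt50
        for day in cfg.sample_days:
            if r.nominal_conc == 0:
                true = 0.0
            elif day == 0.0:
                true = r.measured_1h
            else:
                true = r.measured_1h * np.exp(-k * day) * rng.lognormal(0.0, 0.08)
            censored = true < cfg.detection_limit
            rows.append({
                "tank_id": r.tank_id, "day": day, "analyte": "diquat",
                "value": cfg.detection_limit if censored else true,
                "below_detection": censored,
                "detection_limit": cfg.detection_limit,
            })
    return pd.DataFrame(rows)


def _amphipods(cfg: SimConfig, tanks: pd.DataFrame, rng: np.random.Generator,
               null: bool = False) -> pd.DataFrame:
    weeks = [w for w, _ in cfg.control_survival_by_week]
    p0w = dict(cfg.control_survival_by_week)
    _, b1, b2 = solve_beta_from_metrics(p0w[weeks[-1]], cfg.peak_conc, cfg.lc50_week6)
    if null:
        b1 = b2 = 0.0
    x = transform_concentration(tanks["initial_measured_conc"].to_numpy())
    u = rng.normal(0.0, cfg.sigma_tank, size=len(tanks))
    nominal = tanks["nominal_conc"].to_numpy()
    treat_index = {lv: i for i, lv in enumerate(sorted(set(cfg.nominal_levels)))}
    rows = []
    for i, r in enumerate(tanks.itertuples()):
        p_weeks = [expit(logit(p0w[w]) + b1 * x[i] + b2 * x[i] ** 2 + u[i])
                   for w in weeks]
        for cage in range(1, cfg.cages_per_tank + 1):
            alive = cfg.amphipods_per_cage
            prev_p = 1.0
            for w, p in zip(weeks, p_weeks):
                ratio = min(p / prev_p, 1.0)
                alive = int(rng.binomial(alive, ratio))
                prev_p = p
                last_week = w == weeks[-1]
                juv = 0
                mass = np.nan
                if last_week and alive > 0:
                    lam = np.exp(cfg.juvenile_log_rate
                                 + (0.0 if null else cfg.juvenile_conc_slope * x[i])
                                 + rng.normal(0.0, cfg.juvenile_log_sd))
                    juv = int(rng.poisson(lam * alive))
                    boost = 0.0 if null else cfg.growth_log2_boost[treat_index[nominal[i]]]
                    mass = cfg.growth_base_mg * 2.0 ** (
                        boost + rng.normal(0.0, cfg.growth_log2_sd))
                rows.append({
                    "tank_id": r.tank_id, "cage_id": f"{r.tank_id}C{cage}",
                    "week": w, "n_atrisk": cfg.amphipods_per_cage,
                    "n_alive": alive, "n_juveniles": juv,
                    "wet_mass_mg": round(mass, 6) if np.isfinite(mass) else np.nan,
                })
    return pd.DataFrame(rows)


def _tadpoles(cfg: SimConfig, tanks: pd.DataFrame, rng: np.random.Generator,
              null: bool = False) -> pd.DataFrame:
    x = transform_concentration(tanks["initial_measured_conc"].to_numpy())
    x_top = float(x.max())
    b0 = logit(cfg.tadpole_control_survival)
    b1 = 0.0 if null or x_top == 0 else (logit(cfg.tadpole_top_survival) - b0) / x_top
    u = rng.normal(0.0, cfg.tadpole_sigma_tank, size=len(tanks))
    mass_slope = 0.0 if null else np.log2(1.0 + cfg.mass_pct_per_doubling / 100.0)
    rows = []
    for i, r in enumerate(tanks.itertuples()):
        treated = r.nominal_conc > 0 and not null
        p_surv = expit(b0 + b1 * x[i] + u[i])
        for j in range(1, cfg.tadpoles_per_tank + 1):
            tid = f"{r.tank_id}P{j:02d}"
            survived = bool(rng.random() < p_surv)
            if not survived:
                rows.append({"tank_id": r.tank_id, "tadpole_id": tid,
                             "survived": False, "gosner_stage": np.nan,
                             "days_elapsed": np.nan, "wet_mass_g": np.nan,
                             "liver_mass_g": np.nan, "sex": "unknown"})
                continue
            base = cfg.dev_rate_treated if treated else cfg.dev_rate_control
            lograte = (np.log2(base)
                       + (cfg.dev_rate_conc_log2_slope * x[i] if treated else 0.0)
                       + rng.normal(0.0, cfg.dev_rate_log2_sd))
            rate = 2.0 ** lograte
            days_to_meta = (46.0 - 25.0) / rate
            if days_to_meta < cfg.duration_days:
                days = float(np.ceil(days_to_meta))
                stage = 46
            else:
                days = cfg.duration_days
                stage = int(np.clip(round(25 + rate * days), 25, 46))
            stage_c = stage - 34.0
            log2_mass = (np.log2(cfg.mass_base_g) + mass_slope * x[i]
                         + 0.04 * stage_c - 0.004 * stage_c ** 2
                         + rng.normal(0.0, cfg.mass_log2_sd))
            mass = 2.0 ** log2_mass
            log2_hsi = (np.log2(cfg.hsi_base) + cfg.hsi_stage_log2_slope * stage_c
                        + rng.normal(0.0, cfg.hsi_log2_sd))
            liver = (2.0 ** log2_hsi) / 100.0 * mass
            if stage >= 36:
                sex = "F" if rng.random() < 0.5 else "M"
            else:
                sex = "unknown" if rng.random() < 0.6 else ("F" if rng.random() < 0.5 else "M")
            rows.append({"tank_id": r.tank_id, "tadpole_id": tid, "survived": True,
                         "gosner_stage": stage, "days_elapsed": days,
                         "wet_mass_g": round(mass, 6),
                         "liver_mass_g": round(liver, 8), "sex": sex})
    return pd.DataFrame(rows)


def _algae(cfg: SimConfig, tanks: pd.DataFrame, rng: np.random.Generator,
           null: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    x = transform_concentration(tanks["initial_measured_conc"].to_numpy())
    tol_mask = np.isin(_TAXA, TOLERANT_TAXA)
    rows, chl_rows = [], []
    for i, r in enumerate(tanks.itertuples()):
        for day in cfg.algae_days:
            w = _BASE_TAXON_WEIGHTS.copy()
            if day > 0 and not null:
                shift = (cfg.tolerant_shift_day7 if day <= 7
                         else cfg.tolerant_shift_day41)
                w = np.where(tol_mask, w * np.exp(shift * x[i]), w)
            if day > 7:
                # late-season evenness loss affects every tank incl. controls
                w = np.where(tol_mask, w * np.exp(cfg.control_day41_evenness_loss), w)
            w = w / w.sum()
            alpha = w * cfg.dirichlet_precision
            comp = rng.dirichlet(alpha)
            n_cells = cfg.cells_min + int(rng.poisson(cfg.cells_mean_extra))
            counts = rng.multinomial(n_cells, comp)
            biom = counts * _CELL_MASS
            for t, cnt, bm in zip(_TAXA, counts, biom):
                if cnt > 0:
                    rows.append({"tank_id": r.tank_id, "day": day, "taxon": t,
                                 "count": int(cnt),
                                 "biomass_mg_m3": round(float(bm), 4)})
            chl = 10.0
            if day > 0 and not null:
                pulse = 8.0 * x[i] if day <= 7 else 1.5 * x[i]
                chl += pulse
            chl *= rng.lognormal(0.0, 0.15)
            chl_rows.append({"tank_id": r.tank_id, "day": day,
                             "chl_a_ug_L": round(float(chl), 4)})
    return pd.DataFrame(rows), pd.DataFrame(chl_rows)


def _stress(cfg: SimConfig, tanks: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    mu_h = np.log(cfg.hne_mean) - 0.5 * cfg.hne_log_sd ** 2
    mu_p = np.log(cfg.pc_mean) - 0.5 * cfg.pc_log_sd ** 2
    return pd.DataFrame({
        "tank_id": tanks["tank_id"],
        "hne_ug_g": np.round(rng.lognormal(mu_h, cfg.hne_log_sd, len(tanks)), 4),
        "protein_carbonyl_nmol_mg": np.round(
            rng.lognormal(mu_p, cfg.pc_log_sd, len(tanks)), 5),
    })


def simulate_experiment(config: SimConfig | None = None,
                        seed: int | None = None,
                        null: bool = False) -> Dataset:
    """Generate a full synthetic Dataset; reproducible under the config seed."""
    cfg = config or SimConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed)
    streams = {name: np.random.default_rng(ss) for name, ss in zip(
        ("tanks", "chemistry", "amphipods", "tadpoles", "algae", "stress"),
        root.spawn(6))}
    tanks, meas = _tank_table(cfg, streams["tanks"])
    chem = _chemistry(cfg, meas, streams["chemistry"])
    amph = _amphipods(cfg, tanks, streams["amphipods"], null=null)
    tads = _tadpoles(cfg, tanks, streams["tadpoles"], null=null)
    algae, chl = _algae(cfg, tanks, streams["algae"], null=null)
    stress = _stress(cfg, tanks, streams["stress"])
    return Dataset(tanks=tanks, chemistry=chem, amphipods=amph, tadpoles=tads,
                   algae=algae, chlorophyll=chl, stress=stress)


def simulate_null_experiment(config: SimConfig | None = None,
                             seed: int | None = None) -> Dataset:
    """As :func:`simulate_experiment` with all treatment effects zeroed."""
    return simulate_experiment(config, seed=seed, null=True)
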