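"""Full-analysis orchestration: chemistry -> amphipods -> tadpoles -> algae.

A single :class:`RunConfig` drives all stages.  One global seed spawns
independent per-stage substreams, so adding or skipping a stage never perturbs
another stage's randomness, and identical config + seed reproduce identical
outputs.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import community, exposure, hormesis, mixedmodels as mm
from .datamodel import Dataset, read_dataset, validate_dataset, write_results

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

STAGES = ("chemistry", "amphipods", "amphipod_endpoints", "tadpoles", "algae")

log = logging.getLogger("mesotox")


@dataclass
class RunConfig:
    input_path: str | None = None
    layout: str = "csv_dir"
    stages: tuple = STAGES
    out_dir: str | None = None
    seed: int = 0
    # amphipod survival model settings
    mcmc_chains: int = 4
    mcmc_warmup: int = 600
    mcmc_draws: int = 1000
    run_loo: bool = False
    loo_week: int = 6
    loo_mcmc: dict = field(default_factory=lambda: {
        "chains": 2, "warmup": 200, "draws": 400, "thin": 8})
    # community settings
    n_permutations: int = 999
    nmds_starts: int = 50
    conc_column: str = "initial_measured_conc"

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def _stage_seed(seed: int, stage: str) -> int:
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence(seed, spawn_key=(idx,)).generate_state(1)[0] % (2 ** 31))


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def _chemistry_stage(ds: Dataset, cfg: RunConfig, out: dict, report: list) -> None:
    chem = ds.chemistry
    m1h = chem[(chem["day"] == 0.0) & (chem["analyte"] == "diquat")
               & ~chem["below_detection"]].set_index("tank_id")["value"]
    nominal = ds.tanks.set_index("tank_id")["nominal_conc"]
    pon = exposure.percent_of_nominal(m1h, nominal.loc[m1h.index.intersection(nominal.index)])
    out["fate_summary"] = pd.DataFrame([pon])
    report.append(f"measured/nominal at 1 h: {pon['mean']:.1f}% +/- {pon['se']:.1f}% "
                  f"(n={pon['n']}, range {pon['min']:.1f}-{pon['max']:.1f}%)")
    fits = []
    for nominal_level, grp in ds.tanks.groupby("nominal_conc"):
        if nominal_level == 0:
            continue
        try:
            f = exposure.fit_dissipation(chem, tank_ids=grp["tank_id"])
            fits.append({"nominal_conc": nominal_level, "k_per_day": f.k_per_day,
                         "dt50_days": f.dt50_days, "r2": f.r2, "n_used": f.n_used,
                         "n_censored_excluded": f.n_censored_excluded})
        except ValueError as e:
            fits.append({"nominal_conc": nominal_level, "k_per_day": np.nan,
                         "dt50_days": np.nan, "r2": np.nan, "n_used": 0,
                         "n_censored_excluded": 0, "note": str(e)})
    out["dissipation_fits"] = pd.DataFrame(fits)
    days = sorted(chem["day"].unique())
    det = pd.concat([exposure.detection_status_table(chem, d, nominal).assign(day=d)
                     for d in days], ignore_index=True)
    out["detection_status"] = det


def _amphipods_stage(ds: Dataset, cfg: RunConfig, out: dict, report: list) -> None:
    conc = ds.conc_for_tank(cfg.conc_column)
    weeks = sorted(ds.amphipods["week"].unique())
    metr_tables, diag_rows, obs_rows = [], [], []
    seed = _stage_seed(cfg.seed, "amphipods")
    for w in weeks:
        obs = hormesis.observations_from_table(ds.amphipods, conc, week=int(w))
        post = None
        for attempt in range(3):  # lengthen chains until the R-hat gate passes
            spec = hormesis.HormesisModelSpec(
                form="quadratic", chains=cfg.mcmc_chains,
                warmup=cfg.mcmc_warmup * (attempt + 1),
                draws=cfg.mcmc_draws, thin=5 * 2 ** attempt,
                seed=seed + int(w) + 97 * attempt)
            try:
                post = hormesis.fit_hormetic_model(obs, spec)
                break
            except hormesis.ConvergenceError:
                if attempt == 2:
                    raise
        assert post is not None
        metr = hormesis.derived_metrics_table(post, int(w))
        metr_tables.append(metr)
        diag_rows.extend({"week": int(w), "parameter": k, "rhat": v,
                          "ess": post.ess[k]} for k, v in post.rhat.items())
        lc50 = metr.set_index("metric").loc["LC50"]
        report.append(f"week {w}: LC50 median {lc50['median']:.0f} ug/L "
                      f"(95% HDI {lc50['hdi_low']:.0f}-{lc50['hdi_high']:.0f})")
        # observed control survival (control tanks, this week)
        ctrl = ds.tanks.loc[ds.tanks["nominal_conc"] == 0, "tank_id"]
        sub = ds.amphipods[(ds.amphipods["week"] == w)
                           & ds.amphipods["tank_id"].isin(ctrl)]
        obs_rows.append({"week": int(w),
                         "observed_control_survival":
                             float(sub["n_alive"].sum() / sub["n_atrisk"].sum())})
    out["derived_metrics"] = pd.concat(metr_tables, ignore_index=True)
    out["lcx_estimates"] = out["derived_metrics"][
        out["derived_metrics"]["metric"].str.startswith("LC")]
    out["mcmc_diagnostics"] = pd.DataFrame(diag_rows)
    out["observed_control_survival"] = pd.DataFrame(obs_rows)
    if cfg.run_loo:
        obs = hormesis.observations_from_table(ds.amphipods, conc, week=cfg.loo_week)
        base = dict(seed=seed + 99, **cfg.loo_mcmc)
        specs = {
            "quadratic": hormesis.HormesisModelSpec(form="quadratic", **base),
            "linear": hormesis.HormesisModelSpec(form="linear", **base),
            "null": hormesis.HormesisModelSpec(form="null", **base),
        }
        comp = hormesis.exact_loo_compare(obs, specs)
        out["loo_table"] = pd.DataFrame(
            [{"model": m, "elpd": comp.elpd[m], "rank": i + 1}
             for i, m in enumerate(comp.ranking)])
        out["loo_differences"] = comp.diff_table()
        report.append(f"exact LOO ranking (week {cfg.loo_week}): "
                      + " > ".join(comp.ranking))


def _amphipod_endpoints_stage(ds: Dataset, cfg: RunConfig, out: dict, report: list) -> None:
    conc = ds.conc_for_tank(cfg.conc_column)
    week_last = int(ds.amphipods["week"].max())
    am = ds.amphipods[ds.amphipods["week"] == week_last].copy()
    am["conc"] = am["tank_id"].map(conc)
    am["treatment"] = am["tank_id"].map(ds.tanks.set_index("tank_id")["nominal_conc"])
    growth = am.dropna(subset=["wet_mass_mg"])
    growth = growth[growth["wet_mass_mg"] > 0]
    grp_sizes = growth.groupby("treatment").size()
    usable = grp_sizes[grp_sizes >= 2].index
    growth = growth[growth["treatment"].isin(usable)]
    F, df, p, pairwise = mm.anova_tukey(
        np.log2(growth["wet_mass_mg"].to_numpy()), growth["treatment"].to_numpy())
    out["growth_anova"] = pd.DataFrame(
        [{"F": F, "df_between": df[0], "df_within": df[1], "p": p}])
    out["growth_tukey"] = pairwise
    report.append(f"growth ANOVA: F({df[0]},{df[1]}) = {F:.2f}, p = {p:.3g}")

    rep = am[am["n_alive"] > 0].copy()
    rep["trials"] = rep["n_alive"] + rep["n_juveniles"]
    seed = _stage_seed(cfg.seed, "amphipod_endpoints")
    null_spec = mm.ModelSpec(response=("n_juveniles", "trials"), family="binomial",
                             fixed=(), group=None)
    conc_spec = mm.ModelSpec(response=("n_juveniles", "trials"), family="binomial",
                             fixed=(("conc", "log2_plus1"),), group=None)
    fits = {"null": mm.fit_binomial_glmm(null_spec, rep, seed=seed),
            "treatment": mm.fit_binomial_glmm(conc_spec, rep, seed=seed + 1)}
    out["reproduction_aicc"] = mm.aicc_compare(fits)
    out["reproduction_coefficients"] = fits["treatment"].coefficients
    delta = float(out["reproduction_aicc"]["delta_aicc"].max())
    best = out["reproduction_aicc"].iloc[0]["model"]
    report.append(f"reproduction GLMM: best = {best} (dAICc = {delta:.2f})")


def _tadpoles_stage(ds: Dataset, cfg: RunConfig, out: dict, report: list) -> None:
    conc = ds.conc_for_tank(cfg.conc_column)
    td = ds.tadpoles.copy()
    td["conc"] = td["tank_id"].map(conc)
    td["survived_int"] = td["survived"].astype(int)
    seed = _stage_seed(cfg.seed, "tadpoles")

    # survival GLMM: null / linear / quadratic on log2(conc + 1)
    td["x"] = np.log2(td["conc"] + 1.0)
    specs = {
        "null": mm.ModelSpec(response=("survived_int", 1), family="binomial",
                             fixed=(), group="tank_id"),
        "linear": mm.ModelSpec(response=("survived_int", 1), family="binomial",
                               fixed=(("conc", "log2_plus1"),), group="tank_id"),
        "quadratic": mm.ModelSpec(response=("survived_int", 1), family="binomial",
                                  fixed=(("x", "poly2"),), group="tank_id"),
    }
    fits = {k: mm.fit_binomial_glmm(s, td, seed=seed) for k, s in specs.items()}
    out["tadpole_survival_aicc"] = mm.aicc_compare(fits)
    best_name = out["tadpole_survival_aicc"].iloc[0]["model"]
    lin = fits["linear"]
    pred = mm.predict_conditional(
        lin, pd.DataFrame({"conc": [0.0, float(td["conc"].max())]}))
    out["tadpole_survival_predictions"] = pd.DataFrame({
        "conc": [0.0, float(td["conc"].max())],
        "survival": pred,
    })
    overall = float(td["survived"].mean())
    out["tadpole_survival_overall"] = pd.DataFrame(
        [{"overall_survival": overall, "n": len(td)}])
    report.append(
        f"tadpole survival: overall {100 * overall:.1f}%; best model {best_name}; "
        f"conditional predictions {100 * pred[0]:.1f}% (control) -> "
        f"{100 * pred[1]:.1f}% (top)")

    surv = td[td["survived"]].copy()
    surv["dev_rate"] = mm.development_rate(surv["gosner_stage"], surv["days_elapsed"])
    dev_fit = mm.fit_lmm(mm.ModelSpec(response="dev_rate", fixed=(("conc", "log2_plus1"),),
                                      group="tank_id", estimation="REML",
                                      log2_response=True), surv)
    out["development_rate_coefficients"] = dev_fit.coefficients
    by_level = (surv.assign(treated=surv["conc"] > 0)
                .groupby("treated")["dev_rate"].mean())
    out["development_rate_means"] = pd.DataFrame({
        "group": ["control", "treated"],
        "mean_stages_per_day": [float(by_level.get(False, np.nan)),
                                float(by_level.get(True, np.nan))],
    })
    report.append("development rate (stages/day): control "
                  f"{by_level.get(False, np.nan):.3f}, treated "
                  f"{by_level.get(True, np.nan):.3f}")

    surv["stage_c"] = surv["gosner_stage"]
    mass_fit = mm.fit_lmm(mm.ModelSpec(
        response="wet_mass_g", fixed=(("conc", "log2_plus1"), ("stage_c", "poly2")),
        group="tank_id", estimation="REML", log2_response=True), surv)
    b = mass_fit.coef("log2(conc+1)")
    row = mass_fit.coefficients.set_index("term").loc["log2(conc+1)"]
    out["mass_coefficients"] = mass_fit.coefficients
    out["mass_effect"] = pd.DataFrame([{
        "pct_per_doubling": 100 * (2.0 ** b - 1.0),
        "ci_low_pct": 100 * (2.0 ** row["ci_low"] - 1.0),
        "ci_high_pct": 100 * (2.0 ** row["ci_high"] - 1.0),
    }])
    report.append(f"mass: {100 * (2.0 ** b - 1.0):+.2f}% per concentration doubling")

    surv["hsi"] = mm.hepatosomatic_index(surv["wet_mass_g"], surv["liver_mass_g"])
    hsi_fit = mm.fit_lmm(mm.ModelSpec(
        response="hsi", fixed=(("conc", "log2_plus1"), ("stage_c", "poly2")),
        group="tank_id", estimation="REML", log2_response=True), surv)
    out["hsi_coefficients"] = hsi_fit.coefficients

    try:
        sex_fit = mm.fit_sex_ratio_glmm(ds.tadpoles, conc, seed=seed + 5)
        out["sex_ratio_coefficients"] = sex_fit.coefficients
        if sex_fit.notes:
            report.append("sex ratio: " + "; ".join(sex_fit.notes))
    except ValueError as e:
        report.append(f"sex ratio model skipped: {e}")

    st = ds.stress.copy()
    st["treatment"] = st["tank_id"].map(ds.tanks.set_index("tank_id")["nominal_conc"])
    rows = []
    for col, label in (("hne_ug_g", "HNE"), ("protein_carbonyl_nmol_mg", "protein_carbonyl")):
        H, p = mm.kruskal_wallis(st[col].to_numpy(), st["treatment"].to_numpy())
        est, lo, hi = mm.bca_bootstrap_ci(st[col].to_numpy(), np.mean,
                                          B=9999, seed=seed + 10)
        rows.append({"marker": label, "kw_H": H, "kw_p": p,
                     "mean": est, "bca_low": lo, "bca_high": hi})
        report.append(f"{label}: Kruskal-Wallis p = {p:.2f}; "
                      f"mean {est:.1f} (95% BCa CI {lo:.1f}-{hi:.1f})")
    out["oxidative_stress"] = pd.DataFrame(rows)


def _algae_stage(ds: Dataset, cfg: RunConfig, out: dict, report: list) -> None:
    treatment = ds.tanks.set_index("tank_id")["nominal_conc"]
    seed = _stage_seed(cfg.seed, "algae")
    al = ds.algae
    days = sorted(al["day"].unique())

    H_rows = []
    for d in days:
        cm = community.community_matrix_from_table(al, d, treatment)
        for tank in cm.counts.index:
            H_rows.append({"tank_id": tank, "day": d,
                           "treatment": float(treatment[tank]),
                           "H": community.shannon_index(cm.counts.loc[tank].to_numpy())})
    H = pd.DataFrame(H_rows)
    out["shannon_diversity"] = H
    cells, contrasts = community.diversity_lm_contrasts(
        H["H"], H["treatment"], H["day"], control_label=0.0)
    out["diversity_contrasts"] = contrasts

    perm_rows, nmds_rows, disp_rows = [], [], []
    for i, d in enumerate(days):
        cm = community.community_matrix_from_table(al, d, treatment)
        dist = community.bray_curtis(cm.counts)
        res = community.permanova(dist, cm.treatment, n_perm=cfg.n_permutations,
                                  seed=seed + i)
        disp_p, disp = community.dispersion_homogeneity(
            dist, cm.treatment, n_perm=cfg.n_permutations, seed=seed + 50 + i)
        ord_res = community.nmds(dist, k=2, n_starts=cfg.nmds_starts, seed=seed + 100 + i)
        perm_rows.append({"day": d, "pseudo_F": res.pseudo_f, "R2": res.r2,
                          "p": res.p, "n_permutations": res.n_permutations,
                          "dispersion_p": disp_p})
        nmds_rows.append({"day": d, "stress": ord_res.stress,
                          "converged": ord_res.converged})
        out[f"nmds_coordinates_day{int(d)}"] = ord_res.coordinates.reset_index(
            names="tank_id")
        report.append(f"day {d:g}: PERMANOVA R2 = {res.r2:.2f}, p = {res.p:.3f} "
                      f"(dispersion p = {disp_p:.2f}); NMDS stress = {ord_res.stress:.3f}")
    out["permanova"] = pd.DataFrame(perm_rows)
    out["nmds_summary"] = pd.DataFrame(nmds_rows)

    post = [d for d in days if d > 0]
    if post:
        from .simulate import TOLERANT_TAXA
        cm = community.community_matrix_from_table(al, post[0], treatment)
        present = [t for t in TOLERANT_TAXA if t in cm.counts.columns]
        if present:
            share = community.dominance_share(cm, present)
            out["dominant_taxa_share"] = share.rename("share").reset_index()

    chl = ds.chlorophyll.merge(
        al.groupby(["tank_id", "day"])["biomass_mg_m3"].sum().reset_index(),
        on=["tank_id", "day"], how="inner")
    if len(chl) >= 3:
        r2, p = community.chlorophyll_biomass_r2(chl["chl_a_ug_L"], chl["biomass_mg_m3"])
        out["chlorophyll_biomass"] = pd.DataFrame([{"r2": r2, "p": p}])


_STAGE_FUNCS = {
    "chemistry": _chemistry_stage,
    "amphipods": _amphipods_stage,
    "amphipod_endpoints": _amphipod_endpoints_stage,
    "tadpoles": _tadpoles_stage,
    "algae": _algae_stage,
}


def run_pipeline(dataset: Dataset | str | Path, config: RunConfig | None = None
                 ) -> tuple[dict[str, pd.DataFrame], str]:
    """Run the requested stages in order; returns (result tables, text report).

    Refuses to fit anything when the dataset fails validation.  When
    ``config.out_dir`` is set, tables and a manifest are written there.
    """
    cfg = config or RunConfig()
    if not isinstance(dataset, Dataset):
        dataset = read_dataset(dataset, layout=cfg.layout)
    rep = validate_dataset(dataset)
    if not rep.ok:
        raise ValueError("dataset failed validation:\n" + "\n".join(rep.errors))

    out: dict[str, pd.DataFrame] = {}
    report: list[str] = [f"mesotox analysis (seed {cfg.seed})"]
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        log.info("running stage %s", stage)
        try:
            _STAGE_FUNCS[stage](dataset, cfg, out, report)
        except Exception as e:
            raise PipelineError(stage, e) from e
    text = "\n".join(report)
    if cfg.out_dir:
        write_results(out, cfg.out_dir, config=asdict(cfg), seed=cfg.seed)
        Path(cfg.out_dir, "report.txt").write_text(text + "\n")
    return out, text
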