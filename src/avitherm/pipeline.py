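"""End-to-end orchestration: simulate -> process -> fit -> model -> report.

One :func:`run_pipeline` call generates a synthetic population, forward-
models and reduces its respirometry traces (or shortcuts straight to
steady-state profiles), fits per-individual breakpoint models, computes
energy budgets and relative-size indices, ranks the candidate GLMs for
every thermoregulatory response, and writes CSV tables, SVG figures and
a JSON summary stamped with the seed and a configuration hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import energetics, inference, io, segmented
from .config import flatten_config
from .morphometrics import mass_independent
from .respirometry import ThermalProfile, reduce_trace
from .synthetic import (GeneratorConfig, TraceConfig, generate_population,
                        generate_profiles, generate_trace,
                        trace_config_for_temperature, _individual_rng)

__all__ = ["RunConfig", "run_pipeline", "fit_population_tnz",
           "build_analysis_frame", "run_model_selection"]

HOT_TEMPS = (35.0, 37.0, 40.0)


@dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    outdir: Path = Path("avitherm_run")
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    trace: TraceConfig = field(default_factory=TraceConfig)
    grid_step: float = 0.05
    stability_frac: float = 0.05
    delta_cut: float = 2.0
    use_traces: bool = True
    write_traces: bool = False
    make_figures: bool = True
    seed: int = 0

    def config_hash(self) -> str:
        flat = flatten_config(self.generator, "generator.")
        flat.update(flatten_config(self.trace, "trace."))
        flat.update({"grid_step": str(self.grid_step),
                     "stability_frac": str(self.stability_frac),
                     "delta_cut": str(self.delta_cut),
                     "use_traces": str(self.use_traces),
                     "seed": str(self.seed)})
        text = "\n".join(f"{k}={v}" for k, v in sorted(flat.items()))
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def simulate_steady_states(population, profiles, tconfig: TraceConfig,
                           seed: int, stability_frac: float = 0.05,
                           traces_dir: Path | None = None) -> pd.DataFrame:
    """Forward-model a trace per (individual, Ta) and reduce it back.

    The animal-segment count is raised automatically when the default
    schedule would not leave a full stable window after chamber washout.
    """
    measures = []
    for i, (record, profile) in enumerate(zip(population, profiles)):
        for j, ta in enumerate(profile.temps):
            tc = trace_config_for_temperature(float(ta), tconfig)
            needed = 5.0 * tc.washout_tau + 2.0 * tc.channel_dwell
            total = tc.n_animal_segments * tc.channel_dwell
            if total < needed:
                extra = int(np.ceil((needed - total) / tc.channel_dwell))
                tc = dataclasses.replace(
                    tc, n_animal_segments=tc.n_animal_segments + extra)
            rng = _individual_rng(seed, i, stream=100 + j)
            trace = generate_trace(record, float(ta),
                                   float(profile.vo2[j]),
                                   float(profile.ewl[j]), tc, rng=rng)
            if traces_dir is not None:
                io.write_trace(trace, traces_dir / f"{record.id}_{ta:g}C.csv")
            measures.append(reduce_trace(trace,
                                         stability_frac=stability_frac))
    return io.measures_to_frame(measures)


def fit_population_tnz(profiles, grid_step: float = 0.05,
                       tnz_bounds=segmented.DEFAULT_TNZ_BOUNDS,
                       ewl_bounds=segmented.DEFAULT_EWL_BOUNDS,
                       ) -> pd.DataFrame:
    """Per-individual two-breakpoint VO2 and one-breakpoint EWL fits.

    Returns one row per individual with NaN for quantities whose fit did
    not converge.
    """
    rows = []
    for profile in profiles:
        row = {"id": profile.individual_id, "tlc": np.nan, "tuc": np.nan,
               "breadth": np.nan, "bmr": np.nan, "ewl_inflection": np.nan,
               "tlc_se": np.nan, "tuc_se": np.nan,
               "ewl_inflection_se": np.nan, "flags": ""}
        fit2 = segmented.fit_piecewise(profile.temps, profile.vo2,
                                       n_breakpoints=2, bounds=tnz_bounds,
                                       grid_step=grid_step)
        if fit2.converged:
            est = segmented.tnz_from_fit(fit2, profile)
            row.update(tlc=est.tlc, tuc=est.tuc, breadth=est.breadth,
                       bmr=est.bmr, tlc_se=est.tlc_se, tuc_se=est.tuc_se,
                       flags=";".join(est.flags))
        else:
            row["flags"] = f"tnz:{fit2.message}"
        fit1 = segmented.fit_piecewise(profile.temps, profile.ewl,
                                       n_breakpoints=1, bounds=ewl_bounds,
                                       grid_step=grid_step)
        if fit1.converged:
            psi, se = segmented.ewl_inflection(fit1)
            row["ewl_inflection"] = psi
            row["ewl_inflection_se"] = se
        else:
            row["flags"] = (row["flags"] + ";" if row["flags"] else "") + \
                f"ewl:{fit1.message}"
        rows.append(row)
    return pd.DataFrame(rows)


def build_analysis_frame(population, profiles, tnz_frame: pd.DataFrame,
                         ) -> pd.DataFrame:
    """Assemble the per-individual frame the candidate models consume.

    Columns: sex, Mb, the two relative-size indices, the fitted TNZ
    quantities, log cooling efficiency at the hot temperatures, and
    mass-independent VO2/EWL at every test temperature.
    """
    ind = io.individuals_to_frame(population)[
        ["id", "sex", "mb_g", "bill_index", "tarsi_index"]]
    ind = ind.rename(columns={"mb_g": "Mb"})
    frame = ind.merge(tnz_frame.drop(columns=["flags"], errors="ignore"),
                      on="id", how="left")

    ratio_rows = {}
    for profile in profiles:
        for budget in energetics.budgets_from_profile(profile, HOT_TEMPS):
            ratio_rows.setdefault(
                f"log_ehl_mhp_{budget.ta:g}", {})[profile.individual_id] = \
                np.log(budget.ratio)
    for col, values in ratio_rows.items():
        frame[col] = frame["id"].map(values)

    temps = profiles[0].temps
    mb = frame.set_index("id")["Mb"]
    for j, ta in enumerate(temps):
        ids = [p.individual_id for p in profiles]
        vo2 = np.array([p.vo2[j] for p in profiles])
        ewl = np.array([p.ewl[j] for p in profiles])
        masses = mb.loc[ids].to_numpy()
        frame[f"mi_vo2_{ta:g}"] = frame["id"].map(
            dict(zip(ids, mass_independent(vo2, masses))))
        frame[f"mi_ewl_{ta:g}"] = frame["id"].map(
            dict(zip(ids, mass_independent(ewl, masses))))
    return frame


def run_model_selection(analysis: pd.DataFrame, delta_cut: float = 2.0,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """AICc tables and averaged coefficients for every response.

    Cooling-efficiency responses include body mass as a covariate; all
    others use the standard five-term pool.
    """
    responses = [c for c in analysis.columns
                 if c.startswith(("tlc", "tuc", "breadth", "ewl_inflection",
                                  "log_ehl_mhp", "mi_"))
                 and not c.endswith("_se")]
    tables, coefs = [], []
    for response in responses:
        terms = inference.DEFAULT_TERMS
        if response.startswith("log_ehl_mhp"):
            terms = terms + ("Mb",)
        table = inference.rank_models(analysis, response, terms=terms)
        shown = table.top_set(delta_cut).table.copy()
        shown.insert(0, "response", response)
        tables.append(shown)
        avg = inference.model_average(table, delta_cut=delta_cut)
        block = avg.table.copy()
        block.insert(0, "term", block.index)
        block.insert(0, "response", response)
        coefs.append(block.reset_index(drop=True))
    return pd.concat(tables, ignore_index=True), \
        pd.concat(coefs, ignore_index=True)


def _figures(profiles, tnz_summary: pd.DataFrame, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    temps = np.concatenate([p.temps for p in profiles])
    vo2 = np.concatenate([p.vo2 for p in profiles])
    ewl = np.concatenate([p.ewl for p in profiles])

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(temps, vo2, "o", ms=3, alpha=0.4, color="tab:blue")
    for name, style in (("tlc", "--"), ("tuc", "--")):
        if name in tnz_summary.index:
            ax.axvline(tnz_summary.loc[name, "mean"], ls=style, color="gray")
    ax.set_xlabel("Ambient temperature (degC)")
    ax.set_ylabel("VO2 (ml O2 min$^{-1}$)")
    ax.set_title("Metabolic rate vs Ta (dashed: mean Tlc, Tuc)")
    fig.tight_layout()
    fig.savefig(outdir / "vo2_vs_ta.svg")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(temps, ewl, "o", ms=3, alpha=0.4, color="tab:red")
    if "ewl_inflection" in tnz_summary.index:
        ax.axvline(tnz_summary.loc["ewl_inflection", "mean"], ls="--",
                   color="gray")
    ax.set_xlabel("Ambient temperature (degC)")
    ax.set_ylabel("EWL (mg h$^{-1}$)")
    ax.set_title("Evaporative water loss vs Ta (dashed: mean inflection)")
    fig.tight_layout()
    fig.savefig(outdir / "ewl_vs_ta.svg")
    plt.close(fig)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle under ``outdir``.

    Returns the in-memory tables keyed by stage name.  Identical config
    and seed produce byte-identical CSV outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    generator = dataclasses.replace(config.generator, seed=config.seed)

    population = generate_population(generator)
    profiles = generate_profiles(population, generator)
    io.write_individuals(population, outdir / "individuals.csv")
    io.write_profiles(profiles, outdir / "profiles.csv")

    if config.use_traces:
        traces_dir = None
        if config.write_traces:
            traces_dir = outdir / "traces"
            traces_dir.mkdir(exist_ok=True)
        steady = simulate_steady_states(population, profiles, config.trace,
                                        seed=config.seed,
                                        stability_frac=config.stability_frac,
                                        traces_dir=traces_dir)
        steady.to_csv(outdir / "steady_state.csv", index=False)
        measured_profiles = io.frame_to_profiles(
            steady.rename(columns={}))
    else:
        measured_profiles = profiles

    tnz_frame = fit_population_tnz(measured_profiles,
                                   grid_step=config.grid_step)
    tnz_frame.to_csv(outdir / "tnz_individual.csv", index=False)
    converged = tnz_frame.dropna(subset=["tlc", "tuc"])
    summary = segmented.population_summary(
        converged, columns=["tlc", "tuc", "breadth", "bmr"])
    infl = tnz_frame.dropna(subset=["ewl_inflection"])
    summary.loc["ewl_inflection"] = segmented.population_summary(
        infl, columns=["ewl_inflection"]).loc["ewl_inflection"]
    summary.index.name = "quantity"
    summary.to_csv(outdir / "tnz_population.csv")

    budgets = [b for p in measured_profiles
               for b in energetics.budgets_from_profile(p, HOT_TEMPS)]
    budget_frame = pd.DataFrame([{
        "id": b.individual_id, "ta_c": b.ta, "mhp_w": b.mhp,
        "ehl_w": b.ehl, "ehl_mhp": b.ratio} for b in budgets])
    budget_frame.to_csv(outdir / "energy_budget.csv", index=False)

    analysis = build_analysis_frame(population, measured_profiles, tnz_frame)
    analysis.to_csv(outdir / "analysis_frame.csv", index=False)
    model_tables, averaged = run_model_selection(analysis, config.delta_cut)
    model_tables.to_csv(outdir / "model_selection.csv", index=False)
    averaged.to_csv(outdir / "averaged_coefficients.csv", index=False)

    if config.make_figures:
        _figures(measured_profiles, summary, outdir)

    meta = {"seed": config.seed, "config_hash": config.config_hash(),
            "n_individuals": len(population),
            "n_converged_tnz": int(len(converged)),
            "population_summary": {
                q: {"mean": float(summary.loc[q, "mean"]),
                    "se": float(summary.loc[q, "se"])}
                for q in summary.index}}
    (outdir / "summary.json").write_text(json.dumps(meta, indent=2,
                                                    sort_keys=True))
    return {"population": population, "profiles": measured_profiles,
            "tnz_individual": tnz_frame, "tnz_population": summary,
            "energy_budget": budget_frame, "analysis": analysis,
            "model_selection": model_tables, "averaged": averaged,
            "meta": meta}
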