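"""End-to-end pipeline: simulate/load -> flux summaries -> tracer
calibration -> Rayleigh fit -> isotopocule map -> report.

Each run writes its artefacts plus a manifest (config hash, seed, package
version) into the output directory, and is idempotent for a given
config + seed.  Stages never mutate one another's outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, datasets
from .fluxes import (CO2_BASELINE_KG_HA_H, DEFAULT_WINDOWS, GasFluxSeries,
                     cumulative_emission, product_ratio, subtract_baseline)
from .isotopocules import EndmemberMap, IsotopocouleRecord, classify_sp_o18
from .rayleigh import fit_nie, simulate_one_pool, simulate_two_pool
from .synthetic import (SyntheticExperiment, SyntheticScenario,
                        default_parameters, generate_experiment)
from .tracer import contribution_series, fit_cubic_mixing

log = logging.getLogger(__name__)

#: the standard between-treatment cumulative-emission ratios reported for
#: this design: (quantity, numerator treatment, denominator treatment).
FOLD_CHANGE_DEFS: tuple[tuple[str, str, str], ...] = (
    ("NO", "3c", "1c"),
    ("N2O", "3c", "1c"),
    ("CO2", "3c", "1c"),
    ("CO2", "3c", "control"),
    ("Total N", "3c", "1c"),
    ("Total N", "3c", "control"),
)


def fold_changes(cumulative: pd.DataFrame,
                 defs: tuple[tuple[str, str, str], ...] = FOLD_CHANGE_DEFS
                 ) -> pd.DataFrame:
    """Between-treatment ratios of cumulative emissions.

    ``cumulative`` has gas rows (including "Total N") and treatment
    columns, as returned by :func:`cumulative_table` or
    :func:`n2opools.datasets.reference_cumulative_emissions`.
    """
    rows = []
    for gas, num, den in defs:
        rows.append({"quantity": gas, "numerator": num, "denominator": den,
                     "ratio": float(cumulative.loc[gas, num] / cumulative.loc[gas, den])})
    return pd.DataFrame(rows)


def cumulative_table(fluxes: dict[str, dict[str, GasFluxSeries]],
                     windows: dict[str, tuple[float, float]] | None = None,
                     co2_baseline_kg_ha_h: float = CO2_BASELINE_KG_HA_H
                     ) -> pd.DataFrame:
    """Treatment-mean cumulative emissions over the per-gas windows.

    Returns gas rows (plus "Total N" = NO + N2O + N2) by treatment columns,
    averaging vessels within a treatment.  The constant respiration
    baseline is subtracted from CO2 before integration (pass 0 to keep it),
    so CO2 totals reflect amendment-attributable emissions; other gases
    take no baseline.
    """
    windows = windows or DEFAULT_WINDOWS
    per_vessel: list[dict] = []
    for vessel_id, gases in fluxes.items():
        treatment = next(iter(gases.values())).vessel.treatment
        row = {"vessel_id": vessel_id, "treatment": treatment}
        for gas, series in gases.items():
            if gas == "CO2" and co2_baseline_kg_ha_h:
                series = subtract_baseline(series, co2_baseline_kg_ha_h)
            lo, hi = windows[gas]
            row[gas] = cumulative_emission(series, lo, hi).total
        row["Total N"] = row.get("NO", 0) + row.get("N2O", 0) + row.get("N2", 0)
        per_vessel.append(row)
    df = pd.DataFrame(per_vessel)
    means = df.groupby("treatment")[["NO", "N2O", "N2", "CO2", "Total N"]].mean()
    return means.T


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: Path
    mode: str = "synthetic"            # "synthetic" | "measured"
    seed: int = 0
    model: str = "two-pool"            # "two-pool" | "one-pool"
    reduction_form: str = "closed"     # "closed" | "open"
    windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WINDOWS))
    # measured-mode inputs
    flux_csv: Path | None = None           # long: vessel_id,treatment,gas,time_days,flux
    labelled_csv: Path | None = None       # vessel_id,treatment,time_days,at_percent_15N
    isotopocule_csv: Path | None = None    # treatment,time_days,delta_bulk[,delta_alpha|sp],delta_o18
    cumulative_csv: Path | None = None     # gas x treatment table (bypasses integration)
    map_config: Path | None = None         # EndmemberMap JSON

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a YAML or JSON config file."""
        path = Path(path)
        raw = yaml.safe_load(path.read_text()) or {}
        raw.update(overrides)
        for key in ("outdir", "flux_csv", "labelled_csv", "isotopocule_csv",
                    "cumulative_csv", "map_config"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        if "windows" in raw:
            raw["windows"] = {g: tuple(w) for g, w in raw["windows"].items()}
        return cls(**raw)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: (str(v) if isinstance(v, Path) else v) for k, v in d.items()}


def _write_manifest(config: RunConfig, artefacts: dict[str, Path]) -> Path:
    cfg = config.to_jsonable()
    digest = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()
    manifest = {
        "package": "n2opools",
        "version": __version__,
        "seed": config.seed,
        "config": cfg,
        "config_sha256": digest,
        "artefacts": {k: str(v.name) for k, v in artefacts.items()},
    }
    path = Path(config.outdir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def _flux_long_df(fluxes: dict[str, dict[str, GasFluxSeries]]) -> pd.DataFrame:
    rows = []
    for vessel_id, gases in fluxes.items():
        for gas, series in gases.items():
            rows.append(pd.DataFrame({
                "vessel_id": vessel_id,
                "treatment": series.vessel.treatment if series.vessel else "",
                "gas": gas, "time_days": series.times, "flux": series.fluxes}))
    return pd.concat(rows, ignore_index=True)


def read_flux_csv(path: Path) -> dict[str, dict[str, GasFluxSeries]]:
    """Read the long-format flux CSV the pipeline writes/accepts."""
    from .vessels import VesselConfig
    df = pd.read_csv(path)
    out: dict[str, dict[str, GasFluxSeries]] = {}
    for (vessel_id, gas), grp in df.groupby(["vessel_id", "gas"], sort=True):
        grp = grp.sort_values("time_days")
        treatment = str(grp.treatment.iloc[0])
        vessel = VesselConfig.from_treatment(str(vessel_id), treatment)
        out.setdefault(str(vessel_id), {})[str(gas)] = GasFluxSeries(
            gas=str(gas), times=grp.time_days.to_numpy(),
            fluxes=grp.flux.to_numpy(), vessel=vessel)
    return out


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the configured stages; returns the artefact paths."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artefacts: dict[str, Path] = {}

    experiment: SyntheticExperiment | None = None
    if config.mode == "synthetic":
        scenario = SyntheticScenario(seed=config.seed)
        experiment = generate_experiment(scenario)
        fluxes = experiment.fluxes
        p = outdir / "fluxes.csv"
        _flux_long_df(fluxes).to_csv(p, index=False)
        artefacts["fluxes"] = p
    elif config.mode == "measured":
        if config.flux_csv is None and config.cumulative_csv is None:
            raise ValueError("measured mode needs flux_csv or cumulative_csv")
        fluxes = read_flux_csv(config.flux_csv) if config.flux_csv else {}
    else:
        raise ValueError(f"unknown mode {config.mode!r}")

    # --- flux summaries ---------------------------------------------------
    if config.cumulative_csv is not None:
        cum = pd.read_csv(config.cumulative_csv, index_col=0)
    elif fluxes:
        cum = cumulative_table(fluxes, config.windows)
    else:
        cum = None
    if cum is not None:
        p = outdir / "cumulative.csv"
        cum.to_csv(p)
        artefacts["cumulative"] = p
        fc = fold_changes(cum)
        p = outdir / "fold_changes.csv"
        fc.to_csv(p, index=False)
        artefacts["fold_changes"] = p

    if fluxes:
        ratios = []
        for vessel_id, gases in fluxes.items():
            if "N2O" in gases and "N2" in gases:
                r = product_ratio(gases["N2O"], gases["N2"])
                ratios.append(pd.DataFrame({
                    "vessel_id": vessel_id, "time_days": r.times,
                    "r_n2o": r.r_n2o, "defined": r.defined}))
        if ratios:
            p = outdir / "product_ratio.csv"
            pd.concat(ratios, ignore_index=True).to_csv(p, index=False)
            artefacts["product_ratio"] = p

    # --- tracer partitioning ---------------------------------------------
    mixing_fns = {}
    contrib_rows = []
    labelled_series: dict[str, tuple[str, object]] = {}
    if experiment is not None:
        for vessel in experiment.scenario.vessels:
            if vessel.vessel_id in experiment.labelled:
                labelled_series[vessel.vessel_id] = (
                    vessel.treatment, experiment.labelled[vessel.vessel_id])
    elif config.labelled_csv is not None:
        from .tracer import AtomFractionSeries
        df = pd.read_csv(config.labelled_csv)
        for vessel_id, grp in df.groupby("vessel_id", sort=True):
            grp = grp.sort_values("time_days")
            labelled_series[str(vessel_id)] = (
                str(grp.treatment.iloc[0]),
                AtomFractionSeries(times=grp.time_days.to_numpy(),
                                   at_percent=grp.at_percent_15N.to_numpy(),
                                   vessel_id=str(vessel_id)))
    if labelled_series:
        by_treatment: dict[str, list] = {}
        for vessel_id, (treatment, series) in labelled_series.items():
            contrib = contribution_series(series, treatment)
            by_treatment.setdefault(treatment, []).append(contrib)
            contrib_rows.append(pd.DataFrame({
                "vessel_id": vessel_id, "treatment": treatment,
                "time_days": contrib.times,
                "percent_fertiliser": contrib.percent_fertiliser}))
        from .tracer import SourceContributionSeries
        for treatment, contribs in sorted(by_treatment.items()):
            times = contribs[0].times
            mean_pct = np.mean([c.percent_fertiliser for c in contribs], axis=0)
            pooled = SourceContributionSeries(times=times,
                                              percent_fertiliser=mean_pct,
                                              treatment=treatment)
            mixing_fns[treatment] = fit_cubic_mixing(pooled)
        p = outdir / "contributions.csv"
        pd.concat(contrib_rows, ignore_index=True).to_csv(p, index=False)
        artefacts["contributions"] = p
        p = outdir / "mixing.json"
        p.write_text(json.dumps(
            {tr: {"a3": fn.a3, "a2": fn.a2, "a1": fn.a1, "a0": fn.a0,
                  "r_squared": fn.r_squared} for tr, fn in mixing_fns.items()},
            indent=2, sort_keys=True))
        artefacts["mixing"] = p

    # --- Rayleigh fit ------------------------------------------------------
    if fluxes and (experiment is not None or config.isotopocule_csv is not None):
        fit_out = {}
        traj_rows = []
        if experiment is not None:
            iso_by_treatment: dict[str, dict[float, list[float]]] = {}
            for vessel in experiment.scenario.vessels:
                recs = experiment.isotopocules.get(vessel.vessel_id)
                if not recs or vessel.treatment not in ("1c", "3c"):
                    continue
                for rec in recs:
                    iso_by_treatment.setdefault(vessel.treatment, {}) \
                        .setdefault(rec.time, []).append(rec.delta_bulk)
            obs = {tr: (np.array(sorted(d)), np.array([np.mean(d[k]) for k in sorted(d)]))
                   for tr, d in iso_by_treatment.items()}
        else:
            df = pd.read_csv(config.isotopocule_csv)
            obs = {}
            for treatment, grp in df.groupby("treatment", sort=True):
                if treatment not in ("1c", "3c"):
                    continue
                grp = grp.sort_values("time_days")
                obs[str(treatment)] = (grp.time_days.to_numpy(),
                                       grp.delta_bulk.to_numpy())
        for treatment, (obs_t, obs_d) in sorted(obs.items()):
            vsel = [v for v in fluxes if fluxes[v]["N2O"].vessel.treatment == treatment]
            if not vsel:
                continue
            t_grid = fluxes[vsel[0]]["N2O"].times
            mean_n2o = np.mean([fluxes[v]["N2O"].fluxes for v in vsel], axis=0)
            mean_n2 = np.mean([fluxes[v]["N2"].fluxes for v in vsel], axis=0)
            proto = fluxes[vsel[0]]["N2O"].vessel
            n2o = GasFluxSeries("N2O", t_grid, mean_n2o, proto)
            n2 = GasFluxSeries("N2", t_grid, mean_n2, proto)
            params = default_parameters(treatment)
            mixing = mixing_fns.get(treatment,
                                    datasets.CALIBRATED_MIXING.get(treatment))
            use_mixing = mixing if config.model == "two-pool" else None
            result = fit_nie(obs_t, obs_d, n2o, n2, use_mixing, params.pools,
                             reduction_form=config.reduction_form,
                             seed=config.seed)
            fit_out[treatment] = {
                "model": config.model,
                "eta_production": result.params.eta_production,
                "eta_reduction": result.params.eta_reduction,
                "r_squared": result.r_squared,
                "n_observations": result.n_observations,
                "converged": result.converged,
                "n_starts": result.n_starts,
            }
            if config.model == "two-pool":
                traj = simulate_two_pool(result.params, n2o, n2, mixing,
                                         config.reduction_form)
            else:
                traj = simulate_one_pool(result.params, n2o, n2,
                                         config.reduction_form)
            traj_rows.append(pd.DataFrame({
                "treatment": treatment, "time_days": traj.times,
                "f_pool1": traj.pool1.f_substrate,
                "f_pool2": (traj.pool2.f_substrate if traj.pool2 is not None
                            else np.nan),
                "x1": traj.mixing_fraction,
                "delta_bulk_mixed": traj.delta_bulk_mixed}))
        if fit_out:
            p = outdir / "rayleigh_fit.json"
            p.write_text(json.dumps(fit_out, indent=2, sort_keys=True))
            artefacts["rayleigh_fit"] = p
            p = outdir / "trajectory.csv"
            pd.concat(traj_rows, ignore_index=True).to_csv(p, index=False)
            artefacts["trajectory"] = p

    # --- isotopocule map ---------------------------------------------------
    iso_records: list[tuple[str, IsotopocouleRecord]] = []
    if experiment is not None:
        for vessel_id, recs in sorted(experiment.isotopocules.items()):
            iso_records.extend((vessel_id, r) for r in recs)
    elif config.isotopocule_csv is not None:
        df = pd.read_csv(config.isotopocule_csv)
        for _, row in df.iterrows():
            if "sp" in df.columns:
                rec = IsotopocouleRecord.from_sp(row.time_days, row.delta_bulk,
                                                 row.sp, row.delta_o18)
            else:
                rec = IsotopocouleRecord.from_alpha(row.time_days, row.delta_bulk,
                                                    row.delta_alpha, row.delta_o18)
            iso_records.append((str(row.treatment), rec))
    if iso_records:
        emap = EndmemberMap.from_json(config.map_config) if config.map_config else None
        rows = []
        for key, rec in iso_records:
            row = {"series": key, "time_days": rec.time,
                   "delta_bulk": rec.delta_bulk, "delta_alpha": rec.delta_alpha,
                   "delta_beta": rec.delta_beta, "delta_o18": rec.delta_o18,
                   "sp": rec.sp}
            if emap is not None:
                cls = classify_sp_o18(rec, emap)
                row["label"] = cls.label
                row["reduction_progress"] = cls.reduction_progress
            rows.append(row)
        p = outdir / "isotopocules.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        artefacts["isotopocules"] = p

    artefacts["manifest"] = _write_manifest(config, artefacts)
    log.info("pipeline wrote %d artefacts to %s", len(artefacts), outdir)
    return artefacts
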