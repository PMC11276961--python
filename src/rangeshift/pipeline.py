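"""End-to-end study orchestration.

``run_pipeline`` executes, for every configured species: occurrence
sampling → uncertainty filtering → 5-km spatial thinning → jackknife +
collinearity predictor selection → gated ensemble fitting → per-scenario
suitability prediction → MSS binarization → range dynamics; and across
species: OIHS/OIPR/expanding-range overlap maps, change maps, the fraction
of land with increasing overlap, hotspot masks, and the paired t-test of
current vs future range sizes.  Everything is a pure function of the config
and its seed, so a rerun reproduces identical tables byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import overlap as ov
from . import ranges as ra
from .bioclim import BIOCLIM_NAMES
from .grid import RasterGrid, cell_area_grid
from .maps import RangeMap, SuitabilityMap
from .occurrences import OccurrenceSet, filter_uncertainty, thin_spatial
from .predictors import (LANDUSE_NAMES, TERRAIN_NAMES, jackknife_importance,
                         pearson_matrix, select_predictors)
from .sdm import build_ensemble, ensemble_predict, sample_pseudo_absences
from .synthetic_world import (NicheSpec, ScenarioDelta, SyntheticWorld,
                              WorldConfig, apply_scenario, demo_niches,
                              demo_scenarios, generate_world,
                              sample_occurrences, true_suitability)

log = logging.getLogger("rangeshift")

ALL_PREDICTORS = tuple(BIOCLIM_NAMES) + LANDUSE_NAMES + TERRAIN_NAMES
_CSV_FMT = "%.10g"


@dataclass
class RunConfig:
    """Everything a full run needs; defaults follow the study design
    (5-km cleaning/thinning, |r| ≤ 0.7, TSS > 0.6 OR AUC > 0.8 gate,
    5 PA × 5 CV repetitions at a 70/30 split)."""

    world: WorldConfig = dc_field(default_factory=WorldConfig)
    scenarios: list[ScenarioDelta] = dc_field(default_factory=list)
    species: list[NicheSpec] = dc_field(default_factory=list)
    n_occurrences: int = 600
    uncertainty_range_km: tuple[float, float] = (0.0, 8.0)
    max_uncertainty_km: float = 5.0
    thin_km: float = 5.0
    corr_threshold: float = 0.7
    tss_gate: float = 0.6
    auc_gate: float = 0.8
    cv_fraction: float = 0.7
    n_pa_repetitions: int = 5
    n_cv_repetitions: int = 5
    n_pa: int | None = None
    algorithms: tuple[str, ...] = ("SRE", "GLM", "RF", "GBM")
    hotspot_quantile: float = 0.9
    #: recompute the MSS threshold from each scenario's own scores instead of
    #: calibrating once on the current scenario (see docs/methods.md)
    mss_per_scenario: bool = False
    seed: int = 0
    outdir: str | Path | None = None
    write_maps: bool = False


@dataclass
class RunReport:
    """All result tables of one run, plus provenance."""

    evaluation: pd.DataFrame
    importance: pd.DataFrame
    retained: dict[str, list[str]]
    mss_thresholds: pd.DataFrame
    range_dynamics: pd.DataFrame
    overlap_summary: pd.DataFrame
    occurrence_counts: pd.DataFrame
    paired_t: dict[str, tuple[float, float]]
    failures: list[str]
    provenance: dict
    suitability: dict[tuple[str, str], SuitabilityMap] = dc_field(default_factory=dict)
    range_maps: dict[tuple[str, str], RangeMap] = dc_field(default_factory=dict)
    truth: dict[str, SuitabilityMap] = dc_field(default_factory=dict)
    overlap_maps: dict[tuple[str, str], ov.OverlapMap] = dc_field(default_factory=dict)


def demo_config(seed: int = 0, outdir: str | Path | None = None) -> RunConfig:
    """The shipped reference study: two virtual species, four future
    scenarios, full 5 PA × 5 CV ensemble design on the default world."""
    return RunConfig(world=WorldConfig(seed=seed), scenarios=demo_scenarios(),
                     species=demo_niches(), seed=seed, outdir=outdir)


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of human-readable issues; empty iff the config can run."""
    issues: list[str] = []
    labels = [d.label for d in config.scenarios]
    if len(set(labels)) != len(labels):
        issues.append("scenarios: duplicate labels")
    if "current" in labels:
        issues.append('scenarios: label "current" is reserved for the baseline')
    if not config.species:
        issues.append("species: at least one niche is required")
    names = {n.species for n in config.species}
    if len(names) != len(config.species):
        issues.append("species: duplicate labels")
    for niche in config.species:
        unknown = [p for p in niche.predictors if p not in ALL_PREDICTORS]
        if unknown:
            issues.append(f"species {niche.species}: unknown predictors {unknown}")
    if not 0 < config.cv_fraction < 1:
        issues.append("cv_fraction: must be in (0,1)")
    if not 0 < config.corr_threshold <= 1:
        issues.append("corr_threshold: must be in (0,1]")
    if not -1 <= config.tss_gate <= 1:
        issues.append("tss_gate: must be in [-1,1]")
    if not 0 <= config.auc_gate <= 1:
        issues.append("auc_gate: must be in [0,1]")
    if not 0 < config.hotspot_quantile < 1:
        issues.append("hotspot_quantile: must be in (0,1)")
    if config.n_occurrences < 10:
        issues.append("n_occurrences: need at least 10")
    if config.max_uncertainty_km <= 0 or config.thin_km < 0:
        issues.append("cleaning thresholds must be positive")
    if config.n_pa_repetitions < 1 or config.n_cv_repetitions < 1:
        issues.append("repetition counts must be at least 1")
    return issues


def _extract_at(grid: RasterGrid, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    row, col = grid.cell_index(lon, lat)
    row = np.clip(row, 0, grid.nrows - 1)
    col = np.clip(col, 0, grid.ncols - 1)
    vals = grid.values[row, col]
    return vals[np.isfinite(vals)]


def run_pipeline(config: RunConfig) -> RunReport:
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid config: " + "; ".join(issues))

    world = generate_world(config.world)
    worlds: dict[str, SyntheticWorld] = {"current": world}
    for delta in config.scenarios:
        worlds[delta.label] = apply_scenario(world, delta)
    stacks = {label: w.predictor_stack() for label, w in worlds.items()}
    areas = cell_area_grid(world.grid)
    scenario_labels = ["current"] + [d.label for d in config.scenarios]

    ss = np.random.SeedSequence(config.seed)
    species_seeds = ss.spawn(len(config.species))

    eval_rows, imp_rows, mss_rows, dyn_rows, occ_rows = [], [], [], [], []
    retained_by_species: dict[str, list[str]] = {}
    failures: list[str] = []
    suitability: dict[tuple[str, str], SuitabilityMap] = {}
    range_maps: dict[tuple[str, str], RangeMap] = {}
    truths: dict[str, SuitabilityMap] = {}

    for niche, sseq in zip(config.species, species_seeds):
        sp = niche.species
        seeds = sseq.generate_state(5) % (2**31)
        log.info("species %s: seeds %s", sp, seeds.tolist())
        try:
            truth = true_suitability(world, niche)
            truths[sp] = truth
            raw = sample_occurrences(truth, config.n_occurrences, int(seeds[0]),
                                     config.uncertainty_range_km)
            filtered = filter_uncertainty(raw, config.max_uncertainty_km)
            thinned = thin_spatial(filtered, config.thin_km, int(seeds[1]))
            occ_rows.append({"species": sp, "raw": len(raw),
                             "filtered": len(filtered), "thinned": len(thinned)})
            log.info("species %s: %d raw -> %d filtered -> %d thinned",
                     sp, len(raw), len(filtered), len(thinned))

            stack_cur = stacks["current"]
            # zero-variance predictors cannot inform the model; drop up front
            tbl = stack_cur.table()
            candidates = [n for n in ALL_PREDICTORS if tbl[n].std(ddof=0) > 0]
            prelim = sample_pseudo_absences(stack_cur.subset(candidates), thinned,
                                            0, int(seeds[2]), n_pa=config.n_pa)
            importance = jackknife_importance(stack_cur.subset(candidates),
                                              prelim.presence, prelim.absence,
                                              seed=int(seeds[2]))
            corr = pearson_matrix(stack_cur, names=candidates)
            retained = select_predictors(corr, importance, config.corr_threshold)
            retained_by_species[sp] = retained
            for name in candidates:
                imp_rows.append({"species": sp, "predictor": name,
                                 "importance": importance[name],
                                 "retained": name in retained})

            ensemble, etable = build_ensemble(
                stack_cur, thinned, retained, seed=int(seeds[3]),
                n_pa_repetitions=config.n_pa_repetitions,
                n_cv_repetitions=config.n_cv_repetitions,
                cv_fraction=config.cv_fraction, algorithms=config.algorithms,
                tss_gate=config.tss_gate, auc_gate=config.auc_gate,
                n_pa=config.n_pa)
            eval_rows.append(etable)

            # fixed presence/PA evaluation sites reused across scenarios
            eval_pa = sample_pseudo_absences(stack_cur.subset(retained), thinned,
                                             0, int(seeds[4]), n_pa=config.n_pa)
            pa_lon, pa_lat = eval_pa.absence_coords

            per_scenario_ranges: dict[str, RangeMap] = {}
            calibrated_thr: float | None = None
            for label in scenario_labels:
                suit = ensemble_predict(ensemble, stacks[label])
                suitability[(sp, label)] = suit
                if config.mss_per_scenario or calibrated_thr is None:
                    sp_scores = _extract_at(suit.grid,
                                            thinned.records.lon.to_numpy(),
                                            thinned.records.lat.to_numpy())
                    sa_scores = _extract_at(suit.grid, pa_lon, pa_lat)
                    thr = ra.mss_threshold(sp_scores, sa_scores)
                    if calibrated_thr is None:
                        calibrated_thr = thr  # "current" runs first
                else:
                    thr = calibrated_thr
                mss_rows.append({"species": sp, "scenario": label,
                                 "mss_threshold": thr})
                rmap = ra.binarize(suit, thr)
                per_scenario_ranges[label] = rmap
                range_maps[(sp, label)] = rmap

            for delta in config.scenarios:
                dyn = ra.range_dynamics(per_scenario_ranges["current"],
                                        per_scenario_ranges[delta.label], areas)
                dyn_rows.append(dyn.__dict__)
        except ValueError as err:
            failures.append(f"{sp}: {err}")
            log.warning("species %s failed: %s", sp, err)

    # ---- cross-species aggregation ---------------------------------------
    overlap_rows = []
    overlap_maps: dict[tuple[str, str], ov.OverlapMap] = {}
    ok_species = [n.species for n in config.species
                  if all((n.species, lbl) in suitability for lbl in scenario_labels)]
    oihs: dict[str, ov.OverlapMap] = {}
    if ok_species:
        for label in scenario_labels:
            oihs[label] = ov.overlap_suitability(
                [suitability[(sp, label)] for sp in ok_species])
            oipr = ov.overlap_ranges([range_maps[(sp, label)] for sp in ok_species])
            overlap_maps[("oihs", label)] = oihs[label]
            overlap_maps[("oipr", label)] = oipr
        for delta in config.scenarios:
            label = delta.label
            change = ov.suitability_change(oihs["current"], oihs[label])
            frac_inc = ov.fraction_area_increasing(change, areas)
            expanding = [ra.expanding_range(range_maps[(sp, "current")],
                                            range_maps[(sp, label)])
                         for sp in ok_species]
            exp_overlap = ov.overlap_expanding(expanding)
            overlap_maps[("expanding", label)] = exp_overlap
            overlap_maps[("oihs_change", label)] = ov.OverlapMap(
                change.grid, "oihs_change", label, len(ok_species))
            row = {"scenario": label, "pct_land_increasing_oihs": frac_inc}
            for kind, omap in (("oihs", oihs[label]), ("oipr",
                               overlap_maps[("oipr", label)]),
                               ("expanding", exp_overlap)):
                try:
                    mask = ov.hotspot_mask(omap, areas, config.hotspot_quantile)
                    row[f"hotspot_area_km2_{kind}"] = float(
                        areas.values[mask.mask & (mask.values == 1)].sum())
                except ValueError:
                    row[f"hotspot_area_km2_{kind}"] = np.nan
            overlap_rows.append(row)

    paired: dict[str, tuple[float, float]] = {}
    dyn_df = pd.DataFrame(dyn_rows)
    if len(ok_species) >= 2 and not dyn_df.empty:
        for delta in config.scenarios:
            sub = dyn_df[dyn_df.scenario == delta.label]
            try:
                paired[delta.label] = ra.paired_t_test(sub.rc_area_km2,
                                                       sub.rf_area_km2)
            except ValueError as err:
                log.warning("paired t-test skipped for %s: %s", delta.label, err)

    report = RunReport(
        evaluation=(pd.concat(eval_rows, ignore_index=True)
                    if eval_rows else pd.DataFrame()),
        importance=pd.DataFrame(imp_rows),
        retained=retained_by_species,
        mss_thresholds=pd.DataFrame(mss_rows),
        range_dynamics=dyn_df,
        overlap_summary=pd.DataFrame(overlap_rows),
        occurrence_counts=pd.DataFrame(occ_rows),
        paired_t=paired,
        failures=failures,
        provenance={"seed": config.seed, "n_species": len(config.species),
                    "scenarios": scenario_labels},
        suitability=suitability, range_maps=range_maps, truth=truths,
        overlap_maps=overlap_maps,
    )
    if config.outdir is not None:
        write_report(report, config)
    return report


def write_report(report: RunReport, config: RunConfig) -> None:
    """Write all tables (and optionally maps) under config.outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {
        "evaluation.csv": report.evaluation,
        "importance.csv": report.importance,
        "mss_thresholds.csv": report.mss_thresholds,
        "range_dynamics.csv": report.range_dynamics,
        "overlap_summary.csv": report.overlap_summary,
        "occurrence_counts.csv": report.occurrence_counts,
    }
    for fname, df in tables.items():
        df.to_csv(outdir / fname, index=False, float_format=_CSV_FMT)
    pd.DataFrame(
        [{"species": sp, "retained": " ".join(names)}
         for sp, names in report.retained.items()]
    ).to_csv(outdir / "retained_predictors.csv", index=False)
    pd.DataFrame(
        [{"scenario": k, "t": v[0], "p": v[1]} for k, v in report.paired_t.items()]
    ).to_csv(outdir / "paired_t.csv", index=False, float_format=_CSV_FMT)
    with open(outdir / "failures.txt", "w") as fh:
        fh.write("\n".join(report.failures))
    if config.write_maps:
        mapdir = outdir / "maps"
        mapdir.mkdir(exist_ok=True)
        for (sp, label), smap in report.suitability.items():
            smap.grid.write_ascii(mapdir / f"suitability_{sp}_{label}.asc")
        for (sp, label), rmap in report.range_maps.items():
            rmap.grid.write_ascii(mapdir / f"range_{sp}_{label}.asc")
        for (kind, label), omap in report.overlap_maps.items():
            omap.grid.write_ascii(mapdir / f"{kind}_{label}.asc")
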