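"""File formats, run configuration and the end-to-end pipeline driver.

All interchange is long-format CSV.  A screen file has one row per well
(combo_id, cell_line, drug_a, drug_b, dose_a, dose_b, viability); prediction
files carry cell_line, combination_id, prediction.  Every output table gets a
schema-version and generating-seed header comment via the run manifest.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, biomarkers, dose_response, ensembles, metrics
from . import response_classes, synthdata
from .dose_response import DoseResponseMatrix

__all__ = ["SCHEMA_VERSION", "StageError", "RunConfig", "read_screen",
           "write_screen", "read_predictions", "write_predictions",
           "run_pipeline"]

SCHEMA_VERSION = 1

logger = logging.getLogger("synergybench")

SCREEN_COLUMNS = ["combo_id", "cell_line", "drug_a", "drug_b",
                  "dose_a", "dose_b", "viability"]


class StageError(RuntimeError):
    """A pipeline stage failed; earlier stage outputs are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def write_screen(matrices, path) -> None:
    rows = []
    for m in matrices:
        for i, da in enumerate(m.doses_a):
            for j, db in enumerate(m.doses_b):
                rows.append((m.combo_id, m.cell_id, m.drug_a, m.drug_b,
                             da, db, m.viability[i, j]))
    # %.17g keeps the dose/viability round trip bit-exact
    pd.DataFrame(rows, columns=SCREEN_COLUMNS).to_csv(path, index=False,
                                                      float_format="%.17g")


def read_screen(path, report: list | None = None) -> list:
    """Parse a long-format screen CSV into validated 6x6 matrices.

    Malformed experiments (duplicate dose keys, missing monotherapy row or
    column, ragged grids) are rejected with a warning naming the offending
    rows; pass ``report`` to collect (combo_id, cell_line, reason) tuples.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in SCREEN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"screen file missing columns {missing}")
    matrices = []
    for (combo, cell), grp in df.groupby(["combo_id", "cell_line"], sort=True):
        reason = None
        if grp.duplicated(["dose_a", "dose_b"]).any():
            dup_rows = grp.index[grp.duplicated(["dose_a", "dose_b"])].tolist()
            reason = f"duplicated (dose_a, dose_b) keys at rows {dup_rows}"
        else:
            doses_a = np.sort(grp["dose_a"].unique())
            doses_b = np.sort(grp["dose_b"].unique())
            if doses_a[0] != 0 or doses_b[0] != 0:
                reason = "missing monotherapy row/column (no zero dose)"
            elif len(grp) != len(doses_a) * len(doses_b):
                reason = f"incomplete grid ({len(grp)} rows at rows {grp.index.tolist()})"
        if reason is None:
            pivot = grp.pivot(index="dose_a", columns="dose_b",
                              values="viability").sort_index().sort_index(axis=1)
            if pivot.isna().any().any():
                reason = "grid is not a full cross of doses"
        if reason is not None:
            warnings.warn(f"experiment ({combo}, {cell}) rejected: {reason}",
                          stacklevel=2)
            if report is not None:
                report.append((combo, cell, reason))
            continue
        matrices.append(DoseResponseMatrix(
            combo_id=str(combo), cell_id=str(cell),
            drug_a=str(grp["drug_a"].iloc[0]), drug_b=str(grp["drug_b"].iloc[0]),
            doses_a=pivot.index.to_numpy(float),
            doses_b=pivot.columns.to_numpy(float),
            viability=pivot.to_numpy(float)))
    return matrices


def write_predictions(preds: pd.DataFrame, path) -> None:
    out = preds.rename(columns={"cell_id": "cell_line",
                                "combo_id": "combination_id"})
    out.to_csv(path, index=False)


def read_predictions(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return df.rename(columns={"cell_line": "cell_id",
                              "combination_id": "combo_id"})


@dataclass
class RunConfig:
    """Pipeline configuration; thresholds default to the published values."""

    seed: int = 0
    out_dir: str = "synergybench-run"
    # generator sizes
    n_cells: int = 30
    n_genes: int = 40
    tissues: tuple = ("breast", "lung", "bladder", "gi")
    event_prob: float = 0.25
    n_drugs: int = 12
    n_pathways: int = 4
    n_combos: int = 20
    cells_per_combo: int = 12
    noise_sd: float = 3.0
    coupling: bool = True
    n_teams: int = 8
    team_skill: tuple = (0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.2, 0.0)
    pdx_models: int = 40
    # published thresholds / options
    synergy_threshold: float = 20.0
    score_cap: float = 100.0
    bayes_factor_cutoff: float = 5.0
    fdr: float = 0.05
    enrichment_step: float = 0.1
    bootstrap_iters: int = 1000
    enrichment_boot: tuple = (5, 0.8)
    null_permutations: int = 1000

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        allowed = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("tissues", "team_skill", "enrichment_boot"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _mono_sensitivities(matrices, curves=None) -> pd.DataFrame:
    """Per (drug, cell) single-agent sensitivity from refit monotherapy rows,
    averaged over experiments that rescreened the same monotherapy."""
    rows = []
    for i, m in enumerate(matrices):
        ca, cb = (curves[i] if curves is not None
                  else dose_response.fit_monotherapies(m))
        rows.append((m.drug_a, m.cell_id,
                     biomarkers.monotherapy_sensitivity(ca, m.doses_a)))
        rows.append((m.drug_b, m.cell_id,
                     biomarkers.monotherapy_sensitivity(cb, m.doses_b)))
    df = pd.DataFrame(rows, columns=["drug_id", "cell_id", "sensitivity"])
    return df.groupby(["drug_id", "cell_id"], as_index=False)["sensitivity"].mean()


def run_pipeline(config: RunConfig) -> Path:
    """Run generation -> scoring -> benchmarking -> ensembles -> biomarkers ->
    PDX comparison, writing CSVs and a machine-readable manifest.

    Stages fail atomically: on error a :class:`StageError` names the stage
    and outputs of earlier stages are kept on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"schema_version": SCHEMA_VERSION, "version": __version__,
                "seed": config.seed, "config": asdict(config), "stages": []}
    state: dict = {}

    def stage(name, fn):
        logger.info("stage=%s starting", name)
        try:
            counts = fn()
        except Exception as exc:  # noqa: BLE001 - relabeled with stage context
            _write_manifest(out, manifest)
            raise StageError(name, exc) from exc
        manifest["stages"].append({"name": name, "tables": counts})
        logger.info("stage=%s done %s", name, counts)

    def _simulate():
        panel = synthdata.make_panel(config.n_cells, config.n_genes,
                                     config.tissues, config.event_prob,
                                     config.seed)
        drugs = synthdata.make_drug_library(config.n_drugs, panel.bem.index,
                                            config.n_pathways, config.seed)
        design = synthdata.make_design(panel, drugs, config.n_combos,
                                       config.cells_per_combo, config.seed)
        screen_cfg = synthdata.ScreenConfig(noise_sd=config.noise_sd,
                                            coupling=config.coupling)
        matrices, truth = synthdata.simulate_screen(panel, drugs, design,
                                                    screen_cfg, config.seed)
        state.update(panel=panel, drugs=drugs, design=design,
                     matrices=matrices, truth=truth)
        write_screen(matrices, out / "screen.csv")
        truth.to_csv(out / "ground_truth.csv", index=False)
        panel.bem.to_csv(out / "bem.csv")
        panel.tissue.rename("tissue").to_csv(out / "tissues.csv")
        drugs.to_csv(out / "drugs.csv")
        return {"screen_rows": len(design) * 36, "experiments": len(matrices)}

    def _score_surfaces():
        curves = [dose_response.fit_monotherapies(m) for m in state["matrices"]]
        state["curves"] = curves
        synergy = dose_response.score_screen(state["matrices"], curves)
        state["synergy"] = synergy
        synergy.to_csv(out / "synergy.csv", index=False)
        return {"experiments": len(synergy)}

    def _score_teams():
        synergy = state["synergy"]
        preds = synthdata.simulate_teams(synergy, config.n_teams,
                                         config.team_skill,
                                         config.synergy_threshold, config.seed)
        state["preds"] = preds
        write_predictions(preds, out / "predictions.csv")
        splits = synthdata.make_splits(state["design"], "SC1", config.seed)
        splits.to_csv(out / "splits_sc1.csv", index=False)
        team_tables = {t: g for t, g in preds.groupby("team")}
        bf = metrics.bootstrap_bayes_factor(team_tables, synergy, "SC1",
                                            config.bootstrap_iters, config.seed)
        null = metrics.null_model(synergy, "SC1", config.null_permutations,
                                  config.seed)
        pm = {t: metrics.weighted_pearson(g, synergy)
              for t, g in team_tables.items()}
        btr = metrics.better_than_random(pm, null, config.fdr)
        leaderboard = bf.merge(btr[["team", "p", "q", "passes_fdr"]], on="team")
        leaderboard["indistinguishable_from_best"] = (
            leaderboard["K"] <= config.bayes_factor_cutoff)
        tb = {}
        for t, g in team_tables.items():
            try:
                tb[t] = metrics.sc1_tiebreak(g, synergy,
                                             threshold=config.synergy_threshold)
            except metrics.UndefinedMetricError:
                tb[t] = np.nan
        leaderboard["tiebreak"] = leaderboard["team"].map(tb)
        leaderboard.to_csv(out / "leaderboard.csv", index=False)
        state["leaderboard"] = leaderboard
        return {"teams": len(leaderboard), "null_permutations": len(null)}

    def _ensemble():
        preds = state["preds"]
        pm = ensembles.PredictionMatrix.from_table(preds)
        v = ensembles.sml_estimate(pm)
        v.rename_axis("team").to_csv(out / "sml_scores.csv")
        labels = ensembles.sml_ensemble(pm)
        ens = pd.DataFrame({
            "combo_id": [k[0] for k in labels.index],
            "cell_id": [k[1] for k in labels.index],
            "prediction_binary": labels.to_numpy(),
        })
        write_predictions(ens, out / "ensemble_predictions.csv")
        return {"teams": len(v), "experiments": len(ens)}

    def _biomarkers():
        mono = _mono_sensitivities(state["matrices"], state.get("curves"))
        mono.to_csv(out / "monotherapy_response.csv", index=False)
        assocs = biomarkers.monotherapy_association(mono, state["panel"].bem)
        assocs.to_csv(out / "monotherapy_associations.csv", index=False)
        resist = assocs[assocs["direction"] == "resistance"]
        if not resist.empty:
            curve = biomarkers.synergy_enrichment(
                resist, state["synergy"], state["panel"].bem,
                config.enrichment_step, config.enrichment_boot, config.seed)
            pd.DataFrame({"threshold": curve.thresholds,
                          "selected_fraction": curve.selected_fraction,
                          "pct_synergistic": curve.pct_synergistic}) \
                .to_csv(out / "enrichment_curve.csv", index=False)
        candidates = [(g, c) for g, c in
                      state["truth"][["biomarker", "combo_id"]]
                      .dropna().drop_duplicates().itertuples(index=False)]
        anova = biomarkers.synergy_biomarker_anova(
            state["synergy"], state["panel"].bem, state["panel"].tissue,
            candidates)
        anova.to_csv(out / "synergy_biomarkers.csv", index=False)
        return {"associations": len(assocs), "candidates": len(anova)}

    def _pdx():
        cohort = synthdata.simulate_pdx(state["design"], config.pdx_models,
                                        synthdata.PDXCoupling(
                                            enabled=config.coupling),
                                        config.seed)
        classes = response_classes.classify_pdx_cohort(cohort)
        classes.to_csv(out / "pdx_classes.csv", index=False)
        try:
            table, r = response_classes.synergy_rate_concordance(
                classes, state["synergy"], config.synergy_threshold)
            table.assign(pearson_r=r).to_csv(out / "pdx_concordance.csv")
        except ValueError:
            pass
        return {"pdx_records": len(classes)}

    stage("simulate", _simulate)
    stage("score-surfaces", _score_surfaces)
    stage("score-teams", _score_teams)
    stage("ensemble", _ensemble)
    stage("biomarkers", _biomarkers)
    stage("pdx", _pdx)
    _write_manifest(out, manifest)
    return out


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
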