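"""Seeded generators for every input the analysis pipeline consumes.

Produces cell-line panels with binary event matrices, drug libraries with
target/pathway annotation, sparse combination-screen designs, dose-response
surfaces with known ground-truth synergy, team prediction tables of
controllable skill, challenge-style data splits and PDX response cohorts.
All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .dose_response import HillCurve, DoseResponseMatrix, hill_response, loewe_surface
from ._seeding import stage_rng

__all__ = [
    "CellLinePanel",
    "ScreenConfig",
    "PDXCoupling",
    "make_panel",
    "make_drug_library",
    "make_design",
    "make_dose_series",
    "simulate_screen",
    "simulate_teams",
    "make_splits",
    "simulate_pdx",
]

RESPONSE_LABELS = ("PD", "SD", "PR", "CR")


@dataclass
class CellLinePanel:
    """Cell lines with tissue labels and a genes x cells binary event matrix."""

    cell_ids: list
    tissue: pd.Series  # indexed by cell id
    bem: pd.DataFrame  # genes x cells, entries in {0, 1}

    def __post_init__(self) -> None:
        if list(self.bem.columns) != list(self.cell_ids):
            raise ValueError("BEM columns must equal cell_ids")
        if not self.tissue.index.equals(pd.Index(self.cell_ids)):
            raise ValueError("tissue index must equal cell_ids")
        vals = self.bem.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("BEM entries must be 0/1")


def make_panel(n_cells: int, n_genes: int, tissues, event_prob: float,
               seed: int) -> CellLinePanel:
    """Random panel: Bernoulli(event_prob) BEM, tissues assigned uniformly.

    Gene rows that come out all-zero get one random event so every gene is
    informative.
    """
    if n_cells < 2 or n_genes < 1:
        raise ValueError("n_cells must be >=2 and n_genes >=1")
    if not 0 < event_prob < 1:
        raise ValueError("event_prob must be in (0, 1)")
    tissues = list(tissues)
    if not tissues:
        raise ValueError("need at least one tissue label")
    rng = stage_rng(seed, "panel")
    cell_ids = [f"CL{i:04d}" for i in range(n_cells)]
    gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    tissue = pd.Series(rng.choice(tissues, size=n_cells), index=cell_ids,
                       name="tissue")
    events = (rng.random((n_genes, n_cells)) < event_prob).astype(int)
    for g in np.flatnonzero(events.sum(axis=1) == 0):
        events[g, rng.integers(n_cells)] = 1
    bem = pd.DataFrame(events, index=gene_ids, columns=cell_ids)
    return CellLinePanel(cell_ids=cell_ids, tissue=tissue, bem=bem)


def make_drug_library(n_drugs: int, genes, n_pathways: int, seed: int) -> pd.DataFrame:
    """Drug table with a target gene and a pathway group per drug.

    Pathways partition the drugs; targets are drawn from ``genes`` so
    resistance biomarkers can be coupled to drug targets downstream.
    """
    if n_drugs < 2:
        raise ValueError("need at least 2 drugs to form combinations")
    genes = list(genes)
    rng = stage_rng(seed, "drugs")
    drug_ids = [f"D{i:03d}" for i in range(n_drugs)]
    return pd.DataFrame(
        {
            "drug_id": drug_ids,
            "target": rng.choice(genes, size=n_drugs),
            "pathway": [f"PW{rng.integers(n_pathways)}" for _ in range(n_drugs)],
        }
    ).set_index("drug_id")


def make_design(panel: CellLinePanel, drugs: pd.DataFrame, n_combos: int,
                cells_per_combo: int, seed: int) -> pd.DataFrame:
    """Sparse (combination x cell line) design table.

    Each combination pairs two distinct drugs and is measured in a random
    subset of cells, mimicking a selectively profiled screen.
    """
    if cells_per_combo > len(panel.cell_ids):
        raise ValueError("cells_per_combo exceeds panel size")
    rng = stage_rng(seed, "design")
    rows = []
    drug_ids = list(drugs.index)
    seen = set()
    attempts = 0
    while len(seen) < n_combos:
        attempts += 1
        if attempts > 100 * n_combos:
            raise ValueError("cannot draw enough distinct drug pairs")
        a, b = rng.choice(drug_ids, size=2, replace=False)
        pair = tuple(sorted((a, b)))
        if pair in seen:
            continue
        seen.add(pair)
        combo_id = f"{pair[0]}.{pair[1]}"
        cells = rng.choice(panel.cell_ids, size=cells_per_combo, replace=False)
        for c in sorted(cells):
            rows.append((combo_id, pair[0], pair[1], c))
    return pd.DataFrame(rows, columns=["combo_id", "drug_a", "drug_b", "cell_id"])


def make_dose_series(top_dose: float = 10.0, ratio: float = 4.0,
                     n_positive: int = 5) -> np.ndarray:
    """Geometric dose series (descending factor ``ratio``) plus dose 0 first."""
    if top_dose <= 0 or ratio <= 1:
        raise ValueError("top_dose must be positive and ratio > 1")
    doses = top_dose / ratio ** np.arange(n_positive - 1, -1, -1)
    return np.concatenate([[0.0], doses])


@dataclass
class ScreenConfig:
    """Ground-truth model for the synthetic screen.

    The pre-noise surface is the Loewe-additive surface of two Hill curves
    minus a separable Gaussian bump in log-dose space whose area-normalised
    log-space integral equals the synergy amplitude ``delta`` -- making the
    ground truth exactly the scorer's target.  When ``coupling`` is on, a
    combination inherits the target gene of its first drug as linked
    biomarker: event carriers draw ``delta`` from the synergy regime through
    a logistic link, and their monotherapy curves are shifted toward
    resistance.
    """

    noise_sd: float = 0.0
    e_inf_range: tuple = (55.0, 80.0)
    h_range: tuple = (0.8, 2.5)
    coupling: bool = False
    delta_mean: float = 40.0
    delta_sd: float = 8.0
    delta_null_sd: float = 2.0
    logit_base: float = -4.0
    logit_event: float = 8.0
    resistance_ec50_factor: float = 8.0
    resistance_e_inf_shift: float = 12.0
    bump_width: float = 0.6  # sd of the Gaussian bump in normalised log-dose
    top_dose: float = 10.0
    dose_ratio: float = 4.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


def _bump_weights(doses_a: np.ndarray, doses_b: np.ndarray, width: float):
    """Separable Gaussian weights over the positive 5x5 log-dose grid and the
    area-normalised trapezoidal mean used to calibrate the bump amplitude."""
    la = np.log10(doses_a[1:])
    lb = np.log10(doses_b[1:])
    ua = (la - la[0]) / (la[-1] - la[0])
    ub = (lb - lb[0]) / (lb[-1] - lb[0])
    ga = np.exp(-((ua - 0.5) ** 2) / (2 * width ** 2))
    gb = np.exp(-((ub - 0.5) ** 2) / (2 * width ** 2))
    w = np.outer(ga, gb)
    inner = np.trapezoid(w, x=lb, axis=1)
    mean = float(np.trapezoid(inner, x=la) / ((la[-1] - la[0]) * (lb[-1] - lb[0])))
    return w, mean


def _draw_curve(rng: np.random.Generator, cfg: ScreenConfig, doses: np.ndarray,
                resistant: bool) -> HillCurve:
    e_inf = rng.uniform(*cfg.e_inf_range)
    pos = doses[doses > 0]
    log_lo, log_hi = np.log10(pos[0]), np.log10(pos[-1])
    ec50 = 10.0 ** rng.uniform(log_lo + 0.2, log_hi - 0.2)
    h = rng.uniform(*cfg.h_range)
    if resistant:
        ec50 = min(ec50 * cfg.resistance_ec50_factor, pos[-1] * 50)
        e_inf = min(e_inf + cfg.resistance_e_inf_shift, 95.0)
    return HillCurve(100.0, float(e_inf), float(ec50), float(h))


def simulate_screen(panel: CellLinePanel, drugs: pd.DataFrame,
                    design: pd.DataFrame, config: ScreenConfig, seed: int,
                    delta_override=None):
    """Simulate 6x6 dose-response matrices for every design row.

    Returns ``(matrices, truth)`` where ``truth`` is a tidy ground-truth
    sidecar keyed by (combo_id, cell_id) with the injected synergy amplitude,
    linked biomarker and carrier status.

    ``delta_override`` may be a scalar or a ``{(combo_id, cell_id): delta}``
    mapping forcing exact bump amplitudes (used for recovery tests).
    """
    if design.empty:
        raise ValueError("design is empty")
    rng = stage_rng(seed, "screen")
    doses = make_dose_series(config.top_dose, config.dose_ratio)
    w, w_mean = _bump_weights(doses, doses, config.bump_width)

    matrices: list[DoseResponseMatrix] = []
    truth_rows = []
    for row in design.itertuples(index=False):
        combo_id, drug_a, drug_b, cell = row.combo_id, row.drug_a, row.drug_b, row.cell_id
        linked_gene = None
        carrier = 0
        if config.coupling:
            linked_gene = drugs.loc[drug_a, "target"]
            if linked_gene in panel.bem.index:
                carrier = int(panel.bem.loc[linked_gene, cell])
        resist_a = bool(carrier) and config.coupling
        curve_a = _draw_curve(rng, config, doses, resistant=resist_a)
        curve_b = _draw_curve(rng, config, doses, resistant=False)

        if delta_override is not None:
            if np.isscalar(delta_override):
                delta = float(delta_override)
            else:
                delta = float(delta_override[(combo_id, cell)])
        elif config.coupling:
            p_syn = float(expit(config.logit_base + config.logit_event * carrier))
            if rng.random() < p_syn:
                delta = float(rng.normal(config.delta_mean, config.delta_sd))
            else:
                delta = float(rng.normal(0.0, config.delta_null_sd))
        else:
            delta = float(rng.normal(0.0, config.delta_null_sd))

        additive, _ = loewe_surface(curve_a, curve_b, doses, doses)
        viability = additive.copy()
        viability[0, 0] = 100.0
        viability[1:, 0] = hill_response(curve_a, doses[1:])
        viability[0, 1:] = hill_response(curve_b, doses[1:])
        viability[1:, 1:] = additive[1:, 1:] - (delta / w_mean) * w
        if config.noise_sd > 0:
            viability = viability + rng.normal(0.0, config.noise_sd, viability.shape)
        viability = np.clip(viability, 0.0, 120.0)
        matrices.append(DoseResponseMatrix(combo_id, cell, drug_a, drug_b,
                                           doses.copy(), doses.copy(), viability))
        truth_rows.append((combo_id, cell, drug_a, drug_b, delta,
                           config.noise_sd, linked_gene, carrier,
                           curve_a.e_inf, curve_a.ec50, curve_a.h,
                           curve_b.e_inf, curve_b.ec50, curve_b.h))
    truth = pd.DataFrame(truth_rows, columns=[
        "combo_id", "cell_id", "drug_a", "drug_b", "delta", "noise_sd",
        "biomarker", "carrier", "e_inf_a", "ec50_a", "h_a",
        "e_inf_b", "ec50_b", "h_b"])
    return matrices, truth


def simulate_teams(truth: pd.DataFrame, n_teams: int, skill,
                   binarize_threshold: float = 20.0, seed: int = 0) -> pd.DataFrame:
    """Teams of controllable skill predicting a synergy table.

    Each team's continuous prediction is a correlation-``skill`` mixture of
    the standardised truth and independent Gaussian noise, mapped back to the
    truth's scale; the binary prediction thresholds that (noisy) copy at
    ``binarize_threshold``.  Teams are conditionally independent given truth.
    """
    if n_teams < 1:
        raise ValueError("n_teams must be >= 1")
    skill = np.broadcast_to(np.asarray(skill, dtype=float), (n_teams,))
    if np.any(np.abs(skill) > 1):
        raise ValueError("skill values must lie in [-1, 1]")
    rng = stage_rng(seed, "teams")
    scores = truth["score"].to_numpy(dtype=float) if "score" in truth else \
        truth["delta"].to_numpy(dtype=float)
    mu, sd = float(np.mean(scores)), float(np.std(scores))
    if sd == 0:
        raise ValueError("truth scores have zero variance")
    z = (scores - mu) / sd
    frames = []
    for t in range(n_teams):
        rho = skill[t]
        noise = rng.standard_normal(len(z))
        pred = mu + sd * (rho * z + np.sqrt(max(0.0, 1 - rho ** 2)) * noise)
        frames.append(pd.DataFrame({
            "team": f"team{t:02d}",
            "combo_id": truth["combo_id"].to_numpy(),
            "cell_id": truth["cell_id"].to_numpy(),
            "prediction": pred,
            "prediction_binary": (pred >= binarize_threshold).astype(int),
        }))
    return pd.concat(frames, ignore_index=True)


def make_splits(design: pd.DataFrame, mode: str, seed: int) -> pd.DataFrame:
    """Challenge-style data splits.

    SC1: per combination, cells are split 3/6 train, 1/6 leaderboard and
    2/6 validation (floor for leaderboard, remainder to validation then
    train); combinations with fewer than 6 cells are excluded with a warning.
    SC2: combinations are split into two disjoint halves (leaderboard /
    validation).
    """
    rng = stage_rng(seed, f"splits-{mode}")
    if mode == "SC1":
        out = []
        for combo_id, grp in design.groupby("combo_id", sort=True):
            cells = sorted(grp["cell_id"].unique())
            n = len(cells)
            if n < 6:
                warnings.warn(
                    f"combination {combo_id} has {n} < 6 cells; excluded from SC1",
                    stacklevel=2,
                )
                continue
            perm = rng.permutation(n)
            n_lb, n_val, n_train = n // 6, n // 3, n // 2
            leftover = n - n_lb - n_val - n_train
            if leftover > 0:
                n_val += 1
                leftover -= 1
            if leftover > 0:
                n_train += 1
            labels = (["train"] * n_train + ["leaderboard"] * n_lb
                      + ["validation"] * n_val)
            for idx, lab in zip(perm, labels):
                out.append((combo_id, cells[idx], lab))
        return pd.DataFrame(out, columns=["combo_id", "cell_id", "split"])
    if mode == "SC2":
        combos = sorted(design["combo_id"].unique())
        perm = rng.permutation(len(combos))
        half = len(combos) // 2
        rows = [(combos[i], "leaderboard" if k < half else "validation")
                for k, i in enumerate(perm)]
        return pd.DataFrame(rows, columns=["combo_id", "split"])
    raise ValueError(f"unknown split mode {mode!r} (expected 'SC1' or 'SC2')")


@dataclass
class PDXCoupling:
    """Biomarker coupling for PDX cohorts: carriers of a combination's linked
    event get an elevated probability that the combination beats the better
    monotherapy by two response classes."""

    enabled: bool = True
    event_prob: float = 0.3
    benefit_prob: float = 0.7
    response_probs: tuple = (0.55, 0.25, 0.12, 0.08)  # PD, SD, PR, CR

    def __post_init__(self) -> None:
        if not 0 <= self.event_prob <= 1 or not 0 <= self.benefit_prob <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        p = np.asarray(self.response_probs, dtype=float)
        if len(p) != 4 or abs(p.sum() - 1) > 1e-9 or (p < 0).any():
            raise ValueError("response_probs must be 4 non-negative values summing to 1")


def simulate_pdx(drug_pairs: pd.DataFrame, n_models: int,
                 coupling: PDXCoupling, seed: int,
                 event_prob_by_combo: dict | None = None) -> pd.DataFrame:
    """PDX cohort with best responses for each combination and both
    monotherapies across ``n_models`` models per combination.

    ``event_prob_by_combo`` optionally overrides the carrier frequency per
    combination, letting cohorts share combination-level biomarker structure
    with an in vitro screen.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    rng = stage_rng(seed, "pdx")
    codes = np.arange(1, 5)
    probs = np.asarray(coupling.response_probs, dtype=float)
    rows = []
    for row in drug_pairs.drop_duplicates("combo_id").itertuples(index=False):
        p_event = coupling.event_prob
        if event_prob_by_combo is not None:
            p_event = event_prob_by_combo.get(row.combo_id, p_event)
        for m in range(n_models):
            carrier = int(rng.random() < p_event)
            mono_a, mono_b = rng.choice(codes, size=2, p=probs)
            combo = int(rng.choice(codes, p=probs))
            if coupling.enabled and carrier and rng.random() < coupling.benefit_prob:
                combo = int(min(4, max(mono_a, mono_b) + 2))
            rows.append((f"PDX{m:04d}", row.combo_id, row.drug_a, row.drug_b,
                         carrier,
                         RESPONSE_LABELS[combo - 1],
                         RESPONSE_LABELS[mono_a - 1],
                         RESPONSE_LABELS[mono_b - 1]))
    return pd.DataFrame(rows, columns=[
        "model_id", "combo_id", "drug_a", "drug_b", "carrier",
        "response_combo", "response_a", "response_b"])
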