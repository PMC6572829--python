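"""Monotherapy-resistance biomarkers and synergy-biomarker analytics.

Monotherapy markers are genomic events that separate single-agent response
(Wilcoxon rank-sum); ordering experiments by the significance of their linked
resistance markers yields the threshold-stringency enrichment curve of
synergistic outcomes.  Synergy biomarkers are tested per (gene, combination)
candidate with an ANOVA correcting for tissue of origin, BH-adjusted across
candidates, with directional validation against an independent synergy table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dose_response import HillCurve, SYNERGY_THRESHOLD, hill_response
from ._seeding import stage_rng

__all__ = [
    "EnrichmentCurve",
    "extend_bem",
    "monotherapy_sensitivity",
    "monotherapy_association",
    "synergy_enrichment",
    "synergy_biomarker_anova",
    "validate_directionality",
]

#: Copy-number thresholds for the extended event matrix: homozygous deletion
#: (0 copies) or amplification strictly above 7 copies.
AMPLIFICATION_COPIES = 7


def extend_bem(mutations: pd.DataFrame, copy_numbers: pd.DataFrame) -> pd.DataFrame:
    """Extended binary event matrix: a gene is altered in a cell if deleted
    (0 copies), amplified (>7 copies) or mutated in any sense."""
    if not mutations.index.equals(copy_numbers.index) or \
            not mutations.columns.equals(copy_numbers.columns):
        raise ValueError("mutation and copy-number matrices must be aligned")
    cn = copy_numbers.to_numpy()
    if not np.issubdtype(cn.dtype, np.number) or (cn < 0).any():
        raise ValueError("copy numbers must be non-negative integers")
    if not np.allclose(cn, np.round(cn)):
        raise ValueError("copy numbers must be integers")
    mut = mutations.to_numpy().astype(bool)
    altered = mut | (cn == 0) | (cn > AMPLIFICATION_COPIES)
    return pd.DataFrame(altered.astype(int), index=mutations.index,
                        columns=mutations.columns)


def monotherapy_sensitivity(curve: HillCurve, doses) -> float:
    """Scalar single-agent response: 1 minus the normalised area under the
    fitted viability curve over the tested log-dose range (higher = more
    sensitive; a flat 100% curve scores 0)."""
    doses = np.asarray(doses, dtype=float)
    pos = doses[doses > 0]
    if len(pos) < 2:
        raise ValueError("need >=2 positive doses")
    ld = np.log10(pos)
    grid = np.linspace(ld[0], ld[-1], 101)
    viab = hill_response(curve, 10.0 ** grid) / 100.0
    auc = float(np.trapezoid(viab, x=grid) / (ld[-1] - ld[0]))
    return float(np.clip(1.0 - auc, 0.0, 1.0))


def monotherapy_association(mono_response: pd.DataFrame, bem: pd.DataFrame,
                            min_group: int = 3) -> pd.DataFrame:
    """Wilcoxon rank-sum association of each (drug, gene) pair.

    ``mono_response`` is tidy with columns drug_id, cell_id, sensitivity.
    Direction is 'resistance' when the mutant median sensitivity is below the
    wild-type median.  Pairs with a group smaller than ``min_group`` are
    skipped.
    """
    required = {"drug_id", "cell_id", "sensitivity"}
    if not required.issubset(mono_response.columns):
        raise ValueError(f"mono_response needs columns {sorted(required)}")
    rows = []
    for drug_id, grp in mono_response.groupby("drug_id", sort=True):
        cells = grp["cell_id"].to_numpy()
        sens = grp["sensitivity"].to_numpy(float)
        present = [c in bem.columns for c in cells]
        cells, sens = cells[present], sens[np.asarray(present)]
        if len(cells) == 0:
            continue
        events = bem[cells]
        for gene in bem.index:
            mask = events.loc[gene].to_numpy() == 1
            mut, wt = sens[mask], sens[~mask]
            if len(mut) < min_group or len(wt) < min_group:
                continue
            if np.ptp(sens) == 0:
                p, direction = 1.0, "none"
            else:
                res = stats.mannwhitneyu(mut, wt, alternative="two-sided",
                                         method="auto")
                p = float(res.pvalue)
                med_mut, med_wt = np.median(mut), np.median(wt)
                if med_mut < med_wt:
                    direction = "resistance"
                elif med_mut > med_wt:
                    direction = "sensitivity"
                else:
                    direction = "none"
            rows.append((drug_id, gene, p, direction, len(mut), len(wt)))
    return pd.DataFrame(rows, columns=["drug_id", "gene", "p", "direction",
                                       "n_mut", "n_wt"])


@dataclass
class EnrichmentCurve:
    """Threshold-stringency curve of synergy enrichment.

    At each -log10(p) threshold ``t`` (grid step 0.1), an experiment is
    linked when one of its drugs has a resistance association of strength
    >= t for a gene altered in that cell; the curve reports the selected
    fraction of experiments and the % synergistic among them, plus bootstrap
    replicate curves (rows) computed on random 80% subsets.
    """

    thresholds: np.ndarray
    selected_fraction: np.ndarray
    pct_synergistic: np.ndarray
    boot_selected: np.ndarray
    boot_pct: np.ndarray

    def correlation(self) -> float:
        """Pearson r between selected fraction and % synergistic over the
        defined grid points (negative = enrichment with stringency)."""
        ok = ~np.isnan(self.pct_synergistic)
        if ok.sum() < 3:
            raise ValueError("fewer than 3 defined grid points")
        return float(stats.pearsonr(self.selected_fraction[ok],
                                    self.pct_synergistic[ok])[0])


def _link_strength(synergy: pd.DataFrame, assocs: pd.DataFrame,
                   bem: pd.DataFrame) -> np.ndarray:
    """Per-experiment max -log10(p) over resistance associations whose gene
    is altered in the experiment's cell line; -inf when unlinked."""
    best = {}
    for r in assocs.itertuples(index=False):
        strength = -np.log10(max(r.p, 1e-300))
        key = r.drug_id
        best.setdefault(key, []).append((r.gene, strength))
    out = np.full(len(synergy), -np.inf)
    for i, row in enumerate(synergy.itertuples(index=False)):
        cell = row.cell_id
        s = -np.inf
        for drug in (row.drug_a, row.drug_b):
            for gene, strength in best.get(drug, ()):
                if gene in bem.index and cell in bem.columns and \
                        bem.loc[gene, cell] == 1:
                    s = max(s, strength)
        out[i] = s
    return out


def _curve_values(strength: np.ndarray, synergistic: np.ndarray,
                  thresholds: np.ndarray, n_total: int):
    sel = np.empty(len(thresholds))
    pct = np.empty(len(thresholds))
    for k, t in enumerate(thresholds):
        linked = strength >= t
        n_linked = int(linked.sum())
        sel[k] = n_linked / n_total
        pct[k] = 100.0 * synergistic[linked].mean() if n_linked else np.nan
    return sel, pct


def synergy_enrichment(assocs: pd.DataFrame, synergy: pd.DataFrame,
                       bem: pd.DataFrame, step: float = 0.1,
                       boot: tuple = (5, 0.8), seed: int = 0) -> EnrichmentCurve:
    """Build the enrichment curve from resistance associations and a
    classified synergy table (columns combo_id, cell_id, drug_a, drug_b,
    score)."""
    assocs = assocs[assocs["direction"] == "resistance"]
    if assocs.empty:
        raise ValueError("no resistance-direction associations supplied")
    strength = _link_strength(synergy, assocs, bem)
    synergistic = (synergy["score"].to_numpy(float) >= SYNERGY_THRESHOLD)
    finite = strength[np.isfinite(strength)]
    t_max = float(finite.max()) if len(finite) else 0.0
    thresholds = np.arange(0.0, t_max + step / 2, step)
    n_total = len(synergy)
    sel, pct = _curve_values(strength, synergistic, thresholds, n_total)

    n_boot, frac = boot
    rng = stage_rng(seed, "enrichment-bootstrap")
    boot_sel = np.empty((n_boot, len(thresholds)))
    boot_pct = np.empty((n_boot, len(thresholds)))
    for b in range(n_boot):
        idx = rng.choice(n_total, size=int(round(frac * n_total)), replace=False)
        boot_sel[b], boot_pct[b] = _curve_values(strength[idx],
                                                 synergistic[idx], thresholds,
                                                 len(idx))
    return EnrichmentCurve(thresholds, sel, pct, boot_sel, boot_pct)


def _tissue_anova(y: np.ndarray, tissue: np.ndarray, event: np.ndarray):
    """F-test p for the event term entered after tissue (sequential), via
    nested residual sums of squares."""
    n = len(y)
    t_dum = pd.get_dummies(pd.Series(tissue)).to_numpy(float)
    m1 = np.hstack([np.ones((n, 1)), t_dum[:, 1:]])
    m2 = np.hstack([m1, event.reshape(-1, 1)])

    def rss(m):
        beta, _, rank, _ = np.linalg.lstsq(m, y, rcond=None)
        resid = y - m @ beta
        return float(resid @ resid), int(rank)

    rss1, _ = rss(m1)
    rss2, rank2 = rss(m2)
    dof = n - rank2
    if dof < 1:
        return np.nan
    f = max(0.0, rss1 - rss2) / (rss2 / dof) if rss2 > 0 else np.inf
    return float(stats.f.sf(f, 1, dof))


def synergy_biomarker_anova(synergy: pd.DataFrame, bem: pd.DataFrame,
                            tissues: pd.Series,
                            candidates) -> pd.DataFrame:
    """Tissue-corrected ANOVA per (gene, combination) candidate with BH
    correction across all candidates; effect size is the mean synergy
    difference mutant minus wild-type."""
    rows = []
    for gene, combo in candidates:
        sub = synergy[synergy["combo_id"] == combo]
        cells = [c for c in sub["cell_id"] if c in bem.columns]
        sub = sub[sub["cell_id"].isin(cells)]
        if gene not in bem.index:
            continue
        event = bem.loc[gene, sub["cell_id"]].to_numpy(float)
        y = sub["score"].to_numpy(float)
        if (event == 1).sum() < 2 or (event == 0).sum() < 2:
            continue
        tis = tissues.loc[sub["cell_id"]].to_numpy()
        if len(np.unique(tis)) < 2:
            warnings.warn(
                f"candidate ({gene}, {combo}): single tissue; reduces to a "
                "two-group comparison", stacklevel=2)
        p = _tissue_anova(y, tis, event)
        effect = float(y[event == 1].mean() - y[event == 0].mean())
        rows.append((gene, combo, effect, p,
                     int((event == 1).sum()), int((event == 0).sum())))
    out = pd.DataFrame(rows, columns=["gene", "combo_id", "effect_size", "p",
                                      "n_mut", "n_wt"])
    if out.empty:
        return out.assign(q=pd.Series(dtype=float))
    ok = out["p"].notna()
    q = np.full(len(out), np.nan)
    if ok.any():
        _, q_ok, _, _ = multipletests(out.loc[ok, "p"], method="fdr_bh")
        q[ok.to_numpy()] = q_ok
    return out.assign(q=q)


def validate_directionality(discovery: pd.DataFrame,
                            independent_synergy: pd.DataFrame,
                            bem: pd.DataFrame) -> float:
    """Fraction of discovery associations whose effect size keeps its sign in
    an independent synergy table; candidates absent there are excluded."""
    concordant = total = 0
    for r in discovery.itertuples(index=False):
        sub = independent_synergy[independent_synergy["combo_id"] == r.combo_id]
        sub = sub[sub["cell_id"].isin(bem.columns)]
        if sub.empty or r.gene not in bem.index:
            continue
        event = bem.loc[r.gene, sub["cell_id"]].to_numpy(float)
        if (event == 1).sum() < 1 or (event == 0).sum() < 1:
            continue
        y = sub["score"].to_numpy(float)
        effect = y[event == 1].mean() - y[event == 0].mean()
        if effect == 0 or r.effect_size == 0:
            total += 1
            continue
        total += 1
        if np.sign(effect) == np.sign(r.effect_size):
            concordant += 1
    if total == 0:
        raise ValueError("no discovery association present in the independent table")
    return concordant / total
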