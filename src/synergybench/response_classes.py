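"""In vivo (PDX) and in vitro combination-benefit classes and their
per-combination concordance.

PDX best responses are coded CR=4, PR=3, SD=2, PD=1; the combination class is
derived from the change versus the better monotherapy: +2 or more is synergy,
-2 or less antagonism, anything in between additive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dose_response import SYNERGY_THRESHOLD

__all__ = ["RESPONSE_CODES", "CombinationBenefitClass", "encode_best_response",
           "pdx_combination_class", "classify_pdx_cohort",
           "synergy_rate_concordance"]

RESPONSE_CODES = {"CR": 4, "PR": 3, "SD": 2, "PD": 1}


@dataclass(frozen=True)
class CombinationBenefitClass:
    benefit_class: str  # synergy | additive | antagonism
    delta: int
    efficacy: bool  # optional annotation: combination reached PR or better


def encode_best_response(label: str) -> int:
    """CR=4, PR=3, SD=2, PD=1; a range like 'PR->PD' takes the earliest."""
    if not isinstance(label, str):
        raise ValueError(f"unknown best-response label {label!r}")
    first = label.replace("→", "->").split("->")[0].strip()
    if first not in RESPONSE_CODES:
        raise ValueError(f"unknown best-response label {label!r}")
    return RESPONSE_CODES[first]


def pdx_combination_class(combo: int, mono_a: int, mono_b: int) -> CombinationBenefitClass:
    """Class from the change of the combination versus the better monotherapy."""
    for code in (combo, mono_a, mono_b):
        if code not in (1, 2, 3, 4):
            raise ValueError(f"response codes must be in 1..4, got {code}")
    delta = combo - max(mono_a, mono_b)
    if delta >= 2:
        cls = "synergy"
    elif delta <= -2:
        cls = "antagonism"
    else:
        cls = "additive"
    return CombinationBenefitClass(cls, delta, efficacy=combo >= 3)


def classify_pdx_cohort(records: pd.DataFrame) -> pd.DataFrame:
    """Classify a PDX table with response_combo / response_a / response_b
    label columns (ranges allowed)."""
    out = records.copy()
    combo = out["response_combo"].map(encode_best_response)
    mono_a = out["response_a"].map(encode_best_response)
    mono_b = out["response_b"].map(encode_best_response)
    classes = [pdx_combination_class(c, a, b)
               for c, a, b in zip(combo, mono_a, mono_b)]
    out["delta"] = [c.delta for c in classes]
    out["benefit_class"] = [c.benefit_class for c in classes]
    out["efficacy"] = [c.efficacy for c in classes]
    return out


def synergy_rate_concordance(pdx_classes: pd.DataFrame,
                             cell_synergy: pd.DataFrame,
                             threshold: float = SYNERGY_THRESHOLD):
    """Per-combination paired synergy rates (fraction of PDX models classed
    synergy vs. fraction of cell lines with score >= threshold) and their
    Pearson correlation over shared combinations."""
    pdx_rate = (pdx_classes.assign(syn=pdx_classes["benefit_class"] == "synergy")
                .groupby("combo_id")["syn"].mean())
    cell_rate = (cell_synergy.assign(syn=cell_synergy["score"] >= threshold)
                 .groupby("combo_id")["syn"].mean())
    shared = pdx_rate.index.intersection(cell_rate.index)
    if len(shared) < 3:
        raise ValueError("need >=3 shared combinations for the correlation")
    table = pd.DataFrame({"pdx_synergy_rate": pdx_rate.loc[shared],
                          "cell_synergy_rate": cell_rate.loc[shared]})
    x, y = table["pdx_synergy_rate"], table["cell_synergy_rate"]
    if x.std() == 0 or y.std() == 0:
        r = np.nan
    else:
        r = float(stats.pearsonr(x, y)[0])
    return table, r
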