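"""Challenge-style scoring of prediction tables.

SC1 is scored by the average weighted Pearson correlation across drug
combinations (weight sqrt(n_i - 1)); its tie-break restricts the same metric
to combinations with at least one synergistic cell line.  SC2 is scored by a
signed sequential three-way ANOVA (drug combination, then cell line, then
the binary prediction; intercept fixed to zero) with balanced accuracy as
tie-break.  Team comparison uses paired-bootstrap Bayes factors; benchmarking
uses a within-cell-line permutation null, a replicate-based upper bound and
better-than-random calls at a fixed FDR.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dose_response import SYNERGY_THRESHOLD
from ._seeding import stage_rng

__all__ = [
    "UndefinedMetricError",
    "weighted_pearson",
    "sc1_tiebreak",
    "sc2_primary",
    "balanced_accuracy",
    "bootstrap_bayes_factor",
    "null_model",
    "replicate_upper_bound",
    "better_than_random",
    "combination_predictability",
]

KEY = ["combo_id", "cell_id"]

#: p-value floor protecting SA against log-of-zero underflow.
P_FLOOR = 1e-300


class UndefinedMetricError(ValueError):
    """The metric is undefined on the given inputs (e.g. empty subset)."""


def _merge(pred: pd.DataFrame, obs: pd.DataFrame, pred_col: str) -> pd.DataFrame:
    for df, cols in ((pred, KEY + [pred_col]), (obs, KEY + ["score"])):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns {missing}")
    if pred.duplicated(KEY).any() or obs.duplicated(KEY).any():
        raise ValueError("duplicate (combo_id, cell_id) keys")
    merged = pred[KEY + [pred_col]].merge(obs[KEY + ["score"]], on=KEY, how="left")
    if merged["score"].isna().any():
        raise ValueError("prediction keys absent from the observation table")
    return merged


def _grouped_pearson(codes: np.ndarray, x: np.ndarray, y: np.ndarray,
                     n_groups: int):
    """Per-group Pearson r via group sums; invalid groups (n < 2 or zero
    variance on either side) get NaN."""
    n = np.bincount(codes, minlength=n_groups).astype(float)
    sx = np.bincount(codes, weights=x, minlength=n_groups)
    sy = np.bincount(codes, weights=y, minlength=n_groups)
    sxx = np.bincount(codes, weights=x * x, minlength=n_groups)
    syy = np.bincount(codes, weights=y * y, minlength=n_groups)
    sxy = np.bincount(codes, weights=x * y, minlength=n_groups)
    with np.errstate(invalid="ignore", divide="ignore"):
        vx = sxx - sx * sx / np.where(n > 0, n, 1)
        vy = syy - sy * sy / np.where(n > 0, n, 1)
        cov = sxy - sx * sy / np.where(n > 0, n, 1)
        r = cov / np.sqrt(vx * vy)
    valid = (n >= 2) & (vx > 1e-12) & (vy > 1e-12)
    r = np.where(valid, r, np.nan)
    return r, n


def _weighted_pearson_arrays(codes: np.ndarray, pred: np.ndarray,
                             obs: np.ndarray, n_groups: int,
                             warn: bool = False) -> float:
    r, n = _grouped_pearson(codes, pred, obs, n_groups)
    valid = ~np.isnan(r)
    if warn and (~valid & (n > 0)).any():
        warnings.warn(
            f"{int((~valid & (n > 0)).sum())} combination(s) with undefined "
            "Pearson excluded from the weighted average", stacklevel=3)
    if not valid.any():
        raise UndefinedMetricError("no combination with a defined correlation")
    w = np.sqrt(n[valid] - 1.0)
    return float(np.sum(w * r[valid]) / np.sum(w))


def weighted_pearson(pred: pd.DataFrame, obs: pd.DataFrame,
                     pred_col: str = "prediction") -> float:
    """Average weighted Pearson correlation across drug combinations.

    ``rho_w = sum_i sqrt(n_i - 1) rho_i / sum_i sqrt(n_i - 1)`` with ``rho_i``
    the per-combination Pearson of predicted vs. observed scores and ``n_i``
    the number of cell lines.  Combinations with undefined correlation
    (fewer than two cells or zero variance) are excluded from both sums.
    """
    merged = _merge(pred, obs, pred_col)
    codes, uniques = pd.factorize(merged["combo_id"], sort=True)
    return _weighted_pearson_arrays(
        codes, merged[pred_col].to_numpy(float), merged["score"].to_numpy(float),
        len(uniques), warn=True)


def sc1_tiebreak(pred: pd.DataFrame, obs: pd.DataFrame,
                 pred_col: str = "prediction",
                 threshold: float = SYNERGY_THRESHOLD) -> float:
    """Weighted Pearson restricted to combinations with at least one cell
    line whose observed score reaches the synergy threshold."""
    qualifying = obs.loc[obs["score"] >= threshold, "combo_id"].unique()
    if len(qualifying) == 0:
        raise UndefinedMetricError("no combination reaches the synergy threshold")
    keep = obs["combo_id"].isin(qualifying)
    return weighted_pearson(pred[pred["combo_id"].isin(qualifying)],
                            obs[keep], pred_col)


def _design_matrices(merged: pd.DataFrame, pred_col: str):
    """No-intercept sequential design: full drug-combination indicators,
    cell-line indicators with one level dropped, then the binary prediction."""
    dc = pd.get_dummies(merged["combo_id"]).to_numpy(float)
    cl = pd.get_dummies(merged["cell_id"]).to_numpy(float)[:, 1:]
    x = merged[pred_col].to_numpy(float).reshape(-1, 1)
    return dc, cl, x


def _rss(m: np.ndarray, y: np.ndarray):
    beta, _, rank, _ = np.linalg.lstsq(m, y, rcond=None)
    resid = y - m @ beta
    return float(resid @ resid), int(rank), beta


def sc2_primary(pred: pd.DataFrame, obs: pd.DataFrame,
                pred_col: str = "prediction_binary") -> float:
    """Signed sequential three-way ANOVA score SA = -sgn x log10(p).

    Observed synergy is regressed (no intercept) on drug-combination
    indicators, then cell-line indicators, then the team's binary prediction;
    ``p`` is the type-1 F-test p-value for the prediction term entered last
    and the sign comes from its fitted coefficient, so correct-direction
    separation yields positive SA.
    """
    merged = _merge(pred, obs, pred_col)
    x_vals = merged[pred_col].to_numpy()
    if not np.isin(x_vals, (0, 1)).all():
        raise ValueError("SC2 predictions must be binary 0/1")
    if len(np.unique(x_vals)) < 2:
        raise UndefinedMetricError("prediction is constant; SA undefined")
    if merged["combo_id"].nunique() < 2 or merged["cell_id"].nunique() < 2:
        raise ValueError("need >=2 combinations and >=2 cell lines")
    dc, cl, x = _design_matrices(merged, pred_col)
    y = merged["score"].to_numpy(float)
    return _sa_from_design(dc, cl, x, y)


def _sa_from_design(dc, cl, x, y) -> float:
    m2 = np.hstack([dc, cl])
    m3 = np.hstack([dc, cl, x])
    rss2, rank2, _ = _rss(m2, y)
    rss3, rank3, beta3 = _rss(m3, y)
    df_x = rank3 - rank2
    if df_x < 1:  # prediction aliased with drug/cell effects
        raise UndefinedMetricError("prediction term aliased; SA undefined")
    dof = len(y) - rank3
    if dof < 1:
        raise UndefinedMetricError("no residual degrees of freedom")
    f_stat = max(0.0, (rss2 - rss3) / df_x) / (rss3 / dof)
    p = max(float(stats.f.sf(f_stat, df_x, dof)), P_FLOOR)
    sign = float(np.sign(beta3[-1]))
    return float(sign * -np.log10(p))


def balanced_accuracy(pred_binary, truth_binary) -> float:
    """(sensitivity + specificity) / 2 for binary predictions."""
    pred = np.asarray(pred_binary, dtype=int)
    truth = np.asarray(truth_binary, dtype=int)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth lengths differ")
    pos, neg = truth == 1, truth == 0
    if not pos.any() or not neg.any():
        raise UndefinedMetricError("both truth classes must be present")
    sens = float(np.mean(pred[pos] == 1))
    spec = float(np.mean(pred[neg] == 0))
    return 0.5 * (sens + spec)


def _metric_on_indices(codes, preds, obs_scores, n_groups, merged_list, metric,
                       idx):
    """Primary metric per team on one bootstrap index set."""
    out = []
    if metric == "SC1":
        for p in preds:
            out.append(_weighted_pearson_arrays(codes[idx], p[idx],
                                                obs_scores[idx], n_groups))
    else:
        for m in merged_list:
            sub = m.iloc[idx]
            dc, cl, x = _design_matrices(sub, "prediction_binary")
            if len(np.unique(x)) < 2:
                out.append(np.nan)
                continue
            try:
                out.append(_sa_from_design(dc, cl, x, sub["score"].to_numpy(float)))
            except UndefinedMetricError:
                out.append(np.nan)
    return out


def bootstrap_bayes_factor(team_preds: dict, obs: pd.DataFrame,
                           metric: str = "SC1", iters: int = 1000,
                           seed: int = 0) -> pd.DataFrame:
    """Paired-bootstrap Bayes factors against the best team.

    The same bootstrap index sets are applied to every team; for team T,
    ``K_T = #(pm_T,i < pm_best,i) / #(pm_T,i >= pm_best,i)`` where best is the
    team with the highest non-bootstrapped primary metric.  Teams with
    ``K <= 5`` are statistically indistinguishable from the best.
    """
    if metric not in ("SC1", "SC2"):
        raise ValueError("metric must be 'SC1' or 'SC2'")
    if len(team_preds) < 2:
        raise ValueError("need at least 2 teams")
    pred_col = "prediction" if metric == "SC1" else "prediction_binary"
    teams = sorted(team_preds)
    merged_list = [_merge(team_preds[t], obs, pred_col) for t in teams]
    key0 = merged_list[0][KEY]
    for m in merged_list[1:]:
        if not m[KEY].equals(key0):
            raise ValueError("all teams must be scored on identical observations")
    n_obs = len(key0)
    codes, uniques = pd.factorize(merged_list[0]["combo_id"], sort=True)
    obs_scores = merged_list[0]["score"].to_numpy(float)
    preds = [m[pred_col].to_numpy(float) for m in merged_list]

    if metric == "SC1":
        pm = [_weighted_pearson_arrays(codes, p, obs_scores, len(uniques))
              for p in preds]
    else:
        pm = [sc2_primary(team_preds[t], obs) for t in teams]
    best_idx = int(np.argmax(pm))

    rng = stage_rng(seed, "bootstrap-bf")
    boot = np.empty((iters, len(teams)))
    for i in range(iters):
        idx = rng.integers(0, n_obs, n_obs)
        boot[i] = _metric_on_indices(codes, preds, obs_scores, len(uniques),
                                     merged_list, metric, idx)

    out = []
    for t_i, team in enumerate(teams):
        pair = ~(np.isnan(boot[:, t_i]) | np.isnan(boot[:, best_idx]))
        less = int(np.sum(boot[pair, t_i] < boot[pair, best_idx]))
        geq = int(np.sum(boot[pair, t_i] >= boot[pair, best_idx]))
        k = float(less) / geq if geq > 0 else np.inf
        out.append((team, float(pm[t_i]), k, teams[best_idx]))
    df = pd.DataFrame(out, columns=["team", "pm", "K", "best_team"])
    return df.sort_values("pm", ascending=False, ignore_index=True)


def null_model(obs: pd.DataFrame, metric: str = "SC1", n_perm: int = 1000,
               seed: int = 0, threshold: float = SYNERGY_THRESHOLD) -> np.ndarray:
    """Permutation null: synergy values shuffled within each cell line across
    combinations, then treated as predictions and rescored."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = stage_rng(seed, "null-model")
    obs = obs.sort_values(KEY, ignore_index=True)
    codes, uniques = pd.factorize(obs["combo_id"], sort=True)
    scores = obs["score"].to_numpy(float)
    cell_groups = [np.flatnonzero(obs["cell_id"].to_numpy() == c)
                   for c in obs["cell_id"].unique()]
    vals = np.empty(n_perm)
    perm_scores = scores.copy()
    for i in range(n_perm):
        for g in cell_groups:
            perm_scores[g] = scores[g[rng.permutation(len(g))]]
        if metric == "SC1":
            vals[i] = _weighted_pearson_arrays(codes, perm_scores, scores,
                                               len(uniques))
        else:
            pred = obs[KEY].copy()
            pred["prediction_binary"] = (perm_scores >= threshold).astype(int)
            try:
                vals[i] = sc2_primary(pred, obs)
            except UndefinedMetricError:
                vals[i] = np.nan
    return vals


def replicate_upper_bound(rep1: pd.DataFrame, rep2: pd.DataFrame,
                          metric: str = "SC1") -> float:
    """Primary metric achieved when one replicate predicts the other."""
    shared = rep1[KEY].merge(rep2[KEY], on=KEY)
    if shared["combo_id"].nunique() < 2:
        raise UndefinedMetricError("need replicate pairs for >=2 combinations")
    r1 = rep1.merge(shared, on=KEY)
    r2 = rep2.merge(shared, on=KEY)
    pred = r1[KEY].copy()
    if metric == "SC1":
        pred["prediction"] = r1["score"].to_numpy()
        return weighted_pearson(pred, r2)
    pred["prediction_binary"] = (r1["score"].to_numpy()
                                 >= SYNERGY_THRESHOLD).astype(int)
    return sc2_primary(pred, r2)


def better_than_random(team_pms: dict, null: np.ndarray,
                       fdr: float = 0.05) -> pd.DataFrame:
    """Empirical add-one p-values against the permutation null with
    Benjamini-Hochberg control at ``fdr``."""
    null = np.asarray(null, dtype=float)
    null = null[~np.isnan(null)]
    teams = sorted(team_pms)
    p = np.array([(1.0 + np.sum(null >= team_pms[t])) / (1.0 + len(null))
                  for t in teams])
    reject, q, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return pd.DataFrame({"team": teams, "pm": [team_pms[t] for t in teams],
                         "p": p, "q": q, "passes_fdr": reject})


def combination_predictability(team_preds: dict, obs: pd.DataFrame,
                               pred_col: str = "prediction") -> pd.DataFrame:
    """Mean per-combination Pearson across teams, classed poor (inside the
    random band (-0.25, 0.25)), well (> 0.5) or intermediate."""
    if len(team_preds) < 2:
        raise ValueError("need >=2 teams")
    per_team = []
    for team in sorted(team_preds):
        merged = _merge(team_preds[team], obs, pred_col)
        codes, uniques = pd.factorize(merged["combo_id"], sort=True)
        r, _ = _grouped_pearson(codes, merged[pred_col].to_numpy(float),
                                merged["score"].to_numpy(float), len(uniques))
        per_team.append(pd.Series(r, index=uniques))
    mat = pd.concat(per_team, axis=1)
    counts = obs.groupby("combo_id").size().reindex(mat.index).fillna(0)
    small = counts < 3
    if small.any():
        warnings.warn(f"{int(small.sum())} combination(s) with <3 cells excluded",
                      stacklevel=2)
    mat = mat[~small]
    mean_r = mat.mean(axis=1)

    def classify(r: float) -> str:
        if np.isnan(r):
            return "undefined"
        if r > 0.5:
            return "well"
        if -0.25 < r < 0.25:
            return "poor"
        return "intermediate"

    return pd.DataFrame({"combo_id": mean_r.index, "mean_pearson": mean_r.values,
                         "predictability": [classify(v) for v in mean_r.values]})
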