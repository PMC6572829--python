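"""Label-free aggregation of binary prediction tables.

The spectral meta-learner estimates each team's balanced accuracy (up to a
positive scale) from the leading eigenvector of the off-diagonal structure of
the prediction covariance matrix -- valid when teams are conditionally
independent given the true label -- and aggregates by a weighted vote.
Random aggregation (equal-weight majority vote of random team subsets) is the
reference it is compared against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import balanced_accuracy
from ._seeding import stage_rng

__all__ = ["PredictionMatrix", "sml_estimate", "sml_ensemble",
           "random_aggregation", "average_continuous"]


@dataclass
class PredictionMatrix:
    """Teams x experiments matrix of {-1, +1} recoded binary predictions."""

    values: np.ndarray
    team_ids: list
    experiment_keys: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (teams x experiments)")
        if not np.isin(self.values, (-1, 1)).all():
            raise ValueError("entries must be -1/+1")
        if self.values.shape[0] != len(self.team_ids):
            raise ValueError("team_ids length mismatch")
        if self.values.shape[1] != len(self.experiment_keys):
            raise ValueError("experiment_keys length mismatch")

    @classmethod
    def from_table(cls, preds: pd.DataFrame,
                   pred_col: str = "prediction_binary") -> "PredictionMatrix":
        """Pivot a tidy (team, combo_id, cell_id, prediction) table.

        Experiments not predicted by every team are dropped (complete-case).
        """
        wide = preds.pivot_table(index="team", columns=["combo_id", "cell_id"],
                                 values=pred_col, aggfunc="first")
        wide = wide.dropna(axis=1)
        if wide.empty:
            raise ValueError("no experiment is covered by all teams")
        values = wide.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("binary predictions must be 0/1")
        return cls(values=2 * values.astype(int) - 1,
                   team_ids=list(wide.index),
                   experiment_keys=list(wide.columns))


def _as_matrix(preds) -> PredictionMatrix:
    if isinstance(preds, PredictionMatrix):
        return preds
    if isinstance(preds, pd.DataFrame):
        return PredictionMatrix.from_table(preds)
    raise TypeError("expected PredictionMatrix or tidy DataFrame")


def sml_estimate(preds, max_iter: int = 100, tol: float = 1e-8) -> pd.Series:
    """Spectral estimate of per-team performance (2*BAC - 1 up to scale).

    The sample covariance of conditionally independent {-1,+1} predictions is
    rank-1 off the diagonal; the diagonal is iteratively re-imputed from the
    current rank-1 reconstruction before extracting the leading eigenvector.
    The global sign is fixed so the majority of entries are positive.
    Constant teams are excluded with a warning.
    """
    pm = _as_matrix(preds)
    values = pm.values.astype(float)
    keep = values.std(axis=1) > 0
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} constant team(s) from SML",
            stacklevel=2)
    values = values[keep]
    teams = [t for t, k in zip(pm.team_ids, keep) if k]
    if len(teams) < 3:
        raise ValueError("SML needs >=3 non-constant teams")

    q = np.cov(values)
    r = q.copy()
    for _ in range(max_iter):
        eigvals, eigvecs = np.linalg.eigh(r)
        lam, v1 = eigvals[-1], eigvecs[:, -1]
        new_diag = lam * v1 ** 2
        if np.max(np.abs(new_diag - np.diag(r))) < tol:
            break
        np.fill_diagonal(r, new_diag)
    v = np.sqrt(max(lam, 0.0)) * v1
    if np.sum(v > 0) < np.sum(v < 0) or (np.sum(v > 0) == np.sum(v < 0)
                                         and v.sum() < 0):
        v = -v
    return pd.Series(v, index=teams, name="sml_score")


def sml_ensemble(preds) -> pd.Series:
    """Weighted-vote ensemble prediction: sign(sum_i v_i x_i) mapped to {0,1};
    a zero vote predicts 0 (non-synergy)."""
    pm = _as_matrix(preds)
    v = sml_estimate(pm)
    rows = [pm.team_ids.index(t) for t in v.index]
    votes = v.to_numpy() @ pm.values[rows].astype(float)
    labels = (votes > 0).astype(int)
    return pd.Series(labels, index=pd.Index(pm.experiment_keys), name="sml")


def random_aggregation(preds, n: int, truth, repeats: int = 10,
                       seed: int = 0) -> tuple[float, float]:
    """Mean +/- standard error of majority-vote BAC over ``repeats`` random
    subsets of ``n`` teams (ties vote 0 / non-synergy)."""
    pm = _as_matrix(preds)
    n_teams = pm.values.shape[0]
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > n_teams:
        raise ValueError("n exceeds the number of teams")
    truth = np.asarray(truth, dtype=int)
    if truth.shape[0] != pm.values.shape[1]:
        raise ValueError("truth length must match number of experiments")
    rng = stage_rng(seed, "random-aggregation")
    bacs = np.empty(repeats)
    for i in range(repeats):
        rows = rng.choice(n_teams, size=n, replace=False)
        votes = pm.values[rows].sum(axis=0)
        bacs[i] = balanced_accuracy((votes > 0).astype(int), truth)
    return float(bacs.mean()), float(bacs.std(ddof=0) / np.sqrt(repeats))


def average_continuous(preds: pd.DataFrame,
                       pred_col: str = "prediction") -> pd.DataFrame:
    """Utility: simple average of continuous predictions across teams."""
    out = (preds.groupby(["combo_id", "cell_id"], as_index=False)[pred_col]
           .mean())
    return out.rename(columns={pred_col: "prediction"})
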