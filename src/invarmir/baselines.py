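"""Correlation and regression baselines, interaction ranking, and Borda
rank aggregation.

Pearson scores each miRNA-mRNA pair by the plain correlation of the two
expression profiles; Lasso regresses each mRNA on all miRNAs jointly with
an L1 penalty.  Rankings order pairs by score magnitude by default — miRNA
regulation is typically repressive, so strong negative associations must
rank highly.  Borda aggregation averages per-method ranks, letting the
ensemble inherit complementary signal from its members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix
from .icp import InteractionScoreMatrix

logger = logging.getLogger(__name__)


@dataclass
class InteractionRanking:
    """Ordered list of regulator-target pairs.

    The table has columns ``regulator_id, target_id, score, rank,
    avg_rank`` (plus ``mean_rank`` for Borda output).  Ordering is by
    decreasing score magnitude (or decreasing signed score for
    ``direction="signed"``), with exact ties broken lexicographically on
    ``(regulator_id, target_id)``; ``rank`` is the contiguous 1..n position
    after that tie-break while ``avg_rank`` assigns tied scores the mean of
    their positions (the value Borda averages, so ties contribute equally).
    """

    table: pd.DataFrame
    method: str
    direction: str = "abs"

    def __post_init__(self) -> None:
        required = {"regulator_id", "target_id", "score", "rank", "avg_rank"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"ranking table missing column(s) {sorted(missing)}")
        n = len(self.table)
        if not np.array_equal(self.table["rank"].to_numpy(), np.arange(1, n + 1)):
            raise ValueError("ranks must be contiguous 1..n in table order")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.table["regulator_id"], self.table["target_id"]))

    def pair_universe(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.pairs)


def rank_interactions(matrix: InteractionScoreMatrix, direction: str = "abs") -> InteractionRanking:
    """Turn a score matrix into a full ranking of all pairs.

    ``direction="abs"`` ranks by decreasing |score| (default; repression
    counts), ``"signed"`` by decreasing signed score.
    """
    if direction not in ("abs", "signed"):
        raise ValueError(f"unknown direction {direction!r}")
    long = matrix.to_long().rename(columns={"miRNA": "regulator_id", "mRNA": "target_id"})
    key = long["score"].abs() if direction == "abs" else long["score"]
    long = long.assign(_key=-key.to_numpy())
    long["avg_rank"] = stats.rankdata(long["_key"], method="average")
    long = long.sort_values(
        ["_key", "regulator_id", "target_id"], kind="stable"
    ).reset_index(drop=True)
    long["rank"] = np.arange(1, len(long) + 1)
    table = long[["regulator_id", "target_id", "score", "rank", "avg_rank"]]
    return InteractionRanking(table=table, method=matrix.method, direction=direction)


def pearson_scores(
    regulators: ExpressionMatrix, targets: ExpressionMatrix
) -> InteractionScoreMatrix:
    """Pearson correlation of each regulator profile with each target
    profile across all samples.  Zero-variance features get score 0 with a
    warning."""
    if regulators.sample_ids != targets.sample_ids:
        raise ValueError("regulator and target matrices have mismatched samples")
    R = regulators.values
    T = targets.values
    Rc = R - R.mean(axis=1, keepdims=True)
    Tc = T - T.mean(axis=1, keepdims=True)
    rs = np.sqrt((Rc ** 2).sum(axis=1))
    ts = np.sqrt((Tc ** 2).sum(axis=1))
    bad_r, bad_t = rs == 0, ts == 0
    if bad_r.any() or bad_t.any():
        logger.warning(
            "%d zero-variance feature(s); their correlations set to 0",
            int(bad_r.sum() + bad_t.sum()),
        )
    rs[bad_r] = 1.0
    ts[bad_t] = 1.0
    corr = (Rc @ Tc.T) / np.outer(rs, ts)
    corr[bad_r, :] = 0.0
    corr[:, bad_t] = 0.0
    corr = np.clip(corr, -1.0, 1.0)
    return InteractionScoreMatrix(
        regulator_ids=regulators.feature_ids,
        target_ids=targets.feature_ids,
        scores=corr,
        method="pearson",
    )


def lasso_scores(
    regulators: ExpressionMatrix,
    targets: ExpressionMatrix,
    lambda_rule: str = "cv",
    fixed_lambda: float | None = None,
    seed: int = 0,
    n_folds: int = 10,
) -> InteractionScoreMatrix:
    """Per target, L1-penalised regression of the target on all regulators.

    Predictors are standardised for the fit; reported scores are the fitted
    coefficients on the original predictor scale.  The penalty is chosen by
    ``n_folds``-fold cross-validation at minimum CV error (seeded folds) or
    fixed via ``fixed_lambda``.
    """
    from sklearn.linear_model import Lasso, LassoCV, LinearRegression
    from sklearn.model_selection import KFold

    if lambda_rule not in ("cv", "fixed"):
        raise ValueError(f"unknown lambda_rule {lambda_rule!r}")
    if lambda_rule == "fixed" and fixed_lambda is None:
        raise ValueError("lambda_rule='fixed' requires fixed_lambda")
    if regulators.sample_ids != targets.sample_ids:
        raise ValueError("regulator and target matrices have mismatched samples")

    X = regulators.values.T  # samples x p
    sd = X.std(axis=0)
    zero_var = sd == 0
    if zero_var.any():
        logger.warning("%d zero-variance regulator(s); coefficients forced to 0",
                       int(zero_var.sum()))
    sd_safe = np.where(zero_var, 1.0, sd)
    Xs = (X - X.mean(axis=0)) / sd_safe
    Xs[:, zero_var] = 0.0

    out = np.zeros((regulators.n_features, targets.n_features))
    for t_idx in range(targets.n_features):
        y = targets.values[t_idx]
        if lambda_rule == "cv":
            cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
            model = LassoCV(cv=cv, random_state=seed, max_iter=5000)
        elif fixed_lambda == 0:
            model = LinearRegression()
        else:
            model = Lasso(alpha=fixed_lambda, max_iter=5000)
        model.fit(Xs, y)
        out[:, t_idx] = model.coef_ / sd_safe  # back to original scale
    out[zero_var, :] = 0.0
    return InteractionScoreMatrix(
        regulator_ids=regulators.feature_ids,
        target_ids=targets.feature_ids,
        scores=out,
        method="lasso",
    )


def borda_aggregate(rankings: list[InteractionRanking]) -> InteractionRanking:
    """Borda ensemble: each pair's score is the arithmetic mean of its ranks
    across the input rankings; the ensemble orders pairs by increasing mean
    rank (ties broken lexicographically) and reassigns ranks 1..n.

    All rankings must cover the identical pair universe; a mismatch raises
    with the symmetric difference listed rather than silently intersecting.
    """
    if len(rankings) < 2:
        raise ValueError("Borda aggregation needs at least 2 rankings")
    universe = rankings[0].pair_universe()
    for r in rankings[1:]:
        if r.pair_universe() != universe:
            diff = sorted(universe ^ r.pair_universe())
            raise ValueError(
                f"pair universes differ between {rankings[0].method!r} and "
                f"{r.method!r}; symmetric difference (first 10): {diff[:10]}"
            )
    acc: pd.Series | None = None
    for r in rankings:
        s = r.table.set_index(["regulator_id", "target_id"])["avg_rank"]
        acc = s if acc is None else acc.add(s)
    mean_rank = (acc / len(rankings)).rename("mean_rank").reset_index()
    mean_rank["avg_rank"] = stats.rankdata(mean_rank["mean_rank"], method="average")
    mean_rank = mean_rank.sort_values(
        ["mean_rank", "regulator_id", "target_id"], kind="stable"
    ).reset_index(drop=True)
    mean_rank["rank"] = np.arange(1, len(mean_rank) + 1)
    # smaller mean rank = better; store the negated mean rank as the score so
    # signed-descending ordering semantics still hold for the ensemble table
    mean_rank["score"] = -mean_rank["mean_rank"]
    table = mean_rank[["regulator_id", "target_id", "score", "rank", "avg_rank", "mean_rank"]]
    method = "borda(" + "+".join(r.method for r in rankings) + ")"
    return InteractionRanking(table=table, method=method, direction="signed")


__all__ = [
    "InteractionRanking",
    "rank_interactions",
    "pearson_scores",
    "lasso_scores",
    "borda_aggregate",
]
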