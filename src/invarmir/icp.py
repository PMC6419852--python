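"""Invariant causal prediction (ICP) per target, and the hidden-confounder
moment-difference variant.

The model: across environments ``e`` the target satisfies
``Y^e = mu + X^e_{S*} gamma* + eps^e`` with the error distribution of
``eps`` identical in every environment and independent of the causal
predictors ``X_{S*}``.  A candidate predictor subset ``S`` is *accepted*
when the pooled-regression residuals look invariant — same mean (Welch
two-sample t-test) and same variance (variance-ratio F-test) — in each
environment versus the rest.  The parent estimate is the intersection of
all accepted subsets, which under the model is contained in the true
parent set with probability at least ``1 - alpha``.

The hidden-variable variant ``Y^e = X^e gamma* + g(H^e, eps^e)`` tolerates
unobserved confounders ``H`` whose joint distribution with the noise is
invariant; ``gamma*`` is then recovered from between-environment shifts of
the second moments (a difference-of-moments estimator), yielding a dense
coefficient vector instead of a subset estimate.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .expression import EnvironmentAssignment, ExpressionMatrix

logger = logging.getLogger(__name__)


class UntestableSubsetError(ValueError):
    """Raised when a predictor subset cannot be tested (collinear design)."""


# ---------------------------------------------------------------------------
# pooled regression
# ---------------------------------------------------------------------------

@dataclass
class RegressionFit:
    """OLS fit of the target on a predictor subset, pooled over all samples."""

    subset: tuple[int, ...]
    intercept: float
    coefficients: np.ndarray  # aligned to subset
    residuals: np.ndarray     # over all pooled samples
    coef_stderr: np.ndarray = field(default_factory=lambda: np.empty(0))
    df_resid: int = 0

    def coef_confint(self, alpha: float) -> np.ndarray:
        """Per-coefficient ``1 - alpha`` confidence interval, shape (|S|, 2)."""
        if len(self.subset) == 0:
            return np.empty((0, 2))
        tq = stats.t.ppf(1 - alpha / 2, self.df_resid)
        lo = self.coefficients - tq * self.coef_stderr
        hi = self.coefficients + tq * self.coef_stderr
        return np.column_stack([lo, hi])


def fit_pooled_regression(X: np.ndarray, Y: np.ndarray, subset) -> RegressionFit:
    """Ordinary least squares of ``Y`` on ``X[:, subset]`` with intercept,
    pooled over all samples of all environments.

    The empty subset yields the intercept-only fit (residuals are the
    mean-centred target).  A collinear subset raises
    :class:`UntestableSubsetError`.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float).ravel()
    subset = tuple(int(j) for j in subset)
    n = Y.shape[0]
    if len(subset) >= n:
        raise UntestableSubsetError(
            f"subset size {len(subset)} not below sample count {n}"
        )
    design = np.column_stack([np.ones(n)] + [X[:, j] for j in subset])
    q = design.shape[1]
    coef, _, rank, _ = np.linalg.lstsq(design, Y, rcond=None)
    if rank < q:
        raise UntestableSubsetError(f"collinear predictor subset {subset}")
    resid = Y - design @ coef
    df = n - q
    if df > 0 and len(subset):
        sigma2 = float(resid @ resid) / df
        xtx_inv = np.linalg.inv(design.T @ design)
        stderr = np.sqrt(np.clip(sigma2 * np.diag(xtx_inv)[1:], 0.0, None))
    else:
        stderr = np.zeros(len(subset))
    return RegressionFit(
        subset=subset,
        intercept=float(coef[0]),
        coefficients=coef[1:].copy(),
        residuals=resid,
        coef_stderr=stderr,
        df_resid=df,
    )


# ---------------------------------------------------------------------------
# invariance testing
# ---------------------------------------------------------------------------

def _welch_t_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)

def _f_test_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        return 1.0
    if va == 0.0 or vb == 0.0:
        return 0.0
    f = va / vb
    dist = stats.f(a.size - 1, b.size - 1)
    return float(min(1.0, 2.0 * min(dist.cdf(f), dist.sf(f))))


def invariance_pvalue(
    residuals: np.ndarray,
    env: EnvironmentAssignment,
    e: str,
    sample_ids: list[str],
) -> float:
    """P-value that pooled residuals are invariant in environment ``e``
    versus all remaining samples.

    Combines a Welch two-sample t-test on the means with a two-sided
    variance-ratio F-test on the variances by Bonferroni:
    ``min(1, 2 * min(p_t, p_F))``.
    """
    residuals = np.asarray(residuals, dtype=float)
    mask = env.mask(e, sample_ids)
    r_in, r_out = residuals[mask], residuals[~mask]
    if r_in.size < env.min_size or r_out.size < env.min_size:
        raise ValueError(
            f"environment {e!r} split sizes {r_in.size}/{r_out.size} below "
            f"minimum {env.min_size}"
        )
    p_t = _welch_t_pvalue(r_in, r_out)
    p_f = _f_test_pvalue(r_in, r_out)
    return min(1.0, 2.0 * min(p_t, p_f))


@dataclass
class SubsetTestResult:
    """Outcome of the invariance test for one predictor subset."""

    subset: tuple[int, ...]
    p_invariance: float
    accepted: bool
    fit: RegressionFit


def test_subset(
    X: np.ndarray,
    Y: np.ndarray,
    subset,
    env: EnvironmentAssignment,
    sample_ids: list[str],
    alpha: float = 0.05,
) -> SubsetTestResult:
    """Fit the pooled regression on ``subset`` and test residual invariance
    in every environment; Bonferroni over environments.

    ``p_invariance = min(1, |E| * min_e p_e)``; accepted iff it is at least
    ``alpha``.
    """
    fit = fit_pooled_regression(X, Y, subset)
    pvals = [
        invariance_pvalue(fit.residuals, env, e, sample_ids)
        for e in env.environments
    ]
    p = min(1.0, len(env.environments) * min(pvals))
    return SubsetTestResult(subset=fit.subset, p_invariance=p, accepted=p >= alpha, fit=fit)


# ---------------------------------------------------------------------------
# parent estimation (plain ICP)
# ---------------------------------------------------------------------------

@dataclass
class ICPResult:
    """Per-target ICP output: accepted subsets, their intersection (the
    parent estimate), per-predictor confidence envelopes and scores."""

    target_id: str
    alpha: float
    accepted_sets: list[tuple[int, ...]]
    parent_set: frozenset[int]
    coefficient_bounds: np.ndarray  # (p, 2)
    scores: np.ndarray              # (p,)
    model_rejected: bool
    subset_results: list[SubsetTestResult] = field(default_factory=list, repr=False)


def _lasso_entry_order(X: np.ndarray, Y: np.ndarray) -> list[int]:
    """Predictor indices ordered by first entry along the lasso path."""
    from sklearn.linear_model import lars_path

    Xs = X - X.mean(axis=0)
    sd = Xs.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = Xs / sd
    yc = Y - Y.mean()
    alphas, _, coefs = lars_path(Xs, yc, method="lasso")
    entry = np.full(X.shape[1], np.inf)
    for j in range(X.shape[1]):
        nz = np.nonzero(coefs[j] != 0)[0]
        if nz.size:
            entry[j] = nz[0]
    return [int(j) for j in np.argsort(entry, kind="stable")]


def icp_parents(
    X: np.ndarray,
    Y: np.ndarray,
    env: EnvironmentAssignment,
    sample_ids: list[str],
    alpha: float = 0.05,
    max_set_size: int = 3,
    preselect: int = 10,
    exhaustive: bool = False,
    target_id: str = "",
) -> ICPResult:
    """Estimate the invariant parent set of one target.

    Enumerates subsets of the candidate predictors up to ``max_set_size``
    (the empty set included), tests each for residual invariance, and
    intersects the accepted subsets.  With ``exhaustive=True`` all ``2^p``
    subsets are searched (practical for p <= ~15); otherwise candidates are
    the first ``preselect`` predictors to enter the lasso path, which keeps
    the search tractable at p = 30.

    Collinear subsets are untestable and treated as rejected (logged).
    ``coefficient_bounds[j]`` is the union envelope of the OLS confidence
    intervals of predictor ``j`` over accepted subsets containing it
    ([0, 0] when it appears in none); ``scores[j]`` is the signed
    coefficient of largest magnitude over those subsets (0 when in none).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float).ravel()
    p = X.shape[1]
    if p < 1:
        raise ValueError("need at least one predictor")
    if exhaustive:
        candidates = list(range(p))
        max_size = p
        if p > 15:
            logger.warning("exhaustive ICP over p=%d predictors (2^%d subsets)", p, p)
    else:
        max_size = min(max_set_size, p)
        if preselect < p:
            candidates = _lasso_entry_order(X, Y)[:preselect]
            logger.info(
                "target %s: lasso-path preselection truncated %d predictors to %d",
                target_id, p, len(candidates),
            )
        else:
            candidates = list(range(p))

    results: list[SubsetTestResult] = []
    accepted: list[tuple[int, ...]] = []
    for size in range(0, max_size + 1):
        for subset in itertools.combinations(sorted(candidates), size):
            try:
                res = test_subset(X, Y, subset, env, sample_ids, alpha=alpha)
            except UntestableSubsetError as exc:
                logger.warning("target %s: subset %s untestable (%s); rejected",
                               target_id, subset, exc)
                continue
            results.append(res)
            if res.accepted:
                accepted.append(res.subset)

    if accepted:
        parents = frozenset(accepted[0])
        for s in accepted[1:]:
            parents &= frozenset(s)
    else:
        parents = frozenset()

    bounds = np.zeros((p, 2))
    scores = np.zeros(p)
    seen = np.zeros(p, dtype=bool)
    for res in results:
        if not res.accepted or not res.subset:
            continue
        ci = res.fit.coef_confint(alpha)
        for pos, j in enumerate(res.subset):
            if not seen[j]:
                bounds[j] = ci[pos]
                seen[j] = True
            else:
                bounds[j, 0] = min(bounds[j, 0], ci[pos, 0])
                bounds[j, 1] = max(bounds[j, 1], ci[pos, 1])
            if abs(res.fit.coefficients[pos]) > abs(scores[j]):
                scores[j] = res.fit.coefficients[pos]
    return ICPResult(
        target_id=target_id,
        alpha=alpha,
        accepted_sets=accepted,
        parent_set=parents,
        coefficient_bounds=bounds,
        scores=scores,
        model_rejected=not accepted,
        subset_results=results,
    )


# ---------------------------------------------------------------------------
# hidden-confounder variant
# ---------------------------------------------------------------------------

@dataclass
class HiddenICPResult:
    """Dense causal-coefficient estimate under hidden confounding."""

    target_id: str
    coefficients: np.ndarray        # (p,)
    conf_intervals: np.ndarray      # (p, 2)
    significant: np.ndarray         # (p,) bool
    degenerate: bool = False


def _moment_difference_system(
    X: np.ndarray, Y: np.ndarray, masks: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Stack ``(G_e - G)`` and ``(g_e - g)`` over environments, where
    ``G_e = X_e'X_e / n_e`` and ``g_e = X_e'Y_e / n_e`` (pooled G, g)."""
    n, p = X.shape
    G = X.T @ X / n
    g = X.T @ Y / n
    A = np.empty((len(masks) * p, p))
    b = np.empty(len(masks) * p)
    for i, m in enumerate(masks):
        Xe, Ye = X[m], Y[m]
        ne = Xe.shape[0]
        A[i * p:(i + 1) * p] = Xe.T @ Xe / ne - G
        b[i * p:(i + 1) * p] = Xe.T @ Ye / ne - g
    return A, b


def _solve_stacked(A: np.ndarray, b: np.ndarray, target_id: str = "") -> np.ndarray:
    gamma, _, rank, sv = np.linalg.lstsq(A, b, rcond=None)
    p = A.shape[1]
    if rank < p or (sv.size and sv[0] > 0 and sv[-1] / sv[0] < 1e-10):
        ridge = 1e-8 * (sv[0] ** 2 if sv.size and sv[0] > 0 else 1.0)
        logger.warning(
            "target %s: singular moment-difference system (rank %d of %d); "
            "ridge-stabilised solve", target_id, rank, p,
        )
        gamma = np.linalg.solve(A.T @ A + ridge * np.eye(p), A.T @ b)
    return gamma


def hidden_icp_coefficients(
    X: np.ndarray,
    Y: np.ndarray,
    env: EnvironmentAssignment,
    sample_ids: list[str],
    n_boot: int = 100,
    seed: int = 0,
    target_id: str = "",
) -> HiddenICPResult:
    """Difference-of-moments estimate of the causal coefficients under the
    hidden-confounder model.

    ``gamma`` solves, in least squares, the system stacked over environments
    ``(G_e - G) gamma = (g_e - g)`` with ``G_e``/``g_e`` the per-environment
    second moments and ``G``/``g`` their pooled counterparts.  Between-
    environment noise interventions on the predictors make the left side
    informative; the invariant confounder contribution cancels in the
    differences.  Confidence intervals come from a nonparametric bootstrap
    resampling samples within each environment (``n_boot`` replicates,
    seeded; 0 disables and returns zero-width intervals at the estimate).

    With two environments the least-squares solution coincides with the
    closed form ``(G_1 - G_2)^{-1} (g_1 - g_2)`` whenever that inverse
    exists.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float).ravel()
    if len(env.environments) < 2:
        raise ValueError("hidden ICP needs at least 2 environments")
    masks = [env.mask(e, sample_ids) for e in env.environments]
    A, b = _moment_difference_system(X, Y, masks)
    p = X.shape[1]
    scale = np.abs(np.diag(X.T @ X / X.shape[0])).max()
    degenerate = bool(np.abs(A).max() < 1e-6 * max(scale, 1.0))
    if degenerate:
        logger.warning(
            "target %s: environments nearly identically distributed; "
            "moment differences ~ 0, estimate is ill-posed", target_id,
        )
    gamma = _solve_stacked(A, b, target_id)

    if n_boot > 0:
        rng = np.random.default_rng(seed)
        env_idx = [np.nonzero(m)[0] for m in masks]
        boots = np.empty((n_boot, p))
        for bi in range(n_boot):
            take = np.concatenate([idx[rng.integers(0, idx.size, idx.size)]
                                   for idx in env_idx])
            bmasks = []
            off = 0
            for idx in env_idx:
                m = np.zeros(take.size, dtype=bool)
                m[off:off + idx.size] = True
                bmasks.append(m)
                off += idx.size
            Ab, bb = _moment_difference_system(X[take], Y[take], bmasks)
            boots[bi] = _solve_stacked(Ab, bb, target_id)
        ci = np.column_stack([
            np.percentile(boots, 2.5, axis=0),
            np.percentile(boots, 97.5, axis=0),
        ])
    else:
        ci = np.column_stack([gamma, gamma])
    significant = (ci[:, 0] > 0) | (ci[:, 1] < 0)
    if n_boot == 0:
        significant = np.zeros(p, dtype=bool)
    return HiddenICPResult(
        target_id=target_id,
        coefficients=gamma,
        conf_intervals=ci,
        significant=significant,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# all-pairs scoring
# ---------------------------------------------------------------------------

@dataclass
class InteractionScoreMatrix:
    """Dense regulator x target score matrix from any scoring method."""

    regulator_ids: list[str]
    target_ids: list[str]
    scores: np.ndarray  # (n_regulators, n_targets)
    method: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.regulator_ids), len(self.target_ids)):
            raise ValueError("score matrix shape inconsistent with identifiers")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("score matrix contains non-finite entries")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.scores, index=self.regulator_ids, columns=self.target_ids)

    def to_long(self):
        import pandas as pd

        df = self.to_frame().reset_index(names="miRNA").melt(
            id_vars="miRNA", var_name="mRNA", value_name="score"
        )
        df["method"] = self.method
        return df


def score_all_pairs(
    regulators: ExpressionMatrix,
    targets: ExpressionMatrix,
    env: EnvironmentAssignment,
    method: str = "hidden_icp",
    alpha: float = 0.05,
    seed: int = 0,
    **params,
) -> InteractionScoreMatrix:
    """Score every regulator-target pair by per-target causal estimation.

    ``method="icp"`` uses the subset-search parent estimator (scores are the
    per-predictor accepted-set coefficients, 0 outside every accepted set);
    ``method="hidden_icp"`` uses the dense moment-difference coefficients.
    Per-target failures yield a zero column with a logged warning rather
    than aborting the run.
    """
    if method not in ("icp", "hidden_icp"):
        raise ValueError(f"unknown method {method!r}")
    if regulators.sample_ids != targets.sample_ids:
        if set(regulators.sample_ids) == set(targets.sample_ids):
            targets = targets.subset_samples(regulators.sample_ids)
        else:
            raise ValueError("regulator and target matrices have mismatched samples")
    env.check_samples(regulators)
    sample_ids = regulators.sample_ids
    X = regulators.values.T  # samples x p
    out = np.zeros((regulators.n_features, targets.n_features))
    for t_idx, tid in enumerate(targets.feature_ids):
        Y = targets.values[t_idx]
        try:
            if method == "icp":
                res = icp_parents(
                    X, Y, env, sample_ids, alpha=alpha, target_id=tid, **params
                )
                out[:, t_idx] = res.scores
            else:
                res = hidden_icp_coefficients(
                    X, Y, env, sample_ids,
                    n_boot=params.get("n_boot", 0),
                    seed=seed + t_idx,
                    target_id=tid,
                )
                out[:, t_idx] = res.coefficients
        except Exception as exc:  # noqa: BLE001 - per-target robustness by contract
            logger.warning("target %s: scoring failed (%s); zero column", tid, exc)
            out[:, t_idx] = 0.0
    return InteractionScoreMatrix(
        regulator_ids=regulators.feature_ids,
        target_ids=targets.feature_ids,
        scores=out,
        method=method,
    )


__all__ = [
    "RegressionFit",
    "SubsetTestResult",
    "ICPResult",
    "HiddenICPResult",
    "InteractionScoreMatrix",
    "UntestableSubsetError",
    "fit_pooled_regression",
    "invariance_pvalue",
    "test_subset",
    "icp_parents",
    "hidden_icp_coefficients",
    "score_all_pairs",
]
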