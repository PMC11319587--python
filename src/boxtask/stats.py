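"""Supporting statistics: Benjamini-Hochberg FDR control, standardized-beta
multiple regression (the within-group covariate analysis), and seeded
permutation contrasts for group/set-size differences in mean error counts.

The permutation contrasts are the package's inferential route for pairwise
group comparisons: labels are shuffled within each comparison and the
two-sided p-value is ``(1 + #{|T_perm| >= |T_obs|}) / (1 + n_perm)``, with
the family of contrasts BH-corrected at Q = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .task_core import DomainError

#: the within-group regression predictor set (executive function enters as
#: the Trails B minus A difference to avoid collinearity with Trails A)
REGRESSION_PREDICTORS = (
    "ace_visuospatial",
    "spatial_span_forward",
    "spatial_span_backward",
    "rcf_copy",
    "rcf_recall",
    "trails_a_time",
    "trails_b_minus_a",
)


@dataclass(frozen=True)
class FdrResult:
    pvals: tuple[float, ...]
    q: float
    reject: tuple[bool, ...]  # aligned with the input order
    critical_values: tuple[float, ...]  # k*Q/m for the sorted p-values


@dataclass(frozen=True)
class RegressionResult:
    terms: tuple[str, ...]
    standardized_betas: dict[str, float]
    pvalues: dict[str, float]
    r_squared: float
    n: int
    k: int


@dataclass(frozen=True)
class ContrastResult:
    set_size: int
    group_a: str
    group_b: str
    mean_difference: float  # mean(a) - mean(b)
    p_value: float
    n_permutations: int
    seed: int
    reject: bool | None = None  # BH flag, filled by group_setsize_contrasts


def benjamini_hochberg(pvals: Sequence[float], q: float = 0.05) -> FdrResult:
    """Reject all sorted p(i) with i <= k*, k* the largest k with
    p(k) <= k*Q/m (stable sort, so ties keep input order)."""
    pvals = list(pvals)
    if not pvals:
        raise DomainError("empty p-value list")
    if any(not (0.0 <= p <= 1.0) for p in pvals):
        raise DomainError("p-values must lie in [0, 1]")
    if not (0.0 < q < 1.0):
        raise DomainError("Q must be in (0, 1)")
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    crit = [(k + 1) * q / m for k in range(m)]
    k_star = -1
    for k in range(m):
        if pvals[order[k]] <= crit[k]:
            k_star = k
    reject = [False] * m
    for k in range(k_star + 1):
        reject[order[k]] = True
    return FdrResult(
        pvals=tuple(pvals), q=q, reject=tuple(reject), critical_values=tuple(crit)
    )


def _collinear_columns(z: pd.DataFrame) -> list[str]:
    """Columns perfectly predicted by the others (detected via R^2 ~ 1)."""
    names = []
    for col in z.columns:
        others = z.drop(columns=col)
        if others.shape[1] == 0:
            continue
        fit = sm.OLS(z[col], sm.add_constant(others)).fit()
        if fit.rsquared > 1 - 1e-8:
            names.append(col)
    return names


def standardized_regression(design: pd.DataFrame, response: Sequence[float]) -> RegressionResult:
    """OLS on z-scored predictors and response; the coefficients are the
    standardized betas and p-values come from classical two-sided t-tests
    with n - k - 1 degrees of freedom."""
    y = np.asarray(response, dtype=float)
    n, k = len(y), design.shape[1]
    if len(design) != n:
        raise DomainError("design and response differ in length")
    if n <= k + 1:
        raise DomainError(f"need n > k + 1 (n={n}, k={k})")
    sds = design.std(ddof=1)
    constant = [c for c in design.columns if sds[c] == 0 or not np.isfinite(sds[c])]
    if constant:
        raise DomainError(f"constant predictor column(s): {constant}")
    z_x = (design - design.mean()) / sds
    if np.linalg.matrix_rank(z_x.to_numpy()) < k:
        raise DomainError(f"collinear predictor column(s): {_collinear_columns(z_x)}")
    y_sd = y.std(ddof=1)
    if y_sd == 0:
        raise DomainError("response is constant")
    z_y = (y - y.mean()) / y_sd
    fit = sm.OLS(z_y, sm.add_constant(z_x)).fit()
    betas = {c: float(fit.params[c]) for c in design.columns}
    pvals = {c: float(fit.pvalues[c]) for c in design.columns}
    return RegressionResult(
        terms=tuple(design.columns),
        standardized_betas=betas,
        pvalues=pvals,
        r_squared=float(fit.rsquared),
        n=n,
        k=k,
    )


def regression_dissociation_check(
    aggregates: pd.DataFrame,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[dict[str, RegressionResult], bool]:
    """Within-group regression of 6-box between-search mean errors on the
    cognitive predictor set, run separately in AD and bvFTD.

    The verdict is True iff RCF 3-min recall is a significant predictor in
    the AD group and non-significant in the bvFTD group — the dissociation
    the generator's couplings encode (episodic-memory-driven errors in AD
    only, attentional contributions in both).
    """
    dv = aggregates[aggregates["set_size"] == 6][["participant_id", "between_mean"]]
    merged = covariates.merge(dv, on="participant_id")
    results: dict[str, RegressionResult] = {}
    for group in ("AD", "bvFTD"):
        sub = merged[merged["group"] == group]
        if len(sub) < len(REGRESSION_PREDICTORS) + 2:
            raise DomainError(f"group '{group}': n={len(sub)} too small for k={len(REGRESSION_PREDICTORS)}")
        results[group] = standardized_regression(
            sub[list(REGRESSION_PREDICTORS)], sub["between_mean"].to_numpy()
        )
    verdict = (
        results["AD"].pvalues["rcf_recall"] < alpha
        and results["bvFTD"].pvalues["rcf_recall"] >= alpha
    )
    return results, verdict


def group_setsize_contrasts(
    aggregates: pd.DataFrame,
    n_permutations: int = 9999,
    seed: int = 0,
    measure: str = "between_mean",
    q: float = 0.05,
) -> list[ContrastResult]:
    """Two-sided permutation tests for the difference in mean ``measure``
    between every pair of groups at every set size, BH-corrected as one
    family."""
    if n_permutations < 99:
        raise DomainError("need n_permutations >= 99")
    groups = sorted(aggregates["group"].dropna().unique())
    if len(groups) < 2:
        raise DomainError("need >= 2 groups")
    rng = np.random.default_rng(seed)
    results: list[ContrastResult] = []
    for set_size in sorted(aggregates["set_size"].unique()):
        at_size = aggregates[aggregates["set_size"] == set_size]
        for ga, gb in combinations(groups, 2):
            xa = at_size.loc[at_size["group"] == ga, measure].to_numpy(dtype=float)
            xb = at_size.loc[at_size["group"] == gb, measure].to_numpy(dtype=float)
            pooled = np.concatenate([xa, xb])
            na = len(xa)
            obs = xa.mean() - xb.mean()
            perm = np.empty(n_permutations)
            for i in range(n_permutations):
                shuffled = rng.permutation(pooled)
                perm[i] = shuffled[:na].mean() - shuffled[na:].mean()
            p = (1.0 + np.sum(np.abs(perm) >= abs(obs))) / (1.0 + n_permutations)
            results.append(
                ContrastResult(
                    set_size=int(set_size),
                    group_a=ga,
                    group_b=gb,
                    mean_difference=float(obs),
                    p_value=float(p),
                    n_permutations=n_permutations,
                    seed=seed,
                )
            )
    fdr = benjamini_hochberg([r.p_value for r in results], q=q)
    return [
        ContrastResult(**{**r.__dict__, "reject": bool(flag)})
        for r, flag in zip(results, fdr.reject)
    ]


def contrasts_table(results: Sequence[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_size": r.set_size,
                "group_a": r.group_a,
                "group_b": r.group_b,
                "mean_difference": r.mean_difference,
                "p_value": r.p_value,
                "reject_bh": r.reject,
                "n_permutations": r.n_permutations,
                "seed": r.seed,
            }
            for r in results
        ]
    )


def regression_table(result: RegressionResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term": list(result.terms),
            "standardized_beta": [result.standardized_betas[t] for t in result.terms],
            "p_value": [result.pvalues[t] for t in result.terms],
        }
    )
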