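"""Method-of-moments MAIC weight estimation, ESS, and balance reporting.

Patients in the index trial receive weights :math:`w_i = \\exp(z_i^T \\beta)`
where :math:`z_i` are the match covariates centred at the aggregate targets.
The coefficients minimise the convex objective :math:`\\sum_i \\exp(z_i^T
\\beta)`; at the optimum the weighted mean of every centred covariate is zero,
i.e. the weighted sample exactly matches the aggregate profile's moments.

The optimiser is Newton's method with backtracking line search from
:math:`\\beta = 0` (deterministic), falling back to BFGS when the Hessian is
ill conditioned.  Infeasible targets — a target outside the convex hull of the
sample covariates — are detected and reported rather than silently returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize

from .trial_data import (
    AggregateProfile,
    IPDTable,
    MatchSpec,
    ValidationError,
    _raw_indicator,
    default_match_spec,
    encode_for_matching,
    target_center,
)

__all__ = [
    "WeightSet",
    "WeightingInfeasibleError",
    "estimate_weights",
    "effective_sample_size",
    "balance_table",
]

#: Moment constraints must be met to this absolute tolerance at convergence.
MOMENT_TOL = 1e-6
_GRAD_TOL = 1e-8
_MAX_ITER = 200
_BETA_BOUND = 50.0

#: Pre-weighting imbalance flag threshold (relative difference >= 10%).
IMBALANCE_REL_DIFF = 0.10


class WeightingInfeasibleError(RuntimeError):
    """The aggregate target cannot be reached by reweighting this sample."""


@dataclass
class WeightSet:
    """Estimated MAIC weights for one analysis population.

    ``weights`` are the raw (unnormalised) exponential-tilt weights indexed
    like the design matrix; ``ess`` is the effective sample size
    :math:`(\\sum w)^2 / \\sum w^2`.
    """

    weights: pd.Series
    coefficients: pd.Series
    ess: float
    converged: bool
    iterations: int

    @property
    def n(self) -> int:
        return len(self.weights)

    def rescaled_to_ess(self) -> pd.Series:
        """Weights rescaled to sum to the ESS (used for displayed counts)."""
        w = self.weights
        return w * (self.ess / w.sum())


def effective_sample_size(weights) -> float:
    """Kish effective sample size ``(sum w)^2 / sum w^2`` (scale invariant)."""
    w = np.asarray(weights, dtype=float)
    if len(w) == 0 or np.any(w < 0):
        raise ValidationError("weights must be non-negative and non-empty")
    sw2 = float(np.sum(w**2))
    if sw2 == 0.0:
        raise ValidationError("all weights are zero")
    return float(np.sum(w)) ** 2 / sw2


def _check_feasibility(Z: np.ndarray, columns) -> None:
    # A centred column that never changes sign (and is not identically zero)
    # means the target lies outside the convex hull of the sample values.
    for j, name in enumerate(columns):
        col = Z[:, j]
        if np.all(col > 0) or np.all(col < 0):
            raise WeightingInfeasibleError(
                f"target for {name!r} lies outside the sample range "
                f"(column bounds [{col.min():.4g}, {col.max():.4g}])"
            )


def estimate_weights(design: pd.DataFrame | np.ndarray) -> WeightSet:
    """Estimate MAIC weights from a centred match design matrix.

    Raises :class:`WeightingInfeasibleError` when no finite coefficient vector
    can satisfy the moment constraints, and ``numpy.linalg.LinAlgError`` when
    the design is rank deficient.
    """
    if isinstance(design, pd.DataFrame):
        columns = list(design.columns)
        index = design.index
        Z = design.to_numpy(dtype=float)
    else:
        Z = np.asarray(design, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        columns = [f"z{j}" for j in range(Z.shape[1])]
        index = pd.RangeIndex(Z.shape[0])
    if not np.all(np.isfinite(Z)):
        raise ValidationError("design matrix contains non-finite values")
    n, p = Z.shape
    if n == 0:
        raise ValidationError("empty design matrix")

    sv = np.linalg.svd(Z, compute_uv=False) if n >= p else np.zeros(p)
    if sv[-1] < 1e-10 * max(sv[0], 1.0):
        raise np.linalg.LinAlgError(
            "match design is rank deficient (collinear columns)"
        )
    _check_feasibility(Z, columns)

    def objective(beta: np.ndarray) -> float:
        return float(np.exp(Z @ beta).sum())

    beta = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        w = np.exp(Z @ beta)
        grad = Z.T @ w
        if np.linalg.norm(grad) < _GRAD_TOL * max(1.0, w.sum()):
            converged = True
            break
        hess = (Z * w[:, None]).T @ Z
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = None
        if step is None or not np.all(np.isfinite(step)):
            break
        # backtracking line search on the convex objective
        f0 = w.sum()
        alpha = 1.0
        while alpha > 1e-12 and objective(beta - alpha * step) > f0:
            alpha *= 0.5
        beta = beta - alpha * step
        if np.linalg.norm(beta, np.inf) > _BETA_BOUND:
            raise WeightingInfeasibleError(
                "coefficients diverging; target appears infeasible "
                f"(|beta| > {_BETA_BOUND})"
            )
    if not converged:
        # quasi-Newton fallback for ill-conditioned designs
        res = scipy.optimize.minimize(
            lambda b: np.exp(Z @ b).sum(),
            beta,
            jac=lambda b: Z.T @ np.exp(Z @ b),
            method="BFGS",
            options={"gtol": _GRAD_TOL, "maxiter": 500},
        )
        beta = res.x
        it += int(res.nit)
        w = np.exp(Z @ beta)
        converged = bool(np.linalg.norm(Z.T @ w) < 1e-6 * max(1.0, w.sum()))
        if not converged:
            raise WeightingInfeasibleError(
                "weight estimation did not converge; gradient norm "
                f"{np.linalg.norm(Z.T @ w):.3g}"
            )

    w = np.exp(Z @ beta)
    moment_gap = np.abs(Z.T @ w) / w.sum()
    if np.any(moment_gap > MOMENT_TOL):
        raise WeightingInfeasibleError(
            f"moment constraints violated (max gap {moment_gap.max():.3g})"
        )
    return WeightSet(
        weights=pd.Series(w, index=index, name="weight"),
        coefficients=pd.Series(beta, index=columns, name="beta"),
        ess=effective_sample_size(w),
        converged=converged,
        iterations=it,
    )


def _weighted_summary(values: pd.Series, weights: np.ndarray, statistic: str) -> float:
    v = values.to_numpy(dtype=float)
    if statistic == "median":
        order = np.argsort(v)
        cw = np.cumsum(weights[order])
        return float(v[order][np.searchsorted(cw, 0.5 * cw[-1])])
    return float(np.average(v, weights=weights))


def balance_table(
    ipd: IPDTable,
    weightset: WeightSet,
    profile: AggregateProfile,
    spec: MatchSpec | None = None,
) -> pd.DataFrame:
    """Pre- vs post-weighting covariate summaries against the targets.

    One row per match target with the unweighted summary, the weighted
    summary, the target, and an imbalance flag marking pre-weighting relative
    differences of 10% or more.  Weighted summaries of matched statistics
    equal their targets up to the moment tolerance.
    """
    spec = spec or default_match_spec()
    design = encode_for_matching(ipd, profile, spec)
    frame = ipd.frame.loc[design.index]
    w = weightset.weights.loc[design.index].to_numpy(dtype=float)
    ones = np.ones(len(frame))

    rows = []
    for target in profile.targets:
        if target.statistic == "median":
            values = pd.to_numeric(frame[target.variable])
            pre = _weighted_summary(values, ones, "median")
            post = _weighted_summary(values, w, "median")
        else:
            ind = _raw_indicator(frame, target) + 0.0  # uncentred
            pre = float(np.average(ind, weights=ones))
            post = float(np.average(ind, weights=w))
        tgt = float(target.value)
        rel = abs(pre - tgt) / abs(tgt) if tgt != 0 else np.inf
        rows.append(
            {
                "target": target.key,
                "statistic": target.statistic,
                "target_value": tgt,
                "unweighted": pre,
                "weighted": post,
                "rel_diff_pre": rel,
                "imbalance_flag": bool(rel >= IMBALANCE_REL_DIFF),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n"] = int(len(frame))
    out.attrs["ess"] = float(weightset.ess)
    return out
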