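"""Naive and weighted endpoint comparisons with noninferiority classification.

Binary endpoints are compared by the absolute rate difference (percentage
points, mod minus label) with a Wald confidence interval, the odds ratio with
a Woolf (log-OR Wald) interval, and a two-sided Fisher exact p-value (minlike
convention: the sum of hypergeometric probabilities no larger than that of the
observed table).  Time-to-event endpoints use a weighted Cox model with a
single treatment covariate (Breslow tie handling, robust sandwich variance)
and a weighted log-rank test.

Results that are not statistically significant at the 5% level are read
against prespecified noninferiority margins: 13 percentage points for response
and safety rate differences, and hazard-ratio bounds 1.333 (OS) and 1.298
(PFS).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2, hypergeom, norm

from .trial_data import ValidationError
from .maic_weighting import effective_sample_size

logger = logging.getLogger(__name__)

__all__ = [
    "MarginSet",
    "BinaryComparison",
    "SurvivalComparison",
    "ConvergenceError",
    "fisher_exact_two_sided",
    "binary_compare",
    "weighted_cox_hr",
    "weighted_logrank",
    "classify",
]

Z975 = float(norm.ppf(0.975))  # 1.959964...
_FISHER_TIE_TOL = 1e-7

CLASSIFICATIONS = ("superior", "noninferior", "inferior", "inconclusive")


class ConvergenceError(RuntimeError):
    """The partial-likelihood maximiser failed to converge."""


@dataclass(frozen=True)
class MarginSet:
    """Prespecified noninferiority margins and significance level.

    Rate-difference margins are in percentage points; survival margins bound
    the hazard ratio of the comparator-disadvantage direction.
    """

    response_margin: float = 13.0
    safety_margin: float = 13.0
    os_margin: float = 1.333
    pfs_margin: float = 1.298
    alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in ("response_margin", "safety_margin", "os_margin", "pfs_margin"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must lie in (0, 1)")


@dataclass
class BinaryComparison:
    """Rate difference / odds ratio comparison of one binary endpoint."""

    k_mod: float
    n_mod: float
    k_lab: float
    n_lab: float
    rd: float
    rd_ci: tuple[float, float]
    or_: float
    or_ci: tuple[float, float]
    p: float
    label: str | None = None
    or_continuity: float | None = None  # sensitivity value when a cell is zero
    weighted: bool = False
    ess: float | None = None
    display_counts: tuple[int, int] | None = None


@dataclass
class SurvivalComparison:
    """Hazard-ratio comparison of one time-to-event endpoint."""

    hr: float
    hr_ci: tuple[float, float]
    p: float | None = None
    label: str | None = None
    log_hr_se: float | None = None
    n_events: tuple[float, float] | None = None


# ---------------------------------------------------------------------------
# Fisher exact test


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p-value by hypergeometric enumeration.

    ``table`` is a 2x2 of non-negative integers ``((a, b), (c, d))``.  The
    p-value sums the probabilities of all tables with the observed margins
    whose probability does not exceed the observed table's (minlike
    convention, with a small relative tolerance for floating-point ties).
    Any zero margin gives p = 1 by convention.
    """
    (a, b), (c, d) = table
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0) or np.any(cells != np.round(cells)):
        raise ValidationError("Fisher test requires non-negative integer counts")
    a, b, c, d = (int(x) for x in cells)
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if row1 == 0 or col1 == 0 or row1 == n or col1 == n:
        logger.info("degenerate 2x2 margin; Fisher p = 1 by convention")
        return 1.0
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = hypergeom.pmf(support, n, row1, col1)
    p_obs = hypergeom.pmf(a, n, row1, col1)
    p = float(pmf[pmf <= p_obs * (1.0 + _FISHER_TIE_TOL)].sum())
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# Binary endpoint comparison


def _woolf_ci(a: float, b: float, c: float, d: float) -> tuple[float, float]:
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (math.exp(log_or - Z975 * se), math.exp(log_or + Z975 * se))


def binary_compare(
    k_mod: float,
    n_mod: float,
    k_lab: float | None = None,
    n_lab: float | None = None,
    *,
    label_responders=None,
    label_weights=None,
) -> BinaryComparison:
    """Compare a binary endpoint between the pooled mod arm and the label arm.

    Unweighted mode takes the four counts.  Weighted mode takes per-patient
    0/1 ``label_responders`` and MAIC ``label_weights`` instead of
    ``k_lab``/``n_lab``; the label-arm proportion is the weighted proportion
    and the effective denominator is the ESS.  For the exact test the weighted
    responder count is rescaled to sum to the ESS and rounded to the nearest
    integer (weights are not frequency counts, so the displayed table is the
    integer table closest to the weighted one).
    """
    weighted = label_responders is not None
    ess = None
    display = None
    if weighted:
        y = np.asarray(label_responders, dtype=float)
        w = np.asarray(label_weights, dtype=float)
        if np.any((y != 0) & (y != 1)):
            raise ValidationError("label responder flags must be 0/1")
        if np.any(w < 0):
            raise ValidationError("weights must be non-negative")
        p_lab = float(np.average(y, weights=w))
        ess = effective_sample_size(w)
        n_lab_eff = ess
        k_lab_eff = p_lab * ess
        k_int = int(round(k_lab_eff))
        n_int = int(round(n_lab_eff))
        display = (k_int, n_int)
    else:
        if k_lab is None or n_lab is None:
            raise ValidationError("unweighted mode requires k_lab and n_lab")
        if n_lab <= 0 or not 0 <= k_lab <= n_lab:
            raise ValidationError("counts must satisfy 0 <= k <= n, n > 0")
        p_lab = k_lab / n_lab
        n_lab_eff, k_lab_eff = float(n_lab), float(k_lab)
        k_int, n_int = int(round(k_lab)), int(round(n_lab))

    if not (0 <= k_mod <= n_mod) or n_mod <= 0 or n_lab_eff <= 0:
        raise ValidationError("counts must satisfy 0 <= k <= n, n > 0")
    p_mod = k_mod / n_mod

    rd = 100.0 * (p_mod - p_lab)
    se_rd = math.sqrt(
        p_mod * (1 - p_mod) / n_mod + p_lab * (1 - p_lab) / n_lab_eff
    )
    rd_ci = (rd - Z975 * 100 * se_rd, rd + Z975 * 100 * se_rd)

    a, b = float(k_mod), float(n_mod - k_mod)
    c, d = k_lab_eff, n_lab_eff - k_lab_eff
    or_continuity = None
    if min(a, b, c, d) <= 0:
        or_ = float("nan")
        acc = (a + 0.5, b + 0.5, c + 0.5, d + 0.5)
        or_cc = (acc[0] * acc[3]) / (acc[1] * acc[2])
        or_ci = _woolf_ci(*acc)
        or_continuity = or_cc
        logger.warning(
            "zero cell in 2x2 table; odds ratio undefined, reporting "
            "continuity-corrected sensitivity value %.4g", or_cc
        )
    else:
        or_ = (a * d) / (b * c)
        or_ci = _woolf_ci(a, b, c, d)

    p = fisher_exact_two_sided(
        ((int(round(k_mod)), int(round(n_mod - k_mod))), (k_int, n_int - k_int))
    )
    return BinaryComparison(
        k_mod=k_mod,
        n_mod=n_mod,
        k_lab=k_lab_eff,
        n_lab=n_lab_eff,
        rd=rd,
        rd_ci=rd_ci,
        or_=or_,
        or_ci=or_ci,
        p=p,
        or_continuity=or_continuity,
        weighted=weighted,
        ess=ess,
        display_counts=display,
    )


# ---------------------------------------------------------------------------
# Weighted Cox model (single treatment covariate, Breslow ties)


def _cox_quantities(beta: float, t, d, x, w):
    """Score, information and log-likelihood pieces at beta (Breslow)."""
    order = np.argsort(-t, kind="stable")  # descending time
    t_s, d_s, x_s, w_s = t[order], d[order], x[order], w[order]
    r = w_s * np.exp(beta * x_s)
    s0 = np.cumsum(r)  # risk-set sums walking backwards in time
    s1 = np.cumsum(r * x_s)
    # positions of distinct event times
    asc = t_s[::-1]
    ev_times = np.unique(t[d > 0])
    # index in descending arrays of the last subject with time >= ev_time
    idx = len(t_s) - np.searchsorted(asc, ev_times, side="left") - 1 + 1
    S0 = s0[idx - 1]
    S1 = s1[idx - 1]
    # weighted events per distinct time
    Dw = np.zeros(len(ev_times))
    Dx = np.zeros(len(ev_times))
    pos = np.searchsorted(ev_times, t[d > 0])
    np.add.at(Dw, pos, w[d > 0])
    np.add.at(Dx, pos, (w * x)[d > 0])
    xbar = S1 / S0
    U = float(np.sum(Dx - Dw * xbar))
    info = float(np.sum(Dw * xbar * (1.0 - xbar)))  # x binary: S2 == S1
    return U, info, ev_times, Dw, S0, xbar


def weighted_cox_hr(times, events, arm, weights=None) -> SurvivalComparison:
    """Weighted Cox hazard ratio for a binary treatment indicator.

    Maximises the case-weighted Breslow partial likelihood by Newton's method
    and reports ``exp(beta)`` with a robust (sandwich) 95% CI — the weights
    are analytic, not frequency, weights, so the model-based variance would be
    anticonservative.
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    x = np.asarray(arm, dtype=float)
    w = np.ones_like(t) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValidationError("weights must be non-negative")
    if set(np.unique(x)) - {0.0, 1.0}:
        raise ValidationError("arm indicator must be 0/1")
    for grp in (0.0, 1.0):
        if np.sum((x == grp) & (d == 1) & (w > 0)) == 0:
            raise ConvergenceError(
                f"no (weighted) events in arm {int(grp)}; hazard ratio diverges"
            )

    beta = 0.0
    U = np.inf
    for _ in range(50):
        U, info, *_ = _cox_quantities(beta, t, d, x, w)
        if abs(U) < 1e-10 * max(1.0, w.sum()):
            break
        if info <= 0:
            raise ConvergenceError("vanishing information; model degenerate")
        beta += float(np.clip(U / info, -5.0, 5.0))
        if abs(beta) > 30:
            raise ConvergenceError("hazard ratio diverging (|log HR| > 30)")
    else:
        raise ConvergenceError(
            f"Newton iteration did not converge; score {U:.3g}"
        )

    _, info, ev_times, Dw, S0, xbar = _cox_quantities(beta, t, d, x, w)
    # robust sandwich variance from per-subject score residuals
    risk = np.exp(beta * x)
    dL0 = Dw / S0  # Breslow baseline hazard increments
    pos_all = np.searchsorted(ev_times, t, side="right")  # events up to t_i
    cum_dL = np.concatenate([[0.0], np.cumsum(dL0)])
    cum_dLx = np.concatenate([[0.0], np.cumsum(dL0 * xbar)])
    ev_pos = np.searchsorted(ev_times, t)
    obs_term = np.where(
        (d == 1) & (ev_pos < len(ev_times)),
        x - xbar[np.clip(ev_pos, 0, len(ev_times) - 1)],
        0.0,
    )
    exp_term = risk * (x * cum_dL[pos_all] - cum_dLx[pos_all])
    resid = obs_term - exp_term
    meat = float(np.sum((w * resid) ** 2))
    se_rob = math.sqrt(meat) / info
    hr = math.exp(beta)
    ci = (math.exp(beta - Z975 * se_rob), math.exp(beta + Z975 * se_rob))
    n_ev = (float(np.sum(w[(x == 1) & (d == 1)])), float(np.sum(w[(x == 0) & (d == 1)])))
    return SurvivalComparison(hr=hr, hr_ci=ci, log_hr_se=se_rob, n_events=n_ev)


def weighted_logrank(times, events, arm, weights=None) -> float:
    """Two-sided weighted log-rank p-value.

    At each distinct event time the observed-minus-expected weighted event
    count in the treated arm is accumulated with the weighted hypergeometric
    variance; with unit weights this is the classical log-rank test, and
    integer weights reproduce the physically duplicated sample exactly.
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    x = np.asarray(arm, dtype=float)
    w = np.ones_like(t) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValidationError("weights must be non-negative")

    ev_times = np.unique(t[d > 0])
    if len(ev_times) == 0:
        return 1.0
    O_minus_E = 0.0
    V = 0.0
    for tk in ev_times:  # modest number of distinct event times
        at_risk = t >= tk
        nw = float(np.sum(w[at_risk]))
        nw1 = float(np.sum(w[at_risk & (x == 1)]))
        ev = (t == tk) & (d == 1)
        dw = float(np.sum(w[ev]))
        dw1 = float(np.sum(w[ev & (x == 1)]))
        if nw <= 1 or dw == 0:
            continue
        frac = nw1 / nw
        O_minus_E += dw1 - dw * frac
        V += dw * frac * (1 - frac) * (nw - dw) / (nw - 1)
    if V <= 0:
        return 1.0
    stat = O_minus_E**2 / V
    return float(chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# Noninferiority classification


def classify(
    estimate_kind: str,
    estimate: float,
    ci: tuple[float, float],
    p: float,
    margins: MarginSet,
    endpoint: str | None = None,
) -> str:
    """Classify one endpoint as superior / noninferior / inferior / inconclusive.

    Significant results (p < alpha) are superior or inferior by the direction
    of the estimate; non-significant results are noninferior when the CI
    excludes a disadvantage beyond the margin, else inconclusive.  A p-value
    exactly at alpha takes the non-significant (margin) path.

    ``estimate_kind``: ``rate_difference_benefit`` (higher rate favours mod),
    ``rate_difference_harm`` (safety; lower rate favours mod), or
    ``hazard_ratio`` (event hazard; HR < 1 favours mod, ``endpoint`` must be
    ``"os"`` or ``"pfs"`` to select the margin).
    """
    lo, hi = ci
    if not lo <= estimate <= hi:
        raise ValidationError("confidence interval must bracket the estimate")
    alpha = margins.alpha
    if estimate_kind == "rate_difference_benefit":
        margin = margins.response_margin
        if p < alpha and estimate > 0:
            return "superior"
        if p < alpha and estimate < 0:
            return "inferior"
        return "noninferior" if lo > -margin else "inconclusive"
    if estimate_kind == "rate_difference_harm":
        margin = margins.safety_margin
        if p < alpha and estimate < 0:
            return "superior"
        if p < alpha and estimate > 0:
            return "inferior"
        return "noninferior" if hi < margin else "inconclusive"
    if estimate_kind == "hazard_ratio":
        if endpoint not in ("os", "pfs"):
            raise ValidationError(
                "hazard_ratio classification requires endpoint 'os' or 'pfs'"
            )
        margin = margins.os_margin if endpoint == "os" else margins.pfs_margin
        if p < alpha and estimate < 1:
            return "superior"
        if p < alpha and estimate > 1:
            return "inferior"
        return "noninferior" if hi < margin else "inconclusive"
    raise ValidationError(f"unknown estimate kind {estimate_kind!r}")
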