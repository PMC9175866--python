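"""Published inputs for the dosing-regimen comparison.

The source publication prints the naive 2x2 counts, the estimate/CI/p of
every comparison row, and the prespecified noninferiority margins.  These are
*inputs* to the package (the analysis re-derives the statistics from the
counts); nothing here is a computed result.

Orientation throughout: "mod" is the pooled modified-dosing arm (CASSIOPEIA +
the phase II study), "label" is the per-label-dosing arm.  Efficacy pooling is
591 = 542 + 49 patients; the safety population pools 587 = 538 + 49.  The
label arm has 130 patients in both populations.
"""

from __future__ import annotations

from dataclasses import dataclass

from .comparative_stats import MarginSet
from .trial_data import AggregateProfile, MatchTarget

__all__ = [
    "N_MOD_EFFICACY",
    "N_MOD_SAFETY",
    "N_LABEL",
    "NAIVE_BINARY_COUNTS",
    "PrintedRow",
    "PRINTED_BINARY_ROWS",
    "PRINTED_SURVIVAL_ROWS",
    "PUBLISHED_MARGINS",
    "efficacy_profile",
    "safety_profile",
]

N_MOD_EFFICACY = 591  # 542 + 49
N_MOD_SAFETY = 587  # 538 + 49
N_LABEL = 130

#: Naive 2x2 inputs: endpoint -> (k_mod, n_mod, k_label, n_label).
NAIVE_BINARY_COUNTS: dict[str, tuple[int, int, int, int]] = {
    "postinduction_cr_plus": (50, N_MOD_EFFICACY, 46, N_LABEL),
    "postinduction_vgpr_plus": (338, N_MOD_EFFICACY, 64, N_LABEL),
    "postinduction_orr": (536, N_MOD_EFFICACY, 110, N_LABEL),
    "posttransplant_cr_plus": (94, N_MOD_EFFICACY, 61, N_LABEL),
    "posttransplant_vgpr_plus": (406, N_MOD_EFFICACY, 72, N_LABEL),
    "posttransplant_orr": (536, N_MOD_EFFICACY, 101, N_LABEL),
    "discontinued_ae": (32, N_MOD_SAFETY, 8, N_LABEL),
    "thrombosis_g34": (12, N_MOD_SAFETY, 1, N_LABEL),
    "neuropathy_g34": (39, N_MOD_SAFETY, 7, N_LABEL),
}


@dataclass(frozen=True)
class PrintedRow:
    """One printed comparison row: estimate, CI, p, and its printed verdict."""

    endpoint: str
    analysis: str  # "naive" | "MAIC"
    kind: str  # classify() estimate_kind
    estimate: float
    ci: tuple[float, float]
    p: float  # printed two-sided p ("<.0001" encoded as 5e-5)
    verdict: str
    margin_key: str | None = None  # for hazard ratios


P_FLOOR = 5e-5  # stands in for a printed "<.0001"

#: Response (benefit) and safety (harm) rows as printed, naive and MAIC.
PRINTED_BINARY_ROWS: tuple[PrintedRow, ...] = (
    PrintedRow("postinduction_cr_plus", "naive", "rate_difference_benefit",
               -26.92, (-35.44, -18.4), P_FLOOR, "inferior"),
    PrintedRow("postinduction_cr_plus", "MAIC", "rate_difference_benefit",
               -27.51, (-36.5, -18.52), P_FLOOR, "inferior"),
    PrintedRow("postinduction_vgpr_plus", "naive", "rate_difference_benefit",
               7.96, (-1.51, 17.44), 0.118, "noninferior"),
    PrintedRow("postinduction_vgpr_plus", "MAIC", "rate_difference_benefit",
               3.18, (-6.7, 13.07), 0.541, "noninferior"),
    PrintedRow("postinduction_orr", "naive", "rate_difference_benefit",
               6.08, (-0.55, 12.71), 0.055, "noninferior"),
    PrintedRow("postinduction_orr", "MAIC", "rate_difference_benefit",
               6.15, (-0.82, 13.11), 0.065, "noninferior"),
    PrintedRow("posttransplant_cr_plus", "naive", "rate_difference_benefit",
               -31.02, (-40.09, -21.95), P_FLOOR, "inferior"),
    PrintedRow("posttransplant_cr_plus", "MAIC", "rate_difference_benefit",
               -31.52, (-41.04, -21.99), P_FLOOR, "inferior"),
    PrintedRow("posttransplant_vgpr_plus", "naive", "rate_difference_benefit",
               13.31, (3.99, 22.64), 0.004, "superior"),
    PrintedRow("posttransplant_vgpr_plus", "MAIC", "rate_difference_benefit",
               10.95, (1.24, 20.66), 0.0024, "superior"),
    PrintedRow("posttransplant_orr", "naive", "rate_difference_benefit",
               13.00, (5.47, 20.53), P_FLOOR, "superior"),
    PrintedRow("posttransplant_orr", "MAIC", "rate_difference_benefit",
               12.14, (4.34, 19.95), 0.001, "superior"),
    PrintedRow("discontinued_ae", "naive", "rate_difference_harm",
               -0.70, (-5.22, 3.82), 0.678, "noninferior"),
    PrintedRow("discontinued_ae", "MAIC", "rate_difference_harm",
               -0.18, (-4.65, 4.29), 0.831, "noninferior"),
    PrintedRow("thrombosis_g34", "naive", "rate_difference_harm",
               1.28, (-0.61, 3.16), 0.481, "noninferior"),
    PrintedRow("thrombosis_g34", "MAIC", "rate_difference_harm",
               1.11, (-0.95, 3.16), 0.709, "noninferior"),
    PrintedRow("neuropathy_g34", "naive", "rate_difference_harm",
               1.26, (-3.11, 5.63), 0.696, "noninferior"),
    PrintedRow("neuropathy_g34", "MAIC", "rate_difference_harm",
               2.40, (-1.70, 6.49), 0.409, "noninferior"),
)

#: OS and PFS statements (weighted Cox HR with log-rank p).
PRINTED_SURVIVAL_ROWS: tuple[PrintedRow, ...] = (
    PrintedRow("os", "naive", "hazard_ratio",
               0.614, (0.360, 1.048), 0.072, "noninferior", "os"),
    PrintedRow("os", "MAIC", "hazard_ratio",
               0.640, (0.363, 1.129), 0.121, "noninferior", "os"),
    PrintedRow("pfs", "naive", "hazard_ratio",
               0.663, (0.467, 0.941), 0.021, "superior", "pfs"),
    PrintedRow("pfs", "MAIC", "hazard_ratio",
               0.672, (0.467, 0.966), 0.031, "superior", "pfs"),
)

#: Prespecified margins: 13 pp (response), 13 pp (safety), HR 1.333 (OS),
#: HR 1.298 (PFS), two-sided alpha 0.05.
PUBLISHED_MARGINS = MarginSet()

#: Published effective sample sizes after weighting (efficacy, safety).
PUBLISHED_ESS = {"efficacy": 105, "safety": 116}


def efficacy_profile() -> AggregateProfile:
    """The pooled mod-arm baseline profile used for efficacy matching."""
    return AggregateProfile(
        targets=(
            MatchTarget("age", "median", 58.0),
            MatchTarget("sex", "proportion", 0.58, "male"),
            MatchTarget("ecog_ge1", "proportion", 0.52, 1),
            MatchTarget("myeloma_type", "proportion", 0.61, "IgG"),
            MatchTarget("iss", "proportion", 0.41, "I"),
            MatchTarget("iss", "proportion", 0.43, "II"),
            MatchTarget("creatinine_clearance", "median", 95.2),
        ),
        source_n=N_MOD_EFFICACY,
    )


def safety_profile() -> AggregateProfile:
    """The pooled mod-arm baseline profile used for safety matching."""
    prof = efficacy_profile()
    return AggregateProfile(targets=prof.targets, source_n=N_MOD_SAFETY)
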