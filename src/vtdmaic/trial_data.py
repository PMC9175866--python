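"""Patient-level trial data model and IO.

This module defines the containers used throughout the MAIC pipeline:

* :class:`IPDTable` — individual patient data for one or more trial arms,
  validated against the myeloma-trial schema (baseline covariates, ordinal
  response levels, time-to-event outcomes, safety flags).
* :class:`AggregateProfile` / :class:`MatchTarget` — the published summary
  statistics of the comparator population that the IPD will be reweighted to.
* :class:`MatchSpec` — the encoding rules that turn each match target into one
  centred column of the weighting design matrix.

IPD travels as comma-separated text with a mandatory header; aggregate
profiles and match specifications travel as YAML.  Writers emit UTF-8 with a
fixed column order and a leading provenance comment.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "ValidationError",
    "RESPONSE_LEVELS",
    "ISS_LEVELS",
    "IPD_COLUMNS",
    "MatchTarget",
    "AggregateProfile",
    "EncodingRule",
    "MatchSpec",
    "default_match_spec",
    "IPDTable",
    "read_ipd",
    "write_ipd",
    "read_profile",
    "write_profile",
    "pool_trials",
    "encode_for_matching",
    "response_counts",
]


class SchemaError(ValueError):
    """A file or configuration does not match the declared schema."""


class ValidationError(ValueError):
    """Well-formed input whose values violate a domain invariant."""


#: Ordinal response coding, worst to best.  ``CR`` means complete response or
#: better; levels below partial response are collapsed into ``none``.
RESPONSE_LEVELS = ("none", "PR", "VGPR", "CR")

ISS_LEVELS = ("I", "II", "III")
SEX_LEVELS = ("female", "male")
MYELOMA_LEVELS = ("non-IgG", "IgG")

#: Canonical column order for IPD files.  The first nine are mandatory.
IPD_COLUMNS = (
    "patient_id",
    "trial_id",
    "arm",
    "age",
    "sex",
    "ecog_ge1",
    "myeloma_type",
    "iss",
    "creatinine_clearance",
    "hemoglobin",
    "platelets",
    "response_postinduction",
    "response_posttransplant",
    "os_time",
    "os_event",
    "pfs_time",
    "pfs_event",
    "discontinued_ae",
    "thrombosis_g34",
    "neuropathy_g34",
)
MANDATORY_COLUMNS = IPD_COLUMNS[:9]

_FLAG_COLUMNS = (
    "ecog_ge1",
    "os_event",
    "pfs_event",
    "discontinued_ae",
    "thrombosis_g34",
    "neuropathy_g34",
)
_TIME_COLUMNS = ("os_time", "pfs_time")
_RESPONSE_COLUMNS = ("response_postinduction", "response_posttransplant")


@dataclass(frozen=True)
class MatchTarget:
    """One summary statistic of the aggregate comparator population.

    Parameters
    ----------
    variable
        Covariate name (an IPD column).
    statistic
        ``"mean"``, ``"proportion"`` or ``"median"``.
    value
        Target value in the variable's units (proportions on (0, 1)).
    level
        Category label for proportion targets (e.g. ``iss`` level ``"I"``).
    """

    variable: str
    statistic: str
    value: float
    level: str | int | None = None

    def __post_init__(self) -> None:
        if self.statistic not in ("mean", "proportion", "median"):
            raise ValidationError(
                f"unknown statistic {self.statistic!r} for {self.variable!r}"
            )
        if self.statistic == "proportion":
            if self.level is None:
                raise ValidationError(
                    f"proportion target {self.variable!r} requires a level"
                )
            if not 0.0 < float(self.value) < 1.0:
                raise ValidationError(
                    f"proportion target {self.variable!r}={self.value} outside (0, 1)"
                )

    @property
    def key(self) -> str:
        if self.level is not None:
            return f"{self.variable}[{self.level}]"
        return self.variable


@dataclass(frozen=True)
class AggregateProfile:
    """Target summary profile of the population being matched to."""

    targets: tuple[MatchTarget, ...]
    source_n: int

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValidationError("aggregate profile has no targets")
        keys = [t.key for t in self.targets]
        dupes = {k for k in keys if keys.count(k) > 1}
        if dupes:
            raise ValidationError(f"duplicate profile targets: {sorted(dupes)}")
        if self.source_n <= 0:
            raise ValidationError("source_n must be positive")


@dataclass(frozen=True)
class EncodingRule:
    """How one matched variable enters the design matrix.

    ``reference`` documents the omitted category for dummy-coded variables
    (female sex, non-IgG myeloma, ISS III, ECOG 0).
    """

    variable: str
    statistic: str
    level: str | int | None = None
    reference: str | None = None


@dataclass(frozen=True)
class MatchSpec:
    """Ordered encoding rules mapping match targets to design columns.

    Median targets are encoded as the indicator ``I(x <= target)`` with target
    proportion 0.5, which constrains the weighted median to the target.
    """

    rules: tuple[EncodingRule, ...]

    def rule_for(self, target: MatchTarget) -> EncodingRule:
        for rule in self.rules:
            if rule.variable == target.variable and (
                target.level is None or rule.level == target.level
            ):
                return rule
        raise SchemaError(
            f"no encoding rule for target {target.key!r} in match spec"
        )


def default_match_spec() -> MatchSpec:
    """The seven-variable matching specification used by the analysis.

    ISS is dummy coded as I and II with III as reference; sex is the male
    indicator (female reference); myeloma type is the IgG indicator (non-IgG
    reference); ECOG is the >=1 indicator (ECOG 0 reference); age and
    creatinine clearance are matched on their medians via indicators.
    """
    return MatchSpec(
        rules=(
            EncodingRule("age", "median"),
            EncodingRule("sex", "proportion", level="male", reference="female"),
            EncodingRule("ecog_ge1", "proportion", level=1, reference="ECOG 0"),
            EncodingRule(
                "myeloma_type", "proportion", level="IgG", reference="non-IgG"
            ),
            EncodingRule("iss", "proportion", level="I", reference="III"),
            EncodingRule("iss", "proportion", level="II", reference="III"),
            EncodingRule("creatinine_clearance", "median"),
        )
    )


# ---------------------------------------------------------------------------
# IPD table


@dataclass
class IPDTable:
    """Validated individual patient data for one or more trials.

    Wraps a :class:`pandas.DataFrame` in the canonical column order.
    ``provenance`` maps trial ids to free-text source labels.
    """

    frame: pd.DataFrame
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frame = _validate_frame(self.frame)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n(self) -> int:
        return len(self.frame)

    def trials(self) -> list[str]:
        return list(dict.fromkeys(self.frame["trial_id"]))

    def subset(self, mask: Sequence[bool] | pd.Series) -> "IPDTable":
        sub = self.frame.loc[np.asarray(mask, dtype=bool)].reset_index(drop=True)
        return IPDTable(sub, dict(self.provenance))


def _name_rows(idx: Iterable[int], limit: int = 5) -> str:
    rows = [str(i + 1) for i in list(idx)[:limit]]  # 1-based data rows
    return ", ".join(rows)


def _validate_frame(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")
    frame = frame.copy()
    for col in IPD_COLUMNS:
        if col not in frame.columns:
            frame[col] = np.nan
    frame = frame[list(IPD_COLUMNS)].reset_index(drop=True)

    frame["patient_id"] = frame["patient_id"].astype(str)
    frame["trial_id"] = frame["trial_id"].astype(str)
    frame["arm"] = frame["arm"].astype(str)

    dup = frame.duplicated(subset=["trial_id", "patient_id"])
    if dup.any():
        raise ValidationError(
            "duplicate (trial_id, patient_id) on rows "
            f"{_name_rows(np.flatnonzero(dup))}"
        )

    for col in ("age", "creatinine_clearance", "hemoglobin", "platelets") + _TIME_COLUMNS:
        try:
            frame[col] = pd.to_numeric(frame[col])
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(frame[col], errors="coerce").isna() & frame[col].notna()
            raise SchemaError(
                f"non-numeric value in column {col!r} on rows "
                f"{_name_rows(np.flatnonzero(bad))}"
            ) from exc

    for col, levels in (
        ("sex", SEX_LEVELS),
        ("myeloma_type", MYELOMA_LEVELS),
        ("iss", ISS_LEVELS),
    ):
        vals = frame[col].astype(str)
        bad = ~vals.isin(levels) & frame[col].notna()
        if bad.any():
            raise ValidationError(
                f"invalid {col!r} value (allowed {list(levels)}) on rows "
                f"{_name_rows(np.flatnonzero(bad.to_numpy()))}"
            )
        frame[col] = vals.where(frame[col].notna())

    for col in _RESPONSE_COLUMNS:
        vals = frame[col].where(frame[col].notna())
        bad = vals.notna() & ~vals.astype(str).isin(RESPONSE_LEVELS)
        if bad.any():
            raise ValidationError(
                f"invalid response level in {col!r} on rows "
                f"{_name_rows(np.flatnonzero(bad.to_numpy()))}"
            )

    for col in _FLAG_COLUMNS:
        vals = pd.to_numeric(frame[col], errors="coerce")
        bad = frame[col].notna() & (~vals.isin([0, 1]) | vals.isna())
        if bad.any():
            raise ValidationError(
                f"flag column {col!r} must be 0/1; bad rows "
                f"{_name_rows(np.flatnonzero(bad.to_numpy()))}"
            )
        frame[col] = vals

    for col in _TIME_COLUMNS:
        bad = frame[col].notna() & (frame[col] < 0)
        if bad.any():
            raise ValidationError(
                f"negative time in {col!r} on rows "
                f"{_name_rows(np.flatnonzero(bad.to_numpy()))}"
            )
    return frame


def response_counts(ipd: IPDTable, timepoint: str) -> dict[str, int]:
    """Nested responder counts at a timepoint.

    Returns ``{"orr": ..., "vgpr_plus": ..., "cr_plus": ..., "n": ...}`` where
    ORR counts PR or better.  Nesting ``cr_plus <= vgpr_plus <= orr`` holds by
    construction of the ordinal coding.
    """
    col = f"response_{timepoint}"
    if col not in ipd.frame.columns:
        raise SchemaError(f"unknown response timepoint {timepoint!r}")
    resp = ipd.frame[col].dropna().astype(str)
    rank = resp.map({lev: i for i, lev in enumerate(RESPONSE_LEVELS)})
    return {
        "orr": int((rank >= 1).sum()),
        "vgpr_plus": int((rank >= 2).sum()),
        "cr_plus": int((rank >= 3).sum()),
        "n": int(len(resp)),
    }


# ---------------------------------------------------------------------------
# IO


def read_ipd(path: str | Path, provenance: Mapping[str, str] | None = None) -> IPDTable:
    """Read a comma-separated IPD file into a validated :class:`IPDTable`.

    Lines starting with ``#`` are treated as provenance comments.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, comment="#")
    return IPDTable(frame, dict(provenance or {}))


def write_ipd(ipd: IPDTable, path: str | Path) -> None:
    """Write an IPD table as UTF-8 CSV with a provenance header comment."""
    path = Path(path)
    prov = "; ".join(f"{k}: {v}" for k, v in ipd.provenance.items()) or "synthetic"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# vtdmaic IPD | provenance: {prov}\n")
        ipd.frame.to_csv(fh, index=False)


def read_profile(path: str | Path) -> AggregateProfile:
    """Read an aggregate baseline profile from YAML.

    Expected layout::

        source_n: 591
        targets:
          - {variable: age, statistic: median, value: 58}
          - {variable: sex, statistic: proportion, level: male, value: 0.58}
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not isinstance(raw, Mapping) or "targets" not in raw:
        raise SchemaError(f"{path}: expected mapping with a 'targets' list")
    targets = tuple(
        MatchTarget(
            variable=str(t["variable"]),
            statistic=str(t["statistic"]),
            value=float(t["value"]),
            level=t.get("level"),
        )
        for t in raw["targets"]
    )
    return AggregateProfile(targets=targets, source_n=int(raw.get("source_n", 0)))


def write_profile(profile: AggregateProfile, path: str | Path) -> None:
    doc = {
        "source_n": int(profile.source_n),
        "targets": [
            {
                k: v
                for k, v in dataclasses.asdict(t).items()
                if v is not None
            }
            for t in profile.targets
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def pool_trials(tables: Sequence[IPDTable]) -> IPDTable:
    """Concatenate trial tables into one pooled arm, preserving provenance.

    Raises on any (trial_id, patient_id) collision; the pooled size is the sum
    of the input sizes.
    """
    if not tables:
        raise ValidationError("nothing to pool")
    frames = [t.frame for t in tables]
    pooled = pd.concat(frames, ignore_index=True)
    prov: dict[str, str] = {}
    for t in tables:
        prov.update(t.provenance)
    return IPDTable(pooled, prov)  # duplicate pairs rejected by validation


# ---------------------------------------------------------------------------
# Encoding for matching


def _raw_indicator(frame: pd.DataFrame, target: MatchTarget) -> pd.Series:
    col = frame[target.variable]
    if target.statistic == "mean":
        return pd.to_numeric(col)
    if target.statistic == "median":
        return (pd.to_numeric(col) <= target.value).astype(float).where(col.notna())
    # proportion
    if pd.api.types.is_numeric_dtype(col):
        return (col == float(target.level)).astype(float).where(col.notna())
    return (col.astype(str) == str(target.level)).astype(float).where(col.notna())


def target_center(target: MatchTarget) -> float:
    """The value each encoded column is centred at (0.5 for median targets)."""
    return 0.5 if target.statistic == "median" else float(target.value)


def encode_for_matching(
    ipd: IPDTable,
    profile: AggregateProfile,
    spec: MatchSpec | None = None,
) -> pd.DataFrame:
    """Build the centred design matrix for weight estimation.

    Each profile target becomes one column, centred so that an unweighted
    column mean of zero means the sample already matches that target.  Rows
    with missing matched covariates are excluded with a logged count.
    """
    spec = spec or default_match_spec()
    for target in profile.targets:
        if target.variable not in ipd.frame.columns:
            raise SchemaError(
                f"match target variable {target.variable!r} absent from IPD"
            )
        spec.rule_for(target)  # raises if the spec cannot encode the target

    cols = {}
    for target in profile.targets:
        cols[target.key] = _raw_indicator(ipd.frame, target) - target_center(target)
    design = pd.DataFrame(cols, index=ipd.frame.index)
    keep = design.notna().all(axis=1)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning(
            "encode_for_matching: excluding %d/%d patients with missing matched covariates",
            n_drop,
            len(design),
        )
    return design.loc[keep]
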