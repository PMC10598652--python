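"""Clinical-trial metadata handling and cohort assembly.

A trial metadata sheet arrives as CSV/TSV with arbitrary column names; a
``ColumnMap`` names which columns play the four mandatory roles (patient
id, trial arm, survival status, time to event) plus optional covariates.
The trial-arm and survival-status columns must be strictly binary; any
two-level encoding is accepted and coerced to 0/1 with the chosen mapping
echoed to the log (by default the lexicographically larger level maps
to 1, so "treatment" > "placebo" and "1" > "0" behave as expected).

Joining with a gene tally yields one row per clinical patient with that
patient's SV count in a chosen target gene; patients missing from the VCF
get a count of 0 with a warning.  Carrier stratification applies an
optional [min_sv, max_sv] window: a patient with 0 SVs is always a
non-carrier, a patient inside the window is a carrier, and a patient with
a nonzero count outside the window is excluded from stratified analyses
rather than silently relabeled as SV-free.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .tally import GeneTally

__all__ = ["ColumnMap", "ClinicalTable", "CohortFrame", "read_metadata",
           "join_cohort", "stratify_by_sv", "arm_sv_crosstab"]

log = logging.getLogger(__name__)

TIME_UNITS = ("days", "weeks", "months", "years")


@dataclass
class ColumnMap:
    """Mapping from metadata column names to their semantic roles."""

    id_col: str
    arm_col: str
    event_col: str
    time_col: str
    time_unit: str = "years"
    covariate_cols: list = field(default_factory=list)  # (name, "numeric"|"categorical")
    arm_levels: dict | None = None    # optional explicit level -> {0,1} maps
    event_levels: dict | None = None

    def __post_init__(self):
        roles = [self.id_col, self.arm_col, self.event_col, self.time_col]
        if len(set(roles)) != 4:
            raise ValidationError(f"mapped role columns must be distinct, got {roles}")
        if self.time_unit not in TIME_UNITS:
            raise ValidationError(f"time_unit must be one of {TIME_UNITS}")
        for name, kind in self.covariate_cols:
            if kind not in ("numeric", "categorical"):
                raise ValidationError(f"covariate kind for {name!r} must be numeric|categorical")


@dataclass
class ClinicalTable:
    """Validated trial metadata in canonical columns.

    ``frame`` has columns patient_id, arm (0=placebo/reference, 1=treatment),
    event (1=event observed, 0=censored), time (>0, in ``time_unit``), plus
    one column per covariate.
    """

    frame: pd.DataFrame
    time_unit: str
    arm_levels: dict
    event_levels: dict
    covariates: list = field(default_factory=list)


def _coerce_binary(series: pd.Series, role: str, level_map: dict | None) -> tuple[pd.Series, dict]:
    levels = sorted(series.dropna().astype(str).unique())
    if set(levels) <= {"0", "1"} and level_map is None:
        # already 0/1 coded; accept even if only one level is observed
        return series.astype(str).astype(int), {"0": 0, "1": 1}
    if len(levels) != 2:
        raise ValidationError(
            f"{role} column {series.name!r} must be binary; found {len(levels)} "
            f"level(s): {levels}")
    if level_map is None:
        level_map = {levels[0]: 0, levels[1]: 1}  # lexicographically larger -> 1
    else:
        if sorted(map(str, level_map)) != levels:
            raise ValidationError(f"explicit {role} level map {level_map} does not cover {levels}")
        level_map = {str(k): int(v) for k, v in level_map.items()}
    log.info("%s column %r coded as %s", role, series.name, level_map)
    return series.astype(str).map(level_map).astype(int), level_map


def read_metadata(path, column_map: ColumnMap, sep: str | None = None) -> ClinicalTable:
    """Read and validate a CSV/TSV metadata sheet.

    The delimiter is inferred from the file extension (.tsv/.tab -> tab,
    anything else -> comma) unless ``sep`` is given.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    try:
        raw = pd.read_csv(path, sep=sep)
    except Exception as exc:
        raise FormatError(f"cannot read metadata {path}: {exc}") from exc

    cm = column_map
    needed = [cm.id_col, cm.arm_col, cm.event_col, cm.time_col] + [c for c, _ in cm.covariate_cols]
    missing = [c for c in needed if c not in raw.columns]
    if missing:
        raise ValidationError(
            f"metadata is missing mapped column(s) {missing}; available: {list(raw.columns)}")

    ids = raw[cm.id_col].astype(str)
    dup = ids[ids.duplicated()].unique()
    if len(dup):
        raise ValidationError(f"duplicate patient id(s): {sorted(dup)}")
    for col in (cm.id_col, cm.arm_col, cm.event_col, cm.time_col):
        if raw[col].isna().any():
            bad = raw.index[raw[col].isna()].tolist()
            raise ValidationError(f"missing values in mandatory column {col!r} at rows {bad}")

    arm, arm_levels = _coerce_binary(raw[cm.arm_col], "trial-arm", cm.arm_levels)
    event, event_levels = _coerce_binary(raw[cm.event_col], "survival-status", cm.event_levels)

    time = pd.to_numeric(raw[cm.time_col], errors="coerce")
    bad = raw.index[time.isna() | (time <= 0)].tolist()
    if bad:
        raise ValidationError(
            f"time column {cm.time_col!r} must be positive numeric; bad rows: {bad}")

    frame = pd.DataFrame({"patient_id": ids, "arm": arm, "event": event,
                          "time": time.astype(float)})
    for name, kind in cm.covariate_cols:
        if kind == "numeric":
            vals = pd.to_numeric(raw[name], errors="coerce")
            if vals.isna().any():
                raise ValidationError(f"numeric covariate {name!r} has non-numeric entries")
            frame[name] = vals.astype(float)
        else:
            frame[name] = raw[name].astype(str)
    return ClinicalTable(frame=frame.reset_index(drop=True), time_unit=cm.time_unit,
                         arm_levels=arm_levels, event_levels=event_levels,
                         covariates=[c for c, _ in cm.covariate_cols])


@dataclass
class CohortFrame:
    """Clinical rows joined with one target gene's SV counts.

    ``frame`` extends the clinical columns with ``sv_count`` and, after
    stratification, ``carrier`` (bool) and ``excluded`` (bool: nonzero
    count outside the active [min_sv, max_sv] window).
    """

    frame: pd.DataFrame
    target_gene: str
    time_unit: str
    covariates: list = field(default_factory=list)
    min_sv: int | None = None
    max_sv: float = math.inf
    n_missing_in_vcf: int = 0

    @property
    def stratified(self) -> bool:
        return "carrier" in self.frame.columns

    def analyzed(self) -> pd.DataFrame:
        """Rows entering stratified analyses (exclusions dropped)."""
        if not self.stratified:
            raise ValidationError("cohort not stratified yet; call stratify_by_sv first")
        return self.frame[~self.frame["excluded"]].reset_index(drop=True)


def join_cohort(tally: GeneTally, clinical: ClinicalTable, target_gene: str) -> CohortFrame:
    """One row per clinical patient with the target-gene SV count attached.

    Patients absent from the VCF get sv_count 0 (warned); tally samples
    absent from the metadata are dropped (warned).  Zero id overlap is a
    hard error since it almost always means mismatched id schemes.
    """
    counts = tally.gene_counts(target_gene)
    ids = clinical.frame["patient_id"]
    overlap = set(ids) & set(counts.index.astype(str))
    if len(tally.samples) and not overlap:
        raise ValidationError(
            "no overlap between tally samples and clinical patient ids — "
            f"id scheme mismatch? (tally: {tally.samples[:3]}..., "
            f"metadata: {ids.tolist()[:3]}...)")
    extra = set(map(str, counts.index)) - set(ids)
    if extra:
        log.warning("%d tally sample(s) absent from metadata are dropped: %s",
                    len(extra), sorted(extra)[:5])
    sv = ids.map(lambda i: counts.get(i, None))
    n_missing = int(sv.isna().sum())
    if n_missing:
        log.warning("%d patient(s) in metadata but not in VCF; their SV count is set to 0",
                    n_missing)
    frame = clinical.frame.copy()
    frame["sv_count"] = sv.fillna(0).astype(int)
    return CohortFrame(frame=frame, target_gene=target_gene, time_unit=clinical.time_unit,
                       covariates=list(clinical.covariates), n_missing_in_vcf=n_missing)


def stratify_by_sv(cohort: CohortFrame, min_sv: int = 1, max_sv: float = math.inf) -> CohortFrame:
    """Label carriers by an SV-count window and mark out-of-window exclusions.

    carrier  <=> min_sv <= sv_count <= max_sv
    excluded <=> 0 < sv_count < min_sv  or  sv_count > max_sv

    sv_count == 0 always means non-carrier.
    """
    if min_sv < 1:
        raise ValidationError("min_sv must be >= 1")
    if max_sv < min_sv:
        raise ValidationError(f"max_sv ({max_sv}) must be >= min_sv ({min_sv})")
    frame = cohort.frame.copy()
    sv = frame["sv_count"]
    frame["carrier"] = (sv >= min_sv) & (sv <= max_sv)
    frame["excluded"] = (sv > 0) & ~frame["carrier"]
    n_excl = int(frame["excluded"].sum())
    if n_excl == len(frame):
        raise ValidationError("SV-count constraints exclude every patient")
    if n_excl:
        log.info("%d patient(s) with 0 < sv_count < %d or > %s excluded from "
                 "stratified analyses", n_excl, min_sv, max_sv)
    return CohortFrame(frame=frame, target_gene=cohort.target_gene,
                       time_unit=cohort.time_unit, covariates=list(cohort.covariates),
                       min_sv=min_sv, max_sv=max_sv,
                       n_missing_in_vcf=cohort.n_missing_in_vcf)


def arm_sv_crosstab(cohort: CohortFrame) -> pd.DataFrame:
    """2x2 arm x carrier counts with per-arm proportions on the analyzed cohort."""
    df = cohort.analyzed()
    tab = pd.crosstab(df["arm"], df["carrier"]).reindex(
        index=[0, 1], columns=[False, True], fill_value=0)
    tab.index = pd.Index(["placebo", "treatment"], name="arm")
    tab.columns = ["non_carrier", "carrier"]
    totals = tab.sum(axis=1)
    with np.errstate(invalid="ignore"):
        tab["carrier_fraction"] = np.where(totals > 0, tab["carrier"] / totals, np.nan)
    tab["n"] = totals
    return tab
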