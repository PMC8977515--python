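"""Recipient cohort: loading, validation, eligibility filtering and summaries.

A cohort is a list of :class:`CohortRecord`, one per kidney-transplant
recipient, carrying the plasma ddcfDNA fraction measured at biopsy, the
histopathological diagnosis group (NR / Borderline / TCMR / ABMR), the Banff
lesion scores assigned by pathologists, demographics, and an exclusion flag
from the screening step. Eligibility filtering reproduces the screening
arithmetic of the study design: records flagged with one of the seven
exclusion categories are removed (logged per category), and an age floor is
applied to the remainder.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BanffScores",
    "CohortRecord",
    "EligibilityCriteria",
    "ExclusionLog",
    "DIAGNOSIS_GROUPS",
    "EXCLUSION_CATEGORIES",
    "BANFF_LESIONS",
    "load_cohort",
    "write_cohort",
    "apply_eligibility",
    "lesion_contingency",
    "summarize_demographics",
]

DIAGNOSIS_GROUPS = ("NR", "Borderline", "TCMR", "ABMR")

#: Exclusion categories in screening order; when a record matches several,
#: the first in this order is the one logged.
EXCLUSION_CATEGORIES = (
    "recurrent_or_denovo_GN",
    "BKVN",
    "possible_BKVN",
    "TCMR_with_BK_load",
    "multiorgan_tx",
    "repeat_tx",
    "CNI_toxicity",
)

#: Banff lesion sub-scores (all ordinal 0-3). ``mvi`` is derived (g + ptc)
#: and deliberately not in this tuple.
BANFF_LESIONS = ("g", "t", "v", "i", "ci", "ct", "cg", "cv", "mm", "ah", "aah", "ptc", "c4d")

SEX_VALUES = ("M", "F")
DIALYSIS_VALUES = ("None", "HD", "PD")
INDUCTION_VALUES = ("None", "Simulect", "ATG")
DONOR_TYPES = ("DCD", "LD")


@dataclass
class BanffScores:
    """Ordinal Banff lesion grades for one biopsy.

    Each score is an integer in {0, 1, 2, 3}. Microvascular inflammation
    (``mvi``) is always recomputed as ``g + ptc`` and never stored.
    """

    g: int = 0
    t: int = 0
    v: int = 0
    i: int = 0
    ci: int = 0
    ct: int = 0
    cg: int = 0
    cv: int = 0
    mm: int = 0
    ah: int = 0
    aah: int = 0
    ptc: int = 0
    c4d: int = 0

    def __post_init__(self) -> None:
        for lesion in BANFF_LESIONS:
            score = getattr(self, lesion)
            if not isinstance(score, (int, np.integer)) or not 0 <= score <= 3:
                raise ValueError(f"Banff score {lesion}={score!r} not an integer in 0..3")
            setattr(self, lesion, int(score))

    @property
    def mvi(self) -> int:
        """Microvascular inflammation, the sum g + ptc (0-6)."""
        return self.g + self.ptc

    def score(self, lesion: str) -> int:
        if lesion == "mvi":
            return self.mvi
        if lesion not in BANFF_LESIONS:
            raise KeyError(f"unknown Banff lesion {lesion!r}")
        return getattr(self, lesion)


@dataclass
class CohortRecord:
    recipient_id: str
    ddcfdna_fraction: float  # percent of total plasma cfDNA, 0-100
    diagnosis: Optional[str] = None
    banff: BanffScores = field(default_factory=BanffScores)
    ddcfdna_concentration: Optional[float] = None
    age_years: Optional[float] = None
    sex: Optional[str] = None
    height_cm: Optional[float] = None
    weight_kg: Optional[float] = None
    bmi: Optional[float] = None
    hla_mismatch: Optional[int] = None
    dialysis: Optional[str] = None
    induction: Optional[str] = None
    donor_type: Optional[str] = None
    exclusion_reason: str = "none"

    def __post_init__(self) -> None:
        if not 0 <= self.ddcfdna_fraction <= 100:
            raise ValueError(
                f"record {self.recipient_id}: ddcfdna_fraction={self.ddcfdna_fraction} "
                "outside 0..100"
            )
        if self.exclusion_reason not in EXCLUSION_CATEGORIES + ("none",):
            raise ValueError(
                f"record {self.recipient_id}: unknown exclusion_reason {self.exclusion_reason!r}"
            )
        if self.diagnosis is not None:
            if self.exclusion_reason != "none":
                raise ValueError(
                    f"record {self.recipient_id}: diagnosis defined but record is excluded"
                )
            if self.diagnosis not in DIAGNOSIS_GROUPS:
                raise ValueError(
                    f"record {self.recipient_id}: unknown diagnosis {self.diagnosis!r}"
                )
        for name, allowed in (
            ("sex", SEX_VALUES),
            ("dialysis", DIALYSIS_VALUES),
            ("induction", INDUCTION_VALUES),
            ("donor_type", DONOR_TYPES),
        ):
            value = getattr(self, name)
            if value is not None and value not in allowed:
                raise ValueError(f"record {self.recipient_id}: {name}={value!r} not in {allowed}")
        if self.hla_mismatch is not None and not 0 <= int(self.hla_mismatch) <= 6:
            raise ValueError(f"record {self.recipient_id}: hla_mismatch outside 0..6")
        if self.bmi is not None and self.height_cm and self.weight_kg:
            expected = self.weight_kg / (self.height_cm / 100.0) ** 2
            if abs(expected - self.bmi) > 0.1:
                raise ValueError(
                    f"record {self.recipient_id}: bmi={self.bmi} inconsistent with "
                    f"height/weight (expected {expected:.2f})"
                )

    @property
    def mvi(self) -> int:
        return self.banff.mvi


@dataclass
class EligibilityCriteria:
    min_age_years: float = 18.0
    min_graft_function_decline: float = 20.0  # percent from nadir; screening metadata
    excluded_categories: frozenset = frozenset(EXCLUSION_CATEGORIES)

    def __post_init__(self) -> None:
        if not self.excluded_categories:
            raise ValueError("excluded_categories must be non-empty")


class ExclusionLog(dict):
    """Counts of excluded records per category (plus ``under_age``)."""

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dict(self), indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# CSV I/O

CSV_COLUMNS = [
    "recipient_id", "ddcfdna_fraction", "diagnosis",
    "g", "t", "v", "i", "ci", "ct", "cg", "cv", "mm", "ah", "aah", "ptc", "c4d",
    "age", "sex", "height_cm", "weight_kg", "hla_mm", "dialysis", "induction",
    "donor_type", "exclusion_reason",
]

_REQUIRED = {"recipient_id", "ddcfdna_fraction", "exclusion_reason"}


def _opt(value, cast=float):
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return cast(value)


def load_cohort(path: str | Path) -> list[CohortRecord]:
    """Read a cohort CSV into validated :class:`CohortRecord` objects.

    Malformed rows raise ``ValueError`` naming the (1-based, header-exclusive)
    row number and the offending column.
    """
    df = pd.read_csv(path, dtype={"recipient_id": str})
    missing = _REQUIRED - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    records = []
    for idx, row in df.iterrows():
        rownum = int(idx) + 1
        try:
            banff = BanffScores(**{l: int(row.get(l, 0) if pd.notna(row.get(l, 0)) else 0)
                                   for l in BANFF_LESIONS})
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: row {rownum}, Banff columns: {exc}") from exc
        try:
            record = CohortRecord(
                recipient_id=str(row["recipient_id"]),
                ddcfdna_fraction=float(row["ddcfdna_fraction"]),
                diagnosis=_opt(row.get("diagnosis"), str),
                banff=banff,
                age_years=_opt(row.get("age")),
                sex=_opt(row.get("sex"), str),
                height_cm=_opt(row.get("height_cm")),
                weight_kg=_opt(row.get("weight_kg")),
                hla_mismatch=_opt(row.get("hla_mm"), int),
                dialysis=_opt(row.get("dialysis"), str),
                induction=_opt(row.get("induction"), str),
                donor_type=_opt(row.get("donor_type"), str),
                exclusion_reason=str(row.get("exclusion_reason", "none")),
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {rownum}: {exc}") from exc
        records.append(record)
    return records


def write_cohort(records: Sequence[CohortRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {
            "recipient_id": r.recipient_id,
            "ddcfdna_fraction": r.ddcfdna_fraction,
            "diagnosis": r.diagnosis if r.diagnosis is not None else "",
            "age": r.age_years, "sex": r.sex, "height_cm": r.height_cm,
            "weight_kg": r.weight_kg, "hla_mm": r.hla_mismatch,
            "dialysis": r.dialysis, "induction": r.induction,
            "donor_type": r.donor_type, "exclusion_reason": r.exclusion_reason,
        }
        for lesion in BANFF_LESIONS:
            row[lesion] = getattr(r.banff, lesion)
        rows.append(row)
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Eligibility

def apply_eligibility(
    records: Sequence[CohortRecord],
    criteria: EligibilityCriteria | None = None,
) -> tuple[list[CohortRecord], ExclusionLog]:
    """Partition records into retained vs excluded, logging per category.

    Category exclusions take precedence (in :data:`EXCLUSION_CATEGORIES`
    order); the age floor applies only to records with no exclusion category,
    logged under ``under_age``. The partition is exact:
    ``len(retained) + sum(log.values()) == len(records)``.
    """
    criteria = criteria or EligibilityCriteria()
    retained: list[CohortRecord] = []
    log = ExclusionLog()
    for record in records:
        if record.exclusion_reason != "none" and record.exclusion_reason in criteria.excluded_categories:
            log[record.exclusion_reason] = log.get(record.exclusion_reason, 0) + 1
        elif record.age_years is not None and record.age_years < criteria.min_age_years:
            log["under_age"] = log.get("under_age", 0) + 1
        else:
            retained.append(record)
    assert len(retained) + sum(log.values()) == len(records)
    return retained, log


# ---------------------------------------------------------------------------
# Summaries

def lesion_contingency(cohort: Sequence[CohortRecord], lesion: str):
    """Score-level x diagnosis-group contingency table for one Banff lesion.

    Rows are score levels in ascending order (0..3, or 0..6 for the derived
    ``mvi``); columns are the diagnosis groups in NR, Borderline, TCMR, ABMR
    order. Cell counts sum to the number of diagnosed records.
    """
    from .stats import ContingencyTable

    if lesion != "mvi" and lesion not in BANFF_LESIONS:
        raise KeyError(f"unknown Banff lesion {lesion!r}")
    levels = list(range(7)) if lesion == "mvi" else list(range(4))
    counts = np.zeros((len(levels), len(DIAGNOSIS_GROUPS)), dtype=int)
    for record in cohort:
        if record.diagnosis is None:
            raise ValueError(f"record {record.recipient_id} has no diagnosis")
        row = record.banff.score(lesion)
        col = DIAGNOSIS_GROUPS.index(record.diagnosis)
        counts[row, col] += 1
    return ContingencyTable(
        row_labels=[f"{lesion}{lvl}" for lvl in levels],
        col_labels=list(DIAGNOSIS_GROUPS),
        counts=counts,
    )


_CONTINUOUS = ["age_years", "height_cm", "weight_kg", "bmi", "hla_mismatch"]
_CATEGORICAL = ["sex", "dialysis", "induction", "donor_type"]


def summarize_demographics(
    cohort: Sequence[CohortRecord],
    continuous: Iterable[str] = tuple(_CONTINUOUS),
    categorical: Iterable[str] = tuple(_CATEGORICAL),
) -> pd.DataFrame:
    """Per-group demographics table: mean +/- SEM for continuous variables
    (one-way ANOVA p), counts for categoricals (chi-square p).

    Groups with fewer than two values report the SEM as missing and are left
    out of the ANOVA (a warning is emitted when that drops the test below
    two groups).
    """
    import warnings

    from . import stats as assoc

    if not cohort:
        raise ValueError("cohort is empty")
    groups = {g: [r for r in cohort if r.diagnosis == g] for g in DIAGNOSIS_GROUPS}
    groups = {g: rs for g, rs in groups.items() if rs}
    rows = []
    for field_name in continuous:
        cells: dict[str, str] = {}
        samples = []
        for g, rs in groups.items():
            vals = np.array([getattr(r, field_name) for r in rs
                             if getattr(r, field_name) is not None], dtype=float)
            if len(vals) == 0:
                cells[g] = ""
                continue
            mean = vals.mean()
            if len(vals) >= 2:
                sem = vals.std(ddof=1) / np.sqrt(len(vals))
                cells[g] = f"{mean:.2f} ± {sem:.2f}"
                samples.append(vals)
            else:
                cells[g] = f"{mean:.2f} ± NA"
        if len(samples) >= 2:
            res = assoc.one_way_anova(samples)
            p, method = res.p_value, res.method
        else:
            warnings.warn(f"{field_name}: fewer than two groups with n>=2; ANOVA skipped")
            p, method = np.nan, "skipped"
        rows.append({"variable": field_name, **cells, "p_value": p, "method": method})
    for field_name in categorical:
        levels = sorted({getattr(r, field_name) for r in cohort
                         if getattr(r, field_name) is not None})
        counts = np.array([[sum(1 for r in rs if getattr(r, field_name) == lvl)
                            for g, rs in groups.items()] for lvl in levels], dtype=int)
        cells = {g: "/".join(str(c) for c in counts[:, j])
                 for j, g in enumerate(groups)}
        if counts.shape[0] >= 2 and counts.shape[1] >= 2:
            from .stats import ContingencyTable

            res = assoc.chi_square_test(
                ContingencyTable(levels, list(groups), counts))
            p, method = res.p_value, res.method
        else:
            p, method = np.nan, "skipped"
        rows.append({"variable": field_name, **cells, "p_value": p, "method": method})
    return pd.DataFrame(rows)
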