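"""Core claims/registry data model.

The atomic evidence unit is a :class:`ClaimLine` — one billed code on one
service date, with its setting (in-hospital vs outpatient clinic) and the
prescribing department.  The analysis unit is an :class:`AdmissionEpisode`:
an index hospitalization carrying a cerebrovascular diagnosis code (ICD-10 /
KCD I60–I64 as principal or additional diagnosis), together with the claim
lines attributed to it and the patient's prior claim history.  Episode truth
labels come from linkage with a stroke registry (:class:`RegistryRecord`,
:class:`LinkedEpisode`).
"""

from __future__ import annotations

import dataclasses
import datetime
import enum


class Setting(str, enum.Enum):
    """Where a claim line was generated."""

    IN_HOSPITAL = "in_hospital"
    OUTPATIENT = "outpatient"


class Department(str, enum.Enum):
    """Prescribing department, coarsened to the categories the rules use."""

    NEUROLOGY = "neurology"
    NEUROSURGERY = "neurosurgery"
    REHABILITATION = "rehabilitation"
    OTHER = "other"


class CodeKind(str, enum.Enum):
    DIAGNOSIS = "diagnosis"
    PROCEDURE = "procedure"
    DRUG = "drug"


class DxPosition(str, enum.Enum):
    """Position of a diagnosis code on the claim; NONE for non-diagnosis lines."""

    PRINCIPAL = "principal"
    ADDITIONAL = "additional"
    NONE = "none"


@dataclasses.dataclass(slots=True)
class ClaimLine:
    """One billed code on one date, with its billing context.

    ``service_date`` is the date the service was rendered; ``claim_start_date``
    is the start date of the claim the line belongs to (for an in-hospital
    claim, the admission date — the anchor all identifier windows are offset
    from).
    """

    patient_id: str
    claim_id: str
    setting: Setting
    department: Department
    code: str
    code_kind: CodeKind
    dx_position: DxPosition
    service_date: datetime.date
    claim_start_date: datetime.date

    def validate(self) -> None:
        if not self.code:
            raise ValueError("claim line has an empty code")
        is_dx = self.code_kind is CodeKind.DIAGNOSIS
        has_pos = self.dx_position is not DxPosition.NONE
        if is_dx != has_pos:
            raise ValueError(
                f"dx_position={self.dx_position.value!r} inconsistent with "
                f"code_kind={self.code_kind.value!r} for code {self.code!r}"
            )


@dataclasses.dataclass(slots=True)
class AdmissionEpisode:
    """An index hospitalization and the claim lines attributed to it.

    ``index_date`` is the start date of the qualifying in-hospital claim;
    identifier windows are day offsets from it.  ``episode_lines`` holds every
    line of the same patient inside the attribution window (wide enough for
    all identifier windows); ``lookback_lines`` holds the patient's lines
    strictly before the index date (used for the prior-stroke washout and the
    180-day drug-exposure lookback).
    """

    episode_id: str
    patient_id: str
    index_date: datetime.date
    principal_dx: str
    episode_lines: list[ClaimLine]
    lookback_lines: list[ClaimLine]
    site: str | None = None

    def day_offset(self, line: ClaimLine) -> int:
        """Whole-day offset of a line's service date from the index date."""
        return (line.service_date - self.index_date).days


@dataclasses.dataclass(frozen=True, slots=True)
class RegistryRecord:
    """Gold-standard registry entry keyed by the episode's claim serial key."""

    episode_id: str
    true_ais: bool


@dataclasses.dataclass(slots=True)
class LinkedEpisode:
    """An episode with its linkage-derived truth label.

    The label is exactly the linkage outcome: an episode with no registry
    match is labelled ``false``.
    """

    episode: AdmissionEpisode
    true_ais: bool

    @property
    def episode_id(self) -> str:
        return self.episode.episode_id
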