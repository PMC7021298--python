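"""Episode reconstruction from claim lines.

Reads delimited claims/registry tables, reconstructs admission episodes from
patient-level claim lines (one episode per in-hospital claim carrying a
cerebrovascular I60–I64 diagnosis as principal or additional code), applies
the prior-stroke washout, and links episodes to gold-standard registry
labels.  All downstream results are invariant to the order of the input
claim lines.
"""

from __future__ import annotations

import dataclasses
import datetime
from collections import defaultdict
from typing import Iterable, Sequence

import pandas as pd

from .model import (
    AdmissionEpisode,
    ClaimLine,
    CodeKind,
    Department,
    DxPosition,
    LinkedEpisode,
    RegistryRecord,
    Setting,
)

#: 3-character stems of the cerebrovascular diagnosis family used both for
#: episode inclusion and for the prior-stroke washout.
STROKE_DX_PREFIXES: tuple[str, ...] = ("I60", "I61", "I62", "I63", "I64")

#: Day-offset window, relative to the index date, of claim lines attributed
#: to an episode.  It is the union of every identifier window (widest:
#: imaging at -7 days, outpatient antithrombotics at +90 days); each
#: identifier then applies its own narrower window.
ATTRIBUTION_WINDOW: tuple[int, int] = (-7, 90)

REQUIRED_CLAIMS_COLUMNS = (
    "patient_id",
    "claim_id",
    "setting",
    "department",
    "code",
    "code_kind",
    "dx_position",
    "service_date",
    "claim_start_date",
)

REQUIRED_REGISTRY_COLUMNS = ("episode_id", "true_ais")


class ClaimsSchemaError(ValueError):
    """The input table is missing a required column."""


class ClaimsRowError(ValueError):
    """A row has an unparseable or invalid field; carries the row index."""

    def __init__(self, message: str, rows: Sequence[int]):
        super().__init__(message)
        self.rows = list(rows)


def _parse_dates(df: pd.DataFrame, column: str) -> pd.Series:
    parsed = pd.to_datetime(df[column], format="ISO8601", errors="coerce")
    bad = df.index[parsed.isna() & df[column].notna()].tolist()
    bad += df.index[df[column].isna()].tolist()
    if bad:
        bad = sorted(bad)
        raise ClaimsRowError(
            f"unparseable date in column {column!r} at row(s) {bad[:10]}", bad
        )
    return parsed.dt.date


def _parse_enum(df: pd.DataFrame, column: str, enum_cls) -> list:
    allowed = {e.value: e for e in enum_cls}
    values = df[column].astype(str)
    bad = df.index[~values.isin(allowed)].tolist()
    if bad:
        raise ClaimsRowError(
            f"invalid {column!r} value at row(s) {sorted(bad)[:10]}; "
            f"allowed: {sorted(allowed)}",
            bad,
        )
    return [allowed[v] for v in values]


def claim_lines_from_frame(df: pd.DataFrame) -> list[ClaimLine]:
    """Convert a claims table (documented schema) into validated claim lines."""
    missing = [c for c in REQUIRED_CLAIMS_COLUMNS if c not in df.columns]
    if missing:
        raise ClaimsSchemaError(f"claims table missing required column(s): {missing}")
    df = df.reset_index(drop=True)
    service = _parse_dates(df, "service_date")
    start = _parse_dates(df, "claim_start_date")
    settings = _parse_enum(df, "setting", Setting)
    departments = _parse_enum(df, "department", Department)
    kinds = _parse_enum(df, "code_kind", CodeKind)
    positions = _parse_enum(df, "dx_position", DxPosition)
    lines: list[ClaimLine] = []
    for i, (pid, cid, code) in enumerate(
        zip(df["patient_id"].astype(str), df["claim_id"].astype(str), df["code"].astype(str))
    ):
        line = ClaimLine(
            patient_id=pid,
            claim_id=cid,
            setting=settings[i],
            department=departments[i],
            code=code,
            code_kind=kinds[i],
            dx_position=positions[i],
            service_date=service.iloc[i],
            claim_start_date=start.iloc[i],
        )
        try:
            line.validate()
        except ValueError as exc:
            raise ClaimsRowError(f"invalid row {i}: {exc}", [i]) from exc
        lines.append(line)
    return lines


def read_claims(source) -> list[ClaimLine]:
    """Read a claims CSV (UTF-8, header row, ISO-8601 dates) into claim lines.

    ``source`` may be a path, a file-like object, or an already-loaded
    :class:`pandas.DataFrame`.
    """
    if isinstance(source, pd.DataFrame):
        return claim_lines_from_frame(source)
    return claim_lines_from_frame(pd.read_csv(source, dtype=str, keep_default_na=False))


def read_registry(source) -> list[RegistryRecord]:
    """Read a registry CSV with columns episode_id, true_ais (0/1)."""
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, dtype=str)
    missing = [c for c in REQUIRED_REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise ClaimsSchemaError(f"registry table missing required column(s): {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        raw = str(row.true_ais).strip().lower()
        if raw in {"1", "true"}:
            flag = True
        elif raw in {"0", "false"}:
            flag = False
        else:
            raise ClaimsRowError(f"invalid true_ais value {raw!r} at row {i}", [i])
        records.append(RegistryRecord(episode_id=str(row.episode_id), true_ais=flag))
    return records


def _is_stroke_dx(line: ClaimLine, prefixes: tuple[str, ...]) -> bool:
    return (
        line.code_kind is CodeKind.DIAGNOSIS
        and line.dx_position is not DxPosition.NONE
        and line.code.startswith(prefixes)
    )


def build_episodes(
    lines: Iterable[ClaimLine],
    stroke_dx_prefixes: Sequence[str] = STROKE_DX_PREFIXES,
) -> list[AdmissionEpisode]:
    """Reconstruct admission episodes from patient-level claim lines.

    One episode is created per in-hospital claim carrying a stroke diagnosis
    code (principal or additional); its ``episode_id`` is that claim's id
    (the claim-serial-number analogue used for registry linkage) and its
    index date is the claim's start date.  A patient readmitted twice yields
    two episodes.
    """
    prefixes = tuple(stroke_dx_prefixes)
    by_patient: dict[str, list[ClaimLine]] = defaultdict(list)
    for line in lines:
        by_patient[line.patient_id].append(line)

    episodes: list[AdmissionEpisode] = []
    seen_ids: set[str] = set()
    for pid in sorted(by_patient):
        plines = by_patient[pid]
        # index candidate claims: in-hospital claims with a stroke dx line
        claims: dict[str, dict] = {}
        for line in plines:
            if line.setting is not Setting.IN_HOSPITAL:
                continue
            rec = claims.setdefault(
                line.claim_id, {"start": line.claim_start_date, "stroke": False, "principal": ""}
            )
            if line.claim_start_date < rec["start"]:
                rec["start"] = line.claim_start_date
            if _is_stroke_dx(line, prefixes):
                rec["stroke"] = True
            if (
                line.code_kind is CodeKind.DIAGNOSIS
                and line.dx_position is DxPosition.PRINCIPAL
                and not rec["principal"]
            ):
                rec["principal"] = line.code
        lo, hi = ATTRIBUTION_WINDOW
        for cid in sorted(claims, key=lambda c: (claims[c]["start"], c)):
            rec = claims[cid]
            if not rec["stroke"]:
                continue
            if cid in seen_ids:
                raise ValueError(f"duplicate episode (claim) id {cid!r}")
            seen_ids.add(cid)
            index_date = rec["start"]
            episode_lines = [
                l for l in plines if lo <= (l.service_date - index_date).days <= hi
            ]
            lookback = [l for l in plines if l.service_date < index_date]
            episodes.append(
                AdmissionEpisode(
                    episode_id=cid,
                    patient_id=pid,
                    index_date=index_date,
                    principal_dx=rec["principal"],
                    episode_lines=episode_lines,
                    lookback_lines=lookback,
                )
            )
    return episodes


def apply_washout(
    episodes: Iterable[AdmissionEpisode],
    washout_days: int | None = None,
    stroke_dx_prefixes: Sequence[str] = STROKE_DX_PREFIXES,
) -> list[AdmissionEpisode]:
    """Drop patients with a stroke diagnosis before their first admission.

    A patient is excluded (all episodes dropped) when the lookback of their
    earliest episode contains an I60–I64 diagnosis within ``washout_days``
    before that episode's index date (``None`` = unlimited history, the
    default).  For retained patients, later admissions are kept as
    readmission episodes; their lookbacks necessarily contain the first
    admission's codes, which is why the washout is anchored on the earliest
    episode only (and why the operation is idempotent).
    """
    prefixes = tuple(stroke_dx_prefixes)
    episodes = list(episodes)
    earliest: dict[str, AdmissionEpisode] = {}
    for ep in episodes:
        cur = earliest.get(ep.patient_id)
        if cur is None or (ep.index_date, ep.episode_id) < (cur.index_date, cur.episode_id):
            earliest[ep.patient_id] = ep

    excluded: set[str] = set()
    for pid, ep in earliest.items():
        cutoff = (
            None
            if washout_days is None
            else ep.index_date - datetime.timedelta(days=washout_days)
        )
        for line in ep.lookback_lines:
            if not _is_stroke_dx(line, prefixes):
                continue
            if line.service_date >= ep.index_date:
                continue
            if cutoff is not None and line.service_date < cutoff:
                continue
            excluded.add(pid)
            break
    return [ep for ep in episodes if ep.patient_id not in excluded]


@dataclasses.dataclass(slots=True)
class LinkageResult:
    """Episodes with linkage labels plus the registry-only discard tally."""

    linked: list[LinkedEpisode]
    n_registry_unmatched: int

    @property
    def n_true_ais(self) -> int:
        return sum(le.true_ais for le in self.linked)


def link_registry(
    episodes: Iterable[AdmissionEpisode], registry: Iterable[RegistryRecord]
) -> LinkageResult:
    """Label every episode by the existence of a registry linkage.

    Registry records with no matching claims episode are dropped and counted
    in ``n_registry_unmatched``.  Duplicate registry keys are an error.
    """
    by_id: dict[str, RegistryRecord] = {}
    for rec in registry:
        if rec.episode_id in by_id:
            raise ValueError(f"duplicate registry episode_id {rec.episode_id!r}")
        by_id[rec.episode_id] = rec

    linked: list[LinkedEpisode] = []
    episode_ids: set[str] = set()
    for ep in episodes:
        episode_ids.add(ep.episode_id)
        rec = by_id.get(ep.episode_id)
        linked.append(LinkedEpisode(episode=ep, true_ais=bool(rec and rec.true_ais)))
    unmatched = sum(1 for eid in by_id if eid not in episode_ids)
    return LinkageResult(linked=linked, n_registry_unmatched=unmatched)
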