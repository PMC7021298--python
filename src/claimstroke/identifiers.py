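"""Evaluation of the 17 boolean key identifiers for an admission episode.

Each identifier is a windowed code search over the episode's attributed
claim lines (day offsets measured from the index date, window endpoints
inclusive), except for four special rules:

* **image follow-up** — at least two distinct imaging events, counted as
  distinct (code, service date) pairs over the CT/MRI/CTA code union within
  [-7, +7], at least one of them a CT or MRI code;
* **new antithrombotics** — the set of antithrombotic ingredients dispensed
  in the post-index window differs from the 180-day pre-index exposure set
  (first-ever use, added ingredient, or changed composition); the 90-day
  variant restricts *outpatient* lines to neurology/neurosurgery clinics;
* **anticoagulants** — presence (not novelty) of any anticoagulant
  ingredient within [0, +7];
* **transfer to rehab** — in-hospital lines from both the neurology and the
  rehabilitation department within [0, +30], regardless of code.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import pandas as pd

from .catalog import ANTICOAGULANT_INGREDIENTS, Catalog, IdentifierDefinition, default_catalog
from .model import AdmissionEpisode, CodeKind, Department, Setting

#: Exposure lookback horizon for the new-user antithrombotic rules ("not
#: used in the last 6 months" = 180 days).
LOOKBACK_DAYS = 180

FLAG_NAMES: tuple[str, ...] = (
    "af",
    "brain_ct",
    "brain_mri",
    "cta",
    "image_fu",
    "holter",
    "ivt",
    "evt",
    "cea",
    "carotid_angioplasty",
    "intracranial_angioplasty",
    "new_antithrombotics_3d",
    "new_antithrombotics_7d",
    "new_antithrombotics_90d_nrns_opd",
    "anticoagulants_7d",
    "rehab",
    "transfer_to_rehab",
)


@dataclasses.dataclass(frozen=True, slots=True)
class IdentifierVector:
    """The 17 boolean key-identifier flags for one episode."""

    af: bool = False
    brain_ct: bool = False
    brain_mri: bool = False
    cta: bool = False
    image_fu: bool = False
    holter: bool = False
    ivt: bool = False
    evt: bool = False
    cea: bool = False
    carotid_angioplasty: bool = False
    intracranial_angioplasty: bool = False
    new_antithrombotics_3d: bool = False
    new_antithrombotics_7d: bool = False
    new_antithrombotics_90d_nrns_opd: bool = False
    anticoagulants_7d: bool = False
    rehab: bool = False
    transfer_to_rehab: bool = False

    def as_dict(self) -> dict[str, bool]:
        return {name: getattr(self, name) for name in FLAG_NAMES}

    def as_tuple(self) -> tuple[bool, ...]:
        return tuple(getattr(self, name) for name in FLAG_NAMES)

    @classmethod
    def from_dict(cls, flags: dict) -> "IdentifierVector":
        unknown = set(flags) - set(FLAG_NAMES)
        if unknown:
            raise ValueError(f"unknown identifier flag(s): {sorted(unknown)}")
        return cls(**{k: bool(v) for k, v in flags.items()})


def _scope_allows(defn: IdentifierDefinition, setting: Setting) -> bool:
    if defn.scope == "in_hospital_only":
        return setting is Setting.IN_HOSPITAL
    return True


def evaluate_code_window(
    episode: AdmissionEpisode, definition: IdentifierDefinition
) -> bool:
    """Plain windowed code search (identifiers without special logic)."""
    if definition.special_logic != "none":
        raise ValueError(
            f"identifier {definition.name!r} uses special logic "
            f"{definition.special_logic!r}; not a plain code-window rule"
        )
    lo, hi = definition.window_days
    cs = definition.code_set
    for line in episode.episode_lines:
        if not _scope_allows(definition, line.setting):
            continue
        if definition.code_kind is not None and line.code_kind is not definition.code_kind:
            continue
        if (
            definition.department_filter is not None
            and line.department.value not in definition.department_filter
        ):
            continue
        if lo <= episode.day_offset(line) <= hi and cs.matches(line.code):
            return True
    return False


def evaluate_image_followup(
    episode: AdmissionEpisode, catalog: Catalog | None = None
) -> bool:
    """Re-imaging rule: >= 2 distinct (code, date) imaging events in [-7, +7]."""
    catalog = catalog or default_catalog()
    defn = catalog.identifiers["image_fu"]
    lo, hi = defn.window_days
    union = defn.code_set.codes
    ct_or_mri = catalog.code_set("brain_ct").codes | catalog.code_set("brain_mri").codes
    events: set[tuple[str, object]] = set()
    for line in episode.episode_lines:
        if line.code_kind is not CodeKind.PROCEDURE:
            continue
        if lo <= episode.day_offset(line) <= hi and line.code in union:
            events.add((line.code, line.service_date))
    return len(events) >= 2 and any(code in ct_or_mri for code, _ in events)


def _exposure_sets(
    episode: AdmissionEpisode,
    catalog: Catalog,
    window_hi: int,
    department_filter: frozenset[str] | None,
) -> tuple[set[str], set[str]]:
    """(lookback ingredient set L, window ingredient set W) for new-user logic."""
    anti = catalog.antithrombotic_ingredients
    lookback: set[str] = set()
    for line in episode.lookback_lines:
        if line.code_kind is not CodeKind.DRUG:
            continue
        off = episode.day_offset(line)
        if -LOOKBACK_DAYS <= off <= -1:
            ing = catalog.ingredient_of(line.code)
            if ing in anti:
                lookback.add(ing)
    window: set[str] = set()
    for line in episode.episode_lines:
        if line.code_kind is not CodeKind.DRUG:
            continue
        if (
            department_filter is not None
            and line.setting is Setting.OUTPATIENT
            and line.department.value not in department_filter
        ):
            continue
        if 0 <= episode.day_offset(line) <= window_hi:
            ing = catalog.ingredient_of(line.code)
            if ing in anti:
                window.add(ing)
    return lookback, window


def evaluate_new_antithrombotics(
    episode: AdmissionEpisode,
    window_hi: int,
    department_filter: frozenset[str] | None = None,
    catalog: Catalog | None = None,
) -> bool:
    """New-user rule: the post-index ingredient set is non-empty and differs
    from the 180-day pre-index exposure set (any symmetric difference; pure
    discontinuation does not count)."""
    catalog = catalog or default_catalog()
    lookback, window = _exposure_sets(episode, catalog, window_hi, department_filter)
    return bool(window) and window != lookback


def evaluate_anticoagulants(
    episode: AdmissionEpisode, catalog: Catalog | None = None
) -> bool:
    """Presence of any anticoagulant ingredient within [0, +7] (any setting)."""
    catalog = catalog or default_catalog()
    lo, hi = catalog.identifiers["anticoagulants_7d"].window_days
    for line in episode.episode_lines:
        if line.code_kind is not CodeKind.DRUG:
            continue
        if lo <= episode.day_offset(line) <= hi:
            if catalog.ingredient_of(line.code) in ANTICOAGULANT_INGREDIENTS:
                return True
    return False


def evaluate_transfer_to_rehab(episode: AdmissionEpisode) -> bool:
    """In-hospital lines from both neurology and rehabilitation in [0, +30]."""
    lo, hi = 0, 30
    seen_neuro = seen_rehab = False
    for line in episode.episode_lines:
        if line.setting is not Setting.IN_HOSPITAL:
            continue
        if not (lo <= episode.day_offset(line) <= hi):
            continue
        if line.department is Department.NEUROLOGY:
            seen_neuro = True
        elif line.department is Department.REHABILITATION:
            seen_rehab = True
        if seen_neuro and seen_rehab:
            return True
    return False


def extract_identifier_vector(
    episode: AdmissionEpisode, catalog: Catalog | None = None
) -> IdentifierVector:
    """Evaluate all 17 key identifiers for one episode (order-invariant)."""
    catalog = catalog or default_catalog()
    flags: dict[str, bool] = {}
    for name, defn in catalog.identifiers.items():
        if defn.special_logic == "none":
            flags[name] = evaluate_code_window(episode, defn)
        elif defn.special_logic == "image_followup":
            flags[name] = evaluate_image_followup(episode, catalog)
        elif defn.special_logic == "new_antithrombotics":
            flags[name] = evaluate_new_antithrombotics(
                episode, defn.window_days[1], defn.department_filter, catalog
            )
        elif defn.special_logic == "anticoagulants":
            flags[name] = evaluate_anticoagulants(episode, catalog)
        elif defn.special_logic == "transfer_to_rehab":
            flags[name] = evaluate_transfer_to_rehab(episode)
    return IdentifierVector.from_dict(flags)


def extract_flags_table(
    episodes: Iterable[AdmissionEpisode], catalog: Catalog | None = None
) -> pd.DataFrame:
    """One row per episode: episode_id, principal_dx, 17 flag columns (0/1)."""
    catalog = catalog or default_catalog()
    rows = []
    for ep in episodes:
        vec = extract_identifier_vector(ep, catalog)
        row = {"episode_id": ep.episode_id, "principal_dx": ep.principal_dx}
        row.update({name: int(v) for name, v in vec.as_dict().items()})
        rows.append(row)
    return pd.DataFrame(rows, columns=["episode_id", "principal_dx", *FLAG_NAMES])
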