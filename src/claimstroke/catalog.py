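"""Code catalog: KCD diagnosis, procedure and drug-product code sets.

The catalog houses the operational definition of each of the 17 key
identifiers — its code set, temporal window (day offsets from the index
date), data scope (in-hospital only vs in-hospital + outpatient clinic),
optional department filter, and special-evaluation logic — plus the
drug-product → ingredient map needed by the new-user antithrombotic rules.

The shipped catalog (version ``CRCS-K-2020``) is a JSON data file so that
code-list drift (e.g. newly listed drug products) is a data change, not a
code change.  Diagnosis code sets use prefix matching (claims carry 4–6
character KCD codes at mixed granularity); procedure and drug sets match
exactly.
"""

from __future__ import annotations

import dataclasses
import functools
import json
from importlib import resources
from typing import Mapping

from .model import CodeKind

#: Ingredients counted as anticoagulants (a strict subset of the
#: antithrombotic ingredients; the remainder are antiplatelets).
ANTICOAGULANT_INGREDIENTS = frozenset(
    {
        "warfarin",
        "rivaroxaban",
        "dabigatran",
        "apixaban",
        "edoxaban",
        "enoxaparin",
        "dalteparin",
        "nadroparin",
        "heparin",
    }
)

#: Thrombolytics are catalogued (IVT) but are not antithrombotic exposure.
THROMBOLYTIC_INGREDIENTS = frozenset({"alteplase"})

VALID_INGREDIENTS = ANTICOAGULANT_INGREDIENTS | THROMBOLYTIC_INGREDIENTS | {
    "aspirin",
    "clopidogrel",
    "cilostazol",
    "triflusal",
    "ticlopidine",
}

SPECIAL_LOGICS = (
    "none",
    "image_followup",
    "new_antithrombotics",
    "anticoagulants",
    "transfer_to_rehab",
)

SCOPES = ("in_hospital_only", "in_hospital_and_outpatient")


@dataclasses.dataclass(frozen=True)
class CodeSet:
    """A named set of claims codes with its matching mode."""

    name: str
    codes: frozenset[str]
    match_mode: str  # "exact" | "prefix"

    def __post_init__(self):
        if self.match_mode not in ("exact", "prefix"):
            raise ValueError(f"unknown match_mode {self.match_mode!r}")
        object.__setattr__(self, "_prefixes", tuple(sorted(self.codes)))

    def matches(self, code: str) -> bool:
        if self.match_mode == "exact":
            return code in self.codes
        return code.startswith(self._prefixes) if self.codes else False


@dataclasses.dataclass(frozen=True)
class IdentifierDefinition:
    """Operational definition of one key identifier."""

    name: str
    window_days: tuple[int, int]
    scope: str
    code_kind: CodeKind | None
    special_logic: str = "none"
    department_filter: frozenset[str] | None = None
    code_set: CodeSet | None = None

    def __post_init__(self):
        lo, hi = self.window_days
        if lo > hi:
            raise ValueError(f"{self.name}: window lo {lo} > hi {hi}")
        if self.scope not in SCOPES:
            raise ValueError(f"{self.name}: unknown scope {self.scope!r}")
        if self.special_logic not in SPECIAL_LOGICS:
            raise ValueError(f"{self.name}: unknown special_logic {self.special_logic!r}")
        if self.special_logic != "transfer_to_rehab" and (
            self.code_set is None or not self.code_set.codes
        ):
            raise ValueError(f"{self.name}: empty code set")


class Catalog:
    """The identifier registry plus the drug-product → ingredient map."""

    def __init__(
        self,
        version: str,
        identifiers: Mapping[str, IdentifierDefinition],
        ingredient_map: Mapping[str, str],
    ):
        self.version = version
        self.identifiers: dict[str, IdentifierDefinition] = dict(identifiers)
        self.ingredient_map: dict[str, str] = dict(ingredient_map)
        bad = sorted(set(self.ingredient_map.values()) - VALID_INGREDIENTS)
        if bad:
            raise ValueError(f"unknown ingredient(s) in map: {bad}")

    # -- lookups ---------------------------------------------------------

    def code_set(self, name: str) -> CodeSet:
        try:
            cs = self.identifiers[name].code_set
        except KeyError:
            raise KeyError(f"unknown identifier {name!r}") from None
        if cs is None:
            raise KeyError(f"identifier {name!r} has no code set")
        return cs

    def ingredient_of(self, code: str) -> str | None:
        """Ingredient of a catalogued drug product code, else ``None``."""
        return self.ingredient_map.get(code)

    @functools.cached_property
    def antithrombotic_ingredients(self) -> frozenset[str]:
        """Ingredients counted as antithrombotic exposure (no thrombolytics)."""
        return frozenset(self.ingredient_map.values()) - THROMBOLYTIC_INGREDIENTS

    @functools.cached_property
    def antithrombotic_codes(self) -> frozenset[str]:
        return frozenset(
            c for c, ing in self.ingredient_map.items()
            if ing in self.antithrombotic_ingredients
        )

    @functools.cached_property
    def anticoagulant_codes(self) -> frozenset[str]:
        return frozenset(
            c for c, ing in self.ingredient_map.items()
            if ing in ANTICOAGULANT_INGREDIENTS
        )

    # -- (de)serialization ----------------------------------------------

    def to_dict(self) -> dict:
        out: dict = {"version": self.version, "identifiers": {}, "ingredient_map": dict(sorted(self.ingredient_map.items()))}
        for name, d in self.identifiers.items():
            out["identifiers"][name] = {
                "codes": sorted(d.code_set.codes) if d.code_set else [],
                "match_mode": d.code_set.match_mode if d.code_set else "exact",
                "window_days": list(d.window_days),
                "scope": d.scope,
                "code_kind": d.code_kind.value if d.code_kind else None,
                "special_logic": d.special_logic,
                "department_filter": sorted(d.department_filter) if d.department_filter else None,
            }
        return out

    @classmethod
    def from_dict(cls, data: Mapping) -> "Catalog":
        identifiers = {}
        for name, spec in data["identifiers"].items():
            code_set = None
            if spec["codes"] or spec["special_logic"] != "transfer_to_rehab":
                code_set = CodeSet(
                    name=name,
                    codes=frozenset(spec["codes"]),
                    match_mode=spec["match_mode"],
                )
            identifiers[name] = IdentifierDefinition(
                name=name,
                window_days=tuple(spec["window_days"]),
                scope=spec["scope"],
                code_kind=CodeKind(spec["code_kind"]) if spec["code_kind"] else None,
                special_logic=spec["special_logic"],
                department_filter=(
                    frozenset(spec["department_filter"])
                    if spec.get("department_filter")
                    else None
                ),
                code_set=code_set,
            )
        return cls(
            version=data["version"],
            identifiers=identifiers,
            ingredient_map=data["ingredient_map"],
        )

    def dump(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=False)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "Catalog":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@functools.lru_cache(maxsize=1)
def default_catalog() -> Catalog:
    """Load the shipped ``CRCS-K-2020`` catalog (treat as read-only)."""
    ref = resources.files("claimstroke").joinpath("data/catalog_crcsk2020.json")
    return Catalog.from_dict(json.loads(ref.read_text(encoding="utf-8")))


def ingredient_of(code: str) -> str | None:
    """Ingredient of a drug product code under the default catalog."""
    return default_catalog().ingredient_of(code)
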