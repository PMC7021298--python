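"""Synthetic claims + registry cohort generator.

The generator emulates an admission-episode cohort with the statistical
structure the identification algorithm assumes: ~32% of episodes are true
AIS (registry-linkable); principal diagnoses follow the published admission
mix (about one third cerebral infarction, the rest haemorrhages, TIA and
non-cerebrovascular codes carrying a secondary stroke code); and each key
identifier fires with a label-conditional probability chosen inside the
published sensitivity/specificity envelopes (imaging sensitive but
unspecific, reperfusion/intervention rare but highly specific, new
antithrombotics ≈70%/70%).

Generation is two-stage.  :func:`generate_blueprints` draws, per episode, a
truth label, a principal diagnosis and an *intended* 17-flag identifier
vector (flags conditionally independent given the label, with structural
implications enforced by drawing implied parents first).
:func:`materialize_claims` then turns each blueprint into concrete claim
lines whose codes, settings, departments and day offsets satisfy exactly
the intended identifiers and no others — the round-trip guarantee that the
extractor recovers the intended vector for every episode.  Materialization
handles the subtle negative cases: e.g. an anticoagulant that must be
present without being "new" is also planted in the 180-day lookback so the
novelty rule fails, and a 3-day antithrombotic change that must not fire
the 90-day outpatient identifier is issued from a non-neurology outpatient
clinic.
"""

from __future__ import annotations

import dataclasses
import datetime
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import Catalog, default_catalog
from .identifiers import FLAG_NAMES, IdentifierVector
from .model import RegistryRecord

BASE_DATE = datetime.date(2011, 1, 1)
STUDY_PERIOD_DAYS = 1095  # admissions spread over 2011-2013

#: Default label-conditional flag probabilities (P(flag | AIS), P(flag | not AIS)).
#: Chosen inside the published envelopes: imaging sensitivity 32-91% with
#: specificity 25-79% (MRI more sensitive and specific than CT); reperfusion
#: and intervention sensitivity < 10% with specificity > 98%; new
#: antithrombotics ~ 70%/70% (highest for the 90-day outpatient variant);
#: transfer-to-rehab more specific but less sensitive than rehab.  Every
#: identifier's implied overall frequency lies in [0.4%, 80%].
DEFAULT_FLAG_MODEL: dict[str, tuple[float, float]] = {
    "af": (0.20, 0.12),
    "brain_ct": (0.65, 0.70),
    "brain_mri": (0.91, 0.25),
    "cta": (0.32, 0.21),
    "image_fu": (0.60, 0.40),
    "holter": (0.30, 0.15),
    "ivt": (0.07, 0.005),
    "evt": (0.03, 0.003),
    "cea": (0.009, 0.002),
    "carotid_angioplasty": (0.012, 0.002),
    "intracranial_angioplasty": (0.012, 0.002),
    "new_antithrombotics_3d": (0.70, 0.30),
    "new_antithrombotics_7d": (0.75, 0.33),
    "new_antithrombotics_90d_nrns_opd": (0.76, 0.22),
    "anticoagulants_7d": (0.25, 0.10),
    "rehab": (0.35, 0.20),
    "transfer_to_rehab": (0.15, 0.04),
}

#: Marginal principal-diagnosis mix (published admission proportions; the
#: residual mass is non-cerebrovascular principal codes — neoplasms, other
#: nervous/circulatory disease — whose episodes carry the stroke code as an
#: additional diagnosis).
DEFAULT_DX_MIX: dict[str, float] = {
    "I63": 0.333,
    "I60": 0.057,
    "I61": 0.061,
    "I62": 0.020,
    "I64": 0.030,
    "TIA": 0.015,
    "other": 0.484,
}

#: Principal-diagnosis mix among true AIS episodes (I63-enriched); the
#: non-AIS conditional mix is derived so the marginal matches DEFAULT_DX_MIX
#: at the default prevalence.
DEFAULT_DX_GIVEN_AIS: dict[str, float] = {
    "I63": 0.80,
    "I60": 0.01,
    "I61": 0.01,
    "I62": 0.01,
    "I64": 0.05,
    "TIA": 0.02,
    "other": 0.10,
}

#: A representative claims code per principal-diagnosis category.
DX_CATEGORY_CODES: dict[str, str] = {
    "I63": "I639",
    "I60": "I609",
    "I61": "I619",
    "I62": "I629",
    "I64": "I64",
    "TIA": "G459",
    "other": "C349",
}


@dataclasses.dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_episodes: int = 1000
    prevalence: float = 0.317
    principal_dx_mix: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_DX_MIX)
    )
    dx_mix_given_ais: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_DX_GIVEN_AIS)
    )
    flag_model: Mapping[str, tuple[float, float]] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_FLAG_MODEL)
    )
    age_mean: float = 65.6
    age_sd: float = 15.6
    male_fraction: float = 0.54
    #: probability a true-AIS episode appears in the registry (consent-like
    #: subsampling knob; 1.0 keeps every true episode linkable)
    registry_consent_rate: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_episodes < 0:
            raise ValueError("n_episodes must be non-negative")
        for name, p in [
            ("prevalence", self.prevalence),
            ("male_fraction", self.male_fraction),
            ("registry_consent_rate", self.registry_consent_rate),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for mix_name, mix in [
            ("principal_dx_mix", self.principal_dx_mix),
            ("dx_mix_given_ais", self.dx_mix_given_ais),
        ]:
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{mix_name} must sum to 1")
            if any(p < 0 for p in mix.values()):
                raise ValueError(f"{mix_name} has negative probabilities")
        missing = set(FLAG_NAMES) - set(self.flag_model)
        if missing:
            raise ValueError(f"flag_model missing identifiers: {sorted(missing)}")
        for name, (p1, p0) in self.flag_model.items():
            if not (0.0 <= p1 <= 1.0 and 0.0 <= p0 <= 1.0):
                raise ValueError(f"flag_model[{name!r}] out of [0, 1]")
        for pair in zip(
            self.flag_model["new_antithrombotics_3d"],
            self.flag_model["new_antithrombotics_7d"],
        ):
            if pair[0] > pair[1]:
                raise ValueError("P(new antithrombotics <=3d) must not exceed <=7d")
        for pair in zip(self.flag_model["cta"], self.flag_model["brain_ct"]):
            if pair[0] > pair[1]:
                raise ValueError("P(cta) must not exceed P(brain_ct)")

    def dx_mix_given_not_ais(self) -> dict[str, float]:
        """Non-AIS conditional dx mix implied by the marginal mix."""
        if self.prevalence >= 1.0:
            return dict(self.dx_mix_given_ais)
        out = {}
        for cat, marginal in self.principal_dx_mix.items():
            p_ais = self.dx_mix_given_ais.get(cat, 0.0)
            p = (marginal - self.prevalence * p_ais) / (1.0 - self.prevalence)
            if p < -1e-9:
                raise ValueError(
                    f"dx mix infeasible for category {cat!r}: "
                    f"marginal {marginal} < prevalence * P({cat}|AIS)"
                )
            out[cat] = max(p, 0.0)
        total = sum(out.values())
        return {k: v / total for k, v in out.items()}


@dataclasses.dataclass
class EpisodeBlueprint:
    """The generator's latent design record for one episode."""

    episode_id: str
    patient_id: str
    true_ais: bool
    dx_category: str
    principal_dx: str
    intended_flags: IdentifierVector
    age: float
    sex: str
    index_date: datetime.date


def _bern(rng: np.random.Generator, p: float) -> bool:
    return bool(rng.random() < p)


def _draw_flags(rng: np.random.Generator, model: Mapping, ais: bool) -> IdentifierVector:
    idx = 0 if ais else 1

    def p(name: str) -> float:
        return model[name][idx]

    flags: dict[str, bool] = {}
    # implied parents first: cta -> brain_ct, 3d -> 7d; residual probabilities
    # keep the marginals exact.
    cta = _bern(rng, p("cta"))
    p_ct, p_cta = p("brain_ct"), p("cta")
    residual_ct = 0.0 if p_cta >= 1.0 else (p_ct - p_cta) / (1.0 - p_cta)
    flags["cta"] = cta
    flags["brain_ct"] = cta or _bern(rng, residual_ct)
    flags["brain_mri"] = _bern(rng, p("brain_mri"))
    n3 = _bern(rng, p("new_antithrombotics_3d"))
    p3, p7 = p("new_antithrombotics_3d"), p("new_antithrombotics_7d")
    residual_n7 = 0.0 if p3 >= 1.0 else (p7 - p3) / (1.0 - p3)
    flags["new_antithrombotics_3d"] = n3
    flags["new_antithrombotics_7d"] = n3 or _bern(rng, residual_n7)
    for name in (
        "af",
        "holter",
        "ivt",
        "evt",
        "cea",
        "carotid_angioplasty",
        "intracranial_angioplasty",
        "new_antithrombotics_90d_nrns_opd",
        "anticoagulants_7d",
        "rehab",
        "transfer_to_rehab",
    ):
        flags[name] = _bern(rng, p(name))
    # a CT-code event and an MRI-code event inside [-7,+2] are always two
    # distinct imaging events inside [-7,+7], so image follow-up is forced.
    forced_fu = flags["brain_ct"] and flags["brain_mri"]
    flags["image_fu"] = forced_fu or _bern(rng, p("image_fu"))
    return IdentifierVector.from_dict(flags)


def generate_blueprints(
    config: GeneratorConfig,
) -> tuple[list[EpisodeBlueprint], list[RegistryRecord]]:
    """Draw episode blueprints and the matching registry records."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    dx_given_not = config.dx_mix_given_not_ais()
    categories = list(config.principal_dx_mix)
    p_ais_arr = np.array([config.dx_mix_given_ais.get(c, 0.0) for c in categories])
    p_not_arr = np.array([dx_given_not[c] for c in categories])
    p_ais_arr = p_ais_arr / p_ais_arr.sum() if p_ais_arr.sum() else p_ais_arr
    blueprints: list[EpisodeBlueprint] = []
    registry: list[RegistryRecord] = []
    for i in range(config.n_episodes):
        eid = f"E{i:07d}"
        ais = _bern(rng, config.prevalence)
        probs = p_ais_arr if ais else p_not_arr
        cat = categories[int(rng.choice(len(categories), p=probs))]
        flags = _draw_flags(rng, config.flag_model, ais)
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 18.0, 105.0))
        sex = "M" if _bern(rng, config.male_fraction) else "F"
        index_date = BASE_DATE + datetime.timedelta(
            days=int(rng.integers(0, STUDY_PERIOD_DAYS))
        )
        blueprints.append(
            EpisodeBlueprint(
                episode_id=eid,
                patient_id=f"P{i:07d}",
                true_ais=ais,
                dx_category=cat,
                principal_dx=DX_CATEGORY_CODES[cat],
                intended_flags=flags,
                age=round(age, 1),
                sex=sex,
                index_date=index_date,
            )
        )
        if ais and _bern(rng, config.registry_consent_rate):
            registry.append(RegistryRecord(episode_id=eid, true_ais=True))
    return blueprints, registry


# ---------------------------------------------------------------------------
# materialization


class InfeasibleBlueprintError(ValueError):
    """The intended flag combination cannot be realized as claim lines."""


_CT_NOT_CTA = ("HA451", "HA441", "HA461", "HA851")
_AF_CODES = ("I480", "I481", "I482", "I489")
_NOVEL_ANTIPLATELET = "136901ATB"  # clopidogrel
_NOVEL_ANTICOAGULANT = "249103ATB"  # warfarin
_MASKED_ANTICOAGULANT = "168601BIJ"  # heparin (also planted in lookback)


class _EpisodeWriter:
    """Accumulates claim-line rows for one episode."""

    def __init__(self, bp: EpisodeBlueprint, rng: np.random.Generator):
        self.bp = bp
        self.rng = rng
        self.rows: list[dict] = []
        self._outpatient_seq = 0

    def add(
        self,
        code: str,
        code_kind: str,
        off: int,
        *,
        setting: str = "in_hospital",
        department: str = "other",
        dx_position: str = "none",
    ) -> None:
        service_date = self.bp.index_date + datetime.timedelta(days=int(off))
        if setting == "in_hospital":
            claim_id = self.bp.episode_id
            claim_start = self.bp.index_date
        else:
            self._outpatient_seq += 1
            claim_id = f"{self.bp.episode_id}.o{self._outpatient_seq}"
            claim_start = service_date
        self.rows.append(
            {
                "patient_id": self.bp.patient_id,
                "claim_id": claim_id,
                "setting": setting,
                "department": department,
                "code": code,
                "code_kind": code_kind,
                "dx_position": dx_position,
                "service_date": service_date.isoformat(),
                "claim_start_date": claim_start.isoformat(),
            }
        )

    def offset(self, lo: int, hi: int) -> int:
        return int(self.rng.integers(lo, hi + 1))

    def choice(self, options: Sequence[str]) -> str:
        return options[int(self.rng.integers(0, len(options)))]

    def filler_code(self) -> str:
        # reserved non-catalog namespace; cannot collide with any code set
        return f"ZZ{int(self.rng.integers(0, 10000)):04d}"


def _materialize_imaging(w: _EpisodeWriter, f: IdentifierVector) -> None:
    events: set[tuple[str, int]] = set()
    if f.cta and not f.brain_ct:
        raise InfeasibleBlueprintError(
            f"{w.bp.episode_id}: cta without brain_ct (CTA code is a CT code)"
        )
    if f.brain_ct and f.brain_mri and not f.image_fu:
        raise InfeasibleBlueprintError(
            f"{w.bp.episode_id}: brain_ct and brain_mri force image_fu"
        )
    if f.cta:
        off = w.offset(-7, 2)
        w.add("HA471", "procedure", off)
        events.add(("HA471", off))
    elif f.brain_ct:
        code = w.choice(_CT_NOT_CTA)
        off = w.offset(-7, 2)
        w.add(code, "procedure", off)
        events.add((code, off))
    if f.brain_mri:
        code = w.choice(tuple(sorted(_MRI_CODES)))
        off = w.offset(-7, 2)
        w.add(code, "procedure", off)
        events.add((code, off))
    if f.image_fu:
        # extra re-imaging events at offsets +3..+7: inside the follow-up
        # window but outside the CT/MRI windows, so modality flags are safe
        pool = tuple(sorted(_ALL_IMAGING_CODES))
        while len(events) < 2:
            cand = (w.choice(pool), w.offset(3, 7))
            if cand in events:
                continue
            w.add(cand[0], "procedure", cand[1])
            events.add(cand)


def _materialize_medication(w: _EpisodeWriter, f: IdentifierVector) -> None:
    n3 = f.new_antithrombotics_3d
    n7 = f.new_antithrombotics_7d
    n90 = f.new_antithrombotics_90d_nrns_opd
    ac = f.anticoagulants_7d
    if n3 and not n7:
        raise InfeasibleBlueprintError(
            f"{w.bp.episode_id}: new antithrombotics <=3d without <=7d"
        )
    if n7:
        off = w.offset(0, 3) if n3 else w.offset(4, 7)
        code = _NOVEL_ANTICOAGULANT if ac else _NOVEL_ANTIPLATELET
        if n90:
            w.add(code, "drug", off)  # in-hospital: counts in every window
        else:
            # non-neurology outpatient clinic: counts for 3/7-day windows
            # (no department restriction) but is excluded from the 90-day
            # neurology/neurosurgery-outpatient identifier
            w.add(code, "drug", off, setting="outpatient", department="other")
    elif n90:
        dept = w.choice(("neurology", "neurosurgery"))
        w.add(
            _NOVEL_ANTIPLATELET,
            "drug",
            w.offset(8, 90),
            setting="outpatient",
            department=dept,
        )
        if ac:
            _masked_anticoagulant(w)
    else:
        if ac:
            _masked_anticoagulant(w)


def _masked_anticoagulant(w: _EpisodeWriter) -> None:
    """Anticoagulant present in [0,+7] but not 'new': also in the lookback."""
    w.add(_MASKED_ANTICOAGULANT, "drug", w.offset(0, 7))
    w.add(
        _MASKED_ANTICOAGULANT,
        "drug",
        -int(w.rng.integers(20, 171)),
        setting="outpatient",
        department="other",
    )


def materialize_episode(
    bp: EpisodeBlueprint, rng: np.random.Generator, catalog: Catalog | None = None
) -> list[dict]:
    """Emit claim-line rows realizing exactly the blueprint's intended flags."""
    f = bp.intended_flags
    w = _EpisodeWriter(bp, rng)
    # index in-hospital claim: principal diagnosis (+ the qualifying stroke
    # code as an additional diagnosis when the principal is not I60-I64)
    w.add(bp.principal_dx, "diagnosis", 0, dx_position="principal")
    if not bp.principal_dx.startswith(("I60", "I61", "I62", "I63", "I64")):
        w.add("I639", "diagnosis", 0, dx_position="additional")
    if f.af:
        w.add(w.choice(_AF_CODES), "diagnosis", w.offset(0, 30), dx_position="additional")
    _materialize_imaging(w, f)
    if f.holter:
        w.add("E6545", "procedure", w.offset(0, 30))
    if f.ivt:
        w.add(w.choice(("223501BIJ", "223502BIJ")), "drug", w.offset(0, 2))
    if f.evt:
        w.add(w.choice(tuple(sorted(_EVT_CODES))), "procedure", w.offset(0, 2))
    if f.cea:
        w.add(w.choice(("O0226", "O0227", "O2066")), "procedure", w.offset(0, 30))
    if f.carotid_angioplasty:
        w.add(w.choice(("M6594", "M6602")), "procedure", w.offset(0, 30))
    if f.intracranial_angioplasty:
        w.add(
            w.choice(("M6593", "M6597", "M6599", "M6601", "M6605")),
            "procedure",
            w.offset(0, 30),
        )
    _materialize_medication(w, f)
    if f.rehab:
        w.add(
            w.choice(tuple(sorted(_REHAB_CODES))),
            "procedure",
            w.offset(0, 30),
            department="rehabilitation",
        )
    if f.transfer_to_rehab:
        w.add(w.filler_code(), "procedure", w.offset(0, 30), department="neurology")
        w.add(w.filler_code(), "procedure", w.offset(0, 30), department="rehabilitation")
    # non-informative filler lines (exercise order/irrelevance invariance)
    for _ in range(int(rng.integers(1, 4))):
        w.add(w.filler_code(), "procedure", w.offset(-7, 90))
    w.add(
        w.filler_code(),
        "procedure",
        -int(rng.integers(190, 400)),
        setting="outpatient",
    )
    return w.rows


_cat = default_catalog()
_MRI_CODES = _cat.code_set("brain_mri").codes
_EVT_CODES = _cat.code_set("evt").codes
_REHAB_CODES = _cat.code_set("rehab").codes
_ALL_IMAGING_CODES = _cat.code_set("image_fu").codes
del _cat


def materialize_claims(
    blueprints: Iterable[EpisodeBlueprint],
    config: GeneratorConfig,
    catalog: Catalog | None = None,
) -> pd.DataFrame:
    """Materialize blueprints into a claims table (documented CSV schema)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    rows: list[dict] = []
    for bp in blueprints:
        rows.extend(materialize_episode(bp, rng, catalog))
    columns = [
        "patient_id",
        "claim_id",
        "setting",
        "department",
        "code",
        "code_kind",
        "dx_position",
        "service_date",
        "claim_start_date",
    ]
    return pd.DataFrame(rows, columns=columns)


@dataclasses.dataclass
class SyntheticCohort:
    """Claims + registry tables with the generator's truth-audit table."""

    claims: pd.DataFrame
    registry: pd.DataFrame
    audit: pd.DataFrame
    blueprints: list[EpisodeBlueprint]


def _audit_frame(blueprints: Sequence[EpisodeBlueprint]) -> pd.DataFrame:
    rows = []
    for bp in blueprints:
        row = {
            "episode_id": bp.episode_id,
            "patient_id": bp.patient_id,
            "true_ais": int(bp.true_ais),
            "dx_category": bp.dx_category,
            "principal_dx": bp.principal_dx,
            "age": bp.age,
            "sex": bp.sex,
            "index_date": bp.index_date.isoformat(),
        }
        row.update({k: int(v) for k, v in bp.intended_flags.as_dict().items()})
        rows.append(row)
    return pd.DataFrame(rows)


def generate_validation_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """One-call fixture: blueprints drawn and materialized, with audit table."""
    blueprints, registry = generate_blueprints(config)
    claims = materialize_claims(blueprints, config)
    registry_df = pd.DataFrame(
        [{"episode_id": r.episode_id, "true_ais": int(r.true_ais)} for r in registry],
        columns=["episode_id", "true_ais"],
    )
    return SyntheticCohort(
        claims=claims,
        registry=registry_df,
        audit=_audit_frame(blueprints),
        blueprints=blueprints,
    )


def design_performance_cohort(
    n_episodes: int,
    sensitivity: float = 0.80,
    specificity: float = 0.82,
    prevalence: float = 0.317,
    seed: int = 0,
) -> SyntheticCohort:
    """Cohort whose per-episode *call* behaviour is designed, not emergent.

    Each episode's intended algorithm call is drawn directly —
    P(AIS call | true AIS) = ``sensitivity``, P(AIS call | not AIS) =
    1 - ``specificity`` — and realized through flags that deterministically
    route the decision tree (an IVT line forces an AIS leaf in every branch;
    an all-false vector falls through to a non-AIS leaf).  Running the full
    pipeline on the materialized claims must therefore recover the designed
    sensitivity/specificity up to binomial sampling error.
    """
    config = GeneratorConfig(n_episodes=n_episodes, prevalence=prevalence, seed=seed)
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    dx_given_not = config.dx_mix_given_not_ais()
    categories = list(config.principal_dx_mix)
    p_ais_arr = np.array([config.dx_mix_given_ais.get(c, 0.0) for c in categories])
    p_ais_arr = p_ais_arr / p_ais_arr.sum()
    p_not_arr = np.array([dx_given_not[c] for c in categories])
    blueprints: list[EpisodeBlueprint] = []
    registry: list[RegistryRecord] = []
    intended_calls: list[int] = []
    for i in range(n_episodes):
        eid = f"E{i:07d}"
        ais = _bern(rng, prevalence)
        call = _bern(rng, sensitivity) if ais else _bern(rng, 1.0 - specificity)
        probs = p_ais_arr if ais else p_not_arr
        cat = categories[int(rng.choice(len(categories), p=probs))]
        flags = IdentifierVector(ivt=True) if call else IdentifierVector()
        blueprints.append(
            EpisodeBlueprint(
                episode_id=eid,
                patient_id=f"P{i:07d}",
                true_ais=ais,
                dx_category=cat,
                principal_dx=DX_CATEGORY_CODES[cat],
                intended_flags=flags,
                age=round(float(np.clip(rng.normal(config.age_mean, config.age_sd), 18, 105)), 1),
                sex="M" if _bern(rng, config.male_fraction) else "F",
                index_date=BASE_DATE + datetime.timedelta(days=int(rng.integers(0, STUDY_PERIOD_DAYS))),
            )
        )
        intended_calls.append(int(call))
        if ais:
            registry.append(RegistryRecord(episode_id=eid, true_ais=True))
    claims = materialize_claims(blueprints, config)
    registry_df = pd.DataFrame(
        [{"episode_id": r.episode_id, "true_ais": int(r.true_ais)} for r in registry],
        columns=["episode_id", "true_ais"],
    )
    audit = _audit_frame(blueprints)
    audit["intended_call_ais"] = intended_calls
    return SyntheticCohort(
        claims=claims, registry=registry_df, audit=audit, blueprints=blueprints
    )
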