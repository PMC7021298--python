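# Methods

## Unit of analysis and episode reconstruction

The analysis unit is the **admission episode**: one in-hospital claim
carrying a cerebrovascular diagnosis (any code with prefix I60–I64, as
principal *or* additional diagnosis). The episode's index date is the
claim's start date; its id is the claim id (the claim-serial-number
analogue used for registry linkage). The principal diagnosis of the
episode is whatever code sits in the claim's principal position — it need
not be a stroke code (about two-thirds of admissions carry the stroke code
only as an additional diagnosis: neoplasms, other nervous/circulatory
disease, TIA).

Claims data do not say which surrounding lines "belong" to an admission,
so an attribution rule is needed: every line of the same patient whose
service date falls in **[−7, +90] days** of the index date is attributed
to the episode. This is the union of all identifier windows (imaging
reaches back 7 days; the 90-day outpatient antithrombotic identifier
reaches forward 90), so episodes are self-contained for identifier
evaluation; each identifier then applies its own narrower window. Lines
strictly before the index date form the lookback history (washout,
180-day drug exposure).

**Washout.** Patients with any I60–I64 diagnosis before their first
qualifying admission are excluded entirely — the cohort is incident
strokes. The washout horizon is unlimited by default (configurable in
days for data with truncated history) and is anchored on each patient's
*earliest* episode, so that readmissions of a washout-surviving patient
are retained even though their lookback necessarily contains the first
admission's codes. This also makes the operation idempotent.

**Linkage.** An episode is a true AIS iff a registry record with its
episode id exists; absence of linkage is a negative label. Registry
records without claims data are dropped and tallied.

## Key identifiers

Each identifier is (code set, window [lo, hi] in days from the index
date, scope, optional department filter). Windows are **closed
intervals** (the published "0 days ~ +30 days" notation naturally
includes both endpoints). Diagnosis code sets match by **prefix** (claims
carry 4–6-character KCD codes below the listed stems, e.g. I4891 under
I48); procedure and drug sets match exactly. Day offsets use each line's
own service date, for outpatient lines included.

Special rules:

* **Image follow-up**: ≥ 2 distinct imaging *events* — (code, service
  date) pairs over the CT ∪ MRI ∪ CTA union — in [−7, +7], at least one
  being a CT/MRI code. Two modalities on one date are two events; the
  same code on two dates is two events; duplicate lines on one date are
  one.
* **New antithrombotics** (3-, 7-, 90-day variants): let L be the set of
  antithrombotic *ingredients* dispensed in the 180 days before the index
  date ("last 6 months" = 180 days) and W the set dispensed in
  [0, window]. The flag fires iff W ≠ ∅ and W ≠ L — first-ever use, an
  added ingredient, or any composition change; pure discontinuation does
  not fire. Thrombolytics (alteplase) are not antithrombotic exposure.
  The 90-day variant restricts **outpatient** lines to
  neurology/neurosurgery clinics; in-hospital lines in [0, 90] count
  without department restriction, and the novelty condition applies to
  all three variants. Note the department restriction breaks
  monotonicity: the 3-day flag implies the 7-day flag, but not the
  90-day one.
* **Anticoagulants**: presence (not novelty) of any anticoagulant
  ingredient in [0, +7].
* **Transfer to rehab**: in-hospital lines from both the neurology and
  the rehabilitation department in [0, +30], regardless of code.

One catalogue quirk: three product codes (517900ACE/ATE/ACH) are
aspirin–clopidogrel combination products listed under both ingredients in
the original code tables; the ingredient map requires a unique assignment and
carries them as aspirin. The shipped catalog is a versioned JSON file
(`CRCS-K-2020`), so code-list updates are data changes.

## Decision tree

The shipped ruleset reconstructs the published cascade. Root split:
principal diagnosis I63 or not; within I63, brain CT done or not.

* **I63+, CT+ (branch A)**: IVT → EVT → (CEA ∨ carotid ∨ intracranial
  angioplasty) ∧ new-antithrombotics-3d → 3d ∧ MRI → 3d ∧ CTA → the
  follow-up cascade.
* **I63+, CT− (branch B)**: as A but without the CTA step (CTA implies a
  CT code under the shipped catalog).
* **I63− (branch C)**: (IVT ∨ EVT) → 3d ∧ transfer-to-rehab (replacing
  the clinically irrelevant intervention step) → 3d ∧ MRI → 3d ∧ CTA →
  the follow-up cascade.

The follow-up cascade (entered when MRI was done without a 3-day
medication change) tests image follow-up; if positive: 7-day change →
Holter → AF (→ anticoagulants → 90-day change → *AIS by hemorrhagic
transformation* when AF is positive but no antithrombotic was ever
given) → 90-day change → non-AIS; if negative: the same AF block but
ending in non-AIS. Episodes without MRI at that point are non-AIS.

Interventions are deliberately conjunctive with the 3-day medication
change — endarterectomy and stenting are also performed electively, so
alone they do not indicate an acute event.

This reconstruction yields **52 trajectories** (40 AIS leaves); the
original description of the cascade counts 57, from a figure whose full
topology is not publicly recoverable, so the count is reported and frozen
as a conformance snapshot rather than asserted. The plain `rehab` identifier
is catalogued and extracted but unused by the shipped tree (only the
transfer-to-rehab combination appears in the published cascade); it
remains available to amended rulesets, which are plain JSON documents
validated for unknown flags, cycles, unreachable nodes and duplicate
trajectory ids.

The dataset classifier additionally returns a flow audit — per-edge case
counts and %-true-AIS — with a conservation check (inflow = outflow at
every node).

## Validation metrics

Episodes are split into development and validation sets by sorting on a
keyed blake2b hash of the episode id; the development set takes
floor(ratio·N) episodes (0.7 · 40,443 → 28,310 / 12,133). The original
validation design fixes the 7:3 ratio but no mechanism or seed; the keyed
hash makes the
split deterministic, order-invariant and reproducible from
(episode id, seed) alone. Sensitivity, specificity, accuracy, PPV and
NPV are computed as exact ratios; zero-denominator ratios are NaN, never
0. Percentages (one decimal) exist only at the reporting layer.

## Synthetic cohort generator

The generator emulates the study conditions: prevalence 0.317 of
registry-linkable AIS; principal-diagnosis mix with I63 ≈ 1/3 marginally
and strongly enriched among AIS (P(I63|AIS) = 0.80, non-AIS conditional
mix derived so the marginal matches); demographics age ~ N(65.6, 15.6²)
years, 54% male; and per-identifier label-conditional probabilities
(P(flag|AIS), P(flag|¬AIS)) chosen inside the published envelopes —
imaging sensitive but unspecific (MRI 0.91/0.75 sens/spec, CT 0.65/0.30),
reperfusion and interventions rare but highly specific (< 10% / > 98%),
new antithrombotics ≈ 0.70/0.70 with the 90-day outpatient variant best,
transfer-to-rehab more specific but less sensitive than rehab. Exact
per-identifier frequencies were never published; the defaults are
envelope-constrained, every implied overall frequency lying in the
published [0.4%, 80%] range, and are tunable via `GeneratorConfig`.

Flags are drawn conditionally independent given the label, except for
three structural implications enforced by drawing implied parents first
with residual probabilities that keep the marginals exact:
CTA ⇒ brain CT (the CTA code *is* a CT code); 3-day ⇒ 7-day
antithrombotic change; and brain CT ∧ MRI ⇒ image follow-up (a CT event
and an MRI event inside [−7, +2] are always two distinct events inside
[−7, +7]). The third implication means the I63+/CT+ follow-up-negative
sub-branch of the tree is reachable by abstract flag vectors but not by
any materializable episode — the test suite asserts exactly this
partition.

Materialization turns intended flags into claim lines that satisfy
exactly those identifiers: codes sampled uniformly from each set, offsets
uniformly from each window, with the discriminating cases handled
explicitly — an anticoagulant that must be present but not "new" is also
planted in the lookback; an early antithrombotic change that must not
fire the 90-day identifier is issued from a non-neurology outpatient
clinic; re-imaging events for modality-negative follow-up land at
offsets +3..+7 (inside the follow-up window, outside the CT/MRI
windows). Filler lines use a reserved ZZ-prefixed code namespace that
cannot collide with the catalog. Identical seeds produce byte-identical
tables.

**What the generator does not emulate**: correlations among identifiers
beyond the label (no shared severity process), readmissions, multiple
claims per admission, hospital-level clustering, costs, lengths of stay,
or realistic national claims file layouts. Passing round-trip and
recovery tests therefore demonstrates that the *implementation* of the
identifiers, tree and metrics is exact and self-consistent — not that
the algorithm achieves any particular accuracy on real claims, which
requires the original linked data.

A separate designed-performance mode draws each episode's *call* directly
(P(AIS call|AIS) = 0.80, P(non-AIS call|¬AIS) = 0.82) and realizes it with
deterministic routing flags (IVT-only ⇒ AIS leaf in every branch;
all-false ⇒ non-AIS), so the full pipeline must recover the designed
operating point up to binomial error — the end-to-end correctness check
used at the published cohort size N = 40,443.

## Problem sizes and numerical choices

The shipped test suite and acceptance script run the full pipeline at
N = 40,443 (the published cohort size), round-trip checks at 10,000+
episodes, exhaustive tree enumeration over all 2¹⁶ used-flag
combinations per diagnosis stratum, and the window oracle over every
identifier × catalogued code × offsets −30..+120 — sizes chosen to make
the checks exhaustive where the space is small and binomially tight
where it is not. Dates are ISO-8601 calendar dates; offsets are whole
days; no floating-point time arithmetic is involved. Degenerate inputs
(empty cohorts, empty registries, all-false vectors) are defined
behaviour, not errors.

## Known limitations

* The tree topology is a documented reconstruction from prose; branch
  details that only exist in an unpublished figure (the 57-vs-52
  trajectory gap) cannot be verified.
* The combination-product assignment (517900* → aspirin) undercounts
  clopidogrel exposure in the rare combo-product case.
* Washout correctness depends on the depth of claims history supplied;
  with truncated extracts, set `washout_days` accordingly.
* Metrics are point estimates; no confidence intervals are produced (a
  rule cascade has no threshold to sweep).
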