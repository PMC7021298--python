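# claimstroke

Identify **acute ischemic stroke (AIS) admissions** in health-insurance
claims data with a transparent, rule-based algorithm, and validate it
against gold-standard registry linkage.

Administrative claims record every reimbursed diagnosis, procedure and
prescription, but ICD-10/KCD cerebrovascular codes (I60–I64) alone cannot
separate acute ischemic strokes from haemorrhages, chronic stroke
sequelae or incidental coding. `claimstroke` implements a computable
phenotype built for the Korean single-payer setting: each admission
episode is summarized by **17 boolean key identifiers** — claims codes for
atrial fibrillation, brain CT/CTA/MRI, repeat imaging, Holter monitoring,
intravenous thrombolysis (IVT), endovascular treatment (EVT), carotid
endarterectomy and angioplasty/stenting, *new* antithrombotic therapy at
3/7/90 days, anticoagulants, and rehabilitation — each evaluated over a
temporal window around the admission date, and a diagnosis-stratified
decision tree maps each identifier vector to an AIS / non-AIS call.

The package is aimed at pharmaco-epidemiologists and health-services
researchers who need to reproduce, audit, adapt or stress-test this kind
of phenotyping algorithm. Because the real national claims–registry
linkage cannot be redistributed, the package ships a **synthetic cohort
generator** that emulates the study conditions (≈32% AIS prevalence,
published principal-diagnosis mix, identifier sensitivities/specificities
inside the published envelopes) with an exact round-trip guarantee:
materialized claim lines reproduce the intended identifier flags, episode
for episode.

## The method in brief

For an admission episode with index date $t_0$ (start date of the
in-hospital claim), each key identifier $k$ is

$$X_k = \mathbb{1}\left[\exists\,\text{claim line } (c, t):\; c \in
\mathcal{C}_k,\; t - t_0 \in [l_k, u_k],\; \text{scope}_k\right]$$

with four special rules: *image follow-up* requires ≥ 2 distinct
(code, date) imaging events in $[-7,+7]$; *new antithrombotics* compares
the post-index ingredient set $W$ against the 180-day pre-index exposure
set $L$ and fires iff $W \neq \emptyset$ and $W \neq L$ (first use, added
ingredient, or changed composition); *anticoagulants* tests presence, not
novelty; *transfer to rehab* requires in-hospital lines from both the
neurology and rehabilitation departments. A decision tree stratified on
principal diagnosis (I63 ± brain CT vs non-I63) cascades these flags —
reperfusion first, interventions (with antithrombotic change) next, then
the MRI / image-follow-up / medication steps — producing one of 52
root-to-leaf *trajectories* per episode.

Validation follows the registry-linkage design: episodes are labelled by
linkage existence, split 7:3 into development and validation sets
(N = 40,443 → 28,310 / 12,133), and scored by sensitivity, specificity,
accuracy, PPV and NPV.

## Worked example

```sh
claimstroke simulate --n 2000 --seed 7 \
    --out-claims claims.csv --out-registry registry.csv --out-audit audit.csv
claimstroke extract  --claims claims.csv --out flags.csv
claimstroke classify --flags flags.csv --out calls.csv --audit flow.csv
claimstroke validate --calls calls.csv --registry registry.csv \
    --split 0.7 --seed 7 --out report.json
```

prints

```
wrote 2000 episodes (646 true AIS) to claims.csv
wrote flags for 2000 episodes to flags.csv
classified 2000 episodes (876 AIS) to calls.csv
development (n=1400): sens 89.1% spec 78.1% acc 81.6% ppv 65.8% npv 93.8%
```

The simulated cohort has 646/2000 = 32.3% true AIS episodes. The default
ruleset calls 876 episodes AIS; on the 1,400-episode development partition
it recovers 89.1% of true AIS (sensitivity) while rejecting 78.1% of
non-AIS admissions (specificity); the negative predictive value of 93.8%
means a non-AIS call is rarely a missed stroke. `flow.csv` contains the
per-edge case counts (and %-true-AIS) through the decision tree, the audit
view used to inspect which cascade steps do the work. These numbers
describe the synthetic cohort's emergent behaviour under the default
identifier probabilities, not a claim about any real dataset.

The same workflow is available as a library:

```python
from claimstroke import GeneratorConfig, generate_validation_cohort, run_pipeline

cohort = generate_validation_cohort(GeneratorConfig(n_episodes=2000, seed=7))
result = run_pipeline(cohort.claims, cohort.registry, split_seed=7)
print(result.report["overall"]["metrics_pct"])
# {'sensitivity': 89.2, 'specificity': 77.8, 'accuracy': 81.5, 'ppv': 65.8, 'npv': 93.8}
```

## Layout

| module | role |
|---|---|
| `claimstroke.model` | claim-line / episode / registry data types |
| `claimstroke.claims` | CSV ingest, episode reconstruction, washout, linkage |
| `claimstroke.catalog` | KCD code sets, windows, drug→ingredient map (JSON-shipped) |
| `claimstroke.identifiers` | the 17 key-identifier evaluators |
| `claimstroke.ruleset` | config-driven decision tree, trajectories, flow audit |
| `claimstroke.metrics` | 7:3 split, confusion counts, the five metrics |
| `claimstroke.simulate` | blueprint generator + claims materializer |
| `claimstroke.cli` | `claimstroke` console commands |

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
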