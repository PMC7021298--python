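"""Development/validation split and diagnostic accuracy metrics.

Episodes are partitioned 7:3 into development and validation sets by a
keyed, order-independent hash of the episode id (the source data states the
ratio but no splitting mechanism or seed, so the split is made reproducible
via a user-supplied seed).  Confusion counts against the gold-standard
linkage labels yield sensitivity, specificity, accuracy, PPV and NPV;
ratios with a zero denominator are reported as NaN, never as 0.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
from typing import Iterable, Mapping, Sequence

from .model import LinkedEpisode
from .ruleset import AIS, ClassificationResult

METRIC_NAMES = ("sensitivity", "specificity", "accuracy", "ppv", "npv")


def _episode_key(item) -> str:
    return item.episode_id if hasattr(item, "episode_id") else str(item)


def split_dataset(
    episodes: Sequence, ratio: float = 0.7, seed: int = 0
) -> tuple[list, list]:
    """Deterministic, order-independent split into (development, validation).

    The development set receives ``floor(ratio * N)`` items (e.g. 40,443 at
    0.7 → 28,310 / 12,133); membership depends only on (episode_id, seed).
    """
    if not 0 < ratio < 1:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    items = list(episodes)

    def sort_key(item):
        key = _episode_key(item)
        digest = hashlib.blake2b(
            f"{seed}:{key}".encode("utf-8"), digest_size=8
        ).hexdigest()
        return (digest, key)

    ordered = sorted(items, key=sort_key)
    n_dev = math.floor(ratio * len(ordered))
    return ordered[:n_dev], ordered[n_dev:]


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def prevalence(self) -> float:
        return (self.tp + self.fn) / self.total if self.total else float("nan")


def _as_call_map(calls) -> dict[str, bool]:
    if isinstance(calls, Mapping):
        return {str(k): bool(v) for k, v in calls.items()}
    out: dict[str, bool] = {}
    for item in calls:
        if isinstance(item, ClassificationResult):
            out[item.episode_id] = item.label == AIS
        else:
            eid, label = item
            out[str(eid)] = (label == AIS) if isinstance(label, str) else bool(label)
    return out


def _as_label_map(labels) -> dict[str, bool]:
    if isinstance(labels, Mapping):
        return {str(k): bool(v) for k, v in labels.items()}
    out: dict[str, bool] = {}
    for item in labels:
        if isinstance(item, LinkedEpisode):
            out[item.episode_id] = item.true_ais
        else:
            eid, truth = item
            out[str(eid)] = bool(truth)
    return out


def confusion(
    calls: Iterable | Mapping[str, bool], labels: Iterable | Mapping[str, bool]
) -> ConfusionCounts:
    """Confusion counts of algorithm calls against gold-standard labels.

    ``calls`` and ``labels`` must cover the same episode set; a mismatch is
    an error listing the offending ids.
    """
    call_map = _as_call_map(calls)
    label_map = _as_label_map(labels)
    only_calls = sorted(set(call_map) - set(label_map))
    only_labels = sorted(set(label_map) - set(call_map))
    if only_calls or only_labels:
        raise ValueError(
            f"episode sets differ; only in calls: {only_calls[:5]}, "
            f"only in labels: {only_labels[:5]}"
        )
    tp = fp = fn = tn = 0
    for eid, call in call_map.items():
        truth = label_map[eid]
        if call and truth:
            tp += 1
        elif call and not truth:
            fp += 1
        elif not call and truth:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclasses.dataclass(frozen=True)
class ValidationMetrics:
    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    npv: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}

    def as_percent(self, ndigits: int = 1) -> dict[str, float]:
        """Percentage rendering (reporting layer only; one decimal)."""
        return {
            name: round(100.0 * value, ndigits) if not math.isnan(value) else float("nan")
            for name, value in self.as_dict().items()
        }


def _ratio(num: int, den: int) -> float:
    return num / den if den else float("nan")


def metrics(counts: ConfusionCounts) -> ValidationMetrics:
    """The five diagnostic accuracy metrics as proportions in [0, 1]."""
    return ValidationMetrics(
        sensitivity=_ratio(counts.tp, counts.tp + counts.fn),
        specificity=_ratio(counts.tn, counts.tn + counts.fp),
        accuracy=_ratio(counts.tp + counts.tn, counts.total),
        ppv=_ratio(counts.tp, counts.tp + counts.fp),
        npv=_ratio(counts.tn, counts.tn + counts.fn),
    )


def validation_report(
    calls: Iterable | Mapping[str, bool],
    labels: Iterable | Mapping[str, bool],
    ratio: float = 0.7,
    seed: int = 0,
) -> dict:
    """Counts and metrics for the overall, development and validation sets."""
    call_map = _as_call_map(calls)
    label_map = _as_label_map(labels)
    dev_ids, val_ids = split_dataset(sorted(call_map), ratio=ratio, seed=seed)
    report: dict = {"split": {"ratio": ratio, "seed": seed}}
    for name, ids in (
        ("overall", list(call_map)),
        ("development", dev_ids),
        ("validation", val_ids),
    ):
        sub_calls = {eid: call_map[eid] for eid in ids}
        sub_labels = {eid: label_map[eid] for eid in ids if eid in label_map}
        counts = confusion(sub_calls, sub_labels)
        m = metrics(counts)
        report[name] = {
            "n": counts.total,
            "counts": dataclasses.asdict(counts),
            "metrics": m.as_dict(),
            "metrics_pct": m.as_percent(),
        }
    return report
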