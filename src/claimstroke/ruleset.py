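"""Declarative decision tree classifying episodes as AIS / non-AIS.

The shipped ruleset (``CRCS-K-2020``) encodes the published clinical
cascade.  The tree first splits on whether the principal diagnosis is
cerebral infarction (I63) and, within I63, on whether brain CT was
performed.  Each branch then applies an ordered cascade: reperfusion
therapy (IVT, then EVT) first; carotid/intracranial interventions combined
with a 3-day antithrombotic change next (interventions alone may be
elective, so they only count together with new antithrombotics); then MRI
or CTA combined with the 3-day change; and finally, for MRI-positive cases
without an early medication change, an image-follow-up cascade over the
7-day antithrombotic change, Holter monitoring, atrial fibrillation with
anticoagulation (AF without any antithrombotic is still called AIS, read as
hemorrhagic transformation precluding medication), and the 90-day
outpatient antithrombotic change.  In the non-I63 branch the intervention
step is clinically irrelevant and is replaced by the combination of a 3-day
antithrombotic change with transfer-to-rehabilitation.

Every episode follows exactly one root-to-leaf path (its *trajectory*).
The engine is config-driven: a tree is a JSON document and can be amended
without code changes; :func:`enumerate_trajectories` plus the conformance
snapshot in the test suite guard against silent drift of the shipped tree.
"""

from __future__ import annotations

import dataclasses
import json
from collections import Counter
from importlib import resources
from typing import Iterable, Mapping, Sequence, Union

from .identifiers import FLAG_NAMES, IdentifierVector

AIS = "AIS"
NON_AIS = "non_AIS"

RULESET_VERSION = "CRCS-K-2020"


# ---------------------------------------------------------------------------
# tests (node predicates)


@dataclasses.dataclass(frozen=True)
class FlagTest:
    name: str

    def evaluate(self, flags: Mapping[str, bool], principal_dx: str) -> bool:
        return bool(flags[self.name])

    def flag_names(self):
        yield self.name

    def to_dict(self) -> dict:
        return {"type": "flag", "name": self.name}


@dataclasses.dataclass(frozen=True)
class DxPrefixTest:
    prefix: str

    def evaluate(self, flags: Mapping[str, bool], principal_dx: str) -> bool:
        return principal_dx.startswith(self.prefix)

    def flag_names(self):
        return iter(())

    def to_dict(self) -> dict:
        return {"type": "dx_prefix", "prefix": self.prefix}


@dataclasses.dataclass(frozen=True)
class AllOf:
    tests: tuple

    def evaluate(self, flags, principal_dx) -> bool:
        return all(t.evaluate(flags, principal_dx) for t in self.tests)

    def flag_names(self):
        for t in self.tests:
            yield from t.flag_names()

    def to_dict(self) -> dict:
        return {"type": "all", "tests": [t.to_dict() for t in self.tests]}


@dataclasses.dataclass(frozen=True)
class AnyOf:
    tests: tuple

    def evaluate(self, flags, principal_dx) -> bool:
        return any(t.evaluate(flags, principal_dx) for t in self.tests)

    def flag_names(self):
        for t in self.tests:
            yield from t.flag_names()

    def to_dict(self) -> dict:
        return {"type": "any", "tests": [t.to_dict() for t in self.tests]}


Test = Union[FlagTest, DxPrefixTest, AllOf, AnyOf]


def test_from_dict(data: Mapping) -> Test:
    kind = data.get("type")
    if kind == "flag":
        return FlagTest(data["name"])
    if kind == "dx_prefix":
        return DxPrefixTest(data["prefix"])
    if kind in ("all", "any"):
        sub = tuple(test_from_dict(t) for t in data["tests"])
        return AllOf(sub) if kind == "all" else AnyOf(sub)
    raise RulesetError(f"unknown test type {kind!r}")


# ---------------------------------------------------------------------------
# tree


class RulesetError(ValueError):
    """Invalid ruleset configuration."""


@dataclasses.dataclass(frozen=True)
class Leaf:
    label: str  # AIS | non_AIS
    trajectory_id: str


@dataclasses.dataclass(frozen=True)
class Node:
    node_id: str
    test: Test
    if_true: Union["Node", Leaf]
    if_false: Union["Node", Leaf]


@dataclasses.dataclass(frozen=True)
class ClassificationResult:
    episode_id: str
    label: str
    trajectory_id: str


@dataclasses.dataclass(frozen=True)
class Trajectory:
    trajectory_id: str
    label: str
    #: sequence of (node_id, branch_taken) pairs from root to leaf
    path: tuple[tuple[str, bool], ...]


class DecisionTree:
    """A validated, single-rooted, acyclic decision tree."""

    def __init__(self, root: Node, version: str = RULESET_VERSION):
        self.root = root
        self.version = version
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        seen_nodes: set[str] = set()
        seen_traj: set[str] = set()
        stack: list[tuple[object, tuple[str, ...]]] = [(self.root, ())]
        while stack:
            item, ancestry = stack.pop()
            if isinstance(item, Leaf):
                if item.label not in (AIS, NON_AIS):
                    raise RulesetError(
                        f"leaf {item.trajectory_id!r}: unknown label {item.label!r}"
                    )
                if item.trajectory_id in seen_traj:
                    raise RulesetError(
                        f"duplicate trajectory_id {item.trajectory_id!r}"
                    )
                seen_traj.add(item.trajectory_id)
                continue
            if item.node_id in ancestry:
                raise RulesetError(f"cycle through node {item.node_id!r}")
            if item.node_id in seen_nodes:
                raise RulesetError(f"node {item.node_id!r} has multiple parents")
            seen_nodes.add(item.node_id)
            for name in item.test.flag_names():
                if name not in FLAG_NAMES:
                    raise RulesetError(
                        f"node {item.node_id!r}: unknown identifier flag {name!r}"
                    )
            nxt = ancestry + (item.node_id,)
            stack.append((item.if_true, nxt))
            stack.append((item.if_false, nxt))

    # -- classification --------------------------------------------------

    def classify(
        self, vector: IdentifierVector | Mapping[str, bool], principal_dx: str
    ) -> tuple[Leaf, tuple[tuple[str, bool], ...]]:
        """Single-path evaluation; returns the leaf and the edges traversed."""
        flags = vector.as_dict() if isinstance(vector, IdentifierVector) else dict(vector)
        node: object = self.root
        path: list[tuple[str, bool]] = []
        while isinstance(node, Node):
            branch = node.test.evaluate(flags, principal_dx)
            path.append((node.node_id, branch))
            node = node.if_true if branch else node.if_false
        return node, tuple(path)

    # -- enumeration -----------------------------------------------------

    def enumerate_trajectories(self) -> list[Trajectory]:
        """All root-to-leaf paths with leaf labels, in stable DFS order."""
        out: list[Trajectory] = []

        def walk(item, path):
            if isinstance(item, Leaf):
                out.append(Trajectory(item.trajectory_id, item.label, tuple(path)))
                return
            walk(item.if_true, path + [(item.node_id, True)])
            walk(item.if_false, path + [(item.node_id, False)])

        walk(self.root, [])
        return out

    # -- (de)serialization ----------------------------------------------

    def to_dict(self) -> dict:
        nodes: dict[str, dict] = {}
        leaves: dict[str, dict] = {}

        def ref(item) -> str:
            if isinstance(item, Leaf):
                leaves[item.trajectory_id] = {
                    "label": item.label,
                    "trajectory_id": item.trajectory_id,
                }
                return f"leaf:{item.trajectory_id}"
            emit(item)
            return f"node:{item.node_id}"

        def emit(node: Node) -> None:
            nodes[node.node_id] = {
                "test": node.test.to_dict(),
                "if_true": ref(node.if_true),
                "if_false": ref(node.if_false),
            }

        emit(self.root)
        return {
            "version": self.version,
            "root": f"node:{self.root.node_id}",
            "nodes": nodes,
            "leaves": leaves,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "DecisionTree":
        nodes = data.get("nodes", {})
        leaves = data.get("leaves", {})

        building: set[str] = set()
        built: dict[str, Node] = {}

        def resolve(ref: str):
            kind, _, key = ref.partition(":")
            if kind == "leaf":
                if key not in leaves:
                    raise RulesetError(f"unknown leaf reference {ref!r}")
                spec = leaves[key]
                return Leaf(label=spec["label"], trajectory_id=spec["trajectory_id"])
            if kind == "node":
                if key not in nodes:
                    raise RulesetError(f"unknown node reference {ref!r}")
                return build(key)
            raise RulesetError(f"malformed reference {ref!r}")

        def build(node_id: str) -> Node:
            if node_id in built:
                return built[node_id]
            if node_id in building:
                raise RulesetError(f"cycle through node {node_id!r}")
            building.add(node_id)
            spec = nodes[node_id]
            node = Node(
                node_id=node_id,
                test=test_from_dict(spec["test"]),
                if_true=resolve(spec["if_true"]),
                if_false=resolve(spec["if_false"]),
            )
            building.discard(node_id)
            built[node_id] = node
            return node

        root_ref = data["root"]
        kind, _, root_id = root_ref.partition(":")
        if kind != "node" or root_id not in nodes:
            raise RulesetError(f"invalid root reference {root_ref!r}")
        tree = cls(build(root_id), version=data.get("version", "custom"))
        unreachable = set(nodes) - set(built)
        if unreachable:
            raise RulesetError(f"unreachable node(s): {sorted(unreachable)}")
        return tree

    def dump(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def load_ruleset(source) -> DecisionTree:
    """Load and validate a ruleset from a JSON path/file-like/dict."""
    if isinstance(source, Mapping):
        return DecisionTree.from_dict(source)
    if hasattr(source, "read"):
        return DecisionTree.from_dict(json.load(source))
    with open(source, encoding="utf-8") as fh:
        return DecisionTree.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# the shipped CRCS-K-2020 tree


def _followup_cascade(p: str) -> Node:
    """MRI → image-follow-up cascade shared by all three branches."""

    def af_subtree(q: str, af_negative_leaf: Leaf) -> Node:
        # AF+ without any antithrombotic/anticoagulant: hemorrhagic
        # transformation assumed in the follow-up-positive arm only.
        return Node(
            f"{p}.{q}.af",
            FlagTest("af"),
            Node(
                f"{p}.{q}.af.anticoagulants",
                FlagTest("anticoagulants_7d"),
                Leaf(AIS, f"{p}.{q}.af.anticoagulants.ais"),
                Node(
                    f"{p}.{q}.af.n90",
                    FlagTest("new_antithrombotics_90d_nrns_opd"),
                    Leaf(AIS, f"{p}.{q}.af.n90.ais"),
                    af_negative_leaf,
                ),
            ),
            Node(
                f"{p}.{q}.n90",
                FlagTest("new_antithrombotics_90d_nrns_opd"),
                Leaf(AIS, f"{p}.{q}.n90.ais"),
                Leaf(NON_AIS, f"{p}.{q}.non_ais"),
            ),
        )

    fu_positive = Node(
        f"{p}.fu.n7",
        FlagTest("new_antithrombotics_7d"),
        Leaf(AIS, f"{p}.fu.n7.ais"),
        Node(
            f"{p}.fu.holter",
            FlagTest("holter"),
            Leaf(AIS, f"{p}.fu.holter.ais"),
            af_subtree("fu", Leaf(AIS, f"{p}.fu.af.hemorrhagic_transformation.ais")),
        ),
    )
    fu_negative = af_subtree("nofu", Leaf(NON_AIS, f"{p}.nofu.af.non_ais"))
    return Node(
        f"{p}.mri",
        FlagTest("brain_mri"),
        Node(f"{p}.image_fu", FlagTest("image_fu"), fu_positive, fu_negative),
        Leaf(NON_AIS, f"{p}.no_mri.non_ais"),
    )


def _intervention_test() -> Test:
    return AllOf(
        (
            AnyOf(
                (
                    FlagTest("cea"),
                    FlagTest("carotid_angioplasty"),
                    FlagTest("intracranial_angioplasty"),
                )
            ),
            FlagTest("new_antithrombotics_3d"),
        )
    )


def _branch_i63(p: str, with_cta_step: bool) -> Node:
    """I63+ cascade; the CTA step only applies when brain CT was performed."""
    tail: Union[Node, Leaf] = _followup_cascade(p)
    if with_cta_step:
        tail = Node(
            f"{p}.n3_cta",
            AllOf((FlagTest("new_antithrombotics_3d"), FlagTest("cta"))),
            Leaf(AIS, f"{p}.n3_cta.ais"),
            tail,
        )
    return Node(
        f"{p}.ivt",
        FlagTest("ivt"),
        Leaf(AIS, f"{p}.ivt.ais"),
        Node(
            f"{p}.evt",
            FlagTest("evt"),
            Leaf(AIS, f"{p}.evt.ais"),
            Node(
                f"{p}.intervention",
                _intervention_test(),
                Leaf(AIS, f"{p}.intervention.ais"),
                Node(
                    f"{p}.n3_mri",
                    AllOf((FlagTest("new_antithrombotics_3d"), FlagTest("brain_mri"))),
                    Leaf(AIS, f"{p}.n3_mri.ais"),
                    tail,
                ),
            ),
        ),
    )


def _branch_non_i63() -> Node:
    p = "C"
    return Node(
        f"{p}.reperfusion",
        AnyOf((FlagTest("ivt"), FlagTest("evt"))),
        Leaf(AIS, f"{p}.reperfusion.ais"),
        Node(
            f"{p}.n3_transfer_rehab",
            AllOf((FlagTest("new_antithrombotics_3d"), FlagTest("transfer_to_rehab"))),
            Leaf(AIS, f"{p}.n3_transfer_rehab.ais"),
            Node(
                f"{p}.n3_mri",
                AllOf((FlagTest("new_antithrombotics_3d"), FlagTest("brain_mri"))),
                Leaf(AIS, f"{p}.n3_mri.ais"),
                Node(
                    f"{p}.n3_cta",
                    AllOf((FlagTest("new_antithrombotics_3d"), FlagTest("cta"))),
                    Leaf(AIS, f"{p}.n3_cta.ais"),
                    _followup_cascade(p),
                ),
            ),
        ),
    )


def default_ruleset() -> DecisionTree:
    """The shipped ``CRCS-K-2020`` tree (reconstructed published cascade)."""
    root = Node(
        "root.i63",
        DxPrefixTest("I63"),
        Node(
            "root.brain_ct",
            FlagTest("brain_ct"),
            _branch_i63("A", with_cta_step=True),
            _branch_i63("B", with_cta_step=False),
        ),
        _branch_non_i63(),
    )
    return DecisionTree(root, version=RULESET_VERSION)


def default_ruleset_resource() -> DecisionTree:
    """Load the shipped ruleset JSON data file (same tree as in code)."""
    ref = resources.files("claimstroke").joinpath("data/ruleset_crcsk2020.json")
    return DecisionTree.from_dict(json.loads(ref.read_text(encoding="utf-8")))


# ---------------------------------------------------------------------------
# dataset-level classification with flow audit


@dataclasses.dataclass
class FlowAudit:
    """Per-edge traversal counts (and true-AIS tallies when labels given)."""

    n_total: int
    edge_counts: Counter  # (node_id, branch) -> n
    edge_true: Counter  # (node_id, branch) -> n true AIS
    leaf_counts: Counter  # trajectory_id -> n
    leaf_true: Counter
    labelled: bool

    def check_conservation(self, tree: DecisionTree) -> None:
        """Assert inflow == outflow at every internal node."""

        def walk(item, inflow):
            if isinstance(item, Leaf):
                if self.leaf_counts[item.trajectory_id] != inflow:
                    raise AssertionError(
                        f"leaf {item.trajectory_id!r}: inflow {inflow} != "
                        f"count {self.leaf_counts[item.trajectory_id]}"
                    )
                return
            out_t = self.edge_counts[(item.node_id, True)]
            out_f = self.edge_counts[(item.node_id, False)]
            if out_t + out_f != inflow:
                raise AssertionError(
                    f"node {item.node_id!r}: inflow {inflow} != outflow {out_t + out_f}"
                )
            walk(item.if_true, out_t)
            walk(item.if_false, out_f)

        walk(tree.root, self.n_total)

    def to_frame(self):
        import pandas as pd

        rows = []
        for (node_id, branch), n in sorted(self.edge_counts.items()):
            row = {"node_id": node_id, "branch": branch, "n": n}
            if self.labelled:
                n_true = self.edge_true[(node_id, branch)]
                row["n_true_ais"] = n_true
                row["pct_true_ais"] = round(100.0 * n_true / n, 1) if n else float("nan")
            rows.append(row)
        return pd.DataFrame(rows)


def classify_episode(
    vector: IdentifierVector | Mapping[str, bool],
    principal_dx: str,
    ruleset: DecisionTree,
    episode_id: str = "",
) -> ClassificationResult:
    leaf, _ = ruleset.classify(vector, principal_dx)
    return ClassificationResult(
        episode_id=episode_id, label=leaf.label, trajectory_id=leaf.trajectory_id
    )


def classify_dataset(
    records: Iterable[tuple[str, str, IdentifierVector | Mapping[str, bool]]],
    ruleset: DecisionTree,
    labels: Mapping[str, bool] | None = None,
) -> tuple[list[ClassificationResult], FlowAudit]:
    """Classify (episode_id, principal_dx, vector) records with a flow audit."""
    results: list[ClassificationResult] = []
    edge_counts: Counter = Counter()
    edge_true: Counter = Counter()
    leaf_counts: Counter = Counter()
    leaf_true: Counter = Counter()
    n = 0
    for episode_id, principal_dx, vector in records:
        leaf, path = ruleset.classify(vector, principal_dx)
        results.append(
            ClassificationResult(
                episode_id=episode_id, label=leaf.label, trajectory_id=leaf.trajectory_id
            )
        )
        n += 1
        is_true = bool(labels and labels.get(episode_id, False))
        for edge in path:
            edge_counts[edge] += 1
            if is_true:
                edge_true[edge] += 1
        leaf_counts[leaf.trajectory_id] += 1
        if is_true:
            leaf_true[leaf.trajectory_id] += 1
    audit = FlowAudit(
        n_total=n,
        edge_counts=edge_counts,
        edge_true=edge_true,
        leaf_counts=leaf_counts,
        leaf_true=leaf_true,
        labelled=labels is not None,
    )
    return results, audit


def enumerate_trajectories(ruleset: DecisionTree) -> list[Trajectory]:
    return ruleset.enumerate_trajectories()
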