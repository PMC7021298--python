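"""Decision-tree structure, classification semantics and flow audit."""

import itertools
import random

import numpy as np
import pytest

from claimstroke import (
    GeneratorConfig,
    IdentifierVector,
    build_episodes,
    classify_dataset,
    classify_episode,
    default_ruleset,
    extract_identifier_vector,
    load_ruleset,
    read_claims,
)
from claimstroke.ruleset import (
    AIS,
    NON_AIS,
    DecisionTree,
    RulesetError,
    default_ruleset_resource,
)
from claimstroke.simulate import EpisodeBlueprint, materialize_episode
import claimstroke.simulate as sim

import pandas as pd


def _vec(**flags):
    return IdentifierVector.from_dict(flags)


def _used_flags(tree):
    used = set()

    def walk(item):
        if hasattr(item, "test"):
            used.update(item.test.flag_names())
            walk(item.if_true)
            walk(item.if_false)

    walk(tree.root)
    return sorted(used)


class TestDefaultRuleset:
    def test_root_splits_on_principal_dx_i63(self, ruleset):
        assert ruleset.root.test.to_dict() == {"type": "dx_prefix", "prefix": "I63"}

    def test_shipped_json_matches_in_code_tree(self, ruleset):
        assert default_ruleset_resource().to_dict() == ruleset.to_dict()

    @pytest.mark.parametrize(
        "principal_dx, flags, label",
        [
            # reperfusion therapy identifies AIS in every branch
            ("I639", dict(brain_ct=True, ivt=True), AIS),
            ("I639", dict(ivt=True), AIS),
            ("I619", dict(evt=True), AIS),
            # interventions count only together with new antithrombotics
            ("I639", dict(brain_ct=True, cea=True), NON_AIS),
            ("I639", dict(brain_ct=True, cea=True, new_antithrombotics_3d=True), AIS),
            ("I639", dict(brain_ct=True, new_antithrombotics_3d=True, brain_mri=True, image_fu=True), AIS),
            ("I639", dict(brain_ct=True, new_antithrombotics_3d=True, cta=True), AIS),
            # MRI without an early medication change: the follow-up cascade
            ("I639", dict(brain_mri=True, image_fu=True, new_antithrombotics_7d=True), AIS),
            ("I639", dict(brain_mri=True, image_fu=True, holter=True), AIS),
            # AF without anticoagulation or late antithrombotics is still AIS
            # in the follow-up-positive arm (hemorrhagic transformation)
            ("I639", dict(brain_mri=True, image_fu=True, af=True), AIS),
            ("I639", dict(brain_mri=True, af=True), NON_AIS),
            ("I639", dict(brain_mri=True, af=True, anticoagulants_7d=True), AIS),
            ("I639", dict(brain_mri=True, new_antithrombotics_90d_nrns_opd=True), AIS),
            # transfer-to-rehab step exists only in the non-I63 branch
            ("I619", dict(new_antithrombotics_3d=True, transfer_to_rehab=True), AIS),
            ("I639", dict(brain_ct=True, new_antithrombotics_3d=True, transfer_to_rehab=True), NON_AIS),
            ("I609", dict(cea=True, new_antithrombotics_3d=True), NON_AIS),
            # fall-through leaves
            ("I639", dict(), NON_AIS),
            ("I609", dict(), NON_AIS),
            ("C349", dict(), NON_AIS),
        ],
    )
    def test_classification_examples(self, ruleset, principal_dx, flags, label):
        assert classify_episode(_vec(**flags), principal_dx, ruleset).label == label

    def test_trajectory_count_snapshot(self, ruleset):
        trajs = ruleset.enumerate_trajectories()
        assert len(trajs) == 52
        assert sum(t.label == AIS for t in trajs) == 40
        ids = {t.trajectory_id for t in trajs}
        assert len(ids) == 52
        assert "A.fu.af.hemorrhagic_transformation.ais" in ids
        assert "C.n3_transfer_rehab.ais" in ids


class TestValidation:
    def _tiny(self, **overrides):
        cfg = {
            "version": "t",
            "root": "node:n1",
            "nodes": {
                "n1": {
                    "test": {"type": "flag", "name": "ivt"},
                    "if_true": "leaf:yes",
                    "if_false": "leaf:no",
                }
            },
            "leaves": {
                "yes": {"label": AIS, "trajectory_id": "yes"},
                "no": {"label": NON_AIS, "trajectory_id": "no"},
            },
        }
        cfg.update(overrides)
        return cfg

    def test_single_test_tree_has_two_paths(self):
        tree = load_ruleset(self._tiny())
        assert len(tree.enumerate_trajectories()) == 2

    def test_unknown_flag_rejected(self):
        cfg = self._tiny()
        cfg["nodes"]["n1"]["test"] = {"type": "flag", "name": "mri2"}
        with pytest.raises(RulesetError, match="mri2"):
            load_ruleset(cfg)

    def test_cycle_rejected(self):
        cfg = self._tiny()
        cfg["nodes"]["n1"]["if_true"] = "node:n1"
        with pytest.raises(RulesetError, match="cycle"):
            load_ruleset(cfg)

    def test_unreachable_node_rejected(self):
        cfg = self._tiny()
        cfg["nodes"]["orphan"] = {
            "test": {"type": "flag", "name": "evt"},
            "if_true": "leaf:yes2",
            "if_false": "leaf:no2",
        }
        cfg["leaves"]["yes2"] = {"label": AIS, "trajectory_id": "yes2"}
        cfg["leaves"]["no2"] = {"label": NON_AIS, "trajectory_id": "no2"}
        with pytest.raises(RulesetError, match="unreachable"):
            load_ruleset(cfg)

    def test_duplicate_trajectory_id_rejected(self):
        cfg = self._tiny()
        cfg["leaves"]["no"]["trajectory_id"] = "yes"
        with pytest.raises(RulesetError, match="duplicate trajectory"):
            load_ruleset(cfg)

    def test_dangling_reference_rejected(self):
        cfg = self._tiny()
        cfg["nodes"]["n1"]["if_true"] = "leaf:ghost"
        with pytest.raises(RulesetError, match="ghost"):
            load_ruleset(cfg)

    def test_round_trip_serialization(self, ruleset, tmp_path):
        path = tmp_path / "tree.json"
        ruleset.dump(path)
        assert load_ruleset(path).to_dict() == ruleset.to_dict()


def test_totality_every_vector_reaches_exactly_one_leaf(ruleset):
    """Exhaustive over all used-flag combinations in both dx strata."""
    used = _used_flags(ruleset)
    assert len(used) == 16  # plain rehab is catalogued but not in the tree
    leaf_ids = {t.trajectory_id for t in ruleset.enumerate_trajectories()}
    reached = set()
    for principal_dx in ("I639", "C349"):
        for bits in itertools.product((False, True), repeat=len(used)):
            flags = dict(zip(used, bits))
            leaf, path = ruleset.classify(
                {**{n: False for n in IdentifierVector().as_dict()}, **flags},
                principal_dx,
            )
            assert leaf.trajectory_id in leaf_ids
            reached.add(leaf.trajectory_id)
    # every trajectory is reachable by some flag vector
    assert reached == leaf_ids


def test_flags_off_the_traversed_path_are_irrelevant(ruleset):
    rng = random.Random(12)
    names = list(IdentifierVector().as_dict())
    for _ in range(200):
        flags = {n: rng.random() < 0.3 for n in names}
        dx = rng.choice(["I639", "I619", "C349"])
        leaf, path = ruleset.classify(flags, dx)
        node_by_id = {}

        def index(item):
            if hasattr(item, "test"):
                node_by_id[item.node_id] = item
                index(item.if_true)
                index(item.if_false)

        index(ruleset.root)
        on_path = set()
        for node_id, _branch in path:
            on_path.update(node_by_id[node_id].test.flag_names())
        for name in set(names) - on_path:
            flipped = dict(flags)
            flipped[name] = not flipped[name]
            leaf2, _ = ruleset.classify(flipped, dx)
            assert leaf2.trajectory_id == leaf.trajectory_id


def test_flow_conservation_on_random_dataset(ruleset):
    rng = random.Random(3)
    names = list(IdentifierVector().as_dict())
    records = []
    labels = {}
    for i in range(500):
        eid = f"E{i}"
        records.append(
            (
                eid,
                rng.choice(["I639", "I619", "C349"]),
                {n: rng.random() < 0.25 for n in names},
            )
        )
        labels[eid] = rng.random() < 0.3
    results, audit = classify_dataset(records, ruleset, labels=labels)
    assert len(results) == 500
    audit.check_conservation(ruleset)
    assert sum(audit.leaf_counts.values()) == 500
    frame = audit.to_frame()
    assert set(frame.columns) == {"node_id", "branch", "n", "n_true_ais", "pct_true_ais"}


def _witness_vectors_by_trajectory(ruleset):
    """Exhaustive enumeration of generator-coherent witness vectors."""
    used = _used_flags(ruleset)
    witnesses = {}
    for principal_dx in ("I639", "C349"):
        for bits in itertools.product((False, True), repeat=len(used)):
            flags = {**{n: False for n in IdentifierVector().as_dict()}, **dict(zip(used, bits))}
            coherent = (
                (not flags["cta"] or flags["brain_ct"])
                and (
                    not flags["new_antithrombotics_3d"]
                    or flags["new_antithrombotics_7d"]
                )
                and (
                    not (flags["brain_ct"] and flags["brain_mri"])
                    or flags["image_fu"]
                )
            )
            if not coherent:
                continue
            leaf, _ = ruleset.classify(flags, principal_dx)
            witnesses.setdefault(leaf.trajectory_id, (principal_dx, flags))
    return witnesses


def test_every_feasible_trajectory_has_a_materialized_witness(ruleset):
    """Generator-backed reachability: synthesize an episode per trajectory.

    In the I63+/CT+ branch the image-follow-up-negative sub-branch cannot be
    realized by any claims episode (a CT event and an MRI event inside their
    shared window always count as two imaging events), so those trajectories
    have vector-level but not episode-level witnesses.
    """
    witnesses = _witness_vectors_by_trajectory(ruleset)
    all_ids = {t.trajectory_id for t in ruleset.enumerate_trajectories()}
    infeasible = {tid for tid in all_ids if tid.startswith("A.nofu.")}
    assert set(witnesses) == all_ids - infeasible
    rng = np.random.default_rng(99)
    for tid, (principal_dx, flags) in sorted(witnesses.items()):
        bp = EpisodeBlueprint(
            episode_id="W1",
            patient_id="PW1",
            true_ais=True,
            dx_category="I63" if principal_dx.startswith("I63") else "other",
            principal_dx=principal_dx,
            intended_flags=IdentifierVector.from_dict(flags),
            age=70.0,
            sex="F",
            index_date=sim.BASE_DATE,
        )
        rows = materialize_episode(bp, rng)
        (episode,) = build_episodes(read_claims(pd.DataFrame(rows)))
        vec = extract_identifier_vector(episode)
        result = classify_episode(vec, episode.principal_dx, ruleset, episode.episode_id)
        assert result.trajectory_id == tid, f"trajectory {tid} not reproduced"
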