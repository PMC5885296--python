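"""Founder seeding, division classification and name propagation."""

import numpy as np
import pytest

import sulston as s
from sulston.naming import (
    DegenerateDivisionError,
    NameCollisionError,
    Provenance,
    SeedingError,
)

from conftest import name_embryo


def identity_meta(**kw):
    return s.EmbryoMetadata(xy_res=1.0, z_res=1.0, **kw)


class TestSeedFounders:
    def test_canonical_diamond_gets_ground_truth_names(self, embryo):
        tree = s.build_tracks(embryo.frames)
        seeds = s.seed_founders(tree, s.RigidTransform.identity(), embryo.metadata)
        assert {seeds[k] for k in seeds} == {"ABa", "ABp", "EMS", "P2"}
        for key, name in seeds.items():
            assert embryo.truth[key] == name

    def test_rotated_embryo_seeds_identically(self, embryo, rotated_embryo):
        tree = s.build_tracks(rotated_embryo.frames)
        transform = s.canonical_transform(
            rotated_embryo.metadata.ap_vector, rotated_embryo.metadata.lr_vector
        )
        seeds = s.seed_founders(tree, transform, rotated_embryo.metadata)
        assert seeds == s.seed_founders(
            s.build_tracks(embryo.frames), s.RigidTransform.identity(), embryo.metadata
        )

    def test_manual_seeds_applied_verbatim(self):
        frames = [[s.NucleusRecord(time=1, index=1)]]
        tree = s.build_tracks(frames)
        seeds = s.seed_founders(
            tree, s.RigidTransform.identity(), identity_meta(),
            mode=s.SeedMode.MANUAL, manual={(1, 1): "ABa"},
        )
        assert seeds == {(1, 1): "ABa"}
        asg = s.assign_names(tree, s.RigidTransform.identity(), s.NamingRuleSet(),
                             identity_meta(), seeds=seeds)
        assert asg[(1, 1)].provenance is Provenance.SEED

    def test_no_4cell_frame_suggests_manual(self):
        frames = [[s.NucleusRecord(time=1, index=1)]]
        tree = s.build_tracks(frames)
        with pytest.raises(SeedingError, match="MANUAL"):
            s.seed_founders(tree, s.RigidTransform.identity(), identity_meta())

    def test_duplicate_manual_names_rejected(self):
        frames = [[s.NucleusRecord(time=1, index=1), s.NucleusRecord(time=1, index=2)]]
        tree = s.build_tracks(frames)
        with pytest.raises(SeedingError, match="duplicate"):
            s.seed_founders(
                tree, s.RigidTransform.identity(), identity_meta(),
                mode=s.SeedMode.MANUAL, manual={(1, 1): "ABa", (1, 2): "ABa"},
            )


def division_frames(d1_pos, d2_pos, parent_pos=(0, 0, 0)):
    px, py, pz = parent_pos
    return [
        [s.NucleusRecord(time=1, index=1, x=px, y=py, z=pz, successor1=1, successor2=2)],
        [s.NucleusRecord(time=2, index=1, predecessor=1,
                         x=d1_pos[0], y=d1_pos[1], z=d1_pos[2]),
         s.NucleusRecord(time=2, index=2, predecessor=1,
                         x=d2_pos[0], y=d2_pos[1], z=d2_pos[2])],
    ]


class TestDivisionVector:
    def test_pure_image_x_separation_in_canonical_embryo(self):
        tree = s.build_tracks(division_frames((-1, 0, 0), (1, 0, 0)))
        v = s.division_vector(tree.roots[0], s.RigidTransform.identity(),
                              identity_meta())
        assert np.allclose(v, [1, 0, 0])

    def test_rotated_embryo_recovers_canonical_axis(self):
        q = s.random_orientation(np.random.default_rng(3)).rotation
        d1, d2 = q @ np.array([-1.0, 0, 0]), q @ np.array([1.0, 0, 0])
        tree = s.build_tracks(division_frames(tuple(d1), tuple(d2)))
        transform = s.canonical_transform(q @ s.CANONICAL_AP, q @ s.CANONICAL_LR)
        v = s.division_vector(tree.roots[0], transform, identity_meta())
        assert np.allclose(v, [1, 0, 0], atol=1e-9)

    def test_result_is_unit_for_random_divisions(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            d1, d2 = rng.uniform(-10, 10, 3), rng.uniform(-10, 10, 3)
            tree = s.build_tracks(division_frames(tuple(d1), tuple(d2)))
            v = s.division_vector(tree.roots[0], s.RigidTransform.identity(),
                                  identity_meta())
            assert np.isclose(np.linalg.norm(v), 1.0, atol=1e-9)

    def test_anisotropy_is_corrected_before_the_angle(self):
        # daughters 1 plane apart in z: at z_res=2 the axis is still pure z
        tree = s.build_tracks(division_frames((0, 0, 0), (0, 0, 1)))
        meta = s.EmbryoMetadata(xy_res=0.1, z_res=2.0)
        v = s.division_vector(tree.roots[0], s.RigidTransform.identity(), meta)
        assert np.allclose(v, [0, 0, 1])

    def test_coincident_daughters_are_degenerate(self):
        tree = s.build_tracks(division_frames((1, 1, 1), (1, 1, 1)))
        with pytest.raises(DegenerateDivisionError):
            s.division_vector(tree.roots[0], s.RigidTransform.identity(),
                              identity_meta())


class TestClassifyDivision:
    def test_pure_ap_fallback_orders_anterior_first(self):
        rules = s.NamingRuleSet()
        # v points daughter1→daughter2 along -AP: daughter2 is anterior
        assert s.classify_division("AB", np.array([-1.0, 0, 0]), rules)[:2] == \
               ("ABp", "ABa")
        assert s.classify_division("AB", np.array([1.0, 0, 0]), rules)[:2] == \
               ("ABa", "ABp")

    @pytest.mark.parametrize("v, expected", [
        (np.array([0, 1.0, 0]), ("ABd", "ABv")),
        (np.array([0, 0, -1.0]), ("ABr", "ABl")),
    ])
    def test_fallback_uses_dominant_axis_suffixes(self, v, expected):
        assert s.classify_division("AB", v, s.NamingRuleSet())[:2] == expected

    def test_special_daughters_ordered_by_sign(self):
        rules = s.NamingRuleSet()
        n1, n2, _ = s.classify_division("P1", np.array([1.0, 0, 0]), rules)
        assert (n1, n2) == ("EMS", "P2")
        n1, n2, _ = s.classify_division("P1", np.array([-1.0, 0, 0]), rules)
        assert (n1, n2) == ("P2", "EMS")

    def test_expected_axis_entry_overrides_fallback(self):
        axis = np.array([0.6, 0.8, 0.0])  # DV-dominant, but a/p suffixes
        rules = s.NamingRuleSet(expected_axes={
            "MSa": s.ExpectedAxis(axis, ("a", "p")),
        })
        n1, n2, prov = s.classify_division("MSa", axis, rules)
        assert (n1, n2) == ("MSaa", "MSap")
        assert prov is Provenance.EXPECTED_AXIS

    def test_exact_tie_breaks_ap_over_dv(self):
        v = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
        n1, n2, _ = s.classify_division("C", v, s.NamingRuleSet())
        assert (n1, n2) == ("Ca", "Cp")


class TestAssignNames:
    def test_zero_noise_full_ground_truth_recovery(self, embryo):
        _, _, _, _, assignments = name_embryo(embryo)
        assert all(assignments[k].name == v for k, v in embryo.truth.items())

    def test_rotation_invariance_of_all_names(self, embryo, rotated_embryo):
        _, _, _, _, base = name_embryo(embryo)
        _, _, _, _, rotated = name_embryo(rotated_embryo)
        assert {k: a.name for k, a in base.items()} == \
               {k: a.name for k, a in rotated.items()}

    def test_determinism(self, embryo):
        a1 = name_embryo(embryo)[4]
        a2 = name_embryo(embryo)[4]
        assert a1 == a2

    def test_unseeded_tree_gets_auto_tags_and_suffixed_descendants(self):
        tree = s.build_tracks(division_frames((-1, 0, 0), (1, 0, 0)))
        asg = s.assign_names(tree, s.RigidTransform.identity(), s.NamingRuleSet(),
                             identity_meta())
        root = asg[tree.roots[0].key]
        assert root.name == "Nuc-1" and root.provenance is Provenance.AUTO_TAG
        daughters = {asg[d.key].name for d in tree.roots[0].daughters}
        assert daughters == {"Nuc-1a", "Nuc-1p"}

    def test_forced_name_colliding_with_generated_name_raises(self, embryo):
        tree, transform, rules, seeds, assignments = name_embryo(embryo)
        victim = tree.name_index["ABa"]
        with pytest.raises(NameCollisionError):
            s.force_name(tree, victim, "ABp", rules, transform, embryo.metadata,
                         seeds=seeds)

    def test_fallback_covers_missing_expected_entries(self, embryo):
        """Dropping canonical-axis-aligned entries must not change any name."""
        tree, transform, rules, seeds, base = name_embryo(embryo)
        aligned = {
            name for name, ax in rules.expected_axes.items()
            if np.isclose(np.abs(ax.vector).max(), 1.0)
        }
        assert aligned  # the founders' entries are axis-aligned by design
        pruned = s.NamingRuleSet(
            expected_axes={k: v for k, v in rules.expected_axes.items()
                           if k not in aligned}
        )
        again = s.assign_names(s.build_tracks(embryo.frames), transform, pruned,
                               embryo.metadata, seeds=seeds)
        assert {k: a.name for k, a in base.items()} == \
               {k: a.name for k, a in again.items()}

    def test_axis_aligned_divisions_survive_positional_noise(self):
        """Noise at 20% of the division distance leaves names intact."""
        cfg = s.SimConfig(seed=23, n_rounds=2, division_distance=4.0,
                          position_noise_sd=0.8)
        res = s.generate(cfg)
        _, _, _, _, assignments = name_embryo(res)
        assert all(assignments[k].name == v for k, v in res.truth.items())


class TestForceName:
    def test_force_root_rederives_daughters(self):
        tree = s.build_tracks(division_frames((-1, 0, 0), (1, 0, 0)))
        meta = identity_meta()
        rules = s.NamingRuleSet()
        asg, forced = s.force_name(tree, tree.roots[0], "C", rules,
                                   s.RigidTransform.identity(), meta)
        assert asg[tree.roots[0].key].provenance is Provenance.FORCED
        names = {asg[d.key].name: asg[d.key].provenance
                 for d in tree.roots[0].daughters}
        assert set(names) == {"Ca", "Cp"}
        assert all(p is Provenance.PROPAGATED_FROM_FORCED for p in names.values())

    def test_forcing_same_name_twice_is_idempotent(self):
        tree = s.build_tracks(division_frames((-1, 0, 0), (1, 0, 0)))
        meta = identity_meta()
        rules = s.NamingRuleSet()
        t = s.RigidTransform.identity()
        asg1, forced = s.force_name(tree, tree.roots[0], "C", rules, t, meta)
        asg2, _ = s.force_name(tree, tree.roots[0], "C", rules, t, meta,
                               forced=forced)
        assert asg1 == asg2

    def test_forcing_mid_tree_leaves_ancestors_untouched(self, embryo):
        tree, transform, rules, seeds, base = name_embryo(embryo)
        target = tree.name_index["ABaa"] if "ABaa" in tree.name_index else \
            tree.name_index["ABa"].daughters[0]
        asg, _ = s.force_name(tree, target, "Forced-X", rules, transform,
                              embryo.metadata, seeds=seeds)

        def subtree_keys(track):
            yield track.key
            for d in track.daughters:
                yield from subtree_keys(d)

        inside = set(subtree_keys(target))
        for key, a in base.items():
            if key not in inside:
                assert asg[key] == a, key
        assert asg[target.key].name == "Forced-X"


class TestRenameAfterEdit:
    def test_noop_edit_changes_no_assignment(self, embryo):
        tree, transform, rules, seeds, base = name_embryo(embryo)
        again = s.rename_after_edit(s.build_tracks(embryo.frames), transform,
                                    rules, embryo.metadata, seeds=seeds)
        assert base == again

    def test_unlink_renames_only_the_affected_lineage(self, embryo):
        """Severing one daughter re-roots it; names outside the old parent's
        subtree are byte-identical, and incremental equals from-scratch."""
        tree, transform, rules, seeds, base = name_embryo(embryo)
        parent = tree.name_index["EMS"]
        donor = parent.last_record
        severed = parent.daughters[1]
        t_div = parent.end_time
        script = [
            s.EditCommand(s.EditKind.UNLINK, time=t_div, index=donor.index,
                          partner_time=t_div + 1,
                          partner_index=severed.first_record.index),
        ]
        result = s.edit_script(embryo.frames, script, transform=transform,
                               rules=rules, meta=embryo.metadata, seeds=seeds)

        def subtree_keys(track):
            yield track.key
            for d in track.daughters:
                yield from subtree_keys(d)

        affected = set(subtree_keys(parent))  # old EMS subtree (incl. severed)
        for key, a in result.assignments.items():
            if key not in affected:
                assert base[key].name == a.name, key
        # the severed daughter is now an unseeded root with an auto tag
        assert result.assignments[severed.key].name.startswith("Nuc-")
        # incremental renaming equals a from-scratch assignment
        scratch = s.assign_names(s.build_tracks(result.frames), transform,
                                 rules, embryo.metadata, seeds=seeds)
        assert {k: a.name for k, a in scratch.items()} == \
               {k: a.name for k, a in result.assignments.items()}

    def test_delete_then_restore_recovers_original_names(self, embryo):
        tree, transform, rules, seeds, base = name_embryo(embryo)
        parent = tree.name_index["MS"] if "MS" in tree.name_index else tree.roots[0]
        t_div = parent.end_time
        donor = parent.last_record
        d1 = parent.daughters[0].first_record
        script = [
            s.EditCommand(s.EditKind.UNLINK, time=t_div, index=donor.index,
                          partner_time=t_div + 1, partner_index=d1.index),
            s.EditCommand(s.EditKind.LINK, time=t_div, index=donor.index,
                          partner_time=t_div + 1, partner_index=d1.index),
        ]
        result = s.edit_script(embryo.frames, script, transform=transform,
                               rules=rules, meta=embryo.metadata, seeds=seeds)
        assert {k: a.name for k, a in result.assignments.items()} == \
               {k: a.name for k, a in base.items()}
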