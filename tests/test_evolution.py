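"""Trajectory classification, patterns, parallel evolution, clonality."""

import pytest

from mmct.evolution import (
    DEFAULT_PATHWAYS,
    TrajectoryConfig,
    classify_paired_variant,
    classify_patient_pattern,
    classify_trajectory,
    clonality_call,
    detect_parallel_evolution,
    presence_call,
    summarize_pathways_and_druggable,
)
from mmct.variant_filter import run_cascade
from mmct.synthetic_data import SimulationConfig, simulate_cohort

from conftest import make_obs

CFG = TrajectoryConfig()


def traj(first, paired, gene="KRAS", cdna="c.35G>A", pos=100,
         config=CFG):
    o1 = make_obs(sample=1, gene=gene, cdna=cdna, pos=pos,
                  depth=first[1], alt_reads=first[0])
    o2 = make_obs(sample=2, gene=gene, cdna=cdna, pos=pos,
                  depth=paired[1], alt_reads=paired[0])
    return classify_trajectory(o1, o2, config)


class TestPresence:
    @pytest.mark.parametrize("alt, depth, expected", [
        (0, 250, False),
        (30, 250, True),         # vaf 0.12
        (3, 150, True),          # exactly the floors: 3 reads, vaf 0.02
        (2, 100, False),         # below read floor
        (3, 200, False),         # vaf 0.015 below vaf floor
    ])
    def test_read_and_vaf_floors(self, alt, depth, expected):
        assert presence_call(make_obs(depth=depth, alt_reads=alt), CFG) is expected


class TestTrajectoryClasses:
    def test_disappearing_variant_is_lost(self):
        assert traj((60, 200), (0, 210)).trajectory_class == "lost"

    def test_new_variant_is_acquired(self):
        assert traj((0, 220), (55, 220)).trajectory_class == "acquired"

    def test_large_significant_increase_is_expanded(self):
        # 30/200 (0.15) -> 90/200 (0.45): z-test p ~ 6e-11, delta 0.30
        assert traj((30, 200), (90, 200)).trajectory_class == "expanded"

    def test_small_change_is_stable(self):
        # 60/200 (0.30) -> 66/200 (0.33): delta 0.03 below the effect floor
        assert traj((60, 200), (66, 200)).trajectory_class == "stable"

    def test_large_but_insignificant_change_is_stable(self):
        # shallow depth: delta 0.17 but the z-test cannot reject at n=6
        t = traj((2, 6), (3, 6), config=TrajectoryConfig(
            presence_alt_reads_min=1, presence_vaf_min=0.01))
        assert t.trajectory_class == "stable"

    def test_decline_is_symmetric_to_expansion(self):
        assert traj((90, 200), (30, 200)).trajectory_class == "declined"

    def test_absent_at_both_timepoints_raises(self):
        with pytest.raises(ValueError, match="absent at both"):
            traj((0, 200), (0, 200))

    def test_mismatched_keys_raise(self):
        o1 = make_obs(pos=1)
        o2 = make_obs(pos=2, sample=2)
        with pytest.raises(ValueError, match="mismatched"):
            classify_trajectory(o1, o2)

    def test_swap_symmetry(self):
        """Swapping the samples maps acquired<->lost, expanded<->declined
        and fixes stable."""
        cases = [((0, 220), (55, 220)), ((60, 200), (0, 210)),
                 ((30, 200), (90, 200)), ((90, 200), (30, 200)),
                 ((60, 200), (66, 200))]
        swap = {"acquired": "lost", "lost": "acquired",
                "expanded": "declined", "declined": "expanded",
                "stable": "stable"}
        for first, paired in cases:
            fwd = traj(first, paired).trajectory_class
            o1 = make_obs(sample=1, depth=paired[1], alt_reads=paired[0])
            o2 = make_obs(sample=2, depth=first[1], alt_reads=first[0])
            rev = classify_trajectory(o1, o2).trajectory_class
            assert rev == swap[fwd]


class TestPatientPattern:
    def _trajs(self, spec):
        out = []
        shapes = {"acquired": ((0, 200), (60, 200)),
                  "lost": ((60, 200), (0, 200)),
                  "stable": ((60, 200), (62, 200))}
        pos = 1
        for klass, n in spec.items():
            for _ in range(n):
                out.append(traj(*shapes[klass], pos=pos))
                pos += 1
        return out

    @pytest.mark.parametrize("spec, expected", [
        ({"acquired": 1, "lost": 1, "stable": 3}, "branching"),
        ({"acquired": 2, "lost": 0}, "acquisition"),
        ({"acquired": 0, "lost": 2, "stable": 1}, "loss"),
        ({"acquired": 0, "lost": 0, "stable": 4}, "stable"),
    ])
    def test_pattern_table(self, spec, expected):
        assert classify_patient_pattern(self._trajs(spec)).pattern == expected

    def test_empty_trajectories_raise(self):
        with pytest.raises(ValueError):
            classify_patient_pattern([])

    def test_patterns_partition_patients(self, recovery_cohort):
        cohort, _ = recovery_cohort
        retained, _ = run_cascade(cohort)
        patterns = []
        for pid, pvs in retained.items():
            trajs = [classify_paired_variant(pv) for pv in pvs]
            patterns.append(classify_patient_pattern(trajs).pattern)
        from collections import Counter
        counts = Counter(patterns)
        assert sum(counts.values()) == len(retained)
        assert set(counts) <= {"branching", "acquisition", "loss", "stable"}

    def test_classes_partition_variants(self, small_cohort):
        cohort, _ = small_cohort
        retained, _ = run_cascade(cohort)
        for pvs in retained.values():
            for pv in pvs:
                t = classify_paired_variant(pv)
                assert t.trajectory_class in (
                    "acquired", "lost", "expanded", "declined", "stable")


class TestParallelEvolution:
    def test_two_tp53_variants_in_same_sample_is_one_event(self):
        t1 = traj((0, 200), (40, 200), gene="TP53", cdna="c.550G>C", pos=10)
        t2 = traj((0, 200), (35, 200), gene="TP53", cdna="c.814G>A", pos=20)
        events = detect_parallel_evolution([t1, t2])
        assert len(events) == 1
        gene, keys = events[0]
        assert gene == "TP53" and len(keys) == 2

    def test_single_variant_gene_no_event(self):
        assert detect_parallel_evolution([traj((0, 200), (40, 200))]) == []

    def test_different_genes_no_event(self):
        t1 = traj((0, 200), (40, 200), gene="TP53", pos=10)
        t2 = traj((0, 200), (35, 200), gene="KRAS", pos=20)
        assert detect_parallel_evolution([t1, t2]) == []

    def test_acquired_only_flag_excludes_co_present_pairs(self):
        stable1 = traj((50, 200), (52, 200), gene="RYR2", pos=10)
        stable2 = traj((40, 200), (42, 200), gene="RYR2", pos=20)
        assert len(detect_parallel_evolution([stable1, stable2])) == 1
        strict = TrajectoryConfig(parallel_requires_acquired=True)
        assert detect_parallel_evolution([stable1, stable2], strict) == []


class TestClonality:
    def test_subclonal_to_clonal_transition(self):
        t = traj((36, 200), (104, 200))   # vafs 0.18 -> 0.52
        assert t.clonality == ("subclonal", "clonal")
        assert t.clonal_transition

    def test_clonal_at_both_no_transition(self):
        t = traj((90, 200), (96, 200))    # 0.45 -> 0.48
        assert t.clonality == ("clonal", "clonal")
        assert not t.clonal_transition

    def test_boundary_vaf_040_is_clonal(self):
        t = traj((80, 200), (80, 200))    # exactly 0.40
        assert t.clonality == ("clonal", "clonal")

    def test_absent_timepoint_labeled_absent(self):
        t = traj((0, 200), (90, 200))
        assert t.clonality[0] == "absent"


class TestSummaries:
    def test_kras_patient_flags_mapk(self):
        trajs = {"P1": [traj((60, 200), (62, 200), gene="KRAS")]}
        pathway, _ = summarize_pathways_and_druggable(trajs)
        assert bool(pathway.loc[0, "MAPK_ERK"])
        assert not bool(pathway.loc[0, "DNA_repair"])

    def test_empty_druggable_lists_give_empty_table(self):
        trajs = {"P1": [traj((60, 200), (62, 200))]}
        _, druggable = summarize_pathways_and_druggable(trajs, druggable_lists={})
        assert druggable.empty

    def test_counts_equal_set_algebra_oracle(self, small_cohort):
        cohort, _ = small_cohort
        retained, _ = run_cascade(cohort)
        trajs = {pid: [classify_paired_variant(pv) for pv in pvs]
                 for pid, pvs in retained.items()}
        lists = {"oncokb": {"KRAS", "BRAF", "ALK", "SF3B1"}}
        _, table = summarize_pathways_and_druggable(trajs, druggable_lists=lists)
        flat = [t for ts in trajs.values() for t in ts
                if t.gene in lists["oncokb"]]
        assert table.loc[0, "n_shared"] == sum(
            t.presence == (True, True) for t in flat)
        assert table.loc[0, "n_acquired"] == sum(
            t.trajectory_class == "acquired" for t in flat)

    def test_variant_class_recovery_on_ground_truth(self, recovery_cohort):
        """At panel depth with CCF changes >= 0.30 or exactly 0, at least
        95% of core variants recover their true class."""
        cohort, truth = recovery_cohort
        retained, _ = run_cascade(cohort)
        vt = truth.variants
        vt = vt[vt.kind == "core"].set_index(
            ["patient_id", "chrom", "pos", "ref", "alt"])
        ok = total = 0
        for pid, pvs in retained.items():
            for pv in pvs:
                idx = (pid, *pv.key)
                if idx not in vt.index:
                    continue
                t = classify_paired_variant(pv)
                total += 1
                ok += t.trajectory_class == vt.loc[idx, "true_class"]
        assert total > 900
        assert ok / total >= 0.95

    def test_pattern_recovery_on_ground_truth(self, recovery_cohort):
        cohort, truth = recovery_cohort
        retained, _ = run_cascade(cohort)
        pat = truth.patients.set_index("patient_id")["pattern"]
        ok = total = 0
        for pid, pvs in retained.items():
            trajs = [classify_paired_variant(pv) for pv in pvs]
            total += 1
            ok += classify_patient_pattern(trajs).pattern == pat[pid]
        assert total == 200
        assert ok / total >= 0.95
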