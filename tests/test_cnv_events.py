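"""CNV region events, evolution, biallelic and double-hit detection."""

import numpy as np
import pytest

from mmct.cohort_model import CNVSegment
from mmct.cnv_events import (
    CNVConfig,
    CNVEventSet,
    DEL1P_SUBREGIONS,
    EVENT_LABELS,
    HitEvent,
    RegionDef,
    call_events,
    classify_cnv_evolution,
    default_regions,
    detect_biallelic,
    detect_double_hit,
    region_log2,
)
from mmct.evolution import classify_trajectory

from conftest import make_obs

CFG = CNVConfig()
REGIONS = default_regions()
BY_LABEL = {r.label: r for r in REGIONS}


def seg_for(label, log2, frac=1.0):
    r = BY_LABEL[label]
    end = r.start + int(r.length * frac)
    return CNVSegment(r.chrom, r.start, end, log2)


class TestRegionLog2:
    def test_full_span_returns_segment_value(self):
        r = BY_LABEL["del17p"]
        value, cov = region_log2([seg_for("del17p", -0.6)], r, CFG)
        assert value == pytest.approx(-0.6)
        assert cov == pytest.approx(1.0)

    def test_weighted_mean_of_half_covering_segments(self):
        r = BY_LABEL["del17p"]
        mid = (r.start + r.end) // 2
        segs = [CNVSegment(r.chrom, r.start, mid, -0.6),
                CNVSegment(r.chrom, mid, r.end, 0.0)]
        value, cov = region_log2(segs, r, CFG)
        assert value == pytest.approx(-0.3, abs=1e-6)
        assert cov == pytest.approx(1.0)

    def test_no_overlap_returns_missing(self):
        value, cov = region_log2(
            [CNVSegment("chr9", 0, 1000, -1.0)], BY_LABEL["del17p"], CFG)
        assert value is None and cov == 0.0

    def test_sliver_coverage_is_missing(self):
        value, cov = region_log2(
            [seg_for("del17p", -0.9, frac=0.2)], BY_LABEL["del17p"], CFG)
        assert value is None
        assert cov == pytest.approx(0.2, abs=0.01)


class TestCallEvents:
    def test_single_deleted_subregion_fires_composite_del1p(self):
        segs = [seg_for("del1p_1p22_1", -0.5),
                seg_for("del1p_1p12", 0.0), seg_for("del1p_1p32_3", 0.0)]
        events = call_events(segs, config=CFG)
        assert events["del1p"] is True

    def test_neutral_profile_fires_nothing(self):
        segs = [seg_for(label, 0.02 * (i % 2 * 2 - 1))
                for i, label in enumerate(BY_LABEL)]
        events = call_events(segs, config=CFG)
        assert all(v is False for v in events.events.values())

    def test_deleted_17p_fires_del17p(self):
        events = call_events([seg_for("del17p", -0.6)], config=CFG)
        assert events["del17p"] is True

    def test_uncovered_regions_are_missing(self):
        events = call_events([seg_for("del17p", -0.6)], config=CFG)
        assert events["del13q"] is None

    def test_gain_threshold(self):
        assert call_events([seg_for("gain1q21", 0.25)], config=CFG)["gain1q21"] is True
        assert call_events([seg_for("gain1q21", 0.15)], config=CFG)["gain1q21"] is False

    def test_del1p_composite_equals_or_of_subregions(self, rng):
        """Metamorphic: on random segment sets, the composite always equals
        the three-valued OR of its sub-region calls."""
        for _ in range(200):
            segs = []
            for label in DEL1P_SUBREGIONS:
                u = rng.uniform()
                if u < 0.2:
                    continue   # leave uncovered
                frac = 1.0 if u < 0.8 else float(rng.uniform(0.1, 0.45))
                segs.append(seg_for(label, float(rng.normal(-0.15, 0.3)), frac))
            events = call_events(segs, config=CFG)
            subs = []
            for label in DEL1P_SUBREGIONS:
                value, _ = region_log2(segs, BY_LABEL[label], CFG)
                subs.append(None if value is None
                            else value <= CFG.loss_log2_max)
            if any(s is True for s in subs):
                expected = True
            elif any(s is None for s in subs):
                expected = None
            else:
                expected = False
            assert events["del1p"] is expected

    def test_shrinking_log2_magnitudes_never_creates_events(self, rng):
        """Multiplying all log2 values by s in (0,1) can only switch events
        off, never on."""
        for _ in range(100):
            segs = [seg_for(label, float(rng.normal(0, 0.5)))
                    for label in BY_LABEL]
            s = float(rng.uniform(0.1, 0.9))
            shrunk = [CNVSegment(g.chrom, g.start, g.end, g.log2 * s)
                      for g in segs]
            before = call_events(segs, config=CFG).events
            after = call_events(shrunk, config=CFG).events
            for label in EVENT_LABELS:
                if after[label] is True:
                    assert before[label] is True


class TestCnvEvolution:
    def _events(self, **kwargs):
        base = {label: False for label in EVENT_LABELS}
        base.update(kwargs)
        return CNVEventSet(events=base, fish={})

    def test_gain_appearing_is_acquired(self):
        transitions, stable, _ = classify_cnv_evolution(
            self._events(), self._events(gain1q21=True))
        assert transitions["gain1q21"] == "acquired"
        assert not stable

    def test_gain_disappearing_is_lost(self):
        transitions, _, _ = classify_cnv_evolution(
            self._events(gain1q21=True), self._events())
        assert transitions["gain1q21"] == "lost"

    def test_identical_sets_are_stable_profile(self):
        same = self._events(del17p=True)
        transitions, stable, _ = classify_cnv_evolution(same, same)
        assert stable
        assert transitions["del17p"] == "stable_present"

    def test_missing_regions_excluded_and_reported(self):
        transitions, stable, uninformative = classify_cnv_evolution(
            self._events(del13q=None), self._events(del13q=True))
        assert transitions["del13q"] is None
        assert "del13q" in uninformative
        assert stable


def biallelic_traj(vaf1, vaf2, gene="TP53", chrom="chr17", pos=7675001):
    o1 = make_obs(sample=1, gene=gene, chrom=chrom, pos=pos,
                  depth=200, alt_reads=int(round(vaf1 * 200)))
    o2 = make_obs(sample=2, gene=gene, chrom=chrom, pos=pos,
                  depth=200, alt_reads=int(round(vaf2 * 200)))
    return classify_trajectory(o1, o2)


class TestBiallelic:
    def test_high_vaf_neutral_locus_is_biallelic(self):
        t = biallelic_traj(0.85, 0.85)
        segs = {1: [seg_for("del17p", 0.0)], 2: [seg_for("del17p", 0.0)]}
        assert detect_biallelic(t, segs, CFG)

    def test_high_vaf_amplified_locus_is_excluded(self):
        t = biallelic_traj(0.85, 0.85)
        segs = {1: [seg_for("del17p", 0.5)], 2: [seg_for("del17p", 0.5)]}
        assert not detect_biallelic(t, segs, CFG)

    def test_below_80_percent_both_samples_is_not(self):
        t = biallelic_traj(0.79, 0.79)
        assert not detect_biallelic(t, {}, CFG)

    def test_uncovered_locus_counts_as_not_amplified(self):
        assert detect_biallelic(biallelic_traj(0.9, 0.5), {}, CFG)

    def test_monotone_in_vaf(self):
        """Raising VAF with CNV fixed can only turn the call on."""
        segs = {1: [seg_for("del17p", 0.0)], 2: [seg_for("del17p", 0.0)]}
        previous = False
        for vaf in np.linspace(0.3, 0.95, 14):
            call = detect_biallelic(biallelic_traj(float(vaf), 0.3), segs, CFG)
            assert call >= previous
            previous = call


class TestDoubleHit:
    def _events(self, fish=None, **kwargs):
        base = {label: False for label in EVENT_LABELS}
        base.update(kwargs)
        return CNVEventSet(events=base, fish=fish or {})

    def test_three_lesions_is_triple_hit(self):
        ev = self._events(del17p=True, gain1q21=True, del1p=True)
        hits = detect_double_hit(ev)
        assert [h.kind for h in hits] == ["triple_hit"]
        assert set(hits[0].lesions) == {"del17p", "gain1q21", "del1p"}

    def test_two_lesions_is_double_hit(self):
        hits = detect_double_hit(self._events(gain1q21=True, del1p=True))
        assert [h.kind for h in hits] == ["double_hit"]

    def test_fish_translocation_counts_as_lesion(self):
        ev = self._events(gain1q21=True, del1p=True, fish={"t_4_14": True})
        assert [h.kind for h in detect_double_hit(ev)] == ["triple_hit"]

    def test_del17p_with_tp53_mutation_is_tp53_double_hit(self):
        t = biallelic_traj(0.3, 0.35)
        hits = detect_double_hit(self._events(del17p=True), variants=[t],
                                 timepoint=0)
        assert any(h.kind == "tp53_double_hit" for h in hits)

    def test_single_lesion_no_hit(self):
        assert detect_double_hit(self._events(del17p=True)) == []


class TestRegionDefs:
    def test_bundled_regions_are_well_formed(self):
        labels = [r.label for r in REGIONS]
        assert len(labels) == len(set(labels)) == 7
        assert set(DEL1P_SUBREGIONS) <= set(labels)
        for r in REGIONS:
            assert r.start < r.end
            assert r.direction in ("loss", "gain")

    def test_cnv_event_recovery_on_ground_truth(self, recovery_cohort):
        """Default noise (sd 0.10) against event shifts -0.5/+0.4 recovers
        >= 98% of true event states."""
        cohort, truth = recovery_cohort
        ct = truth.cnv.set_index(["patient_id", "timepoint", "event"])["present"]
        ok = total = 0
        for pid in cohort.patients:
            for tp, sidx in zip(("first", "paired"), (1, 2)):
                ev = call_events(cohort.segments_for(pid, sidx))
                for label in EVENT_LABELS:
                    v = ev.events[label]
                    assert v is not None   # simulator covers every region
                    total += 1
                    ok += v == ct.loc[(pid, tp, label)]
        assert total == 2000
        assert ok / total >= 0.98
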