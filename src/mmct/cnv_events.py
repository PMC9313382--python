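"""Prognostic copy-number events from segment log2 ratios.

Five events are tracked per sample: del1p (a composite — deletion of at
least one of 1p12, 1p22.1, 1p32.3), gain1q21, del17p, del13q and del14q.
A region fires when the length-weighted mean log2 ratio of the segments
covering it crosses a threshold (<= -0.25 for losses, >= +0.20 for gains by
default, near CNVkit's conventional cutoffs); a region covered by less than
half its length is reported as missing rather than guessed.

Region windows ship as an editable BED-like file (GRCh38 cytoband
boundaries); "del17p / 17 monosomy" is represented by the 17p13.1 window
alone.  Translocations t(4;14), t(14;16) and t(11;14) come only from FISH
input flags — a capture panel cannot call IGH breakpoints.

The module also detects biallelic events (VAF >= 80% in at least one sample
at a non-amplified locus) and double/triple-hit co-occurrence of high-risk
lesions.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from mmct.cohort_model import CNVSegment, ClinicalRecord, VariantKey
from mmct.evolution import VariantTrajectory

REGION_LABELS = ("del1p_1p12", "del1p_1p22_1", "del1p_1p32_3",
                 "gain1q21", "del17p", "del13q", "del14q")
EVENT_LABELS = ("del1p", "gain1q21", "del17p", "del13q", "del14q")
DEL1P_SUBREGIONS = ("del1p_1p12", "del1p_1p22_1", "del1p_1p32_3")

#: High-risk lesions entering the double/triple-hit count.
HIGH_RISK_LESIONS = ("del17p", "gain1q21", "del1p", "t_4_14", "t_14_16")

TRANSITIONS = ("stable_present", "stable_absent", "acquired", "lost")


@dataclass(frozen=True)
class RegionDef:
    label: str
    chrom: str
    start: int
    end: int
    direction: str  # "loss" or "gain"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"region {self.label}: start must be < end")
        if self.direction not in ("loss", "gain"):
            raise ValueError(f"region {self.label}: direction must be loss/gain")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CNVConfig:
    loss_log2_max: float = -0.25
    gain_log2_min: float = 0.20
    amplified_log2_min: float = 0.30
    min_region_overlap: float = 0.5

    def __post_init__(self) -> None:
        if not (self.loss_log2_max < 0 < self.gain_log2_min <= self.amplified_log2_min):
            raise ValueError("need loss_log2_max < 0 < gain_log2_min <= amplified_log2_min")
        if not 0 < self.min_region_overlap <= 1:
            raise ValueError("min_region_overlap must lie in (0,1]")


@dataclass(frozen=True)
class CNVEventSet:
    """Per-sample event flags; ``None`` marks a region without adequate
    segment coverage.  The composite del1p equals the three-valued OR of its
    sub-regions (true if any true; false only if all informative sub-regions
    are false and at least one is informative ... strictly: false iff all
    three are false)."""

    events: Mapping[str, Optional[bool]]
    fish: Mapping[str, Optional[bool]]

    def __getitem__(self, label: str) -> Optional[bool]:
        return self.events[label]


def load_regions(path) -> list[RegionDef]:
    """Read region definitions from a BED-like file:
    chrom / start / end / label / direction (tab-separated, no header)."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        chrom, start, end, label, direction = line.split("\t")
        out.append(RegionDef(label=label, chrom=chrom, start=int(start),
                             end=int(end), direction=direction))
    labels = [r.label for r in out]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate region labels")
    return out


def default_regions() -> list[RegionDef]:
    """The bundled GRCh38 windows for the seven tracked regions."""
    ref = resources.files("mmct").joinpath("data/regions_grch38.bed")
    with resources.as_file(ref) as path:
        return load_regions(path)


def region_log2(segments: Sequence[CNVSegment], region: RegionDef,
                config: CNVConfig = CNVConfig(),
                ) -> tuple[Optional[float], float]:
    """Length-weighted mean log2 of segment portions intersecting the region.

    Returns ``(value, coverage_fraction)``; the value is ``None`` when less
    than ``min_region_overlap`` of the region is covered by segments.
    """
    covered = 0
    weighted = 0.0
    for seg in segments:
        if seg.chrom != region.chrom:
            continue
        ov = seg.overlap(region.start, region.end)
        if ov > 0:
            covered += ov
            weighted += ov * seg.log2
    coverage = covered / region.length
    if coverage < config.min_region_overlap or covered == 0:
        return None, coverage
    return weighted / covered, coverage


def _three_valued_or(values: Iterable[Optional[bool]]) -> Optional[bool]:
    values = list(values)
    if any(v is True for v in values):
        return True
    if any(v is None for v in values):
        return None
    return False


def call_events(segments: Sequence[CNVSegment],
                region_defs: Optional[Sequence[RegionDef]] = None,
                config: CNVConfig = CNVConfig(),
                fish: Optional[Mapping[str, Optional[bool]]] = None,
                ) -> CNVEventSet:
    """Call the five prognostic events for one sample.

    Loss regions fire iff mean log2 <= ``loss_log2_max``; gain regions iff
    >= ``gain_log2_min``; del1p is the OR of its three sub-regions.
    """
    region_defs = list(region_defs) if region_defs is not None else default_regions()
    by_label = {r.label: r for r in region_defs}
    calls: dict[str, Optional[bool]] = {}
    for label, region in by_label.items():
        value, _ = region_log2(segments, region, config)
        if value is None:
            calls[label] = None
        elif region.direction == "loss":
            calls[label] = value <= config.loss_log2_max
        else:
            calls[label] = value >= config.gain_log2_min
    events: dict[str, Optional[bool]] = {
        "del1p": _three_valued_or(calls.get(sub) for sub in DEL1P_SUBREGIONS)
    }
    for label in ("gain1q21", "del17p", "del13q", "del14q"):
        events[label] = calls.get(label)
    return CNVEventSet(events=events, fish=dict(fish or {}))


def classify_cnv_evolution(events_first: CNVEventSet,
                           events_paired: CNVEventSet,
                           ) -> tuple[dict[str, Optional[str]], bool, list[str]]:
    """Per-region transition between the paired samples.

    Returns ``(transitions, stable_profile, uninformative)``: transitions
    maps each event label to one of stable_present / stable_absent /
    acquired / lost (``None`` when either side is missing); stable_profile
    is true iff no informative region was acquired or lost; uninformative
    lists regions excluded from that judgment.
    """
    transitions: dict[str, Optional[str]] = {}
    uninformative: list[str] = []
    for label in EVENT_LABELS:
        a = events_first.events.get(label)
        b = events_paired.events.get(label)
        if a is None or b is None:
            transitions[label] = None
            uninformative.append(label)
        elif a and b:
            transitions[label] = "stable_present"
        elif not a and not b:
            transitions[label] = "stable_absent"
        elif b:
            transitions[label] = "acquired"
        else:
            transitions[label] = "lost"
    stable = all(t in ("stable_present", "stable_absent", None)
                 for t in transitions.values())
    return transitions, stable, uninformative


def locus_log2(segments: Sequence[CNVSegment], chrom: str, pos: int,
               ) -> Optional[float]:
    """log2 ratio of the segment covering a 1-based variant position, or
    ``None`` when no segment covers it."""
    start0 = pos - 1
    for seg in segments:
        if seg.chrom == chrom and seg.start <= start0 < seg.end:
            return seg.log2
    return None


def detect_biallelic(trajectory: VariantTrajectory,
                     segments_by_sample: Mapping[int, Sequence[CNVSegment]],
                     config: CNVConfig = CNVConfig()) -> bool:
    """Biallelic event: VAF >= 80% in at least one sample at a locus that is
    not amplified there (an amplified wild-type allele can inflate VAF
    without a second hit; conversely amplification of the mutant allele can
    mimic one).  A locus without segment coverage counts as not amplified.
    """
    chrom, pos, _, _ = trajectory.key
    for obs in (trajectory.obs_first, trajectory.obs_paired):
        if obs.vaf >= 0.80:
            l2 = locus_log2(segments_by_sample.get(obs.sample_index, ()), chrom, pos)
            if l2 is None or l2 < config.amplified_log2_min:
                return True
    return False


@dataclass(frozen=True)
class HitEvent:
    kind: str           # "double_hit", "triple_hit" or "tp53_double_hit"
    lesions: tuple[str, ...]


def detect_double_hit(patient_events: CNVEventSet,
                      fish_flags: Optional[Mapping[str, Optional[bool]]] = None,
                      variants: Sequence[VariantTrajectory] = (),
                      timepoint: int = 0) -> list[HitEvent]:
    """Co-occurring high-risk lesions in one sample.

    (a) counts distinct lesions among {del17p, gain1q21, del1p, t(4;14),
    t(14;16)}: two -> double-hit, three or more -> triple-hit;
    (b) flags a TP53 double-hit when del17p co-occurs with a retained TP53
    mutation present at the given timepoint.
    """
    fish = dict(fish_flags) if fish_flags is not None else dict(patient_events.fish)
    present: list[str] = []
    for lesion in HIGH_RISK_LESIONS:
        flag = (patient_events.events.get(lesion) if lesion in EVENT_LABELS
                else fish.get(lesion))
        if flag:
            present.append(lesion)
    hits: list[HitEvent] = []
    if len(present) >= 3:
        hits.append(HitEvent("triple_hit", tuple(present)))
    elif len(present) == 2:
        hits.append(HitEvent("double_hit", tuple(present)))
    if patient_events.events.get("del17p"):
        tp53_mut = [v for v in variants
                    if v.gene == "TP53" and v.presence[timepoint]]
        if tp53_mut:
            hits.append(HitEvent("tp53_double_hit",
                                 ("del17p",) + tuple(v.cdna for v in tp53_mut)))
    return hits
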