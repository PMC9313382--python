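"""Synthetic longitudinal myeloma cohorts with ground-truth labels.

The generator emulates the data structure the pipeline consumes: per patient
a (first, paired) pair of bone-marrow samples with post-sorting purity,
somatic variants whose cancer-cell-fraction (CCF) trajectories realize one
of four evolution patterns, binomial read counts at panel-like overdispersed
depth (mean 267x), annotation verdicts with configurable error rates,
common-SNP contaminants and curated-benign decoys for the filter cascade,
copy-number segments with Gaussian log2 noise around event shifts, clinical
staging inputs, and survival times exponential per R-ISS'' risk group with
independent uniform censoring.

Observed VAF expectation is purity x CCF / 2 (diploid heterozygous
assumption); biallelic fixtures override this with a high VAF directly,
standing in for copy-neutral LOH.  A single global seed governs all draws;
per-patient substreams are derived deterministically so changing the patient
count does not reshuffle earlier patients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from mmct.cohort_model import (
    CNVSegment,
    ClinicalRecord,
    Cohort,
    PREDICTOR_LABELS,
    CANCER_SPECIFIC_PREDICTORS,
    POPULATION_DBS,
    SampleMeta,
    SurvivalRecord,
    VariantAnnotation,
    VariantObservation,
)
from mmct.cnv_events import DEL1P_SUBREGIONS, EVENT_LABELS, RegionDef, default_regions
from mmct.staging_survival import compute_iss, compute_riss, high_risk_cytogenetics

# --------------------------------------------------------------------------
# Gene catalogue (GRCh38 representative coding positions)

GENE_LOCI: dict[str, tuple[str, int]] = {
    "KRAS": ("chr12", 25_225_000), "TP53": ("chr17", 7_670_000),
    "BRAF": ("chr7", 140_753_000), "EGFR": ("chr7", 55_019_000),
    "FGFR3": ("chr4", 1_793_000), "DUSP2": ("chr2", 96_143_000),
    "ATM": ("chr11", 108_223_000), "ATR": ("chr3", 142_449_000),
    "FANCA": ("chr16", 89_737_000), "BRCA2": ("chr13", 32_315_000),
    "BRIP1": ("chr17", 61_679_000), "MLH1": ("chr3", 36_993_000),
    "ARID1A": ("chr1", 26_693_000), "ARID2": ("chr12", 45_729_000),
    "CREBBP": ("chr16", 3_725_000), "EP300": ("chr22", 41_092_000),
    "KMT2B": ("chr19", 35_718_000), "KMT2C": ("chr7", 152_134_000),
    "KMT2D": ("chr12", 49_018_000), "NCOR2": ("chr12", 124_324_000),
    "PRDM9": ("chr5", 23_507_000), "PABPC1": ("chr8", 100_702_000),
    "RYR2": ("chr1", 237_042_000), "ZFHX3": ("chr16", 72_787_000),
    "CYLD": ("chr16", 50_742_000), "DNAH5": ("chr5", 13_720_000),
    "DNAH11": ("chr7", 21_543_000), "EDC4": ("chr16", 67_878_000),
    "FAT4": ("chr4", 125_316_000), "TET2": ("chr4", 105_145_000),
    "RET": ("chr10", 43_077_000), "LRP1B": ("chr2", 140_231_000),
    "SOX9": ("chr17", 72_121_000), "SF3B1": ("chr2", 197_389_000),
    "ALK": ("chr2", 29_192_000), "DNMT3A": ("chr2", 25_227_000),
    "CDKN2A": ("chr9", 21_967_000), "USP9X": ("chrX", 41_085_000),
    "CDKN1B": ("chr12", 12_715_000),
}

#: Genes recurrently mutated in myeloma — eligible for the single
#: cancer-specific-predictor rescue in the filter cascade.
RECURRENT_MM_GENES: frozenset[str] = frozenset({
    "KRAS", "TP53", "BRAF", "FGFR3", "CYLD", "ATM", "EGFR",
    "DUSP2", "PABPC1", "ZFHX3", "TET2", "ARID1A", "KMT2C",
})

DRUGGABLE_ONCOKB: frozenset[str] = frozenset({
    "KRAS", "BRAF", "ALK", "SF3B1", "ARID1A", "CDKN2A", "FGFR3", "EGFR"})
DRUGGABLE_TARGET: frozenset[str] = frozenset({
    "KRAS", "BRAF", "ALK", "ATR", "DNMT3A", "TP53", "ATM", "RET",
    "EGFR", "FGFR3"})

_BASES = ("A", "C", "G", "T")
PATTERNS = ("branching", "acquisition", "loss", "stable")


# --------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the simulated cohort.

    Defaults mirror the cohort the pipeline is designed for: 30 patients,
    mean panel depth 267x, purity 0.82-0.98, pattern frequencies 8/11/7/4
    (branching/acquisition/loss/stable), a median of 5 variants per patient
    (range 2-33), and PFS / OS'' / OS' medians of 11/21/53 months for
    R-ISS'' 1-or-2 versus 3/9/37 months for R-ISS'' 3.
    """

    n_patients: int = 30
    mean_depth: float = 267.0
    depth_dispersion: float = 30.0      # negative-binomial size; larger = tighter
    purity_range: tuple[float, float] = (0.82, 0.98)
    pattern_mix: tuple[float, float, float, float] = (8 / 30, 11 / 30, 7 / 30, 4 / 30)
    variants_median: int = 5
    variants_sigma: float = 0.7          # lognormal spread of the per-patient count
    variants_min: int = 2
    variants_max: int = 33
    extra_acquired_prob: float = 0.15
    extra_lost_prob: float = 0.10
    shared_class_mix: tuple[float, float, float] = (0.25, 0.29, 0.46)  # expanded/declined/stable
    ccf_present_range: tuple[float, float] = (0.30, 1.00)
    ccf_change_range: tuple[float, float] = (0.30, 0.60)
    predictor_sensitivity: float = 0.90
    predictor_specificity: float = 0.95
    contaminant_rate: float = 0.15
    benign_rate: float = 0.10
    biallelic_rate: float = 0.04
    cnv_noise_sd: float = 0.10
    event_log2_loss: float = -0.5
    event_log2_gain: float = 0.4
    cnv_first_prob: dict = field(default_factory=lambda: {
        "del1p": 0.33, "gain1q21": 0.63, "del17p": 0.27,
        "del13q": 0.43, "del14q": 0.20})
    cnv_acquired_prob: dict = field(default_factory=lambda: {
        "del1p": 0.14, "gain1q21": 0.14, "del17p": 0.14,
        "del13q": 0.17, "del14q": 0.10})
    cnv_lost_prob: float = 0.07
    ldh_high_prob: float = 0.25
    ldh_missing_prob: float = 0.05
    median_low_risk: dict = field(default_factory=lambda: {
        "pfs": 11.0, "os2": 21.0, "os1": 53.0})
    median_high_risk: dict = field(default_factory=lambda: {
        "pfs": 3.0, "os2": 9.0, "os1": 37.0})
    censoring_rate: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.pattern_mix) - 1.0) > 1e-9:
            raise ValueError("pattern_mix must sum to 1")
        for rate in (self.contaminant_rate, self.benign_rate, self.biallelic_rate,
                     self.censoring_rate, self.predictor_sensitivity,
                     self.predictor_specificity):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0,1]")
        if self.variants_max < 2:
            raise ValueError("variants_max must allow the branching pattern "
                             "(>= 1 acquired + >= 1 lost)")
        if not self.variants_min <= self.variants_median <= self.variants_max:
            raise ValueError("need variants_min <= variants_median <= variants_max")


@dataclass
class GroundTruth:
    """Truth tables keyed identically to the cohort outputs."""

    variants: pd.DataFrame    # one row per (patient, variant key)
    patients: pd.DataFrame    # one row per patient
    cnv: pd.DataFrame         # one row per (patient, timepoint, event label)


# --------------------------------------------------------------------------
# Read-level simulation


def simulate_reads(true_vaf: float, rng: np.random.Generator,
                   mean_depth: float = 267.0, dispersion: float = 30.0,
                   ) -> tuple[int, int]:
    """Draw (depth, alt_reads): depth from an overdispersed negative-binomial
    around ``mean_depth``, alt reads binomial at ``true_vaf``."""
    if not 0.0 <= true_vaf <= 1.0:
        raise ValueError(f"true_vaf outside [0,1]: {true_vaf}")
    p = dispersion / (dispersion + mean_depth)
    depth = int(rng.negative_binomial(dispersion, p))
    depth = max(depth, 1)
    alt = int(rng.binomial(depth, true_vaf))
    return depth, alt


# --------------------------------------------------------------------------
# Survival simulation (shared with the acceptance checks)


def _uniform_censor_bound(rate_lambda: float, censor_frac: float) -> float:
    """Upper bound u of C ~ U(0, u) such that P(C < T) = censor_frac for
    exponential T with hazard ``rate_lambda``."""
    if censor_frac <= 0:
        return math.inf

    def frac(x: float) -> float:  # censored fraction as a function of lambda*u
        return (1.0 - math.exp(-x)) / x - censor_frac

    x = brentq(frac, 1e-9, 1e4)
    return x / rate_lambda


def simulate_exponential_survival(n: int, median_months: float,
                                  censoring: float, rng: np.random.Generator,
                                  ) -> tuple[np.ndarray, np.ndarray]:
    """Exponential event times with the given median and independent uniform
    censoring calibrated to the requested expected censored fraction."""
    lam = math.log(2) / median_months
    t = rng.exponential(1.0 / lam, size=n)
    if censoring <= 0:
        return t, np.ones(n, dtype=bool)
    u = _uniform_censor_bound(lam, censoring)
    c = rng.uniform(0.0, u, size=n)
    observed = np.minimum(t, c)
    events = t <= c
    return observed, events


def simulate_two_group_survival(n_per_arm: int, median_low: float, true_hr: float,
                                censoring: float, rng: np.random.Generator,
                                ) -> pd.DataFrame:
    """Two-arm proportional-hazards data: the high-risk arm's hazard is
    ``true_hr`` times the low-risk arm's.  Returns time/event/group."""
    t0, e0 = simulate_exponential_survival(n_per_arm, median_low, censoring, rng)
    t1, e1 = simulate_exponential_survival(n_per_arm, median_low / true_hr,
                                           censoring, rng)
    return pd.DataFrame({
        "time": np.concatenate([t0, t1]),
        "event": np.concatenate([e0, e1]).astype(int),
        "group": np.repeat([0, 1], n_per_arm)})


# --------------------------------------------------------------------------
# Cohort simulation


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _draw_pattern(rng: np.random.Generator, mix) -> str:
    return PATTERNS[rng.choice(len(PATTERNS), p=np.asarray(mix, dtype=float))]


def _n_variants(rng: np.random.Generator, cfg: SimulationConfig, floor: int) -> int:
    n = int(round(float(rng.lognormal(math.log(cfg.variants_median),
                                      cfg.variants_sigma))))
    return int(np.clip(n, max(cfg.variants_min, floor), cfg.variants_max))


def _assign_classes(rng: np.random.Generator, cfg: SimulationConfig,
                    pattern: str, n: int) -> list[str]:
    required = {"branching": ["acquired", "lost"],
                "acquisition": ["acquired"],
                "loss": ["lost"],
                "stable": []}[pattern]
    if n < len(required):
        raise ValueError(f"infeasible: {n} variants cannot realize {pattern}")
    classes = list(required)
    mix = np.asarray(cfg.shared_class_mix, dtype=float)
    mix = mix / mix.sum()
    for _ in range(n - len(required)):
        u = rng.uniform()
        if pattern in ("branching", "acquisition") and u < cfg.extra_acquired_prob:
            classes.append("acquired")
        elif pattern in ("branching", "loss") and u < cfg.extra_acquired_prob + cfg.extra_lost_prob:
            classes.append("lost")
        else:
            classes.append(["expanded", "declined", "stable"][
                rng.choice(3, p=mix)])
    rng.shuffle(classes)
    return classes


def _true_ccfs(rng: np.random.Generator, cfg: SimulationConfig,
               klass: str) -> tuple[float, float]:
    lo, hi = cfg.ccf_present_range
    dlo, dhi = cfg.ccf_change_range
    if klass == "acquired":
        return 0.0, float(rng.uniform(lo, hi))
    if klass == "lost":
        return float(rng.uniform(lo, hi)), 0.0
    if klass == "expanded":
        c1 = float(rng.uniform(lo, hi - dlo))
        return c1, float(min(1.0, c1 + rng.uniform(dlo, dhi)))
    if klass == "declined":
        c1 = float(rng.uniform(lo + dlo, hi))
        return c1, float(max(0.05, c1 - rng.uniform(dlo, dhi)))
    c = float(rng.uniform(lo, hi))
    return c, c


def _random_variant_key(rng: np.random.Generator, gene: str,
                        used: set) -> tuple[str, int, str, str, str]:
    chrom, base = GENE_LOCI[gene]
    while True:
        offset = int(rng.integers(0, 60_000))
        pos = base + offset
        ref, alt = rng.choice(len(_BASES), size=2, replace=False)
        key = (chrom, pos, _BASES[ref], _BASES[alt])
        if key not in used:
            used.add(key)
            cdna = f"c.{offset + 1}{_BASES[ref]}>{_BASES[alt]}"
            return chrom, pos, _BASES[ref], _BASES[alt], cdna


def _somatic_annotation(rng: np.random.Generator, cfg: SimulationConfig,
                        gene: str, benign_label: bool) -> VariantAnnotation:
    """Annotation for a truly pathogenic somatic variant: rare or absent in
    population databases, mostly-pathogenic predictor verdicts."""
    pop = {}
    for db in POPULATION_DBS:
        if rng.uniform() < 0.5:
            pop[db] = None
        else:
            pop[db] = float(rng.uniform(0.0, 0.002))
    verdicts = {}
    for p in PREDICTOR_LABELS:
        if rng.uniform() < cfg.predictor_sensitivity:
            verdicts[p] = "pathogenic"
        else:
            verdicts[p] = "benign" if rng.uniform() < 0.5 else "missing"
    acmg = ("likely_benign" if benign_label and rng.uniform() < 0.5
            else "benign" if benign_label
            else ["vus", "likely_pathogenic", "pathogenic"][rng.choice(3)])
    sources = set()
    if gene in DRUGGABLE_ONCOKB:
        sources.add("oncokb")
    if gene in DRUGGABLE_TARGET:
        sources.add("target")
    return VariantAnnotation(
        pop_af=pop, predictor_verdict=verdicts, acmg_class=acmg,
        recurrent_mm_gene=gene in RECURRENT_MM_GENES,
        druggable_sources=frozenset(sources))


def _contaminant_annotation(rng: np.random.Generator, cfg: SimulationConfig,
                            gene: str) -> VariantAnnotation:
    """A common germline SNP: at least one database AF >= 1%."""
    pop = {db: float(rng.uniform(0.0, 0.005)) for db in POPULATION_DBS}
    hot = POPULATION_DBS[rng.choice(len(POPULATION_DBS))]
    pop[hot] = float(rng.uniform(0.01, 0.30))
    verdicts = {p: ("benign" if rng.uniform() < cfg.predictor_specificity
                    else "pathogenic") for p in PREDICTOR_LABELS}
    return VariantAnnotation(
        pop_af=pop, predictor_verdict=verdicts, acmg_class="benign",
        recurrent_mm_gene=gene in RECURRENT_MM_GENES)


_REGION_BY_LABEL: dict[str, RegionDef] = {r.label: r for r in default_regions()}

_BACKGROUND_WINDOWS = [
    ("chr2", 20_000_000, 60_000_000), ("chr3", 30_000_000, 70_000_000),
    ("chr5", 10_000_000, 40_000_000), ("chr8", 90_000_000, 120_000_000),
    ("chr12", 20_000_000, 55_000_000), ("chr16", 40_000_000, 75_000_000),
]
# NB: TP53 falls inside the del17p region segment, so biallelic locus queries
# on chr17 resolve against that segment's log2.


def _cnv_truth_for_patient(rng: np.random.Generator, cfg: SimulationConfig,
                           ) -> dict[str, tuple[bool, bool]]:
    """Draw per-event (first, paired) presence for the five tracked events."""
    truth = {}
    for label in EVENT_LABELS:
        p1 = cfg.cnv_first_prob[label]
        p_acq = cfg.cnv_acquired_prob[label]
        first = bool(rng.uniform() < p1)
        if first:
            paired = not bool(rng.uniform() < cfg.cnv_lost_prob)
        else:
            paired = bool(rng.uniform() < p_acq / max(1e-9, 1.0 - p1))
        truth[label] = (first, paired)
    return truth


def _segments_for_sample(rng: np.random.Generator, cfg: SimulationConfig,
                         events: dict[str, bool], del1p_sub: str,
                         ) -> list[CNVSegment]:
    segs: list[CNVSegment] = []
    for label, region in _REGION_BY_LABEL.items():
        event_label = "del1p" if label in DEL1P_SUBREGIONS else label
        fired = events.get(event_label, False)
        if event_label == "del1p":
            fired = fired and label == del1p_sub
        shift = 0.0
        if fired:
            shift = (cfg.event_log2_gain if region.direction == "gain"
                     else cfg.event_log2_loss)
        log2 = float(rng.normal(shift, cfg.cnv_noise_sd))
        segs.append(CNVSegment(chrom=region.chrom, start=region.start,
                               end=region.end, log2=log2,
                               n_markers=max(1, region.length // 1_000_000)))
    for chrom, start, end in _BACKGROUND_WINDOWS:
        log2 = float(rng.normal(0.0, cfg.cnv_noise_sd))
        segs.append(CNVSegment(chrom=chrom, start=start, end=end, log2=log2,
                               n_markers=max(1, (end - start) // 1_000_000)))
    return segs


def _draw_response(rng: np.random.Generator, pattern: str) -> str:
    p_good = {"loss": 0.70, "acquisition": 0.10}.get(pattern, 0.40)
    if rng.uniform() < p_good:
        return "CR" if rng.uniform() < 0.4 else "VGPR"
    return ["PR", "SD", "PD"][rng.choice(3, p=[0.6, 0.25, 0.15])]


def simulate_cohort(config: SimulationConfig = SimulationConfig(),
                    ) -> tuple[Cohort, GroundTruth]:
    """Generate a complete cohort plus ground truth under ``config``.

    Each patient gets a true evolution pattern, variant CCF trajectories
    consistent with it, read counts, annotations (including common-SNP
    contaminants and curated-benign decoys beyond the pattern-defining set),
    CNV segments, staging inputs and survival times.  One whitelisted
    KMT2C c.1173C>A likely-benign variant is injected into the first patient
    of every cohort.  A fixed seed yields identical output.
    """
    cfg = config
    cohort = Cohort()
    gene_pool = sorted(GENE_LOCI)
    variant_rows: list[dict] = []
    patient_rows: list[dict] = []
    cnv_rows: list[dict] = []

    for i in range(cfg.n_patients):
        rng = _patient_rng(cfg.seed, i)
        pid = f"P{i + 1:03d}"
        purity = (float(rng.uniform(*cfg.purity_range)),
                  float(rng.uniform(*cfg.purity_range)))
        cohort.add_sample(SampleMeta(pid, 1, "Dx", purity[0]))
        cohort.add_sample(SampleMeta(pid, 2, "PD", purity[1]))

        pattern = _draw_pattern(rng, cfg.pattern_mix)
        floor = 2 if pattern == "branching" else 1
        n_core = _n_variants(rng, cfg, floor)
        classes = _assign_classes(rng, cfg, pattern, n_core)

        used_keys: set = set()
        specs: list[tuple[str, str, bool, bool]] = []  # (class, kind, benign, contaminant)
        for klass in classes:
            specs.append((klass, "core", False, False))
        n_extra_contaminant = int(rng.binomial(n_core + 2, cfg.contaminant_rate))
        n_extra_benign = int(rng.binomial(n_core + 2, cfg.benign_rate))
        for _ in range(n_extra_contaminant):
            specs.append(("stable", "contaminant", False, True))
        for _ in range(n_extra_benign):
            specs.append(("stable", "benign", True, False))
        if i == 0:
            specs.append(("stable", "whitelist", True, False))

        for klass, kind, benign, contaminant in specs:
            if kind == "whitelist":
                gene = "KMT2C"
                chrom, base = GENE_LOCI[gene]
                pos = base + 1172
                ref, alt, cdna = "C", "A", "c.1173C>A"
                key = (chrom, pos, ref, alt)
                used_keys.add(key)
            else:
                gene = gene_pool[rng.choice(len(gene_pool))]
                chrom, pos, ref, alt, cdna = _random_variant_key(rng, gene, used_keys)
                key = (chrom, pos, ref, alt)

            if contaminant:
                ccf1 = ccf2 = None          # germline: VAF ~ 0.5 regardless of purity
                vafs = (0.5, 0.5)
                cohort.annotations[key] = _contaminant_annotation(rng, cfg, gene)
            else:
                ccf1, ccf2 = _true_ccfs(rng, cfg, klass)
                vafs = (purity[0] * ccf1 / 2.0, purity[1] * ccf2 / 2.0)
                cohort.annotations[key] = _somatic_annotation(rng, cfg, gene, benign)

            biallelic = False
            if kind == "core" and klass in ("stable", "expanded") \
                    and rng.uniform() < cfg.biallelic_rate:
                # copy-neutral LOH stand-in: both-timepoint high VAF
                vafs = (float(rng.uniform(0.85, 0.95)),
                        float(rng.uniform(0.85, 0.95)))
                biallelic = True

            for sidx, vaf in zip((1, 2), vafs):
                depth, alt_reads = simulate_reads(
                    vaf, rng, cfg.mean_depth, cfg.depth_dispersion)
                cohort.add_observation(VariantObservation(
                    patient_id=pid, sample_index=sidx, chrom=chrom, pos=pos,
                    ref=ref, alt=alt, gene=gene, cdna=cdna, depth=depth,
                    alt_reads=alt_reads,
                    vaf=alt_reads / depth if depth else 0.0))

            variant_rows.append({
                "patient_id": pid, "chrom": chrom, "pos": pos, "ref": ref,
                "alt": alt, "gene": gene, "cdna": cdna, "kind": kind,
                "true_class": klass if kind == "core" else "n/a",
                "ccf_first": ccf1 if ccf1 is not None else np.nan,
                "ccf_paired": ccf2 if ccf2 is not None else np.nan,
                "true_pathogenic": kind in ("core",),
                "contaminant": contaminant, "benign_label": benign,
                "whitelisted": kind == "whitelist", "biallelic": biallelic})

        # ---- CNV truth and segments
        cnv_truth = _cnv_truth_for_patient(rng, cfg)
        del1p_sub = DEL1P_SUBREGIONS[rng.choice(3)]
        for tp, sidx in (("first", 1), ("paired", 2)):
            events_tp = {label: cnv_truth[label][0 if tp == "first" else 1]
                         for label in EVENT_LABELS}
            for seg in _segments_for_sample(rng, cfg, events_tp, del1p_sub):
                cohort.add_segment(pid, sidx, seg)
            for label in EVENT_LABELS:
                cnv_rows.append({"patient_id": pid, "timepoint": tp,
                                 "event": label, "present": events_tp[label]})

        # ---- clinical, staging and survival
        stages = {}
        clin_values = {}
        for tp, sidx in (("first", 1), ("paired", 2)):
            albumin = float(rng.lognormal(math.log(3.8), 0.15))
            b2m = float(rng.lognormal(math.log(4.0), 0.5))
            u = rng.uniform()
            ldh = ("missing" if u < cfg.ldh_missing_prob
                   else "high" if u < cfg.ldh_missing_prob + cfg.ldh_high_prob
                   else "normal")
            fish = {
                "del17p": cnv_truth["del17p"][0 if tp == "first" else 1],
                "t_4_14": bool(rng.uniform() < 0.17) if tp == "first" else None,
                "t_14_16": bool(rng.uniform() < 0.05) if tp == "first" else None,
                "t_11_14": bool(rng.uniform() < 0.07),
                "igh_other": bool(rng.uniform() < 0.27),
            }
            if tp == "paired":  # FISH translocations are clonal and persist
                first_fish = clin_values[("first", "fish")]
                fish["t_4_14"] = first_fish["t_4_14"]
                fish["t_14_16"] = first_fish["t_14_16"]
            iss = compute_iss(albumin, b2m)
            riss = compute_riss(iss, high_risk_cytogenetics(fish), ldh)
            stages[tp] = (iss, riss)
            clin_values[(tp, "albumin")] = albumin
            clin_values[(tp, "b2m")] = b2m
            clin_values[(tp, "ldh")] = ldh
            clin_values[(tp, "fish")] = fish

        response = _draw_response(rng, pattern)
        high_risk = stages["paired"][1] == "III"
        med_hi, med_lo = cfg.median_high_risk, cfg.median_low_risk
        meds = med_hi if high_risk else med_lo
        pfs_t, pfs_e = simulate_exponential_survival(
            1, meds["pfs"], cfg.censoring_rate, rng)
        os2_t, os2_e = simulate_exponential_survival(
            1, meds["os2"], cfg.censoring_rate, rng)
        gap = float(rng.uniform(6.0, 36.0))   # months between the two samples
        surv = SurvivalRecord(
            pfs_months=float(pfs_t[0]), pfs_event=bool(pfs_e[0]),
            os1_months=float(os2_t[0]) + gap, os1_event=bool(os2_e[0]),
            os2_months=float(os2_t[0]), os2_event=bool(os2_e[0]))
        cohort.survival[pid] = surv

        for tp, sidx in (("first", 1), ("paired", 2)):
            cohort.clinical[(pid, sidx)] = ClinicalRecord(
                albumin=clin_values[(tp, "albumin")],
                b2m=clin_values[(tp, "b2m")],
                ldh=clin_values[(tp, "ldh")],
                ecog=int(rng.choice(3, p=[0.5, 0.35, 0.15])),
                fish=clin_values[(tp, "fish")],
                response_between_samples=response if tp == "paired" else None,
                refractory_pi=bool(rng.uniform() < 0.25),
                refractory_imid=bool(rng.uniform() < 0.25),
                refractory_alkylator=bool(rng.uniform() < 0.15))

        patient_rows.append({
            "patient_id": pid, "pattern": pattern,
            "n_core_variants": n_core,
            "purity_first": purity[0], "purity_paired": purity[1],
            "iss_first": stages["first"][0], "riss_first": stages["first"][1],
            "iss_paired": stages["paired"][0], "riss_paired": stages["paired"][1],
            "high_risk_group": high_risk, "response": response,
            "pfs_months": surv.pfs_months, "pfs_event": surv.pfs_event,
            "os1_months": surv.os1_months, "os1_event": surv.os1_event,
            "os2_months": surv.os2_months, "os2_event": surv.os2_event})

    truth = GroundTruth(
        variants=pd.DataFrame(variant_rows),
        patients=pd.DataFrame(patient_rows),
        cnv=pd.DataFrame(cnv_rows))
    return cohort, truth


def export_truth(truth: GroundTruth, out_dir) -> dict[str, Path]:
    """Write the truth tables as TSVs keyed like the cohort outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (("variants_truth", truth.variants),
                     ("patients_truth", truth.patients),
                     ("cnv_truth", truth.cnv)):
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, na_rep=".",
                  float_format="%.6g")
        paths[name] = path
    return paths
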