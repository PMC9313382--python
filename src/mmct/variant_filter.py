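"""Somatic variant inclusion cascade for the paired-sample analysis.

Four stages applied per (patient, variant-key) unit, in order:

1. population AF: every non-missing database allele frequency < 1%
   (absence from all three databases counts as rare);
2. read support: VAF >= 10% with >= 5 alt reads in at least one member of
   the designated sample pair;
3. predictor consensus: pathogenic in >= 2 of six predictors, or — for genes
   recurrently mutated in myeloma — pathogenic in >= 1 of the four
   cancer-specific predictors (CRAVAT, CHASM, FATHMM Cancer, CScape);
4. curated-class rejection: drop variants labeled benign/likely benign,
   except whitelisted (gene, cDNA) pairs.

Thresholds and the whitelist live in :class:`FilterConfig`; boundary
semantics are strict for "<1%" and inclusive for ">=10%" and ">=5 reads".
Missing predictor verdicts count as non-pathogenic; a missing curated class
is retained (rejection requires affirmative benign evidence).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from mmct.cohort_model import (
    CANCER_SPECIFIC_PREDICTORS,
    Cohort,
    FilterReport,
    PairedVariant,
    VariantAnnotation,
    VariantObservation,
)

DEFAULT_WHITELIST: frozenset[tuple[str, str]] = frozenset({("KMT2C", "c.1173C>A")})


@dataclass(frozen=True)
class FilterConfig:
    pop_af_max: float = 0.01
    vaf_min: float = 0.10
    alt_reads_min: int = 5
    consensus_min: int = 2
    whitelist: frozenset[tuple[str, str]] = DEFAULT_WHITELIST

    def __post_init__(self) -> None:
        if not (self.pop_af_max > 0 and self.vaf_min > 0 and
                self.alt_reads_min > 0 and self.consensus_min > 0):
            raise ValueError("all filter thresholds must be > 0")
        if self.consensus_min > 6:
            raise ValueError("consensus_min cannot exceed the six predictors")


def population_af_pass(annotation: VariantAnnotation,
                       config: FilterConfig = FilterConfig()) -> bool:
    """True iff every non-missing database AF is strictly below the cutoff.

    All-missing AFs pass: absence from the population databases is evidence
    of rarity.
    """
    observed = [v for v in annotation.pop_af.values() if v is not None]
    for v in observed:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"population AF outside [0,1]: {v}")
    return all(v < config.pop_af_max for v in observed)


def vaf_support_pass(obs_first: VariantObservation,
                     obs_paired: VariantObservation,
                     config: FilterConfig = FilterConfig()) -> bool:
    """True iff at least one of the two paired observations reaches both the
    VAF floor and the alt-read floor (boundaries inclusive)."""
    if obs_first.key != obs_paired.key:
        raise ValueError(f"mismatched variant keys: {obs_first.key} vs {obs_paired.key}")
    return any(o.vaf >= config.vaf_min and o.alt_reads >= config.alt_reads_min
               for o in (obs_first, obs_paired))


def predictor_consensus_pass(annotation: VariantAnnotation,
                             config: FilterConfig = FilterConfig()) -> bool:
    """Consensus rule with the recurrent-gene exception.

    Pass iff the pathogenic-verdict count reaches ``consensus_min``, or the
    gene is recurrently mutated in myeloma and at least one cancer-specific
    predictor votes pathogenic.
    """
    if annotation.n_pathogenic() >= config.consensus_min:
        return True
    return (annotation.recurrent_mm_gene
            and annotation.n_pathogenic_cancer_specific() >= 1)


def varsome_stage(variants: Sequence[PairedVariant],
                  config: FilterConfig = FilterConfig(),
                  ) -> tuple[list[PairedVariant], list[PairedVariant]]:
    """Reject curated benign/likely-benign variants unless whitelisted.

    Returns ``(retained, rejected)``; their union is the input, disjoint.
    Variants with a missing or VUS-or-worse class are retained.
    """
    retained, rejected = [], []
    for pv in variants:
        benign = pv.annotation.acmg_class in ("benign", "likely_benign")
        if benign and (pv.gene, pv.cdna) not in config.whitelist:
            rejected.append(pv)
        else:
            retained.append(pv)
    return retained, rejected


def run_cascade(cohort: Cohort, config: FilterConfig = FilterConfig(),
                ) -> tuple[dict[str, list[PairedVariant]], FilterReport]:
    """Apply the four stages in order over every paired variant of the cohort.

    A variant passes or fails as a (patient, variant-key) unit using its
    observations at the designated pair only; additional samples of the same
    patient cannot rescue it.  Returns the retained variants grouped by
    patient and a :class:`FilterReport` with per-stage counts.
    """
    candidates: list[PairedVariant] = []
    for pid in cohort.patients:
        candidates.extend(cohort.paired_variants(pid))

    report = FilterReport()
    report.add("input", len(candidates), 0)

    stage1 = [pv for pv in candidates
              if population_af_pass(pv.annotation, config)]
    report.add("population_af", len(stage1), len(candidates) - len(stage1))

    stage2 = [pv for pv in stage1
              if vaf_support_pass(pv.obs_first, pv.obs_paired, config)]
    report.add("vaf_support", len(stage2), len(stage1) - len(stage2))

    stage3 = [pv for pv in stage2
              if predictor_consensus_pass(pv.annotation, config)]
    report.add("predictor_consensus", len(stage3), len(stage2) - len(stage3))

    stage4, rejected4 = varsome_stage(stage3, config)
    report.add("varsome", len(stage4), len(rejected4))

    by_patient: dict[str, list[PairedVariant]] = {}
    for pv in stage4:
        by_patient.setdefault(pv.patient_id, []).append(pv)
    return by_patient, report
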