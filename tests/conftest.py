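import numpy as np
import pytest

from mmct.cohort_model import (
    Cohort,
    SampleMeta,
    VariantAnnotation,
    VariantObservation,
)
from mmct.synthetic_data import SimulationConfig, simulate_cohort


def make_obs(patient="P1", sample=1, chrom="chr1", pos=100, ref="A", alt="T",
             gene="KRAS", cdna="c.35G>A", depth=200, alt_reads=60):
    return VariantObservation(
        patient_id=patient, sample_index=sample, chrom=chrom, pos=pos,
        ref=ref, alt=alt, gene=gene, cdna=cdna, depth=depth,
        alt_reads=alt_reads, vaf=alt_reads / depth if depth else 0.0)


def make_annotation(pop_af=None, pathogenic=(), benign=(), acmg="vus",
                    recurrent=False, druggable=()):
    verdicts = {p: "pathogenic" for p in pathogenic}
    verdicts.update({p: "benign" for p in benign})
    return VariantAnnotation(
        pop_af=pop_af or {}, predictor_verdict=verdicts, acmg_class=acmg,
        recurrent_mm_gene=recurrent, druggable_sources=frozenset(druggable))


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-patient simulated cohort shared by read-only tests."""
    return simulate_cohort(SimulationConfig(n_patients=12, seed=11))


@pytest.fixture(scope="session")
def recovery_cohort():
    """The 200-patient cohort used by the end-to-end recovery checks."""
    return simulate_cohort(SimulationConfig(n_patients=200, seed=123))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
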