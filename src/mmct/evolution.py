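"""Paired-sample variant trajectories and patient-level evolution patterns.

Each filtered variant of a patient is classified by comparing its read
support at the first and the paired sample:

* ``acquired`` — absent first, present at the paired sample;
* ``lost`` — present first, absent later;
* ``expanded`` / ``declined`` — present at both, with a VAF change that is
  both statistically significant (two-sided two-proportion z-test on the
  read counts) and large enough in effect size (|dVAF| >= 0.10 by default);
* ``stable`` — present at both without such a change.

Presence itself uses a small read floor (>= 3 alt reads and VAF >= 2% by
default) so that sequencing noise at ~267x depth cannot turn a stable
variant into an acquisition/loss call.

Patients are then assigned one of four progression patterns from their
acquired/lost counts: branching (>= 1 acquired and >= 1 lost), acquisition
(>= 1 acquired, none lost), loss (>= 1 lost, none acquired) or stable
(neither).  Parallel evolution flags genes carrying two independent variants
in the same sample; clonality calls use a VAF threshold (>= 40% ~ clonal
under diploid heterozygosity at high purity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from statsmodels.stats.proportion import proportions_ztest

from mmct.cohort_model import (
    PairedVariant,
    VariantKey,
    VariantObservation,
)

log = logging.getLogger("mmct")

TRAJECTORY_CLASSES = ("acquired", "lost", "expanded", "declined", "stable")
PATTERNS = ("branching", "acquisition", "loss", "stable")

#: Gene sets for the pathway summary: MAPK/ERK signaling, DNA repair and
#: epigenetic regulators recurrently altered in myeloma.
DEFAULT_PATHWAYS: dict[str, frozenset[str]] = {
    "MAPK_ERK": frozenset({"KRAS", "BRAF", "EGFR", "FGFR3", "DUSP2"}),
    "DNA_repair": frozenset({"ATM", "ATR", "FANCA", "BRCA2", "BRIP1", "MLH1", "TP53"}),
    "epigenetic": frozenset({"ARID1A", "ARID2", "ARID4B", "CCND1", "CREBBP",
                             "EP300", "KMT2B", "KMT2C", "KMT2D", "NCOR2", "PRDM9"}),
}


@dataclass(frozen=True)
class TrajectoryConfig:
    presence_alt_reads_min: int = 3
    presence_vaf_min: float = 0.02
    change_alpha: float = 0.05
    change_delta_min: float = 0.10
    clonal_vaf_min: float = 0.40
    #: require both variants of a parallel-evolution event to be acquired
    #: (default: co-presence in the same sample suffices)
    parallel_requires_acquired: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.presence_vaf_min < self.clonal_vaf_min <= 1:
            raise ValueError("need 0 < presence_vaf_min < clonal_vaf_min <= 1")
        if not 0 < self.change_alpha < 1:
            raise ValueError("change_alpha must lie in (0,1)")


@dataclass(frozen=True)
class VariantTrajectory:
    """Classified trajectory of one variant across the designated pair."""

    patient_id: str
    key: VariantKey
    gene: str
    cdna: str
    obs_first: VariantObservation
    obs_paired: VariantObservation
    presence: tuple[bool, bool]
    trajectory_class: str
    clonality: tuple[str, str] = ("absent", "absent")
    clonal_transition: bool = False

    def __post_init__(self) -> None:
        expected = {
            "acquired": (False, True),
            "lost": (True, False),
        }.get(self.trajectory_class)
        if expected is not None and self.presence != expected:
            raise ValueError(
                f"{self.trajectory_class} requires presence={expected}, "
                f"got {self.presence}")
        if self.trajectory_class in ("expanded", "declined", "stable") \
                and self.presence != (True, True):
            raise ValueError(
                f"{self.trajectory_class} requires presence at both timepoints")


@dataclass(frozen=True)
class PatientEvolution:
    patient_id: str
    pattern: str
    n_acquired: int
    n_lost: int
    n_shared: int
    parallel_events: tuple[tuple[str, frozenset[VariantKey]], ...] = ()
    clonal_transitions: tuple[VariantKey, ...] = ()


def presence_call(observation: VariantObservation,
                  config: TrajectoryConfig = TrajectoryConfig()) -> bool:
    """A variant counts as present when it clears both the alt-read floor and
    the VAF floor (boundaries inclusive)."""
    return (observation.alt_reads >= config.presence_alt_reads_min
            and observation.vaf >= config.presence_vaf_min)


def _vaf_change_significant(o1: VariantObservation, o2: VariantObservation,
                            alpha: float) -> bool:
    """Two-sided two-proportion z-test on (alt_reads, depth) pairs."""
    if o1.depth == 0 or o2.depth == 0:
        return False
    pooled = (o1.alt_reads + o2.alt_reads) / (o1.depth + o2.depth)
    if pooled in (0.0, 1.0):  # identical degenerate proportions
        return False
    _, p = proportions_ztest([o1.alt_reads, o2.alt_reads],
                             [o1.depth, o2.depth], alternative="two-sided")
    return bool(p < alpha)


def classify_trajectory(obs_first: VariantObservation,
                        obs_paired: VariantObservation,
                        config: TrajectoryConfig = TrajectoryConfig(),
                        ) -> VariantTrajectory:
    """Classify one variant's paired-sample trajectory.

    Expansion/decline requires the two-proportion test to reject at
    ``change_alpha`` *and* an absolute VAF difference of at least
    ``change_delta_min`` in the corresponding direction; anything short of
    both is called stable.  A variant absent at both timepoints violates the
    upstream filter's guarantee and raises.
    """
    if obs_first.key != obs_paired.key:
        raise ValueError(
            f"mismatched variant keys: {obs_first.key} vs {obs_paired.key}")
    p1 = presence_call(obs_first, config)
    p2 = presence_call(obs_paired, config)
    if not p1 and not p2:
        raise ValueError(
            f"variant {obs_first.key} absent at both timepoints; such "
            "variants must be removed by the filter cascade")
    if not p1:
        klass = "acquired"
    elif not p2:
        klass = "lost"
    else:
        delta = obs_paired.vaf - obs_first.vaf
        if (abs(delta) >= config.change_delta_min
                and _vaf_change_significant(obs_first, obs_paired,
                                            config.change_alpha)):
            klass = "expanded" if delta > 0 else "declined"
        else:
            klass = "stable"
    traj = VariantTrajectory(
        patient_id=obs_first.patient_id, key=obs_first.key,
        gene=obs_first.gene if obs_first.gene != "." else obs_paired.gene,
        cdna=obs_first.cdna if obs_first.cdna != "." else obs_paired.cdna,
        obs_first=obs_first, obs_paired=obs_paired,
        presence=(p1, p2), trajectory_class=klass)
    return clonality_call(traj, config)


def classify_paired_variant(pv: PairedVariant,
                            config: TrajectoryConfig = TrajectoryConfig(),
                            ) -> VariantTrajectory:
    traj = classify_trajectory(pv.obs_first, pv.obs_paired, config)
    return replace(traj, gene=pv.gene, cdna=pv.cdna)


def classify_patient_pattern(trajectories: Sequence[VariantTrajectory],
                             ) -> PatientEvolution:
    """Patient-level progression pattern from acquired/lost counts.

    branching iff >=1 acquired and >=1 lost; acquisition iff >=1 acquired
    and none lost; loss symmetric; stable iff neither.
    """
    if not trajectories:
        raise ValueError("cannot classify a patient without trajectories")
    pid = trajectories[0].patient_id
    n_acq = sum(t.trajectory_class == "acquired" for t in trajectories)
    n_lost = sum(t.trajectory_class == "lost" for t in trajectories)
    n_shared = sum(t.presence == (True, True) for t in trajectories)
    if n_acq >= 1 and n_lost >= 1:
        pattern = "branching"
    elif n_acq >= 1:
        pattern = "acquisition"
    elif n_lost >= 1:
        pattern = "loss"
    else:
        pattern = "stable"
    return PatientEvolution(
        patient_id=pid, pattern=pattern, n_acquired=n_acq, n_lost=n_lost,
        n_shared=n_shared,
        parallel_events=tuple(detect_parallel_evolution(trajectories)),
        clonal_transitions=tuple(t.key for t in trajectories
                                 if t.clonal_transition))


def detect_parallel_evolution(trajectories: Sequence[VariantTrajectory],
                              config: TrajectoryConfig = TrajectoryConfig(),
                              ) -> list[tuple[str, frozenset[VariantKey]]]:
    """Genes carrying >= 2 independent variants in the same sample of one
    patient — the footprint of convergent selection on a single gene.

    By default co-presence in either member of the pair qualifies; with
    ``parallel_requires_acquired`` both variants must be newly acquired.
    """
    by_gene: dict[str, set[VariantKey]] = {}
    for timepoint in (0, 1):
        present: dict[str, set[VariantKey]] = {}
        for t in trajectories:
            if config.parallel_requires_acquired and t.trajectory_class != "acquired":
                continue
            if t.presence[timepoint]:
                present.setdefault(t.gene, set()).add(t.key)
        for gene, keys in present.items():
            if len(keys) >= 2:
                by_gene.setdefault(gene, set()).update(keys)
    return sorted((g, frozenset(k)) for g, k in by_gene.items())


def clonality_call(trajectory: VariantTrajectory,
                   config: TrajectoryConfig = TrajectoryConfig(),
                   ) -> VariantTrajectory:
    """Attach clonal/subclonal labels per timepoint (VAF >= 40% ~ clonal) and
    flag subclonal-to-clonal transitions."""
    labels = []
    for present, obs in zip(trajectory.presence,
                            (trajectory.obs_first, trajectory.obs_paired)):
        if not present:
            labels.append("absent")
        elif obs.vaf >= config.clonal_vaf_min:
            labels.append("clonal")
        else:
            labels.append("subclonal")
    transition = labels[0] == "subclonal" and labels[1] == "clonal"
    return replace(trajectory, clonality=tuple(labels),
                   clonal_transition=transition)


def summarize_pathways_and_druggable(
    trajectories_by_patient: Mapping[str, Sequence[VariantTrajectory]],
    pathway_map: Optional[Mapping[str, Iterable[str]]] = None,
    druggable_lists: Optional[Mapping[str, Iterable[str]]] = None,
    known_genes: Optional[Iterable[str]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-patient pathway involvement and druggable-gene trajectory counts.

    Returns ``(pathway_table, druggable_table)``: the first is patients x
    pathways booleans (>= 1 retained variant in a member gene); the second
    counts, per druggable-gene database, the variants shared by both samples
    split by trajectory class, plus acquired ones, with the number of
    distinct patients involved.
    """
    pathway_map = {k: frozenset(v) for k, v in (pathway_map or DEFAULT_PATHWAYS).items()}
    druggable_lists = {k: frozenset(v) for k, v in (druggable_lists or {}).items()}

    if known_genes is not None:
        known = set(known_genes)
        for label, genes in list(pathway_map.items()) + list(druggable_lists.items()):
            unknown = genes - known
            if unknown:
                log.warning("%s: ignoring unknown gene symbol(s) %s",
                            label, sorted(unknown))

    rows = []
    for pid, trajs in trajectories_by_patient.items():
        genes = {t.gene for t in trajs}
        rows.append({"patient_id": pid,
                     **{p: bool(genes & members)
                        for p, members in pathway_map.items()}})
    pathway_table = pd.DataFrame(rows, columns=["patient_id", *pathway_map])

    rows = []
    for db, genes in druggable_lists.items():
        hits = [t for trajs in trajectories_by_patient.values() for t in trajs
                if t.gene in genes]
        shared = [t for t in hits if t.presence == (True, True)]
        row = {"database": db,
               "n_shared": len(shared),
               "n_patients_shared": len({t.patient_id for t in shared})}
        for klass in ("expanded", "declined", "stable", "acquired"):
            subset = [t for t in hits if t.trajectory_class == klass]
            row[f"n_{klass}"] = len(subset)
            row[f"n_patients_{klass}"] = len({t.patient_id for t in subset})
        rows.append(row)
    columns = (["database", "n_shared", "n_patients_shared"]
               + [f"n_{k}" for k in ("expanded", "declined", "stable", "acquired")]
               + [f"n_patients_{k}" for k in ("expanded", "declined", "stable", "acquired")])
    druggable_table = pd.DataFrame(rows, columns=columns)
    return pathway_table, druggable_table


def trajectories_to_frame(trajectories: Iterable[VariantTrajectory]) -> pd.DataFrame:
    rows = []
    for t in trajectories:
        chrom, pos, ref, alt = t.key
        rows.append({
            "patient_id": t.patient_id, "chrom": chrom, "pos": pos,
            "ref": ref, "alt": alt, "gene": t.gene, "cdna": t.cdna,
            "vaf_first": round(t.obs_first.vaf, 6),
            "vaf_paired": round(t.obs_paired.vaf, 6),
            "depth_first": t.obs_first.depth, "depth_paired": t.obs_paired.depth,
            "alt_first": t.obs_first.alt_reads, "alt_paired": t.obs_paired.alt_reads,
            "present_first": t.presence[0], "present_paired": t.presence[1],
            "trajectory_class": t.trajectory_class,
            "clonality_first": t.clonality[0], "clonality_paired": t.clonality[1],
            "clonal_transition": t.clonal_transition,
        })
    return pd.DataFrame(rows)
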