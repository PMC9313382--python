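"""Domain types, file readers/writers and cohort-level validation.

Conventions
-----------
* Variant coordinates are 1-based (VCF convention); copy-number segments are
  0-based half-open (BED convention).  :func:`vcf_to_bed_interval` and
  :func:`bed_to_vcf_pos` convert explicitly.
* Tabular files are UTF-8 TSV with a header row and ``.`` for missing values.
* A variant's identity key is ``(chrom, pos, ref, alt)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pandas as pd

log = logging.getLogger("mmct")

# --------------------------------------------------------------------------
# Controlled vocabularies

PREDICTOR_LABELS: tuple[str, ...] = (
    "cravat", "chasm", "cscape", "fathmm_cancer", "deogen2", "primateai",
)
#: Cancer-specific predictors eligible for the recurrent-gene single-vote rule.
CANCER_SPECIFIC_PREDICTORS: frozenset[str] = frozenset(
    {"cravat", "chasm", "fathmm_cancer", "cscape"}
)
POPULATION_DBS: tuple[str, ...] = ("g1000", "gnomad", "esp")
ACMG_CLASSES: frozenset[str] = frozenset(
    {"benign", "likely_benign", "vus", "likely_pathogenic", "pathogenic", "missing"}
)
FISH_FLAGS: tuple[str, ...] = ("del17p", "t_4_14", "t_14_16", "t_11_14", "igh_other")
RESPONSES: tuple[str, ...] = ("CR", "VGPR", "PR", "SD", "PD")

MISSING = "."

VariantKey = tuple[str, int, str, str]


def vcf_to_bed_interval(pos: int, ref: str) -> tuple[int, int]:
    """1-based VCF position + ref allele -> 0-based half-open interval."""
    return pos - 1, pos - 1 + len(ref)


def bed_to_vcf_pos(start: int) -> int:
    """0-based interval start -> 1-based position of its first base."""
    return start + 1


# --------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class SampleMeta:
    """One physical sample: temporal order, label and post-sorting purity."""

    patient_id: str
    sample_index: int
    timepoint_label: str  # "Dx" or "PD"
    purity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sample_index < 1:
            raise ValueError(f"sample_index must be >=1, got {self.sample_index}")
        if self.purity is not None and not 0.0 <= self.purity <= 1.0:
            raise ValueError(f"purity must lie in [0,1], got {self.purity}")


@dataclass(frozen=True)
class VariantObservation:
    """One variant in one sample, with read support.

    ``vaf`` must equal ``alt_reads / depth`` within 1e-6 whenever depth > 0.
    A zero-depth observation (depth=0, alt_reads=0, vaf=0) encodes "not seen";
    it is what paired-sample bookkeeping fills in when a variant was called in
    only one member of the pair.
    """

    patient_id: str
    sample_index: int
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    cdna: str
    depth: int
    alt_reads: int
    vaf: float

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if not 0 <= self.alt_reads <= self.depth:
            raise ValueError(
                f"alt_reads must satisfy 0 <= alt_reads <= depth; "
                f"got alt_reads={self.alt_reads}, depth={self.depth} "
                f"at {self.chrom}:{self.pos}"
            )
        if self.depth > 0 and abs(self.vaf - self.alt_reads / self.depth) > 1e-6:
            raise ValueError(
                f"vaf {self.vaf} inconsistent with alt_reads/depth = "
                f"{self.alt_reads}/{self.depth} at {self.chrom}:{self.pos}"
            )

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @classmethod
    def absent(
        cls, patient_id: str, sample_index: int, key: VariantKey,
        gene: str = MISSING, cdna: str = MISSING,
    ) -> "VariantObservation":
        """Zero-count placeholder for a variant not called in this sample."""
        chrom, pos, ref, alt = key
        return cls(patient_id, sample_index, chrom, pos, ref, alt,
                   gene, cdna, depth=0, alt_reads=0, vaf=0.0)


@dataclass(frozen=True)
class VariantAnnotation:
    """External evidence for one variant key: population AFs, six predictor
    verdicts, ACMG-style class and gene-level flags."""

    pop_af: Mapping[str, Optional[float]] = field(default_factory=dict)
    predictor_verdict: Mapping[str, str] = field(default_factory=dict)
    acmg_class: str = "missing"
    recurrent_mm_gene: bool = False
    druggable_sources: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        verdicts = dict(self.predictor_verdict)
        unknown = set(verdicts) - set(PREDICTOR_LABELS)
        if unknown:
            raise ValueError(f"unknown predictor label(s): {sorted(unknown)}")
        for label in PREDICTOR_LABELS:
            verdicts.setdefault(label, "missing")
        object.__setattr__(self, "predictor_verdict", verdicts)
        afs = {db: dict(self.pop_af).get(db) for db in POPULATION_DBS}
        for db, value in afs.items():
            if value is not None and not 0.0 <= value <= 1.0:
                raise ValueError(f"population AF for {db} outside [0,1]: {value}")
        object.__setattr__(self, "pop_af", afs)
        if self.acmg_class not in ACMG_CLASSES:
            raise ValueError(f"unknown ACMG class {self.acmg_class!r}")

    @classmethod
    def all_missing(cls) -> "VariantAnnotation":
        return cls()

    def n_pathogenic(self) -> int:
        return sum(v == "pathogenic" for v in self.predictor_verdict.values())

    def n_pathogenic_cancer_specific(self) -> int:
        return sum(
            self.predictor_verdict[p] == "pathogenic"
            for p in CANCER_SPECIFIC_PREDICTORS
        )


@dataclass(frozen=True)
class CNVSegment:
    """One copy-number segment (0-based half-open) with its log2 copy ratio."""

    chrom: str
    start: int
    end: int
    log2: float
    n_markers: int = 1

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"segment start must be < end: {self.start}..{self.end}")
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")

    def overlap(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start))


@dataclass(frozen=True)
class ClinicalRecord:
    """Staging inputs and response at one timepoint.

    ``ldh`` is {normal, high, missing}; FISH flags are True/False/None
    (None = not assayed); response refers to the therapy received between the
    paired samples and is recorded on the paired-sample row.
    """

    albumin: Optional[float] = None       # g/dL
    b2m: Optional[float] = None           # mg/L
    ldh: str = "missing"
    ecog: Optional[int] = None
    fish: Mapping[str, Optional[bool]] = field(default_factory=dict)
    response_between_samples: Optional[str] = None
    refractory_pi: Optional[bool] = None
    refractory_imid: Optional[bool] = None
    refractory_alkylator: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.albumin is not None and self.albumin <= 0:
            raise ValueError("albumin must be > 0")
        if self.b2m is not None and self.b2m <= 0:
            raise ValueError("b2m must be > 0")
        if self.ldh not in ("normal", "high", "missing"):
            raise ValueError(f"ldh must be normal/high/missing, got {self.ldh!r}")
        flags = {f: dict(self.fish).get(f) for f in FISH_FLAGS}
        object.__setattr__(self, "fish", flags)
        if (self.response_between_samples is not None
                and self.response_between_samples not in RESPONSES):
            raise ValueError(f"unknown response {self.response_between_samples!r}")


@dataclass(frozen=True)
class SurvivalRecord:
    """Per-patient endpoint times in months.

    PFS runs from the start of the therapy given immediately after the paired
    sample; OS' from the first sample; OS'' from the paired sample.  Since the
    first sample precedes the paired one, os1 >= os2 whenever both observed.
    """

    pfs_months: Optional[float] = None
    pfs_event: Optional[bool] = None
    os1_months: Optional[float] = None
    os1_event: Optional[bool] = None
    os2_months: Optional[float] = None
    os2_event: Optional[bool] = None

    def __post_init__(self) -> None:
        for name in ("pfs_months", "os1_months", "os2_months"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if (self.os1_months is not None and self.os2_months is not None
                and self.os1_months < self.os2_months - 1e-9):
            raise ValueError("os1_months (from first sample) cannot be shorter "
                             "than os2_months (from paired sample)")


@dataclass(frozen=True)
class PairedVariant:
    """A variant key of one patient with its observation at both members of
    the designated (first, paired) sample pair; either side may be a
    zero-count placeholder."""

    patient_id: str
    key: VariantKey
    gene: str
    cdna: str
    obs_first: VariantObservation
    obs_paired: VariantObservation
    annotation: VariantAnnotation


@dataclass
class FilterReport:
    """Ordered per-stage retention bookkeeping of the filter cascade."""

    stages: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, name: str, retained: int, rejected: int) -> None:
        if self.stages:
            prev_retained = self.stages[-1][1]
            if retained + rejected != prev_retained:
                raise ValueError(
                    f"stage {name}: retained+rejected ({retained}+{rejected}) "
                    f"!= previous retained ({prev_retained})"
                )
        self.stages.append((name, retained, rejected))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "retained", "rejected"])


@dataclass
class ValidationReport:
    unpaired_patients: list[str] = field(default_factory=list)
    vaf_inconsistencies: list[str] = field(default_factory=list)
    overlapping_segments: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.unpaired_patients or self.vaf_inconsistencies
                    or self.overlapping_segments)

    def raise_on_failure(self) -> None:
        if not self.ok:
            raise ValueError(f"cohort validation failed: {self}")


# --------------------------------------------------------------------------
# Cohort container


class Cohort:
    """In-memory longitudinal cohort keyed by (patient_id, sample_index).

    The designated (first, paired) pair per patient defaults to the two
    earliest samples; a ``paired`` flag in the clinical table can designate a
    later sample instead.  Patients with fewer than two samples have no pair
    and are excluded from paired analyses.
    """

    def __init__(self) -> None:
        self.samples: dict[tuple[str, int], SampleMeta] = {}
        self.observations: dict[tuple[str, int], dict[VariantKey, VariantObservation]] = {}
        self.annotations: dict[VariantKey, VariantAnnotation] = {}
        self.segments: dict[tuple[str, int], list[CNVSegment]] = {}
        self.clinical: dict[tuple[str, int], ClinicalRecord] = {}
        self.survival: dict[str, SurvivalRecord] = {}
        self._paired_override: dict[str, int] = {}

    # -- construction ------------------------------------------------------

    def add_sample(self, meta: SampleMeta) -> None:
        self.samples[(meta.patient_id, meta.sample_index)] = meta

    def add_observation(self, obs: VariantObservation) -> None:
        sample_key = (obs.patient_id, obs.sample_index)
        if sample_key not in self.samples:
            self.add_sample(SampleMeta(obs.patient_id, obs.sample_index,
                                       "Dx" if obs.sample_index == 1 else "PD"))
        self.observations.setdefault(sample_key, {})[obs.key] = obs

    def add_segment(self, patient_id: str, sample_index: int, seg: CNVSegment) -> None:
        self.segments.setdefault((patient_id, sample_index), []).append(seg)

    # -- views -------------------------------------------------------------

    @property
    def patients(self) -> list[str]:
        seen: dict[str, None] = {}
        for pid, _ in self.samples:
            seen.setdefault(pid)
        return list(seen)

    def sample_indices(self, patient_id: str) -> list[int]:
        return sorted(i for (pid, i) in self.samples if pid == patient_id)

    def designated_pair(self, patient_id: str) -> Optional[tuple[int, int]]:
        indices = self.sample_indices(patient_id)
        if len(indices) < 2:
            return None
        first = indices[0]
        paired = self._paired_override.get(patient_id, indices[1])
        if paired not in indices or paired <= first:
            return None
        return first, paired

    def annotation_for(self, key: VariantKey) -> VariantAnnotation:
        return self.annotations.get(key, VariantAnnotation.all_missing())

    def paired_variants(self, patient_id: str) -> list[PairedVariant]:
        """All variant keys called in either member of the designated pair,
        each with observations at both timepoints (zero-count placeholders
        where uncalled)."""
        pair = self.designated_pair(patient_id)
        if pair is None:
            return []
        first_idx, paired_idx = pair
        obs_first = self.observations.get((patient_id, first_idx), {})
        obs_paired = self.observations.get((patient_id, paired_idx), {})
        out: list[PairedVariant] = []
        for key in sorted(set(obs_first) | set(obs_paired)):
            o1 = obs_first.get(key)
            o2 = obs_paired.get(key)
            gene = (o1 or o2).gene
            cdna = (o1 or o2).cdna
            if o1 is None:
                o1 = VariantObservation.absent(patient_id, first_idx, key, gene, cdna)
            if o2 is None:
                o2 = VariantObservation.absent(patient_id, paired_idx, key, gene, cdna)
            out.append(PairedVariant(patient_id, key, gene, cdna, o1, o2,
                                     self.annotation_for(key)))
        return out

    def segments_for(self, patient_id: str, sample_index: int) -> list[CNVSegment]:
        return sorted(self.segments.get((patient_id, sample_index), []),
                      key=lambda s: (s.chrom, s.start))

    def n_samples(self) -> int:
        return len(self.samples)


# --------------------------------------------------------------------------
# Parsing helpers

_VARIANT_COLUMNS = ["patient_id", "sample_index", "chrom", "pos", "ref", "alt",
                    "gene", "cdna", "depth", "alt_reads"]
_SEGMENT_COLUMNS = ["patient_id", "sample_index", "chrom", "start", "end",
                    "log2", "n_markers"]
_ANNOTATION_COLUMNS = (["chrom", "pos", "ref", "alt"]
                       + [f"af_{db}" for db in POPULATION_DBS]
                       + list(PREDICTOR_LABELS)
                       + ["acmg_class", "recurrent_mm_gene", "druggable_sources"])
_CLINICAL_REQUIRED = ["patient_id", "sample_index", "timepoint"]


def _read_tsv(path: Path, required: Sequence[str], known: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[MISSING], keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        log.warning("%s: ignoring unknown column(s) %s", path, unknown)
    return df


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def _opt_bool(value) -> Optional[bool]:
    v = _opt_float(value)
    return None if v is None else bool(int(v))


def _load_variants_tsv(path: Path) -> list[VariantObservation]:
    df = _read_tsv(path, _VARIANT_COLUMNS, _VARIANT_COLUMNS + ["vaf"])
    out = []
    for row in df.itertuples(index=False):
        depth = int(row.depth)
        alt_reads = int(row.alt_reads)
        vaf = alt_reads / depth if depth > 0 else 0.0
        out.append(VariantObservation(
            patient_id=str(row.patient_id), sample_index=int(row.sample_index),
            chrom=str(row.chrom), pos=int(row.pos), ref=str(row.ref),
            alt=str(row.alt), gene=str(row.gene), cdna=str(row.cdna),
            depth=depth, alt_reads=alt_reads, vaf=vaf))
    return out


def _load_variants_vcf(path: Path) -> list[VariantObservation]:
    """Read a multi-sample VCF 4.2 with per-sample AD/DP.

    Sample IDs must follow ``<patient_id>_<sample_index>``.  Multi-allelic
    sites are split into one record per alternate allele, with the AD column
    for that allele; this assumes alternate alleles are independent calls.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = []
    for s in vcf.samples:
        pid, _, idx = s.rpartition("_")
        if not pid or not idx.isdigit():
            raise ValueError(f"VCF sample name {s!r} does not follow "
                             "'<patient_id>_<sample_index>'")
        sample_ids.append((pid, int(idx)))
    out = []
    for record in vcf:
        gene = record.INFO.get("GENE", MISSING)
        cdna = record.INFO.get("CDNA", MISSING)
        ad = record.format("AD")   # (n_samples, 1 + n_alt)
        dp = record.format("DP")
        for alt_i, alt in enumerate(record.ALT):
            for samp_i, (pid, sidx) in enumerate(sample_ids):
                depth = int(dp[samp_i][0]) if dp is not None else 0
                alt_reads = int(ad[samp_i][1 + alt_i]) if ad is not None else 0
                if depth < 0 or alt_reads < 0:   # cyvcf2 encodes missing as negative
                    continue
                vaf = alt_reads / depth if depth > 0 else 0.0
                out.append(VariantObservation(
                    patient_id=pid, sample_index=sidx, chrom=record.CHROM,
                    pos=record.POS, ref=record.REF, alt=alt, gene=gene,
                    cdna=cdna, depth=depth, alt_reads=alt_reads, vaf=vaf))
    return out


def _load_annotations(path: Path) -> dict[VariantKey, VariantAnnotation]:
    df = _read_tsv(path, ["chrom", "pos", "ref", "alt"], _ANNOTATION_COLUMNS + ["gene"])
    out: dict[VariantKey, VariantAnnotation] = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        key = (str(d["chrom"]), int(d["pos"]), str(d["ref"]), str(d["alt"]))
        pop_af = {db: _opt_float(d.get(f"af_{db}")) for db in POPULATION_DBS}
        verdicts = {}
        for p in PREDICTOR_LABELS:
            v = d.get(p)
            verdicts[p] = v if v in ("pathogenic", "benign") else "missing"
        acmg = d.get("acmg_class")
        if acmg is None or (isinstance(acmg, float) and math.isnan(acmg)):
            acmg = "missing"
        sources = d.get("druggable_sources")
        if sources is None or (isinstance(sources, float) and math.isnan(sources)) or sources == "":
            druggable: frozenset[str] = frozenset()
        else:
            druggable = frozenset(s for s in str(sources).split(",") if s)
        out[key] = VariantAnnotation(
            pop_af=pop_af, predictor_verdict=verdicts, acmg_class=acmg,
            recurrent_mm_gene=bool(_opt_bool(d.get("recurrent_mm_gene")) or False),
            druggable_sources=druggable)
    return out


def _load_segments(path: Path) -> list[tuple[str, int, CNVSegment]]:
    df = _read_tsv(path, _SEGMENT_COLUMNS, _SEGMENT_COLUMNS)
    out = []
    for row in df.itertuples(index=False):
        out.append((str(row.patient_id), int(row.sample_index), CNVSegment(
            chrom=str(row.chrom), start=int(row.start), end=int(row.end),
            log2=float(row.log2), n_markers=int(row.n_markers))))
    return out


_CLINICAL_KNOWN = (_CLINICAL_REQUIRED
                   + ["purity", "paired", "albumin", "b2m", "ldh", "ecog",
                      "response_between_samples",
                      "refractory_pi", "refractory_imid", "refractory_alkylator"]
                   + [f"fish_{f}" for f in FISH_FLAGS]
                   + ["pfs_months", "pfs_event", "os1_months", "os1_event",
                      "os2_months", "os2_event"])


def _load_clinical(path: Path, cohort: Cohort) -> None:
    df = _read_tsv(path, _CLINICAL_REQUIRED, _CLINICAL_KNOWN)
    for row in df.itertuples(index=False):
        d = row._asdict()
        pid = str(d["patient_id"])
        sidx = int(d["sample_index"])
        cohort.add_sample(SampleMeta(
            patient_id=pid, sample_index=sidx,
            timepoint_label=str(d["timepoint"]),
            purity=_opt_float(d.get("purity"))))
        if _opt_bool(d.get("paired")):
            cohort._paired_override[pid] = sidx
        ldh = d.get("ldh")
        if ldh not in ("normal", "high"):
            ldh = "missing"
        response = d.get("response_between_samples")
        if response not in RESPONSES:
            response = None
        fish = {f: _opt_bool(d.get(f"fish_{f}")) for f in FISH_FLAGS}
        ecog = _opt_float(d.get("ecog"))
        cohort.clinical[(pid, sidx)] = ClinicalRecord(
            albumin=_opt_float(d.get("albumin")), b2m=_opt_float(d.get("b2m")),
            ldh=ldh, ecog=None if ecog is None else int(ecog), fish=fish,
            response_between_samples=response,
            refractory_pi=_opt_bool(d.get("refractory_pi")),
            refractory_imid=_opt_bool(d.get("refractory_imid")),
            refractory_alkylator=_opt_bool(d.get("refractory_alkylator")))
        surv = SurvivalRecord(
            pfs_months=_opt_float(d.get("pfs_months")),
            pfs_event=_opt_bool(d.get("pfs_event")),
            os1_months=_opt_float(d.get("os1_months")),
            os1_event=_opt_bool(d.get("os1_event")),
            os2_months=_opt_float(d.get("os2_months")),
            os2_event=_opt_bool(d.get("os2_event")))
        if any(getattr(surv, f) is not None for f in
               ("pfs_months", "os1_months", "os2_months")):
            cohort.survival[pid] = surv


# --------------------------------------------------------------------------
# Public loaders / writers


def load_cohort(variant_path, annotation_path=None, segment_path=None,
                clinical_path=None) -> Cohort:
    """Assemble a :class:`Cohort` from tabular (or VCF) inputs.

    ``variant_path`` may be a VCF 4.2 (FORMAT AD/DP, sample IDs
    ``<patient>_<index>``) or a TSV with the VariantObservation columns.  The
    other paths are TSV.  Annotations are joined to variants by the identity
    key ``(chrom, pos, ref, alt)``; variants without an annotation row are
    retained with an all-missing annotation (logged).  When the annotation
    file carries a gene symbol conflicting with the variant file, the
    annotation file wins (logged).
    """
    variant_path = Path(variant_path)
    cohort = Cohort()

    if variant_path.suffix in (".vcf", ".gz") or variant_path.name.endswith(".vcf.gz"):
        observations = _load_variants_vcf(variant_path)
    else:
        observations = _load_variants_tsv(variant_path)

    ann_genes: dict[VariantKey, str] = {}
    if annotation_path is not None:
        df = pd.read_csv(annotation_path, sep="\t", dtype=str,
                         na_values=[MISSING], keep_default_na=False)
        cohort.annotations = _load_annotations(Path(annotation_path))
        if "gene" in df.columns:
            for row in df.itertuples(index=False):
                d = row._asdict()
                g = d.get("gene")
                if isinstance(g, str) and g:
                    ann_genes[(str(d["chrom"]), int(d["pos"]),
                               str(d["ref"]), str(d["alt"]))] = g

    n_unannotated = 0
    for obs in observations:
        better_gene = ann_genes.get(obs.key)
        if better_gene is not None and better_gene != obs.gene:
            log.info("gene symbol conflict at %s:%s: %r -> %r (annotation wins)",
                     obs.chrom, obs.pos, obs.gene, better_gene)
            obs = replace(obs, gene=better_gene)
        if cohort.annotations and obs.key not in cohort.annotations:
            n_unannotated += 1
        cohort.add_observation(obs)
    if n_unannotated:
        log.warning("%d variant observation(s) lack an annotation row; "
                    "retained with all-missing annotation", n_unannotated)

    if segment_path is not None:
        for pid, sidx, seg in _load_segments(Path(segment_path)):
            cohort.add_segment(pid, sidx, seg)

    if clinical_path is not None:
        _load_clinical(Path(clinical_path), cohort)

    return cohort


def write_cohort(cohort: Cohort, out_dir) -> dict[str, Path]:
    """Write variants/annotations/segments/clinical TSVs readable by
    :func:`load_cohort`; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rows = []
    for (pid, sidx), obs_map in sorted(cohort.observations.items()):
        for key in sorted(obs_map):
            o = obs_map[key]
            rows.append((o.patient_id, o.sample_index, o.chrom, o.pos, o.ref,
                         o.alt, o.gene, o.cdna, o.depth, o.alt_reads,
                         f"{o.vaf:.6f}"))
    paths["variants"] = out_dir / "variants.tsv"
    pd.DataFrame(rows, columns=_VARIANT_COLUMNS + ["vaf"]).to_csv(
        paths["variants"], sep="\t", index=False, na_rep=MISSING)

    rows = []
    for key in sorted(cohort.annotations):
        a = cohort.annotations[key]
        chrom, pos, ref, alt = key
        row = {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt}
        for db in POPULATION_DBS:
            v = a.pop_af[db]
            row[f"af_{db}"] = MISSING if v is None else f"{v:.6g}"
        for p in PREDICTOR_LABELS:
            v = a.predictor_verdict[p]
            row[p] = MISSING if v == "missing" else v
        row["acmg_class"] = MISSING if a.acmg_class == "missing" else a.acmg_class
        row["recurrent_mm_gene"] = int(a.recurrent_mm_gene)
        row["druggable_sources"] = ",".join(sorted(a.druggable_sources)) or MISSING
        rows.append(row)
    paths["annotations"] = out_dir / "annotations.tsv"
    pd.DataFrame(rows, columns=_ANNOTATION_COLUMNS).to_csv(
        paths["annotations"], sep="\t", index=False)

    rows = []
    for (pid, sidx), segs in sorted(cohort.segments.items()):
        for s in sorted(segs, key=lambda s: (s.chrom, s.start)):
            rows.append((pid, sidx, s.chrom, s.start, s.end,
                         f"{s.log2:.4f}", s.n_markers))
    paths["segments"] = out_dir / "segments.tsv"
    pd.DataFrame(rows, columns=_SEGMENT_COLUMNS).to_csv(
        paths["segments"], sep="\t", index=False)

    rows = []
    for (pid, sidx), meta in sorted(cohort.samples.items()):
        rec = cohort.clinical.get((pid, sidx), ClinicalRecord())
        surv = cohort.survival.get(pid, SurvivalRecord())
        pair = cohort.designated_pair(pid)
        row = {
            "patient_id": pid, "sample_index": sidx,
            "timepoint": meta.timepoint_label,
            "purity": MISSING if meta.purity is None else f"{meta.purity:.4f}",
            "paired": int(pair is not None and sidx == pair[1]),
            "albumin": MISSING if rec.albumin is None else f"{rec.albumin:.3f}",
            "b2m": MISSING if rec.b2m is None else f"{rec.b2m:.3f}",
            "ldh": MISSING if rec.ldh == "missing" else rec.ldh,
            "ecog": MISSING if rec.ecog is None else rec.ecog,
            "response_between_samples": rec.response_between_samples or MISSING,
            "refractory_pi": _fmt_bool(rec.refractory_pi),
            "refractory_imid": _fmt_bool(rec.refractory_imid),
            "refractory_alkylator": _fmt_bool(rec.refractory_alkylator),
        }
        for f in FISH_FLAGS:
            row[f"fish_{f}"] = _fmt_bool(rec.fish[f])
        for f in ("pfs_months", "os1_months", "os2_months"):
            v = getattr(surv, f)
            row[f] = MISSING if v is None else f"{v:.4f}"
        for f in ("pfs_event", "os1_event", "os2_event"):
            row[f] = _fmt_bool(getattr(surv, f))
        rows.append(row)
    paths["clinical"] = out_dir / "clinical.tsv"
    pd.DataFrame(rows, columns=_CLINICAL_KNOWN).to_csv(
        paths["clinical"], sep="\t", index=False)
    return paths


def _fmt_bool(value: Optional[bool]):
    return MISSING if value is None else int(value)


# --------------------------------------------------------------------------
# Validation


def validate_cohort(cohort: Cohort) -> ValidationReport:
    """Cohort-level consistency checks; returns a report, never raises.

    Hard failures (reported, and downstream stages should refuse to run):
    patients without a valid (first, paired) pair, VAF/read inconsistencies,
    overlapping segments on one chromosome of one sample.
    """
    report = ValidationReport()
    for pid in cohort.patients:
        if cohort.designated_pair(pid) is None:
            report.unpaired_patients.append(pid)
    for (pid, sidx), obs_map in cohort.observations.items():
        for o in obs_map.values():
            if o.depth > 0 and abs(o.vaf - o.alt_reads / o.depth) > 1e-6:
                report.vaf_inconsistencies.append(
                    f"{pid}/s{sidx} {o.chrom}:{o.pos}")
    for (pid, sidx), segs in cohort.segments.items():
        by_chrom: dict[str, list[CNVSegment]] = {}
        for s in segs:
            by_chrom.setdefault(s.chrom, []).append(s)
        for chrom, group in by_chrom.items():
            group = sorted(group, key=lambda s: s.start)
            for a, b in zip(group, group[1:]):
                if b.start < a.end:
                    report.overlapping_segments.append(
                        f"{pid}/s{sidx} {chrom}:{a.start}-{a.end} "
                        f"overlaps {b.start}-{b.end}")
    return report
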