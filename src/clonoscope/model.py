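"""Shared data types for the clonal-hematopoiesis pipeline.

The pipeline operates on tabulated deep-sequencing output: per-variant read
counts in one tissue of one animal (:class:`VariantObservation`), the same
variant's frequency profile across all tissues of an animal
(:class:`VariantProfile`), per-animal covariates (:class:`AnimalRecord`), and
genotypes of single HSC/MPP-derived colonies (:class:`ColonyGenotypeMatrix`).

Coordinates are 1-based (VCF convention); deletions and insertions carry the
anchor base in the longer allele, so ``ref="CAT", alt="C"`` is a 2-nt deletion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional

import numpy as np

__all__ = [
    "Variant",
    "VariantObservation",
    "VariantProfile",
    "AnimalRecord",
    "ColonyGenotypeMatrix",
    "HEMATOPOIETIC_TISSUES",
    "NON_HEMATOPOIETIC_TISSUES",
    "NH_REFERENCE_TISSUES",
    "normalize_tissue",
]

_DNA = frozenset("ACGT")

#: Tissues counted as part of the hematopoietic system: bone marrow, lymphoid
#: organs, and the sorted BM blood-cell fractions (T, B, granulocyte, erythroid).
HEMATOPOIETIC_TISSUES = frozenset(
    {"BM", "spleen", "thymus", "T", "B", "GRAN", "ERY"}
)

#: Solid tissues used to detect embryonic mosaicism.  Liver and kidney filter
#: blood and can carry hematopoietic signal, so the default mosaicism
#: *reference* set below is restricted to tail/brain/testis/thyroid.
NON_HEMATOPOIETIC_TISSUES = frozenset(
    {"tail", "kidney", "liver", "brain", "thyroid", "testis"}
)

#: Default tissues whose maximum VAF defines the non-hematopoietic reference
#: level when classifying a variant as mosaic vs hematopoietic-restricted.
NH_REFERENCE_TISSUES = frozenset({"tail", "brain", "testis", "thyroid"})

_TISSUE_ALIASES = {
    "bm": "BM",
    "bone_marrow": "BM",
    "bonemarrow": "BM",
    "marrow": "BM",
    "spl": "spleen",
    "spleen": "spleen",
    "thym": "thymus",
    "thymus": "thymus",
    "tail": "tail",
    "kid": "kidney",
    "kidney": "kidney",
    "kidneys": "kidney",
    "liv": "liver",
    "liver": "liver",
    "br": "brain",
    "brain": "brain",
    "thyr": "thyroid",
    "thyroid": "thyroid",
    "thyroid_gland": "thyroid",
    "tes": "testis",
    "testis": "testis",
    "testes": "testis",
    "t": "T",
    "t_cell": "T",
    "tcell": "T",
    "b": "B",
    "b_cell": "B",
    "bcell": "B",
    "gran": "GRAN",
    "granulocyte": "GRAN",
    "granulocytes": "GRAN",
    "ery": "ERY",
    "erythroid": "ERY",
}


def normalize_tissue(name: str) -> str:
    """Map a tissue label onto the closed vocabulary, case-insensitively.

    Unknown labels pass through unchanged with a warning so that new sorted
    fractions can be added without code changes.
    """
    key = str(name).strip().lower().replace("-", "_").replace(" ", "_")
    try:
        return _TISSUE_ALIASES[key]
    except KeyError:
        warnings.warn(f"unknown tissue label {name!r}; passing through", stacklevel=2)
        return str(name)


class Variant(NamedTuple):
    """A genomic variant identified by position and alleles (1-based, VCF style)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @classmethod
    def from_key(cls, key: str) -> "Variant":
        chrom, pos, alleles = key.split(":")
        ref, alt = alleles.split(">")
        return cls(chrom, int(pos), ref, alt)


def _check_alleles(ref: str, alt: str) -> None:
    if not ref or not alt:
        raise ValueError("ref and alt must be non-empty")
    if not (_DNA.issuperset(ref) and _DNA.issuperset(alt)):
        raise ValueError(f"alleles must match [ACGT]+: ref={ref!r} alt={alt!r}")
    if ref == alt:
        raise ValueError(f"ref == alt ({ref!r}) is not a variant")


@dataclass(frozen=True)
class VariantObservation:
    """Read support for one variant in one tissue of one animal.

    ``vaf`` is always recomputed as ``alt_reads / depth``; a zero-depth site
    has no defined VAF and is flagged via :attr:`vaf_defined`.
    """

    animal_id: str
    tissue: str
    chrom: str
    pos: int
    ref: str
    alt: str
    alt_reads: int
    depth: int

    def __post_init__(self) -> None:
        _check_alleles(self.ref, self.alt)
        if self.pos < 1:
            raise ValueError(f"pos must be 1-based positive, got {self.pos}")
        if self.alt_reads < 0:
            raise ValueError("alt_reads must be >= 0")
        if self.depth < self.alt_reads:
            raise ValueError(
                f"depth ({self.depth}) < alt_reads ({self.alt_reads})"
            )

    @property
    def variant(self) -> Variant:
        return Variant(self.chrom, self.pos, self.ref, self.alt)

    @property
    def vaf_defined(self) -> bool:
        return self.depth > 0

    @property
    def vaf(self) -> float:
        """Alternate allele frequency; NaN when depth is zero."""
        if self.depth == 0:
            return math.nan
        return self.alt_reads / self.depth


#: Classification labels for a variant's tissue distribution.
CLASS_LABELS = ("MOSAIC_NOT_CH", "CH_MOSAIC", "CH_NONMOSAIC", "UNCLASSIFIED")


@dataclass
class VariantProfile:
    """One variant's VAF vector across the tissues of one animal.

    ``class_label`` stays ``UNCLASSIFIED`` until the tissue-distribution
    classifier has run.  ``variant_type`` is one of SNV/INS/DEL/MULTISITE
    (COMPLEX for irreducible substitutions).
    """

    animal_id: str
    variant: Variant
    vaf_by_tissue: dict[str, tuple[float, int]] = field(default_factory=dict)
    variant_type: str = ""
    class_label: str = "UNCLASSIFIED"
    class_reason: str = ""

    def vaf(self, tissue: str) -> Optional[float]:
        entry = self.vaf_by_tissue.get(tissue)
        return None if entry is None else entry[0]

    @property
    def bm_vaf(self) -> Optional[float]:
        return self.vaf("BM")


@dataclass(frozen=True)
class AnimalRecord:
    """Per-animal covariates and optional peripheral-blood indices."""

    animal_id: str
    group: str  # IRRADIATED or CONTROL
    dose_Gy: float
    sex: str  # M or F
    age_months: float
    lym_pct: Optional[float] = None
    mye_pct: Optional[float] = None
    rdw: Optional[float] = None

    def __post_init__(self) -> None:
        if self.group not in ("IRRADIATED", "CONTROL"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.age_months <= 0:
            raise ValueError("age_months must be positive")
        if self.dose_Gy < 0:
            raise ValueError("dose_Gy must be >= 0")
        if (self.dose_Gy == 0) != (self.group == "CONTROL"):
            raise ValueError("dose_Gy must be 0 iff group is CONTROL")


PRESENT, ABSENT, AMBIGUOUS = "PRESENT", "ABSENT", "AMBIGUOUS"


@dataclass
class ColonyGenotypeMatrix:
    """Colonies (rows) x variants (columns) VAF/depth matrix for one animal.

    ``calls`` is ``None`` until :func:`clonoscope.clones.genotype_colonies`
    fills it with PRESENT/ABSENT/AMBIGUOUS strings.  Missing VAFs are NaN.
    """

    animal_id: str
    colonies: list[tuple[str, str]]  # (colony_id, compartment HSC|MPP)
    variants: list[Variant]
    vaf: np.ndarray  # float, NaN = missing
    depth: np.ndarray  # int
    calls: Optional[np.ndarray] = None  # dtype object, same shape

    def __post_init__(self) -> None:
        n, m = len(self.colonies), len(self.variants)
        self.vaf = np.asarray(self.vaf, dtype=float).reshape(n, m)
        self.depth = np.asarray(self.depth, dtype=int).reshape(n, m)
        ids = [c for c, _ in self.colonies]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicated colony_id")
        for _, comp in self.colonies:
            if comp not in ("HSC", "MPP"):
                raise ValueError(f"unknown compartment label {comp!r}")

    @property
    def n_colonies(self) -> int:
        return len(self.colonies)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def compartment_of(self, colony_id: str) -> str:
        for cid, comp in self.colonies:
            if cid == colony_id:
                return comp
        raise KeyError(colony_id)


def profiles_from_observations(
    observations: Iterable[VariantObservation],
) -> list[VariantProfile]:
    """Pivot flat per-tissue observations into per-(animal, variant) profiles."""
    table: dict[tuple[str, Variant], VariantProfile] = {}
    for obs in observations:
        key = (obs.animal_id, obs.variant)
        prof = table.get(key)
        if prof is None:
            prof = VariantProfile(animal_id=obs.animal_id, variant=obs.variant)
            table[key] = prof
        prof.vaf_by_tissue[obs.tissue] = (obs.vaf, obs.depth)
    return list(table.values())
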