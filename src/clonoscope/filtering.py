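"""Candidate filtering and tissue-distribution classification.

Somatic-mutation candidates from deep bone-marrow sequencing are filtered on
bone-marrow VAF (the germline exclusion window keeps 0.02–0.35), read support
(at least 6 alternate reads), and cross-cohort recurrence (a variant detected
in most animals is treated as a technical artifact, panel-of-normals style).

Surviving variants are then classified by how their VAF distributes across
tissues: an embryonic mosaic mutation appears in hematopoietic and
non-hematopoietic tissues at similar frequencies; a clonal-hematopoiesis (CH)
mutation is restricted to, or strongly expanded in, the hematopoietic system.
The three resulting groups — MOSAIC_NOT_CH, CH_MOSAIC (mosaic origin, blood
expansion), CH_NONMOSAIC (blood only) — mirror the standard presentation of
recurrent-mutation counts per animal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    NH_REFERENCE_TISSUES,
    AnimalRecord,
    Variant,
    VariantObservation,
    VariantProfile,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "FilterResult",
    "CohortSummary",
    "filter_candidates",
    "classify_profile",
    "clone_fraction",
    "summarize_cohort",
]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for candidate filtering and tissue classification.

    vaf_min, vaf_max
        Bone-marrow VAF window for somatic candidates; VAF above ``vaf_max``
        is treated as suspected germline, below ``vaf_min`` as sub-clonal
        noise.  Both bounds are inclusive.
    min_alt_reads
        Minimum alternate reads in BM (6 excludes variants supported by <= 5).
    recurrence_fraction
        A variant detected in more than this fraction of sequenced animals is
        rejected as a recurrent artifact.
    detect_vaf
        Minimum VAF at which a variant counts as "detected" in a tissue.
    similar_fold / expanded_fold
        BM : non-hematopoietic fold-ratio bounds separating "similar VAFs"
        (mosaic, not CH) from "substantially expanded in blood" (CH with
        mosaic origin).  Ratios between the two folds stay UNCLASSIFIED.
    nh_reference_tissues
        Tissues whose maximum VAF defines the non-hematopoietic reference;
        blood-filtering organs (liver, kidney) are excluded by default.
    """

    vaf_min: float = 0.02
    vaf_max: float = 0.35
    min_alt_reads: int = 6
    recurrence_fraction: float = 0.5
    detect_vaf: float = 0.005
    similar_fold: float = 3.0
    expanded_fold: float = 5.0
    nh_reference_tissues: frozenset[str] = NH_REFERENCE_TISSUES

    def __post_init__(self) -> None:
        if not (0 < self.vaf_min < self.vaf_max < 0.5):
            raise ValueError("need 0 < vaf_min < vaf_max < 0.5")
        if self.similar_fold > self.expanded_fold:
            raise ValueError("similar_fold must be <= expanded_fold")
        if not (0 < self.recurrence_fraction <= 1):
            raise ValueError("recurrence_fraction must be in (0, 1]")
        object.__setattr__(
            self, "nh_reference_tissues", frozenset(self.nh_reference_tissues)
        )

    @classmethod
    def from_dict(cls, d: Mapping) -> "FilterConfig":
        return cls(**dict(d))


@dataclass
class FilterResult:
    """Outcome of candidate filtering for one cohort."""

    survivors: dict[str, list[Variant]]  # animal_id -> surviving variants
    rejections: dict[tuple[str, str], str]  # (animal_id, variant key) -> reason


# Rejection reasons, in precedence order.
GERMLINE_VAF = "germline-VAF"
LOW_VAF = "low-VAF"
READ_SUPPORT = "read-support"
RECURRENCE = "recurrence"


def filter_candidates(
    observations: Iterable[VariantObservation],
    config: FilterConfig = FilterConfig(),
    n_animals: Optional[int] = None,
) -> FilterResult:
    """Apply the BM-VAF window, read-support, and recurrence filters.

    A candidate is evaluated on its bone-marrow observation.  The recurrence
    filter counts, per variant, the fraction of animals in which the variant
    is detected (any tissue VAF >= ``detect_vaf``) out of ``n_animals``
    (default: the number of distinct animals in the input).  Each rejected
    candidate carries exactly one primary reason with precedence
    germline-VAF > low-VAF > read-support > recurrence.
    """
    obs = list(observations)
    if not obs:
        raise ValueError("empty cohort: no observations")
    animals = sorted({o.animal_id for o in obs})
    if n_animals is None:
        n_animals = len(animals)

    # Per variant: animals in which it is detected anywhere.
    detected_in: dict[Variant, set[str]] = {}
    bm: dict[tuple[str, Variant], VariantObservation] = {}
    candidates: dict[str, set[Variant]] = {a: set() for a in animals}
    for o in obs:
        if o.vaf_defined and o.vaf >= config.detect_vaf:
            detected_in.setdefault(o.variant, set()).add(o.animal_id)
        if o.tissue == "BM":
            bm[(o.animal_id, o.variant)] = o
            candidates[o.animal_id].add(o.variant)

    survivors: dict[str, list[Variant]] = {a: [] for a in animals}
    rejections: dict[tuple[str, str], str] = {}
    for animal in animals:
        for variant in sorted(candidates[animal]):
            o = bm[(animal, variant)]
            vaf = o.vaf if o.vaf_defined else 0.0
            recurrence = len(detected_in.get(variant, ())) / n_animals
            if vaf > config.vaf_max:
                reason = GERMLINE_VAF
            elif vaf < config.vaf_min:
                reason = LOW_VAF
            elif o.alt_reads < config.min_alt_reads:
                reason = READ_SUPPORT
            elif recurrence > config.recurrence_fraction:
                reason = RECURRENCE
            else:
                survivors[animal].append(variant)
                continue
            rejections[(animal, variant.key)] = reason
    return FilterResult(survivors=survivors, rejections=rejections)


def classify_profile(
    profile: VariantProfile, config: FilterConfig = FilterConfig()
) -> str:
    """Label a variant's tissue distribution; sets ``profile.class_label``.

    With ``v_bm`` the BM VAF and ``v_nh`` the maximum VAF over the
    non-hematopoietic reference tissues:

    * ``CH_NONMOSAIC`` — undetectable outside blood (``v_nh < detect_vaf``);
    * ``CH_MOSAIC``   — detectable but expanded ``>= expanded_fold`` in BM;
    * ``MOSAIC_NOT_CH`` — detectable with BM within ``similar_fold`` of it;
    * ``UNCLASSIFIED``  — ratio falls between the folds, BM is missing, or no
      reference tissue was measured (reason recorded).
    """
    v_bm = profile.bm_vaf
    if v_bm is None:
        profile.class_label = "UNCLASSIFIED"
        profile.class_reason = "no BM observation"
        return profile.class_label
    nh_vafs = [
        vaf
        for tissue, (vaf, _depth) in profile.vaf_by_tissue.items()
        if tissue in config.nh_reference_tissues and not np.isnan(vaf)
    ]
    if not nh_vafs:
        profile.class_label = "UNCLASSIFIED"
        profile.class_reason = "no non-hematopoietic tissue measured"
        logger.info(
            "%s %s: no non-hematopoietic reference tissue", profile.animal_id,
            profile.variant.key,
        )
        return profile.class_label
    v_nh = max(nh_vafs)
    if v_nh < config.detect_vaf:
        label, reason = "CH_NONMOSAIC", ""
    elif v_bm / v_nh >= config.expanded_fold:
        label, reason = "CH_MOSAIC", ""
    elif v_bm / v_nh <= config.similar_fold:
        label, reason = "MOSAIC_NOT_CH", ""
    else:
        label = "UNCLASSIFIED"
        reason = (
            f"BM/non-hematopoietic ratio {v_bm / v_nh:.2f} between "
            f"similar_fold and expanded_fold"
        )
        logger.info("%s %s: %s", profile.animal_id, profile.variant.key, reason)
    profile.class_label = label
    profile.class_reason = reason
    return label


def clone_fraction(vaf: float) -> float:
    """Convert a heterozygous VAF to the fraction of cells carrying the clone.

    A somatic mutation normally hits one chromosome of a diploid cell, so the
    carrier-cell fraction is twice the allele frequency; a VAF of 0.1 marks a
    clone delivering 20% of cells.  VAF above 0.5 violates the assumption.
    """
    if vaf < 0 or vaf > 0.5:
        raise ValueError(f"VAF {vaf} outside [0, 0.5]: heterozygous-diploid assumption violated")
    return 2.0 * vaf


@dataclass
class CohortSummary:
    """Per-animal class counts with BM VAF > 0.1 sub-counts, and group means."""

    per_animal: pd.DataFrame  # indexed by animal_id
    group_means: pd.DataFrame  # indexed by group
    n_with_ch: dict[str, int] = field(default_factory=dict)  # per group
    n_with_ch_high_vaf: dict[str, int] = field(default_factory=dict)

    COUNT_COLS = (
        "MOSAIC_NOT_CH",
        "CH_MOSAIC",
        "CH_NONMOSAIC",
        "MOSAIC_NOT_CH_gt01",
        "CH_MOSAIC_gt01",
        "CH_NONMOSAIC_gt01",
    )

    def total(self, label: str) -> int:
        return int(self.per_animal[label].sum())


def summarize_cohort(
    profiles: Sequence[VariantProfile],
    animals: Sequence[AnimalRecord],
    high_vaf: float = 0.1,
) -> CohortSummary:
    """Tabulate classified variants per animal and average within dose groups.

    Sub-counts (``*_gt01``) use a strict BM VAF > ``high_vaf``.  Also reports,
    per group, the number of animals carrying at least one CH-associated
    mutation (CH_MOSAIC + CH_NONMOSAIC), overall and at BM VAF > ``high_vaf``.
    Every profile must be classified and reference a known animal.
    """
    known = {a.animal_id: a for a in animals}
    counts = pd.DataFrame(
        0,
        index=pd.Index([a.animal_id for a in animals], name="animal_id"),
        columns=list(CohortSummary.COUNT_COLS),
    )
    for p in profiles:
        if p.class_label == "UNCLASSIFIED":
            raise ValueError(
                f"profile {p.animal_id}/{p.variant.key} is unclassified"
            )
        if p.animal_id not in known:
            raise KeyError(f"profile references unknown animal {p.animal_id!r}")
        counts.loc[p.animal_id, p.class_label] += 1
        bm = p.bm_vaf
        if bm is not None and bm > high_vaf:
            counts.loc[p.animal_id, f"{p.class_label}_gt01"] += 1

    group_of = pd.Series({a.animal_id: a.group for a in animals}, name="group")
    group_means = counts.groupby(group_of).mean()

    ch = counts["CH_MOSAIC"] + counts["CH_NONMOSAIC"]
    ch_high = counts["CH_MOSAIC_gt01"] + counts["CH_NONMOSAIC_gt01"]
    n_with_ch = {
        g: int((ch[group_of == g] > 0).sum()) for g in group_of.unique()
    }
    n_with_ch_high = {
        g: int((ch_high[group_of == g] > 0).sum()) for g in group_of.unique()
    }
    return CohortSummary(
        per_animal=counts,
        group_means=group_means,
        n_with_ch=n_with_ch,
        n_with_ch_high_vaf=n_with_ch_high,
    )
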