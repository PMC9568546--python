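"""Mutation-spectrum characterization.

Typed events are tallied per animal: base substitutions collapsed onto the
pyrimidine strand (six classes, C→T transitions dominate in both aging and
post-irradiation blood), deletion lengths (ionizing radiation yields an excess
of multi-nucleotide deletions, often with junction microhomology from
microhomology-mediated end joining), and multisite events — clusters of nearby
SNVs/indels arising from a single damage track, detected here by
single-linkage clustering on genomic distance with VAF agreement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .model import Variant, VariantProfile

logger = logging.getLogger(__name__)

__all__ = [
    "DeletionContext",
    "SpectrumSummary",
    "variant_type",
    "substitution_class",
    "microhomology_length",
    "detect_multisite",
    "spectrum_summary",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
DELETION_LENGTH_BINS = ("1-3", "4", "5-31", ">31")


def variant_type(ref: str, alt: str) -> str:
    """Classify VCF-style alleles as SNV, INS, DEL, or COMPLEX.

    DEL/INS require the shorter allele to be a prefix of the longer (anchor
    base convention); anything irreducible is COMPLEX and excluded from the
    histograms downstream.
    """
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if len(ref) > len(alt) and ref.startswith(alt):
        return "DEL"
    if len(alt) > len(ref) and alt.startswith(ref):
        return "INS"
    logger.info("complex substitution %s>%s excluded from histograms", ref, alt)
    return "COMPLEX"


def deletion_length(ref: str, alt: str) -> int:
    if variant_type(ref, alt) != "DEL":
        raise ValueError(f"{ref}>{alt} is not a deletion")
    return len(ref) - len(alt)


def substitution_class(ref: str, alt: str) -> str:
    """Pyrimidine-strand substitution class of an SNV (G→A reported as C→T)."""
    if ref == alt:
        raise ValueError("ref == alt is not a substitution")
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError(f"{ref}>{alt} is not an SNV")
    if ref in "GA":
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
    return f"{ref}>{alt}"


@dataclass(frozen=True)
class DeletionContext:
    """A deleted segment with its flanking reference sequence.

    ``left_flank`` ends immediately 5' of the deleted bases; ``right_flank``
    starts immediately 3' of them.  Flanks should each be at least as long as
    the deleted segment (pad from the reference when extracting).
    """

    deleted_seq: str
    left_flank: str
    right_flank: str

    def __post_init__(self) -> None:
        if not self.deleted_seq:
            raise ValueError("empty deleted_seq")


def microhomology_length(context: DeletionContext) -> int:
    """Length of junction microhomology between deleted and flanking sequence.

    Returns the larger of (a) the longest common prefix of the deleted segment
    and the right flank and (b) the longest common suffix of the deleted
    segment and the left flank — homology at either junction end counts.
    Microhomology-mediated end joining is inferred for lengths >= 2.
    """
    d = context.deleted_seq
    right = context.right_flank
    prefix = 0
    for a, b in zip(d, right):
        if a != b:
            break
        prefix += 1
    left = context.left_flank
    suffix = 0
    for a, b in zip(reversed(d), reversed(left)):
        if a != b:
            break
        suffix += 1
    return max(prefix, suffix)


def has_microhomology(context: DeletionContext, min_len: int = 2) -> bool:
    return microhomology_length(context) >= min_len


@dataclass
class MultisiteCluster:
    members: list[Variant]

    @property
    def size(self) -> int:
        return len(self.members)


def detect_multisite(
    variants: Sequence[tuple[Variant, float]],
    window_bp: int = 100,
    vaf_tol: float = 0.05,
) -> list[MultisiteCluster]:
    """Find clustered variants of one animal that form single multisite events.

    Input is (variant, BM VAF) pairs.  Two variants link when they sit on the
    same chromosome within ``window_bp`` of each other and their BM VAFs agree
    within ``vaf_tol`` (absolute); single-linkage connected components of size
    >= 2 are returned as multisite events.  Members of an event are excluded
    from the plain SNV/deletion tallies by :func:`spectrum_summary`.
    """
    items = sorted(variants, key=lambda it: (it[0].chrom, it[0].pos, it[0].key))
    n = len(items)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(n):
        vi, fi = items[i]
        for j in range(i + 1, n):
            vj, fj = items[j]
            if vj.chrom != vi.chrom or vj.pos - vi.pos > window_bp:
                break
            if abs(fi - fj) <= vaf_tol:
                union(i, j)

    groups: dict[int, list[Variant]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(items[i][0])
    return [MultisiteCluster(members=g) for g in groups.values() if len(g) >= 2]


@dataclass
class SpectrumSummary:
    """Event counts and histograms for one cohort's CH-associated mutations."""

    per_animal: pd.DataFrame  # columns DEL, SNV, MULTISITE, COMPLEX
    substitution_hist: dict[str, int] = field(default_factory=dict)
    deletion_length_hist: dict[str, int] = field(default_factory=dict)
    microhomology_count: int = 0
    n_deletions_with_context: int = 0

    def total(self, col: str) -> int:
        return int(self.per_animal[col].sum()) if col in self.per_animal else 0


def spectrum_summary(
    profiles: Sequence[VariantProfile],
    contexts: Optional[dict[str, DeletionContext]] = None,
    window_bp: int = 100,
    vaf_tol: float = 0.05,
    mh_min_len: int = 2,
    class_labels: Iterable[str] = ("CH_NONMOSAIC",),
) -> SpectrumSummary:
    """Summarize the mutation spectrum of CH-associated non-mosaic variants.

    Multisite clustering runs per animal first; cluster members are counted as
    one MULTISITE event and removed from the SNV/DEL tallies, so per-animal
    counts are post-clustering event counts.  ``contexts`` maps variant keys
    to :class:`DeletionContext` for junction-microhomology scoring; deletions
    without a context are skipped for that tally only.  Deletion lengths are
    histogrammed into the bins 1-3 / 4 / 5-31 / >31 nt.
    """
    wanted = [p for p in profiles if p.class_label in set(class_labels)]
    animal_ids = sorted({p.animal_id for p in wanted})
    counts = pd.DataFrame(
        0,
        index=pd.Index(animal_ids, name="animal_id"),
        columns=["DEL", "SNV", "MULTISITE", "INS", "COMPLEX"],
    )
    sub_hist = {c: 0 for c in SUBSTITUTION_CLASSES}
    del_hist = {b: 0 for b in DELETION_LENGTH_BINS}
    mh_count = 0
    n_del_ctx = 0

    for animal in animal_ids:
        mine = [p for p in wanted if p.animal_id == animal]
        bm = {p.variant: (p.bm_vaf if p.bm_vaf is not None else 0.0) for p in mine}
        clusters = detect_multisite(
            [(v, f) for v, f in bm.items()], window_bp=window_bp, vaf_tol=vaf_tol
        )
        clustered = {v for c in clusters for v in c.members}
        counts.loc[animal, "MULTISITE"] = len(clusters)
        for p in mine:
            v = p.variant
            if v in clustered:
                continue
            vt = variant_type(v.ref, v.alt)
            if vt == "SNV":
                counts.loc[animal, "SNV"] += 1
                sub_hist[substitution_class(v.ref, v.alt)] += 1
            elif vt == "DEL":
                counts.loc[animal, "DEL"] += 1
                d = deletion_length(v.ref, v.alt)
                if d <= 3:
                    del_hist["1-3"] += 1
                elif d == 4:
                    del_hist["4"] += 1
                elif d <= 31:
                    del_hist["5-31"] += 1
                else:
                    del_hist[">31"] += 1
                ctx = (contexts or {}).get(v.key)
                if ctx is not None:
                    n_del_ctx += 1
                    if has_microhomology(ctx, mh_min_len):
                        mh_count += 1
            elif vt == "INS":
                counts.loc[animal, "INS"] += 1
            else:
                counts.loc[animal, "COMPLEX"] += 1
    return SpectrumSummary(
        per_animal=counts,
        substitution_hist=sub_hist,
        deletion_length_hist=del_hist,
        microhomology_count=mh_count,
        n_deletions_with_context=n_del_ctx,
    )
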