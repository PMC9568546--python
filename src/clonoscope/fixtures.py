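"""Deterministic in-memory fixtures encoding a published irradiated-mouse cohort.

These encode, as pipeline *inputs*, the published per-mouse data: the
three-group mutation counts of the 18-mouse cohort (with BM VAF > 0.1
sub-counts and ages), the mutation-type breakdown of the 65
hematopoietic-restricted mutations (35 deletions / 27 SNVs / 3 multisite
events, deletion lengths split 12 at 1–3 nt and 23 at 5–31 nt with 8
microhomology junctions), and the two colony-genotyped mice: mouse 33
(embryonic Nell2 SNV at BM VAF 0.29 containing two exclusive subclones,
Eif3I SNV at 0.14 and a 1700122O11Rik deletion at 0.12) and mouse 85 (four
independent clones over 10 mutations delivering 80% of BM).

Acceptance and regression tests run the real pipeline on these fixtures and
compare against the published totals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .model import (
    AnimalRecord,
    ColonyGenotypeMatrix,
    Variant,
    VariantObservation,
    VariantProfile,
)
from .spectrum import DeletionContext
from . import io as cio

__all__ = ["ReferenceFixtures", "make_reference_fixtures"]

_DEPTH = 30_000
_VALIDATION_TISSUES = ("BM", "spleen", "tail", "brain", "testis")

# Per-mouse (age, class counts with BM VAF > 0.1 sub-counts).
_TABLE1 = {
    # mouse: (age, group, mosaic(gt01), ch_mosaic(gt01), ch_nonmosaic(gt01))
    "11": (19.5, "IRRADIATED", (1, 1), (0, 0), (2, 1)),
    "12": (19.5, "IRRADIATED", (0, 0), (2, 2), (5, 5)),
    "21": (19.1, "IRRADIATED", (1, 0), (0, 0), (2, 0)),
    "22": (19.1, "IRRADIATED", (0, 0), (0, 0), (5, 4)),
    "23": (19.1, "IRRADIATED", (1, 1), (0, 0), (0, 0)),
    "31": (19.1, "IRRADIATED", (0, 0), (0, 0), (3, 0)),
    "32": (19.1, "IRRADIATED", (1, 1), (0, 0), (5, 4)),
    "33": (19.1, "IRRADIATED", (0, 0), (1, 1), (2, 2)),
    "85": (16.0, "IRRADIATED", (0, 0), (0, 0), (10, 3)),
    "91": (14.7, "IRRADIATED", (0, 0), (0, 0), (8, 1)),
    "92": (14.7, "IRRADIATED", (0, 0), (1, 1), (15, 9)),
    "94": (14.7, "IRRADIATED", (0, 0), (1, 1), (8, 2)),
    "51": (19.1, "CONTROL", (1, 1), (0, 0), (0, 0)),
    "52": (19.1, "CONTROL", (0, 0), (0, 0), (0, 0)),
    "53": (19.4, "CONTROL", (1, 1), (0, 0), (0, 0)),
    "61": (19.2, "CONTROL", (0, 0), (0, 0), (0, 0)),
    "71": (17.2, "CONTROL", (3, 3), (0, 0), (0, 0)),
    "73": (18.5, "CONTROL", (0, 0), (0, 0), (0, 0)),
}

# Per-mouse (deletions, SNVs, multisite events) among the hematopoietic-
# restricted mutations.
_TABLE2 = {
    "11": (2, 0, 0), "12": (2, 3, 0), "21": (2, 0, 0), "22": (1, 4, 0),
    "23": (0, 0, 0), "31": (2, 1, 0), "32": (3, 2, 0), "33": (1, 1, 0),
    "85": (6, 3, 1), "91": (3, 4, 1), "92": (9, 6, 0), "94": (4, 3, 1),
}

# Named mutations of the two colony-genotyped mice (chrom, pos from the
# published per-mutation positions; alleles synthetic).
_NELL2 = Variant("chr15", 95_432_868, "A", "G")
_EIF3I = Variant("chr15", 79_076_783, "T", "C")
_RIK_DEL = Variant("chr17", 48_036_757, "CTGA", "C")

_MOUSE85_GROUPS: list[tuple[list[Variant], float]] = [
    ([Variant("chr1", 170_961_340, "C", "T"),      # Fcgr2b
      Variant("chr8", 36_512_373, "G", "A")],      # 6430573F11Rik
     0.14),
    ([Variant("chr12", 80_649_329, "A", "G"),      # Slc39a9
      Variant("chr2", 52_720_990, "C", "A"),       # Stam2
      Variant("chr9", 56_918_333, "T", "C")],      # Snx33
     0.08),
    ([Variant("chr13", 49_239_072, "G", "T"),      # Susd3
      Variant("chr13", 58_259_599, "C", "T"),      # Gkap1
      Variant("chr14", 50_392_765, "A", "T"),      # Olfr736
      Variant("chr17", 24_594_785, "G", "C")],     # Pkd1
     0.06),
    ([Variant("chr13", 67_673_456, "T", "A")],     # Zfp738
     0.12),
]


@dataclass
class ReferenceFixtures:
    animals: list[AnimalRecord]
    table1_observations: list[VariantObservation]
    table2_profiles: list[VariantProfile]
    table2_contexts: dict[str, DeletionContext]
    mouse33_colonies: ColonyGenotypeMatrix
    mouse33_bulk_bm: dict[str, float]
    mouse85_colonies: ColonyGenotypeMatrix
    mouse85_bulk_bm: dict[str, float]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cio.write_animals(self.animals, outdir / "animals.csv")
        cio.write_variant_table(self.table1_observations, outdir / "table1_variants.tsv")
        cio.write_variant_profiles(self.table2_profiles, outdir / "table2_profiles.tsv")
        cio.write_colony_matrix(self.mouse33_colonies, outdir / "colonies_33.csv")
        cio.write_colony_matrix(self.mouse85_colonies, outdir / "colonies_85.csv")


class _PositionFactory:
    """Well-separated deterministic positions (>= 1 Mb apart per chromosome)."""

    def __init__(self) -> None:
        self._i = 0

    def __call__(self) -> tuple[str, int]:
        i = self._i
        self._i += 1
        return f"chr{1 + i % 19}", 5_000_000 + (i // 19 + 1) * 1_000_000 + i


def _obs(animal: str, variant: Variant, vaf_by_tissue: dict[str, float]
         ) -> list[VariantObservation]:
    return [
        VariantObservation(
            animal_id=animal, tissue=t, chrom=variant.chrom, pos=variant.pos,
            ref=variant.ref, alt=variant.alt,
            alt_reads=int(round(v * _DEPTH)), depth=_DEPTH,
        )
        for t, v in vaf_by_tissue.items()
    ]


def _tissue_vafs(label: str, bm_vaf: float) -> dict[str, float]:
    if label == "MOSAIC_NOT_CH":
        return {t: bm_vaf for t in _VALIDATION_TISSUES}
    if label == "CH_MOSAIC":
        nh = bm_vaf / 10.0  # detectable but 10-fold expanded in blood
        return {"BM": bm_vaf, "spleen": bm_vaf, "tail": nh, "brain": nh, "testis": nh}
    return {"BM": bm_vaf, "spleen": bm_vaf, "tail": 0.0, "brain": 0.0, "testis": 0.0}


def _table1_observations() -> list[VariantObservation]:
    pos_factory = _PositionFactory()
    observations: list[VariantObservation] = []
    for mouse, (_age, _group, mosaic, chm, chnm) in _TABLE1.items():
        specs: list[tuple[str, float, Variant | None]] = []
        for label, (count, gt01) in (
            ("MOSAIC_NOT_CH", mosaic), ("CH_MOSAIC", chm), ("CH_NONMOSAIC", chnm)
        ):
            for k in range(count):
                vaf = 0.2 if k < gt01 else 0.05
                specs.append((label, vaf, None))
        # named mutations of the colony-genotyped mice replace generic ones
        if mouse == "33":
            specs = [("CH_MOSAIC", 0.29, _NELL2),
                     ("CH_NONMOSAIC", 0.14, _EIF3I),
                     ("CH_NONMOSAIC", 0.12, _RIK_DEL)]
        if mouse == "85":
            specs = [("CH_NONMOSAIC", vaf, v)
                     for group, vaf in _MOUSE85_GROUPS for v in group]
        for j, (label, vaf, variant) in enumerate(specs):
            if variant is None:
                chrom, pos = pos_factory()
                # the cohort's two mosaic deletions (mice 23 and 94); all
                # other tabulated mutations are SNVs
                if (mouse == "23" and label == "MOSAIC_NOT_CH") or (
                    mouse == "94" and label == "CH_MOSAIC"
                ):
                    variant = Variant(chrom, pos, "GTC", "G")
                else:
                    variant = Variant(chrom, pos, "ACGT"[j % 4], "GTAC"[j % 4])
            observations.extend(_obs(mouse, variant, _tissue_vafs(label, vaf)))
    return observations


def _table2_fixture() -> tuple[list[VariantProfile], dict[str, DeletionContext]]:
    # 35 deletion lengths: 12 short (1-3 nt), 23 long (5-27 nt); junction
    # microhomology planted in 8 of the long ones.
    lengths = [1, 2, 3] * 4 + list(range(5, 28))
    mh_flags = [False] * 12 + [True] * 8 + [False] * 15
    del_iter = iter(zip(lengths, mh_flags))

    rng = np.random.default_rng(20221014)  # fixed: fixture must be deterministic
    pos_factory = _PositionFactory()
    profiles: list[VariantProfile] = []
    contexts: dict[str, DeletionContext] = {}

    def add_profile(mouse: str, variant: Variant, vaf: float) -> None:
        profiles.append(VariantProfile(
            animal_id=mouse, variant=variant,
            vaf_by_tissue={"BM": (vaf, _DEPTH), "tail": (0.0, _DEPTH)},
            class_label="CH_NONMOSAIC",
        ))

    for mouse, (n_del, n_snv, n_multi) in _TABLE2.items():
        for _ in range(n_del):
            length, mh = next(del_iter)
            chrom, pos = pos_factory()
            deleted = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
            left = "".join("ACGT"[i] for i in rng.integers(0, 4, size=31))
            right = "".join("ACGT"[i] for i in rng.integers(0, 4, size=31))
            if mh:
                k = min(3, length)
                right = deleted[:k] + right[k:]
            else:
                # scrub chance homology so the microhomology count is exact
                right = _break_prefix(deleted, right)
                left = _break_suffix(deleted, left)
            variant = Variant(chrom, pos, "A" + deleted, "A")
            contexts[variant.key] = DeletionContext(deleted, left, right)
            add_profile(mouse, variant, 0.15)
        for k in range(n_snv):
            chrom, pos = pos_factory()
            add_profile(mouse, Variant(chrom, pos, "CT"[k % 2], "TC"[k % 2]), 0.15)
        for _ in range(n_multi):
            chrom, pos = pos_factory()
            add_profile(mouse, Variant(chrom, pos, "G", "A"), 0.12)
            add_profile(mouse, Variant(chrom, pos + 30, "C", "T"), 0.12)
    return profiles, contexts


def _break_prefix(deleted: str, right: str) -> str:
    if len(deleted) >= 2 and right[:2] == deleted[:2]:
        swap = {"A": "C", "C": "A", "G": "T", "T": "G"}
        right = swap[right[0]] + right[1:]
    return right


def _break_suffix(deleted: str, left: str) -> str:
    if len(deleted) >= 2 and left[-2:] == deleted[-2:]:
        swap = {"A": "C", "C": "A", "G": "T", "T": "G"}
        left = left[:-1] + swap[left[-1]]
    return left


def _colony_matrix(animal: str, n_hsc: int, n_mpp: int,
                   presence: dict[str, tuple[set[int], set[int]]],
                   variants: list[Variant]) -> ColonyGenotypeMatrix:
    """Build a noise-free colony matrix from 1-based HSC/MPP colony index sets."""
    colonies = [(f"HSC{i:02d}", "HSC") for i in range(1, n_hsc + 1)]
    colonies += [(f"MPP{i:02d}", "MPP") for i in range(1, n_mpp + 1)]
    n, m = len(colonies), len(variants)
    vaf = np.zeros((n, m))
    depth = np.full((n, m), 100, dtype=int)
    for j, v in enumerate(variants):
        hsc_idx, mpp_idx = presence[v.key]
        for i, (cid, comp) in enumerate(colonies):
            idx = int(cid[3:])
            wanted = hsc_idx if comp == "HSC" else mpp_idx
            if idx in wanted:
                vaf[i, j] = 0.5
    return ColonyGenotypeMatrix(
        animal_id=animal, colonies=colonies, variants=variants, vaf=vaf, depth=depth,
    )


def make_reference_fixtures() -> ReferenceFixtures:
    """Build all fixtures; deterministic (no free randomness)."""
    animals = [
        AnimalRecord(
            animal_id=mouse, group=group,
            dose_Gy=3.0 if group == "IRRADIATED" else 0.0,
            sex="M", age_months=age,
        )
        for mouse, (age, group, *_counts) in _TABLE1.items()
    ]
    table2_profiles, table2_contexts = _table2_fixture()

    # Mouse 33: Nell2 clone (13/20 HSC, 9/20 MPP colonies) containing two
    # exclusive subclones, Eif3I (HSC+MPP) and the Rik deletion (MPP only).
    m33 = _colony_matrix(
        "33", 20, 20,
        presence={
            _NELL2.key: (set(range(1, 14)), set(range(1, 10))),
            _EIF3I.key: (set(range(1, 7)), set(range(1, 5))),
            _RIK_DEL.key: (set(), set(range(5, 9))),
        },
        variants=[_NELL2, _EIF3I, _RIK_DEL],
    )
    m33_bulk = {_NELL2.key: 0.29, _EIF3I.key: 0.14, _RIK_DEL.key: 0.12}

    # Mouse 85: four mutually exclusive clones; one spans HSC and MPP, one
    # sits in a single HSC colony, two are MPP-only.
    g1, g2, g3, g4 = (grp for grp, _vaf in _MOUSE85_GROUPS)
    presence85: dict[str, tuple[set[int], set[int]]] = {}
    for v in g1:
        presence85[v.key] = (set(range(1, 8)), set(range(1, 7)))
    for v in g2:
        presence85[v.key] = (set(), set(range(7, 13)))
    for v in g3:
        presence85[v.key] = (set(), set(range(13, 19)))
    for v in g4:
        presence85[v.key] = ({8}, set())
    m85_variants = [v for grp, _vaf in _MOUSE85_GROUPS for v in grp]
    m85 = _colony_matrix("85", 26, 26, presence85, m85_variants)
    m85_bulk = {v.key: vaf for grp, vaf in _MOUSE85_GROUPS for v in grp}

    return ReferenceFixtures(
        animals=animals,
        table1_observations=_table1_observations(),
        table2_profiles=table2_profiles,
        table2_contexts=table2_contexts,
        mouse33_colonies=m33,
        mouse33_bulk_bm=m33_bulk,
        mouse85_colonies=m85,
        mouse85_bulk_bm=m85_bulk,
    )
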