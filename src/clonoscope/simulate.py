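"""Synthetic-cohort generator with exported ground truth.

Emulates the statistical structure of a deep-sequencing study of
radiation-induced clonal hematopoiesis in mice: a cohort of irradiated and
non-irradiated animals carrying (a) embryonic mosaic mutations shared across
tissues at correlated frequencies, (b) hematopoietic-restricted clonal
mutations, (c) embryonic mosaics that later expanded in blood, with a
radiation-like spectrum (C→T-dominant substitutions, 1–31 nt deletions with
optional junction microhomology, clustered multisite events), binomial read
sampling at configurable depths, and single-HSPC colonies drawn from the
clone mixture with heterozygous VAFs near 0.5.

The generator is parametric, not mechanistic: clone fractions are drawn once
per animal (no birth–death dynamics), and colony matrices cover only the
hematopoietically expanded clones, which are modeled as mutually exclusive.
A separate harness (:func:`random_clone_tree` /
:func:`simulate_colonies_from_tree`) generates arbitrary nested clone trees
for structure-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .model import (
    AnimalRecord,
    ColonyGenotypeMatrix,
    Variant,
    VariantObservation,
)
from .spectrum import DeletionContext
from . import io as cio

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimulatedCohort",
    "simulate",
    "random_clone_tree",
    "simulate_colonies_from_tree",
    "CloneTree",
]

_BASES = "ACGT"

DEFAULT_TISSUES = (
    "BM", "spleen", "thymus", "tail", "kidney", "liver", "brain",
    "thyroid", "testis", "T", "B", "GRAN", "ERY",
)

#: Pyrimidine-strand substitution weights, C→T transitions dominant as in
#: aging and post-irradiation hematopoietic spectra.
DEFAULT_SUB_WEIGHTS = {
    "C>A": 0.08, "C>G": 0.06, "C>T": 0.40, "T>A": 0.10, "T>C": 0.24, "T>G": 0.12,
}


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation parameters.

    Defaults mirror the study conditions being emulated: 12 irradiated and 6
    control animals, about 5.8 clonal-hematopoiesis mutations per irradiated
    mouse above the 0.02 VAF threshold (ch_rate clones of ~2.3 mutations
    each), ~0.5 embryonic mosaics per animal, deep targeted sequencing at
    30,000x with a 500x discovery depth, and colony genotyping at 100x.
    """

    n_irradiated: int = 12
    n_control: int = 6
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    seed: int = 0
    mosaic_rate: float = 0.5
    ch_rate_irradiated: float = 4.0
    ch_rate_control: float = 0.0
    ch_mosaic_rate: float = 0.4
    clone_dirichlet: float = 1.0
    max_total_fraction: float = 0.9
    mutations_per_clone_lam: float = 2.0
    sub_weights: tuple[tuple[str, float], ...] = tuple(DEFAULT_SUB_WEIGHTS.items())
    deletion_fraction: float = 0.55
    short_deletion_prob: float = 0.35  # P(length 1-3), else uniform on 5-31
    microhomology_prob: float = 0.25
    multisite_prob: float = 0.05
    depth_bulk: int = 500
    depth_amplicon: int = 30000
    depth_colony: int = 100
    seq_error: float = 0.001
    t_cell_exclusion_prob: float = 0.5
    n_hsc_colonies: int = 20
    n_mpp_colonies: int = 20
    noise: str = "binomial"  # "binomial" or "none"

    def __post_init__(self) -> None:
        for r in (self.mosaic_rate, self.ch_rate_irradiated, self.ch_rate_control,
                  self.ch_mosaic_rate):
            if r < 0:
                raise ValueError("rates must be >= 0")
        if not (0 < self.max_total_fraction <= 1):
            raise ValueError("max_total_fraction must be in (0, 1]")
        total = sum(w for _, w in self.sub_weights)
        if abs(total - 1) > 1e-6:
            raise ValueError("substitution weights must normalize to 1")
        if self.noise not in ("binomial", "none"):
            raise ValueError("noise must be 'binomial' or 'none'")


@dataclass
class TrueMutation:
    variant: Variant
    true_class: str  # MOSAIC_NOT_CH / CH_MOSAIC / CH_NONMOSAIC
    clone_id: str
    vaf_by_tissue: dict[str, float]
    multisite_event: Optional[str] = None  # event id when part of a cluster
    context: Optional[DeletionContext] = None


@dataclass
class TrueClone:
    clone_id: str
    bm_fraction: float
    mutation_keys: list[str]


@dataclass
class SimTruth:
    """Ground truth emitted by the simulator, keyed by animal."""

    clones: dict[str, list[TrueClone]] = field(default_factory=dict)
    mutations: dict[str, list[TrueMutation]] = field(default_factory=dict)
    colony_clone: dict[str, dict[str, str]] = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            "clones": {
                a: [asdict(c) for c in cs] for a, cs in sorted(self.clones.items())
            },
            "mutations": {
                a: [
                    {
                        "key": m.variant.key,
                        "true_class": m.true_class,
                        "clone_id": m.clone_id,
                        "vaf_by_tissue": m.vaf_by_tissue,
                        "multisite_event": m.multisite_event,
                    }
                    for m in ms
                ]
                for a, ms in sorted(self.mutations.items())
            },
            "colony_clone": {a: dict(sorted(d.items())) for a, d in sorted(self.colony_clone.items())},
        }


@dataclass
class SimulatedCohort:
    config: SimConfig
    animals: list[AnimalRecord]
    observations: list[VariantObservation]
    colony_matrices: dict[str, ColonyGenotypeMatrix]
    truth: SimTruth
    contexts: dict[str, DeletionContext]

    def write(self, outdir: str | Path) -> None:
        """Write variants.tsv, animals.csv, colonies_<id>.csv, truth.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cio.write_variant_table(self.observations, outdir / "variants.tsv")
        cio.write_animals(self.animals, outdir / "animals.csv")
        for aid in sorted(self.colony_matrices):
            cio.write_colony_matrix(
                self.colony_matrices[aid], outdir / f"colonies_{aid}.csv"
            )
        with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
            json.dump(self.truth.to_jsonable(), fh, indent=1, sort_keys=True)
        with open(outdir / "contexts.tsv", "w", encoding="utf-8") as fh:
            fh.write("variant_key\tdeleted_seq\tleft_flank\tright_flank\n")
            for key in sorted(self.contexts):
                c = self.contexts[key]
                fh.write(f"{key}\t{c.deleted_seq}\t{c.left_flank}\t{c.right_flank}\n")


def _zt_poisson(rng: np.random.Generator, lam: float) -> int:
    """Zero-truncated Poisson draw (rejection sampling)."""
    while True:
        k = int(rng.poisson(lam))
        if k > 0:
            return k


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _draw_position(rng: np.random.Generator, used: list[tuple[str, int]],
                   min_gap: int = 1000) -> tuple[str, int]:
    while True:
        chrom = f"chr{rng.integers(1, 20)}"
        pos = int(rng.integers(3_000_000, 180_000_000))
        if all(c != chrom or abs(p - pos) > min_gap for c, p in used):
            used.append((chrom, pos))
            return chrom, pos


def _draw_snv_alleles(rng: np.random.Generator, weights: dict[str, float]
                      ) -> tuple[str, str]:
    classes = list(weights)
    probs = np.array([weights[c] for c in classes])
    cls = classes[rng.choice(len(classes), p=probs / probs.sum())]
    ref, alt = cls.split(">")
    if rng.random() < 0.5:  # emit on the purine strand half the time
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        ref, alt = comp[ref], comp[alt]
    return ref, alt


def _draw_deletion(rng: np.random.Generator, cfg: SimConfig
                   ) -> tuple[str, str, DeletionContext]:
    if rng.random() < cfg.short_deletion_prob:
        length = int(rng.integers(1, 4))
    else:
        length = int(rng.integers(5, 32))
    deleted = _random_seq(rng, length)
    flank_len = max(31, length)
    left = _random_seq(rng, flank_len)
    right = _random_seq(rng, flank_len)
    if rng.random() < cfg.microhomology_prob:
        mh = int(rng.integers(2, min(4, length) + 1)) if length >= 2 else 0
        if mh >= 2:
            right = deleted[:mh] + right[mh:]
    anchor = _random_seq(rng, 1)
    ref = anchor + deleted
    alt = anchor
    return ref, alt, DeletionContext(deleted, left, right)


def _sample_reads(rng: np.random.Generator, depth: int, vaf: float,
                  cfg: SimConfig) -> tuple[int, int]:
    p = min(vaf + cfg.seq_error, 1.0)
    if cfg.noise == "none":
        return int(round(vaf * depth)), depth
    return int(rng.binomial(depth, p)), depth


def _lineage_factors(rng: np.random.Generator, cfg: SimConfig,
                     restricted: bool) -> dict[str, float]:
    """Per-tissue multipliers on the hematopoietic clone fraction.

    ``restricted`` clones (post-irradiation expansions) contribute to B,
    granulocyte and erythroid output but may be excluded from the T lineage
    and contribute little to the thymus.
    """
    f = {"BM": 1.0, "spleen": float(rng.uniform(0.85, 1.15))}
    if restricted and rng.random() < cfg.t_cell_exclusion_prob:
        t_factor = 0.0
    else:
        t_factor = float(rng.uniform(0.5, 1.1))
    f["T"] = t_factor
    f["thymus"] = t_factor * float(rng.uniform(0.4, 1.0))
    for lin in ("B", "GRAN", "ERY"):
        f[lin] = float(rng.uniform(0.7, 1.3))
    return f


def simulate(config: SimConfig = SimConfig(), seed: Optional[int] = None
             ) -> SimulatedCohort:
    """Generate a full synthetic cohort with ground truth.

    Reproducible: the same config and seed give byte-identical output files.
    ``seed`` overrides ``config.seed`` when given.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    nh_tissues = [t for t in cfg.tissues if t in
                  ("tail", "kidney", "liver", "brain", "thyroid", "testis")]

    animals: list[AnimalRecord] = []
    truth = SimTruth()
    observations: list[VariantObservation] = []
    colony_matrices: dict[str, ColonyGenotypeMatrix] = {}
    contexts: dict[str, DeletionContext] = {}
    cohort_variants: list[tuple[str, TrueMutation]] = []  # (animal, mutation)

    ids = [f"irr{i + 1:02d}" for i in range(cfg.n_irradiated)] + [
        f"ctl{i + 1:02d}" for i in range(cfg.n_control)
    ]
    groups = ["IRRADIATED"] * cfg.n_irradiated + ["CONTROL"] * cfg.n_control

    for aid, group in zip(ids, groups):
        irradiated = group == "IRRADIATED"
        sex = "M" if rng.random() < 0.5 else "F"
        age = float(np.round(rng.uniform(14.0, 20.0), 1))
        # Blood indices: group shift plus mild age/sex structure; irradiated
        # animals get larger residual spread (motivates the WLS weighting).
        sd_scale = 1.8 if irradiated else 1.0
        lym = 68.0 - 0.4 * age - (10.0 if irradiated else 0.0) \
            + (1.5 if sex == "F" else 0.0) + float(rng.normal(0, 4.0 * sd_scale))
        mye = 24.0 + 0.3 * age + (10.0 if irradiated else 0.0) \
            - (1.0 if sex == "F" else 0.0) + float(rng.normal(0, 3.5 * sd_scale))
        rdw = 13.8 + 0.03 * age + (2.2 if irradiated else 0.0) \
            + float(rng.normal(0, 0.4 * (4.0 if irradiated else 1.0)))
        animals.append(AnimalRecord(
            animal_id=aid, group=group, dose_Gy=3.0 if irradiated else 0.0,
            sex=sex, age_months=age,
            lym_pct=round(max(lym, 1.0), 2), mye_pct=round(max(mye, 1.0), 2),
            rdw=round(max(rdw, 11.0), 2),
        ))

        used_positions: list[tuple[str, int]] = []
        mutations: list[TrueMutation] = []
        clones: list[TrueClone] = []
        mut_counter = 0
        event_counter = 0

        def new_variant(vaf_by_tissue: dict[str, float], true_class: str,
                        clone_id: str, multisite_event: Optional[str],
                        offset_from: Optional[tuple[str, int]] = None,
                        force_snv: bool = False) -> TrueMutation:
            nonlocal mut_counter
            mut_counter += 1
            if offset_from is not None:
                chrom, base = offset_from
                pos = base + int(rng.integers(5, 80))
            else:
                chrom, pos = _draw_position(rng, used_positions)
            ctx = None
            if not force_snv and rng.random() < cfg.deletion_fraction:
                ref, alt, ctx = _draw_deletion(rng, cfg)
            else:
                ref, alt = _draw_snv_alleles(rng, dict(cfg.sub_weights))
            m = TrueMutation(
                variant=Variant(chrom, pos, ref, alt), true_class=true_class,
                clone_id=clone_id, vaf_by_tissue=vaf_by_tissue,
                multisite_event=multisite_event, context=ctx,
            )
            if ctx is not None:
                contexts[m.variant.key] = ctx
            mutations.append(m)
            cohort_variants.append((aid, m))
            return m

        # (a) embryonic mosaic, no blood expansion: similar VAFs everywhere
        for _ in range(rng.poisson(cfg.mosaic_rate)):
            base_vaf = float(rng.uniform(0.025, 0.30))
            vafs = {t: base_vaf * float(rng.uniform(0.85, 1.18))
                    for t in cfg.tissues}
            clone_id = f"{aid}_mosaic{mut_counter + 1}"
            m = new_variant(vafs, "MOSAIC_NOT_CH", clone_id, None)
            clones.append(TrueClone(clone_id, 2 * vafs["BM"], [m.variant.key]))

        # (c) embryonic mosaic later expanded in the hematopoietic system
        n_chm = rng.poisson(cfg.ch_mosaic_rate) if irradiated else 0
        for _ in range(n_chm):
            nh_vaf = float(rng.uniform(0.006, 0.02))
            bm_vaf = float(rng.uniform(0.15, 0.30))
            factors = _lineage_factors(rng, cfg, restricted=False)
            vafs = {t: nh_vaf * float(rng.uniform(0.85, 1.18)) for t in nh_tissues}
            for t, fac in factors.items():
                if t in cfg.tissues:
                    vafs[t] = min(bm_vaf * fac, 0.5)
            vafs["BM"] = bm_vaf
            clone_id = f"{aid}_chm{mut_counter + 1}"
            m = new_variant(vafs, "CH_MOSAIC", clone_id, None)
            clones.append(TrueClone(clone_id, 2 * bm_vaf, [m.variant.key]))

        # (b) hematopoietic-restricted clones, exclusive, Dirichlet fractions
        rate = cfg.ch_rate_irradiated if irradiated else cfg.ch_rate_control
        n_clones = rng.poisson(rate)
        if n_clones > 0:
            shares = rng.dirichlet(np.full(n_clones + 1, cfg.clone_dirichlet))
            fractions = shares[:n_clones] * cfg.max_total_fraction
            for k, frac in enumerate(fractions):
                clone_id = f"{aid}_ch{k + 1}"
                vaf = float(frac) / 2.0
                factors = _lineage_factors(rng, cfg, restricted=True)
                n_mut = _zt_poisson(rng, cfg.mutations_per_clone_lam)
                keys = []
                for _ in range(n_mut):
                    vafs = {t: 0.0 for t in nh_tissues}
                    for t, fac in factors.items():
                        if t in cfg.tissues:
                            vafs[t] = min(vaf * fac, 0.5)
                    vafs["BM"] = vaf
                    if rng.random() < cfg.multisite_prob:
                        event_counter += 1
                        event = f"{aid}_ms{event_counter}"
                        n_members = int(rng.integers(2, 4))
                        anchor_m = new_variant(dict(vafs), "CH_NONMOSAIC",
                                               clone_id, event, force_snv=True)
                        keys.append(anchor_m.variant.key)
                        for _j in range(n_members - 1):
                            mm = new_variant(
                                dict(vafs), "CH_NONMOSAIC", clone_id, event,
                                offset_from=(anchor_m.variant.chrom,
                                             anchor_m.variant.pos),
                            )
                            keys.append(mm.variant.key)
                    else:
                        m = new_variant(dict(vafs), "CH_NONMOSAIC", clone_id, None)
                        keys.append(m.variant.key)
                clones.append(TrueClone(clone_id, float(frac), keys))

        truth.clones[aid] = clones
        truth.mutations[aid] = mutations

    # --- emit read-count observations -------------------------------------
    # Carried variants: rows for every tissue at validation (amplicon) depth.
    # Other animals' variants: a BM row at discovery depth with error-only
    # reads, which feeds the cross-cohort recurrence filter.
    all_variants: dict[str, TrueMutation] = {}
    carried: dict[tuple[str, str], TrueMutation] = {}
    for aid, m in cohort_variants:
        all_variants.setdefault(m.variant.key, m)
        carried[(aid, m.variant.key)] = m
    for aid, _group in zip(ids, groups):
        for key in sorted(all_variants):
            mine = carried.get((aid, key))
            v = all_variants[key].variant
            if mine is not None:
                for t in cfg.tissues:
                    true_vaf = mine.vaf_by_tissue.get(t, 0.0)
                    alt, depth = _sample_reads(rng, cfg.depth_amplicon, true_vaf, cfg)
                    observations.append(VariantObservation(
                        animal_id=aid, tissue=t, chrom=v.chrom, pos=v.pos,
                        ref=v.ref, alt=v.alt, alt_reads=alt, depth=depth,
                    ))
            else:
                alt, depth = _sample_reads(rng, cfg.depth_bulk, 0.0, cfg)
                observations.append(VariantObservation(
                    animal_id=aid, tissue="BM", chrom=v.chrom, pos=v.pos,
                    ref=v.ref, alt=v.alt, alt_reads=alt, depth=depth,
                ))

    # --- colony matrices ---------------------------------------------------
    # Colonies read out the hematopoietically expanded clones (restricted and
    # mosaic-expanded), modeled as mutually exclusive in BM.
    for aid in ids:
        expanded = [c for c in truth.clones[aid]
                    if not c.clone_id.split("_")[1].startswith("mosaic")]
        if not expanded:
            continue
        matrix, assignment = _draw_colony_matrix(rng, cfg, aid, expanded, truth)
        colony_matrices[aid] = matrix
        truth.colony_clone[aid] = assignment

    return SimulatedCohort(
        config=cfg, animals=animals, observations=observations,
        colony_matrices=colony_matrices, truth=truth, contexts=contexts,
    )


def _draw_colony_matrix(
    rng: np.random.Generator, cfg: SimConfig, aid: str,
    clones: Sequence[TrueClone], truth: SimTruth,
) -> tuple[ColonyGenotypeMatrix, dict[str, str]]:
    fracs = np.array([c.bm_fraction for c in clones])
    total = fracs.sum()
    if total > 1:  # clip pathological configs rather than fail mid-cohort
        fracs = fracs / total * 0.95
    probs = np.append(fracs, 1 - fracs.sum())
    variant_keys = [k for c in clones for k in c.mutation_keys]
    variants = [Variant.from_key(k) for k in variant_keys]
    colonies = [(f"{aid}_HSC{i + 1:02d}", "HSC") for i in range(cfg.n_hsc_colonies)]
    colonies += [(f"{aid}_MPP{i + 1:02d}", "MPP") for i in range(cfg.n_mpp_colonies)]
    n, m = len(colonies), len(variants)
    vaf = np.zeros((n, m))
    depth = np.full((n, m), cfg.depth_colony, dtype=int)
    assignment: dict[str, str] = {}
    clone_of_key = {k: c.clone_id for c in clones for k in c.mutation_keys}
    for i, (cid, _comp) in enumerate(colonies):
        pick = rng.choice(len(clones) + 1, p=probs)
        clone_id = clones[pick].clone_id if pick < len(clones) else "WT"
        assignment[cid] = clone_id
        for j, key in enumerate(variant_keys):
            carried = clone_of_key[key] == clone_id
            true_vaf = 0.5 if carried else 0.0
            if cfg.noise == "none":
                vaf[i, j] = true_vaf
            else:
                p = min(true_vaf + cfg.seq_error, 1.0)
                vaf[i, j] = rng.binomial(cfg.depth_colony, p) / cfg.depth_colony
    matrix = ColonyGenotypeMatrix(
        animal_id=aid, colonies=colonies, variants=variants, vaf=vaf, depth=depth,
    )
    return matrix, assignment


# --------------------------------------------------------------------------
# Clone-tree harness for structure-recovery tests
# --------------------------------------------------------------------------

@dataclass
class CloneNode:
    clone_id: str
    parent: Optional[str]
    clade_fraction: float  # fraction of cells carrying this node's mutations
    own_fraction: float  # clade minus children's clades
    mutations: list[Variant] = field(default_factory=list)


@dataclass
class CloneTree:
    nodes: dict[str, CloneNode]

    def ancestors(self, cid: str) -> list[str]:
        out = []
        p = self.nodes[cid].parent
        while p is not None:
            out.append(p)
            p = self.nodes[p].parent
        return out

    def expected_partition(self) -> list[frozenset[str]]:
        return [frozenset(v.key for v in n.mutations) for n in self.nodes.values()]

    def expected_nested(self) -> set[tuple[str, str]]:
        return {
            (c, a) for c in self.nodes for a in self.ancestors(c)
        }

    def expected_exclusive(self) -> set[frozenset[str]]:
        out = set()
        ids = list(self.nodes)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                if a not in self.ancestors(b) and b not in self.ancestors(a):
                    out.add(frozenset((a, b)))
        return out


def random_clone_tree(
    rng: np.random.Generator,
    n_clones: int,
    mutations_per_clone_lam: float = 2.0,
    total_fraction: float = 0.9,
) -> CloneTree:
    """Draw a random nested clone tree with consistent clade fractions.

    Each clone attaches to the root or to an earlier clone uniformly at
    random.  Clade fractions are assigned top-down with Dirichlet shares and
    a 0.85 occupancy factor, so every node keeps a positive own fraction
    (cells carrying its mutations but none of its children's).
    """
    parents: dict[str, Optional[str]] = {}
    ids = [f"C{i + 1}" for i in range(n_clones)]
    for i, cid in enumerate(ids):
        choices: list[Optional[str]] = [None] + ids[:i]
        parents[cid] = choices[rng.integers(0, len(choices))]

    children: dict[Optional[str], list[str]] = {}
    for cid, p in parents.items():
        children.setdefault(p, []).append(cid)

    nodes: dict[str, CloneNode] = {}

    def assign(parent: Optional[str], budget: float) -> None:
        kids = children.get(parent, [])
        if not kids:
            return
        shares = rng.dirichlet(np.ones(len(kids) + 1)) * 0.85 * budget
        for cid, share in zip(kids, shares[:-1]):
            clade = float(share)
            nodes[cid] = CloneNode(cid, parent, clade, clade)
            assign(cid, clade)
            nodes[cid].own_fraction = clade - sum(
                nodes[k].clade_fraction for k in children.get(cid, [])
            )

    assign(None, total_fraction)

    used: list[tuple[str, int]] = []
    counter = 0
    for cid in ids:
        n_mut = 1 + int(rng.poisson(mutations_per_clone_lam))
        for _ in range(n_mut):
            counter += 1
            chrom, pos = _draw_position(rng, used)
            ref, alt = _draw_snv_alleles(rng, DEFAULT_SUB_WEIGHTS)
            nodes[cid].mutations.append(Variant(chrom, pos, ref, alt))
    return CloneTree(nodes=nodes)


def simulate_colonies_from_tree(
    tree: CloneTree,
    rng: np.random.Generator,
    n_colonies: int = 60,
    depth: int = 1000,
    noise: str = "none",
    allocation: str = "proportional",
    animal_id: str = "sim",
) -> ColonyGenotypeMatrix:
    """Draw single-HSPC colonies from a clone tree.

    A colony founded by a cell of clone C carries C's mutations plus those of
    all its ancestors at VAF 0.5 (heterozygous).  ``allocation="proportional"``
    assigns colony counts deterministically by each node's own fraction with
    at least one colony per clone (suitable for noise-free recovery
    harnesses); ``"multinomial"`` samples colony founders at random.
    """
    node_ids = list(tree.nodes) + ["WT"]
    own = np.array([
        tree.nodes[c].own_fraction if c != "WT" else
        1.0 - sum(n.clade_fraction for n in tree.nodes.values() if n.parent is None)
        for c in node_ids
    ])
    own = np.clip(own, 0, None)
    if allocation == "proportional":
        n_real = len(node_ids) - 1
        if n_colonies < n_real:
            raise ValueError("need at least one colony per clone")
        counts = np.maximum(np.floor(own / own.sum() * n_colonies).astype(int), 0)
        counts[:-1] = np.maximum(counts[:-1], 1)
        while counts.sum() > n_colonies:
            counts[np.argmax(counts)] -= 1
        counts[-1] += n_colonies - counts.sum()
        founders = [cid for cid, k in zip(node_ids, counts) for _ in range(k)]
    elif allocation == "multinomial":
        founders = [node_ids[i] for i in
                    rng.choice(len(node_ids), size=n_colonies, p=own / own.sum())]
    else:
        raise ValueError("allocation must be 'proportional' or 'multinomial'")

    variants = [v for cid in tree.nodes for v in tree.nodes[cid].mutations]
    var_clone = {v.key: cid for cid in tree.nodes for v in tree.nodes[cid].mutations}
    colonies = []
    for i, founder in enumerate(founders):
        comp = "HSC" if i % 2 == 0 else "MPP"
        colonies.append((f"{animal_id}_c{i + 1:03d}", comp))
    n, m = len(colonies), len(variants)
    vaf = np.zeros((n, m))
    depths = np.full((n, m), depth, dtype=int)
    for i, founder in enumerate(founders):
        lineage = set() if founder == "WT" else {founder, *tree.ancestors(founder)}
        for j, v in enumerate(variants):
            true_vaf = 0.5 if var_clone[v.key] in lineage else 0.0
            if noise == "none":
                vaf[i, j] = true_vaf
            else:
                vaf[i, j] = rng.binomial(depth, max(true_vaf, 1e-4)) / depth \
                    if true_vaf > 0 else rng.binomial(depth, 1e-4) / depth
    return ColonyGenotypeMatrix(
        animal_id=animal_id, colonies=colonies, variants=variants,
        vaf=vaf, depth=depths,
    )


def expected_bulk_bm_vaf(tree: CloneTree) -> dict[str, float]:
    """Bulk BM VAF implied by the tree: half of each mutation's clade fraction."""
    return {
        v.key: tree.nodes[cid].clade_fraction / 2.0
        for cid in tree.nodes
        for v in tree.nodes[cid].mutations
    }
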