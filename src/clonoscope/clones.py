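"""Clonal-architecture reconstruction from single-HSPC-colony genotypes.

Each colony grows from one sorted HSC or MPP, so a heterozygous somatic
mutation carried by that founder cell reads out at a VAF near 0.5 in the
colony.  Mutations whose presence/absence patterns across colonies coincide
belong to one clone; strict containment of patterns reveals nested subclones
and disjoint patterns reveal mutually exclusive clones.  Clone sizes in whole
bone marrow come from the bulk VAFs (doubled, heterozygous-diploid
assumption), not from colony proportions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .filtering import clone_fraction
from .model import (
    ABSENT,
    AMBIGUOUS,
    PRESENT,
    ColonyGenotypeMatrix,
    Variant,
    VariantObservation,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeCallConfig",
    "MutationGroup",
    "CloneModel",
    "genotype_colonies",
    "group_mutations",
    "infer_relations",
    "estimate_fractions",
    "render_composition",
]


@dataclass(frozen=True)
class GenotypeCallConfig:
    """Thresholds for calling a mutation present in a colony.

    A heterozygous founder mutation should sit near VAF 0.5; the call window
    ``[het_low, het_high]`` (default [0.3, 0.7]) tolerates amplification
    noise.  Calls require ``min_depth`` reads; low depth — or VAF above
    ``het_high``, which suggests loss of heterozygosity or contamination —
    yields AMBIGUOUS rather than a forced call.  ``max_pattern_mismatch``
    colonies of disagreement are tolerated when matching presence patterns.
    """

    min_depth: int = 20
    het_low: float = 0.3
    het_high: float = 0.7
    max_pattern_mismatch: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.het_low < 0.5 < self.het_high <= 1):
            raise ValueError("need 0 < het_low < 0.5 < het_high <= 1")


def genotype_colonies(
    matrix: ColonyGenotypeMatrix, config: GenotypeCallConfig = GenotypeCallConfig()
) -> ColonyGenotypeMatrix:
    """Fill ``matrix.calls`` with PRESENT / ABSENT / AMBIGUOUS.

    PRESENT: depth >= min_depth and het_low <= VAF <= het_high.
    ABSENT:  depth >= min_depth and VAF < het_low.
    AMBIGUOUS otherwise (insufficient depth, missing VAF, or VAF > het_high).
    """
    calls = np.full(matrix.vaf.shape, AMBIGUOUS, dtype=object)
    deep = matrix.depth >= config.min_depth
    with np.errstate(invalid="ignore"):
        vaf = matrix.vaf
        present = deep & (vaf >= config.het_low) & (vaf <= config.het_high)
        absent = deep & (vaf < config.het_low)
    calls[present] = PRESENT
    calls[absent] = ABSENT
    calls[np.isnan(vaf)] = AMBIGUOUS
    matrix.calls = calls
    return matrix


@dataclass
class MutationGroup:
    """A candidate clone: mutations sharing one colony presence pattern."""

    group_id: str
    mutations: list[Variant]
    support: frozenset[str]  # colony ids with the group PRESENT
    compartments: frozenset[str] = frozenset()


def _require_calls(matrix: ColonyGenotypeMatrix) -> np.ndarray:
    if matrix.calls is None:
        raise ValueError("calls not populated; run genotype_colonies first")
    return matrix.calls


def group_mutations(
    matrix: ColonyGenotypeMatrix, config: GenotypeCallConfig = GenotypeCallConfig()
) -> list[MutationGroup]:
    """Group mutations whose PRESENT-colony sets coincide.

    Two mutations join one group when, over colonies with unambiguous calls
    for both, their presence patterns disagree in at most
    ``max_pattern_mismatch`` colonies (single linkage).  AMBIGUOUS cells never
    count as disagreement, so colony dropout cannot split a clone.
    """
    calls = _require_calls(matrix)
    m = matrix.n_variants
    ids = [cid for cid, _ in matrix.colonies]
    comp = {cid: c for cid, c in matrix.colonies}

    parent = list(range(m))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(m):
        for j in range(i + 1, m):
            both = (calls[:, i] != AMBIGUOUS) & (calls[:, j] != AMBIGUOUS)
            mism = int(np.sum(calls[both, i] != calls[both, j]))
            # mutations never seen in any shared colony carry no co-occurrence
            # evidence and stay in their own groups
            copresent = int(np.sum((calls[both, i] == PRESENT) | (calls[both, j] == PRESENT)))
            if mism <= config.max_pattern_mismatch and copresent > 0:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

    by_root: dict[int, list[int]] = {}
    for i in range(m):
        by_root.setdefault(find(i), []).append(i)

    groups = []
    for k, members in enumerate(sorted(by_root.values(), key=lambda ms: ms[0])):
        support = {
            ids[r]
            for r in range(len(ids))
            if any(calls[r, j] == PRESENT for j in members)
        }
        groups.append(
            MutationGroup(
                group_id=f"G{k + 1}",
                mutations=[matrix.variants[j] for j in members],
                support=frozenset(support),
                compartments=frozenset(comp[c] for c in support),
            )
        )
    return groups


@dataclass
class CloneModel:
    """Mutation groups with their nesting/exclusion relations and BM fractions.

    ``nested`` holds (child, parent) group-id pairs, ``exclusive`` unordered
    id pairs, ``conflicts`` pairs whose colony supports cross (overlap without
    containment), which violates the single-tree assumption.
    """

    groups: list[MutationGroup]
    nested: set[tuple[str, str]] = field(default_factory=set)
    exclusive: set[frozenset[str]] = field(default_factory=set)
    conflicts: list[tuple[str, str]] = field(default_factory=list)
    fractions: dict[str, Optional[float]] = field(default_factory=dict)
    frac_tol: float = 0.1

    def parents_of(self, gid: str) -> list[str]:
        return [p for c, p in self.nested if c == gid]

    def minimal_parent(self, gid: str) -> Optional[str]:
        """Immediate parent: the smallest-support ancestor."""
        parents = self.parents_of(gid)
        if not parents:
            return None
        support = {g.group_id: g.support for g in self.groups}
        return min(parents, key=lambda p: (len(support[p]), p))

    def top_level(self) -> list[str]:
        return [g.group_id for g in self.groups if not self.parents_of(g.group_id)]

    def delivered_fraction(self) -> float:
        """Total BM fraction delivered by top-level clones (nested do not add)."""
        vals = [self.fractions.get(g) for g in self.top_level()]
        return float(sum(v for v in vals if v is not None))


def infer_relations(
    groups: Sequence[MutationGroup], matrix: ColonyGenotypeMatrix
) -> CloneModel:
    """Derive nesting and exclusivity from colony supports.

    For each pair, supports are restricted to colonies with unambiguous calls
    for both groups (missing data must not break subset tests).  B is nested
    in A when its restricted support is a strict, non-empty subset of A's;
    disjoint non-empty supports are mutually exclusive; crossing supports are
    recorded as conflicts.
    """
    calls = _require_calls(matrix)
    ids = [cid for cid, _ in matrix.colonies]
    col_index = {v.key: j for j, v in enumerate(matrix.variants)}
    model = CloneModel(groups=list(groups))

    def unambiguous_rows(group: MutationGroup) -> np.ndarray:
        cols = [col_index[v.key] for v in group.mutations]
        return np.all(calls[:, cols] != AMBIGUOUS, axis=1)

    unamb = {g.group_id: unambiguous_rows(g) for g in groups}
    support = {g.group_id: g.support for g in groups}

    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            rows = unamb[a.group_id] & unamb[b.group_id]
            shared = {ids[r] for r in np.flatnonzero(rows)}
            sa = support[a.group_id] & shared
            sb = support[b.group_id] & shared
            if not sa and not sb:
                continue
            if sa == sb:
                model.conflicts.append((a.group_id, b.group_id))
            elif sb < sa and sb:
                model.nested.add((b.group_id, a.group_id))
            elif sa < sb and sa:
                model.nested.add((a.group_id, b.group_id))
            elif not (sa & sb):
                if sa and sb:
                    model.exclusive.add(frozenset((a.group_id, b.group_id)))
            else:
                model.conflicts.append((a.group_id, b.group_id))
    return model


def estimate_fractions(
    model: CloneModel,
    bm_observations: Mapping[str, float] | Sequence[VariantObservation],
    frac_tol: float = 0.1,
    vaf_tol: float = 0.05,
) -> CloneModel:
    """Estimate each clone's share of BM nuclear cells from bulk BM VAFs.

    ``bm_observations`` maps variant keys to bulk BM VAFs (or is a sequence of
    BM :class:`VariantObservation`).  A group's fraction is twice the mean BM
    VAF over its member mutations; members of one clone should agree, so a
    spread beyond ``vaf_tol`` is logged as a warning.  Consistency checks:
    child fraction <= parent fraction + ``frac_tol`` and top-level fractions
    summing to <= 1 + ``frac_tol``; violations are logged, not fatal.
    """
    if not isinstance(bm_observations, Mapping):
        bm_vaf = {
            o.variant.key: o.vaf
            for o in bm_observations
            if o.tissue == "BM" and o.vaf_defined
        }
    else:
        bm_vaf = dict(bm_observations)

    model.frac_tol = frac_tol
    for g in model.groups:
        vafs = [bm_vaf[v.key] for v in g.mutations if v.key in bm_vaf]
        if not vafs:
            model.fractions[g.group_id] = None
            logger.warning("group %s has no BM observation; fraction missing", g.group_id)
            continue
        if max(vafs) - min(vafs) > vaf_tol:
            logger.warning(
                "group %s member BM VAFs disagree beyond %.2f: %s",
                g.group_id, vaf_tol, vafs,
            )
        model.fractions[g.group_id] = clone_fraction(float(np.mean(vafs)))

    for child, parent in model.nested:
        fc, fp = model.fractions.get(child), model.fractions.get(parent)
        if fc is not None and fp is not None and fc > fp + frac_tol:
            logger.warning(
                "nested clone %s fraction %.2f exceeds parent %s fraction %.2f",
                child, fc, parent, fp,
            )
    total = model.delivered_fraction()
    if total > 1 + frac_tol:
        logger.warning("top-level clone fractions sum to %.2f > 1", total)
    return model


def render_composition(model: CloneModel) -> dict:
    """Emit the nested-composition report as a JSON-serializable tree.

    Top-level clones appear as root nodes with their children nested inside;
    the unassigned remainder is 1 minus the delivered fraction (bounded below
    by -frac_tol when fractions overshoot).
    """
    children: dict[Optional[str], list[str]] = {}
    for g in model.groups:
        children.setdefault(model.minimal_parent(g.group_id), []).append(g.group_id)

    by_id = {g.group_id: g for g in model.groups}

    def node(gid: str) -> dict:
        g = by_id[gid]
        return {
            "clone_id": gid,
            "mutations": [v.key for v in g.mutations],
            "fraction_bm": model.fractions.get(gid),
            "compartments": sorted(g.compartments),
            "children": [node(c) for c in sorted(children.get(gid, []))],
        }

    delivered = model.delivered_fraction()
    return {
        "clones": [node(gid) for gid in sorted(children.get(None, []))],
        "delivered_fraction": delivered,
        "remainder": 1.0 - delivered,
        "exclusive_pairs": sorted(sorted(p) for p in model.exclusive),
        "nested_pairs": sorted(model.nested),
        "conflicts": sorted(model.conflicts),
    }
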