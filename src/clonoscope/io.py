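"""Readers and writers for the tabular and VCF input formats.

Formats
-------
Variant table (TSV)
    Columns ``animal_id, tissue, chrom, pos, ref, alt, alt_reads, depth``;
    lines starting with ``#`` are comments.  VAF is always recomputed from the
    counts, never read from a file.
Minimal VCF (v4.2)
    Single- or multi-sample records with FORMAT ``AD`` (allelic depths).  The
    sample name encodes identity as ``<animal_id>:<tissue>``; both parts can
    be overridden by arguments.  Anything richer should be exported to TSV.
Colony CSV
    ``colony_id, compartment`` then paired ``<variantkey>_vaf`` /
    ``<variantkey>_depth`` columns, where a variant key is
    ``chrom:pos:ref>alt``.
Animals CSV
    ``animal_id, group, dose_Gy, sex, age_months[, lym_pct, mye_pct, rdw]``.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .model import (
    AnimalRecord,
    ColonyGenotypeMatrix,
    Variant,
    VariantObservation,
    VariantProfile,
    normalize_tissue,
)

logger = logging.getLogger(__name__)

VARIANT_TABLE_COLUMNS = (
    "animal_id",
    "tissue",
    "chrom",
    "pos",
    "ref",
    "alt",
    "alt_reads",
    "depth",
)


class MalformedRowError(ValueError):
    """A row of an input table failed validation; carries the line number."""


def read_variant_table(
    path: str | Path,
    format: Optional[str] = None,
    animal_id: Optional[str] = None,
    tissue: Optional[str] = None,
) -> list[VariantObservation]:
    """Read per-tissue variant observations from a TSV table or a minimal VCF.

    ``format`` is ``"TSV"`` or ``"VCF"``; when omitted it is inferred from the
    file extension.  Rows whose depth is smaller than the alt-read count are
    rejected and logged rather than raising.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "VCF" if path.suffix.lower() == ".vcf" else "TSV"
    format = format.upper()
    if format == "TSV":
        return _read_variant_tsv(path)
    if format == "VCF":
        return _read_variant_vcf(path, animal_id=animal_id, tissue=tissue)
    raise ValueError(f"unknown format {format!r}")


def _read_variant_tsv(path: Path) -> list[VariantObservation]:
    observations: list[VariantObservation] = []
    with open(path, encoding="utf-8") as fh:
        header: Optional[list[str]] = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = set(VARIANT_TABLE_COLUMNS) - set(header)
                if missing:
                    raise MalformedRowError(
                        f"{path}:{lineno}: header missing columns {sorted(missing)}"
                    )
                idx = {c: header.index(c) for c in VARIANT_TABLE_COLUMNS}
                continue
            if len(fields) != len(header):
                raise MalformedRowError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            try:
                alt_reads = int(fields[idx["alt_reads"]])
                depth = int(fields[idx["depth"]])
                obs = VariantObservation(
                    animal_id=fields[idx["animal_id"]],
                    tissue=normalize_tissue(fields[idx["tissue"]]),
                    chrom=fields[idx["chrom"]],
                    pos=int(fields[idx["pos"]]),
                    ref=fields[idx["ref"]].upper(),
                    alt=fields[idx["alt"]].upper(),
                    alt_reads=alt_reads,
                    depth=depth,
                )
            except ValueError as exc:
                if "depth" in str(exc) and "alt_reads" in str(exc):
                    logger.warning("%s:%d: rejected row (%s)", path, lineno, exc)
                    continue
                raise MalformedRowError(f"{path}:{lineno}: {exc}") from exc
            observations.append(obs)
        if header is None:
            raise MalformedRowError(f"{path}: empty file, no header")
    return observations


def _read_variant_vcf(
    path: Path, animal_id: Optional[str], tissue: Optional[str]
) -> list[VariantObservation]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    observations: list[VariantObservation] = []
    for rec in vcf:
        ad = rec.format("AD")
        if ad is None:
            raise MalformedRowError(
                f"{path}: record {rec.CHROM}:{rec.POS} lacks FORMAT/AD"
            )
        for alt_index, alt in enumerate(rec.ALT):
            for s_index, sample in enumerate(samples):
                ref_reads = int(ad[s_index][0])
                alt_reads = int(ad[s_index][1 + alt_index])
                if ref_reads < 0 or alt_reads < 0:  # missing genotype
                    continue
                aid, tis = _sample_identity(sample, animal_id, tissue)
                observations.append(
                    VariantObservation(
                        animal_id=aid,
                        tissue=normalize_tissue(tis),
                        chrom=rec.CHROM,
                        pos=rec.POS,
                        ref=rec.REF.upper(),
                        alt=alt.upper(),
                        alt_reads=alt_reads,
                        depth=ref_reads + alt_reads,
                    )
                )
    return observations


def _sample_identity(
    sample: str, animal_id: Optional[str], tissue: Optional[str]
) -> tuple[str, str]:
    if animal_id is not None and tissue is not None:
        return animal_id, tissue
    if ":" in sample:
        aid, tis = sample.split(":", 1)
    else:
        aid, tis = sample, "BM"
    return animal_id or aid, tissue or tis


def write_variant_table(
    observations: Iterable[VariantObservation], path: str | Path
) -> None:
    """Write observations as the canonical eight-column TSV."""
    rows = [
        {
            "animal_id": o.animal_id,
            "tissue": o.tissue,
            "chrom": o.chrom,
            "pos": o.pos,
            "ref": o.ref,
            "alt": o.alt,
            "alt_reads": o.alt_reads,
            "depth": o.depth,
        }
        for o in observations
    ]
    df = pd.DataFrame(rows, columns=list(VARIANT_TABLE_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


def write_variant_profiles(
    profiles: Sequence[VariantProfile], path: str | Path
) -> None:
    """Write per-(animal, variant) profiles as a wide TSV.

    Per-tissue columns ``<tissue>_vaf`` / ``<tissue>_depth`` cover the union
    of tissues seen across profiles; tissues absent from a profile stay empty,
    so the reader round-trips the structure exactly.
    """
    tissues = sorted({t for p in profiles for t in p.vaf_by_tissue})
    columns = [
        "animal_id",
        "chrom",
        "pos",
        "ref",
        "alt",
        "variant_type",
        "class_label",
    ]
    for t in tissues:
        columns += [f"{t}_vaf", f"{t}_depth"]
    rows = []
    for p in profiles:
        row: dict[str, object] = {
            "animal_id": p.animal_id,
            "chrom": p.variant.chrom,
            "pos": p.variant.pos,
            "ref": p.variant.ref,
            "alt": p.variant.alt,
            "variant_type": p.variant_type,
            "class_label": p.class_label,
        }
        for t, (vaf, depth) in p.vaf_by_tissue.items():
            row[f"{t}_vaf"] = repr(vaf) if not math.isnan(vaf) else "nan"
            row[f"{t}_depth"] = depth
        rows.append(row)
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def read_variant_profiles(path: str | Path) -> list[VariantProfile]:
    """Read profiles written by :func:`write_variant_profiles`."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"animal_id": str, "chrom": str},
                     float_precision="round_trip")
    tissue_cols = [c[: -len("_vaf")] for c in df.columns if c.endswith("_vaf")]
    profiles = []
    for _, row in df.iterrows():
        vaf_by_tissue: dict[str, tuple[float, int]] = {}
        for t in tissue_cols:
            v = row[f"{t}_vaf"]
            d = row[f"{t}_depth"]
            if pd.isna(v) and pd.isna(d):
                continue
            vaf_by_tissue[t] = (float(v), int(d))
        profiles.append(
            VariantProfile(
                animal_id=str(row["animal_id"]),
                variant=Variant(
                    str(row["chrom"]), int(row["pos"]), str(row["ref"]), str(row["alt"])
                ),
                vaf_by_tissue=vaf_by_tissue,
                variant_type="" if pd.isna(row["variant_type"]) else str(row["variant_type"]),
                class_label=str(row["class_label"]),
            )
        )
    return profiles


def read_colony_matrix(path: str | Path, animal_id: str = "") -> ColonyGenotypeMatrix:
    """Read a colony CSV into a :class:`ColonyGenotypeMatrix`.

    A zero-row file yields a valid empty matrix.  Duplicated colony ids and
    unknown compartment labels raise.
    """
    df = pd.read_csv(path, dtype={"colony_id": str}, float_precision="round_trip")
    if "colony_id" not in df.columns or "compartment" not in df.columns:
        raise MalformedRowError(f"{path}: need colony_id and compartment columns")
    keys = [c[: -len("_vaf")] for c in df.columns if c.endswith("_vaf")]
    variants = [Variant.from_key(k) for k in keys]
    colonies = [(str(r.colony_id), str(r.compartment)) for r in df.itertuples()]
    n, m = len(colonies), len(variants)
    vaf = np.full((n, m), np.nan)
    depth = np.zeros((n, m), dtype=int)
    for j, k in enumerate(keys):
        vaf[:, j] = pd.to_numeric(df[f"{k}_vaf"], errors="coerce").to_numpy()
        depth[:, j] = (
            pd.to_numeric(df[f"{k}_depth"], errors="coerce").fillna(0).astype(int).to_numpy()
        )
    return ColonyGenotypeMatrix(
        animal_id=animal_id, colonies=colonies, variants=variants, vaf=vaf, depth=depth
    )


def write_colony_matrix(matrix: ColonyGenotypeMatrix, path: str | Path) -> None:
    data: dict[str, object] = {
        "colony_id": [c for c, _ in matrix.colonies],
        "compartment": [comp for _, comp in matrix.colonies],
    }
    for j, v in enumerate(matrix.variants):
        data[f"{v.key}_vaf"] = [
            "" if math.isnan(x) else repr(float(x)) for x in matrix.vaf[:, j]
        ]
        data[f"{v.key}_depth"] = matrix.depth[:, j]
    pd.DataFrame(data).to_csv(path, index=False)


def read_animals(path: str | Path) -> list[AnimalRecord]:
    df = pd.read_csv(path, dtype={"animal_id": str}, float_precision="round_trip")
    records = []
    for _, row in df.iterrows():
        def _opt(col: str) -> Optional[float]:
            if col not in df.columns or pd.isna(row[col]):
                return None
            return float(row[col])

        records.append(
            AnimalRecord(
                animal_id=str(row["animal_id"]),
                group=str(row["group"]),
                dose_Gy=float(row["dose_Gy"]),
                sex=str(row["sex"]),
                age_months=float(row["age_months"]),
                lym_pct=_opt("lym_pct"),
                mye_pct=_opt("mye_pct"),
                rdw=_opt("rdw"),
            )
        )
    return records


def write_animals(animals: Iterable[AnimalRecord], path: str | Path) -> None:
    rows = [
        {
            "animal_id": a.animal_id,
            "group": a.group,
            "dose_Gy": a.dose_Gy,
            "sex": a.sex,
            "age_months": a.age_months,
            "lym_pct": "" if a.lym_pct is None else repr(a.lym_pct),
            "mye_pct": "" if a.mye_pct is None else repr(a.mye_pct),
            "rdw": "" if a.rdw is None else repr(a.rdw),
        }
        for a in animals
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_config(path: str | Path) -> dict:
    """Load the YAML configuration holding every tunable threshold.

    Sections (all optional): ``filter``, ``genotype``, ``spectrum``, ``sim``.
    CLI flags override these values.
    """
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: top level of config must be a mapping")
    return cfg
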