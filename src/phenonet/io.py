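"""Readers and writers for the external formats the pipeline touches.

Supported genotype carriers: VCF 4.x (GT-based, via cyvcf2), the PLINK
binary triplet (.bed/.bim/.fam), and a plain tab-separated dosage table.
Gene models come from BED (0-based half-open, converted on read) or GFF3
(1-based; CDS features define coding subintervals).  All round trips
(write -> read) are identities on dosages and metadata.
"""

from __future__ import annotations

import math
import os
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    AssociationRecord,
    GeneInterval,
    GenotypeMatrix,
    PhenotypeColumn,
    PhenotypeTable,
    Variant,
)

SUMMARY_COLUMNS = ["variant", "phenotype", "effect", "se", "p", "n", "model"]

_PLINK_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit PLINK codes (SNP-major) -> dosage of the A1 (=alt here) allele
_PLINK_CODE_TO_DOSE = {0b00: 2.0, 0b01: np.nan, 0b10: 1.0, 0b11: 0.0}
_DOSE_TO_PLINK_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}


class GenotypeParseError(ValueError):
    """Malformed genotype input; message names the offending record."""


# ---------------------------------------------------------------------------
# genotype readers


def read_genotypes(
    path: str, format: str, multiallelic: str = "split"
) -> GenotypeMatrix:
    """Read genotypes as alt-allele dosages.

    Parameters
    ----------
    path : str
        For ``plink-binary`` this is the triplet prefix (``path + .bed`` etc.).
    format : {"vcf", "plink-binary", "dosage-tsv"}
    multiallelic : {"split", "reject"}
        VCF only.  ``split`` turns an n-allelic site into n-1 bi-allelic
        records (dosage = count of that alt); ``reject`` raises.
    """
    if format == "vcf":
        return _read_vcf(path, multiallelic=multiallelic)
    if format == "plink-binary":
        return _read_plink(path)
    if format == "dosage-tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: str, multiallelic: str = "split") -> GenotypeMatrix:
    from cyvcf2 import VCF

    if multiallelic not in ("split", "reject"):
        raise ValueError("multiallelic policy must be 'split' or 'reject'")
    vcf = VCF(path)
    samples = list(vcf.samples)
    variants: List[Variant] = []
    columns: List[np.ndarray] = []
    seen = set()
    for rec in vcf:
        alts = rec.ALT
        if len(alts) == 0:
            continue
        if len(alts) > 1 and multiallelic == "reject":
            raise GenotypeParseError(
                f"multi-allelic site at {rec.CHROM}:{rec.POS} "
                f"({rec.ID or '.'}) rejected by policy"
            )
        gts = rec.genotypes  # [[a0, a1, phased], ...]
        for ai, alt in enumerate(alts, start=1):
            dose = np.full(len(samples), np.nan)
            for i, gt in enumerate(gts):
                alleles = [a for a in gt[:-1] if a is not None and a >= 0]
                if len(alleles) < 2:
                    continue
                dose[i] = float(sum(1 for a in alleles if a == ai))
            vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
            if len(alts) > 1:
                vid = f"{vid}:{alt}"
            if vid in seen:
                raise GenotypeParseError(f"duplicate variant id {vid!r}")
            seen.add(vid)
            variants.append(
                Variant(
                    id=vid,
                    chromosome=str(rec.CHROM),
                    position=int(rec.POS),
                    ref_allele=rec.REF,
                    alt_allele=alt,
                )
            )
            columns.append(dose)
    dosages = (
        np.column_stack(columns) if columns else np.empty((len(samples), 0))
    )
    return GenotypeMatrix(samples, variants, dosages)


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write a minimal GT-only VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(v.chromosome for v in gm.variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.individuals)
            + "\n"
        )
        gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, v in enumerate(gm.variants):
            col = gm.dosages[:, j]
            gts = "\t".join(
                "./." if math.isnan(d) else gt_of[d] for d in col
            )
            fh.write(
                f"{v.chromosome}\t{v.position}\t{v.id}\t{v.ref_allele}\t"
                f"{v.alt_allele}\t.\t.\t.\tGT\t{gts}\n"
            )


def _read_plink(prefix: str) -> GenotypeMatrix:
    fam = pd.read_csv(
        prefix + ".fam",
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype=str,
    )
    bim = pd.read_csv(
        prefix + ".bim",
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    n = len(fam)
    m = len(bim)
    with open(prefix + ".bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _PLINK_MAGIC:
            raise GenotypeParseError(
                f"{prefix}.bed: bad magic bytes (not SNP-major PLINK 1 .bed)"
            )
        data = np.frombuffer(fh.read(), dtype=np.uint8)
    bytes_per_variant = (n + 3) // 4
    if len(data) != bytes_per_variant * m:
        raise GenotypeParseError(
            f"{prefix}.bed: expected {bytes_per_variant * m} data bytes for "
            f"{n} samples x {m} variants, found {len(data)}"
        )
    data = data.reshape(m, bytes_per_variant)
    # unpack 2-bit codes, little-endian within each byte
    codes = np.stack(
        [(data >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=-1
    ).reshape(m, -1)[:, :n]
    lookup = np.array(
        [_PLINK_CODE_TO_DOSE[c] for c in range(4)], dtype=float
    )
    dosages = lookup[codes].T  # (n, m)
    variants = [
        Variant(
            id=row.id,
            chromosome=str(row.chrom),
            position=int(row.pos),
            ref_allele=row.a2,
            alt_allele=row.a1,
        )
        for row in bim.itertuples()
    ]
    return GenotypeMatrix(list(fam["iid"]), variants, dosages)


def write_plink(gm: GenotypeMatrix, prefix: str) -> None:
    """Write the .bed/.bim/.fam triplet (SNP-major, alt allele as A1)."""
    with open(prefix + ".fam", "w") as fh:
        for iid in gm.individuals:
            fh.write(f"{iid} {iid} 0 0 0 -9\n")
    with open(prefix + ".bim", "w") as fh:
        for v in gm.variants:
            fh.write(
                f"{v.chromosome}\t{v.id}\t0\t{v.position}\t"
                f"{v.alt_allele}\t{v.ref_allele}\n"
            )
    n = gm.n_individuals
    bytes_per_variant = (n + 3) // 4
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_PLINK_MAGIC)
        for j in range(gm.n_variants):
            codes = np.full(bytes_per_variant * 4, 0b11, dtype=np.uint8)
            col = gm.dosages[:, j]
            for i, d in enumerate(col):
                codes[i] = 0b01 if math.isnan(d) else _DOSE_TO_PLINK_CODE[d]
            packed = (
                codes.reshape(-1, 4)
                * np.array([1, 4, 16, 64], dtype=np.uint8)
            ).sum(axis=1, dtype=np.uint8)
            fh.write(packed.tobytes())


def _read_dosage_tsv(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["variant", "chromosome", "position", "ref", "alt"]
    for col in required:
        if col not in df.columns:
            raise GenotypeParseError(f"{path}: missing column {col!r}")
    sample_cols = [c for c in df.columns if c not in required]
    variants = []
    for idx, row in enumerate(df.itertuples(), start=2):
        try:
            variants.append(
                Variant(
                    id=row.variant,
                    chromosome=str(row.chromosome),
                    position=int(row.position),
                    ref_allele=row.ref,
                    alt_allele=row.alt,
                )
            )
        except (TypeError, ValueError) as exc:
            raise GenotypeParseError(f"{path} line {idx}: {exc}") from exc
    vals = df[sample_cols].replace({"NA": np.nan, ".": np.nan})
    dosages = vals.to_numpy(dtype=float).T  # rows were variants
    return GenotypeMatrix(sample_cols, variants, dosages)


def write_dosage_tsv(gm: GenotypeMatrix, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "variant\tchromosome\tposition\tref\talt\t"
            + "\t".join(gm.individuals)
            + "\n"
        )
        for j, v in enumerate(gm.variants):
            vals = "\t".join(
                "NA" if math.isnan(d) else str(int(d)) for d in gm.dosages[:, j]
            )
            fh.write(
                f"{v.id}\t{v.chromosome}\t{v.position}\t{v.ref_allele}\t"
                f"{v.alt_allele}\t{vals}\n"
            )


# ---------------------------------------------------------------------------
# phenotypes


def read_phenotypes(
    path: str,
    type_map: Dict[str, str],
    category_map: Dict[str, str],
    id_column: str = "IID",
    missing_markers: Sequence[str] = ("NA", "", ".", "-9"),
) -> PhenotypeTable:
    """Read a tab-separated phenotype table.

    ``type_map`` assigns each phenotype column "continuous" or "binary";
    ``category_map`` assigns the two-letter category code.  ``age`` and
    ``sex`` columns are required covariates.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in (id_column, "age", "sex"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    for name in type_map:
        if name not in df.columns:
            raise ValueError(f"{path}: mapped phenotype {name!r} not present")
        if name not in category_map:
            raise ValueError(f"phenotype {name!r} missing from category_map")
    df = df.replace({m: np.nan for m in missing_markers})
    columns = [
        PhenotypeColumn(name=name, kind=kind, category=category_map[name])
        for name, kind in type_map.items()
    ]
    values = df[[c.name for c in columns]].astype(float)
    for col in columns:
        if col.kind == "binary":
            vals = values[col.name].dropna().unique()
            bad = sorted(set(vals) - {0.0, 1.0})
            if bad:
                raise ValueError(
                    f"binary phenotype {col.name!r} contains invalid values "
                    f"{bad}; binary columns must be coded 0/1"
                )
    covariates = df[["age", "sex"]].astype(float)
    return PhenotypeTable(list(df[id_column]), values, columns, covariates)


def write_phenotypes(table: PhenotypeTable, path: str, id_column: str = "IID") -> None:
    df = pd.DataFrame({id_column: table.individuals})
    df["age"] = table.covariates["age"].to_numpy()
    df["sex"] = table.covariates["sex"].to_numpy()
    for col in table.columns:
        df[col.name] = table.values[col.name].to_numpy()
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# summary statistics


def write_summary_stats(records: Sequence[AssociationRecord], path: str) -> None:
    """Write association records as a tab-separated summary-statistics table."""
    if not records:
        raise ValueError("no records to write")
    with open(path, "w") as fh:
        fh.write("\t".join(SUMMARY_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.variant_id}\t{r.phenotype_name}\t{float(r.effect)!r}\t"
                f"{float(r.standard_error)!r}\t{float(r.p_value)!r}\t"
                f"{int(r.n_samples)}\t{r.model}\n"
            )


def read_summary_stats(path: str) -> List[AssociationRecord]:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"variant": str, "phenotype": str},
        float_precision="round_trip",
    )
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing summary columns {missing}")
    return [
        AssociationRecord(
            variant_id=row.variant,
            phenotype_name=row.phenotype,
            effect=float(row.effect),
            standard_error=float(row.se),
            p_value=float(row.p),
            n_samples=int(row.n),
            model=row.model,
        )
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# gene annotations


def read_gene_intervals(path: str, format: Optional[str] = None) -> List[GeneInterval]:
    """Read gene models from BED or GFF3.

    BED coordinates (0-based half-open) are converted to 1-based inclusive.
    With 12-column BED, blocks define coding subintervals; in GFF3, ``gene``
    features define bodies and ``CDS`` features coding subintervals (grouped
    by their gene via the Parent/gene_name attributes or overlap).
    """
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = "gff3" if ext in (".gff", ".gff3") else "bed"
    if format == "bed":
        return _read_bed_genes(path)
    if format == "gff3":
        return _read_gff3_genes(path)
    raise ValueError(f"unknown annotation format {format!r}")


def _read_bed_genes(path: str) -> List[GeneInterval]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path} line {lineno}: need >= 4 BED columns")
            chrom, start0, end0, name = parts[:4]
            start = int(start0) + 1  # 0-based half-open -> 1-based inclusive
            end = int(end0)
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "+"
            coding = ()
            if len(parts) >= 12:
                sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
                offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
                coding = tuple(
                    (start + off, start + off + size - 1)
                    for off, size in zip(offsets, sizes)
                )
            genes.append(
                GeneInterval(
                    gene_symbol=name,
                    chromosome=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    coding_subintervals=coding,
                )
            )
    return genes


def _parse_gff_attrs(field: str) -> Dict[str, str]:
    out = {}
    for item in field.split(";"):
        item = item.strip()
        if "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
    return out


def _read_gff3_genes(path: str) -> List[GeneInterval]:
    bodies = {}  # id -> dict
    cds: Dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                continue
            chrom, _, ftype, start, end, _, strand, _, attrs = parts[:9]
            attrs = _parse_gff_attrs(attrs)
            if ftype == "gene":
                gid = attrs.get("ID", attrs.get("Name", f"{chrom}:{start}"))
                bodies[gid] = dict(
                    symbol=attrs.get("Name", attrs.get("gene_name", gid)),
                    chromosome=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand if strand in "+-" else "+",
                )
            elif ftype == "CDS":
                parent = attrs.get("gene_id") or attrs.get("Parent")
                if parent:
                    cds.setdefault(parent.split(",")[0], []).append(
                        (int(start), int(end))
                    )
    genes = []
    for gid, b in bodies.items():
        sub = tuple(sorted(cds.get(gid, [])))
        genes.append(
            GeneInterval(
                gene_symbol=b["symbol"],
                chromosome=b["chromosome"],
                start=b["start"],
                end=b["end"],
                strand=b["strand"],
                coding_subintervals=sub,
            )
        )
    return genes
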