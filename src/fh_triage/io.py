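"""Readers and writers for the pipeline's tabular and VCF interfaces.

Annotation tables are TSV, phenotype tables CSV, genotypes either a long
TSV (participant_id, variant_id, n_alt) or a minimal VCF v4.2 with GT
calls.  Schema validation enumerates every malformed row rather than
stopping at the first.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .phenotype import PARTICIPANT_REQUIRED_COLUMNS
from .triage import ANNOTATION_COLUMNS, annotations_from_frame


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read and validate a variant annotation TSV."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: annotation header missing columns: {missing}")
    annotations_from_frame(df)  # raises with all row-level problems
    return df


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read and validate a participant phenotype CSV.

    Checks: required columns present; lipids and observed LDL non-negative;
    age at least 18; ICD-10 codes syntactically valid.  All violations are
    reported together with their row numbers.
    """
    df = pd.read_csv(path)
    missing = [c for c in PARTICIPANT_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: phenotype header missing columns: {missing}")
    errors: list[str] = []
    for col in ("tc", "ldl", "hdl", "tg", "max_ldl_observed"):
        bad = df.index[df[col].fillna(0) < 0]
        errors += [f"row {i}: negative {col} ({df.loc[i, col]})" for i in bad]
    bad = df.index[df["age"].fillna(18) < 18]
    errors += [f"row {i}: age below 18 ({df.loc[i, 'age']})" for i in bad]
    for i, codes in df["icd10_primary"].items():
        if pd.isna(codes) or str(codes) == "":
            continue
        for code in str(codes).split(";"):
            c = code.strip().upper()
            if not (c and c[0].isalpha() and len(c) >= 3 and c[1:3].isdigit()):
                errors.append(f"row {i}: malformed ICD-10 code {code!r}")
    if errors:
        raise ValueError(f"{path}: phenotype validation failed:\n" + "\n".join(errors))
    return df


def read_genotypes(path: str | Path) -> pd.DataFrame:
    """Read a long genotype TSV (participant_id, variant_id, n_alt)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("participant_id", "variant_id", "n_alt") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: genotype header missing columns: {missing}")
    return df


# ---------------------------------------------------------------------------
# Minimal VCF v4.2 (GT only)
# ---------------------------------------------------------------------------

_VCF_CONTIGS = ("1", "2", "19")


def write_vcf(genotypes: pd.DataFrame, variants: pd.DataFrame, path: str | Path) -> None:
    """Write carrier genotypes as a minimal VCF v4.2 (GRCh38 contigs, GT only).

    ``variants`` needs columns variant_id, chrom, pos, ref, alt; samples are
    every participant appearing in ``genotypes``.
    """
    for col in ("variant_id", "chrom", "pos", "ref", "alt"):
        if col not in variants.columns:
            raise ValueError(f"variant table missing column {col!r} needed for VCF output")
    samples = sorted(genotypes["participant_id"].unique())
    calls = {
        (r["variant_id"], r["participant_id"]): int(r["n_alt"])
        for _, r in genotypes.iterrows()
    }
    lines = ["##fileformat=VCFv4.2", "##reference=GRCh38"]
    lines += [f"##contig=<ID={c}>" for c in _VCF_CONTIGS]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    ordered = variants.sort_values(["chrom", "pos"], kind="stable")
    for _, v in ordered.iterrows():
        gts = []
        for s in samples:
            n = calls.get((v["variant_id"], s), 0)
            gts.append({0: "0/0", 1: "0/1", 2: "1/1"}.get(n, "0/0"))
        lines.append(
            f"{v['chrom']}\t{int(v['pos'])}\t{v['variant_id']}\t{v['ref']}\t{v['alt']}"
            f"\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> pd.DataFrame:
    """Read GT calls from a VCF into the long genotype table.

    Any non-reference call makes the participant a carrier of that allele;
    half-calls (one allele missing) are treated as missing with a warning.
    Uses cyvcf2 when available, falling back to a plain-text parse of the
    small GT-only files this package writes.
    """
    try:
        from cyvcf2 import VCF  # optional: compiled reader
    except ImportError:
        VCF = None
    rows: list[dict] = []
    n_half = 0
    if VCF is not None:
        vcf = VCF(str(path))
        samples = vcf.samples
        for var in vcf:
            vid = var.ID or f"{var.CHROM}:{var.POS}:{var.REF}:{var.ALT[0]}"
            for s, gt in zip(samples, var.genotypes):
                alleles = [a for a in gt[:-1]]
                if any(a < 0 for a in alleles) and any(a >= 0 for a in alleles):
                    n_half += 1
                    continue
                if all(a < 0 for a in alleles):
                    continue
                n_alt = sum(1 for a in alleles if a > 0)
                if n_alt:
                    rows.append({"participant_id": s, "variant_id": vid, "n_alt": n_alt})
    else:
        with open(path) as fh:
            samples: list[str] = []
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("##") or not line:
                    continue
                fields = line.split("\t")
                if line.startswith("#CHROM"):
                    samples = fields[9:]
                    continue
                vid = fields[2] if fields[2] != "." else f"{fields[0]}:{fields[1]}:{fields[3]}:{fields[4]}"
                fmt = fields[8].split(":")
                gt_i = fmt.index("GT")
                for s, call in zip(samples, fields[9:]):
                    gt = call.split(":")[gt_i].replace("|", "/")
                    alleles = gt.split("/")
                    miss = [a == "." for a in alleles]
                    if any(miss) and not all(miss):
                        n_half += 1
                        continue
                    if all(miss):
                        continue
                    n_alt = sum(1 for a in alleles if a not in (".", "0"))
                    if n_alt:
                        rows.append({"participant_id": s, "variant_id": vid, "n_alt": n_alt})
    if n_half:
        warnings.warn(f"{n_half} half-call genotypes treated as missing")
    return pd.DataFrame(rows, columns=["participant_id", "variant_id", "n_alt"])


def prepare_model_frame(participants: pd.DataFrame, carrier_ids: set | frozenset) -> pd.DataFrame:
    """Participant table augmented with the model covariate encodings.

    Adds ``carrier``, ``sex_male``, ``smoking_dependent`` and integer
    ``diabetes``/``on_lipid_lowering``; ``ihd`` comes from the column of
    that name when present, otherwise from an I20-I25 code in the
    diagnosis list.
    """
    from .association import icd10_buckets_of

    df = participants.copy()
    df["carrier"] = df["participant_id"].isin(carrier_ids).astype(int)
    df["sex_male"] = df["sex"].eq("M").astype(int)
    df["smoking_dependent"] = df["smoking"].eq("dependent").astype(int)
    df["diabetes"] = df["diabetes"].astype(bool).astype(int)
    df["on_lipid_lowering"] = df["on_lipid_lowering"].astype(bool).astype(int)
    if "ihd" in df.columns:
        df["ihd"] = df["ihd"].astype(bool).astype(int)
    else:
        df["ihd"] = df["icd10_primary"].map(
            lambda s: int("I20-I25" in icd10_buckets_of(s))
        )
    df["age"] = df["age"].astype(float)
    return df
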