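"""Readers/writers for genotypes, summary statistics, phenotypes and cross
plans, plus allele harmonization between a genotype panel and external
summary statistics.

Formats supported:

* PLINK 1.9 binary (BED v1.00 SNP-major + BIM + FAM).  The 2-bit codec is
  implemented here directly: per variant, samples are packed 4 per byte,
  little-endian within the byte, with codes 00 = homozygous A1 (dosage 2),
  01 = missing, 10 = heterozygous (1), 11 = homozygous A2 (0).
* VCF 4.x with a GT field (via cyvcf2); ALT is the counted allele.
* GEMMA ``.assoc.txt`` tab-delimited association output (columns include
  ``allele1, allele0, beta, se, p_wald``; allele1 is the effect allele), or
  a generic dialect with a caller-supplied column map.
* Phenotypes and cross plans as tab-delimited text with headers.

All readers preserve missing genotypes; imputation is a scoring-time
policy.  Multiallelic records are dropped everywhere (panels here are
strictly biallelic).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import Cross, CrossPlan, GenotypeMatrix, SummaryStats

logger = logging.getLogger(__name__)

_BED_MAGIC = b"\x6c\x1b\x01"

# 2-bit PLINK code -> dosage of the BIM A1 allele
_PLINK_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])

PALINDROMIC_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}

GEMMA_COLUMNS = {
    "chrom": "chr",
    "vid": "rs",
    "pos": "ps",
    "effect_allele": "allele1",
    "other_allele": "allele0",
    "af": "af",
    "beta": "beta",
    "se": "se",
    "p": "p_wald",
}


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# PLINK binary
# ---------------------------------------------------------------------------

def read_plink(bed_path, bim_path=None, fam_path=None) -> GenotypeMatrix:
    """Read a PLINK BED/BIM/FAM trio into a :class:`GenotypeMatrix`.

    ``bim_path``/``fam_path`` default to ``bed_path`` with the extension
    swapped.  Dosage counts copies of the BIM A1 allele; missing calls are
    kept as NaN.
    """
    bed_path = Path(bed_path)
    bim_path = Path(bim_path) if bim_path else bed_path.with_suffix(".bim")
    fam_path = Path(fam_path) if fam_path else bed_path.with_suffix(".fam")

    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "vid", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "vid": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        fam_path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"iid": str},
    )
    n_samples, n_variants = len(fam), len(bim)

    raw = bed_path.read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(
            f"{bed_path}: not a PLINK BED v1.00 SNP-major file (bad magic bytes)"
        )
    bytes_per_variant = (n_samples + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != bytes_per_variant * n_variants:
        raise FormatError(
            f"{bed_path}: payload of {payload.size} bytes inconsistent with "
            f"{n_samples} samples x {n_variants} variants from FAM/BIM"
        )
    bad = bim["a1"] == bim["a2"]
    if bad.any():
        raise FormatError(
            f"{bim_path}: non-biallelic record(s): "
            f"{bim.loc[bad, 'vid'].tolist()[:5]}"
        )

    blocks = payload.reshape(n_variants, bytes_per_variant)
    # unpack 4 samples per byte, 2 bits each, low bits first
    codes = np.empty((n_variants, bytes_per_variant * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (blocks >> (2 * k)) & 0b11
    dosage = _PLINK_CODE_TO_DOSAGE[codes[:, :n_samples]].T

    variants = bim[["chrom", "pos", "vid", "a1", "a2"]]
    return GenotypeMatrix(samples=fam["iid"].tolist(), variants=variants, dosage=dosage)


def write_plink(geno: GenotypeMatrix, prefix) -> None:
    """Write ``prefix.bed/.bim/.fam`` (BED v1.00 SNP-major)."""
    prefix = Path(prefix)
    n = geno.n_samples
    bytes_per_variant = (n + 3) // 4

    d = geno.dosage
    codes = np.full(d.shape, 0b01, dtype=np.uint8)  # missing
    codes[d == 2] = 0b00
    codes[d == 1] = 0b10
    codes[d == 0] = 0b11
    padded = np.full((geno.n_variants, bytes_per_variant * 4), 0b00, dtype=np.uint8)
    padded[:, :n] = codes.T
    packed = np.zeros((geno.n_variants, bytes_per_variant), dtype=np.uint8)
    for k in range(4):
        packed |= padded[:, k::4] << (2 * k)
    prefix.with_suffix(".bed").write_bytes(_BED_MAGIC + packed.tobytes())

    bim = geno.variants.assign(cm=0)[["chrom", "vid", "cm", "pos", "a1", "a2"]]
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {"fid": geno.samples, "iid": geno.samples, "pat": 0, "mat": 0, "sex": 0, "pheno": -9}
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(vcf_path) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix; dosage counts ALT copies.

    Multiallelic records are skipped (count logged); half-missing GT calls
    become missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=False)
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"{vcf_path}: VCF carries no samples / GT field")

    rows, dosages = [], []
    n_multiallelic = 0
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            n_multiallelic += 1
            continue
        gts = rec.genotype.array()  # (n_samples, ploidy+1); -1 = missing allele
        alleles = gts[:, :2].astype(float)
        alleles[alleles < 0] = np.nan
        d = alleles.sum(axis=1)  # NaN if any allele missing
        vid = rec.ID if rec.ID else f"{rec.CHROM}:{rec.POS}"
        rows.append((str(rec.CHROM), int(rec.POS), vid, rec.ALT[0], rec.REF))
        dosages.append(d)
    if n_multiallelic:
        logger.info("read_vcf: skipped %d multiallelic record(s)", n_multiallelic)

    variants = pd.DataFrame(rows, columns=["chrom", "pos", "vid", "a1", "a2"])
    dosage = (
        np.array(dosages, dtype=float).T
        if dosages
        else np.empty((len(samples), 0))
    )
    geno = GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)
    geno.n_multiallelic_skipped = n_multiallelic
    return geno


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def read_sumstats(path, dialect="gemma", column_map=None) -> SummaryStats:
    """Read association summary statistics.

    dialect "gemma": tab-delimited GEMMA output; effect allele = allele1.
    dialect "generic": caller supplies ``column_map`` from canonical names
    (vid, effect_allele, beta, se, p, optionally other_allele, af, n, chrom,
    pos) to file column names.

    Records with unparseable or non-positive p are dropped and counted in
    ``SummaryStats.n_dropped``.
    """
    if dialect == "gemma":
        column_map = GEMMA_COLUMNS
    elif dialect == "generic":
        if not column_map:
            raise ValueError("generic dialect requires a column_map")
    else:
        raise ValueError(f"unknown sumstats dialect {dialect!r}")

    raw = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [src for src in column_map.values() if src not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {missing}")

    out = pd.DataFrame({canon: raw[src] for canon, src in column_map.items()})
    for col in ("beta", "se", "p", "af", "n"):
        if col in out.columns:
            out[col] = pd.to_numeric(out[col], errors="coerce")
    n_in = len(out)
    keep = out["p"].notna() & (out["p"] > 0) & (out["p"] <= 1) & out["beta"].notna()
    out = out[keep]
    n_dropped = n_in - len(out)
    if n_dropped:
        logger.info("read_sumstats: dropped %d unparseable record(s)", n_dropped)
    if not len(out):
        logger.warning("read_sumstats: %s yielded no usable records", path)
    return SummaryStats(table=out, n_dropped=n_dropped)


def write_sumstats(ss: SummaryStats, path) -> None:
    """Write GEMMA-dialect tab-delimited summary statistics."""
    t = ss.table
    out = pd.DataFrame(
        {
            "chr": t.get("chrom", pd.Series(["NA"] * len(t))),
            "rs": t["vid"],
            "ps": t.get("pos", pd.Series([0] * len(t))),
            "n_miss": 0,
            "allele1": t["effect_allele"],
            "allele0": t["other_allele"],
            "af": t["af"],
            "beta": t["beta"],
            "se": t["se"],
            "logl_H1": "NA",
            "l_remle": "NA",
            "p_wald": t["p"],
        }
    )
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Phenotypes and cross plans
# ---------------------------------------------------------------------------

def read_phenotypes(path, trait=None) -> pd.Series:
    """Read a tab-delimited phenotype table (first column = sample id).

    With several trait columns, ``trait`` picks one (default: first).
    Returns a float Series indexed by sample id; non-finite values dropped.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    df = df.set_index(df.columns[0])
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids")
    col = trait if trait is not None else df.columns[0]
    if col not in df.columns:
        raise FormatError(f"{path}: trait column {col!r} absent; has {list(df.columns)}")
    s = pd.to_numeric(df[col], errors="coerce")
    return s[np.isfinite(s)].astype(float)


def write_phenotypes(pheno: pd.Series, path, trait="trait") -> None:
    pd.DataFrame({"sample": pheno.index, trait: pheno.values}).to_csv(
        path, sep="\t", index=False
    )


def read_cross_plan(path) -> CrossPlan:
    """Read a tab-delimited cross plan: parent1<TAB>parent2[<TAB>f1_id]."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    need = {"parent1", "parent2"}
    if not need <= set(df.columns):
        raise FormatError(f"{path}: cross plan needs columns {sorted(need)}")
    crosses = []
    for _, row in df.iterrows():
        fid = row.get("f1_id")
        if fid is None or pd.isna(fid):
            fid = f"{row['parent1']}x{row['parent2']}"
        crosses.append(Cross(row["parent1"], row["parent2"], str(fid)))
    return CrossPlan(crosses)


def write_cross_plan(plan: CrossPlan, path) -> None:
    pd.DataFrame(plan.crosses, columns=["parent1", "parent2", "f1_id"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

def _is_palindromic(a1: str, a2: str) -> bool:
    return frozenset((a1.upper(), a2.upper())) in PALINDROMIC_PAIRS


def harmonize(
    geno: GenotypeMatrix, ss: SummaryStats, policy: str = "strict"
) -> tuple[GenotypeMatrix, SummaryStats, dict]:
    """Align a genotype panel with external summary statistics.

    Variants are matched by vid (fallback: chrom+pos with a compatible
    allele pair).  Where the effect allele equals the panel's non-counted
    allele, the dosage column is flipped ``d -> 2 - d`` so that dosage
    always counts the effect allele; betas are never touched.  Palindromic
    A/T and C/G variants are dropped under ``policy="strict"`` (use
    ``"keep-palindromic"`` to retain them).  Variants with irreconcilable
    allele sets are dropped and reported, not fatal.

    Returns the aligned (geno, sumstats) pair, in panel variant order, plus
    a dict of drop counts.
    """
    if policy not in ("strict", "keep-palindromic"):
        raise ValueError(f"unknown harmonization policy {policy!r}")

    sst = ss.table.set_index("vid", drop=False)
    by_pos = {}
    for vid, row in sst.iterrows():
        if pd.notna(row.get("chrom")) and pd.notna(row.get("pos")):
            by_pos[(str(row["chrom"]), int(row["pos"]))] = vid

    keep_idx: list[int] = []
    flip: list[bool] = []
    matched_vids: list[str] = []
    counts = {"matched": 0, "unmatched": 0, "palindromic": 0, "irreconcilable": 0}

    for i, v in geno.variants.iterrows():
        vid = v["vid"]
        if vid in sst.index:
            rec = sst.loc[vid]
        else:
            key = (str(v["chrom"]), int(v["pos"]))
            if key in by_pos:
                rec = sst.loc[by_pos[key]]
            else:
                counts["unmatched"] += 1
                continue
        ea, oa = rec["effect_allele"], rec["other_allele"]
        if policy == "strict" and _is_palindromic(v["a1"], v["a2"]):
            counts["palindromic"] += 1
            continue
        if ea == v["a1"] and (pd.isna(oa) or oa == v["a2"]):
            do_flip = False
        elif ea == v["a2"] and (pd.isna(oa) or oa == v["a1"]):
            do_flip = True
        else:
            counts["irreconcilable"] += 1
            logger.info("harmonize: alleles irreconcilable at %s", vid)
            continue
        counts["matched"] += 1
        keep_idx.append(i)
        flip.append(do_flip)
        matched_vids.append(rec["vid"])

    sub = geno.take_variants(keep_idx)
    flip_arr = np.asarray(flip, dtype=bool)
    dosage = sub.dosage.copy()
    dosage[:, flip_arr] = 2.0 - dosage[:, flip_arr]
    variants = sub.variants.copy()
    a1 = variants["a1"].copy()
    variants.loc[flip_arr, "a1"] = variants.loc[flip_arr, "a2"]
    variants.loc[flip_arr, "a2"] = a1[flip_arr]
    geno_out = GenotypeMatrix(samples=sub.samples, variants=variants, dosage=dosage)

    ss_out_table = sst.loc[matched_vids].reset_index(drop=True)
    ss_out = SummaryStats(table=ss_out_table, n_dropped=ss.n_dropped)
    logger.info("harmonize: %s", counts)
    return geno_out, ss_out, counts
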