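"""Synthetic genotype panels, additive phenotypes and crosses.

The generator emulates the study system end to end: a panel of largely
homozygous diploid yeast isolates (inbreeding coefficient ``F`` close to
1), an additive quantitative trait with a chosen narrow-sense heritability
``h2``, a simple per-variant association scan, and spore-to-spore crosses
with Mendelian gamete sampling — so every pipeline stage can be exercised
with a known ground truth and no external downloads.

Genotype frequencies per variant follow the inbreeding model: with allele
frequency ``f``, dosage 2 has probability ``f^2 + F f (1-f)``, dosage 1
``2 f (1-f) (1-F)``, dosage 0 the remainder.  ``F = 1`` gives a fully
homozygous panel; ``F = 0`` is Hardy-Weinberg.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import Cross, CrossPlan, GenotypeMatrix, SummaryStats, make_cross_plan


@dataclass
class SimConfig:
    """Study-condition knobs for the generator.

    Defaults describe the kind of panel the pipeline targets: ~1000
    isolates, a few thousand biallelic SNPs with intermediate frequencies,
    100 causal loci, heritability 0.5, and near-complete homozygosity
    (F = 0.95) as seen in wild yeast panels.
    """

    n_samples: int = 1000
    n_variants: int = 2000
    maf_bounds: tuple[float, float] = (0.05, 0.5)
    n_causal: int = 100
    h2: float = 0.5
    inbreeding: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_bounds
        if not (0 < lo < hi <= 0.5):
            raise ValueError(f"degenerate maf bounds {self.maf_bounds}")
        if not (0 <= self.h2 <= 1):
            raise ValueError("h2 must lie in [0, 1]")
        if not (0 <= self.inbreeding <= 1):
            raise ValueError("inbreeding coefficient must lie in [0, 1]")
        if self.n_causal > self.n_variants:
            raise ValueError("n_causal cannot exceed n_variants")


def simulate_genotypes(cfg: SimConfig, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Draw a biallelic dosage panel under the inbreeding model."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    lo, hi = cfg.maf_bounds
    f = rng.uniform(lo, hi, size=cfg.n_variants)
    F = cfg.inbreeding
    p2 = f * f + F * f * (1 - f)
    p1 = 2 * f * (1 - f) * (1 - F)
    u = rng.random((cfg.n_samples, cfg.n_variants))
    dosage = np.where(u < p2, 2.0, np.where(u < p2 + p1, 1.0, 0.0))

    n_chrom = 16  # S. cerevisiae karyotype
    per_chrom = -(-cfg.n_variants // n_chrom)
    chroms = [f"chr{1 + i // per_chrom}" for i in range(cfg.n_variants)]
    pos = [1000 * (1 + i % per_chrom) for i in range(cfg.n_variants)]
    bases = np.array(list("ACGT"))
    a2 = bases[rng.integers(0, 4, cfg.n_variants)]
    shift = rng.integers(1, 4, cfg.n_variants)
    a1 = bases[(np.searchsorted(bases, a2) + shift) % 4]
    variants = pd.DataFrame(
        {"chrom": chroms, "pos": pos,
         "vid": [f"snp{i}" for i in range(cfg.n_variants)], "a1": a1, "a2": a2}
    )
    samples = [f"iso{i:04d}" for i in range(cfg.n_samples)]
    return GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)


def simulate_phenotypes(
    geno: GenotypeMatrix, cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.Series, pd.Series]:
    """Additive phenotype at heritability h2; returns (phenotype, true betas).

    Causal effects are standard normal on ``n_causal`` variants drawn at
    random; environmental noise is scaled so Var(g)/Var(y) = h2.  The true
    effect Series (indexed by vid, zero for non-causal loci) supports
    recovery tests.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    m = geno.n_variants
    betas = np.zeros(m)
    causal = rng.choice(m, size=cfg.n_causal, replace=False)
    betas[causal] = rng.standard_normal(cfg.n_causal)

    d = np.nan_to_num(geno.dosage, nan=0.0)
    g = d @ betas
    var_g = g.var()
    if cfg.h2 == 1.0:
        if var_g == 0:
            raise ValueError("h2 = 1 with zero genetic variance")
        y = g
    elif cfg.h2 == 0.0:
        y = rng.standard_normal(geno.n_samples)
    else:
        if var_g == 0:
            raise ValueError(f"h2 = {cfg.h2} with zero genetic variance")
        noise_sd = np.sqrt(var_g * (1 - cfg.h2) / cfg.h2)
        y = g + rng.normal(0.0, noise_sd, size=geno.n_samples)

    pheno = pd.Series(y, index=geno.samples, name="trait")
    truth = pd.Series(betas, index=geno.variants["vid"], name="beta_true")
    return pheno, truth


def ols_scan(geno: GenotypeMatrix, pheno: pd.Series) -> SummaryStats:
    """Per-variant simple linear regression of phenotype on dosage.

    A stand-in association scan for synthetic panels (no relatedness
    correction): per variant it returns the OLS slope, its standard error
    and the two-sided t-test p-value.  Monomorphic variants are skipped.
    Missing dosages are mean-imputed per variant.
    """
    shared = [s for s in geno.samples if s in pheno.index]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 samples for a scan, have {len(shared)}")
    sub = geno.take_samples(shared)
    y = pheno.loc[shared].to_numpy(dtype=float)
    n = len(shared)

    d = sub.dosage
    col_mean = np.nanmean(d, axis=0)
    d = np.where(np.isnan(d), col_mean, d)

    dx = d - d.mean(axis=0)
    yx = y - y.mean()
    sxx = (dx * dx).sum(axis=0)
    poly = sxx > 0
    sxy = dx.T @ yx
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        resid_ss = (yx * yx).sum() - beta * sxy
        resid_ss = np.maximum(resid_ss, 0.0)
        se = np.sqrt(resid_ss / (n - 2) / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    v = sub.variants
    table = pd.DataFrame(
        {
            "vid": v["vid"],
            "chrom": v["chrom"],
            "pos": v["pos"],
            "effect_allele": v["a1"],
            "other_allele": v["a2"],
            "beta": beta,
            "se": se,
            "p": p,
            "af": sub.allele_freq(),
            "n": float(n),
        }
    )[poly].reset_index(drop=True)
    n_skipped = int((~poly).sum())
    return SummaryStats(table=table, n_dropped=n_skipped)


def simulate_crosses(
    geno: GenotypeMatrix,
    n_crosses: int,
    seed: int = 0,
    offspring_per_cross: int = 1,
) -> tuple[CrossPlan, GenotypeMatrix]:
    """Random non-self parent pairs plus realized Mendelian offspring.

    Each offspring draws one gamete per parent per locus (a heterozygous
    parent transmits either allele with probability 1/2, independently
    across loci — no linkage).  Offspring sample ids are
    ``<f1_id>`` or ``<f1_id>_rep<k>`` for multiple offspring per cross.
    """
    rng = np.random.default_rng(seed)
    n = geno.n_samples
    if n < 2:
        raise ValueError("need at least 2 parents to cross")
    all_pairs = n * (n - 1) // 2
    if n_crosses > all_pairs:
        raise ValueError(f"{n_crosses} crosses exceed the {all_pairs} distinct pairs")

    chosen: set[tuple[int, int]] = set()
    while len(chosen) < n_crosses:
        i, j = rng.integers(0, n, 2)
        if i != j:
            chosen.add((min(i, j), max(i, j)))
    pairs = sorted(chosen)

    plan = make_cross_plan(
        [(geno.samples[i], geno.samples[j], f"f1_{k:04d}") for k, (i, j) in enumerate(pairs)]
    )

    off_ids, off_rows = [], []
    for k, (i, j) in enumerate(pairs):
        for rep in range(offspring_per_cross):
            g1 = _sample_gamete(geno.dosage[i], rng)
            g2 = _sample_gamete(geno.dosage[j], rng)
            off_rows.append(g1 + g2)
            fid = f"f1_{k:04d}" if offspring_per_cross == 1 else f"f1_{k:04d}_rep{rep}"
            off_ids.append(fid)
    offspring = GenotypeMatrix(
        samples=off_ids, variants=geno.variants, dosage=np.array(off_rows)
    )
    return plan, offspring


def _sample_gamete(dosage: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One haploid gamete per locus from a diploid dosage vector."""
    g = dosage / 2.0  # 0 -> 0, 2 -> 1 deterministically
    het = dosage == 1
    g = np.where(het, rng.random(len(dosage)) < 0.5, g).astype(float)
    g[np.isnan(dosage)] = np.nan
    return g


def simulate_study(cfg: SimConfig, n_crosses: int = 50, offspring_per_cross: int = 1):
    """Full synthetic study: panel, phenotype, scan, crosses, offspring.

    Returns a dict with keys geno, pheno, truth, sumstats, plan, offspring.
    All randomness descends from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    geno = simulate_genotypes(cfg, rng)
    pheno, truth = simulate_phenotypes(geno, cfg, rng)
    ss = ols_scan(geno, pheno)
    plan, offspring = simulate_crosses(
        geno, n_crosses, seed=int(rng.integers(0, 2**31 - 1)),
        offspring_per_cross=offspring_per_cross,
    )
    return {
        "geno": geno, "pheno": pheno, "truth": truth,
        "sumstats": ss, "plan": plan, "offspring": offspring,
    }
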