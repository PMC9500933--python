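"""Predict F1 hybrid genotypes and polygenic scores from parental genomes.

The expected offspring dosage at a locus is the parental mean (d1 + d2)/2,
which takes values in {0, 0.5, 1, 1.5, 2}: a homozygous x homozygous cross
is fully determined, while each heterozygous parent contributes an
uncertain gamete.  The predicted F1 PRS is the weighted sum of expected
dosages; min/max bounds range over the Mendelian-feasible offspring
genotypes at each uncertain locus (respecting the sign of each weight),
and an exact enumeration of the offspring PRS distribution is available
for small numbers of uncertain loci.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import CrossPlan, GenotypeMatrix
from .prs_scoring import RiskMarkerSet

logger = logging.getLogger(__name__)

ENUMERATION_GUARD = 20  # max uncertain loci for exact enumeration (3^k outcomes)

# gametes a diploid parent of dosage d can produce, with probabilities
_GAMETES = {0.0: ((0, 1.0),), 1.0: ((0, 0.5), (1, 0.5)), 2.0: ((1, 1.0),)}

COMBO_CLASSES = ("AAxAA", "AAxAa", "AAxaa", "AaxAa", "Aaxaa", "aaxaa")
_COMBO_BY_DOSAGE_PAIR = {
    (2, 2): "AAxAA",
    (2, 1): "AAxAa",
    (2, 0): "AAxaa",
    (1, 1): "AaxAa",
    (1, 0): "Aaxaa",
    (0, 0): "aaxaa",
}
HOMOZYGOUS_COMBOS = ("AAxAA", "AAxaa", "aaxaa")


@dataclass
class PredictedF1:
    """Predicted PRS for one cross, with Mendelian uncertainty bounds."""

    cross_id: str
    parent1: str
    parent2: str
    expected_dosage: np.ndarray  # per marker, in {0, .5, 1, 1.5, 2}, NaN skipped
    prs_point: float
    prs_min: float
    prs_max: float
    n_uncertain: int  # loci where >= 1 parent is heterozygous
    n_skipped: int = 0  # loci skipped due to missing parental genotype


@dataclass
class ComboCensus:
    """Per-cross counts of the 6 unordered parental genotype combinations."""

    per_cross: pd.DataFrame  # index cross id, columns COMBO_CLASSES + homozygous_fraction
    homozygous_fraction_mean: float
    homozygous_fraction_sd: float


def estimate_f1_dosage(d1: float, d2: float) -> float:
    """Expected offspring dosage: the parental mean (d1 + d2) / 2.

    Missing in either parent propagates to missing.
    """
    if np.isnan(d1) or np.isnan(d2):
        return np.nan
    return (d1 + d2) / 2.0


def feasible_offspring_dosages(d1: float, d2: float) -> tuple[int, ...]:
    """Mendelian-feasible offspring dosages for one locus, no recombination.

    E.g. Aa x Aa -> (0, 1, 2); AA x Aa -> (1, 2); aa x AA -> (1,).
    """
    out = sorted({g1 + g2 for g1, _ in _GAMETES[d1] for g2, _ in _GAMETES[d2]})
    return tuple(out)


def _cross_vectors(
    geno: GenotypeMatrix, markers: RiskMarkerSet
) -> tuple[np.ndarray, list[str]]:
    vids = markers.vids
    pos = pd.Index(geno.variants["vid"]).get_indexer(vids)
    if (pos < 0).any():
        missing = [v for v, q in zip(vids, pos) if q < 0]
        raise KeyError(f"risk markers absent from genotype panel: {missing[:5]}")
    return geno.dosage[:, pos], vids


def predict_f1_prs(
    markers: RiskMarkerSet, geno: GenotypeMatrix, plan: CrossPlan
) -> list[PredictedF1]:
    """Predicted PRS point estimate and [min, max] bounds per cross.

    prs_point = sum_i beta_i (d1_i + d2_i)/2; the bounds take, per locus,
    the feasible offspring dosage minimizing/maximizing beta_i * d.  Loci
    with a missing parental genotype are skipped for that cross (logged).
    """
    plan.validate_against(geno)
    d_all, _ = _cross_vectors(geno, markers)
    betas = markers.betas
    out = []
    for c in plan:
        d1 = d_all[geno.sample_index(c.parent1)]
        d2 = d_all[geno.sample_index(c.parent2)]
        out.append(_predict_one(c.f1_id, c.parent1, c.parent2, d1, d2, betas))
    return out


def _predict_one(cross_id, p1, p2, d1, d2, betas) -> PredictedF1:
    ok = ~(np.isnan(d1) | np.isnan(d2))
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.info("cross %s: %d marker(s) skipped (missing parent genotype)", cross_id, n_skipped)
    if not ok.any():
        raise ValueError(f"cross {cross_id!r}: no marker with both parents genotyped")

    exp_dos = np.where(ok, (d1 + d2) / 2.0, np.nan)
    point = float(np.nansum(betas * exp_dos))
    lo = hi = 0.0
    n_uncertain = 0
    for i in np.flatnonzero(ok):
        feas = feasible_offspring_dosages(d1[i], d2[i])
        vals = [betas[i] * d for d in feas]
        lo += min(vals)
        hi += max(vals)
        if d1[i] == 1 or d2[i] == 1:
            n_uncertain += 1
    return PredictedF1(
        cross_id=cross_id,
        parent1=p1,
        parent2=p2,
        expected_dosage=exp_dos,
        prs_point=point,
        prs_min=float(lo),
        prs_max=float(hi),
        n_uncertain=n_uncertain,
        n_skipped=n_skipped,
    )


def enumerate_offspring_prs(
    markers: RiskMarkerSet, d1: np.ndarray, d2: np.ndarray
) -> dict:
    """Exact offspring PRS distribution under independent segregation.

    Returns ``{"dist": {prs: prob}, "mean": m, "min": lo, "max": hi}``.
    Feasible only for a bounded number of uncertain loci (3^k outcomes);
    refuses beyond the guard.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    betas = markers.betas
    ok = ~(np.isnan(d1) | np.isnan(d2))
    uncertain = np.flatnonzero(ok & ((d1 == 1) | (d2 == 1)))
    if len(uncertain) > ENUMERATION_GUARD:
        raise ValueError(
            f"{len(uncertain)} uncertain loci exceeds the enumeration guard "
            f"of {ENUMERATION_GUARD}; use predict_f1_prs bounds instead"
        )
    fixed = np.flatnonzero(ok & (d1 != 1) & (d2 != 1))
    base = float(sum(betas[i] * (d1[i] + d2[i]) / 2.0 for i in fixed))

    dist = {round(base, 12): 1.0}
    for i in uncertain:
        locus = {}
        for g1, p1 in _GAMETES[d1[i]]:
            for g2, p2 in _GAMETES[d2[i]]:
                v = betas[i] * (g1 + g2)
                locus[v] = locus.get(v, 0.0) + p1 * p2
        new = {}
        for v0, q0 in dist.items():
            for v1, q1 in locus.items():
                key = round(v0 + v1, 12)
                new[key] = new.get(key, 0.0) + q0 * q1
        dist = new

    vals = np.array(sorted(dist))
    probs = np.array([dist[v] for v in vals])
    return {
        "dist": dict(zip(vals.tolist(), probs.tolist())),
        "mean": float((vals * probs).sum()),
        "min": float(vals.min()),
        "max": float(vals.max()),
    }


def census_combos(geno: GenotypeMatrix, plan: CrossPlan, vids=None) -> ComboCensus:
    """Census the 6 unordered parental genotype combinations per cross.

    Classes: AAxAA, AAxAa, AAxaa, AaxAa, Aaxaa, aaxaa (A = counted allele).
    The panel summary for the both-parents-homozygous fraction is reported
    as mean +/- sd across crosses.
    """
    if len(plan) == 0:
        raise ValueError("empty cross plan")
    plan.validate_against(geno)
    if vids is not None:
        pos = pd.Index(geno.variants["vid"]).get_indexer(vids)
        d_all = geno.dosage[:, pos]
    else:
        d_all = geno.dosage

    rows = []
    for c in plan:
        d1 = d_all[geno.sample_index(c.parent1)]
        d2 = d_all[geno.sample_index(c.parent2)]
        ok = ~(np.isnan(d1) | np.isnan(d2))
        counts = dict.fromkeys(COMBO_CLASSES, 0)
        hi = np.maximum(d1[ok], d2[ok]).astype(int)
        lo = np.minimum(d1[ok], d2[ok]).astype(int)
        for h, l in zip(hi, lo):
            counts[_COMBO_BY_DOSAGE_PAIR[(h, l)]] += 1
        total = sum(counts.values())
        hom = sum(counts[k] for k in HOMOZYGOUS_COMBOS)
        rows.append(
            {"cross": c.f1_id, **counts, "n_loci": total,
             "homozygous_fraction": hom / total if total else np.nan}
        )
    per_cross = pd.DataFrame(rows).set_index("cross")
    frac = per_cross["homozygous_fraction"].to_numpy(dtype=float)
    return ComboCensus(
        per_cross=per_cross,
        homozygous_fraction_mean=float(np.nanmean(frac)),
        homozygous_fraction_sd=float(np.nanstd(frac, ddof=1)) if len(frac) > 1 else 0.0,
    )


def write_predictions(preds: list[PredictedF1], path, provenance: dict | None = None) -> None:
    """Tab-delimited cross/prs_point/prs_min/prs_max/n_uncertain."""
    with open(path, "w") as fh:
        for k, v in (provenance or {}).items():
            fh.write(f"# {k}: {v}\n")
        fh.write("cross\tparent1\tparent2\tprs_point\tprs_min\tprs_max\tn_uncertain\n")
        for p in preds:
            fh.write(
                f"{p.cross_id}\t{p.parent1}\t{p.parent2}\t{p.prs_point:.10g}\t"
                f"{p.prs_min:.10g}\t{p.prs_max:.10g}\t{p.n_uncertain}\n"
            )
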