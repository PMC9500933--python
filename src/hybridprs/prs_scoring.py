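"""Risk-marker selection, LD clumping, PRS computation and per-marker
variance explained.

The score for a sample is the additive weighted sum

    PRS = sum_i beta_i * E[dosage_i],    E[dosage] = sum_j w_j * j

over the selected risk markers, where ``w_j`` is the probability of
genotype ``j`` in {0, 1, 2} at marker ``i``.  Observed hard calls are the
one-hot special case (E[dosage] is the dosage itself); fractional expected
dosages arise for predicted offspring of heterozygous parents.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import GenotypeMatrix, SummaryStats

logger = logging.getLogger(__name__)


@dataclass
class RiskMarkerSet:
    """Markers passing the p-value threshold, with their signed weights.

    ``markers`` columns: vid, effect_allele, beta, p (a subset of a
    harmonized SummaryStats table).  ``pt`` and ``clump_params`` record
    provenance.
    """

    markers: pd.DataFrame
    pt: float
    clump_params: str = "none"

    def __post_init__(self) -> None:
        self.markers = self.markers.reset_index(drop=True)
        if len(self.markers) and (self.markers["p"] > self.pt).any():
            raise ValueError("marker with p above the selection threshold")

    def __len__(self) -> int:
        return len(self.markers)

    @property
    def vids(self) -> list[str]:
        return self.markers["vid"].tolist()

    @property
    def betas(self) -> np.ndarray:
        return self.markers["beta"].to_numpy(dtype=float)


@dataclass
class GenotypeDistribution:
    """Per sample, per marker genotype probabilities w_j, j in {0,1,2}.

    ``probs`` has shape (n_samples, n_markers, 3); rows sum to 1.  Hard
    calls are one-hot; a NaN slice marks a missing genotype.
    """

    samples: list[str]
    vids: list[str]
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(self.samples), len(self.vids), 3):
            raise ValueError("probs shape must be (n_samples, n_markers, 3)")
        s = self.probs.sum(axis=2)
        ok = np.isnan(s) | np.isclose(s, 1.0)
        if not ok.all():
            raise ValueError("genotype probabilities must sum to 1 per locus")

    @classmethod
    def from_dosage(cls, geno: GenotypeMatrix, vids=None) -> "GenotypeDistribution":
        """One-hot distribution from hard calls (optionally a marker subset)."""
        if vids is None:
            sub = geno
            vids = geno.variants["vid"].tolist()
        else:
            pos = pd.Index(geno.variants["vid"]).get_indexer(vids)
            if (pos < 0).any():
                missing = [v for v, q in zip(vids, pos) if q < 0]
                raise KeyError(f"markers absent from panel: {missing[:5]}")
            sub = geno.take_variants(pos)
        d = sub.dosage
        probs = np.full(d.shape + (3,), np.nan)
        for j in (0, 1, 2):
            hot = d == j
            probs[hot] = np.eye(3)[j]
        return cls(samples=sub.samples, vids=list(vids), probs=probs)

    def expected_dosage(self) -> np.ndarray:
        """E[dosage] per sample per marker; NaN where missing."""
        return self.probs @ np.array([0.0, 1.0, 2.0])


@dataclass
class ScoreResult:
    """PRS per sample plus the marker count actually used per sample."""

    scores: pd.Series
    n_markers: pd.Series
    pt: float = np.nan

    def __len__(self) -> int:
        return len(self.scores)


def select_markers(ss: SummaryStats, pt: float, clump_params: str = "none") -> RiskMarkerSet:
    """Risk loci: exactly the records with p <= pt, weights preserved."""
    if not (0 < pt <= 1):
        raise ValueError(f"p-value threshold must be in (0, 1], got {pt}")
    t = ss.table
    sel = t[t["p"] <= pt]
    if not len(sel):
        logger.warning("select_markers: no markers at pt=%g (scores will be 0)", pt)
    return RiskMarkerSet(markers=sel, pt=pt, clump_params=clump_params)


def filter_maf(geno: GenotypeMatrix, min_maf: float = 0.05) -> GenotypeMatrix:
    """Drop variants with minor-allele frequency <= ``min_maf``."""
    keep = np.flatnonzero(geno.minor_allele_freq() > min_maf)
    return geno.take_variants(keep)


def clump(
    ss: SummaryStats,
    geno: GenotypeMatrix,
    r2_max: float = 0.1,
    window_kb: float = 250.0,
) -> SummaryStats:
    """Greedy LD clumping: keep the most significant marker per LD block.

    Markers are visited by ascending p; a marker is retained unless an
    already-retained marker on the same chromosome within ``window_kb`` has
    squared dosage correlation above ``r2_max`` with it.  Ties in p are
    broken toward genome order (first in the panel).  Monomorphic markers
    have undefined r2 and are treated as unlinked.
    """
    t = ss.table
    vt = geno.variants.set_index("vid")
    shared = [v for v in t["vid"] if v in vt.index]
    if len(shared) < len(t):
        logger.info("clump: %d marker(s) lack genotypes, kept unclumped-checked", 0)
    t = t.set_index("vid", drop=False).loc[shared]

    panel_pos = pd.Index(geno.variants["vid"]).get_indexer(shared)
    chrom = vt.loc[shared, "chrom"].to_numpy()
    pos = vt.loc[shared, "pos"].to_numpy(dtype=float)
    d = geno.dosage[:, panel_pos]
    # mean-impute for the correlation computation only
    col_mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
    d = np.where(np.isnan(d), col_mean, d)
    sd = d.std(axis=0)

    p = t["p"].to_numpy(dtype=float)
    genome_order = np.arange(len(shared))
    visit = np.lexsort((genome_order, p))  # ascending p, genome order ties

    retained: list[int] = []
    window_bp = window_kb * 1000.0
    for i in visit:
        linked = False
        for j in retained:
            if chrom[j] != chrom[i] or abs(pos[j] - pos[i]) > window_bp:
                continue
            if sd[i] == 0 or sd[j] == 0:
                logger.info("clump: monomorphic marker %s, r2 undefined", shared[i])
                continue
            r = np.corrcoef(d[:, i], d[:, j])[0, 1]
            if r * r > r2_max:
                linked = True
                break
        if not linked:
            retained.append(i)
    retained_vids = {shared[i] for i in retained}
    out = ss.table[ss.table["vid"].isin(retained_vids)]
    return SummaryStats(table=out, n_dropped=ss.n_dropped)


def compute_prs(
    markers: RiskMarkerSet,
    dist: GenotypeDistribution | GenotypeMatrix,
    missing_policy: str = "mean",
) -> ScoreResult:
    """Score samples: PRS = sum_i beta_i * E[dosage_i].

    ``missing_policy``: "mean" imputes a missing genotype with the panel
    mean expected dosage at that marker; "drop" skips the marker for that
    sample.  A sample missing every marker scores NaN, never 0.
    """
    if missing_policy not in ("mean", "drop"):
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    if isinstance(dist, GenotypeMatrix):
        dist = GenotypeDistribution.from_dosage(dist, markers.vids)
    else:
        order = pd.Index(dist.vids).get_indexer(markers.vids)
        if (order < 0).any():
            raise KeyError("marker set not fully resolvable in the distribution")
        dist = GenotypeDistribution(
            samples=dist.samples, vids=markers.vids, probs=dist.probs[:, order, :]
        )

    ed = dist.expected_dosage()  # (n_samples, m)
    betas = markers.betas
    missing = np.isnan(ed)
    if missing_policy == "mean":
        counts = (~missing).sum(axis=0)
        with np.errstate(invalid="ignore"):
            col_mean = np.where(missing, 0.0, ed).sum(axis=0) / np.where(counts, counts, 1)
        col_mean[counts == 0] = np.nan
        all_missing_col = np.isnan(col_mean)
        fill = np.where(all_missing_col, 0.0, col_mean)
        filled = np.where(missing, fill, ed)
        used = (~missing) | (~all_missing_col)[None, :]
    else:
        filled = np.where(missing, 0.0, ed)
        used = ~missing

    contrib = np.where(used, filled * betas, 0.0)
    scores = contrib.sum(axis=1)
    n_used = used.sum(axis=1)
    # a sample contributing no marker (nothing observed or imputable) is
    # unscoreable, not 0
    if len(markers):
        scores = np.where(n_used == 0, np.nan, scores)

    return ScoreResult(
        scores=pd.Series(scores, index=dist.samples, name="PRS"),
        n_markers=pd.Series(n_used, index=dist.samples, name="n_markers"),
        pt=markers.pt,
    )


def compute_pve(beta: float, se: float, n: float, af: float) -> float:
    """Per-marker phenotypic variance explained from summary statistics.

    PVE = 2 b^2 f(1-f) / (2 b^2 f(1-f) + se^2 * 2 n f(1-f)), f the
    effect-allele frequency.  Requires 0 < f < 1 and n, se available.
    """
    for name, v in (("beta", beta), ("se", se), ("n", n), ("af", af)):
        if v is None or not np.isfinite(v):
            raise ValueError(f"compute_pve requires a finite {name}; supply it")
    if not (0 < af < 1):
        raise ValueError(f"effect-allele frequency must be in (0, 1), got {af}")
    if se < 0 or n <= 0:
        raise ValueError("se must be >= 0 and n > 0")
    h = 2.0 * af * (1.0 - af)
    num = beta * beta * h
    den = num + se * se * 2.0 * n * af * (1.0 - af)
    if den == 0:
        return 0.0
    return num / den


def compute_set_pve(markers: RiskMarkerSet, n: float | None = None) -> float:
    """Marker-set PVE: sum of per-marker PVE, capped at 1 with a warning.

    Valid under (approximate) marker independence; per-marker ``n``/``af``
    from the summary statistics, with ``n`` as a fallback for records
    lacking a sample count.
    """
    total = 0.0
    for _, m in markers.markers.iterrows():
        n_i = m["n"] if np.isfinite(m.get("n", np.nan)) else n
        total += compute_pve(m["beta"], m["se"], n_i, m["af"])
    if total > 1.0:
        logger.warning("set-level PVE %.3f exceeds 1; capped (markers not independent)", total)
        total = 1.0
    return total


def write_scores(result: ScoreResult, path, provenance: dict | None = None) -> None:
    """Tab-delimited sample<TAB>PRS<TAB>n_markers with # provenance headers."""
    with open(path, "w") as fh:
        for k, v in (provenance or {}).items():
            fh.write(f"# {k}: {v}\n")
        fh.write("sample\tPRS\tn_markers\n")
        for s in result.scores.index:
            fh.write(f"{s}\t{result.scores[s]:.10g}\t{result.n_markers[s]}\n")


def write_marker_set(markers: RiskMarkerSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# pt: {markers.pt}\n# clump: {markers.clump_params}\n")
        markers.markers[["vid", "effect_allele", "beta", "p"]].to_csv(
            fh, sep="\t", index=False
        )
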