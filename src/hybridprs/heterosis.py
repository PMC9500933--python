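"""Heterosis metrics for F1 hybrids and rank-sum group comparisons.

For a cross with F1 phenotype ``f1`` and parental phenotypes ``p1, p2``:

    BPH = F1 - BP    (best-parent heterosis; BP = max parent)
    MPH = F1 - MPV   (mid-parent heterosis; MPV = parental mean)
    DEP = WP - F1    (depression; WP = min parent)

A cross shows heterosis when MPH > 0 (strictly), significant heterosis
when BPH > 0, and decline when DEP > 0.  The identity
MPH = (BPH - DEP)/2 holds exactly.  Group contrasts on PRS use the
two-sided Wilcoxon rank-sum test with the statistic in the convention of
R's ``wilcox.test`` (rank sum of group 1 minus its minimum, i.e. the
Mann-Whitney U of group 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class HeterosisRecord:
    cross_id: str
    f1: float
    bp: float
    mpv: float
    wp: float
    bph: float
    mph: float
    dep: float
    shows_heterosis: bool      # MPH > 0
    shows_best_parent: bool    # BPH > 0
    shows_depression: bool     # DEP > 0


@dataclass
class GroupComparison:
    labels: tuple[str, str]
    w: float
    p: float
    n1: int
    n2: int
    method: str  # "exact" or "asymptotic"


def compute_heterosis(cross_id: str, f1: float, p1: float, p2: float) -> HeterosisRecord:
    """BPH/MPH/DEP for one cross; raises on non-finite phenotypes."""
    for name, v in (("f1", f1), ("parent1", p1), ("parent2", p2)):
        if v is None or not np.isfinite(v):
            raise ValueError(f"cross {cross_id!r}: {name} phenotype missing or non-finite")
    bp, wp = max(p1, p2), min(p1, p2)
    mpv = (p1 + p2) / 2.0
    bph, mph, dep = f1 - bp, f1 - mpv, wp - f1
    return HeterosisRecord(
        cross_id=cross_id, f1=f1, bp=bp, mpv=mpv, wp=wp,
        bph=bph, mph=mph, dep=dep,
        shows_heterosis=mph > 0,
        shows_best_parent=bph > 0,
        shows_depression=dep > 0,
    )


def heterosis_table(
    pheno: pd.Series, plan, skip_missing: bool = True
) -> tuple[list[HeterosisRecord], int]:
    """Heterosis records for every cross whose three phenotypes are known.

    Crosses with a missing phenotype are skipped and counted (second
    return value) rather than fatal when ``skip_missing``.
    """
    records, n_skipped = [], 0
    for c in plan:
        try:
            f1 = float(pheno[c.f1_id])
            p1 = float(pheno[c.parent1])
            p2 = float(pheno[c.parent2])
            records.append(compute_heterosis(c.f1_id, f1, p1, p2))
        except (KeyError, ValueError):
            if not skip_missing:
                raise
            n_skipped += 1
    if n_skipped:
        logger.info("heterosis_table: skipped %d cross(es) with missing phenotypes", n_skipped)
    return records, n_skipped


def compare_groups(
    values1: np.ndarray | pd.Series,
    values2: np.ndarray | pd.Series,
    labels: tuple[str, str] = ("group1", "group2"),
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum test between two PRS groups.

    Exact null distribution when both groups have <= 50 observations and
    there are no ties; otherwise the normal approximation with continuity
    correction and tie-corrected variance.  W follows R's ``wilcox.test``:
    the rank sum of group 1 minus n1(n1+1)/2.
    """
    x = np.asarray(values1, dtype=float)
    y = np.asarray(values2, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if len(x) == 0 or len(y) == 0:
        empty = labels[0] if len(x) == 0 else labels[1]
        raise ValueError(f"group {empty!r} is empty")
    n1, n2 = len(x), len(y)

    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        # fully tied data: symmetric by construction
        return GroupComparison(labels=labels, w=n1 * n2 / 2.0, p=1.0,
                               n1=n1, n2=n2, method="degenerate")

    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (n1 <= 50 and n2 <= 50 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return GroupComparison(
        labels=labels, w=float(res.statistic), p=float(min(res.pvalue, 1.0)),
        n1=n1, n2=n2, method=method,
    )


def contrast_by_flag(
    scores: pd.Series, records: list[HeterosisRecord], flag: str
) -> GroupComparison:
    """PRS of crosses with ``flag`` set vs the complement within the F1 set.

    ``flag`` is one of shows_heterosis / shows_best_parent /
    shows_depression.
    """
    if not records:
        raise ValueError("no heterosis records")
    grp1, grp2 = [], []
    for r in records:
        if r.cross_id not in scores.index:
            continue
        (grp1 if getattr(r, flag) else grp2).append(scores[r.cross_id])
    return compare_groups(
        np.array(grp1), np.array(grp2), labels=(flag, f"not_{flag}")
    )


def write_heterosis_table(records: list[HeterosisRecord], path, provenance=None) -> None:
    """Tab-delimited cross/bph/mph/dep plus flag columns."""
    with open(path, "w") as fh:
        for k, v in (provenance or {}).items():
            fh.write(f"# {k}: {v}\n")
        fh.write("cross\tf1\tbp\tmpv\twp\tbph\tmph\tdep\theterosis\tbest_parent\tdepression\n")
        for r in records:
            fh.write(
                f"{r.cross_id}\t{r.f1:.10g}\t{r.bp:.10g}\t{r.mpv:.10g}\t{r.wp:.10g}\t"
                f"{r.bph:.10g}\t{r.mph:.10g}\t{r.dep:.10g}\t"
                f"{int(r.shows_heterosis)}\t{int(r.shows_best_parent)}\t{int(r.shows_depression)}\n"
            )
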