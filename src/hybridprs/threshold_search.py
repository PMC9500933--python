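"""High-resolution p-value-threshold scan for the best-fit PRS.

At each candidate threshold PT the markers with p <= PT are scored and the
phenotype is regressed on the PRS by ordinary least squares; the scan
returns the R-squared curve and the PT that maximizes it (ties broken
toward the smaller, more parsimonious PT).  The default grid unions broad
anchor thresholds with a dense sweep at step 5e-5, so thresholds like
0.37885 are exactly representable.

Because the marker set at a larger PT is a superset of the set at a smaller
one, the scan accumulates per-marker score contributions incrementally in
ascending-p order; the full curve costs one pass over the markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import GenotypeMatrix, SummaryStats
from .prs_scoring import ScoreResult

logger = logging.getLogger(__name__)

BROAD_ANCHORS = (5e-8, 1e-5, 1e-3, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 1.0)


def default_grid(step: float = 5e-5, lo: float = 5e-8, hi: float = 0.5) -> np.ndarray:
    """Broad anchors unioned with a dense sweep of multiples of ``step``."""
    dense = np.round(np.arange(step, hi + step / 2, step), 10)
    grid = np.union1d(np.asarray(BROAD_ANCHORS), dense)
    return grid[(grid >= lo) & (grid <= 1.0)]


@dataclass
class ScanPoint:
    pt: float
    n_markers: int
    r2: float
    p_fit: float
    flagged: bool = False  # zero markers at this PT


@dataclass
class ThresholdScan:
    points: list[ScanPoint]
    best: ScanPoint
    grid_spec: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(q.pt, q.n_markers, q.r2, q.p_fit) for q in self.points],
            columns=["pt", "n_markers", "r2", "p_fit"],
        )


@dataclass
class FitResult:
    """OLS fit of phenotype on PRS with 95% confidence intervals.

    ``slope_ci``/``intercept_ci`` are the 95% bands on the coefficients;
    ``ks_p`` is a Kolmogorov-Smirnov normality p-value for the residuals,
    attached as a diagnostic only.
    """

    slope: float
    intercept: float
    r2: float
    p_fit: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    ks_p: float
    n: int


def _r2_and_p(scores: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """R^2 and two-sided slope p for simple OLS of y on scores."""
    n = len(y)
    sx = scores.std()
    if sx == 0 or y.std() == 0:
        return 0.0, 1.0
    r = np.corrcoef(scores, y)[0, 1]
    r2 = r * r
    if n <= 2:
        return r2, 1.0
    denom = 1.0 - r2
    if denom <= 1e-300:  # numerically perfect fit
        return min(r2, 1.0), 0.0
    t = r * np.sqrt((n - 2) / denom)
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r2, p


def scan_thresholds(
    ss: SummaryStats,
    geno: GenotypeMatrix,
    pheno: pd.Series,
    grid: np.ndarray | None = None,
) -> ThresholdScan:
    """Score at every grid PT and regress phenotype on PRS.

    Samples are the intersection of the panel and the phenotype table
    (>= 3 required).  Missing genotypes are mean-imputed for scoring.
    Returns one ScanPoint per PT; ``best`` maximizes R^2, ties toward the
    smaller PT.  A PT with zero markers is recorded with r2 = 0 and
    flagged.
    """
    if grid is None:
        grid = default_grid()
    grid = np.sort(np.asarray(grid, dtype=float))
    if grid.size == 0:
        raise ValueError("empty threshold grid")
    if np.any(grid <= 0) or np.any(grid > 1):
        raise ValueError("thresholds must lie in (0, 1]")

    shared = [s for s in geno.samples if s in pheno.index]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared samples, have {len(shared)}")
    sub = geno.take_samples(shared)
    y = pheno.loc[shared].to_numpy(dtype=float)

    t = ss.table
    panel_pos = pd.Index(sub.variants["vid"]).get_indexer(t["vid"])
    in_panel = panel_pos >= 0
    if not in_panel.all():
        logger.info("scan: %d sumstats marker(s) absent from panel", int((~in_panel).sum()))
    betas = t["beta"].to_numpy(dtype=float)[in_panel]
    pvals = t["p"].to_numpy(dtype=float)[in_panel]
    cols = panel_pos[in_panel]

    d = sub.dosage[:, cols]
    col_mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0) if d.size else np.empty(0)
    d = np.where(np.isnan(d), np.nan_to_num(col_mean), d)

    order = np.argsort(pvals, kind="stable")
    p_sorted = pvals[order]

    points: list[ScanPoint] = []
    scores = np.zeros(len(shared))
    k = 0
    for pt in grid:
        while k < len(p_sorted) and p_sorted[k] <= pt:
            j = order[k]
            scores = scores + betas[j] * d[:, j]
            k += 1
        if k == 0:
            points.append(ScanPoint(pt=float(pt), n_markers=0, r2=0.0, p_fit=1.0, flagged=True))
            continue
        r2, p_fit = _r2_and_p(scores, y)
        points.append(ScanPoint(pt=float(pt), n_markers=k, r2=r2, p_fit=p_fit))

    best = max(points, key=lambda q: (q.r2, -q.pt))
    return ThresholdScan(points=points, best=best, grid_spec=f"{len(grid)} thresholds")


def fit_prs_phenotype(scores: ScoreResult | pd.Series, pheno: pd.Series) -> FitResult:
    """OLS of phenotype on PRS with 95% CIs and a residual-normality check.

    Two-tailed slope p at alpha 0.05 convention; the KS normality p never
    gates the fit.  Raises on zero-variance PRS.
    """
    import statsmodels.api as sm

    s = scores.scores if isinstance(scores, ScoreResult) else scores
    shared = [i for i in s.index if i in pheno.index and np.isfinite(s[i])]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared samples, have {len(shared)}")
    x = s.loc[shared].to_numpy(dtype=float)
    y = pheno.loc[shared].to_numpy(dtype=float)
    if x.std() == 0:
        raise ValueError("PRS has zero variance; fit undefined")

    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    resid = model.resid
    sd = resid.std(ddof=1)
    ks_p = float(stats.kstest(resid, "norm", args=(resid.mean(), sd)).pvalue) if sd > 0 else 1.0

    return FitResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r2=float(model.rsquared),
        p_fit=float(model.pvalues[1]),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        intercept_ci=(float(ci[0][0]), float(ci[0][1])),
        ks_p=ks_p,
        n=len(shared),
    )


def write_scan_report(scan: ThresholdScan, path) -> None:
    """Tab-delimited pt/n_markers/r2/p_fit with a #best header line."""
    b = scan.best
    with open(path, "w") as fh:
        fh.write(f"# grid: {scan.grid_spec}\n")
        fh.write(f"#best\tpt={b.pt:.10g}\tn_markers={b.n_markers}\tr2={b.r2:.6g}\tp_fit={b.p_fit:.6g}\n")
        fh.write("pt\tn_markers\tr2\tp_fit\n")
        for q in scan.points:
            fh.write(f"{q.pt:.10g}\t{q.n_markers}\t{q.r2:.6g}\t{q.p_fit:.6g}\n")


def plot_scan(scan: ThresholdScan, path, high_resolution: bool = True) -> None:
    """Bar plot at the broad anchors, or the full high-resolution curve."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = scan.to_frame()
    fig, ax = plt.subplots(figsize=(7, 4))
    if high_resolution:
        ax.plot(df["pt"], df["r2"], lw=0.8, color="steelblue")
        anchors = df[df["pt"].isin(BROAD_ANCHORS)]
        ax.plot(anchors["pt"], anchors["r2"], "-o", color="firebrick", ms=4)
        ax.set_xscale("log")
    else:
        anchors = df[df["pt"].isin(BROAD_ANCHORS)]
        ax.bar([f"{p:g}" for p in anchors["pt"]], anchors["r2"], color="steelblue")
    ax.axvline(scan.best.pt, color="grey", ls="--", lw=0.8) if high_resolution else None
    ax.set_xlabel("p-value threshold")
    ax.set_ylabel(r"model fit $R^2$")
    ax.set_title(f"best PT = {scan.best.pt:g} ({scan.best.n_markers} markers)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
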