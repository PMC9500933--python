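"""Core in-memory containers shared across the pipeline.

Genotypes are dosage-coded: the entry for (sample, variant) counts copies
of the counted allele ``a1`` in a diploid genotype, so values are 0, 1 or 2
(aa, Aa, AA) with ``NaN`` for missing calls.  Fractional dosages only ever
appear in *expected* offspring genotypes, never in an observed panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["chrom", "pos", "vid", "a1", "a2"]
SUMSTATS_COLUMNS = ["vid", "effect_allele", "other_allele", "beta", "se", "p", "af", "n"]


class Variant(NamedTuple):
    """A biallelic variant; ``a1`` is the counted (effect/alternate) allele."""

    chrom: str
    pos: int
    vid: str
    a1: str
    a2: str


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with variant metadata.

    Parameters
    ----------
    samples
        Ordered sample identifiers (rows of ``dosage``).
    variants
        DataFrame with columns ``chrom, pos, vid, a1, a2`` (columns of
        ``dosage``), positions 1-based.
    dosage
        float array, shape ``(n_samples, n_variants)``; entries in
        {0, 1, 2} or NaN (missing).
    """

    samples: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.variants = self.variants.reset_index(drop=True)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        missing = set(VARIANT_COLUMNS) - set(self.variants.columns)
        if missing:
            raise ValueError(f"variant table missing columns: {sorted(missing)}")
        vals = self.dosage[~np.isnan(self.dosage)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing dosages must be 0, 1 or 2")
        if self.variants["vid"].duplicated().any():
            dups = self.variants.loc[self.variants["vid"].duplicated(), "vid"]
            raise ValueError(f"duplicate variant ids: {sorted(set(dups))[:5]}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in panel") from None

    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted allele a1 per variant, ignoring missing."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def minor_allele_freq(self) -> np.ndarray:
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def take_variants(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            samples=self.samples,
            variants=self.variants.iloc[idx],
            dosage=self.dosage[:, idx],
        )

    def take_samples(self, ids: Sequence[str]) -> "GenotypeMatrix":
        rows = [self.sample_index(s) for s in ids]
        return GenotypeMatrix(
            samples=list(ids),
            variants=self.variants,
            dosage=self.dosage[rows, :],
        )


@dataclass
class SummaryStats:
    """Per-variant association results (the GWAS side of scoring).

    ``table`` has columns ``vid, effect_allele, other_allele, beta, se, p``
    plus optional ``af`` (effect-allele frequency) and ``n`` (sample count),
    NaN where unknown.  ``n_dropped`` counts input records discarded at
    parse time (unparseable or non-positive p, etc.).
    """

    table: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self) -> None:
        t = self.table.copy()
        for col in SUMSTATS_COLUMNS:
            if col not in t.columns:
                if col in ("af", "n", "other_allele"):
                    t[col] = np.nan
                else:
                    raise ValueError(f"summary statistics missing column {col!r}")
        extras = [c for c in t.columns if c not in SUMSTATS_COLUMNS]
        t = t[SUMSTATS_COLUMNS + extras].reset_index(drop=True)
        if len(t):
            p = t["p"].to_numpy(dtype=float)
            if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
                raise ValueError("p-values must lie in (0, 1]")
            if t["vid"].duplicated().any():
                raise ValueError("duplicate vids in summary statistics")
        self.table = t

    def __len__(self) -> int:
        return len(self.table)


class Cross(NamedTuple):
    parent1: str
    parent2: str
    f1_id: str


@dataclass
class CrossPlan:
    """Ordered list of planned crosses (parent pairs, optional F1 label)."""

    crosses: list[Cross] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.crosses = [Cross(*c) for c in self.crosses]

    def __len__(self) -> int:
        return len(self.crosses)

    def __iter__(self):
        return iter(self.crosses)

    def validate_against(self, geno: GenotypeMatrix) -> None:
        """Raise if any parent is absent from the genotype panel."""
        panel = set(geno.samples)
        for c in self.crosses:
            for p in (c.parent1, c.parent2):
                if p not in panel:
                    raise KeyError(
                        f"cross {c.f1_id!r}: parent {p!r} not in genotype panel"
                    )


def make_cross_plan(pairs: Sequence[tuple]) -> CrossPlan:
    """Build a CrossPlan from (parent1, parent2[, f1_id]) tuples."""
    crosses = []
    for i, pair in enumerate(pairs):
        if len(pair) == 2:
            p1, p2 = pair
            fid = f"{p1}x{p2}"
        else:
            p1, p2, fid = pair
        crosses.append(Cross(str(p1), str(p2), str(fid)))
    return CrossPlan(crosses)
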