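import numpy as np
import pandas as pd
import pytest

from hybridprs import SimConfig, SummaryStats, GenotypeMatrix, simulate_study


def make_variants(n, chrom="chr1", spacing=1000):
    return pd.DataFrame(
        {
            "chrom": [chrom] * n,
            "pos": [spacing * (i + 1) for i in range(n)],
            "vid": [f"v{i}" for i in range(n)],
            "a1": ["G"] * n,
            "a2": ["A"] * n,
        }
    )


def make_geno(dosage, samples=None, variants=None):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    samples = samples or [f"s{i}" for i in range(n)]
    variants = variants if variants is not None else make_variants(m)
    return GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)


def make_sumstats(betas, pvals, vids=None, ses=None, afs=None, n=None):
    m = len(betas)
    vids = vids or [f"v{i}" for i in range(m)]
    return SummaryStats(
        table=pd.DataFrame(
            {
                "vid": vids,
                "effect_allele": ["G"] * m,
                "other_allele": ["A"] * m,
                "beta": betas,
                "se": ses if ses is not None else [0.1] * m,
                "p": pvals,
                "af": afs if afs is not None else [0.3] * m,
                "n": n if n is not None else np.nan,
            }
        )
    )


@pytest.fixture(scope="session")
def small_study():
    """A small but non-trivial synthetic study shared across tests."""
    cfg = SimConfig(n_samples=300, n_variants=400, n_causal=30, h2=0.6,
                    inbreeding=0.9, seed=11)
    return simulate_study(cfg, n_crosses=20)
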