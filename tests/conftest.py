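import numpy as np
import pandas as pd
import pytest

from mrscan.harmonize import HarmonizedSet, HarmonizedVariant
from mrscan.ld import ReferencePanel
from mrscan.sumstats import COLUMNS, GwasSummary


def make_harmonized(rng: np.random.Generator, k: int, theta: float = 0.3) -> HarmonizedSet:
    """A random harmonized set with roughly proportional effects."""
    bx = rng.normal(0.1, 0.05, k)
    bx[np.abs(bx) < 1e-3] = 0.05
    sx = rng.uniform(0.005, 0.02, k)
    sy = rng.uniform(0.01, 0.05, k)
    by = theta * bx + rng.normal(0.0, sy)
    return harmonized_from_arrays(bx, sx, by, sy)


def harmonized_from_arrays(bx, sx, by, sy, exposure_id="X", outcome_id="Y") -> HarmonizedSet:
    variants = [
        HarmonizedVariant(f"rs{i+1}", float(bx[i]), float(sx[i]), float(by[i]),
                          float(sy[i]), 0.3, 0.3, "kept")
        for i in range(len(bx))
    ]
    return HarmonizedSet(exposure_id, outcome_id, variants)


def make_gwas(rows, trait_id="T", trait_type="exposure") -> GwasSummary:
    """GwasSummary from (variant_id, chrom, pos, ea, oa, eaf, beta, se, pval, n) tuples."""
    return GwasSummary(trait_id, trait_type, pd.DataFrame(rows, columns=COLUMNS))


def random_panel(rng: np.random.Generator, m: int, n: int,
                 chroms=("1", "2"), span_bp: int = 2_000_000) -> ReferencePanel:
    """Dense random panel: clustered positions so clumping windows overlap."""
    variants = pd.DataFrame({
        "variant_id": [f"rs{i+1:04d}" for i in range(m)],
        "chrom": rng.choice(chroms, m),
        "pos": rng.integers(1, span_bp, m),
        "ref": "A",
        "alt": "G",
    })
    maf = rng.uniform(0.1, 0.5, m)
    dos = rng.binomial(2, maf[:, None], size=(m, n)).astype(float)
    return ReferencePanel(variants, dos)


@pytest.fixture
def rng():
    return np.random.default_rng(20230915)
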