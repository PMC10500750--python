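import numpy as np
import pandas as pd
import pytest

from prsoverlap.formats import GenotypePanel, PhenotypeTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_panel():
    """2 samples x 3 variants, hand-written dosages."""
    variants = pd.DataFrame(
        {
            "variant_id": ["rs1", "rs2", "rs3"],
            "chrom": ["1", "1", "2"],
            "pos": [100, 200, 100],
            "allele_counted": ["A", "C", "G"],
            "allele_other": ["G", "T", "A"],
        }
    )
    dosage = np.array([[2.0, 1.0, 0.0], [0.0, np.nan, 2.0]])
    return GenotypePanel(variants, ["s1", "s2"], dosage)


def random_panel(rng, n=100, m=50, chrom="1", spacing=1000, maf_low=0.1):
    """Unstructured random panel for quick property checks."""
    maf = rng.uniform(maf_low, 0.5, size=m)
    dosage = rng.binomial(2, maf, size=(n, m)).astype(float)
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{j}" for j in range(m)],
            "chrom": chrom,
            "pos": np.arange(1, m + 1) * spacing,
            "allele_counted": "A",
            "allele_other": "G",
        }
    )
    return GenotypePanel(variants, [f"s{i}" for i in range(n)], dosage)


def binary_pheno(rng, sample_ids, p=0.5, covariates=None):
    tab = pd.DataFrame(
        {"sample_id": sample_ids, "phenotype": rng.integers(0, 2, size=len(sample_ids))}
    )
    # guarantee both classes
    tab.loc[0, "phenotype"] = 0
    tab.loc[1, "phenotype"] = 1
    for name, values in (covariates or {}).items():
        tab[name] = values
    return PhenotypeTable(tab, "binary")
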