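import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


@pytest.fixture
def tiny_genes() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": ["GA", "GB", "GC"],
            "symbol": ["A", "B", "C"],
            "chrom": ["1", "1", "2"],
            "start": [1000, 50_000, 10_000],
            "end": [5000, 60_000, 20_000],
            "strand": ["+", "-", "+"],
        }
    )


@pytest.fixture
def tiny_snps() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": ["rs1", "rs2", "rs3"],
            "chrom": ["1", "1", "2"],
            "pos": [1000, 70_000, 15_000],
            "allele_ref": ["A", "C", "G"],
            "allele_alt": ["T", "G", "A"],
            "pvalue": [1e-9, 0.5, 4e-8],
            "effect": [0.1, -0.2, 0.3],
        }
    )
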