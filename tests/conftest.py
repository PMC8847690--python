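import numpy as np
import pandas as pd
import pytest

from pleioscan.simulate import PlantedLocus, SimConfig, simulate_panel


def write_ma(path, rows, header=("SNP", "chr", "pos", "A1", "A2", "freq", "b", "se", "p", "N")):
    """Write a minimal GCTA-.ma-style summary-statistics file."""
    df = pd.DataFrame(rows, columns=list(header))
    df.to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture
def toy_sumstats(tmp_path):
    """Three well-formed variants plus one with se = 0."""
    rows = [
        ("rs1", "1", 1000, "A", "G", 0.30, 0.10, 0.05, None, 50000),
        ("rs1531817", "15", 101906737, "C", "A", 0.68, 0.02, 0.004, None, 77000),
        ("rs3", "2", 5000, "T", "C", 0.10, -0.30, 0.10, None, 50000),
        ("rs_bad", "3", 9000, "A", "C", 0.20, 0.10, 0.0, None, 50000),
    ]
    return write_ma(tmp_path / "toy.ma", rows)


@pytest.fixture(scope="session")
def null_panel_2trait():
    """10,000-variant two-trait global-null panel with sample-overlap 0.3."""
    cfg = SimConfig(trait_labels=("A", "B"),
                    n_per_trait={"A": 100_000, "B": 200_000},
                    n_variants=10_000, n_blocks=200, within_block_rho=0.5,
                    cross_trait_null_corr=np.array([[1.0, 0.3], [0.3, 1.0]]),
                    seed=42)
    return simulate_panel(cfg)


@pytest.fixture(scope="session")
def planted_panel():
    """Small three-trait panel with one shared and one single-trait locus."""
    cfg = SimConfig(trait_labels=("PAD", "CAD", "T2D"),
                    n_per_trait={"PAD": 77_000, "CAD": 330_000, "T2D": 450_000},
                    n_variants=800, n_blocks=20, within_block_rho=0.6,
                    cross_trait_null_corr=np.array([[1.0, 0.2, 0.1],
                                                    [0.2, 1.0, 0.1],
                                                    [0.1, 0.1, 1.0]]),
                    planted_loci=(
                        PlantedLocus(index=5 * 40 + 20, traits=("PAD", "CAD"),
                                     noncentrality=5.0),
                        PlantedLocus(index=15 * 40 + 20, traits=("PAD",),
                                     noncentrality=6.0),
                    ),
                    is_binary={"PAD": True, "CAD": True, "T2D": True},
                    seed=7)
    return simulate_panel(cfg)
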