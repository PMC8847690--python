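"""Bundled example data.

``load_multitrait_loci`` returns a curated table of 31 published sentinel
variants from bivariate and trivariate atherosclerosis scans (peripheral
and coronary artery disease jointly with cardiometabolic risk factors):
scan traits, sentinel rsID, GRCh37 position, alleles, per-trait direction
of effect, effect-allele frequency, the multivariate p-value and the
single-trait p-values. It is the worked example for the locus-merging and
filter-consistency operations.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_multitrait_loci"]


def load_multitrait_loci() -> pd.DataFrame:
    """Example multi-trait association table (31 sentinel rows)."""
    ref = resources.files("pleioscan.data") / "atherosclerosis_multitrait_loci.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
    df["chrom"] = df["chrom"].astype(str)
    return df
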