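"""Synthetic multi-trait GWAS summary statistics with planted signals.

The generator emulates the statistical structure the analysis assumes, so
every pipeline stage is testable without access-controlled data:

* within-trait LD: variants fall into independent blocks with AR(1)
  correlation rho^|i−j|, a standing-in for a haplotype-block LD panel;
* cross-trait null correlation: a K×K matrix (sample overlap / phenotypic
  correlation) coupled to the LD blocks as a separable (Kronecker) noise
  covariance — the simplest structure consistent with both;
* planted loci: a per-trait non-centrality added to the Z-score mean at a
  causal variant (shared across the trait subset, or one distinct causal
  variant per trait within the same block) and smeared over neighbors by LD;
* molecular QTLs: per gene-tissue association vectors whose causal variant
  either equals a planted GWAS causal variant (colocalized) or is an
  essentially unlinked variant (r² < 0.1) in the same block.

Betas and standard errors are back-filled from z on the standard GWAS scale
(se = 1/sqrt(2·N·MAF·(1−MAF)), MAF uniform on a configured range), and the
output is written in exactly the dialects the readers consume. Everything
is deterministic given the seed. A truth table records every planted effect
for downstream parameter-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, toeplitz

from .coloc import AssocVector
from .significance import z_to_p
from .sumstats import LDTable, TraitScan

__all__ = [
    "PlantedLocus",
    "SimConfig",
    "TruthTable",
    "SimulatedPanel",
    "make_ld_matrix",
    "simulate_panel",
    "simulate_molecular_qtl",
]

_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"),
                 ("C", "A"), ("G", "A"), ("C", "T"), ("G", "T")]


@dataclass(frozen=True)
class PlantedLocus:
    """A causal signal planted at one variant for a subset of traits."""

    index: int                 # global variant index of the (first) causal variant
    traits: tuple              # trait labels carrying the signal
    noncentrality: float = 5.5  # added to the Z mean at the causal variant, per trait
    shared: bool = True        # one shared causal variant vs one per trait


@dataclass
class SimConfig:
    """Study conditions for one simulated panel."""

    trait_labels: tuple
    n_per_trait: dict                 # label -> (effective) sample size
    n_variants: int = 10_000
    n_blocks: int = 200
    within_block_rho: float = 0.6
    cross_trait_null_corr: np.ndarray = None   # K×K; identity when None
    planted_loci: tuple = ()
    is_binary: dict = None
    maf_range: tuple = (0.05, 0.5)
    spacing_bp: int = 5_000
    chrom: str = "1"
    seed: int = 0

    def __post_init__(self):
        K = len(self.trait_labels)
        if self.cross_trait_null_corr is None:
            self.cross_trait_null_corr = np.eye(K)
        C = np.asarray(self.cross_trait_null_corr, dtype=float)
        if C.shape != (K, K) or not np.allclose(C, C.T) or \
                not np.allclose(np.diag(C), 1.0):
            raise ValueError("cross_trait_null_corr must be a K×K correlation matrix")
        if np.linalg.eigvalsh(C).min() < -1e-10:
            raise ValueError("cross_trait_null_corr must be positive semi-definite")
        self.cross_trait_null_corr = C
        if not 0.0 <= self.within_block_rho < 1.0:
            raise ValueError("within_block_rho must be in [0,1)")
        if self.is_binary is None:
            self.is_binary = {t: False for t in self.trait_labels}
        for locus in self.planted_loci:
            if not 0 <= locus.index < self.n_variants:
                raise ValueError(f"planted variant index {locus.index} outside genome")
            unknown = set(locus.traits) - set(self.trait_labels)
            if unknown:
                raise ValueError(f"planted locus names unknown traits {unknown}")
            if not np.isfinite(locus.noncentrality):
                raise ValueError("non-centrality must be finite")


@dataclass
class TruthTable:
    """What was planted, keyed to emitted variant ids."""

    loci: list = field(default_factory=list)   # dicts: variant_id(s), traits, nc, shared
    qtls: list = field(default_factory=list)   # dicts: gene, tissue, variant_id, colocalized

    def to_frames(self):
        return pd.DataFrame(self.loci), pd.DataFrame(self.qtls)

    def write(self, path):
        loci_df, qtl_df = self.to_frames()
        loci_df.to_csv(Path(path).with_suffix(".loci.tsv"), sep="\t", index=False)
        if len(qtl_df):
            qtl_df.to_csv(Path(path).with_suffix(".qtl.tsv"), sep="\t", index=False)


def _block_sizes(n_variants, n_blocks):
    base = n_variants // n_blocks
    if base < 1:
        raise ValueError("more blocks than variants")
    sizes = [base] * n_blocks
    sizes[-1] += n_variants - base * n_blocks
    return sizes


def make_ld_matrix(block_sizes, rho: float) -> np.ndarray:
    """Block-diagonal AR(1) correlation matrix: rho^|i−j| within each block."""
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must be in [0,1)")
    n = int(np.sum(block_sizes))
    out = np.zeros((n, n))
    at = 0
    for m in block_sizes:
        out[at:at + m, at:at + m] = toeplitz(rho ** np.arange(m))
        at += m
    return out


def ld_table_from_blocks(ids, block_sizes, rho, min_r2: float = 0.01) -> LDTable:
    """Pairwise LD table matching the AR(1) block structure.

    Cross-block pairs are omitted (r² = 0 falls back to the table default);
    within-block pairs below ``min_r2`` are likewise left implicit to keep
    the table small.
    """
    table = LDTable(default=0.0)
    if rho == 0.0:
        return table
    max_d = int(np.floor(np.log(min_r2) / (2.0 * np.log(rho)))) if rho > 0 else 0
    at = 0
    for m in block_sizes:
        for i in range(m):
            for d in range(1, min(max_d, m - 1 - i) + 1):
                r = rho ** d
                table.add(ids[at + i], ids[at + i + d], r * r, r=r)
        at += m
    return table


def _ld_frame(table: LDTable, id_pos: dict, chrom: str) -> pd.DataFrame:
    rows = []
    for (a, b), r2 in sorted(table._r2.items()):
        rows.append((chrom, id_pos[a], a, chrom, id_pos[b], b, r2, table.r(a, b)))
    return pd.DataFrame(rows, columns=["CHR_A", "BP_A", "SNP_A",
                                       "CHR_B", "BP_B", "SNP_B", "R2", "R"])


@dataclass
class SimulatedPanel:
    """Generator output: per-trait scans, LD table, and the planted truth."""

    config: SimConfig
    scans: list
    ld: LDTable
    truth: TruthTable
    ids: np.ndarray
    positions: np.ndarray
    block_sizes: list
    z: np.ndarray          # (n_variants, K) — convenience copy of the scan z's

    def block_of(self, index: int):
        """(block number, start, end) global-index bounds of a variant's block."""
        at = 0
        for b, m in enumerate(self.block_sizes):
            if index < at + m:
                return b, at, at + m
            at += m
        raise IndexError(index)

    def write(self, outdir):
        """Emit the consumable files: .ma per trait, LD table, truth table."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for scan in self.scans:
            p = outdir / f"{scan.trait}.sumstats.tsv"
            out = scan.df.rename(columns={
                "variant_id": "SNP", "chrom": "chr", "pos": "pos",
                "effect_allele": "A1", "other_allele": "A2", "eaf": "freq",
                "beta": "b", "se": "se", "p": "p", "n": "N", "z": "z"})
            out.to_csv(p, sep="\t", index=False)
            paths[scan.trait] = p
        ld_path = outdir / "ld_pairs.tsv"
        id_pos = dict(zip(self.ids, self.positions))
        _ld_frame(self.ld, id_pos, self.config.chrom).to_csv(ld_path, sep="\t", index=False)
        self.truth.write(outdir / "truth.tsv")
        return paths, ld_path


def simulate_panel(config: SimConfig) -> SimulatedPanel:
    """Draw one panel of per-trait summary statistics under the config.

    Per trait, Z = Σ·λ_t + ε_t with Σ the block AR(1) LD matrix, λ_t the
    planted non-centralities, and noise separable across (LD blocks) ×
    (cross-trait correlation).
    """
    rng = np.random.default_rng(config.seed)
    K = len(config.trait_labels)
    n = config.n_variants
    sizes = _block_sizes(n, config.n_blocks)
    rho = config.within_block_rho

    ids = np.array([f"snp{i:06d}" for i in range(n)], dtype=object)
    positions = (1 + np.arange(n) * config.spacing_bp).astype(int)
    maf = rng.uniform(*config.maf_range, size=n)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n)

    # planted means on the z scale, smeared over LD neighbors within the block
    lam = np.zeros((n, K))
    truth = TruthTable()
    tindex = {t: k for k, t in enumerate(config.trait_labels)}
    for locus in config.planted_loci:
        b = np.searchsorted(np.cumsum(sizes), locus.index, side="right")
        start = int(np.sum(sizes[:b]))
        end = start + sizes[b]
        causal_ids = {}
        for j, trait in enumerate(locus.traits):
            cidx = locus.index if locus.shared else locus.index + j
            if not start <= cidx < end:
                raise ValueError(
                    f"planted causal variant {cidx} collides with block boundary "
                    f"[{start},{end}) — move the locus or enlarge the block")
            lam[cidx, tindex[trait]] += locus.noncentrality
            causal_ids[trait] = ids[cidx]
        truth.loci.append({
            "variant_ids": ",".join(dict.fromkeys(causal_ids.values())),
            "traits": ",".join(locus.traits),
            "noncentrality": locus.noncentrality,
            "shared": locus.shared,
            "chrom": config.chrom,
            "pos": int(positions[locus.index]),
            "block": int(b),
        })

    L_C = cholesky(config.cross_trait_null_corr + 1e-12 * np.eye(K), lower=True)
    z = np.empty((n, K))
    at = 0
    for m in sizes:
        Sigma = toeplitz(rho ** np.arange(m))
        L_b = cholesky(Sigma, lower=True)
        noise = L_b @ rng.standard_normal((m, K)) @ L_C.T
        z[at:at + m] = Sigma @ lam[at:at + m] + noise
        at += m

    scans = []
    for k, trait in enumerate(config.trait_labels):
        n_eff = float(config.n_per_trait[trait])
        se = 1.0 / np.sqrt(2.0 * n_eff * maf * (1.0 - maf))
        df = pd.DataFrame({
            "variant_id": ids,
            "chrom": config.chrom,
            "pos": positions,
            "effect_allele": [_ALLELE_PAIRS[i][0] for i in pair_idx],
            "other_allele": [_ALLELE_PAIRS[i][1] for i in pair_idx],
            "eaf": maf,
            "beta": z[:, k] * se,
            "se": se,
            "z": z[:, k],
            "p": z_to_p(z[:, k]),
            "n": n_eff,
        })
        scans.append(TraitScan(trait=trait, is_binary=bool(config.is_binary.get(trait, False)),
                               n_total=n_eff, df=df))

    ld = ld_table_from_blocks(ids, sizes, rho)
    return SimulatedPanel(config=config, scans=scans, ld=ld, truth=truth,
                          ids=ids, positions=positions, block_sizes=sizes, z=z)


def simulate_molecular_qtl(panel: SimulatedPanel, locus_index: int,
                           colocalized: bool, effect_size: float = 6.0,
                           gene: str = "GENE1", tissue: str = "tissue",
                           n_samples: float = 600.0, seed: int = 0,
                           r2_max_distinct: float = 0.1):
    """A molecular-QTL association vector over one planted locus's block.

    ``colocalized`` plants the QTL effect on the same causal variant as the
    GWAS locus; otherwise on a variant in the same block with r² below
    ``r2_max_distinct`` to it. Returns (AssocVector, significant-pair
    DataFrame, truth entry).
    """
    rng = np.random.default_rng(seed)
    cfg = panel.config
    entry = panel.truth.loci[locus_index]
    causal_id = entry["variant_ids"].split(",")[0]
    gidx = int(np.where(panel.ids == causal_id)[0][0])
    _, start, end = panel.block_of(gidx)
    m = end - start
    rho = cfg.within_block_rho

    if colocalized:
        qidx = gidx
    else:
        if rho > 0:
            min_d = int(np.ceil(np.log(r2_max_distinct) / (2.0 * np.log(rho)))) + 1
        else:
            min_d = 1
        candidates = [i for i in range(start, end) if abs(i - gidx) >= min_d]
        if not candidates:
            raise ValueError("no variant with r² below the cutoff in this block; "
                             "use a larger block or weaker LD")
        qidx = candidates[0]

    Sigma = toeplitz(rho ** np.arange(m))
    lam = np.zeros(m)
    lam[qidx - start] = effect_size
    L_b = cholesky(Sigma, lower=True)
    zq = Sigma @ lam + L_b @ rng.standard_normal(m)

    ids = panel.ids[start:end]
    maf = np.clip(rng.uniform(*cfg.maf_range, size=m), 1e-3, 0.5)
    se = 1.0 / np.sqrt(2.0 * n_samples * maf * (1.0 - maf))
    vec = AssocVector(label=f"{gene}@{tissue}", ids=ids, beta=zq * se, se=se,
                      trait_kind="quantitative",
                      chrom=np.full(m, cfg.chrom, dtype=object),
                      pos=panel.positions[start:end])
    pairs = pd.DataFrame({"gene": gene, "tissue": tissue, "variant_id": ids,
                          "beta": vec.beta, "se": vec.se})
    truth_entry = {"gene": gene, "tissue": tissue, "variant_id": panel.ids[qidx],
                   "colocalized": bool(colocalized), "gwas_variant_id": causal_id}
    panel.truth.qtls.append(truth_entry)
    return vec, pairs, truth_entry
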