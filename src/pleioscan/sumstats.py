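"""Reading, validation and harmonization of GWAS summary statistics.

Per-trait association tables (GCTA-COJO ``.ma``-style dialect by default,
remappable through a column-name dictionary) are loaded into
:class:`TraitScan` objects, then aligned across traits into a
:class:`HarmonizedPanel`: the variant intersection keyed by
(chromosome, position, unordered allele pair), with every trait's Z-score
re-oriented to a single effect allele per variant. Strand-ambiguous variants
(A/T, C/G) are dropped outright — without frequency information their
orientation cannot be resolved safely and a silent sign error would corrupt
every downstream multivariate statistic.

Also provides the pairwise LD table (PLINK ``--r2`` dialect or a minimal
three/four-column one) and the known-association catalog used by the
novelty filter.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .significance import z_to_p

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_DIALECT",
    "VariantRecord",
    "TraitScan",
    "HarmonizedPanel",
    "LDTable",
    "KnownAssociation",
    "effective_sample_size",
    "read_sumstats",
    "write_sumstats",
    "harmonize_panel",
    "read_ld_table",
    "read_catalog",
]

#: Default header map: GCTA-COJO ``.ma`` columns plus chromosome/position.
DEFAULT_DIALECT = {
    "variant_id": "SNP",
    "chrom": "chr",
    "pos": "pos",
    "effect_allele": "A1",
    "other_allele": "A2",
    "eaf": "freq",
    "beta": "b",
    "se": "se",
    "p": "p",
    "n": "N",
    "z": "z",
}

_CANONICAL = ["variant_id", "chrom", "pos", "effect_allele", "other_allele",
              "eaf", "beta", "se", "z", "p", "n"]

_AMBIGUOUS_PAIRS = {frozenset({"A", "T"}), frozenset({"C", "G"})}

#: Relative tolerance for the z ≈ beta/se and p ≈ tail(z) invariants.
Z_BETA_RTOL = 1e-6
P_Z_RTOL = 1e-3


@dataclass(frozen=True)
class VariantRecord:
    """One variant's harmonized single-trait summary statistics."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    z: float
    p: float
    n: float

    def key(self):
        return variant_key(self.chrom, self.pos, self.effect_allele, self.other_allele)


def variant_key(chrom, pos, a1, a2):
    """Orientation-free variant key: (chrom, pos, sorted allele pair).

    rsIDs are carried as labels only; the genomic key is robust to rsID
    version drift and to effect/other allele swaps between studies.
    """
    return (str(chrom), int(pos), tuple(sorted((str(a1).upper(), str(a2).upper()))))


def effective_sample_size(n_cases: float, n_controls: float) -> float:
    """Case-control effective N: 4 / (1/N_cases + 1/N_controls)."""
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("case and control counts must be positive")
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)


@dataclass
class ParseReport:
    """Bookkeeping for rows rejected or repaired while reading a table."""

    n_rows: int = 0
    n_rejected: int = 0
    n_duplicates: int = 0
    n_p_recomputed: int = 0
    n_p_inconsistent: int = 0
    reasons: dict = field(default_factory=lambda: defaultdict(int))


@dataclass
class TraitScan:
    """One trait's harmonized per-variant summary statistics."""

    trait: str
    is_binary: bool
    n_total: float
    df: pd.DataFrame
    parse_report: ParseReport = field(default_factory=ParseReport)

    def __post_init__(self):
        self.df = self.df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    def __len__(self):
        return len(self.df)

    @property
    def variants(self):
        """Iterate rows as :class:`VariantRecord` objects."""
        for row in self.df.itertuples(index=False):
            yield VariantRecord(
                variant_id=row.variant_id, chrom=row.chrom, pos=int(row.pos),
                effect_allele=row.effect_allele, other_allele=row.other_allele,
                eaf=float(row.eaf), beta=float(row.beta), se=float(row.se),
                z=float(row.z), p=float(row.p), n=float(row.n),
            )


def read_sumstats(path, dialect=None, trait="trait", is_binary=False,
                  n_cases=None, n_controls=None, n_total=None) -> TraitScan:
    """Load one trait's summary statistics into a :class:`TraitScan`.

    The file must provide at least variant id, chromosome, position and both
    alleles, plus either (beta, se) or z, plus a sample size (per-variant
    column, explicit ``n_total``, or case/control counts for binary traits,
    combined as the effective sample size 4/(1/cases + 1/controls)).

    Missing z is filled as beta/se; missing p from the two-sided normal tail
    of z. Rows with non-positive se (or no usable effect) are rejected and
    counted in the parse report. When both z and p are present but disagree
    beyond tolerance, z wins and p is recomputed with a logged warning.
    """
    dmap = dict(DEFAULT_DIALECT)
    if dialect:
        dmap.update(dialect)
    # sniff the delimiter: tab-delimited files may carry empty fields,
    # which a greedy whitespace split would silently collapse
    raw = pd.read_csv(path, sep=None, engine="python")
    report = ParseReport(n_rows=len(raw))

    mandatory = ["variant_id", "chrom", "pos", "effect_allele", "other_allele"]
    for col in mandatory:
        if dmap[col] not in raw.columns:
            raise ValueError(f"missing mandatory column {dmap[col]!r} in {path}")
    has = {k: dmap[k] in raw.columns for k in _CANONICAL}
    if not (has["z"] or (has["beta"] and has["se"])):
        raise ValueError(f"{path}: need either a z column or beta+se columns")

    df = pd.DataFrame({k: raw[dmap[k]] for k in _CANONICAL if has[k]})
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    for col in ("eaf", "beta", "se", "z", "p", "n"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")

    bad = df["pos"].isna()
    if "se" in df.columns:
        se_bad = df["se"].notna() & (df["se"] <= 0)
        # a row survives a bad se only if it carries a direct z
        if "z" in df.columns:
            se_bad &= df["z"].isna()
        report.reasons["nonpositive_se"] += int(se_bad.sum())
        bad |= se_bad
        if "z" not in df.columns:
            bad |= df["se"].isna() | df["beta"].isna()
    report.n_rejected = int(bad.sum())
    df = df.loc[~bad].copy()

    if "z" not in df.columns:
        df["z"] = df["beta"] / df["se"]
    else:
        fill = df["z"].isna()
        if fill.any() and "beta" in df.columns and "se" in df.columns:
            df.loc[fill, "z"] = df.loc[fill, "beta"] / df.loc[fill, "se"]
        still = df["z"].isna()
        report.n_rejected += int(still.sum())
        df = df.loc[~still].copy()
    if "beta" not in df.columns:
        df["beta"] = df["z"]  # unit-variance convention when no effect scale given
        df["se"] = 1.0
    if "se" not in df.columns:
        df["se"] = np.nan

    p_from_z = z_to_p(df["z"].to_numpy())
    if "p" not in df.columns:
        df["p"] = p_from_z
        report.n_p_recomputed = len(df)
    else:
        missing = df["p"].isna()
        df.loc[missing, "p"] = p_from_z[missing.to_numpy()]
        report.n_p_recomputed = int(missing.sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(df["p"].to_numpy() - p_from_z) / np.maximum(p_from_z, 1e-300)
        clash = (~missing.to_numpy()) & (rel > P_Z_RTOL)
        if clash.any():
            report.n_p_inconsistent = int(clash.sum())
            logger.warning("%s: %d rows with p inconsistent with z; z wins",
                           path, report.n_p_inconsistent)
            df.loc[clash, "p"] = p_from_z[clash]

    if n_total is None:
        if is_binary and n_cases is not None and n_controls is not None:
            n_total = effective_sample_size(n_cases, n_controls)
        elif "n" in df.columns:
            n_total = float(df["n"].median())
    if "n" not in df.columns:
        if n_total is None:
            raise ValueError(f"{path}: no sample-size column and no n_total/case-control config")
        df["n"] = float(n_total)
    else:
        df["n"] = df["n"].fillna(float(n_total) if n_total is not None else np.nan)
    if "eaf" not in df.columns:
        df["eaf"] = np.nan

    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
    df["variant_id"] = df["variant_id"].astype(str)
    dup = df["variant_id"].duplicated()
    report.n_duplicates = int(dup.sum())
    if report.n_duplicates:
        logger.warning("%s: dropped %d duplicate variant ids", path, report.n_duplicates)
        df = df.loc[~dup]

    if report.n_rejected:
        logger.info("%s: rejected %d malformed rows", path, report.n_rejected)
    df = df[_CANONICAL].reset_index(drop=True)
    return TraitScan(trait=trait, is_binary=is_binary,
                     n_total=float(n_total) if n_total is not None else float(df["n"].median()),
                     df=df, parse_report=report)


def write_sumstats(scan: TraitScan, path, dialect=None):
    """Write a TraitScan back to disk in the (possibly remapped) dialect."""
    dmap = dict(DEFAULT_DIALECT)
    if dialect:
        dmap.update(dialect)
    out = scan.df.rename(columns={k: v for k, v in dmap.items() if k in scan.df.columns})
    out.to_csv(path, sep="\t", index=False)


@dataclass
class HarmonizedPanel:
    """Variant-by-trait Z matrix aligned to one effect allele per variant."""

    traits: list
    index: pd.DataFrame  # variant_id, chrom, pos, effect_allele, other_allele
    z: np.ndarray        # (n_variants, K)
    n: np.ndarray        # (n_variants, K)
    eaf: np.ndarray
    n_dropped_ambiguous: int = 0

    def __post_init__(self):
        if np.isnan(self.z).any():
            raise ValueError("harmonized z matrix must have no missing cells")

    @property
    def n_variants(self):
        return len(self.index)

    def trait_index(self, trait: str) -> int:
        return self.traits.index(trait)


def _is_ambiguous(a1, a2):
    return frozenset({a1, a2}) in _AMBIGUOUS_PAIRS


def harmonize_panel(scans) -> HarmonizedPanel:
    """Intersect scans on the genomic variant key and align Z-score signs.

    The first scan's (effect, other) orientation is the reference; any scan
    with the alleles swapped at a variant has its z sign flipped there.
    Variants with a strand-ambiguous allele pair are dropped; variants whose
    allele pairs disagree across scans fall out of the key intersection.
    Applying the function to an already-harmonized set of scans is a no-op.
    """
    scans = list(scans)
    if len(scans) < 2:
        raise ValueError("harmonization needs at least two scans")
    keyed = []
    n_ambig = 0
    for scan in scans:
        df = scan.df
        amb = [_is_ambiguous(a1, a2) for a1, a2 in zip(df["effect_allele"], df["other_allele"])]
        amb = np.asarray(amb)
        n_ambig += int(amb.sum())
        df = df.loc[~amb]
        keys = [variant_key(c, p, a1, a2) for c, p, a1, a2 in
                zip(df["chrom"], df["pos"], df["effect_allele"], df["other_allele"])]
        keyed.append(dict(zip(keys, df.itertuples(index=False))))
    if n_ambig:
        logger.info("harmonize: dropped %d strand-ambiguous variant rows", n_ambig)

    common = set(keyed[0])
    for d in keyed[1:]:
        common &= set(d)
    if not common:
        sizes = [(len(set(a) & set(b)), i, j)
                 for i, a in enumerate(keyed) for j, b in enumerate(keyed) if i < j]
        _, i, j = min(sizes)
        raise ValueError(
            f"no shared variants across scans; most disjoint pair: "
            f"{scans[i].trait!r} and {scans[j].trait!r}")

    ref = keyed[0]
    order = sorted(common, key=lambda k: (k[0], k[1]))
    K = len(scans)
    z = np.empty((len(order), K))
    n = np.empty((len(order), K))
    rows = []
    for vi, key in enumerate(order):
        r0 = ref[key]
        rows.append((r0.variant_id, key[0], int(key[1]), r0.effect_allele, r0.other_allele,
                     float(r0.eaf)))
        for ti, d in enumerate(keyed):
            r = d[key]
            flip = (r.effect_allele != r0.effect_allele)
            z[vi, ti] = -r.z if flip else r.z
            n[vi, ti] = r.n
    index = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos",
                                        "effect_allele", "other_allele", "eaf"])
    return HarmonizedPanel(
        traits=[s.trait for s in scans], index=index.drop(columns="eaf"),
        z=z, n=n, eaf=index["eaf"].to_numpy(), n_dropped_ambiguous=n_ambig)


class LDTable:
    """Symmetric variant-pair → r² lookup with an optional signed r.

    Absent pairs return a configurable default (0.0); a variant with itself
    returns 1.0 implicitly. When only r² is known, the signed correlation is
    reported as +sqrt(r²) — callers needing true signs must load them.
    """

    def __init__(self, default: float = 0.0):
        self.default = default
        self._r2 = {}
        self._r = {}
        self._adj = defaultdict(dict)

    @staticmethod
    def _key(a, b):
        return (a, b) if a <= b else (b, a)

    def add(self, a, b, r2, r=None):
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"r2 out of [0,1] for pair ({a},{b}): {r2}")
        k = self._key(str(a), str(b))
        self._r2[k] = float(r2)
        if r is not None:
            if abs(r) > 1.0 + 1e-12:
                raise ValueError(f"|r| > 1 for pair ({a},{b}): {r}")
            self._r[k] = float(r)
        self._adj[str(a)][str(b)] = float(r2)
        self._adj[str(b)][str(a)] = float(r2)

    def r2(self, a, b):
        a, b = str(a), str(b)
        if a == b:
            return 1.0
        return self._r2.get(self._key(a, b), self.default)

    def r(self, a, b):
        a, b = str(a), str(b)
        if a == b:
            return 1.0
        k = self._key(a, b)
        if k in self._r:
            return self._r[k]
        return float(np.sqrt(self._r2.get(k, self.default)))

    def neighbors(self, a):
        """All partners of ``a`` with a stored r², as a dict id → r²."""
        return self._adj.get(str(a), {})

    def __len__(self):
        return len(self._r2)


def read_ld_table(path, default: float = 0.0) -> LDTable:
    """Load a pairwise LD table (PLINK ``--r2`` dialect or minimal columns).

    Accepted layouts: PLINK (CHR_A BP_A SNP_A CHR_B BP_B SNP_B R2 [R]) or a
    minimal (id1, id2, r2[, r]) table. r² values outside [0,1] abort the load
    with the offending row number.
    """
    df = pd.read_csv(path, sep=r"\s+|\t", engine="python")
    cols = {c.upper(): c for c in df.columns}
    table = LDTable(default=default)
    if "SNP_A" in cols and "SNP_B" in cols and "R2" in cols:
        a_col, b_col, r2_col = cols["SNP_A"], cols["SNP_B"], cols["R2"]
        r_col = cols.get("R")
    else:
        if df.shape[1] < 3:
            raise ValueError(f"{path}: LD table needs at least 3 columns")
        a_col, b_col, r2_col = df.columns[:3]
        r_col = df.columns[3] if df.shape[1] > 3 else None
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        r2 = float(getattr(row, r2_col))
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"{path}:{i}: r2 out of [0,1]: {r2}")
        r = float(getattr(row, r_col)) if r_col is not None else None
        table.add(str(getattr(row, a_col)), str(getattr(row, b_col)), r2, r=r)
    return table


@dataclass(frozen=True)
class KnownAssociation:
    """One previously reported trait association from a local catalog table."""

    trait: str
    variant_id: str
    chrom: str
    pos: int
    source: str = "catalog"

    def __post_init__(self):
        if self.pos <= 0:
            raise ValueError("catalog position must be positive")


def read_catalog(path):
    """Read a tab-delimited known-association catalog (trait, rsid, chrom, pos).

    Rows without a usable genomic position are dropped and counted; trait
    labels are preserved verbatim for exact-string matching against scans.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = ["trait", "rsid", "chrom", "pos"]
    for col in need:
        if col not in df.columns:
            raise ValueError(f"{path}: catalog needs columns {need}")
    pos = pd.to_numeric(df["pos"], errors="coerce")
    dropped = int((pos.isna() | (pos <= 0)).sum())
    if dropped:
        logger.info("%s: dropped %d catalog rows without a mapped position", path, dropped)
    keep = df.loc[pos.notna() & (pos > 0)]
    out = [KnownAssociation(trait=r.trait, variant_id=r.rsid, chrom=str(r.chrom),
                            pos=int(float(r.pos)),
                            source=getattr(r, "source", "catalog") or "catalog")
           for r in keep.itertuples(index=False)]
    read_catalog.last_dropped = dropped
    return out
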