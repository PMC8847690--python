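"""Sentinel selection, locus definition, and the pleiotropy/novelty filters.

A locus is the genomic region around a sentinel variant: every variant
within 1 Mb plus any variant in LD (r² > 0.2) with the sentinel regardless
of distance. Sentinels are chosen greedily by ascending multivariate
p-value, each claiming its locus so that later candidates inside it are
absorbed rather than reported twice. A candidate pleiotropic locus must be
at least nominally associated with every scanned trait (p < 5e-3), not
genome-wide significant for any single trait (p > 5e-8), outside the
extended HLA region, and unreported in the known-association catalog for
any scanned trait (no member within 500 kb of, or in r² > 0.2 with, a
catalog variant). Loci from different scans are collapsed into independent
loci by single-linkage clustering of sentinels within 1 Mb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .multitrait import MultiTraitResult
from .sumstats import KnownAssociation, LDTable

__all__ = [
    "HLA_REGION",
    "Locus",
    "find_sentinels",
    "define_locus",
    "discover_loci",
    "apply_pleiotropy_filters",
    "apply_novelty_filter",
    "merge_independent_loci",
]

# Extended MHC bounds on GRCh37; conventional exclusion window.
HLA_REGION = ("6", 25_000_000, 34_000_000)


@dataclass
class Locus:
    """Sentinel variant plus member variants and filter verdicts."""

    scan: object                 # ScanDefinition (duck-typed: .traits, .label)
    sentinel_id: str
    chrom: str
    pos: int
    p_multi: float
    members: set = field(default_factory=set)
    window: tuple = None         # (chrom, start, end), 1-based inclusive
    verdicts: dict = field(default_factory=dict)
    tier: str = "none"           # none | nominal | experiment_wide
    sentinel_row: object = None  # pandas row for the sentinel, if available

    def passes_all(self, names=("pleiotropy_pass", "not_gw_single",
                                "outside_hla", "novel_vs_catalog")) -> bool:
        return all(self.verdicts.get(n, False) for n in names)


def define_locus(sentinel_id: str, result: MultiTraitResult, ld: LDTable,
                 window_bp: int = 1_000_000, r2_min: float = 0.2) -> Locus:
    """Build the locus around a sentinel: 1 Mb window plus LD partners."""
    df = result.df
    srow = df.loc[df["variant_id"] == sentinel_id]
    if srow.empty:
        raise KeyError(f"sentinel {sentinel_id!r} not in scan result")
    srow = srow.iloc[0]
    chrom, pos = str(srow["chrom"]), int(srow["pos"])
    in_window = (df["chrom"].astype(str) == chrom) & \
        ((df["pos"] - pos).abs() <= window_bp)
    members = set(df.loc[in_window, "variant_id"])
    known_ids = set(df["variant_id"])
    for other, r2 in ld.neighbors(sentinel_id).items():
        if r2 > r2_min and other in known_ids:
            members.add(other)
    mpos = df.loc[df["variant_id"].isin(members) &
                  (df["chrom"].astype(str) == chrom), "pos"]
    window = (chrom, int(mpos.min()), int(mpos.max()))
    return Locus(scan=result.scan, sentinel_id=sentinel_id, chrom=chrom, pos=pos,
                 p_multi=float(srow["p_multi"]), members=members, window=window,
                 sentinel_row=srow)


def find_sentinels(result: MultiTraitResult, p_threshold: float, ld: LDTable,
                   window_bp: int = 1_000_000, r2_min: float = 0.2):
    """Greedy sentinel selection by ascending p_multi.

    Repeatedly takes the most significant variant below threshold that is
    not already a member of a previously claimed locus; ties at equal
    p_multi break on (chrom, pos). Returns the ordered sentinel ids.
    """
    return [loc.sentinel_id for loc in
            discover_loci(result, p_threshold, ld, window_bp, r2_min)]


def discover_loci(result: MultiTraitResult, p_threshold: float, ld: LDTable,
                  window_bp: int = 1_000_000, r2_min: float = 0.2):
    """Greedy sentinel selection returning the claimed loci themselves."""
    df = result.df
    sig = df.loc[df["p_multi"] < p_threshold]
    order = sig.sort_values(["p_multi", "chrom", "pos"], kind="mergesort")
    claimed = set()
    loci = []
    for row in order.itertuples(index=False):
        if row.variant_id in claimed:
            continue
        locus = define_locus(row.variant_id, result, ld, window_bp, r2_min)
        claimed |= locus.members
        loci.append(locus)
    return loci


def apply_pleiotropy_filters(locus: Locus, single_trait_p: dict,
                             nominal_p: float = 5e-3, gw_p: float = 5e-8,
                             hla=HLA_REGION) -> Locus:
    """Set the pleiotropy, single-trait-novelty and HLA verdicts in place.

    ``single_trait_p`` maps each scan trait to the sentinel's single-trait
    p-value. Inequalities are strict, exactly as conventionally quoted:
    all p < 5e-3 (pleiotropy), all p > 5e-8 (not already genome-wide
    significant for one trait alone).
    """
    ps = []
    for trait in locus.scan.traits:
        if trait not in single_trait_p:
            raise ValueError(f"missing single-trait p for {trait!r} at {locus.sentinel_id}")
        ps.append(float(single_trait_p[trait]))
    locus.verdicts["pleiotropy_pass"] = all(p < nominal_p for p in ps)
    locus.verdicts["not_gw_single"] = all(p > gw_p for p in ps)
    hchrom, hstart, hend = hla
    wchrom, wstart, wend = locus.window
    intersects = (str(wchrom) == str(hchrom)) and not (wend < hstart or wstart > hend)
    locus.verdicts["outside_hla"] = not intersects
    return locus


def apply_novelty_filter(locus: Locus, catalog, ld: LDTable,
                         member_pos: dict = None,
                         proximity_bp: int = 500_000, r2_min: float = 0.2) -> Locus:
    """Catalog screen: the locus is novel iff no member variant is within
    ``proximity_bp`` of, or in r² > ``r2_min`` with, a catalog entry reported
    for one of the scan's traits. Trait matching is exact-string.
    """
    scan_traits = set(locus.scan.traits)
    relevant = [e for e in catalog if e.trait in scan_traits]
    novel = True
    for entry in relevant:
        for member in locus.members:
            if member_pos is not None and member in member_pos:
                mchrom, mpos = member_pos[member]
                if str(mchrom) == str(entry.chrom) and abs(mpos - entry.pos) <= proximity_bp:
                    novel = False
                    break
            if ld.r2(member, entry.variant_id) > r2_min and \
                    ld.neighbors(member).get(entry.variant_id) is not None:
                novel = False
                break
            if member == entry.variant_id:
                novel = False
                break
        if not novel:
            break
    locus.verdicts["novel_vs_catalog"] = novel
    return locus


def merge_independent_loci(loci, distance_bp: int = 1_000_000):
    """Single-linkage clustering of sentinels within ``distance_bp``.

    Accepts :class:`Locus` objects or anything with ``sentinel_id``,
    ``chrom``, ``pos`` and ``p_multi`` attributes. Identical sentinel ids
    collapse first; sentinels on the same chromosome within the distance
    merge transitively. Returns a list of clusters (lists of the input
    objects), each ordered with the representative (lowest p_multi, ties by
    (chrom, pos)) first; clusters are sorted by representative position.
    """
    items = list(loci)
    if not items:
        return []
    # collapse identical sentinels, then sort by genomic position for chaining
    order = sorted(range(len(items)),
                   key=lambda i: (str(items[i].chrom), int(items[i].pos),
                                  items[i].sentinel_id))
    parent = list(range(len(items)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    by_id = {}
    for i in order:
        sid = items[i].sentinel_id
        if sid in by_id:
            union(by_id[sid], i)
        else:
            by_id[sid] = i
    prev = None
    for i in order:
        if prev is not None and str(items[i].chrom) == str(items[prev].chrom) \
                and int(items[i].pos) - int(items[prev].pos) <= distance_bp:
            union(prev, i)
        prev = i

    groups = {}
    for i in range(len(items)):
        groups.setdefault(find(i), []).append(items[i])
    clusters = []
    for members in groups.values():
        members.sort(key=lambda it: (float(it.p_multi), str(it.chrom), int(it.pos)))
        clusters.append(members)
    clusters.sort(key=lambda c: (str(c[0].chrom), int(c[0].pos)))
    return clusters
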