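"""Bayesian colocalization of association signals via approximate Bayes factors.

For each variant the evidence for association is summarized by the Wakefield
approximate Bayes factor: with V = se², W = prior_sd², r = W/(W+V) and
z = beta/se,

    log ABF = ½·log(1 − r) + r·z²/2 .

Assuming at most one causal variant per trait in the window, the posterior
over sharing hypotheses is a prior-weighted sum of per-variant ABF products:
for two traits the classic five hypotheses H0 (no association) … H3 (both
associated, distinct variants), H4 (shared causal variant); for three traits
all 15 configurations (each trait null or associated, associated traits
partitioned among shared causal variants). The decision statistic is the
conditional probability of colocalization — the probability that all traits
share one causal variant given every trait has a signal, PP4/(PP3+PP4) in
the pairwise case — with verdict bands colocalized (≥0.8), borderline
(0.5–0.8) and distinct.

Allelic heterogeneity violates the single-causal-variant assumption; the
approximate conditional adjustment z' = (z − r·z_c)/√(1−r²) removes a
secondary signal using LD alone so colocalization can be re-run.

All hypothesis sums are evaluated with log-sum-exp; |z| up to 40 is safe.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .sumstats import LDTable

__all__ = [
    "AssocVector",
    "ColocPriors",
    "ColocResult",
    "wakefield_log_abf",
    "coloc_pairwise",
    "moloc_trivariate",
    "conditional_coloc_probability",
    "approx_conditional_z",
    "condition_assoc",
    "detect_secondary_signal",
    "qtl_colocalize",
    "read_qtl_table",
    "verdict_from_probability",
]


@dataclass
class AssocVector:
    """One trait's effect estimates over a shared variant index."""

    label: str
    ids: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    trait_kind: str = "quantitative"  # quantitative | case_control
    chrom: np.ndarray = None
    pos: np.ndarray = None

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=object)
        self.beta = np.asarray(self.beta, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if np.any(self.se <= 0):
            raise ValueError(f"{self.label}: all standard errors must be positive")
        if self.pos is not None:
            self.pos = np.asarray(self.pos, dtype=int)

    @classmethod
    def from_z(cls, label, ids, z, trait_kind="quantitative", **kw):
        """Unit-variance convention: beta = z, se = 1."""
        z = np.asarray(z, dtype=float)
        return cls(label=label, ids=ids, beta=z, se=np.ones_like(z),
                   trait_kind=trait_kind, **kw)

    @property
    def z(self):
        return self.beta / self.se

    def restrict_window(self, chrom, start, end):
        """Subset to variants with start ≤ pos ≤ end (boundaries included)."""
        if self.pos is None:
            raise ValueError("AssocVector has no positions; cannot window")
        mask = (np.asarray(self.chrom, dtype=object) == str(chrom)) & \
            (self.pos >= start) & (self.pos <= end)
        return AssocVector(label=self.label, ids=self.ids[mask], beta=self.beta[mask],
                           se=self.se[mask], trait_kind=self.trait_kind,
                           chrom=np.asarray(self.chrom, dtype=object)[mask],
                           pos=self.pos[mask])


@dataclass(frozen=True)
class ColocPriors:
    """Per-variant prior probabilities for the sharing configurations.

    Pairwise: p1/p2 (trait-specific causal variant) and p12 (shared).
    Trivariate: tri_p1/tri_p2/tri_p3 for a variant causal for one, two or
    all three traits. Effect-scale prior SDs: 0.15 for quantitative traits,
    0.2 on the log-odds scale for case-control traits.
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    tri_p1: float = 1e-4
    tri_p2: float = 1e-6
    tri_p3: float = 1e-7
    prior_sd_quant: float = 0.15
    prior_sd_cc: float = 0.2

    def __post_init__(self):
        for name in ("p1", "p2", "p12", "tri_p1", "tri_p2", "tri_p3"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"prior {name} must be in (0,1), got {v}")
        if self.p12 > min(self.p1, self.p2):
            warnings.warn("p12 exceeds min(p1,p2); shared causality favored a priori",
                          stacklevel=2)

    def prior_sd(self, trait_kind: str) -> float:
        return self.prior_sd_cc if trait_kind == "case_control" else self.prior_sd_quant


@dataclass
class ColocResult:
    """Posterior over sharing hypotheses plus the conditional probability."""

    pp: dict
    conditional_prob: float          # None when undefined (both hypotheses ~0)
    verdict: str                     # colocalized | borderline | distinct
    labels: tuple = ()
    window: tuple = None
    flagged: bool = False
    n_variants: int = 0
    conditioned_on: str = None

    def __post_init__(self):
        total = sum(self.pp.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"posterior probabilities sum to {total}, not 1")


def wakefield_log_abf(beta, se, prior_sd):
    """Log approximate Bayes factor for association at one variant."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    if prior_sd < 0:
        raise ValueError("prior_sd must be non-negative")
    if prior_sd == 0:
        return np.zeros_like(beta)
    V = se ** 2
    W = prior_sd ** 2
    r = W / (W + V)
    z2 = (beta / se) ** 2
    return 0.5 * np.log1p(-r) + 0.5 * r * z2


def verdict_from_probability(prob) -> str:
    if prob is None:
        return "distinct"
    if prob >= 0.8:
        return "colocalized"
    if prob > 0.5:
        return "borderline"
    return "distinct"


def conditional_coloc_probability(pp_signal_all: float, pp_distinct: float):
    """P(shared causal variant | every trait has a signal).

    Pairwise this is PP4/(PP3+PP4). Returns None (undefined) when both
    inputs are zero; callers report the verdict as distinct and flag it.
    """
    if pp_signal_all < 0 or pp_distinct < 0:
        raise ValueError("posterior probabilities must be non-negative")
    denom = pp_signal_all + pp_distinct
    if denom == 0:
        return None
    return pp_signal_all / denom


def _align(vectors):
    """Intersect variant ids across vectors, preserving the first one's order."""
    common = set(vectors[0].ids)
    for v in vectors[1:]:
        common &= set(v.ids)
    order = [i for i in vectors[0].ids if i in common]
    out = []
    for v in vectors:
        lookup = {i: k for k, i in enumerate(v.ids)}
        idx = np.array([lookup[i] for i in order], dtype=int)
        out.append((np.asarray(order, dtype=object), v.beta[idx], v.se[idx], v.trait_kind))
    return order, out


def _log_excl2(SA, SB, SAB):
    """log Σ_{i≠j} A_i B_j given log sums SA, SB and S(AB) = log Σ A_i B_i."""
    val, sign = logsumexp([SA + SB, SAB], b=[1.0, -1.0], return_sign=True)
    return val if sign > 0 else -np.inf


def _log_excl3(S, key_a, key_b, key_c):
    """log Σ over pairwise-distinct (i,j,k) of A_i B_j C_k via inclusion-exclusion."""
    ab = frozenset(key_a | key_b)
    ac = frozenset(key_a | key_c)
    bc = frozenset(key_b | key_c)
    abc = frozenset(key_a | key_b | key_c)
    terms = [S[key_a] + S[key_b] + S[key_c],
             S[key_a] + S[bc], S[key_b] + S[ac], S[key_c] + S[ab],
             np.log(2.0) + S[abc]]
    signs = [1.0, -1.0, -1.0, -1.0, 1.0]
    val, sign = logsumexp(terms, b=signs, return_sign=True)
    return val if sign > 0 else -np.inf


def coloc_pairwise(a: AssocVector, b: AssocVector, priors: ColocPriors = None,
                   window=None) -> ColocResult:
    """Pairwise colocalization over a shared window of variants.

    Returns posteriors over H0 (neither associated), H1/H2 (only one trait),
    H3 (both, distinct causal variants) and H4 (shared causal variant), the
    conditional probability PP4/(PP3+PP4), and the banded verdict.
    """
    priors = priors or ColocPriors()
    if window is not None:
        a = a.restrict_window(*window)
        b = b.restrict_window(*window)
    ids, aligned = _align([a, b])
    if len(ids) < 2:
        raise ValueError("colocalization needs at least 2 shared variants in the window")
    (_, beta1, se1, kind1), (_, beta2, se2, kind2) = aligned
    lbf1 = wakefield_log_abf(beta1, se1, priors.prior_sd(kind1))
    lbf2 = wakefield_log_abf(beta2, se2, priors.prior_sd(kind2))
    S1 = logsumexp(lbf1)
    S2 = logsumexp(lbf2)
    S12 = logsumexp(lbf1 + lbf2)
    logs = {
        "H0": 0.0,
        "H1": np.log(priors.p1) + S1,
        "H2": np.log(priors.p2) + S2,
        "H3": np.log(priors.p1) + np.log(priors.p2) + _log_excl2(S1, S2, S12),
        "H4": np.log(priors.p12) + S12,
    }
    keys = list(logs)
    vals = np.array([logs[k] for k in keys])
    pp_arr = np.exp(vals - logsumexp(vals))
    pp = dict(zip(keys, pp_arr / pp_arr.sum()))
    cond = conditional_coloc_probability(pp["H4"], pp["H3"])
    return ColocResult(pp=pp, conditional_prob=cond,
                       verdict=verdict_from_probability(cond),
                       labels=(a.label, b.label), window=window,
                       flagged=cond is None, n_variants=len(ids))


def _partitions(items):
    """All set partitions of ``items`` (tuple of indices)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _partitions(rest):
        for k in range(len(part)):
            yield part[:k] + [sorted([first] + part[k])] + part[k + 1:]
        yield [[first]] + part


def trivariate_configurations():
    """The 15 sharing configurations of three traits.

    Each configuration is a tuple of groups (tuples of trait indices);
    traits absent from every group are null. () is the global null.
    """
    configs = [()]
    for subset_size in (1, 2, 3):
        for subset in itertools.combinations(range(3), subset_size):
            for part in _partitions(subset):
                configs.append(tuple(tuple(g) for g in sorted(part)))
    return configs


def _config_label(config, labels):
    if not config:
        return "null"
    return ";".join("+".join(labels[i] for i in g) for g in config)


def moloc_trivariate(a: AssocVector, b: AssocVector, c: AssocVector,
                     priors: ColocPriors = None, window=None) -> ColocResult:
    """Trivariate colocalization over the 15 sharing configurations.

    The conditional probability is P(all three traits share one causal
    variant) / P(each of the three traits has an associated variant).
    """
    priors = priors or ColocPriors()
    vecs = [a, b, c]
    if window is not None:
        vecs = [v.restrict_window(*window) for v in vecs]
    ids, aligned = _align(vecs)
    if len(ids) < 2:
        raise ValueError("colocalization needs at least 2 shared variants in the window")
    lbf = [wakefield_log_abf(beta, se, priors.prior_sd(kind))
           for _, beta, se, kind in aligned]
    # log Σ_i Π_{t∈T} ABF_t(i) for every non-empty trait subset T
    S = {}
    for size in (1, 2, 3):
        for subset in itertools.combinations(range(3), size):
            S[frozenset(subset)] = logsumexp(sum(lbf[t] for t in subset))
    group_logprior = {1: np.log(priors.tri_p1), 2: np.log(priors.tri_p2),
                      3: np.log(priors.tri_p3)}

    logs = {}
    for config in trivariate_configurations():
        prior = sum(group_logprior[len(g)] for g in config)
        if len(config) == 0:
            logs[config] = 0.0
        elif len(config) == 1:
            logs[config] = prior + S[frozenset(config[0])]
        elif len(config) == 2:
            g1, g2 = (frozenset(g) for g in config)
            logs[config] = prior + _log_excl2(S[g1], S[g2], S[frozenset(g1 | g2)])
        else:
            g1, g2, g3 = (frozenset(g) for g in config)
            logs[config] = prior + _log_excl3(S, g1, g2, g3)

    keys = list(logs)
    vals = np.array([logs[k] for k in keys])
    pp_arr = np.exp(vals - logsumexp(vals))
    pp_arr = pp_arr / pp_arr.sum()
    labels = tuple(v.label for v in vecs)
    pp = {_config_label(k, labels): float(p) for k, p in zip(keys, pp_arr)}
    full = pp[_config_label(((0, 1, 2),), labels)]
    all_assoc = sum(pp[_config_label(k, labels)] for k in keys
                    if sum(len(g) for g in k) == 3 and len(k) >= 1
                    and {i for g in k for i in g} == {0, 1, 2})
    cond = conditional_coloc_probability(full, all_assoc - full)
    return ColocResult(pp=pp, conditional_prob=cond,
                       verdict=verdict_from_probability(cond),
                       labels=labels, window=window,
                       flagged=cond is None, n_variants=len(ids))


_COLLINEAR_TOL = 1e-6


def approx_conditional_z(z_target, z_cond, r):
    """Association of the target variant conditional on another variant.

    z' = (z_target − r·z_cond) / sqrt(1 − r²), with r the signed LD
    correlation between the two variants. Collinear pairs (|r| ≥ 1−1e-6)
    cannot be conditioned and raise.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0 - _COLLINEAR_TOL):
        raise ValueError("cannot condition on a (near-)collinear variant (|r| ~ 1)")
    return (np.asarray(z_target, dtype=float) - r * np.asarray(z_cond, dtype=float)) \
        / np.sqrt(1.0 - r ** 2)


def condition_assoc(vec: AssocVector, cond_id: str, ld: LDTable) -> AssocVector:
    """Condition a whole association vector on one variant's signal.

    Every variant's z is adjusted using its signed LD with the conditioning
    variant; the conditioning variant itself is set to zero residual signal.
    Effect sizes are rebuilt as beta = z'·se so the vector stays on its
    original effect scale for Bayes-factor evaluation.
    """
    lookup = {i: k for k, i in enumerate(vec.ids)}
    if cond_id not in lookup:
        raise KeyError(f"conditioning variant {cond_id!r} not in vector {vec.label!r}")
    z = vec.z.copy()
    z_c = z[lookup[cond_id]]
    z_new = np.empty_like(z)
    for k, vid in enumerate(vec.ids):
        if vid == cond_id:
            z_new[k] = 0.0
            continue
        r = ld.r(vid, cond_id)
        if abs(r) >= 1.0 - _COLLINEAR_TOL:
            z_new[k] = 0.0  # effectively the same signal; fully absorbed
            continue
        z_new[k] = (z[k] - r * z_c) / np.sqrt(1.0 - r ** 2)
    return AssocVector(label=f"{vec.label}|{cond_id}", ids=vec.ids.copy(),
                       beta=z_new * vec.se, se=vec.se.copy(),
                       trait_kind=vec.trait_kind, chrom=vec.chrom, pos=vec.pos)


def detect_secondary_signal(result_df: pd.DataFrame, traits, sentinel_id: str,
                            ld: LDTable, p_limit: float = 1e-5,
                            r2_limit: float = 0.1):
    """Automated proxy for visual regional-plot inspection.

    Flags the strongest in-window variant with a single-trait p below
    ``p_limit`` that is essentially unlinked to the sentinel (r² below
    ``r2_limit``), returning (trait, variant_id) or None. Such a variant
    indicates allelic heterogeneity and triggers the conditioning path.
    """
    best = None
    for trait in traits:
        col = f"p_{trait}"
        if col not in result_df.columns:
            continue
        for row in result_df.itertuples(index=False):
            vid = row.variant_id
            if vid == sentinel_id:
                continue
            p = getattr(row, col)
            if p < p_limit and ld.r2(vid, sentinel_id) < r2_limit:
                if best is None or p < best[2]:
                    best = (trait, vid, p)
    if best is None:
        return None
    return best[0], best[1]


def read_qtl_table(path) -> pd.DataFrame:
    """Load a significant variant-gene pair table (gene, tissue, variant, beta, se)."""
    df = pd.read_csv(path, sep="\t")
    need = ["gene", "tissue", "variant_id", "beta", "se"]
    for col in need:
        if col not in df.columns:
            raise ValueError(f"{path}: QTL table needs columns {need}")
    return df


@dataclass
class QtlColocRecord:
    gene: str
    tissue: str
    gwas_trait: str
    result: ColocResult
    concordance: str  # e.g. "+/+" — sentinel GWAS sign / QTL sign


def qtl_colocalize(locus, gwas: dict, qtl_pairs: pd.DataFrame,
                   priors: ColocPriors = None, window_bp: int = 500_000,
                   ld: LDTable = None, result_df: pd.DataFrame = None):
    """Colocalize a locus against every gene-tissue QTL that covers its sentinel.

    ``gwas`` maps trait label → AssocVector; the trait whose single-trait
    signal at the sentinel is most significant is used, mirroring the rule
    of picking the disease trait with the strongest sentinel association.
    Gene-tissue pairs whose significant-variant list does not include the
    sentinel are skipped (the upstream QTL screen). Borderline results are
    routed through the approximate-conditional rescue when a secondary
    unlinked signal is detected in the window.
    """
    priors = priors or ColocPriors()
    # trait choice: most significant single-trait z at the sentinel
    best_trait, best_absz = None, -1.0
    for trait, vec in gwas.items():
        lookup = {i: k for k, i in enumerate(vec.ids)}
        if locus.sentinel_id in lookup:
            absz = abs(vec.z[lookup[locus.sentinel_id]])
            if absz > best_absz:
                best_trait, best_absz = trait, absz
    if best_trait is None:
        return []
    gvec = gwas[best_trait]
    half = window_bp // 2
    window = (locus.chrom, locus.pos - half, locus.pos + half)
    records = []
    for (gene, tissue), grp in qtl_pairs.groupby(["gene", "tissue"], sort=True):
        if locus.sentinel_id not in set(grp["variant_id"]):
            continue
        qvec = AssocVector(label=f"{gene}@{tissue}", ids=grp["variant_id"].to_numpy(),
                           beta=grp["beta"].to_numpy(), se=grp["se"].to_numpy(),
                           trait_kind="quantitative")
        gsub = gvec.restrict_window(*window) if gvec.pos is not None else gvec
        res = coloc_pairwise(gsub, qvec, priors)
        if res.verdict == "borderline" and ld is not None and result_df is not None:
            hit = detect_secondary_signal(result_df, [best_trait], locus.sentinel_id, ld)
            if hit is not None:
                _, cond_id = hit
                if cond_id in set(gsub.ids):
                    res2 = coloc_pairwise(condition_assoc(gsub, cond_id, ld), qvec, priors)
                    res2.conditioned_on = cond_id
                    res = res2
        glook = {i: k for k, i in enumerate(gvec.ids)}
        qlook = {i: k for k, i in enumerate(qvec.ids)}
        gsign = "+" if gvec.z[glook[locus.sentinel_id]] > 0 else "-"
        qsign = "+" if qvec.z[qlook[locus.sentinel_id]] > 0 else "-"
        records.append(QtlColocRecord(gene=gene, tissue=tissue, gwas_trait=best_trait,
                                      result=res, concordance=f"{gsign}/{qsign}"))
    return records
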