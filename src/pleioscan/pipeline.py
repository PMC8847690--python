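"""End-to-end orchestration of the multi-trait discovery cascade.

One config drives: read & harmonize per-trait summary statistics →
enumerate scans → N-weighted multivariate statistics → empirical
experiment-wide threshold → sentinel/locus discovery → pleiotropy, single-
trait, HLA and catalog-novelty filters → trait-trait colocalization (with
the approximate-conditional rescue for borderline loci) → merging into
independent loci → optional molecular-QTL colocalization. Every stage logs
a count; the run is deterministic given the seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coloc import (AssocVector, ColocPriors, coloc_pairwise, condition_assoc,
                    detect_secondary_signal, moloc_trivariate, qtl_colocalize,
                    read_qtl_table)
from .loci import (HLA_REGION, apply_novelty_filter, apply_pleiotropy_filters,
                   discover_loci, merge_independent_loci)
from .multitrait import enumerate_scans, estimate_z_correlation, run_scan
from .significance import resampling_threshold
from .sumstats import (effective_sample_size, harmonize_panel, read_catalog,
                       read_ld_table, read_sumstats)

__all__ = ["TraitSpec", "PipelineConfig", "RunReport", "run_pipeline",
           "write_report", "load_config", "read_hla_bed"]


@dataclass
class TraitSpec:
    label: str
    path: str = None
    is_binary: bool = False
    n_cases: float = None
    n_controls: float = None
    n_total: float = None
    dialect: dict = None

    def effective_n(self):
        if self.n_total is not None:
            return self.n_total
        if self.is_binary and self.n_cases and self.n_controls:
            return effective_sample_size(self.n_cases, self.n_controls)
        return None


@dataclass
class PipelineConfig:
    """Every constant of the cascade, flat and serializable."""

    traits: list
    core: tuple
    risk: tuple = ()
    nominal_p: float = 5e-3
    gw_p: float = 5e-8
    percentile: float = 0.95
    n_sets: int = 10_000
    set_size: int = 1_000_000
    seed: int = 0
    locus_window_bp: int = 1_000_000
    coloc_window_bp: int = 500_000
    novelty_bp: int = 500_000
    r2_locus: float = 0.2
    r2_secondary: float = 0.1
    secondary_p: float = 1e-5
    coloc_keep: float = 0.8
    priors: ColocPriors = field(default_factory=ColocPriors)
    null_restrict: float = None       # |z| cutoff for the correlation estimate
    ld_path: str = None
    catalog_path: str = None
    qtl_path: str = None
    hla_bed: str = None
    outdir: str = "pleioscan_out"

    def __post_init__(self):
        self.core = tuple(self.core)
        self.risk = tuple(self.risk)
        self.traits = [t if isinstance(t, TraitSpec) else TraitSpec(**t)
                       for t in self.traits]
        if isinstance(self.priors, dict):
            self.priors = ColocPriors(**self.priors)
        for name in ("nominal_p", "gw_p", "percentile"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1)")

    def validate_paths(self):
        for t in self.traits:
            if t.path is None or not Path(t.path).exists():
                raise FileNotFoundError(f"summary statistics for {t.label}: {t.path}")
        for p in (self.ld_path, self.catalog_path, self.qtl_path, self.hla_bed):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    def fingerprint(self) -> str:
        payload = yaml.safe_dump(_config_dict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["core"] = list(config.core)
    d["risk"] = list(config.risk)
    return d


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PipelineConfig(**raw)


def read_hla_bed(path):
    """First BED interval (0-based half-open) → 1-based inclusive region."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    chrom, start, end = df.iloc[0, 0], int(df.iloc[0, 1]), int(df.iloc[0, 2])
    return (str(chrom).removeprefix("chr"), start + 1, end)


@dataclass
class LocusCall:
    """One discovered locus with its verdicts and colocalization outcome."""

    locus: object
    coloc: object = None
    is_novel_pleiotropic: bool = False


@dataclass
class RunReport:
    threshold: object
    scan_counts: dict
    calls: list
    clusters: list
    qtl_records: list
    config_fingerprint: str
    seed: int
    n_panel_variants: int = 0

    @property
    def novel_calls(self):
        return [c for c in self.calls if c.is_novel_pleiotropic]


def _trait_assoc(panel, result_df, trait, is_binary) -> AssocVector:
    """Per-trait effect vector on the beta scale implied by N and EAF."""
    eaf = result_df["eaf"].to_numpy()
    n = panel.n[:, panel.trait_index(trait)]
    se = 1.0 / np.sqrt(2.0 * n * eaf * (1.0 - eaf))
    z = result_df[f"z_{trait}"].to_numpy()
    return AssocVector(label=trait, ids=result_df["variant_id"].to_numpy(),
                       beta=z * se, se=se,
                       trait_kind="case_control" if is_binary else "quantitative",
                       chrom=result_df["chrom"].astype(str).to_numpy(),
                       pos=result_df["pos"].to_numpy())


def _coloc_locus(locus, result, panel, binary_map, config, ld):
    """Trait-trait colocalization at one locus, with the borderline rescue."""
    half = config.coloc_window_bp // 2
    window = (locus.chrom, locus.pos - half, locus.pos + half)
    vecs = {t: _trait_assoc(panel, result.df, t, binary_map.get(t, False))
            for t in locus.scan.traits}
    wvecs = {t: v.restrict_window(*window) for t, v in vecs.items()}

    def engine(vmap):
        vlist = [vmap[t] for t in locus.scan.traits]
        if len(vlist) == 2:
            return coloc_pairwise(vlist[0], vlist[1], config.priors)
        return moloc_trivariate(*vlist, priors=config.priors)

    res = engine(wvecs)
    if res.verdict == "borderline":
        wdf = result.df.loc[(result.df["chrom"].astype(str) == str(locus.chrom)) &
                            (result.df["pos"].between(window[1], window[2]))]
        hit = detect_secondary_signal(wdf, locus.scan.traits, locus.sentinel_id, ld,
                                      p_limit=config.secondary_p,
                                      r2_limit=config.r2_secondary)
        if hit is not None:
            trait, cond_id = hit
            if cond_id in set(wvecs[trait].ids):
                adjusted = dict(wvecs)
                adjusted[trait] = condition_assoc(wvecs[trait], cond_id, ld)
                res2 = engine(adjusted)
                res2.conditioned_on = cond_id
                res = res2
    return res


def run_pipeline(config: PipelineConfig, panel=None, ld=None, catalog=None,
                 qtl_pairs=None) -> RunReport:
    """Execute the full cascade; inputs may be preloaded objects or paths."""
    binary_map = {t.label: t.is_binary for t in config.traits}
    if panel is None:
        scans_data = []
        for t in config.traits:
            scans_data.append(read_sumstats(
                t.path, dialect=t.dialect, trait=t.label, is_binary=t.is_binary,
                n_cases=t.n_cases, n_controls=t.n_controls, n_total=t.n_total))
        panel = harmonize_panel(scans_data)
    if ld is None:
        if config.ld_path is None:
            raise ValueError("no LD table provided (ld_path or preloaded object)")
        ld = read_ld_table(config.ld_path)
    if catalog is None:
        catalog = read_catalog(config.catalog_path) if config.catalog_path else []
    if qtl_pairs is None and config.qtl_path:
        qtl_pairs = read_qtl_table(config.qtl_path)
    hla = read_hla_bed(config.hla_bed) if config.hla_bed else HLA_REGION

    scan_defs = enumerate_scans(config.core, config.risk)
    R = estimate_z_correlation(panel, null_restrict=config.null_restrict)
    results = [run_scan(panel, s, R) for s in scan_defs]

    # experiment-wide threshold from the cross-scan null correlation
    zmat = np.column_stack([r.df["z_multi"].to_numpy() for r in results])
    R_scan = np.corrcoef(zmat, rowvar=False) if len(results) > 1 else np.array([[1.0]])
    threshold = resampling_threshold(R_scan, set_size=config.set_size,
                                     n_sets=config.n_sets,
                                     percentile=config.percentile, seed=config.seed)

    member_pos = dict(zip(panel.index["variant_id"],
                          zip(panel.index["chrom"].astype(str), panel.index["pos"])))
    calls = []
    scan_counts = {}
    for result in results:
        counts = {"significant_sentinels": 0, "pleiotropic": 0, "not_gw_single": 0,
                  "outside_hla": 0, "novel_vs_catalog": 0, "colocalized": 0}
        loci = discover_loci(result, config.gw_p, ld,
                             window_bp=config.locus_window_bp, r2_min=config.r2_locus)
        counts["significant_sentinels"] = len(loci)
        for locus in loci:
            locus.tier = ("experiment_wide" if locus.p_multi < threshold.p_star
                          else "nominal")
            apply_pleiotropy_filters(locus, result.trait_p_at(locus.sentinel_id),
                                     nominal_p=config.nominal_p, gw_p=config.gw_p,
                                     hla=hla)
            call = LocusCall(locus=locus)
            if not locus.verdicts["pleiotropy_pass"]:
                calls.append(call)
                continue
            counts["pleiotropic"] += 1
            if not locus.verdicts["not_gw_single"]:
                calls.append(call)
                continue
            counts["not_gw_single"] += 1
            if not locus.verdicts["outside_hla"]:
                calls.append(call)
                continue
            counts["outside_hla"] += 1
            apply_novelty_filter(locus, catalog, ld, member_pos=member_pos,
                                 proximity_bp=config.novelty_bp, r2_min=config.r2_locus)
            if not locus.verdicts["novel_vs_catalog"]:
                calls.append(call)
                continue
            counts["novel_vs_catalog"] += 1
            call.coloc = _coloc_locus(locus, result, panel, binary_map, config, ld)
            if call.coloc.conditional_prob is not None and \
                    call.coloc.conditional_prob >= config.coloc_keep:
                call.is_novel_pleiotropic = True
                counts["colocalized"] += 1
            calls.append(call)
        scan_counts[result.scan.label] = counts

    clusters = merge_independent_loci(
        [c.locus for c in calls if c.is_novel_pleiotropic],
        distance_bp=config.locus_window_bp)

    qtl_records = []
    if qtl_pairs is not None and len(qtl_pairs):
        result_by_scan = {r.scan.label: r for r in results}
        for cluster in clusters:
            rep = cluster[0]
            result = result_by_scan[rep.scan.label]
            gwas = {t: _trait_assoc(panel, result.df, t, binary_map.get(t, False))
                    for t in rep.scan.traits if t in config.core}
            if not gwas:
                gwas = {t: _trait_assoc(panel, result.df, t, binary_map.get(t, False))
                        for t in rep.scan.traits}
            recs = qtl_colocalize(rep, gwas, qtl_pairs, priors=config.priors,
                                  window_bp=config.coloc_window_bp, ld=ld,
                                  result_df=result.df)
            qtl_records.extend((rep, r) for r in recs)

    return RunReport(threshold=threshold, scan_counts=scan_counts, calls=calls,
                     clusters=clusters, qtl_records=qtl_records,
                     config_fingerprint=config.fingerprint(), seed=config.seed,
                     n_panel_variants=panel.n_variants)


def report_frame(report: RunReport) -> pd.DataFrame:
    """Flatten the discovered loci into the standard report layout."""
    rows = []
    for call in report.calls:
        loc = call.locus
        srow = loc.sentinel_row
        ps = [srow[f"p_{t}"] for t in loc.scan.traits]
        while len(ps) < 3:
            ps.append(np.nan)
        rows.append({
            "traits": loc.scan.label,
            "annotation": "",
            "sentinel": loc.sentinel_id,
            "chrom": loc.chrom,
            "pos": loc.pos,
            "effect_allele": srow["effect_allele"],
            "other_allele": srow["other_allele"],
            "direction": srow["direction"],
            "eaf": round(float(srow["eaf"]), 4),
            "p_multi": float(loc.p_multi),
            "p_trait1": float(ps[0]),
            "p_trait2": float(ps[1]),
            "p_trait3": float(ps[2]) if np.isfinite(ps[2]) else "NA",
            "tier": loc.tier,
            "pleiotropy_pass": loc.verdicts.get("pleiotropy_pass", False),
            "not_gw_single": loc.verdicts.get("not_gw_single", False),
            "outside_hla": loc.verdicts.get("outside_hla", False),
            "novel_vs_catalog": loc.verdicts.get("novel_vs_catalog", ""),
            "coloc_conditional_prob": (round(call.coloc.conditional_prob, 6)
                                       if call.coloc is not None and
                                       call.coloc.conditional_prob is not None else "NA"),
            "coloc_verdict": call.coloc.verdict if call.coloc is not None else "NA",
            "novel_pleiotropic": call.is_novel_pleiotropic,
        })
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["p_multi", "chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return df


def write_report(report: RunReport, outdir, config: PipelineConfig = None):
    """Emit the locus report, stage counts and a reproducibility manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    loci_path = outdir / "loci_report.tsv"
    report_frame(report).to_csv(loci_path, sep="\t", index=False, float_format="%.6g")

    counts = []
    for label, c in report.scan_counts.items():
        counts.append({"scan": label, **c})
    pd.DataFrame(counts).to_csv(outdir / "stage_counts.tsv", sep="\t", index=False)

    if report.qtl_records:
        rows = [{"sentinel": rep.sentinel_id, "scan": rep.scan.label,
                 "gene": rec.gene, "tissue": rec.tissue, "gwas_trait": rec.gwas_trait,
                 "conditional_prob": (round(rec.result.conditional_prob, 6)
                                      if rec.result.conditional_prob is not None else "NA"),
                 "verdict": rec.result.verdict, "concordance": rec.concordance}
                for rep, rec in report.qtl_records]
        pd.DataFrame(rows).to_csv(outdir / "qtl_coloc.tsv", sep="\t", index=False)

    manifest = {
        "package": "pleioscan",
        "version": __version__,
        "seed": report.seed,
        "config_fingerprint": report.config_fingerprint,
        "threshold": {"z_star": float(report.threshold.z_star),
                      "p_star": float(report.threshold.p_star),
                      "percentile": report.threshold.percentile,
                      "n_sets": report.threshold.n_sets,
                      "set_size": report.threshold.set_size},
        "n_panel_variants": report.n_panel_variants,
    }
    if config is not None:
        manifest["config"] = _config_dict(config)
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return loci_path
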