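"""End-to-end orchestration on synthetic (or user-supplied) count data.

``run_full_analysis`` chains: simulate → scale (both methods, cross-
validated) → differential calling at TSS and remote DNase windows →
induction hierarchy (Distance Index, dendrogram, AU support) → genotype
dependence across all background pairs → direct-target classification →
metaprofiles → RNA regression, and returns one summary dictionary with
every headline statistic.  The pipeline is a pure function of
(config, seed): reruns are identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dependence as dep
from . import differential as diff
from . import hierarchy as hier
from . import metaprofile as meta
from . import normalization as norm
from . import regression as regr
from . import synthetic as synth
from .core import CountMatrix, sample_name
from .genomic_io import classify_direct_targets, classify_dnase_sites

logger = logging.getLogger(__name__)

REFERENCE_SAMPLE = sample_name("WT", "FCS", 0, 1)


@dataclass
class PipelineConfig:
    simulation: synth.SimulationConfig = field(default_factory=synth.SimulationConfig)
    n_boot: int = 1000
    au_scales: tuple[float, ...] = hier.DEFAULT_SCALES
    reference_sample: str = REFERENCE_SAMPLE
    output_dir: str | None = None

    @property
    def seed(self) -> int:
        return self.simulation.seed


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def tss_differential(
    counts: dict[str, CountMatrix],
    factors: dict[str, pd.Series],
    background: str = "WT",
    stim_time: int = 30,
    replicates: list[int] | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-mark TSS differential calling (rest vs stimulated) with the
    per-mark 25th-percentile count floor.

    ``replicates`` restricts the tested columns (dispersions are always
    estimated from the full replicate set) — used for the split-replicate
    dependence analysis.
    """
    results = {}
    for mark, cm in counts.items():
        sub = cm.select(background=background)
        cols_a = list(sub.select(condition="FCS").counts.columns)
        cols_b = list(sub.select(condition="TPA", time=stim_time).counts.columns)
        cols = cols_a + cols_b
        table = sub.counts[cols]
        sf = (1.0 / factors[mark]).reindex(cols)
        sf = sf / sf.mean()  # gauge: mean size factor 1
        groups = sub.samples.loc[cols, "condition"] + sub.samples.loc[cols, "time"].astype(str)
        alphas, _ = diff.estimate_dispersions(table, groups, sf)
        if replicates is not None:
            reps = sub.samples.loc[cols, "replicate"]
            cols_a = [c for c in cols_a if reps[c] in replicates]
            cols_b = [c for c in cols_b if reps[c] in replicates]
        pooled = (table / sf).mean(axis=1)
        floor = diff.select_count_threshold(pooled, "tss")
        res = diff.differential_table(table, cols_a, cols_b, sf, alphas, mark, floor)
        results[mark] = diff.call_changed_regions(res, "tss")
    return results


def dnase_differential(site_counts: dict[str, CountMatrix]) -> dict[str, pd.DataFrame]:
    """Per-mark remote-window calling with the pooled 5x25th-percentile
    floor and the 2-fold / adjusted-p rule."""
    pooled_all = np.concatenate(
        [cm.counts.mean(axis=1).to_numpy() for cm in site_counts.values()]
    )
    floor = diff.select_count_threshold(pooled_all, "dnase")
    results = {}
    for mark, cm in site_counts.items():
        cols_a = list(cm.select(condition="FCS").counts.columns)
        cols_b = list(cm.select(condition="TPA").counts.columns)
        cols = cols_a + cols_b
        sf = pd.Series(1.0, index=cols)
        groups = cm.samples.loc[cols, "condition"]
        alphas, _ = diff.estimate_dispersions(cm.counts[cols], groups, sf)
        res = diff.differential_table(cm.counts[cols], cols_a, cols_b, sf, alphas, mark, floor)
        results[mark] = diff.call_changed_regions(res, "dnase")
    return results


def wt_hierarchy_state(
    sim_config: synth.SimulationConfig,
    use_planted_invariants: bool = True,
) -> dict:
    """Lean wild-type analysis path for recovery studies: simulate, scale
    by invariant-gene factors, call changed TSS regions, and return the
    significant-set fold-change table with its parts.

    ``use_planted_invariants`` anchors method-1 scaling directly on the
    generator's invariant genes, skipping the RNA-based selection step
    (assessed separately) for speed in multi-seed recovery loops.
    """
    counts, truth = synth.simulate_counts(sim_config)
    if use_planted_invariants:
        inv_regions = pd.Index(truth.region_ids[truth.invariant])
    else:
        intronic, _ = synth.simulate_rna(truth)
        inv = norm.select_invariant_genes(intronic, diff.nb_exact_test_many,
                                          dispersion=sim_config.nb_dispersion)
        g2r = dict(zip(truth.gene_ids, truth.region_ids))
        inv_regions = pd.Index([g2r[g] for g in inv if g in g2r])
    factors = {m: norm.scaling_method1(counts[m], inv_regions, REFERENCE_SAMPLE).factors
               for m in sim_config.marks}
    results = tss_differential(counts, factors)
    sig = pd.DataFrame({m: r["significant"] for m, r in results.items()})
    sig_any = sig.any(axis=1)
    normalized = {m: counts[m].scaled(factors[m]) for m in sim_config.marks}
    fc_sig = hier.compute_fold_changes(normalized, background="WT").loc[sig_any]
    return {
        "counts": counts, "truth": truth, "factors": factors,
        "normalized": normalized, "tss_results": results,
        "sig": sig, "sig_any": sig_any, "fc_sig": fc_sig,
    }


def run_full_analysis(config: PipelineConfig) -> dict:
    """Execute every stage; returns the summary bundle (JSON-serializable
    except for the per-stage tables under ``"tables"``)."""
    t0 = time.time()
    cfg = config.simulation
    summary: dict = {"seed": cfg.seed, "config_hash": _config_hash(config), "stages": {}}
    tables: dict = {}

    def stage(name):
        logger.info("stage %s (t=%.1fs)", name, time.time() - t0)
        summary["stages"][name] = round(time.time() - t0, 2)

    stage("simulate")
    counts, truth = synth.simulate_counts(cfg)
    intronic, orf = synth.simulate_rna(truth)
    remote = synth.simulate_remote_sites(cfg, truth.regions)
    site_counts, _site_g = synth.simulate_site_counts(cfg, remote)
    coverage, anchors = synth.simulate_coverage(truth)

    stage("normalize")
    inv_genes = norm.select_invariant_genes(
        intronic, diff.nb_exact_test_many, dispersion=cfg.nb_dispersion
    )
    gene_to_region = dict(zip(truth.gene_ids, truth.region_ids))
    inv_regions = pd.Index([gene_to_region[g] for g in inv_genes if g in gene_to_region])
    factors1 = {
        mark: norm.scaling_method1(counts[mark], inv_regions,
                                   config.reference_sample).factors
        for mark in cfg.marks
    }

    stage("diffcall_tss")
    tss_results = tss_differential(counts, factors1)
    sig = pd.DataFrame({m: r["significant"] for m, r in tss_results.items()})
    n_changed = sig.sum(axis=1)
    sig_any = sig.any(axis=1)
    summary["differential"] = {
        "n_tss_detected": int(tss_results[cfg.marks[0]]["passed_count_filter"].sum()),
        "n_tss_changed": int(sig_any.sum()),
    }
    tables["tss_results"] = tss_results

    stage("scaling_validation")
    # method-2 factors refit on the unchanged regions (two-pass: the first
    # call defines the changed set, whose induction would otherwise bias
    # the Gaussian fit of the stimulated samples), then cross-validated
    # against the invariant-gene factors
    unchanged_regions = sig_any.index[~sig_any]
    slopes, recovery_err = [], []
    for mark in cfg.marks:
        f2 = norm.scaling_method2(counts[mark], config.reference_sample,
                                  region_subset=unchanged_regions).factors
        cmp_tab = norm.compare_scaling_methods(
            counts[mark].scaled(factors1[mark]), counts[mark].scaled(f2))
        slopes.append(cmp_tab["slope"])
        truth_d = truth.distortions[mark]
        for fac in (factors1[mark], f2):
            recovery_err.append(float(np.abs(fac * truth_d - 1.0).mean()))
    all_slopes = pd.concat(slopes)
    summary["scaling"] = {
        "n_invariant_genes": int(len(inv_genes)),
        "method_agreement_slope_mean": float(all_slopes.mean()),
        "method_agreement_slope_range": [float(all_slopes.min()), float(all_slopes.max())],
        "distortion_recovery_mean_abs_err": float(np.mean(recovery_err)),
    }

    stage("diffcall_dnase")
    dnase_results = dnase_differential(site_counts)
    dnase_sig = pd.DataFrame({m: r["significant"] for m, r in dnase_results.items()}).any(axis=1)
    site_classes = classify_dnase_sites(remote.sites, truth.regions, remote.srf_peaks)
    remote_sig = dnase_sig & (site_classes != "TSS-proximal")
    srf_frac = float(
        (site_classes[remote_sig[remote_sig].index] == "remote-SRF").mean()
    ) if remote_sig.any() else np.nan
    summary["dnase"] = {
        "n_sites_changed": int(dnase_sig.sum()),
        "n_remote_changed": int(remote_sig.sum()),
        "remote_srf_fraction": srf_frac,
    }

    stage("hierarchy")
    normalized = {m: counts[m].scaled(factors1[m]) for m in cfg.marks}
    fc_wt = hier.compute_fold_changes(normalized, background="WT")
    fc_sig = fc_wt.loc[sig_any]
    dimat = hier.di_matrix(fc_sig)
    z, labels = hier.cluster_marks(fc_sig)
    au = hier.multiscale_au(fc_sig, config.au_scales, config.n_boot,
                            seed=(cfg.seed * 7919 + 13) % (2**31))
    lead = cfg.marks[0]
    summary["hierarchy"] = {
        "di_row_leading": {m: float(dimat.loc[lead, m]) for m in cfg.marks if m != lead},
        "dendrogram_newick": hier.to_newick(z, labels),
        "au": {k: float(v) for k, v in au.au.items()},
        "n_regions_used": int(len(fc_sig)),
    }
    tables["di_matrix"] = dimat
    tables["fold_changes"] = fc_wt

    stage("dependence")
    # Split-replicate design against the winner's curse: the wild-type
    # fold entering the asymmetry coordinate is measured on replicate 2
    # while region selection rests on replicate-1 significance (joined
    # with the full changed set to purge single-replicate false
    # positives), so selection noise cannot masquerade as genotype
    # dependence.  The non-reference backgrounds never enter selection
    # and use both replicates.
    sel_results = tss_differential(counts, factors1, replicates=[1])
    sel_sig = pd.DataFrame({m: r["significant"] for m, r in sel_results.items()}
                           ).any(axis=1) & sig_any
    detected = sel_results[cfg.marks[0]]["passed_count_filter"]
    unchanged = detected & ~sig_any
    fc_all = {"WT": hier.compute_fold_changes(normalized, background="WT", replicate=2)}
    for bg in ("TKO", "TKO+Elk1", "TKO+Elk1nonA", "TKO+Elk1dFW"):
        fc_all[bg] = hier.compute_fold_changes(normalized, background=bg)
    fc_by_bg = {bg: fc.loc[sel_sig] for bg, fc in fc_all.items()}
    anchor = {bg: fc.loc[unchanged] for bg, fc in fc_all.items()}
    # bin on the selection replicate's induction strength, which is
    # independent of the measurement noise entering the Y coordinate
    fc_wt_r1 = hier.compute_fold_changes(normalized, background="WT", replicate=1)
    bin_vals = np.log2(fc_wt_r1).mean(axis=1).loc[sel_sig]
    flags = dep.tss_dependence_flags(fc_by_bg, "WT", anchor_fc_by_background=anchor,
                                     bin_values=bin_vals)
    variants = dep.combined_pair_flags(fc_by_bg, ("TKO+Elk1nonA", "TKO+Elk1dFW"),
                                       "WT", anchor_fc_by_background=anchor,
                                       bin_values=bin_vals)
    classes = dep.classify_restoration(flags, variants_combined=variants)
    dep_mask = classes != "not-dependent"
    restored = classes.isin(["restored-any-Elk1", "restored-requires-phospho+FW"])
    pts = dep.make_dependence_points(fc_by_bg["WT"][lead], fc_by_bg["TKO"][lead], ("WT", "TKO"))
    reg = dep.fit_asymmetry_regression(pts)
    summary["dependence"] = {
        "n_analyzed": int(len(classes)),
        "n_dependent": int(dep_mask.sum()),
        "dependent_fraction": float(dep_mask.mean()),
        "restored_fraction": float(restored[dep_mask].mean()) if dep_mask.any() else np.nan,
        "phospho_fw_fraction": float(
            (classes[restored] == "restored-requires-phospho+FW").mean()
        ) if restored.any() else np.nan,
        "slope_above_leading_mark": float(reg["above"]["slope"]),
        "class_counts": classes.value_counts().to_dict(),
    }
    tables["restoration_classes"] = classes

    stage("direct_targets")
    target_labels = classify_direct_targets(truth.regions, remote.srf_peaks, remote.links)
    direct_dep = (target_labels.reindex(classes.index) == "direct") & dep_mask
    summary["direct_targets"] = {
        "n_direct_dependent": int(direct_dep.sum()),
        "direct_fraction_of_dependent": float(direct_dep[dep_mask].mean()) if dep_mask.any() else np.nan,
    }

    stage("metaprofile")
    lead_mark, late_mark = cfg.marks[0], cfg.marks[-1]
    skews = {}
    for mark in (lead_mark, late_mark):
        rest_prof = meta.compute_metaprofile(coverage[f"{mark}_t0"], anchors)
        for t in (5, 15, 30):
            stim_prof = meta.compute_metaprofile(coverage[f"{mark}_t{t}"], anchors)
            skews[f"{mark}_t{t}"] = meta.downstream_skew(
                meta.difference_profile(stim_prof, rest_prof)
            )
    counts_lead = normalized[lead_mark].select(background="WT").counts
    classes_meta = meta.group_by_induction(fc_wt, counts_lead, sig[lead_mark])
    summary["metaprofile"] = {
        "downstream_skew": skews,
        "class_sizes": classes_meta[classes_meta != ""].value_counts().to_dict(),
    }

    stage("regression")
    wt_rest = [sample_name("WT", "FCS", 0, r) for r in (1, 2)]
    wt_stim = [sample_name("WT", "TPA", 30, r) for r in (1, 2)]
    rna = regr.rna_fold_change(intronic.counts, orf.counts, wt_rest, wt_stim)
    rna_fold = rna["fold_change"].rename(index=dict(zip(truth.gene_ids, truth.region_ids)))
    common = fc_sig.index.intersection(rna_fold.index)
    y = rna_fold.loc[common]
    X = fc_sig.loc[common]
    model = regr.loglog_fit(y, X)
    diag = regr.model_diagnostics(model)
    step = regr.stepwise_aic(y, X)
    summary["regression"] = {
        "skewness_rna_linear": regr.skewness(y),
        "skewness_rna_log": regr.skewness(np.log2(y)),
        "per_mark_r2": {k: float(v) for k, v in regr.per_mark_r2(y, X).items()},
        "adj_r2_full": model.adj_r_squared,
        "adj_r2_stepwise": step.adj_r_squared,
        "stepwise_terms": step.terms,
        "max_cooks_distance": float(diag["cooks_distance"].max()),
        "n_genes": int(len(common)),
    }
    tables["rna_fold"] = rna

    summary["runtime_s"] = round(time.time() - t0, 2)
    summary["tables"] = tables
    if config.output_dir:
        _write_bundle(Path(config.output_dir), summary, config)
    return summary


def _write_bundle(outdir: Path, summary: dict, config: PipelineConfig) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    tables = summary.get("tables", {})
    for mark, tab in tables.get("tss_results", {}).items():
        tab.to_csv(outdir / f"tss_differential_{mark}.tsv", sep="\t")
    if "di_matrix" in tables:
        tables["di_matrix"].to_csv(outdir / "di_matrix.tsv", sep="\t")
    if "fold_changes" in tables:
        tables["fold_changes"].to_csv(outdir / "fold_changes.tsv", sep="\t")
    if "restoration_classes" in tables:
        tables["restoration_classes"].to_frame("class").to_csv(
            outdir / "restoration_classes.tsv", sep="\t")
    slim = {k: v for k, v in summary.items() if k != "tables"}
    slim["_header"] = {"seed": config.seed, "config_hash": summary["config_hash"]}
    with open(outdir / "summary.json", "w") as fh:
        json.dump(slim, fh, indent=2, default=str)
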