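"""End-to-end orchestration: simulate -> CNA -> TE -> diffrep -> RESTORE ->
stoichiometry -> prognosis -> summary.

``run_pipeline`` executes the stages in dependency order on a synthetic
(or pre-loaded) dataset and aggregates the headline numbers into a
machine-readable summary dict; the CLI serialises it as JSON next to the
per-stage outputs together with the resolved configuration, so a run is
reproducible from its output directory alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from riborestore import cna, diffrep, expression, prognosis, restore, stoichiometry
from riborestore.config import RunConfig
from riborestore.simulate import SimulationConfig, SyntheticDataset, simulate_all


def run_pipeline(
    dataset: SyntheticDataset,
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Run every analysis stage on a dataset; return the summary dict.

    When ``outdir`` is given, per-stage tables, the summary JSON and the
    resolved config are written there.
    """
    config = config or RunConfig()
    out: dict = {}

    # --- CNA stage: segment, re-center, call, gene-level direction
    segments = cna.segment_all_samples(dataset.probe_tracks, config.cna)
    calls = cna.gene_call_matrix(dataset.annotation, segments)
    recurrence = cna.recurrent_aberrations(
        dataset.annotation, calls,
        min_recurrence=config.cna.min_recurrence,
        n_perm=config.cna.n_perm_recurrence,
        fdr=config.cna.recurrence_fdr, seed=config.cna.seed)
    direction = cna.assign_gene_direction(calls)
    out["cna"] = {
        "n_segments": int(len(segments)),
        "n_recurrent_genes": int(recurrence["flagged"].sum()),
        "n_recurrent_regions": int(recurrence.loc[recurrence["flagged"],
                                                  "region_id"].nunique()),
        "n_genes_gain": int((direction["direction"] == "gain").sum()),
        "n_genes_loss": int((direction["direction"] == "loss").sum()),
        "n_genes_conflict": int((direction["direction"] == "conflict").sum()),
    }

    # --- expression stage: filter, normalize, detectability, TE
    tc = expression.filter_probes(dataset.transcriptome, dataset.qc_flags,
                                  config.expression.above_background_frac,
                                  config.expression.good_spot_frac)
    tl = expression.filter_probes(dataset.translatome, dataset.qc_flags,
                                  config.expression.above_background_frac,
                                  config.expression.good_spot_frac)
    tc = expression.normalize_quantile(tc)
    tl = expression.normalize_quantile(tl)
    detectable = sorted(expression.detectable_union(tc, tl))
    tc, tl = tc.loc[detectable], tl.loc[detectable]
    te, te_summary = expression.compute_te(tl, tc)
    profiles = pd.concat(
        [tc.add_suffix(":TC"), tl.add_suffix(":TL")], axis=1)
    level_of = {c: c.rsplit(":", 1)[1] for c in profiles.columns}
    clustering = expression.cluster_profiles(profiles, level_of,
                                             config.expression)
    out["expression"] = {
        "n_detectable": len(detectable),
        "te_median_of_medians": float(te_summary["median"].median()),
        "te_breadth_mean": float(te_summary["iqr"].mean()),
        "n_translatome_coclustered": clustering["n_translatome_coclustered"],
        "n_translatome": clustering["n_translatome"],
    }

    # --- differential representation
    fc = te.dropna()
    rp = diffrep.rank_product_test(fc, n_perm=config.diffrep.rp_n_perm,
                                   seed=config.diffrep.seed,
                                   threshold=config.diffrep.rp_pfp_threshold)
    tt = diffrep.paired_t_test(fc, threshold=config.diffrep.t_q_threshold)
    sam = diffrep.sam_test(fc, n_perm=config.diffrep.sam_n_perm,
                           seed=config.diffrep.seed + 1,
                           fdr_threshold=config.diffrep.sam_fdr_threshold)
    consensus = diffrep.consensus_diffrep(rp, tt, sam)
    n_universe = len(fc)
    out["diffrep"] = {
        "n_tested": n_universe,
        "pct_rp": round(100 * consensus["n_rp"] / n_universe, 1),
        "pct_t": round(100 * consensus["n_t"] / n_universe, 1),
        "pct_sam": round(100 * consensus["n_sam"] / n_universe, 1),
        "share_all_three": consensus["share_all_three"],
        "venn": consensus["venn"],
    }
    primary = consensus["primary"]

    # --- RESTORE/ENHANCE classification and battery
    classified = restore.classify_genes(primary, direction)
    counts = {c: int((classified["class"] == c).sum())
              for c in restore.RESTORE_CLASSES}
    n_restore = counts["RESTORE_UP"] + counts["RESTORE_DOWN"]
    n_enhance = counts["ENHANCE_UP"] + counts["ENHANCE_DOWN"]
    prevalence_p = (restore.prevalence_test(n_restore, n_enhance)
                    if n_restore + n_enhance else float("nan"))
    universe = set(fc.index)
    cna_genes = set(direction.index[direction["direction"].isin(["gain", "loss"])])
    odds, fisher_p = restore.compensatory_enrichment(
        set(primary.index), cna_genes & universe, universe)
    wilcoxon = restore.per_line_wilcoxon(te, calls.loc[te.index],
                                         adjust=config.restore.wilcoxon_adjust)
    r_breadth = restore.breadth_correlation(wilcoxon["p_restore_up"],
                                            te_summary["iqr"])
    cat_enrich = restore.category_enrichment(
        dataset.categories, set(primary.index), universe)
    restore_up = set(classified.index[classified["class"] == "RESTORE_UP"])
    restore_down = set(classified.index[classified["class"] == "RESTORE_DOWN"])
    boot = {}
    for name, gene_set, conc in (("up", restore_up, "loss"),
                                 ("down", restore_down, "gain")):
        if not gene_set:
            continue
        for mode in ("genomewide", "cna_background"):
            res = restore.pan_cancer_bootstrap(
                gene_set, dataset.pan_cancer, concordant=conc, mode=mode,
                n_boot=config.restore.n_boot, seed=config.restore.seed,
                cna_background=cna_genes)
            boot[f"restore_{name}_{mode}"] = {
                "observed": res.observed, "p": res.p,
                "null_mean": float(res.null.mean())}
    out["restore"] = {
        "counts": counts, "n_restore": n_restore, "n_enhance": n_enhance,
        "prevalence_p": prevalence_p,
        "compensatory_enrichment": {"odds_ratio": odds, "p": fisher_p},
        "wilcoxon": {
            "n_lines_significant_up":
                int((wilcoxon["p_restore_up"] < 0.05).sum()),
            "n_lines_significant_down":
                int((wilcoxon["p_restore_down"] < 0.05).sum()),
        },
        "breadth_correlation_r": r_breadth,
        "pan_cancer_bootstrap": boot,
    }

    # --- histone stoichiometry and complex membership
    fam_map = dataset.annotation["family"].dropna()
    fam_map = fam_map[fam_map.index.isin(tc.index)]
    fam_table = stoichiometry.family_signals(tc, tl, fam_map)
    cv = stoichiometry.stoichiometry_cv(fam_table)
    ctrl = dataset.truth.control_line
    others = cv.drop(index=ctrl)
    cstats = stoichiometry.complex_membership_stats(
        set(primary.index), dataset.complexes, universe)
    cboot = stoichiometry.complex_bootstrap(
        set(primary.index), dataset.complexes, universe,
        n_boot=config.stoichiometry.n_boot, seed=config.stoichiometry.seed)
    out["stoichiometry"] = {
        "n_lines_ratio_above_1": int((cv["coordination_ratio"] > 1).sum()),
        "n_lines": int(len(cv)),
        "control_line": ctrl,
        "control_ratio": float(cv.loc[ctrl, "coordination_ratio"]),
        "min_other_ratio": float(others["coordination_ratio"].min()),
        "complex_membership": cstats,
        "complex_bootstrap_p": cboot["p"],
    }

    # --- prognosis concordance
    prog_table, prog_summary = prognosis.restore_prognosis_concordance(
        classified, dataset.cohort, alpha=config.prognosis.alpha)
    out["prognosis"] = prog_summary

    # --- recovery against planted truth
    out["recovery"] = evaluate_recovery(classified, dataset.truth.gene_class)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        from riborestore import io as rio
        rio.write_seg(segments, outdir / "segments.seg")
        direction.to_csv(outdir / "gene_direction.tsv", sep="\t")
        rio.write_expression_matrix(te, outdir / "te_matrix.tsv")
        te_summary.to_csv(outdir / "te_summary.tsv", sep="\t")
        primary.to_csv(outdir / "diffrep_primary.tsv", sep="\t")
        classified.to_csv(outdir / "restore_calls.tsv", sep="\t")
        wilcoxon.to_csv(outdir / "per_line_wilcoxon.tsv", sep="\t")
        cat_enrich.to_csv(outdir / "category_enrichment.tsv", sep="\t")
        cv.to_csv(outdir / "stoichiometry_cv.tsv", sep="\t")
        prog_table.to_csv(outdir / "prognosis_per_gene.tsv", sep="\t")
        (outdir / "summary.json").write_text(json.dumps(out, indent=1,
                                                        default=_json_default))
        config.save(outdir / "config_resolved.yaml")
    return out


def evaluate_recovery(classified: pd.DataFrame, gene_class: dict) -> dict:
    """Compare recovered classes to the planted truth.

    recovery = fraction of planted RESTORE genes recovered with their exact
    class; confusion = planted RESTORE classified as ENHANCE or vice versa,
    as a fraction of planted genes that were classified at all.
    """
    planted_restore = {g for g, c in gene_class.items() if c.startswith("RESTORE")}
    got = classified["class"]
    exact = sum(1 for g in planted_restore
                if g in got.index and got[g] == gene_class[g])
    planted_classified = [g for g in gene_class if g in got.index]
    confused = sum(
        1 for g in planted_classified
        if got[g].split("_")[0] != gene_class[g].split("_")[0])
    return {
        "n_planted_restore": len(planted_restore),
        "n_restore_recovered": exact,
        "restore_recovery_fraction": exact / len(planted_restore)
        if planted_restore else float("nan"),
        "n_planted_classified": len(planted_classified),
        "n_cross_class_confused": confused,
        "confusion_fraction": confused / len(planted_classified)
        if planted_classified else float("nan"),
    }


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.DataFrame):
        return o.to_dict()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_synthetic(
    sim_config: SimulationConfig | None = None,
    run_config: RunConfig | None = None,
    outdir: str | Path | None = None,
) -> tuple[SyntheticDataset, dict]:
    """Convenience wrapper: simulate with defaults, then analyse."""
    sim_config = sim_config or SimulationConfig()
    dataset = simulate_all(sim_config,
                           outdir=None if outdir is None
                           else Path(outdir) / "inputs")
    summary = run_pipeline(dataset, run_config, outdir=outdir)
    return dataset, summary
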