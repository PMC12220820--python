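"""End-to-end synthetic benchmark: simulate -> derive -> score -> screen.

:func:`run_benchmark` chains every pipeline stage on synthetic data with
planted ground truth and reports recovery metrics:

1. packaged catalog / panel fixture counts;
2. bulk time-course simulation and panel derivation (Jaccard of the
   derived panel against the planted core responders);
3. single-cell simulation, rank-AUC scoring, automatic threshold
   stratification (balanced accuracy against latent labels, per-group
   high-activity fractions);
4. planted score-shift slopes, confidence-interval coverage, and the
   bootstrap slope ratio;
5. an adult-vs-neonatal contrast signature, preranked panel enrichment,
   and a 3-dataset signature-reversal consensus screen (reverser/mimic
   retention).

The report is a plain JSON-serializable dict, byte-reproducible given the
seed.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from . import connectivity as conn
from . import scoring
from .genesets import build_catalog, catalog_summary, read_gmt
from .panel import (
    Panel,
    cross_model_ranksum_filter,
    derive_panel,
    injury_responsive_set,
    moderated_t_test,
)
from .simulate import (
    BulkSimConfig,
    CellSimConfig,
    LibrarySimConfig,
    simulate_bulk_timecourse,
    simulate_cell_population,
    simulate_perturbation_library,
    simulate_score_table,
)

__all__ = [
    "packaged_catalog",
    "packaged_panel",
    "derive_panel_from_sim",
    "contrast_logfc",
    "balanced_accuracy",
    "run_benchmark",
]

_DATA = resources.files("thanatoset") / "data"


def packaged_catalog():
    """The packaged 13-pathway pan-PCD catalog (synthetic stand-in fixture)."""
    with resources.as_file(_DATA / "pan_pcd_pathways.synthetic.gmt") as p:
        return build_catalog(read_gmt(p))


def packaged_panel() -> Panel:
    """The packaged 68-gene core panel (synthetic stand-in fixture)."""
    with resources.as_file(_DATA / "thanatoset_panel.synthetic.tsv") as p:
        return Panel.from_tsv(p)


def derive_panel_from_sim(per_model, truth, primary_model: str = "crush"):
    """Run the full derivation pipeline on simulated bulk data.

    Moderated t per acute time point (injured vs sham, adult samples) in
    the primary model, DEG union intersected with the planted catalog,
    then a rank-sum filter in every other model, then the cross-model
    intersection.

    Returns ``(panel, details)`` where details holds the intermediate set
    sizes.
    """
    catalog = truth.extras["catalog"]
    expr = per_model[primary_model]
    timepoints = [t for t in expr.sample_meta["timepoint"].unique() if t != "sham"]
    sham = expr.samples_where(timepoint="sham", age="adult")
    deg_by_tp = {}
    for tp in timepoints:
        injured = expr.samples_where(timepoint=tp, age="adult")
        deg_by_tp[tp] = moderated_t_test(expr, sham, injured)
    responsive, provenance = injury_responsive_set(deg_by_tp, catalog)

    per_model_sets = {primary_model: responsive}
    dropped: dict[str, list[str]] = {}
    for model, mexpr in per_model.items():
        if model == primary_model:
            continue
        adult_cols = mexpr.samples_where(age="adult")
        sub = type(mexpr)(
            values=mexpr.values[adult_cols],
            sample_meta=mexpr.sample_meta.loc[adult_cols],
        )
        retained, missing = cross_model_ranksum_filter(responsive, sub)
        per_model_sets[model] = retained
        dropped[model] = missing

    panel = derive_panel(
        per_model_sets, catalog, provenance={g: {"timepoints": ",".join(tps)} for g, tps in provenance.items()}
    )
    details = {
        "n_injury_responsive": len(responsive),
        "per_model_retained": {m: len(s) for m, s in per_model_sets.items()},
        "dropped_missing": dropped,
    }
    return panel, details


def contrast_logfc(adata_a, adata_b, pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-gene log2 fold change (A vs B) of mean CPM with Welch-t p-values.

    A lightweight cellular contrast: cells are CPM-normalized and
    log2(1+x)-transformed; logFC is the difference of group means and p a
    two-sided Welch t-test per gene.  Returns a DEG-style table.
    """

    def _log_cpm(adata):
        X = np.asarray(adata.X.todense(), dtype=float) if hasattr(adata.X, "todense") else np.asarray(adata.X, dtype=float)
        lib = X.sum(axis=1, keepdims=True)
        return np.log2(pseudocount + 1e6 * X / np.maximum(lib, 1.0))

    a = _log_cpm(adata_a)
    b = _log_cpm(adata_b)
    logfc = a.mean(axis=0) - b.mean(axis=0)
    t, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    return pd.DataFrame(
        {"logFC": logfc, "t": t, "p": p}, index=pd.Index(adata_a.var_names, name="gene")
    )


def balanced_accuracy(truth_labels: pd.Series, predicted: pd.Series, positive: str = "high") -> float:
    t = truth_labels.to_numpy() == positive
    p = predicted.to_numpy() == positive
    tpr = (t & p).sum() / max(t.sum(), 1)
    tnr = (~t & ~p).sum() / max((~t).sum(), 1)
    return float((tpr + tnr) / 2.0)


def run_benchmark(seed: int = 1, n_cells: int = 2000, n_perm: int = 1000) -> dict:
    """Execute the full synthetic benchmark and return the report dict."""
    report: dict = {"seed": int(seed)}

    # 1. packaged fixtures -------------------------------------------------
    catalog = packaged_catalog()
    panel_fixture = packaged_panel()
    summary = catalog_summary(catalog)
    fixture_types = set()
    for g in panel_fixture.genes:
        fixture_types |= set(catalog.entries.get(g, ()))
    report["fixtures"] = {
        "catalog_genes": summary["union_size"],
        "catalog_pcd_types": summary["n_types"],
        "panel_genes": len(panel_fixture),
        "panel_pcd_types": len(fixture_types),
    }

    # 2. bulk simulation and panel derivation ------------------------------
    bulk_cfg = BulkSimConfig(seed=seed)
    per_model, bulk_truth = simulate_bulk_timecourse(bulk_cfg)
    derived, details = derive_panel_from_sim(per_model, bulk_truth)
    core = set(bulk_truth.responder_genes["core"])
    got = set(derived.genes)
    jaccard = len(core & got) / len(core | got)
    report["derivation"] = {
        "planted_core": len(core),
        "derived_panel": len(got),
        "jaccard": float(jaccard),
        **details,
    }

    # 3. single-cell scoring and stratification ----------------------------
    # one population, both ages, shared baseline abundances: high-activity
    # prevalence rises with injury in adults but stays near baseline in
    # neonates
    cell_cfg = CellSimConfig(
        seed=seed + 1,
        n_cells=n_cells,
        panel=tuple(derived.genes),
        ages=("adult", "neonatal"),
        high_fraction={
            ("sham", "adult"): 0.2,
            ("injured", "adult"): 0.6,
            ("sham", "neonatal"): 0.2,
            ("injured", "neonatal"): 0.2,
        },
    )
    adata, cell_truth = simulate_cell_population(cell_cfg)
    score_table = scoring.score_cells(adata, derived, seed=seed + 2)
    thr = scoring.detect_threshold(score_table["auc_score"])
    stratified = scoring.stratify_cells(score_table, thr.threshold)
    bal_acc = balanced_accuracy(cell_truth.cell_labels, stratified["stratum"])
    frac = scoring.stratum_summary(stratified, by=["group", "age"]).set_index(["group", "age"])[
        "high_fraction"
    ]
    report["stratification"] = {
        "threshold": float(thr.threshold),
        "threshold_method": thr.method,
        "balanced_accuracy": float(bal_acc),
        "high_fraction_sham": float(frac.get(("sham", "adult"), np.nan)),
        "high_fraction_injured": float(frac.get(("injured", "adult"), np.nan)),
        "n_cells": int(adata.n_obs),
    }

    # 4. planted score shifts: slopes and slope ratio ----------------------
    shifts = {"adult": 0.16, "neonatal": 0.02}
    scores, score_truth = simulate_score_table(shifts, n_per_group=n_cells, seed=seed + 3)
    slopes = scoring.group_slope(scores, "sham", {"injured"}, by="cell_type").set_index("cell_type")
    arms = {
        arm: (
            scores.loc[(scores.cell_type == arm) & (scores.group == "sham"), "auc_score"].to_numpy(),
            scores.loc[(scores.cell_type == arm) & (scores.group == "injured"), "auc_score"].to_numpy(),
        )
        for arm in shifts
    }
    ratio = scoring.slope_ratio(arms["adult"], arms["neonatal"], n_boot=n_perm, seed=seed + 4)
    report["slopes"] = {
        "adult_slope": float(slopes.loc["adult", "slope"]),
        "adult_ci": [float(slopes.loc["adult", "ci_low"]), float(slopes.loc["adult", "ci_high"])],
        "neonatal_slope": float(slopes.loc["neonatal", "slope"]),
        "neonatal_ci": [
            float(slopes.loc["neonatal", "ci_low"]),
            float(slopes.loc["neonatal", "ci_high"]),
        ],
        "planted_shifts": score_truth.score_shifts,
        "planted_ratio": float(shifts["adult"] / shifts["neonatal"]),
        "slope_ratio": float(ratio["ratio"]),
        "ratio_ci": [float(ratio["ci_low"]), float(ratio["ci_high"])],
    }

    # 5. contrast signature, enrichment, and consensus screen --------------
    injured = adata[adata.obs["group"] == "injured"]
    adult_injured = injured[injured.obs["age"] == "adult"]
    neo_injured = injured[injured.obs["age"] == "neonatal"]
    deg = contrast_logfc(adult_injured, neo_injured)
    signature = conn.build_query_signature(deg, derived, description="adult vs neonatal injured")
    enr = conn.preranked_enrichment(
        deg["logFC"], derived, n_perm=n_perm, seed=seed + 6
    )
    sig_dirs = {
        "up_matches_planted": sorted(signature.up)
        == sorted(set(cell_truth.responder_genes["panel_up"]) & set(signature.logfc.index)),
        "down_matches_planted": sorted(signature.down)
        == sorted(set(cell_truth.responder_genes["panel_down"]) & set(signature.logfc.index)),
    }

    tables = {}
    lib_truth = None
    for i in range(3):
        lib_cfg = LibrarySimConfig(query=signature.logfc, seed=seed + 10 + i)
        library, lib_truth = simulate_perturbation_library(lib_cfg)
        tables[f"dataset{i + 1}"] = conn.screen_library(
            library, signature, n_perm=n_perm, seed=seed + 20 + i
        )
    consensus = conn.consensus_screen(tables, alpha=0.05)
    retained = consensus.index[consensus["retained"]]
    classes = lib_truth.compound_classes
    report["screen"] = {
        "signature_up": len(signature.up),
        "signature_down": len(signature.down),
        "signature_direction_match": sig_dirs,
        "panel_nes": float(enr.nes),
        "panel_es": float(enr.es),
        "panel_enrichment_p": float(enr.p),
        "reversers_retained": int(sum(classes[c] == "reverser" for c in retained)),
        "mimics_retained": int(sum(classes[c] == "mimic" for c in retained)),
        "inert_retained": int(sum(classes[c] == "inert" for c in retained)),
        "n_reversers_planted": int(sum(v == "reverser" for v in classes.values())),
        "n_mimics_planted": int(sum(v == "mimic" for v in classes.values())),
        "n_compounds": len(classes),
    }
    return report
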