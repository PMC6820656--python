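"""End-to-end orchestration: simulate/load -> differential expression ->
subnetwork -> NSR + knowledge filter -> evaluation -> enrichment.

Stages communicate only through files under the output directory, so any
stage can be re-run or audited from its persisted inputs, and the final
report aggregates numbers that are all re-derivable from those files.
All randomness derives from the single config seed via per-stage seed
derivation, so a rerun with the same config is deterministic.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import data_io, diffexpr, enrichment, evaluation, network as netmod, nsr as nsrmod
from . import synthetic
from .data_io import RunConfig
from .errors import InputError

logger = logging.getLogger(__name__)

__all__ = ["run_all", "analyze", "stage_seed", "simulate_inputs"]


def stage_seed(seed: int, stage: int) -> int:
    """Deterministic per-stage seed below 2**31 derived from the run seed."""
    return int(np.random.SeedSequence([int(seed), int(stage)]).generate_state(1)[0] % (2**31))


def simulate_inputs(config: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate all pipeline input files from the synthetic generator and
    return their paths.  Generator parameters come from ``config.simulate``
    (missing keys use the generator defaults)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = dict(config.simulate)
    net_keys = {
        "n_mirna", "n_mrna", "mean_targets", "n_planted", "planted_excess_singles",
        "de_frac", "de_log2fc", "n_decoy_resistance", "resistance_per_biomarker",
    }
    expr_keys = {"n_sensitive", "n_resistant", "sigma"}
    clin_keys = {"baseline_hazard", "censor_rate", "post_progression_factor"}
    unknown = set(sim) - net_keys - expr_keys - clin_keys
    if unknown:
        raise InputError(f"unknown simulate parameters: {sorted(unknown)}")

    net, truth = synthetic.generate_network(
        **{k: v for k, v in sim.items() if k in net_keys},
        seed=stage_seed(config.seed, 1),
    )
    expr_mi, expr_mr, groups = synthetic.generate_expression(
        net, truth,
        **{k: v for k, v in sim.items() if k in expr_keys},
        seed=stage_seed(config.seed, 2),
    )
    clinical = synthetic.generate_clinical(
        expr_mi, truth,
        **{k: v for k, v in sim.items() if k in clin_keys},
        seed=stage_seed(config.seed, 3),
    )

    paths = {
        "network": outdir / "network.tsv",
        "mirna_expr": outdir / "mirna_expr.tsv",
        "mrna_expr": outdir / "mrna_expr.tsv",
        "groups": outdir / "groups.tsv",
        "clinical": outdir / "clinical.tsv",
        "resistance_genes": outdir / "resistance_genes.txt",
        "gene_sets": outdir / "gene_sets.gmt",
        "truth": outdir / "truth.json",
    }
    data_io.write_network(net, paths["network"])
    data_io.write_expression(expr_mi, paths["mirna_expr"], corner="mirna")
    data_io.write_expression(expr_mr, paths["mrna_expr"], corner="gene")
    data_io.write_groups(groups, paths["groups"])
    data_io.write_clinical(clinical, paths["clinical"])
    with open(paths["resistance_genes"], "w") as fh:
        for g in truth.resistance_genes:
            fh.write(g + "\n")
    _write_synthetic_gene_sets(net, truth, paths["gene_sets"], stage_seed(config.seed, 4))
    data_io.write_report(truth.to_dict(), paths["truth"])
    return paths


def _write_synthetic_gene_sets(net, truth, path: Path, seed: int) -> None:
    rng = np.random.default_rng(seed)
    sets = {"resistance_genes": ("planted resistance annotations",
                                 tuple(truth.resistance_genes))}
    pool = list(net.mrnas)
    for i in range(3):
        size = min(15, len(pool))
        members = tuple(pool[j] for j in rng.choice(len(pool), size=size, replace=False))
        sets[f"random_set_{i + 1}"] = ("random control set", members)
    data_io.write_gene_sets(data_io.GeneSetCollection(sets), path)


def analyze(
    reference,
    expr_mirna: pd.DataFrame,
    expr_mrna: pd.DataFrame,
    groups: pd.Series,
    resistance_genes,
    config: RunConfig | None = None,
) -> dict:
    """In-memory analysis core: DE -> subnetwork -> NSR -> selection.

    Returns a dict with keys de_mirnas, de_mrnas, subnetwork, nsr_table
    (None when the subnetwork is empty) and selected (list of miRNA IDs).
    Used by callers that do not need per-stage files.
    """
    config = config or RunConfig()
    table_mi, _ = diffexpr.moderated_t(expr_mirna, groups)
    table_mr, _ = diffexpr.moderated_t(expr_mrna, groups)
    de_mi = diffexpr.filter_de(table_mi, config.fc_hi, config.fc_lo, config.de_alpha)
    de_mr = diffexpr.filter_de(table_mr, config.fc_hi, config.fc_lo, config.de_alpha)
    sub = netmod.extract_subnetwork(reference, de_mi, de_mr)
    out = {"de_mirnas": de_mi, "de_mrnas": de_mr, "subnetwork": sub,
           "nsr_table": None, "selected": []}
    if sub.n_edges > 0:
        table = nsrmod.nsr_table(
            sub, resistance_genes,
            nsr_alpha=config.nsr_alpha,
            method=config.nsr_method,
            n_perm=config.n_perm,
            seed=stage_seed(config.seed, 5),
        )
        out["nsr_table"] = table
        out["selected"] = [m for m, row in table.iterrows() if row["selected"]]
    return out


def _de_stage(expr_path, groups, config: RunConfig, out_path: Path):
    expr = data_io.read_expression(expr_path)
    table, params = diffexpr.moderated_t(expr, groups)
    table = diffexpr.add_de_flag(table, fc_hi=config.fc_hi, fc_lo=config.fc_lo,
                                 alpha=config.de_alpha)
    table.to_csv(out_path, sep="\t", index_label="feature")
    de_ids = [f for f, flag in zip(table.index, table["is_de"]) if flag]
    return table, de_ids, params


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    """Execute every stage in order and write ``report.json``.

    Returns the report dictionary.  When ``config.paths`` is non-empty
    the stages read those input files; otherwise inputs are simulated
    under ``<outdir>/inputs`` using the generator parameters in
    ``config.simulate`` (missing parameters fall back to the generator
    defaults).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.paths:
        paths = {k: Path(v) for k, v in config.paths.items()}
        required = ("network", "mirna_expr", "mrna_expr", "groups")
        missing = [k for k in required if k not in paths]
        if missing:
            raise InputError(f"config.paths missing required entries: {missing}")
        for k, p in paths.items():
            if not p.exists():
                raise InputError(f"input path for {k!r} does not exist: {p}")
    else:
        paths = simulate_inputs(config, outdir / "inputs")

    report: dict = {"seed": config.seed, "config": {
        k: v for k, v in vars(config).items() if k not in ("paths", "simulate")
    }}

    # --- stage 1: differential expression ------------------------------
    groups = data_io.read_groups(paths["groups"])
    _, de_mirnas, _ = _de_stage(paths["mirna_expr"], groups, config, outdir / "de_mirna.tsv")
    _, de_mrnas, _ = _de_stage(paths["mrna_expr"], groups, config, outdir / "de_mrna.tsv")
    report["de"] = {"n_de_mirnas": len(de_mirnas), "n_de_mrnas": len(de_mrnas)}
    logger.info("DE: %d miRNAs, %d mRNAs", len(de_mirnas), len(de_mrnas))

    # --- stage 2: subnetwork + topology --------------------------------
    reference = data_io.read_network(paths["network"])
    sub = netmod.extract_subnetwork(reference, de_mirnas, de_mrnas)
    data_io.write_network(sub, outdir / "subnetwork.tsv")
    subnet_report: dict = {
        "n_edges": sub.n_edges,
        "n_mirnas": len(sub.mirnas),
        "n_mrnas": len(sub.mrnas),
        "powerlaw": None,
        "hub_and_bottleneck_mirnas": [],
    }
    topo = None
    if sub.n_edges > 0:
        topo = netmod.topology(sub, hub_fraction=config.hub_fraction)
        topo.to_csv(outdir / "topology.tsv", sep="\t")
        both = topo[(topo["kind"] == "mirna") & topo["hub"] & topo["bottleneck"]]
        subnet_report["hub_and_bottleneck_mirnas"] = sorted(both.index)
        try:
            fit = netmod.powerlaw_fit(sub)
            subnet_report["powerlaw"] = vars(fit)
        except Exception as exc:  # degenerate degree distribution
            logger.warning("power-law fit skipped: %s", exc)
    report["subnetwork"] = subnet_report

    # --- stage 3: NSR + knowledge filter -------------------------------
    selected: list[str] = []
    nsr_report: dict = {"selected_biomarkers": [], "comparison": {}}
    if sub.n_edges > 0 and "resistance_genes" in paths:
        resistance = data_io.read_gene_sets(paths["resistance_genes"])
        table = nsrmod.nsr_table(
            sub, resistance,
            nsr_alpha=config.nsr_alpha,
            method=config.nsr_method,
            n_perm=config.n_perm,
            seed=stage_seed(config.seed, 5),
        )
        table.to_csv(outdir / "nsr.tsv", sep="\t")
        selected = [m for m, row in table.iterrows() if row["selected"]]
        nsr_report["selected_biomarkers"] = selected
        if selected:
            sub_nsr = nsrmod.compute_nsr(sub)
            sel_vals = [sub_nsr[m] for m in selected]
            nsr_report["comparison"]["selected_vs_subnetwork_p"] = nsrmod.compare_nsr_groups(
                sel_vals, list(sub_nsr.values())
            )
            ref_nsr = nsrmod.compute_nsr(reference)
            nsr_report["comparison"]["selected_vs_reference_p"] = nsrmod.compare_nsr_groups(
                sel_vals, list(ref_nsr.values())
            )
    report["nsr"] = nsr_report
    logger.info("selected biomarkers: %s", selected)

    # --- stage 4: evaluation -------------------------------------------
    eval_report: dict = {}
    if selected:
        expr_mi = data_io.read_expression(paths["mirna_expr"])
        clinical = data_io.read_clinical(paths["clinical"]) if "clinical" in paths else None
        rows = []
        for m in selected:
            entry: dict = {}
            roc = evaluation.roc_auc(expr_mi.loc[m], groups, mirna_id=m)
            entry["auc"] = roc.auc
            if clinical is not None:
                for endpoint in ("PFS", "OS"):
                    try:
                        fit = evaluation.km_logrank(expr_mi.loc[m], clinical,
                                                    endpoint=endpoint,
                                                    quartile=config.quartile)
                        entry[f"{endpoint.lower()}_logrank_p"] = fit.p
                        entry[f"{endpoint.lower()}_threshold"] = fit.split_threshold
                    except InputError as exc:
                        logger.warning("%s %s survival skipped: %s", m, endpoint, exc)
            eval_report[m] = entry
            rows.append({"mirna": m, **entry})
        pd.DataFrame(rows).set_index("mirna").to_csv(outdir / "evaluation.tsv", sep="\t")
    report["evaluation"] = eval_report

    # --- stage 5: enrichment of selected-biomarker targets -------------
    enrich_report: dict = {"n_tested": 0, "n_significant": 0}
    if selected and "gene_sets" in paths:
        gene_sets = data_io.read_gene_sets(paths["gene_sets"])
        query = sorted({g for m in selected for g in sub.targets(m)})
        universe = list(reference.mrnas)
        if query:
            table = enrichment.ora(query, gene_sets, universe,
                                   alpha=config.enrich_alpha,
                                   fold_cut=config.enrich_fold)
            table.to_csv(outdir / "enrichment.tsv", sep="\t")
            enrich_report = {
                "n_tested": int(len(table)),
                "n_significant": int(table["significant"].sum()),
                "significant_sets": sorted(table.index[table["significant"]]),
            }
    report["enrichment"] = enrich_report

    data_io.write_report(report, outdir / "report.json")
    return report
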