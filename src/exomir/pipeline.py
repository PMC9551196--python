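"""End-to-end orchestration: simulate (or load) -> DE -> partition -> vote ->
network decomposition/scoring -> stage subnetworks -> ROC/survival/drug ->
ceRNA, with every intermediate written as a diffable text artifact and a JSON
run report auditing row counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import cerna as cerna_mod
from . import evalstats, io, stagesets, synthdata, targetdb, tpoma
from .errors import DegenerateStatisticError, InputError
from .exprde import HEALTHY, STAGES, ExpressionStudy

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str = "exomir_out"
    seed: int = 0
    simulate: bool = True
    # input paths, used when simulate is False
    expression: str | None = None
    samples: str | None = None
    evidence: str | None = None
    relevance: str | None = None
    tfs: str | None = None
    survival: str | None = None
    ic50: str | None = None
    cerna_expr: str | None = None
    mirna_lncrna: str | None = None
    # thresholds (defaults are the workflow's published operating points)
    p_max: float = 0.05
    lfc_min: float = 1.0
    use_adjusted: bool = False
    top_frac: float = 0.2
    pred_min: int = 4
    valid_min: int = 2
    relevance_min: float = 5.0
    top_k: int = 15
    indegree_min: int = 5
    auc_flag: float = 0.85
    stage_auc_flag: float = 0.65
    cerna_p_max: float = 0.05
    sim: dict = field(default_factory=dict)  # SimulationConfig overrides

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)


def flag_candidates(
    roc: pd.DataFrame, auc_col: str = "auc", threshold: float = 0.85
) -> pd.DataFrame:
    """Mark ROC rows whose AUC strictly exceeds the flag threshold."""
    out = roc.copy()
    out["flagged"] = out[auc_col] > threshold
    return out


def _sim_config(cfg: RunConfig) -> synthdata.SimulationConfig:
    return synthdata.SimulationConfig(seed=cfg.seed, **cfg.sim)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full workflow; returns the run report (also written as JSON)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # config echo records analysis parameters; the output location is omitted
    # so identical analyses give identical reports wherever they are written
    cfg_echo = {k: v for k, v in asdict(cfg).items() if k != "out_dir"}
    report: dict = {"version": __version__, "seed": cfg.seed,
                    "config": cfg_echo, "counts": {}, "stages": {}}

    # ------------------------------------------------ inputs
    truth = None
    if cfg.simulate:
        sim = synthdata.simulate_all(_sim_config(cfg))
        study, truth = sim.study, sim.truth
        evidence, relevance, tf_catalog = sim.evidence, sim.relevance, sim.tf_catalog
        outcomes = sim.outcomes
        io.write_expression(study.matrix, out / "expression.tsv")
        io.write_samples(study.sample_sheet, out / "samples.tsv")
        io.write_table(evidence, out / "evidence.tsv")
        io.write_table(relevance, out / "relevance.tsv")
        io.write_gene_list(tf_catalog, out / "tfs.txt")
        io.write_table(outcomes.survival, out / "survival.tsv")
        io.write_table(outcomes.drug, out / "ic50.tsv")
        io.write_expression(outcomes.cerna_expr, out / "cerna_expr.tsv")
        io.write_table(outcomes.mirna_lncrna, out / "mirna_lncrna.tsv")
        (out / "truth.json").write_text(sim.truth.to_json())
        conserved_dbs = synthdata.conserved_only_dbs(sim.config)
        survival_tab, drug_tab = outcomes.survival, outcomes.drug
        cerna_expr, ml_pairs = outcomes.cerna_expr, outcomes.mirna_lncrna
    else:
        study = io.read_study(cfg.expression, cfg.samples)
        evidence = io.read_table(cfg.evidence, targetdb.EVIDENCE_COLUMNS, "evidence")
        relevance = io.read_table(cfg.relevance, ["gene", "score", "direct"],
                                  "relevance")
        tf_catalog = io.read_gene_list(cfg.tfs)
        survival_tab = io.read_table(cfg.survival, ["sample_id", "time", "event"],
                                     "survival") if cfg.survival else None
        drug_tab = io.read_table(cfg.ic50, ["cell_line", "ic50"], "ic50") \
            if cfg.ic50 else None
        cerna_expr = io.read_expression(cfg.cerna_expr) if cfg.cerna_expr else None
        ml_pairs = io.read_table(cfg.mirna_lncrna, ["mirna", "lncrna"],
                                 "mirna_lncrna") if cfg.mirna_lncrna else None
        conserved_dbs = set()
    report["counts"]["expression_features"] = len(study.matrix)
    report["counts"]["samples"] = study.matrix.shape[1]
    report["counts"]["evidence_records"] = len(evidence)

    # ------------------------------------------------ DE + partition
    de_sets = stagesets.stage_contrasts(study, p_max=cfg.p_max, lfc_min=cfg.lfc_min,
                                        use_adjusted=cfg.use_adjusted)
    for stage in STAGES:
        tab = pd.DataFrame(sorted(de_sets[stage]), columns=["feature", "direction"])
        io.write_table(tab, out / f"de_{stage}.tsv")
        report["stages"][stage] = {"n_de": len(tab)}
    partition = stagesets.partition_sc_ss(de_sets)
    (out / "partition.json").write_text(
        json.dumps(partition.to_dict(), indent=1, sort_keys=True))
    report["counts"]["sc_mirnas"] = len(partition.sc)
    report["counts"]["ss_mirnas"] = sum(len(v) for v in partition.ss.values())

    # ------------------------------------------------ evidence -> consensus pairs
    filtered = targetdb.filter_prediction_evidence(
        evidence, top_frac=cfg.top_frac, conserved_only_dbs=conserved_dbs)
    pairs = targetdb.consensus_vote(filtered, pred_min=cfg.pred_min,
                                    valid_min=cfg.valid_min)
    io.write_table(pairs.table, out / "pairs.tsv")
    report["counts"]["consensus_pairs"] = len(pairs.table)

    gene_universe = set(pairs.table["gene"])
    relevant = targetdb.relevance_filter(gene_universe, relevance,
                                         min_score=cfg.relevance_min)
    report["counts"]["relevant_genes"] = len(relevant)

    # ------------------------------------------------ tPOMA on SC miRNAs
    sc_active = partition.sc & {m for m, _ in pairs.pairs}
    if sc_active:
        net = tpoma.build_network(sc_active, pairs)
        dec = tpoma.decompose(net)
        scores = tpoma.score_mirnas(dec, net, relevant, tf_catalog)
        top_mirnas, top_genes = tpoma.select_candidates(
            scores, dec, relevant, top_k=cfg.top_k, indegree_min=cfg.indegree_min)
        io.write_table(tpoma.rank_mirnas(scores), out / "scores.tsv")
        io.write_table(top_mirnas, out / "candidates_mirna.tsv")
        io.write_table(top_genes, out / "candidates_gene.tsv")
        io.write_sif(net.edges, out / "sc_network.sif")
        report["counts"]["sc_network_edges"] = len(net.edges)
        report["counts"]["hotspot_genes"] = len(dec.hotspot)
        report["counts"]["candidate_mirnas"] = len(top_mirnas)
        report["counts"]["candidate_genes"] = len(top_genes)
        candidate_mirnas = list(top_mirnas["mirna"])
    else:
        logger.warning("no SC miRNA has consensus targets; skipping tPOMA")
        candidate_mirnas = []

    # ------------------------------------------------ SS stage subnetworks
    subnets = tpoma.build_stage_subnetworks(partition, pairs, relevant)
    for stage, sub in subnets.items():
        io.write_sif(sub.edges, out / f"subnet_{stage}.sif")
        report["stages"][stage]["subnet_edges"] = len(sub.edges)

    # ------------------------------------------------ ROC
    roc_rows = []
    for m in candidate_mirnas:
        r = evalstats.crc_auc(study, m)
        roc_rows.append({"mirna": m, "contrast": r.contrast, "auc": r.auc,
                         "direction": r.direction})
    roc = pd.DataFrame(roc_rows, columns=["mirna", "contrast", "auc", "direction"])
    roc = flag_candidates(roc, threshold=cfg.auc_flag)
    io.write_table(roc, out / "roc_sc.tsv")

    stage_rows, combined_rows = [], []
    for stage in STAGES:
        ss = sorted(partition.ss[stage])
        for m in ss:
            r = evalstats.stage_auc(study, m, stage)
            stage_rows.append({"mirna": m, "stage": stage, "auc": r.auc,
                               "direction": r.direction})
        if len(ss) >= 2:
            _, r = evalstats.fit_logistic_combined(
                study, ss, case=stage,
                control=[s for s in STAGES if s != stage])
            combined_rows.append({"stage": stage, "n_features": len(ss),
                                  "auc": r.auc})
    stage_roc = pd.DataFrame(stage_rows, columns=["mirna", "stage", "auc",
                                                  "direction"])
    stage_roc = flag_candidates(stage_roc, threshold=cfg.stage_auc_flag)
    io.write_table(stage_roc, out / "roc_ss.tsv")
    io.write_table(pd.DataFrame(combined_rows,
                                columns=["stage", "n_features", "auc"]),
                   out / "roc_combined.tsv")
    report["counts"]["flagged_sc"] = int(roc["flagged"].sum()) if len(roc) else 0
    report["counts"]["flagged_ss"] = int(stage_roc["flagged"].sum()) \
        if len(stage_roc) else 0

    # ------------------------------------------------ survival (mean split)
    surv_rows = []
    if survival_tab is not None and len(survival_tab):
        sdf = survival_tab.set_index("sample_id")
        common = [s for s in study.matrix.columns if s in sdf.index]
        for m in candidate_mirnas:
            vals = study.matrix.loc[m, common].to_numpy(dtype=float)
            try:
                high = evalstats.expression_split(vals, rule="mean")
            except DegenerateStatisticError:
                continue
            res = evalstats.logrank_test(
                sdf.loc[common, "time"].to_numpy(dtype=float),
                sdf.loc[common, "event"].to_numpy(dtype=int),
                high.astype(int))
            surv_rows.append({"mirna": m, "chi_sq": res.chi_sq, "p": res.p,
                              "significant": res.p < 0.05})
    io.write_table(pd.DataFrame(surv_rows,
                                columns=["mirna", "chi_sq", "p", "significant"]),
                   out / "survival_results.tsv")

    # ------------------------------------------------ drug response (median split)
    drug_rows = []
    if drug_tab is not None and len(drug_tab):
        gene_cols = [c for c in drug_tab.columns if c not in ("cell_line", "ic50")]
        for g in gene_cols:
            try:
                res = evalstats.drug_response_test(
                    drug_tab["ic50"].to_numpy(dtype=float),
                    drug_tab[g].to_numpy(dtype=float))
            except (DegenerateStatisticError, InputError):
                continue
            drug_rows.append({"gene": g, "t": res.statistic, "p": res.p,
                              "direction": res.direction})
    io.write_table(pd.DataFrame(drug_rows, columns=["gene", "t", "p", "direction"]),
                   out / "drug_results.tsv")

    # ------------------------------------------------ ceRNA
    if cerna_expr is not None and ml_pairs is not None:
        cand_pairs = pairs.targets_of(candidate_mirnas) if candidate_mirnas \
            else set()
        mrnas = {g for _, g in cand_pairs}
        lncs = set(ml_pairs["lncrna"])
        lm = cerna_mod.lncrna_mrna_pairs(cerna_expr, mrnas, lncs,
                                         p_max=cfg.cerna_p_max)
        triples = cerna_mod.find_triples(cand_pairs, ml_pairs, lm)
        ttab = cerna_mod.triples_table(triples)
        io.write_table(ttab, out / "triples.tsv")
        io.write_sif({(t.mirna, t.mrna) for t in triples},
                     out / "cerna_targets.sif", relation="targets")
        io.write_sif({(t.mirna, t.lncrna) for t in triples},
                     out / "cerna_sponges.sif", relation="sponges")
        io.write_sif({(t.lncrna, t.mrna) for t in triples},
                     out / "cerna_correlates.sif", relation="correlates")
        report["counts"]["cerna_triples"] = len(ttab)

    # ------------------------------------------------ report + audit
    for fname in sorted(p.name for p in out.glob("*.tsv")):
        with open(out / fname) as fh:
            nrows = max(sum(1 for _ in fh) - 1, 0)
        report.setdefault("file_rows", {})[fname] = nrows
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
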