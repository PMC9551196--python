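"""Synthetic cohort generator with planted ground truth.

Emulates every input the pipeline consumes: group-structured log2 expression
with planted stage-common (SC) and stage-specific (SS) shifts, multi-database
target evidence with per-database sensitivity and false-positive rates over a
planted true-pair set, phenotype-relevance and transcription-factor
annotations, proportional-hazards survival linked to a marker miRNA,
expression-linked IC50 for a small cell-line panel, and latent-factor
correlated lncRNA/mRNA expression carrying planted ceRNA triangles.

Everything random flows from one seeded generator per operation
(``default_rng([seed, op_index])``), so identical config + seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError
from .exprde import HEALTHY, STAGES, ExpressionStudy

DEFAULT_GROUP_SIZES = {
    HEALTHY: 11, "I": 20, "II": 20, "IIIA": 20, "IIIB": 16, "IV": 12,
}


@dataclass
class SimulationConfig:
    n_mirnas: int = 300
    n_genes: int = 800
    n_lncrnas: int = 60
    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    sc_frac: float = 0.10
    ss_frac: float = 0.10
    effect_log2fc: float = 2.0
    sigma: float = 0.7
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    n_pred_dbs: int = 8
    n_valid_dbs: int = 3
    n_conserved_dbs: int = 3
    db_sensitivity: float = 0.8
    db_fpr: float = 0.01
    conserved_frac_true: float = 0.9
    conserved_frac_false: float = 0.5
    single_line_frac: float = 0.35
    max_indegree: int = 6
    relevance_frac: float = 0.3
    tf_frac: float = 0.2
    hazard_beta: float = 1.0
    baseline_hazard: float = 1.0 / 730.0  # per day
    censor_rate: float = 0.3
    n_cell_lines: int = 22
    ic50_delta: float = 1.0
    n_cerna_samples: int = 100
    n_triples: int = 15
    seed: int = 0

    def validate(self) -> None:
        for name in ("sc_frac", "ss_frac", "db_sensitivity", "db_fpr",
                     "relevance_frac", "tf_frac", "censor_rate",
                     "single_line_frac", "conserved_frac_true",
                     "conserved_frac_false"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.sc_frac + self.ss_frac > 1.0:
            raise ConfigError("sc_frac + ss_frac must not exceed 1")
        for name in ("n_mirnas", "n_genes", "n_lncrnas", "n_pred_dbs",
                     "n_valid_dbs", "n_cell_lines", "n_cerna_samples"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if set(self.group_sizes) != set((HEALTHY,) + STAGES):
            raise ConfigError(
                f"group_sizes must cover exactly {(HEALTHY,) + STAGES}")
        if any(v <= 0 for v in self.group_sizes.values()):
            raise ConfigError("group_sizes values must be positive")
        if self.sigma <= 0:
            raise ConfigError("sigma must be positive")
        if self.n_conserved_dbs > self.n_pred_dbs:
            raise ConfigError("n_conserved_dbs cannot exceed n_pred_dbs")

    def _rng(self, op: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), op])


@dataclass
class GroundTruth:
    """Ledger of everything the generator planted, for recovery testing."""

    sc_mirnas: set = field(default_factory=set)
    ss_mirnas: dict = field(default_factory=dict)          # stage -> set of miRNA
    shifts: dict = field(default_factory=dict)             # mirna -> {stage: signed lfc}
    true_pairs: set = field(default_factory=set)           # {(mirna, gene)}
    relevant_genes: set = field(default_factory=set)
    tf_genes: set = field(default_factory=set)
    planted_single_line: dict = field(default_factory=dict)  # mirna -> set of genes
    planted_triples: set = field(default_factory=set)        # {(lncrna, mirna, mrna)}
    marker_mirna: str | None = None
    drug_genes: list = field(default_factory=list)
    lncrnas: list = field(default_factory=list)

    def validate(self) -> None:
        ss_all = [m for s in self.ss_mirnas.values() for m in s]
        if len(ss_all) != len(set(ss_all)):
            raise InputError("planted SS sets must be pairwise disjoint")
        if self.sc_mirnas & set(ss_all):
            raise InputError("planted SC and SS sets must be disjoint")
        indeg: dict[str, int] = {}
        for _, g in self.true_pairs:
            indeg[g] = indeg.get(g, 0) + 1
        for m, genes in self.planted_single_line.items():
            for g in genes:
                if indeg.get(g) != 1:
                    raise InputError(f"planted single-line gene {g} has indegree "
                                     f"{indeg.get(g)}")

    def to_json(self) -> str:
        payload = {
            "sc_mirnas": sorted(self.sc_mirnas),
            "ss_mirnas": {s: sorted(v) for s, v in sorted(self.ss_mirnas.items())},
            "shifts": {m: dict(sorted(v.items())) for m, v in sorted(self.shifts.items())},
            "true_pairs": sorted(map(list, self.true_pairs)),
            "relevant_genes": sorted(self.relevant_genes),
            "tf_genes": sorted(self.tf_genes),
            "planted_single_line": {m: sorted(v) for m, v in
                                    sorted(self.planted_single_line.items())},
            "planted_triples": sorted(map(list, self.planted_triples)),
            "marker_mirna": self.marker_mirna,
            "drug_genes": list(self.drug_genes),
            "lncrnas": list(self.lncrnas),
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            sc_mirnas=set(d["sc_mirnas"]),
            ss_mirnas={s: set(v) for s, v in d["ss_mirnas"].items()},
            shifts={m: {s: float(x) for s, x in v.items()}
                    for m, v in d["shifts"].items()},
            true_pairs={tuple(p) for p in d["true_pairs"]},
            relevant_genes=set(d["relevant_genes"]),
            tf_genes=set(d["tf_genes"]),
            planted_single_line={m: set(v) for m, v in d["planted_single_line"].items()},
            planted_triples={tuple(t) for t in d["planted_triples"]},
            marker_mirna=d.get("marker_mirna"),
            drug_genes=list(d.get("drug_genes", [])),
            lncrnas=list(d.get("lncrnas", [])),
        )


def _mirna_ids(n: int) -> list[str]:
    return [f"miR-{i:04d}" for i in range(1, n + 1)]


def _gene_ids(n: int) -> list[str]:
    return [f"GENE{i:04d}" for i in range(1, n + 1)]


def _lncrna_ids(n: int) -> list[str]:
    return [f"LNC{i:03d}" for i in range(1, n + 1)]


def gen_expression_study(cfg: SimulationConfig) -> tuple[ExpressionStudy, GroundTruth]:
    """Group-structured log2 expression with planted SC/SS shifts.

    Also plants the true miRNA-target pair set (with a known single-line
    fraction) and the ceRNA triangles, so the full truth ledger is available
    to every downstream generator.
    """
    cfg.validate()
    rng = cfg._rng(1)
    mirnas = _mirna_ids(cfg.n_mirnas)
    genes = _gene_ids(cfg.n_genes)
    lncrnas = _lncrna_ids(cfg.n_lncrnas)

    sample_ids, groups = [], []
    for grp in (HEALTHY,) + STAGES:
        for i in range(cfg.group_sizes[grp]):
            sample_ids.append(f"{grp}_{i + 1:02d}")
            groups.append(grp)
    sheet = pd.DataFrame({"group": groups}, index=pd.Index(sample_ids, name="sample_id"))

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_mirnas)
    mat = baseline[:, None] + cfg.sigma * rng.standard_normal(
        (cfg.n_mirnas, len(sample_ids)))

    n_sc = int(round(cfg.sc_frac * cfg.n_mirnas))
    n_ss = int(round(cfg.ss_frac * cfg.n_mirnas))
    planted_idx = rng.choice(cfg.n_mirnas, size=n_sc + n_ss, replace=False)
    sc_idx, ss_idx = planted_idx[:n_sc], planted_idx[n_sc:]
    signs = rng.choice([-1.0, 1.0], size=n_sc + n_ss)

    truth = GroundTruth(lncrnas=lncrnas)
    grp_arr = np.asarray(groups)
    for j, idx in enumerate(sc_idx):
        m = mirnas[idx]
        delta = signs[j] * cfg.effect_log2fc
        truth.sc_mirnas.add(m)
        truth.shifts[m] = {s: float(delta) for s in STAGES}
        mat[idx, grp_arr != HEALTHY] += delta
    truth.ss_mirnas = {s: set() for s in STAGES}
    for j, idx in enumerate(ss_idx):
        m = mirnas[idx]
        stage = STAGES[j % len(STAGES)]
        delta = signs[n_sc + j] * cfg.effect_log2fc
        truth.ss_mirnas[stage].add(m)
        truth.shifts[m] = {stage: float(delta)}
        mat[idx, grp_arr == stage] += delta

    # planted target pairs: per gene, indegree 1 with prob single_line_frac,
    # else uniform on 2..max_indegree
    single = rng.random(cfg.n_genes) < cfg.single_line_frac
    for gi, g in enumerate(genes):
        if single[gi]:
            k = 1
        else:
            k = int(rng.integers(2, max(cfg.max_indegree, 2) + 1))
        k = min(k, cfg.n_mirnas)
        regs = rng.choice(cfg.n_mirnas, size=k, replace=False)
        for ri in regs:
            truth.true_pairs.add((mirnas[ri], g))
        if k == 1:
            truth.planted_single_line.setdefault(mirnas[regs[0]], set()).add(g)

    # planted ceRNA triangles: distinct target pairs, distinct lncRNAs;
    # drawn from SC miRNAs' pairs when possible, mirroring the key-miRNA focus
    sc_pairs = sorted(p for p in truth.true_pairs if p[0] in truth.sc_mirnas)
    pair_list = sc_pairs if len(sc_pairs) >= cfg.n_triples else sorted(truth.true_pairs)
    n_triples = min(cfg.n_triples, cfg.n_lncrnas, len(pair_list))
    tri_pairs = rng.choice(len(pair_list), size=n_triples, replace=False)
    for t, pi in enumerate(tri_pairs):
        m, g = pair_list[pi]
        truth.planted_triples.add((lncrnas[t], m, g))

    truth.marker_mirna = sorted(truth.sc_mirnas)[0] if truth.sc_mirnas else mirnas[0]
    truth.validate()
    study = ExpressionStudy(
        matrix=pd.DataFrame(mat, index=pd.Index(mirnas, name="feature"),
                            columns=sample_ids),
        sample_sheet=sheet,
        meta={"seed": cfg.seed},
    )
    return study, truth


def pred_db_names(cfg: SimulationConfig) -> list[str]:
    return [f"pred_db_{i + 1}" for i in range(cfg.n_pred_dbs)]


def valid_db_names(cfg: SimulationConfig) -> list[str]:
    return [f"valid_db_{i + 1}" for i in range(cfg.n_valid_dbs)]


def conserved_only_dbs(cfg: SimulationConfig) -> set[str]:
    return set(pred_db_names(cfg)[: cfg.n_conserved_dbs])


def gen_evidence_tables(cfg: SimulationConfig, truth: GroundTruth) -> pd.DataFrame:
    """Per-database detection records over the planted true-pair set.

    True pairs are detected by each database with probability
    ``db_sensitivity`` and score Uniform(0, 0.2); false pairs appear with
    probability ``db_fpr`` and score Uniform(0, 1), so true pairs
    stochastically rank better under the p-value-like (smaller-better)
    confidence. Validation-database records carry no score. Conserved flags
    are attached to records from the conserved-only databases.
    """
    cfg.validate()
    if cfg.n_pred_dbs < 4:
        raise ConfigError("n_pred_dbs must be >= 4 (prediction vote threshold "
                          "of 4 databases would be unreachable)")
    if not truth.true_pairs:
        raise InputError("truth.true_pairs is empty")
    rng = cfg._rng(2)
    mirnas = _mirna_ids(cfg.n_mirnas)
    genes = _gene_ids(cfg.n_genes)
    m_index = {m: i for i, m in enumerate(mirnas)}
    g_index = {g: i for i, g in enumerate(genes)}

    true_sorted = sorted(truth.true_pairs)
    true_flat = np.array([m_index[m] * cfg.n_genes + g_index[g]
                          for m, g in true_sorted], dtype=np.int64)
    n_all = cfg.n_mirnas * cfg.n_genes
    false_flat = np.setdiff1d(np.arange(n_all, dtype=np.int64), true_flat,
                              assume_unique=False)
    cons_dbs = conserved_only_dbs(cfg)

    rows: list[tuple] = []

    def emit(db: str, dtype: str, flat_idx: np.ndarray, is_true: bool) -> None:
        mi, gi = np.divmod(flat_idx, cfg.n_genes)
        n = len(flat_idx)
        if dtype == "predicted":
            scores = rng.uniform(0.0, 0.2, n) if is_true else rng.uniform(0.0, 1.0, n)
        else:
            scores = np.full(n, np.nan)
        if db in cons_dbs:
            frac = cfg.conserved_frac_true if is_true else cfg.conserved_frac_false
            conserved = rng.random(n) < frac
        else:
            conserved = np.zeros(n, dtype=bool)
        for j in range(n):
            rows.append((mirnas[mi[j]], genes[gi[j]], db, dtype,
                         scores[j], bool(conserved[j])))

    for db in pred_db_names(cfg) + valid_db_names(cfg):
        dtype = "predicted" if db.startswith("pred") else "validated"
        hit = rng.random(len(true_flat)) < cfg.db_sensitivity
        emit(db, dtype, true_flat[hit], is_true=True)
        if cfg.db_fpr > 0 and len(false_flat):
            k = rng.binomial(len(false_flat), cfg.db_fpr)
            if k > 0:
                fp = rng.choice(false_flat, size=min(k, len(false_flat)),
                                replace=False)
                emit(db, dtype, np.sort(fp), is_true=False)

    table = pd.DataFrame(rows, columns=["mirna", "gene", "db", "type",
                                        "score", "conserved"])
    return table.sort_values(["db", "mirna", "gene"], kind="mergesort").reset_index(drop=True)


def gen_gene_annotations(
    cfg: SimulationConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, set[str]]:
    """Phenotype-relevance table and TF catalog; sets recorded in the truth.

    Planted relevant genes score Uniform(5, 20] with a direct association
    flag; all other genes either score at most 5 or lack the direct flag, so
    the downstream (score > 5 AND direct) filter recovers the planted set
    exactly.
    """
    cfg.validate()
    rng = cfg._rng(3)
    genes = _gene_ids(cfg.n_genes)
    n_rel = int(round(cfg.relevance_frac * cfg.n_genes))
    rel_idx = set(rng.choice(cfg.n_genes, size=n_rel, replace=False).tolist())
    n_tf = int(round(cfg.tf_frac * cfg.n_genes))
    tf_idx = set(rng.choice(cfg.n_genes, size=n_tf, replace=False).tolist())

    scores, directs = np.empty(cfg.n_genes), np.empty(cfg.n_genes, dtype=bool)
    for i in range(cfg.n_genes):
        if i in rel_idx:
            scores[i] = 5.0 + 15.0 * (1.0 - rng.random())  # in (5, 20]
            directs[i] = True
        elif rng.random() < 0.5:
            scores[i] = 5.0 * (1.0 - rng.random())  # in (0, 5]
            directs[i] = True
        else:
            scores[i] = 20.0 * rng.random()
            directs[i] = False
    table = pd.DataFrame({"gene": genes, "score": scores, "direct": directs})
    truth.relevant_genes = {genes[i] for i in rel_idx}
    truth.tf_genes = {genes[i] for i in tf_idx}
    return table, set(truth.tf_genes)


@dataclass
class OutcomeData:
    survival: pd.DataFrame      # sample_id, time (days), event
    drug: pd.DataFrame          # cell_line, <gene expression columns>, ic50
    cerna_expr: pd.DataFrame    # features (mRNA + lncRNA) x tumor samples
    mirna_lncrna: pd.DataFrame  # mirna, lncrna


def gen_outcome_data(
    cfg: SimulationConfig, study: ExpressionStudy, truth: GroundTruth
) -> OutcomeData:
    """Survival, drug-response, and ceRNA expression panels tied to the truth.

    Survival times are exponential with hazard h0 * exp(beta * x) on the
    standardized marker-miRNA expression of tumor samples, with independent
    exponential censoring calibrated to ``censor_rate``. IC50 across the
    cell-line panel shifts by ``ic50_delta`` between high and low expression
    of the designated drug gene. lncRNA/mRNA pairs inside planted triangles
    share a latent factor, giving positive co-expression.
    """
    cfg.validate()
    rng = cfg._rng(4)
    sheet = study.sample_sheet
    if not set(study.matrix.columns) <= set(sheet.index):
        raise InputError("sample IDs in matrix and sheet do not match")

    # --- survival for tumor samples, proportional hazards on the marker ---
    tumor = [s for s in study.matrix.columns
             if sheet.loc[s, "group"] != HEALTHY]
    marker = truth.marker_mirna or study.feature_ids[0]
    x = study.matrix.loc[marker, tumor].to_numpy(dtype=float)
    x = (x - x.mean()) / (x.std(ddof=0) or 1.0)
    rate = cfg.baseline_hazard * np.exp(cfg.hazard_beta * x)
    t_event = rng.exponential(1.0 / rate)
    if cfg.censor_rate > 0:
        rate_c = cfg.baseline_hazard * cfg.censor_rate / (1.0 - cfg.censor_rate)
        t_cens = rng.exponential(1.0 / rate_c, size=len(tumor))
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(len(tumor), dtype=int)
    survival = pd.DataFrame({"sample_id": tumor, "time": time, "event": event})

    # --- IC50 panel linked to the first designated drug gene ---
    drug_genes = sorted(truth.relevant_genes)[:3] or _gene_ids(cfg.n_genes)[:3]
    truth.drug_genes = list(drug_genes)
    cells = [f"CL{i + 1:02d}" for i in range(cfg.n_cell_lines)]
    expr = {g: rng.normal(8.0, 1.0, cfg.n_cell_lines) for g in drug_genes}
    g0 = drug_genes[0]
    high = expr[g0] > np.median(expr[g0])
    ic50 = 3.0 + cfg.ic50_delta * high + 0.3 * rng.standard_normal(cfg.n_cell_lines)
    drug = pd.DataFrame({"cell_line": cells, **expr, "ic50": ic50})

    # --- ceRNA expression panel with latent-factor planted triangles ---
    genes = _gene_ids(cfg.n_genes)
    feats = genes + list(truth.lncrnas)
    n_s = cfg.n_cerna_samples
    mu = rng.normal(6.0, 1.0, len(feats))
    panel = mu[:, None] + rng.standard_normal((len(feats), n_s))
    fi = {f: i for i, f in enumerate(feats)}
    for (l, _m, g) in sorted(truth.planted_triples):
        f = rng.standard_normal(n_s)
        panel[fi[l]] = mu[fi[l]] + f + 0.7 * rng.standard_normal(n_s)
        panel[fi[g]] = mu[fi[g]] + f + 0.7 * rng.standard_normal(n_s)
    cerna_expr = pd.DataFrame(
        panel, index=pd.Index(feats, name="feature"),
        columns=[f"TUM{i + 1:03d}" for i in range(n_s)])

    # --- validated miRNA-lncRNA interactions: planted plus decoys ---
    mirnas = _mirna_ids(cfg.n_mirnas)
    ml = sorted({(m, l) for (l, m, _g) in truth.planted_triples})
    planted_lnc = {l for (l, _m, _g) in truth.planted_triples}
    for l in truth.lncrnas:
        if l not in planted_lnc and rng.random() < 0.3:
            ml.append((mirnas[int(rng.integers(cfg.n_mirnas))], l))
    mirna_lncrna = pd.DataFrame(sorted(set(ml)), columns=["mirna", "lncrna"])
    return OutcomeData(survival=survival, drug=drug, cerna_expr=cerna_expr,
                       mirna_lncrna=mirna_lncrna)


@dataclass
class SimulatedData:
    config: SimulationConfig
    study: ExpressionStudy
    truth: GroundTruth
    evidence: pd.DataFrame
    relevance: pd.DataFrame
    tf_catalog: set[str]
    outcomes: OutcomeData


def simulate_all(cfg: SimulationConfig) -> SimulatedData:
    """Run all four generators in order and bundle the results."""
    study, truth = gen_expression_study(cfg)
    evidence = gen_evidence_tables(cfg, truth)
    relevance, tfs = gen_gene_annotations(cfg, truth)
    outcomes = gen_outcome_data(cfg, study, truth)
    return SimulatedData(config=cfg, study=study, truth=truth, evidence=evidence,
                         relevance=relevance, tf_catalog=tfs, outcomes=outcomes)


def config_to_dict(cfg: SimulationConfig) -> dict:
    return asdict(cfg)
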