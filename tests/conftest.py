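import numpy as np
import pandas as pd
import pytest

from exomir.exprde import ExpressionStudy
from exomir.synthdata import SimulationConfig

# schematic three-miRNA / four-gene regulation diagram: gene2 and gene4 are
# regulated only by miRNA1; gene1 by all three miRNAs; gene3 by miRNA2+miRNA3
FIG2_EDGES = {
    ("miRNA1", "gene1"), ("miRNA1", "gene2"), ("miRNA1", "gene4"),
    ("miRNA2", "gene1"), ("miRNA2", "gene3"),
    ("miRNA3", "gene1"), ("miRNA3", "gene3"),
}

# published top-26 vulnerability-score table: (miRNA, NCGSM-TF, NCGSM, NGSM, NGM)
# in its printed row order, and the hotspot-gene column (gene, indegree)
TABLE1_MIRNAS = [
    ("miR-30e-5p", 3, 16, 237, 573),
    ("miR-221-3p", 2, 10, 75, 251),
    ("miR-34c-5p", 2, 9, 101, 212),
    ("miR-767-5p", 2, 6, 33, 100),
    ("miR-539-5p", 2, 3, 55, 152),
    ("miR-23b-3p", 1, 16, 224, 489),
    ("miR-146a-5p", 1, 13, 87, 126),
    ("miR-25-3p", 1, 12, 163, 418),
    ("miR-548a-5p", 1, 6, 78, 210),
    ("miR-19a-3p", 1, 5, 166, 619),
    ("miR-331-3p", 1, 3, 30, 73),
    ("miR-142-5p", 1, 2, 66, 204),
    ("miR-186-5p", 0, 14, 181, 437),
    ("miR-22-3p", 0, 12, 78, 182),
    ("miR-142-3p", 0, 10, 117, 268),
    ("miR-613", 0, 4, 82, 206),
    ("miR-582-5p", 0, 4, 64, 195),
    ("miR-491-5p", 0, 4, 19, 44),
    ("miR-513a-3p", 0, 3, 83, 208),
    ("miR-185-5p", 0, 3, 68, 152),
    ("miR-197-3p", 0, 3, 23, 54),
    ("miR-214-3p", 0, 2, 71, 159),
    ("miR-324-3p", 0, 2, 27, 52),
    ("miR-454-3p", 0, 2, 26, 415),
    ("miR-642a-5p", 0, 2, 8, 17),
    ("miR-663a", 0, 2, 4, 4),
]

TABLE1_GENES = [
    ("PTEN", 13), ("QKI", 8), ("ZNF148", 7), ("KMT2C", 6), ("MET", 6),
    ("SMAD4", 6), ("CCND1", 6), ("PTPRD", 6), ("PTPRG", 6), ("SOX5", 6),
    ("ACSL4", 6), ("TSHZ1", 5), ("RAC1", 5), ("WNK1", 5), ("MAPK1", 5),
    ("CCNA2", 5), ("ESR1", 5), ("IGF1", 5), ("PTP4A1", 5), ("TGFBR2", 5),
    ("ZEB2", 5), ("ZNF217", 5), ("MYCN", 5), ("CDKN1A", 5), ("CDK6", 5),
    ("MCL1", 5),
]


@pytest.fixture
def fig2_edges():
    return set(FIG2_EDGES)


@pytest.fixture
def table1_scores():
    return pd.DataFrame(
        TABLE1_MIRNAS, columns=["mirna", "ncgsm_tf", "ncgsm", "ngsm", "ngm"])


@pytest.fixture
def table1_genes():
    return pd.DataFrame(TABLE1_GENES, columns=["gene", "indegree"])


def make_study(matrix, groups, feature_prefix="f"):
    """Small ExpressionStudy from a raw array and per-sample group labels."""
    matrix = np.asarray(matrix, dtype=float)
    features = [f"{feature_prefix}{i}" for i in range(matrix.shape[0])]
    samples = [f"s{j}" for j in range(matrix.shape[1])]
    return ExpressionStudy(
        matrix=pd.DataFrame(matrix, index=features, columns=samples),
        sample_sheet=pd.DataFrame({"group": list(groups)},
                                  index=pd.Index(samples, name="sample_id")),
    )


def small_sim_config(**overrides) -> SimulationConfig:
    """Fast simulation config for unit tests (not the study conditions)."""
    base = dict(
        n_mirnas=40, n_genes=80, n_lncrnas=10, n_triples=5,
        group_sizes={"healthy": 6, "I": 8, "II": 8, "IIIA": 8, "IIIB": 6,
                     "IV": 6},
        seed=0,
    )
    base.update(overrides)
    return SimulationConfig(**base)
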