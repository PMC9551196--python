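"""Bipartite miRNA-target network decomposition and vulnerability scoring.

The model rests on two assumptions about exosomal miRNA regulation:

* a gene targeted by exactly one miRNA in the network ("single-line" regulation,
  indegree 1) reflects regulatory *specificity* of that miRNA — the more
  disease-relevant single-line targets a miRNA has, the more important it is;
* a gene targeted by two or more miRNAs (a "hotspot", indegree >= 2) is under a
  heavier repressive burden from the circulating miRNA pool.

Per-miRNA vulnerability scores count, in decreasing strictness:
NGM = all targets; NGSM = single-line targets; NCGSM = disease-relevant
single-line targets; NCGSM-TF = disease-relevant single-line targets that are
transcription factors. Candidate miRNAs are ranked by descending
(NCGSM-TF, NCGSM, NGSM) with alphabetical tie-break; candidate hotspot genes by
descending indegree among disease-relevant hotspot genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import InputError
from .stagesets import StagePartition
from .targetdb import ConsensusPairs

logger = logging.getLogger(__name__)

SCORE_COLUMNS = ("mirna", "ngm", "ngsm", "ncgsm", "ncgsm_tf")


def _as_pair_set(pairs) -> set[tuple[str, str]]:
    if isinstance(pairs, ConsensusPairs):
        return pairs.pairs
    return {(m, g) for m, g in pairs}


@dataclass
class MirTargetNetwork:
    """Bipartite miRNA -> gene network as a duplicate-free edge set."""

    edges: frozenset[tuple[str, str]]
    indegree: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        indeg: dict[str, int] = {}
        for _, g in self.edges:
            indeg[g] = indeg.get(g, 0) + 1
        self.indegree = indeg

    @property
    def mirnas(self) -> set[str]:
        return {m for m, _ in self.edges}

    @property
    def genes(self) -> set[str]:
        return {g for _, g in self.edges}

    def targets_of(self, mirna: str) -> set[str]:
        return {g for m, g in self.edges if m == mirna}

    def regulators_of(self, gene: str) -> set[str]:
        return {m for m, g in self.edges if g == gene}


@dataclass
class Decomposition:
    """Partition of targeted genes into single-line and hotspot classes."""

    single_line: dict[str, set[str]]  # mirna -> its indegree-1 targets
    hotspot: dict[str, set[str]]      # gene (indegree >= 2) -> its regulators

    @property
    def single_line_genes(self) -> set[str]:
        return {g for gs in self.single_line.values() for g in gs}


@dataclass
class StageSubnetwork:
    stage: str
    edges: set[tuple[str, str]]

    @property
    def genes(self) -> set[str]:
        return {g for _, g in self.edges}


def build_network(mirnas: Iterable[str], pairs) -> MirTargetNetwork:
    """Restrict consensus pairs to the given miRNA set and build the network."""
    mirnas = set(mirnas)
    if not mirnas:
        raise InputError("miRNA set is empty")
    edges = frozenset((m, g) for m, g in _as_pair_set(pairs) if m in mirnas)
    if not edges:
        logger.warning("no consensus pairs survive for the %d given miRNAs", len(mirnas))
    return MirTargetNetwork(edges=edges)


def decompose(net: MirTargetNetwork) -> Decomposition:
    """Split targeted genes into single-line (indegree 1) and hotspot (>= 2)."""
    single_line: dict[str, set[str]] = {m: set() for m in net.mirnas}
    hotspot: dict[str, set[str]] = {}
    for m, g in net.edges:
        if net.indegree[g] == 1:
            single_line[m].add(g)
        else:
            hotspot.setdefault(g, set()).add(m)
    return Decomposition(single_line=single_line, hotspot=hotspot)


def score_mirnas(
    dec: Decomposition,
    net: MirTargetNetwork,
    relevant: set[str],
    tfs: set[str],
) -> pd.DataFrame:
    """One vulnerability score row (ngm, ngsm, ncgsm, ncgsm_tf) per miRNA.

    The relevance and TF intersections are taken on single-line targets only.
    """
    relevant, tfs = set(relevant), set(tfs)
    rows = []
    for m in sorted(net.mirnas):
        targets = net.targets_of(m)
        sl = dec.single_line.get(m, set())
        csl = sl & relevant
        rows.append({
            "mirna": m,
            "ngm": len(targets),
            "ngsm": len(sl),
            "ncgsm": len(csl),
            "ncgsm_tf": len(csl & tfs),
        })
    return pd.DataFrame(rows, columns=list(SCORE_COLUMNS))


def rank_mirnas(scores: pd.DataFrame) -> pd.DataFrame:
    """Sort descending by (ncgsm_tf, ncgsm, ngsm), then miRNA name ascending."""
    return scores.sort_values(
        ["ncgsm_tf", "ncgsm", "ngsm", "mirna"],
        ascending=[False, False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)


def rank_hotspot_genes(
    indegree: Mapping[str, int],
    relevant: set[str] | None = None,
    indegree_min: int = 2,
) -> pd.DataFrame:
    """Disease-relevant hotspot genes with indegree >= threshold, ranked."""
    items = [
        (g, d) for g, d in indegree.items()
        if d >= indegree_min and (relevant is None or g in relevant)
    ]
    items.sort(key=lambda t: (-t[1], t[0]))
    return pd.DataFrame(items, columns=["gene", "indegree"])


def select_candidates(
    scores: pd.DataFrame,
    dec: Decomposition,
    relevant: set[str],
    top_k: int = 15,
    indegree_min: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k ranked miRNAs and the relevant hotspot genes above the indegree cut.

    Gene indegree is counted within the relevance-filtered hotspot network
    (only relevant genes, regulators from the same decomposition).
    """
    ranked = rank_mirnas(scores)
    if top_k > len(ranked):
        logger.warning("top_k=%d exceeds %d available miRNAs; returning all",
                       top_k, len(ranked))
    top = ranked.head(top_k).reset_index(drop=True)
    hotspot_indeg = {g: len(ms) for g, ms in dec.hotspot.items() if g in set(relevant)}
    genes = rank_hotspot_genes(hotspot_indeg, indegree_min=indegree_min)
    return top, genes


def build_stage_subnetworks(
    partition: StagePartition,
    pairs,
    relevant: set[str],
) -> dict[str, StageSubnetwork]:
    """Per-stage subnetworks of SS miRNAs onto stage-exclusive relevant genes.

    A gene enters a stage's subnetwork only if it is targeted by that stage's
    SS miRNAs and by no other stage's.
    """
    pair_set = _as_pair_set(pairs)
    relevant = set(relevant)
    targets: dict[str, set[str]] = {}
    for stage, mirnas in partition.ss.items():
        targets[stage] = {g for m, g in pair_set if m in mirnas and g in relevant}
    out: dict[str, StageSubnetwork] = {}
    for stage, mirnas in partition.ss.items():
        others = set().union(*(targets[s] for s in targets if s != stage)) if len(targets) > 1 else set()
        exclusive = targets[stage] - others
        edges = {(m, g) for m, g in pair_set if m in mirnas and g in exclusive}
        out[stage] = StageSubnetwork(stage=stage, edges=edges)
    return out
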