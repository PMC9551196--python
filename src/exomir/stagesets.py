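"""Stage-common / stage-specific partitioning of differential miRNAs.

A miRNA differentially expressed versus healthy in all five tumor stages is
stage-common (SC); one differential in exactly one stage is stage-specific
(SS) for that stage. miRNAs hit in 2-4 stages are reported as "intermediate"
and belong to neither set — the Venn semantics of the five-way contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InputError
from .exprde import STAGES, HEALTHY, ExpressionStudy, moderated_t_test, threshold_de


@dataclass
class StagePartition:
    sc: set[str]
    ss: dict[str, set[str]]
    intermediate: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        all_ss = [m for s in self.ss.values() for m in s]
        if len(all_ss) != len(set(all_ss)):
            raise InputError("SS sets must be pairwise disjoint")
        if self.sc & set(all_ss):
            raise InputError("SC and SS sets must be disjoint")

    def to_dict(self) -> dict:
        return {
            "sc": sorted(self.sc),
            "ss": {s: sorted(v) for s, v in sorted(self.ss.items())},
            "intermediate": sorted(self.intermediate),
        }


def stage_contrasts(
    study: ExpressionStudy,
    p_max: float = 0.05,
    lfc_min: float = 1.0,
    use_adjusted: bool = False,
) -> dict[str, set[tuple[str, str]]]:
    """Run each stage-vs-healthy contrast and threshold it.

    Returns, per stage, the set of (miRNA, direction) pairs passing the
    differential-expression filter.
    """
    present = set(study.sample_sheet.loc[list(study.matrix.columns), "group"])
    missing = [g for g in (HEALTHY, *STAGES) if g not in present]
    if missing:
        raise InputError(f"study is missing group(s): {missing}")
    out: dict[str, set[tuple[str, str]]] = {}
    for stage in STAGES:
        table = moderated_t_test(study, case=stage, control=HEALTHY)
        out[stage] = threshold_de(table, p_max=p_max, lfc_min=lfc_min,
                                  use_adjusted=use_adjusted)
    return out


def partition_sc_ss(
    sets: dict[str, set[tuple[str, str]]],
    strict_direction: bool = False,
) -> StagePartition:
    """Partition DE sets into SC (all five stages) and SS (exactly one).

    Membership is by miRNA identity; with ``strict_direction`` the SC set
    additionally requires a consistent sign across all five contrasts.
    """
    if set(sets) != set(STAGES):
        raise InputError(f"expected exactly stages {STAGES}, got {sorted(sets)}")
    members: dict[str, list[str]] = {}
    signs: dict[str, set[str]] = {}
    for stage in STAGES:
        for mirna, direction in sets[stage]:
            members.setdefault(mirna, []).append(stage)
            signs.setdefault(mirna, set()).add(direction)
    sc: set[str] = set()
    ss: dict[str, set[str]] = {s: set() for s in STAGES}
    intermediate: set[str] = set()
    for mirna, stages in members.items():
        n = len(set(stages))
        if n == len(STAGES):
            if strict_direction and len(signs[mirna]) > 1:
                intermediate.add(mirna)
            else:
                sc.add(mirna)
        elif n == 1:
            ss[stages[0]].add(mirna)
        else:
            intermediate.add(mirna)
    return StagePartition(sc=sc, ss=ss, intermediate=intermediate)
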