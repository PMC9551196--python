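"""Competing-endogenous-RNA (ceRNA) triple discovery.

A ceRNA triangle (lncRNA L, miRNA m, mRNA G) requires three edges: m targets G
(consensus pair), m is an experimentally validated interactor of L, and L and
G are positively co-expressed (Spearman rho > 0, p below threshold) — the
sponge geometry in which L and G compete for the same miRNA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .errors import DegenerateStatisticError
from .evalstats import spearman_test
from .targetdb import ConsensusPairs

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CernaTriple:
    lncrna: str
    mirna: str
    mrna: str
    rho: float
    p: float


def lncrna_mrna_pairs(
    expr: pd.DataFrame,
    mrnas,
    lncrnas,
    p_max: float = 0.05,
    sample_mask=None,
) -> pd.DataFrame:
    """Positively correlated (lncRNA, mRNA) pairs on the given expression panel.

    ``expr`` is features x samples. Pairs with rho > 0 and p < p_max (strict,
    unadjusted) are kept; pairs with a missing feature are skipped with a log
    entry. ``sample_mask`` restricts the correlation to a sample subset
    (e.g. tumor samples only).
    """
    cols = list(expr.columns) if sample_mask is None else \
        [c for c in expr.columns if c in set(sample_mask)]
    rows = []
    have = set(expr.index)
    for lnc in sorted(set(lncrnas)):
        if lnc not in have:
            logger.info("lncRNA %s missing from expression panel; skipped", lnc)
            continue
        lv = expr.loc[lnc, cols].to_numpy(dtype=float)
        for mr in sorted(set(mrnas)):
            if mr not in have:
                logger.info("mRNA %s missing from expression panel; skipped", mr)
                continue
            try:
                rho, p = spearman_test(lv, expr.loc[mr, cols].to_numpy(dtype=float))
            except DegenerateStatisticError:
                continue
            if rho > 0 and p < p_max:
                rows.append({"lncrna": lnc, "mrna": mr, "rho": rho, "p": p})
    return pd.DataFrame(rows, columns=["lncrna", "mrna", "rho", "p"])


def find_triples(
    pairs,
    ml_pairs: pd.DataFrame,
    lm_pairs: pd.DataFrame,
) -> set[CernaTriple]:
    """Join the three edge tables into ceRNA triples.

    (L, m, G) is emitted iff (m, G) is a consensus target pair, (m, L) is a
    validated miRNA-lncRNA interaction, and (L, G) passed the positive
    co-expression screen.
    """
    target = pairs.pairs if isinstance(pairs, ConsensusPairs) else {(m, g) for m, g in pairs}
    sponge = set(zip(ml_pairs["mirna"], ml_pairs["lncrna"]))
    corr = {(r.lncrna, r.mrna): (r.rho, r.p) for r in lm_pairs.itertuples()}
    triples = set()
    for (m, g) in target:
        for (m2, l) in sponge:
            if m2 != m:
                continue
            stat = corr.get((l, g))
            if stat is not None:
                triples.add(CernaTriple(lncrna=l, mirna=m, mrna=g,
                                        rho=stat[0], p=stat[1]))
    return triples


def triples_table(triples: set[CernaTriple]) -> pd.DataFrame:
    rows = sorted(
        ({"lncrna": t.lncrna, "mirna": t.mirna, "mrna": t.mrna,
          "rho": t.rho, "p": t.p} for t in triples),
        key=lambda r: (r["lncrna"], r["mirna"], r["mrna"]),
    )
    return pd.DataFrame(rows, columns=["lncrna", "mirna", "mrna", "rho", "p"])
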