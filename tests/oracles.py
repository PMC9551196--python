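"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles (pair counting, set algebra,
exhaustive enumeration, hand formulas) and deliberately shares no code with
the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def auc_pairs(values, labels):
    """AUC by exhaustive concordant/tied pair counting."""
    cases = [v for v, l in zip(values, labels) if l]
    ctrls = [v for v, l in zip(values, labels) if not l]
    total = conc = ties = 0
    for c in cases:
        for d in ctrls:
            total += 1
            if c > d:
                conc += 1
            elif c == d:
                ties += 1
    return (conc + 0.5 * ties) / total


def decompose_oracle(edges):
    """Single-line/hotspot split by raw column counting."""
    genes = {g for _, g in edges}
    indeg = {g: sum(1 for _, gg in edges if gg == g) for g in genes}
    single = {}
    hot = {}
    for m, g in edges:
        if indeg[g] == 1:
            single.setdefault(m, set()).add(g)
        else:
            hot.setdefault(g, set()).add(m)
    return single, hot


def scores_oracle(edges, relevant, tfs):
    """(ngm, ngsm, ncgsm, ncgsm_tf) per miRNA by plain set algebra."""
    single, _ = decompose_oracle(edges)
    out = {}
    for m in {m for m, _ in edges}:
        targets = {g for mm, g in edges if mm == m}
        sl = single.get(m, set())
        csl = {g for g in sl if g in relevant}
        out[m] = (len(targets), len(sl), len(csl),
                  len({g for g in csl if g in tfs}))
    return out


def partition_oracle(sets):
    """SC/SS/intermediate by counting stage memberships per label."""
    stages = sorted(sets)
    members = {}
    for s in stages:
        for item in sets[s]:
            m = item[0] if isinstance(item, tuple) else item
            members.setdefault(m, set()).add(s)
    sc = {m for m, st in members.items() if len(st) == len(stages)}
    ss = {s: {m for m, st in members.items() if st == {s}} for s in stages}
    mid = {m for m, st in members.items() if 1 < len(st) < len(stages)}
    return sc, ss, mid


def vote_oracle(records, pred_min, valid_min):
    """Consensus pairs by per-pair distinct-DB counting over raw tuples.

    ``records``: iterable of (mirna, gene, db, type) tuples.
    """
    support = {}
    for m, g, db, typ in records:
        support.setdefault((m, g), {"predicted": set(), "validated": set()})
        support[(m, g)][typ].add(db)
    return {
        pair for pair, s in support.items()
        if len(s["predicted"]) >= pred_min or len(s["validated"]) >= valid_min
    }


def triples_oracle(target_pairs, ml_pairs, lm_pairs):
    """ceRNA triples by O(L*m*G) triple-loop enumeration."""
    lncs = {l for _, l in ml_pairs}
    mirnas = {m for m, _ in target_pairs} | {m for m, _ in ml_pairs}
    genes = {g for _, g in target_pairs}
    found = set()
    for l in lncs:
        for m in mirnas:
            for g in genes:
                if (m, g) in target_pairs and (m, l) in ml_pairs \
                        and (l, g) in lm_pairs:
                    found.add((l, m, g))
    return found


def bh_stepup(p):
    """Benjamini-Hochberg by the textbook step-up recursion."""
    p = list(p)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [0.0] * n
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * n / rank)
        adj[i] = val
        prev = val
    return adj


def km_hand(times, events):
    """Product-limit estimate, ties grouped, computed step by step."""
    data = sorted(zip(times, events))
    s = 1.0
    curve = []
    event_times = sorted({t for t, e in data if e == 1})
    for t in event_times:
        at_risk = sum(1 for tt, _ in data if tt >= t)
        d = sum(1 for tt, e in data if tt == t and e == 1)
        s *= (at_risk - d) / at_risk
        curve.append((t, s))
    return curve


def logrank_hand(times, events, groups):
    """Two-group log-rank: chi2 = (sum(O-E))^2 / sum(V) over event times."""
    labels = sorted(set(groups))
    data = list(zip(times, events, groups))
    event_times = sorted({t for t, e, _ in data if e == 1})
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n = sum(1 for tt, _, _ in data if tt >= t)
        n1 = sum(1 for tt, _, g in data if tt >= t and g == labels[0])
        d = sum(1 for tt, e, _ in data if tt == t and e == 1)
        d1 = sum(1 for tt, e, g in data if tt == t and e == 1 and g == labels[0])
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi = o_minus_e ** 2 / var if var > 0 else 0.0
    return chi


def welch_hand(a, b):
    """Welch t statistic and df from the closed-form formulas."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va / na + vb / nb)
    df = (va / na + vb / nb) ** 2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df


def hypergeom_enum(universe, gene_set, query):
    """P(overlap >= observed) by enumerating all draws of |query| genes."""
    universe = sorted(universe)
    gene_set = set(gene_set)
    k_obs = len(set(query) & gene_set)
    total = hits = 0
    for draw in itertools.combinations(universe, len(query)):
        total += 1
        if len(set(draw) & gene_set) >= k_obs:
            hits += 1
    return hits / total


def random_bipartite(rng, n_mirnas, n_genes, p=0.1):
    """Random miRNA->gene edge set for oracle-equivalence sweeps."""
    mirnas = [f"m{i}" for i in range(n_mirnas)]
    genes = [f"g{j}" for j in range(n_genes)]
    edges = {(m, g) for m in mirnas for g in genes if rng.random() < p}
    if not edges:
        edges = {(mirnas[0], genes[0])}
    return edges
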