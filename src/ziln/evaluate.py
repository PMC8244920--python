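"""Network-recovery metrics and graph/count summaries.

True edges are a tiny minority among the p(p-1)/2 candidate pairs, so the
headline metric is the area under the precision-recall curve over ranked
edge prefixes (AUROC is retained as a secondary view).  Also provided:
per-feature two-sample Kolmogorov-Smirnov distances between two count
tables, Newman's categorical assortativity of a labeled graph, and the
intersection-region counts of several methods' top-k edge sets.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .infer import RankedEdges
from .simulate import CountMatrix, GraphTruth

__all__ = [
    "MetricReport",
    "pr_metrics",
    "ks_feature_distance",
    "assortativity",
    "edge_overlap",
]

Pair = tuple[int, int]


@dataclass
class MetricReport:
    aupr: float
    auroc: float
    precision_at_k: dict[int, float]
    n_true_edges: int
    n_candidate_pairs: int
    extras: dict = field(default_factory=dict)


def _tie_blocks(ranked: RankedEdges) -> list[list[Pair]]:
    """Group consecutive pairs sharing an identical ranking key."""
    blocks: list[list[Pair]] = []
    prev_key = None
    for pair, key in zip(ranked.pairs, ranked.tie_keys()):
        if key != prev_key:
            blocks.append([])
            prev_key = key
        blocks[-1].append(pair)
    return blocks


def pr_metrics(ranked: RankedEdges, truth: GraphTruth, ks: tuple[int, ...] = (50,)) -> MetricReport:
    """Precision-recall and ROC areas of a ranked edge list against truth.

    Tied pairs (identical first-entry penalty and tie-break score) are
    consumed as one block, so the curve — and both areas — do not depend on
    the arbitrary order within a tie.  AUPR and AUROC are trapezoids over
    recall and false-positive rate respectively.  precision@k uses the
    deterministic full ordering.
    """
    true_set = set(truth.edges())
    e = len(true_set)
    if e == 0:
        raise ValueError("truth has zero edges")
    n_pairs = len(ranked.pairs)

    tp = fp = 0
    recalls = [0.0]
    precisions: list[float] = []
    fprs = [0.0]
    tprs = [0.0]
    n_neg = n_pairs - e
    for block in _tie_blocks(ranked):
        tp += sum(1 for pr in block if pr in true_set)
        fp += len(block) - sum(1 for pr in block if pr in true_set)
        precisions.append(tp / (tp + fp))
        recalls.append(tp / e)
        tprs.append(tp / e)
        fprs.append(fp / n_neg if n_neg else 0.0)
    # anchor the PR curve at recall 0 with the first block's precision
    precisions.insert(0, precisions[0])
    aupr = float(np.trapezoid(precisions, recalls))
    auroc = float(np.trapezoid(tprs, fprs))

    p_at_k = {}
    for k in ks:
        if k <= n_pairs:
            p_at_k[k] = sum(1 for pr in ranked.pairs[:k] if pr in true_set) / k
    return MetricReport(
        aupr=aupr,
        auroc=auroc,
        precision_at_k=p_at_k,
        n_true_edges=e,
        n_candidate_pairs=n_pairs,
    )


def ks_feature_distance(counts_a: CountMatrix, counts_b: CountMatrix) -> dict[str, float]:
    """Per-taxon two-sample KS statistics between two count tables.

    Taxa are matched by id; a taxon missing from either table is skipped
    with a warning.  The distribution of the returned statistics summarizes
    how closely one generator reproduces the other's marginals.
    """
    ids_a = {t: j for j, t in enumerate(counts_a.taxon_ids)}
    ids_b = {t: j for j, t in enumerate(counts_b.taxon_ids)}
    shared = [t for t in counts_a.taxon_ids if t in ids_b]
    missing = (set(counts_a.taxon_ids) | set(counts_b.taxon_ids)) - set(shared)
    if missing:
        warnings.warn(f"skipping {len(missing)} taxa absent from one matrix")
    out = {}
    for t in shared:
        stat = stats.ks_2samp(
            counts_a.counts[:, ids_a[t]], counts_b.counts[:, ids_b[t]]
        ).statistic
        out[t] = float(stat)
    return out


def assortativity(edges, node_labels: dict) -> float:
    """Newman's categorical assortativity coefficient of a labeled graph.

    Builds the edge mixing matrix E (fraction of edge ends joining each
    label pair, both directions counted) and returns
    (sum_i E_ii - sum_i a_i b_i) / (1 - sum_i a_i b_i), in [-1, 1]:
    1 when edges run only within label groups, negative when they
    preferentially cross groups.
    """
    edges = list(edges)
    if not edges:
        raise ValueError("need at least one edge")
    labels = sorted({node_labels[u] for u, v in edges} | {node_labels[v] for u, v in edges})
    if len(labels) < 2:
        raise ValueError("assortativity undefined: all endpoints share one label")
    idx = {lab: i for i, lab in enumerate(labels)}
    m = np.zeros((len(labels), len(labels)))
    for u, v in edges:
        m[idx[node_labels[u]], idx[node_labels[v]]] += 1
        m[idx[node_labels[v]], idx[node_labels[u]]] += 1
    m /= m.sum()
    a = m.sum(axis=1)
    b = m.sum(axis=0)
    ab = float(a @ b)
    if np.isclose(1.0, ab):
        raise ValueError("assortativity undefined: degenerate mixing matrix")
    return float((np.trace(m) - ab) / (1.0 - ab))


def edge_overlap(named_edge_sets: dict[str, list], top_k: int) -> dict:
    """Intersection-region counts of several methods' top-k edge lists.

    Each method's ranked list is truncated to its first ``top_k`` edges
    (shorter lists are used whole, with a warning); every edge is assigned
    to the exact subset of methods containing it.  Returns the region
    counts keyed by "&"-joined sorted method names, the unanimous count,
    the per-method idiosyncratic counts and, per method, the ratio of
    unanimous to idiosyncratic predictions (inf when nothing is
    idiosyncratic).
    """
    if len(named_edge_sets) < 2:
        raise ValueError("need at least 2 edge sets")
    truncated: dict[str, set] = {}
    for name, edges in named_edge_sets.items():
        edges = [tuple(sorted(e)) for e in edges]
        if len(edges) < top_k:
            warnings.warn(f"{name}: only {len(edges)} edges (< top_k={top_k}); using all")
        truncated[name] = set(edges[:top_k])
    names = sorted(truncated)
    regions: dict[str, int] = {}
    universe = set().union(*truncated.values())
    member = {e: frozenset(n for n in names if e in truncated[n]) for e in universe}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            key = "&".join(combo)
            regions[key] = sum(1 for e in universe if member[e] == frozenset(combo))
    unanimous = regions["&".join(names)]
    idiosyncratic = {n: regions[n] for n in names}
    ratio = {
        n: (unanimous / idiosyncratic[n]) if idiosyncratic[n] else float("inf") for n in names
    }
    return {
        "regions": regions,
        "unanimous": unanimous,
        "idiosyncratic": idiosyncratic,
        "unanimous_ratio": ratio,
    }
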