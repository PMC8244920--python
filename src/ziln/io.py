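"""Plain-text readers/writers: count TSVs, graphs, fits and edge rankings.

Count tables are TSV with a header row of taxon ids and a first column of
sample ids (samples in rows); a transpose flag accepts the taxa-in-rows
dialect.  Graphs go out as GraphML and as 2-column edge-list TSV; marginal
fits as JSON; rankings as a 5-column TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .estimate import MarginalFit
from .infer import RankedEdges
from .simulate import CountMatrix, GraphTruth
from .transform import TransformedMatrix

__all__ = [
    "read_counts",
    "write_counts",
    "write_graph",
    "read_graph",
    "write_transformed",
    "write_fit",
    "read_fit",
    "write_ranked_edges",
    "read_ranked_edges",
]


def read_counts(path, transpose: bool = False) -> CountMatrix:
    """Read a counts TSV, validating that every cell is a non-negative integer."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if transpose:
        df = df.T
    arr = df.to_numpy()
    bad = ~np.isfinite(arr.astype(float)) | (arr.astype(float) < 0) | (arr.astype(float) % 1 != 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid count {df.iat[i, j]!r} at sample {df.index[i]!r}, taxon {df.columns[j]!r}: "
            "cells must be non-negative integers"
        )
    counts = arr.astype(np.int64)
    return CountMatrix(
        counts=counts,
        sample_ids=[str(s) for s in df.index],
        taxon_ids=[str(t) for t in df.columns],
        library_sizes=counts.sum(axis=1),
    )


def write_counts(counts: CountMatrix, path) -> None:
    df = pd.DataFrame(counts.counts, index=counts.sample_ids, columns=counts.taxon_ids)
    df.to_csv(path, sep="\t", index_label="sample")


def write_graph(graph: GraphTruth, graphml_path=None, edgelist_path=None) -> None:
    """Write a ground-truth graph as GraphML and/or 2-column TSV edge list."""
    g = nx.from_numpy_array(graph.adjacency)
    if graphml_path is not None:
        nx.write_graphml(g, graphml_path)
    if edgelist_path is not None:
        with open(edgelist_path, "w") as fh:
            for j, k in graph.edges():
                fh.write(f"{j}\t{k}\n")


def read_graph(graphml_path, topology: str = "erdos_renyi") -> GraphTruth:
    g = nx.read_graphml(graphml_path)
    g = nx.convert_node_labels_to_integers(g, ordering="sorted")
    adj = nx.to_numpy_array(g, dtype=int)
    adj[adj != 0] = 1
    return GraphTruth(adjacency=adj, topology=topology, edge_count=int(adj.sum()) // 2)


def write_transformed(tm: TransformedMatrix, path, mask_path=None) -> None:
    """Write transformed values; the zero mask goes to a sidecar TSV."""
    n, p = tm.values.shape
    sids = tm.sample_ids or [f"S{i}" for i in range(n)]
    tids = tm.taxon_ids or [f"T{j}" for j in range(p)]
    pd.DataFrame(tm.values, index=sids, columns=tids).to_csv(path, sep="\t", index_label="sample")
    if mask_path is not None:
        pd.DataFrame(tm.zero_mask.astype(int), index=sids, columns=tids).to_csv(
            mask_path, sep="\t", index_label="sample"
        )


def write_fit(fit: MarginalFit, path, taxon_ids=None) -> None:
    tids = taxon_ids or [f"T{j}" for j in range(fit.p)]
    payload = {
        t: {
            "mu_hat": float(fit.mu_hat[j]),
            "sigma2_hat": float(fit.sigma2_hat[j]),
            "delta_hat": None if np.isneginf(fit.delta_hat[j]) else float(fit.delta_hat[j]),
            "converged": bool(fit.converged[j]),
            "loglik": float(fit.loglik[j]),
        }
        for j, t in enumerate(tids)
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_fit(path) -> MarginalFit:
    payload = json.loads(Path(path).read_text())
    vals = list(payload.values())
    return MarginalFit(
        mu_hat=np.array([v["mu_hat"] for v in vals]),
        sigma2_hat=np.array([v["sigma2_hat"] for v in vals]),
        delta_hat=np.array(
            [-np.inf if v["delta_hat"] is None else v["delta_hat"] for v in vals]
        ),
        converged=np.array([v["converged"] for v in vals]),
        loglik=np.array([v["loglik"] for v in vals]),
    )


def write_ranked_edges(ranked: RankedEdges, path, taxon_ids=None) -> None:
    rows = []
    for rank, (pair, lam, score) in enumerate(
        zip(ranked.pairs, ranked.first_entry_lambda, ranked.score), start=1
    ):
        a, b = pair
        if taxon_ids is not None:
            a, b = taxon_ids[a], taxon_ids[b]
        rows.append((a, b, rank, lam, score))
    pd.DataFrame(
        rows, columns=["taxon_a", "taxon_b", "rank", "first_entry_lambda", "score"]
    ).to_csv(path, sep="\t", index=False)


def read_ranked_edges(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
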