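"""Cross-mutant comparison: Venn overlap, hub network, sample clustering.

Given DEP sets for the five mutants, this module computes exact membership
(Venn) region counts, builds the hub-centric regulatory network (each mutant's
knocked-out regulator as a hub, connected to every protein differentially
expressed in that mutant, restricted to proteins hit in at least two
mutants), and hierarchically clusters the strain x replicate sample profiles
to check that replicates group by strain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .quantio import FoldChangeMatrix


@dataclass(frozen=True)
class OverlapSummary:
    """Exact counts for every nonempty membership region over m sets."""

    mutants: tuple[str, ...]
    regions: Mapping[tuple[str, ...], tuple[str, ...]]  # signature -> proteins

    def count(self, signature: Sequence[str]) -> int:
        return len(self.regions.get(tuple(sorted(signature)), ()))

    @property
    def shared_all(self) -> tuple[str, ...]:
        return self.regions.get(tuple(sorted(self.mutants)), ())

    def specific(self, mutant: str) -> tuple[str, ...]:
        return self.regions.get((mutant,), ())

    def total(self) -> int:
        return sum(len(v) for v in self.regions.values())

    def to_dict(self) -> dict:
        return {
            "mutants": list(self.mutants),
            "regions": {
                "&".join(sig): sorted(prots) for sig, prots in self.regions.items()
            },
        }


@dataclass(frozen=True)
class ClusterResult:
    """Agglomerative clustering of sample columns."""

    samples: tuple[str, ...]
    linkage: np.ndarray
    leaf_order: tuple[str, ...]
    labels: Mapping[str, int]  # sample -> flat cluster id at the cut

    def purity(self, strain_of: Mapping[str, str] | None = None) -> float:
        """Fraction of samples agreeing with their cluster's majority strain."""
        if strain_of is None:
            strain_of = {s: s.rsplit(":", 1)[0] for s in self.samples}
        by_cluster: dict[int, list[str]] = {}
        for s in self.samples:
            by_cluster.setdefault(self.labels[s], []).append(strain_of[s])
        agree = sum(
            max(members.count(x) for x in set(members))
            for members in by_cluster.values()
        )
        return agree / len(self.samples)


def overlap(dep_sets: Mapping[str, set[str]]) -> OverlapSummary:
    """Exact Venn region counts by membership signature.

    Every protein in the union is assigned to the region given by the sorted
    tuple of mutants containing it; only nonempty regions are stored.
    Protein lists within regions are sorted, so output is deterministic.
    """
    if len(dep_sets) < 2:
        raise ValueError("overlap needs at least 2 sets")
    mutants = tuple(sorted(dep_sets))
    regions: dict[tuple[str, ...], list[str]] = {}
    for protein in sorted(set().union(*dep_sets.values())):
        sig = tuple(m for m in mutants if protein in dep_sets[m])
        regions.setdefault(sig, []).append(protein)
    return OverlapSummary(
        mutants=mutants,
        regions={sig: tuple(prots) for sig, prots in sorted(regions.items())},
    )


def build_network(
    calls: pd.DataFrame, min_mutants: int = 2, hubs: Sequence[str] | None = None
) -> nx.DiGraph:
    """Hub-centric regulatory network of multiply-regulated DEPs.

    Nodes are the hub regulators (one per mutant) plus every protein called a
    DEP in at least ``min_mutants`` mutants; a signed edge hub -> protein
    exists iff the protein is a DEP in that hub's mutant.  ``calls`` is the
    tidy table from :func:`tmtpanel.depcall.call_deps`.
    """
    if min_mutants < 1:
        raise ValueError("min_mutants must be at least 1")
    deps = calls[calls["is_dep"]]
    mutants = sorted(calls["mutant"].unique())
    hubs = list(hubs) if hubs is not None else mutants
    if len(hubs) != len(mutants):
        raise ValueError("one hub per mutant required")
    hub_of = dict(zip(mutants, hubs))
    counts = deps.groupby("protein")["mutant"].nunique()
    keep = set(counts[counts >= min_mutants].index)
    g = nx.DiGraph()
    for m in mutants:
        g.add_node(hub_of[m], kind="hub", mutant=m)
    for row in deps.itertuples(index=False):
        if row.protein in keep:
            g.add_node(row.protein, kind="protein")
            g.add_edge(hub_of[row.mutant], row.protein, direction=row.direction,
                       log2fc=float(row.log2fc))
    return g


def cluster_samples(
    data: FoldChangeMatrix | pd.DataFrame,
    n_clusters: int | None = None,
    linkage_rule: str = "average",
    distance: str = "euclidean",
) -> ClusterResult:
    """Hierarchical agglomerative clustering of sample columns.

    ``data`` is either a z-scored protein x sample matrix (columns named
    ``strain:replicate``) or a FoldChangeMatrix, whose per-protein z-score
    matrix is used.  Columns are ordered lexicographically before linkage so
    agglomeration ties break deterministically.  The tree is cut into
    ``n_clusters`` flat clusters (default: the number of distinct strains).
    """
    if isinstance(data, FoldChangeMatrix):
        data = data.zscores
    data = data.reindex(sorted(data.columns), axis=1)
    data = data.dropna(axis=0)
    if data.shape[1] < 2:
        raise ValueError("need at least 2 sample columns")
    if data.shape[0] < 1:
        raise ValueError("no complete protein rows to cluster on")
    samples = tuple(data.columns)
    mat = data.to_numpy().T  # samples x proteins
    # zero-variance guard for correlation-type distances
    if distance == "correlation":
        keep = mat.std(axis=0) > 0
        mat = mat[:, keep]
    d = pdist(mat, metric=distance)
    link = hierarchy.linkage(d, method=linkage_rule)
    if n_clusters is None:
        n_clusters = len({s.rsplit(":", 1)[0] for s in samples})
    flat = hierarchy.fcluster(link, t=n_clusters, criterion="maxclust")
    order = hierarchy.leaves_list(link)
    return ClusterResult(
        samples=samples,
        linkage=link,
        leaf_order=tuple(samples[i] for i in order),
        labels={s: int(c) for s, c in zip(samples, flat)},
    )


# ---------------------------------------------------------------------------
# Exports and figures
# ---------------------------------------------------------------------------


def write_overlap(summary: OverlapSummary, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(summary.to_dict(), indent=2, sort_keys=True))
    return path


def write_network(g: nx.DiGraph, edge_path: str | Path,
                  graphml_path: str | Path | None = None) -> Path:
    edge_path = Path(edge_path)
    edge_path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {"hub": u, "protein": v, **attrs} for u, v, attrs in g.edges(data=True)
    ]
    pd.DataFrame(rows).to_csv(edge_path, sep="\t", index=False)
    if graphml_path is not None:
        nx.write_graphml(g, graphml_path)
    return edge_path


def category_heatmap(
    log2fc: pd.DataFrame,
    categories: Mapping[str, str],
    p_values: pd.DataFrame | None = None,
    path: str | Path | None = None,
    alpha: float = 0.05,
):
    """Fold-change heat map with proteins grouped by functional category.

    Rows (proteins) are ordered by category then id; cells show log2 fold
    change per mutant, with a significance star where p < alpha.  Returns
    the matplotlib Figure; writes it to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = sorted(log2fc.index, key=lambda p: (categories.get(p, "~"), p))
    mat = log2fc.loc[rows]
    fig, ax = plt.subplots(
        figsize=(2 + 0.5 * mat.shape[1], max(2.0, 0.12 * len(rows)))
    )
    vmax = np.nanmax(np.abs(mat.to_numpy())) or 1.0
    im = ax.imshow(mat.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(rows)), rows, fontsize=4)
    if p_values is not None:
        for i, prot in enumerate(rows):
            for j, mut in enumerate(mat.columns):
                if prot in p_values.index and p_values.loc[prot, mut] < alpha:
                    ax.text(j, i, "*", ha="center", va="center", fontsize=5)
    fig.colorbar(im, ax=ax, label="log2 fold change (mutant / WT)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
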