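"""Relatedness handling: kinship graphs and pruning of related samples.

Pairwise kinship coefficients (phi, typically produced by KING) are
thresholded at the third-degree cutoff 0.0442 to build a relatedness
graph.  To keep as many samples as possible while removing relatedness,
nodes of maximal degree are removed recursively until every remaining
component has at most one edge; for each surviving pair one member is
kept at random (seeded), and all singletons are kept.  The result always
induces an edge-free subgraph.  Max-degree removal is a greedy heuristic,
not a maximum-independent-set solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, ValidationError

#: third-degree kinship cutoff (inclusive), as established by KING
THIRD_DEGREE_CUTOFF = 0.0442


@dataclass
class KinshipGraph:
    """Samples as nodes; edges carry kinship phi >= the cutoff used."""

    graph: nx.Graph
    cutoff: float = THIRD_DEGREE_CUTOFF

    def __post_init__(self) -> None:
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise ValidationError(f"self-edge on {u!r}")
            if data.get("phi", self.cutoff) < self.cutoff:
                raise ValidationError(
                    f"edge ({u},{v}) phi {data['phi']} below cutoff {self.cutoff}"
                )

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)


def build_kinship_graph(
    pairs, cutoff: float = THIRD_DEGREE_CUTOFF
) -> KinshipGraph:
    """Threshold pairwise kinship rows into a graph.

    ``pairs`` is an iterable of (id_i, id_j, phi) or a DataFrame with those
    three columns.  The cutoff is inclusive (phi >= cutoff makes an edge).
    Samples seen only in sub-cutoff pairs remain as isolated nodes.
    Conflicting duplicate pairs are an error.
    """
    if isinstance(pairs, pd.DataFrame):
        rows = pairs.iloc[:, :3].itertuples(index=False)
    else:
        rows = pairs
    g = nx.Graph()
    seen: dict[tuple, float] = {}
    for i, j, phi in rows:
        i, j = str(i), str(j)
        phi = float(phi)
        if not math.isfinite(phi):
            raise ValidationError(f"non-finite phi for pair ({i},{j})")
        if not i or not j:
            raise ValidationError("empty sample ID in kinship table")
        if i == j:
            raise ValidationError(f"self-pair {i!r} in kinship table")
        key = (min(i, j), max(i, j))
        if key in seen and seen[key] != phi:
            raise ValidationError(
                f"duplicate pair {key} with conflicting phi {seen[key]} vs {phi}"
            )
        seen[key] = phi
        g.add_node(i)
        g.add_node(j)
        if phi >= cutoff:
            g.add_edge(i, j, phi=phi)
    return KinshipGraph(graph=g, cutoff=cutoff)


def prune_related(
    graph: KinshipGraph, seed: int = 0
) -> tuple[set[str], set[str]]:
    """Greedy relatedness pruning; returns (keep, removed) sample-ID sets.

    While any node has degree >= 2, the node of maximal degree is removed
    (ties broken by lexicographically smallest ID, for determinism).  Each
    remaining isolated edge then contributes one randomly chosen member to
    the keep set; isolated nodes are all kept.
    """
    g = graph.graph.copy()
    removed: set[str] = set()
    while True:
        degrees = dict(g.degree)
        if not degrees or max(degrees.values()) <= 1:
            break
        max_deg = max(degrees.values())
        victim = min(n for n, d in degrees.items() if d == max_deg)
        g.remove_node(victim)
        removed.add(victim)
    # remaining components are single edges or singletons; resolve the pairs
    rng = np.random.default_rng(seed)
    for u, v in sorted((min(e), max(e)) for e in g.edges):
        loser = v if rng.random() < 0.5 else u
        removed.add(loser)
    keep = {n for n in graph.graph.nodes if n not in removed}
    return keep, removed


def kinship_from_genotypes(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Robust pairwise kinship estimates from a genotype matrix.

    Implements the between-family robust estimator of Manichaikul et al.
    (the method behind KING):  phi = (N_het,het - 2 * N_opposite_hom) /
    (N_het(i) + N_het(j)), using only sites where both genotypes are
    called (here: all sites, missing being coded 0).  Duplicate samples
    give phi ~ 0.5, unrelated samples ~ 0.  Pairs where both samples have
    zero heterozygous calls get phi = NaN (undefined).

    Returns a DataFrame with columns (ID1, ID2, phi), one row per
    unordered pair, and the formula recorded in ``df.attrs['formula']``.
    """
    if matrix.n_samples < 2 or matrix.n_variants < 1:
        raise ValidationError("need >= 2 samples and >= 1 variant")
    G = matrix.values
    het = (G == 1).astype(np.float64)
    hom_ref = (G == 0).astype(np.float64)
    hom_alt = (G == 2).astype(np.float64)
    n_hh = het @ het.T
    n_opp = hom_ref @ hom_alt.T + hom_alt @ hom_ref.T
    n_het = het.sum(axis=1)
    denom = n_het[:, None] + n_het[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(denom > 0, (n_hh - 2.0 * n_opp) / denom, np.nan)
    rows = []
    for a in range(matrix.n_samples):
        for b in range(a + 1, matrix.n_samples):
            rows.append((matrix.samples[a], matrix.samples[b], phi[a, b]))
    df = pd.DataFrame(rows, columns=["ID1", "ID2", "phi"])
    df.attrs["formula"] = (
        "phi = (N_het_het - 2*N_opposing_hom) / (N_het_i + N_het_j); "
        "robust between-family estimator (Manichaikul et al. 2010, KING)"
    )
    return df


def read_kinship_table(path) -> pd.DataFrame:
    """Tab-separated (ID1, ID2, phi or kinship) pairwise kinship input."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = {c.lower(): c for c in df.columns}
    id1 = cols.get("id1")
    id2 = cols.get("id2")
    phi = cols.get("phi") or cols.get("kinship")
    if not (id1 and id2 and phi):
        raise ValidationError(
            f"{path}: expected columns ID1, ID2 and phi/kinship; got {list(df.columns)}"
        )
    out = df[[id1, id2, phi]].copy()
    out.columns = ["ID1", "ID2", "phi"]
    return out


def write_kinship_table(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        formula = df.attrs.get("formula")
        if formula:
            fh.write(f"# {formula}\n")
        df.to_csv(fh, sep="\t", index=False)
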