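"""Mitochondrial analyses: consensus calling, diversity, haplotype networks,
and the marginal-likelihood model-comparison rule with effective-size scaling.

Nucleotide diversity uses pairwise deletion: each pair of sequences is
compared only at positions where neither carries a gap or N, and the per-pair
proportions are averaged over all pairs.  Haplotype identity treats N (and
gaps) as wildcards, so sequences that differ only at uncalled positions
collapse into one haplotype instead of inflating the haplotype count.

The haplotype network is an epsilon-relaxed minimum spanning network: all
minimum-spanning-tree edges plus every edge not longer than (1 + epsilon)
times the largest edge on the MST path between its endpoints — i.e. the
weight at which the endpoints' components merged.  epsilon = 0 with distinct
weights gives exactly the MST; larger epsilon admits reticulations.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import networkx as nx
import numpy as np

from .datatypes import DiversityResult, ModelEvidence, SequenceAlignment

logger = logging.getLogger("popkit")

WILDCARDS = {"N", "-"}


# ---------------------------------------------------------------------------
# consensus calling
# ---------------------------------------------------------------------------

@dataclass
class PileupColumn:
    """Observed bases at one 1-based position (multiset; may be empty)."""

    position: int
    bases: dict  # base -> count


def majority_consensus(columns, min_depth: int = 5) -> str:
    """Majority-rule consensus over ordered pileup columns.

    Emits the most frequent base per column; emits ``N`` when total depth is
    below ``min_depth`` or the top count is tied.
    """
    out = []
    last_pos = None
    for col in columns:
        if last_pos is not None and col.position <= last_pos:
            raise ValueError("pileup columns must be ordered by position")
        last_pos = col.position
        depth = sum(col.bases.values())
        if depth < min_depth:
            out.append("N")
            continue
        ranked = sorted(col.bases.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            out.append("N")
        else:
            out.append(ranked[0][0])
    return "".join(out)


# ---------------------------------------------------------------------------
# diversity statistics
# ---------------------------------------------------------------------------

def _pair_diff(a: np.ndarray, b: np.ndarray):
    """(differences, usable sites) under pairwise deletion of N/gaps."""
    usable = ~(np.isin(a, list(WILDCARDS)) | np.isin(b, list(WILDCARDS)))
    return int(np.sum((a != b) & usable)), int(usable.sum())


def nucleotide_diversity(aln: SequenceAlignment) -> float:
    """Mean pairwise proportion of differing sites (pairwise deletion)."""
    if aln.n < 2:
        raise ValueError("nucleotide diversity needs at least 2 sequences")
    arr = aln.array()
    total = 0.0
    n_pairs = 0
    for i, j in combinations(range(aln.n), 2):
        d, L = _pair_diff(arr[i], arr[j])
        if L == 0:
            warnings.warn(
                f"pair ({aln.names[i]}, {aln.names[j]}) shares no usable sites; excluded"
            )
            continue
        total += d / L
        n_pairs += 1
    if n_pairs == 0:
        raise ValueError("no sequence pair shares a usable site")
    return total / n_pairs


def _compatible(a: str, b: str) -> bool:
    return all(x == y or x in WILDCARDS or y in WILDCARDS for x, y in zip(a, b))


def _merge_repr(a: str, b: str) -> str:
    """Fill each wildcard with the other sequence's base where known."""
    return "".join(y if x in WILDCARDS else x for x, y in zip(a, b))


def collapse_haplotypes(aln: SequenceAlignment):
    """Group sequences into haplotypes, treating N/- as wildcards.

    Sequences are visited in name order and merged into the first compatible
    cluster; clusters are then re-merged to a fixpoint so the result does not
    depend on incidental wildcard placement.  Returns a list of
    ``(representative_sequence, member_names)``.
    """
    order = sorted(range(aln.n), key=lambda i: aln.names[i])
    clusters = []  # [representative, [names]]
    for i in order:
        seq = aln.sequences[i]
        for c in clusters:
            if _compatible(c[0], seq):
                c[0] = _merge_repr(c[0], seq)
                c[1].append(aln.names[i])
                break
        else:
            clusters.append([seq, [aln.names[i]]])
    merged = True
    while merged:
        merged = False
        for a, b in combinations(range(len(clusters)), 2):
            if _compatible(clusters[a][0], clusters[b][0]):
                clusters[a][0] = _merge_repr(clusters[a][0], clusters[b][0])
                clusters[a][1].extend(clusters[b][1])
                del clusters[b]
                merged = True
                break
    return [(c[0], sorted(c[1])) for c in clusters]


def haplotype_diversity(aln: SequenceAlignment) -> float:
    """h = n/(n-1) * (1 - sum p_k^2) over collapsed haplotype frequencies."""
    if aln.n < 2:
        raise ValueError("haplotype diversity needs at least 2 sequences")
    clusters = collapse_haplotypes(aln)
    n = aln.n
    freqs = np.array([len(members) for _, members in clusters]) / n
    return float(n / (n - 1) * (1.0 - np.sum(freqs ** 2)))


def diversity(aln: SequenceAlignment) -> DiversityResult:
    """Bundle n, haplotype count, h and pi for one alignment."""
    arr = aln.array()
    n_pairwise = {}
    for i, j in combinations(range(aln.n), 2):
        _, L = _pair_diff(arr[i], arr[j])
        n_pairwise[(aln.names[i], aln.names[j])] = L
    return DiversityResult(
        n=aln.n,
        n_haplotypes=len(collapse_haplotypes(aln)),
        h=haplotype_diversity(aln),
        pi=nucleotide_diversity(aln),
        n_pairwise_sites=n_pairwise,
    )


# ---------------------------------------------------------------------------
# haplotype network
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeNetwork:
    """Haplotype nodes with locality multisets and mutation-step edges."""

    nodes: dict  # node id -> (member name list, locality Counter)
    edges: list = field(default_factory=list)  # (node_a, node_b, mutations)
    epsilon: float = 0.1

    def edge_list(self):
        return sorted(self.edges)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(self.edges)
        return g


def build_haplotype_network(aln: SequenceAlignment,
                            epsilon: float = 0.1) -> HaplotypeNetwork:
    """Epsilon-relaxed minimum spanning network over collapsed haplotypes."""
    if aln.n < 2:
        raise ValueError("network needs at least 2 sequences")
    clusters = collapse_haplotypes(aln)
    loc = dict(zip(aln.names, aln.localities or ["unknown"] * aln.n))
    node_ids = [f"H{i + 1}" for i in range(len(clusters))]
    nodes = {
        nid: (members, Counter(loc[m] for m in members))
        for nid, (_, members) in zip(node_ids, clusters)
    }
    if len(clusters) == 1:
        return HaplotypeNetwork(nodes=nodes, edges=[], epsilon=epsilon)

    reps = [np.frombuffer(rep.encode(), dtype="S1").astype("U1")
            for rep, _ in clusters]
    g = nx.Graph()
    for i, j in combinations(range(len(clusters)), 2):
        d, L = _pair_diff(reps[i], reps[j])
        if L == 0:
            raise ValueError("haplotype pair shares no usable sites")
        g.add_edge(node_ids[i], node_ids[j], weight=d)
    mst = nx.minimum_spanning_tree(g, weight="weight")
    edges = []
    for u, v, data in g.edges(data=True):
        w = data["weight"]
        path = nx.shortest_path(mst, u, v)
        merge_w = max(
            mst[a][b]["weight"] for a, b in zip(path, path[1:])
        )
        if w <= (1.0 + epsilon) * merge_w:
            a, b = sorted((u, v))
            edges.append((a, b, w))
    return HaplotypeNetwork(nodes=nodes, edges=edges, epsilon=epsilon)


# ---------------------------------------------------------------------------
# model comparison and Ne scaling
# ---------------------------------------------------------------------------

def compare_models(a: ModelEvidence, b: ModelEvidence) -> str:
    """Decide between two models from nested-sampling marginal likelihoods.

    The model with the larger log marginal likelihood is favoured when the
    difference exceeds 2*sqrt(SD_a^2 + SD_b^2); otherwise the models are
    indistinguishable.  Returns ``"a_favoured"``, ``"b_favoured"`` or
    ``"indistinguishable"``.
    """
    diff = a.log_marginal_likelihood - b.log_marginal_likelihood
    threshold = 2.0 * np.sqrt(a.sd ** 2 + b.sd ** 2)
    if abs(diff) > threshold:
        return "a_favoured" if diff > 0 else "b_favoured"
    return "indistinguishable"


def model_comparison_details(a: ModelEvidence, b: ModelEvidence) -> dict:
    """The verdict plus the intermediate quantities of the decision rule."""
    return {
        "delta_log_ml": abs(a.log_marginal_likelihood - b.log_marginal_likelihood),
        "threshold": 2.0 * float(np.sqrt(a.sd ** 2 + b.sd ** 2)),
        "verdict": compare_models(a, b),
        "favoured": {
            "a_favoured": a.name, "b_favoured": b.name,
            "indistinguishable": None,
        }[compare_models(a, b)],
    }


def scale_effective_size(coalescent_size: float, generation_time: float = 23.4) -> float:
    """Convert a coalescent size in N*tau (years) units into N_ef individuals."""
    if generation_time <= 0:
        raise ValueError("generation time must be > 0")
    return coalescent_size / generation_time
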