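"""Toy-scale in-silico mate-pair scaffolding.

Reproduces the cross-species scaffolding recipe at desk scale: simulate
mate-pair libraries of several insert sizes from a consensus sequence, place
the reads on contigs by exact match, accumulate contig-end links with gap
estimates, and greedily order/orient contigs along the strongest unambiguous
links, joining them with N-gaps.

Mate pairs are emitted in outward orientation (the left read reverse
complemented, the right read forward) and normalised back to genome-forward
during placement, so the link logic works in one orientation convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .simulate import reverse_complement

logger = logging.getLogger("popkit")

DEFAULT_INSERTS = (1000, 2000, 5000, 8000, 10000, 15000, 20000)


@dataclass
class MatePairParams:
    insert_sizes_bp: tuple = DEFAULT_INSERTS
    read_length_bp: int = 150
    depth: float = 30.0
    insert_sd_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.read_length_bp >= min(self.insert_sizes_bp):
            raise ValueError("read_length must be shorter than the smallest insert")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.insert_sd_fraction < 0:
            raise ValueError("insert_sd_fraction must be >= 0")


@dataclass
class ReadPair:
    name: str
    read1: str  # outward-oriented left read (reverse complemented)
    read2: str  # right read, forward
    insert_nominal: int
    truth_start: int  # fragment [start, end) on the source sequence
    truth_end: int


@dataclass
class ScaffoldParams:
    min_links: int = 5
    max_ratio: float = 0.7  # reject a link when second_best/best exceeds this
    min_scaffold_bp: int = 1000

    def __post_init__(self):
        if self.min_links < 1:
            raise ValueError("min_links must be >= 1")
        if not 0 < self.max_ratio <= 1:
            raise ValueError("max_ratio must be in (0, 1]")


@dataclass
class ScaffoldGraph:
    contigs: dict  # id -> sequence
    links: dict = field(default_factory=dict)
    # links key: (contig_a, end_a, contig_b, end_b) canonical (a < b)
    # value: {"support": int, "gaps": [float, ...]}


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def generate_mate_pairs(consensus: str, params: MatePairParams = MatePairParams()) -> list:
    """Simulate mate-pair libraries from a consensus sequence.

    Per library the pair count is depth * L / (2 * read_length); inserts are
    Normal(insert, insert * sd_fraction) truncated to [read_length, L].
    Libraries whose insert exceeds the sequence are skipped with a warning.
    Truth fragment coordinates are kept on each pair.
    """
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    L = len(consensus)
    rl = params.read_length_bp
    pairs = []
    for insert in params.insert_sizes_bp:
        if insert >= L:
            logger.warning("insert %d >= sequence length %d; library skipped",
                           insert, L)
            continue
        n_pairs = int(round(params.depth * L / (2 * rl)))
        sd = params.insert_sd_fraction * insert
        sizes = rng.normal(insert, sd, size=n_pairs) if sd > 0 else np.full(n_pairs, insert)
        sizes = np.clip(np.rint(sizes), rl, L).astype(int)
        starts = rng.integers(0, L - sizes + 1)
        for k, (s, size) in enumerate(zip(starts, sizes)):
            e = int(s) + int(size)
            pairs.append(ReadPair(
                name=f"lib{insert}_p{k}",
                read1=reverse_complement(consensus[s:s + rl]),
                read2=consensus[e - rl:e],
                insert_nominal=insert,
                truth_start=int(s),
                truth_end=e,
            ))
    return pairs


def write_read_pairs_fastq(pairs, path) -> None:
    """Interleaved FASTQ with the truth span in the comment field."""
    with open(path, "w") as fh:
        for p in pairs:
            meta = f"insert={p.insert_nominal} span={p.truth_start}-{p.truth_end}"
            for mate, seq in ((1, p.read1), (2, p.read2)):
                fh.write(f"@{p.name}/{mate} {meta}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_read_pairs_fastq(path) -> list:
    from Bio import SeqIO
    recs = list(SeqIO.parse(str(path), "fastq"))
    if len(recs) % 2:
        raise ValueError("odd number of FASTQ records; expected interleaved pairs")
    pairs = []
    for r1, r2 in zip(recs[::2], recs[1::2]):
        name = r1.id.rsplit("/", 1)[0]
        meta = dict(kv.split("=") for kv in r1.description.split()[1:])
        span = meta.get("span", "0-0").split("-")
        pairs.append(ReadPair(
            name=name, read1=str(r1.seq), read2=str(r2.seq),
            insert_nominal=int(meta.get("insert", 0)),
            truth_start=int(span[0]), truth_end=int(span[1]),
        ))
    return pairs


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------

@dataclass
class Placement:
    contig: str
    pos: int      # 0-based start within the contig
    strand: str   # '+': genome-forward read equals contig slice


def _kmer_index(contigs: dict, k: int) -> dict:
    index = {}
    for cid, seq in contigs.items():
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i:i + k], []).append((cid, i))
    return index


def place_reads(contigs: dict, pairs: list):
    """Exact-match placement of mate pairs on contigs.

    Reads are normalised to genome-forward orientation first (read1 is
    stored reverse complemented).  A read is placed only when it matches
    exactly one contig location over both strands; others are discarded and
    counted.  Returns ``(placements, stats)`` where ``placements`` maps pair
    name to a (left Placement, right Placement) tuple (entries may be None).
    """
    if not pairs:
        return {}, {"n_placed": 0, "n_unmatched": 0, "n_multi": 0}
    k = len(pairs[0].read1)
    index = _kmer_index(contigs, k)

    def place(read_fwd: str) -> Optional[Placement]:
        hits = [(c, p, "+") for c, p in index.get(read_fwd, [])]
        rc = reverse_complement(read_fwd)
        hits += [(c, p, "-") for c, p in index.get(rc, [])]
        if len(hits) != 1:
            return ("multi" if len(hits) > 1 else None)
        c, p, s = hits[0]
        return Placement(contig=c, pos=p, strand=s)

    placements = {}
    stats = {"n_placed": 0, "n_unmatched": 0, "n_multi": 0}
    for pair in pairs:
        left = place(reverse_complement(pair.read1))
        right = place(pair.read2)
        pl = []
        for x in (left, right):
            if isinstance(x, Placement):
                stats["n_placed"] += 1
                pl.append(x)
            else:
                stats["n_multi" if x == "multi" else "n_unmatched"] += 1
                pl.append(None)
        placements[pair.name] = tuple(pl)
    return placements, stats


# ---------------------------------------------------------------------------
# link graph
# ---------------------------------------------------------------------------

def build_links(contigs: dict, placements: dict, pairs: list) -> ScaffoldGraph:
    """Accumulate contig-end links from cross-contig mate pairs.

    The left read points genome-right, the right read genome-left; the
    contig end a mate extends past follows from the placement strand.  The
    gap estimate is insert - (distance of each read to its linking end).
    """
    graph = ScaffoldGraph(contigs=dict(contigs))
    rl = len(pairs[0].read1) if pairs else 0
    by_name = {p.name: p for p in pairs}
    for name, (left, right) in placements.items():
        if left is None or right is None:
            continue
        if left.contig == right.contig:
            continue
        pair = by_name[name]

        def end_and_dist(pl: Placement, mate_direction: str):
            # mate_direction: 'right' for the left read, 'left' for the right read
            clen = len(contigs[pl.contig])
            toward_right = (mate_direction == "right") == (pl.strand == "+")
            if toward_right:
                return "R", clen - pl.pos
            return "L", pl.pos + rl

        e1, d1 = end_and_dist(left, "right")
        e2, d2 = end_and_dist(right, "left")
        gap = pair.insert_nominal - d1 - d2
        c1, c2 = left.contig, right.contig
        if c1 > c2:
            c1, e1, c2, e2 = c2, e2, c1, e1
        key = (c1, e1, c2, e2)
        rec = graph.links.setdefault(key, {"support": 0, "gaps": []})
        rec["support"] += 1
        rec["gaps"].append(float(gap))
    return graph


# ---------------------------------------------------------------------------
# greedy scaffolding
# ---------------------------------------------------------------------------

def n50(lengths) -> int:
    """Length at which contigs at least that long cover half the total."""
    lengths = sorted((int(x) for x in lengths), reverse=True)
    if not lengths:
        return 0
    half = sum(lengths) / 2.0
    acc = 0
    for x in lengths:
        acc += x
        if acc >= half:
            return x
    return lengths[-1]


@dataclass
class ScaffoldResult:
    scaffolds: dict          # id -> sequence (with N gaps), after length filter
    joins: list              # accepted links, (c1, e1, c2, e2, support, gap)
    n50_before: int
    n50_after: int
    n_dropped_short: int
    layout: list             # per scaffold: [(contig, orientation), ...]


def greedy_scaffold(graph: ScaffoldGraph,
                    params: ScaffoldParams = ScaffoldParams()) -> ScaffoldResult:
    """Order and orient contigs along high-support unambiguous links.

    Links are visited by decreasing support; a link is accepted when its
    support reaches ``min_links``, it is the strongest link at both of its
    contig ends with the runner-up at most ``max_ratio`` of it, neither end
    is already joined, and it does not close a cycle.  Joined contigs are
    concatenated with max(mean gap estimate, 1) Ns; output scaffolds shorter
    than ``min_scaffold_bp`` are dropped.
    """
    end_links = {}
    for key, rec in graph.links.items():
        c1, e1, c2, e2 = key
        end_links.setdefault((c1, e1), []).append((rec["support"], key))
        end_links.setdefault((c2, e2), []).append((rec["support"], key))

    def end_ok(end, key, support):
        others = [s for s, k in end_links[end] if k != key]
        if not others:
            return True
        return max(others) <= params.max_ratio * support

    candidates = sorted(
        ((rec["support"], key) for key, rec in graph.links.items()
         if rec["support"] >= params.min_links),
        key=lambda t: (-t[0], t[1]),
    )
    used_ends = set()
    parent = {c: c for c in graph.contigs}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    joins = []
    adj = {}
    for support, key in candidates:
        c1, e1, c2, e2 = key
        if (c1, e1) in used_ends or (c2, e2) in used_ends:
            continue
        if not (end_ok((c1, e1), key, support) and end_ok((c2, e2), key, support)):
            continue
        if find(c1) == find(c2):
            logger.info("link %s would close a cycle; skipped", key)
            continue
        used_ends.update([(c1, e1), (c2, e2)])
        parent[find(c1)] = find(c2)
        gap = float(np.mean(graph.links[key]["gaps"]))
        joins.append((c1, e1, c2, e2, support, gap))
        adj[(c1, e1)] = (c2, e2, gap)
        adj[(c2, e2)] = (c1, e1, gap)

    # walk chains: each contig end is used at most once and cycles were
    # refused, so every connected component is a simple path
    visited = set()
    scaffolds = {}
    layouts = []
    sid = 0
    for start in sorted(graph.contigs):
        if start in visited:
            continue
        # walk leftward to a terminus (a contig whose exit end is free)
        cur, exit_end = start, "L"
        seen = {start}
        while (cur, exit_end) in adj:
            nxt_c, nxt_end, _gap = adj[(cur, exit_end)]
            if nxt_c in seen:
                break
            cur = nxt_c
            exit_end = "L" if nxt_end == "R" else "R"
            seen.add(cur)
        # traverse from the free end through the chain; '+' reads L->R
        orient = "+" if exit_end == "L" else "-"
        parts = []
        layout = []
        prev_gap = None
        while True:
            visited.add(cur)
            seq = (graph.contigs[cur] if orient == "+"
                   else reverse_complement(graph.contigs[cur]))
            if prev_gap is not None:
                parts.append("N" * max(int(round(prev_gap)), 1))
            parts.append(seq)
            layout.append((cur, orient))
            out_end = "R" if orient == "+" else "L"
            nxt = adj.get((cur, out_end))
            if nxt is None or nxt[0] in visited:
                break
            nxt_c, nxt_end, prev_gap = nxt
            cur = nxt_c
            orient = "+" if nxt_end == "L" else "-"
        scaffolds[f"scaffold{sid:03d}"] = "".join(parts)
        layouts.append(layout)
        sid += 1

    before = n50(len(s) for s in graph.contigs.values())
    after_all = n50(len(s) for s in scaffolds.values())
    kept = {k: v for k, v in scaffolds.items() if len(v) >= params.min_scaffold_bp}
    kept_layouts = [lay for k, lay in zip(scaffolds, layouts) if k in kept]
    return ScaffoldResult(
        scaffolds=kept,
        joins=joins,
        n50_before=before,
        n50_after=after_all,
        n_dropped_short=len(scaffolds) - len(kept),
        layout=kept_layouts,
    )


# ---------------------------------------------------------------------------
# hierarchical multi-library pipeline
# ---------------------------------------------------------------------------

def _flip(orient: str) -> str:
    return "-" if orient == "+" else "+"


def scaffold_pipeline(contigs: dict, pairs: list,
                      params: ScaffoldParams = ScaffoldParams()):
    """Scaffold with several insert-size libraries, smallest first.

    Short-insert links can only join adjacent contigs, so each round merges
    immediate neighbours; once merged, a longer library's links across them
    become intra-scaffold and are ignored, which keeps long-insert skip links
    from bridging over small contigs.  Returns ``(ScaffoldResult,
    composition)`` where ``composition`` maps each final scaffold to its
    ordered ``(original_contig, orientation)`` list.
    """
    seqs = dict(contigs)
    comp = {cid: [(cid, "+")] for cid in contigs}
    round_params = ScaffoldParams(min_links=params.min_links,
                                  max_ratio=params.max_ratio, min_scaffold_bp=1)
    all_joins = []
    by_lib = {}
    for p in pairs:
        by_lib.setdefault(p.insert_nominal, []).append(p)
    for insert in sorted(by_lib):
        placements, _stats = place_reads(seqs, by_lib[insert])
        graph = build_links(seqs, placements, by_lib[insert])
        res = greedy_scaffold(graph, round_params)
        if not res.joins:
            continue
        all_joins.extend(res.joins)
        new_seqs, new_comp = {}, {}
        for (sid, seq), chain in zip(res.scaffolds.items(), res.layout):
            items = []
            for seqid, orient in chain:
                sub = comp[seqid]
                if orient == "-":
                    sub = [(c, _flip(o)) for c, o in reversed(sub)]
                items.extend(sub)
            new_seqs[sid] = seq
            new_comp[sid] = items
        seqs, comp = new_seqs, new_comp

    before = n50(len(s) for s in contigs.values())
    after = n50(len(s) for s in seqs.values())
    kept = {k: v for k, v in seqs.items() if len(v) >= params.min_scaffold_bp}
    result = ScaffoldResult(
        scaffolds=kept,
        joins=all_joins,
        n50_before=before,
        n50_after=after,
        n_dropped_short=len(seqs) - len(kept),
        layout=[comp[k] for k in kept],
    )
    return result, {k: comp[k] for k in kept}


def scaffold_adjacencies(composition: dict) -> set:
    """Canonical oriented contig adjacencies implied by final scaffolds."""
    out = set()
    for items in composition.values():
        for (ca, oa), (cb, ob) in zip(items, items[1:]):
            ea = "R" if oa == "+" else "L"
            eb = "L" if ob == "+" else "R"
            if ca > cb:
                ca, ea, cb, eb = cb, eb, ca, ea
            out.add((ca, ea, cb, eb))
    return out


def evaluate_layouts(composition: dict, truth_layout: list) -> dict:
    """Recall/precision of final scaffold adjacencies against truth.

    An adjacency counts as correct when the two contigs are genome-adjacent
    and joined by the ends their true orientations imply (a reversed whole
    scaffold is the same layout, so both polarities match).
    """
    truth = truth_adjacencies(truth_layout)
    reported = scaffold_adjacencies(composition)
    tp = len(reported & truth)
    return {
        "n_truth": len(truth),
        "n_reported": len(reported),
        "n_correct": tp,
        "recall": tp / len(truth) if truth else float("nan"),
        "precision": tp / len(reported) if reported else float("nan"),
    }


# ---------------------------------------------------------------------------
# truth comparison
# ---------------------------------------------------------------------------

def truth_adjacencies(layout: list) -> set:
    """Oriented truth joins from a fragment_genome layout.

    Each adjacency is the canonical link key (c1, e1, c2, e2) that a correct
    scaffolder should recover between genome-consecutive contigs.
    """
    ordered = sorted(layout, key=lambda t: t[1])
    out = set()
    for (ca, _, sa), (cb, _, sb) in zip(ordered, ordered[1:]):
        ea = "R" if sa == "+" else "L"   # genome-right end of left contig
        eb = "L" if sb == "+" else "R"   # genome-left end of right contig
        if ca > cb:
            ca, ea, cb, eb = cb, eb, ca, ea
        out.add((ca, ea, cb, eb))
    return out


def evaluate_joins(joins: list, layout: list) -> dict:
    """Recall/precision of accepted joins against the truth layout."""
    truth = truth_adjacencies(layout)
    reported = {(c1, e1, c2, e2) for c1, e1, c2, e2, _s, _g in joins}
    tp = len(reported & truth)
    return {
        "n_truth": len(truth),
        "n_reported": len(reported),
        "n_correct": tp,
        "recall": tp / len(truth) if truth else float("nan"),
        "precision": tp / len(reported) if reported else float("nan"),
    }
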