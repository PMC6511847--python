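"""Peptide similarity networking and dereplication.

Retrieved peptides are compared all-vs-all by Smith–Waterman local alignment
(BLOSUM62, affine gaps: a gap of length k costs open + k·extend). A pair is
connected when its best hit passes every threshold — E-value, percent
identity over alignment columns, coverage of the shorter sequence, and
minimum alignment length — and connected components, ranked by size, are the
peptide networks. Large networks group recurrent precursor families across
gene clusters; singletons are reported separately. A greedy 99%-identity
dereplicator collapses near-duplicate proteins to one representative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_KNOWN = set(str(a) for a in _BLOSUM62.alphabet)


@dataclass
class NetworkConfig:
    """Edge thresholds plus the alignment/statistics constants behind them.

    The defaults are the networking settings used throughout: E ≤ 10,
    identity ≥ 40%, the hit covering ≥ 35% of the shorter sequence, and hit
    length ≥ 15 aa. λ and K are standard gapped Karlin–Altschul constants for
    BLOSUM62 with gap open 11 / extend 1; with an E cutoff of 10 the topology
    is dominated by the identity/coverage/length thresholds.
    """

    evalue_max: float = 10.0
    identity_min_pct: float = 40.0
    coverage_min_pct: float = 35.0
    hitlen_min: int = 15
    gap_open: float = 11.0
    gap_extend: float = 1.0
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041
    matrix: str = "BLOSUM62"


@dataclass
class AlignmentHit:
    query_id: str
    subject_id: str
    raw_score: float
    bit_score: float
    evalue: float
    identity_pct: float
    hit_len: int
    coverage_shorter_pct: float


@dataclass
class PeptideNetwork:
    rank: int
    member_ids: list[str]
    size: int


def _aligner(cfg: NetworkConfig, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load(cfg.matrix)
    # gap of length k costs open + k*extend
    aligner.open_gap_score = -(cfg.gap_open + cfg.gap_extend)
    aligner.extend_gap_score = -cfg.gap_extend
    return aligner


def _sanitize(seq: str) -> str:
    return "".join(c if c in _KNOWN else "X" for c in seq.upper().rstrip("*"))


def _alignment_stats(alignment) -> tuple[int, int, int, int, int, int]:
    """(identical, columns, a_span_start, a_span_end, b_span_start, b_span_end)."""
    a = str(alignment.sequences[0])
    b = str(alignment.sequences[1])
    blocks_a, blocks_b = alignment.aligned
    identical = 0
    columns = 0
    prev_a_end: Optional[int] = None
    prev_b_end: Optional[int] = None
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        if prev_a_end is not None:
            columns += (a0 - prev_a_end) + (b0 - prev_b_end)  # gap columns
        columns += a1 - a0
        identical += sum(1 for i in range(a1 - a0) if a[a0 + i] == b[b0 + i])
        prev_a_end, prev_b_end = a1, b1
    if len(blocks_a) == 0:
        return 0, 0, 0, 0, 0, 0
    return (
        identical,
        columns,
        int(blocks_a[0][0]),
        int(blocks_a[-1][1]),
        int(blocks_b[0][0]),
        int(blocks_b[-1][1]),
    )


def estimate_evalue(
    raw_score: float, m: int, n: int, cfg: Optional[NetworkConfig] = None
) -> float:
    """Karlin–Altschul expectation: bit = (λ·S − ln K)/ln 2, E = m·n·2^(−bit)."""
    cfg = cfg or NetworkConfig()
    bit = (cfg.karlin_lambda * raw_score - math.log(cfg.karlin_k)) / math.log(2)
    return m * n * 2.0 ** (-bit)


def bit_score(raw_score: float, cfg: Optional[NetworkConfig] = None) -> float:
    cfg = cfg or NetworkConfig()
    return (cfg.karlin_lambda * raw_score - math.log(cfg.karlin_k)) / math.log(2)


def local_align(
    a: str, b: str, cfg: Optional[NetworkConfig] = None, db_residues: Optional[int] = None,
    query_id: str = "a", subject_id: str = "b",
) -> AlignmentHit:
    """Optimal Smith–Waterman hit between two peptides.

    Identity is counted over alignment columns (gap columns included);
    coverage is the aligned span of the shorter sequence over its length.
    Non-standard residues are mapped to X (scores 0 against everything).
    *db_residues* sets n in the E-value (defaults to len(b)).
    """
    cfg = cfg or NetworkConfig()
    sa, sb = _sanitize(a), _sanitize(b)
    if not sa or not sb:
        raise ValueError("peptides must be non-empty")
    aligner = _aligner(cfg, "local")
    alignments = aligner.align(sa, sb)
    n_db = db_residues if db_residues is not None else len(sb)
    if alignments.score <= 0:
        return AlignmentHit(
            query_id, subject_id, 0.0, bit_score(0.0, cfg),
            estimate_evalue(0.0, len(sa), n_db, cfg), 0.0, 0, 0.0,
        )
    best = alignments[0]
    identical, columns, a0, a1, b0, b1 = _alignment_stats(best)
    shorter_len = min(len(sa), len(sb))
    span = (a1 - a0) if len(sa) <= len(sb) else (b1 - b0)
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        raw_score=float(alignments.score),
        bit_score=bit_score(alignments.score, cfg),
        evalue=estimate_evalue(alignments.score, len(sa), n_db, cfg),
        identity_pct=100.0 * identical / columns if columns else 0.0,
        hit_len=columns,
        coverage_shorter_pct=100.0 * span / shorter_len,
    )


def hit_passes(hit: AlignmentHit, cfg: NetworkConfig) -> bool:
    return (
        hit.evalue <= cfg.evalue_max
        and hit.identity_pct >= cfg.identity_min_pct
        and hit.coverage_shorter_pct >= cfg.coverage_min_pct
        and hit.hit_len >= cfg.hitlen_min
    )


def build_network(
    peptides: Mapping[str, str], cfg: Optional[NetworkConfig] = None
) -> tuple[list[PeptideNetwork], list[AlignmentHit], list[str]]:
    """All-vs-all networks from peptides {id: sequence}.

    Each unordered pair is aligned once (the hit is symmetric under this
    scheme). Returns (networks ranked by size, passing edges, singleton ids).
    Rank ties are broken by lexicographically smallest member id.
    """
    cfg = cfg or NetworkConfig()
    ids = list(peptides)
    if len(ids) != len(set(ids)):
        raise ValueError("peptide ids must be unique")
    total_residues = sum(len(_sanitize(s)) for s in peptides.values())
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    edges: list[AlignmentHit] = []
    for i, qid in enumerate(ids):
        for sid in ids[i + 1 :]:
            hit = local_align(
                peptides[qid], peptides[sid], cfg,
                db_residues=total_residues, query_id=qid, subject_id=sid,
            )
            if hit_passes(hit, cfg):
                edges.append(hit)
                graph.add_edge(qid, sid)
    components = [sorted(c) for c in nx.connected_components(graph)]
    multi = sorted(
        (c for c in components if len(c) > 1), key=lambda c: (-len(c), c[0])
    )
    networks = [
        PeptideNetwork(rank=r, member_ids=c, size=len(c))
        for r, c in enumerate(multi, start=1)
    ]
    singletons = sorted(c[0] for c in components if len(c) == 1)
    return networks, edges, singletons


def export_network(
    networks: Sequence[PeptideNetwork],
    edges: Sequence[AlignmentHit],
    node_attributes: Mapping[str, Mapping[str, object]],
    sif_path,
    attr_path,
    edge_path=None,
) -> None:
    """Write Cytoscape SIF plus a node-attribute TSV (and optional edge TSV)."""
    with open(sif_path, "w") as fh:
        for e in sorted(edges, key=lambda e: (e.query_id, e.subject_id)):
            fh.write(f"{e.query_id}\tsim\t{e.subject_id}\n")
    rank_of = {m: nw.rank for nw in networks for m in nw.member_ids}
    keys: list[str] = []
    for attrs in node_attributes.values():
        for k in attrs:
            if k not in keys:
                keys.append(k)
    with open(attr_path, "w") as fh:
        fh.write("\t".join(["id", "network_rank"] + keys) + "\n")
        for nid in sorted(node_attributes):
            attrs = node_attributes[nid]
            rank = rank_of.get(nid, "")
            fh.write(
                "\t".join(
                    [str(nid), str(rank)] + [str(attrs.get(k, "")) for k in keys]
                )
                + "\n"
            )
    if edge_path is not None:
        with open(edge_path, "w") as fh:
            fh.write(
                "query_id\tsubject_id\traw_score\tbit_score\tevalue\t"
                "identity_pct\thit_len\tcoverage_shorter_pct\n"
            )
            for e in sorted(edges, key=lambda e: (e.query_id, e.subject_id)):
                fh.write(
                    f"{e.query_id}\t{e.subject_id}\t{e.raw_score:g}\t"
                    f"{e.bit_score:.3f}\t{e.evalue:.4g}\t{e.identity_pct:.2f}\t"
                    f"{e.hit_len}\t{e.coverage_shorter_pct:.2f}\n"
                )


def read_sif(path) -> nx.Graph:
    graph = nx.Graph()
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) == 3:
                graph.add_edge(parts[0], parts[2])
    return graph


def global_identity_pct(a: str, b: str, cfg: Optional[NetworkConfig] = None) -> float:
    """Percent identity over columns of the optimal global alignment."""
    cfg = cfg or NetworkConfig()
    sa, sb = _sanitize(a), _sanitize(b)
    aligner = _aligner(cfg, "global")
    best = aligner.align(sa, sb)[0]
    identical, columns, *_ = _alignment_stats(best)
    # global alignment: terminal gaps count as columns too
    blocks_a, blocks_b = best.aligned
    if len(blocks_a):
        lead = max(int(blocks_a[0][0]), int(blocks_b[0][0]))
        trail = max(len(sa) - int(blocks_a[-1][1]), len(sb) - int(blocks_b[-1][1]))
        columns += lead + trail
    else:
        columns = max(len(sa), len(sb))
    return 100.0 * identical / columns if columns else 0.0


def dereplicate(
    sequences: Mapping[str, str], identity_threshold_pct: float = 99.0
) -> tuple[list[str], dict[str, str]]:
    """Greedy dereplication at ≥ *identity_threshold_pct* global identity.

    Sequences are processed longest-first; each either joins the first
    representative it matches at or above the threshold or founds a new one.
    Returns (representative ids, {sequence id: representative id}).
    """
    order = sorted(sequences, key=lambda k: (-len(sequences[k]), k))
    reps: list[str] = []
    membership: dict[str, str] = {}
    for sid in order:
        for rep in reps:
            if sequences[sid] == sequences[rep] or global_identity_pct(
                sequences[sid], sequences[rep]
            ) >= identity_threshold_pct:
                membership[sid] = rep
                break
        else:
            reps.append(sid)
            membership[sid] = sid
    return reps, membership
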