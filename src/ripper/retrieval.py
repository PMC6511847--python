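"""Filtering, strand reward, distance rules and top-N/threshold retrieval.

This is the decision core of the workflow: candidate short ORFs are kept only
if they barely overlap existing annotation (≤ 20 nt) and encode a peptide in
the precursor size window (20–120 aa by default); same-strand candidates get a
score reward; within ±8 kb of the tailoring enzyme the top 3 scorers are
always retrieved plus everything above the score threshold; everything else is
eligible for domain-based rescue into the ``distant`` bucket.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional, Sequence

from .io_genbank import GeneFeature, GenomicRegion
from .orf_caller import CandidateOrf, CodingModel, score_candidate, translate_cds

OUT_COLUMNS = [
    "te_accession",
    "source_accession",
    "strain",
    "peptide",
    "distance_nt",
    "same_strand",
    "score",
    "annotated",
    "start",
    "end",
    "strand",
    "domains",
]


@dataclass
class RipperConfig:
    """Workflow parameters (defaults follow the tool's standard analysis)."""

    flank_len: int = 17500
    same_strand_reward: float = 5.0
    min_pp_len: int = 20
    max_pp_len: int = 120
    max_dist_from_te: int = 8000
    fasta_output_limit: int = 3
    prodigal_score_thresh: float = 7.5
    max_overlap_nt: int = 20

    def __post_init__(self) -> None:
        if self.min_pp_len >= self.max_pp_len:
            raise ValueError("min_pp_len must be < max_pp_len")
        for name in ("flank_len", "min_pp_len", "max_pp_len", "max_dist_from_te"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class RetrievedPeptide:
    """One tabulated retrieval row (out.txt / distant.txt)."""

    te_accession: str
    source_accession: str
    strain: str
    peptide: str
    distance_nt: int
    same_strand: bool
    score: float
    annotated: bool
    start: int
    end: int
    strand: int
    domains: list[str] = field(default_factory=list)
    bucket: str = "retrieved"

    @property
    def key(self) -> tuple[str, int, int, int]:
        return (self.source_accession, self.start, self.end, self.strand)


def interval_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Length of the intersection of two half-open intervals (strand-blind)."""
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def filter_candidates(
    candidates: Iterable[CandidateOrf],
    features: Sequence[GeneFeature],
    cfg: RipperConfig,
) -> list[CandidateOrf]:
    """Keep candidates overlapping every annotated gene by ≤ max_overlap_nt
    and encoding a peptide within [min_pp_len, max_pp_len]."""
    annotated = [f for f in features if f.annotated and f.kind == "CDS"]
    kept = []
    for c in candidates:
        if not (cfg.min_pp_len <= len(c.peptide) <= cfg.max_pp_len):
            continue
        if any(
            interval_overlap(c.start, c.end, f.start, f.end) > cfg.max_overlap_nt
            for f in annotated
        ):
            continue
        kept.append(c)
    return kept


def apply_strand_reward(
    candidates: Iterable[CandidateOrf], rte: GeneFeature, reward: float
) -> list[CandidateOrf]:
    """Add *reward* to total_score of same-strand candidates, exactly once.

    A second application is a no-op (flagged per candidate); annotated short
    genes are rewarded the same way as unannotated candidates.
    """
    out = []
    for c in candidates:
        if not c.strand_reward_applied:
            if c.strand == rte.strand:
                c.total_score += reward
            c.strand_reward_applied = True
        else:
            c.notes = (c.notes + "; strand reward already applied").lstrip("; ")
        out.append(c)
    return out


def distance_from_te(item, rte: GeneFeature) -> int:
    """Gap in nt between two intervals; 0 if they overlap or abut."""
    if item.start >= rte.end:
        return item.start - rte.end
    if rte.start >= item.end:
        return rte.start - item.end
    return 0


def collect_annotated_short_genes(
    region: GenomicRegion, cfg: RipperConfig, model: CodingModel
) -> list[CandidateOrf]:
    """Wrap annotated CDS encoding ≤ max_pp_len aa as scored candidates.

    These bypass the overlap filter (they are the annotation) and min_pp_len;
    the tailoring enzyme itself is excluded since it anchors the search.
    """
    out = []
    for f in region.features:
        if f.kind != "CDS" or not f.annotated:
            continue
        if f.feature_id == region.rte_feature_id:
            continue
        peptide = f.translation
        if peptide is None:
            try:
                peptide = translate_cds(
                    region.sequence[f.start : f.end], f.strand
                )
            except ValueError:
                continue
        if len(peptide) > cfg.max_pp_len:
            continue
        orf = CandidateOrf(
            start=f.start,
            end=f.end,
            strand=f.strand,
            peptide=peptide,
            annotated=True,
            feature_id=f.feature_id,
        )
        out.append(score_candidate(orf, model, region))
    return out


def _as_row(
    c: CandidateOrf,
    rte: GeneFeature,
    te_accession: str,
    source_accession: str,
    strain: str,
    bucket: str,
) -> RetrievedPeptide:
    return RetrievedPeptide(
        te_accession=te_accession,
        source_accession=source_accession,
        strain=strain,
        peptide=c.peptide,
        distance_nt=distance_from_te(c, rte),
        same_strand=c.strand == rte.strand,
        score=c.total_score,
        annotated=c.annotated,
        start=c.start,
        end=c.end,
        strand=c.strand,
        bucket=bucket,
    )


def select_peptides(
    candidates: Sequence[CandidateOrf],
    region: GenomicRegion,
    cfg: RipperConfig,
) -> list[RetrievedPeptide]:
    """Retrieve peptides near the tailoring enzyme (bucket = retrieved).

    Among items within max_dist_from_te: the fasta_output_limit top scorers
    (no lower threshold; ties broken by smaller distance then lower start)
    plus every further item scoring ≥ prodigal_score_thresh. Deduplicated by
    (source accession, start, end, strand) so identical peptide sequences at
    different loci are all kept.
    """
    rte = region.rte
    in_window = [
        c for c in candidates if distance_from_te(c, rte) <= cfg.max_dist_from_te
    ]
    in_window.sort(
        key=lambda c: (-c.total_score, distance_from_te(c, rte), c.start)
    )
    chosen: list[CandidateOrf] = []
    seen = set()
    for i, c in enumerate(in_window):
        if i >= cfg.fasta_output_limit and c.total_score < cfg.prodigal_score_thresh:
            continue
        if c.key in seen:
            continue
        seen.add(c.key)
        chosen.append(c)
    return [
        _as_row(
            c, rte, region.rte_feature_id, region.accession, region.organism,
            "retrieved",
        )
        for c in chosen
    ]


def rescue_distant(
    all_candidates: Sequence[CandidateOrf],
    retrieved: Sequence[RetrievedPeptide],
    domain_hits: dict[tuple[int, int, int], list[str]],
    region: GenomicRegion,
) -> list[RetrievedPeptide]:
    """Rescue non-retrieved peptides bearing a precursor-domain hit.

    Every candidate not in the retrieved set — no distance or score threshold
    — that has at least one domain hit lands in the distant bucket with its
    hit names; candidates without hits are dropped.
    """
    rte = region.rte
    retrieved_keys = {(r.start, r.end, r.strand) for r in retrieved}
    out = []
    for c in all_candidates:
        if c.key in retrieved_keys:
            continue
        hits = domain_hits.get(c.key, [])
        if not hits:
            continue
        row = _as_row(
            c, rte, region.rte_feature_id, region.accession, region.organism,
            "distant",
        )
        row.domains = list(hits)
        out.append(row)
    # dedup by coordinates (shared-stop duplicates are distinct keys already)
    seen = set()
    uniq = []
    for r in out:
        if r.key not in seen:
            seen.add(r.key)
            uniq.append(r)
    return uniq


def tabulate(rows: Iterable[RetrievedPeptide], path) -> None:
    """Write rows as a tab-separated table with a single header row.

    Rows from multiple regions are collated into the one file by the caller;
    scores are fixed to 3 decimals so re-runs are byte-identical.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(OUT_COLUMNS)
        for r in rows:
            w.writerow(
                [
                    r.te_accession,
                    r.source_accession,
                    r.strain,
                    r.peptide,
                    r.distance_nt,
                    int(r.same_strand),
                    f"{r.score:.3f}",
                    int(r.annotated),
                    r.start,
                    r.end,
                    "+" if r.strand == 1 else "-",
                    ";".join(r.domains),
                ]
            )


def read_table(path) -> list[RetrievedPeptide]:
    """Parse an out.txt/distant.txt back into RetrievedPeptide rows."""
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(
                RetrievedPeptide(
                    te_accession=row["te_accession"],
                    source_accession=row["source_accession"],
                    strain=row["strain"],
                    peptide=row["peptide"],
                    distance_nt=int(row["distance_nt"]),
                    same_strand=bool(int(row["same_strand"])),
                    score=float(row["score"]),
                    annotated=bool(int(row["annotated"])),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=1 if row["strand"] == "+" else -1,
                    domains=[d for d in row["domains"].split(";") if d],
                )
            )
    return out
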