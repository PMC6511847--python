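"""End-to-end orchestration over one or many genomic regions.

Per region: window around the tailoring enzyme → self-train the coding model →
enumerate and score short ORFs → overlap/size filters → strand reward →
top-N/threshold retrieval → domain rescue of distant peptides → annotated
GenBank. Across regions: collated out.txt/distant.txt tables, collated FASTA,
and one similarity network over all retrieved (and distant) peptides.
"""

from __future__ import annotations

import os
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import io_genbank
from .domain_scan import DomainProfile, load_profiles, scan_peptide
from .io_genbank import GenomicRegion, read_genbank, extract_window
from .networking import NetworkConfig, build_network, export_network
from .orf_caller import enumerate_orfs, score_candidate, train_coding_model
from .retrieval import (
    RetrievedPeptide,
    RipperConfig,
    apply_strand_reward,
    collect_annotated_short_genes,
    filter_candidates,
    rescue_distant,
    select_peptides,
    tabulate,
)

CONFIG_KEYS = {
    "flankLen": ("ripper", "flank_len", int),
    "sameStrandReward": ("ripper", "same_strand_reward", float),
    "minPPlen": ("ripper", "min_pp_len", int),
    "maxPPlen": ("ripper", "max_pp_len", int),
    "maxDistFromTE": ("ripper", "max_dist_from_te", int),
    "fastaOutputLimit": ("ripper", "fasta_output_limit", int),
    "prodigalScoreThresh": ("ripper", "prodigal_score_thresh", float),
    "maxOverlapNt": ("ripper", "max_overlap_nt", int),
    "evalueMax": ("network", "evalue_max", float),
    "identityMinPct": ("network", "identity_min_pct", float),
    "coverageMinPct": ("network", "coverage_min_pct", float),
    "hitlenMin": ("network", "hitlen_min", int),
}


def parse_local_conf(path) -> tuple[RipperConfig, NetworkConfig]:
    """Parse a flat ``key = value`` configuration file (local.conf style).

    Unknown keys raise; missing keys keep their defaults.
    """
    rip: dict = {}
    net: dict = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in CONFIG_KEYS:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            section, attr, cast = CONFIG_KEYS[key]
            (rip if section == "ripper" else net)[attr] = cast(val)
    return RipperConfig(**rip), NetworkConfig(**net)


@dataclass
class RunManifest:
    inputs: list[tuple[str, Optional[str]]]  # (GenBank path, RTE id or None)
    config: RipperConfig = field(default_factory=RipperConfig)
    net_config: NetworkConfig = field(default_factory=NetworkConfig)
    output_dir: str = "ripper_out"
    profiles_path: Optional[str] = None
    build_networks: bool = True
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.inputs:
            raise ValueError("manifest requires at least one input region")


def process_region(
    region: GenomicRegion,
    cfg: RipperConfig,
    profiles: Sequence[DomainProfile] = (),
) -> tuple[list[RetrievedPeptide], list[RetrievedPeptide], list]:
    """Run the per-region workflow on an already-loaded region.

    Returns (retrieved rows, distant rows, all scored candidates for the
    annotated GenBank output).
    """
    window = extract_window(region, cfg.flank_len)
    model = train_coding_model(window)
    raw = enumerate_orfs(window, min_nt=60, max_aa=cfg.max_pp_len)
    candidates = filter_candidates(raw, window.features, cfg)
    for c in candidates:
        score_candidate(c, model, window)
    pool = candidates + collect_annotated_short_genes(window, cfg, model)
    apply_strand_reward(pool, window.rte, cfg.same_strand_reward)
    retrieved = select_peptides(pool, window, cfg)

    domain_hits: dict[tuple[int, int, int], list[str]] = {}
    if profiles:
        for c in pool:
            hits = scan_peptide(c.peptide, profiles)
            if hits:
                domain_hits[c.key] = [h.profile_name for h in hits]
        by_key = {r.key[1:]: r for r in retrieved}
        for key, names in domain_hits.items():
            if key in by_key:
                by_key[key].domains = list(names)
    distant = rescue_distant(pool, retrieved, domain_hits, window)
    return retrieved, distant, pool


def run_ripper(manifest: RunManifest) -> dict:
    """Execute the workflow over every region in the manifest.

    A failing region is logged and skipped; the run fails only if all regions
    fail. Outputs land in manifest.output_dir: one annotated GenBank per
    region, collated out.txt/distant.txt and out.faa/distant.faa, and (when ≥ 2
    peptides were retrieved) network SIF/TSV exports. Rows are sorted by
    source accession then distance, so identical runs are byte-identical.
    """
    outdir = Path(manifest.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    profiles = (
        load_profiles(manifest.profiles_path) if manifest.profiles_path else []
    )
    cfg = manifest.config
    all_retrieved: list[RetrievedPeptide] = []
    all_distant: list[RetrievedPeptide] = []
    per_region: dict[str, dict] = {}
    failures: list[str] = []

    for path, rte_id in manifest.inputs:
        try:
            region = read_genbank(path, rte_id=rte_id)
            retrieved, distant, pool = process_region(region, cfg, profiles)
            window = extract_window(region, cfg.flank_len)
            selected_keys = {r.key[1:] for r in retrieved} | {
                r.key[1:] for r in distant
            }
            shown = [c for c in pool if c.key in selected_keys and not c.annotated]
            io_genbank.write_annotated_genbank(
                window, shown, outdir / f"{region.accession}.ripper.gbk"
            )
            all_retrieved.extend(retrieved)
            all_distant.extend(distant)
            per_region[region.accession] = {
                "retrieved": len(retrieved),
                "distant": len(distant),
                "candidates": len(pool),
            }
        except Exception as exc:  # noqa: BLE001 — skip & report bad regions
            failures.append(f"{path}: {exc}")
            manifest.log.append(traceback.format_exc())
    if not per_region:
        raise RuntimeError("all regions failed: " + "; ".join(failures))

    sort_key = lambda r: (r.source_accession, r.distance_nt, r.start)  # noqa: E731
    all_retrieved.sort(key=sort_key)
    all_distant.sort(key=sort_key)
    tabulate(all_retrieved, outdir / "out.txt")
    tabulate(all_distant, outdir / "distant.txt")
    io_genbank.write_fasta(all_retrieved, outdir / "out.faa")
    io_genbank.write_fasta(all_distant, outdir / "distant.faa")

    networks = []
    if manifest.build_networks:
        peptides = {
            io_genbank.fasta_header(r): r.peptide
            for r in all_retrieved + all_distant
        }
        if len(peptides) >= 2:
            networks, edges, singletons = build_network(
                peptides, manifest.net_config
            )
            attrs = {
                io_genbank.fasta_header(r): {
                    "peptide": r.peptide,
                    "score": f"{r.score:.3f}",
                    "distance_nt": r.distance_nt,
                    "bucket": r.bucket,
                }
                for r in all_retrieved + all_distant
            }
            export_network(
                networks,
                edges,
                attrs,
                outdir / "network.sif",
                outdir / "node_attributes.tsv",
                outdir / "edges.tsv",
            )
            with open(outdir / "networks.tsv", "w") as fh:
                fh.write("rank\tsize\tmembers\n")
                for nw in networks:
                    fh.write(f"{nw.rank}\t{nw.size}\t{';'.join(nw.member_ids)}\n")

    return {
        "regions": per_region,
        "failures": failures,
        "retrieved_total": len(all_retrieved),
        "distant_total": len(all_distant),
        "networks": [(nw.rank, nw.size) for nw in networks],
        "output_dir": str(outdir),
    }
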