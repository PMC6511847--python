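"""Seeded synthetic genomic regions, peptide families and reference comparison.

Every stage of the mining workflow is testable without downloads: this module
emulates actinobacterial input regions — GC-rich contigs carrying annotated
genes that share a codon-usage table and Shine–Dalgarno motifs, one marked
tailoring enzyme, and planted *unannotated* short precursor ORFs with the same
codon usage and RBS at controlled distances and strands from the enzyme. A
truth table records what was planted so recovery can be scored exactly.

What this emulates: compositional contrast between genes and intergenic DNA,
RBS-driven starts, realistic gene density, precursor placement inside/outside
the retrieval window. What it does not: real taxonomic codon tables,
sequencing error, horizontally transferred segments, operonic structure —
so passing tests demonstrate the workflow's selection logic, not performance
on any particular genome.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

from Bio.Data.CodonTable import unambiguous_dna_by_id

from .domain_scan import DomainProfile, profile_from_consensus
from .io_genbank import GeneFeature, GenomicRegion, write_genbank
from .orf_caller import translate_cds

_TABLE11 = unambiguous_dna_by_id[11]

#: toy precursor-domain consensus embedded in planted distant precursors;
#: synthetic stand-in for a characterized precursor-domain model
DOMAIN_CONSENSUS = "LTEEQLIEVAGGFGC"

AA20 = "ACDEFGHIKLMNPQRSTVWY"


class PlantedPrecursor(NamedTuple):
    length_aa: int  # encoded peptide length (stop codon excluded)
    distance_nt: int  # gap to the RTE; negative = upstream (left) side
    strand: int = 1  # relative to the RTE: +1 same strand, -1 opposite
    has_domain: bool = False


@dataclass
class RegionSpec:
    """Parameters of one synthetic region; deterministic for a fixed seed."""

    seed: int
    length_nt: int = 25000
    gc_fraction: float = 0.65
    n_genes: int = 10
    rbs_motif: str = "AGGAGG"
    planted_precursors: list[PlantedPrecursor] = field(default_factory=list)
    rte_index: Optional[int] = None  # position of the RTE in gene order
    codon_usage: Optional[dict[str, dict[str, float]]] = None

    def __post_init__(self) -> None:
        if not 0 < self.gc_fraction < 1:
            raise ValueError("gc_fraction must be in (0, 1)")
        for p in self.planted_precursors:
            if not 20 <= p.length_aa <= 120:
                raise ValueError("planted precursor lengths must be in [20, 120]")


class TruthRecord(NamedTuple):
    start: int
    end: int
    strand: int
    peptide: str
    distance_nt: int
    has_domain: bool


def default_codon_usage(gc_fraction: float) -> dict[str, dict[str, float]]:
    """Back-translation weights favouring G/C at each position per the GC target."""
    p = {
        "G": gc_fraction / 2,
        "C": gc_fraction / 2,
        "A": (1 - gc_fraction) / 2,
        "T": (1 - gc_fraction) / 2,
    }
    usage: dict[str, dict[str, float]] = {}
    for codon, aa in _TABLE11.forward_table.items():
        w = p[codon[0]] * p[codon[1]] * p[codon[2]]
        usage.setdefault(aa, {})[codon] = w
    for aa, codons in usage.items():
        total = sum(codons.values())
        usage[aa] = {c: w / total for c, w in codons.items()}
    return usage


def _weighted_choice(rng: random.Random, weights: dict[str, float]) -> str:
    r = rng.random() * sum(weights.values())
    acc = 0.0
    for k, w in weights.items():
        acc += w
        if r <= acc:
            return k
    return k  # floating-point edge


def _encode_peptide(
    rng: random.Random,
    peptide: str,
    usage: dict[str, dict[str, float]],
    start_codon: str,
    stop_codon: str,
) -> str:
    codons = [start_codon]
    for aa in peptide[1:]:
        codons.append(_weighted_choice(rng, usage[aa]))
    codons.append(stop_codon)
    return "".join(codons)


def _random_peptide(rng: random.Random, length: int) -> str:
    return "M" + "".join(rng.choice(AA20) for _ in range(length - 1))


def _background(rng: random.Random, length: int, gc: float) -> str:
    """Stop-rich random background: a stop codon is injected roughly every
    16 frame-0 codons to suppress accidental long ORFs where the GC target
    would otherwise make stops rare."""
    bases_gc = "GC"
    bases_at = "AT"
    stops = ("TAA", "TAG", "TGA")
    out = []
    n_codons = length // 3 + 1
    for i in range(n_codons):
        if i % 16 == 15:
            out.append(rng.choice(stops))
        else:
            for _ in range(3):
                out.append(
                    rng.choice(bases_gc) if rng.random() < gc else rng.choice(bases_at)
                )
    return "".join(out)[:length]


def _pick_start(rng: random.Random) -> str:
    r = rng.random()
    return "ATG" if r < 0.8 else ("GTG" if r < 0.95 else "TTG")


def _pick_stop(rng: random.Random) -> str:
    r = rng.random()
    return "TGA" if r < 0.5 else ("TAA" if r < 0.75 else "TAG")


def _overlaps(a: tuple[int, int], blocks: Sequence[tuple[int, int]], pad: int = 0) -> bool:
    return any(a[0] - pad < e and s < a[1] + pad for s, e in blocks)


def _domain_peptide(rng: random.Random, length: int) -> str:
    core = DOMAIN_CONSENSUS
    if length < len(core) + 2:
        raise ValueError("domain-bearing precursor too short for the consensus")
    lead = rng.randint(0, length - 1 - len(core))
    tail = length - 1 - len(core) - lead
    return (
        "M"
        + "".join(rng.choice(AA20) for _ in range(lead))
        + core
        + "".join(rng.choice(AA20) for _ in range(tail))
    )


def make_synthetic_region(spec: RegionSpec) -> tuple[GenomicRegion, list[TruthRecord]]:
    """Build a region per *spec*; returns (region, truth table of planted ORFs).

    Annotated genes and planted precursors share the codon-usage table and the
    RBS motif (spacer 5–9 nt); precursors are not annotated as features.
    """
    rng = random.Random(spec.seed)
    L = spec.length_nt
    usage = spec.codon_usage or default_codon_usage(spec.gc_fraction)
    seq = list(_background(rng, L, spec.gc_fraction))
    margin = 60

    def write_gene(start: int, nt: str, strand: int) -> None:
        if strand == 1:
            seq[start : start + len(nt)] = nt
        else:
            rc = translate_rc(nt)
            seq[start : start + len(nt)] = rc

    def translate_rc(nt: str) -> str:
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
        return "".join(comp[b] for b in reversed(nt))

    def write_rbs(start: int, end: int, strand: int) -> None:
        spacer = rng.randint(5, 9)
        motif = spec.rbs_motif
        if strand == 1 and start - spacer - len(motif) >= 0:
            seq[start - spacer - len(motif) : start - spacer] = motif
        elif strand == -1 and end + spacer + len(motif) <= L:
            seq[end + spacer : end + spacer + len(motif)] = translate_rc(motif)

    # --- tailoring enzyme, centered -----------------------------------------
    rte_aa = rng.randint(400, 600)
    rte_nt_len = 3 * (rte_aa + 1)
    rte_start = L // 2 - rte_nt_len // 2
    rte_end = rte_start + rte_nt_len
    rte_strand = rng.choice((1, -1))
    reserved: list[tuple[int, int]] = [(rte_start - 20, rte_end + 20)]

    # --- planted precursors at controlled distances -------------------------
    truth: list[TruthRecord] = []
    precursor_blocks: list[tuple[int, int, int, str]] = []
    for p in spec.planted_precursors:
        orf_nt = 3 * (p.length_aa + 1)
        d = p.distance_nt
        if d >= 0:
            start = rte_end + d
        else:
            start = rte_start - (-d) - orf_nt
        end = start + orf_nt
        if start < margin or end > L - margin:
            raise ValueError(
                f"planted precursor at distance {d} does not fit in region"
            )
        block = (start - 20, end + 20)
        if _overlaps(block, reserved):
            raise ValueError("planted precursors collide with the RTE or each other")
        reserved.append(block)
        peptide = (
            _domain_peptide(rng, p.length_aa)
            if p.has_domain
            else _random_peptide(rng, p.length_aa)
        )
        nt = _encode_peptide(rng, peptide, usage, _pick_start(rng), _pick_stop(rng))
        strand = rte_strand * p.strand
        precursor_blocks.append((start, end, strand, peptide))
        truth.append(TruthRecord(start, end, strand, peptide, abs(d), p.has_domain))
        write_gene(start, nt, strand)
        write_rbs(start, end, strand)

    # --- annotated genes outward from the RTE --------------------------------
    n_other = max(0, spec.n_genes - 1)
    gene_defs: list[tuple[int, int]] = []  # (start, aa_len) later
    gene_lengths = []
    short_idx = rng.randrange(n_other) if n_other else -1
    for i in range(n_other):
        if i == short_idx:
            gene_lengths.append(rng.randint(85, 110))  # one short annotated gene
        else:
            gene_lengths.append(rng.randint(150, 400))
    n_right = n_other // 2
    placements: list[tuple[int, int, int]] = []  # (start, end, aa_len)

    def place_side(lengths: Sequence[int], rightward: bool) -> None:
        cursor = rte_end if rightward else rte_start
        for aa_len in lengths:
            nt_len = 3 * (aa_len + 1)
            gap = rng.randint(150, 450)
            for _ in range(50):
                if rightward:
                    start = cursor + gap
                    end = start + nt_len
                else:
                    end = cursor - gap
                    start = end - nt_len
                if start < margin or end > L - margin:
                    return
                if _overlaps((start, end), reserved, pad=40):
                    # jump past the blocking reservation
                    blockers = [
                        b for b in reserved if b[0] - 40 < end and start < b[1] + 40
                    ]
                    if rightward:
                        cursor = max(b[1] for b in blockers) + 40
                    else:
                        cursor = min(b[0] for b in blockers) - 40
                    continue
                placements.append((start, end, aa_len))
                reserved.append((start - 20, end + 20))
                cursor = end if rightward else start
                break

    place_side(gene_lengths[:n_right], rightward=True)
    place_side(gene_lengths[n_right:], rightward=False)

    features: list[GeneFeature] = []
    acc = f"SYN{spec.seed & 0x7FFFFFFF:010d}"
    genes: list[tuple[int, int, int, str, str]] = [
        (rte_start, rte_end, rte_strand, "rte", "TfuA-like RiPP tailoring protein")
    ]
    for start, end, aa_len in placements:
        genes.append((start, end, rng.choice((1, -1)), "gene", "hypothetical protein"))
    genes.sort()
    rte_id = ""
    for i, (start, end, strand, kind, product) in enumerate(genes, 1):
        peptide = _random_peptide(rng, (end - start) // 3 - 1)
        nt = _encode_peptide(rng, peptide, usage, _pick_start(rng), _pick_stop(rng))
        write_gene(start, nt, strand)
        write_rbs(start, end, strand)
        fid = f"{acc}_g{i:02d}"
        if kind == "rte":
            rte_id = fid
        features.append(
            GeneFeature(
                feature_id=fid,
                start=start,
                end=end,
                strand=strand,
                product=product,
                translation=peptide,
            )
        )

    region = GenomicRegion(
        accession=acc,
        organism=f"Synthetica exemplaris seed{spec.seed}",
        sequence="".join(seq),
        features=features,
        rte_feature_id=rte_id,
        log=[f"synthetic region seed={spec.seed}"],
    )
    return region, truth


def standard_region_spec(
    seed: int, with_distant: bool = False, length_nt: int = 25000
) -> RegionSpec:
    """The default study condition: a 25 kb, 65% GC region with 10 annotated
    genes and one same-strand precursor planted inside the ±8 kb window
    (optionally plus one distant domain-bearing precursor beyond it)."""
    rng = random.Random(seed ^ 0x5EED)
    planted = [
        PlantedPrecursor(
            length_aa=rng.randint(25, 90),
            distance_nt=rng.randint(500, 6000) * rng.choice((1, -1)),
            strand=1,  # same strand as the RTE
            has_domain=False,
        )
    ]
    if with_distant:
        planted.append(
            PlantedPrecursor(
                length_aa=rng.randint(40, 90),
                distance_nt=rng.randint(8600, 10200),
                strand=1,
                has_domain=True,
            )
        )
    return RegionSpec(seed=seed, length_nt=length_nt, planted_precursors=planted)


def toy_profiles() -> list[DomainProfile]:
    """The profile set matching the planted domain consensus (synthetic
    stand-in for characterized precursor-domain models)."""
    return [
        profile_from_consensus(
            "toy_precursor_domain", DOMAIN_CONSENSUS, match=2.0, mismatch=-1.0,
            threshold=20.0,
        )
    ]


def write_region_fixture(spec: RegionSpec, genbank_path, truth_path=None):
    """Write the region as GenBank (RTE marked by qualifier) plus a truth TSV."""
    region, truth = make_synthetic_region(spec)
    write_genbank(region, genbank_path)
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            fh.write("start\tend\tstrand\tpeptide\tdistance_nt\thas_domain\n")
            for t in truth:
                fh.write(
                    f"{t.start}\t{t.end}\t{'+' if t.strand == 1 else '-'}\t"
                    f"{t.peptide}\t{t.distance_nt}\t{int(t.has_domain)}\n"
                )
    return region, truth


def make_peptide_family(
    seed: int,
    n_families: int,
    family_sizes: Sequence[int],
    substitution_rate: float,
    length: int = 50,
    n_singletons: int = 0,
) -> tuple[dict[str, str], dict[str, str]]:
    """Grow peptide families from random ancestors by per-site substitution.

    Returns ({id: sequence}, {id: family label}); singletons are unrelated
    random sequences labelled "singleton". At substitution rates ≤ 0.25,
    family members stay above the 40% identity networking threshold with high
    probability while unrelated sequences stay below it.
    """
    if len(family_sizes) != n_families:
        raise ValueError("family_sizes must have n_families entries")
    rng = random.Random(seed)
    seqs: dict[str, str] = {}
    labels: dict[str, str] = {}
    for fi in range(n_families):
        ancestor = "".join(rng.choice(AA20) for _ in range(length))
        for mi in range(family_sizes[fi]):
            member = [
                (rng.choice(AA20) if rng.random() < substitution_rate else aa)
                for aa in ancestor
            ]
            sid = f"fam{fi + 1}_{mi + 1}"
            seqs[sid] = "".join(member)
            labels[sid] = f"fam{fi + 1}"
    for si in range(n_singletons):
        sid = f"single_{si + 1}"
        seqs[sid] = "".join(rng.choice(AA20) for _ in range(length))
        labels[sid] = "singleton"
    return seqs, labels


class ReferenceComparison(NamedTuple):
    matched: int
    total_reference: int
    fraction: float


def compare_to_reference(
    retrieved_peptides: Sequence[str], reference_peptides: Sequence[str]
) -> ReferenceComparison:
    """Fraction of reference peptides recovered, by exact sequence equality
    (trailing stop marks stripped) — the strictest reproducible match rule."""
    retrieved = {p.rstrip("*") for p in retrieved_peptides}
    reference = [p.rstrip("*") for p in reference_peptides]
    matched = sum(1 for p in reference if p in retrieved)
    total = len(reference)
    return ReferenceComparison(matched, total, matched / total if total else 0.0)
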