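"""GenBank and FASTA input/output for genomic regions around RiPP tailoring enzymes.

Internal coordinates are 0-based half-open throughout; conversion to GenBank's
1-based inclusive convention happens only at the file boundary (Biopython does
this for us). Compound (``join``) locations are rejected: the bacterial regions
this tool targets carry single-span CDS features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

RTE_QUALIFIER = "ripper_rte"
CANDIDATE_QUALIFIER = "ripper_candidate"

#: Artemis /colour convention, "R G B"
RTE_COLOUR = (0, 255, 0)
RAMP_LOW = (255, 200, 200)  # pale red, lowest score in file
RAMP_HIGH = (255, 0, 255)  # bright pink, highest score in file


@dataclass
class GeneFeature:
    """An annotated gene (or other) feature on a region, 0-based half-open."""

    feature_id: str
    start: int
    end: int
    strand: int
    kind: str = "CDS"
    product: str = ""
    translation: Optional[str] = None
    annotated: bool = True
    notes: str = ""

    def __post_init__(self) -> None:
        if self.strand not in (1, -1):
            raise ValueError(f"strand must be +1 or -1, got {self.strand}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomicRegion:
    """A nucleotide region with annotated features and one designated RTE."""

    accession: str
    organism: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    rte_feature_id: str = ""
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features.sort(key=lambda f: (f.start, f.end))

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def rte(self) -> GeneFeature:
        for f in self.features:
            if f.feature_id == self.rte_feature_id:
                return f
        raise KeyError(
            f"RTE feature {self.rte_feature_id!r} not found in {self.accession}"
        )


class RteNotFoundError(KeyError):
    """Raised when the designated tailoring-enzyme feature cannot be located."""


def _feature_identifier(feat: SeqFeature, index: int) -> str:
    for key in ("protein_id", "locus_tag", "gene"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    return f"cds_{index}"


def read_genbank(path, rte_id: Optional[str] = None) -> GenomicRegion:
    """Read a single-record GenBank flat file into a :class:`GenomicRegion`.

    The tailoring enzyme is designated, in order of precedence, by a
    ``/ripper_rte`` qualifier on a CDS, by *rte_id* matching a CDS
    protein_id/locus_tag/gene, or — as an explicit logged fallback — by the
    CDS nearest the record midpoint (mimicking RODEO regions centered on the
    enzyme).
    """
    record = SeqIO.read(str(path), "genbank")
    seq = str(record.seq).upper()
    if not seq:
        raise ValueError(f"{path}: record has no ORIGIN sequence")

    log: list[str] = []
    features: list[GeneFeature] = []
    rte_feature_id = ""
    for i, feat in enumerate(record.features):
        if feat.type not in ("CDS",):
            continue
        if len(feat.location.parts) > 1:
            raise ValueError(
                f"{record.id}: compound (join) location unsupported "
                f"for feature {_feature_identifier(feat, i)}"
            )
        fid = _feature_identifier(feat, i)
        annotated = CANDIDATE_QUALIFIER not in feat.qualifiers
        gf = GeneFeature(
            feature_id=fid,
            start=int(feat.location.start),
            end=int(feat.location.end),
            strand=int(feat.location.strand or 1),
            kind="CDS",
            product=str(feat.qualifiers.get("product", [""])[0]),
            translation=(
                str(feat.qualifiers["translation"][0])
                if "translation" in feat.qualifiers
                else None
            ),
            annotated=annotated,
            notes=str(feat.qualifiers.get("note", [""])[0]),
        )
        features.append(gf)
        if RTE_QUALIFIER in feat.qualifiers:
            rte_feature_id = fid
            log.append(f"RTE designated by /{RTE_QUALIFIER} qualifier: {fid}")

    if not rte_feature_id and rte_id is not None:
        for gf in features:
            if gf.feature_id == rte_id:
                rte_feature_id = gf.feature_id
                log.append(f"RTE designated by identifier argument: {rte_id}")
                break
        else:
            raise RteNotFoundError(
                f"RTE {rte_id!r} not found among CDS features of {record.id}"
            )
    if not rte_feature_id:
        if not features:
            raise RteNotFoundError(f"{record.id}: no CDS features, cannot pick RTE")
        mid = len(seq) / 2
        nearest = min(features, key=lambda f: abs((f.start + f.end) / 2 - mid))
        rte_feature_id = nearest.feature_id
        log.append(f"RTE fallback: CDS nearest record midpoint ({rte_feature_id})")

    organism = record.annotations.get("organism", "") or str(
        record.annotations.get("source", "")
    )
    return GenomicRegion(
        accession=record.id or record.name,
        organism=organism,
        sequence=seq,
        features=features,
        rte_feature_id=rte_feature_id,
        log=log,
    )


def extract_window(region: GenomicRegion, flank_len: int) -> GenomicRegion:
    """Return the sub-region spanning *flank_len* nt on each side of the RTE.

    Clipped silently at contig ends (recorded in the log). Features
    intersecting the window are retained with shifted, clipped coordinates;
    features only partially inside are marked ``partial`` in their notes.
    """
    rte = region.rte
    win_start = max(0, rte.start - flank_len)
    win_end = min(len(region), rte.end + flank_len)
    log = list(region.log)
    if win_start > 0 or win_end < len(region):
        log.append(f"window [{win_start}, {win_end}) extracted, flank={flank_len}")
    if rte.start - flank_len < 0:
        log.append(f"left flank clipped to {rte.start} nt")
    if rte.end + flank_len > len(region):
        log.append(f"right flank clipped to {len(region) - rte.end} nt")

    kept: list[GeneFeature] = []
    for f in region.features:
        if f.end <= win_start or f.start >= win_end:
            continue
        ns, ne = max(f.start, win_start), min(f.end, win_end)
        partial = (ns, ne) != (f.start, f.end)
        kept.append(
            replace(
                f,
                start=ns - win_start,
                end=ne - win_start,
                notes=(f.notes + "; partial" if partial else f.notes).lstrip("; "),
            )
        )
    return GenomicRegion(
        accession=region.accession,
        organism=region.organism,
        sequence=region.sequence[win_start:win_end],
        features=kept,
        rte_feature_id=region.rte_feature_id,
        log=log,
    )


def _colour_ramp(score: float, lo: float, hi: float) -> str:
    t = 0.0 if hi <= lo else (score - lo) / (hi - lo)
    rgb = [round(a + t * (b - a)) for a, b in zip(RAMP_LOW, RAMP_HIGH)]
    return " ".join(str(v) for v in rgb)


def _region_to_record(region: GenomicRegion, candidates: Sequence = ()) -> SeqRecord:
    record = SeqRecord(
        Seq(region.sequence),
        id=region.accession,
        name=region.accession.split(".")[0][:16] or "region",
        description=f"{region.organism} RiPP mining region",
        annotations={"molecule_type": "DNA", "organism": region.organism},
    )
    for f in region.features:
        quals = {"locus_tag": [f.feature_id]}
        if f.product:
            quals["product"] = [f.product]
        if f.translation:
            quals["translation"] = [f.translation]
        if f.notes:
            quals["note"] = [f.notes]
        if f.feature_id == region.rte_feature_id:
            quals[RTE_QUALIFIER] = ["true"]
            quals["colour"] = [" ".join(str(v) for v in RTE_COLOUR)]
        record.features.append(
            SeqFeature(
                SimpleLocation(f.start, f.end, strand=f.strand),
                type="CDS",
                qualifiers=quals,
            )
        )
    if candidates:
        scores = [c.total_score for c in candidates]
        lo, hi = min(scores), max(scores)
        for i, c in enumerate(candidates):
            quals = {
                "locus_tag": [f"ripper_orf_{i + 1}"],
                CANDIDATE_QUALIFIER: ["true"],
                "colour": [_colour_ramp(c.total_score, lo, hi)],
                "translation": [c.peptide],
                "note": [
                    f"total_score={c.total_score:.3f}; "
                    f"coding_score={c.coding_score:.3f}; "
                    f"rbs_score={c.rbs_score:.3f}; "
                    f"start_bonus={c.start_bonus:.3f}"
                    + (f"; {c.notes}" if c.notes else "")
                ],
            }
            record.features.append(
                SeqFeature(
                    SimpleLocation(c.start, c.end, strand=c.strand),
                    type="CDS",
                    qualifiers=quals,
                )
            )
    record.features.sort(key=lambda f: (int(f.location.start), int(f.location.end)))
    return record


def write_genbank(region: GenomicRegion, path) -> None:
    """Write the region (features only, no candidates) as a GenBank flat file."""
    write_annotated_genbank(region, (), path)


def write_annotated_genbank(region: GenomicRegion, candidates, path) -> None:
    """Write the region with candidate ORFs added as colour-ramped CDS features.

    Candidates are coloured from pale red (lowest score in the file) to bright
    pink (highest); the RTE is green. Per-candidate scoring criteria go into
    ``/note`` qualifiers so they are viewable in genome browsers.
    """
    record = _region_to_record(region, list(candidates))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # Biopython warns on long LOCUS names
        SeqIO.write(record, str(path), "genbank")


def fasta_header(p) -> str:
    strand = "+" if p.strand == 1 else "-"
    return (
        f"{p.te_accession}|{p.source_accession}|{p.start}-{p.end}|"
        f"{strand}|score={p.score:.3f}"
    )


def write_fasta(peptides: Iterable, path) -> None:
    """Write retrieved peptides as FASTA, 60-column wrapped.

    Header fields: RTE accession, source accession, coordinates, strand, score.
    No deduplication at this layer: identical peptides from two regions are
    both written.
    """
    with open(path, "w") as fh:
        for p in peptides:
            fh.write(f">{fasta_header(p)}\n")
            seq = p.peptide
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.description] = str(rec.seq)
    return out
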