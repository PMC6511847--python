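"""Ungapped position-specific profile scanning of peptides.

Distant candidates are rescued when they carry a characterized
precursor-peptide domain. Full profile-HMM search is abstracted behind a
simple interface: profiles are per-position score tables over the 20-residue
alphabet with a per-profile reporting threshold (in the spirit of Pfam
gathering cutoffs), scanned ungapped over every offset of the peptide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

FORMAT_HEADER = "# ripper profile v1"


@dataclass
class DomainProfile:
    name: str
    columns: list[list[float]]  # one row of 20 scores per position
    threshold: float

    @property
    def min_len(self) -> int:
        return len(self.columns)

    def max_score(self) -> float:
        return sum(max(col) for col in self.columns)

    def consensus(self) -> str:
        return "".join(ALPHABET[col.index(max(col))] for col in self.columns)


@dataclass
class DomainHit:
    profile_name: str
    score: float
    start: int
    end: int


class ProfileFormatError(ValueError):
    pass


def profile_from_consensus(
    name: str,
    consensus: str,
    match: float = 2.0,
    mismatch: float = -1.0,
    threshold: Optional[float] = None,
) -> DomainProfile:
    """Build a toy profile that rewards an exact consensus residue per column."""
    cols = []
    for aa in consensus:
        col = [mismatch] * 20
        col[_INDEX[aa]] = match
        cols.append(col)
    if threshold is None:
        threshold = 0.66 * match * len(consensus)
    return DomainProfile(name=name, columns=cols, threshold=threshold)


def load_profiles(path) -> list[DomainProfile]:
    """Parse the plain-text profile format.

    Layout: a version header, then per profile a ``>NAME threshold=T length=L``
    line followed by L lines of 20 whitespace-separated scores (column order
    ACDEFGHIKLMNPQRSTVWY). Malformed lines raise with their line number;
    duplicate names are rejected.
    """
    profiles: list[DomainProfile] = []
    name = ""
    threshold = 0.0
    expect = 0
    columns: list[list[float]] = []

    def flush(lineno: int) -> None:
        if not name:
            return
        if len(columns) != expect:
            raise ProfileFormatError(
                f"line {lineno}: profile {name!r} declares length {expect} "
                f"but has {len(columns)} column lines"
            )
        if any(p.name == name for p in profiles):
            raise ProfileFormatError(f"line {lineno}: duplicate profile {name!r}")
        profiles.append(DomainProfile(name, list(columns), threshold))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush(lineno)
                fields = line[1:].split()
                try:
                    name = fields[0]
                    kv = dict(f.split("=", 1) for f in fields[1:])
                    threshold = float(kv["threshold"])
                    expect = int(kv["length"])
                except (IndexError, KeyError, ValueError) as exc:
                    raise ProfileFormatError(f"line {lineno}: bad header: {line}") from exc
                columns = []
            else:
                vals = line.split()
                if len(vals) != 20:
                    raise ProfileFormatError(
                        f"line {lineno}: expected 20 scores, got {len(vals)}"
                    )
                try:
                    columns.append([float(v) for v in vals])
                except ValueError as exc:
                    raise ProfileFormatError(f"line {lineno}: non-numeric score") from exc
        flush(lineno if "lineno" in dir() else 0)
    return profiles


def write_profiles(profiles: Iterable[DomainProfile], path) -> None:
    with open(path, "w") as fh:
        fh.write(FORMAT_HEADER + "\n")
        for p in profiles:
            fh.write(f">{p.name} threshold={p.threshold} length={p.min_len}\n")
            for col in p.columns:
                fh.write(" ".join(f"{v:g}" for v in col) + "\n")


def _window_score(peptide: str, profile: DomainProfile, offset: int) -> float:
    total = 0.0
    for i, col in enumerate(profile.columns):
        idx = _INDEX.get(peptide[offset + i])
        if idx is not None:  # X and other non-standard residues score 0
            total += col[idx]
    return total


def scan_peptide(
    peptide: str, profiles: Sequence[DomainProfile]
) -> list[DomainHit]:
    """Best ungapped window per profile; a hit is reported iff ≥ threshold.

    Peptides shorter than a profile cannot hit it. Multiple profiles may hit
    the same peptide. Non-standard residues (X etc.) contribute 0, so padding
    with X never changes a profile's best score.
    """
    pep = peptide.upper().rstrip("*")
    hits: list[DomainHit] = []
    for profile in profiles:
        L = profile.min_len
        if len(pep) < L:
            continue
        best = None
        best_off = 0
        for off in range(len(pep) - L + 1):
            s = _window_score(pep, profile, off)
            if best is None or s > best:
                best, best_off = s, off
        if best is not None and best >= profile.threshold:
            hits.append(DomainHit(profile.name, best, best_off, best_off + L))
    return hits
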