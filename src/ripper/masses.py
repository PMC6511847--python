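"""Monoisotopic mass arithmetic for modified short peptides.

Models the thiovarsolin-type chemistry: N-terminal acetylation, backbone
thioamidation (sulfur replacing the carbonyl oxygen of a specified
inter-residue bond) and desaturation (loss of H2). Also provides the two MS
screens used to look for further such products: an H2S neutral-loss scan over
MS2 fragment lists (the loss of 33.988 Da is diagnostic of a thioamide) and
tolerance-based comparative feature matching between sample groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from pyteomics import mass as _pmass

PROTON = 1.00727646688
WATER = _pmass.calculate_mass(formula="H2O")  # 18.0105646...
ACETYL = _pmass.calculate_mass(formula="C2H2O")  # +42.010565
THIOAMIDE = _pmass.calculate_mass(formula="S") - _pmass.calculate_mass(formula="O")
DEHYDRO = _pmass.calculate_mass(formula="H2")  # subtracted per desaturation
H2S = _pmass.calculate_mass(formula="H2S")  # 33.987721, the diagnostic loss

_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class ModifiedPeptide:
    """A peptide with optional N-acetyl, backbone thioamides and desaturations.

    ``thioamide_positions`` are inter-residue bond indices, 1 = the bond after
    residue 1; ``dehydro_count`` is position-agnostic since a -H2 delta does
    not depend on where the double bond sits.
    """

    sequence: str
    n_acetyl: bool = False
    thioamide_positions: tuple[int, ...] = ()
    dehydro_count: int = 0

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - _ALPHABET
        if bad:
            raise ValueError(f"unknown residue letter(s): {sorted(bad)}")
        self.sequence = self.sequence.upper()
        self.thioamide_positions = tuple(self.thioamide_positions)
        n = len(self.sequence)
        for b in self.thioamide_positions:
            if not 1 <= b <= n - 1:
                raise ValueError(f"thioamide bond index {b} outside [1, {n - 1}]")
        if self.dehydro_count < 0:
            raise ValueError("dehydro_count must be >= 0")


def monoisotopic_mass(p: ModifiedPeptide) -> float:
    """Neutral monoisotopic mass in Da (residues + water + modification deltas)."""
    base = _pmass.calculate_mass(sequence=p.sequence, monoisotopic=True)
    return (
        base
        + (ACETYL if p.n_acetyl else 0.0)
        + THIOAMIDE * len(p.thioamide_positions)
        - DEHYDRO * p.dehydro_count
    )


def mz_protonated(p: ModifiedPeptide, charge: int = 1) -> float:
    """m/z of the [M+zH]z+ ion."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (monoisotopic_mass(p) + charge * PROTON) / charge


def ppm_error(observed: float, theoretical: float) -> float:
    return (observed - theoretical) / theoretical * 1e6


def thiovarsolin(variant: str) -> ModifiedPeptide:
    """The four thiovarsolins: N-acetylated APR/GPR tripeptides with a
    Pro–Arg thioamide; A and C carry one Arg-side-chain desaturation."""
    variants = {
        "A": ModifiedPeptide("APR", True, (2,), 1),
        "B": ModifiedPeptide("APR", True, (2,), 0),
        "C": ModifiedPeptide("GPR", True, (2,), 1),
        "D": ModifiedPeptide("GPR", True, (2,), 0),
    }
    try:
        return variants[variant.upper()]
    except KeyError:
        raise ValueError(f"unknown thiovarsolin variant {variant!r}") from None


@dataclass
class H2SLossHit:
    spectrum_id: str
    mz_high: float
    mz_low: float
    delta: float
    involves_precursor: bool = False


def h2s_loss_screen(
    spectra: Mapping[str, tuple[Optional[float], Sequence[float]]],
    tol: float = 0.01,
) -> list[H2SLossHit]:
    """Find H2S neutral-loss pairs within each spectrum.

    *spectra* maps spectrum id → (precursor m/z or None, fragment m/z list).
    Reports every fragment pair, and precursor–fragment pair, whose m/z
    difference is within *tol* (inclusive) of the H2S mass 33.987721 Da.
    """
    hits: list[H2SLossHit] = []
    for sid, (precursor, fragments) in spectra.items():
        frags = sorted(fragments)
        for i, lo in enumerate(frags):
            for hi in frags[i + 1 :]:
                if abs(hi - lo - H2S) <= tol:
                    hits.append(H2SLossHit(sid, hi, lo, hi - lo))
        if precursor is not None:
            for f in frags:
                if abs(precursor - f - H2S) <= tol:
                    hits.append(H2SLossHit(sid, precursor, f, precursor - f, True))
    return hits


def read_fragment_table(path) -> dict[str, tuple[Optional[float], list[float]]]:
    """Two-column TSV (spectrum/precursor id, fragment m/z) into screen input.

    A row whose id ends in ``:precursor`` sets the precursor m/z instead.
    """
    spectra: dict[str, tuple[Optional[float], list[float]]] = {}
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "mz"], comment="#")
    for _, row in df.iterrows():
        sid = str(row["id"])
        if sid.endswith(":precursor"):
            base = sid[: -len(":precursor")]
            prec, frags = spectra.get(base, (None, []))
            spectra[base] = (float(row["mz"]), frags)
        else:
            prec, frags = spectra.get(sid, (None, []))
            frags.append(float(row["mz"]))
            spectra[sid] = (prec, frags)
    return spectra


def _matches(f: pd.Series, table: pd.DataFrame, mz_tol: float, rt_tol: float) -> bool:
    return bool(
        (
            ((table["mz"] - f["mz"]).abs() <= mz_tol)
            & ((table["rt"] - f["rt"]).abs() <= rt_tol)
        ).any()
    )


def differential_features(
    sample_groups: Mapping[str, Sequence[pd.DataFrame]],
    mz_tol: float = 0.1,
    rt_tol: float = 0.1,
    intensity_min: float = 100000.0,
) -> dict[str, pd.DataFrame]:
    """Features unique to one sample group (comparative metabolomics).

    Each group maps to ≥ 1 replicate feature tables with columns mz, rt,
    intensity. Features below *intensity_min* are discarded; two features
    match when |Δmz| ≤ mz_tol and |Δrt| ≤ rt_tol (inclusive). A feature is
    unique to group A iff present post-threshold in all A replicates and
    matched in no replicate of any other group.
    """
    filtered = {
        g: [t[t["intensity"] >= intensity_min].reset_index(drop=True) for t in tables]
        for g, tables in sample_groups.items()
    }
    unique: dict[str, pd.DataFrame] = {}
    for group, tables in filtered.items():
        if not tables:
            raise ValueError(f"group {group!r} has no replicate tables")
        others = [t for g, ts in filtered.items() if g != group for t in ts]
        rows = []
        anchor = tables[0]
        for _, f in anchor.iterrows():
            if not all(_matches(f, t, mz_tol, rt_tol) for t in tables[1:]):
                continue
            if any(_matches(f, t, mz_tol, rt_tol) for t in others):
                continue
            rows.append(f)
        unique[group] = (
            pd.DataFrame(rows).reset_index(drop=True)
            if rows
            else anchor.iloc[0:0].copy()
        )
    return unique


def read_feature_table(path) -> pd.DataFrame:
    """CSV/TSV with mz, rt, intensity columns (delimiter sniffed by pandas)."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"mz", "rt", "intensity"} - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    return df
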