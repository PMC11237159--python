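"""Per-domain physicochemical profiles: GRAVY, disorder, secondary structure,
composition, molecular weight and theoretical pI.

These are the metrics behind the comparative domain table contrasting glue
and non-glue PRIT homologues: glue domains are more hydrophilic (more negative
GRAVY) and more disordered, while beta-sheet content is conserved. Disorder
and secondary-structure values are consumed from per-residue tracks produced
by external predictors (IUPred-style scores in [0,1], GOR-style H/E/C
strings); thresholds are inclusive (score >= 0.5 calls a residue disordered
or a site glycosylated).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import PROTEIN_ALPHABET, ResidueTrack, SequenceRecord

# Kyte-Doolittle hydropathy scale
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Average residue masses (Da); a peptide adds one water (18.0153 Da)
WATER_MASS = 18.0153
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

# Bjellqvist pKa values (ProtParam convention): side chains, C-terminus, and
# residue-specific N-terminal pKa.
PKA_POSITIVE = {"K": 10.0, "R": 12.0, "H": 5.98}
PKA_NEGATIVE = {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
PKA_CTERM = 3.55
PKA_NTERM_DEFAULT = 7.5
PKA_NTERM = {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7}


def _residues(seq: SequenceRecord | str) -> str:
    return seq.residues if isinstance(seq, SequenceRecord) else seq


def _canonical(s: str) -> str:
    return "".join(ch for ch in s if ch in PROTEIN_ALPHABET)


def gravy(seq: SequenceRecord | str) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value per residue.

    Unknown residues (X) are excluded from the average; a span consisting only
    of X is an error.
    """
    s = _canonical(_residues(seq))
    if not s:
        raise ValueError("no canonical residues to average")
    return sum(KYTE_DOOLITTLE[ch] for ch in s) / len(s)


def disorder_fraction(
    track: ResidueTrack,
    span: tuple[int, int] | None = None,
    threshold: float = 0.5,
) -> float:
    """Percent of residues in the span with disorder score >= threshold."""
    if track.kind != "disorder":
        raise ValueError(f"expected a disorder track, got {track.kind!r}")
    values = track.slice(*span) if span else track.values
    if not values:
        raise ValueError("empty span")
    return 100.0 * sum(1 for v in values if v >= threshold) / len(values)


def secstruct_fractions(
    track: ResidueTrack, span: tuple[int, int] | None = None
) -> dict[str, float]:
    """Percent helix (H), strand (E) and coil (C) over the span."""
    if track.kind != "secstruct":
        raise ValueError(f"expected a secstruct track, got {track.kind!r}")
    values = track.slice(*span) if span else track.values
    if not values:
        raise ValueError("empty span")
    n = len(values)
    return {state: 100.0 * values.count(state) / n for state in "HEC"}


@dataclass(frozen=True)
class Composition:
    """Residue percentages over canonical residues; X counted separately."""

    percent: dict[str, float]
    n_unknown: int


def composition(seq: SequenceRecord | str) -> Composition:
    """Residue composition in percent. X is excluded from the denominator and
    reported as a separate flag count."""
    s = _residues(seq)
    if not s:
        raise ValueError("empty sequence")
    canon = _canonical(s)
    if not canon:
        raise ValueError("no canonical residues")
    n = len(canon)
    pct = {ch: 100.0 * canon.count(ch) / n for ch in sorted(set(canon))}
    return Composition(percent=pct, n_unknown=s.count("X"))


def molecular_weight(seq: SequenceRecord | str) -> float:
    """Average molecular weight in Daltons (residue masses + one water)."""
    s = _residues(seq)
    if not s:
        raise ValueError("empty sequence")
    if "X" in s:
        raise ValueError("molecular weight undefined for sequences containing X")
    return sum(AVERAGE_RESIDUE_MASS[ch] for ch in s) + WATER_MASS


def peptide_charge(seq: SequenceRecord | str, ph: float) -> float:
    """Net charge at a given pH, Henderson-Hasselbalch per ionisable group."""
    s = _canonical(_residues(seq))
    if not s:
        raise ValueError("no canonical residues")
    pos = [PKA_NTERM.get(s[0], PKA_NTERM_DEFAULT)]
    pos += [PKA_POSITIVE[ch] for ch in s if ch in PKA_POSITIVE]
    neg = [PKA_CTERM]
    neg += [PKA_NEGATIVE[ch] for ch in s if ch in PKA_NEGATIVE]
    charge = sum(1.0 / (1.0 + 10 ** (ph - pka)) for pka in pos)
    charge -= sum(1.0 / (1.0 + 10 ** (pka - ph)) for pka in neg)
    return charge


def isoelectric_point(seq: SequenceRecord | str, tol: float = 0.01) -> float:
    """Theoretical pI: the pH of zero net charge, by bisection on [0, 14].

    Net charge is strictly decreasing in pH, so the root is unique; bisection
    runs to an interval narrower than ``tol`` (default 0.01 pH units).
    """
    lo, hi = 0.0, 14.0
    while hi - lo > tol / 4:
        mid = (lo + hi) / 2
        if peptide_charge(seq, mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


@dataclass(frozen=True)
class DomainProfile:
    """Physicochemical summary of one domain (1-based inclusive span)."""

    sequence_id: str
    start: int
    end: int
    length: int
    gravy: float
    pct_disorder: float | None = None
    pct_helix: float | None = None
    pct_beta: float | None = None
    pct_coil: float | None = None
    composition: Mapping[str, float] | None = None
    n_unknown: int = 0
    mw: float | None = None
    pi: float | None = None


def profile_domain(
    seq: SequenceRecord,
    span: tuple[int, int] | None = None,
    disorder_track: ResidueTrack | None = None,
    secstruct_track: ResidueTrack | None = None,
    threshold: float = 0.5,
) -> DomainProfile:
    """Build the full :class:`DomainProfile` for a span of a protein."""
    start, end = span if span else (1, len(seq))
    if not (1 <= start <= end <= len(seq)):
        raise ValueError(f"span ({start}, {end}) outside sequence of length {len(seq)}")
    sub = seq.residues[start - 1 : end]
    comp = composition(sub)
    sec = secstruct_fractions(secstruct_track, (start, end)) if secstruct_track else None
    return DomainProfile(
        sequence_id=seq.id,
        start=start,
        end=end,
        length=end - start + 1,
        gravy=gravy(sub),
        pct_disorder=(
            disorder_fraction(disorder_track, (start, end), threshold)
            if disorder_track
            else None
        ),
        pct_helix=sec["H"] if sec else None,
        pct_beta=sec["E"] if sec else None,
        pct_coil=sec["C"] if sec else None,
        composition=comp.percent,
        n_unknown=comp.n_unknown,
        mw=molecular_weight(sub) if "X" not in sub else None,
        pi=isoelectric_point(sub),
    )


_TABLE_METRICS = ("gravy", "pct_disorder", "pct_beta", "pct_helix", "pct_coil", "mw", "pi")


def comparative_table(
    profiles_by_species: Mapping[str, Sequence[DomainProfile]],
    glue_flag: Mapping[str, bool],
) -> pd.DataFrame:
    """Per-species min/median/max of each metric plus a glue-vs-nonglue contrast.

    The contrast row holds, per metric, the difference of group medians
    (median over glue-species domain medians minus the non-glue counterpart);
    it is NaN when either group is empty.
    """
    rows = []
    for sp, profiles in profiles_by_species.items():
        if not profiles:
            raise ValueError(f"species {sp!r}: empty profile group")
        row: dict[str, float | str | bool] = {
            "species": sp,
            "glue": bool(glue_flag[sp]),
            "n_domains": len(profiles),
        }
        for metric in _TABLE_METRICS:
            vals = [getattr(p, metric) for p in profiles if getattr(p, metric) is not None]
            if vals:
                row[f"{metric}_min"] = float(np.min(vals))
                row[f"{metric}_median"] = float(np.median(vals))
                row[f"{metric}_max"] = float(np.max(vals))
        rows.append(row)
    df = pd.DataFrame(rows).set_index("species")
    contrast: dict[str, float | str | bool] = {"glue": True, "n_domains": 0}
    for metric in _TABLE_METRICS:
        col = f"{metric}_median"
        if col not in df.columns:
            continue
        glue_vals = df.loc[df["glue"], col].dropna()
        non_vals = df.loc[~df["glue"], col].dropna()
        contrast[col] = (
            float(glue_vals.median() - non_vals.median())
            if len(glue_vals) and len(non_vals)
            else float("nan")
        )
    df.loc["glue_minus_nonglue"] = pd.Series(contrast)
    return df
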