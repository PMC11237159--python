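"""Positive-selection summaries and Nei-Gojobori (1986) dN/dS counting.

The comparative metric is the proportion of codon sites called positively
selected per species, consumed from per-site posterior tables exported by a
branch-site likelihood analysis (that model itself is not re-implemented
here). Alongside it, an NG86 counting estimator of dN/dS provides an
assumption-light, dependency-free omega for synthetic-recovery checks:
synonymous/nonsynonymous site counts from single-nucleotide neighbours
(changes to stop codons count as nonsynonymous), observed differences
averaged over all shortest mutational paths that avoid stop codons, and a
Jukes-Cantor correction d = -(3/4) ln(1 - (4/3) p) that is undefined at
saturation (p >= 3/4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from pathlib import Path
from typing import Sequence

from Bio.Data.CodonTable import standard_dna_table

from .formats import CodonAlignmentSet, FormatError, SequenceRecord

_NUCS = "ACGT"
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

CODON_TABLE = dict(standard_dna_table.forward_table)
STOP_CODONS = set(standard_dna_table.stop_codons)
SENSE_CODONS = tuple(sorted(CODON_TABLE))  # 61 codons, standard code


def synonymous_site_fraction(codon: str) -> float:
    """NG86 synonymous site count of one sense codon.

    Each position contributes (number of synonymous single-nucleotide
    changes) / 3; mutations to stop codons count as nonsynonymous.
    """
    if codon not in CODON_TABLE:
        raise ValueError(f"not a sense codon: {codon!r}")
    aa = CODON_TABLE[codon]
    s = 0.0
    for i in range(3):
        for nt in _NUCS:
            if nt == codon[i]:
                continue
            alt = codon[:i] + nt + codon[i + 1 :]
            if alt not in STOP_CODONS and CODON_TABLE[alt] == aa:
                s += 1.0 / 3.0
    return s


def _path_differences(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) between two sense codons, averaged over shortest paths.

    Paths passing through stop codons are excluded; if every path is blocked,
    all paths are used with stop-involving steps counted as nonsynonymous.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool) -> tuple[float, float] | None:
        sd = nd = 0.0
        cur = c1
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            if nxt in STOP_CODONS and not allow_stops:
                return None
            if cur in STOP_CODONS or nxt in STOP_CODONS:
                nd += 1.0
            elif CODON_TABLE[cur] == CODON_TABLE[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd

    results = [r for order in permutations(diff) if (r := walk(order, False)) is not None]
    if not results:
        results = [walk(order, True) for order in permutations(diff)]
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


_SYN_SITES: dict[str, float] = {c: synonymous_site_fraction(c) for c in SENSE_CODONS}
_PAIR_DIFFS: dict[tuple[str, str], tuple[float, float]] = {}


def _pair_diff(c1: str, c2: str) -> tuple[float, float]:
    key = (c1, c2)
    if key not in _PAIR_DIFFS:
        _PAIR_DIFFS[key] = _path_differences(c1, c2)
    return _PAIR_DIFFS[key]


def jukes_cantor(p: float) -> float | None:
    """JC69 distance; None when p >= 3/4 (saturated)."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return None
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


@dataclass(frozen=True)
class NG86Result:
    """NG86 counts and distances for one pair of coding sequences.

    ``dS``/``dN``/``omega`` are None when undefined (saturation, or dS = 0).
    """

    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float | None
    dN: float | None
    omega: float | None
    n_codons: int
    n_skipped: int


def ng86_pairwise(
    a: SequenceRecord | str, b: SequenceRecord | str
) -> NG86Result:
    """NG86 counting estimate of dN/dS between two aligned coding sequences.

    Codons containing gaps or ambiguous bases in either sequence are skipped
    pairwise and reported in ``n_skipped``. An in-frame stop codon is an
    error.
    """
    sa = a.residues if isinstance(a, SequenceRecord) else a
    sb = b.residues if isinstance(b, SequenceRecord) else b
    if len(sa) != len(sb):
        raise ValueError(f"length mismatch: {len(sa)} vs {len(sb)}")
    if len(sa) % 3 != 0:
        raise ValueError(f"length {len(sa)} not divisible by 3")
    s_a = s_b = sd = nd = 0.0
    n_codons = n_skipped = 0
    for i in range(0, len(sa), 3):
        ca, cb = sa[i : i + 3], sb[i : i + 3]
        if set(ca + cb) - set(_NUCS):
            n_skipped += 1
            continue
        for c in (ca, cb):
            if c in STOP_CODONS:
                raise ValueError(f"in-frame stop codon {c!r} at codon {i // 3 + 1}")
        n_codons += 1
        s_a += _SYN_SITES[ca]
        s_b += _SYN_SITES[cb]
        d = _pair_diff(ca, cb)
        sd += d[0]
        nd += d[1]
    if n_codons == 0:
        raise ValueError("no comparable codons (all skipped)")
    s_sites = (s_a + s_b) / 2.0
    n_sites = 3.0 * n_codons - s_sites
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ds = jukes_cantor(ps)
    dn = jukes_cantor(pn)
    omega = None
    if ds is not None and dn is not None and ds > 0:
        omega = dn / ds
    return NG86Result(
        S_sites=s_sites,
        N_sites=n_sites,
        Sd=sd,
        Nd=nd,
        pS=ps,
        pN=pn,
        dS=ds,
        dN=dn,
        omega=omega,
        n_codons=n_codons,
        n_skipped=n_skipped,
    )


# ---------------------------------------------------------------------------
# Per-site positive-selection summaries


@dataclass(frozen=True)
class SiteClassTable:
    """Per-codon-site posterior probabilities of the positive-selection class."""

    alignment_id: str
    sites: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        prev = 0
        for pos, post in self.sites:
            if pos <= prev:
                raise FormatError(
                    f"{self.alignment_id}: site positions must be strictly increasing "
                    f"(found {pos} after {prev})"
                )
            if not (0.0 <= post <= 1.0):
                raise FormatError(
                    f"{self.alignment_id}: posterior {post} at site {pos} outside [0, 1]"
                )
            prev = pos

    def __len__(self) -> int:
        return len(self.sites)


@dataclass(frozen=True)
class SelectionSummary:
    """Count and proportion of positively selected codon sites for one label."""

    label: str
    n_sites: int
    n_positive: int

    @property
    def percent_positive(self) -> float:
        return 100.0 * self.n_positive / self.n_sites


def positive_site_proportion(
    table: SiteClassTable, posterior_threshold: float = 0.5
) -> SelectionSummary:
    """Proportion of sites with posterior >= threshold (inclusive)."""
    if not table.sites:
        raise ValueError("empty site-class table")
    n_pos = sum(1 for _, post in table.sites if post >= posterior_threshold)
    return SelectionSummary(
        label=table.alignment_id, n_sites=len(table.sites), n_positive=n_pos
    )


def parse_site_class_tsv(path: str | Path, alignment_id: str | None = None) -> SiteClassTable:
    """Read a ``site<TAB>posterior`` TSV into a :class:`SiteClassTable`."""
    path = Path(path)
    sites: list[tuple[int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.lower().startswith("site"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 'site<TAB>posterior'")
            sites.append((int(parts[0]), float(parts[1])))
    return SiteClassTable(
        alignment_id=alignment_id or path.stem, sites=tuple(sites)
    )


def omega_recovery(
    alignment: CodonAlignmentSet, site_classes: Sequence[float]
) -> dict[float, float | None]:
    """Mean pairwise NG86 omega per true omega class of a synthetic alignment.

    ``site_classes`` gives the generating omega for each codon site. For each
    class, codons of that class are concatenated per sequence and NG86 is run
    over all unordered sequence pairs; the class mean covers pairs with a
    defined omega and is None when no pair is informative (e.g. identical
    sequences).
    """
    if len(site_classes) != alignment.n_codons:
        raise ValueError(
            f"{len(site_classes)} site classes for {alignment.n_codons} codons"
        )
    classes = sorted(set(site_classes))
    out: dict[float, float | None] = {}
    for cls in classes:
        idx = [i for i, c in enumerate(site_classes) if c == cls]
        subs = [
            "".join(rec.residues[3 * i : 3 * i + 3] for i in idx)
            for rec in alignment.records
        ]
        omegas = []
        for i in range(len(subs)):
            for j in range(i + 1, len(subs)):
                res = ng86_pairwise(subs[i], subs[j])
                if res.omega is not None:
                    omegas.append(res.omega)
        out[cls] = sum(omegas) / len(omegas) if omegas else None
    return out
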