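"""Tandem-repeat detection and modular-architecture annotation.

Glue proteins of the PRIT family are modular: a signal peptide, one to several
~390-residue structured domains, and intervening arrays of short imperfect
tandem repeats (18-mers in *Dyscophus*, 8-mers in *Breviceps*) carrying tandem
proline-glycine motifs and Ser/Thr O-glycosylation candidates. This module
detects such repeat arrays from sequence alone and assembles the ordered
segment annotation.

Detection strategy: candidate periods are proposed by positional
autocorrelation (the fraction of positions i with seq[i] == seq[i + p]),
candidate regions are refined against a phased majority consensus, and
overlapping explanations are resolved by a smallest-period rule — periods
whose mean identity comes within ``PERIOD_TIE_TOL`` of the best overlapping
candidate are considered to explain the region equally well, and the smallest
such period wins. The tolerance matters because a consensus at any integer
multiple of the true period can only score equal or higher (finer columns
never lower a majority count), so a strict argmax would report multiples.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .formats import GAP, ResidueTrack, SequenceRecord

PERIOD_TIE_TOL = 0.03

DEFAULT_MIN_PERIOD = 2
DEFAULT_MAX_PERIOD = 60
DEFAULT_MIN_COPIES = 3.0
DEFAULT_MIN_IDENTITY = 0.6

SEGMENT_KINDS = ("signal_peptide", "domain", "repeat_region", "linker")
MIN_LINKER = 5  # uncovered stretches shorter than this stay unlabelled


@dataclass(frozen=True)
class RepeatRegion:
    """One detected tandem-repeat array.

    Span is 1-based inclusive. ``copy_number`` may be fractional (imperfect
    final copy). ``unit_pg_counts`` / ``unit_st_counts`` give, for each full
    copy, the longest tandem-PG run and the raw Ser/Thr count.
    """

    start: int
    end: int
    unit_length: int
    copy_number: float
    consensus: str
    mean_identity: float
    unit_pg_counts: tuple[int, ...] = ()
    unit_st_counts: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.unit_length < 1:
            raise ValueError("unit_length must be >= 1")
        if self.end - self.start + 1 < 2 * self.unit_length:
            raise ValueError("repeat region must span at least two units")
        if len(self.consensus) != self.unit_length:
            raise ValueError("consensus length must equal unit_length")
        if not (0.0 <= self.mean_identity <= 1.0):
            raise ValueError("mean_identity outside [0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Segment:
    start: int
    end: int
    kind: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad span ({self.start}, {self.end})")


@dataclass(frozen=True)
class ArchitectureAnnotation:
    """Ordered, non-overlapping segmentation of one protein."""

    sequence_id: str
    length: int
    segments: tuple[Segment, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        prev_end = 0
        for seg in self.segments:
            if seg.start <= prev_end:
                raise ValueError(
                    f"segments overlap or are unsorted at ({seg.start}, {seg.end})"
                )
            if seg.end > self.length:
                raise ValueError(f"segment ({seg.start}, {seg.end}) beyond sequence")
            prev_end = seg.end

    def of_kind(self, kind: str) -> list[Segment]:
        return [s for s in self.segments if s.kind == kind]


# ---------------------------------------------------------------------------
# Detection internals


def _phased_consensus(s: str, r0: int, r1: int, p: int, anchor: int) -> str:
    """Majority residue per phase class over [r0, r1]; ties break alphabetically."""
    cols: list[list[str]] = [[] for _ in range(p)]
    for i in range(r0, r1 + 1):
        cols[(i - anchor) % p].append(s[i])
    out = []
    for col in cols:
        counts = Counter(col)
        best = max(counts.values())
        out.append(min(ch for ch, c in counts.items() if c == best))
    return "".join(out)


def _identity(s: str, r0: int, r1: int, unit: str, anchor: int) -> float:
    p = len(unit)
    match = sum(1 for i in range(r0, r1 + 1) if s[i] == unit[(i - anchor) % p])
    return match / (r1 - r0 + 1)


def _smallest_exact_period(u: str) -> int:
    """Smallest divisor period d such that u is (u[:d]) repeated."""
    n = len(u)
    for d in range(1, n):
        if n % d == 0 and u[:d] * (n // d) == u:
            return d
    return n


def _refine_region(s: str, a0: int, r0: int, r1: int, p: int) -> tuple[int, int, str]:
    """Greedy boundary refinement against the phased consensus (anchor a0)."""
    for _ in range(3):
        unit = _phased_consensus(s, r0, r1, p, anchor=a0)
        changed = False
        while r0 > 0 and s[r0 - 1] == unit[(r0 - 1 - a0) % p]:
            r0 -= 1
            changed = True
        while r1 < len(s) - 1 and s[r1 + 1] == unit[(r1 + 1 - a0) % p]:
            r1 += 1
            changed = True
        # trim terminal mismatches (at most one unit each side)
        t = 0
        while t < p and r1 - r0 + 1 > 2 * p and s[r0] != unit[(r0 - a0) % p]:
            r0 += 1
            t += 1
            changed = True
        t = 0
        while t < p and r1 - r0 + 1 > 2 * p and s[r1] != unit[(r1 - a0) % p]:
            r1 -= 1
            t += 1
            changed = True
        if not changed:
            break
    # rotate consensus so it starts at the final region start
    unit = _phased_consensus(s, r0, r1, p, anchor=a0)
    shift = (r0 - a0) % p
    return r0, r1, unit[shift:] + unit[:shift]


def _unit_counts(s: str, r0: int, r1: int, p: int) -> tuple[tuple[int, ...], tuple[int, ...]]:
    pg, st = [], []
    for u0 in range(r0, r1 - p + 2, p):
        unit = s[u0 : u0 + p]
        pg.append(count_tandem_pg(unit))
        st.append(sum(1 for ch in unit if ch in "ST"))
    return tuple(pg), tuple(st)


def _candidates_for_period(
    s: str, p: int, min_copies: float, min_identity: float
) -> list[RepeatRegion]:
    n = len(s)
    if n < 2 * p:
        return []
    m = [s[i] == s[i + p] for i in range(n - p)]
    # unit-window match fraction f[j] over window [j, j + p)
    cum = [0]
    for v in m:
        cum.append(cum[-1] + v)
    out: list[RepeatRegion] = []
    nf = n - 2 * p + 1  # number of full windows
    runs: list[list[int]] = []
    j = 0
    while j < nf:
        if (cum[j + p] - cum[j]) / p >= min_identity:
            a = j
            while j < nf and (cum[j + p] - cum[j]) / p >= min_identity:
                j += 1
            # bridge short dips (< one unit of windows) to the previous run
            if runs and a - runs[-1][1] <= p:
                runs[-1][1] = j - 1
            else:
                runs.append([a, j - 1])
        else:
            j += 1
    for a, b in runs:
        r0, r1, unit = _refine_region(s, a, a, b + 2 * p - 1, p)
        # reduce to the primitive period of the consensus when it explains
        # the region at least as well (homopolymers, doubled units)
        q = _smallest_exact_period(unit)
        pp = p
        if q < p:
            sub = unit[:q]
            if _identity(s, r0, r1, sub, r0) >= _identity(s, r0, r1, unit, r0) - 1e-12:
                unit, pp = sub, q
        ident = _identity(s, r0, r1, unit, r0)
        copies = (r1 - r0 + 1) / pp
        if copies >= min_copies and ident >= min_identity and r1 - r0 + 1 >= 2 * pp:
            pg, st = _unit_counts(s, r0, r1, pp)
            out.append(
                RepeatRegion(
                    start=r0 + 1,
                    end=r1 + 1,
                    unit_length=pp,
                    copy_number=copies,
                    consensus=unit,
                    mean_identity=ident,
                    unit_pg_counts=pg,
                    unit_st_counts=st,
                )
            )
    return out


def _overlap(a: RepeatRegion, b: RepeatRegion) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def detect_tandem_repeats(
    seq: SequenceRecord | str,
    min_period: int = DEFAULT_MIN_PERIOD,
    max_period: int = DEFAULT_MAX_PERIOD,
    min_copies: float = DEFAULT_MIN_COPIES,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> list[RepeatRegion]:
    """Detect tandem-repeat arrays, reporting the smallest adequate period.

    Defaults (periods 2-60, >= 3 copies, >= 60% identity) bracket both the
    8-mer and 18-mer PRIT repeat units with margin. Overlapping candidate
    regions from different periods are resolved by mean identity, with periods
    within ``PERIOD_TIE_TOL`` of the best treated as ties won by the smallest
    period. Homopolymers reduce to period 1.
    """
    s = seq.residues if isinstance(seq, SequenceRecord) else seq
    n = len(s)
    if not (1 <= min_period <= max_period):
        raise ValueError("need 1 <= min_period <= max_period")
    if n < 2 * min_period:
        raise ValueError(f"sequence of length {n} shorter than two minimal units")
    candidates: list[RepeatRegion] = []
    for p in range(min_period, min(max_period, n // 2) + 1):
        candidates.extend(_candidates_for_period(s, p, min_copies, min_identity))
    # greedy resolution: the candidate explaining the most residues (matched
    # residues = length x identity) anchors each region; overlapping candidates
    # within the tie tolerance of its score compete, smallest period winning
    selected: list[RepeatRegion] = []
    remaining = list(candidates)
    while remaining:
        best = max(remaining, key=lambda r: r.length * r.mean_identity)
        threshold = best.length * (best.mean_identity - PERIOD_TIE_TOL)
        eligible = [
            r
            for r in remaining
            if _overlap(r, best) > 0 and r.length * r.mean_identity >= threshold
        ]
        eligible.sort(key=lambda r: (r.unit_length, -r.mean_identity, r.start))
        winner = eligible[0]
        selected.append(winner)
        remaining = [r for r in remaining if r is not winner and _overlap(r, winner) == 0]
    return sorted(selected, key=lambda r: r.start)


def consensus_unit(region: RepeatRegion, seq: SequenceRecord | str) -> str:
    """Majority consensus of the region's phased columns.

    Ties break alphabetically; columns whose majority character is a gap are
    dropped (relevant only for aligned inputs).
    """
    s = seq.residues if isinstance(seq, SequenceRecord) else seq
    r0, r1, p = region.start - 1, region.end - 1, region.unit_length
    cols: list[list[str]] = [[] for _ in range(p)]
    for i in range(r0, r1 + 1):
        cols[(i - r0) % p].append(s[i])
    out = []
    for col in cols:
        counts = Counter(col)
        best = max(counts.values())
        ch = min(c for c, k in counts.items() if k == best)
        if ch != GAP:
            out.append(ch)
    return "".join(out)


def count_tandem_pg(unit: str) -> int:
    """Longest run of consecutive, non-overlapping PG dipeptides.

    "PGPGPG" scores 3; isolated PGs score 1 each (the maximum of their
    length-1 runs); a unit without PG scores 0.
    """
    best = 0
    i = 0
    n = len(unit)
    while i < n - 1:
        if unit[i : i + 2] == "PG":
            run = 0
            while i < n - 1 and unit[i : i + 2] == "PG":
                run += 1
                i += 2
            best = max(best, run)
        else:
            i += 1
    return best


def count_glyco_candidates(
    span: tuple[int, int],
    seq: SequenceRecord | str,
    track: ResidueTrack | None = None,
    threshold: float = 0.5,
) -> int:
    """Count Ser/Thr O-glycosylation candidates in a 1-based inclusive span.

    With a glyco score track, only S/T positions scoring >= threshold count
    (the threshold is inclusive); without one, every S/T position counts.
    """
    s = seq.residues if isinstance(seq, SequenceRecord) else seq
    start, end = span
    if not (1 <= start <= end <= len(s)):
        raise ValueError(f"span {span} outside sequence of length {len(s)}")
    if track is not None:
        if len(track) != len(s):
            raise ValueError(
                f"track length {len(track)} does not match sequence length {len(s)}"
            )
        return sum(
            1
            for i in range(start - 1, end)
            if s[i] in "ST" and float(track.values[i]) >= threshold
        )
    return sum(1 for i in range(start - 1, end) if s[i] in "ST")


def annotate_architecture(
    seq: SequenceRecord,
    domain_hits: list[tuple[int, int, str]] | None = None,
    repeats: list[RepeatRegion] | None = None,
    signal_peptide: tuple[int, int] | None = None,
) -> ArchitectureAnnotation:
    """Assemble the ordered segment structure of a modular protein.

    Domain coordinates come from an external profile search; repeats from
    :func:`detect_tandem_repeats`. Uncovered stretches of at least 5 residues
    are labelled ``linker``. Overlapping input spans are an error listing the
    conflict.
    """
    n = len(seq)
    spans: list[Segment] = []
    if signal_peptide is not None:
        spans.append(Segment(signal_peptide[0], signal_peptide[1], "signal_peptide", "signal"))
    for start, end, label in domain_hits or []:
        spans.append(Segment(start, end, "domain", label))
    for i, r in enumerate(repeats or [], start=1):
        spans.append(Segment(r.start, r.end, "repeat_region", f"repeat_{i}"))
    for seg in spans:
        if seg.end > n:
            raise ValueError(f"segment {seg.label!r} ({seg.start}, {seg.end}) beyond sequence of length {n}")
    spans.sort(key=lambda seg: (seg.start, seg.end))
    for a, b in zip(spans, spans[1:]):
        if b.start <= a.end:
            raise ValueError(
                f"overlapping spans: {a.kind} {a.label!r} ({a.start}, {a.end}) vs "
                f"{b.kind} {b.label!r} ({b.start}, {b.end})"
            )
    segments: list[Segment] = []
    pos = 1
    for seg in spans:
        if seg.start - pos >= MIN_LINKER:
            segments.append(Segment(pos, seg.start - 1, "linker", "linker"))
        segments.append(seg)
        pos = seg.end + 1
    if n - pos + 1 >= MIN_LINKER:
        segments.append(Segment(pos, n, "linker", "linker"))
    if not spans and n >= MIN_LINKER:
        segments = [Segment(1, n, "linker", "linker")]
    return ArchitectureAnnotation(sequence_id=seq.id, length=n, segments=tuple(segments))
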