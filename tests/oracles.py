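"""Independent brute-force oracles used to cross-check the implementations.

Each oracle is deliberately written from first principles (no code shared
with the package paths it checks): a full period scan for tandem repeats,
explicit path enumeration over the genetic code for NG86 counting, and a
dense pH grid scan for the isoelectric point.
"""

from collections import Counter
from itertools import permutations

import numpy as np

from glueevo.properties import peptide_charge
from glueevo.repeats import PERIOD_TIE_TOL

_CODON_AA = {}
_STOPS = set()
_BASES = "TCAG"
_AA_ORDER = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, _first in enumerate(_BASES):
    for _j, _second in enumerate(_BASES):
        for _k, _third in enumerate(_BASES):
            _aa = _AA_ORDER[16 * _i + 4 * _j + _k]
            _codon = _first + _second + _third
            if _aa == "*":
                _STOPS.add(_codon)
            else:
                _CODON_AA[_codon] = _aa

SENSE = sorted(_CODON_AA)


def oracle_syn_sites(codon: str) -> float:
    """Synonymous site count by explicit neighbour enumeration."""
    s = 0.0
    for i in range(3):
        for nt in "ACGT":
            if nt == codon[i]:
                continue
            alt = codon[:i] + nt + codon[i + 1 :]
            if alt not in _STOPS and _CODON_AA[alt] == _CODON_AA[codon]:
                s += 1 / 3
    return s


def oracle_path_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) averaged over all shortest paths avoiding stop codons."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        cur, steps, blocked = c1, [], False
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            if nxt in _STOPS:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        paths.append((blocked, steps))
    usable = [steps for blocked, steps in paths if not blocked]
    fallback = not usable
    if fallback:
        usable = [steps for _, steps in paths]
    sd = nd = 0.0
    for steps in usable:
        for cur, nxt in steps:
            if cur in _STOPS or nxt in _STOPS:
                nd += 1
            elif _CODON_AA[cur] == _CODON_AA[nxt]:
                sd += 1
            else:
                nd += 1
    return sd / len(usable), nd / len(usable)


def oracle_best_period(s: str, min_p: int = 2, max_p: int = 60) -> int:
    """Full scan over periods: majority consensus per phase class over the
    whole string, identity per period, smallest period within the published
    tie tolerance of the best."""
    identity = {}
    for p in range(min_p, min(max_p, len(s) // 2) + 1):
        cols = [Counter() for _ in range(p)]
        for i, ch in enumerate(s):
            cols[i % p][ch] += 1
        unit = "".join(
            min(c for c, k in col.items() if k == max(col.values())) for col in cols
        )
        identity[p] = sum(ch == unit[i % p] for i, ch in enumerate(s)) / len(s)
    best = max(identity.values())
    return min(p for p, v in identity.items() if v >= best - PERIOD_TIE_TOL)


def oracle_pi(seq: str, step: float = 0.001) -> float:
    """Dense grid scan for the pH of minimal absolute net charge."""
    grid = np.arange(0.0, 14.0 + step, step)
    charges = np.array([peptide_charge(seq, x) for x in grid])
    return float(grid[np.argmin(np.abs(charges))])
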