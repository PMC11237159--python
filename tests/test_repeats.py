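import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glueevo.formats import ResidueTrack, SequenceRecord
from glueevo.repeats import (
    RepeatRegion,
    annotate_architecture,
    consensus_unit,
    count_glyco_candidates,
    count_tandem_pg,
    detect_tandem_repeats,
)

from oracles import oracle_best_period

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestDetector:
    def test_exact_tandem_smallest_period(self):
        (region,) = detect_tandem_repeats("ACDACDACDACD")
        assert region.unit_length == 3
        assert region.copy_number == 4.0
        assert region.mean_identity == 1.0
        assert region.consensus == "ACD"
        assert (region.start, region.end) == (1, 12)

    def test_homopolymer_reduces_to_period_one(self):
        (region,) = detect_tandem_repeats("AAAAAA")
        assert region.unit_length == 1
        assert region.copy_number == 6.0

    def test_mutated_18mer_array(self):
        rng = np.random.default_rng(1)
        unit = "TSPGPGIKEAIGQTKPIE"
        s = list(unit * 14)
        for i in range(len(s)):
            if rng.random() < 0.05:
                s[i] = AA[rng.integers(20)]
        (region,) = detect_tandem_repeats("".join(s))
        assert region.unit_length == 18
        assert abs(region.copy_number - 14.0) <= 0.5
        assert region.mean_identity >= 0.9

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            detect_tandem_repeats("ACD", min_period=2)

    def test_random_sequence_yields_no_long_unit(self):
        rng = np.random.default_rng(2)
        s = "".join(rng.choice(list(AA), size=300))
        assert all(r.unit_length <= 3 for r in detect_tandem_repeats(s))

    @given(st.integers(0, 1000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_exact_tandem_invariant_reports_primitive_period(self, seed):
        rng = np.random.default_rng(seed)
        ulen = int(rng.integers(2, 13))
        unit = "".join(rng.choice(list(AA), size=ulen))
        copies = int(rng.integers(3, 8))
        regions = detect_tandem_repeats(unit * copies)
        region = max(regions, key=lambda r: r.length)
        # smallest period of the unit itself
        prim = next(
            d for d in range(1, ulen + 1) if ulen % d == 0 and unit[:d] * (ulen // d) == unit
        )
        assert region.unit_length == prim
        assert region.mean_identity == 1.0
        assert region.copy_number == pytest.approx(copies * ulen / prim)

    def test_matches_full_scan_oracle_on_short_corpus(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            ulen = int(rng.integers(2, 21))
            unit = "".join(rng.choice(list(AA), size=ulen))
            copies = int(rng.integers(4, max(5, 200 // ulen)))
            s = list((unit * copies)[:200])
            for i in range(len(s)):
                if rng.random() < 0.05:
                    s[i] = AA[rng.integers(20)]
            s = "".join(s)
            region = max(detect_tandem_repeats(s), key=lambda r: r.length)
            assert region.unit_length == oracle_best_period(s), s


class TestConsensus:
    def _region(self, s, p):
        return RepeatRegion(
            start=1, end=len(s), unit_length=p, copy_number=len(s) / p,
            consensus=s[:p], mean_identity=1.0,
        )

    def test_exact_copies(self):
        assert consensus_unit(self._region("ACDACDACDACD", 3), "ACDACDACDACD") == "ACD"

    def test_majority_per_column(self):
        s = "ACDACDAGD"
        assert consensus_unit(self._region(s, 3), s) == "ACD"

    def test_alphabetical_tie_break(self):
        s = "ACAD"
        assert consensus_unit(self._region(s, 2), s) == "AC"


class TestTandemPG:
    @pytest.mark.parametrize(
        "unit,expected",
        [
            ("PGPGPGPG", 4),
            ("QIITEEIPGRPEIPG", 1),  # isolated PGs, no tandem run
            ("APA", 0),
            ("PGPG", 2),
            ("XPGPGPGX", 3),
            ("", 0),
        ],
    )
    def test_longest_tandem_run(self, unit, expected):
        assert count_tandem_pg(unit) == expected

    @given(st.text(alphabet=AA, min_size=0, max_size=40))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bounded_and_suffix_invariant(self, unit):
        n = count_tandem_pg(unit)
        assert 0 <= n <= len(unit) // 2
        # appending a non-PG residue never changes the longest run
        assert count_tandem_pg(unit + "W") == n


class TestGlycoCandidates:
    def test_raw_st_count(self):
        assert count_glyco_candidates((1, 6), "IPGTES") == 2

    def test_track_filter_inclusive_threshold(self):
        track = ResidueTrack(
            sequence_id="s", kind="glyco", values=[0.0, 0.0, 0.0, 0.6, 0.0, 0.3]
        )
        assert count_glyco_candidates((1, 6), "IPGTES", track) == 1
        track2 = ResidueTrack(
            sequence_id="s", kind="glyco", values=[0.0, 0.0, 0.0, 0.5, 0.0, 0.5]
        )
        assert count_glyco_candidates((1, 6), "IPGTES", track2) == 2

    def test_no_st_positions(self):
        assert count_glyco_candidates((1, 6), "GPGIPK") == 0

    def test_track_length_mismatch(self):
        track = ResidueTrack(sequence_id="s", kind="glyco", values=[0.5])
        with pytest.raises(ValueError, match="length"):
            count_glyco_candidates((1, 6), "IPGTES", track)


class TestArchitecture:
    def test_interval_bookkeeping(self):
        seq = SequenceRecord(id="p", description="", residues="A" * 1100)
        region = RepeatRegion(
            start=411, end=699, unit_length=18, copy_number=16.0,
            consensus="TSPGPGIKEAIGQTKPIE", mean_identity=1.0,
        )
        ann = annotate_architecture(
            seq,
            domain_hits=[(21, 410, "IgGFcBD"), (700, 1089, "IgGFcBD")],
            repeats=[region],
            signal_peptide=(1, 20),
        )
        kinds = [s.kind for s in ann.segments]
        assert kinds == ["signal_peptide", "domain", "repeat_region", "domain", "linker"]
        assert ann.segments[-1].start == 1090  # 11-residue tail flank

    def test_no_hits_single_linker(self):
        seq = SequenceRecord(id="p", description="", residues="A" * 50)
        ann = annotate_architecture(seq)
        assert [s.kind for s in ann.segments] == ["linker"]
        assert (ann.segments[0].start, ann.segments[0].end) == (1, 50)

    def test_overlap_error_lists_conflict(self):
        seq = SequenceRecord(id="p", description="", residues="A" * 100)
        region = RepeatRegion(
            start=40, end=90, unit_length=5, copy_number=10.2,
            consensus="AAAAA", mean_identity=1.0,
        )
        with pytest.raises(ValueError, match=r"overlapping.*\(10, 50\).*\(40, 90\)"):
            annotate_architecture(seq, domain_hits=[(10, 50, "d")], repeats=[region])

    def test_short_gaps_left_unlabelled(self):
        seq = SequenceRecord(id="p", description="", residues="A" * 30)
        ann = annotate_architecture(seq, domain_hits=[(1, 14, "d"), (18, 30, "d")])
        assert [s.kind for s in ann.segments] == ["domain", "domain"]
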