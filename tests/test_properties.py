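import numpy as np
import pytest
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from hypothesis import given, settings
from hypothesis import strategies as st

from glueevo.formats import ResidueTrack, SequenceRecord
from glueevo.properties import (
    composition,
    comparative_table,
    disorder_fraction,
    gravy,
    isoelectric_point,
    molecular_weight,
    profile_domain,
    secstruct_fractions,
)

from oracles import oracle_pi

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestGravy:
    @pytest.mark.parametrize(
        "seq,expected", [("GGGG", -0.4), ("IIII", 4.5), ("IK", 0.3)]
    )
    def test_kyte_doolittle_means(self, seq, expected):
        assert gravy(seq) == pytest.approx(expected)

    def test_unknown_residues_excluded(self):
        assert gravy("IXI") == pytest.approx(4.5)
        with pytest.raises(ValueError):
            gravy("XXX")

    def test_agrees_with_protparam(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            s = "".join(rng.choice(list(AA), size=rng.integers(5, 80)))
            assert gravy(s) == pytest.approx(ProteinAnalysis(s).gravy(), abs=1e-9)

    @given(st.text(alphabet=AA, min_size=1, max_size=60), st.text(alphabet=AA, min_size=1, max_size=60))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_partition_mean_invariant(self, a, b):
        whole = gravy(a + b)
        assert whole == pytest.approx((len(a) * gravy(a) + len(b) * gravy(b)) / (len(a) + len(b)))
        assert gravy(a + a) == pytest.approx(gravy(a))


class TestDisorderFraction:
    def _track(self, values):
        return ResidueTrack(sequence_id="s", kind="disorder", values=values)

    def test_fully_disordered(self):
        assert disorder_fraction(self._track([0.6, 0.7, 0.8])) == 100.0

    def test_inclusive_threshold(self):
        assert disorder_fraction(self._track([0.50, 0.40, 0.49, 0.51])) == 50.0

    def test_fully_ordered(self):
        assert disorder_fraction(self._track([0.0, 0.0, 0.0])) == 0.0

    def test_monotone_in_threshold(self):
        track = self._track(list(np.linspace(0, 1, 21)))
        fracs = [disorder_fraction(track, threshold=t) for t in (0.2, 0.5, 0.8)]
        assert fracs == sorted(fracs, reverse=True)


class TestSecstruct:
    def test_counting(self):
        track = ResidueTrack(sequence_id="s", kind="secstruct", values=list("EEEECCCCCC"))
        assert secstruct_fractions(track) == {"H": 0.0, "E": 40.0, "C": 60.0}

    def test_all_strand(self):
        track = ResidueTrack(sequence_id="s", kind="secstruct", values=list("EE"))
        assert secstruct_fractions(track)["E"] == 100.0

    def test_median_across_domains(self):
        assert float(np.median([28.0, 31.0, 34.0])) == 31.0


class TestComposition:
    def test_percentages(self):
        c = composition("GGP")
        assert c.percent["G"] == pytest.approx(200 / 3)
        assert c.percent["P"] == pytest.approx(100 / 3)

    def test_x_excluded_but_flagged(self):
        c = composition("GXG")
        assert c.percent == {"G": 100.0}
        assert c.n_unknown == 1

    def test_order_invariance_and_normalisation(self):
        rng = np.random.default_rng(1)
        s = "".join(rng.choice(list(AA), size=60))
        perm = "".join(rng.permutation(list(s)))
        assert composition(s).percent == composition(perm).percent
        assert sum(composition(s).percent.values()) == pytest.approx(100.0, abs=0.01)


class TestMolecularWeight:
    def test_single_glycine(self):
        assert molecular_weight("G") == pytest.approx(75.07, abs=0.01)

    def test_additivity(self):
        assert molecular_weight("GG") == pytest.approx(
            2 * molecular_weight("G") - 18.0153, abs=0.01
        )

    def test_agrees_with_protparam(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            s = "".join(rng.choice(list(AA), size=rng.integers(2, 120)))
            assert molecular_weight(s) == pytest.approx(
                ProteinAnalysis(s).molecular_weight(), abs=0.5
            )

    def test_errors(self):
        with pytest.raises(ValueError):
            molecular_weight("")
        with pytest.raises(ValueError):
            molecular_weight("GXG")


class TestIsoelectricPoint:
    def test_polylysine_basic(self):
        assert isoelectric_point("K" * 10) > 9.5

    def test_polyaspartate_acidic(self):
        assert isoelectric_point("D" * 10) < 4.5

    def test_single_residue_matches_grid_oracle(self):
        assert isoelectric_point("A") == pytest.approx(oracle_pi("A"), abs=0.01)

    def test_grid_oracle_agreement_random_peptides(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            s = "".join(rng.choice(list(AA), size=rng.integers(1, 51)))
            assert isoelectric_point(s) == pytest.approx(oracle_pi(s), abs=0.01)


class TestProfilesAndTable:
    def _profiles(self, rng, seq_id, disorder_mu):
        seq = SequenceRecord(
            id=seq_id, description="", residues="".join(rng.choice(list(AA), size=120))
        )
        track = ResidueTrack(
            sequence_id=seq_id,
            kind="disorder",
            values=list(np.clip(rng.normal(disorder_mu, 0.05, 120), 0, 1)),
        )
        return [
            profile_domain(seq, (1, 60), disorder_track=track),
            profile_domain(seq, (61, 120), disorder_track=track),
        ]

    def test_contrast_sign_follows_generator(self):
        rng = np.random.default_rng(4)
        profiles = {
            "glue_sp": self._profiles(rng, "glue_sp", 0.8),
            "non_sp": self._profiles(rng, "non_sp", 0.2),
        }
        df = comparative_table(profiles, {"glue_sp": True, "non_sp": False})
        assert df.loc["glue_minus_nonglue", "pct_disorder_median"] > 0

    def test_min_max_reproduce_inputs(self):
        rng = np.random.default_rng(5)
        profiles = {"sp": self._profiles(rng, "sp", 0.5)}
        df = comparative_table(profiles, {"sp": True})
        vals = [p.pct_disorder for p in profiles["sp"]]
        assert df.loc["sp", "pct_disorder_min"] == min(vals)
        assert df.loc["sp", "pct_disorder_max"] == max(vals)
        # single-group table: contrast flagged as NaN
        assert np.isnan(df.loc["glue_minus_nonglue", "pct_disorder_median"])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            comparative_table({"sp": []}, {"sp": True})
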