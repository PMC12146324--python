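"""Correlation descriptor families against brute-force loop oracles."""

import numpy as np
import pytest

from lncsubloc.correlation import (
    AC,
    CORRELATION_DIM,
    GEARY,
    MORAN,
    NMB,
    PARALLEL,
    SERIAL,
    auto_correlation,
    auto_cross_correlation,
    correlation_family,
    correlation_features,
    cross_correlation,
    property_profile,
    pseudo_correlation,
)
from lncsubloc.errors import SequenceTooShortError
from lncsubloc.properties import PropertyTable, default_table, load_property_table

import oracles


@pytest.fixture(scope="module")
def d2():
    return default_table(2)


@pytest.fixture(scope="module")
def d3():
    return default_table(3)


class TestPropertyProfile:
    def test_homopolymer_is_constant(self, d2):
        series = property_profile("AAAA", d2, prop=1)
        assert len(series) == 3
        assert np.allclose(series, d2.value("AA", 1))

    def test_length_and_spot_values(self, d3, rng):
        seq = oracles.random_sequence(rng, 60)
        prof = property_profile(seq, d3)
        assert prof.shape == (58, 12)
        for i in (0, 17, 57):
            for p in (1, 7, 12):
                assert prof[i, p - 1] == pytest.approx(d3.value(seq[i : i + 3], p))

    def test_too_short(self, d3):
        with pytest.raises(SequenceTooShortError):
            property_profile("AC", d3)


class TestAutoCorrelation:
    def test_dimension(self, d2, rng):
        seq = oracles.random_sequence(rng, 100)
        assert len(auto_correlation(seq, d2, MORAN)) == 24

    def test_homopolymer_degenerate_rules(self, d2):
        seq = "A" * 40
        moran = auto_correlation(seq, d2, MORAN).values
        assert np.all(moran == 0.0)
        nmb = auto_correlation(seq, d2, NMB).as_dict()
        expected = d2.value("AA", 1) ** 2
        assert nmb["NMB2_p1_lag1"] == pytest.approx(expected)
        assert nmb["NMB2_p1_lag2"] == pytest.approx(expected)

    @pytest.mark.parametrize("scheme", [AC, MORAN, GEARY, NMB])
    def test_matches_loop_oracle(self, scheme, d2, rng):
        seq = oracles.random_sequence(rng, 300)
        got = auto_correlation(seq, d2, scheme).values
        oracle_fn = {
            AC: oracles.autocovariance,
            MORAN: oracles.moran,
            GEARY: oracles.geary,
            NMB: oracles.moreau_broto,
        }[scheme]
        expected = []
        for c in range(1, 13):
            x = oracles.property_series(seq, d2, c)
            for d in (1, 2):
                expected.append(oracle_fn(x, d))
        np.testing.assert_allclose(got, expected, rtol=1e-10, atol=1e-12)


class TestCrossCorrelation:
    def test_dimension_and_ordered_pairs(self, d3, rng):
        seq = oracles.random_sequence(rng, 200)
        fv = cross_correlation(seq, d3)
        assert len(fv) == 264
        v = fv.as_dict()
        # ordered pairs are distinct descriptors with generally different values
        assert "TCC_p1_p2_lag1" in v and "TCC_p2_p1_lag1" in v
        assert v["TCC_p1_p2_lag1"] != pytest.approx(v["TCC_p2_p1_lag1"], abs=1e-15)

    def test_matches_loop_oracle(self, d3, rng):
        seq = oracles.random_sequence(rng, 150)
        got = cross_correlation(seq, d3).as_dict()
        series = {c: oracles.property_series(seq, d3, c) for c in range(1, 13)}
        for c1 in (1, 4, 12):
            for c2 in (2, 7):
                if c1 == c2:
                    continue
                for d in (1, 2):
                    expected = oracles.cross_covariance(series[c1], series[c2], d)
                    assert got[f"TCC_p{c1}_p{c2}_lag{d}"] == pytest.approx(
                        expected, rel=1e-10, abs=1e-12
                    )


class TestAutoCross:
    def test_dimensions(self, d2, d3, rng):
        seq = oracles.random_sequence(rng, 120)
        assert len(auto_cross_correlation(seq, d2)) == 288
        assert len(auto_cross_correlation(seq, d3)) == 288

    def test_auto_block_equals_autocovariance(self, d2, rng):
        seq = oracles.random_sequence(rng, 200)
        dacc = auto_cross_correlation(seq, d2).as_dict()
        ac = auto_correlation(seq, d2, AC, prefix="DACC").as_dict()
        for name, value in ac.items():
            assert dacc[name] == pytest.approx(value)


class TestPseudoCorrelation:
    def test_dimensions(self, rng):
        seq = oracles.random_sequence(rng, 50)
        assert len(pseudo_correlation(seq, k=2, mode=PARALLEL)) == 17
        assert len(pseudo_correlation(seq, k=3, mode=SERIAL)) == 65

    def test_frequency_block_normalization(self, rng):
        seq = oracles.random_sequence(rng, 100)
        fv = pseudo_correlation(seq, k=2, mode=PARALLEL)
        assert fv.values[:16].sum() <= 1.0 + 1e-12
        assert fv.values.sum() == pytest.approx(1.0)

    def test_both_modes_match_straight_line_oracle(self, d2, d3):
        seq = "ACGTACGTACGTACGT"
        got_p = pseudo_correlation(seq, k=2, mode=PARALLEL).values
        exp_p = oracles.pseudo_type1(seq, k=2, lam=1, w=0.05, table=d2)
        np.testing.assert_allclose(got_p, exp_p, rtol=1e-12)
        got_s = pseudo_correlation(seq, k=3, mode=SERIAL).values
        exp_s = oracles.pseudo_type2(seq, k=3, lam=1, w=0.05, table=d3)
        np.testing.assert_allclose(got_s, exp_s, rtol=1e-12)

    def test_too_short_names_mode(self):
        with pytest.raises(SequenceTooShortError, match="SC_PDNC"):
            pseudo_correlation("ACG", k=2, mode=SERIAL)


class TestFullCorrelationVector:
    def test_dimension_arithmetic(self, rng):
        fv = correlation_features(oracles.random_sequence(rng, 90))
        assert len(fv) == CORRELATION_DIM == 12 * 11 * 2 + 2 * (12 * 12 * 2) + 4 * (12 * 2) + 65 + 17 + 65 + 17

    def test_concatenation_matches_families(self, rng):
        seq = oracles.random_sequence(rng, 130)
        full = correlation_features(seq)
        offset = 0
        for fam in ("TCC", "DACC", "TACC", "TAC", "NMBAC", "MAC", "GAC",
                    "SC_PTNC", "SC_PDNC", "PC_PTNC", "PC_PDNC"):
            fv = correlation_family(seq, fam)
            assert full.names[offset : offset + len(fv)] == fv.names
            np.testing.assert_array_equal(full.values[offset : offset + len(fv)], fv.values)
            offset += len(fv)
        assert offset == CORRELATION_DIM


class TestStandardizationInvariance:
    def test_affine_rescaling_of_raw_table_changes_nothing(self, tmp_path, rng):
        import pandas as pd
        from importlib import resources

        ref = resources.files("lncsubloc.data").joinpath("dinucleotide_properties.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
        df["twist"] = 3.5 * df["twist"] + 100.0  # a > 0 affine transform
        path = tmp_path / "scaled.tsv"
        df.to_csv(path, sep="\t", index=False)
        scaled = load_property_table(path, k=2)
        seq = oracles.random_sequence(rng, 200)
        for scheme in (MORAN, GEARY):
            np.testing.assert_allclose(
                auto_correlation(seq, scaled, scheme).values,
                auto_correlation(seq, default_table(2), scheme).values,
                rtol=1e-10,
            )
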