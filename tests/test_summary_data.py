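import math

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrtarget.exceptions import ConfigurationError, EmptyInputError, NoInstrumentsError
from mrtarget.summary_data import (
    GeneRegion,
    HarmonizedInstruments,
    VariantRecord,
    harmonize,
    read_summary_stats,
    write_summary_stats,
)
from mrtarget.synthetic_data import SimConfig, simulate_two_sample

from conftest import make_dataset, make_record

HEADER = (
    "variant_id\tchromosome\tbase_pair_location\teffect_allele\tother_allele\t"
    "effect_allele_frequency\tbeta\tstandard_error\tp_value\tn\n"
)


def write_rows(path, rows):
    path.write_text(HEADER + "".join(rows))
    return path


class TestVariantRecord:
    def test_valid(self):
        make_record()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"se": 0.0},
            {"se": -1.0},
            {"eaf": 0.0},
            {"eaf": 1.0},
            {"pvalue": 0.0},
            {"pvalue": 1.5},
            {"pos": 0},
            {"n": 0},
            {"effect_allele": "G"},  # equals other allele
            {"effect_allele": "N"},
            {"beta": float("nan")},
        ],
    )
    def test_invariants_rejected(self, kwargs):
        with pytest.raises(ValueError):
            make_record(**kwargs)

    def test_palindromic_detection(self):
        assert make_record(effect_allele="A", other_allele="T").is_palindromic
        assert make_record(effect_allele="G", other_allele="C").is_palindromic
        assert not make_record(effect_allele="A", other_allele="G").is_palindromic


class TestDatasetInvariants:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            make_dataset([make_record("rs1"), make_record("rs1", pos=2_000_000)])

    def test_cases_below_total(self):
        with pytest.raises(ValueError, match="n_cases"):
            make_dataset([make_record()], trait_type="binary", n_total=100, n_cases=100)


class TestReadWrite:
    def test_three_row_file(self, tmp_path):
        rows = [
            f"rs{i}\t1\t{1000 + i}\tA\tG\t0.3\t0.1\t0.02\t1e-9\t1000\n" for i in range(3)
        ]
        ds = read_summary_stats(write_rows(tmp_path / "x.tsv", rows))
        assert len(ds) == 3
        assert ds.records[0].variant_id == "rs0"

    def test_invalid_row_filtered(self, tmp_path, caplog):
        rows = [
            "rs1\t1\t1000\tA\tG\t0.3\t0.1\t0.02\t1e-9\t1000\n",
            "rs2\t1\t1001\tA\tG\t0.3\t0.1\t0\t1e-9\t1000\n",  # se = 0
            "rs3\t1\t1002\tA\tG\t0.3\t0.1\t0.02\t1e-9\t1000\n",
        ]
        with caplog.at_level("WARNING"):
            ds = read_summary_stats(write_rows(tmp_path / "x.tsv", rows))
        assert len(ds) == 2
        assert "rejected 1" in caplog.text

    def test_missing_column_errors(self, tmp_path):
        path = tmp_path / "x.tsv"
        path.write_text("variant_id\tbeta\nrs1\t0.1\n")
        with pytest.raises(ConfigurationError, match="missing mandatory"):
            read_summary_stats(path)

    def test_zero_valid_rows_errors(self, tmp_path):
        rows = ["rs1\t1\t1000\tA\tG\t0.3\t0.1\t0\t1e-9\t1000\n"]
        with pytest.raises(EmptyInputError):
            read_summary_stats(write_rows(tmp_path / "x.tsv", rows))

    def test_empty_dataset_writes_header_only(self, tmp_path):
        ds = make_dataset([], n_total=10)
        path = tmp_path / "empty.tsv"
        write_summary_stats(ds, path)
        assert len(path.read_text().strip().splitlines()) == 1

    def test_one_record_two_lines(self, tmp_path):
        path = tmp_path / "one.tsv"
        write_summary_stats(make_dataset([make_record()]), path)
        assert len(path.read_text().strip().splitlines()) == 2

    def test_round_trip_identity(self, tmp_path, small_dataset):
        path = tmp_path / "rt.tsv"
        write_summary_stats(small_dataset, path)
        back = read_summary_stats(path, trait_name="ldl")
        assert back.records == small_dataset.records

    def test_round_trip_on_simulated_data(self, tmp_path):
        sim = simulate_two_sample(SimConfig(seed=7, k_variants=40))
        path = tmp_path / "sim.tsv"
        write_summary_stats(sim.exposure, path)
        back = read_summary_stats(path, trait_name="exposure")
        for a, b in zip(back.records, sim.exposure.records):
            assert a.variant_id == b.variant_id
            assert a.effect_allele == b.effect_allele
            assert a.beta == pytest.approx(b.beta, abs=0, rel=1e-12)
            assert a.se == pytest.approx(b.se, rel=1e-12)
            assert a.eaf == pytest.approx(b.eaf, rel=1e-12)

    def test_missing_eaf_column_tolerated(self, tmp_path):
        path = tmp_path / "noeaf.tsv"
        path.write_text(
            "variant_id\tchromosome\tbase_pair_location\teffect_allele\tother_allele\t"
            "beta\tstandard_error\tp_value\tn\n"
            "rs1\t1\t1000\tA\tG\t0.1\t0.02\t1e-9\t1000\n"
        )
        ds = read_summary_stats(path)
        assert ds.records[0].eaf is None


class TestGeneRegion:
    def test_parse_and_window(self):
        region = GeneRegion.parse("1:55,505,221-55,530,525", flank=10_000)
        assert region.window_start == 55_495_221
        assert region.window_end == 55_540_525
        assert region.contains("1", 55_495_221)
        assert not region.contains("1", 55_495_220)
        assert not region.contains("2", 55_505_221)

    def test_bad_region_string(self):
        with pytest.raises(ConfigurationError):
            GeneRegion.parse("chr1-nonsense")

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            GeneRegion(chrom="1", start=10, end=5)


class TestHarmonize:
    def test_same_orientation(self):
        exp = make_dataset([make_record(beta=0.1)])
        out = make_dataset([make_record(beta=0.05)])
        h = harmonize(exp, out)
        assert h.variants[0].action_taken == "none"
        assert h.variants[0].beta_out == 0.05

    def test_swapped_alleles_negates_beta(self):
        exp = make_dataset([make_record(effect_allele="A", other_allele="G", beta=0.1)])
        out = make_dataset(
            [make_record(effect_allele="G", other_allele="A", eaf=0.7, beta=0.05)]
        )
        h = harmonize(exp, out)
        v = h.variants[0]
        assert v.action_taken == "swapped"
        assert v.beta_out == pytest.approx(-0.05)
        assert v.eaf_out == pytest.approx(0.3)

    def test_palindromic_midrange_dropped(self):
        exp = make_dataset([make_record(effect_allele="A", other_allele="T", eaf=0.50)])
        out = make_dataset([make_record(effect_allele="A", other_allele="T", eaf=0.50)])
        h = harmonize(exp, out, palindromic_eaf_window=0.08)
        assert len(h) == 0
        assert h.dropped == [("rs1", "palindromic")]

    def test_palindromic_outside_window_kept(self):
        exp = make_dataset([make_record(effect_allele="A", other_allele="T", eaf=0.2, beta=0.1)])
        out = make_dataset([make_record(effect_allele="A", other_allele="T", eaf=0.22, beta=0.05)])
        h = harmonize(exp, out, palindromic_eaf_window=0.08)
        assert len(h) == 1
        assert h.variants[0].beta_out == pytest.approx(0.05)

    def test_palindromic_eaf_discordant_flipped(self):
        # Same labels but frequencies on opposite sides of 0.5: the outcome is
        # read off the other strand, so its effect refers to the other allele.
        exp = make_dataset([make_record(effect_allele="A", other_allele="T", eaf=0.2, beta=0.1)])
        out = make_dataset([make_record(effect_allele="A", other_allele="T", eaf=0.8, beta=0.05)])
        h = harmonize(exp, out, palindromic_eaf_window=0.08)
        v = h.variants[0]
        assert v.beta_out == pytest.approx(-0.05)
        assert v.eaf_out == pytest.approx(0.2)

    def test_palindromic_missing_eaf_always_dropped(self):
        exp = make_dataset([make_record(effect_allele="A", other_allele="T", eaf=None)])
        out = make_dataset([make_record(effect_allele="A", other_allele="T", eaf=0.2)])
        h = harmonize(exp, out)
        assert h.dropped == [("rs1", "palindromic")]

    # The eight non-palindromic allele configurations against exposure A/G,
    # enumerated by hand: (outcome ea, outcome oa, strand flips allowed) ->
    # (expected action or None=dropped, outcome beta sign).
    @pytest.mark.parametrize(
        "ea,oa,allow_flip,action,sign",
        [
            ("A", "G", True, "none", +1),
            ("G", "A", True, "swapped", -1),
            ("T", "C", True, "strand_flipped", +1),  # complement, same orientation
            ("C", "T", True, "swapped", -1),  # complement, swapped
            ("A", "C", True, None, 0),  # irreconcilable alleles
            ("T", "G", True, None, 0),
            ("T", "C", False, None, 0),  # flip needed but disallowed
            ("C", "T", False, None, 0),
        ],
    )
    def test_orientation_enumeration(self, ea, oa, allow_flip, action, sign):
        exp = make_dataset([make_record(effect_allele="A", other_allele="G", beta=0.1)])
        out = make_dataset([make_record(effect_allele=ea, other_allele=oa, beta=0.05)])
        h = harmonize(exp, out, allow_strand_flip=allow_flip)
        if action is None:
            assert len(h) == 0
            assert h.dropped == [("rs1", "allele_mismatch")]
        else:
            v = h.variants[0]
            assert v.action_taken == action
            assert v.beta_out == pytest.approx(sign * 0.05)

    def test_empty_intersection_errors(self):
        exp = make_dataset([make_record("rs1")])
        out = make_dataset([make_record("rs2")])
        with pytest.raises(NoInstrumentsError):
            harmonize(exp, out)

    def test_self_harmonization_is_identity(self):
        sim = simulate_two_sample(SimConfig(seed=11, k_variants=30))
        h = harmonize(sim.exposure, sim.exposure)
        assert len(h) == 30
        for v in h.variants:
            assert v.beta_out == v.beta_exp
            assert v.action_taken == "none"

    def test_flip_and_negate_invariance(self):
        """Swapping alleles + negating beta + reflecting eaf on the outcome side
        must leave the harmonized effects unchanged (up to action_taken)."""
        sim = simulate_two_sample(SimConfig(seed=13, k_variants=25, theta=0.2))
        flipped = make_dataset(
            [
                VariantRecord(
                    variant_id=r.variant_id,
                    chrom=r.chrom,
                    pos=r.pos,
                    effect_allele=r.other_allele,
                    other_allele=r.effect_allele,
                    eaf=1.0 - r.eaf,
                    beta=-r.beta,
                    se=r.se,
                    pvalue=r.pvalue,
                    n=r.n,
                )
                for r in sim.outcome.records
            ],
            trait_name="outcome",
            trait_type="binary",
            n_total=sim.outcome.n_total,
            n_cases=sim.outcome.n_cases,
        )
        h0 = harmonize(sim.exposure, sim.outcome)
        h1 = harmonize(sim.exposure, flipped)
        assert len(h0) == len(h1)
        for a, b in zip(h0.variants, h1.variants):
            assert b.beta_out == pytest.approx(a.beta_out, rel=1e-12)
            assert b.eaf_out == pytest.approx(a.eaf_out, rel=1e-12)

    def test_retained_plus_dropped_equals_intersection(self):
        exp = make_dataset(
            [
                make_record("rs1"),
                make_record("rs2", effect_allele="A", other_allele="T", eaf=0.5, pos=2),
                make_record("rs3", effect_allele="T", other_allele="C", pos=3),
            ]
        )
        out = make_dataset(
            [
                make_record("rs1"),
                make_record("rs2", effect_allele="A", other_allele="T", eaf=0.5, pos=2),
                make_record("rs3", effect_allele="A", other_allele="C", pos=3),  # mismatch
                make_record("rs4", pos=4),  # not in exposure
            ]
        )
        h = harmonize(exp, out)
        assert len(h) + len(h.dropped) == 2 + 1  # rs2 palindromic + rs3 mismatch + rs1 kept
        assert h.n_intersection == 3

    def test_harmonized_tsv_round_trip(self, tmp_path):
        sim = simulate_two_sample(SimConfig(seed=17, k_variants=10))
        h = harmonize(sim.exposure, sim.outcome)
        path = tmp_path / "harmonized.tsv"
        h.write_tsv(path)
        back = HarmonizedInstruments.read_tsv(path)
        assert [v.variant_id for v in back] == [v.variant_id for v in h]
        for a, b in zip(h.variants, back.variants):
            assert b.beta_out == pytest.approx(a.beta_out, rel=1e-12)


@settings(max_examples=50, deadline=None)
@given(
    beta=st.floats(-1, 1, allow_nan=False),
    eaf=st.floats(0.05, 0.95),
    swap=st.booleans(),
)
def test_harmonize_sign_convention_property(beta, eaf, swap):
    """Whatever the orientation, the harmonized eaf tracks the exposure's
    effect allele and the beta sign follows the allele relabelling."""
    exp = make_dataset([make_record(effect_allele="A", other_allele="G", eaf=0.3, beta=0.1)])
    ea, oa = ("G", "A") if swap else ("A", "G")
    out = make_dataset(
        [make_record(effect_allele=ea, other_allele=oa, eaf=eaf, beta=beta)]
    )
    v = harmonize(exp, out).variants[0]
    expected_beta = -beta if swap else beta
    expected_eaf = 1 - eaf if swap else eaf
    assert v.beta_out == pytest.approx(expected_beta, rel=1e-12, abs=1e-15)
    assert v.eaf_out == pytest.approx(expected_eaf, rel=1e-12)
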