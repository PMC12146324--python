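"""Sequence I/O, labeling, filtering, redundancy reduction and splitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lncsubloc import (
    NucleotideSequence,
    assign_labels,
    compute_cnrci,
    filter_by_length,
    normalize_sequence,
    read_fasta,
    reduce_redundancy,
    stratified_split,
    write_fasta,
)
from lncsubloc.dataset import CYTOPLASM, NUCLEUS, estimate_identity, read_cnrci_table
from lncsubloc.errors import (
    DuplicateIdError,
    EmptyDatasetError,
    FastaParseError,
    InvalidAlphabetError,
    StratificationError,
)
from lncsubloc.simulate import make_fixture_suite

from oracles import random_sequence


class TestNormalize:
    def test_rna_maps_to_dna(self):
        assert normalize_sequence("acgu") == "ACGT"

    def test_strict_rejects_ambiguous(self):
        with pytest.raises(InvalidAlphabetError, match="N"):
            normalize_sequence("ACGN")

    def test_drop_ambiguous_policy_removes(self):
        assert normalize_sequence("ACGN", policy="drop-ambiguous") == "ACG"

    @given(st.text(alphabet="ACGTUacgtu", min_size=1, max_size=200))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_normalized_output_is_valid_alphabet(self, raw):
        out = normalize_sequence(raw)
        assert set(out) <= set("ACGT")
        assert len(out) == len(raw)


class TestFasta:
    def test_u_mapped_on_read(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">x\nACGU\n")
        recs = read_fasta(p)
        assert [(r.id, r.residues) for r in recs] == [("x", "ACGT")]

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nAC\n>a\nGT\n")
        with pytest.raises(DuplicateIdError):
            read_fasta(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text("")
        with pytest.raises(EmptyDatasetError):
            read_fasta(p)

    def test_non_fasta_rejected_with_line_number(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text("ACGT\n")
        with pytest.raises(FastaParseError, match=":1:"):
            read_fasta(p)

    def test_roundtrip_100_random_records(self, tmp_path, rng):
        seqs = [
            NucleotideSequence(f"s{i}", random_sequence(rng, int(rng.integers(10, 300))))
            for i in range(100)
        ]
        p = tmp_path / "rt.fasta"
        write_fasta(seqs, p)
        back = read_fasta(p)
        assert [(r.id, r.residues) for r in back] == [(s.id, s.residues) for s in seqs]


class TestCnrci:
    @pytest.mark.parametrize(
        "cyt,nuc,expected", [(4.0, 2.0, 1.0), (1.0, 1.0, 0.0), (1.0, 4.0, -2.0)]
    )
    def test_log2_ratio(self, cyt, nuc, expected):
        assert compute_cnrci(cyt, nuc) == pytest.approx(expected)

    def test_zero_expression_gives_nonfinite(self):
        assert math.isnan(compute_cnrci(2.0, 0.0))
        assert math.isnan(compute_cnrci(0.0, 2.0))

    def test_negative_expression_is_domain_error(self):
        with pytest.raises(ValueError):
            compute_cnrci(-1.0, 2.0)

    def test_labels_follow_sign_and_boundary_dropped(self):
        records, dropped = assign_labels(
            [("a", 1.5), ("b", -0.3), ("c", 0.0), ("d", float("nan"))]
        )
        assert [(r.gene_id, r.label) for r in records] == [
            ("a", CYTOPLASM),
            ("b", NUCLEUS),
        ]
        assert dropped == 2

    def test_label_partition_conservation(self, rng):
        values = rng.normal(size=200)
        values[:20] = 0.0
        records, dropped = assign_labels([(f"g{i}", v) for i, v in enumerate(values)])
        assert len(records) + dropped == 200
        for r in records:
            assert (r.cnrci > 0) == (r.label == CYTOPLASM)

    def test_table_reader_computes_cnrci_from_fpkm(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("gene_id,cell_line,cyt_fpkm,nuc_fpkm\ng1,CL1,4.0,2.0\ng2,CL1,2.0,0.0\n")
        df = read_cnrci_table(p)
        assert df.loc[0, "cnrci"] == pytest.approx(1.0)
        assert math.isnan(df.loc[1, "cnrci"])


class TestLengthFilter:
    def test_inclusive_boundary(self, rng):
        seqs = [
            NucleotideSequence(f"s{n}", random_sequence(rng, n))
            for n in (9999, 10000, 10001)
        ]
        kept, removed = filter_by_length(seqs)
        assert [s.id for s in kept] == ["s9999", "s10000"]
        assert removed == 1

    def test_matches_brute_force_and_preserves_residues(self, rng):
        lengths = rng.integers(1, 400, size=50)
        seqs = [
            NucleotideSequence(f"s{i}", random_sequence(rng, int(n)))
            for i, n in enumerate(lengths)
        ]
        kept, removed = filter_by_length(seqs, max_length=200)
        expected = [s for s in seqs if len(s.residues) <= 200]
        assert kept == expected
        assert removed == len(seqs) - len(expected)


class TestRedundancy:
    def test_identical_sequences_collapse(self, rng):
        s = random_sequence(rng, 300)
        reps = reduce_redundancy(
            [NucleotideSequence("a", s), NucleotideSequence("b", s)]
        )
        assert len(reps) == 1

    def test_unrelated_sequences_kept(self, rng):
        a = NucleotideSequence("a", random_sequence(rng, 300))
        b = NucleotideSequence("b", random_sequence(rng, 300))
        assert estimate_identity(a, b) < 0.90
        assert len(reduce_redundancy([a, b])) == 2

    def test_mutated_families_cluster_to_founders(self, tmp_path):
        paths = make_fixture_suite(tmp_path)
        seqs = read_fasta(paths["redundancy_fasta"])
        assert len(seqs) == 20
        reps = reduce_redundancy(seqs)
        assert len(reps) == 5
        # brute-force pairwise identity confirms the clustering structure
        for s in seqs:
            fam = s.id.split("_")[0]
            founder = next(r for r in reps if r.id.startswith(fam))
            assert estimate_identity(s, founder) >= 0.90

    def test_idempotent(self, rng):
        seqs = [
            NucleotideSequence(f"s{i}", random_sequence(rng, 250)) for i in range(15)
        ]
        once = reduce_redundancy(seqs)
        assert reduce_redundancy(once) == once


class TestStratifiedSplit:
    @pytest.mark.parametrize(
        "n_nuc,n_cyt,val_total,val_nuc,val_cyt",
        [
            (1531, 1021, 511, 307, 204),  # large imbalanced cell line
            (588, 115, 141, 118, 23),     # strongly imbalanced cell line
            (5, 5, 2, 1, 1),
        ],
    )
    def test_validation_counts(self, n_nuc, n_cyt, val_total, val_nuc, val_cyt):
        labels = {f"n{i}": NUCLEUS for i in range(n_nuc)}
        labels.update({f"c{i}": CYTOPLASM for i in range(n_cyt)})
        train, val = stratified_split(labels, test_fraction=0.2, seed=7)
        assert len(val) == val_total
        assert sum(labels[g] == NUCLEUS for g in val) == val_nuc
        assert sum(labels[g] == CYTOPLASM for g in val) == val_cyt
        assert len(train) + len(val) == n_nuc + n_cyt
        assert set(train).isdisjoint(val)

    def test_seed_changes_membership_not_sizes(self):
        labels = {f"g{i}": (NUCLEUS if i % 3 else CYTOPLASM) for i in range(90)}
        t1, v1 = stratified_split(labels, seed=1)
        t2, v2 = stratified_split(labels, seed=2)
        assert len(v1) == len(v2)
        assert set(v1) != set(v2)
        assert stratified_split(labels, seed=1) == (t1, v1)

    def test_tiny_class_raises(self):
        with pytest.raises(StratificationError):
            stratified_split({"a": NUCLEUS, "b": CYTOPLASM})
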