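"""I/O, SNP calling and tallying contracts."""

import numpy as np
import pandas as pd
import pytest

from ddpop.seqio import (
    MISSING,
    FragmentAlignment,
    MatingTypeTally,
    SnpMatrix,
    StrainTable,
    call_snps,
    concatenate_alignments,
    load_mating_type_panel,
    read_fragment_alignments,
    read_snps,
    split_concatenation,
    tally_mating_types,
    write_fragment_alignments,
    write_snps,
    write_strain_table,
)
from ddpop.synthetic import SimParams, simulate_study_design, write_study_design


def _frag(fid, chrom, start, seqs):
    return FragmentAlignment(fid, chrom, start, seqs)


class TestReadFragments:
    def test_round_trip_identity(self, tmp_path):
        frags = [
            _frag("f1", "chr1", 100, {"a": "ACGT", "b": "ACGA", "c": "ACGT"}),
            _frag("f2", "chr2", 500, {"a": "TTTT", "b": "TTCT", "c": "TTTT"}),
        ]
        coords = pd.DataFrame(
            {
                "fragment_id": ["f1", "f2"],
                "chromosome": ["chr1", "chr2"],
                "start": [100, 500],
                "length": [4, 4],
            }
        )
        write_fragment_alignments(frags, coords, tmp_path)
        result = read_fragment_alignments(
            sorted(tmp_path.glob("*.fasta")), tmp_path / "coords.tsv"
        )
        assert not result.rejected
        assert len(result.fragments) == 2
        for orig, got in zip(frags, result.fragments):
            assert got.sequences == dict(orig.sequences)
            assert (got.chromosome, got.start) == (orig.chromosome, orig.start)

    def test_length_mismatch_rejected_others_loaded(self, tmp_path):
        (tmp_path / "bad.fasta").write_text(">a\nACGT\n>b\nACG\n")
        (tmp_path / "ok.fasta").write_text(">a\nACGT\n>b\nACGA\n")
        coords = tmp_path / "coords.tsv"
        coords.write_text(
            "fragment_id\tchromosome\tstart\tlength\nbad\tchr1\t1\t4\nok\tchr1\t100\t4\n"
        )
        result = read_fragment_alignments(
            [tmp_path / "bad.fasta", tmp_path / "ok.fasta"], coords
        )
        assert "bad" in result.rejected
        assert [f.fragment_id for f in result.fragments] == ["ok"]

    def test_unknown_chromosome_errors(self, tmp_path):
        (tmp_path / "f.fasta").write_text(">a\nAC\n")
        coords = tmp_path / "coords.tsv"
        coords.write_text("fragment_id\tchromosome\tstart\tlength\nf\tchr9\t1\t2\n")
        with pytest.raises(ValueError, match="chromosome"):
            read_fragment_alignments([tmp_path / "f.fasta"], coords)

    def test_study_design_write_read_round_trip(self, tmp_path):
        data = simulate_study_design(
            SimParams(seed=11, n_fragments_dense=6, n_fragments_other=4)
        )
        write_study_design(data, tmp_path)
        result = read_fragment_alignments(
            sorted(tmp_path.glob("*.fasta")), tmp_path / "coords.tsv"
        )
        assert not result.rejected
        emitted = {f.fragment_id: f for f in data.fragments}
        assert set(emitted) == {f.fragment_id for f in result.fragments}
        for got in result.fragments:
            assert got.sequences == dict(emitted[got.fragment_id].sequences)


class TestCallSnps:
    def test_single_minor_allele_column(self):
        frag = _frag("f", "chr1", 10, {"a": "A", "b": "A", "c": "A", "d": "T"})
        result = call_snps([frag])
        m = result.matrix
        assert m.s == 1
        assert (m.major[0], m.minor[0]) == ("A", "T")
        assert m.minor_counts()[0] == 1
        assert m.positions[0] == 10

    def test_multiallelic_excluded_and_counted(self):
        frag = _frag("f", "chr1", 1, {"a": "A", "b": "C", "c": "G", "d": "T"})
        result = call_snps([frag])
        assert result.matrix.s == 0
        assert result.n_multiallelic == 1

    def test_missing_chars_do_not_count_as_alleles(self):
        frag = _frag("f", "chr1", 1, {"a": "A", "b": "N", "c": "-", "d": "T"})
        m = call_snps([frag]).matrix
        assert m.s == 1
        assert list(m.genotypes[0]) == [0, MISSING, MISSING, 1]

    def test_matches_per_column_brute_force(self, mini_study):
        """S equals an independent per-column scan over all fragments."""
        result = call_snps(mini_study.fragments)
        expected_s = 0
        for frag in mini_study.fragments:
            seqs = list(frag.sequences.values())
            for col in range(frag.length):
                alleles = {s[col] for s in seqs} - {"N", "-"}
                if len(alleles) == 2:
                    expected_s += 1
        assert result.matrix.s == expected_s

    def test_invariant_under_strain_and_fragment_reordering(self, mini_study):
        frags = mini_study.fragments[:8]
        base = call_snps(frags).matrix
        reordered_frags = list(reversed(frags))
        shuffled = []
        rng = np.random.default_rng(0)
        for f in reordered_frags:
            keys = list(f.sequences)
            rng.shuffle(keys)
            shuffled.append(
                FragmentAlignment(
                    f.fragment_id, f.chromosome, f.start, {k: f.sequences[k] for k in keys}
                )
            )
        other = call_snps(shuffled).matrix
        assert np.array_equal(base.positions, other.positions)
        assert base.strains == other.strains  # strains come out sorted
        assert np.array_equal(base.genotypes, other.genotypes)

    def test_snp_count_bounded_by_variable_columns(self, mini_study):
        result = call_snps(mini_study.fragments)
        naive = 0
        for frag in mini_study.fragments:
            seqs = list(frag.sequences.values())
            for col in range(frag.length):
                if len({s[col] for s in seqs} - {"N", "-"}) >= 2:
                    naive += 1
        assert result.matrix.s <= naive


class TestConcatenation:
    def test_lengths_and_boundaries(self):
        f1 = _frag("f1", "chr1", 1, {"a": "A" * 400, "b": "A" * 400})
        f2 = _frag("f2", "chr1", 1000, {"a": "C" * 600, "b": "C" * 600})
        concat = concatenate_alignments([f1, f2])
        assert concat.length == 1000
        assert concat.boundaries == [("f1", 0, 400), ("f2", 400, 1000)]
        assert concat.locate(399) == ("f1", 399)
        assert concat.locate(400) == ("f2", 0)

    def test_empty_list_errors(self):
        with pytest.raises(ValueError, match="nothing to concatenate"):
            concatenate_alignments([])

    def test_split_inverts(self, mini_study):
        frags = mini_study.fragments[:5]
        concat = concatenate_alignments(frags)
        back = split_concatenation(concat)
        assert [f.fragment_id for f in back] == [f.fragment_id for f in frags]
        for orig, got in zip(frags, back):
            assert got.sequences == dict(orig.sequences)


class TestMatingTypes:
    def test_published_panel_tally(self):
        """The shipped 24-strain panel: 18 assigned, 6 unknown, 8 matA2."""
        tally = tally_mating_types(load_mating_type_panel())
        assert tally.total == 24
        assert tally.assigned == 18
        assert tally.counts["unknown"] == 6
        assert tally.counts["matA2"] == 8

    def test_empty_table(self):
        table = StrainTable(
            pd.DataFrame(
                columns=["strain_id", "site_name", "latitude", "longitude", "mating_type"]
            )
        )
        tally = tally_mating_types(table)
        assert tally.total == 0 and tally.assigned == 0
        assert all(v == 0 for v in tally.counts.values())

    def test_unrecognized_label_rejected(self):
        df = pd.DataFrame(
            {
                "strain_id": ["x"],
                "site_name": ["s"],
                "latitude": [0.0],
                "longitude": [0.0],
                "mating_type": ["matA9"],
            }
        )
        with pytest.raises(ValueError, match="mating-type"):
            StrainTable(df)


class TestVcf:
    def test_single_site_single_data_line(self, tmp_path):
        m = SnpMatrix(["chr1"], [42], ["A"], ["G"], [[0, 1]], ("a", "b"))
        path = tmp_path / "one.vcf"
        write_snps(m, path)
        data_lines = [
            l for l in path.read_text().splitlines() if l and not l.startswith("#")
        ]
        assert len(data_lines) == 1
        assert data_lines[0].startswith("chr1\t42\t.\tA\tG")

    def test_round_trip_on_simulated_matrix(self, tmp_path, mini_matrix):
        path = tmp_path / "rt.vcf"
        write_snps(mini_matrix, path)
        back = read_snps(path)
        assert back.strains == mini_matrix.strains
        assert np.array_equal(back.positions, mini_matrix.positions)
        assert list(back.chromosomes) == list(mini_matrix.chromosomes)
        assert np.array_equal(back.genotypes, mini_matrix.genotypes)

    def test_empty_matrix_header_only(self, tmp_path):
        m = SnpMatrix([], [], [], [], np.zeros((0, 2), dtype=np.int8), ("a", "b"))
        path = tmp_path / "empty.vcf"
        write_snps(m, path)
        assert all(l.startswith("#") for l in path.read_text().splitlines())

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            SnpMatrix(
                ["chr1", "chr1"],
                [10, 5],
                ["A", "A"],
                ["G", "G"],
                [[0, 1], [0, 1]],
                ("a", "b"),
            )
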