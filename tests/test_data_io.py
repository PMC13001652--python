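"""Curation filters, FASTA/table round-trips, fixture generator, CLI."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from capaffinity import (
    AffinityRecord,
    CurationPolicy,
    curate,
    generate_fixture,
    read_dataset_table,
    read_fasta,
    write_dataset_table,
)
from capaffinity.cli import main as cli_main
from capaffinity.data_io import (
    read_feature_table,
    write_feature_table,
)
from capaffinity.errors import FormatError


def make_record(**kw):
    base = dict(
        id="1ABC",
        protein_seq="MKVLARE",
        na_seq="ACGTACGT",
        na_type="DNA",
        pkd=6.1,
        temperature_K=298.0,
    )
    base.update(kw)
    return AffinityRecord(**base)


class TestCurate:
    def test_mixed_tu_rejected_first(self):
        kept, rejected = curate([make_record(na_seq="ACGTU")])
        assert kept == []
        assert rejected[0][1] == "mixed-bases"

    def test_qualified_label_rejected(self):
        _, rejected = curate([make_record(pkd="<5.2")])
        assert rejected[0][1] == "ambiguous-label"

    def test_length_filter_depends_on_policy(self):
        rec = make_record(na_seq="ACGT")
        _, rejected = curate([rec], CurationPolicy(min_na_length=5))
        assert rejected[0][1] == "short-na"
        kept, _ = curate([rec], CurationPolicy(min_na_length=1))
        assert len(kept) == 1

    def test_temperature_filter(self):
        _, rejected = curate([make_record(temperature_K=310.0)])
        assert rejected[0][1] == "temperature"
        _, rejected = curate([make_record(temperature_K=None)])
        assert rejected[0][1] == "temperature"
        kept, _ = curate(
            [make_record(temperature_K=None)],
            CurationPolicy(require_temp_298K=False),
        )
        assert len(kept) == 1

    def test_nonstandard_base_rejected_by_default(self):
        _, rejected = curate([make_record(na_seq="ACGTN")])
        assert rejected[0][1] == "non-standard-base"

    def test_rna_with_t_is_nonstandard(self):
        _, rejected = curate([make_record(na_seq="ACGUT", na_type="RNA")])
        assert rejected[0][1] == "mixed-bases"
        _, rejected = curate([make_record(na_seq="ACGTACGT", na_type="RNA")])
        assert rejected[0][1] == "non-standard-base"

    def test_strip_mode_removes_bases_before_length_filter(self):
        rec = make_record(na_seq="ACGNT")
        policy = CurationPolicy(min_na_length=5, strip_nonstandard=True)
        _, rejected = curate([rec], policy)
        assert rejected[0][1] == "short-na"  # stripped to ACGT, length 4

    def test_rbp_filter_applies_to_rna_only(self):
        policy = CurationPolicy(require_rbp=True)
        rna = make_record(na_seq="ACGUACGU", na_type="RNA", is_rbp=None)
        dna = make_record()
        kept, rejected = curate([rna, dna], policy)
        assert [r.id for r in kept] == ["1ABC"]
        assert rejected[0][1] == "not-rbp"

    def test_idempotent_and_order_stable(self):
        records = [
            make_record(id=f"R{i}", pkd=5.0 + i) for i in range(5)
        ] + [make_record(id="BAD", pkd="~3")]
        kept1, _ = curate(records)
        kept2, rej2 = curate(kept1)
        assert [r.id for r in kept1] == [r.id for r in kept2]
        assert rej2 == []
        assert all(isinstance(r.pkd, float) for r in kept1)


class TestFasta:
    def test_order_and_wrapping(self, tmp_path):
        p = tmp_path / "x.fasta"
        long_seq = "ACGT" * 30
        wrapped = "\n".join(long_seq[i : i + 50] for i in range(0, 120, 50))
        p.write_text(f">b\nacgt\n>a\n{wrapped}\n")
        entries = read_fasta(p)
        assert [e[0] for e in entries] == ["b", "a"]
        assert entries[0][1] == "ACGT"
        assert entries[1][1] == long_seq

    def test_crlf_tolerated(self, tmp_path):
        p = tmp_path / "crlf.fasta"
        p.write_bytes(b">r1\r\nACGT\r\nACGT\r\n")
        assert read_fasta(p) == [("r1", "ACGTACGT")]

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "dup.fasta"
        p.write_text(">a\nACGT\n>a\nGGGG\n")
        with pytest.raises(FormatError, match="a"):
            read_fasta(p)

    def test_empty_record_rejected(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text(">a\n\n>b\nACGT\n")
        with pytest.raises(FormatError):
            read_fasta(p)


class TestTables:
    @pytest.mark.parametrize("ext", ["csv", "tsv"])
    def test_dataset_round_trip(self, tmp_path, ext):
        records, _ = generate_fixture(12, seed=3)
        p = tmp_path / f"data.{ext}"
        write_dataset_table(records, p)
        back = read_dataset_table(p)
        assert [r.id for r in back] == [r.id for r in records]
        assert [r.na_seq for r in back] == [r.na_seq for r in records]
        assert [float(r.pkd) for r in back] == [
            pytest.approx(float(r.pkd)) for r in records
        ]

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("id,protein_seq\nA,MKV\n")
        with pytest.raises(FormatError, match="na_seq"):
            read_dataset_table(p)

    def test_feature_table_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        mat = rng.normal(size=(3, 8))
        p = tmp_path / "feat.tsv"
        write_feature_table(["a", "b", "c"], mat, p)
        ids, back = read_feature_table(p)
        assert ids == ["a", "b", "c"]
        assert np.allclose(back, mat)


class TestFixture:
    def test_determinism(self):
        r1, p1 = generate_fixture(20, seed=5, noise_sd=0.1)
        r2, p2 = generate_fixture(20, seed=5, noise_sd=0.1)
        assert p1 == p2
        assert [(r.id, r.protein_seq, r.na_seq, r.pkd) for r in r1] == [
            (r.id, r.protein_seq, r.na_seq, r.pkd) for r in r2
        ]

    def test_different_seeds_differ(self):
        r1, _ = generate_fixture(20, seed=5)
        r2, _ = generate_fixture(20, seed=6)
        assert [r.na_seq for r in r1] != [r.na_seq for r in r2]

    def test_strand_lengths_in_benchmark_range(self):
        records, _ = generate_fixture(60, seed=1)
        lengths = [len(r.na_seq) for r in records]
        assert min(lengths) >= 5 and max(lengths) <= 45

    def test_records_pass_default_curation(self):
        records, _ = generate_fixture(30, seed=2)
        kept, rejected = curate(records)
        assert rejected == []
        assert len(kept) == 30

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            generate_fixture(5, seed=0)


class TestCli:
    def setup_method(self):
        self.runner = CliRunner()

    def test_facets_command(self):
        result = self.runner.invoke(
            cli_main,
            ["facets", "-"],
            input=json.dumps([[0, 1, 2], [0, 2, 3], [0, 3, 4], [0, 4, 1]]),
        )
        assert result.exit_code == 0
        out = json.loads(result.output)
        assert out["facet_counts"] == [0, 0, 4]

    def test_barcodes_command_matches_library(self):
        from capaffinity import FiltrationGrid, NucleicSequence, facet_barcode
        from capaffinity.cap_features import channel_positions

        seq = "ACAAAAAACCCCCAACACAACAA"
        result = self.runner.invoke(
            cli_main, ["barcodes", "--seq", seq, "--symbol", "C", "--grid", "0:12"]
        )
        assert result.exit_code == 0
        got = json.loads(result.output)
        expected = [
            b.to_json_dict()
            for b in facet_barcode(
                channel_positions(NucleicSequence(seq), "C"),
                FiltrationGrid.from_spec("0:12"),
            )
        ]
        assert got == expected

    def test_featurize_command(self, tmp_path):
        fasta = tmp_path / "in.fasta"
        fasta.write_text(">s1\nACGTACGT\n>s2\nAAAACCCC\n>s3\nGTGTGTGT\n")
        out = tmp_path / "features.tsv"
        result = self.runner.invoke(
            cli_main, ["featurize", str(fasta), "-o", str(out)]
        )
        assert result.exit_code == 0
        ids, mat = read_feature_table(out)
        assert ids == ["s1", "s2", "s3"]
        assert mat.shape == (3, 1200)

    def test_fixture_curate_cv_round_trip(self, tmp_path):
        data = tmp_path / "data.csv"
        r = self.runner.invoke(
            cli_main, ["fixture", "-n", "12", "--seed", "3", "-o", str(data)]
        )
        assert r.exit_code == 0
        curated = tmp_path / "kept.csv"
        r = self.runner.invoke(cli_main, ["curate", str(data), "-o", str(curated)])
        assert r.exit_code == 0
        report_path = tmp_path / "report.json"
        r = self.runner.invoke(
            cli_main,
            [
                "cv", str(curated), "-o", str(report_path),
                "--folds", "3", "--seeds", "1",
                "--profile", "fast", "--mode", "nucleic",
            ],
        )
        assert r.exit_code == 0
        report = json.loads(report_path.read_text())
        assert {"pcc_mean_over_seeds", "rmse_mean_over_seeds",
                "pcc_sd_over_seeds", "rmse_sd_over_seeds"} <= report.keys()

    def test_version(self):
        result = self.runner.invoke(cli_main, ["--version"])
        assert result.exit_code == 0
        assert "cap" in result.output and "profiles" in result.output

    def test_unknown_option_is_usage_error(self):
        result = self.runner.invoke(cli_main, ["facets", "--bogus"])
        assert result.exit_code != 0
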