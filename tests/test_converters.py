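"""Conversion plugins: dispatch, gates, cross-method equivalence, SAM/BAM."""

import shutil
import subprocess
from pathlib import Path

import pytest

from biofmt import convert, default_registry, fastq_gate, run_plan
from biofmt import formats_io as fio
from biofmt.converters import DUMMY_QUALITY
from biofmt.errors import (
    ConversionError,
    MissingExecutableError,
    PairingError,
    ParseError,
    UnknownMethodError,
)
from biofmt.fixtures import FixtureSpec, generate


class TestConvertDispatch:
    def test_fastq2fasta_preserves_ids_and_sequences(self, registry, make_fixture, tmp_path):
        fq = make_fixture("fastq", 10, 40, seed=1)
        out = tmp_path / "out.fasta"
        report = convert(registry, "fastq2fasta", [str(fq)], [str(out)])
        assert report.records_in == report.records_out == 10
        assert report.lossy_warning and "quality" in report.lossy_warning
        with open(fq) as h:
            reads = list(fio.parse_records("fastq", h))
        with open(out) as h:
            contigs = list(fio.parse_records("fasta", h))
        assert [(r.id, r.sequence) for r in reads] == [
            (r.id, r.sequence) for r in contigs
        ]
        assert all(r.quality is None for r in contigs)

    def test_empty_input_gives_empty_valid_output(self, registry, make_fixture, tmp_path):
        fq = make_fixture("fastq", 0)
        out = tmp_path / "empty.fasta"
        report = convert(registry, "fastq2fasta", [str(fq)], [str(out)])
        assert report.records_in == report.records_out == 0
        assert out.read_text() == ""

    def test_unknown_method_lists_available(self, registry, make_fixture, tmp_path):
        fq = make_fixture("fastq", 1)
        with pytest.raises(UnknownMethodError, match="records"):
            convert(registry, "fastq2fasta", [str(fq)], [str(tmp_path / "x.fasta")],
                    method="nosuch")

    def test_arity_mismatch(self, registry, make_fixture, tmp_path):
        fq = make_fixture("fastq", 1)
        with pytest.raises(ConversionError, match="input"):
            convert(registry, "fasta_qual2fastq", [str(fq)], [str(tmp_path / "x.fastq")])

    def test_lossless_conversion_has_no_warning(self, registry, make_fixture, tmp_path):
        nwk = make_fixture("newick", 2)
        report = convert(registry, "newick2nexus", [str(nwk)], [str(tmp_path / "t.nexus")])
        assert report.lossy_warning is None


class TestFastqGate:
    def roundtrip(self, registry, tmp_path, fq):
        fa, qa, back = (tmp_path / n for n in ("g.fasta", "g.qual", "g.fastq"))
        convert(registry, "fastq2fasta_qual", [str(fq)], [str(fa), str(qa)])
        convert(registry, "fasta_qual2fastq", [str(fa), str(qa)], [str(back)])
        return back

    @pytest.mark.parametrize("seed", range(5))
    def test_gate_round_trip_byte_identical(self, registry, tmp_path, seed):
        fq = generate(FixtureSpec("fastq", 12, 51, seed=seed), tmp_path / "r.fastq")
        back = self.roundtrip(registry, tmp_path, fq)
        assert back.read_bytes() == Path(fq).read_bytes()

    def test_single_fasta_output_warns_about_quality(self, registry, make_fixture, tmp_path):
        fq = make_fixture("fastq", 3)
        report = fastq_gate(registry, str(fq), fasta_path=str(tmp_path / "s.fasta"))
        assert "quality" in report.lossy_warning

    def test_qual_only_scores_match_decoded_input(self, registry, make_fixture, tmp_path):
        fq = make_fixture("fastq", 5)
        qual_path = tmp_path / "s.qual"
        report = fastq_gate(registry, str(fq), qual_path=str(qual_path))
        assert report.records_out == 5
        with open(fq) as h:
            reads = list(fio.parse_records("fastq", h))
        with open(qual_path) as h:
            quals = list(fio.parse_records("qual", h))
        assert [r.quality for r in reads] == [q.quality for q in quals]

    def test_gate_requires_an_output(self, registry, make_fixture):
        fq = make_fixture("fastq", 1)
        with pytest.raises(ConversionError):
            fastq_gate(registry, str(fq))


class TestFastaQualPairing:
    def write_pair(self, tmp_path, fasta_text, qual_text):
        fa, qa = tmp_path / "p.fasta", tmp_path / "p.qual"
        fa.write_text(fasta_text)
        qa.write_text(qual_text)
        return str(fa), str(qa)

    def test_id_order_mismatch_names_record(self, registry, tmp_path):
        fa, qa = self.write_pair(
            tmp_path, ">a\nAC\n>b\nGT\n", ">b\n1 2\n>a\n3 4\n"
        )
        with pytest.raises(PairingError, match="record 1"):
            convert(registry, "fasta_qual2fastq", [fa, qa], [str(tmp_path / "x.fastq")])

    def test_length_mismatch_names_record(self, registry, tmp_path):
        fa, qa = self.write_pair(tmp_path, ">a\nAC\n>b\nGT\n", ">a\n1 2\n>b\n3\n")
        with pytest.raises(PairingError, match="record 2"):
            convert(registry, "fasta_qual2fastq", [fa, qa], [str(tmp_path / "x.fastq")])

    def test_count_mismatch_detected(self, registry, tmp_path):
        fa, qa = self.write_pair(tmp_path, ">a\nAC\n>b\nGT\n", ">a\n1 2\n")
        with pytest.raises(PairingError, match="counts"):
            convert(registry, "fasta_qual2fastq", [fa, qa], [str(tmp_path / "x.fastq")])


class TestFasta2Fastq:
    def test_constant_dummy_quality(self, registry, make_fixture, tmp_path):
        fa = make_fixture("fasta", 4, 30)
        out = tmp_path / "p.fastq"
        convert(registry, "fasta2fastq", [str(fa)], [str(out)])
        with open(out) as h:
            for rec in fio.parse_records("fastq", h):
                assert rec.quality == [DUMMY_QUALITY] * len(rec.sequence)


class TestCrossMethodEquivalence:
    def multi_method_specs(self, registry):
        return [s for s in registry.converters if len(s.methods) > 1
                and not s.requires_external]

    def test_registry_has_multi_method_converters(self, registry):
        specs = {s.name: s for s in self.multi_method_specs(registry)}
        assert len(specs["fastq2fasta"].methods) >= 3

    @pytest.mark.parametrize("seed", range(6))
    def test_all_methods_byte_identical(self, registry, tmp_path, seed):
        for spec in self.multi_method_specs(registry):
            fmt = spec.inputs[0]
            src = generate(
                FixtureSpec(fmt, 9, 44, seed=seed), tmp_path / f"cm{seed}.{fmt}"
            )
            outputs = {}
            for method in spec.methods:
                out = tmp_path / f"cm{seed}_{method}.out"
                convert(registry, spec, [str(src)], [str(out)], method=method)
                outputs[method] = out.read_bytes()
            reference = outputs[spec.default_method]
            assert all(data == reference for data in outputs.values()), spec.name

    def test_one_record_fastq_one_record_fasta(self, registry, make_fixture, tmp_path):
        fq = make_fixture("fastq", 1)
        out = tmp_path / "one.fasta"
        for method in registry.get_converter("fastq2fasta").methods:
            report = convert(registry, "fastq2fasta", [str(fq)], [str(out)], method=method)
            assert report.records_out == 1

    def test_buffer_method_rejects_ragged_line_count(self, registry, tmp_path):
        bad = tmp_path / "bad.fastq"
        bad.write_text("@r1\nACGT\n+\n!!!I\n@r2\nAC\n")
        with pytest.raises(ParseError):
            convert(registry, "fastq2fasta", [str(bad)], [str(tmp_path / "x.fasta")],
                    method="buffer")


class TestMsaConversions:
    def read_alignment(self, format, path):
        with open(path) as h:
            return next(fio.parse_records(format, h))

    @pytest.mark.parametrize("seed", range(4))
    def test_clustal_fasta_round_trip(self, registry, tmp_path, seed):
        src = generate(FixtureSpec("clustal", 5, 70, seed=seed), tmp_path / "a.clustal")
        mid, back = tmp_path / "a.fasta", tmp_path / "b.clustal"
        convert(registry, "clustal2fasta", [str(src)], [str(mid)])
        convert(registry, "fasta2clustal", [str(mid)], [str(back)])
        first = self.read_alignment("clustal", src)
        second = self.read_alignment("clustal", back)
        assert [(r.id, r.sequence) for r in first.records] == [
            (r.id, r.sequence) for r in second.records
        ]

    def test_gap_characters_preserved(self, registry, tmp_path):
        src = tmp_path / "g.clustal"
        src.write_text("CLUSTAL x\n\ns1   AC-GT\ns2   A..TT\n")
        out = tmp_path / "g.fasta"
        convert(registry, "clustal2fasta", [str(src)], [str(out)])
        recs = list(fio.parse_records("fasta", open(out)))
        assert [r.sequence for r in recs] == ["AC-GT", "A..TT"]

    def test_single_sequence_alignment_valid_everywhere(self, registry, tmp_path):
        src = tmp_path / "one.fasta"
        src.write_text(">only\nACGT-ACGT\n")
        for conversion, ext in [
            ("fasta2clustal", "clustal"), ("fasta2phylip", "phylip"),
            ("fasta2stockholm", "sto"),
        ]:
            out = tmp_path / f"one.{ext}"
            report = convert(registry, conversion, [str(src)], [str(out)])
            assert report.records_out == 1
            fmt = "stockholm" if ext == "sto" else ext
            assert len(self.read_alignment(fmt, out)) == 1

    def test_ragged_fasta_rejected_by_msa_target(self, registry, tmp_path):
        src = tmp_path / "ragged.fasta"
        src.write_text(">a\nACGT\n>b\nAC\n")
        with pytest.raises(ParseError, match="length"):
            convert(registry, "fasta2phylip", [str(src)], [str(tmp_path / "x.phylip")])

    def test_direct_and_two_hop_routes_agree(self, registry, tmp_path):
        """clustal->phylip direct vs clustal->fasta->phylip: identical records."""
        src = generate(FixtureSpec("clustal", 4, 60, seed=7), tmp_path / "t.clustal")
        direct = tmp_path / "direct.phylip"
        convert(registry, "clustal2phylip", [str(src)], [str(direct)])
        mid, hop = tmp_path / "t.fasta", tmp_path / "hop.phylip"
        convert(registry, "clustal2fasta", [str(src)], [str(mid)])
        convert(registry, "fasta2phylip", [str(mid)], [str(hop)])
        assert direct.read_bytes() == hop.read_bytes()


class TestTreeConversions:
    def test_newick_nexus_round_trip(self, registry, tmp_path):
        src = tmp_path / "t.nwk"
        src.write_text("(a,(b,c));\n")
        nexus, back = tmp_path / "t.nexus", tmp_path / "back.nwk"
        convert(registry, "newick2nexus", [str(src)], [str(nexus)])
        assert "(a,(b,c));" in nexus.read_text()
        convert(registry, "nexus2newick", [str(nexus)], [str(back)])
        assert back.read_text() == "(a,(b,c));\n"

    def test_translate_table_applied_on_newick_output(self, registry, tmp_path):
        src = tmp_path / "t.nexus"
        src.write_text(
            "#NEXUS\nbegin trees;\n translate\n  1 a,\n  2 b;\n"
            " tree T1 = (1,2);\nend;\n"
        )
        out = tmp_path / "t.nwk"
        convert(registry, "nexus2newick", [str(src)], [str(out)])
        assert out.read_text() == "(a,b);\n"

    def test_empty_tree_file_is_error(self, registry, tmp_path):
        src = tmp_path / "empty.nwk"
        src.write_text("")
        with pytest.raises(ParseError):
            convert(registry, "newick2nexus", [str(src)], [str(tmp_path / "x.nexus")])


class TestIntervalConversions:
    def test_gff3_convention_shift(self, registry, tmp_path):
        src = tmp_path / "f.gff"
        src.write_text("##gff-version 3\nchr1\t.\tgene\t1\t100\t.\t+\t.\tID=g1\n")
        out = tmp_path / "f.bed"
        convert(registry, "gff32bed", [str(src)], [str(out)])
        assert out.read_text() == "chr1\t0\t100\tg1\t.\t+\n"

    @pytest.mark.parametrize("format,conversion", [("gff3", "gff32bed"), ("vcf", "vcf2bed")])
    def test_row_conservation(self, registry, tmp_path, format, conversion):
        """Counting oracle: BED rows out == non-header rows in, seeded fixtures."""
        for seed in range(5):
            ext = "gff" if format == "gff3" else format
            src = generate(FixtureSpec(format, 11, 30, seed=seed), tmp_path / f"c{seed}.{ext}")
            out = tmp_path / f"c{seed}.bed"
            report = convert(registry, conversion, [str(src)], [str(out)])
            with open(src) as h:
                data_rows = sum(1 for l in h if l.strip() and not l.startswith("#"))
            bed_rows = sum(1 for _ in open(out))
            assert report.records_out == bed_rows == data_rows == 11

    def test_header_lines_not_emitted(self, registry, make_fixture, tmp_path):
        src = make_fixture("vcf", 3)
        out = tmp_path / "v.bed"
        convert(registry, "vcf2bed", [str(src)], [str(out)])
        assert not any(line.startswith("#") for line in open(out))

    def test_coordinate_error_propagates_line_number(self, registry, tmp_path):
        src = tmp_path / "bad.gff"
        src.write_text("chr1\t.\tgene\t0\t10\t.\t+\t.\tID=g1\n")
        with pytest.raises((ParseError, Exception), match="coordinat|GFF3"):
            convert(registry, "gff32bed", [str(src)], [str(tmp_path / "x.bed")])


class TestSamConversions:
    SAM = (
        "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:1000\n"
        "fwd\t0\tchr1\t1\t60\t4M\t*\t0\t0\tACGT\t!!!I\n"
        "rev\t16\tchr1\t10\t60\t4M\t*\t0\t0\tAACG\t!!!I\n"
        "sec\t256\tchr1\t20\t60\t4M\t*\t0\t0\tACGT\t!!!I\n"
    )

    def test_orientation_restored_and_secondary_dropped(self, registry, tmp_path):
        src = tmp_path / "r.sam"
        src.write_text(self.SAM)
        out = tmp_path / "r.fastq"
        report = convert(registry, "sam2fastq", [str(src)], [str(out)])
        assert report.records_in == 3 and report.records_out == 2
        recs = list(fio.parse_records("fastq", open(out)))
        assert [r.id for r in recs] == ["fwd", "rev"]
        assert recs[1].sequence == "CGTT"  # revcomp of AACG
        assert recs[1].quality == [40, 0, 0, 0]

    def test_sam2fasta_drops_qualities(self, registry, tmp_path):
        src = tmp_path / "r.sam"
        src.write_text(self.SAM)
        out = tmp_path / "r.fasta"
        convert(registry, "sam2fasta", [str(src)], [str(out)])
        recs = list(fio.parse_records("fasta", open(out)))
        assert [r.id for r in recs] == ["fwd", "rev"]

    @pytest.mark.skipif(shutil.which("samtools") is None,
                        reason="external samtools binary not on PATH")
    def test_sam2bam_external_round_trip(self, registry, make_fixture, tmp_path):
        """sam -> bam (external) -> sam recovers the alignment lines."""
        src = make_fixture("sam", 8, 40, seed=2)
        bam = tmp_path / "r.bam"
        report = convert(registry, "sam2bam", [str(src)], [str(bam)])
        assert report.records_in == 8 and bam.exists()
        view = subprocess.run(
            ["samtools", "view", str(bam)], capture_output=True, text=True, check=True
        )
        original = [l for l in open(src) if not l.startswith("@")]
        assert view.stdout.splitlines(keepends=True) == original

    def test_missing_external_binary_is_environment_error(self, registry, make_fixture, tmp_path):
        src = make_fixture("sam", 1)
        with pytest.raises(MissingExecutableError, match="no_such_tool"):
            convert(
                registry, "sam2bam", [str(src)], [str(tmp_path / "x.bam")],
                options={"command_template": "no_such_tool view {input} {output}"},
            )

    def test_external_failure_captures_stderr(self, registry, make_fixture, tmp_path):
        src = make_fixture("sam", 1)
        from biofmt.errors import ExternalToolError

        with pytest.raises(ExternalToolError, match="exit status"):
            convert(
                registry, "sam2bam", [str(src)], [str(tmp_path / "x.bam")],
                options={"command_template": "samtools view --definitely-bad-flag {input}"},
            )


class TestTransitiveExecution:
    def test_run_plan_chains_through_workdir(self, registry, tmp_path):
        src = generate(FixtureSpec("clustal", 3, 50, seed=1), tmp_path / "a.clustal")
        plan = registry.find_path("clustal", "stockholm")
        assert [s.name for s in plan.steps] == ["clustal2fasta", "fasta2stockholm"]
        out = tmp_path / "a.sto"
        work = tmp_path / "work"
        work.mkdir()
        reports = run_plan(registry, plan, str(src), str(out), str(work))
        assert len(reports) == 2 and out.exists()
        aln = next(fio.parse_records("stockholm", open(out)))
        orig = next(fio.parse_records("clustal", open(src)))
        assert [(r.id, r.sequence) for r in aln.records] == [
            (r.id, r.sequence) for r in orig.records
        ]

    def test_empty_plan_rejected(self, registry, tmp_path):
        from biofmt.registry import ConversionPlan

        with pytest.raises(ConversionError):
            run_plan(registry, ConversionPlan(()), "a", "b", str(tmp_path))

    def test_record_order_preserved_everywhere(self, registry, tmp_path):
        fq = generate(FixtureSpec("fastq", 15, 30, seed=4), tmp_path / "o.fastq")
        out = tmp_path / "o.fasta"
        convert(registry, "fastq2fasta", [str(fq)], [str(out)])
        in_ids = [r.id for r in fio.parse_records("fastq", open(fq))]
        out_ids = [r.id for r in fio.parse_records("fasta", open(out))]
        assert in_ids == out_ids
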