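import gffutils
import numpy as np
import pytest

from rnpbscan import (
    LocusCall,
    ScanParams,
    annotate,
    classify_locus,
    map_minus_coordinates,
    rescore,
    resolve_overlaps,
    reverse_complement,
    scan_sequence,
    write_gff3,
    write_negatives_tsv,
    write_tsv,
)
from rnpbscan.align import AlignmentResult
from rnpbscan.scan import read_calls_tsv

from .conftest import random_dna_str


def _aln(ts, te):
    return AlignmentResult(
        ref_id="r", raw_score=10, target_start=ts, target_end=te,
        ref_start=1, ref_end=te - ts + 1, n_matches=te - ts + 1,
        n_mismatches=0, n_gap_columns=0,
        aligned_pairs=[(i, i - ts + 1) for i in range(ts, te + 1)],
    )


def _call(start, end, bits=50.0, evalue=1e-10, stype="A", ref="r1"):
    return LocusCall(
        target_id="g", start=start, end=end, strand="plus",
        structural_type=stype, domain="bacteria", best_ref=ref,
        raw_score=int(bits), bitscore=bits, evalue=evalue, percent_id=95.0,
        sequence="A" * (end - start + 1), aln_len=end - start + 1,
    )


class TestMinusCoordinateMapping:
    @pytest.mark.parametrize(
        "span, L, expected",
        [((1, 10), 100, (91, 100)), ((1, 100), 100, (1, 100)),
         ((41, 60), 100, (41, 60))],
    )
    def test_mapping_formula(self, span, L, expected):
        assert map_minus_coordinates(_aln(*span), L) == expected

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            map_minus_coordinates(_aln(95, 105), 100)


class TestResolveOverlaps:
    def test_higher_bitscore_wins_full_overlap(self):
        survivors = resolve_overlaps([_call(10, 400, 50.0), _call(10, 400, 60.0)])
        assert len(survivors) == 1
        assert survivors[0].bitscore == 60.0

    def test_tie_broken_by_smaller_start(self):
        survivors = resolve_overlaps(
            [_call(20, 400, 50.0), _call(10, 390, 50.0)]
        )
        assert len(survivors) == 1
        assert survivors[0].start == 10

    def test_disjoint_candidates_both_survive(self):
        survivors = resolve_overlaps([_call(10, 300, 50.0), _call(500, 800, 40.0)])
        assert len(survivors) == 2
        assert [c.start for c in survivors] == [10, 500]

    def test_close_runner_up_of_other_type_warns(self):
        winner = _call(10, 400, 80.0, stype="A", ref="rA")
        rival = _call(12, 402, 78.0, stype="B", ref="rB")
        survivors = resolve_overlaps([winner, rival], ambiguity_margin=5.0)
        assert len(survivors) == 1
        assert survivors[0].structural_type == "A"
        assert any("ambiguous" in w for w in survivors[0].warnings)

    def test_distant_runner_up_no_warning(self):
        survivors = resolve_overlaps(
            [_call(10, 400, 80.0, stype="A"), _call(12, 402, 60.0, stype="B")]
        )
        assert survivors[0].warnings == []


class TestScanSequence:
    def test_random_genome_without_plants_is_empty(self, ref_db):
        rng = np.random.default_rng(99)
        genome = random_dna_str(rng, 20_000)
        assert scan_sequence("g", genome, ref_db) == []

    def test_exact_plus_plant_called_boundary_exact(self, ref_db):
        rng = np.random.default_rng(4)
        ref = ref_db.records[0]
        genome = (
            random_dna_str(rng, 5000)
            + ref.sequence
            + random_dna_str(rng, 5000 - len(ref))
        )
        calls = scan_sequence("g", genome, ref_db)
        assert len(calls) == 1
        call = calls[0]
        assert (call.start, call.end) == (5001, 5000 + len(ref))
        assert call.strand == "plus"
        assert call.structural_type == ref.structural_type
        assert call.percent_id == 100.0
        assert call.sequence == ref.sequence

    def test_revcomp_genome_gives_mirrored_minus_call(self, ref_db):
        rng = np.random.default_rng(4)
        ref = ref_db.records[0]
        genome = (
            random_dna_str(rng, 5000)
            + ref.sequence
            + random_dna_str(rng, 5000 - len(ref))
        )
        L = len(genome)
        fwd = scan_sequence("g", genome, ref_db)
        rev = scan_sequence("g", reverse_complement(genome), ref_db)
        assert len(fwd) == len(rev) == 1
        f, r = fwd[0], rev[0]
        assert (r.start, r.end) == (L - f.end + 1, L - f.start + 1)
        assert r.strand == "minus"
        assert r.bitscore == f.bitscore
        assert r.sequence == reverse_complement(f.sequence)

    def test_call_sequence_rescores_to_raw_score(self, ref_db, planted_genome, scheme):
        calls = scan_sequence("g", planted_genome.sequence, ref_db)
        assert calls
        for call in calls:
            called = call.sequence
            if call.strand == "minus":
                called = reverse_complement(called)
            from rnpbscan import smith_waterman

            aln = smith_waterman(called, ref_db.by_id[call.best_ref].sequence, scheme)
            assert aln.raw_score == call.raw_score

    def test_classify_locus_copies_best_ref_labels(self, ref_db, planted_genome):
        calls = scan_sequence("g", planted_genome.sequence, ref_db)
        for call in calls:
            stype, domain = classify_locus(call, ref_db)
            assert (call.structural_type, call.domain) == (stype, domain)


class TestAnnotate:
    def _three_genomes(self, ref_db):
        rng = np.random.default_rng(17)
        r0, r1 = ref_db.records[0], ref_db.records[10]
        g1 = random_dna_str(rng, 3000) + r0.sequence + random_dna_str(rng, 3000)
        g2 = (
            random_dna_str(rng, 3000)
            + reverse_complement(r1.sequence)
            + random_dna_str(rng, 3000)
        )
        g3 = random_dna_str(rng, 6000)
        return [("g1", g1), ("g2", g2), ("g3", g3)]

    def test_negatives_bookkeeping(self, ref_db):
        report = annotate(self._three_genomes(ref_db), ref_db)
        assert {c.target_id for c in report.calls} == {"g1", "g2"}
        assert report.negatives == ["g3"]

    def test_every_target_in_exactly_one_bucket(self, ref_db):
        report = annotate(self._three_genomes(ref_db), ref_db)
        with_calls = {c.target_id for c in report.calls}
        assert with_calls | set(report.negatives) == {"g1", "g2", "g3"}
        assert not with_calls & set(report.negatives)

    def test_worker_count_and_record_order_do_not_change_output(
        self, ref_db, tmp_path
    ):
        genomes = self._three_genomes(ref_db)
        outputs = []
        for threads, order in ((1, genomes), (4, genomes[::-1])):
            report = annotate(order, ref_db, threads=threads)
            tsv = tmp_path / f"calls_{threads}.tsv"
            gff = tmp_path / f"calls_{threads}.gff3"
            write_tsv(report, tsv)
            write_gff3(report, gff)
            outputs.append((tsv.read_bytes(), gff.read_bytes()))
        assert outputs[0] == outputs[1]

    def test_empty_input_rejected(self, ref_db, tmp_path):
        empty = tmp_path / "empty.fa"
        empty.write_text("")
        with pytest.raises(ValueError):
            annotate(empty, ref_db)

    def test_fasta_path_and_gzip_input(self, ref_db, tmp_path):
        import gzip

        genomes = self._three_genomes(ref_db)
        fa = tmp_path / "g.fa.gz"
        with gzip.open(fa, "wt") as fh:
            for rid, seq in genomes:
                fh.write(f">{rid}\n{seq}\n")
        report = annotate(fa, ref_db)
        assert report.negatives == ["g3"]


class TestWriters:
    def _report(self, ref_db):
        return annotate(
            [("g1", _planted(ref_db, seed=31)), ("g2", random_dna_str(np.random.default_rng(32), 4000))],
            ref_db,
        )

    def test_tsv_column_selection_and_order(self, ref_db, tmp_path):
        report = self._report(ref_db)
        out = tmp_path / "calls.tsv"
        write_tsv(report, out, ["target_id", "start", "end", "strand"])
        lines = [
            l for l in out.read_text().splitlines() if not l.startswith("#")
        ]
        assert lines[0] == "target_id\tstart\tend\tstrand"
        assert all(len(l.split("\t")) == 4 for l in lines)

    def test_tsv_default_columns(self, ref_db, tmp_path):
        report = self._report(ref_db)
        out = tmp_path / "calls.tsv"
        write_tsv(report, out)
        header = [
            l for l in out.read_text().splitlines() if not l.startswith("#")
        ][0].split("\t")
        for col in ("bitscore", "evalue", "percent_id", "start", "end",
                    "strand", "sequence"):
            assert col in header

    def test_tsv_unknown_column_rejected(self, ref_db, tmp_path):
        report = self._report(ref_db)
        with pytest.raises(ValueError, match="unknown column"):
            write_tsv(report, tmp_path / "x.tsv", ["start", "bogus"])

    def test_empty_report_writes_header_only(self, ref_db, tmp_path):
        report = annotate(
            [("g", random_dna_str(np.random.default_rng(1), 3000))], ref_db
        )
        out = tmp_path / "empty.tsv"
        write_tsv(report, out)
        lines = [
            l for l in out.read_text().splitlines() if not l.startswith("#")
        ]
        assert len(lines) == 1

    def test_negatives_file(self, ref_db, tmp_path):
        report = self._report(ref_db)
        out = tmp_path / "neg.tsv"
        write_negatives_tsv(report, out)
        assert out.read_text() == "target_id\treason\ng2\tno_hit\n"

    def test_tsv_roundtrip_via_reader(self, ref_db, tmp_path):
        report = self._report(ref_db)
        out = tmp_path / "calls.tsv"
        write_tsv(report, out, ["target_id", "type", "start", "end", "strand"])
        back = read_calls_tsv(out)
        assert [(c.start, c.end, c.strand) for c in back] == [
            (c.start, c.end, c.strand) for c in report.calls
        ]

    def test_gff3_structure_and_roundtrip(self, ref_db, tmp_path):
        report = self._report(ref_db)
        out = tmp_path / "calls.gff3"
        write_gff3(report, out)
        text = out.read_text()
        assert text.startswith("##gff-version 3\n")
        db = gffutils.create_db(str(out), ":memory:", force=True)
        feats = list(db.features_of_type("rnpB"))
        assert [(f.seqid, f.start, f.end) for f in feats] == [
            (c.target_id, c.start, c.end) for c in report.calls
        ]
        for f, c in zip(feats, report.calls):
            assert f.strand == ("+" if c.strand == "plus" else "-")
            assert f.start <= f.end
            assert f.attributes["structural_type"][0] == c.structural_type


def _planted(ref_db, seed):
    rng = np.random.default_rng(seed)
    ref = ref_db.records[5]
    return (
        random_dna_str(rng, 2500) + ref.sequence + random_dna_str(rng, 2500)
    )
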