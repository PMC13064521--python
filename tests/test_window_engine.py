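"""Window tiling, active-region detection, per-window calling, merging."""

import pytest

from somacall import io_formats as io
from somacall import simdata
from somacall.window_engine import (
    CallerConfig,
    Window,
    WindowResult,
    detect_active_region,
    merge_windows,
    tile_genome,
)
from tests.conftest import call_center_window


def _read(seq, name="r", cigar=None, sample="tumor"):
    return io.ReadRecord(
        name=name, sequence=seq, base_qualities=(30,) * len(seq),
        mapping_quality=60, strand="forward", sample=sample, chrom="chr1",
        start=0, cigar=cigar or (("M", len(seq)),),
    )


class TestTileGenome:
    def test_stepping_rule(self):
        w = tile_genome({"chr1": 1000}, 600, 250)
        assert [(x.start, x.end) for x in w] == [(0, 600), (350, 950), (700, 1000)]

    def test_short_contig_single_window(self):
        w = tile_genome({"chr1": 300}, 600, 250)
        assert [(x.start, x.end) for x in w] == [(0, 300)]

    def test_empty_genome(self):
        assert tile_genome({}, 600, 250) == []

    def test_overlap_ge_size_rejected(self):
        with pytest.raises(ValueError):
            tile_genome({"chr1": 1000}, 600, 600)

    @pytest.mark.parametrize("length", [599, 600, 601, 2000, 2349, 5000])
    def test_full_coverage_and_interior_redundancy(self, length):
        windows = tile_genome({"chr1": length}, 600, 250)
        covered = set()
        for w in windows:
            covered.update(range(w.start, w.end))
        assert covered == set(range(length))
        # away from contig ends, every base sits well inside some window
        for pos in range(250, length - 250):
            assert any(
                w.start + 125 <= pos < w.end - 125 or (w.end - w.start) < 350
                for w in windows
            )


class TestActiveRegion:
    REF = "ACGTACCATGGTTGACAGGATCACGTATTGCAAGTACCACGGATT"

    def test_reference_reads_inactive(self):
        reads = [_read(self.REF[i : i + 25], name=f"r{i}") for i in range(5)]
        assert not detect_active_region(reads, [], self.REF, 11)

    def test_shared_novel_kmer_activates(self):
        alt = self.REF[:20] + ("A" if self.REF[20] != "A" else "C") + self.REF[21:]
        reads = [_read(alt[8:36], name="a"), _read(alt[10:40], name="b")]
        assert detect_active_region(reads, [], self.REF, 11, min_active_support=2)

    def test_singleton_error_does_not_activate(self):
        alt = self.REF[:20] + ("A" if self.REF[20] != "A" else "C") + self.REF[21:]
        reads = [_read(alt[8:36], name="a"), _read(self.REF[10:40], name="b")]
        assert not detect_active_region(reads, [], self.REF, 11, min_active_support=2)

    def test_indel_cigar_activates(self):
        reads = [_read(self.REF[:30], cigar=(("M", 10), ("D", 4), ("M", 20)))]
        assert detect_active_region(reads, [], self.REF, 11)

    def test_empty_reads_inactive(self):
        assert not detect_active_region([], [], self.REF, 11)


class TestCallWindow:
    def test_inactive_window_no_calls(self):
        sim = simdata.simulate_pair(length=1400, specs=[], error_rate=0.0, seed=19)
        result = call_center_window(sim)
        assert result.reason == "inactive" and result.records == []

    def test_somatic_snv_called_with_genotypes(self, snv_sim):
        sim, spec = snv_sim
        result = call_center_window(sim)
        assert result.reason is None
        (rec,) = result.records
        assert rec.pos == spec.pos0 + 1
        assert (rec.ref_allele, rec.alt_allele) == (spec.ref_allele, spec.alt_allele)
        assert rec.samples["tumor"]["GT"] == "0/1"
        assert rec.samples["normal"]["GT"] == "0/0"
        assert rec.samples["normal"]["AD"][1] == 0

    def test_no_usable_k_demoted(self):
        reads = [_read("A" * 60)]
        result_window = Window("chr1", 0, 100, 0)
        from somacall.window_engine import call_window

        res = call_window(result_window, reads, [], "A" * 100, CallerConfig())
        assert res.reason == "no_k" and res.records == []


class TestMergeWindows:
    def _rec(self, pos=100, score=None):
        return io.VcfRecord(chrom="chr1", pos=pos, ref_allele="A", alt_allele="G", score=score)

    def _result(self, index, records):
        return WindowResult(window=Window("chr1", 0, 600, index), records=records)

    def test_higher_score_wins(self):
        merged = merge_windows([
            self._result(3, [self._rec(score=0.97)]),
            self._result(4, [self._rec(score=0.95)]),
        ])
        assert len(merged) == 1 and merged[0].score == 0.97

    def test_tie_keeps_lower_window_index(self):
        a, b = self._rec(score=0.9), self._rec(score=0.9)
        merged = merge_windows([self._result(4, [b]), self._result(3, [a])])
        assert merged[0] is a

    def test_disjoint_concatenated_sorted(self):
        merged = merge_windows([
            self._result(1, [self._rec(pos=500)]),
            self._result(0, [self._rec(pos=100)]),
        ])
        assert [r.pos for r in merged] == [100, 500]


class TestRunCalling:
    def test_worker_count_invariance(self, snv_bam_dir, tmp_path):
        """Single- and multi-worker runs write byte-identical VCFs."""
        from somacall.window_engine import run_calling

        outs = []
        for threads in (1, 2):
            out = tmp_path / f"t{threads}.vcf"
            run_calling(
                str(snv_bam_dir / "tumor.bam"), str(snv_bam_dir / "normal.bam"),
                str(snv_bam_dir / "ref.fa"), str(out), threads=threads,
            )
            outs.append(out.read_bytes())
        assert outs[0] == outs[1]

    def test_region_and_exclusion(self, snv_bam_dir, tmp_path):
        from somacall.window_engine import run_calling

        out = tmp_path / "out.vcf"
        records = run_calling(
            str(snv_bam_dir / "tumor.bam"), str(snv_bam_dir / "normal.bam"),
            str(snv_bam_dir / "ref.fa"), str(out), region="chr1:600-900",
        )
        assert len(records) == 1 and records[0].pos == 701
        bed = tmp_path / "x.bed"
        bed.write_text("chr1\t650\t750\n")
        records = run_calling(
            str(snv_bam_dir / "tumor.bam"), str(snv_bam_dir / "normal.bam"),
            str(snv_bam_dir / "ref.fa"), str(out), region="chr1:600-900",
            exclude_bed=str(bed),
        )
        assert records == []


class TestConfigFile:
    def test_overrides(self, tmp_path):
        p = tmp_path / "cfg"
        p.write_text("window_size = 500\nmin_mapq=20\nthreshold_snv=0.8  # loose\n")
        cfg = CallerConfig.from_file(str(p))
        assert cfg.window_size == 500 and cfg.min_mapq == 20
        assert cfg.thresholds["SNV"] == 0.8 and cfg.thresholds["DEL"] == 0.95

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "cfg"
        p.write_text("bogus=1\n")
        with pytest.raises(KeyError):
            CallerConfig.from_file(str(p))
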