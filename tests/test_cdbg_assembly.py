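"""Colored de Bruijn graph: k selection, construction, cleaning, paths."""

import pytest

from somacall import cdbg_assembly as asm
from somacall import simdata
from somacall.io_formats import ReadRecord


def _read(seq, sample="tumor", name="r", qual=30):
    return ReadRecord(
        name=name, sequence=seq, base_qualities=(qual,) * len(seq),
        mapping_quality=60, strand="forward", sample=sample, chrom="chr1",
        start=0, cigar=(("M", len(seq)),),
    )


class TestSelectK:
    def test_random_window_takes_first_candidate(self):
        ref = simdata.make_reference(590, 17)
        if asm.select_k(ref) != 11:  # rare 11-mer repeat: skip-free fallback
            ref = simdata.make_reference(590, 18)
        assert asm.select_k(ref) in (11, 13)

    def test_periodic_window_brute_force(self):
        """k must exceed the repeat period; brute force says 9 for 'ACGT'*3."""
        ref = "ACGTACGTACGT"
        for k in (3, 5, 7):
            kmers = [ref[i : i + k] for i in range(len(ref) - k + 1)]
            assert len(set(kmers)) < len(kmers)
        k9 = [ref[i : i + 9] for i in range(len(ref) - 9 + 1)]
        assert len(set(k9)) == len(k9)
        assert asm.select_k(ref, k_min=3, k_max=11, step=2) == 9

    def test_homopolymer_has_no_usable_k(self):
        with pytest.raises(asm.NoUsableK):
            asm.select_k("A" * 50, k_min=11, k_max=31, step=2)

    def test_even_parameters_rejected(self):
        with pytest.raises(ValueError):
            asm.select_k("ACGT" * 10, k_min=10)
        with pytest.raises(ValueError):
            asm.select_k("ACGT" * 10, k_min=11, step=3)


class TestBuildGraph:
    def test_reference_only_nodes(self):
        ref = simdata.make_reference(100, 2)
        g = asm.build_graph([], [], ref, 11)
        assert len(g.nodes) == len(ref) - 11 + 1
        assert all(n.total == 0 and n.on_reference for n in g.nodes.values())
        assert g.spell_reference_path(ref) == ref

    def test_exact_copies_count_coverage(self):
        ref = simdata.make_reference(60, 2)
        reads = [_read(ref, name=f"r{i}") for i in range(3)]
        g = asm.build_graph(reads, [], ref, 11)
        assert len(g.nodes) == len(ref) - 10
        assert all(n.tumor == 3 for n in g.nodes.values())

    def test_mid_window_snv_adds_k_novel_nodes(self):
        ref = simdata.make_reference(100, 5)
        pos = 50
        alt = "A" if ref[pos] != "A" else "C"
        mutated = ref[:pos] + alt + ref[pos + 1 :]
        g = asm.build_graph([_read(mutated)], [], ref, 11)
        novel = [n for kmer, n in g.nodes.items() if not n.on_reference]
        assert len(novel) == 11
        assert all(n.tumor == 1 and n.normal == 0 for n in novel)

    def test_order_invariance(self):
        ref = simdata.make_reference(80, 6)
        reads = [_read(ref[i : i + 40], name=f"r{i}") for i in range(0, 40, 7)]
        g1 = asm.build_graph(reads, [], ref, 11)
        g2 = asm.build_graph(list(reversed(reads)), [], ref, 11)
        assert g1.edges == g2.edges
        assert {k: (n.tumor, n.normal) for k, n in g1.nodes.items()} == {
            k: (n.tumor, n.normal) for k, n in g2.nodes.items()
        }


class TestCleanGraph:
    def test_singleton_error_bubble_removed(self):
        ref = simdata.make_reference(100, 7)
        pos = 50
        alt = "A" if ref[pos] != "A" else "C"
        erroneous = ref[:pos] + alt + ref[pos + 1 :]
        reads = [_read(ref, name=f"c{i}") for i in range(3)] + [_read(erroneous, name="err")]
        g = asm.build_graph(reads, [], ref, 11)
        asm.clean_graph(g, min_node_cov=2)
        assert all(n.on_reference for n in g.nodes.values())
        assert g.spell_reference_path(ref) == ref

    def test_uncovered_reference_node_retained(self):
        ref = simdata.make_reference(60, 8)
        g = asm.build_graph([], [], ref, 11)
        asm.clean_graph(g, min_node_cov=2)
        assert len(g.nodes) == len(ref) - 10

    def test_idempotent_and_monotone(self):
        ref = simdata.make_reference(120, 9)
        pos = 60
        alt = "A" if ref[pos] != "A" else "C"
        reads = [_read(ref[:80], name="a"), _read(ref[:pos] + alt + ref[pos + 1 : 90], name="b")]
        g = asm.build_graph(reads, [], ref, 11)
        before = set(g.nodes)
        asm.clean_graph(g)
        once = set(g.nodes)
        asm.clean_graph(g)
        assert set(g.nodes) == once <= before


class TestEnumeratePaths:
    def test_reference_only_graph_single_path(self):
        ref = simdata.make_reference(80, 10)
        g = asm.build_graph([], [], ref, 11)
        paths = asm.enumerate_paths(g)
        assert len(paths) == 1 and paths[0].contig == ref

    def _bubble_graph(self, support_alt=2, support_ref=5):
        ref = simdata.make_reference(80, 11)
        pos = 40
        alt_base = "A" if ref[pos] != "A" else "C"
        alt_hap = ref[:pos] + alt_base + ref[pos + 1 :]
        reads = [_read(ref, name=f"r{i}") for i in range(support_ref)]
        reads += [_read(alt_hap, name=f"a{i}") for i in range(support_alt)]
        g = asm.build_graph(reads, [], ref, 11)
        asm.clean_graph(g)
        return g, ref, alt_hap

    def test_snv_bubble_two_paths(self):
        g, ref, alt_hap = self._bubble_graph()
        paths = asm.enumerate_paths(g)
        assert sorted(p.contig for p in paths) == sorted([ref, alt_hap])

    def test_max_paths_one_keeps_better_supported_branch(self):
        g, ref, alt_hap = self._bubble_graph(support_alt=2, support_ref=5)
        paths = asm.enumerate_paths(g, max_paths=1)
        assert len(paths) == 1 and paths[0].contig == ref

    def test_heterozygous_event_recovers_both_haplotypes(self, snv_sim):
        """With error-free reads, the two enumerated contigs are the two
        true haplotypes around the somatic SNV (simulator oracle)."""
        sim, spec = snv_sim
        ws, we = 400, 1000
        tumor = [r for r in sim.tumor_reads if r.start >= ws and r.reference_end <= we]
        normal = [r for r in sim.normal_reads if r.start >= ws and r.reference_end <= we]
        refw = sim.reference[ws:we]
        k = asm.select_k(refw)
        g = asm.build_graph(tumor, normal, refw, k)
        asm.clean_graph(g, 2, k)
        paths = asm.enumerate_paths(g)
        alt_window = refw[: spec.pos0 - ws] + spec.alt_allele + refw[spec.pos0 - ws + 1 :]
        assert sorted(p.contig for p in paths) == sorted([refw, alt_window])

    def test_combinatorial_graph_demoted(self):
        ref = simdata.make_reference(400, 12)
        reads = []
        # many independent double-seen errors create 2^b simple paths
        for b in range(9):
            pos = 30 + 40 * b
            alt = "A" if ref[pos] != "A" else "C"
            hap = ref[:pos] + alt + ref[pos + 1 :]
            reads += [_read(hap, name=f"e{b}x"), _read(hap, name=f"e{b}y")]
        reads += [_read(ref, name=f"r{i}") for i in range(4)]
        g = asm.build_graph(reads, [], ref, 11)
        asm.clean_graph(g)
        with pytest.raises(asm.TooManyPaths):
            asm.enumerate_paths(g, max_paths=16, hard_cap=64)
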