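"""POA MSA, variant extraction and normalization against independent oracles."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from somacall import simdata
from somacall.msa_variants import (
    CandidateVariant,
    PoaGraph,
    Scoring,
    _align_to_graph,
    call_from_msa,
    left_normalize,
    poa_msa,
)


def nw_affine(a: str, b: str, match=2, mismatch=-4, go=-4, ge=-2) -> int:
    """Scalar Needleman–Wunsch with affine gaps (cost go + ge*len); the
    independent oracle for pairwise POA scores."""
    NEG = -(10**9)
    m, n = len(a), len(b)
    H = [[NEG] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    H[0][0] = 0
    oc = go + ge
    for j in range(1, n + 1):
        E[0][j] = go + ge * j
    for i in range(1, m + 1):
        F[i][0] = go + ge * i
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(H[i - 1][j - 1], E[i - 1][j - 1], F[i - 1][j - 1]) + s
            E[i][j] = max(H[i][j - 1] + oc, F[i][j - 1] + oc, E[i][j - 1] + ge)
            F[i][j] = max(H[i - 1][j] + oc, E[i - 1][j] + oc, F[i - 1][j] + ge)
    return max(H[m][n], E[m][n], F[m][n])


def _linear_graph(seq: str) -> PoaGraph:
    g = PoaGraph()
    nodes = [g.add_node(c) for c in seq]
    for u, v in zip(nodes, nodes[1:]):
        g.add_edge(u, v)
    g.traversals.append(nodes)
    g.row_names.append("ref")
    return g


class TestPoaMsa:
    def test_identical_sequences_gap_free(self):
        msa = poa_msa(["ACGTAC", "ACGTAC"])
        assert msa.rows == ["ACGTAC", "ACGTAC"]

    def test_pairwise_score_equals_nw(self):
        random.seed(2)
        for _ in range(60):
            a = "".join(random.choice("ACGT") for _ in range(random.randint(1, 120)))
            b = "".join(random.choice("ACGT") for _ in range(random.randint(1, 120)))
            score, _ = _align_to_graph(_linear_graph(a), b, Scoring())
            assert score == nw_affine(a, b)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            poa_msa(["ACGT", ""])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.text(alphabet="ACGT", min_size=1, max_size=60), min_size=1, max_size=4))
    def test_degap_identity(self, seqs):
        msa = poa_msa(seqs)
        assert [r.replace("-", "") for r in msa.rows] == seqs
        assert len({len(r) for r in msa.rows}) == 1

    def test_ref_offsets_strictly_increase(self):
        msa = poa_msa(["ACGTACGT", "ACGACGTT", "ACTTACG"])
        offsets = [o for o in msa.col_to_ref_offset if o >= 0]
        assert offsets == sorted(set(offsets))


class TestCallFromMsa:
    def test_identical_rows_no_variants(self):
        msa = poa_msa(["ACGTA", "ACGTA"])
        assert call_from_msa(msa, "chr1", 0) == []

    def test_snv_coordinates(self):
        msa = poa_msa(["ACGTA", "ACCTA"])
        (v,) = call_from_msa(msa, "chr1", 100)
        assert (v.pos, v.ref_allele, v.alt_allele, v.vtype) == (103, "G", "C", "SNV")

    def test_deletion_anchoring(self):
        msa = poa_msa(["ACGTA", "ACTA"])
        (v,) = call_from_msa(msa, "chr1", 0)
        assert (v.pos, v.ref_allele, v.alt_allele, v.vtype) == (2, "CG", "C", "DEL")

    def test_shared_event_reported_once_with_sources(self):
        msa = poa_msa(["ACGTACGT", "ACCTACGT", "ACCTACGT"])
        (v,) = call_from_msa(msa, "chr1", 0)
        assert v.source_rows == ["hap1", "hap2"]


class TestLeftNormalize:
    def _apply(self, window, pos0, ref_a, alt_a):
        """Haplotype spelled by the edit; the normalization oracle."""
        return window[:pos0] + alt_a + window[pos0 + len(ref_a) :]

    def test_repeat_deletion_shifts_left(self):
        window = "CATATG"
        v = CandidateVariant("chr1", 3, "TAT", "T", "DEL", 2, (0, 0), None, ["hap1"])
        n = left_normalize(v, window, 0)
        assert (n.pos, n.ref_allele, n.alt_allele) == (1, "CAT", "C")
        assert self._apply(window, 2, "TAT", "T") == self._apply(window, 0, "CAT", "C")

    def test_snv_unchanged(self):
        window = "CATATG"
        v = CandidateVariant("chr1", 4, "A", "C", "SNV", 0, (0, 0), None, ["hap1"])
        n = left_normalize(v, window, 0)
        assert (n.pos, n.ref_allele, n.alt_allele) == (4, "A", "C")

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_normalization_preserves_haplotype_and_is_idempotent(self, data):
        rng = random.Random(data.draw(st.integers(0, 10**6)))
        unit = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 3)))
        window = (
            "".join(rng.choice("ACGT") for _ in range(8))
            + unit * rng.randint(2, 5)
            + "".join(rng.choice("ACGT") for _ in range(8))
        )
        pos0 = rng.randint(1, len(window) - 6)
        if rng.random() < 0.5:  # deletion of 1-4 bases
            size = rng.randint(1, min(4, len(window) - pos0 - 1))
            ref_a, alt_a = window[pos0 : pos0 + size + 1], window[pos0]
        else:  # insertion of 1-4 bases
            ins = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 4)))
            ref_a, alt_a = window[pos0], window[pos0] + ins
        v = CandidateVariant("chr1", pos0 + 1, ref_a, alt_a,
                             "DEL" if len(ref_a) > len(alt_a) else "INS",
                             abs(len(ref_a) - len(alt_a)), (0, 0), None, ["hap1"])
        n = left_normalize(v, window, 0)
        assert self._apply(window, v.pos - 1, v.ref_allele, v.alt_allele) == self._apply(
            window, n.pos - 1, n.ref_allele, n.alt_allele
        )
        again = left_normalize(n, window, 0)
        assert (again.pos, again.ref_allele, again.alt_allele) == (
            n.pos, n.ref_allele, n.alt_allele
        )

    def test_inconsistent_ref_allele_rejected(self):
        v = CandidateVariant("chr1", 2, "TTT", "T", "DEL", 2, (0, 0), None, ["hap1"])
        with pytest.raises(ValueError):
            left_normalize(v, "CATATG", 0)


class TestEndToEndDiscovery:
    @pytest.mark.parametrize("vtype,size", [("SNV", 1), ("INS", 6), ("DEL", 6), ("DEL", 70)])
    def test_implanted_variant_recovered(self, vtype, size):
        """assembly → POA → extraction emits exactly the implanted variant."""
        from tests.conftest import call_center_window

        seed = {"SNV": 31, "INS": 32, "DEL": 33}[vtype] + size
        length = 1400
        ref = simdata.make_reference(length, seed)
        mid = length // 2
        if vtype == "SNV":
            ref_a, alt_a = ref[mid], ("A" if ref[mid] != "A" else "C")
        elif vtype == "INS":
            ref_a = ref[mid]
            alt_a = ref[mid] + "".join(random.Random(seed).choice("ACGT") for _ in range(size))
        else:
            ref_a, alt_a = ref[mid : mid + size + 1], ref[mid]
        spec = simdata.VariantSpec(mid, ref_a, alt_a, "het", "somatic", 0.5)
        sim = simdata.simulate_pair(length=length, specs=[spec], error_rate=0.0, seed=seed)
        result = call_center_window(sim, genotype=False)
        assert result.reason is None
        from somacall.msa_variants import _normalize_offsets

        pos0, nref, nalt = _normalize_offsets(mid, ref_a, alt_a, ref)
        assert [(r.pos, r.ref_allele, r.alt_allele) for r in result.records] == [
            (pos0 + 1, nref, nalt)
        ]
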