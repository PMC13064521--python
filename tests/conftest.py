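"""Shared fixtures: synthetic references, read sets, and trained models."""

from __future__ import annotations

import numpy as np
import pytest

from somacall import simdata
from somacall.window_engine import CallerConfig, Window, call_window


@pytest.fixture(scope="session")
def periodic_fasta(tmp_path_factory):
    """Indexed FASTA with chr1 = 'ACGT' * 250 (1000 bp)."""
    path = tmp_path_factory.mktemp("ref") / "periodic.fa"
    simdata.write_fasta("ACGT" * 250, "chr1", str(path))
    return str(path)


@pytest.fixture(scope="session")
def snv_sim():
    """Error-free tumor/normal pair with one somatic het SNV at VAF 0.5."""
    length = 1400
    ref = simdata.make_reference(length, 3)
    base = ref[700]
    alt = "A" if base != "A" else "C"
    spec = simdata.VariantSpec(700, base, alt, "het", "somatic", 0.5)
    return simdata.simulate_pair(length=length, specs=[spec], error_rate=0.0, seed=3), spec


@pytest.fixture(scope="session")
def snv_bam_dir(tmp_path_factory, snv_sim):
    """On-disk BAMs + FASTA + truth VCF for the SNV scenario."""
    sim, spec = snv_sim
    d = tmp_path_factory.mktemp("snvsim")
    simdata.write_fasta(sim.reference, sim.chrom, str(d / "ref.fa"))
    simdata.write_bam(sim.tumor_reads, sim.chrom, len(sim.reference), str(d / "tumor.bam"))
    simdata.write_bam(sim.normal_reads, sim.chrom, len(sim.reference), str(d / "normal.bam"))
    simdata.write_truth_vcf([spec], sim.chrom, len(sim.reference), str(d / "truth.vcf"))
    return d


def call_center_window(sim, half=300, config=None, model=None, genotype=True):
    """Call the window centered on the simulated locus midpoint."""
    mid = len(sim.reference) // 2
    ws, we = mid - half, mid + half
    window = Window(sim.chrom, ws, we, 0)
    tumor = [r for r in sim.tumor_reads if r.start < we and r.reference_end > ws]
    normal = [r for r in sim.normal_reads if r.start < we and r.reference_end > ws]
    return call_window(
        window, tumor, normal, sim.reference[ws:we], config or CallerConfig(),
        model=model, genotype=genotype,
        ref_context=sim.reference[max(0, ws - 300) : we + 300],
    )


@pytest.fixture(scope="session")
def toy_model():
    """Separable toy: train labels are 1{x0 > 0.5} with 5% flips; the clean
    rule serves as held-out truth."""
    from somacall import somatic_model as sm

    rng = np.random.default_rng(1)
    n = 2000
    X = rng.random((n, 9))
    clean = (X[:, 0] > 0.5).astype(int)
    y = clean.copy()
    flip = rng.random(n) < 0.05
    y[flip] = 1 - y[flip]
    model = sm.train(X, y, rounds=100, seed=1,
                     feature_names=[f"f{i}" for i in range(9)])
    held_X = rng.random((1500, 9))
    held_y = (held_X[:, 0] > 0.5).astype(int)
    return model, np.vstack([X, held_X]), np.r_[clean, held_y]
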