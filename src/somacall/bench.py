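"""Synthetic end-to-end harness: labeled candidates and a default model.

Runs the caller over simulated tumor/normal windows — somatic windows for
positives, germline and error-only windows for negatives — and turns the
discovered candidates into labeled feature rows for training the somatic
scoring model.  Everything is seeded; sub-seeds stay below 2**31.
"""

from __future__ import annotations

import numpy as np

from . import simdata
from . import somatic_model as sm
from .window_engine import CallerConfig, Window, call_window

__all__ = [
    "simulate_window_call",
    "labeled_candidates",
    "train_default_model",
]

_WINDOW = 600
_FLANK = 400  # simulated sequence beyond the called window on each side


def _random_variant(rng: np.random.Generator, reference: str, pos0: int,
                    origin: str, vaf: float) -> simdata.VariantSpec:
    kind = rng.choice(["SNV", "INS", "DEL"])
    if kind == "SNV":
        ref_a = reference[pos0]
        alt_a = str(rng.choice([b for b in "ACGT" if b != ref_a]))
    elif kind == "INS":
        size = int(rng.integers(1, 11))
        ins = "".join("ACGT"[i] for i in rng.integers(0, 4, size))
        ref_a = reference[pos0]
        alt_a = ref_a + ins
    else:
        size = int(rng.integers(1, 11))
        ref_a = reference[pos0 : pos0 + size + 1]
        alt_a = reference[pos0]
    zyg = "het" if origin == "germline" else "het"
    return simdata.VariantSpec(pos0, ref_a, alt_a, zyg, origin, vaf)


def simulate_window_call(
    seed: int,
    kind: str = "somatic",  # somatic | germline | clean
    vaf: float = 0.5,
    error_rate: float = 0.001,
    config: CallerConfig | None = None,
    model=None,
    genotype: bool = True,
    spec: simdata.VariantSpec | None = None,
    tumor_coverage: float = 80.0,
    normal_coverage: float = 60.0,
):
    """Simulate one locus and call its central window.

    Returns (WindowResult, specs).  ``spec`` overrides the randomly drawn
    variant; kind="clean" implants nothing.
    """
    length = _WINDOW + 2 * _FLANK
    reference = simdata.make_reference(length, seed)
    rng = np.random.default_rng((seed + 10_000) % 2**31)
    specs: list[simdata.VariantSpec] = []
    if spec is not None:
        specs = [spec]
    elif kind != "clean":
        pos0 = int(rng.integers(_FLANK + 100, _FLANK + _WINDOW - 100))
        specs = [_random_variant(rng, reference, pos0, kind, vaf)]
    sim = simdata.simulate_pair(
        length=length, specs=specs, error_rate=error_rate, seed=seed,
        tumor_coverage=tumor_coverage, normal_coverage=normal_coverage,
    )
    ws, we = _FLANK, _FLANK + _WINDOW
    window = Window(sim.chrom, ws, we, 0)
    tumor = [r for r in sim.tumor_reads if r.start < we and r.reference_end > ws]
    normal = [r for r in sim.normal_reads if r.start < we and r.reference_end > ws]
    result = call_window(
        window, tumor, normal, reference[ws:we], config or CallerConfig(),
        model=model, genotype=genotype,
        ref_context=reference[max(0, ws - 300) : we + 300],
    )
    return result, specs, reference


def _truth_keys(specs, reference, chrom="chr1"):
    from .msa_variants import _normalize_offsets

    keys = set()
    for s in specs:
        pos0, ref_a, alt_a = _normalize_offsets(s.pos0, s.ref_allele, s.alt_allele, reference)
        keys.add((chrom, pos0 + 1, ref_a, alt_a))
    return keys


def labeled_candidates(
    seed: int,
    n_somatic: int = 30,
    n_germline: int = 20,
    n_clean: int = 20,
    error_rate: float = 0.001,
    config: CallerConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix + binary labels from simulated caller runs.

    Candidates matching an implanted somatic variant (normalized exact
    match) are positives; germline hits, sequencing-error artifacts and any
    other discovery are negatives.
    """
    rows: list[np.ndarray] = []
    labels: list[int] = []
    sub = 0
    for kind, count in (("somatic", n_somatic), ("germline", n_germline), ("clean", n_clean)):
        for i in range(count):
            sub += 1
            vaf = [0.5, 0.25][i % 2] if kind == "somatic" else 0.5
            result, specs, reference = simulate_window_call(
                (seed * 1000 + sub) % 2**31, kind=kind, vaf=vaf,
                error_rate=error_rate, config=config,
            )
            somatic_keys = _truth_keys(
                [s for s in specs if s.origin == "somatic"], reference
            )
            for variant, support in result.candidates:
                rows.append(sm.extract_features(variant, support, result.stats))
                labels.append(1 if variant.key() in somatic_keys else 0)
    return np.array(rows), np.array(labels)


def train_default_model(
    seed: int = 1,
    rounds: int = 150,
    neg_per_pos: int = 30,
    **kwargs,
) -> sm.EbmModel:
    """Train the somatic scoring model on the synthetic labeled cohort."""
    X, y = labeled_candidates(seed, **kwargs)
    keep = sm.undersample(y, neg_per_pos=neg_per_pos, seed=seed)
    return sm.train(X[keep], y[keep], rounds=rounds, seed=seed)
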