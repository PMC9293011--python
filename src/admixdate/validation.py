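"""Reproducible simulation-and-dating experiments at the package's study scale.

These helpers wire the simulator to the dating pipeline under one fixed set
of study conditions: two Balding–Nichols source panels at FST 0.15 (roughly
the west African / European contrast), 50,000 markers on 22 uniform
chromosomes totalling ~35 Morgans, 10 admixed diploids with 20% ancestry
from source 1, and reference panels of 30 diploids per source built from
haplotypes *disjoint* from those used to construct the targets (so the
references are surrogates, not the construction panels).

The copying-panel size scales with the admixture time: each haploid
chromosome consumes about ``1 + (t+1) * L`` haplotypes without replacement,
so the panel holds 1.5x that (and never fewer than ``2n + 4``).

All randomness is driven by a single integer seed via
``numpy.random.SeedSequence``, so every replicate is reproducible.
"""

from __future__ import annotations

import math

import numpy as np

from .dating import DatingResult, date_admixture
from .io import compute_allele_frequencies
from .simulate import (
    AdmixtureSpec,
    SourcePanel,
    TruthTrack,
    make_source_panels,
    mask_missing,
    panel_to_genotype_matrix,
    pseudo_haploidize,
    simulate_admixed,
    split_panel,
)

#: study conditions (fixed; see docs/methods.md)
N_SNPS = 50_000
N_CHROMS = 22
CHROM_LENGTH = 35.0 / 22  # Morgans; ~35 M total, the human autosomal scale
FST = 0.15
ALPHA = 0.2
N_IND = 10
N_REF_DIP = 30


def _child_seeds(seed: int, n: int) -> list[int]:
    """n reproducible sub-seeds (< 2^31) from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


def build_panel_size(t: int, n_ind: int, chrom_length: float = CHROM_LENGTH) -> int:
    """Copying-panel size covering the without-replacement draws at time t.

    A haploid chromosome consumes one haplotype per copying segment; the
    segment count is at most Poisson with mean ``N = 1 + (t+1) * L``, so a
    pool of ``N + 8 sqrt(N) + 10`` keeps the exhaustion probability
    negligible across tens of thousands of chromosome replicates.
    """
    n = 1.0 + (t + 1) * chrom_length
    return max(2 * n_ind + 4, int(math.ceil(n + 8.0 * math.sqrt(n) + 10.0)))


def simulate_and_date(
    t: int,
    seed: int,
    alpha: float = ALPHA,
    n_ind: int = N_IND,
    n_snps: int = N_SNPS,
    n_chroms: int = N_CHROMS,
    chrom_length: float = CHROM_LENGTH,
    fst: float = FST,
    n_ref_dip: int = N_REF_DIP,
    pseudo_haploid: bool = False,
    missing: float = 0.0,
    use_fft: bool = True,
    pooling: str = "pooled",
) -> tuple[DatingResult, TruthTrack]:
    """One full replicate: panels -> admixed diploids -> dated against
    disjoint reference haplotypes.  Returns the pipeline result and the
    ground-truth ancestry track."""
    s_panel, s_admix, s_ph, s_miss = _child_seeds(seed, 4)
    n_build = build_panel_size(t, n_ind, chrom_length)
    p1, p2 = make_source_panels(
        n_snps, n_build + 2 * n_ref_dip, fst, [chrom_length] * n_chroms, seed=s_panel
    )
    build1, ref1 = split_panel(p1, n_build)
    build2, ref2 = split_panel(p2, n_build)
    spec = AdmixtureSpec(alpha=alpha, t=t, n_individuals=n_ind, seed=s_admix)
    gm, truth = simulate_admixed(build1, build2, spec)
    if pseudo_haploid:
        gm = pseudo_haploidize(gm, seed=s_ph)
    if missing > 0.0:
        gm = mask_missing(gm, missing, seed=s_miss)
    freq_a = compute_allele_frequencies(panel_to_genotype_matrix(ref1, "RefA"))
    freq_b = compute_allele_frequencies(panel_to_genotype_matrix(ref2, "RefB"))
    result = date_admixture(gm, freq_a, freq_b, use_fft=use_fft, pooling=pooling)
    return result, truth


def null_replicate(
    seed: int,
    n_ind: int = N_IND,
    n_snps: int = N_SNPS,
    n_chroms: int = N_CHROMS,
    chrom_length: float = CHROM_LENGTH,
    fst: float = FST,
    n_ref_dip: int = N_REF_DIP,
) -> DatingResult:
    """Date a target drawn wholly from source 1 (no admixture).

    The target diploids pair source-1 haplotypes disjoint from the reference
    haplotypes; a correctly calibrated significance gate should rarely fire.
    """
    (s_panel,) = _child_seeds(seed, 1)
    n_target_haps = 2 * n_ind
    p1, p2 = make_source_panels(
        n_snps, n_target_haps + 2 * n_ref_dip, fst, [chrom_length] * n_chroms, seed=s_panel
    )
    tgt_haps, ref1 = split_panel(p1, n_target_haps)
    _, ref2 = split_panel(p2, n_target_haps)
    target = panel_to_genotype_matrix(
        SourcePanel(tgt_haps.haplotypes, p1.snp, "null_target"), "Target"
    )
    freq_a = compute_allele_frequencies(panel_to_genotype_matrix(ref1, "RefA"))
    freq_b = compute_allele_frequencies(panel_to_genotype_matrix(ref2, "RefB"))
    return date_admixture(target, freq_a, freq_b)


def coverage(results: list[DatingResult], truth: float, n_se: float = 2.0) -> float:
    """Fraction of replicates whose jackknife +/- n_se interval covers the truth."""
    hits = [
        abs(r.estimate.t_gen_jack_mean - truth) <= n_se * r.estimate.se_gen
        for r in results
    ]
    return float(np.mean(hits))
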