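import numpy as np
import pandas as pd
import pytest

import admixdate as ad
from admixdate.io import SNP_COLUMNS


def make_panel(freq, count=None, label=""):
    """AlleleFrequencyPanel from a frequency vector (nan = unavailable)."""
    freq = np.asarray(freq, dtype=np.float64)
    available = np.isfinite(freq)
    if count is None:
        count = np.where(available, 20, 0)
    return ad.AlleleFrequencyPanel(
        freq=freq, count=np.asarray(count, dtype=np.int64), available=available, label=label
    )


def make_track(k, valid=None):
    """AncestryWeightTrack from a (n_ind, n_snp) K matrix."""
    k = np.atleast_2d(np.asarray(k, dtype=np.float64))
    if valid is None:
        valid = np.ones(k.shape, dtype=bool)
    kmasked = np.where(valid, k, 0.0)
    kbar = kmasked.sum(axis=1) / np.maximum(valid.sum(axis=1), 1)
    return ad.AncestryWeightTrack(
        k=kmasked, valid=valid, kbar=kbar, alpha=np.full(k.shape[0], 0.5)
    )


def make_snp_table(chrom_positions):
    """SNP table from {chrom_label: positions in Morgans}."""
    rows = []
    for chrom, pos in chrom_positions.items():
        for i, g in enumerate(pos):
            rows.append((f"snp_{chrom}_{i}", str(chrom), float(g), i + 1, "A", "G"))
    return pd.DataFrame(rows, columns=SNP_COLUMNS)


@pytest.fixture(scope="session")
def small_sim():
    """One small but realistic simulated dataset shared by integration tests.

    12,000 markers on 4 chromosomes of 1 Morgan, 30% ancestry from source 1
    admixed 20 generations ago in 5 diploids; references built from
    haplotypes disjoint from the copying panels.
    """
    p1, p2 = ad.make_source_panels(12000, 130, 0.15, [1.0] * 4, seed=42)
    build1, ref1 = ad.split_panel(p1, 80)
    build2, ref2 = ad.split_panel(p2, 80)
    spec = ad.AdmixtureSpec(alpha=0.3, t=20, n_individuals=5, seed=43)
    gm, truth = ad.simulate_admixed(build1, build2, spec)
    freq_a = ad.compute_allele_frequencies(ad.panel_to_genotype_matrix(ref1, "RefA"))
    freq_b = ad.compute_allele_frequencies(ad.panel_to_genotype_matrix(ref2, "RefB"))
    return {
        "gm": gm,
        "truth": truth,
        "freq_a": freq_a,
        "freq_b": freq_b,
        "t": 20,
        "alpha": 0.3,
    }
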