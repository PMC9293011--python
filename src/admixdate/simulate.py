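"""Haplotype-copying admixture simulator with synthetic source panels.

Admixed haploid chromosomes are built by walking along the marker grid and
copying stretches of real (here: synthetic) source haplotypes.  At the start
of each chromosome a haplotype is drawn from ``source_1`` with probability
``alpha`` and from ``source_2`` otherwise.  Between neighbouring markers
separated by ``g`` Morgans a recombination event occurs with probability
``1 - exp(-lambda g)`` where ``lambda = t + 1`` generations (the +1 because
mosaic chromosomes only start forming one generation after the mixture).  On
recombination the ancestry is redrawn — a switch to the same ancestry is
allowed — and a fresh haplotype is taken from that source's pool *without
replacement*; pools are replenished at the start of every chromosome.
Pairs of haploids are merged at random into diploid individuals.

Source panels are Balding–Nichols draws: a shared ancestral frequency per
marker (uniform on [0.05, 0.95]) and per-population frequencies from a Beta
distribution with divergence parameter ``fst``.  This reproduces the
frequency differentiation the dating statistic needs; the linkage structure
of admixture is induced entirely by the copying process.

Ancient-DNA degradation is modelled by two transforms: pseudo-haploidisation
(replace each het by a randomly sampled homozygote) and random missingness.
All outputs are deterministic given (inputs, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SimulationError
from .io import MISSING, GenotypeMatrix, SNP_COLUMNS

__all__ = [
    "SourcePanel",
    "AdmixtureSpec",
    "TruthTrack",
    "make_source_panels",
    "simulate_admixed",
    "simulate_multiway",
    "pseudo_haploidize",
    "mask_missing",
    "split_panel",
    "panel_to_genotype_matrix",
]


@dataclass
class SourcePanel:
    """Phased binary haplotypes for one source population.

    ``ancestry`` is only present for intermediate (already admixed) pools in
    multi-way simulations: it records, per haplotype and marker, which
    original source the allele was copied from.
    """

    haplotypes: np.ndarray  # (n_haps, n_snp) uint8 in {0, 1}
    snp: pd.DataFrame  # shared marker table (io.SNP_COLUMNS)
    label: str
    ancestry: np.ndarray | None = None  # (n_haps, n_snp) int8, optional

    @property
    def n_haps(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_snp(self) -> int:
        return self.haplotypes.shape[1]


@dataclass
class AdmixtureSpec:
    """Parameters of one instantaneous admixture pulse.

    ``alpha`` is the fraction contributed by ``source_1`` (the first panel
    argument); the copying process runs at rate ``lambda = t + 1``.  The
    boundary values 0 and 1 are allowed and yield an unadmixed mosaic of a
    single source (useful for null simulations); the dating pipeline itself
    needs a genuinely admixed target.
    """

    alpha: float
    t: int
    n_individuals: int
    seed: int

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise SimulationError(f"alpha must lie in [0, 1], got {self.alpha}")
        if int(self.t) != self.t or self.t < 1:
            raise SimulationError(f"t must be an integer >= 1, got {self.t}")
        if self.n_individuals < 1:
            raise SimulationError("n_individuals must be >= 1")

    @property
    def lambda_sim(self) -> float:
        return float(self.t + 1)


@dataclass
class TruthTrack:
    """Ground-truth ancestry segments per haploid chromosome.

    ``segments[h][chrom]`` is a list of ``(start, end, label_id)`` tuples in
    Morgans tiling ``[first marker, last marker]`` of that chromosome;
    boundaries fall on recombination draws (and on inherited boundaries from
    earlier pulses in multi-way runs).  ``labels`` maps label ids to panel
    labels.
    """

    segments: list[dict[str, list[tuple[float, float, int]]]]
    labels: list[str]

    def ancestry_fraction(self, label: str | int) -> float:
        """Genome-wide length fraction assigned to one source, over all haploids."""
        lid = label if isinstance(label, int) else self.labels.index(label)
        tot = 0.0
        hit = 0.0
        for per_chrom in self.segments:
            for segs in per_chrom.values():
                for s, e, l in segs:
                    tot += e - s
                    if l == lid:
                        hit += e - s
        return hit / tot if tot > 0 else float("nan")

    def mean_tract_length(self, label: str | int | None = None) -> float:
        """Mean segment length (Morgans), optionally for one source only."""
        lid = None
        if label is not None:
            lid = label if isinstance(label, int) else self.labels.index(label)
        lens = [
            e - s
            for per_chrom in self.segments
            for segs in per_chrom.values()
            for s, e, l in segs
            if lid is None or l == lid
        ]
        return float(np.mean(lens)) if lens else float("nan")

    def to_text(self, path) -> None:
        """BED-like text: positions are genetic (cM), not physical bp."""
        with open(path, "w") as fh:
            fh.write("# ancestry truth track; start/end are genetic positions in cM\n")
            fh.write("# haploid\tchrom\tstart_cM\tend_cM\tsource_label\n")
            for h, per_chrom in enumerate(self.segments):
                for chrom, segs in per_chrom.items():
                    for s, e, l in segs:
                        fh.write(
                            f"{h}\t{chrom}\t{100 * s:.6f}\t{100 * e:.6f}\t{self.labels[l]}\n"
                        )


# ---------------------------------------------------------------------------
# source panels


def make_source_panels(
    n_snps: int,
    n_haps: int,
    fst: float,
    chrom_lengths: list[float],
    seed: int,
    n_panels: int = 2,
) -> tuple[SourcePanel, ...]:
    """Balding–Nichols source panels over a shared random marker map.

    Markers are apportioned to chromosomes proportionally to genetic length
    and placed uniformly; ancestral frequencies are uniform on [0.05, 0.95];
    each panel's frequencies are Beta(p(1-F)/F, (1-p)(1-F)/F) draws with
    F = ``fst``; haplotype alleles are independent Bernoulli draws.
    """
    if not (0.0 < fst < 1.0):
        raise SimulationError(f"fst must lie in (0, 1), got {fst}")
    rng = np.random.default_rng(seed)
    snp = _random_marker_map(n_snps, chrom_lengths, rng)
    p_anc = rng.uniform(0.05, 0.95, size=n_snps)
    shape = (1.0 - fst) / fst
    panels = []
    for k in range(n_panels):
        p_pop = rng.beta(p_anc * shape, (1.0 - p_anc) * shape)
        haps = (rng.random((n_haps, n_snps)) < p_pop[None, :]).astype(np.uint8)
        panels.append(SourcePanel(haplotypes=haps, snp=snp, label=f"source_{k + 1}"))
    return tuple(panels)


def _random_marker_map(n_snps: int, chrom_lengths: list[float], rng) -> pd.DataFrame:
    lengths = np.asarray(chrom_lengths, dtype=np.float64)
    if len(lengths) == 0 or (lengths <= 0).any():
        raise SimulationError("chromosome lengths must be positive")
    # largest-remainder apportionment of markers to chromosomes
    quota = n_snps * lengths / lengths.sum()
    alloc = np.floor(quota).astype(int)
    rem = n_snps - alloc.sum()
    alloc[np.argsort(quota - np.floor(quota))[::-1][:rem]] += 1
    rows = []
    for c, (n_c, length) in enumerate(zip(alloc, lengths), start=1):
        pos = np.sort(rng.uniform(0.0, length, size=n_c))
        for i, g in enumerate(pos):
            rows.append((f"snp_{c}_{i}", str(c), g, int(round(g * 1e8)) + 1, "A", "G"))
    return pd.DataFrame(rows, columns=SNP_COLUMNS)


def split_panel(panel: SourcePanel, n_first: int) -> tuple[SourcePanel, SourcePanel]:
    """Split a panel's haplotypes into two disjoint panels (build vs reference)."""
    if not (0 < n_first < panel.n_haps):
        raise SimulationError("split point must fall inside the panel")
    a = SourcePanel(panel.haplotypes[:n_first], panel.snp, panel.label)
    b = SourcePanel(panel.haplotypes[n_first:], panel.snp, panel.label)
    return a, b


def panel_to_genotype_matrix(
    panel: SourcePanel, group: str, id_prefix: str = ""
) -> GenotypeMatrix:
    """Pair consecutive haplotypes into diploid individuals (reference data)."""
    n_dip = panel.n_haps // 2
    calls = (panel.haplotypes[0 : 2 * n_dip : 2] + panel.haplotypes[1 : 2 * n_dip : 2]).astype(
        np.int8
    )
    prefix = id_prefix or group
    ind = pd.DataFrame(
        {
            "ind_id": [f"{prefix}{i}" for i in range(n_dip)],
            "sex": ["U"] * n_dip,
            "group": [group] * n_dip,
        }
    )
    return GenotypeMatrix(ind=ind, snp=panel.snp, calls=calls, ploidy_mode="diploid").validate()


# ---------------------------------------------------------------------------
# haplotype copying


class _Pool:
    """Without-replacement haplotype pool, refilled per chromosome."""

    def __init__(self, n_haps: int, rng, label: str):
        self.n_haps = n_haps
        self.rng = rng
        self.label = label
        self.order = None
        self.ptr = 0

    def refill(self):
        self.order = self.rng.permutation(self.n_haps)
        self.ptr = 0

    def draw(self) -> int:
        if self.ptr >= self.n_haps:
            raise SimulationError(
                f"haplotype pool for {self.label} exhausted mid-chromosome; "
                "simulate with larger source panels (pool must cover ~1 + lambda*L "
                "draws per chromosome)"
            )
        h = int(self.order[self.ptr])
        self.ptr += 1
        return h


def _chrom_ranges(snp: pd.DataFrame) -> list[tuple[str, int, int]]:
    chrom = snp["chrom"].to_numpy()
    ranges = []
    start = 0
    for i in range(1, len(chrom) + 1):
        if i == len(chrom) or chrom[i] != chrom[start]:
            ranges.append((chrom[start], start, i))
            start = i
    return ranges


def _simulate_haploids(
    p1: SourcePanel,
    p2: SourcePanel,
    lam: float,
    alpha: float,
    n_haploids: int,
    rng,
    label_ids: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray, list[dict]]:
    """Copy ``n_haploids`` mosaic haploid genomes from two source panels.

    Returns (haplotypes, per-marker ancestry labels, truth segments).  When a
    source panel is itself an admixed pool (has an ``ancestry`` matrix), the
    copied stretches inherit its marker-level labels and the truth segments
    are split on the inherited boundaries.
    """
    n_snp = p1.n_snp
    if p2.n_snp != n_snp:
        raise SimulationError("source panels must share one marker table")
    need = n_haploids + 1
    for p in (p1, p2):
        if p.n_haps < need:
            raise SimulationError(
                f"panel {p.label} has {p.n_haps} haplotypes; need more than "
                f"{n_haploids} to build {n_haploids} haploid genomes"
            )
    gpos = p1.snp["gpos"].to_numpy()
    ranges = _chrom_ranges(p1.snp)
    haps = np.empty((n_haploids, n_snp), dtype=np.uint8)
    labs = np.empty((n_haploids, n_snp), dtype=np.int8)
    segments: list[dict] = []
    sources = (p1, p2)
    for h in range(n_haploids):
        per_chrom: dict[str, list[tuple[float, float, int]]] = {}
        pools = (
            _Pool(p1.n_haps, rng, p1.label),
            _Pool(p2.n_haps, rng, p2.label),
        )
        for chrom, lo_i, hi_i in ranges:
            pools[0].refill()
            pools[1].refill()
            pos = gpos[lo_i:hi_i]
            m = hi_i - lo_i
            gaps = np.diff(pos)
            rec = rng.random(m - 1) < -np.expm1(-lam * gaps)
            starts = np.concatenate(([0], np.flatnonzero(rec) + 1))
            ends = np.concatenate((starts[1:], [m]))
            # redraw ancestry at the chromosome start and at every recombination
            from_s1 = rng.random(len(starts)) < alpha
            segs: list[tuple[float, float, int]] = []
            for s, e, is_s1 in zip(starts, ends, from_s1):
                src = 0 if is_s1 else 1
                panel = sources[src]
                hidx = pools[src].draw()
                sl = slice(lo_i + s, lo_i + e)
                haps[h, sl] = panel.haplotypes[hidx, sl]
                seg_start = pos[s]
                seg_end = pos[e - 1] if e == m else pos[e]
                if panel.ancestry is not None:
                    lab_sub = panel.ancestry[hidx, sl]
                    labs[h, sl] = lab_sub
                    segs.extend(_split_segment(pos, s, e, m, lab_sub))
                else:
                    labs[h, sl] = label_ids[src]
                    segs.append((seg_start, seg_end, label_ids[src]))
            per_chrom[chrom] = segs
        segments.append(per_chrom)
    return haps, labs, segments


def _split_segment(pos, s, e, m, lab_sub) -> list[tuple[float, float, int]]:
    """Split a copied stretch on inherited ancestry-label changes."""
    breaks = np.flatnonzero(np.diff(lab_sub)) + 1
    bounds = np.concatenate(([0], breaks, [e - s]))
    out = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        start = pos[s + a]
        end = pos[s + b - 1] if s + b == m else pos[s + b]
        out.append((start, end, int(lab_sub[a])))
    return out


def _pair_haploids(
    haps: np.ndarray, snp: pd.DataFrame, rng, group: str = "Admixed"
) -> GenotypeMatrix:
    n_hap = haps.shape[0]
    perm = rng.permutation(n_hap)
    calls = (haps[perm[0::2]] + haps[perm[1::2]]).astype(np.int8)
    n_dip = n_hap // 2
    ind = pd.DataFrame(
        {
            "ind_id": [f"admix{i}" for i in range(n_dip)],
            "sex": ["U"] * n_dip,
            "group": [group] * n_dip,
        }
    )
    return GenotypeMatrix(ind=ind, snp=snp, calls=calls, ploidy_mode="diploid").validate()


def simulate_admixed(
    p1: SourcePanel, p2: SourcePanel, spec: AdmixtureSpec
) -> tuple[GenotypeMatrix, TruthTrack]:
    """Simulate ``spec.n_individuals`` admixed diploids from two source panels.

    ``spec.alpha`` is the expected ancestry fraction from ``p1``.  Requires
    more than ``2 n_individuals`` haplotypes per panel.
    """
    rng = np.random.default_rng(spec.seed)
    haps, _, segments = _simulate_haploids(
        p1, p2, spec.lambda_sim, spec.alpha, 2 * spec.n_individuals, rng, (0, 1)
    )
    gm = _pair_haploids(haps, p1.snp, rng)
    truth = TruthTrack(segments=segments, labels=[p1.label, p2.label])
    return gm, truth


def simulate_multiway(
    panels: list[SourcePanel], events: list[AdmixtureSpec]
) -> tuple[GenotypeMatrix, TruthTrack]:
    """Iterated pulses: the admixed pool of each event seeds the next one.

    ``events`` are ordered oldest first.  Event 1 mixes ``panels[0]`` and
    ``panels[1]``; event k >= 2 mixes the pool produced by event k-1
    (``source_1``, contributing fraction ``alpha``) with ``panels[k]``.
    Truth labels refer to the original panels throughout.
    """
    if len(panels) < 2 or len(events) != len(panels) - 1:
        raise SimulationError("need k+1 panels for k admixture events")
    labels = [p.label for p in panels]
    current = panels[0]
    current_ids = (0, 1)
    for k, ev in enumerate(events):
        rng = np.random.default_rng(ev.seed)
        other = panels[k + 1]
        last = k == len(events) - 1
        n_haploids = 2 * ev.n_individuals
        haps, labs, segments = _simulate_haploids(
            current, other, ev.lambda_sim, ev.alpha, n_haploids, rng, current_ids
        )
        if last:
            gm = _pair_haploids(haps, current.snp, rng)
            return gm, TruthTrack(segments=segments, labels=labels)
        current = SourcePanel(
            haplotypes=haps, snp=current.snp, label=f"admixed_{k + 1}", ancestry=labs
        )
        current_ids = (0, k + 2)  # first id unused when ancestry matrix present
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# ancient-DNA degradation transforms


def pseudo_haploidize(gm: GenotypeMatrix, seed: int) -> GenotypeMatrix:
    """Replace every heterozygous call by 0 or 2 with probability 1/2 each."""
    if gm.ploidy_mode != "diploid":
        raise SimulationError("pseudo_haploidize expects diploid input")
    rng = np.random.default_rng(seed)
    calls = gm.calls.copy()
    het = calls == 1
    calls[het] = np.where(rng.random(int(het.sum())) < 0.5, 0, 2).astype(np.int8)
    return GenotypeMatrix(
        ind=gm.ind, snp=gm.snp, calls=calls, ploidy_mode="pseudo_haploid"
    ).validate()


def mask_missing(gm: GenotypeMatrix, rate: float, seed: int) -> GenotypeMatrix:
    """Independently set each non-missing call to missing with probability ``rate``."""
    if not (0.0 <= rate < 1.0):
        raise SimulationError(f"missing rate must lie in [0, 1), got {rate}")
    rng = np.random.default_rng(seed)
    calls = gm.calls.copy()
    hit = (calls != MISSING) & (rng.random(calls.shape) < rate)
    calls[hit] = MISSING
    return GenotypeMatrix(
        ind=gm.ind, snp=gm.snp, calls=calls, ploidy_mode=gm.ploidy_mode
    ).validate()
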