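"""Admixture dating from ancestry covariance in single diploid genomes.

The statistic works marker by marker. For an admixed individual with
ancestry fractions ``alpha`` (source A) and ``beta = 1 - alpha`` (source B),
the probability of the observed genotype ``g`` under each source is

    a = P(g | A),   b = P(g | B)      (binomial in the panel frequency),

and the per-site likelihood is ``L = alpha*a + beta*b``.  The ancestry
weight ``K = (a - b) / L`` is positive where source A explains the genotype
better and negative where source B does.  After a single pulse of admixture
``t`` generations before the individual lived, the covariance of ``K``
between marker pairs at genetic distance ``d`` Morgans decays as
``exp(-(t+1) d)``: recombination only starts shuffling ancestry in the
generation after the mixture, hence the ``+1``.

The pipeline is: estimate ``alpha`` by least squares on genotype dosages,
build the weight track, bin the pairwise covariance ``A(d)`` by distance
(naive O(m^2) or FFT-autocorrelation path), fit ``y = A exp(-lambda d) + c``
by profiled least squares over a deterministic lambda grid, and attach
leave-one-chromosome-out weighted-jackknife errors.  Everything here is
deterministic; randomness lives in :mod:`admixdate.simulate`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EstimationError, FitError, InvariantError, JackknifeError
from .io import MISSING, AlleleFrequencyPanel, GenotypeMatrix

logger = logging.getLogger(__name__)

#: frequency clamp replacing division-by-zero handling at monomorphic markers
FREQ_EPS = 1e-4
#: clamp for the estimated ancestry fraction
ALPHA_EPS = 1e-4

DEFAULT_BINSIZE = 0.001  # Morgans (0.1 cM)
DEFAULT_MAXDIS = 1.0  # Morgans
DEFAULT_LO = 0.0045  # Morgans (0.45 cM)
DEFAULT_HI = 1.0  # Morgans
DEFAULT_GENERATION_TIME = 28.0  # years

LAMBDA_GRID_LO = 0.5
LAMBDA_GRID_HI = 500.0
LAMBDA_GRID_STEP = 1.02
SIG_Z = 2.0
SIG_LAMBDA = 200.0
SIG_NRMSD = 0.7


# ---------------------------------------------------------------------------
# mixture proportion


@dataclass
class MixtureEstimate:
    """Genome-wide ancestry fraction from reference A, clamped to (0, 1)."""

    alpha: float
    n_markers_used: int

    @property
    def beta(self) -> float:
        return 1.0 - self.alpha


def estimate_mixture_proportion(
    target_calls: np.ndarray,
    ref_a: AlleleFrequencyPanel,
    ref_b: AlleleFrequencyPanel,
    min_markers: int = 100,
) -> MixtureEstimate:
    """Least-squares ancestry fraction for one individual's genotype vector.

    Minimises ``sum_i (g_i/2 - [alpha p_Ai + (1-alpha) p_Bi])^2`` over markers
    where the target call is non-missing and both panels are available.
    Markers with ``p_A == p_B`` contribute nothing to the slope but are
    retained.  The minimiser is clamped to ``[1e-4, 1 - 1e-4]``.
    """
    target_calls = np.asarray(target_calls)
    usable = (target_calls != MISSING) & ref_a.available & ref_b.available
    n = int(usable.sum())
    if n < min_markers:
        raise EstimationError(
            f"only {n} usable markers for mixture regression (need >= {min_markers})"
        )
    dose = target_calls[usable] / 2.0
    pa = ref_a.freq[usable]
    pb = ref_b.freq[usable]
    diff = pa - pb
    denom = float(diff @ diff)
    if denom == 0.0:
        raise EstimationError("references indistinguishable (p_A == p_B at every marker)")
    alpha = float((dose - pb) @ diff) / denom
    alpha = min(max(alpha, ALPHA_EPS), 1.0 - ALPHA_EPS)
    return MixtureEstimate(alpha=alpha, n_markers_used=n)


# ---------------------------------------------------------------------------
# per-site genotype probabilities and ancestry weights


def site_probabilities(
    g: np.ndarray | int,
    p_a: np.ndarray | float,
    p_b: np.ndarray | float,
    ploidy_mode: str = "diploid",
) -> tuple[np.ndarray, np.ndarray]:
    """P(g | A) and P(g | B) with panel frequencies clamped into [1e-4, 1-1e-4].

    Diploid genotypes are binomial draws of two alleles; pseudo-haploid calls
    (0 or 2) are a single sampled allele.  Missing calls (9) yield ``nan``:
    the site is invalid, not an error.
    """
    g = np.asarray(g)
    a = _genotype_prob(g, np.clip(p_a, FREQ_EPS, 1.0 - FREQ_EPS), ploidy_mode)
    b = _genotype_prob(g, np.clip(p_b, FREQ_EPS, 1.0 - FREQ_EPS), ploidy_mode)
    return a, b


def _genotype_prob(g: np.ndarray, p, ploidy_mode: str) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if ploidy_mode == "diploid":
        out = np.select(
            [g == 0, g == 1, g == 2],
            [(1.0 - p) ** 2, 2.0 * p * (1.0 - p), p**2],
            default=np.nan,
        )
    elif ploidy_mode == "pseudo_haploid":
        out = np.select([g == 0, g == 2], [1.0 - p, p], default=np.nan)
    else:
        raise InvariantError(f"unknown ploidy_mode {ploidy_mode!r}")
    return out


@dataclass
class AncestryWeightTrack:
    """Per-individual, per-marker ancestry weights K with validity mask.

    ``k`` is zero where invalid; ``kbar`` is the per-individual genome-wide
    mean of valid K (the centering constant of the covariance).
    """

    k: np.ndarray  # (n_ind, n_snp) float64
    valid: np.ndarray  # (n_ind, n_snp) bool
    kbar: np.ndarray  # (n_ind,)
    alpha: np.ndarray  # (n_ind,)

    @property
    def n_ind(self) -> int:
        return self.k.shape[0]


def ancestry_weights(
    gm: GenotypeMatrix,
    ref_a: AlleleFrequencyPanel,
    ref_b: AlleleFrequencyPanel,
    mixes: list[MixtureEstimate] | MixtureEstimate,
) -> AncestryWeightTrack:
    """Build the K = (a-b)/L weight track for every target individual.

    A marker is invalid for an individual if the call is missing, either
    panel is unavailable there, or both panel frequencies sit at the same
    clamp boundary (monomorphic and identical: K would be exactly 0 and
    carries no information).
    """
    if isinstance(mixes, MixtureEstimate):
        mixes = [mixes] * gm.n_ind
    if len(mixes) != gm.n_ind:
        raise InvariantError(f"{len(mixes)} mixture estimates for {gm.n_ind} individuals")
    alphas = np.array([m.alpha for m in mixes], dtype=np.float64)

    same_clamp = (
        (ref_a.freq <= FREQ_EPS) & (ref_b.freq <= FREQ_EPS)
        | (ref_a.freq >= 1.0 - FREQ_EPS) & (ref_b.freq >= 1.0 - FREQ_EPS)
    )
    marker_ok = ref_a.available & ref_b.available & ~same_clamp

    a, b = site_probabilities(gm.calls, ref_a.freq, ref_b.freq, gm.ploidy_mode)
    valid = (gm.calls != MISSING) & marker_ok[None, :]
    a = np.where(valid, a, 0.5)
    b = np.where(valid, b, 0.5)
    lik = alphas[:, None] * a + (1.0 - alphas)[:, None] * b
    k = np.where(valid, (a - b) / lik, 0.0)
    if not np.all(np.isfinite(k)):
        raise InvariantError("non-finite ancestry weight")
    with np.errstate(invalid="ignore"):
        kbar = np.where(
            valid.sum(axis=1) > 0,
            k.sum(axis=1) / np.maximum(valid.sum(axis=1), 1),
            0.0,
        )
    return AncestryWeightTrack(k=k, valid=valid, kbar=kbar, alpha=alphas)


# ---------------------------------------------------------------------------
# binned ancestry covariance


@dataclass
class CovarianceCurve:
    """Binned ancestry covariance A(d) with per-chromosome provenance.

    ``sums`` and ``counts`` have shape ``(n_chrom, n_ind, n_bins)`` so the
    leave-one-chromosome-out jackknife and both pooling modes can re-pool
    without touching the genotypes again.  ``bin_dist`` is the representative
    genetic distance of each bin: bin centres for the naive path, grid-lag
    distances for the FFT path.
    """

    binsize: float
    bin_dist: np.ndarray  # (n_bins,)
    chroms: list[str]
    sums: np.ndarray  # (n_chrom, n_ind, n_bins) float64
    counts: np.ndarray  # (n_chrom, n_ind, n_bins) int64
    method: str = "naive"

    @property
    def n_bins(self) -> int:
        return len(self.bin_dist)

    @property
    def is_empty(self) -> bool:
        return bool(self.counts.sum() == 0)

    def values(
        self, pooling: str = "pooled", exclude_chrom: int | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """(A(d), pooled pair counts) per bin under a pooling mode.

        ``pooled`` sums numerators and pair counts over chromosomes and
        individuals before dividing; ``per_individual_mean`` averages the
        per-individual curves.  ``exclude_chrom`` drops one chromosome's
        partial sums (jackknife re-pooling).
        """
        keep = np.ones(len(self.chroms), dtype=bool)
        if exclude_chrom is not None:
            keep[exclude_chrom] = False
        s = self.sums[keep]
        n = self.counts[keep]
        n_pooled = n.sum(axis=(0, 1))
        with np.errstate(invalid="ignore", divide="ignore"):
            if pooling == "pooled":
                y = np.where(n_pooled > 0, s.sum(axis=(0, 1)) / np.maximum(n_pooled, 1), np.nan)
            elif pooling == "per_individual_mean":
                s_i = s.sum(axis=0)  # (n_ind, n_bins)
                n_i = n.sum(axis=0)
                y_i = np.where(n_i > 0, s_i / np.maximum(n_i, 1), np.nan)
                with np.errstate(invalid="ignore"):
                    y = np.nanmean(np.where(n_i > 0, y_i, np.nan), axis=0)
            else:
                raise InvariantError(f"unknown pooling mode {pooling!r}")
        return y, n_pooled


def covariance_curve_naive(
    track: AncestryWeightTrack,
    snp: pd.DataFrame,
    binsize: float = DEFAULT_BINSIZE,
    maxdis: float = DEFAULT_MAXDIS,
) -> CovarianceCurve:
    """O(m^2) within-chromosome pair accumulation; the reference path.

    Every pair (i < j) on one chromosome with distance d < ``maxdis``
    contributes ``(K_i - Kbar)(K_j - Kbar)`` to bin ``floor(d / binsize)``.
    No cross-chromosome pairs.
    """
    _check_bins(binsize, maxdis)
    nbins = int(round(maxdis / binsize))
    chroms, chrom_idx = _chrom_groups(snp)
    n_ind = track.n_ind
    sums = np.zeros((len(chroms), n_ind, nbins))
    counts = np.zeros((len(chroms), n_ind, nbins), dtype=np.int64)
    gpos = snp["gpos"].to_numpy()
    kc = track.k - track.kbar[:, None]
    for ci, idx in enumerate(chrom_idx):
        if len(idx) < 2:
            continue
        pos = gpos[idx]
        ii, jj = np.triu_indices(len(idx), k=1)
        d = pos[jj] - pos[ii]
        b = np.floor(d / binsize + 1e-9).astype(np.int64)
        in_range = b < nbins
        ii, jj, b = ii[in_range], jj[in_range], b[in_range]
        for t in range(n_ind):
            v = track.valid[t, idx]
            pv = v[ii] & v[jj]
            prod = kc[t, idx][ii[pv]] * kc[t, idx][jj[pv]]
            sums[ci, t] += np.bincount(b[pv], weights=prod, minlength=nbins)
            counts[ci, t] += np.bincount(b[pv], minlength=nbins)
    bin_dist = (np.arange(nbins) + 0.5) * binsize
    curve = CovarianceCurve(binsize, bin_dist, chroms, sums, counts, method="naive")
    if curve.is_empty:
        logger.warning("covariance curve is empty (no valid within-chromosome pairs)")
    return curve


def covariance_curve_fft(
    track: AncestryWeightTrack,
    snp: pd.DataFrame,
    binsize: float = DEFAULT_BINSIZE,
    maxdis: float = DEFAULT_MAXDIS,
) -> CovarianceCurve:
    """FFT-autocorrelation covariance: O(m log m) per chromosome.

    Centered weights are aggregated onto a uniform grid of cell width
    ``binsize`` (per-cell sums and counts); lag sums of products and pair
    counts come from linear autocorrelation of the two tracks.  The lag-b bin
    holds pairs whose *grid cells* are b apart, so off-lattice positions are
    discretised with error bounded by one binsize; markers sharing a cell
    land in the lag-0 bin with self-pairs removed.
    """
    _check_bins(binsize, maxdis)
    nbins = int(round(maxdis / binsize))
    chroms, chrom_idx = _chrom_groups(snp)
    n_ind = track.n_ind
    sums = np.zeros((len(chroms), n_ind, nbins))
    counts = np.zeros((len(chroms), n_ind, nbins), dtype=np.int64)
    gpos = snp["gpos"].to_numpy()
    kc = track.k - track.kbar[:, None]
    for ci, idx in enumerate(chrom_idx):
        if len(idx) < 2:
            continue
        pos = gpos[idx]
        cells = np.floor(pos / binsize + 1e-9).astype(np.int64)
        cells -= cells[0]
        ncell = int(cells[-1]) + 1
        nlag = min(nbins, ncell)
        nfft = 1 << int(math.ceil(math.log2(ncell + nlag)))
        v = track.valid[:, idx]
        kvals = np.where(v, kc[:, idx], 0.0)
        flat = (np.arange(n_ind)[:, None] * ncell + cells[None, :])[v]
        s_track = np.bincount(flat, weights=kvals[v], minlength=n_ind * ncell).reshape(
            n_ind, ncell
        )
        n_track = np.bincount(flat, minlength=n_ind * ncell).reshape(n_ind, ncell)
        k2 = np.bincount(flat, weights=kvals[v] ** 2, minlength=n_ind * ncell).reshape(
            n_ind, ncell
        )
        fs = np.fft.rfft(s_track, nfft, axis=1)
        fn = np.fft.rfft(n_track.astype(np.float64), nfft, axis=1)
        auto_s = np.fft.irfft(fs * np.conj(fs), nfft, axis=1)[:, :nlag]
        auto_n = np.fft.irfft(fn * np.conj(fn), nfft, axis=1)[:, :nlag]
        # lag 0: within-cell pairs only (remove the self-pair diagonal)
        auto_s[:, 0] = 0.5 * (auto_s[:, 0] - k2.sum(axis=1))
        nc = n_track.astype(np.int64)
        auto_n_int = np.rint(auto_n).astype(np.int64)
        auto_n_int[:, 0] = (nc * (nc - 1)).sum(axis=1) // 2
        sums[ci, :, :nlag] = auto_s
        counts[ci, :, :nlag] = auto_n_int
    bin_dist = np.arange(nbins) * binsize
    curve = CovarianceCurve(binsize, bin_dist, chroms, sums, counts, method="fft")
    if curve.is_empty:
        logger.warning("covariance curve is empty (no valid within-chromosome pairs)")
    return curve


def _check_bins(binsize: float, maxdis: float) -> None:
    if binsize <= 0:
        raise InvariantError("binsize must be > 0")
    if maxdis <= binsize:
        raise InvariantError("maxdis must exceed binsize")


def _chrom_groups(snp: pd.DataFrame) -> tuple[list[str], list[np.ndarray]]:
    chrom = snp["chrom"].to_numpy()
    chroms = list(dict.fromkeys(chrom))
    return chroms, [np.flatnonzero(chrom == c) for c in chroms]


# ---------------------------------------------------------------------------
# exponential + affine fit


@dataclass
class ExponentialFit:
    """y = amplitude * exp(-lam * d) + c fitted over [lo, hi]; t = lam - 1."""

    amplitude: float
    lam: float
    c: float
    lo: float
    hi: float
    d: np.ndarray  # fitted bin distances
    y: np.ndarray  # empirical values at those bins
    fitted: np.ndarray
    boundary_fit: bool = False

    @property
    def t(self) -> float:
        return self.lam - 1.0

    @property
    def residuals(self) -> np.ndarray:
        return self.y - self.fitted


def _lambda_grid() -> np.ndarray:
    n = int(math.floor(math.log(LAMBDA_GRID_HI / LAMBDA_GRID_LO) / math.log(LAMBDA_GRID_STEP)))
    grid = LAMBDA_GRID_LO * LAMBDA_GRID_STEP ** np.arange(n + 1)
    if grid[-1] < LAMBDA_GRID_HI:
        grid = np.append(grid, LAMBDA_GRID_HI)
    return grid


def _profile_rss(lam: np.ndarray, d: np.ndarray, y: np.ndarray):
    """Profiled least squares: for each lambda solve (A, c) in closed form.

    Returns (rss, A, c) arrays aligned with ``lam``.
    """
    lam = np.atleast_1d(np.asarray(lam, dtype=np.float64))
    e = np.exp(-np.outer(lam, d))
    n = float(len(d))
    se = e.sum(axis=1)
    see = (e * e).sum(axis=1)
    sy = float(y.sum())
    syy = float(y @ y)
    sey = e @ y
    det = n * see - se * se
    safe = det > 1e-30 * n * np.maximum(see, 1e-300)
    amp = np.where(safe, (n * sey - se * sy) / np.where(safe, det, 1.0), 0.0)
    c = (sy - amp * se) / n
    rss = (
        syy
        + amp * amp * see
        + n * c * c
        - 2.0 * amp * sey
        - 2.0 * c * sy
        + 2.0 * amp * c * se
    )
    return rss, amp, c


def fit_decay(d: np.ndarray, y: np.ndarray, lo: float, hi: float) -> ExponentialFit:
    """Deterministic grid + golden-section fit of A e^{-lam d} + c.

    lambda is searched on a multiplicative grid from 0.5 to 500 (step 1.02),
    (A, c) profiled in closed form at each lambda, then refined by
    golden-section around the grid optimum.  Ties break toward smaller
    lambda; an optimum at either grid end is flagged ``boundary_fit``.
    """
    d = np.asarray(d, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(d) == 0:
        raise FitError("no populated bins in the fit range")
    grid = _lambda_grid()
    rss, _, _ = _profile_rss(grid, d, y)
    i = int(np.argmin(rss))
    boundary = i == 0 or i == len(grid) - 1
    a_lo = grid[max(i - 1, 0)]
    a_hi = grid[min(i + 1, len(grid) - 1)]
    lam = _golden_section(lambda l: _profile_rss(l, d, y)[0][0], a_lo, a_hi)
    rss_ref, amp_ref, c_ref = _profile_rss(np.array([lam]), d, y)
    if rss_ref[0] > rss[i]:  # refinement never worsens the grid optimum
        lam = float(grid[i])
        _, amp_ref, c_ref = _profile_rss(np.array([lam]), d, y)
    fitted = amp_ref[0] * np.exp(-lam * d) + c_ref[0]
    return ExponentialFit(
        amplitude=float(amp_ref[0]),
        lam=float(lam),
        c=float(c_ref[0]),
        lo=lo,
        hi=hi,
        d=d,
        y=y,
        fitted=fitted,
        boundary_fit=boundary,
    )


def _golden_section(f, a: float, b: float, rel_tol: float = 1e-9) -> float:
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    x1 = b - invphi * (b - a)
    x2 = a + invphi * (b - a)
    f1, f2 = f(x1), f(x2)
    while (b - a) > rel_tol * max(abs(a), abs(b), 1.0):
        if f1 <= f2:  # ties toward smaller lambda
            b, x2, f2 = x2, x1, f1
            x1 = b - invphi * (b - a)
            f1 = f(x1)
        else:
            a, x1, f1 = x1, x2, f2
            x2 = a + invphi * (b - a)
            f2 = f(x2)
    return 0.5 * (a + b)


def fit_exponential(
    curve: CovarianceCurve,
    lo: float = DEFAULT_LO,
    hi: float = DEFAULT_HI,
    pooling: str = "pooled",
    exclude_chrom: int | None = None,
    min_bins: int = 10,
) -> ExponentialFit:
    """Fit the decay over populated bins of a covariance curve in [lo, hi]."""
    y, n = curve.values(pooling=pooling, exclude_chrom=exclude_chrom)
    mask = (curve.bin_dist >= lo) & (curve.bin_dist <= hi) & (n > 0) & np.isfinite(y)
    if mask.sum() < min_bins:
        raise FitError(
            f"only {int(mask.sum())} populated bins in [{lo}, {hi}] (need >= {min_bins})"
        )
    return fit_decay(curve.bin_dist[mask], y[mask], lo, hi)


# ---------------------------------------------------------------------------
# jackknife, fit quality, calendar conversion


@dataclass
class JackknifeResult:
    """Weighted leave-one-chromosome-out jackknife of the fitted date."""

    t_mean: float
    se: float
    per_block: pd.DataFrame  # columns: chrom, t, weight
    n_blocks: int

    @property
    def z(self) -> float:
        if self.se == 0.0:
            return math.inf if self.t_mean > 0 else (-math.inf if self.t_mean < 0 else 0.0)
        return self.t_mean / self.se


def jackknife_date(
    curve: CovarianceCurve,
    lo: float = DEFAULT_LO,
    hi: float = DEFAULT_HI,
    pooling: str = "pooled",
) -> JackknifeResult:
    """Weighted delete-one jackknife over chromosomes.

    Block weights are proportional to the number of marker pairs the
    chromosome contributes inside the fit range.  The delete-m_j estimator
    of Busing et al. is used for both the bias-adjusted mean and the SE.
    """
    full = fit_exponential(curve, lo, hi, pooling=pooling)
    fit_mask = (curve.bin_dist >= lo) & (curve.bin_dist <= hi)
    w_all = curve.counts[:, :, fit_mask].sum(axis=(1, 2)).astype(np.float64)

    blocks: list[tuple[str, float, float]] = []
    for j, chrom in enumerate(curve.chroms):
        if w_all[j] <= 0:
            continue
        try:
            fit_j = fit_exponential(curve, lo, hi, pooling=pooling, exclude_chrom=j)
        except FitError as e:
            logger.warning("jackknife: dropping chromosome %s (%s)", chrom, e)
            continue
        blocks.append((chrom, fit_j.t, w_all[j]))
    if len(blocks) < 2:
        raise JackknifeError(f"only {len(blocks)} usable jackknife blocks (need >= 2)")

    per_block = pd.DataFrame(blocks, columns=["chrom", "t", "weight"])
    t_del = per_block["t"].to_numpy()
    w = per_block["weight"].to_numpy()
    g = len(t_del)
    w_tot = w.sum()
    theta = full.t
    t_mean = g * theta - float(((1.0 - w / w_tot) * t_del).sum())
    h = w_tot / w
    tau = h * theta - (h - 1.0) * t_del
    var = float((np.square(tau - t_mean) / (h - 1.0)).sum()) / g
    se = math.sqrt(max(var, 0.0))
    return JackknifeResult(t_mean=t_mean, se=se, per_block=per_block, n_blocks=g)


def compute_nrmsd(z: np.ndarray, zhat: np.ndarray) -> float:
    """Root-mean-square deviation of empirical vs fitted bins, normalised by
    the range of the fitted values: sqrt(mean((z - zhat)^2)) / (max - min)."""
    z = np.asarray(z, dtype=np.float64)
    zhat = np.asarray(zhat, dtype=np.float64)
    if z.shape != zhat.shape or z.size < 2:
        raise FitError("NRMSD needs two same-length vectors of >= 2 bins")
    rng = float(zhat.max() - zhat.min())
    if rng <= 0.0:
        raise FitError("degenerate fit range (flat fitted curve)")
    return float(np.sqrt(np.mean((z - zhat) ** 2)) / rng)


@dataclass
class DateEstimate:
    """Final qualified admixture date with calendar conversions."""

    t_gen: float  # full-data point estimate
    t_gen_jack_mean: float
    se_gen: float
    z: float
    nrmsd: float
    significant: bool
    lam: float
    years_bp: float
    year_bce: float
    mean_sampling_age: float
    generation_time: float


def qualify_and_convert(
    fit: ExponentialFit,
    jack: JackknifeResult,
    mean_sampling_age: float = 0.0,
    generation_time: float = DEFAULT_GENERATION_TIME,
) -> DateEstimate:
    """Apply the significance gate and convert generations to calendar dates.

    The date is significant only if Z > 2, lambda < 200 generations and
    NRMSD < 0.7 (all strict).  Years BP = jackknife mean x generation time +
    mean sampling age; BCE uses the 1950 convention (negative = CE).
    """
    try:
        nrmsd = compute_nrmsd(fit.y, fit.fitted)
    except FitError:
        nrmsd = math.inf
    z = jack.z
    significant = (z > SIG_Z) and (fit.lam < SIG_LAMBDA) and (nrmsd < SIG_NRMSD)
    years_bp = jack.t_mean * generation_time + mean_sampling_age
    return DateEstimate(
        t_gen=fit.t,
        t_gen_jack_mean=jack.t_mean,
        se_gen=jack.se,
        z=z,
        nrmsd=nrmsd,
        significant=significant,
        lam=fit.lam,
        years_bp=years_bp,
        year_bce=years_bp - 1950.0,
        mean_sampling_age=mean_sampling_age,
        generation_time=generation_time,
    )


# ---------------------------------------------------------------------------
# end-to-end driver


@dataclass
class DatingResult:
    """Everything the pipeline computed for one target group."""

    estimate: DateEstimate
    fit: ExponentialFit
    jackknife: JackknifeResult
    curve: CovarianceCurve
    mixes: list[MixtureEstimate]
    n_snps_used: int

    @property
    def alpha(self) -> float:
        """Group-level mean ancestry fraction (logging only)."""
        return float(np.mean([m.alpha for m in self.mixes]))


def date_admixture(
    target: GenotypeMatrix,
    ref_a: AlleleFrequencyPanel,
    ref_b: AlleleFrequencyPanel,
    binsize: float = DEFAULT_BINSIZE,
    maxdis: float = DEFAULT_MAXDIS,
    lo: float = DEFAULT_LO,
    hi: float = DEFAULT_HI,
    use_fft: bool = True,
    pooling: str = "pooled",
    generation_time: float = DEFAULT_GENERATION_TIME,
    mean_sampling_age: float | None = None,
) -> DatingResult:
    """Run the full dating pipeline on one target group.

    Per individual: mixture regression and weight track.  Then the pooled
    binned covariance (FFT path by default), the exponential + affine fit
    over [lo, hi] Morgans, leave-one-chromosome-out jackknife errors, the
    NRMSD fit-quality gate, and calendar conversion.
    """
    mixes = [
        estimate_mixture_proportion(target.calls[t], ref_a, ref_b)
        for t in range(target.n_ind)
    ]
    track = ancestry_weights(target, ref_a, ref_b, mixes)
    cov = covariance_curve_fft if use_fft else covariance_curve_naive
    curve = cov(track, target.snp, binsize=binsize, maxdis=maxdis)
    fit = fit_exponential(curve, lo, hi, pooling=pooling)
    jack = jackknife_date(curve, lo, hi, pooling=pooling)
    if mean_sampling_age is None:
        mean_sampling_age = target.mean_sampling_age()
    est = qualify_and_convert(fit, jack, mean_sampling_age, generation_time)
    n_used = int((track.valid.any(axis=0)).sum())
    return DatingResult(
        estimate=est,
        fit=fit,
        jackknife=jack,
        curve=curve,
        mixes=mixes,
        n_snps_used=n_used,
    )
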