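# Methods

## Model

An admixed diploid genome formed by a single pulse of mixture between
sources *A* and *B*, *t* generations before the individual lived, is a
mosaic of ancestry tracts whose boundaries accumulate at recombination rate
one per Morgan per generation.  `admixdate` summarises this mosaic without
inferring local ancestry.  For each marker *i* with genotype
*g<sub>i</sub>* ∈ {0, 1, 2} (count of the reference allele; 9 = missing)
and reference-panel frequencies *p<sub>Ai</sub>*, *p<sub>Bi</sub>*:

- *a<sub>i</sub>* = P(*g<sub>i</sub>* | *A*) and *b<sub>i</sub>* =
  P(*g<sub>i</sub>* | *B*) are binomial genotype probabilities in the panel
  frequency (two draws for diploid calls, one draw for pseudo-haploid calls,
  which carry values 0/2 only);
- *L<sub>i</sub>* = α·*a<sub>i</sub>* + β·*b<sub>i</sub>* is the per-site
  likelihood under ancestry fractions α + β = 1;
- *K<sub>i</sub>* = (*a<sub>i</sub>* − *b<sub>i</sub>*) / *L<sub>i</sub>* is
  the ancestry weight: the coefficient that multiplies the probability of
  shared ancestry when the joint likelihood of two linked markers is
  expanded in the no-recombination probability θ = e^(−td).

The covariance of centered weights between marker pairs at genetic distance
*d*,

    A(d) = Σ_{S(d)} (K1 − K̄)(K2 − K̄) / |S(d)|,

decays in expectation as e^(−(t+1)d).  The rate is t+1, not t: in the first
generation after mixture each offspring inherits one intact chromosome per
source, and crossovers only begin mixing ancestry in the following
generation.  α is estimated per target individual beforehand by ordinary
least squares of the genotype dosages g/2 on the two panel frequencies
(the dosage scale makes a target identical to panel A yield exactly α = 1,
which is then clamped to 1 − 10⁻⁴).

## Pipeline and numerical choices

**Binning.**  Pairs are accumulated within chromosomes only, into uniform
bins of 0.001 M (0.1 cM) out to 1 M.  The naive path bins each pair at
floor(d / binsize) and represents a bin by its centre.  The FFT path
aggregates centered weights onto a grid of cell width binsize and obtains
lag sums of products and pair counts by linear autocorrelation (real FFTs,
zero-padded; self-pairs removed from lag 0), representing lag b by distance
b·binsize.  On positions that sit on the grid the two paths are identical;
off-grid the FFT discretisation error is bounded by one binsize and is
negligible relative to the bin width already chosen.  Markers sharing a
grid cell land in the lag-0 bin, below every fit range in practice.

**Centering.**  K̄ is the per-individual genome-wide mean of valid K.
Global (rather than per-chromosome or per-bin) centering matches the
covariance interpretation and is stable when few markers survive masking.

**Masking.**  A site is invalid for an individual when the call is missing,
either panel has zero observations there, or both panel frequencies sit at
the same clamp boundary (jointly monomorphic markers carry no ancestry
information; K would be 0).  Panel frequencies are clamped into
[10⁻⁴, 1 − 10⁻⁴] instead of special-casing division by zero.

**Pooling.**  With several target individuals the default pools bin
numerators and pair counts over individuals before dividing; a
`per_individual_mean` mode that averages per-individual curves is exposed
as an alternative.  Pooling weights individuals by the pairs they
contribute, which is the behaviour wanted under variable missingness.

**Fit.**  y = A·e^(−λd) + c is fitted by unweighted least squares over
populated bins in [0.45 cM, 100 cM].  λ is searched on a deterministic
multiplicative grid from 0.5 to 500 (step 1.02) with (A, c) profiled in
closed form at each λ, then refined by golden section around the grid
optimum; ties break toward smaller λ, and an optimum at either end of the
grid is flagged as a boundary fit.  There is no random initialisation
anywhere in the dating path.  The effective precision of the fitted λ is
about 10⁻³ relative: the residual surface is flat near the optimum, so
perturbations of the bins at machine precision (for example re-estimating
the swapped α as 1 − α) move λ by up to that much — tests assert swap
invariance of the curve at 10⁻¹⁰ and of the date at 10⁻³.

**Errors.**  Standard errors come from a weighted leave-one-chromosome-out
jackknife with block weights proportional to the marker pairs each
chromosome contributes inside the fit range, using the delete-m_j
estimator of Busing et al. for both the bias-adjusted mean and the
variance.  Z = jackknife mean / SE.

**Fit quality and significance.**  NRMSD = RMS(z − ẑ) / (max ẑ − min ẑ)
over the fitted bins.  A date is significant only if Z > 2, λ < 200
generations, and NRMSD < 0.7, all strict, as printed.  Generations convert
to years at 28 years/generation (overridable), plus the mean sampling age
of the target individuals; BCE = years BP − 1950.

## Simulator

Source panels are Balding–Nichols draws: ancestral frequencies uniform on
[0.05, 0.95], per-population frequencies Beta(p(1−F)/F, (1−p)(1−F)/F) with
divergence F (default 0.15, roughly a west African / European contrast),
haplotypes independent Bernoulli draws, marker positions uniform per
chromosome.  Admixed haploids are built by copying: a source is drawn with
probability α at the chromosome start and after every recombination event,
which occurs per inter-marker gap g with probability 1 − e^(−λg) at
λ = t + 1 (a redraw may select the same source); each copying segment takes
a fresh haplotype from the chosen source's pool without replacement, with
pools refilled at every chromosome.  Haploids are paired at random into
diploids.  Multi-way histories iterate the algorithm with the previous
admixed pool as one source, truth labels carried through marker by marker.
Pseudo-haploidisation replaces each het by 0 or 2 with probability ½;
missingness masks each call independently.  Ground truth is emitted as
segment tracks in genetic coordinates.

What the generator does *not* emulate: background LD within the source
populations (haplotypes are exchangeable draws, so linkage arises only from
the copying process), mutation, genotyping error beyond
missingness/pseudo-haploidy, non-uniform genetic maps, and coalescent
features such as founder events or continuous gene flow.  Passing tests
therefore demonstrate the estimator's behaviour under its own model
assumptions plus frequency noise and ancient-DNA-style degradation — not
robustness to map error or real background LD (the 0.45 cM fit start
exists to damp the latter in real data).

## Study conditions for validation

The validation experiments (tests and `scripts/acceptance.py`) fix: 50,000
markers on 22 chromosomes of 35/22 M each (~35 M, the human autosomal
scale, at reduced marker density), FST 0.15 panels, 10 admixed diploids
with α = 0.2, admixture times 10–200 generations, and reference panels of
30 diploids per source built from haplotypes disjoint from the copying
panels (surrogate references, mirroring the build/date split used with
real data).  The copying-panel size scales as N + 8√N + 10 with
N = 1 + (t+1)·L expected draws per chromosome, so the without-replacement
pool never exhausts across the replicate grid.  Recovery is measured as
coverage of the truth by the jackknife 2-SE interval over 20 replicates per
condition; null calibration uses 50 replicates of targets drawn wholly from
one source.

## Known limitations

- The amplitude of the fitted exponential is reported but is **not** a
  reliable ancestry-proportion estimate; likewise the regression α runs a
  few percentage points above the truth when reference panels are small,
  because sampling noise in the panel frequencies inflates the slope (60
  reference alleles per source at the validation scale put an α of 0.20
  near 0.22).  Treat α as an internal weight, not a headline estimate.
- A true decay rate at or above the λ < 200 significance cutoff (t ≥ 199)
  cannot pass the gate reliably even when the date itself is recovered:
  estimates straddle the cutoff.  The cutoff is a reporting convention, not
  an accuracy limit.
- Multiple-pulse histories yield whatever the single-exponential fit
  yields; with references chosen to isolate the most recent pulse (recent
  source vs pooled older sources) the recent time is recovered, otherwise
  dates can fall between pulses.
- Dates for very recent admixture (t of a few generations) sit close to the
  λ grid floor of 0.5 and are bounded by the 100 cM fit window rather than
  by data.
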