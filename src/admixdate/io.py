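"""EIGENSTRAT (ancestrymap text dialect) genotype I/O and allele-frequency panels.

The three-file EIGENSTRAT representation is the lingua franca of ancient-DNA
genotype data: a ``.geno`` file with one line per SNP and one genotype
character per individual (``0``/``1``/``2`` = count of the reference allele,
``9`` = missing), a ``.snp`` file with marker metadata including the genetic
position in **Morgans**, and a ``.ind`` file with one individual per line
(id, sex, group label).

All genetic distances inside this package are Morgans; centimorgans appear
only at the user-facing surface (CLI flags, report columns).

Sampling ages (years before present) have no slot in ``.ind``; they are read
from a separate two-column whitespace table ``ind_id  age_BP``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EigenstratParseError, InvariantError, LookupError_

logger = logging.getLogger(__name__)

MISSING = 9
VALID_CALLS = frozenset((0, 1, 2, 9))

SNP_COLUMNS = ["snp_id", "chrom", "gpos", "ppos", "allele_ref", "allele_alt"]
IND_COLUMNS = ["ind_id", "sex", "group"]


@dataclass
class GenotypeMatrix:
    """Individuals × markers genotype table with typed metadata.

    Attributes
    ----------
    ind : pandas.DataFrame
        Columns ``ind_id`` (unique), ``sex`` (accepted, ignored), ``group``,
        and optionally ``age_bp`` (sampling age in years before present).
    snp : pandas.DataFrame
        Columns ``snp_id`` (unique), ``chrom`` (opaque string label),
        ``gpos`` (Morgans, non-negative, non-decreasing within chromosome),
        ``ppos`` (bp), ``allele_ref``, ``allele_alt``.
    calls : numpy.ndarray
        ``(n_ind, n_snp)`` int8 array with values in {0, 1, 2, 9}.
    ploidy_mode : str
        ``"diploid"`` or ``"pseudo_haploid"``; pseudo-haploid calls are
        restricted to {0, 2, 9} (one sampled allele reported as homozygous).
    """

    ind: pd.DataFrame
    snp: pd.DataFrame
    calls: np.ndarray
    ploidy_mode: str = "diploid"

    @property
    def n_ind(self) -> int:
        return len(self.ind)

    @property
    def n_snp(self) -> int:
        return len(self.snp)

    def validate(self) -> "GenotypeMatrix":
        if self.ploidy_mode not in ("diploid", "pseudo_haploid"):
            raise InvariantError(f"unknown ploidy_mode {self.ploidy_mode!r}")
        if self.calls.shape != (len(self.ind), len(self.snp)):
            raise InvariantError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.ind)} individuals x {len(self.snp)} snps"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, 9))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise InvariantError(
                f"genotype value {self.calls[i, j]} at individual {i}, snp {j} "
                "outside {0,1,2,9}"
            )
        if self.ploidy_mode == "pseudo_haploid" and (self.calls == 1).any():
            raise InvariantError("pseudo_haploid matrix contains heterozygous calls")
        if self.ind["ind_id"].duplicated().any():
            dup = self.ind["ind_id"][self.ind["ind_id"].duplicated()].iloc[0]
            raise InvariantError(f"duplicate individual id {dup!r}")
        if self.snp["snp_id"].duplicated().any():
            dup = self.snp["snp_id"][self.snp["snp_id"].duplicated()].iloc[0]
            raise InvariantError(f"duplicate snp id {dup!r}")
        g = self.snp["gpos"].to_numpy()
        if not np.all(np.isfinite(g)) or (g < 0).any():
            raise InvariantError("genetic positions must be finite and >= 0")
        return self

    def chromosomes(self) -> list[str]:
        """Chromosome labels in order of first appearance."""
        return list(dict.fromkeys(self.snp["chrom"]))

    def chrom_slices(self) -> dict[str, np.ndarray]:
        """Marker index array per chromosome, in stored order."""
        idx: dict[str, np.ndarray] = {}
        chrom = self.snp["chrom"].to_numpy()
        for c in self.chromosomes():
            idx[c] = np.flatnonzero(chrom == c)
        return idx

    def subset_individuals(self, ind_ids: list[str]) -> "GenotypeMatrix":
        pos = _resolve_ind_ids(self.ind, ind_ids)
        return GenotypeMatrix(
            ind=self.ind.iloc[pos].reset_index(drop=True),
            snp=self.snp,
            calls=self.calls[pos],
            ploidy_mode=self.ploidy_mode,
        )

    def mean_sampling_age(self) -> float:
        """Mean ``age_bp`` over individuals; 0.0 when no ages were attached."""
        if "age_bp" not in self.ind.columns:
            return 0.0
        return float(self.ind["age_bp"].fillna(0.0).mean())


def _resolve_ind_ids(ind: pd.DataFrame, ind_ids: list[str]) -> np.ndarray:
    index = pd.Index(ind["ind_id"])
    pos = index.get_indexer(ind_ids)
    if (pos < 0).any():
        missing = [i for i, p in zip(ind_ids, pos) if p < 0]
        raise LookupError_(f"unknown individual id(s): {missing}")
    return pos


# ---------------------------------------------------------------------------
# reading


def read_eigenstrat(
    geno_path: str | Path,
    snp_path: str | Path,
    ind_path: str | Path,
    ploidy_mode: str = "diploid",
) -> GenotypeMatrix:
    """Read an EIGENSTRAT text triplet into a validated :class:`GenotypeMatrix`.

    Markers unsorted by genetic position within a chromosome are sorted on
    read (with a logged warning); trailing whitespace and a missing final
    newline are tolerated.
    """
    snp = _read_snp(snp_path)
    ind = _read_ind(ind_path)
    calls = _read_geno(geno_path, n_snp=len(snp), n_ind=len(ind))

    # enforce non-decreasing genetic positions within each chromosome
    order = np.arange(len(snp))
    for c, idx in _group_indices(snp["chrom"].to_numpy()).items():
        g = snp["gpos"].to_numpy()[idx]
        if np.any(np.diff(g) < 0):
            logger.warning("chromosome %s: markers unsorted by genetic position; sorting", c)
            order[idx] = idx[np.argsort(g, kind="stable")]
    if not np.array_equal(order, np.arange(len(snp))):
        snp = snp.iloc[order].reset_index(drop=True)
        calls = calls[:, order]

    return GenotypeMatrix(ind=ind, snp=snp, calls=calls, ploidy_mode=ploidy_mode).validate()


def _group_indices(labels: np.ndarray) -> dict:
    out: dict = {}
    for c in dict.fromkeys(labels):
        out[c] = np.flatnonzero(labels == c)
    return out


def _read_snp(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 4:
                parts = parts + ["A", "G"]  # allele columns are optional
            if len(parts) != 6:
                raise EigenstratParseError(
                    f"{path}: line {lineno}: expected 4 or 6 columns, got {len(parts)}"
                )
            try:
                gpos = float(parts[2])
                ppos = int(parts[3])
            except ValueError as e:
                raise EigenstratParseError(f"{path}: line {lineno}: {e}") from None
            rows.append((parts[0], parts[1], gpos, ppos, parts[4], parts[5]))
    return pd.DataFrame(rows, columns=SNP_COLUMNS)


def _read_ind(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 3:
                raise EigenstratParseError(
                    f"{path}: line {lineno}: expected 3 columns (id sex group), got {len(parts)}"
                )
            rows.append(tuple(parts))
    return pd.DataFrame(rows, columns=IND_COLUMNS)


def _read_geno(path: str | Path, n_snp: int, n_ind: int) -> np.ndarray:
    calls = np.empty((n_ind, n_snp), dtype=np.int8)
    row = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.rstrip()
            if not s:
                continue
            if row >= n_snp:
                raise EigenstratParseError(
                    f"{path}: line {lineno}: more genotype rows than .snp rows ({n_snp})"
                )
            if len(s) != n_ind:
                raise EigenstratParseError(
                    f"{path}: line {lineno}: row width {len(s)} does not match "
                    f".ind rows ({n_ind})"
                )
            vals = np.frombuffer(s.encode("ascii"), dtype=np.uint8).astype(np.int16) - ord("0")
            bad = ~np.isin(vals, (0, 1, 2, 9))
            if bad.any():
                col = int(np.flatnonzero(bad)[0])
                raise EigenstratParseError(
                    f"{path}: line {lineno}, column {col + 1}: genotype character "
                    f"{s[col]!r} outside {{0,1,2,9}}"
                )
            calls[:, row] = vals.astype(np.int8)
            row += 1
    if row != n_snp:
        raise EigenstratParseError(
            f"{path}: {row} genotype rows but .snp has {n_snp} rows"
        )
    return calls


def read_age_table(path: str | Path) -> pd.Series:
    """Read the two-column ``ind_id  age_BP`` sampling-age table."""
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None, names=["ind_id", "age_bp"])
    return df.set_index("ind_id")["age_bp"].astype(float)


def attach_ages(gm: GenotypeMatrix, ages: pd.Series) -> GenotypeMatrix:
    """Return a copy of ``gm`` with an ``age_bp`` column (0 where absent)."""
    ind = gm.ind.copy()
    ind["age_bp"] = ind["ind_id"].map(ages).fillna(0.0)
    return replace(gm, ind=ind)


# ---------------------------------------------------------------------------
# writing


def write_eigenstrat(gm: GenotypeMatrix, prefix: str | Path) -> tuple[Path, Path, Path]:
    """Write ``prefix``.geno/.snp/.ind; round-trips through :func:`read_eigenstrat`."""
    gm.validate()
    prefix = Path(prefix)
    geno_path = prefix.parent / (prefix.name + ".geno")
    snp_path = prefix.parent / (prefix.name + ".snp")
    ind_path = prefix.parent / (prefix.name + ".ind")

    with open(snp_path, "w") as fh:
        for r in gm.snp.itertuples(index=False):
            fh.write(
                f"{r.snp_id:>15s} {r.chrom:>4s} {r.gpos:>12.8f} {r.ppos:>12d} "
                f"{r.allele_ref} {r.allele_alt}\n"
            )
    with open(ind_path, "w") as fh:
        for r in gm.ind.itertuples(index=False):
            fh.write(f"{r.ind_id:>20s} {r.sex} {r.group:>20s}\n")
    with open(geno_path, "w") as fh:
        digits = gm.calls.astype(np.uint8) + ord("0")
        for j in range(gm.n_snp):
            fh.write(digits[:, j].tobytes().decode("ascii"))
            fh.write("\n")
    return geno_path, snp_path, ind_path


# ---------------------------------------------------------------------------
# allele frequencies


@dataclass
class AlleleFrequencyPanel:
    """Per-marker allele frequency and observation count for one reference panel.

    ``freq`` is defined only where ``available``; markers with zero
    observations are flagged unavailable and carry ``freq = nan``.
    """

    freq: np.ndarray  # float64, nan where unavailable
    count: np.ndarray  # int64 allele observations
    available: np.ndarray  # bool
    label: str = ""

    def __post_init__(self):
        ok = self.available & np.isfinite(self.freq)
        if np.any(self.available & ~np.isfinite(self.freq)):
            raise InvariantError("available marker with undefined frequency")
        if ok.any() and ((self.freq[ok] < 0) | (self.freq[ok] > 1)).any():
            raise InvariantError("allele frequency outside [0, 1]")


def compute_allele_frequencies(
    gm: GenotypeMatrix, individual_subset: list[str] | None = None, label: str = ""
) -> AlleleFrequencyPanel:
    """Reference-allele frequency per marker over a subset of individuals.

    Diploid calls contribute two allele observations (the genotype value),
    pseudo-haploid calls one (genotype/2); missing calls contribute nothing.
    """
    if individual_subset is None:
        sub = gm
    else:
        if len(individual_subset) == 0:
            raise LookupError_("individual subset is empty")
        sub = gm.subset_individuals(list(individual_subset))
    calls = sub.calls
    obs = calls != MISSING
    alleles_per_call = 2 if gm.ploidy_mode == "diploid" else 1
    count = obs.sum(axis=0).astype(np.int64) * alleles_per_call
    allele_sum = np.where(obs, calls, 0).sum(axis=0).astype(np.float64)
    if gm.ploidy_mode == "pseudo_haploid":
        allele_sum = allele_sum / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = allele_sum / count
    available = count > 0
    freq[~available] = np.nan
    return AlleleFrequencyPanel(freq=freq, count=count, available=available, label=label)
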