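"""Domain types, validation, and readers/writers for the toolkit's tables.

The toolkit works with allele counts observed in a set of A ancient and B
present-day populations.  Each population is modelled, genome-wide, as a
mixture of k unobserved source populations; the mixture proportions live in
a row-stochastic (A+B) x k matrix in the layout produced by ADMIXTURE
(one whitespace-delimited row per population, no header).

Counts tables are TSV with columns ``chrom, pos, id`` followed by paired
``x_<POP>, N_<POP>`` columns, one pair per population; column order defines
the population index and must match the row order of the admixture matrix.

Dated samples (for the time-series machinery) are haploid observations: one
allele, an age in generations before present, and per-individual ancestry
loadings that sum to one.  Diploid individuals are represented as two
haploid samples sharing their loadings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GENERATION_YEARS",
    "ValidationError",
    "ParseError",
    "PopulationCounts",
    "AdmixtureMatrix",
    "SourceFrequencies",
    "DatedSample",
    "VariantRecord",
    "SampleBin",
    "years_to_generations",
    "generations_to_years",
    "read_counts_table",
    "write_counts_table",
    "read_q_matrix",
    "write_q_matrix",
    "read_dated_samples",
    "write_dated_samples",
    "aggregate_samples",
]

#: Mean human generation interval in years used for explicit conversions.
GENERATION_YEARS = 29.0

_ROW_SUM_TOL = 1e-4
_LOADING_TOL = 1e-6


class ValidationError(ValueError):
    """A table parsed, but its values violate a domain invariant."""


class ParseError(ValueError):
    """A file could not be interpreted in the expected layout."""


def years_to_generations(years: float) -> float:
    """Convert years before present to generations (29 years/generation)."""
    return years / GENERATION_YEARS


def generations_to_years(generations: float) -> float:
    """Convert generations before present to years (29 years/generation)."""
    return generations * GENERATION_YEARS


@dataclass(frozen=True)
class PopulationCounts:
    """Per-variant alternate-allele counts across A+B populations.

    Attributes
    ----------
    variant_id : str
    x : ndarray of int
        Alternate-allele count per population.
    N : ndarray of int
        Total called alleles per population.  Pseudohaploid individuals
        contribute 1 per site, diploid individuals 2.
    is_ancient : ndarray of bool
        Flag per population; purely annotative for the statistics.
    labels : tuple of str, optional
        Population labels in index order (carried along from the table).
    """

    variant_id: str
    x: np.ndarray
    N: np.ndarray
    is_ancient: np.ndarray = field(default=None)  # type: ignore[assignment]
    labels: tuple = ()

    def __post_init__(self):
        x = np.asarray(self.x, dtype=np.int64)
        N = np.asarray(self.N, dtype=np.int64)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "N", N)
        if self.is_ancient is None:
            object.__setattr__(self, "is_ancient", np.zeros(len(x), dtype=bool))
        else:
            object.__setattr__(
                self, "is_ancient", np.asarray(self.is_ancient, dtype=bool)
            )
        if x.shape != N.shape or x.ndim != 1:
            raise ValidationError(
                f"variant {self.variant_id}: x and N must be 1-D and equal length"
            )
        if len(self.is_ancient) != len(x):
            raise ValidationError(
                f"variant {self.variant_id}: is_ancient length mismatch"
            )
        if np.any(x < 0) or np.any(N < 0) or np.any(x > N):
            raise ValidationError(
                f"variant {self.variant_id}: need 0 <= x_i <= N_i in every population"
            )
        if not np.any(N > 0):
            raise ValidationError(
                f"variant {self.variant_id}: all populations have N_i = 0"
            )

    @property
    def n_populations(self) -> int:
        return len(self.x)

    @property
    def frequencies(self) -> np.ndarray:
        """Observed f_i = x_i / N_i (NaN where N_i = 0)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.N > 0, self.x / np.maximum(self.N, 1), np.nan)


@dataclass(frozen=True)
class AdmixtureMatrix:
    """Row-stochastic (A+B) x k matrix of genome-wide admixture proportions."""

    M: np.ndarray
    population_labels: tuple = ()
    source_labels: tuple = ()

    def __post_init__(self):
        M = np.asarray(self.M, dtype=float)
        if M.ndim != 2:
            raise ValidationError("admixture matrix must be 2-D")
        object.__setattr__(self, "M", M)
        if M.shape[1] < 1:
            raise ValidationError("admixture matrix needs k >= 1 sources")
        if M.shape[1] > M.shape[0]:
            raise ValidationError(
                f"k={M.shape[1]} sources exceed the {M.shape[0]} populations"
            )
        if np.any(M < -1e-12) or np.any(M > 1 + 1e-12):
            raise ValidationError("admixture proportions must lie in [0, 1]")
        sums = M.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValidationError(
                f"admixture matrix row {bad} sums to {sums[bad]:.8f}, not 1"
            )
        if self.population_labels and len(self.population_labels) != M.shape[0]:
            raise ValidationError("population_labels length mismatch")
        if self.source_labels and len(self.source_labels) != M.shape[1]:
            raise ValidationError("source_labels length mismatch")

    @property
    def n_populations(self) -> int:
        return self.M.shape[0]

    @property
    def k(self) -> int:
        return self.M.shape[1]


@dataclass(frozen=True)
class SourceFrequencies:
    """Allele frequencies of one variant in the k source populations."""

    q: np.ndarray

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        object.__setattr__(self, "q", q)
        if q.ndim != 1:
            raise ValidationError("source frequencies must be a vector")
        if np.any(q < -1e-12) or np.any(q > 1 + 1e-12):
            raise ValidationError("source frequencies must lie in [0, 1]")


@dataclass(frozen=True)
class DatedSample:
    """One haploid observation: allele, age, and ancestry loadings."""

    time: int
    allele: int
    loadings: np.ndarray
    sample_id: str = ""

    def __post_init__(self):
        if self.allele not in (0, 1):
            raise ValidationError(f"sample {self.sample_id}: allele must be 0 or 1")
        if self.time < 0:
            raise ValidationError(f"sample {self.sample_id}: time must be >= 0")
        q = np.asarray(self.loadings, dtype=float)
        object.__setattr__(self, "loadings", q)
        if abs(q.sum() - 1.0) > _LOADING_TOL:
            raise ValidationError(
                f"sample {self.sample_id}: loadings sum to {q.sum():.8f}, not 1"
            )


@dataclass(frozen=True)
class VariantRecord:
    """A variant with genomic coordinates plus its population counts."""

    chrom: str
    pos: int
    counts: PopulationCounts

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError(
                f"variant {self.counts.variant_id}: pos must be >= 1 (1-based)"
            )

    @property
    def variant_id(self) -> str:
        return self.counts.variant_id

    @property
    def pos0(self) -> int:
        """0-based coordinate used for internal window arithmetic."""
        return self.pos - 1


@dataclass(frozen=True)
class SampleBin:
    """Dated samples grouped into one time bin."""

    index: int
    samples: tuple

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def mean_loadings(self) -> np.ndarray:
        return np.mean([s.loadings for s in self.samples], axis=0)


# ---------------------------------------------------------------------------
# Counts tables


def read_counts_table(path, ancient: Sequence[str] = ()) -> list:
    """Read a TSV counts table into validated :class:`VariantRecord` s.

    Layout: header ``chrom  pos  id  x_POP1  N_POP1  x_POP2  N_POP2 ...``.
    Column order defines the population index.  ``ancient`` optionally names
    the populations to flag as ancient.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    required = ["chrom", "pos", "id"]
    if list(df.columns[:3]) != required:
        raise ParseError(
            f"{path}: first three columns must be {required}, got "
            f"{list(df.columns[:3])}"
        )
    pair_cols = list(df.columns[3:])
    if len(pair_cols) % 2 != 0 or not pair_cols:
        raise ParseError(f"{path}: expected paired x_/N_ population columns")
    labels = []
    for i in range(0, len(pair_cols), 2):
        xc, nc = pair_cols[i], pair_cols[i + 1]
        if not (xc.startswith("x_") and nc.startswith("N_") and xc[2:] == nc[2:]):
            raise ParseError(f"{path}: malformed column pair ({xc}, {nc})")
        labels.append(xc[2:])
    labels = tuple(labels)
    is_ancient = np.array([lab in set(ancient) for lab in labels])

    xs = df[[f"x_{lab}" for lab in labels]].to_numpy()
    ns = df[[f"N_{lab}" for lab in labels]].to_numpy()
    if not (np.issubdtype(xs.dtype, np.integer) and np.issubdtype(ns.dtype, np.integer)):
        bad = df.index[
            ~np.isfinite(xs.astype(float)).all(axis=1)
            | ~np.isfinite(ns.astype(float)).all(axis=1)
        ]
        if len(bad):
            raise ParseError(f"{path}: non-numeric counts at data line {bad[0] + 2}")
        if np.any(xs.astype(float) % 1 != 0) or np.any(ns.astype(float) % 1 != 0):
            raise ParseError(f"{path}: counts must be integers")
        xs, ns = xs.astype(np.int64), ns.astype(np.int64)

    records = []
    seen = set()
    for row, x, N in zip(df.itertuples(index=False), xs, ns):
        key = (str(row.chrom), int(row.pos))
        if key in seen:
            raise ValidationError(f"{path}: duplicate coordinate {key}")
        seen.add(key)
        counts = PopulationCounts(
            variant_id=str(row.id), x=x, N=N, is_ancient=is_ancient, labels=labels
        )
        records.append(VariantRecord(chrom=str(row.chrom), pos=int(row.pos), counts=counts))
    return records


def write_counts_table(records: Sequence[VariantRecord], path) -> None:
    """Write records back to the TSV layout read by :func:`read_counts_table`."""
    if not records:
        raise ValueError("cannot write an empty counts table (labels unknown)")
    labels = records[0].counts.labels
    cols = {"chrom": [r.chrom for r in records], "pos": [r.pos for r in records],
            "id": [r.variant_id for r in records]}
    xs = np.array([r.counts.x for r in records])
    ns = np.array([r.counts.N for r in records])
    for j, lab in enumerate(labels):
        cols[f"x_{lab}"] = xs[:, j]
        cols[f"N_{lab}"] = ns[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ADMIXTURE .Q matrices


def read_q_matrix(path, labels: Sequence[str] = (), source_labels: Sequence[str] = ()) -> AdmixtureMatrix:
    """Read an ADMIXTURE .Q file (whitespace-delimited, no header).

    Rows whose sum deviates from 1 by at most 1e-4 are renormalized; larger
    deviations are an error.  Row order must match the counts-table column
    order.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric entry") from exc
            rows.append(vals)
    if not rows:
        raise ParseError(f"{path}: empty .Q file")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ParseError(f"{path}: ragged rows (expected {width} columns everywhere)")
    M = np.array(rows, dtype=float)
    sums = M.sum(axis=1)
    bad = np.abs(sums - 1.0) > _ROW_SUM_TOL
    if np.any(bad):
        i = int(np.argmax(bad))
        raise ParseError(
            f"{path}: row {i + 1} sums to {sums[i]:.6f}; "
            f"outside the +-{_ROW_SUM_TOL} renormalization tolerance"
        )
    M = M / sums[:, None]
    return AdmixtureMatrix(
        M=M, population_labels=tuple(labels), source_labels=tuple(source_labels)
    )


def write_q_matrix(matrix: AdmixtureMatrix, path) -> None:
    np.savetxt(path, matrix.M, fmt="%.12f", delimiter=" ")


# ---------------------------------------------------------------------------
# Dated samples


def read_dated_samples(path) -> list:
    """Read dated haploid samples from TSV: sample_id, time_gen, allele, q_1..q_K."""
    df = pd.read_csv(path, sep="\t")
    qcols = [c for c in df.columns if c.startswith("q_")]
    if not qcols or list(df.columns[:3]) != ["sample_id", "time_gen", "allele"]:
        raise ParseError(
            f"{path}: expected columns sample_id, time_gen, allele, q_1..q_K"
        )
    out = []
    for row in df.itertuples(index=False):
        out.append(
            DatedSample(
                sample_id=str(row.sample_id),
                time=int(row.time_gen),
                allele=int(row.allele),
                loadings=np.array([getattr(row, c) for c in qcols], dtype=float),
            )
        )
    return out


def write_dated_samples(samples: Sequence[DatedSample], path) -> None:
    if not samples:
        raise ValueError("no samples to write")
    K = len(samples[0].loadings)
    cols = {
        "sample_id": [s.sample_id for s in samples],
        "time_gen": [s.time for s in samples],
        "allele": [s.allele for s in samples],
    }
    Q = np.array([s.loadings for s in samples])
    for j in range(K):
        cols[f"q_{j + 1}"] = np.round(Q[:, j], 12)
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def aggregate_samples(samples: Sequence[DatedSample], bin_width: int) -> list:
    """Group dated samples into time bins of ``bin_width`` generations.

    Bin index is floor(time / bin_width); individual loadings are preserved
    within each bin.  Returns bins sorted by index (youngest first).
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    groups: dict = {}
    for s in samples:
        if s.time < 0:
            raise ValidationError(f"sample {s.sample_id}: negative time")
        groups.setdefault(s.time // bin_width, []).append(s)
    return [SampleBin(index=i, samples=tuple(groups[i])) for i in sorted(groups)]
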