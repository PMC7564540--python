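"""Epiallele matrices and methylation-class (MC) distributions.

An *epiallele* is the methylation configuration of a single sequenced DNA
molecule across the N CpG sites of an amplicon, encoded as a binary vector
(0 = unmethylated, 1 = methylated).  Epialleles are grouped into N+1
*methylation classes* by the number of methylated sites they carry; the
class frequencies of replicate individuals are averaged into a condition
distribution D_n with standard errors sigma_n.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "EpialleleMatrix",
    "MCDistribution",
    "ConditionDistribution",
    "EpialleleFormatError",
    "read_epiallele_matrix",
    "methylation_classes",
    "average_condition",
    "mean_methylation",
    "write_mc_distribution",
    "write_condition_distribution",
]


class EpialleleFormatError(ValueError):
    """Raised when an epiallele file violates the expected layout."""


def _as_read_array(reads) -> np.ndarray:
    arr = np.asarray(reads)
    if arr.dtype.kind in "UOS":
        # rows given as strings over {0,1}
        rows = [list(str(r)) for r in np.atleast_1d(arr)]
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ValueError("reads have inconsistent lengths")
        arr = np.array(rows)
        if not np.isin(arr, ["0", "1"]).all():
            raise ValueError("read entries must be 0 or 1")
        arr = arr.astype(np.uint8)
    arr = np.atleast_2d(arr)
    return arr


@dataclass(frozen=True)
class EpialleleMatrix:
    """Per-sample collection of binary CpG-state vectors, one per molecule.

    Parameters
    ----------
    sample_id : str
        Label of the sequenced sample.
    n_sites : int
        Number N of CpG sites in the amplicon (N >= 1).
    reads : ndarray of shape (n_reads, n_sites)
        One row per molecule, entries in {0, 1}.
    """

    sample_id: str
    n_sites: int
    reads: np.ndarray

    def __post_init__(self):
        arr = _as_read_array(self.reads)
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if arr.ndim != 2:
            raise ValueError("reads must be a 2-D array")
        if arr.shape[0] < 1:
            raise ValueError("no reads")
        if arr.shape[1] != self.n_sites:
            raise ValueError(
                f"reads have {arr.shape[1]} sites, expected {self.n_sites}"
            )
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("read entries must be 0 or 1")
        object.__setattr__(self, "reads", np.ascontiguousarray(arr, dtype=np.uint8))

    @property
    def n_reads(self) -> int:
        return self.reads.shape[0]


@dataclass(frozen=True)
class MCDistribution:
    """Methylation-class counts and frequencies for one sample.

    Class n collects the molecules with exactly n methylated sites, so a
    region with N CpGs has N+1 classes.
    """

    n_sites: int
    counts: np.ndarray
    total_reads: int
    frequencies: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        freqs = np.asarray(self.frequencies, dtype=float)
        if counts.shape != (self.n_sites + 1,) or freqs.shape != (self.n_sites + 1,):
            raise ValueError("counts and frequencies must have length n_sites + 1")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if counts.sum() != self.total_reads:
            raise ValueError("counts must sum to total_reads")
        if self.total_reads < 1:
            raise ValueError("total_reads must be >= 1")
        if abs(freqs.sum() - 1.0) > 1e-12:
            raise ValueError("frequencies must sum to 1")
        if not np.allclose(freqs, counts / self.total_reads, rtol=0, atol=1e-12):
            raise ValueError("frequencies must equal counts / total_reads")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "frequencies", freqs)


@dataclass(frozen=True)
class ConditionDistribution:
    """Replicate-averaged class distribution D_n with standard errors sigma_n."""

    condition_id: str
    n_sites: int
    d: np.ndarray
    sigma: np.ndarray
    n_individuals: int

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        if d.shape != (self.n_sites + 1,) or sigma.shape != (self.n_sites + 1,):
            raise ValueError("d and sigma must have length n_sites + 1")
        if abs(d.sum() - 1.0) > 1e-9:
            raise ValueError("d must sum to 1")
        if (sigma < 0).any():
            raise ValueError("sigma entries must be non-negative")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "sigma", sigma)


def read_epiallele_matrix(
    path: Union[str, Path],
    format: str = "compact",
    sample_id: str | None = None,
) -> EpialleleMatrix:
    """Read and validate an epiallele matrix from disk.

    Two plain-text dialects are supported.  ``compact``: one read per line
    as a string over {0,1}; lines starting with ``#`` are comments, with the
    optional directive ``#N=<int>`` checked against the row length.
    ``csv``: header ``read_id,cpg_1,...,cpg_N`` and one row per read with
    0/1 cells.

    Reads with characters outside {0,1} are rejected, not imputed: silently
    filling in ambiguous site calls would bias the class counts.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    if format == "compact":
        return _read_compact(path, sample_id)
    if format == "csv":
        return _read_csv(path, sample_id)
    raise ValueError(f"unknown format {format!r}; expected 'compact' or 'csv'")


def _read_compact(path: Path, sample_id: str) -> EpialleleMatrix:
    declared_n = None
    rows: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.upper().startswith("N="):
                    try:
                        declared_n = int(body[2:])
                    except ValueError as exc:
                        raise EpialleleFormatError(
                            f"{path}:{lineno}: malformed #N= directive"
                        ) from exc
                continue
            if set(line) - {"0", "1"}:
                raise EpialleleFormatError(
                    f"{path}:{lineno}: characters outside {{0,1}} in read {line!r}"
                )
            if rows and len(line) != len(rows[0]):
                raise EpialleleFormatError(
                    f"{path}:{lineno}: read length {len(line)} does not match "
                    f"first read length {len(rows[0])}"
                )
            rows.append(line)
    if not rows:
        raise EpialleleFormatError(f"{path}: no reads")
    n = len(rows[0])
    if declared_n is not None and declared_n != n:
        raise EpialleleFormatError(
            f"{path}: #N={declared_n} does not match read length {n}"
        )
    arr = np.array([list(r) for r in rows], dtype=np.uint8)
    return EpialleleMatrix(sample_id=sample_id, n_sites=n, reads=arr)


def _read_csv(path: Path, sample_id: str) -> EpialleleMatrix:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise EpialleleFormatError(f"{path}: no reads") from exc
    except pd.errors.ParserError as exc:
        raise EpialleleFormatError(f"{path}: {exc}") from exc
    cols = list(df.columns)
    if not cols or cols[0] != "read_id":
        raise EpialleleFormatError(f"{path}: first CSV column must be 'read_id'")
    site_cols = cols[1:]
    expected = [f"cpg_{i}" for i in range(1, len(site_cols) + 1)]
    if site_cols != expected:
        raise EpialleleFormatError(
            f"{path}: site columns must be cpg_1..cpg_N, got {site_cols}"
        )
    if df.shape[0] == 0:
        raise EpialleleFormatError(f"{path}: no reads")
    vals = df[site_cols].to_numpy()
    if df[site_cols].isna().any().any() or not np.isin(vals, (0, 1)).all():
        bad = int(np.where(~np.isin(vals, (0, 1)).all(axis=1))[0][0]) + 2
        raise EpialleleFormatError(f"{path}:{bad}: cell values must be 0 or 1")
    return EpialleleMatrix(
        sample_id=sample_id, n_sites=len(site_cols), reads=vals.astype(np.uint8)
    )


def methylation_classes(matrix: EpialleleMatrix) -> MCDistribution:
    """Group reads into methylation classes by methylated-site count.

    ``counts[n]`` is the number of molecules with exactly n methylated
    CpGs; frequencies are counts normalised by the total number of reads.
    """
    n_meth = matrix.reads.sum(axis=1)
    counts = np.bincount(n_meth, minlength=matrix.n_sites + 1)
    total = matrix.n_reads
    return MCDistribution(
        n_sites=matrix.n_sites,
        counts=counts,
        total_reads=total,
        frequencies=counts / total,
    )


def average_condition(
    replicates: Sequence[MCDistribution],
    condition_id: str = "condition",
) -> ConditionDistribution:
    """Average replicate class frequencies into a condition distribution.

    D_n is the mean class-n frequency over the m individuals; sigma_n is
    the standard error, i.e. the sample standard deviation (denominator
    m - 1) divided by sqrt(m).  A single replicate yields sigma = 0.
    """
    if len(replicates) < 1:
        raise ValueError("at least one replicate required")
    n = replicates[0].n_sites
    if any(r.n_sites != n for r in replicates):
        raise ValueError("replicates must share the same number of CpG sites")
    freqs = np.stack([r.frequencies for r in replicates])
    m = freqs.shape[0]
    d = freqs.mean(axis=0)
    if m == 1:
        sigma = np.zeros(n + 1)
    else:
        sigma = freqs.std(axis=0, ddof=1) / np.sqrt(m)
    return ConditionDistribution(
        condition_id=condition_id, n_sites=n, d=d, sigma=sigma, n_individuals=m
    )


def mean_methylation(matrix: EpialleleMatrix) -> float:
    """Average methylation level: total methylated calls / (reads * N)."""
    return float(matrix.reads.mean())


def write_mc_distribution(dist: MCDistribution, path: Union[str, Path]) -> None:
    """Write an MC distribution as TSV with columns n, count, frequency."""
    df = pd.DataFrame(
        {
            "n": np.arange(dist.n_sites + 1),
            "count": dist.counts,
            "frequency": dist.frequencies,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_condition_distribution(
    cond: ConditionDistribution, path: Union[str, Path]
) -> None:
    """Write a condition distribution as TSV with columns n, d, sigma."""
    df = pd.DataFrame(
        {"n": np.arange(cond.n_sites + 1), "d": cond.d, "sigma": cond.sigma}
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
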