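"""Core in-memory containers shared across the pipeline.

A :class:`GenotypeMatrix` holds additive allele dosages (samples x markers,
values in [0, 2], ``NaN`` for missing calls) together with the marker map
(chromosome, 1-based position).  A :class:`PhenotypeVector` holds one
quantitative trait, keyed by sample ID.  A :class:`PopulationPartition`
assigns every sample to exactly one labelled subpopulation, whether the
grouping is phenotypic ("Ppop"), genetic ("Gpop") or the simulator's truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import DataError, IntegrityError

logger = logging.getLogger("soygs")


def _as_str_array(values: Sequence) -> np.ndarray:
    return np.asarray(values, dtype=str)


@dataclass
class GenotypeMatrix:
    """Samples x markers additive dosage matrix with a marker map.

    Dosages count copies of the alternate (or minor) allele: integers
    0/1/2 before imputation, reals in [0, 2] after mean imputation.
    Missing calls are ``NaN``.
    """

    sample_ids: np.ndarray
    marker_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = _as_str_array(self.sample_ids)
        self.marker_ids = _as_str_array(self.marker_ids)
        self.chrom = _as_str_array(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise IntegrityError(
                f"dosage rows ({n}) do not match sample_ids ({len(self.sample_ids)})"
            )
        if not (len(self.marker_ids) == len(self.chrom) == len(self.pos) == m):
            raise IntegrityError("marker metadata lengths do not match dosage columns")
        if len(np.unique(self.sample_ids)) != n:
            raise IntegrityError("duplicate sample IDs")
        if len(np.unique(self.marker_ids)) != m:
            raise IntegrityError("duplicate marker IDs")
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise IntegrityError("non-missing dosages must lie in [0, 2]")
        # positions must be non-decreasing within each contiguous chromosome block
        for k in range(1, m):
            if self.chrom[k] == self.chrom[k - 1] and self.pos[k] < self.pos[k - 1]:
                raise IntegrityError(
                    f"positions decrease within chromosome {self.chrom[k]} "
                    f"at marker {self.marker_ids[k]}"
                )

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def has_missing(self) -> bool:
        return bool(np.isnan(self.dosages).any())

    def subset_samples(self, index) -> "GenotypeMatrix":
        """Row subset by positional index array (order preserved)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            sample_ids=self.sample_ids[index],
            marker_ids=self.marker_ids,
            chrom=self.chrom,
            pos=self.pos,
            dosages=self.dosages[index],
        )

    def subset_markers_by_id(self, marker_ids: Sequence[str]) -> "GenotypeMatrix":
        """Column subset by marker ID, preserving map order of the input matrix."""
        wanted = set(map(str, marker_ids))
        missing = wanted - set(self.marker_ids)
        if missing:
            raise IntegrityError(f"unknown marker IDs: {sorted(missing)[:5]} ...")
        mask = np.isin(self.marker_ids, list(wanted))
        return GenotypeMatrix(
            sample_ids=self.sample_ids,
            marker_ids=self.marker_ids[mask],
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            dosages=self.dosages[:, mask],
        )

    def reorder_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = index_of(self.sample_ids, sample_ids)
        return self.subset_samples(idx)


@dataclass
class PhenotypeVector:
    """One quantitative trait (mg/g for the seed-composition traits), sample-keyed."""

    sample_ids: np.ndarray
    values: np.ndarray
    trait_name: str = "trait"

    def __post_init__(self) -> None:
        self.sample_ids = _as_str_array(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.sample_ids) != len(self.values):
            raise IntegrityError("phenotype sample_ids and values differ in length")
        if len(np.unique(self.sample_ids)) != len(self.sample_ids):
            raise IntegrityError("duplicate sample IDs in phenotype")
        if not np.all(np.isfinite(self.values)):
            raise IntegrityError("phenotype values must be finite")

    def __len__(self) -> int:
        return len(self.values)

    def subset(self, index) -> "PhenotypeVector":
        index = np.asarray(index)
        return PhenotypeVector(self.sample_ids[index], self.values[index], self.trait_name)

    def reorder(self, sample_ids: Sequence[str]) -> "PhenotypeVector":
        return self.subset(index_of(self.sample_ids, sample_ids))


@dataclass
class PhenotypeSummary:
    """Descriptive statistics of one trait (sample n-1 conventions, excess kurtosis)."""

    n: int
    min: float
    max: float
    mean: float
    sd: float
    variance: float
    skewness: float
    kurtosis: float
    cv_percent: float


@dataclass
class PopulationPartition:
    """Assignment of every sample to one labelled subpopulation."""

    sample_ids: np.ndarray
    labels: np.ndarray
    scheme: str = "true_simulated"  # {phenotypic, genetic, true_simulated}

    def __post_init__(self) -> None:
        self.sample_ids = _as_str_array(self.sample_ids)
        self.labels = _as_str_array(self.labels)
        if len(self.sample_ids) != len(self.labels):
            raise IntegrityError("partition sample_ids and labels differ in length")

    def group_names(self) -> list[str]:
        """Labels ordered by descending group size, ties by label."""
        names, counts = np.unique(self.labels, return_counts=True)
        order = np.lexsort((names, -counts))
        return [str(names[i]) for i in order]

    def group_sizes(self) -> dict[str, int]:
        names, counts = np.unique(self.labels, return_counts=True)
        return {str(a): int(c) for a, c in zip(names, counts)}

    def members(self, label: str) -> np.ndarray:
        """Positional indices of a group's samples."""
        return np.flatnonzero(self.labels == str(label))

    def subset(self, index) -> "PopulationPartition":
        index = np.asarray(index)
        return PopulationPartition(self.sample_ids[index], self.labels[index], self.scheme)


def index_of(haystack: np.ndarray, needles: Sequence[str]) -> np.ndarray:
    """Positions of `needles` in `haystack` (exact, order of needles)."""
    lookup = {s: i for i, s in enumerate(haystack)}
    try:
        return np.array([lookup[str(s)] for s in needles], dtype=np.intp)
    except KeyError as exc:
        raise IntegrityError(f"sample/marker ID not found: {exc.args[0]}") from exc


def align(G: GenotypeMatrix, y: PhenotypeVector) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Join genotypes and phenotypes on sample_id intersection.

    Order follows the genotype matrix; dropped samples are counted and
    logged, mirroring how a real panel is merged with GRIN-style trait
    records that may not cover every genotyped accession.
    """
    common = set(G.sample_ids) & set(y.sample_ids)
    if not common:
        raise IntegrityError("no overlapping sample IDs between genotypes and phenotypes")
    dropped_g = G.n_samples - len(common)
    dropped_y = len(y) - len(common)
    if dropped_g or dropped_y:
        logger.info(
            "align: dropped %d genotyped and %d phenotyped samples without a match",
            dropped_g,
            dropped_y,
        )
    keep = np.array([s in common for s in G.sample_ids])
    G2 = G.subset_samples(np.flatnonzero(keep))
    y2 = y.reorder(G2.sample_ids)
    return G2, y2


def check_aligned(G: GenotypeMatrix, y: PhenotypeVector) -> None:
    if len(y) != G.n_samples or not np.array_equal(G.sample_ids, y.sample_ids):
        raise IntegrityError(
            "genotype and phenotype samples are not aligned; use soygs.datatypes.align"
        )


__all__ = [
    "GenotypeMatrix",
    "PhenotypeVector",
    "PhenotypeSummary",
    "PopulationPartition",
    "align",
    "check_aligned",
    "index_of",
    "replace",
    "field",
]
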