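"""Core in-memory containers shared by every pipeline stage.

Conventions used throughout the package:

* coordinates are 0-based, half-open, in base pairs;
* chromosome labels are strings; numeric labels sort numerically and "X"
  sorts after every autosome;
* missing genotype/allele calls are encoded as ``-1`` in integer arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

MISSING = -1

#: default conversion between physical and genetic distance when no genetic
#: map is available (cM per Mb); cattle averages close to 1.
DEFAULT_CM_PER_MB = 1.0


class BlockclockError(Exception):
    """Base class for all package-specific errors."""


class FormatError(BlockclockError):
    """A file did not conform to its declared on-disk dialect."""


class ParameterError(BlockclockError):
    """An argument fell outside its documented domain."""


class InvariantError(BlockclockError):
    """An internal data-structure invariant was violated."""


def chrom_sort_key(label: str) -> tuple:
    """Sort key placing numeric chromosomes in numeric order and letters after."""
    s = str(label)
    return (0, int(s), "") if s.isdigit() else (1, 0, s)


@dataclass
class MarkerMap:
    """Ordered SNP marker positions, grouped by chromosome.

    Parameters
    ----------
    chrom : array of str
        Chromosome label per marker ("1".."29", "X").
    name : array of str
        Marker identifiers, unique.
    pos_bp : array of int
        Physical position in base pairs; strictly increasing within each
        chromosome after :meth:`canonicalize`.
    pos_cm : array of float, optional
        Genetic position in centimorgans. When absent, genetic distances are
        derived from ``pos_bp`` at a uniform ``cm_per_mb`` rate.
    """

    chrom: np.ndarray
    name: np.ndarray
    pos_bp: np.ndarray
    pos_cm: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.name = np.asarray(self.name, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        if self.pos_cm is not None:
            self.pos_cm = np.asarray(self.pos_cm, dtype=np.float64)

    @property
    def n_markers(self) -> int:
        return len(self.name)

    def chromosomes(self) -> list[str]:
        """Chromosome labels present, in canonical order."""
        return sorted(set(self.chrom.tolist()), key=chrom_sort_key)

    def canonical_order(self) -> np.ndarray:
        """Indices that sort markers by (chromosome, pos_bp)."""
        keys = [chrom_sort_key(c) for c in self.chrom]
        return np.lexsort((self.pos_bp, np.array([k for k in keys], dtype=object)))

    def canonicalize(self) -> tuple["MarkerMap", np.ndarray]:
        """Return a (chrom, pos_bp)-sorted copy plus the permutation applied."""
        order = np.array(
            sorted(range(self.n_markers), key=lambda i: (chrom_sort_key(self.chrom[i]), self.pos_bp[i])),
            dtype=np.intp,
        )
        return self.subset(order), order

    def subset(self, idx: np.ndarray) -> "MarkerMap":
        return MarkerMap(
            chrom=self.chrom[idx],
            name=self.name[idx],
            pos_bp=self.pos_bp[idx],
            pos_cm=None if self.pos_cm is None else self.pos_cm[idx],
        )

    def chrom_indices(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.chrom == chrom)

    def genetic_positions(self, cm_per_mb: float = DEFAULT_CM_PER_MB) -> np.ndarray:
        """Genetic positions in cM, derived from pos_bp when pos_cm is absent."""
        if self.pos_cm is not None:
            return self.pos_cm
        return self.pos_bp.astype(np.float64) / 1e6 * cm_per_mb

    def validate(self) -> None:
        if len({len(self.chrom), len(self.name), len(self.pos_bp)}) != 1:
            raise InvariantError("marker map arrays have inconsistent lengths")
        for c in self.chromosomes():
            pos = self.pos_bp[self.chrom_indices(c)]
            if np.any(np.diff(pos) <= 0):
                raise InvariantError(f"pos_bp not strictly increasing on chromosome {c}")
            if self.pos_cm is not None:
                cm = self.pos_cm[self.chrom_indices(c)]
                if np.any(np.diff(cm) < 0):
                    raise InvariantError(f"pos_cm decreasing on chromosome {c}")


@dataclass
class GenotypeTable:
    """Diploid genotype calls (copies of the reference-coded allele).

    ``calls`` is an (individuals x markers) int8 matrix with values in
    {0, 1, 2, MISSING}.
    """

    individuals: np.ndarray
    breed: np.ndarray
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.individuals = np.asarray(self.individuals, dtype=object)
        self.breed = np.asarray(self.breed, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def subset_individuals(self, idx: np.ndarray) -> "GenotypeTable":
        return GenotypeTable(self.individuals[idx], self.breed[idx], self.calls[idx, :])

    def subset_markers(self, idx: np.ndarray) -> "GenotypeTable":
        return GenotypeTable(self.individuals, self.breed, self.calls[:, idx])

    def validate(self, marker_map: Optional[MarkerMap] = None) -> None:
        if self.calls.ndim != 2 or self.calls.shape[0] != self.n_individuals:
            raise InvariantError("calls matrix shape inconsistent with individuals")
        if len(self.breed) != self.n_individuals:
            raise InvariantError("breed labels inconsistent with individuals")
        ok = np.isin(self.calls, (0, 1, 2, MISSING))
        if not ok.all():
            raise InvariantError("genotype calls outside {0,1,2,missing}")
        if marker_map is not None and marker_map.n_markers != self.n_markers:
            raise InvariantError(
                f"genotypes carry {self.n_markers} markers but map has {marker_map.n_markers}"
            )


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes.

    ``alleles`` is an (haplotypes x markers) int8 matrix in {0, 1, MISSING}.
    ``labels`` carries the breed/group of the source individual per haplotype.
    """

    haplotype_ids: np.ndarray
    alleles: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.haplotype_ids = np.asarray(self.haplotype_ids, dtype=object)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.labels = np.asarray(self.labels, dtype=object)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotype_ids)

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[1]

    def individual_of(self, hap_index: int) -> str:
        """Sample id of a haplotype, by the "<sample>_<phase>" convention."""
        hid = str(self.haplotype_ids[hap_index])
        return hid.rsplit("_", 1)[0]

    def individuals(self) -> list[str]:
        seen: dict[str, None] = {}
        for i in range(self.n_haplotypes):
            seen.setdefault(self.individual_of(i), None)
        return list(seen)

    def subset(self, idx: np.ndarray) -> "HaplotypePanel":
        return HaplotypePanel(self.haplotype_ids[idx], self.alleles[idx, :], self.labels[idx])

    def subset_markers(self, idx: np.ndarray) -> "HaplotypePanel":
        return HaplotypePanel(self.haplotype_ids, self.alleles[:, idx], self.labels)

    def validate(self, marker_map: Optional[MarkerMap] = None) -> None:
        if self.alleles.ndim != 2 or self.alleles.shape[0] != self.n_haplotypes:
            raise InvariantError("allele matrix shape inconsistent with haplotype ids")
        if not np.isin(self.alleles, (0, 1, MISSING)).all():
            raise InvariantError("alleles outside {0,1,missing}")
        if marker_map is not None and marker_map.n_markers != self.n_markers:
            raise InvariantError("haplotype panel and marker map disagree on marker count")


@dataclass
class AncestryPainting:
    """Per-site posterior probability of copying from donor panel A.

    Two-panel model: P(B) = 1 - prob_A everywhere.
    """

    haplotype_ids: np.ndarray
    prob_A: np.ndarray

    def __post_init__(self) -> None:
        self.haplotype_ids = np.asarray(self.haplotype_ids, dtype=object)
        self.prob_A = np.asarray(self.prob_A, dtype=np.float64)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotype_ids)

    @property
    def n_markers(self) -> int:
        return self.prob_A.shape[1]

    def validate(self) -> None:
        if self.prob_A.ndim != 2 or self.prob_A.shape[0] != self.n_haplotypes:
            raise InvariantError("painting shape inconsistent with haplotype ids")
        if np.any(self.prob_A < 0) or np.any(self.prob_A > 1):
            raise InvariantError("copying probabilities outside [0,1]")


@dataclass
class Block:
    """One contiguous ancestry-labelled interval (0-based half-open, bp)."""

    haplotype_id: str
    chrom: str
    start_bp: int
    end_bp: int
    label: str  # "A", "B" or "uncertain"

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass
class BlockSet:
    """Ancestry blocks per haplotype-chromosome plus the marker span used as
    the denominator of per-chromosome proportions."""

    blocks: list[Block] = field(default_factory=list)
    #: chromosome -> (first marker bp, last marker bp)
    span_bp: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.blocks)

    def haplotype_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for b in self.blocks:
            seen.setdefault(b.haplotype_id, None)
        return list(seen)

    def for_haplotype_chrom(self, haplotype_id: str, chrom: str) -> list[Block]:
        return [b for b in self.blocks if b.haplotype_id == haplotype_id and b.chrom == chrom]

    def sorted_blocks(self) -> list[Block]:
        return sorted(
            self.blocks,
            key=lambda b: (str(b.haplotype_id), chrom_sort_key(b.chrom), b.start_bp),
        )

    def validate(self) -> None:
        groups: dict[tuple[str, str], list[Block]] = {}
        for b in self.blocks:
            if b.label not in ("A", "B", "uncertain"):
                raise InvariantError(f"unknown block label {b.label!r}")
            if b.end_bp < b.start_bp:
                raise InvariantError("block with negative length")
            groups.setdefault((b.haplotype_id, b.chrom), []).append(b)
        for (hid, chrom), blist in groups.items():
            blist = sorted(blist, key=lambda b: b.start_bp)
            for prev, nxt in zip(blist, blist[1:]):
                if nxt.start_bp < prev.end_bp:
                    raise InvariantError(
                        f"overlapping blocks on haplotype {hid} chromosome {chrom}"
                    )
                if nxt.start_bp != prev.end_bp:
                    raise InvariantError(
                        f"gap between blocks on haplotype {hid} chromosome {chrom}"
                    )
                if nxt.label == prev.label:
                    raise InvariantError(
                        f"adjacent blocks share label on haplotype {hid} chromosome {chrom}"
                    )
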