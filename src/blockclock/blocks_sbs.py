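"""Ancestry blocks and the scaled block size (SBS) statistic.

A painting is discretized into contiguous ancestry blocks: a marker is
called A when its panel-A posterior exceeds the calling threshold (default
0.75), B when the posterior is below one minus the threshold, uncertain in
between. Runs of the same call merge into blocks whose boundaries sit at
the midpoint between adjacent differing markers; terminal blocks end at the
first/last marker.

SBS summarizes how intact the *introgressed* (genome-wide minority)
ancestry still is. For one haplotype-chromosome with minority blocks of
lengths :math:`b_1..b_k` (as proportions of the painted marker span),

.. math:: \\mathrm{SBS} = \\operatorname{median}(b_i) / \\sum_i b_i .

A single intact introgressed segment gives SBS = 1; recombination over
generations fragments it and drives SBS toward 0, so larger values indicate
more recent admixture. Per individual, SBS is the mean over all defined
(haplotype x autosome) components. Individuals are classified as recently
admixed when their SBS is at least the minimum SBS among reference
individuals of known recent hybrid origin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .types import (
    AncestryPainting,
    Block,
    BlockSet,
    MarkerMap,
    ParameterError,
)

LABELS = ("A", "uncertain", "B")  # integer codes 0, 1, 2


@dataclass
class MinorityCall:
    """Genome-wide minority ("introgressed") ancestry of one individual."""

    individual: str
    minority_label: str  # "A" or "B"
    genomewide_minority_fraction: float  # in [0, 0.5)


@dataclass
class SBSResult:
    """Per-individual SBS with its haplotype-autosome components."""

    individual: str
    sbs: Optional[float]
    components: dict = field(default_factory=dict)  # (haplotype_id, chrom) -> float | None
    n_defined: int = 0
    minority: Optional[MinorityCall] = None

    def to_row(self) -> dict:
        return {
            "individual": self.individual,
            "sbs": self.sbs,
            "n_defined": self.n_defined,
            "minority_label": None if self.minority is None else self.minority.minority_label,
            "minority_fraction": (
                None if self.minority is None else self.minority.genomewide_minority_fraction
            ),
        }


def _marker_runs(
    prob_a: np.ndarray, pos_bp: np.ndarray, threshold: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run-length encode marker ancestry calls into block coordinates.

    Returns (starts_bp, ends_bp, label_codes); boundaries between runs are
    integer midpoints of the flanking marker positions.
    """
    codes = np.where(prob_a > threshold, 0, np.where(prob_a < 1.0 - threshold, 2, 1))
    change = np.flatnonzero(np.diff(codes) != 0)
    run_start_idx = np.concatenate(([0], change + 1))
    run_end_idx = np.concatenate((change, [len(codes) - 1]))
    cuts = (pos_bp[run_end_idx[:-1]] + pos_bp[run_start_idx[1:]]) // 2
    starts = np.concatenate(([pos_bp[0]], cuts))
    ends = np.concatenate((cuts, [pos_bp[-1]]))
    return starts, ends, codes[run_start_idx]


def call_blocks(
    painting: AncestryPainting, marker_map: MarkerMap, threshold: float = 0.75
) -> BlockSet:
    """Discretize a painting into ancestry blocks at the calling threshold."""
    if not (0.5 < threshold < 1):
        raise ParameterError(f"block-calling threshold must lie in (0.5, 1), got {threshold}")
    painting.validate()
    if painting.n_markers != marker_map.n_markers:
        raise ParameterError("painting and marker map disagree on marker count")

    out = BlockSet()
    chrom_idx = {c: marker_map.chrom_indices(c) for c in marker_map.chromosomes()}
    for chrom, idx in chrom_idx.items():
        pos = marker_map.pos_bp[idx]
        out.span_bp[chrom] = (int(pos[0]), int(pos[-1]))
        if len(idx) == 1:
            warnings.warn(
                f"chromosome {chrom} has a single marker; its block spans zero length",
                stacklevel=2,
            )
    for i in range(painting.n_haplotypes):
        hid = str(painting.haplotype_ids[i])
        for chrom, idx in chrom_idx.items():
            starts, ends, labels = _marker_runs(
                painting.prob_A[i, idx], marker_map.pos_bp[idx], threshold
            )
            for s, e, lab in zip(starts, ends, labels):
                out.blocks.append(Block(hid, chrom, int(s), int(e), LABELS[lab]))
    return out


def minority_label(blocks: BlockSet, individual: Optional[str] = None) -> MinorityCall:
    """Genome-wide minority ancestry over the autosomal blocks of one
    individual (both haplotypes); uncertain bp is excluded from numerator
    and denominator."""
    relevant = [b for b in blocks.blocks if b.chrom != "X"]
    if individual is not None:
        relevant = [b for b in relevant if str(b.haplotype_id).rsplit("_", 1)[0] == individual]
    a_bp = sum(b.length_bp for b in relevant if b.label == "A")
    b_bp = sum(b.length_bp for b in relevant if b.label == "B")
    if a_bp + b_bp == 0:
        raise ParameterError("no labelled (non-uncertain) autosomal bp for this individual")
    if a_bp == b_bp:
        raise ParameterError("no majority ancestor: ancestries tie at exactly 50/50")
    minority = "A" if a_bp < b_bp else "B"
    frac = min(a_bp, b_bp) / (a_bp + b_bp)
    if individual is None:
        ids = blocks.haplotype_ids()
        individual = str(ids[0]).rsplit("_", 1)[0] if ids else ""
    return MinorityCall(individual=individual, minority_label=minority, genomewide_minority_fraction=frac)


def chromosome_sbs(
    blocks: Sequence[Block], minority: str, span_bp: float
) -> Optional[float]:
    """SBS component for one haplotype-chromosome.

    ``blocks`` are the blocks of a single haplotype on a single chromosome;
    only those labelled with the minority ancestry enter. Returns None
    ("undefined") when the chromosome carries no minority block.
    """
    if span_bp <= 0:
        raise ParameterError("chromosome span must be positive")
    lengths = np.array([b.length_bp for b in blocks if b.label == minority], dtype=float)
    return _sbs_from_lengths(lengths, span_bp)


def _sbs_from_lengths(minority_lengths: np.ndarray, span_bp: float) -> Optional[float]:
    if len(minority_lengths) == 0:
        return None
    props = np.asarray(minority_lengths, dtype=float) / span_bp
    p = props.sum()
    if p == 0:
        return None
    return float(np.median(props) / p)


def individual_sbs(
    components: dict, minority: MinorityCall
) -> SBSResult:
    """Average defined haplotype-autosome SBS components for one individual.

    ``components`` maps (haplotype_id, chrom) to a scaled value or None;
    X-chromosome entries must already be excluded. All-undefined components
    mean the individual shows no introgressed block at all (non-admixed at
    the calling resolution): sbs is None.
    """
    defined = [v for v in components.values() if v is not None]
    sbs = float(np.mean(defined)) if defined else None
    return SBSResult(
        individual=minority.individual,
        sbs=sbs,
        components=dict(components),
        n_defined=len(defined),
        minority=minority,
    )


def sbs_for_individuals(blocks: BlockSet) -> list[SBSResult]:
    """Compute SBS for every individual represented in a BlockSet."""
    by_ind: dict[str, dict[tuple[str, str], list[Block]]] = {}
    for b in blocks.blocks:
        ind = str(b.haplotype_id).rsplit("_", 1)[0]
        by_ind.setdefault(ind, {}).setdefault((str(b.haplotype_id), b.chrom), []).append(b)

    results = []
    for ind in sorted(by_ind):
        minority = minority_label(blocks, individual=ind)
        components: dict[tuple[str, str], Optional[float]] = {}
        for (hid, chrom), blist in by_ind[ind].items():
            if chrom == "X":
                continue
            lo, hi = blocks.span_bp.get(chrom, (min(b.start_bp for b in blist), max(b.end_bp for b in blist)))
            span = hi - lo
            components[(hid, chrom)] = chromosome_sbs(blist, minority.minority_label, span) if span > 0 else None
        results.append(individual_sbs(components, minority))
    return results


def sbs_from_painting(
    painting: AncestryPainting, marker_map: MarkerMap, threshold: float = 0.75
) -> list[SBSResult]:
    """SBS straight from a painting, without materializing Block objects.

    Equivalent to ``sbs_for_individuals(call_blocks(...))`` but array-based,
    for large simulated cohorts.
    """
    if not (0.5 < threshold < 1):
        raise ParameterError(f"block-calling threshold must lie in (0.5, 1), got {threshold}")
    chroms = [c for c in marker_map.chromosomes() if c != "X"]
    chrom_idx = {c: marker_map.chrom_indices(c) for c in chroms}
    spans = {c: float(marker_map.pos_bp[i][-1] - marker_map.pos_bp[i][0]) for c, i in chrom_idx.items()}

    # per individual: total A/B bp and per-(hap, chrom) lengths by label
    per_ind: dict[str, dict] = {}
    for i in range(painting.n_haplotypes):
        hid = str(painting.haplotype_ids[i])
        ind = hid.rsplit("_", 1)[0]
        slot = per_ind.setdefault(ind, {"a": 0.0, "b": 0.0, "lengths": {}})
        for chrom in chroms:
            idx = chrom_idx[chrom]
            starts, ends, labels = _marker_runs(
                painting.prob_A[i, idx], marker_map.pos_bp[idx], threshold
            )
            lengths = (ends - starts).astype(float)
            la = lengths[labels == 0]
            lb = lengths[labels == 2]
            slot["a"] += la.sum()
            slot["b"] += lb.sum()
            slot["lengths"][(hid, chrom)] = (la, lb)

    results = []
    for ind in sorted(per_ind):
        slot = per_ind[ind]
        a_bp, b_bp = slot["a"], slot["b"]
        if a_bp + b_bp == 0:
            raise ParameterError(f"no labelled autosomal bp for individual {ind}")
        if a_bp == b_bp:
            raise ParameterError(f"no majority ancestor for individual {ind}")
        minority = MinorityCall(
            individual=ind,
            minority_label="A" if a_bp < b_bp else "B",
            genomewide_minority_fraction=min(a_bp, b_bp) / (a_bp + b_bp),
        )
        components = {
            key: _sbs_from_lengths(la if minority.minority_label == "A" else lb, spans[key[1]])
            for key, (la, lb) in slot["lengths"].items()
        }
        results.append(individual_sbs(components, minority))
    return results


def classify_recent(
    results: Sequence[SBSResult], reference_ids: Sequence[str]
) -> tuple[dict[str, bool], float]:
    """Flag recently admixed individuals against known-recent references.

    The cutoff is the minimum defined SBS among the reference individuals;
    an individual is flagged recent when its SBS is >= the cutoff (so every
    reference classifies as recent). Individuals with undefined SBS are not
    flagged.
    """
    refs = set(map(str, reference_ids))
    ref_sbs = [r.sbs for r in results if r.individual in refs and r.sbs is not None]
    if not ref_sbs:
        raise ParameterError("no reference individual has a defined SBS")
    cutoff = float(min(ref_sbs))
    flags = {r.individual: (r.sbs is not None and r.sbs >= cutoff) for r in results}
    return flags, cutoff
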