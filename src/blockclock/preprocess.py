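"""Quality filters applied to SNP-array genotypes before phasing/painting.

The filters mirror common SNP-chip curation practice for multi-breed cattle
panels: loci that look heterozygous in many breeds (paralogy proxy), loci
with poor call rates in many breeds (null-allele proxy), loci missing in
most individuals, then a missingness sweep over individuals and loci. Sex is
assigned from X-chromosome heterozygosity outside the pseudoautosomal
region: a male carries one X, so apparent X heterozygosity beyond genotyping
error marks a female.

All filter thresholds are strict inequalities except the 70%-missing locus
rule, which is "at least".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import MISSING, GenotypeTable, MarkerMap, ParameterError

#: first base of the X pseudoautosomal region in the UMD3.1 cattle assembly,
#: 1-based coordinates (converted to the package's 0-based convention at use)
PAR_START_BP = 137_109_768

HIGH_HET = "high_het"
LOW_CALLRATE = "low_callrate"
MISSING_70 = "missing_70"
MISSING_10 = "missing_10"


@dataclass
class FilterReport:
    """Which loci/individuals a filter removed, and why.

    Each removed marker is recorded under the first rule that triggered, so
    reasons partition the removed set.
    """

    removed_loci: dict[str, str] = field(default_factory=dict)
    removed_individuals: dict[str, str] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for reason in list(self.removed_loci.values()) + list(self.removed_individuals.values()):
            out[reason] = out.get(reason, 0) + 1
        return out

    def to_rows(self) -> list[dict]:
        rows = [
            {"item": name, "kind": "locus", "reason": reason}
            for name, reason in self.removed_loci.items()
        ]
        rows += [
            {"item": name, "kind": "individual", "reason": reason}
            for name, reason in self.removed_individuals.items()
        ]
        return rows


@dataclass
class SexAssignment:
    """Per-individual sex call from X heterozygosity.

    ``sex`` holds "male"/"female"; individuals with no usable X call are in
    ``unassigned`` and excluded from ``sex``.
    """

    sex: dict[str, str]
    x_het_fraction: dict[str, float]
    unassigned: list[str] = field(default_factory=list)

    def to_rows(self) -> list[dict]:
        rows = [
            {"individual": ind, "sex": s, "x_het_fraction": self.x_het_fraction[ind]}
            for ind, s in self.sex.items()
        ]
        rows += [
            {"individual": ind, "sex": "unassigned", "x_het_fraction": float("nan")}
            for ind in self.unassigned
        ]
        return rows


def _per_breed_stats(gt: GenotypeTable) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per (breed, locus) observed heterozygosity and call rate."""
    breeds = sorted(set(gt.breed.tolist()))
    n_b, n_m = len(breeds), gt.n_markers
    het = np.zeros((n_b, n_m))
    callrate = np.zeros((n_b, n_m))
    for bi, breed in enumerate(breeds):
        sub = gt.calls[gt.breed == breed, :]
        called = sub != MISSING
        n_called = called.sum(axis=0)
        n_het = (sub == 1).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            het[bi] = np.where(n_called > 0, n_het / np.maximum(n_called, 1), 0.0)
        callrate[bi] = n_called / sub.shape[0]
    return het, callrate, breeds


def filter_loci(
    gt: GenotypeTable,
    marker_map: MarkerMap,
    n_breed_threshold: int = 10,
    het_threshold: float = 0.5,
    callrate_threshold: float = 0.8,
    missing_ind_threshold: float = 0.70,
    exclude_markers: set[str] | None = None,
) -> tuple[GenotypeTable, MarkerMap, FilterReport]:
    """Remove paralogy-suspect, null-allele-suspect and mostly-missing loci.

    A locus is removed when (in this order; first rule wins in the report):

    a. mean observed heterozygosity > ``het_threshold`` in at least
       ``n_breed_threshold`` breeds,
    b. call rate < ``callrate_threshold`` in at least ``n_breed_threshold``
       breeds,
    c. missing in at least ``missing_ind_threshold`` of all individuals.

    ``exclude_markers`` is an optional curation list (markers undecodable
    against the chip manifest, supplied externally) removed before any rule.
    """
    if gt.n_individuals == 0 or gt.n_markers == 0:
        raise ParameterError("cannot filter an empty genotype table")
    gt.validate(marker_map)

    keep = np.ones(gt.n_markers, dtype=bool)
    report = FilterReport()

    if exclude_markers:
        for j, name in enumerate(marker_map.name):
            if name in exclude_markers:
                keep[j] = False
                report.removed_loci[str(name)] = "manifest_excluded"

    het, callrate, _ = _per_breed_stats(gt)
    n_high_het = (het > het_threshold).sum(axis=0)
    n_low_call = (callrate < callrate_threshold).sum(axis=0)
    missing_frac = gt.missing_mask().mean(axis=0)

    for j in range(gt.n_markers):
        if not keep[j]:
            continue
        name = str(marker_map.name[j])
        if n_high_het[j] >= n_breed_threshold:
            keep[j] = False
            report.removed_loci[name] = HIGH_HET
        elif n_low_call[j] >= n_breed_threshold:
            keep[j] = False
            report.removed_loci[name] = LOW_CALLRATE
        elif missing_frac[j] >= missing_ind_threshold:
            keep[j] = False
            report.removed_loci[name] = MISSING_70

    idx = np.flatnonzero(keep)
    return gt.subset_markers(idx), marker_map.subset(idx), report


def filter_missingness(
    gt: GenotypeTable,
    marker_map: MarkerMap,
    ind_threshold: float = 0.10,
    locus_threshold: float = 0.10,
) -> tuple[GenotypeTable, MarkerMap, FilterReport]:
    """Drop individuals with > ``ind_threshold`` missing data, then loci
    missing in > ``locus_threshold`` of the remaining individuals.

    Both comparisons are strict, so an individual missing exactly 10% of
    loci survives. The order matters: a locus can become droppable only
    after high-missingness individuals leave.
    """
    if gt.n_individuals == 0 or gt.n_markers == 0:
        raise ParameterError("cannot filter an empty genotype table")
    report = FilterReport()

    ind_missing = gt.missing_mask().mean(axis=1)
    keep_ind = ind_missing <= ind_threshold
    for i in np.flatnonzero(~keep_ind):
        report.removed_individuals[str(gt.individuals[i])] = MISSING_10
    if not keep_ind.any():
        raise ParameterError(
            "all individuals exceed the missingness threshold; review ind_threshold"
        )
    gt = gt.subset_individuals(np.flatnonzero(keep_ind))

    locus_missing = gt.missing_mask().mean(axis=0)
    keep_loc = locus_missing <= locus_threshold
    for j in np.flatnonzero(~keep_loc):
        report.removed_loci[str(marker_map.name[j])] = MISSING_10
    idx = np.flatnonzero(keep_loc)
    return gt.subset_markers(idx), marker_map.subset(idx), report


def exclude_par(marker_map: MarkerMap, par_start_bp: int = PAR_START_BP) -> MarkerMap:
    """Drop X markers inside the pseudoautosomal region.

    ``par_start_bp`` is given in the 1-based assembly coordinates in which
    the boundary is conventionally quoted; internally positions are 0-based,
    so a marker is removed when ``pos_bp >= par_start_bp - 1`` on "X".
    Autosomes are untouched; maps without an X chromosome pass through.
    """
    threshold0 = par_start_bp - 1  # convert 1-based boundary to 0-based
    keep = ~((marker_map.chrom == "X") & (marker_map.pos_bp >= threshold0))
    return marker_map.subset(np.flatnonzero(keep))


def assign_sex(
    gt: GenotypeTable,
    marker_map: MarkerMap,
    het_threshold: float = 0.01,
) -> tuple[SexAssignment, GenotypeTable]:
    """Assign sex from X heterozygosity and recode male X hets as missing.

    An individual is male when the fraction of its non-missing X calls that
    are heterozygous is below ``het_threshold`` (the margin absorbs
    genotyping error); residual heterozygous X calls in males are recoded to
    missing, since a hemizygous X cannot truly be heterozygous. The marker
    map must already have the pseudoautosomal region excluded.
    """
    x_cols = np.flatnonzero(marker_map.chrom == "X")
    if len(x_cols) == 0:
        raise ParameterError("no X-linked markers available for sex assignment")
    x_calls = gt.calls[:, x_cols]
    called = x_calls != MISSING
    n_called = called.sum(axis=1)
    n_het = (x_calls == 1).sum(axis=1)

    sex: dict[str, str] = {}
    het_frac: dict[str, float] = {}
    unassigned: list[str] = []
    calls = gt.calls.copy()
    for i in range(gt.n_individuals):
        ind = str(gt.individuals[i])
        if n_called[i] == 0:
            unassigned.append(ind)
            continue
        frac = n_het[i] / n_called[i]
        het_frac[ind] = float(frac)
        if frac < het_threshold:
            sex[ind] = "male"
            het_cols = x_cols[x_calls[i] == 1]
            calls[i, het_cols] = MISSING
        else:
            sex[ind] = "female"

    out = GenotypeTable(gt.individuals, gt.breed, calls)
    return SexAssignment(sex=sex, x_het_fraction=het_frac, unassigned=unassigned), out
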