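"""Synthetic admixture data with known ancestry tracts.

The generator emulates the study system end-to-end: two source populations
diverged by drift (Balding–Nichols allele frequencies around a common
ancestral frequency, with SNP-chip-style ascertainment toward high minor
allele frequencies), a single admixture pulse contributing a proportion
``m`` of ancestry B ``g`` generations ago, and recombination each
generation. Every simulated haplotype comes with its true ancestry tracts,
so the painter, the block caller and the SBS statistic can all be validated
against ground truth.

Two admixture engines are provided:

* :func:`sim_admixed_forward` — explicit diploid Wright–Fisher forward
  simulation with Poisson crossovers; exact but O(N * g).
* :func:`sim_admixed_pulse` — the standard Markovian approximation in
  which tract breakpoints form a Poisson process of rate ``g`` per Morgan
  and tract ancestries are i.i.d. B with probability ``m``. Valid for
  g << N (before drift correlates tracts); used for large/old cohorts.

Within founder panels, loci are independent given population frequencies
(no background LD) — ancestry structure, not haplotype structure, is what
the downstream statistics consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .painter import DonorPanels
from .types import HaplotypePanel, MarkerMap, ParameterError


@dataclass
class SimConfig:
    """Simulation parameters.

    Defaults describe a deliberately tractable cattle-like genome: 10
    chromosomes of 100 cM carrying 300 evenly spaced chip markers each,
    source populations at Fst-like divergence F = 0.2 (deeply split
    lineages), an admixture pulse of m = 0.33 (the introgressed fraction
    reported for known recent hybrid breeds) g = 25 generations ago, and a
    diploid admixed population of N = 1000 from which 50 individuals are
    sampled. Chip ascertainment keeps loci with combined minor allele
    frequency >= 0.1.
    """

    n_loci: int = 300
    n_chrom: int = 10
    chrom_length_cm: float = 100.0
    F: float = 0.2
    m: float = 0.33
    g: int = 25
    N: int = 1000
    n_sample: int = 50
    maf_min: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_loci, self.n_chrom, self.g, self.N, self.n_sample) < 1:
            raise ParameterError("counts and g must be positive")
        if not (0 <= self.F <= 1):
            raise ParameterError("F must lie in [0, 1]")
        if not (0 <= self.m <= 1):
            raise ParameterError("m must lie in [0, 1]")
        if not (0 <= self.maf_min < 0.5):
            raise ParameterError("maf_min must lie in [0, 0.5)")
        if self.chrom_length_cm <= 0:
            raise ParameterError("chrom_length_cm must be positive")
        if self.N < self.n_sample:
            raise ParameterError("cannot sample more individuals than the population holds")


@dataclass
class TruthSet:
    """Ground-truth ancestry for a simulated cohort.

    ``labels`` is (haplotypes x markers) with 0 = ancestry A, 1 = B;
    ``tracts`` maps (haplotype_id, chrom) to [(start_cm, end_cm, "A"/"B")]
    intervals tiling the chromosome.
    """

    haplotype_ids: np.ndarray
    labels: np.ndarray
    tracts: dict = field(default_factory=dict)

    def minority_fraction(self, hap_indices: np.ndarray) -> float:
        lab = self.labels[hap_indices]
        frac_b = float(lab.mean())
        return min(frac_b, 1 - frac_b)


def build_marker_map(cfg: SimConfig) -> MarkerMap:
    """Evenly spaced markers; bp positions at 1 cM/Mb so physical and
    genetic coordinates stay mutually consistent."""
    chroms, names, bps, cms = [], [], [], []
    for c in range(1, cfg.n_chrom + 1):
        for j in range(cfg.n_loci):
            cm = (j + 0.5) * cfg.chrom_length_cm / cfg.n_loci
            chroms.append(str(c))
            names.append(f"snp{c}_{j + 1}")
            cms.append(cm)
            bps.append(int(round(cm * 1e6)))
    return MarkerMap(
        chrom=np.array(chroms, dtype=object),
        name=np.array(names, dtype=object),
        pos_bp=np.array(bps, dtype=np.int64),
        pos_cm=np.array(cms, dtype=float),
    )


def _balding_nichols(rng: np.random.Generator, p0: np.ndarray, F: float) -> np.ndarray:
    if F < 1e-12:
        return p0.copy()
    if F > 1 - 1e-12:
        return (rng.random(p0.shape) < p0).astype(float)
    a = p0 * (1 - F) / F
    b = (1 - p0) * (1 - F) / F
    return rng.beta(a, b)


def sim_divergent_panels(
    cfg: SimConfig, n_A: int = 100, n_B: int = 100, max_rounds: int = 200
) -> tuple[DonorPanels, tuple[np.ndarray, np.ndarray]]:
    """Draw two drift-diverged donor panels plus their allele frequencies.

    Ancestral frequencies are Uniform(0.05, 0.95) per locus; population
    frequencies follow the Balding–Nichols distribution with parameter F,
    independently for the two populations. Loci whose combined (mean of the
    two populations) minor allele frequency falls below ``maf_min`` are
    redrawn, mimicking SNP-chip ascertainment toward common variants.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_loci = cfg.n_loci * cfg.n_chrom
    p_a = np.empty(n_loci)
    p_b = np.empty(n_loci)
    todo = np.arange(n_loci)
    for _ in range(max_rounds):
        if todo.size == 0:
            break
        p0 = rng.uniform(0.05, 0.95, size=todo.size)
        pa = _balding_nichols(rng, p0, cfg.F)
        pb = _balding_nichols(rng, p0, cfg.F)
        combined = (pa + pb) / 2.0
        ok = np.minimum(combined, 1 - combined) >= cfg.maf_min
        p_a[todo[ok]] = pa[ok]
        p_b[todo[ok]] = pb[ok]
        todo = todo[~ok]
    if todo.size:
        raise ParameterError(
            f"could not ascertain {todo.size} loci at maf_min={cfg.maf_min} "
            f"after {max_rounds} redraw rounds; lower maf_min"
        )

    def _panel(p: np.ndarray, n_hap: int, prefix: str) -> HaplotypePanel:
        alleles = (rng.random((n_hap, n_loci)) < p[None, :]).astype(np.int8)
        ids = np.array(
            [f"{prefix}{i // 2 + 1}_{i % 2}" for i in range(n_hap)], dtype=object
        )
        labels = np.array([prefix.rstrip("_")] * n_hap, dtype=object)
        return HaplotypePanel(haplotype_ids=ids, alleles=alleles, labels=labels)

    panels = DonorPanels(panel_A=_panel(p_a, n_A, "donA"), panel_B=_panel(p_b, n_B, "donB"))
    panels.validate()
    return panels, (p_a, p_b)


def _emit_alleles(
    rng: np.random.Generator,
    labels: np.ndarray,
    freqs: tuple[np.ndarray, np.ndarray],
) -> np.ndarray:
    """Sample alleles per marker from the tract-ancestry population frequency."""
    p_a, p_b = freqs
    p = np.where(labels == 0, p_a[None, :], p_b[None, :])
    return (rng.random(labels.shape) < p).astype(np.int8)


def _tracts_to_marker_labels(
    breaks_cm: np.ndarray, seg_labels: np.ndarray, marker_cm: np.ndarray
) -> np.ndarray:
    """Ancestry label at each marker given segment breakpoints (cM)."""
    return seg_labels[np.searchsorted(breaks_cm, marker_cm, side="right")]


def sim_admixed_pulse(
    cfg: SimConfig, freqs: tuple[np.ndarray, np.ndarray], id_prefix: str = "sim"
) -> tuple[HaplotypePanel, TruthSet, MarkerMap]:
    """Sample an admixed cohort under the Poisson-tract pulse approximation.

    Per haplotype-chromosome, breakpoints form a Poisson process of rate g
    per Morgan; tract ancestries are i.i.d. B with probability m. This is
    the classical single-pulse approximation, accurate while g << N; used
    for comparative (recent vs ancient) questions rather than absolute
    dating.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1)
    marker_map = build_marker_map(cfg)
    n_hap = 2 * cfg.n_sample
    morgan = cfg.chrom_length_cm / 100.0

    hap_ids = np.array(
        [f"{id_prefix}{i // 2 + 1}_{i % 2}" for i in range(n_hap)], dtype=object
    )
    labels = np.empty((n_hap, marker_map.n_markers), dtype=np.int8)
    tracts: dict = {}
    for h in range(n_hap):
        for c in range(1, cfg.n_chrom + 1):
            idx = marker_map.chrom_indices(str(c))
            marker_cm = marker_map.pos_cm[idx]
            k = rng.poisson(cfg.g * morgan)
            breaks = np.sort(rng.uniform(0, cfg.chrom_length_cm, size=k))
            seg_lab = (rng.random(k + 1) < cfg.m).astype(np.int8)
            labels[h, idx] = _tracts_to_marker_labels(breaks, seg_lab, marker_cm)
            # merge adjacent same-label segments so tracts are maximal runs,
            # comparable with the forward engine's output
            keep = np.flatnonzero(np.diff(seg_lab) != 0)
            edges = np.concatenate(([0.0], breaks[keep], [cfg.chrom_length_cm]))
            run_lab = seg_lab[np.concatenate(([0], keep + 1))]
            tracts[(str(hap_ids[h]), str(c))] = [
                (float(edges[s]), float(edges[s + 1]), "B" if run_lab[s] else "A")
                for s in range(len(run_lab))
            ]

    alleles = _emit_alleles(rng, labels, freqs)
    panel = HaplotypePanel(
        haplotype_ids=hap_ids,
        alleles=alleles,
        labels=np.array(["admixed"] * n_hap, dtype=object),
    )
    return panel, TruthSet(haplotype_ids=hap_ids, labels=labels, tracts=tracts), marker_map


def _recombine(
    rng: np.random.Generator,
    hap0: tuple[np.ndarray, np.ndarray],
    hap1: tuple[np.ndarray, np.ndarray],
    length_cm: float,
) -> tuple[np.ndarray, np.ndarray]:
    """One meiosis: Poisson crossovers between two parental tract lists.

    Haplotypes are (breakpoints_cm, segment_labels) with len(labels) =
    len(breaks) + 1.
    """
    k = rng.poisson(length_cm / 100.0)
    start = int(rng.integers(2))
    if k == 0:
        br, lab = hap0 if start == 0 else hap1
        return br.copy(), lab.copy()
    xs = np.sort(rng.uniform(0, length_cm, size=k))
    parents = (hap0, hap1)
    edges = np.concatenate(([0.0], xs, [length_cm]))
    out_breaks: list[float] = []
    out_labels: list[int] = []
    cur = start
    for s in range(k + 1):
        lo, hi = float(edges[s]), float(edges[s + 1])
        br, lab = parents[cur]
        # parent segment j covers [br[j-1], br[j]); find the one holding lo
        j = int(np.searchsorted(br, lo, side="right"))
        pos = lo
        while pos < hi:
            seg_end = float(br[j]) if j < len(br) else length_cm
            seg_lab = int(lab[j])
            if not out_labels or out_labels[-1] != seg_lab:
                if out_labels:
                    out_breaks.append(pos)
                out_labels.append(seg_lab)
            pos = min(seg_end, hi)
            j += 1
        cur = 1 - cur
    return np.array(out_breaks), np.array(out_labels, dtype=np.int8)


def sim_admixed_forward(
    cfg: SimConfig, freqs: tuple[np.ndarray, np.ndarray], id_prefix: str = "sim"
) -> tuple[HaplotypePanel, TruthSet, MarkerMap]:
    """Forward diploid Wright–Fisher simulation of the admixture pulse.

    Generation 0 holds N founder individuals, each wholly ancestry B with
    probability m (every founder chromosome a single full-length tract), so
    generation-1 haplotypes are unrecombined F1 gametes. Every generation each offspring
    haplotype is a recombinant of one uniformly chosen parent's two
    haplotypes (Poisson(chromosome length in Morgans) crossovers at uniform
    genetic positions). After g generations n_sample individuals are drawn
    without replacement.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 2)
    marker_map = build_marker_map(cfg)
    L = cfg.chrom_length_cm
    n_hap_pop = 2 * cfg.N

    # population[h][c] = (breaks, labels) tract list per chromosome.
    # Founder ancestry is assigned per *individual* (both haplotypes alike):
    # the pulse unites whole migrants, so first-generation offspring are F1s
    # whose chromosomes are still single unrecombined tracts.
    population = []
    for ind in range(cfg.N):
        lab_val = 1 if rng.random() < cfg.m else 0
        for _ in range(2):
            lab = np.array([lab_val], dtype=np.int8)
            population.append([(np.empty(0), lab.copy()) for _ in range(cfg.n_chrom)])

    for _ in range(cfg.g):
        nxt = []
        parents = rng.integers(cfg.N, size=n_hap_pop)
        for h in range(n_hap_pop):
            p = int(parents[h])
            haps = [
                _recombine(rng, population[2 * p][c], population[2 * p + 1][c], L)
                for c in range(cfg.n_chrom)
            ]
            nxt.append(haps)
        population = nxt

    chosen = rng.choice(cfg.N, size=cfg.n_sample, replace=False)
    hap_ids = np.array(
        [f"{id_prefix}{i // 2 + 1}_{i % 2}" for i in range(2 * cfg.n_sample)], dtype=object
    )
    labels = np.empty((2 * cfg.n_sample, marker_map.n_markers), dtype=np.int8)
    tracts: dict = {}
    for out_i in range(2 * cfg.n_sample):
        ind = int(chosen[out_i // 2])
        src = population[2 * ind + out_i % 2]
        for c in range(cfg.n_chrom):
            idx = marker_map.chrom_indices(str(c + 1))
            breaks, seg_lab = src[c]
            labels[out_i, idx] = _tracts_to_marker_labels(
                breaks, seg_lab, marker_map.pos_cm[idx]
            )
            edges = np.concatenate(([0.0], breaks, [L]))
            tracts[(str(hap_ids[out_i]), str(c + 1))] = [
                (float(edges[s]), float(edges[s + 1]), "B" if seg_lab[s] else "A")
                for s in range(len(seg_lab))
            ]

    alleles = _emit_alleles(rng, labels, freqs)
    panel = HaplotypePanel(
        haplotype_ids=hap_ids,
        alleles=alleles,
        labels=np.array(["admixed"] * (2 * cfg.n_sample), dtype=object),
    )
    return panel, TruthSet(haplotype_ids=hap_ids, labels=labels, tracts=tracts), marker_map


def truth_painting(truth: TruthSet) -> "AncestryPainting":
    """Oracle painting with posterior 1 for the true ancestry at every site."""
    from .types import AncestryPainting

    return AncestryPainting(
        haplotype_ids=truth.haplotype_ids.copy(),
        prob_A=(truth.labels == 0).astype(float),
    )


def mean_tract_length_morgans(truth: TruthSet, label: str = "B") -> float:
    """Mean length (Morgans) of tracts of one ancestry across the cohort."""
    lengths = [
        (hi - lo) / 100.0
        for segs in truth.tracts.values()
        for (lo, hi, lab) in segs
        if lab == label
    ]
    if not lengths:
        raise ParameterError(f"no tracts with label {label}")
    return float(np.mean(lengths))
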