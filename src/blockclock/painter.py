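"""Two-panel haplotype-copying HMM ("chromosome painting").

Each target haplotype is modelled as an imperfect mosaic copy of donor
haplotypes drawn from two reference panels (A and B). Hidden states are the
individual donor haplotypes; the posterior probability that a site was
copied from panel A is the local-ancestry estimate.

Model
-----
* initial distribution: probability mass 1/2 per panel, uniform within a
  panel (equal a-priori copying probabilities for the two donor
  populations);
* between adjacent markers at genetic distance ``d`` cM the chain switches
  to a uniformly chosen donor (over both panels) with probability
  ``1 - exp(-rho * d)`` and otherwise stays;
* emission: the target allele matches the donor's with probability
  ``1 - epsilon``; a missing allele on either side is uninformative
  (emission probability 1).

Posteriors come from the scaled forward–backward recursion, renormalized at
every site, and each chromosome is an independent chain. Genetic distances
default to physical distance at a uniform cM/Mb rate when the map carries
no genetic positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import (
    DEFAULT_CM_PER_MB,
    MISSING,
    AncestryPainting,
    HaplotypePanel,
    MarkerMap,
    ParameterError,
)

#: effective-population-size surrogate for the pooled cattle breeds; the
#: default switch rate below is the package's calibration consistent with it
NE_SURROGATE = 4000


@dataclass
class PainterParams:
    """Copying-model parameters.

    Parameters
    ----------
    rho : float
        Ancestry-switch rate per centimorgan. The default 0.1 gives an
        expected ~10 copying switches per Morgan, a deliberately coarse
        rate suited to detecting ancestry tracts rather than fine-scale
        haplotype sharing.
    epsilon : float
        Per-site miscopy probability, in (0, 0.5). This absorbs both
        genotyping error and the fact that a target is never a literal
        mosaic of a finite donor panel, so it is set well above a raw
        genotyping-error rate; 0.15 calibrates the painter to recover
        simulated ancestry tracts reliably on low-LD chip data.
    panel_prior : float
        Prior probability of copying from panel A at the first marker;
        fixed at 0.5 (equal priors for the two donor populations).
    """

    rho: float = 0.1
    epsilon: float = 0.15
    panel_prior: float = 0.5

    def validate(self) -> None:
        if not self.rho > 0:
            raise ParameterError(f"rho must be positive, got {self.rho}")
        if not (0 < self.epsilon < 0.5):
            raise ParameterError(f"epsilon must lie in (0, 0.5), got {self.epsilon}")
        if self.panel_prior != 0.5:
            raise ParameterError("panel_prior is fixed at 0.5 in the two-panel model")


@dataclass
class DonorPanels:
    """The two donor reference panels (A: taurine-role, B: indicine-role)."""

    panel_A: HaplotypePanel
    panel_B: HaplotypePanel

    def validate(self) -> None:
        if self.panel_A.n_haplotypes == 0 or self.panel_B.n_haplotypes == 0:
            raise ParameterError("both donor panels must be nonempty")
        if self.panel_A.n_markers != self.panel_B.n_markers:
            raise ParameterError("donor panels disagree on marker count")


def select_donor_panels(
    global_ancestry: dict[str, float],
    candidates: HaplotypePanel,
    threshold: float = 0.02,
) -> DonorPanels:
    """Pick donor haplotypes from individuals with < ``threshold``
    introgressed ancestry.

    ``global_ancestry`` maps individual id to its proportion of ancestry A.
    Panel A takes haplotypes of individuals whose ancestry-B proportion is
    strictly below the threshold; panel B symmetrically. Everything else is
    excluded (admixed; paintable but not a donor).
    """
    a_idx, b_idx = [], []
    for i in range(candidates.n_haplotypes):
        ind = candidates.individual_of(i)
        if ind not in global_ancestry:
            raise ParameterError(f"no global ancestry estimate for individual {ind}")
        prop_a = global_ancestry[ind]
        if 1.0 - prop_a < threshold:
            a_idx.append(i)
        elif prop_a < threshold:
            b_idx.append(i)
    if not a_idx or not b_idx:
        raise ParameterError(
            f"no pure donors on one side at the {threshold:.0%} introgression threshold"
        )
    panels = DonorPanels(
        panel_A=candidates.subset(np.asarray(a_idx)),
        panel_B=candidates.subset(np.asarray(b_idx)),
    )
    panels.validate()
    return panels


def _emissions(target: np.ndarray, donors: np.ndarray, epsilon: float) -> np.ndarray:
    """Emission matrix (markers x donor states); missing alleles emit 1."""
    t = target[None, :]
    match = donors == t
    em = np.where(match, 1.0 - epsilon, epsilon)
    uninformative = (t == MISSING) | (donors == MISSING)
    em[uninformative] = 1.0
    return em.T.copy()


def _forward_backward(
    em: np.ndarray, switch: np.ndarray, init: np.ndarray
) -> np.ndarray:
    """Scaled forward–backward for the uniform-switch copying chain.

    ``em``: (n_markers, n_states) emissions; ``switch``: per-interval switch
    probabilities (length n_markers - 1); ``init``: initial distribution.
    Returns the (n_markers, n_states) posterior.
    """
    n_m, n_s = em.shape
    fwd = np.empty_like(em)
    scale = np.empty(n_m)
    f = init * em[0]
    scale[0] = f.sum()
    fwd[0] = f / scale[0]
    for j in range(1, n_m):
        r = switch[j - 1]
        # transition kernel: (1-r) I + (r/n) 11^T; previous row sums to 1
        f = ((1.0 - r) * fwd[j - 1] + r / n_s) * em[j]
        scale[j] = f.sum()
        fwd[j] = f / scale[j]

    post = np.empty_like(em)
    b = np.ones(n_s)
    post[n_m - 1] = fwd[n_m - 1]
    for j in range(n_m - 2, -1, -1):
        r = switch[j]
        eb = em[j + 1] * b
        b = ((1.0 - r) * eb + r / n_s * eb.sum()) / scale[j + 1]
        p = fwd[j] * b
        post[j] = p / p.sum()
    return post


def paint_haplotype(
    target: np.ndarray,
    panels: DonorPanels,
    marker_map: MarkerMap,
    params: PainterParams | None = None,
    cm_per_mb: float = DEFAULT_CM_PER_MB,
) -> np.ndarray:
    """Posterior probability of copying from panel A at every marker.

    Chromosomes are painted as independent chains. Raises if a chromosome
    with several markers has zero total genetic length (degenerate chain).
    """
    params = params or PainterParams()
    params.validate()
    panels.validate()
    target = np.asarray(target, dtype=np.int8)
    if target.shape[0] != marker_map.n_markers:
        raise ParameterError("target haplotype and marker map disagree on marker count")

    n_a = panels.panel_A.n_haplotypes
    n_b = panels.panel_B.n_haplotypes
    donors = np.vstack([panels.panel_A.alleles, panels.panel_B.alleles])
    n_s = n_a + n_b
    init = np.concatenate(
        [np.full(n_a, params.panel_prior / n_a), np.full(n_b, (1 - params.panel_prior) / n_b)]
    )

    prob_a = np.empty(marker_map.n_markers)
    gpos = marker_map.genetic_positions(cm_per_mb)
    for chrom in marker_map.chromosomes():
        idx = marker_map.chrom_indices(chrom)
        em = _emissions(target[idx], donors[:, idx], params.epsilon)
        if len(idx) == 1:
            f = init * em[0]
            post = (f / f.sum())[None, :]
        else:
            d = np.diff(gpos[idx])
            if np.all(d <= 0):
                raise ParameterError(
                    f"chromosome {chrom}: zero genetic distance between all markers "
                    "(degenerate chain); supply genetic positions or a cm_per_mb rate"
                )
            switch = 1.0 - np.exp(-params.rho * d)
            post = _forward_backward(em, switch, init)
        prob_a[idx] = post[:, :n_a].sum(axis=1)
    return prob_a


def paint_cohort(
    targets: HaplotypePanel,
    panels: DonorPanels,
    marker_map: MarkerMap,
    params: PainterParams | None = None,
    cm_per_mb: float = DEFAULT_CM_PER_MB,
) -> AncestryPainting:
    """Paint every target haplotype; rows align with ``targets`` order."""
    rows = np.empty((targets.n_haplotypes, marker_map.n_markers))
    for i in range(targets.n_haplotypes):
        rows[i] = paint_haplotype(targets.alleles[i], panels, marker_map, params, cm_per_mb)
    return AncestryPainting(haplotype_ids=targets.haplotype_ids.copy(), prob_A=rows)


def global_ancestry_from_painting(painting: AncestryPainting) -> dict[str, float]:
    """Mean panel-A posterior per individual (averaging its haplotypes)."""
    acc: dict[str, list[float]] = {}
    for i in range(painting.n_haplotypes):
        ind = str(painting.haplotype_ids[i]).rsplit("_", 1)[0]
        acc.setdefault(ind, []).append(float(painting.prob_A[i].mean()))
    return {ind: float(np.mean(v)) for ind, v in acc.items()}
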