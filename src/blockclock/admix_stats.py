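"""Resampling tests for chromosome-level ancestry deviations.

Given per-individual, per-chromosome ancestry proportions within a group,
these tests ask whether any chromosome departs from the group's overall
ancestry pattern under the null of uniform admixture across chromosomes:

* :func:`bootstrap_median_test` — pool every (individual, chromosome) value
  of the group, repeatedly resample "new chromosomes" (n values with
  replacement, n = group size) and record their medians; a chromosome whose
  observed median falls outside the empirical two-tailed cutoffs at the
  Bonferroni-corrected level is flagged. p-values are reported as the bound
  (c + 1) / n_reps at the resampling resolution.
* :func:`permutation_variability_test` — one-way ANOVA on the absolute
  deviations from each chromosome's group median, with the F null built by
  permuting chromosome labels (the deviations are far from normal, so the
  parametric F reference is not trusted).

Ancestry proportions may come from the built-in painter
(:func:`chromosome_ancestry_proportions`) or from any external source via a
plain individual x chromosome table.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .blocks_sbs import _marker_runs
from .types import AncestryPainting, MarkerMap, ParameterError, chrom_sort_key


@dataclass
class ChromAncestryMatrix:
    """Proportion of ancestry A per individual per chromosome."""

    individuals: np.ndarray
    chromosomes: list[str]
    value: np.ndarray  # (n_individuals, n_chromosomes)
    group: np.ndarray  # group/breed label per individual

    def group_values(self, group: str) -> np.ndarray:
        sel = self.group == group
        if sel.sum() < 2:
            raise ParameterError(f"group {group!r} needs at least 2 individuals")
        vals = self.value[sel, :]
        if np.isnan(vals).any():
            raise ParameterError(
                f"group {group!r} has missing chromosome ancestry entries"
            )
        return vals


@dataclass
class ChromTestRow:
    chrom: str
    observed_median: float
    obs_min: float
    obs_max: float
    p_bound: float
    significant: bool


@dataclass
class BootstrapTestResult:
    """Bootstrap median test output for one group."""

    group: str
    alpha_corrected: float
    n_reps: int
    seed: int
    lower_cutoff: float
    upper_cutoff: float
    pool_median: float
    rows: list[ChromTestRow] = field(default_factory=list)

    def significant_chromosomes(self) -> list[str]:
        return [r.chrom for r in self.rows if r.significant]

    def to_rows(self) -> list[dict]:
        return [
            {
                "group": self.group,
                "chrom": r.chrom,
                "observed_median": r.observed_median,
                "range_low": r.obs_min,
                "range_high": r.obs_max,
                "lower_cutoff": self.lower_cutoff,
                "upper_cutoff": self.upper_cutoff,
                "p_bound": r.p_bound,
                "significant": r.significant,
            }
            for r in self.rows
        ]


def chromosome_ancestry_proportions(
    painting: AncestryPainting,
    marker_map: MarkerMap,
    groups: Optional[Mapping[str, str]] = None,
    threshold: float = 0.75,
) -> ChromAncestryMatrix:
    """Per-chromosome ancestry-A proportions from a painting.

    For each haplotype-chromosome, ancestry-A bp over labelled (non-
    uncertain) bp at the block-calling threshold; an individual's value is
    the mean of its two haplotypes. Chromosomes with no labelled bp yield
    NaN (rejected later if the individual enters a tested group).
    """
    chroms = marker_map.chromosomes()
    chrom_idx = {c: marker_map.chrom_indices(c) for c in chroms}

    per_hap: dict[str, dict[str, list[float]]] = {}
    for i in range(painting.n_haplotypes):
        ind = str(painting.haplotype_ids[i]).rsplit("_", 1)[0]
        slot = per_hap.setdefault(ind, {c: [] for c in chroms})
        for c in chroms:
            idx = chrom_idx[c]
            starts, ends, labels = _marker_runs(
                painting.prob_A[i, idx], marker_map.pos_bp[idx], threshold
            )
            lengths = (ends - starts).astype(float)
            a = lengths[labels == 0].sum()
            b = lengths[labels == 2].sum()
            slot[c].append(a / (a + b) if a + b > 0 else math.nan)

    individuals = sorted(per_hap)
    value = np.full((len(individuals), len(chroms)), np.nan)
    for r, ind in enumerate(individuals):
        for k, c in enumerate(chroms):
            vals = [v for v in per_hap[ind][c]]
            value[r, k] = float(np.mean(vals))
    group = np.array(
        [groups.get(ind, "all") if groups else "all" for ind in individuals], dtype=object
    )
    return ChromAncestryMatrix(
        individuals=np.array(individuals, dtype=object),
        chromosomes=list(chroms),
        value=value,
        group=group,
    )


def matrix_from_table(df, group_col: str = "group") -> ChromAncestryMatrix:
    """Build a ChromAncestryMatrix from a DataFrame (individual, group,
    one column per chromosome) — the drop-in path for externally estimated
    ancestry proportions."""
    chroms = [c for c in df.columns if c not in ("individual", group_col)]
    chroms = sorted(chroms, key=chrom_sort_key)
    return ChromAncestryMatrix(
        individuals=df["individual"].to_numpy(dtype=object),
        chromosomes=chroms,
        value=df[chroms].to_numpy(dtype=float),
        group=df[group_col].to_numpy(dtype=object),
    )


def bonferroni_alpha(
    familywise_two_tailed: float = 0.05, n_chromosomes: int = 30, n_groups: int = 4
) -> tuple[float, float]:
    """Bonferroni-corrected per-test alpha for a two-tailed family.

    Halves the familywise level for the two-tailed test, then divides by
    the number of chromosome x group tests. Returns the exact value and a
    1-significant-figure display value (defaults: 0.025/120 ~ 2.08e-4,
    displayed 0.0002).
    """
    if n_chromosomes < 1 or n_groups < 1:
        raise ParameterError("counts must be positive")
    exact = (familywise_two_tailed / 2.0) / (n_chromosomes * n_groups)
    display = float(f"{exact:.0e}")
    return exact, display


def bootstrap_median_test(
    m: ChromAncestryMatrix,
    group: str,
    n_reps: int = 50_000,
    alpha: float = 0.0002,
    seed: int = 0,
) -> BootstrapTestResult:
    """Pooled-bootstrap test for chromosomes deviating in median ancestry.

    The pool holds every (individual, chromosome) value in the group. Each
    replicate draws n values with replacement (n = group size, one
    synthetic chromosome) and records the median. Cutoffs are the empirical
    alpha/2 and 1-alpha/2 quantiles of replicate medians; a chromosome is
    significant when its observed median falls outside them. The per-
    chromosome p is reported as the upper bound (c + 1) / n_reps with c the
    number of replicates at least as extreme in the nearer tail.
    """
    if n_reps < 1.0 / alpha:
        raise ParameterError(
            f"n_reps={n_reps} cannot resolve quantiles at alpha={alpha}; "
            f"need at least {math.ceil(1.0 / alpha)} replicates"
        )
    vals = m.group_values(group)  # (n_ind, n_chrom)
    n = vals.shape[0]
    pool = vals.ravel()

    rng = np.random.default_rng(seed)
    draws = rng.choice(pool, size=(n_reps, n), replace=True)
    rep_medians = np.median(draws, axis=1)
    lower, upper = np.quantile(rep_medians, [alpha / 2.0, 1.0 - alpha / 2.0])

    rows = []
    for k, chrom in enumerate(m.chromosomes):
        col = vals[:, k]
        obs = float(np.median(col))
        c = int(min((rep_medians <= obs).sum(), (rep_medians >= obs).sum()))
        rows.append(
            ChromTestRow(
                chrom=chrom,
                observed_median=obs,
                obs_min=float(col.min()),
                obs_max=float(col.max()),
                p_bound=(c + 1) / n_reps,
                significant=bool(obs < lower or obs > upper),
            )
        )
    return BootstrapTestResult(
        group=group,
        alpha_corrected=alpha,
        n_reps=n_reps,
        seed=seed,
        lower_cutoff=float(lower),
        upper_cutoff=float(upper),
        pool_median=float(np.median(pool)),
        rows=rows,
    )


def _oneway_f(columns: np.ndarray) -> float:
    """One-way ANOVA F with the matrix columns as groups.

    Hand-rolled so degenerate cases are explicit: zero within-group
    variance with positive between-group variance gives +inf; zero
    between-group variance gives 0.
    """
    grand = columns.mean()
    n_per = columns.shape[0]
    k = columns.shape[1]
    means = columns.mean(axis=0)
    ssb = n_per * ((means - grand) ** 2).sum()
    ssw = ((columns - means) ** 2).sum()
    if ssb == 0:
        return 0.0
    if ssw == 0:
        return math.inf
    return float((ssb / (k - 1)) / (ssw / (k * n_per - k)))


def permutation_variability_test(
    m: ChromAncestryMatrix,
    group: str,
    n_reps: int = 5000,
    seed: int = 0,
    exact: bool = False,
) -> tuple[float, float]:
    """Permutation ANOVA on deviations from per-chromosome group medians.

    d[i, c] = |value[i, c] - median_i(value[., c])|; the observed statistic
    is the one-way F with chromosomes as groups. The null is built by
    permuting chromosome labels over the pooled deviations. With
    ``exact=True`` (feasible only for tiny pools, <= 8 values) all distinct
    permutations are enumerated and p is the exact tail fraction; otherwise
    p = (#{F_perm >= F_obs} + 1) / (n_reps + 1).
    """
    vals = m.group_values(group)
    if vals.shape[1] < 2:
        raise ParameterError("need at least 2 chromosomes")
    dev = np.abs(vals - np.median(vals, axis=0, keepdims=True))
    f_obs = _oneway_f(dev)
    if not np.any(dev != dev.ravel()[0]):
        warnings.warn("zero total variance in deviations; p = 1", stacklevel=2)
        return f_obs, 1.0

    pool = dev.ravel()
    shape = dev.shape
    if exact:
        if pool.size > 8:
            raise ParameterError("exact enumeration limited to pools of <= 8 values")
        total = 0
        hits = 0
        for perm in itertools.permutations(range(pool.size)):
            f_p = _oneway_f(pool[list(perm)].reshape(shape))
            total += 1
            if f_p >= f_obs:
                hits += 1
        return f_obs, hits / total

    rng = np.random.default_rng(seed)
    hits = 0
    work = pool.copy()
    for _ in range(n_reps):
        rng.shuffle(work)
        if _oneway_f(work.reshape(shape)) >= f_obs:
            hits += 1
    return f_obs, (hits + 1) / (n_reps + 1)


def summary_stats(
    x: Sequence[float],
    y: Sequence[float],
    groups: Sequence[Sequence[float]],
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Pearson correlation between x and y, and a one-way ANOVA over groups.

    Standard parametric versions (t-approximation for r's p), used for the
    descriptive summaries rather than the resampling hypothesis tests.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ParameterError("x and y must have equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ParameterError("correlation undefined for zero-variance input")
    r, p_r = sps.pearsonr(x, y)
    f, p_f = sps.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    return (float(r), float(p_r)), (float(f), float(p_f))
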