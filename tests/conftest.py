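"""Shared fixtures and independent oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from blockclock import GenotypeTable, HaplotypePanel, MarkerMap


def enum_copying_posterior(
    target: np.ndarray,
    panel_a: np.ndarray,
    panel_b: np.ndarray,
    gpos_cm: np.ndarray,
    rho: float,
    eps: float,
) -> np.ndarray:
    """Brute-force panel-A posterior by summing over every donor path.

    Independent of the forward–backward implementation: enumerates all
    n_donors ** n_markers hidden paths of the copying chain (equal panel
    priors, uniform-switch transitions, symmetric miscopy emissions) and
    marginalizes. Only feasible for tiny instances.
    """
    donors = np.vstack([panel_a, panel_b])
    n, n_m = donors.shape
    n_a = panel_a.shape[0]
    init = np.concatenate([np.full(n_a, 0.5 / n_a), np.full(n - n_a, 0.5 / (n - n_a))])
    r = 1.0 - np.exp(-rho * np.diff(gpos_cm))

    def emis(j: int, s: int) -> float:
        if target[j] == -1 or donors[s, j] == -1:
            return 1.0
        return 1.0 - eps if donors[s, j] == target[j] else eps

    post = np.zeros((n_m, n))
    total = 0.0
    for path in itertools.product(range(n), repeat=n_m):
        p = init[path[0]] * emis(0, path[0])
        for j in range(1, n_m):
            trans = (1.0 - r[j - 1]) * (path[j] == path[j - 1]) + r[j - 1] / n
            p *= trans * emis(j, path[j])
        total += p
        for j in range(n_m):
            post[j, path[j]] += p
    post /= total
    return post[:, :n_a].sum(axis=1)


def hudson_fst(alleles_a: np.ndarray, alleles_b: np.ndarray) -> float:
    """Hudson-type Fst estimator (ratio of averages) from two haplotype sets."""
    pa = alleles_a.mean(axis=0)
    pb = alleles_b.mean(axis=0)
    na, nb = alleles_a.shape[0], alleles_b.shape[0]
    num = (pa - pb) ** 2 - pa * (1 - pa) / (na - 1) - pb * (1 - pb) / (nb - 1)
    den = pa * (1 - pb) + pb * (1 - pa)
    return float(num.sum() / den.sum())


@pytest.fixture
def hmm_oracle():
    return enum_copying_posterior


@pytest.fixture
def fst_oracle():
    return hudson_fst


@pytest.fixture
def toy_map() -> MarkerMap:
    """3 markers on chromosome 1, one on 2."""
    return MarkerMap(
        chrom=np.array(["1", "1", "1", "2"], dtype=object),
        name=np.array(["m1", "m2", "m3", "m4"], dtype=object),
        pos_bp=np.array([100, 200, 300, 50]),
    )


@pytest.fixture
def toy_genotypes(toy_map) -> GenotypeTable:
    return GenotypeTable(
        individuals=np.array(["i1", "i2"], dtype=object),
        breed=np.array(["Angus", "Brahman"], dtype=object),
        calls=np.array([[0, 1, 2, -1], [2, 2, 0, 1]], dtype=np.int8),
    )


@pytest.fixture
def small_panel() -> HaplotypePanel:
    rng = np.random.default_rng(7)
    alleles = rng.integers(0, 2, size=(4, 5)).astype(np.int8)
    return HaplotypePanel(
        haplotype_ids=np.array(["s1_0", "s1_1", "s2_0", "s2_1"], dtype=object),
        alleles=alleles,
        labels=np.array(["X", "X", "Y", "Y"], dtype=object),
    )
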