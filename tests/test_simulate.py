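"""Simulator self-checks against closed-form expectations."""

import numpy as np
import pytest

from blockclock import (
    ParameterError,
    SimConfig,
    sim_admixed_forward,
    sim_admixed_pulse,
    sim_divergent_panels,
    truth_painting,
)
from blockclock.simulate import build_marker_map, mean_tract_length_morgans


def _freqs_for(cfg, n=4):
    return sim_divergent_panels(cfg, n, n)[1]


class TestDivergentPanels:
    def test_no_drift_limit(self, fst_oracle):
        cfg = SimConfig(n_loci=1000, n_chrom=10, F=0.0, seed=1)
        panels, (pa, pb) = sim_divergent_panels(cfg, 100, 100)
        np.testing.assert_array_equal(pa, pb)
        assert abs(fst_oracle(panels.panel_A.alleles, panels.panel_B.alleles)) < 0.01

    def test_full_drift_fixes_loci(self):
        cfg = SimConfig(n_loci=100, n_chrom=2, F=1.0, maf_min=0.0, seed=2)
        panels, (pa, pb) = sim_divergent_panels(cfg, 20, 20)
        assert set(np.unique(pa)) <= {0.0, 1.0}
        col_means = panels.panel_A.alleles.mean(axis=0)
        assert set(np.unique(col_means)) <= {0.0, 1.0}

    def test_fst_matches_divergence_parameter(self, fst_oracle):
        cfg = SimConfig(n_loci=1000, n_chrom=10, F=0.2)
        ests = []
        for seed in range(10):
            cfg.seed = 100 + seed
            panels, _ = sim_divergent_panels(cfg, 100, 100)
            ests.append(fst_oracle(panels.panel_A.alleles, panels.panel_B.alleles))
        assert 0.15 <= np.mean(ests) <= 0.25

    def test_ascertainment_floor_enforced(self):
        cfg = SimConfig(n_loci=200, n_chrom=1, F=0.2, maf_min=0.2, seed=3)
        _, (pa, pb) = sim_divergent_panels(cfg, 10, 10)
        combined = (pa + pb) / 2
        assert np.minimum(combined, 1 - combined).min() >= 0.2

    def test_unsatisfiable_maf_rejected(self):
        cfg = SimConfig(n_loci=50, n_chrom=1, F=1.0, maf_min=0.49, seed=4)
        with pytest.raises(ParameterError, match="maf_min"):
            sim_divergent_panels(cfg, 10, 10, max_rounds=5)


class TestPulse:
    def test_zero_admixture_all_parental(self):
        cfg = SimConfig(n_loci=50, n_chrom=2, m=0.0, g=10, n_sample=10, N=50, seed=5)
        _, truth, _ = sim_admixed_pulse(cfg, _freqs_for(cfg))
        assert (truth.labels == 0).all()

    def test_full_admixture_all_introgressed(self):
        cfg = SimConfig(n_loci=50, n_chrom=2, m=1.0, g=10, n_sample=10, N=50, seed=6)
        _, truth, _ = sim_admixed_pulse(cfg, _freqs_for(cfg))
        assert (truth.labels == 1).all()

    def test_single_tract_fraction_matches_poisson_arithmetic(self):
        # g=1 on a 1-Morgan chromosome: a chromosome is a single (maximal)
        # tract when all Poisson segments share one label; summing the
        # Poisson series gives P = m e^{-g(1-m)} + (1-m) e^{-gm}, which
        # reduces to the breakpoint-free zero class e^{-g} as m -> 0 or 1.
        g_, m_ = 1.0, 0.3
        expected = m_ * np.exp(-g_ * (1 - m_)) + (1 - m_) * np.exp(-g_ * m_)
        cfg = SimConfig(
            n_loci=10, n_chrom=1, chrom_length_cm=100.0, m=m_, g=1,
            N=5000, n_sample=5000, seed=7,
        )
        _, truth, _ = sim_admixed_pulse(cfg, _freqs_for(cfg))
        single = np.mean([len(segs) == 1 for segs in truth.tracts.values()])
        assert single == pytest.approx(expected, abs=0.02)

    def test_breakpoint_rate_close_to_g(self):
        for g in (10, 100):
            cfg = SimConfig(
                n_loci=10, n_chrom=1, chrom_length_cm=100.0, m=0.5, g=g,
                N=5000, n_sample=5000, seed=8 + g,
            )
            _, truth, _ = sim_admixed_pulse(cfg, _freqs_for(cfg))
            # count ancestry switches; under i.i.d. labels a breakpoint is
            # visible with probability 2m(1-m) = 0.5
            switches = np.mean([len(segs) - 1 for segs in truth.tracts.values()])
            assert switches == pytest.approx(g * 0.5, rel=0.05)

    def test_minority_fraction_matches_m(self):
        fracs = []
        for seed in range(8):
            cfg = SimConfig(n_loci=100, n_chrom=5, m=0.33, g=20, n_sample=30, N=100, seed=20 + seed)
            _, truth, _ = sim_admixed_pulse(cfg, _freqs_for(cfg))
            fracs.append(float((truth.labels == 1).mean()))
        se = np.std(fracs) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - 0.33) < 2 * se + 0.01


class TestForward:
    def test_zero_admixture(self):
        cfg = SimConfig(n_loci=20, n_chrom=1, m=0.0, g=3, N=30, n_sample=10, seed=9)
        _, truth, _ = sim_admixed_forward(cfg, _freqs_for(cfg))
        assert (truth.labels == 0).all()

    def test_first_generation_gametes_are_pure(self):
        cfg = SimConfig(n_loci=20, n_chrom=2, m=0.4, g=1, N=50, n_sample=25, seed=10)
        _, truth, _ = sim_admixed_forward(cfg, _freqs_for(cfg))
        for segs in truth.tracts.values():
            assert len({lab for _, _, lab in segs}) == 1

    def test_tract_length_decreases_with_age(self):
        means = {g: [] for g in (5, 25, 100)}
        for seed in range(3):
            for g in means:
                cfg = SimConfig(
                    n_loci=20, n_chrom=1, chrom_length_cm=100.0, m=0.3, g=g,
                    N=500, n_sample=50, seed=30 + seed,
                )
                _, truth, _ = sim_admixed_forward(cfg, _freqs_for(cfg))
                means[g].append(mean_tract_length_morgans(truth))
        assert np.mean(means[5]) > np.mean(means[25]) > np.mean(means[100])

    def test_agrees_with_pulse_for_young_admixture(self):
        # g <= N/10 regime: mean minority tract length within 15%. Very
        # small g carries a structural g/(g-1) offset (the first meiosis
        # happens inside pure founders), so the check sits at g = 25.
        fwd, pul = [], []
        for seed in range(6):
            cfg = SimConfig(
                n_loci=20, n_chrom=1, chrom_length_cm=200.0, m=0.3, g=25,
                N=250, n_sample=40, seed=50 + seed,
            )
            freqs = _freqs_for(cfg)
            _, tf, _ = sim_admixed_forward(cfg, freqs)
            _, tp, _ = sim_admixed_pulse(cfg, freqs)
            fwd.append(mean_tract_length_morgans(tf))
            pul.append(mean_tract_length_morgans(tp))
        assert np.mean(fwd) == pytest.approx(np.mean(pul), rel=0.15)

    def test_minority_fraction_matches_m(self):
        fracs = []
        for seed in range(10):
            cfg = SimConfig(n_loci=20, n_chrom=2, m=0.33, g=5, N=200, n_sample=50, seed=70 + seed)
            _, truth, _ = sim_admixed_forward(cfg, _freqs_for(cfg))
            fracs.append(float((truth.labels == 1).mean()))
        se = np.std(fracs) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - 0.33) < 2 * se + 0.02


class TestTruthConsistency:
    def test_marker_labels_match_tracts(self):
        cfg = SimConfig(n_loci=50, n_chrom=2, m=0.4, g=15, N=100, n_sample=10, seed=11)
        _, truth, mm = sim_admixed_pulse(cfg, _freqs_for(cfg))
        for h, hid in enumerate(truth.haplotype_ids):
            for chrom in ("1", "2"):
                idx = mm.chrom_indices(chrom)
                segs = truth.tracts[(str(hid), chrom)]
                # tracts tile the chromosome
                assert segs[0][0] == 0.0
                assert segs[-1][1] == pytest.approx(cfg.chrom_length_cm)
                for (a, b, _), (c, d, _) in zip(segs, segs[1:]):
                    assert b == pytest.approx(c)
                for cm, lab in zip(mm.pos_cm[idx], truth.labels[h, idx]):
                    seg_lab = next(l for lo, hi, l in segs if lo <= cm < hi)
                    assert (seg_lab == "B") == bool(lab)

    def test_truth_painting_is_binary_and_aligned(self):
        cfg = SimConfig(n_loci=30, n_chrom=1, m=0.5, g=5, N=50, n_sample=5, seed=12)
        _, truth, _ = sim_admixed_pulse(cfg, _freqs_for(cfg))
        tp = truth_painting(truth)
        assert set(np.unique(tp.prob_A)) <= {0.0, 1.0}
        np.testing.assert_array_equal(tp.prob_A == 0.0, truth.labels == 1)

    def test_marker_map_is_valid(self):
        mm = build_marker_map(SimConfig(n_loci=100, n_chrom=3))
        mm.validate()
        assert mm.chromosomes() == ["1", "2", "3"]
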