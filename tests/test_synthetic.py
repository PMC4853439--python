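"""Seeded generators: determinism, planted-site closed loop, parameter recovery."""

import math

import numpy as np
import pytest
from scipy import stats

from mirvar import association as assoc
from mirvar import clinical_stats as cs
from mirvar import qpcr_quant as qq
from mirvar import seed_scan as ss
from mirvar import synthetic_data as sd


class TestMirnaLibrary:
    def test_seeded_determinism(self):
        assert sd.make_mirna_library(5, 22, seed=1) == sd.make_mirna_library(5, 22, seed=1)

    def test_alphabet_and_length(self):
        lib = sd.make_mirna_library(10, 22, seed=3)
        assert all(len(m.sequence) == 22 for m in lib)
        assert all(set(m.sequence) <= set("ACGU") for m in lib)
        assert [m.mirna_id for m in lib] == [f"sim-miR-{i:04d}" for i in range(1, 11)]

    def test_distinct_seeds_differ(self):
        a = sd.make_mirna_library(5, 22, seed=1)
        b = sd.make_mirna_library(5, 22, seed=2)
        assert any(x.sequence != y.sequence for x, y in zip(a, b))

    def test_short_length_rejected(self):
        with pytest.raises(ValueError):
            sd.make_mirna_library(1, 7)


class TestPlantGainVariant:
    @pytest.mark.parametrize("site_type,footprint", [
        ("6mer", 6), ("7mer-A1", 7), ("7mer-m8", 7), ("8mer", 8),
    ])
    def test_closed_loop_with_scanner(self, site_type, footprint):
        """diff_sites on planted output reports exactly the planted gain."""
        mirna = sd.make_mirna_library(1, 22, seed=11)[0]
        utr, v = sd.plant_gain_variant(mirna, site_type, 120, seed=5)
        delta = ss.diff_sites(utr, [mirna], v)
        assert len(delta.gained) == 1 and delta.lost == ()
        site = delta.gained[0]
        assert site.site_type == site_type
        assert site.end - site.start + 1 == footprint
        assert site.overlaps(v.position)

    def test_reverting_variant_leaves_no_sites(self):
        mirna = sd.make_mirna_library(1, 22, seed=11)[0]
        utr, v = sd.plant_gain_variant(mirna, "8mer", 120, seed=5)
        reverted = ss.apply_variant(ss.apply_variant(utr, v), v.swapped())
        assert ss.scan_sites(reverted, [mirna]) == []

    def test_reference_allele_has_no_site(self):
        mirna = sd.make_mirna_library(1, 22, seed=11)[0]
        utr, _ = sd.plant_gain_variant(mirna, "7mer-m8", 120, seed=9)
        assert ss.scan_sites(utr, [mirna]) == []


class TestSimulateCohort:
    def test_seeded_determinism(self):
        cfg = sd.SimulationConfig(rng_seed=4, n_cases=50, n_controls=50)
        assert sd.simulate_cohort(cfg) == sd.simulate_cohort(cfg)

    def test_zero_probability_gives_no_carriers(self):
        cfg = sd.SimulationConfig(
            rng_seed=1, n_cases=200, n_controls=200,
            carrier_prob_cases=0.0, carrier_prob_controls=0.0,
        )
        assert not any(g.is_carrier for g in sd.simulate_cohort(cfg))

    def test_null_cfg_median_or_near_unity(self):
        """Equal carrier probabilities: median OR of replicates centred at 1."""
        p = 47 / 2248
        ors = []
        for seed in range(200):
            cfg = sd.SimulationConfig(rng_seed=seed, carrier_prob_cases=p,
                                      carrier_prob_controls=p)
            t = assoc.build_carrier_table(sd.simulate_cohort(cfg))
            or_, _, _ = assoc.odds_ratio_ci(t)
            ors.append(or_)
        assert 0.8 <= float(np.median(ors)) <= 1.25


class TestSimulateEcg:
    def test_seeded_determinism(self):
        cfg = sd.SimulationConfig(rng_seed=2, n_cases=30, n_controls=30)
        genos = sd.simulate_cohort(cfg)
        assert sd.simulate_ecg(genos, cfg) == sd.simulate_ecg(genos, cfg)

    def test_pr_shift_recovered_within_3_sem(self):
        cfg = sd.SimulationConfig(rng_seed=8, n_cases=378, n_controls=1,
                                  carrier_prob_cases=15 / 378)
        # force a carrier/noncarrier split of study-like size
        genos = [g for g in sd.simulate_cohort(cfg) if g.group == "case"]
        phenos = sd.simulate_ecg(genos, cfg)
        carriers = [p.pr_ms for p, g in zip(phenos, genos) if g.is_carrier]
        noncarr = [p.pr_ms for p, g in zip(phenos, genos) if not g.is_carrier]
        mean_c = float(np.mean(carriers))
        sem = cfg.pr_sd / math.sqrt(len(carriers))
        assert abs(mean_c - (cfg.pr_mean_noncarrier + cfg.pr_shift_carrier)) <= 3 * sem
        assert np.mean(carriers) > np.mean(noncarr)
        # design property: generating carrier mean crosses the 200 ms threshold
        assert cfg.pr_mean_noncarrier + cfg.pr_shift_carrier > 200

    def test_null_shift_p_values_uniform(self):
        """With no PR shift, t-test p-values are uniform (KS at alpha=0.01)."""
        pvals = []
        for seed in range(200):
            cfg = sd.SimulationConfig(rng_seed=seed, n_cases=40, n_controls=1,
                                      carrier_prob_cases=0.5, pr_shift_carrier=0.0)
            genos = [g for g in sd.simulate_cohort(cfg) if g.group == "case"]
            phenos = sd.simulate_ecg(genos, cfg)
            x = [p.pr_ms for p, g in zip(phenos, genos) if g.is_carrier]
            y = [p.pr_ms for p, g in zip(phenos, genos) if not g.is_carrier]
            if len(x) < 2 or len(y) < 2:
                continue
            pvals.append(cs.two_sample_t(x, y).p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestSimulatePlasmaCt:
    def test_seeded_determinism(self):
        cfg = sd.SimulationConfig(rng_seed=3, n_cases=20, n_controls=20)
        genos = sd.simulate_cohort(cfg)
        assert sd.simulate_plasma_ct(genos, cfg) == sd.simulate_plasma_ct(genos, cfg)

    def test_shift_formula_limit_is_one_third(self):
        cfg = sd.SimulationConfig()
        assert 2.0 ** -cfg.ct_shift_carrier == pytest.approx(1 / 3, abs=1e-12)

    def test_threefold_ratio_recovered(self):
        cfg = sd.SimulationConfig(rng_seed=6, n_cases=400, n_controls=1,
                                  carrier_prob_cases=0.5)
        genos = [g for g in sd.simulate_cohort(cfg) if g.group == "case"]
        cts = sd.simulate_plasma_ct(genos, cfg)
        by_sample = {}
        for r in cts:
            by_sample.setdefault(r.sample_id, {})[r.role] = r
        carrier_vals, noncarr_vals = [], []
        carrier_of = {g.subject_id: g.is_carrier for g in genos}
        for sid, roles in by_sample.items():
            t = qq.aggregate_ct(roles["target"].ct_values)
            s = qq.aggregate_ct(roles["spike_in"].ct_values)
            v = qq.spike_in_expression(t, s, sid).value
            (carrier_vals if carrier_of[sid] else noncarr_vals).append(v)
        ratio = qq.group_fold_change(carrier_vals, noncarr_vals)
        assert ratio == pytest.approx(1 / 3, rel=0.15)

    def test_no_shift_ratio_near_unity(self):
        cfg = sd.SimulationConfig(rng_seed=7, n_cases=400, n_controls=1,
                                  carrier_prob_cases=0.5, ct_shift_carrier=0.0)
        genos = [g for g in sd.simulate_cohort(cfg) if g.group == "case"]
        cts = sd.simulate_plasma_ct(genos, cfg)
        carrier_of = {g.subject_id: g.is_carrier for g in genos}
        vals = {True: [], False: []}
        by_sample = {}
        for r in cts:
            by_sample.setdefault(r.sample_id, {})[r.role] = r
        for sid, roles in by_sample.items():
            t = qq.aggregate_ct(roles["target"].ct_values)
            s = qq.aggregate_ct(roles["spike_in"].ct_values)
            vals[carrier_of[sid]].append(qq.spike_in_expression(t, s, sid).value)
        ratio = qq.group_fold_change(vals[True], vals[False])
        assert ratio == pytest.approx(1.0, rel=0.15)


class TestOrRecovery:
    def test_generating_or_recovered_in_median(self):
        """Median OR across seeded replicates tracks the generating odds ratio."""
        cfg = sd.SimulationConfig()
        gen_or = (cfg.carrier_prob_cases / (1 - cfg.carrier_prob_cases)) / (
            cfg.carrier_prob_controls / (1 - cfg.carrier_prob_controls)
        )
        ors = []
        for seed in range(100):
            t = assoc.build_carrier_table(
                sd.simulate_cohort(sd.SimulationConfig(rng_seed=seed))
            )
            or_, _, _ = assoc.odds_ratio_ci(t)
            ors.append(or_)
        med = float(np.median(ors))
        assert abs(med - gen_or) / gen_or <= 0.20
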