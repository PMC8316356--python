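"""Synthetic generator: expected intensities, truth oracle, sampling."""

import math

import numpy as np
import pytest

from junctiso import (
    cascade_fractions,
    cterm_fractions,
    read_exon_counts,
    read_depths,
    read_star_junctions,
)
from junctiso.simulate import (
    SimulationConfig,
    expected_exon_intensity,
    expected_junction_intensity,
    simulate,
    truth_fractions,
    write_simulation,
)


class TestExpectedIntensities:
    def test_single_isoform_puts_equal_mass_on_its_junctions(self, tp73):
        cfg = SimulationConfig(model=tp73, mixture={"dN-alpha": 1.0}, depth=1000.0)
        nj = expected_junction_intensity(cfg)
        on_path = {j.uid for j in tp73.transcript_junctions("dN-alpha")}
        on = {u: v for u, v in nj.items() if u in on_path}
        off = {u: v for u, v in nj.items() if u not in on_path}
        assert len(set(round(v, 9) for v in on.values())) == 1
        assert all(v == 0 for v in off.values())
        assert sum(nj.values()) == pytest.approx(1000.0)

    def test_symmetric_promoters_balance_five_prime_junctions(self, tp73):
        cfg = SimulationConfig(
            model=tp73, mixture={"TA-alpha": 0.5, "dN-alpha": 0.5}, depth=1000.0
        )
        nj = expected_junction_intensity(cfg)
        assert nj["E3-E4"] == pytest.approx(nj["E3p-E4"])
        assert nj["E5-E6"] == pytest.approx(2 * nj["E3-E4"])

    def test_unknown_mixture_name_rejected(self, tp73):
        cfg = SimulationConfig(model=tp73, mixture={"dN-omega": 1.0})
        with pytest.raises(KeyError, match="omega"):
            expected_junction_intensity(cfg)

    def test_exon_profile_flat_without_bias(self, tp73):
        cfg = SimulationConfig(model=tp73, mixture={"TA-alpha": 1.0}, depth=1e4)
        ec = expected_exon_intensity(cfg)
        path = tp73.transcript_path("TA-alpha")
        per_bp = [ec[lab] / tp73.exon(lab).length_bp for lab in path]
        assert max(per_bp) == pytest.approx(min(per_bp))

    def test_bias_depresses_five_prime_exons(self, tp73):
        cfg = SimulationConfig(
            model=tp73, mixture={"TA-alpha": 1.0}, depth=1e4, bias_decay_bp=500.0
        )
        ec = expected_exon_intensity(cfg)
        assert ec["E3"] / tp73.exon("E3").length_bp < ec["E13"] / tp73.exon("E13").length_bp


class TestTruthFractions:
    def test_marginalization(self, tp73):
        cfg = SimulationConfig(
            model=tp73, mixture={"TA-alpha": 0.3, "dN-alpha": 0.7}
        )
        truth = truth_fractions(cfg)
        assert truth["N"] == pytest.approx({"TA": 30.0, "dN": 70.0, "I3a": 0.0})
        assert truth["C"]["alpha"] == pytest.approx(100.0)

    def test_tp63_c_marginal(self, tp63):
        cfg = SimulationConfig(
            model=tp63, mixture={"dN-alpha": 0.5, "dN-gamma": 0.5}
        )
        truth = truth_fractions(cfg)
        assert truth["C"]["alpha"] == pytest.approx(50.0)
        assert truth["C"]["gamma"] == pytest.approx(50.0)

    def test_e4_transcript_invisible_to_n_cascade(self, tp73):
        cfg = SimulationConfig(
            model=tp73, mixture={"TA-alpha": 0.1, "E4p73": 0.9}
        )
        truth = truth_fractions(cfg)
        assert truth["N"]["TA"] == pytest.approx(100.0)
        assert truth["C"]["alpha"] == pytest.approx(100.0)

    def test_e8s_share_sets_variant_split(self, tp63):
        cfg = SimulationConfig(
            model=tp63, mixture={"dN-alpha": 1.0}, e8s_share=0.3
        )
        truth = truth_fractions(cfg)
        assert truth["E8variant"] == pytest.approx({"E8": 70.0, "E8s": 30.0})


class TestOracleConsistency:
    @pytest.mark.parametrize("gene", ["TP73", "TP63"])
    def test_quantifier_reproduces_truth_on_expected_counts(self, gene, request):
        model = request.getfixturevalue(gene.lower())
        if gene == "TP73":
            names = [f"{n}-{c}" for n in ("TA", "dN")
                     for c in ("alpha", "beta", "gamma+epsilon", "zeta", "delta")]
            extras = ["I3a", "E4p73"]
        else:
            names = [f"{n}-{c}" for n in ("TA", "dN")
                     for c in ("alpha", "beta", "gamma", "delta")]
            extras = []
        rng = np.random.default_rng(19)
        for trial in range(25):
            vocab = names + (extras if trial % 2 else [])
            w = rng.dirichlet(np.ones(len(vocab)))
            cfg = SimulationConfig(
                model=model, mixture=dict(zip(vocab, map(float, w))),
                e8s_share=float(rng.uniform(0, 1)) if gene == "TP63" else 0.0,
            )
            nj = expected_junction_intensity(cfg)
            truth = truth_fractions(cfg)
            for cascade in model.cascades:
                got = cascade_fractions(nj, cascade)
                for leaf, exp in truth[cascade.terminus].items():
                    if math.isnan(exp):
                        assert math.isnan(got[leaf])
                    else:
                        assert got[leaf] == pytest.approx(exp, abs=1e-9)

    def test_c_root_fractions_survive_finite_bias(self, tp73):
        """Competing C-root junctions sit at the same transcript position
        only when the tails they lead into have equal length; with a
        common suffix (alpha for all) the root split stays exact."""
        cfg = SimulationConfig(
            model=tp73,
            mixture={"TA-alpha": 0.6, "dN-alpha": 0.4},
            bias_decay_bp=800.0,
        )
        nj = expected_junction_intensity(cfg)
        got = cterm_fractions(nj, tp73)
        assert got["alpha"] == pytest.approx(100.0, abs=1e-9)


class TestSampling:
    def test_fixed_seed_is_reproducible(self, tp63):
        cfg = SimulationConfig(
            model=tp63, mixture={"dN-alpha": 1.0}, depth=1e4, n_samples=3, seed=5
        )
        a, b = simulate(cfg), simulate(cfg)
        for sa, sb in zip(a, b):
            assert sa.junction_counts.raw == sb.junction_counts.raw
            assert sa.exon_counts.raw == sb.exon_counts.raw

    def test_poisson_recovery_of_mixture(self, tp63):
        cfg = SimulationConfig(
            model=tp63, mixture={"dN-alpha": 0.8, "dN-beta": 0.2},
            depth=1e5, n_samples=200, seed=11,
        )
        samples = simulate(cfg)
        errs = []
        for s in samples:
            got = cterm_fractions(s.junction_counts, tp63)
            errs.append(
                np.mean([abs(got[k] - v) for k, v in s.truth["C"].items()])
            )
        assert np.mean(errs) < 1.0

    def test_total_reads_concentrate_around_depth(self, tp73):
        depth = 1e5
        cfg = SimulationConfig(
            model=tp73, mixture={"dN-alpha": 1.0}, depth=depth,
            n_samples=100, seed=2,
        )
        totals = [sum(s.junction_counts.raw.values()) for s in simulate(cfg)]
        frac_ok = np.mean(
            [abs(t - depth) <= 3 * math.sqrt(depth) for t in totals]
        )
        assert frac_ok >= 0.99

    def test_negative_binomial_is_overdispersed(self, tp73):
        base = dict(model=tp73, mixture={"dN-alpha": 1.0}, depth=1e4,
                    n_samples=300, seed=8)
        pois = [sum(s.junction_counts.raw.values())
                for s in simulate(SimulationConfig(**base))]
        nb = [sum(s.junction_counts.raw.values())
              for s in simulate(SimulationConfig(**base, nb_dispersion=0.2))]
        assert np.var(nb) > 3 * np.var(pois)

    def test_invalid_configs_rejected(self, tp73):
        with pytest.raises(ValueError, match="depth"):
            SimulationConfig(model=tp73, mixture={"dN-alpha": 1.0}, depth=0).validate()
        with pytest.raises(ValueError, match="sum"):
            SimulationConfig(model=tp73, mixture={"dN-alpha": 0.5}).validate()


class TestRoundTripThroughReaders:
    def test_written_cohort_is_read_back_exactly(self, tp63, tmp_path):
        cfg = SimulationConfig(
            model=tp63, mixture={"dN-alpha": 0.7, "dN-gamma": 0.3},
            depth=5e4, n_samples=2, seed=4,
        )
        samples = simulate(cfg)
        write_simulation(samples, tp63, tmp_path, tissue="skin")
        depths = read_depths(tmp_path / "depths.tsv")
        for s in samples:
            sid = s.junction_counts.sample_id
            jc = read_star_junctions(
                tmp_path / f"{sid}.sj.tab", tp63, depths[sid], sample_id=sid
            )
            assert jc.raw == s.junction_counts.raw
        ecs = read_exon_counts(tmp_path / "exon_counts.tsv", tp63, depths)
        assert ecs[0].raw == samples[0].exon_counts.raw
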