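"""Generators: determinism, ground-truth carriage, and distributional checks."""

import numpy as np
import pytest

from geomine.sequence_mining import identity_matrix
from geomine.synthetic_data import (
    FamilySimSpec,
    KineticsSimSpec,
    ScoreSimSpec,
    simulate_design_set,
    simulate_family,
    simulate_kinetics,
    simulate_scores,
    simulate_titers,
)


class TestSimulateFamily:
    def test_zero_rate_all_identical(self):
        records, _ = simulate_family(
            FamilySimSpec(n_sequences=6, root_length=50, substitution_rate=0.0, seed=1)
        )
        assert len({r.sequence for r in records}) == 1
        m = identity_matrix(records)
        assert np.allclose(m.values, 1.0)

    def test_same_seed_identical_output(self, tmp_path):
        from geomine.io import write_fasta

        out = []
        for _ in range(2):
            records, clade = simulate_family(FamilySimSpec(n_sequences=8, seed=42))
            path = tmp_path / f"fam{len(out)}.fasta"
            write_fasta(records, path)
            out.append((path.read_bytes(), clade))
        assert out[0] == out[1]

    @pytest.mark.parametrize("shape", ["balanced", "coalescent"])
    def test_clade_fraction_and_labels(self, shape):
        spec = FamilySimSpec(
            n_sequences=32, root_length=60, functional_clade_fraction=0.25,
            tree_shape=shape, seed=3,
        )
        records, clade = simulate_family(spec)
        assert 0 < len(clade) < 32
        assert abs(len(clade) - 8) <= 4  # subtree granularity
        tagged = {r.id for r in records if "clade=1" in r.description}
        assert tagged == clade

    def test_distinct_seeds_distinct_output(self):
        seqs = set()
        for seed in range(10):
            records, _ = simulate_family(FamilySimSpec(n_sequences=4, root_length=40, seed=seed))
            seqs.add("".join(r.sequence for r in records))
        assert len(seqs) == 10

    def test_mean_identity_decreases_with_rate(self):
        means = []
        for rate in (0.2, 0.5, 1.0):
            vals = []
            for seed in (1, 2, 3):
                records, _ = simulate_family(FamilySimSpec(
                    n_sequences=10, root_length=100, substitution_rate=rate, seed=seed))
                m = identity_matrix(records)
                iu = np.triu_indices(10, k=1)
                vals.append(m.values[iu].mean())
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_invalid_fields_named(self):
        with pytest.raises(ValueError, match="n_sequences"):
            FamilySimSpec(n_sequences=1)
        with pytest.raises(ValueError, match="substitution_rate"):
            FamilySimSpec(substitution_rate=-0.1)
        with pytest.raises(ValueError, match="functional_clade_fraction"):
            FamilySimSpec(functional_clade_fraction=1.5)


class TestSimulateScores:
    def test_noiseless_clade_energy_exact(self, small_family):
        records, clade = small_family
        spec = ScoreSimSpec(clade_energy_mean=-12.0, background_energy_mean=-2.0,
                            noise_sd=0.0, seed=0)
        cands = simulate_scores(records, clade, spec)
        for c in cands:
            expected = -12.0 if c.id in clade else -2.0
            assert c.interface_energy == expected

    def test_noiseless_ranking_puts_clade_first(self, small_family):
        records, clade = small_family
        cands = simulate_scores(records, clade, ScoreSimSpec(noise_sd=0.0, seed=0))
        ranked = sorted(cands, key=lambda c: c.interface_energy)
        assert {c.id for c in ranked[: len(clade)]} == clade

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            simulate_scores([], set(), ScoreSimSpec())

    def test_clade_must_be_lower_energy(self):
        with pytest.raises(ValueError, match="clade_energy_mean"):
            ScoreSimSpec(clade_energy_mean=0.0, background_energy_mean=-5.0)

    def test_lowest_energy_hit_rate_matches_direct_monte_carlo(self, small_family):
        """With heavy noise, P(lowest-energy record is in the clade) should
        match an independent numpy-only re-estimate of the same quantity."""
        records, clade = small_family
        n, k = len(records), len(clade)
        spec = ScoreSimSpec(clade_energy_mean=-4.0, background_energy_mean=-2.0,
                            noise_sd=1.0)
        hits = 0
        n_seeds = 1000
        for seed in range(n_seeds):
            cands = simulate_scores(
                records, clade,
                ScoreSimSpec(clade_energy_mean=-4.0, background_energy_mean=-2.0,
                             noise_sd=1.0, seed=seed))
            best = min(cands, key=lambda c: c.interface_energy)
            hits += best.id in clade
        impl_rate = hits / n_seeds

        rng = np.random.default_rng(987654)
        trials = 40_000
        clade_draws = rng.normal(-4.0, 1.0, size=(trials, k))
        bg_draws = rng.normal(-2.0, 1.0, size=(trials, n - k))
        oracle_rate = float(np.mean(clade_draws.min(axis=1) < bg_draws.min(axis=1)))
        assert impl_rate == pytest.approx(oracle_rate, abs=0.02)


class TestSimulateKinetics:
    def test_half_saturation_identity(self):
        spec = KineticsSimSpec(true_kcat=5.0, true_KM=1.0, noise_sd=0.0,
                               substrate_grid=(0.1, 0.5, 1.0, 2.0, 10.0))
        data, _ = simulate_kinetics(spec)
        at_km = data.velocities_M_per_s[data.concentrations_mM == 1.0]
        assert at_km[0] == pytest.approx(5.0 * spec.enzyme_conc / 2.0, rel=1e-12)

    def test_inhibition_optimum_at_sqrt_km_ki(self):
        # calculus optimum of S/(KM + S + S^2/Ki) is at S = sqrt(KM * Ki)
        km, ki = 0.58, 2.0
        grid = tuple(np.geomspace(0.01, 10.0, 400))
        data, _ = simulate_kinetics(KineticsSimSpec(
            true_KM=km, true_Ki=ki, noise_sd=0.0, substrate_grid=grid))
        s_star = data.concentrations_mM[np.argmax(data.velocities_M_per_s)]
        assert s_star == pytest.approx(np.sqrt(km * ki), rel=2e-2)

    def test_same_seed_identical(self):
        a, _ = simulate_kinetics(KineticsSimSpec(seed=9))
        b, _ = simulate_kinetics(KineticsSimSpec(seed=9))
        assert np.array_equal(a.velocities_M_per_s, b.velocities_M_per_s)

    def test_truth_carried(self):
        _, truth = simulate_kinetics(KineticsSimSpec(true_kcat=3.0, true_KM=0.4))
        assert truth["kcat"] == 3.0 and truth["KM_mM"] == 0.4

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError, match="substrate_grid"):
            KineticsSimSpec(substrate_grid=(0.0, 1.0, 2.0, 3.0, 4.0))


class TestSimulateDesignSet:
    NATIVE = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"

    def test_native_only_alphabet_returns_native(self):
        # options at the design position collapse to the native residue
        designs = simulate_design_set(
            5, positions=(1,), native=self.NATIVE, allowed_alphabet=[self.NATIVE[0]], seed=0)
        assert all(d == self.NATIVE for d in designs)

    def test_letters_within_alphabet_or_native(self):
        positions = tuple(range(1, 30, 3))  # 10 positions
        alphabet = "VLIMFHGATYW"
        designs = simulate_design_set(50, positions, self.NATIVE, alphabet, seed=4)
        assert len(designs) == 50
        pos_set = set(positions)
        for d in designs:
            assert len(d) == len(self.NATIVE)
            for i, (x, y) in enumerate(zip(d, self.NATIVE), start=1):
                if i in pos_set:
                    assert x in set(alphabet) | {y}
                else:
                    assert x == y

    def test_per_position_tally_matches_brute_force(self):
        positions = (2, 8, 14)
        designs = simulate_design_set(30, positions, self.NATIVE, "VLIA", seed=7)
        from collections import Counter

        for p in positions:
            tally = Counter(d[p - 1] for d in designs)
            brute = Counter()
            for d in designs:
                brute[d[p - 1]] += 1
            assert tally == brute
            assert sum(tally.values()) == 30

    def test_position_outside_native_rejected(self):
        with pytest.raises(ValueError):
            simulate_design_set(3, (99,), self.NATIVE, "VLI", seed=0)


class TestSimulateTiters:
    MEANS = {"pentanol": 118.0, "hexanol": 341.0, "heptanol": 269.0}

    def test_zero_sd_equals_truth(self):
        table, truth = simulate_titers(self.MEANS, replicate_sd=0.0, seed=0)
        assert table.quantified_means == truth

    def test_below_loq_flagged(self):
        table, _ = simulate_titers({"octanol": 1.0}, replicate_sd=0.0, loq=5.0, seed=0)
        assert table.below_loq == ("octanol",)
        assert table.quantified_means == {}

    def test_replicate_mean_sampling_distribution(self):
        """Empirical SD of 3-replicate means ~ sd/sqrt(3)."""
        sd, n_reps = 10.0, 3
        rep_means = []
        for seed in range(4000):
            table, _ = simulate_titers({"hexanol": 341.0}, replicate_sd=sd,
                                       n_reps=n_reps, seed=seed)
            rep_means.append(np.mean(table.replicates["hexanol"]))
        assert np.std(rep_means) == pytest.approx(sd / np.sqrt(n_reps), rel=0.05)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            simulate_titers(self.MEANS, replicate_sd=-1.0)
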