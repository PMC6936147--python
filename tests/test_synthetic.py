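import dataclasses
from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from dytidriver.synthetic import (
    SyntheticConfig,
    generate_network,
    generate_tissue_expression,
    simulate_cohort,
    write_cohort,
)


def predicted_outlying_rate(q, shift):
    """Closed-form outlying probability for a shifted neighbor cell.

    With a fraction q of patients shifted by +shift, the cohort reference
    distribution has mean q*shift and variance 1 + shift^2 q(1-q); a shifted
    observation is N(shift, 1). Outlying means falling outside mean +/- 2 sd
    of the reference.
    """
    mu = q * shift
    sd = np.sqrt(1 + shift**2 * q * (1 - q))
    upper = stats.norm.sf(mu + 2 * sd - shift)
    lower = stats.norm.cdf(mu - 2 * sd - shift)
    return upper + lower


class TestDeterminism:
    def test_same_seed_reproduces_every_artifact(self):
        cfg = SyntheticConfig.small(seed=11)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        assert set(a.network.edges) == set(b.network.edges)
        assert a.mutations.equals(b.mutations)
        assert (a.tumor_expr.to_numpy() == b.tumor_expr.to_numpy()).all()
        assert (a.tissue_expr.to_numpy() == b.tissue_expr.to_numpy()).all()
        assert a.truth == b.truth

    def test_written_artifacts_byte_identical(self, tmp_path):
        cfg = SyntheticConfig.small(seed=3)
        p1 = write_cohort(simulate_cohort(cfg), tmp_path / "a")
        p2 = write_cohort(simulate_cohort(cfg), tmp_path / "b")
        for name in p1:
            assert p1[name].read_bytes() == p2[name].read_bytes()


class TestNetwork:
    def test_zero_background_keeps_edges_inside_module(self):
        cfg = SyntheticConfig(
            n_genes=20,
            n_patients=5,
            n_tissue_samples=10,
            n_modules=1,
            module_size=4,
            drivers_per_module=1,
            background_edge_prob=0.0,
            module_edge_prob=1.0,
            seed=0,
        )
        net, modules = generate_network(cfg, np.random.default_rng(cfg.seed))
        members = set(modules[0])
        assert net.number_of_nodes() == 20
        for a, b in net.edges:
            assert a in members and b in members

    def test_within_module_density_matches_binomial_expectation(self):
        cfg = SyntheticConfig(seed=0)
        counts = []
        for seed in range(20):
            net, modules = generate_network(cfg, np.random.default_rng(seed))
            for mod in modules:
                counts.append(
                    sum(net.has_edge(a, b) for a, b in combinations(mod, 2))
                )
        n_pairs = cfg.module_size * (cfg.module_size - 1) / 2
        assert np.mean(counts) >= 0.8 * n_pairs

    def test_infeasible_sizes_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            SyntheticConfig(n_genes=10, n_modules=3, module_size=5)
        with pytest.raises(ValueError, match="exceed"):
            SyntheticConfig(driver_mut_rate=0.01, passenger_mut_rate=0.02)


class TestTissueExpression:
    def _mean_abs_pcc(self, cfg, seeds):
        within, background = [], []
        for seed in seeds:
            rng = np.random.default_rng(seed)
            net, modules = generate_network(cfg, rng)
            expr = generate_tissue_expression(cfg, modules, rng)
            r = np.corrcoef(expr.to_numpy(), rowvar=False)
            members = [expr.columns.get_loc(g) for g in modules[0]]
            outside = [
                j
                for j in range(cfg.n_genes - 20, cfg.n_genes)
                if expr.columns[j] not in set().union(*map(set, modules))
            ]
            within.append(
                np.mean([abs(r[i, j]) for i, j in combinations(members, 2)])
            )
            background.append(
                np.mean([abs(r[i, j]) for i, j in combinations(outside, 2)])
            )
        return np.array(within), np.array(background)

    def test_zero_loading_indistinguishable_from_background(self):
        cfg = dataclasses.replace(SyntheticConfig(), coexpr_strength=0.0)
        within, background = self._mean_abs_pcc(cfg, range(20))
        _, p = stats.ttest_ind(within, background)
        assert p > 0.01

    def test_strong_loading_clears_the_pcc_threshold(self):
        cfg = dataclasses.replace(
            SyntheticConfig(), coexpr_strength=0.9, noise_sd=0.3
        )
        within, _ = self._mean_abs_pcc(cfg, range(20))
        # factor model: expected r = lambda^2/(lambda^2 + sigma^2) = 0.9
        assert within.mean() > 0.3


class TestMutationsAndExpression:
    def test_certain_driver_mutation_gives_frequency_one(self):
        cfg = dataclasses.replace(SyntheticConfig.small(), driver_mut_rate=1.0)
        cohort = simulate_cohort(cfg)
        for g in cohort.truth:
            assert cohort.mutations[g].mean() == 1.0

    def test_truth_lies_inside_modules_and_network(self):
        cohort = simulate_cohort(SyntheticConfig.small(seed=2))
        module_genes = {g for mod in cohort.modules for g in mod}
        assert cohort.truth <= set(cohort.network.nodes)
        assert cohort.truth <= module_genes
        assert len(cohort.truth) == (
            cohort.config.n_modules * cohort.config.drivers_per_module
        )

    def _neighbor_cell_outlier_rate(self, cfg, seeds):
        """Outlying rate over (mutated-driver patient, neighbor) cells for
        neighbors of exactly one driver."""
        from dytidriver.filtering import call_outlying, compute_zscores

        hits = total = 0
        for seed in seeds:
            cohort = simulate_cohort(dataclasses.replace(cfg, seed=seed))
            out = call_outlying(compute_zscores(cohort.tumor_expr))
            drivers = sorted(cohort.truth)
            nbr_count = {}
            for d in drivers:
                for nbr in cohort.network[d]:
                    nbr_count[nbr] = nbr_count.get(nbr, 0) + 1
            for d in drivers:
                patients = cohort.mutations.index[cohort.mutations[d] == 1]
                for nbr in cohort.network[d]:
                    if nbr_count[nbr] != 1 or nbr in cohort.truth:
                        continue
                    hits += int(out.loc[patients, nbr].sum())
                    total += len(patients)
        return hits / total

    def test_zero_shift_outlier_rate_is_background(self):
        cfg = dataclasses.replace(SyntheticConfig(), dysregulation_shift=0.0)
        rate = self._neighbor_cell_outlier_rate(cfg, range(20))
        background = 2 * stats.norm.sf(2)  # ~0.0455
        assert abs(rate - background) < 0.01

    def test_shift_four_outlier_rate_matches_dilution_aware_oracle(self):
        # the cohort reference statistics are inflated by the shifted
        # patients themselves, so the naive N(4,1) tail only applies as the
        # mutation rate goes to zero
        cfg = dataclasses.replace(
            SyntheticConfig(), dysregulation_shift=4.0, drivers_per_module=1
        )
        rate = self._neighbor_cell_outlier_rate(cfg, range(10))
        assert abs(rate - predicted_outlying_rate(0.3, 4.0)) < 0.05

        low = dataclasses.replace(
            SyntheticConfig(),
            dysregulation_shift=4.0,
            drivers_per_module=1,
            driver_mut_rate=0.05,
        )
        low_rate = self._neighbor_cell_outlier_rate(low, range(10))
        assert abs(low_rate - predicted_outlying_rate(0.05, 4.0)) < 0.07
        assert low_rate > rate  # dilution shrinks with the mutation rate
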