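import numpy as np
import pytest
from scipy import stats

from plankweb.simulate import (
    CommunitySimSpec,
    GroundTruth,
    simulate_block_network,
    simulate_dispersal_structured,
    simulate_neutral,
    simulate_niche_gradient,
    stick_breaking_abundances,
)


def neutral_spec(**kw):
    base = dict(n_taxa=100, n_samples=10, reads_per_sample=2000, regime="neutral", m=0.2, seed=0)
    base.update(kw)
    return CommunitySimSpec(**base)


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(m=0.0),
            dict(m=1.5),
            dict(n_taxa=1),
            dict(n_samples=2),
            dict(reads_per_sample=0),
        ],
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            neutral_spec(**kw)

    def test_block_needs_enough_modules(self):
        with pytest.raises(ValueError):
            CommunitySimSpec(
                n_taxa=4, n_samples=5, reads_per_sample=100,
                regime="block_network", n_modules=5, seed=0,
            )

    def test_niche_needs_groups(self):
        with pytest.raises(ValueError):
            CommunitySimSpec(
                n_taxa=10, n_samples=6, reads_per_sample=100,
                regime="niche", gradient_groups=(), seed=0,
            )

    def test_ground_truth_must_sum_to_one(self):
        with pytest.raises(ValueError):
            GroundTruth(metacommunity_abundances=np.array([0.5, 0.4]))


class TestStickBreaking:
    def test_sums_to_one_and_long_tailed(self):
        rng = np.random.default_rng(0)
        p = stick_breaking_abundances(500, 5.0, rng)
        assert p.shape == (500,)
        assert abs(p.sum() - 1.0) < 1e-12
        assert (p >= 0).all()
        # long tail: the top decile holds most of the mass
        assert np.sort(p)[::-1][:50].sum() > 0.8


class TestDeterminism:
    @pytest.mark.parametrize("regime,kw", [
        ("neutral", dict(m=0.3)),
        ("dispersal", dict()),
        ("block_network", dict(n_modules=3)),
        ("niche", dict()),
    ])
    def test_bit_identical_for_same_seed(self, regime, kw):
        spec = CommunitySimSpec(
            n_taxa=30, n_samples=8, reads_per_sample=500, regime=regime, seed=7, **kw
        )
        from plankweb.simulate import simulate

        a = simulate(spec)[0]
        b = simulate(spec)[0]
        assert a.counts.equals(b.counts)


class TestNeutral:
    def test_high_m_concentrates_near_metacommunity_frequency(self):
        # Beta mean is p regardless of m; with m=1 and huge reads the local
        # relative abundances hug the metacommunity frequency
        spec = neutral_spec(n_taxa=2, reads_per_sample=200000, m=1.0, n_samples=50)
        table, truth = simulate_neutral(spec)
        rel = table.relative_abundance().to_numpy()
        p = truth.metacommunity_abundances
        assert np.allclose(rel.mean(axis=1), p, atol=0.02)

    def test_low_m_steepens_occupancy_curve(self):
        # dispersal limitation pushes occurrence frequencies to 0 or 1
        extreme = {m: [] for m in (0.05, 0.8)}
        for m in extreme:
            for seed in range(10):
                spec = neutral_spec(m=m, seed=seed)
                table, _ = simulate_neutral(spec)
                freq = (table.counts > 0).mean(axis=1)
                extreme[m].append(((freq < 0.05) | (freq > 0.95)).mean())
        assert np.mean(extreme[0.05]) > np.mean(extreme[0.8])

    def test_occupancy_tracks_sloan_band(self):
        # each abundance decile's occupancy falls inside the model's own 95%
        # band in the vast majority of replicates
        from plankweb.ncm import ncm_predict
        from plankweb.ncm import _wilson_band

        hits = trials = 0
        for seed in range(10):
            spec = neutral_spec(n_taxa=300, n_samples=20, reads_per_sample=5000, seed=seed)
            table, truth = simulate_neutral(spec)
            occ = table.counts.gt(0).mean(axis=1).to_numpy()
            p = table.relative_abundance().mean(axis=1).to_numpy()
            keep = (p > 0) & (p < 1) & (occ > 0)
            p, occ = p[keep], occ[keep]
            pred = ncm_predict(p, 5000, 0.2, np.log(2) / 5000)
            lower, upper = _wilson_band(pred, 20, 0.95)
            deciles = np.quantile(p, np.linspace(0, 1, 11))
            for lo, hi in zip(deciles[:-1], deciles[1:]):
                sel = (p >= lo) & (p <= hi)
                if sel.sum() < 3:
                    continue
                trials += 1
                hits += lower[sel].mean() <= occ[sel].mean() <= upper[sel].mean()
        assert hits / trials >= 0.9


class TestNiche:
    def test_metadata_matches_design(self):
        spec = CommunitySimSpec(
            n_taxa=50, n_samples=20, reads_per_sample=1000, regime="niche", seed=1
        )
        table, truth, meta = simulate_niche_gradient(spec)
        assert table.sample_ids == meta.sample_ids
        by_region = meta.frame.groupby("region")["salinity"].mean()
        assert abs(by_region["offshore"] - 29.17) < 0.5
        assert abs(by_region["estuary"] - 13.15) < 1.5
        assert (table.sample_totals() == 1000).all()

    def test_marine_optimum_taxon_prefers_saline_group(self):
        # a taxon with optimum ~30 psu should be relatively more abundant
        # offshore than in the estuary in nearly every replicate
        wins = 0
        for seed in range(20):
            spec = CommunitySimSpec(
                n_taxa=50, n_samples=12, reads_per_sample=2000, regime="niche",
                niche_width=3.0, seed=seed,
            )
            table, truth, meta = simulate_niche_gradient(spec)
            idx = int(np.argmin(np.abs(truth.niche_optima - 30.0)))
            rel = table.relative_abundance().iloc[idx]
            regions = meta.frame["region"]
            wins += (
                rel[regions == "offshore"].mean() > rel[regions == "estuary"].mean()
            )
        assert wins >= 16

    def test_flat_response_removes_group_signal(self):
        from plankweb.diversity import bray_curtis
        from plankweb.ordination import permanova

        pvals = []
        for seed in range(10):
            spec = CommunitySimSpec(
                n_taxa=40, n_samples=12, reads_per_sample=1000, regime="niche",
                niche_width=1e6, seed=seed,
            )
            table, _, meta = simulate_niche_gradient(spec)
            res = permanova(bray_curtis(table), meta.frame["region"],
                            n_permutations=199, seed=seed)
            pvals.append(res.p_value)
        # no niche signal: p-values spread out instead of piling up near 0
        assert np.mean(np.array(pvals) <= 0.05) <= 0.3


class TestDispersal:
    def test_occupancy_matches_assigned_probabilities(self):
        probs = np.linspace(0.1, 0.9, 20)
        spec = CommunitySimSpec(
            n_taxa=20, n_samples=200, reads_per_sample=500, regime="dispersal",
            occupancy_probs=probs, seed=2,
        )
        table, truth = simulate_dispersal_structured(spec)
        observed = table.counts.gt(0).sum(axis=1).to_numpy()
        lo = stats.binom.ppf(0.0005, 200, probs)
        hi = stats.binom.ppf(0.9995, 200, probs)
        assert ((observed >= lo) & (observed <= hi)).all()

    def test_full_occupancy_is_degenerate_for_dnci(self):
        from plankweb.dnci import dnci_pair

        spec = CommunitySimSpec(
            n_taxa=10, n_samples=8, reads_per_sample=500, regime="dispersal",
            occupancy_probs=np.ones(10), seed=0,
        )
        table, _ = simulate_dispersal_structured(spec)
        with pytest.raises(ValueError, match="turnover"):
            dnci_pair(table.presence_absence().to_numpy(), ["A"] * 4 + ["B"] * 4)


class TestBlockNetwork:
    def test_ground_truth_edges_are_within_module_or_bridge(self):
        spec = CommunitySimSpec(
            n_taxa=23, n_samples=10, reads_per_sample=5000,
            regime="block_network", n_modules=3, seed=0,
        )
        table, truth = simulate_block_network(spec)
        modules = dict(zip(table.taxon_ids, truth.module_assignment))
        for a, b in truth.true_edges:
            ma, mb = modules[a], modules[b]
            assert ma == mb or -1 in (ma, mb)

    def test_zero_loading_gives_no_edges(self):
        from plankweb.network import spearman_edges

        spec = CommunitySimSpec(
            n_taxa=23, n_samples=15, reads_per_sample=20000,
            regime="block_network", n_modules=3, factor_loading=0.0, seed=3,
        )
        table, _ = simulate_block_network(spec)
        edges = spearman_edges(table)
        assert len(edges) <= 1
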