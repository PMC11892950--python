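"""Generator contracts: determinism, planted structure, degenerate cases."""

import io

import numpy as np
import pytest

from cellumend.geochip import filter_probes, gene_response_ratio
from cellumend.mend import MendParams, MendState, simulate
from cellumend.synthetic import (EnrichmentEffect, ForcingDesign,
                                 SyntheticDesign, gen_forcing,
                                 gen_observations, gen_paired_communities,
                                 gen_probe_table, gen_trait_reference)


class TestTraitReference:
    def test_degenerate_range_gives_constant_rrn(self):
        d = SyntheticDesign(n_taxa=50, seed=1)
        ref = gen_trait_reference(d, match_fraction=1.0, rrn_range=(3, 3))
        assert len(ref.matched_taxa) == 50
        assert (ref.table["rrn_copies"] == 3.0).all()

    def test_match_count_at_study_rate(self):
        d = SyntheticDesign(n_taxa=10000, seed=2)
        ref = gen_trait_reference(d, match_fraction=0.2156)
        assert len(ref.matched_taxa) == 2156

    def test_same_seed_identical_tables(self):
        d = SyntheticDesign(n_taxa=80, seed=9)
        a = gen_trait_reference(d).table
        b = gen_trait_reference(d).table
        sa, sb = io.StringIO(), io.StringIO()
        a.to_csv(sa)
        b.to_csv(sb)
        assert sa.getvalue() == sb.getvalue()

    def test_empty_taxon_list_rejected(self):
        with pytest.raises(ValueError):
            SyntheticDesign(n_taxa=0, seed=0)


class TestPairedCommunities:
    def test_null_design_between_equals_within(self):
        from cellumend.community import bray_curtis
        d = SyntheticDesign(n_taxa=100, shared_fraction=1.0,
                            dispersion_scale=1.0, depth=3000, seed=3)
        t = gen_paired_communities(d)
        dm = bray_curtis(t)
        hab = t.metadata["habitat"].to_numpy()
        same = hab[:, None] == hab[None, :]
        iu = np.triu_indices(dm.n, 1)
        within = dm.data[iu][same[iu]]
        between = dm.data[iu][~same[iu]]
        assert abs(within.mean() - between.mean()) < 0.02

    def test_planted_enrichment_recovered_across_seeds(self):
        taxa = tuple(f"zOTU{i + 1}" for i in range(50))
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            d = SyntheticDesign(
                n_taxa=150, n_samples_per_group=6, depth=2000, seed=seed,
                enrichment_effects=(EnrichmentEffect(taxa, 2.0,
                                                     target="litterbag"),))
            t = gen_paired_communities(d)
            rel = t.relative()
            lb = t.metadata["habitat"] == "litterbag"
            mean_lb = rel.loc[lb, list(taxa)].to_numpy().mean()
            mean_soil = rel.loc[~lb, list(taxa)].to_numpy().mean()
            hits += mean_lb > mean_soil
        assert hits >= 0.95 * n_seeds

    def test_dispersion_scale_raises_litterbag_heterogeneity(self):
        from cellumend.community import bray_curtis, group_dispersion
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            d = SyntheticDesign(n_taxa=80, n_samples_per_group=6,
                                dispersion_scale=2.0, depth=1500, seed=seed)
            t = gen_paired_communities(d)
            dm = bray_curtis(t)
            disp = group_dispersion(
                dm.subset(t.group_samples("WL") + t.group_samples("WS")),
                {"WL": t.group_samples("WL"), "WS": t.group_samples("WS")},
                permutations=1, seed=seed)
            hits += disp.group_means["WL"] > disp.group_means["WS"]
        assert hits >= 0.95 * n_seeds

    def test_unknown_enrichment_taxon_rejected(self):
        d = SyntheticDesign(n_taxa=20, seed=0,
                            enrichment_effects=((("nope",), 2.0),))
        with pytest.raises(ValueError, match="nope"):
            gen_paired_communities(d)

    def test_relative_abundances_close(self, small_table):
        rel = small_table.relative()
        assert np.allclose(rel.sum(axis=1), 1.0, atol=1e-12)

    def test_same_seed_identical(self, small_design):
        a = gen_paired_communities(small_design)
        b = gen_paired_communities(small_design)
        assert a.counts.equals(b.counts)


class TestProbeTable:
    def test_full_detection_no_effects(self):
        pt = gen_probe_table(60, detection_rate=1.0, seed=4)
        assert (pt.intensities.to_numpy() > 0).all()

    def test_empty_table_flows_through_filter(self):
        pt = gen_probe_table(0, seed=0)
        groups = {g: [s for s in pt.samples if s.startswith(g + "_")]
                  for g in ("WL", "CL", "WS", "CS")}
        out = filter_probes(pt, groups, 3)
        assert out.intensities.empty

    def test_unknown_gene_in_effect_map_rejected(self):
        with pytest.raises(ValueError, match="unknown gene"):
            gen_probe_table(10, effect_map={"not_a_gene": 2.0}, seed=0)

    def test_planted_warming_effect_power(self):
        """1.5-fold endoglucanase enrichment detected at n=12 with
        probe-level noise sd 0.2 in >= 80% of replicates."""
        hits = 0
        n_rep = 50
        for rep in range(n_rep):
            pt = gen_probe_table(100, detection_rate=0.8,
                                 effect_map={"endoglucanase": 1.5},
                                 effect_groups=("WL",), noise_sd=0.2,
                                 seed=5000 + rep)
            groups = {g: [s for s in pt.samples if s.startswith(g + "_")]
                      for g in ("WL", "CL", "WS", "CS")}
            f = filter_probes(pt, groups, 3)
            r = gene_response_ratio(f, "endoglucanase", groups["WL"],
                                    groups["CL"])
            hits += r.status == "enriched"
        assert hits / n_rep >= 0.8


class TestForcing:
    def test_noise_free_difference_is_exactly_offset(self):
        d = ForcingDesign(n_days=200, seed=1, noise_sd={"temperature": 0.0,
                                                        "moisture": 0.0,
                                                        "litter": 0.0})
        c = gen_forcing(d, warmed=False)
        w = gen_forcing(d, warmed=True)
        assert np.allclose(w.temperature - c.temperature,
                           d.warming_offset, atol=1e-12)
        assert np.allclose(w.moisture, c.moisture * (1 - d.moisture_reduction))

    def test_zero_noise_zero_amplitude_constant(self):
        d = ForcingDesign(n_days=50, seasonal_amplitude=0.0, seed=1,
                          noise_sd={"temperature": 0.0, "moisture": 0.0,
                                    "litter": 0.0})
        f = gen_forcing(d)
        assert np.ptp(f.temperature) == 0.0

    def test_default_design_mean_offset(self):
        d = ForcingDesign(seed=12)
        c = gen_forcing(d, warmed=False)
        w = gen_forcing(d, warmed=True)
        assert abs((w.temperature - c.temperature).mean() - 1.8) <= 0.05

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            ForcingDesign(seasonal_amplitude=-1.0)

    def test_litter_nonnegative(self):
        d = ForcingDesign(n_days=365, litter_input_mean=0.001,
                          noise_sd={"litter": 0.01}, seed=3)
        assert (gen_forcing(d).litter_input >= 0).all()


class TestObservations:
    def test_noise_free_gene_series_tracks_enzyme_pool(self, default_params,
                                                       default_init):
        fc = gen_forcing(ForcingDesign(n_days=365, seed=5))
        obs = gen_observations(default_params, default_init, fc,
                               noise_sd_map={"rh": 0, "mbc": 0, "gene": 0},
                               seed=1)
        traj = simulate(default_params, default_init, fc)
        ep2 = traj.pool("EP2")[obs.gene_days + 1]
        assert abs(np.corrcoef(ep2, obs.gene)[0, 1] - 1.0) < 1e-12

    def test_noise_free_self_fit_is_perfect(self, default_params,
                                            default_init):
        from cellumend.calibrate import ObjectiveSpec, objective_total
        fc = gen_forcing(ForcingDesign(n_days=365, seed=6))
        obs = gen_observations(default_params, default_init, fc,
                               noise_sd_map={"rh": 0, "mbc": 0, "gene": 0},
                               seed=2)
        j, j1, j2, j3 = objective_total(default_params, obs, default_init,
                                        fc, ObjectiveSpec(w3=1.0))
        assert j1 == pytest.approx(1.0, abs=1e-12)
        assert j2 == pytest.approx(1.0, abs=1e-12)
        assert j3 == pytest.approx(1.0, abs=1e-9)
        assert j == pytest.approx(0.0, abs=1e-9)

    def test_moderate_noise_keeps_gene_correlation(self, default_params,
                                                   default_init):
        fc = gen_forcing(ForcingDesign(n_days=365, seed=8))
        traj = simulate(default_params, default_init, fc)
        cors = []
        for seed in range(20):
            obs = gen_observations(default_params, default_init, fc,
                                   noise_sd_map={"gene": 0.1}, seed=seed)
            ep2 = traj.pool("EP2")[obs.gene_days + 1]
            cors.append(np.corrcoef(ep2, obs.gene)[0, 1])
        assert min(cors) >= 0.9

    def test_negative_noise_rejected(self, default_params, default_init):
        fc = gen_forcing(ForcingDesign(n_days=60, seed=1))
        with pytest.raises(ValueError):
            gen_observations(default_params, default_init, fc,
                             noise_sd_map={"rh": -0.1}, seed=0)
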