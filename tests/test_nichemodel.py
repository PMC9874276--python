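"""Read universe, beta-binomial GLMM, niche summaries, community-weighted traits."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from trophic import nichemodel, synthio
from trophic.nichemodel import GlmmFit, ReadCountTable
from trophic.synthio import CommunitySimConfig
from trophic.tradeoff import TraitRecord


def annotated_table(rows, samples=("S1", "S2")):
    data = {"otu_id": [r[0] for r in rows], "taxogroup": [r[1] for r in rows]}
    for j, s in enumerate(samples):
        data[s] = [r[2 + j] for r in rows]
    return pd.DataFrame(data)


class TestReadUniverse:
    def test_totals_sum_whitelisted_reads(self):
        raw = annotated_table([
            ("o1", "Haptophyta", 100, 50),
            ("o2", "Pelagophyceae", 40, 60),
        ])
        table = nichemodel.assemble_read_universe(raw)
        assert list(table.totals) == [140, 110]

    def test_dinoflagellate_reads_do_not_change_totals(self):
        base = annotated_table([("o1", "Haptophyta", 100, 50)])
        with_dino = annotated_table([
            ("o1", "Haptophyta", 100, 50),
            ("dino", "Dinophyceae", 9000, 9000),
        ])
        t0 = nichemodel.assemble_read_universe(base)
        t1 = nichemodel.assemble_read_universe(with_dino)
        assert list(t0.totals) == list(t1.totals)
        assert "dino" not in t1.otu_ids

    def test_heterotroph_otus_excluded(self):
        raw = annotated_table([
            ("o1", "Haptophyta", 100, 50),
            ("het", "Chrysophyceae/Synurophyceae", 30, 30),
        ])
        table = nichemodel.assemble_read_universe(raw, heterotroph_otus=["het"])
        assert list(table.totals) == [100, 50]

    def test_empty_whitelist_rejected(self):
        raw = annotated_table([("o1", "Haptophyta", 1, 1)])
        with pytest.raises(ValueError, match="whitelist"):
            nichemodel.assemble_read_universe(raw, whitelist=[])

    def test_unknown_taxogroup_strict_vs_permissive(self):
        raw = annotated_table([("o1", "Haptophyta", 10, 10), ("o2", "Mystery", 5, 5)])
        with pytest.raises(ValueError, match="Mystery"):
            nichemodel.assemble_read_universe(raw, strict=True)
        table = nichemodel.assemble_read_universe(raw, strict=False)
        assert "o2" not in table.otu_ids

    def test_zero_total_sample_dropped(self):
        raw = annotated_table([("o1", "Haptophyta", 10, 0)])
        table = nichemodel.assemble_read_universe(raw)
        assert table.sample_ids == ["S1"]


class TestGlmmFit:
    def test_recovers_interaction_and_covers_truth(self, community):
        table, meta, traits, truth = community
        fit = nichemodel.fit_trait_niche_glmm(table, meta, traits)
        assert fit.creff == pytest.approx(0.5, abs=0.15)
        assert fit.creff_low <= 0.5 <= fit.creff_high

    def test_chla_environment_uses_surface_samples_only(self):
        config = CommunitySimConfig(n_otus=13, n_samples=40, creff_true=0.5,
                                    env_kind="chla_continuous", seed=5)
        table, meta, traits, _ = synthio.gen_community_dataset(config)
        fit = nichemodel.fit_trait_niche_glmm(table, meta, traits,
                                              env_kind="chla_continuous")
        surface = set(meta.loc[meta["layer"] == "surface", "sample_id"])
        assert set(fit.sample_ids) <= surface

    def test_high_chla_station_withheld(self):
        config = CommunitySimConfig(n_otus=8, n_samples=30, creff_true=0.3,
                                    env_kind="chla_continuous", seed=6)
        table, meta, traits, _ = synthio.gen_community_dataset(config)
        meta = meta.copy()
        outlier = meta.loc[meta["layer"] == "surface"].index[0]
        meta.loc[outlier, "chla"] = 5.5
        fit = nichemodel.fit_trait_niche_glmm(table, meta, traits,
                                              env_kind="chla_continuous")
        assert meta.loc[outlier, "sample_id"] not in fit.sample_ids

    def test_mixotroph_subset_recovers_same_sign(self, community):
        table, meta, traits, _ = community
        fit_all = nichemodel.fit_trait_niche_glmm(table, meta, traits)
        fit_mix = nichemodel.fit_trait_niche_glmm(table, meta, traits,
                                                  subset="mixotrophs_only")
        assert np.sign(fit_mix.creff) == np.sign(fit_all.creff)

    def test_taxon_variance_near_zero_on_null_taxa(self, community):
        table, meta, traits, _ = community
        fit = nichemodel.fit_trait_niche_glmm(table, meta, traits,
                                              include_taxon_effects=True)
        assert fit.taxon_variance is not None and fit.taxon_variance < 0.05

    def test_identical_clearances_unidentifiable(self, community):
        table, meta, traits, _ = community
        flat = [TraitRecord(t.strain_id, 1.0, t.growth_high_light,
                            t.growth_low_light, True, otu_id=t.otu_id)
                for t in traits]
        with pytest.raises(ValueError, match="unidentifiable|identical"):
            nichemodel.fit_trait_niche_glmm(table, meta, flat)

    def test_invariance_to_otu_and_sample_order(self, community):
        table, meta, traits, _ = community
        fit = nichemodel.fit_trait_niche_glmm(table, meta, traits)
        rng = np.random.default_rng(0)
        otu_perm = list(rng.permutation(table.otu_ids))
        sample_perm = list(rng.permutation(table.sample_ids))
        shuffled = table.select_otus(otu_perm).select_samples(sample_perm)
        fit2 = nichemodel.fit_trait_niche_glmm(shuffled, meta, traits)
        assert fit2.creff == pytest.approx(fit.creff, abs=1e-3)

    def test_mcmc_mode_agrees_with_laplace_point_estimate(self):
        config = CommunitySimConfig(n_otus=8, n_samples=24, creff_true=0.4,
                                    total_reads=5000, seed=9)
        table, meta, traits, _ = synthio.gen_community_dataset(config)
        lap = nichemodel.fit_trait_niche_glmm(table, meta, traits)
        mcmc = nichemodel.fit_trait_niche_glmm(table, meta, traits, fit_method="mcmc",
                                               mcmc_steps=600, mcmc_burn=300, seed=2)
        assert mcmc.creff == pytest.approx(lap.creff, abs=0.15)
        assert mcmc.creff_low <= mcmc.creff <= mcmc.creff_high

    def test_fixed_effect_fit_matches_glmmtmb(self, tmp_path):
        # independent oracle: R glmmTMB on the same beta-binomial regression
        config = CommunitySimConfig(n_otus=8, n_samples=24, creff_true=0.6,
                                    slope_sd=0.0, sample_sd=0.0,
                                    total_reads=20000, seed=9)
        table, meta, traits, truth = synthio.gen_community_dataset(config)
        env = np.array(truth["env_model"])
        crz = np.array(truth["cr_z"])
        rows = []
        for i, otu in enumerate(table.otu_ids):
            for j in range(len(table.sample_ids)):
                rows.append({"otu": otu, "reads": int(table.reads[i, j]),
                             "total": int(table.totals[j]),
                             "crz_env": crz[i] * env[j]})
        csv = tmp_path / "bb.csv"
        pd.DataFrame(rows).to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(glmmTMB))
            d <- read.csv("{csv}")
            m <- glmmTMB(cbind(reads, total - reads) ~ crz_env + (1 | otu),
                         family = betabinomial(link = "logit"), data = d)
            cat(summary(m)$coefficients$cond["crz_env", "Estimate"], "\\n")
        """))
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True)
        reference = float(out.stdout.strip().split()[-1])
        fit = nichemodel.fit_trait_niche_glmm(table, meta, traits)
        assert fit.creff == pytest.approx(reference, abs=0.1)


def manual_fit(intercepts, slopes, creff, cr, env_kind="depth_binary"):
    cr = np.asarray(cr, float)
    crz = (cr - cr.mean()) / cr.std()
    n = len(cr)
    return GlmmFit(
        creff=creff, creff_low=creff - 0.1, creff_high=creff + 0.1,
        intercepts=np.asarray(intercepts, float), sample_effects=np.zeros(3),
        slopes=np.asarray(slopes, float), dispersions=np.full(n, 100.0),
        env_kind=env_kind, fit_method="map_laplace",
        otu_ids=[f"o{i}" for i in range(n)], sample_ids=["s1", "s2", "s3"],
        cr_values=cr, cr_z=crz,
    )


class TestNicheSummaries:
    def test_zero_total_effect_gives_unit_ratio(self):
        cr = [0.0, 1.0, 2.0]
        crz = (np.array(cr) - np.mean(cr)) / np.std(cr)
        fit = manual_fit([-3, -3, -3], -0.4 * crz, 0.4, cr)
        out = nichemodel.derive_otu_niche_summaries(fit, [])
        assert np.allclose(out["surface_dcm_ratio"], 1.0)

    def test_small_p_ratio_approximates_exp_of_logit_difference(self):
        cr = [0.0, 1.0, 2.0]
        slopes = np.array([0.5, -0.2, 0.1])
        fit = manual_fit([-7, -7, -7], slopes, 0.3, cr)
        out = nichemodel.derive_otu_niche_summaries(fit, [])
        d = fit.cr_z * 0.3 + slopes
        assert np.allclose(out["surface_dcm_ratio"], np.exp(d), rtol=0.01)

    def test_depth_ratio_unavailable_from_chla_fit(self):
        fit = manual_fit([-3, -3, -3], [0, 0, 0], 0.3, [0, 1, 2],
                         env_kind="other")
        with pytest.raises(TypeError):
            nichemodel.derive_otu_niche_summaries(fit, [])

    def test_single_positive_responder_sign_recovered(self):
        # autotroph-like OTUs (lowest clearance) get positive Chl slopes when
        # the interaction is negative; grazers get negative slopes
        config = CommunitySimConfig(n_otus=10, n_samples=40, creff_true=-0.6,
                                    slope_sd=0.0, env_kind="chla_continuous", seed=21)
        table, meta, traits, _ = synthio.gen_community_dataset(config)
        fit = nichemodel.fit_trait_niche_glmm(table, meta, traits,
                                              env_kind="chla_continuous")
        out = nichemodel.derive_otu_niche_summaries(fit, traits).set_index("otu_id")
        cr = out["clearance_specific"]
        assert out.loc[cr.idxmin(), "chla_slope"] > 0
        assert out.loc[cr.idxmax(), "chla_slope"] < 0
        assert out.attrs["r_squared"] > 0.5


class TestCommunityWeightedTrait:
    def table(self, reads, cr):
        n_otus, n_samples = np.shape(reads)
        table = ReadCountTable(
            otu_ids=[f"o{i}" for i in range(n_otus)],
            sample_ids=[f"s{j}" for j in range(n_samples)],
            reads=np.asarray(reads), totals=np.asarray(reads).sum(axis=0) + 10,
        )
        traits = [TraitRecord(f"st{i}", float(c), 0.3, 0.0, c > 0, otu_id=f"o{i}")
                  for i, c in enumerate(cr)]
        return table, traits

    def test_single_otu_sample_equals_its_trait(self):
        table, traits = self.table([[50], [0]], cr=[3.0, 1.0])
        cwm = nichemodel.community_weighted_trait(table, traits)
        assert cwm["s0"] == pytest.approx(3.0)

    def test_equal_reads_average_traits(self):
        table, traits = self.table([[50], [50]], cr=[0.0, 4.0])
        cwm = nichemodel.community_weighted_trait(table, traits)
        assert cwm["s0"] == pytest.approx(2.0)

    def test_zero_matched_reads_gives_nan(self):
        table, traits = self.table([[50, 0], [50, 0]], cr=[0.0, 4.0])
        cwm = nichemodel.community_weighted_trait(table, traits)
        assert np.isnan(cwm["s1"])

    def test_constructed_gradient_quadruples_cwm(self):
        # two OTUs with CR 1 and 4; mixing fraction tuned so CWM runs 1 -> 4
        fracs = np.linspace(0.0, 1.0, 9)
        reads = np.round(1e4 * np.vstack([1 - fracs, fracs])).astype(int)
        table, traits = self.table(reads, cr=[1.0, 4.0])
        cwm = nichemodel.community_weighted_trait(table, traits)
        assert cwm.iloc[-1] / cwm.iloc[0] == pytest.approx(4.0, abs=0.2)
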