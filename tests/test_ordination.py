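"""PCoA of community composition and its trait/environment overlays."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import procrustes
from scipy.spatial.distance import pdist, squareform

from trophic import ordination, synthio
from trophic.nichemodel import ReadCountTable
from trophic.synthio import CommunitySimConfig
from trophic.tradeoff import TraitRecord


def make_table(reads, totals=None):
    reads = np.asarray(reads)
    n_otus, n_samples = reads.shape
    if totals is None:
        totals = reads.sum(axis=0)
    return ReadCountTable(
        otu_ids=[f"o{i}" for i in range(n_otus)],
        sample_ids=[f"s{j}" for j in range(n_samples)],
        reads=reads, totals=totals,
    )


@pytest.fixture(scope="module")
def stratified_community():
    config = CommunitySimConfig(n_otus=13, n_samples=60, creff_true=-0.6,
                                env_kind="chla_continuous", seed=11)
    return synthio.gen_community_dataset(config)


class TestPcoa:
    def test_bray_curtis_matches_hand_calculation(self):
        reads = np.array([[10, 0, 5], [0, 10, 5]])
        table = make_table(reads)
        profiles = (reads / reads.sum(axis=0)).T
        expected = squareform(pdist(profiles, "braycurtis"))
        # hand value: samples 1 and 2 share nothing -> distance 1
        assert expected[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert expected[0, 2] == pytest.approx(0.5, abs=1e-12)
        result = ordination.pcoa_composition(table)
        # reconstructed distances from all coordinates match the input metric
        coords = result.axis_scores.to_numpy()
        recon = squareform(pdist(coords))
        assert np.allclose(recon, expected, atol=1e-10)

    def test_euclidean_pcoa_reproduces_plane_points(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(1, 10, size=(8, 2))
        reads = np.round(pts * 100).astype(int).T  # 2 OTUs x 8 samples
        totals = np.full(8, 10_000)
        table = make_table(reads, totals=totals)
        result = ordination.pcoa_composition(table, metric="euclidean",
                                             renormalize=False)
        profiles = (reads / totals[None, :]).T
        _, _, disparity = procrustes(profiles, result.axis_scores.to_numpy()[:, :2])
        assert disparity < 1e-10

    def test_two_clusters_separated_on_axis_one(self):
        rng = np.random.default_rng(1)
        block_a = rng.integers(200, 300, size=(3, 6))
        block_b = rng.integers(0, 10, size=(3, 6))
        reads = np.block([[block_a, block_b], [block_b, block_a]])
        table = make_table(reads)
        result = ordination.pcoa_composition(table)
        axis1 = result.axis_scores["PC1"].to_numpy()
        assert (axis1[:6].max() < axis1[6:].min()) or (axis1[6:].max() < axis1[:6].min())
        # variance explained matches a direct eigendecomposition oracle
        profiles = (reads / reads.sum(axis=0)).T
        d = squareform(pdist(profiles, "braycurtis"))
        if result.cailliez_constant > 0:
            d = d + result.cailliez_constant * ((d > 0) & ~np.eye(len(d), dtype=bool))
        n = len(d)
        J = np.eye(n) - np.ones((n, n)) / n
        eig = np.linalg.eigvalsh(-0.5 * J @ (d**2) @ J)
        pos = np.sort(eig[eig > 1e-12])[::-1]
        assert result.variance_explained[0] == pytest.approx(pos[0] / pos.sum(), rel=1e-6)

    def test_eigenvalue_sum_equals_total_inertia(self, stratified_community):
        table, meta, traits, _ = stratified_community
        result = ordination.pcoa_composition(table)
        profiles = table.reads / table.reads.sum(axis=0)[None, :]
        d = squareform(pdist(profiles.T, "braycurtis"))
        if result.cailliez_constant > 0:
            d = d + result.cailliez_constant * ((d > 0) & ~np.eye(len(d), dtype=bool))
        n = len(d)
        J = np.eye(n) - np.ones((n, n)) / n
        inertia = np.trace(-0.5 * J @ (d**2) @ J)
        assert result.eigenvalues.sum() == pytest.approx(inertia, rel=1e-10)

    def test_order_invariance(self, stratified_community):
        table, *_ = stratified_community
        result = ordination.pcoa_composition(table)
        rng = np.random.default_rng(3)
        shuffled = table.select_otus(list(rng.permutation(table.otu_ids)))
        shuffled = shuffled.select_samples(list(rng.permutation(table.sample_ids)))
        result2 = ordination.pcoa_composition(shuffled)
        assert np.allclose(result.eigenvalues[:5], result2.eigenvalues[:5], atol=1e-9)
        s1 = result.axis_scores["PC1"]
        s2 = result2.axis_scores["PC1"].reindex(s1.index)
        assert np.allclose(np.abs(s1), np.abs(s2), atol=1e-9)

    def test_duplicate_sample_coincides(self):
        rng = np.random.default_rng(5)
        reads = rng.integers(10, 100, size=(4, 6))
        reads = np.hstack([reads, reads[:, [0]]])
        table = make_table(reads)
        result = ordination.pcoa_composition(table)
        a = result.axis_scores.iloc[0].to_numpy()
        b = result.axis_scores.iloc[-1].to_numpy()
        assert np.linalg.norm(a - b) < 1e-8

    def test_identical_samples_degenerate(self):
        table = make_table(np.tile([[5], [5]], (1, 4)))
        with pytest.raises(ValueError, match="degenerate"):
            ordination.pcoa_composition(table)


class TestEnvironmentCorrelations:
    def test_axis_equal_to_metadata_column_gives_unit_r(self):
        rng = np.random.default_rng(2)
        scores = pd.DataFrame({"PC1": rng.normal(size=10)},
                              index=[f"s{j}" for j in range(10)])
        result = ordination.OrdinationResult(
            axis_scores=scores, eigenvalues=np.array([1.0]),
            variance_explained=np.array([1.0]),
            otu_scores=pd.DataFrame({"PC1": [1.0]}, index=["o0"]),
            distance_metric="braycurtis",
        )
        meta = pd.DataFrame({"sample_id": scores.index, "chla": scores["PC1"].to_numpy()})
        out = ordination.correlate_axis_environment(result, meta, variables=("chla",))
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_stratification_sign_pattern_recovered(self, stratified_community):
        table, meta, traits, _ = stratified_community
        surface = meta.loc[meta["layer"] == "surface", "sample_id"].tolist()
        result = ordination.pcoa_composition(table, samples=surface)
        corr = ordination.correlate_axis_environment(result, meta).set_index("variable")
        assert corr.loc["chla", "r"] > 0
        assert corr.loc["nitrate", "r"] > 0
        assert corr.loc["mld", "r"] > 0
        assert corr.loc["sst", "r"] < 0
        assert corr.loc["par_depth", "r"] < 0

    def test_axis_reflection_leaves_magnitudes_unchanged(self, stratified_community):
        table, meta, *_ = stratified_community
        result = ordination.pcoa_composition(table)
        corr = ordination.correlate_axis_environment(result, meta)
        result.axis_scores["PC1"] *= -1
        corr_flipped = ordination.correlate_axis_environment(result, meta)
        assert np.allclose(np.abs(corr["r"]), np.abs(corr_flipped["r"]))


class TestTraitCorrelation:
    def test_traits_equal_to_positions_give_unit_r(self, stratified_community):
        table, meta, traits, _ = stratified_community
        result = ordination.pcoa_composition(table)
        positions = result.otu_scores["PC1"]
        shift = float(positions.min())
        synth = [TraitRecord(f"t{i}", float(v) - shift + 0.01, 0.3, 0.0, True,
                             otu_id=o)
                 for i, (o, v) in enumerate(positions.items())]
        # traits are an affine transform of positions, so r = 1 exactly
        r, _ = ordination.correlate_axis_trait(result, synth)
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_grazers_load_opposite_to_stratification(self, stratified_community):
        # generated with negative trait x environment interaction: high-CR OTUs
        # decline as the stratification axis (oriented +Chl a) increases
        table, meta, traits, _ = stratified_community
        surface = meta.loc[meta["layer"] == "surface", "sample_id"].tolist()
        result = ordination.pcoa_composition(table, samples=surface)
        corr = ordination.correlate_axis_environment(result, meta).set_index("variable")
        flip = -1.0 if corr.attrs.get("axis_flipped") else 1.0
        result.axis_scores["PC1"] *= flip
        result.otu_scores["PC1"] *= flip
        r, p = ordination.correlate_axis_trait(result, traits)
        assert r < -0.4

    def test_constant_trait_rejected(self, stratified_community):
        table, *_ = stratified_community
        result = ordination.pcoa_composition(table)
        flat = [TraitRecord(f"t{i}", 1.0, 0.3, 0.0, True, otu_id=o)
                for i, o in enumerate(result.otu_scores.index)]
        with pytest.raises(ValueError, match="constant"):
            ordination.correlate_axis_trait(result, flat)
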