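"""Portraits, spot segmentation (vs. a flood-fill oracle), rendering, wTO."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from PIL import Image

from somportrait.portraits import (
    Portrait,
    detect_spots,
    gene_spot_frame,
    group_spot_summary,
    mean_portrait,
    render_portrait,
    render_portraits,
    sample_portrait,
    spot_expression_profile,
    spot_profiles,
    unassigned_genes,
    wto_network,
)
from somportrait.som import SOMConfig, train

from conftest import centered


def flood_fill_components(mask: np.ndarray) -> list[set[tuple[int, int]]]:
    """Brute-force 8-connected components, independent of skimage."""
    rows, cols = mask.shape
    seen = set()
    components = []
    for r in range(rows):
        for c in range(cols):
            if not mask[r, c] or (r, c) in seen:
                continue
            stack, comp = [(r, c)], set()
            while stack:
                y, x = stack.pop()
                if (y, x) in comp:
                    continue
                comp.add((y, x))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        yy, xx = y + dy, x + dx
                        if 0 <= yy < rows and 0 <= xx < cols and mask[yy, xx] \
                                and (yy, xx) not in comp:
                            stack.append((yy, xx))
            seen |= comp
            components.append(comp)
    return components


class TestPortraits:
    @pytest.fixture(scope="class")
    def model(self):
        rng = np.random.default_rng(0)
        return train(
            centered(rng.normal(size=(60, 6))), SOMConfig(rows=5, cols=4, n_epochs=10)
        )

    def test_reshape_conserves_column_sum(self, model):
        portrait = sample_portrait(model, "s2")
        assert portrait.values.shape == (5, 4)
        assert portrait.values.sum() == pytest.approx(model.codebook[:, 2].sum())
        # row-major: unit k sits at (k // cols, k % cols)
        assert portrait.values[1, 3] == model.codebook[1 * 4 + 3, 2]

    def test_unknown_sample_errors(self, model):
        with pytest.raises(KeyError):
            sample_portrait(model, "who")

    def test_identical_input_columns_give_identical_portraits(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 3))
        X[:, 2] = X[:, 0]
        model = train(centered(X), SOMConfig(rows=3, cols=3, n_epochs=8))
        a, b = sample_portrait(model, "s0"), sample_portrait(model, "s2")
        assert np.allclose(a.values, b.values)

    def test_mean_portrait_identity_symmetry_idempotence(self):
        rng = np.random.default_rng(2)
        p = Portrait("p", rng.normal(size=(4, 4)))
        neg = Portrait("n", -p.values)
        assert np.array_equal(mean_portrait([p], "m").values, p.values)
        assert np.allclose(mean_portrait([p, neg], "m").values, 0.0)
        assert np.allclose(mean_portrait([p, p, p], "m").values, p.values)
        with pytest.raises(ValueError):
            mean_portrait([], "empty")


class TestRendering:
    def test_constant_portrait_renders_single_color(self, tmp_path):
        path = render_portrait(Portrait("flat", np.full((6, 6), 2.0)), tmp_path / "flat.png")
        pixels = np.asarray(Image.open(path).convert("RGB"))
        assert (pixels == pixels[0, 0]).all()

    def test_pixel_dimensions_proportional_to_lattice(self, tmp_path):
        path = render_portrait(
            Portrait("p", np.random.default_rng(3).normal(size=(5, 8))),
            tmp_path / "p.png",
            upscale=7,
        )
        with Image.open(path) as img:
            assert img.size == (8 * 7, 5 * 7)  # (width, height)

    def test_shared_scale_uses_one_global_min_max(self, tmp_path):
        low = Portrait("low", np.zeros((4, 4)))
        high = Portrait("high", np.full((4, 4), 10.0))
        paths = render_portraits([low, high], tmp_path, shared_scale=True)
        solo = render_portrait(low, tmp_path / "solo.png", vmin=0.0, vmax=10.0)
        shared_bytes = (paths["low"]).read_bytes()
        assert shared_bytes == solo.read_bytes()

    def test_rendering_does_not_mutate_the_portrait(self, tmp_path):
        values = np.random.default_rng(4).normal(size=(4, 4))
        portrait = Portrait("p", values.copy())
        render_portrait(portrait, tmp_path / "p.png")
        assert np.array_equal(portrait.values, values)


class TestDetectSpots:
    def test_two_plateaus_give_two_spots_matching_flood_fill(self):
        values = np.zeros((10, 10))
        values[0:3, 0:3] = 5.0   # 9 units
        values[7:10, 7:10] = 4.0  # 9 units
        portrait = Portrait("two", values)
        spots = detect_spots(portrait, threshold_quantile=0.9, min_units=4)
        assert len(spots) == 2
        threshold = np.quantile(values, 0.9)
        oracle = [c for c in flood_fill_components(values >= threshold) if len(c) >= 4]
        assert sorted(map(sorted, oracle)) == sorted(sorted(s.units) for s in spots)
        # labels in decreasing peak order
        assert spots[0].peak_value >= spots[1].peak_value
        assert [s.label for s in spots] == ["A", "B"]

    def test_min_units_dominates(self):
        values = np.zeros((8, 8))
        values[0, 0:3] = 1.0
        portrait = Portrait("small", values)
        assert detect_spots(portrait, threshold_quantile=0.97, min_units=4) == []

    def test_constant_portrait_yields_one_lattice_spanning_spot(self):
        spots = detect_spots(Portrait("flat", np.ones((6, 6))), 0.98, 4)
        assert len(spots) == 1
        assert len(spots[0].units) == 36

    def test_segmentation_matches_flood_fill_on_random_portraits(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            values = rng.normal(size=(12, 12))
            portrait = Portrait("r", values)
            spots = detect_spots(portrait, threshold_quantile=0.9, min_units=2)
            threshold = np.quantile(values, 0.9)
            oracle = [
                sorted(c)
                for c in flood_fill_components(values >= threshold)
                if len(c) >= 2
            ]
            assert sorted(oracle) == sorted(sorted(s.units) for s in spots)
            # disjointness
            all_units = [u for s in spots for u in s.units]
            assert len(all_units) == len(set(all_units))

    def test_bad_quantile_rejected(self):
        with pytest.raises(ValueError):
            detect_spots(Portrait("p", np.ones((3, 3))), threshold_quantile=1.5)


class TestGroupSummary:
    def test_single_group_reduces_to_detect_spots(self, small_run):
        model = small_run["model"]
        samples = list(model.sample_ids)
        catalog = group_spot_summary(
            model, {"all": samples}, threshold_quantile=0.95, min_units=3
        )
        portrait = mean_portrait([sample_portrait(model, s) for s in samples], "all")
        direct = detect_spots(portrait, 0.95, 3)
        assert sorted(sorted(s.units) for s in catalog) == sorted(
            sorted(s.units) for s in direct
        )

    def test_overlapping_groups_rejected(self, small_run):
        model = small_run["model"]
        s = list(model.sample_ids)
        with pytest.raises(ValueError, match="appears in groups"):
            group_spot_summary(model, {"a": s[:3], "b": s[2:5]})

    def test_gene_counts_are_definitional(self, small_run):
        model = small_run["model"]
        catalog = group_spot_summary(model, small_run["groups"], 0.97, 3)
        for spot in catalog:
            unit_idx = {r * model.cols + c for r, c in spot.units}
            expected = {
                g for g, u in zip(model.gene_ids, model.bmu) if int(u) in unit_idx
            }
            assert set(spot.member_genes) == expected
            assert spot.n_genes == len(spot.member_genes)

    def test_each_gene_in_at_most_one_spot_and_rest_unassigned(self, small_run):
        model = small_run["model"]
        catalog = group_spot_summary(model, small_run["groups"], 0.97, 3)
        assigned = gene_spot_frame(catalog)["gene_id"]
        assert not assigned.duplicated().any()
        assert len(assigned) + len(unassigned_genes(model, catalog)) == len(model.gene_ids)


class TestSpotProfilesAndWTO:
    def test_singleton_spot_profile_is_that_unit_row(self, small_run):
        model = small_run["model"]
        from somportrait.portraits import SpotModule

        spot = SpotModule("X", frozenset({(2, 3)}), 1.0, (2, 3), "warm")
        profile = spot_expression_profile(model, spot)
        assert np.allclose(profile.to_numpy(), model.codebook[2 * model.cols + 3])
        assert len(profile) == len(model.sample_ids)

    def test_full_lattice_spot_profile_is_codebook_column_means(self, small_run):
        model = small_run["model"]
        from somportrait.portraits import SpotModule

        units = frozenset((r, c) for r in range(model.rows) for c in range(model.cols))
        spot = SpotModule("F", units, 1.0, (0, 0), "warm")
        assert np.allclose(
            spot_expression_profile(model, spot).to_numpy(), model.codebook.mean(axis=0)
        )

    def test_wto_two_spots_reduces_to_adjacency(self):
        """Algebraic n=2 reduction: ω₁₂ = a₁₂ (verified against the raw formula)."""
        rng = np.random.default_rng(6)
        profiles = pd.DataFrame(rng.normal(size=(2, 12)), index=["A", "B"])
        network = wto_network(profiles)
        a12 = abs(np.corrcoef(profiles.values)[0, 1])
        # brute-force evaluation of the formula
        a = np.abs(np.corrcoef(profiles.values))
        num = sum(a[0, u] * a[u, 1] for u in range(2)) - a[0, 0] * a[0, 1] \
            - a[0, 1] * a[1, 1] + a[0, 1]
        den = min(a[0, 1], a[1, 0]) + 1 - a[0, 1]
        assert network.wto.loc["A", "B"] == pytest.approx(num / den)
        assert network.wto.loc["A", "B"] == pytest.approx(a12)

    def test_wto_identical_profiles_is_all_ones(self):
        profile = np.arange(8.0)
        profiles = pd.DataFrame([profile, profile, profile], index=list("ABC"))
        network = wto_network(profiles)
        assert np.allclose(network.wto.to_numpy(), 1.0)

    def test_wto_symmetric_unit_interval_on_random_profiles(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            profiles = pd.DataFrame(rng.normal(size=(6, 15)))
            w = wto_network(profiles).wto.to_numpy()
            assert np.allclose(w, w.T)
            assert (w >= 0).all() and (w <= 1).all()
            assert np.allclose(np.diag(w), 1.0)

    def test_constant_profile_warns_and_gets_zero_correlation(self):
        profiles = pd.DataFrame(
            [np.arange(6.0), np.ones(6)], index=["ok", "flat"]
        )
        with pytest.warns(UserWarning, match="constant"):
            network = wto_network(profiles)
        assert network.correlation.loc["ok", "flat"] == 0.0

    def test_wto_needs_two_spots(self):
        with pytest.raises(ValueError):
            wto_network(pd.DataFrame([np.arange(4.0)]))


class TestPlantedRecoverySmall:
    def test_one_spot_per_condition_with_planted_modules(self, small_run):
        """Scaled-down structural recovery: each condition yields its own spot."""
        model, config = small_run["model"], small_run["config"]
        catalog = group_spot_summary(model, small_run["groups"], 0.95, 3)
        sources = {src for s in catalog for src in s.source_portrait.split("+")}
        assert sources == set(small_run["design"].conditions)

    def test_opposite_condition_spot_profiles_anticorrelate(self, small_run):
        model = small_run["model"]
        catalog = group_spot_summary(model, small_run["groups"], 0.95, 3)
        profiles = spot_profiles(model, catalog)
        by_condition = {}
        for s in catalog:
            by_condition.setdefault(s.source_portrait.split("+")[0], s.label)
        corr = np.corrcoef(
            profiles.loc[by_condition["warm"]], profiles.loc[by_condition["freeze"]]
        )[0, 1]
        assert corr < 0
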