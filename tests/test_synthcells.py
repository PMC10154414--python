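"""Synthetic generators: seeded determinism, placement geometry, and the
statistical structure downstream stages rely on."""

import numpy as np
import pytest

from sdscam import coag, structmetrics, synthcells
from sdscam.synthcells import (
    PlacementError,
    ToyStructureSpec,
    generate_cell_field,
    generate_repertoire_pair,
    generate_toy_dimer,
)

from conftest import SMALL_FRAME


class TestCellField:
    def test_empty_field_is_all_zeros(self):
        img = generate_cell_field(0, 0, "disperse", image_dims=SMALL_FRAME, seed=0)
        assert img.red_channel.sum() == 0
        assert img.green_channel.sum() == 0

    def test_seed_determinism_bit_identical(self):
        a = generate_cell_field(40, 40, "coaggregate", image_dims=SMALL_FRAME, seed=7)
        b = generate_cell_field(40, 40, "coaggregate", image_dims=SMALL_FRAME, seed=7)
        assert np.array_equal(a.red_channel, b.red_channel)
        assert np.array_equal(a.green_channel, b.green_channel)
        c = generate_cell_field(40, 40, "coaggregate", image_dims=SMALL_FRAME, seed=8)
        assert not np.array_equal(a.red_channel, c.red_channel)

    def test_channel_conservation_counts(self):
        img = generate_cell_field(37, 23, "coaggregate", image_dims=SMALL_FRAME, seed=3)
        assert len(img.provenance["red_centers"]) == 37
        assert len(img.provenance["green_centers"]) == 23

    def test_segregate_squares_are_monochrome_by_construction(self):
        """With clusters > 4 cluster radii apart, no CoAg square can reach
        both colors: verified brute-force from the stored cell centers."""
        img = generate_cell_field(
            100, 100, "segregate", cluster_count=2, cluster_radius_px=80,
            image_dims=SMALL_FRAME, seed=11,
        )
        grid = coag.default_grid(img)
        diag = grid.square_side_px * np.sqrt(2)
        reach = diag + 2 * img.cell_radius_px
        red = img.provenance["red_centers"]
        green = img.provenance["green_centers"]
        d = np.linalg.norm(red[:, None, :] - green[None, :, :], axis=2)
        assert d.min() > reach  # no square can intersect both colors
        result = coag.coag_index(img, grid)
        assert result.n_mixed == 0

    def test_coaggregate_cells_lie_within_cluster_radius(self):
        img = generate_cell_field(
            100, 100, "coaggregate", cluster_count=2, cluster_radius_px=80,
            image_dims=SMALL_FRAME, seed=5,
        )
        centers = img.provenance["cluster_centers"]
        all_cells = np.vstack(
            [img.provenance["red_centers"], img.provenance["green_centers"]]
        )
        dists = np.linalg.norm(
            all_cells[:, None, :] - centers[None, :, :], axis=2
        ).min(axis=1)
        assert (dists <= 80.0).mean() >= 0.9

    def test_painted_intensities_in_unit_range(self):
        img = generate_cell_field(
            50, 50, "coaggregate", image_dims=SMALL_FRAME, seed=2, noise_sigma=0.05
        )
        for ch in (img.red_channel, img.green_channel):
            assert ch.min() >= 0 and ch.max() <= 1

    def test_placement_failure_names_limiting_parameter(self):
        with pytest.raises(PlacementError):
            generate_cell_field(
                10, 10, "segregate", cluster_count=4, cluster_radius_px=200,
                image_dims=(400, 400), seed=0,
            )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            generate_cell_field(-1, 0, "disperse", image_dims=SMALL_FRAME)
        with pytest.raises(ValueError):
            generate_cell_field(
                1, 1, "coaggregate", cluster_radius_px=1.0,
                cell_radius_px=5.6, image_dims=SMALL_FRAME,
            )

    def test_mode_label_recovered_downstream(self):
        """classify_mixing recovers the generation mode for >= 90% of
        segregate and coaggregate images."""
        hits = {m: 0 for m in ("segregate", "coaggregate")}
        n = 25
        for mode, want in (("segregate", "segregated"), ("coaggregate", "intermixed")):
            for seed in range(n):
                img = generate_cell_field(
                    100, 100, mode, cluster_count=2, cluster_radius_px=80,
                    image_dims=SMALL_FRAME, seed=seed,
                )
                if coag.coag_index(img).classification == want:
                    hits[mode] += 1
        assert hits["segregate"] >= 0.9 * n
        assert hits["coaggregate"] >= 0.9 * n

    def test_image_roundtrip_png(self, tmp_path):
        img = generate_cell_field(20, 20, "coaggregate", image_dims=SMALL_FRAME, seed=1)
        path = tmp_path / "field.png"
        synthcells.write_image(img, path)
        back = synthcells.read_image(path)
        assert back.shape == img.shape
        # 8-bit quantization: intensities agree to 1/255
        assert np.abs(back.red_channel - img.red_channel).max() <= 1 / 255 + 1e-6
        assert (tmp_path / "field.png.provenance.txt").exists()


class TestRepertoirePair:
    def test_full_sharing_gives_identical_sets(self):
        a, b = generate_repertoire_pair(20000, 50, 50, seed=1)
        assert a.isoforms == b.isoforms

    def test_zero_sharing_gives_disjoint_sets(self):
        a, b = generate_repertoire_pair(20000, 50, 0, seed=1)
        assert not (a.isoforms & b.isoforms)

    @pytest.mark.parametrize("shared", [0, 1, 3, 5])
    def test_exact_shared_count_and_size(self, shared):
        a, b = generate_repertoire_pair(100, 5, shared, seed=shared)
        assert a.k == b.k == 5
        assert len(a.isoforms & b.isoforms) == shared

    def test_infeasible_constraints_raise(self):
        with pytest.raises(ValueError):
            generate_repertoire_pair(10, 6, 1, seed=0)  # 2k - shared > pool
        with pytest.raises(ValueError):
            generate_repertoire_pair(10, 3, 4, seed=0)  # shared > k

    def test_marginal_uniformity_over_seeds(self):
        """Each pool element lands in repertoire A with frequency k/N
        (binomial SE oracle) — exchangeability of the constrained draw."""
        N, k, shared, reps = 10, 3, 1, 10_000
        counts = np.zeros(N)
        for seed in range(reps):
            a, _ = generate_repertoire_pair(N, k, shared, seed=seed)
            for i in a.isoforms:
                counts[i] += 1
        freq = counts / reps
        se = np.sqrt((k / N) * (1 - k / N) / reps)
        assert np.all(np.abs(freq - k / N) <= 3 * se)


class TestToyDimer:
    def test_exact_rigid_copy_superposes_to_zero(self):
        spec = ToyStructureSpec(
            n_residues=60,
            rotation=_rot_z(40.0),
            translation=np.array([5.0, -3.0, 8.0]),
            noise_sigma=0.0,
        )
        model = generate_toy_dimer(spec)
        sup = structmetrics.kabsch_superpose(model.chain("A"), model.chain("B"))
        assert sup.rmsd < 1e-8

    def test_translation_only_recovers_identity_rotation(self):
        spec = ToyStructureSpec(
            n_residues=60, translation=np.array([10.0, 0.0, 0.0])
        )
        model = generate_toy_dimer(spec)
        sup = structmetrics.kabsch_superpose(model.chain("A"), model.chain("B"))
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-6)

    def test_noise_sets_rmsd_scale(self):
        """With isotropic per-coordinate noise sigma on one chain, the
        superposition RMSD concentrates near sigma*sqrt(3) for large n."""
        sigma, n_res, n_seeds = 0.5, 200, 100
        rmsds = []
        for seed in range(n_seeds):
            spec = ToyStructureSpec(
                n_residues=n_res, rotation=_rot_z(25.0),
                translation=np.array([3.0, 4.0, 5.0]),
                noise_sigma=sigma, seed=seed,
            )
            model = generate_toy_dimer(spec)
            sup = structmetrics.kabsch_superpose(model.chain("A"), model.chain("B"))
            rmsds.append(sup.rmsd)
        expected = sigma * np.sqrt(3.0)
        assert abs(np.mean(rmsds) - expected) / expected < 0.10

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ToyStructureSpec(rotation=np.diag([1.0, 1.0, -1.0]))  # reflection
        with pytest.raises(ValueError):
            ToyStructureSpec(noise_sigma=-0.1)
        with pytest.raises(ValueError):
            ToyStructureSpec(geometry="sheet")

    @pytest.mark.parametrize("geometry", ["helix", "strand", "coil"])
    def test_geometries_deterministic(self, geometry):
        spec = ToyStructureSpec(n_residues=30, geometry=geometry, seed=4)
        m1, m2 = generate_toy_dimer(spec), generate_toy_dimer(spec)
        assert np.array_equal(m1.coords, m2.coords)


def _rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
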