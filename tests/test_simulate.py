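"""Synthetic image pairs and expression matrices with planted ground truth."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
import yaml

from punctacoloc.simulate import (
    ExprSimConfig,
    ImageSimConfig,
    load_config,
    simulate_expression,
    simulate_image_pair,
    truth_to_frame,
    write_image_pair_png,
    write_image_pair_tiff,
    write_truth_csv,
)


def small_cfg(**kw) -> ImageSimConfig:
    base = dict(height=200, width=200, n_spots_A=15, n_spots_B=15,
                true_coincident_fraction=0.4, seed=7)
    base.update(kw)
    return ImageSimConfig(**base)


class TestImagePair:
    def test_no_spots_gives_constant_background(self):
        cfg = small_cfg(n_spots_A=0, n_spots_B=0, background_level=10)
        a, b, truth = simulate_image_pair(cfg)
        assert truth == []
        assert (a == 10).all() and (b == 10).all()
        assert a.shape == b.shape == (200, 200)

    def test_full_coincidence_zero_jitter(self):
        cfg = small_cfg(true_coincident_fraction=1.0, partner_jitter=0.0)
        _, _, truth = simulate_image_pair(cfg)
        by_id = {s.spot_id: s for s in truth}
        a_spots = [s for s in truth if s.channel == "A"]
        assert all(s.partner_id is not None for s in a_spots)
        for s in a_spots:
            partner = by_id[s.partner_id]
            assert partner.channel == "B"
            assert (partner.row, partner.col) == (s.row, s.col)
            assert partner.partner_id == s.spot_id  # symmetric link

    def test_partner_count_exact(self):
        for frac in (0.0, 0.25, 0.5, 0.73, 1.0):
            cfg = small_cfg(true_coincident_fraction=frac)
            _, _, truth = simulate_image_pair(cfg)
            n_links = sum(s.channel == "A" and s.partner_id is not None for s in truth)
            assert n_links == round(frac * cfg.n_spots_A)

    def test_rendered_peak_matches_direct_evaluation(self):
        # oracle: evaluate the Gaussian-sum rendering formula at the pixel
        cfg = ImageSimConfig(height=300, width=300, n_spots_A=50, n_spots_B=0,
                             true_coincident_fraction=0.0, seed=42)
        img_a, _, truth = simulate_image_pair(cfg)
        a_spots = [s for s in truth if s.channel == "A"]
        for s in a_spots[:10]:
            r, c = int(np.floor(s.row + 0.5)), int(np.floor(s.col + 0.5))
            expected = cfg.background_level
            for t in a_spots:
                expected += t.amplitude * np.exp(
                    -((r - t.row) ** 2 + (c - t.col) ** 2) / (2 * t.sigma**2)
                )
            assert img_a[r, c] == np.clip(np.round(expected), 0, 255)
            # peak ~ background + amplitude up to sub-pixel discretization
            assert abs(img_a[r, c] - (cfg.background_level + s.amplitude)) < 0.3 * s.amplitude

    def test_seed_reproducibility(self):
        a1, b1, t1 = simulate_image_pair(small_cfg())
        a2, b2, t2 = simulate_image_pair(small_cfg())
        assert np.array_equal(a1, a2) and np.array_equal(b1, b2) and t1 == t2
        a3, _, _ = simulate_image_pair(small_cfg(seed=8))
        assert not np.array_equal(a1, a3)

    def test_minimum_is_background_without_noise(self):
        a, b, _ = simulate_image_pair(small_cfg())
        assert a.min() == 10.0 and b.min() == 10.0

    def test_same_channel_separation_respected(self):
        cfg = small_cfg()
        _, _, truth = simulate_image_pair(cfg)
        for ch in "AB":
            pos = [(s.row, s.col) for s in truth if s.channel == ch]
            partner_of = {s.spot_id: s.partner_id for s in truth}
            ids = [s.spot_id for s in truth if s.channel == ch]
            for i in range(len(pos)):
                for j in range(i + 1, len(pos)):
                    d = np.hypot(pos[i][0] - pos[j][0], pos[i][1] - pos[j][1])
                    # partner-derived spots may sit jitter-close to the
                    # planted grid but never same-channel
                    assert d >= cfg.min_separation - 2 * cfg.partner_jitter * 2

    def test_infeasible_density_raises(self):
        with pytest.raises(ValueError, match="minimum-separation"):
            simulate_image_pair(
                ImageSimConfig(height=60, width=60, n_spots_A=400, n_spots_B=0,
                               true_coincident_fraction=0.0, seed=1)
            )

    def test_coincident_exceeding_b_spots_raises(self):
        with pytest.raises(ValueError, match="n_spots_B"):
            simulate_image_pair(small_cfg(n_spots_B=2, true_coincident_fraction=1.0))

    def test_noise_models_run_and_clip(self):
        for model in ("gaussian", "poisson"):
            a, _, _ = simulate_image_pair(small_cfg(noise_model=model))
            assert a.min() >= 0 and a.max() <= 255

    @pytest.mark.parametrize("bad", [
        dict(true_coincident_fraction=1.2),
        dict(partner_jitter=-1),
        dict(sigma_range=(0.0, 1.0)),
        dict(noise_model="salt"),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            small_cfg(**bad)


class TestExpressionSim:
    def test_perfect_correlation_rows_affinely_identical(self):
        cfg = ExprSimConfig(
            gene_names=("g1", "g2"), n_samples=20,
            target_correlation=np.array([[1.0, 1.0], [1.0, 1.0]]),
            means=np.array([0.0, 5.0]), sds=1.0, n_dead=3, n_unknown=0, seed=3,
        )
        m = simulate_expression(cfg)
        x, y = m.gene("g1"), m.gene("g2")
        assert np.allclose(y - y.mean(), x - x.mean())

    def test_status_labels_and_group_shift(self):
        cfg = ExprSimConfig(n_dead=10, n_unknown=1, group_shift=2.0, seed=5)
        m = simulate_expression(cfg)
        assert m.sample_status.count("dead") == 10
        assert m.sample_status.count("unknown") == 1
        assert m.sample_status.count("alive") == 57
        null = simulate_expression(dataclasses.replace(cfg, group_shift=0.0))
        status = np.array(m.sample_status)
        diff = m.values.to_numpy() - null.values.to_numpy()
        assert np.allclose(diff[:, status == "dead"], 2.0)
        assert np.allclose(diff[:, status != "dead"], 0.0)

    def test_planted_correlation_recovered_at_large_n(self):
        corr = np.full((5, 5), 0.3)
        np.fill_diagonal(corr, 1.0)
        cfg = ExprSimConfig(
            gene_names=tuple("abcde"), n_samples=10_000,
            target_correlation=corr, n_dead=10, n_unknown=0, seed=11,
        )
        m = simulate_expression(cfg)
        emp = np.corrcoef(m.values.to_numpy())
        off = emp[~np.eye(5, dtype=bool)]
        assert np.abs(off - 0.3).max() < 0.03

    def test_non_psd_correlation_rejected(self):
        corr = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            ExprSimConfig(gene_names=("a", "b", "c"), target_correlation=corr,
                          n_samples=10, n_dead=2, n_unknown=0)

    def test_seed_reproducibility(self):
        m1 = simulate_expression(ExprSimConfig(seed=9))
        m2 = simulate_expression(ExprSimConfig(seed=9))
        assert m1.values.equals(m2.values)


class TestWriters:
    def test_truth_csv_round_trip(self, tmp_path):
        import pandas as pd

        _, _, truth = simulate_image_pair(small_cfg())
        path = tmp_path / "truth.csv"
        write_truth_csv(truth, path)
        df = pd.read_csv(path)
        assert list(df.columns) == [
            "spot_id", "channel", "row", "col", "amplitude", "sigma", "partner_id"
        ]
        assert len(df) == 30
        frame = truth_to_frame(truth)
        n_links = (frame.partner_id != "").sum()
        assert n_links == 2 * round(0.4 * 15)

    def test_tiff_and_png_round_trip(self, tmp_path):
        import imageio.v3 as iio
        import tifffile

        a, b, _ = simulate_image_pair(small_cfg())
        pa, pb = write_image_pair_tiff(a, b, tmp_path)
        assert np.array_equal(tifffile.imread(pa), a.astype(np.uint8))
        assert np.array_equal(tifffile.imread(pb), b.astype(np.uint8))
        png = write_image_pair_png(a, b, tmp_path / "rgb.png")
        rgb = iio.imread(png)
        assert np.array_equal(rgb[:, :, 0], a.astype(np.uint8))
        assert np.array_equal(rgb[:, :, 1], b.astype(np.uint8))
        assert (rgb[:, :, 2] == 0).all()

    def test_yaml_config_load(self, tmp_path):
        cfg_file = tmp_path / "cfg.yaml"
        cfg_file.write_text(yaml.safe_dump({
            "height": 128, "width": 128, "n_spots_A": 5, "n_spots_B": 5,
            "true_coincident_fraction": 0.2, "amplitude_range": [40, 60], "seed": 2,
        }))
        cfg = load_config(cfg_file, "image")
        assert cfg.height == 128 and cfg.amplitude_range == (40.0, 60.0)
        expr_file = tmp_path / "expr.yaml"
        expr_file.write_text(yaml.safe_dump({
            "gene_names": ["a", "b"], "n_samples": 12, "n_dead": 3, "n_unknown": 0,
        }))
        ecfg = load_config(expr_file, "expression")
        assert ecfg.gene_names == ("a", "b") and ecfg.n_samples == 12
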