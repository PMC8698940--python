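import numpy as np
import pytest

import ductmorph as dm
from ductmorph.render import BACKGROUND, FOREGROUND


def straight_duct(length_um=100.0, rate=20.0):
    st = dm.ScriptedTree(rate=rate, step_um=2.0)
    st.add_original((60, 250), direction=0.0, initial_length=0.0)
    return st.build(length_um / rate)


class TestRasterization:
    def test_straight_duct_foreground_run(self):
        tree, _ = straight_duct(100.0)
        cfg = dm.GrowthConfig(field_size_px=(256, 256), duration_h=5.0,
                              frame_interval_min=30.0, pixel_size_um=2.0)
        stack = dm.render_stack(tree, cfg)
        last = stack.frames[-1]
        row = last[125]  # duct axis at y = 250 um -> row 125
        run = int((row == FOREGROUND).sum())
        # 100 um at 2 um/px = 50 px, plus a tube end-cap radius at each end
        assert run == pytest.approx(50, abs=6)

    def test_empty_tree_all_background(self):
        st = dm.ScriptedTree()
        st.add_original((60, 250), 0.0, initial_length=0.0)
        tree, _ = st.build(0.5)
        tree.segments.clear()
        cfg = dm.GrowthConfig(field_size_px=(128, 128), duration_h=0.5,
                              frame_interval_min=30.0)
        with pytest.raises(Exception):
            dm.render_stack(tree, cfg)  # no points at all: nothing to bound

    def test_foreground_monotone_nondecreasing(self):
        tree, _ = dm.sample_forest(
            dm.lobe_preset("lp1", seed=2, duration_h=24.0,
                           field_size_px=(640, 512), duct_spacing_um=150.0)
        )
        cfg = dm.lobe_preset("lp1", seed=2, duration_h=24.0,
                             field_size_px=(640, 512), duct_spacing_um=150.0)
        stack = dm.render_stack(tree, cfg)
        counts = (stack.frames > BACKGROUND).reshape(len(stack), -1).sum(axis=1)
        assert (np.diff(counts) >= 0).all()

    def test_out_of_field_rejected(self):
        tree, _ = straight_duct(400.0)
        cfg = dm.GrowthConfig(field_size_px=(128, 128), duration_h=20.0,
                              frame_interval_min=30.0)
        with pytest.raises(dm.RenderError, match="larger field"):
            dm.render_stack(tree, cfg)

    def test_timestamps_uniform_and_pixel_size_recorded(self):
        tree, _ = straight_duct(100.0)
        cfg = dm.GrowthConfig(field_size_px=(256, 256), duration_h=5.0,
                              frame_interval_min=30.0)
        stack = dm.render_stack(tree, cfg)
        assert len(stack) == 11
        assert np.allclose(np.diff(stack.timestamps), 0.5)
        assert stack.pixel_size == cfg.pixel_size_um


class TestStackIO:
    def test_tiff_sidecar_round_trip(self, tmp_path):
        tree, _ = straight_duct(100.0)
        cfg = dm.GrowthConfig(field_size_px=(256, 256), duration_h=5.0,
                              frame_interval_min=30.0)
        stack = dm.render_stack(tree, cfg)
        stack.save(tmp_path / "s.tif")
        back = dm.FrameStack.load(tmp_path / "s.tif")
        assert np.array_equal(back.frames, stack.frames)
        assert np.allclose(back.timestamps, stack.timestamps)
        assert back.anchor_x_um == stack.anchor_x_um

    def test_noise_option_changes_frames_deterministically(self):
        tree, _ = straight_duct(100.0)
        cfg = dm.GrowthConfig(field_size_px=(256, 256), duration_h=5.0,
                              frame_interval_min=30.0, noise_sigma=5.0, seed=9)
        s1 = dm.render_stack(tree, cfg)
        s2 = dm.render_stack(tree, cfg)
        assert np.array_equal(s1.frames, s2.frames)
        assert s1.frames.std() > dm.render_stack(tree, cfg.replace(noise_sigma=0.0)).frames.std()
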