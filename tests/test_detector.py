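import numpy as np
import pytest

from gridtag import (
    Codebook,
    DetectorOptions,
    assemble_tag,
    binarize_adaptive,
    binarize_global,
    compose_scene,
    decode_candidate,
    find_candidate_regions,
    fit_quad,
    gradient_lit_frames,
    locate_codes,
    render_tag,
    rotate_tag,
    sample_code_grid,
    to_grayscale,
)


class TestGrayscale:
    @pytest.mark.parametrize("rgb,expected", [
        ((1.0, 1.0, 1.0), 1.0),
        ((0.0, 0.0, 0.0), 0.0),
        ((1.0, 0.0, 0.0), 0.299),
        ((0.0, 1.0, 0.0), 0.587),
    ])
    def test_rec601_weights(self, rgb, expected):
        img = np.full((2, 2, 3), rgb)
        assert np.allclose(to_grayscale(img), expected)

    def test_uint8_input_normalised(self):
        img = np.full((2, 2, 3), 255, dtype=np.uint8)
        assert np.allclose(to_grayscale(img), 1.0)

    def test_wrong_channels_rejected(self):
        with pytest.raises(ValueError):
            to_grayscale(np.zeros((4, 4, 2)))


class TestBinarize:
    def test_global_threshold(self):
        img = np.full((3, 3), 0.6)
        assert binarize_global(img, 0.5).all()
        assert not binarize_global(img, 0.7).any()

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.3, 1.5])
    def test_global_threshold_bounds(self, bad):
        with pytest.raises(ValueError):
            binarize_global(np.zeros((3, 3)), bad)

    def test_rendered_tag_binarises_to_its_pattern(self):
        tag = assemble_tag(99)
        img = render_tag(tag, 1)
        assert (binarize_global(img, 0.5)[2:7, 2:7] == tag.matrix).all()

    def test_adaptive_constant_image_uniform(self):
        img = np.full((30, 30), 0.4)
        out = binarize_adaptive(img, 15, 0.1)
        assert len(np.unique(out)) == 1

    def test_adaptive_window_validation(self):
        with pytest.raises(ValueError):
            binarize_adaptive(np.zeros((30, 30)), 14, 0.1)
        with pytest.raises(ValueError):
            binarize_adaptive(np.zeros((10, 10)), 21, 0.1)

    def test_adaptive_beats_global_under_gradient(self, book_small):
        frames = gradient_lit_frames(book_small, n_frames=1, n_tags=6, seed=4,
                                     ambient_range=(0.02, 0.75), contrast=0.22)
        scene = frames[0]
        n_global = max(
            len(locate_codes(scene.image,
                             DetectorOptions(threshold=t), book_small))
            for t in np.linspace(0.2, 0.9, 15))
        opts = DetectorOptions(thresh_mode="adaptive", adaptive_window=31,
                               adaptive_sensitivity=0.05)
        dets = locate_codes(scene.image, opts, book_small)
        assert sorted(d.id for d in dets) == sorted(scene.ids)
        assert n_global < len(scene.ids)  # the gradient defeats any single cutoff


class TestRegionsAndQuads:
    def test_blank_image_no_candidates(self):
        assert find_candidate_regions(np.zeros((50, 50), dtype=bool)) == []

    def test_single_tag_yields_candidate(self, book_small):
        scene = compose_scene(book_small, [book_small.ids[0]], [(60, 60)],
                              [0], 6, 0.5, (120, 120))
        regs = find_candidate_regions(scene.image > 0.5)
        assert any(r.corners is not None for r in regs)

    def test_disk_rejected_by_fill_ratio(self):
        yy, xx = np.mgrid[:80, :80]
        disk = (yy - 40) ** 2 + (xx - 40) ** 2 <= 30 ** 2
        regs = find_candidate_regions(disk, min_area=10, max_area=10_000)
        assert len(regs) == 1
        assert regs[0].corners is None
        assert regs[0].reject_reason is not None

    def test_l_shape_rejected(self):
        img = np.zeros((60, 60), dtype=bool)
        img[10:50, 10:25] = True
        img[35:50, 10:50] = True
        regs = find_candidate_regions(img, min_area=10, max_area=10_000)
        assert regs[0].corners is None

    def test_axis_aligned_square_corners(self):
        img = np.zeros((50, 50), dtype=bool)
        img[10:41, 5:36] = True
        coords = np.argwhere(img)
        corners, reason = fit_quad(coords)
        assert reason is None
        expect = {(5, 10), (35, 10), (35, 40), (5, 40)}
        assert {tuple(map(round, c)) for c in corners} == expect
        assert tuple(np.round(corners[0]).astype(int)) == (5, 10)  # top-left first

    def test_rotated_square_corners_within_one_px(self):
        from skimage.draw import polygon
        c, half, ang = 60.0, 25.0, np.deg2rad(30)
        base = np.array([[-half, -half], [half, -half],
                         [half, half], [-half, half]])
        rot = np.array([[np.cos(ang), -np.sin(ang)],
                        [np.sin(ang), np.cos(ang)]])
        true_corners = base @ rot.T + c
        rr, cc = polygon(true_corners[:, 1], true_corners[:, 0], (120, 120))
        coords = np.stack([rr, cc], axis=1)
        corners, reason = fit_quad(coords)
        assert reason is None
        for tc in true_corners:
            assert np.min(np.linalg.norm(corners - tc, axis=1)) <= 1.5

    def test_collinear_region_rejected(self):
        coords = np.stack([np.full(30, 5), np.arange(30)], axis=1)
        corners, reason = fit_quad(coords)
        assert corners is None


class TestSampleGrid:
    def test_axis_aligned_tag_exact(self, book_small):
        tid = book_small.ids[3]
        img = render_tag(book_small[tid], 6)
        corners = np.array([[6, 6], [48, 6], [48, 48], [6, 48]], dtype=float) - 0.5
        matrix, margin = sample_code_grid(img, corners, 0.5)
        assert (matrix == book_small[tid].matrix).all()
        assert margin > 0.4

    def test_all_white_square(self):
        img = np.ones((60, 60))
        m, _ = sample_code_grid(img, np.array([[5, 5], [55, 5],
                                               [55, 55], [5, 55]],
                                              dtype=float), 0.5)
        assert (m == 1).all()

    def test_mild_perspective_warp_same_matrix(self, book_small, rng):
        tid = book_small.ids[3]
        img = render_tag(book_small[tid], 8)
        corners = np.array([[8, 8], [64, 8], [64, 64], [8, 64]], dtype=float) - 0.5
        edge = 56.0
        for _ in range(10):
            warped = corners + rng.uniform(-0.05, 0.05, (4, 2)) * edge
            m, _ = sample_code_grid(img, warped, 0.5)
            assert (m == book_small[tid].matrix).all()

    def test_nonconvex_corners_rejected(self):
        bad = np.array([[0, 0], [10, 0], [3, 3], [0, 10]], dtype=float)
        with pytest.raises(ValueError, match="convex"):
            sample_code_grid(np.ones((20, 20)), bad, 0.5)


class TestDecode:
    def test_canonical_and_rotations(self, book_small):
        tid = book_small.ids[7]
        m = book_small[tid].matrix
        assert decode_candidate(m, book_small) == (tid, 0)
        assert decode_candidate(rotate_tag(m, 3), book_small) == (tid, 1)

    def test_valid_code_outside_codebook_rejected(self, book_small):
        # a uniquely-orientable id excluded from a truncated codebook
        truncated = Codebook(book_small.codes[:5], book_small.min_hamming)
        outside = book_small.codes[10]
        assert decode_candidate(outside.matrix, truncated) is None

    def test_garbage_rejected(self, book_small, rng):
        for _ in range(20):
            m = rng.integers(0, 2, (5, 5))
            dec = decode_candidate(m, book_small)
            if dec is not None:
                assert dec[0] in book_small


class TestLocateCodes:
    def test_twelve_tag_scene_all_found(self, book_small):
        ids = book_small.ids[:12]
        scene = compose_scene(
            book_small, ids,
            [(70 + 110 * (i % 4), 70 + 110 * (i // 4)) for i in range(12)],
            [10 * i for i in range(12)], 6, 0.5, (420, 520))
        dets = locate_codes(scene.image, DetectorOptions(), book_small)
        assert sorted(d.id for d in dets) == sorted(ids)

    def test_blank_background_empty(self, book_small):
        assert locate_codes(np.full((80, 80), 0.4), DetectorOptions(),
                            book_small) == []

    def test_requires_codebook(self):
        with pytest.raises(ValueError):
            locate_codes(np.zeros((10, 10)))

    def test_deterministic_ordering(self, book_small):
        ids = book_small.ids[:4]
        scene = compose_scene(book_small, ids,
                              [(60, 60), (170, 60), (60, 170), (170, 170)],
                              None, 6, 0.5, (240, 240))
        dets = locate_codes(scene.image, DetectorOptions(), book_small)
        keys = [(d.centroid[1], d.centroid[0]) for d in dets]
        assert keys == sorted(keys)

    @pytest.mark.parametrize("angle", [0, 90, 180, 270])
    def test_orientation_within_two_degrees(self, book_small, angle):
        tid = book_small.ids[2]
        scene = compose_scene(book_small, [tid], [(80, 80)], [angle], 6,
                              0.5, (160, 160))
        d, = locate_codes(scene.image, DetectorOptions(), book_small)
        diff = (d.orientation_deg - angle + 180) % 360 - 180
        assert abs(diff) <= 2.0

    def test_corner_rms_accuracy_axis_aligned(self, book_small):
        ids = book_small.ids[:6]
        scene = compose_scene(book_small, ids,
                              [(70 + 110 * (i % 3), 70 + 110 * (i // 3))
                               for i in range(6)],
                              None, 6, 0.5, (300, 420))
        dets = {d.id: d for d in locate_codes(scene.image, DetectorOptions(),
                                              book_small)}
        errs = []
        for p in scene.placements:
            errs.append(dets[p.id].corners - p.corners)
        rms = np.sqrt(np.mean(np.square(errs)))
        assert rms <= 1.5

    def test_rgb_input_accepted(self, book_small):
        tid = book_small.ids[0]
        scene = compose_scene(book_small, [tid], [(60, 60)], [0], 6,
                              0.5, (120, 120))
        rgb = np.stack([scene.image] * 3, axis=-1)
        d, = locate_codes(rgb, DetectorOptions(), book_small)
        assert d.id == tid

    def test_visualize_writes_overlay(self, tmp_path, book_small):
        tid = book_small.ids[0]
        scene = compose_scene(book_small, [tid], [(60, 60)], [0], 6,
                              0.5, (120, 120))
        out = tmp_path / "overlay.png"
        locate_codes(scene.image, DetectorOptions(visualize=out), book_small)
        assert out.exists() and out.stat().st_size > 0
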