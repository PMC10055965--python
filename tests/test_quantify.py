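"""Connected-component counting and circular Hough droplet detection."""

import numpy as np
import pytest

import notchsim as ns


def flood_fill_count(binary, min_area=1):
    """Brute-force 8-connected component count (stack-based flood fill)."""
    visited = np.zeros_like(binary, dtype=bool)
    rows, cols = binary.shape
    count = 0
    for r0 in range(rows):
        for c0 in range(cols):
            if binary[r0, c0] and not visited[r0, c0]:
                area = 0
                todo = [(r0, c0)]
                visited[r0, c0] = True
                while todo:
                    r, c = todo.pop()
                    area += 1
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (
                                0 <= rr < rows
                                and 0 <= cc < cols
                                and binary[rr, cc]
                                and not visited[rr, cc]
                            ):
                                visited[rr, cc] = True
                                todo.append((rr, cc))
                if area >= min_area:
                    count += 1
    return count


def draw_disks(shape, centers, radius):
    img = np.zeros(shape)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for cy, cx in centers:
        img[np.hypot(yy - cy, xx - cx) <= radius] = 1.0
    return img


class TestSegmentObjects:
    def test_counts_separated_disks(self):
        img = draw_disks((128, 128), [(20, 20), (20, 90), (64, 50), (100, 20), (100, 100)], 6)
        result = ns.segment_objects(img)
        assert result.count == 5
        assert len(result.areas) == 5

    def test_blank_image_counts_zero(self):
        assert ns.segment_objects(np.zeros((64, 64))).count == 0

    def test_matches_flood_fill_oracle_on_random_images(self):
        rng = np.random.default_rng(0)
        from scipy import ndimage

        for trial in range(20):
            raw = ndimage.gaussian_filter(rng.random((96, 96)), 2.0)
            binary = raw > np.quantile(raw, 0.85)
            result = ns.segment_objects(
                binary.astype(float), threshold_method="fixed",
                fixed_threshold=0.5, min_area=5,
            )
            assert result.count == flood_fill_count(binary, min_area=5), f"trial {trial}"

    def test_min_area_prunes_specks(self):
        img = np.zeros((64, 64))
        img[10:14, 10:14] = 1.0  # 16 px object
        img[40, 40] = 1.0  # single-pixel speck
        assert ns.segment_objects(img, threshold_method="fixed", min_area=9).count == 1


class TestCountTimeseries:
    def test_identical_frames_constant(self):
        img = draw_disks((64, 64), [(20, 20), (40, 40)], 5)
        result = ns.count_timeseries([img, img, img])
        assert list(result["counts"]) == [2, 2, 2]
        assert list(result["changes"]) == [0, 0]

    def test_fission_event_counts_up(self):
        before = draw_disks((64, 64), [(32, 28)], 8)
        after = draw_disks((64, 64), [(32, 18), (32, 44)], 5)
        result = ns.count_timeseries([before, after])
        assert list(result["counts"]) == [1, 2]
        assert list(result["changes"]) == [1]

    def test_programmed_schedule(self):
        rng = np.random.default_rng(1)
        schedule = [3, 4, 4, 2, 5]
        frames = []
        for n in schedule:
            centers = []
            while len(centers) < n:
                cand = (rng.integers(10, 86), rng.integers(10, 86))
                if all(np.hypot(cand[0] - c[0], cand[1] - c[1]) > 14 for c in centers):
                    centers.append(cand)
            frames.append(draw_disks((96, 96), centers, 4))
        result = ns.count_timeseries(frames)
        assert list(result["counts"]) == schedule

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            ns.count_timeseries([])


def ring_image(shape, circles, pixel_size_nm, thickness_px=1.5):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.zeros(shape)
    for cx, cy, r_nm in circles:
        d = np.hypot(xx - cx, yy - cy)
        img += np.exp(-((d - r_nm / pixel_size_nm) ** 2) / (2 * (thickness_px / 2.3548) ** 2))
    return img


class TestDetectCircles:
    PIXEL = 20.0

    def test_single_ring_recovered(self):
        img = ring_image((128, 128), [(64, 64, 600.0)], self.PIXEL)
        found = ns.detect_circles(img, 300.0, 900.0, self.PIXEL)
        assert len(found) == 1
        assert found.radii_nm[0] == pytest.approx(600.0, rel=0.10)

    def test_blank_image_empty(self):
        found = ns.detect_circles(np.zeros((128, 128)), 300.0, 900.0, self.PIXEL)
        assert len(found) == 0

    def test_three_radii(self):
        img = ring_image(
            (192, 192), [(50, 50, 300.0), (140, 60, 600.0), (80, 140, 900.0)], self.PIXEL
        )
        found = ns.detect_circles(img, 200.0, 1100.0, self.PIXEL)
        assert len(found) == 3
        for want in (300.0, 600.0, 900.0):
            err = np.abs(found.radii_nm - want).min() / want
            assert err <= 0.10

    def test_invalid_radius_range(self):
        with pytest.raises(ValueError):
            ns.detect_circles(np.zeros((64, 64)), 900.0, 300.0, self.PIXEL)

    def test_fifty_droplet_panel_recall_precision(self):
        """≥90% recall and precision on a 50-droplet synthetic panel."""
        sample, truth = ns.make_phantom(
            "droplets", (512, 512),
            {"n": 50, "radii_nm": None, "min_separation_factor": 2.0},
            seed=20, pixel_size_nm=self.PIXEL,
        )
        found = ns.detect_circles(sample.density, 200.0, 1200.0, self.PIXEL)
        centers_true = truth["centers_nm"] / self.PIXEL
        matched_truth = set()
        true_positive = 0
        for (x, y), r_nm in zip(found.centers_xy, found.radii_nm):
            best, best_idx = np.inf, None
            for idx, ((tx, ty), tr) in enumerate(zip(centers_true, truth["radii_nm"])):
                d = np.hypot(x - tx, y - ty)
                if d < best:
                    best, best_idx = d, idx
            if (
                best_idx is not None
                and best_idx not in matched_truth
                and best * self.PIXEL < 0.5 * truth["radii_nm"][best_idx]
                and abs(r_nm - truth["radii_nm"][best_idx]) / truth["radii_nm"][best_idx] < 0.25
            ):
                matched_truth.add(best_idx)
                true_positive += 1
        recall = true_positive / 50
        precision = true_positive / max(len(found), 1)
        assert recall >= 0.90
        assert precision >= 0.90


class TestRadiusHistogram:
    def make_set(self, radii_nm):
        radii = np.asarray(radii_nm, dtype=float)
        return ns.DropletSet(
            centers_xy=np.zeros((len(radii), 2)),
            radii_nm=radii,
            scores=np.ones(len(radii)),
        )

    def test_half_open_binning(self):
        droplets = self.make_set([300.0, 600.0, 900.0])
        counts = ns.radius_histogram(droplets, [0.0, 500.0, 1000.0, 1500.0])
        assert list(counts) == [1, 2, 0]

    def test_edge_value_goes_right(self):
        counts = ns.radius_histogram(self.make_set([500.0]), [0.0, 500.0, 1000.0])
        assert list(counts) == [0, 1]

    def test_empty_set(self):
        counts = ns.radius_histogram(self.make_set([]), [0.0, 500.0, 1000.0])
        assert list(counts) == [0, 0]

    def test_conservation_when_edges_span(self):
        rng = np.random.default_rng(2)
        radii = rng.uniform(100, 1400, 30)
        counts = ns.radius_histogram(self.make_set(radii), np.arange(0.0, 1600.0, 100.0))
        assert counts.sum() == 30

    def test_unsorted_edges_rejected(self):
        with pytest.raises(ValueError):
            ns.radius_histogram(self.make_set([300.0]), [0.0, 1000.0, 500.0])
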