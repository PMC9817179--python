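"""Image metrics: projections, maxima detection vs brute-force oracle,
FWHM refinement, punctate percentage, live/fixed comparison."""

import numpy as np
import pytest

from fixartifact import puncta


# ---------------------------------------------------------------- oracle
def oracle_prominence_maxima(img, mask, tol):
    """Brute-force prominence maxima by descending threshold flooding.

    Independent of the package's union-find detector: at each unique
    intensity level the superlevel set is relabelled from scratch with
    scipy.ndimage; a peak dies at the level where its component first
    contains a higher (or equal-but-earlier row-major) peak, with
    prominence = peak height - death level.
    """
    from scipy import ndimage

    img = np.asarray(img, float)
    mask = np.asarray(mask, bool)
    levels = np.unique(img[mask])[::-1]
    peaks = []  # dicts: pos (flat row-major of peak pixel), val, alive, prominence
    w = img.shape[1]
    for lv in levels:
        lab, n = ndimage.label((img >= lv) & mask, structure=np.ones((3, 3)))
        for c in range(1, n + 1):
            comp = lab == c
            members = [p for p in peaks if comp[p["pos"] // w, p["pos"] % w]]
            if not members:
                # new component: its peak is the first row-major pixel at max value
                ys, xs = np.nonzero(comp)
                vals = img[ys, xs]
                order = np.lexsort((xs[vals == vals.max()], ys[vals == vals.max()]))
                yy = ys[vals == vals.max()][order][0]
                xx = xs[vals == vals.max()][order][0]
                peaks.append({"pos": yy * w + xx, "val": vals.max(), "alive": True,
                              "prom": None})
                continue
            alive = [p for p in members if p["alive"]]
            if len(alive) <= 1:
                continue
            winner = min(alive, key=lambda p: (-p["val"], p["pos"]))
            for p in alive:
                if p is winner:
                    continue
                p["alive"] = False
                p["prom"] = p["val"] - lv
    # survivors: prominence relative to the minimum of their final component
    lab, n = ndimage.label(mask, structure=np.ones((3, 3)))
    for p in peaks:
        if p["alive"]:
            comp = lab == lab[p["pos"] // w, p["pos"] % w]
            p["prom"] = p["val"] - img[comp].min()
    return sorted(p["pos"] for p in peaks if p["prom"] > tol)


def plateau_centroid_oracle(img, mask, pos):
    """BFS over the equal-valued plateau; rounded centroid."""
    h, w = img.shape
    y0, x0 = divmod(pos, w)
    level = img[y0, x0]
    seen = {(y0, x0)}
    queue = [(y0, x0)]
    while queue:
        y, x = queue.pop()
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                ny, nx = y + dy, x + dx
                if (0 <= ny < h and 0 <= nx < w and (ny, nx) not in seen
                        and mask[ny, nx] and img[ny, nx] == level):
                    seen.add((ny, nx))
                    queue.append((ny, nx))
    ys = [p[0] for p in seen]
    xs = [p[1] for p in seen]
    return int(round(np.mean(ys))), int(round(np.mean(xs)))


def gaussian_image(shape, centers, sigmas, amps, background=0.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.full(shape, float(background))
    for (cy, cx), s, a in zip(centers, sigmas, amps):
        sy, sx = (s, s) if np.isscalar(s) else s
        img += a * np.exp(-((yy - cy) ** 2 / (2 * sy**2) + (xx - cx) ** 2 / (2 * sx**2)))
    return img


# ------------------------------------------------------------ projections
class TestProject:
    def test_single_plane_identity(self):
        plane = np.random.default_rng(0).random((8, 9))
        stack = plane[None]
        assert np.array_equal(puncta.project(stack, "max"), plane)
        assert np.array_equal(puncta.project(stack, "sum"), plane)

    def test_constant_planes(self):
        stack = np.stack([np.full((4, 4), 1.0), np.full((4, 4), 3.0)])
        assert np.all(puncta.project(stack, "max") == 3)
        assert np.all(puncta.project(stack, "sum") == 4)

    def test_sum_preserves_total(self):
        stack = np.random.default_rng(1).random((3, 10, 10))
        assert puncta.project(stack, "sum").sum() == pytest.approx(stack.sum())

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            puncta.project(np.zeros((1, 4, 4)), "median")


class TestNormalize:
    def test_constant_image_uniform(self):
        mask = np.zeros((6, 6), bool)
        mask[1:5, 1:5] = True
        out = puncta.normalize_to_mask(np.full((6, 6), 7.0), mask)
        assert out[mask] == pytest.approx(1 / 16)
        assert np.all(out[~mask] == 0)

    def test_scale_invariance_and_unit_sum(self):
        rng = np.random.default_rng(2)
        img = rng.random((12, 12)) + 0.1
        mask = rng.random((12, 12)) > 0.3
        a = puncta.normalize_to_mask(img, mask)
        b = puncta.normalize_to_mask(10 * img, mask)
        assert a == pytest.approx(b)
        assert a[mask].sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_image_rejected(self):
        with pytest.raises(ValueError):
            puncta.normalize_to_mask(np.zeros((4, 4)), np.ones((4, 4), bool))


# ---------------------------------------------------------------- maxima
class TestFindPuncta:
    def test_constant_image_no_maxima(self):
        assert puncta.find_puncta(np.ones((16, 16)), np.ones((16, 16), bool), 0.0) == []

    def test_single_blob_found_at_center(self):
        img = gaussian_image((41, 41), [(20, 20)], [3], [10.0])
        got = puncta.find_puncta(img, np.ones((41, 41), bool), 0.5)
        assert got == [(20, 20)]

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_oracle_random(self, seed):
        """Exact agreement with the threshold-descent oracle on small images."""
        rng = np.random.default_rng(seed)
        # integer-valued smoothed noise: plenty of plateaus and ties
        from scipy import ndimage as ndi

        img = np.floor(ndi.gaussian_filter(rng.random((28, 28)), 1.2) * 40)
        mask = np.ones((28, 28), bool)
        if seed % 2:  # irregular mask half the time
            yy, xx = np.mgrid[0:28, 0:28]
            mask = (yy - 13.5) ** 2 + (xx - 13.5) ** 2 <= 13.5**2
        for tol in (0.0, 1.0, 3.0, 8.0):
            got = puncta.find_puncta(img, mask, tol)
            exp = oracle_prominence_maxima(img, mask, tol)
            exp_centers = sorted(plateau_centroid_oracle(img, mask, p) for p in exp)
            assert sorted(got) == exp_centers, f"tol={tol}"

    def test_planted_blobs_recovered(self):
        rng = np.random.default_rng(42)
        centers = [(y, x) for y in (20, 60, 100) for x in (20, 60, 100, 140)]
        tol = 1.0
        img = gaussian_image((121, 161), centers, [2] * 12, [50 * tol] * 12)
        img += rng.normal(0, tol / 10, img.shape)
        got = puncta.find_puncta(img, np.ones(img.shape, bool), tol)
        assert len(got) == 12
        dists = [
            min(np.hypot(gy - cy, gx - cx) for cy, cx in centers) for gy, gx in got
        ]
        assert max(dists) <= 1.0

    def test_tolerance_suppresses_shallow_peak(self):
        # peaks 10 and 5 joined through a 3-valued saddle pixel: the lower
        # peak's prominence is 5 - 3 = 2
        img = np.zeros((3, 5))
        img[1, 1] = 10.0
        img[1, 2] = 3.0
        img[1, 3] = 5.0
        mask = np.ones(img.shape, bool)
        assert len(puncta.find_puncta(img, mask, 1.9)) == 2
        assert len(puncta.find_puncta(img, mask, 2.0)) == 1  # strict: 2 > 2 fails

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            puncta.find_puncta(np.ones((4, 4)), np.zeros((4, 4), bool), 0.1)


class TestSurfaceRoughness:
    def test_constant_is_zero(self):
        assert puncta.surface_roughness(np.full((5, 5), 2.0), np.ones((5, 5), bool)) == 0

    def test_two_level_closed_form(self):
        img = np.zeros((4, 4))
        img[:2] = 3.0
        img[2:] = 7.0
        assert puncta.surface_roughness(img, np.ones((4, 4), bool)) == pytest.approx(2.0)

    def test_monotone_in_punctum_amplitude(self):
        mask = np.ones((61, 61), bool)
        values = []
        for amp in (1.0, 2.0, 4.0, 8.0):
            img = gaussian_image((61, 61), [(30, 30)], [3], [amp], background=1.0)
            values.append(puncta.surface_roughness(puncta.normalize_to_mask(img, mask), mask))
        assert np.all(np.diff(values) > 0)

    def test_too_few_pixels(self):
        m = np.zeros((4, 4), bool)
        m[0, 0] = True
        with pytest.raises(ValueError):
            puncta.surface_roughness(np.ones((4, 4)), m)


class TestRefineCenterAndFwhm:
    def test_isotropic_gaussian_analytic_fwhm(self):
        img = gaussian_image((61, 61), [(30, 30)], [3], [1.0])
        p = puncta.refine_center_and_fwhm(img, (30, 30))
        assert p.fwhm == pytest.approx(2 * np.sqrt(2 * np.log(2)) * 3, rel=0.02)

    def test_elliptical_gaussian_major_axis(self):
        img = gaussian_image((81, 81), [(40, 40)], [(4, 2)], [1.0])
        p = puncta.refine_center_and_fwhm(img, (40, 40))
        assert p.fwhm == pytest.approx(2 * np.sqrt(2 * np.log(2)) * 4, rel=0.02)

    def test_center_recovered_on_grid(self):
        img = gaussian_image((41, 41), [(22, 18)], [2.5], [1.0])
        p = puncta.refine_center_and_fwhm(img, (22, 18))
        assert np.hypot(p.refined_center[0] - 22, p.refined_center[1] - 18) <= 0.5

    def test_off_center_preliminary_recovers_true_center(self):
        img = gaussian_image((41, 41), [(20, 20)], [3], [1.0])
        p = puncta.refine_center_and_fwhm(img, (21, 21))  # 1px off, as find-maxima may be
        assert np.hypot(p.refined_center[0] - 20, p.refined_center[1] - 20) <= 0.5

    def test_unresolved_flagged(self):
        with pytest.warns(UserWarning, match="unresolved"):
            p = puncta.refine_center_and_fwhm(np.ones((21, 21)), (10, 10), max_half_length=5)
        assert not p.resolved


class TestPunctatePercentage:
    def test_empty_list_zero(self):
        stack = np.ones((1, 8, 8))
        assert puncta.punctate_percentage(stack, np.ones((8, 8), bool), []) == 0.0

    def test_gaussian_encircled_energy_half(self):
        # disk of diameter FWHM holds exactly half a 2-D Gaussian's energy
        img = gaussian_image((101, 101), [(50, 50)], [4], [1.0])
        mask = np.ones((101, 101), bool)
        p = puncta.refine_center_and_fwhm(img, (50, 50))
        pct = puncta.punctate_percentage(img[None], mask, [p])
        assert pct == pytest.approx(50.0, abs=2.0)

    def test_two_puncta_same_ratio_as_one(self):
        mask = np.ones((101, 201), bool)
        one = gaussian_image((101, 201), [(50, 50)], [4], [1.0])
        two = gaussian_image((101, 201), [(50, 50), (50, 150)], [4, 4], [1.0, 1.0])
        p1 = puncta.refine_center_and_fwhm(one, (50, 50))
        p2a = puncta.refine_center_and_fwhm(two, (50, 50))
        p2b = puncta.refine_center_and_fwhm(two, (50, 150))
        pct1 = puncta.punctate_percentage(one[None], mask, [p1])
        pct2 = puncta.punctate_percentage(two[None], mask, [p2a, p2b])
        assert pct2 == pytest.approx(pct1, rel=0.02)

    def test_overlapping_disks_counted_once(self):
        img = gaussian_image((61, 61), [(30, 30)], [4], [1.0])
        mask = np.ones((61, 61), bool)
        p = puncta.refine_center_and_fwhm(img, (30, 30))
        doubled = puncta.punctate_percentage(img[None], mask, [p, p])
        assert doubled == puncta.punctate_percentage(img[None], mask, [p])

    def test_bounded_and_monotone_in_puncta(self):
        img = gaussian_image((81, 81), [(20, 20), (60, 60)], [3, 3], [1.0, 1.0])
        mask = np.ones((81, 81), bool)
        pa = puncta.refine_center_and_fwhm(img, (20, 20))
        pb = puncta.refine_center_and_fwhm(img, (60, 60))
        v1 = puncta.punctate_percentage(img[None], mask, [pa])
        v2 = puncta.punctate_percentage(img[None], mask, [pa, pb])
        assert 0 <= v1 <= v2 <= 100


class TestScaleInvariance:
    def test_all_parameters_invariant_under_gain(self):
        from fixartifact import synth

        stack, mask, _ = synth.make_nucleus_stack(synth.SyntheticImageSpec(seed=9))
        r1 = puncta.quantify(stack, mask, 10.0, tolerance_units="raw")
        r2 = puncta.quantify(stack.voxels * 7.5, mask, 75.0, tolerance_units="raw")
        assert r1.n_puncta == r2.n_puncta
        assert r1.surface_roughness == pytest.approx(r2.surface_roughness)
        assert r1.punctate_percentage == pytest.approx(r2.punctate_percentage)


class TestCompareLiveFixed:
    def mk(self, n, rough, pct, tol=1.0):
        return puncta.PunctaQuantResult(n, rough, pct, noise_tolerance=tol)

    def test_percent_change_example(self):
        ch = puncta.compare_live_fixed(self.mk(20, 1, 10), self.mk(30, 1, 10))
        assert ch.percent_change["n_puncta"] == pytest.approx(50.0)

    def test_zero_live_flagged(self):
        ch = puncta.compare_live_fixed(self.mk(0, 1, 10), self.mk(5, 1, 10))
        assert not ch.valid["n_puncta"]
        assert np.isnan(ch.percent_change["n_puncta"])
        assert ch.absolute_change["n_puncta"] == 5

    def test_roughness_ratio_example(self):
        ch = puncta.compare_live_fixed(self.mk(10, 1.0, 10), self.mk(10, 0.52, 10))
        assert ch.percent_change["surface_roughness"] == pytest.approx(-48.0)

    def test_mismatched_tolerance_rejected(self):
        with pytest.raises(ValueError):
            puncta.compare_live_fixed(self.mk(1, 1, 1, tol=1.0), self.mk(1, 1, 1, tol=2.0))


class TestMaskHelpers:
    def test_multi_region_mask_warns(self):
        m = np.zeros((10, 10), bool)
        m[1, 1] = True
        m[8, 8] = True
        with pytest.warns(UserWarning, match="connected regions"):
            puncta.NucleusMask(m)

    def test_otsu_helper_finds_nucleus(self):
        from fixartifact import synth

        stack, mask, _ = synth.make_nucleus_stack(
            synth.SyntheticImageSpec(seed=1, noise_sd=0.5)
        )
        est = puncta.estimate_nucleus_mask(puncta.project(stack, "max"))
        overlap = (est & mask.pixels).sum() / mask.pixels.sum()
        assert overlap > 0.95
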