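from dataclasses import replace

import numpy as np
import pytest

from tjmetrics.morphometry import classify_transverse_profile, line_scan
from tjmetrics.morphometry.linescan import LineScanProfile
from tjmetrics.network import polyline_length
from tjmetrics.simulate import MonolayerSpec, generate_monolayer


def _longest_interior_side(net):
    return max(net.interior_sides(), key=lambda s: polyline_length(s.polyline))


def _transverse_scan_geometry(side, reach_um=2.0):
    p0, p1 = side.polyline[0], side.polyline[-1]
    mid = (p0 + p1) / 2
    t = (p1 - p0) / np.linalg.norm(p1 - p0)
    n = np.array([-t[1], t[0]])
    return tuple(mid - reach_um * n), tuple(mid + reach_um * n)


class TestLineScan:
    def test_peak_at_junction_crossing(self, small_image, small_spec):
        side = _longest_interior_side(small_image.truth)
        a, b = _transverse_scan_geometry(side)
        prof = line_scan(
            small_image.channels["junction"], small_spec.pixel_size_um, a, b, width_um=0.3
        )
        peak_pos = prof.positions_um[np.argmax(prof.intensity)]
        # crossing is at the scan midpoint; tolerance one pixel
        assert abs(peak_pos - 2.0) <= small_spec.pixel_size_um

    def test_background_scan_constant(self, small_spec):
        spec = replace(small_spec, noise_sd=2.0, seed=8)
        img = generate_monolayer(spec)
        # scan within the interior of the largest cell: use a short scan
        # far from any junction by probing a low-intensity region
        ch = img.channels["junction"]
        bg = np.argwhere(ch < np.percentile(ch, 10))
        r, c = bg[len(bg) // 2]
        x, y = (c + 0.5) * 0.1, (r + 0.5) * 0.1
        prof = line_scan(ch, 0.1, (max(x - 0.3, 0), y), (min(x + 0.3, 59.9), y))
        assert prof.intensity.std() <= 3 * spec.noise_sd

    def test_zero_length_raises(self, small_image):
        with pytest.raises(ValueError, match="zero-length"):
            line_scan(small_image.channels["junction"], 0.1, (5.0, 5.0), (5.0, 5.0))

    def test_endpoint_outside_raises(self, small_image):
        with pytest.raises(ValueError, match="outside"):
            line_scan(small_image.channels["junction"], 0.1, (0.0, 0.0), (1000.0, 0.0))

    def test_positions_strictly_increasing(self, small_image):
        prof = line_scan(small_image.channels["junction"], 0.1, (5.0, 5.0), (20.0, 30.0))
        assert np.all(np.diff(prof.positions_um) > 0)
        assert prof.positions_um.shape == prof.intensity.shape

    def test_two_row_peak_separation(self):
        spec = MonolayerSpec(
            field_width_um=60,
            field_height_um=60,
            n_cells=25,
            seed=11,
            junction_width_um=0.2,
            psf_sigma_um=0.1,
            myosin_mode="two_row",
            two_row_offset_um=0.5,
        )
        img = generate_monolayer(spec)
        side = _longest_interior_side(img.truth)
        a, b = _transverse_scan_geometry(side)
        prof = line_scan(img.channels["myosin"], spec.pixel_size_um, a, b, width_um=0.3)
        rng = np.ptp(prof.intensity)
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(prof.intensity, prominence=0.2 * rng)
        assert len(peaks) >= 2
        top2 = peaks[np.argsort(prof.intensity[peaks])[-2:]]
        sep = abs(prof.positions_um[top2[0]] - prof.positions_um[top2[1]])
        assert sep == pytest.approx(2 * spec.two_row_offset_um, abs=0.3)


class TestClassify:
    def _profile(self, y):
        return LineScanProfile(
            positions_um=np.arange(len(y), dtype=float) * 0.1,
            intensity=np.asarray(y, dtype=float),
            width_um=0.0,
        )

    def test_single_gaussian_bump(self):
        x = np.linspace(-3, 3, 101)
        assert classify_transverse_profile(self._profile(np.exp(-(x**2)))) == "single_peak"

    def test_two_gaussian_bumps(self):
        x = np.linspace(-6, 6, 201)
        y = np.exp(-((x - 2.5) ** 2)) + np.exp(-((x + 2.5) ** 2))
        assert classify_transverse_profile(self._profile(y)) == "double_peak"

    def test_flat_profile_none(self):
        assert classify_transverse_profile(self._profile(np.ones(50))) == "none"

    def test_monotone_ramp_none(self):
        assert classify_transverse_profile(self._profile(np.linspace(0, 1, 50))) == "none"


class TestModesMonteCarlo:
    @pytest.mark.parametrize(
        "mode,expected", [("continuous", "single_peak"), ("two_row", "double_peak")]
    )
    def test_mode_classification_majority(self, mode, expected):
        hits = 0
        n_scans = 0
        for seed in range(4):
            spec = MonolayerSpec(
                field_width_um=50,
                field_height_um=50,
                n_cells=16,
                seed=seed,
                tortuosity_amplitude_um=0.0,
                junction_width_um=0.2,
                psf_sigma_um=0.1,
                myosin_mode=mode,
            )
            img = generate_monolayer(spec)
            sides = sorted(
                img.truth.interior_sides(),
                key=lambda s: -polyline_length(s.polyline),
            )[:5]
            for side in sides:
                a, b = _transverse_scan_geometry(side)
                try:
                    prof = line_scan(img.channels["myosin"], 0.1, a, b, width_um=0.3)
                except ValueError:
                    continue
                n_scans += 1
                hits += classify_transverse_profile(prof) == expected
        assert n_scans >= 15
        assert hits / n_scans >= 0.9
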