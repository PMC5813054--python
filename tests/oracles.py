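"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles (explicit loops over
definitions) and stays independent of the implementation paths it checks.
"""

from __future__ import annotations

import math

import numpy as np


def icc2_oracle(x1, x2):
    """ICC(2,1) from the raw two-way ANOVA definition, with explicit sums.

    Subjects are rows, the two measurements are columns.  Mean squares are
    accumulated term by term; the ICC follows the two-way random-effects,
    absolute-agreement, single-measures formula.
    """
    x1 = list(map(float, x1))
    x2 = list(map(float, x2))
    n = len(x1)
    k = 2
    table = [[x1[i], x2[i]] for i in range(n)]
    grand = sum(sum(row) for row in table) / (n * k)
    row_means = [sum(row) / k for row in table]
    col_means = [sum(table[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((rm - grand) ** 2 for rm in row_means)
    ss_cols = n * sum((cm - grand) ** 2 for cm in col_means)
    ss_total = sum((table[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def cov_oracle(x1, x2):
    """Eq.-style CoV in percent: sample sd of differences over the mean of
    pair means, every sum written out."""
    x1 = list(map(float, x1))
    x2 = list(map(float, x2))
    n = len(x1)
    d = [a - b for a, b in zip(x1, x2)]
    dbar = sum(d) / n
    sd = math.sqrt(sum((di - dbar) ** 2 for di in d) / (n - 1))
    denom = sum((a + b) / 2.0 for a, b in zip(x1, x2)) / n
    return 100.0 * sd / denom


def annulus_volume_oracle(r_lumen, r_outer, length):
    """Analytic wall volume of a cylindrical annulus."""
    return math.pi * (r_outer**2 - r_lumen**2) * length


def regular_polygon_area_oracle(n_vertices, circumradius):
    """Closed-form area of a regular polygon: (n/2) R^2 sin(2 pi / n)."""
    return 0.5 * n_vertices * circumradius**2 * math.sin(2 * math.pi / n_vertices)


def erf_edge_d2080_oracle(sigma):
    """20-80 distance of a Gaussian-blurred step: (z_0.8 - z_0.2) * sigma."""
    from scipy.stats import norm

    return (norm.ppf(0.8) - norm.ppf(0.2)) * sigma


def comb_alias_positions_oracle(n, factor):
    """Image-domain replica offsets produced by keeping every ``factor``-th
    k-space line of an n-point axis: multiples of n // factor."""
    return [j * (n // factor) for j in range(factor)]


def radial_profile_chain_oracle(
    positions_mm,
    lumen_edge_mm=3.0,
    outer_edge_mm=4.0,
    intensities=(0.05, 1.0, 0.3),
    pixel_mm=0.625,
    pixel_phase=0.5,
    fine_mm=0.2,
    fine_origin_mm=-12.0,
):
    """1-D model of the rendering + resampling chain along a radial ray.

    The black-blood radial intensity (lumen | wall | background with edges
    at the lumen and outer radii) is area-averaged over acquisition pixels
    of width ``pixel_mm`` centred at ``(j + pixel_phase) * pixel_mm``
    (exact partial-volume rendering), linearly interpolated onto the
    ``fine_mm`` axial grid anchored at ``fine_origin_mm``, and linearly
    interpolated again at the requested profile positions -- mirroring,
    independently, what the imaging chain does to an ideal edge.  The
    sub-pixel alignment of the edge with the grids matters, which is why
    the grid phases are explicit.
    """
    from scipy.interpolate import interp1d

    lum, wall, bg = intensities
    src = (np.arange(-60, 61) + pixel_phase) * pixel_mm

    # supersampled 2-D coverage of the disks over the two source-pixel rows
    # adjacent to y = 0 (the axial resample averages them with weight 1/2)
    ns = 64
    sub = (np.arange(ns) + 0.5) / ns - 0.5
    xs = src[:, None, None, None] + pixel_mm * sub[None, :, None, None]
    y_rows = np.array([-pixel_phase * pixel_mm, pixel_phase * pixel_mm])
    ys = y_rows[None, None, None, :] + pixel_mm * sub[None, None, :, None]
    rad = np.hypot(xs, ys)

    def cov(edge):  # mean coverage of the disk r <= edge per pixel, row-averaged
        return (rad <= edge).mean(axis=(1, 2, 3))

    intens = bg + (wall - bg) * cov(outer_edge_mm) + (lum - wall) * cov(lumen_edge_mm)
    n_fine = int((src[-2] - fine_origin_mm) / fine_mm)
    fine = fine_origin_mm + fine_mm * np.arange(max(n_fine, 1))
    fine = fine[(fine >= src[0]) & (fine <= src[-1])]
    stage1 = interp1d(src, intens)(fine)
    return interp1d(fine, stage1)(positions_mm)
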