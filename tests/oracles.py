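"""Independent brute-force reference implementations used only by tests.

Everything here is written as literally as possible (explicit loops,
closed forms, dense matrices) and must stay independent of the package
code paths it checks.
"""

from __future__ import annotations

import math

import numpy as np


def nrmse_loops(im, ri):
    n = 0
    acc = 0.0
    s = 0.0
    for a, b in zip(np.ravel(im), np.ravel(ri)):
        acc += (a - b) ** 2
        s += b
        n += 1
    return math.sqrt(acc / n) / (s / n)


def nmae_loops(im, ri):
    n = 0
    acc = 0.0
    s = 0.0
    for a, b in zip(np.ravel(im), np.ravel(ri)):
        acc += abs(a - b)
        s += b
        n += 1
    return (acc / n) / (s / n)


def psnr_loops(im, ri):
    n = 0
    acc = 0.0
    mx = -math.inf
    for a, b in zip(np.ravel(im), np.ravel(ri)):
        acc += (a - b) ** 2
        mx = max(mx, a, b)
        n += 1
    rmse = math.sqrt(acc / n)
    if rmse == 0:
        return math.inf
    return 20.0 * math.log10(mx / rmse)


def ssim_global_loops(im, ri):
    x = np.ravel(np.asarray(im, float))
    y = np.ravel(np.asarray(ri, float))
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    vx = sum((a - mx) ** 2 for a in x) / n
    vy = sum((b - my) ** 2 for b in y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    L = max(y) - min(y)
    if L == 0:
        L = max(abs(max(y)), 1.0)
    c1 = (0.01 * L) ** 2
    c2 = (0.03 * L) ** 2
    return ((2 * mx * my + c1) * (2 * cov + c2)) / (
        (mx**2 + my**2 + c1) * (vx + vy + c2)
    )


def raysum_rotate_loops(vol, angle_deg):
    """Straight ray sum along +y of the bilinearly rotated volume.

    Literal triple-loop re-derivation of the rotate-and-sum discretisation
    (no attenuation, no PSF, unit scaling).
    """
    nx, ny, nz = vol.shape
    th = math.radians(angle_deg)
    c, s = math.cos(th), math.sin(th)
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    out = np.zeros((nx, nz))
    for i in range(nx):
        for j in range(ny):
            xs = c * (i - cx) - s * (j - cy) + cx
            ys = s * (i - cx) + c * (j - cy) + cy
            x0, y0 = math.floor(xs), math.floor(ys)
            fx, fy = xs - x0, ys - y0
            for dx_, dy_, w in (
                (0, 0, (1 - fx) * (1 - fy)),
                (1, 0, fx * (1 - fy)),
                (0, 1, (1 - fx) * fy),
                (1, 1, fx * fy),
            ):
                xi, yi = x0 + dx_, y0 + dy_
                if 0 <= xi < nx and 0 <= yi < ny and w > 0:
                    for k in range(nz):
                        out[i, k] += w * vol[xi, yi, k]
    return out


def ols_r2_loops(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((a - mx) ** 2 for a in x)
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    slope = sxy / sxx
    intercept = my - slope * mx
    ss_res = sum((b - (slope * a + intercept)) ** 2 for a, b in zip(x, y))
    ss_tot = sum((b - my) ** 2 for b in y)
    return slope, intercept, 1.0 - ss_res / ss_tot


def paired_t_p_loops(d):
    """Two-sided one-sample t-test p-value from the textbook formulas."""
    from scipy.stats import t as tdist

    n = len(d)
    mean = sum(d) / n
    var = sum((x - mean) ** 2 for x in d) / (n - 1)
    t = mean / math.sqrt(var / n)
    return 2.0 * tdist.sf(abs(t), n - 1)


def rm_anova_loops(m):
    """Long-form sums-of-squares repeated-measures ANOVA."""
    from scipy.stats import f as fdist

    m = np.asarray(m, float)
    n, k = m.shape
    grand = m.sum() / (n * k)
    ss_m = sum(n * (m[:, j].mean() - grand) ** 2 for j in range(k))
    ss_s = sum(k * (m[i, :].mean() - grand) ** 2 for i in range(n))
    ss_t = sum((m[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_e = ss_t - ss_m - ss_s
    F = (ss_m / (k - 1)) / (ss_e / ((n - 1) * (k - 1)))
    return F, fdist.sf(F, k - 1, (n - 1) * (k - 1))


def sphere_count_loops(center, radius_mm, voxel_size_mm, shape):
    cnt = 0
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                d2 = ((i - center[0]) ** 2 + (j - center[1]) ** 2 + (k - center[2]) ** 2)
                if d2 * voxel_size_mm**2 <= radius_mm**2:
                    cnt += 1
    return cnt
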