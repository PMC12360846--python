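"""Independent brute-force reference implementations used by the tests.

Everything here is written as plainly as possible — triple loops, two-pass
statistics — and must stay independent of the package code paths it checks.
"""

import numpy as np


def trilinear_resample_oracle(data, voxel_in, origin_in, voxel_out, n_out):
    """Triple-loop trilinear interpolation on world coordinates.

    ``data`` is (z, y, x); ``voxel_*``/``origin_in`` are (x, y, z) vectors;
    ``n_out`` is the output sample count per (x, y, z) axis.  Samples outside
    the input grid evaluate to 0.
    """
    data = np.asarray(data, dtype=np.float64)
    nz, ny, nx = data.shape
    out = np.zeros((n_out[2], n_out[1], n_out[0]))
    for k in range(n_out[2]):
        for j in range(n_out[1]):
            for i in range(n_out[0]):
                # world position of output sample, then fractional input index
                fx = i * voxel_out[0] / voxel_in[0]
                fy = j * voxel_out[1] / voxel_in[1]
                fz = k * voxel_out[2] / voxel_in[2]
                x0, y0, z0 = int(np.floor(fx)), int(np.floor(fy)), int(np.floor(fz))
                tx, ty, tz = fx - x0, fy - y0, fz - z0
                acc = 0.0
                for dz in (0, 1):
                    for dy in (0, 1):
                        for dx in (0, 1):
                            xi, yi, zi = x0 + dx, y0 + dy, z0 + dz
                            if 0 <= xi < nx and 0 <= yi < ny and 0 <= zi < nz:
                                v = data[zi, yi, xi]
                            else:
                                v = 0.0
                            wgt = (
                                (tx if dx else 1 - tx)
                                * (ty if dy else 1 - ty)
                                * (tz if dz else 1 - tz)
                            )
                            acc += wgt * v
                out[k, j, i] = acc
    return out


def gaussian_sum_oracle(positions, atomic_numbers, theta, k, grid_shape, voxel, origin):
    """Triple loop over voxels and atoms evaluating the Gaussian sum.

    ``grid_shape`` is (nz, ny, nx); no cutoff.
    """
    nz, ny, nx = grid_shape
    out = np.zeros((nz, ny, nx))
    for kz in range(nz):
        for jy in range(ny):
            for ix in range(nx):
                x = origin[0] + ix * voxel[0]
                y = origin[1] + jy * voxel[1]
                z = origin[2] + kz * voxel[2]
                total = 0.0
                for pos, zi in zip(positions, atomic_numbers):
                    d2 = (x - pos[0]) ** 2 + (y - pos[1]) ** 2 + (z - pos[2]) ** 2
                    total += theta * zi * np.exp(-k * d2)
                out[kz, jy, ix] = total
    return out


def ssim_oracle(x, y, window=7, data_range=1.0):
    """Triple loop over all fully contained windows; sample (ddof=1) stats."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    r = window // 2
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    nz, ny, nx = x.shape
    vals = []
    for k in range(r, nz - r):
        for j in range(r, ny - r):
            for i in range(r, nx - r):
                wx = x[k - r : k + r + 1, j - r : j + r + 1, i - r : i + r + 1].ravel()
                wy = y[k - r : k + r + 1, j - r : j + r + 1, i - r : i + r + 1].ravel()
                mx, my = wx.mean(), wy.mean()
                n = wx.size
                vx = ((wx - mx) ** 2).sum() / (n - 1)
                vy = ((wy - my) ** 2).sum() / (n - 1)
                vxy = ((wx - mx) * (wy - my)).sum() / (n - 1)
                vals.append(
                    ((2 * mx * my + c1) * (2 * vxy + c2))
                    / ((mx * mx + my * my + c1) * (vx + vy + c2))
                )
    return float(np.mean(vals))


def pcc_oracle(x, y):
    """Two-pass mean/covariance Pearson correlation."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    mx = x.sum() / x.size
    my = y.sum() / y.size
    num = 0.0
    sx = 0.0
    sy = 0.0
    for xi, yi in zip(x, y):
        num += (xi - mx) * (yi - my)
        sx += (xi - mx) ** 2
        sy += (yi - my) ** 2
    return num / (np.sqrt(sx) * np.sqrt(sy))
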