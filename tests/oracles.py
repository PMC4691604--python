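"""Independent brute-force oracles used by the test suite.

Each oracle deliberately avoids the code path it checks: explicit Python
loops, dense eigendecompositions, and pairwise counting instead of the
vectorized / closed-form implementations in the package.
"""

import numpy as np


def loop_gradients(plane):
    """Central differences in the interior, one-sided at borders, by loops."""
    h, w = plane.shape
    dx = np.zeros((h, w))
    dy = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            if 0 < c < w - 1:
                dx[r, c] = (plane[r, c + 1] - plane[r, c - 1]) / 2.0
            elif c == 0:
                dx[r, c] = plane[r, 1] - plane[r, 0]
            else:
                dx[r, c] = plane[r, w - 1] - plane[r, w - 2]
            if 0 < r < h - 1:
                dy[r, c] = (plane[r + 1, c] - plane[r - 1, c]) / 2.0
            elif r == 0:
                dy[r, c] = plane[1, c] - plane[0, c]
            else:
                dy[r, c] = plane[h - 1, c] - plane[h - 2, c]
    return dx, dy


def gaussian_kernel_1d(sigma, truncate=4.0):
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def windowed_gaussian_smooth(plane, sigma, truncate=4.0):
    """Per-pixel weighted window sum with mirror borders, by loops."""
    k1 = gaussian_kernel_1d(sigma, truncate)
    radius = (k1.size - 1) // 2
    k2 = np.outer(k1, k1)
    padded = np.pad(plane, radius, mode="reflect")
    h, w = plane.shape
    out = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            window = padded[r: r + 2 * radius + 1, c: c + 2 * radius + 1]
            out[r, c] = (window * k2).sum()
    return out


def brute_force_tensor(image_pixels, sigma, truncate=4.0):
    """G/F/H planes from loop gradients + explicit windowed Gaussian sums."""
    gxx = gxy = gyy = 0.0
    h, w, nchan = image_pixels.shape
    gxx = np.zeros((h, w))
    gxy = np.zeros((h, w))
    gyy = np.zeros((h, w))
    for i in range(nchan):
        dx, dy = loop_gradients(image_pixels[:, :, i])
        gxx += dx * dx
        gxy += dx * dy
        gyy += dy * dy
    return (windowed_gaussian_smooth(gxx, sigma, truncate),
            windowed_gaussian_smooth(gxy, sigma, truncate),
            windowed_gaussian_smooth(gyy, sigma, truncate))


def eigen_sum_diff_by_solver(g, f, h):
    """(λ1−λ2, λ1+λ2) from numpy's symmetric eigensolver, per pixel."""
    g = np.atleast_1d(np.asarray(g, dtype=float).ravel())
    f = np.atleast_1d(np.asarray(f, dtype=float).ravel())
    h = np.atleast_1d(np.asarray(h, dtype=float).ravel())
    diffs, sums = [], []
    for gi, fi, hi in zip(g, f, h):
        lam = np.linalg.eigvalsh(np.array([[gi, fi], [fi, hi]]))
        diffs.append(lam[1] - lam[0])
        sums.append(lam[1] + lam[0])
    return np.array(diffs), np.array(sums)


def pair_count_auc(pos, neg):
    """(concordant + ½·ties) / pairs, by explicit double loop."""
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))
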