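"""From-scratch scalar reference implementations used as test oracles.

Everything here is pure Python over nested lists (no array library) and is
written directly from the defining formulas, independently of the package's
vectorized code paths.
"""

import math

SMOOTH, TEXTURE, EDGE = 0, 1, 2

SOBEL_X = [[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]]
SOBEL_Y = [[-1, -2, -1], [0, 0, 0], [1, 2, 1]]


def rho(alpha):
    m = 1.0 - alpha + alpha / math.gamma(alpha)
    return (
        1.0 / m,
        alpha / (2.0 * m),
        (alpha**3 - alpha**2) / (2.0 * m),
        (alpha**2 - alpha**4) / (6.0 * m),
    )


def _index(i, n, padding):
    if padding == "replicate":
        return min(max(i, 0), n - 1)
    # scipy-style 'reflect': (d c b a | a b c d | d c b a)
    while i < 0 or i >= n:
        if i < 0:
            i = -1 - i
        if i >= n:
            i = 2 * n - 1 - i
    return i


def correlate(img, kernel, padding="replicate"):
    """Double-loop correlation with the given boundary policy."""
    h, w = len(img), len(img[0])
    k = len(kernel)
    half = k // 2
    out = [[0.0] * w for _ in range(h)]
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for u in range(k):
                for v in range(k):
                    ii = _index(i + u - half, h, padding)
                    jj = _index(j + v - half, w, padding)
                    acc += kernel[u][v] * img[ii][jj]
            out[i][j] = acc
    return out


def gradient_magnitude(img):
    gx = correlate(img, SOBEL_X, "replicate")
    gy = correlate(img, SOBEL_Y, "replicate")
    return [
        [math.hypot(a, b) for a, b in zip(ra, rb)] for ra, rb in zip(gx, gy)
    ]


def segment(img):
    grad = gradient_magnitude(img)
    flat = [g for row in grad for g in row]
    t1 = sum(flat) / len(flat)
    above = [g for g in flat if g > t1]
    t2 = sum(above) / len(above) if above else t1
    labels = [
        [EDGE if g > t2 else TEXTURE if g > t1 else SMOOTH for g in row]
        for row in grad
    ]
    return labels, t1, t2


# ---------------------------------------------------------------------------
# mask grids, written out literally in terms of rho0/rho1

DIRECTIONS = {
    "pos_x": (0, 1),
    "neg_x": (0, -1),
    "pos_y": (-1, 0),
    "neg_y": (1, 0),
    "up_right": (-1, 1),
    "up_left": (-1, -1),
    "down_right": (1, 1),
    "down_left": (1, -1),
}


def directional_grid(alpha, name):
    r0, r1, _, _ = rho(alpha)
    g = [[0.0] * 3 for _ in range(3)]
    g[1][1] = r0
    di, dj = DIRECTIONS[name]
    g[1 + di][1 + dj] = r1
    return g


def bidirectional_grids(alpha):
    """Canonical bidirectional grids for the four axes, written out."""
    r0, r1, _, _ = rho(alpha)
    a, b = r1 / 3.0, r0 / 5.0
    p, m = a - b, b - a
    return {
        "pos_y": [[p, p, p], [0.0, 0.0, 0.0], [m, m, m]],
        "up_right": [[0.0, p, p], [m, 0.0, p], [m, m, 0.0]],
        "pos_x": [[m, 0.0, p], [m, 0.0, p], [m, 0.0, p]],
        "down_right": [[m, m, 0.0], [m, 0.0, p], [0.0, p, p]],
    }


def composite_grid(alpha):
    r0, r1, _, _ = rho(alpha)
    a, b = r1 / 3.0, r0 / 5.0
    c = 2 * b + a
    return [
        [-a, -2 * a, -c, 2 * a, a],
        [-2 * a, -3 * b, -r0, 3 * b, 2 * a],
        [-c, -r0, 0.0, r0, c],
        [-2 * a, -3 * b, r0, 3 * b, 2 * a],
        [-a, -2 * a, c, 2 * a, a],
    ]


def _response(img, alpha, mask_kind, padding):
    r0, r1, _, _ = rho(alpha)
    if mask_kind == "composite":
        grids = [composite_grid(alpha)]
        dc = [0.0]
    elif mask_kind == "bidirectional":
        grids = list(bidirectional_grids(alpha).values())
        dc = [0.0] * 4
    else:
        grids = [directional_grid(alpha, n) for n in DIRECTIONS]
        dc = [r0 + r1] * 8
    h, w = len(img), len(img[0])
    total = [[0.0] * w for _ in range(h)]
    for g, s in zip(grids, dc):
        resp = correlate(img, g, padding)
        for i in range(h):
            for j in range(w):
                total[i][j] += resp[i][j] - s * img[i][j]
    return total


def enhance(
    img,
    alphas=(0.4, 0.6, 0.8),
    mask_kind="composite",
    lam=1.0,
    padding="replicate",
    adaptive=True,
):
    """Scalar reimplementation of the full adaptive enhancement pipeline."""
    h, w = len(img), len(img[0])
    if adaptive:
        labels, _, _ = segment(img)
        responses = {a: _response(img, a, mask_kind, padding) for a in set(alphas)}
        resp = [
            [responses[alphas[labels[i][j]]][i][j] for j in range(w)]
            for i in range(h)
        ]
    else:
        resp = _response(img, alphas[1], mask_kind, padding)
    return [
        [min(255.0, max(0.0, img[i][j] + lam * resp[i][j])) for j in range(w)]
        for i in range(h)
    ]


# ---------------------------------------------------------------------------
# metric oracles


def mse(x, y):
    n = len(x) * len(x[0])
    return sum((a - b) ** 2 for rx, ry in zip(x, y) for a, b in zip(rx, ry)) / n


def psnr(x, y, max_val=255.0):
    e = mse(x, y)
    return math.inf if e == 0 else 10.0 * math.log10(max_val**2 / e)


def ssim_mean(x, y, window=8, c1=(0.01 * 255) ** 2, c2=(0.03 * 255) ** 2):
    """Windowed SSIM via explicit per-window loops and the component form."""
    c3 = c2 / 2.0
    h, w = len(x), len(x[0])
    scores = []
    for i in range(h - window + 1):
        for j in range(w - window + 1):
            px = [x[i + u][j + v] for u in range(window) for v in range(window)]
            py = [y[i + u][j + v] for u in range(window) for v in range(window)]
            n = float(window * window)
            mx, my = sum(px) / n, sum(py) / n
            vx = sum(a * a for a in px) / n - mx * mx
            vy = sum(a * a for a in py) / n - my * my
            cov = sum(a * b for a, b in zip(px, py)) / n - mx * my
            sx, sy = math.sqrt(max(vx, 0)), math.sqrt(max(vy, 0))
            lum = (2 * mx * my + c1) / (mx * mx + my * my + c1)
            con = (2 * sx * sy + c2) / (vx + vy + c2)
            struct = (cov + c3) / (sx * sy + c3)
            scores.append(lum * con * struct)
    return sum(scores) / len(scores)
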