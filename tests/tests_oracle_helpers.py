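"""Shared brute-force oracles used by both the unit and acceptance suites."""

import numpy as np


def brute_force_otsu(img, n_bins=256):
    """Exhaustive scan of all histogram cuts minimizing w1*var1 + w2*var2."""
    lo, hi = float(img.min()), float(img.max())
    counts, edges = np.histogram(img, bins=n_bins, range=(lo, hi))
    p = counts / counts.sum()
    mids = 0.5 * (edges[:-1] + edges[1:])
    best_t, best_val = None, np.inf
    for t in range(n_bins - 1):
        w1, w2 = p[: t + 1].sum(), p[t + 1 :].sum()
        val = 0.0
        for w, sel in ((w1, slice(None, t + 1)), (w2, slice(t + 1, None))):
            if w > 0:
                mu = (p[sel] * mids[sel]).sum() / w
                val += ((mids[sel] - mu) ** 2 * p[sel]).sum()
        if val < best_val - 1e-15:
            best_val, best_t = val, t
    return float(edges[best_t + 1])


def brute_force_edt(mask):
    """Min Euclidean distance to any background pixel, O(N^2)."""
    out = np.zeros(mask.shape, dtype=float)
    bg = np.argwhere(~mask)
    for r, c in np.argwhere(mask):
        out[r, c] = np.sqrt(((bg - (r, c)) ** 2).sum(axis=1).min()) if len(bg) else 0.0
    return out
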