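"""Independent brute-force oracles used to cross-check fast implementations.

Everything here is written from the defining formulas, with no reuse of the
package's FFT or neighbor-grid code paths.
"""

from __future__ import annotations

import itertools

import numpy as np


def naive_translation_scan(x, xmask, y, support, map_kind):
    """Direct per-shift evaluation of the combined cc + ov search score.

    ``x`` is the thresholded experimental density (zero below the working
    contour and outside its grid), ``xmask`` its contour mask, ``y`` the
    subunit density and ``support`` its footprint.  Returns
    ``(best_shift, best_score, cc_map, ov_map)`` with dict keys = shifts.
    """
    nx = np.array(x.shape)
    my = np.array(y.shape)
    sup_idx = np.argwhere(support)
    yv = y[support]
    n = len(sup_idx)
    y_mean = yv.mean()
    sy2 = float(yv @ yv)
    sy2c = sy2 - n * y_mean**2
    cc_map, ov_map = {}, {}
    pad = np.pad(x, [(m - 1, m - 1) for m in my])
    padm = np.pad(xmask, [(m - 1, m - 1) for m in my])
    for shift in itertools.product(*[range(-(m - 1), nn) for m, nn in zip(my, nx)]):
        off = np.array(shift) + (my - 1)
        xv = pad[off[0] + sup_idx[:, 0], off[1] + sup_idx[:, 1], off[2] + sup_idx[:, 2]]
        xm = padm[off[0] + sup_idx[:, 0], off[1] + sup_idx[:, 1], off[2] + sup_idx[:, 2]]
        ov_map[shift] = xm.sum() / n
        if map_kind == "experimental":
            sx2 = float(xv @ xv)
            cc_map[shift] = (
                float(xv @ yv) / np.sqrt(sx2 * sy2) if sx2 > 0 else -np.inf
            )
        else:
            sx = xv.sum()
            var_x = float(xv @ xv) - sx**2 / n
            if var_x > 1e-12:
                cov = float(xv @ yv) - y_mean * sx
                cc_map[shift] = cov / np.sqrt(var_x * sy2c)
            else:
                cc_map[shift] = -np.inf
    best = max(
        cc_map,
        key=lambda s: (cc_map[s] + ov_map[s] if np.isfinite(cc_map[s]) else -np.inf),
    )
    return best, cc_map[best] + ov_map[best], cc_map, ov_map


def brute_force_clashes(coords_a, coords_b, cutoff):
    """O(n m) strict-inequality clash count."""
    d = np.linalg.norm(
        np.asarray(coords_a)[:, None, :] - np.asarray(coords_b)[None, :, :], axis=-1
    )
    return int(np.sum(d < cutoff))


def enumerate_top_k(node_energies, edges, k):
    """Exhaustive top-k assignments of a pairwise model, (energy, tuple) sorted."""
    ranges = [range(len(e)) for e in node_energies]
    out = []
    for a in itertools.product(*ranges):
        e = sum(ne[x] for ne, x in zip(node_energies, a))
        for (i, j), table in edges.items():
            e += table[a[i], a[j]]
        out.append((float(e), a))
    out.sort(key=lambda t: (t[0], t[1]))
    return out[:k]
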