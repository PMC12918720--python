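"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

_STRUCTURE = np.ones((3, 3), bool)  # 8-connectivity


def _plateaus(image: np.ndarray):
    """8-connected components of equal value, as lists of pixel indices."""
    seen = np.zeros(image.shape, bool)
    out = []
    for r in range(image.shape[0]):
        for c in range(image.shape[1]):
            if seen[r, c]:
                continue
            labels, _ = ndimage.label(image == image[r, c], structure=_STRUCTURE)
            members = np.argwhere(labels == labels[r, c])
            for rr, cc in members:
                seen[rr, cc] = True
            out.append(members)
    return out


def flood_fill_maxima(image: np.ndarray, prominence: float):
    """Exhaustive prominence computation by per-peak flood filling.

    For every local-maximum plateau, the water level is lowered from the
    peak value until the connected region around the peak touches a
    strictly higher pixel; the prominence is peak value minus that level
    (or peak minus the image minimum if no higher pixel exists).  Returns
    the accepted maxima as a set of (row, col) plateau centroids rounded
    half-up, sorted by (row, col).
    """
    image = np.asarray(image, dtype=float)
    lo = image.min()
    accepted = []
    for members in _plateaus(image):
        r0, c0 = members[0]
        v = image[r0, c0]
        # local maximum test: every 8-neighbor outside the plateau is lower
        is_max = True
        for rr, cc in members:
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    nr, nc = rr + dr, cc + dc
                    if (0 <= nr < image.shape[0] and 0 <= nc < image.shape[1]
                            and image[nr, nc] > v):
                        is_max = False
        if not is_max:
            continue
        prom = v - lo
        for level in np.unique(image[image < v])[::-1]:
            region, _ = ndimage.label(image >= level, structure=_STRUCTURE)
            if (image[region == region[r0, c0]] > v).any():
                prom = v - level
                break
        if prom >= prominence:
            cen = members.mean(axis=0)
            accepted.append((int(np.floor(cen[0] + 0.5)),
                             int(np.floor(cen[1] + 0.5))))
    return sorted(accepted)
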