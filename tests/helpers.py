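"""Independent oracles shared by the unit and acceptance tests.

These deliberately avoid the code paths they check: the thickness oracle
enumerates every sphere by brute-force pairwise distances (no distance
transform), and the erosion oracle thresholds a padded distance transform.
"""

import numpy as np


def brute_force_local_thickness(mask: np.ndarray) -> np.ndarray:
    """Exhaustive largest-inscribed-sphere thickness in voxel units.

    For every foreground voxel c the admissible radius is the minimum
    distance to any background voxel (the array boundary continues as
    foreground); a voxel v inside that closed sphere inherits its diameter.
    Returns squared *diameters / 4* is avoided: output is diameter in voxels.
    """
    fg = np.argwhere(mask)
    bg = np.argwhere(~mask)
    if fg.size == 0:
        raise ValueError("empty mask")
    if bg.size == 0:
        raise ValueError("no background; thickness unbounded")
    # squared distance of every fg voxel to every bg voxel
    d2 = ((fg[:, None, :] - bg[None, :, :]) ** 2).sum(axis=2)
    r2 = d2.min(axis=1)  # admissible squared radius per center
    # pairwise fg-fg squared distances
    p2 = ((fg[:, None, :] - fg[None, :, :]) ** 2).sum(axis=2)
    covered = p2 <= r2[None, :]  # v i covered by center j
    best = np.where(covered, r2[None, :], -1).max(axis=1)
    out = np.full(mask.shape, np.nan)
    out[tuple(fg.T)] = 2.0 * np.sqrt(best)
    return out


def erosion_by_distance_transform(mask: np.ndarray, radius: int,
                                  slicewise: bool) -> np.ndarray:
    """Erosion oracle: {v : dist(v, background) > radius}, with the outside
    of the array treated as background (pad before the transform)."""
    from scipy.ndimage import distance_transform_edt

    if slicewise:
        out = np.zeros_like(mask)
        for k in range(mask.shape[0]):
            padded = np.pad(mask[k], 1)
            d = distance_transform_edt(padded)[1:-1, 1:-1]
            out[k] = np.round(d**2) > radius * radius
        return out & mask
    padded = np.pad(mask, 1)
    d = distance_transform_edt(padded)[1:-1, 1:-1, 1:-1]
    return (np.round(d**2) > radius * radius) & mask


def random_blob_mask(shape, seed, threshold=0.0):
    """A smoothed random field thresholded into a blobby boolean mask."""
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    field = gaussian_filter(rng.standard_normal(shape), 1.5)
    mask = field > threshold + field.mean()
    return mask
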