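import numpy as np
import pytest

from olfquant import Epoch, EpochSchedule


@pytest.fixture
def one_air_epoch():
    return EpochSchedule((Epoch("air", 0.0, 300.0),))


@pytest.fixture
def disc_roi():
    """64x64 boolean disc of radius 24 centered in the frame."""
    rr, cc = np.ogrid[:64, :64]
    return (rr - 32) ** 2 + (cc - 32) ** 2 <= 24 ** 2


def brute_force_occupancy(signal_mask, roi, radii):
    """Independent exhaustive tile enumeration of the occupancy metric.

    Tiles of side 2r anchored at the ROI bounding-box origin; a tile counts
    when it holds >= 1 ROI pixel and is occupied when it holds >= 1 in-ROI
    signal pixel.  Kept deliberately loop-based and separate from the library
    implementation.
    """
    rows, cols = np.nonzero(roi)
    r0, c0, r1, c1 = rows.min(), cols.min(), rows.max(), cols.max()
    inside = signal_mask & roi
    out = []
    for rad in radii:
        side = 2 * int(rad)
        n_roi = n_occ = 0
        for tr in range(r0, r1 + 1, side):
            for tc in range(c0, c1 + 1, side):
                tile_roi = roi[tr:tr + side, tc:tc + side]
                if tile_roi.any():
                    n_roi += 1
                    if inside[tr:tr + side, tc:tc + side].any():
                        n_occ += 1
        out.append(100.0 * n_occ / n_roi)
    return out
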