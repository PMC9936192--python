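import numpy as np
import pytest


def brute_force_autocorrelation(image, mask=None):
    """Reference masked autocorrelation by explicit pixel-pair enumeration.

    O(N^2) double loop over lags; tractable only for tiny images.  Returns
    (values, pair_counts) with the same centered layout as the FFT path.
    """
    I = np.asarray(image, dtype=float)
    H, W = I.shape
    M = np.ones((H, W)) if mask is None else (np.asarray(mask) != 0).astype(float)
    vals = np.full((2 * H - 1, 2 * W - 1), np.nan)
    cnts = np.zeros((2 * H - 1, 2 * W - 1), dtype=np.int64)
    for dy in range(-(H - 1), H):
        for dx in range(-(W - 1), W):
            y0, y1 = max(0, -dy), min(H, H - dy)
            x0, x1 = max(0, -dx), min(W, W - dx)
            a = (I * M)[y0:y1, x0:x1]
            b = (I * M)[y0 + dy : y1 + dy, x0 + dx : x1 + dx]
            ma = M[y0:y1, x0:x1]
            mb = M[y0 + dy : y1 + dy, x0 + dx : x1 + dx]
            n = (ma * mb).sum()
            cnts[dy + H - 1, dx + W - 1] = int(round(n))
            if n > 0:
                vals[dy + H - 1, dx + W - 1] = (a * b).sum() / n
    return vals, cnts


def band_coverage(z, width=3.0):
    """Fraction of finite z-scores within +-width."""
    z = np.asarray(z)
    z = z[np.isfinite(z)]
    return np.mean(np.abs(z) <= width)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
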