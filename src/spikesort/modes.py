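"""1-D multimodality detection and valley location.

Used to decide when a cluster projection or an amplitude histogram contains
more than one mode. The test fits 1- and 2-component Gaussian mixtures and
declares multimodality when the 2-component fit wins on BIC *and* the two
components are genuinely separated (Ashman's D > 2 with non-trivial weights)
— a pair of heavily overlapping components is a skewed unimodal bump, not two
modes.
"""

from __future__ import annotations

import numpy as np

__all__ = ["is_multimodal", "fit_two_modes", "find_valley"]

_MIN_WEIGHT = 0.03


def fit_two_modes(x: np.ndarray) -> dict | None:
    """Fit a 2-component Gaussian mixture if it beats one component on BIC.

    Returns None when the sample looks unimodal; otherwise a dict with the
    component means, sds, weights (sorted by mean), and Ashman's D
    sqrt(2)|mu1 - mu2| / sqrt(s1^2 + s2^2).
    """
    from sklearn.mixture import GaussianMixture

    x = np.asarray(x, dtype=float).reshape(-1, 1)
    if len(x) < 8 or np.ptp(x) == 0:
        return None
    g1 = GaussianMixture(1, random_state=0).fit(x)
    g2 = GaussianMixture(2, n_init=3, random_state=0).fit(x)
    if g2.bic(x) >= g1.bic(x):
        return None
    means = g2.means_.ravel()
    sds = np.sqrt(g2.covariances_.ravel())
    weights = g2.weights_.ravel()
    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]
    d = np.sqrt(2.0) * abs(means[1] - means[0]) / np.sqrt(sds[0] ** 2 + sds[1] ** 2)
    return {"means": means, "sds": sds, "weights": weights, "ashman_d": float(d)}


def is_multimodal(x: np.ndarray) -> bool:
    fit = fit_two_modes(x)
    if fit is None:
        return False
    return fit["ashman_d"] > 2.0 and fit["weights"].min() > _MIN_WEIGHT


def find_valley(
    x: np.ndarray,
    bins: int = 32,
    between: tuple[float, float] | None = None,
) -> float:
    """Deepest histogram valley between two modes.

    With ``between=(m1, m2)`` (e.g. mixture-component means) the valley is the
    center of the minimum-count bin strictly inside that interval; ties
    resolve to the middle of the lowest stretch. Without ``between``, the two
    modes are taken as the two highest local maxima of a smoothed histogram.
    """
    x = np.asarray(x, dtype=float)
    counts, edges = np.histogram(x, bins=bins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    if between is None:
        smooth = np.convolve(counts, [0.25, 0.5, 0.25], mode="same")
        peaks = [
            i for i in range(len(smooth))
            if smooth[i] > 0
            and (i == 0 or smooth[i] >= smooth[i - 1])
            and (i == len(smooth) - 1 or smooth[i] >= smooth[i + 1])
        ]
        if len(peaks) < 2:
            return float(np.median(x))
        peaks.sort(key=lambda i: -smooth[i])
        m1, m2 = sorted(centers[p] for p in peaks[:2])
    else:
        m1, m2 = sorted(between)
    inner = np.flatnonzero((centers > m1) & (centers < m2))
    if inner.size == 0:
        return float((m1 + m2) / 2.0)
    vmin = counts[inner].min()
    tie = inner[counts[inner] == vmin]
    return float(centers[tie[len(tie) // 2]])
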