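"""Bayesian neighbourhood smoothing of class-probability rasters.

Pixel-based classifiers leave salt-and-pepper noise where class
probabilities are nearly tied (borders, mixed pixels).  Smoothing borrows
strength from the neighbourhood: per class, each pixel's probability —
expressed as a logit x — is combined with the mean m and sample variance
s2 of its neighbours' logits (Chebyshev-radius window, centre excluded)
through the Gaussian conjugate posterior

    posterior logit = (s2 * x + sigma2 * m) / (s2 + sigma2)

where sigma2 is a global smoothness parameter.  sigma2 = 0 leaves the
cube unchanged; larger sigma2 pulls pixels toward the neighbourhood mean;
a noisy neighbourhood (large s2) protects the original value.  Labels are
re-derived as the posterior argmax and the smoothed probabilities are the
renormalised inverse logits.

The logit transform and the conjugate form are this implementation's
reading of neighbourhood Bayesian smoothing; they reproduce the limiting
behaviours above, which are the method's defining properties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.special import expit

from .classify import ProbabilityCube
from .consistency_rules import ClassMap
from .data_model import DEFAULT_VOCABULARY, ClassVocabulary


@dataclass
class SmoothingConfig:
    """Smoothing parameters: global variance, window radius, logit clamp."""

    sigma2: float = 10.0
    radius: int = 1
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be nonnegative")
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if not 0.0 < self.epsilon < 0.5:
            raise ValueError("epsilon must be in (0, 0.5)")


def to_logits(probs: np.ndarray, epsilon: float = 1e-6) -> np.ndarray:
    """Clamp probabilities to [epsilon, 1-epsilon] and map to log-odds."""
    p = np.clip(np.asarray(probs, dtype=float), epsilon, 1.0 - epsilon)
    return np.log(p / (1.0 - p))


def to_probs(logits: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_logits` (without renormalisation)."""
    return expit(np.asarray(logits, dtype=float))


def neighborhood_stats(
    plane: np.ndarray, radius: int = 1
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Neighbour mean, sample variance and count for every pixel.

    The window is the (2r+1) x (2r+1) Chebyshev neighbourhood excluding
    the centre pixel, truncated at raster edges.  Sample variance uses
    the n-1 denominator and is defined as 0 when n < 2.
    """
    plane = np.asarray(plane, dtype=float)
    size = 2 * radius + 1
    kernel = np.ones((size, size))
    ones = np.ones_like(plane)

    win_sum = ndimage.correlate(plane, kernel, mode="constant", cval=0.0)
    win_sumsq = ndimage.correlate(plane**2, kernel, mode="constant", cval=0.0)
    win_n = ndimage.correlate(ones, kernel, mode="constant", cval=0.0)

    n = np.rint(win_n - 1.0)
    s = win_sum - plane
    ss = win_sumsq - plane**2

    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(n > 0, s / np.maximum(n, 1), 0.0)
        s2 = np.where(n > 1, (ss - s**2 / np.maximum(n, 1)) / np.maximum(n - 1, 1), 0.0)
    s2 = np.maximum(s2, 0.0)  # guard rounding
    return m, s2, n.astype(int)


def smooth(
    cube: ProbabilityCube,
    config: SmoothingConfig = SmoothingConfig(),
    vocabulary: ClassVocabulary = DEFAULT_VOCABULARY,
) -> tuple[ProbabilityCube, ClassMap]:
    """Smooth a probability cube and re-derive the label map.

    Per class plane, the posterior logit is (s2*x + sigma2*m)/(s2 + sigma2);
    when both s2 and sigma2 are zero (or a pixel has no neighbours) the
    original logit is kept, so sigma2 = 0 is the identity.
    """
    cube.validate()
    x = to_logits(cube.probs, config.epsilon)  # (H, W, K)
    posterior = np.empty_like(x)
    for k in range(x.shape[2]):
        plane = x[:, :, k]
        m, s2, n = neighborhood_stats(plane, config.radius)
        denom = s2 + config.sigma2
        post = np.where(denom > 0, (s2 * plane + config.sigma2 * m) / np.where(denom > 0, denom, 1.0), plane)
        post = np.where(n == 0, plane, post)
        posterior[:, :, k] = post

    raw = to_probs(posterior)
    probs = raw / raw.sum(axis=2, keepdims=True)
    smoothed = ProbabilityCube(cube.year, probs, cube.class_order)

    codes = np.array([vocabulary.code(c) for c in cube.class_order])
    # class_order is ascending code; argmax takes the first maximum,
    # so ties resolve to the lowest class code.
    labels = codes[np.argmax(posterior, axis=2)].astype(np.uint8)
    return smoothed, ClassMap(cube.year, labels)


def confidence_map(cube: ProbabilityCube) -> np.ndarray:
    """Per-pixel confidence: margin between the top two probabilities."""
    if len(cube.class_order) < 2:
        return np.ones(cube.probs.shape[:2])
    part = np.partition(cube.probs, -2, axis=2)
    return part[:, :, -1] - part[:, :, -2]
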