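"""Independent numerical oracles used by the metric tests."""

import numpy as np
from scipy.stats import norm


def wrapped_gaussian_mi_quadrature(sigma, time_bins=24, phase_bins=24,
                                   period=24.0, n_quad=16, n_wrap=4):
    """Discrete MI between a uniform time-of-day bin and a phase bin for the
    generative model phase = omega * t + N(0, sigma^2), wrapped.

    Computed directly from the definition: wrapped-normal bin probabilities
    integrated over each time bin by midpoint quadrature.
    """
    omega = 2 * np.pi / period
    edges = np.linspace(-np.pi, np.pi, phase_bins + 1)
    wraps = 2 * np.pi * np.arange(-n_wrap, n_wrap + 1)[:, None]
    joint = np.zeros((time_bins, phase_bins))
    for k in range(time_bins):
        ts = (k + (np.arange(n_quad) + 0.5) / n_quad) * (period / time_bins)
        for t in ts:
            mu = np.angle(np.exp(1j * omega * t))
            cdf = norm.cdf((edges[None, :] - mu + wraps) / sigma).sum(axis=0)
            joint[k] += np.diff(cdf)
    joint /= joint.sum()
    pt = joint.sum(1, keepdims=True)
    pp = joint.sum(0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / (pt @ pp)[nz])))
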