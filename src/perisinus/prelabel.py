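"""EM Gaussian-mixture pre-labeling of the peri-sinus mask.

Inside the first-stage mask the T2 intensity histogram is bimodal: the
hypointense sinus lumen versus the intermediate-intensity PSD (which at
this stage shares a label with the AGs).  A two-component 1-D Gaussian
mixture is fit by EM and each masked voxel takes the component with the
larger posterior; the lower-mean component is the lumen.  The "optimal
threshold" of the original pipeline is exactly this MAP decision
boundary — no separate thresholding step exists.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .volumes import LabelMap, Volume3D

__all__ = ["GaussianMixtureFit", "fit_gmm_em", "map_prelabel", "map_boundary"]

log = logging.getLogger(__name__)


@dataclass
class GaussianMixtureFit:
    k: int
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    loglik_trace: list = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0
    sd_floored: bool = False

    def posterior(self, x: np.ndarray) -> np.ndarray:
        """Component posteriors, shape ``x.shape + (k,)``."""
        x = np.asarray(x, dtype=np.float64)[..., None]
        logp = (np.log(self.weights)
                - 0.5 * np.log(2 * np.pi * self.sds**2)
                - 0.5 * ((x - self.means) / self.sds) ** 2)
        logp = logp - logsumexp(logp, axis=-1, keepdims=True)
        return np.exp(logp)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "weights": self.weights.tolist(),
            "converged": self.converged,
            "n_iter": self.n_iter,
            "final_loglik": self.loglik_trace[-1] if self.loglik_trace else None,
        }


def fit_gmm_em(intensities: np.ndarray, k: int = 2, init=None,
               tol: float = 1e-6, max_iter: int = 200,
               seed: int | None = None,
               sd_floor_frac: float = 1e-3) -> GaussianMixtureFit:
    """Fit a k-component 1-D Gaussian mixture by EM.

    Initialization is deterministic: component means at evenly spaced
    intensity percentiles (25th/75th for k = 2), equal weights, pooled
    sd — robust for the bimodal masked intensities this stage sees.
    ``init`` may override with ``(means, sds, weights)``.  Component sds
    are floored at ``sd_floor_frac`` of the intensity range; a floored
    fit is flagged.  The log-likelihood trace is non-decreasing (EM
    guarantee) and iteration stops when its relative change drops below
    ``tol``.
    """
    x = np.asarray(intensities, dtype=np.float64).ravel()
    if x.size < 2 * k:
        raise ValueError(f"need at least {2 * k} samples to fit {k} components")
    if not np.all(np.isfinite(x)):
        raise ValueError("intensities must be finite")

    rng = np.random.default_rng(seed)
    del rng  # deterministic percentile init; generator kept for API stability
    span = float(x.max() - x.min())
    sd_floor = max(sd_floor_frac * span, 1e-12)

    if k == 1:
        mu, sd = float(x.mean()), max(float(x.std()), sd_floor)
        ll = float(np.sum(-0.5 * np.log(2 * np.pi * sd**2)
                          - 0.5 * ((x - mu) / sd) ** 2))
        return GaussianMixtureFit(1, np.array([mu]), np.array([sd]),
                                  np.array([1.0]), [ll], True, 1)

    if init is not None:
        means, sds, weights = (np.asarray(a, dtype=np.float64) for a in init)
    else:
        qs = np.linspace(0, 100, k + 2)[1:-1] if k != 2 else np.array([25.0, 75.0])
        means = np.percentile(x, qs)
        sds = np.full(k, max(float(x.std()), sd_floor))
        weights = np.full(k, 1.0 / k)

    trace: list[float] = []
    converged = False
    floored = False
    n_it = 0
    for n_it in range(1, max_iter + 1):
        logp = (np.log(weights)[None, :]
                - 0.5 * np.log(2 * np.pi * sds**2)[None, :]
                - 0.5 * ((x[:, None] - means[None, :]) / sds[None, :]) ** 2)
        norm = logsumexp(logp, axis=1)
        trace.append(float(norm.sum()))
        resp = np.exp(logp - norm[:, None])
        nk = resp.sum(axis=0)
        weights = nk / x.size
        means = (resp * x[:, None]).sum(axis=0) / np.maximum(nk, 1e-300)
        var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) \
            / np.maximum(nk, 1e-300)
        sds = np.sqrt(var)
        if np.any(sds < sd_floor):
            floored = True
            sds = np.maximum(sds, sd_floor)
        if len(trace) >= 2:
            prev, cur = trace[-2], trace[-1]
            if abs(cur - prev) <= tol * (abs(prev) + 1e-300):
                converged = True
                break
    if floored:
        log.warning("GMM component collapse: sd floored at %.3g", sd_floor)
    return GaussianMixtureFit(k, means, sds, weights, trace, converged, n_it,
                              sd_floored=floored)


def map_boundary(fit: GaussianMixtureFit) -> float:
    """Closed-form two-Gaussian MAP decision boundary between the two
    components (equal-sd, equal-weight case: midpoint of the means)."""
    if fit.k != 2:
        raise ValueError("map_boundary is defined for k = 2")
    (m1, m2), (s1, s2), (w1, w2) = fit.means, fit.sds, fit.weights
    if abs(s1 - s2) < 1e-12:
        # linear discriminant
        if abs(m1 - m2) < 1e-12:
            return float(m1)
        return float((m1 + m2) / 2
                     + s1**2 * np.log(w1 / w2) / (m2 - m1))
    a = 1 / (2 * s2**2) - 1 / (2 * s1**2)
    b = m1 / s1**2 - m2 / s2**2
    c = m2**2 / (2 * s2**2) - m1**2 / (2 * s1**2) + np.log((w1 * s2) / (w2 * s1))
    disc = b**2 - 4 * a * c
    roots = np.roots([a, b, c]) if disc >= 0 else []
    lo, hi = sorted((m1, m2))
    for r in roots:
        if lo <= r <= hi:
            return float(r)
    return float((m1 + m2) / 2)


def map_prelabel(mask: LabelMap, v: Volume3D, fit: GaussianMixtureFit) -> LabelMap:
    """Assign PSD-vs-lumen pre-labels inside the peri-sinus mask by MAP.

    Component semantics are fixed by mean ordering, not component index:
    the lower-mean (T2-hypointense) component is the sinus lumen (code
    1), the higher-mean component is the PSD (code 2; AGs share this
    code at this stage).  Voxels with equal posteriors go to PSD.
    """
    if fit.n_iter == 0 or fit.k != 2:
        raise ValueError("map_prelabel needs a fitted 2-component mixture")
    if not mask.same_grid(v):
        raise ValueError("mask and volume are on different grids")
    m = np.asarray(mask.data) > 0
    out = np.zeros(mask.shape, dtype=np.int16)
    post = fit.posterior(np.asarray(v.data)[m])
    psd_comp = int(np.argmax(fit.means))
    is_psd = post[:, psd_comp] >= 0.5   # boundary ties resolve to PSD
    vals = np.where(is_psd, 2, 1).astype(np.int16)
    out[m] = vals
    return LabelMap(out, mask.spacing, mask.affine.copy(), mask.space_tag)
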