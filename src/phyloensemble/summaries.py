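"""Posterior summarization: modes, HPD intervals, pMCMC, contrasts, I2.

Conventions follow standard Bayesian mixed-model reporting: point estimates
are kernel-density posterior modes, intervals are 95% highest-posterior-
density intervals, significance of a contrast is the two-sided MCMC p value
(fraction of draws crossing zero, floored at one draw), and variance
components are expressed as I2 percentages of the total random variance --
with the logit link's distribution variance pi^2/3 entering the denominator
for binomial models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

__all__ = [
    "ContrastResult",
    "posterior_mode",
    "hpd_interval",
    "pmcmc",
    "level_contrast",
    "i2_partition",
]

LOGIT_DISTRIBUTION_VARIANCE = np.pi**2 / 3


@dataclass
class ContrastResult:
    """Summary of a posterior difference between two factor levels."""

    name: str
    posterior_mode: float
    hpd_low: float
    hpd_high: float
    pmcmc: float

    def __str__(self) -> str:
        return (
            f"{self.name}: {self.posterior_mode:.3g} "
            f"(CI {self.hpd_low:.3g} to {self.hpd_high:.3g}), "
            f"pMCMC = {self.pmcmc:.4g}"
        )


def posterior_mode(samples) -> float:
    """Argmax of a Gaussian KDE (Silverman bandwidth) over the sample points.

    Evaluating the density at the sample points themselves keeps the mode
    scale-free and deterministic. All-identical samples return that value.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        if x.size == 1:
            return float(x[0])
        raise ValueError("posterior_mode requires >= 2 samples")
    if np.ptp(x) == 0:
        return float(x[0])
    kde = gaussian_kde(x, bw_method="silverman")
    dens = kde(x)
    return float(x[np.argmax(dens)])


def hpd_interval(samples, prob: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(prob * N)`` samples."""
    if not 0 < prob < 1:
        raise ValueError("prob must be in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    k = int(np.ceil(prob * n))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1 + np.arange(n - k + 1)] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def pmcmc(samples) -> float:
    """Two-sided MCMC p value of a posterior sample against zero.

    ``2 * max(0.5/N, min(#positive, #negative)/N)``, capped at 1; the floor
    corresponds to a single draw on the minority side, so a chain of N draws
    can never report less than 1/N.
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("pmcmc requires >= 2 samples")
    nzero = int((x == 0).sum())  # ties split between the two sides
    npos = int((x > 0).sum()) + nzero / 2
    nneg = int((x < 0).sum()) + nzero / 2
    p = 2.0 * max(0.5 / n, min(npos, nneg) / n)
    return float(min(p, 1.0))


def pmcmc_one_sided(samples) -> float:
    """Literal one-sided reading: minority-side fraction, floored at 0.5/N."""
    x = np.asarray(samples, dtype=float)
    n = x.size
    npos = int((x > 0).sum())
    nneg = int((x < 0).sum())
    return float(max(0.5 / n, min(npos, nneg) / n))


def level_contrast(samples_a, samples_b, label: str = "a - b") -> ContrastResult:
    """Posterior summary of the draw-paired difference between two levels."""
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(
            f"contrast samples must be paired by draw ({a.shape} vs {b.shape})"
        )
    d = a - b
    lo, hi = hpd_interval(d)
    return ContrastResult(
        name=label,
        posterior_mode=posterior_mode(d),
        hpd_low=lo,
        hpd_high=hi,
        pmcmc=pmcmc(d),
    )


def i2_partition(variance_samples: dict, family: str) -> dict:
    """Percentage of total random variance attributable to each term (I2).

    Per draw, ``I2_i = V_i / (sum_j V_j + D) * 100`` where D is the link's
    distribution variance: 0 for gaussian, pi^2/3 for binomial-logit. The
    residual ("units") term must be present. Returns, per term, the posterior
    mode and 95% HPD interval of its I2 along with the per-draw values.
    """
    if family not in ("gaussian", "binomial-logit"):
        raise ValueError(f"unknown family: {family!r}")
    if "units" not in variance_samples:
        raise ValueError("variance samples must include the residual 'units' term")
    arrays = {k: np.asarray(v, dtype=float) for k, v in variance_samples.items()}
    lengths = {v.size for v in arrays.values()}
    if len(lengths) != 1:
        raise ValueError("variance samples must have equal lengths")
    D = 0.0 if family == "gaussian" else LOGIT_DISTRIBUTION_VARIANCE
    total = sum(arrays.values()) + D
    out = {}
    for name, v in arrays.items():
        i2 = v / total * 100.0
        lo, hi = hpd_interval(i2) if i2.size >= 10 else (float(i2.min()), float(i2.max()))
        mode = posterior_mode(i2) if i2.size >= 2 else float(i2[0])
        out[name] = {"mode": mode, "hpd_low": lo, "hpd_high": hi, "draws": i2}
    return out
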