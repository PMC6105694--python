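"""Closed-form mismatch-probability model for donor/recipient pairs.

For a peptide encoded by an allele at population frequency ``f`` under
Hardy-Weinberg equilibrium, the probability that a random unrelated pair is
mismatched (the recipient carries the encoding allele, the donor lacks it) is

    P_mm(f)     = f (1-f)^2 (2-f)            = u (1-u),  u = (1-f)^2

and for sibling pairs (one transmission per parent per child, no recombination)

    P_mm^sib(f) = (1-f)^2 f (4-f) / 4.

Both vanish at f = 0 and f = 1.  The unrelated model peaks at
f* = 1 - 1/sqrt(2) ~ 0.293 with P = 1/4; the sibling model at
f* = (7 - sqrt(33))/4 ~ 0.314 with P ~ 0.136.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq, minimize_scalar

RELATIONSHIPS = ("unrelated", "sibling")

#: closed-form argmax of the unrelated model: (1-f)^2 = 1/2
F_STAR_UNRELATED = 1.0 - 1.0 / math.sqrt(2.0)
#: closed-form argmax of the sibling model (root of the cubic derivative)
F_STAR_SIBLING = (7.0 - math.sqrt(33.0)) / 4.0


def _check_f(f):
    arr = np.asarray(f, dtype=float)
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValueError("allele frequency must lie in [0, 1]")
    return arr


def pmm_unrelated(f):
    """Mismatch probability f(1-f)^2(2-f) for an unrelated pair; accepts arrays."""
    arr = _check_f(f)
    out = arr * (1.0 - arr) ** 2 * (2.0 - arr)
    return float(out) if np.isscalar(f) or out.ndim == 0 else out


def pmm_sibling(f):
    """Mismatch probability (1-f)^2 f (4-f)/4 for a sibling pair; accepts arrays."""
    arr = _check_f(f)
    out = (1.0 - arr) ** 2 * arr * (4.0 - arr) / 4.0
    return float(out) if np.isscalar(f) or out.ndim == 0 else out


def pmm(f, relationship: str = "unrelated"):
    if relationship == "unrelated":
        return pmm_unrelated(f)
    if relationship == "sibling":
        return pmm_sibling(f)
    raise ValueError(f"unknown relationship {relationship!r}")


def pmm_extremum(relationship: str = "unrelated") -> tuple[float, float]:
    """(f*, P_max) of the chosen model, accurate to >= 6 decimals.

    Found numerically; the closed forms above serve as cross-checks in tests.
    """
    func = pmm_unrelated if relationship == "unrelated" else pmm_sibling
    if relationship not in RELATIONSHIPS:
        raise ValueError(f"unknown relationship {relationship!r}")
    res = minimize_scalar(lambda f: -func(f), bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-12})
    return float(res.x), float(-res.fun)


def pmm_frequency_window(relationship: str, threshold: float) -> tuple[float, float]:
    """The allele-frequency window (f_low, f_high) where P_mm(f) > threshold.

    The two roots of P(f) = threshold bracketing the maximum, to better than
    1e-10.  Raises when the threshold is not below the model's maximum.
    """
    func = pmm_unrelated if relationship == "unrelated" else pmm_sibling
    f_star, p_max = pmm_extremum(relationship)
    if not 0.0 < threshold < p_max:
        raise ValueError(f"empty window: threshold {threshold} not in (0, {p_max:.6f})")
    g = lambda f: func(f) - threshold
    f_low = brentq(g, 1e-15, f_star, xtol=1e-12)
    f_high = brentq(g, f_star, 1.0 - 1e-15, xtol=1e-12)
    return float(f_low), float(f_high)


def unrelated_window_closed_form(threshold: float) -> tuple[float, float]:
    """Closed-form window for the unrelated model via u(1-u) = threshold, u=(1-f)^2."""
    if not 0.0 < threshold < 0.25:
        raise ValueError("threshold must lie in (0, 0.25)")
    root = math.sqrt(1.0 - 4.0 * threshold)
    u_high = (1.0 + root) / 2.0
    u_low = (1.0 - root) / 2.0
    return 1.0 - math.sqrt(u_high), 1.0 - math.sqrt(u_low)


def saturation_probability(p: float, n: int):
    """Probability 1-(1-p)^n that a peptide with per-pair mismatch probability
    p is observed in at least one of n independent pairs."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValueError("p must lie in [0, 1]")
    if n < 0 or int(n) != n:
        raise ValueError("n must be a non-negative integer")
    safe = np.where(arr < 1.0, arr, 0.0)
    out = -np.expm1(n * np.log1p(-safe))
    out = np.where(arr >= 1.0, 1.0 if n > 0 else 0.0, out)
    return float(out) if np.isscalar(p) or out.ndim == 0 else out


_SPECTRA: dict[str, Callable[[float], float]] = {
    "uniform": lambda f: 1.0,
}


def _spectrum_density(spectrum) -> Callable[[float], float]:
    if callable(spectrum):
        return spectrum
    if spectrum == "uniform":
        return _SPECTRA["uniform"]
    if isinstance(spectrum, tuple) and spectrum and spectrum[0] == "truncated_1_over_f":
        f_min = float(spectrum[1])
        if not 0.0 < f_min < 1.0:
            raise ValueError("truncated 1/f spectrum requires 0 < f_min < 1")
        norm = math.log(1.0 / f_min)
        return lambda f: (1.0 / (f * norm)) if f >= f_min else 0.0
    raise ValueError(f"unknown spectrum {spectrum!r}")


def expected_fold_reduction(spectrum="uniform") -> float:
    """Ratio of spectrum-integrated mismatch expectations, unrelated over sibling.

    ``spectrum`` is "uniform", ("truncated_1_over_f", f_min), ("point", f), or a
    density callable on (0, 1).  For the uniform spectrum the exact value is
    (2/15)/(3/40) = 16/9 ~ 1.78; quadrature is used for general densities with
    relative tolerance 1e-10.
    """
    if isinstance(spectrum, tuple) and spectrum and spectrum[0] == "point":
        f = float(spectrum[1])
        denom = pmm_sibling(f)
        if denom == 0.0:
            raise ValueError("point spectrum at f with zero sibling mismatch probability")
        return pmm_unrelated(f) / denom
    phi = _spectrum_density(spectrum)
    eps = 1e-12
    norm, norm_err = quad(phi, eps, 1.0 - eps, epsrel=1e-10, limit=200)
    if not math.isfinite(norm) or norm <= 0.0:
        raise ValueError("spectrum is not normalizable on (0, 1)")
    num, _ = quad(lambda f: pmm_unrelated(f) * phi(f), eps, 1.0 - eps, epsrel=1e-10, limit=200)
    den, _ = quad(lambda f: pmm_sibling(f) * phi(f), eps, 1.0 - eps, epsrel=1e-10, limit=200)
    return num / den


def assign_pmm(
    urps: Sequence,
    relationship: str = "unrelated",
    *,
    therapeutic_thresholds: tuple[float, ...] = (0.1, 0.2),
) -> list:
    """Set ``pmm`` on classified URPs from their encoding allele frequency.

    ``therapeutic_tier`` is set to the highest threshold the URP's mismatch
    probability exceeds (None when below all tiers); the defaults mark the
    P_mm > 0.1 and P_mm > 0.2 regions.
    """
    tiers = sorted(therapeutic_thresholds)
    for urp in urps:
        f = urp.encoding_allele_frequency
        if f is None:
            raise ValueError(f"URP {urp.peptide} has no encoding allele frequency")
        urp.pmm = pmm(f, relationship)
        urp.therapeutic_tier = None
        for t in tiers:
            if urp.pmm > t:
                urp.therapeutic_tier = t
    return list(urps)
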