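"""Least-squares Gaussian expansions of Slater-type orbitals.

The minimal reference basis shipped with this package is an STO-6G-style
construction: each Slater orbital (with the standard molecular-optimized
minimal-basis exponents below) is expanded in six Gaussians by weighted
least squares on a radial grid.  This is the same recipe that defines the
classic STO-NG sets, re-derived in-package so the reference data has a
fully reproducible provenance; the shipped file is labelled synthetic
accordingly.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares

from .basis import p_cart_norm, s_norm
from .bse import ReferenceShell

__all__ = ["SLATER_ZETAS", "slater_radial", "fit_slater_expansion",
           "make_reference_shells"]

#: standard minimal-basis Slater exponents (molecular-optimized values)
SLATER_ZETAS: dict[str, dict[str, float]] = {
    "H": {"1s": 1.24},
    "He": {"1s": 1.69},
    "C": {"1s": 5.67, "2s": 1.72, "2p": 1.72},
    "N": {"1s": 6.67, "2s": 1.95, "2p": 1.95},
    "O": {"1s": 7.66, "2s": 2.25, "2p": 2.25},
}


def slater_radial(label: str, zeta: float, r: np.ndarray) -> np.ndarray:
    """Normalized Slater orbital amplitude along a ray.

    For "1s"/"2s" this is the full orbital value at radius r; for "2p" it is
    the amplitude along the lobe axis (i.e. the orbital value at (0, 0, r)).
    """
    r = np.asarray(r, dtype=float)
    if label == "1s":
        return np.sqrt(zeta ** 3 / np.pi) * np.exp(-zeta * r)
    if label == "2s":
        return np.sqrt(zeta ** 5 / (3.0 * np.pi)) * r * np.exp(-zeta * r)
    if label == "2p":
        return np.sqrt(zeta ** 5 / np.pi) * r * np.exp(-zeta * r)
    raise ValueError(f"unsupported shell label {label!r}")


def _gauss_amplitude(label: str, alphas: np.ndarray, coeffs: np.ndarray,
                     r: np.ndarray) -> np.ndarray:
    r2 = r * r
    if label.endswith("p"):
        radial = sum(c * p_cart_norm(a) * np.exp(-a * r2)
                     for a, c in zip(alphas, coeffs))
        return radial * r
    return sum(c * s_norm(a) * np.exp(-a * r2)
               for a, c in zip(alphas, coeffs))


def fit_slater_expansion(element: str, label: str, zeta: float,
                         n_gauss: int = 6) -> ReferenceShell:
    """Fit ``n_gauss`` normalized Gaussians to a Slater orbital.

    Weighted least squares in the 3D L2 norm (radial weight r^2 for s, r^4/3
    absorbed into the amplitude for p), on a fixed geometric radial grid; the
    initial exponents are an even-tempered ladder scaled by zeta^2, so the
    fit is deterministic.
    """
    r = np.geomspace(5e-4, 30.0 / zeta, 600)
    dr = np.gradient(r)
    w = r * r * dr
    if label.endswith("p"):
        w = w * r * r / 3.0
        target = slater_radial(label, zeta, r) / r  # radial factor f(r)

        def amp(alphas, coeffs):
            return sum(c * p_cart_norm(a) * np.exp(-a * r * r)
                       for a, c in zip(alphas, coeffs))
    else:
        target = slater_radial(label, zeta, r)

        def amp(alphas, coeffs):
            return sum(c * s_norm(a) * np.exp(-a * r * r)
                       for a, c in zip(alphas, coeffs))
    sw = np.sqrt(w)

    # even-tempered ladder: geometric from ~0.06 to ~25 for zeta = 1 (1s);
    # shells with a radial node or higher n start lower
    top = 25.0 if label == "1s" else 8.0
    bot = 0.06 if label == "1s" else 0.02
    a0 = zeta ** 2 * np.geomspace(bot, top, n_gauss)[::-1]

    def design(alphas):
        if label.endswith("p"):
            return np.stack([p_cart_norm(a) * np.exp(-a * r * r)
                             for a in alphas], axis=1)
        return np.stack([s_norm(a) * np.exp(-a * r * r) for a in alphas],
                        axis=1)

    c0, *_ = np.linalg.lstsq(design(a0) * sw[:, None], target * sw, rcond=None)

    def resid(x):
        alphas = np.exp(x[:n_gauss])
        coeffs = x[n_gauss:]
        return (amp(alphas, coeffs) - target) * sw

    x0 = np.concatenate([np.log(a0), c0])
    res = least_squares(resid, x0, method="trf", xtol=1e-15, ftol=1e-15,
                        gtol=1e-15, max_nfev=20000)
    alphas = np.exp(res.x[:n_gauss])
    coeffs = res.x[n_gauss:]
    order = np.argsort(alphas)[::-1]
    alphas, coeffs = alphas[order], coeffs[order]
    # normalize the contraction to unit self-overlap
    if label.endswith("p"):
        nrm = p_cart_norm(alphas)
        asum = alphas[:, None] + alphas[None, :]
        s = np.einsum("a,b,ab->", coeffs * nrm, coeffs * nrm,
                      (np.pi / asum) ** 1.5 / (2.0 * asum))
    else:
        nrm = s_norm(alphas)
        asum = alphas[:, None] + alphas[None, :]
        s = np.einsum("a,b,ab->", coeffs * nrm, coeffs * nrm,
                      (np.pi / asum) ** 1.5)
    coeffs = coeffs / np.sqrt(s)
    return ReferenceShell(element, label, alphas, coeffs, zeta=zeta)


def make_reference_shells(elements=None, n_gauss: int = 6
                          ) -> dict[str, list[ReferenceShell]]:
    """Build the full reference shell table for the supported elements."""
    elements = list(elements or SLATER_ZETAS)
    out: dict[str, list[ReferenceShell]] = {}
    for el in elements:
        if el not in SLATER_ZETAS:
            raise KeyError(f"no Slater exponents for element {el!r}")
        out[el] = [fit_slater_expansion(el, label, zeta, n_gauss)
                   for label, zeta in SLATER_ZETAS[el].items()]
    return out
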