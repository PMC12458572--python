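"""Independent numerical oracles used by the test suite.

These deliberately avoid the closed forms under test: overlaps and kinetic
integrals are done by dense real-space quadrature; the Coulomb kernel is
reduced with elementary Gaussian algebra (completing the square) to a 1D
integral that is evaluated adaptively — no error-function identity is
used anywhere here.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad


class Primitive:
    """A Gaussian primitive ``c * (r_axis - A_axis) * exp(-a |r-A|^2)``.

    ``axis`` is None for s-type or 0/1/2 for a Cartesian p monomial.
    """

    def __init__(self, coef, alpha, center, axis=None):
        self.coef = float(coef)
        self.alpha = float(alpha)
        self.center = np.asarray(center, float).reshape(3)
        self.axis = axis

    def evaluate(self, pts):
        d = pts - self.center
        v = self.coef * np.exp(-self.alpha * np.sum(d * d, axis=1))
        if self.axis is not None:
            v = v * d[:, self.axis]
        return v

    def laplacian(self, pts):
        """Analytic Laplacian (elementary calculus; no integral identities)."""
        d = pts - self.center
        r2 = np.sum(d * d, axis=1)
        g = np.exp(-self.alpha * r2)
        a = self.alpha
        if self.axis is None:
            return self.coef * (4 * a * a * r2 - 6 * a) * g
        x = d[:, self.axis]
        return self.coef * x * (4 * a * a * r2 - 10 * a) * g


def reference_shell_primitives(shell, center, axis=2):
    """Expand a normalized reference contraction into Primitive objects."""
    from lobehf.basis import p_cart_norm, s_norm
    prims = []
    for a, c in zip(shell.exponents, shell.coefficients):
        if shell.is_p:
            prims.append(Primitive(c * p_cart_norm(a), a, center, axis))
        else:
            prims.append(Primitive(c * s_norm(a), a, center, None))
    return prims


def lobe_orbital_primitives(orbital):
    return [Primitive(p.coefficient, p.exponent, p.center, None)
            for p in orbital.primitives]


def _axis_grid(pa: Primitive, pb: Primitive, k: int) -> np.ndarray:
    """1D quadrature grid along axis k covering both primitive supports."""
    h = 0.25 / np.sqrt(pa.alpha + pb.alpha)
    reach = 9.0 / np.sqrt(min(pa.alpha, pb.alpha))
    lo = min(pa.center[k], pb.center[k]) - reach
    hi = max(pa.center[k], pb.center[k]) + reach
    return np.arange(lo, hi + h / 2, h)


def _axis_factor(prim: Primitive, k: int, u: np.ndarray,
                 deriv2: bool = False) -> np.ndarray:
    """Per-axis factor of a primitive (or of its second axis-derivative).

    Gaussian-monomial primitives are separable, so 3D integrals of pair
    products reduce to products of 1D integrals; the second derivatives
    used for the kinetic oracle are elementary calculus.
    """
    x = u - prim.center[k]
    a = prim.alpha
    g = np.exp(-a * x * x)
    has_monomial = prim.axis == k
    if not deriv2:
        return (x if has_monomial else 1.0) * g
    if has_monomial:
        return (4 * a * a * x ** 3 - 6 * a * x) * g
    return (4 * a * a * x * x - 2 * a) * g


def _pair_quadrature(pa: Primitive, pb: Primitive, use_laplacian=False):
    """<pa|pb> (or <pa|lap pb>) via per-axis 1D Riemann sums.

    Trapezoidal sampling of Gaussians converges exponentially, so each 1D
    factor reaches ~1e-13 relative without any closed-form identity.
    """
    if not use_laplacian:
        val = pa.coef * pb.coef
        for k in range(3):
            u = _axis_grid(pa, pb, k)
            h = u[1] - u[0]
            val *= float(np.sum(_axis_factor(pa, k, u)
                                * _axis_factor(pb, k, u)) * h)
        return val
    total = 0.0
    for d_axis in range(3):
        term = pa.coef * pb.coef
        for k in range(3):
            u = _axis_grid(pa, pb, k)
            h = u[1] - u[0]
            term *= float(np.sum(
                _axis_factor(pa, k, u)
                * _axis_factor(pb, k, u, deriv2=(k == d_axis))) * h)
        total += term
    return total


def overlap_quadrature(prims_a, prims_b) -> float:
    """<a|b> summed over primitive pairs via separable 1D quadrature."""
    return sum(_pair_quadrature(pa, pb)
               for pa in prims_a for pb in prims_b)


def kinetic_quadrature(prims_a, prims_b) -> float:
    """<a| -lap/2 |b> with analytic per-axis second derivatives."""
    return -0.5 * sum(_pair_quadrature(pa, pb, use_laplacian=True)
                      for pa in prims_a for pb in prims_b)


def _axis_pair_integral(a: float, c: float, A: float, C: float,
                        s2: float) -> float:
    """Closed 2D Gaussian integral along one axis for the s-transform.

    integral dx dx' exp(-a (x-A)^2 - c (x'-C)^2 - s2 (x-x')^2), evaluated
    by completing the square (2x2 quadratic form).
    """
    M = np.array([[a + s2, -s2], [-s2, c + s2]])
    det = M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
    b = np.array([a * A, c * C])
    const = a * A * A + c * C * C
    sol = np.linalg.solve(M, b)
    expo = b @ sol - const
    return np.pi / np.sqrt(det) * np.exp(expo)


def eri_quadrature(alpha, centers, coeffs=None) -> float:
    """(g_a g_b | g_c g_d) via the 1/r = (2/sqrt(pi)) int exp(-s^2 r^2) ds
    transform: three analytic per-axis Gaussian integrals and one adaptive
    1D integral over the substitution u = s / sqrt(1 + s^2).

    ``alpha``: 4 exponents; ``centers``: (4, 3); ``coeffs``: 4 prefactors.
    """
    alpha = np.asarray(alpha, float)
    centers = np.asarray(centers, float).reshape(4, 3)
    coeffs = np.ones(4) if coeffs is None else np.asarray(coeffs, float)
    aa, ab, ac, ad = alpha
    # combine same-electron Gaussians (completing the square per pair)
    p = aa + ab
    q = ac + ad
    P = (aa * centers[0] + ab * centers[1]) / p
    Q = (ac * centers[2] + ad * centers[3]) / q
    pre = float(np.prod(coeffs)) * np.exp(
        -aa * ab / p * np.sum((centers[0] - centers[1]) ** 2)
        - ac * ad / q * np.sum((centers[2] - centers[3]) ** 2))

    def integrand(u):
        # s = u / sqrt(1 - u^2) maps (0, 1) -> (0, inf)
        s = u / np.sqrt(1.0 - u * u)
        s2 = s * s
        val = 1.0
        for k in range(3):
            val *= _axis_pair_integral(p, q, P[k], Q[k], s2)
        jac = 1.0 / (1.0 - u * u) ** 1.5
        return val * jac

    integral, err = quad(integrand, 0.0, 1.0, epsabs=1e-14, epsrel=1e-10,
                         limit=200)
    return pre * 2.0 / np.sqrt(np.pi) * integral


def nuclear_attraction_quadrature(alpha_a, center_a, alpha_b, center_b,
                                  nucleus, charge) -> float:
    """<g_a | -Z/|r-C| | g_b> via the same s-transform (limit q -> inf)."""
    p = alpha_a + alpha_b
    P = (alpha_a * np.asarray(center_a) + alpha_b * np.asarray(center_b)) / p
    pre = np.exp(-alpha_a * alpha_b / p
                 * np.sum((np.asarray(center_a) - np.asarray(center_b)) ** 2))

    def integrand(u):
        s = u / np.sqrt(1.0 - u * u)
        s2 = s * s
        val = 1.0
        for k in range(3):
            # integral dx exp(-p (x-P)^2 - s2 (x-C)^2) with C the nucleus
            a_eff = p * s2 / (p + s2)
            val *= np.sqrt(np.pi / (p + s2)) * np.exp(
                -a_eff * (P[k] - nucleus[k]) ** 2)
        jac = 1.0 / (1.0 - u * u) ** 1.5
        return val * jac

    integral, _ = quad(integrand, 0.0, 1.0, epsabs=1e-14, epsrel=1e-10,
                       limit=200)
    return -charge * pre * 2.0 / np.sqrt(np.pi) * integral


def erf_series(x: float, terms: int = 200) -> float:
    """High-precision erf by Taylor series (small x) or continued
    complement (large x), independent of any library erf."""
    if x > 2.0:
        # complement via numerical integration of the tail; the alternating
        # Taylor series cancels catastrophically for large x
        tail, _ = quad(lambda t: np.exp(-t * t), x, np.inf,
                       epsabs=1e-22, epsrel=1e-14)
        return 1.0 - 2.0 / np.sqrt(np.pi) * tail
    acc = 0.0
    term = x
    for n in range(terms):
        acc += term / (2 * n + 1)
        term *= -x * x / (n + 1)
        if abs(term) < 1e-20:
            break
    return 2.0 / np.sqrt(np.pi) * acc


def _singles_matrices(scf_result, eris_dense):
    C = scf_result.mo_coefficients
    e = scf_result.orbital_energies
    n_occ = scf_result.n_occupied
    n = len(e)
    mo = np.einsum("pi,qj,rk,sl,pqrs->ijkl", C, C, C, C, eris_dense,
                   optimize=True)
    pairs = [(i, a) for i in range(n_occ) for a in range(n_occ, n)]
    dim = len(pairs)
    A = np.zeros((dim, dim))
    B = np.zeros((dim, dim))
    for xi, (i, a) in enumerate(pairs):
        for xj, (j, b) in enumerate(pairs):
            A[xi, xj] = 2.0 * mo[i, a, j, b] - mo[i, j, a, b]
            if i == j and a == b:
                A[xi, xj] += e[a] - e[i]
            B[xi, xj] = 2.0 * mo[i, a, j, b] - mo[i, b, j, a]
    return A, B


def cis_lowest_excitation(scf_result, eris_dense: np.ndarray) -> float:
    """Lowest singlet CIS/TDA excitation (Hartree): eigenvalue of A."""
    A, _ = _singles_matrices(scf_result, eris_dense)
    return float(np.linalg.eigvalsh(A)[0])


def tdhf_lowest_excitation(scf_result, eris_dense: np.ndarray) -> float:
    """Lowest singlet linear-response TDHF (RPA) excitation (Hartree).

    Solves the Casida problem omega^2 = eig((A - B)(A + B)); this is the
    excitation the real-time propagation probes, built independently from
    the same SCF ground state.
    """
    A, B = _singles_matrices(scf_result, eris_dense)
    w2 = np.linalg.eigvals((A - B) @ (A + B))
    return float(np.sqrt(np.sort(w2.real)[0]))


def dense_eri_tensor(eris) -> np.ndarray:
    """Expand a canonical ScreenedERISet into the full (n,n,n,n) tensor."""
    n = eris.n_bf
    out = np.zeros((n, n, n, n))
    vals = eris.weighted_values()
    for (i, j, k, l), v in zip(eris.quads, vals):
        for (a, b) in ((i, j), (j, i)):
            for (c, d) in ((k, l), (l, k)):
                out[a, b, c, d] = v
                out[c, d, a, b] = v
    return out
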