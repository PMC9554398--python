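"""Basis functions of the quantile order p used by coefficient modelling.

Each quantile-regression coefficient is written as a linear combination of
known functions of p on (0, 1).  The required set comprises the shifted
Legendre polynomials (orthogonal on [0, 1]; numerically preferable to raw
monomials while spanning the same space), the tail logarithm -log(1-p), the
left-tail logarithm log(p), and power roots p**a.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy.special import eval_sh_legendre

__all__ = [
    "BasisFunction",
    "legendre_shifted_coeffs",
    "legendre",
    "minus_log1mp",
    "log_p",
    "root",
    "poly_basis",
    "monomial_to_shifted_legendre",
]


@dataclass(frozen=True)
class BasisFunction:
    """One basis function b_j(p), evaluable on the open interval (0, 1).

    kind is one of ``legendre_shifted`` (with ``degree``), ``minus_log1mp``,
    ``log_p`` or ``root`` (with ``power``).
    """

    kind: str
    degree: int = 0
    power: float = 0.5

    _KINDS = ("legendre_shifted", "minus_log1mp", "log_p", "root")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown basis kind {self.kind!r}")
        if self.kind == "legendre_shifted" and self.degree < 0:
            raise ValueError("Legendre degree must be >= 0")
        if self.kind == "root" and self.power <= 0:
            raise ValueError("root power must be positive")

    def __call__(self, p):
        p = np.asarray(p, dtype=float)
        if np.any(p <= 0.0) or np.any(p >= 1.0):
            raise ValueError("basis functions are defined on the open interval (0, 1)")
        if self.kind == "legendre_shifted":
            return eval_sh_legendre(self.degree, p)
        if self.kind == "minus_log1mp":
            return -np.log1p(-p)
        if self.kind == "log_p":
            return np.log(p)
        return p ** self.power

    def label(self) -> str:
        if self.kind == "legendre_shifted":
            return f"legendre{self.degree}"
        if self.kind == "minus_log1mp":
            return "-log(1-p)"
        if self.kind == "log_p":
            return "log(p)"
        return f"p^{self.power}"

    def to_dict(self) -> dict:
        d = {"kind": self.kind}
        if self.kind == "legendre_shifted":
            d["degree"] = self.degree
        elif self.kind == "root":
            d["power"] = self.power
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BasisFunction":
        return cls(kind=d["kind"], degree=int(d.get("degree", 0)),
                   power=float(d.get("power", 0.5)))


def legendre(degree: int) -> BasisFunction:
    return BasisFunction("legendre_shifted", degree=degree)


def minus_log1mp() -> BasisFunction:
    return BasisFunction("minus_log1mp")


def log_p() -> BasisFunction:
    return BasisFunction("log_p")


def root(power: float) -> BasisFunction:
    return BasisFunction("root", power=power)


def poly_basis(r: int) -> list[BasisFunction]:
    """Shifted Legendre polynomials of degrees 0..r inclusive (r+1 terms)."""
    return [legendre(j) for j in range(r + 1)]


def legendre_shifted_coeffs(degree: int) -> np.ndarray:
    """Monomial coefficients (constant first) of the shifted Legendre polynomial.

    The degree-j shifted Legendre polynomial is P_j(2p - 1); e.g. degree 1 is
    2p - 1 and degree 2 is 6p^2 - 6p + 1.
    """
    if degree < 0:
        raise ValueError("degree must be non-negative")
    if degree > 12:
        raise ValueError("degrees above 12 are numerically unreliable in the monomial basis")
    # Exact closed form: Ptilde_j(p) = sum_k (-1)^(j+k) C(j,k) C(j+k,k) p^k.
    j = degree
    return np.array(
        [(-1) ** (j + k) * comb(j, k) * comb(j + k, k) for k in range(j + 1)],
        dtype=float,
    )


def monomial_to_shifted_legendre(mono_coeffs) -> np.ndarray:
    """Re-express a polynomial sum_j a_j p^j in the shifted Legendre basis.

    Returns c with sum_j c_j * Ptilde_j(p) equal to the input polynomial;
    used to translate human-readable monomial curves into the fitting basis.
    """
    a = np.asarray(mono_coeffs, dtype=float)
    r = a.size - 1
    M = np.zeros((r + 1, r + 1))
    for j in range(r + 1):
        M[: j + 1, j] = legendre_shifted_coeffs(j)
    return np.linalg.solve(M, a)
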