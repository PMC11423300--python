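"""Structure factors, the sphere form factor, and simulated SAXS curves.

For monodisperse spheres the scattered intensity factorizes as
I(q) = scale * P(q) * S(q) + background, with the structure factor
obtained from the radial distribution function through

    S(q) = 1 + 4 pi n_p * integral_0^{r_max} [g(r) - 1] sin(qr)/(qr) r^2 dr

evaluated by trapezoidal quadrature over the RDF bins.  Real-space
lengths are nm; q is stored in 1/Angstrom (the SAXS file convention) and
converted internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import q_in_nm_inv, DEFAULT_DIAMETER_NM
from .mc import RDF

__all__ = [
    "SAXSCurve",
    "make_q_grid",
    "structure_factor",
    "sphere_form_factor",
    "intensity",
]

#: The experimental grid: 225 points covering 0.012-0.501 1/Angstrom.
DEFAULT_Q_MIN = 0.012
DEFAULT_Q_MAX = 0.501
DEFAULT_N_Q = 225


@dataclass
class SAXSCurve:
    """A 1-D scattering curve on a fixed q grid.

    ``q`` in 1/Angstrom (strictly increasing), ``intensity`` positive in
    arbitrary units, optional per-point uncertainty ``sigma`` and, for
    synthetic curves, the generating ``labels`` (z_eff, kappa_inv).
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    labels: tuple[float, float] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.shape != self.intensity.shape:
            raise ValueError("q and intensity must have the same length")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity <= 0):
            raise ValueError("intensity must be finite and positive")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma must match the q grid")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive where present")

    def __len__(self) -> int:
        return self.q.size


def make_q_grid(q_min: float = DEFAULT_Q_MIN, q_max: float = DEFAULT_Q_MAX,
                n: int = DEFAULT_N_Q, spacing: str = "linear") -> np.ndarray:
    """Strictly increasing q grid in 1/Angstrom (linear by default)."""
    if not q_min < q_max:
        raise ValueError("need q_min < q_max")
    if n < 2:
        raise ValueError("need at least 2 grid points")
    if spacing == "linear":
        return np.linspace(q_min, q_max, n)
    if spacing == "log":
        if q_min <= 0:
            raise ValueError("log spacing requires q_min > 0")
        return np.geomspace(q_min, q_max, n)
    raise ValueError(f"unknown spacing {spacing!r}")


def structure_factor(rdf: RDF, q) -> np.ndarray:
    """S(q) from g(r) by the sine-transform quadrature above.

    ``q`` in 1/Angstrom (may contain 0: the sinc limit applies), RDF bins
    in nm.  S -> 1 as q -> inf and is finite everywhere.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    q_nm = q_in_nm_inv(q)
    r = rdf.r_centers
    h = rdf.g_values - 1.0
    # sin(x)/x with the x -> 0 limit handled by np.sinc
    kernel = np.sinc(np.outer(q_nm, r) / np.pi)
    integrand = kernel * (h * r * r)
    integral = np.trapezoid(integrand, r, axis=1)
    return 1.0 + 4.0 * np.pi * rdf.n_p * integral


def sphere_form_factor(q, diameter: float = DEFAULT_DIAMETER_NM) -> np.ndarray:
    """Normalized form factor of a homogeneous sphere, P(0) = 1.

    P(q) = [3 (sin(qR) - qR cos(qR)) / (qR)^3]^2 with R = diameter/2;
    ``q`` in 1/Angstrom, ``diameter`` in nm.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    q = np.atleast_1d(np.asarray(q, dtype=float))
    x = q_in_nm_inv(q) * diameter / 2.0
    amp = np.ones_like(x)
    small = np.abs(x) < 1e-4
    xs = np.where(small, 1.0, x)
    amp = np.where(small,
                   1.0 - x * x / 10.0,  # series limit near x = 0
                   3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs ** 3)
    return amp * amp


def intensity(p_of_q: np.ndarray, s_of_q: np.ndarray, q: np.ndarray,
              scale: float = 1.0, background: float = 0.0,
              sigma: np.ndarray | None = None,
              labels: tuple[float, float] | None = None,
              metadata: dict | None = None) -> SAXSCurve:
    """Compose I(q) = scale * P(q) * S(q) + background into a SAXSCurve."""
    p_of_q = np.asarray(p_of_q, dtype=float)
    s_of_q = np.asarray(s_of_q, dtype=float)
    q = np.asarray(q, dtype=float)
    if not (p_of_q.shape == s_of_q.shape == q.shape):
        raise ValueError("P(q), S(q) and q must share one grid")
    i_of_q = scale * p_of_q * s_of_q + background
    return SAXSCurve(q, i_of_q, sigma=sigma, labels=labels,
                     metadata=metadata or {})
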