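"""Closed-form visual pigment absorbance templates and oil droplet filters.

The pigment template is the vitamin-A1 (rhodopsin-family) nomogram of
Govardovskii et al. (2000), *In search of the visual pigment template*,
Vis. Neurosci. 17:509-528: an alpha band parameterized by ``lambda_max``
plus a Gaussian beta band.  The template is renormalized so that the
fractional absorbance at the nominal ``lambda_max`` equals 1.

The long-wavelength (right-hand) limb of the template is strictly
monotone, which makes the forward map invertible: given a fractional
absorbance observed at a wavelength on the long limb, there is a unique
``lambda_max`` whose template passes through that point.
:func:`invert_long_limb` recovers it by bracketed bisection.

Oil droplet cut-off filters use the conventional exponentiated-exponential
(Gompertz) transmittance sigmoid parameterized by a mid-point wavelength
and slope, with the mid-point derived from the Lipetz cut-off wavelength
by a configurable linear map.

All wavelengths are in nm.
"""
from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, EstimationError

# A1 template shape constants, transcribed from Govardovskii et al. (2000),
# eqs. 1-2 (alpha band) and 3-5a/5b (beta band).  Kept in one table so they
# can be audited and exported; nothing else in the package hard-codes them.
A1_TEMPLATE_CONSTANTS: dict[str, float] = {
    "alpha_A": 69.7,
    "alpha_B": 28.0,
    "alpha_C": -14.9,
    "alpha_D": 0.674,
    "alpha_b": 0.922,
    "alpha_c": 1.104,
    # a = a0 + a1 * exp(-(lambda_max - a2)^2 / a3)
    "alpha_a0": 0.8795,
    "alpha_a1": 0.0459,
    "alpha_a2": 300.0,
    "alpha_a3": 11940.0,
    "beta_A": 0.26,
    # lambda_m_beta = m0 + m1 * lambda_max
    "beta_m0": 189.0,
    "beta_m1": 0.315,
    # bandwidth b_beta = b0 + b1 * lambda_max
    "beta_b0": -40.5,
    "beta_b1": 0.195,
}

LAMBDA_MAX_RANGE = (350.0, 620.0)
WAVELENGTH_RANGE = (330.0, 800.0)
#: lambda_max search interval used by the long-limb inversion.
INVERSION_SEARCH_RANGE = (300.0, 700.0)


def constants_table() -> str:
    """Return the template constants as a delimited-text table (TSV)."""
    buf = io.StringIO()
    buf.write("constant\tvalue\n")
    for key, value in A1_TEMPLATE_CONSTANTS.items():
        buf.write(f"{key}\t{value}\n")
    return buf.getvalue()


def export_constants(path) -> None:
    """Write the template constants table to ``path`` for audit."""
    with open(path, "w") as fh:
        fh.write(constants_table())


@dataclass(frozen=True)
class PigmentTemplate:
    """A1 visual pigment template pinned to one ``lambda_max``."""

    lambda_max: float
    include_beta: bool = True
    chromophore: str = "A1"

    def __post_init__(self):
        lo, hi = LAMBDA_MAX_RANGE
        if not (lo <= self.lambda_max <= hi):
            raise DomainError(
                f"lambda_max={self.lambda_max} outside supported range [{lo}, {hi}] nm"
            )
        if self.chromophore != "A1":
            raise DomainError(f"unsupported chromophore {self.chromophore!r}; only A1")

    def __call__(self, wavelength):
        return pigment_absorbance(self, wavelength)


def _raw_absorbance(lambda_max, wavelength, include_beta: bool = True):
    """Unnormalized alpha(+beta) absorbance; vectorized, no range checks."""
    c = A1_TEMPLATE_CONSTANTS
    lambda_max = np.asarray(lambda_max, dtype=float)
    wavelength = np.asarray(wavelength, dtype=float)
    x = lambda_max / wavelength
    a = c["alpha_a0"] + c["alpha_a1"] * np.exp(
        -((lambda_max - c["alpha_a2"]) ** 2) / c["alpha_a3"]
    )
    alpha = 1.0 / (
        np.exp(c["alpha_A"] * (a - x))
        + np.exp(c["alpha_B"] * (c["alpha_b"] - x))
        + np.exp(c["alpha_C"] * (c["alpha_c"] - x))
        + c["alpha_D"]
    )
    if not include_beta:
        return alpha
    lam_beta = c["beta_m0"] + c["beta_m1"] * lambda_max
    b_beta = c["beta_b0"] + c["beta_b1"] * lambda_max
    beta = c["beta_A"] * np.exp(-(((wavelength - lam_beta) / b_beta) ** 2))
    return alpha + beta


def pigment_absorbance(template: PigmentTemplate | float, wavelength,
                       include_beta: bool | None = None):
    """Fractional absorbance of the template at ``wavelength``.

    Normalized so the value at the nominal ``lambda_max`` is exactly 1.
    Accepts a :class:`PigmentTemplate` or a bare ``lambda_max``; wavelength
    may be a scalar or array.
    """
    if isinstance(template, PigmentTemplate):
        lambda_max = template.lambda_max
        if include_beta is None:
            include_beta = template.include_beta
    else:
        lambda_max = float(template)
        if include_beta is None:
            include_beta = True
        lo, hi = LAMBDA_MAX_RANGE
        if not (lo <= lambda_max <= hi):
            raise DomainError(
                f"lambda_max={lambda_max} outside supported range [{lo}, {hi}] nm"
            )
    wl = np.asarray(wavelength, dtype=float)
    lo, hi = WAVELENGTH_RANGE
    if np.any(wl < lo) or np.any(wl > hi):
        raise DomainError(
            f"wavelength outside supported range [{lo}, {hi}] nm"
        )
    peak = _raw_absorbance(lambda_max, lambda_max, include_beta)
    out = _raw_absorbance(lambda_max, wl, include_beta) / peak
    if np.isscalar(wavelength) or np.ndim(wavelength) == 0:
        return float(out)
    return out


def _normalized_eval(lambda_max, wavelength, include_beta: bool):
    """Vectorized normalized template evaluation without range checks.

    Used by the inversion routines, which must probe lambda_max values
    outside the public supported range while bisecting.
    """
    peak = _raw_absorbance(lambda_max, lambda_max, include_beta)
    return _raw_absorbance(lambda_max, wavelength, include_beta) / peak


def _vector_bisect(func, lo, hi, tol: float, max_iter: int = 80):
    """Vectorized bisection for a function increasing in its argument."""
    lo = np.array(lo, dtype=float, copy=True)
    hi = np.array(hi, dtype=float, copy=True)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        up = func(mid) < 0.0
        lo = np.where(up, mid, lo)
        hi = np.where(up, hi, mid)
        if np.all(hi - lo < tol):
            break
    return 0.5 * (lo + hi)


def invert_long_limb(fraction, wavelength, *, fraction_bounds=(0.05, 0.95),
                     search_range=INVERSION_SEARCH_RANGE, tol: float = 0.001,
                     include_beta: bool = True):
    """Recover ``lambda_max`` from a fractional absorbance on the long limb.

    Solves ``template(lambda_max)(wavelength) == fraction`` for the unique
    root with ``lambda_max < wavelength`` (the long-wavelength limb branch)
    by bracketed bisection; the forward map is strictly increasing in
    ``lambda_max`` there.

    Parameters
    ----------
    fraction : float or array
        Fractional absorbance, strictly inside ``fraction_bounds``.
    wavelength : float or array
        Wavelength (nm) at which the fraction was observed.

    Raises
    ------
    EstimationError
        If a fraction is outside the configured bounds or no root exists
        inside ``search_range``.
    """
    frac = np.atleast_1d(np.asarray(fraction, dtype=float))
    wl = np.atleast_1d(np.asarray(wavelength, dtype=float))
    frac, wl = np.broadcast_arrays(frac, wl)
    lo_b, hi_b = fraction_bounds
    if np.any(frac <= lo_b) or np.any(frac >= hi_b):
        bad = frac[(frac <= lo_b) | (frac >= hi_b)]
        raise EstimationError(
            f"fraction(s) {bad} outside open bounds ({lo_b}, {hi_b})"
        )
    lo = np.full(frac.shape, search_range[0])
    hi = np.minimum(wl, search_range[1])

    def g(m):
        return _normalized_eval(m, wl, include_beta) - frac

    glo, ghi = g(lo), g(hi)
    if np.any(glo >= 0.0) or np.any(ghi <= 0.0):
        raise EstimationError(
            "no long-limb root bracketed in search interval "
            f"[{search_range[0]}, {search_range[1]}] nm"
        )
    root = _vector_bisect(g, lo, hi, tol)
    if np.isscalar(fraction) and np.isscalar(wavelength):
        return float(root[0])
    return root


def invert_short_branch(fraction, wavelength, *, search_range=INVERSION_SEARCH_RANGE,
                        tol: float = 0.001, include_beta: bool = True):
    """Recover ``lambda_max`` for a point on the short-wavelength side.

    Mirror of :func:`invert_long_limb` on the branch ``lambda_max >
    wavelength``, where the forward map is decreasing in ``lambda_max``.
    This realizes the single-point least-squares template placement used
    for peak-centred points: when a root exists the squared deviation at
    that wavelength is exactly zero there.
    """
    frac = np.atleast_1d(np.asarray(fraction, dtype=float))
    wl = np.atleast_1d(np.asarray(wavelength, dtype=float))
    frac, wl = np.broadcast_arrays(frac, wl)
    if np.any(frac <= 0.0) or np.any(frac >= 1.0):
        raise EstimationError("fraction must lie strictly in (0, 1)")
    lo = np.array(wl, copy=True)
    hi = np.full(frac.shape, float(search_range[1]))

    def g(m):
        # negated: decreasing branch -> make it increasing for the bisector
        return frac - _normalized_eval(m, wl, include_beta)

    glo, ghi = g(lo), g(hi)
    if np.any(glo >= 0.0) or np.any(ghi <= 0.0):
        raise EstimationError(
            "no short-branch root bracketed in search interval "
            f"[{wl.min()}, {search_range[1]}] nm"
        )
    root = _vector_bisect(g, lo, hi, tol)
    if np.isscalar(fraction) and np.isscalar(wavelength):
        return float(root[0])
    return root


@dataclass(frozen=True)
class DropletFilter:
    """Long-pass oil droplet transmittance filter.

    ``T(lambda) = exp(-exp(-b_mid * (lambda - lambda_mid)))`` — the
    conventional exponentiated-exponential cut-off sigmoid.
    """

    lambda_cut: float
    lambda_mid: float
    b_mid: float

    def __post_init__(self):
        for name in ("lambda_cut", "lambda_mid", "b_mid"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise DomainError(f"{name} must be finite, got {v}")
        if not (330.0 <= self.lambda_cut <= 700.0):
            raise DomainError(
                f"lambda_cut={self.lambda_cut} outside supported range [330, 700] nm"
            )
        if self.b_mid <= 0:
            raise DomainError(f"b_mid must be positive, got {self.b_mid}")

    def __call__(self, wavelength):
        return droplet_transmittance(self, wavelength)


def droplet_filter_from_cut(lambda_cut: float, *, mid_offset: float = 10.0,
                            mid_slope: float = 1.0, b_mid: float = 0.08) -> DropletFilter:
    """Build a :class:`DropletFilter` from a cut-off wavelength.

    ``lambda_mid = mid_slope * lambda_cut + mid_offset`` (a configurable
    linear map; the default places the half-transmittance point 10 nm
    long of the cut-off).
    """
    return DropletFilter(
        lambda_cut=float(lambda_cut),
        lambda_mid=mid_slope * float(lambda_cut) + mid_offset,
        b_mid=b_mid,
    )


def droplet_transmittance(filt: DropletFilter, wavelength):
    """Transmittance of the droplet filter in [0, 1]; vectorized."""
    wl = np.asarray(wavelength, dtype=float)
    if not np.all(np.isfinite(wl)):
        raise DomainError("wavelength must be finite")
    out = np.exp(-np.exp(-filt.b_mid * (wl - filt.lambda_mid)))
    if np.isscalar(wavelength) or np.ndim(wavelength) == 0:
        return float(out)
    return out
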