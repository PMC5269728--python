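"""Per-cell measurement pipeline: scan merging, normalization, template-based
lambda_max estimation and quality-control filtering.

The measurement protocol pairs an outward sweep (750 -> 350 nm, 2 nm steps,
even wavelengths) with a return sweep (351 -> 749 nm, odd wavelengths).
Adjacent outward/return samples are averaged onto a midpoint grid, the mean
curve is baseline-subtracted and rescaled to fractional absorbance, and
lambda_max is estimated twice:

* **primary** — the 20 consecutive samples immediately long-ward of the peak
  whose fractional absorbance lies inside a configurable window (default
  0.10-0.90) are each inverted through the template's long limb; the
  estimate is their mean and the per-point spread is the right-limb SD.
* **secondary** — 50 samples centred on the peak; long-limb points are
  inverted as above, points at or short of the peak are placed on the
  template by single-point least-squares shift (short-branch inversion).

Selection criteria (strict regime, rod/LWS/MWS): transverse density > 0.01,
right-limb SD < 12 nm, |primary - secondary| < 6 nm — strict inequalities.
For the rare SWS/UVS classes the criteria are relaxed: a cell is retained
iff it shows convincing post-measurement bleaching.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import templates
from .exceptions import (
    DegenerateSpectrumError,
    DomainError,
    FormatError,
    InsufficientLimbError,
    EstimationError,
)

GRID_SPACING_NM = 2.0
RELAXED_CLASSES = frozenset({"SWS", "UVS"})


@dataclass
class SpectralScan:
    """One directional sweep of (wavelength, absorbance) samples."""

    wavelengths: np.ndarray
    absorbance: np.ndarray
    direction: str  # "outward" (descending) or "return" (ascending)

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths.shape != self.absorbance.shape:
            raise FormatError("wavelength and absorbance lengths differ")
        if self.direction not in ("outward", "return"):
            raise FormatError(f"unknown scan direction {self.direction!r}")
        d = np.diff(self.wavelengths)
        expected = -GRID_SPACING_NM if self.direction == "outward" else GRID_SPACING_NM
        if len(d) and not np.allclose(d, expected, atol=1e-9):
            raise FormatError(
                f"{self.direction} scan is not a monotone {GRID_SPACING_NM} nm grid"
            )

    def ascending(self) -> tuple[np.ndarray, np.ndarray]:
        if self.direction == "outward":
            return self.wavelengths[::-1], self.absorbance[::-1]
        return self.wavelengths, self.absorbance


@dataclass
class MSPRecord:
    """A cell's scans plus identifying metadata."""

    cell_id: str
    bird_id: str
    population: str
    putative_class: str
    outward: SpectralScan
    return_: SpectralScan
    post_bleach: Optional[SpectralScan] = None
    morphology: str = ""

    def __post_init__(self):
        if not self.bird_id or not self.population:
            raise FormatError(f"record {self.cell_id}: bird_id/population empty")


@dataclass
class MergedSpectrum:
    """Averaged outward/return curve, optionally normalized."""

    wavelengths: np.ndarray
    mean_absorbance: np.ndarray
    baseline: Optional[float] = None
    fractional: Optional[np.ndarray] = None
    transverse_density: Optional[float] = None
    #: low-noise copy of ``fractional`` used for peak location and point
    #: selection only; equals ``fractional`` when smoothing is disabled
    smoothed_fractional: Optional[np.ndarray] = None


@dataclass
class QCVerdict:
    passed: bool
    # criterion name -> (threshold, observed, passed)
    criteria: dict[str, tuple[object, object, bool]]
    regime: str  # "strict" or "relaxed"

    @property
    def failed_criteria(self) -> list[str]:
        return [k for k, (_, _, ok) in self.criteria.items() if not ok]


@dataclass
class LambdaMaxEstimate:
    cell_id: str = ""
    lambda_max_primary: float = float("nan")
    sd_right_limb: float = float("nan")
    lambda_max_secondary: float = float("nan")
    method_difference: float = float("nan")
    transverse_density: float = float("nan")
    n_points_primary: int = 0
    n_points_secondary: int = 0
    bleach_confirmed: Optional[bool] = None
    qc: Optional[QCVerdict] = None
    error: str = ""
    pigment_class: str = "unknown"


def merge_scans(outward: SpectralScan, return_: SpectralScan) -> MergedSpectrum:
    """Average adjacent outward/return samples onto a midpoint grid.

    Each return sample at wavelength ``w`` is paired with the outward
    sample 1 nm below it; the merged sample sits at the pair midpoint
    ``w - 0.5`` nm.  Outward
    samples with no return partner (the 750 nm endpoint) are dropped, so
    201 outward + 200 return samples merge to 200.
    """
    if outward.direction != "outward" or return_.direction != "return":
        raise FormatError("merge_scans expects (outward, return) in that order")
    wo, ao = outward.ascending()
    wr, ar = return_.ascending()
    half = GRID_SPACING_NM / 2.0
    # outward partner for each return wavelength
    idx = np.searchsorted(wo, wr - half)
    bad = []
    ok = np.zeros(len(wr), dtype=bool)
    for k, (i, w) in enumerate(zip(idx, wr)):
        if i < len(wo) and abs(wo[i] - (w - half)) < 1e-6:
            ok[k] = True
        else:
            bad.append(w)
    if bad:
        raise FormatError(
            f"scans do not interleave: return wavelengths {bad[:5]}... have no "
            f"outward partner {half} nm below"
        )
    merged_wl = wr - half / 2.0  # midpoint of the (w - 1, w) pair
    merged_ab = 0.5 * (ao[idx] + ar)
    return MergedSpectrum(wavelengths=merged_wl, mean_absorbance=merged_ab)


def normalize(merged: MergedSpectrum,
              baseline_window: tuple[float, float] = (730.0, 750.0),
              peak_smoothing: int | None = 11) -> MergedSpectrum:
    """Baseline-subtract and rescale to fractional absorbance (peak = 1).

    The baseline is the mean absorbance inside ``baseline_window``; the
    transverse density is the peak absorbance minus the baseline.  The peak
    height is read off a Savitzky-Golay (quadratic) smoothed copy of the
    curve when ``peak_smoothing`` is an odd window length > 1: the raw
    maximum of a noisy curve is upward-biased, which would deflate every
    fractional value and bias lambda_max short-ward.  Pass ``None`` (or 1)
    to use the raw maximum; for noise-free spectra the two agree to within
    the sampling granularity of the peak.

    Raises
    ------
    DegenerateSpectrumError
        If the peak does not exceed the baseline.
    """
    wl = merged.wavelengths
    ab = merged.mean_absorbance
    lo, hi = baseline_window
    mask = (wl >= lo) & (wl <= hi)
    if not mask.any():
        raise DomainError(f"baseline window [{lo}, {hi}] outside spectrum coverage")
    baseline = float(ab[mask].mean())
    if peak_smoothing and peak_smoothing > 1 and len(ab) >= peak_smoothing:
        from scipy.signal import savgol_filter
        smooth = savgol_filter(ab, peak_smoothing, 2)
    else:
        smooth = ab
    peak = float(smooth.max())
    density = peak - baseline
    if density <= 1e-9:  # OD; below any measurable transverse density
        raise DegenerateSpectrumError(
            f"peak absorbance {peak:.5g} does not exceed baseline {baseline:.5g}"
        )
    fractional = (ab - baseline) / density
    return MergedSpectrum(
        wavelengths=wl,
        mean_absorbance=ab,
        baseline=baseline,
        fractional=fractional,
        transverse_density=density,
        smoothed_fractional=(smooth - baseline) / density,
    )


def _require_normalized(merged: MergedSpectrum):
    if merged.fractional is None:
        raise DomainError("spectrum must be normalized first (call normalize())")


def refine_normalization(merged: MergedSpectrum, lambda_max: float, *,
                         include_beta: bool = True,
                         region_threshold: float = 0.5) -> MergedSpectrum:
    """Re-estimate the transverse density by template-assisted least squares.

    Any peak-height estimate obtained by maximizing over a noisy curve is
    upward-biased, which deflates every fractional value and drags the
    per-point lambda_max inversions short-ward.  Given a provisional
    ``lambda_max``, the density is instead fit as the linear least-squares
    scale between the baseline-subtracted curve and the template over the
    region where the template exceeds ``region_threshold`` — a linear
    (hence unbiased) estimator.  The baseline is kept fixed.
    """
    _require_normalized(merged)
    lm = float(np.clip(lambda_max, *templates.LAMBDA_MAX_RANGE))
    t = templates.pigment_absorbance(lm, merged.wavelengths,
                                     include_beta=include_beta)
    mask = t >= region_threshold
    sub = merged.mean_absorbance - merged.baseline
    denom = float(np.sum(t[mask] ** 2))
    density = float(np.sum(t[mask] * sub[mask]) / denom)
    if density <= 0:
        raise DegenerateSpectrumError("refined transverse density is non-positive")
    scale = merged.transverse_density / density
    return MergedSpectrum(
        wavelengths=merged.wavelengths,
        mean_absorbance=merged.mean_absorbance,
        baseline=merged.baseline,
        fractional=sub / density,
        transverse_density=density,
        smoothed_fractional=(None if merged.smoothed_fractional is None
                             else merged.smoothed_fractional * scale),
    )


def estimate_primary(merged: MergedSpectrum, *,
                     window: tuple[float, float] = (0.10, 0.90),
                     n_points: int = 20,
                     fraction_floor: float = 0.02,
                     include_beta: bool = True) -> tuple[float, float, int]:
    """Long-limb estimate: mean and SD of per-point template inversions.

    Selects the first ``n_points`` consecutive samples long-ward of the
    fractional peak whose value lies inside ``window``, inverts each
    through the template long limb, and returns (mean, SD, n).
    """
    _require_normalized(merged)
    frac = merged.fractional
    guide = merged.smoothed_fractional if merged.smoothed_fractional is not None else frac
    wl = merged.wavelengths
    peak_idx = int(np.argmax(guide))
    lo, hi = window
    # Window membership is judged on the smoothed curve so that sample noise
    # cannot truncate the eligible run or bias which points are selected;
    # the raw fractional values are what get inverted.
    sel_wl, sel_frac = [], []
    for i in range(peak_idx + 1, len(wl)):
        g = guide[i]
        if g > hi:
            continue  # still above the window while descending from the peak
        if g < lo:
            break  # left the window: the eligible run has ended
        sel_wl.append(wl[i])
        sel_frac.append(np.clip(frac[i], fraction_floor, 1.0 - 1e-6))
        if len(sel_wl) == n_points:
            break
    if len(sel_wl) < n_points:
        raise InsufficientLimbError(
            f"only {len(sel_wl)} of {n_points} required long-limb samples "
            f"inside fractional window [{lo}, {hi}]"
        )
    per_point = templates.invert_long_limb(
        np.array(sel_frac), np.array(sel_wl),
        fraction_bounds=(0.0, 1.0), include_beta=include_beta,
    )
    return float(np.mean(per_point)), float(np.std(per_point, ddof=1)), n_points


def estimate_secondary(merged: MergedSpectrum, *, n_points: int = 50,
                       include_beta: bool = True) -> tuple[float, int]:
    """Peak-centred estimate averaging ``n_points`` per-point placements.

    Points long of the peak use long-limb inversion; points at or short of
    the peak are placed by single-point least-squares shift on the short
    branch.  Points whose placement cannot be bracketed (noise pushing the
    fraction out of range) are dropped; at least half must survive.
    """
    _require_normalized(merged)
    frac = merged.fractional
    guide = merged.smoothed_fractional if merged.smoothed_fractional is not None else frac
    wl = merged.wavelengths
    peak_idx = int(np.argmax(guide))
    half = n_points // 2
    start, stop = peak_idx - half, peak_idx + (n_points - half)
    # keep the span centred where possible, sliding it inward at the grid edges
    if start < 0:
        start, stop = 0, n_points
    if stop > len(wl):
        start, stop = len(wl) - n_points, len(wl)
    if start < 0 or stop > len(wl):
        raise InsufficientLimbError(
            f"cannot place {n_points} peak-centred samples "
            f"(spectrum has {len(wl)} samples)"
        )
    eps = 1e-6
    estimates = []
    long_f, long_w, short_f, short_w = [], [], [], []
    for i in range(start, stop):
        f = float(np.clip(frac[i], eps, 1.0 - eps))
        if i > peak_idx:
            long_f.append(f)
            long_w.append(wl[i])
        else:
            short_f.append(f)
            short_w.append(wl[i])
    for inverter, fs, ws in (
        (templates.invert_long_limb, long_f, long_w),
        (templates.invert_short_branch, short_f, short_w),
    ):
        if not fs:
            continue
        try:
            kw = {"fraction_bounds": (eps / 2, 1.0)} if inverter is templates.invert_long_limb else {}
            vals = inverter(np.array(fs), np.array(ws), include_beta=include_beta, **kw)
            estimates.extend(np.atleast_1d(vals))
        except EstimationError:
            # fall back to per-point attempts so one bad sample is dropped,
            # not the whole batch
            for f, w in zip(fs, ws):
                try:
                    estimates.append(inverter(f, w, include_beta=include_beta))
                except EstimationError:
                    pass
    if len(estimates) < n_points // 2:
        raise InsufficientLimbError(
            f"only {len(estimates)} of {n_points} peak-centred samples could be placed"
        )
    return float(np.mean(estimates)), len(estimates)


def check_bleach(merged_pre: MergedSpectrum, post_bleach: Optional[SpectralScan], *,
                 peak_drop_fraction: float = 0.5,
                 shortwave_max: float = 420.0,
                 photoproduct_min_fraction: float = 0.05,
                 baseline_window: tuple[float, float] = (730.0, 750.0)) -> Optional[bool]:
    """Verify post-bleach pigment loss and photoproduct appearance.

    True iff (a) the baseline-subtracted post-bleach absorbance at the
    pre-bleach peak has dropped to at most ``peak_drop_fraction`` of the
    pre-bleach density, and (b) short-wavelength (<= ``shortwave_max``)
    absorbance shows photoproduct: its mean is at least the smaller of the
    pre-bleach short-wavelength mean and ``photoproduct_min_fraction`` of
    the pre-bleach density.  (A plain "must not decrease" rule would
    condemn every genuine UV/short-wave pigment, whose own absorbance
    below 420 nm necessarily collapses when the pigment is destroyed.)
    Returns None ("unverified") when no post-bleach scan exists.
    """
    if post_bleach is None:
        return None
    _require_normalized(merged_pre)
    tol = 1e-6  # OD; negligible against real transverse densities
    wl = merged_pre.wavelengths
    pre_sub = merged_pre.mean_absorbance - merged_pre.baseline
    guide = (merged_pre.smoothed_fractional
             if merged_pre.smoothed_fractional is not None else merged_pre.fractional)
    peak_wl = wl[int(np.argmax(guide))]
    pw, pa = post_bleach.ascending()
    post = np.interp(wl, pw, pa)
    lo, hi = baseline_window
    bmask = (wl >= lo) & (wl <= hi)
    post_sub = post - float(post[bmask].mean())
    post_peak = float(np.interp(peak_wl, wl, post_sub))
    pre_peak = float(merged_pre.transverse_density)
    dropped = post_peak <= peak_drop_fraction * pre_peak + tol
    sw = wl <= shortwave_max
    if not sw.any():
        return bool(dropped)
    required = min(float(pre_sub[sw].mean()),
                   photoproduct_min_fraction * pre_peak)
    photoproduct = float(post_sub[sw].mean()) >= required - tol
    return bool(dropped and photoproduct)


def apply_qc(estimate: LambdaMaxEstimate, putative_class: str, *,
             min_density: float = 0.01,
             max_limb_sd: float = 12.0,
             max_method_diff: float = 6.0) -> QCVerdict:
    """Evaluate the selection criteria for a cell record.

    Strict regime (rod/LWS/MWS): transverse density strictly greater than
    ``min_density``, right-limb SD strictly less than ``max_limb_sd``,
    inter-method difference strictly less than ``max_method_diff``.
    Relaxed regime (SWS/UVS): retained iff bleaching was confirmed.
    """
    regime = "relaxed" if putative_class in RELAXED_CLASSES else "strict"
    criteria: dict[str, tuple[object, object, bool]] = {}
    if estimate.error:
        criteria["estimation"] = ("no estimation error", estimate.error, False)
        return QCVerdict(passed=False, criteria=criteria, regime=regime)
    if regime == "strict":
        criteria["transverse_density"] = (
            f"> {min_density}", estimate.transverse_density,
            bool(estimate.transverse_density > min_density),
        )
        criteria["sd_right_limb"] = (
            f"< {max_limb_sd}", estimate.sd_right_limb,
            bool(estimate.sd_right_limb < max_limb_sd),
        )
        criteria["method_difference"] = (
            f"< {max_method_diff}", estimate.method_difference,
            bool(estimate.method_difference < max_method_diff),
        )
    else:
        criteria["bleach_confirmed"] = (
            "bleaching confirmed", estimate.bleach_confirmed,
            estimate.bleach_confirmed is True,
        )
    passed = all(ok for (_, _, ok) in criteria.values())
    return QCVerdict(passed=passed, criteria=criteria, regime=regime)


DEFAULT_CLASS_BOUNDARIES: tuple[tuple[str, float, float], ...] = (
    ("UVS", 330.0, 400.0),
    ("SWS", 400.0, 480.0),
    ("MWS_or_rod", 480.0, 540.0),
    ("LWS", 540.0, 620.0),
)


def classify_pigment(lambda_max: float, morphology: str = "",
                     boundaries=DEFAULT_CLASS_BOUNDARIES) -> str:
    """Assign a pigment class from lambda_max and (where needed) morphology.

    The 480-540 nm band contains both rod and MWS cone pigments; the
    record's morphology label breaks the tie.  Returns "unknown" when no
    rule fires rather than guessing.
    """
    if not (330.0 <= lambda_max <= 620.0):
        raise DomainError(f"lambda_max={lambda_max} outside [330, 620] nm")
    for name, lo, hi in boundaries:
        if lo <= lambda_max < hi or (hi == 620.0 and lambda_max == hi):
            if name != "MWS_or_rod":
                return name
            label = morphology.lower()
            if "rod" in label:
                return "rod"
            if "cone" in label:
                return "MWS"
            return "unknown"
    return "unknown"


#: Per-class overrides for the primary point selection.  The UV template's
#: long limb spans too few 2 nm samples between the default fractional
#: bounds to supply 20 points, so UVS cells use a wider window and fewer
#: points — consistent with the relaxed handling of these rare cells.
DEFAULT_CLASS_OVERRIDES: dict[str, dict] = {
    "UVS": {"primary_window": (0.15, 0.95), "n_points_primary": 15},
}


def process_record(record: MSPRecord, *,
                   baseline_window: tuple[float, float] = (730.0, 750.0),
                   peak_smoothing: int | None = 11,
                   primary_window: tuple[float, float] = (0.10, 0.90),
                   n_points_primary: int = 20,
                   n_points_secondary: int = 50,
                   refine_iterations: int = 2,
                   include_beta: bool = True,
                   min_density: float = 0.01,
                   max_limb_sd: float = 12.0,
                   max_method_diff: float = 6.0,
                   peak_drop_fraction: float = 0.5,
                   shortwave_max: float = 420.0,
                   class_boundaries=DEFAULT_CLASS_BOUNDARIES,
                   class_overrides: dict[str, dict] | None = None) -> LambdaMaxEstimate:
    """Run the full per-cell pipeline; estimation failures become failed
    QC verdicts, never exceptions.

    The normalization is refined ``refine_iterations`` times: each pass
    re-fits the transverse density against the template placed at the
    current primary estimate (see :func:`refine_normalization`), removing
    the upward bias of the initial peak-maximum density estimate.
    """
    if class_overrides is None:
        class_overrides = DEFAULT_CLASS_OVERRIDES
    ov = class_overrides.get(record.putative_class, {})
    primary_window = ov.get("primary_window", primary_window)
    n_points_primary = ov.get("n_points_primary", n_points_primary)
    est = LambdaMaxEstimate(cell_id=record.cell_id)
    try:
        merged = normalize(merge_scans(record.outward, record.return_),
                           baseline_window=baseline_window,
                           peak_smoothing=peak_smoothing)
        for _ in range(max(0, refine_iterations)):
            lam, _, _ = estimate_primary(
                merged, window=primary_window, n_points=n_points_primary,
                include_beta=include_beta,
            )
            merged = refine_normalization(merged, lam, include_beta=include_beta)
        est.transverse_density = merged.transverse_density
        est.lambda_max_primary, est.sd_right_limb, est.n_points_primary = estimate_primary(
            merged, window=primary_window, n_points=n_points_primary,
            include_beta=include_beta,
        )
        est.lambda_max_secondary, est.n_points_secondary = estimate_secondary(
            merged, n_points=n_points_secondary, include_beta=include_beta,
        )
        est.method_difference = abs(est.lambda_max_primary - est.lambda_max_secondary)
        est.bleach_confirmed = check_bleach(
            merged, record.post_bleach,
            peak_drop_fraction=peak_drop_fraction, shortwave_max=shortwave_max,
            baseline_window=baseline_window,
        )
        try:
            est.pigment_class = classify_pigment(
                est.lambda_max_primary, record.morphology or record.putative_class,
                boundaries=class_boundaries,
            )
        except DomainError:
            est.pigment_class = "unknown"
    except EstimationError as exc:
        est.error = f"{type(exc).__name__}: {exc}"
    est.qc = apply_qc(
        est, record.putative_class,
        min_density=min_density, max_limb_sd=max_limb_sd,
        max_method_diff=max_method_diff,
    )
    return est
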