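"""Oil droplet cut-off wavelength estimation (Lipetz tangent construction).

A droplet absorbance spectrum is high at short wavelengths and falls off
along its long-wavelength edge.  The cut-off is located by fitting a
tangent line to the spectrum at its 50%-of-maximum point on that falling
edge and extrapolating it back up: the wavelength at which the tangent
reaches the maximum measured absorbance is ``lambda_cut``.  The tangent is
realized as a least-squares line over a short symmetric sample window
around the half-maximum crossing.

T-type droplets have no detectable absorbance and carry no cut-off.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import AmbiguousSpectrumError, ContractViolation
from .msp import MergedSpectrum

DROPLET_TYPES = ("R", "Y", "C", "P", "T")


@dataclass
class DropletRecord:
    droplet_id: str
    bird_id: str
    population: str
    droplet_type: str
    spectrum: Optional[MergedSpectrum] = None
    lambda_cut: float = float("nan")
    lambda_tangent_point: float = float("nan")
    tangent_slope: float = float("nan")
    error: str = ""

    def __post_init__(self):
        if self.droplet_type not in DROPLET_TYPES:
            raise ContractViolation(
                f"droplet_type {self.droplet_type!r} not one of {DROPLET_TYPES}"
            )


def lambda_cut(spectrum: MergedSpectrum, *,
               tangent_samples: int = 5) -> tuple[float, float, float]:
    """Cut-off wavelength by the tangent construction.

    Returns ``(lambda_cut, tangent_point, slope)`` where ``tangent_point``
    is the wavelength of the half-maximum crossing on the falling edge and
    ``slope`` the fitted tangent slope (negative, baseline-subtracted OD
    per nm).

    Raises
    ------
    AmbiguousSpectrumError
        If the falling edge crosses half-maximum zero times or more than
        once inside the analysis window.
    """
    wl = np.asarray(spectrum.wavelengths, dtype=float)
    ab = np.asarray(spectrum.mean_absorbance, dtype=float)
    if spectrum.baseline is not None:
        ab = ab - spectrum.baseline
    a_max = float(ab.max())
    if a_max <= 0:
        raise AmbiguousSpectrumError("spectrum has no positive absorbance")
    half = 0.5 * a_max
    peak_idx = int(np.argmax(ab))
    # descending crossings on the long-wavelength side of the maximum
    crossings = []
    for i in range(peak_idx, len(wl) - 1):
        if ab[i] >= half > ab[i + 1]:
            crossings.append(i)
    if len(crossings) != 1:
        raise AmbiguousSpectrumError(
            f"found {len(crossings)} half-maximum crossings on the falling "
            f"edge (need exactly 1); half-max={half:.4g}"
        )
    i = crossings[0]
    # linear interpolation of the crossing wavelength
    frac = (half - ab[i]) / (ab[i + 1] - ab[i])
    tangent_point = float(wl[i] + frac * (wl[i + 1] - wl[i]))
    # least-squares tangent over `tangent_samples` samples centred on the
    # sample nearest the crossing
    centre = i if abs(wl[i] - tangent_point) <= abs(wl[i + 1] - tangent_point) else i + 1
    k = tangent_samples // 2
    lo = max(0, centre - k)
    hi = min(len(wl), lo + tangent_samples)
    lo = max(0, hi - tangent_samples)
    slope, intercept = np.polyfit(wl[lo:hi], ab[lo:hi], 1)
    if slope >= 0:
        raise AmbiguousSpectrumError(
            f"tangent slope {slope:.4g} is not negative at the falling edge"
        )
    cut = float((a_max - intercept) / slope)
    return cut, tangent_point, float(slope)


def process_droplet(record: DropletRecord, *,
                    tangent_samples: int = 5) -> DropletRecord:
    """Fill in the cut-off fields of a droplet record in place.

    T-type droplets are passed through untouched (no detectable
    absorbance, hence no cut-off); estimation failures are recorded on
    the record rather than raised.
    """
    if record.droplet_type == "T":
        record.error = "T-type droplet: no detectable absorbance"
        return record
    try:
        cut, tp, slope = lambda_cut(record.spectrum,
                                    tangent_samples=tangent_samples)
        record.lambda_cut = cut
        record.lambda_tangent_point = tp
        record.tangent_slope = slope
    except AmbiguousSpectrumError as exc:
        record.error = str(exc)
    return record


_TABLE_COLUMNS = ["droplet_id", "bird_id", "population", "droplet_type",
                  "lambda_cut", "lambda_tangent_point", "tangent_slope",
                  "error"]


def droplet_table(records: list[DropletRecord]) -> pd.DataFrame:
    """Tabulate processed droplet records (one row per droplet)."""
    if not records:
        return pd.DataFrame(columns=_TABLE_COLUMNS)
    return pd.DataFrame(
        {
            "droplet_id": r.droplet_id,
            "bird_id": r.bird_id,
            "population": r.population,
            "droplet_type": r.droplet_type,
            "lambda_cut": r.lambda_cut,
            "lambda_tangent_point": r.lambda_tangent_point,
            "tangent_slope": r.tangent_slope,
            "error": r.error,
        }
        for r in records
    )


def summarize_droplets(records: list[DropletRecord], *, alpha: float = 0.05,
                       df_method: str = "satterthwaite") -> pd.DataFrame:
    """Per-type population comparison of cut-off wavelengths.

    T-type droplets and records with estimation errors are excluded.
    Delegates the per-type mixed-model comparison to :mod:`pymsp.stats`.
    """
    from . import stats

    if not records:
        return pd.DataFrame()
    tab = droplet_table(records)
    tab = tab[(tab["droplet_type"] != "T") & (tab["error"] == "")]
    tab = tab.rename(columns={"lambda_cut": "value"})
    if not len(tab):
        return pd.DataFrame()
    return stats._compare_types(
        tab, "droplet_type", list(stats._DROPLET_ORDER),
        alpha=alpha, df_method=df_method, compute_icc=False,
    )
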