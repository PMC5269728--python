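"""Readers and writers for the plain-text scan and manifest formats.

Scan files are two-column TSV (``wavelength_nm``, ``absorbance_od``) with a
header line; manifests are TSV tables pointing at scan files relative to
the manifest's directory.
"""
from __future__ import annotations

from pathlib import Path
import numpy as np
import pandas as pd

from .exceptions import FormatError
from .msp import MSPRecord, MergedSpectrum, SpectralScan
from .droplets import DropletRecord

SCAN_COLUMNS = ("wavelength_nm", "absorbance_od")


def write_scan(path, scan: SpectralScan) -> None:
    pd.DataFrame({
        SCAN_COLUMNS[0]: scan.wavelengths,
        SCAN_COLUMNS[1]: scan.absorbance,
    }).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_scan(path, direction: str) -> SpectralScan:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SCAN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return SpectralScan(df[SCAN_COLUMNS[0]].to_numpy(float),
                        df[SCAN_COLUMNS[1]].to_numpy(float), direction)


def write_merged(path, spectrum: MergedSpectrum) -> None:
    pd.DataFrame({
        SCAN_COLUMNS[0]: spectrum.wavelengths,
        SCAN_COLUMNS[1]: spectrum.mean_absorbance,
    }).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_merged(path) -> MergedSpectrum:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SCAN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    wl = df[SCAN_COLUMNS[0]].to_numpy(float)
    ab = df[SCAN_COLUMNS[1]].to_numpy(float)
    order = np.argsort(wl)
    return MergedSpectrum(wavelengths=wl[order], mean_absorbance=ab[order])


def read_cell_manifest(path, *, mask_populations: bool = False) -> list[MSPRecord]:
    """Load MSP records listed in a cell manifest.

    ``mask_populations`` replaces every population label with a constant
    placeholder so estimation can be run blind; estimates must not depend
    on it.
    """
    path = Path(path)
    root = path.parent
    df = pd.read_csv(path, sep="\t").fillna("")
    required = {"cell_id", "bird_id", "population", "putative_class",
                "outward_path", "return_path"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: manifest missing column(s) {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        post = None
        if row.get("postbleach_path", ""):
            post = read_scan(root / row["postbleach_path"], "return")
        records.append(MSPRecord(
            cell_id=str(row["cell_id"]),
            bird_id=str(row["bird_id"]),
            population="masked" if mask_populations else str(row["population"]),
            putative_class=str(row["putative_class"]),
            outward=read_scan(root / row["outward_path"], "outward"),
            return_=read_scan(root / row["return_path"], "return"),
            post_bleach=post,
            morphology=str(row.get("morphology", "")),
        ))
    return records


def read_droplet_manifest(path) -> list[DropletRecord]:
    path = Path(path)
    root = path.parent
    df = pd.read_csv(path, sep="\t").fillna("")
    required = {"droplet_id", "bird_id", "population", "droplet_type",
                "spectrum_path"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: manifest missing column(s) {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        spectrum = None
        if row["spectrum_path"]:
            from .msp import normalize
            spectrum = normalize(read_merged(root / row["spectrum_path"]))
        records.append(DropletRecord(
            droplet_id=str(row["droplet_id"]),
            bird_id=str(row["bird_id"]),
            population=str(row["population"]),
            droplet_type=str(row["droplet_type"]),
            spectrum=spectrum,
        ))
    return records


def estimates_table(estimates) -> pd.DataFrame:
    """Flatten LambdaMaxEstimate objects (plus metadata) to one table."""
    rows = []
    for rec, est in estimates:
        row = {
            "cell_id": est.cell_id,
            "bird_id": rec.bird_id,
            "population": rec.population,
            "putative_class": rec.putative_class,
            "pigment_class": est.pigment_class,
            "lambda_max_primary": est.lambda_max_primary,
            "sd_right_limb": est.sd_right_limb,
            "lambda_max_secondary": est.lambda_max_secondary,
            "method_difference": est.method_difference,
            "transverse_density": est.transverse_density,
            "n_points_primary": est.n_points_primary,
            "n_points_secondary": est.n_points_secondary,
            "bleach_confirmed": est.bleach_confirmed,
            "qc_passed": est.qc.passed if est.qc else False,
            "qc_regime": est.qc.regime if est.qc else "",
            "qc_failed_criteria": ";".join(est.qc.failed_criteria) if est.qc else "",
            "error": est.error,
        }
        rows.append(row)
    return pd.DataFrame(rows)
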