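"""Nuclear/perinuclear pH quantification and hierarchical aggregation.

Per field: segment nuclei from a DNA-stain channel (Otsu threshold, hole
filling, distance-transform watershed to split touching nuclei, size filter),
build a perinuclear annulus of shared width equal to the field's mean
equivalent nuclear radius, convert region-mean dye ratios to pH through the
fitted calibration curves, and report per-cell records:

    pHn   from the H34580 440/490 ratio over nuclear pixels,
    pHc   from the cSNARF1 580/640 ratio over the annulus,
    ΔpHnc = pHn − pHc.

Cells are nested in isolations (biological replicates); condition summaries
average cells within isolation first and treat the isolation as the unit of
replication (mean of isolation means, SEM = SD of isolation means / sqrt(n)).
pH-coupling slopes (pHc vs pHe, pHn vs pHe) are ordinary least squares on the
condition means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops_table
from skimage.segmentation import watershed

from .ph_calibration import CalibrationCurve, pH_to_ratio, ratio_to_pH

__all__ = [
    "NucleusLabelMap",
    "AnnulusLabelMap",
    "segment_nuclei",
    "build_annuli",
    "quantify_cell_pH",
    "hierarchical_summary",
    "ph_coupling_slopes",
    "propagated_dpnc_sd",
]


@dataclass
class NucleusLabelMap:
    """Labelled nuclei (0 = background, 1..n) with per-label geometry."""

    labels: np.ndarray
    table: pd.DataFrame  # label, area, centroid_row, centroid_col, eq_radius

    @property
    def n_nuclei(self) -> int:
        return len(self.table)

    @property
    def mean_equivalent_radius(self) -> float:
        return float(self.table["eq_radius"].mean()) if len(self.table) else 0.0


@dataclass
class AnnulusLabelMap:
    """Perinuclear annuli sharing nucleus labels; one shared width per field."""

    labels: np.ndarray
    annulus_width_px: int


def segment_nuclei(
    dna_image: np.ndarray,
    min_area_px: float = 30.0,
    max_area_px: float = 800.0,
    *,
    marker_min_distance: Optional[int] = None,
) -> NucleusLabelMap:
    """Otsu threshold → hole fill → distance-transform watershed → size filter.

    Deterministic for a fixed input.  A blank image (or one with no region in
    the size window) yields an empty label map, not an error.
    ``marker_min_distance`` controls watershed seed spacing; the default is
    derived from the mid-range expected nucleus radius.
    """
    img = np.asarray(dna_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("dna_image must be a single-channel 2-D image")
    if min_area_px >= max_area_px:
        raise ValueError("min_area_px must be < max_area_px")

    empty = NucleusLabelMap(
        labels=np.zeros(img.shape, dtype=int),
        table=pd.DataFrame(
            columns=["label", "area", "centroid_row", "centroid_col", "eq_radius"]
        ),
    )
    if np.ptp(img) == 0:
        return empty
    thr = threshold_otsu(img)
    mask = img > thr
    if not mask.any():
        return empty
    mask = ndi.binary_fill_holes(mask)

    if marker_min_distance is None:
        marker_min_distance = max(
            3, int(round(np.sqrt((min_area_px + max_area_px) / 2.0 / np.pi)))
        )
    distance = ndi.distance_transform_edt(mask)
    coords = peak_local_max(
        distance, min_distance=marker_min_distance, labels=mask,
        exclude_border=False,
    )
    markers = np.zeros(img.shape, dtype=int)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        return empty
    labels = watershed(-distance, markers, mask=mask)

    props = regionprops_table(labels, properties=("label", "area", "centroid"))
    keep = [
        lab
        for lab, area in zip(props["label"], props["area"])
        if min_area_px <= area <= max_area_px
    ]
    out = np.zeros(img.shape, dtype=int)
    rows = []
    for new, lab in enumerate(sorted(keep), start=1):
        sel = labels == lab
        out[sel] = new
        area = int(sel.sum())
        rr, cc = np.nonzero(sel)
        rows.append(
            dict(
                label=new,
                area=area,
                centroid_row=float(rr.mean()),
                centroid_col=float(cc.mean()),
                eq_radius=float(np.sqrt(area / np.pi)),
            )
        )
    table = pd.DataFrame(
        rows, columns=["label", "area", "centroid_row", "centroid_col", "eq_radius"]
    )
    return NucleusLabelMap(labels=out, table=table)


def build_annuli(nuclei: NucleusLabelMap) -> AnnulusLabelMap:
    """Perinuclear annuli of shared width = round(mean equivalent radius).

    A background pixel belongs to the annulus if it lies within the shared
    width of any nuclear pixel; contested pixels go to the nucleus with the
    nearest centroid.  Annuli are disjoint from all nuclei and each other.
    """
    if nuclei.n_nuclei < 1:
        raise ValueError("need at least one nucleus to build annuli")
    width = int(round(nuclei.mean_equivalent_radius))
    nuc_mask = nuclei.labels > 0
    distance = ndi.distance_transform_edt(~nuc_mask)
    candidate = (~nuc_mask) & (distance <= width)

    centroids = nuclei.table[["centroid_row", "centroid_col"]].to_numpy()
    labels_of = nuclei.table["label"].to_numpy()
    rr, cc = np.nonzero(candidate)
    if rr.size:
        # nearest-centroid assignment, vectorised over candidate pixels
        d2 = (
            (rr[:, None] - centroids[None, :, 0]) ** 2
            + (cc[:, None] - centroids[None, :, 1]) ** 2
        )
        nearest = labels_of[np.argmin(d2, axis=1)]
    else:
        nearest = np.array([], dtype=int)
    out = np.zeros_like(nuclei.labels)
    out[rr, cc] = nearest
    return AnnulusLabelMap(labels=out, annulus_width_px=width)


def quantify_cell_pH(
    nuclei: NucleusLabelMap,
    annuli: AnnulusLabelMap,
    h34580_440: np.ndarray,
    h34580_490: np.ndarray,
    snarf_580: np.ndarray,
    snarf_640: np.ndarray,
    curve_h34580: CalibrationCurve,
    curve_snarf: CalibrationCurve,
    *,
    condition=None,
    isolation=None,
    field_id=None,
    min_pixels: int = 5,
) -> pd.DataFrame:
    """Per-cell pHn / pHc / ΔpHnc records.

    Region ratios are ratio-of-means (mean numerator / mean denominator) for
    noise robustness.  Cells whose ratio falls outside a curve's invertible
    range get ``flag_out_of_range=True`` and NaN pH; cells with too few
    annulus pixels are dropped.
    """
    channels = {
        "440": np.asarray(h34580_440, dtype=float),
        "490": np.asarray(h34580_490, dtype=float),
        "580": np.asarray(snarf_580, dtype=float),
        "640": np.asarray(snarf_640, dtype=float),
    }
    for name, img in channels.items():
        if img.shape != nuclei.labels.shape:
            raise ValueError(f"channel {name} shape does not match label map")

    records = []
    for _, row in nuclei.table.iterrows():
        lab = int(row["label"])
        nuc = nuclei.labels == lab
        ann = annuli.labels == lab
        n_nuc = int(nuc.sum())
        n_ann = int(ann.sum())
        if n_nuc < min_pixels or n_ann < min_pixels:
            continue
        ratio_n = channels["440"][nuc].mean() / channels["490"][nuc].mean()
        ratio_c = channels["580"][ann].mean() / channels["640"][ann].mean()
        pHn = ratio_to_pH(curve_h34580, ratio_n)
        pHc = ratio_to_pH(curve_snarf, ratio_c)
        out_of_range = bool(np.isnan(pHn) or np.isnan(pHc))
        records.append(
            dict(
                cell=lab,
                field=field_id,
                isolation=isolation,
                condition=condition,
                pHn=pHn,
                pHc=pHc,
                dpnc=pHn - pHc,
                n_pixels_nucleus=n_nuc,
                n_pixels_annulus=n_ann,
                flag_out_of_range=out_of_range,
            )
        )
    df = pd.DataFrame(
        records,
        columns=[
            "cell", "field", "isolation", "condition", "pHn", "pHc", "dpnc",
            "n_pixels_nucleus", "n_pixels_annulus", "flag_out_of_range",
        ],
    )
    if len(df):
        # ΔpHnc identity holds by construction; assert it anyway
        ok = df["flag_out_of_range"] | np.isclose(
            df["dpnc"], df["pHn"] - df["pHc"], atol=1e-12, equal_nan=True
        )
        assert bool(np.all(ok)), "dpnc != pHn - pHc"
    return df


def hierarchical_summary(
    records: pd.DataFrame, by: str = "condition", *, include_flagged: bool = False
) -> pd.DataFrame:
    """Condition summaries with the isolation as the unit of replication.

    Cells are averaged within isolation; the condition mean is the unweighted
    mean of isolation means, and SEM is the SD (ddof=1) of isolation means
    divided by sqrt(n_isolations).  With a single isolation the SEM is
    reported as NaN.
    """
    df = records
    if not include_flagged and "flag_out_of_range" in df.columns:
        df = df[~df["flag_out_of_range"].astype(bool)]
    if df.empty:
        raise ValueError("no usable cell records")

    out = []
    for cond, grp in df.groupby(by, sort=True):
        iso_means = grp.groupby("isolation")[["pHn", "pHc", "dpnc"]].mean()
        n_iso = len(iso_means)
        means = iso_means.mean(axis=0)
        if n_iso > 1:
            sems = iso_means.std(axis=0, ddof=1) / np.sqrt(n_iso)
        else:
            sems = pd.Series(np.nan, index=iso_means.columns)
        out.append(
            {
                by: cond,
                "n_cells": int(len(grp)),
                "n_isolations": int(n_iso),
                "mean_pHn": float(means["pHn"]),
                "sem_pHn": float(sems["pHn"]),
                "mean_pHc": float(means["pHc"]),
                "sem_pHc": float(sems["pHc"]),
                "mean_dpnc": float(means["dpnc"]),
                "sem_dpnc": float(sems["dpnc"]),
            }
        )
    return pd.DataFrame(out)


def ph_coupling_slopes(summaries: pd.DataFrame, pHe_column: str = "condition") -> dict:
    """OLS of condition-mean pHc and pHn on pHe.

    ``summaries`` is the output of :func:`hierarchical_summary` with numeric
    pHe values in ``pHe_column``.  Requires >= 3 distinct levels.  Returns a
    dict with slopes, intercepts and R² for both compartments.
    """
    pHe = np.asarray(summaries[pHe_column], dtype=float)
    if np.unique(pHe).size < 3:
        raise ValueError("need >= 3 distinct pHe levels for slope estimation")
    out = {}
    for comp, col in (("pHc", "mean_pHc"), ("pHn", "mean_pHn")):
        res = stats.linregress(pHe, np.asarray(summaries[col], dtype=float))
        out[f"slope_{comp}_vs_pHe"] = float(res.slope)
        out[f"intercept_{comp}"] = float(res.intercept)
        out[f"r2_{comp}"] = float(res.rvalue**2)
    return out


def propagated_dpnc_sd(
    curve_h34580: CalibrationCurve,
    curve_snarf: CalibrationCurve,
    pH: float,
    channel_noise_sd: float,
    base_intensity: float,
    n_pixels_nucleus: int,
    n_pixels_annulus: int,
) -> float:
    """First-order noise propagation: SD of ΔpHnc at a common true pH.

    With additive channel noise of SD s on numerator and denominator whose
    means are R·B and B over n pixels, the region ratio-of-means has
    SD ≈ (s / (B·sqrt(n))) · sqrt(1 + R²); dividing by |dR/dpH| of the
    titration curve converts to pH units.  ΔpHnc combines the nuclear and
    cytoplasmic contributions in quadrature.
    """
    def sd_pH(curve: CalibrationCurve, n_px: int) -> float:
        R = pH_to_ratio(curve, pH)
        sd_ratio = (
            channel_noise_sd / (base_intensity * np.sqrt(n_px))
        ) * np.sqrt(1.0 + R**2)
        dR_dpH = (
            np.log(10.0)
            * curve.hill
            * (R - curve.r_min)
            * (curve.r_max - R)
            / (curve.r_max - curve.r_min)
        )
        return float(sd_ratio / abs(dR_dpH))

    return float(
        np.hypot(
            sd_pH(curve_h34580, n_pixels_nucleus),
            sd_pH(curve_snarf, n_pixels_annulus),
        )
    )
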