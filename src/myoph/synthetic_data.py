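"""Seeded phantom images and omics tables with known ground truth.

Every downstream stage of the pipeline (tissue ratio maps, dye calibration,
nuclear/perinuclear pH quantification, omics concordance statistics) can be
exercised on data generated here, where the truth is known by construction:

* ``generate_tissue_phantom`` — a two-channel whole-section image pair
  (pHLIP-Cy5.5 + Hoechst-33342) of an elliptical tissue disk whose inner-wall
  band is an acidic niche, with additive Gaussian background on each channel.
* ``generate_calibration_series`` — noisy (pH, ratio) titration tables as
  produced by a nigericin-clamp experiment.
* ``generate_monolayer`` — four-channel monolayer fields of disk nuclei with
  dye ratios computed from known calibration curves and known per-cell
  pHn/pHc, clustered by isolation.
* ``generate_omics_tables`` — DEG/DAP/peak/TSS tables with controlled
  direction-concordance, peak-presence probabilities and promoter-overlap
  probability.

All generators are deterministic: identical spec + seed give byte-identical
outputs.  Noise is additive Gaussian on each emission channel (not Poisson)
for analytic tractability; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .ph_calibration import CalibrationCurve, pH_to_ratio

__all__ = [
    "TissuePhantomSpec",
    "MonolayerPhantomSpec",
    "OmicsTableSpec",
    "default_h34580_curve",
    "default_snarf_curve",
    "generate_tissue_phantom",
    "generate_calibration_series",
    "generate_monolayer",
    "generate_omics_tables",
]


# ---------------------------------------------------------------------------
# default dye curves (synthetic placeholders for the generator; real analyses
# must fit their own curves from a clamp series)
# ---------------------------------------------------------------------------

def default_h34580_curve() -> CalibrationCurve:
    """Synthetic H34580 440/490 curve used by the monolayer generator.

    The acid asymptote is the lower ratio; pKa is placed in the physiological
    range.  These numbers parameterise the phantom only — they are not
    measured dye properties.
    """
    return CalibrationCurve(
        dye="H34580", r_min=0.4, r_max=1.9, pKa=7.1, hill=1.0,
        numerator_band="440", denominator_band="490",
    )


def default_snarf_curve() -> CalibrationCurve:
    """Synthetic cSNARF1 580/640 curve (ratio falls as pH rises)."""
    return CalibrationCurve(
        dye="cSNARF1", r_min=2.0, r_max=0.4, pKa=7.3, hill=1.0,
        numerator_band="580", denominator_band="640",
    )


# ---------------------------------------------------------------------------
# tissue phantom
# ---------------------------------------------------------------------------

@dataclass
class TissuePhantomSpec:
    """Forward model of a pHLIP/Hoechst whole-section image pair.

    The tissue is an axis-aligned elliptical disk centred in the image with
    semi-axes ``axes_frac`` times the half image size.  The acidic niche is
    the band of fractional elliptical radius in
    [``niche_inner_frac``, ``niche_outer_frac``] — an "inner wall" ring.
    pHLIP signal follows a decreasing logistic insertion curve in pHe centred
    at ``insertion_pK``; Hoechst tracks cell density only.
    """

    image_shape: Tuple[int, int] = (256, 256)
    axes_frac: Tuple[float, float] = (0.42, 0.42)
    niche_inner_frac: float = 0.45
    niche_outer_frac: float = 0.75
    niche_pHe: float = 6.4
    background_pHe: float = 7.4
    phlip_gain: float = 200.0
    hoechst_gain: float = 300.0
    insertion_pK: float = 6.6
    insertion_slope: float = 1.0
    density_field: Optional[np.ndarray] = None  # relative density in [0, 1]
    bg_mean: float = 10.0
    bg_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.image_shape
        if rows <= 0 or cols <= 0:
            raise ValueError("image_shape must be positive")
        if not (0 < self.axes_frac[0] <= 0.5 and 0 < self.axes_frac[1] <= 0.5):
            raise ValueError("tissue ellipse must fit inside the image")
        if not (0 <= self.niche_inner_frac < self.niche_outer_frac <= 1):
            raise ValueError("niche band fractions must satisfy 0 <= inner < outer <= 1")
        if not self.niche_pHe < self.background_pHe:
            raise ValueError("niche pHe must be below background pHe")
        if self.bg_sd < 0:
            raise ValueError("bg_sd must be >= 0")
        if self.density_field is not None:
            d = np.asarray(self.density_field, dtype=float)
            if d.shape != tuple(self.image_shape):
                raise ValueError("density_field shape must match image_shape")
            if d.min() < 0 or d.max() > 1:
                raise ValueError("density_field values must lie in [0, 1]")


def _insertion_fraction(pHe: np.ndarray, pK: float, slope: float) -> np.ndarray:
    """Fraction of pHLIP in the membrane-inserted state: decreasing logistic."""
    return 1.0 / (1.0 + 10.0 ** (slope * (pHe - pK)))


def generate_tissue_phantom(
    spec: TissuePhantomSpec,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Render (phlip_image, hoechst_image, truth_pHe_map, bg_region_mask).

    ``truth_pHe_map`` is NaN outside the tissue; ``bg_region_mask`` selects
    the tissue-free surround (usable for background statistics).
    """
    rows, cols = spec.image_shape
    rr, cc = np.mgrid[0:rows, 0:cols].astype(float)
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    a = spec.axes_frac[0] * rows
    b = spec.axes_frac[1] * cols
    # fractional elliptical radius: 1.0 on the tissue boundary
    rho = np.sqrt(((rr - cy) / a) ** 2 + ((cc - cx) / b) ** 2)
    tissue = rho <= 1.0
    niche = tissue & (rho >= spec.niche_inner_frac) & (rho <= spec.niche_outer_frac)

    truth = np.full((rows, cols), np.nan)
    truth[tissue] = spec.background_pHe
    truth[niche] = spec.niche_pHe

    density = (
        np.asarray(spec.density_field, dtype=float)
        if spec.density_field is not None
        else np.ones((rows, cols))
    )
    density = np.where(tissue, density, 0.0)

    f = np.zeros((rows, cols))
    f[tissue] = _insertion_fraction(
        truth[tissue], spec.insertion_pK, spec.insertion_slope
    )

    rng = np.random.default_rng(spec.seed)
    phlip = spec.phlip_gain * density * f + rng.normal(
        spec.bg_mean, spec.bg_sd, size=(rows, cols)
    )
    hoechst = spec.hoechst_gain * density + rng.normal(
        spec.bg_mean, spec.bg_sd, size=(rows, cols)
    )
    bg_region_mask = ~tissue
    return phlip, hoechst, truth, bg_region_mask


# ---------------------------------------------------------------------------
# calibration series
# ---------------------------------------------------------------------------

def generate_calibration_series(
    curve: CalibrationCurve,
    pH_levels: Sequence[float],
    noise_sd: float = 0.0,
    n_rois: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Nigericin-clamp titration table: ``n_rois`` ratio readings per pH level.

    observed ratio = curve(pH) + N(0, noise_sd).
    """
    pH_levels = list(pH_levels)
    if len(pH_levels) == 0:
        raise ValueError("pH_levels must be non-empty")
    if n_rois < 1:
        raise ValueError("n_rois must be >= 1")
    rng = np.random.default_rng(seed)
    pH = np.repeat(np.asarray(pH_levels, dtype=float), n_rois)
    ratio = pH_to_ratio(curve, pH) + rng.normal(0.0, noise_sd, size=pH.size)
    return pd.DataFrame({"pH": pH, "ratio": ratio})


# ---------------------------------------------------------------------------
# monolayer phantom
# ---------------------------------------------------------------------------

@dataclass
class MonolayerPhantomSpec:
    """Forward model of dual-dye NRVM monolayer fields across pHe levels.

    One field is rendered per (pHe level, isolation).  Each field holds
    ``n_cells / n_isolations`` disk nuclei (rejection-sampled so that nuclei
    and their perinuclear annuli stay apart).  Ground-truth per-cell pH:

        pHc = pHc_intercept + pHc_slope * pHe + isolation offset + cell jitter
        pHn = pHc + (dpnc_intercept + dpnc_slope * pHe)

    The H34580 440/490 ratio encodes pHn inside nuclei; the cSNARF1 580/640
    ratio encodes pHc in the surrounding cytoplasm (covering the annular
    zone).  Channels get additive Gaussian noise of SD ``photon_noise_sd``.
    """

    image_shape: Tuple[int, int] = (640, 640)
    n_cells: int = 500                      # total per pHe level, across isolations
    nucleus_radius_px: Tuple[float, float] = (8.0, 1.0)   # mean, SD
    true_pHc_model: Tuple[float, float] = (4.9, 0.3)      # intercept, slope vs pHe
    true_dpnc_model: Tuple[float, float] = (0.82, -0.1)   # intercept, slope vs pHe
    pHe_levels: Sequence[float] = (6.24, 6.54, 6.84, 7.14, 7.44)
    curve_h34580: CalibrationCurve = field(default_factory=default_h34580_curve)
    curve_snarf: CalibrationCurve = field(default_factory=default_snarf_curve)
    photon_noise_sd: float = 2.0
    base_intensity: float = 120.0           # denominator-band level inside cells
    n_isolations: int = 5
    cell_jitter_sd: float = 0.03            # pH units, per cell
    isolation_sd: float = 0.02              # pH units, per isolation (shared across levels)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_isolations < 1:
            raise ValueError("n_cells and n_isolations must be >= 1")
        if self.nucleus_radius_px[0] <= 0:
            raise ValueError("mean nucleus radius must be > 0")
        if len(self.pHe_levels) == 0:
            raise ValueError("pHe_levels must be non-empty")
        for curve in (self.curve_h34580, self.curve_snarf):
            lo, hi = sorted((curve.r_min, curve.r_max))
            for pHe in self.pHe_levels:
                # crude range check: both compartment pH stay invertible
                # (logistic curves are invertible everywhere, asymptotes excluded)
                r = pH_to_ratio(curve, pHe)
                if not (lo < r < hi):
                    raise ValueError("pHe level outside the dye curve's invertible range")


def _place_nuclei(
    rng: np.random.Generator,
    shape: Tuple[int, int],
    n: int,
    radius_mean: float,
    radius_sd: float,
    *,
    max_tries_per_cell: int = 400,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rejection-sample non-overlapping disk nuclei; returns (cy, cx, r).

    Centres are kept at least ``r_i + r_j + 2 * radius_mean + 2`` apart so
    that perinuclear annuli (width = mean radius) stay essentially disjoint.
    """
    rows, cols = shape
    margin = 3.0 * radius_mean + radius_sd * 3 + 2
    cys: List[float] = []
    cxs: List[float] = []
    rs: List[float] = []
    for _ in range(n):
        placed = False
        for _ in range(max_tries_per_cell):
            r = float(np.clip(rng.normal(radius_mean, radius_sd),
                              max(2.0, radius_mean - 3 * radius_sd),
                              radius_mean + 3 * radius_sd))
            cy = rng.uniform(margin, rows - margin)
            cx = rng.uniform(margin, cols - margin)
            ok = True
            for py, px, pr in zip(cys, cxs, rs):
                min_d = r + pr + 2.0 * radius_mean + 2.0
                if (cy - py) ** 2 + (cx - px) ** 2 < min_d**2:
                    ok = False
                    break
            if ok:
                cys.append(cy)
                cxs.append(cx)
                rs.append(r)
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place {n} non-overlapping nuclei in {shape} "
                f"after {max_tries_per_cell} tries per cell"
            )
    return np.array(cys), np.array(cxs), np.array(rs)


def _render_field(
    rng: np.random.Generator,
    spec: MonolayerPhantomSpec,
    cy: np.ndarray,
    cx: np.ndarray,
    rad: np.ndarray,
    pHn: np.ndarray,
    pHc: np.ndarray,
) -> Dict[str, np.ndarray]:
    """Paint the four emission channels for one field."""
    rows, cols = spec.image_shape
    B = spec.base_intensity
    mean_r = float(np.mean(rad))
    cyto_extent = 2.0 * mean_r  # cytoplasm reaches this far beyond the nucleus

    ch = {name: np.zeros((rows, cols)) for name in ("440", "490", "580", "640")}
    # distance-to-chosen-centre map so contested cytoplasm goes to the nearest cell
    dist_best = np.full((rows, cols), np.inf)
    owner_pHc = np.zeros((rows, cols))
    in_cyto = np.zeros((rows, cols), dtype=bool)
    nucleus_any = np.zeros((rows, cols), dtype=bool)

    r_h = pH_to_ratio(spec.curve_h34580, pHn)
    r_s_cell = pH_to_ratio(spec.curve_snarf, pHc)

    for i in range(cy.size):
        r_out = rad[i] + cyto_extent
        y0, y1 = int(max(0, cy[i] - r_out - 1)), int(min(rows, cy[i] + r_out + 2))
        x0, x1 = int(max(0, cx[i] - r_out - 1)), int(min(cols, cx[i] + r_out + 2))
        yy, xx = np.mgrid[y0:y1, x0:x1].astype(float)
        d = np.sqrt((yy - cy[i]) ** 2 + (xx - cx[i]) ** 2)
        nuc = d <= rad[i]
        cyt = d <= r_out
        win = (slice(y0, y1), slice(x0, x1))

        nucleus_any[win] |= nuc
        ch["490"][win][nuc] = B
        ch["440"][win][nuc] = r_h[i] * B

        closer = cyt & (d < dist_best[win])
        db = dist_best[win]
        db[closer] = d[closer]
        dist_best[win] = db
        op = owner_pHc[win]
        op[closer] = r_s_cell[i]
        owner_pHc[win] = op
        ic = in_cyto[win]
        ic[closer] = True
        in_cyto[win] = ic

    cyto = in_cyto & ~nucleus_any
    ch["640"][cyto] = B
    ch["580"][cyto] = owner_pHc[cyto] * B

    if spec.photon_noise_sd > 0:
        for name in ("440", "490", "580", "640"):
            ch[name] = ch[name] + rng.normal(
                0.0, spec.photon_noise_sd, size=(rows, cols)
            )
    return ch


def generate_monolayer(
    spec: MonolayerPhantomSpec,
) -> Tuple[Dict[Tuple[float, int], Dict[str, np.ndarray]], pd.DataFrame]:
    """Render all fields and the CellTruth table.

    Returns
    -------
    fields:
        Mapping ``(pHe_level, isolation_id) -> {"440": img, "490": img,
        "580": img, "640": img}``.
    truth:
        DataFrame with one row per cell: condition (pHe), isolation, cell,
        field row/col centre, radius, true pHn, pHc, dpnc.
    """
    rng = np.random.default_rng(spec.seed)
    n_per_field = int(np.ceil(spec.n_cells / spec.n_isolations))
    iso_offsets = rng.normal(0.0, spec.isolation_sd, size=spec.n_isolations)

    a_c, b_c = spec.true_pHc_model
    a_d, b_d = spec.true_dpnc_model

    fields: Dict[Tuple[float, int], Dict[str, np.ndarray]] = {}
    rows_out: List[dict] = []
    cell_counter = 0
    for pHe in spec.pHe_levels:
        dpnc_true = a_d + b_d * pHe
        for iso in range(spec.n_isolations):
            cy, cx, rad = _place_nuclei(
                rng, spec.image_shape, n_per_field,
                spec.nucleus_radius_px[0], spec.nucleus_radius_px[1],
            )
            jitter = rng.normal(0.0, spec.cell_jitter_sd, size=n_per_field)
            pHc = a_c + b_c * pHe + iso_offsets[iso] + jitter
            pHn = pHc + dpnc_true
            fields[(pHe, iso)] = _render_field(rng, spec, cy, cx, rad, pHn, pHc)
            for i in range(n_per_field):
                rows_out.append(
                    dict(
                        condition=pHe,
                        isolation=iso,
                        cell=cell_counter,
                        centre_row=cy[i],
                        centre_col=cx[i],
                        radius=rad[i],
                        pHn=pHn[i],
                        pHc=pHc[i],
                        dpnc=pHn[i] - pHc[i],
                    )
                )
                cell_counter += 1
    return fields, pd.DataFrame(rows_out)


# ---------------------------------------------------------------------------
# omics tables
# ---------------------------------------------------------------------------

@dataclass
class OmicsTableSpec:
    """Generative model for DEG / DAP / peak-presence / TSS tables.

    True DEGs get a signed log2 fold-change of mean magnitude ``effect_size``
    and p-values concentrated near zero (Beta(1, p_alt_beta_b)); null genes
    get p ~ Uniform(0, 1) and small, sign-free fold-changes.  Matched DAPs
    share their DEG's direction with probability ``concordance_prob``.  Union
    peaks live on "chr2" with Bernoulli presence flags per condition
    (rejection-sampled so every peak is present somewhere); promoter peaks
    for a ``promoter_overlap_prob`` fraction of genes are placed inside the
    gene's promoter window on "chr1", where TSSs sit on a jittered grid so
    windows never collide.
    """

    n_genes: int = 2000
    frac_down: float = 0.03
    frac_up: float = 0.03
    effect_size: float = 1.5          # mean |log2FC| of true DEGs
    p_alt_beta_b: float = 2000.0      # alternative p ~ Beta(1, b)
    null_lfc_sd: float = 0.15
    n_matched_proteins: int = 100
    concordance_prob: float = 0.9
    peak_conditions: Sequence[str] = ("pH7.4", "pH6.4", "p300i")
    presence_probs: Mapping[str, float] = field(
        default_factory=lambda: {"pH7.4": 0.87, "pH6.4": 0.71, "p300i": 0.42}
    )
    n_background_peaks: int = 2000
    promoter_overlap_prob: float = 2.0 / 3.0
    promoter_window_bp: int = 2000
    genome_length: int = 100_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [self.frac_down, self.frac_up, self.concordance_prob,
                 self.promoter_overlap_prob, *self.presence_probs.values()]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.frac_down + self.frac_up > 1.0:
            raise ValueError("frac_down + frac_up must be <= 1")
        if set(self.presence_probs) != set(self.peak_conditions):
            raise ValueError("presence_probs must cover exactly peak_conditions")
        if self.genome_length <= 2 * self.promoter_window_bp:
            raise ValueError("genome_length too small for promoter windows")


def _draw_presence(
    rng: np.random.Generator, probs: Sequence[float], n: int
) -> np.ndarray:
    """Bernoulli presence flags per condition, conditioned on >= 1 present."""
    probs = np.asarray(probs, dtype=float)
    flags = np.zeros((n, probs.size), dtype=bool)
    for i in range(n):
        while True:
            row = rng.random(probs.size) < probs
            if row.any():
                flags[i] = row
                break
    return flags


def generate_omics_tables(
    spec: OmicsTableSpec,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (deg_table, dap_table, peak_table, tss_table).

    ``deg_table``/``dap_table``: columns id, log2fc, pvalue (+ fraction and
    true_direction bookkeeping columns; downstream code ignores the latter).
    ``peak_table``: chrom, start, end plus one boolean column per condition.
    ``tss_table``: gene, chrom, tss (0-based), strand.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    ids = np.array([f"g{i:06d}" for i in range(n)])

    n_down = int(round(spec.frac_down * n))
    n_up = int(round(spec.frac_up * n))
    direction = np.zeros(n, dtype=int)            # -1 down, +1 up, 0 null
    order = rng.permutation(n)
    direction[order[:n_down]] = -1
    direction[order[n_down:n_down + n_up]] = 1

    lfc = rng.normal(0.0, spec.null_lfc_sd, size=n)
    magnitude = np.clip(
        rng.normal(spec.effect_size, spec.effect_size / 4.0, size=n),
        0.1 * spec.effect_size, None,
    )
    true_mask = direction != 0
    lfc[true_mask] = direction[true_mask] * magnitude[true_mask]

    p = rng.uniform(0.0, 1.0, size=n)
    p[true_mask] = rng.beta(1.0, spec.p_alt_beta_b, size=int(true_mask.sum()))

    deg_table = pd.DataFrame(
        {"id": ids, "log2fc": lfc, "pvalue": p, "true_direction": direction}
    )

    # matched proteins: sampled from the true DEGs, direction flipped with
    # probability (1 - concordance_prob)
    true_ids = ids[true_mask]
    n_matched = min(spec.n_matched_proteins, true_ids.size)
    chosen = rng.choice(true_ids.size, size=n_matched, replace=False)
    prot_ids = true_ids[chosen]
    gene_dir = direction[true_mask][chosen]
    flip = rng.random(n_matched) >= spec.concordance_prob
    prot_dir = np.where(flip, -gene_dir, gene_dir)
    prot_mag = np.clip(
        rng.normal(spec.effect_size, spec.effect_size / 4.0, size=n_matched),
        0.1 * spec.effect_size, None,
    )
    dap_table = pd.DataFrame(
        {
            "id": prot_ids,
            "log2fc": prot_dir * prot_mag,
            "pvalue": rng.beta(1.0, spec.p_alt_beta_b, size=n_matched),
            "fraction": "F_S",
            "true_direction": prot_dir,
        }
    )

    # TSS grid on chr1: windows can never collide, so promoter overlap is a
    # clean Bernoulli(promoter_overlap_prob) per gene
    w = spec.promoter_window_bp
    spacing = spec.genome_length // n
    if spacing <= 2 * w + 400:
        raise ValueError("genome too short for non-colliding promoter windows")
    jitter_cap = min(5000, (spacing - 2 * w - 400) // 2)
    base = np.arange(n) * spacing + spacing // 2
    tss = base + rng.integers(-jitter_cap, jitter_cap + 1, size=n)
    strand = np.where(rng.random(n) < 0.5, "+", "-")
    tss_table = pd.DataFrame(
        {"gene": ids, "chrom": "chr1", "tss": tss, "strand": strand}
    )

    conds = list(spec.peak_conditions)
    probs = [spec.presence_probs[c] for c in conds]

    # promoter peaks on chr1 for a random subset of genes
    has_peak = rng.random(n) < spec.promoter_overlap_prob
    prom_idx = np.where(has_peak)[0]
    prom_start = tss[prom_idx] - 150
    prom_end = tss[prom_idx] + 150
    prom_flags = _draw_presence(rng, probs, prom_idx.size)

    # background peaks on chr2 (never overlap promoter windows)
    n_bg = spec.n_background_peaks
    bg_start = rng.integers(0, spec.genome_length - 1000, size=n_bg)
    bg_width = rng.integers(200, 801, size=n_bg)
    bg_end = bg_start + bg_width
    bg_flags = _draw_presence(rng, probs, n_bg)

    peak_table = pd.DataFrame(
        {
            "chrom": np.concatenate(
                [np.full(prom_idx.size, "chr1"), np.full(n_bg, "chr2")]
            ),
            "start": np.concatenate([prom_start, bg_start]).astype(int),
            "end": np.concatenate([prom_end, bg_end]).astype(int),
        }
    )
    flags = np.vstack([prom_flags, bg_flags])
    for j, c in enumerate(conds):
        peak_table[c] = flags[:, j]
    if (peak_table["start"] < 0).any():
        peak_table["start"] = peak_table["start"].clip(lower=0)
    return deg_table, dap_table, peak_table, tss_table
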