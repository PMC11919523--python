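"""Reduction of 2-D WAXD detector frames to fibril-strain line scans.

Each scan point yields one detector frame.  A cake-shaped azimuthal sector
around the (002) chitin reflection is integrated to a radial intensity
profile I(q); the (002) peak is fitted with a Gaussian on a linear
background, giving the peak position ``q_002`` and lattice spacing
``D_002 = 2 pi / q_002``.  Percentage shifts of ``D_002`` relative to a
site-matched unloaded reference are the axial fibril strain.  The total
scattered intensity over 11.85-19.05 nm^-1 locates the specimen along the
scan and separates exocuticle from endocuticle.

Units: q in nm^-1, D in nm, strains in percent, detector lengths in mm,
pixel pitch in um.  Pixel coordinates are 0-based with the origin at the
top-left corner; a pixel coordinate is (x, y) = (column, row).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import lmfit
import numpy as np
import pandas as pd

__all__ = [
    "DetectorGeometry",
    "DetectorFrame",
    "RadialProfile",
    "PeakFit",
    "LineScan",
    "PrestrainProfile",
    "pilatus_geometry",
    "mini_geometry",
    "pixel_to_q",
    "cake_integrate",
    "fit_peak_002",
    "fibril_strain",
    "segment_scan",
    "prestrain_profile",
    "prestress_equivalent",
    "reduce_scan",
    "attach_strain",
    "reduce_manifest",
    "load_geometry",
]

#: hc in keV * nm
_HC_KEV_NM = 1.23984

#: intensity-map window used to locate the specimen (nm^-1)
INTENSITY_WINDOW = (11.85, 19.05)

#: default (002) fit window (nm^-1); the peak sits near 12.15-12.25
FIT_WINDOW_002 = (11.8, 12.6)


@dataclass(frozen=True)
class DetectorGeometry:
    """Flat detector normal to the beam.

    ``beam_center_px`` is (x, y) in pixel units and may lie outside the
    active area (offset detector).  ``shape`` is the numpy array shape
    (rows, columns).
    """

    distance_mm: float
    pixel_um: float
    beam_center_px: tuple[float, float]
    energy_keV: float
    shape: tuple[int, int]

    def __post_init__(self) -> None:
        if self.distance_mm <= 0 or self.pixel_um <= 0 or self.energy_keV <= 0:
            raise ValueError("distance, pixel size and energy must be > 0")

    @property
    def wavelength_nm(self) -> float:
        return _HC_KEV_NM / self.energy_keV


def pilatus_geometry(
    distance_mm: float = 150.0,
    beam_center_px: tuple[float, float] = (737.0, 839.0),
    energy_keV: float = 14.0,
) -> DetectorGeometry:
    """Pilatus P3-2M-like geometry: 1475 x 1679 pixels of 172 um."""
    return DetectorGeometry(
        distance_mm=distance_mm,
        pixel_um=172.0,
        beam_center_px=beam_center_px,
        energy_keV=energy_keV,
        shape=(1679, 1475),
    )


def mini_geometry(
    distance_mm: float = 230.0,
    beam_center_px: tuple[float, float] = (-200.0, 31.5),
    energy_keV: float = 14.0,
    shape: tuple[int, int] = (64, 64),
) -> DetectorGeometry:
    """Small offset-detector geometry for fast synthetic studies.

    The beam centre sits well outside the 64 x 64 active area so the frame
    samples a narrow annulus at large radius: the (002) ring crosses the
    frame nearly radially with fine effective q resolution despite the tiny
    pixel count.
    """
    return DetectorGeometry(
        distance_mm=distance_mm,
        pixel_um=172.0,
        beam_center_px=beam_center_px,
        energy_keV=energy_keV,
        shape=shape,
    )


@dataclass
class DetectorFrame:
    """Photon-count image with an optional validity mask (True = use pixel)."""

    data: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("frame must be a 2-D array")
        if np.any(self.data < 0):
            raise ValueError("frame counts must be non-negative")
        if self.mask is not None and self.mask.shape != self.data.shape:
            raise ValueError("mask shape must match frame shape")


_MAP_CACHE: dict[DetectorGeometry, tuple[np.ndarray, np.ndarray]] = {}


def _pixel_maps(geometry: DetectorGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel scattering vector q (nm^-1) and azimuth (deg, [0, 360))."""
    cached = _MAP_CACHE.get(geometry)
    if cached is not None:
        return cached
    rows, cols = geometry.shape
    cx, cy = geometry.beam_center_px
    x = (np.arange(cols) - cx) * geometry.pixel_um / 1000.0   # mm
    y = (np.arange(rows) - cy) * geometry.pixel_um / 1000.0
    xx, yy = np.meshgrid(x, y)
    r = np.hypot(xx, yy)
    two_theta = np.arctan2(r, geometry.distance_mm)
    q = (4.0 * math.pi / geometry.wavelength_nm) * np.sin(two_theta / 2.0)
    az = np.degrees(np.arctan2(yy, xx)) % 360.0
    _MAP_CACHE[geometry] = (q, az)
    return q, az


def pixel_to_q(geometry: DetectorGeometry, pixel) -> np.ndarray | float:
    """Scattering vector magnitude q (nm^-1) at pixel (x, y).

    q = (4 pi / lambda) sin(theta) with 2 theta = atan(r / distance) and r
    the radial distance from the beam centre in mm.
    """
    px = np.asarray(pixel, dtype=float)
    x = (px[..., 0] - geometry.beam_center_px[0]) * geometry.pixel_um / 1000.0
    y = (px[..., 1] - geometry.beam_center_px[1]) * geometry.pixel_um / 1000.0
    r = np.hypot(x, y)
    two_theta = np.arctan2(r, geometry.distance_mm)
    q = (4.0 * math.pi / geometry.wavelength_nm) * np.sin(two_theta / 2.0)
    return float(q) if q.ndim == 0 else q


@dataclass
class RadialProfile:
    """Azimuthally averaged intensity on a uniform q grid.

    Bins with no contributing pixels keep ``counts == 0`` and NaN intensity;
    they are flagged, never zero-filled.
    """

    q: np.ndarray
    intensity: np.ndarray
    counts: np.ndarray
    q_eff: np.ndarray | None = None

    @property
    def nonempty(self) -> np.ndarray:
        return self.counts > 0

    @property
    def q_fit(self) -> np.ndarray:
        """Abscissa for peak fitting: mean pixel q per bin when available.

        The mean of the contributing pixels' q values removes most of the
        sub-bin quantisation bias of the geometric bin centre, which
        otherwise rescales small peak shifts by ~1%.
        """
        return self.q if self.q_eff is None else self.q_eff


def cake_integrate(
    frame: DetectorFrame,
    geometry: DetectorGeometry,
    q_window: tuple[float, float] = (11.0, 20.0),
    azimuth_deg: float | None = None,
    half_width_deg: float = 15.0,
    n_bins: int = 400,
) -> RadialProfile:
    """Mean intensity per q bin over a pooled pair of opposite azimuthal sectors.

    The sector is centred on ``azimuth_deg`` (and its mirror at +180 deg);
    when None, the azimuth of the brightest pixel inside ``q_window`` is
    used, which centres the cake on the (002) arc meridian.
    """
    q, az = _pixel_maps(geometry)
    valid = np.ones(frame.data.shape, dtype=bool) if frame.mask is None else frame.mask
    in_window = (q >= q_window[0]) & (q <= q_window[1]) & valid
    if not np.any(in_window):
        raise ValueError("no valid pixels inside the q window")
    if azimuth_deg is None:
        idx = np.unravel_index(
            np.argmax(np.where(in_window, frame.data, -np.inf)), frame.data.shape
        )
        azimuth_deg = float(az[idx])
    d1 = np.abs((az - azimuth_deg + 180.0) % 360.0 - 180.0)
    d2 = np.abs((az - azimuth_deg) % 360.0 - 180.0)
    sector = in_window & ((d1 <= half_width_deg) | (d2 <= half_width_deg))
    if not np.any(sector):
        raise ValueError("azimuthal sector contains no valid pixels")
    edges = np.linspace(q_window[0], q_window[1], n_bins + 1)
    qs = q[sector]
    vals = frame.data[sector]
    counts, _ = np.histogram(qs, bins=edges)
    sums, _ = np.histogram(qs, bins=edges, weights=vals)
    qsums, _ = np.histogram(qs, bins=edges, weights=qs)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    q_eff = np.where(counts > 0, qsums / np.maximum(counts, 1), centers)
    return RadialProfile(q=centers, intensity=mean, counts=counts, q_eff=q_eff)


@dataclass
class PeakFit:
    """Gaussian-plus-linear-background fit of the (002) reflection."""

    q0: float
    sigma: float
    amplitude: float
    c0: float
    c1: float
    residual_norm: float
    converged: bool

    @property
    def D_nm(self) -> float:
        """Lattice spacing 2 pi / q0 (exact identity with q0)."""
        return 2.0 * math.pi / self.q0 if self.q0 > 0 else float("nan")


_FAILED_FIT = dict(q0=float("nan"), sigma=float("nan"), amplitude=float("nan"),
                   c0=float("nan"), c1=float("nan"), residual_norm=float("inf"))


def fit_peak_002(
    profile: RadialProfile,
    window: tuple[float, float] = FIT_WINDOW_002,
    min_bins: int = 8,
) -> PeakFit:
    """Nonlinear least-squares fit a exp(-(q-q0)^2 / 2 sigma^2) + c0 + c1 q.

    Initial values come from background-subtracted moments of the window.
    Degenerate input (too few non-empty bins, vanishing signal, optimizer
    failure, or a peak centre escaping the window) yields
    ``converged=False`` rather than an exception, so scan points outside the
    specimen propagate as missing values.
    """
    sel = profile.nonempty & (profile.q >= window[0]) & (profile.q <= window[1])
    if np.count_nonzero(sel) < min_bins:
        return PeakFit(converged=False, **_FAILED_FIT)
    q = profile.q_fit[sel]
    y = profile.intensity[sel]

    k = max(3, len(y) // 8)
    bg = 0.5 * (float(np.median(y[:k])) + float(np.median(y[-k:])))
    sig = y - bg
    if not np.any(sig > 0) or float(np.max(sig)) <= 0:
        return PeakFit(converged=False, **_FAILED_FIT)
    w = np.clip(sig, 0, None)
    q0_init = float(np.sum(w * q) / np.sum(w))
    var = float(np.sum(w * (q - q0_init) ** 2) / np.sum(w))
    sigma_init = min(max(math.sqrt(max(var, 1e-8)), 0.005), (window[1] - window[0]) / 2)

    model = lmfit.models.GaussianModel() + lmfit.models.LinearModel()
    params = model.make_params()
    params["center"].set(value=q0_init, min=window[0], max=window[1])
    params["sigma"].set(value=sigma_init, min=1e-4, max=window[1] - window[0])
    params["amplitude"].set(
        value=float(np.max(sig)) * sigma_init * math.sqrt(2 * math.pi), min=0.0
    )
    params["intercept"].set(value=bg)
    params["slope"].set(value=0.0)
    try:
        result = model.fit(y, params, x=q)
    except Exception:
        return PeakFit(converged=False, **_FAILED_FIT)

    q0 = float(result.params["center"].value)
    height = float(result.params["height"].value)
    noise = float(np.std(result.residual)) if result.residual is not None else 0.0
    ok = (
        bool(result.success)
        and window[0] + 1e-9 < q0 < window[1] - 1e-9
        and height > max(5.0 * noise, 1e-12)
    )
    return PeakFit(
        q0=q0,
        sigma=float(result.params["sigma"].value),
        amplitude=float(result.params["amplitude"].value),
        c0=float(result.params["intercept"].value),
        c1=float(result.params["slope"].value),
        residual_norm=float(np.linalg.norm(result.residual)),
        converged=ok,
    )


def fibril_strain(fit: PeakFit, ref_fit: PeakFit) -> float:
    """Axial fibril strain in % from the (002) peak shift.

    strain% = 100 (D - D_ref)/D_ref = 100 (q_ref/q0 - 1).  Unconverged
    input propagates as NaN.
    """
    if not (fit.converged and ref_fit.converged):
        return float("nan")
    return 100.0 * (ref_fit.q0 / fit.q0 - 1.0)


def prestress_equivalent(prestrain_pct: float, E_fibril_GPa: float = 120.0) -> float:
    """Axial fibril stress (MPa) equivalent to a pre-strain, sigma = eps * E_F.

    The default 120 GPa is the axial chitin crystal modulus from density
    functional theory.
    """
    return prestrain_pct / 100.0 * E_fibril_GPa * 1000.0


def segment_scan(
    intensity,
    t1_fraction: float,
    exo_side: str = "start",
    threshold: float | None = None,
):
    """Locate the cuticle along a line scan and assign layer labels and depth.

    The specimen is the longest contiguous run of points whose total WAXD
    intensity exceeds ``threshold`` (default: 3x the median of the three
    lowest-intensity points, i.e. background).  Normalised depth runs from 0
    at the exocuticle surface to 1 at the inner endocuticle surface;
    ``exo_side`` states which scan end the exocuticle faces.  Points with
    depth below ``t1_fraction`` are exocuticle, the rest endocuticle.

    Returns ``(labels, depth)``: labels in {"outside", "exocuticle",
    "endocuticle"} and NaN depth outside the specimen.
    """
    inten = np.asarray(intensity, dtype=float)
    if len(inten) < 5:
        raise ValueError("scan needs at least 5 points")
    if exo_side not in ("start", "end"):
        raise ValueError("exo_side must be 'start' or 'end'")
    if not 0 < t1_fraction < 1:
        raise ValueError("t1_fraction must lie in (0, 1)")
    if threshold is None:
        low3 = np.sort(inten)[:3]
        threshold = 3.0 * float(np.median(low3))
    above = inten > threshold
    if not np.any(above):
        raise ValueError(
            "no sample found: no scan point exceeds the intensity threshold"
        )
    best_len, best_start, run_start = 0, 0, None
    for i, a in enumerate(np.append(above, False)):
        if a and run_start is None:
            run_start = i
        elif not a and run_start is not None:
            if i - run_start > best_len:
                best_len, best_start = i - run_start, run_start
            run_start = None
    i0, i1 = best_start, best_start + best_len - 1

    labels = np.array(["outside"] * len(inten), dtype=object)
    depth = np.full(len(inten), np.nan)
    idx = np.arange(i0, i1 + 1)
    frac = (idx - i0) / max(i1 - i0, 1)
    if exo_side == "end":
        frac = 1.0 - frac
    depth[idx] = frac
    labels[idx] = np.where(frac < t1_fraction, "exocuticle", "endocuticle")
    return labels, depth


@dataclass
class LineScan:
    """Reduced line scan: one row per scan point.

    Columns: position_um, q0, sigma, amplitude, D_nm, intensity, converged,
    label, depth_norm and (after :func:`attach_strain`) strain_pct.
    """

    points: pd.DataFrame
    step_pct: float = 0.0
    fits: list = field(default_factory=list, repr=False)

    def cuticle(self) -> pd.DataFrame:
        return self.points[self.points["label"] != "outside"]


def reduce_scan(
    frames,
    positions_um,
    geometry: DetectorGeometry,
    *,
    step_pct: float = 0.0,
    t1_fraction: float = 0.35,
    exo_side: str = "start",
    fit_window: tuple[float, float] = FIT_WINDOW_002,
    half_width_deg: float = 15.0,
    n_bins: int = 400,
) -> LineScan:
    """Reduce an ordered list of frames at scan positions to a LineScan."""
    records, fits = [], []
    for frame, pos in zip(frames, positions_um):
        profile = cake_integrate(
            frame, geometry, half_width_deg=half_width_deg, n_bins=n_bins
        )
        sel = (
            profile.nonempty
            & (profile.q >= INTENSITY_WINDOW[0])
            & (profile.q <= INTENSITY_WINDOW[1])
        )
        total = float(np.sum(profile.intensity[sel] * profile.counts[sel]))
        fit = fit_peak_002(profile, window=fit_window)
        fits.append(fit)
        records.append(
            dict(
                position_um=float(pos),
                q0=fit.q0,
                sigma=fit.sigma,
                amplitude=fit.amplitude,
                D_nm=fit.D_nm,
                intensity=total,
                converged=fit.converged,
            )
        )
    df = pd.DataFrame.from_records(records)
    labels, depth = segment_scan(df["intensity"].to_numpy(), t1_fraction, exo_side)
    df["label"] = labels
    df["depth_norm"] = depth
    return LineScan(points=df, step_pct=step_pct, fits=fits)


def attach_strain(scan: LineScan, reference: LineScan) -> LineScan:
    """Fibril strain per point against the site-matched unloaded reference.

    Matching is by nearest normalised depth in the step-0 scan (successive
    scans are laterally offset, so exact site identity is impossible).
    """
    ref = reference.points
    ref_ok = ref[(ref["label"] != "outside") & ref["converged"]]
    strains = []
    for _, row in scan.points.iterrows():
        if row["label"] == "outside" or not row["converged"] or len(ref_ok) == 0:
            strains.append(float("nan"))
            continue
        i_ref = (ref_ok["depth_norm"] - row["depth_norm"]).abs().idxmin()
        q_ref = ref_ok.loc[i_ref, "q0"]
        strains.append(100.0 * (q_ref / row["q0"] - 1.0))
    scan.points["strain_pct"] = strains
    return scan


@dataclass
class PrestrainProfile:
    """Through-thickness % change of D_002 relative to the exocuticle surface."""

    depth_norm: np.ndarray
    delta_pct: np.ndarray
    labels: np.ndarray
    exo_mean_pct: float
    endo_mean_pct: float

    @property
    def endo_minus_exo_pct(self) -> float:
        return self.endo_mean_pct - self.exo_mean_pct


def prestrain_profile(scan: LineScan, min_valid: int = 3) -> PrestrainProfile:
    """Pre-strain gradient from an unloaded (step-0) segmented line scan.

    Delta%(z) = 100 (D(z) - D(0)) / D(0) with D(0) the first converged
    point at the exocuticle surface.  Layer means require at least
    ``min_valid`` converged points each.
    """
    cut = scan.cuticle()
    valid = cut[cut["converged"]].sort_values("depth_norm")
    if len(valid) == 0:
        raise ValueError("no converged fits inside the cuticle")
    if valid.index[0] != cut.sort_values("depth_norm").index[0]:
        warnings.warn(
            "surface fit unconverged; using first converged point as reference",
            stacklevel=2,
        )
    d0 = float(valid.iloc[0]["D_nm"])
    delta = 100.0 * (valid["D_nm"].to_numpy() - d0) / d0
    labels = valid["label"].to_numpy()
    means = {}
    for layer in ("exocuticle", "endocuticle"):
        vals = delta[labels == layer]
        means[layer] = float(np.mean(vals)) if len(vals) >= min_valid else float("nan")
    return PrestrainProfile(
        depth_norm=valid["depth_norm"].to_numpy(),
        delta_pct=delta,
        labels=labels,
        exo_mean_pct=means["exocuticle"],
        endo_mean_pct=means["endocuticle"],
    )


def load_geometry(path) -> DetectorGeometry:
    """Read a detector geometry from a TOML or YAML config file."""
    path = Path(path)
    if path.suffix == ".toml":
        import tomllib

        cfg = tomllib.loads(path.read_text())
    else:
        import yaml

        cfg = yaml.safe_load(path.read_text())
    return DetectorGeometry(
        distance_mm=float(cfg["distance_mm"]),
        pixel_um=float(cfg["pixel_um"]),
        beam_center_px=tuple(float(v) for v in cfg["beam_center_px"]),
        energy_keV=float(cfg["energy_keV"]),
        shape=tuple(int(v) for v in cfg["shape"]),
    )


def reduce_manifest(
    manifest,
    geometry: DetectorGeometry,
    frames_dir=None,
    *,
    t1_fraction: float = 0.35,
    exo_side: str = "start",
    **kwargs,
) -> dict[float, LineScan]:
    """Reduce a whole scan manifest (frame, step_pct, position_um) to LineScans.

    ``manifest`` is a DataFrame or CSV path; frame paths are resolved
    relative to ``frames_dir``.  Fibril strain is attached to every loaded
    step using the step-0 scan as reference.
    """
    import tifffile

    if not isinstance(manifest, pd.DataFrame):
        manifest_path = Path(manifest)
        if frames_dir is None:
            frames_dir = manifest_path.parent
        manifest = pd.read_csv(manifest_path)
    frames_dir = Path(frames_dir) if frames_dir is not None else Path(".")

    scans: dict[float, LineScan] = {}
    for step, group in manifest.groupby("step_pct"):
        group = group.sort_values("position_um")
        frames = [
            DetectorFrame(tifffile.imread(frames_dir / f)) for f in group["frame"]
        ]
        scans[float(step)] = reduce_scan(
            frames,
            group["position_um"].to_numpy(),
            geometry,
            step_pct=float(step),
            t1_fraction=t1_fraction,
            exo_side=exo_side,
            **kwargs,
        )
    if 0.0 in scans:
        for scan in scans.values():
            attach_strain(scan, scans[0.0])
    return scans
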