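"""Seeded synthetic scanning-WAXD datasets with known ground truth.

A phantom emulates a curved bilayer cuticle specimen under stepwise
compression or tension: a through-thickness (002) lattice-spacing gradient
(the fibril pre-strain), tissue strains from the large-deflection beam
forward model, fibril strains through a prescribed strain-concentration
factor, detector frames with Poisson counting noise, a scan manifest, and a
stepwise load-relaxation trace.  Every artefact is a pure function of
``(PhantomSpec, seed)``, so downstream reduction and inversion stages can be
tested end to end without any measured data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cuticleflex import beam
from cuticleflex.beam import ArcGeometry, BeamSolution
from cuticleflex.waxd import DetectorFrame, DetectorGeometry, mini_geometry

__all__ = [
    "NoiseModel",
    "PhantomSpec",
    "GroundTruth",
    "default_arc",
    "make_phantom",
    "render_frame",
    "simulate_load_trace",
    "write_dataset",
    "spec_from_config",
]

#: fixed synthetic ring positions for the (110)/(013) reflections (nm^-1);
#: chosen inside the 11.85-19.05 intensity-map window, carrying no strain.
RING_110_NM1 = 13.9
RING_013_NM1 = 17.0


def default_arc() -> ArcGeometry:
    """Default synthetic specimen: shallow circular arc, 5 mm chord.

    Width matches the sectioned-strip preparation (0.7 mm); the exocuticle
    occupies 35% of the 0.5 mm thickness.  The shallow rise makes the
    stepwise load-displacement curve strongly nonlinear, which is what
    renders the layer-modulus ratio identifiable from loads alone.
    """
    return ArcGeometry(
        R_mm=12.0, alpha_rad=0.42, b_mm=0.7, h_mm=0.5, t1_mm=0.175, t2_mm=0.325
    )


@dataclass(frozen=True)
class NoiseModel:
    """Counting and read-out noise for rendered frames plus load-cell noise.

    ``exposure_scale`` multiplies the noiseless photon model before Poisson
    sampling; 0 disables the source entirely (dark frame).  ``read_sigma``
    is additive Gaussian read-out noise in counts.  ``load_sigma_N`` is
    absolute Gaussian noise on the simulated load trace.  ``poisson=False``
    disables counting statistics entirely (ideal noiseless frames).
    """

    exposure_scale: float = 1.0
    read_sigma: float = 1.0
    load_sigma_N: float = 0.0
    poisson: bool = True

    def __post_init__(self) -> None:
        if self.exposure_scale < 0 or self.read_sigma < 0 or self.load_sigma_N < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass(frozen=True)
class PhantomSpec:
    """Complete ground-truth description of a synthetic dataset.

    Pre-strains are mean % changes of D_(002) relative to ``D_ref_nm`` in
    each layer; the through-thickness profile blends between them with a
    smooth logistic transition over ``transition_frac`` of the thickness,
    centred at the layer interface.  ``AF_compression``/``AF_tension`` are
    the ground-truth strain-concentration factors linking tissue strain to
    fibril strain.
    """

    seed: int
    arc: ArcGeometry = field(default_factory=default_arc)
    E1_GPa: float = 24.0
    eta: float = 7.0 / 24.0
    prestrain_exo_pct: float = 0.0
    prestrain_endo_pct: float = 0.15
    D_ref_nm: float = 0.5150
    AF_compression: float = 0.39
    AF_tension: float = 0.33
    strain_steps_pct: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0)
    mode: str = "compression"
    scan_step_um: float = 20.0
    scan_offset_um: float = 25.0
    scan_margin_um: float = 80.0
    transition_frac: float = 0.10
    geometry: DetectorGeometry = field(default_factory=mini_geometry)
    noise: NoiseModel = field(default_factory=NoiseModel)
    peak_amplitude: float = 120.0
    background: float = 2.0
    peak_sigma_nm1: float = 0.06
    azimuth_sigma_deg: float = 20.0
    hold_s: float = 150.0
    relax_tau_s: float = 30.0
    relax_amplitude: float = 0.10

    def __post_init__(self) -> None:
        if not 0 < self.eta <= 1:
            raise ValueError("PhantomSpec.eta must lie in (0, 1]")
        if self.E1_GPa <= 0:
            raise ValueError("PhantomSpec.E1_GPa must be > 0")
        if self.D_ref_nm <= 0:
            raise ValueError("PhantomSpec.D_ref_nm must be > 0")
        steps = self.strain_steps_pct
        if len(steps) < 1 or steps[0] != 0.0 or any(
            b <= a for a, b in zip(steps, steps[1:])
        ):
            raise ValueError(
                "PhantomSpec.strain_steps_pct must be strictly increasing and start at 0"
            )
        if self.mode not in ("compression", "tension"):
            raise ValueError("PhantomSpec.mode must be 'compression' or 'tension'")
        if self.scan_step_um <= 0:
            raise ValueError("PhantomSpec.scan_step_um must be > 0")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("PhantomSpec.seed must be an integer")

    @property
    def sign(self) -> float:
        """Sign of the prescribed chord change (- for compression)."""
        return -1.0 if self.mode == "compression" else 1.0

    def prestrain_at(self, Z_mm) -> np.ndarray:
        """Pre-strain (%) at depth Z from the exocuticle surface.

        Logistic blend centred at the exo/endo interface with a 10-90%
        transition span of ``transition_frac * h``.
        """
        Z = np.asarray(Z_mm, dtype=float)
        s = self.transition_frac * self.arc.h_mm / math.log(81.0)
        lo, hi = self.prestrain_exo_pct, self.prestrain_endo_pct
        return lo + (hi - lo) / (1.0 + np.exp(-(Z - self.arc.t1_mm) / s))

    def AF_true(self) -> float:
        return self.AF_compression if self.mode == "compression" else self.AF_tension


@dataclass
class GroundTruth:
    """Per-frame truth table plus per-step equilibrium loads.

    ``table`` has one record per rendered frame: step_pct, line_index,
    position_um (depth coordinate of the beam), in_sample, prestrain_pct,
    eps_T_pct (true tissue strain), fibril_strain_pct (= AF * eps_T),
    D_nm (true lattice spacing).  ``loads_N`` maps step_pct to the
    equilibrium horizontal load H0.
    """

    table: pd.DataFrame
    loads_N: dict[float, float]
    solutions: dict[float, BeamSolution] = field(default_factory=dict, repr=False)


def _beam_solutions(spec: PhantomSpec) -> dict[float, BeamSolution]:
    arc = spec.arc
    section = beam.section_properties(arc, spec.eta)
    sols: dict[float, BeamSolution] = {}
    guess = None
    for step in spec.strain_steps_pct:
        delta = spec.sign * step / 100.0 * arc.chord_mm
        sol = beam.shoot(arc, section, delta, initial_guess=guess)
        guess = (sol.H_bar, sol.M_apex_bar)
        sols[step] = sol
    return sols


def make_phantom(spec: PhantomSpec) -> tuple[GroundTruth, pd.DataFrame]:
    """Tabulate the ground truth and scan manifest for a phantom spec.

    For each strain step the tissue strain field comes from the beam
    forward model (solved at the prescribed chord change); the fibril
    strain is ``AF * eps_T`` and the rendered lattice spacing is
    ``D_ref * (1 + (prestrain + AF * eps_T)/100)``.  Line scans step
    ``scan_step_um`` through the thickness and successive steps are offset
    ``scan_offset_um`` along the arc.
    """
    arc = spec.arc
    section = beam.section_properties(arc, spec.eta)
    sols = _beam_solutions(spec)
    af = spec.AF_true()

    z_scan = np.arange(
        -spec.scan_margin_um,
        arc.h_mm * 1000.0 + spec.scan_margin_um + 1e-9,
        spec.scan_step_um,
    )
    records, manifest = [], []
    for k, step in enumerate(spec.strain_steps_pct):
        sol = sols[step]
        s_mm = k * spec.scan_offset_um / 1000.0
        for i, z_um in enumerate(z_scan):
            z_mm = z_um / 1000.0
            in_sample = 0.0 <= z_mm <= arc.h_mm
            if in_sample:
                eps_t = float(
                    beam.tissue_strain_field(sol, section, z_mm, s_mm)
                )
                pre = float(spec.prestrain_at(z_mm))
                eps_f = af * eps_t
                d_nm = spec.D_ref_nm * (1.0 + (pre + eps_f) / 100.0)
            else:
                eps_t, pre, eps_f, d_nm = (
                    float("nan"),
                    float("nan"),
                    float("nan"),
                    float("nan"),
                )
            frame_name = f"scan{k}_pt{i:03d}.tif"
            records.append(
                dict(
                    step_pct=step,
                    line_index=i,
                    position_um=float(z_um),
                    in_sample=in_sample,
                    prestrain_pct=pre,
                    eps_T_pct=eps_t,
                    fibril_strain_pct=eps_f,
                    D_nm=d_nm,
                )
            )
            manifest.append(
                dict(
                    frame=frame_name,
                    step_pct=step,
                    position_um=float(z_um),
                    line_index=i,
                )
            )
    loads = {step: sols[step].physical_load_N(spec.E1_GPa) for step in sols}
    truth = GroundTruth(
        table=pd.DataFrame.from_records(records), loads_N=loads, solutions=sols
    )
    return truth, pd.DataFrame.from_records(manifest)


def render_frame(
    true_D_nm: float | None,
    geometry: DetectorGeometry,
    noise: NoiseModel,
    seed,
    *,
    peak_amplitude: float = 120.0,
    background: float = 2.0,
    peak_sigma_nm1: float = 0.06,
    azimuth_sigma_deg: float = 20.0,
    azimuth0_deg: float = 0.0,
) -> DetectorFrame:
    """Render one detector frame; ``true_D_nm=None`` gives a background frame.

    The (002) reflection is an azimuthally arced ring at ``q = 2 pi / D``
    (Gaussian in azimuth about the meridian ``azimuth0_deg``, mirrored at
    +180 deg); fixed isotropic rings near 13.9 and 17.0 nm^-1 stand in for
    the (110)/(013) reflections and carry no strain signal.  Counts are
    Poisson-distributed around the noiseless model with additive Gaussian
    read noise; zero exposure returns an all-zero frame.
    """
    from cuticleflex.waxd import _pixel_maps

    q, az = _pixel_maps(geometry)
    if noise.exposure_scale == 0.0:
        return DetectorFrame(np.zeros(geometry.shape, dtype=np.float32))

    model = np.full(geometry.shape, float(background))
    if true_D_nm is not None:
        for q_ring, amp in ((RING_110_NM1, 0.5 * peak_amplitude),
                            (RING_013_NM1, 0.5 * peak_amplitude)):
            model += amp * np.exp(-((q - q_ring) ** 2) / (2.0 * peak_sigma_nm1**2))
        if true_D_nm <= 0:
            raise ValueError("true_D_nm must be > 0")
        q0 = 2.0 * math.pi / true_D_nm
        if q0 < q.min() + 3 * peak_sigma_nm1 or q0 > q.max() - 3 * peak_sigma_nm1:
            raise ValueError(
                f"(002) ring at q={q0:.3f} nm^-1 falls off the detector "
                f"(frame covers {q.min():.2f}-{q.max():.2f} nm^-1)"
            )
        daz = (az - azimuth0_deg + 180.0) % 360.0 - 180.0
        daz_m = (az - azimuth0_deg) % 360.0 - 180.0
        arc_weight = np.exp(-(daz**2) / (2.0 * azimuth_sigma_deg**2)) + np.exp(
            -(daz_m**2) / (2.0 * azimuth_sigma_deg**2)
        )
        model += (
            peak_amplitude
            * arc_weight
            * np.exp(-((q - q0) ** 2) / (2.0 * peak_sigma_nm1**2))
        )

    rng = np.random.default_rng(seed)
    scaled = model * noise.exposure_scale
    counts = rng.poisson(scaled).astype(np.float64) if noise.poisson else scaled
    if noise.read_sigma > 0:
        counts = counts + rng.normal(0.0, noise.read_sigma, size=counts.shape)
    return DetectorFrame(np.clip(counts, 0.0, None).astype(np.float32))


def simulate_load_trace(
    spec: PhantomSpec,
    truth: GroundTruth | None = None,
    dt_s: float = 1.0,
) -> pd.DataFrame:
    """Stepwise load-displacement-time trace with relaxation holds.

    Ramps run at 0.05% s^-1 macroscopic strain rate; at each hold the load
    relaxes exponentially (time constant ``relax_tau_s``) from
    ``(1 + relax_amplitude)`` times the equilibrium load toward the beam
    model's equilibrium value.  Columns: t_s, displacement_mm, load_N.
    """
    from scipy.interpolate import PchipInterpolator

    if truth is None:
        sols = _beam_solutions(spec)
        loads = {s: sols[s].physical_load_N(spec.E1_GPa) for s in sols}
    else:
        loads = truth.loads_N
    steps = list(spec.strain_steps_pct)
    chord = spec.arc.chord_mm
    deltas = [spec.sign * s / 100.0 * chord for s in steps]
    if len(steps) > 1:
        h_eq = PchipInterpolator(
            np.sort(deltas), np.array([loads[s] for s in steps])[np.argsort(deltas)]
        )
    else:
        h_eq = lambda d: np.full_like(np.asarray(d, dtype=float), loads[steps[0]])
    rate_pct_s = 0.05

    t_list, d_list, l_list = [], [], []
    t = 0.0
    amp = spec.relax_amplitude
    for i, step in enumerate(steps):
        if i > 0:
            ramp_T = (steps[i] - steps[i - 1]) / rate_pct_s
            tt = np.arange(dt_s, ramp_T + 1e-9, dt_s)
            frac = tt / ramp_T
            dd = deltas[i - 1] + frac * (deltas[i] - deltas[i - 1])
            t_list.append(t + tt)
            d_list.append(dd)
            l_list.append(h_eq(dd) * (1.0 + amp))
            t += ramp_T
        tt = np.arange(dt_s, spec.hold_s + 1e-9, dt_s)
        t_list.append(t + tt)
        d_list.append(np.full_like(tt, deltas[i]))
        l_list.append(loads[step] * (1.0 + amp * np.exp(-tt / spec.relax_tau_s)))
        t += spec.hold_s

    trace = pd.DataFrame(
        dict(
            t_s=np.concatenate(t_list),
            displacement_mm=np.concatenate(d_list),
            load_N=np.concatenate(l_list),
        )
    )
    if spec.noise.load_sigma_N > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 9999]))
        trace["load_N"] += rng.normal(0, spec.noise.load_sigma_N, len(trace))
    return trace


def write_dataset(spec: PhantomSpec, outdir) -> dict[str, Path]:
    """Materialise a full phantom dataset on disk.

    Writes 32-bit float TIFF frames (``scan{step}_pt{index}.tif``), the
    scan manifest, the load trace, the ground-truth table and loads, and
    the detector geometry.  Deterministic for identical (spec, seed).
    """
    import tifffile
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth, manifest = make_phantom(spec)

    for rec, frame_name in zip(
        truth.table.itertuples(index=False), manifest["frame"]
    ):
        seed_seq = np.random.SeedSequence(
            [int(spec.seed), int(round(rec.step_pct * 1000)), int(rec.line_index)]
        )
        frame = render_frame(
            rec.D_nm if rec.in_sample else None,
            spec.geometry,
            spec.noise,
            seed_seq,
            peak_amplitude=spec.peak_amplitude,
            background=spec.background,
            peak_sigma_nm1=spec.peak_sigma_nm1,
            azimuth_sigma_deg=spec.azimuth_sigma_deg,
        )
        tifffile.imwrite(outdir / frame_name, frame.data.astype(np.float32))

    manifest.to_csv(outdir / "manifest.csv", index=False)
    trace = simulate_load_trace(spec, truth)
    trace.to_csv(outdir / "loadtrace.csv", index=False)
    truth.table.to_csv(outdir / "ground_truth.csv", index=False)
    (outdir / "ground_truth.json").write_text(
        json.dumps(
            dict(
                loads_N={str(k): v for k, v in truth.loads_N.items()},
                AF_true=spec.AF_true(),
                E1_GPa=spec.E1_GPa,
                eta=spec.eta,
                prestrain_exo_pct=spec.prestrain_exo_pct,
                prestrain_endo_pct=spec.prestrain_endo_pct,
                D_ref_nm=spec.D_ref_nm,
                mode=spec.mode,
                t1_fraction=spec.arc.t1_mm / spec.arc.h_mm,
                seed=int(spec.seed),
            ),
            indent=2,
        )
    )
    geo = spec.geometry
    (outdir / "geometry.yaml").write_text(
        yaml.safe_dump(
            dict(
                distance_mm=geo.distance_mm,
                pixel_um=geo.pixel_um,
                beam_center_px=list(geo.beam_center_px),
                energy_keV=geo.energy_keV,
                shape=list(geo.shape),
            )
        )
    )
    return dict(
        manifest=outdir / "manifest.csv",
        loadtrace=outdir / "loadtrace.csv",
        ground_truth=outdir / "ground_truth.json",
        geometry=outdir / "geometry.yaml",
        outdir=outdir,
    )


def spec_from_config(path) -> PhantomSpec:
    """Build a PhantomSpec from a TOML/YAML config file; ``seed`` is mandatory."""
    path = Path(path)
    if path.suffix == ".toml":
        import tomllib

        cfg = tomllib.loads(path.read_text())
    else:
        import yaml

        cfg = yaml.safe_load(path.read_text())
    if "seed" not in cfg:
        raise ValueError("phantom config must set 'seed'")
    kwargs = dict(cfg)
    if "arc" in kwargs:
        kwargs["arc"] = ArcGeometry(**kwargs["arc"])
    if "geometry" in kwargs:
        g = kwargs["geometry"]
        kwargs["geometry"] = DetectorGeometry(
            distance_mm=float(g["distance_mm"]),
            pixel_um=float(g["pixel_um"]),
            beam_center_px=tuple(g["beam_center_px"]),
            energy_keV=float(g["energy_keV"]),
            shape=tuple(g["shape"]),
        )
    if "noise" in kwargs:
        kwargs["noise"] = NoiseModel(**kwargs["noise"])
    if "strain_steps_pct" in kwargs:
        kwargs["strain_steps_pct"] = tuple(kwargs["strain_steps_pct"])
    return PhantomSpec(**kwargs)
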