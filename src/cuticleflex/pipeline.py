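"""End-to-end orchestration: phantom -> reduction -> inversion -> shear-lag -> stats.

``run_synthetic`` materialises one or more synthetic specimens, reduces
their scans, extracts plateau loads from the simulated traces, inverts the
bilayer beam model for layer moduli, regresses fibril strain on modelled
tissue strain at the first load level for the strain-concentration factor,
and runs the layer-wise statistics.  Every stage writes its intermediate
artefacts (CSV/JSON) so each module can be re-run and inspected on its own.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cuticleflex import beam, phantom, shearlag, stats, waxd

__all__ = ["RunConfig", "run_synthetic", "plateau_loads"]


@dataclass
class RunConfig:
    """Configuration of a full synthetic run.

    Exactly one of ``phantom_spec`` (synthetic mode) or ``manifest``
    (real-data mode; frames + geometry on disk) must be set.
    ``n_samples`` replicate specimens are generated with independent noise
    and a small specimen-to-specimen jitter of the endocuticle pre-strain.
    """

    outdir: Path
    seed: int
    phantom_spec: phantom.PhantomSpec | None = None
    manifest: Path | None = None
    n_samples: int = 3
    xi_F: float = shearlag.XI_F_DEFAULT
    phi_F: float = shearlag.PHI_F_DEFAULT
    sample_jitter_pct: float = 0.02
    plateau_window_s: float = 10.0

    def __post_init__(self) -> None:
        if (self.phantom_spec is None) == (self.manifest is None):
            raise ValueError(
                "exactly one of phantom_spec or manifest must be provided"
            )
        self.outdir = Path(self.outdir)


def plateau_loads(trace: pd.DataFrame, spec: phantom.PhantomSpec,
                  window_s: float = 10.0) -> dict[float, float]:
    """Mean load over the last ``window_s`` seconds of each relaxation hold."""
    rate = 0.05
    t = 0.0
    out = {}
    steps = list(spec.strain_steps_pct)
    for i, step in enumerate(steps):
        if i > 0:
            t += (steps[i] - steps[i - 1]) / rate
        t += spec.hold_s
        sel = (trace["t_s"] > t - window_s) & (trace["t_s"] <= t + 1e-9)
        out[step] = float(trace.loc[sel, "load_N"].mean())
    return out


def _sample_specs(config: RunConfig) -> list[phantom.PhantomSpec]:
    base = config.phantom_spec
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 77]))
    specs = []
    for i in range(config.n_samples):
        jit = float(rng.normal(0.0, config.sample_jitter_pct))
        specs.append(
            dataclasses.replace(
                base,
                seed=int(
                    np.random.SeedSequence([int(config.seed), i]).generate_state(1)[0]
                    % 2**31
                ),
                prestrain_endo_pct=base.prestrain_endo_pct + jit,
            )
        )
    return specs


def run_synthetic(config: RunConfig) -> dict:
    """Run the full synthetic workflow and write the results bundle.

    Per sample: write the phantom dataset, reduce every line scan, fit the
    pre-strain profile, extract plateau loads and invert (E1, eta), then
    pool first-load-level strain pairs across samples for the shear-lag
    fit.  Deterministic for a fixed (config, seed).
    """
    if config.phantom_spec is None:
        raise NotImplementedError(
            "real-data mode: reduce the manifest with waxd.reduce_manifest and "
            "fit stages individually"
        )
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    specs = _sample_specs(config)

    samples = []
    all_pairs = []
    for i, spec in enumerate(specs):
        sdir = outdir / f"sample{i}"
        paths = phantom.write_dataset(spec, sdir / "raw")
        t1_fraction = spec.arc.t1_mm / spec.arc.h_mm
        scans = waxd.reduce_manifest(
            paths["manifest"], spec.geometry, t1_fraction=t1_fraction
        )
        for step, scan in scans.items():
            scan.points.to_csv(sdir / f"scan_step{step:g}.csv", index=False)

        profile = waxd.prestrain_profile(scans[0.0])
        trace = pd.read_csv(paths["loadtrace"])
        plateaus = plateau_loads(trace, spec, config.plateau_window_s)
        load_steps = [
            (spec.sign * s / 100.0 * spec.arc.chord_mm, plateaus[s])
            for s in spec.strain_steps_pct
            if s > 0
        ]
        fit = beam.fit_moduli(np.array(load_steps), spec.arc)

        # strain pairs at the first load level: measured fibril strain vs
        # model tissue strain at the same (S, Z), using the fitted moduli
        first = sorted(s for s in spec.strain_steps_pct if s > 0)[0]
        section = beam.section_properties(spec.arc, fit.params.eta)
        sol = beam.shoot(
            spec.arc,
            section,
            spec.sign * first / 100.0 * spec.arc.chord_mm,
        )
        k = list(spec.strain_steps_pct).index(first)
        s_mm = k * spec.scan_offset_um / 1000.0
        pts = scans[first].cuticle()
        pts = pts[pts["converged"] & np.isfinite(pts["strain_pct"])]
        eps_t = beam.tissue_strain_field(
            sol, section, pts["depth_norm"].to_numpy() * spec.arc.h_mm, s_mm
        )
        pairs = pd.DataFrame(
            dict(
                sample=i,
                step_pct=first,
                depth_norm=pts["depth_norm"].to_numpy(),
                layer=pts["label"].to_numpy(),
                eps_T_pct=eps_t,
                eps_F_pct=pts["strain_pct"].to_numpy(),
            )
        )
        all_pairs.append(pairs)

        truth = json.loads(Path(paths["ground_truth"]).read_text())
        samples.append(
            dict(
                sample=i,
                E1_GPa=fit.params.E1_GPa,
                eta=fit.params.eta,
                E2_GPa=fit.params.E2_GPa,
                eta_identifiable=fit.eta_identifiable,
                objective=fit.objective,
                exo_prestrain_pct=profile.exo_mean_pct,
                endo_prestrain_pct=profile.endo_mean_pct,
                prestrain_diff_pct=profile.endo_minus_exo_pct,
                true_eta=truth["eta"],
                true_E1_GPa=truth["E1_GPa"],
                true_prestrain_diff_pct=truth["prestrain_endo_pct"]
                - truth["prestrain_exo_pct"],
                true_AF=truth["AF_true"],
            )
        )

    pairs_df = pd.concat(all_pairs, ignore_index=True)
    pairs_df.to_csv(outdir / "strain_pairs.csv", index=False)
    af_fit = shearlag.fit_AF(pairs_df)
    kappa = shearlag.invert_concentration(min(max(af_fit.AF, 1e-6), 1 - 1e-9))
    gm_over_ef = shearlag.modulus_ratio(kappa, config.xi_F, config.phi_F)

    sample_df = pd.DataFrame(samples)
    sample_df.to_csv(outdir / "samples.csv", index=False)

    stat_block = {}
    if config.n_samples >= 2:
        paired = stats.PairedSamples(
            tuple(sample_df["endo_prestrain_pct"]),
            tuple(sample_df["exo_prestrain_pct"]),
        )
        try:
            w, p = stats.wilcoxon_signed_rank(paired)
            stat_block["prestrain_wilcoxon"] = dict(
                W=w, p=p, stars=stats.significance_stars(p)
            )
        except ValueError as exc:
            stat_block["prestrain_wilcoxon"] = dict(error=str(exc))

    results = dict(
        mode=config.phantom_spec.mode,
        n_samples=config.n_samples,
        moduli=dict(
            E1_GPa=[s["E1_GPa"] for s in samples],
            eta=[s["eta"] for s in samples],
            median_eta=float(sample_df["eta"].median()),
            median_E1_GPa=float(sample_df["E1_GPa"].median()),
            true_eta=config.phantom_spec.eta,
            true_E1_GPa=config.phantom_spec.E1_GPa,
        ),
        shearlag=dict(
            AF=af_fit.AF,
            AF_stderr=af_fit.stderr,
            kappa=kappa,
            GM_over_EF=gm_over_ef,
            EF_over_GM=1.0 / gm_over_ef if gm_over_ef > 0 else float("inf"),
            true_AF=config.phantom_spec.AF_true(),
            xi_F=config.xi_F,
            phi_F=config.phi_F,
        ),
        prestrain=dict(
            diff_pct=[s["prestrain_diff_pct"] for s in samples],
            mean_diff_pct=float(sample_df["prestrain_diff_pct"].mean()),
            true_diff_pct=config.phantom_spec.prestrain_endo_pct
            - config.phantom_spec.prestrain_exo_pct,
        ),
        stats=stat_block,
    )
    (outdir / "results.json").write_text(json.dumps(results, indent=2))
    return results
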