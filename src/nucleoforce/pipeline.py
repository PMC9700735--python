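"""End-to-end orchestration: simulate -> stepfit -> kinetics -> fractions.

``run_pipeline`` executes the full analysis over a configuration: for
each condition and clamp force it simulates force-clamp traces, detects
plateaus and classifies unwrapping events, builds censored lifetime
ensembles, estimates per-force unwrapped fractions with exact CIs,
applies the tetrasome correction, fits the two-state force model per
condition, derives the free-energy barrier, and (when two conditions
are present) the difference curve.  All randomness flows from the one
seed in the configuration, so a fixed config yields a byte-identical
report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from nucleoforce import __version__
from nucleoforce import fractions as frac
from nucleoforce import kinetics, stepfit, synth

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Run configuration; round-trips losslessly through YAML."""

    conditions: list = field(default_factory=lambda: ["NO_PROTEIN", "PICH_ATP"])
    forces: list = field(default_factory=lambda: [3.0, 5.0, 7.5, 10.0, 12.5, 15.0])
    n_constructs: int = 3
    synth: dict = field(default_factory=dict)  # SimulationConfig overrides
    min_dwell: float = 0.5
    sensitivity: float = 3.0
    tetrasome_fraction: float = frac.DEFAULT_TETRASOME_FRACTION
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        synth_overrides = d.get("synth", {})
        synth_known = {f.name for f in dataclasses.fields(synth.SimulationConfig)}
        bad = set(synth_overrides) - synth_known
        if bad:
            raise ValueError(f"unknown synth config keys: {sorted(bad)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def save(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and return the JSON-serializable report."""
    ss = np.random.SeedSequence(config.seed)
    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "config_hash": config.digest(),
        "seed": config.seed,
        "conditions": {},
    }
    window = config.synth.get("observation_window", 600.0)

    arr_fits: dict[str, frac.ArrheniusFit] = {}
    for condition in config.conditions:
        cond_out: dict = {"per_force": [], "recovery": []}
        all_samples_by_force: dict[float, list] = {}
        for force in config.forces:
            n_unwrapped = 0
            n_total = 0
            samples: list[kinetics.LifetimeSample] = []
            for _ in range(config.n_constructs):
                seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
                cfg = synth.config_for(condition, seed=seed, **config.synth)
                trace, truth = _stage(
                    "simulate", synth.simulate_force_clamp, cfg, force
                )
                segments = _stage(
                    "stepfit", stepfit.fit_steps, trace, config.min_dwell,
                    config.sensitivity,
                )
                events = _stage("classify", stepfit.classify_events, segments)
                # anomalous (>= 3-fold) steps enter event accounting with
                # their implied multiplicity but are excluded from lifetimes
                n_events = sum(e.implied_multiplicity for e in events)
                # post-clamp stretch: nucleosomes still wrapped rupture here;
                # the total is events + ruptures, as in the assay
                curve, _ = _stage(
                    "stretch", synth.simulate_stretch_curve, truth.n_censored,
                    seed=seed + 1,
                )
                n_ruptures = _stage("ruptures", stepfit.count_ruptures, curve)
                samples += kinetics.extract_lifetimes(
                    [e for e in events if not e.anomalous],
                    window, n_ruptures, force=force, condition=condition,
                )
                n_unwrapped += n_events
                n_total += n_events + n_ruptures
                cond_out["recovery"].append(
                    {
                        "force_pN": force,
                        "true_unwrapped": int(np.sum(~truth.censored)),
                        "detected_unwrapped": int(n_events),
                        "true_remaining": int(truth.n_censored),
                        "counted_ruptures": int(n_ruptures),
                    }
                )
            est = _stage(
                "fractions", frac.unwrapped_fraction, n_unwrapped, n_total,
                force=force, condition=condition,
            )
            corrected = frac.tetrasome_correct(est.alpha, config.tetrasome_fraction)
            cond_out["per_force"].append(
                {
                    "force_pN": force,
                    "n_unwrapped": est.n_unwrapped,
                    "n_total": est.n_total,
                    "alpha": est.alpha,
                    "ci": [est.ci_low, est.ci_high],
                    "alpha_corrected": corrected,
                }
            )
            all_samples_by_force[force] = samples

        # bi-exponential lifetime fits where the data allow it
        cond_out["lifetime_fits"] = []
        for force, samples in all_samples_by_force.items():
            durations = [s.duration for s in samples if not s.censored]
            if len(set(durations)) < 8:
                continue
            try:
                t, cpd = kinetics.build_cpd(samples)
                fit = kinetics.fit_biexponential(t, cpd)
            except (ValueError, RuntimeError):
                continue
            cond_out["lifetime_fits"].append(
                {
                    "force_pN": force,
                    "major_fraction": fit.major_fraction,
                    "tau_major_s": fit.tau_major,
                    "tau_minor_s": fit.tau_minor,
                    "n_events": fit.n_events,
                    "degenerate": fit.degenerate,
                }
            )

        # two-state model fit on tetrasome-corrected counts
        obs = [
            (
                row["force_pN"],
                int(round(row["alpha_corrected"] * row["n_total"])),
                row["n_total"],
            )
            for row in cond_out["per_force"]
        ]
        try:
            fit = _stage("arrhenius", frac.fit_arrhenius, obs)
            arr_fits[condition] = fit
            cond_out["arrhenius"] = {
                "f_half_pN": fit.f_half,
                "f_half_se": fit.f_half_se,
                "delta_x_nm": fit.delta_x,
                "delta_x_se": fit.delta_x_se,
                "delta_g_kBT": frac.delta_g(fit),
            }
        except (ValueError, RuntimeError) as exc:
            cond_out["arrhenius"] = {"error": str(exc)}
        report["conditions"][condition] = cond_out

    if "NO_PROTEIN" in arr_fits and "PICH_ATP" in arr_fits:
        try:
            dc = frac.difference_curve(arr_fits["NO_PROTEIN"], arr_fits["PICH_ATP"])
            report["difference_curve"] = {
                "peak_force_pN": dc["peak_force"],
                "peak_height": dc["peak_height"],
                "fwhm_pN": [dc["fwhm_low"], dc["fwhm_high"]],
            }
        except ValueError as exc:
            report["difference_curve"] = {"error": str(exc)}

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
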