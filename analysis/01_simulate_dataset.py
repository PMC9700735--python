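"""Generate the synthetic single-molecule dataset for the analyses.

Emulates a constant-force study of nucleosome arrays with and without
an ATP-dependent remodeler: force-clamp distance-time traces at six
clamp forces (10-minute window, 50 Hz), post-clamp stretch curves for
the nucleosomes that remained wrapped, a low-coverage kymograph, and
remodeler-driven histone-sliding trajectories.  Ground truth is stored
beside each file so downstream scripts can report recovery.

Writes the dataset under scratch/synthetic/ (regenerated on demand).
"""

import json
from pathlib import Path

import numpy as np

from nucleoforce import io, synth

OUT = Path(__file__).resolve().parents[1] / "scratch" / "synthetic"
SEED = 20240
FORCES = [3.0, 5.0, 7.5, 10.0, 12.5, 15.0]
N_CONSTRUCTS = 2


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    manifest = []
    ss = np.random.SeedSequence(SEED)
    for condition in ("NO_PROTEIN", "PICH_ATP"):
        for force in FORCES:
            for rep in range(N_CONSTRUCTS):
                seed = int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)
                cfg = synth.config_for(condition, n_nucleosomes=15, seed=seed)
                trace, truth = synth.simulate_force_clamp(cfg, force)
                stem = f"trace_{condition}_{force:g}pN_{rep}"
                io.write_trace(trace, OUT / f"{stem}.csv")
                curve, _ = synth.simulate_stretch_curve(truth.n_censored,
                                                        seed=seed + 1)
                np.savetxt(OUT / f"{stem}_stretch.csv",
                           np.column_stack([curve.force, curve.distance]),
                           delimiter=",", header="force_pN,distance_nm",
                           comments="")
                manifest.append({
                    "file": f"{stem}.csv",
                    "condition": condition,
                    "force_pN": force,
                    "n_nucleosomes": cfg.n_nucleosomes,
                    "true_unwrapped": int(np.sum(~truth.censored)),
                    "true_remaining": int(truth.n_censored),
                    "n_tetrasomes": int(truth.is_tetrasome.sum()),
                })

    # a low-coverage construct: 7 bound proteins in 4 apparent oligomers
    km, km_truth = synth.simulate_kymograph(
        [(1500.0, 2), (3000.0, 1), (4500.0, 1), (6000.0, 3)],
        photons_per_monomer_per_line=100.0, n_lines=100, seed=SEED,
    )
    io.write_kymograph(km, OUT / "kymograph.tiff")

    # sliding trajectories: translocation at ~10 nm/s with pauses
    rng = np.random.default_rng(SEED)
    for i in range(11):
        v = rng.normal(10.0, 1.5)
        plan = [(rng.uniform(20, 40), v), (rng.uniform(5, 15), 0.0),
                (rng.uniform(20, 40), v)]
        t, pos, _ = synth.simulate_sliding_trajectory(
            plan, noise_sd=4.0, seed=SEED + i
        )
        io.write_trajectory(t, pos, OUT / f"trajectory_{i:02d}.csv",
                            oligomer=1 if i < 7 else 2)

    (OUT / "manifest.json").write_text(json.dumps(manifest, indent=2))
    n_traces = len(manifest)
    print(f"wrote {n_traces} force-clamp traces (+stretch curves), "
          f"1 kymograph ({sum(c for _, c in km_truth.emitters)} proteins), "
          f"11 trajectories -> {OUT}")


if __name__ == "__main__":
    main()
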