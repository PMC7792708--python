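#!/usr/bin/env python
"""Simulate a three-group cohort of optically mapped hearts.

Groups mirror the study design: healthy controls (Sham), pressure-overloaded
hearts (TAC) with elevated steady-state APD, slowed conduction and a region
of 2:1 conduction block at fast pacing, and treated hearts (TAC+CNO) in
between. Each heart is a 32×32 synthetic movie under a 250/200/175/150 ms
dynamic pacing staircase (6 pulses per step) with camera noise, drift and
photobleaching.

Movies land in scratch/cohort/ (large, binary); the cohort manifest and
ground truth go to results/.
"""

import json
from pathlib import Path

import numpy as np

import epimap as em

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"

GRID = (32, 32)
PROTOCOL = em.build_protocol([250.0, 200.0, 175.0, 150.0], 6, 490.2)

# Group-level truth: steady-state APD_60 (ms) and conduction speed (cm/s)
# chosen to mirror the cohort contrasts (elevated APD_ss and slowed, failing
# conduction under pressure overload; partial rescue with treatment).
GROUPS = {
    "Sham": dict(apd_ss=57.9, speed=61.0, block=False, n=3),
    "TAC": dict(apd_ss=78.3, speed=39.0, block=True, n=3),
    "TAC+CNO": dict(apd_ss=65.5, speed=42.0, block=False, n=3),
}


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    rng = np.random.default_rng(2026)
    manifest = []
    for group, spec in GROUPS.items():
        for i in range(spec["n"]):
            heart = f"{group.replace('+', '_')}_{i + 1}"
            apd_ss = spec["apd_ss"] + rng.normal(0.0, 3.0)
            # mild regional heterogeneity on top of the group mean
            field = np.full(GRID, apd_ss)
            field[:, GRID[1] // 2 :] += rng.normal(0.0, 1.0) + 2.0
            block = None
            if spec["block"]:
                block = np.zeros(GRID, bool)
                block[8:20, 8:20] = True
            wave = em.WavePattern(
                speed=spec["speed"] + rng.normal(0.0, 2.0),
                block_mask=block,
                block_pcls=(150.0,),
            )
            noise = em.NoiseModel(
                gaussian_sd=8.0,
                drift_slope=6.0,
                bleach_tau=120.0,
                dead_pixel_fraction=0.01,
                seed=int(rng.integers(2**31)),
            )
            movie, gt = em.simulate_movie(
                PROTOCOL, em.APModel(apd_ss_true=field), wave, noise, GRID
            )
            path = SCRATCH / f"{heart}.h5"
            em.write_movie(movie, path)
            em.export_ground_truth(gt, SCRATCH / heart)
            manifest.append(
                {
                    "heart": heart,
                    "group": group,
                    "movie": str(path.relative_to(ROOT)),
                    "true_speed_cm_s": wave.speed,
                    "true_apd_ss_mean_ms": float(field.mean()),
                    "has_block": bool(spec["block"]),
                }
            )
            print(f"simulated {heart}: APD_ss~{field.mean():.1f} ms, "
                  f"{wave.speed:.1f} cm/s" + (" (2:1 block region)" if block is not None else ""))
    (RESULTS / "cohort_manifest.json").write_text(json.dumps(manifest, indent=2))
    print(f"\n{len(manifest)} hearts -> {SCRATCH}")


if __name__ == "__main__":
    main()
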