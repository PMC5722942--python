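#!/usr/bin/env python
"""Ensemble post-processing on synthetic conformational mixtures.

Builds multi-model ensembles with known Class 1 / Class 2 mixtures, runs
the full ensemble analysis (per-frame RMSD of A1-A4 against a Class 2
reference after a B-helix fit, Class-2 occupancy by the 1.5 A threshold,
Thr A8 hydrogen-bond partner occupancies), and compares the recovered
fractions against the generating truth.  Writes results/ensemble_*.
"""

import json
from pathlib import Path

import numpy as np

from insulin_conformers.ensemble_analysis import Ensemble, summarize
from insulin_conformers.synth import build_class_toy, build_ensemble

OUT = Path(__file__).resolve().parent.parent / "results"
N_FRAMES = 1000
MIXES = ({"CLASS1": 0.7, "CLASS2": 0.3},
         {"CLASS1": 0.96, "CLASS2": 0.04})
SEED = 77


def main() -> None:
    OUT.mkdir(exist_ok=True)
    reference = build_class_toy("CLASS2")
    report = {}
    for k, mixture in enumerate(MIXES):
        frames, truth = build_ensemble(mixture, N_FRAMES, noise_sigma=0.1,
                                       seed=SEED + k)
        stats = summarize(Ensemble(frames), reference)
        want = float(np.mean([t == "CLASS2" for t in truth]))
        tag = f"mixture_{int(100 * mixture['CLASS2'])}pct"
        report[tag] = {
            "n_frames": N_FRAMES,
            "true_class2_fraction": want,
            "recovered_class2_fraction": round(stats.class2_fraction, 4),
            "thr_a8_partner_occupancy": {p: round(v, 4) for p, v
                                         in stats.partner_occupancy.items()},
            "rmsd_mean": round(stats.rmsd_mean, 3),
            "rmsd_sd": round(stats.rmsd_sd, 3),
        }
        with open(OUT / f"ensemble_rmsd_{tag}.tsv", "w") as fh:
            fh.write("frame\trmsd\n")
            for i, v in enumerate(stats.rmsd_series, 1):
                fh.write(f"{i}\t{v:.3f}\n")
        print(f"{tag}: true Class-2 fraction {want:.3f}, recovered "
              f"{stats.class2_fraction:.3f}; Thr A8 -> Val A3 occupancy "
              f"{stats.partner_occupancy['A3']:.3f}; "
              f"RMSD {stats.rmsd_mean:.2f} +/- {stats.rmsd_sd:.2f} A")
    (OUT / "ensemble_summary.json").write_text(json.dumps(report, indent=1))
    print(f"wrote {OUT/'ensemble_summary.json'}")


if __name__ == "__main__":
    main()
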