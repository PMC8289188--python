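#!/usr/bin/env python
"""Generate every synthetic dataset the downstream analyses consume.

Writes, under results/data/:
  * a ThT kinetic panel (75 μM protein, molar ratios 1:0 ... 1:10,
    150 h at 10 min sampling, triplicate, 2% noise) with its well
    metadata;
  * intrinsic-Trp and ANS titration curves for both inhibitors at the
    dissociation constants the binding analysis targets;
  * an acrylamide quenching curve for the protein alone and for the
    1:1 complexes;
  * far-UV CD-like spectra (five repeats) for the native protein and a
    slightly perturbed complex;
  * AFM height samples for fibrils alone and 1:10 aggregates.
"""

from pathlib import Path

import numpy as np

from pomamyloid import io
from pomamyloid.synthetic_data import (
    PanelDesign,
    gen_heights,
    gen_kinetic_panel,
    gen_quenching_curve,
    gen_spectrum,
    gen_titration_curve,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 2026

# (label, Kd uM, S0, Sinf, grid max uM, n points, probe)
TITRATIONS = [
    ("titration_trp_TiNb9", 2.48, 100.0, 40.0, 25.0, 25, "intrinsic-Trp"),
    ("titration_trp_Nb10", 2.86, 100.0, 40.0, 30.0, 25, "intrinsic-Trp"),
    ("titration_ans_TiNb9", 0.45, 100.0, 30.0, 5.0, 20, "ANS"),
    ("titration_ans_Nb10", 1.17, 100.0, 30.0, 10.0, 20, "ANS"),
]

# (label, Ksv M^-1, radius A) for protein alone and the two 1:1 complexes
QUENCHING = [
    ("quench_alone", 5.24, 7.7),
    ("quench_TiNb9", 4.5, 8.4),
    ("quench_Nb10", 3.0, 8.7),
]

# (label, median nm, median deviation nm, n)
HEIGHTS = [
    ("heights_alone", 2.1, 0.35, 400),
    ("heights_TiNb9_1to10", 2.5, 0.66, 400),
    ("heights_Nb10_1to10", 3.09, 0.73, 400),
]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    panel = gen_kinetic_panel(PanelDesign(seed=SEED))
    io.write_kinetic_csv(panel, OUT / "kinetics.csv", OUT / "kinetics_metadata.csv")
    print(f"kinetic panel: {len(panel)} traces x {panel[0].times.size} points")

    for i, (label, kd, s0, sinf, cmax, n, probe) in enumerate(TITRATIONS):
        curve = gen_titration_curve(kd, s0, sinf, np.linspace(0, cmax, n),
                                    noise_fraction=0.02, seed=SEED + i, probe=probe)
        io.write_titration_csv(curve, OUT / f"{label}.csv")
    print(f"titrations: {len(TITRATIONS)} curves (Kd {[t[1] for t in TITRATIONS]} uM)")

    for i, (label, ksv, r) in enumerate(QUENCHING):
        curve = gen_quenching_curve(ksv, r, np.linspace(0, 0.5, 11),
                                    noise_fraction=0.01, seed=SEED + 10 + i)
        io.write_quench_csv(curve, OUT / f"{label}.csv")
    print(f"quenching: {len(QUENCHING)} curves")

    wl = np.arange(200.0, 260.0, 0.5)
    native = gen_spectrum([(208.0, 6.0, -8.0), (222.0, 10.0, -9.0)], wl,
                          noise_sd=0.15, n_repeats=5, seed=SEED + 20)
    complexed = gen_spectrum([(208.0, 6.0, -7.8), (222.0, 10.0, -8.9)], wl,
                             noise_sd=0.15, n_repeats=5, seed=SEED + 21)
    io.write_spectrum_csv(native, OUT / "cd_native.csv")
    io.write_spectrum_csv(complexed, OUT / "cd_complex.csv")
    print("CD-like spectra: native + 1:1 complex, 5 repeats each")

    for i, (label, med, spread, n) in enumerate(HEIGHTS):
        io.write_heights_csv(gen_heights(med, spread, n, seed=SEED + 30 + i,
                                         condition=label.removeprefix("heights_")),
                             OUT / f"{label}.csv")
    print(f"AFM heights: {len(HEIGHTS)} samples -> {OUT}")


if __name__ == "__main__":
    main()
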