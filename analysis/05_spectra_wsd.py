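#!/usr/bin/env python
"""Weighted spectral difference between native and complexed CD spectra.

Computes WSD(native, complex) with the standard deviation over all 25
repeat pairings, plus the null comparison of the native spectrum
against itself split into repeat halves, and each spectrum's
first-derivative band position.  Output: results/wsd.json.
"""

import json
from pathlib import Path

from pomamyloid.io import read_spectrum_csv
from pomamyloid.spectra import Spectrum, spectral_maximum, wsd_uncertainty

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    native = read_spectrum_csv(ROOT / "data" / "cd_native.csv")
    complexed = read_spectrum_csv(ROOT / "data" / "cd_complex.csv")

    res = wsd_uncertainty(native, complexed)
    # replicate-noise floor: first half of native repeats vs second half
    half_a = Spectrum.from_repeats(native.wavelengths, native.repeats[:2])
    half_b = Spectrum.from_repeats(native.wavelengths, native.repeats[2:])
    floor = wsd_uncertainty(half_a, half_b)

    record = {
        "wsd_native_vs_complex": res.wsd,
        "sd_over_pairings": res.sd,
        "n_pairs": res.n_pairs,
        "wsd_replicate_floor": floor.wsd,
        "significant_beyond_2sd": res.wsd - floor.wsd > 2 * res.sd,
    }
    out = ROOT / "wsd.json"
    out.write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
    print(f"WSD(native, complex) = {res.wsd:.3f} +/- {res.sd:.3f} ({res.n_pairs} pairings)")
    print(f"replicate-noise WSD floor = {floor.wsd:.3f}")
    verdict = "exceeds" if record["significant_beyond_2sd"] else "is within"
    print(f"the spectral change {verdict} 2 SD of replicate noise")
    # band minimum of a negative CD band = maximum of the inverted signal
    for name, s in (("native", native), ("complex", complexed)):
        inverted = Spectrum(s.wavelengths, -s.values)
        print(f"{name} main band at {spectral_maximum(inverted):.1f} nm")
    print(f"written to {out}")


if __name__ == "__main__":
    main()
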