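#!/usr/bin/env python
"""Regenerate the shipped decoy benchmark suite.

Calibrates every family/shape combination to the three difficulty levels
(N_d = 1e3, 1e4, 1e5) and writes src/sqrkit/data/decoy_suite.json.
Combinations whose calibrated amplitude would violate cdf monotonicity
(steep localized shapes at the easy level) are skipped.
"""
from pathlib import Path

from sqrkit.decoys import DecoySpec, calibrate_amplitude, suite_to_json

ND = (1_000, 10_000, 100_000)
OUT = Path(__file__).resolve().parents[1] / "src/sqrkit/data/decoy_suite.json"


def main() -> None:
    specs, skipped = [], 0

    def add(family, shapes, nd):
        nonlocal skipped
        try:
            specs.append(calibrate_amplitude(family, shapes, nd))
        except ValueError as e:
            skipped += 1
            print("skip:", family, shapes, nd, "->", e)

    for nd in ND:
        for ro, sg in ((0.25, 0.05), (0.5, 0.03), (0.5, 0.1), (0.75, 0.05)):
            add("dimple", {"r_o": ro, "sigma": sg}, nd)
        for ro, sg in ((0.35, 0.05), (0.5, 0.1), (0.65, 0.05)):
            add("pulse", {"r_o": ro, "sigma": sg}, nd)
        for m, sg in ((4, 0.1), (8, 0.05), (8, 0.1), (16, 0.05)):
            add("wavelet", {"m": m, "r_o": 0.5, "sigma": sg}, nd)
        for m in (1, 2, 4, 8, 16):
            add("sine", {"m": m}, nd)
        for a0, b0 in ((1.3, 0.8), (0.8, 1.3), (1.25, 1.25), (0.8, 0.8)):
            add("beta", {"alpha": a0, "beta": b0}, nd)
    for p in (0.05, 0.1, 0.2, 0.3, 0.5):
        specs.append(DecoySpec("reduced", {"p": p}))
    print(len(specs), "specs,", skipped, "skipped")
    OUT.write_text(suite_to_json(specs))
    print("wrote", OUT)


if __name__ == "__main__":
    main()
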