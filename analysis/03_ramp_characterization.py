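"""Measure gain versus stimulus amplitude with ramp stimuli.

Windowed gain/phase profiles across the eight study frequencies plus the
per-unit Lorentzian contrast-gain fits, written under
results/ramp_characterization/.
"""

import argparse
from pathlib import Path

import vestcode as vc


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("results/ramp_characterization"))
    args = parser.parse_args()

    report = vc.run_ramp_characterization(vc.ExperimentConfig(seed=args.seed))
    report.write(args.outdir)

    s = report.summary
    print("Per-window gain falls with stimulus amplitude while phase stays "
          "nearly constant (max spread %.2f deg across amplitudes)."
          % s["max_phase_spread_deg"])
    print("Lorentzian fits recover the generating contrast-gain parameters: "
          "median |rel. error| %.1f%% (P1), %.1f%% (P2)."
          % (100 * s["median_P1_rel_err"], 100 * s["median_P2_rel_err"]))
    print(f"Tables written to {args.outdir}/")


if __name__ == "__main__":
    main()
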