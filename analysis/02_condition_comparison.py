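"""Compare coding of naturalistic versus sinusoidal stimulation.

Simulates the jittered TC and VN populations, estimates gain/phase per
condition and the ambiguity distributions (plain, phase-aligned,
amplitude-thresholded), runs the per-frequency Kruskal-Wallis
comparisons, and writes the tables under results/condition_comparison/.
"""

import argparse
from pathlib import Path

import vestcode as vc


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--config", type=Path, default=None,
                        help="optional YAML overriding the default study conditions")
    parser.add_argument("--outdir", type=Path, default=Path("results/condition_comparison"))
    args = parser.parse_args()

    cfg = (vc.ExperimentConfig.from_yaml(args.config) if args.config
           else vc.ExperimentConfig(seed=args.seed))
    report = vc.run_condition_comparison(cfg)
    report.write(args.outdir)

    tests = report.tables["tests"]
    for cls in ("TC", "VN"):
        sub = tests[tests.neuron_class == cls]
        lower = int((sub.delta_median < 0).sum())
        print(f"{cls}: naturalistic ambiguity median below the sinusoidal median "
              f"at {lower}/8 frequencies "
              f"(Kruskal-Wallis p < 0.05 at {(sub.p_value < 0.05).sum()}/8).")
    print(f"Tables written to {args.outdir}/")


if __name__ == "__main__":
    main()
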