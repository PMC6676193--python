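"""Generate the synthetic 4-subject study used by the downstream stages.

Writes beta/parameter/QC tables, the probe annotation, the
reference-interaction set, annotation sets and the planted ground truth
under results/study/.
"""

import argparse
from pathlib import Path

from methylink import synthetic


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/study"))
    args = ap.parse_args()

    cfg = synthetic.SimulationConfig(seed=args.seed)
    study = synthetic.generate_study(cfg)
    synthetic.write_study(study, args.out)

    n_truth = len(study.truth["truth_pairs"])
    print(f"wrote {len(study.subjects)} subjects x {cfg.n_probes} probes x "
          f"{cfg.n_parameters} parameters to {args.out}")
    print(f"planted: {cfg.n_planted} biclusters "
          f"({cfg.probe_block_size} probes x {cfg.param_block_size} parameters each), "
          f"{n_truth} ground-truth gene-parameter pairs, "
          f"{len(study.reference)} reference-interaction pairs")


if __name__ == "__main__":
    main()
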