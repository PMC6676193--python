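"""Per-subject probe x parameter Spearman matrices over the seven shared
in-mission days, column-standardized for biclustering.

Writes correlation_<subject>.tsv and standardized_<subject>.tsv under
results/correlation/.
"""

import argparse
from pathlib import Path

from methylink import correlation, synthetic
from methylink import io as mio


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--study", type=Path, default=Path("results/study"))
    ap.add_argument("--filtered", type=Path, default=Path("results/preprocess"))
    ap.add_argument("--out", type=Path, default=Path("results/correlation"))
    args = ap.parse_args()

    study = synthetic.read_study(args.study)
    shape = None
    for subj in study.subjects:
        beta = mio.read_beta_table(args.filtered / f"filtered_beta_{subj}.tsv")
        rho = correlation.spearman_matrix(beta, study.params[subj])
        mio.write_table(rho, args.out / f"correlation_{subj}.tsv")
        mio.write_table(correlation.standardize(rho),
                        args.out / f"standardized_{subj}.tsv")
        shape = rho.shape
    print(f"wrote {len(study.subjects)} {shape[0]}x{shape[1]} correlation "
          f"matrices (Spearman over 7 shared days) to {args.out}")


if __name__ == "__main__":
    main()
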