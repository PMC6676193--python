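"""Validate the consensus associations against the reference-interaction
set: overlap count/ratio, background ratio over the gene x parameter
universe, the hypergeometric upper-tail test, and the 1000-fold
permutation null.
"""

import argparse
from pathlib import Path

from methylink import associations as assoc
from methylink import pipeline, stats, synthetic
from methylink import io as mio


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--study", type=Path, default=Path("results/study"))
    ap.add_argument("--associations", type=Path,
                    default=Path("results/associations/consensus_associations.tsv"))
    ap.add_argument("--out", type=Path, default=Path("results/validation.json"))
    ap.add_argument("--n-perm", type=int, default=1000)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    study = synthetic.read_study(args.study)
    table = mio.read_table(args.associations, index_col=None)
    pairs = assoc.association_pairs(table)
    count, ratio = stats.validated_ratio(pairs, study.reference)
    genes = sorted({g for g, _ in pairs})
    params = sorted({q for _, q in pairs})
    universe = len(genes) * len(params)
    bg = sum(1 for g in genes for q in params if (g, q) in study.reference)
    p_hyper = stats.hypergeom_tail(count, len(pairs), bg, universe)
    perm = stats.permutation_test(genes, params, study.reference, len(pairs),
                                  count, n_perm=args.n_perm,
                                  seed=pipeline.stage_seed(args.seed, 50))
    result = {
        "validated_count": count, "n_associations": len(pairs),
        "validated_pct": round(100 * ratio, 2),
        "background_count": bg, "pair_universe": universe,
        "background_pct": round(100 * bg / universe, 2),
        "hypergeom_p": p_hyper, "permutation_p": perm.empirical_p,
        "n_perm": args.n_perm,
    }
    mio.write_json(result, args.out)
    print(f"{count} of {len(pairs)} associations in the reference set "
          f"({result['validated_pct']}%) vs {result['background_pct']}% over the "
          f"{universe}-pair universe")
    print(f"hypergeometric p = {p_hyper:.3g}; permutation p = "
          f"{perm.empirical_p:.3g} ({args.n_perm} permutations)")


if __name__ == "__main__":
    main()
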