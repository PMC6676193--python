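"""Term enrichment of the consensus genes and construction of
parameter-disease associations from the per-parameter partner gene sets
(hypergeometric test, p <= 0.05), plus per-parameter bicluster coverage.
"""

import argparse
from pathlib import Path

from methylink import stats, synthetic
from methylink import io as mio


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--study", type=Path, default=Path("results/study"))
    ap.add_argument("--associations", type=Path,
                    default=Path("results/associations/consensus_associations.tsv"))
    ap.add_argument("--biclusters", type=Path, default=Path("results/biclusters"))
    ap.add_argument("--out", type=Path, default=Path("results/enrichment"))
    ap.add_argument("--p-max", type=float, default=0.05)
    args = ap.parse_args()

    study = synthetic.read_study(args.study)
    table = mio.read_table(args.associations, index_col=None)
    universe = sorted({g for payload in study.anno_sets.values() for g in payload[0]})
    query = sorted(set(table["gene"]) & set(universe))

    enr = stats.term_enrichment(query, universe, study.anno_sets, p_max=args.p_max)
    mio.write_table(enr, args.out / "term_enrichment.tsv", index=False)

    pd_table = stats.parameter_disease(table, study.anno_sets, universe,
                                       p_max=args.p_max)
    mio.write_table(pd_table, args.out / "parameter_disease.tsv", index=False)

    from methylink.cli import _frame_to_biclusters
    per_subject = {
        subj: _frame_to_biclusters(
            mio.read_table(args.biclusters / f"biclusters_{subj}.tsv",
                           index_col=None))
        for subj in study.subjects
    }
    coverage = stats.coverage_counts(per_subject)
    mio.write_table(coverage, args.out / "parameter_coverage.tsv", index=False)

    top = coverage.head(3)
    print(f"{int(enr['significant'].sum()) if len(enr) else 0} terms enriched at "
          f"p<={args.p_max} for {len(query)} consensus genes; "
          f"{len(pd_table)} parameter-disease associations")
    print("widest bicluster coverage:",
          "; ".join(f"{r.item} in {r.n_biclusters} biclusters"
                    for r in top.itertuples()))


if __name__ == "__main__":
    main()
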