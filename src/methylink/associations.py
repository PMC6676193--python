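"""Bicluster co-membership associations and cross-subject consensus.

A probe (or its annotated gene) and a parameter appearing in the same
bicluster constitute a candidate functional association. Per-subject pair
sets are reduced to a consensus table by requiring support in at least
``min_support`` subjects (three of four by default).
"""

from __future__ import annotations

import logging

import pandas as pd

from methylink.errors import ConfigurationError, DataIntegrityError
from methylink.fabia import Bicluster

log = logging.getLogger(__name__)


def _probe_genes(annotation: pd.DataFrame) -> dict[str, list[str]]:
    return {
        pid: [g for g in str(gl).split(";") if g]
        for pid, gl in annotation["genes"].fillna("").items()
    }


def comembership_pairs(
    biclusters: list[Bicluster],
    annotation: pd.DataFrame | None = None,
    level: str = "gene",
) -> dict[tuple[str, str], tuple[str, ...]]:
    """All (item, parameter) pairs co-occurring in one subject's biclusters.

    Returns pair -> sorted tuple of contributing bicluster ids. At gene
    level, multi-gene probes contribute every symbol; unannotated probes
    are skipped (and counted in the log). At probe level the annotation is
    not consulted.
    """
    if level not in ("gene", "probe"):
        raise ConfigurationError("level must be 'gene' or 'probe'")
    if level == "gene" and annotation is None:
        raise ConfigurationError("gene-level pairs require an annotation")
    gene_map = _probe_genes(annotation) if level == "gene" else {}

    pairs: dict[tuple[str, str], set[str]] = {}
    n_unannotated = 0
    for b in biclusters:
        if level == "probe":
            items = list(b.probe_ids)
        else:
            items = []
            for pid in b.probe_ids:
                genes = gene_map.get(pid)
                if genes is None:
                    n_unannotated += 1
                    continue
                if not genes:
                    n_unannotated += 1
                    continue
                items.extend(genes)
        for item in set(items):
            for q in b.parameter_ids:
                pairs.setdefault((item, q), set()).add(b.id)
    if n_unannotated:
        log.info("comembership_pairs: %d probe memberships without gene annotation", n_unannotated)
    return {pair: tuple(sorted(bids)) for pair, bids in pairs.items()}


def consensus(
    pair_sets: dict[str, dict[tuple[str, str], tuple[str, ...]]],
    min_support: int = 3,
) -> pd.DataFrame:
    """Pairs supported by at least ``min_support`` subjects.

    A pair backed by several biclusters within one subject counts once;
    support is the number of distinct subjects. Output columns: gene,
    parameter, support, subjects, biclusters; sorted by support descending,
    then gene, then parameter.
    """
    if min_support > len(pair_sets):
        raise ConfigurationError(
            f"min_support={min_support} exceeds number of subjects ({len(pair_sets)})"
        )
    support: dict[tuple[str, str], list[str]] = {}
    bic_ids: dict[tuple[str, str], list[str]] = {}
    for subj in sorted(pair_sets):
        for pair, bids in pair_sets[subj].items():
            support.setdefault(pair, []).append(subj)
            bic_ids.setdefault(pair, []).extend(bids)
    rows = [
        {
            "gene": g,
            "parameter": q,
            "support": len(subjects),
            "subjects": ";".join(subjects),
            "biclusters": ";".join(sorted(set(bic_ids[(g, q)]))),
        }
        for (g, q), subjects in support.items()
        if len(subjects) >= min_support
    ]
    df = pd.DataFrame(rows, columns=["gene", "parameter", "support", "subjects", "biclusters"])
    if len(df):
        df = df.sort_values(
            ["support", "gene", "parameter"], ascending=[False, True, True]
        ).reset_index(drop=True)
    return df


def venn_counts(
    pair_sets: dict[str, dict | set]
) -> dict[str, int]:
    """Cardinality of every subject-combination region of the Venn diagram.

    Keys are '+'-joined subject ids; the values over all regions sum to the
    size of the union of the subject pair sets.
    """
    subjects = sorted(pair_sets)
    membership: dict[tuple[str, str], frozenset[str]] = {}
    for subj in subjects:
        for pair in pair_sets[subj]:
            membership[pair] = membership.get(pair, frozenset()) | {subj}
    counts: dict[str, int] = {}
    for owners in membership.values():
        key = "+".join(sorted(owners))
        counts[key] = counts.get(key, 0) + 1
    return counts


def region_distribution(
    probe_sets: dict[str, set[str]], annotation: pd.DataFrame
) -> pd.DataFrame:
    """Proportion of probes per gene-region group for each named collection."""
    regions = annotation["region"]
    vocab = sorted(regions.unique())
    rows = {}
    for name, probes in probe_sets.items():
        if not probes:
            raise DataIntegrityError(f"probe set {name!r} is empty")
        known = [p for p in probes if p in regions.index]
        if not known:
            raise DataIntegrityError(f"probe set {name!r} has no annotated probes")
        counts = regions.loc[known].value_counts()
        rows[name] = [counts.get(r, 0) / len(known) for r in vocab]
    return pd.DataFrame.from_dict(rows, orient="index", columns=vocab)


def association_pairs(table: pd.DataFrame) -> set[tuple[str, str]]:
    """The (gene, parameter) pair set of a consensus table."""
    return set(zip(table["gene"], table["parameter"]))
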