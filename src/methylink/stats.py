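"""Validation and enrichment statistics.

Hypergeometric upper-tail tests (computed in log space), the permutation
null over random gene-parameter recombinations, generic term enrichment,
parameter-disease association construction and bicluster coverage counts.
All tests are one-sided enrichment tests, P(X >= k); raw p-values are
reported by default with Benjamini-Hochberg q-values available opt-in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from methylink.errors import ConfigurationError, DataIntegrityError

log = logging.getLogger(__name__)


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Exact upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N: universe size, K: annotated items in the universe, n: sample
    (query) size, k: annotated items observed in the sample. Summation is
    done on log probabilities for numerical range.
    """
    k, n, K, N = int(k), int(n), int(K), int(N)
    if not (0 <= k <= n <= N and 0 <= K <= N and k <= K):
        raise ConfigurationError(f"inconsistent hypergeometric counts k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    support = np.arange(k, min(n, K) + 1)
    if support.size == 0:
        return 0.0
    logs = sps.hypergeom.logpmf(support, N, K, n)
    return float(min(1.0, np.exp(logsumexp(logs))))


def validated_ratio(assoc_pairs, ref_pairs) -> tuple[int, float]:
    """Overlap of an association pair set with a reference-interaction set.

    Returns (count, fraction); the fraction is conventionally reported as
    a percentage with two decimals.
    """
    assoc = set(assoc_pairs)
    if not assoc:
        raise DataIntegrityError("association set is empty")
    count = len(assoc & set(ref_pairs))
    return count, count / len(assoc)


@dataclass
class PermutationResult:
    observed_count: int
    null_counts: np.ndarray
    empirical_p: float
    seed: int

    @property
    def n_perm(self) -> int:
        return len(self.null_counts)


def permutation_test(
    gene_pool,
    param_pool,
    ref_pairs,
    n_assoc: int,
    observed_count: int,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Null distribution of reference-validated counts under random pairing.

    Each permutation draws ``n_assoc`` distinct pairs uniformly from the
    gene x parameter universe and counts the overlap with the reference
    set; the empirical p-value uses the add-one estimator
    (1 + #{null >= observed}) / (n_perm + 1), so it is never 0.
    """
    genes = sorted(set(gene_pool))
    params = sorted(set(param_pool))
    n_universe = len(genes) * len(params)
    if n_assoc > n_universe:
        raise ConfigurationError("n_assoc exceeds the pair universe")
    if observed_count > n_assoc:
        raise ConfigurationError("observed_count cannot exceed n_assoc")

    gene_idx = {g: i for i, g in enumerate(genes)}
    param_idx = {p: i for i, p in enumerate(params)}
    ref_flat = np.zeros(n_universe, dtype=bool)
    for g, p in ref_pairs:
        if g in gene_idx and p in param_idx:
            ref_flat[gene_idx[g] * len(params) + param_idx[p]] = True

    rng = np.random.default_rng(seed)
    null_counts = np.empty(n_perm, dtype=int)
    for t in range(n_perm):
        draw = rng.choice(n_universe, size=n_assoc, replace=False)
        null_counts[t] = int(ref_flat[draw].sum())
    empirical_p = (1 + int((null_counts >= observed_count).sum())) / (n_perm + 1)
    return PermutationResult(
        observed_count=int(observed_count), null_counts=null_counts,
        empirical_p=float(empirical_p), seed=seed,
    )


def term_enrichment(
    query_items,
    universe_items,
    sets: dict[str, tuple],
    p_max: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Hypergeometric enrichment of a query set against named item sets.

    ``sets`` maps term -> (items, catalog, kind) or term -> items. Only
    terms overlapping the query (k >= 1) are reported, sorted by ascending
    p; terms disjoint from the universe are skipped with a log entry.
    """
    query = set(query_items)
    universe = set(universe_items)
    if not query <= universe:
        raise DataIntegrityError("query items must be a subset of the universe")
    N, n = len(universe), len(query)
    rows = []
    for term, payload in sets.items():
        items = payload[0] if isinstance(payload, tuple) else payload
        members = set(items) & universe
        if not members:
            log.info("term_enrichment: term %r disjoint from universe, skipped", term)
            continue
        K = len(members)
        k = len(query & members)
        if k < 1:
            continue
        p = hypergeom_tail(k, n, K, N)
        rows.append({"term": term, "k": k, "n": n, "K": K, "N": N, "p": p})
    df = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N", "p"])
    if len(df):
        df = df.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
        df["significant"] = df["p"] <= p_max
        if fdr:
            df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["significant"] = pd.Series(dtype=bool)
    return df


def parameter_disease(
    assoc: pd.DataFrame,
    disease_sets: dict[str, tuple],
    universe_genes,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Per-parameter enrichment of partner genes against disease gene sets.

    For every parameter in the consensus association table, its partner
    gene set is tested against each disease set; rows with p <= p_max are
    returned sorted by ascending p.
    """
    if assoc.empty:
        raise DataIntegrityError("association table is empty")
    universe = set(universe_genes)
    rows = []
    for parameter, sub in assoc.groupby("parameter"):
        partner_genes = set(sub["gene"]) & universe
        if not partner_genes:
            log.info("parameter_disease: parameter %r has no partner genes in universe", parameter)
            continue
        enr = term_enrichment(partner_genes, universe, disease_sets, p_max=p_max)
        for _, r in enr[enr["significant"]].iterrows():
            rows.append(
                {"parameter": parameter, "disease": r["term"], "k": int(r["k"]), "p": r["p"]}
            )
    df = pd.DataFrame(rows, columns=["parameter", "disease", "k", "p"])
    if len(df):
        df = df.sort_values(["p", "parameter", "disease"], kind="mergesort").reset_index(drop=True)
    return df


def coverage_counts(
    biclusters_per_subject: dict[str, list],
    enrichments_per_bicluster: dict[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Distinct-bicluster coverage per parameter (and per enriched term).

    Counts, for each parameter, the number of distinct (subject, bicluster)
    units whose membership includes it; when per-bicluster enrichment
    tables are supplied, counts for each term the biclusters in which it
    is significantly enriched.
    """
    rows = []
    for subj, biclusters in biclusters_per_subject.items():
        for b in biclusters:
            for q in b.parameter_ids:
                rows.append({"item": q, "kind": "parameter", "unit": b.id})
    if enrichments_per_bicluster:
        for bid, enr in enrichments_per_bicluster.items():
            if enr.empty:
                continue
            for term in enr.loc[enr["significant"], "term"]:
                rows.append({"item": term, "kind": "term", "unit": bid})
    if not rows:
        return pd.DataFrame(columns=["item", "kind", "n_biclusters"])
    df = pd.DataFrame(rows).drop_duplicates()
    out = (
        df.groupby(["item", "kind"], as_index=False)
        .agg(n_biclusters=("unit", "nunique"))
        .sort_values(["n_biclusters", "item"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    return out
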