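"""Probe QC filtering and variability-based probe selection.

Two stages mirror standard 450k practice for small longitudinal cohorts:

1. Five QC filters applied in a fixed order — detection p-value, bead
   count, SNP overlap, multi-mapping, sex chromosomes — each recorded in a
   :class:`FilterReport`.
2. A variability screen that keeps only probes whose across-day beta-value
   standard deviation (``sd_personal``) exceeds both the technical error
   between the two baseline replicate samples (``err_personal``) and an
   absolute floor (default 0.03), in every subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from methylink.errors import ConfigurationError, DataIntegrityError
from methylink.synthetic import ProbeQCTable


@dataclass(frozen=True)
class PreprocessConfig:
    det_p_max: float = 0.01
    bead_min: int = 3
    bead_sample_frac: float = 0.05
    sd_min: float = 0.03
    baseline_days: tuple[str, str] = ("day-45", "day-15")
    #: require sd criteria in every subject ("all") or at least one ("any")
    sd_scope: str = "all"

    def __post_init__(self):
        if self.det_p_max <= 0 or self.bead_min <= 0 or self.sd_min <= 0:
            raise ConfigurationError("thresholds must be positive")
        if len(self.baseline_days) != 2:
            raise ConfigurationError("exactly two baseline days required")
        if self.sd_scope not in ("all", "any"):
            raise ConfigurationError("sd_scope must be 'all' or 'any'")


@dataclass
class FilterReport:
    """Ordered record of filtering steps; retained counts are non-increasing."""

    steps: list[dict] = field(default_factory=list)

    def add(self, name: str, n_removed: int, n_retained: int) -> None:
        if self.steps and n_retained > self.steps[-1]["n_retained"]:
            raise DataIntegrityError("retained count increased across filter steps")
        self.steps.append(
            {"name": name, "n_removed": int(n_removed), "n_retained": int(n_retained)}
        )

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


def qc_filter(
    beta: pd.DataFrame, qc: ProbeQCTable, cfg: PreprocessConfig = PreprocessConfig()
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the five QC filters in order and report per-step removals."""
    for table, name in ((qc.detection_p, "detection_p"), (qc.bead_count, "bead_count"),
                        (qc.flags, "flags")):
        if not beta.index.equals(table.index):
            raise DataIntegrityError(f"probe universe of {name} does not match beta matrix")

    report = FilterReport()
    keep = beta.index

    def apply(name: str, failing: pd.Index):
        nonlocal keep
        removed = keep.intersection(failing)
        keep = keep.difference(removed, sort=False)
        report.add(name, len(removed), len(keep))

    det_fail = qc.detection_p.gt(cfg.det_p_max).any(axis=1)
    apply("detection_p", det_fail.index[det_fail])

    low_bead_frac = qc.bead_count.lt(cfg.bead_min).mean(axis=1)
    apply("bead_count", low_bead_frac.index[low_bead_frac >= cfg.bead_sample_frac])

    for flag, name in (("snp_flag", "snp"), ("multimap_flag", "multimap"),
                       ("sex_chrom_flag", "sex_chromosomes")):
        col = qc.flags[flag]
        apply(name, col.index[col])

    # preserve original probe order
    keep = beta.index[beta.index.isin(keep)]
    return beta.loc[keep], report


def compute_sd_personal(beta: pd.DataFrame, sampling_days=None) -> pd.Series:
    """Per-probe sample sd (n-1 denominator) of beta across sampling days.

    Probes with fewer than two non-missing values get NaN, never zero.
    """
    sub = beta if sampling_days is None else beta[list(sampling_days)]
    if sub.shape[1] < 2:
        raise ConfigurationError("need at least two sampling days")
    sd = sub.std(axis=1, ddof=1, skipna=True)
    sd[sub.notna().sum(axis=1) < 2] = np.nan
    sd.name = "sd_personal"
    return sd


def compute_err_personal(beta: pd.DataFrame, baseline_days) -> pd.Series:
    """Per-probe absolute beta difference between the two baseline replicates."""
    d1, d2 = baseline_days
    for d in (d1, d2):
        if d not in beta.columns:
            raise ConfigurationError(f"baseline day {d!r} not present in beta matrix")
    err = (beta[d1] - beta[d2]).abs()
    err.name = "err_personal"
    return err


def variability_stats(beta: pd.DataFrame, cfg: PreprocessConfig) -> pd.DataFrame:
    """sd_personal and err_personal for one subject's (QC-filtered) beta matrix."""
    return pd.DataFrame(
        {
            "sd_personal": compute_sd_personal(beta),
            "err_personal": compute_err_personal(beta, cfg.baseline_days),
        }
    )


def select_probes(
    stats: dict[str, pd.DataFrame], cfg: PreprocessConfig = PreprocessConfig()
) -> tuple[pd.Index, dict[str, int]]:
    """Intersect the two variability criteria across subjects.

    Criterion A: sd_personal > err_personal (signal above replicate noise);
    criterion B: sd_personal > cfg.sd_min. Under ``sd_scope='all'`` both
    must hold in every subject. Returns the selected probes plus the
    cardinalities of A, B and their intersection for auditability.
    """
    if not stats:
        raise DataIntegrityError("no subjects provided")
    frames = list(stats.values())
    index = frames[0].index
    for subj, df in stats.items():
        if not df.index.equals(index):
            raise DataIntegrityError(f"probe universe mismatch for subject {subj!r}")
        if {"sd_personal", "err_personal"} - set(df.columns):
            raise DataIntegrityError(f"missing variability columns for subject {subj!r}")

    crit_a = pd.concat(
        [(df["sd_personal"] > df["err_personal"]).fillna(False) for df in frames], axis=1
    )
    crit_b = pd.concat(
        [(df["sd_personal"] > cfg.sd_min).fillna(False) for df in frames], axis=1
    )
    agg = (lambda d: d.all(axis=1)) if cfg.sd_scope == "all" else (lambda d: d.any(axis=1))
    set_a, set_b = agg(crit_a), agg(crit_b)
    final = set_a & set_b

    counts = {
        "sd_above_replicate_error": int(set_a.sum()),
        "sd_above_floor": int(set_b.sum()),
        "selected": int(final.sum()),
    }
    return index[final], counts
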