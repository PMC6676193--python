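"""Synthetic longitudinal methylation studies with planted bicluster structure.

The generator emulates a small-cohort, multi-timepoint design: a handful of
subjects sampled on ~12 days (two of which are baseline technical
replicates), a probes x days beta-value matrix and a parameters x days
biochemistry matrix per subject, probe-level QC metadata, a probe -> gene
annotation, a partially informative gene-parameter reference-interaction
set, and term -> gene annotation sets for enrichment.

Planted signal: each planted bicluster couples a block of probes to a block
of parameters through a shared latent time course drawn independently per
subject. Courses are distinct slow physiological programs — cosine patterns
of distinct frequency over the mission timeline (monotone drift, mid-mission
dip, oscillation) with random sign and jitter — orthogonalized over the
correlation days so different programs are statistically separable, and
monotonically respaced so their levels on the correlation days are
well-resolved against the assay noise. Member probes move on the logit
scale, member parameters on the raw scale. A configurable fraction of
background probes carries its own independent random-walk course
(biologically variable but linked to no parameter); the rest is independent
noise. Beta values are logit-normal — Gaussian biological noise on the logit
scale squashed through the inverse logit — which keeps them in [0, 1] with
realistic variance-vs-mean behaviour. Baseline replicate days share their
biology and differ only by technical noise added on the beta scale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from methylink import io as mio
from methylink.errors import ConfigurationError, DataIntegrityError

REGION_GROUPS = ("TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR", "intergenic")

DEFAULT_SAMPLING_DAYS = (-45, -15, 2, 30, 60, 75, 90, 105, 120, 150, 175, 210)
DEFAULT_BASELINE_DAYS = (-45, -15)
#: the seven days shared between methylation and parameter sampling
DEFAULT_SHARED_DAYS = (2, 30, 60, 90, 120, 150, 175)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and noise parameters for one synthetic cohort.

    Noise scales: ``effect_sd`` and ``bio_sd`` act on the logit scale,
    ``tech_sd`` on the beta scale (it is the sd of the replicate-to-replicate
    technical error per sample). Defaults are calibrated so that background
    probes show across-day beta sds around 0.013 and baseline replicate
    differences around 0.008 — the magnitudes typical of blood 450k data —
    while planted probes clear the 0.03 variability cut.
    """

    n_subjects: int = 4
    n_probes: int = 2000
    n_parameters: int = 60
    sampling_days: tuple[int, ...] = DEFAULT_SAMPLING_DAYS
    baseline_days: tuple[int, int] = DEFAULT_BASELINE_DAYS
    correlation_days: tuple[int, ...] = DEFAULT_SHARED_DAYS
    n_planted: int = 3
    probe_block_size: int = 80
    param_block_size: int = 12
    effect_sd: float = 0.35
    tech_sd: float = 0.007
    bio_sd: float = 0.065
    param_noise_sd: float = 0.15
    bg_variable_frac: float = 0.10
    ref_recall: float = 0.8
    ref_background: float = 0.0169
    n_genes: int | None = None
    probes_per_gene: float = 2.0
    qc_fail_frac: float = 0.01
    seed: int = 0

    def __post_init__(self):
        for name in ("n_subjects", "n_probes", "n_parameters", "n_planted",
                     "probe_block_size", "param_block_size"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if len(set(self.sampling_days)) != len(self.sampling_days):
            raise ConfigurationError("sampling_days must be unique")
        if len(self.baseline_days) != 2:
            raise ConfigurationError("exactly two baseline replicate days required")
        if not set(self.baseline_days) <= set(self.sampling_days):
            raise ConfigurationError("baseline_days must be among sampling_days")
        if len(self.sampling_days) - 2 < 7:
            raise ConfigurationError("need at least 7 in-mission sampling days")
        if not set(self.correlation_days) <= set(self.sampling_days):
            raise ConfigurationError("correlation_days must be among sampling_days")
        for name in ("ref_recall", "ref_background"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.n_planted * self.probe_block_size > self.n_probes:
            raise ConfigurationError("planted probe blocks exceed n_probes")
        if self.n_planted * self.param_block_size > self.n_parameters:
            raise ConfigurationError("planted parameter blocks exceed n_parameters")


@dataclass
class ProbeQCTable:
    """Per-probe QC metadata mirroring the 450k screening inputs."""

    detection_p: pd.DataFrame  # probes x samples, in [0, 1]
    bead_count: pd.DataFrame   # probes x samples, non-negative ints
    flags: pd.DataFrame        # probes x {snp_flag, multimap_flag, sex_chrom_flag}


@dataclass
class SyntheticStudy:
    """A complete generated cohort plus its ground truth."""

    config: SimulationConfig
    beta: dict[str, pd.DataFrame]       # subject -> probes x days
    qc: dict[str, ProbeQCTable]
    params: dict[str, pd.DataFrame]     # subject -> parameters x days
    annotation: pd.DataFrame            # probe_id -> chromosome, genes, region
    reference: frozenset                # validated (gene, parameter) pairs
    anno_sets: dict[str, tuple[frozenset, str, str]]  # term -> (genes, catalog, kind)
    truth: dict = field(default_factory=dict)

    @property
    def subjects(self) -> list[str]:
        return sorted(self.beta)


def _random_walk(rng: np.random.Generator, n_points: int) -> np.ndarray:
    """Standardized smooth random walk: serially correlated, mean 0, sd 1."""
    walk = np.cumsum(rng.normal(size=n_points))
    sd = walk.std()
    if sd < 1e-12:  # degenerate draw; fall back to white noise
        walk = rng.normal(size=n_points)
        sd = max(walk.std(), 1e-12)
    return (walk - walk.mean()) / sd


def _latent_courses(
    rng: np.random.Generator,
    n_planted: int,
    bio_days: np.ndarray,
    shared_idx: np.ndarray,
) -> np.ndarray:
    """Distinct physiological programs over the mission timeline.

    Each course is a cosine of distinct frequency over the (scaled) day
    axis with random sign and smooth jitter. Courses are Gram-Schmidt
    orthogonalized on their correlation-day restriction so different
    programs are statistically separable at seven points, then
    monotonically respaced so the correlation-day levels are equispaced —
    rank patterns stay resolvable against biological noise. Mean 0, sd 1
    over the correlation days.
    """
    n_bio = len(bio_days)
    u = (bio_days - bio_days[0]) / max(bio_days[-1] - bio_days[0], 1)
    pool = np.arange(1, max(3, n_planted) + 1)
    freqs = rng.permutation(pool)[:n_planted]
    G = np.empty((n_planted, n_bio))
    for i, f0 in enumerate(freqs):
        G[i] = np.cos(np.pi * f0 * u) * rng.choice([-1.0, 1.0]) + rng.normal(0, 0.1, n_bio)
    # orthogonalize on the correlation-day restriction
    for i in range(n_planted):
        gi = G[i] - G[i][shared_idx].mean()
        for j in range(i):
            gj = G[j]
            denom = gj[shared_idx] @ gj[shared_idx]
            gi = gi - (gi[shared_idx] @ gj[shared_idx]) / max(denom, 1e-12) * gj
        G[i] = gi / max(gi[shared_idx].std(), 1e-9)
    # monotone respacing of the correlation-day levels
    H = np.empty_like(G)
    for i in range(n_planted):
        sv = np.sort(G[i][shared_idx])
        grid = np.linspace(-1.5, 1.5, len(shared_idx))
        h = np.interp(G[i], sv, grid)
        H[i] = (h - h[shared_idx].mean()) / max(h[shared_idx].std(), 1e-9)
    return H


def generate_probe_annotation(
    n_probes: int,
    n_genes: int,
    region_groups: tuple[str, ...] = REGION_GROUPS,
    probes_per_gene: float = 2.0,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Assign 0-2 gene symbols and one region group per probe.

    Each gene receives ``1 + Poisson(probes_per_gene - 1)`` probes drawn
    without replacement, so the mean gene multiplicity matches the
    configured value; probes can carry up to two symbols (multi-gene
    probes), and leftover probes stay unannotated.
    """
    if not region_groups:
        raise ConfigurationError("region_groups must be non-empty")
    if n_probes < n_genes:
        raise ConfigurationError("n_probes must be >= n_genes")
    if probes_per_gene < 1:
        raise ConfigurationError("probes_per_gene must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)

    probe_ids = [f"cg{i:08d}" for i in range(n_probes)]
    genes_per_probe: list[list[str]] = [[] for _ in range(n_probes)]
    for g in range(n_genes):
        gene = f"GENE{g:05d}"
        mult = 1 + rng.poisson(probes_per_gene - 1.0)
        open_slots = np.flatnonzero([len(gl) < 2 for gl in genes_per_probe])
        take = min(mult, open_slots.size)
        for p in rng.choice(open_slots, size=take, replace=False):
            genes_per_probe[p].append(gene)

    regions = rng.choice(len(region_groups), size=n_probes)
    return pd.DataFrame(
        {
            "chromosome": [f"chr{1 + i % 22}" for i in range(n_probes)],
            "genes": [";".join(gl) for gl in genes_per_probe],
            "region": [region_groups[r] for r in regions],
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )


def generate_reference_set(
    truth_pairs,
    all_genes,
    all_parameters,
    ref_recall: float,
    ref_background: float,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> frozenset:
    """Independent Bernoulli inclusion: truth pairs at rate ``ref_recall``,
    all other gene x parameter pairs at rate ``ref_background``."""
    truth_pairs = set(truth_pairs)
    genes, params = sorted(all_genes), sorted(all_parameters)
    universe = {(g, p) for g in genes for p in params}
    if not truth_pairs <= universe:
        raise ConfigurationError("truth_pairs must lie inside all_genes x all_parameters")
    rng = rng if rng is not None else np.random.default_rng(seed)
    out = set()
    for g in genes:
        for p in params:
            rate = ref_recall if (g, p) in truth_pairs else ref_background
            if rng.random() < rate:
                out.add((g, p))
    return frozenset(out)


def generate_annotation_sets(
    all_genes,
    n_terms: int,
    size_range: tuple[int, int],
    planted_terms: dict[str, frozenset] | None = None,
    catalog_labels: tuple[str, ...] = ("catalog_A", "catalog_B", "catalog_C"),
    kind: str = "disease",
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> dict[str, tuple[frozenset, str, str]]:
    """Random item sets per term plus verbatim planted terms, each with a
    catalog label."""
    genes = sorted(all_genes)
    planted_terms = dict(planted_terms or {})
    lo, hi = size_range
    if not (1 <= lo <= hi <= len(genes)):
        raise ConfigurationError("size_range must lie within [1, len(all_genes)]")
    for term, members in planted_terms.items():
        unknown = set(members) - set(genes)
        if unknown:
            raise DataIntegrityError(
                f"planted term {term!r} references unknown genes: {sorted(unknown)[:3]}"
            )
    rng = rng if rng is not None else np.random.default_rng(seed)
    out: dict[str, tuple[frozenset, str, str]] = {}
    for term, members in planted_terms.items():
        label = catalog_labels[len(out) % len(catalog_labels)]
        out[term] = (frozenset(members), label, kind)
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(rng.choice(genes, size=size, replace=False))
        label = catalog_labels[int(rng.integers(len(catalog_labels)))]
        out[f"term{t:04d}"] = (members, label, kind)
    return out


def generate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate a full cohort; deterministic given ``config.seed``.

    Planted blocks (probe and parameter memberships) are shared across
    subjects; latent time courses and every noise draw are independent per
    subject, so cross-subject consensus genuinely tests replication.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    probe_ids = [f"cg{i:08d}" for i in range(cfg.n_probes)]
    param_ids = [f"param{q:04d}" for q in range(cfg.n_parameters)]
    days = list(cfg.sampling_days)
    day_labels = [f"day{d:+d}" for d in days]
    b1, b2 = cfg.baseline_days

    # biological time points: the two baseline replicate days share one
    bio_point: dict[int, int] = {}
    bio_day_values: list[int] = []
    nxt = 0
    for d in days:
        if d == b2:
            bio_point[d] = bio_point[b1]
        else:
            bio_point[d] = nxt
            bio_day_values.append(d)
            nxt += 1
    n_bio = nxt
    shared_bio_idx = np.array([bio_point[d] for d in cfg.correlation_days])

    # planted memberships (shared across subjects), drawn disjointly so the
    # ground truth is unambiguous
    probe_perm = rng.permutation(cfg.n_probes)
    param_perm = rng.permutation(cfg.n_parameters)
    planted_probes = [
        sorted(probe_perm[i * cfg.probe_block_size:(i + 1) * cfg.probe_block_size])
        for i in range(cfg.n_planted)
    ]
    planted_params = [
        sorted(param_perm[i * cfg.param_block_size:(i + 1) * cfg.param_block_size])
        for i in range(cfg.n_planted)
    ]
    member_probe_idx = np.concatenate(planted_probes) if cfg.n_planted else np.array([], int)

    background_idx = np.setdiff1d(np.arange(cfg.n_probes), member_probe_idx)
    n_variable = int(round(cfg.bg_variable_frac * background_idx.size))
    # intrinsically variable probes are a probe property, shared across
    # subjects; their time courses are drawn per subject
    variable_idx = (
        rng.choice(background_idx, size=n_variable, replace=False)
        if n_variable else np.array([], int)
    )

    # base methylation level per probe: signal-carrying probes kept
    # mid-range so the logit-scale effect translates into beta-scale
    # variability
    base_beta = rng.uniform(0.05, 0.95, size=cfg.n_probes)
    signal_idx = np.concatenate([member_probe_idx, variable_idx])
    base_beta[signal_idx] = rng.uniform(0.3, 0.7, size=signal_idx.size)
    base_logit = logit(base_beta)
    probe_sign = rng.choice([-1.0, 1.0], size=cfg.n_probes)
    param_gain = rng.uniform(0.8, 1.2, size=cfg.n_parameters) * rng.choice(
        [-1.0, 1.0], size=cfg.n_parameters
    )

    subjects = [f"S{s + 1:02d}" for s in range(cfg.n_subjects)]
    beta: dict[str, pd.DataFrame] = {}
    params: dict[str, pd.DataFrame] = {}
    qc: dict[str, ProbeQCTable] = {}

    # SNP/multi-mapping/sex-chromosome flags are probe properties, shared
    # by all subjects; detection p and bead counts vary per sample
    shared_flags = pd.DataFrame(
        False, index=pd.Index(probe_ids, name="probe_id"),
        columns=["snp_flag", "multimap_flag", "sex_chrom_flag"],
    )
    n_fail_flags = int(round(cfg.qc_fail_frac * cfg.n_probes))
    for col in shared_flags.columns:
        if n_fail_flags and background_idx.size:
            picks = rng.choice(background_idx,
                               size=min(n_fail_flags, background_idx.size),
                               replace=False)
            shared_flags.iloc[picks, shared_flags.columns.get_loc(col)] = True

    for subj in subjects:
        courses = (
            _latent_courses(rng, cfg.n_planted, np.array(bio_day_values, float),
                            shared_bio_idx)
            if cfg.n_planted else np.zeros((0, n_bio))
        )

        # logit-scale signal per probe per biological point
        signal = np.zeros((cfg.n_probes, n_bio))
        for i in range(cfg.n_planted):
            idx = planted_probes[i]
            signal[idx, :] += np.outer(probe_sign[idx], cfg.effect_sd * courses[i])
        # biologically variable but parameter-unlinked background probes
        for p in variable_idx:
            signal[p, :] = cfg.effect_sd * _random_walk(rng, n_bio)
        bio_noise = rng.normal(0.0, cfg.bio_sd, size=(cfg.n_probes, n_bio))
        logit_bio = base_logit[:, None] + signal + bio_noise
        beta_bio = expit(logit_bio)

        cols = np.array([bio_point[d] for d in days])
        tech = rng.normal(0.0, cfg.tech_sd, size=(cfg.n_probes, len(days)))
        values = np.clip(beta_bio[:, cols] + tech, 0.0, 1.0)
        beta[subj] = pd.DataFrame(
            values, index=pd.Index(probe_ids, name="probe_id"), columns=day_labels
        )

        psignal = np.zeros((cfg.n_parameters, n_bio))
        for i in range(cfg.n_planted):
            idx = planted_params[i]
            psignal[idx, :] += np.outer(param_gain[idx], courses[i])
        pnoise = rng.normal(0.0, cfg.param_noise_sd, size=(cfg.n_parameters, len(days)))
        background = rng.normal(0.0, 1.0, size=(cfg.n_parameters, n_bio))
        is_member_param = np.zeros(cfg.n_parameters, bool)
        for idx in planted_params:
            is_member_param[idx] = True
        pvalues = np.where(
            is_member_param[:, None], psignal[:, cols], background[:, cols]
        ) + pnoise
        params[subj] = pd.DataFrame(
            pvalues, index=pd.Index(param_ids, name="parameter_id"), columns=day_labels
        )

        qc[subj] = _generate_qc(
            rng, probe_ids, day_labels, member_probe_idx, cfg.qc_fail_frac,
            shared_flags,
        )

    annotation = generate_probe_annotation(
        cfg.n_probes,
        cfg.n_genes if cfg.n_genes is not None else max(1, cfg.n_probes // 4),
        REGION_GROUPS,
        cfg.probes_per_gene,
        rng=rng,
    )

    gene_lists = annotation["genes"].str.split(";")
    probe_genes = {
        pid: [g for g in gl if g]
        for pid, gl in zip(annotation.index, gene_lists)
    }
    truth_pairs: set[tuple[str, str]] = set()
    planted_gene_sets: list[frozenset] = []
    for i in range(cfg.n_planted):
        genes_i: set[str] = set()
        for p in planted_probes[i]:
            genes_i.update(probe_genes[probe_ids[p]])
        planted_gene_sets.append(frozenset(genes_i))
        for g in genes_i:
            for q in planted_params[i]:
                truth_pairs.add((g, param_ids[q]))

    all_genes = sorted({g for gl in probe_genes.values() for g in gl})
    reference = generate_reference_set(
        truth_pairs, all_genes, param_ids, cfg.ref_recall, cfg.ref_background, rng=rng
    )
    planted_terms = {
        f"planted_term{i}": gs for i, gs in enumerate(planted_gene_sets) if gs
    }
    anno_sets = generate_annotation_sets(
        all_genes,
        n_terms=40,
        size_range=(5, max(6, len(all_genes) // 10)),
        planted_terms=planted_terms,
        rng=rng,
    )

    truth = {
        "planted_probes": [[probe_ids[p] for p in blk] for blk in planted_probes],
        "planted_params": [[param_ids[q] for q in blk] for blk in planted_params],
        "planted_genes": [sorted(gs) for gs in planted_gene_sets],
        "truth_pairs": sorted(truth_pairs),
    }
    return SyntheticStudy(
        config=cfg, beta=beta, qc=qc, params=params, annotation=annotation,
        reference=reference, anno_sets=anno_sets, truth=truth,
    )


def _generate_qc(
    rng: np.random.Generator,
    probe_ids: list[str],
    day_labels: list[str],
    member_probe_idx: np.ndarray,
    qc_fail_frac: float,
    shared_flags: pd.DataFrame,
) -> ProbeQCTable:
    """Mostly-clean QC tables with a small planted failure fraction.

    Failures are drawn from non-member probes only, so the planted signal
    is not silently truncated and ground-truth recovery stays interpretable.
    """
    n = len(probe_ids)
    det = rng.uniform(0.0, 0.009, size=(n, len(day_labels)))
    beads = rng.poisson(12, size=(n, len(day_labels))) + 3

    background = np.setdiff1d(np.arange(n), member_probe_idx)
    n_fail = int(round(qc_fail_frac * n))

    def pick(k):
        return rng.choice(background, size=min(k, background.size), replace=False)

    for p in pick(n_fail):  # detection failure in one random sample
        det[p, rng.integers(len(day_labels))] = 0.02
    for p in pick(n_fail):  # low bead count in >=5% of samples
        k = max(1, int(np.ceil(0.05 * len(day_labels))))
        beads[p, rng.choice(len(day_labels), size=k, replace=False)] = 1

    idx = pd.Index(probe_ids, name="probe_id")
    return ProbeQCTable(
        detection_p=pd.DataFrame(det, index=idx, columns=day_labels),
        bead_count=pd.DataFrame(beads, index=idx, columns=day_labels),
        flags=shared_flags.copy(),
    )


def write_study(study: SyntheticStudy, outdir: str | Path) -> Path:
    """Serialize a study as TSV/GMT/JSON files under ``outdir``."""
    outdir = Path(outdir)
    for subj in study.subjects:
        mio.write_table(study.beta[subj], outdir / f"beta_{subj}.tsv")
        mio.write_table(study.params[subj], outdir / f"params_{subj}.tsv")
        q = study.qc[subj]
        mio.write_table(q.detection_p, outdir / f"qc_detection_p_{subj}.tsv")
        mio.write_table(q.bead_count, outdir / f"qc_bead_count_{subj}.tsv")
        mio.write_table(q.flags, outdir / f"qc_flags_{subj}.tsv")
    mio.write_table(study.annotation, outdir / "annotation.tsv")
    ref = pd.DataFrame(sorted(study.reference), columns=["gene", "parameter"])
    mio.write_table(ref, outdir / "reference.tsv", index=False)
    mio.write_gmt(
        {t: (members, f"{label}|{kind}") for t, (members, label, kind) in study.anno_sets.items()},
        outdir / "annotation_sets.gmt",
    )
    mio.write_json(study.truth, outdir / "truth.json")
    cfg_dict = dataclasses.asdict(study.config)
    for key in ("sampling_days", "baseline_days", "correlation_days"):
        cfg_dict[key] = list(cfg_dict[key])
    mio.write_json({"subjects": study.subjects, "config": cfg_dict},
                   outdir / "study.json")
    return outdir


def read_study(indir: str | Path) -> SyntheticStudy:
    """Load a study previously written by :func:`write_study`."""
    import json

    indir = Path(indir)
    meta = json.loads((indir / "study.json").read_text())
    subjects = meta["subjects"]
    beta, params, qc = {}, {}, {}
    for subj in subjects:
        beta[subj] = mio.read_beta_table(indir / f"beta_{subj}.tsv")
        params[subj] = mio.read_table(indir / f"params_{subj}.tsv")
        qc[subj] = ProbeQCTable(
            detection_p=mio.read_table(indir / f"qc_detection_p_{subj}.tsv"),
            bead_count=mio.read_table(indir / f"qc_bead_count_{subj}.tsv"),
            flags=mio.read_table(indir / f"qc_flags_{subj}.tsv").astype(bool),
        )
    annotation = mio.read_table(indir / "annotation.tsv")
    annotation["genes"] = annotation["genes"].fillna("")
    ref_df = mio.read_table(indir / "reference.tsv", index_col=None)
    reference = frozenset(map(tuple, ref_df.to_numpy()))
    raw_sets = mio.read_gmt(indir / "annotation_sets.gmt")
    anno_sets = {}
    for term, members in raw_sets.items():
        anno_sets[term] = (members, "", "disease")
    truth = json.loads((indir / "truth.json").read_text())
    truth["truth_pairs"] = [tuple(p) for p in truth.get("truth_pairs", [])]
    cfg_dict = meta["config"]
    for key in ("sampling_days", "baseline_days", "correlation_days"):
        cfg_dict[key] = tuple(cfg_dict[key])
    cfg = SimulationConfig(**cfg_dict)
    return SyntheticStudy(
        config=cfg, beta=beta, qc=qc, params=params, annotation=annotation,
        reference=reference, anno_sets=anno_sets, truth=truth,
    )
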