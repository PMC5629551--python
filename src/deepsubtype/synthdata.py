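"""Synthetic tumor cohorts with a planted process → pathway → TF → gene hierarchy.

The generator emulates the statistical structure the downstream analysis
assumes: per-tissue Gaussian control distributions, tumor subtypes that
activate a fixed subset of biological processes (cascading deterministically
to pathways, transcription factors, and finally standardized expression
shifts of each TF's target genes), copy-number events that shift expression
with matching sign, subtype-enriched driver mutations, and subtype-dependent
exponential survival.

Every draw flows from a single integer seed, so a cohort is byte-identical
across runs with the same config.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: sentinel subtype for non-tumor (control) samples
CONTROL_SUBTYPE = -1

_EXPRESSION_TSV = "expression.tsv"
_CNV_TSV = "cnv.tsv"
_MUTATIONS_TSV = "mutations.tsv"
_CLINICAL_TSV = "clinical.tsv"
_METADATA_TSV = "metadata.tsv"
_SIDECAR_JSON = "cohort.json"


@dataclass(frozen=True)
class LatentHierarchy:
    """Fixed regulatory hierarchy: processes contain pathways, pathways
    contain transcription factors (TFs), TFs target disjoint-or-overlapping
    gene sets.

    ``effect_size`` is the standardized shift (in control-SD units) applied
    to a TF's target genes in tumors where that TF is active.
    """

    n_processes: int
    n_pathways: int
    n_tfs: int
    tf_to_genes: dict[int, tuple[int, ...]]
    pathway_to_tfs: dict[int, tuple[int, ...]]
    process_to_pathways: dict[int, tuple[int, ...]]
    effect_size: float = 6.0
    #: TFs that exist only to satisfy coverage (background genes); they are
    #: never part of an activation cascade and shift nothing
    background_tfs: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        for name, n, mapping in [
            ("process_to_pathways", self.n_processes, self.process_to_pathways),
            ("pathway_to_tfs", self.n_pathways, self.pathway_to_tfs),
            ("tf_to_genes", self.n_tfs, self.tf_to_genes),
        ]:
            if set(mapping) != set(range(n)):
                raise ValueError(f"{name} must have keys 0..{n - 1}")
            if any(len(v) == 0 for v in mapping.values()):
                raise ValueError(f"{name} has an empty target set")
        covered_tfs = {t for v in self.pathway_to_tfs.values() for t in v}
        if covered_tfs != set(range(self.n_tfs)):
            raise ValueError("every TF must belong to >=1 pathway")
        covered_pw = {p for v in self.process_to_pathways.values() for p in v}
        if covered_pw != set(range(self.n_pathways)):
            raise ValueError("every pathway must belong to >=1 process")

    def genes_of_process(self, process: int) -> set[int]:
        genes: set[int] = set()
        for pw in self.process_to_pathways[process]:
            for tf in self.pathway_to_tfs[pw]:
                genes.update(self.tf_to_genes[tf])
        return genes

    def covered_genes(self) -> set[int]:
        return {g for v in self.tf_to_genes.values() for g in v}

    @classmethod
    def balanced(
        cls,
        n_genes: int,
        n_tfs: int = 9,
        n_pathways: int = 3,
        n_processes: int = 3,
        effect_size: float = 6.0,
        signal_fraction: float = 0.6,
    ) -> "LatentHierarchy":
        """Round-robin hierarchy over the first ``signal_fraction`` of genes.

        Signal genes are split evenly across the ``n_tfs`` signal TFs; the
        remaining background genes hang off one extra TF that is listed in
        ``background_tfs`` and therefore never activated -- background genes
        carry no subtype signal, only control noise.
        """
        if not 0 < signal_fraction <= 1:
            raise ValueError("signal_fraction in (0,1]")
        n_signal = max(n_tfs, int(round(n_genes * signal_fraction)))
        n_signal = min(n_signal, n_genes)
        tf_to_genes: dict[int, list[int]] = {t: [] for t in range(n_tfs)}
        for g in range(n_signal):
            tf_to_genes[g % n_tfs].append(g)
        if n_signal < n_genes:
            # background genes hang off a dedicated, never-activated TF
            n_tfs_total = n_tfs + 1
            tf_to_genes[n_tfs] = list(range(n_signal, n_genes))
        else:
            n_tfs_total = n_tfs
        pathway_to_tfs: dict[int, list[int]] = {p: [] for p in range(n_pathways)}
        for t in range(n_tfs):
            pathway_to_tfs[t % n_pathways].append(t)
        if n_tfs_total > n_tfs:
            # coverage invariant needs a pathway; activation skips this TF
            pathway_to_tfs[0].append(n_tfs)
        process_to_pathways: dict[int, list[int]] = {p: [] for p in range(n_processes)}
        for pw in range(n_pathways):
            process_to_pathways[pw % n_processes].append(pw)
        return cls(
            n_processes=n_processes,
            n_pathways=n_pathways,
            n_tfs=n_tfs_total,
            tf_to_genes={k: tuple(v) for k, v in tf_to_genes.items()},
            pathway_to_tfs={k: tuple(v) for k, v in pathway_to_tfs.items()},
            process_to_pathways={k: tuple(v) for k, v in process_to_pathways.items()},
            effect_size=effect_size,
            background_tfs=(n_tfs,) if n_tfs_total > n_tfs else (),
        )


@dataclass(frozen=True)
class CohortConfig:
    """Generation parameters for a synthetic cohort.

    Expression scale is strictly positive: control means are drawn from
    ``control_mean_range`` whose lower bound must sit >= 5 SD (upper bound of
    ``control_sd_range``) above zero, so fold-change rules are well defined.
    """

    n_tissues: int = 2
    tumors_per_tissue: int = 100
    controls_per_tissue: int = 50
    n_genes: int = 400
    n_subtypes: int = 3
    hierarchy: LatentHierarchy | None = None
    control_mean_range: tuple[float, float] = (4.0, 10.0)
    control_sd_range: tuple[float, float] = (0.25, 0.6)
    cnv_rate: float = 0.02
    cnv_expression_shift: float = 3.0
    mutations_per_subtype: int = 5
    mutation_enrichment: float = 0.6
    background_mutation_rate: float = 0.05
    baseline_hazard: float = 0.02
    subtype_hazard_ratios: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tissues", "tumors_per_tissue", "controls_per_tissue",
                     "n_genes", "n_subtypes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("cnv_rate", "mutation_enrichment", "background_mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0,1]")
        for name in ("control_mean_range", "control_sd_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a positive, ordered interval")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.subtype_hazard_ratios is not None:
            if len(self.subtype_hazard_ratios) != self.n_subtypes:
                raise ValueError("subtype_hazard_ratios length must equal n_subtypes")
            if any(r <= 0 for r in self.subtype_hazard_ratios):
                raise ValueError("hazard ratios must be > 0")
        if self.control_mean_range[0] < 5 * self.control_sd_range[1]:
            raise ValueError(
                "control_mean_range lower bound must be >= 5x the largest control SD "
                "(positive-scale requirement for fold-change rules)"
            )

    def resolved_hierarchy(self) -> LatentHierarchy:
        if self.hierarchy is not None:
            return self.hierarchy
        return LatentHierarchy.balanced(self.n_genes)

    def resolved_hazard_ratios(self) -> np.ndarray:
        if self.subtype_hazard_ratios is not None:
            return np.asarray(self.subtype_hazard_ratios, dtype=float)
        # geometric spacing from 1 to 3 across subtypes
        if self.n_subtypes == 1:
            return np.array([1.0])
        return np.geomspace(1.0, 3.0, self.n_subtypes)


@dataclass
class ExpressionCohort:
    """A cohort: continuous expression plus sample metadata and optional
    CNV, mutation, and survival tables.

    ``expression`` is samples x genes. ``true_subtype`` is the planted label
    for tumors and :data:`CONTROL_SUBTYPE` for controls (synthetic only).
    """

    expression: pd.DataFrame
    tissue: pd.Series
    is_tumor: pd.Series
    cnv: pd.DataFrame | None = None
    mutations: pd.DataFrame | None = None
    survival_time: pd.Series | None = None
    survival_event: pd.Series | None = None
    true_subtype: pd.Series | None = None
    config: CohortConfig | None = None
    truth: dict = field(default_factory=dict)

    @property
    def sample_ids(self) -> pd.Index:
        return self.expression.index

    @property
    def gene_ids(self) -> pd.Index:
        return self.expression.columns

    @property
    def n_samples(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    def tumors(self) -> pd.DataFrame:
        return self.expression.loc[self.is_tumor.astype(bool)]

    def controls(self) -> pd.DataFrame:
        return self.expression.loc[~self.is_tumor.astype(bool)]

    def validate(self) -> None:
        n, g = self.expression.shape
        if self.expression.isna().any().any():
            raise ValueError("expression contains missing values")
        for name in ("tissue", "is_tumor"):
            s = getattr(self, name)
            if not s.index.equals(self.sample_ids):
                raise ValueError(f"{name} index does not match sample ids")
        for name in ("cnv", "mutations"):
            m = getattr(self, name)
            if m is not None and (not m.index.equals(self.sample_ids)
                                  or not m.columns.equals(self.gene_ids)):
                raise ValueError(f"{name} is not aligned with expression")
        if self.true_subtype is not None:
            ctrl = ~self.is_tumor.astype(bool)
            if (self.true_subtype[ctrl] != CONTROL_SUBTYPE).any():
                raise ValueError("controls must carry the control-subtype sentinel")

    def __eq__(self, other: object) -> bool:  # round-trip equality
        if not isinstance(other, ExpressionCohort):
            return NotImplemented

        def _eq(a, b):
            if a is None or b is None:
                return a is None and b is None
            if a.shape != b.shape or list(a.index) != list(b.index):
                return False
            av, bv = np.asarray(a), np.asarray(b)
            nan_ok = av.dtype.kind == "f" and bv.dtype.kind == "f"
            return bool(np.array_equal(av, bv, equal_nan=nan_ok))

        return (
            _eq(self.expression, other.expression)
            and list(self.gene_ids) == list(other.gene_ids)
            and _eq(self.tissue, other.tissue)
            and _eq(self.is_tumor, other.is_tumor)
            and _eq(self.cnv, other.cnv)
            and _eq(self.mutations, other.mutations)
            and _eq(self.survival_time, other.survival_time)
            and _eq(self.survival_event, other.survival_event)
            and _eq(self.true_subtype, other.true_subtype)
        )


def _subtype_process_code(n_subtypes: int, n_processes: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Fixed binary subtype -> process activation code, distinct and nonempty
    per subtype so clusters are identifiable.

    The first ``min(n_subtypes, n_processes)`` subtypes get singleton codes
    (one private process each, in seeded order) so that subtypes are
    pairwise non-nested -- nested codes would make some pairs of subtypes
    geometrically closer and the planted k ambiguous.  Additional subtypes
    draw seeded distinct multi-process combinations."""
    n_combos = 2 ** n_processes - 1
    if n_subtypes > n_combos:
        raise ValueError(
            f"n_subtypes={n_subtypes} exceeds the {n_combos} distinct nonempty "
            f"process combinations available with {n_processes} processes"
        )
    code = np.zeros((n_subtypes, n_processes), dtype=int)
    singleton_order = rng.permutation(n_processes)
    n_single = min(n_subtypes, n_processes)
    for s in range(n_single):
        code[s, singleton_order[s]] = 1
    if n_subtypes > n_single:
        singles = set(1 << int(p) for p in range(n_processes))
        pool = np.array([x for x in range(1, n_combos + 1) if x not in singles])
        combos = rng.permutation(pool)[: n_subtypes - n_single]
        code[n_single:] = ((combos[:, None] >> np.arange(n_processes)[None, :])
                           & 1).astype(int)
    return code


def generate_cohort(config: CohortConfig) -> ExpressionCohort:
    """Draw a full synthetic cohort from ``config`` (seeded, reproducible).

    Controls are drawn per (tissue, gene) from Gaussians whose means and SDs
    are sampled from the config ranges.  Tumors start from the same control
    Gaussian, then each subtype's active TFs shift their target genes by
    ``+/- effect_size`` control SDs (direction fixed per TF), CNV events add
    ``cnv_expression_shift`` SDs with matching sign, and survival is
    exponential with subtype-specific hazards plus independent exponential
    censoring (~30% censored).
    """
    rng = np.random.default_rng(config.seed)
    hier = config.resolved_hierarchy()
    if hier.covered_genes() != set(range(config.n_genes)):
        raise ValueError("hierarchy must cover exactly the configured genes")

    n_t, n_c = config.tumors_per_tissue, config.controls_per_tissue
    n_genes = config.n_genes
    tissues = [f"tissue{t}" for t in range(config.n_tissues)]
    gene_ids = pd.Index([f"G{g:04d}" for g in range(n_genes)], name="gene_id")

    # fixed per-run latent structure
    code = _subtype_process_code(config.n_subtypes, hier.n_processes, rng)
    # TF direction: +1 up, -1 down, Bernoulli(0.5) per TF
    tf_sign = rng.choice([-1.0, 1.0], size=hier.n_tfs)
    # which TFs a subtype activates (signal TFs only; background TFs added by
    # LatentHierarchy.balanced are never in any process cascade of the code)
    subtype_gene_shift = np.zeros((config.n_subtypes, n_genes))
    for s in range(config.n_subtypes):
        active_tfs: set[int] = set()
        for proc in np.flatnonzero(code[s]):
            for pw in hier.process_to_pathways[proc]:
                active_tfs.update(hier.pathway_to_tfs[pw])
        active_tfs -= set(hier.background_tfs)
        for tf in active_tfs:
            genes = list(hier.tf_to_genes[tf])
            subtype_gene_shift[s, genes] += tf_sign[tf] * hier.effect_size

    # per (tissue, gene) control Gaussians
    lo_m, hi_m = config.control_mean_range
    lo_s, hi_s = config.control_sd_range
    control_mean = rng.uniform(lo_m, hi_m, size=(config.n_tissues, n_genes))
    control_sd = rng.uniform(lo_s, hi_s, size=(config.n_tissues, n_genes))

    sample_ids: list[str] = []
    tissue_labels: list[str] = []
    is_tumor_flags: list[int] = []
    blocks: list[np.ndarray] = []
    subtype_all: list[int] = []
    cnv_blocks: list[np.ndarray] = []

    hr = config.resolved_hazard_ratios()

    for t, tname in enumerate(tissues):
        mu, sd = control_mean[t], control_sd[t]
        # controls
        ctrl = rng.normal(mu, sd, size=(n_c, n_genes))
        blocks.append(ctrl)
        cnv_blocks.append(np.zeros((n_c, n_genes), dtype=int))
        sample_ids += [f"{tname}-N{i:04d}" for i in range(n_c)]
        tissue_labels += [tname] * n_c
        is_tumor_flags += [0] * n_c
        subtype_all += [CONTROL_SUBTYPE] * n_c
        # tumors: subtypes round-robin for balanced arms
        subtypes = np.arange(n_t) % config.n_subtypes
        tum = rng.normal(mu, sd, size=(n_t, n_genes))
        tum += subtype_gene_shift[subtypes] * sd[None, :]
        # CNV events
        cnv = np.zeros((n_t, n_genes), dtype=int)
        if config.cnv_rate > 0:
            hit = rng.random((n_t, n_genes)) < config.cnv_rate
            sign = rng.choice([-1, 1], size=(n_t, n_genes))
            cnv = np.where(hit, sign, 0)
            tum += cnv * config.cnv_expression_shift * sd[None, :]
        blocks.append(tum)
        cnv_blocks.append(cnv)
        sample_ids += [f"{tname}-T{i:04d}" for i in range(n_t)]
        tissue_labels += [tname] * n_t
        is_tumor_flags += [1] * n_t
        subtype_all += list(subtypes)

    idx = pd.Index(sample_ids, name="sample_id")
    expression = pd.DataFrame(np.vstack(blocks), index=idx, columns=gene_ids)
    tissue = pd.Series(tissue_labels, index=idx, name="tissue")
    is_tumor = pd.Series(is_tumor_flags, index=idx, name="is_tumor")
    true_subtype = pd.Series(subtype_all, index=idx, name="true_subtype")
    cnv_df = pd.DataFrame(np.vstack(cnv_blocks), index=idx, columns=gene_ids)

    # subtype-enriched driver mutations over a background rate
    n_total = len(idx)
    tumor_mask = np.asarray(is_tumor_flags, dtype=bool)
    mut = (rng.random((n_total, n_genes)) < config.background_mutation_rate)
    mut[~tumor_mask] = False
    driver_genes = {}
    all_drivers = rng.permutation(n_genes)[: config.mutations_per_subtype
                                           * config.n_subtypes]
    for s in range(config.n_subtypes):
        dg = all_drivers[s * config.mutations_per_subtype:
                         (s + 1) * config.mutations_per_subtype]
        driver_genes[s] = [str(gene_ids[g]) for g in dg]
        rows = np.flatnonzero(tumor_mask & (np.asarray(subtype_all) == s))
        enriched = rng.random((len(rows), len(dg))) < config.mutation_enrichment
        mut[np.ix_(rows, dg)] |= enriched
    mutations = pd.DataFrame(mut.astype(int), index=idx, columns=gene_ids)

    # exponential survival with subtype hazards; independent exponential
    # censoring tuned for ~30% censored events overall
    subtype_arr = np.asarray(subtype_all)
    hazard = np.where(tumor_mask, config.baseline_hazard
                      * np.where(subtype_arr >= 0, hr[np.clip(subtype_arr, 0, None)], 1.0),
                      np.nan)
    censor_rate = (3.0 / 7.0) * config.baseline_hazard * float(np.mean(hr))
    t_event = np.full(n_total, np.nan)
    t_cens = np.full(n_total, np.nan)
    t_event[tumor_mask] = rng.exponential(1.0 / hazard[tumor_mask])
    t_cens[tumor_mask] = rng.exponential(1.0 / censor_rate, size=tumor_mask.sum())
    time = np.where(tumor_mask, np.minimum(t_event, t_cens), np.nan)
    event = np.where(tumor_mask, (t_event <= t_cens).astype(float), np.nan)

    cohort = ExpressionCohort(
        expression=expression,
        tissue=tissue,
        is_tumor=is_tumor,
        cnv=cnv_df if config.cnv_rate > 0 else cnv_df,  # always materialized
        mutations=mutations,
        survival_time=pd.Series(time, index=idx, name="time"),
        survival_event=pd.Series(event, index=idx, name="event"),
        true_subtype=true_subtype,
        config=config,
        truth={
            "control_mean": control_mean,
            "control_sd": control_sd,
            "tf_sign": tf_sign,
            "subtype_process_code": code,
            "subtype_gene_shift": subtype_gene_shift,
            "driver_genes": driver_genes,
            "censor_rate": censor_rate,
            "tissues": tissues,
        },
    )
    cohort.validate()
    return cohort


def _config_to_jsonable(config: CohortConfig) -> dict:
    d = dataclasses.asdict(config)
    if config.hierarchy is not None:
        d["hierarchy"] = {
            "n_processes": config.hierarchy.n_processes,
            "n_pathways": config.hierarchy.n_pathways,
            "n_tfs": config.hierarchy.n_tfs,
            "effect_size": config.hierarchy.effect_size,
            "tf_to_genes": {str(k): list(v) for k, v in config.hierarchy.tf_to_genes.items()},
            "pathway_to_tfs": {str(k): list(v) for k, v in config.hierarchy.pathway_to_tfs.items()},
            "process_to_pathways": {str(k): list(v)
                                    for k, v in config.hierarchy.process_to_pathways.items()},
        }
    return d


def write_cohort(cohort: ExpressionCohort, directory: str | Path,
                 overwrite: bool = False) -> list[Path]:
    """Write cohort TSVs (genes in rows, samples in columns for matrices)
    plus a sidecar JSON with the generating config and seed.

    Refuses to overwrite existing files unless ``overwrite`` is set.
    Optional tables that are absent are simply not written.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _target(name: str) -> Path:
        p = directory / name
        if p.exists() and not overwrite:
            raise FileExistsError(f"{p} exists; pass overwrite=True to replace it")
        return p

    def _write_matrix(df: pd.DataFrame, name: str, as_int: bool = False) -> None:
        p = _target(name)
        out = df.T  # genes in rows, samples in columns
        out.index.name = "gene_id"
        if as_int:
            out = out.astype(int)
            out.to_csv(p, sep="\t")
        else:
            # %.17g round-trips float64 exactly
            out.to_csv(p, sep="\t", float_format="%.17g")
        written.append(p)

    cohort.validate()
    _write_matrix(cohort.expression, _EXPRESSION_TSV)
    if cohort.cnv is not None:
        _write_matrix(cohort.cnv, _CNV_TSV, as_int=True)
    if cohort.mutations is not None:
        _write_matrix(cohort.mutations, _MUTATIONS_TSV, as_int=True)

    clinical = pd.DataFrame({
        "sample_id": cohort.sample_ids,
        "tissue": cohort.tissue.values,
        "is_tumor": cohort.is_tumor.astype(int).values,
        "time": (cohort.survival_time.values
                 if cohort.survival_time is not None else np.nan),
        "event": (cohort.survival_event.values
                  if cohort.survival_event is not None else np.nan),
        "true_subtype": (cohort.true_subtype.values
                         if cohort.true_subtype is not None else CONTROL_SUBTYPE),
    })
    p = _target(_CLINICAL_TSV)
    clinical.to_csv(p, sep="\t", index=False, float_format="%.17g")
    written.append(p)

    meta = clinical[["sample_id", "tissue", "is_tumor"]]
    p = _target(_METADATA_TSV)
    meta.to_csv(p, sep="\t", index=False)
    written.append(p)

    p = _target(_SIDECAR_JSON)
    sidecar = {"seed": cohort.config.seed if cohort.config else None,
               "config": _config_to_jsonable(cohort.config) if cohort.config else None}
    p.write_text(json.dumps(sidecar, indent=2, default=str))
    written.append(p)
    return written


def read_cohort(directory: str | Path) -> ExpressionCohort:
    """Read a cohort written by :func:`write_cohort`; tolerates missing
    optional tables (cnv, mutations)."""
    directory = Path(directory)
    expr = pd.read_csv(directory / _EXPRESSION_TSV, sep="\t", index_col=0,
                       float_precision="round_trip").T
    expr.index.name = "sample_id"
    expr.columns.name = "gene_id"
    clinical = pd.read_csv(directory / _CLINICAL_TSV, sep="\t",
                           float_precision="round_trip").set_index("sample_id")
    clinical = clinical.loc[expr.index]

    def _opt_matrix(name: str) -> pd.DataFrame | None:
        p = directory / name
        if not p.exists():
            return None
        m = pd.read_csv(p, sep="\t", index_col=0).T
        m.index.name = "sample_id"
        m.columns.name = "gene_id"
        return m.loc[expr.index, expr.columns].astype(int)

    has_surv = clinical["time"].notna().any()
    return ExpressionCohort(
        expression=expr,
        tissue=clinical["tissue"].rename("tissue"),
        is_tumor=clinical["is_tumor"].astype(int).rename("is_tumor"),
        cnv=_opt_matrix(_CNV_TSV),
        mutations=_opt_matrix(_MUTATIONS_TSV),
        survival_time=clinical["time"].rename("time") if has_surv else None,
        survival_event=clinical["event"].rename("event") if has_surv else None,
        true_subtype=clinical["true_subtype"].astype(int).rename("true_subtype"),
    )
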