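"""Tumor-vs-normal expression binarization with copy-number masking.

Per (gene, tissue), a Gaussian is fitted to tissue-matched control samples
only.  A tumor's expression is called aberrant when it falls outside a
two-sided tail of that Gaussian (default tail mass 0.001 per side,
z ~= 3.0902).  Genes whose control SD is below ``low_sd`` (default 0.2) use a
fold-change rule instead (default 3-fold up, 1/3 down), which presumes a
strictly positive expression scale.  Up-calls co-occurring with copy-number
amplification, and down-calls with deletion, are masked to 0: such changes
are attributed to the genomic alteration rather than regulatory signaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthdata import ExpressionCohort


@dataclass
class ControlGaussians:
    """Per (tissue, gene) control-fit means and SDs.

    ``mean`` and ``sd`` are tissue x gene DataFrames; ``ddof`` records the SD
    divisor convention (1 = unbiased n-1 divisor, the default; 0 = MLE).
    """

    mean: pd.DataFrame
    sd: pd.DataFrame
    ddof: int = 1

    @property
    def tissues(self) -> pd.Index:
        return self.mean.index

    @property
    def gene_ids(self) -> pd.Index:
        return self.mean.columns

    def low_variance_mask(self, low_sd: float = 0.2) -> pd.DataFrame:
        """Boolean tissue x gene mask of fits routed to the fold-change rule."""
        return self.sd < low_sd


def fit_control_gaussians(cohort: ExpressionCohort, ddof: int = 1) -> ControlGaussians:
    """Fit per-(gene, tissue) Gaussians from control samples only.

    Raises if any tissue has fewer than two controls (SD undefined).
    """
    is_ctrl = ~cohort.is_tumor.astype(bool)
    means, sds = {}, {}
    for tissue, grp in cohort.expression[is_ctrl].groupby(cohort.tissue[is_ctrl]):
        if len(grp) < 2:
            raise ValueError(
                f"tissue {tissue!r} has {len(grp)} control sample(s); "
                "need >=2 to fit a Gaussian"
            )
        means[tissue] = grp.mean(axis=0)
        sds[tissue] = grp.std(axis=0, ddof=ddof)
    tumor_tissues = set(cohort.tissue[cohort.is_tumor.astype(bool)])
    missing = tumor_tissues - set(means)
    if missing:
        raise ValueError(f"no control samples for tissue(s): {sorted(missing)}")
    return ControlGaussians(mean=pd.DataFrame(means).T,
                            sd=pd.DataFrame(sds).T, ddof=ddof)


def call_aberrations(
    tumors: pd.DataFrame,
    tissue_labels: pd.Series,
    params: ControlGaussians,
    tail: float = 0.001,
    low_sd: float = 0.2,
    fold: float = 3.0,
) -> pd.DataFrame:
    """Signed aberration calls (-1 down, 0 none, +1 up) for tumor samples.

    Gaussian branch (control sd >= ``low_sd``): call +1 above
    ``mean + z*sd`` and -1 below ``mean - z*sd``, where z is the
    standard-normal quantile at ``1 - tail`` (z ~= 3.0902 at tail 0.001).
    Fold branch (sd < ``low_sd``): +1 at >= ``fold * mean``, -1 at
    <= ``mean / fold``.  ``tail`` is the per-side tail mass; callers wanting a
    total two-sided mass of 0.001 should pass ``tail=0.0005``.
    """
    if not 0 < tail < 0.5:
        raise ValueError("tail must be in (0, 0.5)")
    if fold <= 1:
        raise ValueError("fold must be > 1")
    if not tissue_labels.index.equals(tumors.index):
        raise ValueError("tissue_labels must be indexed like tumors")
    missing_t = set(tissue_labels) - set(params.tissues)
    if missing_t:
        raise ValueError(f"no control fit for tissue(s): {sorted(missing_t)}")
    if not tumors.columns.isin(params.gene_ids).all():
        bad = tumors.columns[~tumors.columns.isin(params.gene_ids)][0]
        raise ValueError(f"no control fit for gene {bad!r}")

    z = stats.norm.ppf(1.0 - tail)
    mu = params.mean.loc[tissue_labels, tumors.columns].to_numpy()
    sd = params.sd.loc[tissue_labels, tumors.columns].to_numpy()
    x = tumors.to_numpy(dtype=float)

    fold_branch = sd < low_sd
    if np.any(fold_branch & (mu <= 0)):
        i, j = np.argwhere(fold_branch & (mu <= 0))[0]
        raise ValueError(
            "fold-change rule undefined for nonpositive control mean "
            f"(sample {tumors.index[i]!r}, gene {tumors.columns[j]!r})"
        )

    up_g = x > mu + z * sd
    dn_g = x < mu - z * sd
    up_f = x >= fold * mu
    dn_f = x <= mu / fold
    up = np.where(fold_branch, up_f, up_g)
    dn = np.where(fold_branch, dn_f, dn_g)
    calls = up.astype(int) - dn.astype(int)
    return pd.DataFrame(calls, index=tumors.index, columns=tumors.columns)


def mask_cnv(calls: pd.DataFrame, cnv: pd.DataFrame,
             with_audit: bool = True) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Binary aberration matrix after masking copy-number-explained calls.

    An up-call (+1) with amplification (cnv >= +1), or a down-call (-1) with
    deletion (cnv <= -1), is set to 0; every other call contributes |call|.
    GISTIC scores of +/-2 are treated as +/-1.  Returns (binary matrix,
    audit table of nonzero calls: sample, gene, call, cnv, masked).
    """
    if not calls.index.equals(cnv.index):
        diff = calls.index.symmetric_difference(cnv.index)
        raise ValueError(f"sample ids misaligned; first mismatch: {diff[0]!r}")
    if not calls.columns.equals(cnv.columns):
        diff = calls.columns.symmetric_difference(cnv.columns)
        raise ValueError(f"gene ids misaligned; first mismatch: {diff[0]!r}")
    c = calls.to_numpy()
    g = np.clip(cnv.to_numpy(), -1, 1)
    masked = (c != 0) & (c == g)
    out = np.abs(c)
    out[masked] = 0
    binary = pd.DataFrame(out, index=calls.index, columns=calls.columns)

    audit = None
    if with_audit:
        rows, cols = np.nonzero(c)
        audit = pd.DataFrame({
            "sample_id": calls.index[rows],
            "gene_id": calls.columns[cols],
            "call": c[rows, cols],
            "cnv": cnv.to_numpy()[rows, cols],
            "masked": masked[rows, cols].astype(int),
        })
    return binary, audit


def aberration_matrix(
    cohort: ExpressionCohort,
    tail: float = 0.001,
    low_sd: float = 0.2,
    fold: float = 3.0,
    ddof: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """End-to-end: fit controls, call tumor aberrations, mask by CNV.

    Controls are never scored; the returned binary matrix covers tumor
    samples only.  Returns (binary matrix, masking audit or None when the
    cohort has no CNV table).
    """
    params = fit_control_gaussians(cohort, ddof=ddof)
    tumor_mask = cohort.is_tumor.astype(bool)
    calls = call_aberrations(cohort.expression[tumor_mask],
                             cohort.tissue[tumor_mask], params,
                             tail=tail, low_sd=low_sd, fold=fold)
    if cohort.cnv is not None:
        return mask_cnv(calls, cohort.cnv.loc[tumor_mask])
    return calls.abs(), None
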