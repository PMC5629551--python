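"""Feature filters for the binary aberration matrix.

Two unsupervised filters remove uninformative or tissue-confounded genes
before representation learning:

* Bernoulli-variance filter: a gene aberrant (or non-aberrant) in at least a
  fraction ``p`` of tumors (default 0.90) carries little variance and is
  removed.  The stricter 0.95 and the high-variance 0.70 settings are the
  same operation at a different ``p``.
* Tissue-correlation filter: a gene whose absolute Pearson correlation with
  any tissue's one-hot indicator exceeds ``r_max`` (default 0.85) is a
  tissue marker, not a disease signal, and is removed.

Both are stable (kept genes preserve input order), idempotent, and monotone
in their threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class FeatureFilterReport:
    """Outcome of a filter pass: kept gene ids (input order) and a removal
    table with per-gene reason and statistic."""

    kept_genes: list[str]
    removed: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["gene_id", "reason", "statistic", "detail"])
    )

    def apply(self, m: pd.DataFrame) -> pd.DataFrame:
        return m.loc[:, self.kept_genes]

    @property
    def removed_genes(self) -> list[str]:
        return list(self.removed["gene_id"])


def _check_binary(m: pd.DataFrame) -> None:
    if m.size == 0:
        raise ValueError("empty aberration matrix")
    vals = m.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("aberration matrix must be binary (0/1)")


def bernoulli_variance_filter(m: pd.DataFrame, p: float = 0.90) -> FeatureFilterReport:
    """Remove genes with Bernoulli success rate (fraction of 1s) >= ``p`` or
    <= ``1 - p``; ties at exactly ``p`` are removed."""
    _check_binary(m)
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    rate = m.mean(axis=0)
    extreme = np.maximum(rate, 1.0 - rate)
    drop = extreme >= p
    removed = pd.DataFrame({
        "gene_id": m.columns[drop],
        "reason": "low_bernoulli_variance",
        "statistic": rate[drop].to_numpy(),
        "detail": "",
    })
    return FeatureFilterReport(kept_genes=list(m.columns[~drop]), removed=removed)


def tissue_correlation_filter(
    m: pd.DataFrame, tissue_labels: pd.Series, r_max: float = 0.85
) -> FeatureFilterReport:
    """Remove genes whose |Pearson r| against any tissue one-hot indicator
    exceeds ``r_max`` (strict).  Constant genes are removed with reason
    "constant".  With a single tissue the filter is a logged no-op.
    """
    _check_binary(m)
    if not tissue_labels.index.equals(m.index):
        raise ValueError("tissue_labels must be indexed like the matrix samples")
    tissues = pd.unique(tissue_labels)
    if len(tissues) < 2:
        logger.warning("tissue_correlation_filter: single tissue -- no-op")
        return FeatureFilterReport(kept_genes=list(m.columns))

    x = m.to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    x_ss = np.sqrt((xc ** 2).sum(axis=0))
    constant = x_ss == 0

    max_abs_r = np.zeros(m.shape[1])
    worst = np.array([""] * m.shape[1], dtype=object)
    for t in tissues:
        y = (tissue_labels == t).to_numpy(dtype=float)
        yc = y - y.mean()
        y_ss = np.sqrt((yc ** 2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.abs(xc.T @ yc) / (x_ss * y_ss)
        r = np.where(constant, 0.0, r)
        upd = r > max_abs_r
        max_abs_r = np.where(upd, r, max_abs_r)
        worst[upd] = str(t)

    drop_corr = max_abs_r > r_max
    drop = drop_corr | constant
    reason = np.where(constant, "constant", "tissue_correlated")
    removed = pd.DataFrame({
        "gene_id": m.columns[drop],
        "reason": reason[drop],
        "statistic": max_abs_r[drop],
        "detail": worst[drop],
    })
    return FeatureFilterReport(kept_genes=list(m.columns[~drop]), removed=removed)


def filter_features(
    m: pd.DataFrame,
    tissue_labels: pd.Series | None = None,
    p: float = 0.90,
    r_max: float = 0.85,
) -> tuple[pd.DataFrame, FeatureFilterReport]:
    """Bernoulli-variance then tissue-correlation filtering; returns the
    filtered matrix and a combined report."""
    rep1 = bernoulli_variance_filter(m, p=p)
    m1 = rep1.apply(m)
    if tissue_labels is not None and m1.shape[1] > 0:
        rep2 = tissue_correlation_filter(m1, tissue_labels, r_max=r_max)
        m2 = rep2.apply(m1)
        removed = pd.concat([rep1.removed, rep2.removed], ignore_index=True)
        return m2, FeatureFilterReport(kept_genes=rep2.kept_genes, removed=removed)
    return m1, rep1


def write_filter_report(report: FeatureFilterReport, path) -> None:
    """filter_report.tsv: one row per gene with decision, reason, statistic."""
    kept = pd.DataFrame({"gene_id": report.kept_genes, "decision": "kept",
                         "reason": "", "statistic": np.nan, "detail": ""})
    rem = report.removed.copy()
    rem.insert(1, "decision", "removed")
    pd.concat([kept, rem], ignore_index=True).to_csv(path, sep="\t", index=False)
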