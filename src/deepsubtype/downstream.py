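"""Clinical and mechanistic readout of clusters.

Survival: Kaplan-Meier curves per cluster and the g-sample log-rank test
(observed-minus-expected events across pooled event times, chi-square with
g-1 degrees of freedom); both are delegated to lifelines.

Correlates: for each cluster, the Pearson correlation between every binary
feature (aberration call or mutation) and the cluster's one-vs-rest
indicator; the top-k positively correlated features per cluster are ranked
for word-cloud-style reporting, with weights normalized within each cluster
only (weights are not comparable across clusters).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

logger = logging.getLogger(__name__)


@dataclass
class SurvivalRecords:
    """Aligned per-sample survival data: time >= 0, event in {0, 1},
    group = cluster id."""

    time: np.ndarray
    event: np.ndarray
    group: np.ndarray
    sample_ids: list | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=float)
        self.group = np.asarray(self.group)
        if self.time.shape != self.event.shape or self.time.shape != self.group.shape:
            raise ValueError("time, event, group must be aligned")
        if (self.time < 0).any():
            raise ValueError("negative survival times")
        if not np.isin(self.event, (0.0, 1.0)).all():
            raise ValueError("event indicator must be 0/1")

    @classmethod
    def from_frames(cls, clinical: pd.DataFrame,
                    assignment: pd.Series) -> "SurvivalRecords":
        """Join a clinical table (time, event columns) with cluster labels
        on sample id; samples without survival data are dropped."""
        df = clinical.loc[clinical.index.intersection(assignment.index)].copy()
        df["group"] = assignment.loc[df.index]
        df = df.dropna(subset=["time", "event"])
        return cls(time=df["time"].to_numpy(), event=df["event"].to_numpy(),
                   group=df["group"].to_numpy(), sample_ids=list(df.index))


def km_estimate(records: SurvivalRecords, group=None) -> pd.DataFrame:
    """Kaplan-Meier product-limit curve for one group (or all records).

    Returns a step-function table (time, survival, at_risk, censored):
    right-continuous, nonincreasing, starting at S(0)=1."""
    if group is not None:
        mask = records.group == group
        if not mask.any():
            raise ValueError(f"no records in group {group!r}")
        t, e = records.time[mask], records.event[mask]
    else:
        t, e = records.time, records.event
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    surv = kmf.survival_function_["KM_estimate"]
    ev_table = kmf.event_table
    out = pd.DataFrame({
        "time": surv.index.to_numpy(dtype=float),
        "survival": surv.to_numpy(dtype=float),
        "at_risk": ev_table["at_risk"].reindex(surv.index).to_numpy(),
        "censored": ev_table["censored"].reindex(surv.index).to_numpy(),
    })
    return out.reset_index(drop=True)


def km_curves(records: SurvivalRecords) -> pd.DataFrame:
    """KM curve table for every group, long format (group, time, survival,
    at_risk, censored)."""
    frames = []
    for g in np.unique(records.group):
        f = km_estimate(records, g)
        f.insert(0, "group", g)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


@dataclass
class LogrankResult:
    statistic: float
    df: int
    p_value: float


def logrank_test(records: SurvivalRecords) -> LogrankResult:
    """g-sample log-rank test across clusters (chi-square, g-1 df)."""
    groups = np.unique(records.group)
    if len(groups) < 2:
        raise ValueError("log-rank test needs >= 2 groups")
    for g in groups:
        if not (records.group == g).any():
            raise ValueError(f"empty group {g!r}")
    if records.event.sum() == 0:
        raise ValueError("log-rank test undefined with no observed events")
    res = multivariate_logrank_test(records.time, records.group, records.event)
    return LogrankResult(statistic=float(res.test_statistic),
                         df=int(len(groups) - 1),
                         p_value=float(res.p_value))


@dataclass
class CorrelateTable:
    """Per-cluster ranked positive correlates plus the full signed table.

    ``top``: columns (cluster, rank, feature, r); ``full``: one row per
    (cluster, feature) with the signed Pearson r; ``excluded``: features
    dropped for zero variance; ``n``: samples used (for downstream
    significance calculations)."""

    top: pd.DataFrame
    full: pd.DataFrame
    excluded: list[str]
    n: int


def cluster_correlates(features: pd.DataFrame, assignment: pd.Series,
                       top_k: int = 10) -> CorrelateTable:
    """Pearson correlation of each binary feature with each cluster's
    one-vs-rest indicator; per cluster, the ``top_k`` largest positive
    correlations are ranked.  Zero-variance features are excluded (logged).
    """
    if not features.index.equals(assignment.index):
        raise ValueError("features and assignment must share sample ids")
    x = features.to_numpy(dtype=float)
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValueError("features must be binary")
    xc = x - x.mean(axis=0)
    x_ss = np.sqrt((xc ** 2).sum(axis=0))
    constant = x_ss == 0
    excluded = list(features.columns[constant])
    if excluded:
        logger.info("cluster_correlates: excluded %d zero-variance features",
                    len(excluded))

    full_rows, top_rows = [], []
    for cl in np.unique(assignment):
        y = (assignment == cl).to_numpy(dtype=float)
        yc = y - y.mean()
        y_ss = np.sqrt((yc ** 2).sum())
        if y_ss == 0:
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xc.T @ yc) / (x_ss * y_ss)
        r = np.where(constant, np.nan, r)
        for feat, rv in zip(features.columns, r):
            if np.isfinite(rv):
                full_rows.append({"cluster": cl, "feature": feat, "r": rv})
        order = np.argsort(-np.where(np.isfinite(r), r, -np.inf))
        rank = 0
        for j in order:
            if rank >= top_k or not np.isfinite(r[j]) or r[j] <= 0:
                break
            rank += 1
            top_rows.append({"cluster": cl, "rank": rank,
                             "feature": features.columns[j], "r": float(r[j])})
    return CorrelateTable(
        top=pd.DataFrame(top_rows, columns=["cluster", "rank", "feature", "r"]),
        full=pd.DataFrame(full_rows, columns=["cluster", "feature", "r"]),
        excluded=excluded,
        n=len(features),
    )


def export_wordcloud_table(table: CorrelateTable) -> pd.DataFrame:
    """Relative-size weights for word-cloud-style display.

    Weights are scaled within each cluster only (that cluster's max r maps
    to 1.0); sizes are deliberately not comparable across clusters."""
    if table.top.empty:
        raise ValueError("empty correlate table")
    out = table.top.copy()
    out["weight"] = out.groupby("cluster")["r"].transform(lambda s: s / s.max())
    return out


def plot_km(records: SurvivalRecords, path, title: str = "Kaplan-Meier") -> None:
    """KM plot with one curve per cluster and the log-rank p in the title."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for g in np.unique(records.group):
        mask = records.group == g
        kmf = KaplanMeierFitter()
        kmf.fit(records.time[mask], records.event[mask],
                label=f"cluster {g} (n={mask.sum()})")
        kmf.plot_survival_function(ax=ax, ci_show=False)
    try:
        p = logrank_test(records).p_value
        title = f"{title} (log-rank p = {p:.3g})"
    except ValueError:
        pass
    ax.set_title(title)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
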