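"""Clustering of developmental trajectories into pattern groups.

Complete 7-step trajectory vectors are clustered (k-means by default, with a
Gaussian mixture as a sensitivity alternative) to find recurring
developmental patterns.  One step per domain group contains only a single
milestone (step 5, 12-18 months, for motor; step 3, 6-9 months, for
language-social) and is therefore dropped from the clustering features —
but cluster centroids are always reported over all 7 entries of the member
vectors.

Centroids are labeled with a qualitative pattern:

* ``adequate`` — near-zero scores throughout;
* ``catching_up`` — high early scores that resolve by the last steps;
* ``worsening`` — scores that grow high toward 36 months;
* ``other`` — anything else (e.g. a mid-infancy bump that recovers).

The thresholds quantifying "near-zero" and "high" are configurable
(defaults 0.15 and 0.5 on the 0-4 score range).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .scale import DomainGroup
from .trajectory import STEP_COLUMNS

logger = logging.getLogger(__name__)

#: single-milestone step excluded from the clustering features, per group
DEFAULT_DROPPED_STEP: Mapping[DomainGroup, int] = {
    DomainGroup.MOTOR: 5,
    DomainGroup.LANGUAGE_SOCIAL: 3,
}


class ClusterMethod(str, Enum):
    KMEANS = "kmeans"
    GMM = "gmm"


class PatternLabel(str, Enum):
    ADEQUATE = "adequate"
    CATCHING_UP = "catching_up"
    WORSENING = "worsening"
    OTHER = "other"


@dataclass(frozen=True)
class ClusterConfig:
    k: int = 4
    method: ClusterMethod = ClusterMethod.KMEANS
    dropped_step: int | None = None   # resolved from the group when None
    seed: int = 0
    n_init: int = 10
    theta_low: float = 0.15
    theta_high: float = 0.5

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")
        if self.n_init < 1:
            raise ValueError(f"n_init must be positive, got {self.n_init}")
        if self.dropped_step is not None and not 1 <= self.dropped_step <= 7:
            raise ValueError(f"dropped_step must be in 1..7, got {self.dropped_step}")
        object.__setattr__(self, "method", ClusterMethod(self.method))


@dataclass
class ClusterReport:
    assignments: pd.Series            # child_id -> cluster index (0-based)
    centroids: np.ndarray             # k x 7, means over all entries
    sizes: np.ndarray                 # per-cluster member counts
    fractions: np.ndarray
    validity: float                   # Calinski-Harabasz on the features used
    labels: list[PatternLabel]
    dropped_step: int
    config: ClusterConfig

    def to_dict(self) -> dict:
        return {
            "k": int(self.config.k),
            "method": self.config.method.value,
            "dropped_step": int(self.dropped_step),
            "centroids": [[round(float(v), 6) for v in row] for row in self.centroids],
            "sizes": [int(s) for s in self.sizes],
            "fractions": [round(float(f), 6) for f in self.fractions],
            "validity": float(self.validity),
            "labels": [lab.value for lab in self.labels],
        }


def _feature_matrix(dtvs: pd.DataFrame, dropped_step: int) -> tuple[np.ndarray, np.ndarray]:
    X = dtvs[list(STEP_COLUMNS)].to_numpy(dtype=float)
    if np.isnan(X).any():
        bad = dtvs.loc[np.isnan(X).any(axis=1), "child_id"].head(3).tolist()
        raise ValueError(
            f"clustering requires complete trajectories; incomplete children include {bad} "
            "(run trajectory.filter_complete first)"
        )
    keep = [j for j in range(7) if j != dropped_step - 1]
    return X, X[:, keep]


def cluster_dtvs(
    dtvs: pd.DataFrame,
    config: ClusterConfig = ClusterConfig(),
    group: DomainGroup | None = None,
) -> ClusterReport:
    """Partition complete trajectories into ``config.k`` pattern clusters.

    Fitting uses 6 of the 7 steps (the group's single-milestone step is
    dropped; pass ``config.dropped_step`` to override); centroids are then
    recomputed over all 7 entries from the final assignment.  Deterministic
    given ``seed`` and ``n_init``.
    """
    if group is None and config.dropped_step is None:
        groups = set(dtvs["group"].unique()) if "group" in dtvs else set()
        if len(groups) == 1:
            group = DomainGroup(groups.pop())
        else:
            raise ValueError("dropped_step not set and domain group is ambiguous")
    dropped = config.dropped_step or DEFAULT_DROPPED_STEP[DomainGroup(group)]

    X_full, X_fit = _feature_matrix(dtvs, dropped)
    n = X_fit.shape[0]
    if n <= config.k:
        raise ValueError(f"need more than k={config.k} complete vectors, got {n}")

    if config.method is ClusterMethod.KMEANS:
        model = KMeans(
            n_clusters=config.k, init="k-means++",
            n_init=config.n_init, random_state=config.seed,
        )
        assign = model.fit_predict(X_fit)
        fit_centers = model.cluster_centers_
    else:
        model = GaussianMixture(
            n_components=config.k, covariance_type="full",
            n_init=config.n_init, random_state=config.seed, reg_covar=1e-6,
        )
        assign = model.fit_predict(X_fit)
        fit_centers = model.means_

    # order clusters by size (descending) for stable, report-friendly indices
    counts = np.bincount(assign, minlength=config.k)
    order = np.argsort(-counts, kind="stable")
    relabel = np.empty_like(order)
    relabel[order] = np.arange(config.k)
    assign = relabel[assign]

    sizes = np.bincount(assign, minlength=config.k)
    # empty clusters (possible only on degenerate inputs) keep the model's
    # fitted center, with the dropped step filled by its overall mean
    fallback = np.insert(fit_centers[order], dropped - 1,
                         X_full[:, dropped - 1].mean(), axis=1)
    centroids = np.vstack([
        X_full[assign == c].mean(axis=0) if sizes[c] else fallback[c]
        for c in range(config.k)
    ])
    nonempty = sizes > 0
    validity = (
        calinski_harabasz(X_fit, assign) if nonempty.sum() >= 2 and n > nonempty.sum()
        else float("nan")
    )
    labels = label_patterns(centroids, config.theta_low, config.theta_high)
    assignments = pd.Series(assign, index=pd.Index(dtvs["child_id"], name="child_id"),
                            name="cluster")
    return ClusterReport(
        assignments=assignments, centroids=centroids, sizes=sizes,
        fractions=sizes / n, validity=validity, labels=labels,
        dropped_step=dropped, config=config,
    )


def calinski_harabasz(X: np.ndarray, labels: Sequence[int]) -> float:
    """Calinski-Harabasz variance-ratio index.

    ``[between-cluster SS / (k-1)] / [within-cluster SS / (n-k)]`` with sums
    of squared Euclidean distances to the respective means.  Zero within
    dispersion (duplicated points per cluster) yields ``inf``.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    n, k = X.shape[0], uniq.size
    if k < 2:
        raise ValueError(f"need >= 2 clusters, got {k}")
    if n <= k:
        raise ValueError(f"need more points ({n}) than clusters ({k})")
    grand = X.mean(axis=0)
    between = 0.0
    within = 0.0
    for lab in uniq:
        members = X[labels == lab]
        if members.shape[0] == 0:
            raise ValueError(f"empty cluster {lab!r}")
        mu = members.mean(axis=0)
        between += members.shape[0] * float(((mu - grand) ** 2).sum())
        within += float(((members - mu) ** 2).sum())
    if within == 0.0:
        return float("inf")
    return (between / (k - 1)) / (within / (n - k))


def label_patterns(
    centroids: np.ndarray,
    theta_low: float = 0.15,
    theta_high: float = 0.5,
) -> list[PatternLabel]:
    """Qualitative pattern label per centroid (length-7 score vectors).

    ``adequate``: all entries below ``theta_low``.  ``catching_up``: first
    entry at least ``theta_high`` and the last two below ``theta_low``.
    ``worsening``: last entry at least ``theta_high`` and above the first.
    Anything else — including the (threshold-dependent) case where both the
    catching-up and worsening criteria fire — is ``other``.
    """
    out = []
    for c in np.asarray(centroids, dtype=float):
        if c.shape[-1] != 7:
            raise ValueError(f"centroid must have 7 entries, got {c.shape[-1]}")
        adequate = bool((c < theta_low).all())
        catching = c[0] >= theta_high and c[5] < theta_low and c[6] < theta_low
        worsening = c[6] >= theta_high and c[6] > c[0]
        if adequate:
            out.append(PatternLabel.ADEQUATE)
        elif catching and worsening:
            out.append(PatternLabel.OTHER)
        elif catching:
            out.append(PatternLabel.CATCHING_UP)
        elif worsening:
            out.append(PatternLabel.WORSENING)
        else:
            out.append(PatternLabel.OTHER)
    return out


def cluster_covariate_table(
    report: ClusterReport,
    children: pd.DataFrame,
    covariates: Sequence[str] = ("sex", "dev_tracking", "maternal_education"),
) -> pd.DataFrame:
    """Per-cluster covariate distributions (counts and within-cluster %).

    Long-form table with one row per (covariate, category, cluster).
    Children with a missing value for a covariate are not counted toward
    that covariate's tallies.  Percentages are relative to cluster size, so
    categories of a fully observed covariate sum to 100 within a cluster.
    """
    assign = report.assignments.rename("cluster").reset_index()
    merged = assign.merge(children, on="child_id", how="left")
    sizes = merged.groupby("cluster").size()
    rows = []
    for cov in covariates:
        if cov not in merged:
            raise KeyError(f"covariate {cov!r} absent from children table")
        sub = merged.dropna(subset=[cov])
        counts = sub.groupby(["cluster", cov]).size()
        for (cluster, category), n in counts.items():
            rows.append({
                "covariate": cov,
                "category": category,
                "cluster": int(cluster),
                "n": int(n),
                "pct": round(100.0 * n / sizes[cluster], 1),
            })
    return pd.DataFrame(rows, columns=["covariate", "category", "cluster", "n", "pct"])
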