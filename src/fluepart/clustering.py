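"""Site classification by drought response.

Sites are partitioned into four clusters in a fixed precedence order:

* ``cNA`` — not affected: relative soil water never drops below 0.25;
* ``cLS`` — low sensitivity: fLUE at vanishing soil moisture stays above 0.8;
* ``cDD`` / ``cGR`` — the remaining sites are split by k-means (k = 2) on a
  six-value response vector (median relative reduction of greenness and of
  fLUE in the windows -20..-1, 0..19 and 20..39 days around drought onset);
  the cluster whose centroid shows the larger greenness reduction is the
  drought-deciduous one (cDD), the other keeps green during drought (cGR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .events import CompositeResult

CNA_MIN_THETA = 0.25
CLS_MIN_FLUE0 = 0.8
FEATURE_WINDOWS = ((-20, -1), (0, 19), (20, 39))
FEATURE_NAMES = [f"{var}_w{lo}_{hi}" for var in ("greenness", "flue")
                 for lo, hi in FEATURE_WINDOWS]


def assign_cna(theta_rel) -> bool:
    """Not-affected rule: soil water never fell below 0.25 of capacity
    (boundary inclusive)."""
    return bool(np.nanmin(np.asarray(theta_rel, dtype=float)) >= CNA_MIN_THETA)


def assign_cls(flue0: float) -> bool:
    """Low-sensitivity rule: fLUE at vanishing soil moisture strictly above 0.8."""
    if not np.isfinite(flue0):
        raise ValueError("flue0 undefined; site cannot be classified as cLS")
    return bool(flue0 > CLS_MIN_FLUE0)


def build_features(composites: CompositeResult,
                   greenness_var: str = "evi", flue_var: str = "flue"
                   ) -> np.ndarray:
    """Six-value drought response vector for one site.

    For greenness and fLUE (both onset-normalised composites) the day-wise
    median across events is averaged inside each window; the feature is one
    minus that level, i.e. the relative reduction. Requires at least one
    event with the full pre-onset window.
    """
    if next(iter(composites.matrices.values())).shape[0] == 0:
        raise ValueError("no drought events; response vector undefined")
    feats = []
    for var in (greenness_var, flue_var):
        band = composites.bands[var]["median"]
        for lo, hi in FEATURE_WINDOWS:
            window = band.loc[lo:hi]
            feats.append(1.0 - float(window.mean()))
    return np.asarray(feats)


@dataclass
class ClusterOutcome:
    labels: pd.Series
    centroids: np.ndarray
    degenerate: bool = False


def cluster_dd_gr(features: pd.DataFrame, seed: int = 0,
                  n_restarts: int = 25) -> ClusterOutcome:
    """k-means (k = 2) split of the remaining sites into cDD and cGR.

    Features are used unstandardised (all six are unit-free reductions).
    Cluster identity is semantic, not positional: the centroid with the
    larger mean greenness reduction is labelled cDD. All-identical vectors
    make the split degenerate (flagged; all sites fall to cGR).
    """
    X = features.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("k-means needs at least 2 sites with complete vectors")
    if np.allclose(X, X[0]):
        labels = pd.Series("cGR", index=features.index)
        return ClusterOutcome(labels=labels, centroids=np.vstack([X[0], X[0]]),
                              degenerate=True)
    km = KMeans(n_clusters=2, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(X)
    greenness_cols = [i for i, n in enumerate(features.columns)
                      if n.startswith("greenness")]
    reduction = km.cluster_centers_[:, greenness_cols].mean(axis=1)
    dd_cluster = int(np.argmax(reduction))
    labels = pd.Series(np.where(raw == dd_cluster, "cDD", "cGR"),
                       index=features.index)
    return ClusterOutcome(labels=labels, centroids=km.cluster_centers_)


def classify_sites(summary: pd.DataFrame, features: pd.DataFrame | None = None,
                   seed: int = 0) -> pd.DataFrame:
    """Assign every site exactly one label (or an explicit exclusion reason).

    ``summary`` needs columns ``min_theta_rel`` and ``flue0``; ``features``
    holds the six-value response vectors (indexed by site) for the sites
    that reach the k-means stage. Precedence: cNA first, then cLS, then
    k-means on the remainder.
    """
    out = summary.copy()
    out["label"] = ""
    out["exclusion_reason"] = ""

    is_cna = out["min_theta_rel"] >= CNA_MIN_THETA
    out.loc[is_cna, "label"] = "cNA"

    rest = ~is_cna
    undef = rest & ~np.isfinite(out["flue0"].to_numpy(dtype=float))
    out.loc[undef, "exclusion_reason"] = "flue0_undefined"
    is_cls = rest & ~undef & (out["flue0"] > CLS_MIN_FLUE0)
    out.loc[is_cls, "label"] = "cLS"

    remainder = out.index[rest & ~undef & ~is_cls]
    if len(remainder) > 0:
        if features is None:
            out.loc[remainder, "exclusion_reason"] = "no_response_vector"
        else:
            have = [s for s in remainder if s in features.index
                    and np.all(np.isfinite(features.loc[s].to_numpy(dtype=float)))]
            missing = [s for s in remainder if s not in have]
            out.loc[missing, "exclusion_reason"] = "no_response_vector"
            if len(have) >= 2:
                res = cluster_dd_gr(features.loc[have], seed=seed)
                out.loc[have, "label"] = res.labels
            elif len(have) == 1:
                out.loc[have, "exclusion_reason"] = "too_few_sites_for_kmeans"
    return out
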