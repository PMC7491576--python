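"""Binding-mode classification, WE-style group schemes, clustering.

A frame is D147-bound when the ligand's key-nitrogen distance to the Asp147
carboxylate is at or below the mode threshold (3.5 A by default), H297-bound
when the distance to the unprotonated His297 imidazole nitrogen is; BOTH and
NEITHER complete the partition (the standard thresholds make BOTH
geometrically near-impossible but it is classified for totality).

Group schemes reproduce the interval-predicate groupings used to pick
cluster input from weighted-ensemble output.  WE statistical weights are
deliberately ignored: the frames are treated as plain unweighted samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from sklearn.cluster import AgglomerativeClustering
from sklearn.preprocessing import StandardScaler

from .errors import ConfigError, DataError

MODE_THRESHOLD = 3.5

LABELS = ("D147", "H297", "BOTH", "NEITHER")


def classify_frame(fen_d147: float, fen_h297: float,
                   threshold: float = MODE_THRESHOLD) -> str:
    """Label one frame from its two key distances."""
    if fen_d147 < 0 or fen_h297 < 0:
        raise DataError("distances must be non-negative")
    d = fen_d147 <= threshold
    h = fen_h297 <= threshold
    if d and h:
        return "BOTH"
    if d:
        return "D147"
    if h:
        return "H297"
    return "NEITHER"


def classify_series(series: pd.DataFrame,
                    threshold: float = MODE_THRESHOLD) -> pd.DataFrame:
    """Vectorized :func:`classify_frame` over a descriptor table with
    ``fen_d147``/``fen_h297`` columns; adds a ``label`` column."""
    d147 = series["fen_d147"].to_numpy()
    h297 = series["fen_h297"].to_numpy()
    if (d147 < 0).any() or (h297 < 0).any():
        raise DataError("distances must be non-negative")
    d = d147 <= threshold
    h = h297 <= threshold
    label = np.where(d & h, "BOTH",
                     np.where(d, "D147", np.where(h, "H297", "NEITHER")))
    out = series.copy()
    out["label"] = label
    return out


@dataclass(frozen=True)
class Group:
    """Interval predicate over (fen_d147, fen_h297); None bound = open."""

    name: str
    d147_max: float | None = None
    d147_min: float | None = None
    h297_max: float | None = None
    h297_min: float | None = None

    def matches(self, d147, h297):
        ok = np.ones(np.shape(d147), dtype=bool)
        if self.d147_max is not None:
            ok &= d147 <= self.d147_max
        if self.d147_min is not None:
            ok &= d147 >= self.d147_min
        if self.h297_max is not None:
            ok &= h297 <= self.h297_max
        if self.h297_min is not None:
            ok &= h297 >= self.h297_min
        return ok


@dataclass
class GroupScheme:
    """Ordered groups; a frame gets the first group it matches."""

    name: str
    groups: tuple

    def assign(self, d147, h297) -> np.ndarray:
        d147 = np.asarray(d147, dtype=float)
        h297 = np.asarray(h297, dtype=float)
        out = np.full(d147.shape, "unassigned", dtype=object)
        unset = np.ones(d147.shape, dtype=bool)
        for g in self.groups:
            hit = unset & g.matches(d147, h297)
            out[hit] = g.name
            unset &= ~hit
        return out


#: groups used with the HIE-tautomer ensemble: D147-bound; detached from
#: D147 but near H297; detached from both.
WE_HIE_SCHEME = GroupScheme("WE-HIE", (
    Group("D147-bound", d147_max=3.5),
    Group("near-H297", d147_min=4.0, h297_max=8.0),
    Group("detached", d147_min=4.0, h297_min=8.0),
))

#: groups used with the HID-tautomer ensemble: D147-bound; H297-bound
#: (hydrogen-bonded); detached.
WE_HID_SCHEME = GroupScheme("WE-HID", (
    Group("D147-bound", d147_max=3.5),
    Group("H297-bound", h297_max=3.5),
    Group("detached", d147_min=8.5, h297_min=4.0),
))

PRESET_SCHEMES = {"WE-HIE": WE_HIE_SCHEME, "WE-HID": WE_HID_SCHEME}


def assign_groups(series: pd.DataFrame, scheme: GroupScheme) -> pd.DataFrame:
    """Add a ``group`` column (first-matching-group, else 'unassigned')."""
    out = series.copy()
    out["group"] = scheme.assign(series["fen_d147"].to_numpy(),
                                 series["fen_h297"].to_numpy())
    return out


def occupancy(labels) -> dict:
    """Fraction of frames per label; fractions sum to 1."""
    labels = list(labels)
    if not labels:
        raise DataError("no labels")
    counts = pd.Series(labels).value_counts()
    return {str(k): float(v) / len(labels) for k, v in counts.items()}


def cumulative_time(iteration_index: int, segments_per_iteration,
                    tau_ns: float) -> float:
    """Cumulative sampling time (ns) after ``iteration_index`` WE iterations.

    ``segments_per_iteration`` is a constant or a per-iteration sequence of
    trajectory-segment counts; each segment advances tau_ns.
    """
    if iteration_index < 1 or tau_ns <= 0:
        raise ConfigError("iteration index and tau must be positive")
    if np.isscalar(segments_per_iteration):
        return float(iteration_index * segments_per_iteration * tau_ns)
    seg = list(segments_per_iteration)
    if len(seg) < iteration_index:
        raise ConfigError("fewer segment counts than iterations")
    return float(sum(seg[:iteration_index]) * tau_ns)


@dataclass
class ClusterResult:
    assignments: pd.Series  # frame -> cluster id
    medoids: dict           # cluster id -> frame index
    sizes: dict             # cluster id -> member count
    linkage: str

    def clusters_by_size(self):
        """Cluster ids, most populated first (ties: lower id first)."""
        return sorted(self.sizes, key=lambda c: (-self.sizes[c], c))


def cluster_frames(series: pd.DataFrame, k: int,
                   features=("fen_d147", "fen_h297", "delta_z"),
                   linkage: str = "average") -> ClusterResult:
    """Agglomerative clustering of frames on standardized descriptors.

    Features are z-scored before the Euclidean metric is applied.  The
    representative of each cluster is its medoid (member minimizing summed
    in-cluster distance; ties broken by lowest frame index).  Cluster ids
    are relabeled by descending size.
    """
    n = len(series)
    if k < 1 or k > n:
        raise ConfigError(f"k={k} outside 1..{n}")
    X = series.loc[:, list(features)].to_numpy(dtype=float)
    Xs = StandardScaler().fit_transform(X)
    if k == n:
        raw = np.arange(n)
    else:
        model = AgglomerativeClustering(n_clusters=k, linkage=linkage,
                                        metric="euclidean")
        raw = model.fit_predict(Xs)
    frames = series["frame"].to_numpy() if "frame" in series else np.arange(n)

    # relabel clusters by (descending size, then lowest member frame)
    order = sorted(
        np.unique(raw),
        key=lambda c: (-(raw == c).sum(), frames[raw == c].min()),
    )
    remap = {c: i for i, c in enumerate(order)}
    labels = np.array([remap[c] for c in raw])

    D = squareform(pdist(Xs))
    medoids, sizes = {}, {}
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        cost = D[np.ix_(members, members)].sum(axis=1)
        best = members[np.lexsort((frames[members], cost))[0]]
        medoids[int(c)] = int(frames[best])
        sizes[int(c)] = int(members.size)
    return ClusterResult(
        assignments=pd.Series(labels, index=frames, name="cluster"),
        medoids=medoids, sizes=sizes, linkage=linkage,
    )
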