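"""Temporal waves, zone profiles and hierarchical clustering.

Nodule development is followed as a time course in days post inoculation
(dpi).  A gene's temporal activation is summarized by the ratio of its
signal at each dpi to the signal at a reference stage (default 14 dpi,
when the family transcriptome is fully active).  Genes are assigned to
one of three activation waves from the first dpi at which they pass an
activation rule (a configurable fraction of the 14 dpi level plus an
absolute floor above background):

* wave 1 - activated by 4 dpi,
* wave 2 - activated at 6 dpi,
* wave 3 - activated at 10 or 14 dpi,

and classified as *maintained* or *declining* depending on whether the
latest time point retains the gene's temporal maximum.

Spatially, mature indeterminate nodules are profiled through five
hand-dissected zone samples (I apical meristem .. IV senescence zone);
each gene's zone profile is reported as log2(zone signal / mean over the
five zones), so the five values back-transform to a unit mean.

Clustering is agglomerative average linkage (UPGMA) under either
Euclidean distance or correlation distance 1 - r (sign-sensitive, since
profile co-activation is directional), with explicit deterministic
tie-breaking: among equal-distance merge candidates the pair containing
the lowest original row index wins, and the leaf order places the subtree
with the smaller minimum index on the left.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .compendium_io import Compendium, MappingError, ValidationError, ZONE_CLASSES

__all__ = [
    "TemporalRatioTable",
    "ZoneProfile",
    "WaveTable",
    "Dendrogram",
    "timecourse_means",
    "temporal_ratios",
    "timepoint_correlation",
    "zone_relative_profile",
    "assign_waves",
    "hierarchical_cluster",
    "heatmap_matrix",
]


# ---------------------------------------------------------------------------
# time course
# ---------------------------------------------------------------------------


def timecourse_means(compendium: Compendium) -> pd.DataFrame:
    """Replicate-averaged signal per inoculation time point (gene x dpi).

    The time course consists of the whole-organ, untreated conditions with
    a dpi timepoint: nodules from 4 dpi on, and the 0/3 dpi root-stage
    samples of the same kinetics.
    """
    meta = compendium.conditions
    sel = (
        (meta["sample_class"] == "whole_organ")
        & meta["treatment"].isin(["", "none"])
        & (meta["timepoint_unit"] == "dpi")
        & meta["organ"].isin(["nodule", "root"])
        & meta["timepoint"].notna()
    )
    picked = meta[sel]
    if picked.empty:
        raise MappingError("compendium has no inoculation time-course conditions")
    by_dpi: dict[float, pd.Series] = {}
    for dpi, grp in picked.groupby("timepoint"):
        by_dpi[float(dpi)] = compendium.signals[list(grp.index)].mean(axis=1)
    frame = pd.DataFrame(by_dpi, index=compendium.signals.index)
    return frame[sorted(frame.columns)]


@dataclass
class TemporalRatioTable:
    """Signal ratios to the reference dpi, plus the averaged signals."""

    ratios: pd.DataFrame  # gene x dpi
    signals: pd.DataFrame  # gene x dpi (all available time points)
    reference: float
    defined: pd.Series  # reference signal > 0
    #: per queried dpi, genes ordered from high ratio to low ratio
    ordering: dict[float, list[str]] = field(default_factory=dict)


def temporal_ratios(
    compendium: Compendium,
    timepoints: Sequence[float] = (4, 6, 10),
    reference: float = 14,
) -> TemporalRatioTable:
    """Per-gene ratio of each requested dpi to the reference dpi."""
    signals = timecourse_means(compendium)
    missing = [t for t in list(timepoints) + [reference] if float(t) not in signals.columns]
    if missing:
        raise MappingError(f"time point(s) missing from the compendium: {missing}")
    ref = signals[float(reference)]
    defined = ref > 0
    ratios = pd.DataFrame(index=signals.index)
    for t in timepoints:
        ratios[float(t)] = (signals[float(t)] / ref.where(defined)).astype(float)
    ordering = {
        float(t): list(ratios[float(t)].sort_values(ascending=False, kind="stable").index)
        for t in timepoints
    }
    return TemporalRatioTable(ratios, signals, float(reference), defined, ordering)


def timepoint_correlation(
    compendium: Compendium,
    timepoints: Sequence[float] = (0, 3, 4, 6, 10, 14),
    gene_subset: Sequence[str] | None = None,
    log2: bool = False,
) -> pd.DataFrame:
    """Pearson correlation between time-point expression vectors.

    Computed over the replicate-averaged signals of ``gene_subset`` (all
    genes when None).  Pairs involving a zero-variance vector are NA.
    """
    signals = timecourse_means(compendium)
    missing = [t for t in timepoints if float(t) not in signals.columns]
    if missing:
        raise MappingError(f"time point(s) missing from the compendium: {missing}")
    cols = [float(t) for t in timepoints]
    mat = signals[cols]
    if gene_subset is not None:
        gene_subset = list(gene_subset)
        if len(gene_subset) < 2:
            raise ValidationError("timepoint correlation needs >= 2 genes")
        mat = mat.loc[gene_subset]
    if log2:
        mat = np.log2(mat.clip(lower=1e-12))
    values = mat.to_numpy(dtype=float)
    sd = values.std(axis=0)
    corr = np.full((len(cols), len(cols)), np.nan)
    ok = sd > 0
    if ok.any():
        sub = np.corrcoef(values[:, ok], rowvar=False)
        corr[np.ix_(ok, ok)] = sub
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=cols, columns=cols)


# ---------------------------------------------------------------------------
# zones
# ---------------------------------------------------------------------------


@dataclass
class ZoneProfile:
    """log2(zone / five-zone mean) per gene; undefined when the mean is 0."""

    values: pd.DataFrame  # gene x zone (I, II, II-III, III, IV)
    defined: pd.Series
    zone_means: pd.DataFrame  # replicate-averaged linear signals


def zone_relative_profile(compendium: Compendium) -> ZoneProfile:
    meta = compendium.conditions
    means = {}
    for zone in ZONE_CLASSES:
        conds = list(meta.index[meta["sample_class"] == zone])
        if not conds:
            raise MappingError(f"zone sample class {zone!r} missing from compendium")
        means[zone] = compendium.signals[conds].mean(axis=1)
    zone_means = pd.DataFrame(means, index=compendium.signals.index)
    overall = zone_means.mean(axis=1)
    defined = overall > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.log2(zone_means.div(overall.where(defined), axis=0))
    values[~defined] = np.nan
    return ZoneProfile(values, defined, zone_means)


# ---------------------------------------------------------------------------
# waves
# ---------------------------------------------------------------------------


@dataclass
class WaveTable:
    """Per-gene wave label, activation dpi and maintenance class."""

    frame: pd.DataFrame  # columns: wave, activation_dpi, maintenance


def assign_waves(
    ratios: TemporalRatioTable,
    activation_fraction: float = 0.5,
    decline_fraction: float = 0.5,
    background: float = 9.0,
    floor_factor: float = 5.0,
) -> WaveTable:
    """Assign temporal waves from the activation rule.

    A gene is *activated* at dpi d when its signal reaches
    ``activation_fraction`` of its reference (14 dpi) level and exceeds an
    absolute floor of ``floor_factor * background``.  The first activating
    dpi maps to the wave label: 4 -> 1, 6 -> 2, 10 or 14 -> 3.  Genes
    never activated are unassigned.  A gene is *declining* when its
    latest-time-point signal falls below ``decline_fraction`` of its
    temporal maximum.
    """
    floor = floor_factor * background
    signals = ratios.signals
    ref = signals[ratios.reference]
    check_dpi = [d for d in (4.0, 6.0, 10.0) if d in signals.columns]
    check_dpi.append(ratios.reference)

    frame = pd.DataFrame(index=signals.index)
    activation = pd.Series(np.nan, index=signals.index)
    for dpi in check_dpi:
        sig = signals[dpi]
        active = (sig >= activation_fraction * ref) & (sig >= floor)
        newly = active & activation.isna()
        activation[newly] = dpi
    wave = pd.Series("unassigned", index=signals.index, dtype=object)
    wave[activation == 4.0] = "1"
    wave[activation == 6.0] = "2"
    wave[activation.isin([10.0, ratios.reference])] = "3"

    latest = signals[signals.columns.max()]
    peak = signals.max(axis=1)
    declining = latest < decline_fraction * peak
    maintenance = pd.Series(
        np.where(declining, "declining", "maintained"), index=signals.index
    )
    maintenance[wave == "unassigned"] = "maintained"

    frame["wave"] = wave
    frame["activation_dpi"] = activation
    frame["maintenance"] = maintenance
    return WaveTable(frame)


# ---------------------------------------------------------------------------
# hierarchical clustering (UPGMA)
# ---------------------------------------------------------------------------


@dataclass
class Dendrogram:
    """Average-linkage merge tree with a deterministic leaf order.

    ``merges`` lists (left, right, height) with scipy-style ids: leaves
    are 0..n-1 in input row order, the cluster created by merge k gets id
    n + k.  Heights are non-decreasing (UPGMA is monotone).
    """

    merges: list[tuple[int, int, float]]
    leaf_names: list[str]
    leaf_order: list[str]

    def to_newick(self) -> str:
        """Newick string; branch lengths are height differences."""
        n = len(self.leaf_names)
        height = {i: 0.0 for i in range(n)}
        node: dict[int, str] = {}
        min_leaf = self._min_leaf()
        for k, (a, b, h) in enumerate(self.merges):
            for child in (a, b):
                if child not in node:
                    node[child] = self.leaf_names[child]
            # smaller-min-index subtree first, matching the leaf order
            first, second = _ordered_children(a, b, min_leaf)
            lf = h - height[first]
            ls = h - height[second]
            node[n + k] = f"({node[first]}:{lf:.6g},{node[second]}:{ls:.6g})"
            height[n + k] = h
        root = n + len(self.merges) - 1 if self.merges else 0
        return node.get(root, self.leaf_names[0] if self.leaf_names else "") + ";"

    def _min_leaf(self) -> dict[int, int]:
        n = len(self.leaf_names)
        min_leaf = {i: i for i in range(n)}
        for k, (a, b, _) in enumerate(self.merges):
            min_leaf[n + k] = min(min_leaf[a], min_leaf[b])
        return min_leaf


def _ordered_children(a: int, b: int, min_leaf: dict[int, int]) -> tuple[int, int]:
    return (a, b) if min_leaf[a] <= min_leaf[b] else (b, a)


def _pairwise_distance(values: np.ndarray, metric: str, names: Sequence[str]) -> np.ndarray:
    if metric == "euclidean":
        diff = values[:, None, :] - values[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))
    if metric == "pearson":
        sd = values.std(axis=1)
        zero = np.flatnonzero(sd == 0)
        if len(zero):
            raise ValidationError(
                f"zero-variance row(s) under pearson distance: "
                f"{[names[i] for i in zero[:5]]}"
            )
        r = np.corrcoef(values)
        return 1.0 - r
    raise ValueError(f"unknown distance metric {metric!r}")


def hierarchical_cluster(
    matrix: pd.DataFrame, distance: str = "euclidean", linkage: str = "average"
) -> Dendrogram:
    """Agglomerative average-linkage (UPGMA) clustering of matrix rows.

    Tie-breaking is deterministic: among equal-distance candidate pairs,
    the pair whose smallest original row index is lowest wins (then the
    smaller partner index).
    """
    if linkage != "average":
        raise ValueError("only average linkage is supported")
    values = matrix.to_numpy(dtype=float)
    names = list(matrix.index)
    n = len(names)
    if n < 2:
        raise ValidationError("clustering needs at least two rows")

    dist = _pairwise_distance(values, distance, names)
    dist = (dist + dist.T) / 2.0  # corrcoef is asymmetric at 1 ulp
    np.fill_diagonal(dist, np.inf)

    active: dict[int, int] = {i: 1 for i in range(n)}  # cluster id -> size
    min_leaf = {i: i for i in range(n)}
    # work matrix indexed by position; pos_id maps positions to cluster ids
    work = dist.copy()
    pos_id = list(range(n))
    merges: list[tuple[int, int, float]] = []

    for step in range(n - 1):
        upper = np.triu_indices_from(work, k=1)
        m = work[upper].min()
        cand = [(int(i), int(j)) for i, j in zip(*upper) if work[i, j] == m]
        # deterministic tie-break on original leaf indices
        cand.sort(
            key=lambda ij: (
                min(min_leaf[pos_id[ij[0]]], min_leaf[pos_id[ij[1]]]),
                max(min_leaf[pos_id[ij[0]]], min_leaf[pos_id[ij[1]]]),
            )
        )
        i, j = cand[0]
        a, b = pos_id[i], pos_id[j]
        new_id = n + step
        merges.append((a, b, float(m)))
        size_a, size_b = active.pop(a), active.pop(b)
        active[new_id] = size_a + size_b
        min_leaf[new_id] = min(min_leaf[a], min_leaf[b])

        # average-linkage update: weighted mean of the two old distances
        d_new = (size_a * work[i, :] + size_b * work[j, :]) / (size_a + size_b)
        work[i, :] = d_new
        work[:, i] = d_new
        work[i, i] = np.inf
        pos_id[i] = new_id
        work = np.delete(np.delete(work, j, axis=0), j, axis=1)
        del pos_id[j]

    order = _leaf_order(merges, n)
    return Dendrogram(merges, names, [names[i] for i in order])


def _leaf_order(merges: list[tuple[int, int, float]], n: int) -> list[int]:
    min_leaf = {i: i for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for k, (a, b, _) in enumerate(merges):
        min_leaf[n + k] = min(min_leaf[a], min_leaf[b])
        children[n + k] = (a, b)

    def walk(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = children[node]
        first, second = _ordered_children(a, b, min_leaf)
        return walk(first) + walk(second)

    root = n + len(merges) - 1 if merges else 0
    return walk(root)


# ---------------------------------------------------------------------------
# display scaling
# ---------------------------------------------------------------------------


def heatmap_matrix(
    matrix: pd.DataFrame, row_scaling: str = "none"
) -> tuple[pd.DataFrame, pd.Index]:
    """Return the matrix as scaled for heat-map rendering.

    ``row_max`` divides each row by its maximum (zero-max rows are scaled
    to zeros and reported in the returned index); ``log2_ratio`` maps each
    row to log2(value / row mean), matching the zone-profile transform;
    ``none`` is the identity.
    """
    if row_scaling == "none":
        return matrix.copy(), pd.Index([])
    if row_scaling == "row_max":
        maxima = matrix.max(axis=1)
        flagged = matrix.index[maxima <= 0]
        safe = maxima.where(maxima > 0, other=1.0)
        scaled = matrix.div(safe, axis=0)
        scaled.loc[flagged] = 0.0
        return scaled, flagged
    if row_scaling == "log2_ratio":
        means = matrix.mean(axis=1)
        flagged = matrix.index[means <= 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            scaled = np.log2(matrix.div(means.where(means > 0), axis=0))
        scaled.loc[flagged] = np.nan
        return scaled, flagged
    raise ValueError(f"unknown row_scaling {row_scaling!r}")
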