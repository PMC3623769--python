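"""Moran's I spatial autocorrelation of Y-STR repeat counts.

Sample pairs are binned into distance classes by the great-circle distance
between their sampling sites: class 0 holds same-site pairs (zero distance),
classes 1..K split the nonzero inter-site distances into K bins with equal
pair counts. Within a class, Moran's I is computed per marker on the repeat
counts with binary weights (w_ij = 1 iff the pair falls in the class) and
averaged over markers; under no spatial structure E[I] = -1/(n-1).

Significance comes from a permutation test that reshuffles whole haplotypes
over sample positions (the classing — who sits where — is fixed), recomputing
the marker-averaged I; the reported p is two-sided around E[I].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ystrpopgen.data import SampleTable, filter_complete
from ystrpopgen.distance import great_circle_distance, profile_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceClassing",
    "MoranResult",
    "build_distance_classes",
    "morans_i",
    "spatial_autocorrelogram",
]


@dataclass
class DistanceClassing:
    sample_ids: tuple
    bounds: list  # per class: (low, high], class 0 is (0, 0]
    pair_counts: list
    pairs: list  # per class: (i_indices, j_indices) arrays

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def n_classes(self) -> int:
        return len(self.bounds)


def build_distance_classes(
    sites: dict, table: SampleTable, k: int = 10
) -> DistanceClassing:
    """Bin all sample pairs into 1 + *k* distance classes.

    Same-site pairs form class 0; the remaining pairs are sorted by inter-site
    great-circle distance (stable, ties broken by pair enumeration order) and
    split into *k* classes with equal pair counts (difference at most 1).
    """
    recs = table.records
    n = len(recs)
    site_ids = sorted({r.site_id for r in recs})
    if len(site_ids) < 2:
        raise ValueError("all samples at one site: no nonzero distance classes")
    site_index = {s: i for i, s in enumerate(site_ids)}
    coords = [
        (sites[s].latitude, sites[s].longitude) for s in site_ids
    ]
    m = len(site_ids)
    sited = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            sited[i, j] = sited[j, i] = great_circle_distance(coords[i], coords[j])

    samp_site = np.array([site_index[r.site_id] for r in recs])
    ii, jj = np.triu_indices(n, k=1)
    dist = sited[samp_site[ii], samp_site[jj]]

    zero = dist == 0.0
    pairs = [(ii[zero], jj[zero])]
    bounds = [(0.0, 0.0)]
    pair_counts = [int(zero.sum())]

    nz = np.flatnonzero(~zero)
    order = nz[np.argsort(dist[nz], kind="stable")]
    total = len(order)
    if total == 0:
        raise ValueError("no nonzero-distance pairs")
    base, rem = divmod(total, k)
    start = 0
    prev_high = 0.0
    for c in range(k):
        size = base + (1 if c < rem else 0)
        sel = order[start : start + size]
        start += size
        pairs.append((ii[sel], jj[sel]))
        high = float(dist[sel].max()) if size else prev_high
        bounds.append((prev_high, high))
        prev_high = high
        pair_counts.append(size)
    return DistanceClassing(
        sample_ids=tuple(r.sample_id for r in recs),
        bounds=bounds,
        pair_counts=pair_counts,
        pairs=pairs,
    )


def morans_i(values, classing: DistanceClassing, k: int) -> float:
    """Moran's I for one numeric variable in distance class *k*.

    With binary symmetric weights restricted to the class:
    ``I = (n / W) * (sum_ij w_ij z_i z_j) / (sum_i z_i^2)``, z centered.
    Returns nan for an empty class; raises on zero variance.
    """
    z = np.asarray(values, dtype=float)
    if len(z) != classing.n:
        raise ValueError("values length does not match classing")
    z = z - z.mean()
    denom = float(np.sum(z * z))
    if denom == 0.0:
        raise ValueError("monomorphic: zero variance")
    a, b = classing.pairs[k]
    npairs = len(a)
    if npairs == 0:
        logger.warning("distance class %d is empty; Moran's I undefined", k)
        return float("nan")
    w = 2.0 * npairs
    cross = 2.0 * float(z[a] @ z[b])
    return (classing.n / w) * cross / denom


@dataclass
class MoranResult:
    class_index: int
    bounds: tuple
    pair_count: int
    i_mean: float
    i_per_marker: dict
    expected: float
    p_value: float | None


def spatial_autocorrelogram(
    table: SampleTable,
    marker_set,
    classing: DistanceClassing,
    permutations: int = 10000,
    seed: int | None = None,
) -> list:
    """Marker-averaged Moran's I per distance class with permutation p-values.

    Markers with zero variance are dropped (logged); the permutation reshuffles
    whole haplotypes across sample positions, so per-marker values move
    together and the classing is preserved.
    """
    marker_set = tuple(marker_set)
    table = filter_complete(table, marker_set)
    if tuple(r.sample_id for r in table.records) != classing.sample_ids:
        raise ValueError("classing was built on a different sample set")
    x = profile_matrix(table, marker_set)
    n = x.shape[0]
    keep = [m for m in range(x.shape[1]) if np.ptp(x[:, m]) > 0]
    if not keep:
        raise ValueError("monomorphic: all markers have zero variance")
    if len(keep) < x.shape[1]:
        dropped = [marker_set[m] for m in range(x.shape[1]) if m not in keep]
        logger.warning("dropping monomorphic markers: %s", dropped)
    markers = [marker_set[m] for m in keep]
    z = x[:, keep] - x[:, keep].mean(axis=0)
    denom = np.sum(z * z, axis=0)  # per marker
    expected = -1.0 / (n - 1)

    def class_means(zm: np.ndarray) -> np.ndarray:
        """Marker-averaged I per class for centered value matrix *zm*."""
        out = np.empty(classing.n_classes)
        for c in range(classing.n_classes):
            a, b = classing.pairs[c]
            if len(a) == 0:
                out[c] = np.nan
                continue
            cross = 2.0 * np.sum(zm[a] * zm[b], axis=0)
            i_m = (n / (2.0 * len(a))) * cross / denom
            out[c] = float(np.mean(i_m))
        return out

    obs = class_means(z)
    per_marker = []
    for c in range(classing.n_classes):
        a, b = classing.pairs[c]
        if len(a) == 0:
            per_marker.append({m: float("nan") for m in markers})
            continue
        cross = 2.0 * np.sum(z[a] * z[b], axis=0)
        i_m = (n / (2.0 * len(a))) * cross / denom
        per_marker.append(dict(zip(markers, i_m.tolist())))

    p_values = [None] * classing.n_classes
    if permutations > 0:
        rng = np.random.default_rng(seed)
        exceed = np.zeros(classing.n_classes)
        obs_dev = np.abs(obs - expected)
        for _ in range(permutations):
            perm = rng.permutation(n)
            sim = class_means(z[perm])
            exceed += np.abs(sim - expected) >= obs_dev - 1e-12
        p_values = ((exceed + 1.0) / (permutations + 1.0)).tolist()

    results = []
    for c in range(classing.n_classes):
        results.append(
            MoranResult(
                class_index=c,
                bounds=tuple(classing.bounds[c]),
                pair_count=classing.pair_counts[c],
                i_mean=float(obs[c]),
                i_per_marker=per_marker[c],
                expected=expected,
                p_value=p_values[c],
            )
        )
    return results
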