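"""Genetic and geographic distances.

The microsatellite distance between two haplotypes is the sum over loci of
squared repeat-count differences — the quantity whose AMOVA decomposition
yields R_ST, the stepwise-mutation analogue of F_ST. Geographic distances are
great-circle (haversine) kilometers on a sphere of radius 6371 km.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ystrpopgen.data import SampleTable

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "DistanceMatrix",
    "repeat_distance",
    "profile_matrix",
    "rst_pairwise",
    "great_circle_distance",
    "EARTH_RADIUS_KM",
]


@dataclass
class DistanceMatrix:
    """Labelled symmetric matrix. Genetic squared-repeat distances are
    non-negative; R_ST estimates may be slightly negative and are preserved."""

    labels: tuple
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("label count does not match matrix dimension")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("nonzero diagonal")

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t" + "\t".join(str(l) for l in self.labels) + "\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(str(lab) + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def repeat_distance(h1: dict, h2: dict, marker_set) -> float:
    """Sum over *marker_set* of squared repeat-count differences.

    Both profiles must be complete on the marker set; callers filter first.
    """
    total = 0.0
    for m in marker_set:
        a, b = h1.get(m), h2.get(m)
        if not isinstance(a, (int, np.integer)) or not isinstance(b, (int, np.integer)):
            raise ValueError(f"missing or deleted genotype at {m}")
        total += float(a - b) ** 2
    return total


def profile_matrix(table: SampleTable, marker_set) -> np.ndarray:
    """(n_samples, n_markers) integer repeat matrix; raises on incomplete rows."""
    marker_set = tuple(marker_set)
    rows = []
    for r in table.records:
        if not r.is_complete(marker_set):
            raise ValueError(f"{r.sample_id}: incomplete on marker set")
        rows.append([int(r.str_profile[m]) for m in marker_set])
    return np.array(rows, dtype=np.float64)


def _two_group_rst(x1: np.ndarray, x2: np.ndarray) -> float:
    """R_ST between two groups of repeat-count rows via the AMOVA
    variance-component route (see :mod:`ystrpopgen.amova`)."""
    from ystrpopgen.amova import _one_factor_components

    n1, n2 = len(x1), len(x2)
    x = np.vstack([x1, x2])
    labels = np.array([0] * n1 + [1] * n2)
    sigma_a, sigma_w = _one_factor_components(x, labels)
    denom = sigma_a + sigma_w
    if denom == 0.0:
        return 0.0
    return sigma_a / denom


def rst_pairwise(
    table: SampleTable, grouping: dict, marker_set, min_size: int = 1
) -> DistanceMatrix:
    """Pairwise R_ST between groups of samples.

    *grouping* maps sample_id -> group label. Groups with fewer than
    *min_size* complete samples are excluded (with a warning via logging).
    Negative estimates are reported as computed.
    """
    import logging

    marker_set = tuple(marker_set)
    by_group: dict = {}
    for r in table.records:
        g = grouping.get(r.sample_id)
        if g is None or not r.is_complete(marker_set):
            continue
        by_group.setdefault(g, []).append(
            [int(r.str_profile[m]) for m in marker_set]
        )
    dropped = [g for g, rows in by_group.items() if len(rows) < min_size]
    for g in dropped:
        logging.getLogger(__name__).warning(
            "rst_pairwise: group %r has <%d complete samples, excluded", g, min_size
        )
        del by_group[g]
    if len(by_group) < 2:
        raise ValueError("need at least two groups with complete samples")
    labels = tuple(sorted(by_group, key=str))
    arrays = {g: np.array(rows, dtype=np.float64) for g, rows in by_group.items()}
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = _two_group_rst(arrays[labels[i]], arrays[labels[j]])
            out[i, j] = out[j, i] = r
    return DistanceMatrix(labels, out)


def great_circle_distance(a, b) -> float:
    """Haversine distance in km between (lat, lon) pairs in decimal degrees."""
    lat1, lon1 = np.radians(a[0]), np.radians(a[1])
    lat2, lon2 = np.radians(b[0]), np.radians(b[1])
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0))))


def site_distance_matrix(sites: dict) -> DistanceMatrix:
    """Great-circle distances between all sites, labelled by site_id."""
    labels = tuple(sorted(sites))
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        si = sites[labels[i]]
        for j in range(i + 1, n):
            sj = sites[labels[j]]
            d = great_circle_distance(
                (si.latitude, si.longitude), (sj.latitude, sj.longitude)
            )
            out[i, j] = out[j, i] = d
    return DistanceMatrix(labels, out)
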