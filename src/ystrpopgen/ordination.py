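"""Classical multidimensional scaling (principal coordinates) of R_ST matrices.

Pairwise R_ST values between sampling sites are treated as distances: the
matrix is squared inside the Gower double-centering ``-1/2 J D^2 J``, the
centered matrix is eigendecomposed, and the top axes with positive eigenvalues
are returned. Negative R_ST entries — sampling noise around zero — are clamped
to 0 before ordination (logged). Proportion explained is relative to the sum
of positive eigenvalues; negative eigenvalues are reported separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skbio.stats.ordination import pcoa as _skbio_pcoa

from ystrpopgen.distance import DistanceMatrix

logger = logging.getLogger(__name__)

__all__ = ["MdsResult", "principal_coordinates"]


@dataclass
class MdsResult:
    labels: tuple
    coordinates: np.ndarray  # (n_groups, k)
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportion_explained: np.ndarray  # per retained axis
    negative_eigenvalues: np.ndarray


def principal_coordinates(d: DistanceMatrix, k: int = 2) -> MdsResult:
    """Principal-coordinates analysis of a labelled distance matrix.

    Returns up to *k* axes with positive eigenvalues (fewer, with a warning,
    if the matrix supports fewer).
    """
    values = np.array(d.values, dtype=float)
    if np.any(values < 0):
        n_neg = int(np.sum(values < 0) // 2)
        logger.warning("clamping %d negative distance entries to 0", n_neg)
        values = np.clip(values, 0.0, None)
        np.fill_diagonal(values, 0.0)

    from skbio import DistanceMatrix as SkbioDM

    res = _skbio_pcoa(SkbioDM(values, ids=[str(l) for l in d.labels]), method="eigh")
    eig = np.asarray(res.eigvals, dtype=float)  # descending
    pos = eig[eig > 1e-12]
    n_axes = min(k, len(pos))
    if n_axes < k:
        logger.warning("only %d positive eigenvalues; returning %d axes", len(pos), n_axes)
    coords = np.asarray(res.samples.values, dtype=float)[:, :n_axes]
    pos_sum = pos.sum() if len(pos) else 1.0
    return MdsResult(
        labels=tuple(d.labels),
        coordinates=coords,
        eigenvalues=eig,
        proportion_explained=(pos[:n_axes] / pos_sum) if len(pos) else np.array([]),
        negative_eigenvalues=eig[eig < -1e-12],
    )
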