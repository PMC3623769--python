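"""Diversity indices and haplogroup-language association statistics.

Gene diversity follows Nei's unbiased estimator
``h = n/(n-1) * (1 - sum p_i^2)`` — the probability that two randomly drawn
alleles differ, with small-sample correction. Association between nominal
variables (haplogroup vs language group/class) is measured by Cramér's V and
tested by a Monte-Carlo Fisher exact test that samples contingency tables
from the fixed-margins null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

from ystrpopgen.data import SampleTable, filter_complete

logger = logging.getLogger(__name__)

__all__ = [
    "gene_diversity",
    "haplotype_diversity_per_site",
    "cramers_v",
    "fisher_exact_mc",
    "FisherMcResult",
]


def gene_diversity(allele_counts) -> float:
    """Nei gene diversity from allele (or haplotype) counts."""
    counts = np.asarray(allele_counts, dtype=float)
    counts = counts[counts > 0]
    n = counts.sum()
    if n < 2:
        raise ValueError("gene diversity needs at least two observations")
    p = counts / n
    return float(n / (n - 1.0) * (1.0 - np.sum(p * p)))


def haplotype_diversity_per_site(table: SampleTable, marker_set) -> dict:
    """Per-site Nei diversity of whole haplotypes on *marker_set*.

    Sites with fewer than two complete samples map to None (undefined).
    """
    marker_set = tuple(marker_set)
    table = filter_complete(table, marker_set)
    by_site: dict = {}
    for r in table.records:
        key = tuple(int(r.str_profile[m]) for m in marker_set)
        by_site.setdefault(r.site_id, {})
        by_site[r.site_id][key] = by_site[r.site_id].get(key, 0) + 1
    out = {}
    for sid, counts in by_site.items():
        n = sum(counts.values())
        out[sid] = gene_diversity(list(counts.values())) if n >= 2 else None
    return out


def _clean_contingency(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if np.any(t < 0) or t.sum() <= 0:
        raise ValueError("contingency counts must be non-negative with positive total")
    rows = t.sum(axis=1) > 0
    cols = t.sum(axis=0) > 0
    if not rows.all() or not cols.all():
        logger.warning(
            "dropping %d zero rows and %d zero columns",
            int((~rows).sum()),
            int((~cols).sum()),
        )
        t = t[rows][:, cols]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table needs at least 2 nonzero rows and columns")
    return t


def cramers_v(contingency) -> float:
    """Cramér's V = sqrt(chi2 / (n * min(r-1, c-1))), chi-square without
    continuity correction; zero rows/columns are dropped first."""
    t = _clean_contingency(contingency)
    chi2 = sps.chi2_contingency(t, correction=False)[0]
    n = t.sum()
    r, c = t.shape
    return float(np.sqrt(chi2 / (n * min(r - 1, c - 1))))


@dataclass
class FisherMcResult:
    p_value: float
    se: float
    n_as_extreme: int
    reps: int
    upper_bound: bool  # True when no sampled table was as extreme


def _log_table_prob(t: np.ndarray, lgn: float, lg_margins: float) -> float:
    # log P(table | margins) under the multiple hypergeometric null
    return lg_margins - lgn - float(np.sum(gammaln(t + 1.0)))


def fisher_exact_mc(
    contingency, reps: int = 1_000_000, seed: int | None = None, batch: int = 100_000
) -> FisherMcResult:
    """Monte-Carlo Fisher exact test for an r x c table.

    Tables are sampled from the fixed-margins null (Patefield algorithm, via
    :func:`scipy.stats.random_table`); a sampled table counts as extreme when
    its null probability is no larger than the observed table's. The estimate
    is ``(b + 1) / (reps + 1)``; when b = 0 the value is an upper bound, never
    reported as zero.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    t = _clean_contingency(contingency)
    row = t.sum(axis=1).astype(int)
    col = t.sum(axis=0).astype(int)
    n = int(t.sum())
    lgn = float(gammaln(n + 1.0))
    lg_margins = float(np.sum(gammaln(row + 1.0)) + np.sum(gammaln(col + 1.0)))
    log_obs = _log_table_prob(t, lgn, lg_margins)

    rng = np.random.default_rng(seed)
    dist = sps.random_table(row, col)
    b = 0
    done = 0
    while done < reps:
        m = min(batch, reps - done)
        samples = dist.rvs(size=m, method="patefield", random_state=rng)
        logp = (
            lg_margins
            - lgn
            - np.sum(gammaln(np.asarray(samples) + 1.0), axis=(1, 2))
        )
        b += int(np.sum(logp <= log_obs + 1e-9))
        done += m
    p = (b + 1) / (reps + 1)
    se = float(np.sqrt(p * (1.0 - p) / reps))
    return FisherMcResult(
        p_value=p, se=se, n_as_extreme=b, reps=reps, upper_bound=(b == 0)
    )
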