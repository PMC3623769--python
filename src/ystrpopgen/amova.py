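"""Analysis of molecular variance (AMOVA) on squared repeat-count distances.

For microsatellite data the AMOVA of pairwise squared repeat differences is
algebraically identical to a classical (nested) ANOVA on the repeat counts
themselves, summed over loci: for any group of rows,
``sum_{i<j} (x_i - x_j)^2 / n = sum_i (x_i - mean)^2``. Variance components
are extracted with the standard unequal-sample-size coefficients, and the
ratio of the among-group component to the total is R_ST (the stepwise-mutation
analogue of F_ST). Negative component estimates are retained — they are
sampling noise around zero, and truncating them would bias percentages.

Significance is assessed by permutation: samples (or whole sites, for the
among-cluster level of the nested design) are reshuffled across groups and
the observed statistic is compared with its permutation distribution;
``p = (b + 1) / (R + 1)`` where ``b`` counts permutations at least as extreme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ystrpopgen.data import SampleTable, filter_complete
from ystrpopgen.distance import profile_matrix

__all__ = [
    "AmovaResult",
    "amova_one_factor",
    "amova_two_factor",
    "matched_subsample_amova",
    "MatchedSubsampleResult",
]


@dataclass
class AmovaResult:
    design: str  # "one_factor" | "two_factor"
    components: dict
    percentages: dict | None
    statistics: dict
    p_values: dict
    df: dict
    degenerate: bool = False
    flags: list = field(default_factory=list)

    def __post_init__(self):
        if self.percentages is not None:
            total = sum(self.percentages.values())
            if abs(total - 100.0) > 1e-6:
                raise ValueError(f"percentages sum to {total}, not 100")


def _group_codes(values) -> np.ndarray:
    uniq = {g: i for i, g in enumerate(dict.fromkeys(values))}
    return np.array([uniq[v] for v in values], dtype=np.int64)


def _ss_within(x: np.ndarray, labels: np.ndarray, n_groups: int):
    """Within-group sum of squares (over all markers) and group sizes."""
    counts = np.bincount(labels, minlength=n_groups).astype(float)
    ss = 0.0
    for m in range(x.shape[1]):
        col = x[:, m]
        sums = np.bincount(labels, weights=col, minlength=n_groups)
        sumsq = np.bincount(labels, weights=col * col, minlength=n_groups)
        with np.errstate(invalid="ignore"):
            ss += float(np.sum(sumsq - np.where(counts > 0, sums**2 / counts, 0.0)))
    return ss, counts


def _one_factor_components(x: np.ndarray, labels: np.ndarray):
    """(sigma2_among, sigma2_within) for repeat matrix *x* grouped by
    integer *labels* (0..G-1, every group nonempty)."""
    n, _ = x.shape
    n_groups = int(labels.max()) + 1
    ss_total = float(np.sum((x - x.mean(axis=0)) ** 2))
    ss_within, counts = _ss_within(x, labels, n_groups)
    ss_among = ss_total - ss_within
    df_a = n_groups - 1
    df_w = n - n_groups
    if df_a <= 0:
        return 0.0, ss_within / df_w if df_w > 0 else 0.0
    sigma_w = ss_within / df_w if df_w > 0 else 0.0
    n_prime = (n - float(np.sum(counts**2)) / n) / df_a
    sigma_a = (ss_among / df_a - sigma_w) / n_prime if n_prime > 0 else 0.0
    return sigma_a, sigma_w


def _phi(sigma_a: float, sigma_w: float) -> float:
    denom = sigma_a + sigma_w
    return sigma_a / denom if denom != 0.0 else 0.0


def amova_one_factor(
    table: SampleTable,
    grouping: dict,
    marker_set,
    permutations: int = 1000,
    seed: int | None = None,
) -> AmovaResult:
    """One-factor AMOVA of squared repeat distances.

    *grouping* maps sample_id -> group label; records incomplete on
    *marker_set* are excluded first (the deletion/missing exclusion rule).
    """
    marker_set = tuple(marker_set)
    table = filter_complete(table, marker_set)
    recs = [r for r in table.records if grouping.get(r.sample_id) is not None]
    if len(recs) < 2:
        raise ValueError("fewer than two usable samples")
    sub = SampleTable(recs, table.sites, table.panel, table.haplogroups)
    x = profile_matrix(sub, marker_set)
    labels = _group_codes([grouping[r.sample_id] for r in recs])
    if labels.max() < 1:
        raise ValueError("need at least two groups")

    sigma_a, sigma_w = _one_factor_components(x, labels)
    total = sigma_a + sigma_w
    phi = _phi(sigma_a, sigma_w)

    if total == 0.0:
        return AmovaResult(
            design="one_factor",
            components={"among": 0.0, "within": 0.0},
            percentages=None,
            statistics={"Phi_ST": 0.0},
            p_values={},
            df={"among": int(labels.max()), "within": len(recs) - int(labels.max()) - 1},
            degenerate=True,
            flags=["zero total variance"],
        )

    p_values = {}
    if permutations > 0:
        rng = np.random.default_rng(seed)
        b = 0
        lab = labels.copy()
        for _ in range(permutations):
            rng.shuffle(lab)
            sa, sw = _one_factor_components(x, lab)
            if _phi(sa, sw) >= phi - 1e-12:
                b += 1
        p_values["Phi_ST"] = (b + 1) / (permutations + 1)

    return AmovaResult(
        design="one_factor",
        components={"among": sigma_a, "within": sigma_w},
        percentages={
            "among": 100.0 * sigma_a / total,
            "within": 100.0 * sigma_w / total,
        },
        statistics={"Phi_ST": phi},
        p_values=p_values,
        df={"among": int(labels.max()), "within": len(recs) - int(labels.max()) - 1},
    )


def _two_factor_components(x, site_lab, cluster_lab, cluster_of_site):
    """Variance components (sigma_a among clusters, sigma_b among sites within
    clusters, sigma_c within sites) with hierarchical unequal-n coefficients."""
    n = x.shape[0]
    n_sites = int(site_lab.max()) + 1
    n_clusters = int(cluster_lab.max()) + 1

    ss_wp, site_counts = _ss_within(x, site_lab, n_sites)
    ss_wg, cluster_counts = _ss_within(x, cluster_lab, n_clusters)
    ss_total = float(np.sum((x - x.mean(axis=0)) ** 2))
    ss_ap = ss_wg - ss_wp  # among sites within clusters
    ss_ag = ss_total - ss_wg  # among clusters

    df_c = n - n_sites
    df_b = n_sites - n_clusters
    df_a = n_clusters - 1

    sigma_c = ss_wp / df_c if df_c > 0 else 0.0

    # Sum over clusters of (sum of n_p^2 within cluster) / n_g
    sum_np2_over_ng = 0.0
    for g in range(n_clusters):
        sel = site_counts[np.array([cluster_of_site[p] == g for p in range(n_sites)])]
        if cluster_counts[g] > 0:
            sum_np2_over_ng += float(np.sum(sel**2)) / cluster_counts[g]
    sum_np2_over_n = float(np.sum(site_counts**2)) / n
    sum_ng2_over_n = float(np.sum(cluster_counts**2)) / n

    n1 = (n - sum_np2_over_ng) / df_b if df_b > 0 else 0.0
    n2 = (sum_np2_over_ng - sum_np2_over_n) / df_a if df_a > 0 else 0.0
    n3 = (n - sum_ng2_over_n) / df_a if df_a > 0 else 0.0

    sigma_b = (ss_ap / df_b - sigma_c) / n1 if df_b > 0 and n1 > 0 else 0.0
    ms_ag = ss_ag / df_a if df_a > 0 else 0.0
    sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3 if n3 > 0 else 0.0
    return sigma_a, sigma_b, sigma_c


def amova_two_factor(
    table: SampleTable,
    site_grouping: dict,
    cluster_grouping: dict,
    marker_set,
    permutations: int = 1000,
    seed: int | None = None,
) -> AmovaResult:
    """Two-factor (nested) AMOVA: clusters / sites-within-clusters / samples.

    Sites must nest cleanly in clusters. Three permutation schemes give the
    level-wise p-values: samples among sites within clusters (Phi_SC), whole
    sites among clusters (Phi_CT), and samples among clusters (Phi_ST).
    """
    marker_set = tuple(marker_set)
    table = filter_complete(table, marker_set)
    recs = [
        r
        for r in table.records
        if site_grouping.get(r.sample_id) is not None
        and cluster_grouping.get(r.sample_id) is not None
    ]
    if len(recs) < 3:
        raise ValueError("fewer than three usable samples")
    sub = SampleTable(recs, table.sites, table.panel, table.haplogroups)
    x = profile_matrix(sub, marker_set)
    site_lab = _group_codes([site_grouping[r.sample_id] for r in recs])
    cluster_lab = _group_codes([cluster_grouping[r.sample_id] for r in recs])
    n_sites = int(site_lab.max()) + 1
    n_clusters = int(cluster_lab.max()) + 1
    if n_clusters < 2:
        raise ValueError("need at least two clusters")

    cluster_of_site = np.full(n_sites, -1, dtype=np.int64)
    for s, c in zip(site_lab, cluster_lab):
        if cluster_of_site[s] == -1:
            cluster_of_site[s] = c
        elif cluster_of_site[s] != c:
            raise ValueError("sites are not nested within clusters")

    flags = []
    sites_per_cluster = np.bincount(cluster_of_site, minlength=n_clusters)
    if np.any(sites_per_cluster == 1):
        flags.append("cluster with a single site")

    sigma_a, sigma_b, sigma_c = _two_factor_components(
        x, site_lab, cluster_lab, cluster_of_site
    )
    total = sigma_a + sigma_b + sigma_c
    stats = {
        "Phi_CT": sigma_a / total if total else 0.0,
        "Phi_SC": sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) else 0.0,
        "Phi_ST": (sigma_a + sigma_b) / total if total else 0.0,
    }

    if total == 0.0:
        return AmovaResult(
            design="two_factor",
            components={
                "among_clusters": 0.0,
                "among_sites_within": 0.0,
                "within_sites": 0.0,
            },
            percentages=None,
            statistics=stats,
            p_values={},
            df={
                "among_clusters": n_clusters - 1,
                "among_sites_within": n_sites - n_clusters,
                "within_sites": len(recs) - n_sites,
            },
            degenerate=True,
            flags=flags + ["zero total variance"],
        )

    p_values = {}
    if permutations > 0:
        rng = np.random.default_rng(seed)
        obs_sc, obs_ct, obs_st = stats["Phi_SC"], stats["Phi_CT"], stats["Phi_ST"]
        b_sc = b_ct = b_st = 0
        n = len(recs)
        for _ in range(permutations):
            # 1) samples among sites within clusters: permute site labels
            #    within each cluster, clusters fixed.
            perm_site = site_lab.copy()
            for c in range(n_clusters):
                idx = np.flatnonzero(cluster_lab == c)
                perm_site[idx] = site_lab[idx[rng.permutation(len(idx))]]
            sa, sb, sc = _two_factor_components(
                x, perm_site, cluster_lab, cluster_of_site
            )
            if (sb / (sb + sc) if (sb + sc) else 0.0) >= obs_sc - 1e-12:
                b_sc += 1
            # 2) whole sites among clusters: permute the site->cluster map.
            perm_map = cluster_of_site[rng.permutation(n_sites)]
            perm_cluster = perm_map[site_lab]
            sa, sb, sc = _two_factor_components(x, site_lab, perm_cluster, perm_map)
            tot = sa + sb + sc
            if (sa / tot if tot else 0.0) >= obs_ct - 1e-12:
                b_ct += 1
            # 3) samples among clusters: permute individuals across everything.
            shuf = rng.permutation(n)
            sa, sb, sc = _two_factor_components(
                x[shuf], site_lab, cluster_lab, cluster_of_site
            )
            tot = sa + sb + sc
            if ((sa + sb) / tot if tot else 0.0) >= obs_st - 1e-12:
                b_st += 1
        p_values = {
            "Phi_SC": (b_sc + 1) / (permutations + 1),
            "Phi_CT": (b_ct + 1) / (permutations + 1),
            "Phi_ST": (b_st + 1) / (permutations + 1),
        }

    return AmovaResult(
        design="two_factor",
        components={
            "among_clusters": sigma_a,
            "among_sites_within": sigma_b,
            "within_sites": sigma_c,
        },
        percentages={
            "among_clusters": 100.0 * sigma_a / total,
            "among_sites_within": 100.0 * sigma_b / total,
            "within_sites": 100.0 * sigma_c / total,
        },
        statistics=stats,
        p_values=p_values,
        df={
            "among_clusters": n_clusters - 1,
            "among_sites_within": n_sites - n_clusters,
            "within_sites": len(recs) - n_sites,
        },
        flags=flags,
    )


@dataclass
class MatchedSubsampleResult:
    percentages: list  # among-cluster percentage per replicate
    median: float
    q1: float
    q3: float
    minimum: float
    maximum: float


def matched_subsample_amova(
    reference: SampleTable,
    template_sizes,
    n_replicates: int = 100,
    marker_set=None,
    cluster_attr: str = "cluster_A",
    seed: int | None = None,
) -> MatchedSubsampleResult:
    """Matched-subsampling comparison: repeatedly draw subsets of a large
    reference dataset with the same number of sites and the same per-site
    sample-size profile as a target study, and run the two-factor AMOVA
    (clusters / sites / samples) on each.

    This quantifies how much among-cluster structure a reference population
    would show if it had been sampled exactly like the target study.
    Template sizes are matched greedily from largest to smallest, each to a
    randomly chosen not-yet-used site with at least that many complete
    samples; an unattainable template raises an error listing the blocking
    sizes.
    """
    marker_set = tuple(marker_set) if marker_set is not None else reference.panel.markers
    ref = filter_complete(reference, marker_set)
    template = sorted(template_sizes, reverse=True)
    if len(template) == 0:
        raise ValueError("empty template")

    by_site: dict = {}
    for r in ref.records:
        by_site.setdefault(r.site_id, []).append(r)
    site_ids = sorted(by_site)
    if len(site_ids) < len(template):
        raise ValueError(
            f"reference has {len(site_ids)} sites, template needs {len(template)}"
        )
    for sid in site_ids:
        if getattr(ref.sites[sid], cluster_attr) is None:
            raise ValueError(f"site {sid} lacks {cluster_attr}")

    sizes = np.array([len(by_site[s]) for s in site_ids])
    rng = np.random.default_rng(seed)
    percentages = []
    for _ in range(n_replicates):
        available = np.ones(len(site_ids), dtype=bool)
        chosen: list = []
        blocking = []
        for s in template:
            eligible = np.flatnonzero(available & (sizes >= s))
            if len(eligible) == 0:
                blocking.append(s)
                continue
            pick = int(rng.choice(eligible))
            available[pick] = False
            chosen.append((site_ids[pick], s))
        if blocking:
            raise ValueError(f"template unattainable; blocking sizes: {blocking}")
        recs = []
        for sid, s in chosen:
            pool = by_site[sid]
            idx = rng.choice(len(pool), size=s, replace=False)
            recs.extend(pool[i] for i in idx)
        sub = SampleTable(recs, ref.sites, ref.panel, ref.haplogroups)
        site_grp = {r.sample_id: r.site_id for r in recs}
        clus_grp = {
            r.sample_id: getattr(ref.sites[r.site_id], cluster_attr) for r in recs
        }
        res = amova_two_factor(
            sub, site_grp, clus_grp, marker_set, permutations=0
        )
        if res.percentages is None:
            percentages.append(0.0)
        else:
            percentages.append(res.percentages["among_clusters"])

    arr = np.array(percentages)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return MatchedSubsampleResult(
        percentages=percentages,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        minimum=float(arr.min()),
        maximum=float(arr.max()),
    )
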