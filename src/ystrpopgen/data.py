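"""Haplotype tables, site metadata, and the tabular IO all analyses consume.

The universal input is a :class:`SampleTable`: one :class:`HaplotypeRecord`
per sampled male (site, Y-SNP haplogroup, ethnic/linguistic labels, repeat
counts for up to 15 Y-STR loci), joined to per-site coordinates and
geographic-cluster labels, under a fixed :class:`~ystrpopgen.markers.MarkerPanel`.

Missing genotypes and the AZFa-deletion failure-to-amplify state are distinct
codes: both exclude a record from marker-set analyses (never imputed), but
they are reported separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ystrpopgen.markers import MarkerPanel

logger = logging.getLogger(__name__)

__all__ = [
    "MISSING",
    "DELETED",
    "LANGUAGE_CLASSES",
    "DEFAULT_HAPLOGROUPS",
    "HaplotypeRecord",
    "SiteMetadata",
    "SampleTable",
    "read_haplotype_table",
    "write_haplotype_table",
    "read_site_table",
    "write_site_table",
    "filter_complete",
    "summarize_sites",
    "SiteSummary",
]


class _Code:
    """Sentinel genotype code (singleton per name)."""

    __slots__ = ("name",)

    def __init__(self, name: str):
        self.name = name

    def __repr__(self):
        return self.name

    def __deepcopy__(self, memo):
        return self

    def __copy__(self):
        return self


MISSING = _Code("MISSING")
DELETED = _Code("DELETED")

LANGUAGE_CLASSES = (
    "Andean",
    "Chibchan-Paezan",
    "Equatorial-Tucanoan",
    "Ge-Pano-Carib",
    "isolate",
    "unassigned",
)

#: Default controlled vocabulary of Y-SNP haplogroup labels. Loaded datasets
#: with other clades (e.g. Asian C3* reference panels) may pass their own.
DEFAULT_HAPLOGROUPS = frozenset(
    {"Q1a3a", "Q1a3", "Q1a3a1", "Q1a3a-del", "C3*", "C3b", "Q*"}
)

_CLUSTER_A = frozenset({f"A{i}" for i in range(1, 7)})
_CLUSTER_B = frozenset({f"B{i}" for i in range(1, 4)})


@dataclass(frozen=True)
class HaplotypeRecord:
    sample_id: str
    site_id: str
    haplogroup: str
    ethnic_group: str
    language_group: str
    language_class: str
    str_profile: dict

    def __post_init__(self):
        if self.language_class not in LANGUAGE_CLASSES:
            raise ValueError(
                f"{self.sample_id}: unknown language class {self.language_class!r}"
            )
        for marker, value in self.str_profile.items():
            if value is MISSING or value is DELETED:
                continue
            if not isinstance(value, (int, np.integer)) or isinstance(value, bool):
                raise ValueError(
                    f"{self.sample_id}: non-integer repeat count at {marker}: {value!r}"
                )
            if not 5 <= int(value) <= 50:
                raise ValueError(
                    f"{self.sample_id}: repeat count at {marker} outside [5, 50]: {value}"
                )

    def is_complete(self, marker_set) -> bool:
        """True when every marker in *marker_set* has an integer repeat count."""
        return all(
            isinstance(self.str_profile.get(m, MISSING), (int, np.integer))
            for m in marker_set
        )


@dataclass(frozen=True)
class SiteMetadata:
    site_id: str
    latitude: float
    longitude: float
    cluster_A: str | None = None
    cluster_B: str | None = None

    def __post_init__(self):
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"{self.site_id}: latitude out of range")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"{self.site_id}: longitude out of range")
        if self.cluster_A is not None and self.cluster_A not in _CLUSTER_A:
            raise ValueError(f"{self.site_id}: unknown cluster_A {self.cluster_A!r}")
        if self.cluster_B is not None and self.cluster_B not in _CLUSTER_B:
            raise ValueError(f"{self.site_id}: unknown cluster_B {self.cluster_B!r}")


@dataclass
class SampleTable:
    """Haplotype records joined to site metadata under one marker panel."""

    records: list
    sites: dict
    panel: MarkerPanel
    haplogroups: frozenset = DEFAULT_HAPLOGROUPS

    def __post_init__(self):
        seen = set()
        for rec in self.records:
            if rec.sample_id in seen:
                raise ValueError(f"duplicate sample_id {rec.sample_id!r}")
            seen.add(rec.sample_id)
            if rec.site_id not in self.sites:
                raise ValueError(
                    f"{rec.sample_id}: site_id {rec.site_id!r} has no metadata"
                )
            if rec.haplogroup not in self.haplogroups:
                raise ValueError(
                    f"{rec.sample_id}: haplogroup {rec.haplogroup!r} not in vocabulary"
                )
            unknown = [m for m in rec.str_profile if m not in self.panel.markers]
            if unknown:
                raise ValueError(f"{rec.sample_id}: markers not in panel: {unknown}")

    def __len__(self):
        return len(self.records)

    def site_of(self, rec: HaplotypeRecord) -> SiteMetadata:
        return self.sites[rec.site_id]

    def grouping(self, by: str) -> dict:
        """Map sample_id -> group label for a named grouping.

        *by* is one of ``site``, ``cluster_A``, ``cluster_B``, ``haplogroup``,
        ``ethnic_group``, ``language_group``, ``language_class``.
        """
        if by == "site":
            return {r.sample_id: r.site_id for r in self.records}
        if by in ("cluster_A", "cluster_B"):
            return {
                r.sample_id: getattr(self.sites[r.site_id], by) for r in self.records
            }
        if by in ("haplogroup", "ethnic_group", "language_group", "language_class"):
            return {r.sample_id: getattr(r, by) for r in self.records}
        raise ValueError(f"unknown grouping {by!r}")


def _parse_cell(value, marker, sample_id):
    if value is None:
        return MISSING
    text = str(value).strip()
    if text in ("", "NA", "na", "NaN", "nan"):
        return MISSING
    if text.lower() == "del":
        return DELETED
    try:
        return int(text)
    except ValueError:
        raise ValueError(
            f"{sample_id}: non-integer repeat value at {marker}: {text!r}"
        ) from None


_META_COLUMNS = (
    "sample_id",
    "site_id",
    "haplogroup",
    "ethnic_group",
    "language_group",
    "language_class",
)


def read_haplotype_table(
    source,
    panel: MarkerPanel,
    sites: dict | None = None,
    haplogroups: frozenset = DEFAULT_HAPLOGROUPS,
) -> SampleTable:
    """Read a UTF-8 TSV haplotype table into a validated :class:`SampleTable`.

    Columns: the six metadata columns then one column per marker. Missing is
    coded as empty/``NA``, the AZFa deletion as ``del``. Row order preserved.
    If *sites* is None, placeholder site metadata at (0, 0) is attached (the
    geographic analyses then require a proper site table).
    """
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    for col in _META_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"haplotype table lacks column {col!r}")
    marker_cols = [c for c in df.columns if c not in _META_COLUMNS]
    unknown = [m for m in marker_cols if m not in panel.markers]
    if unknown:
        raise ValueError(f"unknown marker columns: {unknown}")

    records = []
    for row in df.itertuples(index=False):
        row = row._asdict()
        sid = row["sample_id"]
        profile = {m: _parse_cell(row[m], m, sid) for m in marker_cols}
        records.append(
            HaplotypeRecord(
                sample_id=sid,
                site_id=row["site_id"],
                haplogroup=row["haplogroup"],
                ethnic_group=row["ethnic_group"],
                language_group=row["language_group"],
                language_class=row["language_class"],
                str_profile=profile,
            )
        )
    if sites is None:
        sites = {
            r.site_id: SiteMetadata(r.site_id, 0.0, 0.0) for r in records
        }
    return SampleTable(records, sites, panel, haplogroups)


def write_haplotype_table(table: SampleTable, path) -> None:
    markers = [m for m in table.panel.markers]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_META_COLUMNS + tuple(markers)) + "\n")
        for r in table.records:
            cells = [
                r.sample_id,
                r.site_id,
                r.haplogroup,
                r.ethnic_group,
                r.language_group,
                r.language_class,
            ]
            for m in markers:
                v = r.str_profile.get(m, MISSING)
                if v is MISSING:
                    cells.append("NA")
                elif v is DELETED:
                    cells.append("del")
                else:
                    cells.append(str(int(v)))
            fh.write("\t".join(cells) + "\n")


def read_site_table(source) -> dict:
    """Read the TSV site table ``site_id, latitude, longitude, cluster_A,
    cluster_B`` into a site_id -> :class:`SiteMetadata` map."""
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    sites = {}
    for row in df.itertuples(index=False):
        row = row._asdict()
        sid = row["site_id"]
        if sid in sites:
            raise ValueError(f"duplicate site_id {sid!r}")
        sites[sid] = SiteMetadata(
            site_id=sid,
            latitude=float(row["latitude"]),
            longitude=float(row["longitude"]),
            cluster_A=row.get("cluster_A") or None,
            cluster_B=row.get("cluster_B") or None,
        )
    return sites


def write_site_table(sites: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("site_id\tlatitude\tlongitude\tcluster_A\tcluster_B\n")
        for s in sites.values():
            fh.write(
                f"{s.site_id}\t{s.latitude:.6f}\t{s.longitude:.6f}\t"
                f"{s.cluster_A or ''}\t{s.cluster_B or ''}\n"
            )


def filter_complete(table: SampleTable, marker_set) -> SampleTable:
    """Keep only records with an integer repeat count at every marker in
    *marker_set*; records carrying a deletion or missing genotype at any of
    those loci are excluded (never imputed)."""
    marker_set = tuple(marker_set)
    if not marker_set:
        raise ValueError("empty marker_set")
    unknown = [m for m in marker_set if m not in table.panel.markers]
    if unknown:
        raise ValueError(f"markers not in panel: {unknown}")
    kept = [r for r in table.records if r.is_complete(marker_set)]
    n_removed = len(table.records) - len(kept)
    if n_removed:
        n_del = sum(
            1
            for r in table.records
            if not r.is_complete(marker_set)
            and any(r.str_profile.get(m) is DELETED for m in marker_set)
        )
        logger.info(
            "filter_complete: removed %d of %d records (%d with deletions)",
            n_removed,
            len(table.records),
            n_del,
        )
    return SampleTable(kept, table.sites, table.panel, table.haplogroups)


@dataclass(frozen=True)
class SiteSummary:
    per_site_n: dict
    per_site_haplogroups: dict
    n_min: int
    n_max: int
    n_median: float
    n_q1: float
    n_q3: float


def summarize_sites(table: SampleTable) -> SiteSummary:
    """Per-site sample sizes and haplogroup counts, with the distribution of
    per-site n (median/quartiles by linear interpolation, the numpy default)."""
    if not table.records:
        raise ValueError("empty table")
    per_site_n: dict = {}
    per_hg: dict = {}
    for r in table.records:
        per_site_n[r.site_id] = per_site_n.get(r.site_id, 0) + 1
        per_hg.setdefault(r.site_id, {})
        per_hg[r.site_id][r.haplogroup] = per_hg[r.site_id].get(r.haplogroup, 0) + 1
    sizes = np.array(sorted(per_site_n.values()), dtype=float)
    q1, med, q3 = np.percentile(sizes, [25, 50, 75])
    return SiteSummary(
        per_site_n=per_site_n,
        per_site_haplogroups=per_hg,
        n_min=int(sizes.min()),
        n_max=int(sizes.max()),
        n_median=float(med),
        n_q1=float(q1),
        n_q3=float(q3),
    )
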