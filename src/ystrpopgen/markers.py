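"""Y-STR marker panels: marker order, per-locus mutation rates, network weights.

A :class:`MarkerPanel` fixes the marker order used throughout the package and
carries per-generation single-step mutation-rate estimates for each locus.
Median-joining network construction weights each marker by the reciprocal of
its mutation rate (slowly mutating loci are trusted more), normalised so the
mean weight is one — only relative weights matter.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import yaml

__all__ = [
    "MarkerPanel",
    "DEFAULT_PANEL",
    "SMALL_SET",
    "LARGE_SET",
    "NETWORK_SET",
    "read_panel",
    "write_panel",
]

#: The forensic 'minimal haplotype' loci.
SMALL_SET = (
    "DYS19",
    "DYS389I",
    "DYS389II",
    "DYS390",
    "DYS391",
    "DYS392",
    "DYS393",
)

#: Yfiler loci minus the duplicated DYS385ab.
LARGE_SET = SMALL_SET + (
    "DYS437",
    "DYS438",
    "DYS439",
    "DYS448",
    "DYS456",
    "DYS458",
    "DYS635",
    "YGATAH4",
)

#: Loci used for C3* network / TMRCA analyses: small set plus DYS439, with
#: DYS389II recoded as DYS389II-DYS389I (see :func:`transform_dys389`).
NETWORK_SET = SMALL_SET + ("DYS439",)


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered marker names with per-generation mutation rates.

    Invariants: marker names unique, every rate in (0, 0.05), weights are the
    reciprocal rates rescaled to mean 1.
    """

    markers: tuple[str, ...]
    mutation_rate: dict[str, float]
    weight: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("duplicate marker names in panel")
        missing = [m for m in self.markers if m not in self.mutation_rate]
        if missing:
            raise ValueError(f"no mutation rate for markers: {missing}")
        for m in self.markers:
            r = self.mutation_rate[m]
            if not 0.0 < r < 0.05:
                raise ValueError(f"mutation rate for {m} outside (0, 0.05): {r}")
        if not self.weight:
            inv = {m: 1.0 / self.mutation_rate[m] for m in self.markers}
            mean = sum(inv.values()) / len(inv)
            object.__setattr__(
                self, "weight", {m: v / mean for m, v in inv.items()}
            )
        else:
            for m in self.markers:
                if self.weight.get(m, 0.0) <= 0:
                    raise ValueError(f"non-positive weight for {m}")

    def subset(self, markers) -> "MarkerPanel":
        markers = tuple(markers)
        unknown = [m for m in markers if m not in self.markers]
        if unknown:
            raise ValueError(f"markers not in panel: {unknown}")
        return MarkerPanel(
            markers, {m: self.mutation_rate[m] for m in markers}
        )


# Default per-locus average father-son mutation rates (per generation), the
# published locus-specific estimates routinely used for forensic Y-STR panels.
_DEFAULT_RATES = {
    "DYS19": 2.2e-3,
    "DYS389I": 2.5e-3,
    "DYS389II": 3.6e-3,
    "DYS390": 2.1e-3,
    "DYS391": 2.6e-3,
    "DYS392": 4.0e-4,
    "DYS393": 1.1e-3,
    "DYS437": 1.3e-3,
    "DYS438": 3.0e-4,
    "DYS439": 5.1e-3,
    "DYS448": 1.4e-3,
    "DYS456": 4.2e-3,
    "DYS458": 6.4e-3,
    "DYS635": 3.8e-3,
    "YGATAH4": 2.8e-3,
}

DEFAULT_PANEL = MarkerPanel(LARGE_SET, dict(_DEFAULT_RATES))


def read_panel(source) -> MarkerPanel:
    """Read a marker panel from YAML (``marker: rate`` map or list of
    ``{marker, mutation_rate}``) or two-column TSV ``marker<TAB>rate``."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    stripped = text.lstrip()
    if "\t" in stripped.splitlines()[0]:
        rates: dict[str, float] = {}
        for line in stripped.splitlines():
            if not line.strip():
                continue
            name, rate = line.split("\t")[:2]
            if name.lower() in ("marker", "locus"):
                continue
            rates[name] = float(rate)
    else:
        data = yaml.safe_load(io.StringIO(text))
        if isinstance(data, list):
            rates = {d["marker"]: float(d["mutation_rate"]) for d in data}
        else:
            rates = {str(k): float(v) for k, v in data.items()}
    return MarkerPanel(tuple(rates), rates)


def write_panel(panel: MarkerPanel, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("marker\tmutation_rate\n")
        for m in panel.markers:
            fh.write(f"{m}\t{panel.mutation_rate[m]:g}\n")


def transform_dys389(profile: dict) -> dict:
    """Return a copy of an STR profile with DYS389II recoded as the repeat
    count of the second locus alone (DYS389II - DYS389I).

    Multiplex genotyping reads DYS389II as the combined count of both loci;
    profiles here store per-locus counts, so network panels that call for the
    differenced coding derive it on demand and never store it.
    """
    out = dict(profile)
    a, b = profile.get("DYS389I"), profile.get("DYS389II")
    if isinstance(a, int) and isinstance(b, int):
        out["DYS389II"] = b - a
    return out
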