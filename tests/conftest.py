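import numpy as np
import pytest

from ystrpopgen.data import HaplotypeRecord, SampleTable, SiteMetadata
from ystrpopgen.markers import MarkerPanel


@pytest.fixture
def panel1():
    return MarkerPanel(("M1",), {"M1": 2e-3})


@pytest.fixture
def panel2():
    return MarkerPanel(("M1", "M2"), {"M1": 2e-3, "M2": 3e-3})


@pytest.fixture
def make_table():
    """Factory: build a SampleTable from {site: [repeat values]} (one marker)
    or {site: [profile dicts]}; site coordinates spread along a meridian."""

    def _make(groups, panel=None, cluster_of=None, coords=None):
        markers = None
        recs, sites = [], {}
        i = 0
        for s, vals in groups.items():
            lat, lon = (coords or {}).get(s, (float(len(sites)), 0.0))
            sites[s] = SiteMetadata(
                s, lat, lon, cluster_A=(cluster_of or {}).get(s)
            )
            for v in vals:
                prof = v if isinstance(v, dict) else {"M1": v}
                markers = markers or tuple(prof)
                recs.append(
                    HaplotypeRecord(
                        f"x{i}", s, "Q1a3a", "eth", "grp", "Andean", dict(prof)
                    )
                )
                i += 1
        if panel is None:
            panel = MarkerPanel(markers, {m: 2e-3 for m in markers})
        return SampleTable(recs, sites, panel)

    return _make


@pytest.fixture(scope="session")
def survey():
    """Small synthetic survey shared by pipeline-level tests."""
    from ystrpopgen.simulate import SimConfig, simulate_dataset

    cfg = SimConfig(
        n_sites=15,
        n_demes=3,
        deme_size=300.0,
        migration_rate=0.02,
        rare_clades={"Q1a3": (0.05, 2), "C3*": (0.03, 1)},
        dominant_frequency=0.92,
        seed=42,
    )
    table, sites = simulate_dataset(cfg)
    return table
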