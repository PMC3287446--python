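"""Shared fixtures: reference worked-example tables and small synthetic data.

TABLE2 holds the five worked columns of raw counts (a large marine-data
publisher analyzed over one month, a medium and a small Danish publisher
over half-years, and the Danish national aggregate). TABLE3 holds the
download/record pairs behind the relative usage-impact example. Both are
inputs; the derived indicator values tests assert against are stated next
to each test.
"""

from datetime import datetime, timezone

import pytest
from hypothesis import settings

from dui import AnalysisWindow, DatasetInventory, SimConfig, build_registry, generate

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")

# column -> the six raw counts plus datasets-used n
TABLE2 = {
    "OBIS-Dec09": dict(s=2_092_927, d=555_835, r=11_140_298, S=42_860, D=601, N=180, n=171),
    "DanBIF-09b": dict(s=5_682_095, d=854_761, r=4_995_544, S=249_214, D=4_486, N=38, n=36),
    "HUA-09a": dict(s=2_299_133, d=809_468, r=259_077, S=126_449, D=2_059, N=2, n=2),
    "HUA-09b": dict(s=7_328_160, d=717_102, r=259_077, S=198_910, D=1_710, N=2, n=2),
    "DK-2009b": dict(s=13_010_255, d=1_571_863, r=4_836_771, S=448_124, D=6_246, N=40, n=36),
}

# unit -> (downloaded records d, stored records r)
TABLE3 = {
    "AAU-Herbarium": (716_772, 110_357),
    "AAU-PalmTransect": (250_330, 148_720),
    "HUA": (717_102, 259_077),
    "DanBIF": (854_761, 4_995_544),
    "Denmark": (1_571_863, 4_836_771),
}


def utc(*args) -> datetime:
    return datetime(*args, tzinfo=timezone.utc)


@pytest.fixture
def window_2009b() -> AnalysisWindow:
    return AnalysisWindow(utc(2009, 7, 1), utc(2010, 1, 1), label="2009b")


@pytest.fixture
def small_inventories() -> list[DatasetInventory]:
    """Five datasets, two publishers, one country; tiny known record sets."""
    def inv(ds, pub, n, species=None):
        return DatasetInventory(
            dataset_id=ds, publisher_id=pub, country_code="DK",
            total_records=n,
            species_records=species or {},
            record_ids=frozenset(f"{ds}:{i}" for i in range(n)),
        )

    return [
        inv("d1", "pubA", 10, {"sp1": 6, "sp2": 4}),
        inv("d2", "pubA", 5, {"sp1": 5}),
        inv("d3", "pubA", 20, {"sp2": 20}),
        inv("d4", "pubB", 40, {"sp3": 40}),
        inv("d5", "pubB", 25, {"sp1": 10, "sp3": 15}),
    ]


@pytest.fixture
def small_registry(small_inventories):
    return build_registry(small_inventories)


@pytest.fixture(scope="session")
def sim_small():
    """One small seeded synthetic portal log shared across tests."""
    config = SimConfig(
        n_publishers=8,
        n_species=60,
        n_ips=80,
        events_per_ip={"dist": "poisson", "lam": 12},
        download_given_search=0.2,
        seed=20090701,
    )
    return generate(config)
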