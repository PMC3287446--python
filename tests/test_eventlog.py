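"""Event parsing, bounce filtering, sessionization and raw counting."""

import io
import random
from datetime import datetime, timedelta, timezone

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dui import (
    AnalysisWindow,
    UsageEvent,
    build_registry,
    count_events,
    filter_bounces,
    parse_events,
    sessionize,
)
from dui.errors import UnknownUnitError, ValidationError
from dui.eventlog import DOWNLOAD_TYPES, SEARCH_TYPES

UTC = timezone.utc
T0 = datetime(2009, 7, 1, tzinfo=UTC)


def ev(minutes=0.0, ip="ip1", etype="search", ds="d1", n=1, ids=None):
    return UsageEvent(
        T0 + timedelta(minutes=minutes), ip, etype, ds, n,
        frozenset(ids) if ids is not None else None,
    )


class TestParseEvents:
    CSV = (
        "timestamp,ip_key,event_type,dataset_id,records_touched,record_ids\n"
        "2009-07-01T10:00:00,ip1,search,d1,2,a;b\n"
        "2009-07-01T09:00:00,ip2,download,d1,1,c\n"
        "2009-07-01T11:00:00,ip1,metadata_view,,0,\n"
    )

    def test_csv_happy_path_sorted(self):
        res = parse_events(io.StringIO(self.CSV))
        assert len(res) == 3 and not res.errors
        assert [e.ip_key for e in res] == ["ip2", "ip1", "ip1"]
        assert res.events[1].record_ids == frozenset("ab")

    def test_unknown_event_type_is_line_error(self):
        bad = self.CSV + "2009-07-01T12:00:00,ip3,purchase,d1,1,x\n"
        res = parse_events(io.StringIO(bad))
        assert len(res) == 3
        assert len(res.errors) == 1
        assert "purchase" in res.errors[0].raw
        assert res.errors[0].line == 5

    def test_unparseable_timestamp_is_line_error(self):
        bad = self.CSV + "yesterday,ip3,search,d1,1,x\n"
        res = parse_events(io.StringIO(bad))
        assert len(res.errors) == 1 and "yesterday" in res.errors[0].message

    def test_missing_required_column_rejects_file(self):
        with pytest.raises(ValidationError, match="ip_key"):
            parse_events(io.StringIO("timestamp,event_type,records_touched\n"))

    def test_jsonl(self):
        lines = (
            '{"timestamp": "2009-07-01T10:00:00", "ip_key": "ip1",'
            ' "event_type": "view", "dataset_id": "d1", "records_touched": 2,'
            ' "record_ids": ["a", "b"]}\n'
            "not json\n"
        )
        res = parse_events(io.StringIO(lines))
        assert len(res) == 1 and len(res.errors) == 1
        assert res.events[0].event_type == "view"

    def test_shuffled_input_sorted_by_timestamp(self):
        rng = random.Random(7)
        stamps = [T0 + timedelta(minutes=m) for m in rng.sample(range(500), 100)]
        body = "".join(
            f"{t.isoformat()},ip{i%7},search,d1,1,\n" for i, t in enumerate(stamps)
        )
        res = parse_events(io.StringIO(
            "timestamp,ip_key,event_type,dataset_id,records_touched,record_ids\n" + body
        ))
        assert [e.timestamp for e in res] == sorted(stamps)


class TestFilterBounces:
    def test_metadata_heavy_stream(self):
        events = [ev(i, etype="metadata_view", ds=None, n=0) for i in range(66)]
        events += [ev(100 + i, n=2) for i in range(34)]
        kept, frac = filter_bounces(events)
        assert frac == pytest.approx(0.66)
        assert len(kept) == 34

    def test_no_bounces(self):
        kept, frac = filter_bounces([ev(n=1), ev(1, etype="download", n=3)])
        assert frac == 0.0 and len(kept) == 2

    def test_empty_stream(self):
        assert filter_bounces([]) == ([], 0.0)

    def test_zero_record_search_is_bounce_but_not_download(self):
        events = [ev(0, n=0), ev(1, etype="download", n=0), ev(2, n=5)]
        kept, frac = filter_bounces(events)
        assert [e.event_type for e in kept] == ["download", "search"]
        assert frac == pytest.approx(1 / 3)

    @given(st.lists(st.tuples(
        st.sampled_from(sorted(SEARCH_TYPES | DOWNLOAD_TYPES | {"metadata_view"})),
        st.integers(0, 5)), max_size=60))
    def test_matches_independent_predicate_scan(self, spec):
        events = [
            ev(i, etype=t, n=0 if t == "metadata_view" else n)
            for i, (t, n) in enumerate(spec)
        ]
        kept, frac = filter_bounces(events)
        oracle = [
            e for e in events
            if not (e.event_type == "metadata_view"
                    or (e.event_type in SEARCH_TYPES and e.records_touched == 0))
        ]
        assert kept == oracle
        assert frac == ((len(events) - len(oracle)) / len(events) if events else 0.0)


def brute_force_sessions(events, gap_minutes=30.0):
    """Reference sessionizer: independent linear scan per visitor key."""
    out = {}
    for e in sorted(events, key=lambda e: e.timestamp):
        out.setdefault(e.ip_key, []).append(e)
    sessions = []
    for ip, evs in out.items():
        runs = [[evs[0]]]
        for prev, cur in zip(evs, evs[1:]):
            if (cur.timestamp - prev.timestamp).total_seconds() >= gap_minutes * 60:
                runs.append([cur])
            else:
                runs[-1].append(cur)
        for i, run in enumerate(runs):
            sessions.append((ip, run[0].timestamp, run[-1].timestamp,
                             tuple(run), i > 0))
    return sorted(sessions, key=lambda s: (s[1], s[0]))


class TestSessionize:
    def test_sub_threshold_gaps_single_session(self):
        events = [ev(i * 29.0) for i in range(4)]
        (s,) = sessionize(events)
        assert not s.loyal and len(s.events) == 4

    def test_exactly_30_minute_gap_splits_and_marks_loyal(self):
        events = [ev(0.0), ev(30.0)]
        s1, s2 = sessionize(events)
        assert not s1.loyal
        assert s2.loyal  # a reappearance after >= 30 min idle is loyal

    def test_first_session_per_ip_never_loyal(self):
        events = [ev(0, ip="a"), ev(0, ip="b"), ev(100, ip="a"), ev(200, ip="b")]
        loyal = {(s.ip_key, s.start): s.loyal for s in sessionize(events)}
        assert loyal[("a", T0)] is False and loyal[("b", T0)] is False

    def test_non_positive_gap_rejected(self):
        with pytest.raises(ValidationError):
            sessionize([ev()], gap_minutes=0)

    def test_interleaving_of_ips_is_irrelevant(self):
        rng = random.Random(11)
        events = [ev(rng.uniform(0, 600), ip=f"ip{rng.randrange(5)}")
                  for _ in range(80)]
        shuffled = events[:]
        rng.shuffle(shuffled)
        a = sessionize(events)
        b = sessionize(shuffled)
        assert [(s.ip_key, s.start, s.end, s.loyal) for s in a] == [
            (s.ip_key, s.start, s.end, s.loyal) for s in b
        ]

    @settings(deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_random_streams_match_brute_force(self, seed):
        rng = random.Random(seed)
        events = [
            ev(rng.uniform(0, 48 * 60), ip=f"ip{rng.randrange(50)}")
            for _ in range(rng.randrange(0, 120))
        ]
        got = [
            (s.ip_key, s.start, s.end, s.events, s.loyal)
            for s in sessionize(events)
        ]
        assert got == brute_force_sessions(events)


class TestCountEvents:
    @pytest.fixture
    def registry(self, small_registry):
        return small_registry

    @pytest.fixture
    def window(self, window_2009b):
        return window_2009b

    def test_fields_match_pandas_groupby_oracle(self, sim_small):
        import pandas as pd

        from dui import build_registry, filter_bounces

        reg = build_registry(sim_small.inventories)
        kept, _ = filter_bounces(sim_small.events)
        window = sim_small.config.window
        df = pd.DataFrame(
            {
                "ds": e.dataset_id,
                "type": e.event_type,
                "n": e.records_touched,
                "is_search": e.event_type in SEARCH_TYPES,
            }
            for e in kept
        )
        pub = reg.unit("publisher:P001")
        got = count_events(kept, pub, window, reg)
        sub = df[df.ds.isin(pub.member_datasets)]
        assert got.s == sub[sub.is_search].n.sum()
        assert got.S == int(sub.is_search.sum())
        assert got.d == sub[~sub.is_search].n.sum()
        assert got.D == int((~sub.is_search).sum())
        assert got.n == sub.ds.nunique()

    def test_empty_window_all_zero(self, registry):
        w = AnalysisWindow(datetime(2001, 1, 1), datetime(2001, 1, 2))
        got = count_events([ev(n=3)], "world", w, registry)
        assert (got.s, got.d, got.S, got.D, got.n) == (0, 0, 0, 0, 0)
        assert got.U == 0 and got.I == 0

    def test_unknown_unit_rejected(self, registry, window):
        with pytest.raises(UnknownUnitError):
            count_events([], "publisher:nope", window, registry)

    def test_unique_counts_unavailable_without_ids(self, registry, window):
        got = count_events([ev(n=3)], "world", window, registry)
        assert got.s == 3 and got.I is None

    def test_unique_counts_are_set_unions(self, registry, window):
        events = [
            ev(0, etype="download", n=2, ids={"a", "b"}),
            ev(1, etype="download", n=2, ids={"b", "c"}),
            ev(2, n=2, ids={"a", "x"}),
        ]
        got = count_events(events, "world", window, registry)
        assert got.d == 4 and got.U == 3
        assert got.s == 2 and got.I == 2

    def test_additive_over_window_partition(self, sim_small):
        reg = build_registry(sim_small.inventories)
        kept, _ = filter_bounces(sim_small.events)
        w = sim_small.config.window
        mid = w.start + (w.end - w.start) / 2
        w1 = AnalysisWindow(w.start, mid)
        w2 = AnalysisWindow(mid, w.end)
        full = count_events(kept, "world", w, reg)
        a = count_events(kept, "world", w1, reg)
        b = count_events(kept, "world", w2, reg)
        assert (a.s + b.s, a.d + b.d, a.S + b.S, a.D + b.D) == (
            full.s, full.d, full.S, full.D,
        )
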