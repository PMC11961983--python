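import pandas as pd
import pytest

import pvsignal as pv


def make_universe(target_events: dict[str, int], other_events: dict[str, int]) -> pv.EventUniverse:
    """Build an EventUniverse from per-PT event counts, one report per event."""
    rows = []
    pid = 0
    for pt, k in sorted(target_events.items()):
        for _ in range(k):
            pid += 1
            rows.append((f"t{pid:05d}", pv.normalize_term(pt), True))
    for pt, k in sorted(other_events.items()):
        for _ in range(k):
            pid += 1
            rows.append((f"o{pid:05d}", pv.normalize_term(pt), False))
    events = pd.DataFrame(rows, columns=["primaryid", "pt", "is_target"])
    reports = pd.DataFrame({"primaryid": events["primaryid"].unique()})
    return pv.EventUniverse(
        reports=reports,
        events=events,
        target_report_ids=set(events.loc[events["is_target"], "primaryid"]),
    )


@pytest.fixture(scope="session")
def synthetic_db():
    """A mid-sized synthetic database shared across tests (fixed seed)."""
    return pv.generate_database(pv.GeneratorConfig(n_reports=800, seed=42))


@pytest.fixture(scope="session")
def toy_dict():
    return pv.toy_dictionary()
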