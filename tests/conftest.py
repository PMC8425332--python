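import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from scanstab import MeasurementTable

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def long_records(values_by_subject, measure="m", site_of=None, scanner_of=None):
    """Build long-format rows from {subject: [v1, v2, ...]} (None = missing)."""
    site_of = site_of or {}
    scanner_of = scanner_of or {}
    rows = []
    for subj, values in values_by_subject.items():
        site = site_of.get(subj, "SiteA")
        for j, v in enumerate(values, start=1):
            if v is None:
                continue
            rows.append(
                {
                    "subject_id": subj,
                    "site": site,
                    "scanner_type": scanner_of.get(site, "ScannerX"),
                    "visit": j,
                    "measure": measure,
                    "value": float(v),
                }
            )
    return rows


@pytest.fixture
def toy_table():
    """Five subjects, one measure, three visits, no missing data."""
    rng = np.random.default_rng(0)
    recs = long_records({f"S{i}": rng.normal(10, 2, 3) for i in range(5)})
    return MeasurementTable(pd.DataFrame(recs))


@pytest.fixture
def two_scanner_table():
    """Two sites per scanner, 6 subjects per site, three visits."""
    rng = np.random.default_rng(1)
    site_of = {}
    values = {}
    for s, site in enumerate(["Leiden", "Vancouver", "London", "Paris"]):
        for i in range(6):
            subj = f"{site[:3]}{i}"
            site_of[subj] = site
            values[subj] = rng.normal(10, 2, 3)
    scanner_of = {"Leiden": "Philips", "Vancouver": "Philips",
                  "London": "Siemens", "Paris": "Siemens"}
    recs = long_records(values, site_of=site_of, scanner_of=scanner_of)
    return MeasurementTable(pd.DataFrame(recs))
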