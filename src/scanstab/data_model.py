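"""Measurement data model, long-format CSV I/O and complete-case filtering.

The analysis consumes *derived* scalar measures only: one row per
subject x visit x measure, with site and scanner-type metadata.  Values are
kept in measure-native units (mm for thickness, mm^3 for volume, mm^2/s for
diffusivities) and never converted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("subject_id", "site", "scanner_type", "visit", "measure", "value")


class SchemaError(ValueError):
    """An input table does not carry the required columns / dtypes."""


class IntegrityError(ValueError):
    """An input table violates a structural invariant (duplicates, a
    subject at two sites, a site on two scanner types)."""


class DegenerateDataError(ValueError):
    """Too little data for the requested statistic (e.g. fewer than two
    complete cases, or a zero variance denominator)."""


class ConfigurationError(ValueError):
    """A configuration value is inconsistent with the study design."""


class MeasurementTable:
    """Validated long-format table of scalar measures.

    Parameters
    ----------
    data:
        DataFrame with columns ``subject_id, site, scanner_type, visit,
        measure, value``.  ``visit`` is a 1-based integer index; no dates
        are modelled.
    roster:
        Optional explicit cohort roster (all enrolled subject ids).  The
        roster is the denominator for missing-case bookkeeping: a measure's
        missing-case count is ``len(roster) - n_complete``, so subjects who
        contribute no record at all for a measure still count as missing.
        Defaults to the subjects present anywhere in ``data``.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        roster: Sequence[str] | None = None,
        validate: bool = True,
    ) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in data.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
        df = data.loc[:, list(REQUIRED_COLUMNS)].copy()
        try:
            df["visit"] = df["visit"].astype(np.int64)
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"visit column is not integer-valued: {exc}") from None
        try:
            df["value"] = df["value"].astype(np.float64)
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"value column is not numeric: {exc}") from None
        for col in ("subject_id", "site", "scanner_type", "measure"):
            df[col] = df[col].astype(str)
        df = df.reset_index(drop=True)
        if validate:
            self._validate(df)
        self._data = df
        if roster is None:
            roster = sorted(df["subject_id"].unique())
        self._roster = tuple(str(s) for s in roster)
        extra = set(df["subject_id"]) - set(self._roster)
        if extra:
            raise IntegrityError(
                f"{len(extra)} subject(s) appear in the data but not in the roster"
            )

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        if (df["visit"] < 1).any():
            raise IntegrityError("visit indices must be >= 1")
        dup = df.duplicated(subset=["subject_id", "measure", "visit"])
        if dup.any():
            first = df.loc[dup.idxmax(), ["subject_id", "measure", "visit"]]
            raise IntegrityError(
                "duplicate (subject, measure, visit) record: "
                f"{tuple(first)}"
            )
        sites_per_subject = df.groupby("subject_id")["site"].nunique()
        if (sites_per_subject > 1).any():
            bad = sites_per_subject[sites_per_subject > 1].index[0]
            raise IntegrityError(f"subject {bad!r} is listed at more than one site")
        scanners_per_site = df.groupby("site")["scanner_type"].nunique()
        if (scanners_per_site > 1).any():
            bad = scanners_per_site[scanners_per_site > 1].index[0]
            raise IntegrityError(f"site {bad!r} maps to more than one scanner type")

    # -- accessors ---------------------------------------------------------

    @property
    def data(self) -> pd.DataFrame:
        """The underlying long-format records (do not mutate)."""
        return self._data

    @property
    def roster(self) -> tuple[str, ...]:
        return self._roster

    @property
    def k(self) -> int:
        """Number of visits, inferred as the largest visit index present."""
        return int(self._data["visit"].max())

    @property
    def measures(self) -> tuple[str, ...]:
        return tuple(sorted(self._data["measure"].unique()))

    @property
    def subjects(self) -> tuple[str, ...]:
        return tuple(sorted(self._data["subject_id"].unique()))

    def site_of(self) -> dict[str, str]:
        """Mapping subject_id -> site."""
        return dict(
            self._data.drop_duplicates("subject_id")[["subject_id", "site"]].values
        )

    def scanner_of_site(self) -> dict[str, str]:
        """Mapping site -> scanner_type."""
        return dict(
            self._data.drop_duplicates("site")[["site", "scanner_type"]].values
        )

    def __len__(self) -> int:
        return len(self._data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MeasurementTable):
            return NotImplemented
        return self._roster == other._roster and self._data.equals(other._data)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"MeasurementTable({len(self._data)} records, "
            f"{len(self.subjects)} subjects, {len(self.measures)} measures, "
            f"k={self.k})"
        )


@dataclass(frozen=True)
class CompleteCaseMatrix:
    """Per-measure subjects x visits value matrix after listwise deletion.

    ``missing_cases`` is counted against the cohort roster, mirroring the
    bookkeeping of per-measure missing-case columns in multi-site
    reliability reports.
    """

    values: np.ndarray
    subject_ids: tuple[str, ...]
    group_labels: tuple[str, ...]
    missing_cases: int
    measure: str
    site_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise SchemaError("values must be a 2-D subjects x visits matrix")
        n, k = values.shape
        if n < 2 or k < 2:
            raise DegenerateDataError(f"need n >= 2 subjects and k >= 2 visits, got {n}x{k}")
        if np.isnan(values).any():
            raise IntegrityError("complete-case matrix contains missing entries")
        if len(self.subject_ids) != n or len(self.group_labels) != n:
            raise SchemaError("subject_ids/group_labels length must equal row count")
        if self.missing_cases < 0:
            raise IntegrityError("missing_cases must be >= 0")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


def read_long_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    roster: Sequence[str] | None = None,
) -> MeasurementTable:
    """Read a long-format CSV into a validated :class:`MeasurementTable`.

    Parameters
    ----------
    path:
        CSV file with a header row; comma separated, UTF-8, decimal point.
        Scientific notation in the value column is accepted.
    schema:
        Optional mapping from canonical column name (``subject_id`` etc.)
        to the actual column name in the file.
    roster:
        Optional explicit cohort roster (see :class:`MeasurementTable`).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if schema:
        rename = {actual: canonical for canonical, actual in schema.items()}
        absent = [a for a in rename if a not in df.columns]
        if absent:
            raise SchemaError(f"schema maps to absent column(s): {absent}")
        df = df.rename(columns=rename)
    return MeasurementTable(df, roster=roster)


def filter_complete_cases(
    table: MeasurementTable, measure: str, k: int | None = None
) -> CompleteCaseMatrix:
    """Listwise-delete subjects missing any of the ``k`` visits for a measure.

    Returns the n x k value matrix of subjects with all visits ``1..k``
    present, their scanner-type group labels, and the missing-case count
    relative to the cohort roster.
    """
    if measure not in set(table.data["measure"]):
        raise KeyError(f"measure {measure!r} not present in table")
    if k is None:
        k = table.k
    if k < 2:
        raise DegenerateDataError("need k >= 2 visits")
    sub = table.data[table.data["measure"] == measure]
    wide = sub.pivot(index="subject_id", columns="visit", values="value")
    wide = wide.reindex(columns=range(1, k + 1))
    complete = wide.dropna(axis=0, how="any").sort_index()
    n = len(complete)
    if n < 2:
        raise DegenerateDataError(
            f"measure {measure!r}: only {n} complete case(s); need >= 2"
        )
    site_of = table.site_of()
    scanner_of = table.scanner_of_site()
    subject_ids = tuple(complete.index)
    sites = tuple(site_of[s] for s in subject_ids)
    groups = tuple(scanner_of[site] for site in sites)
    return CompleteCaseMatrix(
        values=complete.to_numpy(dtype=float),
        subject_ids=subject_ids,
        group_labels=groups,
        missing_cases=len(table.roster) - n,
        measure=measure,
        site_labels=sites,
    )


def _format_value(v: object) -> object:
    """Report formatting: 6 significant digits, scientific notation for
    small magnitudes (diffusivities print as e.g. 1.18E-03)."""
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    if isinstance(v, (float, np.floating)):
        if np.isnan(v):
            return ""
        if v != 0 and abs(v) < 1e-2:
            return f"{v:.6E}"
        return f"{v:.6G}"
    return v


def write_report_table(results: pd.DataFrame, path: str | Path) -> None:
    """Write a report table to CSV with deterministic row order.

    Rows are sorted by the ``measure`` column when present; floats are
    written to 6 significant digits (scientific notation below 1e-2), which
    round-trips through :func:`read_report_table`.
    """
    if results is None or len(results) == 0:
        raise ValueError("refusing to write an empty report table")
    df = results.copy()
    if "measure" in df.columns:
        df = df.sort_values("measure", kind="stable").reset_index(drop=True)
    out = df.map(_format_value)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)


def read_report_table(path: str | Path) -> pd.DataFrame:
    """Read back a report CSV written by :func:`write_report_table`."""
    return pd.read_csv(path)


def build_table(
    records: Iterable[Mapping[str, object]],
    roster: Sequence[str] | None = None,
) -> MeasurementTable:
    """Convenience constructor from an iterable of record dicts."""
    return MeasurementTable(pd.DataFrame(list(records)), roster=roster)
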