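"""Pipeline orchestration and report tables.

Assembles the full analysis — simulate or ingest, listwise-filter, ICC,
mixed ANOVA with sphericity handling, scanner/site effects, power — into
flat per-measure report tables, and writes them as CSV.

Report conventions: ICCs are reported to 2 decimals in the formatted
columns, F to 2 decimals, p-values with a "<0.001" floor; the numeric
columns keep full precision (the CSV writer rounds to 6 significant
digits).  Measures are grouped into families (e.g. connectivity,
thickness, volume) and each effect's Bonferroni correction uses the family
size c.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .anova import apply_gg_if_violated, bonferroni_family, lsd_site_comparison, mixed_anova
from .cohort import SimulationConfig, default_config, load_simulation_config, simulate_cohort
from .data_model import (
    ConfigurationError,
    MeasurementTable,
    filter_complete_cases,
    read_long_table,
    write_report_table,
)
from .icc import DEFAULT_CUTOFF, icc_from_matrix
from .power import attenuate_effect, power_curve, power_two_sample_t, required_n

logger = logging.getLogger("scanstab")


def format_p(p: float) -> str:
    """Render a p-value the way reliability tables print them."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "<0.001"
    return f"{p:.3f}" if p < 0.01 else f"{p:.2f}"


def percent_decline(mean_first: float, mean_last: float) -> float:
    """Percent decrease from the first to the last visit mean.

    Positive for a decline; e.g. a volume falling 1860 -> 1805 across the
    study is a ~3% decrease.
    """
    if mean_first == 0:
        raise ValueError("first-visit mean is zero; percent change undefined")
    return 100.0 * (mean_first - mean_last) / mean_first


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``input_path`` (long-format CSV) or ``simulation``
    drives the input stage.  ``families`` maps a family name to its measure
    list and Bonferroni family size c; every analysed measure must belong
    to exactly one family and c must be at least the family's measure
    count.
    """

    simulation: SimulationConfig | None = None
    input_path: str | None = None
    families: Mapping[str, tuple[Sequence[str], int]] = field(default_factory=dict)
    cutoff: float = DEFAULT_CUTOFF
    alpha: float = 0.05
    alpha_sphericity: float = 0.05
    delta: float = 0.75
    target_power: float = 0.80
    power_curve_deltas: Sequence[float] = (0.25, 0.5, 0.75, 1.0, 1.25, 1.5)
    power_curve_reliabilities: Sequence[float] = (0.6, 0.68, 0.8, 0.9, 0.92, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.input_path is None):
            raise ConfigurationError(
                "exactly one of simulation config or input path must be set"
            )
        seen: dict[str, str] = {}
        for fam, (measures, c) in self.families.items():
            if c < len(measures):
                raise ConfigurationError(
                    f"family {fam!r}: c={c} < {len(measures)} measures"
                )
            for m in measures:
                if m in seen:
                    raise ConfigurationError(
                        f"measure {m!r} in families {seen[m]!r} and {fam!r}"
                    )
                seen[m] = fam

    def family_of(self, measure: str) -> tuple[str, int]:
        for fam, (measures, c) in self.families.items():
            if measure in measures:
                return fam, c
        return "default", max(len(self._all_family_measures()), 1)

    def _all_family_measures(self) -> list[str]:
        return [m for measures, _ in self.families.values() for m in measures]


def _measure_stats(table: MeasurementTable, measure: str, cutoff: float,
                   alpha_sphericity: float) -> dict:
    """Filter, ICC and ANOVA for one measure; shared by the report builders."""
    ccm = filter_complete_cases(table, measure)
    icc = icc_from_matrix(ccm, cutoff=cutoff)
    res = apply_gg_if_violated(mixed_anova(ccm), alpha_sphericity=alpha_sphericity)
    return {"ccm": ccm, "icc": icc, "anova": res}


def reliability_report(
    table: MeasurementTable,
    measures: Sequence[str] | None = None,
    bonferroni_c: int | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    alpha: float = 0.05,
    alpha_sphericity: float = 0.05,
) -> pd.DataFrame:
    """Per-measure reliability table: per-visit mean (SD), missing cases,
    ICC(2,k), ICC(2,1), and the time main effect with GG adjustment.

    The time and interaction effects each form a Bonferroni family of size
    ``bonferroni_c`` (default: the number of measures).  A significant time
    effect is flagged as superseded when the time x scanner interaction is
    itself significant at the family-adjusted alpha.
    """
    measures = list(measures) if measures is not None else list(table.measures)
    c = bonferroni_c if bonferroni_c is not None else len(measures)
    stats_by_measure = {
        m: _measure_stats(table, m, cutoff, alpha_sphericity) for m in measures
    }
    adj_alpha, time_flags = bonferroni_family(
        [stats_by_measure[m]["anova"].time.p for m in measures], c, alpha
    )
    inter_ps = [
        (stats_by_measure[m]["anova"].interaction.p
         if stats_by_measure[m]["anova"].interaction is not None else np.nan)
        for m in measures
    ]
    _, inter_flags = bonferroni_family(
        [p if np.isfinite(p) else 1.0 for p in inter_ps], c, alpha
    )
    rows = []
    for m, t_sig, i_p, i_sig in zip(measures, time_flags, inter_ps, inter_flags):
        st = stats_by_measure[m]
        ccm, icc, res = st["ccm"], st["icc"], st["anova"]
        row: dict[str, object] = {"measure": m, "n": ccm.n, "missing_cases": ccm.missing_cases}
        for j in range(ccm.k):
            row[f"mean_t{j + 1}"] = float(ccm.values[:, j].mean())
            row[f"sd_t{j + 1}"] = float(ccm.values[:, j].std(ddof=1))
        inter = res.interaction
        row.update(
            icc_2k=icc.icc_average,
            icc_21=icc.icc_single,
            reliable=icc.reliable_flag,
            time_f=res.time.f,
            time_df1=res.time.df1,
            time_df2=res.time.df2,
            time_p=res.time.p,
            time_p_text=format_p(res.time.p),
            mauchly_w=res.mauchly_w,
            mauchly_p=res.mauchly_p,
            gg_applied=res.gg_applied,
            time_sig_bonferroni=t_sig,
            interaction_f=inter.f if inter else np.nan,
            interaction_p=i_p,
            interaction_sig_bonferroni=bool(i_sig) if inter else False,
            time_superseded=bool(t_sig and inter and i_sig),
            bonferroni_alpha=adj_alpha,
        )
        rows.append(row)
    report = pd.DataFrame(rows).sort_values("measure", kind="stable").reset_index(drop=True)
    logger.info("reliability report: %d measures, family alpha %.5f", len(rows), adj_alpha)
    return report


def scanner_report(
    table: MeasurementTable,
    measures: Sequence[str] | None = None,
    bonferroni_c: int | None = None,
    alpha: float = 0.05,
    alpha_sphericity: float = 0.05,
) -> pd.DataFrame:
    """Per-measure scanner/site table: per-scanner and per-site means (SD)
    collapsed across visits, within-scanner Fisher's-LSD p, and the scanner
    main effect F(df1, df2) with its Bonferroni flag."""
    measures = list(measures) if measures is not None else list(table.measures)
    c = bonferroni_c if bonferroni_c is not None else len(measures)
    scanner_of = table.scanner_of_site()
    scanners = sorted(set(scanner_of.values()))
    if len(scanners) < 2:
        raise ConfigurationError("scanner report needs >= 2 scanner groups")
    rows = []
    scanner_ps = []
    for m in measures:
        ccm = filter_complete_cases(table, m)
        res = mixed_anova(ccm)
        if res.scanner is None:
            raise ConfigurationError("scanner report needs >= 2 scanner groups")
        subj_means = ccm.values.mean(axis=1)
        grp = np.array(ccm.group_labels)
        sites_arr = np.array(ccm.site_labels)
        row: dict[str, object] = {"measure": m, "n": ccm.n}
        for sc in scanners:
            x = subj_means[grp == sc]
            row[f"mean_{sc}"] = float(x.mean())
            row[f"sd_{sc}"] = float(x.std(ddof=1))
            for site in sorted(s for s, v in scanner_of.items() if v == sc):
                xs = subj_means[sites_arr == site]
                row[f"mean_{site}"] = float(xs.mean()) if len(xs) else np.nan
                row[f"sd_{site}"] = float(xs.std(ddof=1)) if len(xs) > 1 else np.nan
            lsd = lsd_site_comparison(table, m, sc)
            row[f"lsd_p_{sc}"] = lsd.p
            row[f"lsd_t_{sc}"] = lsd.t
        row.update(
            scanner_f=res.scanner.f,
            scanner_df1=res.scanner.df1,
            scanner_df2=res.scanner.df2,
            scanner_p=res.scanner.p,
            scanner_p_text=format_p(res.scanner.p),
        )
        scanner_ps.append(res.scanner.p)
        rows.append(row)
    adj_alpha, flags = bonferroni_family(scanner_ps, c, alpha)
    for row, flag in zip(rows, flags):
        row["scanner_sig_bonferroni"] = flag
        row["bonferroni_alpha"] = adj_alpha
    report = pd.DataFrame(rows).sort_values("measure", kind="stable").reset_index(drop=True)
    logger.info("scanner report: %d measures, family alpha %.5f", len(rows), adj_alpha)
    return report


def power_report(
    icc_report: pd.DataFrame,
    delta: float = 0.75,
    alpha: float = 0.05,
    target_power: float = 0.80,
) -> pd.DataFrame:
    """Per-measure sample-size planning from the reliability report.

    Reliability is taken as each measure's ICC(2,1); the idealized effect
    ``delta`` is attenuated by sqrt(reliability) and the minimal per-group
    n for the target power computed exactly.
    """
    if "icc_21" not in icc_report.columns:
        raise KeyError("icc_report lacks an 'icc_21' column")
    rows = []
    for _, rec in icc_report.iterrows():
        r = float(rec["icc_21"])
        r_clipped = float(min(max(r, 0.0), 1.0))
        d = attenuate_effect(delta, r_clipped)
        n = required_n(d, alpha, target_power) if d > 0 else np.nan
        rows.append(
            {
                "measure": rec["measure"],
                "reliability": r,
                "delta": delta,
                "d_attenuated": d,
                "n_per_group": n,
                "achieved_power": power_two_sample_t(d, int(n), alpha) if d > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows).sort_values("measure", kind="stable").reset_index(drop=True)


def _default_families(measures: Sequence[str]) -> dict[str, tuple[list[str], int]]:
    """Assign measures to the conventional families by name; family sizes
    default to 16 (connectivity) and 14 (thickness, volume)."""
    fams: dict[str, list[str]] = {"connectivity": [], "thickness": [], "volume": []}
    for m in measures:
        low = m.lower()
        if "thick" in low:
            fams["thickness"].append(m)
        elif "vol" in low:
            fams["volume"].append(m)
        else:
            fams["connectivity"].append(m)
    sizes = {"connectivity": 16, "thickness": 14, "volume": 14}
    return {
        fam: (ms, max(sizes[fam], len(ms)))
        for fam, ms in fams.items()
        if ms
    }


def run_pipeline(
    config: PipelineConfig, out_dir: str | Path, dry_run: bool = False
) -> dict[str, pd.DataFrame]:
    """Execute the full pipeline and write the report CSVs.

    Writes ``reliability.csv``, ``scanner.csv``, ``power.csv`` and
    ``power_curve.csv`` under ``out_dir``.  With ``dry_run`` the
    configuration (and, for file input, the table schema) is validated and
    nothing is computed or written.  Deterministic: a fixed config and seed
    yield byte-identical outputs.
    """
    out_dir = Path(out_dir)
    if config.simulation is not None:
        sim = config.simulation.with_seed(config.seed)
        if dry_run:
            logger.info("dry run: simulation config valid (%d subjects)", sim.n_total)
            return {}
        table = simulate_cohort(sim)
        logger.info("simulated %d records for %d subjects", len(table), len(table.subjects))
    else:
        table = read_long_table(config.input_path)
        logger.info("read %d records from %s", len(table), config.input_path)
        if dry_run:
            return {}

    families = dict(config.families) or _default_families(table.measures)
    rel_parts, scan_parts = [], []
    for fam, (measures, c) in families.items():
        logger.info("family %s: %d measures, c=%d", fam, len(measures), c)
        rel = reliability_report(
            table, measures, bonferroni_c=c, cutoff=config.cutoff,
            alpha=config.alpha, alpha_sphericity=config.alpha_sphericity,
        )
        rel.insert(1, "family", fam)
        rel_parts.append(rel)
        scan = scanner_report(
            table, measures, bonferroni_c=c, alpha=config.alpha,
            alpha_sphericity=config.alpha_sphericity,
        )
        scan.insert(1, "family", fam)
        scan_parts.append(scan)
    reliability = pd.concat(rel_parts, ignore_index=True)
    scanner = pd.concat(scan_parts, ignore_index=True)
    power = power_report(
        reliability, delta=config.delta, alpha=config.alpha,
        target_power=config.target_power,
    )
    curve = power_curve(
        config.power_curve_deltas, config.power_curve_reliabilities,
        alpha=config.alpha, target_power=config.target_power,
    )
    outputs = {
        "reliability": reliability,
        "scanner": scanner,
        "power": power,
        "power_curve": curve,
    }
    for name, df in outputs.items():
        write_report_table(df, out_dir / f"{name}.csv")
        logger.info("wrote %s (%d rows)", out_dir / f"{name}.csv", len(df))
    return outputs


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from YAML.

    Recognised top-level keys: ``input`` (CSV path) *or* the simulation
    keys understood by :func:`~scanstab.cohort.load_simulation_config`;
    ``families`` (name -> {measures: [...], c: int}); ``cutoff``, ``alpha``,
    ``alpha_sphericity``, ``delta``, ``target_power``, ``seed``;
    ``power_curve`` ({deltas: [...], reliabilities: [...]}).
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    input_path = raw.get("input")
    simulation = None
    if input_path is None:
        simulation = (
            load_simulation_config(path)
            if ("measures" in raw or "design" in raw)
            else default_config(seed=int(raw.get("seed", 0)))
        )
    families = {
        str(fam): (list(spec.get("measures", [])), int(spec.get("c", len(spec.get("measures", [])))))
        for fam, spec in (raw.get("families") or {}).items()
    }
    curve = raw.get("power_curve") or {}
    kwargs = dict(
        simulation=simulation,
        input_path=input_path,
        families=families,
        cutoff=float(raw.get("cutoff", DEFAULT_CUTOFF)),
        alpha=float(raw.get("alpha", 0.05)),
        alpha_sphericity=float(raw.get("alpha_sphericity", 0.05)),
        delta=float(raw.get("delta", 0.75)),
        target_power=float(raw.get("target_power", 0.80)),
        seed=int(raw.get("seed", 0)),
    )
    if curve:
        kwargs["power_curve_deltas"] = tuple(float(x) for x in curve.get("deltas", (0.75,)))
        kwargs["power_curve_reliabilities"] = tuple(
            float(x) for x in curve.get("reliabilities", (0.68, 0.92, 1.0))
        )
    return PipelineConfig(**kwargs)
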