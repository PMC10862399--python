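"""Headline ratios and report assembly.

``derived_ratios`` computes the ratio-type headline figures — case fatality,
psychiatric share of all-cause cost, quality-of-life reductions from
QALY/life-year pairs, and the pandemic entrant fold — from whatever inputs
are supplied (a model run's summary, or published aggregate figures).
``build_report`` writes a scenario run to disk as CSV tables plus a JSON
summary with a configuration echo; rounding happens only at presentation.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .markov_engine import CohortTrace, summarise


class ReportingError(ValueError):
    pass


def _pct(numerator: float, denominator: float, name: str) -> float:
    if denominator == 0:
        raise ReportingError(f"zero denominator in ratio {name}")
    return 100.0 * numerator / denominator


def derived_ratios(
    *,
    deaths: float,
    entrants: float,
    cost_allcause: float,
    cost_psychiatric: float,
    qaly_ly: Mapping[str, tuple[float, float]],
    entrants_pandemic: float | None = None,
) -> dict:
    """Headline ratio figures, raw and at presentation rounding.

    ``qaly_ly`` maps attribution groups (e.g. ``all``, ``trd``,
    ``comorbid``) to (QALY, life-years) pairs; the quality-of-life reduction
    of a group is (1 - QALY/LY) x 100.
    """
    raw: dict[str, float] = {
        "case_fatality_pct": _pct(deaths, entrants, "case_fatality"),
        "psychiatric_share_pct": _pct(
            cost_psychiatric, cost_allcause, "psychiatric_share"
        ),
    }
    for group, (q, ly) in qaly_ly.items():
        if ly == 0:
            raise ReportingError(f"zero life-years for group {group!r}")
        raw[f"qol_reduction_{group}_pct"] = 100.0 * (1.0 - q / ly)
    if entrants_pandemic is not None:
        if entrants == 0:
            raise ReportingError("zero entrants in pandemic fold")
        raw["pandemic_fold"] = entrants_pandemic / entrants

    rounded = {}
    for key, value in raw.items():
        if key == "pandemic_fold":
            rounded[key] = round(value, 2)
        elif key == "psychiatric_share_pct":
            rounded[key] = round(value)  # shares printed as integer %
        else:
            rounded[key] = round(value, 1)
    return {"raw": raw, "rounded": rounded}


@dataclass
class BurdenReport:
    summary: dict
    annual_costs: pd.DataFrame
    subgroup_table: pd.DataFrame
    occupancy: pd.DataFrame

    def validate(self) -> None:
        """Subgroup tables must re-add to the run totals."""
        for col, key in (
            ("cost_allcause", "cumulative_cost_allcause"),
            ("cost_psychiatric", "cumulative_cost_psychiatric"),
            ("deaths", "cumulative_deaths"),
        ):
            total = float(self.subgroup_table[col].sum())
            if abs(total - self.summary[key]) > 1e-6 * max(1.0, abs(total)):
                raise ReportingError(f"subgroup totals disagree with summary for {col}")


def _software_fingerprint() -> dict:
    import scipy
    import statsmodels

    from . import __version__

    return {
        "trdburden": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }


def build_report(
    trace: CohortTrace,
    outdir: str | Path,
    config_echo: Mapping | None = None,
    seed: int | None = None,
) -> BurdenReport:
    """Persist one scenario run: annual cost table, 16-subgroup table,
    occupancy trace and a full-precision JSON summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    summary = summarise(trace)
    subgroups = summary.pop("subgroups")
    cycles = np.arange(1, trace.n_cycles + 1)
    annual = pd.DataFrame(
        {
            "cycle": trace.years if trace.years else cycles,
            "cost_allcause": trace.annual("cost_allcause"),
            "cost_psychiatric": trace.annual("cost_psychiatric"),
            "deaths": trace.annual("deaths"),
            "life_years": trace.annual("life_years"),
            "qalys": trace.annual("qalys"),
        }
    )
    occupancy = trace.to_frame()

    report = BurdenReport(
        summary=summary,
        annual_costs=annual,
        subgroup_table=subgroups,
        occupancy=occupancy,
    )
    report.validate()

    annual.to_csv(outdir / "annual_costs.csv", index=False)
    subgroups.to_csv(outdir / "subgroup_burden.csv", index=False)
    occupancy.to_csv(outdir / "occupancy.csv", index=False)
    doc = {
        "summary": summary,
        "ratios": derived_ratios(
            deaths=summary["cumulative_deaths"],
            entrants=summary["entrants"],
            cost_allcause=summary["cumulative_cost_allcause"],
            cost_psychiatric=summary["cumulative_cost_psychiatric"],
            qaly_ly={
                "all": (summary["qalys"], summary["life_years"]),
                "trd": (summary["qalys_trd"], summary["life_years_trd"]),
                "comorbid": (summary["qalys_comorbid"], summary["life_years_comorbid"]),
            },
        ),
        "config": dict(config_echo) if config_echo else {},
        "seed": seed,
        "software": _software_fingerprint(),
    }
    (outdir / "summary.json").write_text(json.dumps(doc, indent=2, sort_keys=True))
    return report
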