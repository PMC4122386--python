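"""Report rendering in the published table layouts.

Engine outputs stay at full precision inside the returned DataFrames
("Sum" rows are recomputed from sub-rows); rounding — event counts to two
decimals, costs to whole euros — happens only in the formatting helpers.
ICERs are always computed from unrounded internals, which is why an ICER
can differ from the ratio of its rounded display cells.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import EventTally
from .econ import ArmOutcome, CEResult
from .params import ModelParameters, config_hash
from .uncertainty import PsaResult, ScenarioResult, TornadoEntry, ceac

_STROKE_SECTIONS = [
    ("IS", "is", False),
    ("Recurrent IS", "is", True),
    ("HS", "hs", False),
    ("Recurrent HS", "hs", True),
]
_SEVERITY_ROWS = [("mild", "Mild, non-fatal"), ("moderate", "Moderate, non-fatal"), ("severe", "Severe, non-fatal")]


def _acute(breakdown: dict, label: str) -> float:
    return breakdown["acute"].get(label, 0.0)


def render_event_cost_table(tally: EventTally, breakdown: dict) -> pd.DataFrame:
    """Event counts and per-patient lifetime costs for one arm, shaped like
    the published complication table."""
    rows: list[dict] = []

    def add(section: str, row: str, events: float, acute: float, long_term: Optional[float] = None):
        rows.append({"section": section, "row": row, "events": events,
                     "acute_cost_pp": acute, "long_term_cost_pp": long_term})

    lt = breakdown["long_term"]
    for section, ev, rec in _STROKE_SECTIONS:
        total_ev = total_cost = 0.0
        for sev, label in _SEVERITY_ROWS:
            n = tally.count(ev, subtype=sev, fatal=False, recurrent=rec)
            key = f"{ev}:{sev}:nonfatal" + (":recurrent" if rec else "")
            cost = _acute(breakdown, key)
            lt_key = f"{ev}_{sev}" + ("_recurrent" if rec else "")
            add(section, label, n, cost, lt.get(lt_key, 0.0))
            total_ev += n
            total_cost += cost
        n_f = tally.count(ev, fatal=True, recurrent=rec)
        c_f = _acute(breakdown, f"{ev}:fatal" + (":recurrent" if rec else ""))
        add(section, "Fatal", n_f, c_f)
        add(section, "Sum", total_ev + n_f, total_cost + c_f)

    for section, ev in (("SE", "se"), ("Other ICH", "other_ich")):
        n_nf = tally.count(ev, fatal=False)
        n_f = tally.count(ev, fatal=True)
        c_nf = _acute(breakdown, f"{ev}:nonfatal")
        c_f = _acute(breakdown, f"{ev}:fatal")
        add(section, "Non-fatal", n_nf, c_nf)
        add(section, "Fatal", n_f, c_f)
        add(section, "Sum", n_nf + n_f, c_nf + c_f)

    n_gi = tally.count("other_mb", subtype="gi")
    n_ngi = tally.count("other_mb", subtype="non_gi")
    n_mbf = tally.count("other_mb", fatal=True)
    c_gi = _acute(breakdown, "other_mb:gi:nonfatal")
    c_ngi = _acute(breakdown, "other_mb:non_gi:nonfatal")
    c_mbf = _acute(breakdown, "other_mb:fatal")
    add("Other MBs", "Non-fatal GI bleedings", n_gi, c_gi)
    add("Other MBs", "Non-fatal non-GI MBs", n_ngi, c_ngi)
    add("Other MBs", "Fatal", n_mbf, c_mbf)
    add("Other MBs", "Sum", n_gi + n_ngi + n_mbf, c_gi + c_ngi + c_mbf)

    add("CRNM bleeding", "All", tally.count("crnm"), _acute(breakdown, "crnm:nonfatal") + _acute(breakdown, "crnm:fatal"))

    n_mi = tally.count("mi", fatal=False)
    n_mif = tally.count("mi", fatal=True)
    add("MI", "Non-fatal", n_mi, _acute(breakdown, "mi:nonfatal"), lt.get("mi", 0.0))
    add("MI", "Fatal", n_mif, _acute(breakdown, "mi:fatal"))
    add("MI", "Sum", n_mi + n_mif, _acute(breakdown, "mi:nonfatal") + _acute(breakdown, "mi:fatal"))

    add("Other treatment discontinuation", "All", tally.count("discontinuation"), 0.0)
    add("Treatment", "Cost of anticoagulants", np.nan, breakdown["drug"])
    add("Treatment", "Cost of routine care", np.nan, breakdown["routine_care"])
    add("Treatment", "Cost of INR monitoring", np.nan, breakdown["inr_monitoring"])
    add("Treatment", "Total costs", np.nan, breakdown["total"])
    return pd.DataFrame(rows)


def format_event_cost_table(df: pd.DataFrame) -> str:
    """Display formatting: counts with two decimals, costs as whole euros."""
    out = df.copy()
    out["events"] = out["events"].map(lambda v: "" if pd.isna(v) else f"{v:.2f}")
    for col in ("acute_cost_pp", "long_term_cost_pp"):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.0f}")
    return out.to_string(index=False)


def render_ce_summary(result: CEResult, params: Optional[ModelParameters] = None,
                      seed: Optional[int] = None) -> pd.DataFrame:
    """Per-arm totals, incrementals, ICERs and dominance label."""
    ref, comp = result.reference, result.comparator
    df = pd.DataFrame(
        [
            {"treatment": comp.arm.value, "cost": comp.cost_total, "qalys": comp.qalys, "lys": comp.lys,
             "delta_cost": np.nan, "delta_qaly": np.nan, "delta_ly": np.nan,
             "icer_per_qaly": np.nan, "icer_per_ly": np.nan, "label": ""},
            {"treatment": ref.arm.value, "cost": ref.cost_total, "qalys": ref.qalys, "lys": ref.lys,
             "delta_cost": result.delta_cost, "delta_qaly": result.delta_qalys, "delta_ly": result.delta_lys,
             "icer_per_qaly": result.icer_per_qaly if result.icer_per_qaly is not None else np.nan,
             "icer_per_ly": result.icer_per_ly if result.icer_per_ly is not None else np.nan,
             "label": result.label},
        ]
    )
    df.attrs["seed"] = seed
    if params is not None:
        df.attrs["config_hash"] = config_hash(params)
    return df


def format_ce_summary(df: pd.DataFrame) -> str:
    out = df.copy()
    for col in ("cost", "delta_cost", "icer_per_qaly", "icer_per_ly"):
        out[col] = out[col].map(lambda v: "-" if pd.isna(v) else f"{v:.0f}")
    for col in ("qalys", "lys", "delta_qaly", "delta_ly"):
        out[col] = out[col].map(lambda v: "-" if pd.isna(v) else f"{v:.2f}")
    text = out.to_string(index=False)
    footer = []
    if df.attrs.get("seed") is not None:
        footer.append(f"seed={df.attrs['seed']}")
    if df.attrs.get("config_hash"):
        footer.append(f"config_hash={df.attrs['config_hash']}")
    if footer:
        text += "\n# " + " ".join(footer)
    return text


def render_scenario_grid(results: Sequence[ScenarioResult]) -> pd.DataFrame:
    """Scenario grid: adjusted rates, per-arm totals, incrementals, ICERs."""
    rows = []
    for sc in results:
        res = sc.result
        for arm_outcome, is_ref in ((res.comparator, False), (res.reference, True)):
            th = arm_outcome.arm.value
            adj = sc.adjusted_rates.get(th, {})
            row = {
                "scenario": sc.scenario,
                "treatment": th,
                "is_rate": adj.get("ischemic_stroke", np.nan),
                "ich_rate": adj.get("ich", np.nan),
                "other_mb_rate": adj.get("other_mb", np.nan),
                "crnm_rate": adj.get("crnm", np.nan),
                "cost": arm_outcome.cost_total,
                "qalys": arm_outcome.qalys,
                "lys": arm_outcome.lys,
            }
            if is_ref:
                row.update(
                    delta_cost=res.delta_cost,
                    delta_qaly=res.delta_qalys,
                    delta_ly=res.delta_lys,
                    icer_per_qaly=res.icer_per_qaly if res.icer_per_qaly is not None else np.nan,
                    icer_per_ly=res.icer_per_ly if res.icer_per_ly is not None else np.nan,
                )
            else:
                row.update(delta_cost=np.nan, delta_qaly=np.nan, delta_ly=np.nan,
                           icer_per_qaly=np.nan, icer_per_ly=np.nan)
            rows.append(row)
    return pd.DataFrame(rows)


def render_tornado(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"parameter": e.parameter, "low": e.low, "high": e.high,
             "icer_low": e.icer_low if e.icer_low is not None else np.nan,
             "icer_high": e.icer_high if e.icer_high is not None else np.nan}
            for e in entries
        ]
    )


def render_ceac(psa: PsaResult, wtp_grid: Sequence[float]) -> pd.DataFrame:
    probs = ceac(psa, wtp_grid)
    return pd.DataFrame({"wtp": list(wtp_grid), "probability_cost_effective": probs})


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Comma-separated, UTF-8, '.' decimal; stable column order."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def plot_ce_plane(psa: PsaResult, path: str | Path, wtp: Sequence[float] = (20000.0, 30000.0)) -> None:
    """Scatter of incremental (QALY, cost) draws with WTP rays."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(psa.delta_qalys, psa.delta_costs, s=6, alpha=0.4)
    xs = np.linspace(min(0, psa.delta_qalys.min()), max(0, psa.delta_qalys.max()), 50)
    for lam, style in zip(wtp, ("--", "-")):
        ax.plot(xs, lam * xs, style, color="grey", lw=1, label=f"WTP {lam:,.0f}/QALY")
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(psa: PsaResult, path: str | Path, wtp_max: float = 50000.0) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = np.linspace(0.0, wtp_max, 101)
    probs = ceac(psa, grid)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(grid, probs, label="apixaban")
    ax.plot(grid, 1.0 - probs, label="VKA")
    ax.set_xlabel("Willingness to pay (per QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
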