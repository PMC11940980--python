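"""End-to-end orchestration: cohort -> LOT -> outcomes -> HCRU/costs.

``run_all`` executes every stage on a dataset and returns a bundle of
result tables shaped like the analysis deliverables: the selection
(attrition) cascade, baseline characteristics, the first-line category
distribution, censored duration and TTNT summaries, and PPPM
utilization/cost tables.  Given the same input and configuration the
bundle is byte-identical on rerun; the manifest records row counts per
stage and a hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import hcru as hcru_mod
from . import lot as lot_mod
from . import outcomes as outcomes_mod
from .config import AnalysisConfig
from .dataset import ClaimsDataset, read_dataset


def config_hash(config: AnalysisConfig) -> str:
    payload = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_all(data: ClaimsDataset | str | Path,
            config: AnalysisConfig | None = None) -> dict:
    """Run the full pipeline; returns a dict of result tables."""
    config = config or AnalysisConfig()
    if isinstance(data, ClaimsDataset):
        ds, rejections = data, None
    else:
        ds, rejections = read_dataset(data, config)

    cohort, attrition = cohort_mod.build_cohort(ds, config)
    baseline = cohort_mod.baseline_table(ds, cohort, config)
    lots = lot_mod.derive_all_lots(ds, cohort, config)
    bounds = lot_mod.followup_bounds(ds, cohort, config)

    durations = outcomes_mod.duration_table(lots)
    ttnt = outcomes_mod.ttnt_table(lots)
    periods = outcomes_mod.sact_period_table(lots, bounds, config)
    curves = outcomes_mod.km_by_category(durations) if len(durations) \
        else {}
    km_frame = outcomes_mod.km_curve_frame(curves)
    pppm = hcru_mod.patient_pppm_table(ds, periods, config) \
        if len(periods) else pd.DataFrame()
    summary = hcru_mod.summarize(pppm, config) if len(pppm) \
        else pd.DataFrame()

    l1 = lots[lots["lot_number"] == 1]
    dist = l1["category"].value_counts().rename_axis("category") \
        .reset_index(name="n")
    dist["pct"] = 100.0 * dist["n"] / max(1, len(l1))

    manifest = {
        "config_hash": config_hash(config),
        "rows": {
            "patients": int(ds.n_patients),
            "medical_claims": int(len(ds.medical_claims)),
            "pharmacy_claims": int(len(ds.pharmacy_claims)),
            "cohort": int(len(cohort)),
            "eligible": int(cohort["eligible"].sum()),
            "lot_segments": int(len(lots)),
            "durations": int(len(durations)),
            "ttnt": int(len(ttnt)),
        },
        "rejected_rows": (rejections.total if rejections else 0),
    }

    return {
        "cohort": cohort, "attrition": attrition.to_frame(),
        "baseline": baseline, "lots": lots, "durations": durations,
        "ttnt": ttnt, "sact_periods": periods, "km_curves": km_frame,
        "pppm": pppm, "hcru_summary": summary,
        "category_distribution": dist, "manifest": manifest,
        "_km_objects": curves,
    }


def headline_stats(bundle: dict, config: AnalysisConfig | None = None,
                   ) -> dict:
    """The pooled scalar results of a run, in reporting units."""
    config = config or AnalysisConfig()
    mld = config.month_length_days
    cohort = bundle["cohort"]
    elig = cohort[cohort["eligible"]]
    curves = bundle.get("_km_objects", {})
    km_med = curves["ALL"].median_months(mld) if "ALL" in curves else None
    ttnt = bundle["ttnt"]
    pppm = bundle["pppm"]
    dist = bundle["category_distribution"].set_index("category")

    out = {
        "n_eligible": int(len(elig)),
        "mean_index_age_years": float(elig["index_age"].mean())
        if len(elig) else float("nan"),
        "km_median_1l_duration_months": km_med,
        "mean_ttnt_months": float(ttnt["ttnt_days"].mean() / mld)
        if len(ttnt) else float("nan"),
        "share_ici_pbct_pct": float(dist.loc["ICI_PBCT", "pct"])
        if "ICI_PBCT" in dist.index else 0.0,
    }
    if len(pppm):
        out.update({
            "outpatient_visits_pppm": float(
                pppm["visits_outpatient"].mean()),
            "inpatient_admissions_pppm": float(
                pppm["adm_inpatient"].mean()),
            "ed_visits_pppm": float(pppm["visits_ed"].mean()),
            "total_cost_pppm_usd2022": float(pppm["cost_total"].mean()),
            "outpatient_cost_pppm_usd2022": float(
                pppm["cost_outpatient"].mean()),
        })
    return out


def write_bundle(bundle: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, obj in bundle.items():
        if name.startswith("_"):
            continue
        if isinstance(obj, pd.DataFrame):
            df = obj.copy()
            for col in df.columns:
                if pd.api.types.is_datetime64_any_dtype(df[col]):
                    df[col] = df[col].dt.strftime("%Y-%m-%d")
            df.to_csv(out / f"{name}.csv", index=False)
        else:
            (out / f"{name}.json").write_text(
                json.dumps(obj, indent=2, sort_keys=True))


def render_tables(bundle: dict, config: AnalysisConfig | None = None,
                  ) -> str:
    """Plain-text report: selection cascade, baseline, categories,
    duration/TTNT, and pooled PPPM results (percentages to 1 decimal)."""
    config = config or AnalysisConfig()
    lines: list[str] = []
    att = bundle["attrition"]
    lines.append("Selection of study population")
    for _, r in att.iterrows():
        lines.append(f"  {r['label']}: {r['remaining']}")

    cohort = bundle["cohort"]
    elig = cohort[cohort["eligible"]]
    n = max(1, len(elig))
    lines.append("")
    lines.append(f"Baseline characteristics (n = {len(elig)})")
    if len(elig):
        lines.append(f"  Age at index, mean: "
                     f"{elig['index_age'].mean():.1f} years")
    base = bundle["baseline"]
    order = ["hypertension", "copd", "coronary_heart_disease", "anemia",
             "diabetes", "chronic_kidney_disease",
             "chronic_liver_disease", "dementia",
             "cerebrovascular_disease"]
    for name in order:
        if name in base.columns:
            lines.append(f"  {name}: {100.0 * base[name].mean():.1f}%")
    if "nci_cci" in base.columns and len(base):
        lines.append(f"  NCI-CCI, mean (SD): {base['nci_cci'].mean():.1f}"
                     f" ({base['nci_cci'].std(ddof=1):.1f})")

    lines.append("")
    lines.append("First-line treatment distribution")
    for _, r in bundle["category_distribution"].iterrows():
        lines.append(f"  {r['category']}: {r['n']} ({r['pct']:.1f}%)")

    stats = headline_stats(bundle, config)
    lines.append("")
    lines.append("Outcomes and PPPM burden (pooled)")
    for key, val in stats.items():
        if val is None:
            continue
        lines.append(f"  {key}: "
                     f"{val:.2f}" if isinstance(val, float)
                     else f"  {key}: {val}")
    return "\n".join(lines) + "\n"
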