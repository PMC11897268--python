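"""Report writers: results tables, comparison files, tornado CSV.

CSV files hold full precision; the human-readable table rounds to whole
euros for costs and one decimal for percentages.  The comparison file puts
computed values next to the packaged reference values with their absolute
differences — discrepancies are reported, never patched.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from .cohort import ArmEvaluation
from .parameters import ARMS, load_reference_results
from .psa import PSAResult
from .sensitivity import TornadoRow


def _eur(x: float) -> str:
    return f"€{x:,.0f}"


def write_results_table(
    results: Mapping[int, dict],
    out_dir: str | Path,
    reference: dict | None = None,
) -> dict[str, Path]:
    """Write results.csv, results.txt and comparison.csv for the analyses in
    ``results``.

    ``results[analysis_id]`` maps ``"deterministic"`` to a dict of
    :class:`ArmEvaluation` per arm and optionally ``"psa"`` to a
    :class:`PSAResult`; missing PSA results leave the probabilistic columns
    empty.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reference = reference or load_reference_results()

    rows = []
    for aid, res in sorted(results.items()):
        det: dict[str, ArmEvaluation] = res["deterministic"]
        psa: PSAResult | None = res.get("psa")
        for arm in ARMS:
            row: dict = {
                "analysis": aid,
                "arm": arm,
                "deterministic_cost": det[arm].expected_cost,
            }
            if psa is not None:
                s = psa.per_arm[arm]
                row.update(
                    psa_mean=s["mean"], psa_sd=s["sd"],
                    psa_ci95_low=s["ci95_low"], psa_ci95_high=s["ci95_high"],
                    p_optimal=(psa.p_saving_with_tdm if arm == "with_tdm"
                               else psa.p_saving_without_tdm),
                )
            rows.append(row)
        row = {
            "analysis": aid,
            "arm": "incremental",
            "deterministic_cost": det["with_tdm"].expected_cost - det["without_tdm"].expected_cost,
        }
        if psa is not None:
            row.update(psa_mean=psa.incremental["mean"], psa_sd=psa.incremental["se"])
        rows.append(row)
    frame = pd.DataFrame(rows)
    csv_path = out_dir / "results.csv"
    frame.to_csv(csv_path, index=False)

    txt_path = out_dir / "results.txt"
    with open(txt_path, "w") as fh:
        fh.write("Cost analysis results (EUR 2024, per patient)\n")
        for aid, res in sorted(results.items()):
            det = res["deterministic"]
            psa = res.get("psa")
            fh.write(f"\nAnalysis {aid}\n")
            for arm in ARMS:
                line = f"  {arm:<12} deterministic {_eur(det[arm].expected_cost):>9}"
                if psa is not None:
                    s = psa.per_arm[arm]
                    p = psa.p_saving_with_tdm if arm == "with_tdm" else psa.p_saving_without_tdm
                    line += (f"  PSA {_eur(s['mean'])} ± {_eur(s['sd'])}"
                             f" ({_eur(s['ci95_low'])}; {_eur(s['ci95_high'])})"
                             f"  optimal {100 * p:.1f}%")
                fh.write(line + "\n")
            inc = det["with_tdm"].expected_cost - det["without_tdm"].expected_cost
            line = f"  {'incremental':<12} deterministic {_eur(inc):>9}"
            if psa is not None:
                line += (f"  PSA {_eur(psa.incremental['mean'])}"
                         f" ± {_eur(psa.incremental['se'])}")
            fh.write(line + "\n")

    comp_rows = []
    for aid, res in sorted(results.items()):
        det = res["deterministic"]
        psa = res.get("psa")
        ref_det = reference["deterministic"][str(aid)]
        for arm in ARMS:
            comp_rows.append(_comp_row(aid, f"deterministic:{arm}",
                                       det[arm].expected_cost, ref_det[arm]))
        inc = det["with_tdm"].expected_cost - det["without_tdm"].expected_cost
        comp_rows.append(_comp_row(aid, "deterministic:incremental", inc, ref_det["incremental"]))
        if psa is not None:
            ref_psa = reference["psa"][str(aid)]
            for arm in ARMS:
                for key in ("mean", "sd"):
                    comp_rows.append(_comp_row(aid, f"psa:{arm}:{key}",
                                               psa.per_arm[arm][key], ref_psa[arm][key]))
                for key, refkey in (("ci95_low", 0), ("ci95_high", 1)):
                    comp_rows.append(_comp_row(aid, f"psa:{arm}:{key}",
                                               psa.per_arm[arm][key], ref_psa[arm]["ci95"][refkey]))
            note = ("reference CI bounds printed inverted"
                    if ref_psa["incremental"].get("ci95_printed_inverted") else "")
            comp_rows.append(_comp_row(aid, "psa:incremental:mean",
                                       psa.incremental["mean"],
                                       ref_psa["incremental"]["mean"], note))
            comp_rows.append(_comp_row(aid, "psa:incremental:se",
                                       psa.incremental["se"], ref_psa["incremental"]["se"]))
            comp_rows.append(_comp_row(aid, "psa:p_saving_with_tdm",
                                       100 * psa.p_saving_with_tdm,
                                       ref_psa["p_saving_with_tdm"]))
    comp_path = out_dir / "comparison.csv"
    pd.DataFrame(comp_rows).to_csv(comp_path, index=False)
    return {"results_csv": csv_path, "results_txt": txt_path, "comparison_csv": comp_path}


def _comp_row(aid: int, cell: str, computed: float, reference: float, note: str = "") -> dict:
    return {
        "analysis": aid,
        "cell": cell,
        "computed": computed,
        "reference": reference,
        "abs_difference": abs(computed - reference),
        "note": note,
    }


def write_tornado_csv(rows: list[TornadoRow], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {
                "variable_code": r.variable_code,
                "low_value": r.low_value,
                "base_value": r.base_value,
                "high_value": r.high_value,
                "incremental_at_low": r.incremental_at_low,
                "incremental_at_high": r.incremental_at_high,
                "span": r.span,
            }
            for r in rows
        ]
    ).to_csv(path, index=False)
    return path


def write_psa_outputs(result: PSAResult, out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    iter_path = out_dir / "iterations.csv"
    result.iteration_costs.to_csv(iter_path, index=False)
    summary_path = out_dir / "psa_summary.json"
    with open(summary_path, "w") as fh:
        json.dump(result.to_summary_dict(), fh, indent=1)
        fh.write("\n")
    return {"iterations_csv": iter_path, "summary_json": summary_path}
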