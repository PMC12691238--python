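"""End-to-end analysis: simulate/load -> estimate -> summarize -> agree -> diagnose.

``run_pipeline`` is a pure function of (input, rule, config, seed) apart
from the report timestamp.  It produces a :class:`RunReport` holding the
cohort summary tables, the three pairwise Bland-Altman blocks, the
difference-vs-age trends for the two calculated methods, and the two
diagnostic-concordance blocks, and can write the report as JSON plus a
human-readable text rendering (mg/dL values rounded to 2 decimals,
proportions to 3, full precision kept internally).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import __version__
from .agreement import bland_altman, difference_trend
from .diagnostics import DyslipidemiaRule, evaluate_method
from .io import read_cohort, write_cohort
from .lipids import LdlMethod, LipidPanel, friedewald_ldl, sampson_ldl
from .simulate import CohortConfig, generate
from .summaries import chi_square_2x2, lipid_table, rank_sum_test, summarize

logger = logging.getLogger(__name__)

__all__ = ["RunReport", "run_pipeline"]

_PAIRS = [
    ("direct_vs_friedewald", LdlMethod.DIRECT, LdlMethod.FRIEDEWALD),
    ("direct_vs_sampson", LdlMethod.DIRECT, LdlMethod.SAMPSON),
    ("friedewald_vs_sampson", LdlMethod.FRIEDEWALD, LdlMethod.SAMPSON),
]


@dataclass
class RunReport:
    """Aggregated pipeline output; every block is present or marked skipped."""

    tables: dict
    agreements: dict
    trends: dict
    diagnostics: dict
    excluded_count: Optional[int]
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "tables": self.tables,
            "agreements": self.agreements,
            "trends": self.trends,
            "diagnostics": self.diagnostics,
            "excluded_count": self.excluded_count,
            "provenance": self.provenance,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(_rounded(self.to_dict()), **{"indent": 2, **kwargs})

    def to_text(self) -> str:
        lines = [f"pedlipid run report (v{self.provenance.get('version', '?')})", ""]
        lines.append("== Cohort summaries ==")
        for name, table in self.tables.items():
            lines.append(f"-- {name} --")
            if isinstance(table, str):
                lines.append(table)
            else:
                lines.append(pd.DataFrame(table).round(3).to_string(index=False))
            lines.append("")
        lines.append("== Method agreement (Bland-Altman, a - b) ==")
        for name, block in self.agreements.items():
            if isinstance(block, str):
                lines.append(f"{name}: {block}")
                continue
            lines.append(
                f"{name}: n={block['n']}  bias={block['bias']:.2f} "
                f"(95% CI {block['bias_ci95'][0]:.2f} to {block['bias_ci95'][1]:.2f})  "
                f"LoA [{block['loa_low']:.2f}, {block['loa_high']:.2f}]  "
                f"range={block['loa_range']:.2f}  "
                f"bias%range={block['bias_pct_of_range']:.2f}%"
            )
        lines.append("")
        lines.append("== Difference-vs-age trends (mg/dL per year) ==")
        for name, block in self.trends.items():
            if isinstance(block, str):
                lines.append(f"{name}: {block}")
                continue
            lines.append(
                f"{name}: slope={block['slope']:.3f} "
                f"(95% CI {block['slope_ci95'][0]:.3f} to {block['slope_ci95'][1]:.3f}) "
                f"at centering age {block['centering_age']:.0f}"
            )
        lines.append("")
        lines.append("== Dyslipidemia diagnostics vs direct method ==")
        if self.excluded_count is not None:
            lines.append(f"(excluded outside rule age window: {self.excluded_count})")
        for name, block in self.diagnostics.items():
            if isinstance(block, str):
                lines.append(f"{name}: {block}")
                continue
            cm = block["confusion"]
            rep = block["report"]
            lines.append(f"-- {name} --")
            lines.append(
                f"  tp={cm['tp']} fp={cm['fp']} fn={cm['fn']} tn={cm['tn']}"
            )
            lines.append(
                f"  accuracy={rep['accuracy']:.3f} "
                f"({rep['accuracy_ci95'][0]:.3f}-{rep['accuracy_ci95'][1]:.3f})  "
                f"kappa={rep['kappa']:.3f}  sens={rep['sensitivity']:.3f}  "
                f"spec={rep['specificity']:.3f}  ppv={rep['ppv']:.3f}  npv={rep['npv']:.3f}"
            )
            lines.append(
                f"  balanced_acc={rep['balanced_accuracy']:.3f}  "
                f"mcnemar_p={rep['mcnemar_p']:.2e}  p_acc_gt_nir={rep['p_accuracy_gt_nir']:.2e}"
            )
        return "\n".join(lines) + "\n"


def _rounded(obj, mgdl_decimals: int = 2, prop_decimals: int = 3):
    """Round floats for serialization: proportion-scale to 3, mg/dL-scale to 2."""
    if isinstance(obj, dict):
        return {k: _rounded(v, mgdl_decimals, prop_decimals) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_rounded(v, mgdl_decimals, prop_decimals) for v in obj]
    if isinstance(obj, float):
        nd = prop_decimals if abs(obj) <= 1.0 else mgdl_decimals
        return round(obj, max(nd, 6) if abs(obj) < 1e-3 else nd)
    return obj


def _table1(panels: list[LipidPanel]) -> dict:
    """Age summary overall and by sex, plus the sex x age-group chi-square."""
    ages = [p.age_years for p in panels]
    by_sex = {
        s: [p.age_years for p in panels if p.sex.value == s] for s in ("boy", "girl")
    }
    out = {
        "age_overall": dataclasses.asdict(summarize(ages)),
    }
    counts = {}
    for s, vals in by_sex.items():
        if vals:
            out[f"age_{s}"] = dataclasses.asdict(summarize(vals))
            counts[s] = (
                sum(1 for v in vals if v < 13),
                sum(1 for v in vals if v >= 13),
            )
    if len(counts) == 2 and all(min(c) > 0 for c in counts.values()):
        table = [list(counts["girl"]), list(counts["boy"])]
        stat, p = chi_square_2x2(table)
        out["sex_by_age_group"] = {"table_girl_boy_x_lt13_ge13": table, "chi2": stat, "p": p}
        _, p_age = rank_sum_test(by_sex["boy"], by_sex["girl"])
        out["age_by_sex_ranksum_p"] = p_age
    return out


def run_pipeline(
    source: Union[str, Path, CohortConfig, list],
    rule: DyslipidemiaRule = DyslipidemiaRule(),
    output_dir: Optional[Union[str, Path]] = None,
    seed: Optional[int] = None,
) -> RunReport:
    """Run the full analysis over a cohort CSV, a generator config, or panels.

    Agreement blocks use only panels where both methods in the pair are
    valid; diagnostics follow :func:`pedlipid.diagnostics.evaluate_method`.
    When ``output_dir`` is given, writes ``report.json``, ``report.txt``,
    the cohort CSV (if simulated), and per-pair (mean, difference) CSVs for
    external Bland-Altman plotting.
    """
    provenance: dict = {
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
    }
    if isinstance(source, CohortConfig):
        if seed is not None:
            source = source.replace(seed=seed)
        panels = generate(source)
        cfg_json = json.dumps(source.to_dict(), sort_keys=True)
        provenance["config_sha256"] = hashlib.sha256(cfg_json.encode()).hexdigest()
        provenance["source"] = "simulated"
        provenance["seed"] = source.seed
        simulated_config = source
    elif isinstance(source, (str, Path)):
        panels = read_cohort(source)
        provenance["config_sha256"] = hashlib.sha256(
            Path(source).read_bytes()
        ).hexdigest()
        provenance["source"] = str(source)
        simulated_config = None
    else:
        panels = list(source)
        provenance["source"] = "in-memory panels"
        provenance["config_sha256"] = None
        simulated_config = None

    if not panels:
        raise ValueError("cohort contains no panels")

    has_direct = all(p.ldl_direct is not None for p in panels)
    if not has_direct:
        logger.warning(
            "cohort lacks direct LDL for %d panel(s): direct-method agreement "
            "and diagnostics skipped",
            sum(1 for p in panels if p.ldl_direct is None),
        )

    # --- estimates per panel (invalid ones carried with their flags) ---
    ests = {
        LdlMethod.FRIEDEWALD: [friedewald_ldl(p.tc, p.hdl, p.tg) for p in panels],
        LdlMethod.SAMPSON: [sampson_ldl(p.tc, p.hdl, p.tg) for p in panels],
    }
    n_invalid_friedewald = sum(1 for e in ests[LdlMethod.FRIEDEWALD] if not e.valid)
    if n_invalid_friedewald:
        logger.info("%d panel(s) with invalid Friedewald estimates", n_invalid_friedewald)

    # --- summary tables ---
    tables: dict = {"table1_age_by_sex": _table1(panels)}
    try:
        tables["table2_lipids_by_sex"] = lipid_table(panels, "sex").to_dict("records")
        tables["table3_lipids_by_age"] = lipid_table(panels, "age_lt_13").to_dict("records")
    except ValueError as exc:
        tables["table2_lipids_by_sex"] = f"skipped: {exc}"
        tables["table3_lipids_by_age"] = f"skipped: {exc}"

    # --- pairwise agreement on jointly valid panels ---
    # nonpositive calculated values stay in (they are returned unclipped
    # precisely so difference analyses stay unbiased); only TG-domain
    # violations disqualify a pair
    def series_for(method: LdlMethod, i: int) -> Optional[float]:
        if method is LdlMethod.DIRECT:
            return panels[i].ldl_direct
        e = ests[method][i]
        return e.value if (e.valid or e.reason == "nonpositive") else None

    agreements: dict = {}
    trends: dict = {}
    pair_data: dict = {}
    for name, ma, mb in _PAIRS:
        a, b, age = [], [], []
        for i in range(len(panels)):
            va, vb = series_for(ma, i), series_for(mb, i)
            if va is not None and vb is not None:
                a.append(va)
                b.append(vb)
                age.append(panels[i].age_years)
        if len(a) < 2:
            agreements[name] = "skipped: fewer than 2 jointly valid pairs"
            continue
        ba = bland_altman(a, b)
        agreements[name] = ba.to_dict()
        pair_data[name] = (a, b)
        if ma is LdlMethod.DIRECT and len(a) >= 3 and len(set(age)) > 1:
            trends[name] = difference_trend(
                [x - y for x, y in zip(a, b)], age
            ).to_dict()

    # --- diagnostics ---
    diagnostics: dict = {}
    excluded_count: Optional[int] = None
    if has_direct:
        for method in (LdlMethod.FRIEDEWALD, LdlMethod.SAMPSON):
            cm, rep, excluded = evaluate_method(panels, method, rule)
            diagnostics[method.value] = {
                "confusion": dataclasses.asdict(cm),
                "report": rep.to_dict(),
            }
            excluded_count = excluded
    else:
        diagnostics["friedewald"] = "skipped: no direct LDL reference"
        diagnostics["sampson"] = "skipped: no direct LDL reference"

    report = RunReport(
        tables=tables,
        agreements=agreements,
        trends=trends,
        diagnostics=diagnostics,
        excluded_count=excluded_count,
        provenance=provenance,
    )

    if output_dir is not None:
        outdir = Path(output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(report.to_json() + "\n", encoding="utf-8")
        (outdir / "report.txt").write_text(report.to_text(), encoding="utf-8")
        if simulated_config is not None:
            write_cohort(panels, outdir / "cohort.csv")
            simulated_config.to_file(outdir / "cohort_config.json")
        for name, (a, b) in pair_data.items():
            pd.DataFrame(
                {
                    "mean": [(x + y) / 2 for x, y in zip(a, b)],
                    "difference": [x - y for x, y in zip(a, b)],
                }
            ).to_csv(outdir / f"ba_pairs_{name}.csv", index=False)
    return report
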