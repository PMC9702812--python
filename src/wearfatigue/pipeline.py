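"""End-to-end orchestration: simulate -> clean -> quality -> features/L5
-> associate -> hrr -> report.

A single validated configuration drives every stage; all study
thresholds (accepted ranges, contextual thresholds and windows, the
100-step / 80%-lying L5 rule, the 70% coverage gate, the 6-min /
60 steps-per-min / 3-s walk rules, alpha) live here with their default
values.  Every output directory carries the configuration hash so a
rerun with identical config and inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import pathlib
from typing import Dict, List, Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import association, hrr, preprocessing, quality, synthetic, windows
from .core import HR, RR_INTERVAL, ParticipantBundle


class CohortParams(BaseModel):
    n_healthy: int = Field(3, ge=0)
    n_ndd: int = Field(3, ge=0)
    n_imid: int = Field(3, ge=0)
    days_per_participant: int = Field(5, ge=1)
    wear_gap_rate: float = Field(0.1, ge=0.0, le=0.375)
    fatigue_effect_beta: float = 3.0
    pro_dropout: float = Field(0.1, ge=0.0, le=1.0)
    pro_noise_sd: float = Field(0.7, ge=0.0)
    sleep_shift_error_rate: float = Field(0.05, ge=0.0, le=1.0)


class PipelineConfig(BaseModel):
    """Schema-validated configuration of the full pipeline run."""

    seed: int = 0
    out_dir: str = "wearfatigue_out"
    input_dir: Optional[str] = None  # None -> simulate
    variant: Literal["a", "b"] = "b"
    alpha: float = Field(0.05, gt=0.0, lt=1.0)
    coverage_min: float = Field(0.70, ge=0.0, le=1.0)
    hrr_definition: Literal["max_minus_min", "onset_minus_min"] = "max_minus_min"
    timezone: str = "UTC"
    cohort: CohortParams = Field(default_factory=CohortParams)
    write_raw: bool = False

    def config_hash(self) -> str:
        """Hash of the analysis-relevant parameters (paths excluded)."""
        payload = self.model_dump(exclude={"out_dir", "input_dir", "write_raw"})
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})


def _cohort_config(cfg: PipelineConfig) -> synthetic.CohortConfig:
    c = cfg.cohort
    return synthetic.CohortConfig(
        n_healthy=c.n_healthy,
        n_ndd=c.n_ndd,
        n_imid=c.n_imid,
        days_per_participant=c.days_per_participant,
        seed=cfg.seed,
        wear_gap_rate=c.wear_gap_rate,
        fatigue_effect_beta=c.fatigue_effect_beta,
        pro_dropout=c.pro_dropout,
        pro_noise_sd=c.pro_noise_sd,
        sleep_shift_error_rate=c.sleep_shift_error_rate,
    )


def run_all(cfg: PipelineConfig) -> Dict[str, object]:
    """Execute every stage; returns the result bundle and writes outputs."""
    out = pathlib.Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(
        json.dumps({"hash": cfg.config_hash(), **cfg.model_dump()}, indent=1)
    )

    # --- inputs -----------------------------------------------------------
    if cfg.input_dir is not None:
        if not pathlib.Path(cfg.input_dir).exists():
            raise FileNotFoundError(f"input_dir does not exist: {cfg.input_dir}")
        bundles = synthetic.read_cohort(cfg.input_dir)
        truths = {}
    else:
        bundles, truths = synthetic.generate_cohort(_cohort_config(cfg))
        if cfg.write_raw:
            synthetic.write_cohort(bundles, truths, out / "raw")

    # --- clean ------------------------------------------------------------
    cleaned: List[ParticipantBundle] = []
    reports = {}
    for b in bundles:
        cb, rep = preprocessing.clean_bundle(b)
        cleaned.append(cb)
        reports[b.participant_id] = rep.to_dict()
    (out / "cleaning_report.json").write_text(json.dumps(reports, indent=1))

    # --- quality ----------------------------------------------------------
    coverage = quality.cohort_coverage_table(cleaned, cfg.timezone)
    coverage.to_csv(out / "coverage.csv", index=False)

    # --- features / L5 ----------------------------------------------------
    tables = []
    all_l5: List[windows.L5Window] = []
    sleep_intervals = []
    for b in cleaned:
        agg = windows.build_aggregate_table(b)
        l5 = windows.detect_l5_all(b, cfg.timezone)
        all_l5.extend(l5)
        sleep_intervals.extend(windows.reported_sleep_intervals(b.pros))
        tables.append(windows.normalize_table(agg, l5, cfg.variant))
    feature_table = (
        pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    )
    feature_table.to_csv(out / "feature_table.csv", index=False)
    l5_df = pd.DataFrame(
        [
            {
                "participant_id": w.participant_id,
                "start": w.start,
                "end": w.end,
                "step_total": w.step_total,
                "lying_fraction": w.lying_fraction,
            }
            for w in all_l5
        ]
    )
    l5_df.to_csv(out / "l5_windows.csv", index=False)
    sleep_agreement = windows.l5_sleep_agreement(all_l5, sleep_intervals)

    # --- association ------------------------------------------------------
    assoc = association.associate(
        feature_table, alpha=cfg.alpha, coverage_min=cfg.coverage_min
    )
    assoc.to_csv(out / "rmcorr.csv", index=False)

    # --- heart-rate recovery ---------------------------------------------
    hrr_table = hrr.cohort_hrr_table(cleaned, cfg.hrr_definition)
    demo = {
        b.participant_id: (b.age, b.sex, b.group) for b in cleaned
    }
    if len(hrr_table):
        hrr_table["age"] = hrr_table["participant_id"].map(lambda p: demo[p][0])
        hrr_table["sex"] = hrr_table["participant_id"].map(lambda p: demo[p][1])
    hrr_table.to_csv(out / "hrr.csv", index=False)
    stats_block = {}
    try:
        comp = hrr.ancova_groups(hrr_table)
        stats_block = {
            "F": comp.f_stat,
            "p": comp.p,
            "partial_eta2": comp.partial_eta2,
            "tukey": comp.tukey.to_dict(orient="records"),
            "group_n": comp.group_n,
        }
    except (ValueError, KeyError):
        stats_block = {"error": "ANCOVA not estimable on this cohort"}

    fat = pd.concat([b.pros for b in cleaned], ignore_index=True)
    fat = fat[fat["item_id"] == "physical_fatigue"]
    fatigue_means = fat.groupby("participant_id")["value"].mean()
    split = (
        hrr.fatigue_split(hrr_table, fatigue_means) if len(hrr_table) else pd.DataFrame()
    )
    (out / "hrr_stats.json").write_text(
        json.dumps(
            {
                "ancova": stats_block,
                "fatigue_split": split.to_dict(orient="records"),
                "l5_sleep_agreement": sleep_agreement,
            },
            indent=1,
            default=float,
        )
    )

    results = {
        "config": cfg,
        "bundles": cleaned,
        "truths": truths,
        "cleaning_reports": reports,
        "coverage": coverage,
        "feature_table": feature_table,
        "l5_windows": all_l5,
        "l5_sleep_agreement": sleep_agreement,
        "rmcorr": assoc,
        "hrr_table": hrr_table,
        "hrr_stats": stats_block,
        "fatigue_split": split,
    }
    report_md = render_report(results)
    (out / "report.md").write_text(report_md)
    results["report_hash"] = hashlib.sha256(report_md.encode()).hexdigest()
    return results


def render_report(results: Dict[str, object]) -> str:
    """Markdown cohort report summarising every stage."""
    cfg: PipelineConfig = results["config"]
    lines = [
        "# Wearable fatigue & sleep pipeline report",
        "",
        f"Config hash: `{cfg.config_hash()}`  | normalization variant: {cfg.variant}"
        f" | alpha: {cfg.alpha}",
        "",
        "## Coverage (participant-level mean of daily values)",
        "",
    ]
    cov = results["coverage"]
    if len(cov):
        pivot = cov.pivot_table(
            index="group", columns="modality", values="coverage", aggfunc="mean"
        )
        lines.append(pivot.round(3).to_markdown())
    lines += ["", "## L5 rest windows", ""]
    lines.append(f"Detected L5 windows: {len(results['l5_windows'])}")
    ag = results["l5_sleep_agreement"]
    if ag.get("n_compared"):
        lines.append(
            f"Agreement with reported sleep (n={ag['n_compared']}): "
            f"{100 * ag['frac_entirely_within']:.1f}% entirely within, "
            f"{100 * ag['frac_within_threshold']:.1f}% within 30 min."
        )
    lines += ["", "## Repeated-measures correlation (significant cells)", ""]
    assoc = results["rmcorr"]
    if len(assoc):
        sig = assoc[assoc["significant"]].sort_values("p")
        lines.append(f"{len(sig)} of {len(assoc)} cells significant at alpha={cfg.alpha}.")
        if len(sig):
            lines.append("")
            lines.append(
                sig.head(20)[["group", "feature", "item_id", "r", "df", "p"]]
                .round(4)
                .to_markdown(index=False)
            )
    lines += ["", "## Heart-rate recovery", ""]
    ht = results["hrr_table"]
    if len(ht):
        lines.append(
            ht.groupby("group")["hrr"].agg(["count", "mean", "std"]).round(2).to_markdown()
        )
        st = results["hrr_stats"]
        if "F" in st:
            lines.append("")
            lines.append(
                f"ANCOVA (hrr ~ group + age + sex): F = {st['F']:.2f}, p = {st['p']:.4g}; "
                f"partial eta^2 = "
                + ", ".join(f"{k}: {v:.3f}" for k, v in st["partial_eta2"].items())
            )
            for row in st["tukey"]:
                lines.append(
                    f"- Tukey {row['pair']}: estimate {row['estimate']:.2f}, "
                    f"p_adj {row['p_adj']:.4g}"
                )
    split = results["fatigue_split"]
    if len(split):
        lines += ["", "### High/low fatigue split (Welch t on HRR)", ""]
        lines.append(split.round(3).to_markdown(index=False))
    lines.append("")
    return "\n".join(lines)
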