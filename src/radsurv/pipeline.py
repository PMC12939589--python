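"""End-to-end orchestration of the biomarker-discovery workflow.

One run executes, in order: cohort generation (or CSV ingestion) →
elastic-net frequency ranking → redundancy analysis and representative
selection → binary data mapping and stratum counts → Kaplan–Meier /
log-rank panels on the original cohort → exploratory SMOTE-balanced
panels (clearly tagged; balanced rows never feed the ranking or
representative stages) → a human-readable report.  Every artifact is a
CSV (or markdown) written into a run directory together with the config
snapshot and seed, and re-running with the same config reproduces the
tables byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from radsurv.cohort import (
    Cohort, read_cohort, read_schema, write_cohort, write_schema,
    summarize_cohort,
)
from radsurv.ranking import RankingConfig, FrequencyTable, run_frequency_ranking
from radsurv.redundancy import select_representative, DEFAULT_REDUNDANCY_THRESHOLD
from radsurv.smote import SmoteConfig, smote_balance
from radsurv.stratify import (
    BinaryFactor, binarize_age, binarize_gender, binarize_stage,
    biomarker_factor, build_strata,
)
from radsurv.survival import compare_strata, PanelRecord
from radsurv.synthetic import SyntheticSpec, generate_cohort, spec_sidecar

logger = logging.getLogger(__name__)

_STAGE_NAMES = ("simulate", "rank", "redundancy", "stratify", "survive",
                "balance", "report")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


@dataclasses.dataclass
class PipelineConfig:
    """One config object covering every stage; all thresholds live here."""

    #: path to an input cohort CSV (with optional schema CSV); when None,
    #: a synthetic cohort is generated from ``synthetic``.
    cohort_csv: str | None = None
    schema_csv: str | None = None
    synthetic: SyntheticSpec = dataclasses.field(default_factory=SyntheticSpec)
    ranking: RankingConfig = dataclasses.field(default_factory=RankingConfig)
    smote: SmoteConfig = dataclasses.field(
        default_factory=lambda: SmoteConfig(skip_singleton_strata=True))
    smote_enabled: bool = True
    redundancy_threshold: float = DEFAULT_REDUNDANCY_THRESHOLD
    ci_level: float = 0.95
    factor_order: tuple[str, ...] = ("age", "gender", "stage")
    seed: int = 0
    plots: bool = False

    def stage_seed(self, k: int) -> int:
        """Counter-based per-stage seed derived from the global seed."""
        return int(np.random.SeedSequence(self.seed, spawn_key=(k,))
                   .generate_state(1)[0] % (2**31))

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"]["block_sizes"] = dict(self.synthetic.block_sizes)
        return d

    @staticmethod
    def from_dict(d: Mapping) -> "PipelineConfig":
        d = dict(d)
        if "synthetic" in d and isinstance(d["synthetic"], Mapping):
            d["synthetic"] = SyntheticSpec(**d["synthetic"])
        if "ranking" in d and isinstance(d["ranking"], Mapping):
            d["ranking"] = RankingConfig(**d["ranking"])
        if "smote" in d and isinstance(d["smote"], Mapping):
            d["smote"] = SmoteConfig(**d["smote"])
        if "factor_order" in d:
            d["factor_order"] = tuple(d["factor_order"])
        return PipelineConfig(**d)

    @staticmethod
    def from_file(path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = (json.loads(text) if str(path).endswith(".json")
                else yaml.safe_load(text))
        return PipelineConfig.from_dict(data or {})

    def snapshot(self, path: Path) -> None:
        path.write_text(yaml.safe_dump(_plain(self.to_dict()), sort_keys=True))


def _plain(obj):
    if isinstance(obj, Mapping):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _load_cohort(config: PipelineConfig) -> Cohort:
    if config.cohort_csv is not None:
        schema = read_schema(config.schema_csv) if config.schema_csv else None
        return read_cohort(config.cohort_csv, schema)
    spec = dataclasses.replace(config.synthetic, seed=config.stage_seed(0))
    return generate_cohort(spec)


def _clinical_factors(cohort: Cohort) -> dict[str, BinaryFactor]:
    return {
        "age": binarize_age(cohort.age),
        "gender": binarize_gender(cohort.gender),
        "stage": binarize_stage(cohort.stage),
    }


def _original_panels(cohort, factors, bio) -> list[PanelRecord]:
    """Single-factor panels plus every clinical × biomarker cross panel."""
    panels = []
    for nm, f in [*factors.items(), (bio.name, bio)]:
        rec = compare_strata(cohort, f, name=f"all:{nm}")
        if rec:
            panels.append(rec)
    for nm, f in factors.items():
        # biomarker split within each clinical level, and vice versa
        for lv in f.levels:
            rec = compare_strata(cohort, bio, within=f.mask(lv),
                                 name=f"{nm}={lv}:biomarker")
            if rec:
                panels.append(rec)
        for lv in bio.levels:
            rec = compare_strata(cohort, f, within=bio.mask(lv),
                                 name=f"biomarker={lv}:{nm}")
            if rec:
                panels.append(rec)
    return panels


def _balanced_panels(cohort, factors, bio, config) -> list[PanelRecord]:
    """Stage-vs-biomarker panels inside demographic cells, on rows balanced
    across the (demographic × stage × biomarker) classes by SMOTE."""
    panels = []
    stage_f = factors["stage"]
    for demo_name in ("age", "gender"):
        demo = factors[demo_name]
        classes = np.array(
            [f"{a}|{s}|{b}" for a, s, b in
             zip(demo.labels, stage_f.labels, bio.labels)], dtype=object)
        cfg = dataclasses.replace(config.smote, seed=config.stage_seed(5))
        try:
            balanced = smote_balance(cohort.data, classes, cfg,
                                     feature_cols=cohort.feature_names)
        except ValueError as exc:
            logger.warning("SMOTE balancing for %s skipped: %s", demo_name, exc)
            continue
        bdata = balanced.data
        lab = bdata["class_label"].str.split("|", expand=True)
        demo_l, stage_l, bio_l = (lab[0].to_numpy(object),
                                  lab[1].to_numpy(object),
                                  lab[2].to_numpy(object))
        bio_f = BinaryFactor(bio.name, bio_l, bio.levels)
        stage_b = BinaryFactor("stage", stage_l, stage_f.levels)
        for dl in demo.levels:
            in_demo = demo_l == dl
            for bl in bio.levels:
                rec = compare_strata(bdata, stage_b,
                                     within=in_demo & (bio_l == bl),
                                     name=f"smote:{demo_name}={dl},biomarker={bl}:stage")
                if rec:
                    panels.append(rec)
            for sl in stage_f.levels:
                rec = compare_strata(bdata, bio_f,
                                     within=in_demo & (stage_l == sl),
                                     name=f"smote:{demo_name}={dl},stage={sl}:biomarker")
                if rec:
                    panels.append(rec)
    return panels


def _panels_to_frame(panels: list[PanelRecord]) -> pd.DataFrame:
    return pd.DataFrame([p.to_row() for p in panels])


def _plot_panels(panels: list[PanelRecord], outdir: Path, level: float) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from radsurv.survival import greenwood_ci

    outdir.mkdir(exist_ok=True)
    for p in panels:
        fig, ax = plt.subplots(figsize=(5, 4))
        for lv, curve in p.curves.items():
            t = np.concatenate([[0.0], curve.times])
            s = np.concatenate([[1.0], curve.survival])
            ax.step(t, s, where="post", label=lv)
            lo, hi = greenwood_ci(curve, level)
            ax.fill_between(curve.times, lo, hi, step="post", alpha=0.2)
        ax.set_xlabel("time (years)")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.02)
        ax.set_title(f"{p.name}  (log-rank p = {p.logrank.display_p()})")
        ax.legend()
        fig.tight_layout()
        safe = p.name.replace(":", "_").replace("=", "-").replace(",", "_")
        fig.savefig(outdir / f"{safe}.png", dpi=110)
        plt.close(fig)


# ---------------------------------------------------------------------------
# entry points
# ---------------------------------------------------------------------------

def run_full_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute every stage and write the run directory; returns its path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.snapshot(out / "config.yaml")

    stage = "simulate"
    try:
        cohort = _load_cohort(config)
        write_cohort(cohort, out / "cohort.csv",
                     sidecar=spec_sidecar(config.synthetic)
                     if config.cohort_csv is None else None)
        write_schema(cohort.feature_categories, out / "schema.csv")
        summarize_cohort(cohort).to_frame().to_csv(out / "cohort_summary.csv",
                                                   index=False)

        stage = "rank"
        rcfg = dataclasses.replace(config.ranking, seed=config.stage_seed(1))
        freq = run_frequency_ranking(cohort, rcfg)
        freq.to_csv(out / "frequency_table.csv")

        stage = "redundancy"
        rep, report = select_representative(
            freq, cohort, threshold=config.redundancy_threshold)
        report.to_csv(out / "correlation_matrix.csv", out / "rss.csv")
        (out / "representative.txt").write_text(rep + "\n")

        stage = "stratify"
        factors = _clinical_factors(cohort)
        bio = biomarker_factor(cohort, rep)
        strata = build_strata(
            cohort, [factors[n] for n in config.factor_order] + [bio])
        strata.counts_frame().to_csv(out / "strata_counts.csv", index=False)

        stage = "survive"
        panels = _original_panels(cohort, factors, bio)
        _panels_to_frame(panels).to_csv(out / "km_panels.csv", index=False)
        if config.plots:
            _plot_panels(panels, out / "plots", config.ci_level)

        stage = "balance"
        if config.smote_enabled:
            bpanels = _balanced_panels(cohort, factors, bio, config)
            _panels_to_frame(bpanels).to_csv(out / "km_panels_smote.csv",
                                             index=False)
            if config.plots and bpanels:
                _plot_panels(bpanels, out / "plots_smote", config.ci_level)

        stage = "report"
        make_report(out)
    except Exception as exc:
        record = {"stage": stage, "error": str(exc),
                  "type": type(exc).__name__}
        (out / "error.json").write_text(json.dumps(record, indent=2))
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc
    return out


def make_report(run_dir: str | Path) -> Path:
    """Summarize a completed run directory into ``report.md`` (idempotent)."""
    run = Path(run_dir)
    freq_path = run / "frequency_table.csv"
    rep_path = run / "representative.txt"
    panels_path = run / "km_panels.csv"
    for p in (freq_path, rep_path, panels_path):
        if not p.exists():
            raise PipelineError("report", f"incomplete run: missing {p.name}")
    freq = pd.read_csv(freq_path)
    rep = rep_path.read_text().strip()
    panels = pd.read_csv(panels_path)
    rss = pd.read_csv(run / "rss.csv") if (run / "rss.csv").exists() else None

    lines = ["# radsurv run report", ""]
    lines.append(f"Representative biomarker: **{rep}**")
    if rss is not None and (rss["feature"] == rep).any():
        val = float(rss.loc[rss["feature"] == rep, "rss"].iloc[0])
        lines.append(f"(representativeness strength score RSS = {val:.2f})")
    lines += ["", "## Top-ranked features", ""]
    top = freq.head(16)
    lines.append(top.to_markdown(index=False))

    bio_within = panels[panels["panel"].str.contains(r":biomarker$", regex=True)
                        & panels["panel"].str.startswith("stage=")]
    stage_within = panels[panels["panel"].str.startswith("biomarker=")
                          & panels["panel"].str.endswith(":stage")]
    lines += ["", "## Stage vs biomarker asymmetry", ""]
    if len(bio_within) and len(stage_within):
        p_bio = bio_within["p_value"].median()
        p_stage = stage_within["p_value"].median()
        verdict = ("biomarker splits separate survival within stage strata "
                   "while stage splits do not within biomarker strata"
                   if p_bio < 0.05 <= p_stage else
                   "no clear asymmetry between stage and biomarker splits")
        lines.append(f"Median log-rank p, biomarker-within-stage: {p_bio:.3g}; "
                     f"stage-within-biomarker: {p_stage:.3g}. Verdict: {verdict}.")
    lines += ["", "## Panels", ""]
    show = panels[["panel", "p_display"]]
    lines.append(show.to_markdown(index=False))
    lines.append("")
    out = run / "report.md"
    out.write_text("\n".join(lines))
    return out
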