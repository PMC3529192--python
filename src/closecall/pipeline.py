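"""End-to-end orchestration: simulate (or ingest) audio, measure
segment features, screen collinearity, run stepwise discriminant
classification with bootstrap chance correction per group, and run
crossed permuted DFAs for the context, group and sex cues — separately
for the whole call and the noisy and harmonic segments.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .acoustics import (FEATURE_COLUMNS, SEGMENT_KINDS, SpectrogramParams,
                        extract_features, read_features, write_features)
from .collinearity import select_noncollinear
from .dfa import stepwise_select
from .inference import bootstrap_chance, chance_level, crossed_pdfa
from .synth import SyntheticConfig, generate_dataset, read_annotations

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "•"
    return ""


@dataclass
class PipelineConfig:
    mode: str = "synthetic"                    # "synthetic" | "real"
    output_dir: str = "closecall_run"
    annotations_path: str | None = None        # real mode
    audio_root: str | None = None              # real mode
    synth: SyntheticConfig = field(default_factory=SyntheticConfig)
    fft_size: int = 1024
    overlap_fraction: float = 0.9687
    vif_threshold: float = 2.5
    stepwise_improvement: float = 0.05
    n_permutations: int = 1000
    n_randomizations: int = 1000
    n_selections: int = 100
    min_calls: int = 5
    min_contexts: int = 2
    sample_per_individual: int = 5
    min_groups_for_group_cue: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ValueError(f"mode must be 'synthetic' or 'real', "
                             f"got {self.mode!r}")
        if self.mode == "real" and not self.annotations_path:
            raise ValueError("real mode needs annotations_path")


@dataclass
class AnalysisReport:
    individual_rows: pd.DataFrame      # group x segment CV-values + bootstrap P
    context_rows: pd.DataFrame         # segment x comparison ncce + pDFA P
    group_sex_rows: pd.DataFrame       # group / sex cue pDFAs per segment
    parameter_summary: pd.DataFrame    # per segment x context mean ± sd
    retained_predictors: dict[str, list[str]]
    provenance: dict

    def to_text(self) -> str:
        lines = ["Close-call analysis report", "=" * 60, ""]
        lines += ["Individual vocal cue classification (leave-one-out CV-values"
                  " %, bootstrap significance)", ""]
        lines.append(self.individual_rows.to_string(index=False))
        lines += ["", "Context / behavioral vocal cue (crossed pDFA, ncce as %"
                  " of cross-classified elements)", ""]
        lines.append(self.context_rows.to_string(index=False))
        lines += ["", "Group and sex vocal cues (pDFA, subjects as permutation"
                  " units)", ""]
        lines.append(self.group_sex_rows.to_string(index=False))
        lines += ["", "Acoustic parameters per segment and context (mean ± sd)",
                  ""]
        lines.append(self.parameter_summary.to_string())
        lines += ["", "Retained predictors after VIF screening:"]
        for seg, preds in self.retained_predictors.items():
            lines.append(f"  {seg}: {', '.join(preds)}")
        lines += ["", "No multiple-testing correction is applied across the "
                  "pairwise context comparisons.",
                  "", "Provenance: " + json.dumps(self.provenance)]
        return "\n".join(lines)

    def to_json(self) -> str:
        def _df(d: pd.DataFrame):
            return json.loads(d.to_json(orient="records"))
        return json.dumps({
            "individual": _df(self.individual_rows),
            "context": _df(self.context_rows),
            "group_sex": _df(self.group_sex_rows),
            "retained_predictors": self.retained_predictors,
            "provenance": self.provenance,
        }, indent=2)


def apply_inclusion_rules(features: pd.DataFrame, min_calls: int = 5,
                          min_contexts: int = 2,
                          sample_per_individual: int = 5,
                          seed: int | None = None,
                          rng: np.random.Generator | None = None,
                          ) -> pd.DataFrame:
    """Apply the call-count inclusion rule to a one-row-per-call table.

    Keeps only (individual, context) cells with at least ``min_calls``
    calls, keeps only individuals retaining at least ``min_contexts``
    such cells, and down-samples every kept cell to
    ``sample_per_individual`` calls, reproducibly by seed.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    if features.attrs:
        features = features.copy()
        features.attrs = {}   # non-scalar attrs break pd.concat
    counts = features.groupby(["individual_id", "context"]).size()
    kept_cells = counts[counts >= min_calls]
    cells_per_ind = kept_cells.groupby("individual_id").size()
    kept_inds = set(cells_per_ind[cells_per_ind >= min_contexts].index)

    pieces = []
    for (ind, ctx), n in kept_cells.items():
        if ind not in kept_inds:
            continue
        cell = features[(features["individual_id"] == ind)
                        & (features["context"] == ctx)]
        if n > sample_per_individual:
            take = np.sort(rng.choice(n, size=sample_per_individual,
                                      replace=False))
            cell = cell.iloc[take]
        pieces.append(cell)
    if not pieces:
        raise ValueError("no individual satisfies the inclusion rule "
                         f"(>= {min_calls} calls in >= {min_contexts} contexts)")
    return pd.concat(pieces).sort_index().reset_index(drop=True)


def _usable_predictors(seg_table: pd.DataFrame) -> list[str]:
    """Features without NaN (F0 features are NaN on unvoiced segments) and
    with non-zero variance."""
    out = []
    for col in FEATURE_COLUMNS:
        vals = seg_table[col]
        if vals.isna().any():
            continue
        if np.isclose(vals.std(ddof=0), 0.0):
            continue
        out.append(col)
    return out


def _config_hash(config: PipelineConfig) -> str:
    """Hash of the analysis-relevant configuration (paths excluded)."""
    payload = asdict(config)
    for key in ("output_dir", "annotations_path", "audio_root"):
        payload.pop(key, None)
    blob = json.dumps(payload, default=str, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _acquire(config: PipelineConfig, out: Path) -> tuple[pd.DataFrame, Path]:
    if config.mode == "synthetic":
        synth_cfg = config.synth.with_seed(config.seed)
        annotations = generate_dataset(synth_cfg, out / "data")
        return annotations, out / "data"
    annotations = read_annotations(Path(config.annotations_path))
    root = Path(config.audio_root or Path(config.annotations_path).parent)
    return annotations, root


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Execute every stage for the whole call and both segments; write the
    report (text + JSON) and the feature table under ``output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(config.seed)
    seeds = {name: np.random.default_rng(s) for name, s in zip(
        ("inclusion", "bootstrap", "pdfa"), master.spawn(3))}

    stage = "acquire"
    try:
        annotations, audio_root = _acquire(config, out)
        stage = "extract"
        params = SpectrogramParams(sample_rate=float(
            config.synth.sample_rate if config.mode == "synthetic" else 44100),
            fft_size=config.fft_size,
            overlap_fraction=config.overlap_fraction)
        features = extract_features(annotations, audio_root, params)
        write_features(features, out / "features.csv")
    except Exception as exc:
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    individual_rows, context_rows, group_sex_rows = [], [], []
    retained: dict[str, list[str]] = {}
    summaries = []

    for segment in SEGMENT_KINDS:
        seg_all = features[features["segment"] == segment].reset_index(drop=True)
        if seg_all.empty:
            log.warning("no rows for segment %s", segment)
            continue
        stage = f"inclusion[{segment}]"
        try:
            seg = apply_inclusion_rules(
                seg_all, config.min_calls, config.min_contexts,
                config.sample_per_individual, rng=seeds["inclusion"])
            stage = f"vif[{segment}]"
            predictors = _usable_predictors(seg)
            vif = select_noncollinear(seg, predictors,
                                      threshold=config.vif_threshold)
            retained[segment] = vif.retained
            log.info("segment %s: retained %s (dropped %s)", segment,
                     vif.retained, vif.dropped)

            stage = f"individual[{segment}]"
            individual_rows += _individual_analysis(seg, vif.retained, config,
                                                    segment, seeds["bootstrap"])
            stage = f"context[{segment}]"
            context_rows += _context_analysis(seg, vif.retained, config,
                                              segment, seeds["pdfa"])
            stage = f"group_sex[{segment}]"
            group_sex_rows += _group_sex_analysis(seg, vif.retained, config,
                                                  segment, seeds["pdfa"])
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage {stage!r} failed: {exc}") from exc

        summary = (seg_all.groupby("context")[FEATURE_COLUMNS]
                   .agg(["mean", "std"]).round(4))
        summary.index = pd.MultiIndex.from_product([[segment], summary.index])
        summaries.append(summary)

    report = AnalysisReport(
        individual_rows=pd.DataFrame(individual_rows),
        context_rows=pd.DataFrame(context_rows),
        group_sex_rows=pd.DataFrame(group_sex_rows),
        parameter_summary=pd.concat(summaries),
        retained_predictors=retained,
        provenance={"config_hash": _config_hash(config), "seed": config.seed,
                    "version": __version__,
                    "n_permutations": config.n_permutations,
                    "n_randomizations": config.n_randomizations})

    (out / "report.txt").write_text(report.to_text())
    (out / "results.json").write_text(report.to_json())
    return report


def _individual_analysis(seg: pd.DataFrame, predictors: list[str],
                         config: PipelineConfig, segment: str,
                         rng: np.random.Generator) -> list[dict]:
    """Per-group stepwise DFA classifying calls to individuals, with
    bootstrap chance correction."""
    rows = []
    for group_id, sub in seg.groupby("group_id"):
        sub = sub.reset_index(drop=True)
        n_ind = sub["individual_id"].nunique()
        if n_ind < 2:
            continue
        trace = stepwise_select(sub, "individual_id", predictors,
                                improvement=config.stepwise_improvement,
                                max_predictors=n_ind - 1)
        boot = bootstrap_chance(sub, "individual_id", trace.selected,
                                n_randomizations=config.n_randomizations,
                                rng=rng)
        rows.append({
            "segment": segment, "group_id": group_id, "n_individuals": n_ind,
            "n_calls": len(sub), "chance_percent": round(chance_level(n_ind), 1),
            "cv_percent": round(trace.cv_result.cv_percent, 1),
            "p_value": boot.p_value,
            "stars": significance_stars(boot.p_value),
            "selected_predictors": ",".join(trace.selected)})
    return rows


def _context_pairs(contexts: list[str]) -> list[tuple[str, ...]]:
    pairs = [tuple(c) for c in itertools.combinations(sorted(contexts), 2)]
    out = [tuple(sorted(contexts))] if len(contexts) > 2 else []
    return out + pairs


def _context_analysis(seg: pd.DataFrame, predictors: list[str],
                      config: PipelineConfig, segment: str,
                      rng: np.random.Generator) -> list[dict]:
    """Overall and pairwise context pDFAs, duration always included."""
    contexts = sorted(seg["context"].unique())
    if len(contexts) < 2:
        return []
    rows = []
    for combo in _context_pairs(contexts):
        sub = seg[seg["context"].isin(combo)].reset_index(drop=True)
        per_ind = sub.groupby("individual_id")["context"].nunique()
        eligible = per_ind[per_ind >= 2].index
        sub = sub[sub["individual_id"].isin(eligible)].reset_index(drop=True)
        if sub.empty or sub["context"].nunique() < 2:
            continue
        n_ind = sub["individual_id"].nunique()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            trace = stepwise_select(sub, "context", predictors,
                                    improvement=config.stepwise_improvement,
                                    max_predictors=max(1, n_ind - 1),
                                    forced=("duration",))
            result = crossed_pdfa(sub, "context", "individual_id",
                                  trace.selected,
                                  n_permutations=config.n_permutations,
                                  n_selections=config.n_selections, rng=rng)
        rows.append({
            "segment": segment, "comparison": "-".join(combo),
            "n_individuals": result.n_subjects,
            "ncce": round(result.observed_ncce, 2),
            "p_value": result.p_value,
            "n_permutations": result.n_permutations,
            "stars": significance_stars(result.p_value),
            "selected_predictors": ",".join(trace.selected)})
    return rows


def _group_sex_analysis(seg: pd.DataFrame, predictors: list[str],
                        config: PipelineConfig, segment: str,
                        rng: np.random.Generator) -> list[dict]:
    """Group-cue and sex-cue pDFAs with the individual as permutation unit."""
    rows = []
    for factor, min_levels in (("group_id", config.min_groups_for_group_cue),
                               ("sex", 2)):
        n_levels = seg[factor].nunique()
        if n_levels < min_levels:
            log.warning("skipping %s cue: only %d level(s)", factor, n_levels)
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                result = crossed_pdfa(seg.reset_index(drop=True), factor,
                                      "individual_id", predictors,
                                      n_permutations=config.n_permutations,
                                      n_selections=config.n_selections,
                                      rng=rng)
        except ValueError as exc:
            log.warning("skipping %s cue: %s", factor, exc)
            continue
        rows.append({
            "segment": segment, "factor": factor,
            "n_individuals": result.n_subjects,
            "ncce": round(result.observed_ncce, 2),
            "p_value": result.p_value,
            "n_permutations": result.n_permutations,
            "stars": significance_stars(result.p_value)})
    return rows
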