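"""Pipeline orchestration: filter -> univariate -> projections -> MCCV ->
consensus -> panel evaluation -> response analysis.

A :class:`PipelineConfig` holds every threshold and seed; the run is
deterministic given the root seed, from which all stage seeds are spawned.
Reports are written as JSON/TSV into the configured output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as evio
from .exceptions import ConfigurationError
from .matrix import ExpressionMatrix, GROUP_HC, GROUP_BASELINE, GROUP_FOLLOWUP
from .mccv import consensus_panel, evaluate_panel, run_mccv_all, SELECTOR_NAMES
from .npx import apply_filters
from .projection import fit_pca, fit_plsda
from .response import build_response_table, correlations_to_frame, spearman_bh, ResponseTable
from .stats import results_to_frame, roc_with_youden, three_group_test, two_group_test
from .synthetic import SyntheticConfig, generate_npx_cohort, generate_response_data

logger = logging.getLogger("evpanel")


@dataclass
class PipelineConfig:
    """Declarative configuration of a full pipeline run."""

    npx_path: str | None = None
    response_path: str | None = None
    output_dir: str = "evpanel_out"
    simulate: dict | None = None  # SyntheticConfig fields; used when npx_path is None

    max_below_lod_frac: float = 0.5
    max_missing_frac: float = 0.30
    alpha_normality: float = 0.05
    q_max: float = 0.05
    fc_min_log2: float = 1.0

    n_splits: int = 100
    train_frac: float = 0.7
    stability: float = 0.60
    rule: str = "top_k_aggregate"
    k: int = 2
    ridge_cv: int = 10
    selectors: tuple[str, ...] = SELECTOR_NAMES
    selector_params: dict = field(default_factory=dict)

    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        for name in ("max_below_lod_frac", "max_missing_frac", "alpha_normality", "q_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v!r}")
        if not 0.0 < self.train_frac < 1.0:
            raise ConfigurationError(f"train_frac must be in (0, 1), got {self.train_frac!r}")
        if not 0.0 <= self.stability <= 1.0:
            raise ConfigurationError(f"stability must be in [0, 1], got {self.stability!r}")
        if self.rule not in ("top_k_aggregate", "stable_intersection"):
            raise ConfigurationError(f"unknown consensus rule {self.rule!r}")
        if self.npx_path is None and self.simulate is None:
            raise ConfigurationError("either npx_path or simulate must be given")

    # -- serialization (lossless round trip) ------------------------------

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["selectors"] = list(self.selectors)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "selectors" in d:
            d["selectors"] = tuple(d["selectors"])
        return cls(**d)

    def config_hash(self) -> str:
        d = asdict(self)
        d["selectors"] = list(self.selectors)
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _load_inputs(config: PipelineConfig):
    """Load or simulate the cohort (and response inputs when simulating)."""
    truth = None
    response_data = None
    if config.npx_path is not None:
        matrix = evio.read_npx_table(config.npx_path)
    else:
        syn = SyntheticConfig(**{**(config.simulate or {}), "seed": config.seed})
        matrix, truth = generate_npx_cohort(syn)
        if syn.n_fu >= 5:
            response_data = generate_response_data(
                syn.n_fu, truth, syn.resp_rho,
                seed=int(np.random.SeedSequence([config.seed, 7]).generate_state(1)[0] % (2**31)),
                noise_sd=syn.noise_sd,
            )
    return matrix, truth, response_data


def _impute_overall_median(values: pd.DataFrame) -> pd.DataFrame:
    med = values.median(axis=0)
    return values.fillna(med).fillna(0.0)


def run_full_pipeline(
    config: PipelineConfig,
    matrix: ExpressionMatrix | None = None,
    label: str = "full_cohort",
) -> dict:
    """Execute every stage and write the report bundle; returns it as a dict."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.output_dir) / label
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"label": label, "seed": config.seed, "config_hash": config.config_hash()}

    truth = None
    response_data = None
    if matrix is None:
        matrix, truth, response_data = _load_inputs(config)
    logger.info("[%s] input: %d samples x %d proteins", label, matrix.n_samples, matrix.n_proteins)

    # 1. filters
    filtered, filter_report = apply_filters(
        matrix, config.max_below_lod_frac, config.max_missing_frac
    )
    evio.write_filter_report(filter_report, out_dir / "filter_report.json",
                             out_dir / "filter_report.tsv")
    bundle["filter"] = filter_report.to_dict()
    logger.info("[%s] filters retained %d / %d proteins", label,
                filter_report.n_retained, filter_report.n_input)

    groups = set(filtered.sample_group.unique())

    # 2. univariate differential + single-marker ROC
    diff_be = two_group_test(filtered, GROUP_HC, GROUP_BASELINE,
                             alpha_normality=config.alpha_normality,
                             q_max=config.q_max, fc_min_log2=config.fc_min_log2)
    diff_frame = results_to_frame(diff_be)
    diff_frame.to_csv(out_dir / "differential_hc_vs_baseline.tsv", sep="\t", index=False)
    bundle["differential_hc_vs_baseline"] = diff_frame
    if GROUP_FOLLOWUP in groups:
        diff_fu = two_group_test(filtered, GROUP_BASELINE, GROUP_FOLLOWUP,
                                 alpha_normality=config.alpha_normality,
                                 q_max=config.q_max, fc_min_log2=config.fc_min_log2)
        results_to_frame(diff_fu).to_csv(
            out_dir / "differential_baseline_vs_followup.tsv", sep="\t", index=False)
        if len(groups) >= 3:
            omni = three_group_test(filtered, alpha_normality=config.alpha_normality)
            results_to_frame(omni).to_csv(out_dir / "differential_three_group.tsv",
                                          sep="\t", index=False)

    top5 = diff_frame.sort_values("delta_npx", ascending=False).head(5)["protein_id"].tolist()
    hc_be = filtered.subset_samples(
        filtered.sample_ids[filtered.sample_group.isin([GROUP_HC, GROUP_BASELINE])]
    )
    y_bin = (hc_be.sample_group == GROUP_BASELINE).astype(int)
    roc_rows = []
    for pid in top5:
        vals = hc_be.values[pid]
        ok = vals.notna()
        if ok.sum() < 4 or y_bin[ok].nunique() < 2 or vals[ok].nunique() < 2:
            continue
        r = roc_with_youden(vals[ok], y_bin[ok], marker_id=pid, seed=config.seed)
        roc_rows.append(asdict(r))
    pd.DataFrame(roc_rows).to_csv(out_dir / "roc_top5.tsv", sep="\t", index=False)
    bundle["roc_top5"] = roc_rows

    # 3. projections on overall-median-imputed data
    imputed = _impute_overall_median(filtered.values)
    n_comp = min(2, imputed.shape[0] - 1, imputed.shape[1])
    pca = fit_pca(imputed, n_components=n_comp)
    pls = fit_plsda(imputed, filtered.sample_group.to_numpy(), n_components=n_comp)
    evio.write_json(
        {
            "pca_variance_explained": pca.variance_explained,
            "plsda_variance_explained": pls.variance_explained,
        },
        out_dir / "projection.json",
    )
    bundle["projection"] = {
        "pca_variance_explained": list(map(float, pca.variance_explained)),
        "plsda_variance_explained": list(map(float, pls.variance_explained)),
    }

    # 4. three-selector MCCV
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    mccv_seed, panel_seed, _ = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in seeds]
    results = run_mccv_all(
        filtered,
        selectors=config.selectors,
        selector_params=config.selector_params,
        ridge_cv=config.ridge_cv,
        n_splits=config.n_splits,
        train_frac=config.train_frac,
        seed=mccv_seed,
    )
    freqs = {name: res.selection_freq for name, res in results.items()}
    evio.write_selection_frequencies(freqs, out_dir / "selection_frequencies.tsv")
    with open(out_dir / "selector_outputs.jsonl", "w") as fh:
        for name, res in results.items():
            for o in res.selector_outputs:
                fh.write(json.dumps({
                    "model": o.model,
                    "split_index": o.split_index,
                    "selected": o.selected,
                    "diagnostics": {k: v for k, v in o.diagnostics.items()
                                    if isinstance(v, (str, int, float, bool, list))},
                }) + "\n")
    perf = {
        name: {
            "median_auc": res.median_auc,
            "auc_iqr": list(res.auc_iqr),
            "pooled_oof_auc": res.pooled_oof_auc,
            "pooled_oof_ci": list(res.pooled_oof_ci),
        }
        for name, res in results.items()
    }
    bundle["mccv"] = perf

    # 5. consensus panel + fresh-split evaluation
    panel = consensus_panel(freqs, stability=config.stability, rule=config.rule, k=config.k)
    if panel.panel:
        panel.panel_eval = evaluate_panel(
            panel.panel, filtered, fresh_seed=panel_seed,
            n_splits=config.n_splits, train_frac=config.train_frac,
            ridge_cv=config.ridge_cv,
        )
        perf["panel"] = {
            "proteins": panel.panel,
            "median_auc": panel.panel_eval.median_auc,
            "auc_iqr": list(panel.panel_eval.auc_iqr),
            "pooled_oof_auc": panel.panel_eval.pooled_oof_auc,
            "pooled_oof_ci": list(panel.panel_eval.pooled_oof_ci),
        }
    evio.write_json(perf, out_dir / "model_performance.json")
    evio.write_json(
        {
            "rule": panel.rule,
            "stability": panel.stability,
            "stable_sets": panel.stable_sets,
            "panel": panel.panel,
            "aggregate_counts": panel.aggregate_counts,
            "warnings": panel.warnings,
        },
        out_dir / "panel.json",
    )
    bundle["panel"] = panel

    # 6. response analysis
    resp_table = None
    if config.response_path is not None:
        sld = evio.read_response_table(config.response_path)
        resp_table = build_response_table(filtered, sld)
    elif response_data is not None:
        keep = [p for p in response_data.delta_npx.columns if p in filtered.protein_ids]
        resp_table = ResponseTable(
            sld_baseline=response_data.sld_baseline,
            sld_followup=response_data.sld_followup,
            pct_delta_sld=response_data.pct_delta_sld,
            delta_npx=response_data.delta_npx[keep],
        )
    if resp_table is not None and len(resp_table.delta_npx) >= 5:
        corr = spearman_bh(resp_table.delta_npx, resp_table.pct_delta_sld)
        correlations_to_frame(corr).to_csv(out_dir / "response_correlations.tsv",
                                           sep="\t", index=False)
        bundle["response"] = corr

    if truth is not None:
        evio.write_ground_truth(truth, out_dir / "ground_truth.json")
        bundle["ground_truth"] = truth

    config.to_yaml(out_dir / "config.yaml")
    evio.write_json(
        {
            "seed": config.seed,
            "config_hash": bundle["config_hash"],
            "n_samples": matrix.n_samples,
            "n_proteins_input": filter_report.n_input,
            "n_proteins_retained": filter_report.n_retained,
            "n_splits": config.n_splits,
            "panel": panel.panel,
        },
        out_dir / "run_log.json",
    )
    return bundle


def subgroup_rerun(config: PipelineConfig, sample_ids, description: str,
                   matrix: ExpressionMatrix | None = None) -> dict:
    """Re-run the identical pipeline on a sample subset (sensitivity check).

    ``sample_ids`` names the retained samples; the report is labelled with
    ``description``. Errors when the subset empties a diagnostic class.
    """
    config.validate()
    if matrix is None:
        matrix, _, _ = _load_inputs(config)
    sub = matrix.subset_samples(sample_ids)
    counts = sub.sample_group.value_counts()
    for grp in (GROUP_HC, GROUP_BASELINE):
        if counts.get(grp, 0) < 2:
            raise ConfigurationError(
                f"subgroup {description!r} leaves fewer than 2 {grp} samples"
            )
    label = "subgroup_" + "".join(c if c.isalnum() else "_" for c in description)[:40]
    return run_full_pipeline(config, matrix=sub, label=label)
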