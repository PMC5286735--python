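"""Run configuration, stage orchestration and the artifact manifest.

A run is a pure function of its configuration and seed: every stage writes
its outputs under the configured directory and records each file with a
content hash in a manifest, so re-running an identical configuration
reproduces identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .codebook import Codebook
from .dataset import Dataset, read_dataset
from .diagnostics import crosstab, crosstab_agreement, normalized_profile, posterior_summary
from .errors import LcasubError
from .preprocess import apply_recode, drop_variables, rare_category_screen
from .search import run_search
from .simulate import default_cohort_spec, generate_cohort, with_seed
from .two_stage import run_two_stage

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "search", "two-stage", "diagnose", "compare")


@dataclass
class RunConfig:
    """All tunables of a pipeline run."""

    out_dir: str
    stages: list[str] = field(default_factory=lambda: ["simulate", "search", "diagnose"])
    data_path: str | None = None
    codebook_path: str | None = None
    compare_paths: tuple[str, str] | None = None
    seed: int = 0
    n: int = 928
    K_max: int = 12
    n_restarts: int = 10
    tol: float = 1e-8
    max_iter: int = 1000
    variance_mode: str = "pooled"
    screen_threshold: float = 0.85
    drop_flagged: bool = False
    domain_Ks: dict | str = "search"

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise LcasubError(f"unknown stage(s): {sorted(unknown)}")
        if not 0.0 < self.screen_threshold < 1.0:
            raise LcasubError("screen_threshold must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)


class Manifest:
    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.entries: list[dict] = []

    def record(self, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.entries.append({"path": str(path.relative_to(self.out_dir)),
                             "sha256": digest})
        logger.info("wrote %s (%s)", path, digest[:12])

    def write(self) -> Path:
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps({"files": self.entries}, indent=2))
        return path


def _write_fit(fit, out_dir: Path, stem: str, manifest: Manifest) -> None:
    params = out_dir / f"{stem}_params.csv"
    fit.model.to_long_frame().to_csv(params, index=False)
    manifest.record(params)
    meta = out_dir / f"{stem}_meta.json"
    meta.write_text(json.dumps(fit.metadata(), indent=2))
    manifest.record(meta)


def run_pipeline(config: RunConfig) -> tuple[int, list[dict]]:
    """Execute the requested stages in order; returns (exit status,
    manifest entries). Any stage error raises with a stage label."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(out_dir)
    data: Dataset | None = None
    codebook: Codebook | None = None
    search_result = None

    if config.data_path and config.codebook_path:
        codebook = Codebook.from_yaml(config.codebook_path)
        data = read_dataset(config.data_path, codebook, on_all_missing="drop")
        if getattr(data, "dropped_rows", []):
            logger.info("dropped %d all-missing row(s): %s",
                        len(data.dropped_rows), data.dropped_rows[:10])

    for stage in config.stages:
        try:
            if stage == "simulate":
                spec = with_seed(default_cohort_spec(n=config.n), config.seed)
                data, codebook, truth = generate_cohort(spec)
                data_path = out_dir / "cohort.csv"
                data_path.write_text(data.to_csv())
                manifest.record(data_path)
                cb_path = out_dir / "codebook.yaml"
                codebook.to_yaml(cb_path)
                manifest.record(cb_path)
                truth_path = out_dir / "truth.csv"
                truth_df = truth.domain_categories.copy()
                truth_df.insert(0, "global_class", truth.classes)
                truth_df.to_csv(truth_path, index_label="row_id")
                manifest.record(truth_path)
            elif stage == "preprocess":
                _need(data, stage)
                report = rare_category_screen(data, codebook, config.screen_threshold)
                path = out_dir / "screen_report.csv"
                report.table.to_csv(path, index=False)
                manifest.record(path)
                if config.drop_flagged and report.flagged:
                    data, codebook = drop_variables(data, codebook, report.flagged)
                data, codebook = apply_recode(data, codebook)
                path = out_dir / "preprocessed.csv"
                path.write_text(data.to_csv())
                manifest.record(path)
            elif stage == "search":
                _need(data, stage)
                search_result = run_search(
                    data, codebook, K_max=config.K_max, base_seed=config.seed,
                    n_restarts=config.n_restarts, tol=config.tol,
                    max_iter=config.max_iter, variance_mode=config.variance_mode)
                path = out_dir / "bic_table.csv"
                search_result.bic_frame().to_csv(path, index=False)
                manifest.record(path)
                log = {"starting_K": search_result.starting_K,
                       "rules": {K: rs.rule for K, rs in search_result.per_K.items()},
                       "seed": config.seed}
                path = out_dir / "search_log.json"
                path.write_text(json.dumps(log, indent=2))
                manifest.record(path)
                for K, rs in search_result.per_K.items():
                    _write_fit(rs.retained, out_dir, f"K{K}", manifest)
            elif stage == "two-stage":
                _need(data, stage)
                result = run_two_stage(
                    data, codebook, domain_Ks=config.domain_Ks,
                    K_max=config.K_max, base_seed=config.seed,
                    n_restarts=config.n_restarts, tol=config.tol,
                    max_iter=config.max_iter)
                mem = result.membership
                long = mem.categories.stack().rename("category").reset_index()
                long.columns = ["patient", "domain", "category"]
                long["posterior"] = mem.posteriors.stack().to_numpy()
                path = out_dir / "membership.csv"
                long.to_csv(path, index=False)
                manifest.record(path)
                path = out_dir / "second_stage_bic.csv"
                result.second_stage.bic_frame().to_csv(path, index=False)
                manifest.record(path)
                _write_fit(result.second_stage.retained(result.second_stage.starting_K),
                           out_dir, "second_stage_starting", manifest)
            elif stage == "diagnose":
                if search_result is None:
                    raise LcasubError("diagnose requires a prior search stage")
                fit = search_result.retained(search_result.starting_K)
                summ = posterior_summary(fit.posteriors)
                path = out_dir / "posterior_summary.json"
                path.write_text(json.dumps({
                    "median_max_posterior": summ.median_max_posterior,
                    "iqr": list(summ.iqr_max_posterior),
                    "n_below_070": summ.n_below_070,
                    "n_multi_033": summ.n_multi_033,
                    "n": summ.n}, indent=2))
                manifest.record(path)
                profile = normalized_profile(fit, codebook)
                path = out_dir / "profile.csv"
                profile.scores.to_csv(path, index_label="variable")
                manifest.record(path)
            elif stage == "compare":
                if config.compare_paths is None:
                    raise LcasubError("compare requires two assignment files")
                a = pd.read_csv(config.compare_paths[0])["assignment"].to_numpy()
                b = pd.read_csv(config.compare_paths[1])["assignment"].to_numpy()
                ct = crosstab(np.asarray(a), np.asarray(b))
                path = out_dir / "crosstab.csv"
                ct.counts.to_csv(path)
                manifest.record(path)
                path = out_dir / "crosstab_flags.csv"
                ct.flags.to_csv(path)
                manifest.record(path)
                agr = crosstab_agreement(ct)
                path = out_dir / "agreement.json"
                path.write_text(json.dumps({
                    "percent_agreement": agr.percent_agreement,
                    "ari": agr.ari}, indent=2))
                manifest.record(path)
        except (LcasubError, ValueError, KeyError) as exc:
            raise LcasubError(f"stage {stage!r}: {exc}") from exc
    manifest.write()
    return 0, manifest.entries


def _need(data, stage: str) -> None:
    if data is None:
        raise LcasubError(
            f"stage {stage!r} needs data (simulate first or pass data/codebook paths)"
        )
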