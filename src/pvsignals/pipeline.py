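"""End-to-end orchestration: simulate/ingest -> dedup -> cohort -> screens ->
TTO -> regression, with a run manifest and deterministic table outputs.

``run_pipeline`` executes every stage in memory and only writes files once
all stages have succeeded, so a failing stage leaves no partial outputs.
Identical configuration (including seed) produces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import __version__
from .cohort import Cohort, IndicationDictionary, baseline_tables, build_cohort
from .config import PipelineConfig, SimulationConfig
from .disproportionality import ScreenResults, run_screen
from .errors import ConfigurationError, PipelineStageError, PVSignalsError
from .interaction import InteractionResults, run_interaction_screen
from .io import (
    IngestionLog,
    deduplicate,
    load_two_column_csv,
    normalize_drug_names,
    normalize_terms,
    read_cvard_dialect,
    read_faers_dialect,
)
from .regression import IRAELogit, IRAELogitResults, RegressionSpec
from .simulate import generate_dataset
from .tables import SRSTables
from .tto import TTOResults, run_tto_analysis


def _log_event(stage: str, message: str, seed: Optional[int] = None, **counts) -> None:
    record = {"stage": stage, "level": "info", "message": message}
    if seed is not None:
        record["seed"] = seed
    if counts:
        record["counts"] = counts
    print(json.dumps(record), file=sys.stderr)


@dataclass
class OutputBundle:
    """All stage outputs of one pipeline run."""

    tables: SRSTables
    cohort: Cohort
    baseline: pd.DataFrame
    screen: ScreenResults
    interaction: InteractionResults
    tto: TTOResults
    regression: Optional[IRAELogitResults]
    manifest: Dict
    ingestion_log: IngestionLog
    truth = None


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(config.model_dump_json().encode()).hexdigest()[:16]


def _baseline_frame(cohort: Cohort) -> pd.DataFrame:
    rows = []
    for table in baseline_tables(cohort):
        for category, counts in table.counts.iterrows():
            row = {"variable": table.variable, "category": category}
            row.update({g: int(c) for g, c in counts.items()})
            row.update({"chi_square": table.chi_square, "df": table.df, "p_value": table.p_value})
            rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, output_dir=None) -> OutputBundle:
    """Execute the full pipeline; optionally write the output tables.

    Raises :class:`PipelineStageError` naming the failing stage.
    """
    seed = config.seed
    log = IngestionLog()
    truth = None

    def stage(name, fn):
        try:
            return fn()
        except PVSignalsError:
            raise
        except Exception as exc:
            raise PipelineStageError(name, str(exc)) from exc

    # --- input -------------------------------------------------------------
    if config.simulate is not None:
        sim = config.simulate.model_copy(update={"seed": config.simulate.seed or seed})
        tables, truth = stage("simulate", lambda: generate_dataset(sim))
        _log_event("simulate", "generated synthetic dataset", seed=sim.seed,
                   reports=len(tables.reports))
    else:
        parts = []
        if config.faers_dir:
            t, log = stage("ingest", lambda: read_faers_dialect(config.faers_dir, log))
            parts.append(t)
        if config.cvard_path:
            t, log = stage("ingest", lambda: read_cvard_dialect(config.cvard_path, log))
            parts.append(t)
        tables = parts[0]
        for extra in parts[1:]:
            tables = SRSTables(
                pd.concat([tables.reports, extra.reports], ignore_index=True),
                pd.concat([tables.drugs, extra.drugs], ignore_index=True),
                pd.concat([tables.events, extra.events], ignore_index=True),
            )
        _log_event("ingest", "read dialect files", seed=seed, reports=len(tables.reports))

    # --- normalization and dedup -------------------------------------------
    tables.drugs = normalize_drug_names(tables.drugs)
    if config.term_map_path:
        term_map = dict(load_two_column_csv(config.term_map_path))
        tables.events, log = stage(
            "normalize", lambda: normalize_terms(tables.events, term_map, log)
        )
    n_before = len(tables.reports)
    tables, log = stage("deduplicate", lambda: deduplicate(tables, log=log))
    _log_event("deduplicate", "removed duplicate case versions", seed=seed,
               before=n_before, after=len(tables.reports))

    # --- cohort -------------------------------------------------------------
    dictionary = IndicationDictionary()
    if config.dictionary_path:
        dictionary = IndicationDictionary.from_pairs(load_two_column_csv(config.dictionary_path))
    cohort = stage(
        "cohort",
        lambda: build_cohort(
            tables, dictionary, mode=config.exposure_mode, both_ps_policy=config.both_ps_policy
        ),
    )
    cohort.flow = {"ingested": n_before, "deduplicated": len(tables.reports), **cohort.flow}
    _log_event("cohort", "built exposure cohort", seed=seed, **cohort.group_sizes())

    baseline = stage("baseline", lambda: _baseline_frame(cohort))
    screen = stage(
        "screen",
        lambda: run_screen(
            cohort, min_n=config.min_n, comparator_mode=config.comparator_mode,
            bh_adjust=config.bh_adjust,
        ),
    )
    _log_event("screen", "disproportionality screen", seed=seed, rows=len(screen.frame))
    interaction = stage(
        "interact", lambda: run_interaction_screen(cohort, min_n=config.interaction_min_n)
    )
    tto = stage("tto", lambda: run_tto_analysis(cohort, fit_min_n=config.tto_fit_min_n))

    spec = RegressionSpec(irae_terms=tuple(config.irae_terms) if config.irae_terms else RegressionSpec().irae_terms)
    try:
        regression = IRAELogit.from_cohort(cohort, spec).fit()
    except PVSignalsError as exc:
        _log_event("regress", f"regression skipped: {exc}", seed=seed)
        regression = None

    manifest = {
        "seed": seed,
        "config_hash": _config_hash(config),
        "pvsignals_version": __version__,
        "flow": cohort.flow,
        "stage_rows": {
            "baseline": len(baseline),
            "screen": len(screen.frame),
            "interaction": len(interaction.frame),
            "tto_summary": len(tto.summaries),
            "weibull_fits": len(tto.fits),
            "regression": len(regression.frame) if regression is not None else 0,
        },
        "dedup_removed": len(log.removed_duplicates),
    }
    bundle = OutputBundle(tables, cohort, baseline, screen, interaction, tto,
                          regression, manifest, log)
    bundle.truth = truth
    if output_dir is not None:
        write_bundle(bundle, output_dir)
    return bundle


def _interaction_vs(frame: pd.DataFrame, column: str) -> pd.DataFrame:
    """Rows where the combination is disproportionate against one monotherapy,
    mirroring how per-comparator interaction tables are printed."""
    return frame.loc[frame[column] >= 2.0].reset_index(drop=True)


def write_bundle(bundle: OutputBundle, output_dir) -> List[Path]:
    """Write the nine stage tables plus flow/manifest JSON and the ingestion log."""
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    def write_csv(name: str, frame: pd.DataFrame):
        path = outdir / name
        frame.to_csv(path, index=False)
        written.append(path)

    write_csv("baseline.csv", bundle.baseline)
    for group in ("COMBO", "DRUG_A_MONO", "DRUG_B_MONO"):
        sub = bundle.screen.frame
        write_csv(f"screen_{group}.csv", sub.loc[sub["group"] == group].reset_index(drop=True))
    write_csv("interaction_vs_A.csv", _interaction_vs(bundle.interaction.frame, "prr_combo_vs_a"))
    write_csv("interaction_vs_B.csv", _interaction_vs(bundle.interaction.frame, "prr_combo_vs_b"))
    write_csv("tto_summary.csv", bundle.tto.summaries)
    write_csv("weibull_fits.csv", bundle.tto.fits)
    if bundle.regression is not None:
        write_csv("regression.csv", bundle.regression.frame)
        fit_block = {
            "mcfadden_r2": bundle.regression.mcfadden_r2,
            "aic": bundle.regression.aic,
            "bic": bundle.regression.bic,
            "n_observations": bundle.regression.nobs,
        }
        (outdir / "regression_fit.json").write_text(json.dumps(fit_block, indent=2) + "\n")
        written.append(outdir / "regression_fit.json")
    (outdir / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2, sort_keys=True) + "\n")
    written.append(outdir / "manifest.json")
    bundle.ingestion_log.to_jsonl(outdir / "ingestion_log.jsonl")
    written.append(outdir / "ingestion_log.jsonl")
    return written


def validate_config(path) -> List[str]:
    """Validate a pipeline configuration file; returns a list of problems
    (empty = OK)."""
    problems: List[str] = []
    try:
        raw = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        return [f"cannot read config: {exc}"]
    try:
        config = PipelineConfig(**raw)
    except (ConfigurationError, Exception) as exc:
        return [str(exc)]
    for key in ("faers_dir", "cvard_path", "dictionary_path", "term_map_path"):
        value = getattr(config, key)
        if value is not None and not Path(value).exists():
            problems.append(f"{key}: file not found: {value}")
    return problems


__all__ = ["run_pipeline", "write_bundle", "validate_config", "OutputBundle"]
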