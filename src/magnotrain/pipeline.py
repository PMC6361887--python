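"""End-to-end "replicate the study in silico" pipeline.

Composes the stages: generate the synthetic cohort, apply the inclusion
screen, summarise group x session means, and run the full mixed
repeated-measures analysis on every outcome measure. Writes the cohort
CSV, summary CSV, JSON report and a run manifest.

Reproducibility: a master seed is split into named per-stage streams
(via ``SeedSequence`` spawn keys derived from the stage name), so adding
a stage never perturbs existing streams.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import zlib
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import __version__, io as mio
from .cohort import (
    CohortConfig,
    MEASURES,
    default_config,
    generate_cohort,
    screen_inclusion,
    summarize_by_group_session,
)
from .stats import (
    format_effect,
    independent_t,
    mann_whitney_u,
    mixed_anova,
    pairwise_within,
)

__all__ = ["stage_rng", "stage_seed", "run_full_pipeline", "analyse_measure"]

logger = logging.getLogger("magnotrain")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2**31)."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(zlib.crc32(stage.encode()),))
    return int(ss.generate_state(1)[0] % 2**31)


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(master_seed, stage))


def _clean(x):
    if isinstance(x, float) and math.isnan(x):
        return None
    if isinstance(x, dict):
        return {k: _clean(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_clean(v) for v in x]
    return x


def analyse_measure(table: pd.DataFrame, measure: str) -> Dict:
    """Mixed ANOVA + follow-up tests for one measure, as a JSON-able dict."""
    res = mixed_anova(table, measure)
    out = {
        "anova": res.table.to_dict(orient="records"),
        "sphericity": res.sphericity._asdict() if res.sphericity else None,
        "text": [
            format_effect(res, "group"),
            format_effect(res, "session"),
            format_effect(res, "group:session"),
        ],
    }
    out["pairwise_within"] = [
        {
            "label": t.label,
            "t": t.statistic,
            "df": t.df,
            "p": t.p,
            "p_bonferroni": t.p_bonferroni,
            "mean_difference": t.estimate,
        }
        for t in pairwise_within(table, measure)
    ]
    between = []
    sub = table[table["measure"] == measure]
    for session in dict.fromkeys(sub["session"]):
        cell = sub[sub["session"] == session]
        a = cell[cell["group"] == "experimental"]["value"].to_numpy()
        b = cell[cell["group"] == "control"]["value"].to_numpy()
        t = independent_t(a, b)
        u = mann_whitney_u(a, b)
        between.append(
            {
                "session": session,
                "t": t.statistic,
                "df": t.df,
                "p": t.p,
                "mean_difference": t.estimate,
                "mann_whitney_u": u.statistic,
                "p_mann_whitney": u.p,
            }
        )
    out["between_groups_per_session"] = between
    return _clean(out)


def run_full_pipeline(
    config: Optional[CohortConfig] = None,
    seed: int = 0,
    out_dir: Optional[Path] = None,
) -> Dict:
    """Run cohort generation, screening and analysis; return the manifest.

    If ``out_dir`` is given, writes cohort.csv, summary.csv, report.json
    and manifest.json there. On a partial failure the manifest still
    records the stages that completed.
    """
    config = config if config is not None else default_config()
    config_digest = hashlib.sha256(
        json.dumps(mio.config_to_dict(config), sort_keys=True).encode()
    ).hexdigest()
    manifest: Dict = {
        "package_version": __version__,
        "master_seed": seed,
        "config_sha256": config_digest,
        "stage_seeds": {},
        "started_utc": datetime.now(timezone.utc).isoformat(),
        "stages_completed": [],
        "outputs": {},
    }
    outputs: Dict = {"manifest": manifest}
    try:
        manifest["stage_seeds"]["cohort"] = stage_seed(seed, "cohort")
        table = generate_cohort(config, rng=stage_rng(seed, "cohort"))
        logger.info("cohort: generated %d rows", len(table))
        manifest["stages_completed"].append("cohort")

        eligible, screen_report = screen_inclusion(
            table, config.apra_cutoff, config.rdk_cutoff
        )
        manifest["screen"] = screen_report
        logger.info("screen: kept %(kept)d, dropped %(dropped)d", screen_report)
        manifest["stages_completed"].append("screen")

        summary = summarize_by_group_session(eligible)
        manifest["stages_completed"].append("summary")

        report = {
            "screen": screen_report,
            "measures": {m: analyse_measure(eligible, m) for m in MEASURES},
        }
        manifest["stages_completed"].append("analysis")
        outputs.update(cohort=eligible, summary=summary, report=report)
    finally:
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            if "cohort" in outputs:
                mio.write_cohort_csv(outputs["cohort"], out_dir / "cohort.csv")
                manifest["outputs"]["cohort"] = "cohort.csv"
            if "summary" in outputs:
                outputs["summary"].to_csv(out_dir / "summary.csv", index=False)
                manifest["outputs"]["summary"] = "summary.csv"
            if "report" in outputs:
                mio.write_json(outputs["report"], out_dir / "report.json")
                manifest["outputs"]["report"] = "report.json"
            mio.write_json(manifest, out_dir / "manifest.json")
    return outputs
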