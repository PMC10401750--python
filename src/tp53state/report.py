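"""End-to-end pipeline and summary reporting.

``run_pipeline`` chains the stages — simulate (or read) a cohort, classify
every patient, optionally run the cutoff search — and writes a calls TSV
plus a summary JSON.  Every artifact carries the schema version, the seed
and a hash of the configuration so outputs are traceable and bit-stable
under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import classifier
from .cohort import Cohort, read_cohort_tsv, write_classified_tsv
from .cutoff import CutoffSearchConfig, cross_validate
from .simulate import SimulationParams, generate_cohort
from .survival import SurvivalSample, km_median, logrank_test

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"


@dataclass
class PipelineConfig:
    input_path: Optional[str] = None        # cohort TSV; None -> simulate
    cutoff: float = classifier.DEFAULT_CUTOFF
    run_cutoff_search: bool = False
    search: CutoffSearchConfig = field(default_factory=CutoffSearchConfig)
    sim: SimulationParams = field(default_factory=SimulationParams)
    outdir: str = "tp53state_out"

    def hash(self) -> str:
        payload = {
            "input_path": self.input_path, "cutoff": self.cutoff,
            "run_cutoff_search": self.run_cutoff_search,
            "search": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                       for k, v in vars(self.search).items()},
            "sim": asdict(self.sim),
        }
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def summarize_groups(calls, cohort: Cohort) -> dict:
    """Per allelic state: n, share, KM median OS; plus pairwise log-rank
    p-values between states (unadjusted, as labeled)."""
    if len(calls) != len(cohort):
        raise ValueError("calls must align with the cohort")
    times = np.array([p.os_time for p in cohort])
    events = np.array([p.os_event for p in cohort])
    states = np.array([c.state for c in calls])
    n = len(cohort)
    groups = {}
    order = ["obligatory_biallelic", "probable_biallelic",
             "probable_monoallelic", "wild_type", "del17p_only"]
    for state in order:
        mask = states == state
        if not mask.any():
            groups[state] = {"n": 0, "note": "no patients"}
            continue
        med = km_median(times[mask], events[mask])
        groups[state] = {
            "n": int(mask.sum()),
            "share_pct": round(100.0 * mask.sum() / n, 1),
            "km_median_months": None if np.isinf(med) else round(med, 2),
        }
    pairwise = {}
    present = [s for s in order if groups[s].get("n", 0) > 0]
    for i, a in enumerate(present):
        for b in present[i + 1:]:
            ma, mb = states == a, states == b
            chi2, p = logrank_test([
                SurvivalSample(times[ma], events[ma]),
                SurvivalSample(times[mb], events[mb])])
            pairwise[f"{a}_vs_{b}"] = {"chi2": round(chi2, 4),
                                       "p_unadjusted": round(p, 6)}
    return {"groups": groups, "pairwise_logrank": pairwise}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run simulate/read -> classify -> (optional) cutoff search -> report.

    Returns the summary dict; writes ``calls.tsv``, ``summary.json`` and,
    when requested, ``cutoff_result.json`` under ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        if config.input_path is not None:
            cohort = read_cohort_tsv(config.input_path)
            truth = None
        else:
            cohort, truth = generate_cohort(config.sim)
    except FileNotFoundError as exc:
        raise RuntimeError(f"stage=input: missing input path: {exc}") from exc
    except Exception as exc:
        raise RuntimeError(f"stage=input: {exc}") from exc

    try:
        calls, class_summary = classifier.classify_cohort(cohort, config.cutoff)
        traditional = [classifier.classify_traditional(p) for p in cohort]
        recl = classifier.reclassification_table(traditional, calls)
    except Exception as exc:
        raise RuntimeError(f"stage=classify: {exc}") from exc

    summary = {
        "schema_version": SCHEMA_VERSION,
        "config_hash": config.hash(),
        "seed": config.sim.seed,
        "cutoff": config.cutoff,
        "classification": class_summary,
        "reclassification": {k: v for k, v in recl.items() if k != "table"},
        "survival_by_state": summarize_groups(calls, cohort),
    }
    if truth is not None:
        summary["simulation_truth_biallelic_n"] = int(truth["has_biallelic"].sum())

    if config.run_cutoff_search:
        try:
            vafs = np.array([classifier.combined_vaf(p) for p in cohort])
            ambiguous = np.array(
                [c.state in ("probable_biallelic", "probable_monoallelic")
                 for c in calls])
            sample = SurvivalSample(
                np.array([p.os_time for p in cohort])[ambiguous],
                np.array([p.os_event for p in cohort])[ambiguous])
            result = cross_validate(vafs[ambiguous], sample, config.search)
            summary["cutoff_search"] = result.to_dict()
            with open(outdir / "cutoff_result.json", "w") as fh:
                json.dump({"schema_version": SCHEMA_VERSION,
                           "config_hash": config.hash(),
                           **result.to_dict()}, fh, indent=2)
        except Exception as exc:
            raise RuntimeError(f"stage=cutoff_search: {exc}") from exc

    write_classified_tsv(cohort, calls, outdir / "calls.tsv")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
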