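"""End-to-end orchestration: trajectories + activities → annotated report.

`run_pipeline` ties the stages together the way the study ran them: scan
each replicate trajectory for interactions, aggregate to per-peptide
frequency tables (catalytic-pose exclusion, truncation), apply the
panel-wide low-frequency filter, normalize the activity panel to the
reference peptide, run the two-stage cluster statistics, and export
heat-map TSVs plus a JSON report.  All thresholds live in
`AnalysisConfig`; its defaults are the printed significance thresholds of
the study (cluster stage p ≤ 0.01 Bonferroni-corrected, activity stage
p ≤ 0.05, co-occurrence p ≤ 1e-10, correlation p < 0.01).

Reports are deterministic: rerunning with the same config and inputs
reproduces every output file byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import __version__
from .activity import ActivityRecord, normalize_activities
from .heatmap import export_heatmap
from .interactions import (
    FrequencyTable,
    InteractionCriteria,
    aggregate_frequencies,
    apply_low_frequency_filter,
    scan_interactions,
)
from .peptides import PeptideSequence
from .selectivity import SelectivityReport, run_selectivity_analysis
from .trajectory import Trajectory, load_trajectory

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class AnalysisConfig:
    """Thresholds and parameters for one analysis invocation."""

    criteria: InteractionCriteria = field(default_factory=InteractionCriteria)
    alphabet: str = "AERWY"
    positions: tuple[int, ...] = (1, 2)
    cluster_alpha: float = 0.01
    activity_alpha: float = 0.05
    cooccurrence_alpha: float = 1e-10
    correlation_alpha: float = 0.01
    reference_peptide: str = "FRKacWR"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "cluster_alpha", "activity_alpha",
            "cooccurrence_alpha", "correlation_alpha",
        ):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")


def load_activity_csv(
    path, detection_limit: float = 0.0, enzyme: str = ""
) -> list[ActivityRecord]:
    """Read an activity panel CSV.

    Expected columns: ``peptide`` plus either replicate columns (``rep1``,
    ``rep2``, ...) or summary ``mean``/``sd`` columns.
    """
    df = pd.read_csv(path)
    rep_cols = [c for c in df.columns if c.lower().startswith("rep")]
    records = []
    for row in df.itertuples(index=False):
        peptide = PeptideSequence.parse(getattr(row, "peptide"))
        if rep_cols:
            reps = [
                float(getattr(row, c))
                for c in rep_cols
                if pd.notna(getattr(row, c))
            ]
            rec = ActivityRecord(
                peptide, enzyme, replicates=reps,
                detection_limit=detection_limit,
            )
        else:
            rec = ActivityRecord(
                peptide,
                enzyme,
                mean=float(getattr(row, "mean")),
                sd=float(getattr(row, "sd", float("nan"))),
                detection_limit=detection_limit,
            )
        records.append(rec)
    return records


def frequency_tables(
    trajectories: dict[PeptideSequence, list[Trajectory]],
    criteria: InteractionCriteria,
) -> dict[PeptideSequence, FrequencyTable]:
    """Scan every replicate and aggregate per peptide, then apply the
    panel-wide low-frequency filter."""
    tables = {}
    for peptide, reps in trajectories.items():
        records = [scan_interactions(t, criteria) for t in reps]
        tables[peptide] = aggregate_frequencies(records)
    return apply_low_frequency_filter(tables)


def _freq_by_key(tables: dict[PeptideSequence, FrequencyTable]):
    out: dict = {}
    for peptide, table in tables.items():
        for key, value in table.entries.items():
            out.setdefault(key, {})[peptide] = float(value)
    return out


def _json_key(key) -> str:
    res, position, itype = key
    return f"{res[2]}{res[1]}|{position:+d}|{itype}"


def _report_json(
    config: AnalysisConfig,
    tables: dict[PeptideSequence, FrequencyTable],
    report: SelectivityReport,
    normalized,
) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "software": {
            "kdacsel": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "config": {
            "criteria": dataclasses.asdict(config.criteria),
            "alphabet": config.alphabet,
            "positions": list(config.positions),
            "cluster_alpha": config.cluster_alpha,
            "activity_alpha": config.activity_alpha,
            "cooccurrence_alpha": config.cooccurrence_alpha,
            "correlation_alpha": config.correlation_alpha,
            "reference_peptide": config.reference_peptide,
            "seed": config.seed,
        },
        "frequencies": {
            str(p): {_json_key(k): v for k, v in sorted(
                t.entries.items(), key=lambda kv: _json_key(kv[0])
            )}
            for p, t in sorted(tables.items(), key=lambda pt: str(pt[0]))
        },
        "exclusions": {
            str(p): {_json_key(k): r for k, r in sorted(
                t.excluded.items(), key=lambda kv: _json_key(kv[0])
            )}
            for p, t in sorted(tables.items(), key=lambda pt: str(pt[0]))
        },
        "normalized_activity": {
            str(n.peptide): {"value": n.value, "sd": n.sd}
            for n in sorted(normalized, key=lambda n: str(n.peptide))
        },
        "cluster_tests": [
            {
                "cluster": r.cluster.label,
                "enzyme_residue": f"{r.enzyme_residue[2]}{r.enzyme_residue[1]}",
                "itype": r.itype,
                "t": r.t_statistic,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "significant": r.significant,
            }
            for r in report.cluster_tests
        ],
        "activity_associations": {
            label: {
                "U": a.U_statistic,
                "p": a.p_value,
                "direction": a.direction,
                "significant": a.significant,
            }
            for label, a in sorted(report.activity_associations.items())
        },
        "family_size": report.family_size,
    }


def run_pipeline(
    config: AnalysisConfig,
    trajectories: dict[PeptideSequence, list[Trajectory]],
    activities: list[ActivityRecord],
    out_dir,
) -> dict:
    """Run scan → aggregate → filter → normalize → cluster statistics.

    Writes per-peptide/per-position heat-map TSVs, an exclusion log and
    ``report.json`` under ``out_dir``; returns the report dict.
    """
    if not trajectories:
        raise PipelineError("no trajectories")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        tables = frequency_tables(trajectories, config.criteria)
    except Exception as exc:
        raise PipelineError(f"interaction stage failed: {exc}") from exc
    try:
        reference = PeptideSequence.parse(config.reference_peptide)
        normalized = normalize_activities(activities, reference)
        activity_map = {n.peptide: n.value for n in normalized}
    except Exception as exc:
        raise PipelineError(f"activity stage failed: {exc}") from exc
    try:
        report = run_selectivity_analysis(
            _freq_by_key(tables),
            activity_map,
            peptides=sorted(tables, key=str),
            alphabet=config.alphabet,
            positions=config.positions,
            cluster_alpha=config.cluster_alpha,
            activity_alpha=config.activity_alpha,
        )
    except Exception as exc:
        raise PipelineError(f"statistics stage failed: {exc}") from exc

    annotations = {
        (r.enzyme_residue, r.cluster.position, r.itype): True
        for r in report.significant_pairs()
    }
    for peptide, table in sorted(tables.items(), key=lambda pt: str(pt[0])):
        pdir = out_dir / str(peptide)
        pdir.mkdir(exist_ok=True)
        for position in sorted({k[1] for k in table.entries}):
            export_heatmap(
                table,
                position,
                pdir / f"position{position:+d}.tsv",
                annotations=annotations,
            )
    payload = _report_json(config, tables, report, normalized)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return payload


def load_trajectory_glob(
    paths,
    enzyme_chain: str,
    substrate_chain: str,
    kac_residue: int,
    peptide: PeptideSequence,
    **kwargs,
) -> list[Trajectory]:
    """Load an ordered list of replicate PDB files for one peptide."""
    return [
        load_trajectory(
            p, enzyme_chain, substrate_chain, kac_residue,
            peptide=peptide, replicate_id=i + 1, **kwargs,
        )
        for i, p in enumerate(sorted(str(x) for x in paths))
    ]
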