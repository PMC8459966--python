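"""End-to-end orchestration: ingest -> count -> profile -> partition ->
truncate -> stats -> report.

The pipeline reproduces the structure of the charge-composition analysis:
per-protein metrics tables for the matrix-preferring (MPP) and
urine-preferring (UPP) groups, the Spearman correlation of net-charge
percentage against net-charge number over the full MPP set, the +/-5 %
net-charge truncation tally, the Mann-Whitney comparison of total-charge
percentage between truncated MPP and UPP with group summaries, tidy
cluster-plot data (total% vs net% per protein), and a sensitivity re-run
that drops the single highest-total-charge% protein from the truncated set
(a robustness check against one extreme protein driving the conclusion).

Outputs are deterministic: identical config and seed give identical report
bytes. Progress is logged to stderr with per-stage record counts.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .charge_metrics import ChargeProfile, charge_profile
from .partition import (PartitionConfig, TruncationResult, build_groups,
                        truncate_by_net_charge)
from .sequence_io import (Group, ProteinRecord, ProteinSet, read_annotation_table,
                          read_fasta, write_metrics_table)
from .stats import (CorrelationResult, GroupSummary, RankTestResult,
                    mann_whitney, spearman, summarize)
from .synthetic_data import mpp_upp_scenario

__all__ = [
    "PipelineConfig",
    "AnalysisReport",
    "PipelineError",
    "profile_records",
    "plot_cluster_data",
    "run_pipeline",
]

logger = logging.getLogger("stonecharge")

MIN_CORRELATION_N = 3
INSUFFICIENT = "insufficient n"

ProfilePair = tuple[ProteinRecord, ChargeProfile]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and record context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs and knobs for one pipeline run.

    Exactly one ingestion route must be active: synthetic mode, a
    pre-grouped pair of MPP/UPP sources (FASTA or annotation table, decided
    by extension), or matrix+urine abundance tables to be partitioned by
    :func:`stonecharge.partition.build_groups`.
    """

    mpp_source: str | None = None
    upp_source: str | None = None
    matrix_table: str | None = None
    urine_table: str | None = None
    synthetic: bool = False
    seed: int = 0
    partition: PartitionConfig = field(default_factory=PartitionConfig)
    pka_set: str = "emboss"
    out_dir: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        routes = [
            self.synthetic,
            self.mpp_source is not None or self.upp_source is not None,
            self.matrix_table is not None and self.urine_table is not None,
        ]
        if sum(routes) != 1:
            raise ValueError(
                "configure exactly one input route: synthetic mode, "
                "mpp/upp sources, or matrix+urine abundance tables"
            )


@dataclass
class AnalysisReport:
    """Everything one run computes, with consistent tallies."""

    mpp: list[ProfilePair]
    upp: list[ProfilePair]
    truncation: TruncationResult
    correlation: CorrelationResult | str
    rank_test: RankTestResult | str
    mpp_summary: GroupSummary | str
    upp_summary: GroupSummary | str
    sensitivity: dict
    cluster_data: pd.DataFrame
    reassigned: list[str] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)

    @property
    def truncated_mpp(self) -> list[ProfilePair]:
        return self.truncation.retained

    def to_dict(self) -> dict:
        def _stat(obj):
            if isinstance(obj, str):
                return {"note": obj}
            d = dict(obj.__dict__)
            if "method" in d:
                d["method"] = d["method"].value
            return d

        return {
            "groups": {"mpp_n": len(self.mpp), "upp_n": len(self.upp),
                       "reassigned": self.reassigned, "excluded": self.excluded},
            "truncation": self.truncation.tally,
            "spearman_net_pct_vs_net_charge": _stat(self.correlation),
            "mann_whitney_total_pct": _stat(self.rank_test),
            "truncated_mpp_total_pct": _stat(self.mpp_summary),
            "upp_total_pct": _stat(self.upp_summary),
            "sensitivity": self.sensitivity,
        }


def profile_records(proteins: ProteinSet | list[ProteinRecord]) -> list[ProfilePair]:
    """Score each record, from its sequence or its precomputed counts."""
    out: list[ProfilePair] = []
    for rec in proteins:
        if rec.sequence:
            out.append((rec, charge_profile(rec.sequence)))
        elif rec.counts is not None:
            out.append((rec, charge_profile(rec.counts)))
        else:
            raise PipelineError(
                "profile", f"record {rec.identifier!r} has neither a sequence "
                "nor precomputed residue counts"
            )
    return out


def plot_cluster_data(profiles: list[ProfilePair],
                      group: Group | None = None) -> pd.DataFrame:
    """Tidy (id, group, total_pct, net_pct) table for any plotting front-end.

    Percentages are rounded to one decimal, matching the metrics tables, so
    plot coordinates and table values share a single source of truth.
    """
    if not profiles:
        raise ValueError("no profiles to tabulate")
    rows = [
        {
            "id": rec.identifier,
            "group": (group or rec.group).value,
            "total_pct": round(prof.total_charge_pct, 1),
            "net_pct": round(prof.net_charge_pct, 1),
        }
        for rec, prof in profiles
    ]
    return pd.DataFrame(rows, columns=["id", "group", "total_pct", "net_pct"])


def _read_source(path: str, label: str) -> ProteinSet:
    p = Path(path)
    if p.suffix.lower() in (".fasta", ".fa", ".faa"):
        return read_fasta(p, label=label)
    return read_annotation_table(p, label=label)


def _ingest(config: PipelineConfig) -> tuple[ProteinSet, ProteinSet, list[str], list[str]]:
    if config.synthetic:
        mpp, upp = mpp_upp_scenario(config.seed)
        return mpp, upp, [], []
    if config.matrix_table is not None:
        matrix = _read_source(config.matrix_table, "matrix")
        urine = _read_source(config.urine_table, "urine")
        result = build_groups(matrix, urine, config.partition)
        return result.mpp, result.upp, result.reassigned, result.excluded
    if config.mpp_source is None or config.upp_source is None:
        raise PipelineError("ingest", "both mpp_source and upp_source are required")
    return (_read_source(config.mpp_source, "MPP"),
            _read_source(config.upp_source, "UPP"), [], [])


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Execute the full analysis and (optionally) write all artifacts."""
    logging.basicConfig(stream=sys.stderr, level=config.log_level,
                        format="%(name)s %(levelname)s %(message)s")

    try:
        mpp_set, upp_set, reassigned, excluded = _ingest(config)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("ingest", str(exc)) from exc
    logger.info("ingest: %d MPP, %d UPP records", len(mpp_set), len(upp_set))

    mpp = profile_records(mpp_set)
    upp = profile_records(upp_set)
    logger.info("profile: scored %d records", len(mpp) + len(upp))

    try:
        truncation = truncate_by_net_charge(mpp, config.partition)
    except Exception as exc:
        raise PipelineError("truncate", str(exc)) from exc
    logger.info("truncate: %s", truncation.tally)

    # Spearman over the full MPP set: net charge % vs net charge number
    if len(mpp) >= MIN_CORRELATION_N:
        try:
            correlation: CorrelationResult | str = spearman(
                [p.net_charge_pct for _, p in mpp],
                [p.net_charge for _, p in mpp],
            )
        except ValueError as exc:
            correlation = f"not computed: {exc}"
    else:
        correlation = INSUFFICIENT

    trunc_totals = [p.total_charge_pct for _, p in truncation.retained]
    upp_totals = [p.total_charge_pct for _, p in upp]
    if trunc_totals and upp_totals:
        rank_test: RankTestResult | str = mann_whitney(trunc_totals, upp_totals)
        mpp_summary: GroupSummary | str = summarize(trunc_totals)
        upp_summary: GroupSummary | str = summarize(upp_totals)
    else:
        rank_test = mpp_summary = upp_summary = INSUFFICIENT
    logger.info("stats: correlation=%s rank_test=%s", correlation, rank_test)

    # sensitivity: drop the single highest-total% protein from the truncated set
    sensitivity: dict = {"note": INSUFFICIENT}
    if len(trunc_totals) >= 2 and upp_totals:
        top = max(range(len(trunc_totals)), key=trunc_totals.__getitem__)
        reduced = [v for i, v in enumerate(trunc_totals) if i != top]
        sens_test = mann_whitney(reduced, upp_totals)
        sensitivity = {
            "dropped": truncation.retained[top][0].identifier,
            "U": sens_test.U,
            "p_two_tailed": sens_test.p_two_tailed,
            "method": sens_test.method.value,
        }

    cluster = pd.concat(
        [plot_cluster_data(mpp, Group.MPP), plot_cluster_data(upp, Group.UPP)],
        ignore_index=True,
    )

    report = AnalysisReport(
        mpp=mpp, upp=upp, truncation=truncation,
        correlation=correlation, rank_test=rank_test,
        mpp_summary=mpp_summary, upp_summary=upp_summary,
        sensitivity=sensitivity, cluster_data=cluster,
        reassigned=reassigned, excluded=excluded,
    )

    if config.out_dir is not None:
        _write_report(report, Path(config.out_dir))
    return report


def _write_report(report: AnalysisReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_metrics_table(report.mpp, out_dir / "mpp_metrics.tsv")
    write_metrics_table(report.upp, out_dir / "upp_metrics.tsv")
    if report.truncation.retained:
        write_metrics_table(report.truncation.retained,
                            out_dir / "mpp_truncated_metrics.tsv")
    report.cluster_data.to_csv(out_dir / "cluster_data.tsv", sep="\t", index=False)
    with (out_dir / "report.json").open("w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("report: wrote artifacts to %s", out_dir)
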