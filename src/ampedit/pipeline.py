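"""End-to-end analysis pipeline and result serialization.

``analyze_reads`` is the in-memory core (also used by the simulator-driven
tests); ``run_pipeline`` wraps it with FASTQ/panel I/O and writes the
output tables:

* ``demux_summary.tsv``  - per-site read assignment accounting
* ``site_results.tsv``   - editing activity, CI, active flag per site
* ``classifier_dump.tsv``- every classified (type, position) cell
* ``translocations.tsv`` - per-pair fusion counts, p and q values
* ``run_summary.json``   - parameters, read accounting, q estimate
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .align import AlignParams, EventTable, build_event_table, event_table_frame
from .classify import (
    ClassifyParams,
    EditModelParams,
    build_prior_ladder,
    classify_site,
    estimate_q,
    mark_edited_reads,
)
from .demux import DemuxParams, DemuxPools, build_pools
from .errors import AmpEditError, ConfigError
from .panel import CutSite, Read, SiteConfig, locate_cut_sites, parse_panel
from .preprocess import PreprocessParams, preprocess_sample
from .quantify import SiteResult, site_result
from .translocation import TranslocationParams, TranslocationResult, analyze_translocations

log = logging.getLogger("ampedit")


@dataclass
class RunConfig:
    """All tunable parameters of a run, with the package defaults."""

    tx_r1: str | None = None
    tx_r2: str | None = None
    m_r1: str | None = None
    m_r2: str | None = None
    panel_path: str | None = None
    output_dir: str = "ampedit_out"
    skip_preprocess: bool = False     # inputs already merged/filtered
    alpha: float = 0.05               # CI level
    active_threshold: float = 1e-3    # editing activity for the "active" call
    q_override: float | None = None
    max_len_class: int = 30
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    demux: DemuxParams = field(default_factory=DemuxParams)
    align: AlignParams = field(default_factory=AlignParams)
    classify: ClassifyParams = field(default_factory=ClassifyParams)
    translocation: TranslocationParams = field(default_factory=TranslocationParams)
    plots: bool = False
    depth_imbalance_warn: float = 3.0


@dataclass
class AnalysisResult:
    site_results: dict[str, SiteResult]
    decisions: dict[str, list]
    event_tables: dict[str, EventTable]
    translocations: list[TranslocationResult]
    edited_read_ids: dict[str, set]
    q_params: EditModelParams
    tx_pools: DemuxPools
    m_pools: DemuxPools
    cut_sites: dict[str, CutSite]
    accounting: dict = field(default_factory=dict)


def analyze_reads(
    tx_reads: Sequence[Read],
    m_reads: Sequence[Read],
    panel: Sequence[SiteConfig],
    config: RunConfig | None = None,
) -> AnalysisResult:
    """Run demultiplexing, alignment, classification, quantification and
    translocation analysis on in-memory read pools."""
    config = config or RunConfig()
    cuts = locate_cut_sites(panel)

    tx_pools = build_pools(tx_reads, panel, config.demux)
    m_pools = build_pools(m_reads, panel, config.demux)

    for site in panel:
        n_tx = tx_pools.totals[site.site_id]
        n_m = m_pools.totals[site.site_id]
        if n_tx and n_m and max(n_tx, n_m) > config.depth_imbalance_warn * min(n_tx, n_m):
            log.warning(
                "site %s: Tx/M depth imbalance %d vs %d exceeds %.1fx; "
                "comparative inference quality degrades",
                site.site_id, n_tx, n_m, config.depth_imbalance_warn,
            )

    event_tables: dict[str, EventTable] = {}
    for site in panel:
        event_tables[site.site_id] = build_event_table(
            tx_pools.site_reads[site.site_id],
            m_pools.site_reads[site.site_id],
            site,
            cuts[site.site_id],
            config.align,
            window_half_width=config.classify.window_half_width,
            max_len_class=config.max_len_class,
        )

    on_targets = [s.site_id for s in panel if s.on_target]
    if config.q_override is not None:
        q_params = EditModelParams(q=config.q_override, source="override")
    else:
        q_params = estimate_q(event_tables, cuts, on_targets, config.classify)
    log.info("edit-model q = %.4f (%s)", q_params.q, q_params.source)

    site_results: dict[str, SiteResult] = {}
    decisions: dict[str, list] = {}
    edited_ids: dict[str, set] = {}
    for site in panel:
        table = event_tables[site.site_id]
        ladder = build_prior_ladder(table.window, cuts[site.site_id], config.classify)
        site_decisions = classify_site(table, ladder, q_params.q)
        decisions[site.site_id] = site_decisions
        edited = mark_edited_reads(table, site_decisions)
        edited_ids[site.site_id] = edited
        site_results[site.site_id] = site_result(
            site.site_id, table.n_tx, table.n_m, len(edited),
            alpha=config.alpha, active_threshold=config.active_threshold,
        )

    active = {sid for sid, r in site_results.items() if r.active}
    translocations, _ = analyze_translocations(
        tx_pools.candidates, m_pools.candidates, panel, cuts,
        tx_pools.totals, m_pools.totals,
        active_sites=active, params=config.translocation,
    )

    accounting = {
        "tx": _sample_accounting(tx_pools, len(tx_reads)),
        "mock": _sample_accounting(m_pools, len(m_reads)),
    }
    return AnalysisResult(
        site_results=site_results,
        decisions=decisions,
        event_tables=event_tables,
        translocations=translocations,
        edited_read_ids=edited_ids,
        q_params=q_params,
        tx_pools=tx_pools,
        m_pools=m_pools,
        cut_sites=cuts,
        accounting=accounting,
    )


def _sample_accounting(pools: DemuxPools, n_input: int) -> dict:
    acc = {
        "input": n_input,
        "assigned": pools.n_assigned,
        "candidates": len(pools.candidates),
        "discarded": pools.discarded,
    }
    assert acc["assigned"] + acc["candidates"] + acc["discarded"] == n_input
    return acc


def demux_summary_frame(result: AnalysisResult) -> pd.DataFrame:
    rows = []
    for sid in result.site_results:
        rows.append({
            "site_id": sid,
            "n_tx": result.tx_pools.totals.get(sid, 0),
            "n_m": result.m_pools.totals.get(sid, 0),
        })
    rows.append({
        "site_id": "__candidates__",
        "n_tx": len(result.tx_pools.candidates),
        "n_m": len(result.m_pools.candidates),
    })
    rows.append({
        "site_id": "__discarded__",
        "n_tx": result.tx_pools.discarded,
        "n_m": result.m_pools.discarded,
    })
    return pd.DataFrame(rows, columns=["site_id", "n_tx", "n_m"])


def site_results_frame(result: AnalysisResult) -> pd.DataFrame:
    rows = []
    for r in result.site_results.values():
        rows.append({
            "site_id": r.site_id,
            "n_tx": r.n_tx,
            "n_m": r.n_m,
            "edited_reads": r.edited_reads,
            "activity_pct": round(100.0 * r.activity, 3),
            "ci_low_pct": round(100.0 * r.ci_low, 3),
            "ci_high_pct": round(100.0 * r.ci_high, 3),
            "active": r.active,
        })
    return pd.DataFrame(rows, columns=[
        "site_id", "n_tx", "n_m", "edited_reads",
        "activity_pct", "ci_low_pct", "ci_high_pct", "active",
    ])


def classifier_frame(result: AnalysisResult) -> pd.DataFrame:
    rows = []
    for sid, decisions in result.decisions.items():
        for d in decisions:
            rows.append({
                "site_id": sid,
                "kind": d.kind,
                "length_class": d.length_class,
                "position": d.position,
                "n_tx": d.n_tx,
                "n_m": d.n_m,
                "log_post_edit": d.log_posterior_edit,
                "log_post_noedit": d.log_posterior_noedit,
                "label": d.label,
            })
    return pd.DataFrame(rows, columns=[
        "site_id", "kind", "length_class", "position", "n_tx", "n_m",
        "log_post_edit", "log_post_noedit", "label",
    ])


def translocations_frame(result: AnalysisResult) -> pd.DataFrame:
    rows = []
    for t in result.translocations:
        rows.append({
            "site_a": t.site_a,
            "site_b": t.site_b,
            "c_tx": t.c_tx,
            "c_m": t.c_m,
            "n": t.n,
            "N": t.N,
            "p_value": t.p_value,
            "q_value": t.q_value,
            "significant": t.significant,
        })
    return pd.DataFrame(rows, columns=[
        "site_a", "site_b", "c_tx", "c_m", "n", "N",
        "p_value", "q_value", "significant",
    ])


def write_outputs(result: AnalysisResult, config: RunConfig, extra_summary: dict | None = None) -> dict:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    frames = {
        "demux_summary.tsv": demux_summary_frame(result),
        "site_results.tsv": site_results_frame(result),
        "classifier_dump.tsv": classifier_frame(result),
        "translocations.tsv": translocations_frame(result),
    }
    for name, frame in frames.items():
        path = outdir / name
        frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
        paths[name] = str(path)

    summary = {
        "version": __version__,
        "q": result.q_params.q,
        "q_source": result.q_params.source,
        "accounting": result.accounting,
        "site_activity": {
            sid: {
                "activity": r.activity,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "edited_reads": r.edited_reads,
                "active": r.active,
            }
            for sid, r in result.site_results.items()
        },
        "n_translocation_tests": len(result.translocations),
        "n_significant_translocations": sum(t.significant for t in result.translocations),
        "parameters": {
            "alpha": config.alpha,
            "active_threshold": config.active_threshold,
            "window_half_width": config.classify.window_half_width,
            "fdr_threshold": config.translocation.fdr_threshold,
            "align": asdict(config.align),
        },
    }
    if extra_summary:
        summary.update(extra_summary)
    path = outdir / "run_summary.json"
    path.write_text(json.dumps(summary, indent=2, default=str))
    paths["run_summary.json"] = str(path)

    if config.plots:
        try:
            plot_path = outdir / "translocation_heatmap.png"
            plot_translocation_heatmap(result, plot_path)
            paths["translocation_heatmap.png"] = str(plot_path)
        except Exception as exc:  # plotting must never fail a run
            log.warning("heatmap plot failed: %s", exc)
    return paths


def plot_translocation_heatmap(result: AnalysisResult, path) -> None:
    """Read-count heatmap of significant translocation pairs."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    sig = [t for t in result.translocations if t.significant]
    if not sig:
        return
    sites = sorted({t.site_a for t in sig} | {t.site_b for t in sig})
    idx = {s: i for i, s in enumerate(sites)}
    mat = np.zeros((len(sites), len(sites)))
    for t in sig:
        mat[idx[t.site_a], idx[t.site_b]] = t.c_tx
        mat[idx[t.site_b], idx[t.site_a]] = t.c_tx
    fig, ax = plt.subplots(figsize=(1 + 0.5 * len(sites), 1 + 0.5 * len(sites)))
    im = ax.imshow(mat, cmap="viridis")
    ax.set_xticks(range(len(sites)), sites, rotation=90)
    ax.set_yticks(range(len(sites)), sites)
    fig.colorbar(im, ax=ax, label="Tx fusion reads")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> AnalysisResult:
    """File-based entry point; raises AmpEditError subclasses on bad input."""
    if config.panel_path is None:
        raise ConfigError("no panel table given")
    panel = parse_panel(config.panel_path)

    if config.tx_r1 is None or config.m_r1 is None:
        raise ConfigError("both treatment and mock FASTQ inputs are required")

    pre_stats = {}
    if config.skip_preprocess:
        from .preprocess import read_fastq

        tx_reads = list(read_fastq(config.tx_r1))
        m_reads = list(read_fastq(config.m_r1))
    else:
        tx_reads, tx_stats = preprocess_sample(config.tx_r1, config.tx_r2, config.preprocess)
        m_reads, m_stats = preprocess_sample(config.m_r1, config.m_r2, config.preprocess)
        pre_stats = {"preprocess": {"tx": tx_stats.as_dict(), "mock": m_stats.as_dict()}}

    if not tx_reads:
        raise AmpEditError("no treatment reads after preprocessing")
    if not m_reads:
        raise AmpEditError("no mock reads after preprocessing")

    result = analyze_reads(tx_reads, m_reads, panel, config)
    write_outputs(result, config, extra_summary=pre_stats)
    return result
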