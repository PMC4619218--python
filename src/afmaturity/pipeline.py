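"""End-to-end orchestration: simulate (or load) -> normalize/filter ->
stage DE + temporal trends -> tissue profiling + marker enrichment ->
morbidity moderated t -> junction PSI -> summary.json.

Every stage writes its TSV next to ``summary.json`` in the output
directory; the summary is a pure function of the inputs and seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import io_formats as io
from . import normalization_de as de
from . import splicing_psi as sp
from . import tissue_profiling as tp
from .io_formats import ValidationError
from .synthetic import SimulationConfig, simulate_study, write_bundle

log = logging.getLogger("afmaturity")

SUMMARY_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    out_dir: str = "afmaturity_run"
    seed: int = 0
    alpha: float = 0.05
    fold_min: float = 1.5
    moderated_fold_min: float = 2.0
    quantile: float = 0.90
    delta_psi_min: float = 0.1
    min_junction_reads: int = 10
    rpkm_min: float = 1.0
    trend_method: str = "sign"
    simulation: SimulationConfig | None = None  # None -> default, seeded

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.fold_min < 1.0 or self.moderated_fold_min < 1.0:
            raise ValidationError("fold thresholds must be >= 1")
        if not (0.0 <= self.quantile < 1.0):
            raise ValidationError("quantile must be in [0, 1)")
        if not (0.0 <= self.delta_psi_min <= 1.0):
            raise ValidationError("delta_psi_min must be in [0, 1]")
        if self.min_junction_reads < 0:
            raise ValidationError("min_junction_reads must be >= 0")
        if self.trend_method not in ("sign", "som"):
            raise ValidationError(f"unknown trend method {self.trend_method!r}")


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline on a (seeded) synthetic study and return
    the machine-readable summary, also written to ``out_dir/summary.json``."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sim = config.simulation or SimulationConfig(seed=config.seed)
    log.info("stage=simulate seed=%d n_genes=%d", sim.seed, sim.n_genes)
    bundle = simulate_study(sim)
    write_bundle(bundle, out / "inputs")

    matrix = de.filter_expressed(bundle.expression, config.rpkm_min)
    log.info("stage=filter kept=%d/%d genes", matrix.shape[0],
             bundle.expression.shape[0])

    results = de.anova_stage_test(matrix, bundle.metadata,
                                  alpha=config.alpha, fold_min=config.fold_min)
    results = de.classify_temporal_patterns(
        results, matrix, bundle.metadata, method=config.trend_method,
        seed=config.seed,
    )
    _write_de_table(results, out / "stage_de.tsv")
    n_diff = sum(r.is_differential for r in results)
    n_induced = sum(r.trend == "induced" for r in results if r.is_differential)
    n_suppressed = sum(r.trend == "suppressed" for r in results if r.is_differential)
    log.info("stage=de differential=%d induced=%d suppressed=%d",
             n_diff, n_induced, n_suppressed)

    # tissue profiling
    profile = tp.stage_marker_profile(matrix, bundle.metadata, bundle.atlas,
                                      quantile=config.quantile)
    profile.to_csv(out / "stage_marker_profile.tsv", sep="\t",
                   index_label="tissue")
    calls = tp.score_tissue_specificity(matrix.gene_ids, bundle.atlas)
    n_specific = sum(c.is_specific for c in calls)

    universe = set(matrix.gene_ids)
    diff_genes = [r.gene_id for r in results if r.is_differential]
    enrich = tp.marker_enrichment(diff_genes, universe, bundle.markers,
                                  alpha=config.alpha)
    _write_enrichment(enrich, out / "marker_enrichment.tsv")
    n_enriched_sets = sum(e.is_enriched for e in enrich)

    origin = tp.check_fetal_origin(matrix, bundle.metadata)
    checked = [r for r in origin if r.concordant is not None]
    concordance = (sum(r.concordant for r in checked) / len(checked)
                   if checked else float("nan"))

    # morbidity contrasts (late-preterm subgroups vs term), moderated t
    morbidity_counts = {}
    for flag in ("gavage_feeding", "respiratory_support"):
        mod = de.moderated_t_test(matrix, bundle.metadata, flag, "FT",
                                  fold_min=config.moderated_fold_min,
                                  alpha=config.alpha)
        morbidity_counts[flag] = sum(r.is_regulated for r in mod)
    log.info("stage=morbidity regulated=%s", morbidity_counts)

    # splicing
    pooled = [r for recs in bundle.junctions.values() for r in recs]
    events = sp.detect_reciprocal_events(pooled, bundle.junction_gene_map)
    psi = sp.compute_psi(events, bundle.junctions, config.min_junction_reads)
    psi.psi.to_csv(out / "psi.tsv", sep="\t", index_label="event_id")
    comps = sp.compare_psi_groups(psi, bundle.metadata, "PT", "FT",
                                  delta_min=config.delta_psi_min)
    regulated = [c for c in comps if c.is_regulated]
    _write_psi_comparisons(comps, out / "psi_pt_vs_ft.tsv")
    reg_events = [psi.events[c.event_id] for c in regulated]
    found, absent = sp.filter_against_panel(reg_events, bundle.panel)

    morb_gene_sets = {}
    for flag in ("gavage_feeding", "respiratory_support"):
        flag_comps = sp.compare_psi_groups(psi, bundle.metadata, flag, "FT",
                                           delta_min=config.delta_psi_min)
        morb_gene_sets[flag] = sp.regulated_genes(flag_comps)
    only_a, only_b, shared = sp.overlap_events(
        morb_gene_sets["gavage_feeding"], morb_gene_sets["respiratory_support"]
    )

    summary = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "seed": config.seed,
        "n_genes_tested": matrix.shape[0],
        "n_samples": matrix.shape[1],
        "differential": {
            "n_differential": n_diff,
            "n_induced": n_induced,
            "n_suppressed": n_suppressed,
        },
        "tissue_profiling": {
            "n_specific_markers": n_specific,
            "n_enriched_marker_sets": n_enriched_sets,
            "stage_profile": {t: dict(row) for t, row in profile.round(6).iterrows()},
        },
        "fetal_origin": {
            "n_samples_checked": len(checked),
            "sex_concordance": concordance,
        },
        "morbidity_de": morbidity_counts,
        "splicing": {
            "n_events": len(events),
            "n_regulated_pt_vs_ft": len(regulated),
            "n_regulated_in_panel": len(found),
            "n_regulated_absent_from_panel": len(absent),
            "morbidity_regulated_genes": {
                "gavage_only": only_a,
                "respiratory_only": only_b,
                "shared": shared,
            },
        },
    }
    # wall time goes to the log only: summary.json must be byte-identical
    # across runs with the same seed and inputs
    log.info("stage=done wall_time_s=%.3f", time.time() - t0)
    with open(out / "summary.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return summary


def _write_de_table(results, path: Path) -> None:
    rows = []
    for r in results:
        row = {
            "gene_id": r.gene_id,
            "anova_p": r.anova_p,
            "anova_p_adjusted": r.anova_p_adjusted,
            "is_differential": r.is_differential,
            "trend": r.trend,
        }
        for (ga, gb), s in r.pairwise.items():
            row[f"fold_{ga}_{gb}"] = s.fold_change
            row[f"dir_{ga}_{gb}"] = s.direction
            row[f"p_{ga}_{gb}"] = s.p
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_enrichment(enrich, path: Path) -> None:
    pd.DataFrame([asdict(e) for e in enrich]).to_csv(path, sep="\t", index=False)


def _write_psi_comparisons(comps, path: Path) -> None:
    pd.DataFrame([asdict(c) for c in comps]).to_csv(path, sep="\t", index=False)
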