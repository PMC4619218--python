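"""Tissue/cell-of-origin profiling of amniotic-fluid cfRNA.

Two complementary approaches:

1. atlas-based specificity scoring — genes abundant in AF at a given stage
   (above the 90th-percentile of per-gene stage means) are mapped onto a
   multi-tissue expression atlas; a gene is *enriched* in its top tissue
   when its expression there is >= 3x the mean of all other tissues, and a
   *specific marker* when it is additionally the argmax with >= 1.5x its
   expression in every other tissue.  Per tissue and stage, the fraction of
   its specific markers detected as abundant gives a stage activity profile.

2. marker-set enrichment — a one-sided Fisher/hypergeometric test of a
   query gene list against curated tissue/cell marker sets, with the
   finite-population z-score used by marker-classification tools.

A fetal-origin check compares XIST (X-inactivation, high in female fetuses)
against chrY-specific transcripts per sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import (
    ExpressionMatrix,
    MarkerDatabase,
    SampleMetadata,
    TissueAtlas,
    ValidationError,
)

ENRICHED_FOLD = 3.0      # vs mean of all other tissues
SPECIFIC_FOLD = 1.5      # vs max of all other tissues


@dataclass(frozen=True)
class TissueMarkerCall:
    gene_id: str
    tissue: str
    fold_vs_mean_others: float
    fold_vs_max_other: float
    is_enriched: bool
    is_specific: bool


class SpecificityCalls(list):
    """List of :class:`TissueMarkerCall` with the genes that could not be
    scored (absent from the atlas, or all-zero rows) in ``skipped``."""

    def __init__(self, calls: Iterable[TissueMarkerCall], skipped: list[str]):
        super().__init__(calls)
        self.skipped = skipped


@dataclass(frozen=True)
class EnrichmentResult:
    label: str
    overlap: int          # r
    set_size: int         # R (after intersection with universe)
    query_size: int       # n
    universe_size: int    # N
    fisher_p: float
    z_score: float
    is_enriched: bool


@dataclass(frozen=True)
class OriginReport:
    sample_id: str
    chry_mean: float
    xist: float
    predicted_sex: str
    recorded_sex: str
    concordant: bool | None  # None when either side is unknown


def abundant_genes(
    m: ExpressionMatrix,
    metadata: Sequence[SampleMetadata],
    stage: str,
    quantile: float = 0.90,
) -> set[str]:
    """Genes whose mean over the stage's samples strictly exceeds the given
    quantile (linear interpolation) of all per-gene stage means."""
    ids = [s.sample_id for s in metadata
           if s.stage == stage and s.sample_id in set(m.sample_ids)]
    if not ids:
        raise ValidationError(f"no samples for stage {stage!r}")
    means = m.data[ids].mean(axis=1)
    cutoff = float(np.quantile(means.to_numpy(), quantile))
    return set(means.index[means > cutoff])


def score_tissue_specificity(
    genes: Iterable[str],
    atlas: TissueAtlas,
) -> SpecificityCalls:
    """Score genes against the atlas; the candidate tissue is the argmax.

    Genes missing from the atlas or with an all-zero atlas row are skipped
    with a warning and listed in the result's ``skipped`` attribute.  Ties
    on the argmax make a gene non-specific (fold_vs_max_other = 1).
    """
    calls: list[TissueMarkerCall] = []
    skipped: list[str] = []
    data = atlas.data
    for gene in genes:
        if gene not in data.index:
            skipped.append(gene)
            continue
        row = data.loc[gene].to_numpy(dtype=float)
        if row.sum() == 0:
            warnings.warn(f"gene {gene!r}: all-zero atlas row, skipped", stacklevel=2)
            skipped.append(gene)
            continue
        j = int(np.argmax(row))
        top = row[j]
        others = np.delete(row, j)
        mean_others = float(others.mean())
        max_other = float(others.max())
        fold_mean = top / mean_others if mean_others > 0 else np.inf
        fold_max = top / max_other if max_other > 0 else np.inf
        is_enriched = fold_mean >= ENRICHED_FOLD
        is_specific = bool(is_enriched and fold_max >= SPECIFIC_FOLD)
        calls.append(
            TissueMarkerCall(
                gene_id=gene,
                tissue=atlas.tissue_labels[j],
                fold_vs_mean_others=float(fold_mean),
                fold_vs_max_other=float(fold_max),
                is_enriched=bool(is_enriched),
                is_specific=is_specific,
            )
        )
    if skipped:
        warnings.warn(f"{len(skipped)} gene(s) not scored against the atlas",
                      stacklevel=2)
    return SpecificityCalls(calls, skipped)


def specific_markers_by_tissue(calls: Iterable[TissueMarkerCall]) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for c in calls:
        if c.is_specific:
            out.setdefault(c.tissue, set()).add(c.gene_id)
    return out


def stage_marker_profile(
    m: ExpressionMatrix,
    metadata: Sequence[SampleMetadata],
    atlas: TissueAtlas,
    quantile: float = 0.90,
) -> pd.DataFrame:
    """Per-tissue, per-stage fraction of the tissue's specific markers that
    are abundant in AF at that stage.

    Specific markers are determined once from the atlas over all genes in
    the matrix; the denominator counts markers present in the matrix, and
    tissues with no specific marker are omitted.  Returns a tissues x
    stages DataFrame of proportions in [0, 1].
    """
    calls = score_tissue_specificity(m.gene_ids, atlas)
    markers = specific_markers_by_tissue(calls)
    if not markers:
        return pd.DataFrame(columns=["PN", "PT", "FT"], dtype=float)
    abundant = {stage: abundant_genes(m, metadata, stage, quantile)
                for stage in ("PN", "PT", "FT")}
    rows = {}
    for tissue, genes in sorted(markers.items()):
        rows[tissue] = {
            stage: len(genes & abundant[stage]) / len(genes)
            for stage in ("PN", "PT", "FT")
        }
    return pd.DataFrame.from_dict(rows, orient="index")[["PN", "PT", "FT"]]


def marker_enrichment(
    query_genes: Iterable[str],
    universe_genes: Iterable[str],
    markers: MarkerDatabase,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """One-sided over-representation test of the query against each marker
    set (gene symbols matched case-insensitively).

    fisher_p is the exact hypergeometric upper tail P(X >= r) for drawing
    the query from the universe; the z-score is the normal approximation
    with finite-population correction,
    z = (r - nR/N) / sqrt(n (R/N)(1-R/N)(1-(n-1)/(N-1))).
    Marker sets with empty intersection with the universe are skipped.
    """
    universe = {str(g).upper() for g in universe_genes}
    query = {str(g).upper() for g in query_genes}
    stray = query - universe
    if stray:
        raise ValidationError(
            f"query genes missing from universe: {sorted(stray)[:10]}"
        )
    n_universe = len(universe)
    n_query = len(query)
    out: list[EnrichmentResult] = []
    for label, genes in markers.items():
        in_universe = genes & universe
        big_r = len(in_universe)
        if big_r == 0:
            continue
        r = len(in_universe & query)
        p = float(stats.hypergeom.sf(r - 1, n_universe, big_r, n_query))
        out.append(
            EnrichmentResult(
                label=label,
                overlap=r,
                set_size=big_r,
                query_size=n_query,
                universe_size=n_universe,
                fisher_p=p,
                z_score=enrichment_z(r, big_r, n_query, n_universe),
                is_enriched=bool(p < alpha),
            )
        )
    out.sort(key=lambda e: (e.fisher_p, e.label))
    return out


def enrichment_z(r: int, big_r: int, n: int, big_n: int) -> float:
    """Standardized overlap under the hypergeometric null (exact mean and
    variance, i.e. normal approximation with finite-population correction)."""
    if big_n <= 1 or n == 0 or big_r == 0 or big_r == big_n:
        return 0.0
    frac = big_r / big_n
    mean = n * frac
    var = n * frac * (1.0 - frac) * (1.0 - (n - 1) / (big_n - 1))
    if var <= 0:
        return 0.0
    return float((r - mean) / np.sqrt(var))


def check_fetal_origin(
    m: ExpressionMatrix,
    metadata: Sequence[SampleMetadata],
    xist_gene: str = "XIST",
    chr_y_genes: Sequence[str] = ("RPS4Y1", "DDX3Y", "EIF1AY"),
) -> list[OriginReport]:
    """Per-sample fetal-origin/sex check: predicted male when the mean of
    the chrY markers exceeds XIST, female otherwise; "unknown" when the
    required markers are missing from the matrix."""
    have_xist = xist_gene in m.data.index
    chry = [g for g in chr_y_genes if g in m.data.index]
    if not have_xist or not chry:
        warnings.warn("sex markers missing; predictions downgraded to unknown",
                      stacklevel=2)
    meta = {s.sample_id: s for s in metadata}
    reports = []
    for sid in m.sample_ids:
        xist = float(m.data.at[xist_gene, sid]) if have_xist else np.nan
        chry_mean = float(m.data.loc[chry, sid].mean()) if chry else np.nan
        if not have_xist or not chry:
            predicted = "unknown"
        else:
            predicted = "male" if chry_mean > xist else "female"
        recorded = meta[sid].fetal_sex if sid in meta else "unknown"
        concordant = (predicted == recorded
                      if "unknown" not in (predicted, recorded) else None)
        reports.append(
            OriginReport(
                sample_id=sid,
                chry_mean=chry_mean,
                xist=xist,
                predicted_sex=predicted,
                recorded_sex=recorded,
                concordant=concordant,
            )
        )
    return reports
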