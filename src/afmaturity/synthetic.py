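"""Synthetic amniotic-fluid cfRNA study generator with recorded ground truth.

Emulates the structure of a three-stage gestational cohort (4 prenatal, 6
late-preterm, 6 term samples) profiled by cell-free RNA-seq:

* an RPKM-scale gene-by-sample expression matrix with log2-normal noise,
  planted stage-monotone genes (half induced, half suppressed with
  gestational age), planted tissue-marker genes whose abundance in AF
  follows a per-tissue stage-activity table, and reserved fetal-sex marker
  genes (XIST high in females; RPS4Y1/DDX3Y/EIF1AY high in males);
* a tissue expression atlas in which each tissue's markers are a fixed fold
  above the mean of the other tissues;
* per-sample splice-junction files containing planted cassette-exon events
  whose inclusion level (PSI) shifts between late-preterm and term groups,
  plus decoy junctions that belong to no event;
* optionally a deep "body map"-like junction panel containing a configured
  fraction of the planted events.

Everything is drawn from a single seeded generator: the same seed yields a
byte-identical bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    ExpressionMatrix,
    JunctionRecord,
    MarkerDatabase,
    SampleMetadata,
    TissueAtlas,
    ValidationError,
    write_expression_matrix,
    write_junctions_bed,
    write_marker_database,
    write_sample_metadata,
    write_tissue_atlas,
)
from .splicing_psi import make_event_id

XIST_GENE = "XIST"
CHR_Y_GENES = ("RPS4Y1", "DDX3Y", "EIF1AY")

#: per-tissue marker-activity patterns (fraction of the tissue's markers
#: detectable in AF at PN, PT, FT); tissues cycle through these, emulating
#: organ systems that come online at different gestational ages
_MATURATION_PATTERNS = (
    (0.1, 0.3, 0.5),   # ramp up with gestation
    (0.0, 0.1, 0.4),   # late-activating (e.g. lung surfactant program)
    (0.4, 0.2, 0.1),   # early, fading
    (0.2, 0.2, 0.2),   # constitutive
    (0.0, 0.0, 0.1),   # barely detectable
    (0.1, 0.4, 0.2),   # transient mid-gestation
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the cohort layout (group sizes 4/6/6) and otherwise use
    effect sizes a cfRNA study of this design could plausibly resolve.
    """

    n_genes: int = 2000
    n_tissues: int = 66
    markers_per_tissue: int = 10
    group_sizes: tuple[int, int, int] = (4, 6, 6)
    stage_effect_log2: float = 1.5
    marker_expression_fold: float = 8.0
    noise_sd_log2: float = 0.4
    n_monotone_genes: int = 200
    n_splicing_events: int = 50
    psi_shift: float = 0.3
    base_junction_depth: int = 60
    seed: int = 0
    # elevation (log2) of a marker gene in AF samples of stages where active
    activity_log2: float = 6.0
    # "maturation": per-tissue stage-varying activity; "constant": identical
    # activity in all stages (a stage-null configuration)
    activity_profile: str = "maturation"
    n_decoy_junctions: int = 20
    # fraction of planted events fully present in the reference panel
    panel_fraction: float = 0.5
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 1.5

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_tissues", "markers_per_tissue", "base_junction_depth"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("n_monotone_genes", "n_splicing_events", "n_decoy_junctions"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if len(self.group_sizes) != 3 or any(g <= 0 for g in self.group_sizes):
            raise ValidationError("group_sizes must be three positive counts")
        if self.noise_sd_log2 < 0:
            raise ValidationError("noise_sd_log2 must be >= 0")
        if not (0.0 <= self.psi_shift <= 0.7):
            # base PSI is drawn from [0.15, 0.85 - shift]; larger shifts
            # would push a group mean outside [0, 1]
            raise ValidationError("psi_shift must be in [0, 0.7]")
        if not (0.0 <= self.panel_fraction <= 1.0):
            raise ValidationError("panel_fraction must be in [0, 1]")
        if self.activity_profile not in ("maturation", "constant"):
            raise ValidationError(f"unknown activity_profile {self.activity_profile!r}")
        n_markers = self.n_tissues * self.markers_per_tissue
        reserved = n_markers + self.n_monotone_genes + 1 + len(CHR_Y_GENES)
        if reserved > self.n_genes:
            raise ValidationError(
                f"n_genes={self.n_genes} too small for {n_markers} markers + "
                f"{self.n_monotone_genes} monotone genes + sex markers"
            )


@dataclass
class GroundTruth:
    """Planted parameters of a simulated bundle; consumed only by tests and
    by recovery/benchmark reporting, never by the pipeline itself."""

    induced_gene_ids: list[str]
    suppressed_gene_ids: list[str]
    tissue_marker_map: dict[str, list[str]]
    # tissue -> stage -> realized fraction of that tissue's markers active
    marker_activity: dict[str, dict[str, float]]
    # stage -> set of marker genes elevated in AF at that stage
    active_markers: dict[str, list[str]]
    # event id -> stage -> true PSI
    splicing_truth: dict[str, dict[str, float]]
    # event id -> gene symbol assigned to the event's junctions
    event_genes: dict[str, str]
    # event ids fully present in the reference junction panel
    panel_events: list[str]
    sample_sex: dict[str, str]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class StudyBundle:
    expression: ExpressionMatrix
    metadata: list[SampleMetadata]
    atlas: TissueAtlas
    markers: MarkerDatabase
    junctions: dict[str, list[JunctionRecord]]  # sample id -> records
    panel: list[JunctionRecord]
    junction_gene_map: dict[tuple[str, int, int], str]
    truth: GroundTruth


def simulate_study(config: SimulationConfig) -> StudyBundle:
    """Generate the full synthetic study bundle from a single seed."""
    rng = np.random.default_rng(config.seed)

    samples = _make_metadata(config)
    sample_ids = [s.sample_id for s in samples]
    stages = np.array([s.stage for s in samples])
    stage_step = {"PN": 0, "PT": 1, "FT": 2}

    n_markers = config.n_tissues * config.markers_per_tissue
    tissues = [f"tissue_{i + 1:02d}" for i in range(config.n_tissues)]
    n_generic = config.n_genes - 1 - len(CHR_Y_GENES)
    gene_ids = [f"G{i + 1:05d}" for i in range(n_generic)]
    gene_ids += [XIST_GENE, *CHR_Y_GENES]

    marker_genes = gene_ids[:n_markers]
    tissue_marker_map = {
        t: marker_genes[i * config.markers_per_tissue:(i + 1) * config.markers_per_tissue]
        for i, t in enumerate(tissues)
    }
    n_half = config.n_monotone_genes // 2
    induced = gene_ids[n_markers:n_markers + n_half]
    suppressed = gene_ids[n_markers + n_half:n_markers + config.n_monotone_genes]

    # --- stage-activity table for markers -------------------------------
    marker_activity: dict[str, dict[str, float]] = {}
    active_markers: dict[str, set[str]] = {"PN": set(), "PT": set(), "FT": set()}
    for i, t in enumerate(tissues):
        if config.activity_profile == "constant":
            fracs = (0.2, 0.2, 0.2)
        else:
            fracs = _MATURATION_PATTERNS[i % len(_MATURATION_PATTERNS)]
        row: dict[str, float] = {}
        for stage, frac in zip(("PN", "PT", "FT"), fracs):
            k = int(round(frac * config.markers_per_tissue))
            row[stage] = k / config.markers_per_tissue
            active_markers[stage].update(tissue_marker_map[t][:k])
        marker_activity[t] = row

    # --- expression matrix ----------------------------------------------
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd,
                          size=config.n_genes)
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    # markers get a fixed modest baseline so that, when inactive, they stay
    # clear of the top-decile abundance cut in every stage
    for g in marker_genes:
        baseline[gene_index[g]] = 2.0

    log2_mu = np.tile(baseline[:, None], (1, len(samples)))
    steps = np.array([stage_step[s] for s in stages], dtype=float)
    for g in induced:
        log2_mu[gene_index[g], :] += config.stage_effect_log2 * steps
    for g in suppressed:
        log2_mu[gene_index[g], :] += config.stage_effect_log2 * (2.0 - steps)
    for stage in ("PN", "PT", "FT"):
        cols = np.flatnonzero(stages == stage)
        for g in active_markers[stage]:
            log2_mu[np.ix_([gene_index[g]], cols)] += config.activity_log2

    sex = np.array([s.fetal_sex for s in samples])
    male_cols = np.flatnonzero(sex == "male")
    female_cols = np.flatnonzero(sex == "female")
    log2_mu[gene_index[XIST_GENE], female_cols] = 7.0
    log2_mu[gene_index[XIST_GENE], male_cols] = -1.0
    for g in CHR_Y_GENES:
        log2_mu[gene_index[g], male_cols] = 6.0
        log2_mu[gene_index[g], female_cols] = -3.0

    noise = rng.normal(0.0, config.noise_sd_log2, size=log2_mu.shape)
    values = np.exp2(log2_mu + noise)
    expression = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids), scale="rpkm"
    )

    # --- tissue atlas ----------------------------------------------------
    atlas_base = rng.normal(config.baseline_log2_mean, 1.0, size=config.n_genes)
    atlas_noise = rng.normal(0.0, config.noise_sd_log2,
                             size=(config.n_genes, config.n_tissues))
    atlas_values = np.exp2(atlas_base[:, None] + atlas_noise)
    tissue_index = {t: j for j, t in enumerate(tissues)}
    for t, genes in tissue_marker_map.items():
        j = tissue_index[t]
        for g in genes:
            i = gene_index[g]
            others = np.delete(atlas_values[i], j)
            atlas_values[i, j] = config.marker_expression_fold * others.mean()
    atlas = TissueAtlas(pd.DataFrame(atlas_values, index=gene_ids, columns=tissues))
    markers = MarkerDatabase(tissue_marker_map)

    # --- junctions --------------------------------------------------------
    (junctions, splicing_truth, event_genes, panel,
     panel_events, junction_gene_map) = simulate_junctions(config, samples, rng)

    truth = GroundTruth(
        induced_gene_ids=list(induced),
        suppressed_gene_ids=list(suppressed),
        tissue_marker_map={t: list(g) for t, g in tissue_marker_map.items()},
        marker_activity=marker_activity,
        active_markers={s: sorted(g) for s, g in active_markers.items()},
        splicing_truth=splicing_truth,
        event_genes=event_genes,
        panel_events=panel_events,
        sample_sex={s.sample_id: s.fetal_sex for s in samples},
    )
    return StudyBundle(
        expression=expression,
        metadata=samples,
        atlas=atlas,
        markers=markers,
        junctions=junctions,
        panel=panel,
        junction_gene_map=junction_gene_map,
        truth=truth,
    )


def _make_metadata(config: SimulationConfig) -> list[SampleMetadata]:
    """Sample sheet: stages PN/PT/FT with sexes balanced within each stage
    (so sex markers carry no stage signal) and the late-preterm morbidity
    layout of the emulated cohort (2 respiratory, 2 gavage, 1 both, 1 none
    when the group has 6 samples; proportional otherwise)."""
    n_pn, n_pt, n_ft = config.group_sizes
    weeks = {"PN": 20.0, "PT": 35.0, "FT": 39.0}
    samples: list[SampleMetadata] = []
    counter = 0
    for stage, n in zip(("PN", "PT", "FT"), (n_pn, n_pt, n_ft)):
        for i in range(n):
            counter += 1
            flags: frozenset[str] = frozenset()
            if stage == "PT":
                if i in (0, 1):
                    flags = frozenset({"respiratory_support"})
                elif i in (2, 3):
                    flags = frozenset({"gavage_feeding"})
                elif i == 4:
                    flags = frozenset({"respiratory_support", "gavage_feeding"})
            samples.append(
                SampleMetadata(
                    sample_id=f"AF{counter:02d}",
                    stage=stage,
                    gestational_weeks=weeks[stage],
                    fetal_sex="male" if i % 2 == 0 else "female",
                    morbidity_flags=flags,
                )
            )
    return samples


def draw_event_counts(rng: np.random.Generator, depth: int, psi: float
                      ) -> tuple[int, int, int]:
    """Draw (inclusion1, inclusion2, exclusion) junction read counts for one
    cassette event in one sample.

    ``n_incl ~ Binomial(depth, psi)`` reads support inclusion and the rest
    exclusion, so the event-level PSI estimate ``n_incl/depth`` is exactly
    binomial around the true PSI; the inclusion reads are then split
    between the two flanking junctions, preserving their average."""
    n_incl = int(rng.binomial(depth, psi))
    excl = depth - n_incl
    incl1 = int(rng.binomial(2 * n_incl, 0.5)) if n_incl > 0 else 0
    incl2 = 2 * n_incl - incl1
    return incl1, incl2, excl


def simulate_junctions(
    config: SimulationConfig,
    samples: list[SampleMetadata],
    rng: np.random.Generator,
) -> tuple[dict[str, list[JunctionRecord]], dict[str, dict[str, float]],
           dict[str, str], list[JunctionRecord], list[str],
           dict[tuple[str, int, int], str]]:
    """Generate per-sample junction records for the planted cassette events.

    Each event contributes two inclusion junctions and one exclusion
    junction sharing its outer boundaries.  Per-sample read depth is Poisson
    around ``base_junction_depth``; inclusion/exclusion counts are binomial
    at the sample's stage-specific true PSI.  The true PSI shifts by
    ``psi_shift`` between the late-preterm and term groups (alternating
    direction across events); the prenatal group follows late-preterm.
    """
    chrom = "chr1"
    splicing_truth: dict[str, dict[str, float]] = {}
    event_genes: dict[str, str] = {}
    junction_gene_map: dict[tuple[str, int, int], str] = {}
    event_coords: list[tuple[tuple[int, int], tuple[int, int], tuple[int, int]]] = []
    event_ids: list[str] = []

    lo = 0.15
    hi = 0.85 - config.psi_shift
    for e in range(config.n_splicing_events):
        s = 10_000 * (e + 1)
        incl1 = (s, s + 400)
        incl2 = (s + 500, s + 900)
        excl = (s, s + 900)
        event_id = make_event_id(chrom, excl, [incl1, incl2])
        base = float(rng.uniform(lo, max(lo, hi)))
        if e % 2 == 0:
            psi = {"PN": base, "PT": base, "FT": base + config.psi_shift}
        else:
            psi = {"PN": base + config.psi_shift, "PT": base + config.psi_shift,
                   "FT": base}
        gene = f"SPLG{e + 1:04d}"
        splicing_truth[event_id] = psi
        event_genes[event_id] = gene
        event_coords.append((incl1, incl2, excl))
        event_ids.append(event_id)
        for start, end in (incl1, incl2, excl):
            junction_gene_map[(chrom, start, end)] = gene

    decoys = [(1_000_000 + 5_000 * d + 123, 1_000_000 + 5_000 * d + 456)
              for d in range(config.n_decoy_junctions)]

    junctions: dict[str, list[JunctionRecord]] = {}
    for sample in samples:
        recs: list[JunctionRecord] = []
        for (incl1, incl2, excl), eid in zip(event_coords, event_ids):
            depth = max(1, int(rng.poisson(config.base_junction_depth)))
            c1, c2, ce = draw_event_counts(
                rng, depth, splicing_truth[eid][sample.stage]
            )
            for (start, end), count in ((incl1, c1), (incl2, c2), (excl, ce)):
                recs.append(JunctionRecord(chrom, start, end, "+", count,
                                           sample.sample_id))
        for start, end in decoys:
            count = int(rng.poisson(config.base_junction_depth / 2))
            recs.append(JunctionRecord("chr2", start, end, "+", count,
                                       sample.sample_id))
        recs.sort(key=lambda r: (r.chrom, r.intron_start, r.intron_end))
        junctions[sample.sample_id] = recs

    # deep reference panel containing a fixed fraction of the events
    n_in_panel = int(round(config.panel_fraction * config.n_splicing_events))
    panel_events = event_ids[:n_in_panel]
    panel: list[JunctionRecord] = []
    for (incl1, incl2, excl), eid in zip(event_coords, event_ids):
        if eid not in panel_events:
            continue
        for start, end in (incl1, incl2, excl):
            panel.append(JunctionRecord(chrom, start, end, "+", 1000, "panel"))
    panel.sort(key=lambda r: (r.chrom, r.intron_start, r.intron_end))
    return junctions, splicing_truth, event_genes, panel, panel_events, junction_gene_map


def write_bundle(bundle: StudyBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write every bundle component plus ground_truth.json into a directory;
    returns the mapping of component name to path."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "metadata": out / "metadata.tsv",
        "atlas": out / "atlas.tsv",
        "markers": out / "markers.gmt",
        "panel": out / "panel.bed",
        "junction_gene_map": out / "junction_genes.tsv",
        "ground_truth": out / "ground_truth.json",
    }
    write_expression_matrix(bundle.expression, paths["expression"])
    write_sample_metadata(bundle.metadata, paths["metadata"])
    write_tissue_atlas(bundle.atlas, paths["atlas"])
    write_marker_database(bundle.markers, paths["markers"])
    write_junctions_bed(bundle.panel, paths["panel"])
    junc_dir = out / "junctions"
    junc_dir.mkdir(exist_ok=True)
    for sid, recs in bundle.junctions.items():
        p = junc_dir / f"{sid}.bed"
        write_junctions_bed(recs, p)
        paths[f"junctions/{sid}"] = p
    with open(paths["junction_gene_map"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("chrom\tintron_start\tintron_end\tgene\n")
        for (chrom, start, end), gene in sorted(bundle.junction_gene_map.items()):
            fh.write(f"{chrom}\t{start}\t{end}\t{gene}\n")
    with open(paths["ground_truth"], "w", encoding="utf-8", newline="\n") as fh:
        json.dump(bundle.truth.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
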