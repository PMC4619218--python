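"""Normalization, expression filtering and differential testing across
gestational stages and morbidity groups.

The workflow mirrors standard bulk RNA-seq practice for a small cohort:
trimmed-mean (TMM-style) between-sample normalization, an RPKM > 1
detectability filter, one-way ANOVA across the three stages with
Benjamini-Hochberg FDR control plus pairwise fold-change calls, an
empirical-Bayes moderated t-test for the tiny morbidity subgroups, and
classification of differential genes into gestationally induced or
suppressed temporal patterns (monotone-sign rule or a 1-D self-organizing
map).

All log-scale statistics use log2(value + 1): the pseudocount bounds fold
changes and tames zeros in RPKM-scale data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix, SampleMetadata, ValidationError

PSEUDOCOUNT = 1.0
CONTRASTS = (("PN", "FT"), ("PN", "PT"), ("PT", "FT"))


@dataclass(frozen=True)
class PairwiseStat:
    fold_change: float        # ratio >= 1 of pseudocounted group means
    direction: str            # "up" = second group higher, "down" = lower
    p: float


@dataclass(frozen=True)
class DifferentialResult:
    gene_id: str
    anova_p: float
    anova_p_adjusted: float
    pairwise: dict[tuple[str, str], PairwiseStat]
    is_differential: bool
    trend: str = "none"       # "induced" | "suppressed" | "none"


@dataclass(frozen=True)
class ModeratedTResult:
    gene_id: str
    log_fold_change: float    # log2, group B minus group A
    t_moderated: float
    p: float
    p_adjusted: float
    prior_df: float           # d0 (may be inf)
    prior_variance: float     # s0^2
    is_regulated: bool


# ---------------------------------------------------------------------------
# normalization & filtering
# ---------------------------------------------------------------------------

def tmm_normalize(
    counts: ExpressionMatrix,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
    ref_sample: str | None = None,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Trimmed-mean-of-M-values scaling of a count-scale matrix.

    Each sample's factor is exp2 of the weighted mean of per-gene log2
    ratios against a reference sample, after trimming the most extreme
    ``trim_m`` fraction from each tail by log-ratio (M) and ``trim_a`` by
    average log abundance (A); weights are inverse approximate binomial
    variances.  Factors are rescaled to geometric mean 1 and divided out of
    the matrix.  Genes with a zero in either sample are excluded from that
    sample's factor estimate.
    """
    df = counts.data
    if df.shape[1] < 2:
        raise ValidationError("TMM needs at least 2 samples")
    lib = df.sum(axis=0)
    zero_samples = lib.index[lib == 0].tolist()
    if zero_samples:
        raise ValidationError(f"all-zero sample(s): {zero_samples}")
    if ref_sample is None:
        # sample whose upper quartile is most typical
        uq = df.apply(lambda c: np.quantile(c[c > 0], 0.75) if (c > 0).any() else 0.0)
        ref_sample = (uq - uq.mean()).abs().idxmin()
    ref = df[ref_sample].to_numpy(dtype=float)
    n_ref = float(ref.sum())

    log_factors = {}
    for sid in df.columns:
        if sid == ref_sample:
            log_factors[sid] = 0.0
            continue
        obs = df[sid].to_numpy(dtype=float)
        n_obs = float(obs.sum())
        ok = (obs > 0) & (ref > 0)
        o, r = obs[ok], ref[ok]
        m = np.log2(o / r)
        a = 0.5 * np.log2(o * r)
        keep = _double_trim_mask(m, a, trim_m, trim_a)
        if not keep.any():
            keep = np.ones_like(m, dtype=bool)
        w = 1.0 / ((n_obs - o[keep]) / (n_obs * o[keep])
                   + (n_ref - r[keep]) / (n_ref * r[keep]))
        log_factors[sid] = float(np.sum(w * m[keep]) / np.sum(w))

    factors = pd.Series({sid: 2.0 ** lf for sid, lf in log_factors.items()})
    factors = factors[df.columns]
    factors /= np.exp(np.log(factors).mean())  # geometric mean 1
    normalized = ExpressionMatrix(df.div(factors, axis=1), scale=counts.scale)
    return normalized, factors


def _double_trim_mask(m: np.ndarray, a: np.ndarray,
                      trim_m: float, trim_a: float) -> np.ndarray:
    """Keep genes inside the [trim, 1-trim] rank window on both M and A."""
    n = len(m)
    rank_m = stats.rankdata(m, method="average")
    rank_a = stats.rankdata(a, method="average")
    lo_m, hi_m = n * trim_m + 1, n * (1 - trim_m)
    lo_a, hi_a = n * trim_a + 1, n * (1 - trim_a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    return keep


def filter_expressed(m: ExpressionMatrix, rpkm_min: float = 1.0) -> ExpressionMatrix:
    """Keep genes exceeding ``rpkm_min`` in at least one sample."""
    keep = m.data.max(axis=1) > rpkm_min
    return ExpressionMatrix(m.data.loc[keep], scale=m.scale)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must be finite and within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# stage ANOVA
# ---------------------------------------------------------------------------

def _stage_columns(m: ExpressionMatrix, metadata: Sequence[SampleMetadata],
                   min_per_group: int = 2) -> dict[str, list[str]]:
    present = set(m.sample_ids)
    groups = {stage: [s.sample_id for s in metadata
                      if s.stage == stage and s.sample_id in present]
              for stage in ("PN", "PT", "FT")}
    small = [st for st, ids in groups.items() if len(ids) < min_per_group]
    if small:
        raise ValidationError(f"stage(s) with < {min_per_group} samples: {small}")
    return groups


def anova_stage_test(
    m: ExpressionMatrix,
    metadata: Sequence[SampleMetadata],
    alpha: float = 0.05,
    fold_min: float = 1.5,
) -> list[DifferentialResult]:
    """One-way ANOVA across PN/PT/FT on log2(RPKM+1) per gene, BH-adjusted,
    plus the three pairwise contrasts with linear-scale fold changes.

    A gene is differential when its adjusted ANOVA p <= ``alpha`` and at
    least one pairwise fold change >= ``fold_min``.  Genes with zero
    between-group variance report p = 1.
    """
    groups = _stage_columns(m, metadata)
    logm = np.log2(m.data + PSEUDOCOUNT)
    blocks = {st: logm[ids].to_numpy() for st, ids in groups.items()}
    lin_means = {st: (m.data[ids].mean(axis=1) + PSEUDOCOUNT).to_numpy()
                 for st, ids in groups.items()}

    anova_p = _vectorized_anova([blocks[st] for st in ("PN", "PT", "FT")])
    adj = benjamini_hochberg(anova_p)

    pairwise_stats: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for ga, gb in CONTRASTS:
        ratio = lin_means[gb] / lin_means[ga]
        fold = np.maximum(ratio, 1.0 / ratio)
        with np.errstate(invalid="ignore"):
            tp = stats.ttest_ind(blocks[gb], blocks[ga], axis=1).pvalue
        tp = np.where(np.isfinite(tp), tp, 1.0)  # zero-variance ties -> 1
        pairwise_stats[(ga, gb)] = (fold, ratio, tp)

    results = []
    for i, gene in enumerate(m.gene_ids):
        pw = {
            (ga, gb): PairwiseStat(
                fold_change=float(pairwise_stats[(ga, gb)][0][i]),
                direction="up" if pairwise_stats[(ga, gb)][1][i] >= 1.0 else "down",
                p=float(pairwise_stats[(ga, gb)][2][i]),
            )
            for ga, gb in CONTRASTS
        }
        max_fold = max(s.fold_change for s in pw.values())
        results.append(
            DifferentialResult(
                gene_id=gene,
                anova_p=float(anova_p[i]),
                anova_p_adjusted=float(adj[i]),
                pairwise=pw,
                is_differential=bool(adj[i] <= alpha and max_fold >= fold_min),
            )
        )
    return results


def _vectorized_anova(blocks: list[np.ndarray]) -> np.ndarray:
    """One-way fixed-effects F-test per row across the given group blocks.

    Degenerate rows: zero between-group variance -> p = 1; positive
    between- with zero within-group variance -> p = 0.
    """
    ns = [b.shape[1] for b in blocks]
    n_total = sum(ns)
    k = len(blocks)
    grand = np.hstack(blocks).mean(axis=1)
    ssb = sum(n * (b.mean(axis=1) - grand) ** 2 for n, b in zip(ns, blocks))
    ssw = sum(((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) for b in blocks)
    df_b, df_w = k - 1, n_total - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df_b) / (ssw / df_w)
        p = stats.f.sf(f, df_b, df_w)
    tol = 1e-12
    p = np.where(ssb <= tol * np.maximum(ssw, 1.0), 1.0, p)
    p = np.where((ssw <= tol) & (ssb > tol), 0.0, p)
    return p


# ---------------------------------------------------------------------------
# moderated t-test (empirical Bayes variance shrinkage)
# ---------------------------------------------------------------------------

def _select_group(metadata: Sequence[SampleMetadata], group: str) -> list[str]:
    if group in ("PN", "PT", "FT"):
        ids = [s.sample_id for s in metadata if s.stage == group]
    else:
        ids = [s.sample_id for s in metadata if group in s.morbidity_flags]
    if not ids:
        raise ValidationError(f"no samples match group {group!r}")
    return ids


def _trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone decreasing)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < tol * y:
            break
    return y


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior (d0, s0^2) to the
    observed per-gene residual variances.

    Works on log variances: if s^2 ~ s0^2 * F(df, d0) then
    E[log s^2] and Var[log s^2] have closed digamma/trigamma forms; the
    excess of the observed log-variance spread over the chi-square part
    determines d0 (via the inverse trigamma), and the mean determines s0^2.
    Returns d0 = inf (no excess spread) when variances are essentially
    exchangeable with a single value.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        return np.inf, float(np.median(s2)) if s2.size else 1.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    n = z.size
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_t_test(
    m: ExpressionMatrix,
    metadata: Sequence[SampleMetadata],
    group_a: str,
    group_b: str,
    fold_min: float = 2.0,
    alpha: float = 0.05,
    prior_df: float | None = None,
) -> list[ModeratedTResult]:
    """Two-group empirical-Bayes moderated t-test on log2(RPKM+1).

    Per-gene pooled variances are shrunk toward the moment-matched prior:
    s_tilde^2 = (d0*s0^2 + d*s^2) / (d0 + d); the moderated t uses d + d0
    degrees of freedom.  ``prior_df`` overrides the estimated d0 (0 recovers
    the ordinary two-sample t-test exactly).  A gene is regulated when the
    (unadjusted) p <= ``alpha`` and its fold change exceeds ``fold_min`` on
    the ratio scale; BH-adjusted p-values are reported alongside.
    """
    ids_a = _select_group(metadata, group_a)
    ids_b = _select_group(metadata, group_b)
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValidationError("each group needs >= 2 samples")
    if m.data.shape[0] == 0:
        raise ValidationError("no genes to test")

    logm = np.log2(m.data + PSEUDOCOUNT)
    a = logm[ids_a].to_numpy()
    b = logm[ids_b].to_numpy()
    na, nb = a.shape[1], b.shape[1]
    df_resid = float(na + nb - 2)

    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    lfc = mean_b - mean_a
    ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + ((b - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid

    if prior_df is None:
        d0, s0_sq = estimate_variance_prior(s2, df_resid)
    else:
        d0 = float(prior_df)
        s0_sq = float(np.median(s2[s2 > 0])) if np.any(s2 > 0) else 1.0

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = df_resid + d0

    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / se
    t = np.where(se > 0, t, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(lfc == 0.0, 1.0, p)
    adj = benjamini_hochberg(p)

    fold = np.exp2(np.abs(lfc))
    return [
        ModeratedTResult(
            gene_id=g,
            log_fold_change=float(lfc[i]),
            t_moderated=float(t[i]),
            p=float(p[i]),
            p_adjusted=float(adj[i]),
            prior_df=float(d0),
            prior_variance=float(s0_sq),
            is_regulated=bool(p[i] <= alpha and fold[i] > fold_min),
        )
        for i, g in enumerate(m.gene_ids)
    ]


# ---------------------------------------------------------------------------
# temporal-pattern classification
# ---------------------------------------------------------------------------

def classify_temporal_patterns(
    results: Sequence[DifferentialResult],
    m: ExpressionMatrix,
    metadata: Sequence[SampleMetadata],
    method: Literal["sign", "som"] = "sign",
    som_nodes: int = 2,
    som_epochs: int = 500,
    seed: int = 0,
    flat_tol: float = 0.0,
) -> list[DifferentialResult]:
    """Label each differential gene induced or suppressed with gestation.

    sign: stage means (log2) must rise PN -> PT -> FT, allowing one flat
    step (within ``flat_tol``), for "induced"; the mirror for "suppressed";
    anything else is "none".

    som: a seeded 1-D self-organizing map on z-scored stage-mean triples;
    each node is labelled by the slope of its codebook vector and genes
    inherit their winning node's label.

    Non-differential genes keep trend "none".  Returns new result records.
    """
    if method not in ("sign", "som"):
        raise ValidationError(f"unknown method {method!r}")
    groups = _stage_columns(m, metadata, min_per_group=1)
    logm = np.log2(m.data + PSEUDOCOUNT)
    means = np.column_stack([logm[groups[st]].mean(axis=1) for st in ("PN", "PT", "FT")])
    gene_pos = {g: i for i, g in enumerate(m.gene_ids)}

    diff_idx = [gene_pos[r.gene_id] for r in results if r.is_differential]
    labels: dict[int, str] = {}
    if method == "sign":
        for i in diff_idx:
            labels[i] = _sign_trend(means[i], flat_tol)
    elif diff_idx:
        triples = means[diff_idx]
        z = (triples - triples.mean(axis=1, keepdims=True))
        sd = triples.std(axis=1, keepdims=True)
        z = np.divide(z, sd, out=np.zeros_like(z), where=sd > 0)
        codebook = _fit_som_1d(z, som_nodes, som_epochs, seed)
        node_label = ["induced" if cb[2] > cb[0] else "suppressed" if cb[2] < cb[0]
                      else "none" for cb in codebook]
        winners = np.argmin(
            ((z[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2), axis=1
        )
        for i, w in zip(diff_idx, winners):
            labels[i] = node_label[w]

    return [
        DifferentialResult(
            gene_id=r.gene_id,
            anova_p=r.anova_p,
            anova_p_adjusted=r.anova_p_adjusted,
            pairwise=r.pairwise,
            is_differential=r.is_differential,
            trend=labels.get(gene_pos[r.gene_id], "none"),
        )
        for r in results
    ]


def _sign_trend(stage_means: np.ndarray, flat_tol: float) -> str:
    d1 = stage_means[1] - stage_means[0]
    d2 = stage_means[2] - stage_means[1]
    if d1 >= -flat_tol and d2 >= -flat_tol and (d1 > flat_tol or d2 > flat_tol):
        return "induced"
    if d1 <= flat_tol and d2 <= flat_tol and (d1 < -flat_tol or d2 < -flat_tol):
        return "suppressed"
    return "none"


def _fit_som_1d(data: np.ndarray, n_nodes: int, epochs: int, seed: int) -> np.ndarray:
    """Train a 1-D rectangular SOM (Gaussian neighbourhood, learning rate
    decaying linearly 0.5 -> 0.01) and return the codebook (n_nodes x dim)."""
    rng = np.random.default_rng(seed)
    n, dim = data.shape
    idx = rng.choice(n, size=n_nodes, replace=n < n_nodes)
    codebook = data[idx].astype(float).copy()
    positions = np.arange(n_nodes, dtype=float)
    sigma0 = max(n_nodes / 2.0, 1.0)
    for epoch in range(epochs):
        frac = epoch / max(epochs - 1, 1)
        lr = 0.5 + (0.01 - 0.5) * frac
        sigma = sigma0 + (0.5 - sigma0) * frac
        order = rng.permutation(n)
        for i in order:
            x = data[i]
            winner = int(np.argmin(((codebook - x) ** 2).sum(axis=1)))
            h = np.exp(-((positions - winner) ** 2) / (2.0 * sigma ** 2))
            codebook += lr * h[:, None] * (x - codebook)
    return codebook
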