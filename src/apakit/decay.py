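"""Isoform-specific mRNA decay from transcription-shutoff time courses.

After transcription is blocked (actinomycin-D style chase), transcript
abundance decays approximately exponentially, count(t) = c0 * exp(-k t).
Each isoform's decay constant k is estimated by ordinary least squares of
ln(count) on time; half-life t1/2 = ln(2)/k. Quality gates follow common
practice for such fits: at least 10 counts at t = 0, at least 3 usable
timepoints, R^2 > 0.6 on the log scale, and a positive decay constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from apakit import stats as _stats
from apakit.io import GeneSiteMap, SiteCountMatrix

QC_OK = "ok"
QC_LOW_T0 = "low_t0"
QC_POOR_FIT = "poor_fit"
QC_NONPOSITIVE_K = "nonpositive_k"
QC_TOO_FEW_POINTS = "too_few_points"


@dataclass
class DecayFit:
    """Log-linear decay fit for one isoform in one condition/replicate."""

    site_id: str
    gene_id: str
    condition: str
    k: float
    half_life_h: float
    r2: float
    n_points_used: int
    qc: str


def fit_decay(
    counts_by_time: dict[float, float],
    min_t0: int = 10,
    r2_min: float = 0.6,
    site_id: str = "",
    gene_id: str = "",
    condition: str = "",
) -> DecayFit:
    """Fit ln(count) = ln(c0) - k*t by least squares over positive timepoints.

    Zero-count timepoints are dropped (not pseudocounted). ``qc`` is the
    first failed gate among: low_t0 (count at t=0 below ``min_t0``),
    too_few_points (< 3 positive timepoints), poor_fit (R^2 <= ``r2_min``),
    nonpositive_k. Half-life is reported whenever k > 0, but only qc="ok"
    fits should enter downstream comparisons.
    """
    times = np.array(sorted(counts_by_time), dtype=float)
    if 0.0 not in counts_by_time:
        raise ValueError("time course must include t = 0")
    if len(times) < 2:
        raise ValueError("need >= 2 timepoints")
    counts = np.array([counts_by_time[t] for t in times], dtype=float)
    if (counts < 0).any():
        raise ValueError("negative counts")
    pos = counts > 0
    t_used, c_used = times[pos], counts[pos]
    n_used = int(pos.sum())

    k = np.nan
    r2 = np.nan
    if n_used >= 2:
        if len(np.unique(t_used)) < 2:
            raise ValueError("need >= 2 distinct positive timepoints for a fit")
        fit = sps.linregress(t_used, np.log(c_used))
        k = -fit.slope
        r2 = float(fit.rvalue**2)

    if n_used == 0:
        qc = QC_TOO_FEW_POINTS
    elif counts_by_time[0.0] < min_t0:
        qc = QC_LOW_T0
    elif n_used < 3:
        qc = QC_TOO_FEW_POINTS
    elif r2 <= r2_min:
        qc = QC_POOR_FIT
    elif k <= 0:
        qc = QC_NONPOSITIVE_K
    else:
        qc = QC_OK
    half_life = float(np.log(2) / k) if np.isfinite(k) and k > 0 else np.nan
    return DecayFit(site_id, gene_id, condition, float(k), half_life, r2, n_used, qc)


def fit_decay_matrix(
    m: SiteCountMatrix,
    gene_maps: dict[str, GeneSiteMap] | None = None,
    min_t0: int = 10,
    r2_min: float = 0.6,
) -> pd.DataFrame:
    """Fit every site in every (condition, replicate) time course.

    The sample sheet's ``timepoint_h`` column defines the series; each
    replicate is fit separately. Returns one row per (site, condition,
    replicate) with the fit parameters and QC flag.
    """
    site_gene = {}
    if gene_maps:
        for gm in gene_maps.values():
            for s in gm.sites:
                site_gene[s.site_id] = gm.gene_id
    rows = []
    groups = m.samples.groupby(["condition", "replicate"], sort=True)
    for (condition, replicate), sheet in groups:
        tps = sheet["timepoint_h"].astype(float)
        if tps.duplicated().any():
            raise ValueError(
                f"duplicate timepoints for condition {condition!r} replicate {replicate}"
            )
        sample_by_time = dict(zip(tps, sheet.index))
        for site_id in m.site_ids:
            series = {
                t: float(m.counts.loc[site_id, sid]) for t, sid in sample_by_time.items()
            }
            fit = fit_decay(
                series,
                min_t0=min_t0,
                r2_min=r2_min,
                site_id=site_id,
                gene_id=site_gene.get(site_id, ""),
                condition=str(condition),
            )
            rows.append(
                {
                    "site_id": site_id,
                    "gene_id": fit.gene_id,
                    "condition": fit.condition,
                    "replicate": replicate,
                    "k": fit.k,
                    "half_life_h": fit.half_life_h,
                    "r2": fit.r2,
                    "n_points_used": fit.n_points_used,
                    "qc": fit.qc,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class StabilityComparison:
    """Paired proximal-vs-distal half-life comparison within one condition."""

    condition: str
    n_pairs: int
    median_proximal_h: float
    median_distal_h: float
    statistic: float | None
    p_two_tailed: float | None
    warning: str | None


def compare_isoform_stability(
    fits: pd.DataFrame,
    gene_maps: dict[str, GeneSiteMap],
    min_pairs: int = 5,
) -> list[StabilityComparison]:
    """Compare proximal vs distal isoform half-lives per condition.

    For each gene with both isoforms passing QC in a condition, half-lives
    (replicate-averaged) are paired and compared by Wilcoxon signed-rank.
    Fewer than ``min_pairs`` pairs yields a descriptive report with a
    warning and no p-value.
    """
    ok = fits[fits["qc"] == QC_OK]
    # replicate-average half-lives per (site, condition)
    hl = ok.groupby(["site_id", "condition"])["half_life_h"].mean()
    out = []
    for condition in sorted(fits["condition"].unique()):
        prox, dist = [], []
        for gm in gene_maps.values():
            if gm.n_sites < 2:
                continue
            kp = (gm.proximal.site_id, condition)
            kd = (gm.distal.site_id, condition)
            if kp in hl.index and kd in hl.index:
                prox.append(hl[kp])
                dist.append(hl[kd])
        n = len(prox)
        if n == 0:
            continue
        prox_arr, dist_arr = np.array(prox), np.array(dist)
        if n < min_pairs:
            warnings.warn(
                f"condition {condition!r}: only {n} proximal/distal pairs; no test run"
            )
            out.append(
                StabilityComparison(
                    condition, n, float(np.median(prox_arr)), float(np.median(dist_arr)),
                    None, None, f"fewer than {min_pairs} pairs",
                )
            )
            continue
        stat, p = _stats.rank_tests(dist_arr, prox_arr, paired=True)
        out.append(
            StabilityComparison(
                condition, n, float(np.median(prox_arr)), float(np.median(dist_arr)),
                stat, p, None,
            )
        )
    return out


@dataclass
class ExpressionRatioReport:
    """log2 expression-ratio distributions for shifted vs control genes."""

    ratios_shifted: pd.Series
    ratios_control: pd.Series
    median_shifted: float
    median_control: float
    p_two_tailed: float
    n_excluded_zero: int


def expression_ratio_by_shift(
    gene_counts: pd.DataFrame,
    samples: pd.DataFrame,
    shift_calls: dict[str, str],
    cond_a: str,
    cond_b: str,
    shifted_label: str = "lengthened",
) -> ExpressionRatioReport:
    """Compare log2(condB/condA) expression between shifted and control genes.

    Gene counts are median-of-ratios normalized, replicate-averaged per
    condition, and log2-ratioed per gene. Genes with a zero normalized mean
    in either condition are excluded (tallied). Shifted genes are those whose
    call equals ``shifted_label``; controls are all other called genes.
    """
    size_factors, norm = _stats.median_of_ratios_normalize(gene_counts)
    ids_a = [s for s in samples.index[samples["condition"] == cond_a] if s in norm.columns]
    ids_b = [s for s in samples.index[samples["condition"] == cond_b] if s in norm.columns]
    if not ids_a or not ids_b:
        raise ValueError("both conditions must have samples in the count matrix")
    mean_a = norm[ids_a].mean(axis=1)
    mean_b = norm[ids_b].mean(axis=1)
    usable = (mean_a > 0) & (mean_b > 0)
    n_excluded = int((~usable).sum())
    log2fc = np.log2(mean_b[usable] / mean_a[usable])
    shifted = log2fc[[g for g in log2fc.index if shift_calls.get(g) == shifted_label]]
    control = log2fc[
        [g for g in log2fc.index if g in shift_calls and shift_calls[g] != shifted_label]
    ]
    if control.empty:
        raise ValueError("control group is empty")
    if shifted.empty:
        raise ValueError("shifted group is empty")
    _, p = _stats.rank_tests(shifted.to_numpy(), control.to_numpy(), paired=False)
    return ExpressionRatioReport(
        ratios_shifted=shifted,
        ratios_control=control,
        median_shifted=float(shifted.median()),
        median_control=float(control.median()),
        p_two_tailed=p,
        n_excluded_zero=n_excluded,
    )
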