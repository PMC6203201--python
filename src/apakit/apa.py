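"""APA quantification: read-to-site assignment, RUD, shift calling, summaries.

The central quantity for two-site genes is the relative use of the distal
site, RUD = distal counts / (proximal + distal counts), computed per
replicate, averaged within condition, and differenced between conditions;
a gene is called lengthened (shortened) when the RUD difference exceeds
(falls below) +/- a threshold, 0.05 by default. Genes with more than two
sites are handled with the per-site generalization, relative site usage.

Proximal and distal are defined in transcript orientation (strand-aware),
never by genomic coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from apakit import stats as _stats
from apakit.io import (
    GeneSiteMap,
    PolyASite,
    SiteCountMatrix,
    VALID_ANNOT_CLASSES,
)

SHIFT_LENGTHENED = "lengthened"
SHIFT_SHORTENED = "shortened"
SHIFT_UNCHANGED = "unchanged"

UTR_APA = "UTR_APA"
UR_APA = "UR_APA"


class AtlasOverlapError(ValueError):
    """Same-strand poly(A)-site clusters overlap; assignment would be ambiguous."""


@dataclass
class AssignmentResult:
    """Read 3'-end to site assignment: counts plus the unassigned tally."""

    matrix: SiteCountMatrix
    n_assigned: int
    n_unassigned: int


@dataclass
class GeneAPAResult:
    """Per-gene APA call between two conditions.

    For two-site genes ``rud_*`` fields are populated and ``delta_rud`` is
    mean RUD(condition B) - mean RUD(condition A). For genes with more than
    two sites the usage vectors are populated instead and ``delta_rud``
    holds the distal site's usage change.
    """

    gene_id: str
    n_sites: int
    shift_call: str
    delta_rud: float
    rud_by_replicate: dict[tuple[str, str], float] = field(default_factory=dict)
    rud_mean: dict[str, float] = field(default_factory=dict)
    apa_class: str | None = None
    usage_by_condition: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class CohortSummary:
    """Cohort-level shift counts and the reporting percentages.

    Percentages are rounded to the nearest integer; they are ``None`` when
    the denominator is zero.
    """

    n_significant: int
    n_lengthened: int
    n_shortened: int
    pct_lengthened: int | None
    n_utr_apa_of_lengthened: int
    pct_utr_apa: int | None


def validate_atlas_nonoverlapping(atlas: list[PolyASite]) -> None:
    """Reject atlases with overlapping same-strand clusters."""
    by_key: dict[tuple[str, str], list[PolyASite]] = {}
    for s in atlas:
        by_key.setdefault((s.chrom, s.strand), []).append(s)
    for (chrom, strand), sites in by_key.items():
        sites.sort(key=lambda s: s.cluster_start)
        for a, b in zip(sites, sites[1:]):
            if b.cluster_start <= a.cluster_end:
                raise AtlasOverlapError(
                    f"clusters {a.site_id} and {b.site_id} overlap on {chrom}{strand}"
                )


def assign_read_ends(
    read_ends: pd.DataFrame,
    atlas: list[PolyASite],
    samples: pd.DataFrame | None = None,
) -> AssignmentResult:
    """Count read 3' ends per poly(A)-site cluster.

    A read with 1-based coordinate ``pos`` increments site ``s`` iff it lies
    on the same chrom and strand and ``cluster_start <= pos <= cluster_end``
    (both boundaries inclusive). Reads in no cluster are tallied as
    unassigned. ``read_ends`` needs columns chrom, strand, pos and
    optionally ``sample_id``; without it all reads form one sample.
    """
    validate_atlas_nonoverlapping(atlas)
    df = read_ends.copy()
    if "sample_id" not in df.columns:
        df["sample_id"] = "sample_1"
    sample_ids = sorted(df["sample_id"].unique())
    if samples is None:
        samples = pd.DataFrame(
            {"condition": "na", "replicate": 1, "timepoint_h": np.nan},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    # sorted cluster starts per (chrom, strand) for O(log n) lookup
    index: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, list[str]]] = {}
    by_key: dict[tuple[str, str], list[PolyASite]] = {}
    for s in atlas:
        by_key.setdefault((s.chrom, s.strand), []).append(s)
    for key, sites in by_key.items():
        sites.sort(key=lambda s: s.cluster_start)
        index[key] = (
            np.array([s.cluster_start for s in sites]),
            np.array([s.cluster_end for s in sites]),
            [s.site_id for s in sites],
        )
    atlas_ids = [s.site_id for s in atlas]
    counts = pd.DataFrame(0, index=pd.Index(atlas_ids, name="site_id"), columns=sample_ids)
    n_unassigned = 0
    for (chrom, strand, sample_id), group in df.groupby(["chrom", "strand", "sample_id"]):
        key = (chrom, strand)
        if key not in index:
            n_unassigned += len(group)
            continue
        starts, ends, ids = index[key]
        pos = group["pos"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos <= ends[np.clip(idx, 0, None)])
        n_unassigned += int((~ok).sum())
        hit, n = np.unique(idx[ok], return_counts=True)
        for i, c in zip(hit, n):
            counts.loc[ids[i], sample_id] += int(c)
    matrix = SiteCountMatrix(counts, samples)
    return AssignmentResult(matrix, int(counts.to_numpy().sum()), n_unassigned)


def filter_sites(
    m: SiteCountMatrix, atlas: list[PolyASite], min_total: int = 10
) -> SiteCountMatrix:
    """Keep sites in class TE/EX/IN with >= ``min_total`` counts over all samples.

    The count threshold is inclusive (a row-sum of exactly ``min_total``
    passes). Filtering is for APA calling; gene-level expression aggregation
    uses the unfiltered matrix.
    """
    by_id = {s.site_id: s for s in atlas}
    keep = []
    totals = m.counts.sum(axis=1)
    for site_id in m.site_ids:
        site = by_id.get(site_id)
        if site is None or site.annot_class not in VALID_ANNOT_CLASSES:
            continue
        if totals[site_id] >= min_total:
            keep.append(site_id)
    return m.subset_sites(keep)


def compute_rud(m: SiteCountMatrix, gene_map: GeneSiteMap) -> pd.Series:
    """Per-sample RUD = distal/(proximal+distal) for a two-site gene.

    Samples whose proximal+distal total is zero get NaN (undefined), never 0:
    a zero-coverage replicate carries no usage information.
    """
    if gene_map.n_sites != 2:
        raise ValueError(f"gene {gene_map.gene_id}: RUD requires exactly 2 sites")
    proximal = m.counts.loc[gene_map.proximal.site_id]
    distal = m.counts.loc[gene_map.distal.site_id]
    total = proximal + distal
    rud = distal / total.where(total > 0)
    rud.name = gene_map.gene_id
    return rud


def call_apa_shift(
    rud: pd.Series,
    samples: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    threshold: float = 0.05,
) -> tuple[dict[str, float], float, str] | None:
    """Average replicate RUDs per condition and call the shift direction.

    Returns ``(rud_mean, delta_rud, shift_call)`` with
    ``delta_rud = mean(B) - mean(A)``; lengthened when delta > threshold,
    shortened when delta < -threshold (strict inequalities), unchanged
    otherwise. Returns None when a condition has no defined replicate RUD.
    """
    rud_mean: dict[str, float] = {}
    for cond in (cond_a, cond_b):
        ids = samples.index[samples["condition"] == cond]
        vals = rud.loc[[i for i in ids if i in rud.index]].dropna()
        if vals.empty:
            return None
        rud_mean[cond] = float(vals.mean())
    delta = rud_mean[cond_b] - rud_mean[cond_a]
    # strict inequality at the threshold, guarded against float rounding
    eps = 1e-9
    if delta > threshold + eps:
        call = SHIFT_LENGTHENED
    elif delta < -threshold - eps:
        call = SHIFT_SHORTENED
    else:
        call = SHIFT_UNCHANGED
    return rud_mean, delta, call


def classify_apa_type(gene_map: GeneSiteMap) -> str:
    """UTR-APA when the proximal site sits in the terminal exon (TE); UR-APA
    when it lies upstream of the 3' UTR (internal exon EX or intron IN)."""
    if gene_map.n_sites != 2:
        raise ValueError("APA type classification defined for 2-site genes")
    return UTR_APA if gene_map.proximal.annot_class == "TE" else UR_APA


def relative_site_usage(
    m: SiteCountMatrix, gene_map: GeneSiteMap, conditions: list[str]
) -> dict[str, np.ndarray] | None:
    """Per-condition usage vectors (site counts / gene total), replicate-averaged.

    Usage is computed per replicate and then averaged within condition, so
    each returned vector sums to 1. Replicates with zero gene total are
    skipped; a condition with no usable replicate makes the gene unusable
    (returns None).
    """
    site_ids = [s.site_id for s in gene_map.sites]
    sub = m.counts.loc[site_ids]
    usage: dict[str, np.ndarray] = {}
    for cond in conditions:
        ids = [i for i in m.samples.index[m.samples["condition"] == cond] if i in sub.columns]
        vecs = []
        for sample_id in ids:
            col = sub[sample_id].to_numpy(dtype=float)
            total = col.sum()
            if total > 0:
                vecs.append(col / total)
        if not vecs:
            return None
        usage[cond] = np.mean(vecs, axis=0)
    return usage


def aggregate_gene_counts(
    m: SiteCountMatrix, gene_maps: dict[str, GeneSiteMap]
) -> pd.DataFrame:
    """Sum site counts per gene (gene x sample matrix) for expression analysis."""
    rows = {}
    for gene_id, gm in gene_maps.items():
        ids = [s.site_id for s in gm.sites if s.site_id in m.counts.index]
        if ids:
            rows[gene_id] = m.counts.loc[ids].sum(axis=0)
    out = pd.DataFrame(rows).T
    out.index.name = "gene_id"
    return out


def call_apa_cohort(
    m: SiteCountMatrix,
    gene_maps: dict[str, GeneSiteMap],
    cond_a: str,
    cond_b: str,
    threshold: float = 0.05,
) -> list[GeneAPAResult]:
    """Call APA shifts for every gene with >= 2 retained sites.

    ``m`` should already be site-filtered. Two-site genes get the RUD
    treatment plus UTR/UR classification; genes with more sites are called
    on the distal site's usage change (lengthened when the distal site gains
    more than ``threshold`` usage while some upstream site loses usage,
    mirrored for shortened).
    """
    results: list[GeneAPAResult] = []
    present = set(m.counts.index)
    for gene_id in sorted(gene_maps):
        gm = gene_maps[gene_id]
        retained = [s for s in gm.sites if s.site_id in present]
        if len(retained) < 2:
            continue
        sub_map = GeneSiteMap(gene_id, tuple(retained))
        if sub_map.n_sites == 2:
            rud = compute_rud(m, sub_map)
            called = call_apa_shift(rud, m.samples, cond_a, cond_b, threshold)
            if called is None:
                continue
            rud_mean, delta, call = called
            by_rep = {
                (str(m.samples.loc[sid, "condition"]), str(sid)): float(v)
                for sid, v in rud.items()
                if not np.isnan(v)
            }
            results.append(
                GeneAPAResult(
                    gene_id=gene_id,
                    n_sites=2,
                    shift_call=call,
                    delta_rud=delta,
                    rud_by_replicate=by_rep,
                    rud_mean=rud_mean,
                    apa_class=classify_apa_type(sub_map),
                )
            )
        else:
            usage = relative_site_usage(m, sub_map, [cond_a, cond_b])
            if usage is None:
                continue
            d_usage = usage[cond_b] - usage[cond_a]
            distal_delta = float(d_usage[-1])
            if distal_delta > threshold and (d_usage[:-1] < 0).any():
                call = SHIFT_LENGTHENED
            elif distal_delta < -threshold and (d_usage[:-1] > 0).any():
                call = SHIFT_SHORTENED
            else:
                call = SHIFT_UNCHANGED
            results.append(
                GeneAPAResult(
                    gene_id=gene_id,
                    n_sites=sub_map.n_sites,
                    shift_call=call,
                    delta_rud=distal_delta,
                    usage_by_condition=usage,
                )
            )
    return results


def summarize_cohort(results: list[GeneAPAResult]) -> CohortSummary:
    """Count significant / lengthened / shortened calls among two-site genes
    and compute the rounded reporting percentages."""
    two_site = [r for r in results if r.n_sites == 2]
    lengthened = [r for r in two_site if r.shift_call == SHIFT_LENGTHENED]
    shortened = [r for r in two_site if r.shift_call == SHIFT_SHORTENED]
    n_sig = len(lengthened) + len(shortened)
    n_utr = sum(1 for r in lengthened if r.apa_class == UTR_APA)
    pct_len = round(100 * len(lengthened) / n_sig) if n_sig else None
    pct_utr = round(100 * n_utr / len(lengthened)) if lengthened else None
    return CohortSummary(
        n_significant=n_sig,
        n_lengthened=len(lengthened),
        n_shortened=len(shortened),
        pct_lengthened=pct_len,
        n_utr_apa_of_lengthened=n_utr,
        pct_utr_apa=pct_utr,
    )


def overlap_shift_sets(
    set_a: set[str], set_b: set[str], universe: set[str]
) -> _stats.OverlapResult:
    """Overlap of two shifted-gene sets with hypergeometric enrichment p.

    ``fraction_a`` is the share of set A found in set B (NaN when A is
    empty); the p-value is the upper tail including the observed overlap.
    """
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("gene sets must be subsets of the universe")
    return _stats.hypergeom_overlap(
        n_universe=len(universe),
        n_a=len(set_a),
        n_b=len(set_b),
        n_intersection=len(set_a & set_b),
    )


def results_to_frame(results: list[GeneAPAResult]) -> pd.DataFrame:
    """Flatten cohort results to a tidy per-gene table for TSV export."""
    rows = []
    for r in results:
        row = {
            "gene_id": r.gene_id,
            "n_sites": r.n_sites,
            "shift_call": r.shift_call,
            "delta_rud": r.delta_rud,
            "apa_class": r.apa_class if r.apa_class else "NA",
        }
        for cond, v in r.rud_mean.items():
            row[f"rud_mean_{cond}"] = v
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")
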