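"""Synthetic 3'-end-sequencing data with known ground truth.

Generators for (i) a poly(A)-site atlas plus two-condition replicate count
matrices with planted RUD shifts, (ii) transcription-shutoff decay time
courses with known half-lives, (iii) genomic sequence with planted PAS
hexamers, UGUA elements and downstream U/GU composition, and (iv) splice-site
sequences sampled from a PWM with a tunable "weakness" admixture.

The hierarchical count model mirrors what 3'-end counting imposes: a
negative-binomial total depth per gene and sample, split multinomially
across the gene's sites according to the condition's true usage vector.
Every generator is deterministic given the config seed, and the returned
truth tables are sufficient to score any downstream caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from apakit.io import GeneSiteMap, PolyASite, SiteCountMatrix, reverse_complement

COND_A = "proliferating"
COND_B = "quiescent"

_USAGE_FLOOR = 0.01


@dataclass
class MotifParams:
    """Per-site motif planting probabilities for sequence simulation.

    ``p_canonical``/``p_other`` give the hexamer class mix (remainder =
    no hexamer); ``ugua_rate`` the chance of planting one UGUA in the
    100 nt upstream window; ``u_content``/``g_content`` the iid base
    composition of the +20..+40 downstream window. The ``*_proximal_lengthened``
    overrides, when set, apply to proximal sites of genes whose true label
    is "lengthened" (for planted-enrichment experiments).
    """

    p_canonical: float = 0.5
    p_other: float = 0.3
    ugua_rate: float = 0.5
    u_content: float = 0.35
    g_content: float = 0.15
    p_canonical_proximal_lengthened: float | None = None
    u_content_proximal_lengthened: float | None = None


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults describe a small two-condition, two-replicate cohort of
    1000 two-site genes at mean depth 500 with negative-binomial
    dispersion (size) 10 — enough read depth for RUD estimates at the
    0.05 calling threshold while running in seconds.
    """

    n_genes: int = 1000
    sites_per_gene: int | dict[int, float] = 2
    frac_lengthened: float = 0.3
    frac_shortened: float = 0.05
    delta_rud_effect: float = 0.3
    mean_gene_depth: float = 500.0
    dispersion: float = 10.0
    n_replicates: int = 2
    seed: int = 0
    decay_halflife_range_h: tuple[float, float] = (1.0, 10.0)
    timepoints_h: tuple[float, ...] = (0.0, 2.0, 4.0, 8.0)
    motif_params: MotifParams = field(default_factory=MotifParams)

    def __post_init__(self) -> None:
        if not 0 <= self.frac_lengthened <= 1 or not 0 <= self.frac_shortened <= 1:
            raise ValueError("shift fractions must lie in [0, 1]")
        if self.frac_lengthened + self.frac_shortened > 1:
            raise ValueError("frac_lengthened + frac_shortened must be <= 1")
        if self.delta_rud_effect <= 0:
            raise ValueError("delta_rud_effect must be > 0")
        if self.mean_gene_depth <= 0 or self.dispersion <= 0:
            raise ValueError("depth and dispersion must be > 0")
        if self.n_replicates < 1:
            raise ValueError("need >= 1 replicate")
        lo, hi = self.decay_halflife_range_h
        if lo <= 0 or hi < lo:
            raise ValueError("invalid half-life range")
        if self.timepoints_h[0] != 0:
            raise ValueError("timepoints must start at 0")


@dataclass
class SimTruth:
    """Planted ground truth for one simulated cohort."""

    usage: dict[str, dict[str, np.ndarray]]  # condition -> gene -> usage vector
    shift_label: dict[str, str]  # gene -> lengthened | shortened | unchanged
    half_life_h: dict[tuple[str, str], float]  # (site_id, condition) -> hours
    renormalized_genes: set[str] = field(default_factory=set)
    planted_motifs: pd.DataFrame | None = None

    def true_delta_rud(self, gene_id: str) -> float:
        """Distal-usage change (condition B - A); equals Delta RUD for 2-site genes."""
        return float(
            self.usage[COND_B][gene_id][-1] - self.usage[COND_A][gene_id][-1]
        )


def _draw_sites_per_gene(cfg: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    if isinstance(cfg.sites_per_gene, int):
        return np.full(n, cfg.sites_per_gene, dtype=int)
    ks = np.array(sorted(cfg.sites_per_gene), dtype=int)
    ps = np.array([cfg.sites_per_gene[int(k)] for k in ks], dtype=float)
    ps = ps / ps.sum()
    return rng.choice(ks, size=n, p=ps)


def _shift_usage(base: np.ndarray, delta: float) -> tuple[np.ndarray, bool]:
    """Move ``delta`` usage onto the distal site, taking it from the proximal.

    If any component leaves [0, 1] the vector is floored at 0.01 and
    renormalized; the caller records the gene as renormalized.
    """
    shifted = base.copy()
    shifted[-1] += delta
    shifted[0] -= delta
    if (shifted < 0).any() or (shifted > 1).any():
        shifted = np.clip(shifted, _USAGE_FLOOR, None)
        shifted = shifted / shifted.sum()
        return shifted, True
    return shifted, False


def _gene_depths(cfg: SimConfig, rng: np.random.Generator, size: int) -> np.ndarray:
    if math.isinf(cfg.dispersion):
        return rng.poisson(cfg.mean_gene_depth, size=size)
    p = cfg.dispersion / (cfg.dispersion + cfg.mean_gene_depth)
    return rng.negative_binomial(cfg.dispersion, p, size=size)


def simulate_apa_counts(
    cfg: SimConfig,
) -> tuple[list[PolyASite], SiteCountMatrix, SimTruth]:
    """Simulate an atlas and a two-condition replicate count matrix.

    A planted "lengthened" gene has its condition-B usage shifted by
    ``+delta_rud_effect`` on the distal site (shortened genes the mirror
    image); other genes share the same usage in both conditions. Per gene
    and sample, total depth is negative-binomial (Poisson when dispersion
    is infinite) and site counts are multinomial within the gene.
    """
    rng = np.random.default_rng(cfg.seed)
    n_sites = _draw_sites_per_gene(cfg, rng, cfg.n_genes)
    labels = np.array(["unchanged"] * cfg.n_genes, dtype=object)
    n_len = int(round(cfg.frac_lengthened * cfg.n_genes))
    n_sho = int(round(cfg.frac_shortened * cfg.n_genes))
    idx = rng.permutation(cfg.n_genes)
    labels[idx[:n_len]] = "lengthened"
    labels[idx[n_len : n_len + n_sho]] = "shortened"

    atlas: list[PolyASite] = []
    usage_a: dict[str, np.ndarray] = {}
    usage_b: dict[str, np.ndarray] = {}
    shift_label: dict[str, str] = {}
    renormalized: set[str] = set()
    half_life: dict[tuple[str, str], float] = {}
    hl_lo, hl_hi = cfg.decay_halflife_range_h

    cursor = 1000  # genomic layout cursor; sites spaced widely enough for motif windows
    site_spacing, gene_spacing, cluster_half = 500, 2000, 10
    for gi in range(cfg.n_genes):
        gene_id = f"g{gi + 1:05d}"
        k = int(n_sites[gi])
        strand = "+" if rng.random() < 0.5 else "-"
        label = str(labels[gi])
        shift_label[gene_id] = label

        # baseline usage with headroom for the planted shift
        if k == 2:
            if label == "lengthened":
                base_rud = rng.uniform(0.15, 1.0 - cfg.delta_rud_effect - 0.05)
            elif label == "shortened":
                base_rud = rng.uniform(cfg.delta_rud_effect + 0.05, 0.85)
            else:
                base_rud = rng.uniform(0.15, 0.85)
            base = np.array([1.0 - base_rud, base_rud])
        else:
            base = rng.dirichlet(np.full(k, 5.0))
            base = np.clip(base, 0.05, None)
            base = base / base.sum()
        if label == "lengthened":
            shifted, renorm = _shift_usage(base, cfg.delta_rud_effect)
        elif label == "shortened":
            shifted, renorm = _shift_usage(base, -cfg.delta_rud_effect)
        else:
            shifted, renorm = base.copy(), False
        if renorm:
            renormalized.add(gene_id)
        usage_a[gene_id] = base
        usage_b[gene_id] = shifted

        # genomic layout: clusters left to right; transcript order follows strand
        positions = [cursor + j * site_spacing for j in range(k)]
        cursor = positions[-1] + gene_spacing
        order = range(k) if strand == "+" else range(k - 1, -1, -1)
        # proximal annot_class: mostly terminal exon (UTR-APA), sometimes EX/IN
        for transcript_rank, j in enumerate(order):
            rep = positions[j]
            if transcript_rank == k - 1:
                annot = "TE"
            else:
                annot = str(rng.choice(["TE", "EX", "IN"], p=[0.9, 0.04, 0.06]))
            site_id = f"{gene_id}_s{transcript_rank + 1}"
            atlas.append(
                PolyASite(
                    site_id=site_id,
                    gene_id=gene_id,
                    chrom="chrS",
                    strand=strand,
                    cluster_start=rep - cluster_half,
                    cluster_end=rep + cluster_half,
                    rep_pos=rep,
                    annot_class=annot,
                )
            )
            for cond in (COND_A, COND_B):
                half_life[(site_id, cond)] = float(rng.uniform(hl_lo, hl_hi))

    # transcript-rank order of sites per gene, matching atlas insertion order
    site_ids = [s.site_id for s in atlas]
    sample_ids = [
        f"{cond}_r{rep}" for cond in (COND_A, COND_B) for rep in range(1, cfg.n_replicates + 1)
    ]
    samples = pd.DataFrame(
        {
            "condition": [sid.rsplit("_r", 1)[0] for sid in sample_ids],
            "replicate": [int(sid.rsplit("_r", 1)[1]) for sid in sample_ids],
            "timepoint_h": np.nan,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    counts = np.zeros((len(site_ids), len(sample_ids)), dtype=int)
    row = 0
    for gi in range(cfg.n_genes):
        gene_id = f"g{gi + 1:05d}"
        k = int(n_sites[gi])
        for col, sid in enumerate(sample_ids):
            cond = samples.loc[sid, "condition"]
            usage = usage_a[gene_id] if cond == COND_A else usage_b[gene_id]
            depth = int(_gene_depths(cfg, rng, 1)[0])
            counts[row : row + k, col] = rng.multinomial(depth, usage)
        row += k
    matrix = SiteCountMatrix(
        pd.DataFrame(counts, index=pd.Index(site_ids, name="site_id"), columns=sample_ids),
        samples,
    )
    truth = SimTruth(
        usage={COND_A: usage_a, COND_B: usage_b},
        shift_label=shift_label,
        half_life_h=half_life,
        renormalized_genes=renormalized,
    )
    return atlas, matrix, truth


def simulate_decay_counts(
    cfg: SimConfig,
    truth: SimTruth,
    conditions: tuple[str, ...] = (COND_A, COND_B),
    poisson: bool = True,
    c0: dict[str, float] | None = None,
) -> SiteCountMatrix:
    """Simulate a transcription-shutoff time course from planted half-lives.

    Expected count at time t is ``c0 * 2**(-t / half_life)``; with
    ``poisson=True`` observed counts are Poisson draws, otherwise the exact
    expectations are returned (floats, useful for closed-form checks).
    Initial abundance c0 is drawn from the gene-depth model per site and
    replicate unless overridden per site.
    """
    if any(hl <= 0 for hl in truth.half_life_h.values()):
        raise ValueError("half-lives must be positive")
    rng = np.random.default_rng(cfg.seed + 1)
    site_ids = sorted({sid for sid, _ in truth.half_life_h})
    sample_rows = []
    for cond in conditions:
        for rep in range(1, cfg.n_replicates + 1):
            for t in cfg.timepoints_h:
                sample_rows.append(
                    {
                        "sample_id": f"{cond}_r{rep}_t{t:g}",
                        "condition": cond,
                        "replicate": rep,
                        "timepoint_h": float(t),
                    }
                )
    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    counts = pd.DataFrame(
        0.0, index=pd.Index(site_ids, name="site_id"), columns=samples.index
    )
    for cond in conditions:
        for rep in range(1, cfg.n_replicates + 1):
            for site_id in site_ids:
                hl = truth.half_life_h[(site_id, cond)]
                base = (
                    float(c0[site_id])
                    if c0 is not None and site_id in c0
                    else float(_gene_depths(cfg, rng, 1)[0])
                )
                for t in cfg.timepoints_h:
                    expected = base * 2.0 ** (-t / hl)
                    value = rng.poisson(expected) if poisson else expected
                    counts.loc[site_id, f"{cond}_r{rep}_t{t:g}"] = value
    if poisson:
        counts = counts.astype(int)
    return SiteCountMatrix(counts, samples)


_BG_BASES = np.array(list("ACG"))  # U-free background: no spurious UGUA/UUUU/PAS

_CANONICAL = ("AAUAAA", "AUUAAA")
_OTHER = (
    "AAACAU", "AAUAAC", "UUAAAG", "UUAAAU", "UAUAAA", "AAUACA", "CAUAAA",
    "AAUAUA", "GAUAAA", "AAUGAA", "AAGAAA", "ACUAAA", "AAUAGA", "AAUAAU",
    "AACAAA", "AUUACA", "AUUAUA", "AACAAG", "AAUAAG",
)


def simulate_site_sequences(
    cfg: SimConfig,
    atlas: list[PolyASite],
    truth: SimTruth | None = None,
    region: tuple[int, int] = (-100, 45),
) -> tuple[dict[str, str], pd.DataFrame, list[PolyASite]]:
    """Plant motif elements around each atlas site and emit genome FASTA records.

    Each site's transcript-space region (default -100..+45 around the
    cleavage position) is built from a U-free random background, then a PAS
    hexamer is planted in -50..-10 (class drawn from ``motif_params``), a
    UGUA optionally in -100..-1, and the +20..+40 window drawn iid with the
    configured U/G composition. The region is written into the contig
    reverse-complemented for minus-strand sites.

    Returns ``(contigs, planted_table, atlas_with_hexamers)`` where the
    returned atlas copy carries the planted hexamer annotations.
    """
    mp = cfg.motif_params
    rng = np.random.default_rng(cfg.seed + 2)
    lo, hi = region
    if lo > -100 or hi < 41:
        raise ValueError("region must cover -100..-1 upstream and +20..+40 downstream")
    length = hi - lo + 1

    occupied: dict[str, list[tuple[int, int]]] = {}
    contig_len: dict[str, int] = {}
    pieces: dict[str, list[tuple[int, str]]] = {}
    rows = []
    new_atlas: list[PolyASite] = []
    for site in atlas:
        # per-site class probabilities, optionally enriched for proximal
        # sites of truly lengthened genes
        p_can, u_content = mp.p_canonical, mp.u_content
        if truth is not None and truth.shift_label.get(site.gene_id) == "lengthened":
            if site.site_id.endswith("_s1"):
                if mp.p_canonical_proximal_lengthened is not None:
                    p_can = mp.p_canonical_proximal_lengthened
                if mp.u_content_proximal_lengthened is not None:
                    u_content = mp.u_content_proximal_lengthened
        region_seq = list(rng.choice(_BG_BASES, size=length))

        def put(offset: int, text: str) -> None:
            start = offset - lo
            region_seq[start : start + len(text)] = list(text)

        u = rng.random()
        if u < p_can:
            hexamer = _CANONICAL[rng.integers(2)]
            hex_class = "canonical"
        elif u < p_can + mp.p_other:
            hexamer = _OTHER[rng.integers(len(_OTHER))]
            hex_class = "other"
        else:
            hexamer = None
            hex_class = "none"
        hex_span = None
        if hexamer:
            hex_start = int(rng.integers(-50, -10 - 6 + 2))
            put(hex_start, hexamer)
            hex_span = (hex_start, hex_start + 5)
        ugua_planted = bool(rng.random() < mp.ugua_rate)
        if ugua_planted:
            # keep the UGUA clear of the planted hexamer (bounded retries)
            for _ in range(100):
                ug_start = int(rng.integers(-100, -4))
                if hex_span is None or ug_start > hex_span[1] or ug_start + 3 < hex_span[0]:
                    break
            else:
                raise RuntimeError("could not place UGUA without motif collision")
            put(ug_start, "UGUA")
        p_a = max(1.0 - u_content - mp.g_content, 0.0) / 2
        down = rng.choice(
            np.array(list("UGAC")), size=21, p=[u_content, mp.g_content, p_a, p_a]
        )
        put(20, "".join(down))

        dna = "".join(region_seq).replace("U", "T")
        if site.strand == "+":
            g_start = site.rep_pos + lo  # 1-based
        else:
            g_start = site.rep_pos - hi
            dna = reverse_complement(dna)
        g_end = g_start + length - 1
        if g_start < 1:
            raise ValueError(f"site {site.site_id}: region runs off contig start")
        for a, b in occupied.setdefault(site.chrom, []):
            if g_start <= b and a <= g_end:
                raise ValueError(f"site {site.site_id}: motif regions overlap on {site.chrom}")
        occupied[site.chrom].append((g_start, g_end))
        pieces.setdefault(site.chrom, []).append((g_start, dna))
        contig_len[site.chrom] = max(contig_len.get(site.chrom, 0), g_end + 100)
        hexamers = ((hexamer, float(rng.uniform(1, 10))),) if hexamer else ()
        new_atlas.append(replace(site, hexamers=hexamers))
        rows.append(
            {
                "site_id": site.site_id,
                "hexamer": hexamer or "NA",
                "hexamer_class": hex_class,
                "ugua_planted": ugua_planted,
                "u_content": u_content,
            }
        )

    contigs = {}
    for chrom, n in contig_len.items():
        arr = rng.choice(_BG_BASES, size=n)  # U-free, valid as DNA
        for g_start, dna in pieces[chrom]:
            arr[g_start - 1 : g_start - 1 + len(dna)] = list(dna)
        contigs[chrom] = "".join(arr)
    table = pd.DataFrame(rows).set_index("site_id")
    return contigs, table, new_atlas


def simulate_splice_sites(
    pwm, n: int, weakness: float, seed: int
) -> list[str]:
    """Sample splice-site sequences from a PWM diluted toward uniform.

    Per position the sampling distribution is
    ``(1 - weakness) * pwm + weakness * uniform``; weakness 0 reproduces the
    PWM, weakness 1 is uniform random sequence.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= weakness <= 1:
        raise ValueError("weakness must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = (1.0 - weakness) * pwm.probs + weakness * 0.25
    bases = np.array(list("ACGU"))
    out = []
    for _ in range(n):
        out.append("".join(bases[rng.choice(4, p=probs[p])] for p in range(pwm.length)))
    return out


def write_simulation(
    out_dir, atlas, matrix: SiteCountMatrix, truth: SimTruth, contigs: dict[str, str] | None = None
) -> None:
    """Write a simulated cohort in the TSV/FASTA dialects the readers consume."""
    from pathlib import Path

    from apakit.io import write_atlas, write_counts

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_atlas(atlas, out / "atlas.tsv")
    write_counts(matrix, out / "counts.tsv", out / "samples.tsv")
    truth_df = pd.DataFrame(
        {
            "gene_id": list(truth.shift_label),
            "shift_label": [truth.shift_label[g] for g in truth.shift_label],
            "true_delta_rud": [truth.true_delta_rud(g) for g in truth.shift_label],
            "renormalized": [g in truth.renormalized_genes for g in truth.shift_label],
        }
    )
    truth_df.to_csv(out / "truth.tsv", sep="\t", index=False)
    if contigs:
        with open(out / "genome.fa", "w") as fh:
            for name, seq in contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
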