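"""Readers/writers for poly(A)-site atlases, count matrices, sequences and gene sets.

Coordinate conventions live here and nowhere else:

* atlas coordinates are 1-based and inclusive on both ends
  (``cluster_start <= rep_pos <= cluster_end``);
* BED export converts to 0-based half-open;
* sequence windows are expressed as offsets from the representative cleavage
  position in *transcript* orientation (negative = upstream of the cleavage
  site), and returned in the RNA alphabet {A,U,G,C} regardless of the strand
  or the alphabet of the underlying FASTA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

VALID_ANNOT_CLASSES = frozenset({"TE", "EX", "IN"})

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


class AtlasParseError(ValueError):
    """Malformed atlas record; the message names the offending line."""


class CountsValidationError(ValueError):
    """Count matrix inconsistent with its atlas or sample sheet."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    """Uppercase and convert the DNA alphabet to RNA (T -> U)."""
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class PolyASite:
    """One annotated cleavage/polyadenylation site.

    ``annot_class`` is the atlas annotation of where the site falls in the
    transcript: ``TE`` terminal exon, ``EX`` any other exon, ``IN`` intron.
    ``hexamers`` lists the polyadenylation-signal hexamers associated with
    the site together with their signal strengths.
    """

    site_id: str
    gene_id: str
    chrom: str
    strand: str
    cluster_start: int
    cluster_end: int
    rep_pos: int
    annot_class: str
    hexamers: tuple[tuple[str, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"site {self.site_id}: strand must be '+' or '-', got {self.strand!r}")
        if not (self.cluster_start <= self.rep_pos <= self.cluster_end):
            raise ValueError(
                f"site {self.site_id}: require cluster_start <= rep_pos <= cluster_end, "
                f"got {self.cluster_start} <= {self.rep_pos} <= {self.cluster_end}"
            )
        if self.annot_class not in VALID_ANNOT_CLASSES:
            raise ValueError(
                f"site {self.site_id}: unknown annot_class {self.annot_class!r} "
                f"(expected one of {sorted(VALID_ANNOT_CLASSES)})"
            )
        for hexamer, strength in self.hexamers:
            if len(hexamer) != 6:
                raise ValueError(f"site {self.site_id}: hexamer {hexamer!r} is not 6 nt")
            if strength < 0:
                raise ValueError(f"site {self.site_id}: negative signal strength {strength}")


@dataclass
class SiteCountMatrix:
    """Site x sample count matrix with sample metadata.

    ``counts`` is indexed by site_id with one column per sample_id;
    ``samples`` is indexed by sample_id with columns ``condition``,
    ``replicate`` and (optionally) ``timepoint_h``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            raise CountsValidationError("duplicate site_id in count matrix")
        if not self.counts.columns.is_unique:
            raise CountsValidationError("duplicate sample_id in count matrix")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise CountsValidationError(f"samples missing from sample sheet: {sorted(missing)}")
        if (self.counts.to_numpy() < 0).any():
            raise CountsValidationError("negative counts")

    @property
    def site_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_for(self, condition: str) -> list[str]:
        sel = self.samples[self.samples["condition"] == condition]
        return list(sel.index)

    def subset_sites(self, site_ids: Sequence[str]) -> "SiteCountMatrix":
        return SiteCountMatrix(self.counts.loc[list(site_ids)], self.samples)


@dataclass
class GeneSiteMap:
    """A gene's poly(A) sites ordered proximal -> distal in transcript direction.

    For a ``+`` strand gene transcript order follows genomic coordinate; for a
    ``-`` strand gene it is the reverse, so "proximal" (first used during
    transcription) is the genomically rightmost site.
    """

    gene_id: str
    sites: tuple[PolyASite, ...]

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError(f"gene {self.gene_id}: no sites")
        strands = {s.strand for s in self.sites}
        if len(strands) > 1:
            raise ValueError(f"gene {self.gene_id}: sites on both strands")
        pos = [s.rep_pos for s in self.sites]
        if self.strand == "+":
            ok = all(a < b for a, b in zip(pos, pos[1:]))
        else:
            ok = all(a > b for a, b in zip(pos, pos[1:]))
        if not ok:
            raise ValueError(f"gene {self.gene_id}: sites not in transcript order")

    @property
    def strand(self) -> str:
        return self.sites[0].strand

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def proximal(self) -> PolyASite:
        return self.sites[0]

    @property
    def distal(self) -> PolyASite:
        return self.sites[-1]


def build_gene_site_maps(atlas: Iterable[PolyASite]) -> dict[str, GeneSiteMap]:
    """Group atlas sites by gene and sort them proximal -> distal."""
    by_gene: dict[str, list[PolyASite]] = {}
    for site in atlas:
        by_gene.setdefault(site.gene_id, []).append(site)
    maps = {}
    for gene_id, sites in by_gene.items():
        reverse = sites[0].strand == "-"
        ordered = tuple(sorted(sites, key=lambda s: s.rep_pos, reverse=reverse))
        maps[gene_id] = GeneSiteMap(gene_id, ordered)
    return maps


ATLAS_COLUMNS = [
    "chrom",
    "cluster_start",
    "cluster_end",
    "site_id",
    "gene_id",
    "strand",
    "rep_pos",
    "annot_class",
    "hexamers",
]


def _parse_hexamers(token: str, lineno: int) -> tuple[tuple[str, float], ...]:
    token = token.strip()
    if not token or token == ".":
        return ()
    out = []
    for part in token.split(";"):
        if ":" not in part:
            raise AtlasParseError(f"line {lineno}: bad hexamer token {part!r} (want HEXAMER:strength)")
        hexamer, strength = part.rsplit(":", 1)
        try:
            out.append((hexamer.strip(), float(strength)))
        except ValueError as exc:
            raise AtlasParseError(f"line {lineno}: non-numeric hexamer strength in {part!r}") from exc
    return tuple(out)


def read_atlas(path: str | Path) -> list[PolyASite]:
    """Read a poly(A)-site atlas TSV.

    The file is tab-separated with a header line naming at least the columns
    in :data:`ATLAS_COLUMNS`; ``hexamers`` is a semicolon-separated list of
    ``HEXAMER:strength`` tokens (``.`` or empty = no hexamer).
    """
    path = Path(path)
    sites: list[PolyASite] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {name: i for i, name in enumerate(header)}
        missing = [c for c in ATLAS_COLUMNS if c not in col]
        if missing:
            raise AtlasParseError(f"{path}: header missing columns {missing}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                start = int(fields[col["cluster_start"]])
                end = int(fields[col["cluster_end"]])
                rep = int(fields[col["rep_pos"]])
            except ValueError as exc:
                raise AtlasParseError(f"{path} line {lineno}: non-integer coordinate") from exc
            site_id = fields[col["site_id"]]
            if site_id in seen:
                raise AtlasParseError(f"{path} line {lineno}: duplicate site_id {site_id!r}")
            seen.add(site_id)
            try:
                site = PolyASite(
                    site_id=site_id,
                    gene_id=fields[col["gene_id"]],
                    chrom=fields[col["chrom"]],
                    strand=fields[col["strand"]],
                    cluster_start=start,
                    cluster_end=end,
                    rep_pos=rep,
                    annot_class=fields[col["annot_class"]],
                    hexamers=_parse_hexamers(fields[col["hexamers"]], lineno),
                )
            except ValueError as exc:
                raise AtlasParseError(f"{path} line {lineno}: {exc}") from exc
            sites.append(site)
    return sites


def write_atlas(sites: Iterable[PolyASite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ATLAS_COLUMNS) + "\n")
        for s in sites:
            hexamers = ";".join(f"{h}:{v!r}" for h, v in s.hexamers) or "."
            fh.write(
                "\t".join(
                    [
                        s.chrom,
                        str(s.cluster_start),
                        str(s.cluster_end),
                        s.site_id,
                        s.gene_id,
                        s.strand,
                        str(s.rep_pos),
                        s.annot_class,
                        hexamers,
                    ]
                )
                + "\n"
            )


def write_bed6(sites: Iterable[PolyASite], path: str | Path) -> None:
    """Export site clusters as BED6 (0-based half-open, score = 0)."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.cluster_start - 1}\t{s.cluster_end}\t{s.site_id}\t0\t{s.strand}\n"
            )


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    required = {"sample_id", "condition", "replicate"}
    missing = required - set(sheet.columns)
    if missing:
        raise CountsValidationError(f"sample sheet missing columns {sorted(missing)}")
    if "timepoint_h" not in sheet.columns:
        sheet["timepoint_h"] = float("nan")
    return sheet.set_index("sample_id")


def read_counts(
    path: str | Path,
    atlas: Sequence[PolyASite],
    sample_sheet: str | Path | pd.DataFrame,
) -> SiteCountMatrix:
    """Read a site x sample count TSV (first column site_id) against an atlas.

    Counts must be non-negative integers; every site must exist in the atlas.
    The returned matrix is reindexed to atlas order, with zero rows for atlas
    sites absent from the file.
    """
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    if isinstance(sample_sheet, (str, Path)):
        samples = read_sample_sheet(sample_sheet)
    else:
        samples = sample_sheet
    atlas_ids = [s.site_id for s in atlas]
    unknown = set(counts.index) - set(atlas_ids)
    if unknown:
        raise CountsValidationError(f"sites not in atlas: {sorted(unknown)[:5]}")
    values = counts.to_numpy()
    if (values < 0).any():
        raise CountsValidationError("negative counts in matrix")
    if (values != values.astype(int)).any():
        raise CountsValidationError("non-integer counts in matrix")
    counts = counts.reindex(atlas_ids, fill_value=0).astype(int)
    return SiteCountMatrix(counts, samples)


def write_counts(m: SiteCountMatrix, counts_path: str | Path, sheet_path: str | Path | None = None) -> None:
    m.counts.to_csv(counts_path, sep="\t", index_label="site_id")
    if sheet_path is not None:
        m.samples.to_csv(sheet_path, sep="\t", index_label="sample_id")


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Read a 2-column (set_id, gene_id) TSV into {set_id: genes}."""
    df = pd.read_csv(path, sep="\t", header=None, names=["set_id", "gene_id"], dtype=str)
    sets: dict[str, set[str]] = {}
    for set_id, group in df.groupby("set_id"):
        sets[str(set_id)] = set(group["gene_id"])
    return sets


def read_read_ends(path: str | Path) -> pd.DataFrame:
    """Read a table of read 3'-end coordinates: chrom, strand, pos (1-based)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    required = {"chrom", "strand", "pos"}
    missing = required - set(df.columns)
    if missing:
        raise CountsValidationError(f"read-end table missing columns {sorted(missing)}")
    return df


def extract_window(
    fasta: Mapping[str, str],
    site: PolyASite,
    start_offset: int,
    end_offset: int,
) -> tuple[str, bool]:
    """Extract the transcript-oriented sequence window around a cleavage site.

    Offsets are relative to ``rep_pos`` in transcript orientation: negative
    offsets are upstream (5') of the cleavage site, positive downstream (3').
    The window includes both endpoint offsets, so its length is
    ``end_offset - start_offset + 1``. On the minus strand the genomic window
    is mirrored and reverse-complemented. Sequence is returned as RNA.

    ``fasta`` is any mapping of contig name to sequence string (a
    ``pyfaidx.Fasta`` works: its records coerce to string).

    Returns ``(sequence, truncated)``; ``truncated`` is True when the window
    ran off the end of the contig (the available portion is returned).
    """
    if end_offset < start_offset:
        raise ValueError("end_offset must be >= start_offset")
    contig = str(fasta[site.chrom][:])
    n = len(contig)
    if site.strand == "+":
        g_start = site.rep_pos + start_offset  # 1-based inclusive
        g_end = site.rep_pos + end_offset
    else:
        g_start = site.rep_pos - end_offset
        g_end = site.rep_pos - start_offset
    truncated = g_start < 1 or g_end > n
    lo = max(g_start, 1)
    hi = min(g_end, n)
    seq = contig[lo - 1 : hi] if hi >= lo else ""
    if site.strand == "-":
        seq = reverse_complement(seq)
    return to_rna(seq), truncated
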