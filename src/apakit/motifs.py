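"""Poly(A)-site sequence features: PAS hexamer class, UGUA, downstream U/GU content.

The cleavage machinery reads three sequence elements around a poly(A) site:
the CPSF-bound hexamer (canonically AAUAAA/AUUAAA) upstream, CFIm-bound
UGUA elements further upstream (here scanned in the 100 nt upstream of the
cleavage position), and the CstF-bound U-rich / GU-rich region 20-40 nt
downstream. This module profiles those features per site and compares their
frequencies between gene groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from apakit import stats as _stats
from apakit.io import PolyASite, extract_window

CANONICAL_HEXAMERS = frozenset({"AAUAAA", "AUUAAA"})

# non-canonical PAS hexamer vocabulary (atlas signal annotation)
OTHER_HEXAMERS = frozenset(
    {
        "AAACAU", "AAUAAC", "UUAAAG", "UUAAAU", "UAUAAA", "AAUACA", "CAUAAA",
        "AAUAUA", "GAUAAA", "AAUGAA", "AAGAAA", "ACUAAA", "AAUAGA", "AAUAAU",
        "AACAAA", "AUUACA", "AUUAUA", "AACAAG", "AAUAAG",
    }
)

HEXAMER_CANONICAL = "canonical"
HEXAMER_OTHER = "other"
HEXAMER_NONE = "none"

UPSTREAM_UGUA_WINDOW = (-100, -1)
DOWNSTREAM_WINDOW = (20, 40)


@dataclass
class MotifProfile:
    """Per-site motif summary over the standard windows.

    ``ugua_count`` counts exact UGUA matches at every offset of the
    100 nt upstream window; the downstream composition fields describe the
    +20..+40 window (21 nt when not truncated by a contig end).
    """

    site_id: str
    hexamer_class: str
    chosen_hexamer: str | None
    ugua_count: int
    u_fraction: float
    ug_fraction: float
    has_u4run: bool
    truncated: bool = False


def classify_hexamer(
    site: PolyASite,
    canonical: frozenset[str] = CANONICAL_HEXAMERS,
    other: frozenset[str] = OTHER_HEXAMERS,
) -> tuple[str, str | None]:
    """Pick the site's strongest-signal hexamer and classify it.

    Sites annotated with several hexamers use the one with the highest
    signal strength. Class is ``canonical`` (AAUAAA/AUUAAA), ``other``
    (known non-canonical vocabulary; unknown strings also fall here), or
    ``none`` when the site has no hexamer.
    """
    if not site.hexamers:
        return HEXAMER_NONE, None
    for h, strength in site.hexamers:
        if strength < 0:
            raise ValueError(f"site {site.site_id}: negative hexamer signal strength")
    chosen = max(site.hexamers, key=lambda hs: hs[1])[0]
    if chosen in canonical:
        return HEXAMER_CANONICAL, chosen
    if chosen not in other:
        import warnings

        warnings.warn(f"site {site.site_id}: hexamer {chosen!r} outside known vocabulary")
    return HEXAMER_OTHER, chosen


def scan_ugua(seq: str) -> int:
    """Count exact UGUA matches at every offset (overlaps counted; N never matches)."""
    seq = seq.upper()
    return sum(1 for i in range(len(seq) - 3) if seq[i : i + 4] == "UGUA")


def downstream_composition(seq: str) -> tuple[float, float, bool]:
    """U fraction, U+G fraction and presence of a UUUU run in a downstream window.

    Fractions are over the available window length (truncated windows allowed);
    an empty window returns NaNs.
    """
    seq = seq.upper()
    if not seq:
        return float("nan"), float("nan"), False
    n = len(seq)
    n_u = seq.count("U")
    n_g = seq.count("G")
    return n_u / n, (n_u + n_g) / n, "UUUU" in seq


def profile_site(fasta: Mapping[str, str], site: PolyASite) -> MotifProfile:
    """Build the full motif profile of one site from genomic sequence."""
    hex_class, chosen = classify_hexamer(site)
    upstream, trunc_up = extract_window(fasta, site, *UPSTREAM_UGUA_WINDOW)
    downstream, trunc_dn = extract_window(fasta, site, *DOWNSTREAM_WINDOW)
    u_frac, ug_frac, u4 = downstream_composition(downstream)
    return MotifProfile(
        site_id=site.site_id,
        hexamer_class=hex_class,
        chosen_hexamer=chosen,
        ugua_count=scan_ugua(upstream),
        u_fraction=u_frac,
        ug_fraction=ug_frac,
        has_u4run=u4,
        truncated=trunc_up or trunc_dn,
    )


def profile_sites(fasta: Mapping[str, str], sites: Iterable[PolyASite]) -> list[MotifProfile]:
    return [profile_site(fasta, s) for s in sites]


CATEGORICAL_FEATURES = ("hexamer_class", "ugua_presence", "has_u4run")
CONTINUOUS_FEATURES = ("u_fraction", "ug_fraction")


def _feature_flags(profiles: Sequence[MotifProfile], feature: str, level: str | None) -> np.ndarray:
    if feature == "hexamer_class":
        return np.array([p.hexamer_class == level for p in profiles])
    if feature == "ugua_presence":
        return np.array([p.ugua_count >= 1 for p in profiles])
    if feature == "has_u4run":
        return np.array([p.has_u4run for p in profiles])
    raise ValueError(f"unknown categorical feature {feature!r}")


def compare_motif_frequencies(
    profiles_shifted: Sequence[MotifProfile],
    profiles_control: Sequence[MotifProfile],
    feature: str,
) -> pd.DataFrame:
    """Compare one motif feature between two site groups.

    Categorical features (hexamer class levels, UGUA presence, UUUU-run
    presence) are tested with two-tailed Fisher's exact test on the 2x2
    presence/absence table; continuous features (u_fraction, ug_fraction)
    with the unpaired rank-sum test. Returns one row per tested level.
    """
    if not profiles_shifted or not profiles_control:
        raise ValueError("both profile groups must be non-empty")
    rows = []
    if feature in CONTINUOUS_FEATURES:
        x = np.array([getattr(p, feature) for p in profiles_shifted], dtype=float)
        y = np.array([getattr(p, feature) for p in profiles_control], dtype=float)
        x, y = x[np.isfinite(x)], y[np.isfinite(y)]
        stat, p = _stats.rank_tests(x, y, paired=False)
        rows.append(
            {
                "feature": feature,
                "level": "NA",
                "test": "rank_sum",
                "shifted_summary": float(np.median(x)),
                "control_summary": float(np.median(y)),
                "odds_ratio": np.nan,
                "p": p,
            }
        )
    elif feature in CATEGORICAL_FEATURES:
        levels = (
            [HEXAMER_CANONICAL, HEXAMER_OTHER, HEXAMER_NONE]
            if feature == "hexamer_class"
            else [feature]
        )
        for level in levels:
            fs = _feature_flags(profiles_shifted, feature, level)
            fc = _feature_flags(profiles_control, feature, level)
            table = _stats.ContingencyTable2x2(
                a=int(fs.sum()),
                b=int((~fs).sum()),
                c=int(fc.sum()),
                d=int((~fc).sum()),
            )
            odds, p = _stats.fisher_exact_2x2(table)
            rows.append(
                {
                    "feature": feature,
                    "level": level,
                    "test": "fisher_exact",
                    "shifted_summary": float(fs.mean()),
                    "control_summary": float(fc.mean()),
                    "odds_ratio": odds,
                    "p": p,
                }
            )
    else:
        raise ValueError(f"unknown feature {feature!r}")
    return pd.DataFrame(rows)


def profiles_to_frame(profiles: Sequence[MotifProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "site_id": p.site_id,
                "hexamer_class": p.hexamer_class,
                "chosen_hexamer": p.chosen_hexamer or "NA",
                "ugua_count": p.ugua_count,
                "u_fraction": p.u_fraction,
                "ug_fraction": p.ug_fraction,
                "has_u4run": p.has_u4run,
                "truncated": p.truncated,
            }
            for p in profiles
        ]
    ).set_index("site_id")
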