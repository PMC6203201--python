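"""Splice-site position weight matrices: build, score, information content.

A 5' splice site is modeled as a 9-nt window (3 exonic + 6 intronic bases)
and a 3' splice site as a 23-nt window (20 intronic + 3 exonic bases).
PWMs are trained on constitutive splice-site sequences; a candidate site is
scored by the log10 probability of its sequence under the PWM, and group
differences in score are assessed by one-way ANOVA with Tukey HSD.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from apakit import stats as _stats

ALPHABET = "ACGU"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"
SITE_LENGTHS = {FIVE_PRIME: 9, THREE_PRIME: 23}


@dataclass
class PWMModel:
    """Per-position base probabilities for one splice-site kind."""

    site_kind: str
    probs: np.ndarray  # positions x 4, rows sum to 1
    pseudocount: float
    n_training: int

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be positions x 4 (A,C,G,U)")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each position's probabilities must sum to 1")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))


def build_pwm(
    training_seqs: Sequence[str],
    site_kind: str,
    pseudocount: float = 1.0,
) -> PWMModel:
    """Estimate a PWM from equal-length RNA sequences with Laplace smoothing.

    probs[p][b] = (count(p,b) + pseudocount) / (n + 4*pseudocount).
    Sequences containing characters outside {A,C,G,U} (e.g. N) are dropped.
    """
    if site_kind not in SITE_LENGTHS:
        raise ValueError(f"site_kind must be one of {sorted(SITE_LENGTHS)}")
    length = SITE_LENGTHS[site_kind]
    usable = []
    n_dropped = 0
    for i, seq in enumerate(training_seqs):
        seq = seq.upper().replace("T", "U")
        if len(seq) != length:
            raise ValueError(
                f"training sequence {i} has length {len(seq)}, expected {length} for {site_kind}"
            )
        if any(b not in _BASE_INDEX for b in seq):
            n_dropped += 1
            continue
        usable.append(seq)
    if not usable:
        raise ValueError("no usable training sequences (empty set or all contained N)")
    counts = np.zeros((length, 4))
    for seq in usable:
        for p, b in enumerate(seq):
            counts[p, _BASE_INDEX[b]] += 1
    n = len(usable)
    probs = (counts + pseudocount) / (n + 4 * pseudocount)
    return PWMModel(site_kind, probs, pseudocount, n)


def score_sequence(pwm: PWMModel, seq: str) -> float:
    """log10 probability of ``seq`` under the PWM (sum of per-position logs).

    Sequences containing N score NaN. A zero-probability base (possible only
    with pseudocount 0) scores -inf.
    """
    seq = seq.upper().replace("T", "U")
    if len(seq) != pwm.length:
        raise ValueError(f"sequence length {len(seq)} != PWM length {pwm.length}")
    total = 0.0
    for p, b in enumerate(seq):
        if b not in _BASE_INDEX:
            return float("nan")
        prob = pwm.probs[p, _BASE_INDEX[b]]
        if prob == 0.0:
            return float("-inf")
        total += np.log10(prob)
    return total


def information_content(pwm: PWMModel) -> np.ndarray:
    """Per-position information content in bits: 2 + sum_b p log2 p (0*log0 = 0).

    Ranges from 0 bits (uniform position) to 2 bits (deterministic position).
    """
    p = pwm.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    return 2.0 + plogp.sum(axis=1)


@dataclass
class GroupComparison:
    scores: dict[str, np.ndarray]
    group_medians: pd.Series
    p_omnibus: float
    pairwise: pd.DataFrame
    excluded_groups: list[str]


def compare_site_groups(
    pwm: PWMModel, groups: Mapping[str, Sequence[str]]
) -> GroupComparison:
    """Score each group's sequences and compare log10-score distributions.

    One-way ANOVA across groups with Tukey HSD pairwise comparisons; groups
    with fewer than 2 finite scores are excluded with a warning.
    """
    import warnings

    scored: dict[str, np.ndarray] = {}
    excluded = []
    for label, seqs in groups.items():
        s = np.array([score_sequence(pwm, q) for q in seqs], dtype=float)
        s = s[np.isfinite(s)]
        if len(s) < 2:
            warnings.warn(f"group {label!r} excluded (<2 usable scores)")
            excluded.append(label)
            continue
        scored[label] = s
    if len(scored) < 2:
        raise ValueError("need >= 2 groups with >= 2 usable scores each")
    res = _stats.anova_tukey(scored)
    medians = pd.Series({k: float(np.median(v)) for k, v in scored.items()}, name="median")
    return GroupComparison(scored, medians, res.p_omnibus, res.pairwise, excluded)


def write_pwm(pwm: PWMModel, path: str | Path) -> None:
    df = pd.DataFrame(pwm.probs, columns=list(ALPHABET))
    df.index.name = "position"
    with open(path, "w") as fh:
        fh.write(f"# site_kind={pwm.site_kind} pseudocount={pwm.pseudocount:g} n_training={pwm.n_training}\n")
        df.to_csv(fh, sep="\t")


def read_pwm(path: str | Path) -> PWMModel:
    with open(path) as fh:
        header = fh.readline()
        meta = dict(tok.split("=") for tok in header.lstrip("# ").split())
        df = pd.read_csv(fh, sep="\t", index_col=0)
    return PWMModel(
        site_kind=meta["site_kind"],
        probs=df[list(ALPHABET)].to_numpy(),
        pseudocount=float(meta["pseudocount"]),
        n_training=int(meta["n_training"]),
    )
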