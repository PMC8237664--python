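"""Mitochondrial consensus, contamination, diversity, and haplogroups.

Ancient-sample contamination is estimated from heteroplasmy: mtDNA is
effectively haploid, so at positions known to vary among goat haplotypes
any reads discordant with the sample's own consensus betray exogenous
molecules (or sequencing error).  The estimate is the pooled discordant
read fraction over those diagnostic positions, with an exact
(Clopper-Pearson) binomial confidence interval.

Within-group diversity is the mean number of pairwise differences among
haplotype sequences; haplogroups (goat mtDNA clades A, B, C, D, F, G) are
assigned by the nearest labeled reference under Hamming distance.
Sequences are treated as linear: circularity is resolved upstream by
realignment to a linearized reference.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ContaminationEstimate",
    "HaplogroupCall",
    "mt_consensus",
    "estimate_contamination",
    "mean_pairwise_differences",
    "assign_haplogroup",
]

_BASES = "ACGT"


@dataclass
class ContaminationEstimate:
    sample: str
    n_diagnostic_sites: int
    n_reads: int
    n_discordant: int
    c_hat: float
    ci_low: float
    ci_high: float


@dataclass
class HaplogroupCall:
    label: str
    distance: int
    margin: int
    ambiguous: bool


def mt_consensus(pileup: np.ndarray, min_depth: int = 3) -> str:
    """Majority-rule consensus from a (4, L) ACGT base-count pileup.

    Positions with depth below ``min_depth`` or a tied majority are
    called N.
    """
    pileup = np.asarray(pileup)
    if pileup.ndim != 2 or pileup.shape[0] != 4:
        raise ValueError("pileup must have shape (4, L) with rows A,C,G,T")
    if pileup.shape[1] == 0:
        raise ValueError("empty pileup")
    depth = pileup.sum(axis=0)
    best = pileup.argmax(axis=0)
    top = pileup.max(axis=0)
    tied = (pileup == top).sum(axis=0) > 1
    seq = np.array([_BASES[i] for i in best])
    seq[(depth < min_depth) | tied] = "N"
    return "".join(seq)


def estimate_contamination(
    pileup: np.ndarray,
    known_variant_positions: np.ndarray,
    sample: str = "",
    min_depth: int = 3,
    ci_level: float = 0.95,
) -> ContaminationEstimate:
    """Contamination from the heteroplasmic rate at known variant positions.

    ``known_variant_positions`` are 1-based positions known to vary among
    haplotypes.  Discordance is measured against the sample's own
    consensus; positions where the consensus is N are skipped.  The
    estimate is total discordant reads / total reads over the diagnostic
    positions, with a Clopper-Pearson binomial CI.
    """
    pileup = np.asarray(pileup)
    consensus = mt_consensus(pileup, min_depth=min_depth)
    pos_idx = np.asarray(known_variant_positions, dtype=np.int64) - 1
    if np.any((pos_idx < 0) | (pos_idx >= pileup.shape[1])):
        raise ValueError("diagnostic position outside pileup length")
    total = 0
    discordant = 0
    n_used = 0
    for p in pos_idx:
        base = consensus[p]
        if base == "N":
            continue
        col = pileup[:, p]
        depth = int(col.sum())
        if depth == 0:
            continue
        total += depth
        discordant += depth - int(col[_BASES.index(base)])
        n_used += 1
    if total == 0:
        raise ValueError("no reads at the known variant positions")
    c_hat = discordant / total
    lo, hi = _clopper_pearson(discordant, total, ci_level)
    return ContaminationEstimate(
        sample=sample,
        n_diagnostic_sites=n_used,
        n_reads=total,
        n_discordant=discordant,
        c_hat=c_hat,
        ci_low=lo,
        ci_high=hi,
    )


def _clopper_pearson(k: int, n: int, level: float) -> tuple[float, float]:
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def _hamming(a: str, b: str) -> tuple[int, int]:
    """(differences, compared positions), skipping positions with N."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    diffs = compared = 0
    for x, y in zip(a, b):
        if x == "N" or y == "N":
            continue
        compared += 1
        diffs += x != y
    return diffs, compared


def mean_pairwise_differences(sequences: list[str]) -> float:
    """Mean Hamming distance over all unordered pairs of haplotypes.

    Positions with N in either sequence of a pair are skipped for that
    pair only.
    """
    if len(sequences) < 2:
        raise ValueError("need >= 2 sequences")
    total = 0.0
    n_pairs = 0
    for a, b in itertools.combinations(sequences, 2):
        diffs, _ = _hamming(a, b)
        total += diffs
        n_pairs += 1
    return total / n_pairs


def assign_haplogroup(query: str, references: dict[str, str]) -> HaplogroupCall:
    """Assign the label of the minimum-Hamming labeled reference.

    ``references`` maps reference name -> sequence; names carry the
    haplogroup label either as the whole name or as the prefix before an
    underscore (e.g. ``B_ref1``).  Margin is the second-best distance
    minus the best; equidistant distinct labels set the ambiguous flag.
    """
    if len({_label(n) for n in references}) < 2:
        raise ValueError("need references from >= 2 distinct haplogroup labels")
    dists: list[tuple[int, str]] = []
    for name, seq in references.items():
        d, _ = _hamming(query, seq)
        dists.append((d, _label(name)))
    dists.sort()
    best_d, best_label = dists[0]
    other = [d for d, lab in dists if lab != best_label]
    margin = (min(other) - best_d) if other else 0
    ambiguous = any(d == best_d and lab != best_label for d, lab in dists)
    return HaplogroupCall(
        label=best_label, distance=best_d, margin=margin, ambiguous=ambiguous
    )


def _label(name: str) -> str:
    return name.split("_", 1)[0]
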