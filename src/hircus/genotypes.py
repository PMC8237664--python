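"""Site-panel ascertainment and pseudohaploid genotype calling.

Low-coverage ancient genomes cannot be diploid-genotyped reliably, so the
standard practice is pseudohaploid calling: at each site of an ascertained
panel, one sequencing read is sampled uniformly at random and its allele
reported as a haploid call.  Panels are restricted to biallelic
transversion sites (immune to post-mortem C->T deamination) polymorphic in
a set of modern reference genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "SitePanel",
    "PseudohaploidMatrix",
    "is_transversion",
    "ascertain_panel",
    "pseudohaploid_call",
    "population_frequencies",
]

MISSING = -1
_TRANSITIONS = {frozenset("AG"), frozenset("CT")}
_VALID_BASES = set("ACGT")


def is_transversion(ref: str, alt: str) -> bool:
    """True when {ref, alt} is a purine<->pyrimidine substitution pair."""
    pair = frozenset((ref.upper(), alt.upper()))
    if len(pair) != 2 or not pair <= _VALID_BASES:
        return False
    return pair not in _TRANSITIONS


@dataclass
class SitePanel:
    """Ascertained biallelic transversion sites with per-population counts.

    ``sites`` columns: chrom, pos (1-based), ref, alt, then per population
    ``<pop>_alt`` and ``<pop>_n`` allele counts from the ascertainment set.
    """

    sites: pd.DataFrame
    populations: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        bad = [
            (r, a)
            for r, a in zip(self.sites["ref"], self.sites["alt"])
            if not is_transversion(r, a)
        ]
        if bad:
            raise ValueError(f"panel contains non-transversion pairs: {bad[:3]}")

    def __len__(self) -> int:
        return len(self.sites)

    def to_tsv(self, path) -> None:
        self.sites.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SitePanel":
        sites = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        pops = tuple(
            c[: -len("_alt")] for c in sites.columns if c.endswith("_alt")
        )
        return cls(sites, pops)


@dataclass
class PseudohaploidMatrix:
    """Samples x panel-sites haploid calls in {0 (ref), 1 (alt), MISSING}."""

    calls: np.ndarray  # int8, shape (n_samples, n_sites)
    samples: tuple[str, ...]
    panel: SitePanel

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.samples), len(self.panel)):
            raise ValueError("calls shape does not match samples x panel sites")
        if not np.isin(self.calls, (MISSING, 0, 1)).all():
            raise ValueError("calls must be 0, 1 or MISSING")

    @property
    def callable_counts(self) -> np.ndarray:
        """Per-sample number of non-missing calls."""
        return (self.calls != MISSING).sum(axis=1)

    @property
    def missing_rate(self) -> np.ndarray:
        return 1.0 - self.callable_counts / self.calls.shape[1]

    def sample_index(self, name: str) -> int:
        return self.samples.index(name)


def ascertain_panel(
    sites: pd.DataFrame,
    genotypes: np.ndarray,
    sample_pops: list[str],
    min_pops_polymorphic: int = 0,
) -> SitePanel:
    """Ascertain a biallelic-transversion panel from modern diploid genotypes.

    ``sites`` carries chrom, pos, ref, alt; ``genotypes`` is a
    samples x sites alt-dosage matrix in {0, 1, 2} with MISSING (-1) for
    no-calls; ``sample_pops`` assigns each row a population.  Sites are
    retained when the ref/alt pair is a transversion and the pooled modern
    set is polymorphic (0 < pooled alt frequency < 1).  With
    ``min_pops_polymorphic`` > 0, at least that many individual
    populations must also be polymorphic.  Per-population allele counts
    are recorded for downstream frequency-based statistics.
    """
    genotypes = np.asarray(genotypes)
    if genotypes.shape != (len(sample_pops), len(sites)):
        raise ValueError("genotypes shape must be (n_samples, n_sites)")
    pops = sorted(set(sample_pops))
    pop_rows = {p: np.array([sp == p for sp in sample_pops]) for p in pops}

    tv = np.array([is_transversion(r, a) for r, a in zip(sites["ref"], sites["alt"])])
    observed = genotypes != MISSING
    alt_total = np.where(observed, genotypes, 0).sum(axis=0)
    n_total = 2 * observed.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = np.where(n_total > 0, alt_total / np.maximum(n_total, 1), np.nan)
    polymorphic = (n_total > 0) & (alt_total > 0) & (alt_total < n_total)

    keep = tv & polymorphic
    if min_pops_polymorphic > 0:
        per_pop_poly = np.zeros(len(sites), dtype=int)
        for p in pops:
            rows = pop_rows[p]
            obs = observed[rows]
            alt = np.where(obs, genotypes[rows], 0).sum(axis=0)
            tot = 2 * obs.sum(axis=0)
            per_pop_poly += ((alt > 0) & (alt < tot)).astype(int)
        keep &= per_pop_poly >= min_pops_polymorphic

    out = sites.loc[keep, ["chrom", "pos", "ref", "alt"]].reset_index(drop=True)
    for p in pops:
        rows = pop_rows[p]
        obs = observed[rows]
        out[f"{p}_alt"] = np.where(obs, genotypes[rows], 0).sum(axis=0)[keep]
        out[f"{p}_n"] = (2 * obs.sum(axis=0))[keep]
    return SitePanel(out, tuple(pops))


def pseudohaploid_call(
    pileups: dict[str, pd.DataFrame],
    panel: SitePanel,
    rng: np.random.Generator,
    min_depth: int = 1,
) -> PseudohaploidMatrix:
    """Random-read-sampling haploid calls at panel sites.

    ``pileups`` maps sample name -> pileup table with columns chrom, pos,
    ref_count, alt_count (and optionally other_count for reads matching
    neither panel allele).  At each panel site with at least ``min_depth``
    reads one read is chosen uniformly at random; the call is its allele
    when it matches ref or alt and MISSING otherwise.  Zero coverage gives
    MISSING, never an error.  Deterministic given the generator state.
    """
    n_sites = len(panel)
    key = panel.sites[["chrom", "pos"]]
    calls = np.full((len(pileups), n_sites), MISSING, dtype=np.int8)
    samples = tuple(pileups)
    for i, name in enumerate(samples):
        pile = pileups[name]
        merged = key.merge(pile, on=["chrom", "pos"], how="left")
        ref_c = merged["ref_count"].fillna(0).to_numpy(dtype=np.int64)
        alt_c = merged["alt_count"].fillna(0).to_numpy(dtype=np.int64)
        oth_c = (
            merged["other_count"].fillna(0).to_numpy(dtype=np.int64)
            if "other_count" in merged
            else np.zeros(n_sites, dtype=np.int64)
        )
        depth = ref_c + alt_c + oth_c
        covered = depth >= max(1, min_depth)
        # index of the sampled read within [0, depth)
        draw = rng.integers(0, np.maximum(depth, 1))
        is_alt = (draw >= ref_c) & (draw < ref_c + alt_c)
        is_ref = draw < ref_c
        site_call = np.where(is_ref, 0, np.where(is_alt, 1, MISSING)).astype(np.int8)
        calls[i] = np.where(covered, site_call, MISSING)
    return PseudohaploidMatrix(calls, samples, panel)


def population_frequencies(
    calls: np.ndarray, sample_pops: list[str], ploidy: int = 1
) -> pd.DataFrame:
    """Per-population alt-allele frequencies from a call matrix.

    ``calls`` is samples x sites with MISSING (-1) entries; haploid
    pseudohaploid calls use ``ploidy=1``, diploid dosage matrices
    ``ploidy=2``.  Returns a long-form frame with one row per
    (population, site): columns pop, site, freq, n (allele count),
    available (False when no sample in the population was called).
    """
    calls = np.asarray(calls)
    if len(sample_pops) != calls.shape[0]:
        raise ValueError("one population label per sample row is required")
    pops = sorted(set(sample_pops))
    frames = []
    for p in pops:
        rows = np.array([sp == p for sp in sample_pops])
        if not rows.any():
            raise ValueError(f"population {p!r} has no samples")
        sub = calls[rows]
        obs = sub != MISSING
        n = ploidy * obs.sum(axis=0)
        alt = np.where(obs, sub, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "pop": p,
                    "site": np.arange(calls.shape[1]),
                    "freq": freq,
                    "n": n,
                    "available": n > 0,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
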