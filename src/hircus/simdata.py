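"""Synthetic populations, genomes, reads, pedigrees and mtDNA pileups.

The generator emulates the data structure of an ancient-DNA population
study: a rooted tree of wild/domestic populations diverging by genetic
drift (Balding-Nichols model), optional admixture edges, diploid
individuals with planted autozygous tracts, sequencing reads at
configurable coverage and base error, haploid male X chromosomes,
pedigreed pairs, and mitochondrial pileups with a known contamination
fraction.  Every stochastic quantity is recorded in a ``SimTruth`` so
downstream estimators can be validated by recovery tests.

Sites are unlinked; linkage enters only through genomic position labels,
which is sufficient to exercise window and block machinery downstream.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PopulationNode",
    "SimConfig",
    "SimTruth",
    "drift_frequencies",
    "admix_frequencies",
    "simulate_individuals",
    "simulate_reads",
    "simulate_pedigree_pair",
    "simulate_mt_pileup",
    "simulate_world",
    "simulate_window_track",
    "simulate_site_positions",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
# Transversion-safe allele pair used for synthetic panels.
REF_BASE, ALT_BASE = "A", "T"

PEDIGREE_PI = {
    "unrelated": 0.0,
    "parent_offspring": 0.5,
    "full_sib": 0.5,
    "self": 1.0,
}


@dataclass(frozen=True)
class PopulationNode:
    """One branch of the population tree.

    ``drift`` is the Balding-Nichols F of the branch leading to this
    population from its parent (the root has no drift).
    """

    name: str
    parent: str | None
    drift: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.drift < 1.0):
            raise ValueError(
                f"drift F must lie in [0, 1); got {self.drift!r} for {self.name!r}"
            )


@dataclass(frozen=True)
class SimConfig:
    """Full description of a synthetic world.

    Identical configs (including ``seed``) produce bit-identical output;
    child random streams are spawned per population and per individual so
    determinism survives any generation order.
    """

    tree: tuple[PopulationNode, ...]
    n_sites: int
    n_individuals: dict[str, int]
    chrom_lengths: dict[str, int]
    coverage: float = 2.0
    base_error: float = 2e-5
    admixture_edges: tuple[tuple[str, str, float], ...] = ()
    roh_tracts: dict[str, tuple[tuple[str, int, int], ...]] = field(
        default_factory=dict
    )
    seed: int = 0

    def __post_init__(self) -> None:
        names = [n.name for n in self.tree]
        if len(set(names)) != len(names):
            raise ValueError("duplicate population names in tree")
        known = set(names)
        roots = [n for n in self.tree if n.parent is None]
        if len(roots) != 1:
            raise ValueError("tree must have exactly one root")
        for node in self.tree:
            if node.parent is not None and node.parent not in known:
                raise ValueError(f"unknown parent {node.parent!r}")
        for src, dst, alpha in self.admixture_edges:
            if src not in known or dst not in known:
                raise ValueError(f"admixture edge references unknown population")
            if not (0.0 <= alpha <= 1.0):
                raise ValueError(f"admixture proportion must be in [0, 1]; got {alpha}")
        if not (0.0 <= self.base_error <= 0.01):
            raise ValueError("base_error must lie in [0, 0.01]")
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")
        for pop in self.n_individuals:
            if pop not in known:
                raise ValueError(f"n_individuals references unknown population {pop!r}")
        for indiv, tracts in self.roh_tracts.items():
            seen: dict[str, list[tuple[int, int]]] = {}
            for chrom, start, end in tracts:
                if chrom not in self.chrom_lengths:
                    raise ValueError(f"tract on unknown chromosome {chrom!r}")
                if not (1 <= start <= end <= self.chrom_lengths[chrom]):
                    raise ValueError(
                        f"tract {chrom}:{start}-{end} outside chromosome bounds"
                    )
                for s0, e0 in seen.get(chrom, []):
                    if start <= e0 and s0 <= end:
                        raise ValueError(
                            f"overlapping tracts for {indiv!r} on {chrom}"
                        )
                seen.setdefault(chrom, []).append((start, end))

    @property
    def populations(self) -> list[str]:
        return [n.name for n in self.tree]


@dataclass
class SimTruth:
    """Ground truth of a simulated world, for recovery tests."""

    config: SimConfig
    chrom: np.ndarray  # per-site chromosome label
    pos: np.ndarray  # per-site 1-based position
    pop_freqs: dict[str, np.ndarray]  # per-pop alt allele frequency per site
    genotypes: dict[str, np.ndarray]  # sample -> alt-allele dosage in {0,1,2}
    sample_pop: dict[str, str]
    tract_registry: dict[str, tuple[tuple[str, int, int], ...]]

    def to_json(self) -> str:
        payload = {
            "config": _config_to_dict(self.config),
            "samples": {s: p for s, p in self.sample_pop.items()},
            "tracts": {
                s: [list(t) for t in tr] for s, tr in self.tract_registry.items()
            },
            "pop_freq_means": {
                p: float(np.mean(f)) for p, f in self.pop_freqs.items()
            },
            "n_sites": int(self.pos.size),
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _config_to_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["tree"] = [dataclasses.asdict(n) for n in config.tree]
    return d


def drift_frequencies(
    ancestral_freqs: np.ndarray, F: float, rng: np.random.Generator
) -> np.ndarray:
    """Drift allele frequencies down one branch of the population tree.

    Child frequencies are drawn per site from the Balding-Nichols
    distribution Beta(p(1-F)/F, (1-p)(1-F)/F), whose mean is the parental
    frequency p and whose variance is F p(1-p).  ``F = 0`` copies the
    frequencies exactly, and fixed alleles (p in {0, 1}) stay fixed.
    """
    if not (0.0 <= F < 1.0):
        raise ValueError(f"drift F must lie in [0, 1); got {F}")
    p = np.asarray(ancestral_freqs, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("ancestral frequencies must lie in [0, 1]")
    if F == 0.0:
        return p.copy()
    out = p.copy()
    seg = (p > 0) & (p < 1)
    scale = (1.0 - F) / F
    out[seg] = rng.beta(p[seg] * scale, (1.0 - p[seg]) * scale)
    return out


def admix_frequencies(
    p_source: np.ndarray, p_dest: np.ndarray, alpha: float
) -> np.ndarray:
    """Mix a source population's frequencies into a destination's.

    Returns ``alpha * p_source + (1 - alpha) * p_dest`` elementwise,
    modelling a single admixture pulse contributing proportion ``alpha``.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"admixture proportion must lie in [0, 1]; got {alpha}")
    p_source = np.asarray(p_source, dtype=float)
    p_dest = np.asarray(p_dest, dtype=float)
    if p_source.shape != p_dest.shape:
        raise ValueError(
            f"frequency vectors differ in shape: {p_source.shape} vs {p_dest.shape}"
        )
    return alpha * p_source + (1.0 - alpha) * p_dest


def simulate_site_positions(
    n_sites: int, chrom_lengths: dict[str, int], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Scatter panel sites uniformly over the genome, sorted per chromosome.

    Sites are apportioned to chromosomes proportionally to length and given
    distinct uniform 1-based positions.
    """
    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    counts = np.floor(n_sites * lengths / lengths.sum()).astype(int)
    # distribute the remainder to the longest chromosomes first
    for i in np.argsort(-lengths)[: n_sites - counts.sum()]:
        counts[i] += 1
    chrom_out: list[np.ndarray] = []
    pos_out: list[np.ndarray] = []
    for c, k in zip(chroms, counts):
        if k == 0:
            continue
        pos = np.sort(
            rng.choice(chrom_lengths[c], size=k, replace=False).astype(np.int64) + 1
        )
        chrom_out.append(np.full(k, c, dtype=object))
        pos_out.append(pos)
    return np.concatenate(chrom_out), np.concatenate(pos_out)


def _tract_mask(
    chrom: np.ndarray,
    pos: np.ndarray,
    tracts: Sequence[tuple[str, int, int]],
) -> np.ndarray:
    mask = np.zeros(pos.size, dtype=bool)
    for tchrom, start, end in tracts:
        mask |= (chrom == tchrom) & (pos >= start) & (pos <= end)
    return mask


def simulate_individuals(
    freqs: np.ndarray,
    n: int,
    rng: np.random.Generator,
    roh_tracts: Sequence[Sequence[tuple[str, int, int]]] | None = None,
    chrom: np.ndarray | None = None,
    pos: np.ndarray | None = None,
) -> np.ndarray:
    """Draw diploid genotypes (alt-allele dosage 0/1/2) for ``n`` individuals.

    Outside planted tracts genotypes follow Hardy-Weinberg proportions at
    the supplied frequencies; inside a tract a single allele is drawn and
    duplicated, forcing homozygosity (the autozygosity signal the ROH
    caller must recover).
    """
    freqs = np.asarray(freqs, dtype=float)
    genos = np.empty((n, freqs.size), dtype=np.int8)
    for i in range(n):
        a1 = rng.random(freqs.size) < freqs
        a2 = rng.random(freqs.size) < freqs
        g = a1.astype(np.int8) + a2.astype(np.int8)
        if roh_tracts is not None and len(roh_tracts) > i and roh_tracts[i]:
            if chrom is None or pos is None:
                raise ValueError("roh_tracts requires site chrom/pos arrays")
            inside = _tract_mask(chrom, pos, roh_tracts[i])
            g[inside] = 2 * a1[inside].astype(np.int8)
        genos[i] = g
    return genos


def simulate_reads(
    genotypes: np.ndarray,
    coverage: float,
    base_error: float,
    rng: np.random.Generator,
    ploidy: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a per-site allele-count pileup for one sample.

    Depth is Poisson(``coverage``) per site; each read copies the allele of
    a uniformly chosen chromosome and is flipped to the other panel allele
    with probability ``base_error``.  ``ploidy=1`` models the male X or
    mtDNA (genotypes then take values 0/1).

    Returns ``(ref_count, alt_count)`` arrays.
    """
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    if not (0.0 <= base_error <= 0.01):
        raise ValueError("base_error must lie in [0, 0.01]")
    if ploidy not in (1, 2):
        raise ValueError("ploidy must be 1 or 2")
    g = np.asarray(genotypes, dtype=float)
    if g.max(initial=0) > ploidy:
        raise ValueError("genotype dosage exceeds ploidy")
    depth = rng.poisson(coverage, size=g.size)
    p_alt_true = g / ploidy
    p_alt = p_alt_true * (1.0 - base_error) + (1.0 - p_alt_true) * base_error
    alt = rng.binomial(depth, p_alt)
    return (depth - alt).astype(np.int64), alt.astype(np.int64)


def simulate_pedigree_pair(
    freqs: np.ndarray, relation: str, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float]:
    """Simulate two diploid genotypes with a known pedigree relationship.

    Supported relations and their true genome-wide IBD proportions (pi):
    ``unrelated`` (0), ``parent_offspring`` (0.5), ``full_sib`` (0.5),
    ``self`` (1).  Returns ``(genotype_a, genotype_b, pi)``.
    """
    if relation not in PEDIGREE_PI:
        raise ValueError(
            f"relation must be one of {sorted(PEDIGREE_PI)}; got {relation!r}"
        )
    freqs = np.asarray(freqs, dtype=float)
    m = freqs.size

    def haplotype() -> np.ndarray:
        return (rng.random(m) < freqs).astype(np.int8)

    if relation == "unrelated":
        a = haplotype() + haplotype()
        b = haplotype() + haplotype()
    elif relation == "self":
        a = haplotype() + haplotype()
        b = a.copy()
    elif relation == "parent_offspring":
        pa1, pa2 = haplotype(), haplotype()
        a = pa1 + pa2
        transmit = np.where(rng.random(m) < 0.5, pa1, pa2)
        b = transmit + haplotype()
    else:  # full_sib
        pa1, pa2 = haplotype(), haplotype()
        pb1, pb2 = haplotype(), haplotype()
        a = np.where(rng.random(m) < 0.5, pa1, pa2) + np.where(
            rng.random(m) < 0.5, pb1, pb2
        )
        b = np.where(rng.random(m) < 0.5, pa1, pa2) + np.where(
            rng.random(m) < 0.5, pb1, pb2
        )
    return a.astype(np.int8), b.astype(np.int8), PEDIGREE_PI[relation]


def simulate_mt_pileup(
    endogenous_hap: str,
    contaminant_hap: str,
    c: float,
    coverage: float,
    base_error: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate an mtDNA pileup as a (4, L) base-count matrix (rows ACGT).

    Each read at a position derives from the contaminant haplotype with
    probability ``c`` and the endogenous haplotype otherwise; sequencing
    error substitutes a uniformly chosen other base with probability
    ``base_error``.
    """
    if len(endogenous_hap) != len(contaminant_hap):
        raise ValueError("endogenous and contaminant sequences differ in length")
    if not (0.0 <= c <= 1.0):
        raise ValueError("contamination fraction must lie in [0, 1]")
    endo = _encode_bases(endogenous_hap)
    cont = _encode_bases(contaminant_hap)
    L = endo.size
    counts = np.zeros((4, L), dtype=np.int64)
    depth = rng.poisson(coverage, size=L)
    n_cont = rng.binomial(depth, c)
    for src_idx, n_src in ((endo, depth - n_cont), (cont, n_cont)):
        n_err = rng.binomial(n_src, base_error)
        correct = n_src - n_err
        np.add.at(counts, (src_idx, np.arange(L)), correct)
        # errors pick one of the three other bases uniformly
        total_err = int(n_err.sum())
        if total_err:
            pos_idx = np.repeat(np.arange(L), n_err)
            shift = rng.integers(1, 4, size=total_err)
            base_idx = (src_idx[pos_idx] + shift) % 4
            np.add.at(counts, (base_idx, pos_idx), 1)
    return counts


def _encode_bases(seq: str) -> np.ndarray:
    lut = {"A": 0, "C": 1, "G": 2, "T": 3}
    try:
        return np.array([lut[b] for b in seq.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"sequence contains non-ACGT base {exc.args[0]!r}") from exc


def simulate_world(config: SimConfig) -> SimTruth:
    """Realise a full synthetic world from its configuration.

    Root frequencies are drawn Uniform(0.05, 0.95) (keeping most sites
    usefully polymorphic), drifted down each branch with the
    Balding-Nichols model, then admixture edges are applied in order.
    Individuals are named ``<pop><index>`` and may carry planted
    autozygous tracts keyed by that name in ``config.roh_tracts``.
    """
    root_seq = np.random.SeedSequence(config.seed)
    keys = ["positions", "root"] + [n.name for n in config.tree[1:]] + [
        f"admix{i}" for i in range(len(config.admixture_edges))
    ]
    streams = {
        k: np.random.default_rng(s)
        for k, s in zip(keys, root_seq.spawn(len(keys)))
    }

    chrom, pos = simulate_site_positions(
        config.n_sites, config.chrom_lengths, streams["positions"]
    )

    root = config.tree[0]
    if root.parent is not None:
        raise ValueError("first tree node must be the root")
    freqs: dict[str, np.ndarray] = {
        root.name: streams["root"].uniform(0.05, 0.95, size=pos.size)
    }
    for node in config.tree[1:]:
        if node.parent not in freqs:
            raise ValueError("tree nodes must be listed parents-first")
        freqs[node.name] = drift_frequencies(
            freqs[node.parent], node.drift, streams[node.name]
        )
    for i, (src, dst, alpha) in enumerate(config.admixture_edges):
        freqs[dst] = admix_frequencies(freqs[src], freqs[dst], alpha)

    genotypes: dict[str, np.ndarray] = {}
    sample_pop: dict[str, str] = {}
    tract_registry: dict[str, tuple[tuple[str, int, int], ...]] = {}
    indiv_seq = root_seq.spawn(1)[0]
    for pop in config.populations:
        n = config.n_individuals.get(pop, 0)
        for j, sub in enumerate(indiv_seq.spawn(n) if n else []):
            name = f"{pop}{j}"
            tracts = config.roh_tracts.get(name, ())
            g = simulate_individuals(
                freqs[pop],
                1,
                np.random.default_rng(sub),
                roh_tracts=[tracts],
                chrom=chrom,
                pos=pos,
            )[0]
            genotypes[name] = g
            sample_pop[name] = pop
            tract_registry[name] = tuple(tracts)

    return SimTruth(
        config=config,
        chrom=chrom,
        pos=pos,
        pop_freqs=freqs,
        genotypes=genotypes,
        sample_pop=sample_pop,
        tract_registry=tract_registry,
    )


def simulate_four_pop_frequencies(
    rng: np.random.Generator,
    n_sites: int = 200_000,
    drift: float = 0.02,
    admixture: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Frequencies for a four-population D-statistic world.

    Topology (((H1, H2), H3), H4): the root frequencies are Uniform(0.05,
    0.95), H1/H2 share an ancestor drifted by ``drift`` and then drift
    independently by the same amount, H3 drifts from the root, and H4 is
    an undrifted outgroup proxy.  With ``admixture`` > 0, that proportion
    of H3 ancestry is mixed into H2 — the gene-flow signal a positive D
    detects.  Returns (p1, p2, p3, p4).
    """
    root = rng.uniform(0.05, 0.95, n_sites)
    anc12 = drift_frequencies(root, drift, rng)
    p1 = drift_frequencies(anc12, drift, rng)
    p2 = drift_frequencies(anc12, drift, rng)
    p3 = drift_frequencies(root, drift, rng)
    p4 = root.copy()
    if admixture:
        p2 = admix_frequencies(p3, p2, admixture)
    return p1, p2, p3, p4


def simulate_window_track(
    chrom_lengths: dict[str, int],
    het_rate: float,
    error_rate: float,
    rng: np.random.Generator,
    roh_tracts: Sequence[tuple[str, int, int]] = (),
    callable_fraction: float = 0.9,
    window_size: int = 500_000,
    haploid: bool = False,
    min_callable_bp: int = 50_000,
):
    """Simulate a per-window heterozygosity track for one 2X genome.

    Emulates dense diploid calling at the window level: each 500-kb window
    receives ``callable_fraction`` of its span as callable bases, and
    heterozygous-site counts are Binomial draws at the true per-bp rate.
    Outside planted tracts that rate is ``het_rate`` plus the false-het
    error term ``2e(1-e)``; inside a tract (or everywhere, for a haploid
    male X) only the error term remains.  Windows straddling a tract
    boundary mix the two rates in exact proportion to the overlap.

    Returns a :class:`hircus.diversity.WindowTrack`.
    """
    from .diversity import WindowTrack, make_windows

    if not (0.0 < callable_fraction <= 1.0):
        raise ValueError("callable_fraction must lie in (0, 1]")
    err_het = 2.0 * error_rate * (1.0 - error_rate)
    base_rate = 0.0 if haploid else het_rate
    windows = make_windows(chrom_lengths, window_size)
    callable_bp = np.maximum(
        1, np.round((windows["end"] - windows["start"] + 1) * callable_fraction)
    ).astype(np.int64)

    het_counts = np.zeros(len(windows), dtype=np.int64)
    for i, (wchrom, wstart, wend) in enumerate(
        zip(windows["chrom"], windows["start"], windows["end"])
    ):
        span = wend - wstart + 1
        overlap = 0
        for tchrom, tstart, tend in roh_tracts:
            if tchrom == wchrom:
                overlap += max(0, min(wend, tend) - max(wstart, tstart) + 1)
        frac_in = overlap / span
        n_in = int(round(callable_bp[i] * frac_in))
        n_out = int(callable_bp[i]) - n_in
        rate_out = base_rate + err_het * (1.0 - base_rate)
        het_counts[i] = rng.binomial(n_out, rate_out) + rng.binomial(n_in, err_het)

    return WindowTrack.from_counts(
        windows, callable_bp, het_counts, min_callable_bp=min_callable_bp
    )
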