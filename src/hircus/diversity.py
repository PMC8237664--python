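"""Windowed heterozygosity, error correction, and the long-ROH caller.

Heterozygosity is measured as the rate of transversion heterozygous sites
per callable base pair in non-overlapping 500-kb windows.  Long runs of
homozygosity (ROH, >= 5 Mb) are called with an observation-based rule:
windows are assessed in sliding groups of ten (one-window steps); a group
is flagged as putative ROH when at least nine of its ten windows fall
below a heterozygosity threshold tau and any window above tau is
non-terminal (not the first or last of the group).  A positional gap of
more than 10 Mb between consecutive usable windows restarts the group.
Flagged groups are merged, and the inbreeding summary F_ROH5Mb is the
fraction of all filtered windows lying inside merged ROH of genomic span
at least 5 Mb.

The threshold tau is calibrated from the non-pseudoautosomal region of
2X-downsampled male X chromosomes — haploid, hence truly devoid of
heterozygotes — as the pooled mean plus two sample standard deviations of
per-window rates, so tau absorbs the per-sample error floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WindowTrack",
    "RohCallSet",
    "ErrorEstimate",
    "make_windows",
    "window_heterozygosity",
    "estimate_error",
    "corrected_heterozygosity",
    "calibrate_threshold",
    "call_roh",
]

WINDOW_SIZE = 500_000
MIN_CALLABLE_BP = 50_000
GROUP_SIZE = 10
MAX_ABOVE = 1
GAP_BP = 10_000_000
MIN_ROH_SPAN = 5_000_000


def make_windows(chrom_lengths: dict[str, int], window_size: int = WINDOW_SIZE) -> pd.DataFrame:
    """Build the fixed non-overlapping window grid (1-based inclusive)."""
    rows = []
    for chrom, length in chrom_lengths.items():
        starts = np.arange(1, length + 1, window_size, dtype=np.int64)
        ends = np.minimum(starts + window_size - 1, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


@dataclass
class WindowTrack:
    """Per-window callable length and transversion-heterozygote counts.

    ``windows`` holds columns chrom, start, end, callable_bp, het_count,
    rate, passes_filter; windows lie on a fixed non-overlapping grid.
    """

    windows: pd.DataFrame
    window_size: int = WINDOW_SIZE
    min_callable_bp: int = MIN_CALLABLE_BP

    @classmethod
    def from_counts(
        cls,
        grid: pd.DataFrame,
        callable_bp: np.ndarray,
        het_count: np.ndarray,
        window_size: int = WINDOW_SIZE,
        min_callable_bp: int = MIN_CALLABLE_BP,
    ) -> "WindowTrack":
        df = grid.copy()
        df["callable_bp"] = np.asarray(callable_bp, dtype=np.int64)
        df["het_count"] = np.asarray(het_count, dtype=np.int64)
        with np.errstate(divide="ignore", invalid="ignore"):
            df["rate"] = np.where(
                df["callable_bp"] > 0, df["het_count"] / df["callable_bp"], np.nan
            )
        df["passes_filter"] = df["callable_bp"] > min_callable_bp
        return cls(df, window_size=window_size, min_callable_bp=min_callable_bp)

    def passing(self) -> pd.DataFrame:
        """Filtered windows, sorted by chromosome then position."""
        out = self.windows[self.windows["passes_filter"]]
        return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)

    def restrict(self, chrom: str, start: int, end: int) -> "WindowTrack":
        """Subset to windows fully contained in a genomic interval."""
        w = self.windows
        keep = (w["chrom"] == chrom) & (w["start"] >= start) & (w["end"] <= end)
        return WindowTrack(
            w[keep].reset_index(drop=True), self.window_size, self.min_callable_bp
        )

    def to_tsv(self, path) -> None:
        self.windows.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "WindowTrack":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class ErrorEstimate:
    """Per-sample transversion error rate from outgroup-discordance excess."""

    sample: str
    rate: float
    outgroup: str = ""
    reference_individual: str = ""

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("error rate must be >= 0")


@dataclass
class RohCallSet:
    """Merged ROH intervals for one sample plus the F_ROH5Mb summary."""

    sample: str
    threshold: float
    intervals: pd.DataFrame  # chrom, start, end, n_windows, span_bp
    n_passing_windows: int
    f_roh_5mb: float = field(init=False)

    def __post_init__(self) -> None:
        long_mask = self.intervals["span_bp"] >= MIN_ROH_SPAN
        in_long = int(self.intervals.loc[long_mask, "n_windows"].sum())
        self.f_roh_5mb = (
            in_long / self.n_passing_windows if self.n_passing_windows else 0.0
        )

    @property
    def long_intervals(self) -> pd.DataFrame:
        return self.intervals[self.intervals["span_bp"] >= MIN_ROH_SPAN].reset_index(
            drop=True
        )

    def to_bed(self, path) -> None:
        """Write intervals as BED (0-based half-open)."""
        bed = self.intervals.copy()
        bed["start"] = bed["start"] - 1
        bed[["chrom", "start", "end"]].to_csv(
            path, sep="\t", header=False, index=False
        )


def window_heterozygosity(
    het_positions: dict[str, np.ndarray],
    callable_bp_per_window: pd.DataFrame | None,
    chrom_lengths: dict[str, int],
    window_size: int = WINDOW_SIZE,
    min_callable_bp: int = MIN_CALLABLE_BP,
) -> WindowTrack:
    """Bin transversion-heterozygous site positions onto the window grid.

    ``het_positions`` maps chromosome -> sorted 1-based positions of
    heterozygous calls.  ``callable_bp_per_window`` supplies the callable
    mask already reduced per window (columns chrom, start, callable_bp);
    ``None`` treats every base as callable — appropriate for simulated
    diploid truth where all sites are observed.
    """
    grid = make_windows(chrom_lengths, window_size)
    het_count = np.zeros(len(grid), dtype=np.int64)
    for chrom, positions in het_positions.items():
        if chrom not in chrom_lengths:
            raise ValueError(f"het positions on unknown chromosome {chrom!r}")
        positions = np.asarray(positions, dtype=np.int64)
        if positions.size == 0:
            continue
        if positions.min() < 1 or positions.max() > chrom_lengths[chrom]:
            raise ValueError(f"het position outside {chrom!r} bounds")
        mask = grid["chrom"] == chrom
        idx = np.flatnonzero(mask.to_numpy())
        bins = (positions - 1) // window_size
        counts = np.bincount(bins, minlength=idx.size)
        het_count[idx] += counts[: idx.size]

    if callable_bp_per_window is None:
        callable_bp = (grid["end"] - grid["start"] + 1).to_numpy()
    else:
        merged = grid.merge(
            callable_bp_per_window[["chrom", "start", "callable_bp"]],
            on=["chrom", "start"],
            how="left",
        )
        callable_bp = merged["callable_bp"].fillna(0).to_numpy()
    return WindowTrack.from_counts(
        grid, callable_bp, het_count, window_size, min_callable_bp
    )


def estimate_error(
    sample: str,
    sample_alleles: np.ndarray,
    outgroup_alleles: np.ndarray,
    reference_alleles: np.ndarray,
    outgroup: str = "outgroup",
    reference_individual: str = "reference",
) -> ErrorEstimate:
    """Estimate a sample's per-bp transversion error rate.

    The outgroup defines the putative ancestral allele at each site; a
    designated low-error reference individual absorbs true shared derived
    variation.  The estimate is ``max(0, d_s - d_p)`` where ``d_s`` is the
    sample's rate of outgroup-discordant alleles and ``d_p`` the reference
    individual's rate at the same sites.  Missing calls (encoded -1) in
    any of the three vectors drop the site.
    """
    s = np.asarray(sample_alleles)
    o = np.asarray(outgroup_alleles)
    r = np.asarray(reference_alleles)
    if not (s.shape == o.shape == r.shape):
        raise ValueError("allele vectors must share a common site set")
    usable = (s >= 0) & (o >= 0) & (r >= 0)
    n = int(usable.sum())
    if n == 0:
        raise ValueError("no jointly covered sites for error estimation")
    d_s = float(np.mean(s[usable] != o[usable]))
    d_p = float(np.mean(r[usable] != o[usable]))
    return ErrorEstimate(
        sample=sample,
        rate=max(0.0, d_s - d_p),
        outgroup=outgroup,
        reference_individual=reference_individual,
    )


def corrected_heterozygosity(h_obs: float, error_rate: float) -> float:
    """Remove the false-heterozygote error floor from an observed rate.

    A base error on either of the two sampled chromosomes at a truly
    homozygous site fakes a heterozygote, inflating the observed rate by
    ``2e(1-e)``; the corrected rate is ``max(0, h_obs - 2e(1-e))``.
    """
    if h_obs < 0 or error_rate < 0:
        raise ValueError("rates must be >= 0")
    return max(0.0, h_obs - 2.0 * error_rate * (1.0 - error_rate))


def calibrate_threshold(
    male_x_tracks: Sequence[WindowTrack],
    nonpar_interval: tuple[str, int, int] | None = None,
) -> float:
    """Calibrate the ROH heterozygosity threshold from male X chromosomes.

    Pools per-window rates over all filtered non-pseudoautosomal male-X
    windows across samples and returns mean + 2 sample SDs.  The male X is
    haploid, so any apparent heterozygosity there is error; the threshold
    thereby accounts for the error floor of 2X data.
    """
    if not male_x_tracks:
        raise ValueError("at least one male X track is required")
    rates: list[np.ndarray] = []
    for track in male_x_tracks:
        t = track
        if nonpar_interval is not None:
            t = track.restrict(*nonpar_interval)
        rates.append(t.passing()["rate"].to_numpy())
    pooled = np.concatenate(rates)
    if pooled.size < 3:
        raise ValueError(
            f"need >= 3 filtered non-PAR windows to calibrate; got {pooled.size}"
        )
    return float(pooled.mean() + 2.0 * pooled.std(ddof=1))


def _flag_groups(
    rates: np.ndarray,
    starts: np.ndarray,
    ends: np.ndarray,
    tau: float,
    group_size: int,
    max_above: int,
    gap_bp: int,
) -> np.ndarray:
    """Flag sliding window groups as putative ROH on one chromosome.

    Returns a boolean per-window mask of membership in any flagged group.
    Groups are formed over consecutive usable windows; a positional gap
    greater than ``gap_bp`` between one window's end and the next window's
    start restarts grouping (no group spans the gap).
    """
    n = rates.size
    member = np.zeros(n, dtype=bool)
    if n < group_size:
        return member
    # split into runs separated by >gap_bp
    breaks = np.flatnonzero(starts[1:] - ends[:-1] > gap_bp) + 1
    for run in np.split(np.arange(n), breaks):
        if run.size < group_size:
            continue
        above = rates[run] >= tau
        for i in range(run.size - group_size + 1):
            window_above = above[i : i + group_size]
            n_above = int(window_above.sum())
            if n_above > max_above:
                continue
            # any above-threshold window must be non-terminal
            if n_above and (window_above[0] or window_above[-1]):
                continue
            member[run[i : i + group_size]] = True
    return member


def call_roh(
    track: WindowTrack,
    tau: float,
    sample: str = "",
    group_size: int = GROUP_SIZE,
    max_above: int = MAX_ABOVE,
    gap_bp: int = GAP_BP,
) -> RohCallSet:
    """Call long runs of homozygosity from a heterozygosity window track.

    Applies the 9-of-10 / non-terminal / >10-Mb-gap rule per chromosome to
    the filtered windows, merges overlapping flagged groups into ROH
    intervals spanning first-window start to last-window end, and computes
    F_ROH5Mb as (filtered windows inside merged ROH of span >= 5 Mb) /
    (all filtered windows genome-wide).
    """
    if tau <= 0:
        raise ValueError("threshold tau must be > 0")
    passing = track.passing()
    records = []
    for chrom, sub in passing.groupby("chrom", sort=False):
        rates = sub["rate"].to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        member = _flag_groups(
            rates, starts, ends, tau, group_size, max_above, gap_bp
        )
        # merge consecutive member windows into intervals
        idx = np.flatnonzero(member)
        if idx.size == 0:
            continue
        splits = np.flatnonzero(np.diff(idx) > 1) + 1
        for seg in np.split(idx, splits):
            records.append(
                {
                    "chrom": chrom,
                    "start": int(starts[seg[0]]),
                    "end": int(ends[seg[-1]]),
                    "n_windows": int(seg.size),
                    "span_bp": int(ends[seg[-1]] - starts[seg[0]] + 1),
                }
            )
    intervals = pd.DataFrame(
        records, columns=["chrom", "start", "end", "n_windows", "span_bp"]
    )
    return RohCallSet(
        sample=sample,
        threshold=tau,
        intervals=intervals,
        n_passing_windows=len(passing),
    )
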