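"""Sliding-window selection scan: Watterson's theta, Hudson Fst, the joint
divergence/diversity outlier filter, and the population branch statistic.

The scan mirrors a domestication-era selection screen: diversity
(theta_Watterson per bp) and differentiation (Fst against a wild
reference) are computed in 50-kb windows sliding by 10 kb; candidate
windows show both extreme divergence (Fst at or above the empirical 0.99
quantile) and reduced diversity in the target relative to the reference
(log(theta_target / theta_reference) < 0).  The population branch
statistic converts three pairwise Fst values into branch lengths
T = -log(1 - Fst) and isolates the drift specific to the focal
population: PBS1 = (T12 + T13 - T23) / 2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "watterson_theta",
    "hudson_fst_sites",
    "make_sliding_windows",
    "windowed_scan",
    "outlier_filter",
    "pbs",
]

WINDOW_BP = 50_000
STEP_BP = 10_000
FST_CLAMP = 1.0 - 1e-6


def watterson_theta(n_segregating: int, n_chromosomes: int, callable_bp: float) -> float:
    """Watterson's theta per bp: S / (a_n * L), a_n = sum_{i<n} 1/i."""
    if n_chromosomes < 2:
        raise ValueError("need >= 2 chromosomes")
    if callable_bp <= 0:
        raise ValueError("callable_bp must be > 0")
    a_n = np.sum(1.0 / np.arange(1, n_chromosomes))
    return float(n_segregating / (a_n * callable_bp))


def hudson_fst_sites(
    p1: np.ndarray, n1: np.ndarray, p2: np.ndarray, n2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Hudson Fst numerator and denominator (Bhatia et al. form).

    num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    den = p1(1-p2) + p2(1-p1)

    Windows combine these as a ratio of averages, which is unbiased under
    unequal sample sizes where the average of per-site ratios is not.
    """
    p1, p2 = np.asarray(p1, float), np.asarray(p2, float)
    n1 = np.broadcast_to(np.asarray(n1, float), p1.shape)
    n2 = np.broadcast_to(np.asarray(n2, float), p2.shape)
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("sample sizes must be >= 2 at every used site")
    num = (
        (p1 - p2) ** 2
        - p1 * (1 - p1) / (n1 - 1)
        - p2 * (1 - p2) / (n2 - 1)
    )
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def make_sliding_windows(
    chrom_lengths: dict[str, int], window_bp: int = WINDOW_BP, step_bp: int = STEP_BP
) -> pd.DataFrame:
    rows = []
    for chrom, length in chrom_lengths.items():
        starts = np.arange(1, max(length - window_bp + 2, 2), step_bp, dtype=np.int64)
        rows.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": np.minimum(starts + window_bp - 1, length)}
            )
        )
    return pd.concat(rows, ignore_index=True)


def windowed_scan(
    sites: pd.DataFrame,
    chrom_lengths: dict[str, int],
    target: str,
    reference: str,
    window_bp: int = WINDOW_BP,
    step_bp: int = STEP_BP,
    min_snps: int = 10,
    callable_fraction: float = 1.0,
) -> pd.DataFrame:
    """Per-window theta_W for both populations and Hudson Fst between them.

    ``sites`` columns: chrom, pos, then ``<pop>_freq`` / ``<pop>_n``
    (allele frequency and chromosome count) for the target and reference
    populations.  Windows with fewer than ``min_snps`` segregating sites
    are dropped.  ``callable_fraction`` scales the window span into the
    callable length used for theta.
    """
    windows = make_sliding_windows(chrom_lengths, window_bp, step_bp)
    t_p = sites[f"{target}_freq"].to_numpy()
    t_n = sites[f"{target}_n"].to_numpy()
    r_p = sites[f"{reference}_freq"].to_numpy()
    r_n = sites[f"{reference}_n"].to_numpy()
    num, den = hudson_fst_sites(t_p, t_n, r_p, r_n)
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()

    rows = []
    for chrom, wsub in windows.groupby("chrom", sort=False):
        on_chrom = chrom_arr == chrom
        cpos = pos_arr[on_chrom]
        order = np.argsort(cpos)
        cpos = cpos[order]
        idx = np.flatnonzero(on_chrom)[order]
        for start, end in zip(wsub["start"], wsub["end"]):
            lo, hi = np.searchsorted(cpos, (start, end + 1))
            sel = idx[lo:hi]
            seg_t = int(((t_p[sel] > 0) & (t_p[sel] < 1)).sum())
            seg_r = int(((r_p[sel] > 0) & (r_p[sel] < 1)).sum())
            n_snps = hi - lo
            if n_snps < min_snps:
                continue
            span = (end - start + 1) * callable_fraction
            d_sum = den[sel].sum()
            fst = np.clip(num[sel].sum() / d_sum, 0.0, 1.0) if d_sum > 0 else np.nan
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(start),
                    "end": int(end),
                    "n_snps": int(n_snps),
                    "theta_target": watterson_theta(
                        seg_t, int(np.median(t_n[sel])), span
                    ),
                    "theta_reference": watterson_theta(
                        seg_r, int(np.median(r_n[sel])), span
                    ),
                    "fst": fst,
                }
            )
    return pd.DataFrame(rows)


def outlier_filter(
    scan: pd.DataFrame, fst_quantile: float = 0.99
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Joint divergence/diversity outlier filter.

    Flags windows with Fst at or above the empirical ``fst_quantile``
    (linear-interpolation definition, computed over all sliding windows
    including overlaps) AND log(theta_target / theta_reference) strictly
    below zero.  Windows with zero reference theta are excluded from the
    ratio test.  Returns (scan with outlier_flag column, merged regions).
    """
    out = scan.copy()
    usable_fst = out["fst"].dropna()
    if usable_fst.empty:
        raise ValueError("no windows with defined Fst")
    cutoff = float(np.quantile(usable_fst, fst_quantile))
    ratio_ok = out["theta_reference"] > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio = np.where(
            ratio_ok, np.log(out["theta_target"] / out["theta_reference"]), np.nan
        )
    out["log_theta_ratio"] = log_ratio
    out["outlier_flag"] = (
        (out["fst"] >= cutoff) & ratio_ok & (log_ratio < 0)
    ).fillna(False)

    regions = _merge_flagged(out[out["outlier_flag"]])
    return out, regions


def _merge_flagged(flagged: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for chrom, sub in flagged.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        cur_start = cur_end = None
        for start, end in zip(sub["start"], sub["end"]):
            if cur_start is None:
                cur_start, cur_end = start, end
            elif start <= cur_end + 1:
                cur_end = max(cur_end, end)
            else:
                rows.append({"chrom": chrom, "start": cur_start, "end": cur_end})
                cur_start, cur_end = start, end
        if cur_start is not None:
            rows.append({"chrom": chrom, "start": cur_start, "end": cur_end})
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def pbs(
    fst_12: np.ndarray,
    fst_13: np.ndarray,
    fst_23: np.ndarray,
    top_fraction: float = 0.001,
) -> pd.DataFrame:
    """Population branch statistic for population 1 per window.

    T_ij = -log(1 - Fst_ij) with Fst clamped just below 1;
    PBS1 = (T12 + T13 - T23) / 2.  Windows in the top ``top_fraction`` of
    PBS values are flagged.  Windows with any missing pairwise Fst are
    skipped.
    """
    f12 = np.asarray(fst_12, float)
    f13 = np.asarray(fst_13, float)
    f23 = np.asarray(fst_23, float)
    usable = ~(np.isnan(f12) | np.isnan(f13) | np.isnan(f23))
    t12 = -np.log(1.0 - np.clip(f12, 0.0, FST_CLAMP))
    t13 = -np.log(1.0 - np.clip(f13, 0.0, FST_CLAMP))
    t23 = -np.log(1.0 - np.clip(f23, 0.0, FST_CLAMP))
    values = (t12 + t13 - t23) / 2.0
    values[~usable] = np.nan
    out = pd.DataFrame({"pbs": values, "usable": usable})
    if usable.any():
        cut = np.quantile(values[usable], 1.0 - top_fraction)
        out["top_flag"] = usable & (values >= cut)
    else:
        out["top_flag"] = False
    out["rank"] = out["pbs"].rank(ascending=False, method="min")
    return out
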