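"""Incision-site distances around nucleosome dyads.

Lesions (located by their mismatch) within 500 bp of a nucleosome dyad are
binned by the lesion-to-dyad distance, strand-aligned so the 5' incision
always points in the negative direction: the signed distance is
``lesion - dyad`` for plus-strand reads and ``dyad - lesion`` for minus
strand. Each bin accumulates the 5' and 3' cut-site distances of its
lesions; a lesion near two dyads contributes to both bins but is counted
once in the grand mean. Per-bin significance is a one-sample two-tailed
t-test of the bin's distances against the scalar grand mean across all
in-range records, at a fixed cutoff (no multiple-testing correction).

Dyads inside blacklisted regions are excluded first: a dyad is dropped when
its nucleosome footprint (dyad +/- 73 nt, i.e. the interval
``[d-73, d+74)``) intersects any blacklist interval.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .incision import IncisionRecord


def load_bed(path, point: bool = False) -> pd.DataFrame:
    """Read a 3+ column BED file (0-based half-open intervals).

    With ``point=True`` single-base intervals are returned as dyad positions
    (columns contig/pos). Malformed lines raise with their line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                contig, start, end = parts[0], int(parts[1]), int(parts[2])
                if end <= start:
                    raise ValueError
            except (IndexError, ValueError):
                raise ValueError(f"{path}: malformed BED line {lineno}: {line!r}")
            rows.append((contig, start, end))
    df = pd.DataFrame(rows, columns=["contig", "start", "end"])
    if point:
        return pd.DataFrame({"contig": df["contig"], "pos": df["start"]})
    return df


def blacklist_filter(dyads: pd.DataFrame, blacklist: pd.DataFrame,
                     half_width: int = 73) -> pd.DataFrame:
    """Drop dyads whose ``[pos - half_width, pos + half_width + 1)`` footprint
    overlaps any blacklist interval."""
    if blacklist.empty:
        return dyads.reset_index(drop=True)
    keep_parts = []
    for contig, grp in dyads.groupby("contig", sort=False):
        bl = blacklist[blacklist["contig"] == contig]
        if bl.empty:
            keep_parts.append(grp)
            continue
        starts = bl["start"].to_numpy()
        ends = bl["end"].to_numpy()
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        pos = grp["pos"].to_numpy()
        lo = pos - half_width
        hi = pos + half_width + 1
        # overlap iff some interval has start < hi and end > lo
        j = np.searchsorted(starts, hi)  # intervals with start < hi
        max_end = np.concatenate(([np.iinfo(np.int64).min],
                                  np.maximum.accumulate(ends)))
        overlaps = max_end[j] > lo
        keep_parts.append(grp[~overlaps])
    return pd.concat(keep_parts, ignore_index=True)


def dyad_profile(records: Sequence[IncisionRecord], dyads: pd.DataFrame,
                 max_dist: int = 500) -> pd.DataFrame:
    """Per-bin mean 5'/3' cut-site distances around dyads.

    Returns a frame indexed by bin (integer lesion-minus-dyad distance,
    strand-aligned, within +/- ``max_dist``) with columns n, mean_d5, sd_d5,
    mean_d3, sd_d3. Grand means over in-range records (each record once,
    even when binned at two dyads) are stored in ``attrs``.
    """
    dyad_pos: Dict[str, np.ndarray] = {
        contig: np.sort(grp["pos"].to_numpy())
        for contig, grp in dyads.groupby("contig")
    }
    sums: Dict[int, np.ndarray] = {}
    grand_d5, grand_d3, grand_n = 0.0, 0.0, 0
    for r in records:
        if r.contig is None or r.lesion_pos is None:
            continue
        dp = dyad_pos.get(r.contig)
        if dp is None or not len(dp):
            continue
        lo = np.searchsorted(dp, r.lesion_pos - max_dist, side="left")
        hi = np.searchsorted(dp, r.lesion_pos + max_dist, side="right")
        if hi == lo:
            continue
        grand_d5 += r.d5
        grand_d3 += r.d3
        grand_n += 1
        for d in dp[lo:hi]:
            signed = r.lesion_pos - d if r.strand == "+" else d - r.lesion_pos
            b = int(round(signed))
            if abs(b) > max_dist:
                continue
            acc = sums.setdefault(b, np.zeros(5))
            acc += (1.0, r.d5, r.d5 ** 2, r.d3, r.d3 ** 2)
    rows = []
    for b in sorted(sums):
        n, s5, ss5, s3, ss3 = sums[b]
        mean5, mean3 = s5 / n, s3 / n
        var5 = (ss5 - n * mean5 ** 2) / (n - 1) if n > 1 else np.nan
        var3 = (ss3 - n * mean3 ** 2) / (n - 1) if n > 1 else np.nan
        rows.append((b, int(n), mean5, np.sqrt(max(var5, 0.0)),
                     mean3, np.sqrt(max(var3, 0.0))))
    out = pd.DataFrame(rows, columns=["bin", "n", "mean_d5", "sd_d5",
                                      "mean_d3", "sd_d3"]).set_index("bin")
    out.attrs["grand_mean_d5"] = grand_d5 / grand_n if grand_n else np.nan
    out.attrs["grand_mean_d3"] = grand_d3 / grand_n if grand_n else np.nan
    out.attrs["n_records"] = grand_n
    return out


def bin_significance(profile: pd.DataFrame, alpha: float = 5e-5) -> pd.DataFrame:
    """One-sample two-tailed t-tests of each bin's distances vs the grand mean.

    d5 and d3 are tested separately; bins with n < 2 get NaN statistics. A
    zero-variance bin whose mean differs from the grand mean is flagged with
    p = 0 (an underflow sentinel). Returns a copy of the profile with t_d5,
    p_d5, sig_d5, t_d3, p_d3, sig_d3 columns added.
    """
    out = profile.copy()
    for side in ("d5", "d3"):
        grand = profile.attrs[f"grand_mean_{side}"]
        n = out["n"].to_numpy(dtype=float)
        mean = out[f"mean_{side}"].to_numpy(dtype=float)
        sd = out[f"sd_{side}"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (mean - grand) / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(np.abs(t), n - 1)
        degenerate = (sd == 0) & (n >= 2)
        p = np.where(degenerate & (mean != grand), 0.0, p)
        t = np.where(degenerate & (mean != grand), np.inf, t)
        p = np.where(n < 2, np.nan, p)
        out[f"t_{side}"] = t
        out[f"p_{side}"] = p
        out[f"sig_{side}"] = pd.Series(p, index=out.index) < alpha
    out.attrs.update(profile.attrs)
    out.attrs["alpha"] = alpha
    return out
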