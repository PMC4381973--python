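"""ChIP-exo downstream analysis.

Mapped reads are reduced to their 5'-end (the protein-DNA cross-linking
point), peaks are called on each strand separately, and a bound region is the
interval between the midpoints of a forward-strand ("left") peak and a
reverse-strand ("right") peak lying within a pairing distance (20 bp by
default).  All coordinates are 0-based half-open as in BED.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks


def reads_to_5prime(reads: pd.DataFrame) -> pd.DataFrame:
    """Reduce stranded read intervals to single 5'-end points.

    A forward read [start, end) maps to ``start``; a reverse read to
    ``end - 1``.  Returns per-position counts with columns
    ``chrom, pos, strand, count``; the counts sum to the number of input
    reads.
    """
    fwd = reads["strand"] == "+"
    pos = np.where(fwd, reads["start"], reads["end"] - 1)
    df = pd.DataFrame({"chrom": reads["chrom"], "pos": pos,
                       "strand": reads["strand"]})
    out = (df.groupby(["chrom", "pos", "strand"], observed=True)
             .size().reset_index(name="count"))
    return out.sort_values(["chrom", "strand", "pos"]).reset_index(drop=True)


def call_peaks(
    counts: pd.DataFrame,
    strand: str,
    smoothing_sd_bp: float = 5.0,
    min_height: float = 1.0,
) -> pd.DataFrame:
    """Smoothed local-maximum peak calling on a 5'-end count profile.

    A simple stand-in for a dedicated exonuclease peak caller: the
    per-position counts on one strand are Gaussian-smoothed, local maxima
    above ``min_height`` become peaks, and each peak's extent is the
    contiguous region above half its smoothed height.  The score is the sum
    of raw counts within the extent.

    Returns BED-like rows ``chrom, start, end, name, score, strand`` with the
    peak mode stored in ``mode``.
    """
    rows = []
    sel = counts[counts["strand"] == strand]
    pad = int(np.ceil(4 * smoothing_sd_bp)) + 1  # boundary maxima stay interior
    for chrom, grp in sel.groupby("chrom", observed=True):
        lo = int(grp["pos"].min()) - pad
        hi = int(grp["pos"].max()) + pad
        profile = np.zeros(hi - lo + 1)
        profile[grp["pos"].to_numpy() - lo] = grp["count"].to_numpy(float)
        smooth = gaussian_filter1d(profile, smoothing_sd_bp, mode="constant")
        idx, _ = find_peaks(smooth, height=min_height)
        for p in idx:
            half = smooth[p] / 2.0
            a = p
            while a > 0 and smooth[a - 1] >= half:
                a -= 1
            b = p
            while b < len(smooth) - 1 and smooth[b + 1] >= half:
                b += 1
            score = float(profile[a:b + 1].sum())
            rows.append((chrom, lo + a, lo + b + 1, f"peak_{chrom}_{lo + p}",
                         score, strand, lo + p))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand", "mode"]
    )


def peak_midpoint(peaks: pd.DataFrame) -> np.ndarray:
    """Peak middle point, (start + end) // 2 (floor on odd widths)."""
    return ((peaks["start"].to_numpy() + peaks["end"].to_numpy()) // 2)


def pair_peaks(
    left: pd.DataFrame,
    right: pd.DataFrame,
    max_dist_bp: int = 20,
    require_order: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Greedy pairing of forward ("left") and reverse ("right") strand peaks.

    Candidate pairs are a left and a right peak on the same chromosome whose
    midpoints lie within ``max_dist_bp``; with ``require_order`` the left
    (forward) midpoint must not lie downstream of the right (reverse) one,
    the orientation a sense/antisense cross-link footprint implies.
    Candidates are consumed greedily by increasing midpoint distance (ties by
    leftmost coordinate), each peak used at most once.

    Returns ``(regions, unpaired_left, unpaired_right)``; a region spans
    [min(midpoints), max(midpoints)] with score the sum of both peak scores.
    """
    left = left.reset_index(drop=True)
    right = right.reset_index(drop=True)
    lmid = peak_midpoint(left)
    rmid = peak_midpoint(right)
    cands = []
    for chrom in np.intersect1d(left["chrom"].unique(), right["chrom"].unique()):
        li = np.nonzero((left["chrom"] == chrom).to_numpy())[0]
        ri = np.nonzero((right["chrom"] == chrom).to_numpy())[0]
        for i in li:
            d = np.abs(rmid[ri] - lmid[i])
            for j, dist in zip(ri[d <= max_dist_bp], d[d <= max_dist_bp]):
                if require_order and lmid[i] > rmid[j]:
                    continue
                cands.append((int(dist), int(lmid[i]), i, j))
    cands.sort()
    used_l, used_r, rows = set(), set(), []
    for dist, lm, i, j in cands:
        if i in used_l or j in used_r:
            continue
        used_l.add(i)
        used_r.add(j)
        a, b = sorted((lmid[i], rmid[j]))
        rows.append((left.at[i, "chrom"], int(a), int(b),
                     float(left.at[i, "score"] + right.at[j, "score"]),
                     int(lmid[i]), int(rmid[j])))
    regions = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "score", "left_mid", "right_mid"]
    ).sort_values(["chrom", "start"]).reset_index(drop=True)
    unpaired_left = left.drop(index=list(used_l)).reset_index(drop=True)
    unpaired_right = right.drop(index=list(used_r)).reset_index(drop=True)
    return regions, unpaired_left, unpaired_right


def chrom_bin_density(
    regions: pd.DataFrame,
    chrom_sizes: dict[str, int],
    bins_per_chrom: int = 500,
    top_n: int | None = 7000,
) -> pd.DataFrame:
    """Bound-region density along chromosomes.

    Regions are ranked by score and the genome-wide top ``top_n`` retained;
    each chromosome is divided into ``bins_per_chrom`` equal-width bins and
    region midpoints are counted per bin.  Bin counts sum to the number of
    retained regions.
    """
    kept = regions.sort_values("score", ascending=False)
    if top_n is not None:
        kept = kept.head(top_n)
    rows = []
    for chrom, size in chrom_sizes.items():
        edges = np.linspace(0, size, bins_per_chrom + 1)
        mids = ((kept.loc[kept["chrom"] == chrom, "start"]
                 + kept.loc[kept["chrom"] == chrom, "end"]) // 2).to_numpy()
        counts, _ = np.histogram(mids, bins=edges)
        for b in range(bins_per_chrom):
            rows.append((chrom, b, int(counts[b])))
    return pd.DataFrame(rows, columns=["chrom", "bin", "count"])


def tss_distance_cdf(
    regions: pd.DataFrame,
    tss: pd.DataFrame,
    chrom_sizes: dict[str, int] | None = None,
    n_random: int | None = None,
    seed: int = 0,
):
    """Cumulative distribution of distances from bound regions to the nearest
    transcription start site.

    For each region midpoint the absolute distance to the nearest TSS on the
    same chromosome is computed; regions on chromosomes without any TSS are
    dropped.  If ``chrom_sizes`` is given, a matched set of uniform random
    genomic positions (``n_random``, default the number of regions) provides
    the chance-expectation reference curve.

    Returns a dict with sorted ``distances`` and ``cdf`` arrays and, when
    requested, ``random_distances`` / ``random_cdf``.
    """
    tss_by_chrom = {c: np.sort(g["pos"].to_numpy())
                    for c, g in tss.groupby("chrom", observed=True)}

    def nearest(chroms, positions):
        out = []
        for c, p in zip(chroms, positions):
            t = tss_by_chrom.get(c)
            if t is None or t.size == 0:
                continue
            k = np.searchsorted(t, p)
            best = min(
                abs(p - t[k - 1]) if k > 0 else np.inf,
                abs(t[k] - p) if k < t.size else np.inf,
            )
            out.append(best)
        return np.sort(np.array(out, dtype=float))

    mids = (regions["start"].to_numpy() + regions["end"].to_numpy()) // 2
    d = nearest(regions["chrom"].to_numpy(), mids)
    if d.size == 0:
        raise ValueError("no region lies on a chromosome with a TSS")
    result = {"distances": d, "cdf": np.arange(1, d.size + 1) / d.size}
    if chrom_sizes is not None:
        rng = np.random.default_rng(seed)
        m = n_random if n_random is not None else len(mids)
        chroms = list(chrom_sizes)
        sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
        ci = rng.choice(len(chroms), size=m, p=sizes / sizes.sum())
        rpos = (rng.random(m) * sizes[ci]).astype(int)
        rd = nearest([chroms[i] for i in ci], rpos)
        result["random_distances"] = rd
        result["random_cdf"] = np.arange(1, rd.size + 1) / rd.size
    return result
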