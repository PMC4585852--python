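"""Copy-number analysis: segmentation, re-centering, calling, recurrence.

Segmentation is a recursive changepoint search of the circular binary
segmentation family: at each step the arc maximising the two-sample t
statistic against its complement is accepted if its within-segment
permutation p-value clears ``alpha`` and every resulting piece keeps
``min_probes`` probes.  Preceded by an outlier-smoothing pass that
winsorizes probes deviating more than k MADs from their neighbourhood
median.  Calling uses fixed thresholds on re-centered segment means; the
re-centering shift is the probe-weighted kernel-density mode of the segment
means (the profile's most likely zero level).

Empirical p-values follow the add-one convention
p = (1 + #null >= observed) / (n_perm + 1) throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from riborestore.config import CNAParams

CALL_ORDER = ("loss", "neutral", "gain", "amplification")


@dataclass
class Segment:
    sample: str
    chrom: str
    start: int            # 0-based half-open, genomic
    end: int
    mean: float
    n_probes: int
    call: str | None = None
    probe_slice: tuple[int, int] = (0, 0)  # probe-index interval, half-open


def smooth_outliers(values: np.ndarray, window: int = 5, k: float = 4.0) -> np.ndarray:
    """Winsorize probes beyond k * MAD of their neighbourhood median."""
    x = np.asarray(values, dtype=float).copy()
    n = len(x)
    if n < window:
        return x
    half = window // 2
    med = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        med[i] = np.median(values[lo:hi])
    resid = values - med
    mad = np.median(np.abs(resid - np.median(resid)))
    if mad == 0:
        return x
    bound = k * 1.4826 * mad
    x = np.clip(x, med - bound, med + bound)
    return x


@lru_cache(maxsize=64)
def _arc_grids(n: int, min_probes: int):
    """Cached (i, j) index grids for the arc scan at a given length."""
    i = np.arange(0, n - min_probes + 1)
    j = np.arange(min_probes, n + 1)
    jj, ii = np.meshgrid(j, i)
    n1 = (jj - ii).astype(float)
    valid = (n1 >= min_probes) & (n - n1 >= min_probes)
    return i, j, ii, jj, n1, valid


def _best_split(values: np.ndarray, min_probes: int) -> tuple[int, int, float]:
    """Best circular split: the arc [i, j) maximising the two-sample t
    statistic between the arc and its complement.

    The two-changepoint (arc) form is what gives the method power against
    an interior aberration flanked by normal copy number on both sides,
    where a single binary cut dilutes the contrast.  Returns
    (i, j, |t|); (-1, -1, 0) if no admissible arc.  An infinite |t| marks
    an exact (zero-variance) separation.
    """
    n = len(values)
    if n < 2 * min_probes or np.ptp(values) < 1e-10:
        return -1, -1, 0.0
    cs = np.concatenate([[0.0], np.cumsum(values)])
    cs2 = np.concatenate([[0.0], np.cumsum(values ** 2)])
    total, total2 = cs[-1], cs2[-1]
    i, j, ii, jj, n1, valid = _arc_grids(n, min_probes)
    if not valid.any():
        return -1, -1, 0.0
    s1 = cs[jj] - cs[ii]
    q1 = cs2[jj] - cs2[ii]
    n2 = n - n1
    with np.errstate(divide="ignore", invalid="ignore"):
        m1 = s1 / n1
        m2 = (total - s1) / n2
        ss = (q1 - n1 * m1 ** 2) + ((total2 - q1) - n2 * m2 ** 2)
        pooled = np.sqrt(np.maximum(ss, 0.0) / max(n - 2, 1)) \
            * np.sqrt(1 / n1 + 1 / n2)
        t = np.abs(m1 - m2) / pooled
    bad = ~np.isfinite(t)
    t[bad] = np.where(np.abs(m1 - m2)[bad] > 1e-10, np.inf, 0.0)
    t[~valid] = 0.0
    flat = int(np.argmax(t))
    bi, bj = np.unravel_index(flat, t.shape)
    best_t = float(t[bi, bj])
    if best_t == 0.0:
        return -1, -1, 0.0
    return int(i[bi]), int(j[bj]), best_t


def segment_profile(
    positions: np.ndarray,
    values: np.ndarray,
    params: CNAParams | None = None,
    sample: str = "sample",
    chrom: str = "chr",
    rng: np.random.Generator | None = None,
) -> list[Segment]:
    """Segment one chromosome's ordered probe track.

    ``positions`` must be strictly increasing.  With fewer than
    ``2 * min_probes`` probes a single segment is returned with a warning.
    """
    params = params or CNAParams()
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    positions = np.asarray(positions)
    values = np.asarray(values, dtype=float)
    if len(positions) != len(values):
        raise ValueError("positions and values differ in length")
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing within a chromosome")
    x = smooth_outliers(values, params.smooth_window, params.mad_k)
    n = len(x)
    if n < 2 * params.min_probes:
        warnings.warn(f"{sample}/{chrom}: fewer than {2 * params.min_probes} probes; "
                      "returning a single segment")
        return [_make_segment(sample, chrom, positions, x, 0, n)]

    breakpoints: list[int] = []

    def accept(lo: int, i: int, j: int, hi: int) -> None:
        if i > 0:
            breakpoints.append(lo + i)
        if lo + j < hi:
            breakpoints.append(lo + j)
        recurse(lo, lo + i) if i > 0 else None
        recurse(lo + i, lo + j)
        if lo + j < hi:
            recurse(lo + j, hi)

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        i, j, t_obs = _best_split(seg, params.min_probes)
        if i < 0:
            return
        if np.isinf(t_obs):  # exact separation; permutation cannot beat it
            accept(lo, i, j, hi)
            return
        # permutation p-value of the maximal arc statistic; stop as soon
        # as enough exceedances make significance impossible
        max_count = params.alpha * (params.n_perm_split + 1) - 1
        count = 0
        for _ in range(params.n_perm_split):
            perm = rng.permutation(seg)
            _, _, t_null = _best_split(perm, params.min_probes)
            if t_null >= t_obs:
                count += 1
                if count > max_count:
                    break  # split can no longer reach significance
        p = (1 + count) / (params.n_perm_split + 1)
        if p < params.alpha:
            accept(lo, i, j, hi)

    recurse(0, n)
    bps = sorted(set(breakpoints))
    bounds = [0] + bps + [n]
    return [_make_segment(sample, chrom, positions, x, a, b)
            for a, b in zip(bounds[:-1], bounds[1:])]


def _make_segment(sample, chrom, positions, values, a, b) -> Segment:
    start = int(positions[a])
    end = int(positions[b - 1]) + 1
    return Segment(sample=sample, chrom=chrom, start=start, end=end,
                   mean=float(np.mean(values[a:b])), n_probes=b - a,
                   probe_slice=(a, b))


def recenter_profile(segments: list[Segment], bandwidth: float = 0.1) -> list[Segment]:
    """Shift one sample's segment means so the modal level sits at zero.

    The shift is the mode of the probe-weighted Gaussian kernel density of
    segment means (the profile's most likely zero value).
    """
    if not segments:
        return []
    means = np.array([s.mean for s in segments])
    weights = np.array([s.n_probes for s in segments], dtype=float)
    if len(segments) == 1 or np.ptp(means) < 1e-12:
        shift = float(means[np.argmax(weights)])
    else:
        grid = np.linspace(means.min() - 3 * bandwidth, means.max() + 3 * bandwidth, 2048)
        dens = np.zeros_like(grid)
        for m, w in zip(means, weights):
            dens += w * np.exp(-0.5 * ((grid - m) / bandwidth) ** 2)
        shift = float(grid[np.argmax(dens)])
    return [Segment(sample=s.sample, chrom=s.chrom, start=s.start, end=s.end,
                    mean=s.mean - shift, n_probes=s.n_probes, call=s.call,
                    probe_slice=s.probe_slice)
            for s in segments]


def call_segments(segments: list[Segment], params: CNAParams | None = None) -> list[Segment]:
    """Threshold re-centered segment means into loss/neutral/gain/amplification."""
    params = params or CNAParams()
    if not params.t_gain < params.t_amp:
        raise ValueError("thresholds must satisfy t_gain < t_amp")
    out = []
    for s in segments:
        if s.mean < -params.t_loss:
            call = "loss"
        elif s.mean > params.t_amp:
            call = "amplification"
        elif s.mean > params.t_gain:
            call = "gain"
        else:
            call = "neutral"
        out.append(Segment(sample=s.sample, chrom=s.chrom, start=s.start, end=s.end,
                           mean=s.mean, n_probes=s.n_probes, call=call,
                           probe_slice=s.probe_slice))
    return out


def segments_to_frame(segments: list[Segment]) -> pd.DataFrame:
    return pd.DataFrame(
        {"sample": [s.sample for s in segments], "chrom": [s.chrom for s in segments],
         "start": [s.start for s in segments], "end": [s.end for s in segments],
         "n_probes": [s.n_probes for s in segments], "mean": [s.mean for s in segments],
         "call": [s.call for s in segments]})


def segment_all_samples(
    tracks: pd.DataFrame, params: CNAParams | None = None
) -> pd.DataFrame:
    """Segment, re-center and call every (sample, chromosome) track.

    ``tracks`` has columns chrom, position, sample, log_ratio.  Returns a
    called segment frame (one row per segment).
    """
    params = params or CNAParams()
    rng = np.random.default_rng(params.seed)
    frames = []
    for sample, sgrp in tracks.groupby("sample", sort=True):
        segs: list[Segment] = []
        for chrom, cgrp in sgrp.groupby("chrom", sort=True):
            cgrp = cgrp.sort_values("position")
            segs.extend(segment_profile(cgrp["position"].to_numpy(),
                                        cgrp["log_ratio"].to_numpy(),
                                        params, sample=str(sample),
                                        chrom=str(chrom), rng=rng))
        segs = call_segments(recenter_profile(segs, params.kde_bandwidth), params)
        frames.append(segments_to_frame(segs))
    return pd.concat(frames, ignore_index=True)


def gene_call_matrix(annotation: pd.DataFrame, segments: pd.DataFrame) -> pd.DataFrame:
    """Map called segments onto genes: genes x samples call matrix.

    A gene takes the call of the segment containing its midpoint; genes not
    covered by any segment are neutral.
    """
    samples = sorted(segments["sample"].unique())
    calls = pd.DataFrame("neutral", index=annotation.index, columns=samples)
    mid = (annotation["start"] + annotation["end"]) // 2
    for (sample, chrom), grp in segments.groupby(["sample", "chrom"]):
        sel = annotation["chrom"] == chrom
        if not sel.any():
            continue
        gmid = mid[sel]
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        segcalls = grp["call"].to_numpy()
        order = np.argsort(starts)
        starts, ends, segcalls = starts[order], ends[order], segcalls[order]
        idx = np.searchsorted(starts, gmid.to_numpy(), side="right") - 1
        ok = (idx >= 0) & (gmid.to_numpy() < ends[np.clip(idx, 0, len(ends) - 1)])
        genes = gmid.index[ok]
        calls.loc[genes, sample] = segcalls[idx[ok]]
    return calls


_SIGN = {"loss": -1, "neutral": 0, "gain": 1, "amplification": 1}


def recurrent_aberrations(
    annotation: pd.DataFrame,
    calls: pd.DataFrame,
    min_recurrence: int = 3,
    n_perm: int = 200,
    fdr: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Count-based recurrence test with a rotation null.

    Per gene, the recurrence count is the larger of the number of lines
    with a gain-sign call and with a loss-sign call.  The null preserves
    each sample's spatial run structure by cyclically shifting its
    genome-ordered call track; the per-gene empirical p follows the add-one
    convention, BH-adjusted across genes.  A gene is flagged when its count
    reaches ``min_recurrence`` and q <= fdr; adjacent flagged genes with
    the same direction merge into regions (region_id column).
    """
    n_samples = calls.shape[1]
    if min_recurrence > n_samples:
        raise ValueError("min_recurrence exceeds the number of samples")
    if n_samples < 2:
        raise ValueError("recurrence requires calls for at least 2 samples")
    order = annotation.sort_values(["chrom", "start"]).index
    sign = calls.loc[order].apply(lambda c: c.map(_SIGN)).to_numpy(dtype=int)
    n_genes = len(order)
    gain_count = (sign > 0).sum(axis=1)
    loss_count = (sign < 0).sum(axis=1)
    observed = np.maximum(gain_count, loss_count)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_genes, dtype=int)
    for _ in range(n_perm):
        null = np.empty_like(sign)
        for j in range(n_samples):
            null[:, j] = np.roll(sign[:, j], int(rng.integers(n_genes)))
        null_count = np.maximum((null > 0).sum(axis=1), (null < 0).sum(axis=1))
        exceed += null_count >= observed
    pvals = (1 + exceed) / (n_perm + 1)
    from statsmodels.stats.multitest import multipletests
    qvals = multipletests(pvals, method="fdr_bh")[1]

    direction = np.where(gain_count >= loss_count, "gain", "loss")
    flagged = (observed >= min_recurrence) & (qvals <= fdr) & (observed > 0)

    region_ids = np.full(n_genes, "", dtype=object)
    rid = 0
    chroms = annotation.loc[order, "chrom"].to_numpy()
    prev = False
    for i in range(n_genes):
        if flagged[i]:
            new_region = not prev or direction[i] != direction[i - 1] \
                or chroms[i] != chroms[i - 1]
            if new_region:
                rid += 1
            region_ids[i] = f"region{rid:03d}"
        prev = flagged[i]
    return pd.DataFrame(
        {"count": observed, "direction": direction, "p": pvals, "q": qvals,
         "flagged": flagged, "region_id": region_ids},
        index=order,
    ).reindex(calls.index)


def assign_gene_direction(calls: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-line calls into a consensus direction per gene.

    Sign-unanimity rule: if every non-neutral call agrees in sign
    (amplification counts as gain) the gene takes that direction with its
    supporting line count; both signs present -> "conflict" (excluded
    downstream); all neutral -> "none".
    """
    sign = calls.apply(lambda c: c.map(_SIGN)).to_numpy(dtype=int)
    n_gain = (sign > 0).sum(axis=1)
    n_loss = (sign < 0).sum(axis=1)
    direction = np.where(
        (n_gain > 0) & (n_loss > 0), "conflict",
        np.where(n_gain > 0, "gain", np.where(n_loss > 0, "loss", "none")),
    )
    support = np.where(direction == "gain", n_gain,
                       np.where(direction == "loss", n_loss, 0))
    return pd.DataFrame({"direction": direction, "support": support},
                        index=calls.index)
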