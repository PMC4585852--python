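"""Differential representation between transcriptome and translatome.

The unit of analysis is the paired log2 fold change fc(g, i) =
TL(g, i) - TC(g, i) per gene g and line i (numerically identical to log2
TE).  Three independently implemented statistics detect genes consistently
shifted across lines:

* rank product — geometric mean of per-sample fold-change ranks, with a
  permutation estimate of the expected number of false positives (PFP,
  percentage of false positives);
* one-sample paired t against zero with Benjamini-Hochberg correction;
* SAM-style moderated statistic d = mean / (s + s0) with a sign-flip
  permutation FDR at the selected threshold delta.

The consensus report gives the 7-region Venn decomposition; the primary
gene set is the rank-product selection (the most conservative method),
each gene labeled up (polysome-enriched) or down (polysome-depleted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def _rank_columns(fc: np.ndarray, ascending: bool) -> np.ndarray:
    """Average-tie ranks per column; ascending=False ranks largest first."""
    x = fc if ascending else -fc
    return np.apply_along_axis(stats.rankdata, 0, x)


def rank_product_statistic(fc: np.ndarray, direction: str) -> np.ndarray:
    """RP(g) = geometric mean of per-sample ranks (1 = most extreme).

    direction "up": large positive fold changes rank first;
    direction "down": large negative fold changes rank first.
    """
    if direction not in {"up", "down"}:
        raise ValueError("direction must be 'up' or 'down'")
    ranks = _rank_columns(np.asarray(fc, float), ascending=(direction == "down"))
    return np.exp(np.mean(np.log(ranks), axis=1))


def _pfp_from_null(rp_obs: np.ndarray, rp_null: np.ndarray, n_perm: int) -> np.ndarray:
    """PFP(g) = E[#null RP <= RP(g)] / rank-position of g, clipped to [0,1]."""
    pooled = np.sort(rp_null.ravel())
    e_fp = np.searchsorted(pooled, rp_obs, side="right") / n_perm
    order_rank = stats.rankdata(rp_obs, method="average")
    return np.clip(e_fp / order_rank, 0.0, 1.0)


def rank_product_test(
    fc: pd.DataFrame, n_perm: int = 1000, seed: int = 0,
    threshold: float = 0.05,
) -> pd.DataFrame:
    """Rank-product test in both directions with permutation PFP.

    The null shuffles ranks independently within each sample ``n_perm``
    times.  A gene's direction is the one with the smaller RP; a gene
    cannot be significant in both directions (asserted).  Returns a frame
    with rp_up, pfp_up, rp_down, pfp_down, direction, significant.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = fc.to_numpy(dtype=float)
    if np.isnan(x).all(axis=1).any():
        raise ValueError("a gene with no fold-change values is not testable")
    n_genes, n_samples = x.shape
    if n_samples < 2:
        raise ValueError("rank product requires at least 2 samples")
    rp_up = rank_product_statistic(x, "up")
    rp_down = rank_product_statistic(x, "down")

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, n_genes))
    base = np.arange(1, n_genes + 1, dtype=float)
    for b in range(n_perm):
        logs = np.zeros(n_genes)
        for _ in range(n_samples):
            logs += np.log(rng.permutation(base))
        null[b] = np.exp(logs / n_samples)
    pfp_up = _pfp_from_null(rp_up, null, n_perm)
    pfp_down = _pfp_from_null(rp_down, null, n_perm)

    direction = np.where(rp_up <= rp_down, "up", "down")
    pfp_best = np.where(direction == "up", pfp_up, pfp_down)
    significant = pfp_best <= threshold
    sig_both = (pfp_up <= threshold) & (pfp_down <= threshold)
    assert not sig_both.any(), "a gene cannot be significant in both directions"
    return pd.DataFrame(
        {"rp_up": rp_up, "pfp_up": pfp_up, "rp_down": rp_down,
         "pfp_down": pfp_down, "direction": direction, "pfp": pfp_best,
         "significant": significant},
        index=fc.index,
    )


def paired_t_test(fc: pd.DataFrame, threshold: float = 0.05) -> pd.DataFrame:
    """One-sample t of the paired fold changes against zero, BH-adjusted.

    Degenerate genes (zero variance, nonzero mean) get the smallest
    representable p and a flag; zero variance with zero mean gives t = 0,
    p = 1.
    """
    x = fc.to_numpy(dtype=float)
    n = (~np.isnan(x)).sum(axis=1)
    if (n < 2).any():
        raise ValueError("each gene needs >= 2 non-missing fold changes")
    mean = np.nanmean(x, axis=1)
    sd = np.nanstd(x, axis=1, ddof=1)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(np.abs(t), df=n - 1)
    t = np.where(degenerate & (mean == 0), 0.0, t)
    p = np.where(degenerate & (mean == 0), 1.0, p)
    tiny = np.nextafter(0, 1)
    p = np.where(degenerate & (mean != 0), tiny, p)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"t": t, "p": p, "q": q,
         "direction": np.where(mean >= 0, "up", "down"),
         "degenerate": degenerate, "significant": q <= threshold},
        index=fc.index,
    )


def _sam_s0(mean: np.ndarray, s: np.ndarray) -> float:
    """Fudge factor by the coefficient-of-variation minimization search.

    Candidates are percentiles of s (0, 5, ..., 100).  For each candidate,
    d_alpha = mean / (s + s_alpha); genes are binned into ~10 quantile bins
    of s; the candidate minimizing the coefficient of variation of the
    per-bin median absolute deviations of d_alpha wins.
    """
    if len(s) < 20:
        return float(np.median(s))
    qs = np.percentile(s, np.arange(0, 101, 5))
    bins = np.quantile(s, np.linspace(0, 1, 11))
    bin_idx = np.clip(np.searchsorted(bins, s, side="right") - 1, 0, 9)
    best, best_cv = float(np.median(s)), np.inf
    for s0 in qs:
        d = mean / (s + s0)
        mads = []
        for b in range(10):
            sel = bin_idx == b
            if sel.sum() >= 2:
                db = d[sel]
                mads.append(np.median(np.abs(db - np.median(db))))
        mads = np.asarray(mads)
        if len(mads) < 2 or np.mean(mads) == 0:
            continue
        cv = np.std(mads, ddof=1) / np.mean(mads)
        if cv < best_cv:
            best_cv, best = cv, float(s0)
    return best


@dataclass
class SamResult:
    table: pd.DataFrame          # per gene: d, direction, selected
    s0: float
    delta: float                 # selected threshold
    fdr_table: pd.DataFrame      # per candidate delta: n_selected, fdr


def sam_test(
    fc: pd.DataFrame, n_perm: int = 200, seed: int = 0,
    fdr_threshold: float = 0.05,
) -> SamResult:
    """SAM-style one-sample analysis with sign-flip permutation FDR.

    d(g) = mean(fc_g) / (se_g + s0).  The null flips the sign of whole
    samples (columns), the natural exchangeability for a paired design.
    FDR(delta) = median over permutations of the number of null genes with
    |d*| >= delta, divided by the number of observed genes with
    |d| >= delta.  The selected set uses the smallest delta (scanned over
    the observed |d| values) with FDR <= ``fdr_threshold``.
    """
    if n_perm < 10:
        raise ValueError("SAM needs n_perm >= 10")
    x = fc.to_numpy(dtype=float)
    n_genes, n_samples = x.shape
    if n_samples < 3:
        raise ValueError("SAM requires at least 3 samples")
    mean = x.mean(axis=1)
    se = x.std(axis=1, ddof=1) / np.sqrt(n_samples)
    s0 = _sam_s0(mean, se)
    denom = se + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(denom > 0, mean / np.where(denom > 0, denom, 1.0),
                     np.where(mean == 0, 0.0, np.inf * np.sign(mean)))

    rng = np.random.default_rng(seed)
    null_abs = np.empty((n_perm, n_genes))
    for b in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n_samples)
        xb = x * signs[None, :]
        mb = xb.mean(axis=1)
        sb = xb.std(axis=1, ddof=1) / np.sqrt(n_samples)
        db = sb + s0
        null_abs[b] = np.abs(np.where(db > 0, mb / np.where(db > 0, db, 1.0),
                                      0.0))

    abs_d = np.abs(d)
    candidates = np.unique(abs_d[abs_d > 0])
    if len(candidates) == 0:
        table = pd.DataFrame({"d": d, "direction": np.where(mean >= 0, "up", "down"),
                              "selected": False}, index=fc.index)
        return SamResult(table=table, s0=s0, delta=np.inf,
                         fdr_table=pd.DataFrame(columns=["delta", "n_selected", "fdr"]))
    null_sorted = np.sort(null_abs, axis=1)
    # per permutation, number of null genes at or beyond each candidate delta
    null_counts = np.empty((n_perm, len(candidates)), dtype=int)
    for b in range(n_perm):
        null_counts[b] = n_genes - np.searchsorted(null_sorted[b], candidates,
                                                   side="left")
    med_null = np.median(null_counts, axis=0)
    rows = []
    for j, delta in enumerate(candidates):
        n_obs = int((abs_d >= delta).sum())
        fdr = med_null[j] / n_obs if n_obs else np.nan
        rows.append((float(delta), n_obs, min(float(fdr), 1.0)))
    fdr_table = pd.DataFrame(rows, columns=["delta", "n_selected", "fdr"])
    ok = fdr_table[fdr_table["fdr"] <= fdr_threshold]
    delta = float(ok["delta"].iloc[0]) if len(ok) else np.inf
    selected = abs_d >= delta
    table = pd.DataFrame(
        {"d": d, "direction": np.where(mean >= 0, "up", "down"),
         "selected": selected}, index=fc.index)
    return SamResult(table=table, s0=s0, delta=delta, fdr_table=fdr_table)


def consensus_diffrep(
    rp: pd.DataFrame, t: pd.DataFrame, sam: SamResult,
) -> dict:
    """Venn decomposition of the three selections and the primary set.

    The primary set is the rank-product selection (PFP <= threshold) with
    its direction labels; ``share_all_three`` is the fraction of the
    primary set also found by both other methods.
    """
    universe = set(rp.index)
    if set(t.index) != universe or set(sam.table.index) != universe:
        raise ValueError("the three results cover different gene universes")
    a = set(rp.index[rp["significant"]])
    b = set(t.index[t["significant"]])
    c = set(sam.table.index[sam.table["selected"]])
    venn = {
        "rp_only": len(a - b - c),
        "t_only": len(b - a - c),
        "sam_only": len(c - a - b),
        "rp_t": len((a & b) - c),
        "rp_sam": len((a & c) - b),
        "t_sam": len((b & c) - a),
        "all_three": len(a & b & c),
    }
    share = len(a & b & c) / len(a) if a else float("nan")
    primary = rp.loc[sorted(a), ["direction", "pfp"]].copy()
    return {"venn": venn, "primary": primary, "share_all_three": share,
            "n_rp": len(a), "n_t": len(b), "n_sam": len(c)}
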