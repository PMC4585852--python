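"""RESTORE/ENHANCE classification and its statistical battery.

A differentially represented gene bearing a collinear CNA falls into one of
four classes from the sign pair (CNA direction, TE direction):

    (loss, up)   -> RESTORE_UP     translation opposes a deletion
    (gain, down) -> RESTORE_DOWN   translation opposes a gain
    (gain, up)   -> ENHANCE_UP     translation magnifies a gain
    (loss, down) -> ENHANCE_DOWN   translation magnifies a deletion

RESTORE means opposing signs (compensation), ENHANCE same signs
(magnification).  The battery: exact binomial prevalence of RESTORE over
ENHANCE, Fisher enrichment of compensatory TE inside CNAs, per-line
one-sided Wilcoxon shift tests of TE for lost/gained vs neutral genes,
Pearson correlation of per-line test strength with TE distribution
breadth, generic category enrichment, and the pan-cancer alteration
frequency bootstrap with genome-wide or CNA-background nulls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

RESTORE_CLASSES = ("RESTORE_UP", "RESTORE_DOWN", "ENHANCE_UP", "ENHANCE_DOWN")

_CLASS_MAP = {
    ("loss", "up"): "RESTORE_UP",
    ("gain", "down"): "RESTORE_DOWN",
    ("gain", "up"): "ENHANCE_UP",
    ("loss", "down"): "ENHANCE_DOWN",
}


def classify_restore(cna_direction: str, te_direction: str) -> str:
    """Map (CNA direction, TE direction) to its compensation class."""
    key = (cna_direction, te_direction)
    if key not in _CLASS_MAP:
        raise ValueError(
            f"unclassifiable pair {key!r}; CNA must be loss/gain and TE up/down"
        )
    return _CLASS_MAP[key]


def classify_genes(
    diffrep_primary: pd.DataFrame, gene_direction: pd.DataFrame
) -> pd.DataFrame:
    """Classify every diffrep gene with an unambiguous collinear CNA.

    ``diffrep_primary`` carries a ``direction`` column (up/down) for the
    primary differentially represented set; ``gene_direction`` the per-gene
    consensus CNA direction (loss/gain/none/conflict) with support counts.
    Genes with direction none or conflict are excluded.
    """
    rows = []
    for g in diffrep_primary.index:
        if g not in gene_direction.index:
            continue
        cna_dir = gene_direction.at[g, "direction"]
        if cna_dir not in ("loss", "gain"):
            continue
        te_dir = diffrep_primary.at[g, "direction"]
        rows.append((g, cna_dir, te_dir, classify_restore(cna_dir, te_dir),
                     int(gene_direction.at[g, "support"])))
    return pd.DataFrame(
        rows, columns=["gene_id", "cna_direction", "te_direction", "class",
                       "support"],
    ).set_index("gene_id")


def prevalence_test(n_restore: int, n_enhance: int) -> float:
    """Exact two-sided binomial test of RESTORE vs ENHANCE counts (p0 = 0.5).

    Sums the point probabilities not exceeding that of the observed count.
    """
    if n_restore < 0 or n_enhance < 0:
        raise ValueError("counts must be non-negative")
    n = n_restore + n_enhance
    if n < 1:
        raise ValueError("at least one classified gene is required")
    return float(stats.binomtest(n_restore, n, 0.5, alternative="two-sided").pvalue)


def compensatory_enrichment(
    compensatory: set[str], cna_genes: set[str], universe: set[str]
) -> tuple[float, float]:
    """Fisher 2x2 of (compensatory TE) x (inside a CNA) over the universe.

    Returns (odds_ratio, two-sided p).
    """
    if not universe:
        raise ValueError("empty universe")
    compensatory &= universe
    cna_genes &= universe
    a = len(compensatory & cna_genes)
    b = len(compensatory - cna_genes)
    c = len(cna_genes - compensatory)
    d = len(universe) - a - b - c
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)


def per_line_wilcoxon(
    te: pd.DataFrame, calls: pd.DataFrame, adjust: bool = False,
) -> pd.DataFrame:
    """Per-line one-sided rank-sum tests of the dosage-compensation shift.

    For each line: TE of lost genes vs neutral genes (alternative:
    lost greater — the RESTORE_UP family) and TE of gained genes vs
    neutral (alternative: gained less — RESTORE_DOWN).  Amplification
    counts as gained.  Exact p for small strata, normal approximation with
    tie correction otherwise.  Lines with an empty stratum get NaN with a
    warning.  Optional BH adjustment across lines per family.
    """
    rows = []
    for line in te.columns:
        col_calls = calls[line]
        te_col = te[line]
        lost = te_col[col_calls == "loss"].dropna()
        gained = te_col[col_calls.isin(["gain", "amplification"])].dropna()
        neutral = te_col[col_calls == "neutral"].dropna()
        p_up = p_down = np.nan
        if len(neutral) == 0 or (len(lost) == 0 and len(gained) == 0):
            warnings.warn(f"line {line}: empty stratum, Wilcoxon omitted")
        else:
            if len(lost) > 0:
                p_up = stats.mannwhitneyu(lost, neutral,
                                          alternative="greater").pvalue
            else:
                warnings.warn(f"line {line}: no lost genes")
            if len(gained) > 0:
                p_down = stats.mannwhitneyu(gained, neutral,
                                            alternative="less").pvalue
            else:
                warnings.warn(f"line {line}: no gained genes")
        rows.append((line, len(lost), len(gained), len(neutral), p_up, p_down))
    out = pd.DataFrame(rows, columns=["line", "n_lost", "n_gained", "n_neutral",
                                      "p_restore_up", "p_restore_down"]
                       ).set_index("line")
    if adjust:
        for col in ("p_restore_up", "p_restore_down"):
            ok = out[col].notna()
            if ok.any():
                out.loc[ok, col] = multipletests(out.loc[ok, col],
                                                 method="fdr_bh")[1]
    return out


def breadth_correlation(pvalues: pd.Series, breadth: pd.Series) -> float:
    """Pearson r of per-line -log10(p) against TE distribution breadth (IQR)."""
    joined = pd.concat([pvalues, breadth], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 lines with both values")
    x = -np.log10(joined.iloc[:, 0].to_numpy(dtype=float))
    y = joined.iloc[:, 1].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y)[0])


def category_enrichment(
    categories: dict[str, set[str]], target: set[str], universe: set[str],
) -> pd.DataFrame:
    """One Fisher 2x2 per category, BH across categories, fold enrichment.

    fold = (hits / |target|) / (|category| / |universe|).  Categories
    disjoint from the universe are skipped with a warning; an empty target
    is an error.
    """
    if not target:
        raise ValueError("empty target set")
    target = target & universe
    rows = []
    for name, members in categories.items():
        members = members & universe
        if not members:
            warnings.warn(f"category {name!r} is disjoint from the universe; skipped")
            continue
        a = len(target & members)
        b = len(target - members)
        c = len(members - target)
        d = len(universe) - a - b - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        fold = (a / len(target)) / (len(members) / len(universe))
        rows.append((name, a, len(members), odds, p, fold))
    out = pd.DataFrame(rows, columns=["category", "hits", "category_size",
                                      "odds_ratio", "p", "fold_enrichment"]
                       ).set_index("category")
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


@dataclass
class BootstrapResult:
    observed: float
    null: np.ndarray
    p: float
    n_set: int
    mode: str


def pan_cancer_bootstrap(
    gene_set: set[str],
    freq_table: pd.DataFrame,
    concordant: str,
    mode: str = "genomewide",
    n_boot: int = 1000,
    seed: int = 0,
    cna_background: set[str] | None = None,
) -> BootstrapResult:
    """Bootstrap test of pan-cancer concordant alteration frequency.

    ``freq_table`` is genes x "<tumor_type>:gain"/"<tumor_type>:loss"
    columns; ``concordant`` picks which alteration counts as concordant
    ("gain" for RESTORE_DOWN sets, "loss" for RESTORE_UP).  The observed
    statistic is the unweighted mean concordant frequency of the set over
    tumor types; the null re-draws same-size gene sets from the
    genome-wide background or, with mode "cna_background", from
    ``cna_background`` minus the tested set.  Add-one empirical p.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if concordant not in {"gain", "loss"}:
        raise ValueError("concordant must be 'gain' or 'loss'")
    cols = [c for c in freq_table.columns if c.endswith(f":{concordant}")]
    if not cols:
        raise ValueError(f"frequency table has no ':{concordant}' columns")
    gene_set = {g for g in gene_set if g in freq_table.index}
    if not gene_set:
        raise ValueError("gene set does not intersect the frequency table")
    sub = freq_table.loc[sorted(gene_set), cols]
    observed = float(sub.to_numpy().mean())

    if mode == "genomewide":
        background = list(freq_table.index)
    elif mode == "cna_background":
        if cna_background is None:
            raise ValueError("cna_background mode requires the background set")
        background = sorted((cna_background & set(freq_table.index)) - gene_set)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    k = len(gene_set)
    if len(background) < k:
        raise ValueError("background smaller than the tested set")
    rng = np.random.default_rng(seed)
    values = freq_table.loc[background, cols].to_numpy()
    null = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.choice(len(background), size=k, replace=False)
        null[b] = values[idx].mean()
    p = (1 + int((null >= observed).sum())) / (n_boot + 1)
    return BootstrapResult(observed=observed, null=null, p=p, n_set=k, mode=mode)
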