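"""Expression preprocessing and translational-efficiency computation.

Probe filtering, quantile normalization, detectability, log2 TE (the
translatome minus transcriptome difference), per-sample TE distribution
summaries, profile clustering, and delta-CT qPCR normalization.

TE is carried in log2: a positive value marks translational enhancement
(polysome-enriched), a negative one translational repression.  The first
quartile used by the detectability rule follows the linear-interpolation
convention, pinned in config so tests are exact.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from riborestore.config import ExpressionParams


def filter_probes(
    matrix: pd.DataFrame,
    flags: dict[str, pd.DataFrame],
    above_background_frac: float = 0.25,
    good_spot_frac: float = 0.75,
) -> pd.DataFrame:
    """Apply the probe quality rule and median-summarize duplicate probes.

    A probe is kept iff it is above background in at least
    ``above_background_frac`` of samples, a good spot in at least
    ``good_spot_frac``, and saturated or an outlier in none.  Rows sharing
    an index label (duplicate probes for one gene) are summarized by their
    per-sample median after filtering.
    """
    for frac in (above_background_frac, good_spot_frac):
        if not 0.0 <= frac <= 1.0:
            raise ValueError("filter fractions must lie in [0, 1]")
    for name in ("above_background", "good_spot", "saturated", "outlier"):
        if name not in flags:
            raise ValueError(f"missing QC flag table {name!r}")
        if flags[name].shape != matrix.shape:
            raise ValueError(f"QC flag table {name!r} not aligned to the matrix")
    n = matrix.shape[1]
    keep = (
        (flags["above_background"].to_numpy().sum(axis=1) >= above_background_frac * n)
        & (flags["good_spot"].to_numpy().sum(axis=1) >= good_spot_frac * n)
        & ~flags["saturated"].to_numpy().any(axis=1)
        & ~flags["outlier"].to_numpy().any(axis=1)
    )
    filtered = matrix.loc[keep]
    if filtered.index.has_duplicates:
        filtered = filtered.groupby(level=0, sort=False).median()
    return filtered


def normalize_quantile(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile normalization: mean of order statistics across samples.

    Every sample's sorted values are replaced by the across-sample mean of
    order statistics; tied values within a sample receive the average of
    the values they would have been assigned.  Missing values stay missing;
    a sample's non-missing values are mapped through the reference
    distribution by rank.  An all-missing sample is an error.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization requires at least 2 samples")
    x = matrix.to_numpy(dtype=float)
    if np.all(np.isnan(x), axis=0).any():
        bad = matrix.columns[np.all(np.isnan(x), axis=0)][0]
        raise ValueError(f"sample {bad!r} has no values")
    n_genes = x.shape[0]
    complete = ~np.isnan(x).any(axis=1)
    if complete.all():
        ref = np.sort(x, axis=0).mean(axis=1)
        out = np.empty_like(x)
        for j in range(x.shape[1]):
            col = x[:, j]
            order = np.argsort(col, kind="mergesort")
            assigned = np.empty(n_genes)
            assigned[order] = ref
            # average assigned values over ties
            ser = pd.Series(assigned)
            out[:, j] = ser.groupby(col).transform("mean").to_numpy()
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    # missing-aware: build the reference from per-column quantiles
    grid = np.linspace(0, 1, n_genes)
    cols_q = [np.quantile(x[~np.isnan(x[:, j]), j], grid) for j in range(x.shape[1])]
    ref = np.mean(np.column_stack(cols_q), axis=1)
    out = np.full_like(x, np.nan)
    for j in range(x.shape[1]):
        col = x[:, j]
        ok = ~np.isnan(col)
        vals = col[ok]
        ranks = pd.Series(vals).rank(method="average").to_numpy()
        q = (ranks - 1) / (len(vals) - 1) if len(vals) > 1 else np.array([0.5])
        out[ok, j] = np.interp(q, grid, ref)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def detectable_genes(matrix: pd.DataFrame) -> set[str]:
    """Genes whose median expression reaches the first quartile of medians.

    Genes below the first quartile are considered
    non-expressed.  Applied per level; callers union across levels.
    """
    med = matrix.median(axis=1, skipna=True)
    q1 = float(np.quantile(med.dropna().to_numpy(), 0.25, method="linear"))
    return set(med.index[med >= q1])


def detectable_union(tc: pd.DataFrame, tl: pd.DataFrame) -> set[str]:
    """Union of per-level detectable sets (a gene silenced at one level
    but detected at the other remains analyzable)."""
    return detectable_genes(tc) | detectable_genes(tl)


def compute_te(tl: pd.DataFrame, tc: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """log2 translational efficiency TE = TL - TC plus per-sample summaries.

    Returns (te_matrix, summary) where summary has per-sample median, IQR
    ("breadth"), and tail fractions beyond +/-1 log2 (>= 2-fold shifts).
    """
    if not (tl.index.equals(tc.index) and tl.columns.equals(tc.columns)):
        raise ValueError("translatome and transcriptome matrices are misaligned")
    te = tl - tc
    q1 = te.quantile(0.25)
    q3 = te.quantile(0.75)
    summary = pd.DataFrame({
        "median": te.median(),
        "iqr": q3 - q1,
        "frac_above_1": (te > 1).mean(),
        "frac_below_-1": (te < -1).mean(),
    })
    summary.index.name = "sample"
    return te, summary


def cluster_profiles(
    profiles: pd.DataFrame,
    level_of: dict[str, str],
    params: ExpressionParams | None = None,
) -> dict:
    """Cluster expression profiles with Pearson distance and Ward linkage.

    ``profiles`` is genes x profiles (both levels side by side);
    ``level_of`` maps each profile name to its level label ("TC"/"TL").
    Returns the linkage matrix, k-means labels, PCA coordinates, and the
    number of translatome profiles whose nearest profile (Pearson distance)
    is another translatome profile rather than any transcriptome one — the
    by-level co-clustering readout.
    """
    params = params or ExpressionParams()
    if profiles.shape[1] < 3:
        raise ValueError("clustering requires at least 3 profiles")
    sd = profiles.std(axis=0, ddof=0)
    if (sd == 0).any():
        bad = sd.index[sd == 0][0]
        raise ValueError(f"profile {bad!r} has zero variance")
    corr = np.corrcoef(profiles.to_numpy().T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="ward")

    km = KMeans(n_clusters=params.kmeans_k, n_init=params.kmeans_n_init,
                random_state=params.seed)
    km_labels = km.fit_predict(profiles.to_numpy().T)
    pca = PCA(n_components=min(3, profiles.shape[1] - 1),
              random_state=params.seed)
    coords = pca.fit_transform(profiles.to_numpy().T)

    names = list(profiles.columns)
    tl_names = [p for p in names if level_of[p] == "TL"]
    co = 0
    for p in tl_names:
        i = names.index(p)
        d = dist[i].copy()
        d[i] = np.inf
        nearest = names[int(np.argmin(d))]
        if level_of[nearest] == "TL":
            co += 1
    return {
        "linkage": linkage,
        "profile_names": names,
        "kmeans_labels": dict(zip(names, km_labels.tolist())),
        "pca_coordinates": pd.DataFrame(
            coords, index=names,
            columns=[f"PC{i + 1}" for i in range(coords.shape[1])]),
        "explained_variance_ratio": pca.explained_variance_ratio_.tolist(),
        "n_translatome_coclustered": co,
        "n_translatome": len(tl_names),
    }


def normalize_qpcr(ct_table: pd.DataFrame, reference_ids: list[str]) -> pd.DataFrame:
    """Delta-CT normalization against the mean CT of reference genes.

    ``ct_table`` is long format with columns gene_id, sample, ct
    (replicate rows allowed; averaged first).  The arithmetic mean of
    reference CTs corresponds to the geometric mean of their linear
    levels.  Relative level = 2 ** -(CT_target - mean CT_references).
    """
    need = {"gene_id", "sample", "ct"}
    if not need <= set(ct_table.columns):
        raise ValueError(f"ct_table needs columns {sorted(need)}")
    mean_ct = ct_table.groupby(["sample", "gene_id"])["ct"].mean().unstack()
    missing = [r for r in reference_ids if r not in mean_ct.columns]
    if missing:
        raise ValueError(f"reference gene(s) missing from table: {missing}")
    ref = mean_ct[list(reference_ids)].mean(axis=1)
    rel = 2.0 ** -(mean_ct.sub(ref, axis=0))
    return rel.drop(columns=list(reference_ids))
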