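"""Histone-family stoichiometry and protein-complex membership statistics.

Replication-dependent histone genes produce near-identical proteins within
a family (H1, H2A, H2B, H3, H4), so the biologically meaningful signal is
the family-level sum of linear-scale mRNA abundances.  Translational
coordination shows up as per-line family sums that are far less dispersed
across families in the translatome than in the transcriptome; the pinned
scalar metric is the coefficient of variation (sample SD / mean) of family
sums within a line, and the coordination ratio CV_TC / CV_TL (> 1 means
the translatome is the coordinated level).

Complex membership statistics test whether differentially represented
genes aggregate in annotated protein complexes, with a same-size random
draw bootstrap null.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def family_signals(
    tc: pd.DataFrame, tl: pd.DataFrame, family_map: pd.Series,
) -> pd.DataFrame:
    """Linear-scale family sums per line and level.

    ``family_map`` maps gene_id -> family label for member genes.  log2
    member values are de-logged (2**x) and summed within each family.
    Families with no measured member are omitted with a warning.  Returns
    a long frame (line, family, level, signal) plus the across-line mean
    rows (line = "__mean__").
    """
    rows = []
    families = sorted(set(family_map.dropna()))
    for family in families:
        members = [g for g in family_map.index[family_map == family] if g in tc.index]
        if not members:
            warnings.warn(f"family {family!r} has no measured member; omitted")
            continue
        for level, mat in (("TC", tc), ("TL", tl)):
            lin = 2.0 ** mat.loc[members]
            sums = lin.sum(axis=0)
            for line, v in sums.items():
                rows.append((line, family, level, float(v)))
            rows.append(("__mean__", family, level, float(sums.mean())))
    return pd.DataFrame(rows, columns=["line", "family", "level", "signal"])


def stoichiometry_cv(family_table: pd.DataFrame) -> pd.DataFrame:
    """Per-line, per-level CV across family sums and the coordination ratio.

    CV = sample standard deviation / mean of the family sums within a
    (line, level) cell; requires >= 2 families.  The coordination ratio is
    CV_TC / CV_TL: values above 1 mean the translatome level is the
    coordinated one.  Zero-mean cells yield NaN (undefined), reported.
    """
    obs = family_table[family_table["line"] != "__mean__"]
    n_fam = obs["family"].nunique()
    if n_fam < 2:
        raise ValueError("coordination CV needs at least 2 families")
    rows = []
    for line, grp in obs.groupby("line", sort=True):
        cvs = {}
        for level, lg in grp.groupby("level"):
            v = lg["signal"].to_numpy(dtype=float)
            m = v.mean()
            cvs[level] = float(np.std(v, ddof=1) / m) if m != 0 else np.nan
        ratio = cvs.get("TC", np.nan) / cvs.get("TL", np.nan) \
            if cvs.get("TL") not in (0, None) else np.nan
        rows.append((line, cvs.get("TC", np.nan), cvs.get("TL", np.nan), ratio))
    return pd.DataFrame(rows, columns=["line", "cv_tc", "cv_tl",
                                       "coordination_ratio"]).set_index("line")


def complex_membership_stats(
    diffrep_set: set[str], catalog: dict[str, set[str]], universe: set[str],
) -> dict:
    """Membership of diffrep genes in annotated complexes.

    Returns n_members (diffrep genes in >= 1 complex) and
    n_complexes_half_covered (complexes with at least half their members —
    ties count — in the diffrep set).  Catalog members outside the
    universe are warned about and dropped.
    """
    if not catalog:
        raise ValueError("empty complex catalog")
    diffrep_set = diffrep_set & universe
    clean: dict[str, set[str]] = {}
    for cid, members in catalog.items():
        inside = members & universe
        if len(inside) < len(members):
            warnings.warn(f"complex {cid!r}: dropped {len(members) - len(inside)} "
                          "member(s) outside the universe")
        if inside:
            clean[cid] = inside
    complexed = set().union(*clean.values()) if clean else set()
    n_members = len(diffrep_set & complexed)
    half = sum(1 for members in clean.values()
               if len(members & diffrep_set) * 2 >= len(members))
    return {"n_members": n_members, "n_complexes_half_covered": half,
            "n_complexes": len(clean), "n_complexed_genes": len(complexed)}


def complex_bootstrap(
    diffrep_set: set[str], catalog: dict[str, set[str]], universe: set[str],
    n_boot: int = 1000, seed: int = 0,
) -> dict:
    """Add-one empirical p for n_members against same-size random draws."""
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    diffrep_set = diffrep_set & universe
    if len(universe) < len(diffrep_set):
        raise ValueError("universe smaller than the tested set")
    observed = complex_membership_stats(diffrep_set, catalog, universe)["n_members"]
    complexed = set()
    for members in catalog.values():
        complexed |= members & universe
    uni = np.array(sorted(universe))
    in_complex = np.isin(uni, sorted(complexed))
    rng = np.random.default_rng(seed)
    k = len(diffrep_set)
    null = np.empty(n_boot, dtype=int)
    for b in range(n_boot):
        idx = rng.choice(len(uni), size=k, replace=False)
        null[b] = int(in_complex[idx].sum())
    p = (1 + int((null >= observed).sum())) / (n_boot + 1)
    return {"observed": observed, "null": null, "p": p}
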