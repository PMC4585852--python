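"""Headline report arithmetic over class and concordance counts.

These helpers turn the raw per-class counts produced by the pipeline (or
any user-supplied counts) into the totals, fractions and percentages the
summary report prints.  Percentages are rounded to one decimal for
display; the exact fractions are returned alongside.
"""

from __future__ import annotations


def collinear_summary(n_deletion: int, n_gain: int) -> dict:
    """Total of differentially represented genes bearing collinear CNAs."""
    return {"n_deletion": n_deletion, "n_gain": n_gain,
            "n_collinear": n_deletion + n_gain}


def collinear_fraction(n_collinear: int, n_diffrep: int) -> dict:
    """Collinear genes as a percentage of all differentially represented."""
    frac = n_collinear / n_diffrep
    return {"fraction": frac, "percent": round(100 * frac, 1)}


def class_totals(n_restore_up: int, n_restore_down: int,
                 n_enhance_up: int, n_enhance_down: int) -> dict:
    """RESTORE and ENHANCE totals from the four subclass counts."""
    return {
        "n_restore": n_restore_up + n_restore_down,
        "n_enhance": n_enhance_up + n_enhance_down,
        "n_classified": (n_restore_up + n_restore_down
                         + n_enhance_up + n_enhance_down),
    }


def concordance_summary(n_down_concordant: int, n_down: int,
                        n_up_concordant: int, n_up: int) -> dict:
    """Prognosis concordance fraction over all RESTORE genes.

    Combines the two subclass readouts (high-expression risk for
    RESTORE_DOWN, low-expression risk for RESTORE_UP) into the global
    concordant percentage.
    """
    total = n_down + n_up
    conc = n_down_concordant + n_up_concordant
    frac = conc / total
    return {"n_concordant": conc, "n_restore": total,
            "fraction": frac, "percent": round(100 * frac)}


def family_total(member_counts: list[int] | dict) -> int:
    """Total enriched genes across stoichiometric families."""
    counts = list(member_counts.values()) if isinstance(member_counts, dict) \
        else list(member_counts)
    return sum(counts)


def subset_fraction(n_subset: int, n_total: int) -> dict:
    """A subset as a fraction and one-decimal percentage of its total
    (e.g. cis-element carriers within a class, half-covered complexes)."""
    frac = n_subset / n_total
    return {"fraction": frac, "percent": round(100 * frac, 1)}
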