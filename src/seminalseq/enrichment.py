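"""Category and synteny over/under-representation via chi-square with
Yates' continuity correction.

Expected counts come from the distribution of a background gene set (the
"expressed" universe by default); a category is declared over-represented
when significantly more genes than expected fall in it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ContingencyTable2x2, ValidationError

__all__ = [
    "EnrichmentResult",
    "chisq_yates",
    "category_enrichment",
    "synteny_enrichment",
]


@dataclass
class EnrichmentResult:
    """One category's test: observed vs expected with direction and p."""

    name: str
    observed: int
    expected: float
    chi2_stat: float
    p_value: float
    direction: str  # OVER | UNDER | NONE
    significant: bool


def chisq_yates(table: ContingencyTable2x2) -> tuple[float, float]:
    """Yates-corrected chi-square statistic and p (1 df) for a 2x2 table.

    statistic = sum over cells of max(|O - E| - 0.5, 0)^2 / E, with expected
    counts from the row/column margins. Returns (nan, nan) with a warning
    when any expected cell is zero.
    """
    obs = table.as_array()
    total = obs.sum()
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    if (exp <= 0).any():
        warnings.warn("zero expected cell; chi-square undefined")
        return (float("nan"), float("nan"))
    adj = np.maximum(np.abs(obs - exp) - 0.5, 0.0)
    stat = float((adj**2 / exp).sum())
    p = float(stats.chi2.sf(stat, df=1))
    return stat, p


def _direction(observed: float, expected: float, significant: bool) -> str:
    if not significant:
        return "NONE"
    return "OVER" if observed > expected else "UNDER"


def category_enrichment(
    de_genes: Iterable[str],
    category_map: Mapping[str, str] | pd.Series,
    background: Iterable[str],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-category 2x2 Yates chi-square of a gene set against a background.

    For each category the table is (in-category vs not) x (in the DE set vs
    rest of background); the expected in-category DE count is
    |DE| * (category share of background). Categories absent from the
    background are skipped with a warning.
    """
    if isinstance(category_map, pd.Series):
        category_map = category_map.dropna().to_dict()
    background = list(dict.fromkeys(background))
    de_set = set(de_genes)
    stray = de_set - set(background)
    if stray:
        raise ValidationError(
            f"{len(stray)} DE gene(s) not in background (first: "
            f"{sorted(stray)[0]!r})"
        )
    bg_cat = {g: category_map.get(g) for g in background}
    categories = sorted({c for c in category_map.values() if c is not None})
    n_bg = len(background)
    n_de = len(de_set)
    rows = []
    for cat in categories:
        in_cat = [g for g in background if bg_cat[g] == cat]
        if not in_cat:
            warnings.warn(f"category {cat!r} absent from background; skipped")
            continue
        a = sum(1 for g in in_cat if g in de_set)          # in-cat, DE
        b = len(in_cat) - a                                 # in-cat, not DE
        c = n_de - a                                        # out-cat, DE
        d = (n_bg - len(in_cat)) - c                        # out-cat, not DE
        stat, p = chisq_yates(ContingencyTable2x2(a, b, c, d))
        expected = n_de * len(in_cat) / n_bg
        sig = bool(np.isfinite(p) and p < alpha)
        rows.append({
            "category": cat, "observed": a, "expected": expected,
            "n_category": len(in_cat), "chi2_stat": stat, "p_value": p,
            "direction": _direction(a, expected, sig), "significant": sig,
        })
    return pd.DataFrame(rows).set_index("category")


def synteny_enrichment(
    gene_set: Iterable[str],
    annotation: pd.DataFrame,
    reference: str | tuple[int, int] = "EXPRESSED",
    background: Iterable[str] | None = None,
    alpha: float = 0.01,
) -> EnrichmentResult:
    """Non-syntenic over/under-representation of a gene set.

    ``reference`` is either "EXPRESSED" (compare against ``background``, the
    expressed universe, via annotation synteny labels) or a pair
    (n_nonsyntenic, n_syntenic) giving the whole-genome reference margins
    directly (e.g. the published filtered-gene-set totals). Genes with
    UNKNOWN synteny are excluded with a logged count.
    """
    genes = list(dict.fromkeys(gene_set))
    if not genes:
        return EnrichmentResult("synteny", 0, float("nan"), float("nan"),
                                float("nan"), "NONE", False)
    labels = annotation.loc[[g for g in genes if g in annotation.index],
                            "synteny"]
    unknown = int((labels == "UNKNOWN").sum())
    if unknown:
        warnings.warn(f"excluding {unknown} gene(s) with UNKNOWN synteny")
    labels = labels[labels != "UNKNOWN"]
    a = int((labels == "NON_SYNTENIC").sum())
    b = int((labels == "SYNTENIC").sum())

    if isinstance(reference, tuple):
        c, d = int(reference[0]), int(reference[1])
    elif reference == "EXPRESSED":
        if background is None:
            raise ValidationError("reference='EXPRESSED' requires a background")
        bg = [g for g in dict.fromkeys(background) if g in annotation.index]
        bl = annotation.loc[bg, "synteny"]
        bl = bl[bl != "UNKNOWN"]
        c = int((bl == "NON_SYNTENIC").sum())
        d = int((bl == "SYNTENIC").sum())
    else:
        raise ValueError(f"unknown reference {reference!r}")

    stat, p = chisq_yates(ContingencyTable2x2(a, b, c, d))
    set_frac = a / (a + b) if (a + b) else float("nan")
    ref_frac = c / (c + d) if (c + d) else float("nan")
    expected = (a + b) * ref_frac
    sig = bool(np.isfinite(p) and p < alpha)
    return EnrichmentResult(
        name="non_syntenic", observed=a, expected=expected, chi2_stat=stat,
        p_value=p, direction=_direction(a, expected, sig), significant=sig,
    )
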