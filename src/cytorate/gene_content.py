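"""Gene-content bias and retention statistics across subgenomes.

After allopolyploidy, duplicated genes fractionate: each homoeolog can be
lost independently, and loss may favour one subgenome.  The bias statistic
is the difference in the proportions of surviving genes between the
paternal and maternal subgenomes, delta = (n_pat - n_mat)/(n_pat + n_mat),
with an exact (Clopper-Pearson) binomial confidence interval and exact
binomial p against equal content.  Category-level biases are also tested
against the genome-wide background (the non-organelle-targeted genes), and
duplicate retention is compared by Pearson chi-square.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats


@dataclasses.dataclass
class BiasResult:
    """Paternal-vs-maternal content bias with exact binomial uncertainty."""

    n_pat: int
    n_mat: int
    delta: float
    ci95: tuple[float, float]
    p: float

    @property
    def direction(self) -> str:
        if self.delta > 0:
            return "paternal"
        if self.delta < 0:
            return "maternal"
        return "none"


def subgenome_bias(n_pat: int, n_mat: int) -> BiasResult:
    """Exact binomial bias of gene content between subgenomes.

    delta = (n_pat - n_mat) / (n_pat + n_mat).  The 95% CI is the exact
    Clopper-Pearson interval on the paternal proportion transformed to the
    delta scale by 2p - 1; the p-value is the exact two-sided binomial test
    against 0.5.
    """
    n_pat, n_mat = int(n_pat), int(n_mat)
    if n_pat < 0 or n_mat < 0:
        raise ValueError("counts must be non-negative")
    n = n_pat + n_mat
    if n == 0:
        raise ValueError("both subgenome counts are zero")
    test = stats.binomtest(n_pat, n, 0.5)
    ci = test.proportion_ci(confidence_level=0.95, method="exact")
    return BiasResult(
        n_pat=n_pat,
        n_mat=n_mat,
        delta=(n_pat - n_mat) / n,
        ci95=(2.0 * ci.low - 1.0, 2.0 * ci.high - 1.0),
        p=float(test.pvalue),
    )


@dataclasses.dataclass
class NormalizedBiasResult:
    """Category bias relative to the genome-wide (NOT) background."""

    difference: float  # category paternal proportion minus NOT paternal proportion
    direction: str  # paternal | maternal | none, relative to background
    p: float
    odds_ratio: float


def normalized_bias(category: BiasResult, background: BiasResult) -> NormalizedBiasResult:
    """Exact two-proportion test of a category against the NOT background.

    Rather than testing against 0.5, the category's paternal proportion is
    compared with the background's via the conditional exact
    (hypergeometric) test on the 2x2 count table.
    """
    table = np.array(
        [[category.n_pat, category.n_mat], [background.n_pat, background.n_mat]]
    )
    res = stats.fisher_exact(table, alternative="two-sided")
    p_cat = category.n_pat / (category.n_pat + category.n_mat)
    p_bg = background.n_pat / (background.n_pat + background.n_mat)
    diff = p_cat - p_bg
    direction = "paternal" if diff > 0 else ("maternal" if diff < 0 else "none")
    return NormalizedBiasResult(
        difference=diff,
        direction=direction,
        p=float(res.pvalue),
        odds_ratio=float(res.statistic),
    )


@dataclasses.dataclass
class RetentionResult:
    chi2: float
    p: float
    direction: int  # +1 category retention above background, -1 below, 0 equal
    low_expected: bool  # any expected cell below 1


def retention_test(
    category_counts: tuple[int, int], not_counts: tuple[int, int]
) -> RetentionResult:
    """Pearson chi-square of duplicate retention vs the NOT background.

    Counts are (retained_duplicate, single_copy).  No continuity
    correction is applied; a warning flag marks expected cells below 1.
    """
    table = np.array([category_counts, not_counts], float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    r_cat = table[0, 0] / table[0].sum()
    r_not = table[1, 0] / table[1].sum()
    direction = int(np.sign(r_cat - r_not))
    return RetentionResult(
        chi2=float(chi2),
        p=float(p),
        direction=direction,
        low_expected=bool((expected < 1).any()),
    )


def retention_binomial(n_retained_duplicate: int, n_single: int) -> float:
    """Exact binomial p of the background against equal retention (0.5)."""
    n = n_retained_duplicate + n_single
    if n == 0:
        raise ValueError("no genes")
    return float(stats.binomtest(n_retained_duplicate, n, 0.5).pvalue)


# ---------------------------------------------------------------------------
# tabular report


CONTENT_COLUMNS = [
    "category", "n_pat", "n_mat", "n_dip_pat", "n_dip_mat",
    "n_retained_duplicate", "n_single",
]


def read_content_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CONTENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"content table lacks columns: {sorted(missing)}")
    return df


def bias_report(content: pd.DataFrame, background_category: str = "NOT") -> pd.DataFrame:
    """Per-category bias rows shaped like a content-bias summary table."""
    bg_rows = content[content["category"] == background_category]
    background = None
    if len(bg_rows) == 1:
        bg = bg_rows.iloc[0]
        background = subgenome_bias(bg["n_pat"], bg["n_mat"])
    rows = []
    for _, r in content.iterrows():
        bias = subgenome_bias(r["n_pat"], r["n_mat"])
        row = {
            "category": r["category"],
            "n_dip_pat": r["n_dip_pat"],
            "n_pat": r["n_pat"],
            "n_mat": r["n_mat"],
            "n_dip_mat": r["n_dip_mat"],
            "delta": round(bias.delta, 3),
            "ci_low": round(bias.ci95[0], 3),
            "ci_high": round(bias.ci95[1], 3),
            "p_binomial": bias.p,
        }
        if background is not None and r["category"] != background_category:
            norm = normalized_bias(bias, background)
            row["p_vs_background"] = norm.p
            row["direction_vs_background"] = norm.direction
        rows.append(row)
    return pd.DataFrame(rows)
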