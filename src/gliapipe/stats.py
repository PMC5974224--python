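"""Group-comparison statistics on per-animal summaries.

The animal is the unit of analysis: per-cell and per-image measures are
averaged within each image, then across an animal's images, before any
test is run. Fixed-effects two-way ANOVA (age x stress, Type-II sums of
squares) is the parametric comparison; Mann-Whitney U, Kruskal-Wallis
and two-sample Kolmogorov-Smirnov cover skewed measures; Pearson r links
glial measures to external covariates such as dendritic spine density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import ManifestError, ParameterError, UnbalancedDesignError, UndefinedCorrelationError
from .types import CellRecord, ImageGRSummary

__all__ = [
    "TestResult",
    "two_way_anova",
    "mann_whitney_u",
    "kruskal_wallis",
    "ks_test",
    "pearson_r",
    "ecdf",
    "per_animal_summary",
]

#: Largest per-group n for which the Mann-Whitney p-value is computed by
#: exact enumeration (ties force the tie-corrected normal approximation).
EXACT_MWU_MAX_N = 8


@dataclass
class TestResult:
    """One test outcome. ``terms`` is populated for multi-term models
    (ANOVA: age, stress, interaction), otherwise ``statistic``/``pvalue``
    hold the single result."""

    test: str
    statistic: float = float("nan")
    pvalue: float = float("nan")
    n: tuple[int, ...] = ()
    terms: dict[str, dict[str, float]] = field(default_factory=dict)
    degenerate: bool = False
    note: str = ""

    def to_row(self) -> dict:
        row = {
            "test": self.test,
            "statistic": self.statistic,
            "pvalue": self.pvalue,
            "n": "/".join(str(x) for x in self.n),
            "degenerate": self.degenerate,
            "note": self.note,
        }
        for term, fp in self.terms.items():
            row[f"{term}_F"] = fp["F"]
            row[f"{term}_p"] = fp["p"]
        return row


def two_way_anova(
    values, age_labels, stress_labels, ss_type: int = 2
) -> TestResult:
    """Two-factor fixed-effects ANOVA with interaction.

    Type-II sums of squares by default (robust to mild imbalance);
    Type I/III selectable. Returns F and p for the age and stress main
    effects and their interaction. A design with zero within-cell
    variance is flagged ``degenerate`` (F is infinite or undefined).

    Raises
    ------
    UnbalancedDesignError
        If any age x stress cell of the design is empty.
    """
    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "age": list(age_labels),
            "stress": list(stress_labels),
        }
    )
    ages = sorted(df["age"].unique())
    stresses = sorted(df["stress"].unique())
    if len(ages) < 2 or len(stresses) < 2:
        raise ParameterError("each factor needs at least two levels")
    for a in ages:
        for s in stresses:
            if ((df["age"] == a) & (df["stress"] == s)).sum() == 0:
                raise UnbalancedDesignError(f"empty design cell: age={a}, stress={s}")
    model = smf.ols("value ~ C(age) * C(stress)", data=df).fit()
    with np.errstate(divide="ignore", invalid="ignore"):
        table = sm.stats.anova_lm(model, typ=ss_type)
    resid_ss = float(table.loc["Residual", "sum_sq"])
    total_between = float(
        table.loc[[i for i in table.index if i != "Residual"], "sum_sq"].sum()
    )
    degenerate = resid_ss <= 1e-12 * max(total_between, 1.0)
    terms = {}
    for key, term in (
        ("age", "C(age)"),
        ("stress", "C(stress)"),
        ("interaction", "C(age):C(stress)"),
    ):
        ss_term = float(table.loc[term, "sum_sq"])
        f = float(table.loc[term, "F"])
        p = float(table.loc[term, "PR(>F)"])
        if degenerate:
            # zero residual variance: F is 0/0 for a null term, +inf otherwise
            f = 0.0 if ss_term <= 1e-12 * max(total_between, 1.0) else float("inf")
            p = float("nan")
        elif np.isnan(f):
            f, p = 0.0, 1.0
        terms[key] = {"F": f, "p": p}
    ns = tuple(
        int(((df["age"] == a) & (df["stress"] == s)).sum())
        for a in ages
        for s in stresses
    )
    return TestResult(
        test="two_way_anova",
        n=ns,
        terms=terms,
        degenerate=degenerate,
        note="zero within-cell variance" if degenerate else "",
    )


def mann_whitney_u(x, y) -> TestResult:
    """Mann-Whitney U with the min(U_x, U_y) reporting convention.

    p-value: exact enumeration when both samples have n <= 8 and no ties
    straddle the groups; otherwise the tie-corrected normal
    approximation (with continuity correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("both samples must be nonempty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = (
        "exact"
        if (max(x.size, y.size) <= EXACT_MWU_MAX_N and not has_ties)
        else "asymptotic"
    )
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u_x = float(res.statistic)
    u_y = x.size * y.size - u_x
    return TestResult(
        test="mann_whitney_u",
        statistic=min(u_x, u_y),
        pvalue=float(res.pvalue),
        n=(x.size, y.size),
        note=method,
    )


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H with tie correction and chi-square p.

    All-identical data across groups yields H = 0 (not an error).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ParameterError("need >= 2 nonempty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return TestResult(
            test="kruskal_wallis",
            statistic=0.0,
            pvalue=1.0,
            n=tuple(g.size for g in groups),
            note="all values tied",
        )
    res = sps.kruskal(*groups)
    return TestResult(
        test="kruskal_wallis",
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        n=tuple(g.size for g in groups),
    )


def ks_test(x, y) -> TestResult:
    """Two-sample Kolmogorov-Smirnov: D = max |eCDF_x - eCDF_y| with the
    asymptotic p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("both samples must be nonempty")
    res = sps.ks_2samp(x, y, method="asymp")
    return TestResult(
        test="ks_test",
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        n=(x.size, y.size),
    )


def pearson_r(x, y) -> TestResult:
    """Pearson correlation with a two-sided t-based p-value.

    Pairs with a missing value in either variable are dropped first.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ParameterError("samples must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ParameterError("need >= 3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("zero variance in a sample")
    res = sps.pearsonr(x, y)
    return TestResult(
        test="pearson_r",
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        n=(x.size,),
    )


def ecdf(values) -> list[tuple[float, float]]:
    """Right-continuous empirical CDF as ordered (value, fraction) pairs;
    the final fraction is 1."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ParameterError("ecdf of an empty sample")
    uniq, counts = np.unique(values, return_counts=True)
    fracs = np.cumsum(counts) / values.size
    return [(float(v), float(f)) for v, f in zip(uniq, fracs)]


#: Per-animal measures produced by the aggregation, in output order.
ANIMAL_MEASURES = (
    "microglial_volume",
    "n_microglia",
    "mean_soma_volume",
    "nonnuclear_gr_microglia",
    "nonnuclear_gr_astrocyte",
    "astrocyte_volume",
    "n_high_gr_nuclei",
)


def per_animal_summary(
    cells: list[CellRecord],
    image_summaries: list[ImageGRSummary],
    manifest: pd.DataFrame,
) -> pd.DataFrame:
    """Aggregate image-level measures to one row per animal.

    Each measure is averaged across the animal's images (per-cell soma
    volumes are first averaged within each image). Animals whose images
    contain zero classified microglia get NaN — not zero — for the
    microglia-conditional measures (soma volume).

    Raises
    ------
    ManifestError
        If an image id is missing from the manifest.
    """
    man = manifest.set_index("image_id")
    if man.index.has_duplicates:
        raise ManifestError("duplicate image ids in manifest")
    rows = []
    for s in image_summaries:
        if s.image_id not in man.index:
            raise ManifestError(f"image {s.image_id!r} not in manifest")
        m = man.loc[s.image_id]
        rows.append(
            {
                "image_id": s.image_id,
                "animal_id": m["animal_id"],
                "age": m["age"],
                "stress": m["stress"],
                "microglial_volume": s.microglial_volume,
                "astrocyte_volume": s.astrocyte_volume,
                "n_microglia": s.n_microglia,
                "n_high_gr_nuclei": s.n_high_gr_nuclei,
                "nonnuclear_gr_microglia": s.nonnuclear_gr_microglia,
                "nonnuclear_gr_astrocyte": s.nonnuclear_gr_astrocyte,
                "mean_soma_volume": s.mean_soma_volume,
            }
        )
    images = pd.DataFrame(rows)
    if images.empty:
        raise ParameterError("no image summaries supplied")
    grouped = images.groupby("animal_id")
    out = grouped[list(ANIMAL_MEASURES)].mean()
    out[["age", "stress"]] = grouped[["age", "stress"]].first()
    out["n_images"] = grouped.size()
    return out.reset_index()
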