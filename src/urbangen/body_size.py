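"""Body-size cline analysis: factorial ANOVA and least-squares-means contrasts.

Worker thorax width (mm) is modeled by ordinary least squares with species,
site, and their interaction as fixed categorical factors (sum-to-zero coding
so Type-III-style partial F tests are well defined under imbalance).
Least-squares means are model-predicted cell means; intraspecific site
contrasts are differences of LS means with t tests on the residual degrees
of freedom, judged against a Bonferroni-adjusted alpha of
``alpha / n_contrasts``.  Species x site cells with 15 or fewer measured
workers are excluded before fitting, and the input is expected to carry one
randomly chosen sister per colony.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "SizeAnalysisResult",
    "filter_size_cells",
    "fit_size_model",
    "intraspecific_contrasts",
    "analyze_body_size",
]

MIN_WORKERS_EXCLUSIVE = 15  # cells with <= this many measurements are excluded


@dataclass
class SizeAnalysisResult:
    anova: pd.DataFrame | None
    cell_means: pd.DataFrame  # species, site, n, lsmean, se
    contrasts: pd.DataFrame | None = None
    alpha_bonferroni: float | None = None
    excluded_cells: list[dict] = field(default_factory=list)
    residual_df: int = 0
    _model: object = field(default=None, repr=False)


def _as_frame(measurements) -> pd.DataFrame:
    df = pd.DataFrame(measurements)
    required = {"species", "site", "thorax_width"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")
    df = df.dropna(subset=["thorax_width"]).copy()
    df["species"] = df["species"].astype(str)
    df["site"] = df["site"].astype(str)
    return df


def filter_size_cells(
    measurements, min_workers: int = MIN_WORKERS_EXCLUSIVE
) -> tuple[pd.DataFrame, list[dict]]:
    """Remove species x site cells with <= ``min_workers`` measured workers.

    The boundary is inclusive: a cell of exactly 15 measurements is excluded
    at the default.  Returns the retained rows and the exclusion list.
    """
    df = _as_frame(measurements)
    if df.empty:
        return df, []
    counts = df.groupby(["species", "site"], sort=True).size()
    excluded = [
        {"species": sp, "site": si, "n": int(n), "reason": f"<= {min_workers} workers"}
        for (sp, si), n in counts.items()
        if n <= min_workers
    ]
    bad = {(e["species"], e["site"]) for e in excluded}
    keep = df[[tuple(x) not in bad for x in df[["species", "site"]].to_numpy()]]
    return keep.reset_index(drop=True), excluded


def fit_size_model(measurements) -> SizeAnalysisResult:
    """Two-way fixed-effects ANOVA of thorax width with LS cell means.

    The factorial model (sum coding, Type-III partial F tests) supplies the
    species / site / interaction ANOVA; LS means and their SEs come from the
    equivalent cell-means parameterization, whose coefficient covariance
    gives exact contrast SEs even when some cells are missing.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = _as_frame(measurements)
    if df["species"].nunique() < 2 or df["site"].nunique() < 2:
        raise ValueError("need >= 2 species and >= 2 sites after exclusions")

    anova = None
    try:
        factorial = smf.ols(
            "thorax_width ~ C(species, Sum) * C(site, Sum)", data=df
        ).fit()
        anova_tab = sm.stats.anova_lm(factorial, typ=3)
        anova = anova_tab.rename(
            index=lambda s: {
                "C(species, Sum)": "species",
                "C(site, Sum)": "site",
                "C(species, Sum):C(site, Sum)": "species:site",
            }.get(s, s)
        )
    except Exception:  # rank-deficient incomplete design: cells still usable
        anova = None

    df = df.copy()
    df["cell"] = df["species"] + "|" + df["site"]
    cell_model = smf.ols("thorax_width ~ C(cell) - 1", data=df).fit()
    rows = []
    names = list(cell_model.params.index)
    for name, beta in cell_model.params.items():
        cell = name[len("C(cell)[") : -1]
        species, site = cell.split("|", 1)
        idx = names.index(name)
        se = float(np.sqrt(cell_model.cov_params().iloc[idx, idx]))
        rows.append(
            {
                "species": species,
                "site": site,
                "n": int((df["cell"] == cell).sum()),
                "lsmean": float(beta),
                "se": se,
            }
        )
    cell_means = (
        pd.DataFrame(rows).sort_values(["species", "site"]).reset_index(drop=True)
    )
    return SizeAnalysisResult(
        anova=anova,
        cell_means=cell_means,
        residual_df=int(cell_model.df_resid),
        _model=cell_model,
    )


def intraspecific_contrasts(
    result: SizeAnalysisResult, alpha: float = 0.05
) -> SizeAnalysisResult:
    """All unordered same-species site contrasts of LS means, Bonferroni-held.

    Each contrast is a difference of two cell LS means with a t test on the
    model's residual degrees of freedom; ``alpha_bonferroni = alpha / n``
    with ``n`` the number of contrasts, compared at the exact (unrounded)
    threshold.  A species retained at a single site yields no contrasts.
    """
    from scipy import stats as sps

    model = result._model
    if model is None:
        raise ValueError("fit_size_model must be run first")
    cov = model.cov_params().to_numpy()
    params = model.params
    names = list(params.index)

    def cell_index(species: str, site: str) -> int:
        return names.index(f"C(cell)[{species}|{site}]")

    cells = result.cell_means[["species", "site"]].itertuples(index=False)
    by_species: dict[str, list[str]] = {}
    for species, site in cells:
        by_species.setdefault(species, []).append(site)
    contrast_rows = []
    for species in sorted(by_species):
        for site_a, site_b in combinations(sorted(by_species[species]), 2):
            ia, ib = cell_index(species, site_a), cell_index(species, site_b)
            vec = np.zeros(len(names))
            vec[ia], vec[ib] = 1.0, -1.0
            estimate = float(vec @ params.to_numpy())
            se = float(np.sqrt(vec @ cov @ vec))
            tval = estimate / se
            p = float(2.0 * sps.t.sf(abs(tval), result.residual_df))
            contrast_rows.append(
                {
                    "species": species,
                    "site_a": site_a,
                    "site_b": site_b,
                    "estimate": estimate,
                    "se": se,
                    "t": tval,
                    "p": p,
                }
            )
    contrasts = pd.DataFrame(
        contrast_rows,
        columns=["species", "site_a", "site_b", "estimate", "se", "t", "p"],
    )
    n_contrasts = len(contrasts)
    alpha_bonf = alpha / n_contrasts if n_contrasts else alpha
    if n_contrasts:
        contrasts["significant"] = contrasts["p"] < alpha_bonf
    result.contrasts = contrasts
    result.alpha_bonferroni = alpha_bonf
    return result


def analyze_body_size(
    measurements,
    min_workers: int = MIN_WORKERS_EXCLUSIVE,
    alpha: float = 0.05,
) -> SizeAnalysisResult:
    """Exclusion -> ANOVA -> LS means -> Bonferroni-corrected contrasts."""
    retained, excluded = filter_size_cells(measurements, min_workers)
    if retained.empty:
        raise ValueError("no cells retained after exclusions")
    result = fit_size_model(retained)
    result = intraspecific_contrasts(result, alpha)
    result.excluded_cells = excluded
    return result


def plot_body_size(measurements, ax=None, site_order=None):
    """Per-species strip/box plot of thorax widths across sites (optional)."""
    import matplotlib.pyplot as plt

    df = _as_frame(measurements)
    species_list = sorted(df["species"].unique())
    if ax is None:
        _, ax = plt.subplots(
            1, len(species_list), figsize=(3 * len(species_list), 3), squeeze=False
        )
        ax = ax[0]
    for k, species in enumerate(species_list):
        sub = df[df["species"] == species]
        sites = site_order or sorted(sub["site"].unique())
        data = [sub.loc[sub["site"] == s, "thorax_width"] for s in sites]
        ax[k].boxplot(data, tick_labels=sites)
        ax[k].set_title(species, fontsize=8)
        ax[k].set_ylabel("thorax width (mm)")
    return ax
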