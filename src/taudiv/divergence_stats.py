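"""Statistics on tau divergence: per-age-class correlations, decay
regressions with model comparison, group contrasts, Storey q-values,
same-tissue contingency counts and outgroup asymmetry.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDesignError, DimensionError, UndefinedCorrelationError
from .io_tables import TissueMap

logger = logging.getLogger(__name__)

MIN_PAIRS_PER_POINT = 3


@dataclass
class DivergencePoint:
    """One (age, correlation) observation entering the decay regressions."""

    age_my: float
    r: float
    n_pairs: int
    pair_class: str  # 'ortholog' | 'paralog'
    dataset_id: str = ""
    condition: str = "all_tissues"
    node_label: str = ""


@dataclass
class DecayFit:
    model: str  # 'linear' | 'log10'
    slope: float
    intercept: float
    slope_p: float
    rss: float


@dataclass
class ModelComparison:
    model_a: str
    model_b: str
    f_stat: float
    df: tuple[int, int]
    p_value: float
    preferred: str
    extra: dict = field(default_factory=dict)


def points_frame(points: list[DivergencePoint]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in points])


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------


def tau_correlation(
    pairs: pd.DataFrame,
    tau_ref: pd.DataFrame,
    tau_alt: pd.DataFrame,
    method: str = "pearson",
    dataset_id: str = "",
    condition: str = "all_tissues",
) -> DivergencePoint | None:
    """Correlation of tau across homolog pairs of one age class.

    ``pairs`` must carry a single age (one class); genes with undefined tau
    on either side are dropped.  Returns None (with a warning) when fewer
    than 3 usable pairs remain; raises UndefinedCorrelationError when one
    side has zero variance.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    if pairs.empty:
        logger.warning("tau_correlation: empty pair list")
        return None
    ages = pairs["age_my"].unique()
    if len(ages) != 1:
        raise ValueError("tau_correlation expects pairs of a single age class")
    x = pairs["gene_ref"].map(tau_ref["tau"]).to_numpy(dtype=float)
    y = pairs["gene_alt"].map(tau_alt["tau"]).to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < MIN_PAIRS_PER_POINT:
        logger.warning(
            "tau_correlation: only %d usable pairs at age %s — point dropped", n, ages[0]
        )
        return None
    x, y = x[ok], y[ok]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in tau on one side of the pairs")
    if method == "pearson":
        r = stats.pearsonr(x, y).statistic
    else:
        r = stats.spearmanr(x, y).statistic
    node = pairs["node_label"].iloc[0] if "node_label" in pairs else ""
    cls = pairs["pair_class"].iloc[0] if "pair_class" in pairs else ""
    return DivergencePoint(
        age_my=float(ages[0]), r=float(r), n_pairs=n, pair_class=cls,
        dataset_id=dataset_id, condition=condition, node_label=str(node),
    )


# ---------------------------------------------------------------------------
# Decay regression and model comparison
# ---------------------------------------------------------------------------


def _ols(y: np.ndarray, X: np.ndarray):
    return sm.OLS(y, sm.add_constant(X)).fit()


def fit_decay(points: list[DivergencePoint], alpha: float = 0.05) -> dict:
    """Fit r ~ age and r ~ log10(age) and compare the two decay shapes.

    Both single-predictor fits are returned together with two comparisons:
    the residual-sum-of-squares preference between the equally-parameterised
    models, and (default criterion) the added-variable F-test of log10(age)
    entering on top of the linear term.  ``preferred`` is 'log10' only when
    the added-variable test rejects at ``alpha``; otherwise 'linear'.
    """
    if len(points) < 4:
        raise DimensionError(f"fit_decay needs >= 4 points, got {len(points)}")
    age = np.array([p.age_my for p in points], dtype=float)
    r = np.array([p.r for p in points], dtype=float)
    if np.ptp(age) == 0:
        raise DegenerateDesignError("all divergence ages identical")
    if (age <= 0).any():
        raise ValueError("ages must be positive for the log10 model")

    lin = _ols(r, age[:, None])
    logfit = _ols(r, np.log10(age)[:, None])

    fits = {
        "linear": DecayFit("linear", float(lin.params[1]), float(lin.params[0]),
                           float(lin.pvalues[1]), float(lin.ssr)),
        "log10": DecayFit("log10", float(logfit.params[1]), float(logfit.params[0]),
                          float(logfit.pvalues[1]), float(logfit.ssr)),
    }

    rss_preferred = "log10" if logfit.ssr < lin.ssr else "linear"

    n_distinct = len(np.unique(age))
    if n_distinct >= 3 and len(points) >= 4:
        both = _ols(r, np.column_stack([age, np.log10(age)]))
        df_num, df_den = 1, int(both.df_resid)
        f_stat = (lin.ssr - both.ssr) / (both.ssr / both.df_resid) if both.ssr > 0 else np.inf
        p_value = float(stats.f.sf(f_stat, df_num, df_den))
    else:
        # age and log10(age) are collinear with < 3 distinct ages
        f_stat, p_value, df_num, df_den = np.nan, np.nan, 1, 0
    preferred = "log10" if (np.isfinite(p_value) and p_value < alpha) else "linear"

    comparison = ModelComparison(
        model_a="r ~ age",
        model_b="r ~ age + log10(age)",
        f_stat=float(f_stat),
        df=(df_num, df_den),
        p_value=p_value,
        preferred=preferred,
        extra={"rss_preferred": rss_preferred,
               "rss_linear": float(lin.ssr), "rss_log10": float(logfit.ssr)},
    )
    return {"linear": fits["linear"], "log10": fits["log10"], "comparison": comparison}


def compare_groups(
    points_a: list[DivergencePoint],
    points_b: list[DivergencePoint],
    label_a: str = "a",
    label_b: str = "b",
) -> ModelComparison:
    """Nested F-test for a group offset: r ~ age vs r ~ age + group.

    Used both for the ortholog-vs-paralog contrast and for condition
    effects (e.g. tau computed with vs without the testis).
    """
    if not points_a or not points_b:
        raise DimensionError("compare_groups requires two non-empty groups")
    age = np.array([p.age_my for p in points_a + points_b], dtype=float)
    r = np.array([p.r for p in points_a + points_b], dtype=float)
    group = np.array([0.0] * len(points_a) + [1.0] * len(points_b))
    if np.ptp(age) == 0 and len(np.unique(group)) < 2:
        raise DegenerateDesignError("degenerate combined design")
    if len(age) < 4:
        raise DimensionError("compare_groups needs >= 4 points in total")

    small = _ols(r, age[:, None])
    big = _ols(r, np.column_stack([age, group]))
    if big.df_resid <= 0:
        raise DegenerateDesignError("no residual degrees of freedom")
    if big.ssr <= 0:
        f_stat = math.inf if small.ssr > 0 else 0.0
        p_value = 0.0 if small.ssr > 0 else 1.0
    else:
        f_stat = (small.ssr - big.ssr) / (big.ssr / big.df_resid)
        p_value = float(stats.f.sf(f_stat, 1, int(big.df_resid)))
    effect = float(big.params[2])
    preferred = f"with_{label_b}_offset" if p_value < 0.05 else "common"
    return ModelComparison(
        model_a=f"r ~ age  ({label_a} + {label_b} pooled)",
        model_b=f"r ~ age + is_{label_b}",
        f_stat=float(f_stat),
        df=(1, int(big.df_resid)),
        p_value=p_value,
        preferred=preferred,
        extra={"group_effect": effect},
    )


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------


def estimate_pi0(p, lambda_: float = 0.5) -> float:
    """Point estimate of the true-null proportion: #{p > lambda} / (m (1-lambda))."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    pi0 = (p > lambda_).mean() / (1.0 - lambda_)
    return float(min(pi0, 1.0))


def qvalues(p, lambda_: float = 0.5) -> np.ndarray:
    """Storey q-values: pi0 (fixed-lambda estimate) times the BH-adjusted p.

    Monotone non-decreasing in sorted p and bounded by 1.  With small
    batteries the fixed-lambda pi0 can reach 0, which propagates to the
    q-values; callers comparing against a q threshold should keep that
    degenerate case in mind.
    """
    p = np.asarray(p, dtype=float)
    pi0 = estimate_pi0(p, lambda_=lambda_)
    bh = multipletests(p, method="fdr_bh")[1]
    return pi0 * bh


# ---------------------------------------------------------------------------
# Same-tissue contingency
# ---------------------------------------------------------------------------


def same_tissue_counts(
    pairs: pd.DataFrame,
    tau_ref: pd.DataFrame,
    tau_alt: pd.DataFrame,
    tissue_map: TissueMap | None = None,
    species_ref: str = "",
    species_alt: str = "",
    threshold: float = 0.8,
) -> pd.DataFrame:
    """Count both-specific pairs by whether their main tissues agree.

    Specificity is re-evaluated at ``threshold`` from the stored tau values
    (plus any testis-forced calls).  Main tissues are translated to
    canonical labels through ``tissue_map`` when given (needed across
    species); pairs whose tissue is unmapped are excluded and counted.
    Returns one row per (node_label, age class) with n_same, n_different,
    n_excluded;  n_same + n_different + n_excluded = number of
    both-specific pairs.
    """

    def spec_mask(table: pd.DataFrame, genes: pd.Series) -> np.ndarray:
        tau = genes.map(table["tau"]).to_numpy(dtype=float)
        forced = genes.map(table.get("testis_forced", pd.Series(dtype=bool))).fillna(False)
        return (np.isfinite(tau) & (tau >= threshold)) | forced.to_numpy(dtype=bool)

    if pairs.empty:
        return pd.DataFrame(
            columns=["node_label", "age_my", "pair_class", "n_same", "n_different", "n_excluded"]
        )

    both = spec_mask(tau_ref, pairs["gene_ref"]) & spec_mask(tau_alt, pairs["gene_alt"])
    sub = pairs.loc[both].copy()
    t_ref = sub["gene_ref"].map(tau_ref["max_tissue"])
    t_alt = sub["gene_alt"].map(tau_alt["max_tissue"])
    if tissue_map is not None:
        t_ref = t_ref.map(lambda t: tissue_map.canonical(species_ref, t))
        t_alt = t_alt.map(lambda t: tissue_map.canonical(species_alt, t))
    sub["_excluded"] = t_ref.isna() | t_alt.isna()
    sub["_same"] = (t_ref == t_alt) & ~sub["_excluded"]

    out = []
    for (node, age, cls), grp in sub.groupby(["node_label", "age_my", "pair_class"], sort=True):
        n_exc = int(grp["_excluded"].sum())
        n_same = int(grp["_same"].sum())
        out.append(
            {
                "node_label": node,
                "age_my": float(age),
                "pair_class": cls,
                "n_same": n_same,
                "n_different": len(grp) - n_same - n_exc,
                "n_excluded": n_exc,
            }
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Outgroup asymmetry
# ---------------------------------------------------------------------------


def outgroup_asymmetry(
    triplets: pd.DataFrame,
    tau_focal: pd.DataFrame,
    tau_outgroup: dict[str, pd.DataFrame],
    method: str = "pearson",
    condition: str = "all_tissues",
) -> pd.DataFrame:
    """Correlation with the unduplicated outgroup, per paralog role.

    For each duplication age class, correlates tau of the higher-expressed
    (major) and lower-expressed (minor) paralog separately against tau of
    the outgroup co-ortholog.  Returns one row per (age class, role) with
    r and n; classes with fewer than 3 usable triplets are dropped with a
    warning.
    """
    rows = []
    if triplets.empty:
        return pd.DataFrame(columns=["node_label", "age_my", "role", "r", "n"])
    for (node, age), grp in triplets.groupby(["node_label", "age_my"], sort=True):
        out_tau = np.array(
            [
                tau_outgroup[sp]["tau"].get(g, np.nan)
                for g, sp in zip(grp["outgroup_gene"], grp["outgroup_species"])
            ],
            dtype=float,
        )
        for role, col in (("major", "gene_ref"), ("minor", "gene_alt")):
            par_tau = grp[col].map(tau_focal["tau"]).to_numpy(dtype=float)
            ok = np.isfinite(par_tau) & np.isfinite(out_tau)
            if ok.sum() < MIN_PAIRS_PER_POINT:
                logger.warning(
                    "outgroup_asymmetry: %s at %s has %d usable triplets — dropped",
                    role, node, int(ok.sum()),
                )
                continue
            x, y = par_tau[ok], out_tau[ok]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                raise UndefinedCorrelationError(
                    f"zero tau variance for {role} paralogs at {node}"
                )
            if method == "pearson":
                r = stats.pearsonr(x, y).statistic
            else:
                r = stats.spearmanr(x, y).statistic
            rows.append(
                {
                    "node_label": node,
                    "age_my": float(age),
                    "role": role,
                    "r": float(r),
                    "n": int(ok.sum()),
                    "condition": condition,
                }
            )
    return pd.DataFrame(rows)
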