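"""Unsupervised feature extraction from the decomposed tensor.

The screen proceeds in four steps:

1. identify the dose-mode component that tracks the dose gradient
   (empirically the second component, varying almost linearly with dose);
2. optionally screen the matching core-tensor slice for exceptionally large
   couplings, scoring (G / sigma_G)^2 against a 1-df chi-squared null
   (reported as a diagnostic — the list it yields is typically far too long
   to drive feature extraction directly);
3. truncate the compound and gene modes at the smallest K whose leading
   (D, K, K) core block carries at least 95% of the tensor energy;
4. score every compound j by S_j = sum_{k<=K} (x_{k,j}/sigma_k)^2 and every
   gene likewise, attach upper-tail chi-squared(K) P-values, adjust by
   Benjamini-Hochberg, and select items with adjusted P below the threshold.

The statistics divide loadings by the per-component standard deviation
without subtracting the mean — the fidelity choice matching the method as
published; see the methods note for its consequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError
from .hosvd import HOSVDResult, cumulative_contribution

logger = logging.getLogger(__name__)


@dataclass
class DoseComponentReport:
    """Correlation of each dose-mode component with the dose covariate."""

    correlations: np.ndarray  # NaN where undefined (zero-variance component)
    chosen_k1: int  # 1-based
    covariate: str
    covariate_values: np.ndarray
    overridden: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": np.arange(1, len(self.correlations) + 1),
                "pearson_r": self.correlations,
                "chosen": np.arange(1, len(self.correlations) + 1) == self.chosen_k1,
            }
        )


@dataclass
class CoreScreenResult:
    """Chi-squared screen of the dose-component core slice G[k1*, :, :]."""

    k1: int
    sigma_g: float
    table: pd.DataFrame  # columns: k2, k3, G, statistic, p, p_adj, significant
    threshold: float

    @property
    def significant_pairs(self) -> list[tuple[int, int]]:
        sig = self.table[self.table["significant"]]
        return list(zip(sig["k2"].astype(int), sig["k3"].astype(int)))


@dataclass
class SelectionResult:
    """Inferred compounds and genes with their chi-squared scores."""

    K2: int
    K3: int
    compound_table: pd.DataFrame  # columns: compound, S, p, p_adj, selected
    gene_table: pd.DataFrame  # columns: gene, S, p, p_adj, selected
    sigma_k2: np.ndarray
    sigma_k3: np.ndarray
    threshold: float
    dose_report: DoseComponentReport | None = None

    @property
    def selected_compounds(self) -> list[str]:
        t = self.compound_table
        return list(t.loc[t["selected"], "compound"])

    @property
    def selected_genes(self) -> list[str]:
        t = self.gene_table
        return list(t.loc[t["selected"], "gene"])


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    Accepts values in [0, 1] (0 can arise from tail underflow).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def find_dose_component(
    result: HOSVDResult,
    doses,
    override: int | None = None,
    covariate: str = "index",
) -> DoseComponentReport:
    """Pick the dose-mode component most correlated with the dose gradient.

    ``covariate`` is ``"index"`` (1..D, the default — dose conditions are
    roughly geometrically spaced so the index is the natural linear scale) or
    ``"log_dose"``.  Components whose unfolding singular value is numerically
    zero, or whose loadings have zero variance, are skipped (correlation NaN).
    """
    doses = np.asarray(doses, dtype=float)
    d = len(doses)
    if d < 3:
        raise ValueError("need at least three dose levels")
    if covariate == "index":
        cov = np.arange(1, d + 1, dtype=float)
    elif covariate == "log_dose":
        cov = np.log10(doses)
    else:
        raise ValueError(f"unknown covariate {covariate!r}")
    if np.ptp(cov) == 0:
        raise DegenerateInputError("dose covariate is constant")

    fdose = result.factor_dose
    sv = result.singular_values[0]
    tol = max(sv[0], 1.0) * 1e-12 if sv.size else 0.0
    corrs = np.full(fdose.shape[0], np.nan)
    for k in range(fdose.shape[0]):
        if sv[k] <= tol or np.std(fdose[k]) <= 1e-12:
            continue
        corrs[k] = np.corrcoef(fdose[k], cov)[0, 1]

    if override is not None:
        if not 1 <= override <= fdose.shape[0]:
            raise ValueError(f"override component {override} out of range")
        return DoseComponentReport(corrs, override, covariate, cov, overridden=True)
    if np.all(np.isnan(corrs)):
        raise DegenerateInputError("no dose component has a defined dose correlation")
    chosen = int(np.nanargmax(np.abs(corrs))) + 1
    return DoseComponentReport(corrs, chosen, covariate, cov)


def screen_core(
    result: HOSVDResult, k1_star: int, threshold: float = 0.01
) -> CoreScreenResult:
    """Score core couplings G[k1*, k2, k3] as (G/sigma_G)^2 against chi-squared(1)."""
    if not 1 <= k1_star <= result.core.shape[0]:
        raise ValueError(f"k1_star={k1_star} out of range")
    g = result.core[k1_star - 1]
    sigma = float(g.std(ddof=1))
    if sigma == 0.0:
        raise DegenerateInputError("core slice has zero standard deviation")
    stat = (g / sigma) ** 2
    p = stats.chi2.sf(stat, df=1)
    p_adj = bh_adjust(p.ravel()).reshape(p.shape)
    k2, k3 = np.meshgrid(
        np.arange(1, g.shape[0] + 1), np.arange(1, g.shape[1] + 1), indexing="ij"
    )
    table = pd.DataFrame(
        {
            "k2": k2.ravel(),
            "k3": k3.ravel(),
            "G": g.ravel(),
            "statistic": stat.ravel(),
            "p": p.ravel(),
            "p_adj": p_adj.ravel(),
            "significant": p_adj.ravel() < threshold,
        }
    )
    return CoreScreenResult(k1=k1_star, sigma_g=sigma, table=table, threshold=threshold)


def choose_truncation(
    result: HOSVDResult,
    default_K: int = 6,
    K_max: int | None = None,
    contribution_threshold: float = 0.95,
    override: int | None = None,
) -> tuple[int, int]:
    """Pick the compound/gene truncation (K2, K3), tied to a single K.

    The smallest K in [default_K, K_max] whose leading (D, K, K) core block
    reaches the contribution threshold is used; if none does, K_max is used
    with a warning.  ``override`` pins K directly (e.g. the K=8 exception some
    cell lines need when higher components still carry non-negligible energy).
    """
    d1, d2, d3 = result.core.shape
    cap = min(d2, d3)
    if override is not None:
        if not 1 <= override <= cap:
            raise ValueError(f"override K={override} outside 1..{cap}")
        return override, override
    k_lo = min(default_K, cap)
    k_hi = min(K_max if K_max is not None else max(8, k_lo), cap)
    if k_hi < k_lo:
        raise ValueError(f"K_max={K_max} below default_K={default_K}")
    for K in range(k_lo, k_hi + 1):
        if cumulative_contribution(result, d1, K, K) >= contribution_threshold:
            return K, K
    logger.warning(
        "cumulative contribution below %.2f up to K=%d; using K=%d",
        contribution_threshold,
        k_hi,
        k_hi,
    )
    return k_hi, k_hi


def score_mode(factor: np.ndarray, K: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Chi-squared score of each item from its first K component loadings.

    ``factor`` is (components x items).  Returns (S, raw P, per-component sd),
    where S_item = sum_{k<=K} (loading[k,item]/sd_k)^2 and P is the upper tail
    of chi-squared with K degrees of freedom.
    """
    factor = np.asarray(factor, dtype=float)
    if not 1 <= K <= factor.shape[0]:
        raise ValueError(f"K={K} outside 1..{factor.shape[0]}")
    if factor.shape[1] < 2:
        raise ValueError("need at least two items to define a standard deviation")
    sub = factor[:K]
    sd = sub.std(axis=1, ddof=1)
    if np.any(sd == 0):
        raise DegenerateInputError("a component has zero loading variance")
    s = ((sub / sd[:, None]) ** 2).sum(axis=0)
    return s, stats.chi2.sf(s, df=K), sd


def select_features(
    result: HOSVDResult,
    doses,
    compound_ids,
    gene_ids,
    threshold: float = 0.01,
    k1_override: int | None = None,
    dose_covariate: str = "index",
    default_K: int = 6,
    K_max: int | None = None,
    contribution_threshold: float = 0.95,
    K_override: int | None = None,
    K2: int | None = None,
    K3: int | None = None,
) -> SelectionResult:
    """Full feature-extraction pass: dose component, truncation, scoring, BH.

    ``K2``/``K3`` decouple the two truncations if explicitly given; otherwise
    both equal the single K from :func:`choose_truncation`.
    """
    report = find_dose_component(result, doses, override=k1_override, covariate=dose_covariate)
    k2, k3 = choose_truncation(
        result, default_K=default_K, K_max=K_max,
        contribution_threshold=contribution_threshold, override=K_override,
    )
    if K2 is not None:
        k2 = K2
    if K3 is not None:
        k3 = K3

    s_c, p_c, sd_c = score_mode(result.factor_compound, k2)
    s_g, p_g, sd_g = score_mode(result.factor_gene, k3)
    adj_c = bh_adjust(p_c)
    adj_g = bh_adjust(p_g)

    def _mask(adj):
        # threshold >= 1 disables filtering (adjusted P is capped at 1)
        return adj < threshold if threshold < 1 else adj <= 1

    compound_table = pd.DataFrame(
        {
            "compound": list(compound_ids),
            "S": s_c,
            "p": p_c,
            "p_adj": adj_c,
            "selected": _mask(adj_c),
        }
    )
    gene_table = pd.DataFrame(
        {
            "gene": list(gene_ids),
            "S": s_g,
            "p": p_g,
            "p_adj": adj_g,
            "selected": _mask(adj_g),
        }
    )
    return SelectionResult(
        K2=k2,
        K3=k3,
        compound_table=compound_table,
        gene_table=gene_table,
        sigma_k2=sd_c,
        sigma_k3=sd_g,
        threshold=threshold,
        dose_report=report,
    )
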