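"""Validation of predicted targets and supporting analytic statistics.

Predicted target lists are compared with independently curated drug-target
references by a Fisher exact test over a genome-wide background (20,000 genes
by default, an approximate human gene count).  A random-gene-set negative
control checks that enrichment hits do not arise from non-biological
structure in the library.  The module also provides the analytic minimal
Pearson correlation needed to reach a given significance level at a given
sample size — the figure that shows why per-pair correlation testing is
hopeless with only six dose points while the decomposition-based screen is
not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import enrich_gene_sets, fisher_exact_2x2
from .io import GeneSetLibrary

STATUS_SIGNIFICANT = "significant"  # the table's "o" mark
STATUS_NOT_SIGNIFICANT = "not_significant"  # "x"
STATUS_NO_DATA = "no_data"  # "-"


@dataclass
class OverlapValidation:
    """One compound's predicted-vs-known target contingency test."""

    compound: str
    table: tuple[int, int, int, int]  # (both, predicted only, known only, neither)
    p: float
    significant: bool
    status: str


def overlap_test(
    predicted,
    known,
    background: int = 20000,
    sided: str = "two",
    alpha: float = 0.05,
    compound: str = "",
) -> OverlapValidation:
    """Fisher test of the overlap between predicted and known target sets.

    An empty known list yields the no-data status (reference databases cover
    only some compounds).  ``background`` is the assumed total gene count.
    """
    predicted = set(g.upper() for g in predicted)
    known = set(g.upper() for g in known)
    if not known:
        return OverlapValidation(compound, (0, len(predicted), 0, 0), float("nan"), False, STATUS_NO_DATA)
    if not predicted:
        raise ValueError("predicted set is empty")
    union = len(predicted | known)
    if background < union:
        raise ValueError(f"background={background} smaller than union size {union}")
    a = len(predicted & known)
    b = len(predicted - known)
    c = len(known - predicted)
    d = background - a - b - c
    p = fisher_exact_2x2(a, b, c, d, sided=sided)
    sig = p < alpha
    return OverlapValidation(
        compound, (a, b, c, d), p,
        sig, STATUS_SIGNIFICANT if sig else STATUS_NOT_SIGNIFICANT,
    )


def validate_targets(
    predicted_by_compound: dict[str, list[str]],
    reference,
    background: int = 20000,
    sided: str = "two",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-compound validation table with significant / not_significant / no_data status."""
    rows = []
    for compound, predicted in predicted_by_compound.items():
        known = reference.get(compound) if hasattr(reference, "get") else None
        v = overlap_test(
            predicted, known or [], background=background, sided=sided,
            alpha=alpha, compound=compound,
        )
        a, b, c, d = v.table
        rows.append((compound, a, b, c, d, v.p, v.status))
    return pd.DataFrame(
        rows,
        columns=["compound", "both", "predicted_only", "known_only", "neither", "p", "status"],
    )


def random_set_control(
    universe,
    library: GeneSetLibrary,
    set_size: int = 50,
    trials: int = 100,
    cutoff: float = 1e-4,
    universe_size: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Enrichment of randomly drawn gene sets — the negative control.

    Each trial draws ``set_size`` genes uniformly without replacement and
    records the library sets whose BH-adjusted P falls below ``cutoff``
    (default 1e-4, i.e. 1e-2 Bonferroni-shared across 100 repeat uploads).
    Returns a per-trial table with the minimum adjusted P and the hit sets.
    """
    universe = list(universe)
    if set_size > len(universe):
        raise ValueError("set_size exceeds universe size")
    rng = np.random.default_rng(seed)
    rows = []
    for trial in range(trials):
        draw = rng.choice(universe, size=set_size, replace=False)
        enr = enrich_gene_sets(draw, library, universe_size=universe_size)
        hits = enr.table.loc[enr.table["p_adj"] < cutoff, "set"]
        rows.append(
            (trial, float(enr.table["p_adj"].min()), len(hits), ";".join(hits))
        )
    return pd.DataFrame(rows, columns=["trial", "min_p_adj", "n_hits", "hit_sets"])


def pcc_significance_threshold(n: int, alpha: float, sided: str = "one") -> float:
    """Smallest |r| whose correlation-test P-value reaches ``alpha``.

    Inverts the exact t test for a Pearson correlation,
    t = r sqrt(n-2) / sqrt(1-r^2) with n-2 degrees of freedom.  With n = 6
    dose points, reaching alpha = 1e-7 (a multiple-testing-proof level for a
    screen of this size) requires |r| >= 0.9996 one-sided (0.9997 two-sided).
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if sided == "one":
        tail = alpha
    elif sided == "two":
        tail = alpha / 2
    else:
        raise ValueError(f"sided must be 'one' or 'two', got {sided!r}")
    df = n - 2
    t_crit = stats.t.isf(tail, df)
    if t_crit <= 0:  # alpha at or beyond the median: r = 0 already suffices
        return 0.0
    return float(t_crit / np.sqrt(df + t_crit**2))
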