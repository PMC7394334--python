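"""Drug-target inference by gene-set enrichment of the dose-dependent genes.

Each library set is named after a perturbed gene or hub protein; a set whose
members are over-represented among the selected genes marks its *name* as a
predicted target protein.  Enrichment uses the one-sided Fisher exact test on
the 2x2 membership table with Benjamini-Hochberg adjustment across sets.

Cross-cell-line intersection of predictions is supported, together with the
closed-form expected size of a random intersection, N * (m/N)^C, used to argue
that a non-trivial common-target set cannot arise by chance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSetLibrary
from .selection import SelectionResult, bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    """Per-set Fisher enrichment of a selected-gene list against a library."""

    table: pd.DataFrame  # set, overlap, set_size, selected_size, universe, p, p_adj
    universe_size: int
    library_name: str


@dataclass
class TargetPrediction:
    """Gene-set names passing the enrichment threshold, read as target proteins."""

    targets: list[str]
    enrichment: EnrichmentResult
    library_name: str
    threshold: float


def fisher_exact_2x2(a: int, b: int, c: int, d: int, sided: str = "one") -> float:
    """Fisher exact P for the table [[a, b], [c, d]].

    ``sided="one"`` is the enrichment-direction upper tail P(X >= a) of the
    hypergeometric with margins fixed; ``"two"`` sums all tables at most as
    probable as the observed one.  A zero margin carries no information and
    returns P = 1 with a warning.
    """
    counts = (a, b, c, d)
    if any(x < 0 for x in counts):
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    if n == 0 or min(a + b, c + d, a + c, b + d) == 0:
        warnings.warn("degenerate 2x2 table (zero margin); returning P = 1")
        return 1.0
    if sided == "one":
        return float(stats.hypergeom.sf(a - 1, n, a + b, a + c))
    if sided == "two":
        return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    raise ValueError(f"sided must be 'one' or 'two', got {sided!r}")


def enrich_gene_sets(
    selected_genes: Iterable[str],
    library: GeneSetLibrary,
    universe_size: int | None = None,
    sided: str = "one",
) -> EnrichmentResult:
    """Fisher enrichment of each library set in the selected genes.

    The background defaults to the union of library genes and the selected
    list; pass e.g. ``universe_size=20000`` to use a genome-wide background.
    """
    if len(library) == 0:
        raise ValueError("empty gene-set library")
    selected = set(g.upper() for g in selected_genes)
    if not selected:
        raise ValueError("no selected genes supplied")
    implied = library.all_genes() | selected
    if library.universe is not None:
        implied |= set(library.universe)
    n_universe = universe_size if universe_size is not None else len(implied)
    if n_universe < len(implied):
        raise ValueError(
            f"universe_size={n_universe} smaller than the {len(implied)} genes involved"
        )

    rows = []
    for set_name, members in library.sets.items():
        mem = set(members)
        a = len(mem & selected)
        b = len(mem) - a
        c = len(selected) - a
        d = n_universe - a - b - c
        p = fisher_exact_2x2(a, b, c, d, sided=sided)
        rows.append((set_name, a, len(mem), len(selected), p))
    table = pd.DataFrame(
        rows, columns=["set", "overlap", "set_size", "selected_size", "p"]
    )
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    table["universe"] = n_universe
    return EnrichmentResult(table=table, universe_size=n_universe, library_name=library.name)


def predict_targets(
    selection: SelectionResult | Iterable[str],
    library: GeneSetLibrary,
    threshold: float = 0.01,
    universe_size: int | None = None,
    sided: str = "one",
) -> TargetPrediction:
    """Predicted targets = set names with BH-adjusted enrichment P below threshold.

    ``selection`` may be a :class:`SelectionResult` or a plain gene list.
    An empty selection yields an empty prediction with a warning.
    """
    genes = (
        selection.selected_genes
        if isinstance(selection, SelectionResult)
        else list(selection)
    )
    if not genes:
        warnings.warn("no selected genes; returning empty target prediction")
        empty = pd.DataFrame(
            columns=["set", "overlap", "set_size", "selected_size", "p", "p_adj", "universe"]
        )
        return TargetPrediction(
            targets=[],
            enrichment=EnrichmentResult(empty, universe_size or 0, library.name),
            library_name=library.name,
            threshold=threshold,
        )
    enr = enrich_gene_sets(genes, library, universe_size=universe_size, sided=sided)
    # threshold >= 1 disables filtering (adjusted P is capped at 1)
    mask = enr.table["p_adj"] < threshold if threshold < 1 else enr.table["p_adj"] <= 1
    hits = enr.table.loc[mask, "set"]
    return TargetPrediction(
        targets=list(hits), enrichment=enr, library_name=library.name, threshold=threshold
    )


def intersect_targets(
    predictions: Sequence[TargetPrediction | Iterable[str]],
    min_cell_lines: int | None = None,
) -> list[str]:
    """Target symbols predicted in at least ``min_cell_lines`` lists (default: all)."""
    if not predictions:
        raise ValueError("need at least one prediction")
    lists = [
        set(p.targets) if isinstance(p, TargetPrediction) else set(p) for p in predictions
    ]
    need = len(lists) if min_cell_lines is None else min_cell_lines
    counts: dict[str, int] = {}
    for s in lists:
        for t in s:
            counts[t] = counts.get(t, 0) + 1
    return sorted(t for t, c in counts.items() if c >= need)


def expected_common_overlap(N: int, m: float, C: int) -> float:
    """Expected size of the intersection of C independent random m-subsets of N.

    Each of the N items survives all C draws with probability (m/N)^C, so the
    expectation is N * (m/N)^C — essentially zero already for moderate C when
    m < N, which is the yardstick against which an observed common-target
    count is judged.
    """
    if C < 1:
        raise ValueError("C must be >= 1")
    if not 0 <= m <= N:
        raise ValueError(f"m must lie in [0, N], got m={m}, N={N}")
    if N == 0:
        return 0.0
    return float(N * (m / N) ** C)
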