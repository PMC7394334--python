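"""Model/Results facade over the decomposition-and-selection pipeline.

``DoseResponseScreen`` plays the role of a statsmodels-style model object:
it is constructed from a complete expression tensor (or built from a long
table / DataFrame), holds the screening configuration, and ``fit()`` returns
a ``DoseResponseResults`` carrying the decomposition, the dose-component
diagnostics, the core screen, and the inferred compounds and genes, with a
``summary()`` table and target-prediction / serialization methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as tdio
from .hosvd import HOSVDResult, cumulative_contribution, hosvd
from .enrichment import TargetPrediction, predict_targets
from .io import ExpressionTensor, GeneSetLibrary
from .selection import (
    CoreScreenResult,
    SelectionResult,
    find_dose_component,
    screen_core,
    select_features,
)


class DoseResponseScreen:
    """Dose-dependence screen of a compound-perturbation expression tensor.

    Parameters
    ----------
    tensor
        Complete dose x compound x gene :class:`ExpressionTensor`.
    dose_covariate
        ``"index"`` or ``"log_dose"``; the covariate the dose-mode components
        are correlated against.
    k1_override
        Pin the dose-dependence component (e.g. 2) instead of auto-detection.
    default_K, K_max, contribution_threshold, K_override
        Truncation rule for the compound and gene modes.
    selection_threshold
        BH-adjusted P cutoff for inferred compounds and genes.
    """

    def __init__(
        self,
        tensor: ExpressionTensor,
        dose_covariate: str = "index",
        k1_override: int | None = None,
        default_K: int = 6,
        K_max: int | None = None,
        contribution_threshold: float = 0.95,
        K_override: int | None = None,
        selection_threshold: float = 0.01,
        gene_center: bool = False,
    ):
        if gene_center:
            centered = tensor.values - tensor.values.mean(axis=(0, 1), keepdims=True)
            tensor = ExpressionTensor(
                centered, tensor.dose_levels, tensor.compound_ids, tensor.gene_ids
            )
        self.tensor = tensor
        self.dose_covariate = dose_covariate
        self.k1_override = k1_override
        self.default_K = default_K
        self.K_max = K_max
        self.contribution_threshold = contribution_threshold
        self.K_override = K_override
        self.selection_threshold = selection_threshold
        self.gene_center = gene_center

    @classmethod
    def from_long_table(cls, path, cell_line: str, mapping=None, **kwargs):
        records = tdio.read_long_table(path, mapping=mapping)
        return cls(tdio.build_tensor(records, cell_line), **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, cell_line: str, **kwargs):
        """Build from a long-format DataFrame with the standard column names."""
        records = [
            tdio.ExpressionRecord(
                cell_line=str(r.cell_line),
                compound=str(r.compound),
                dose=float(r.dose),
                gene=str(r.gene),
                expression=float(r.expression),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(tdio.build_tensor(records, cell_line), **kwargs)

    def fit(self) -> "DoseResponseResults":
        decomposition = hosvd(self.tensor)
        selection = select_features(
            decomposition,
            self.tensor.dose_levels,
            self.tensor.compound_ids,
            self.tensor.gene_ids,
            threshold=self.selection_threshold,
            k1_override=self.k1_override,
            dose_covariate=self.dose_covariate,
            default_K=self.default_K,
            K_max=self.K_max,
            contribution_threshold=self.contribution_threshold,
            K_override=self.K_override,
        )
        core = screen_core(decomposition, selection.dose_report.chosen_k1)
        return DoseResponseResults(
            model=self, hosvd=decomposition, selection=selection, core_screen=core
        )


@dataclass
class DoseResponseResults:
    """Fitted screen: decomposition, diagnostics and the inferred feature sets."""

    model: DoseResponseScreen
    hosvd: HOSVDResult
    selection: SelectionResult
    core_screen: CoreScreenResult
    predictions: dict[str, TargetPrediction] = field(default_factory=dict)

    @property
    def inferred_compounds(self) -> list[str]:
        return self.selection.selected_compounds

    @property
    def inferred_genes(self) -> list[str]:
        return self.selection.selected_genes

    def predict_targets(
        self, library: GeneSetLibrary, threshold: float = 0.01, universe_size=None
    ) -> TargetPrediction:
        pred = predict_targets(
            self.selection, library, threshold=threshold, universe_size=universe_size
        )
        self.predictions[library.name] = pred
        return pred

    def summary(self) -> str:
        t = self.model.tensor
        rep = self.selection.dose_report
        d, j, l = t.shape
        contrib = cumulative_contribution(
            self.hosvd, d, self.selection.K2, self.selection.K3
        )
        lines = [
            "Dose-response tensor screen",
            "=" * 60,
            f"tensor shape (dose, compound, gene): ({d}, {j}, {l})",
            f"dose levels: {', '.join(f'{x:g}' for x in t.dose_levels)}",
            f"dose component k1* = {rep.chosen_k1}"
            + (" (override)" if rep.overridden else "")
            + f", |r| = {abs(rep.correlations[rep.chosen_k1 - 1]):.4f}"
            f" vs {rep.covariate}",
            f"truncation K2 = {self.selection.K2}, K3 = {self.selection.K3}"
            f" (cumulative contribution {contrib:.3f})",
            f"core couplings significant at adj. P < {self.core_screen.threshold:g}: "
            f"{len(self.core_screen.significant_pairs)}",
            f"inferred compounds (adj. P < {self.selection.threshold:g}): "
            f"{len(self.inferred_compounds)} / {j}",
            f"inferred genes    (adj. P < {self.selection.threshold:g}): "
            f"{len(self.inferred_genes)} / {l}",
        ]
        for name, pred in self.predictions.items():
            lines.append(
                f"predicted targets [{name}] (adj. P < {pred.threshold:g}): "
                f"{len(pred.targets)}"
            )
        return "\n".join(lines)

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {
            "dose_components": self.selection.dose_report.to_frame(),
            "core_screen": self.core_screen.table,
            "inferred_compounds": self.selection.compound_table,
            "inferred_genes": self.selection.gene_table,
        }
        for name, pred in self.predictions.items():
            out[f"enrichment_{name}"] = pred.enrichment.table
            out[f"predicted_targets_{name}"] = pd.DataFrame({"target": pred.targets})
        return out

    def to_files(self, out_dir, summary_extra: dict | None = None) -> dict[str, Path]:
        m = self.model
        summary = {
            "tensor_shape": list(m.tensor.shape),
            "dose_covariate": m.dose_covariate,
            "k1": self.selection.dose_report.chosen_k1,
            "K2": self.selection.K2,
            "K3": self.selection.K3,
            "selection_threshold": m.selection_threshold,
            "n_inferred_compounds": len(self.inferred_compounds),
            "n_inferred_genes": len(self.inferred_genes),
            "n_predicted_targets": {k: len(v.targets) for k, v in self.predictions.items()},
        }
        summary.update(summary_extra or {})
        return tdio.write_results(self.tables(), out_dir, summary=summary)
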