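"""Synthetic dose x compound x gene screens with planted dose-dependent structure.

The generator emulates the geometry the decomposition-based screen assumes:
a subset of "active" compounds perturbs a subset of signature genes linearly
in dose, on top of gene-specific baselines and i.i.d. Gaussian noise,

    x[i, j, l] = mu_l + beta * s_j * w_l * t_i + eps[i, j, l],

with t the standardized linear ramp over dose index, s the 0/1 active-compound
indicator and w in {-1, 0, +1} balanced-sign gene weights (balanced so the
dose-dependent component is not confounded with the baseline component).
A matched gene-set library plants "signal" sets drawing most members from the
active genes, and a drug-target reference links active compounds to the
signal-set names, so every pipeline stage is exercisable without downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import DrugTargetReference, ExpressionTensor, GeneSetLibrary


@dataclass
class SyntheticGroundTruth:
    """What was planted: which items are active and with what effect."""

    active_compounds: list[str]
    active_genes: list[str]
    gene_weights: dict[str, int]
    beta: float
    sigma: float
    baseline: np.ndarray
    seed: int | None
    compound_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)
    signal_sets: list[str] = field(default_factory=list)


def _ramp(D: int, profile: str) -> np.ndarray:
    idx = np.arange(1, D + 1, dtype=float)
    if profile == "linear":
        t = idx
    elif profile == "quadratic":
        t = (idx - idx.mean()) ** 2
    else:
        raise ValueError(f"unknown dose profile {profile!r}")
    t = t - t.mean()
    return t / t.std()


def simulate_tensor(
    D: int = 6,
    J: int = 100,
    L: int = 500,
    n_active_compounds: int = 10,
    n_active_genes: int = 50,
    beta: float = 2.0,
    sigma: float = 1.0,
    seed: int | None = None,
    dose_profile: str = "linear",
) -> tuple[ExpressionTensor, SyntheticGroundTruth]:
    """Generate a complete synthetic screen tensor with planted dose response.

    Defaults mirror a mid-sized single-cell-line screen: six doses, one
    hundred compounds, a five-hundred-gene panel, ten active compounds
    hitting fifty signature genes at effect size ``beta`` = 2 against unit
    noise.  Everything is reproducible from ``seed``.
    """
    if not (0 <= n_active_compounds <= J and 0 <= n_active_genes <= L):
        raise ValueError("active counts must not exceed axis sizes")
    if D < 2 or J < 2 or L < 2:
        raise ValueError("every axis needs at least two levels")
    if sigma <= 0 or beta < 0:
        raise ValueError("require sigma > 0 and beta >= 0")

    rng = np.random.default_rng(seed)
    compound_ids = [f"CPD{j:04d}" for j in range(1, J + 1)]
    gene_ids = [f"G{l:04d}" for l in range(1, L + 1)]
    dose_levels = np.geomspace(0.1, 10.0, D)

    active_c = sorted(rng.choice(J, size=n_active_compounds, replace=False))
    active_g = sorted(rng.choice(L, size=n_active_genes, replace=False))
    s = np.zeros(J)
    s[active_c] = 1.0
    w = np.zeros(L)
    signs = np.ones(n_active_genes)
    signs[: n_active_genes // 2] = -1.0
    w[active_g] = rng.permutation(signs)

    t = _ramp(D, dose_profile)
    mu = rng.normal(size=L)
    eps = rng.normal(scale=sigma, size=(D, J, L))
    values = (
        mu[None, None, :]
        + beta * t[:, None, None] * s[None, :, None] * w[None, None, :]
        + eps
    )

    tensor = ExpressionTensor(values, dose_levels, compound_ids, gene_ids)
    truth = SyntheticGroundTruth(
        active_compounds=[compound_ids[j] for j in active_c],
        active_genes=[gene_ids[l] for l in active_g],
        gene_weights={gene_ids[l]: int(w[l]) for l in active_g},
        beta=beta,
        sigma=sigma,
        baseline=mu,
        seed=seed,
        compound_ids=compound_ids,
        gene_ids=gene_ids,
    )
    return tensor, truth


def simulate_library(
    truth: SyntheticGroundTruth,
    n_sets: int = 200,
    set_size: int = 50,
    n_signal_sets: int = 5,
    overlap_fraction: float = 0.8,
    seed: int | None = None,
) -> GeneSetLibrary:
    """Gene-set library with ``n_signal_sets`` sets enriched for the planted genes.

    Signal sets draw ``overlap_fraction`` of their members from the active
    genes and the rest uniformly from the remaining panel; noise sets are
    uniform draws from the whole panel.  Signal sets are named ``SIGSET_*``
    (noise sets ``RNDSET_*``) so truth-aware tests can tell them apart.
    """
    universe = list(truth.gene_ids)
    if set_size > len(universe):
        raise ValueError("set_size exceeds universe size")
    if not 0 <= overlap_fraction <= 1:
        raise ValueError("overlap_fraction must be in [0, 1]")
    n_from_active = round(overlap_fraction * set_size)
    if n_from_active > len(truth.active_genes):
        raise ValueError(
            f"signal sets need {n_from_active} active genes but only "
            f"{len(truth.active_genes)} were planted"
        )
    if n_signal_sets > n_sets:
        raise ValueError("n_signal_sets exceeds n_sets")

    rng = np.random.default_rng(seed)
    inactive = [g for g in universe if g not in set(truth.active_genes)]
    sets: dict[str, list[str]] = {}
    signal_names = []
    for i in range(1, n_signal_sets + 1):
        members = list(rng.choice(truth.active_genes, size=n_from_active, replace=False))
        members += list(rng.choice(inactive, size=set_size - n_from_active, replace=False))
        name = f"SIGSET_{i:03d}"
        sets[name] = members
        signal_names.append(name)
    for i in range(1, n_sets - n_signal_sets + 1):
        sets[f"RNDSET_{i:03d}"] = list(rng.choice(universe, size=set_size, replace=False))

    truth.signal_sets = signal_names
    return GeneSetLibrary(name="synthetic_perturbations", sets=sets, universe=universe)


def simulate_drug_targets(
    truth: SyntheticGroundTruth,
    n_targets: int = 3,
    seed: int | None = None,
) -> DrugTargetReference:
    """Known-target reference linking each active compound to signal-set names."""
    if not truth.signal_sets:
        raise ValueError("simulate_library must run first to define signal sets")
    rng = np.random.default_rng(seed)
    k = min(n_targets, len(truth.signal_sets))
    targets = {
        c: list(rng.choice(truth.signal_sets, size=k, replace=False))
        for c in truth.active_compounds
    }
    return DrugTargetReference(targets)
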