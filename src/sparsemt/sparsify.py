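"""Training-data removal models for sparsification benchmarks.

Three removal models emulate how activity data go missing:

* ``label`` removal blanks individual cells — the matrix keeps its size but
  becomes sparse;
* ``compound`` removal drops whole rows — the matrix shrinks but stays
  complete;
* ``assay`` removal drops whole columns — likewise complete but narrower
  (only sensible when the panel has many assays).

Removal counts use round-half-away-from-zero on fraction*count, each fraction
is sampled independently (grids are not nested), and removal never touches
retained values — label removal only clears mask entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma

import numpy as np

from ._utils import round_half_away
from .matrix import ActivityMatrix

REMOVAL_MODELS = ("label", "compound", "assay")

#: default removal-fraction grids: a fine 101-level grid for wide
#: regression panels and a 40-level grid for few-assay classification panels
PKIS_GRID = tuple(np.round(np.arange(0, 101) / 100.0, 2))
HTSFP_GRID = tuple(np.round(np.arange(0, 40) * 0.025, 3))


@dataclass
class SparsifyPlan:
    """A removal model plus an ordered fraction grid starting at 0."""

    removal_model: str = "label"
    fractions: tuple[float, ...] = PKIS_GRID
    removal_seed: int = 0

    def __post_init__(self) -> None:
        if self.removal_model not in REMOVAL_MODELS:
            raise ValueError(f"removal_model must be one of {REMOVAL_MODELS}")
        f = tuple(float(x) for x in self.fractions)
        if not f or f[0] != 0.0:
            raise ValueError("fraction grid must start at 0 (complete-data reference)")
        if any(b <= a for a, b in zip(f, f[1:])):
            raise ValueError("fractions must be strictly increasing")
        if f[-1] > 1.0 or f[0] < 0.0:
            raise ValueError("fractions must lie in [0, 1]")
        self.fractions = f

    def apply(self, train: ActivityMatrix):
        """Yield (fraction, sparsified matrix); each fraction sampled independently."""
        for idx, frac in enumerate(self.fractions):
            seed = np.random.SeedSequence([self.removal_seed, idx]).generate_state(1)[0]
            yield frac, remove(train, self.removal_model, frac, int(seed) & (2**31 - 1))


def remove(train: ActivityMatrix, model: str, fraction: float, seed: int) -> ActivityMatrix:
    if model == "label":
        return remove_labels(train, fraction, seed)
    if model == "compound":
        return remove_compounds(train, fraction, seed)
    if model == "assay":
        return remove_assays(train, fraction, seed)
    raise ValueError(f"unknown removal model {model!r}")


def remove_labels(train: ActivityMatrix, fraction: float, seed: int) -> ActivityMatrix:
    """Blank round(fraction*L) observed cells chosen uniformly without replacement.

    The matrix keeps its dimensions; only the observed mask changes.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    out = train.copy()
    if fraction == 0.0:
        return out
    obs_rows, obs_cols = np.nonzero(train.observed)
    L = obs_rows.size
    n_remove = round_half_away(fraction * L)
    if n_remove == 0:
        return out
    rng = np.random.default_rng(seed)
    pick = rng.choice(L, size=n_remove, replace=False)
    out.observed[obs_rows[pick], obs_cols[pick]] = False
    out.values[obs_rows[pick], obs_cols[pick]] = np.nan
    return out


def remove_compounds(train: ActivityMatrix, fraction: float, seed: int) -> ActivityMatrix:
    """Drop round(fraction*n) whole rows; the observed pattern of the rest is untouched."""
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    n = train.n_compounds
    n_remove = round_half_away(fraction * n)
    if n_remove >= n:
        raise ValueError("compound removal would leave no compounds")
    if n_remove == 0:
        return train.copy()
    rng = np.random.default_rng(seed)
    drop = rng.choice(n, size=n_remove, replace=False)
    keep = np.setdiff1d(np.arange(n), drop)
    return train.take_compounds(keep)


def remove_assays(train: ActivityMatrix, fraction: float, seed: int) -> ActivityMatrix:
    """Drop round(fraction*m) whole columns; evaluation later restricts to survivors."""
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    m = train.n_assays
    if m < 2:
        raise ValueError("assay removal needs at least 2 assays")
    n_remove = round_half_away(fraction * m)
    if n_remove >= m:
        raise ValueError("assay removal would leave no assays")
    if n_remove == 0:
        return train.copy()
    rng = np.random.default_rng(seed)
    drop = rng.choice(m, size=n_remove, replace=False)
    keep = np.setdiff1d(np.arange(m), drop)
    return train.take_assays(keep)


@dataclass
class EmptyAudit:
    empty_assays: list[str] = field(default_factory=list)
    empty_compounds: list[str] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not self.empty_assays and not self.empty_compounds


def audit_empty(train: ActivityMatrix) -> EmptyAudit:
    """Assays and compounds left with zero observed labels.

    High removal fractions empty whole assays by chance, at which point
    per-assay models cannot be fit — callers consult this report to record a
    failure instead of crashing.
    """
    col_counts = train.observed.sum(axis=0)
    row_counts = train.observed.sum(axis=1)
    return EmptyAudit(
        empty_assays=[a for a, c in zip(train.assay_ids, col_counts) if c == 0],
        empty_compounds=[c for c, r in zip(train.compound_ids, row_counts) if r == 0],
    )


def expected_empty_assays(n: int, m: int, fraction: float) -> float:
    """Expected number of assays emptied by label removal on a complete n x m grid.

    Removing r = round(fraction*n*m) of the N = n*m cells uniformly without
    replacement empties a given column exactly when all n of its cells are
    among the removed, which happens with hypergeometric probability
    C(N-n, r-n) / C(N, r); the expectation is m times that.
    """
    N = n * m
    r = round_half_away(fraction * N)
    if r < n:
        return 0.0
    if r == N:
        return float(m)

    def logC(a: int, b: int) -> float:
        return lgamma(a + 1) - lgamma(b + 1) - lgamma(a - b + 1)

    return m * float(np.exp(logC(N - n, r - n) - logC(N, r)))
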