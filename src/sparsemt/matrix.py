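"""Activity matrices, fingerprints and the descriptive statistics reported on them.

The central container is :class:`ActivityMatrix`: a dense compounds x assays
grid of responses (percent inhibition for regression, {0, 1} labels for
classification) together with an explicit observed-cell mask. Sparsity is a
property of the mask, never of sentinel values: unobserved cells hold NaN for
hygiene but all code consults ``observed``.

Fingerprints are 1024-bit hashed circular (Morgan radius 2 / ECFP4-style)
substructure keys, one row per compound, aligned with the activity matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from ._utils import round_half_away

TaskType = Literal["regression", "classification"]

_CLASS_TOKENS = {"active": 1.0, "inactive": 0.0, "1": 1.0, "0": 0.0}


@dataclass
class ActivityMatrix:
    """Compounds x assays response grid with an observed-cell mask.

    Parameters
    ----------
    values : (n, m) float array
        Measured responses. Cells where ``observed`` is False are set to NaN.
    observed : (n, m) bool array
        True where a measurement exists.
    compound_ids, assay_ids : sequences of str
        Row and column identifiers.
    task_type : {"regression", "classification"}
        Classification matrices hold only {0, 1} at observed cells
        (inactive = 0, active = 1).
    """

    values: np.ndarray
    observed: np.ndarray
    compound_ids: list[str]
    assay_ids: list[str]
    task_type: TaskType = "regression"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).copy()
        self.observed = np.asarray(self.observed, dtype=bool).copy()
        self.compound_ids = [str(c) for c in self.compound_ids]
        self.assay_ids = [str(a) for a in self.assay_ids]
        if self.values.shape != self.observed.shape:
            raise ValueError(
                f"values shape {self.values.shape} != observed shape {self.observed.shape}"
            )
        n, m = self.values.shape
        if len(self.compound_ids) != n or len(self.assay_ids) != m:
            raise ValueError("identifier lengths do not match matrix dimensions")
        if len(set(self.compound_ids)) != n:
            raise ValueError("duplicate compound ids")
        if len(set(self.assay_ids)) != m:
            raise ValueError("duplicate assay ids")
        if self.task_type not in ("regression", "classification"):
            raise ValueError(f"unknown task_type {self.task_type!r}")
        obs_vals = self.values[self.observed]
        if np.isnan(obs_vals).any():
            raise ValueError("NaN at an observed cell")
        if self.task_type == "classification" and obs_vals.size:
            if not np.isin(obs_vals, (0.0, 1.0)).all():
                raise ValueError("classification matrix must contain only {0, 1} at observed cells")
        self.values[~self.observed] = np.nan

    # -- basic geometry -------------------------------------------------
    @property
    def n_compounds(self) -> int:
        return self.values.shape[0]

    @property
    def n_assays(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_observed(self) -> int:
        """Number of filled cells L."""
        return int(self.observed.sum())

    def dense_nan(self) -> np.ndarray:
        """Values with NaN at unobserved cells (copy); the estimator Y format."""
        return self.values.copy()

    def copy(self) -> "ActivityMatrix":
        return ActivityMatrix(
            self.values, self.observed, self.compound_ids, self.assay_ids, self.task_type
        )

    def take_compounds(self, idx: np.ndarray) -> "ActivityMatrix":
        idx = np.asarray(idx)
        return ActivityMatrix(
            self.values[idx],
            self.observed[idx],
            [self.compound_ids[i] for i in idx],
            self.assay_ids,
            self.task_type,
        )

    def take_assays(self, idx: np.ndarray) -> "ActivityMatrix":
        idx = np.asarray(idx)
        return ActivityMatrix(
            self.values[:, idx],
            self.observed[:, idx],
            self.compound_ids,
            [self.assay_ids[i] for i in idx],
            self.task_type,
        )


@dataclass
class FingerprintSet:
    """n x B binary substructure-fingerprint matrix aligned with an ActivityMatrix."""

    bits: np.ndarray
    compound_ids: list[str]

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits)
        if self.bits.ndim != 2:
            raise ValueError("bits must be 2-D")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("fingerprint bits must be binary")
        self.bits = self.bits.astype(np.uint8)
        self.compound_ids = [str(c) for c in self.compound_ids]
        if len(self.compound_ids) != self.bits.shape[0]:
            raise ValueError("compound id count does not match fingerprint rows")
        if len(set(self.compound_ids)) != len(self.compound_ids):
            raise ValueError("duplicate compound ids")
        if (self.bits.sum(axis=1) == 0).any():
            raise ValueError("every fingerprint must have at least one bit set")

    @property
    def n_bits(self) -> int:
        return self.bits.shape[1]

    def take(self, idx: np.ndarray) -> "FingerprintSet":
        idx = np.asarray(idx)
        return FingerprintSet(self.bits[idx], [self.compound_ids[i] for i in idx])

    def align_to(self, matrix: ActivityMatrix) -> "FingerprintSet":
        """Reorder rows to the compound order of ``matrix`` (error if not a superset)."""
        pos = {c: i for i, c in enumerate(self.compound_ids)}
        try:
            idx = np.array([pos[c] for c in matrix.compound_ids], dtype=int)
        except KeyError as exc:
            raise ValueError(f"fingerprints missing compound {exc.args[0]!r}") from exc
        return self.take(idx)


@dataclass
class SplitResult:
    """Compound-wise train/test partition at a 3:1 default ratio."""

    train: ActivityMatrix
    test: ActivityMatrix
    split_seed: int = 0


# ---------------------------------------------------------------------------
# I/O — wide CSV, first column compound id, header row assay ids, empty = missing
# ---------------------------------------------------------------------------

def read_activity_csv(path: str | Path, task_type: TaskType = "regression") -> ActivityMatrix:
    """Read a wide activity CSV.

    Missing cells are the empty string only; "NA"/"NaN" tokens are rejected so
    that a stray spreadsheet export cannot silently change the observed mask.
    Classification cells accept the tokens {active, inactive, 1, 0}.
    """
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    compound_ids = [str(c) for c in df.index]
    if len(set(compound_ids)) != len(compound_ids):
        dupes = sorted({c for c in compound_ids if compound_ids.count(c) > 1})
        raise ValueError(f"duplicate compound ids in {path}: {dupes[:5]}")
    assay_ids = [str(a) for a in df.columns]
    raw = df.to_numpy(dtype=object)
    n, m = raw.shape
    values = np.full((n, m), np.nan)
    observed = np.zeros((n, m), dtype=bool)
    for i in range(n):
        for j in range(m):
            cell = str(raw[i, j]).strip()
            if cell == "":
                continue
            if task_type == "classification":
                token = cell.lower()
                if token not in _CLASS_TOKENS:
                    raise ValueError(
                        f"unknown classification token {cell!r} at row "
                        f"{compound_ids[i]!r}, column {assay_ids[j]!r}"
                    )
                values[i, j] = _CLASS_TOKENS[token]
            else:
                try:
                    values[i, j] = float(cell)
                except ValueError as exc:
                    raise ValueError(
                        f"non-numeric value {cell!r} at row {compound_ids[i]!r}, "
                        f"column {assay_ids[j]!r}"
                    ) from exc
            observed[i, j] = True
    return ActivityMatrix(values, observed, compound_ids, assay_ids, task_type)


def write_activity_csv(matrix: ActivityMatrix, path: str | Path) -> None:
    """Write the wide CSV format read by :func:`read_activity_csv`."""
    cells = np.empty(matrix.shape, dtype=object)
    cells[:] = ""
    obs = matrix.observed
    if matrix.task_type == "classification":
        cells[obs] = np.where(matrix.values[obs] > 0.5, "active", "inactive")
    else:
        cells[obs] = [np.format_float_positional(v, trim="0") for v in matrix.values[obs]]
    df = pd.DataFrame(cells, index=matrix.compound_ids, columns=matrix.assay_ids)
    df.index.name = "compound_id"
    df.to_csv(path)


def read_fingerprint_csv(path: str | Path) -> FingerprintSet:
    df = pd.read_csv(path, index_col=0)
    return FingerprintSet(df.to_numpy(), [str(c) for c in df.index])


def write_fingerprint_csv(fps: FingerprintSet, path: str | Path) -> None:
    df = pd.DataFrame(
        fps.bits,
        index=fps.compound_ids,
        columns=[f"bit_{b}" for b in range(fps.n_bits)],
    )
    df.index.name = "compound_id"
    df.to_csv(path)


def fingerprints_from_smiles(smiles: list[str], compound_ids: list[str] | None = None,
                             n_bits: int = 1024, radius: int = 2) -> FingerprintSet:
    """Hashed circular fingerprints from SMILES via RDKit (optional adapter).

    Molecule standardization is deliberately out of scope; SMILES are used
    as given. Unparseable SMILES raise.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    rows = []
    for smi in smiles:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smi!r}")
        rows.append(np.array(gen.GetFingerprint(mol), dtype=np.uint8))
    ids = compound_ids if compound_ids is not None else [f"C{i}" for i in range(len(smiles))]
    return FingerprintSet(np.vstack(rows), ids)


# ---------------------------------------------------------------------------
# Descriptive statistics
# ---------------------------------------------------------------------------

def fill_fraction_from_counts(n: int, m: int, n_observed: int) -> tuple[float, float]:
    """(percent_filled, percent_missing) from cell counts without materializing."""
    total = int(n) * int(m)
    if total <= 0:
        raise ValueError("empty matrix: n*m must be positive")
    if not 0 <= n_observed <= total:
        raise ValueError(f"observed count {n_observed} outside [0, {total}]")
    percent_missing = 100.0 * (total - n_observed) / total
    return 100.0 - percent_missing, percent_missing


def fill_fraction(matrix: ActivityMatrix) -> tuple[float, float]:
    """Percent of cells filled and missing; filled + missing == 100 exactly."""
    return fill_fraction_from_counts(matrix.n_compounds, matrix.n_assays, matrix.n_observed)


def train_test_split(matrix: ActivityMatrix, test_fraction: float = 0.25,
                     seed: int = 0, fps: FingerprintSet | None = None):
    """Split compounds (rows) into disjoint train/test sets.

    The default 3:1 ratio reserves round(0.25*n) compounds for testing. Only
    rows are split — assays are shared — because performance is later scored
    per assay on held-out compounds. If ``fps`` is given, returns
    (SplitResult, train_fps, test_fps) with fingerprints partitioned alongside.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    n = matrix.n_compounds
    if n < 2:
        raise ValueError("need at least 2 compounds to split")
    n_test = round_half_away(test_fraction * n)
    if n_test == 0 or n_test == n:
        raise ValueError(
            f"split of {n} compounds at test_fraction={test_fraction} leaves an empty side"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    result = SplitResult(
        train=matrix.take_compounds(train_idx),
        test=matrix.take_compounds(test_idx),
        split_seed=seed,
    )
    if fps is None:
        return result
    aligned = fps.align_to(matrix)
    return result, aligned.take(train_idx), aligned.take(test_idx)


def tanimoto_matrix(bits: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto |a AND b| / |a OR b| over binary row vectors."""
    b = np.asarray(bits, dtype=np.int64)
    inter = b @ b.T
    counts = b.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    return sim


def describe(matrix: ActivityMatrix, fps: FingerprintSet,
             max_compounds_for_similarity: int | None = None,
             seed: int = 0) -> dict:
    """Dataset descriptors: value range, in-[0,100] fraction, class balance,
    bits-set summary and pairwise Tanimoto summary.

    ``max_compounds_for_similarity`` caps the quadratic similarity computation
    by subsampling compounds (seeded); None computes all pairs.
    """
    fps = fps.align_to(matrix)
    obs = matrix.values[matrix.observed]
    out: dict = {
        "n_compounds": matrix.n_compounds,
        "n_assays": matrix.n_assays,
        "n_observed": matrix.n_observed,
    }
    out["percent_filled"], out["percent_missing"] = fill_fraction(matrix)
    if matrix.task_type == "regression":
        out["value_min"] = float(obs.min()) if obs.size else np.nan
        out["value_max"] = float(obs.max()) if obs.size else np.nan
        out["fraction_in_0_100"] = (
            float(((obs >= 0) & (obs <= 100)).mean()) if obs.size else np.nan
        )
    else:
        ratios = {}
        for j, aid in enumerate(matrix.assay_ids):
            col = matrix.values[matrix.observed[:, j], j]
            n_act = int((col == 1).sum())
            n_inact = int((col == 0).sum())
            ratios[aid] = n_act / n_inact if n_inact else np.inf
        out["active_inactive_ratio"] = ratios

    nbits = fps.bits.sum(axis=1)
    out["bits_set"] = {
        "min": int(nbits.min()),
        "mean": float(nbits.mean()),
        "median": float(np.median(nbits)),
        "max": int(nbits.max()),
    }
    bits = fps.bits
    if max_compounds_for_similarity is not None and bits.shape[0] > max_compounds_for_similarity:
        rng = np.random.default_rng(seed)
        bits = bits[rng.choice(bits.shape[0], max_compounds_for_similarity, replace=False)]
    sim = tanimoto_matrix(bits)
    iu = np.triu_indices(sim.shape[0], k=1)
    pair = sim[iu]
    out["tanimoto"] = {
        "min": float(pair.min()) if pair.size else np.nan,
        "mean": float(pair.mean()) if pair.size else np.nan,
        "median": float(np.median(pair)) if pair.size else np.nan,
        "max": float(pair.max()) if pair.size else np.nan,
    }
    return out
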