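"""Orchestration of sparsification grids.

A :class:`RunSpec` names a dataset (synthetic preset or CSV paths), the
methods with their hyperparameter sets, the removal models, the fraction
grid and the seed-control design (split seeds x removal seeds; the default
control preset is 4 x 4 = 16 runs). :func:`run` executes the full grid —

    split -> sparsify -> fit -> predict on the untouched test set -> score

— appending per-assay scores to a single long-form CSV, the sole source of
truth from which :func:`report` derives progression curves, knee tables and
plots. Runs are resumable: grid cells already present in the CSV are skipped,
and an identical spec re-run from scratch reproduces the file byte for byte
(for the deterministic methods, i.e. all of them — every source of
randomness is seeded).

Fits that fail because sparsification emptied an assay are recorded as
status rows, mirroring the regime where a benchmark simply cannot produce
predictions, rather than crashing the grid.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import factorization, forest, network
from ._utils import derive_seed
from .matrix import (
    ActivityMatrix,
    FingerprintSet,
    read_activity_csv,
    read_fingerprint_csv,
    train_test_split,
)
from .forest import impute_assay_mean
from .metrics import ProgressionCurve, aggregate, score_matrix, threshold_crossing
from .sparsify import REMOVAL_MODELS, remove
from .synthetic import generate

logger = logging.getLogger("sparsemt")

METHODS = ("macau", "net", "forest")
_METHOD_KEY = {name: i + 1 for i, name in enumerate(METHODS)}

RESULT_COLUMNS = [
    "dataset", "method", "removal_model", "hp_set", "split_seed",
    "removal_seed", "fraction", "status", "assay_id", "metric", "value",
]


@dataclass
class RunSpec:
    """Full description of a sparsification experiment grid."""

    dataset: str = "pkis_like"
    dataset_overrides: dict = field(default_factory=dict)
    activity_csv: str | None = None
    fingerprint_csv: str | None = None
    task_type: str = "regression"
    methods: dict[str, list[dict]] = field(default_factory=lambda: {"macau": [{}]})
    removal_models: tuple[str, ...] = ("label",)
    fractions: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 0.9)
    split_seeds: tuple[int, ...] = (0,)
    removal_seeds: tuple[int, ...] = (0,)
    test_fraction: float = 0.25
    out_dir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        self.removal_models = tuple(self.removal_models)
        self.fractions = tuple(float(f) for f in self.fractions)
        self.split_seeds = tuple(int(s) for s in self.split_seeds)
        self.removal_seeds = tuple(int(s) for s in self.removal_seeds)
        self.validate()

    def validate(self) -> None:
        for model in self.removal_models:
            if model not in REMOVAL_MODELS:
                raise ValueError(f"unknown removal model {model!r}")
        for name in self.methods:
            if name not in METHODS:
                raise ValueError(f"unknown method {name!r}; choose from {METHODS}")
            if not self.methods[name]:
                raise ValueError(f"method {name!r} needs at least one hyperparameter set")
        if "forest" in self.methods:
            bad = [m for m in self.removal_models if m != "compound"]
            if bad:
                raise ValueError(
                    "the forest baseline needs complete training matrices and is "
                    f"only valid with the compound removal model, not {bad}"
                )
        if not self.fractions or self.fractions[0] != 0.0:
            raise ValueError("fraction grid must start at 0 (complete-data reference)")
        if any(b <= a for a, b in zip(self.fractions, self.fractions[1:])):
            raise ValueError("fractions must be strictly increasing")

    # -- (de)serialization ---------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["removal_models"] = list(self.removal_models)
        d["fractions"] = list(self.fractions)
        d["split_seeds"] = list(self.split_seeds)
        d["removal_seeds"] = list(self.removal_seeds)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunSpec":
        d = yaml.safe_load(Path(path).read_text())
        if not isinstance(d, dict):
            raise ValueError(f"run spec {path} must be a YAML mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown run-spec keys: {sorted(unknown)}")
        return cls(**d)


def load_dataset(spec: RunSpec) -> tuple[ActivityMatrix, FingerprintSet]:
    if spec.activity_csv is not None:
        if spec.fingerprint_csv is None:
            raise ValueError("activity_csv requires fingerprint_csv")
        matrix = read_activity_csv(spec.activity_csv, spec.task_type)
        fps = read_fingerprint_csv(spec.fingerprint_csv).align_to(matrix)
        return matrix, fps
    overrides = dict(spec.dataset_overrides)
    overrides.setdefault("seed", spec.seed)
    matrix, fps, _ = generate(spec.dataset, **overrides)
    return matrix, fps


# ---------------------------------------------------------------------------
# Fitting a single grid cell
# ---------------------------------------------------------------------------

def fit_predict(method: str, train: ActivityMatrix, train_fps: FingerprintSet,
                test_fps: FingerprintSet, hp: dict, seed: int) -> np.ndarray:
    """Fit one method on a (possibly sparsified) training matrix and predict
    the activity profile of the test compounds."""
    if method == "macau":
        model = factorization.fit(train, train_fps, seed=seed, **hp)
        return factorization.predict(model, test_fps)
    if method == "net":
        hp = dict(hp)
        if "hidden_sizes" in hp:
            hp["hidden_sizes"] = tuple(hp["hidden_sizes"])
        model = network.fit(train, train_fps, seed=seed, **hp)
        return network.predict(model, test_fps)
    if method == "forest":
        model = forest.fit(impute_assay_mean(train), train_fps, seed=seed, **hp)
        return forest.predict(model, test_fps)
    raise ValueError(f"unknown method {method!r}")


def _cell_rows(spec: RunSpec, matrix: ActivityMatrix, fps: FingerprintSet,
               method: str, hp_idx: int, hp: dict, removal_model: str,
               split_seed: int, removal_seed: int,
               frac_idx: int, fraction: float) -> list[dict]:
    split, train_fps, test_fps = train_test_split(
        matrix, spec.test_fraction, seed=derive_seed(spec.seed, 11, split_seed), fps=fps
    )
    rm_seed = derive_seed(spec.seed, 13, removal_seed, frac_idx)
    train = remove(split.train, removal_model, fraction, rm_seed)
    fit_seed = derive_seed(spec.seed, 17, _METHOD_KEY[method], hp_idx,
                           split_seed, removal_seed, frac_idx)
    base = {
        "dataset": spec.dataset if spec.activity_csv is None else spec.activity_csv,
        "method": method, "removal_model": removal_model, "hp_set": hp_idx,
        "split_seed": split_seed, "removal_seed": removal_seed, "fraction": fraction,
    }
    test = split.test
    if removal_model == "assay":
        keep = [i for i, a in enumerate(test.assay_ids) if a in set(train.assay_ids)]
        test = test.take_assays(np.array(keep, dtype=int))
    try:
        preds = fit_predict(method, train, train_fps, test_fps, hp, fit_seed)
    except ValueError as exc:
        logger.info("grid cell failed (%s f=%.3g): %s", method, fraction, exc)
        return [{**base, "status": "empty_assay", "assay_id": "", "metric": "", "value": np.nan}]
    scores = score_matrix(test, preds)
    rows = []
    for assay_id, srow in scores.iterrows():
        for metric, value in srow.items():
            rows.append({**base, "status": "ok", "assay_id": assay_id,
                         "metric": metric, "value": value})
    return rows


def _grid(spec: RunSpec):
    for method, hp_sets in spec.methods.items():
        for hp_idx, hp in enumerate(hp_sets):
            for removal_model in spec.removal_models:
                for split_seed in spec.split_seeds:
                    for removal_seed in spec.removal_seeds:
                        for frac_idx, fraction in enumerate(spec.fractions):
                            yield (method, hp_idx, hp, removal_model,
                                   split_seed, removal_seed, frac_idx, fraction)


def _cell_key(method, hp_idx, removal_model, split_seed, removal_seed, fraction):
    return (method, int(hp_idx), removal_model, int(split_seed),
            int(removal_seed), round(float(fraction), 6))


def run(spec: RunSpec) -> Path:
    """Execute the grid; returns the path of the long-form results CSV.

    Cells already present in the CSV are skipped (idempotent resume). Rows
    are written in deterministic grid order with a fixed float format, so a
    from-scratch re-run of an identical spec is byte-identical.
    """
    out_dir = Path(spec.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results_path = out_dir / "results.csv"
    spec.to_yaml(out_dir / "runspec.yaml")

    done: set = set()
    existing: pd.DataFrame | None = None
    if results_path.exists():
        existing = pd.read_csv(results_path, keep_default_na=False,
                               na_values=[""], dtype={"assay_id": str, "metric": str})
        for _, r in existing.drop_duplicates(
                ["method", "hp_set", "removal_model", "split_seed",
                 "removal_seed", "fraction"]).iterrows():
            done.add(_cell_key(r["method"], r["hp_set"], r["removal_model"],
                               r["split_seed"], r["removal_seed"], r["fraction"]))

    matrix, fps = load_dataset(spec)
    new_rows: list[dict] = []
    for (method, hp_idx, hp, removal_model, split_seed, removal_seed,
         frac_idx, fraction) in _grid(spec):
        key = _cell_key(method, hp_idx, removal_model, split_seed, removal_seed, fraction)
        if key in done:
            continue
        logger.info("running %s hp%d %s split=%d rm=%d f=%.3g",
                    method, hp_idx, removal_model, split_seed, removal_seed, fraction)
        new_rows.extend(_cell_rows(spec, matrix, fps, method, hp_idx, hp,
                                   removal_model, split_seed, removal_seed,
                                   frac_idx, fraction))
        done.add(key)

    frames = [f for f in (existing, pd.DataFrame(new_rows, columns=RESULT_COLUMNS))
              if f is not None and len(f)]
    df = (pd.concat(frames, ignore_index=True)[RESULT_COLUMNS]
          if frames else pd.DataFrame(columns=RESULT_COLUMNS))
    df.to_csv(results_path, index=False, float_format="%.10g")
    return results_path


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def _scores_by_fraction(df: pd.DataFrame, metric: str) -> dict[float, pd.DataFrame]:
    out = {}
    for fraction, g in df[(df["status"] == "ok") & (df["metric"] == metric)].groupby("fraction"):
        wide = g.pivot_table(index="assay_id", values="value", aggfunc="mean")
        wide.columns = [metric]
        out[float(fraction)] = wide
    return out


def curves_from_results(df: pd.DataFrame, metric: str) -> list[ProgressionCurve]:
    """One curve per (method, removal_model, hp_set), medians across assays
    (and across seed runs at the same fraction)."""
    curves = []
    for (method, removal_model, hp_set), g in df.groupby(
            ["method", "removal_model", "hp_set"]):
        per_fraction = _scores_by_fraction(g, metric)
        if 0.0 not in per_fraction:
            continue
        curve = aggregate(per_fraction, metric, method=f"{method}/hp{hp_set}",
                          removal_model=removal_model)
        curves.append(curve)
    return curves


def average_curve(curves: list[ProgressionCurve]) -> ProgressionCurve:
    """Pointwise average of per-hyperparameter-set curves (matched fractions only)."""
    if not curves:
        raise ValueError("no curves to average")
    common = sorted(set.intersection(*(set(c.fractions.tolist()) for c in curves)))
    fr = np.array(common)
    med = np.nanmean(np.stack([
        [c.median[list(c.fractions).index(f)] for f in common] for c in curves
    ]), axis=0)
    rel = np.nanmean(np.stack([
        [c.relative[list(c.fractions).index(f)] for f in common] for c in curves
    ]), axis=0)
    first = curves[0]
    return ProgressionCurve(fr, med, rel, first.metric,
                            method=first.method.split("/")[0] + "/avg",
                            removal_model=first.removal_model)


def report(results_csv: str | Path, metric: str | None = None,
           rel_change: float = 0.10, make_plots: bool = True) -> dict:
    """Progression curves, knee table and plots from a results CSV.

    ``metric`` defaults to RMSD when present (regression results), else MCC.
    Returns {"curves": DataFrame, "knees": DataFrame, "plot_paths": [...]}.
    """
    results_csv = Path(results_csv)
    df = pd.read_csv(results_csv, keep_default_na=False, na_values=[""],
                     dtype={"assay_id": str, "metric": str})
    present = set(df.loc[df["status"] == "ok", "metric"])
    if metric is None:
        metric = "rmsd" if "rmsd" in present else "mcc"
    if metric not in present:
        raise ValueError(f"metric {metric!r} not present in {results_csv}")

    all_curves: list[ProgressionCurve] = []
    knee_rows = []
    for removal_model in sorted(df["removal_model"].unique()):
        for method in sorted(df.loc[df["removal_model"] == removal_model, "method"].unique()):
            sub = df[(df["method"] == method) & (df["removal_model"] == removal_model)]
            curves = curves_from_results(sub, metric)
            if not curves:
                continue
            all_curves.extend(curves)
            avg = average_curve(curves)
            all_curves.append(avg)
            knee_rows.append({
                "method": method, "removal_model": removal_model, "metric": metric,
                "rel_change": rel_change,
                "knee_fraction": threshold_crossing(avg, rel_change),
            })

    curve_df = pd.concat([c.to_frame() for c in all_curves], ignore_index=True)
    knee_df = pd.DataFrame(knee_rows)
    out_dir = results_csv.parent
    curve_df.to_csv(out_dir / f"curves_{metric}.csv", index=False, float_format="%.10g")
    knee_df.to_csv(out_dir / f"knees_{metric}.csv", index=False, float_format="%.10g")

    plot_paths = []
    if make_plots:
        plot_paths.append(_plot_curves(all_curves, metric, out_dir))
    return {"curves": curve_df, "knees": knee_df, "plot_paths": plot_paths}


def _plot_curves(curves: list[ProgressionCurve], metric: str, out_dir: Path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(11, 4.5), sharex=True)
    cmap = plt.get_cmap("tab10")
    series = sorted({(c.method.split("/")[0], c.removal_model) for c in curves})
    color_of = {s: cmap(i % 10) for i, s in enumerate(series)}
    for c in curves:
        key = (c.method.split("/")[0], c.removal_model)
        is_avg = c.method.endswith("/avg")
        kw = {"color": color_of[key], "alpha": 1.0 if is_avg else 0.3,
              "lw": 2.0 if is_avg else 1.0}
        label = f"{key[0]} ({key[1]})" if is_avg else None
        axes[0].plot(c.fractions, c.median, label=label, **kw)
        axes[1].plot(c.fractions, c.relative, label=label, **kw)
    axes[0].set_xlabel("fraction of training data removed")
    axes[1].set_xlabel("fraction of training data removed")
    axes[0].set_ylabel(f"median {metric.upper()}")
    axes[1].set_ylabel(f"relative median {metric.upper()}")
    axes[1].axhline(1.0, color="grey", lw=0.8, ls=":")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    path = out_dir / f"progression_{metric}.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


#: the seed-control preset: 4 split seeds x 4 removal seeds = 16 runs
def seed_control_spec(**overrides) -> RunSpec:
    base = dict(
        split_seeds=(0, 1, 2, 3),
        removal_seeds=(0, 1, 2, 3),
    )
    base.update(overrides)
    return RunSpec(**base)
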