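"""Synthetic complete activity matrices with controllable multitask structure.

Real kinase-panel and screening-panel matrices owe their predictability to two
kinds of redundancy: assays are correlated with each other (a low-rank
inter-task structure), and activity is partly determined by compound structure
(fingerprint-linked signal). The generator reproduces both, with explicit
knobs, so that sparsification experiments and factorization models can be
exercised end to end without any external data:

* compound latent factors are a seeded mix of a linear function of the
  fingerprint bits (weight ``signal_from_fingerprint``) and an independent
  component;
* assay latent factors are drawn around shared cluster means, so assays in
  the same cluster correlate;
* the observed grid is ``latent_compound @ latent_assay.T`` plus Gaussian
  noise, affinely rescaled into the requested response range (regression) or
  thresholded per assay at the quantile that hits a target active:inactive
  ratio (classification).

Presets ``pkis_like``, ``htsfp5_like`` and ``htsfp10_like`` encode the printed
descriptors of the corresponding benchmark datasets: a 367x454 percent-
inhibition panel spanning [-77, 130] with ~80% of values in [0, 100],
fingerprints with 26-88 bits set and mean pairwise Tanimoto ~0.15; and
5/10-assay binary screening panels with active:inactive ratios spanning
[0.25, 2.9] / [0.14, 1.9], every compound active in at least one assay, and
fingerprints with 12-102 bits set (median ~43).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._utils import round_half_away
from .matrix import ActivityMatrix, FingerprintSet


@dataclass
class SyntheticConfig:
    """All knobs of the generator; see the module docstring for semantics.

    ``bits_set_range`` is (min, median, max) bits per fingerprint.
    ``common_pool`` / ``common_frac`` control a small pool of globally popular
    bits that sets the baseline pairwise Tanimoto level; ``scaffold_bits``
    adds per-cluster shared bits on top (within-cluster similarity).
    """

    n_compounds: int = 367
    n_assays: int = 454
    latent_rank: int = 3
    assay_clusters: int = 3
    cluster_scale: float = 2.5
    cluster_spread: float = 0.3
    noise_sd: float = 1.0
    signal_from_fingerprint: float = 0.9
    value_range: tuple[float, float] = (-77.0, 130.0)
    central_band: tuple[float, float] = (0.0, 100.0)
    central_band_mass: float = 0.80
    target_active_ratios: tuple[float, ...] | None = None
    bits_set_range: tuple[int, int, int] = (26, 52, 88)
    n_bits: int = 1024
    compound_clusters: int = 18
    common_pool: int = 30
    common_frac: float = 0.35
    scaffold_bits: int = 4
    missing_fraction: float = 87 / (367 * 454)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_rank < self.assay_clusters or self.assay_clusters < 1:
            raise ValueError("need latent_rank >= assay_clusters >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.signal_from_fingerprint <= 1.0:
            raise ValueError("signal_from_fingerprint must lie in [0, 1]")
        lo, med, hi = self.bits_set_range
        if not (1 <= lo <= med <= hi):
            raise ValueError("bits_set_range must satisfy 1 <= min <= median <= max")
        if hi > self.n_bits:
            raise ValueError(f"cannot set {hi} bits in a {self.n_bits}-bit fingerprint")
        if self.target_active_ratios is not None:
            if any(r <= 0 for r in self.target_active_ratios):
                raise ValueError("active:inactive ratios must be positive")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must lie in [0, 1)")


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated matrix, for oracle-style tests.

    ``value_scale``/``value_offset`` are the affine map from latent scores to
    the response scale; ``noise_sd_scaled`` is the additive noise standard
    deviation expressed in response units after that map.
    """

    latent_compound: np.ndarray
    latent_assay: np.ndarray
    link: np.ndarray
    assay_cluster_of: np.ndarray
    thresholds: np.ndarray | None = None
    value_scale: float = 1.0
    value_offset: float = 0.0
    noise_sd_scaled: float = 0.0

    def noiseless_signal(self) -> np.ndarray:
        return self.latent_compound @ self.latent_assay.T


# ---------------------------------------------------------------------------
# Presets encoding the printed dataset descriptors
# ---------------------------------------------------------------------------

def _geom_ratios(hi: float, lo: float, m: int) -> tuple[float, ...]:
    return tuple(float(r) for r in np.geomspace(hi, lo, m))


PRESETS: dict[str, SyntheticConfig] = {
    "pkis_like": SyntheticConfig(),
    "htsfp5_like": SyntheticConfig(
        n_compounds=49713,
        n_assays=5,
        latent_rank=3,
        assay_clusters=2,
        target_active_ratios=_geom_ratios(2.9, 0.25, 5),
        bits_set_range=(12, 43, 102),
        common_frac=0.42,
        compound_clusters=40,
        missing_fraction=0.0,
    ),
    "htsfp10_like": SyntheticConfig(
        n_compounds=56892,
        n_assays=10,
        latent_rank=4,
        assay_clusters=3,
        target_active_ratios=_geom_ratios(1.9, 0.14, 10),
        bits_set_range=(12, 43, 102),
        common_frac=0.42,
        compound_clusters=40,
        missing_fraction=0.0,
    ),
}


def preset(name: str, **overrides) -> SyntheticConfig:
    """A named preset with optional field overrides (e.g. a smaller n_compounds)."""
    try:
        base = PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
    return replace(base, **overrides)


# ---------------------------------------------------------------------------
# Fingerprints
# ---------------------------------------------------------------------------

def gen_fingerprints(config: SyntheticConfig, rng: np.random.Generator | None = None,
                     cluster_of: np.ndarray | None = None) -> FingerprintSet:
    """Binary fingerprints with configured bits-set min/median/max and a
    popularity structure that sets the mean pairwise Tanimoto level.

    Per-compound bit counts are drawn uniformly on [min, median] or
    [median, max] with equal probability, which pins the three order
    statistics. A fraction ``common_frac`` of each compound's bits comes from
    a small shared pool of "popular" substructure bits (raising all pairwise
    similarities), and compounds in the same cluster additionally share
    ``scaffold_bits`` fixed scaffold bits.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, B = config.n_compounds, config.n_bits
    lo, med, hi = config.bits_set_range
    if cluster_of is None:
        cluster_of = rng.integers(0, max(config.compound_clusters, 1), size=n)

    if lo == med == hi:
        counts = np.full(n, lo)
    else:
        upper = rng.random(n) < 0.5
        counts = np.where(
            upper,
            rng.integers(med, hi + 1, size=n),
            rng.integers(lo, med + 1, size=n),
        )

    pool = min(config.common_pool, B)
    n_clusters = int(cluster_of.max()) + 1 if n else 0
    # fixed scaffold-bit blocks per cluster, laid out right after the common
    # pool so the fingerprint-linked signal can live on a compact support
    scaffold: dict[int, np.ndarray] = {}
    if config.scaffold_bits > 0 and pool + n_clusters * config.scaffold_bits <= B:
        scaffold = {
            c: np.arange(pool + c * config.scaffold_bits,
                         pool + (c + 1) * config.scaffold_bits)
            for c in range(n_clusters)
        }

    bits = np.zeros((n, B), dtype=np.uint8)
    rest = np.arange(B)
    for i in range(n):
        c = counts[i]
        chosen: list[np.ndarray] = []
        n_common = min(round_half_away(config.common_frac * c), pool, c)
        if n_common:
            chosen.append(rng.choice(pool, size=n_common, replace=False))
        budget = c - n_common
        scaf = scaffold.get(int(cluster_of[i]))
        if scaf is not None and budget > 0:
            take = min(len(scaf), budget)
            chosen.append(scaf[:take])
            budget -= take
        if budget > 0:
            used = np.concatenate(chosen) if chosen else np.empty(0, dtype=int)
            avail = np.setdiff1d(rest, used, assume_unique=False)
            chosen.append(rng.choice(avail, size=budget, replace=False))
        bits[i, np.concatenate(chosen).astype(int)] = 1
    return FingerprintSet(bits, [f"C{i:05d}" for i in range(n)])


# ---------------------------------------------------------------------------
# Latent structure shared by both task types
# ---------------------------------------------------------------------------

def _latent_scores(config: SyntheticConfig, rng: np.random.Generator):
    """Fingerprints, latent factors and the noiseless + noisy score grids."""
    n, m, k = config.n_compounds, config.n_assays, config.latent_rank
    cluster_of_compound = rng.integers(0, max(config.compound_clusters, 1), size=n)
    fps = gen_fingerprints(config, rng, cluster_of=cluster_of_compound)

    # Compound latents: standardized fingerprint-linked part mixed with an
    # independent part at weight signal_from_fingerprint. The link is
    # supported on the common-pool and scaffold bits only — the informative
    # substructure keys — so the bits->activity map is estimable from a few
    # hundred compounds (a dense link over all 1024 bits would make
    # cold-start prediction impossible at this sample size, hiding every
    # other effect the benchmark measures).
    support_size = min(
        config.common_pool + max(config.compound_clusters, 1) * config.scaffold_bits,
        config.n_bits,
    )
    link = np.zeros((config.n_bits, k))
    link[:support_size] = rng.normal(size=(support_size, k))
    Z = (fps.bits.astype(float) @ link)
    Z = (Z - Z.mean(axis=0)) / np.maximum(Z.std(axis=0), 1e-12)
    G = rng.normal(size=(n, k))
    s = config.signal_from_fingerprint
    U = s * Z + (1.0 - s) * G
    # effective link from bits to U (exact when s == 1)
    eff_link = s * link / np.maximum(Z.std(axis=0), 1e-12) if s > 0 else np.zeros_like(link)

    # Assay latents around shared cluster means -> within-cluster correlation.
    cluster_of_assay = np.arange(m) % config.assay_clusters
    means = config.cluster_scale * rng.normal(size=(config.assay_clusters, k))
    V = means[cluster_of_assay] + config.cluster_spread * rng.normal(size=(m, k))

    signal = U @ V.T
    noisy = signal + config.noise_sd * rng.normal(size=(n, m))
    truth = SyntheticTruth(
        latent_compound=U,
        latent_assay=V,
        link=eff_link,
        assay_cluster_of=cluster_of_assay,
        noise_sd_scaled=config.noise_sd,
    )
    return fps, truth, signal, noisy


# ---------------------------------------------------------------------------
# Regression matrices
# ---------------------------------------------------------------------------

def gen_regression_matrix(config: SyntheticConfig):
    """Complete percent-inhibition-like matrix.

    Scores are affinely mapped so their extremes land on ``value_range``; with
    the default preset's latent structure this leaves roughly 80% of values in
    [0, 100]. A small ``missing_fraction`` of cells (default 0.05%) is blanked
    to emulate pre-existing gaps in an otherwise complete panel.

    Returns (ActivityMatrix, FingerprintSet, SyntheticTruth).
    """
    rng = np.random.default_rng(config.seed)
    fps, truth, _, noisy = _latent_scores(config, rng)
    lo, hi = config.value_range
    b_lo, b_hi = config.central_band
    # Anchor the affine map on the central-band property: the quantiles that
    # leave central_band_mass of the values inside [b_lo, b_hi] are mapped to
    # the band edges (tail mass split in proportion to how far value_range
    # extends beyond the band on each side). Anchoring on interior quantiles
    # instead of the min/max cells keeps the realized band mass stable across
    # seeds; the value extremes then land near value_range.
    margin_lo, margin_hi = b_lo - lo, hi - b_hi
    tail = 1.0 - config.central_band_mass
    p_lo = tail * margin_lo / (margin_lo + margin_hi)
    p_hi = 1.0 - tail * margin_hi / (margin_lo + margin_hi)
    q_lo, q_hi = np.quantile(noisy, p_lo), np.quantile(noisy, p_hi)
    if q_hi <= q_lo:
        raise ValueError("degenerate score distribution; cannot rescale")
    scale = (b_hi - b_lo) / (q_hi - q_lo)
    offset = b_lo - q_lo * scale
    values = noisy * scale + offset
    truth.value_scale = float(scale)
    truth.value_offset = float(offset)
    truth.noise_sd_scaled = float(config.noise_sd * scale)

    n, m = values.shape
    observed = np.ones((n, m), dtype=bool)
    n_missing = round_half_away(config.missing_fraction * n * m)
    if n_missing:
        flat = rng.choice(n * m, size=n_missing, replace=False)
        observed.flat[flat] = False
    mat = ActivityMatrix(values, observed, fps.compound_ids,
                         [f"A{j:04d}" for j in range(m)], "regression")
    return mat, fps, truth


# ---------------------------------------------------------------------------
# Classification matrices
# ---------------------------------------------------------------------------

def gen_classification_matrix(config: SyntheticConfig):
    """Complete binary active/inactive matrix with per-assay class balance.

    Each assay's activity threshold is the empirical quantile of its latent
    score column that yields the target active:inactive ratio, so the
    pre-exclusion balance matches the target up to ties. Compounds active in
    no assay are then dropped (panel assembly keeps only compounds active
    somewhere), which slightly raises the realized ratios.

    Returns (ActivityMatrix, FingerprintSet, SyntheticTruth).
    """
    if config.target_active_ratios is None:
        raise ValueError("classification generation needs target_active_ratios")
    if len(config.target_active_ratios) != config.n_assays:
        raise ValueError("need one target ratio per assay")
    rng = np.random.default_rng(config.seed)
    fps, truth, _, noisy = _latent_scores(config, rng)

    m = config.n_assays
    n = noisy.shape[0]
    if (noisy.min(axis=0) == noisy.max(axis=0)).any():
        raise ValueError("degenerate scores in some assay: target ratio unreachable")
    p_target = np.array([r / (1.0 + r) for r in config.target_active_ratios])
    # Feasibility: after dropping never-active compounds, every kept row has
    # >= 1 active, so the per-assay active fractions must sum to more than 1
    # (each kept compound contributes sum(p) expected actives).
    if p_target.sum() <= 1.0:
        raise ValueError(
            "target active:inactive ratios are unreachable: the active "
            f"fractions sum to {p_target.sum():.3f} <= 1, but every retained "
            "compound must be active in at least one assay"
        )

    # Dropping never-active compounds removes only inactives, inflating every
    # realized ratio. Thresholds are therefore set by quantile at an adjusted
    # active fraction p_adj = p_target * kept/n, where kept (the number of
    # compounds active somewhere) is solved by fixed-point iteration — the
    # realized post-drop ratios then match the targets up to ties.
    kept_n = n
    converged = False
    thresholds = np.empty(m)
    labels = np.zeros_like(noisy)
    for _ in range(100):
        p_adj = np.clip(p_target * kept_n / n, 1.0 / n, 1.0)
        for j in range(m):
            thresholds[j] = np.quantile(noisy[:, j], 1.0 - p_adj[j])
            labels[:, j] = (noisy[:, j] > thresholds[j]).astype(float)
        new_kept = int((labels.sum(axis=1) >= 1).sum())
        if new_kept == kept_n:
            converged = True
            break
        kept_n = new_kept
    if not converged or kept_n < max(0.05 * n, 2):
        raise ValueError(
            "target active:inactive ratios are unreachable for these scores "
            "(the retained-compound fixed point collapsed; assays may be too "
            "correlated for the requested class balance)"
        )
    truth.thresholds = thresholds

    keep = labels.sum(axis=1) >= 1
    if not keep.any():
        raise ValueError("no compound is active in any assay; ratios unreachable")
    labels = labels[keep]
    fps = fps.take(np.where(keep)[0])
    truth.latent_compound = truth.latent_compound[keep]

    observed = np.ones(labels.shape, dtype=bool)
    mat = ActivityMatrix(labels, observed, fps.compound_ids,
                         [f"A{j:04d}" for j in range(m)], "classification")
    return mat, fps, truth


def generate(config_or_preset: SyntheticConfig | str, **overrides):
    """Dispatch on task type: classification when target ratios are set."""
    config = (preset(config_or_preset, **overrides)
              if isinstance(config_or_preset, str)
              else (replace(config_or_preset, **overrides) if overrides else config_or_preset))
    if config.target_active_ratios is not None:
        return gen_classification_matrix(config)
    return gen_regression_matrix(config)
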