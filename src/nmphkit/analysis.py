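"""Pattern estimation, similarity, and resampling inference.

The measurement chain: a GLM turns a run's BOLD series into one response
pattern per image; Pearson correlations between pairmate patterns give
one similarity value per pair (and hence per similarity level); the
level-wise post-minus-pre difference is the representational change
curve; a second-order correlation between similarity level and pattern
similarity (Fisher-transformed) measures model-brain correspondence.

Inference is non-parametric throughout: percentile confidence intervals
from bootstrap resampling of participants, and null distributions from
re-pairing A and B images at random (the true pairing is *not* excluded
from the permutation set, which makes the null conservative).  P-values
use the add-one rule (k + 1) / (n + 1), with ties between the null and
the observed statistic counted at half weight.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import RunDesign
from .simulate import ChangeCurve, PatternMatrix, design_matrix

__all__ = [
    "SimilarityProfile",
    "StatResult",
    "fit_glm",
    "pairmate_similarity",
    "cross_pair_correlations",
    "correspondence",
    "fisher_z",
    "representational_change",
    "change_curves",
    "arrangement_analysis",
    "ArrangementResult",
    "bootstrap_ci",
    "shuffle_null",
    "searchlight_map",
    "SingularDesignError",
    "UndefinedCorrelationError",
    "MissingPairError",
]

_FISHER_CLAMP = 1.0 - 1e-7


class SingularDesignError(np.linalg.LinAlgError):
    """GLM design matrix is (numerically) rank-deficient."""


class UndefinedCorrelationError(ValueError):
    """A correlation over a zero-variance vector was requested."""


class MissingPairError(ValueError):
    """A pair was never co-presented for some participant."""


@dataclass
class SimilarityProfile:
    """Pairmate Pearson correlations ordered by similarity level."""

    r_by_level: np.ndarray
    run_label: str = ""

    def __post_init__(self) -> None:
        self.r_by_level = np.asarray(self.r_by_level, dtype=np.float64)
        if np.any(np.abs(self.r_by_level) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")


@dataclass
class StatResult:
    """Point estimate with resampling CI and/or permutation p-value."""

    estimate: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    p: float = float("nan")
    n_boot: int = 0
    n_perm: int = 0
    n_failed: int = 0

    def __post_init__(self) -> None:
        if np.isfinite(self.ci_low) and np.isfinite(self.ci_high):
            if self.ci_low > self.ci_high:
                raise ValueError("ci_low must not exceed ci_high")


# -- GLM --------------------------------------------------------------------

def fit_glm(
    bold: np.ndarray,
    run: RunDesign,
    hrf_params: dict | None = None,
    n_images: int = 16,
) -> PatternMatrix:
    """Per-voxel OLS estimates for the image regressors (+ intercept).

    ``bold`` is (n_voxels, n_volumes); regressors are image-onset delta
    trains convolved with the double-gamma response.  Returns an images
    x voxels pattern matrix.
    """
    bold = np.asarray(bold, dtype=np.float64)
    if bold.shape[1] != run.n_volumes:
        raise ValueError(
            f"series length {bold.shape[1]} != n_volumes {run.n_volumes}"
        )
    X = design_matrix(run, hrf_params, n_images=n_images)
    X = np.column_stack([X, np.ones(len(X))])
    cond = np.linalg.cond(X)
    if cond > 1e8:
        raise SingularDesignError(
            f"design matrix rank-deficient (condition number {cond:.3g})"
        )
    betas, *_ = np.linalg.lstsq(X, bold.T, rcond=None)
    return PatternMatrix(betas[:n_images], run.kind)


# -- similarity -------------------------------------------------------------

def default_pairing(n_pairs: int = 8) -> list[tuple[int, int]]:
    """Image-id pairing: pair p = (2p-1, 2p), p ordered by level."""
    return [(2 * p + 1, 2 * p + 2) for p in range(n_pairs)]


def _pearson(a: np.ndarray, b: np.ndarray, what: str) -> float:
    ac = a - a.mean()
    bc = b - b.mean()
    na = np.linalg.norm(ac)
    nb = np.linalg.norm(bc)
    if na == 0 or nb == 0:
        raise UndefinedCorrelationError(f"zero-variance pattern for {what}")
    return float(ac @ bc / (na * nb))


def pairmate_similarity(
    patterns: PatternMatrix | np.ndarray,
    pairing: list[tuple[int, int]] | None = None,
    run_label: str | None = None,
) -> SimilarityProfile:
    """Pearson correlation between the two pairmate patterns of each pair."""
    values = (
        patterns.values if isinstance(patterns, PatternMatrix) else np.asarray(patterns)
    )
    if pairing is None:
        pairing = default_pairing(values.shape[0] // 2)
    rs = []
    for a, b in pairing:
        for img in (a, b):
            if np.std(values[img - 1]) == 0:
                raise UndefinedCorrelationError(
                    f"zero-variance pattern for image {img}"
                )
        rs.append(_pearson(values[a - 1], values[b - 1], f"pair ({a},{b})"))
    if run_label is None:
        run_label = patterns.run_label if isinstance(patterns, PatternMatrix) else ""
    return SimilarityProfile(np.asarray(rs), run_label)


def cross_pair_correlations(patterns: PatternMatrix | np.ndarray) -> np.ndarray:
    """(n_pairs, n_pairs) matrix of corr(A_i, B_j) for re-pairing nulls."""
    values = (
        patterns.values if isinstance(patterns, PatternMatrix) else np.asarray(patterns)
    )
    n_pairs = values.shape[0] // 2
    z = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(z, axis=1)
    if np.any(norms == 0):
        bad = int(np.flatnonzero(norms == 0)[0]) + 1
        raise UndefinedCorrelationError(f"zero-variance pattern for image {bad}")
    z = z / norms[:, None]
    a = z[0::2]  # A images
    b = z[1::2]  # B images
    return a @ b.T


def fisher_z(r: float) -> float:
    """atanh with clamping so perfect correlations stay finite."""
    if np.isnan(r):
        return float("nan")
    if abs(r) >= _FISHER_CLAMP:
        warnings.warn("correlation at +-1 clamped before Fisher transform")
        r = np.clip(r, -_FISHER_CLAMP, _FISHER_CLAMP)
    return float(np.arctanh(r))


def correspondence(
    profile: SimilarityProfile | np.ndarray, levels: np.ndarray | None = None
) -> float:
    """Fisher-transformed second-order correlation of similarity level
    with pattern similarity.  NaN (with a warning) when either side has
    no variance."""
    values = (
        profile.r_by_level if isinstance(profile, SimilarityProfile) else np.asarray(profile)
    )
    if levels is None:
        levels = np.arange(1, len(values) + 1, dtype=np.float64)
    levels = np.asarray(levels, dtype=np.float64)
    if len(levels) < 3:
        raise ValueError("need at least 3 levels")
    if np.std(values) == 0 or np.std(levels) == 0:
        warnings.warn("zero-variance profile: correspondence undefined")
        return float("nan")
    r = float(np.corrcoef(levels, values)[0, 1])
    return fisher_z(r)


def representational_change(
    pre: SimilarityProfile, post: SimilarityProfile
) -> ChangeCurve:
    """Post-minus-pre pairmate similarity per level.

    Positive values indicate integration (patterns moved together),
    negative values differentiation (patterns moved apart).
    """
    if len(pre.r_by_level) != len(post.r_by_level):
        raise ValueError("pre/post profiles cover different pairings")
    return ChangeCurve(post.r_by_level - pre.r_by_level)


def change_curves(
    participants: list[dict[str, PatternMatrix]],
    pairing: list[tuple[int, int]] | None = None,
) -> np.ndarray:
    """(n_participants, n_levels) stack of per-participant change curves."""
    curves = []
    for part in participants:
        pre = pairmate_similarity(part["pre"], pairing)
        post = pairmate_similarity(part["post"], pairing)
        curves.append(representational_change(pre, post).delta)
    return np.stack(curves)


# -- behavioral arrangements -------------------------------------------------

@dataclass
class ArrangementResult:
    pair_distances: pd.DataFrame  # participant x pair mean distances (long form)
    per_participant_r: pd.Series  # level-vs-distance Pearson r per participant
    group_r: float  # on participant-averaged distances


def arrangement_analysis(
    placements: pd.DataFrame, n_levels: int = 8
) -> ArrangementResult:
    """Pairmate Euclidean distances and their correlation with level.

    Distances are computed per trial for every pair whose two images were
    both placed, averaged across trials within participant, correlated
    with similarity level per participant, and again on the
    participant-averaged distances (one value per pair).
    """
    df = placements.copy()
    df["pair"] = (df["image_id"] + 1) // 2
    df["position"] = np.where(df["image_id"] % 2 == 1, "A", "B")
    wide = df.pivot_table(
        index=["participant", "trial", "pair"],
        columns="position",
        values=["x", "y"],
    ).dropna()
    dist = np.hypot(
        wide[("x", "A")] - wide[("x", "B")], wide[("y", "A")] - wide[("y", "B")]
    )
    dist = dist.rename("distance").reset_index()
    per_part = (
        dist.groupby(["participant", "pair"])["distance"].mean().reset_index()
    )
    all_pairs = set(df["pair"].unique())
    for part, grp in per_part.groupby("participant"):
        missing = all_pairs - set(grp["pair"])
        if missing:
            raise MissingPairError(
                f"participant {part} never saw pair(s) {sorted(missing)} co-presented"
            )
    per_part["level"] = ((per_part["pair"] - 1) % n_levels) + 1

    def _safe_corr(g: pd.DataFrame) -> float:
        if g["distance"].std() == 0 or g["level"].std() == 0:
            warnings.warn("zero-variance distances: correlation undefined")
            return float("nan")
        return float(np.corrcoef(g["level"], g["distance"])[0, 1])

    per_participant_r = per_part.groupby("participant").apply(
        _safe_corr, include_groups=False
    )
    group = per_part.groupby("pair").agg(
        distance=("distance", "mean"), level=("level", "first")
    )
    group_r = _safe_corr(group)
    return ArrangementResult(per_part, per_participant_r, group_r)


# -- resampling inference ----------------------------------------------------

def bootstrap_ci(
    stat_fn,
    per_participant_inputs: list,
    n_boot: int = 50_000,
    seed: int = 0,
    ci: float = 0.95,
    exhaustive: bool = False,
) -> StatResult:
    """Percentile CI of ``stat_fn`` over with-replacement participant resamples.

    ``stat_fn`` maps a list of per-participant inputs to a scalar.
    Resamples on which it raises are excluded (their count is reported).
    With ``exhaustive=True`` all n^n resamples are enumerated instead of
    drawn (only sensible for tiny n).
    """
    n = len(per_participant_inputs)
    if n < 2:
        raise ValueError("need at least 2 participants")
    estimate = float(stat_fn(per_participant_inputs))
    if exhaustive:
        draws = itertools.product(range(n), repeat=n)
    else:
        rng = np.random.default_rng(seed)
        draws = rng.integers(0, n, size=(n_boot, n))
    stats_, failed = [], 0
    for idx in draws:
        sample = [per_participant_inputs[i] for i in idx]
        try:
            stats_.append(float(stat_fn(sample)))
        except Exception:
            failed += 1
    if not stats_:
        raise RuntimeError("statistic failed on every bootstrap resample")
    lo, hi = np.percentile(stats_, [100 * (1 - ci) / 2, 100 * (1 + ci) / 2])
    return StatResult(
        estimate, float(lo), float(hi), n_boot=len(stats_), n_failed=failed
    )


def random_pairings(
    rng: np.random.Generator, n_perm: int, n_pairs: int = 8
) -> np.ndarray:
    """(n_perm, n_pairs) array of B-image permutations (true pairing allowed)."""
    return np.stack([rng.permutation(n_pairs) for _ in range(n_perm)])


def shuffle_null(
    stat_fn,
    patterns_by_participant: list,
    n_perm: int = 50_000,
    seed: int = 0,
    n_pairs: int = 8,
) -> StatResult:
    """One-tailed re-pairing permutation test.

    Each permutation re-pairs A and B images uniformly at random — the
    true pairing is *not* excluded — and ``stat_fn(inputs, pairing)`` is
    recomputed, where ``pairing[i]`` gives the B image index assigned to
    A image i.  The observed statistic uses the identity pairing.
    p = (#{null >= observed} + 1) / (n_perm + 1), with exact ties counted
    at half weight.
    """
    rng = np.random.default_rng(seed)
    identity = np.arange(n_pairs)
    observed = float(stat_fn(patterns_by_participant, identity))
    null = np.array(
        [
            float(stat_fn(patterns_by_participant, rng.permutation(n_pairs)))
            for _ in range(n_perm)
        ]
    )
    k = np.sum(null > observed) + 0.5 * np.sum(null == observed)
    p = (k + 1.0) / (n_perm + 1.0)
    return StatResult(observed, p=float(p), n_perm=n_perm)


def group_correspondence_stat(
    corr_matrices: list[np.ndarray] | np.ndarray, pairing: np.ndarray
) -> float:
    """Group mean Fisher-z correspondence under a given A/B pairing.

    ``corr_matrices`` holds per-participant (n_pairs, n_pairs) cross-pair
    correlation matrices (from :func:`cross_pair_correlations`); the
    pairing indexes each A image's assigned B image.  Levels follow the
    A image's pair index.
    """
    mats = np.asarray(corr_matrices)
    n_pairs = mats.shape[-1]
    levels = np.arange(1, n_pairs + 1, dtype=np.float64)
    lv = (levels - levels.mean()) / np.linalg.norm(levels - levels.mean())
    rows = np.arange(n_pairs)
    profiles = mats[:, rows, pairing]  # (n_subj, n_pairs)
    pc = profiles - profiles.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(pc, axis=1)
    rs = np.zeros(len(profiles))
    ok = norms > 0
    rs[ok] = (pc[ok] @ lv) / norms[ok]
    rs = np.clip(rs, -_FISHER_CLAMP, _FISHER_CLAMP)
    return float(np.mean(np.arctanh(rs)))


# -- searchlight --------------------------------------------------------------

def searchlight_map(
    volume: np.ndarray,
    mask: np.ndarray,
    stat_fn,
    radius: int = 2,
    min_voxels: int = 2,
    fisher: bool = True,
) -> np.ndarray:
    """Apply ``stat_fn`` to the cube neighborhood of every in-mask voxel.

    ``volume`` is (n_images, X, Y, Z); neighborhoods are (2r+1)^3 cubes
    (<= 125 voxels at radius 2) intersected with the mask.  The per-voxel
    statistic (a correlation) is Fisher-transformed unless ``fisher`` is
    off; centers whose neighborhood holds fewer than ``min_voxels``
    voxels are skipped (NaN).  ``radius=0`` with ``min_voxels=1`` gives a
    plain voxelwise map.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if volume.shape[1:] != mask.shape:
        raise ValueError("volume and mask shapes disagree")
    out = np.full(mask.shape, np.nan)
    nx, ny, nz = mask.shape
    for x, y, z in zip(*np.nonzero(mask)):
        sl = (
            slice(max(0, x - radius), min(nx, x + radius + 1)),
            slice(max(0, y - radius), min(ny, y + radius + 1)),
            slice(max(0, z - radius), min(nz, z + radius + 1)),
        )
        sub_mask = mask[sl]
        if sub_mask.sum() < min_voxels:
            continue
        patterns = volume[(slice(None),) + sl][:, sub_mask]
        stat = float(stat_fn(patterns))
        out[x, y, z] = fisher_z(stat) if fisher else stat
    return out
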