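"""Synthetic data with planted ground truth for the analysis pipeline.

Generates the three data modalities the analyses consume:

* **voxel patterns** — per-participant pre/post 16 x V pattern matrices
  in which each pairmate pair at similarity level *i* has a planted
  population correlation (a baseline per level in the pre run; baseline
  plus a planted change-curve value post learning);
* **BOLD time series** — a forward model of a templating run: per-image
  delta trains convolved with a double-gamma hemodynamic response,
  weighted by the planted patterns, plus white Gaussian noise;
* **arrangement tables** — behavioral image-placement coordinates in a
  circular arena whose pairmate distances fall linearly with similarity
  level, with participant- and trial-level noise.

Pattern generation uses the mixing construction B = alpha A +
sqrt(1 - alpha^2) e with unit-variance Gaussian patterns, for which the
population correlation of the *noisy* observations (measurement noise of
standard deviation s added independently per run) is alpha / (1 + s^2);
alpha is set to r (1 + s^2) so the planted correlation refers to what
the estimator actually sees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import RunDesign

__all__ = [
    "ChangeCurve",
    "PatternMatrix",
    "SimSpec",
    "planted_cubic",
    "default_planted_curve",
    "flat_curve",
    "synthetic_patterns",
    "double_gamma_hrf",
    "design_matrix",
    "synthetic_bold",
    "synthetic_arrangements",
]

N_LEVELS = 8

#: Default planted-curve cubic coefficients (standardized level axis):
#: a gentle U with its differentiation trough at levels 5-6 and a
#: rebound toward integration at the top level — the qualitative shape
#: nonmonotonic plasticity predicts, at desk-scale magnitude.
DEFAULT_CUBIC = (0.04, 0.035, -0.075, -0.047)


@dataclass
class ChangeCurve:
    """Per-level representational change: delta r = r_post - r_pre."""

    delta: np.ndarray  # (n_levels,)

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=np.float64)
        if np.any(np.abs(self.delta) > 2):
            raise ValueError("|delta r| cannot exceed 2")


@dataclass
class PatternMatrix:
    """Images x voxels response estimates for one run/ROI/participant."""

    values: np.ndarray  # (16, V)
    run_label: str  # "pre" | "post"
    roi_label: str = "sim"
    participant: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] < 2:
            raise ValueError("values must be (n_images, V >= 2)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("patterns contain non-finite values")


def standardized_levels(n_levels: int = N_LEVELS) -> np.ndarray:
    """Similarity levels 1..n centered and scaled to unit (population) SD."""
    x = np.arange(1, n_levels + 1, dtype=np.float64)
    return (x - x.mean()) / x.std()


def planted_cubic(
    a: float, b: float, c: float, d: float, n_levels: int = N_LEVELS
) -> ChangeCurve:
    """Cubic change curve a z^3 + b z^2 + c z + d on standardized levels."""
    z = standardized_levels(n_levels)
    return ChangeCurve(a * z**3 + b * z**2 + c * z + d)


def default_planted_curve() -> ChangeCurve:
    return planted_cubic(*DEFAULT_CUBIC)


def flat_curve(n_levels: int = N_LEVELS, value: float = 0.0) -> ChangeCurve:
    return ChangeCurve(np.full(n_levels, float(value)))


@dataclass
class SimSpec:
    """Study conditions for the synthetic cohort.

    Defaults mirror the learning-analysis sample (36 participants) with
    a voxel count typical of an anatomical ROI, a pre-learning pairmate
    correlation baseline rising linearly with similarity level (0 to
    0.3, a reduced-magnitude analogue of the model-to-brain
    correspondence seen in high-level visual cortex), and the default
    U-shaped planted change curve.
    """

    n_participants: int = 36
    n_voxels: int = 2000
    baseline_pairmate_r: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 0.3, N_LEVELS)
    )
    planted_curve: ChangeCurve = field(default_factory=default_planted_curve)
    pattern_noise_sd: float = 0.4
    bold_noise_sd: float = 1.0
    arrangement_slope: float = -45.0
    arrangement_intercept: float = 500.0
    arrangement_participant_sd: float = 40.0
    arrangement_trial_sd: float = 60.0
    arena_radius: float = 450.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.baseline_pairmate_r = np.asarray(self.baseline_pairmate_r, np.float64)
        if np.any(np.abs(self.baseline_pairmate_r) >= 1):
            raise ValueError("baseline pairmate correlations must be in (-1, 1)")
        post = self.baseline_pairmate_r + self.planted_curve.delta
        if np.any(np.abs(post) >= 1):
            raise ValueError("post-learning correlations must stay in (-1, 1)")

    @property
    def n_levels(self) -> int:
        return len(self.baseline_pairmate_r)


def _mixing_alpha(r: float, noise_sd: float, level: int) -> float:
    alpha = r * (1.0 + noise_sd**2)
    if abs(alpha) >= 1:
        raise ValueError(
            f"target correlation {r:.3f} infeasible at level {level} "
            f"with measurement noise sd {noise_sd} (needs |alpha| < 1)"
        )
    return alpha


def synthetic_patterns(spec: SimSpec) -> list[dict[str, PatternMatrix]]:
    """Per-participant pre/post pattern matrices with planted correlations.

    Image 2p-1 is pairmate A and image 2p pairmate B of the pair at
    similarity level p.  The A pattern and B's independent component are
    shared between runs (a stable item code); only the mixing weight
    changes from pre to post, plus fresh measurement noise per run.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0]))
    out = []
    s = spec.pattern_noise_sd
    for p in range(spec.n_participants):
        rows: dict[str, list[np.ndarray]] = {"pre": [], "post": []}
        for lev in range(spec.n_levels):
            r_pre = float(spec.baseline_pairmate_r[lev])
            r_post = r_pre + float(spec.planted_curve.delta[lev])
            a_pre = _mixing_alpha(r_pre, s, lev + 1)
            a_post = _mixing_alpha(r_post, s, lev + 1)
            base = rng.standard_normal(spec.n_voxels)
            indep = rng.standard_normal(spec.n_voxels)
            for run, alpha in (("pre", a_pre), ("post", a_post)):
                pat_a = base + s * rng.standard_normal(spec.n_voxels)
                pat_b = (
                    alpha * base
                    + np.sqrt(1 - alpha**2) * indep
                    + s * rng.standard_normal(spec.n_voxels)
                )
                rows[run].extend([pat_a, pat_b])
        out.append(
            {
                run: PatternMatrix(np.stack(rows[run]), run, participant=p)
                for run in ("pre", "post")
            }
        )
    return out


# -- hemodynamics ----------------------------------------------------------

def double_gamma_hrf(
    t: np.ndarray,
    peak: float = 6.0,
    undershoot: float = 16.0,
    ratio: float = 6.0,
    dispersion: float = 1.0,
) -> np.ndarray:
    """Canonical double-gamma impulse response, unit peak amplitude.

    The positive lobe is a gamma density with mode exactly at ``peak``
    seconds; the undershoot a gamma density with mode at ``undershoot``
    seconds, scaled down by ``ratio``.
    """
    t = np.asarray(t, dtype=np.float64)
    pos = stats.gamma.pdf(t, a=peak / dispersion + 1, scale=dispersion)
    neg = stats.gamma.pdf(t, a=undershoot / dispersion + 1, scale=dispersion)
    h = pos - neg / ratio
    return h / h.max()


def design_matrix(
    run: RunDesign,
    hrf_params: dict | None = None,
    dt: float = 0.1,
    n_images: int = 16,
) -> np.ndarray:
    """(n_volumes, n_images) convolved regressor matrix for a run.

    A delta function at each image onset is convolved with the
    double-gamma response on a fine grid, then sampled at volume times.
    Catch trials share their image's regressor.
    """
    hrf_params = hrf_params or {}
    t_hrf = np.arange(0, 33, dt)
    hrf = double_gamma_hrf(t_hrf, **hrf_params)
    n_fine = int(np.ceil(run.duration / dt)) + len(t_hrf)
    X = np.zeros((run.n_volumes, n_images))
    vol_idx = np.round(np.arange(run.n_volumes) * run.tr / dt).astype(int)
    for img in range(1, n_images + 1):
        train = np.zeros(n_fine)
        for e in run.events:
            if e.image_id == img:
                train[int(round(e.onset / dt))] = 1.0
        conv = np.convolve(train, hrf)[:n_fine]
        X[:, img - 1] = conv[vol_idx]
    return X


def synthetic_bold(
    run: RunDesign,
    patterns: PatternMatrix | np.ndarray,
    hrf_params: dict | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Forward BOLD model: (n_voxels, n_volumes) = patterns^T X^T + noise."""
    values = (
        patterns.values if isinstance(patterns, PatternMatrix) else np.asarray(patterns)
    )
    max_image = max(e.image_id for e in run.events)
    if max_image > values.shape[0]:
        raise ValueError(
            f"run presents image {max_image} but patterns have only "
            f"{values.shape[0]} rows"
        )
    X = design_matrix(run, hrf_params, n_images=values.shape[0])
    rng = np.random.default_rng(seed)
    signal = values.T @ X.T  # (V, n_volumes)
    return signal + noise_sd * rng.standard_normal(signal.shape)


# -- behavioral arrangements ----------------------------------------------

def synthetic_arrangements(
    spec: SimSpec,
    n_trials_per_participant: int = 10,
    n_sets: int = 8,
    pairs_per_trial: int = 13,
) -> pd.DataFrame:
    """Image-placement tables (participant, trial, image_id, x, y).

    The stimulus pool is ``n_sets`` endpoint sets x ``n_levels`` levels
    (64 pairs, 128 images by default).  Each trial shows a subset of
    pairs (both pairmates always together, cycling through the pool so
    every pair occurs several times per participant).  A pair's placement
    distance is its participant-level mean (intercept + slope x level +
    participant offset) plus trial noise, realized at a random position
    and orientation inside the circular arena.

    Pair p (1-based) comprises images 2p-1 and 2p at similarity level
    ((p-1) mod n_levels) + 1.
    """
    if n_trials_per_participant < 10:
        raise ValueError("need at least 10 trials per participant")
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 1]))
    n_pairs = n_sets * spec.n_levels
    levels = np.array([(p % spec.n_levels) + 1 for p in range(n_pairs)])
    rows = []
    for part in range(spec.n_participants):
        offset = spec.arrangement_participant_sd * rng.standard_normal()
        cycle = rng.permutation(n_pairs)
        pos = 0
        for trial in range(n_trials_per_participant):
            chosen = []
            for _ in range(pairs_per_trial):
                if pos == len(cycle):
                    cycle = rng.permutation(n_pairs)
                    pos = 0
                chosen.append(int(cycle[pos]))
                pos += 1
            for p in chosen:
                mean_d = (
                    spec.arrangement_intercept
                    + spec.arrangement_slope * levels[p]
                    + offset
                )
                d = max(mean_d + spec.arrangement_trial_sd * rng.standard_normal(), 1.0)
                d = min(d, 2 * spec.arena_radius - 2.0)
                max_c = spec.arena_radius - d / 2
                if max_c > 0:
                    rad = max_c * np.sqrt(rng.uniform())
                    ang = rng.uniform(0, 2 * np.pi)
                    cx, cy = rad * np.cos(ang), rad * np.sin(ang)
                else:
                    cx, cy = 0.0, 0.0
                theta = rng.uniform(0, 2 * np.pi)
                ux, uy = np.cos(theta), np.sin(theta)
                rows.append(
                    dict(participant=part, trial=trial, image_id=2 * p + 1,
                         x=cx + ux * d / 2, y=cy + uy * d / 2)
                )
                rows.append(
                    dict(participant=part, trial=trial, image_id=2 * p + 2,
                         x=cx - ux * d / 2, y=cy - uy * d / 2)
                )
    return pd.DataFrame(rows)
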