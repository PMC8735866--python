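"""Templating and statistical-learning run designs.

A run shows 16 images (8 pairmates A/B), 1 s each, first onset at 6 s,
inter-stimulus intervals of 1, 3 or 5 s in a 40:40:20 ratio, inside 203
volumes at TR 1.5 s (304.5 s).  Templating runs present the images in
pseudo-random order (each block of 16 a permutation, no immediate
repeats) so each image's response can be measured in isolation;
statistical-learning runs present pairs intact (A always immediately
followed by its B) with the pair order permuted per block of eight and
no pair repeated back-to-back.  One in ten trials carries a gray-patch
catch for the cover task.

ISIs are allocated by largest remainder rather than sampled i.i.d., so
every generated run fits the fixed scan length exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TrialEvent",
    "RunDesign",
    "templating_sequence",
    "learning_sequence",
    "assign_timing",
    "assign_catch",
    "make_run",
    "write_events",
    "read_events",
    "InfeasibleDesignError",
]

ISI_MENU: dict[float, float] = {1.0: 0.4, 3.0: 0.4, 5.0: 0.2}
N_IMAGES = 16
N_PAIRS = 8


class InfeasibleDesignError(ValueError):
    """The trial sequence cannot fit in the scan duration."""


@dataclass(frozen=True)
class TrialEvent:
    onset: float
    duration: float
    image_id: int  # 1..16
    pair_id: int  # 1..8
    position: str  # "A" | "B"
    catch: bool = False


@dataclass
class RunDesign:
    kind: str  # "templating" | "learning"
    events: list[TrialEvent]
    lead_in: float = 6.0
    tr: float = 1.5
    n_volumes: int = 203

    def __post_init__(self) -> None:
        onsets = [e.onset for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("onsets must be strictly increasing")
        if self.events and self.events[-1].onset + self.events[-1].duration > self.duration:
            raise InfeasibleDesignError("events exceed scan duration")

    @property
    def duration(self) -> float:
        return self.tr * self.n_volumes

    @property
    def n_trials(self) -> int:
        return len(self.events)

    def image_ids(self) -> list[int]:
        return [e.image_id for e in self.events]


def image_pair(image_id: int) -> tuple[int, str]:
    """Map image id 1..16 to (pair_id 1..8, position A/B).

    Pair p consists of images 2p-1 (A) and 2p (B).
    """
    pair_id = (image_id + 1) // 2
    position = "A" if image_id % 2 == 1 else "B"
    return pair_id, position


def _block_permutations(
    rng: np.random.Generator, n_items: int, n_blocks: int
) -> list[int]:
    """Concatenated per-block permutations with no adjacent repeats anywhere."""
    order: list[int] = []
    for _ in range(n_blocks):
        while True:
            block = list(rng.permutation(n_items) + 1)
            if not order or block[0] != order[-1]:
                if all(a != b for a, b in zip(block, block[1:])):
                    break
        order.extend(block)
    return order


def templating_sequence(
    n_images: int = N_IMAGES, reps: int = 5, seed: int | np.random.Generator = 0
) -> list[int]:
    """Pseudo-random image order: ``reps`` blocks, each a permutation of
    1..n_images, with no image shown twice in a row (block boundaries
    included)."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _block_permutations(rng, n_images, reps)


def learning_sequence(
    n_pairs: int = N_PAIRS, blocks: int = 5, seed: int | np.random.Generator = 0
) -> list[int]:
    """Structured order: pairs intact and in A->B order, pair order a fresh
    permutation per block of ``n_pairs``, no pair twice in a row."""
    if blocks < 1:
        raise ValueError("blocks must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pair_order = _block_permutations(rng, n_pairs, blocks)
    order: list[int] = []
    for pair in pair_order:
        order.extend((2 * pair - 1, 2 * pair))  # A then its pairmate B
    return order


def _largest_remainder_counts(n: int, ratios: dict[float, float]) -> dict[float, int]:
    keys = sorted(ratios)  # shortest ISI first; deterministic tie-break
    quotas = {k: n * ratios[k] for k in keys}
    counts = {k: int(np.floor(quotas[k])) for k in keys}
    leftover = n - sum(counts.values())
    by_remainder = sorted(keys, key=lambda k: (-(quotas[k] - counts[k]), k))
    for k in by_remainder[:leftover]:
        counts[k] += 1
    return counts


def assign_timing(
    order: list[int],
    kind: str = "templating",
    seed: int | np.random.Generator = 0,
    lead_in: float = 6.0,
    duration: float = 1.0,
    tr: float = 1.5,
    n_volumes: int = 203,
    isi_menu: dict[float, float] | None = None,
) -> RunDesign:
    """Onsets from the lead-in plus largest-remainder-allocated ISIs.

    The n-1 ISIs take the menu values in counts matching the stated
    ratios as exactly as the trial count allows, then are shuffled.
    """
    if not order:
        raise ValueError("order must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    isi_menu = isi_menu or ISI_MENU
    n_isi = len(order) - 1
    counts = _largest_remainder_counts(n_isi, isi_menu)
    isis = np.concatenate([np.full(c, k) for k, c in counts.items()] or [np.empty(0)])
    rng.shuffle(isis)
    min_total = lead_in + len(order) * duration + n_isi * min(isi_menu)
    if min_total > tr * n_volumes:
        raise InfeasibleDesignError(
            f"{len(order)} trials cannot fit {n_volumes} volumes at TR {tr}"
        )
    events = []
    onset = lead_in
    for i, image_id in enumerate(order):
        pair_id, position = image_pair(image_id)
        events.append(TrialEvent(onset, duration, int(image_id), pair_id, position))
        if i < n_isi:
            onset += duration + isis[i]
    run = RunDesign(kind, events, lead_in, tr, n_volumes)
    if run.events[-1].onset + duration > run.duration:
        raise InfeasibleDesignError("allocated ISIs exceed scan duration")
    return run


def assign_catch(
    run: RunDesign, fraction: float = 0.10, seed: int | np.random.Generator = 0
) -> RunDesign:
    """Flag exactly round(fraction * n_trials) trials as catch trials,
    chosen uniformly at random without replacement."""
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_catch = int(round(fraction * run.n_trials))
    flagged = set(rng.choice(run.n_trials, size=n_catch, replace=False).tolist())
    events = [replace(e, catch=(i in flagged)) for i, e in enumerate(run.events)]
    return RunDesign(run.kind, events, run.lead_in, run.tr, run.n_volumes)


def make_run(
    kind: str,
    seed: int = 0,
    reps: int = 5,
    blocks: int = 5,
    catch_fraction: float = 0.10,
) -> RunDesign:
    """One fully-specified run: sequence, timing, and catch trials."""
    kind_offset = {"templating": 0, "learning": 1}
    if kind not in kind_offset:
        raise ValueError(f"unknown run kind {kind!r}")
    rng = np.random.default_rng(np.random.SeedSequence([kind_offset[kind], int(seed)]))
    if kind == "templating":
        order = templating_sequence(N_IMAGES, reps, rng)
    else:
        order = learning_sequence(N_PAIRS, blocks, rng)
    run = assign_timing(order, kind, rng)
    return assign_catch(run, catch_fraction, rng)


def write_events(run: RunDesign, path: str | Path) -> None:
    """BIDS-style tab-separated events file."""
    df = pd.DataFrame(
        {
            "onset": [e.onset for e in run.events],
            "duration": [e.duration for e in run.events],
            "trial_type": [e.image_id for e in run.events],
            "pair_id": [e.pair_id for e in run.events],
            "position": [e.position for e in run.events],
            "catch": [int(e.catch) for e in run.events],
        }
    )
    df.to_csv(Path(path), sep="\t", index=False, float_format="%.12g")


def read_events(
    path: str | Path, kind: str = "templating", tr: float = 1.5, n_volumes: int = 203
) -> RunDesign:
    df = pd.read_csv(Path(path), sep="\t")
    events = [
        TrialEvent(
            float(r.onset), float(r.duration), int(r.trial_type),
            int(r.pair_id), str(r.position), bool(r.catch),
        )
        for r in df.itertuples()
    ]
    lead_in = events[0].onset if events else 6.0
    return RunDesign(kind, events, lead_in, tr, n_volumes)
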