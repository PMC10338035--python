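"""Questionnaire and cognitive score derivations.

KIDMED Mediterranean-diet index, Family Affluence Scale categories,
Pubertal Development Scale onset, signal-detection d′ and hit-reaction-time
standard error.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

N_KIDMED_ITEMS = 15
N_KIDMED_POSITIVE = 11  # first 11 items score +1, last 4 score −1


class ScoreError(ValueError):
    pass


def kidmed_score(items) -> int:
    """KIDMED diet index: +1 per endorsed positive item (first 11),
    −1 per endorsed negative item (last 4); range −4..11."""
    items = list(items)
    if len(items) != N_KIDMED_ITEMS:
        raise ScoreError(f"expected {N_KIDMED_ITEMS} KIDMED items, got {len(items)}")
    flags = [bool(v) for v in items]
    return sum(flags[:N_KIDMED_POSITIVE]) - sum(flags[N_KIDMED_POSITIVE:])


def fas_category(score: int) -> str:
    """Family Affluence Scale composite 0–9 → low (0–2), medium (3–5), high (6–9)."""
    if not float(score).is_integer() or not 0 <= score <= 9:
        raise ScoreError(f"FAS composite must be an integer in 0..9, got {score!r}")
    score = int(score)
    if score <= 2:
        return "low"
    if score <= 5:
        return "medium"
    return "high"


def puberty_onset(pds_items, menarche: int | None = None) -> tuple[float, bool]:
    """Pubertal Development Scale mean and onset flag.

    Items are on 1–4 (1 = no development, 4 = completed). For girls the
    menarche item (coded 1 = no, 4 = yes) is included in the mean. Onset is
    defined as mean > 1.
    """
    items = [float(v) for v in pds_items]
    if menarche is not None:
        if menarche not in (1, 4):
            raise ScoreError(f"menarche must be coded 1 (no) or 4 (yes), got {menarche!r}")
        items.append(float(menarche))
    if not items:
        raise ScoreError("no PDS items supplied")
    for v in items:
        if not 1.0 <= v <= 4.0:
            raise ScoreError(f"PDS item {v!r} outside 1..4")
    mean = float(np.mean(items))
    return mean, mean > 1.0


def dprime(hit_rate: float, fa_rate: float, n_trials: int | None = None) -> float:
    """Signal-detection sensitivity d′ = Φ⁻¹(hit rate) − Φ⁻¹(false-alarm rate).

    Rates of exactly 0 or 1 are undefined; when ``n_trials`` is given they
    are clamped to [1/(2n), 1 − 1/(2n)], otherwise they raise.
    """
    if not (0.0 <= hit_rate <= 1.0 and 0.0 <= fa_rate <= 1.0):
        raise ScoreError("rates must lie in [0, 1]")
    if n_trials is not None:
        lo, hi = 1.0 / (2 * n_trials), 1.0 - 1.0 / (2 * n_trials)
        hit_rate = min(max(hit_rate, lo), hi)
        fa_rate = min(max(fa_rate, lo), hi)
    elif hit_rate in (0.0, 1.0) or fa_rate in (0.0, 1.0):
        raise ScoreError("rate of exactly 0 or 1 requires n_trials for the extreme-rate correction")
    return float(norm.ppf(hit_rate) - norm.ppf(fa_rate))


def hrt_se(reaction_times) -> float:
    """Standard error of hit reaction times: SD(times)/√n, n = number of hits."""
    times = np.asarray(list(reaction_times), dtype=float)
    if len(times) < 2:
        raise ScoreError("need at least 2 hit reaction times")
    return float(np.std(times, ddof=1) / np.sqrt(len(times)))
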