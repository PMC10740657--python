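"""Spatial-randomization null model and the paired change tests.

Model validation compares the number of occurrence records a habitat map
captures against a null in which the same number of points is scattered at
random over the woodland-and-forest sampling region (optionally constrained
to the species' model zones).  The null is summarized two ways: the raw
count of iterations equaling or outperforming the model, and a one-tailed
two-proportion z-test (with continuity correction) of the observed capture
proportion against the pooled null draw.

Climate-change impact on the validation records is assessed with McNemar
tests on the paired in/out state of each record under current vs projected
habitat, applying the continuity correction whenever any cell of the 2x2
table is below 5 (a flag restores the more common b+c-only trigger).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .landscape import HabitatMap

__all__ = [
    "RandomizationResult",
    "McNemarResult",
    "randomization_null",
    "one_tailed_z",
    "mcnemar",
]


@dataclass
class RandomizationResult:
    """Outcome of the spatially randomized sampling procedure."""

    observed: int
    n_points: int
    iterations: int
    null_counts: np.ndarray
    seed: int

    @property
    def outperform(self) -> int:
        """Iterations whose capture count equals or exceeds the observed."""
        return int((self.null_counts >= self.observed).sum())

    @property
    def null_total(self) -> int:
        return int(self.null_counts.sum())


def randomization_null(n_points: int, sampling_mask: np.ndarray | HabitatMap,
                       habitat_mask: np.ndarray | HabitatMap,
                       observed: int, iterations: int = 500,
                       seed: int = 0) -> RandomizationResult:
    """Draw the spatial randomization null for one species.

    Each iteration draws ``n_points`` cells uniformly with replacement from
    the sampling region (all woodland and forest cells, already
    zone-constrained by the caller where the species requires it) and
    counts how many fall in the habitat mask.  Deterministic per seed.
    """
    samp = sampling_mask.mask if isinstance(sampling_mask, HabitatMap) else sampling_mask
    hab = habitat_mask.mask if isinstance(habitat_mask, HabitatMap) else habitat_mask
    samp = np.asarray(samp, dtype=bool)
    hab = np.asarray(hab, dtype=bool)
    if samp.shape != hab.shape:
        raise ValueError("sampling and habitat masks must share a grid")
    if not samp.any():
        raise ValueError("sampling mask is empty")
    if n_points < 1 or iterations < 1:
        raise ValueError("n_points and iterations must be >= 1")
    in_hab = hab[samp]  # per sampling-cell membership in habitat
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, in_hab.size, size=(iterations, n_points))
    counts = in_hab[draws].sum(axis=1).astype(int)
    return RandomizationResult(observed=int(observed), n_points=int(n_points),
                               iterations=int(iterations), null_counts=counts,
                               seed=int(seed))


def one_tailed_z(observed: int, n: int, null_counts: np.ndarray
                 ) -> tuple[float | None, float, bool]:
    """One-tailed pooled two-proportion z-test against the aggregated null.

    Compares p1 = observed/n with p2 = (total null captures)/(n x
    iterations).  The continuity correction c = (1/n1 + 1/n2)/2 is
    subtracted from the excess p1 − p2 only when that shrinks it.  Returns
    ``(z, p, degenerate)``; when the pooled proportion is 0 or 1 the z
    statistic is undefined (None) and p comes from the exact degenerate
    comparison with the flag set.
    """
    null_counts = np.asarray(null_counts)
    if n < 1 or null_counts.size < 1:
        raise ValueError("need n >= 1 and at least one iteration")
    n1 = n
    n2 = n * null_counts.size
    p1 = observed / n1
    p2 = float(null_counts.sum()) / n2
    pooled = (observed + null_counts.sum()) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return None, (1.0 if p1 <= p2 else 0.0), True
    diff = p1 - p2
    c = (1.0 / n1 + 1.0 / n2) / 2.0
    if abs(diff) > c:  # apply only when it reduces the excess
        diff = diff - math.copysign(c, diff)
    se = math.sqrt(pooled * (1 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = diff / se
    return z, float(stats.norm.sf(z)), False


@dataclass
class McNemarResult:
    """Paired 2x2 change-test result.

    Cells: a = in/in, b = in/out, c = out/in, d = out/out (current state
    first, projected second).  ``chi2``/``p`` are None when b + c = 0 (the
    statistic is undefined with no discordant pairs).
    """

    a: int
    b: int
    c: int
    d: int
    chi2: float | None
    p: float | None
    correction_applied: bool
    message: str = ""


def mcnemar(b: int, c: int, a: int = 0, d: int = 0,
            correction_rule: str = "any_cell") -> McNemarResult:
    """McNemar test on discordant counts b (in→out) and c (out→in).

    The continuity-corrected statistic (|b−c| − 1)²/(b+c) is used when the
    correction rule triggers, else (b−c)²/(b+c); p is the upper tail of
    chi-square with 1 df.  ``correction_rule``:

    * ``"any_cell"`` (default): correct whenever any of a, b, c, d < 5;
    * ``"discordant"``: correct whenever b + c < 5 (common practice).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be >= 0")
    if correction_rule not in {"any_cell", "discordant"}:
        raise ValueError(f"unknown correction rule {correction_rule!r}")
    if b + c == 0:
        return McNemarResult(a, b, c, d, None, None, False,
                             "no discordant pairs; statistic undefined")
    if correction_rule == "any_cell":
        correct = min(a, b, c, d) < 5
    else:
        correct = (b + c) < 5
    if correct:
        chi2 = (abs(b - c) - 1.0) ** 2 / (b + c)
    else:
        chi2 = (b - c) ** 2 / (b + c)
    p = float(stats.chi2.sf(chi2, df=1))
    return McNemarResult(a, b, c, d, float(chi2), p, correct)
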