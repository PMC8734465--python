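"""Null-model simulation and Monte Carlo envelope tests.

Two families of null models:

* complete spatial randomness (CSR) conditioned on the observed number of
  points — the null for the pair-correlation function;
* random labelling — tree locations fixed, marks shuffled, either over
  all trees (univariate mark correlation) or over the non-focal pattern
  only (bivariate Schlather's I).

The envelope is pointwise: with ``nsim`` null replicates and envelope
rank ``k``, the lower/upper bounds at each lag are the k-th smallest and
k-th largest simulated values, a two-sided test of nominal pointwise
level ``2k/(nsim+1)`` (0.05 for the default 199 simulations, k = 5).
Pointwise envelopes read per lag are liberal as a global test across
lags; a rank-corrected global envelope is deliberately out of scope.

Replicate randomness comes from per-replicate substreams spawned from a
single seed sequence, so replicate i is the same whatever ``nsim`` is and
results are independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .census import PlotWindow
from .errors import ConfigurationError, StandppError
from .pointpattern import (EstimatorCurve, LagSpec, MarkedPattern,
                           mark_correlation, pcf_estimate, schlather_I)

__all__ = [
    "NullSpec",
    "EnvelopeResult",
    "simulate_csr",
    "shuffle_marks",
    "envelope_test",
]

#: statistic -> admissible null model
_COMPATIBLE = {
    "g": "csr",
    "kmm": "shuffle_marks_all",
    "I": "shuffle_marks_nonfocal",
}


@dataclass(frozen=True)
class NullSpec:
    """Null-model configuration for an envelope test."""

    model: str  # csr | shuffle_marks_all | shuffle_marks_nonfocal
    nsim: int = 199
    rank: int = 5
    seed: int | None = None

    def __post_init__(self):
        if self.model not in ("csr", "shuffle_marks_all", "shuffle_marks_nonfocal"):
            raise ConfigurationError(f"unknown null model {self.model!r}")
        if self.nsim < 1:
            raise ConfigurationError("nsim must be >= 1")
        if not (1 <= self.rank <= self.nsim // 2):
            raise ConfigurationError("envelope rank must satisfy 1 <= k <= nsim/2")

    @property
    def pointwise_level(self) -> float:
        """Nominal two-sided pointwise level 2k/(nsim+1)."""
        return 2.0 * self.rank / (self.nsim + 1.0)


@dataclass
class EnvelopeResult:
    """Observed curve with pointwise simulation envelope and per-lag calls."""

    statistic: str
    r: np.ndarray
    observed: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    calls: np.ndarray  # "below" | "within" | "above" per lag
    null: NullSpec
    simulated: np.ndarray | None = None  # (nsim, n_lags), kept for diagnostics

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "r": self.r, "observed": self.observed,
            "lower": self.lower, "upper": self.upper, "call": self.calls,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @property
    def fraction_outside(self) -> float:
        return float(np.mean(self.calls != "within"))


def simulate_csr(n: int, window: PlotWindow, rng: np.random.Generator) -> MarkedPattern:
    """``n`` points uniform iid on the window (binomial process, fixed n)."""
    if n < 0:
        raise StandppError("n must be >= 0")
    x0, y0 = window.origin
    pts = rng.uniform((x0, y0), (x0 + window.width, y0 + window.height), size=(n, 2))
    return MarkedPattern(pts.reshape(-1, 2), window)


def shuffle_marks(pattern: MarkedPattern, rng: np.random.Generator,
                  scope: np.ndarray | None = None) -> MarkedPattern:
    """Random labelling: coordinates fixed, marks permuted within ``scope``.

    ``scope`` is a boolean mask of the points whose marks are shuffled
    (default: all); marks outside the scope are untouched and the mark
    multiset inside the scope is preserved exactly.
    """
    if pattern.marks is None:
        raise StandppError("shuffle_marks requires marks")
    if scope is None:
        scope = np.ones(pattern.n, dtype=bool)
    scope = np.asarray(scope, dtype=bool)
    if scope.shape[0] != pattern.n:
        raise StandppError("scope mask must align with points")
    idx = np.flatnonzero(scope)
    if idx.size == 0:
        raise StandppError("shuffle scope selects zero points")
    marks = pattern.marks.copy()
    marks[idx] = marks[rng.permutation(idx)]
    return MarkedPattern(pattern.points.copy(), pattern.window, marks,
                         None if pattern.species is None else pattern.species.copy())


def _observed_and_simulator(statistic, pattern, other, spec, null):
    """Return (observed curve, replicate function rng -> values)."""
    if statistic == "g":
        obs = pcf_estimate(pattern, spec)
        n, window = pattern.n, pattern.window

        def replicate(rng):
            return pcf_estimate(simulate_csr(n, window, rng), spec).values
    elif statistic == "kmm":
        obs = mark_correlation(pattern, spec)

        def replicate(rng):
            return mark_correlation(shuffle_marks(pattern, rng), spec).values
    elif statistic == "I":
        if other is None:
            raise ConfigurationError("Schlather's I needs focal and other patterns")
        obs = schlather_I(pattern, other, spec)

        def replicate(rng):
            return schlather_I(pattern, shuffle_marks(other, rng), spec).values
    else:
        raise ConfigurationError(f"unknown statistic {statistic!r}")
    return obs, replicate


def envelope_test(pattern: MarkedPattern, statistic: str,
                  spec: LagSpec | None = None, null: NullSpec | None = None,
                  other: MarkedPattern | None = None,
                  threads: int = 1) -> EnvelopeResult:
    """Monte Carlo envelope test of one spatial statistic.

    Runs ``null.nsim`` replicates of the matching null model, recomputes
    the statistic on each, and classifies the observed curve per lag as
    ``below``, ``within`` or ``above`` the rank-k envelope.

    ``statistic`` is one of ``g`` (CSR null), ``kmm`` (marks shuffled over
    all trees) or ``I`` (marks shuffled over the non-focal pattern).  A
    mismatched statistic/null pairing is a configuration error.
    """
    if null is None:
        null = NullSpec(model=_COMPATIBLE[statistic])
    if statistic not in _COMPATIBLE:
        raise ConfigurationError(f"unknown statistic {statistic!r}")
    if null.model != _COMPATIBLE[statistic]:
        raise ConfigurationError(
            f"null model {null.model!r} incompatible with statistic {statistic!r} "
            f"(expected {_COMPATIBLE[statistic]!r})")
    if spec is None:
        spec = LagSpec() if statistic == "g" else LagSpec.mark_default()

    obs, replicate = _observed_and_simulator(statistic, pattern, other, spec, null)
    streams = np.random.SeedSequence(null.seed).spawn(null.nsim)

    def run_one(ss):
        return replicate(np.random.Generator(np.random.PCG64(ss)))

    if threads > 1:
        from joblib import Parallel, delayed
        sims = Parallel(n_jobs=threads, prefer="threads")(
            delayed(run_one)(ss) for ss in streams)
    else:
        sims = [run_one(ss) for ss in streams]
    sims = np.asarray(sims)  # (nsim, n_lags)

    order = np.sort(sims, axis=0)
    lower = order[null.rank - 1]
    upper = order[null.nsim - null.rank]
    calls = np.where(obs.values < lower, "below",
                     np.where(obs.values > upper, "above", "within"))
    return EnvelopeResult(statistic, obs.r, obs.values, lower, upper,
                          calls.astype(object), null, simulated=sims)
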