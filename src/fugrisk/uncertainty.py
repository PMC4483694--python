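"""One-at-a-time relative sensitivity and Monte Carlo uncertainty propagation.

Relative sensitivity of the total risk R_t to a scalar parameter alpha under
a multiplicative perturbation (factors 0.9 and 1.1)::

    S = (dR_t / R_t) / (dalpha / alpha)

reported as a percentage; +100% means R_t scales one-for-one with alpha.

Monte Carlo: parameters carry triangular (or degenerate point) distributions
organised in three groups -- 1: environmental/physicochemical (entering
through triangular rescaling of the point-estimate concentrations, which
sidesteps their mutual correlation), 2: exposure factors, 3: dose-response
factors.  Groups not varied are held at their point estimates.  Sampling is
reproducible: one master seed, per-parameter derived streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .media import ParameterError


class SensitivityError(RuntimeError):
    """Sensitivity is undefined (e.g. zero baseline output)."""


# ---------------------------------------------------------------------------
# one-at-a-time sensitivity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SensitivityRecord:
    parameter: str
    factor: float
    s_bar_percent: float


def relative_sensitivity(
    runner: Callable[[Mapping[str, float]], float],
    parameter: str,
    factor: float,
    baseline: float | None = None,
) -> SensitivityRecord:
    """Relative sensitivity from a full model re-run at ``alpha * factor``.

    ``runner`` maps an override dict ({parameter: factor}) to the scalar
    model output (here: mean annual total risk).
    """
    if baseline is None:
        baseline = runner({})
    if baseline == 0:
        raise SensitivityError(
            f"baseline output is 0; sensitivity to {parameter!r} undefined"
        )
    if factor == 1.0:
        raise ParameterError("perturbation factor must differ from 1")
    perturbed = runner({parameter: factor})
    s = ((perturbed - baseline) / baseline) / (factor - 1.0)
    if not np.isfinite(s):
        raise SensitivityError(f"non-finite sensitivity for {parameter!r}")
    return SensitivityRecord(
        parameter=parameter, factor=factor, s_bar_percent=100.0 * s
    )


def rank_parameters(
    runner: Callable[[Mapping[str, float]], float],
    parameters: Sequence[str],
    factors: Sequence[float] = (1.1, 0.9),
    baseline: float | None = None,
) -> pd.DataFrame:
    """Evaluate every (parameter, factor) pair; sort by max |S| per parameter.

    Output has one row per parameter and one column per factor, mirroring
    the usual report layout of OAT sensitivity tables.
    """
    if baseline is None:
        baseline = runner({})
    records = {
        p: {
            f: relative_sensitivity(runner, p, f, baseline).s_bar_percent
            for f in factors
        }
        for p in parameters
    }
    df = pd.DataFrame.from_dict(records, orient="index")
    df.columns = [f"s_bar_{f}" for f in factors]
    df.index.name = "parameter"
    df["max_abs_s"] = df.abs().max(axis=1)
    return df.sort_values("max_abs_s", ascending=False).drop(columns="max_abs_s")


# ---------------------------------------------------------------------------
# distributions and sampling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterDistribution:
    """Uncertainty assignment for one parameter.

    ``family`` is "triangular" (params = (a, m, b) with a <= m <= b) or
    "point" (params = (m,)).  ``group`` is 1 (environmental/physicochemical,
    applied as relative concentration rescaling), 2 (exposure) or 3
    (dose-response).  ``relative`` marks multiplier distributions (the draw
    scales the point estimate instead of replacing it).
    """

    path: str
    family: str
    params: tuple
    group: int
    relative: bool = False

    def __post_init__(self) -> None:
        if self.group not in (1, 2, 3):
            raise ParameterError(f"group must be 1, 2 or 3, got {self.group}")
        if self.family == "triangular":
            a, m, b = self.params
            if not (a <= m <= b) or a == b:
                raise ParameterError(
                    f"triangular parameters must satisfy a <= m <= b (a < b), got {self.params}"
                )
        elif self.family == "point":
            if len(self.params) != 1:
                raise ParameterError("point distribution takes a single value")
        else:
            raise ParameterError(f"unknown distribution family {self.family!r}")

    @property
    def point(self) -> float:
        """The point estimate (mode for triangular)."""
        return self.params[1] if self.family == "triangular" else self.params[0]


def sample(dist: ParameterDistribution, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` values; triangular sampling uses the inverse CDF."""
    if n < 1:
        raise ParameterError(f"sample size must be >= 1, got {n}")
    if dist.family == "point":
        return np.full(n, dist.params[0])
    a, m, b = dist.params
    return rng.triangular(a, m, b, size=n)


def triangular_cdf(x, a: float, m: float, b: float):
    """Closed-form triangular CDF (vectorized), for sampler verification."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    left = (x > a) & (x <= m)
    right = (x > m) & (x < b)
    if m > a:
        out[left] = (x[left] - a) ** 2 / ((b - a) * (m - a))
    if b > m:
        out[right] = 1.0 - (b - x[right]) ** 2 / ((b - a) * (b - m))
    out[x >= b] = 1.0
    return out


# ---------------------------------------------------------------------------
# Monte Carlo
# ---------------------------------------------------------------------------


@dataclass
class MonteCarloResult:
    """Per-draw total risks plus empirical-CDF summaries."""

    samples: np.ndarray
    point_estimate: float
    draws: pd.DataFrame
    percentiles: Mapping[int, float] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return int(self.samples.shape[0])

    def cdf(self, x: float) -> float:
        """Empirical CDF of the sampled risks at ``x``."""
        return float(np.count_nonzero(self.samples <= x)) / self.n

    def cdf_table(self) -> pd.DataFrame:
        s = np.sort(self.samples)
        return pd.DataFrame({
            "risk": s, "cumulative_probability": np.arange(1, self.n + 1) / self.n
        })


def monte_carlo(
    evaluator: Callable[[Mapping[str, float]], float],
    dists: Sequence[ParameterDistribution],
    groups: Sequence[int],
    n: int,
    seed: int,
    point_estimate: float | None = None,
) -> MonteCarloResult:
    """Propagate parameter uncertainty through the risk evaluator.

    ``evaluator`` maps {parameter path: sampled value} to a total risk;
    parameters whose group is not in ``groups`` are held at their point
    estimates.  Draws are independent across parameters; each parameter gets
    its own RNG stream derived from the master seed (keyed by path order),
    so results are bit-reproducible for a given seed and distribution list.
    """
    if n < 1:
        raise ParameterError(f"Monte Carlo sample count must be >= 1, got {n}")
    groups = set(groups)
    ss = np.random.SeedSequence([int(seed) % (2**31), 29])
    streams = ss.spawn(len(dists))
    columns: dict[str, np.ndarray] = {}
    for dist, stream in zip(dists, streams):
        if dist.group in groups:
            columns[dist.path] = sample(dist, n, np.random.default_rng(stream))
        else:
            columns[dist.path] = np.full(n, dist.point)
    samples = np.array([
        evaluator({path: columns[path][i] for path in columns}) for i in range(n)
    ])
    if point_estimate is None:
        point_estimate = float(evaluator({d.path: d.point for d in dists}))
    draws = pd.DataFrame(columns)
    draws.insert(0, "draw", np.arange(n))
    draws["r_total"] = samples
    return MonteCarloResult(
        samples=samples,
        point_estimate=point_estimate,
        draws=draws,
        percentiles={
            p: float(np.percentile(samples, p)) for p in (1, 5, 25, 50, 75, 95, 99)
        },
    )


def compare_point_vs_cdf(mc: MonteCarloResult, point: float | None = None) -> dict:
    """Where the deterministic point estimate falls within the sampled CDF."""
    point = mc.point_estimate if point is None else point
    return {
        "point_estimate": point,
        "cdf_at_point": mc.cdf(point),
        "sample_mean": float(mc.samples.mean()),
        "sample_median": float(np.median(mc.samples)),
        "percentiles": dict(mc.percentiles),
    }
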