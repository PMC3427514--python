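"""Stochastic exploration of the 27-dimensional parameter space.

Three campaign styles are supported: blind i.i.d. sampling of a box
(uniform or log-uniform per coordinate), multiplicative perturbation of a
reference set (each coordinate scaled by an independent uniform factor in
[1-f, 1+f]), and an automated guided search that iteratively narrows the
sampling box around physiological hits until a verification batch is
entirely physiological.

All draws come from a seeded Mersenne-twister generator, so campaigns
are exactly reproducible from (generation spec, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .geometry import DomainSpec, build_grid
from .model import PARAM_NAMES, ModelParameters, check_constraints
from .numerics import NumericsConfig, System
from .simulation import (ClassificationReport, ClassifierConfig,
                         classify_solution, run_simulation)

__all__ = [
    "SampleSet", "ScreeningSummary", "sample_parameters",
    "perturb_parameters", "screen", "guided_search", "GuidedSearchResult",
]

CATEGORIES = ("physiological", "non_neurogenic", "unphysical")


def _rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.MT19937(seed))


@dataclass
class SampleSet:
    """A reproducible batch of parameter sets."""

    samples: list[ModelParameters]
    seed: int
    generation_spec: dict
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.ids:
            self.ids = [f"s{k:04d}" for k in range(len(self.samples))]

    def __len__(self) -> int:
        return len(self.samples)

    def as_matrix(self) -> np.ndarray:
        return np.stack([p.as_array() for p in self.samples])


def _normalize_ranges(ranges) -> dict[str, tuple[float, float]]:
    if isinstance(ranges, tuple) and len(ranges) == 2 \
            and np.isscalar(ranges[0]):
        ranges = {k: (float(ranges[0]), float(ranges[1]))
                  for k in PARAM_NAMES}
    out = {}
    for k in PARAM_NAMES:
        lo, hi = ranges[k]
        if not (hi > lo):
            raise ValueError(f"invalid interval for {k}: ({lo}, {hi})")
        out[k] = (float(lo), float(hi))
    return out


def sample_parameters(ranges, distribution: str, n: int, seed: int
                      ) -> SampleSet:
    """Draw ``n`` parameter sets, each coordinate i.i.d. on its interval.

    ``ranges`` is either one (lo, hi) pair applied to every coordinate or
    a mapping name -> (lo, hi).  ``distribution`` is 'uniform' or
    'log-uniform' (the latter needs positive bounds).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    box = _normalize_ranges(ranges)
    if distribution not in ("uniform", "log-uniform"):
        raise ValueError(f"unknown distribution {distribution!r}")
    if distribution == "log-uniform":
        for k, (lo, hi) in box.items():
            if lo <= 0:
                raise ValueError(f"log-uniform needs positive bounds ({k})")
    rng = _rng(seed)
    lo = np.array([box[k][0] for k in PARAM_NAMES])
    hi = np.array([box[k][1] for k in PARAM_NAMES])
    u = rng.random((n, len(PARAM_NAMES)))
    if distribution == "uniform":
        theta = lo + u * (hi - lo)
    else:
        theta = np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo)))
    samples = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for row in theta:
            samples.append(ModelParameters.from_array(row))
    return SampleSet(samples, seed,
                     {"kind": "box", "distribution": distribution,
                      "ranges": box, "n": n})


def perturb_parameters(reference: ModelParameters, fraction: float,
                       n: int, seed: int) -> SampleSet:
    """Each coordinate multiplied by an independent uniform factor in
    (1-fraction, 1+fraction)."""
    if not (0 < fraction < 1):
        raise ValueError("fraction must lie in (0, 1)")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    ref = reference.as_array()
    u = rng.uniform(-fraction, fraction, size=(n, ref.size))
    theta = ref * (1.0 + u)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        samples = [ModelParameters.from_array(row) for row in theta]
    return SampleSet(samples, seed,
                     {"kind": "perturb", "fraction": fraction, "n": n,
                      "reference": reference.to_dict()})


@dataclass
class ScreeningSummary:
    """Aggregate of one screening campaign."""

    counts: dict[str, int]
    reports: list[ClassificationReport]
    ids: list[str]
    final_signals: np.ndarray
    constraint_passed: list[bool]
    zeta2: Optional[np.ndarray] = None
    most_neurogenic: Optional[str] = None
    least_neurogenic: Optional[str] = None
    n_failed: int = 0

    def category_of(self, sid: str) -> str:
        return self.reports[self.ids.index(sid)].category

    def to_frame(self):
        import pandas as pd

        d = {"id": self.ids,
             "category": [r.category for r in self.reports],
             "final_ob_signal": self.final_signals,
             "constraints_passed": self.constraint_passed}
        if self.zeta2 is not None:
            d["zeta2"] = self.zeta2
        return pd.DataFrame(d)


def screen(samples: SampleSet, spec: DomainSpec | None = None,
           config: NumericsConfig | None = None,
           classifier: ClassifierConfig | None = None,
           reference_result=None,
           progress: bool = False,
           callback: Callable[[str, ClassificationReport], None] | None = None,
           ) -> ScreeningSummary:
    """Simulate and classify every sample.

    Constraint screening is recorded but never skips a run.  When a
    ``reference_result`` is given, the deviation metric zeta^2 of every
    non-failed run against it is recorded as well (full trajectories are
    discarded after each sample to bound memory).
    """
    if len(samples) == 0:
        raise ValueError("empty sample set")
    spec = spec or DomainSpec()
    config = config or NumericsConfig()
    grid = build_grid(spec)
    system = System(grid)
    system.jac_sparsity()           # build once, reuse across samples
    reports, flags, sigs = [], [], []
    z2 = [] if reference_result is not None else None
    if reference_result is not None:
        from .sloppiness import zeta_squared
    n_failed = 0
    for k, params in enumerate(samples.samples):
        res = run_simulation(params, spec, config, grid=grid, system=system)
        rep = classify_solution(res, params, classifier)
        reports.append(rep)
        flags.append(bool(res.constraints.passed))
        sigs.append(res.readouts["ob_signal"].final
                    if res.n_saved else 0.0)
        n_failed += int(res.failure_flag)
        if z2 is not None:
            ok = (not res.failure_flag
                  and res.n_saved == reference_result.n_saved)
            z2.append(zeta_squared(res, reference_result) if ok else np.nan)
        if callback is not None:
            callback(samples.ids[k], rep)
        if progress:
            print(f"  [{k + 1}/{len(samples)}] {samples.ids[k]}: "
                  f"{rep.category}", flush=True)
    counts = {c: 0 for c in CATEGORIES}
    for r in reports:
        counts[r.category] += 1
    sigs = np.asarray(sigs)
    order = np.argsort(sigs)
    return ScreeningSummary(
        counts=counts, reports=reports, ids=list(samples.ids),
        final_signals=sigs, constraint_passed=flags,
        zeta2=None if z2 is None else np.asarray(z2),
        most_neurogenic=samples.ids[int(order[-1])],
        least_neurogenic=samples.ids[int(order[0])],
        n_failed=n_failed)


@dataclass
class GuidedSearchResult:
    final_ranges: dict[str, tuple[float, float]]
    range_history: list[dict[str, tuple[float, float]]]
    hits: SampleSet
    hit_rates: list[float]
    converged: bool


def guided_search(start_ranges, rounds: int, samples_per_round: int,
                  seed: int,
                  spec: DomainSpec | None = None,
                  config: NumericsConfig | None = None,
                  verification_n: int = 200,
                  pad: float = 0.2,
                  runner: Callable[[ModelParameters], str] | None = None,
                  ) -> GuidedSearchResult:
    """Iteratively narrow the sampling box around physiological hits.

    Each round draws ``samples_per_round`` sets uniformly from the
    current box, classifies them (via ``runner`` if given — a callable
    mapping parameters to a category, injectable for testing — otherwise
    by full simulation), and shrinks every coordinate range to the span
    of the physiological hits padded by ``pad`` on each side.  After any
    round with hits, a verification batch of ``verification_n`` draws is
    classified; the search stops early when that batch is entirely
    physiological (the stopping rule).
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    ranges = _normalize_ranges(start_ranges)
    if runner is None:
        def runner(params: ModelParameters) -> str:     # noqa: F811
            res = run_simulation(params, spec or DomainSpec(),
                                 config or NumericsConfig())
            return classify_solution(res, params).category

    history = [dict(ranges)]
    hit_params: list[ModelParameters] = []
    hit_ids: list[str] = []
    rates: list[float] = []
    converged = False
    for rnd in range(rounds):
        batch = sample_parameters(ranges, "uniform", samples_per_round,
                                  seed + rnd)
        cats = [runner(p) for p in batch.samples]
        hits = [p for p, c in zip(batch.samples, cats) if c == "physiological"]
        rates.append(len(hits) / samples_per_round)
        for j, p in enumerate(hits):
            hit_ids.append(f"r{rnd}h{j}")
            hit_params.append(p)
        if not hits:
            warnings.warn(f"guided search round {rnd}: no physiological "
                          "hits, ranges unchanged", stacklevel=2)
        else:
            mat = np.stack([p.as_array() for p in hits])
            lo, hi = mat.min(axis=0), mat.max(axis=0)
            span = np.maximum(hi - lo, 1e-12 * np.maximum(np.abs(hi), 1.0))
            cur_lo = np.array([ranges[k][0] for k in PARAM_NAMES])
            cur_hi = np.array([ranges[k][1] for k in PARAM_NAMES])
            # pad the hit span, but never widen beyond the current box
            lo2 = np.clip(lo - pad * span, cur_lo, None)
            hi2 = np.clip(hi + pad * span, None, cur_hi)
            ranges = {k: (float(lo2[i]), float(hi2[i]))
                      for i, k in enumerate(PARAM_NAMES)}
            history.append(dict(ranges))
            verify = sample_parameters(ranges, "uniform", verification_n,
                                       seed + 10_000 + rnd)
            if all(runner(p) == "physiological" for p in verify.samples):
                converged = True
                break
    hits_set = SampleSet(hit_params, seed,
                         {"kind": "guided", "rounds": rounds,
                          "samples_per_round": samples_per_round},
                         ids=hit_ids)
    return GuidedSearchResult(ranges, history, hits_set, rates, converged)
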