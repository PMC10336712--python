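"""Low-level MCMC utilities: univariate slice sampling and step adaptation.

The slice sampler is Neal's stepping-out-and-shrinkage procedure for a
univariate log-density, optionally bounded.  It needs no tuning beyond an
initial step width, which makes it a safe choice for the non-conjugate
scalar hyperparameters of the hierarchy (eta, kappa, nu).
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np


def slice_sample(
    logf: Callable[[float], float],
    x0: float,
    w: float,
    rng: np.random.Generator,
    lower: float = -math.inf,
    upper: float = math.inf,
    max_steps: int = 50,
) -> float:
    """One update of a univariate slice sampler with stepping out.

    ``logf`` is the log target up to a constant; ``x0`` must lie in the
    support.  ``lower``/``upper`` bound the support (the interval is clipped
    to them before shrinkage).
    """
    fx0 = logf(x0)
    if not np.isfinite(fx0):
        raise ValueError("slice_sample: initial point outside support")
    logy = fx0 + math.log(rng.random() + 1e-300)

    u = rng.random()
    left = x0 - w * u
    right = left + w
    j = int(math.floor(max_steps * rng.random()))
    k = max_steps - 1 - j
    while j > 0 and left > lower and logf(left) > logy:
        left -= w
        j -= 1
    while k > 0 and right < upper and logf(right) > logy:
        right += w
        k -= 1
    left = max(left, lower)
    right = min(right, upper)

    for _ in range(1000):
        x1 = left + (right - left) * rng.random()
        if logf(x1) >= logy:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
        if right - left < 1e-15:
            return x0
    return x0


class StepAdapter:
    """Robbins-Monro adaptation of per-coordinate Metropolis step sizes.

    Drives the acceptance rate toward ``target`` during burn-in; callers
    must freeze (stop calling :meth:`update`) afterwards so the chain is a
    valid time-homogeneous Markov chain.
    """

    def __init__(self, n: int, initial: float = 0.5, target: float = 0.44):
        self.log_step = np.full(n, math.log(initial))
        self.target = target
        self._t = 0

    @property
    def step(self) -> np.ndarray:
        return np.exp(self.log_step)

    def update(self, accepted: np.ndarray) -> None:
        self._t += 1
        gain = min(0.5, 2.0 / math.sqrt(self._t))
        self.log_step += gain * (accepted.astype(float) - self.target)
        np.clip(self.log_step, math.log(1e-4), math.log(50.0), out=self.log_step)
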