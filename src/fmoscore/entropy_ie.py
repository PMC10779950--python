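"""Interaction-entropy estimator for the gas-phase binding entropy term.

Given a time series E_t of protein--ligand gas-phase interaction energies
from an MD trajectory, the interaction-entropy (IE) method estimates

    -T*dS = kB*T * ln < exp(beta * dE) >,   dE_t = E_t - <E>,  beta = 1/(kB*T)

i.e. the log of the ensemble-averaged exponential of the mean-centred
fluctuation.  By Jensen's inequality the estimate is non-negative, and it is
invariant to adding a constant to the whole series.  The exponential average
is evaluated through a max-shifted log-sum-exp: at 300 K beta is about
1.68 mol/kcal, so a naive exp overflows for fluctuations of a few hundred
kcal/mol and loses precision long before that.

The estimator converges slowly (it is an exponential average), hence the
block diagnostic: estimates over contiguous sub-blocks whose spread indicates
whether the trajectory is long enough.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .errors import DegenerateInputError
from .thermo import DEFAULT_TEMPERATURE, KB_KCAL_PER_MOL_K

__all__ = [
    "DOMINATION_THRESHOLD",
    "InteractionSeries",
    "BlockDiagnostics",
    "interaction_entropy",
    "block_estimates",
]

#: When beta*max(dE) exceeds this, a handful of frames dominate the
#: exponential average and the estimate is untrustworthy.
DOMINATION_THRESHOLD = 20.0


@dataclass
class InteractionSeries:
    """Ordered protein--ligand interaction energies (kcal/mol) at a temperature (K)."""

    values: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size < 1:
            raise ValueError("series must contain at least one value")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("interaction energies must be finite")
        if not (np.isfinite(self.temperature) and self.temperature > 0):
            raise ValueError(f"temperature must be positive, got {self.temperature}")

    def __len__(self) -> int:
        return int(self.values.size)


def interaction_entropy(s: InteractionSeries, warn_domination: bool = True) -> float:
    """-T*dS in kcal/mol from the fluctuation of the interaction energy.

    Requires at least two frames.  Evaluated as
    ``kB*T * (logsumexp(beta*dE) - ln N)`` which cannot overflow; the result
    is clamped at zero against sub-epsilon negative rounding (mathematically
    it is >= 0).  Warns when a single frame dominates the average
    (``beta*max(dE) >`` :data:`DOMINATION_THRESHOLD`).
    """
    n = len(s)
    if n < 2:
        raise DegenerateInputError(
            "interaction entropy needs >= 2 frames to measure a fluctuation"
        )
    kt = KB_KCAL_PER_MOL_K * s.temperature
    beta = 1.0 / kt
    de = s.values - s.values.mean()
    arg = beta * de
    if warn_domination and arg.max() > DOMINATION_THRESHOLD:
        warnings.warn(
            f"beta*max(dE) = {arg.max():.1f} > {DOMINATION_THRESHOLD}: the exponential "
            "average is dominated by a few frames; the IE estimate is unreliable",
            stacklevel=2,
        )
    val = kt * (logsumexp(arg) - np.log(n))
    return max(float(val), 0.0)


@dataclass(frozen=True)
class BlockDiagnostics:
    """Per-block IE estimates and their spread (all kcal/mol)."""

    estimates: list[float]
    mean: float
    spread: float  # max - min over blocks


def block_estimates(s: InteractionSeries, n_blocks: int) -> BlockDiagnostics:
    """IE over ``n_blocks`` contiguous equal-length blocks, as a convergence check.

    Each block has ``N // n_blocks`` frames (a short remainder at the end is
    dropped); requires ``N >= 2 * n_blocks`` so every block holds a
    fluctuation.  Well-converged series give near-identical block estimates.
    """
    if n_blocks < 1:
        raise ValueError(f"n_blocks must be >= 1, got {n_blocks}")
    n = len(s)
    if n < 2 * n_blocks:
        raise DegenerateInputError(
            f"need at least {2 * n_blocks} frames for {n_blocks} blocks, got {n}"
        )
    size = n // n_blocks
    ests = []
    for b in range(n_blocks):
        chunk = s.values[b * size : (b + 1) * size]
        ests.append(
            interaction_entropy(
                InteractionSeries(values=chunk, temperature=s.temperature),
                warn_domination=False,
            )
        )
    return BlockDiagnostics(
        estimates=ests, mean=float(np.mean(ests)), spread=float(np.max(ests) - np.min(ests))
    )
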