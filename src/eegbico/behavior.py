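"""Up-down (staircase) estimation of the 50% paw-withdrawal threshold.

A series of von Frey filaments with approximately equal log10 spacing is
applied: after a withdrawal (positive response) the next weaker filament is
used, after no response the next stronger, and the staircase ends a fixed
number of stimuli after the first change in response. The 50% threshold is

    PWT50 = 10^(X_f + k * delta) / 10^4   [grams],

where X_f is log10 of the last filament force expressed in 0.1 mg units
(log10(10^4 * grams)), delta is the mean log10 spacing of the ladder, and
k is a correction read from a table indexed by the terminal pattern of
positive/negative responses. The packaged k-table is Dixon-style but
generated here: for each terminal pattern, k is the probit
maximum-likelihood threshold (with sigma fixed at one ladder step)
expressed in steps relative to the last filament. Its provenance is this
package, not any published tabulation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "FilamentLadder",
    "UpDownSequence",
    "KTable",
    "PWTEstimate",
    "CHAPLAN_LADDER",
    "mean_log_interval",
    "pwt50",
    "pwt50_from_last",
    "build_k_table",
    "load_k_table",
    "estimator_study",
    "UnknownPatternError",
]

POSITIVE, NEGATIVE = "X", "O"


class UnknownPatternError(KeyError):
    """A terminal response pattern missing from the k-table."""


@dataclass(frozen=True)
class FilamentLadder:
    """Ordered von Frey filament bending forces in grams."""

    forces: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.forces) < 2:
            raise ValueError("ladder needs at least two filaments")
        if any(b <= a for a, b in zip(self.forces, self.forces[1:])):
            raise ValueError("filament forces must be strictly increasing")
        if self.forces[0] <= 0:
            raise ValueError("forces must be positive")

    @property
    def log_forces(self) -> np.ndarray:
        return np.log10(np.asarray(self.forces))

    @property
    def delta(self) -> float:
        """Mean log10 interval between successive filaments."""
        return float(np.mean(np.diff(self.log_forces)))


#: The standard eight-filament ladder used for rodent mechanical allodynia.
CHAPLAN_LADDER = FilamentLadder((0.41, 0.70, 1.20, 2.00, 3.63, 5.50, 8.50, 15.10))


def mean_log_interval(ladder: FilamentLadder) -> float:
    """Mean log10 spacing of the ladder (delta of the threshold formula)."""
    return ladder.delta


@dataclass
class UpDownSequence:
    """An ordered staircase of (force_g, response) trials.

    ``response`` is 1 for withdrawal (positive), 0 for no response.
    ``terminated`` is True when the staircase ended by the stopping rule
    (six stimuli after the first change by default) rather than by
    saturating at a ladder boundary without any response change.
    """

    trials: list[tuple[float, int]]
    first_change_index: int | None = None
    terminated: bool = False

    def __post_init__(self) -> None:
        if not self.trials:
            raise ValueError("sequence has no trials")
        if self.first_change_index is None:
            for i in range(1, len(self.trials)):
                if self.trials[i][1] != self.trials[i - 1][1]:
                    self.first_change_index = i
                    break

    @property
    def responses(self) -> str:
        return "".join(POSITIVE if r else NEGATIVE for _, r in self.trials)

    @property
    def terminal_pattern(self) -> str | None:
        """Responses from the trial before the first change to the end."""
        if self.first_change_index is None:
            return None
        return self.responses[self.first_change_index - 1 :]

    @property
    def last_force(self) -> float:
        return self.trials[-1][0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.trials, columns=["force_g", "response"])


@dataclass
class KTable:
    """Correction values k indexed by terminal response pattern."""

    values: dict[str, float] = field(default_factory=dict)

    def lookup(self, pattern: str) -> float:
        try:
            return self.values[pattern]
        except KeyError:
            raise UnknownPatternError(
                f"terminal pattern {pattern!r} not in k-table "
                f"({len(self.values)} known patterns)"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.values.items()), columns=["pattern", "k"]
        )


def _probit_mle(x_steps: np.ndarray, responses: np.ndarray) -> float:
    """ML threshold of a probit model with sigma = 1 ladder step.

    The log-likelihood sum(r*log Phi(x-theta) + (1-r)*log Phi(theta-x))
    is concave in theta, so a scalar bounded search suffices.
    """
    from scipy.optimize import minimize_scalar
    from scipy.stats import norm

    def nll(theta: float) -> float:
        z = x_steps - theta
        return -float(
            np.sum(responses * norm.logcdf(z) + (1 - responses) * norm.logcdf(-z))
        )

    lo, hi = x_steps.min() - 3.0, x_steps.max() + 3.0
    res = minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x)


def build_k_table(n_post_change: int = 6) -> KTable:
    """Enumerate terminal patterns and compute each k by probit ML.

    A terminal pattern is the response before the first change, the change
    itself, then ``n_post_change`` free responses. The filament trajectory
    is reconstructed from the pattern (down one step after X, up after O,
    no boundary saturation assumed), and
    k = theta_hat - x_last in ladder-step units.
    """
    table: dict[str, float] = {}
    for first in (POSITIVE, NEGATIVE):
        second = NEGATIVE if first == POSITIVE else POSITIVE
        for tail_bits in range(2 ** n_post_change):
            tail = "".join(
                POSITIVE if (tail_bits >> i) & 1 else NEGATIVE
                for i in range(n_post_change)
            )
            pattern = first + second + tail
            x = np.zeros(len(pattern))
            for i, r in enumerate(pattern[:-1]):
                x[i + 1] = x[i] + (-1.0 if r == POSITIVE else 1.0)
            resp = np.array([1.0 if r == POSITIVE else 0.0 for r in pattern])
            theta = _probit_mle(x, resp)
            table[pattern] = round(theta - x[-1], 4)
    return KTable(table)


def load_k_table() -> KTable:
    """Load the packaged k-table (identical to ``build_k_table()``)."""
    text = resources.files("eegbico.data").joinpath("k_table.csv").read_text()
    df = pd.read_csv(io.StringIO(text), comment="#")
    return KTable(dict(zip(df["pattern"], df["k"].astype(float))))


@dataclass
class PWTEstimate:
    """A 50% withdrawal threshold estimate with boundary bookkeeping.

    ``censored`` is 'none' for an interior estimate, 'below'/'above' when
    the staircase saturated at the weakest/strongest filament (the value
    is then the boundary force, to be read as <= / >= that force).
    """

    value_g: float
    censored: str = "none"
    k: float | None = None
    pattern: str | None = None
    clamped: bool = False


def pwt50_from_last(last_force_g: float, k: float, delta: float) -> float:
    """Evaluate the threshold formula for a last filament force and k.

    X_f = log10(force in 0.1 mg) = log10(1e4 * grams); the 1e4 divisor
    returns grams, so k = 0 reproduces the last force exactly.
    """
    x_f = np.log10(1e4 * last_force_g)
    return float(10 ** (x_f + k * delta) / 1e4)


def pwt50(
    seq: UpDownSequence,
    ladder: FilamentLadder | None = None,
    k_table: KTable | None = None,
) -> PWTEstimate:
    """50% withdrawal threshold from a terminated up-down sequence.

    Saturated sequences (no response change) are reported as censored
    bounds at the ladder floor/ceiling. Interior estimates falling outside
    the ladder range are clamped to it and flagged.
    """
    ladder = ladder if ladder is not None else CHAPLAN_LADDER
    if seq.first_change_index is None:
        all_pos = all(r for _, r in seq.trials)
        if all_pos:
            return PWTEstimate(value_g=ladder.forces[0], censored="below")
        return PWTEstimate(value_g=ladder.forces[-1], censored="above")
    if k_table is None:
        k_table = load_k_table()
    pattern = seq.terminal_pattern
    assert pattern is not None
    k = k_table.lookup(pattern)
    if seq.last_force not in ladder.forces:
        raise ValueError(f"last force {seq.last_force} g not in ladder")
    value = pwt50_from_last(seq.last_force, k, ladder.delta)
    clamped = False
    if value < ladder.forces[0]:
        value, clamped = ladder.forces[0], True
    elif value > ladder.forces[-1]:
        value, clamped = ladder.forces[-1], True
    return PWTEstimate(value_g=value, k=k, pattern=pattern, clamped=clamped)


def estimator_study(
    true_thresholds: list[float],
    ladder: FilamentLadder | None = None,
    n_reps: int = 20,
    seed: int = 0,
    slope: float = np.inf,
    start_force: float = 2.00,
) -> pd.DataFrame:
    """Bias/precision of the staircase estimator over simulated responders.

    For each true threshold, ``n_reps`` staircases are simulated and the
    mean, SD, and censoring rate of the estimates reported.
    """
    from .synth import Responder, simulate_updown

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ladder = ladder if ladder is not None else CHAPLAN_LADDER
    k_table = load_k_table()
    ss = np.random.SeedSequence(seed)
    rows = []
    for theta in true_thresholds:
        seeds = [s.generate_state(1)[0] % 2**31 for s in ss.spawn(n_reps)]
        ests, censored = [], 0
        for s in seeds:
            seq = simulate_updown(
                Responder(true_threshold=theta, slope=slope, seed=s),
                filaments=ladder,
                start_force=start_force,
            )
            est = pwt50(seq, ladder, k_table)
            ests.append(est.value_g)
            censored += est.censored != "none"
        rows.append(
            {
                "true_threshold_g": theta,
                "mean_estimate_g": float(np.mean(ests)),
                "sd_estimate_g": float(np.std(ests, ddof=1)) if n_reps > 1 else 0.0,
                "censored_rate": censored / n_reps,
                "n_reps": n_reps,
            }
        )
    return pd.DataFrame(rows)
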