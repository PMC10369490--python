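"""pH replica-exchange (pHRE) acceptance rule, bookkeeping and a toy ladder.

In pHRE, parallel constant-pH simulations run at the pH values of a ladder
and periodically attempt to swap conformations + protonation states between
adjacent pH values.  A swap between pH values pH_m and pH_l, whose current
states carry x_i and x_j protonated groups, is accepted with the Metropolis
probability

    p = min{ 1, 10^{(pH_m − pH_l)(x_i − x_j)} }

(x_i belongs to the replica at pH_m).  The base-10 form follows from the
Henderson–Hasselbalch free energy of moving protons across a pH gap; the
convention is pinned by a detailed-balance test.

The toy ladder simulator redraws each replica's protonation count per cycle
from independent per-site logistic probabilities — no conformational
dynamics — which is all that exchange-efficiency studies need.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._utils import hill_protonation, substream

__all__ = [
    "ReplicaState",
    "ExchangeAttempt",
    "ExchangeLedger",
    "EfficiencyReport",
    "exchange_probability",
    "attempt_exchange",
    "simulate_ladder",
    "exchange_efficiency",
]


@dataclass(frozen=True)
class ReplicaState:
    """One replica: its ladder pH and the current number of protonated groups."""

    ph: float
    n_protonated: int

    def __post_init__(self):
        if self.n_protonated < 0:
            raise ValueError("protonated-group count must be >= 0")


@dataclass(frozen=True)
class ExchangeAttempt:
    """Record of one swap attempt between the replicas at pH_m and pH_l."""

    cycle_index: int
    ph_m: float
    ph_l: float
    x_i: int
    x_j: int
    accepted: bool

    def __post_init__(self):
        if self.ph_m == self.ph_l:
            raise ValueError("exchange requires two distinct pH values")
        if min(self.x_i, self.x_j) < 0:
            raise ValueError("protonated-group counts must be >= 0")

    @property
    def pair(self) -> tuple[float, float]:
        return tuple(sorted((self.ph_m, self.ph_l)))


@dataclass
class ExchangeLedger:
    """Accumulated exchange attempts plus the attempt period τ_RE (ps)."""

    attempts: list = field(default_factory=list)
    tau_re_ps: float = 20.0

    def append(self, attempt: ExchangeAttempt) -> None:
        self.attempts.append(attempt)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": [a.cycle_index for a in self.attempts],
                "ph_m": [a.ph_m for a in self.attempts],
                "ph_l": [a.ph_l for a in self.attempts],
                "x_i": [a.x_i for a in self.attempts],
                "x_j": [a.x_j for a in self.attempts],
                "accepted": [a.accepted for a in self.attempts],
            }
        )


@dataclass(frozen=True)
class EfficiencyReport:
    overall: float
    per_pair: dict
    n_attempts: int


def exchange_probability(ph_m: float, ph_l: float, x_i: int, x_j: int) -> float:
    """Metropolis acceptance probability min{1, 10^{(pH_m − pH_l)(x_i − x_j)}}."""
    for v in (ph_m, ph_l):
        if not np.isfinite(v):
            raise ValueError("pH values must be finite")
    exponent = (float(ph_m) - float(ph_l)) * (float(x_i) - float(x_j))
    if exponent >= 0:
        return 1.0
    return float(10.0**exponent)


def attempt_exchange(
    state_a: ReplicaState,
    state_b: ReplicaState,
    rng: np.random.Generator,
    cycle_index: int = 0,
) -> tuple[bool, ReplicaState, ReplicaState, ExchangeAttempt]:
    """Attempt one swap; on acceptance the states trade pH slots.

    Returns ``(accepted, new_state_a, new_state_b, record)`` where the new
    states occupy the same pH slots (a keeps pH_a) but carry the swapped
    protonation counts when the move is accepted.
    """
    if state_a.ph == state_b.ph:
        raise ValueError("cannot exchange replicas with identical pH labels")
    p = exchange_probability(state_a.ph, state_b.ph, state_a.n_protonated, state_b.n_protonated)
    accepted = bool(rng.random() < p)
    record = ExchangeAttempt(
        cycle_index=cycle_index,
        ph_m=state_a.ph,
        ph_l=state_b.ph,
        x_i=state_a.n_protonated,
        x_j=state_b.n_protonated,
        accepted=accepted,
    )
    if accepted:
        new_a = replace(state_a, n_protonated=state_b.n_protonated)
        new_b = replace(state_b, n_protonated=state_a.n_protonated)
    else:
        new_a, new_b = state_a, state_b
    return accepted, new_a, new_b, record


def simulate_ladder(
    site_pkas: Sequence[float],
    ph_ladder: Sequence[float],
    n_cycles: int,
    seed: int = 0,
    hill_n: float = 1.0,
    tau_re_ps: float = 20.0,
) -> ExchangeLedger:
    """Toy pHRE ladder: resample protonation each cycle, attempt neighbor swaps.

    Each cycle every replica redraws its protonated-group count as a sum of
    independent Bernoulli draws with the logistic probability of each site
    at the replica's pH (mimicking the Monte Carlo protonation step), then
    adjacent pairs attempt exchanges — even pairs on even cycles, odd pairs
    on odd cycles.
    """
    ladder = [float(p) for p in ph_ladder]
    if len(ladder) < 2:
        raise ValueError("ph_ladder must contain at least two pH values")
    if any(b <= a for a, b in zip(ladder, ladder[1:])):
        raise ValueError("ph_ladder must be sorted strictly ascending")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    pkas = np.asarray(site_pkas, dtype=float)

    rng_state = substream(seed, "ladder/protonation")
    rng_swap = substream(seed, "ladder/metropolis")
    ledger = ExchangeLedger(tau_re_ps=tau_re_ps)
    states = [ReplicaState(ph=p, n_protonated=0) for p in ladder]
    for cycle in range(n_cycles):
        for k, ph in enumerate(ladder):
            if pkas.size:
                p_prot = hill_protonation(ph, pkas, hill_n)
                x = int(np.count_nonzero(rng_state.random(pkas.size) < p_prot))
            else:
                x = 0
            states[k] = ReplicaState(ph=ph, n_protonated=x)
        start = cycle % 2
        for i in range(start, len(ladder) - 1, 2):
            _, states[i], states[i + 1], rec = attempt_exchange(
                states[i], states[i + 1], rng_swap, cycle_index=cycle
            )
            ledger.append(rec)
    return ledger


def exchange_efficiency(ledger: ExchangeLedger) -> EfficiencyReport:
    """Accepted / attempted fraction, overall and per neighbor pair."""
    if not ledger.attempts:
        raise ValueError("ledger holds no exchange attempts")
    per_pair: dict = {}
    for a in ledger.attempts:
        acc, tot = per_pair.get(a.pair, (0, 0))
        per_pair[a.pair] = (acc + int(a.accepted), tot + 1)
    overall = sum(acc for acc, _ in per_pair.values()) / len(ledger.attempts)
    return EfficiencyReport(
        overall=float(overall),
        per_pair={pair: acc / tot for pair, (acc, tot) in per_pair.items()},
        n_attempts=len(ledger.attempts),
    )
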