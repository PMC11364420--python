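"""Event-driven stochastic counterpart of the fragmentation kernel.

Works on integer molecule counts of a small, well-mixed volume and serves
as an independent check of the deterministic population-balance solution:
the ensemble mean of many realizations converges to the ODE trajectory
when counts are identified with concentrations (unit volume).

Exo events pick a chain class i >= 2 with probability proportional to its
class rate and remove one terminal monomer; endo events pick a class with
probability proportional to its bond-weighted rate and then a cut
position uniformly among the chain's i-1 bonds.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import KineticParams, ValidationError

__all__ = ["gillespie_run", "gillespie_ensemble", "first_cut_fragments", "EnsembleResult"]

MAX_COUNTS = 10_000
MAX_LENGTH = 50


def _check_size(counts: np.ndarray) -> None:
    if counts.sum() > MAX_COUNTS or counts.size > MAX_LENGTH:
        raise ValidationError(
            "stochastic oracle is restricted to small systems "
            f"(total counts <= {MAX_COUNTS}, chain length <= {MAX_LENGTH})"
        )


def gillespie_run(
    counts,
    p: KineticParams,
    E_exo: float,
    E_endo: float,
    record_times,
    rng: np.random.Generator,
    max_events: int | None = None,
) -> np.ndarray:
    """One stochastic realization; returns counts at ``record_times``.

    ``counts[i-1]`` is the integer number of i-chains.  Enzyme
    concentrations stay fixed (enzyme-only conditions).  If ``max_events``
    is given the dynamics freeze after that many reaction events.
    """
    counts = np.asarray(counts, dtype=np.int64).copy()
    _check_size(counts)
    record_times = np.asarray(record_times, dtype=float)
    n = counts.size
    sizes = np.arange(1, n + 1, dtype=float)
    bonds = sizes - 1.0

    out = np.empty((record_times.size, n), dtype=np.int64)
    t = 0.0
    k_rec = 0
    n_events = 0
    while max_events is None or n_events < max_events:
        chains = counts[1:].sum()
        total_bonds = float(bonds @ counts)
        denom_x = p.km + (counts.sum() if p.exo_denominator_includes_monomers else chains)
        rates_x = p.k_exo * E_exo * counts / denom_x
        rates_x[0] = 0.0
        rates_n = p.k_endo * E_endo * bonds * counts / (p.km + total_bonds)
        total = rates_x.sum() + rates_n.sum()
        if total <= 0.0:
            break
        t_next = t + rng.exponential(1.0 / total)
        while k_rec < record_times.size and record_times[k_rec] < t_next:
            out[k_rec] = counts
            k_rec += 1
        if k_rec >= record_times.size:
            break
        t = t_next
        n_events += 1
        r = rng.uniform(0.0, total)
        sx = rates_x.sum()
        if r < sx:
            # exo event on an (i+1)-chain: terminal monomer removed
            i = int(np.searchsorted(np.cumsum(rates_x), r, side="right"))
            counts[i] -= 1
            counts[i - 1] += 1
            counts[0] += 1
        else:
            # endo cut of an (i+1)-chain at a uniform bond
            i = int(np.searchsorted(np.cumsum(rates_n), r - sx, side="right"))
            j = int(rng.integers(1, i + 1))       # fragment sizes j and i+1-j
            counts[i] -= 1
            counts[j - 1] += 1
            counts[i - j] += 1
    while k_rec < record_times.size:
        out[k_rec] = counts
        k_rec += 1
    return out


@dataclass
class EnsembleResult:
    t: np.ndarray
    mean: np.ndarray      #: (len(t), n) ensemble-mean counts
    sem: np.ndarray       #: standard error of the mean
    n_reps: int


def gillespie_ensemble(
    counts,
    p: KineticParams,
    E_exo: float,
    E_endo: float,
    record_times,
    n_reps: int,
    seed: int,
) -> EnsembleResult:
    """Mean +- standard error of ``n_reps`` independent realizations."""
    rng = np.random.default_rng(seed)
    record_times = np.asarray(record_times, dtype=float)
    acc = None
    acc2 = None
    for _ in range(n_reps):
        traj = gillespie_run(counts, p, E_exo, E_endo, record_times, rng).astype(float)
        if acc is None:
            acc = traj.copy()
            acc2 = traj**2
        else:
            acc += traj
            acc2 += traj**2
    mean = acc / n_reps
    var = np.maximum(acc2 / n_reps - mean**2, 0.0) * n_reps / max(n_reps - 1, 1)
    sem = np.sqrt(var / n_reps)
    return EnsembleResult(t=record_times, mean=mean, sem=sem, n_reps=n_reps)


def first_cut_fragments(
    n: int, n_reps: int, seed: int, p: KineticParams | None = None
) -> np.ndarray:
    """Smaller fragment size of the first endo cut of a single n-chain.

    Runs the full event machinery for exactly one event per replicate.
    The cut yields the unordered fragment pair {j, n-j}; one of the two is
    reported uniformly at random, so under uniform scission the returned
    sizes are uniform on {1, ..., n-1}.
    """
    if n < 2:
        raise ValidationError("need a chain with at least one bond")
    if p is None:
        p = KineticParams(k_exo=0.0, k_endo=1.0)
    rng = np.random.default_rng(seed)
    start = np.zeros(n, dtype=np.int64)
    start[n - 1] = 1
    frags = np.empty(n_reps, dtype=np.int64)
    horizon = np.array([np.inf])
    for k in range(n_reps):
        final = gillespie_run(start, p, 0.0, 1.0, horizon, rng, max_events=1)[-1]
        produced = np.repeat(np.arange(1, n), final[: n - 1])  # the two fragments
        frags[k] = int(rng.choice(produced))
    return frags
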