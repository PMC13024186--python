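"""Tent chaotic map streams.

The tent map ``x -> c*x`` for ``x < 1/2`` and ``c*(1-x)`` otherwise is, at
control parameter ``c = 2``, fully chaotic on (0, 1) with a uniform
invariant density.  The evolutionary engine uses one guarded tent stream
for population initialisation and for chaotic mutation; every other random
draw comes from an ordinary seeded PRNG.

Degeneracy guard.  In exact arithmetic the raw map sends 0, 1/2, 1 (and
every dyadic rational) into the absorbing fixed point 0; in binary
floating point the doubling shifts one mantissa bit out per step, so
*every* orbit collapses onto a dyadic within about 50 iterations.  The
guard detects a raw iterate outside ``(EPS, 1-EPS)`` and re-seeds the
orbit at ``frac(x + j*phi)``, where ``phi`` is the golden-ratio fraction
and ``j`` counts guard events on the stream.  Indexing the re-seed by
``j`` walks the restart points along a low-discrepancy Weyl sequence, so
successive orbit segments start at well-spread positions and the long-run
empirical distribution stays uniform (a re-seed independent of ``j``
would restart every segment near ``phi``, because ``x`` at guard time is
always close to 0 or 1, and would bias the stream).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Half-width of the excluded neighbourhoods of 0 and 1.
EPS = 1e-9

#: Golden-ratio fractional constant: the Weyl increment of the re-seed.
GOLDEN_RATIO_FRAC = 0.6180339887

#: Default control parameter: fully developed chaos.
DEFAULT_CONTROL = 2.0


def _reseed(x: float, event_index: int) -> float:
    y = (x + event_index * GOLDEN_RATIO_FRAC) % 1.0
    return min(max(y, EPS), 1.0 - EPS)


def tent_next(
    x: float, control: float = DEFAULT_CONTROL, *, guard_event: int = 1
) -> float:
    """One guarded tent-map step from ``x``.

    ``guard_event`` is the 1-based index the degeneracy re-seed uses if
    it fires; streams advance it per event, the stateless call leaves it
    at 1.  Raises a domain error when ``x`` is outside [0, 1] or
    ``control`` is not positive.
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"tent map state must be in [0, 1], got {x}")
    if control <= 0.0:
        raise ValueError("control parameter must be positive")
    raw = control * x if x < 0.5 else control * (1.0 - x)
    if EPS < raw < 1.0 - EPS:
        return raw
    return _reseed(raw, guard_event)


@dataclass
class TentMapStream:
    """A stateful guarded tent-map stream.

    One stream is shared across chaotic initialisation and chaotic
    mutation within an evolutionary run, so the whole run is a single
    deterministic orbit of the map.
    """

    state: float
    control: float = DEFAULT_CONTROL
    guard_events: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.state < 1.0:
            raise ValueError("initial state must lie strictly in (0, 1)")

    def next(self) -> float:
        raw = (
            self.control * self.state
            if self.state < 0.5
            else self.control * (1.0 - self.state)
        )
        if not EPS < raw < 1.0 - EPS:
            self.guard_events += 1
            raw = _reseed(raw, self.guard_events)
        self.state = raw
        return raw

    def take(self, n: int) -> np.ndarray:
        if n < 1:
            raise ValueError("n must be at least 1")
        out = np.empty(n, dtype=float)
        for i in range(n):
            out[i] = self.next()
        return out


def tent_sequence(
    seed_value: float, length: int, control: float = DEFAULT_CONTROL
) -> np.ndarray:
    """``length`` successive guarded iterates starting from ``seed_value``."""
    if length < 1:
        raise ValueError("length must be at least 1")
    return TentMapStream(seed_value, control).take(length)


def chaotic_init_matrix(
    rows: int, cols: int, seed_value: float, control: float = DEFAULT_CONTROL
) -> np.ndarray:
    """A rows x cols matrix filled row-major from one continuous stream."""
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be positive")
    return tent_sequence(seed_value, rows * cols, control).reshape(rows, cols)


def tent_orbit_extrema(
    seeds: np.ndarray, n_steps: int, control: float = DEFAULT_CONTROL
) -> tuple[float, float]:
    """Run many guarded orbits in lockstep; return the global (min, max).

    Vectorised over seeds so that long-orbit containment checks (millions
    of iterates) stay cheap.  Each orbit keeps its own guard-event
    counter.  The returned extrema cover every iterate of every orbit,
    excluding the seeds themselves.
    """
    x = np.array(seeds, dtype=float)
    if np.any((x <= 0.0) | (x >= 1.0)):
        raise ValueError("seeds must lie strictly in (0, 1)")
    events = np.zeros(x.shape, dtype=np.int64)
    lo, hi = 1.0, 0.0
    for _ in range(n_steps):
        x = np.where(x < 0.5, control * x, control * (1.0 - x))
        bad = (x <= EPS) | (x >= 1.0 - EPS)
        if bad.any():
            events[bad] += 1
            x[bad] = np.clip(
                (x[bad] + events[bad] * GOLDEN_RATIO_FRAC) % 1.0,
                EPS,
                1.0 - EPS,
            )
        m = x.min()
        M = x.max()
        if m < lo:
            lo = float(m)
        if M > hi:
            hi = float(M)
    return lo, hi
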