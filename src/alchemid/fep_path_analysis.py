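"""Free-energy path bookkeeping for runs through an intermediate.

Inserting an intermediate I splits the alchemical transformation A -> B
into A -> I and I -> B.  The ΔΔG of the split path is the sum of the leg
estimates; its standard deviation is the root of the summed squares of the
leg standard deviations (legs are independent runs).  Because free energy
is a state function the split path and the direct path must agree (cycle
closure): their discrepancy, with propagated uncertainty, is the standard
diagnostic.

Convergence of a ΔG(t) time series is declared at the earliest time t such
that the value changes by at most ``threshold`` kcal/mol over a ``window``
ns stretch.  "Change over the window" is read as the max-min spread within
the window by default (robust to oscillation); an endpoint-difference
variant is available via ``mode="endpoint"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd

from .errors import WindowTooLong


class _NotConverged:
    """Sentinel: the series never satisfies the convergence criterion."""

    def __repr__(self) -> str:
        return "NOT_CONVERGED"

    def __bool__(self) -> bool:
        return False


NOT_CONVERGED = _NotConverged()


@dataclass(frozen=True)
class LegEstimate:
    """A ΔΔG estimate for one alchemical leg, in kcal/mol, with the standard
    deviation over independent replicates."""

    label: str
    ddg: float
    sd: float
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def path_estimate(*legs: LegEstimate, label: str = "") -> LegEstimate:
    """Combine consecutive legs (A->I, I->B, ...) into one path estimate:
    ΔΔG values add, standard deviations combine as sqrt(sum of squares).

    Associative: folding legs pairwise equals a single pass over all legs.
    """
    if len(legs) < 1:
        raise ValueError("at least one leg required")
    ddg = float(sum(l.ddg for l in legs))
    sd = float(np.sqrt(sum(l.sd**2 for l in legs)))
    n = min(l.n_replicates for l in legs)
    if not label:
        label = "+".join(l.label for l in legs)
    return LegEstimate(label=label, ddg=ddg, sd=sd, n_replicates=n)


def cycle_closure(direct: LegEstimate, via_intermediate: LegEstimate) -> LegEstimate:
    """Discrepancy (via - direct) between the intermediate path and the
    direct path, with propagated sd; zero within uncertainty means the
    thermodynamic cycle closes."""
    return LegEstimate(
        label=f"({via_intermediate.label})-({direct.label})",
        ddg=via_intermediate.ddg - direct.ddg,
        sd=float(np.sqrt(direct.sd**2 + via_intermediate.sd**2)),
        n_replicates=min(direct.n_replicates, via_intermediate.n_replicates),
    )


@dataclass(frozen=True)
class DGSeries:
    """ΔG sampled on a uniform time grid (ns, kcal/mol)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or times.size < 2:
            raise ValueError("need at least two time points")
        if times.size != values.size:
            raise ValueError("times and values length mismatch")
        dt = np.diff(times)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("times must be uniformly spaced")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @classmethod
    def from_csv(cls, path) -> "DGSeries":
        """Read columns ``time_ns`` and ``dg_kcal_mol``."""
        df = pd.read_csv(path)
        return cls(
            times=df["time_ns"].to_numpy(), values=df["dg_kcal_mol"].to_numpy()
        )


def convergence_time(
    series: DGSeries,
    threshold: float = 0.1,
    window: float = 2.0,
    mode: str = "spread",
) -> Union[float, _NotConverged]:
    """Earliest time t (ns) after which ΔG changes at most ``threshold``
    kcal/mol over every full ``window``-ns stretch [u, u + window], u >= t.

    A transient early plateau does not count as convergence: all later
    windows must satisfy the bound too, so for a series with a single step
    at t_s and flat tails the result is t_s, not 0.

    mode="spread" (default): max-min spread of all samples in the window.
    mode="endpoint": |ΔG(u + window) - ΔG(u)| only.

    Returns NOT_CONVERGED when the final full window violates the bound
    (no convergence point exists).  Raises WindowTooLong when the series
    spans less than ``window``.
    """
    if mode not in ("spread", "endpoint"):
        raise ValueError("mode must be 'spread' or 'endpoint'")
    t, v = series.times, series.values
    span = t[-1] - t[0]
    if span < window - 1e-9:
        raise WindowTooLong(f"series spans {span:.3g} ns < window {window:.3g} ns")
    w = int(round(window / series.dt))
    first_good = None
    for i in range(len(t) - w):
        seg = v[i : i + w + 1]
        change = (seg.max() - seg.min()) if mode == "spread" else abs(seg[-1] - seg[0])
        if change <= threshold + 1e-12:
            if first_good is None:
                first_good = i
        else:
            first_good = None
    if first_good is None:
        return NOT_CONVERGED
    return float(t[first_good])


def read_legs_csv(path) -> list[LegEstimate]:
    """Read leg estimates from CSV columns label, ddg, sd[, n_replicates]."""
    df = pd.read_csv(path)
    legs = []
    for _, row in df.iterrows():
        legs.append(
            LegEstimate(
                label=str(row["label"]),
                ddg=float(row["ddg"]),
                sd=float(row["sd"]),
                n_replicates=int(row.get("n_replicates", 3)),
            )
        )
    return legs
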