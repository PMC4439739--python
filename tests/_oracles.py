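"""Hand-written brute-force oracles, independent of the library's vectorized code.

These deliberately use plain Python loops and the statistics module so that
agreement with the numpy implementations is a genuine cross-check.
"""

from __future__ import annotations

import math
import statistics

import numpy as np

from micoskit.apms import StatsTable


def percentile_linear(sorted_vals, q):
    """Linear-interpolation percentile of an ascending list (inclusive method)."""
    n = len(sorted_vals)
    if n == 1:
        return sorted_vals[0]
    h = (n - 1) * q / 100.0
    lo = math.floor(h)
    hi = min(lo + 1, n - 1)
    return sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo])


def compass_bruteforce(table: StatsTable, percentile: float = 98.0) -> dict:
    """Re-evaluate WD/Z/NWD per detected pair, straight from the definitions."""
    k = table.k
    X = table.apsm
    P = table.detections
    results: dict = {}
    wds: list[float] = []
    order: list[tuple[str, str]] = []
    for j, prey in enumerate(table.preys):
        col = [float(X[i, j]) for i in range(k)]
        mean = sum(col) / k
        sd = statistics.stdev(col)
        f = sum(1 for v in col if v > 0)
        omega = max(1.0, sd / mean) if mean > 0 else 1.0
        for i, bait in enumerate(table.baits):
            x = float(X[i, j])
            if x <= 0:
                continue
            z = (x - mean) / sd if sd > 0 else 0.0
            wd = math.sqrt(x * ((k / f) * omega) ** int(P[i, j]))
            results[(bait, prey)] = {
                "X": x, "f": f, "p": int(P[i, j]), "omega": omega, "Z": z, "WD": wd,
            }
            order.append((bait, prey))
            wds.append(wd)
    norm = percentile_linear(sorted(w for w in wds if w > 0), percentile)
    for key, wd in zip(order, wds):
        results[key]["NWD"] = wd / norm
    return results


def random_stats_table(rng: np.random.Generator, k: int, n_preys: int) -> StatsTable:
    """A random small table obeying the X>0 <=> p>=1 invariant."""
    X = np.zeros((k, n_preys))
    P = np.zeros((k, n_preys), dtype=int)
    for i in range(k):
        for j in range(n_preys):
            if rng.random() < 0.45:
                counts = rng.integers(0, 12, size=2)
                if counts.sum() > 0:
                    X[i, j] = counts.mean()
                    P[i, j] = int((counts > 0).sum())
    if not (X > 0).any():
        X[0, 0], P[0, 0] = 3.0, 2
    return StatsTable(
        baits=[f"b{i}" for i in range(k)],
        preys=[f"y{j}" for j in range(n_preys)],
        apsm=X,
        detections=P,
    )


def nearest_bruteforce(particles, cjs) -> list[float]:
    """All-pairs minimum distance, plain loops."""
    out = []
    for px, py in particles:
        best = math.inf
        for cx, cy in cjs:
            best = min(best, math.hypot(px - cx, py - cy))
        out.append(best)
    return out
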