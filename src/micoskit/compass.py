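"""CompPASS-style interaction scoring over a multi-bait stats table.

Given a panel of k unrelated baits, a prey's plausibility as a true
interactor of a particular bait rises with its abundance in that bait's
runs (APSM, X), its rarity across the panel (detected by f of k baits),
the variability of its abundance across the panel (weight omega), and its
reproducibility across technical replicates (exponent p):

    WD[i,j] = sqrt( X[i,j] * ((k / f_j) * omega_j) ** p[i,j] )

where, over the full prey column including zeros, x_bar_j is the mean,
sigma_j the sample standard deviation, and omega_j = max(1, sigma_j /
x_bar_j).  A z-score Z[i,j] = (X[i,j] - x_bar_j) / sigma_j is reported
alongside.  WD scores are normalized (NWD) by a high percentile of all
positive WD values so that "NWD > 1" marks roughly the top
(100 - percentile)% of pairs; preys passing that cut (optionally with an
abundance floor and a membership filter such as a mitochondrial protein
list) are high-confidence interacting proteins (HCIPs).
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .apms import StatsTable

__all__ = [
    "ScoredInteraction",
    "HcipFilterConfig",
    "wd_score",
    "score_interactions",
    "filter_hcips",
    "scores_to_frame",
    "write_scores",
    "read_scores",
]


@dataclass
class ScoredInteraction:
    """One detected bait-prey pair with its CompPASS statistics."""

    bait: str
    prey: str
    X: float          # APSM of the prey in this bait
    f: int            # number of baits in the panel detecting the prey
    p: int            # replicate detections for this pair
    omega: float      # variability weight, >= 1
    Z: float          # z-score of X over the prey column
    WD: float
    NWD: float = float("nan")
    is_hcip: bool = False


@dataclass(frozen=True)
class HcipFilterConfig:
    """Thresholds defining high-confidence interacting proteins.

    ``min_apsm`` = 2 reproduces the abundance floor used for FLAG-tag
    panels scored against small (tens-of-baits) background tables;
    ``membership`` restricts preys to a known compartment (e.g. a
    mitochondrial protein inventory).
    """

    nwd_threshold: float = 1.0
    min_apsm: float = 0.0
    membership: frozenset[str] | None = None
    normalization_percentile: float = 98.0

    def __post_init__(self) -> None:
        if self.nwd_threshold < 0 or self.min_apsm < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0.0 < self.normalization_percentile < 100.0:
            raise ValueError("normalization_percentile must lie in (0, 100)")


def wd_score(x: float, k: int, f: int, omega: float, p: int) -> float:
    """The un-normalized WD statistic for a single pair."""
    return math.sqrt(x * ((k / f) * omega) ** p)


def score_interactions(
    table: StatsTable, normalization_percentile: float = 98.0
) -> list[ScoredInteraction]:
    """Score every detected bait-prey pair in the panel.

    Column statistics (mean, sample standard deviation) include the zero
    cells of baits that did not detect the prey; sigma uses ddof=1, hence
    the k >= 2 requirement.  Pairs are emitted in table order (baits, then
    preys).  NWD divides WD by the ``normalization_percentile``-th
    percentile of all positive WD values.
    """
    k = table.k
    if k < 2:
        raise ValueError("background model undefined for k < 2 baits")
    X = table.apsm
    P = table.detections
    if not (X > 0).any():
        raise ValueError("stats table has no detected pairs")
    if not 0.0 < normalization_percentile < 100.0:
        raise ValueError("normalization_percentile must lie in (0, 100)")

    mean = X.mean(axis=0)
    sigma = X.std(axis=0, ddof=1)
    f = (X > 0).sum(axis=0)

    omega = np.ones_like(mean)
    nz = mean > 0
    omega[nz] = np.maximum(1.0, sigma[nz] / mean[nz])

    scores: list[ScoredInteraction] = []
    for i, bait in enumerate(table.baits):
        for j, prey in enumerate(table.preys):
            x = X[i, j]
            if x <= 0:
                continue
            z = (x - mean[j]) / sigma[j] if sigma[j] > 0 else 0.0
            wd = wd_score(x, k, int(f[j]), omega[j], int(P[i, j]))
            scores.append(
                ScoredInteraction(
                    bait=bait,
                    prey=prey,
                    X=float(x),
                    f=int(f[j]),
                    p=int(P[i, j]),
                    omega=float(omega[j]),
                    Z=float(z),
                    WD=float(wd),
                )
            )
    wds = np.array([s.WD for s in scores])
    norm = float(np.percentile(wds[wds > 0], normalization_percentile))
    if norm <= 0:
        raise ValueError("degenerate WD distribution: normalizer is zero")
    for s in scores:
        s.NWD = s.WD / norm
    return scores


def filter_hcips(
    scores: Iterable[ScoredInteraction], config: HcipFilterConfig | None = None
) -> list[ScoredInteraction]:
    """Apply the HCIP rule; marks ``is_hcip`` on every input score.

    A pair is retained iff NWD strictly exceeds the threshold, X meets the
    abundance floor, and (when a membership list is given) the prey is a
    member.  Input order is preserved.
    """
    config = config or HcipFilterConfig()
    kept: list[ScoredInteraction] = []
    for s in scores:
        ok = (
            s.NWD > config.nwd_threshold
            and s.X >= config.min_apsm
            and (config.membership is None or s.prey in config.membership)
        )
        s.is_hcip = ok
        if ok:
            kept.append(s)
    return kept


def scores_to_frame(scores: Sequence[ScoredInteraction]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bait": [s.bait for s in scores],
            "prey": [s.prey for s in scores],
            "X": [s.X for s in scores],
            "f": [s.f for s in scores],
            "p": [s.p for s in scores],
            "omega": [s.omega for s in scores],
            "Z": [s.Z for s in scores],
            "WD": [s.WD for s in scores],
            "NWD": [s.NWD for s in scores],
            "is_hcip": [s.is_hcip for s in scores],
        }
    )


def write_scores(scores: Sequence[ScoredInteraction], path) -> None:
    scores_to_frame(scores).to_csv(path, sep="\t", index=False)


def read_scores(path) -> list[ScoredInteraction]:
    df = pd.read_csv(path, sep="\t")
    return [
        ScoredInteraction(
            bait=str(r.bait),
            prey=str(r.prey),
            X=float(r.X),
            f=int(r.f),
            p=int(r.p),
            omega=float(r.omega),
            Z=float(r.Z),
            WD=float(r.WD),
            NWD=float(r.NWD),
            is_hcip=bool(r.is_hcip),
        )
        for r in df.itertuples()
    ]
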