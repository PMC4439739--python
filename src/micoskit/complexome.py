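"""SILAC BN-PAGE complexome profiling.

Blue-native PAGE separates intact protein complexes by mass; slicing the
lane into gel pieces and quantifying each slice by SILAC mass spectrometry
yields, per protein and slice, a heavy:light (H:L) intensity ratio between
two conditions mixed 1:1 (here: heavy = knockdown, light = control, so
H:L < 1 means depletion).  Comparing the ratio in the mature-complex mass
window against a lower sub-complex window detects disassembly: loss from
the ~700 kDa complex with concomitant accumulation at ~500 kDa indicates a
stable assembly intermediate, while a global drop of the summed H:L signal
indicates degradation of the subunit.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PeptideQuant",
    "FractionCalibration",
    "ComplexomeProfile",
    "ShiftCall",
    "calibrate_fractions",
    "mass_to_slice",
    "protein_fraction_ratios",
    "total_abundance_ratios",
    "detect_shift",
    "render_heatmap",
    "read_peptide_quants",
    "write_peptide_quants",
]

QUANT_COLUMNS = ("peptide", "protein", "fraction", "heavy_intensity", "light_intensity")


@dataclass(frozen=True)
class PeptideQuant:
    """One peptide's channel intensities in one gel slice."""

    peptide: str
    protein: str
    fraction: int
    heavy_intensity: float
    light_intensity: float

    def __post_init__(self) -> None:
        if self.fraction < 1:
            raise ValueError("fraction indices are 1-based")
        if self.heavy_intensity < 0 or self.light_intensity < 0:
            raise ValueError("intensities must be non-negative")


@dataclass(frozen=True)
class FractionCalibration:
    """Mapping between gel slices and molecular mass.

    Slices are equally spaced in log10 mass from ``mass_top`` (slice 1)
    down to ``mass_bottom`` (slice ``n_slices``).
    """

    n_slices: int = 20
    mass_top: float = 1000.0   # kDa
    mass_bottom: float = 60.0  # kDa

    def __post_init__(self) -> None:
        if self.n_slices < 2:
            raise ValueError("need at least 2 slices")
        if self.mass_bottom <= 0 or self.mass_top <= self.mass_bottom:
            raise ValueError("require mass_top > mass_bottom > 0")

    @property
    def log_edges(self) -> np.ndarray:
        """Slice boundaries in log10 kDa, strictly decreasing, length n+1."""
        return np.linspace(
            math.log10(self.mass_top), math.log10(self.mass_bottom), self.n_slices + 1
        )

    @property
    def slice_centers_log10(self) -> np.ndarray:
        e = self.log_edges
        return (e[:-1] + e[1:]) / 2.0

    @property
    def slice_centers_kda(self) -> np.ndarray:
        return 10.0 ** self.slice_centers_log10

    def contains(self, mass_kda: float) -> bool:
        return self.mass_bottom < mass_kda <= self.mass_top


def calibrate_fractions(
    n_slices: int = 20, mass_top: float = 1000.0, mass_bottom: float = 60.0
) -> FractionCalibration:
    return FractionCalibration(n_slices=n_slices, mass_top=mass_top, mass_bottom=mass_bottom)


def mass_to_slice(
    cal: FractionCalibration, mass_kda: float, return_clamp: bool = False
):
    """Slice index (1-based) whose half-open [upper, lower) interval holds the mass.

    Masses above ``mass_top`` clamp to slice 1; masses at or below
    ``mass_bottom`` clamp to the last slice.  With ``return_clamp=True``
    returns ``(index, clamped)``.
    """
    if mass_kda <= 0:
        raise ValueError("mass must be positive")
    step = (math.log10(cal.mass_top) - math.log10(cal.mass_bottom)) / cal.n_slices
    position = (math.log10(cal.mass_top) - math.log10(mass_kda)) / step
    raw = math.floor(position) + 1
    idx = min(max(raw, 1), cal.n_slices)
    clamped = raw != idx
    return (idx, clamped) if return_clamp else idx


@dataclass
class ComplexomeProfile:
    """Protein x slice H:L ratio matrix plus per-protein totals.

    ``ratios`` has proteins as rows and 1-based slice indices as columns;
    missing cells are NaN.  ``capped`` flags cells where the light channel
    was absent and the ratio was capped.  ``total_ratio`` is the quotient
    of protein-level summed intensities over all slices.
    """

    ratios: pd.DataFrame
    capped: pd.DataFrame
    total_ratio: pd.Series
    cap: float = 100.0

    @property
    def proteins(self) -> list[str]:
        return list(self.ratios.index)


def _grouped_sums(quants: Sequence[PeptideQuant]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "peptide": [q.peptide for q in quants],
            "protein": [q.protein for q in quants],
            "fraction": [q.fraction for q in quants],
            "heavy": [q.heavy_intensity for q in quants],
            "light": [q.light_intensity for q in quants],
        }
    )
    return df


def _ratio(heavy: float, light: float, cap: float) -> tuple[float, bool]:
    # cap only applies to one-channel (light-absent) detections
    if light > 0:
        return heavy / light, False
    if heavy > 0:
        return cap, True
    return float("nan"), False


def protein_fraction_ratios(
    quants: Sequence[PeptideQuant],
    cal: FractionCalibration | None = None,
    cap: float = 100.0,
    method: str = "sum",
) -> ComplexomeProfile:
    """Per-protein, per-slice H:L ratios.

    ``method="sum"`` (default) divides summed heavy by summed light
    intensity over the protein's peptides in the slice; ``"median"`` takes
    the median of per-peptide ratios instead.  A slice with signal in only
    the heavy channel is capped at ``cap`` and flagged; heavy-absent slices
    get ratio 0.  Proteins appear in first-seen order.
    """
    if not quants:
        raise ValueError("no peptide quantifications given")
    if method not in ("sum", "median"):
        raise ValueError(f"unknown aggregation method {method!r}")
    cal = cal or FractionCalibration()
    df = _grouped_sums(quants)
    if (df["fraction"] > cal.n_slices).any():
        raise ValueError("fraction index outside calibration range")

    proteins = list(dict.fromkeys(df["protein"]))
    cols = list(range(1, cal.n_slices + 1))
    ratios = pd.DataFrame(np.nan, index=proteins, columns=cols, dtype=float)
    capped = pd.DataFrame(False, index=proteins, columns=cols, dtype=bool)

    for (prot, frac), sub in df.groupby(["protein", "fraction"], sort=False):
        if method == "sum":
            r, was_capped = _ratio(sub["heavy"].sum(), sub["light"].sum(), cap)
        else:
            pep = sub.groupby("peptide", sort=False)[["heavy", "light"]].sum()
            vals = [_ratio(h, l, cap) for h, l in zip(pep["heavy"], pep["light"])]
            finite = [v for v, _ in vals if not math.isnan(v)]
            r = float(np.median(finite)) if finite else float("nan")
            was_capped = any(c for _, c in vals)
        ratios.loc[prot, frac] = r
        capped.loc[prot, frac] = was_capped

    totals = df.groupby("protein", sort=False)[["heavy", "light"]].sum()
    total_ratio = pd.Series(
        {p: _ratio(totals.loc[p, "heavy"], totals.loc[p, "light"], cap)[0] for p in proteins},
        name="total_ratio",
    )
    return ComplexomeProfile(ratios=ratios, capped=capped, total_ratio=total_ratio, cap=cap)


def total_abundance_ratios(
    quants: Sequence[PeptideQuant], cap: float = 100.0
) -> tuple[pd.DataFrame, pd.Series]:
    """H:L totals across all slices, per peptide and per protein.

    Per-peptide ratio = summed heavy / summed light over fractions (0 when
    detected light-only, capped when heavy-only); the per-protein total is
    the quotient of protein-level channel sums, reported alongside the
    peptide-level distribution.
    """
    if not quants:
        raise ValueError("no peptide quantifications given")
    df = _grouped_sums(quants)
    pep = df.groupby(["protein", "peptide"], sort=False)[["heavy", "light"]].sum()
    pep = pep.reset_index()
    pep["ratio"] = [
        _ratio(h, l, cap)[0] for h, l in zip(pep["heavy"], pep["light"])
    ]
    prot = df.groupby("protein", sort=False)[["heavy", "light"]].sum()
    protein_ratio = pd.Series(
        {p: _ratio(prot.loc[p, "heavy"], prot.loc[p, "light"], cap)[0] for p in prot.index},
        name="total_ratio",
    )
    return pep[["protein", "peptide", "heavy", "light", "ratio"]], protein_ratio


@dataclass(frozen=True)
class ShiftCall:
    """Disassembly verdict for one protein.

    ``call`` is one of no_change, depleted, subcomplex_shift, degraded, or
    insufficient_data when a mass window has no quantified slices.
    """

    protein: str
    mature_log2: float
    sub_log2: float
    total_log2: float
    call: str


def _window(cal: FractionCalibration, mass_kda: float) -> set[int]:
    center = mass_to_slice(cal, mass_kda)
    return {s for s in (center - 1, center, center + 1) if 1 <= s <= cal.n_slices}


def detect_shift(
    profile: ComplexomeProfile,
    cal: FractionCalibration | None = None,
    mature_mass: float = 700.0,
    sub_mass: float = 500.0,
    delta: float = math.log2(1.5),
    ratio_floor: float | None = None,
) -> list[ShiftCall]:
    """Classify each protein's redistribution between two mass windows.

    Windows are +/-1 slice around the slice of each mass; slices belonging
    to both windows are assigned to the mature window only, so the
    sub-complex window is not contaminated by the mature complex's
    migration tail.  With window means m = mature_log2 and s = sub_log2 and
    t = log2 total ratio, the call is:

    - ``subcomplex_shift`` iff m < -delta and s > +delta,
    - else ``degraded`` iff t < -delta (global loss, no accumulation),
    - else ``depleted`` iff m < -delta,
    - else ``no_change``.

    Zero ratios are floored at ``ratio_floor`` (default 1/cap) before the
    log transform.
    """
    cal = cal or FractionCalibration()
    floor = ratio_floor if ratio_floor is not None else 1.0 / profile.cap
    mature_w = _window(cal, mature_mass)
    sub_w = _window(cal, sub_mass) - mature_w
    if not sub_w:
        raise ValueError("mature and sub-complex windows fully overlap")

    calls: list[ShiftCall] = []
    for prot in profile.proteins:
        row = profile.ratios.loc[prot]

        def window_mean(slices: set[int]) -> float:
            vals = row[sorted(slices)].dropna()
            if vals.empty:
                return float("nan")
            return float(np.mean(np.log2(np.maximum(vals.to_numpy(), floor))))

        m = window_mean(mature_w)
        s = window_mean(sub_w)
        total = profile.total_ratio[prot]
        t = math.log2(max(total, floor)) if not math.isnan(total) else float("nan")

        if math.isnan(m) or math.isnan(s):
            call = "insufficient_data"
        elif m < -delta and s > delta:
            call = "subcomplex_shift"
        elif not math.isnan(t) and t < -delta:
            call = "degraded"
        elif m < -delta:
            call = "depleted"
        else:
            call = "no_change"
        calls.append(ShiftCall(protein=prot, mature_log2=m, sub_log2=s, total_log2=t, call=call))
    return calls


def render_heatmap(profile: ComplexomeProfile, path, figsize=None):
    """Render the ratio matrix as a green (H:L < 1) to red (H:L > 1) heatmap.

    The colour scale is symmetric in log2 around ratio 1; missing cells are
    drawn grey.  Returns the saved path.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    if profile.ratios.empty:
        raise ValueError("empty profile")
    log2 = np.log2(profile.ratios.to_numpy(dtype=float))
    span = np.nanmax(np.abs(log2)) if np.isfinite(log2).any() else 1.0
    span = max(span, 1.0)
    cmap = LinearSegmentedColormap.from_list(
        "green_red", ["#1a9850", "#f7f7f7", "#d73027"]
    )
    cmap.set_bad("#bdbdbd")
    n_prot, n_slice = log2.shape
    if figsize is None:
        figsize = (max(4.0, 0.35 * n_slice), max(2.0, 0.4 * n_prot))
    fig, ax = plt.subplots(figsize=figsize)
    masked = np.ma.masked_invalid(log2)
    im = ax.pcolormesh(masked, cmap=cmap, vmin=-span, vmax=span)
    ax.set_xticks(np.arange(n_slice) + 0.5, labels=[str(c) for c in profile.ratios.columns])
    ax.set_yticks(np.arange(n_prot) + 0.5, labels=profile.proteins)
    ax.invert_yaxis()
    ax.set_xlabel("gel slice (high mass → low mass)")
    fig.colorbar(im, ax=ax, label="log2 H:L")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def read_peptide_quants(path, columns: Mapping[str, str] | None = None) -> list[PeptideQuant]:
    """Read peptide quantifications from TSV.

    ``columns`` optionally maps the canonical names (peptide, protein,
    fraction, heavy_intensity, light_intensity) to the file's column
    names, for evidence-style exports.
    """
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    colmap = {c: c for c in QUANT_COLUMNS}
    if columns:
        colmap.update(columns)
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    return [
        PeptideQuant(
            peptide=str(r[colmap["peptide"]]),
            protein=str(r[colmap["protein"]]),
            fraction=int(r[colmap["fraction"]]),
            heavy_intensity=float(r[colmap["heavy_intensity"]]),
            light_intensity=float(r[colmap["light_intensity"]]),
        )
        for _, r in df.iterrows()
    ]


def write_peptide_quants(quants: Iterable[PeptideQuant], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(QUANT_COLUMNS) + "\n")
        for q in quants:
            # repr gives the shortest exact round-trip decimal for floats
            fh.write(
                f"{q.peptide}\t{q.protein}\t{q.fraction}\t"
                f"{q.heavy_intensity!r}\t{q.light_intensity!r}\n"
            )
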