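"""AP-MS run handling: PSM-to-APSM assembly, replicate merging, stats tables.

An affinity-purification mass-spectrometry (AP-MS) experiment purifies a
tagged *bait* protein and identifies co-purifying *preys* by their peptide
spectral matches (PSMs).  Peptides whose sequence occurs in more than one
protein must be apportioned before counts can be compared across proteins;
replicate runs are then averaged into APSMs (average peptide spectral
matches).  A *stats table* collects APSMs for a panel of unrelated baits and
is the background model for interaction scoring (:mod:`micoskit.compass`).
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PsmRecord",
    "BaitRun",
    "BaitSummary",
    "StatsTable",
    "SHARED_PEPTIDE_POLICIES",
    "assemble_apsm",
    "merge_replicates",
    "read_runs",
    "read_stats_table",
    "write_stats_table",
    "read_membership",
    "write_membership",
]

#: Supported shared-peptide allocation policies.
SHARED_PEPTIDE_POLICIES = ("proportional", "parsimony")

RUN_COLUMNS = ("cell_line", "bait", "replicate", "prey", "spectral_count")
STATS_COLUMNS = ("bait", "prey", "apsm", "replicates")


@dataclass(frozen=True)
class PsmRecord:
    """One peptide-level identification within a single bait run.

    ``proteins`` lists every protein whose sequence contains the peptide;
    counts for multi-protein peptides are apportioned by
    :func:`assemble_apsm`.
    """

    peptide: str
    proteins: tuple[str, ...]
    spectral_count: int
    bait: str
    replicate: str

    def __post_init__(self) -> None:
        if not self.proteins:
            raise ValueError("PsmRecord requires at least one matched protein")
        if self.spectral_count < 0:
            raise ValueError("spectral_count must be non-negative")


@dataclass
class BaitRun:
    """Per-protein spectral counts from one replicate run of one bait."""

    bait: str
    replicate: str
    counts: dict[str, float]
    cell_line: str = ""

    def __post_init__(self) -> None:
        for prey, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for prey {prey!r}")


@dataclass
class BaitSummary:
    """Replicate-merged view of one bait: APSMs and replicate detections."""

    bait: str
    cell_line: str
    n_replicates: int
    apsm: dict[str, float]
    detections: dict[str, int]


def assemble_apsm(
    psms: Iterable[PsmRecord], policy: str = "proportional"
) -> BaitRun:
    """Collapse peptide spectral matches into per-protein counts.

    Unique peptides contribute their counts directly.  Shared peptides are
    handled per ``policy``:

    ``proportional``
        split the count across matched proteins in proportion to each
        protein's unique-peptide evidence (equal split when no matched
        protein has unique evidence);
    ``parsimony``
        assign the whole count to the matched protein with the most unique
        evidence (ties broken lexicographically); proteins without unique
        evidence are dropped.

    The proportional policy conserves the total PSM count.
    """
    if policy not in SHARED_PEPTIDE_POLICIES:
        raise ValueError(
            f"unknown shared-peptide policy {policy!r}; "
            f"expected one of {SHARED_PEPTIDE_POLICIES}"
        )
    records = list(psms)
    if not records:
        return BaitRun(bait="", replicate="", counts={})

    baits = {r.bait for r in records}
    reps = {r.replicate for r in records}
    if len(baits) != 1 or len(reps) != 1:
        raise ValueError("all PSMs must share one bait and one replicate")

    unique: dict[str, float] = {}
    for r in records:
        if len(r.proteins) == 1:
            unique[r.proteins[0]] = unique.get(r.proteins[0], 0.0) + r.spectral_count

    counts = dict(unique)
    for r in records:
        if len(r.proteins) == 1:
            continue
        weights = [unique.get(p, 0.0) for p in r.proteins]
        total = sum(weights)
        if policy == "proportional":
            if total == 0.0:
                share = r.spectral_count / len(r.proteins)
                for p in r.proteins:
                    counts[p] = counts.get(p, 0.0) + share
            else:
                for p, w in zip(r.proteins, weights):
                    if w > 0.0:
                        counts[p] = counts.get(p, 0.0) + r.spectral_count * w / total
        else:  # parsimony
            if total == 0.0:
                continue  # no matched protein has unique evidence
            best = max(sorted(r.proteins), key=lambda p: unique.get(p, 0.0))
            counts[best] = counts.get(best, 0.0) + r.spectral_count
    counts = {p: c for p, c in counts.items() if c > 0.0}
    rec = records[0]
    return BaitRun(bait=rec.bait, replicate=rec.replicate, counts=counts)


def merge_replicates(runs: Sequence[BaitRun]) -> BaitSummary:
    """Average replicate runs of one bait into APSMs.

    The divisor is the number of replicates acquired, so a prey absent from
    a replicate drags its average down; ``detections`` counts replicates
    with a positive count.
    """
    runs = list(runs)
    if not runs:
        raise ValueError("merge_replicates requires at least one run")
    if len({r.bait for r in runs}) != 1:
        raise ValueError("runs must share one bait")
    if len({r.replicate for r in runs}) != len(runs):
        raise ValueError("replicate identifiers must be unique within a bait")
    n = len(runs)
    totals: dict[str, float] = {}
    det: dict[str, int] = {}
    for run in runs:
        for prey, c in run.counts.items():
            totals[prey] = totals.get(prey, 0.0) + c
            if c > 0:
                det[prey] = det.get(prey, 0) + 1
    apsm = {p: t / n for p, t in totals.items() if t > 0}
    det = {p: det[p] for p in apsm}
    return BaitSummary(
        bait=runs[0].bait,
        cell_line=runs[0].cell_line,
        n_replicates=n,
        apsm=apsm,
        detections=det,
    )


@dataclass
class StatsTable:
    """APSM panel over a set of baits: the CompPASS background model.

    ``apsm`` is the k-bait x n-prey matrix X of average peptide spectral
    matches; ``detections`` holds the replicate-detection counts p.  A cell
    is *detected* iff X > 0, in which case p >= 1.
    """

    baits: list[str]
    preys: list[str]
    apsm: np.ndarray
    detections: np.ndarray
    cell_line: str = ""

    def __post_init__(self) -> None:
        self.apsm = np.asarray(self.apsm, dtype=float)
        self.detections = np.asarray(self.detections, dtype=int)
        k, n = len(self.baits), len(self.preys)
        if self.apsm.shape != (k, n) or self.detections.shape != (k, n):
            raise ValueError("matrix shapes must be (n_baits, n_preys)")
        if (self.apsm < 0).any() or (self.detections < 0).any():
            raise ValueError("counts must be non-negative")
        if ((self.apsm > 0) != (self.detections >= 1)).any():
            raise ValueError("X[i,j] > 0 must hold exactly where p[i,j] >= 1")
        if len(set(self.baits)) != k or len(set(self.preys)) != n:
            raise ValueError("bait and prey identifiers must be unique")

    @property
    def k(self) -> int:
        return len(self.baits)

    @property
    def n_preys(self) -> int:
        return len(self.preys)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StatsTable):
            return NotImplemented
        return (
            self.baits == other.baits
            and self.preys == other.preys
            and self.cell_line == other.cell_line
            and np.array_equal(self.apsm, other.apsm)
            and np.array_equal(self.detections, other.detections)
        )

    @classmethod
    def from_summaries(cls, summaries: Sequence[BaitSummary]) -> "StatsTable":
        """Stack per-bait summaries into a table (preys sorted, baits kept)."""
        baits = [s.bait for s in summaries]
        preys = sorted({p for s in summaries for p in s.apsm})
        jdx = {p: j for j, p in enumerate(preys)}
        X = np.zeros((len(baits), len(preys)))
        P = np.zeros((len(baits), len(preys)), dtype=int)
        for i, s in enumerate(summaries):
            for prey, x in s.apsm.items():
                X[i, jdx[prey]] = x
                P[i, jdx[prey]] = s.detections[prey]
        cell_lines = {s.cell_line for s in summaries}
        cl = cell_lines.pop() if len(cell_lines) == 1 else ""
        return cls(baits=baits, preys=preys, apsm=X, detections=P, cell_line=cl)


def _read_tsv(path, required: tuple[str, ...]) -> tuple[pd.DataFrame, list[str]]:
    comments: list[str] = []
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    data_lines = []
    for line in lines:
        if line.startswith("#"):
            comments.append(line.rstrip("\n"))
        elif line.strip():
            data_lines.append(line)
    if not data_lines:
        raise ValueError(f"{path}: empty file (no header)")
    from io import StringIO

    df = pd.read_csv(StringIO("".join(data_lines)), sep="\t", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df, comments


def write_stats_table(table: StatsTable, path) -> None:
    """Write a stats table as TSV; rows sorted by (bait, prey)."""
    rows = []
    for i, bait in enumerate(table.baits):
        for j, prey in enumerate(table.preys):
            if table.apsm[i, j] > 0:
                rows.append((bait, prey, table.apsm[i, j], table.detections[i, j]))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# cell_line: {table.cell_line}\n")
        fh.write("# baits: " + "\t".join(table.baits) + "\n")
        fh.write("# preys: " + "\t".join(table.preys) + "\n")
        fh.write("bait\tprey\tapsm\treplicates\n")
        for bait, prey, x, p in rows:
            fh.write(f"{bait}\t{prey}\t{float(x)!r}\t{p}\n")


def read_stats_table(path) -> StatsTable:
    """Read a stats table written by :func:`write_stats_table`.

    Bait/prey ordering comes from the ``# baits:`` / ``# preys:`` comment
    lines when present (this preserves baits with no detected preys),
    otherwise from the sorted identifiers seen in the rows.
    """
    df, comments = _read_tsv(path, STATS_COLUMNS)
    cell_line = ""
    baits: list[str] | None = None
    preys: list[str] | None = None
    for c in comments:
        body = c.lstrip("#").strip()
        if body.startswith("cell_line:"):
            cell_line = body.split(":", 1)[1].strip()
        elif body.startswith("baits:"):
            baits = body.split(":", 1)[1].strip().split("\t")
        elif body.startswith("preys:"):
            preys = body.split(":", 1)[1].strip().split("\t")
    if baits is None:
        baits = sorted(df["bait"].unique())
    if preys is None:
        preys = sorted(df["prey"].unique())
    X = np.zeros((len(baits), len(preys)))
    P = np.zeros((len(baits), len(preys)), dtype=int)
    idx = {b: i for i, b in enumerate(baits)}
    jdx = {p: j for j, p in enumerate(preys)}
    for _, row in df.iterrows():
        x = float(row["apsm"])
        p = int(row["replicates"])
        if x < 0 or p < 0:
            raise ValueError(f"{path}: negative count for {row['bait']}/{row['prey']}")
        X[idx[row["bait"]], jdx[row["prey"]]] = x
        P[idx[row["bait"]], jdx[row["prey"]]] = p
    return StatsTable(baits=baits, preys=preys, apsm=X, detections=P, cell_line=cell_line)


def read_runs(path) -> list[BaitRun]:
    """Read per-replicate run counts from a TSV file.

    Required columns: cell_line, bait, replicate, prey, spectral_count.
    Returns one :class:`BaitRun` per (bait, replicate) pair, in file order.
    """
    df, _ = _read_tsv(path, RUN_COLUMNS)
    runs: dict[tuple[str, str], BaitRun] = {}
    for _, row in df.iterrows():
        key = (row["bait"], row["replicate"])
        count = float(row["spectral_count"])
        if count < 0:
            raise ValueError(f"{path}: negative spectral_count for {key}")
        if key not in runs:
            runs[key] = BaitRun(
                bait=row["bait"],
                replicate=row["replicate"],
                counts={},
                cell_line=row["cell_line"],
            )
        run = runs[key]
        if row["prey"] in run.counts:
            warnings.warn(f"duplicate prey {row['prey']!r} in run {key}; summing")
            run.counts[row["prey"]] += count
        else:
            run.counts[row["prey"]] = count
    return list(runs.values())


def read_membership(path) -> frozenset[str]:
    """Read a membership list (e.g. mitochondrial proteins), one id per line."""
    members = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                members.add(line)
    return frozenset(members)


def write_membership(members: Iterable[str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for m in sorted(set(members)):
            fh.write(m + "\n")
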