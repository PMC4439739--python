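"""Synthetic-data generators with known ground truth.

Each generator emits inputs with the statistical structure its analysis
stage assumes, plus the planted truth, so recovery tests can measure
recall, false-positive rates and calibration:

- :func:`simulate_apms` builds a multi-bait stats table of overdispersed
  background spectral counts with planted bait-specific interactors;
- :func:`simulate_complexome` builds SILAC BN-PAGE peptide tables for a
  complex with programmed knockdown effects (mature-complex depletion,
  sub-complex accumulation, subunit degradation);
- :func:`simulate_micrograph` scatters gold particles along cristae
  either uniformly or concentrated near cristae junctions.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

from .apms import StatsTable
from .complexome import FractionCalibration, PeptideQuant, mass_to_slice
from .goldmap import MicrographAnnotation, sample_along_paths, total_path_length

__all__ = [
    "PlantedInteraction",
    "ApmsSimConfig",
    "simulate_apms",
    "ComplexSpec",
    "SubunitEffect",
    "ComplexomeSimConfig",
    "micos_knockdown_config",
    "simulate_complexome",
    "GoldSimConfig",
    "simulate_micrograph",
]


# ---------------------------------------------------------------------------
# AP-MS stats tables


@dataclass(frozen=True)
class PlantedInteraction:
    """A true bait-prey interaction to plant into the background table.

    Planted preys carry elevated APSMs (``multiplier`` times the background
    mean) and are reproducible: each replicate is acquired with probability
    ``reproducibility`` and, when acquired, has at least one spectral count.
    """

    bait: str
    prey: str
    multiplier: float = 5.0
    reproducibility: float = 1.0

    def __post_init__(self) -> None:
        if self.multiplier <= 1:
            raise ValueError("multiplier must exceed 1")
        if not 0.0 <= self.reproducibility <= 1.0:
            raise ValueError("reproducibility must lie in [0, 1]")


@dataclass
class ApmsSimConfig:
    """Study conditions for a synthetic stats table.

    Background preys are detected per bait with a prey-specific frequency
    drawn uniformly from ``bg_frequency_range``; their replicate spectral
    counts follow a negative binomial with mean ``bg_apsm_mean`` and
    dispersion ``bg_dispersion`` (smaller = more overdispersed), matching
    the overdispersion of empirical spectral counts.
    """

    k_baits: int = 50
    n_background_preys: int = 500
    bg_frequency_range: tuple[float, float] = (0.02, 0.6)
    bg_apsm_mean: float = 4.0
    bg_dispersion: float = 2.0
    planted: list[PlantedInteraction] = field(default_factory=list)
    replicates: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.bg_frequency_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("frequencies must lie in [0, 1]")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float, size) -> np.ndarray:
    # negative binomial parameterized by mean and shape r (overdispersion)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def simulate_apms(config: ApmsSimConfig) -> tuple[StatsTable, list[tuple[str, str]]]:
    """Generate a stats table plus the planted ground-truth pair list."""
    if config.k_baits < 2:
        raise ValueError("need at least 2 baits for a background model")
    rng = np.random.default_rng(config.seed)
    k, nbg, reps = config.k_baits, config.n_background_preys, config.replicates
    baits = [f"BAIT{i + 1:03d}" for i in range(k)]
    bg_preys = [f"PREY{j + 1:04d}" for j in range(nbg)]
    plant_preys = sorted({pl.prey for pl in config.planted})
    for pl in config.planted:
        if pl.bait not in baits:
            raise ValueError(f"planted bait {pl.bait!r} not in panel of {k} baits")
        if pl.prey in bg_preys:
            raise ValueError(f"planted prey {pl.prey!r} collides with background")
    preys = bg_preys + plant_preys
    jdx = {p: j for j, p in enumerate(preys)}
    idx = {b: i for i, b in enumerate(baits)}

    X = np.zeros((k, len(preys)))
    P = np.zeros((k, len(preys)), dtype=int)

    lo, hi = config.bg_frequency_range
    freqs = rng.uniform(lo, hi, size=nbg)
    detected = rng.random((k, nbg)) < freqs[None, :]
    for i in range(k):
        for j in np.nonzero(detected[i])[0]:
            counts = _nb_draw(rng, config.bg_apsm_mean, config.bg_dispersion, reps)
            if counts.sum() == 0:
                continue
            X[i, j] = counts.mean()
            P[i, j] = int((counts > 0).sum())

    truth: list[tuple[str, str]] = []
    for pl in sorted(config.planted, key=lambda p: (p.bait, p.prey)):
        i, j = idx[pl.bait], jdx[pl.prey]
        counts = np.zeros(reps, dtype=float)
        for r in range(reps):
            if rng.random() < pl.reproducibility:
                counts[r] = max(
                    1,
                    _nb_draw(
                        rng, config.bg_apsm_mean * pl.multiplier, config.bg_dispersion, 1
                    )[0],
                )
        if counts.sum() > 0:
            X[i, j] = counts.mean()
            P[i, j] = int((counts > 0).sum())
        truth.append((pl.bait, pl.prey))

    # drop preys never detected anywhere so the table satisfies its invariant
    keep = X.sum(axis=0) > 0
    preys = [p for p, kk in zip(preys, keep) if kk]
    table = StatsTable(
        baits=baits, preys=preys, apsm=X[:, keep], detections=P[:, keep], cell_line="sim"
    )
    return table, truth


# ---------------------------------------------------------------------------
# SILAC BN-PAGE complexome


@dataclass(frozen=True)
class ComplexSpec:
    """A migrating complex: apparent mass and its subunit proteins."""

    mass_kda: float
    subunits: tuple[str, ...]


@dataclass(frozen=True)
class SubunitEffect:
    """Programmed knockdown response of one subunit (heavy channel).

    ``mature_depletion`` scales the heavy signal of the mature-complex
    component, ``sub_accumulation`` scales the sub-complex component, and
    ``degradation`` scales the heavy channel globally.  All 1.0 = no
    change.
    """

    mature_depletion: float = 1.0
    sub_accumulation: float = 1.0
    degradation: float = 1.0

    def __post_init__(self) -> None:
        if min(self.mature_depletion, self.sub_accumulation, self.degradation) < 0:
            raise ValueError("effect factors must be non-negative")


@dataclass
class ComplexomeSimConfig:
    """Study conditions for a synthetic SILAC BN-PAGE experiment.

    The light (control) channel of each subunit migrates as a mixture of a
    mature-complex band at the complex mass and a minor sub-complex band
    (share ``sub_fraction``) at ``sub_mass_kda``; migration profiles are
    Gaussian in log10 mass with standard deviation ``migration_width`` so
    a ~700 kDa band spans one to two of 20 slices.  The heavy channel is
    the light channel times the programmed per-slice effect times
    multiplicative log-normal noise of coefficient of variation
    ``noise_cv`` (mean 1, so programmed ratios are unbiased).
    """

    complexes: list[ComplexSpec] = field(default_factory=list)
    effects: dict[str, SubunitEffect] = field(default_factory=dict)
    sub_mass_kda: float = 500.0
    sub_fraction: float = 0.1
    peptides_per_subunit: int = 5
    peptide_abundance_sd: float = 0.5   # log-normal spread of peptide base intensity
    migration_width: float = 0.03       # sd of the migration profile, log10 kDa
    intensity_scale: float = 1e6
    noise_cv: float = 0.2
    min_rel_intensity: float = 1e-4     # detection floor, fraction of peptide total
    n_slices: int = 20
    mass_top: float = 1000.0
    mass_bottom: float = 60.0
    seed: int | None = None

    @property
    def calibration(self) -> FractionCalibration:
        return FractionCalibration(
            n_slices=self.n_slices, mass_top=self.mass_top, mass_bottom=self.mass_bottom
        )


def micos_knockdown_config(
    shift_depletion: float = 0.5,
    shift_accumulation: float = 2.0,
    degradation: float = 0.3,
    null: bool = False,
    seed: int | None = None,
    **overrides,
) -> ComplexomeSimConfig:
    """The default MICOS-disassembly scenario.

    One ~700 kDa complex of nine proteins: three sub-complex-forming
    subunits (MIC60/MIC19/MIC25 analogues) that shift into the ~500 kDa
    band, three degraded subunits (MIC10/MIC26/MIC27 analogues), and three
    unaffected membrane partners (SAMM50/MTX1/MTX2 analogues).  With
    ``null=True`` all effects are 1 (the 1:1 control mixing scenario).
    """
    subunits = (
        "MIC60", "MIC19", "MIC25",
        "MIC10", "MIC26", "MIC27",
        "SAMM50", "MTX1", "MTX2",
    )
    effects: dict[str, SubunitEffect] = {}
    if not null:
        for s in ("MIC60", "MIC19", "MIC25"):
            effects[s] = SubunitEffect(
                mature_depletion=shift_depletion, sub_accumulation=shift_accumulation
            )
        for s in ("MIC10", "MIC26", "MIC27"):
            effects[s] = SubunitEffect(degradation=degradation)
    return ComplexomeSimConfig(
        complexes=[ComplexSpec(700.0, subunits)],
        effects=effects,
        seed=seed,
        **overrides,
    )


def _band_shares(
    cal: FractionCalibration, center_log10: float, width: float
) -> np.ndarray:
    """Fraction of a Gaussian band's mass captured by each slice."""
    edges = cal.log_edges  # decreasing
    upper = norm.cdf(edges[:-1], loc=center_log10, scale=width)
    lower = norm.cdf(edges[1:], loc=center_log10, scale=width)
    return upper - lower


def expected_shift_call(
    config: ComplexomeSimConfig, protein: str, delta: float = math.log2(1.5)
) -> str:
    """Noise-free ground-truth call implied by a subunit's programmed effects."""
    eff = config.effects.get(protein, SubunitEffect())
    thr = 2.0 ** delta
    mature = eff.degradation * eff.mature_depletion
    sub = eff.degradation * eff.sub_accumulation
    total = eff.degradation * (
        (1 - config.sub_fraction) * eff.mature_depletion
        + config.sub_fraction * eff.sub_accumulation
    )
    if mature < 1 / thr and sub > thr:
        return "subcomplex_shift"
    if total < 1 / thr:
        return "degraded"
    if mature < 1 / thr:
        return "depleted"
    return "no_change"


def simulate_complexome(
    config: ComplexomeSimConfig,
) -> tuple[list[PeptideQuant], dict[str, str]]:
    """Generate peptide quantifications plus per-protein ground-truth calls."""
    if not config.complexes:
        raise ValueError("at least one complex required")
    cal = config.calibration
    for cx in config.complexes:
        if not cal.contains(cx.mass_kda):
            raise ValueError(
                f"complex mass {cx.mass_kda} kDa outside calibration range "
                f"({cal.mass_bottom}, {cal.mass_top}]"
            )
    rng = np.random.default_rng(config.seed)
    sigma_ln = math.sqrt(math.log(1.0 + config.noise_cv**2))
    mu_ln = -0.5 * sigma_ln**2  # mean-one log-normal noise

    sub_shares = _band_shares(cal, math.log10(config.sub_mass_kda), config.migration_width)
    quants: list[PeptideQuant] = []
    truth: dict[str, str] = {}
    for cx in config.complexes:
        mature_shares = _band_shares(cal, math.log10(cx.mass_kda), config.migration_width)
        for prot in cx.subunits:
            eff = config.effects.get(prot, SubunitEffect())
            truth[prot] = expected_shift_call(config, prot)
            light_profile = (
                (1.0 - config.sub_fraction) * mature_shares
                + config.sub_fraction * sub_shares
            )
            heavy_profile = config.effects.get(prot, SubunitEffect()).degradation * (
                (1.0 - config.sub_fraction) * eff.mature_depletion * mature_shares
                + config.sub_fraction * eff.sub_accumulation * sub_shares
            )
            for pidx in range(config.peptides_per_subunit):
                base = config.intensity_scale * rng.lognormal(
                    0.0, config.peptide_abundance_sd
                )
                pep = f"{prot}_pep{pidx + 1:02d}"
                for s in range(cal.n_slices):
                    if light_profile[s] < config.min_rel_intensity:
                        continue
                    light = base * light_profile[s]
                    heavy = base * heavy_profile[s] * rng.lognormal(mu_ln, sigma_ln)
                    quants.append(
                        PeptideQuant(
                            peptide=pep,
                            protein=prot,
                            fraction=s + 1,
                            heavy_intensity=float(heavy),
                            light_intensity=float(light),
                        )
                    )
    return quants, truth


# ---------------------------------------------------------------------------
# Immunogold micrographs


@dataclass
class GoldSimConfig:
    """Study conditions for a synthetic immunogold annotation.

    ``placement="uniform"`` scatters particles uniformly by arc length
    along the cristae membranes (the null of the enrichment test);
    ``"cj_concentrated"`` picks a CJ and displaces the particle along the
    membrane by a half-normal(``sigma_nm``) arc distance, emulating a CJ
    resident protein.  ``jitter_nm`` adds isotropic Gaussian localization
    error (antibody/label offset).
    """

    cristae_paths: list[np.ndarray] = field(default_factory=list)
    cj_points: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    n_particles: int = 200
    placement: str = "uniform"
    sigma_nm: float = 30.0
    jitter_nm: float = 0.0
    scale_nm_per_px: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.placement not in ("uniform", "cj_concentrated"):
            raise ValueError(f"unknown placement mode {self.placement!r}")
        if self.placement == "cj_concentrated" and self.sigma_nm <= 0:
            raise ValueError("sigma_nm must be positive for cj_concentrated")
        if self.n_particles < 0:
            raise ValueError("n_particles must be non-negative")


def _path_arcs(path: np.ndarray) -> np.ndarray:
    return np.concatenate(
        ([0.0], np.cumsum(np.linalg.norm(np.diff(path, axis=0), axis=1)))
    )


def _point_at_arc(path: np.ndarray, arcs: np.ndarray, t: float) -> np.ndarray:
    total = arcs[-1]
    # reflect into [0, total]
    t = math.fmod(t, 2 * total) if total > 0 else 0.0
    if t < 0:
        t += 2 * total
    if t > total:
        t = 2 * total - t
    i = int(np.searchsorted(arcs, t, side="right")) - 1
    i = min(max(i, 0), len(arcs) - 2)
    seg = arcs[i + 1] - arcs[i]
    frac = (t - arcs[i]) / seg if seg > 0 else 0.0
    return path[i] + frac * (path[i + 1] - path[i])


def _project_to_path(path: np.ndarray, arcs: np.ndarray, point: np.ndarray):
    """(arc position, distance) of the closest point on a polyline."""
    best = (0.0, math.inf)
    for i in range(len(path) - 1):
        a, b = path[i], path[i + 1]
        v = b - a
        denom = float(v @ v)
        t = float(np.clip((point - a) @ v / denom, 0.0, 1.0)) if denom > 0 else 0.0
        proj = a + t * v
        d = float(np.linalg.norm(point - proj))
        if d < best[1]:
            best = (arcs[i] + t * (arcs[i + 1] - arcs[i]), d)
    return best


def simulate_micrograph(
    config: GoldSimConfig,
) -> tuple[MicrographAnnotation, dict]:
    """Generate a micrograph annotation plus placement ground truth.

    The truth dict carries the placement mode and, for CJ-concentrated
    placement, the chosen CJ index and programmed arc displacement of each
    particle.
    """
    paths = [np.asarray(p, dtype=float) for p in config.cristae_paths]
    if config.n_particles > 0 and not paths:
        raise ValueError("cristae geometry required to place particles")
    if config.n_particles > 0 and total_path_length(paths) <= 0:
        raise ValueError("zero total polyline length")
    rng = np.random.default_rng(config.seed)
    cj = np.asarray(config.cj_points, dtype=float).reshape(-1, 2)

    truth: dict = {"placement": config.placement}
    if config.n_particles == 0:
        particles = np.empty((0, 2))
    elif config.placement == "uniform":
        particles = sample_along_paths(paths, config.n_particles, rng)
    else:
        if len(cj) == 0:
            raise ValueError("cj_concentrated placement requires CJ points")
        arcs = [_path_arcs(p) for p in paths]
        # anchor each CJ to its closest point on the membrane
        anchors = []
        for c in cj:
            best = (0, 0.0, math.inf)
            for pi, (p, a) in enumerate(zip(paths, arcs)):
                s, d = _project_to_path(p, a, c)
                if d < best[2]:
                    best = (pi, s, d)
            anchors.append(best[:2])
        cj_idx = rng.integers(0, len(cj), size=config.n_particles)
        disp = np.abs(rng.normal(0.0, config.sigma_nm, size=config.n_particles))
        signs = rng.choice([-1.0, 1.0], size=config.n_particles)
        particles = np.empty((config.n_particles, 2))
        for i in range(config.n_particles):
            pi, s0 = anchors[cj_idx[i]]
            particles[i] = _point_at_arc(paths[pi], arcs[pi], s0 + signs[i] * disp[i])
        truth["cj_index"] = cj_idx
        truth["arc_displacement"] = disp
    if config.jitter_nm > 0 and config.n_particles > 0:
        particles = particles + rng.normal(0.0, config.jitter_nm, size=particles.shape)

    annotation = MicrographAnnotation(
        particles=particles,
        cj_points=cj,
        cristae_paths=paths,
        scale_nm_per_px=config.scale_nm_per_px,
    )
    return annotation, truth
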