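"""Synthetic multi-condition adhesion/migration/invasion studies.

Generates, per ECM-like condition, (a) labeled cell-mask images of perturbed
ellipses, (b) single-cell trajectories from a persistent random walk and
(c) spheroid day-1/day-5 area pairs — with a known latent coupling from the
shape knobs (elongation, irregularity, size) to the mean spheroid fold
change, so downstream prediction experiments have a recoverable ground
truth.

The three shape knobs map onto the three empirical feature families of
adhesion morphometry: ``size_scale`` (mean equivalent-disk radius, µm) drives
area/perimeter/Feret/mean-radius, ``elongation`` (target mean eccentricity)
drives eccentricity/aspect-ratio/compactness, and ``irregularity`` (radial
boundary-noise amplitude, fraction of the local radius) drives
solidity/extent/form-factor.

Cell outlines are ellipses of the requested eccentricity whose radius is
modulated by low-order Fourier noise::

    R(theta) = r_ell(theta) * (1 + irregularity * f(theta))

where ``f`` is a unit-RMS sum of cosines of orders 2..6 with random phases.

Trajectories are persistent random walks with fixed step length
``speed_base * 10 min`` and wrapped-Gaussian turning angles; the turning
sigma is chosen from a frozen Monte-Carlo calibration table so that the
expected net/total displacement ratio of a 96-step track equals
``persistence_base`` (ratios below the uncorrelated-walk baseline of ~0.09
are not reachable and are clamped).

Everything is deterministic given the spec seed; per-condition streams are
derived by hashing (master seed, condition name).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .morphometry import LabeledMask
from .motility import Trajectory, SpheroidMeasurement

__all__ = [
    "NoiseSpec",
    "ConditionSpec",
    "SyntheticStudy",
    "generate_cell_mask",
    "generate_trajectories",
    "generate_spheroids",
    "generate_study",
    "write_study",
    "derive_seed",
    "persistence_to_sigma",
    "expected_path_ratio",
    "default_study_specs",
    "recovery_study_specs",
]

#: Canvas geometry: typical widefield field of view.
CANVAS_SHAPE = (1024, 1024)
PIXEL_SIZE_UM = 0.65

#: Number of trajectory samples: 16 h at 10-min intervals.
N_TIMEPOINTS = 97
DT_MIN = 10.0

#: Baseline spheroid geometry.
SPHEROID_AREA_UM2 = 1.0e5

# Frozen Monte-Carlo calibration of the persistent random walk: turning-angle
# sigma (rad) -> expected net/total displacement ratio of a 96-step track
# (2e5 tracks per point, seed 12345). Monotone decreasing to the
# uncorrelated-walk baseline ~0.0904.
_PERSISTENCE_TABLE = np.array([
    (0.000000, 1.000000), (0.020000, 0.996808), (0.024347, 0.995269),
    (0.029639, 0.993017), (0.036081, 0.989628), (0.043924, 0.984717),
    (0.053471, 0.977489), (0.065094, 0.966745), (0.079242, 0.951135),
    (0.096466, 0.928683), (0.117433, 0.896646), (0.142958, 0.851813),
    (0.174031, 0.791290), (0.211858, 0.715272), (0.257907, 0.627882),
    (0.313965, 0.538727), (0.382208, 0.453619), (0.465283, 0.377802),
    (0.566416, 0.313936), (0.689531, 0.259336), (0.839405, 0.214946),
    (1.021855, 0.177884), (1.243963, 0.148428), (1.514347, 0.125569),
    (1.843501, 0.108530), (2.244199, 0.098003), (2.731992, 0.092670),
    (3.325809, 0.090755),
])
_SIGMA_MAX = 6.0


def persistence_to_sigma(p: float) -> float:
    """Turning-angle sigma whose expected path ratio equals ``p``.

    Values of ``p`` below the uncorrelated baseline are clamped to the
    maximum calibrated sigma.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"persistence must be in [0, 1], got {p}")
    sig, ratio = _PERSISTENCE_TABLE[:, 0], _PERSISTENCE_TABLE[:, 1]
    if p >= ratio[-1]:
        # interpolate on the (reversed, increasing) ratio axis
        return float(np.interp(p, ratio[::-1], sig[::-1]))
    return _SIGMA_MAX


def expected_path_ratio(p: float) -> float:
    """Expected measured net/total ratio for a spec persistence ``p``."""
    sig, ratio = _PERSISTENCE_TABLE[:, 0], _PERSISTENCE_TABLE[:, 1]
    return float(np.interp(persistence_to_sigma(p), sig, ratio))


@dataclass(frozen=True)
class NoiseSpec:
    """Per-channel noise scales.

    position: isotropic Gaussian localization noise on trajectory points, µm.
    speed_cv: lognormal coefficient of variation of per-cell step length.
    shape_sd: per-cell scatter of eccentricity (additive, clipped) and of
        log equivalent radius.
    spheroid_sigma: sigma of the mean-one lognormal noise on the fold change.
    """

    position: float = 0.3
    speed_cv: float = 0.25
    shape_sd: float = 0.05
    spheroid_sigma: float = 0.25

    @classmethod
    def off(cls) -> "NoiseSpec":
        return cls(0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class ConditionSpec:
    """Generative parameters for one (cell line, ECM) condition."""

    name: str
    cell_line: str = "231"
    n_cells: int = 100
    size_scale: float = 20.0        # mean equivalent-disk radius, µm
    elongation: float = 0.6         # target mean eccentricity, [0, 1)
    irregularity: float = 0.1       # boundary-noise amplitude, fraction of radius
    speed_base: float = 0.4         # µm/min
    persistence_base: float = 0.4   # target net/total ratio, [0, 1]
    invasion_link: tuple[float, float, float] = (0.0, 0.0, 0.0)  # beta (elong, irreg, size)
    base_fold: float = 4.0          # noiseless fold change at zero latent
    noise_sd: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0
    cells_per_mask: int = 25

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0.0 <= self.elongation < 1.0:
            raise ValueError(f"elongation must be in [0, 1), got {self.elongation}")
        if self.size_scale <= 0:
            raise ValueError(f"size_scale must be positive, got {self.size_scale}")
        if not 0.0 <= self.persistence_base <= 1.0:
            raise ValueError("persistence_base must be in [0, 1]")
        if self.irregularity < 0:
            raise ValueError("irregularity must be >= 0")

    @property
    def n_masks(self) -> int:
        return -(-self.n_cells // self.cells_per_mask)

    def latent(self) -> np.ndarray:
        """Latent shape factors feeding the invasion coupling.

        Centered so that a mid-range condition (elongation 0.5, irregularity
        0.15, radius 20 µm) has zero latent and hence the baseline fold.
        """
        return np.array([
            self.elongation - 0.5,
            self.irregularity - 0.15,
            np.log(self.size_scale / 20.0),
        ])

    def expected_fold(self) -> float:
        """Analytic mean fold change (ignoring the floor at 1)."""
        z = float(np.dot(self.invasion_link, self.latent()))
        return 1.0 + (self.base_fold - 1.0) * np.exp(z)


def derive_seed(master: int, *parts: str) -> int:
    """Stable per-stream seed below 2**31 from a master seed and labels."""
    h = hashlib.sha256(("|".join([str(master), *parts])).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _cell_rng(spec: ConditionSpec, stream: str, index: int) -> np.random.Generator:
    return np.random.default_rng(derive_seed(spec.seed, spec.name, stream, str(index)))


def _raster_cell(
    canvas: np.ndarray,
    label: int,
    center: tuple[float, float],
    r_eq_px: float,
    ecc: float,
    phi: float,
    irregularity: float,
    fourier: tuple[np.ndarray, np.ndarray],
) -> None:
    """Paint one perturbed-ellipse cell onto the canvas (background only)."""
    # ellipse with equivalent-disk radius r_eq: a*b = r_eq^2, b/a = sqrt(1-e^2)
    ratio = np.sqrt(1.0 - ecc * ecc)
    a = r_eq_px / ratio**0.5
    b = r_eq_px * ratio**0.5
    amps, phases = fourier
    r_max = a * (1.0 + irregularity * np.abs(amps).sum())
    cy, cx = center
    y0, y1 = int(np.floor(cy - r_max)), int(np.ceil(cy + r_max)) + 1
    x0, x1 = int(np.floor(cx - r_max)), int(np.ceil(cx + r_max)) + 1
    y0c, x0c = max(y0, 0), max(x0, 0)
    y1c, x1c = min(y1, canvas.shape[0]), min(x1, canvas.shape[1])
    if y0c >= y1c or x0c >= x1c:
        return
    yy, xx = np.mgrid[y0c:y1c, x0c:x1c]
    dy, dx = yy - cy, xx - cx
    # rotate into the ellipse frame
    u = np.cos(phi) * dx + np.sin(phi) * dy
    v = -np.sin(phi) * dx + np.cos(phi) * dy
    rho = np.hypot(u, v)
    theta = np.arctan2(v, u)
    r_ell = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    orders = np.arange(2, 2 + len(amps))
    f = np.zeros_like(theta)
    for k, amp, ph in zip(orders, amps, phases):
        f += amp * np.cos(k * theta + ph)
    boundary = r_ell * (1.0 + irregularity * f)
    inside = rho <= boundary
    patch = canvas[y0c:y1c, x0c:x1c]
    patch[inside & (patch == 0)] = label


def generate_cell_mask(spec: ConditionSpec, index: int) -> LabeledMask:
    """One labeled mask image (the ``index``-th of the condition).

    Cells are non-overlapping perturbed ellipses; centers are drawn over the
    whole canvas so some cells may be clipped by the image border (which the
    morphometry stage must then exclude). Deterministic given (seed, index).
    """
    rng = _cell_rng(spec, "mask", index)
    n_here = min(spec.cells_per_mask, spec.n_cells - index * spec.cells_per_mask)
    if n_here <= 0:
        raise ValueError(f"mask index {index} out of range for {spec.n_cells} cells")
    canvas = np.zeros(CANVAS_SHAPE, dtype=np.uint16)
    placed: list[tuple[float, float, float]] = []  # (cy, cx, clearance radius)
    label = 0
    for _ in range(n_here):
        r_eq_um = spec.size_scale * np.exp(rng.normal(0.0, spec.noise_sd.shape_sd))
        r_eq_px = r_eq_um / PIXEL_SIZE_UM
        ecc = float(np.clip(
            spec.elongation + rng.normal(0.0, 2.0 * spec.noise_sd.shape_sd), 0.0, 0.97
        ))
        phi = rng.uniform(0, np.pi)
        n_orders = 5
        raw = rng.normal(0.0, 1.0, n_orders)
        rms = np.sqrt(0.5 * np.sum(raw**2))  # RMS of sum of cosines
        amps = raw / rms if rms > 0 else raw
        phases = rng.uniform(0, 2 * np.pi, n_orders)
        ratio = np.sqrt(1.0 - ecc * ecc)
        clearance = r_eq_px / ratio**0.5 * (1.0 + spec.irregularity * np.abs(amps).sum())
        for _try in range(300):
            cy = rng.uniform(0, CANVAS_SHAPE[0])
            cx = rng.uniform(0, CANVAS_SHAPE[1])
            if all(
                np.hypot(cy - py, cx - px) > clearance + pc + 2.0
                for py, px, pc in placed
            ):
                break
        else:
            continue  # canvas too crowded; drop this cell
        label += 1
        _raster_cell(
            canvas, label, (cy, cx), r_eq_px, ecc, phi, spec.irregularity,
            (amps, phases),
        )
        placed.append((cy, cx, clearance))
    return LabeledMask(labels=canvas.astype(np.int64), pixel_size=PIXEL_SIZE_UM)


def generate_masks(spec: ConditionSpec) -> list[LabeledMask]:
    """All mask images for a condition (n_cells split across images)."""
    return [generate_cell_mask(spec, i) for i in range(spec.n_masks)]


def generate_trajectories(spec: ConditionSpec) -> list[Trajectory]:
    """``n_cells`` persistent-random-walk tracks, 97 points at 10-min spacing."""
    sigma = persistence_to_sigma(spec.persistence_base)
    times = np.arange(N_TIMEPOINTS) * DT_MIN
    out: list[Trajectory] = []
    for i in range(spec.n_cells):
        rng = _cell_rng(spec, "traj", i)
        cv = spec.noise_sd.speed_cv
        if cv > 0:
            s2 = np.log1p(cv * cv)
            step = spec.speed_base * DT_MIN * rng.lognormal(-s2 / 2.0, np.sqrt(s2))
        else:
            step = spec.speed_base * DT_MIN
        h0 = rng.uniform(0, 2 * np.pi)
        turns = rng.normal(0.0, sigma, N_TIMEPOINTS - 2)
        headings = np.concatenate([[h0], h0 + np.cumsum(turns)])
        dx = step * np.cos(headings)
        dy = step * np.sin(headings)
        pos = np.zeros((N_TIMEPOINTS, 2))
        pos[1:, 0] = np.cumsum(dx)
        pos[1:, 1] = np.cumsum(dy)
        if spec.noise_sd.position > 0:
            pos = pos + rng.normal(0.0, spec.noise_sd.position, pos.shape)
        out.append(Trajectory(cell_id=f"{spec.name}_{i}", times=times.copy(), positions=pos))
    return out


def generate_spheroids(spec: ConditionSpec, n_replicates: int) -> list[SpheroidMeasurement]:
    """Spheroid day-1/day-5 area pairs for one condition.

    Day-1 areas are lognormal around a fixed spheroid size; the fold change is
    ``1 + (F0 - 1) * exp(beta . latent) * eps`` where F0 is the condition's
    base fold constant and ``eps`` is mean-one lognormal noise, floored at 1
    so a spheroid never shrinks below its starting area.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(derive_seed(spec.seed, spec.name, "spheroid"))
    z = float(np.dot(spec.invasion_link, spec.latent()))
    sig = spec.noise_sd.spheroid_sigma
    out: list[SpheroidMeasurement] = []
    for rep in range(n_replicates):
        a1 = SPHEROID_AREA_UM2 * rng.lognormal(0.0, 0.1)
        eps = rng.lognormal(-sig * sig / 2.0, sig) if sig > 0 else 1.0
        fold = max(1.0 + (spec.base_fold - 1.0) * np.exp(z) * eps, 1.0)
        out.append(SpheroidMeasurement(
            condition=spec.name, replicate=rep, area_day1=a1, area_day5=a1 * fold,
        ))
    return out


@dataclass
class SyntheticStudy:
    """A complete multi-condition synthetic dataset plus its ground truth."""

    conditions: list[ConditionSpec]
    masks: dict[str, list[LabeledMask]]
    trajectories: dict[str, list[Trajectory]]
    spheroids: dict[str, list[SpheroidMeasurement]]
    truth: dict[str, dict]

    def condition_names(self) -> list[str]:
        return [c.name for c in self.conditions]


def generate_study(
    config: Sequence[ConditionSpec],
    master_seed: int | None = None,
    n_spheroid_replicates: int = 18,
) -> SyntheticStudy:
    """Assemble masks, trajectories, spheroids and truth for >= 2 conditions.

    If ``master_seed`` is given, each condition's seed is rederived from
    (master, condition name), overriding any seed in the specs.
    """
    config = list(config)
    if len(config) < 2:
        raise ValueError("a study needs at least 2 conditions")
    names = [c.name for c in config]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate condition names: {names}")
    if master_seed is not None:
        config = [
            ConditionSpec(**{**asdict_spec(c), "seed": derive_seed(master_seed, c.name)})
            for c in config
        ]
    masks = {c.name: generate_masks(c) for c in config}
    trajectories = {c.name: generate_trajectories(c) for c in config}
    spheroids = {c.name: generate_spheroids(c, n_spheroid_replicates) for c in config}
    truth = {
        c.name: {
            "latent": c.latent().tolist(),
            "expected_eccentricity": c.elongation,
            "expected_speed": c.speed_base,
            "expected_persistence": expected_path_ratio(c.persistence_base),
            "expected_fold": c.expected_fold(),
            "seed": c.seed,
        }
        for c in config
    }
    return SyntheticStudy(
        conditions=config, masks=masks, trajectories=trajectories,
        spheroids=spheroids, truth=truth,
    )


def asdict_spec(spec: ConditionSpec) -> dict:
    d = asdict(spec)
    d["noise_sd"] = spec.noise_sd  # keep the dataclass, not a nested dict
    return d


def write_study(study: SyntheticStudy, outdir: str | Path) -> None:
    """Serialize a study: label TIFFs, trajectory/spheroid CSVs, truth JSON."""
    import tifffile

    outdir = Path(outdir)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    for name, masks in study.masks.items():
        for i, m in enumerate(masks):
            tifffile.imwrite(
                outdir / "masks" / f"{name}_{i:03d}.tif",
                m.labels.astype(np.uint16),
            )
    rows = []
    for name, trajs in study.trajectories.items():
        for tr in trajs:
            for t, (x, y) in zip(tr.times, tr.positions):
                rows.append((name, tr.cell_id, t, x, y))
    pd.DataFrame(rows, columns=["condition", "cell_id", "t_min", "x_um", "y_um"]).to_csv(
        outdir / "trajectories.csv", index=False, float_format="%.9g"
    )
    rows = [
        (s.condition, s.replicate, s.area_day1, s.area_day5)
        for sph in study.spheroids.values()
        for s in sph
    ]
    pd.DataFrame(
        rows, columns=["condition", "replicate", "area_day1_um2", "area_day5_um2"]
    ).to_csv(outdir / "spheroids.csv", index=False, float_format="%.9g")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(study.truth, fh, indent=1)


# ---------------------------------------------------------------------------
# Canned study configurations


def default_study_specs(master_seed: int = 0, n_cells: int = 80) -> list[ConditionSpec]:
    """A five-condition study mimicking no-ECM / Collagen I / Fibronectin /
    Tenascin C / Collagen IV for one mesenchymal-like cell line.

    Knob settings follow the qualitative ordering of the measured study:
    collagens elongate cells, raise speed/persistence and drive strong
    invasion; Tenascin C shrinks and rounds cells with weak migration.
    """
    link = (3.5, 4.0, 0.0)
    base = dict(cell_line="231", n_cells=n_cells, invasion_link=link)
    specs = [
        ConditionSpec(name="noECM", size_scale=18, elongation=0.45, irregularity=0.08,
                      speed_base=0.35, persistence_base=0.30, **base),
        ConditionSpec(name="CollagenI", size_scale=24, elongation=0.80, irregularity=0.22,
                      speed_base=0.65, persistence_base=0.55, **base),
        ConditionSpec(name="Fibronectin", size_scale=22, elongation=0.65, irregularity=0.18,
                      speed_base=0.40, persistence_base=0.35, **base),
        ConditionSpec(name="TenascinC", size_scale=14, elongation=0.35, irregularity=0.06,
                      speed_base=0.25, persistence_base=0.40, **base),
        ConditionSpec(name="CollagenIV", size_scale=21, elongation=0.75, irregularity=0.25,
                      speed_base=0.60, persistence_base=0.50, **base),
    ]
    return [
        ConditionSpec(**{**asdict_spec(s), "seed": derive_seed(master_seed, s.name)})
        for s in specs
    ]


def recovery_study_specs(
    master_seed: int = 0,
    n_conditions: int = 8,
    n_cells: int = 50,
    invasion_link: tuple[float, float, float] = (1.2, 1.4, 0.0),
) -> list[ConditionSpec]:
    """An ``n_conditions``-condition study for parameter-recovery experiments.

    Elongation and irregularity vary over their realistic ranges and drive
    invasion through ``invasion_link``; size varies independently of invasion
    so that size features act as realistic nuisance variation.
    """
    rng = np.random.default_rng(derive_seed(master_seed, "recovery-design"))
    elongs = np.linspace(0.35, 0.85, n_conditions)
    if n_conditions < 2:
        raise ValueError("recovery design needs at least 2 conditions")
    # irregularity: a permutation kept only weakly correlated with the
    # elongation ramp so both latent drivers are separately identifiable
    irreg_levels = np.linspace(0.04, 0.32, n_conditions)
    for _ in range(200):
        irreg_order = rng.permutation(n_conditions)
        if abs(np.corrcoef(elongs, irreg_levels[irreg_order])[0, 1]) < 0.3:
            break
    irregs = irreg_levels[irreg_order]
    # size: shuffled symmetric levels, kept near-orthogonal to both invasion
    # drivers so size features act as nuisance variation, not signal
    size_levels = np.linspace(14.0, 28.0, n_conditions)
    for _ in range(500):
        size_order = rng.permutation(n_conditions)
        sizes = size_levels[size_order]
        if (abs(np.corrcoef(elongs, sizes)[0, 1]) < 0.25
                and abs(np.corrcoef(irregs, sizes)[0, 1]) < 0.25):
            break
    specs = []
    for i in range(n_conditions):
        elong = float(elongs[i])
        irreg = float(irregs[i])
        size = float(sizes[i])
        speed = 0.2 + 0.4 * (elong - 0.3) + 0.2 * float(rng.uniform())
        specs.append(ConditionSpec(
            name=f"ECM{i}", cell_line="231", n_cells=n_cells,
            size_scale=size, elongation=round(elong, 3), irregularity=round(irreg, 3),
            speed_base=round(speed, 3), persistence_base=round(0.25 + 0.5 * elong, 3),
            invasion_link=invasion_link,
            noise_sd=NoiseSpec(spheroid_sigma=0.15),
            seed=derive_seed(master_seed, f"ECM{i}"),
        ))
    return specs


def shifted_line_specs(
    specs: Sequence[ConditionSpec],
    master_seed: int = 0,
    cell_line: str = "468",
    base_fold: float = 2.6,
    size_factor: float = 0.85,
) -> list[ConditionSpec]:
    """The same ECM conditions measured in a second, shifted cell line.

    Emulates an epithelial-like line responding to the same cues with a
    lower invasion baseline and smaller cells: the base fold constant drops
    and sizes shrink by ``size_factor`` while the latent couplings are kept.
    Used for model-augmentation experiments in which adding the new line's
    baseline condition to the training set should reduce prediction error on
    its remaining conditions.
    """
    return [
        ConditionSpec(**{
            **asdict_spec(s),
            "name": f"{s.name}_{cell_line}",
            "cell_line": cell_line,
            "base_fold": base_fold,
            "size_scale": s.size_scale * size_factor,
            "seed": derive_seed(master_seed, s.name, "shifted-line"),
        })
        for s in specs
    ]
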