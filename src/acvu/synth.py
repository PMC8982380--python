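"""Synthetic two-channel gonad-primordium stacks with known ground truth.

During the first larval stages of *C. elegans* gonadogenesis, four proximal
somatic gonad cells -- two alpha cells and their lineage sisters, the beta
cells -- transiently share anchor-cell (AC) potential.  The beta cells
normally adopt the ventral uterine precursor (VU) fate, while the alpha
cells resolve AC vs. VU by LIN-12/Notch lateral signalling.  A
nuclear-localised GFP fusion to the E-protein HLH-2 stays bright in the AC
and is degraded in VUs, and a ubiquitously expressed nuclear mCherry
histone marker labels all four nuclei for segmentation.

This module emulates the statistical structure of confocal z-stacks of that
primordium: four Gaussian nuclear blobs on a dim intra-animal background,
imaged in two channels with shot and read noise.  Every stochastic quantity
(fluorescence totals, fates, geometry, noise) flows from one explicit seed
through spawned child generators, so whole screen datasets are exactly
reproducible.  Condition parameters encode biological perturbations:
``ac_count_dist`` models genotypes with supernumerary ACs (e.g. a Notch
null), and ``stabilization_penetrance`` models RNAi clones that block
GFP::HLH-2 degradation in a fraction of VU-fated cells.

Arrays are stored ``(z, y, x)`` as is conventional for image stacks;
coordinates in the public API and sidecar files are ``(x, y, z)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

ROLES = ("alpha1", "alpha2", "beta1", "beta2")
SISTER_OF = {"alpha1": "beta1", "beta1": "alpha1", "alpha2": "beta2", "beta2": "alpha2"}
FATES = ("AC", "VU", "unspecified")

#: default z step of the emulated confocal acquisition, in nanometres
DEFAULT_Z_SPACING_NM = 260.0


def _rng(seed) -> np.random.Generator:
    """Accept an int seed, a SeedSequence, or an existing Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        raise ValueError("an explicit seed is required; no global RNG state is used")
    return np.random.default_rng(seed)


def _spawn(seed, n: int) -> list[np.random.SeedSequence]:
    if isinstance(seed, np.random.SeedSequence):
        return seed.spawn(n)
    return np.random.SeedSequence(seed).spawn(n)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LogNormal:
    """Log-normal level distribution parameterised by median and log-scale."""

    median: float
    sigma: float

    def __post_init__(self):
        if self.median < 0:
            raise ValueError(f"median must be >= 0, got {self.median}")
        if self.sigma < 0:
            raise ValueError(f"log-scale sigma must be >= 0, got {self.sigma}")

    def sample(self, rng: np.random.Generator, size=None):
        return self.median * np.exp(rng.normal(0.0, self.sigma, size=size))


@dataclass(frozen=True)
class NucleusTruth:
    """Ground truth for one rendered nucleus.

    ``center`` is in voxel coordinates ``(x, y, z)``; ``radius`` in voxels.
    ``true_gfp_total`` / ``true_mcherry_total`` are total integrated
    fluorescence in arbitrary units (AU) before background and noise.
    ``stabilized`` marks a VU-fated cell that received an AC-like GFP draw
    (the phenotype an RNAi hit produces).
    """

    cell_id: str
    sister_id: str
    center: tuple[float, float, float]
    radius: float
    true_gfp_total: float
    true_mcherry_total: float
    fate: str = "unspecified"
    stabilized: bool = False

    def __post_init__(self):
        if self.cell_id not in ROLES:
            raise ValueError(f"cell_id must be one of {ROLES}, got {self.cell_id!r}")
        if SISTER_OF[self.cell_id] != self.sister_id:
            raise ValueError(
                f"sister pairing must partition the 4 cells into alpha/beta sister "
                f"pairs; {self.cell_id} pairs with {SISTER_OF[self.cell_id]}, "
                f"not {self.sister_id}"
            )
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.true_gfp_total < 0:
            raise ValueError("true_gfp_total must be >= 0")
        if self.true_mcherry_total <= 0:
            raise ValueError("true_mcherry_total must be > 0")
        if self.fate not in FATES:
            raise ValueError(f"fate must be one of {FATES}")


@dataclass
class ImageStack:
    """Two-channel voxel grid plus acquisition metadata and a larva mask."""

    gfp: np.ndarray
    mcherry: np.ndarray
    larva_mask: np.ndarray
    z_spacing_nm: float = DEFAULT_Z_SPACING_NM
    xy_spacing_nm: float = DEFAULT_Z_SPACING_NM

    def __post_init__(self):
        self.gfp = np.asarray(self.gfp, dtype=float)
        self.mcherry = np.asarray(self.mcherry, dtype=float)
        self.larva_mask = np.asarray(self.larva_mask, dtype=bool)
        if self.gfp.shape != self.mcherry.shape or self.gfp.shape != self.larva_mask.shape:
            raise ValueError(
                f"channel/mask shapes differ: gfp {self.gfp.shape}, "
                f"mcherry {self.mcherry.shape}, mask {self.larva_mask.shape}"
            )
        if self.gfp.ndim != 3:
            raise ValueError("stacks must be 3-D (z, y, x)")
        for name, arr in (("gfp", self.gfp), ("mcherry", self.mcherry)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} channel contains non-finite values")
            if arr.min() < 0:
                raise ValueError(f"{name} channel contains negative intensities")

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.gfp.shape

    @property
    def shape_xyz(self) -> tuple[int, int, int]:
        nz, ny, nx = self.gfp.shape
        return (nx, ny, nz)


@dataclass(frozen=True)
class NoiseParams:
    """Camera model: Poisson shot noise on expected counts + Gaussian read noise."""

    poisson: bool = True
    read_sigma: float = 80.0

    def __post_init__(self):
        if self.read_sigma < 0:
            raise ValueError("read_sigma must be >= 0")


NOISE_OFF = NoiseParams(poisson=False, read_sigma=0.0)

#: default per-fate GFP::HLH-2 total-intensity distributions (AU).  The AC
#: retains bright GFP (median 10x the degraded VU level); the AC spread is
#: wide enough that, as in real populations, roughly 85-90% of ACs lie above
#: one SD below the mean.  "unspecified" is a broad calibration range used
#: for parameter-recovery experiments.
DEFAULT_GFP_LEVELS = {
    "AC": LogNormal(20000.0, 0.35),
    "VU": LogNormal(2000.0, 0.20),
    "unspecified": LogNormal(6300.0, 0.80),
}

DEFAULT_MCHERRY_LEVEL = LogNormal(30000.0, 0.15)


@dataclass(frozen=True)
class ConditionParams:
    """One experimental condition (a genotype or RNAi clone).

    ``ac_count_dist`` maps number of AC-fated cells per animal to its
    probability (e.g. ``{1: 1.0}`` for wild type, ``{2: 1.0}`` for a Notch
    null where both alpha cells become ACs).  ``stabilization_penetrance``
    is the fraction of VU-fated cells that nonetheless receive an AC-like
    GFP draw, the phenotype produced by depleting a GFP::HLH-2 degrader.
    """

    name: str
    gfp_levels: dict = field(default_factory=lambda: dict(DEFAULT_GFP_LEVELS))
    mcherry_level: LogNormal = DEFAULT_MCHERRY_LEVEL
    stabilization_penetrance: float = 0.0
    ac_count_dist: dict = field(default_factory=lambda: {1: 1.0})
    n_animals: int = 20
    control: str | None = None  # None | "negative" | "positive"
    calibration: bool = False  # all fates "unspecified", GFP from the wide range

    def __post_init__(self):
        if not 0.0 <= self.stabilization_penetrance <= 1.0:
            raise ValueError("stabilization_penetrance must lie in [0, 1]")
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        probs = np.array(list(self.ac_count_dist.values()), dtype=float)
        if probs.size == 0 or probs.min() < 0 or not math.isclose(probs.sum(), 1.0, rel_tol=1e-9):
            raise ValueError("ac_count_dist probabilities must be >= 0 and sum to 1")
        for k in self.ac_count_dist:
            if not 0 <= int(k) <= 4:
                raise ValueError("AC counts must lie in [0, 4]")
        if self.control not in (None, "negative", "positive"):
            raise ValueError("control must be None, 'negative' or 'positive'")


# condition factories ------------------------------------------------------


def negative_control(n_animals: int = 20) -> ConditionParams:
    """lacZ-style negative control: one AC, VUs degrade GFP::HLH-2."""
    return ConditionParams(name="lacZ", n_animals=n_animals, control="negative")


def positive_control(n_animals: int = 20, beta_penetrance: float = 0.7) -> ConditionParams:
    """Notch-RNAi-style positive control: both alpha cells AC-fated and
    GFP::HLH-2 frequently stabilized in the beta cells."""
    return ConditionParams(
        name="lin-12",
        n_animals=n_animals,
        control="positive",
        ac_count_dist={2: 1.0},
        stabilization_penetrance=beta_penetrance,
    )


def rnai_clone(name: str, penetrance: float, n_animals: int = 20) -> ConditionParams:
    """Experimental RNAi clone stabilizing GFP::HLH-2 with the given penetrance."""
    return ConditionParams(
        name=name, n_animals=n_animals, stabilization_penetrance=penetrance
    )


def lin12_null(n_animals: int = 20, beta_ac_fraction: float = 0.15) -> ConditionParams:
    """Notch-null genotype: both alphas become ACs; a minority of beta cells
    transform to the AC fate as well (temperature-dependent in vivo)."""
    p = beta_ac_fraction
    # number of AC-fated cells = 2 alphas + Binomial(2, p) betas
    dist = {2: (1 - p) ** 2, 3: 2 * p * (1 - p), 4: p**2}
    return ConditionParams(name="lin-12(0)", n_animals=n_animals, ac_count_dist=dist)


def recovery_condition(n_animals: int = 50) -> ConditionParams:
    """Calibration condition: every nucleus draws its GFP total from one wide
    log-normal spanning the VU-to-AC dynamic range, for measuring how well the
    quantification pipeline recovers known totals."""
    return ConditionParams(
        name="recovery", n_animals=n_animals, ac_count_dist={0: 1.0}, calibration=True
    )


# ---------------------------------------------------------------------------
# per-animal specification sampling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnimalSpec:
    """Sampled ground truth for one animal, plus its private render seed."""

    animal_id: str
    condition: str
    nuclei: tuple[NucleusTruth, ...]
    render_seed: int


#: default stack geometry (x, y, z); nuclei sit on a 2x2 lateral grid in the
#: left 2/3 of the frame so an outside-larva background region always exists.
DEFAULT_SHAPE_XYZ = (48, 48, 16)
_GRID_XY = ((12.0, 16.0), (24.0, 16.0), (12.0, 32.0), (24.0, 32.0))
_DEFAULT_RADIUS_RANGE = (2.3, 2.7)


def _sample_geometry(rng: np.random.Generator):
    order = rng.permutation(4)
    centers, radii = [], []
    zc = DEFAULT_SHAPE_XYZ[2] / 2.0
    for i in range(4):
        x0, y0 = _GRID_XY[order[i]]
        centers.append(
            (
                x0 + rng.uniform(-1.0, 1.0),
                y0 + rng.uniform(-1.0, 1.0),
                zc + rng.uniform(-0.7, 0.7),
            )
        )
        radii.append(rng.uniform(*_DEFAULT_RADIUS_RANGE))
    return centers, radii


def sample_animal(params: ConditionParams, seed, animal_id: str = "a0") -> AnimalSpec:
    """Draw one animal's four-nucleus ground truth for a condition."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    centers, radii = _sample_geometry(rng)

    counts = sorted(params.ac_count_dist)
    probs = [params.ac_count_dist[c] for c in counts]
    n_ac = int(rng.choice(counts, p=probs))

    # AC fate fills the alpha cells first (the AC always arises from an
    # alpha cell unless betas transform); which alpha becomes the AC when
    # there is only one is natural variability.
    fates = {}
    alphas = ["alpha1", "alpha2"]
    betas = ["beta1", "beta2"]
    rng.shuffle(alphas)
    rng.shuffle(betas)
    for i, cell in enumerate(alphas + betas):
        fates[cell] = "AC" if i < n_ac else "VU"
    if params.calibration:
        fates = {c: "unspecified" for c in ROLES}

    nuclei = []
    for i, cell in enumerate(ROLES):
        fate = fates[cell]
        stabilized = False
        if fate == "VU" and rng.random() < params.stabilization_penetrance:
            stabilized = True
        level_key = "AC" if (fate == "AC" or stabilized) else fate
        gfp = float(params.gfp_levels[level_key].sample(rng))
        mch = float(params.mcherry_level.sample(rng))
        nuclei.append(
            NucleusTruth(
                cell_id=cell,
                sister_id=SISTER_OF[cell],
                center=centers[i],
                radius=radii[i],
                true_gfp_total=gfp,
                true_mcherry_total=mch,
                fate=fate,
                stabilized=stabilized,
            )
        )
    render_seed = int(rng.integers(0, 2**31 - 1))
    return AnimalSpec(
        animal_id=animal_id,
        condition=params.name,
        nuclei=tuple(nuclei),
        render_seed=render_seed,
    )


def sample_condition(params: ConditionParams, seed) -> list[AnimalSpec]:
    """Sample ``params.n_animals`` animal specifications for one condition.

    Per-fate GFP totals follow the configured log-normals; the fraction of
    VU-fated cells receiving AC-like draws converges to
    ``stabilization_penetrance`` as the number of animals grows.
    """
    seqs = _spawn(seed, params.n_animals)
    return [
        sample_animal(params, np.random.default_rng(s), animal_id=f"{params.name}-{i:03d}")
        for i, s in enumerate(seqs)
    ]


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


@dataclass
class GroundTruthRecord:
    """Everything known about a rendered animal image."""

    nuclei: tuple[NucleusTruth, ...]
    overlapping_pairs: tuple[tuple[str, str], ...]
    background_level: float
    noise: NoiseParams
    seed: int | None
    animal_id: str = ""
    condition: str = ""


def _larva_mask(shape_zyx, nuclei: Sequence[NucleusTruth], margin_factor: float = 4.0):
    """Axis-aligned ellipsoid containing every nucleus with margin, so that
    an outside-the-animal region exists for background measurement."""
    nz, ny, nx = shape_zyx
    xs = np.array([n.center[0] for n in nuclei])
    ys = np.array([n.center[1] for n in nuclei])
    zs = np.array([n.center[2] for n in nuclei])
    rmax = max(n.radius for n in nuclei)
    margin_xy = margin_factor * rmax
    cx, cy, cz = (xs.min() + xs.max()) / 2, (ys.min() + ys.max()) / 2, (zs.min() + zs.max()) / 2
    ax = (xs.max() - xs.min()) / 2 + margin_xy
    ay = (ys.max() - ys.min()) / 2 + margin_xy
    az = (zs.max() - zs.min()) / 2 + 3.0 * rmax + 1.0
    zz, yy, xx = np.ogrid[:nz, :ny, :nx]
    return ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 + ((zz - cz) / az) ** 2 <= 1.0


def _render_blob(channel: np.ndarray, center_xyz, radius: float, total: float):
    """Add an isotropic 3-D Gaussian blob (sigma = radius/2, truncated at
    3 sigma, renormalised) whose voxel sum equals ``total`` exactly."""
    nz, ny, nx = channel.shape
    x, y, z = center_xyz
    sigma = radius / 2.0
    ext = 3.0 * sigma
    zlo, zhi = int(math.floor(z - ext)), int(math.ceil(z + ext))
    ylo, yhi = int(math.floor(y - ext)), int(math.ceil(y + ext))
    xlo, xhi = int(math.floor(x - ext)), int(math.ceil(x + ext))
    if zlo < 0 or ylo < 0 or xlo < 0 or zhi >= nz or yhi >= ny or xhi >= nx:
        raise ValueError(
            f"nucleus at (x={x:.1f}, y={y:.1f}, z={z:.1f}) with radius {radius:.2f} "
            f"does not fit inside the {nx}x{ny}x{nz} grid"
        )
    zz, yy, xx = np.ogrid[zlo : zhi + 1, ylo : yhi + 1, xlo : xhi + 1]
    d2 = (xx - x) ** 2 + (yy - y) ** 2 + (zz - z) ** 2
    w = np.exp(-d2 / (2.0 * sigma**2))
    w[d2 > ext**2] = 0.0
    w /= w.sum()
    channel[zlo : zhi + 1, ylo : yhi + 1, xlo : xhi + 1] += total * w


def make_animal_image(
    nuclei: Sequence[NucleusTruth],
    background_level: float = 2.0,
    noise: NoiseParams = NoiseParams(),
    seed=None,
    shape_xyz: tuple[int, int, int] = DEFAULT_SHAPE_XYZ,
    animal_id: str = "",
    condition: str = "",
) -> tuple[ImageStack, GroundTruthRecord]:
    """Render one animal's two-channel stack from nucleus ground truth.

    Each nucleus is an isotropic 3-D Gaussian blob whose noise-free voxel
    sum equals its true channel total.  ``background_level`` (AU/voxel) is
    added inside the larva mask only; shot and read noise are then applied
    voxelwise.  Nuclei whose truncated kernel would leave the grid are
    rejected with their coordinates; overlapping nuclei are allowed but the
    pair is flagged in the returned record.
    """
    if not nuclei:
        raise ValueError("at least one nucleus is required")
    if noise != NOISE_OFF and seed is None:
        raise ValueError("a seed is required when noise is enabled")
    nx, ny, nz = shape_xyz
    gfp = np.zeros((nz, ny, nx), dtype=float)
    mch = np.zeros((nz, ny, nx), dtype=float)
    for nuc in nuclei:
        _render_blob(gfp, nuc.center, nuc.radius, nuc.true_gfp_total)
        _render_blob(mch, nuc.center, nuc.radius, nuc.true_mcherry_total)

    mask = _larva_mask((nz, ny, nx), nuclei)
    if background_level < 0:
        raise ValueError("background_level must be >= 0")
    gfp[mask] += background_level
    mch[mask] += background_level

    overlaps = []
    for i in range(len(nuclei)):
        for j in range(i + 1, len(nuclei)):
            d = math.dist(nuclei[i].center, nuclei[j].center)
            if d < nuclei[i].radius + nuclei[j].radius:
                overlaps.append((nuclei[i].cell_id, nuclei[j].cell_id))

    if noise != NOISE_OFF:
        rng = _rng(seed)
        for arr in (gfp, mch):
            if noise.poisson:
                arr[:] = rng.poisson(arr)
            if noise.read_sigma > 0:
                arr += rng.normal(0.0, noise.read_sigma, size=arr.shape)
            np.clip(arr, 0.0, None, out=arr)

    stack = ImageStack(gfp=gfp, mcherry=mch, larva_mask=mask)
    record = GroundTruthRecord(
        nuclei=tuple(nuclei),
        overlapping_pairs=tuple(overlaps),
        background_level=background_level,
        noise=noise,
        seed=None if seed is None else int(seed) if isinstance(seed, (int, np.integer)) else -1,
        animal_id=animal_id,
        condition=condition,
    )
    return stack, record


def render_animal(
    spec: AnimalSpec,
    background_level: float = 2.0,
    noise: NoiseParams = NoiseParams(),
    shape_xyz: tuple[int, int, int] = DEFAULT_SHAPE_XYZ,
) -> tuple[ImageStack, GroundTruthRecord]:
    """Render a sampled :class:`AnimalSpec` using its private seed."""
    return make_animal_image(
        spec.nuclei,
        background_level=background_level,
        noise=noise,
        seed=spec.render_seed,
        shape_xyz=shape_xyz,
        animal_id=spec.animal_id,
        condition=spec.condition,
    )


# ---------------------------------------------------------------------------
# screen datasets
# ---------------------------------------------------------------------------


@dataclass
class ScreenRound:
    name: str
    conditions: list  # list of (ConditionParams, list[AnimalSpec])


@dataclass
class ScreenDataset:
    """A whole screen: rounds of conditions plus per-clone truth labels."""

    rounds: list
    truth_hits: dict
    seed: int

    def clone_names(self) -> list[str]:
        out = []
        for rnd in self.rounds:
            out.extend(p.name for p, _ in rnd.conditions if p.control is None)
        return out


def make_screen_dataset(design: Sequence[Sequence[ConditionParams]], seed: int) -> ScreenDataset:
    """Sample a full screen dataset from a round-structured design.

    ``design`` is a list of rounds, each a list of :class:`ConditionParams`
    containing exactly one negative and one positive control.  Ground-truth
    hit labels (``stabilization_penetrance > 0`` for experimental clones)
    are stored for recovery testing.  Deterministic given ``seed``.
    """
    truth = {}
    for r, round_params in enumerate(design):
        negs = [p for p in round_params if p.control == "negative"]
        poss = [p for p in round_params if p.control == "positive"]
        if len(negs) != 1 or len(poss) != 1:
            raise ValueError(
                f"round {r} must contain exactly one negative and one positive "
                f"control (got {len(negs)} negative, {len(poss)} positive)"
            )
        for p in round_params:
            if p.control is None:
                if p.name in truth:
                    raise ValueError(f"duplicate clone name {p.name!r}")
                truth[p.name] = p.stabilization_penetrance > 0

    round_seqs = _spawn(seed, len(design))
    rounds = []
    for r, (round_params, rseq) in enumerate(zip(design, round_seqs)):
        cond_seqs = rseq.spawn(len(round_params))
        conds = [
            (p, sample_condition(p, cseq)) for p, cseq in zip(round_params, cond_seqs)
        ]
        rounds.append(ScreenRound(name=f"round-{r:02d}", conditions=conds))
    return ScreenDataset(rounds=rounds, truth_hits=truth, seed=int(seed))


def default_screen_design(
    n_clones: int = 10,
    hit_clones: Sequence[str] = ("clone-00", "clone-01"),
    hit_penetrance: float = 0.9,
    n_animals: int = 20,
    clones_per_round: int = 10,
) -> list[list[ConditionParams]]:
    """Design with planted hits: rounds of up to 10 experimental clones, each
    round carrying a lacZ negative and a lin-12 positive control."""
    clones = []
    for i in range(n_clones):
        name = f"clone-{i:02d}"
        pen = hit_penetrance if name in hit_clones else 0.0
        clones.append(rnai_clone(name, pen, n_animals=n_animals))
    design = []
    for start in range(0, len(clones), clones_per_round):
        chunk = clones[start : start + clones_per_round]
        design.append(
            [negative_control(n_animals), positive_control(n_animals)] + chunk
        )
    return design
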