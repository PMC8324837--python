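"""Synthetic SIMS data with known ground truth.

Three generators cover the inputs the analysis pipeline consumes:

* :func:`generate_nuclear_phantom` — a multichannel 3D ion-count volume of a
  cell built from parametric subnuclear structures (nucleolus, speckles,
  heterochromatin, euchromatin, lamina, cytoplasm), with Poisson counting
  noise and a per-structure drug partitioning, plus the voxel-exact label
  volume.
* :func:`generate_edge_linescan` — a Gaussian-blurred step-edge intensity
  profile for resolution estimation.
* :func:`generate_splicing_counts` — per-gene exon/intron fragment counts for
  a control vs treatment comparison, with a configurable fraction of genes
  whose exon/intron ratio changes by a known fold.

All generators are bit-reproducible given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import ChannelStack, LineScan, MultiplexVolume

__all__ = [
    "StructureSpec",
    "PhantomConfig",
    "GroundTruth",
    "generate_nuclear_phantom",
    "generate_edge_linescan",
    "generate_splicing_counts",
    "nuclear_phantom_config",
    "multidrug_phantom_config",
    "DEFAULT_CHANNELS",
    "DEFAULT_DRUG_MULTIPLIERS",
    "STRUCTURE_PRECEDENCE",
]

#: standard channel panel: isotope -> marker
DEFAULT_CHANNELS = {
    "12C": "carbon",
    "19F": "nucleolin",
    "31P": "DNA",
    "81Br": "H3K9me3",
    "127I": "H3K27Ac",
    "194Pt": "cisplatin",
    "197Au": "SC35",
}

#: painting precedence when structure geometries overlap (higher wins)
STRUCTURE_PRECEDENCE = [
    "background",
    "cytoplasm",
    "euchromatin",
    "lamina",
    "nucleus_envelope",
    "heterochromatin",
    "perinucleolar_rim",
    "nucleolus",
    "speckle",
]

#: drug partitioning default: enriched in speckles, depleted from
#: heterochromatin, absent from bare substrate
DEFAULT_DRUG_MULTIPLIERS = {
    "background": 0.0,
    "cytoplasm": 1.0,
    "euchromatin": 1.2,
    "lamina": 0.8,
    "nucleus_envelope": 0.8,
    "heterochromatin": 0.3,
    "perinucleolar_rim": 0.8,
    "nucleolus": 1.0,
    "speckle": 3.0,
}


@dataclass
class StructureSpec:
    """Parametric geometry of one subcellular structure, pixel units.

    kind: ``full`` (covers the grid), ``ellipsoid`` (center + radii, both
    (z, y, x)), ``shell`` (ellipsoid shell of given thickness), or ``blobs``
    (n spheres of given radius scattered uniformly inside a containing
    ellipsoid).
    """

    name: str
    kind: str
    center: tuple[float, float, float] | None = None
    radii: tuple[float, float, float] | None = None
    thickness: float = 0.0
    n_blobs: int = 0
    blob_radius: float = 0.0
    ellipsoids: list[tuple[tuple[float, float, float],
                           tuple[float, float, float]]] = field(default_factory=list)
    #: ignore z: the structure spans the whole acquired slab (appropriate when
    #: the slab is thinner than the organelle, ~5 nm/plane)
    cylindrical: bool = False

    def validate(self, dims: tuple[int, int, int]) -> None:
        if self.name not in STRUCTURE_PRECEDENCE:
            raise ValueError(f"unknown structure name {self.name!r}")
        if self.kind not in {"full", "ellipsoid", "shell", "blobs", "ellipsoids"}:
            raise ValueError(f"unknown geometry kind {self.kind!r}")
        geoms = list(self.ellipsoids)
        if self.kind in {"ellipsoid", "shell", "blobs"}:
            if self.center is None or self.radii is None:
                raise ValueError(f"{self.name}: {self.kind} needs center and radii")
            geoms.append((self.center, self.radii))
        for center, radii in geoms:
            axes = zip(center, radii, dims)
            if self.cylindrical:  # z unconstrained
                axes = list(axes)[1:]
            for c, r, d in axes:
                if r < 0:
                    raise ValueError(f"{self.name}: negative radius")
                if c - r < -0.5 or c + r > d - 0.5:
                    raise ValueError(
                        f"{self.name}: geometry extends outside grid of dims {dims}"
                    )


@dataclass
class PhantomConfig:
    dims: tuple[int, int, int]  # (n_z, n_y, n_x)
    structures: list[StructureSpec]
    channels: list[str]
    markers: list[str]
    intensity_matrix: np.ndarray  # (n_structures, n_channels) mean counts/px
    drug_channel: str = "194Pt"
    noise_model: str = "poisson"
    seed: int = 0
    fov_id: str = "fov0"

    def __post_init__(self) -> None:
        self.intensity_matrix = np.asarray(self.intensity_matrix, dtype=float)
        if any(d < 1 for d in self.dims):
            raise ValueError(f"dims must all be >= 1, got {self.dims}")
        if self.intensity_matrix.shape != (len(self.structures), len(self.channels)):
            raise ValueError(
                "intensity_matrix must be (n_structures, n_channels) = "
                f"({len(self.structures)}, {len(self.channels)}), got "
                f"{self.intensity_matrix.shape}"
            )
        if np.any(self.intensity_matrix < 0):
            raise ValueError("intensity_matrix entries must be >= 0")
        if self.noise_model != "poisson":
            raise ValueError(f"unsupported noise model {self.noise_model!r}")
        for s in self.structures:
            s.validate(self.dims)


@dataclass
class GroundTruth:
    """Voxel-exact structure labels: values index ``PhantomConfig.structures``."""

    label_volume: np.ndarray
    structure_names: dict[int, str]

    def name_of(self, label: int) -> str:
        return self.structure_names[int(label)]


def _ellipsoid_mask(dims, center, radii, cylindrical=False) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, d) for d in dims)]
    terms = zip(grids, center, radii)
    if cylindrical:
        terms = list(terms)[1:]
    r = sum(((g - c) / max(rad, 1e-9)) ** 2 for g, c, rad in terms)
    return np.broadcast_to(r <= 1.0, dims)


def _structure_mask(spec: StructureSpec, dims, rng: np.random.Generator) -> np.ndarray:
    if spec.kind == "full":
        return np.ones(dims, dtype=bool)
    if spec.kind == "ellipsoid":
        return _ellipsoid_mask(dims, spec.center, spec.radii, spec.cylindrical)
    if spec.kind == "ellipsoids":
        mask = np.zeros(dims, dtype=bool)
        for center, radii in spec.ellipsoids:
            mask = mask | _ellipsoid_mask(dims, center, radii, spec.cylindrical)
        return mask
    if spec.kind == "shell":
        outer = _ellipsoid_mask(dims, spec.center, spec.radii, spec.cylindrical)
        inner_radii = tuple(max(r - spec.thickness, 0.0) for r in spec.radii)
        return outer & ~_ellipsoid_mask(dims, spec.center, inner_radii,
                                        spec.cylindrical)
    if spec.kind == "blobs":
        # scatter blob centers uniformly inside the containing ellipsoid,
        # shrunk so each blob stays inside it
        mask = np.zeros(dims, dtype=bool)
        margins = tuple(max(r - spec.blob_radius, 1e-9) for r in spec.radii)
        placed = 0
        while placed < spec.n_blobs:
            u = rng.uniform(-1.0, 1.0, size=3)
            if spec.cylindrical:
                u[0] = 0.0
            if np.sum(u**2) > 1.0:
                continue
            center = tuple(c + ui * m for c, ui, m in zip(spec.center, u, margins))
            mask = mask | _ellipsoid_mask(dims, center,
                                          (spec.blob_radius,) * 3,
                                          spec.cylindrical)
            placed += 1
        return mask
    raise ValueError(spec.kind)


def generate_nuclear_phantom(
    config: PhantomConfig,
) -> tuple[MultiplexVolume, GroundTruth]:
    """Render the phantom and draw Poisson ion counts per channel.

    Overlapping geometries are resolved by ``STRUCTURE_PRECEDENCE`` (e.g. a
    speckle inside euchromatin keeps the speckle label). Every pixel must be
    covered by some structure; include a ``full``-kind background or
    cytoplasm structure to guarantee this.
    """
    rng = np.random.default_rng(config.seed)
    dims = config.dims
    rank = {name: i for i, name in enumerate(STRUCTURE_PRECEDENCE)}

    label = np.full(dims, -1, dtype=np.int32)
    order = sorted(range(len(config.structures)),
                   key=lambda i: rank[config.structures[i].name])
    for i in order:  # low precedence first; higher overwrites
        mask = _structure_mask(config.structures[i], dims, rng)
        label[mask] = i
    if np.any(label < 0):
        raise ValueError(
            "phantom grid not fully covered: add a 'full'-kind background "
            "or cytoplasm structure"
        )

    stacks = []
    for j, (chan, marker) in enumerate(zip(config.channels, config.markers)):
        mean = config.intensity_matrix[label, j]
        counts = rng.poisson(mean).astype(np.uint32)
        stacks.append(ChannelStack(chan, marker, counts))
    volume = MultiplexVolume(stacks, fov_id=config.fov_id)
    truth = GroundTruth(
        label_volume=label,
        structure_names={i: s.name for i, s in enumerate(config.structures)},
    )
    return volume, truth


# ---------------------------------------------------------------------------
# canned phantom configurations

def _panel_intensities(structures, base_drug, drug_multipliers):
    """Mean counts/px per (structure, channel) for the standard 7-channel panel.

    Values are chosen to mimic summed high-current acquisitions: carbon is
    high wherever there is organic material, phosphorus tracks chromatin
    density, and each antibody channel is dominated by its target structure.
    """
    base = {
        #              12C   19F   31P  81Br  127I 194Pt 197Au
        "background":   (0.5,  0.05, 0.05, 0.05, 0.05, 0.0, 0.05),
        "cytoplasm":    (40.0, 0.5,  4.0,  0.5,  1.0,  0.0, 0.5),
        "euchromatin":  (40.0, 1.0, 25.0,  2.0, 30.0,  0.0, 2.0),
        "lamina":       (40.0, 1.0, 30.0, 10.0,  5.0,  0.0, 1.0),
        "nucleus_envelope": (40.0, 1.0, 30.0, 10.0, 5.0, 0.0, 1.0),
        "heterochromatin": (40.0, 1.0, 55.0, 45.0, 3.0, 0.0, 1.0),
        "perinucleolar_rim": (40.0, 5.0, 45.0, 30.0, 3.0, 0.0, 1.0),
        "nucleolus":    (40.0, 50.0, 20.0,  2.0,  3.0, 0.0, 1.0),
        "speckle":      (40.0, 1.0, 18.0,  2.0,  8.0,  0.0, 45.0),
    }
    drug_idx = list(DEFAULT_CHANNELS).index("194Pt")
    rows = []
    for s in structures:
        row = list(base[s.name])
        row[drug_idx] = base_drug * drug_multipliers.get(s.name, 1.0)
        rows.append(row)
    return np.array(rows)


def nuclear_phantom_config(
    dims: tuple[int, int, int] = (20, 300, 300),
    seed: int = 0,
    base_drug: float = 2.0,
    drug_multipliers: dict[str, float] | None = None,
    n_speckles: int = 5,
    n_hetero: int = 5,
    fov_id: str = "fov0",
) -> PhantomConfig:
    """Five-structure single-cell phantom: cytoplasm filling the frame, a
    nuclear (euchromatin) disk containing heterochromatin blobs, two
    nucleoli and speckles.

    Structure radii scale with the frame and correspond, at the 10-20
    nm/px pitch of a high-resolution raster, to organelles of roughly
    0.4-1 um — large relative to a 10 px analysis window, as in real data.
    """
    nz, ny, nx = dims
    cz, cy, cx = (nz - 1) / 2, (ny - 1) / 2, (nx - 1) / 2
    # structures span the acquired slab (a few-hundred-nm depth is thinner
    # than any of these organelles), so geometries are cylindrical in z
    structures = [
        StructureSpec("cytoplasm", "full"),
        StructureSpec("euchromatin", "ellipsoid", center=(cz, cy, cx),
                      radii=(nz, ny * 0.42, nx * 0.42), cylindrical=True),
        StructureSpec("heterochromatin", "blobs", center=(cz, cy, cx),
                      radii=(nz, ny * 0.32, nx * 0.32),
                      n_blobs=n_hetero, blob_radius=min(ny, nx) * 0.09,
                      cylindrical=True),
        StructureSpec(
            "nucleolus", "ellipsoids", cylindrical=True,
            ellipsoids=[
                ((cz, cy - ny * 0.16, cx - nx * 0.14),
                 (nz, ny * 0.13, nx * 0.13)),
                ((cz, cy + ny * 0.15, cx + nx * 0.16),
                 (nz, ny * 0.11, nx * 0.11)),
            ],
        ),
        StructureSpec("speckle", "blobs", center=(cz, cy, cx),
                      radii=(nz, ny * 0.32, nx * 0.32),
                      n_blobs=n_speckles, blob_radius=min(ny, nx) * 0.065,
                      cylindrical=True),
    ]
    mult = dict(DEFAULT_DRUG_MULTIPLIERS)
    if drug_multipliers:
        mult.update(drug_multipliers)
    return PhantomConfig(
        dims=dims,
        structures=structures,
        channels=list(DEFAULT_CHANNELS),
        markers=list(DEFAULT_CHANNELS.values()),
        intensity_matrix=_panel_intensities(structures, base_drug, mult),
        seed=seed,
        fov_id=fov_id,
    )


def multidrug_phantom_config(
    condition: str,
    dims: tuple[int, int, int] = (12, 120, 120),
    seed: int = 0,
    base_drug: float = 0.02,
    fov_id: str = "fov0",
) -> PhantomConfig:
    """Two-condition phantom for the drug-exclusion comparison.

    ``condition='retained'`` places drug throughout the cell (speckle
    enriched); ``condition='excluded'`` removes it from all nuclear
    structures, leaving only cytoplasmic drug. Bare substrate around the
    cell carries near-zero carbon so empty voxels can be filtered on 12C.

    The default drug level (0.02 counts/px) reflects how sparse native
    drug detection is relative to antibody channels: per-voxel mean counts
    then fall in the 0.01-0.05 range the global clip normalisation expects.
    """
    if condition not in {"retained", "excluded"}:
        raise ValueError(f"condition must be 'retained' or 'excluded', "
                         f"got {condition!r}")
    nz, ny, nx = dims
    cz, cy, cx = (nz - 1) / 2, (ny - 1) / 2, (nx - 1) / 2
    structures = [
        StructureSpec("background", "full"),
        StructureSpec("cytoplasm", "ellipsoid", center=(cz, cy, cx),
                      radii=(nz, ny * 0.47, nx * 0.47), cylindrical=True),
        StructureSpec("euchromatin", "ellipsoid", center=(cz, cy, cx),
                      radii=(nz, ny * 0.30, nx * 0.30), cylindrical=True),
        StructureSpec("heterochromatin", "blobs", center=(cz, cy, cx),
                      radii=(nz, ny * 0.26, nx * 0.26),
                      n_blobs=4, blob_radius=min(ny, nx) * 0.06,
                      cylindrical=True),
        StructureSpec("nucleolus", "ellipsoid", center=(cz, cy, cx),
                      radii=(nz, ny * 0.10, nx * 0.10), cylindrical=True),
        StructureSpec("speckle", "blobs", center=(cz, cy, cx),
                      radii=(nz, ny * 0.26, nx * 0.26),
                      n_blobs=3, blob_radius=min(ny, nx) * 0.045,
                      cylindrical=True),
    ]
    mult = dict(DEFAULT_DRUG_MULTIPLIERS)
    mult["cytoplasm"] = 2.0
    if condition == "excluded":
        for name in ("euchromatin", "heterochromatin", "nucleolus", "speckle",
                     "lamina", "nucleus_envelope", "perinucleolar_rim"):
            mult[name] = 0.0
    return PhantomConfig(
        dims=dims,
        structures=structures,
        channels=list(DEFAULT_CHANNELS),
        markers=list(DEFAULT_CHANNELS.values()),
        intensity_matrix=_panel_intensities(structures, base_drug, mult),
        seed=seed,
        fov_id=fov_id,
    )


# ---------------------------------------------------------------------------
# edge line scans

def generate_edge_linescan(
    sigma: float,
    step: float,
    amplitude: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    span: float | None = None,
    x0: float = 0.0,
) -> LineScan:
    """Step edge at ``x0`` convolved with a Gaussian PSF of width ``sigma``.

    The noiseless profile is ``amplitude * Phi((x - x0) / sigma)`` (an ideal
    step for ``sigma == 0``); ``noise_sd`` adds i.i.d. Gaussian noise.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if step <= 0:
        raise ValueError("sampling interval must be > 0")
    if span is None:
        span = max(20.0 * step, 12.0 * sigma)
    n = int(np.floor(span / step)) + 1
    position = x0 - span / 2 + step * np.arange(n)
    if sigma == 0:
        intensity = amplitude * (position >= x0).astype(float)
    else:
        intensity = amplitude * norm.cdf((position - x0) / sigma)
    if noise_sd > 0:
        intensity = intensity + np.random.default_rng(seed).normal(
            0.0, noise_sd, size=n
        )
    return LineScan(position, intensity)


# ---------------------------------------------------------------------------
# splicing count tables

def generate_splicing_counts(
    n_genes: int,
    n_replicates: int = 3,
    frac_affected: float = 0.2,
    effect_fold: float = 0.5,
    mean_depth: float = 500.0,
    dispersion: float = 0.1,
    seed: int = 0,
    ratio_dispersion: float = 0.0,
) -> pd.DataFrame:
    """Exon/intron fragment counts for a control vs treatment comparison.

    Each replicate's total fragment count is negative-binomial with the given
    mean and dispersion (variance = mu + dispersion * mu^2; Poisson at 0) and
    is split binomially between exon and intron according to the gene's
    exon/intron ratio. Affected genes have their treatment-condition ratio
    multiplied by ``effect_fold``. ``ratio_dispersion`` (sd on the logit
    scale, default 0) adds extra-binomial replicate-to-replicate ratio noise.

    Returns a long-form table: gene_id, condition, replicate, exon_count,
    intron_count, truth_affected.
    """
    if not 0.0 <= frac_affected <= 1.0:
        raise ValueError("frac_affected must be in [0, 1]")
    if effect_fold <= 0:
        raise ValueError("effect_fold must be > 0")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    rng = np.random.default_rng(seed)

    # baseline exon/intron ratios: lognormal around ~4, as polyA libraries show
    log2_ratio = rng.normal(2.0, 1.0, size=n_genes)
    base_ratio = 2.0 ** log2_ratio
    n_affected = int(round(frac_affected * n_genes))
    affected = np.zeros(n_genes, dtype=bool)
    affected[rng.choice(n_genes, size=n_affected, replace=False)] = True

    def draw_total(size):
        if dispersion <= 0:
            t = rng.poisson(mean_depth, size=size)
        else:
            n_param = 1.0 / dispersion
            p_param = n_param / (n_param + mean_depth)
            t = rng.negative_binomial(n_param, p_param, size=size)
        return np.maximum(t, 1)

    rows = []
    for condition in ("control", "treatment"):
        ratio = base_ratio.copy()
        if condition == "treatment":
            ratio[affected] *= effect_fold
        p_exon = ratio / (1.0 + ratio)
        for rep in range(1, n_replicates + 1):
            total = draw_total(n_genes)
            p = p_exon
            if ratio_dispersion > 0:
                logit = np.log(p / (1 - p)) + rng.normal(
                    0.0, ratio_dispersion, size=n_genes
                )
                p = 1.0 / (1.0 + np.exp(-logit))
            exon = rng.binomial(total, p)
            rows.append(pd.DataFrame({
                "gene_id": [f"g{i:05d}" for i in range(n_genes)],
                "condition": condition,
                "replicate": rep,
                "exon_count": exon,
                "intron_count": total - exon,
                "truth_affected": affected,
            }))
    return pd.concat(rows, ignore_index=True)
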