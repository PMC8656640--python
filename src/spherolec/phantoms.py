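"""Synthetic two-channel 3D coculture phantoms with ground truth.

The generator emulates the two phenotypes seen in 3D tumor/lymphatic
cocultures on basement-membrane gels:

* a **LEC channel**: branching reticular endothelial networks — blobs
  (central nodes) connected by tubes, built as a random geometric graph
  whose edge set is a minimum spanning tree plus a few extra short edges
  (a tree with occasional cycles);
* a **TNBC channel**: spheroidal tumor structures, each a ball (the
  proliferative core) with a few thin capsule-shaped multicellular
  invasive outgrowths.

Spheroid centres are placed on the network skeleton with probability
``association_strength``, otherwise uniformly — this dial controls the
true spatial association between the channels. Ground truth (masks,
per-spheroid core/outgrowth voxel sets, volumes, inside-network flags,
and the true degree of overlap in both object and voxel mode) is
recorded **before** blur and noise; the anisotropic Gaussian PSF and the
Poisson/Gaussian noise are part of the measurement model that the
downstream pipeline must undo.

Time courses share one frozen geometry across timepoints: each spheroid
carries a fixed uniform draw and joins the network once the scheduled
association passes it, and cores grow geometrically so that their volume
changes by ``core_growth_factor`` across ``growth_ref_days``. Both
constructions make the true overlap nondecreasing in time by design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import squareform, pdist

from .errors import ConfigurationError
from .image_io import ImageStack
from .segment import BinaryMask

__all__ = [
    "PhantomConfig",
    "SpheroidTruth",
    "PhantomTruth",
    "generate_phantom",
    "generate_truth",
    "generate_timecourse",
]

INTENSITY_MAX = 65535.0


@dataclass
class PhantomConfig:
    """Phantom generator parameters (lengths in µm, days in days).

    Defaults describe a modest desk-scale volume: a 64×128×128 µm grid
    with 2×1×1 µm anisotropic voxels, three spheroids of ~9 µm radius
    with three ~15 µm outgrowths each, and an eight-node network of 5 µm
    tubes whose total volume is roughly five times the tumor volume —
    echoing the 1:5 tumor:endothelial seeding ratio of the emulated
    cocultures. Signal 10000 over background 1000 with the default noise
    settings gives a contrast-to-noise ratio of about 5.
    """

    grid_shape: tuple[int, int, int] = (32, 128, 128)  # voxels (z, y, x)
    voxel_size: tuple[float, float, float] = (2.0, 1.0, 1.0)  # µm (dz, dy, dx)
    n_spheroids: int = 3
    spheroid_radius_mean: float = 8.5
    spheroid_radius_sd: float = 1.5
    outgrowth_count_per_spheroid: int = 3
    outgrowth_length: float = 15.0
    outgrowth_radius: float = 3.0
    network_node_count: int = 8
    network_tube_radius: float = 6.5
    network_edge_probability: float = 0.25
    association_strength: float = 0.9  # 0 = uniform centres, 1 = all on network
    core_growth_factor: float = 3.5  # core volume fold-change over growth_ref_days
    growth_ref_days: tuple[float, float] = (3.0, 6.0)
    timepoints: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0)
    psf_sigma: tuple[float, float, float] = (1.5, 0.75, 0.75)  # µm (z, y, x)
    background_level: float = 1000.0
    signal_level: float = 10000.0
    noise_model: str | None = "both"  # poisson | gaussian | both | none/None
    gaussian_sd: float = 1800.0
    poisson_gain: float = 50.0  # intensity units per photon
    seed: int = 0

    def __post_init__(self):
        if any(s < 1 for s in self.grid_shape):
            raise ConfigurationError(f"grid_shape must be positive, got {self.grid_shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise ConfigurationError(f"voxel_size must be positive, got {self.voxel_size}")
        for name in (
            "spheroid_radius_mean",
            "outgrowth_length",
            "outgrowth_radius",
            "network_tube_radius",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.spheroid_radius_sd < 0:
            raise ConfigurationError("spheroid_radius_sd must be >= 0")
        if not (0.0 <= self.association_strength <= 1.0):
            raise ConfigurationError("association_strength must be in [0, 1]")
        if not (0.0 <= self.network_edge_probability <= 1.0):
            raise ConfigurationError("network_edge_probability must be in [0, 1]")
        if self.network_node_count < 1:
            raise ConfigurationError("network_node_count must be >= 1")
        if self.n_spheroids < 0:
            raise ConfigurationError("n_spheroids must be >= 0")
        if self.noise_model not in (None, "none", "poisson", "gaussian", "both"):
            raise ConfigurationError(f"unknown noise_model '{self.noise_model}'")
        if self.core_growth_factor <= 0:
            raise ConfigurationError("core_growth_factor must be > 0")
        d0, d1 = self.growth_ref_days
        if not d1 > d0:
            raise ConfigurationError("growth_ref_days must be strictly increasing")
        extent = [s * v for s, v in zip(self.grid_shape, self.voxel_size)]
        half = min(extent) / 2
        for name in ("spheroid_radius_mean", "network_tube_radius", "outgrowth_length"):
            if getattr(self, name) > half:
                raise ConfigurationError(
                    f"{name}={getattr(self, name)} µm does not fit the grid "
                    f"(half the shortest physical extent is {half} µm)"
                )

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical grid extent (z, y, x) in µm."""
        return tuple(s * v for s, v in zip(self.grid_shape, self.voxel_size))


@dataclass
class SpheroidTruth:
    """Ground-truth record of one spheroid (voxel sets as flat indices)."""

    label: int
    core_indices: np.ndarray
    outgrowth_indices: np.ndarray
    core_volume: float
    outgrowth_volume: float
    total_volume: float
    inside_network: bool  # placed on the network skeleton, by construction


@dataclass
class PhantomTruth:
    """Ground truth of one phantom, recorded before blur and noise."""

    tnbc_truth_mask: BinaryMask
    lec_truth_mask: BinaryMask
    tnbc_labels: np.ndarray  # int grid, 0 = background
    per_spheroid: list[SpheroidTruth]
    lec_total_volume: float
    true_degree_object: float
    true_degree_voxel: float
    config_echo: PhantomConfig

    @property
    def tnbc_total_volume(self) -> float:
        return sum(s.total_volume for s in self.per_spheroid)

    def spheroid_mask(self, label: int) -> BinaryMask:
        rec = next(s for s in self.per_spheroid if s.label == label)
        flat = np.zeros(np.prod(self.tnbc_labels.shape), dtype=bool)
        flat[rec.core_indices] = True
        flat[rec.outgrowth_indices] = True
        return BinaryMask(flat.reshape(self.tnbc_labels.shape),
                          self.tnbc_truth_mask.voxel_size, "TNBC")


# ---------------------------------------------------------------------------
# geometry


@dataclass
class _Spheroid:
    u: float  # fixed uniform draw; on-network iff u < association
    center_on: np.ndarray  # µm, on the network skeleton
    center_off: np.ndarray  # µm, uniform placement
    radius: float  # µm, at the growth reference day
    directions: np.ndarray  # (k, 3) unit vectors for outgrowths


@dataclass
class _Geometry:
    nodes: np.ndarray  # (n, 3) µm
    edges: list[tuple[int, int]]
    spheroids: list[_Spheroid]


def _sample_network(cfg: PhantomConfig, rng: np.random.Generator):
    margin = cfg.network_tube_radius * 1.5
    lo = np.array([margin] * 3)
    hi = np.maximum(np.array(cfg.extent) - margin, lo + 1e-6)
    nodes = rng.uniform(lo, hi, size=(cfg.network_node_count, 3))
    edges: list[tuple[int, int]] = []
    if cfg.network_node_count > 1:
        dist = squareform(pdist(nodes))
        mst = minimum_spanning_tree(dist).toarray()
        tree = {(i, j) for i in range(len(nodes)) for j in range(len(nodes)) if mst[i, j] > 0}
        edges = sorted((min(i, j), max(i, j)) for i, j in tree)
        non_tree = sorted(
            ((i, j) for i in range(len(nodes)) for j in range(i + 1, len(nodes))
             if (i, j) not in set(edges)),
            key=lambda ij: dist[ij],
        )
        extras = 0
        for ij in non_tree:
            if extras >= cfg.network_node_count // 2:
                break
            if rng.random() < cfg.network_edge_probability:
                edges.append(ij)
                extras += 1
    return nodes, edges


_N_CANDIDATES = 200  # candidate centres pre-drawn per spheroid


def _skeleton_points(nodes, edges, rng: np.random.Generator, n: int) -> np.ndarray:
    """n random points on the network skeleton, edge picked ∝ length."""
    if not edges:
        idx = rng.integers(len(nodes), size=n)
        return nodes[idx].copy()
    lengths = np.array([np.linalg.norm(nodes[j] - nodes[i]) for i, j in edges])
    probs = lengths / lengths.sum() if lengths.sum() > 0 else None
    ks = rng.choice(len(edges), size=n, p=probs)
    ts = rng.random(n)
    pts = np.empty((n, 3))
    for row, (k, t) in enumerate(zip(ks, ts)):
        i, j = edges[k]
        pts[row] = nodes[i] + t * (nodes[j] - nodes[i])
    return pts


def _sample_geometry(cfg: PhantomConfig, rng: np.random.Generator) -> _Geometry:
    """Sample the full phantom geometry.

    The number of random draws consumed is fixed by ``n_spheroids``,
    ``outgrowth_count_per_spheroid`` and ``network_node_count`` only:
    candidate centres are pre-drawn and then selected deterministically.
    Configs that differ only in deterministic size parameters (e.g.
    outgrowth length) therefore share radii and candidate positions.
    """
    nodes, edges = _sample_network(cfg, rng)
    extent = np.array(cfg.extent)
    spheroids: list[_Spheroid] = []
    placed: list[tuple[np.ndarray, float]] = []  # (position, radius) of accepted centres

    for _ in range(cfg.n_spheroids):
        u = rng.random()
        raw_radius = rng.normal(cfg.spheroid_radius_mean, cfg.spheroid_radius_sd or 0.0)
        radius = float(
            np.clip(
                raw_radius,
                0.3 * cfg.spheroid_radius_mean,
                cfg.spheroid_radius_mean + 3 * (cfg.spheroid_radius_sd or 0.0),
            )
        )
        margin = np.minimum(radius + 1.0, extent / 2 - 1e-6)
        on_candidates = np.clip(
            _skeleton_points(nodes, edges, rng, _N_CANDIDATES), margin, extent - margin
        )
        off_candidates = rng.uniform(margin, extent - margin, size=(_N_CANDIDATES, 3))
        dirs = rng.normal(size=(cfg.outgrowth_count_per_spheroid, 3))

        min_sep = lambda rq: radius + rq + cfg.outgrowth_length + 2.0

        def _select(candidates):
            best, best_d = candidates[0], -1.0
            for pos in candidates:
                d = min((np.linalg.norm(pos - q) for q, _ in placed), default=np.inf)
                if all(np.linalg.norm(pos - q) >= min_sep(rq) for q, rq in placed):
                    return pos
                if d > best_d:
                    best, best_d = pos, d
            return best  # best-effort when the grid is crowded

        center_on = _select(on_candidates)
        center_off = _select(off_candidates)
        for pos in (center_on, center_off):
            placed.append((pos, radius))
        norms = np.linalg.norm(dirs, axis=1, keepdims=True)
        dirs = np.where(norms > 0, dirs / np.maximum(norms, 1e-12), [[0.0, 0.0, 1.0]])
        spheroids.append(_Spheroid(u, center_on, center_off, radius, dirs))
    return _Geometry(nodes, edges, spheroids)


# ---------------------------------------------------------------------------
# rasterization (voxel centres at (index + 0.5) * voxel_size)


def _capsule_into(mask: np.ndarray, p0, p1, radius: float, voxel_size) -> None:
    """OR a capsule (segment p0→p1 dilated by radius, in µm) into mask."""
    vs = np.asarray(voxel_size)
    shape = np.asarray(mask.shape)
    lo_phys = np.minimum(p0, p1) - radius
    hi_phys = np.maximum(p0, p1) + radius
    lo = np.maximum(np.floor(lo_phys / vs - 0.5).astype(int), 0)
    hi = np.minimum(np.ceil(hi_phys / vs + 0.5).astype(int) + 1, shape)
    if np.any(lo >= hi):
        return
    grids = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    coords = [(g + 0.5) * v for g, v in zip(grids, vs)]
    d = np.asarray(p1, dtype=float) - np.asarray(p0, dtype=float)
    L2 = float(d @ d)
    if L2 == 0:
        dist2 = sum((c - p)**2 for c, p in zip(coords, p0))
    else:
        t = sum((c - p) * di for c, p, di in zip(coords, p0, d)) / L2
        t = np.clip(t, 0.0, 1.0)
        dist2 = sum((c - (p + t * di))**2 for c, p, di in zip(coords, p0, d))
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= dist2 <= radius**2 * (1 + 1e-12)


def _rasterize_network(cfg: PhantomConfig, geom: _Geometry) -> np.ndarray:
    lec = np.zeros(cfg.grid_shape, dtype=bool)
    node_radius = 1.4 * cfg.network_tube_radius
    for p in geom.nodes:
        _capsule_into(lec, p, p, node_radius, cfg.voxel_size)
    for i, j in geom.edges:
        _capsule_into(lec, geom.nodes[i], geom.nodes[j], cfg.network_tube_radius, cfg.voxel_size)
    return lec


def _rasterize_spheroids(cfg: PhantomConfig, geom: _Geometry, association: float,
                         radius_scale: float):
    shape = cfg.grid_shape
    labels = np.zeros(shape, dtype=np.int32)
    records: list[SpheroidTruth] = []
    voxel_volume = float(np.prod(cfg.voxel_size))
    for idx, sph in enumerate(geom.spheroids, start=1):
        on = sph.u < association
        center = sph.center_on if on else sph.center_off
        r = sph.radius * radius_scale
        core = np.zeros(shape, dtype=bool)
        _capsule_into(core, center, center, r, cfg.voxel_size)
        full = core.copy()
        for d in sph.directions:
            # capsule runs from the centre so that a growing core only
            # extends the outgrowth outward: the mask is monotone in r
            tip = center + d * (r + cfg.outgrowth_length)
            _capsule_into(full, center, tip, cfg.outgrowth_radius, cfg.voxel_size)
        claimed = full & (labels == 0)
        labels[claimed] = idx
        core_claimed = claimed & core
        out_claimed = claimed & ~core
        records.append(
            SpheroidTruth(
                label=idx,
                core_indices=np.flatnonzero(core_claimed.ravel()),
                outgrowth_indices=np.flatnonzero(out_claimed.ravel()),
                core_volume=int(core_claimed.sum()) * voxel_volume,
                outgrowth_volume=int(out_claimed.sum()) * voxel_volume,
                total_volume=int(claimed.sum()) * voxel_volume,
                inside_network=bool(on),
            )
        )
    return labels, records


def _build_truth(cfg: PhantomConfig, geom: _Geometry, association: float,
                 radius_scale: float) -> PhantomTruth:
    lec = _rasterize_network(cfg, geom)
    labels, records = _rasterize_spheroids(cfg, geom, association, radius_scale)
    tnbc = labels > 0
    voxel_volume = float(np.prod(cfg.voxel_size))
    v_lec = int(lec.sum()) * voxel_volume
    if v_lec > 0:
        true_voxel = int((tnbc & lec).sum()) * voxel_volume / v_lec
        true_object = sum(s.total_volume for s in records if s.inside_network) / v_lec
    else:
        true_voxel = float("nan")
        true_object = float("nan")
    return PhantomTruth(
        tnbc_truth_mask=BinaryMask(tnbc, cfg.voxel_size, "TNBC"),
        lec_truth_mask=BinaryMask(lec, cfg.voxel_size, "LEC"),
        tnbc_labels=labels,
        per_spheroid=records,
        lec_total_volume=v_lec,
        true_degree_object=true_object,
        true_degree_voxel=true_voxel,
        config_echo=cfg,
    )


# ---------------------------------------------------------------------------
# rendering


def _render_channel(cfg: PhantomConfig, mask: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    from scipy import ndimage

    img = np.where(mask, cfg.signal_level, cfg.background_level).astype(np.float64)
    sigma_vox = [s / v for s, v in zip(cfg.psf_sigma, cfg.voxel_size)]
    if any(s > 0 for s in sigma_vox):
        img = ndimage.gaussian_filter(img, sigma=sigma_vox, mode="nearest")
    model = cfg.noise_model or "none"
    if model in ("poisson", "both"):
        img = rng.poisson(np.maximum(img, 0.0) / cfg.poisson_gain) * cfg.poisson_gain
    if model in ("gaussian", "both"):
        img = img + rng.normal(0.0, cfg.gaussian_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, INTENSITY_MAX)
    return img.astype(np.uint16)


def _streams(cfg: PhantomConfig, n_noise: int):
    geom_ss, noise_ss = np.random.SeedSequence(cfg.seed).spawn(2)
    return np.random.default_rng(geom_ss), [np.random.default_rng(c) for c in noise_ss.spawn(n_noise)]


def _make_stacks(cfg: PhantomConfig, truth: PhantomTruth, rng, day=None) -> dict[str, ImageStack]:
    meta = {"condition": "phantom", "replicate": cfg.seed}
    if day is not None:
        meta["day"] = day
    stacks = {}
    for chan, mask in (("TNBC", truth.tnbc_truth_mask), ("LEC", truth.lec_truth_mask)):
        img = _render_channel(cfg, mask.voxels, rng)
        stacks[chan] = ImageStack(img, cfg.voxel_size, channel=chan, meta=dict(meta))
    return stacks


def _radius_scale(cfg: PhantomConfig, day: float) -> float:
    d0, d1 = cfg.growth_ref_days
    return float(cfg.core_growth_factor ** ((day - d0) / (d1 - d0))) ** (1.0 / 3.0)


def generate_truth(config: PhantomConfig) -> PhantomTruth:
    """Ground truth only (no rendering) — fast path for Monte-Carlo use."""
    geom_rng, _ = _streams(config, 1)
    geom = _sample_geometry(config, geom_rng)
    return _build_truth(config, geom, config.association_strength, 1.0)


def generate_phantom(config: PhantomConfig) -> tuple[dict[str, ImageStack], PhantomTruth]:
    """Generate one two-channel phantom and its ground truth.

    Identical ``(config, seed)`` produce bit-identical stacks and truth.
    """
    geom_rng, noise_rngs = _streams(config, 1)
    geom = _sample_geometry(config, geom_rng)
    truth = _build_truth(config, geom, config.association_strength, 1.0)
    stacks = _make_stacks(config, truth, noise_rngs[0])
    return stacks, truth


def generate_timecourse(
    config: PhantomConfig,
) -> list[tuple[float, dict[str, ImageStack], PhantomTruth]]:
    """One phantom per timepoint over a single frozen geometry.

    Cores grow by ``core_growth_factor`` in volume across
    ``growth_ref_days`` (geometric interpolation in between), and the
    on-network spheroid set grows with a linearly ramped association
    ending at ``association_strength`` — so the true overlap is
    nondecreasing across timepoints by construction.
    """
    days = tuple(float(d) for d in config.timepoints)
    if not days:
        raise ConfigurationError("timepoints must be nonempty")
    if any(b <= a for a, b in zip(days, days[1:])):
        raise ConfigurationError(f"timepoints must be strictly increasing, got {days}")
    geom_rng, noise_rngs = _streams(config, len(days))
    geom = _sample_geometry(config, geom_rng)
    if len(days) == 1:
        assoc = [config.association_strength]
    else:
        assoc = np.linspace(config.association_strength / 6.0,
                            config.association_strength, len(days))
    out = []
    for k, day in enumerate(days):
        truth = _build_truth(config, geom, float(assoc[k]), _radius_scale(config, day))
        stacks = _make_stacks(config, truth, noise_rngs[k], day=day)
        out.append((day, stacks, truth))
    return out
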