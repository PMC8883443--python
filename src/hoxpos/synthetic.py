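"""Seeded synthetic data with the generative structure the mapping model assumes.

The generators emulate the study system: seven Hox genes expressed along a
normalized anterior–posterior (AP) axis — the three anterior genes in sharply
bounded, non-overlapping stripes and the four posterior genes in broad,
partially overlapping domains — with read counts drawn Poisson around a
gene-wise rate ``r_g`` scaled by the reference intensity, and a small
background rate λ in territory where the reference says the gene is off.
Additional generators plant spatially patterned non-Hox genes and
homeodomain-code cell clusters with linked immunoglobulin-domain programs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .containers import CountMatrix, ReferenceMap, SimTruth

#: Fraction of the peak below which smooth curves are truncated to exact zero,
#: giving every gene a compact expression territory (needed for the λ branch
#: of the observation model to be exercised).
_SUPPORT_FLOOR = 1e-4


@dataclass(frozen=True)
class StripeSpec:
    """One gene's expression domain along the AP axis.

    ``shape``: ``boxcar`` (hard-edged stripe), ``gaussian`` (bell-shaped
    domain, truncated to zero at 3 standard deviations, with σ = width/2) or
    ``sigmoid-tail`` (plateau at the peak from the center to the posterior
    end with a sigmoidal anterior rise of characteristic width ``width``).
    """

    gene: str
    center: float
    width: float
    shape: str = "boxcar"
    peak: float = 1.0

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError("width must be > 0")
        if not 0 < self.peak <= 1:
            raise ValueError("peak must be in (0, 1]")
        if self.shape not in {"boxcar", "gaussian", "sigmoid-tail"}:
            raise ValueError(f"unknown shape {self.shape!r}")

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.shape == "boxcar":
            lo, hi = self.center - self.width / 2, self.center + self.width / 2
            return np.where((x >= lo) & (x <= hi), self.peak, 0.0)
        if self.shape == "gaussian":
            sd = self.width / 2
            y = self.peak * np.exp(-0.5 * ((x - self.center) / sd) ** 2)
            y[np.abs(x - self.center) > 3 * sd] = 0.0
            return y
        # sigmoid-tail: rises over [center-width, center], flat at peak after
        rise = expit((x - self.center + self.width / 2) / (self.width / 8))
        y = self.peak * np.minimum(rise / expit(4.0), 1.0)
        y[y < self.peak * _SUPPORT_FLOOR] = 0.0
        return y


#: Default seven-gene panel mimicking lab, Dfd, Scr (anterior stripes) and
#: Antp, Ubx, abd-A, Abd-B (overlapping posterior domains).
DEFAULT_HOX_SPECS: list[StripeSpec] = [
    StripeSpec("lab", center=0.06, width=0.08, shape="boxcar"),
    StripeSpec("Dfd", center=0.18, width=0.10, shape="boxcar"),
    StripeSpec("Scr", center=0.30, width=0.08, shape="boxcar"),
    StripeSpec("Antp", center=0.45, width=0.18, shape="gaussian"),
    StripeSpec("Ubx", center=0.60, width=0.20, shape="gaussian"),
    StripeSpec("abd-A", center=0.75, width=0.20, shape="gaussian"),
    StripeSpec("Abd-B", center=0.82, width=0.20, shape="sigmoid-tail"),
]


def make_reference(
    stripe_specs: list[StripeSpec], grid_size: int = 201, seed: int | None = None
) -> ReferenceMap:
    """Build a ReferenceMap from stripe specifications.

    ``seed`` is accepted for interface symmetry; the construction is
    deterministic.  Overlapping boxcar stripes raise a warning (posterior
    Hox domains genuinely overlap; anterior stripes should not).
    """
    if grid_size < 2:
        raise ValueError("grid_size must be ≥ 2")
    if not stripe_specs:
        raise ValueError("at least one StripeSpec is required")
    grid = np.linspace(0.0, 1.0, grid_size)
    curves = np.vstack([s.evaluate(grid) for s in stripe_specs])
    boxcars = [i for i, s in enumerate(stripe_specs) if s.shape == "boxcar"]
    for a_pos, i in enumerate(boxcars):
        for j in boxcars[a_pos + 1 :]:
            if np.minimum(curves[i], curves[j]).sum() > 0:
                warnings.warn(
                    f"boxcar stripes {stripe_specs[i].gene} and "
                    f"{stripe_specs[j].gene} overlap",
                    stacklevel=2,
                )
    return ReferenceMap(grid, curves, [s.gene for s in stripe_specs])


def simulate_cells(
    reference: ReferenceMap,
    n_cells: int,
    r: float | np.ndarray = 20.0,
    lambda_bg: float = 0.1,
    depth_spread: float = 0.0,
    seed: int = 0,
) -> tuple[CountMatrix, SimTruth]:
    """Draw cells at uniform AP positions and Poisson counts from the model.

    Counts for gene g in a cell at position x are Poisson with mean
    ``r_g · Y_g(x)`` where ``Y_g(x) > 0`` and mean ``lambda_bg`` elsewhere.
    ``depth_spread`` adds a per-cell lognormal depth factor (sd on the log
    scale) multiplying all means.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    r = np.broadcast_to(np.asarray(r, dtype=float), (reference.n_genes,)).copy()
    if (r <= 0).any():
        raise ValueError("all rates r must be positive")
    if lambda_bg < 0:
        raise ValueError("lambda_bg must be nonnegative")
    if depth_spread < 0:
        raise ValueError("depth_spread must be nonnegative")
    rng = np.random.default_rng(seed)
    positions = rng.uniform(0.0, 1.0, size=n_cells)
    y = reference.interpolate(positions)  # genes × cells
    mean = np.where(y > 0, r[:, None] * y, lambda_bg)
    if depth_spread > 0:
        depth = rng.lognormal(mean=0.0, sigma=depth_spread, size=n_cells)
    else:
        depth = np.ones(n_cells)
    counts = rng.poisson(mean * depth[None, :])
    cm = CountMatrix(
        counts,
        list(reference.gene_ids),
        [f"cell{i:04d}" for i in range(n_cells)],
        {g: {"Hox"} for g in reference.gene_ids},
    )
    truth = SimTruth(
        positions=positions,
        spatial_gene_flags={g: True for g in reference.gene_ids},
        params={
            "r": r,
            "lambda_bg": lambda_bg,
            "depth_factors": depth,
            "depth_spread": depth_spread,
            "seed": seed,
        },
    )
    return cm, truth


def add_spatial_genes(
    counts: CountMatrix,
    truth: SimTruth,
    n_spatial: int,
    n_flat: int,
    effect: float = 8.0,
    base_mean: float = 2.0,
    seed: int = 0,
) -> tuple[CountMatrix, SimTruth]:
    """Append planted spatially patterned and flat genes.

    Spatial genes follow a smooth function of the cell's true position —
    half are sigmoidal in a random direction, half a single Gaussian bump —
    with dynamic range ``effect`` (mean from ``base_mean`` to
    ``base_mean × effect``).  Flat genes have a position-independent mean at
    the geometric midpoint of that range.
    """
    if effect <= 1:
        raise ValueError("effect must be > 1")
    if truth.positions is None:
        raise ValueError("truth must contain cell positions")
    rng = np.random.default_rng(seed)
    x = truth.positions
    depth = truth.params.get("depth_factors", np.ones(x.size))
    blocks, gene_ids, flags = [], [], {}
    for i in range(n_spatial):
        center = rng.uniform(0.2, 0.8)
        if i % 2 == 0:
            g = expit((x - center) / 0.05)
            if rng.random() < 0.5:
                g = 1.0 - g
        else:
            g = np.exp(-0.5 * ((x - center) / 0.1) ** 2)
        mean = base_mean * effect**g
        blocks.append(rng.poisson(mean * depth))
        name = f"SPG{i:03d}"
        gene_ids.append(name)
        flags[name] = True
    flat_mean = base_mean * np.sqrt(effect)
    for i in range(n_flat):
        blocks.append(rng.poisson(flat_mean * np.ones(x.size) * depth))
        name = f"FLT{i:03d}"
        gene_ids.append(name)
        flags[name] = False
    new_counts = np.vstack([counts.counts] + [b[None, :] for b in blocks])
    classes = (
        {g: set(s) for g, s in counts.gene_classes.items()}
        if counts.gene_classes
        else {}
    )
    for g in gene_ids:
        classes[g] = set()
    cm = CountMatrix(new_counts, counts.gene_ids + gene_ids, list(counts.cell_ids), classes)
    new_truth = SimTruth(
        positions=truth.positions,
        cluster_labels=truth.cluster_labels,
        spatial_gene_flags={**truth.spatial_gene_flags, **flags},
        params={**truth.params, "spatial_effect": effect, "spatial_seed": seed},
    )
    return cm, new_truth


def simulate_homeo_population(
    n_clusters: int,
    cells_per_cluster: int = 40,
    n_homeobox: int = 20,
    n_ig: int = 40,
    code_density: float = 0.3,
    link_strength: float = 4.0,
    seed: int = 0,
    n_flat: int = 0,
    on_mean: float = 20.0,
    ig_base_mean: float = 3.0,
    ig_link_fraction: float = 0.25,
    lambda_bg: float = 0.1,
    depth_spread: float = 0.0,
) -> tuple[CountMatrix, SimTruth]:
    """Simulate cell clusters defined by binary homeodomain-TF codes.

    Each cluster receives a distinct random binary code over the homeobox
    panel ("on" genes Poisson mean ``on_mean``, "off" genes mean λ) and a
    cluster-specific subset of Ig-domain genes whose mean is multiplied by
    ``link_strength`` in that cluster.  ``n_flat`` extra genes carry no
    cluster signal (background for association testing).  Clusters are laid
    out in order along the AP axis so downstream cluster ordering by mean
    inferred position is meaningful.
    """
    if n_clusters < 2:
        raise ValueError("n_clusters must be ≥ 2")
    if not 0 < code_density < 1:
        raise ValueError("code_density must be in (0, 1)")
    if link_strength < 1:
        raise ValueError("link_strength must be ≥ 1")
    if n_clusters > 2**n_homeobox:
        raise ValueError(
            f"cannot draw {n_clusters} distinct codes from 2^{n_homeobox} possibilities"
        )
    rng = np.random.default_rng(seed)
    codes: list[tuple[int, ...]] = []
    seen: set[tuple[int, ...]] = set()
    for _ in range(n_clusters):
        for _attempt in range(100):
            code = tuple(int(v) for v in rng.random(n_homeobox) < code_density)
            if code not in seen:
                seen.add(code)
                codes.append(code)
                break
        else:
            raise RuntimeError("could not draw distinct cluster codes in 100 tries")
    code_matrix = np.array(codes, dtype=float)  # clusters × homeobox

    n_cells = n_clusters * cells_per_cluster
    labels = np.repeat(np.arange(n_clusters), cells_per_cluster)
    centers = (np.arange(n_clusters) + 0.5) / n_clusters
    positions = np.clip(centers[labels] + rng.normal(0, 0.03, size=n_cells), 0, 1)

    n_link = max(1, int(round(ig_link_fraction * n_ig)))
    ig_means = np.full((n_clusters, n_ig), ig_base_mean)
    linked: dict[int, np.ndarray] = {}
    for k in range(n_clusters):
        subset = rng.choice(n_ig, size=n_link, replace=False)
        linked[k] = subset
        ig_means[k, subset] *= link_strength

    homeo_mean = np.where(code_matrix[labels].T > 0, on_mean, lambda_bg)
    ig_mean = ig_means[labels].T
    blocks = [homeo_mean, ig_mean]
    if n_flat > 0:
        blocks.append(np.full((n_flat, n_cells), ig_base_mean))
    mean = np.vstack(blocks)
    if depth_spread > 0:
        depth = rng.lognormal(0.0, depth_spread, size=n_cells)
    else:
        depth = np.ones(n_cells)
    counts = rng.poisson(mean * depth[None, :])

    homeo_ids = [f"HD{i:03d}" for i in range(n_homeobox)]
    ig_ids = [f"IG{i:03d}" for i in range(n_ig)]
    flat_ids = [f"BG{i:03d}" for i in range(n_flat)]
    classes: dict[str, set[str]] = {g: {"homeobox"} for g in homeo_ids}
    classes.update({g: {"Ig-domain"} for g in ig_ids})
    classes.update({g: set() for g in flat_ids})
    cm = CountMatrix(
        counts,
        homeo_ids + ig_ids + flat_ids,
        [f"cell{i:04d}" for i in range(n_cells)],
        classes,
    )
    truth = SimTruth(
        positions=positions,
        cluster_labels=labels,
        spatial_gene_flags={},
        params={
            "codes": code_matrix,
            "linked_ig": linked,
            "linked_ig_genes": sorted(
                {ig_ids[j] for subset in linked.values() for j in subset}
            ),
            "link_strength": link_strength,
            "on_mean": on_mean,
            "ig_base_mean": ig_base_mean,
            "lambda_bg": lambda_bg,
            "depth_factors": depth,
            "seed": seed,
        },
    )
    return cm, truth
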