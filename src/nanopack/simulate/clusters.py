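"""Ground-truth generators for clustered membrane molecules and antibody labelling.

The molecule model is a marked planar point process: cluster centres form a
homogeneous Poisson process over a square field, each cluster carries a number
of molecules placed uniformly inside a disk, and an optional free (monomeric)
pool is scattered uniformly over the field.  Antibody labelling is modelled as
random sequential adsorption (RSA): antibodies bind epitopes one at a time in
random order, and a bound antibody sterically excludes further binding within
its footprint.  This reproduces the key phenomenology of epitope shielding —
the tighter the epitopes are packed, the smaller the fraction that can be
labelled — with a hard upper bound on bound antibodies per unit area (the RSA
jamming limit for hard disks, coverage ~0.547 in the dense-epitope limit).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ClusterField",
    "AntibodyModel",
    "simulate_cluster_field",
    "simulate_antibody_binding",
]

#: default cluster diameter range, nm (syntaxin-type nanoclusters)
DEFAULT_CLUSTER_SIZE_NM = (50.0, 60.0)
#: default molecules per cluster range
DEFAULT_MOLECULES_PER_CLUSTER = (50, 75)


@dataclass
class ClusterField:
    """Ground truth for one simulated membrane field.

    Positions are in nm within a square field of side ``side_nm``; the field
    origin is at (0, 0).  ``occupancy`` is ``None`` until antibody binding has
    been simulated.
    """

    area_um2: float
    cluster_centers: np.ndarray          # (n_clusters, 2) nm
    molecules_per_cluster: np.ndarray    # (n_clusters,) int
    cluster_radius_nm: np.ndarray        # (n_clusters,) nm
    free_molecule_density: float         # molecules per um^2 outside clusters
    epitope_positions: np.ndarray        # (n_molecules, 2) nm
    occupancy: np.ndarray | None = None  # (n_molecules,) bool
    cluster_index: np.ndarray = field(default=None)  # (n_molecules,) int, -1 = free
    seed: int | None = None

    @property
    def side_nm(self) -> float:
        return float(np.sqrt(self.area_um2) * 1000.0)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_centers)

    @property
    def n_molecules(self) -> int:
        return len(self.epitope_positions)

    def bound_positions(self) -> np.ndarray:
        """Positions (nm) of epitopes carrying a bound antibody."""
        if self.occupancy is None:
            raise ValueError("antibody occupancy not simulated yet")
        return self.epitope_positions[self.occupancy]

    def __post_init__(self):
        self.cluster_centers = np.atleast_2d(np.asarray(self.cluster_centers, float))
        if self.cluster_centers.size == 0:
            self.cluster_centers = np.empty((0, 2))
        self.molecules_per_cluster = np.asarray(self.molecules_per_cluster, int)
        self.cluster_radius_nm = np.asarray(self.cluster_radius_nm, float)
        self.epitope_positions = np.asarray(self.epitope_positions, float).reshape(-1, 2)
        if self.cluster_index is None:
            self.cluster_index = np.full(len(self.epitope_positions), -1, int)
        if self.occupancy is not None and len(self.occupancy) != self.n_molecules:
            raise ValueError("occupancy length must equal epitope count")
        if np.any(self.molecules_per_cluster < 1):
            raise ValueError("molecules_per_cluster must be >= 1")
        side = self.side_nm
        if self.n_clusters and (
            self.cluster_centers.min() < 0 or self.cluster_centers.max() > side
        ):
            raise ValueError("cluster centers must lie within the field")


@dataclass(frozen=True)
class AntibodyModel:
    """Steric model of antibody labelling.

    footprint_diameter_nm
        Exclusion diameter of one bound antibody: a new antibody cannot bind an
        epitope closer than this to an already-bound epitope.  Default 12 nm,
        the typical lateral extent of an IgG.
    binding_attempts
        Adsorption attempts per epitope.  Because binding is irreversible and
        the blocked set only grows, a single randomized pass already reaches
        the jammed state; the parameter is retained for interface completeness.
    label_efficiency
        Probability that a sterically accessible epitope can bind an antibody
        at all (epitope display, antibody concentration etc.).
    """

    footprint_diameter_nm: float = 12.0
    binding_attempts: int = 1
    label_efficiency: float = 1.0

    def __post_init__(self):
        if self.footprint_diameter_nm <= 0:
            raise ValueError("footprint_diameter_nm must be > 0")
        if not 0.0 <= self.label_efficiency <= 1.0:
            raise ValueError("label_efficiency must be in [0, 1]")
        if self.binding_attempts < 1:
            raise ValueError("binding_attempts must be >= 1")


def _hard_core_centers(
    n: int, side: float, min_sep: float, rng: np.random.Generator
) -> np.ndarray:
    """Dart-throwing placement of n points with a hard minimum separation."""
    centers = np.empty((n, 0 + 2))
    placed = 0
    min_sep2 = min_sep * min_sep
    attempts = 0
    max_attempts = 1000 * max(n, 1)
    while placed < n:
        if attempts > max_attempts:
            raise ValueError(
                "could not place cluster centers at the requested density and separation"
            )
        attempts += 1
        c = rng.uniform(0.0, side, 2)
        d2 = ((centers[:placed] - c) ** 2).sum(axis=1)
        if placed == 0 or d2.min() >= min_sep2:
            centers[placed] = c
            placed += 1
    return centers


def simulate_cluster_field(
    density_per_um2: float,
    area_um2: float,
    size_dist: tuple[float, float] = DEFAULT_CLUSTER_SIZE_NM,
    molecules_dist: tuple[int, int] = DEFAULT_MOLECULES_PER_CLUSTER,
    free_molecule_density: float = 0.0,
    seed: int | None = None,
    min_separation_nm: float | None = None,
) -> ClusterField:
    """Draw a clustered molecule field.

    Cluster centres follow a homogeneous Poisson process with intensity
    ``density_per_um2``; each cluster's diameter is uniform in ``size_dist``
    (nm) and its molecule count uniform (integer) in ``molecules_dist``;
    molecules are placed uniformly inside the cluster disk.  Free molecules
    are an independent Poisson process with intensity ``free_molecule_density``.

    ``min_separation_nm`` optionally enforces a hard-core distance between
    cluster centres (dart-throwing placement of the Poisson-drawn count),
    for benchmarks that require optically resolvable clusters.
    """
    if density_per_um2 < 0:
        raise ValueError("density_per_um2 must be >= 0")
    if area_um2 <= 0:
        raise ValueError("area_um2 must be > 0")
    if free_molecule_density < 0:
        raise ValueError("free_molecule_density must be >= 0")
    rng = np.random.default_rng(seed)
    side = np.sqrt(area_um2) * 1000.0  # nm

    n_clusters = rng.poisson(density_per_um2 * area_um2)
    if min_separation_nm:
        centers = _hard_core_centers(n_clusters, side, min_separation_nm, rng)
    else:
        centers = rng.uniform(0.0, side, size=(n_clusters, 2))
    diam = rng.uniform(size_dist[0], size_dist[1], size=n_clusters)
    radius = diam / 2.0
    n_mol = rng.integers(molecules_dist[0], molecules_dist[1] + 1, size=n_clusters)

    positions = []
    cluster_index = []
    for k in range(n_clusters):
        # uniform in a disk: sqrt-radius trick
        r = radius[k] * np.sqrt(rng.random(n_mol[k]))
        theta = rng.uniform(0.0, 2.0 * np.pi, n_mol[k])
        pts = centers[k] + np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        positions.append(pts)
        cluster_index.append(np.full(n_mol[k], k, int))

    n_free = rng.poisson(free_molecule_density * area_um2)
    if n_free:
        positions.append(rng.uniform(0.0, side, size=(n_free, 2)))
        cluster_index.append(np.full(n_free, -1, int))

    if positions:
        epitopes = np.concatenate(positions)
        cluster_index = np.concatenate(cluster_index)
    else:
        epitopes = np.empty((0, 2))
        cluster_index = np.empty(0, int)

    return ClusterField(
        area_um2=area_um2,
        cluster_centers=centers,
        molecules_per_cluster=n_mol,
        cluster_radius_nm=radius,
        free_molecule_density=free_molecule_density,
        epitope_positions=epitopes,
        cluster_index=cluster_index,
        seed=seed,
    )


def _rsa_occupancy(
    positions: np.ndarray,
    footprint_nm: float,
    label_efficiency: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random sequential adsorption on a fixed set of candidate sites.

    Visits the sites in random order; a site binds iff it passes the
    label-efficiency coin and no already-bound site lies strictly within the
    footprint diameter.  A uniform grid with cell size = footprint keeps the
    neighbour search O(1) per site.
    """
    n = len(positions)
    bound = np.zeros(n, bool)
    if n == 0:
        return bound
    capable = rng.random(n) < label_efficiency if label_efficiency < 1.0 else np.ones(n, bool)
    order = rng.permutation(n)
    cell = footprint_nm
    f2 = footprint_nm * footprint_nm
    grid: dict[tuple[int, int], list[int]] = {}
    for i in order:
        if not capable[i]:
            continue
        x, y = positions[i]
        cx = int(x // cell)
        cy = int(y // cell)
        blocked = False
        for gx in (cx - 1, cx, cx + 1):
            for gy in (cy - 1, cy, cy + 1):
                for j in grid.get((gx, gy), ()):
                    dx = x - positions[j, 0]
                    dy = y - positions[j, 1]
                    if dx * dx + dy * dy < f2:
                        blocked = True
                        break
                if blocked:
                    break
            if blocked:
                break
        if not blocked:
            bound[i] = True
            grid.setdefault((cx, cy), []).append(i)
    return bound


def simulate_antibody_binding(
    field: ClusterField,
    model: AntibodyModel,
    seed: int | None = None,
) -> ClusterField:
    """Fill antibody occupancy on a field under the RSA shielding model.

    Returns a new :class:`ClusterField` with ``occupancy`` set; the input is
    not modified.  Epitopes closer than the antibody footprint to an
    already-bound epitope remain unlabelled — the mechanism by which tight
    molecular packing attenuates staining intensity.
    """
    if field.n_molecules == 0:
        return replace(field, occupancy=np.zeros(0, bool))
    rng = np.random.default_rng(seed)
    occ = _rsa_occupancy(
        field.epitope_positions,
        model.footprint_diameter_nm,
        model.label_efficiency,
        rng,
    )
    return replace(field, occupancy=occ)
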