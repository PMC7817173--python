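"""Stochastic two-compartment clone growth on a basal-layer lattice.

The model formalises the renewing-edge / differentiating-core picture of
oncogene-expressing epidermal clones: basal progenitors sit on a 2D
hexagonal lattice (epithelial packing); each cell divides at rate
``lambda`` per day and draws one of the three division types from a
fate-probability triplet (p_SR, p_AD, p_SD) that depends on its local
neighbourhood.  A mutant cell whose homotypic (same-clone mutant)
neighbour fraction reaches ``homotypic_threshold`` uses the *inner*
triplet (net differentiating, r < 0.5); any mutant in contact with
wild-type tissue or free space uses the *edge* triplet (net renewing,
r = 0.69 by default, the rate measured for single mutant progenitors).
Wild-type cells adjacent to a mutant clone use a reduced-renewal
triplet (r = 0.41) and distant wild-type cells the homeostatic one
(r = 0.50).

On division: symmetric renewal places the second daughter in an
adjacent free site, displacing cells outward along the shortest free
path when the neighbourhood is full; asymmetric division delaminates
one daughter (basal -> suprabasal, post-mitotic); symmetric
differentiation delaminates both and frees the site.  The update is
discrete-time Bernoulli sampling with dt*lambda <= 0.1.

The module doubles as the synthetic-data generator for every other
module: it emits cell tables, division-event tables and trajectories in
the shared schemas, plus multinomial pulse-chase (CFI) datasets and
negative-binomial shRNA screen count tables.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError, LatticeBoundaryError
from .fate_stats import FateFractions
from .morphometry import DegenerateGeometryError, circularity, fit_ellipse

logger = logging.getLogger(__name__)

__all__ = [
    "FateParams",
    "SimConfig",
    "Cell",
    "SimState",
    "initialize_state",
    "classify_context",
    "fate_probabilities",
    "step",
    "run",
    "expected_growth",
    "sample_cfi_dataset",
    "cfi_daughter_cell_table",
    "ScreenDesign",
    "simulate_screen_counts",
]

# axial-coordinate displacement to the six hexagonal neighbours
HEX_NEIGHBORS = ((1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1))

#: fate-probability triplets (p_SR, p_AD, p_SD) per context.  The
#: wild-type and mutant edge/single triplets are the measured division
#: frequencies.  The adjacent and inner triplets keep the measured
#: asymmetric fraction (0.44) and shift the symmetric balance to match
#: the measured renewal rates: 0.41 for wild-type cells touching a
#: clone, and for the clone core the value implied by the late-stage
#: observations — with ~55% edge cells still renewing at 0.69 and
#: whole-clone renewal back to ~0.5, the core must renew at ~0.27.
DEFAULT_TRIPLETS: dict[str, tuple[float, float, float]] = {
    "wt_distant": (0.29, 0.44, 0.27),   # r = 0.50: homeostasis
    "wt_adjacent": (0.19, 0.44, 0.37),  # r = 0.41: suppressed renewal near a clone
    "edge": (0.48, 0.42, 0.10),         # r = 0.69: single mutant cells / clone edge
    "inner": (0.05, 0.44, 0.51),        # r = 0.27: differentiating clone core
}

_CONTEXT_LABEL = {
    "wt_distant": "wt_distant",
    "wt_adjacent": "wt_adjacent",
    "edge": "clone_edge",
    "inner": "clone_inner",
}


@dataclass(frozen=True)
class FateParams:
    """Per-context fate-probability triplets (p_SR, p_AD, p_SD)."""

    triplets: dict = field(default_factory=lambda: dict(DEFAULT_TRIPLETS))

    def __post_init__(self) -> None:
        for ctx, t in self.triplets.items():
            t = tuple(float(p) for p in t)
            if len(t) != 3 or any(p < 0 or p > 1 for p in t):
                raise InvalidInputError(f"{ctx}: probabilities must be in [0, 1]")
            if abs(sum(t) - 1.0) > 1e-9:
                raise InvalidInputError(f"{ctx}: triplet must sum to 1, got {sum(t)}")

    def triplet(self, context: str) -> tuple[float, float, float]:
        try:
            return tuple(self.triplets[context])
        except KeyError:
            raise InvalidInputError(f"no fate triplet for context {context!r}")

    def renewal_rate(self, context: str) -> float:
        p_sr, p_ad, _ = self.triplet(context)
        return p_sr + p_ad / 2.0


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one lattice simulation.

    ``init`` selects the starting condition: ``single_mutant`` (one
    mutant progenitor on an empty lattice), ``mutant_rosette`` (7-cell
    clone), ``wt_field`` (confluent wild-type tissue) or
    ``mutant_in_wt_field`` (``mutant_seed_cells`` mutant progenitors, 1
    or 7, at the centre of confluent wild-type tissue — the in vivo
    geometry).  Field modes keep the lattice confluent: on symmetric
    renewal the tissue is displaced outward along a random lattice ray,
    with the outermost cell leaving the observation window; on symmetric
    differentiation the freed site is compacted by pulling cells inward
    along a ray, a fresh wild-type cell entering at the window edge.  A
    mutant cell reaching the window edge raises
    :class:`LatticeBoundaryError` (the clone outgrew the window).
    Empty-lattice modes instead place daughters in free sites (shortest
    displacement path when full) and, with ``close_gaps``, heal
    delamination gaps so clones stay compact rather than accumulating
    interior holes (delamination in a confluent epithelium leaves none).

    ``neighborhood_mode``: ``context_rule`` re-evaluates each cell's
    context from its current neighbourhood at every division;
    ``fixed_probabilities`` uses the static context label the cell was
    created with.
    """

    seed: int
    duration_days: float = 14.0
    division_rate_per_day: float = 0.2
    dt_days: float = 0.05
    grid_radius: int = 40
    lattice: str = "hexagonal"
    spacing_um: float = 10.0
    homotypic_threshold: float = 1.0
    neighborhood_mode: str = "context_rule"
    init: str = "single_mutant"
    close_gaps: bool = True
    smooth_every_days: float | None = 1.0
    mutant_seed_cells: int = 1
    wt_vacancy_fraction: float = 0.0
    wt_adjacent_rule: bool = True
    record_every_days: float = 1.0
    fate_params: FateParams = field(default_factory=FateParams)
    animal_id: str = "sim1"

    def __post_init__(self) -> None:
        if self.dt_days * self.division_rate_per_day > 0.1 + 1e-12:
            raise InvalidInputError(
                "dt*lambda must be <= 0.1 for first-order event sampling"
            )
        if self.duration_days <= 0 or self.dt_days <= 0:
            raise InvalidInputError("duration and dt must be positive")
        if not 0.0 <= self.homotypic_threshold <= 1.0:
            raise InvalidInputError("homotypic_threshold must be in [0, 1]")
        if self.lattice != "hexagonal":
            raise InvalidInputError("only the hexagonal lattice is implemented")
        if self.neighborhood_mode not in ("context_rule", "fixed_probabilities"):
            raise InvalidInputError(f"bad neighborhood_mode {self.neighborhood_mode!r}")


@dataclass
class Cell:
    cell_id: int
    genotype: str  # "WT" | "HrasG12V"
    clone_id: str | None
    context: str = "edge"  # static label, used in fixed_probabilities mode


@dataclass
class SimState:
    """Lattice occupancy plus cumulative division and delamination logs."""

    time_days: float = 0.0
    occupancy: dict = field(default_factory=dict)  # (q, r) -> Cell
    division_log: list = field(default_factory=list)
    delaminated: list = field(default_factory=list)  # (cell_id, genotype, clone_id, q, r)
    n_delaminations: int = 0
    n_displaced_out: int = 0  # cells pushed past the observation window
    n_immigrated: int = 0  # wild-type cells drawn in at the window edge
    next_cell_id: int = 0

    def new_cell(self, genotype: str, clone_id: str | None, context: str) -> Cell:
        c = Cell(self.next_cell_id, genotype, clone_id, context)
        self.next_cell_id += 1
        return c

    def n_basal(self, genotype: str | None = None) -> int:
        if genotype is None:
            return len(self.occupancy)
        return sum(1 for c in self.occupancy.values() if c.genotype == genotype)


def hex_distance(site: tuple[int, int]) -> int:
    q, r = site
    return (abs(q) + abs(r) + abs(q + r)) // 2


def axial_to_xy(site: tuple[int, int], spacing: float) -> tuple[float, float]:
    q, r = site
    return spacing * (q + r / 2.0), spacing * (np.sqrt(3.0) / 2.0) * r


def initialize_state(config: SimConfig, rng: np.random.Generator) -> SimState:
    state = SimState()
    if config.init in ("single_mutant", "mutant_rosette"):
        sites = [(0, 0)]
        if config.init == "mutant_rosette":
            sites += list(HEX_NEIGHBORS)
        for s in sites:
            state.occupancy[s] = state.new_cell("HrasG12V", "clone1", "edge")
    elif config.init in ("wt_field", "mutant_in_wt_field"):
        for q in range(-config.grid_radius + 1, config.grid_radius):
            for r in range(-config.grid_radius + 1, config.grid_radius):
                if hex_distance((q, r)) >= config.grid_radius:
                    continue
                if rng.random() < config.wt_vacancy_fraction:
                    continue
                state.occupancy[(q, r)] = state.new_cell("WT", None, "wt_distant")
        if config.init == "mutant_in_wt_field":
            if config.mutant_seed_cells not in (1, 7):
                raise InvalidInputError("mutant_seed_cells must be 1 or 7")
            seeds = [(0, 0)]
            if config.mutant_seed_cells == 7:
                seeds += list(HEX_NEIGHBORS)
            for s in seeds:
                state.occupancy[s] = state.new_cell("HrasG12V", "clone1", "edge")
    else:
        raise InvalidInputError(f"unknown init mode {config.init!r}")
    return state


def _neighbor_sites(site: tuple[int, int]):
    q, r = site
    return [(q + dq, r + dr) for dq, dr in HEX_NEIGHBORS]


def classify_context(
    cell: Cell,
    site: tuple[int, int],
    state: SimState,
    config: SimConfig,
) -> str:
    """Neighbourhood context of one cell in the current lattice state.

    A mutant whose homotypic neighbour fraction (same-clone occupants
    among the six lattice neighbours; free sites and other genotypes
    count against) reaches the threshold is *inner*, otherwise *edge*;
    a wild-type cell next to any mutant is *wt_adjacent* (if the rule
    is enabled), otherwise *wt_distant*.  Isolated cells fall in the
    edge/distant contexts.
    """
    neighbors = [state.occupancy.get(s) for s in _neighbor_sites(site)]
    if cell.genotype == "WT":
        adjacent = any(n is not None and n.genotype != "WT" for n in neighbors)
        return "wt_adjacent" if (adjacent and config.wt_adjacent_rule) else "wt_distant"
    homotypic = sum(
        1
        for n in neighbors
        if n is not None
        and n.genotype == cell.genotype
        and n.clone_id == cell.clone_id
    )
    frac = homotypic / len(HEX_NEIGHBORS)
    return "inner" if frac >= config.homotypic_threshold else "edge"


def fate_probabilities(
    cell: Cell,
    site: tuple[int, int],
    state: SimState,
    config: SimConfig,
) -> tuple[tuple[float, float, float], str]:
    """Fate triplet and context label for one cell in the current state.

    ``context_rule`` mode evaluates :func:`classify_context` on the
    current neighbourhood; ``fixed_probabilities`` mode uses the cell's
    static context label.
    """
    fp = config.fate_params
    if config.neighborhood_mode == "fixed_probabilities":
        return fp.triplet(cell.context), _CONTEXT_LABEL[cell.context]
    ctx = classify_context(cell, site, state, config)
    return fp.triplet(ctx), _CONTEXT_LABEL[ctx]


def _free_site_for_daughter(
    site: tuple[int, int], state: SimState, config: SimConfig, rng: np.random.Generator
) -> tuple[int, int] | None:
    """Adjacent free in-grid site, or None if the neighbourhood is full.

    Among free sites the most-surrounded one is preferred (ties broken
    at random): daughters fill concavities first, which keeps clones
    compact and roughly circular instead of growing dendritic arms.
    """
    free = [
        s
        for s in _neighbor_sites(site)
        if s not in state.occupancy and hex_distance(s) < config.grid_radius
    ]
    if not free:
        return None
    support = [
        sum(1 for t in _neighbor_sites(s) if t in state.occupancy) for s in free
    ]
    best = max(support)
    candidates = [s for s, k in zip(free, support) if k == best]
    return candidates[rng.integers(len(candidates))]


def _push_to_free_site(
    site: tuple[int, int], state: SimState, config: SimConfig
) -> tuple[int, int]:
    """Open an adjacent site by shifting cells along the shortest free path.

    Breadth-first search from the dividing cell through occupied sites to
    the nearest free site; every cell on the path moves one step outward,
    freeing the site adjacent to the divider.  Raises
    :class:`LatticeBoundaryError` when no free in-grid site is reachable
    (the clone has filled the lattice to its boundary).
    """
    parent: dict = {site: None}
    queue = deque([site])
    target = None
    while queue:
        cur = queue.popleft()
        for nxt in _neighbor_sites(cur):
            if nxt in parent or hex_distance(nxt) >= config.grid_radius:
                continue
            parent[nxt] = cur
            if nxt not in state.occupancy:
                target = nxt
                queue.clear()
                break
            queue.append(nxt)
    if target is None:
        raise LatticeBoundaryError(
            "clone reached the lattice boundary: no free site to displace into"
        )
    # shift cells outward along the path (skip the divider itself)
    path = []
    cur = target
    while cur is not None:
        path.append(cur)
        cur = parent[cur]
    path.reverse()  # site -> ... -> target
    for dst, src in zip(path[-1:0:-1], path[-2:0:-1]):
        state.occupancy[dst] = state.occupancy.pop(src)
    return path[1]


def _close_gap(hole: tuple[int, int], state: SimState, config: SimConfig) -> None:
    """Heal an enclosed vacancy by migrating it to the nearest boundary.

    BFS from the freed site through occupied sites to the nearest free
    in-grid site; every cell on the path shifts one step toward the
    hole, so the vacancy merges with the exterior and the clone stays
    compact.  A hole already touching free space, or a lattice with no
    free site at all, is left as is.
    """
    neighbors = _neighbor_sites(hole)
    support = sum(1 for s in neighbors if s in state.occupancy)
    if support == 0:
        return  # nothing around to rearrange
    if support < len(neighbors):
        # open to the exterior: a deep notch is smoothed by pulling in its
        # most exposed neighbouring cell when that lowers the boundary
        # energy (junctional rearrangement under adhesion); shallow bays
        # are left to be filled by growth
        for _ in range(16):  # bounded cascade
            if support < 4:
                return
            occ_nbrs = [s for s in neighbors if s in state.occupancy]
            exposure = [
                sum(1 for t in _neighbor_sites(s) if t in state.occupancy)
                for s in occ_nbrs
            ]
            k = int(np.argmin(exposure))
            # the mover gains support-1 contacts (it no longer counts
            # itself); move only if that strictly beats its current
            # exposure, so each rearrangement lowers boundary energy
            if exposure[k] >= support - 1:
                return
            src = occ_nbrs[k]
            state.occupancy[hole] = state.occupancy.pop(src)
            hole = src
            neighbors = _neighbor_sites(hole)
            support = sum(1 for s in neighbors if s in state.occupancy)
        return
    parent: dict = {hole: None}
    queue = deque([hole])
    target = None
    while queue:
        cur = queue.popleft()
        for nxt in _neighbor_sites(cur):
            if nxt in parent or hex_distance(nxt) >= config.grid_radius:
                continue
            parent[nxt] = cur
            if nxt not in state.occupancy:
                target = nxt
                queue.clear()
                break
            queue.append(nxt)
    if target is None:
        return  # lattice full to the boundary: hole cannot be resolved
    path = []
    cur = target
    while cur is not None:
        path.append(cur)
        cur = parent[cur]
    path.reverse()  # hole -> ... -> target (free)
    for dst, src in zip(path[:-1], path[1:]):
        if src in state.occupancy:
            state.occupancy[dst] = state.occupancy.pop(src)


def _is_field_mode(config: SimConfig) -> bool:
    return config.init in ("wt_field", "mutant_in_wt_field")


def _radial_direction(
    site: tuple[int, int], rng: np.random.Generator
) -> tuple[int, int]:
    """Hex direction best aligned with the outward radial vector.

    Displacement in a confluent tissue with a centrally seeded clone
    follows the radial strain field: cells yield away from the centre,
    toward the window edge.  Ties (and the origin) are broken randomly.
    """
    x, y = axial_to_xy(site, 1.0)
    if x == 0.0 and y == 0.0:
        return HEX_NEIGHBORS[rng.integers(len(HEX_NEIGHBORS))]
    # sample among outward-pointing directions with probability
    # proportional to radial alignment, so displacement spreads over a
    # cone instead of riding a single lattice ray
    dirs, weights = [], []
    for d in HEX_NEIGHBORS:
        dx, dy = axial_to_xy(d, 1.0)
        dot = (dx * x + dy * y) / np.hypot(dx, dy)
        if dot > 1e-12:
            dirs.append(d)
            weights.append(dot)
    w = np.asarray(weights)
    return dirs[rng.choice(len(dirs), p=w / w.sum())]


def _ray_push_out(
    site: tuple[int, int], state: SimState, config: SimConfig,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Open the site next to ``site`` by displacing tissue outward.

    Cells along a random lattice ray shift one step away from the
    divider, up to the first free site or the window edge; a cell pushed
    past the edge leaves the observation window (the simulated patch is
    part of a larger epithelium).  A non-wild-type cell leaving raises
    :class:`LatticeBoundaryError` — the focal clone outgrew the window.
    Returns the freed adjacent site, or None when the daughter itself is
    displaced out of the window (division right at the edge).
    """
    # insertion is isotropic among directions that avoid displacing the
    # cohesive mutant phase: a clone expands by pushing the surrounding
    # wild-type tissue, and wild-type divisions yield around the clone
    # rather than through it; beyond the first hop the displacement
    # chain follows the outward radial strain field
    dirs = [
        d
        for d in HEX_NEIGHBORS
        if (c := state.occupancy.get((site[0] + d[0], site[1] + d[1]))) is None
        or c.genotype == "WT"
    ] or list(HEX_NEIGHBORS)
    dq, dr = dirs[rng.integers(len(dirs))]
    ray = []
    cur = (site[0] + dq, site[1] + dr)
    while hex_distance(cur) < config.grid_radius and cur in state.occupancy:
        ray.append(cur)
        dq, dr = _radial_direction(cur, rng)
        cur = (cur[0] + dq, cur[1] + dr)
    if hex_distance(cur) < config.grid_radius:
        ray.append(cur)  # first free site: chain stops inside the window
    else:
        if not ray:
            # the divider sits at the window edge: its daughter is born
            # outside the observation window
            if state.occupancy[site].genotype != "WT":
                raise LatticeBoundaryError(
                    "mutant clone reached the edge of the observation window"
                )
            state.n_displaced_out += 1
            return None
        if state.occupancy[ray[-1]].genotype != "WT":
            raise LatticeBoundaryError(
                "mutant clone reached the edge of the observation window"
            )
        state.n_displaced_out += 1
        del state.occupancy[ray[-1]]
    for dst, src in zip(ray[-1:0:-1], ray[-2::-1]):
        state.occupancy[dst] = state.occupancy.pop(src)
    return ray[0]


def _ray_compact(
    hole: tuple[int, int], state: SimState, config: SimConfig,
    rng: np.random.Generator,
) -> None:
    """Close a freed site by pulling tissue inward along a random ray.

    Cells between the hole and the window edge shift one step toward the
    hole; the vacated site at the window edge is refilled by a fresh
    wild-type cell entering the observation window.  If the ray meets an
    interior free site first, that vacancy simply migrates to the hole.
    """
    # material flows inward: the chain is drawn from the outward radial
    # side of the hole, so compaction moves tissue toward the centre
    dq, dr = _radial_direction(hole, rng)
    ray = []
    cur = (hole[0] + dq, hole[1] + dr)
    while hex_distance(cur) < config.grid_radius and cur in state.occupancy:
        ray.append(cur)
        dq, dr = _radial_direction(cur, rng)
        cur = (cur[0] + dq, cur[1] + dr)
    prev = hole
    for src in ray:
        state.occupancy[prev] = state.occupancy.pop(src)
        prev = src
    if hex_distance(cur) >= config.grid_radius:
        # ray reached the window edge: tissue flows in from outside
        state.occupancy[prev] = state.new_cell("WT", None, "wt_distant")
        state.n_immigrated += 1


def relax_interface(state: SimState, config: SimConfig) -> int:
    """One differential-adhesion sweep on the clone/wild-type interface.

    Each mutant cell with heterotypic contacts may swap position with an
    adjacent wild-type cell when the exchange strictly increases the
    total number of homotypic contacts (surface-energy descent), which
    keeps the clone boundary smooth and compact in confluent tissue.
    Greedy single pass in deterministic site order; returns swap count.
    """
    def homotypic(site, genotype, exclude=None):
        n = 0
        for t in _neighbor_sites(site):
            if t == exclude:
                continue
            c = state.occupancy.get(t)
            if c is not None and (c.genotype == genotype):
                n += 1
        return n

    swaps = 0
    mutant_sites = sorted(
        s for s, c in state.occupancy.items() if c.genotype != "WT"
    )
    for site in mutant_sites:
        cell = state.occupancy.get(site)
        if cell is None or cell.genotype == "WT":
            continue
        wt_nbrs = [
            t for t in _neighbor_sites(site)
            if t in state.occupancy and state.occupancy[t].genotype == "WT"
        ]
        if not wt_nbrs:
            continue
        before = homotypic(site, cell.genotype)
        best, best_gain = None, 0
        for t in wt_nbrs:
            other = state.occupancy[t]
            gain = (
                homotypic(t, cell.genotype, exclude=site)
                + homotypic(site, other.genotype, exclude=t)
                - before
                - homotypic(t, other.genotype, exclude=site)
            )
            if gain > best_gain:
                best, best_gain = t, gain
        if best is not None:
            state.occupancy[site], state.occupancy[best] = (
                state.occupancy[best], state.occupancy[site],
            )
            swaps += 1
    return swaps


def relax_boundary(state: SimState, config: SimConfig) -> int:
    """One surface-relaxation sweep: boundary cells hop into better sites.

    Each cell moves to an adjacent free in-grid site where it would have
    strictly more occupied neighbours (surface-energy descent under
    cell-cell adhesion).  A single greedy pass in deterministic site
    order; returns the number of moves.  Keeps clones compact and
    roughly circular, mirroring the junctional rearrangements that keep
    a confluent epithelium sealed.
    """
    moved = 0
    for site in sorted(state.occupancy):
        cell = state.occupancy.get(site)
        if cell is None:
            continue
        exposure = sum(1 for t in _neighbor_sites(site) if t in state.occupancy)
        if exposure >= 5:
            continue
        best_site, best_gain = None, 0
        for t in _neighbor_sites(site):
            if t in state.occupancy or hex_distance(t) >= config.grid_radius:
                continue
            support = sum(1 for u in _neighbor_sites(t) if u in state.occupancy)
            gain = (support - 1) - exposure  # mover does not count itself
            if gain > best_gain:
                best_site, best_gain = t, gain
        if best_site is not None:
            state.occupancy[best_site] = state.occupancy.pop(site)
            moved += 1
    return moved


def step(state: SimState, config: SimConfig, rng: np.random.Generator) -> SimState:
    """Advance the lattice by one time step dt (in place; state returned).

    Each basal cell divides with probability lambda*dt; fates are drawn
    per cell from :func:`fate_probabilities`.  Bookkeeping invariant:
    the change in basal-cell count equals (#SR - #SD) among the step's
    divisions, and delaminations increase by #AD + 2*#SD.
    """
    p_div = config.division_rate_per_day * config.dt_days
    snapshot = list(state.occupancy.items())
    state.time_days += config.dt_days
    if p_div == 0.0 or not snapshot:
        return state
    draws = rng.random(len(snapshot))
    for (site, cell), u in zip(snapshot, draws):
        if u >= p_div:
            continue
        if state.occupancy.get(site) is not cell:
            continue  # displaced or delaminated earlier in this step
        triplet, context = fate_probabilities(cell, site, state, config)
        idx = int(np.searchsorted(np.cumsum(triplet), rng.random(), side="right"))
        ftype = ("SR", "AD", "SD")[min(idx, 2)]
        if ftype == "SR":
            target = _free_site_for_daughter(site, state, config, rng)
            if target is None:
                if _is_field_mode(config):
                    target = _ray_push_out(site, state, config, rng)
                else:
                    target = _push_to_free_site(site, state, config)
            if target is not None:
                state.occupancy[target] = state.new_cell(
                    cell.genotype, cell.clone_id, cell.context
                )
            d1 = d2 = "basal"
        elif ftype == "AD":
            # one daughter keeps the site; the other delaminates
            delam = state.new_cell(cell.genotype, cell.clone_id, cell.context)
            state.delaminated.append((delam.cell_id, cell.genotype, cell.clone_id, site))
            state.n_delaminations += 1
            d1, d2 = ("basal", "suprabasal") if rng.random() < 0.5 else (
                "suprabasal", "basal")
        else:  # SD: both daughters delaminate, the site frees up
            for _ in range(2):
                delam = state.new_cell(cell.genotype, cell.clone_id, cell.context)
                state.delaminated.append(
                    (delam.cell_id, cell.genotype, cell.clone_id, site)
                )
                state.n_delaminations += 1
            del state.occupancy[site]
            if _is_field_mode(config):
                _ray_compact(site, state, config, rng)
            elif config.close_gaps:
                _close_gap(site, state, config)
            d1 = d2 = "suprabasal"
        state.division_log.append(
            {
                "animal_id": config.animal_id,
                "clone_id": cell.clone_id if cell.clone_id is not None else "",
                "context": context,
                "week": state.time_days / 7.0,
                "daughter1_layer": d1,
                "daughter2_layer": d2,
                "daughter1_morph": "unknown",
                "daughter2_morph": "unknown",
                "time_days": state.time_days,
                "division_type": ftype,
                "genotype": cell.genotype,
            }
        )
    return state


def _focal_cells(state: SimState) -> list[tuple[tuple[int, int], Cell]]:
    mutants = [
        (s, c) for s, c in state.occupancy.items() if c.genotype != "WT"
    ]
    return mutants if mutants else list(state.occupancy.items())


def _trajectory_row(state: SimState, config: SimConfig) -> dict:
    focal = _focal_cells(state)
    # edge/inner counts report realised geometry, so classify from the
    # current neighbourhood even when fates are drawn from static labels
    n_edge = n_inner = 0
    for site, cell in focal:
        if classify_context(cell, site, state, config) == "inner":
            n_inner += 1
        else:
            n_edge += 1
    row = {
        "time_days": state.time_days,
        "n_basal": len(state.occupancy),
        "n_focal": len(focal),
        "n_edge": n_edge,
        "n_inner": n_inner,
        "edge_fraction": n_edge / len(focal) if focal else np.nan,
        "n_delaminations": state.n_delaminations,
        "circularity": np.nan,
        "density_per_um2": np.nan,
    }
    if len(focal) >= 3:
        xy = np.array([axial_to_xy(s, config.spacing_um) for s, _ in focal])
        try:
            fit = fit_ellipse(xy, kind="points")
            row["circularity"] = circularity(fit.area_um2, fit.perimeter_um)
            row["density_per_um2"] = len(focal) / fit.area_um2
        except DegenerateGeometryError:
            pass
    counts = {"SR": 0, "AD": 0, "SD": 0}
    for ev in state.division_log:
        counts[ev["division_type"]] += 1
    n_div = sum(counts.values())
    if n_div:
        row.update(
            f_sr=counts["SR"] / n_div,
            f_ad=counts["AD"] / n_div,
            f_sd=counts["SD"] / n_div,
            renewal_rate=(2 * counts["SR"] + counts["AD"]) / (2 * n_div),
        )
    else:
        row.update(f_sr=np.nan, f_ad=np.nan, f_sd=np.nan, renewal_rate=np.nan)
    return row


def cell_table(state: SimState, config: SimConfig) -> pd.DataFrame:
    """Current lattice state as a cell table in the shared schema.

    Delaminated cells are retained with layer = suprabasal and K10+
    (post-mitotic, differentiated); basal cells are K10-.
    """
    rows = []
    for site, cell in state.occupancy.items():
        x, y = axial_to_xy(site, config.spacing_um)
        rows.append(
            {
                "animal_id": config.animal_id,
                "clone_id": cell.clone_id if cell.clone_id is not None else "",
                "cell_id": f"c{cell.cell_id}",
                "x_um": x,
                "y_um": y,
                "layer": "basal",
                "genotype": cell.genotype,
                "edu": 0,
                "brdu": 0,
                "k10": 0,
            }
        )
    for cell_id, genotype, clone_id, site in state.delaminated:
        x, y = axial_to_xy(site, config.spacing_um)
        rows.append(
            {
                "animal_id": config.animal_id,
                "clone_id": clone_id if clone_id is not None else "",
                "cell_id": f"c{cell_id}",
                "x_um": x,
                "y_um": y,
                "layer": "suprabasal",
                "genotype": genotype,
                "edu": 0,
                "brdu": 0,
                "k10": 1,
            }
        )
    return pd.DataFrame(rows)


def run(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run a seeded simulation; returns (trajectory, cell table, events).

    Reproducible: identical config (including seed) gives identical
    outputs.  The run stops early if the focal population goes extinct.
    """
    rng = np.random.default_rng(config.seed)
    state = initialize_state(config, rng)
    n_steps = int(round(config.duration_days / config.dt_days))
    record_every = max(1, int(round(config.record_every_days / config.dt_days)))
    smooth_every = (
        None
        if config.smooth_every_days is None
        else max(1, int(round(config.smooth_every_days / config.dt_days)))
    )
    traj = [_trajectory_row(state, config)]
    for i in range(1, n_steps + 1):
        step(state, config, rng)
        if smooth_every is not None and i % smooth_every == 0:
            if _is_field_mode(config):
                relax_interface(state, config)
            else:
                relax_boundary(state, config)
        if i % record_every == 0 or i == n_steps or not state.occupancy:
            traj.append(_trajectory_row(state, config))
        if not state.occupancy:
            logger.info("population extinct at t=%.2f days", state.time_days)
            break
    trajectory = pd.DataFrame(traj)
    events = pd.DataFrame(
        state.division_log,
        columns=[
            "animal_id", "clone_id", "context", "week",
            "daughter1_layer", "daughter2_layer",
            "daughter1_morph", "daughter2_morph",
            "time_days", "division_type", "genotype",
        ],
    )
    return trajectory, cell_table(state, config), events


def expected_growth(n0: float, lam: float, r: float, t: float) -> float:
    """Mean population size of the branching process: N0*exp(lambda*(2r-1)*t).

    Each division replaces one progenitor by 2r progenitors on average,
    so the expected per-capita growth rate is lambda*(2r-1); r = 0.5 is
    the homeostatic martingale.
    """
    if not 0.0 <= r <= 1.0:
        raise InvalidInputError("renewal rate r must be in [0, 1]")
    if lam < 0:
        raise InvalidInputError("division rate must be non-negative")
    return n0 * float(np.exp(lam * (2.0 * r - 1.0) * t))


def _as_triplet(fractions) -> tuple[float, float, float]:
    if isinstance(fractions, FateFractions):
        return fractions.as_tuple()
    t = tuple(float(p) for p in fractions)
    if len(t) != 3 or any(p < 0 for p in t) or abs(sum(t) - 1.0) > 1e-9:
        raise InvalidInputError(f"invalid fate triplet {fractions!r}")
    return t


def sample_cfi_dataset(
    fractions,
    n_divisions: int,
    *,
    n_animals: int = 1,
    week: float = 0.0,
    context: str = "single_cell",
    genotype: str = "HrasG12V",
    already_divided_fraction: float = 0.15,
    return_cells: bool = False,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
):
    """Draw a synthetic pulse-chase (CFI) division-event table.

    Division types are multinomial at ``fractions`` = (p_SR, p_AD, p_SD);
    each event is emitted as an EdU+/BrdU- doublet with daughter layers
    determined by its type (AD daughter order randomised).  Divisions
    are split evenly across ``n_animals``.  With ``return_cells`` the
    companion cell table is also returned: two EdU+/BrdU- daughters per
    doublet (suprabasal daughters are K10+) plus the label-window cells
    that had already divided before the chase, emitted as EdU+/BrdU+
    basal singles at the assay's measured proportion (default 15% of
    labelled cells) — these are excluded from scoring by construction.
    """
    if n_divisions < 1:
        raise InvalidInputError("n_divisions must be >= 1")
    p = _as_triplet(fractions)
    if rng is None:
        if seed is None:
            raise InvalidInputError("sample_cfi_dataset requires a seed or rng")
        rng = np.random.default_rng(seed)
    per_animal = [n_divisions // n_animals] * n_animals
    for i in range(n_divisions % n_animals):
        per_animal[i] += 1
    rows = []
    for a, n_a in enumerate(per_animal, start=1):
        types = rng.choice(("SR", "AD", "SD"), size=n_a, p=p)
        flip = rng.random(n_a) < 0.5
        for k, t in enumerate(types):
            if t == "SR":
                d1 = d2 = "basal"
            elif t == "SD":
                d1 = d2 = "suprabasal"
            else:
                d1, d2 = ("basal", "suprabasal") if flip[k] else ("suprabasal", "basal")
            rows.append(
                {
                    "animal_id": f"animal{a}",
                    "clone_id": "",
                    "context": context,
                    "week": week,
                    "daughter1_layer": d1,
                    "daughter2_layer": d2,
                    "daughter1_morph": "unknown",
                    "daughter2_morph": "unknown",
                    "genotype": genotype,
                }
            )
    events = pd.DataFrame(rows)
    if not return_cells:
        return events
    return events, cfi_daughter_cell_table(
        events, already_divided_fraction=already_divided_fraction, rng=rng
    )


def cfi_daughter_cell_table(
    events: pd.DataFrame,
    already_divided_fraction: float = 0.15,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    spacing_um: float = 10.0,
) -> pd.DataFrame:
    """Cell table for the daughters of a CFI event table.

    Each doublet contributes two EdU+/BrdU- cells; suprabasal daughters
    are K10+ (differentiated), basal daughters K10-.  A proportion of
    the labelled cohort divided before the BrdU chase; those appear as
    EdU+/BrdU+ basal singles and must be excluded from fate scoring.
    Cell positions are arbitrary (doublets on a coarse grid) — this
    table exercises marker logic, not geometry.
    """
    if not 0.0 <= already_divided_fraction < 1.0:
        raise InvalidInputError("already_divided_fraction must be in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    rows = []
    cid = 0
    for i, ev in events.iterrows():
        for j, layer in enumerate((ev["daughter1_layer"], ev["daughter2_layer"])):
            rows.append(
                {
                    "animal_id": ev["animal_id"],
                    "clone_id": ev.get("clone_id", ""),
                    "cell_id": f"d{cid}",
                    "x_um": spacing_um * (3 * i + j),
                    "y_um": 0.0,
                    "layer": layer,
                    "genotype": ev.get("genotype", "HrasG12V"),
                    "edu": 1,
                    "brdu": 0,
                    "k10": int(layer == "suprabasal"),
                }
            )
            cid += 1
    n_doublet_cells = len(rows)
    # EdU+/BrdU+ singles: fraction f of all labelled cells => f/(1-f) per scored cell
    n_pre = int(round(
        n_doublet_cells * already_divided_fraction / (1.0 - already_divided_fraction)
    ))
    for k in range(n_pre):
        rows.append(
            {
                "animal_id": events["animal_id"].iloc[0] if len(events) else "animal1",
                "clone_id": "",
                "cell_id": f"pre{k}",
                "x_um": spacing_um * (3 * len(events) + k),
                "y_um": 3 * spacing_um,
                "layer": "basal",
                "genotype": "HrasG12V",
                "edu": 1,
                "brdu": 1,
                "k10": 0,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ScreenDesign:
    """Design of a simulated pooled shRNA screen.

    Defaults mirror a compact in vivo pool: 27 genes x 5 hairpins = 135
    constructs, sequenced in basal (alpha6-integrin high) and suprabasal
    (alpha6-integrin low) sorted compartments across 4 animals.
    ``effects`` maps gene -> true log2 basal/suprabasal enrichment (a
    gene whose knockdown inhibits differentiation accumulates in the
    basal compartment, log2 > 0); ``effect_shrnas`` limits the effect to
    the first k hairpins of each affected gene — an int for all genes, a
    per-gene dict, or None for every hairpin (off-target-free pool).
    """

    n_genes: int = 27
    shrnas_per_gene: int = 5
    n_replicates: int = 4
    effects: dict = field(default_factory=dict)
    effect_shrnas: int | dict | None = None
    dispersion: float = 0.15
    library_size: float = 1e6
    abundance_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise InvalidInputError("library_size must be positive")
        if self.dispersion < 0:
            raise InvalidInputError("dispersion must be non-negative")

    @property
    def genes(self) -> list[str]:
        return [f"gene{i + 1:02d}" for i in range(self.n_genes)]


def simulate_screen_counts(
    design: ScreenDesign, seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Negative-binomial shRNA count table with planted enrichment.

    Per-construct baseline abundances are log-normal; a gene effect e
    multiplies the basal mean by 2^(e/2) and divides the suprabasal mean
    by 2^(e/2).  Counts are NB with var = mu + dispersion*mu^2, each
    library scaled to ``library_size`` expected total.
    """
    if rng is None:
        if seed is None:
            raise InvalidInputError("simulate_screen_counts requires a seed or rng")
        rng = np.random.default_rng(seed)
    genes = np.repeat(design.genes, design.shrnas_per_gene)
    shrna_ids = np.array(
        [f"{g}_sh{i + 1}" for g in design.genes for i in range(design.shrnas_per_gene)]
    )
    n = len(shrna_ids)
    base = rng.lognormal(mean=0.0, sigma=design.abundance_sigma, size=n)
    effect = np.zeros(n)
    for g, e in design.effects.items():
        mask = genes == g
        if not mask.any():
            raise InvalidInputError(f"effect for unknown gene {g!r}")
        idx = np.flatnonzero(mask)
        k = design.effect_shrnas
        if isinstance(k, dict):
            k = k.get(g)
        if k is not None:
            idx = idx[:k]
        effect[idx] = e
    mu_basal = base * np.exp2(effect / 2.0)
    mu_supra = base * np.exp2(-effect / 2.0)
    rows = []
    for compartment, mu in (("basal", mu_basal), ("suprabasal", mu_supra)):
        mu_lib = mu / mu.sum() * design.library_size
        for rep in range(1, design.n_replicates + 1):
            if design.dispersion > 0:
                r_nb = 1.0 / design.dispersion
                counts = rng.negative_binomial(r_nb, r_nb / (r_nb + mu_lib))
            else:
                counts = rng.poisson(mu_lib)
            for g, sid, c in zip(genes, shrna_ids, counts):
                rows.append(
                    {
                        "gene": g,
                        "shrna_id": sid,
                        "compartment": compartment,
                        "replicate": f"animal{rep}",
                        "count": int(c),
                    }
                )
    return pd.DataFrame(rows)
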