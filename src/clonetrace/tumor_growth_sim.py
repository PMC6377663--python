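"""Stochastic 3D lattice growth of barcoded cells, with virtual cutting.

One cell per lattice site.  Cells divide (daughter placed in a uniformly
chosen empty neighbor site, suppressed when none is empty), die, or
migrate to an empty neighbor, Gillespie-style with per-cell rates.  The
barcode label is heritable; the grown tumor can be cut into spatial
pieces whose per-piece barcode counts feed the clonal statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .qc_normalize import ClonalProfile

__all__ = ["SimParams", "SimState", "simulate_growth", "virtual_cut", "pieces_to_profiles"]

_VON_NEUMANN = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
_MOORE = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


@dataclass(frozen=True)
class SimParams:
    birth_rate: float = 1.0
    death_rate: float = 0.1
    migration_rate: float = 0.0
    n_init: int = 200
    target_cells: int = 100_000
    neighborhood: str = "von_neumann"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be > 0")
        if self.death_rate < 0 or self.migration_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")
        if self.target_cells < self.n_init:
            raise ValueError("target_cells must be >= n_init")
        if self.neighborhood not in ("von_neumann", "moore"):
            raise ValueError("neighborhood must be 'von_neumann' or 'moore'")


@dataclass
class SimState:
    """Occupied lattice sites with heritable barcode labels."""

    positions: np.ndarray  # (n_cells, 3) int lattice coordinates
    labels: np.ndarray  # (n_cells,) int barcode label per cell
    time: float
    births: int
    deaths: int
    migrations: int
    extinct: bool
    params: SimParams = None  # type: ignore[assignment]

    @property
    def n_cells(self) -> int:
        return len(self.labels)

    def clone_sizes(self) -> pd.Series:
        labels, counts = np.unique(self.labels, return_counts=True)
        return pd.Series(counts, index=labels).sort_values(ascending=False)


def _compact_cluster(n: int, neighbors) -> list[tuple[int, int, int]]:
    """The n lattice sites closest to the origin (BFS ball), deterministic."""
    from heapq import heappop, heappush

    sites: list[tuple[int, int, int]] = []
    seen = {(0, 0, 0)}
    heap = [(0, (0, 0, 0))]
    while heap and len(sites) < n:
        _, pos = heappop(heap)
        sites.append(pos)
        for d in neighbors:
            nxt = (pos[0] + d[0], pos[1] + d[1], pos[2] + d[2])
            if nxt not in seen:
                seen.add(nxt)
                heappush(heap, (nxt[0] ** 2 + nxt[1] ** 2 + nxt[2] ** 2, nxt))
    return sites


def simulate_growth(params: SimParams) -> SimState:
    """Grow a barcoded tumor until ``target_cells`` cells or extinction.

    Event selection is Gillespie-style: total rate (b + d + M) * N, the
    event type chosen proportionally to the rates and a uniformly random
    cell attempting it.  Divisions and migrations into a fully occupied
    neighborhood are suppressed (the event is consumed).  Initial cells
    occupy a compact cluster around the origin with distinct barcode
    labels 0..n_init-1.  Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    neighbors = _VON_NEUMANN if params.neighborhood == "von_neumann" else _MOORE

    init_sites = _compact_cluster(params.n_init, neighbors)
    cells: list[tuple[int, int, int]] = list(init_sites)
    labels: list[int] = list(range(params.n_init))
    occupied: dict[tuple[int, int, int], int] = {
        pos: i for i, pos in enumerate(cells)
    }

    b, d, m = params.birth_rate, params.death_rate, params.migration_rate
    total_per_cell = b + d + m
    p_birth = b / total_per_cell
    p_death = d / total_per_cell
    t = 0.0
    births = deaths = migrations = 0

    # pre-drawn random numbers in blocks to keep the Python loop cheap
    block = 65536
    u_event = rng.random(block)
    u_cell = rng.random(block)
    u_slot = rng.random(block)
    u_exp = rng.exponential(size=block)
    cursor = 0

    def refill():
        nonlocal u_event, u_cell, u_slot, u_exp, cursor
        u_event = rng.random(block)
        u_cell = rng.random(block)
        u_slot = rng.random(block)
        u_exp = rng.exponential(size=block)
        cursor = 0

    while cells and len(cells) < params.target_cells:
        if cursor >= block:
            refill()
        n = len(cells)
        t += u_exp[cursor] / (total_per_cell * n)
        i = int(u_cell[cursor] * n)
        ev = u_event[cursor]
        pos = cells[i]
        if ev < p_birth or ev >= p_birth + p_death:
            empty = [
                (pos[0] + dx, pos[1] + dy, pos[2] + dz)
                for dx, dy, dz in neighbors
                if (pos[0] + dx, pos[1] + dy, pos[2] + dz) not in occupied
            ]
            if empty:
                target = empty[int(u_slot[cursor] * len(empty))]
                if ev < p_birth:  # division
                    occupied[target] = len(cells)
                    cells.append(target)
                    labels.append(labels[i])
                    births += 1
                else:  # migration
                    del occupied[pos]
                    occupied[target] = i
                    cells[i] = target
                    migrations += 1
        else:  # death: swap-remove
            last = len(cells) - 1
            del occupied[pos]
            if i != last:
                cells[i] = cells[last]
                labels[i] = labels[last]
                occupied[cells[i]] = i
            cells.pop()
            labels.pop()
            deaths += 1
        cursor += 1

    return SimState(
        positions=np.array(cells, dtype=int).reshape(-1, 3),
        labels=np.array(labels, dtype=int),
        time=t,
        births=births,
        deaths=deaths,
        migrations=migrations,
        extinct=len(cells) == 0,
        params=params,
    )


def _octant_assign(positions: np.ndarray) -> np.ndarray:
    """Split at the per-axis medians into 8 near-equal octants."""
    piece = np.zeros(len(positions), dtype=int)
    for axis in range(3):
        med = np.median(positions[:, axis])
        # jitter-free tie handling: sites exactly at the median go by rank
        side = positions[:, axis] > med
        at = positions[:, axis] == med
        if at.any():
            # balance ties: alternate assignment by stable order
            idx = np.flatnonzero(at)
            side[idx[: len(idx) // 2]] = False
            side[idx[len(idx) // 2 :]] = True
        piece = piece * 2 + side.astype(int)
    return piece


def _slab_assign(positions: np.ndarray, n_pieces: int) -> np.ndarray:
    axis = np.argmax(positions.max(axis=0) - positions.min(axis=0))
    order = np.argsort(positions[:, axis], kind="stable")
    piece = np.empty(len(positions), dtype=int)
    bounds = np.linspace(0, len(positions), n_pieces + 1).astype(int)
    for k in range(n_pieces):
        piece[order[bounds[k] : bounds[k + 1]]] = k
    return piece


def _kmeans_assign(positions: np.ndarray, n_pieces: int, seed: int) -> np.ndarray:
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=n_pieces, n_init=10, random_state=seed)
    return km.fit_predict(positions.astype(float))


def virtual_cut(
    state: SimState, n_pieces: int, scheme: str = "octants", seed: int = 0
) -> tuple[pd.DataFrame, list[tuple[int, int]]]:
    """Cut the simulated tumor into spatial pieces.

    Returns (piece x barcode count matrix, adjacency edges between
    pieces).  Two pieces are adjacent when any of their cells occupy
    face-neighboring lattice sites.  The default ``octants`` scheme
    splits at the coordinate medians (requires n_pieces == 8) and yields
    near-equal piece sizes; ``slabs`` cuts equal-count slabs along the
    longest axis; ``kmeans_regions`` clusters coordinates.
    """
    if state.n_cells == 0:
        raise ValueError("cannot cut an empty simulation state")
    if n_pieces < 2:
        raise ValueError("n_pieces must be >= 2")
    if n_pieces > state.n_cells:
        raise ValueError("n_pieces exceeds total cell count")
    if scheme == "octants":
        if n_pieces != 8:
            raise ValueError("octants scheme requires n_pieces == 8")
        piece = _octant_assign(state.positions)
    elif scheme == "slabs":
        piece = _slab_assign(state.positions, n_pieces)
    elif scheme == "kmeans_regions":
        piece = _kmeans_assign(state.positions, n_pieces, seed)
    else:
        raise ValueError(f"unknown cut scheme {scheme!r}")

    counts = (
        pd.crosstab(piece, state.labels)
        .reindex(range(n_pieces), fill_value=0)
        .rename_axis(index="piece", columns="barcode")
    )

    # piece adjacency from face-neighboring occupied sites
    site_piece = {
        tuple(pos): int(pc) for pos, pc in zip(state.positions, piece)
    }
    edges = set()
    for pos, pc in site_piece.items():
        for d in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
            other = site_piece.get((pos[0] + d[0], pos[1] + d[1], pos[2] + d[2]))
            if other is not None and other != pc:
                edges.add((min(pc, other), max(pc, other)))
    return counts, sorted(edges)


def pieces_to_profiles(piece_counts: pd.DataFrame, prefix: str = "piece") -> list[ClonalProfile]:
    """Normalize per-piece barcode counts into frequency profiles."""
    profiles = []
    for piece_id, row in piece_counts.iterrows():
        total = row.sum()
        if total == 0:
            continue
        freqs = (row / total).astype(float)
        freqs.index = [f"BC{int(b)}" for b in freqs.index]
        profiles.append(
            ClonalProfile(sample_id=f"{prefix}{piece_id}", frequencies=freqs)
        )
    return profiles
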