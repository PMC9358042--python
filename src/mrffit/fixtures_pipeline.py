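"""Synthetic toy complexes, benchmark construction, and the fitting pipeline.

The toy generator emulates the benchmark protocol used to study the fitting
method: a reference multi-subunit complex is built, its density map is
simulated at a stated resolution and voxel size (defaults 10 Å / 1.0 Å),
every subunit is then independently scrambled by a random rigid transform,
and the fitting pipeline must recover the reference arrangement from the map
and the scrambled subunits alone.

Toy subunits are deterministic pseudo-proteins: compact excluded-volume
Cα random walks decorated with backbone-like N/C/O atoms, packed into mutual
contact with zero steric clashes.  They are deliberately asymmetric (distinct
shapes and sequences) by default so planted-pose recovery has a unique
answer; a duplicate-chain mode reuses one shape to exercise the
chain-permutation metric path.
"""

from __future__ import annotations

import logging
import sys
import time
from dataclasses import dataclass, field

import numpy as np

from . import pair_scoring
from .assembly_metrics import EvalResult, evaluate
from .mrf_topk import (AssemblyModel, MRFGraph, Weights, build_graph,
                       extract_top_k, run_max_sum)
from .pose_search import (DEFAULT_CLUSTER_RADIUS, DEFAULT_MAX_POSES,
                          DEFAULT_OVERLAP_CUTOFF, PoseSet, search_subunit,
                          suggest_contour_level)
from .rigid_structures import (RigidTransform, RotationSet, Subunit,
                               apply_transform, random_transform, rotation_set)
from .voxel_maps import DensityMap, contour_mask, simulate_map

__all__ = [
    "ToyBenchmark",
    "PipelineConfig",
    "PipelineResult",
    "make_toy_complex",
    "make_benchmark",
    "run_pipeline",
]

logger = logging.getLogger("mrffit")

_RES_PALETTES = [
    ("ALA", "LEU", "SER", "LYS", "ASP", "VAL"),
    ("GLY", "PHE", "THR", "GLU", "ARG", "ILE"),
    ("PRO", "MET", "ASN", "HIS", "TYR", "TRP"),
    ("CYS", "GLN", "VAL", "ASP", "LYS", "LEU"),
    ("SER", "ILE", "GLU", "ARG", "ALA", "PHE"),
    ("THR", "LEU", "ASN", "LYS", "GLU", "GLY"),
    ("VAL", "TYR", "SER", "ASP", "ARG", "MET"),
]

_CA_STEP = 3.8
_MIN_SELF_DIST = 4.0


@dataclass
class ToyBenchmark:
    """A synthetic fitting problem with known ground truth."""

    reference: list
    scrambled: list
    map: DensityMap
    planted: list
    seed: int
    resolution: float


def _compact_walk(n: int, rng: np.random.Generator, persistence: float = 0.7,
                  max_radius: float = 12.0) -> np.ndarray:
    """Self-avoiding Cα walk with directional persistence inside a sphere.

    Persistence elongates and bends the chain so each subunit has an
    irregular, orientation-discriminative shape (a featureless globule would
    fit a 10 Å density equally well in many orientations); the radius bound
    keeps it compact enough for a small map box.
    """
    coords = [np.zeros(3)]
    d_prev = rng.normal(size=3)
    d_prev /= np.linalg.norm(d_prev)
    for _ in range(1, n):
        cur = coords[-1]
        placed = False
        for _attempt in range(200):
            step = rng.normal(size=3) * 0.8 + d_prev * persistence
            step /= np.linalg.norm(step)
            cand = cur + step * _CA_STEP
            center = np.mean(coords, axis=0)
            if np.linalg.norm(cand - center) > max_radius:
                # turn back toward the interior
                inward = center - cur
                inward /= max(np.linalg.norm(inward), 1e-9)
                step = rng.normal(size=3) * 0.6 + inward
                step /= np.linalg.norm(step)
                cand = cur + step * _CA_STEP
                if np.linalg.norm(cand - center) > max_radius + 2.0:
                    continue
            prev = np.asarray(coords[:-1]) if len(coords) > 1 else None
            if prev is None or np.min(np.linalg.norm(prev - cand, axis=1)) >= _MIN_SELF_DIST:
                coords.append(cand)
                d_prev = step
                placed = True
                break
        if not placed:
            coords.append(cur + d_prev * _CA_STEP)
    return np.asarray(coords)


def _decorate_backbone(ca: np.ndarray, rng: np.random.Generator):
    """Place N, C, O pseudo-backbone atoms around each Cα."""
    n_res = len(ca)
    names, elements, res_ids, coords = [], [], [], []
    for i in range(n_res):
        d = ca[min(i + 1, n_res - 1)] - ca[max(i - 1, 0)]
        d = d / max(np.linalg.norm(d), 1e-9)
        perp = np.cross(d, rng.normal(size=3))
        perp = perp / max(np.linalg.norm(perp), 1e-9)
        perp2 = np.cross(d, perp)
        names += ["N", "CA", "C", "O"]
        elements += ["N", "C", "C", "O"]
        res_ids += [i + 1] * 4
        coords += [
            ca[i] - 1.46 * d + 0.3 * perp,
            ca[i],
            ca[i] + 1.53 * d + 0.3 * perp2,
            ca[i] + 1.53 * d + 0.3 * perp2 + 1.23 * perp,
        ]
    return names, elements, np.asarray(res_ids), np.asarray(coords)


def _build_subunit(chain_id: str, n_res: int, palette, rng) -> Subunit:
    ca = _compact_walk(n_res, rng)
    names, elements, res_ids, coords = _decorate_backbone(ca, rng)
    res_names = [palette[(i - 1) % len(palette)] for i in res_ids]
    return Subunit(chain_id, names, elements, res_names, res_ids, coords)


def make_toy_complex(
    n_subunits: int = 3,
    residues_per_subunit: int = 40,
    seed: int = 0,
    duplicate_chains: bool = False,
    max_retries: int = 40,
) -> list:
    """Build a packed toy complex of pseudo-protein subunits.

    Subunits are arranged in mutual contact (minimum inter-subunit heavy-atom
    distance inside the interaction cutoff) with zero steric clashes at the
    default clash cutoff.  Deterministic for a fixed seed.
    """
    if n_subunits < 2:
        raise ValueError("a complex needs at least 2 subunits")
    rng = np.random.default_rng(seed)
    chain_ids = [chr(ord("A") + i) for i in range(n_subunits)]
    subunits = []
    for i, cid in enumerate(chain_ids):
        if duplicate_chains and i == 1:
            # identical copy of chain A under a different label
            twin = subunits[0]
            subunits.append(Subunit(cid, twin.atom_names, twin.elements,
                                    twin.res_names, twin.res_ids, twin.coords.copy()))
            continue
        palette = _RES_PALETTES[i % len(_RES_PALETTES)]
        subunits.append(_build_subunit(cid, residues_per_subunit, palette, rng))

    placed = [subunits[0]]
    for s in subunits[1:]:
        assembly = np.vstack([p.coords for p in placed])
        a_center = assembly.mean(axis=0)
        s_centered = s.coords - s.coords.mean(axis=0)
        r_start = float(np.max(np.linalg.norm(assembly - a_center, axis=1))
                        + np.max(np.linalg.norm(s_centered, axis=1)) + 12.0)
        best = None  # (contacts, coords)
        for _attempt in range(max_retries):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            # slide inward from far away until docking contact, no clashes
            r = r_start
            cand = None
            while r > 0:
                trial = s_centered + a_center + direction * r
                dmin = _min_cross_distance(assembly, trial)
                if dmin < 3.4:
                    break
                if dmin <= 5.0:
                    cand = trial
                    break
                r -= 0.5
            if cand is None:
                continue
            contacts = _contact_count(assembly, cand, 6.0)
            if best is None or contacts > best[0]:
                best = (contacts, cand)
        if best is None:
            raise RuntimeError(
                "failed to pack toy complex without clashes; "
                "try fewer or smaller subunits or another seed"
            )
        placed.append(s.with_coords(best[1]))
    # construction keeps all cross distances above the clash cutoff
    return placed


def _min_cross_distance(a: np.ndarray, b: np.ndarray) -> float:
    from scipy.spatial import cKDTree

    d, _ = cKDTree(a).query(b, k=1)
    return float(np.min(d))


def _contact_count(a: np.ndarray, b: np.ndarray, cutoff: float) -> int:
    """Cross atom pairs within cutoff — a proxy for buried interface area."""
    from scipy.spatial import cKDTree

    return int(cKDTree(a).count_neighbors(cKDTree(b), cutoff))


def make_benchmark(
    complex_subunits: list,
    resolution: float = 10.0,
    voxel_size: float = 1.0,
    seed: int = 0,
    max_shift: float | None = None,
    map_padding: float = 8.0,
) -> ToyBenchmark:
    """Simulate the reference map and scramble each subunit independently.

    The defaults (10 Å resolution, 1.0 Å voxel) follow the simulated-map
    convention of the benchmark protocol.  ``planted[i]`` maps scrambled
    subunit i back onto the reference exactly.
    """
    atoms = [
        (e, xyz)
        for s in complex_subunits
        for e, xyz in zip(s.elements, s.coords)
    ]
    dmap = simulate_map(atoms, resolution=resolution, voxel_size=voxel_size,
                        padding=map_padding)
    if max_shift is None:
        box = np.asarray(dmap.dims) * dmap.voxel_size
        max_shift = float(np.linalg.norm(box)) / 2.0
    scrambled, planted = [], []
    for i, s in enumerate(complex_subunits):
        t_scramble = random_transform(np.random.SeedSequence([seed, i]), max_shift)
        scrambled.append(apply_transform(s, t_scramble))
        planted.append(t_scramble.inverse())
    return ToyBenchmark(reference=complex_subunits, scrambled=scrambled,
                        map=dmap, planted=planted, seed=seed,
                        resolution=resolution)


@dataclass
class PipelineConfig:
    """Every tunable of the fitting pipeline with its standard default."""

    map_kind: str = "simulated"
    resolution: float = 10.0
    contour_factor: float = 0.5
    recommended_level: float | None = None
    rotations: RotationSet | int | None = None
    weights: Weights = field(default_factory=Weights)
    top_k: int = 10
    overlap_cutoff: float = DEFAULT_OVERLAP_CUTOFF
    cluster_radius: float = DEFAULT_CLUSTER_RADIUS
    max_poses: int = DEFAULT_MAX_POSES
    clash_fraction: float = pair_scoring.DEFAULT_CLASH_FRACTION

    def rotation_set(self) -> RotationSet:
        if isinstance(self.rotations, RotationSet):
            return self.rotations
        if self.rotations is None:
            return rotation_set()
        return rotation_set(int(self.rotations))


@dataclass
class PipelineResult:
    """Everything the pipeline produced, richest first."""

    models: list
    placed: list
    pose_sets: list
    graph: MRFGraph
    evals: list | None = None


def run_pipeline(
    dmap: DensityMap,
    subunits: list,
    config: PipelineConfig | None = None,
    reference: list | None = None,
) -> PipelineResult:
    """Full fitting pipeline: pose search -> pair scoring -> MRF -> top-K.

    When a reference assembly is given, every emitted model is evaluated
    (permutation-aware RMSD + APS).  Stage progress and counts are logged.
    """
    cfg = config or PipelineConfig()
    rotations = cfg.rotation_set()
    level = cfg.recommended_level
    if level is None:
        level = suggest_contour_level(dmap)
    working_level = cfg.contour_factor * level
    contour = contour_mask(dmap, working_level)
    logger.info("working contour level %.4g (%d voxels occupied)",
                working_level, contour.count())

    pose_sets: list[PoseSet] = []
    for s in subunits:
        t0 = time.time()
        ps = search_subunit(
            dmap, contour, s, rotations,
            map_kind=cfg.map_kind, resolution=cfg.resolution,
            overlap_cutoff=cfg.overlap_cutoff,
            cluster_radius=cfg.cluster_radius, max_poses=cfg.max_poses,
        )
        logger.info("search %s: %d poses retained (%.1f s, %d rotations)",
                    s.id, len(ps), time.time() - t0, len(rotations))
        pose_sets.append(ps)

    t0 = time.time()
    graph = build_graph(pose_sets, subunits, cfg.weights)
    logger.info("pairwise scoring: %d edges (%.1f s)", len(graph.edges), time.time() - t0)

    beliefs = run_max_sum(graph)

    n_atoms = sum(s.n_atoms for s in subunits)

    def no_significant_clash(assignment) -> bool:
        total = sum(
            graph.clash_tables[(i, j)][assignment[i], assignment[j]]
            for (i, j) in graph.edges
        )
        return total <= cfg.clash_fraction * n_atoms

    t0 = time.time()
    models = extract_top_k(graph, beliefs, k=cfg.top_k, is_valid=no_significant_clash)
    logger.info("top-K extraction: %d models (%.1f s)", len(models), time.time() - t0)

    placed = []
    for m in models:
        placed.append([
            apply_transform(subunits[i], pose_sets[i][x].transform)
            for i, x in enumerate(m.assignment)
        ])
    evals = None
    if reference is not None:
        evals = [evaluate(chains, reference) for chains in placed]
    return PipelineResult(models=models, placed=placed, pose_sets=pose_sets,
                          graph=graph, evals=evals)
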