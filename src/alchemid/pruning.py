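"""Similarity scoring, filtering, combination and ranking of intermediates.

An intermediate is useful when it is more similar to *both* parents than the
parents are to each other, so every metric is computed against each parent
and the two scores are combined (sum, weighted sum or harmonic mean,
optionally after min-max normalization over the candidate pool).  The
harmonic mean 2ab/(a+b) penalizes imbalance: a candidate that resembles one
parent only scores poorly.

Metrics
-------
tanimoto
    Tanimoto coefficient over 2048-bit radius-2 circular fingerprints
    (ECFP4-equivalent).
lomap
    exp(-beta * (N_c + N_p - 2 * N_mcs)), the LOMAP-style exponential in the
    number of heavy atoms outside the common substructure.  The LOMAP
    rule-based penalty multipliers (ring-size, net charge, ...) are not
    applied; this is the MCS-distance term only.
shape_color
    Delegated to a registered 3D backend (shape + chemical-feature overlay
    similarity, e.g. ROCS).  A naive voxel-overlap fallback backend named
    ``"grid"`` ships for testing; it uses shape only and assumes the
    conformers are pre-aligned.
"""

from __future__ import annotations

import logging
import math
from collections import namedtuple
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from .core_identification import McsConfig, find_core
from .enumeration import IntermediateSet, RGroup
from .errors import BackendUnavailable, CoreTooSmall, EmptyAfterFilter, McsTimeout
from .records import MoleculeRecord

logger = logging.getLogger(__name__)

KNOWN_METRICS = ("tanimoto", "lomap", "shape_color")
KNOWN_COMBINERS = ("sum", "weighted_sum", "harmonic_mean")


@dataclass(frozen=True)
class PruneConfig:
    metrics: tuple[str, ...] = ("tanimoto", "lomap")
    combiner: str = "harmonic_mean"
    weights: tuple[float, float] = (0.5, 0.5)
    normalize: bool = False
    heavy_atom_min: Optional[int] = None
    heavy_atom_max: Optional[int] = None
    lomap_beta: float = 0.1
    shape_backend: Optional[str] = None

    def __post_init__(self) -> None:
        for m in self.metrics:
            if m not in KNOWN_METRICS:
                raise ValueError(f"unknown metric {m!r}")
        if self.combiner not in KNOWN_COMBINERS:
            raise ValueError(f"unknown combiner {self.combiner!r}")
        if any(w < 0 for w in self.weights) or not any(self.weights):
            raise ValueError("weights must be >= 0 and not both 0")
        if (
            self.heavy_atom_min is not None
            and self.heavy_atom_max is not None
            and self.heavy_atom_min > self.heavy_atom_max
        ):
            raise ValueError("heavy_atom_min must be <= heavy_atom_max")
        if self.lomap_beta <= 0:
            raise ValueError("lomap_beta must be positive")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

_FP_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def tanimoto_score(candidate: MoleculeRecord, parent: MoleculeRecord) -> float:
    """Tanimoto coefficient |F_c & F_p| / |F_c | F_p| over circular
    fingerprint bit sets; symmetric, in [0, 1]."""
    fa = _FP_GEN.GetFingerprint(candidate.mol)
    fb = _FP_GEN.GetFingerprint(parent.mol)
    return DataStructs.TanimotoSimilarity(fa, fb)


def lomap_score(
    candidate: MoleculeRecord,
    parent: MoleculeRecord,
    beta: float = 0.1,
    mcs_cfg: Optional[McsConfig] = None,
) -> float:
    """exp(-beta * (N_c + N_p - 2 * N_mcs)); 1.0 for MCS-identical molecules,
    monotonically decreasing in the number of non-common heavy atoms.
    Returns 0 with a warning when no common substructure is found."""
    try:
        core = find_core(candidate, parent, mcs_cfg)
    except (CoreTooSmall, McsTimeout) as exc:
        logger.warning(
            "lomap_score: no usable MCS for %s vs %s (%s); scoring 0",
            candidate.name,
            parent.name,
            exc,
        )
        return 0.0
    n_mcs = core.num_atoms
    dist = candidate.num_heavy_atoms + parent.num_heavy_atoms - 2 * n_mcs
    return math.exp(-beta * dist)


# --- shape/color plugin protocol -------------------------------------------

_SHAPE_BACKENDS: dict[str, Callable[[MoleculeRecord, MoleculeRecord], float]] = {}


def register_shape_backend(
    name: str, fn: Callable[[MoleculeRecord, MoleculeRecord], float]
) -> None:
    """Register a 3D similarity backend returning a score in [0, 1]."""
    _SHAPE_BACKENDS[name] = fn


def shape_color_score(
    candidate: MoleculeRecord, parent: MoleculeRecord, backend: str = "grid"
) -> float:
    """3D shape(+color) similarity via a registered backend plugin.

    Raises BackendUnavailable if the named backend is not registered."""
    if backend not in _SHAPE_BACKENDS:
        raise BackendUnavailable(
            f"shape backend {backend!r} not registered "
            f"(available: {sorted(_SHAPE_BACKENDS)})"
        )
    return float(_SHAPE_BACKENDS[backend](candidate, parent))


def grid_overlap_score(
    candidate: MoleculeRecord,
    parent: MoleculeRecord,
    voxel: float = 0.4,
    radius: float = 1.7,
) -> float:
    """Voxel-occupancy Tanimoto of two pre-aligned conformers.

    Heavy atoms are spheres of ``radius`` Å rasterized on a shared grid; the
    score is |V1 & V2| / |V1 | V2|.  Shape only, no chemical-feature color,
    no alignment search — a testing fallback, not a ROCS reproduction.
    """
    coords = []
    for rec in (candidate, parent):
        if not rec.has_coordinates:
            raise ValueError(f"{rec.name or 'molecule'} has no 3D coordinates")
        conf = rec.mol.GetConformer()
        xyz = np.array(
            [
                list(conf.GetAtomPosition(a.GetIdx()))
                for a in rec.mol.GetAtoms()
                if a.GetAtomicNum() > 1
            ]
        )
        coords.append(xyz)
    lo = np.minimum(coords[0].min(0), coords[1].min(0)) - radius - voxel
    hi = np.maximum(coords[0].max(0), coords[1].max(0)) + radius + voxel
    axes = [np.arange(lo[d], hi[d] + voxel, voxel) for d in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    masks = []
    for xyz in coords:
        occ = np.zeros(grid.shape[:3], dtype=bool)
        for p in xyz:
            occ |= ((grid - p) ** 2).sum(-1) <= radius**2
        masks.append(occ)
    union = (masks[0] | masks[1]).sum()
    if union == 0:
        return 0.0
    return float((masks[0] & masks[1]).sum() / union)


register_shape_backend("grid", grid_overlap_score)


# ---------------------------------------------------------------------------
# Filtering, combination, ranking
# ---------------------------------------------------------------------------


def heavy_atom_filter(
    candidate_rgroups: Sequence[RGroup],
    min_atoms: Optional[int] = None,
    max_atoms: Optional[int] = None,
) -> tuple[bool, str]:
    """Keep a candidate unless any of its R-groups has a heavy-atom count
    outside the configured bounds.  Returns (keep, reason)."""
    for rg in candidate_rgroups:
        n = rg.heavy_atom_count
        sites = ",".join(str(s) for s in sorted(rg.site_group))
        if min_atoms is not None and n < min_atoms:
            return False, f"R-group at site(s) {sites} has {n} heavy atoms < {min_atoms}"
        if max_atoms is not None and n > max_atoms:
            return False, f"R-group at site(s) {sites} has {n} heavy atoms > {max_atoms}"
    return True, ""


def combine_scores(s_a: float, s_b: float, cfg: PruneConfig) -> float:
    """Combine the two per-parent scores per the configured combiner."""
    if cfg.combiner == "sum":
        return s_a + s_b
    if cfg.combiner == "weighted_sum":
        w_a, w_b = cfg.weights
        return w_a * s_a + w_b * s_b
    # harmonic mean, defined as 0 at (0, 0)
    if s_a + s_b == 0:
        return 0.0
    return 2.0 * s_a * s_b / (s_a + s_b)


def harmonic_mean(s_a: float, s_b: float) -> float:
    if s_a + s_b == 0:
        return 0.0
    return 2.0 * s_a * s_b / (s_a + s_b)


def minmax_normalize(values: Sequence[float]) -> list[float]:
    """Map onto [0, 1]; a constant column maps to all zeros (it carries no
    ranking information and 0/0 is undefined)."""
    arr = np.asarray(values, dtype=float)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return [0.0] * len(arr)
    return list((arr - lo) / (hi - lo))


@dataclass
class ScoreTable:
    """Per-candidate, per-metric scores vs each parent, combined score and
    rank; filtered-out rows keep their reason and no rank."""

    pair_id: str
    df: pd.DataFrame
    primary_metric: str

    def to_csv(self, path) -> None:
        out = self.df.copy()
        out.insert(0, "pair_id", self.pair_id)
        out.to_csv(path, index=False)

    @property
    def ranked(self) -> pd.DataFrame:
        return self.df[~self.df["filtered_out"]].sort_values("rank")


def _metric_fn(metric: str, cfg: PruneConfig):
    if metric == "tanimoto":
        return tanimoto_score
    if metric == "lomap":
        return lambda c, p: lomap_score(c, p, beta=cfg.lomap_beta)
    if metric == "shape_color":
        backend = cfg.shape_backend or "grid"
        return lambda c, p: shape_color_score(c, p, backend=backend)
    raise ValueError(metric)


def rank_candidates(
    candidates: Sequence[MoleculeRecord],
    parent_a: MoleculeRecord,
    parent_b: MoleculeRecord,
    cfg: Optional[PruneConfig] = None,
    rgroups: Optional[Sequence[Sequence[RGroup]]] = None,
    pair_id: str = "pair",
) -> ScoreTable:
    """Score, filter, combine and rank a candidate pool against two parents.

    The heavy-atom filter runs first (only when per-candidate R-group
    provenance is available); each requested metric is computed vs both
    parents; optionally each metric's per-parent columns are min-max
    normalized over the surviving pool; the per-parent scores are combined;
    rows are ranked by the first listed metric's combined score (descending,
    ties broken by canonical form).  Other metrics are reported alongside.

    Raises EmptyAfterFilter when no candidate survives the filter.
    """
    cfg = cfg or PruneConfig()
    if not candidates:
        raise ValueError("candidate list is empty")

    rows: dict[str, list] = {
        "name": [c.name for c in candidates],
        "canonical_form": [c.canonical_form for c in candidates],
    }
    keep = [True] * len(candidates)
    reasons = [""] * len(candidates)
    if rgroups is not None and (
        cfg.heavy_atom_min is not None or cfg.heavy_atom_max is not None
    ):
        for i, rgs in enumerate(rgroups):
            keep[i], reasons[i] = heavy_atom_filter(
                rgs, cfg.heavy_atom_min, cfg.heavy_atom_max
            )
    if not any(keep):
        raise EmptyAfterFilter(
            f"all {len(candidates)} candidates removed by the heavy-atom filter"
        )
    rows["filtered_out"] = [not k for k in keep]
    rows["filter_reason"] = reasons

    metrics = []
    for metric in cfg.metrics:
        fn = _metric_fn(metric, cfg)
        try:
            s_a = [fn(c, parent_a) for c in candidates]
            s_b = [fn(c, parent_b) for c in candidates]
        except BackendUnavailable as exc:
            if cfg.shape_backend is None:
                logger.warning("metric %s skipped: %s", metric, exc)
                continue
            raise
        rows[f"{metric}_a"] = s_a
        rows[f"{metric}_b"] = s_b
        if cfg.normalize:
            kept_a = [v for v, k in zip(s_a, keep) if k]
            kept_b = [v for v, k in zip(s_b, keep) if k]
            norm_a = dict(zip([i for i, k in enumerate(keep) if k], minmax_normalize(kept_a)))
            norm_b = dict(zip([i for i, k in enumerate(keep) if k], minmax_normalize(kept_b)))
            s_a = [norm_a.get(i, float("nan")) for i in range(len(candidates))]
            s_b = [norm_b.get(i, float("nan")) for i in range(len(candidates))]
            rows[f"{metric}_a_norm"] = s_a
            rows[f"{metric}_b_norm"] = s_b
        rows[f"{metric}_combined"] = [
            combine_scores(a, b, cfg) if k else float("nan")
            for a, b, k in zip(s_a, s_b, keep)
        ]
        metrics.append(metric)
    if not metrics:
        raise ValueError("no usable metric (all skipped)")

    primary = metrics[0]
    df = pd.DataFrame(rows)
    kept_df = df[~df["filtered_out"]].sort_values(
        [f"{primary}_combined", "canonical_form"], ascending=[False, True]
    )
    df["rank"] = pd.Series(
        range(1, len(kept_df) + 1), index=kept_df.index, dtype="Int64"
    )
    return ScoreTable(pair_id=pair_id, df=df, primary_metric=primary)


def rank_intermediates(
    iset: IntermediateSet, cfg: Optional[PruneConfig] = None
) -> ScoreTable:
    """Rank the candidates of an :class:`IntermediateSet` (see
    :func:`rank_candidates`); R-group provenance enables the heavy-atom
    filter."""
    return rank_candidates(
        iset.candidates,
        iset.parent_a,
        iset.parent_b,
        cfg,
        rgroups=[iset.rgroups_of(c) for c in iset.candidates],
        pair_id=iset.pair_id,
    )


# ---------------------------------------------------------------------------
# Per-pair and series summaries
# ---------------------------------------------------------------------------

PairSummary = namedtuple("PairSummary", "parent_pair_score mean_hm max_hm")


def summarize_pair(
    iset: IntermediateSet, metric: str = "lomap", cfg: Optional[PruneConfig] = None
) -> PairSummary:
    """Per-pair similarity summary: the parent-parent score (baseline), and
    the mean and maximum over candidates of the harmonic mean of each
    candidate's similarity to both parents."""
    cfg = cfg or PruneConfig()
    fn = _metric_fn(metric, cfg)
    parent_score = fn(iset.parent_a, iset.parent_b)
    hms = [
        harmonic_mean(fn(c, iset.parent_a), fn(c, iset.parent_b))
        for c in iset.candidates
    ]
    if not hms:
        return PairSummary(parent_score, float("nan"), float("nan"))
    return PairSummary(parent_score, float(np.mean(hms)), float(np.max(hms)))


def summarize_series(summaries: Sequence[PairSummary]) -> dict[str, float]:
    """Average the per-pair summaries over a congeneric series: the mean
    parent-parent baseline and the means of the per-pair average and best
    harmonic-mean candidate scores."""
    valid = [s for s in summaries if not math.isnan(s.mean_hm)]
    return {
        "mean_parent_score": float(np.mean([s.parent_pair_score for s in summaries]))
        if summaries
        else float("nan"),
        "mean_of_mean_hm": float(np.mean([s.mean_hm for s in valid]))
        if valid
        else float("nan"),
        "mean_of_max_hm": float(np.mean([s.max_hm for s in valid]))
        if valid
        else float("nan"),
        "n_pairs": len(summaries),
        "n_pairs_with_candidates": len(valid),
    }
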