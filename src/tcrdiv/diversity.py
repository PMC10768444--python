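"""Rényi-entropy diversity profiles and down-sampled profile distances.

A repertoire is summarised by the curve of Rényi entropies

    H_alpha = log(sum_i p_i^alpha) / (1 - alpha)

over a grid of orders ``alpha`` (natural log throughout, so entropies are in
nats).  ``alpha = 0`` gives log richness, ``alpha -> 1`` the Shannon entropy and
large ``alpha`` approaches the Berger-Parker regime ``-log(max p)``, so the
profile captures both the number of clonotypes and the extent of clonal
expansion.  Because sequencing depth varies over orders of magnitude between
samples, two repertoires are only compared after randomly down-sampling the
deeper one (without replacement) to the depth of the shallower; the distance
between two samples is then the Euclidean norm of the difference of their
profiles over the grid.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "AlphaGrid",
    "DEFAULT_GRID",
    "WIDE_GRID",
    "ClonotypeVector",
    "DiversityProfile",
    "DistanceMatrix",
    "renyi_entropy",
    "diversity_profile",
    "downsample",
    "pair_distance",
    "distance_matrix",
    "combined_distance_matrix",
]

#: grid values within this distance of an integer special case are snapped
_ALPHA_SNAP = 1e-9


@dataclass(frozen=True)
class AlphaGrid:
    """Ordered grid of Rényi orders, endpoints included.

    The default ``[0, 10]`` with step 0.2 (51 points) is the profile grid used
    for the main analysis; ``[0, 20]`` with step 0.1 (201 points) is the wider
    variant used to probe sensitivity of the distance matrix to the grid.
    """

    alpha_min: float = 0.0
    alpha_max: float = 10.0
    step: float = 0.2

    def __post_init__(self) -> None:
        if not (0 <= self.alpha_min < self.alpha_max):
            raise ValueError("require 0 <= alpha_min < alpha_max")
        if self.step <= 0:
            raise ValueError("step must be positive")

    @property
    def values(self) -> np.ndarray:
        n = int(round((self.alpha_max - self.alpha_min) / self.step)) + 1
        vals = self.alpha_min + self.step * np.arange(n)
        # include the right endpoint even if the step does not divide the range
        if vals[-1] < self.alpha_max - _ALPHA_SNAP:
            vals = np.append(vals, self.alpha_max)
        return vals

    def __len__(self) -> int:
        return len(self.values)


DEFAULT_GRID = AlphaGrid(0.0, 10.0, 0.2)
WIDE_GRID = AlphaGrid(0.0, 20.0, 0.1)


@dataclass
class ClonotypeVector:
    """Vector of clonotype counts for one sample (order is irrelevant)."""

    sample_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if len(self.counts) and self.counts.min() < 1:
            raise ValueError("clonotype counts must be >= 1")

    @property
    def depth(self) -> int:
        return int(self.counts.sum())

    @property
    def richness(self) -> int:
        return len(self.counts)


@dataclass
class DiversityProfile:
    sample_id: str
    grid: AlphaGrid
    entropies: np.ndarray


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(sample_ids=[str(s) for s in df.index], values=df.to_numpy(float))

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)], dict(self.metadata))


def _as_counts(counts) -> np.ndarray:
    if isinstance(counts, ClonotypeVector):
        return counts.counts
    arr = np.asarray(counts, dtype=np.int64)
    if arr.ndim != 1:
        raise ValueError("counts must be one-dimensional")
    return arr


def _profile_from_counts(counts: np.ndarray, alphas: np.ndarray) -> np.ndarray:
    # collapse to (unique count value, multiplicity) -- repertoires are mostly
    # singletons, so this makes the power sums cheap even at depth 1e5
    if counts.size == 0 or counts.sum() < 1:
        raise ValueError("entropy is undefined for an empty clonotype vector")
    vals, mult = np.unique(counts, return_counts=True)
    depth = float(np.dot(vals, mult))
    logp = np.log(vals) - np.log(depth)
    richness = float(mult.sum())
    shannon = -float(np.dot(mult, np.exp(logp) * logp))

    is_zero = np.abs(alphas) < _ALPHA_SNAP
    is_one = np.abs(alphas - 1.0) < _ALPHA_SNAP
    generic = ~(is_zero | is_one)
    out = np.empty(len(alphas), dtype=float)
    out[is_zero] = np.log(richness)
    out[is_one] = shannon
    if generic.any():
        a = alphas[generic]
        # shift by the dominant term so large orders stay in range
        lmax = logp.max()
        power_sums = np.exp(a[:, None] * (logp[None, :] - lmax)) @ mult
        out[generic] = (a * lmax + np.log(power_sums)) / (1.0 - a)
    return out


def renyi_entropy(counts, alpha: float) -> float:
    """Rényi entropy of order ``alpha`` (nats) of a clonotype count vector.

    ``alpha = 0`` returns log richness and ``alpha = 1`` the Shannon entropy
    (computed directly, not as a numerical limit).
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    return float(_profile_from_counts(_as_counts(counts), np.array([alpha]))[0])


def diversity_profile(counts, grid: AlphaGrid = DEFAULT_GRID) -> DiversityProfile:
    """Evaluate the Rényi entropy on every grid point."""
    sample_id = counts.sample_id if isinstance(counts, ClonotypeVector) else ""
    ent = _profile_from_counts(_as_counts(counts), grid.values)
    return DiversityProfile(sample_id=sample_id, grid=grid, entropies=ent)


def downsample(counts, target_depth: int, rng) -> ClonotypeVector:
    """Draw ``target_depth`` rearrangements without replacement.

    Multivariate-hypergeometric draw on the count vector; clonotypes that drop
    to zero are removed.  ``rng`` is an int seed or ``numpy.random.Generator``.
    """
    vec = counts if isinstance(counts, ClonotypeVector) else ClonotypeVector("", counts)
    if target_depth <= 0:
        raise ValueError("target_depth must be positive")
    if target_depth > vec.depth:
        raise ValueError("target_depth exceeds sample depth")
    if target_depth == vec.depth:
        return ClonotypeVector(vec.sample_id, vec.counts.copy())
    rng = np.random.default_rng(rng)
    drawn = rng.multivariate_hypergeometric(vec.counts, target_depth)
    return ClonotypeVector(vec.sample_id, drawn[drawn > 0])


def _pair_seed(master_seed: int, id_a: str, id_b: str) -> np.random.SeedSequence:
    """Reproducible, order-independent per-pair seed."""
    lo, hi = sorted((str(id_a), str(id_b)))
    return np.random.SeedSequence(
        [int(master_seed) & 0xFFFFFFFF, zlib.crc32(lo.encode()), zlib.crc32(hi.encode())]
    )


def _pair_profiles(
    a: ClonotypeVector, b: ClonotypeVector, alphas: np.ndarray, rng
) -> tuple[np.ndarray, np.ndarray]:
    """Profiles of a pair after down-sampling the deeper member to the
    shallower depth; the shallower member is used as-is."""
    if a.depth == b.depth:
        pa, pb = a, b
    elif a.depth > b.depth:
        pa, pb = downsample(a, b.depth, rng), b
    else:
        pa, pb = a, downsample(b, a.depth, rng)
    return (
        _profile_from_counts(pa.counts, alphas),
        _profile_from_counts(pb.counts, alphas),
    )


def pair_distance(
    a: ClonotypeVector,
    b: ClonotypeVector,
    grid: AlphaGrid = DEFAULT_GRID,
    seed: int = 0,
    n_replicates: int = 1,
) -> float:
    """Euclidean distance between the diversity profiles of two samples.

    The deeper sample is randomly down-sampled to the shallower depth before
    profiling.  With ``n_replicates > 1`` the distance is averaged over
    independent down-sampling draws.  The RNG is seeded from ``seed`` and the
    unordered pair of sample ids, so the distance is symmetric.
    """
    rng = np.random.default_rng(_pair_seed(seed, a.sample_id, b.sample_id))
    alphas = grid.values
    acc = 0.0
    for _ in range(max(1, n_replicates)):
        pa, pb = _pair_profiles(a, b, alphas, rng)
        acc += float(np.linalg.norm(pa - pb))
    return acc / max(1, n_replicates)


def distance_matrix(
    samples: Sequence[ClonotypeVector],
    grid: AlphaGrid = DEFAULT_GRID,
    seed: int = 0,
    n_replicates: int = 1,
) -> DistanceMatrix:
    """Symmetric matrix of pairwise down-sampled profile distances."""
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids")
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    n = len(samples)
    mat = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d = pair_distance(samples[i], samples[j], grid, seed, n_replicates)
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(
        ids,
        mat,
        metadata={
            "alpha_min": grid.alpha_min,
            "alpha_max": grid.alpha_max,
            "alpha_step": grid.step,
            "seed": seed,
            "n_replicates": n_replicates,
            "downsampling": "hypergeometric, deeper member per pair",
        },
    )


def combined_distance_matrix(
    per_chain: Mapping[str, Sequence[ClonotypeVector]],
    grid: AlphaGrid = DEFAULT_GRID,
    seed: int = 0,
    n_replicates: int = 1,
) -> DistanceMatrix:
    """Distance over all chains considered together.

    Per-chain profiles of a pair (with per-chain down-sampling) are
    concatenated before taking the Euclidean norm, i.e. the combined distance
    is the root of the summed squared per-chain distances.  Every chain must
    provide a vector for every sample.
    """
    chains = sorted(per_chain)
    if not chains:
        raise ValueError("no chains given")
    by_chain = {c: {v.sample_id: v for v in per_chain[c]} for c in chains}
    ids = sorted(by_chain[chains[0]])
    for c in chains:
        if sorted(by_chain[c]) != ids:
            raise ValueError(f"chain {c!r} does not cover the same samples")
    sq = np.zeros((len(ids), len(ids)), dtype=float)
    for c in chains:
        sub = distance_matrix([by_chain[c][s] for s in ids], grid, seed, n_replicates)
        sq += sub.values**2
    return DistanceMatrix(
        ids,
        np.sqrt(sq),
        metadata={
            "chains": chains,
            "alpha_min": grid.alpha_min,
            "alpha_max": grid.alpha_max,
            "alpha_step": grid.step,
            "seed": seed,
            "combination": "profile concatenation (root of summed squares)",
        },
    )


def profiles_frame(samples: Iterable[ClonotypeVector], grid: AlphaGrid = DEFAULT_GRID) -> pd.DataFrame:
    """Sample-by-alpha table of entropies (for TSV export)."""
    rows = {}
    for s in samples:
        rows[s.sample_id] = _profile_from_counts(s.counts, grid.values)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=[f"{a:g}" for a in grid.values])
    df.index.name = "sample_id"
    return df
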