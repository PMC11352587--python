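"""Constrained maximum-entropy sketch extraction.

An early-vision compression model: the visual front end is assumed to match
local 3x3 binary patterns against a small dictionary of features, to store at
most ``N`` distinct features (limited capacity), and to transmit at most a
fraction ``W`` of the input locations (fixed output bandwidth).  Under these
constraints the dictionary that transmits the most information is the set of
patterns maximizing the total Shannon entropy

    H(S) = sum_{i in S} p_i * log2(1 / p_i)

subject to ``|S| <= N`` and ``sum_{i in S} p_i <= W``, where ``p_i`` is the
probability of pattern ``i`` in an ensemble of binarized images.  A *sketch*
of an image keeps only the pixels whose local 3x3 pattern belongs to the
selected feature set and blanks everything else.

Pattern codes are integers in ``[0, 511]`` encoding a 3x3 binary patch in
row-major order with the top-left pixel as the most significant bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

N_PATTERNS = 512

#: Sketch pixel states.
BACKGROUND = -1
BLACK = 0
WHITE = 1

# Row-major, top-left = MSB.
_BIT_WEIGHTS = (1 << np.arange(8, -1, -1, dtype=np.int64)).reshape(3, 3)

__all__ = [
    "N_PATTERNS",
    "BACKGROUND",
    "BLACK",
    "WHITE",
    "BinaryImage",
    "PatchDistribution",
    "FeatureSet",
    "Sketch",
    "pattern_to_code",
    "code_to_pattern",
    "load_gray_image",
    "binarize",
    "extract_patch_distribution",
    "entropy_contribution",
    "select_features_greedy",
    "select_features_exact",
    "generate_sketch",
    "sketch_density",
    "save_sketch_png",
]


def pattern_to_code(patch: np.ndarray) -> int:
    """Encode a 3x3 binary patch as an integer in [0, 511]."""
    patch = np.asarray(patch)
    if patch.shape != (3, 3):
        raise ValueError(f"patch must be 3x3, got shape {patch.shape}")
    if not np.isin(patch, (0, 1)).all():
        raise ValueError("patch values must be 0 or 1")
    return int((patch.astype(np.int64) * _BIT_WEIGHTS).sum())


def code_to_pattern(code: int) -> np.ndarray:
    """Decode an integer in [0, 511] into a 3x3 binary patch (uint8)."""
    code = int(code)
    if not 0 <= code < N_PATTERNS:
        raise ValueError(f"code must be in [0, {N_PATTERNS - 1}], got {code}")
    bits = (code >> np.arange(8, -1, -1)) & 1
    return bits.reshape(3, 3).astype(np.uint8)


@dataclass(frozen=True)
class BinaryImage:
    """A {0,1}-valued image with a record of how it was binarized."""

    pixels: np.ndarray
    provenance: str = "unknown"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not np.isin(px, (0, 1)).all():
            raise ValueError("BinaryImage pixels must be 0 or 1")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def load_gray_image(path: str | Path) -> np.ndarray:
    """Read a PNG/PGM image as an 8-bit grayscale array (RGB is averaged)."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=2)
    return np.clip(np.round(arr), 0, 255).astype(np.uint8)


def binarize(
    img: np.ndarray, method: str = "median", threshold: float | None = None
) -> BinaryImage:
    """Convert an 8-bit grayscale image to 1-bit black/white.

    ``method="median"`` thresholds at the per-image median (balanced
    black/white mass); ``method="fixed"`` uses the supplied ``threshold``.
    A pixel >= threshold maps to white (1).
    """
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    if method == "median":
        thr = float(np.median(arr))
        tag = "median"
    elif method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold")
        thr = float(threshold)
        tag = f"fixed({thr:g})"
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    return BinaryImage((arr >= thr).astype(np.uint8), provenance=tag)


def _pixels(img: BinaryImage | np.ndarray) -> np.ndarray:
    px = img.pixels if isinstance(img, BinaryImage) else np.asarray(img)
    if px.ndim != 2:
        raise ValueError("expected a 2-D binary image")
    if px.shape[0] < 3 or px.shape[1] < 3:
        raise ValueError("image must be at least 3x3 for patch extraction")
    return px.astype(np.int64)


def _window_codes(px: np.ndarray) -> np.ndarray:
    """Pattern code of the 3x3 neighborhood of every valid (interior) center."""
    win = np.lib.stride_tricks.sliding_window_view(px, (3, 3))
    return np.tensordot(win, _BIT_WEIGHTS, axes=([2, 3], [0, 1]))


@dataclass(frozen=True)
class PatchDistribution:
    """Empirical distribution of the 512 possible 3x3 binary patterns.

    One count per valid patch center (centers with a complete 3x3
    neighborhood), summed over the input images; overlapping patches all
    count.
    """

    counts: np.ndarray  # shape (512,), non-negative ints
    total: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (N_PATTERNS,) or (counts < 0).any():
            raise ValueError("counts must be a non-negative array of length 512")
        if int(counts.sum()) != int(self.total) or self.total <= 0:
            raise ValueError("total must equal the (positive) sum of counts")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "total", int(self.total))

    @property
    def probs(self) -> np.ndarray:
        return self.counts / self.total

    def prob(self, code: int) -> float:
        return float(self.counts[code]) / self.total

    def to_json(self, path: str | Path) -> None:
        nz = np.nonzero(self.counts)[0]
        payload = {
            "total": self.total,
            "counts": {str(int(c)): int(self.counts[c]) for c in nz},
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PatchDistribution":
        payload = json.loads(Path(path).read_text())
        counts = np.zeros(N_PATTERNS, dtype=np.int64)
        for code, cnt in payload["counts"].items():
            counts[int(code)] = int(cnt)
        return cls(counts=counts, total=payload["total"])


def extract_patch_distribution(
    imgs: Iterable[BinaryImage | np.ndarray],
) -> PatchDistribution:
    """Histogram all overlapping 3x3 patches over an ensemble of binary images."""
    counts = np.zeros(N_PATTERNS, dtype=np.int64)
    n_imgs = 0
    for img in imgs:
        px = _pixels(img)
        codes = _window_codes(px).ravel()
        counts += np.bincount(codes, minlength=N_PATTERNS)
        n_imgs += 1
    if n_imgs == 0:
        raise ValueError("at least one image is required")
    return PatchDistribution(counts=counts, total=int(counts.sum()))


def entropy_contribution(p):
    """Shannon entropy contribution p*log2(1/p) in bits; 0 at p=0 and p=1."""
    arr = np.asarray(p, dtype=float)
    if (arr < 0).any() or (arr > 1).any():
        raise ValueError("probability must lie in [0, 1]")
    out = np.zeros_like(arr)
    pos = arr > 0
    out[pos] = -arr[pos] * np.log2(arr[pos])
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


@dataclass(frozen=True)
class FeatureSet:
    """The selected *optimal* patterns with their achieved budget usage.

    ``N`` is the feature-count capacity, ``W`` the total-probability
    (bandwidth) cap; ``entropy_bits`` is the objective achieved.
    """

    codes: tuple[int, ...]
    probs: tuple[float, ...]
    N: int
    W: float
    total_prob: float = field(default=0.0)
    entropy_bits: float = field(default=0.0)

    def __post_init__(self) -> None:
        if len(self.codes) != len(set(self.codes)):
            raise ValueError("duplicate patterns in FeatureSet")
        if len(self.codes) > self.N:
            raise ValueError("more patterns than the capacity N")
        if self.total_prob > self.W + 1e-12:
            raise ValueError("total probability exceeds the bandwidth W")

    def __len__(self) -> int:
        return len(self.codes)

    def __contains__(self, code: int) -> bool:
        return int(code) in set(self.codes)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "codes": list(map(int, self.codes)),
            "probs": list(map(float, self.probs)),
            "N": int(self.N),
            "W": float(self.W),
            "total_prob": float(self.total_prob),
            "entropy_bits": float(self.entropy_bits),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureSet":
        d = json.loads(Path(path).read_text())
        return cls(
            codes=tuple(d["codes"]),
            probs=tuple(d["probs"]),
            N=d["N"],
            W=d["W"],
            total_prob=d["total_prob"],
            entropy_bits=d["entropy_bits"],
        )


_W_TOL = 1e-12


def _codes_probs(
    dist: PatchDistribution | Mapping[int, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Support (codes, probs) of a distribution, restricted to p > 0."""
    if isinstance(dist, PatchDistribution):
        codes = np.nonzero(dist.counts)[0]
        probs = dist.counts[codes] / dist.total
    else:
        if len(dist) == 0:
            raise ValueError("empty distribution")
        codes = np.array(sorted(dist), dtype=np.int64)
        probs = np.array([float(dist[int(c)]) for c in codes])
        if (probs < 0).any():
            raise ValueError("probabilities must be non-negative")
        s = probs.sum()
        if s <= 0:
            raise ValueError("distribution has no mass")
        probs = probs / s
        codes = codes[probs > 0]
        probs = probs[probs > 0]
    if codes.size == 0:
        raise ValueError("empty distribution")
    return codes, probs


def _build(codes, probs, chosen_idx, N, W) -> FeatureSet:
    order = sorted(
        chosen_idx, key=lambda i: (-entropy_contribution(probs[i]), codes[i])
    )
    sel_codes = tuple(int(codes[i]) for i in order)
    sel_probs = tuple(float(probs[i]) for i in order)
    return FeatureSet(
        codes=sel_codes,
        probs=sel_probs,
        N=int(N),
        W=float(W),
        total_prob=float(sum(sel_probs)),
        entropy_bits=float(sum(entropy_contribution(p) for p in sel_probs)),
    )


def select_features_greedy(
    dist: PatchDistribution | Mapping[int, float],
    N: int,
    W: float,
    refine: bool = True,
) -> FeatureSet:
    """Greedy constrained maximum-entropy feature selection.

    Candidates (patterns with p > 0) are sorted by descending entropy
    contribution, ties broken by ascending pattern code, and scanned in
    order; a pattern is kept iff it fits the remaining bandwidth, stopping
    at capacity ``N``.  With ``refine=True`` (default) the greedy set is
    polished by exchange local search (1-out/1-in and 1-out/2-in moves with
    greedy refill, repeated to a fixed point), which removes the
    knapsack-style pathologies of the plain value-ordered scan (a heavy
    high-value pattern crowding out several lighter ones).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if not 0 < W <= 1:
        raise ValueError("W must be in (0, 1]")
    codes, probs = _codes_probs(dist)
    contrib = entropy_contribution(probs)
    order = np.lexsort((codes, -contrib))  # contribution desc, code asc

    chosen = _greedy_scan(order, probs, N, W)

    if refine:
        # The value-ordered scan can lock high-probability patterns into the
        # bandwidth budget and crowd out several lighter patterns of greater
        # joint entropy.  Restart the scan under exclusions (every subset of
        # the heaviest feasible candidates, and every heavy prefix), then
        # polish the best restarts with destroy-and-repair local search.
        candidates = [chosen]
        fits = sorted(
            (i for i in range(probs.size) if probs[i] <= W + _W_TOL),
            key=lambda i: -probs[i],
        )
        heavy = fits[:_EXCLUDE_POOL]
        for mask in range(1, 1 << len(heavy)):
            banned = {heavy[b] for b in range(len(heavy)) if (mask >> b) & 1}
            candidates.append(_greedy_scan(order, probs, N, W, banned))
        for h in range(1, len(fits)):
            candidates.append(_greedy_scan(order, probs, N, W, set(fits[:h])))
        candidates.sort(key=lambda c: -contrib[c].sum() if c else 0.0)
        seen, best, best_ent = set(), chosen, -1.0
        for cand in candidates[: 10 * _POLISH_TOP]:
            key = frozenset(cand)
            if key in seen:
                continue
            seen.add(key)
            if len(seen) > _POLISH_TOP:
                break
            polished = _local_search(set(cand), order, probs, contrib, N, W)
            ent = contrib[polished].sum() if polished else 0.0
            if ent > best_ent:
                best, best_ent = polished, ent
        chosen = best

    return _build(codes, probs, chosen, N, W)


def _greedy_scan(order, probs, N, W, banned=frozenset()) -> list[int]:
    chosen: list[int] = []
    total = 0.0
    for i in order:
        if len(chosen) >= N:
            break
        if i in banned:
            continue
        if total + probs[i] <= W + _W_TOL:
            chosen.append(int(i))
            total += probs[i]
    return chosen


_EXCLUDE_POOL = 10  # heaviest feasible candidates subject to exclusion restarts
_POLISH_TOP = 8  # distinct restart results polished by local search


_REFINE_POOL = 64  # outsiders considered per exchange move


def _local_search(chosen_set, order, probs, contrib, N, W):
    """Destroy-and-repair: drop 1 or 2 selected patterns (banned from
    immediate re-entry), greedily refill, accept strict entropy gains."""

    def refill(sel, banned=frozenset()):
        total = float(probs[list(sel)].sum()) if sel else 0.0
        for i in order:
            if len(sel) >= N:
                break
            if i in sel or i in banned:
                continue
            if total + probs[i] <= W + _W_TOL:
                sel.add(int(i))
                total += probs[i]
        return sel

    def entropy(sel):
        return float(contrib[list(sel)].sum()) if sel else 0.0

    current = refill(set(chosen_set))
    best_ent = entropy(current)
    improved = True
    while improved:
        improved = False
        members = sorted(current)
        removals = [(i,) for i in members]
        removals += [
            (a, b) for ai, a in enumerate(members) for b in members[ai + 1:]
        ]
        for out in removals:
            trial = refill(current - set(out), banned=set(out))
            ent = entropy(trial)
            if ent > best_ent + 1e-15:
                current, best_ent = trial, ent
                improved = True
                break
    return sorted(current)


def select_features_exact(
    dist: PatchDistribution | Mapping[int, float], N: int, W: float
) -> FeatureSet:
    """Exhaustive constrained maximum-entropy selection (small alphabets).

    Enumerates every subset of the support, keeps those with ``|S| <= N``
    and total probability ``<= W``, and returns the entropy maximizer; ties
    resolve to the lexicographically smallest code set.  Refuses alphabets
    larger than 20 patterns.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if not 0 < W <= 1:
        raise ValueError("W must be in (0, 1]")
    codes, probs = _codes_probs(dist)
    m = codes.size
    if m > 20:
        raise ValueError(f"exact solver limited to <= 20 patterns, got {m}")

    masks = np.arange(1 << m, dtype=np.uint32)
    bits = ((masks[:, None] >> np.arange(m)) & 1).astype(np.float64)
    sizes = bits.sum(axis=1)
    tot = bits @ probs
    ent = bits @ entropy_contribution(probs)
    feasible = (sizes <= N) & (tot <= W + _W_TOL)
    ent = np.where(feasible, ent, -np.inf)
    best = ent.max()
    tie_mask = ent >= best - max(1e-12, 1e-12 * abs(best))
    candidates = np.nonzero(tie_mask)[0]
    key = None
    best_mask = None
    for mask in candidates:
        subset = tuple(
            sorted(int(codes[b]) for b in range(m) if (int(mask) >> b) & 1)
        )
        if key is None or subset < key:
            key, best_mask = subset, int(mask)
    chosen = [b for b in range(m) if (best_mask >> b) & 1]
    return _build(codes, probs, chosen, N, W)


@dataclass(frozen=True)
class Sketch:
    """Three-state rendering: black/white pixels kept, the rest background.

    The border ring (pixels without a full 3x3 neighborhood) is always
    background.
    """

    pixels: np.ndarray  # int8, values in {BACKGROUND, BLACK, WHITE}

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.int8)
        if not np.isin(px, (BACKGROUND, BLACK, WHITE)).all():
            raise ValueError("sketch pixels must be -1 (background), 0 or 1")
        object.__setattr__(self, "pixels", px)

    @property
    def retained_count(self) -> int:
        return int((self.pixels != BACKGROUND).sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def generate_sketch(img: BinaryImage | np.ndarray, features: FeatureSet) -> Sketch:
    """Keep every pixel whose 3x3 neighborhood matches a selected feature."""
    px = _pixels(img)
    out = np.full(px.shape, BACKGROUND, dtype=np.int8)
    codes = _window_codes(px)
    if len(features):
        keep = np.isin(codes, np.array(features.codes, dtype=np.int64))
        interior = px[1:-1, 1:-1]
        out[1:-1, 1:-1] = np.where(keep, interior.astype(np.int8), BACKGROUND)
    return Sketch(out)


def sketch_density(s: Sketch) -> float:
    """Retained pixels per valid patch center (the realized bandwidth)."""
    h, w = s.shape
    centers = (h - 2) * (w - 2)
    if centers <= 0:
        raise ValueError("sketch has no valid patch centers")
    return s.retained_count / centers


def save_sketch_png(s: Sketch, path: str | Path) -> None:
    """Write a sketch as 8-bit PNG: background=127, black=0, white=255."""
    import imageio.v3 as iio

    img = np.full(s.shape, 127, dtype=np.uint8)
    img[s.pixels == BLACK] = 0
    img[s.pixels == WHITE] = 255
    iio.imwrite(Path(path), img)
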