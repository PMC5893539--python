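"""Pairwise gene distances in index space, stratified by functional
similarity.

Genes acting in the same pathway tend to share a regulatory regime, so
their (stability index, translation index) coordinates should lie closer
together than those of unrelated genes.  This module bins gene pairs by an
externally supplied similarity score (GO-fingerprint similarity, or
protein-interaction confidence) and compares the Euclidean distance
distributions of each stratum against an unrelated-pair background with a
one-sided Mann-Whitney rank-sum test (distance distributions are
right-skewed, so a location t-test would be poorly calibrated).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

BACKGROUND_LABEL = "background"


def read_pair_scores(path) -> pd.DataFrame:
    """Read a pair-score TSV (gene_a, gene_b, score)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str}, comment="#")
    if not {"gene_a", "gene_b", "score"}.issubset(df.columns):
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["gene_a", "gene_b", "score"], dtype={0: str, 1: str})
    return validate_pairs(df)


def validate_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Check the pair-table invariants: no self pairs, unordered pairs unique."""
    if (pairs["gene_a"] == pairs["gene_b"]).any():
        raise ValueError("self-pairs are not allowed")
    if not np.isfinite(pairs["score"].to_numpy(float)).all():
        raise ValueError("pair scores must be finite")
    key = pairs.apply(lambda r: tuple(sorted((r["gene_a"], r["gene_b"]))), axis=1)
    if key.duplicated().any():
        raise ValueError("duplicate unordered pairs in score table")
    return pairs


def pair_distance(table: pd.DataFrame, gene_a: str, gene_b: str) -> float:
    """Euclidean distance between two genes' index-plane coordinates."""
    for g in (gene_a, gene_b):
        if g not in table.index:
            raise KeyError(f"gene {g!r} not in index table")
    a = table.loc[gene_a, ["stability_index", "translation_index"]].to_numpy(float)
    b = table.loc[gene_b, ["stability_index", "translation_index"]].to_numpy(float)
    return float(np.hypot(*(a - b)))


@dataclass
class Stratum:
    label: str
    distances: np.ndarray

    @property
    def n(self) -> int:
        return self.distances.size

    @property
    def median(self) -> float:
        return float(np.median(self.distances)) if self.n else float("nan")


def _distances(coords: np.ndarray, ia: np.ndarray, ib: np.ndarray) -> np.ndarray:
    d = coords[ia] - coords[ib]
    return np.hypot(d[:, 0], d[:, 1])


def stratify(table: pd.DataFrame, pairs: pd.DataFrame, score_bins,
             max_background_pairs: int = 1_000_000, seed: int = 0,
             exact_threshold: int = 200) -> list[Stratum]:
    """Distance distributions per similarity-score stratum plus a background.

    ``score_bins`` is an increasing edge sequence; bin i collects pairs with
    ``edges[i] <= score < edges[i+1]`` (the last bin closed on the right).
    The background stratum holds pairs of index-table genes that are absent
    from ``pairs`` (or score below the lowest edge): enumerated exactly when
    the gene count is at most ``exact_threshold``, otherwise estimated from
    a seeded random subsample of at most ``max_background_pairs`` pairs.
    Empty strata are retained (with a warning) so bin bookkeeping stays
    aligned with the requested edges.
    """
    edges = np.asarray(score_bins, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("score_bins must be a strictly increasing 1-D sequence")

    genes = table.index
    pos = pd.Series(np.arange(len(genes)), index=genes)
    coords = table[["stability_index", "translation_index"]].to_numpy(float)

    known = pairs[pairs["gene_a"].isin(pos.index) & pairs["gene_b"].isin(pos.index)]
    n_dropped = len(pairs) - len(known)
    if n_dropped:
        logger.info("stratify: dropped %d pairs with genes absent from the index table",
                    n_dropped)
    ia = pos[known["gene_a"]].to_numpy()
    ib = pos[known["gene_b"]].to_numpy()
    scores = known["score"].to_numpy(float)

    strata: list[Stratum] = []
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        last = i == len(edges) - 2
        in_bin = (scores >= lo) & ((scores <= hi) if last else (scores < hi))
        label = f"score[{lo:g},{hi:g}{']' if last else ')'}"
        if not in_bin.any():
            logger.warning("stratum %s is empty", label)
            strata.append(Stratum(label=label, distances=np.empty(0)))
            continue
        strata.append(Stratum(label=label, distances=_distances(coords, ia[in_bin], ib[in_bin])))

    listed = set(zip(np.minimum(ia, ib).tolist(), np.maximum(ia, ib).tolist()))
    n = len(genes)
    if n <= exact_threshold:
        iu, ju = np.triu_indices(n, k=1)
        mask = np.array([(i, j) not in listed for i, j in zip(iu.tolist(), ju.tolist())])
        bg = _distances(coords, iu[mask], ju[mask])
    else:
        rng = np.random.default_rng(seed)
        n_target = min(max_background_pairs, n * (n - 1) // 2)
        samples: list[np.ndarray] = []
        got = 0
        while got < n_target:
            m = int(1.2 * (n_target - got)) + 16
            i = rng.integers(0, n, size=m)
            j = rng.integers(0, n, size=m)
            lo_, hi_ = np.minimum(i, j), np.maximum(i, j)
            ok = lo_ != hi_
            lo_, hi_ = lo_[ok], hi_[ok]
            if listed:
                keep = np.array([(a, b) not in listed for a, b in zip(lo_.tolist(), hi_.tolist())])
                lo_, hi_ = lo_[keep], hi_[keep]
            samples.append(_distances(coords, lo_, hi_))
            got += lo_.size
        bg = np.concatenate(samples)[:n_target]
    strata.append(Stratum(label=BACKGROUND_LABEL, distances=bg))
    return strata


def stratum_shift_test(strata: list[Stratum],
                       background_label: str = BACKGROUND_LABEL) -> pd.DataFrame:
    """One-sided Mann-Whitney test of each stratum against the background.

    The alternative is "stratum distances are stochastically smaller" —
    functionally similar genes sit closer in the index plane.
    """
    bg = next((s for s in strata if s.label == background_label), None)
    if bg is None or bg.n == 0:
        raise ValueError("background stratum missing or empty")
    rows = []
    for s in strata:
        if s.label == background_label:
            continue
        if s.n == 0:
            p = float("nan")
        else:
            p = float(stats.mannwhitneyu(s.distances, bg.distances,
                                         alternative="less").pvalue)
        rows.append({"stratum": s.label, "n": s.n, "median": s.median, "p_value": p})
    rows.append({"stratum": bg.label, "n": bg.n, "median": bg.median,
                 "p_value": float("nan")})
    return pd.DataFrame(rows)


def strata_histograms(strata: list[Stratum], bin_width: float = 0.25) -> pd.DataFrame:
    """Normalised per-stratum distance histograms on a shared grid."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    hi = max((s.distances.max() for s in strata if s.n), default=1.0)
    edges = np.arange(0.0, hi + bin_width, bin_width)
    rows = []
    for s in strata:
        counts, _ = np.histogram(s.distances, bins=edges)
        dens = counts / counts.sum() if counts.sum() else counts.astype(float)
        for left, c, d in zip(edges[:-1], counts, dens):
            rows.append({"stratum": s.label, "bin_left": left,
                         "bin_right": left + bin_width, "count": int(c),
                         "density": float(d)})
    return pd.DataFrame(rows)
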