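"""Stability and translation indices, their association, the permutation
null, the standardization experiment and dispersion statistics.

For each gene with all three parameters positive:

* stability index   = log2(RA / TR) — production-vs-abundance discrepancy,
  an operational proxy for mRNA stability;
* translation index = log2(TA / RA) — translation activity normalised to
  abundance.

Stabilization-by-translation (active translation shielding mRNAs from
degradation) predicts a positive coupling between the two indices.  The
permutation null destroys that coupling by independently permuting the TR
and TA columns across genes while leaving RA fixed; because RA then appears
with opposite signs in the two indices, the null correlation is negative —
an observed positive correlation therefore cannot be a ratio artefact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ASSAYS, ExpressionProfile

logger = logging.getLogger(__name__)

__all__ = ["compute_indices", "index_association", "Association",
           "PermutationResult", "permutation_null", "standardize_profiles",
           "dispersion_summary", "histogram_overlay"]


def _positive_values(profile: ExpressionProfile, pseudocount: float = 0.0) -> pd.DataFrame:
    v = profile.values
    if pseudocount > 0:
        return v + pseudocount
    ok = (v > 0).all(axis=1)
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("index computation: excluded %d genes with a zero parameter", n_excluded)
    return v.loc[ok]


def compute_indices(profile: ExpressionProfile, pseudocount: float = 0.0) -> pd.DataFrame:
    """Per-gene stability and translation indices.

    Genes with any non-positive parameter are excluded (log ratios
    undefined) unless a ``pseudocount`` is supplied.  The exact identity
    ``stability_index + translation_index == log2(TA/TR)`` holds row-wise.
    """
    v = _positive_values(profile, pseudocount)
    if len(v) == 0:
        raise ValueError("no genes with all three parameters positive")
    out = pd.DataFrame({
        "stability_index": np.log2(v["ra"] / v["tr"]),
        "translation_index": np.log2(v["ta"] / v["ra"]),
    })
    out.index.name = "gene_id"
    return out


@dataclass(frozen=True)
class Association:
    """Correlation and regression between the two indices.

    ``slope`` regresses the stability index on the translation index (the
    scatter's y on its x); ``slope_reverse`` is the other orientation.
    """

    r: float
    slope: float
    slope_reverse: float
    n: int


def index_association(table: pd.DataFrame, method: str = "pearson") -> Association:
    """Association between stability and translation indices."""
    s = table["stability_index"].to_numpy(float)
    t = table["translation_index"].to_numpy(float)
    if s.size < 3:
        raise ValueError("need >= 3 genes")
    if np.var(s) == 0 or np.var(t) == 0:
        raise ValueError("zero-variance index")
    if method == "pearson":
        r = float(stats.pearsonr(s, t).statistic)
    elif method == "spearman":
        r = float(stats.spearmanr(s, t).statistic)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    cov = float(np.cov(s, t)[0, 1])
    return Association(r=r, slope=cov / float(np.var(t, ddof=1)),
                       slope_reverse=cov / float(np.var(s, ddof=1)), n=s.size)


@dataclass
class PermutationResult:
    """Null distribution of the index association under column permutation."""

    correlations: np.ndarray
    slopes: np.ndarray
    n_reps: int
    seed: int
    observed_correlation: float
    observed_slope: float

    def summary(self) -> dict:
        return {
            "n_reps": self.n_reps,
            "seed": self.seed,
            "observed_correlation": self.observed_correlation,
            "observed_slope": self.observed_slope,
            "n_negative_correlations": int((self.correlations < 0).sum()),
            "n_negative_slopes": int((self.slopes < 0).sum()),
            "max_correlation": float(self.correlations.max()),
            "mean_correlation": float(self.correlations.mean()),
        }


def permutation_null(profile: ExpressionProfile, n_reps: int = 1000,
                     seed: int = 0, shared_permutation: bool = False) -> PermutationResult:
    """Permute the TR and TA columns across genes and re-derive the indices.

    Per replicate, TR and TA are each permuted by an independent gene-label
    permutation (RA fixed); ``shared_permutation=True`` applies one common
    permutation to both, the weaker reading that preserves TR–TA pairing.
    Deterministic given ``(seed, n_reps, gene order)``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    v = _positive_values(profile)
    log_tr = np.log2(v["tr"].to_numpy(float))
    log_ra = np.log2(v["ra"].to_numpy(float))
    log_ta = np.log2(v["ta"].to_numpy(float))
    obs = index_association(pd.DataFrame({"stability_index": log_ra - log_tr,
                                          "translation_index": log_ta - log_ra}))
    rng = np.random.default_rng(seed)
    corrs = np.empty(n_reps)
    slopes = np.empty(n_reps)
    n = log_ra.size
    for i in range(n_reps):
        p_tr = rng.permutation(n)
        p_ta = p_tr if shared_permutation else rng.permutation(n)
        stab = log_ra - log_tr[p_tr]
        transl = log_ta[p_ta] - log_ra
        c = np.corrcoef(stab, transl)[0, 1]
        corrs[i] = c
        slopes[i] = np.cov(stab, transl)[0, 1] / np.var(transl, ddof=1)
    return PermutationResult(correlations=corrs, slopes=slopes, n_reps=n_reps,
                             seed=seed, observed_correlation=obs.r,
                             observed_slope=obs.slope)


def permutation_expected_correlation(profile: ExpressionProfile) -> float:
    """Analytic expectation of the null correlation.

    With TR and TA independently permuted, only the shared RA term couples
    the two indices:  E r = -Var(log2 RA) /
    sqrt((Var RA + Var TR)(Var RA + Var TA))  (log2-scale sample variances).
    """
    v = _positive_values(profile)
    var = {a: float(np.var(np.log2(v[a].to_numpy(float)), ddof=1)) for a in ASSAYS}
    return -var["ra"] / np.sqrt((var["ra"] + var["tr"]) * (var["ra"] + var["ta"]))


def standardize_profiles(profile: ExpressionProfile) -> ExpressionProfile:
    """Z-score each parameter's log2 profile across genes (mean 0, sd 1).

    Returned values are ``2**z`` so the profile stays on the linear RPKM-like
    scale and downstream log-ratio indices become z-score differences.  The
    operation is idempotent and preserves within-parameter gene ranking.
    """
    v = _positive_values(profile)
    if len(v) == 0:
        raise ValueError("no genes with all three parameters positive")
    log_v = np.log2(v.to_numpy(float))
    sd = log_v.std(axis=0, ddof=0)
    if (sd == 0).any():
        raise ValueError("zero-variance parameter; cannot standardize")
    z = (log_v - log_v.mean(axis=0)) / sd
    out = pd.DataFrame(np.exp2(z), index=v.index, columns=list(ASSAYS))
    return ExpressionProfile(values=out)


def dispersion_summary(profile: ExpressionProfile) -> pd.DataFrame:
    """Standard deviation and value range of each log2 profile.

    Rising dispersion TR -> RA -> TA is the sequential-enhancement signature:
    more genes take extreme values at each step of the expression cascade.
    """
    v = _positive_values(profile)
    rows = []
    for a in ASSAYS:
        log_a = np.log2(v[a].to_numpy(float))
        rows.append({"parameter": a, "sd": float(log_a.std(ddof=1)),
                     "value_range": float(log_a.max() - log_a.min())})
    return pd.DataFrame(rows)


def histogram_overlay(profile: ExpressionProfile, bin_width: float = 0.25,
                      align: bool = False) -> dict[str, dict]:
    """Per-parameter histogram of log2 values on a common grid.

    With ``align=True`` each parameter is shifted so its modal bin lines up
    with the TR mode, which displays the widening of the distributions
    without the location differences.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    v = _positive_values(profile)
    logs = {a: np.log2(v[a].to_numpy(float)) for a in ASSAYS}
    shifts = {a: 0.0 for a in ASSAYS}
    if align:
        modes = {}
        for a, la in logs.items():
            edges = _edges(la, bin_width)
            counts, edges = np.histogram(la, bins=edges)
            modes[a] = 0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1])
        for a in ASSAYS:
            shifts[a] = modes["tr"] - modes[a]
    lo = min((logs[a] + shifts[a]).min() for a in ASSAYS)
    hi = max((logs[a] + shifts[a]).max() for a in ASSAYS)
    edges = _edges(np.array([lo, hi]), bin_width)
    out = {}
    for a in ASSAYS:
        counts, _ = np.histogram(logs[a] + shifts[a], bins=edges)
        out[a] = {"bin_edges": edges, "counts": counts, "shift": shifts[a]}
    return out


def _edges(x: np.ndarray, bin_width: float) -> np.ndarray:
    lo = np.floor(x.min() / bin_width) * bin_width
    hi = np.ceil(x.max() / bin_width) * bin_width
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width - 1e-9)))
    return lo + bin_width * np.arange(n_bins + 1)
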