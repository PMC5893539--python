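"""Count-table I/O, RPKM conversion and the expressed-gene filter.

The pipeline starts from per-gene exon read counts (htseq-count two-column
dialect: ``gene_id<TAB>count``, with ``__``-prefixed summary rows tolerated
and dropped) for three assays measured on the same cells:

* ``tr`` — transcription rate (GRO-seq),
* ``ra`` — mRNA abundance (RNA-seq),
* ``ta`` — translation activity (polysome-profiling RNA-seq),

each with one or more biological replicates.  Counts are converted to RPKM
(reads per kilobase of exon model per million mapped reads) and genes are
kept when at least one of the three parameters reaches an RPKM cutoff.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: canonical assay order used throughout the package
ASSAYS = ("tr", "ra", "ta")


class ParseError(ValueError):
    """A malformed input line; carries the 1-based line number."""


@dataclass
class CountTable:
    """Per-gene exon read counts for one (assay, replicate) sample."""

    counts: pd.Series  # index: gene_id, values: non-negative int
    assay: str
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"assay must be one of {ASSAYS}, got {self.assay!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids in count table: {dups}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = self.counts.astype(np.int64)

    @property
    def total(self) -> int:
        """Total mapped reads = sum of per-gene counts (summary rows excluded)."""
        return int(self.counts.sum())


def read_counts(path: str | Path, assay: str, replicate: int = 1) -> CountTable:
    """Read an htseq-count two-column TSV into a :class:`CountTable`.

    Summary rows (``__no_feature`` etc.) are dropped.  A duplicated gene id
    or a malformed line raises with the offending line number.
    """
    ids: list[str] = []
    values: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 tab-separated fields, got {len(parts)}")
            gene_id, count_str = parts
            if gene_id.startswith("__"):
                continue
            try:
                count = int(count_str)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: count {count_str!r} is not an integer") from exc
            if count < 0:
                raise ParseError(f"{path}:{lineno}: negative count {count}")
            ids.append(gene_id)
            values.append(count)
    counts = pd.Series(values, index=pd.Index(ids, name="gene_id"), dtype=np.int64)
    return CountTable(counts=counts, assay=assay, replicate=replicate)


def write_counts(table: CountTable, path: str | Path) -> None:
    """Write a count table in the same two-column dialect ``read_counts`` reads."""
    with open(path, "w") as fh:
        for gene_id, count in table.counts.items():
            fh.write(f"{gene_id}\t{count}\n")


def read_lengths(path: str | Path) -> pd.Series:
    """Read a gene-length TSV (gene_id, exon_length in bases)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "exon_length"],
                     dtype={"gene_id": str}, comment="#")
    lengths = df.set_index("gene_id")["exon_length"].astype(np.int64)
    if (lengths < 1).any():
        bad = lengths.index[lengths < 1].tolist()
        raise ValueError(f"exon lengths must be >= 1; offenders: {bad}")
    if lengths.index.has_duplicates:
        raise ValueError("duplicate gene ids in length table")
    return lengths


def write_lengths(lengths: pd.Series, path: str | Path) -> None:
    lengths.rename("exon_length").to_csv(path, sep="\t", header=False)


def rpkm(counts: CountTable, lengths: pd.Series, total_mapped: int | None = None) -> pd.Series:
    """Convert exon read counts to RPKM.

    RPKM_g = count_g / (exon_length_g / 1000) / (total / 1e6).  ``total``
    defaults to the in-table count sum; pass ``total_mapped`` to normalise
    against an externally determined library size instead.
    """
    missing = counts.counts.index.difference(lengths.index)
    if len(missing) > 0:
        raise KeyError(f"genes missing from length table: {sorted(missing)[:20]}"
                       f"{' ...' if len(missing) > 20 else ''}")
    total = counts.total if total_mapped is None else int(total_mapped)
    if total <= 0:
        raise ValueError("total mapped reads must be positive")
    len_kb = lengths.loc[counts.counts.index].astype(float) / 1e3
    return counts.counts.astype(float) / len_kb / (total / 1e6)


@dataclass
class ExpressionProfile:
    """Per-gene RPKM for the three parameters, with per-replicate values.

    ``values`` is the pooled per-assay RPKM matrix (columns ``tr, ra, ta``);
    ``replicates``, when present, has a two-level column index
    ``(assay, replicate)`` holding each replicate's RPKM.
    """

    values: pd.DataFrame
    replicates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [a for a in ASSAYS if a not in self.values.columns]
        if missing:
            raise ValueError(f"profile missing assay columns: {missing}")
        self.values = self.values[list(ASSAYS)].astype(float)
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("profile values must be finite")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("RPKM values must be >= 0")

    @property
    def n_genes(self) -> int:
        return len(self.values)

    def subset(self, gene_ids) -> "ExpressionProfile":
        reps = None if self.replicates is None else self.replicates.loc[gene_ids]
        return ExpressionProfile(self.values.loc[gene_ids], reps)


def profile_from_rpkm(tr: pd.Series, ra: pd.Series, ta: pd.Series) -> ExpressionProfile:
    """Assemble a profile from three per-assay RPKM series (outer join, 0 fill)."""
    values = pd.concat({"tr": tr, "ra": ra, "ta": ta}, axis=1).fillna(0.0)
    values.index.name = "gene_id"
    return ExpressionProfile(values)


def profile_from_counts(
    tables: Iterable[CountTable],
    lengths: pd.Series,
    pooling: str = "mean",
    total_mapped: Mapping[tuple[str, int], int] | None = None,
) -> ExpressionProfile:
    """Build an :class:`ExpressionProfile` from per-sample count tables.

    ``pooling`` is how replicates are combined into the single per-assay
    value: ``"mean"`` (mean of replicate RPKMs, the default) or
    ``"pooled_counts"`` (sum counts across replicates, then RPKM).
    """
    tables = list(tables)
    if not tables:
        raise ValueError("no count tables supplied")
    by_assay: dict[str, list[CountTable]] = {a: [] for a in ASSAYS}
    rep_cols: dict[tuple[str, int], pd.Series] = {}
    for t in tables:
        key = (t.assay, t.replicate)
        if key in rep_cols:
            raise ValueError(f"duplicate sample {key}")
        tm = None if total_mapped is None else total_mapped.get(key)
        rep_cols[key] = rpkm(t, lengths, total_mapped=tm)
        by_assay[t.assay].append(t)
    for a in ASSAYS:
        if not by_assay[a]:
            raise ValueError(f"no count table for assay {a!r}")

    replicates = pd.concat(rep_cols, axis=1).fillna(0.0)
    replicates.columns = pd.MultiIndex.from_tuples(replicates.columns, names=["assay", "replicate"])
    replicates.index.name = "gene_id"

    if pooling == "mean":
        pooled = {a: replicates[a].mean(axis=1) for a in ASSAYS}
    elif pooling == "pooled_counts":
        pooled = {}
        for a in ASSAYS:
            summed = pd.concat([t.counts for t in by_assay[a]], axis=1).fillna(0).sum(axis=1)
            merged = CountTable(counts=summed.astype(np.int64), assay=a, replicate=1)
            pooled[a] = rpkm(merged, lengths)
    else:
        raise ValueError(f"unknown pooling {pooling!r}")
    values = pd.concat(pooled, axis=1).reindex(replicates.index).fillna(0.0)
    values.index.name = "gene_id"
    return ExpressionProfile(values=values, replicates=replicates)


def filter_expressed(
    profile: ExpressionProfile, cutoff: float = 1.0, min_params: int = 1
) -> tuple[ExpressionProfile, dict]:
    """Keep genes with >= ``min_params`` of {tr, ra, ta} at or above ``cutoff``.

    Returns the filtered profile and a report dict (cutoff, retained, dropped).
    The boundary is inclusive: a gene with exactly ``cutoff`` in one parameter
    is retained at the defaults.
    """
    hits = (profile.values >= cutoff).sum(axis=1)
    keep = hits >= min_params
    retained = profile.subset(profile.values.index[keep])
    report = {
        "cutoff": cutoff,
        "min_params": min_params,
        "retained": int(keep.sum()),
        "dropped": int((~keep).sum()),
    }
    logger.info("expressed-gene filter: retained %d of %d genes (cutoff %g RPKM)",
                report["retained"], profile.n_genes, cutoff)
    return retained, report


def replicate_consistency(profile: ExpressionProfile) -> pd.DataFrame:
    """R-squared of log2 replicate-vs-replicate regression, per assay pair.

    Genes with a zero value in either replicate are excluded from the fit
    (log undefined); the exclusion count is reported per pair.  Requires at
    least two replicates per assay.
    """
    if profile.replicates is None:
        raise ValueError("profile has no replicate data")
    rows = []
    for assay in ASSAYS:
        reps = sorted(profile.replicates[assay].columns)
        if len(reps) < 2:
            raise ValueError(f"assay {assay!r} has {len(reps)} replicate(s); need >= 2")
        for i, ra_ in enumerate(reps):
            for rb in reps[i + 1:]:
                x = profile.replicates[(assay, ra_)].to_numpy(float)
                y = profile.replicates[(assay, rb)].to_numpy(float)
                ok = (x > 0) & (y > 0)
                n_excluded = int((~ok).sum())
                if ok.sum() < 3:
                    raise ValueError(f"assay {assay!r} pair ({ra_},{rb}): fewer than 3 positive pairs")
                fit = stats.linregress(np.log2(x[ok]), np.log2(y[ok]))
                rows.append({"assay": assay, "rep_a": ra_, "rep_b": rb,
                             "r_squared": fit.rvalue ** 2, "n_genes": int(ok.sum()),
                             "n_excluded": n_excluded})
                if n_excluded:
                    logger.info("replicate regression %s (%s vs %s): excluded %d zero genes",
                                assay, ra_, rb, n_excluded)
    return pd.DataFrame(rows)


def write_profile(profile: ExpressionProfile, path: str | Path) -> None:
    """Write the pooled RPKM matrix (and replicates as ``assay_rep<k>`` columns)."""
    out = profile.values.copy()
    if profile.replicates is not None:
        for (assay, rep), col in profile.replicates.items():
            out[f"{assay}_rep{rep}"] = col
    out.to_csv(path, sep="\t")


def read_profile(path: str | Path) -> ExpressionProfile:
    """Read a matrix TSV written by :func:`write_profile` (or a bare tr/ra/ta table)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    rep_cols = [c for c in df.columns if "_rep" in c]
    replicates = None
    if rep_cols:
        tuples = []
        for c in rep_cols:
            assay, rep = c.rsplit("_rep", 1)
            tuples.append((assay, int(rep)))
        replicates = df[rep_cols].copy()
        replicates.columns = pd.MultiIndex.from_tuples(tuples, names=["assay", "replicate"])
    return ExpressionProfile(values=df[list(ASSAYS)], replicates=replicates)


def write_filter_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2) + "\n")
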