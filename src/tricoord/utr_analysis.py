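"""UTR proportions and their interaction with stabilization-by-translation.

The fraction of an mRNA occupied by its untranslated regions,

    utr_proportion = (utr5_len + utr3_len) / (utr5_len + cds_len + utr3_len),

measures how much of the transcript is available for post-transcriptional
regulatory signals (miRNA sites, RBP motifs).  A high UTR proportion
attenuates the stability–translation coupling: this module computes the
per-gene annotation, the UTR-binned association curve, the rectangular
selection of "defier" mRNAs (stable yet poorly translated), and gene-group
UTR summaries with a two-sample t-test.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .indices import index_association

logger = logging.getLogger(__name__)

UTR_COLUMNS = ("utr5_len", "cds_len", "utr3_len", "mrna_len", "utr_proportion")


def _finalize_annotation(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("utr5_len", "cds_len", "utr3_len"):
        if (df[col] < 0).any():
            bad = df.index[df[col] < 0].tolist()
            raise ValueError(f"negative {col} for genes {bad}")
    if (df["cds_len"] <= 0).any():
        bad = df.index[df["cds_len"] <= 0].tolist()
        raise ValueError(f"non-positive CDS length for genes {bad}")
    df = df.copy()
    df["mrna_len"] = df["utr5_len"] + df["cds_len"] + df["utr3_len"]
    df["utr_proportion"] = (df["utr5_len"] + df["utr3_len"]) / df["mrna_len"]
    df.index.name = "gene_id"
    return df[list(UTR_COLUMNS)]


def _annotate_from_gtf(path: str | Path) -> pd.DataFrame:
    """Per-gene UTR/CDS lengths from a GTF, one canonical transcript per gene.

    Transcript choice: longest CDS, ties broken by longest mRNA, then
    lexicographically smallest transcript id.  GTF coordinates are 1-based
    inclusive; exonic bases genomically before the first CDS base count as
    5'UTR on the + strand and 3'UTR on the - strand (so a stop codon
    annotated outside the CDS features lands in the 3'UTR).
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique",
                            disable_infer_genes=True, disable_infer_transcripts=True)
    per_gene: dict[str, tuple] = {}
    for tx in db.features_of_type(("transcript", "mRNA")):
        exons = list(db.children(tx, featuretype="exon"))
        cds = list(db.children(tx, featuretype="CDS"))
        if not cds:
            logger.warning("transcript %s has no CDS; skipped", tx.id)
            continue
        if not exons:
            exons = cds
        exon_len = sum(e.end - e.start + 1 for e in exons)
        cds_lo = min(c.start for c in cds)
        cds_hi = max(c.end for c in cds)
        left = sum(max(0, min(e.end, cds_lo - 1) - e.start + 1) for e in exons)
        right = sum(max(0, e.end - max(e.start, cds_hi + 1) + 1) for e in exons)
        if tx.strand == "-":
            utr5, utr3 = right, left
        else:
            utr5, utr3 = left, right
        cds_len = exon_len - utr5 - utr3
        gene_id = tx.attributes.get("gene_id", [tx.id])[0]
        key = (cds_len, exon_len, _NegStr(tx.id))
        if gene_id not in per_gene or key > per_gene[gene_id][0]:
            per_gene[gene_id] = (key, utr5, cds_len, utr3)
    if not per_gene:
        raise ValueError(f"no coding transcripts found in {path}")
    rows = {g: {"utr5_len": u5, "cds_len": c, "utr3_len": u3}
            for g, (_, u5, c, u3) in per_gene.items()}
    return pd.DataFrame.from_dict(rows, orient="index")


class _NegStr(str):
    """Reversed string ordering so max() prefers the lexicographically smaller id."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def annotate_utr(source) -> pd.DataFrame:
    """Per-gene UTR annotation from a GTF, a TSV, or an in-memory table.

    The TSV dialect is four columns: gene_id, utr5_len, cds_len, utr3_len.
    Returns a frame indexed by gene_id with columns utr5_len, cds_len,
    utr3_len, mrna_len and utr_proportion (in [0, 1)).
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
        if "gene_id" in df.columns:
            df = df.set_index("gene_id")
        return _finalize_annotation(df)
    path = Path(source)
    if path.suffix.lower() in {".gtf", ".gff", ".gff3"}:
        return _finalize_annotation(_annotate_from_gtf(path))
    df = pd.read_csv(path, sep="\t", dtype={0: str}, comment="#")
    expected = {"gene_id", "utr5_len", "cds_len", "utr3_len"}
    if not expected.issubset(df.columns):
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["gene_id", "utr5_len", "cds_len", "utr3_len"],
                         dtype={"gene_id": str})
    return _finalize_annotation(df.set_index("gene_id"))


def utr_binned_association(table: pd.DataFrame, utr: pd.DataFrame,
                           bin_edges=None, min_occupancy: int = 50) -> pd.DataFrame:
    """Index association stratified by UTR proportion.

    Within each UTR-proportion bin holding at least ``min_occupancy`` genes,
    the Pearson correlation and regression slope (stability on translation)
    are computed.  Default bins are width 0.1 over [0, 1]; with a single
    [0, 1] bin the result equals the global association on the shared genes.
    """
    if bin_edges is None:
        bin_edges = np.linspace(0.0, 1.0, 11)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if bin_edges.ndim != 1 or len(bin_edges) < 2 or np.any(np.diff(bin_edges) <= 0):
        raise ValueError("bin_edges must be a strictly increasing 1-D sequence")
    shared = table.index.intersection(utr.index)
    t = table.loc[shared]
    u = utr.loc[shared, "utr_proportion"].to_numpy(float)
    rows = []
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        last = hi == bin_edges[-1]
        in_bin = (u >= lo) & ((u <= hi) if last else (u < hi))
        n = int(in_bin.sum())
        if n < min_occupancy:
            continue
        assoc = index_association(t.loc[in_bin])
        rows.append({"bin_left": lo, "bin_right": hi, "bin_center": 0.5 * (lo + hi),
                     "pearson_r": assoc.r, "regression_slope": assoc.slope, "n_genes": n})
    if not rows:
        raise ValueError("all UTR bins below the minimum occupancy")
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DefierSelection:
    """Rectangular selection of stable-yet-poorly-translated mRNAs."""

    stability_min: float
    translation_max: float
    gene_ids: tuple = field(default_factory=tuple)

    @property
    def n(self) -> int:
        return len(self.gene_ids)


def select_defiers(table: pd.DataFrame, stability_min: float = 0.0,
                   translation_max: float = -1.0) -> DefierSelection:
    """Genes with stability_index >= ``stability_min`` and translation_index
    <= ``translation_max`` (closed rectangle: boundary genes are included).

    The defaults keep mRNAs at least as abundant as their production rate
    predicts (stability index >= 0) whose polysome signal is below half their
    abundance (translation index <= -1).
    """
    keep = (table["stability_index"] >= stability_min) & \
           (table["translation_index"] <= translation_max)
    ids = tuple(table.index[keep])
    if not ids:
        logger.warning("defier selection is empty at thresholds (%g, %g)",
                       stability_min, translation_max)
    return DefierSelection(stability_min=stability_min,
                           translation_max=translation_max, gene_ids=ids)


@dataclass(frozen=True)
class UtrShiftResult:
    bin_edges: np.ndarray
    selection_counts: np.ndarray
    background_counts: np.ndarray
    selection_mean: float
    background_mean: float
    t_statistic: float
    p_value: float


def utr_shift_test(selection: DefierSelection, utr: pd.DataFrame,
                   bin_width: float = 0.05, welch: bool = False) -> UtrShiftResult:
    """Compare UTR proportions of selected mRNAs against all annotated genes.

    Returns shared-bin histograms and a two-sample t-test of the proportions
    (pooled-variance Student by default, Welch with ``welch=True``).
    """
    sel_ids = [g for g in selection.gene_ids if g in utr.index]
    if len(sel_ids) < 3:
        raise ValueError(f"selection has {len(sel_ids)} annotated genes; need >= 3")
    sel = utr.loc[sel_ids, "utr_proportion"].to_numpy(float)
    bg = utr["utr_proportion"].to_numpy(float)
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    sel_counts, _ = np.histogram(sel, bins=edges)
    bg_counts, _ = np.histogram(bg, bins=edges)
    t_stat, p = stats.ttest_ind(sel, bg, equal_var=not welch)
    return UtrShiftResult(bin_edges=edges, selection_counts=sel_counts,
                          background_counts=bg_counts,
                          selection_mean=float(sel.mean()),
                          background_mean=float(bg.mean()),
                          t_statistic=float(t_stat), p_value=float(p))


def group_utr_summary(gene_sets: dict[str, list], utr: pd.DataFrame,
                      welch: bool = False) -> dict:
    """Per-group UTR-proportion mean/median plus pairwise two-sample t-tests.

    Unknown gene ids are listed and excluded; each group needs >= 2 annotated
    genes.  The t-test is Student's pooled-variance version by default.
    """
    groups = {}
    props = {}
    for name, ids in gene_sets.items():
        ids = list(ids)
        known = [g for g in ids if g in utr.index]
        unknown = sorted(set(ids) - set(known))
        if len(known) < 2:
            raise ValueError(f"group {name!r} has {len(known)} annotated genes; need >= 2")
        p = utr.loc[known, "utr_proportion"].to_numpy(float)
        props[name] = p
        groups[name] = {"n": len(known), "mean": float(p.mean()),
                        "median": float(np.median(p)), "unknown_ids": unknown}
        if unknown:
            logger.warning("group %s: %d unknown gene ids excluded", name, len(unknown))
    names = list(gene_sets)
    tests = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            t_stat, p = stats.ttest_ind(props[a], props[b], equal_var=not welch)
            tests[f"{a}_vs_{b}"] = {"t_statistic": float(t_stat), "p_value": float(p)}
    return {"groups": groups, "t_tests": tests}
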