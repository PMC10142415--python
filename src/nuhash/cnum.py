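"""Cluster-presence ("Cnum") categorization of single-cell ATAC peaks.

A union peak's *Cnum* is the number of cell clusters whose peak sets it
overlaps: low Cnum marks cell-type-specific open chromatin, maximal Cnum
marks constitutively open chromatin.  Union peaks are matched to bulk
ATAC-seq peaks to attach a bulk intensity; the maximal-Cnum group's bulk
intensities are typically bimodal (stochastic vs. constant open regions) and
are dichotomized at the crossover of a two-component log-scale Gaussian
mixture.  Peaks are annotated to genomic features by their midpoint with
precedence promoter > 5'UTR > 3'UTR > exon > intron > intergenic.

All intervals are 0-based half-open (BED convention); two intervals overlap
when they share at least ``min_overlap`` bases (default 1).
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .demux import chi_squared, round_half_up, _fit_log_mixture

FEATURE_PRECEDENCE = ("promoter", "utr5", "utr3", "exon", "intron", "intergenic")
DEFAULT_PROMOTER_WINDOW = 2000
MIN_SCORES_FOR_DICHOTOMY = 100


@dataclass(frozen=True)
class Peak:
    """Genomic interval, 0-based half-open, with optional intensity score."""

    chrom: str
    start: int
    end: int
    score: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("empty chromosome name")
        if not self.start < self.end:
            raise ValueError(f"start must be < end ({self.start} >= {self.end})")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class CnumRecord:
    """A union peak with cluster-presence count and bulk-intensity context."""

    peak: Peak
    cnum: int
    bulk_score: float | None = None
    intensity_group: str = "not_applicable"   # low | high | not_applicable
    feature: str | None = None

    def __post_init__(self) -> None:
        if self.intensity_group not in ("low", "high", "not_applicable"):
            raise ValueError(f"bad intensity group {self.intensity_group!r}")


# ---------------------------------------------------------------------------
# Peak file IO
# ---------------------------------------------------------------------------

def read_narrowpeak(path: str | Path) -> list[Peak]:
    """Read an ENCODE narrowPeak file; column 7 (signalValue) is the score."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    peaks = []
    for row in df.itertuples(index=False):
        score = float(row[6]) if len(row) > 6 else None
        name = str(row[3]) if len(row) > 3 and str(row[3]) != "." else None
        peaks.append(Peak(str(row[0]), int(row[1]), int(row[2]),
                          score=score, name=name))
    return peaks


def read_bed(path: str | Path) -> list[Peak]:
    """Read BED3/BED6; column 5 (score), when present, becomes the score."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    peaks = []
    for row in df.itertuples(index=False):
        score = float(row[4]) if len(row) > 4 and str(row[4]) != "." else None
        name = str(row[3]) if len(row) > 3 and str(row[3]) != "." else None
        peaks.append(Peak(str(row[0]), int(row[1]), int(row[2]),
                          score=score, name=name))
    return peaks


def write_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            name = p.name or f"peak_{i}"
            score = 0 if p.score is None else p.score
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{score}\t.\n")


def filter_min_width(peaks: Iterable[Peak], min_width: int = 146) -> list[Peak]:
    """Drop peaks narrower than ``min_width`` bases (off by default upstream;
    exposed for pipelines that remove sub-nucleosomal peaks)."""
    return [p for p in peaks if p.width >= min_width]


# ---------------------------------------------------------------------------
# Interval machinery
# ---------------------------------------------------------------------------

def _build_trees(peaks: Iterable[Peak]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for p in peaks:
        trees[p.chrom].addi(p.start, p.end, p)
    return dict(trees)


def _overlapping(trees: Mapping[str, IntervalTree], peak: Peak,
                 min_overlap: int = 1) -> list[Peak]:
    tree = trees.get(peak.chrom)
    if tree is None:
        return []
    hits = []
    for iv in tree.overlap(peak.start, peak.end):
        if min(peak.end, iv.end) - max(peak.start, iv.begin) >= min_overlap:
            hits.append(iv.data)
    return hits


# ---------------------------------------------------------------------------
# Cnum assignment and bulk intensity
# ---------------------------------------------------------------------------

def assign_cnum(union_peaks: Iterable[Peak],
                clusters: Mapping[str, Sequence[Peak]],
                min_overlap: int = 1) -> list[CnumRecord]:
    """Count, per union peak, the clusters containing an overlapping peak."""
    if not clusters:
        raise ValueError("no clusters given")
    cluster_trees = {cid: _build_trees(peaks) for cid, peaks in clusters.items()}
    records = []
    for peak in union_peaks:
        cnum = sum(bool(_overlapping(trees, peak, min_overlap))
                   for trees in cluster_trees.values())
        records.append(CnumRecord(peak=peak, cnum=cnum))
    return records


def attach_bulk(records: Iterable[CnumRecord], bulk_peaks: Iterable[Peak],
                min_overlap: int = 1) -> tuple[list[CnumRecord], int]:
    """Attach the max score among overlapping bulk peaks to each record.

    Returns the updated records and the number of union peaks overlapping
    any bulk peak; non-overlapping peaks keep ``bulk_score=None`` and stay
    out of intensity analysis.
    """
    bulk = list(bulk_peaks)
    if any(p.score is None for p in bulk):
        raise ValueError("bulk peaks must carry scores")
    trees = _build_trees(bulk)
    out = []
    n_overlap = 0
    for rec in records:
        hits = _overlapping(trees, rec.peak, min_overlap)
        if hits:
            n_overlap += 1
            rec = replace(rec, bulk_score=max(p.score for p in hits))
        out.append(rec)
    return out, n_overlap


def dichotomize_intensity(scores: Sequence[float],
                          manual_threshold: float | None = None,
                          ) -> tuple[float, list[str]]:
    """Split a bimodal intensity vector into low/high groups.

    A two-component Gaussian mixture is fitted on log scores (deterministic
    percentile initialization); the threshold is the posterior crossover —
    the smallest score at which the high component's posterior exceeds 0.5
    — which sits at the dip between the two fitted densities.  Scores at or
    above the threshold are labelled ``high``.  A ``manual_threshold``
    bypasses the fit.
    """
    values = np.asarray(scores, dtype=float)
    if (values <= 0).any():
        raise ValueError("intensity scores must be positive")
    if manual_threshold is None:
        if len(values) < MIN_SCORES_FOR_DICHOTOMY:
            raise ValueError(
                f"need >= {MIN_SCORES_FOR_DICHOTOMY} scores to fit the mixture; "
                "pass manual_threshold for smaller sets")
        logv = np.log(values)
        if np.ptp(logv) < 1e-12:
            raise ValueError("all scores equal; supply manual_threshold")
        gmm = _fit_log_mixture(logv)
        hi_comp = int(np.argmax(gmm.means_.ravel()))
        grid = np.linspace(logv.min(), logv.max(), 10_000)
        post = gmm.predict_proba(grid.reshape(-1, 1))[:, hi_comp]
        above = np.nonzero(post > 0.5)[0]
        if above.size == 0 or above[0] == 0:
            raise ValueError("mixture fit found no interior crossover; "
                             "supply manual_threshold")
        threshold = float(np.exp(grid[above[0]]))
    else:
        threshold = float(manual_threshold)
    labels = ["high" if v >= threshold else "low" for v in values]
    return threshold, labels


def apply_intensity_groups(records: Sequence[CnumRecord],
                           manual_threshold: float | None = None,
                           ) -> tuple[list[CnumRecord], float]:
    """Dichotomize the maximal-Cnum group's bulk scores in place.

    Only records with the maximal observed cnum and a bulk score get a
    low/high group; everything else stays ``not_applicable``.
    """
    max_cnum = max(r.cnum for r in records)
    eligible = [i for i, r in enumerate(records)
                if r.cnum == max_cnum and r.bulk_score is not None]
    if not eligible:
        raise ValueError("no maximal-cnum records with bulk scores")
    threshold, labels = dichotomize_intensity(
        [records[i].bulk_score for i in eligible], manual_threshold)
    out = list(records)
    for i, lbl in zip(eligible, labels):
        out[i] = replace(out[i], intensity_group=lbl)
    return out, threshold


# ---------------------------------------------------------------------------
# Feature annotation
# ---------------------------------------------------------------------------

class GeneModel:
    """Midpoint-queryable feature intervals derived from a GTF gene model.

    Promoters are TSS +/- ``promoter_window`` (strand-aware); introns are
    transcript bases not covered by an exon.  GTF coordinates (1-based,
    inclusive) are converted to 0-based half-open internally.
    """

    def __init__(self, gtf_path: str | Path,
                 promoter_window: int = DEFAULT_PROMOTER_WINDOW):
        db = gffutils.create_db(str(gtf_path), dbfn=":memory:", force=True,
                                keep_order=True, disable_infer_genes=True,
                                disable_infer_transcripts=True)
        self.promoter_window = int(promoter_window)
        trees: dict[str, dict[str, IntervalTree]] = {
            k: defaultdict(IntervalTree)
            for k in ("promoter", "utr5", "utr3", "exon", "transcript")}
        for feat in db.all_features():
            start0, end0 = feat.start - 1, feat.end
            if feat.featuretype == "transcript":
                tss = start0 if feat.strand != "-" else end0 - 1
                trees["promoter"][feat.seqid].addi(
                    max(0, tss - self.promoter_window), tss + self.promoter_window + 1)
                trees["transcript"][feat.seqid].addi(start0, end0)
            elif feat.featuretype == "exon":
                trees["exon"][feat.seqid].addi(start0, end0)
            elif feat.featuretype in ("five_prime_utr", "5UTR"):
                trees["utr5"][feat.seqid].addi(start0, end0)
            elif feat.featuretype in ("three_prime_utr", "3UTR"):
                trees["utr3"][feat.seqid].addi(start0, end0)
        self._trees = {k: dict(v) for k, v in trees.items()}
        self._chroms = set().union(*(v.keys() for v in self._trees.values()))

    def _hit(self, kind: str, chrom: str, pos: int) -> bool:
        tree = self._trees[kind].get(chrom)
        return bool(tree is not None and tree[pos])

    def classify_point(self, chrom: str, pos: int) -> str:
        """Feature class of a genomic point, by precedence."""
        if chrom not in self._chroms:
            warnings.warn(f"chromosome {chrom!r} absent from gene model; "
                          "classifying as intergenic", stacklevel=2)
            return "intergenic"
        for kind in ("promoter", "utr5", "utr3", "exon"):
            if self._hit(kind, chrom, pos):
                return kind
        if self._hit("transcript", chrom, pos):
            return "intron"
        return "intergenic"

    def tss_positions(self) -> dict[str, np.ndarray]:
        """Sorted TSS coordinates per chromosome.

        Promoter intervals are [tss-w, tss+w+1) with only the left edge ever
        clipped at 0, so the TSS is recovered as end - w - 1.
        """
        return {
            chrom: np.asarray(
                sorted(iv.end - self.promoter_window - 1 for iv in tree),
                dtype=np.int64)
            for chrom, tree in self._trees["promoter"].items()
        }


def annotate_features(records: Sequence[CnumRecord],
                      gene_model: GeneModel) -> list[CnumRecord]:
    """Assign each record the feature class of its peak midpoint."""
    return [replace(r, feature=gene_model.classify_point(r.peak.chrom,
                                                         r.peak.midpoint))
            for r in records]


# ---------------------------------------------------------------------------
# Comparative interval statistics
# ---------------------------------------------------------------------------

def overlap_fraction(query: Sequence[Peak], subject: Sequence[Peak],
                     min_overlap: int = 1) -> tuple[float, int]:
    """Percentage (one decimal) and count of query peaks overlapping subject."""
    if not query:
        raise ValueError("empty query peak set")
    if not subject:
        raise ValueError("empty subject peak set")
    trees = _build_trees(subject)
    n = sum(bool(_overlapping(trees, p, min_overlap)) for p in query)
    return round_half_up(100.0 * n / len(query), 1), n


def compare_overlap_fractions(query_a: Sequence[Peak], query_b: Sequence[Peak],
                              subject: Sequence[Peak], min_overlap: int = 1,
                              ) -> dict:
    """Chi-squared comparison of two groups' subject-overlap proportions."""
    pct_a, n_a = overlap_fraction(query_a, subject, min_overlap)
    pct_b, n_b = overlap_fraction(query_b, subject, min_overlap)
    table = np.array([[n_a, len(query_a) - n_a],
                      [n_b, len(query_b) - n_b]], dtype=float)
    stat, dof, p, unreliable = chi_squared(table)
    return {"pct_a": pct_a, "pct_b": pct_b, "chi2_stat": stat,
            "chi2_df": dof, "chi2_p": p, "chi2_unreliable": unreliable}


def distance_to_nearest(query: Sequence[Peak],
                        anchors: Mapping[str, Sequence[int]],
                        ) -> list[int | None]:
    """Absolute distance from each peak midpoint to the nearest anchor.

    ``anchors`` maps chromosome -> positions (e.g. TSS coordinates); peaks
    on chromosomes without anchors yield None.
    """
    if not anchors or all(len(v) == 0 for v in anchors.values()):
        raise ValueError("no anchor positions given")
    sorted_anchors = {c: np.sort(np.asarray(v, dtype=np.int64))
                      for c, v in anchors.items() if len(v)}
    out: list[int | None] = []
    for p in query:
        pos = sorted_anchors.get(p.chrom)
        if pos is None:
            out.append(None)
            continue
        mid = p.midpoint
        i = int(np.searchsorted(pos, mid))
        cands = [abs(mid - pos[j]) for j in (i - 1, i) if 0 <= j < len(pos)]
        out.append(int(min(cands)))
    return out


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def records_to_frame(records: Sequence[CnumRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": r.peak.chrom, "start": r.peak.start, "end": r.peak.end,
        "cnum": r.cnum, "bulk_score": r.bulk_score,
        "intensity_group": r.intensity_group, "feature": r.feature,
    } for r in records])


def summarize_cnum(records: Sequence[CnumRecord]) -> pd.DataFrame:
    """Per-cnum group sizes, bulk-score quartiles, and feature fractions."""
    df = records_to_frame(records)
    rows = []
    for cnum, grp in df.groupby("cnum"):
        row = {"cnum": int(cnum), "n_peaks": len(grp)}
        scored = grp["bulk_score"].dropna()
        if len(scored):
            q1, q2, q3 = scored.quantile([0.25, 0.5, 0.75])
            row.update(bulk_q25=float(q1), bulk_median=float(q2), bulk_q75=float(q3))
        if grp["feature"].notna().any():
            fracs = grp["feature"].value_counts(normalize=True)
            for feat in FEATURE_PRECEDENCE:
                row[f"frac_{feat}"] = float(fracs.get(feat, 0.0))
        rows.append(row)
    return pd.DataFrame(rows).set_index("cnum").sort_index()
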