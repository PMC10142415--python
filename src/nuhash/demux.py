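"""Nucleus demultiplexing and barnyard concordance.

Each nucleus is classified twice and the two classifications are compared:

* from hash counts, by the count-cutoff quadrant rule — a nucleus is a
  *singlet* of sample ``s`` when only ``s``'s hash count reaches its cutoff,
  a *multiplet* when two or more samples reach theirs, and *negative* when
  none does;
* from genome alignment counts in a two-genome (barnyard) mixture — a
  *singlet* of the dominant genome when its fraction of fragments reaches
  the purity threshold, a *doublet* when both genomes contribute
  substantially, *undetermined* otherwise.

Cutoffs may be fixed, derived per sample from a two-component Gaussian
mixture on log counts (ambient vs. signal), or set by the CLR/quantile
convention of droplet hashing methods.  Agreement between hash and genome
calls is summarized as a confusion matrix with a Pearson chi-squared test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as scipy_stats
from sklearn.mixture import GaussianMixture

from .counting import HashCountMatrix

DEFAULT_MIN_READS = 10_000
DEFAULT_FIXED_CUTOFF = 10.0
DEFAULT_PURITY = 0.9
DEFAULT_MIN_MINOR = 100
MIN_NUCLEI_FOR_AUTO = 50


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (the convention of reported tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: int, total: int, ndigits: int = 2) -> float:
    """``100 * count / total`` rounded half-up to ``ndigits`` decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100.0 * count / total, ndigits)


# ---------------------------------------------------------------------------
# Records and calls
# ---------------------------------------------------------------------------

@dataclass
class NucleusRecord:
    """Per-nucleus observables feeding classification."""

    cell_barcode: str
    total_reads: int
    genome_counts: dict[str, int] = field(default_factory=dict)
    hash_counts: dict[str, int] = field(default_factory=dict)
    # optional QC metrics (populated from an upstream QC table)
    frip_pct: float | None = None
    fragments_in_peaks: int | None = None
    blacklist_ratio: float | None = None
    nucleosome_signal: float | None = None

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.genome_counts.values()):
            raise ValueError("negative genome count")
        if any(v < 0 for v in self.hash_counts.values()):
            raise ValueError("negative hash count")
        if self.genome_counts and self.total_reads < max(self.genome_counts.values()):
            raise ValueError("total_reads below a single genome's count")


@dataclass(frozen=True)
class HashCall:
    """Hash-based label: singlet (with sample), multiplet, or negative."""

    label: str
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if self.label not in ("singlet", "multiplet", "negative"):
            raise ValueError(f"bad hash label {self.label!r}")
        if (self.label == "singlet") != (self.sample_id is not None):
            raise ValueError("sample_id present iff label is singlet")


@dataclass(frozen=True)
class SpeciesCall:
    """Genome-based label: singlet (with genome), doublet, or undetermined."""

    label: str
    genome_id: str | None = None

    def __post_init__(self) -> None:
        if self.label not in ("singlet", "doublet", "undetermined"):
            raise ValueError(f"bad species label {self.label!r}")
        if (self.label == "singlet") != (self.genome_id is not None):
            raise ValueError("genome_id present iff label is singlet")


@dataclass
class CutoffSet:
    """Per-sample count thresholds; a count >= its threshold is positive."""

    thresholds: dict[str, float]

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.thresholds.values()):
            raise ValueError("cutoffs must be positive")

    def __getitem__(self, sample_id: str) -> float:
        return self.thresholds[sample_id]

    @classmethod
    def fixed(cls, sample_ids: Iterable[str],
              value: float = DEFAULT_FIXED_CUTOFF) -> "CutoffSet":
        return cls({s: float(value) for s in sample_ids})


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_nuclei(records: Iterable[NucleusRecord],
                  min_reads: int = DEFAULT_MIN_READS) -> list[NucleusRecord]:
    """Keep nuclei with at least ``min_reads`` total reads (inclusive)."""
    return [r for r in records if r.total_reads >= min_reads]


@dataclass
class QCThresholds:
    """Per-nucleus QC gates; set a field to None to disable that predicate.

    Defaults drop a nucleus when reads-in-peaks < 15%, fragments in peaks
    < 2000, blacklist ratio > 0.05, or nucleosome signal outside (0.2, 4).
    """

    min_frip_pct: float | None = 15.0
    min_fragments_in_peaks: int | None = 2000
    max_blacklist_ratio: float | None = 0.05
    nucleosome_signal_bounds: tuple[float, float] | None = (0.2, 4.0)


def qc_filter_nuclei(records: Iterable[NucleusRecord],
                     thresholds: QCThresholds | None = None) -> list[NucleusRecord]:
    """Drop nuclei failing ANY enabled QC predicate."""
    th = thresholds or QCThresholds()

    def _require(value, name: str, barcode: str):
        if value is None:
            raise ValueError(f"nucleus {barcode}: missing QC field {name!r} "
                             "required by an enabled predicate")
        return value

    kept = []
    for r in records:
        drop = False
        if th.min_frip_pct is not None:
            drop |= _require(r.frip_pct, "frip_pct", r.cell_barcode) < th.min_frip_pct
        if th.min_fragments_in_peaks is not None:
            drop |= _require(r.fragments_in_peaks, "fragments_in_peaks",
                             r.cell_barcode) < th.min_fragments_in_peaks
        if th.max_blacklist_ratio is not None:
            drop |= _require(r.blacklist_ratio, "blacklist_ratio",
                             r.cell_barcode) > th.max_blacklist_ratio
        if th.nucleosome_signal_bounds is not None:
            lo, hi = th.nucleosome_signal_bounds
            ns = _require(r.nucleosome_signal, "nucleosome_signal", r.cell_barcode)
            drop |= ns < lo or ns > hi
        if not drop:
            kept.append(r)
    return kept


# ---------------------------------------------------------------------------
# Cutoff derivation
# ---------------------------------------------------------------------------

def _fit_log_mixture(log_values: np.ndarray) -> GaussianMixture:
    """Deterministic 2-component 1-D Gaussian mixture (EM, percentile init)."""
    x = log_values.reshape(-1, 1)
    lo, hi = np.percentile(log_values, [25, 75])
    if hi <= lo:
        hi = lo + 1e-3
    gmm = GaussianMixture(
        n_components=2,
        means_init=[[lo], [hi]],
        weights_init=[0.5, 0.5],
        precisions_init=[[[1.0]], [[1.0]]],
        covariance_type="full",
        max_iter=500,
        tol=1e-6,
        reg_covar=1e-6,
    )
    gmm.fit(x)
    return gmm


def auto_cutoff(counts: pd.DataFrame | HashCountMatrix,
                fallback: float = DEFAULT_FIXED_CUTOFF,
                min_separation: float = 1.0) -> CutoffSet:
    """Derive per-sample cutoffs from the bimodality of log hash counts.

    For each sample a two-component Gaussian mixture is fitted to
    ``log1p(count)`` over all nuclei (EM with components seeded at the 25th
    and 75th percentiles, so the fit is deterministic).  The cutoff is the
    smallest integer count at which the high component's posterior exceeds
    0.5.  If the fitted means are separated by less than ``min_separation``
    log-units the distribution is treated as unimodal and the fixed
    ``fallback`` cutoff is used for that sample.
    """
    if isinstance(counts, HashCountMatrix):
        counts = counts.to_dataframe()
    if len(counts) < MIN_NUCLEI_FOR_AUTO:
        raise ValueError(
            f"auto cutoff needs >= {MIN_NUCLEI_FOR_AUTO} nuclei "
            f"(got {len(counts)}); use a fixed cutoff instead")

    thresholds: dict[str, float] = {}
    for sample in counts.columns:
        values = counts[sample].to_numpy(dtype=float)
        logv = np.log1p(values)
        if np.ptp(logv) < 1e-9:
            thresholds[sample] = float(fallback)
            continue
        gmm = _fit_log_mixture(logv)
        means = gmm.means_.ravel()
        hi_comp = int(np.argmax(means))
        if abs(means[1] - means[0]) < min_separation:
            thresholds[sample] = float(fallback)
            continue
        grid = np.arange(0, int(values.max()) + 2)
        post = gmm.predict_proba(np.log1p(grid).reshape(-1, 1))[:, hi_comp]
        above = np.nonzero(post > 0.5)[0]
        if above.size == 0:
            thresholds[sample] = float(fallback)
        else:
            thresholds[sample] = float(max(above[0], 1))
    return CutoffSet(thresholds)


def clr_quantile_cutoff(counts: pd.DataFrame | HashCountMatrix,
                        quantile: float = 0.99) -> CutoffSet:
    """Cutoffs by the droplet-hashing CLR convention.

    Per sample, log1p counts are split into a background and a positive
    cluster by deterministic 2-means (centers seeded at the 25th/75th
    percentiles); the cutoff is one count above the ``quantile`` quantile of
    the background cluster's raw counts, i.e. a count must exceed virtually
    all of the ambient background to be called positive.
    """
    if isinstance(counts, HashCountMatrix):
        counts = counts.to_dataframe()
    thresholds: dict[str, float] = {}
    for sample in counts.columns:
        values = counts[sample].to_numpy(dtype=float)
        logv = np.log1p(values)
        lo, hi = np.percentile(logv, [25, 75])
        if hi <= lo:
            thresholds[sample] = float(values.max()) + 1.0
            continue
        centers = np.array([lo, hi])
        for _ in range(100):
            assign = np.abs(logv[:, None] - centers[None, :]).argmin(axis=1)
            new = np.array([
                logv[assign == k].mean() if (assign == k).any() else centers[k]
                for k in (0, 1)])
            if np.allclose(new, centers):
                break
            centers = new
        background = values[assign == int(np.argmin(centers))]
        thresholds[sample] = float(np.quantile(background, quantile)) + 1.0
    return CutoffSet(thresholds)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_hash(counts: Mapping[str, int], cutoffs: CutoffSet) -> HashCall:
    """Quadrant rule: count the samples whose hash count reaches its cutoff."""
    above = [s for s, c in counts.items() if c >= cutoffs[s]]
    if len(above) == 1:
        return HashCall("singlet", above[0])
    if len(above) >= 2:
        return HashCall("multiplet")
    return HashCall("negative")


def classify_hash_matrix(counts: pd.DataFrame | HashCountMatrix,
                         cutoffs: CutoffSet) -> dict[str, HashCall]:
    """Apply :func:`classify_hash` to every row of a count matrix."""
    if isinstance(counts, HashCountMatrix):
        counts = counts.to_dataframe()
    return {
        str(barcode): classify_hash(row.to_dict(), cutoffs)
        for barcode, row in counts.iterrows()
    }


def assign_species(genome_counts: Mapping[str, int],
                   purity: float = DEFAULT_PURITY,
                   min_minor: int = DEFAULT_MIN_MINOR) -> SpeciesCall:
    """Barnyard call from per-genome fragment counts.

    The nucleus is a singlet of the dominant genome when that genome holds at
    least ``purity`` of all fragments; a doublet when below purity and the
    minor genome contributes at least ``min_minor`` fragments; undetermined
    otherwise (including zero total).
    """
    if len(genome_counts) < 2:
        raise ValueError("species assignment needs counts for >= 2 genomes")
    total = sum(genome_counts.values())
    if total <= 0:
        return SpeciesCall("undetermined")
    top = max(genome_counts, key=genome_counts.get)
    f = genome_counts[top] / total
    if f >= purity:
        return SpeciesCall("singlet", top)
    minor = total - genome_counts[top]
    if minor >= min_minor:
        return SpeciesCall("doublet")
    return SpeciesCall("undetermined")


def summarize_calls(hash_calls: Iterable[HashCall]) -> pd.DataFrame:
    """Counts and percentages per hash label (singlet/multiplet/negative).

    Percentages are over all classified nuclei, rounded half-up to two
    decimals, so they sum to 100 within rounding.
    """
    calls = list(hash_calls)
    if not calls:
        raise ValueError("no calls to summarize")
    total = len(calls)
    rows = []
    for label in ("singlet", "multiplet", "negative"):
        n = sum(1 for c in calls if c.label == label)
        rows.append({"label": label, "count": n, "pct": percentage(n, total)})
    return pd.DataFrame(rows).set_index("label")


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

def chi_squared(table: np.ndarray | pd.DataFrame) -> tuple[float, int, float, bool]:
    """Pearson chi-squared on a contingency table, no continuity correction.

    Returns (statistic, df, p, unreliable) where ``unreliable`` flags any
    expected cell below 5.  All-zero rows/columns are dropped first.
    """
    arr = np.asarray(table, dtype=float)
    arr = arr[arr.sum(axis=1) > 0][:, arr.sum(axis=0) > 0]
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        return 0.0, 0, 1.0, True
    stat, p, dof, expected = scipy_stats.chi2_contingency(arr, correction=False)
    return float(stat), int(dof), float(p), bool((expected < 5).any())


@dataclass
class ConcordanceReport:
    """Agreement between genome-based and hash-based singlet assignments."""

    confusion: pd.DataFrame          # genome singlets (rows) x hash samples (cols)
    n_concordant: int
    n_discordant: int
    discordance_pct: float           # 100 * n_discordant / confusion total
    chi2_stat: float
    chi2_df: int
    chi2_p: float
    chi2_unreliable: bool
    summary_pcts: pd.DataFrame       # hash-label counts/pcts over all classified nuclei

    def to_dict(self) -> dict:
        return {
            "confusion": {g: self.confusion.loc[g].to_dict()
                          for g in self.confusion.index},
            "n_concordant": self.n_concordant,
            "n_discordant": self.n_discordant,
            "discordance_pct": self.discordance_pct,
            "discordance_pct_rounded": round_half_up(self.discordance_pct, 2),
            "chi2_stat": self.chi2_stat,
            "chi2_df": self.chi2_df,
            "chi2_p": self.chi2_p,
            "chi2_unreliable": self.chi2_unreliable,
            "summary": {lbl: {"count": int(row["count"]), "pct": float(row["pct"])}
                        for lbl, row in self.summary_pcts.iterrows()},
        }


def concordance(hash_calls: Mapping[str, HashCall],
                species_calls: Mapping[str, SpeciesCall],
                sample_to_species: Mapping[str, str]) -> ConcordanceReport:
    """Compare hash and genome classifications of the same nuclei.

    The confusion matrix is restricted to nuclei that are singlets under
    both schemes; a nucleus is concordant when its hash sample's species
    matches its genome call.  The chi-squared test is Pearson's without
    continuity correction on that matrix.
    """
    shared = sorted(set(hash_calls) & set(species_calls))
    if not shared:
        raise ValueError("hash and species calls share no cell barcodes")

    genomes = sorted({species_calls[b].genome_id for b in shared
                      if species_calls[b].label == "singlet"})
    samples = sorted(sample_to_species)
    confusion = pd.DataFrame(0, index=pd.Index(genomes, name="genome"),
                             columns=pd.Index(samples, name="hash_sample"))
    n_conc = n_disc = 0
    for b in shared:
        hc, sc = hash_calls[b], species_calls[b]
        if hc.label != "singlet" or sc.label != "singlet":
            continue
        confusion.loc[sc.genome_id, hc.sample_id] += 1
        if sample_to_species.get(hc.sample_id) == sc.genome_id:
            n_conc += 1
        else:
            n_disc += 1

    total = int(confusion.to_numpy().sum())
    disc_pct = 100.0 * n_disc / total if total else float("nan")
    stat, dof, p, unreliable = chi_squared(confusion)
    summary = summarize_calls([hash_calls[b] for b in shared])
    return ConcordanceReport(
        confusion=confusion, n_concordant=n_conc, n_discordant=n_disc,
        discordance_pct=disc_pct, chi2_stat=stat, chi2_df=dof, chi2_p=p,
        chi2_unreliable=unreliable, summary_pcts=summary,
    )


# ---------------------------------------------------------------------------
# Genome-count input
# ---------------------------------------------------------------------------

def read_genome_counts(path: str | Path) -> pd.DataFrame:
    """Read a per-nucleus genome-count TSV.

    Columns: ``cell_barcode  genome_id  fragment_count`` (header optional);
    returns a cell_barcode x genome_id wide table of fragment counts.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["cell_barcode", "genome_id", "fragment_count"])
    if df.iloc[0]["cell_barcode"] == "cell_barcode":  # header row present
        df = df.iloc[1:]
    df["fragment_count"] = df["fragment_count"].astype(int)
    return (df.pivot_table(index="cell_barcode", columns="genome_id",
                           values="fragment_count", aggfunc="sum", fill_value=0)
            .astype(int))


def genome_counts_from_fragments(path: str | Path,
                                 genome_prefixes: Mapping[str, str]) -> pd.DataFrame:
    """Derive per-nucleus genome counts from a 10x-style fragments file.

    ``genome_prefixes`` maps genome_id -> chromosome-name prefix in the
    combined reference (e.g. ``{"human": "GRCh38_", "mouse": "mm10_"}``).
    The fragments file is BED-like, tab-separated:
    ``chrom  start  end  barcode  count`` with optional ``#`` header lines.
    """
    frags = pd.read_csv(path, sep="\t", comment="#", header=None,
                        usecols=[0, 3, 4], names=["chrom", "barcode", "count"])
    genome = pd.Series(pd.NA, index=frags.index, dtype="object")
    for gid, prefix in genome_prefixes.items():
        genome[frags["chrom"].str.startswith(prefix)] = gid
    frags = frags.assign(genome=genome).dropna(subset=["genome"])
    return (frags.pivot_table(index="barcode", columns="genome",
                              values="count", aggfunc="sum", fill_value=0)
            .rename_axis(index="cell_barcode", columns="genome_id").astype(int))


def build_nucleus_records(hash_counts: pd.DataFrame | HashCountMatrix,
                          genome_counts: pd.DataFrame | None = None,
                          total_reads: Mapping[str, int] | None = None,
                          ) -> list[NucleusRecord]:
    """Join hash counts, genome counts, and read totals into NucleusRecords.

    Nuclei are taken from the hash matrix; absent genome counts default to
    zero and absent read totals to the nucleus's summed genome fragments.
    """
    if isinstance(hash_counts, HashCountMatrix):
        hash_counts = hash_counts.to_dataframe()
    records = []
    for barcode, row in hash_counts.iterrows():
        barcode = str(barcode)
        gcounts: dict[str, int] = {}
        if genome_counts is not None:
            if barcode in genome_counts.index:
                gcounts = {str(g): int(c)
                           for g, c in genome_counts.loc[barcode].items()}
            else:
                gcounts = {str(g): 0 for g in genome_counts.columns}
        if total_reads is not None:
            reads = int(total_reads.get(barcode, 0))
        else:
            reads = int(sum(gcounts.values()))
        records.append(NucleusRecord(
            cell_barcode=barcode, total_reads=reads,
            genome_counts=gcounts,
            hash_counts={str(s): int(c) for s, c in row.items()},
        ))
    return records
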