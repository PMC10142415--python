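"""From raw hash reads to a UMI-collapsed valid-cell x sample count matrix.

The pipeline is: locate the 5' anchor in the biological read (small offset
window, bounded mismatches), slice UMI1 / sample barcode / UMI2 by the fixed
layout, error-correct the 16-nt cell barcode from the index read against the
valid-cell whitelist, match the sample barcode against the design, then
collapse UMIs within each (cell, sample) group.  Every read ends in exactly
one parse status, so the status tallies partition the input.

UMI collapse follows the directional-adjacency rule: UMI ``b`` is absorbed
into a more abundant UMI ``a`` when Hamming(a, b) == 1 and
reads(a) >= 2 * reads(b) - 1.  Exact-only collapse is available via
``method="exact"``.
"""

from __future__ import annotations

import gzip
import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
import pysam
from scipy import io as scipy_io
from scipy import sparse

from .design import HashDesign, hamming

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

ANCHOR_OFFSET_WINDOW = 3  # anchor5 may start 0..3 bases into the read


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ParseStatus(str, Enum):
    VALID = "valid"
    NO_ANCHOR = "no_anchor"
    AMBIGUOUS_CELL = "ambiguous_cell"
    UNKNOWN_CELL = "unknown_cell"
    AMBIGUOUS_HASH = "ambiguous_hash"
    UNKNOWN_HASH = "unknown_hash"


@dataclass(frozen=True)
class ParsedHashRead:
    """Outcome of parsing one read pair against a design."""

    raw_cell_barcode: str
    status: ParseStatus
    corrected_cell_barcode: str | None = None
    sample_id: str | None = None
    umi: str | None = None

    def __post_init__(self) -> None:
        is_valid = self.status is ParseStatus.VALID
        has_both = self.corrected_cell_barcode is not None and self.sample_id is not None
        if is_valid != has_both:
            raise ValueError("status 'valid' iff cell barcode and sample present")


class WhitelistIndex:
    """Whitelist lookup with Hamming-distance error correction.

    For tolerance 1 (the common case) correction is O(L) per query via
    single-position wildcard keys; other tolerances fall back to a linear
    scan.  Ties (two whitelist members equally close within tolerance) are
    reported as ambiguous rather than guessed.
    """

    def __init__(self, barcodes: Iterable[str], tol: int = 1):
        self.barcodes = frozenset(barcodes)
        if not self.barcodes:
            raise ValueError("empty whitelist")
        lengths = {len(b) for b in self.barcodes}
        if len(lengths) > 1:
            raise ValueError(f"whitelist barcode lengths differ: {sorted(lengths)}")
        self.barcode_len = lengths.pop()
        self.tol = int(tol)
        self._wildcard: dict[tuple[int, str], list[str]] | None = None
        if self.tol == 1:
            wc: dict[tuple[int, str], list[str]] = defaultdict(list)
            for bc in self.barcodes:
                for i in range(self.barcode_len):
                    wc[(i, bc[:i] + bc[i + 1:])].append(bc)
            self._wildcard = dict(wc)

    @classmethod
    def from_file(cls, path: str | Path, tol: int = 1) -> "WhitelistIndex":
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "rt") as fh:
            barcodes = [line.strip() for line in fh if line.strip()]
        return cls(barcodes, tol=tol)

    def correct(self, raw: str) -> tuple[str | None, ParseStatus | None]:
        """Return (corrected_barcode, None) or (None, failure_status)."""
        if raw in self.barcodes:
            return raw, None
        if self.tol == 0 or len(raw) != self.barcode_len:
            return None, ParseStatus.UNKNOWN_CELL
        if self.tol == 1:
            hits: set[str] = set()
            for i in range(self.barcode_len):
                for cand in self._wildcard.get((i, raw[:i] + raw[i + 1:]), ()):
                    hits.add(cand)
                    if len(hits) > 1:
                        return None, ParseStatus.AMBIGUOUS_CELL
            if len(hits) == 1:
                return hits.pop(), None
            return None, ParseStatus.UNKNOWN_CELL
        # nearest unique winner: only a tie at the minimal distance is ambiguous
        dists = [(hamming(bc, raw), bc) for bc in self.barcodes]
        dmin = min(d for d, _ in dists)
        if dmin > self.tol:
            return None, ParseStatus.UNKNOWN_CELL
        hits = [bc for d, bc in dists if d == dmin]
        if len(hits) == 1:
            return hits[0], None
        return None, ParseStatus.AMBIGUOUS_CELL


def correct_cell_barcode(raw: str, whitelist: Iterable[str] | WhitelistIndex,
                         tol: int = 1) -> str | None:
    """Correct ``raw`` against the whitelist; None on tie or no match."""
    index = whitelist if isinstance(whitelist, WhitelistIndex) else WhitelistIndex(whitelist, tol)
    corrected, _ = index.correct(raw)
    return corrected


def _match_anchor(read: str, anchor: str, start: int, tol: int) -> bool:
    window = read[start:start + len(anchor)]
    return len(window) == len(anchor) and hamming(window, anchor) <= tol


def match_hash_barcode(field: str, design: HashDesign) -> tuple[str | None, ParseStatus | None]:
    """Match a sliced barcode field against the design's barcode set.

    Nearest-unique-winner rule: the barcode at minimal Hamming distance wins
    when that distance is within ``hash_mismatch_tol`` and unique; no
    candidate -> unknown, a tie at the minimum -> ambiguous (discard).  For
    a valid design (min pairwise distance >= 2*tol + 1) ties cannot occur.
    """
    tol = design.hash_mismatch_tol
    dists = [(hamming(b.sequence, field), b.sample_id) for b in design.barcodes]
    dmin = min(d for d, _ in dists)
    if dmin > tol:
        return None, ParseStatus.UNKNOWN_HASH
    hits = [s for d, s in dists if d == dmin]
    if len(hits) == 1:
        return hits[0], None
    return None, ParseStatus.AMBIGUOUS_HASH


def parse_hash_read(read_sequence: str, index_sequence: str, design: HashDesign,
                    whitelist: WhitelistIndex | None = None) -> ParsedHashRead:
    """Parse one biological read + index read into a ParsedHashRead.

    Stages fail in layout order (anchor -> cell -> hash); the status records
    the first failing stage.  When ``whitelist`` is None the raw cell barcode
    is accepted as-is (pre-validated input).
    """
    read_sequence = read_sequence.upper()
    raw_cell = index_sequence.upper()

    offset = None
    if design.anchor5:
        for cand in range(ANCHOR_OFFSET_WINDOW + 1):
            if (len(read_sequence) - cand >= design.layout_len
                    and _match_anchor(read_sequence, design.anchor5, cand,
                                      design.anchor_mismatch_tol)):
                offset = cand
                break
    elif len(read_sequence) >= design.layout_len:
        offset = 0
    if offset is None:
        return ParsedHashRead(raw_cell, ParseStatus.NO_ANCHOR)

    pos = offset + len(design.anchor5)
    umi1 = read_sequence[pos:pos + design.umi1_len]
    pos += design.umi1_len
    bc_field = read_sequence[pos:pos + design.barcode_len]
    pos += design.barcode_len
    umi2 = read_sequence[pos:pos + design.umi2_len]
    pos += design.umi2_len
    if design.anchor3 and not _match_anchor(
            read_sequence, design.anchor3, pos, design.anchor_mismatch_tol):
        return ParsedHashRead(raw_cell, ParseStatus.NO_ANCHOR)

    if whitelist is not None:
        cell, fail = whitelist.correct(raw_cell)
        if cell is None:
            return ParsedHashRead(raw_cell, fail)
    else:
        cell = raw_cell

    sample_id, fail = match_hash_barcode(bc_field, design)
    if sample_id is None:
        return ParsedHashRead(raw_cell, fail)

    return ParsedHashRead(raw_cell, ParseStatus.VALID,
                          corrected_cell_barcode=cell, sample_id=sample_id,
                          umi=umi1 + umi2)


# ---------------------------------------------------------------------------
# UMI collapse
# ---------------------------------------------------------------------------

def _umi_neighbors(umi: str) -> Iterator[str]:
    for i, base in enumerate(umi):
        for sub in "ACGT":
            if sub != base:
                yield umi[:i] + sub + umi[i + 1:]


def collapse_group(umi_counts: Mapping[str, int], method: str = "directional") -> int:
    """Number of distinct molecules among one (cell, sample) group's UMIs.

    ``exact``: distinct UMI strings.  ``directional``: greedy absorption of
    1-mismatch neighbours ``b`` into more abundant UMIs ``a`` when
    reads(a) >= 2*reads(b) - 1, seeds visited in decreasing read count;
    the number of clusters is returned.
    """
    if method == "exact":
        return len(umi_counts)
    if method != "directional":
        raise ValueError(f"unknown collapse method {method!r}")
    counts = dict(umi_counts)
    # deterministic: high counts first, lexicographic tie-break
    order = sorted(counts, key=lambda u: (-counts[u], u))
    assigned: set[str] = set()
    n_clusters = 0
    for seed in order:
        if seed in assigned:
            continue
        n_clusters += 1
        queue = [seed]
        assigned.add(seed)
        while queue:
            node = queue.pop()
            for nb in _umi_neighbors(node):
                if nb in counts and nb not in assigned \
                        and counts[node] >= 2 * counts[nb] - 1:
                    assigned.add(nb)
                    queue.append(nb)
    return n_clusters


def collapse_umis(triples: Iterable[tuple[str, str, str]],
                  method: str = "directional") -> dict[tuple[str, str], int]:
    """Collapse a stream of valid (cell_barcode, sample_id, umi) triples.

    Returns UMI-collapsed molecule counts per (cell, sample) group.
    """
    groups: dict[tuple[str, str], Counter] = defaultdict(Counter)
    for cell, sample, umi in triples:
        groups[(cell, sample)][umi] += 1
    return {key: collapse_group(cnt, method) for key, cnt in groups.items()}


# ---------------------------------------------------------------------------
# Count matrix
# ---------------------------------------------------------------------------

@dataclass
class HashCountMatrix:
    """Valid-cell x sample matrix of hash counts.

    ``counts`` holds UMI-collapsed molecule counts, ``raw_read_counts`` the
    read tallies before collapse; ``parse_stats`` tallies every read by its
    parse status and partitions the input.
    """

    cell_barcodes: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    raw_read_counts: np.ndarray
    parse_stats: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.raw_read_counts = np.asarray(self.raw_read_counts, dtype=np.int64)
        shape = (len(self.cell_barcodes), len(self.sample_ids))
        if self.counts.shape != shape or self.raw_read_counts.shape != shape:
            raise ValueError("matrix shape does not match barcode/sample lists")
        if (self.counts < 0).any() or (self.counts > self.raw_read_counts).any():
            raise ValueError("collapsed counts must lie in [0, raw_read_counts]")

    def to_dataframe(self, raw: bool = False) -> pd.DataFrame:
        mat = self.raw_read_counts if raw else self.counts
        return pd.DataFrame(mat, index=pd.Index(self.cell_barcodes, name="cell_barcode"),
                            columns=self.sample_ids)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "HashCountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        counts = df.to_numpy(dtype=np.int64)
        return cls(cell_barcodes=list(df.index.astype(str)),
                   sample_ids=list(df.columns.astype(str)),
                   counts=counts, raw_read_counts=counts.copy())

    def write_dir(self, out_dir: str | Path) -> None:
        """Write MTX + sidecars, wide TSV, and parse stats JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        scipy_io.mmwrite(out / "hash_counts.mtx", sparse.csr_matrix(self.counts))
        (out / "barcodes.tsv").write_text("".join(f"{b}\n" for b in self.cell_barcodes))
        (out / "samples.tsv").write_text("".join(f"{s}\n" for s in self.sample_ids))
        self.write_tsv(out / "hash_counts.tsv")
        with open(out / "parse_stats.json", "w") as fh:
            json.dump(self.parse_stats, fh, indent=2, sort_keys=True)


def _fastq_records(path: str | Path) -> Iterator[tuple[str, str]]:
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            yield rec.name, rec.sequence


def count_hashes(fastq_r1: str | Path, fastq_r2: str | Path,
                 fastq_index: str | Path, whitelist: str | Path | WhitelistIndex,
                 design: HashDesign, umi_collapse: str = "directional",
                 revcomp_index: bool = False) -> HashCountMatrix:
    """Count hash molecules per valid cell and sample from a FASTQ triplet.

    The three FASTQ streams must be record-synchronized.  Each record is
    parsed from read 1 as sequenced and, failing that, from the reverse
    complement of read 2 (the oligo carries sequencing adapters at both ends,
    so the hash layout may arrive on either mate); the first valid parse
    wins and a failed record keeps read 1's status.  ``revcomp_index``
    reverse-complements the index read before whitelist correction, for
    sequencers that emit the i5 index in the opposite orientation.
    """
    if not isinstance(whitelist, WhitelistIndex):
        whitelist = WhitelistIndex.from_file(whitelist, tol=design.cell_mismatch_tol)

    stats: Counter = Counter()
    umi_groups: dict[tuple[str, str], Counter] = defaultdict(Counter)
    raw_counts: Counter = Counter()

    streams = (_fastq_records(fastq_r1), _fastq_records(fastq_r2),
               _fastq_records(fastq_index))
    try:
        for (n1, s1), (n2, s2), (ni, si) in zip(*streams, strict=True):
            base = n1.split("/")[0]
            if n2.split("/")[0] != base or ni.split("/")[0] != base:
                raise ValueError(
                    f"desynchronized FASTQ streams at record {n1!r}/{n2!r}/{ni!r}")
            index_seq = reverse_complement(si) if revcomp_index else si
            parsed = parse_hash_read(s1, index_seq, design, whitelist)
            if parsed.status is not ParseStatus.VALID:
                mate = parse_hash_read(reverse_complement(s2), index_seq,
                                       design, whitelist)
                if mate.status is ParseStatus.VALID:
                    parsed = mate
            stats[parsed.status.value] += 1
            if parsed.status is ParseStatus.VALID:
                key = (parsed.corrected_cell_barcode, parsed.sample_id)
                umi_groups[key][parsed.umi] += 1
                raw_counts[key] += 1
    except ValueError as exc:
        if "zip(" in str(exc):  # unequal stream lengths from strict zip
            raise ValueError("desynchronized FASTQ streams: unequal record counts") from exc
        raise

    sample_ids = list(design.sample_ids)
    cells = sorted({cell for cell, _ in umi_groups})
    cell_idx = {c: i for i, c in enumerate(cells)}
    samp_idx = {s: j for j, s in enumerate(sample_ids)}
    counts = np.zeros((len(cells), len(sample_ids)), dtype=np.int64)
    raw = np.zeros_like(counts)
    for (cell, sample), umis in umi_groups.items():
        counts[cell_idx[cell], samp_idx[sample]] = collapse_group(umis, umi_collapse)
        raw[cell_idx[cell], samp_idx[sample]] = raw_counts[(cell, sample)]

    parse_stats = {status.value: stats.get(status.value, 0) for status in ParseStatus}
    parse_stats["total"] = sum(stats.values())
    return HashCountMatrix(cell_barcodes=cells, sample_ids=sample_ids,
                           counts=counts, raw_read_counts=raw,
                           parse_stats=parse_stats)
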