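"""Hash-oligo design: sample barcodes, UMI layout, anchors, and tolerances.

A hashing oligonucleotide read has the fixed layout

    anchor5 . UMI1 . sample barcode . UMI2 . anchor3

where the anchors are the constant remnants of the Illumina read1N/read2N
sequences, the sample barcode identifies the hashed sample, and the two UMIs
jointly identify the original molecule.  The design object validates that the
barcode set is mutually distinguishable at the configured mismatch tolerance:
assignment within Hamming distance ``t`` is unambiguous iff the minimum
pairwise Hamming distance among barcodes is at least ``2*t + 1``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

_DNA = frozenset("ACGT")

DEFAULT_HASH_TOL = 1
DEFAULT_CELL_TOL = 1
DEFAULT_ANCHOR_TOL = 2


class DesignError(ValueError):
    """Raised when a hash design violates a structural invariant."""


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class HashBarcode:
    """One sample's hash barcode.

    Parameters
    ----------
    sample_id:
        Short identifier, unique within a design.
    sequence:
        Barcode sequence over {A, C, G, T}.
    species_label:
        Optional genome identifier for barnyard concordance (e.g. ``"human"``).
    """

    sample_id: str
    sequence: str
    species_label: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise DesignError(f"{self.sample_id}: empty barcode sequence")
        bad = set(self.sequence) - _DNA
        if bad:
            raise DesignError(
                f"{self.sample_id}: invalid characters {sorted(bad)} in barcode"
            )


@dataclass(frozen=True)
class HashDesign:
    """Structure of the hashing oligo and the barcode set of one experiment."""

    barcodes: tuple[HashBarcode, ...]
    umi1_len: int = 8
    umi2_len: int = 8
    anchor5: str = ""
    anchor3: str = ""
    cell_barcode_len: int = 16
    hash_mismatch_tol: int = DEFAULT_HASH_TOL
    cell_mismatch_tol: int = DEFAULT_CELL_TOL
    anchor_mismatch_tol: int = DEFAULT_ANCHOR_TOL

    def __post_init__(self) -> None:
        if not self.barcodes:
            raise DesignError("design has no barcodes")
        ids = [b.sample_id for b in self.barcodes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DesignError(f"duplicate sample_id(s): {dupes}")
        lengths = {len(b.sequence) for b in self.barcodes}
        if len(lengths) > 1:
            raise DesignError(f"unequal barcode lengths: {sorted(lengths)}")
        if self.umi1_len + self.umi2_len <= 0:
            raise DesignError("umi1_len + umi2_len must be positive")
        if min(self.umi1_len, self.umi2_len) < 0:
            raise DesignError("UMI lengths must be non-negative")
        for tol in (self.hash_mismatch_tol, self.cell_mismatch_tol,
                    self.anchor_mismatch_tol):
            if tol < 0:
                raise DesignError("mismatch tolerances must be >= 0")
        for anchor in (self.anchor5, self.anchor3):
            bad = set(anchor) - _DNA
            if bad:
                raise DesignError(f"invalid characters {sorted(bad)} in anchor")
        if len(self.barcodes) >= 2:
            dmin = min_pairwise_hamming(self)
            if dmin < 2 * self.hash_mismatch_tol + 1:
                raise DesignError(
                    f"min pairwise Hamming distance {dmin} < "
                    f"{2 * self.hash_mismatch_tol + 1} required for unambiguous "
                    f"assignment at tolerance {self.hash_mismatch_tol}"
                )

    # -- derived layout geometry -------------------------------------------

    @property
    def barcode_len(self) -> int:
        return len(self.barcodes[0].sequence)

    @property
    def layout_len(self) -> int:
        """Total bases of anchor5 + UMI1 + barcode + UMI2 + anchor3."""
        return (len(self.anchor5) + self.umi1_len + self.barcode_len
                + self.umi2_len + len(self.anchor3))

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(b.sample_id for b in self.barcodes)

    @property
    def species_map(self) -> dict[str, str | None]:
        """sample_id -> species_label."""
        return {b.sample_id: b.species_label for b in self.barcodes}

    def barcode_sequences(self) -> dict[str, str]:
        return {b.sample_id: b.sequence for b in self.barcodes}

    def with_tolerances(self, *, hash_tol: int | None = None,
                        cell_tol: int | None = None,
                        anchor_tol: int | None = None) -> "HashDesign":
        return replace(
            self,
            hash_mismatch_tol=self.hash_mismatch_tol if hash_tol is None else hash_tol,
            cell_mismatch_tol=self.cell_mismatch_tol if cell_tol is None else cell_tol,
            anchor_mismatch_tol=(self.anchor_mismatch_tol if anchor_tol is None
                                 else anchor_tol),
        )


def min_pairwise_hamming(design: HashDesign) -> int:
    """Smallest Hamming distance over all unordered barcode pairs."""
    if len(design.barcodes) < 2:
        raise DesignError("pairwise distance undefined for a single barcode")
    return min(
        hamming(a.sequence, b.sequence)
        for a, b in itertools.combinations(design.barcodes, 2)
    )


def load_design(path: str | Path) -> HashDesign:
    """Load and validate a design from a YAML file.

    Expected keys: ``barcodes`` (map sample_id -> {sequence, species}),
    ``umi1_len``, ``umi2_len``, ``anchor5``, ``anchor3``,
    ``cell_barcode_len``, and ``tolerances`` (map with ``hash``, ``cell``,
    ``anchor``).  Unspecified tolerances default to hash 1, cell 1, anchor 2.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "barcodes" not in raw:
        raise DesignError(f"{path}: design file must define a 'barcodes' map")
    barcodes = []
    for sample_id, spec in raw["barcodes"].items():
        if isinstance(spec, str):
            spec = {"sequence": spec}
        barcodes.append(
            HashBarcode(
                sample_id=str(sample_id),
                sequence=str(spec["sequence"]).upper(),
                species_label=spec.get("species"),
            )
        )
    tol = raw.get("tolerances") or {}
    return HashDesign(
        barcodes=tuple(barcodes),
        umi1_len=int(raw.get("umi1_len", 8)),
        umi2_len=int(raw.get("umi2_len", 8)),
        anchor5=str(raw.get("anchor5", "") or "").upper(),
        anchor3=str(raw.get("anchor3", "") or "").upper(),
        cell_barcode_len=int(raw.get("cell_barcode_len", 16)),
        hash_mismatch_tol=int(tol.get("hash", DEFAULT_HASH_TOL)),
        cell_mismatch_tol=int(tol.get("cell", DEFAULT_CELL_TOL)),
        anchor_mismatch_tol=int(tol.get("anchor", DEFAULT_ANCHOR_TOL)),
    )


def write_design(design: HashDesign, path: str | Path) -> None:
    """Write a design to YAML such that ``load_design`` round-trips it."""
    doc = {
        "barcodes": {
            b.sample_id: {"sequence": b.sequence, "species": b.species_label}
            for b in design.barcodes
        },
        "umi1_len": design.umi1_len,
        "umi2_len": design.umi2_len,
        "anchor5": design.anchor5,
        "anchor3": design.anchor3,
        "cell_barcode_len": design.cell_barcode_len,
        "tolerances": {
            "hash": design.hash_mismatch_tol,
            "cell": design.cell_mismatch_tol,
            "anchor": design.anchor_mismatch_tol,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def reference_design(**overrides) -> HashDesign:
    """A self-contained 4-sample barnyard reference design.

    Four synthetic 8-nt barcodes at minimum pairwise Hamming distance 6,
    8+8 UMIs, and short synthetic anchors.  Two samples are labelled human
    and two mouse so the design exercises barnyard concordance end to end.
    """
    base = dict(
        barcodes=(
            HashBarcode("NuHash-1", "AGTAACCA", "human"),
            HashBarcode("NuHash-2", "ATGCCTGT", "mouse"),
            HashBarcode("NuHash-3", "TGAGATGC", "human"),
            HashBarcode("NuHash-4", "CAGACGCG", "mouse"),
        ),
        umi1_len=8,
        umi2_len=8,
        anchor5="TCGTCGGCAGCGTC",
        anchor3="CCGAGCCCACGAGAC",
    )
    base.update(overrides)
    return HashDesign(**base)
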