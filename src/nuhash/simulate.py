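"""Synthetic barnyard hashing experiments with known ground truth.

The generator emulates the observable structure of a pooled two-genome
hashing run: a valid-cell whitelist, record-synchronized FASTQ triplets of
hash reads (biological read 1, biological read 2, 16-nt cell-barcode index
read), per-nucleus per-genome fragment counts, and a truth table naming each
nucleus's sample(s) and species.

The noise model uses two per-nucleus latent factors, both Gamma with mean 1:
a capture-quality factor q (shape ``read_depth_dispersion``) scaling both
sequencing depth and hash yield, and a staining factor s (shape
``hash_depth_dispersion``) scaling hash yield only.  Total reads are
q * read_depth_mean and hash reads are Poisson(q * s * hash_depth_mean), so
hash counts are negative-binomially overdispersed, correlate with read depth
(nuclei failing a read-depth filter are also prone to insufficient hash
counts), and a small tail of well-sequenced nuclei still stains poorly —
the empirical behaviour of droplet hashing data.
Doublets carry hash reads from both constituent samples and fragments from
both species; ambient contamination rewrites a read's sample barcode to a
uniformly chosen other sample; substitution errors hit every written base
i.i.d.  All output is a pure function of (config, design, seed).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .cnum import Peak
from .design import HashDesign, reference_design

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    species_label: str
    n_nuclei: int

    def __post_init__(self) -> None:
        if self.n_nuclei <= 0:
            raise ValueError("n_nuclei must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic hashing experiment."""

    samples: tuple[SampleSpec, ...]
    doublet_rate: float = 0.12
    hash_depth_mean: float = 300.0
    hash_depth_dispersion: float = 8.0
    ambient_fraction: float = 0.05
    base_error_rate: float = 0.01
    genome_depth_mean: float = 2500.0
    cross_species_noise: float = 0.01
    read_depth_mean: float = 25_000.0
    read_depth_dispersion: float = 2.0
    seed: int = 0
    read_length: int = 50

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("no samples configured")
        for frac in (self.doublet_rate, self.ambient_fraction,
                     self.base_error_rate, self.cross_species_noise):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if min(self.hash_depth_mean, self.genome_depth_mean,
               self.read_depth_mean) <= 0:
            raise ValueError("depths must be positive")
        if min(self.hash_depth_dispersion, self.read_depth_dispersion) <= 0:
            raise ValueError("dispersions must be positive")

    @property
    def n_nuclei(self) -> int:
        return sum(s.n_nuclei for s in self.samples)


def barnyard_config(n_nuclei_per_sample: int = 1000, n_samples: int = 2,
                      seed: int = 0) -> SimConfig:
    """The default 2-plex barnyard preset.

    Tuned so that downstream demultiplexing lands near the canonical
    proportions of a real hashing run (~86% singlets, ~12% multiplets, ~2%
    insufficient-count negatives) — a tuning target for realism, not a
    distributional claim.  Samples alternate human/mouse.
    """
    design = reference_design()
    if not 1 <= n_samples <= len(design.barcodes):
        raise ValueError(f"n_samples must be in [1, {len(design.barcodes)}]")
    samples = tuple(
        SampleSpec(b.sample_id, b.species_label, n_nuclei_per_sample)
        for b in design.barcodes[:n_samples])
    return SimConfig(samples=samples, seed=seed)


@dataclass
class SimResult:
    """Paths and ground truth of one simulated experiment."""

    fastq_r1: Path
    fastq_r2: Path
    fastq_index: Path
    whitelist: Path
    genome_counts: Path
    truth: pd.DataFrame
    config: SimConfig


def _int_to_seq(value: int, length: int) -> str:
    out = []
    for _ in range(length):
        value, digit = divmod(value, 4)
        out.append("ACGT"[digit])
    return "".join(out)


def _random_barcodes(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """n distinct random DNA strings of the given length (deterministic)."""
    seen: set[int] = set()
    out: list[int] = []
    while len(out) < n:
        for v in rng.integers(0, 4 ** length, size=n - len(out)):
            v = int(v)
            if v not in seen:
                seen.add(v)
                out.append(v)
    return [_int_to_seq(v, length) for v in out]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _open_deterministic_gzip(path: Path):
    # fixed mtime + empty name keep byte-identical output across runs
    raw = open(path, "wb")
    return gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0)


def simulate_experiment(config: SimConfig, design: HashDesign,
                        out_dir: str | Path) -> SimResult:
    """Generate a full synthetic hashing experiment under ``out_dir``.

    Emits gzipped FASTQ triplets, a whitelist, a long-format genome-count
    TSV, a truth TSV, and the config echoed as YAML; returns paths plus the
    truth table.  Deterministic given (config, design, seed).
    """
    barcode_by_sample = design.barcode_sequences()
    for s in config.samples:
        if s.sample_id not in barcode_by_sample:
            raise ValueError(f"sample {s.sample_id!r} has no barcode in the design")
    n_nuclei = config.n_nuclei
    if n_nuclei > 4 ** design.cell_barcode_len / 100:
        raise ValueError("too many nuclei for the cell-barcode space "
                         "(collision risk)")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    whitelist = _random_barcodes(rng, 10 * n_nuclei, design.cell_barcode_len)
    cell_barcodes = [whitelist[i] for i in
                     rng.choice(len(whitelist), size=n_nuclei, replace=False)]

    sample_ids = [s.sample_id for s in config.samples]
    species_of = {s.sample_id: s.species_label for s in config.samples}
    genomes = sorted({s.species_label for s in config.samples})
    owner = np.repeat(sample_ids, [s.n_nuclei for s in config.samples])

    rd = config.read_depth_dispersion
    hd = config.hash_depth_dispersion
    quality = rng.gamma(shape=rd, scale=1.0 / rd, size=n_nuclei)
    staining = rng.gamma(shape=hd, scale=1.0 / hd, size=n_nuclei)

    wl_path = out / "whitelist.txt"
    wl_path.write_text("".join(f"{b}\n" for b in whitelist))

    truth_rows = []
    genome_rows = []
    r1_path, r2_path = out / "hash_R1.fastq.gz", out / "hash_R2.fastq.gz"
    idx_path = out / "hash_I1.fastq.gz"
    read_len = max(config.read_length, design.layout_len)
    qual_line = "I" * read_len
    qual_idx = "I" * design.cell_barcode_len

    with _open_deterministic_gzip(r1_path) as f1, \
            _open_deterministic_gzip(r2_path) as f2, \
            _open_deterministic_gzip(idx_path) as fi:
        read_no = 0
        for i in range(n_nuclei):
            cell = cell_barcodes[i]
            primary = owner[i]
            is_doublet = (len(sample_ids) > 1
                          and rng.random() < config.doublet_rate)
            if is_doublet:
                others = [s for s in sample_ids if s != primary]
                partner = others[rng.integers(0, len(others))]
                members = [primary, partner]
            else:
                members = [primary]

            total_reads = max(1, int(round(quality[i] * config.read_depth_mean)))
            n_hash = int(rng.poisson(
                quality[i] * staining[i] * config.hash_depth_mean))
            for _ in range(n_hash):
                src = members[rng.integers(0, len(members))]
                if (config.ambient_fraction > 0 and len(sample_ids) > 1
                        and rng.random() < config.ambient_fraction):
                    others = [s for s in sample_ids if s != src]
                    src = others[rng.integers(0, len(others))]
                umi1 = _random_seq(rng, design.umi1_len)
                umi2 = _random_seq(rng, design.umi2_len)
                layout = (design.anchor5 + umi1 + barcode_by_sample[src]
                          + umi2 + design.anchor3)
                pad = read_len - len(layout)
                insert = layout + (_random_seq(rng, pad) if pad > 0 else "")
                r1 = _mutate(rng, insert, config.base_error_rate)
                r2 = _mutate(rng, _revcomp(insert), config.base_error_rate)
                idx = _mutate(rng, cell, config.base_error_rate)
                name = f"sim_read_{read_no}"
                read_no += 1
                f1.write(f"@{name}\n{r1}\n+\n{qual_line}\n".encode())
                f2.write(f"@{name}\n{r2}\n+\n{qual_line}\n".encode())
                fi.write(f"@{name}\n{idx}\n+\n{qual_idx}\n".encode())

            # genome fragments, split among constituent species
            n_frag = int(rng.poisson(quality[i] * config.genome_depth_mean))
            member_species = [species_of[m] for m in members]
            frag_counts = dict.fromkeys(genomes, 0)
            if len(member_species) == 2 and member_species[0] != member_species[1]:
                n_first = int(rng.binomial(n_frag, 0.5))
                frag_counts[member_species[0]] += n_first
                frag_counts[member_species[1]] += n_frag - n_first
            else:
                frag_counts[member_species[0]] += n_frag
            if len(genomes) > 1 and config.cross_species_noise > 0:
                moved = {g: int(rng.binomial(frag_counts[g],
                                             config.cross_species_noise))
                         for g in genomes}
                for g in genomes:
                    frag_counts[g] -= moved[g]
                    others = [x for x in genomes if x != g]
                    alloc = rng.multinomial(moved[g],
                                            [1.0 / len(others)] * len(others))
                    for other, k in zip(others, alloc):
                        frag_counts[other] += int(k)
            for g in genomes:
                genome_rows.append((cell, g, frag_counts[g]))

            truth_rows.append({
                "cell_barcode": cell,
                "true_samples": ",".join(members),
                "true_species": ",".join(sorted(set(member_species))),
                "is_doublet": is_doublet,
                "total_reads": total_reads,
                "n_hash_reads": n_hash,
            })

    gc_path = out / "genome_counts.tsv"
    with open(gc_path, "w") as fh:
        for cell, g, cnt in genome_rows:
            fh.write(f"{cell}\t{g}\t{cnt}\n")

    truth = pd.DataFrame(truth_rows)
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    with open(out / "sim_config.yaml", "w") as fh:
        yaml.safe_dump({
            "samples": [{"sample_id": s.sample_id, "species": s.species_label,
                         "n_nuclei": s.n_nuclei} for s in config.samples],
            **{k: getattr(config, k) for k in (
                "doublet_rate", "hash_depth_mean", "hash_depth_dispersion",
                "ambient_fraction", "base_error_rate", "genome_depth_mean",
                "cross_species_noise", "read_depth_mean",
                "read_depth_dispersion", "read_length", "seed")},
        }, fh, sort_keys=False)

    return SimResult(fastq_r1=r1_path, fastq_r2=r2_path, fastq_index=idx_path,
                     whitelist=wl_path, genome_counts=gc_path,
                     truth=truth, config=config)


# ---------------------------------------------------------------------------
# Cnum fixture
# ---------------------------------------------------------------------------

DEFAULT_CNUM_WEIGHTS = (0.22, 0.15, 0.16, 0.47)  # cell-type-specific .. constitutive


def simulate_cnum_fixture(n_peaks: int = 2000, n_clusters: int = 4,
                          seed: int = 0,
                          cnum_weights: Sequence[float] | None = None,
                          bulk_overlap_fraction: float = 0.9,
                          mu_low: float = 1.0, mu_high: float = 4.0,
                          sigma: float = 0.4, p_high: float = 0.5,
                          ) -> tuple[dict[str, list[Peak]], list[Peak], pd.DataFrame]:
    """Synthetic cluster peak sets, bulk peaks, and truth labels.

    Union peaks are laid out non-overlapping along one chromosome; each is
    assigned a true cnum (how many of the ``n_clusters`` cluster peak sets
    contain it) and, for ``bulk_overlap_fraction`` of peaks, an overlapping
    bulk peak.  Bulk log-scores increase in cnum; the maximal-cnum group is
    drawn from an explicit two-component log-normal mixture
    (exp(N(mu_low, sigma)) vs exp(N(mu_high, sigma))) so intensity
    dichotomization has a known truth.  Returns (cluster peak sets, bulk
    peaks, truth table).
    """
    if n_clusters < 2:
        raise ValueError("need at least 2 clusters")
    weights = np.asarray(cnum_weights if cnum_weights is not None
                         else DEFAULT_CNUM_WEIGHTS
                         if n_clusters == len(DEFAULT_CNUM_WEIGHTS)
                         else [1.0 / n_clusters] * n_clusters, dtype=float)
    if len(weights) != n_clusters:
        raise ValueError("cnum_weights must have one entry per cluster count")
    weights = weights / weights.sum()

    rng = np.random.default_rng(seed)
    cluster_ids = [f"cluster_{chr(65 + i)}" for i in range(n_clusters)]
    clusters: dict[str, list[Peak]] = {cid: [] for cid in cluster_ids}
    bulk: list[Peak] = []
    rows = []

    for i in range(n_peaks):
        start = 2000 * i + int(rng.integers(0, 200))
        width = int(rng.integers(300, 800))
        peak = Peak("chr1", start, start + width, name=f"union_{i}")
        true_cnum = int(rng.choice(np.arange(1, n_clusters + 1), p=weights))
        chosen = rng.choice(n_clusters, size=true_cnum, replace=False)
        for c in chosen:
            clusters[cluster_ids[c]].append(peak)

        has_bulk = bool(rng.random() < bulk_overlap_fraction)
        score = None
        component = "not_applicable"
        if has_bulk:
            if true_cnum == n_clusters:
                component = "high" if rng.random() < p_high else "low"
                mu = mu_high if component == "high" else mu_low
            else:
                # log-mean climbs with cnum but stays below the high mode
                mu = mu_low + (true_cnum - 1) * (mu_high - mu_low) / (2 * n_clusters)
            score = float(np.exp(rng.normal(mu, sigma)))
            jitter = int(rng.integers(-100, 100))
            b_start = max(0, start + jitter)
            bulk.append(Peak("chr1", b_start, b_start + width, score=score,
                             name=f"bulk_{i}"))
        rows.append({"name": peak.name, "chrom": peak.chrom,
                     "start": peak.start, "end": peak.end,
                     "true_cnum": true_cnum, "has_bulk": has_bulk,
                     "bulk_score": score, "true_component": component})

    return clusters, bulk, pd.DataFrame(rows)
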