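"""Generators for every input the pipeline consumes, with known ground truth.

Real inputs to the analysis are (a) doped-nucleotide oligo libraries, (b)
tables of Solo-normalised GFP intensities per reporter variant, (c) paired
FACS-seq/DNA-seq/RNA-seq reads with the fixed flank/barcode structure, and
(d) CDS collections.  Each generator here emulates one of these with
parameters chosen to match the study conditions (doped base composition
25% each, eight FACS bins, 50-nt reporter windows) and records its ground
truth so round-trip and recovery tests can compare pipeline output against
what was planted.

Noise models (not dictated by the experimental design and documented as
package defaults): multiplicative lognormal noise for fluorescence ratios,
a lognormal cell-to-cell intensity distribution within a clone, and
multinomial/Poisson read sampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .library_quant import BinSpec, LibraryDesign, reverse_complement
from .ratchet_core import (
    MrnaLayout,
    ScanParameters,
    exact_recognition_probabilities,
    simulate_ensemble,
)

__all__ = [
    "GroundTruth",
    "DEFAULT_BIN_BARCODES",
    "DEFAULT_BIN_EDGES",
    "generate_oligo_library",
    "generate_gfp_table",
    "FacsRun",
    "generate_facs_run",
    "generate_count_run",
    "generate_synthetic_cds",
    "write_fastq",
]

BASES = np.array(list("ACGT"))

#: Barcodes for the eight FACS bins plus DNA-seq and RNA-seq samples;
#: pairwise Hamming distance >= 3 so single-base errors cannot convert one
#: valid barcode into another.
DEFAULT_BIN_BARCODES = (
    "AACCGT", "CCGATA", "GGTCAC", "TTAGCG",
    "ACGTTG", "CATGGC", "GTACAT", "TGCAGA",
)
DNA_BARCODE = "AGGACC"
RNA_BARCODE = "CTTCAA"

#: Intensity-axis edges separating the eight sorting gates (log-spaced
#: around a unit median; bin 1 collects everything below the first edge).
DEFAULT_BIN_EDGES = tuple(np.geomspace(0.25, 4.0, 7))


@dataclass
class GroundTruth:
    """Planted truth recorded alongside every generated dataset."""

    params: ScanParameters | None = None
    context_leakage: dict[str, float] | None = None
    noise_sd: float | None = None
    seed: int | None = None
    per_variant: dict[str, dict] | None = None
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "params": self.params.as_dict() if self.params else None,
            "context_leakage": self.context_leakage,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "per_variant": self.per_variant,
            "extra": self.extra,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=1))


# ---------------------------------------------------------------------------
# oligo libraries


def generate_oligo_library(
    design: LibraryDesign,
    n_variants: int,
    seed: int | np.random.SeedSequence = 0,
    designed_position: int | None = None,
) -> list[str]:
    """Variable-region sequences with i.i.d. uniform doped nucleotides.

    ``designed_position`` fixes an extra ATG at one library position
    (coordinates relative to the aATG's A = +1, e.g. +9 for a dATG oligo
    or -12 for a uATG oligo); ``None`` yields the fully doped oligo.
    Doped positions are drawn 25% A/C/G/T each, as in doped-nucleotide
    synthesis; stop codons and spurious ATGs arise naturally and are left
    in place for the downstream filters to catch.
    """

    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    rng = np.random.default_rng(seed)
    a0 = design.aatg_offset
    length = design.region_len
    fixed: dict[int, str] = {a0: "A", a0 + 1: "T", a0 + 2: "G"}
    if designed_position is not None:
        offset = designed_position - 1 if designed_position > 0 else designed_position
        start = a0 + offset
        if start < 0 or start + 3 > length or any(start + k in fixed for k in range(3)):
            raise ValueError(f"designed ATG at {designed_position:+d} does not fit the doped region")
        fixed.update({start: "A", start + 1: "T", start + 2: "G"})
    draws = rng.integers(0, 4, size=(n_variants, length))
    mat = BASES[draws]
    for idx, base in fixed.items():
        mat[:, idx] = base
    return ["".join(row) for row in mat]


# ---------------------------------------------------------------------------
# model-generated GFP observation tables


def generate_gfp_table(
    solo: MrnaLayout,
    duos: Sequence[MrnaLayout],
    params: ScanParameters,
    noise_sd: float = 0.05,
    seed: int | np.random.SeedSequence = 0,
    n_reps: int | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Solo-normalised GFP observations generated from the scanning model.

    Expression per layout comes from the exact absorbing-chain solve (or
    from ``n_reps`` stochastic trajectories when given), multiplied by
    lognormal noise of log-scale standard deviation ``noise_sd`` and
    normalised by the (equally noisy) Solo value.  With ``noise_sd=0`` the
    table equals the oracle expression exactly.
    """

    rng = np.random.default_rng(seed)
    layouts = [solo, *duos]
    if n_reps is None:
        expr = np.array(
            [exact_recognition_probabilities(l, params).expression for l in layouts]
        )
    else:
        expr = np.array(
            [simulate_ensemble(l, params, n_reps, rng).expression for l in layouts]
        )
    noisy = expr * np.exp(rng.normal(0.0, noise_sd, size=len(layouts))) if noise_sd > 0 else expr.copy()
    norm = noisy / noisy[0]
    rows = []
    truth_per_variant = {}
    for layout, raw, value in zip(layouts, expr, norm):
        if layout.n_sites == 1:
            position, frame = 0, 0
        else:
            datg = layout.sites[1 if layout.sites[1].position != layout.aatg_position else 0]
            position = datg.position - layout.upstream_len
            frame = (position - 1) % 3
        rows.append((layout.label, position, frame, "N", float(value)))
        truth_per_variant[layout.label] = {"expression": float(raw)}
    table = pd.DataFrame(rows, columns=["label", "position", "frame", "context", "gfp_norm"])
    truth = GroundTruth(
        params=params,
        noise_sd=noise_sd,
        per_variant=truth_per_variant,
        extra={"normalisation": "solo", "engine": "oracle" if n_reps is None else f"simulation({n_reps})"},
    )
    return table, truth


# ---------------------------------------------------------------------------
# FACS-seq read sets


def _pad(seq: str, length: int = 150) -> str:
    adapter = "ATCTCGTATGCCGTCTTCTGCTTGAAAAAA"
    while len(seq) < length:
        seq += adapter
    return seq[:length]


def _read_pair(region: str, barcode: str, design: LibraryDesign, rng: np.random.Generator) -> tuple[str, str]:
    n12a = "".join(rng.choice(BASES, 12))
    n12b = "".join(rng.choice(BASES, 12))
    construct = n12a + barcode + design.flank5 + region + design.flank3 + barcode + n12b
    return _pad(construct), _pad(reverse_complement(construct))


def _corrupt(read1: str, read2: str, design: LibraryDesign, rng: np.random.Generator) -> tuple[str, str, str]:
    """Introduce one of the three rejection-rule violations into a pair."""
    kind = rng.integers(0, 3)
    if kind == 0:  # break the 5' flank of read 1 -> pattern_mismatch
        i = 18 + int(rng.integers(0, len(design.flank5)))
        read1 = read1[:i] + _other_base(read1[i], rng) + read1[i + 1 :]
        return read1, read2, "pattern_mismatch"
    if kind == 1:  # mutate one barcode base -> barcode_mismatch
        i = 12 + int(rng.integers(0, 6))
        read1 = read1[:i] + _other_base(read1[i], rng) + read1[i + 1 :]
        return read1, read2, "barcode_mismatch"
    # substitute inside read 2's copy of the variable region -> pair_disagreement
    r2rc = reverse_complement(read2)
    r0 = r2rc.find(design.flank5) + len(design.flank5)
    i = r0 + int(rng.integers(0, design.region_len))
    r2rc = r2rc[:i] + _other_base(r2rc[i], rng) + r2rc[i + 1 :]
    return read1, reverse_complement(r2rc), "pair_disagreement"


def _other_base(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(0, 3))]


@dataclass
class FacsRun:
    """A generated FACS-seq experiment: read pairs, bin metadata, truth."""

    read_pairs: list[tuple[str, str]]
    bins: list[BinSpec]
    truth: GroundTruth

    def write(self, out_dir: str | Path, prefix: str = "facs") -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        r1 = out / f"{prefix}_R1.fastq"
        r2 = out / f"{prefix}_R2.fastq"
        write_fastq(r1, (p[0] for p in self.read_pairs), prefix="r1")
        write_fastq(r2, (p[1] for p in self.read_pairs), prefix="r2")
        bins_path = out / f"{prefix}_bins.tsv"
        from .library_quant import save_bins

        save_bins(self.bins, bins_path)
        truth_path = out / f"{prefix}_truth.json"
        self.truth.save(truth_path)
        return {"r1": r1, "r2": r2, "bins": bins_path, "truth": truth_path}


def write_fastq(path: str | Path, sequences, prefix: str = "read") -> None:
    with open(path, "w") as handle:
        for i, seq in enumerate(sequences):
            handle.write(f"@{prefix}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def generate_facs_run(
    variants: pd.DataFrame,
    design: LibraryDesign,
    depth: int = 500,
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
    barcodes: Sequence[str] = DEFAULT_BIN_BARCODES,
    cell_sd: float = 0.25,
    corruption: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
) -> FacsRun:
    """Emulate sorting a library into fluorescence bins and sequencing them.

    ``variants`` needs columns ``region`` and ``gfp_true``.  For every
    variant, ``depth`` cells draw a lognormal intensity centred on the
    true GFP (log-scale sd ``cell_sd``), are gated into the bin whose
    intensity interval contains them, and emit one read pair carrying that
    bin's barcode.  Bin metadata is computed from the pooled cells: G_i is
    the median intensity and P_i the fraction of cells in bin i.  A
    ``corruption`` fraction of pairs receives one of the three
    rejection-rule violations for filter testing.
    """

    if depth < 1:
        raise ValueError("depth must be >= 1")
    edges = np.asarray(bin_edges, dtype=float)
    n_bins = len(edges) + 1
    if len(barcodes) != n_bins:
        raise ValueError("one barcode per bin required")
    if not (np.all(np.diff(edges) > 0) and edges[0] > 0):
        raise ValueError("bin edges must be positive and strictly increasing")
    gfp = variants["gfp_true"].to_numpy(dtype=float)
    if gfp.min() <= 0:
        raise ValueError("true GFP values must be positive")
    rng = np.random.default_rng(seed)

    # lognormal cell-to-cell spread centred so the clone's mean intensity
    # equals its true GFP (the quantity the bin-weighted estimator recovers)
    intensities = gfp[:, None] * np.exp(
        rng.normal(-cell_sd**2 / 2, cell_sd, size=(len(gfp), depth))
    )
    bin_of = np.searchsorted(edges, intensities)  # 0..n_bins-1

    pooled = intensities.ravel()
    pooled_bin = bin_of.ravel()
    bins = []
    for b in range(n_bins):
        members = pooled[pooled_bin == b]
        if members.size:
            g = float(np.median(members))
        else:  # empty gate: nominal centre of the interval
            lo = edges[b - 1] if b > 0 else edges[0] / 2
            hi = edges[b] if b < len(edges) else edges[-1] * 2
            g = float(np.sqrt(lo * hi))
        bins.append(BinSpec(b + 1, g, float(members.size / pooled.size), barcodes[b]))

    read_pairs = []
    planted_corruptions = {"pattern_mismatch": 0, "barcode_mismatch": 0, "pair_disagreement": 0}
    for v, region in enumerate(variants["region"]):
        for b in bin_of[v]:
            r1, r2 = _read_pair(region, barcodes[b], design, rng)
            if corruption > 0 and rng.random() < corruption:
                r1, r2, reason = _corrupt(r1, r2, design, rng)
                planted_corruptions[reason] += 1
            read_pairs.append((r1, r2))
    order = rng.permutation(len(read_pairs))
    read_pairs = [read_pairs[i] for i in order]

    truth = GroundTruth(
        per_variant={
            str(r): {"gfp_true": float(g)} for r, g in zip(variants["region"], gfp)
        },
        extra={
            "depth": depth,
            "cell_sd": cell_sd,
            "corruption": corruption,
            "planted_corruptions": planted_corruptions,
        },
    )
    return FacsRun(read_pairs=read_pairs, bins=bins, truth=truth)


def generate_count_run(
    variants: pd.DataFrame,
    design: LibraryDesign,
    total_pairs: int = 50_000,
    barcode: str = DNA_BARCODE,
    weight_column: str | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[list[tuple[str, str]], pd.Series]:
    """A DNA-seq- or RNA-seq-style read set with multinomial read counts.

    Read pairs are allocated to variants proportionally to
    ``weight_column`` (uniform when ``None``); for an RNA-seq library pass
    a weight of abundance x mRNA level.  Returns the shuffled read pairs
    and the true per-variant count.
    """

    rng = np.random.default_rng(seed)
    if weight_column is None:
        w = np.ones(len(variants))
    else:
        w = variants[weight_column].to_numpy(dtype=float)
    p = w / w.sum()
    counts = rng.multinomial(total_pairs, p)
    read_pairs = []
    for region, n in zip(variants["region"], counts):
        for _ in range(int(n)):
            read_pairs.append(_read_pair(region, barcode, design, rng))
    order = rng.permutation(len(read_pairs))
    read_pairs = [read_pairs[i] for i in order]
    return read_pairs, pd.Series(counts, index=variants["region"], name="count")


# ---------------------------------------------------------------------------
# synthetic CDS collections

_SENSE_CODONS = [
    c
    for c in (a + b + d for a in "ACGT" for b in "ACGT" for d in "ACGT")
    if c not in ("TAA", "TAG", "TGA")
]
_CONTEXT_WEIGHT = {"A": 1.0, "G": 0.75, "C": 0.5, "T": 0.25}


def generate_synthetic_cds(
    n_genes: int,
    codon_range: tuple[int, int] = (50, 500),
    depletion: str = "none",
    depletion_strength: float = 0.8,
    window: int = 45,
    expression: bool = False,
    deplete_stratum: str = "all",
    seed: int | np.random.SeedSequence = 0,
) -> tuple[list, pd.DataFrame | None, GroundTruth]:
    """CDS sets with i.i.d. codons and an optional planted proximal-dATG bias.

    ``depletion`` is ``"none"`` (null model: positional dATG counts are
    flat), ``"linear-proximal"`` (out-of-frame ATGs in the early window
    are removed with probability declining linearly from
    ``depletion_strength`` at +4 to 0 at the window end) or
    ``"context-weighted"`` (the same, additionally scaled by -3 context
    strength A > G > C > T).  With ``expression=True`` each gene gets a
    lognormal expression value; ``deplete_stratum="high_expression"``
    plants the bias only in the top half, for stratified comparisons.

    Returns ``(records, expression_table | None, truth)`` where records
    are :class:`~ratchetscan.genome_scan.CdsRecord`.
    """

    from .genome_scan import CdsRecord

    if depletion not in ("none", "linear-proximal", "context-weighted"):
        raise ValueError(f"unknown depletion model {depletion!r}")
    rng = np.random.default_rng(seed)
    codons = np.array(_SENSE_CODONS)
    expr_values = (
        np.exp(rng.normal(0.0, 1.0, size=n_genes)) if expression else [None] * n_genes
    )
    if deplete_stratum not in ("all", "high_expression"):
        raise ValueError(f"unknown stratum {deplete_stratum!r}")
    if deplete_stratum == "high_expression" and not expression:
        raise ValueError("high_expression stratum requires expression=True")
    threshold = np.median(expr_values) if deplete_stratum == "high_expression" else None

    records = []
    n_removed = 0
    for g in range(n_genes):
        n_codons = int(rng.integers(codon_range[0], codon_range[1] + 1))
        body = "".join(rng.choice(codons, n_codons))
        seq = "ATG" + body + "TAA"
        apply_here = depletion != "none" and (
            threshold is None or expr_values[g] >= threshold
        )
        if apply_here:
            seq, removed = _deplete_proximal(seq, depletion, depletion_strength, window, rng)
            n_removed += removed
        records.append(CdsRecord(f"synth_{g:05d}", seq, expr_values[g] if expression else None))

    expr_table = (
        pd.DataFrame({"gene_id": [r.gene_id for r in records], "expression": expr_values})
        if expression
        else None
    )
    truth = GroundTruth(
        seed=None,
        extra={
            "depletion": depletion,
            "depletion_strength": depletion_strength,
            "deplete_stratum": deplete_stratum,
            "n_datg_removed": n_removed,
            "window": window,
        },
    )
    return records, expr_table, truth


def _deplete_proximal(
    seq: str, model: str, strength: float, window: int, rng: np.random.Generator
) -> tuple[str, int]:
    """Resample early out-of-frame ATGs with a position-dependent probability."""
    chars = list(seq)
    last_a = window + 1
    removed = 0
    for _ in range(10):  # resampling can create new ATGs nearby; re-check
        changed = False
        for pos in range(4, last_a + 1):
            i = pos - 1
            if i + 3 > len(chars) or (pos - 1) % 3 == 0:
                continue
            if "".join(chars[i : i + 3]) != "ATG":
                continue
            p_remove = strength * max(0.0, 1.0 - (pos - 4) / (last_a - 4))
            if model == "context-weighted":
                p_remove *= _CONTEXT_WEIGHT[chars[i - 3]]
            if rng.random() < p_remove:
                # mutate the T so the triplet is no longer ATG; avoid
                # creating an in-frame stop in the affected codons
                for candidate in rng.permutation(["A", "C", "G"]):
                    chars[i + 1] = candidate
                    codon_start = (i + 1) - ((i + 1) % 3)
                    codon = "".join(chars[codon_start : codon_start + 3])
                    if codon not in ("TAA", "TAG", "TGA"):
                        break
                removed += 1
                changed = True
        if not changed:
            break
    return "".join(chars), removed
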