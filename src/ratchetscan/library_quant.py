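"""FACS-seq quantification of reporter-library variants.

Turns paired amplicon reads from the doped-oligo reporter libraries into
per-variant GFP intensities and mRNA levels: pattern matching of the fixed
flank/barcode read structure, variant annotation (ATG positions, reading
frames, -3 contexts, stop codons), the ordered filtering rules, and the
bin-weighted fluorescence formula

    GFP_j = sum_i G_i * n_ij * P_i / sum_i n_ij * P_i

where ``n_ij`` is variant j's fraction of the read pairs in FACS bin i,
``G_i`` the bin's median GFP/dTomato ratio and ``P_i`` the proportion of
cells gated into the bin.  mRNA level is the ratio of the variant's
read-pair fraction in the RNA-seq library over the DNA-seq library.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats

__all__ = [
    "FLANK5_DATG",
    "FLANK5_UATG",
    "FLANK5_2A",
    "FLANK3",
    "STOP_CODONS",
    "LibraryDesign",
    "BinSpec",
    "VariantAnnotation",
    "AtgSite",
    "parse_read_pair",
    "count_read_pairs",
    "annotate_variant",
    "build_variant_table",
    "filter_variants",
    "gfp_intensity",
    "compute_gfp_table",
    "mrna_level",
    "compute_mrna_table",
    "group_summary",
    "combine_replicates",
    "reverse_complement",
    "load_bins",
    "save_bins",
]

FLANK5_DATG = "CCTCTATACTTTAACGTCAAGGAGAAAAA"
FLANK5_UATG = "CCTCTATACTTTAACGTCAAGGAGAAAAATTT"
FLANK5_2A = "CCTCTATACTTTAACGTCAAGGAGAAAAAAATTTT"
FLANK3 = "GCAGGTCGACGGATCCCCGGGTTAATTAACA"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class LibraryDesign:
    """Fixed read/oligo structure of one reporter library.

    The amplicon region between the two flanks is
    ``N(upstream_doped) + ATG + N(downstream_doped)``; the fixed ATG is the
    annotated start (aATG).  Reads carry 12 random nt, a 6-nt barcode, the
    5' flank, the region, the 3' flank, a second barcode and 12 more
    random nt.
    """

    kind: str  # 'dATG' | 'uATG' | '2A-dATG'
    upstream_doped: int
    downstream_doped: int
    flank5: str
    flank3: str = FLANK3

    @property
    def region_len(self) -> int:
        return self.upstream_doped + 3 + self.downstream_doped

    @property
    def aatg_offset(self) -> int:
        """0-based index of the aATG's A within the region."""
        return self.upstream_doped

    def is_doped(self, index: int) -> bool:
        """Whether a region index holds a doped (randomised) nucleotide."""
        return 0 <= index < self.region_len and not (
            self.aatg_offset <= index < self.aatg_offset + 3
        )

    def context_nt(self, region: str, a_index: int) -> str:
        """Nucleotide 3 positions 5' of an ATG's A, reading into the 5' flank."""
        i = a_index - 3
        if i >= 0:
            return region[i]
        return self.flank5[i]

    @classmethod
    def datg(cls) -> "LibraryDesign":
        return cls("dATG", 6, 30, FLANK5_DATG)

    @classmethod
    def uatg(cls) -> "LibraryDesign":
        return cls("uATG", 30, 0, FLANK5_UATG)

    @classmethod
    def datg_2a(cls) -> "LibraryDesign":
        return cls("2A-dATG", 0, 30, FLANK5_2A)

    @classmethod
    def from_kind(cls, kind: str) -> "LibraryDesign":
        try:
            return {"dATG": cls.datg, "uATG": cls.uatg, "2A-dATG": cls.datg_2a}[kind]()
        except KeyError:
            raise ValueError(f"unknown library kind {kind!r}") from None


@dataclass(frozen=True)
class BinSpec:
    """One FACS bin: its median GFP/dTomato ratio and gated cell fraction."""

    bin_id: int
    g_median: float
    p_gate: float
    barcode: str = ""

    def __post_init__(self) -> None:
        if self.g_median <= 0:
            raise ValueError("G_i (median GFP/dTomato ratio) must be > 0")
        if self.p_gate < 0:
            raise ValueError("P_i (gate proportion) must be >= 0")


def load_bins(path: str | Path) -> list[BinSpec]:
    df = pd.read_csv(path, sep="\t")
    bins = [
        BinSpec(int(r.bin), float(r.g_median), float(r.p_gate), str(getattr(r, "barcode", "")))
        for r in df.itertuples()
    ]
    if sum(b.p_gate for b in bins) > 1.0 + 1e-9:
        raise ValueError("gate proportions sum to more than 1")
    return bins


def save_bins(bins: Sequence[BinSpec], path: str | Path) -> None:
    pd.DataFrame(
        [(b.bin_id, b.g_median, b.p_gate, b.barcode) for b in bins],
        columns=["bin", "g_median", "p_gate", "barcode"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# read parsing


#: Typed reasons why a read pair is discarded.
PATTERN_MISMATCH = "pattern_mismatch"
BARCODE_MISMATCH = "barcode_mismatch"
PAIR_DISAGREEMENT = "pair_disagreement"


def _extract(seq: str, design: LibraryDesign) -> tuple[str, str, str] | None:
    """Match the read structure; return (barcode5, region, barcode3).

    The 5' flank is located by search rather than at a fixed offset: when
    the sequenced insert is shorter than the read, the far read runs into
    the opposite adapter, shifting the construct within the read.
    """

    f5, f3, rl = design.flank5, design.flank3, design.region_len
    i5 = seq.find(f5)
    if i5 < 6:  # not found, or no room for the upstream barcode
        return None
    r0 = i5 + len(f5)
    end = r0 + rl + len(f3) + 6
    if len(seq) < end:
        return None
    if seq[r0 + rl : r0 + rl + len(f3)] != f3:
        return None
    region = seq[r0 : r0 + rl]
    if any(c not in "ACGT" for c in region):
        return None
    return seq[i5 - 6 : i5], region, seq[r0 + rl + len(f3) : end]


def parse_read_pair(
    read1: str,
    read2: str,
    design: LibraryDesign,
    barcode_to_sample: Mapping[str, str],
) -> tuple[str, str] | str:
    """Extract the variable region from one read pair.

    Returns ``(region, sample)`` when the pair passes all three criteria,
    otherwise one of the rejection reasons ``pattern_mismatch`` (either
    read fails the fixed flank structure), ``barcode_mismatch`` (any of
    the four barcodes is not one introduced for a single sample) or
    ``pair_disagreement`` (the two reads disagree in the variable region).
    """

    m1 = _extract(read1.upper(), design)
    m2 = _extract(reverse_complement(read2.upper()), design)
    if m1 is None or m2 is None:
        return PATTERN_MISMATCH
    barcodes = (m1[0], m1[2], m2[0], m2[2])
    samples = {barcode_to_sample.get(b) for b in barcodes}
    if None in samples or len(samples) != 1:
        return BARCODE_MISMATCH
    if m1[1] != m2[1]:
        return PAIR_DISAGREEMENT
    return m1[1], samples.pop()


def count_read_pairs(
    read1_path: str | Path,
    read2_path: str | Path,
    design: LibraryDesign,
    barcode_to_sample: Mapping[str, str],
) -> tuple[pd.DataFrame, Counter]:
    """Count accepted read pairs per (variable region, sample) from FASTQ.

    Returns a region x sample count table and a tally of rejections.
    """

    counts: Counter = Counter()
    rejections: Counter = Counter()
    with open(read1_path) as h1, open(read2_path) as h2:
        for rec1, rec2 in zip(
            SeqIO.parse(h1, "fastq"), SeqIO.parse(h2, "fastq"), strict=True
        ):
            out = parse_read_pair(str(rec1.seq), str(rec2.seq), design, barcode_to_sample)
            if isinstance(out, str):
                rejections[out] += 1
            else:
                counts[out] += 1
    samples = sorted({s for _, s in counts})
    regions = sorted({r for r, _ in counts})
    table = pd.DataFrame(0, index=regions, columns=samples, dtype=np.int64)
    for (region, sample), n in counts.items():
        table.loc[region, sample] = n
    return table, rejections


# ---------------------------------------------------------------------------
# annotation


@dataclass(frozen=True)
class AtgSite:
    position: int  # A of the ATG; aATG A = +1, upstream negative (no zero)
    frame: int  # 0, 1 or 2 relative to the aATG reading frame
    context: str  # nucleotide at the -3 position


@dataclass(frozen=True)
class VariantAnnotation:
    variant_class: str  # 'Solo' | 'Duo' | 'other'
    atgs: tuple[AtgSite, ...]
    has_inframe_stop: bool
    has_uatg: bool
    has_uorf_stop: bool
    nomenclature: str


def _offset_to_position(offset: int) -> int:
    """0-based offset from the aATG's A to the signed, zero-free coordinate."""
    return offset + 1 if offset >= 0 else offset


def annotate_variant(region: str, design: LibraryDesign) -> VariantAnnotation:
    """Classify one variable-region sequence.

    Enumerates every ATG triplet fully inside the region, assigns each its
    position (A of the aATG = +1, upstream negative, no zero), reading
    frame (in-frame means the triplet is a codon of the main ORF) and -3
    context, detects in-frame stop codons in the downstream doped region,
    upstream ATGs (dATG designs) or uORF stop codons (uATG design), and
    builds the nomenclature string, e.g. ``Duo(1N, 4A)``.
    """

    region = region.upper()
    if len(region) != design.region_len:
        raise ValueError(
            f"region length {len(region)} does not match design ({design.region_len})"
        )
    a0 = design.aatg_offset
    if region[a0 : a0 + 3] != "ATG":
        raise ValueError("designed aATG missing at its fixed offset")

    atgs = []
    for i in range(len(region) - 2):
        if region[i : i + 3] == "ATG":
            offset = i - a0
            atgs.append(
                AtgSite(
                    position=_offset_to_position(offset),
                    frame=offset % 3,
                    context=design.context_nt(region, i),
                )
            )
    n_extra = len(atgs) - 1
    variant_class = "Solo" if n_extra == 0 else ("Duo" if n_extra == 1 else "other")

    # in-frame (frame 0) stop codons in the downstream region
    has_inframe_stop = any(
        region[i : i + 3] in STOP_CODONS
        for i in range(a0 + 3, len(region) - 2, 3)
    )

    has_uatg = any(s.position < 0 for s in atgs if s.position != 1)

    # uORF stop: a stop codon in frame with an upstream ATG, located
    # between that ATG and the aATG (the upstream ORF terminates early)
    has_uorf_stop = False
    for s in atgs:
        if s.position >= 1:
            continue
        start = a0 + s.position  # region index of the uATG's A (negative position == offset)
        for j in range(start + 3, a0, 3):
            if j + 3 <= len(region) and region[j : j + 3] in STOP_CODONS:
                has_uorf_stop = True
                break
        if has_uorf_stop:
            break

    nomenclature = _nomenclature(variant_class, atgs, region, design)
    return VariantAnnotation(
        variant_class=variant_class,
        atgs=tuple(atgs),
        has_inframe_stop=has_inframe_stop,
        has_uatg=has_uatg,
        has_uorf_stop=has_uorf_stop,
        nomenclature=nomenclature,
    )


def _nomenclature(
    variant_class: str, atgs: Sequence[AtgSite], region: str, design: LibraryDesign
) -> str:
    """Nomenclature string: class name plus position+context for each ATG.

    Solo variants are named by the concrete -3 nucleotide of the aATG
    (e.g. ``Solo(1T)``), the grouping used for context-strength analyses.
    In Duo names the aATG's context letter is ``N`` whenever its -3
    position is doped, matching the class labels used when grouping by
    the second ATG's position (e.g. ``Duo(1N, 4A)``).
    """

    items = []
    for s in sorted(atgs, key=lambda x: x.position):
        letter = s.context
        if (
            s.position == 1
            and variant_class != "Solo"
            and design.is_doped(design.aatg_offset - 3)
        ):
            letter = "N"
        items.append(f"{s.position}{letter}")
    return f"{variant_class}({', '.join(items)})"


# ---------------------------------------------------------------------------
# variant table, filters, quantification


def build_variant_table(
    facs_counts: pd.DataFrame,
    dna_counts: pd.Series,
    rna_counts: pd.Series,
    design: LibraryDesign,
) -> pd.DataFrame:
    """Join per-bin FACS counts with DNA/RNA counts and annotate each region.

    ``facs_counts`` is a region x bin table (one column per bin, in bin
    order); missing regions in any library get zero counts.
    """

    regions = sorted(set(facs_counts.index) | set(dna_counts.index) | set(rna_counts.index))
    table = facs_counts.reindex(regions, fill_value=0).copy()
    table.columns = [f"bin_{c}" for c in facs_counts.columns]
    table["facs_total"] = table.sum(axis=1)
    table["dna_count"] = dna_counts.reindex(regions, fill_value=0).astype(np.int64)
    table["rna_count"] = rna_counts.reindex(regions, fill_value=0).astype(np.int64)
    annotations = [annotate_variant(r, design) for r in regions]
    table["class"] = [a.variant_class for a in annotations]
    table["nomenclature"] = [a.nomenclature for a in annotations]
    table["has_inframe_stop"] = [a.has_inframe_stop for a in annotations]
    table["has_uatg"] = [a.has_uatg for a in annotations]
    table["has_uorf_stop"] = [a.has_uorf_stop for a in annotations]
    table.index.name = "region"
    return table


def filter_variants(
    table: pd.DataFrame,
    kind: str = "dATG",
    max_low_dna: int = 8,
    max_low_facs: int = 64,
    has_dna: bool = True,
    has_rna: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the ordered variant filters; return survivors and an audit table.

    Rules, in order: presence in all three libraries (FACS-seq, RNA-seq
    and DNA-seq); DNA-seq read pairs > ``max_low_dna`` (variants at or
    below the threshold are discarded); summed FACS-seq read pairs >
    ``max_low_facs``; no in-frame stop codon in the downstream region;
    no upstream ATG (dATG designs) or no uORF stop codon (uATG design).
    When no DNA-seq (``has_dna=False``) or RNA-seq (``has_rna=False``)
    library was sequenced, the rules involving it are inert but still
    appear in the audit with zero removals.
    """

    audit_rows = []
    kept = table

    def apply(rule: str, mask_keep: pd.Series):
        nonlocal kept
        removed = int((~mask_keep).sum())
        audit_rows.append((rule, removed))
        kept = kept[mask_keep]

    present = kept["facs_total"] > 0
    if has_dna:
        present &= kept["dna_count"] > 0
    if has_rna:
        present &= kept["rna_count"] > 0
    apply("absent_from_a_library", present)
    apply(
        "low_dna_reads",
        kept["dna_count"] > max_low_dna if has_dna else pd.Series(True, index=kept.index),
    )
    apply("low_facs_reads", kept["facs_total"] > max_low_facs)
    apply("inframe_stop", ~kept["has_inframe_stop"])
    if kind == "uATG":
        apply("uorf_stop", ~kept["has_uorf_stop"])
    else:
        apply("uatg", ~kept["has_uatg"])
    audit = pd.DataFrame(audit_rows, columns=["rule", "removed"])
    return kept, audit


def gfp_intensity(
    counts: Sequence[float],
    bins: Sequence[BinSpec],
    bin_totals: Sequence[float] | None = None,
) -> float:
    """Bin-weighted GFP value of one variant.

    ``counts`` are the variant's read-pair counts per bin; when
    ``bin_totals`` is given, ``n_ij`` is the variant's fraction of each
    bin's reads (counts / totals), otherwise the counts are used as
    ``n_ij`` directly.  The result always lies within the range of the
    contributing bins' medians.
    """

    counts = np.asarray(counts, dtype=float)
    if len(counts) != len(bins):
        raise ValueError("one count per bin required")
    n = counts
    if bin_totals is not None:
        totals = np.asarray(bin_totals, dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            n = np.where(totals > 0, counts / totals, 0.0)
    g = np.array([b.g_median for b in bins])
    p = np.array([b.p_gate for b in bins])
    w = n * p
    total = w.sum()
    if total <= 0:
        raise ValueError("zero total weight: no bin contributes")
    return float((g * w).sum() / total)


def compute_gfp_table(table: pd.DataFrame, bins: Sequence[BinSpec]) -> pd.Series:
    """GFP intensity for every variant in a region x bin count table."""
    cols = [f"bin_{b.bin_id}" for b in bins]
    counts = table[cols].to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    return pd.Series(
        [gfp_intensity(row, bins, totals) for row in counts],
        index=table.index,
        name="gfp",
    )


def mrna_level(
    rna_count: float, dna_count: float, rna_total: float, dna_total: float
) -> float:
    """mRNA abundance per cell: RNA-seq read fraction over DNA-seq fraction."""
    if dna_total <= 0 or rna_total <= 0:
        raise ValueError("library totals must be positive")
    dna_fraction = dna_count / dna_total
    if dna_fraction <= 0:
        raise ValueError("zero DNA fraction for variant")
    return (rna_count / rna_total) / dna_fraction


def compute_mrna_table(
    table: pd.DataFrame,
    rna_total: float | None = None,
    dna_total: float | None = None,
) -> pd.Series:
    """mRNA level for every variant; totals default to the table sums."""
    rna_total = float(table["rna_count"].sum()) if rna_total is None else rna_total
    dna_total = float(table["dna_count"].sum()) if dna_total is None else dna_total
    return pd.Series(
        [
            mrna_level(r, d, rna_total, dna_total)
            for r, d in zip(table["rna_count"], table["dna_count"])
        ],
        index=table.index,
        name="mrna",
    )


def group_summary(
    df: pd.DataFrame,
    by: str,
    value: str = "gfp",
    confidence: float = 0.95,
    method: str = "t",
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-group mean and confidence interval of a value column.

    ``method`` is ``"t"`` (t-interval on the mean) or ``"bootstrap"``
    (percentile bootstrap).  Groups of size < 2 are flagged with an
    undefined CI.
    """

    rng = np.random.default_rng(seed)
    rows = []
    for key, sub in df.groupby(by):
        x = sub[value].to_numpy(dtype=float)
        n = len(x)
        mean = float(x.mean())
        if n < 2 or np.ptp(x) == 0:
            lo = hi = mean if n >= 1 else np.nan
            defined = n >= 2  # identical values: zero-width CI
            if n < 2:
                lo = hi = np.nan
        elif method == "t":
            sem = x.std(ddof=1) / np.sqrt(n)
            lo, hi = stats.t.interval(confidence, n - 1, loc=mean, scale=sem)
            defined = True
        elif method == "bootstrap":
            idx = rng.integers(0, n, size=(n_boot, n))
            means = x[idx].mean(axis=1)
            alpha = (1 - confidence) / 2
            lo, hi = np.quantile(means, [alpha, 1 - alpha])
            defined = True
        else:
            raise ValueError(f"unknown CI method {method!r}")
        rows.append((key, n, mean, lo, hi, defined if n >= 2 else False))
    return pd.DataFrame(
        rows, columns=[by, "n", "mean", "ci_low", "ci_high", "ci_defined"]
    ).set_index(by)


def combine_replicates(
    rep1: pd.DataFrame, rep2: pd.DataFrame, columns: Sequence[str] = ("gfp", "mrna")
) -> tuple[pd.DataFrame, dict]:
    """Average per-variant values over two replicates on shared variants.

    Returns the averaged table (shared variants only) and a correlation
    report (Pearson r per column) for the replicate-agreement check.
    """

    shared = rep1.index.intersection(rep2.index)
    merged = rep1.loc[shared].copy()
    report = {}
    for col in columns:
        if col in rep1.columns and col in rep2.columns:
            a, b = rep1.loc[shared, col], rep2.loc[shared, col]
            merged[col] = (a + b) / 2
            report[col] = float(np.corrcoef(a, b)[0, 1]) if len(shared) > 1 else np.nan
    report["n_shared"] = int(len(shared))
    return merged, report
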