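"""Genome-wide scans for depletion of proximal out-of-frame downstream ATGs.

If scanning ribosomes compete between closely spaced start codons, an
out-of-frame ATG shortly downstream of a gene's annotated start (a
"proximal dATG") reduces initiation at the canonical start and is expected
to be purged by purifying selection.  This module counts, for every
position in the early coding region, how many genes harbour a dATG there,
stratified by reading frame and -3 context, tests the positional trend by
rank correlation, compares expression strata, and scores the codon
adaptation index (CAI) of the early coding region.

Coordinates follow the reporter-library convention: the A of the annotated
start is +1, so the first downstream codon starts at +4.  The 45-nt region
downstream of the start spans +4..+48 and is scanned for ATGs whose A lies
at +4..+46.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats

__all__ = [
    "CdsRecord",
    "PositionalCounts",
    "read_cds_fasta",
    "filter_cds",
    "count_datg_positions",
    "positional_trend",
    "stratified_counts",
    "cai_score",
    "relative_adaptiveness",
]

_FRAME_LABELS = {0: "0", 1: "+1", 2: "+2"}


@dataclass(frozen=True)
class CdsRecord:
    """One coding sequence (annotated start codon at the 5' end)."""

    gene_id: str
    sequence: str
    expression: float | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 3:
            raise ValueError(f"{self.gene_id}: CDS shorter than one codon")
        if set(seq) - set("ACGT"):
            raise ValueError(f"{self.gene_id}: CDS contains non-ACGT characters")


def read_cds_fasta(
    path: str | Path, expression: Mapping[str, float] | None = None
) -> list[CdsRecord]:
    """Load CDS records from FASTA, skipping sequences with ambiguous bases."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if set(seq) - set("ACGT"):
            continue
        expr = expression.get(rec.id) if expression is not None else None
        records.append(CdsRecord(rec.id, seq, expr))
    return records


def filter_cds(records: Sequence[CdsRecord], min_len: int = 45) -> tuple[list[CdsRecord], dict]:
    """Keep CDS that start with ATG and are at least ``min_len`` nt long."""
    if not records:
        raise ValueError("empty CDS input")
    kept, removed = [], {"non_atg_start": 0, "too_short": 0}
    for rec in records:
        if not rec.sequence.startswith("ATG"):
            removed["non_atg_start"] += 1
        elif len(rec.sequence) < min_len:
            removed["too_short"] += 1
        else:
            kept.append(rec)
    return kept, removed


@dataclass
class PositionalCounts:
    """Number of genes with a dATG at each position/frame/context stratum."""

    n_genes: int
    window: int
    counts: pd.DataFrame  # columns: position, frame, context, n_genes

    def frame_positions(self, frame: str) -> list[int]:
        """All scannable positions of one frame within the window."""
        offset = {v: k for k, v in _FRAME_LABELS.items()}[frame]
        return [p for p in range(4, self.window + 2) if (p - 1) % 3 == offset]

    def by_frame(self, frame: str, context: str | None = None) -> pd.Series:
        """Gene counts per position for one frame (optionally one context).

        Positions where no gene carries a dATG are reported as zero, not
        dropped; they carry signal for the positional trend.
        """
        df = self.counts[self.counts["frame"] == frame]
        if context is not None:
            df = df[df["context"] == context]
        series = df.groupby("position")["n_genes"].sum()
        return series.reindex(self.frame_positions(frame), fill_value=0)


def count_datg_positions(
    records: Sequence[CdsRecord], window: int = 45
) -> PositionalCounts:
    """Count genes harbouring a dATG at each early-CDS position.

    The scanned region is the ``window`` nt downstream of the annotated
    start (positions +4..+(window+3)); an ATG is counted at the position
    of its A, which can lie at +4..+(window+1).  The -3 context of each
    dATG is read from the CDS itself (for dATGs at +4..+6 it falls inside
    the annotated ATG, mirroring the reporter-library convention).  A gene
    contributes at most once per (position, frame, context) cell.
    """

    tallies: dict[tuple[int, int, str], int] = {}
    last_a = window + 1  # last position whose triplet fits in +4..+(window+3)
    for rec in records:
        seq = rec.sequence
        for pos in range(4, last_a + 1):
            i = pos - 1  # 0-based index of the A
            if i + 3 <= len(seq) and seq[i : i + 3] == "ATG":
                frame = (pos - 1) % 3
                context = seq[i - 3]
                key = (pos, frame, context)
                tallies[key] = tallies.get(key, 0) + 1
    rows = [
        (pos, _FRAME_LABELS[frame], context, n)
        for (pos, frame, context), n in sorted(tallies.items())
    ]
    counts = pd.DataFrame(rows, columns=["position", "frame", "context", "n_genes"])
    return PositionalCounts(n_genes=len(records), window=window, counts=counts)


def positional_trend(
    counts: PositionalCounts, by_context: bool = False
) -> pd.DataFrame:
    """Spearman rank correlation of gene count versus position per stratum.

    A positive correlation (counts rising with distance from the start)
    indicates depletion of proximal dATGs.  Strata with fewer than 3
    positions or constant counts are flagged as undefined.
    """

    strata: list[tuple[tuple, pd.Series]] = []
    if by_context:
        for (frame, context), _ in counts.counts.groupby(["frame", "context"]):
            strata.append(((frame, context), counts.by_frame(frame, context)))
    else:
        for frame in sorted(counts.counts["frame"].unique()):
            strata.append(((frame,), counts.by_frame(frame)))
    rows = []
    for key, series in strata:
        n = len(series)
        if n < 3 or series.nunique() == 1:
            rho, p, defined = np.nan, np.nan, False
        else:
            rho, p = stats.spearmanr(series.index.to_numpy(), series.to_numpy())
            defined = True
        rows.append((*key, n, rho, p, defined))
    cols = (["frame", "context"] if by_context else ["frame"]) + ["n_positions", "rho", "p_value", "defined"]
    return pd.DataFrame(rows, columns=cols)


def stratified_counts(
    records: Sequence[CdsRecord],
    top_n: int = 2000,
    bottom_n: int = 2000,
    window: int = 45,
) -> tuple[PositionalCounts, PositionalCounts, pd.DataFrame]:
    """Positional dATG counts for the highest- vs lowest-expression genes.

    Genes are ranked by their ``expression`` attribute (ties broken
    deterministically by gene id); returns counts for both strata and a
    per-position/frame comparison (high minus low).
    """

    annotated = [r for r in records if r.expression is not None]
    if len(annotated) < top_n + bottom_n:
        raise ValueError(
            f"need expression for at least {top_n + bottom_n} genes, have {len(annotated)}"
        )
    ordered = sorted(annotated, key=lambda r: (-r.expression, r.gene_id))
    high = count_datg_positions(ordered[:top_n], window)
    low = count_datg_positions(ordered[-bottom_n:], window)

    def per_cell(pc: PositionalCounts) -> pd.Series:
        return pc.counts.groupby(["position", "frame"])["n_genes"].sum()

    cmp = pd.concat(
        [per_cell(high).rename("high"), per_cell(low).rename("low")], axis=1
    ).fillna(0)
    cmp["difference"] = cmp["high"] - cmp["low"]
    return high, low, cmp.reset_index()


# ---------------------------------------------------------------------------
# codon adaptation index

_GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D",
    "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R",
    "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R",
    "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def relative_adaptiveness(
    sequences: Iterable[str], zero_weight: float = 0.01
) -> dict[str, float]:
    """Codon weights from a reference gene set (e.g. highly expressed genes).

    Each sense codon's weight is its count divided by the count of the
    most used synonymous codon for the same amino acid; codons never seen
    receive ``zero_weight``.
    """

    counts: dict[str, int] = {c: 0 for c in _GENETIC_CODE}
    for seq in sequences:
        seq = seq.upper()
        for i in range(0, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon in counts:
                counts[codon] += 1
    by_aa: dict[str, int] = {}
    for codon, aa in _GENETIC_CODE.items():
        by_aa[aa] = max(by_aa.get(aa, 0), counts[codon])
    weights = {}
    for codon, aa in _GENETIC_CODE.items():
        if by_aa[aa] == 0 or counts[codon] == 0:
            weights[codon] = zero_weight
        else:
            weights[codon] = counts[codon] / by_aa[aa]
    return weights


def cai_score(region: str, weights: Mapping[str, float]) -> float:
    """CAI of a coding region: geometric mean of its codons' weights.

    Intended for the early coding region (e.g. the 30 nt / 10 codons
    downstream of the annotated start).  The region length must be a
    multiple of 3 and every codon must have a weight in (0, 1].
    """

    region = region.upper()
    if len(region) == 0 or len(region) % 3 != 0:
        raise ValueError("region length must be a positive multiple of 3")
    log_sum = 0.0
    n = 0
    for i in range(0, len(region), 3):
        codon = region[i : i + 3]
        if codon not in weights:
            raise ValueError(f"codon {codon} absent from the weight table")
        w = weights[codon]
        if not (0 < w <= 1):
            raise ValueError(f"weight for {codon} must be in (0, 1], got {w}")
        log_sum += math.log(w)
        n += 1
    return math.exp(log_sum / n)
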