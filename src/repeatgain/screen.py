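"""Saturation mutagenesis around pseudoexon splice junctions.

Splice-modulator drugs act on exon/pseudoexon splice sites, and sequence
variants near those sites can sensitize a gene to the drug or make it
refractory.  This module enumerates every possible SNV within a flank
(default 50 nt) on either side of each splice junction, scores each variant
with a pluggable splice scorer, and classifies variants by the sign of the
score change: positive deltas predict enhanced pseudoexon inclusion
(sensitizing), negative deltas predict interference.

The shipped :class:`PwmSpliceScorer` is a position-weight-matrix donor /
acceptor scorer built on fixed consensus-frequency matrices (9-mer donor,
15-mer acceptor) with scores min-max normalized to [0, 1], so the whole
screen runs without any neural-network dependency.  Any object with the
same ``score(sequence, junction)`` contract (a probability-like value in
[0, 1]) can be substituted.

Coordinates are 1-based.  A junction's ``position`` is the intron-side base
adjacent to the exon-intron boundary; the mutagenesis window is the
``flank`` nt immediately on each side of that boundary (100 positions at
the default flank of 50).  Minus-strand junctions are scored on the
reverse complement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CoordinateError, EmptyInputError, FormatError

__all__ = [
    "SpliceJunction",
    "SNV",
    "SpliceDelta",
    "PwmSpliceScorer",
    "generate_saturation_snvs",
    "score_variants",
    "check_exon_annotation",
    "dataset_overlap",
    "write_snv_vcf",
    "read_junctions",
    "exclude_intron_retention",
]

NUCLEOTIDES = ("A", "C", "G", "T")
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: common/rare boundary on minor allele frequency
COMMON_MAF = 0.01
#: default |delta| needed to call a variant sensitizing or interfering
DEFAULT_DELTA_THRESHOLD = 0.1


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SpliceJunction:
    """One splice site: ``position`` is the 1-based coordinate of the
    intron-side base adjacent to the exon-intron boundary."""

    seq_id: str
    position: int
    side: str  # "donor" (5'ss) | "acceptor" (3'ss)
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.side not in ("donor", "acceptor"):
            raise ValueError(f"side must be donor|acceptor, got {self.side!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be +|-, got {self.strand!r}")

    def boundary_index(self) -> int:
        """0-based index of the first base downstream of the boundary
        (in plus-strand coordinates)."""
        if self.strand == "+":
            return self.position - 1 if self.side == "donor" else self.position
        return self.position if self.side == "donor" else self.position - 1


@dataclass(frozen=True)
class SNV:
    """A single-nucleotide variant, 1-based, with optional MAF."""

    seq_id: str
    position: int
    ref: str
    alt: str
    allele_frequency: float | None = None

    def __post_init__(self) -> None:
        if self.ref not in NUCLEOTIDES or self.alt not in NUCLEOTIDES:
            raise ValueError(f"ref/alt must be one of {NUCLEOTIDES}")
        if self.ref == self.alt:
            raise ValueError("alt must differ from ref")


@dataclass(frozen=True)
class SpliceDelta:
    """Scored variant: delta = score(mutated) - score(reference).

    ``classification`` is sensitizing (delta >= +threshold), interfering
    (delta <= -threshold), nonsignificant otherwise, or "error" when the
    scorer failed on this variant (then ``delta`` is NaN and ``error``
    holds the message).
    """

    snv: SNV
    delta: float
    classification: str
    frequency_class: str = "unknown"
    junction: SpliceJunction | None = None
    error: str | None = None


# Consensus base frequencies for human splice sites; rows are positions in
# transcript orientation, columns A/C/G/T.  Donor covers exonic -3..-1 plus
# intronic +1..+6; acceptor covers intronic -14..-1 plus the first exonic
# base.  Near-invariant GT/AG dinucleotides carry small pseudocounts so
# log-odds stay finite.
DONOR_PWM = np.array(
    [
        [0.33, 0.37, 0.18, 0.12],  # -3
        [0.60, 0.13, 0.13, 0.14],  # -2
        [0.08, 0.04, 0.80, 0.08],  # -1
        [0.001, 0.001, 0.997, 0.001],  # +1 G
        [0.001, 0.001, 0.001, 0.997],  # +2 T
        [0.59, 0.03, 0.35, 0.03],  # +3
        [0.71, 0.08, 0.12, 0.09],  # +4
        [0.06, 0.06, 0.82, 0.06],  # +5
        [0.15, 0.17, 0.19, 0.49],  # +6
    ]
)
_PYRIMIDINE = [0.10, 0.31, 0.10, 0.49]
ACCEPTOR_PWM = np.array(
    [_PYRIMIDINE] * 10  # -14..-5 polypyrimidine tract
    + [
        [0.24, 0.28, 0.22, 0.26],  # -4
        [0.04, 0.75, 0.01, 0.20],  # -3
        [0.997, 0.001, 0.001, 0.001],  # -2 A
        [0.001, 0.001, 0.997, 0.001],  # -1 G
        [0.25, 0.14, 0.49, 0.12],  # +1 (first exonic base)
    ]
)
#: donor site spans boundary-3 .. boundary+5 (transcript orientation)
DONOR_SPAN = (-3, 6)
#: acceptor site spans boundary-14 .. boundary (transcript orientation)
ACCEPTOR_SPAN = (-14, 1)


class PwmSpliceScorer:
    """Log-odds PWM splice-site scorer normalized to [0, 1].

    The raw score of a site k-mer is the summed log2 odds of each base
    against a uniform background; it is mapped to [0, 1] by min-max
    normalization over all possible k-mers, so 1 is the exact consensus
    and 0 the worst possible site.
    """

    def __init__(self) -> None:
        self._logodds = {
            "donor": np.log2(DONOR_PWM / 0.25),
            "acceptor": np.log2(ACCEPTOR_PWM / 0.25),
        }
        self._span = {"donor": DONOR_SPAN, "acceptor": ACCEPTOR_SPAN}

    def site_sequence(self, sequence: str, junction: SpliceJunction) -> str:
        """Extract the site k-mer in transcript orientation."""
        b = junction.boundary_index()
        lo, hi = self._span[junction.side]
        if junction.strand == "+":
            start, stop = b + lo, b + hi
            if start < 0 or stop > len(sequence):
                raise CoordinateError(
                    f"junction {junction} site window [{start}, {stop}) outside sequence"
                )
            return sequence[start:stop].upper()
        rc = revcomp(sequence)
        b_rc = len(sequence) - b
        start, stop = b_rc + lo, b_rc + hi
        if start < 0 or stop > len(rc):
            raise CoordinateError(
                f"junction {junction} site window outside sequence (minus strand)"
            )
        return rc[start:stop].upper()

    def score(self, sequence: str, junction: SpliceJunction) -> float:
        site = self.site_sequence(sequence, junction)
        lo_mat = self._logodds[junction.side]
        try:
            idx = [NUCLEOTIDES.index(base) for base in site]
        except ValueError:
            raise CoordinateError(f"non-ACGT base in site {site!r}") from None
        raw = float(lo_mat[np.arange(len(site)), idx].sum())
        smin = float(lo_mat.min(axis=1).sum())
        smax = float(lo_mat.max(axis=1).sum())
        return (raw - smin) / (smax - smin)


def _covered_positions(junction: SpliceJunction, seq_len: int, flank: int) -> range:
    """1-based positions covered by the mutagenesis window, truncated at
    the sequence ends."""
    b = junction.boundary_index()
    if not 0 <= b <= seq_len:
        raise CoordinateError(
            f"junction {junction} outside sequence of length {seq_len}"
        )
    start0 = max(0, b - flank)
    stop0 = min(seq_len, b + flank)
    return range(start0 + 1, stop0 + 1)


def generate_saturation_snvs(
    sequence: str,
    junctions: Iterable[SpliceJunction],
    flank: int = 50,
) -> list[SNV]:
    """Enumerate all SNVs within ``flank`` nt of each junction boundary.

    Each covered position yields the three non-reference alleles; windows
    of overlapping junctions are deduplicated, and windows running off the
    sequence ends are truncated cleanly.
    """
    sequence = sequence.upper()
    seen: set[tuple[str, int, str]] = set()
    out: list[SNV] = []
    for j in junctions:
        for pos in _covered_positions(j, len(sequence), flank):
            ref = sequence[pos - 1]
            if ref not in NUCLEOTIDES:
                continue
            for alt in NUCLEOTIDES:
                if alt == ref or (j.seq_id, pos, alt) in seen:
                    continue
                seen.add((j.seq_id, pos, alt))
                out.append(SNV(seq_id=j.seq_id, position=pos, ref=ref, alt=alt))
    out.sort(key=lambda s: (s.seq_id, s.position, s.alt))
    return out


def _nearest_junction(snv: SNV, junctions: Sequence[SpliceJunction]) -> SpliceJunction:
    candidates = [j for j in junctions if j.seq_id == snv.seq_id]
    if not candidates:
        raise CoordinateError(f"no junction on sequence {snv.seq_id!r}")
    return min(candidates, key=lambda j: (abs(snv.position - 1 - j.boundary_index()), j.position))


def _frequency_class(af: float | None) -> str:
    if af is None or (isinstance(af, float) and math.isnan(af)):
        return "unknown"
    return "common" if af > COMMON_MAF else "rare"


def score_variants(
    scorer,
    snvs: Sequence[SNV],
    sequence: str,
    junctions: Sequence[SpliceJunction],
    threshold: float = DEFAULT_DELTA_THRESHOLD,
) -> list[SpliceDelta]:
    """Score each SNV against its nearest junction.

    delta = score(mutated sequence) - score(reference sequence); one
    record per input, in input order.  A scorer failure on one variant is
    recorded on that record (classification "error") and the batch
    continues.
    """
    sequence = sequence.upper()
    ref_scores: dict[SpliceJunction, float] = {}
    out: list[SpliceDelta] = []
    for snv in snvs:
        try:
            junction = _nearest_junction(snv, junctions)
            if not 1 <= snv.position <= len(sequence):
                raise CoordinateError(f"SNV position {snv.position} outside sequence")
            if sequence[snv.position - 1] != snv.ref:
                raise CoordinateError(
                    f"ref mismatch at {snv.position}: sequence has "
                    f"{sequence[snv.position - 1]!r}, SNV says {snv.ref!r}"
                )
            if junction not in ref_scores:
                ref_scores[junction] = scorer.score(sequence, junction)
            mutated = (
                sequence[: snv.position - 1] + snv.alt + sequence[snv.position:]
            )
            delta = scorer.score(mutated, junction) - ref_scores[junction]
            if delta >= threshold:
                cls = "sensitizing"
            elif delta <= -threshold:
                cls = "interfering"
            else:
                cls = "nonsignificant"
            out.append(
                SpliceDelta(
                    snv=snv,
                    delta=float(delta),
                    classification=cls,
                    frequency_class=_frequency_class(snv.allele_frequency),
                    junction=junction,
                )
            )
        except Exception as exc:  # record and continue: one bad variant
            out.append(                # must not sink the batch
                SpliceDelta(
                    snv=snv,
                    delta=float("nan"),
                    classification="error",
                    frequency_class=_frequency_class(snv.allele_frequency),
                    error=str(exc),
                )
            )
    return out


def check_exon_annotation(
    exon: tuple[str, int, int],
    annotation: str | Path | pd.DataFrame,
    tolerance: int = 1,
) -> str:
    """Compare an exon against a GFF3 annotation with a coordinate tolerance.

    ``exon`` is (seq_id, start, end), 1-based inclusive.  Returns
    "annotated" when some exon record on the same sequence matches both
    boundaries within ``tolerance`` nt, else "novel".
    """
    seq_id, start, end = exon
    if isinstance(annotation, pd.DataFrame):
        exons = annotation
    else:
        try:
            import pyranges as pr

            gr = pr.read_gff3(str(annotation))
            df = gr.df
        except Exception as exc:
            raise FormatError(f"cannot parse GFF3 {annotation}: {exc}") from exc
        exons = pd.DataFrame(
            {
                "seq_id": df["Chromosome"].astype(str),
                # pyranges stores 0-based half-open intervals
                "start": df["Start"].astype(int) + 1,
                "end": df["End"].astype(int),
                "feature": df["Feature"].astype(str),
            }
        )
        exons = exons[exons["feature"] == "exon"]
    hit = (
        (exons["seq_id"] == seq_id)
        & ((exons["start"] - start).abs() <= tolerance)
        & ((exons["end"] - end).abs() <= tolerance)
    )
    return "annotated" if bool(hit.any()) else "novel"


def dataset_overlap(gene_sets: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Row-normalized overlap matrix between named gene sets.

    Entry (row, col) = |row ∩ col| / |row|; the diagonal is 1.  The matrix
    is generally asymmetric because each row is normalized by its own set
    size.
    """
    sets = {name: set(genes) for name, genes in gene_sets.items()}
    if len(sets) < 2:
        raise EmptyInputError("need at least two named gene sets")
    empty = [name for name, s in sets.items() if not s]
    if empty:
        raise EmptyInputError(f"empty gene set(s): {empty}")
    names = list(sets)
    mat = pd.DataFrame(
        [[len(sets[r] & sets[c]) / len(sets[r]) for c in names] for r in names],
        index=names,
        columns=names,
    )
    return mat


def read_junctions(path: str | Path) -> list[SpliceJunction]:
    """Read junctions from a CSV with columns seq_id, position, side, strand."""
    df = pd.read_csv(path)
    needed = {"seq_id", "position", "side"}
    if not needed <= set(df.columns):
        raise FormatError(f"junction table needs columns {sorted(needed)}")
    return [
        SpliceJunction(
            seq_id=str(r.seq_id),
            position=int(r.position),
            side=str(r.side),
            strand=str(getattr(r, "strand", "+")),
        )
        for r in df.itertuples()
    ]


def exclude_intron_retention(
    events: pd.DataFrame, type_col: str = "event_type"
) -> pd.DataFrame:
    """Drop intron-retention rows from a drug-responsive event list.

    Retention events are not comparable to exon/pseudoexon inclusion
    events; when the table carries a per-event type column they are
    excluded, otherwise the table passes through unchanged.
    """
    if type_col not in events.columns:
        return events
    mask = (
        events[type_col].astype(str).str.lower().str.replace(" ", "_")
        != "intron_retention"
    )
    return events[mask].reset_index(drop=True)


def write_snv_vcf(deltas: Sequence[SpliceDelta], path: str | Path) -> Path:
    """Write scored variants as a minimal VCF 4.2 with DELTA/CLS/AF INFO."""
    path = Path(path)
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=DELTA,Number=1,Type=Float,Description="Splice score delta (mut - ref)">',
        '##INFO=<ID=CLS,Number=1,Type=String,Description="sensitizing|interfering|nonsignificant|error">',
        '##INFO=<ID=AF,Number=1,Type=Float,Description="Minor allele frequency">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for d in deltas:
        info = [f"CLS={d.classification}"]
        if not math.isnan(d.delta):
            info.insert(0, f"DELTA={d.delta:.6f}")
        if d.snv.allele_frequency is not None:
            info.append(f"AF={d.snv.allele_frequency:.6g}")
        lines.append(
            "\t".join(
                [
                    d.snv.seq_id,
                    str(d.snv.position),
                    ".",
                    d.snv.ref,
                    d.snv.alt,
                    ".",
                    ".",
                    ";".join(info),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path
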