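"""CRISPR amplicon editing outcomes and clone zygosity calls.

An amplicon-sequencing analysis (e.g. CRISPResso) reports, per clone, the
alleles observed at the cut site and the fraction of reads supporting each.
Rows sharing an indel signature are aggregated, ranked by read fraction,
and the clone is called homozygous when the top outcome accounts for
strictly more than 85% of the reads carried by the two most frequent
outcomes; otherwise heterozygous.  Reference (unedited) alleles are
eligible for either of the top-two slots, so unedited and monoallelically
edited clones are handled by the same rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .errors import DegenerateOutcomeError, EmptyInputError

__all__ = [
    "EditingOutcome",
    "ZygosityCall",
    "aggregate_outcomes",
    "call_zygosity",
    "call_zygosity_table",
    "HOMOZYGOUS_RATIO",
]

#: a clone is homozygous when top/(top+second) exceeds this, strictly
HOMOZYGOUS_RATIO = 0.85


@dataclass(frozen=True)
class EditingOutcome:
    """One aggregated allele outcome with its read fraction."""

    signature: str
    read_fraction: float
    is_reference: bool = False


@dataclass(frozen=True)
class ZygosityCall:
    call: str  # "homozygous" | "heterozygous"
    top_fraction_of_top_two: float
    top_signature: str
    second_signature: str | None
    top_is_reference: bool = False
    second_is_reference: bool = False


def aggregate_outcomes(raw: pd.DataFrame) -> list[EditingOutcome]:
    """Merge rows by signature and rank by descending read fraction.

    ``raw`` needs a ``signature`` column plus either ``reads`` (counts,
    normalized here) or ``fraction``.  Ties in fraction break
    lexicographically by signature so ranking is deterministic.
    """
    if raw is None or raw.empty:
        raise EmptyInputError("no editing outcomes to aggregate")
    df = raw.copy()
    if "fraction" in df.columns:
        df["fraction"] = df["fraction"].astype(float)
    elif "reads" in df.columns:
        total = df["reads"].astype(float).sum()
        if total <= 0:
            raise EmptyInputError("editing outcome table has zero total reads")
        df["fraction"] = df["reads"].astype(float) / total
    else:
        raise EmptyInputError("need a 'reads' or 'fraction' column")
    if "is_reference" not in df.columns:
        df["is_reference"] = False
    agg = (
        df.groupby("signature", as_index=False)
        .agg(fraction=("fraction", "sum"), is_reference=("is_reference", "any"))
        .sort_values(["fraction", "signature"], ascending=[False, True], kind="stable")
    )
    return [
        EditingOutcome(
            signature=str(r.signature),
            read_fraction=float(r.fraction),
            is_reference=bool(r.is_reference),
        )
        for r in agg.itertuples()
    ]


def call_zygosity(outcomes: list[EditingOutcome]) -> ZygosityCall:
    """Apply the 85%-of-top-two rule to ranked outcomes.

    A single-outcome clone is trivially homozygous (ratio 1.0) with a
    low-complexity warning, since there is no second allele to weigh
    against.
    """
    if not outcomes:
        raise EmptyInputError("no outcomes to call zygosity from")
    top = outcomes[0]
    if len(outcomes) == 1:
        warnings.warn(
            f"single aggregated outcome {top.signature!r}: homozygous call "
            "with top-two ratio 1.0 (low outcome complexity)",
            stacklevel=2,
        )
        return ZygosityCall(
            call="homozygous",
            top_fraction_of_top_two=1.0,
            top_signature=top.signature,
            second_signature=None,
            top_is_reference=top.is_reference,
        )
    second = outcomes[1]
    mass = top.read_fraction + second.read_fraction
    if mass <= 0:
        raise DegenerateOutcomeError("top two outcomes carry zero read mass")
    ratio = top.read_fraction / mass
    return ZygosityCall(
        call="homozygous" if ratio > HOMOZYGOUS_RATIO else "heterozygous",
        top_fraction_of_top_two=float(ratio),
        top_signature=top.signature,
        second_signature=second.signature,
        top_is_reference=top.is_reference,
        second_is_reference=second.is_reference,
    )


def call_zygosity_table(raw: pd.DataFrame, clone_col: str = "clone_id") -> pd.DataFrame:
    """Aggregate and call zygosity for every clone in an outcome table."""
    if raw is None or raw.empty:
        raise EmptyInputError("empty editing outcome table")
    rows = []
    for clone, grp in raw.groupby(clone_col, sort=True):
        call = call_zygosity(aggregate_outcomes(grp))
        rows.append(
            {
                clone_col: clone,
                "call": call.call,
                "top_fraction_of_top_two": call.top_fraction_of_top_two,
                "top_signature": call.top_signature,
                "second_signature": call.second_signature,
                "top_is_reference": call.top_is_reference,
                "second_is_reference": call.second_is_reference,
            }
        )
    return pd.DataFrame(rows)
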