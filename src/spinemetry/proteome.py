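"""Differential-expression retention rule for protein tables.

A protein is called differentially expressed when it was quantified
from at least 2 peptides, its q-value is at most 0.05, and its fold
change lies outside the +/-20% band on the linear scale, i.e. its log2
fold change falls outside the asymmetric interval
[-0.321, 0.263] = [log2 0.8, log2 1.2].  Retained proteins with log2FC
at or above the upper threshold are up-regulated; at or below the
lower threshold, down-regulated.  All comparisons are inclusive.

The packaged reference table (``data/dht_vs_wt_proteins.tsv``) holds
the published differential quantification of intrafusal muscle-spindle
proteins in compound-heterozygous (dHT) vs wild-type mice: 38 proteins
with linear fold change and q-value; the rule above splits it into 14
up- and 24 down-regulated proteins.  Peptide counts are not part of
the published list, so the fixture sets n_peptides = 2 (every listed
protein passed the >= 2 peptide cut by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Sequence

from .errors import UsageError
from .io import ProteinQuantRecord, read_protein_table

__all__ = ["DifferentialCallSet", "filter_differential", "load_reference_table"]

ExclusionReason = Literal["low_peptides", "q_fail", "fc_band"]


@dataclass
class DifferentialCallSet:
    """Partition of a protein table into up / down / excluded calls."""

    up: list[ProteinQuantRecord] = field(default_factory=list)
    down: list[ProteinQuantRecord] = field(default_factory=list)
    excluded: list[tuple[ProteinQuantRecord, ExclusionReason]] = field(
        default_factory=list
    )

    @property
    def n_total(self) -> int:
        return len(self.up) + len(self.down) + len(self.excluded)


def filter_differential(
    records: Sequence[ProteinQuantRecord],
    min_peptides: int = 2,
    log2fc_lower: float = -0.321,
    log2fc_upper: float = 0.263,
    q_max: float = 0.05,
) -> DifferentialCallSet:
    """Apply the retention rule and partition the records.

    Exclusion reasons record the first failing criterion in the order
    peptides -> q-value -> fold-change band.
    """
    if not (log2fc_lower < 0 < log2fc_upper):
        raise UsageError("log2FC thresholds must satisfy lower < 0 < upper")
    if not (0 < q_max <= 1):
        raise UsageError("q_max must be in (0, 1]")
    calls = DifferentialCallSet()
    for rec in records:
        if rec.n_peptides < min_peptides:
            calls.excluded.append((rec, "low_peptides"))
        elif rec.q_value > q_max:
            calls.excluded.append((rec, "q_fail"))
        elif log2fc_lower < rec.log2_fold_change < log2fc_upper:
            calls.excluded.append((rec, "fc_band"))
        elif rec.log2_fold_change >= log2fc_upper:
            calls.up.append(rec)
        else:
            calls.down.append(rec)
    return calls


def load_reference_table() -> list[ProteinQuantRecord]:
    """The packaged dHT-vs-WT intrafusal differential protein table."""
    path = resources.files("spinemetry.data") / "dht_vs_wt_proteins.tsv"
    with resources.as_file(path) as p:
        return read_protein_table(p)
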