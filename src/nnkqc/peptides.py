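"""Translation of validated NNK inserts and stop-codon classification.

Inserts fall into three classes mirroring the standard library-QC pie chart:
``no_stop`` (clean display), ``uag_only`` (at least one amber codon, read
through as Gln in supE44+ hosts) and ``other_stop`` (at least one TGA/TAA,
which no common suppressor rescues).  ``other_stop`` outranks ``uag_only``
when both occur.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .design import AMBER, LibraryDesign, OCHRE, OPAL, translate_codon

NO_STOP = "no_stop"
UAG_ONLY = "uag_only"
OTHER_STOP = "other_stop"
STOP_CLASSES = (NO_STOP, UAG_ONLY, OTHER_STOP)


def translate_nnk(insert: str, amber_as_q: bool = True) -> str:
    """Translate an insert codon-by-codon under the standard code.

    TAG becomes 'Q' when ``amber_as_q`` (supE44 suppression) and '*'
    otherwise; TGA is always '*' (no opal suppressor).
    """
    if len(insert) % 3 != 0:
        raise ValueError(f"insert length {len(insert)} not divisible by 3")
    return "".join(
        translate_codon(insert[i : i + 3], amber_as_q) for i in range(0, len(insert), 3)
    )


def classify_stops(insert: str) -> str:
    """Assign an insert to no_stop / uag_only / other_stop.

    TAA cannot occur in NNK-validated input (third base A) but is handled for
    robustness when validation is bypassed.
    """
    codons = [insert[i : i + 3] for i in range(0, len(insert), 3)]
    if OPAL in codons or OCHRE in codons:
        return OTHER_STOP
    if AMBER in codons:
        return UAG_ONLY
    return NO_STOP


@dataclass
class PeptideTable:
    """Translated inserts with read counts and stop classes.

    ``rows`` columns: insert, peptide, count, stop_class.  Uniqueness is at
    the nucleotide-insert level (synonymous NNK codons encode distinct rows);
    ``unique_peptide_sequences`` gives the peptide-level count.
    """

    rows: pd.DataFrame
    design: LibraryDesign
    amber_as_q: bool

    @property
    def total_peptides(self) -> int:
        return int(self.rows["count"].sum())

    @property
    def unique_peptides(self) -> int:
        return len(self.rows)

    @property
    def unique_peptide_sequences(self) -> int:
        return self.rows["peptide"].nunique()

    def class_fractions(self, weighting: str = "reads") -> dict[str, float]:
        """Stop-class fractions weighted by read count or by unique sequence.

        Empty tables yield NaN fractions (undefined, not zero).
        """
        if weighting not in ("reads", "unique"):
            raise ValueError(f"unknown weighting {weighting!r}")
        if len(self.rows) == 0:
            return {c: float("nan") for c in STOP_CLASSES}
        if weighting == "reads":
            weights = self.rows.groupby("stop_class")["count"].sum()
            total = self.total_peptides
        else:
            weights = self.rows.groupby("stop_class").size()
            total = self.unique_peptides
        return {c: float(weights.get(c, 0)) / total for c in STOP_CLASSES}


def tabulate(inserts, amber_as_q: bool = True) -> PeptideTable:
    """Translate an InsertTable into a PeptideTable.

    The full insert (fixed cysteines included for constrained designs) is
    translated; stop classification scans every codon.
    """
    design = inserts.design
    records = []
    for insert, count in inserts.counts.items():
        records.append(
            {
                "insert": insert,
                "peptide": translate_nnk(insert, amber_as_q),
                "count": int(count),
                "stop_class": classify_stops(insert),
            }
        )
    rows = pd.DataFrame(
        records, columns=["insert", "peptide", "count", "stop_class"]
    ).sort_values("insert", ignore_index=True)
    return PeptideTable(rows=rows, design=design, amber_as_q=amber_as_q)
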