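"""Library layout and NNK genetic-code machinery.

An NNK degenerate codon has any base (N) at positions 1-2 and G or T (K) at
position 3.  The 32 NNK codons encode all 20 amino acids; because TAA and
TGA both end in A, the only stop left in the set is TAG (amber), which
supE44 hosts read through as glutamine.  Everything downstream — read
filtering, translation, composition statistics — consumes the types defined
here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import yaml
from Bio.Data.CodonTable import unambiguous_dna_by_id

BASES = "ACGT"
K_BASES = "GT"

_STANDARD = unambiguous_dna_by_id[1]
#: codon -> one-letter residue, '*' for the three standard stops
CODON_TABLE: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    CODON_TABLE[_stop] = "*"

#: the 32 NNK codons (third base G or T), lexicographic order
NNK_CODONS: tuple[str, ...] = tuple(
    a + b + c for a, b, c in itertools.product(BASES, BASES, K_BASES)
)

# TAG is the only stop reachable under NNK: TAA and TGA both end in A,
# which the K (G/T) constraint excludes.
STOP_CODONS_IN_NNK = frozenset({"TAG"})

AMBER = "TAG"
OPAL = "TGA"
OCHRE = "TAA"

#: rejection reasons shared with the preprocess filters
REASON_WRONG_LENGTH = "wrong_length"
REASON_NON_NNK = "non_nnk"
REASON_MISSING_CYS = "missing_cys"
REASON_AMBIGUOUS = "ambiguous_base"


def _check_dna(name: str, seq: str, allow_empty: bool = True) -> None:
    if not allow_empty and not seq:
        raise ValueError(f"{name} must be non-empty")
    bad = set(seq) - set(BASES)
    if bad:
        raise ValueError(f"{name} contains non-ACGT characters: {sorted(bad)}")


@dataclass(frozen=True)
class LibraryDesign:
    """Immutable description of one library's amplicon layout.

    The simulated/sequenced read is laid out as::

        upstream_flank  [cys]  insert  [cys]  downstream_flank

    with the barcode a substring of ``upstream_flank`` starting at
    ``barcode_offset`` (0-based from the read start).  Coordinates are
    0-based, half-open throughout.

    Parameters
    ----------
    name : str
        Label, e.g. ``"C10C"`` for a cysteine-looped 10-mer.
    n_random_codons : int
        Number of random NNK codons (7, 8, 10, ...).
    constrained : bool
        True for cysteine-looped (CXnC) designs; fixed cysteine codons flank
        the random region.
    cys_codon : str
        Codon used for the fixed cysteines; TGT by default (NNK-compatible).
    """

    name: str
    n_random_codons: int
    constrained: bool = False
    cys_codon: str = "TGT"
    upstream_flank: str = ""
    downstream_flank: str = ""
    barcode: str = ""
    barcode_offset: int = 0

    def __post_init__(self) -> None:
        if self.n_random_codons < 1:
            raise ValueError("n_random_codons must be >= 1")
        _check_dna("upstream_flank", self.upstream_flank)
        _check_dna("downstream_flank", self.downstream_flank)
        _check_dna("barcode", self.barcode)
        if len(self.cys_codon) != 3:
            raise ValueError("cys_codon must be a 3-mer")
        _check_dna("cys_codon", self.cys_codon, allow_empty=False)
        if CODON_TABLE[self.cys_codon] != "C":
            raise ValueError(f"cys_codon {self.cys_codon} does not encode cysteine")
        if self.barcode:
            if self.barcode_offset < 0:
                raise ValueError("barcode_offset must be >= 0")
            end = self.barcode_offset + len(self.barcode)
            if end > len(self.upstream_flank):
                raise ValueError("barcode must lie within upstream_flank")
            found = self.upstream_flank[self.barcode_offset : end]
            if found != self.barcode:
                raise ValueError(
                    f"upstream_flank[{self.barcode_offset}:{end}] = {found!r} "
                    f"does not match barcode {self.barcode!r}"
                )

    @property
    def insert_length(self) -> int:
        """Expected insert length in nucleotides (fixed cysteines included)."""
        return 3 * self.n_random_codons + (6 if self.constrained else 0)

    @property
    def read_length(self) -> int:
        """Total length of a defect-free read."""
        return len(self.upstream_flank) + self.insert_length + len(self.downstream_flank)

    def random_region(self, insert: str) -> str:
        """Strip the fixed cysteine codons from a validated insert."""
        return insert[3:-3] if self.constrained else insert


def is_valid_nnk_insert(seq: str, design: LibraryDesign) -> tuple[bool, Optional[str]]:
    """Check a candidate insert against the design's NNK layout.

    Returns ``(True, None)`` or ``(False, reason)`` with exactly one reason,
    evaluated in the fixed order wrong_length -> non_nnk -> missing_cys ->
    ambiguous_base.  Total function: never raises on string input.
    """
    if len(seq) != design.insert_length:
        return False, REASON_WRONG_LENGTH
    random = design.random_region(seq)
    # third base of every random codon must be K (G or T)
    for i in range(2, len(random), 3):
        if random[i] not in K_BASES:
            return False, REASON_NON_NNK
    if design.constrained:
        if seq[:3] != design.cys_codon or seq[-3:] != design.cys_codon:
            return False, REASON_MISSING_CYS
    if set(seq) - set(BASES):
        return False, REASON_AMBIGUOUS
    return True, None


def translate_codon(codon: str, amber_as_q: bool) -> str:
    """Standard genetic code; TAG read through as Gln when amber_as_q."""
    if amber_as_q and codon == AMBER:
        return "Q"
    return CODON_TABLE[codon]


def nnk_degeneracy_table(variant: str = "amber_as_q") -> dict[str, int]:
    """Residue -> number of NNK codons encoding it, by enumeration.

    ``variant`` is ``"amber_as_q"`` (TAG counted as glutamine, so Gln has
    degeneracy 2 and no stop remains among the 32 codons) or
    ``"amber_as_stop"`` (20 residues summing to 31 plus TAG under ``'*'``).
    Counts sum to 32 in both variants.
    """
    if variant not in ("amber_as_q", "amber_as_stop"):
        raise ValueError(f"unknown variant {variant!r}")
    amber_as_q = variant == "amber_as_q"
    table: dict[str, int] = {}
    for codon in NNK_CODONS:
        aa = translate_codon(codon, amber_as_q)
        table[aa] = table.get(aa, 0) + 1
    return table


def theoretical_complexity(design: LibraryDesign) -> int:
    """Amino-acid-level diversity 20^n (fixed cysteines excluded).

    This is the conventional "theoretical complexity" of a random-peptide
    library; the nucleotide-level NNK diversity 32^n is exposed separately
    as :func:`nnk_nucleotide_complexity`.
    """
    return 20 ** design.n_random_codons


def nnk_nucleotide_complexity(design: LibraryDesign) -> int:
    """Nucleotide-level NNK diversity 32^n."""
    return 32 ** design.n_random_codons


def load_design(source: Union[str, Path, dict]) -> LibraryDesign:
    """Build a LibraryDesign from a YAML file path or an already-parsed dict."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh)
    else:
        data = dict(source)
    allowed = {f.name for f in LibraryDesign.__dataclass_fields__.values()}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown design fields: {sorted(unknown)}")
    return LibraryDesign(**data)
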